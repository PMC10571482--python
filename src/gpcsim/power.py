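"""Replicated power experiments for prioritized and non-prioritized GPC.

Each replicate simulates a two-arm trial, derives per-subject rates of
change, sets every outcome's threshold to a common fraction of that
outcome's model rate SD, and tests the net benefit with a permutation test.
Power is the rejection proportion across replicates.  Replicate seeds are
spawned deterministically from one master seed, so runs with the same seed
share datasets across threshold fractions, modes and priority orderings
(common random numbers) and power curves are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .gpc import TREATED, _prioritized_scores, _sign_tensor
from .simulate import GeneratorConfig, derive_rates, generate_trial, rate_sd

__all__ = [
    "ScenarioConfig",
    "PowerResult",
    "run_power_grid",
    "run_scenario",
    "run_marginal_power",
    "run_ordering_sensitivity",
]

DEFAULT_THRESHOLD_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5)


@dataclass
class ScenarioConfig:
    """One power experiment: design constants plus the analysis to run."""

    mode: str = "prioritized"  # prioritized | nonprioritized | marginal
    priority_order: tuple[int, ...] = (1, 2, 3, 4, 5)  # 1-based domain ranks
    threshold_fractions: tuple[float, ...] = DEFAULT_THRESHOLD_FRACTIONS
    n_per_arm: int = 23
    n_replicates: int = 500
    alpha: float = 0.05
    n_permutations: int = 1000
    master_seed: int = 20240

    def __post_init__(self) -> None:
        if self.mode not in ("prioritized", "nonprioritized", "marginal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        fr = tuple(float(f) for f in self.threshold_fractions)
        if any(f < 0 for f in fr):
            raise ValueError("threshold_fractions must be nonnegative")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("threshold_fractions must be strictly increasing")
        self.threshold_fractions = fr
        self.priority_order = tuple(int(i) for i in self.priority_order)
        if sorted(self.priority_order) != list(range(1, len(self.priority_order) + 1)):
            raise ValueError(
                f"priority_order must be a permutation of 1..K, got {self.priority_order}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "priority_order": list(self.priority_order),
            "threshold_fractions": list(self.threshold_fractions),
            "n_per_arm": self.n_per_arm,
            "n_replicates": self.n_replicates,
            "alpha": self.alpha,
            "n_permutations": self.n_permutations,
            "master_seed": self.master_seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown scenario config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("priority_order", "threshold_fractions"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass(frozen=True)
class PowerResult:
    """Empirical rejection rate for one (analysis, threshold fraction) cell."""

    scenario: str
    threshold_fraction: float
    power: float
    mc_se: float
    n_replicates: int
    mean_delta: float
    deciding_fraction: Optional[dict] = None

    def to_dict(self) -> dict:
        out = {
            "scenario": self.scenario,
            "threshold_fraction": self.threshold_fraction,
            "power": self.power,
            "mc_se": self.mc_se,
            "n_replicates": self.n_replicates,
            "mean_delta": self.mean_delta,
        }
        if self.deciding_fraction is not None:
            for key, value in self.deciding_fraction.items():
                out[f"decided_by_{key}"] = value
        return out


def _normalize_analyses(analyses, k: int) -> list[tuple[str, str, object]]:
    out = []
    seen = set()
    for label, kind, payload in analyses:
        if label in seen:
            raise ValueError(f"duplicate analysis label {label!r}")
        seen.add(label)
        if kind == "prioritized":
            order = tuple(int(i) for i in payload)
            if sorted(order) != list(range(k)):
                raise ValueError(f"ordering must be a permutation of 0..{k - 1}, got {order}")
            out.append((label, kind, order))
        elif kind == "nonprioritized":
            w = np.full(k, 1.0 / k) if payload is None else np.asarray(payload, dtype=float)
            if w.size != k or np.any(w <= 0):
                raise ValueError("weights must be positive, one per domain")
            out.append((label, kind, w / w.sum()))
        elif kind == "marginal":
            d = int(payload)
            if not 0 <= d < k:
                raise ValueError(f"marginal domain index {d} out of range")
            out.append((label, kind, d))
        else:
            raise ValueError(f"unknown analysis kind {kind!r}")
    return out


def run_power_grid(
    gen: GeneratorConfig,
    scenario: ScenarioConfig,
    analyses: Sequence[tuple[str, str, object]],
) -> list[PowerResult]:
    """Shared-replicate engine behind the public power runners.

    ``analyses`` is a list of ``(label, kind, payload)`` where kind is
    ``prioritized`` (payload: 0-based domain order), ``nonprioritized``
    (payload: weights or None for equal) or ``marginal`` (payload: domain
    index).  All analyses and all threshold fractions reuse the same
    replicate datasets and permutation label draws.
    """
    if scenario.n_per_arm < 2:
        raise ValueError(f"n_per_arm must be >= 2, got {scenario.n_per_arm}")
    k = gen.n_domains
    analyses = _normalize_analyses(analyses, k)
    fractions = scenario.threshold_fractions
    n_rep = scenario.n_replicates
    B = scenario.n_permutations
    n = scenario.n_per_arm
    n_pairs = n * n
    sds = rate_sd(gen)
    base_specs = gen.outcome_specs(priorities=False)

    rejections = {(a[0], f): 0 for a in analyses for f in fractions}
    delta_sums = {key: 0.0 for key in rejections}
    decide_counts = {
        (a[0], f): np.zeros(k + 1) for a in analyses for f in fractions if a[1] == "prioritized"
    }

    children = np.random.SeedSequence(scenario.master_seed).spawn(n_rep)
    for child in children:
        data_ss, perm_ss = child.spawn(2)
        data = generate_trial(gen, n, data_ss)
        rates = derive_rates(data)
        values = rates.rates
        t_idx = np.flatnonzero(rates.arm == TREATED)
        total = values.shape[0]

        perm_rng = np.random.default_rng(perm_ss)
        perms = perm_rng.permuted(np.tile(np.arange(total), (B, 1)), axis=1)[:, :n]

        for f in fractions:
            specs = [s.with_threshold(f * sds[i]) for i, s in enumerate(base_specs)]
            signs = _sign_tensor(values, values, specs)
            for label, kind, payload in analyses:
                deciders = None
                if kind == "prioritized":
                    scores, deciders = _prioritized_scores(signs[:, :, payload])
                    matrix = scores.astype(float)
                elif kind == "nonprioritized":
                    matrix = signs.astype(float) @ payload
                else:
                    matrix = signs[:, :, payload].astype(float)
                rowsums = matrix.sum(axis=1)
                delta_obs = rowsums[t_idx].sum() / n_pairs
                delta_perm = rowsums[perms].sum(axis=1) / n_pairs
                exceed = np.count_nonzero(np.abs(delta_perm) >= np.abs(delta_obs) - 1e-12)
                p = (1 + exceed) / (1 + B)
                key = (label, f)
                if p <= scenario.alpha + 1e-12:
                    rejections[key] += 1
                delta_sums[key] += delta_obs
                if deciders is not None:
                    c_mask = np.ones(total, dtype=bool)
                    c_mask[t_idx] = False
                    pair_deciders = deciders[np.ix_(t_idx, c_mask)]
                    decide_counts[key] += np.bincount(
                        pair_deciders.ravel() + 1, minlength=k + 1
                    )

    results = []
    for label, kind, payload in analyses:
        for f in fractions:
            key = (label, f)
            power = rejections[key] / n_rep
            deciding = None
            if kind == "prioritized":
                frac = decide_counts[key] / (n_rep * n_pairs)
                names = [gen.domains[i] for i in payload]
                deciding = {"neutral": float(frac[0])}
                deciding.update({nm: float(frac[j + 1]) for j, nm in enumerate(names)})
            results.append(
                PowerResult(
                    scenario=label,
                    threshold_fraction=f,
                    power=power,
                    mc_se=float(np.sqrt(power * (1 - power) / n_rep)),
                    n_replicates=n_rep,
                    mean_delta=delta_sums[key] / n_rep,
                    deciding_fraction=deciding,
                )
            )
    return results


def _order_label(order_1based: Sequence[int]) -> str:
    return "".join(str(i) for i in order_1based)


def run_scenario(scenario: ScenarioConfig, gen: GeneratorConfig) -> list[PowerResult]:
    """Power curve for the scenario's own mode over its threshold grid."""
    if scenario.mode == "marginal":
        return run_marginal_power(gen, scenario)
    if scenario.mode == "prioritized":
        order0 = tuple(i - 1 for i in scenario.priority_order)
        analyses = [(f"prioritized_{_order_label(scenario.priority_order)}", "prioritized", order0)]
    else:
        analyses = [("nonprioritized_equal", "nonprioritized", None)]
    return run_power_grid(gen, scenario, analyses)


def run_marginal_power(gen: GeneratorConfig, scenario: ScenarioConfig) -> list[PowerResult]:
    """Single-outcome power curve per domain, on shared replicates."""
    analyses = [(f"marginal_{d}", "marginal", i) for i, d in enumerate(gen.domains)]
    return run_power_grid(gen, scenario, analyses)


def run_ordering_sensitivity(
    orderings: Sequence[Sequence[int]],
    gen: GeneratorConfig,
    scenario: ScenarioConfig,
) -> list[PowerResult]:
    """Prioritized power for several priority orderings (1-based), shared replicates.

    The deciding-outcome distribution is reported per threshold to expose
    how large thresholds shift pair classification to lower priorities.
    """
    labels = [_order_label(o) for o in orderings]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate orderings")
    analyses = []
    for order in orderings:
        order = tuple(int(i) for i in order)
        if sorted(order) != list(range(1, gen.n_domains + 1)):
            raise ValueError(f"ordering must be a permutation of 1..{gen.n_domains}, got {order}")
        analyses.append(
            (f"prioritized_{_order_label(order)}", "prioritized", tuple(i - 1 for i in order))
        )
    return run_power_grid(gen, scenario, analyses)


def default_orderings(gen: GeneratorConfig) -> list[tuple[int, ...]]:
    """Identity, its reversal, and the worst case (smallest standardized effect first)."""
    k = gen.n_domains
    identity = tuple(range(1, k + 1))
    reverse = identity[::-1]
    eff = np.abs(gen.slope_treated - gen.slope_control) / rate_sd(gen)
    worst_first = tuple(int(i) + 1 for i in np.argsort(eff))
    out = [identity, reverse]
    if worst_first not in out:
        out.append(worst_first)
    return out
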