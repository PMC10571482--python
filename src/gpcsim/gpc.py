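"""Generalized pairwise comparisons (GPC) of multi-domain outcomes.

Every subject in the treated arm is compared against every subject in the
control arm.  Each ordered pair receives a score of +1 (win for treatment),
-1 (loss) or 0 (neutral) per outcome; a difference whose magnitude does not
exceed the outcome's threshold of clinical relevance is neutral.  Pair
scores are aggregated either hierarchically (prioritized mode: the first
outcome, in priority order, that breaks the tie decides the pair) or as a
weighted average across outcomes (non-prioritized mode).  The net benefit
is the mean pair score, i.e. the net probability that a random treated
subject does better than a random control subject.  Inference is by
permutation of the arm labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeSpec",
    "RateTable",
    "PairScore",
    "NetBenefitEstimate",
    "PermutationTestResult",
    "score_single",
    "score_pair_prioritized",
    "score_pair_nonprioritized",
    "net_benefit",
    "pairwise_score_matrix",
    "permutation_test",
]

Mode = Literal["prioritized", "nonprioritized"]

TREATED = "treated"
CONTROL = "control"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutcomeSpec:
    """Analysis contract for one outcome domain.

    Parameters
    ----------
    name
        Domain label.
    direction
        +1 if larger values are better, -1 if smaller values are better.
    threshold
        Nonnegative threshold of clinical relevance, in the outcome's own
        units.  A pairwise difference whose magnitude does not strictly
        exceed the threshold is neutral.
    priority
        Positive integer rank used by prioritized scoring (1 = highest).
    weight
        Positive weight used by non-prioritized scoring; weights are
        normalized to sum to one across the spec list before scoring.
    """

    name: str
    direction: int = 1
    threshold: float = 0.0
    priority: Optional[int] = None
    weight: Optional[float] = None

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction}")
        if not math.isfinite(self.threshold) or self.threshold < 0:
            raise ValueError(f"threshold must be a finite nonnegative real, got {self.threshold}")
        if self.priority is not None and self.priority < 1:
            raise ValueError(f"priority must be a positive integer, got {self.priority}")
        if self.weight is not None and not self.weight > 0:
            raise ValueError(f"weight must be positive, got {self.weight}")

    def with_threshold(self, threshold: float) -> "OutcomeSpec":
        return OutcomeSpec(self.name, self.direction, float(threshold), self.priority, self.weight)


def _check_specs(specs: Sequence[OutcomeSpec], mode: Mode) -> list[OutcomeSpec]:
    """Validate a spec list for the requested mode.

    Value vectors stay aligned with spec *list* positions; prioritized
    evaluation order comes from :func:`_priority_order`.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("empty outcome spec list")
    if mode == "prioritized":
        _priority_order(specs)
    elif mode != "nonprioritized":
        raise ValueError(f"unknown mode {mode!r}")
    return specs


def _priority_order(specs: Sequence[OutcomeSpec]) -> list[int]:
    """List positions in priority order (rank 1 first).

    Priorities must form a permutation of 1..K; if none are set, list order
    is taken as priority order.
    """
    prios = [s.priority for s in specs]
    if all(p is None for p in prios):
        return list(range(len(specs)))
    if any(p is None for p in prios):
        raise ValueError("either all or none of the specs must carry a priority")
    if sorted(prios) != list(range(1, len(specs) + 1)):
        raise ValueError(f"priorities must be a permutation of 1..{len(specs)}, got {prios}")
    return sorted(range(len(specs)), key=lambda i: prios[i])


def _weights(specs: Sequence[OutcomeSpec]) -> np.ndarray:
    w = np.array([1.0 if s.weight is None else float(s.weight) for s in specs])
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return w / w.sum()


@dataclass(frozen=True)
class PairScore:
    """Score of one treated-vs-control pair.

    ``deciding_outcome`` is the 0-based index (in priority order) of the
    outcome that classified the pair, or None for a fully neutral pair; it
    is always None in non-prioritized mode.
    """

    score: float
    deciding_outcome: Optional[int] = None


class RateTable:
    """Per-subject per-domain analysis values (rates of change) with arm labels.

    Stores a complete ``(n_subjects, n_domains)`` matrix; missing values are
    rejected because the pairwise comparison rules assume complete data.
    """

    def __init__(
        self,
        subject_id: Sequence,
        arm: Sequence[str],
        rates: np.ndarray,
        domains: Sequence[str],
    ) -> None:
        self.subject_id = np.asarray(subject_id)
        self.arm = np.asarray(arm, dtype=object)
        self.rates = np.asarray(rates, dtype=float)
        self.domains = list(domains)
        if self.rates.ndim != 2:
            raise ValueError("rates must be a 2-D (subjects x domains) array")
        n, k = self.rates.shape
        if len(self.subject_id) != n or len(self.arm) != n:
            raise ValueError("subject_id, arm and rates row count disagree")
        if k != len(self.domains):
            raise ValueError("rates column count disagrees with domain labels")
        if not np.all(np.isfinite(self.rates)):
            bad = np.argwhere(~np.isfinite(self.rates))[0]
            raise ValueError(
                f"non-finite rate for subject {self.subject_id[bad[0]]!r}, "
                f"domain {self.domains[bad[1]]!r}; missing data are not supported"
            )
        unknown = set(self.arm) - {TREATED, CONTROL}
        if unknown:
            raise ValueError(f"arm labels must be 'treated' or 'control', got {sorted(unknown)}")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_long(cls, frame: pd.DataFrame) -> "RateTable":
        """Build from a long-format frame with columns subject_id, arm, domain, rate."""
        required = {"subject_id", "arm", "domain", "rate"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"long-format rate table is missing columns {sorted(missing)}")
        wide = frame.pivot_table(
            index=["subject_id", "arm"], columns="domain", values="rate", sort=False
        )
        domains = list(pd.unique(frame["domain"]))
        wide = wide[domains]
        ids = wide.index.get_level_values("subject_id")
        arms = wide.index.get_level_values("arm")
        return cls(ids, arms, wide.to_numpy(), domains)

    @classmethod
    def from_csv(cls, path) -> "RateTable":
        return cls.from_long(pd.read_csv(path))

    def to_frame(self, wide: bool = True) -> pd.DataFrame:
        if wide:
            out = pd.DataFrame(self.rates, columns=self.domains)
            out.insert(0, "arm", self.arm)
            out.insert(0, "subject_id", self.subject_id)
            return out
        rows = pd.DataFrame(self.rates, columns=self.domains)
        rows["subject_id"] = self.subject_id
        rows["arm"] = self.arm
        return rows.melt(
            id_vars=["subject_id", "arm"], var_name="domain", value_name="rate"
        )

    def to_csv(self, path, wide: bool = True) -> None:
        self.to_frame(wide=wide).to_csv(path, index=False)

    # -- views --------------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.rates.shape[0]

    @property
    def n_domains(self) -> int:
        return self.rates.shape[1]

    def arm_values(self, arm: str) -> np.ndarray:
        return self.rates[self.arm == arm]

    def swapped_arms(self) -> "RateTable":
        """Return a copy with treated and control labels exchanged."""
        flipped = np.where(self.arm == TREATED, CONTROL, TREATED)
        return RateTable(self.subject_id, flipped, self.rates, self.domains)


@dataclass(frozen=True)
class NetBenefitEstimate:
    """Net benefit with its win/loss/neutral decomposition.

    ``delta = (wins - losses) / n_pairs``.  In prioritized mode the three
    tallies are integers and sum to ``n_pairs``; in non-prioritized mode
    wins and losses are the positive and negative parts of the fractional
    pair scores, so the same identity holds with fractional tallies.
    ``decided_by`` (prioritized mode) counts, per outcome in priority
    order, how many pairs were classified at that level.
    """

    delta: float
    n_pairs: int
    wins: float
    losses: float
    neutral: float
    mode: Mode
    decided_by: Optional[tuple[int, ...]] = None

    def to_dict(self) -> dict:
        out = {
            "mode": self.mode,
            "delta": self.delta,
            "n_pairs": self.n_pairs,
            "wins": self.wins,
            "losses": self.losses,
            "neutral": self.neutral,
        }
        if self.decided_by is not None:
            out["decided_by"] = list(self.decided_by)
        return out


@dataclass(frozen=True)
class PermutationTestResult:
    """Two-sided permutation test of the null of no treatment effect.

    ``p_value = (1 + #{b : |delta_b| >= |delta_obs|}) / (1 + B)`` where the
    B permutations reassign arm labels at random, preserving arm sizes.
    """

    delta_obs: float
    p_value: float
    n_permutations: int
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "delta_obs": self.delta_obs,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def score_single(x_t: float, x_c: float, spec: OutcomeSpec) -> int:
    """Score one pair on one outcome: +1 win, -1 loss, 0 neutral.

    The pair is a win if the direction-adjusted difference strictly exceeds
    the threshold, a loss if its negation does, neutral otherwise (a
    difference exactly equal to the threshold is neutral).
    """
    if not (math.isfinite(x_t) and math.isfinite(x_c)):
        raise ValueError(
            f"non-finite value in pair ({x_t}, {x_c}) for outcome {spec.name!r}; "
            "missing data are not supported"
        )
    d = spec.direction * (x_t - x_c)
    if d > spec.threshold:
        return 1
    if -d > spec.threshold:
        return -1
    return 0


def _as_vector(v, k: int, what: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size != k:
        raise ValueError(f"{what} has length {arr.size}, expected {k}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite value in {what}; missing data are not supported")
    return arr


def score_pair_prioritized(v_t, v_c, specs: Sequence[OutcomeSpec]) -> PairScore:
    """Hierarchical pair score: the first non-neutral outcome in priority order decides."""
    specs = _check_specs(specs, "prioritized")
    k = len(specs)
    v_t = _as_vector(v_t, k, "treated vector")
    v_c = _as_vector(v_c, k, "control vector")
    for rank, pos in enumerate(_priority_order(specs)):
        s = score_single(v_t[pos], v_c[pos], specs[pos])
        if s != 0:
            return PairScore(score=float(s), deciding_outcome=rank)
    return PairScore(score=0.0, deciding_outcome=None)


def score_pair_nonprioritized(v_t, v_c, specs: Sequence[OutcomeSpec]) -> PairScore:
    """Weighted-average pair score across outcomes (weights normalized to sum 1)."""
    specs = _check_specs(specs, "nonprioritized")
    k = len(specs)
    v_t = _as_vector(v_t, k, "treated vector")
    v_c = _as_vector(v_c, k, "control vector")
    w = _weights(specs)
    total = sum(
        wk * score_single(v_t[i], v_c[i], specs[i]) for i, wk in enumerate(w)
    )
    return PairScore(score=float(total), deciding_outcome=None)


# ---------------------------------------------------------------------------
# vectorized pairwise machinery
# ---------------------------------------------------------------------------


def _sign_tensor(a: np.ndarray, b: np.ndarray, specs: Sequence[OutcomeSpec]) -> np.ndarray:
    """Per-outcome win/loss/neutral signs for every (row of a, row of b) pair.

    Returns an ``(n_a, n_b, K)`` int8 tensor.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    dirs = np.array([s.direction for s in specs], dtype=float)
    taus = np.array([s.threshold for s in specs], dtype=float)
    d = dirs * (a[:, None, :] - b[None, :, :])
    return (d > taus).astype(np.int8) - (d < -taus).astype(np.int8)


def _prioritized_scores(signs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reduce a sign tensor hierarchically along its last axis.

    Returns ``(scores, deciders)`` where ``deciders`` holds the 0-based
    deciding outcome index, or -1 for fully neutral pairs.
    """
    nonzero = signs != 0
    first = np.argmax(nonzero, axis=-1)
    any_nonzero = nonzero.any(axis=-1)
    scores = np.where(
        any_nonzero, np.take_along_axis(signs, first[..., None], axis=-1)[..., 0], 0
    ).astype(np.int8)
    deciders = np.where(any_nonzero, first, -1)
    return scores, deciders


def pairwise_score_matrix(
    values: np.ndarray, specs: Sequence[OutcomeSpec], mode: Mode
) -> np.ndarray:
    """All-vs-all antisymmetric pair score matrix over a pooled sample.

    ``M[i, j]`` is the score of the pair with subject i treated and subject
    j control; ``M[j, i] = -M[i, j]`` because win/loss rules are strict and
    symmetric.  Used by the permutation test, which only relabels arms.
    """
    specs = _check_specs(specs, mode)
    signs = _sign_tensor(values, values, specs)
    if mode == "prioritized":
        scores, _ = _prioritized_scores(signs[:, :, _priority_order(specs)])
        return scores.astype(float)
    return signs.astype(float) @ _weights(specs)


# ---------------------------------------------------------------------------
# net benefit and permutation inference
# ---------------------------------------------------------------------------


def net_benefit(rates: RateTable, specs: Sequence[OutcomeSpec], mode: Mode) -> NetBenefitEstimate:
    """Net benefit over all treated-vs-control pairs.

    Enumerates the ``n_t x n_c`` ordered pairs, scores each under the
    requested mode and returns the mean score together with the
    win/loss/neutral tallies.
    """
    specs = _check_specs(specs, mode)
    treated = rates.arm_values(TREATED)
    control = rates.arm_values(CONTROL)
    if len(treated) == 0 or len(control) == 0:
        raise ValueError(
            f"both arms are required: n_treated={len(treated)}, n_control={len(control)}"
        )
    if treated.shape[1] != len(specs):
        raise ValueError(
            f"rate table has {treated.shape[1]} domains but {len(specs)} outcome specs given"
        )
    signs = _sign_tensor(treated, control, specs)
    n_pairs = signs.shape[0] * signs.shape[1]
    decided_by = None
    if mode == "prioritized":
        scores, deciders = _prioritized_scores(signs[:, :, _priority_order(specs)])
        scores = scores.astype(float)
        counts = np.bincount(deciders[deciders >= 0].ravel(), minlength=len(specs))
        decided_by = tuple(int(c) for c in counts)
    else:
        scores = signs.astype(float) @ _weights(specs)
    wins = float(np.clip(scores, 0, None).sum())
    losses = float(np.clip(-scores, 0, None).sum())
    delta = (wins - losses) / n_pairs
    return NetBenefitEstimate(
        delta=float(delta),
        n_pairs=int(n_pairs),
        wins=wins,
        losses=losses,
        neutral=float(n_pairs - wins - losses),
        mode=mode,
        decided_by=decided_by,
    )


def _delta_from_rowsums(rowsums: np.ndarray, treated_idx: np.ndarray, n_t: int, n_c: int):
    # For an antisymmetric score matrix M, sum_{i,j in T} M[i,j] = 0, so the
    # sum over treated-vs-control pairs reduces to the treated row sums of
    # the pooled all-vs-all matrix.
    return rowsums[treated_idx].sum(axis=-1) / (n_t * n_c)


def permutation_test(
    rates: RateTable,
    specs: Sequence[OutcomeSpec],
    mode: Mode,
    B: int = 1000,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> PermutationTestResult:
    """Two-sided Monte Carlo permutation test of delta = 0.

    Arm labels are reassigned uniformly at random B times, preserving arm
    sizes; the p-value carries the add-one correction so it is never zero
    and lies in [1/(1+B), 1].  Reproducible for a fixed integer seed.
    """
    if B < 1:
        raise ValueError(f"number of permutations must be >= 1, got {B}")
    n_t = int(np.sum(rates.arm == TREATED))
    n_c = int(np.sum(rates.arm == CONTROL))
    if n_t == 0 or n_c == 0:
        raise ValueError(f"both arms are required: n_treated={n_t}, n_control={n_c}")
    matrix = pairwise_score_matrix(rates.rates, specs, mode)
    rowsums = matrix.sum(axis=1)
    n = n_t + n_c
    obs_idx = np.flatnonzero(rates.arm == TREATED)
    delta_obs = float(_delta_from_rowsums(rowsums, obs_idx, n_t, n_c))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = rng.permuted(np.tile(np.arange(n), (B, 1)), axis=1)[:, :n_t]
    delta_perm = _delta_from_rowsums(rowsums, perms, n_t, n_c)
    # pair scores are multiples of 1/n_pairs (times weight resolution); the
    # tolerance guards float round-off in |delta| ties, not real differences
    tol = 1e-12
    exceed = int(np.count_nonzero(np.abs(delta_perm) >= np.abs(delta_obs) - tol))
    p = (1 + exceed) / (1 + B)
    return PermutationTestResult(
        delta_obs=delta_obs,
        p_value=float(p),
        n_permutations=int(B),
        seed=seed if isinstance(seed, int) else None,
    )
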