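"""Shared fixtures and independent brute-force oracles.

The oracles reimplement pair scoring, net benefit and the exhaustive
permutation p-value with plain Python loops, independently of the package's
vectorized code paths, so the two routes cross-check each other.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from gpcsim import GeneratorConfig, OutcomeSpec, RateTable

# ---------------------------------------------------------------------------
# oracles (pure-python, loop-based, no package internals)
# ---------------------------------------------------------------------------


def oracle_single(x_t: float, x_c: float, direction: int, tau: float) -> int:
    d = direction * (x_t - x_c)
    if d > tau:
        return 1
    if -d > tau:
        return -1
    return 0


def oracle_pair(v_t, v_c, specs, mode: str) -> float:
    per = [
        oracle_single(x, y, s.direction, s.threshold) for x, y, s in zip(v_t, v_c, specs)
    ]
    if mode == "prioritized":
        for v in per:
            if v != 0:
                return float(v)
        return 0.0
    return sum(per) / len(per)  # equal weights


def oracle_delta(treated, control, specs, mode: str) -> float:
    total = 0.0
    for v_t in treated:
        for v_c in control:
            total += oracle_pair(v_t, v_c, specs, mode)
    return total / (len(treated) * len(control))


def oracle_exhaustive_p(values, n_treated: int, specs, mode: str, delta_obs: float) -> float:
    """Exact two-sided p over all equal-size label splits of the pooled sample."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    count = 0
    total = 0
    for t_idx in itertools.combinations(range(n), n_treated):
        c_idx = [i for i in range(n) if i not in t_idx]
        d = oracle_delta(values[list(t_idx)], values[c_idx], specs, mode)
        total += 1
        if abs(d) >= abs(delta_obs) - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_specs(k, taus=0.0, dirs=None, priorities=True):
    taus = np.broadcast_to(np.asarray(taus, dtype=float), (k,))
    dirs = [1] * k if dirs is None else dirs
    return [
        OutcomeSpec(
            name=f"d{i + 1}",
            direction=dirs[i],
            threshold=float(taus[i]),
            priority=(i + 1) if priorities else None,
        )
        for i in range(k)
    ]


def make_rate_table(treated, control, domains=None):
    treated = np.atleast_2d(np.asarray(treated, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    k = treated.shape[1]
    domains = domains or [f"d{i + 1}" for i in range(k)]
    n_t, n_c = len(treated), len(control)
    return RateTable(
        subject_id=[f"t{i}" for i in range(n_t)] + [f"c{i}" for i in range(n_c)],
        arm=["treated"] * n_t + ["control"] * n_c,
        rates=np.vstack([treated, control]),
        domains=domains,
    )


@pytest.fixture
def specs5():
    return make_specs(5)


@pytest.fixture
def default_gen():
    return GeneratorConfig()


@pytest.fixture
def small_gen():
    """Cheap 2-domain generator for fast pipeline tests."""
    return GeneratorConfig(
        domains=("a", "b"),
        direction=(1, -1),
        baseline_mean=(10.0, 5.0),
        slope_control=(1.0, 0.0),
        slope_treated=(2.0, -0.5),
        sd_baseline_re=(2.0, 1.0),
        std_effect=(0.8, 0.5),
    )
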