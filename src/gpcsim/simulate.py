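"""Correlated five-domain longitudinal outcome simulator.

Generates per-subject trajectories for five symptom domains (expressive
language, daily living skills, gross motor, sleep, pain) observed at months
0, 6, 12, 18 and 24, from a mixed-effects model with linear and quadratic
time trends, subject-level random intercepts and slopes correlated across
domains, and independent visit-level noise:

    Y_idj = mu_d + s_d(arm) * t_j + q_d * t_j^2 + b0_id + b1_id * t_j + eps_idj

with time in years.  The analysis quantity is the per-subject rate of
change, (Y at 24 months - Y at baseline) / 2 years, so its model SD is
sqrt(sd_slope_re^2 + sd_residual^2 / 2).

Default baseline centers and per-year slopes reproduce the published
natural-history summaries; the variance components are calibration choices
(the fitted covariance structure is unpublished) expressed through
``std_effect``, the standardized slope shift per domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .gpc import CONTROL, TREATED, OutcomeSpec, RateTable

__all__ = [
    "DOMAINS",
    "DOMAIN_DIRECTIONS",
    "GeneratorConfig",
    "LongitudinalDataset",
    "generate_arm",
    "generate_trial",
    "derive_rates",
    "rate_sd",
]

DOMAINS = ("expressive_language", "daily_living", "gross_motor", "sleep", "pain")

# larger is better everywhere except sleep-disturbance score
DOMAIN_DIRECTIONS = (1, 1, 1, -1, 1)

_BASELINE_MEDIANS = (63.0, 30.5, 58.0, 4.0, 75.0)
_SLOPE_CONTROL = (1.31, 0.10, 0.28, -0.01, -0.21)
_SLOPE_TREATED = (3.53, 0.42, 0.94, -0.47, 0.50)

# baseline random-intercept SDs: quarter of the published baseline ranges
_SD_BASELINE = (35.0, 4.75, 18.5, 2.5, 18.75)

# calibrated standardized slope shifts |s_T - s_C| / rate SD: expressive
# language dominates, the remaining domains are moderate
_STD_EFFECT = (1.0, 0.25, 0.35, 0.30, 0.30)

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator, None]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _vec(value, k: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float).ravel()
    if arr.size == 1:
        arr = np.full(k, arr[0])
    if arr.size != k:
        raise ValueError(f"{name} must have length {k}, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class GeneratorConfig:
    """Parameters of the longitudinal generator.

    ``sd_slope_re`` and ``sd_residual`` may be given explicitly; when left
    as None they are calibrated from ``std_effect`` (the target standardized
    slope shift per domain) and ``residual_fraction`` (share of the rate
    variance carried by visit noise rather than the random slope).
    """

    domains: tuple[str, ...] = DOMAINS
    direction: tuple[int, ...] = DOMAIN_DIRECTIONS
    baseline_mean: Sequence[float] = _BASELINE_MEDIANS
    slope_control: Sequence[float] = _SLOPE_CONTROL
    slope_treated: Sequence[float] = _SLOPE_TREATED
    quad_coef: Sequence[float] = 0.0
    sd_baseline_re: Sequence[float] = _SD_BASELINE
    sd_slope_re: Optional[Sequence[float]] = None
    sd_residual: Optional[Sequence[float]] = None
    std_effect: Sequence[float] = _STD_EFFECT
    residual_fraction: float = 0.5
    cross_domain_corr: float = 0.3
    visit_months: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0, 24.0)
    clip_scores: Optional[dict] = None  # domain -> (lo, hi), display only
    seed: int = 0

    def __post_init__(self) -> None:
        self.domains = tuple(str(d) for d in self.domains)
        k = len(self.domains)
        if len(set(self.domains)) != k:
            raise ValueError("domain labels must be unique")
        self.direction = tuple(int(d) for d in np.asarray(self.direction).ravel())
        if len(self.direction) != k or any(d not in (-1, 1) for d in self.direction):
            raise ValueError("direction must be a vector of +1/-1, one per domain")
        self.baseline_mean = _vec(self.baseline_mean, k, "baseline_mean")
        self.slope_control = _vec(self.slope_control, k, "slope_control")
        self.slope_treated = _vec(self.slope_treated, k, "slope_treated")
        self.quad_coef = _vec(self.quad_coef, k, "quad_coef")
        self.sd_baseline_re = _vec(self.sd_baseline_re, k, "sd_baseline_re")
        self.std_effect = _vec(self.std_effect, k, "std_effect")
        if np.any(self.std_effect <= 0):
            raise ValueError("std_effect must be positive per domain")
        if not 0.0 <= self.residual_fraction <= 1.0:
            raise ValueError(f"residual_fraction must lie in [0, 1], got {self.residual_fraction}")
        if not 0.0 <= self.cross_domain_corr < 1.0:
            raise ValueError(
                f"cross_domain_corr must lie in [0, 1), got {self.cross_domain_corr}"
            )
        if self.sd_slope_re is None or self.sd_residual is None:
            target = np.abs(self.slope_treated - self.slope_control) / self.std_effect
            if self.sd_slope_re is None:
                self.sd_slope_re = np.sqrt((1.0 - self.residual_fraction)) * target
            if self.sd_residual is None:
                self.sd_residual = np.sqrt(2.0 * self.residual_fraction) * target
        self.sd_slope_re = _vec(self.sd_slope_re, k, "sd_slope_re")
        self.sd_residual = _vec(self.sd_residual, k, "sd_residual")
        for name in ("sd_baseline_re", "sd_slope_re", "sd_residual"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be nonnegative")
        self.visit_months = tuple(float(m) for m in self.visit_months)
        if sorted(self.visit_months) != list(self.visit_months):
            raise ValueError("visit_months must be increasing")
        if 0.0 not in self.visit_months or 24.0 not in self.visit_months:
            raise ValueError("visit_months must include months 0 and 24 (rate endpoints)")
        # non-PSD covariance is rejected here, not at draw time
        cov = self.random_effect_covariance()
        if np.linalg.eigvalsh(cov).min() < -1e-9:
            raise ValueError("implied random-effect covariance is not positive semi-definite")

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def slopes(self, arm: str) -> np.ndarray:
        if arm == TREATED:
            return self.slope_treated
        if arm == CONTROL:
            return self.slope_control
        raise ValueError(f"arm must be 'treated' or 'control', got {arm!r}")

    def random_effect_covariance(self) -> np.ndarray:
        """Joint covariance of the 2K random effects (K intercepts, K slopes).

        Same-type effects share an exchangeable cross-domain correlation;
        intercepts and slopes are independent of each other.
        """
        k = self.n_domains
        rho = self.cross_domain_corr
        corr = np.full((k, k), rho) + (1.0 - rho) * np.eye(k)
        cov = np.zeros((2 * k, 2 * k))
        d0 = np.diag(self.sd_baseline_re)
        d1 = np.diag(self.sd_slope_re)
        cov[:k, :k] = d0 @ corr @ d0
        cov[k:, k:] = d1 @ corr @ d1
        return cov

    def outcome_specs(
        self, thresholds: Optional[Sequence[float]] = None, priorities: bool = True
    ) -> list[OutcomeSpec]:
        """Outcome specs matching the generator's domains, in config order."""
        taus = np.zeros(self.n_domains) if thresholds is None else _vec(
            thresholds, self.n_domains, "thresholds"
        )
        return [
            OutcomeSpec(
                name=self.domains[i],
                direction=self.direction[i],
                threshold=float(taus[i]),
                priority=(i + 1) if priorities else None,
            )
            for i in range(self.n_domains)
        ]

    def null_config(self) -> "GeneratorConfig":
        """Copy with the treated slopes set to the control slopes (no effect)."""
        return replace(
            self,
            slope_treated=np.array(self.slope_control),
            sd_slope_re=np.array(self.sd_slope_re),
            sd_residual=np.array(self.sd_residual),
        )

    def to_dict(self) -> dict:
        def _list(x):
            return [float(v) for v in np.asarray(x).ravel()]

        return {
            "domains": list(self.domains),
            "direction": list(self.direction),
            "baseline_mean": _list(self.baseline_mean),
            "slope_control": _list(self.slope_control),
            "slope_treated": _list(self.slope_treated),
            "quad_coef": _list(self.quad_coef),
            "sd_baseline_re": _list(self.sd_baseline_re),
            "sd_slope_re": _list(self.sd_slope_re),
            "sd_residual": _list(self.sd_residual),
            "std_effect": _list(self.std_effect),
            "residual_fraction": float(self.residual_fraction),
            "cross_domain_corr": float(self.cross_domain_corr),
            "visit_months": list(self.visit_months),
            "clip_scores": self.clip_scores,
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
        return cls(**data)


class LongitudinalDataset:
    """Long-format scores: one row per (subject, visit, domain).

    The grid is complete by construction — every subject carries a score for
    every (visit, domain) combination.
    """

    COLUMNS = ("subject_id", "arm", "visit_month", "domain", "score")

    def __init__(self, frame: pd.DataFrame, domains: Optional[Sequence[str]] = None) -> None:
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"dataset frame is missing columns {sorted(missing)}")
        self.frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        self.domains = list(domains) if domains is not None else list(
            pd.unique(self.frame["domain"])
        )
        if len(self.frame):
            counts = self.frame.groupby("subject_id", sort=False).size()
            expected = self.frame["visit_month"].nunique() * len(self.domains)
            if counts.nunique() > 1 or counts.iloc[0] != expected:
                raise ValueError("incomplete grid: every subject needs every (visit, domain)")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()

    @property
    def visit_months(self) -> list[float]:
        return sorted(self.frame["visit_month"].unique())

    @staticmethod
    def concat(*parts: "LongitudinalDataset") -> "LongitudinalDataset":
        domains = parts[0].domains if parts else None
        return LongitudinalDataset(
            pd.concat([p.frame for p in parts], ignore_index=True), domains
        )

    def scores_at(self, month: float) -> pd.DataFrame:
        """Wide (subject x domain) score matrix at one visit, with arm labels."""
        sub = self.frame[self.frame["visit_month"] == month]
        wide = sub.pivot_table(
            index=["subject_id", "arm"], columns="domain", values="score", sort=False
        )
        return wide[self.domains]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, domains: Optional[Sequence[str]] = None) -> "LongitudinalDataset":
        return cls(pd.read_csv(path), domains)


def generate_arm(
    config: GeneratorConfig, arm: str, n: int, seed: SeedLike = None
) -> LongitudinalDataset:
    """Simulate ``n`` subjects of one arm on the full visit/domain grid."""
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    rng = _rng(config.seed if seed is None else seed)
    k = config.n_domains
    slopes = config.slopes(arm)
    t = np.asarray(config.visit_months, dtype=float) / 12.0  # years
    nt = len(t)

    effects = rng.multivariate_normal(
        np.zeros(2 * k), config.random_effect_covariance(), size=n, method="svd"
    )
    b0, b1 = effects[:, :k], effects[:, k:]
    eps = rng.standard_normal((n, nt, k)) * config.sd_residual

    fixed = (
        config.baseline_mean[None, :]
        + slopes[None, :] * t[:, None]
        + config.quad_coef[None, :] * (t[:, None] ** 2)
    )  # (nt, k)
    scores = fixed[None] + b0[:, None, :] + b1[:, None, :] * t[None, :, None] + eps

    if config.clip_scores:
        for d, (lo, hi) in config.clip_scores.items():
            j = config.domains.index(d)
            scores[:, :, j] = np.clip(scores[:, :, j], lo, hi)

    ids = np.array([f"{arm}_{i + 1:04d}" for i in range(n)])
    frame = pd.DataFrame(
        {
            "subject_id": np.repeat(ids, nt * k),
            "arm": arm,
            "visit_month": np.tile(np.repeat(config.visit_months, k), n),
            "domain": np.tile(config.domains, n * nt),
            "score": scores.ravel(),
        }
    )
    return LongitudinalDataset(frame, config.domains)


def generate_trial(
    config: GeneratorConfig, n_per_arm: int, seed: SeedLike = None
) -> LongitudinalDataset:
    """Simulate a two-arm trial (control + treated) from one seed."""
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(config.seed if seed is None else seed)
    )
    s_control, s_treated = ss.spawn(2)
    return LongitudinalDataset.concat(
        generate_arm(config, CONTROL, n_per_arm, np.random.default_rng(s_control)),
        generate_arm(config, TREATED, n_per_arm, np.random.default_rng(s_treated)),
    )


def derive_rates(data: LongitudinalDataset) -> RateTable:
    """Per-subject per-domain rate of change: (score at 24 mo - baseline) / 2 years.

    Intermediate visits are carried in the dataset but do not enter this
    estimator.
    """
    by_visit = {}
    for month in (0.0, 24.0):
        sub = data.frame[data.frame["visit_month"] == month]
        wide = sub.pivot_table(
            index=["subject_id", "arm"], columns="domain", values="score", sort=False
        )
        for d in data.domains:
            if d not in wide.columns:
                raise ValueError(f"no scores at month {month:g} for domain {d!r}")
        wide = wide[data.domains]
        if wide.isna().any().any():
            sid = wide.index[wide.isna().any(axis=1)][0][0]
            dom = wide.columns[wide.isna().any(axis=0)][0]
            raise ValueError(
                f"subject {sid!r} is missing a month-{month:g} score for domain {dom!r}"
            )
        by_visit[month] = wide
    y0, y24 = by_visit[0.0], by_visit[24.0]
    if not y0.index.equals(y24.index):
        missing = set(y0.index.get_level_values(0)) ^ set(y24.index.get_level_values(0))
        raise ValueError(f"subjects missing an endpoint visit: {sorted(missing)}")
    rates = (y24.to_numpy() - y0.to_numpy()) / 2.0
    return RateTable(
        subject_id=y0.index.get_level_values("subject_id"),
        arm=y0.index.get_level_values("arm"),
        rates=rates,
        domains=data.domains,
    )


def rate_sd(
    config: GeneratorConfig,
    method: str = "analytic",
    n_pilot: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Model SD of the per-subject rate of change, per domain.

    The rate equals ``slope + 2*quad + b1 + (eps_24 - eps_0)/2``, hence the
    analytic SD is ``sqrt(sd_slope_re^2 + sd_residual^2 / 2)``, identical in
    both arms.  ``method='empirical'`` instead simulates a control-arm pilot
    and returns the sample SD (agrees with the analytic value within Monte
    Carlo error).
    """
    if method == "analytic":
        return np.sqrt(config.sd_slope_re**2 + config.sd_residual**2 / 2.0)
    if method == "empirical":
        pilot = generate_arm(config, CONTROL, n_pilot, seed)
        rates = derive_rates(pilot)
        return rates.rates.std(axis=0, ddof=1)
    raise ValueError(f"method must be 'analytic' or 'empirical', got {method!r}")
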