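"""Synthetic cohort generation.

Real health-examination cohorts cannot be redistributed, so every
downstream stage is exercised on synthetic subjects drawn from a Gaussian
copula with per-sex marginal moments taken from published Korean and
American cohort summaries (fasting glucose, waist, HDL, triglycerides,
systolic and diastolic pressure). Triglycerides use a moment-matched
lognormal marginal because their dispersion approaches their mean;
the remaining factors are Gaussian. The default inter-factor correlation
structure is a stated assumption (mild positive co-occurrence of the
adverse factors, negative loading for HDL), not an empirical estimate.

Measurements are truncated to fixed clinically plausible bounds, and rows
violating sbp > dbp are resampled, so every generated subject passes
cohort validation.

A second generator draws scaled five-vectors with an exact number of
components at or above the 0.5 threshold, used to probe the theoretical
per-count score ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .scoring import SubjectRecord

__all__ = [
    "FACTOR_ORDER",
    "TABLE_MARGINALS",
    "DEFAULT_CORRELATION",
    "CohortSpec",
    "generate_cohort",
    "generate_scaled_vectors",
    "cohort_frame",
]

#: Order of simulated measurements.
FACTOR_ORDER = ("glucose", "waist", "hdl", "triglycerides", "sbp", "dbp")

#: Published per-sex marginal moments (mean, sd) by region.
TABLE_MARGINALS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("korean", "male"): {
        "glucose": (94.8, 17.5), "waist": (84.6, 7.4), "hdl": (50.4, 12.1),
        "triglycerides": (145.3, 105.6), "sbp": (124.0, 14.3), "dbp": (77.9, 9.8),
    },
    ("korean", "female"): {
        "glucose": (89.9, 13.0), "waist": (77.3, 7.8), "hdl": (57.3, 12.9),
        "triglycerides": (104.4, 66.7), "sbp": (118.3, 14.7), "dbp": (73.4, 9.6),
    },
    ("american", "male"): {
        "glucose": (100.2, 19.3), "waist": (94.2, 15.5), "hdl": (49.6, 13.5),
        "triglycerides": (122.7, 116.2), "sbp": (119.6, 13.0), "dbp": (69.3, 12.1),
    },
    ("american", "female"): {
        "glucose": (95.3, 15.1), "waist": (91.0, 16.1), "hdl": (58.3, 15.3),
        "triglycerides": (94.4, 70.0), "sbp": (112.5, 13.9), "dbp": (67.1, 10.5),
    },
}

#: Assumed latent correlation among (glucose, waist, hdl, tg, sbp, dbp):
#: modest positive co-occurrence of adverse factors, HDL loading negative,
#: sbp-dbp strongly coupled.
DEFAULT_CORRELATION = np.array(
    [
        # gl    wc    hdl    tg    sbp   dbp
        [1.00, 0.25, -0.15, 0.25, 0.20, 0.15],
        [0.25, 1.00, -0.25, 0.30, 0.25, 0.20],
        [-0.15, -0.25, 1.00, -0.40, -0.10, -0.05],
        [0.25, 0.30, -0.40, 1.00, 0.20, 0.15],
        [0.20, 0.25, -0.10, 0.20, 1.00, 0.70],
        [0.15, 0.20, -0.05, 0.15, 0.70, 1.00],
    ]
)

#: Fixed truncation bounds keeping measurements clinically plausible and
#: the normalized deviations finite.
TRUNCATION_BOUNDS = {
    "glucose": (40.0, 500.0),
    "waist": (40.0, 200.0),
    "hdl": (10.0, 199.0),
    "triglycerides": (20.0, 1500.0),
    "sbp": (60.0, 260.0),
    "dbp": (30.0, 160.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of one synthetic cohort."""

    n: int = 1000
    sex_ratio: float = 0.5
    region: str = "korean"
    seed: int = 0
    marginals: dict | None = None  # {(sex): {factor: (mean, sd)}} overrides
    correlation: np.ndarray | None = field(default_factory=lambda: DEFAULT_CORRELATION.copy())
    lognormal_factors: tuple[str, ...] = ("triglycerides",)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.correlation is not None:
            r = np.asarray(self.correlation, dtype=float)
            if r.shape != (6, 6):
                raise ValueError("correlation must be 6x6")
            if not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
                raise ValueError("correlation must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(r).min() < -1e-10:
                raise ValueError("correlation must be positive semi-definite")

    def marginal(self, sex: str, factor: str) -> tuple[float, float]:
        if self.marginals and sex in self.marginals and factor in self.marginals[sex]:
            m, s = self.marginals[sex][factor]
        else:
            m, s = TABLE_MARGINALS[(self.region, sex)][factor]
        if s <= 0:
            raise ValueError(f"sd for {factor} must be positive")
        return m, s


def _marginal_ppf(u: np.ndarray, mean: float, sd: float, lognormal: bool) -> np.ndarray:
    if lognormal:
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return np.exp(stats.norm.ppf(u) * np.sqrt(sigma2) + mu)
    return stats.norm.ppf(u, loc=mean, scale=sd)


def _draw_block(rng: np.random.Generator, spec: CohortSpec, sex: str, n: int) -> np.ndarray:
    """Draw an (n, 6) block of measurements for one sex, with resampling
    until sbp > dbp holds in every row."""
    if spec.correlation is not None:
        chol = np.linalg.cholesky(
            spec.correlation + 1e-12 * np.eye(6)
        )
    else:
        chol = None

    def sample(m: int) -> np.ndarray:
        z = rng.standard_normal((m, 6))
        if chol is not None:
            z = z @ chol.T
        u = np.clip(stats.norm.cdf(z), 1e-12, 1 - 1e-12)
        cols = []
        for j, factor in enumerate(FACTOR_ORDER):
            mean, sd = spec.marginal(sex, factor)
            x = _marginal_ppf(u[:, j], mean, sd, factor in spec.lognormal_factors)
            lo, hi = TRUNCATION_BOUNDS[factor]
            cols.append(np.clip(x, lo, hi))
        return np.column_stack(cols)

    out = sample(n)
    i_sbp = FACTOR_ORDER.index("sbp")
    i_dbp = FACTOR_ORDER.index("dbp")
    for _ in range(100):
        bad = out[:, i_sbp] <= out[:, i_dbp]
        if not bad.any():
            break
        out[bad] = sample(int(bad.sum()))
    else:  # pragma: no cover - overwhelmingly unlikely with sane marginals
        raise RuntimeError("could not satisfy sbp > dbp by resampling")
    return out


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate a reproducible synthetic cohort of subject records."""
    rng = np.random.default_rng(spec.seed)
    n_male = int(round(spec.n * spec.sex_ratio))
    records: list[SubjectRecord] = []
    for sex, count in (("male", n_male), ("female", spec.n - n_male)):
        if count == 0:
            continue
        block = _draw_block(rng, spec, sex, count)
        for i in range(count):
            row = dict(zip(FACTOR_ORDER, block[i]))
            records.append(
                SubjectRecord(
                    glucose=row["glucose"],
                    sbp=row["sbp"],
                    dbp=row["dbp"],
                    triglycerides=row["triglycerides"],
                    hdl=row["hdl"],
                    waist=row["waist"],
                    sex=sex,
                    region=spec.region,
                    id=f"{sex[0]}{i:06d}",
                )
            )
    return records


def cohort_frame(records: Sequence[SubjectRecord]):
    """Tabulate generated records as a cohort CSV-compatible DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "glucose": [r.glucose for r in records],
            "sbp": [r.sbp for r in records],
            "dbp": [r.dbp for r in records],
            "triglycerides": [r.triglycerides for r in records],
            "hdl": [r.hdl for r in records],
            "waist": [r.waist for r in records],
            "sex": [r.sex for r in records],
            "region": [r.region for r in records],
        }
    )


def generate_scaled_vectors(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Draw n scaled five-vectors with exactly k components >= 0.5.

    The k at-or-above components are uniform on [0.5, 1], the rest uniform
    on [0, 0.5); component positions are shuffled per row. Returns an
    (n, 5) array (rows are valid :class:`ScaledVector` inputs).
    """
    if not (0 <= k <= 5):
        raise ValueError("k must be in 0..5")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    high = rng.uniform(0.5, 1.0, size=(n, k))
    low = rng.uniform(0.0, 0.5, size=(n, 5 - k))
    # keep the open upper bound of the sub-threshold block
    low = np.minimum(low, np.nextafter(0.5, 0.0))
    out = np.concatenate([high, low], axis=1)
    perm = rng.permuted(np.tile(np.arange(5), (n, 1)), axis=1)
    return np.take_along_axis(out, perm, axis=1)
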