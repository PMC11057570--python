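"""Core scoring: axis scaling, triangular areal similarity (TAS), and RMRS.

The Robust MetS Risk Score (RMRS) turns the five metabolic-syndrome risk
factors — fasting glucose (GL), blood pressure (BP), triglycerides (TG),
HDL-cholesterol (HDL) and waist circumference (WC) — into a continuous
score in [0, 1] anchored only to the AHA/NHLBI diagnostic thresholds,
never to sample statistics.

Pipeline per subject:

1. Each raw measurement is normalized so the diagnostic threshold maps to
   0 and 10 % of the threshold is one unit (``normalize_factor`` /
   ``normalize_bp``), then squashed with the Elliot sigmoid so the
   threshold sits at 0.5 and one unit above/below at 0.75/0.25
   (``elliot_sigmoid``).
2. The five scaled axes are combined into all C(5,3) = 10 three-axis
   radar-chart triads. Each triad receives a TAS score, the average of a
   *closeness* term (area ratio up to the threshold triangle) and a
   *severity* term (excess area beyond it, active only when all three
   axes reach the threshold).
3. RMRS is the square root of the mean of the 10 TAS scores. The fixed
   diagnostic cutoff 0.547 is the midpoint of the minimum three-factor
   score (0.387) and the supremum two-factor score (0.707), a purely
   structural construction (``derive_diagnostic_threshold``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np

__all__ = [
    "FACTORS",
    "DIAGNOSTIC_THRESHOLD",
    "FactorThresholds",
    "SubjectRecord",
    "ScaledVector",
    "TriadScore",
    "RmrsResult",
    "ThresholdDerivation",
    "normalize_factor",
    "normalize_bp",
    "elliot_sigmoid",
    "scale_subject",
    "enumerate_triads",
    "triangle_area",
    "clip_internal",
    "tas_score",
    "tas_value",
    "rmrs_value",
    "rmrs_batch",
    "rmrs",
    "derive_diagnostic_threshold",
    "count_risk_factors",
    "score_subject",
    "round_half_away",
]

#: Canonical reporting order of the five risk-factor axes.
FACTORS: tuple[str, ...] = ("gl", "bp", "tg", "hdl", "wc")

#: Fixed structural diagnostic cutoff for RMRS.
DIAGNOSTIC_THRESHOLD: float = 0.547

#: Area of the threshold triangle (all axes at 0.5) in pairwise-product-sum
#: units: 0.5**2 * 3.  The geometric area carries a further common factor
#: of sin(pi/3)/2 which cancels in every TAS ratio.
C_ALPHA: float = 0.75

#: Severity capacity: maximum triangle minus threshold triangle, 3*C_ALPHA.
C_BETA: float = 2.25

_SIN60_HALF = 0.5 * math.sin(math.pi / 3.0)


class InvalidMeasurementError(ValueError):
    """A raw measurement is missing, non-finite or non-positive."""


class InvalidThresholdError(ValueError):
    """A diagnostic threshold is non-positive or unresolvable."""


class ImplausibleBloodPressureError(ValueError):
    """Systolic pressure does not exceed diastolic pressure."""


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (the convention used for reported scores)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FactorThresholds:
    """AHA/NHLBI diagnostic cutpoints, sex- and region-resolved.

    HDL and waist thresholds depend on sex (HDL: 40 male / 50 female
    mg/dl) and on (region, sex) for waist (American 102/88 cm, Korean
    90/85 cm per the Korean Society for Obesity).
    """

    glucose_mgdl: float = 100.0
    sbp_mmhg: float = 130.0
    dbp_mmhg: float = 85.0
    triglycerides_mgdl: float = 150.0
    hdl_mgdl: float = 40.0
    waist_cm: float = 90.0

    def __post_init__(self) -> None:
        for name in (
            "glucose_mgdl",
            "sbp_mmhg",
            "dbp_mmhg",
            "triglycerides_mgdl",
            "hdl_mgdl",
            "waist_cm",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidThresholdError(f"{name} must be strictly positive, got {v!r}")
        if abs(self.dbp_mmhg - self.sbp_mmhg) <= 0:
            raise InvalidThresholdError("systolic and diastolic thresholds must differ")

    @property
    def bp_unit_mmhg(self) -> float:
        """One normalization unit for BP: 10 % of |d_dbp - d_sbp| (4.5 mmHg
        with defaults)."""
        return 0.1 * abs(self.dbp_mmhg - self.sbp_mmhg)

    @classmethod
    def for_subject(
        cls,
        sex: str,
        region: str = "korean",
        **overrides: float,
    ) -> "FactorThresholds":
        """Resolve sex/region-specific defaults, applying any overrides."""
        sex = sex.lower()
        region = region.lower()
        if sex not in ("male", "female"):
            raise InvalidThresholdError(f"unrecognized sex {sex!r}")
        if region not in ("korean", "american"):
            raise InvalidThresholdError(f"unrecognized region {region!r}")
        hdl = 40.0 if sex == "male" else 50.0
        waist = {
            ("american", "male"): 102.0,
            ("american", "female"): 88.0,
            ("korean", "male"): 90.0,
            ("korean", "female"): 85.0,
        }[(region, sex)]
        values = dict(hdl_mgdl=hdl, waist_cm=waist)
        values.update(overrides)
        return cls(**values)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's raw clinical measurements plus demographics.

    Units: glucose, triglycerides, hdl in mg/dl; sbp, dbp in mmHg;
    waist in cm.
    """

    glucose: float
    sbp: float
    dbp: float
    triglycerides: float
    hdl: float
    waist: float
    sex: Literal["male", "female"]
    region: Literal["korean", "american"] = "korean"
    age: float | None = None
    race: str | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        for name in ("glucose", "sbp", "dbp", "triglycerides", "hdl", "waist"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v <= 0:
                raise InvalidMeasurementError(
                    f"{name} must be a finite positive number, got {v!r}"
                )
        if self.sbp <= self.dbp:
            raise ImplausibleBloodPressureError(
                f"sbp ({self.sbp}) must exceed dbp ({self.dbp})"
            )


@dataclass(frozen=True)
class ScaledVector:
    """Sigmoid-scaled axis values, each in [0, 1]; 0.5 marks the threshold.

    The sigmoid's range is open (0, 1); exact 0 and 1 are admitted as
    limit inputs for analytic configurations.
    """

    s_gl: float
    s_bp: float
    s_tg: float
    s_hdl: float
    s_wc: float

    def __post_init__(self) -> None:
        for v in self.as_tuple():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"scaled component {v!r} outside [0, 1]")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.s_gl, self.s_bp, self.s_tg, self.s_hdl, self.s_wc)

    def as_array(self) -> np.ndarray:
        return np.array(self.as_tuple(), dtype=float)


@dataclass(frozen=True)
class TriadScore:
    """Per-triad TAS quantities for one three-axis radar chart."""

    factors: tuple[str, str, str]
    x: tuple[float, float, float]
    x_prime: tuple[float, float, float]
    big_x: float
    big_x_prime: float
    indicator: int
    closeness: float
    severity: float
    tas: float


@dataclass(frozen=True)
class RmrsResult:
    """Full scoring result for one subject or analytic vector."""

    rmrs: float
    triad_scores: tuple[TriadScore, ...]
    risk_factor_count: int
    diagnosis_by_count: bool
    diagnosis_by_rmrs: bool
    threshold_used: float = DIAGNOSTIC_THRESHOLD
    scaled: ScaledVector | None = None


class ThresholdDerivation(NamedTuple):
    min_three: float
    max_two: float
    threshold: float


# ---------------------------------------------------------------------------
# Axis scaling
# ---------------------------------------------------------------------------


def normalize_factor(
    value: float,
    threshold: float,
    direction: Literal["higher_is_risk", "lower_is_risk"] = "higher_is_risk",
) -> float:
    """Normalize a measurement so the threshold maps to 0 and 10 % of the
    threshold is one unit.

    ``lower_is_risk`` (HDL) flips the sign so risk always increases with Z.
    """
    if not (np.isfinite(threshold) and threshold > 0):
        raise InvalidThresholdError(f"threshold must be positive, got {threshold!r}")
    if value is None or not np.isfinite(value):
        raise InvalidMeasurementError(f"measurement must be finite, got {value!r}")
    z = (value - threshold) / (0.1 * threshold)
    if direction == "lower_is_risk":
        z = -z
    elif direction != "higher_is_risk":
        raise ValueError(f"unknown direction {direction!r}")
    return z


def normalize_bp(sbp: float, dbp: float, thresholds: FactorThresholds | None = None) -> float:
    """Normalize blood pressure: the larger threshold exceedance of the two
    readings, in units of 10 % of the gap between the two cutpoints
    (4.5 mmHg with defaults)."""
    if thresholds is None:
        thresholds = FactorThresholds()
    if not (np.isfinite(sbp) and np.isfinite(dbp)) or sbp <= 0 or dbp <= 0:
        raise InvalidMeasurementError("blood pressures must be finite and positive")
    if sbp <= dbp:
        raise ImplausibleBloodPressureError(f"sbp ({sbp}) must exceed dbp ({dbp})")
    exceed = max(sbp - thresholds.sbp_mmhg, dbp - thresholds.dbp_mmhg)
    return exceed / thresholds.bp_unit_mmhg


def elliot_sigmoid(z):
    """Elliot sigmoid S = 0.5*Z/(1+|Z|) + 0.5.

    Monotone, symmetric about (0, 0.5), range (0, 1); maps -1, 0, 1 to
    exactly 0.25, 0.5, 0.75. Accepts scalars or arrays.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise InvalidMeasurementError("sigmoid input must be finite")
    s = 0.5 * z / (1.0 + np.abs(z)) + 0.5
    return float(s) if s.ndim == 0 else s


def scale_subject(record: SubjectRecord, thresholds: FactorThresholds | None = None) -> ScaledVector:
    """Map a subject's raw measurements to the five scaled axes."""
    if thresholds is None:
        thresholds = FactorThresholds.for_subject(record.sex, record.region)
    z = (
        normalize_factor(record.glucose, thresholds.glucose_mgdl),
        normalize_bp(record.sbp, record.dbp, thresholds),
        normalize_factor(record.triglycerides, thresholds.triglycerides_mgdl),
        normalize_factor(record.hdl, thresholds.hdl_mgdl, "lower_is_risk"),
        normalize_factor(record.waist, thresholds.waist_cm),
    )
    s = elliot_sigmoid(np.array(z))
    return ScaledVector(*(float(v) for v in s))


# ---------------------------------------------------------------------------
# Triads and triangle geometry
# ---------------------------------------------------------------------------


def enumerate_triads(factors: Iterable[str] = FACTORS) -> list[tuple[str, str, str]]:
    """All C(5,3) = 10 unordered factor triples, in canonical order."""
    labels = list(factors)
    if len(labels) != len(set(labels)) or len(labels) != 5:
        raise ValueError(f"expected exactly 5 distinct factor labels, got {labels!r}")
    order = {f: i for i, f in enumerate(FACTORS)}
    if set(labels) == set(FACTORS):
        labels.sort(key=order.__getitem__)
    else:
        labels.sort()
    return list(combinations(labels, 3))


def _check_unit(*values: float) -> None:
    for v in values:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"scaled value {v!r} outside [0, 1]")


def triangle_area(x1: float, x2: float, x3: float) -> float:
    """Planar area of the radar-chart triangle with vertices at radii
    x1, x2, x3 on axes 120 degrees apart: (1/2) sin(60) (x1x2+x2x3+x3x1)."""
    _check_unit(x1, x2, x3)
    return _SIN60_HALF * (x1 * x2 + x2 * x3 + x3 * x1)


def clip_internal(x: Sequence[float]) -> tuple[float, ...]:
    """Clip each component at the threshold 0.5 (internal-triangle radii)."""
    _check_unit(*x)
    return tuple(min(v, 0.5) for v in x)


# ---------------------------------------------------------------------------
# TAS and RMRS
# ---------------------------------------------------------------------------


def tas_score(
    x1: float,
    x2: float,
    x3: float,
    factors: tuple[str, str, str] = ("a", "b", "c"),
) -> TriadScore:
    """TAS score of one triad: average of closeness and severity.

    closeness = X / (C_alpha + X - X'); severity = I * (X - X') / C_beta,
    where X and X' are pairwise-product sums of the raw and
    threshold-clipped scaled values and I indicates all three axes at or
    above the threshold. The common geometric factor sin(60)/2 cancels, so
    C_alpha = 0.75 and C_beta = 2.25 in product-sum units.
    """
    _check_unit(x1, x2, x3)
    x = (x1, x2, x3)
    xp = clip_internal(x)
    big_x = x1 * x2 + x2 * x3 + x3 * x1
    big_xp = xp[0] * xp[1] + xp[1] * xp[2] + xp[2] * xp[0]
    indicator = int(all(v >= 0.5 for v in x))
    s_beta = big_x - big_xp
    closeness = big_x / (C_ALPHA + s_beta)
    severity = indicator * s_beta / C_BETA
    tas = 0.5 * (closeness + severity)
    return TriadScore(
        factors=factors,
        x=x,
        x_prime=xp,
        big_x=big_x,
        big_x_prime=big_xp,
        indicator=indicator,
        closeness=closeness,
        severity=severity,
        tas=tas,
    )


def tas_value(x1: float, x2: float, x3: float) -> float:
    """TAS score of one triad as a bare float."""
    return tas_score(x1, x2, x3).tas


def _triad_scores(values: Sequence[float]) -> tuple[TriadScore, ...]:
    by_label = dict(zip(FACTORS, values))
    return tuple(
        tas_score(by_label[a], by_label[b], by_label[c], factors=(a, b, c))
        for a, b, c in enumerate_triads()
    )


def rmrs_value(values: Sequence[float]) -> float:
    """RMRS of five scaled values: sqrt of the mean TAS over the 10 triads."""
    if len(values) != 5:
        raise ValueError(f"expected 5 scaled values, got {len(values)}")
    scores = _triad_scores(values)
    return math.sqrt(sum(t.tas for t in scores) / 10.0)


_TRIAD_INDEX = list(combinations(range(5), 3))


def rmrs_batch(values: np.ndarray) -> np.ndarray:
    """Vectorized RMRS for an (n, 5) array of scaled vectors."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[1] != 5:
        raise ValueError("expected an (n, 5) array of scaled values")
    if np.any((v < 0) | (v > 1)):
        raise ValueError("scaled values outside [0, 1]")
    vp = np.minimum(v, 0.5)
    tas_sum = np.zeros(len(v))
    for i, j, k in _TRIAD_INDEX:
        x = v[:, i] * v[:, j] + v[:, j] * v[:, k] + v[:, k] * v[:, i]
        xp = vp[:, i] * vp[:, j] + vp[:, j] * vp[:, k] + vp[:, k] * vp[:, i]
        ind = (v[:, i] >= 0.5) & (v[:, j] >= 0.5) & (v[:, k] >= 0.5)
        s_beta = x - xp
        closeness = x / (C_ALPHA + s_beta)
        severity = np.where(ind, s_beta / C_BETA, 0.0)
        tas_sum += 0.5 * (closeness + severity)
    return np.sqrt(tas_sum / 10.0)


def rmrs(
    scaled: ScaledVector | Sequence[float],
    threshold: float = DIAGNOSTIC_THRESHOLD,
) -> RmrsResult:
    """Score a scaled vector.

    When only scaled values are available the risk-factor count is the
    number of axes at or above 0.5; ``score_subject`` counts in raw
    measurement space instead (the two differ only on the HDL boundary).
    """
    if isinstance(scaled, ScaledVector):
        values = scaled.as_tuple()
    else:
        values = tuple(float(v) for v in scaled)
        scaled = ScaledVector(*values)
    scores = _triad_scores(values)
    value = math.sqrt(sum(t.tas for t in scores) / 10.0)
    count = sum(1 for v in values if v >= 0.5)
    return RmrsResult(
        rmrs=value,
        triad_scores=scores,
        risk_factor_count=count,
        diagnosis_by_count=count >= 3,
        diagnosis_by_rmrs=value >= threshold,
        threshold_used=threshold,
        scaled=scaled,
    )


def derive_diagnostic_threshold(eps: float = 1e-9) -> ThresholdDerivation:
    """Derive the fixed cutoff from the score's structure alone.

    The minimum three-factor score comes from (0.5, 0.5, 0.5, 0, 0); the
    supremum two-factor score is the limit of (1, 1, 0.5-e, 0.5-e, 0.5-e)
    as e -> 0, evaluated at e = 1e-9. The cutoff is their midpoint:
    (0.387 + 0.707) / 2 = 0.547 at three decimals.
    """
    min_three = rmrs_value([0.5, 0.5, 0.5, 0.0, 0.0])
    max_two = rmrs_value([1.0, 1.0, 0.5 - eps, 0.5 - eps, 0.5 - eps])
    return ThresholdDerivation(min_three, max_two, (min_three + max_two) / 2.0)


# ---------------------------------------------------------------------------
# Count-based diagnosis and subject-level scoring
# ---------------------------------------------------------------------------


def count_risk_factors(record: SubjectRecord, thresholds: FactorThresholds | None = None) -> int:
    """Count abnormal factors in raw measurement space (Table-style rules):
    GL >= 100, SBP >= 130 or DBP >= 85, TG >= 150, HDL strictly below the
    sex threshold, WC >= the region/sex threshold."""
    if thresholds is None:
        thresholds = FactorThresholds.for_subject(record.sex, record.region)
    abnormal = (
        record.glucose >= thresholds.glucose_mgdl,
        record.sbp >= thresholds.sbp_mmhg or record.dbp >= thresholds.dbp_mmhg,
        record.triglycerides >= thresholds.triglycerides_mgdl,
        record.hdl < thresholds.hdl_mgdl,
        record.waist >= thresholds.waist_cm,
    )
    return sum(abnormal)


def score_subject(
    record: SubjectRecord,
    thresholds: FactorThresholds | None = None,
    threshold: float = DIAGNOSTIC_THRESHOLD,
) -> RmrsResult:
    """Full pipeline for one subject: scale, score all 10 triads, take
    RMRS, and attach both the count-based and score-based diagnoses."""
    if thresholds is None:
        thresholds = FactorThresholds.for_subject(record.sex, record.region)
    scaled = scale_subject(record, thresholds)
    scores = _triad_scores(scaled.as_tuple())
    value = math.sqrt(sum(t.tas for t in scores) / 10.0)
    count = count_risk_factors(record, thresholds)
    return RmrsResult(
        rmrs=value,
        triad_scores=scores,
        risk_factor_count=count,
        diagnosis_by_count=count >= 3,
        diagnosis_by_rmrs=value >= threshold,
        threshold_used=threshold,
        scaled=scaled,
    )
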