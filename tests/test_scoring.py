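"""Unit and property tests for axis scaling, TAS and RMRS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rmrs import (
    FACTORS,
    FactorThresholds,
    ScaledVector,
    SubjectRecord,
    count_risk_factors,
    derive_diagnostic_threshold,
    elliot_sigmoid,
    enumerate_triads,
    normalize_bp,
    normalize_factor,
    rmrs,
    rmrs_batch,
    rmrs_value,
    scale_subject,
    score_subject,
    tas_score,
    tas_value,
    triangle_area,
)
from rmrs.scoring import (
    ImplausibleBloodPressureError,
    InvalidMeasurementError,
    InvalidThresholdError,
    clip_internal,
    round_half_away,
)

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "value, threshold, direction, expected",
    [
        (100, 100, "higher_is_risk", 0.0),
        (110, 100, "higher_is_risk", 1.0),
        (36, 40, "lower_is_risk", 1.0),  # HDL four units below its cutoff
        (90, 100, "higher_is_risk", -1.0),
    ],
)
def test_normalize_factor(value, threshold, direction, expected):
    assert normalize_factor(value, threshold, direction) == pytest.approx(expected)


def test_normalize_factor_rejects_bad_inputs():
    with pytest.raises(InvalidThresholdError):
        normalize_factor(100, 0)
    with pytest.raises(InvalidThresholdError):
        normalize_factor(100, -5)
    with pytest.raises(InvalidMeasurementError):
        normalize_factor(float("nan"), 100)


@pytest.mark.parametrize(
    "sbp, dbp, expected",
    [
        (130, 85, 0.0),
        (139, 80, 2.0),   # max(9, -5) / 4.5
        (120, 85, 0.0),   # diastolic at threshold dominates
        (134.5, 80, 1.0),
    ],
)
def test_normalize_bp(sbp, dbp, expected):
    assert normalize_bp(sbp, dbp) == pytest.approx(expected)


def test_normalize_bp_unit_is_4_5_mmhg():
    assert FactorThresholds().bp_unit_mmhg == pytest.approx(4.5)


def test_normalize_bp_rejects_inverted_readings():
    with pytest.raises(ImplausibleBloodPressureError):
        normalize_bp(80, 120)


# ---------------------------------------------------------------------------
# sigmoid
# ---------------------------------------------------------------------------


def test_sigmoid_anchors_exact():
    """One normalization unit below/at/above threshold maps to exactly
    0.25 / 0.5 / 0.75."""
    assert elliot_sigmoid(-1) == 0.25
    assert elliot_sigmoid(0) == 0.5
    assert elliot_sigmoid(1) == 0.75


@given(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False))
@settings(derandomize=True)
def test_sigmoid_bounded_and_symmetric(z):
    s = elliot_sigmoid(z)
    assert 0.0 < s < 1.0 or z == 0
    assert elliot_sigmoid(-z) == pytest.approx(1.0 - s, abs=1e-12)


@given(st.floats(-100, 100), st.floats(-100, 100))
@settings(derandomize=True)
def test_sigmoid_monotone(a, b):
    if a < b:
        assert elliot_sigmoid(a) <= elliot_sigmoid(b)
    if b - a > 1e-9:  # strict once the gap is numerically resolvable
        assert elliot_sigmoid(a) < elliot_sigmoid(b)


# ---------------------------------------------------------------------------
# subject scaling
# ---------------------------------------------------------------------------


def test_scale_all_at_threshold(at_threshold_korean_male):
    scaled = scale_subject(at_threshold_korean_male)
    assert scaled.as_tuple() == pytest.approx((0.5,) * 5)


def test_scale_glucose_one_unit_above(at_threshold_korean_male):
    rec = SubjectRecord(
        glucose=110, sbp=130, dbp=85, triglycerides=150, hdl=40, waist=90,
        sex="male",
    )
    scaled = scale_subject(rec)
    assert scaled.s_gl == pytest.approx(0.75)
    assert scaled.as_tuple()[1:] == pytest.approx((0.5,) * 4)


def test_scale_hdl_sex_resolved():
    rec = SubjectRecord(
        glucose=90, sbp=110, dbp=70, triglycerides=100, hdl=50, waist=80,
        sex="female",
    )
    assert scale_subject(rec).s_hdl == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# triads and geometry
# ---------------------------------------------------------------------------


def test_enumerate_triads_canonical():
    triads = enumerate_triads()
    assert len(triads) == 10
    assert len(set(triads)) == 10
    assert all(len(t) == 3 for t in triads)
    # order invariance of the input set
    assert enumerate_triads(reversed(FACTORS)) == triads


def test_enumerate_triads_cardinality_check():
    with pytest.raises(ValueError):
        enumerate_triads(["a", "b", "c"])
    with pytest.raises(ValueError):
        enumerate_triads(["a", "a", "b", "c", "d"])


def _shoelace(radii):
    """Independent oracle: planar polygon area from explicit radar-chart
    vertex coordinates at 0, 120, 240 degrees."""
    angles = [0.0, 2 * math.pi / 3, 4 * math.pi / 3]
    pts = [(r * math.cos(a), r * math.sin(a)) for r, a in zip(radii, angles)]
    s = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:] + pts[:1]):
        s += x0 * y1 - x1 * y0
    return abs(s) / 2.0


@pytest.mark.parametrize(
    "radii, expected",
    [
        ((1, 1, 1), 1.299),       # maximum triangle
        ((0.5, 0.5, 0.5), 0.3248),  # threshold triangle
    ],
)
def test_triangle_area_criteria_triangles(radii, expected):
    assert triangle_area(*radii) == pytest.approx(expected, abs=5e-4)


@given(unit, unit, unit)
@settings(derandomize=True, max_examples=300)
def test_triangle_area_matches_shoelace(x1, x2, x3):
    assert triangle_area(x1, x2, x3) == pytest.approx(_shoelace((x1, x2, x3)), abs=1e-12)


def test_clip_internal():
    assert clip_internal((0.9, 0.4, 0.5)) == (0.5, 0.4, 0.5)
    assert clip_internal((0.1, 0.2, 0.3)) == (0.1, 0.2, 0.3)
    assert clip_internal((1, 1, 1)) == (0.5, 0.5, 0.5)


# ---------------------------------------------------------------------------
# TAS
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x, expected",
    [
        ((0.5, 0.5, 0.5), 0.5),   # closeness 1, severity 0
        ((1, 1, 1), 1.0),         # closeness 1, severity (4/9)*2.25 = 1
        ((0.5, 0.5, 0.0), 1 / 6),  # X = X' = 0.25, closeness 1/3
        ((0, 0, 0), 0.0),
    ],
)
def test_tas_examples(x, expected):
    assert tas_value(*x) == pytest.approx(expected, abs=1e-12)


def test_tas_geometric_oracle():
    """TAS agrees with an independent computation done on true geometric
    areas (closeness and severity defined through triangle_area)."""
    rng = np.random.default_rng(42)
    c_alpha = triangle_area(0.5, 0.5, 0.5)
    c_beta = triangle_area(1, 1, 1) - c_alpha
    for x in rng.uniform(0, 1, size=(200, 3)):
        s_x = triangle_area(*x)
        s_xp = triangle_area(*clip_internal(x))
        s_beta = s_x - s_xp
        indicator = 1 if all(v >= 0.5 for v in x) else 0
        closeness = (s_xp + s_beta) / (c_alpha + s_beta)
        severity = indicator * s_beta / c_beta
        assert tas_value(*x) == pytest.approx((closeness + severity) / 2, abs=1e-12)


def test_tas_triad_fields():
    ts = tas_score(0.9, 0.6, 0.7)
    assert ts.indicator == 1
    assert ts.big_x_prime == pytest.approx(0.75)
    assert ts.big_x_prime <= min(ts.big_x, 0.75) + 1e-12
    assert ts.tas == pytest.approx((ts.closeness + ts.severity) / 2)
    below = tas_score(0.9, 0.6, 0.3)
    assert below.indicator == 0
    assert below.severity == 0.0


@given(unit, unit, unit)
@settings(derandomize=True, max_examples=300)
def test_tas_range_and_permutation_invariance(x1, x2, x3):
    t = tas_value(x1, x2, x3)
    assert 0.0 <= t <= 1.0
    for perm in ((x2, x1, x3), (x3, x2, x1), (x2, x3, x1)):
        assert tas_value(*perm) == pytest.approx(t, abs=1e-12)


@given(st.lists(unit, min_size=3, max_size=3), st.lists(unit, min_size=3, max_size=3))
@settings(derandomize=True, max_examples=300)
def test_tas_monotone_componentwise(a, b):
    lo = [min(u, v) for u, v in zip(a, b)]
    hi = [max(u, v) for u, v in zip(a, b)]
    assert tas_value(*lo) <= tas_value(*hi) + 1e-12


# ---------------------------------------------------------------------------
# RMRS
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "values, expected",
    [
        ((0.5, 0.5, 0.5, 0, 0), 0.387),
        ((1, 1, 1, 1, 1), 1.0),
        ((0.5, 0.5, 0, 0, 0), 0.224),
        ((0.5,) * 5, 0.707),
    ],
)
def test_rmrs_printed_values(values, expected):
    assert round_half_away(rmrs_value(values)) == pytest.approx(expected)


@given(st.lists(unit, min_size=5, max_size=5))
@settings(derandomize=True, max_examples=300)
def test_rmrs_range_and_permutation_invariance(values):
    v = rmrs_value(values)
    assert 0.0 <= v <= 1.0
    rng = np.random.default_rng(0)
    for _ in range(3):
        perm = list(rng.permutation(values))
        assert rmrs_value(perm) == pytest.approx(v, abs=1e-12)


@given(st.lists(unit, min_size=5, max_size=5), st.lists(unit, min_size=5, max_size=5))
@settings(derandomize=True, max_examples=200)
def test_rmrs_monotone_componentwise(a, b):
    lo = [min(u, v) for u, v in zip(a, b)]
    hi = [max(u, v) for u, v in zip(a, b)]
    assert rmrs_value(lo) <= rmrs_value(hi) + 1e-12


def test_rmrs_batch_matches_scalar():
    rng = np.random.default_rng(3)
    v = rng.uniform(0, 1, size=(500, 5))
    batch = rmrs_batch(v)
    for row, expected in zip(v, batch):
        assert rmrs_value(row) == pytest.approx(expected, abs=1e-12)


def test_threshold_derivation():
    d = derive_diagnostic_threshold()
    assert round_half_away(d.min_three) == 0.387
    assert round_half_away(d.max_two) == 0.707
    assert round_half_away(d.threshold) == 0.547


# ---------------------------------------------------------------------------
# counting and subject-level scoring
# ---------------------------------------------------------------------------


def test_count_risk_factors_boundary_semantics():
    # GL, TG, WC at threshold count; HDL at threshold does not; BP below both
    rec = SubjectRecord(glucose=100, sbp=120, dbp=80, triglycerides=150,
                        hdl=40, waist=90, sex="male", region="korean")
    assert count_risk_factors(rec) == 3


def test_count_risk_factors_extremes():
    low = SubjectRecord(glucose=80, sbp=105, dbp=65, triglycerides=80,
                        hdl=70, waist=70, sex="male")
    assert count_risk_factors(low) == 0
    high = SubjectRecord(glucose=120, sbp=140, dbp=90, triglycerides=200,
                         hdl=30, waist=95, sex="male", region="korean")
    assert count_risk_factors(high) == 5


def test_score_subject_at_threshold(at_threshold_korean_male):
    res = score_subject(at_threshold_korean_male)
    assert round_half_away(res.rmrs) == 0.707
    # HDL exactly at its cutoff is normal under the strict < rule, so the
    # raw-space count is 4 (GL, BP, TG, WC), and both diagnoses fire.
    assert res.risk_factor_count == 4
    assert res.diagnosis_by_count
    assert res.diagnosis_by_rmrs


def test_score_subject_all_low():
    rec = SubjectRecord(glucose=70, sbp=100, dbp=60, triglycerides=60,
                        hdl=90, waist=60, sex="female")
    res = score_subject(rec)
    assert res.rmrs < 0.3
    assert res.risk_factor_count == 0
    assert not res.diagnosis_by_count
    assert not res.diagnosis_by_rmrs


def test_count_score_disagreement_at_minimal_three():
    """Exactly three factors at threshold, two far below: positive by
    count but the score 0.387 sits under the 0.547 cutoff — the expected
    disagreement at the extreme boundary."""
    res = rmrs([0.5, 0.5, 0.5, 0.0, 0.0])
    assert res.risk_factor_count == 3
    assert res.diagnosis_by_count
    assert not res.diagnosis_by_rmrs


def test_scaled_vector_validates_domain():
    with pytest.raises(ValueError):
        ScaledVector(1.2, 0.5, 0.5, 0.5, 0.5)


def test_subject_record_validation():
    with pytest.raises(InvalidMeasurementError):
        SubjectRecord(glucose=-1, sbp=120, dbp=80, triglycerides=100,
                      hdl=50, waist=80, sex="male")
    with pytest.raises(ImplausibleBloodPressureError):
        SubjectRecord(glucose=90, sbp=80, dbp=120, triglycerides=100,
                      hdl=50, waist=80, sex="male")
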