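"""Hand-oracle and property tests for the agreement statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from posturekit import (
    DeviceAgreement,
    EquivalenceRegion,
    bland_altman,
    correlation,
    difference_test,
    equivalence_region_for,
    escalate_equivalence,
    generate_paired_measurements,
    lin_ccc,
    mcbride_category,
    tost_equivalence,
)
from posturekit.agreement import DegenerateDataError, equivalence_verdict
from posturekit.synthetic import ErrorModel


# ---------------------------------------------------------------------------
# brute-force / textbook oracles (pure-python, independent of the package)
# ---------------------------------------------------------------------------

def _moments(x):
    n = len(x)
    m = sum(x) / n
    return m, sum((v - m) ** 2 for v in x) / n


def brute_ccc(x, y):
    mx, sx2 = _moments(x)
    my, sy2 = _moments(y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / len(x)
    return 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def brute_pearson(x, y):
    mx, sx2 = _moments(x)
    my, sy2 = _moments(y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / len(x)
    return sxy / math.sqrt(sx2 * sy2)


def brute_bland_altman(x, y):
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    bias = sum(d) / n
    sd = math.sqrt(sum((v - bias) ** 2 for v in d) / (n - 1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd

def brute_tost_ci(x, y):
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    m = sum(d) / n
    sd = math.sqrt(sum((v - m) ** 2 for v in d) / (n - 1))
    half = float(stats.t.ppf(0.95, n - 1)) * sd / math.sqrt(n)
    return m - half, m + half


# ---------------------------------------------------------------------------
# difference test
# ---------------------------------------------------------------------------

def test_identical_measurements_flagged_degenerate():
    x = np.array([10.0, 20.0, 30.0, 40.0])
    res = difference_test(x, x)
    assert res.test == "degenerate"
    assert res.p_value is None


def test_gaussian_differences_select_paired_t_and_match_textbook():
    rng = np.random.default_rng(3)
    y = rng.normal(100, 20, 20)
    x = y + rng.normal(0, 5, 20)
    res = difference_test(x, y)
    assert res.test == "paired_t"
    d = x - y
    tstat = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
    p = 2 * float(stats.t.sf(abs(tstat), len(d) - 1))
    assert res.statistic == pytest.approx(tstat, abs=1e-10)
    assert res.p_value == pytest.approx(p, abs=1e-10)


def test_skewed_differences_select_wilcoxon():
    rng = np.random.default_rng(1)
    y = rng.normal(100, 10, 20)
    x = y + rng.lognormal(1.0, 1.2, 20)  # heavily right-skewed differences
    assert float(stats.shapiro(x - y).pvalue) < 0.05
    res = difference_test(x, y)
    assert res.test == "wilcoxon"


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def test_identity_gives_r_of_one():
    x = np.array([1.0, 2.0, 4.0, 8.0, 9.0])
    res = correlation(x, x.copy())
    assert res.r == pytest.approx(1.0)


def test_perfect_negative_linear_association():
    y = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
    x = -y + 100
    res = correlation(x, y)
    assert res.method == "pearson"
    assert res.r == pytest.approx(-1.0)


def test_zero_variance_margin_is_undefined():
    with pytest.raises(DegenerateDataError):
        correlation(np.full(5, 3.0), np.arange(5.0))


def test_large_sample_consistency_of_pearson():
    rng = np.random.default_rng(7)
    n, rho = 10000, 0.9
    z = rng.normal(size=n)
    x = rho * z + math.sqrt(1 - rho**2) * rng.normal(size=n)
    res = correlation(x, z)
    assert abs(res.r - rho) < 0.01
    assert res.ci_low < res.r < res.ci_high


def test_pearson_ci_matches_fisher_formula(toy_pairs):
    x, y = toy_pairs
    res = correlation(x, y)
    z = math.atanh(res.r)
    se = 1 / math.sqrt(len(x) - 3)
    zc = float(stats.norm.ppf(0.975))
    assert res.ci_low == pytest.approx(math.tanh(z - zc * se), abs=1e-10)
    assert res.ci_high == pytest.approx(math.tanh(z + zc * se), abs=1e-10)


# ---------------------------------------------------------------------------
# Lin's CCC and McBride bands
# ---------------------------------------------------------------------------

def test_ccc_matches_hand_moment_formula(toy_pairs):
    x, y = toy_pairs
    ccc, (lo, hi) = lin_ccc(x, y)
    assert ccc == pytest.approx(brute_ccc(list(x), list(y)), abs=1e-12)
    assert lo < ccc < hi


def test_ccc_is_one_for_perfect_concordance():
    x = np.array([5.0, 10.0, 15.0, 20.0])
    ccc, (lo, hi) = lin_ccc(x, x.copy())
    assert ccc == pytest.approx(1.0)
    assert (lo, hi) == (ccc, ccc)


def test_location_shift_penalizes_ccc_but_not_r(toy_pairs):
    x, y = toy_pairs
    shifted = y + 25.0
    ccc, _ = lin_ccc(shifted, y)
    r = brute_pearson(list(shifted), list(y))
    assert ccc < r
    assert r == pytest.approx(1.0)


@settings(max_examples=100, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.floats(0, 300), st.floats(0, 300)), min_size=4, max_size=10
    )
)
def test_ccc_never_exceeds_absolute_pearson(data):
    x = [a for a, _ in data]
    y = [b for _, b in data]
    _, sx2 = _moments(x)
    _, sy2 = _moments(y)
    if sx2 < 1e-9 or sy2 < 1e-9:
        return
    ccc, _ = lin_ccc(np.array(x), np.array(y))
    assert abs(ccc) <= abs(brute_pearson(x, y)) + 1e-9


@pytest.mark.parametrize(
    "ccc, category",
    [
        (0.98, "substantial"),
        (0.93, "moderate"),
        (0.74, "poor"),
        (0.995, "almost perfect"),
        (0.90, "moderate"),
        (0.95, "substantial"),
        (0.99, "almost perfect"),
        (-0.2, "poor"),
    ],
)
def test_mcbride_bands(ccc, category):
    assert mcbride_category(ccc) == category


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def test_bland_altman_closed_form_four_differences():
    y = np.array([10.0, 20.0, 30.0, 40.0])
    x = y + np.array([-3.0, -1.0, 1.0, 3.0])
    res = bland_altman(x, y)
    sd = math.sqrt((9 + 1 + 1 + 9) / 3)  # ddof=1
    assert res.mean_bias == pytest.approx(0.0, abs=1e-12)
    assert res.loa_lower == pytest.approx(-1.96 * sd, abs=1e-12)
    assert res.loa_upper == pytest.approx(1.96 * sd, abs=1e-12)


def test_bland_altman_identity_collapses_loa():
    x = np.array([5.0, 6.0, 7.0])
    res = bland_altman(x, x.copy())
    assert res.mean_bias == res.loa_lower == res.loa_upper == 0.0


@settings(max_examples=100, derandomize=True)
@given(
    diffs=st.lists(st.floats(-50, 50), min_size=2, max_size=12),
)
def test_loa_symmetric_about_bias(diffs):
    y = np.linspace(50, 150, len(diffs))
    x = y + np.array(diffs)
    res = bland_altman(x, y)
    assert res.loa_upper - res.mean_bias == pytest.approx(
        res.mean_bias - res.loa_lower, abs=1e-9
    )
    assert res.loa_lower <= res.mean_bias <= res.loa_upper


# ---------------------------------------------------------------------------
# TOST equivalence
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ci, half, expected",
    [
        ((0.2, 20.8), 30.0, True),
        ((-10.5, 0.3), 11.0, True),
        ((-4.5, 2.1), 4.0, False),
        ((1.3, 12.4), 41.0, True),
        ((-0.9, 4.8), 7.0, True),
    ],
)
def test_equivalence_verdict_interval_containment(ci, half, expected):
    assert equivalence_verdict(ci[0], ci[1], half) is expected


def test_tost_ci_matches_textbook_formula(toy_pairs):
    x, y = toy_pairs
    res = tost_equivalence(x, y, EquivalenceRegion(half_width_min=15.0, derivation="absolute"))
    lo, hi = brute_tost_ci(list(x), list(y))
    assert res.ci90_low == pytest.approx(lo, abs=1e-10)
    assert res.ci90_high == pytest.approx(hi, abs=1e-10)


def test_zero_difference_is_equivalent_for_any_region():
    x = np.array([10.0, 20.0, 30.0])
    res = tost_equivalence(x, x.copy(), 0.5)
    assert res.ci90_low == res.ci90_high == 0.0
    assert res.equivalent


@settings(max_examples=60, derandomize=True)
@given(half=st.floats(0.5, 50), extra=st.floats(0.1, 50))
def test_tost_verdict_monotone_in_half_width(half, extra):
    x = np.array([182.0, 150.0, 95.5, 210.0, 125.0])
    y = np.array([180.0, 160.0, 100.0, 200.0, 130.0])
    narrow = tost_equivalence(x, y, half)
    wide = tost_equivalence(x, y, half + extra)
    if narrow.equivalent:
        assert wide.equivalent


# ---------------------------------------------------------------------------
# equivalence regions and escalation
# ---------------------------------------------------------------------------

def test_region_rounds_to_whole_minutes():
    # 15% of a 75.4-minute criterion mean is 11.31 -> +/-11 min
    region = equivalence_region_for(np.full(20, 75.4), 0.15)
    assert region.half_width_min == 11.0
    # 15% of 24.0 is 3.6 -> rounds up to +/-4 min
    region = equivalence_region_for(np.full(20, 24.0), 0.15)
    assert region.half_width_min == 4.0


def test_invalid_fraction_rejected():
    with pytest.raises(ValueError):
        equivalence_region_for(np.array([10.0]), 0.0)


def test_escalation_zero_difference_stops_at_start():
    x = np.full(10, 60.0)
    assert escalate_equivalence(x, x.copy(), start_fraction=0.10) == pytest.approx(0.10)


def test_escalation_finds_fraction_just_above_bias():
    # noise-free bias of 12% of the criterion mean: 10% fails, 15% passes
    y = np.full(12, 100.0)
    x = y + 12.0
    assert escalate_equivalence(x, y, start_fraction=0.05) == pytest.approx(0.15)
    assert escalate_equivalence(x, y + 1000.0, start_fraction=0.05, max_fraction=0.10) is None


def test_escalation_equals_exhaustive_scan():
    rng = np.random.default_rng(0)
    y = rng.normal(80, 15, 20)
    x = y + rng.normal(6, 4, 20)
    got = escalate_equivalence(x, y, start_fraction=0.05, step=0.05, max_fraction=0.5)
    scan = None
    f = 0.05
    while f <= 0.5 + 1e-9:
        region = equivalence_region_for(y, fraction=f)
        if tost_equivalence(x, y, region).equivalent:
            scan = round(f, 10)
            break
        f += 0.05
    assert got == scan


# ---------------------------------------------------------------------------
# the full model / results workflow
# ---------------------------------------------------------------------------

def test_perfect_agreement_report():
    df = generate_paired_measurements(
        n_subjects=15, error=ErrorModel(bias_min=0.0, noise_sd_min=0.0), seed=6
    )
    results = DeviceAgreement(df).fit()
    for b, res in results.behaviors.items():
        assert res.concordance.ccc == pytest.approx(1.0)
        assert res.bland_altman.mean_bias == 0.0
        assert res.tost.equivalent
        assert res.difference.test == "degenerate"


def test_injected_biases_recovered_at_n500():
    error = ErrorModel(
        bias_min={"sitting": -2.0, "standing": -5.0, "stepping": 1.0},
        noise_sd_min={"sitting": 10.0, "standing": 10.0, "stepping": 5.0},
    )
    df = generate_paired_measurements(n_subjects=500, error=error, seed=13)
    results = DeviceAgreement(df).fit()
    for behavior, bias, sd in (
        ("sitting", -2.0, 10.0),
        ("standing", -5.0, 10.0),
        ("stepping", 1.0, 5.0),
    ):
        got = results[behavior].bland_altman.mean_bias
        assert abs(got - bias) < 3 * sd / math.sqrt(500)


def test_default_study_run_produces_complete_report():
    df = generate_paired_measurements(n_subjects=20, seed=7)
    results = DeviceAgreement(df).fit()
    assert set(results.behaviors) == {
        "sitting", "standing", "stepping", "stationary", "upright", "recording"
    }
    for res in results.behaviors.values():
        assert res.n == 20
        assert res.concordance is not None
        assert res.correlation is not None
        assert res.region.half_width_min > 0
    text = results.summary()
    assert "sitting" in text and "CCC" in text


def test_absolute_region_override():
    df = generate_paired_measurements(n_subjects=20, seed=7)
    results = DeviceAgreement(df, absolute_regions={"stepping": 4.0}).fit()
    assert results["stepping"].region.derivation == "absolute"
    assert results["stepping"].region.half_width_min == 4.0
    assert results["sitting"].region.derivation == "fraction_of_criterion"


def test_report_roundtrip_json_lossless(tmp_path):
    df = generate_paired_measurements(n_subjects=20, seed=8)
    results = DeviceAgreement(df).fit()
    path = tmp_path / "agreement.json"
    results.to_json(path)
    from posturekit import AgreementResults

    loaded = AgreementResults.from_json(path)
    assert set(loaded.behaviors) == set(results.behaviors)
    for b in results.behaviors:
        a, c = results[b], loaded[b]
        assert a.bland_altman.mean_bias == c.bland_altman.mean_bias
        assert a.tost == c.tost
        assert a.concordance == c.concordance
        assert a.minimal_equivalent_fraction == c.minimal_equivalent_fraction
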