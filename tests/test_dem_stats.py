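"""TPM, fold-change, the two-library exact test, DEM and time-pattern rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldmir.dem_stats import (
    DEMThresholds,
    ExpressionRecord,
    TimeSeries,
    ac_pmf_direct,
    classify_dem,
    classify_from_tpm,
    classify_time_pattern,
    fold_change,
    pvalue_two_library,
    tpm,
)


# --- TPM ---------------------------------------------------------------------

def test_tpm_basics():
    assert tpm(21_000_000, 21_000_000) == 1e6
    assert tpm(21, 21_000_000) == 1.0
    assert tpm(0, 21_000_000) == 0.01
    with pytest.raises(ValueError):
        tpm(1, 0)


def test_tpm_conservation():
    rng = np.random.default_rng(3)
    counts = rng.integers(1, 5000, size=400)
    total = counts.sum()
    assert math.isclose(sum(tpm(int(c), total) for c in counts), 1e6, rel_tol=1e-9)


# --- fold change --------------------------------------------------------------

@pytest.mark.parametrize(
    "tpm_ct,tpm_nct,expected",
    [
        (1090.49, 414.93, 1.39),
        (111.79, 0.01, 13.45),
        (0.01, 200.79, -14.29),
        (83.23, 27.25, 1.61),
    ],
)
def test_fold_change_worked_examples(tpm_ct, tpm_nct, expected):
    assert round(fold_change(tpm_ct, tpm_nct), 2) == expected


def test_fold_change_identity_and_errors():
    assert fold_change(3.7, 3.7) == 0.0
    with pytest.raises(ValueError, match="substitution"):
        fold_change(0.0, 5.0)


@settings(deadline=None, derandomize=True)
@given(st.floats(0.01, 1e6), st.floats(0.01, 1e6))
def test_fold_change_antisymmetry(a, b):
    assert math.isclose(fold_change(a, b), -fold_change(b, a), abs_tol=1e-12)


# --- p-values ------------------------------------------------------------------

def test_pvalue_degenerate_zero_counts():
    assert pvalue_two_library(0, 0, 1e6, 1e6) == 1.0
    assert pvalue_two_library(0, 0, 1e6, 1e6, method="ac_tail") == 1.0


def test_ac_tail_equals_direct_summation():
    """Log-space nbinom tails reproduce direct summation of the AC mass."""
    x, y, n1, n2 = 5, 5, 1e6, 1e6
    lower = sum(ac_pmf_direct(k, x, n1, n2) for k in range(0, y + 1))
    upper = sum(ac_pmf_direct(k, x, n1, n2) for k in range(y, 400))
    expected = min(1.0, 2.0 * min(lower, upper))
    got = pvalue_two_library(x, y, n1, n2, method="ac_tail")
    assert abs(got - expected) < 1e-12
    # and on an asymmetric configuration
    x, y, n1, n2 = 3, 12, 2e6, 1e6
    lower = sum(ac_pmf_direct(k, x, n1, n2) for k in range(0, y + 1))
    upper = sum(ac_pmf_direct(k, x, n1, n2) for k in range(y, 600))
    expected = min(1.0, 2.0 * min(lower, upper))
    assert abs(pvalue_two_library(x, y, n1, n2, method="ac_tail") - expected) < 1e-12


def test_extreme_counts_give_vanishing_p():
    assert pvalue_two_library(0, 500, 1e6, 1e6) < 1e-90
    assert pvalue_two_library(0, 500, 1e6, 1e6, method="ac_tail") < 1e-90


@settings(deadline=None, derandomize=True)
@given(
    st.integers(0, 200),
    st.integers(0, 200),
    st.integers(10_000, 5_000_000),
    st.integers(10_000, 5_000_000),
)
def test_default_pvalue_symmetric_under_library_swap(x, y, n1, n2):
    p1 = pvalue_two_library(x, y, n1, n2)
    p2 = pvalue_two_library(y, x, n2, n1)
    assert math.isclose(p1, p2, rel_tol=1e-9, abs_tol=1e-300)


def test_normal_method_agrees_at_large_counts():
    p_exact = pvalue_two_library(5000, 5600, 1e6, 1e6)
    p_norm = pvalue_two_library(5000, 5600, 1e6, 1e6, method="normal")
    assert (p_exact < 1e-6) == (p_norm < 1e-6)


def test_invalid_counts_rejected():
    with pytest.raises(ValueError):
        pvalue_two_library(10, 5, 8, 1e6)
    with pytest.raises(ValueError, match="method"):
        pvalue_two_library(1, 1, 10, 10, method="bogus")


# --- DEM classification --------------------------------------------------------

def test_low_expression_rule():
    fc, cls = classify_from_tpm(9.2, 8.1, p_value=1e-10)
    assert cls == "filtered_low"


def test_threshold_logic_requires_both_fc_and_p():
    _, cls = classify_from_tpm(100.0, 100.0 * 2 ** 1.5, p_value=0.01)
    assert cls == "unchanged"
    _, cls = classify_from_tpm(100.0, 100.0 * 2 ** 1.5, p_value=1e-5)
    assert cls == "up"
    _, cls = classify_from_tpm(100.0 * 2 ** 1.5, 100.0, p_value=1e-5)
    assert cls == "down"


def test_classify_dem_from_counts_applies_zero_substitution():
    rec = ExpressionRecord("m", count_NCT=0, count_CT=800,
                           total_NCT=1_000_000, total_CT=1_000_000)
    res = classify_dem(rec)
    assert res.tpm_NCT == 0.01
    assert res.dem_class == "up"
    assert res.log2_fold_change > 10


def test_unreachable_fc_bound_yields_no_dems():
    t = DEMThresholds(fc=float("inf"))
    rec = ExpressionRecord("m", 10, 10_000, 1_000_000, 1_000_000)
    assert classify_dem(rec, t).dem_class == "unchanged"


# --- time-series groups ---------------------------------------------------------

def _series(values):
    return TimeSeries("m", relative_expression=tuple(values))


@pytest.mark.parametrize(
    "values,group",
    [
        ([1, 0.8, 0.3, 0.4, 0.6, 0.9], "I"),
        ([1, 1.6, 1.2, 0.4, 0.5, 0.8], "II"),
        ([1, 1.8, 2.4, 1.5, 1.1, 0.9], "III"),
        ([1, 0.9, 0.7, 0.5, 1.1, 2.2], "IV"),
        ([1, 1, 1, 1, 1, 1], "unclassified"),
    ],
)
def test_time_pattern_groups(values, group):
    assert classify_time_pattern(_series(values)) == group


def test_time_series_validation():
    with pytest.raises(ValueError):
        classify_time_pattern(_series([2, 1, 1, 1, 1, 1]))
    with pytest.raises(ValueError):
        classify_time_pattern(_series([1, 1, 1]))
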