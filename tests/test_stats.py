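"""Hypothesis tests: frozen hand-computed fixtures, scipy cross-checks,
identities and degenerate cases."""

import math

import numpy as np
import pytest
from scipy import stats as scipy_stats

from dualtcr.errors import ContractError, ZeroVarianceError
from dualtcr.stats import (
    anova_oneway,
    benjamini_hochberg,
    chi_square,
    independent_t,
    paired_t,
)


def test_identical_samples_give_t_zero_p_one():
    x = [1.0, 2.0, 3.0, 4.0]
    res = independent_t(x, x)
    assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)


def test_student_t_on_shifted_sequences():
    # pooled sd = 1.5811, se = 1.0, mean difference −1 ⇒ t = −1.0
    res = independent_t([1, 2, 3, 4, 5], [2, 3, 4, 5, 6], variant="student")
    assert res.statistic == pytest.approx(-1.0)
    assert res.df == 8


def test_welch_is_the_default_variant():
    res = independent_t([1.0, 2.0, 3.0], [2.0, 4.0, 9.0])
    assert res.test_name == "independent_t_welch"
    ref = scipy_stats.ttest_ind([1.0, 2.0, 3.0], [2.0, 4.0, 9.0], equal_var=False)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_too_small_or_degenerate_samples_error():
    with pytest.raises(ContractError):
        independent_t([1.0], [1.0, 2.0])
    with pytest.raises(ZeroVarianceError):
        independent_t([2.0, 2.0], [3.0, 3.0])


def test_paired_t_symmetric_differences_cancel():
    res = paired_t([0.0, 0.0], [1.0, -1.0])
    assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)


def test_paired_t_antisymmetry():
    before, after = [1.0, 2.5, 3.0, 4.2], [2.0, 2.0, 4.5, 5.0]
    assert paired_t(before, after).statistic == pytest.approx(
        -paired_t(after, before).statistic
    )


def test_paired_constant_shift_is_degenerate():
    with pytest.raises(ZeroVarianceError):
        paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


def test_paired_identical_samples_no_evidence():
    res = paired_t([1.0, 2.0], [1.0, 2.0])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_paired_misalignment_guards():
    with pytest.raises(ContractError):
        paired_t([1.0, 2.0], [1.0, 2.0, 3.0])
    with pytest.raises(ContractError, match="duplicate"):
        paired_t([1.0, 2.0], [2.0, 3.0], pairing=["P1", "P1"])


def test_chi_square_identical_rows_give_zero():
    res = chi_square([[10, 20], [10, 20]])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_chi_square_hand_computed_2x2():
    # all expected counts 15; Σ(O−E)²/E = 4·(25/15) = 6.6667, df 1
    res = chi_square([[10, 20], [20, 10]])
    assert res.statistic == pytest.approx(20 / 3)
    assert res.df == 1


def test_chi_square_zero_margin_is_an_error():
    with pytest.raises(ZeroVarianceError):
        chi_square([[0, 0], [5, 10]])


def test_chi_square_equals_squared_two_proportion_z():
    """On a 2×2 table the Pearson statistic is the square of the pooled
    two-proportion z statistic."""
    a, b, c, d = 34, 66, 52, 48
    res = chi_square([[a, b], [c, d]])
    p1, p2 = a / (a + b), c / (c + d)
    pooled = (a + c) / (a + b + c + d)
    z = (p1 - p2) / math.sqrt(pooled * (1 - pooled) * (1 / (a + b) + 1 / (c + d)))
    assert res.statistic == pytest.approx(z**2, rel=1e-12)


def test_anova_hand_computed_fixture():
    # groups {1,2,3},{2,3,4},{3,4,5}: SSB=6 (df 2), SSW=6 (df 6) ⇒ F=3.0
    res = anova_oneway([1, 2, 3], [2, 3, 4], [3, 4, 5])
    assert res.statistic == pytest.approx(3.0)
    assert res.df == (2, 6)


def test_anova_degenerate_constant_groups_error():
    with pytest.raises(ZeroVarianceError):
        anova_oneway([1.0, 1.0], [1.0, 1.0], [1.0, 1.0])
    with pytest.raises(ContractError):
        anova_oneway([1.0, 2.0])


def test_battery_agrees_with_reference_implementation():
    """20 random cases per test, p-values within 1e-6 of scipy."""
    rng = np.random.default_rng(2024)
    for _ in range(20):
        x = rng.normal(size=int(rng.integers(3, 25)))
        y = rng.normal(0.5, 1.3, size=int(rng.integers(3, 25)))
        assert independent_t(x, y, "welch").p_value == pytest.approx(
            scipy_stats.ttest_ind(x, y, equal_var=False).pvalue, abs=1e-6
        )
        assert independent_t(x, y, "student").p_value == pytest.approx(
            scipy_stats.ttest_ind(x, y).pvalue, abs=1e-6
        )
        n = min(x.size, y.size)
        assert paired_t(x[:n], y[:n]).p_value == pytest.approx(
            scipy_stats.ttest_rel(y[:n], x[:n]).pvalue, abs=1e-6
        )
        table = rng.integers(5, 80, size=(2, 3))
        assert chi_square(table).p_value == pytest.approx(
            scipy_stats.chi2_contingency(table, correction=False).pvalue, abs=1e-6
        )
        groups = [rng.normal(size=7) for _ in range(3)]
        assert anova_oneway(*groups).p_value == pytest.approx(
            scipy_stats.f_oneway(*groups).pvalue, abs=1e-6
        )


def test_benjamini_hochberg_monotone_and_bounded():
    p = [0.001, 0.02, 0.04, 0.2, 0.9]
    adj = benjamini_hochberg(p)
    assert all(a >= raw for a, raw in zip(adj, p))
    assert all(0 <= a <= 1 for a in adj)
    # matches the step-up definition on a hand case: p(1)·m/1 = 0.005
    assert adj[0] == pytest.approx(0.005)
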