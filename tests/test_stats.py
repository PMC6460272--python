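"""Unit, property and cross-check tests for the categorical test battery.

scipy and statsmodels implement the same textbook tests independently;
they serve as oracles here, never as the implementation.
"""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given
from hypothesis import strategies as st

from uvkin import (
    ContingencyTable,
    TreatmentGrid,
    chisq_test,
    fisher_exact,
    kruskal_wallis,
    two_way_anova,
)
from uvkin.errors import UsageError, ValidationError
from uvkin.stats import _hypergeom_pmf_exact


# ------------------------------------------------------------------ chi-square
def test_chisq_uniform_table_is_null():
    res = chisq_test(ContingencyTable([[10, 10], [10, 10]]))
    assert res.statistic == 0.0
    assert res.p_value == 1.0
    assert res.df == 1


def test_chisq_hand_worked_2x2():
    t = ContingencyTable([[10, 20], [20, 10]])
    # expected all 15; Yates: 4 * (5 - 0.5)^2 / 15 = 5.4
    assert chisq_test(t, continuity_correction=True).statistic == pytest.approx(5.4)
    # Pearson: 4 * 25 / 15 = 20/3
    assert chisq_test(t, continuity_correction=False).statistic == pytest.approx(20 / 3)


def test_chisq_correction_limited_to_2x2():
    t = ContingencyTable([[10, 20, 5], [20, 10, 5]])
    assert (
        chisq_test(t, True).statistic
        == chisq_test(t, False).statistic
    )


def test_chisq_df_bookkeeping_matches_design_shapes():
    # a 4-site x 3-morphology isolate table has (4-1)(3-1) = 6 df
    t = ContingencyTable(np.arange(1, 13).reshape(4, 3))
    assert chisq_test(t).df == 6


def test_chisq_degenerate_margin_errors():
    with pytest.raises(ValidationError):
        chisq_test(ContingencyTable([[0, 0], [5, 5]]))


def test_chisq_invariant_under_transpose_and_permutation(rng):
    t = rng.integers(1, 40, size=(3, 4))
    base = chisq_test(ContingencyTable(t), False).statistic
    assert chisq_test(ContingencyTable(t.T), False).statistic == pytest.approx(base)
    perm = t[rng.permutation(3)][:, rng.permutation(4)]
    assert chisq_test(ContingencyTable(perm), False).statistic == pytest.approx(base)


@pytest.mark.parametrize("correction", [True, False])
def test_chisq_matches_scipy_on_random_tables(rng, correction):
    for _ in range(25):
        counts = rng.integers(1, 50, size=rng.integers(2, 5, size=2))
        res = chisq_test(ContingencyTable(counts), correction)
        ref = sps.chi2_contingency(counts, correction=correction)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)
        assert res.df == ref.dof


# ---------------------------------------------------------------------- fisher
def test_fisher_symmetric_table():
    assert fisher_exact(ContingencyTable([[1, 1], [1, 1]])).p_value == 1.0


def test_fisher_hand_enumerated_diagonal():
    # margins (2,2,2,2): P(a)=1/6, 4/6, 1/6 -> two-sided p = 1/3
    res = fisher_exact(ContingencyTable([[2, 0], [0, 2]]))
    assert res.p_value == pytest.approx(1 / 3, rel=1e-12)


def test_fisher_antidiagonal_matches_enumeration_oracle():
    # independent oracle: direct hypergeometric enumeration for [[0,5],[5,0]]
    probs = [
        math.comb(5, a) * math.comb(5, 5 - a) / math.comb(10, 5) for a in range(6)
    ]
    p_obs = probs[0]
    expected = sum(p for p in probs if p <= p_obs * (1 + 1e-7))
    res = fisher_exact(ContingencyTable([[0, 5], [5, 0]]))
    assert res.p_value == pytest.approx(expected, rel=1e-12)


def test_fisher_rejects_non_2x2():
    with pytest.raises(UsageError):
        fisher_exact(ContingencyTable([[1, 2, 3], [4, 5, 6]]))


def test_fisher_pmf_normalises():
    for r1, r2, c1 in [(5, 7, 4), (12, 12, 12), (3, 9, 6)]:
        lo, hi = max(0, c1 - r2), min(r1, c1)
        total = sum(_hypergeom_pmf_exact(a, r1, r2, c1) for a in range(lo, hi + 1))
        assert total == pytest.approx(1.0, abs=1e-12)


def test_fisher_matches_scipy_on_random_tables(rng):
    for _ in range(50):
        t = rng.integers(0, 25, size=(2, 2))
        if t.sum() == 0:
            continue
        res = fisher_exact(ContingencyTable(t))
        _, p_ref = sps.fisher_exact(t, alternative="two-sided")
        assert res.p_value == pytest.approx(p_ref, rel=1e-7)


# -------------------------------------------------------------- kruskal-wallis
def test_kw_hand_worked_two_groups():
    res = kruskal_wallis([[1, 2], [3, 4]])
    assert res.statistic == pytest.approx(2.4)
    assert res.df == 1


def test_kw_identical_observations():
    res = kruskal_wallis([[5, 5], [5, 5]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_kw_label_invariance():
    g = [[1.0, 4.0, 2.0], [3.0, 8.0], [0.5, 0.7, 9.0]]
    h0 = kruskal_wallis(g).statistic
    for perm in itertools.permutations(g):
        assert kruskal_wallis(list(perm)).statistic == pytest.approx(h0)


def test_kw_df_tracks_group_count():
    # 14 colour categories -> df 13, regardless of group sizes
    groups = [[float(i), i + 0.5] for i in range(14)]
    assert kruskal_wallis(groups).df == 13


def test_kw_monotone_transformation_invariance(rng):
    groups = [list(rng.normal(i, 1, size=6)) for i in range(3)]
    h0 = kruskal_wallis(groups).statistic
    for f in (np.exp, lambda x: np.asarray(x) ** 3, lambda x: 5 * np.asarray(x) - 2):
        transformed = [list(f(np.asarray(g))) for g in groups]
        assert kruskal_wallis(transformed).statistic == pytest.approx(h0, rel=1e-12)


def test_kw_ties_match_scipy(rng):
    groups = [list(rng.integers(0, 5, size=8)) for _ in range(4)]  # heavy ties
    res = kruskal_wallis(groups)
    ref = sps.kruskal(*groups)
    assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


def test_kw_usage_errors():
    with pytest.raises(UsageError):
        kruskal_wallis([[1, 2, 3]])
    with pytest.raises(UsageError):
        kruskal_wallis([[1, 2], []])


# -------------------------------------------------------------- two-way anova
def _grid(rng, a=4, b=4, r=3, scale=10.0):
    return TreatmentGrid(rng.normal(50, scale, size=(a, b, r)))


def _anova_oracle(y):
    """Brute-force mean-contrast sums of squares via explicit loops."""
    a, b, r = y.shape
    grand = y.mean()
    ss_a = ss_b = ss_ab = ss_err = 0.0
    for i in range(a):
        ss_a += b * r * (y[i].mean() - grand) ** 2
    for j in range(b):
        ss_b += a * r * (y[:, j].mean() - grand) ** 2
    for i in range(a):
        for j in range(b):
            cell = y[i, j].mean()
            ss_ab += r * (cell - y[i].mean() - y[:, j].mean() + grand) ** 2
            for rep in range(r):
                ss_err += (y[i, j, rep] - cell) ** 2
    return ss_a, ss_b, ss_ab, ss_err


def test_anova_ss_decomposition_identity_and_oracle_f(rng):
    for _ in range(5):
        g = _grid(rng)
        y = g.values
        a, b, r = y.shape
        ss_a, ss_b, ss_ab, ss_err = _anova_oracle(y)
        ss_total = float(((y - y.mean()) ** 2).sum())
        assert ss_a + ss_b + ss_ab + ss_err == pytest.approx(ss_total, rel=1e-9)
        res = two_way_anova(g)
        ms_err = ss_err / (a * b * (r - 1))
        assert res["treatment"].statistic == pytest.approx(
            (ss_a / (a - 1)) / ms_err, rel=1e-8
        )
        assert res["time"].statistic == pytest.approx(
            (ss_b / (b - 1)) / ms_err, rel=1e-8
        )
        assert res["interaction"].statistic == pytest.approx(
            (ss_ab / ((a - 1) * (b - 1))) / ms_err, rel=1e-8
        )


def test_anova_matches_statsmodels(rng):
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    g = _grid(rng, a=4, b=4, r=3)
    res = two_way_anova(g)
    df = g.to_long()
    model = ols("cfu ~ C(treatment) * C(time_min)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    assert res["treatment"].statistic == pytest.approx(
        table.loc["C(treatment)", "F"], rel=1e-8
    )
    assert res["time"].statistic == pytest.approx(
        table.loc["C(time_min)", "F"], rel=1e-8
    )
    assert res["interaction"].statistic == pytest.approx(
        table.loc["C(treatment):C(time_min)", "F"], rel=1e-8
    )
    assert res["interaction"].p_value == pytest.approx(
        table.loc["C(treatment):C(time_min)", "PR(>F)"], rel=1e-6
    )


def test_anova_df_bookkeeping_matches_design():
    # 6 treatments x 4 times x 3 replicates
    g = TreatmentGrid(np.random.default_rng(0).poisson(30, size=(6, 4, 3)).astype(float))
    res = two_way_anova(g)
    assert res["treatment"].df == 5
    assert res["time"].df == 3
    assert res["interaction"].df == 15
    assert res["treatment"].df_denom == 6 * 4 * 2


def test_anova_degenerate_factor_a_only():
    # cells constant within level of A, differing across A: error SS is 0
    vals = np.zeros((3, 2, 2))
    for i in range(3):
        vals[i] = i * 10.0
    res = two_way_anova(TreatmentGrid(vals))
    assert math.isinf(res["treatment"].statistic)
    assert "zero_error_variance" in res["treatment"].flags
    assert res["time"].statistic == 0.0
    assert res["interaction"].statistic == 0.0


def test_anova_all_constant_grid():
    res = two_way_anova(TreatmentGrid(np.full((2, 2, 2), 7.0)))
    for term in res.values():
        assert term.statistic == 0.0
        assert term.p_value == 1.0
        assert "zero_variance" in term.flags


def test_anova_needs_replicates_for_interaction():
    with pytest.raises(ValidationError):
        two_way_anova(TreatmentGrid(np.ones((3, 3, 1))))


def test_grid_rejects_unbalanced_long_format():
    import pandas as pd

    df = pd.DataFrame(
        {
            "treatment": ["a", "a", "a", "b", "b"],
            "time_min": [0, 0, 15, 0, 15],
            "cfu": [1, 2, 3, 4, 5],
        }
    )
    with pytest.raises(ValidationError, match="balance"):
        TreatmentGrid.from_long(df)


# ----------------------------------------------------------------- validation
def test_contingency_table_validation():
    with pytest.raises(ValidationError):
        ContingencyTable([[1, -1], [2, 3]])
    with pytest.raises(ValidationError):
        ContingencyTable([[1, 2, 3]])
    with pytest.raises(ValidationError):
        ContingencyTable([[0, 0], [0, 0]])
    with pytest.raises(ValidationError):
        ContingencyTable([[1.5, 2], [3, 4]])
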