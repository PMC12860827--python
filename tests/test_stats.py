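import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from petmiv.stats import (
    StatsError,
    bland_altman,
    cohens_kappa,
    group_compare,
    icc_absolute_agreement,
    pearson_for_spearman,
    spearman_ci,
)

from oracles import (
    oracle_bland_altman,
    oracle_fisher_ci,
    oracle_icc2_point,
    oracle_kappa,
    oracle_kruskal_h,
    oracle_mannwhitney_u,
    oracle_mw_exact_p,
    oracle_spearman,
)


# ---------------------------------------------------------------- Bland-Altman

def test_bland_altman_identical_series_zero_width():
    a = [3.0, 1.0, 4.0, 1.5, 9.0]
    res = bland_altman(a, a)
    assert res.bias == res.loa_low == res.loa_high == 0.0


def test_bland_altman_hand_computed_example():
    a = [2.0, 3.0, 4.0, 6.0]
    b = [1.0, 2.0, 3.0, 3.0]  # differences {1,1,1,3}
    res = bland_altman(a, b)
    assert res.bias == pytest.approx(1.5)
    assert res.sd == pytest.approx(1.0)
    assert res.loa_low == pytest.approx(-0.46)
    assert res.loa_high == pytest.approx(3.46)
    assert res.n == 4


def test_bland_altman_single_pair_errors():
    with pytest.raises(StatsError, match="at least 2"):
        bland_altman([1.0], [2.0])


def test_bland_altman_pairwise_deletion():
    a = [1.0, np.nan, 3.0, 4.0]
    b = [0.0, 2.0, np.nan, 1.0]
    res = bland_altman(a, b)
    assert res.n == 2
    bias, lo, hi = oracle_bland_altman([1.0, 4.0], [0.0, 1.0])
    assert res.bias == pytest.approx(bias)
    assert (res.loa_low, res.loa_high) == pytest.approx((lo, hi))


# ----------------------------------------------------------------------- kappa

def test_kappa_perfect_agreement():
    r = [0, 1, 2, 1, 0, 2, 1]
    res = cohens_kappa(r, r)
    assert res.defined and res.kappa == pytest.approx(1.0)


def test_kappa_undefined_when_single_shared_category():
    """Both readers grade every scan into one category (the feature is
    present on every scan): chance agreement is 1 and kappa is flagged
    undefined instead of being reported."""
    res = cohens_kappa([1] * 10, [1] * 10)
    assert not res.defined
    assert math.isnan(res.kappa)
    assert res.expected_agreement == pytest.approx(1.0)


def test_kappa_2x2_table_matches_contingency_arithmetic():
    # counts [[20,5],[10,15]]
    r1 = [0] * 25 + [1] * 25
    r2 = [0] * 20 + [1] * 5 + [0] * 10 + [1] * 15
    res = cohens_kappa(r1, r2)
    po, pe, kappa = oracle_kappa(r1, r2)
    assert res.observed_agreement == pytest.approx(po)
    assert res.expected_agreement == pytest.approx(pe)
    assert res.kappa == pytest.approx(kappa, rel=1e-12)
    from sklearn.metrics import cohen_kappa_score  # independent cross-check

    assert res.kappa == pytest.approx(cohen_kappa_score(r1, r2), rel=1e-10)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.integers(0, 2), min_size=2, max_size=30),
    st.lists(st.integers(0, 2), min_size=2, max_size=30),
)
def test_kappa_symmetric_and_relabel_invariant(r1, r2):
    n = min(len(r1), len(r2))
    r1, r2 = r1[:n], r2[:n]
    a = cohens_kappa(r1, r2)
    b = cohens_kappa(r2, r1)
    assert a.defined == b.defined
    if a.defined:
        assert a.kappa == pytest.approx(b.kappa, rel=1e-12)
    relabel = {0: 10, 1: 20, 2: 30}
    c = cohens_kappa([relabel[v] for v in r1], [relabel[v] for v in r2])
    assert c.defined == a.defined
    if a.defined:
        assert c.kappa == pytest.approx(a.kappa, rel=1e-12)


def test_kappa_length_mismatch():
    with pytest.raises(StatsError):
        cohens_kappa([1, 2], [1, 2, 3])


# ------------------------------------------------------------------------- ICC

def test_icc_duplicated_columns_is_one(rng):
    col = rng.normal(10, 3, 12)
    m = np.column_stack([col, col])
    res = icc_absolute_agreement(m)
    assert res.icc == pytest.approx(1.0, abs=1e-9)
    assert res.n_subjects == 12 and res.n_raters == 2


def test_icc_point_estimate_matches_anova_oracle(rng):
    subj = rng.normal(0, 2, 20)
    rater = np.array([0.0, 0.5, -0.3])
    m = subj[:, None] + rater[None, :] + rng.normal(0, 1, (20, 3))
    res = icc_absolute_agreement(m)
    assert res.icc == pytest.approx(oracle_icc2_point(m.tolist()), rel=1e-10)
    assert res.ci_low <= res.icc <= res.ci_high <= 1.0


def test_icc_independent_noise_near_zero():
    """No subject effect -> ICC centered on 0 (n=50, averaged over seeded
    replicates to keep the check within Monte-Carlo error)."""
    rng = np.random.default_rng(42)
    vals = [icc_absolute_agreement(rng.normal(0, 1, (50, 2))).icc for _ in range(20)]
    assert abs(float(np.mean(vals))) < 0.1  # ~3 SE of the replicate mean


def test_icc_error_contracts(rng):
    with pytest.raises(StatsError, match="at least 5 subjects"):
        icc_absolute_agreement(rng.normal(size=(4, 2)))
    with pytest.raises(StatsError, match="at least 2 raters"):
        icc_absolute_agreement(rng.normal(size=(10, 1)))
    m = rng.normal(size=(10, 2))
    m[3, 1] = np.nan
    with pytest.raises(StatsError, match="missing"):
        icc_absolute_agreement(m)


def test_icc_zero_variance_flagged_not_raised():
    res = icc_absolute_agreement(np.full((6, 2), 3.0))
    assert math.isnan(res.icc)
    assert "zero-variance" in res.note


# -------------------------------------------------------------------- Spearman

def test_spearman_monotone_and_antitone():
    x = [1.0, 2.0, 5.0, 9.0, 11.0]
    y = [v**3 for v in x]
    assert spearman_ci(x, y).rho == pytest.approx(1.0)
    assert spearman_ci(x, [-v for v in x]).rho == pytest.approx(-1.0)


def test_spearman_matches_rank_oracle_with_ties(rng):
    x = rng.integers(0, 5, 25).astype(float)
    y = rng.integers(0, 5, 25).astype(float) + 0.3 * x
    res = spearman_ci(x, y)
    assert res.rho == pytest.approx(oracle_spearman(x, y), rel=1e-10)
    lo, hi = oracle_fisher_ci(res.rho, 25)
    assert (res.ci_low, res.ci_high) == pytest.approx((lo, hi), rel=1e-10)
    assert res.ci_low <= res.rho <= res.ci_high


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.integers(-50, 50), min_size=4, max_size=25, unique=True))
def test_spearman_invariant_under_increasing_transform(x):
    rng = np.random.default_rng(1)
    x = np.asarray(x, dtype=float)
    y = rng.permutation(len(x)).astype(float)
    base = spearman_ci(x, y).rho
    assert spearman_ci(np.exp(x / 50.0), y).rho == pytest.approx(base, rel=1e-10)
    assert spearman_ci(x**3, y).rho == pytest.approx(base, rel=1e-10)


def test_spearman_planted_association_recovered(rng):
    """n=16 bivariate-normal sample with planted rank correlation 0.6:
    the estimate should land inside the analytic Fisher-z CI of the
    generating value in most draws; assert containment of the truth."""
    r = pearson_for_spearman(0.6)
    hits = 0
    for _ in range(50):
        x = rng.standard_normal(16)
        y = r * x + math.sqrt(1 - r * r) * rng.standard_normal(16)
        res = spearman_ci(x, y)
        if res.ci_low <= 0.6 <= res.ci_high:
            hits += 1
    assert hits >= 40  # nominal 95% coverage, wide margin at 50 reps


def test_spearman_error_contracts():
    with pytest.raises(StatsError, match="at least 4"):
        spearman_ci([1, 2, 3], [1, 2, 3])
    with pytest.raises(StatsError, match="zero variance"):
        spearman_ci([1, 1, 1, 1], [1, 2, 3, 4])


# ----------------------------------------------------------- group comparisons

def test_mw_statistic_matches_pair_counting(rng):
    a = rng.normal(0, 1, 12)
    b = rng.normal(0.5, 1, 9)
    res = group_compare(
        np.concatenate([a, b]), np.array(["a"] * 12 + ["b"] * 9), "mann_whitney"
    )
    assert res.statistic == pytest.approx(oracle_mannwhitney_u(a, b))


def test_mw_exact_p_matches_enumeration():
    a = [1.0, 5.0, 7.0]
    b = [2.0, 3.0, 9.0]
    res = group_compare(a + b, ["x"] * 3 + ["y"] * 3, "mann_whitney")
    assert "exact" in res.method
    assert res.p_value == pytest.approx(oracle_mw_exact_p(a, b), rel=1e-10)


def test_mw_complete_separation_minimal_p():
    a = [1.0, 2.0, 3.0, 4.0, 5.0]
    b = [10.0, 11.0, 12.0, 13.0, 14.0]
    res = group_compare(a + b, ["lo"] * 5 + ["hi"] * 5, "mann_whitney")
    assert res.statistic in (0.0, 25.0)
    assert res.p_value == pytest.approx(2 / math.comb(10, 5), rel=1e-10)


def test_kw_matches_rank_sum_oracle(rng):
    groups = [rng.integers(0, 8, 7).astype(float) for _ in range(3)]
    values = np.concatenate(groups)
    labels = np.repeat(["a", "b", "c"], 7)
    res = group_compare(values, labels, "kruskal_wallis")
    assert res.statistic == pytest.approx(
        oracle_kruskal_h([g.tolist() for g in groups]), rel=1e-10
    )


def test_kw_identical_groups_statistic_zero():
    g = [1.0, 2.0, 3.0]
    res = group_compare(g * 3, ["a"] * 3 + ["b"] * 3 + ["c"] * 3, "kruskal_wallis")
    assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_group_compare_error_contracts():
    with pytest.raises(StatsError, match="exactly 2"):
        group_compare([1, 2, 3], ["a", "b", "c"], "mann_whitney")
    with pytest.raises(StatsError, match="nonempty"):
        group_compare([1.0, 2.0], ["a", "a"], "mann_whitney")
    with pytest.raises(StatsError, match="unknown test"):
        group_compare([1, 2, 3, 4], ["a", "a", "b", "b"], "t_test")
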