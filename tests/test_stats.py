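"""Statistical battery against brute-force and independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from fract3d.stats import (PairedSample, RaterTable, icc_a1, icc_consistency_1,
                           spearman_rho, wilcoxon_signed_rank)


def _enumerate_wilcoxon_p(diffs):
    """Literal 2^n enumeration of all sign patterns (the oracle)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    n = len(d)
    w_plus_obs = ranks[d > 0].sum()
    w_minus_obs = ranks[d < 0].sum()
    w_obs = min(w_plus_obs, w_minus_obs)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        wp = sum(r for s, r in zip(signs, ranks) if s)
        wm = ranks.sum() - wp
        if min(wp, wm) <= w_obs + 1e-12:
            count += 1
    return count / 2**n


def test_wilcoxon_all_positive_n5():
    """Five positive differences: W = 0, exact two-sided p = 2/32."""
    res = wilcoxon_signed_rank(PairedSample([2, 3, 4, 5, 6], [1, 1, 1, 1, 1]))
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.0625, abs=1e-15)
    assert res.method == "exact"


def test_wilcoxon_antisymmetric_pair():
    res = wilcoxon_signed_rank(PairedSample([1.0, -1.0], [0.0, 0.0]))
    assert res.p_value == pytest.approx(1.0)


def test_wilcoxon_degenerate_all_zero():
    res = wilcoxon_signed_rank(PairedSample([1.0, 2.0], [1.0, 2.0]))
    assert res.degenerate
    assert res.n == 0


def test_wilcoxon_matches_enumeration_oracle(rng):
    """Exact p equals full sign enumeration to 1e-12, n <= 12, with ties."""
    for trial in range(100):
        n = int(rng.integers(3, 13))
        d = np.round(rng.normal(size=n) * 3, 1)  # rounding induces ties
        if np.all(d == 0):
            continue
        res = wilcoxon_signed_rank(PairedSample(d, np.zeros(n)))
        assert res.p_value == pytest.approx(_enumerate_wilcoxon_p(d), abs=1e-12)


def test_wilcoxon_matches_scipy_exact_untied(rng):
    """Cross-check against an independent implementation (no ties)."""
    for _ in range(20):
        n = 10
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        ours = wilcoxon_signed_rank(PairedSample(a, b))
        ref = sps.wilcoxon(a, b, mode="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_wilcoxon_invariances(rng):
    """p unchanged by common shifts and positive scaling of differences."""
    a = rng.normal(size=9)
    b = rng.normal(size=9)
    p0 = wilcoxon_signed_rank(PairedSample(a, b)).p_value
    assert wilcoxon_signed_rank(PairedSample(a + 5, b + 5)).p_value == p0
    assert wilcoxon_signed_rank(PairedSample(3 * a, 3 * b)).p_value == p0


def test_wilcoxon_normal_approximation_large_n(rng):
    a = rng.normal(0.3, 1.0, size=40)
    res = wilcoxon_signed_rank(PairedSample(a, np.zeros(40)))
    assert res.method == "normal"
    ref = sps.wilcoxon(a, mode="approx", correction=True)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


def test_wilcoxon_pratt_zero_handling():
    a = np.array([0.0, 1.0, 2.0, -3.0, 4.0])
    res_w = wilcoxon_signed_rank(PairedSample(a, np.zeros(5)), zero_method="wilcox")
    res_p = wilcoxon_signed_rank(PairedSample(a, np.zeros(5)), zero_method="pratt")
    assert res_w.n == res_p.n == 4
    assert res_p.statistic >= res_w.statistic  # pratt ranks past the zero


def test_spearman_trivial_directions():
    assert spearman_rho(PairedSample([1, 2, 3], [10, 20, 30])) == 1.0
    assert spearman_rho(PairedSample([1, 2, 3], [30, 20, 10])) == -1.0


def test_spearman_worked_example():
    """x=(1,2,3,4), y=(1,3,2,4): rho = 1 - 6*2/(4*15) = 0.8."""
    assert spearman_rho(PairedSample([1, 2, 3, 4], [1, 3, 2, 4])) == pytest.approx(0.8)


def test_spearman_constant_list_is_nan():
    assert np.isnan(spearman_rho(PairedSample([1, 1, 1], [1, 2, 3])))


def test_spearman_matches_scipy_with_ties(rng):
    for _ in range(20):
        a = np.round(rng.normal(size=15), 1)
        b = np.round(a + rng.normal(size=15), 1)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        assert spearman_rho(PairedSample(a, b)) == pytest.approx(
            sps.spearmanr(a, b).statistic, abs=1e-12)


def test_spearman_monotone_transform_invariant(rng):
    a = rng.normal(size=20)
    b = rng.normal(size=20)
    r0 = spearman_rho(PairedSample(a, b))
    assert spearman_rho(PairedSample(np.exp(a), b**3)) == pytest.approx(r0)


def _icc_longhand(x):
    """Textbook two-way ANOVA ICC(A,1), written out independently."""
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_icc_identical_columns():
    x = np.column_stack([np.arange(5.0), np.arange(5.0)])
    icc, amd = icc_a1(RaterTable(x))
    assert icc == pytest.approx(1.0)
    assert amd == 0.0


def test_icc_matches_longhand_anova(rng):
    for _ in range(10):
        x = rng.normal(100, 30, size=(10, 2))
        icc, _ = icc_a1(RaterTable(x))
        assert icc == pytest.approx(_icc_longhand(x), abs=1e-10)


def test_icc_matches_pingouin():
    """Cross-check against pingouin's ICC(A,1) on the same table."""
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(8)
    x = rng.normal(500, 200, size=(12, 3)) + rng.normal(0, 40, size=(1, 3))
    icc, _ = icc_a1(RaterTable(x))
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(12), 3),
        "rater": np.tile(np.arange(3), 12),
        "score": x.ravel(),
    })
    ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                   ratings="score")
    ref_a1 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0]
    assert icc == pytest.approx(ref_a1, abs=1e-8)


def test_icc_bias_decreases_agreement(rng):
    base = rng.normal(700, 300, size=12)
    iccs = []
    for bias in (0.0, 100.0, 300.0):
        x = np.column_stack([base, base + bias])
        iccs.append(icc_a1(RaterTable(x))[0])
    assert iccs[0] > iccs[1] > iccs[2]


def test_icc_never_exceeds_one(rng):
    for _ in range(50):
        x = rng.normal(size=(int(rng.integers(2, 12)), int(rng.integers(2, 5))))
        icc, _ = icc_a1(RaterTable(x))
        assert icc <= 1.0 + 1e-12


def test_icc_abs_mean_diff():
    x = np.array([[1.0, 2.0], [3.0, 5.0], [4.0, 4.0]])
    _, amd = icc_a1(RaterTable(x))
    assert amd == pytest.approx(1.0)  # mean(|1|, |2|, |0|)


def test_table_validation():
    with pytest.raises(ValueError):
        RaterTable(np.array([[1.0, 2.0]]))        # one subject
    with pytest.raises(ValueError):
        RaterTable(np.array([[1.0], [2.0]]))      # one rater
    with pytest.raises(ValueError):
        RaterTable(np.array([[1.0, np.nan], [2.0, 3.0]]))
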