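"""Statistics for method comparison and rater agreement.

Implemented from first principles so that small-sample behaviour is exact
and auditable:

* Wilcoxon signed-rank test with an *exact* two-sided p for n <= 25
  (distribution of the rank sum over all 2^n sign assignments, computed by
  convolution; mid-ranks for ties), normal approximation with tie and
  continuity correction above that.
* Spearman's rho as the Pearson correlation of mid-ranks.
* ICC(A,1): intraclass correlation from the two-way ANOVA decomposition,
  single measurements, absolute agreement — the standard model for "two
  raters each measured every subject once, and we care about bias".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass
class PairedSample:
    """Two equal-length measurement lists on the same subjects."""

    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self):
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if self.values_a.shape != self.values_b.shape or self.values_a.ndim != 1:
            raise ValueError("paired sample needs two equal-length 1D lists")
        if len(self.values_a) < 1:
            raise ValueError("paired sample must be non-empty")
        if not (np.all(np.isfinite(self.values_a)) and np.all(np.isfinite(self.values_b))):
            raise ValueError("paired sample must be finite")


@dataclass
class RaterTable:
    """Subjects x raters matrix with no missing cells."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("rater table must be 2D (subjects x raters)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need >= 2 subjects and >= 2 raters")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("rater table must have no missing cells")


@dataclass
class WilcoxonResult:
    statistic: float          # min(W+, W-)
    p_value: float
    n: int                    # nonzero differences used
    method: str               # "exact" | "normal"
    degenerate: bool = False  # all differences zero

    def __iter__(self):  # allow tuple unpacking (W, p)
        return iter((self.statistic, self.p_value))


def _exact_signed_rank_p(ranks: np.ndarray, w_min: float) -> float:
    """P(min(W+, W-) <= w_min) over all sign assignments, by convolution.

    Mid-ranks can be half-integral, so ranks are doubled to keep the
    distribution on an integer lattice.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    top = 0
    for r in r2:
        new = dist.copy()
        new[r : top + r + 1] += dist[: top + 1]
        dist = new
        top += r
    dist /= dist.sum()
    w2 = int(np.rint(2.0 * w_min))
    # two-sided: both tails of the symmetric distribution
    p = dist[: w2 + 1].sum() + dist[total - w2 :].sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(
    sample: PairedSample,
    zero_method: str = "wilcox",
    exact_cutoff: int = 25,
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired measurements.

    ``zero_method='wilcox'`` discards zero differences before ranking
    (Wilcoxon's original treatment); ``'pratt'`` ranks them first and drops
    them afterwards.  Exact p for n <= ``exact_cutoff`` nonzero differences.
    """
    if isinstance(sample, (tuple, list)):
        sample = PairedSample(*sample)
    d = sample.values_a - sample.values_b
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    if zero_method == "wilcox":
        d_nz = d[d != 0]
        if len(d_nz) == 0:
            log.warning("all paired differences are zero; test degenerate")
            return WilcoxonResult(0.0, 1.0, 0, "degenerate", degenerate=True)
        ranks = sps.rankdata(np.abs(d_nz))
    else:
        if np.all(d == 0):
            log.warning("all paired differences are zero; test degenerate")
            return WilcoxonResult(0.0, 1.0, 0, "degenerate", degenerate=True)
        ranks_all = sps.rankdata(np.abs(d))
        d_nz = d[d != 0]
        ranks = ranks_all[d != 0]
    n = len(d_nz)
    w_plus = float(ranks[d_nz > 0].sum())
    w_minus = float(ranks[d_nz < 0].sum())
    w = min(w_plus, w_minus)
    if n <= exact_cutoff:
        p = _exact_signed_rank_p(ranks, w)
        method = "exact"
    else:
        total = ranks.sum()
        mean = total / 2.0
        var = float(np.sum(ranks**2)) / 4.0
        z = (w - mean + 0.5) / np.sqrt(var)  # continuity correction toward the mean
        p = float(min(1.0, 2.0 * sps.norm.cdf(z)))
        method = "normal"
    return WilcoxonResult(w, p, n, method)


def spearman_rho(sample: PairedSample) -> float:
    """Spearman's rank correlation (tie-safe: Pearson on mid-ranks)."""
    if isinstance(sample, (tuple, list)):
        sample = PairedSample(*sample)
    if len(sample.values_a) < 2:
        raise ValueError("need at least 2 pairs")
    ra = sps.rankdata(sample.values_a)
    rb = sps.rankdata(sample.values_b)
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        log.warning("constant list: rank correlation undefined")
        return float("nan")
    return float(np.corrcoef(ra, rb)[0, 1])


def icc_a1(table: RaterTable):
    """ICC(A,1): two-way model, single measurements, absolute agreement.

    Returns ``(icc, abs_mean_diff)`` where the absolute mean difference is
    the mean over subjects of |rater_i - rater_j|, averaged over all rater
    pairs (for two raters: mean |difference|).

    ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))
    """
    if isinstance(table, np.ndarray):
        table = RaterTable(table)
    x = table.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ms_r = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_c = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ms_e = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom <= 0 or (ms_r == 0 and ms_e == 0 and ms_c == 0):
        log.warning("no variance in rater table: ICC undefined")
        return float("nan"), 0.0
    icc = float((ms_r - ms_e) / denom)
    diffs = [
        np.mean(np.abs(x[:, i] - x[:, j]))
        for i in range(k) for j in range(i + 1, k)
    ]
    return icc, float(np.mean(diffs))


def icc_consistency_1(table: RaterTable) -> float:
    """ICC(C,1) (consistency): ignores rater bias; useful as a contrast."""
    if isinstance(table, np.ndarray):
        table = RaterTable(table)
    x = table.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ms_r = k * np.sum((row_means - grand) ** 2) / (n - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ms_e = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e
    if denom <= 0:
        return float("nan")
    return float((ms_r - ms_e) / denom)
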