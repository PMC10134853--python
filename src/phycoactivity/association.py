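"""Permutation association statistics for community matrices and groups.

Implements the Mantel test (matrix correlation with joint row/column
permutation of the second matrix), MRPP with optional strata restricting
permutations to within blocks (here, sampling dates), the paired Wilcoxon
signed-rank test, and an all-pairs Spearman correlation panel with
Benjamini-Hochberg adjustment.

All permutation p-values use the add-one rule p = (1 + #extreme) / (n_perm + 1)
and draw their permutation stream from a seeded numpy Generator, so results
are reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import DistanceMatrix
from .io import ValidationError


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str


@dataclass(frozen=True)
class GroupTestResult:
    test: str
    statistic: float
    p: float
    grouping: str = ""
    strata: str = ""
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CorrelationPanel:
    rho: pd.DataFrame       # row taxa x column taxa
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame

    def stars(self, adjusted: bool = False) -> pd.DataFrame:
        """Significance stars: *** p<0.001, ** p<0.01, * p<0.05."""
        p = self.p_adjusted if adjusted else self.p_raw
        return p.map(significance_stars)


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


def _pearson_vec(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValidationError("zero-variance distance vector in Mantel test")
    return float((xc @ yc) / denom)


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
           seed: int | None = None, method: str = "pearson",
           alternative: str = "greater") -> MantelResult:
    """Mantel test of correlation between two distance matrices.

    ``r`` is the (Pearson or Spearman) correlation of the lower-triangle
    vectors; the null distribution permutes rows and columns of ``d2``
    jointly. ``alternative`` is one-sided "greater" by default, matching the
    usual ecological question of whether the matrices covary positively.
    """
    if d1.sample_ids != d2.sample_ids:
        if set(d1.sample_ids) != set(d2.sample_ids):
            raise ValidationError("Mantel requires matching sample sets")
        d2 = d2.select(list(d1.sample_ids))
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")

    v1 = d1.condensed()
    mat2 = d2.values
    if method == "spearman":
        v1 = stats.rankdata(v1)

    def corr_with(mat: np.ndarray) -> float:
        from scipy.spatial.distance import squareform
        v2 = squareform(mat, checks=False)
        if method == "spearman":
            v2 = stats.rankdata(v2)
        return _pearson_vec(v1, v2)

    r_obs = corr_with(mat2)
    rng = np.random.default_rng(seed)
    n = d1.n
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = corr_with(mat2[np.ix_(perm, perm)])
        if alternative == "greater":
            extreme = r_perm >= r_obs
        elif alternative == "two-sided":
            extreme = abs(r_perm) >= abs(r_obs)
        else:
            extreme = r_perm <= r_obs
        count += extreme
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, method=method)


# ---------------------------------------------------------------------------
# MRPP
# ---------------------------------------------------------------------------


def _mrpp_delta(dist: np.ndarray, labels: np.ndarray) -> float:
    """Weighted mean within-group distance, weights n_g / N."""
    n = len(labels)
    delta = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            continue
        sub = dist[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        delta += (len(idx) / n) * sub[iu].mean()
    return delta


def mrpp(d: DistanceMatrix, groups, strata=None, n_perm: int = 999,
         seed: int | None = None) -> GroupTestResult:
    """Multiple-response permutation procedure with optional strata.

    The observed statistic is delta = sum_g (n_g/N) * mean within-group
    distance; chance-corrected effect size A = 1 - delta / E[delta], with
    E[delta] estimated as the mean permuted delta. When ``strata`` is given,
    group labels are permuted only within each stratum (e.g. within each
    sampling date), so a sample never changes stratum.
    """
    groups = np.asarray(groups)
    if len(groups) != d.n:
        raise ValidationError("groups length must match number of samples")
    counts = pd.Series(groups).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValidationError(f"every group needs >= 2 samples; too small: {list(small.index)}")

    if strata is None:
        strata_arr = np.zeros(d.n, dtype=int)
    else:
        strata_arr = np.asarray(strata)
        if len(strata_arr) != d.n:
            raise ValidationError("strata length must match number of samples")

    stratum_idx = [np.flatnonzero(strata_arr == s) for s in pd.unique(strata_arr)]
    free = [idx for idx in stratum_idx if len(np.unique(groups[idx])) > 1]
    if not free:
        raise ValidationError("all strata contain a single group; no permutation freedom")

    dist = d.values
    delta_obs = _mrpp_delta(dist, groups)

    rng = np.random.default_rng(seed)
    deltas = np.empty(n_perm)
    labels = groups.copy()
    for k in range(n_perm):
        perm_labels = labels.copy()
        for idx in stratum_idx:
            perm_labels[idx] = labels[idx][rng.permutation(len(idx))]
        deltas[k] = _mrpp_delta(dist, perm_labels)
    p = (1 + int((deltas <= delta_obs).sum())) / (n_perm + 1)
    e_delta = float(deltas.mean())
    a = 1.0 - delta_obs / e_delta if e_delta > 0 else 0.0
    return GroupTestResult(
        test="mrpp",
        statistic=delta_obs,
        p=p,
        grouping=f"{len(counts)} groups",
        strata="none" if strata is None else f"{len(stratum_idx)} strata",
        extra={"A": a, "expected_delta": e_delta, "n_perm": n_perm},
    )


# ---------------------------------------------------------------------------
# paired Wilcoxon
# ---------------------------------------------------------------------------


def paired_wilcoxon(x, y) -> GroupTestResult:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    ``x`` and ``y`` are mappings pair_key -> value (or aligned Series); only
    keys present in both with finite values are used. Zero differences are
    discarded; if every difference is zero the result is p = 1 (no evidence
    of a shift).
    """
    xs = pd.Series(dict(x) if not isinstance(x, pd.Series) else x, dtype=float)
    ys = pd.Series(dict(y) if not isinstance(y, pd.Series) else y, dtype=float)
    common = xs.index.intersection(ys.index)
    xv, yv = xs[common], ys[common]
    ok = xv.notna() & yv.notna()
    n_dropped = int(len(xs.index.union(ys.index)) - ok.sum())
    xv, yv = xv[ok].to_numpy(), yv[ok].to_numpy()
    if len(xv) < 5:
        raise ValidationError(f"paired Wilcoxon needs >= 5 complete pairs, got {len(xv)}")
    diffs = yv - xv
    if np.all(diffs == 0):
        return GroupTestResult(
            test="paired_wilcoxon", statistic=0.0, p=1.0,
            extra={"n_pairs": len(xv), "n_zero": len(xv), "n_missing": n_dropped},
        )
    res = stats.wilcoxon(xv, yv, zero_method="wilcox", alternative="two-sided")
    return GroupTestResult(
        test="paired_wilcoxon",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        extra={
            "n_pairs": len(xv),
            "n_zero": int((diffs == 0).sum()),
            "n_missing": n_dropped,
        },
    )


# ---------------------------------------------------------------------------
# Spearman panel
# ---------------------------------------------------------------------------


def spearman_panel(rows_table: pd.DataFrame, cols_table: pd.DataFrame,
                   fdr_method: str = "fdr_bh") -> CorrelationPanel:
    """All-pairs Spearman correlations between two feature tables.

    Both tables are features x samples with matching sample axes. Raw
    p-values use the t approximation; the adjusted matrix applies the chosen
    multiple-testing method across the whole panel. Constant features yield
    NaN entries rather than a spurious coefficient.
    """
    if list(rows_table.columns) != list(cols_table.columns):
        if set(rows_table.columns) != set(cols_table.columns):
            raise ValidationError("Spearman panel requires matching sample axes")
        cols_table = cols_table[rows_table.columns]
    r_names, c_names = list(rows_table.index), list(cols_table.index)
    rho = np.full((len(r_names), len(c_names)), np.nan)
    pval = np.full_like(rho, np.nan)
    r_arr = rows_table.to_numpy(float)
    c_arr = cols_table.to_numpy(float)
    r_const = np.ptp(r_arr, axis=1) == 0
    c_const = np.ptp(c_arr, axis=1) == 0
    for i in range(len(r_names)):
        if r_const[i]:
            continue
        for j in range(len(c_names)):
            if c_const[j]:
                continue
            res = stats.spearmanr(r_arr[i], c_arr[j])
            rho[i, j], pval[i, j] = res.statistic, res.pvalue
    flat = pval.ravel()
    ok = ~np.isnan(flat)
    adj = np.full_like(flat, np.nan)
    if ok.any():
        adj[ok] = multipletests(flat[ok], method=fdr_method)[1]
    adj = adj.reshape(pval.shape)
    mk = lambda a: pd.DataFrame(a, index=r_names, columns=c_names)
    return CorrelationPanel(rho=mk(rho), p_raw=mk(pval), p_adjusted=mk(adj))
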