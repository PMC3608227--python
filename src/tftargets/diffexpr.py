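"""Differential expression: two-group moderated t with permutation FDR, and
a timecourse strain-difference test.

Two statistics drive the target screen:

* the SAM-style moderated t, ``d = (mean_ref - mean_other) / (s + s0)``,
  where ``s`` is the pooled standard error and ``s0`` an exchangeability
  fudge factor chosen to stabilise the coefficient of variation of ``d``
  across the spread of ``s``. False discovery rates come from group-label
  permutations: the FDR at a threshold ``delta`` on ``|d|`` is the median
  permutation count of genes exceeding ``delta`` divided by the observed
  count, and a gene's q-value is the smallest such FDR over thresholds it
  passes.
* an EDGE-style timecourse test: per gene, a shared polynomial curve over
  time (reduced model) is compared with strain-specific curves (full model)
  by an F statistic whose null distribution comes from permuting strain
  labels within timepoints; q-values are Benjamini-Hochberg over the
  permutation p-values.

Expression values are log2 scale throughout; fold changes are reported in
signed-magnitude style (ratio r >= 1 -> +r, r < 1 -> -1/r) with positive
meaning higher in the reference (scrambled-control) group.
"""

from __future__ import annotations

import itertools
import logging
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def _group_masks(labels: Sequence, reference=None) -> tuple[np.ndarray, object]:
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {list(uniq)}")
    if reference is None:
        reference = uniq[0]
    ref_mask = labels == reference
    if ref_mask.sum() < 2 or (~ref_mask).sum() < 2:
        raise ValueError("need >=2 samples per group")
    return ref_mask, reference


def _d_for_masks(X: np.ndarray, masks: np.ndarray, s0: float) -> np.ndarray:
    """Moderated t for each column mask; masks is (n_samples, n_masks) bool."""
    M = masks.astype(float)
    n1 = M.sum(axis=0)
    n2 = M.shape[0] - n1
    X2 = X**2
    sum1, sum2 = X @ M, X @ (1.0 - M)
    mean1, mean2 = sum1 / n1, sum2 / n2
    ss1 = X2 @ M - n1 * mean1**2
    ss2 = X2 @ (1.0 - M) - n2 * mean2**2
    pooled = np.clip(ss1 + ss2, 0.0, None) / (M.shape[0] - 2)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * pooled)
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (mean1 - mean2) / denom
    d[denom == 0] = np.nan
    return d


def pooled_se(expr: pd.DataFrame, labels: Sequence, reference=None) -> pd.Series:
    """Per-gene pooled standard error ``s`` of the two-group mean difference."""
    ref_mask, _ = _group_masks(labels, reference)
    X = expr.to_numpy(dtype=float)
    n1, n2 = int(ref_mask.sum()), int((~ref_mask).sum())
    x1, x2 = X[:, ref_mask], X[:, ~ref_mask]
    ss = ((x1 - x1.mean(1, keepdims=True)) ** 2).sum(1) + \
         ((x2 - x2.mean(1, keepdims=True)) ** 2).sum(1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return pd.Series(s, index=expr.index, name="s")


def sam_d(expr: pd.DataFrame, labels: Sequence, s0: float = 0.0,
          reference=None) -> pd.Series:
    """Moderated t per gene: (mean_ref - mean_other) / (s + s0).

    Genes whose denominator is exactly zero (zero variance with s0 = 0) are
    reported as missing rather than infinite.
    """
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    ref_mask, _ = _group_masks(labels, reference)
    X = expr.to_numpy(dtype=float)
    d = _d_for_masks(X, ref_mask[:, None], s0)[:, 0]
    return pd.Series(d, index=expr.index, name="d_stat")


def choose_s0(expr: pd.DataFrame, labels: Sequence, reference=None,
              n_bins: int = 20,
              candidates: Optional[Sequence[float]] = None) -> float:
    """Pick the exchangeability factor s0 from percentiles of ``s``.

    Candidates are the 0th..100th percentiles of the pooled-SE distribution
    in steps of 5; the winner minimises the coefficient of variation of the
    median absolute spread of ``d`` across quantile bins of ``s``. This
    keeps the statistic's scale roughly independent of expression level.
    Deterministic; degenerate all-zero-variance input falls back to
    median(s).
    """
    s = pooled_se(expr, labels, reference).to_numpy()
    ref_mask, _ = _group_masks(labels, reference)
    X = expr.to_numpy(dtype=float)
    num = X[:, ref_mask].mean(1) - X[:, ~ref_mask].mean(1)
    if not np.any(s > 0):
        log.warning("all genes have zero variance; s0 falls back to median(s)")
        return float(np.median(s))
    if candidates is None:
        candidates = np.percentile(s, np.arange(0, 101, 5))
    elif len(candidates) == 1:
        return float(candidates[0])
    order = np.argsort(s, kind="stable")
    bins = np.array_split(order, min(n_bins, max(3, len(s) // 5)))
    best, best_cv = float(np.median(s)), np.inf
    for a in candidates:
        da = num / (s + a) if a > 0 else np.where(s > 0, num / np.where(s > 0, s, 1), np.nan)
        v = []
        for idx in bins:
            vals = da[idx]
            vals = vals[np.isfinite(vals)]
            if len(vals):
                v.append(np.median(np.abs(vals - np.median(vals))) / 0.64)
        v = np.asarray(v)
        if len(v) < 2 or np.mean(v) == 0:
            continue
        cv = np.std(v) / np.mean(v)
        if cv < best_cv - 1e-12:
            best_cv, best = cv, float(a)
    return best


def _permutation_masks(n: int, n_ref: int, n_perm: int,
                       rng: np.random.Generator) -> np.ndarray:
    """(n, B) boolean reference-group masks: exhaustive when feasible."""
    total = comb(n, n_ref)
    if total <= n_perm:
        log.info("enumerating all %d label assignments", total)
        masks = np.zeros((n, total), dtype=bool)
        for j, idx in enumerate(itertools.combinations(range(n), n_ref)):
            masks[list(idx), j] = True
        return masks
    masks = np.zeros((n, n_perm), dtype=bool)
    for j in range(n_perm):
        masks[rng.choice(n, size=n_ref, replace=False), j] = True
    return masks


def permutation_fdr(expr: pd.DataFrame, labels: Sequence, n_perm: int = 1000,
                    s0: Optional[float] = None, reference=None,
                    fdr: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Permutation-based q-values for the moderated t.

    For every threshold ``delta`` in the grid of observed ``|d|`` values the
    estimated FDR is ``median_b #{|d_perm(b)| >= delta} / #{|d_obs| >=
    delta}``; a gene's q-value is the smallest estimated FDR among
    thresholds at which it is called, which is monotone non-increasing in
    ``|d|`` by construction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ref_mask, reference = _group_masks(labels, reference)
    if s0 is None:
        s0 = choose_s0(expr, labels, reference)
    X = expr.to_numpy(dtype=float)
    d_obs = _d_for_masks(X, ref_mask[:, None], s0)[:, 0]

    rng = np.random.default_rng(seed)
    masks = _permutation_masks(len(ref_mask), int(ref_mask.sum()), n_perm, rng)
    d_perm = _d_for_masks(X, masks, s0)

    valid = np.isfinite(d_obs)
    absd = np.abs(d_obs[valid])
    grid = np.unique(absd)
    sorted_absd = np.sort(absd)
    R = len(absd) - np.searchsorted(sorted_absd, grid, side="left")
    abs_perm = np.abs(d_perm[valid])
    abs_perm = np.where(np.isfinite(abs_perm), abs_perm, -np.inf)
    abs_perm.sort(axis=0)
    V = np.empty((len(grid), abs_perm.shape[1]))
    for b in range(abs_perm.shape[1]):
        V[:, b] = len(absd) - np.searchsorted(abs_perm[:, b], grid, side="left")
    fdr_at = np.minimum(1.0, np.median(V, axis=1) / R)
    prefix_min = np.minimum.accumulate(fdr_at)

    q = np.full(len(d_obs), np.nan)
    pos = np.searchsorted(grid, np.abs(d_obs[valid]), side="right") - 1
    q[valid] = prefix_min[pos]
    called = np.where(np.isnan(q), False, q <= fdr)
    return pd.DataFrame({"d_stat": d_obs, "q_value": q, "called": called},
                        index=expr.index)


def fold_change(expr: pd.DataFrame, labels: Sequence, reference=None) -> pd.Series:
    """Signed linear-scale fold change between group means.

    Expression is log2, so the ratio is ``2**(mean_ref - mean_other)``;
    ratios below 1 are reported as the negative reciprocal, so +2 means
    twice as high in the reference group and -2 twice as high in the other.
    """
    ref_mask, _ = _group_masks(labels, reference)
    X = expr.to_numpy(dtype=float)
    ratio = 2.0 ** (X[:, ref_mask].mean(1) - X[:, ~ref_mask].mean(1))
    fc = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    return pd.Series(fc, index=expr.index, name="fold_change")


def two_group_de(expr: pd.DataFrame, labels: Sequence, reference=None,
                 n_perm: int = 1000, s0: Optional[float] = None,
                 fdr: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Full two-group screen: d, q, call flag and signed fold change."""
    res = permutation_fdr(expr, labels, n_perm=n_perm, s0=s0,
                          reference=reference, fdr=fdr, seed=seed)
    res["fold_change"] = fold_change(expr, labels, reference)
    return res[["d_stat", "fold_change", "q_value", "called"]]


def threshold_filter(results: pd.DataFrame, fc_cut: float,
                     fdr_cut: float = 0.05) -> pd.DataFrame:
    """Genes with |fold change| strictly above ``fc_cut`` and q <= ``fdr_cut``,
    sorted by |fold change| descending."""
    sel = results[(results["fold_change"].abs() > fc_cut)
                  & (results["q_value"] <= fdr_cut)]
    return sel.reindex(sel["fold_change"].abs().sort_values(ascending=False).index)


def _time_basis(timepoints: np.ndarray, df: int) -> np.ndarray:
    t = np.asarray(timepoints, dtype=float)
    span = t.max() - t.min()
    tz = (t - t.min()) / (span if span > 0 else 1.0)
    return np.column_stack([tz**k for k in range(1, df + 1)])


def _rss(Y: np.ndarray, Z: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual sum of squares of each column of Y under design Z, and rank."""
    Q, Rmat = np.linalg.qr(Z)
    rank = int(np.sum(np.abs(np.diag(Rmat)) > 1e-10 * max(1.0, np.abs(Rmat).max())))
    proj = Q[:, :] @ (Q.T @ Y)
    resid = Y - proj
    return (resid**2).sum(axis=0), rank


def timecourse_de(expr: pd.DataFrame, strain_labels: Sequence,
                  timepoints: Sequence, n_perm: int = 1000,
                  basis_df: int = 3, fdr: float = 0.05,
                  seed: int = 0) -> pd.DataFrame:
    """Strain-difference test over a shared timecourse.

    Fits, per gene, a reduced model (one polynomial curve of ``basis_df``
    degrees over time) and a full model adding strain-specific intercept and
    curve shape, and compares them by F. Significance comes from permuting
    strain labels within each timepoint (which preserves the time structure
    of the null); q-values are Benjamini-Hochberg.
    """
    strains = np.asarray(strain_labels)
    tps = np.asarray(timepoints, dtype=float)
    if len(strains) != expr.shape[1] or len(tps) != expr.shape[1]:
        raise ValueError("strain_labels and timepoints must match sample columns")
    uniq = pd.unique(strains)
    if len(uniq) != 2:
        raise ValueError("need exactly two strains")
    n_levels = len(np.unique(tps))
    df_eff = min(basis_df, n_levels - 1)
    if df_eff < basis_df:
        log.info("basis reduced to df=%d (%d timepoints)", df_eff, n_levels)

    B = _time_basis(tps, df_eff)
    Z_r = np.column_stack([np.ones(len(tps)), B])
    Y = expr.to_numpy(dtype=float).T

    def full_design(strain_vec: np.ndarray) -> np.ndarray:
        S = (strain_vec == uniq[1]).astype(float)[:, None]
        return np.column_stack([Z_r, S, S * B])

    rss_r, rank_r = _rss(Y, Z_r)
    rss_f, rank_f = _rss(Y, full_design(strains))
    ddf = rank_f - rank_r
    df_f = len(tps) - rank_f
    if ddf <= 0 or df_f <= 0:
        raise ValueError("design is degenerate: no strain degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = ((rss_r - rss_f) / ddf) / (rss_f / df_f)
    f_obs = np.where(np.isfinite(f_obs), f_obs, 0.0)

    rng = np.random.default_rng(seed)
    blocks = [np.flatnonzero(tps == t) for t in np.unique(tps)]
    exceed = np.zeros(Y.shape[1])
    for _ in range(n_perm):
        perm = strains.copy()
        for idx in blocks:
            perm[idx] = perm[rng.permutation(idx)]
        rss_fp, _ = _rss(Y, full_design(perm))
        with np.errstate(divide="ignore", invalid="ignore"):
            f_p = ((rss_r - rss_fp) / ddf) / (rss_fp / df_f)
        f_p = np.where(np.isfinite(f_p), f_p, 0.0)
        exceed += f_p >= f_obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"f_stat": f_obs, "perm_p": p, "q_value": q,
                         "called": q <= fdr}, index=expr.index)
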