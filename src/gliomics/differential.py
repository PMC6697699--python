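"""Differential expression with permutation p-values and permutation FDR.

The screening test is a one-way ANOVA across the sample groups (cortex and
the two tumor genotypes), with significance assessed by permuting group
labels 1000 times; permutation p-values are adjusted by Benjamini-Hochberg
(a Storey pi0-corrected q-value is available as an option).  Features must
additionally pass a fold-change filter (1.5-fold for proteome/transcriptome,
2-fold for phosphosites) in at least one pairwise group comparison, and the
final false-discovery rate of the selected set is itself estimated by
permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import OmicsMatrix

#: default fold-change cutoffs (as ratios) per layer
FC_CUTS = {"proteome": 1.5, "transcriptome": 1.5, "phosphoproteome": 2.0}


def _group_indices(matrix: OmicsMatrix):
    design = matrix.design
    labels = np.asarray(design.groups)
    groups = list(design.group_names)
    idx = [np.flatnonzero(labels == g) for g in groups]
    return groups, idx


def _f_stats(X: np.ndarray, group_idx) -> np.ndarray:
    """Vectorized one-way ANOVA F for every row of X.

    Degenerate rows (zero between- and within-group variance) yield NaN.
    """
    n = X.shape[1]
    k = len(group_idx)
    grand = X.mean(axis=1, keepdims=True)
    ss_between = np.zeros(X.shape[0])
    ss_within = np.zeros(X.shape[0])
    for idx in group_idx:
        sub = X[:, idx]
        gm = sub.mean(axis=1, keepdims=True)
        ss_between += idx.size * (gm[:, 0] - grand[:, 0]) ** 2
        ss_within += ((sub - gm) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    F[(ss_within == 0) & (ss_between > 0)] = np.inf
    F[(ss_within == 0) & (ss_between == 0)] = np.nan
    return F


def anova_permutation(matrix: OmicsMatrix, n_perm: int = 1000, seed=0,
                      exhaustive: bool = False):
    """Per-feature ANOVA F and permutation p-value.

    Group labels are permuted identically across features within each
    permutation; p uses the +1-smoothed estimator
    ``(1 + #{F_perm >= F_obs}) / (n_perm + 1)`` and is therefore never 0.
    With ``exhaustive=True`` every distinct label assignment is enumerated
    instead and p = #{F_perm >= F_obs} / n_distinct (the identity included,
    no smoothing).  Constant features (no variance at all) are flagged
    with p = 1.

    Returns a DataFrame indexed by feature with columns F_stat, p_perm,
    degenerate.
    """
    m = matrix.require_log2()
    m.design.require_replicates(2)
    X = m.data.to_numpy(dtype=float)
    groups, group_idx = _group_indices(m)
    F_obs = _f_stats(X, group_idx)
    degenerate = ~np.isfinite(F_obs)

    n = X.shape[1]
    count_ge = np.zeros(X.shape[0])
    if exhaustive:
        from sympy.utilities.iterables import multiset_permutations
        labels = list(m.design.groups)
        n_done = 0
        for assignment in multiset_permutations(labels):
            arr = np.asarray(assignment)
            perm_idx = [np.flatnonzero(arr == g) for g in groups]
            Fp = _f_stats(X, perm_idx)
            # relabelings sharing the identity's index partition give the
            # same F up to summation order; count them as ties
            ge = (Fp >= F_obs) | np.isclose(Fp, F_obs, rtol=1e-9, atol=1e-12)
            count_ge += np.where(np.isnan(Fp), 0, ge)
            n_done += 1
        p = count_ge / n_done
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            perm_idx = [perm[idx] for idx in group_idx]
            Fp = _f_stats(X, perm_idx)
            count_ge += np.where(np.isnan(Fp), 0, Fp >= F_obs)
        p = (1.0 + count_ge) / (n_perm + 1.0)
    p[degenerate] = 1.0
    return pd.DataFrame({"F_stat": F_obs, "p_perm": p, "degenerate": degenerate},
                        index=m.data.index)


def adjust_pvalues(p, method: str = "bh"):
    """Benjamini-Hochberg step-up q-values (or Storey pi0-adjusted variant).

    The Storey option estimates pi0 from the p-value density above
    lambda = 0.5 and rescales the BH values; with pi0 = 1 it equals BH.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    q = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q
    if method == "storey":
        lam = 0.5
        pi0 = min(1.0, (p > lam).mean() / (1.0 - lam)) if p.size else 1.0
        return np.minimum(q * pi0, 1.0)
    raise ValueError(f"unknown method {method!r}")


def max_abs_log2fc(matrix: OmicsMatrix) -> pd.Series:
    """Largest absolute pairwise difference of group means (log2 units)."""
    gm = matrix.group_means()
    cols = gm.columns
    best = pd.Series(0.0, index=gm.index)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            best = np.maximum(best, (gm[cols[i]] - gm[cols[j]]).abs())
    return best


def select_de(matrix: OmicsMatrix, anova: pd.DataFrame, p_cut: float = 0.05,
              fc_cut: float | None = None) -> pd.DataFrame:
    """Apply the p-value and fold-change filters.

    ``fc_cut`` is a ratio (1.5 or 2.0 by default depending on layer),
    compared against group-mean differences on the log2 scale; ties at the
    cutoff are included.  Returns the ANOVA table augmented with q_value,
    max_abs_log2fc, group means, and is_de.
    """
    if fc_cut is None:
        fc_cut = FC_CUTS[matrix.layer]
    out = anova.copy()
    out["q_value"] = adjust_pvalues(out["p_perm"].to_numpy())
    out["max_abs_log2fc"] = max_abs_log2fc(matrix)
    gm = matrix.group_means()
    for g in gm.columns:
        out[f"mean_{g}"] = gm[g]
    out["is_de"] = (out["p_perm"] <= p_cut) & \
                   (out["max_abs_log2fc"] >= np.log2(fc_cut))
    return out


def estimate_final_fdr(matrix: OmicsMatrix, de_table: pd.DataFrame,
                       n_perm: int = 100, p_cut: float = 0.05,
                       fc_cut: float | None = None, seed=0) -> float:
    """Permutation estimate of the FDR of the selected DE set.

    For each label permutation, features are re-scored against the pool of
    permuted F statistics (per feature) and re-filtered with the same p and
    fold-change cutoffs; the FDR is the mean count of null passers divided
    by the observed DE count.
    """
    n_de = int(de_table["is_de"].sum())
    if n_de == 0:
        import logging
        logging.getLogger("gliomics").warning("empty DE set; final FDR = 0")
        return 0.0
    if fc_cut is None:
        fc_cut = FC_CUTS[matrix.layer]
    lfc_cut = np.log2(fc_cut)

    m = matrix.require_log2()
    X = m.data.to_numpy(dtype=float)
    groups, group_idx = _group_indices(m)
    rng = np.random.default_rng(seed)
    n = X.shape[1]
    F_perm = np.empty((n_perm, X.shape[0]))
    fc_perm = np.empty((n_perm, X.shape[0]))
    for b in range(n_perm):
        perm = rng.permutation(n)
        perm_idx = [perm[idx] for idx in group_idx]
        F_perm[b] = np.nan_to_num(_f_stats(X, perm_idx), nan=0.0)
        means = np.stack([X[:, idx].mean(axis=1) for idx in perm_idx])
        fc = np.zeros(X.shape[0])
        for i in range(len(perm_idx)):
            for j in range(i + 1, len(perm_idx)):
                fc = np.maximum(fc, np.abs(means[i] - means[j]))
        fc_perm[b] = fc
    # per-feature permutation p of each permuted F within the permutation pool
    order_rank = (F_perm[None, :, :] >= F_perm[:, None, :]).sum(axis=1) \
        if n_perm <= 200 else None
    if order_rank is not None:
        p_null = order_rank / n_perm
    else:  # rank via argsort per feature to bound memory
        p_null = np.empty_like(F_perm)
        for f in range(F_perm.shape[1]):
            col = F_perm[:, f]
            p_null[:, f] = (col[:, None] <= col[None, :]).mean(axis=1)
    passes = (p_null <= p_cut) & (fc_perm >= lfc_cut)
    return float(passes.sum(axis=1).mean() / max(1, n_de))


@dataclass
class TTestResult:
    t: pd.Series
    p: pd.Series
    flagged: pd.Series


def pairwise_ttest(matrix: OmicsMatrix, group_a: str, group_b: str,
                   variant: str = "pooled", alternative: str = "two-sided"
                   ) -> pd.DataFrame:
    """Per-feature Student's (pooled) or Welch's t-test between two groups.

    Features with zero variance in both groups and equal means are flagged
    with p = 1.
    """
    m = matrix.require_log2()
    a = m.data[m.design.samples_of(group_a)].to_numpy(dtype=float)
    b = m.data[m.design.samples_of(group_b)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >=2 samples")
    equal_var = variant == "pooled"
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var,
                               alternative=alternative)
    flagged = ~np.isfinite(t)
    t = np.where(flagged, 0.0, t)
    p = np.where(flagged, 1.0, p)
    return pd.DataFrame({"t": t, "p": p, "flagged": flagged}, index=m.data.index)
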