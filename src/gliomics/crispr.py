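"""Dual-gRNA CRISPR dropout screen analysis.

Each targeted gene carries three dual-gRNA constructs; nontargeting
constructs define the null behavior.  Per replicate, counts are scaled to
counts-per-million and log2-transformed with a pseudocount; each
construct's log2(final/start) ratios are compared with the pooled
nontargeting ratios by a one-sided Student's t-test, and a gene is called
essential when at least two of its three constructs drop out
significantly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError

logger = logging.getLogger("gliomics")

NONTARGETING = "nontargeting"
P_CUT = 0.05


@dataclass
class GRNACountTable:
    """Construct x replicate count table for the start and final pools."""

    table: pd.DataFrame  # construct_id, gene, start_1..n, final_1..n

    def __post_init__(self):
        t = self.table
        if t["construct_id"].duplicated().any():
            raise DataError("duplicate construct ids")
        counts = t[self.start_cols + self.final_cols]
        if (counts.to_numpy() < 0).any():
            raise DataError("negative counts")
        if not (t["gene"] == NONTARGETING).any():
            raise DataError("need at least one nontargeting construct")

    @property
    def start_cols(self) -> list:
        return sorted(c for c in self.table.columns if c.startswith("start_"))

    @property
    def final_cols(self) -> list:
        return sorted(c for c in self.table.columns if c.startswith("final_"))

    @property
    def n_replicates(self) -> int:
        return len(self.start_cols)


@dataclass
class GeneHitCall:
    gene: str
    construct_log2fc: dict      # construct -> mean log2(final/start)
    construct_p: dict
    n_significant_down: int
    is_hit: bool
    flagged: str = ""


def normalize_counts(table: GRNACountTable, pseudocount: float = 1.0
                     ) -> pd.DataFrame:
    """Per-replicate counts-per-million, then log2 with a pseudocount.

    Depth-invariant: replicates with equal composition but different
    sequencing depth normalize to identical profiles.
    """
    t = table.table.set_index("construct_id")
    out = {}
    for col in table.start_cols + table.final_cols:
        lib = t[col].sum()
        if lib <= 0:
            raise DataError(f"zero library size in {col}")
        out[col] = np.log2(t[col] / lib * 1e6 + pseudocount)
    df = pd.DataFrame(out, index=t.index)
    df.insert(0, "gene", t["gene"])
    return df


def construct_ratios(normalized: pd.DataFrame, n_reps: int) -> pd.DataFrame:
    """Per-construct, per-replicate log2(final/start) ratios."""
    cols = {}
    for i in range(1, n_reps + 1):
        cols[f"ratio_{i}"] = normalized[f"final_{i}"] - normalized[f"start_{i}"]
    df = pd.DataFrame(cols, index=normalized.index)
    df.insert(0, "gene", normalized["gene"])
    return df


def construct_dropout_test(ratios: np.ndarray, control_ratios: np.ndarray,
                           p_cut: float = P_CUT) -> tuple:
    """One-sided Student's t of one construct's ratios vs pooled controls.

    Returns (t, p, significant_down); a construct whose mean ratio is not
    below the control mean is never significant_down (one-sidedness).
    Degenerate variance with equal means yields p = 1.
    """
    ratios = np.asarray(ratios, dtype=float)
    control_ratios = np.asarray(control_ratios, dtype=float)
    if ratios.size < 2 or control_ratios.size < 2:
        raise DataError("need >=2 replicate ratios and >=2 control values")
    if np.ptp(ratios) == 0 and np.ptp(control_ratios) == 0 \
            and ratios[0] == control_ratios[0]:
        return 0.0, 1.0, False
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(ratios, control_ratios, equal_var=True,
                               alternative="less")
    if not np.isfinite(t):
        return 0.0, 1.0, False
    down = bool(p <= p_cut and ratios.mean() < control_ratios.mean())
    return float(t), float(p), down


def call_gene_hits(table: GRNACountTable, p_cut: float = P_CUT) -> list:
    """Gene-level essentiality calls by the >=2-of-3-construct rule.

    The nontargeting pseudo-gene is scored for reporting but never
    eligible as a hit.  Genes with a construct count other than three are
    evaluated with the generalized rule >= ceil(2n/3) and flagged.
    """
    norm = normalize_counts(table)
    ratios = construct_ratios(norm, table.n_replicates)
    rep_cols = [c for c in ratios.columns if c.startswith("ratio_")]
    controls = ratios.loc[ratios["gene"] == NONTARGETING, rep_cols] \
        .to_numpy(dtype=float).ravel()
    calls = []
    for gene, sub in ratios.groupby("gene", sort=True):
        fcs, ps = {}, {}
        n_down = 0
        for cid, row in sub[rep_cols].iterrows():
            r = row.to_numpy(dtype=float)
            if gene == NONTARGETING:
                # leave-one-out against the other controls
                others = ratios.loc[(ratios["gene"] == NONTARGETING)
                                    & (ratios.index != cid), rep_cols] \
                    .to_numpy(dtype=float).ravel()
                t, p, down = construct_dropout_test(r, others, p_cut)
            else:
                t, p, down = construct_dropout_test(r, controls, p_cut)
            fcs[cid] = float(r.mean())
            ps[cid] = p
            n_down += down
        n = len(sub)
        need = 2 if n == 3 else ceil(2 * n / 3)
        flagged = "" if n == 3 or gene == NONTARGETING \
            else f"{n} constructs; rule >= {need}"
        if flagged:
            logger.warning("call_gene_hits: gene %s has %s", gene, flagged)
        is_hit = gene != NONTARGETING and n_down >= need
        calls.append(GeneHitCall(gene, fcs, ps, int(n_down), bool(is_hit),
                                 flagged))
    return calls


def hit_summary(calls: list) -> dict:
    targeted = [c for c in calls if c.gene != NONTARGETING]
    hits = [c.gene for c in targeted if c.is_hit]
    return {"n_targeted": len(targeted), "n_hits": len(hits),
            "hit_fraction": len(hits) / len(targeted) if targeted else 0.0,
            "hits": sorted(hits)}
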