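"""Cross-species convergence of oncogene-responsive genes.

Mouse genes whose transcripts follow the oncogenic-potency ordering
NTRK > PDGFRA > cortex with high stringency (>=2-fold NTRK over PDGFRA,
t-test p <= 0.05) and a consistent proteome or phosphoproteome change are
mapped through 1:1 orthology onto a human cohort; genes also higher in
human NTRK-fusion cases than PDGFRA-mutant cases form the convergent
candidate list.  Expression distributions of the two species are matched
by quantile normalization over shared orthologs first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CORTEX, NTRK, PDGFRA, DataError, OmicsMatrix
from .differential import pairwise_ttest

logger = logging.getLogger("gliomics")


@dataclass(frozen=True)
class OrthologyMap:
    """1:1 mouse <-> human gene pairs (non-bijective pairs filtered out)."""

    pairs: tuple  # of (mouse, human)

    def __post_init__(self):
        mouse = [m for m, _ in self.pairs]
        human = [h for _, h in self.pairs]
        keep = [(m, h) for m, h in self.pairs
                if mouse.count(m) == 1 and human.count(h) == 1]
        if len(keep) < len(self.pairs):
            logger.info("OrthologyMap: dropped %d non-1:1 pairs",
                        len(self.pairs) - len(keep))
        object.__setattr__(self, "pairs", tuple(keep))

    @property
    def mouse_to_human(self) -> dict:
        return dict(self.pairs)

    @property
    def human_to_mouse(self) -> dict:
        return {h: m for m, h in self.pairs}


def quantile_normalize(a: pd.DataFrame, b: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map both matrices onto the pooled mean order-statistic distribution.

    Rows are shared orthologs (same row count required); each column's
    values are replaced by the reference quantile at its (average, for
    ties) rank.  Idempotent: normalizing twice equals once.
    """
    if len(a) != len(b):
        raise DataError("matrices must share the ortholog gene set")
    pooled = np.concatenate([a.to_numpy(dtype=float), b.to_numpy(dtype=float)],
                            axis=1)
    reference = np.sort(pooled, axis=0).mean(axis=1)

    def _apply(df: pd.DataFrame) -> pd.DataFrame:
        out = np.empty_like(df.to_numpy(dtype=float))
        for j, col in enumerate(df.columns):
            v = df[col].to_numpy(dtype=float)
            ranks = stats.rankdata(v, method="average")  # 1..n, ties averaged
            out[:, j] = np.interp(ranks, np.arange(1, len(v) + 1), reference)
        return pd.DataFrame(out, index=df.index, columns=df.columns)

    return _apply(a), _apply(b)


def _consistent_direction(de_table: pd.DataFrame, gene_or_sites,
                          p_table: pd.DataFrame | None = None,
                          p_cut: float = 0.05) -> bool:
    """Same-sign NTRK-over-PDGFRA change with nominal significance."""
    for f in gene_or_sites:
        if f not in de_table.index:
            continue
        diff = de_table.loc[f, f"mean_{NTRK}"] - de_table.loc[f, f"mean_{PDGFRA}"]
        if diff <= 0:
            continue
        if p_table is not None:
            if f in p_table.index and p_table.loc[f, "p"] <= p_cut:
                return True
        else:
            return True
    return False


def mouse_candidate_filter(transcriptome: OmicsMatrix,
                           transcript_de: pd.DataFrame,
                           proteome_de: pd.DataFrame,
                           phospho_de: pd.DataFrame,
                           fold_cut: float = 2.0, p_cut: float = 0.05,
                           proteome_p: pd.DataFrame | None = None,
                           phospho_p: pd.DataFrame | None = None) -> list:
    """High-stringency mouse candidates.

    Requires (1) strict transcript ordering NTRK > PDGFRA > cortex,
    (2) >= ``fold_cut`` NTRK over PDGFRA, (3) Student's t p <= ``p_cut``
    for NTRK vs PDGFRA transcripts, and (4) a consistent (same-direction)
    change in the proteome or phosphoproteome.  ``proteome_p``/
    ``phospho_p`` optionally carry per-feature NTRK-vs-PDGFRA t-test
    p-values for the consistency check.
    """
    tt = pairwise_ttest(transcriptome, NTRK, PDGFRA, variant="pooled")
    gm = transcriptome.group_means()
    out = []
    phospho_parents = phospho_de.index.to_series().str.rsplit("_", n=1).str[0] \
        if len(phospho_de) else pd.Series(dtype=object)
    for g in gm.index:
        mN, mP, mC = gm.loc[g, NTRK], gm.loc[g, PDGFRA], gm.loc[g, CORTEX]
        if not (mN > mP > mC):
            continue
        if mN - mP < np.log2(fold_cut):
            continue
        if tt.loc[g, "p"] > p_cut:
            continue
        sites = list(phospho_parents.index[phospho_parents == g])
        ok = _consistent_direction(proteome_de, [g], proteome_p, p_cut) or \
            _consistent_direction(phospho_de, sites, phospho_p, p_cut)
        if ok:
            out.append(g)
    return sorted(out)


def human_candidate_filter(human_fpkm: pd.DataFrame, case_labels: dict,
                           p_cut: float = 0.05, fpkm_floor: float = 1.0
                           ) -> list:
    """Human genes higher in NTRK-fusion than PDGFRA-mutant cases.

    ``case_labels`` maps sample id -> 'NTRK' or 'PDGFRA'.  Genes must pass
    FPKM > ``fpkm_floor`` in at least one class mean; significance by a
    one-sided Student's t-test on log2 values.  With fewer than two cases
    in a class the test degrades to a rank-based comparison (flagged).
    """
    ntrk_cols = [s for s, c in case_labels.items() if c == NTRK]
    pdgfra_cols = [s for s, c in case_labels.items() if c == PDGFRA]
    if not ntrk_cols or not pdgfra_cols:
        raise DataError("need cases of both classes")
    X = human_fpkm
    expressed = (X[ntrk_cols].mean(axis=1) > fpkm_floor) | \
                (X[pdgfra_cols].mean(axis=1) > fpkm_floor)
    L = np.log2(X.clip(lower=X[X > 0].min().min() / 2))
    out = []
    small = len(ntrk_cols) < 2 or len(pdgfra_cols) < 2
    if small:
        logger.warning("human_candidate_filter: <2 cases in a class; "
                       "falling back to a rank comparison")
    for g in X.index[expressed]:
        a = L.loc[g, ntrk_cols].to_numpy(dtype=float)
        b = L.loc[g, pdgfra_cols].to_numpy(dtype=float)
        if small:
            if a.mean() > b.mean() and a.min() > b.max():
                out.append(g)
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            continue
        _, p = stats.ttest_ind(a, b, equal_var=True, alternative="greater")
        if p <= p_cut:
            out.append(g)
    return sorted(out)


def convergent_candidates(mouse_genes, human_genes,
                          orthology: OrthologyMap) -> list:
    """Mouse candidates whose human orthologs were also selected."""
    m2h = orthology.mouse_to_human
    human = set(human_genes)
    return sorted(g for g in mouse_genes if m2h.get(g) in human)
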