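"""Transcription-factor activity inference from regulon enrichment.

TF activity is evidenced by enrichment of the TF's target genes among
differentially expressed genes, tested per layer (transcriptome; each
proteome coexpression cluster) with a one-sided Fisher exact test and
BH correction.  A TF is accepted only when its regulon is significant in
both the transcriptome and at least one proteome cluster AND the TF
protein itself was detected by MS; accepted TFs are then validated by
their own protein-level change and/or increased phosphorylation at a
reported activation site, and classified as activators or repressors by
the sign of their target changes in tumors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import RelationMap
from .differential import adjust_pvalues

#: activation phosphosites reported for the five phospho-validated TFs
#: (synthetic fixtures plant sites with these semantics)
REPORTED_ACTIVATION_SITES = {
    "MYC": ["S62"], "JUND": ["S100"], "JUN": ["S73"],
    "BRCA1": ["S686"], "EP300": ["S2312"],
}


@dataclass
class TFActivityCall:
    tf_id: str
    p_transcriptome: float = float("nan")
    q_transcriptome: float = float("nan")
    p_proteome: float = float("nan")       # best (min) over clusters
    q_proteome: float = float("nan")
    detected_by_ms: bool = False
    accepted_by_targets: bool = False
    reject_reason: str = ""
    validated: str = "none"   # protein_level | phospho_activation_site | both | none
    activation_sites: list = field(default_factory=list)
    mode: str = "undetermined"  # activator | repressor | undetermined


def tf_target_enrichment(de_set, tf_targets: RelationMap, universe,
                         q_cut: float = 0.05) -> pd.DataFrame:
    """Per-TF one-sided Fisher exact test of regulon overlap with a DE set.

    2x2 table: (target vs non-target) x (DE vs not), over ``universe``.
    TFs without targets in the universe are skipped.  Returns a DataFrame
    indexed by TF with n_targets, overlap, p, q, significant.
    """
    universe = set(universe)
    de = set(de_set) & universe
    rows = {}
    for tf in tf_targets.regulators:
        targets = set(tf_targets.targets_of(tf)["target"]) & universe
        if not targets:
            continue
        a = len(targets & de)
        b = len(targets) - a
        c = len(de) - a
        d = len(universe) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows[tf] = {"n_targets": len(targets), "overlap": a, "p": float(p)}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if df.empty:
        return pd.DataFrame(columns=["n_targets", "overlap", "p", "q",
                                     "significant"])
    df["q"] = adjust_pvalues(df["p"].to_numpy())
    df["significant"] = df["q"] <= q_cut
    return df


def intersect_layers(transcriptome_enrich: pd.DataFrame,
                     proteome_enrich_by_cluster: dict,
                     ms_detected_proteins) -> list:
    """Accept TFs significant in transcriptome AND >=1 proteome cluster.

    ``proteome_enrich_by_cluster`` maps cluster id -> enrichment DataFrame.
    The TF protein itself must have been identified by MS.  Returns
    TFActivityCall objects for every TF tested in the transcriptome.
    """
    detected = set(ms_detected_proteins)
    calls = []
    for tf, row in transcriptome_enrich.iterrows():
        call = TFActivityCall(tf, p_transcriptome=row["p"],
                              q_transcriptome=row["q"],
                              detected_by_ms=tf in detected)
        best_p, best_q, sig_prot = np.nan, np.nan, False
        for enr in proteome_enrich_by_cluster.values():
            if tf in enr.index:
                p, q = enr.loc[tf, "p"], enr.loc[tf, "q"]
                if np.isnan(best_p) or p < best_p:
                    best_p, best_q = p, q
                sig_prot = sig_prot or bool(enr.loc[tf, "significant"])
        call.p_proteome, call.q_proteome = best_p, best_q
        if not row["significant"]:
            call.reject_reason = "not significant in transcriptome"
        elif not sig_prot:
            call.reject_reason = "not significant in proteome"
        elif tf not in detected:
            call.reject_reason = "not identified by MS"
        else:
            call.accepted_by_targets = True
        calls.append(call)
    return calls


def validate_tf(call: TFActivityCall, proteome_de: pd.DataFrame,
                phospho_de: pd.DataFrame,
                activation_sites: dict | None = None) -> TFActivityCall:
    """Protein-level / activation-phosphosite validation of an accepted TF.

    ``activation_sites`` maps TF -> list of residue-position labels
    (defaults to the reported five).  Phospho validation requires an
    annotated activation site among DE phosphosites with a positive change
    in tumors (mean tumor log2FC over cortex > 0).
    """
    sites = (activation_sites or REPORTED_ACTIVATION_SITES).get(call.tf_id, [])
    protein_ok = (call.tf_id in proteome_de.index
                  and bool(proteome_de.loc[call.tf_id, "is_de"]))
    phospho_ok = False
    found = []
    tumor_cols = [c for c in phospho_de.columns
                  if c.startswith("mean_") and "cortex" not in c]
    for s in sites:
        sid = f"{call.tf_id}_{s}"
        if sid in phospho_de.index and bool(phospho_de.loc[sid, "is_de"]):
            row = phospho_de.loc[sid]
            up = all(row[c] > row["mean_cortex"] for c in tumor_cols) \
                if tumor_cols and "mean_cortex" in phospho_de.columns else True
            if up:
                phospho_ok = True
                found.append(sid)
    call.activation_sites = found
    if protein_ok and phospho_ok:
        call.validated = "both"
    elif phospho_ok:
        call.validated = "phospho_activation_site"
    elif protein_ok:
        call.validated = "protein_level"
    else:
        call.validated = "none"
    return call


def repressor_mode(call: TFActivityCall, target_log2fc: pd.Series,
                   p_cut: float = 0.05, min_targets: int = 5) -> str:
    """Classify an accepted TF by the predominant direction of its targets.

    A one-sided sign test on the tumor-vs-cortex log2 fold changes of the
    TF's enriched targets: predominantly down -> repressor, predominantly
    up -> activator, otherwise undetermined.  Fewer than ``min_targets``
    informative targets -> undetermined.
    """
    fc = target_log2fc[target_log2fc != 0]
    n = len(fc)
    if n < min_targets:
        call.mode = "undetermined"
        return call.mode
    n_down = int((fc < 0).sum())
    p_down = float(stats.binomtest(n_down, n, 0.5, alternative="greater").pvalue)
    p_up = float(stats.binomtest(n - n_down, n, 0.5, alternative="greater").pvalue)
    if p_down <= p_cut:
        call.mode = "repressor"
    elif p_up <= p_cut:
        call.mode = "activator"
    else:
        call.mode = "undetermined"
    return call.mode
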