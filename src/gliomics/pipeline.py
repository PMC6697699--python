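"""End-to-end orchestration of the integrative analysis stages.

Convenience wrappers that run the standard stage sequence on a study
(synthetic or ingested): differential expression per layer, proteome
coexpression clustering, TF and kinase inference, pathway activity per
tumor group, cross-species convergence, and the CRISPR dropout calls.
Each wrapper returns plain stage outputs so callers can inspect or
re-enter at any point.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import coexpression, crispr, crossspecies, differential, kinase
from . import pathway as pathway_mod
from . import phospho as phospho_mod
from . import tf as tf_mod
from .core import NTRK, PDGFRA, OmicsMatrix


def run_de(matrix: OmicsMatrix, n_perm: int = 1000, seed=0) -> pd.DataFrame:
    """ANOVA-permutation DE with the layer's default fold cutoff."""
    an = differential.anova_permutation(matrix, n_perm=n_perm, seed=seed)
    return differential.select_de(matrix, an)


def run_coexpression(matrix: OmicsMatrix, de_table: pd.DataFrame,
                     min_size: int = 30):
    """Cluster the DE features of one layer and assign memberships."""
    de_feats = de_table.index[de_table["is_de"]]
    sub = matrix.subset(de_feats)
    dist, _ = coexpression.correlation_distance(sub)
    clusters = coexpression.cluster_features(sub, dist, min_size=min_size)
    return coexpression.assign_members(clusters, sub)


def run_tf_stage(study, transcript_de: pd.DataFrame,
                 proteome_de: pd.DataFrame, phospho_de: pd.DataFrame,
                 proteome_clusters) -> list:
    """Regulon enrichment in both layers, intersection, and validation."""
    tx_universe = set(study.transcriptome.feature_ids)
    tx_de = set(transcript_de.index[transcript_de["is_de"]])
    tx_enr = tf_mod.tf_target_enrichment(tx_de, study.tf_target, tx_universe)

    prot_universe = set(study.proteome.feature_ids)
    prot_de = set(proteome_de.index[proteome_de["is_de"]])
    by_cluster = {}
    for cl in proteome_clusters:
        cluster_de = set(cl.members) & prot_de
        by_cluster[cl.cluster_id] = tf_mod.tf_target_enrichment(
            cluster_de, study.tf_target, prot_universe)

    calls = tf_mod.intersect_layers(tx_enr, by_cluster,
                                    study.proteome.feature_ids)
    gm = study.transcriptome.group_means()
    for call in calls:
        if not call.accepted_by_targets:
            continue
        tf_mod.validate_tf(call, proteome_de, phospho_de,
                           study.activation_sites)
        targets = [t for t in study.tf_target.targets_of(call.tf_id)["target"]
                   if t in gm.index]
        if targets:
            fc = (gm.loc[targets, [PDGFRA, NTRK]].mean(axis=1)
                  - gm.loc[targets, "cortex"])
            tf_mod.repressor_mode(call, fc)
    return calls


def run_kinase_stage(study, n_restarts: int = 10, seed=0):
    """Proteome normalization, activity inference, and acceptance filters."""
    norm, _ = phospho_mod.normalize_phospho(study.phosphoproteome,
                                            study.proteome)
    estimates = kinase.infer_activities(norm, study.kinase_substrate,
                                        n_restarts=n_restarts, seed=seed)
    accepted = kinase.filter_activities(estimates, study.kinase_substrate,
                                        study.design)
    return estimates, accepted, norm


def run_pathway_stage(study, phospho_de: pd.DataFrame, n_boot: int = 10_000,
                      seed=0) -> dict:
    """a(P) per tumor group on the planted pathway, and their ratio."""
    results = {}
    for i, grp in enumerate([NTRK, PDGFRA]):
        results[grp] = pathway_mod.pathway_activity(
            phospho_de, study.truth.pathway_proteins, study.functional_sites,
            grp, pathway_id="PI3K-AKT", n_boot=n_boot, seed=seed + i)
    ratio = pathway_mod.pathway_activity_ratio(results[NTRK], results[PDGFRA])
    return {"results": results, "ratio": ratio}


def run_cross_species(study, transcript_de, proteome_de, phospho_de) -> dict:
    """Mouse high-stringency candidates, human candidates, convergence."""
    tt_prot = differential.pairwise_ttest(study.proteome, NTRK, PDGFRA)
    tt_ph = differential.pairwise_ttest(study.phosphoproteome, NTRK, PDGFRA)
    mouse = crossspecies.mouse_candidate_filter(
        study.transcriptome, transcript_de, proteome_de, phospho_de,
        proteome_p=tt_prot, phospho_p=tt_ph)
    human = crossspecies.human_candidate_filter(study.human_fpkm,
                                                study.human_case_labels)
    convergent = crossspecies.convergent_candidates(mouse, human,
                                                    study.orthology)
    return {"mouse": mouse, "human": human, "convergent": convergent}


def run_crispr(study) -> dict:
    calls = crispr.call_gene_hits(study.grna_counts)
    return {"calls": calls, "summary": crispr.hit_summary(calls)}
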