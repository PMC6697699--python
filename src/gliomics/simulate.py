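"""Synthetic multiomics study with planted ground truth.

Emulates the structure of a 10-plex TMT three-group design (3 normal
cortex, 4 PDGFRA-driven HGG, 3 NTRK-driven HGG): a proteome with planted
coexpression clusters, a phosphoproteome whose substrate sites carry
additive kinase-activity signal on top of parent-protein abundance, a
transcriptome with TF-regulon signal, curated-style relationship tables,
functional-phosphosite annotations planting a known pathway-activity
fold difference between the tumor genotypes, localization-score PSM
tables, a negative-binomial dual-gRNA dropout screen, and a small human
cohort for cross-species convergence.  Noise is lognormal on intensities
(Gaussian on log2).  Every quantity needed to score a downstream stage is
recorded in :class:`GroundTruth`.

Group-effect "patterns" are five directions evenly spaced in the
(replicate-weighted) two-dimensional space of centered group contrasts,
scaled to unit per-sample standard deviation; pattern 0 is the monotone
cortex < PDGFRA < NTRK direction that dominates the tumor biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (CORTEX, NTRK, PDGFRA, ConfigError, OmicsMatrix,
                   RelationMap, SampleDesign, site_id)
from .crispr import NONTARGETING, GRNACountTable
from .crossspecies import OrthologyMap
from .phospho import PSMRecord


@dataclass
class StudyConfig:
    """Sizes, noise and effect magnitudes of the synthetic study.

    Effects are on the log2 scale; ``*_effect`` values are the per-sample
    standard deviation of the group-level profile they scale.
    """

    group_sizes: dict = field(default_factory=lambda: {CORTEX: 3, PDGFRA: 4,
                                                       NTRK: 3})
    n_proteins: int = 2000
    n_sites: int = 5000
    n_transcripts: int = 3000
    noise_sd: float = 0.25

    n_clusters: int = 5
    cluster_size: int = 60
    cluster_effect: float = 1.0

    n_kinases: int = 30
    n_active_kinases: int = 24
    kinase_effect: float = 1.0
    kinase_jitter: float = 0.15
    min_substrates: int = 3
    max_substrates: int = 8

    n_tfs: int = 20
    n_active_tfs: int = 8
    targets_per_tf: int = 30
    tf_effect: float = 0.5
    tf_protein_effect: float = 0.5

    n_pathway_proteins: int = 22
    n_negative_sites: int = 5
    pathway_ratio: float = 1.45       # planted NTRK:PDGFRA activity ratio
    pathway_site_shift: tuple = (1.2, 2.5)  # |log2FC| range in PDGFRA

    n_convergent: int = 20
    convergent_transcript_levels: tuple = (0.0, 1.0, 2.6)  # cortex,PDGFRA,NTRK
    convergent_protein_levels: tuple = (0.0, 0.8, 2.0)
    human_cases: dict = field(default_factory=lambda: {NTRK: 3, PDGFRA: 8})
    human_shift: float = 1.8
    human_noise_sd: float = 0.6

    crispr_mean_count: float = 500.0
    crispr_dropout_fold: float = 8.0
    crispr_dispersion: float = 0.05
    crispr_replicates: int = 3

    psm_ambiguity_fraction: float = 0.3
    n_psm_sites: int = 50

    def validate(self):
        for name in ("n_proteins", "n_sites", "n_transcripts", "n_kinases",
                     "n_tfs", "n_clusters", "cluster_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_transcripts < self.n_proteins:
            raise ConfigError("transcriptome must cover the proteome genes")


@dataclass
class GroundTruth:
    proteome_clusters: dict          # feature -> cluster index (1..K)
    phospho_clusters: dict
    group_effects: dict              # cluster label -> {group: log2 shift}
    kinase_activity: pd.DataFrame    # kinase x sample (planted, incl. jitter)
    active_kinases: list
    rescued_kinases: dict            # small-substrate kinase -> upstream kinase
    tf_activity: pd.DataFrame        # TF x sample
    active_tfs: list
    phospho_validated_tfs: list
    tf_targets: dict
    functional_sign: dict            # site -> +1/-1
    pathway_proteins: list
    planted_pathway_ratio: float
    convergent_genes: list
    essential_genes: list
    psm_true_sites: dict = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    design: SampleDesign
    proteome: OmicsMatrix
    phosphoproteome: OmicsMatrix
    transcriptome: OmicsMatrix
    kinase_substrate: RelationMap
    tf_target: RelationMap
    functional_sites: RelationMap
    activation_sites: dict           # TF -> [residue-position labels]
    grna_counts: GRNACountTable
    human_fpkm: pd.DataFrame
    human_case_labels: dict
    orthology: OrthologyMap
    psms: list
    truth: GroundTruth


def group_patterns(design: SampleDesign, n: int = 5) -> np.ndarray:
    """n group-effect directions (n x groups), unit per-sample SD.

    Built from a replicate-weighted orthonormal basis of the centered
    group-contrast space; direction 0 is monotone increasing from cortex
    through PDGFRA to NTRK.
    """
    w = np.array([design.group_sizes()[g] for g in design.group_names],
                 dtype=float)
    v1 = np.array([-1.0, 0.0, 1.0])
    v1 = v1 - (w @ v1) / w.sum()
    v1 /= np.sqrt((w * v1 ** 2).sum() / w.sum())
    v2 = np.array([1.0, -1.5, 1.0])
    v2 = v2 - (w @ v2) / w.sum()
    v2 = v2 - v1 * (w * v1 * v2).sum() / (w * v1 ** 2).sum()
    v2 /= np.sqrt((w * v2 ** 2).sum() / w.sum())
    thetas = 2 * np.pi * np.arange(n) / n
    return np.stack([np.cos(t) * v1 + np.sin(t) * v2 for t in thetas])


def _expand(group_vec, design: SampleDesign) -> np.ndarray:
    """Group-level vector -> per-sample vector in design order."""
    lut = dict(zip(design.group_names, group_vec))
    return np.array([lut[g] for g in design.groups], dtype=float)


def generate_grna_screen(genes, essential, constructs_per_gene: int = 3,
                         dropout_fold: float = 8.0, dispersion: float = 0.05,
                         replicates: int = 3, mean_count: float = 500.0,
                         n_controls: int = 6, seed=0) -> GRNACountTable:
    """Negative-binomial dual-gRNA dropout screen counts.

    Essential genes' final-pool means are scaled down by ``dropout_fold``;
    nontargeting controls are drawn from the null.  Counts have variance
    ``m + dispersion * m^2``.
    """
    genes = list(genes)
    essential = set(essential)
    if not essential <= set(genes):
        raise ConfigError("essential genes must be a subset of targeted genes")
    if dropout_fold < 1:
        raise ConfigError("dropout_fold must be >= 1")
    rng = np.random.default_rng(seed)

    def nb(mean, size):
        if dispersion <= 0:
            return rng.poisson(mean, size=size)
        r = 1.0 / dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p, size=size)

    rows = []
    for gene in genes:
        for c in range(1, constructs_per_gene + 1):
            cid = f"{gene}_c{c}"
            start = nb(mean_count, replicates)
            final_mean = mean_count / dropout_fold if gene in essential \
                else mean_count
            final = nb(final_mean, replicates)
            rows.append({"construct_id": cid, "gene": gene,
                         **{f"start_{i+1}": int(start[i])
                            for i in range(replicates)},
                         **{f"final_{i+1}": int(final[i])
                            for i in range(replicates)}})
    for c in range(1, n_controls + 1):
        start = nb(mean_count, replicates)
        final = nb(mean_count, replicates)
        rows.append({"construct_id": f"{NONTARGETING}_c{c}",
                     "gene": NONTARGETING,
                     **{f"start_{i+1}": int(start[i]) for i in range(replicates)},
                     **{f"final_{i+1}": int(final[i]) for i in range(replicates)}})
    return GRNACountTable(pd.DataFrame(rows))


def generate_psm_table(sites, ambiguity_fraction: float, seed=0,
                       jscore_scale: float = 30.0):
    """PSM records for the given (protein, residue, position) sites.

    Every site receives one well-localized PSM (Lscore gap >= 10 points);
    a fraction of sites additionally receive an ambiguous PSM whose top
    two candidate Lscores differ by <10 points, resolvable through the
    protein-level evidence of the well-localized PSM.  Returns
    ``(psm_list, truth)`` with truth mapping psm_id -> true composite
    site id.
    """
    if not (0.0 <= ambiguity_fraction <= 1.0):
        raise ConfigError("ambiguity_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHILMNQVW"))  # no K/R/P/S/T/Y
    psms, truth = [], {}
    counter = 0
    for prot, res, pos in sites:
        pep = rng.choice(alphabet, size=11)
        pep[5] = res
        decoy_res = "T" if res != "T" else "Y"
        pep[8] = decoy_res
        peptide = "".join(pep)
        start = max(1, pos - 5)
        decoy_pos = start + 8
        counter += 1
        pid = f"psm{counter:05d}"
        psms.append(PSMRecord(pid, peptide, prot,
                              [(res, pos, 95.0), (decoy_res, decoy_pos, 40.0)],
                              jscore=float(rng.gamma(2.0, jscore_scale)),
                              peptide_start=start))
        truth[pid] = site_id(prot, res, pos)
        if rng.random() < ambiguity_fraction:
            counter += 1
            pid = f"psm{counter:05d}"
            psms.append(PSMRecord(pid, peptide, prot,
                                  [(res, pos, 52.0),
                                   (decoy_res, decoy_pos, 48.0)],
                                  jscore=float(rng.gamma(2.0, jscore_scale)),
                                  peptide_start=start))
            truth[pid] = site_id(prot, res, pos)
    return psms, truth


def generate_study(config: StudyConfig | None = None, seed=0) -> SyntheticStudy:
    """Generate the full synthetic study; identical seeds give identical
    studies."""
    cfg = config or StudyConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    design = SampleDesign.from_groups(cfg.group_sizes)
    groups = list(design.group_names)
    n_samp = len(design.sample_ids)
    patterns = group_patterns(design, cfg.n_clusters)

    genes = [f"G{i:04d}" for i in range(1, cfg.n_transcripts + 1)]
    prot_genes = genes[:cfg.n_proteins]
    tf_names = [f"TF{i:02d}" for i in range(1, cfg.n_tfs + 1)]
    kin_names = [f"KIN{i:02d}" for i in range(1, cfg.n_kinases + 1)]

    # ---- gene-block allocation (indices into `genes`) -------------------
    cluster_block = 0                       # 5 x cluster_size
    tf_block = cfg.n_clusters * cfg.cluster_size
    conv_block = tf_block + cfg.n_tfs * cfg.targets_per_tf
    psite_block = 1000                      # phospho-cluster site parents
    ksite_block = 1300                      # kinase-substrate site parents
    path_block = 1600                       # pathway functional-site parents
    bg_block = path_block + cfg.n_pathway_proteins
    if conv_block + cfg.n_convergent > psite_block:
        raise ConfigError("gene blocks overlap; increase n_proteins")

    # ---- ground-truth assignments --------------------------------------
    prot_clusters = {}
    cluster_effects = {}
    for c in range(cfg.n_clusters):
        label = f"WP-C{c+1}"
        cluster_effects[label] = dict(
            zip(groups, cfg.cluster_effect * patterns[c]))
        for i in range(cfg.cluster_size):
            prot_clusters[genes[cluster_block + c * cfg.cluster_size + i]] = c + 1

    tf_targets = {}
    for t, tf in enumerate(tf_names):
        lo = tf_block + t * cfg.targets_per_tf
        tf_targets[tf] = genes[lo:lo + cfg.targets_per_tf]
    active_tfs = tf_names[:cfg.n_active_tfs]
    tf_pattern_idx = {tf: t % cfg.n_clusters for t, tf in enumerate(active_tfs)}

    convergent = genes[conv_block:conv_block + cfg.n_convergent]

    active_kin = kin_names[:cfg.n_active_kinases]
    kin_pattern_idx = {k: i % cfg.n_clusters for i, k in enumerate(active_kin)}
    # two small-substrate kinases rescued by upstream partners sharing
    # their activity pattern
    rescued = {}
    if cfg.n_active_kinases >= 4:
        rescued = {active_kin[-1]: active_kin[0], active_kin[-2]: active_kin[1]}
        for down, up in rescued.items():
            kin_pattern_idx[down] = kin_pattern_idx[up]

    # planted kinase activities (kinase x sample)
    A = np.zeros((cfg.n_kinases, n_samp))
    for i, k in enumerate(kin_names):
        if k in kin_pattern_idx:
            A[i] = cfg.kinase_effect * _expand(
                patterns[kin_pattern_idx[k]], design) \
                + rng.normal(0.0, cfg.kinase_jitter, n_samp)
    kinase_activity = pd.DataFrame(A, index=kin_names,
                                   columns=list(design.sample_ids))

    tf_act = np.zeros((cfg.n_tfs, n_samp))
    for t, tf in enumerate(tf_names):
        if tf in tf_pattern_idx:
            tf_act[t] = cfg.tf_effect * _expand(
                patterns[tf_pattern_idx[tf]], design)
    tf_activity = pd.DataFrame(tf_act, index=tf_names,
                               columns=list(design.sample_ids))

    # ---- proteome -------------------------------------------------------
    prot_features = prot_genes + tf_names + kin_names
    n_pf = len(prot_features)
    base_prot = rng.normal(20.0, 1.5, n_pf)
    eff = np.zeros((n_pf, n_samp))
    fidx = {f: i for i, f in enumerate(prot_features)}
    for g, c in prot_clusters.items():
        eff[fidx[g]] += cfg.cluster_effect * _expand(patterns[c - 1], design)
    for tf in active_tfs:
        shift = tf_activity.loc[tf].to_numpy()
        for g in tf_targets[tf]:
            eff[fidx[g]] += shift
        eff[fidx[tf]] += cfg.tf_protein_effect * _expand(
            patterns[tf_pattern_idx[tf]], design)
    conv_prot = _expand_levels(cfg.convergent_protein_levels, groups, design)
    for g in convergent:
        eff[fidx[g]] += conv_prot
    prot_log2 = base_prot[:, None] + eff \
        + rng.normal(0.0, cfg.noise_sd, (n_pf, n_samp))
    proteome = OmicsMatrix(
        "proteome",
        pd.DataFrame(2.0 ** prot_log2, index=prot_features,
                     columns=list(design.sample_ids)),
        design)

    # ---- phosphoproteome -------------------------------------------------
    site_ids, site_vals = [], []
    ph_clusters = {}

    def add_site(sid, parent, extra):
        site_ids.append(sid)
        site_vals.append(prot_log2[fidx[parent]] + extra)

    # planted phospho coexpression clusters
    for c in range(cfg.n_clusters):
        for i in range(cfg.cluster_size):
            parent = genes[psite_block + c * cfg.cluster_size + i]
            sid = site_id(parent, "S", 100)
            add_site(sid, parent,
                     cfg.cluster_effect * _expand(patterns[c], design))
            ph_clusters[sid] = c + 1

    # kinase-substrate sites
    ks_rows = []
    n_sub = rng.integers(cfg.min_substrates, cfg.max_substrates + 1,
                         cfg.n_kinases)
    next_parent = ksite_block
    kin_row = {k: i for i, k in enumerate(kin_names)}
    for k in kin_names:
        m = 2 if k in rescued else int(n_sub[kin_row[k]])
        for _ in range(m):
            parent = genes[next_parent]
            next_parent += 1
            sid = site_id(parent, "S", 200)
            add_site(sid, parent, A[kin_row[k]])
            ks_rows.append({"regulator": k, "target": parent, "site": "S200"})
    # upstream-rescue edges: site on the downstream kinase protein driven
    # by the upstream kinase's activity
    for down, up in rescued.items():
        sid = site_id(down, "S", 10)
        add_site(sid, down, A[kin_row[up]])
        ks_rows.append({"regulator": up, "target": down, "site": "S10"})

    # pathway functional sites planting the activity ratio
    path_parents = genes[path_block:path_block + cfg.n_pathway_proteins]
    lo, hi = cfg.pathway_site_shift
    mags = rng.uniform(lo, hi, cfg.n_pathway_proteins)
    signs = np.ones(cfg.n_pathway_proteins, dtype=int)
    signs[:cfg.n_negative_sites] = -1
    func_rows, func_sign = [], {}
    gi = {g: i for i, g in enumerate(groups)}
    for j, parent in enumerate(path_parents):
        sid = site_id(parent, "S", 300)
        shift_groups = np.zeros(len(groups))
        shift_groups[gi[PDGFRA]] = signs[j] * mags[j]
        shift_groups[gi[NTRK]] = cfg.pathway_ratio * signs[j] * mags[j]
        add_site(sid, parent, _expand(shift_groups, design))
        func_rows.append({"regulator": parent, "target": "curated",
                          "site": "S300", "sign": int(signs[j])})
        func_sign[sid] = int(signs[j])

    # TF activation sites (phospho-validated TFs), driven by a paired
    # active kinase with the same coactivation pattern
    activation_sites = {}
    phospho_validated = []
    gi0 = {g: i for i, g in enumerate(groups)}
    tumor_up = [c for c in range(cfg.n_clusters)
                if patterns[c][gi0[PDGFRA]] > patterns[c][gi0[CORTEX]]
                and patterns[c][gi0[NTRK]] > patterns[c][gi0[CORTEX]]]
    candidates = [tf for tf in active_tfs if tf_pattern_idx[tf] in tumor_up]
    for tf in candidates[:5]:
        partner = [k for k in active_kin
                   if kin_pattern_idx[k] == tf_pattern_idx[tf]
                   and k not in rescued][0]
        sid = site_id(tf, "S", 62)
        add_site(sid, tf, A[kin_row[partner]])
        ks_rows.append({"regulator": partner, "target": tf, "site": "S62"})
        activation_sites[tf] = ["S62"]
        phospho_validated.append(tf)

    # background sites to reach n_sites
    n_bg = cfg.n_sites - len(site_ids)
    bg_parents = rng.choice(prot_genes, size=n_bg, replace=True)
    offsets = rng.normal(0.0, 0.5, n_bg)
    for i in range(n_bg):
        sid = site_id(str(bg_parents[i]), "S", 400 + i)
        add_site(sid, str(bg_parents[i]), offsets[i])

    ph_log2 = np.asarray(site_vals) \
        + rng.normal(0.0, cfg.noise_sd, (len(site_ids), n_samp))
    phospho = OmicsMatrix(
        "phosphoproteome",
        pd.DataFrame(2.0 ** ph_log2, index=site_ids,
                     columns=list(design.sample_ids)),
        design)

    # ---- transcriptome ---------------------------------------------------
    base_tx = rng.normal(3.0, 1.5, cfg.n_transcripts)
    tidx = {g: i for i, g in enumerate(genes)}
    for g in convergent:
        base_tx[tidx[g]] = rng.normal(3.0, 1.0)
    tx_eff = np.zeros((cfg.n_transcripts, n_samp))
    for tf in active_tfs:
        shift = tf_activity.loc[tf].to_numpy()
        for g in tf_targets[tf]:
            tx_eff[tidx[g]] += shift
    conv_tx = _expand_levels(cfg.convergent_transcript_levels, groups, design)
    for g in convergent:
        tx_eff[tidx[g]] += conv_tx
    tx_log2 = base_tx[:, None] + tx_eff \
        + rng.normal(0.0, cfg.noise_sd, (cfg.n_transcripts, n_samp))
    transcriptome = OmicsMatrix(
        "transcriptome",
        pd.DataFrame(2.0 ** tx_log2, index=genes,
                     columns=list(design.sample_ids)),
        design)

    # ---- relationship tables --------------------------------------------
    ks_map = RelationMap("kinase_substrate", pd.DataFrame(ks_rows))
    tf_rows = [{"regulator": tf, "target": g, "site": None}
               for tf in tf_names for g in tf_targets[tf]]
    tf_map = RelationMap("tf_target", pd.DataFrame(tf_rows))
    func_map = RelationMap("functional_sites", pd.DataFrame(func_rows))

    # ---- human cohort & orthology ---------------------------------------
    h_labels = {}
    h_cols = []
    for grp, n in cfg.human_cases.items():
        for i in range(1, n + 1):
            sid = f"hs_{grp}_{i}"
            h_cols.append(sid)
            h_labels[sid] = grp
    h_genes = [f"HS_{g}" for g in genes]
    h_base = rng.normal(3.0, 1.5, cfg.n_transcripts)
    for g in convergent:
        h_base[tidx[g]] = rng.normal(3.0, 1.0)
    h_log2 = h_base[:, None] + rng.normal(
        0.0, cfg.human_noise_sd, (cfg.n_transcripts, len(h_cols)))
    conv_idx = [tidx[g] for g in convergent]
    ntrk_cols = [j for j, s in enumerate(h_cols) if h_labels[s] == NTRK]
    for j in ntrk_cols:
        h_log2[conv_idx, j] += cfg.human_shift
    human_fpkm = pd.DataFrame(2.0 ** h_log2, index=h_genes, columns=h_cols)
    orthology = OrthologyMap(tuple(zip(genes, h_genes)))

    # ---- CRISPR screen ----------------------------------------------------
    masters = (active_kin[:3] + active_tfs[:2] + active_kin[3:5]
               + active_tfs[2:4])[:9]
    screen_genes = masters + convergent[:6]
    essential = active_kin[:3] + active_tfs[:2] + convergent[:1]
    grna = generate_grna_screen(
        screen_genes, essential, dropout_fold=cfg.crispr_dropout_fold,
        dispersion=cfg.crispr_dispersion, replicates=cfg.crispr_replicates,
        mean_count=cfg.crispr_mean_count,
        seed=int(rng.integers(0, 2**31 - 1)))

    # ---- PSM table --------------------------------------------------------
    psm_sites = [(genes[psite_block + i], "S", 100)
                 for i in range(min(cfg.n_psm_sites,
                                    cfg.n_clusters * cfg.cluster_size))]
    psms, psm_truth = generate_psm_table(
        psm_sites, cfg.psm_ambiguity_fraction,
        seed=int(rng.integers(0, 2**31 - 1)))

    truth = GroundTruth(
        proteome_clusters=prot_clusters,
        phospho_clusters=ph_clusters,
        group_effects=cluster_effects,
        kinase_activity=kinase_activity,
        active_kinases=active_kin,
        rescued_kinases=rescued,
        tf_activity=tf_activity,
        active_tfs=active_tfs,
        phospho_validated_tfs=phospho_validated,
        tf_targets=tf_targets,
        functional_sign=func_sign,
        pathway_proteins=path_parents,
        planted_pathway_ratio=cfg.pathway_ratio,
        convergent_genes=convergent,
        essential_genes=essential,
        psm_true_sites=psm_truth,
    )
    return SyntheticStudy(design, proteome, phospho, transcriptome, ks_map,
                          tf_map, func_map, activation_sites, grna,
                          human_fpkm, h_labels, orthology, psms, truth)


def _expand_levels(levels, groups, design) -> np.ndarray:
    """(cortex, PDGFRA, NTRK) level triple -> per-sample vector."""
    lut = {CORTEX: levels[0], PDGFRA: levels[1], NTRK: levels[2]}
    return np.array([lut[g] for g in design.groups], dtype=float)
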