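"""Coactivation-consistent signaling network assembly.

An edge between two regulators is accepted only when every required
evidence layer shows the same ordering of group means across sample groups
(e.g. NTRK > PDGFRA > cortex for regulator activity, for the
phosphorylation of the connecting site, and for downstream target
transcripts).  This turns the manual network-curation rule into a
reproducible criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RelationMap, SampleDesign, parse_site_id, site_id


@dataclass(frozen=True)
class CoactivationPattern:
    """Ordering of group means, highest first, with the minimal adjacent gap."""

    ordering: tuple
    margin: float
    ambiguous: bool = False

    def matches(self, other: "CoactivationPattern") -> bool:
        return (not self.ambiguous and not other.ambiguous
                and self.ordering == other.ordering)


def pattern_of(values, design: SampleDesign, margin_min: float = 0.0
               ) -> CoactivationPattern:
    """Group-mean ordering of one per-sample profile.

    ``values`` is indexed by sample id (Series or array in design order).
    Adjacent group means closer than ``margin_min`` (or exactly tied) flag
    the pattern ambiguous.
    """
    if not isinstance(values, pd.Series):
        values = pd.Series(np.asarray(values, dtype=float),
                           index=list(design.sample_ids))
    means = {g: float(values[design.samples_of(g)].mean())
             for g in design.group_names}
    ordering = tuple(sorted(means, key=lambda g: -means[g]))
    sorted_means = [means[g] for g in ordering]
    gaps = [sorted_means[i] - sorted_means[i + 1]
            for i in range(len(sorted_means) - 1)]
    margin = min(gaps) if gaps else 0.0
    ambiguous = any(g <= margin_min for g in gaps)
    return CoactivationPattern(ordering, margin, ambiguous)


@dataclass
class NetworkEdge:
    source: str
    target: str
    edge_type: str  # kinase_kinase_direct | kinase_kinase_indirect |
                    # kinase_tf_phospho | tf_target_transcription
    evidence: dict = field(default_factory=dict)


def _kinase_site_edges(ks_map: RelationMap, targets) -> dict:
    """(kinase, target) -> list of sites, for targets in the given set."""
    out = {}
    tgt = set(targets)
    for _, row in ks_map.edges.iterrows():
        if row["target"] in tgt:
            out.setdefault((row["regulator"], row["target"]), []).append(row["site"])
    return out


def build_kinase_kinase(patterns: dict, ks_map: RelationMap,
                        max_indirect_len: int = 2) -> list:
    """Kinase-to-kinase edges among accepted kinases.

    ``patterns`` maps accepted kinase -> CoactivationPattern.  A direct
    edge requires a kinase->kinase substrate-site relation and matching
    patterns; an indirect edge connects two kinases through one accepted
    intermediate when no direct edge exists.
    """
    kinases = sorted(patterns)
    site_edges = _kinase_site_edges(ks_map, kinases)
    direct = []
    direct_pairs = set()
    for (a, b), sites in sorted(site_edges.items()):
        if a in patterns and b in patterns and a != b:
            if patterns[a].matches(patterns[b]):
                direct.append(NetworkEdge(a, b, "kinase_kinase_direct",
                                          {"sites": sorted(filter(None, sites))}))
                direct_pairs.add((a, b))
    indirect = []
    for a, x in sorted(direct_pairs):
        for x2, b in sorted(direct_pairs):
            if x2 == x and b != a and (a, b) not in direct_pairs:
                if patterns[a].matches(patterns[b]):
                    indirect.append(NetworkEdge(a, b, "kinase_kinase_indirect",
                                                {"via": x}))
    return direct + indirect


def build_kinase_tf(kinase_patterns: dict, tf_ids, ks_map: RelationMap,
                    phospho, tf_targets: RelationMap, transcriptome,
                    margin_min: float = 0.0) -> list:
    """Kinase->TF edges accepted on three-layer coactivation agreement.

    Requires (a) the kinase activity pattern, (b) the phosphorylation
    pattern of the kinase's site on the TF, and (c) the mean transcript
    pattern of the TF's targets, to share the same ordering.  ``phospho``
    and ``transcriptome`` are OmicsMatrix layers (phospho un-normalized or
    normalized; the site profile is looked up by composite id).
    """
    ph = phospho.require_log2()
    tx = transcriptome.require_log2()
    design = ph.design
    accepted = []
    tf_set = set(tf_ids)
    site_edges = _kinase_site_edges(ks_map, tf_set)
    for (kin, tf), sites in sorted(site_edges.items()):
        if kin not in kinase_patterns:
            continue
        kpat = kinase_patterns[kin]
        for site in sorted(filter(None, sites)):
            # relation tables carry residue+position (e.g. "S686"); the
            # phospho layer indexes composite ids ("BRCA1_S686")
            sid = site if site in ph.data.index else f"{tf}_{site}"
            if sid not in ph.data.index:
                continue
            spat = pattern_of(ph.data.loc[sid], design, margin_min)
            if not kpat.matches(spat):
                continue
            tgts = [t for t in tf_targets.targets_of(tf)["target"]
                    if t in tx.data.index]
            if not tgts:
                continue
            mean_tx = tx.data.loc[tgts].mean(axis=0)
            tpat = pattern_of(mean_tx, tx.design, margin_min)
            if kpat.matches(tpat):
                accepted.append(NetworkEdge(kin, tf, "kinase_tf_phospho",
                                            {"site": sid,
                                             "ordering": kpat.ordering,
                                             "n_targets": len(tgts)}))
                break
    return accepted


def edges_to_frame(edges: list) -> pd.DataFrame:
    rows = [{"source": e.source, "target": e.target, "edge_type": e.edge_type,
             **{k: (";".join(map(str, v)) if isinstance(v, (list, tuple))
                    else v) for k, v in e.evidence.items()}}
            for e in edges]
    return pd.DataFrame(rows)
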