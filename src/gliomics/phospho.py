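"""Phosphosite localization handling and protein-level normalization.

A phosphopeptide spectrum match (PSM) carries a localization score
(Lscore, 0-100) for each candidate residue.  When the top two candidates
are close (<10 percentage points apart) the assignment is ambiguous and is
resolved by borrowing evidence from better-localized PSMs on the same
protein, then by a heuristic residue order (SP motif, S, T, Y), and
finally by the search-engine score (Jscore) of the supporting PSMs.

Kinase-activity work additionally requires removing the contribution of
substrate protein abundance from site intensities, done here by per-sample
log2 subtraction of the parent protein profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DataError, OmicsMatrix, site_id

logger = logging.getLogger("gliomics")

AMBIGUITY_GAP = 10.0  # percentage points between top two PSM Lscores


@dataclass
class PSMRecord:
    """One phosphopeptide-spectrum match with candidate site localizations.

    ``candidate_sites`` is a list of ``(residue, protein_position, lscore)``
    with residue in S/T/Y; ``peptide_start`` is the 1-based protein position
    of the first peptide residue, used to test the SP motif on the peptide.
    """

    psm_id: str
    peptide: str
    protein_id: str
    candidate_sites: list
    jscore: float = 0.0
    peptide_start: int = 1

    def __post_init__(self):
        if not self.candidate_sites:
            raise DataError(f"PSM {self.psm_id}: no candidate sites")
        for res, pos, ls in self.candidate_sites:
            if res not in "STY":
                raise DataError(f"PSM {self.psm_id}: residue {res!r} not S/T/Y")
            if not (0.0 <= ls <= 100.0):
                raise DataError(f"PSM {self.psm_id}: Lscore {ls} outside [0,100]")


@dataclass
class SiteAssignment:
    protein_id: str
    position: int
    residue: str
    protein_lscore: float
    resolution_rule: str  # unambiguous | protein_evidence | heuristic_order | jscore_rank

    @property
    def site(self) -> str:
        return site_id(self.protein_id, self.residue, self.position)


def aggregate_protein_lscore(psms) -> dict:
    """Max PSM Lscore per (protein, residue, position) across all PSMs."""
    out: dict = {}
    for psm in psms:
        for res, pos, ls in psm.candidate_sites:
            key = (psm.protein_id, res, int(pos))
            if ls > out.get(key, -1.0):
                out[key] = ls
    return out


def _is_sp(psm: PSMRecord, pos: int) -> bool:
    """True when the protein position holds an S immediately followed by P
    within the identified peptide."""
    i = pos - psm.peptide_start  # 0-based index into the peptide
    return (0 <= i < len(psm.peptide) - 1 and psm.peptide[i] == "S"
            and psm.peptide[i + 1] == "P")


_RESIDUE_ORDER = {"S": 1, "T": 2, "Y": 3}


def resolve_site(psm: PSMRecord, protein_evidence: dict | None = None,
                 peer_jscores: dict | None = None) -> SiteAssignment:
    """Assign one site to a PSM following the ambiguity-resolution rules.

    (i) a clear Lscore winner (gap >= 10 points) is taken as-is;
    (ii) otherwise the candidate with the strongest protein-level Lscore
    evidence wins; (iii) otherwise a heuristic order SP-motif > S > T > Y;
    remaining ties are ranked by the Jscore of the best supporting PSM
    (``peer_jscores`` maps (residue, position) -> best Jscore), and last by
    residue position.
    """
    protein_evidence = protein_evidence or {}
    cands = sorted(psm.candidate_sites, key=lambda c: -c[2])
    res, pos, top = cands[0]
    if len(cands) == 1 or top - cands[1][2] >= AMBIGUITY_GAP:
        ls = protein_evidence.get((psm.protein_id, res, int(pos)), top)
        return SiteAssignment(psm.protein_id, int(pos), res, max(ls, top),
                              "unambiguous")

    tied = [c for c in cands if top - c[2] < AMBIGUITY_GAP]
    ev = [protein_evidence.get((psm.protein_id, r, int(p)), 0.0)
          for r, p, _ in tied]
    best = max(ev)
    winners = [c for c, e in zip(tied, ev) if e == best]
    if best > 0 and len(winners) == 1:
        r, p, _ = winners[0]
        return SiteAssignment(psm.protein_id, int(p), r, best, "protein_evidence")

    # heuristic order on the remaining candidates
    def priority(c):
        r, p, _ = c
        return 0 if _is_sp(psm, int(p)) else _RESIDUE_ORDER[r]

    winners = winners if best > 0 else tied
    best_pri = min(priority(c) for c in winners)
    winners = [c for c in winners if priority(c) == best_pri]
    if len(winners) == 1:
        r, p, _ = winners[0]
        ls = protein_evidence.get((psm.protein_id, r, int(p)), winners[0][2])
        return SiteAssignment(psm.protein_id, int(p), r, ls, "heuristic_order")

    peer_jscores = peer_jscores or {}
    scored = sorted(winners,
                    key=lambda c: (-peer_jscores.get((c[0], int(c[1])),
                                                     psm.jscore), int(c[1])))
    r, p, _ = scored[0]
    ls = protein_evidence.get((psm.protein_id, r, int(p)), scored[0][2])
    return SiteAssignment(psm.protein_id, int(p), r, ls, "jscore_rank")


def resolve_all(psms) -> list:
    """Resolve every PSM using protein-level evidence pooled from the batch."""
    evidence = aggregate_protein_lscore(
        [p for p in psms if len(p.candidate_sites) == 1
         or (sorted(ls for _, _, ls in p.candidate_sites)[-1]
             - sorted(ls for _, _, ls in p.candidate_sites)[-2]) >= AMBIGUITY_GAP])
    peer = {}
    for p in psms:
        for res, pos, _ in p.candidate_sites:
            key = (res, int(pos))
            if p.jscore > peer.get(key, -np.inf):
                peer[key] = p.jscore
    return [resolve_site(p, evidence, peer) for p in psms]


def normalize_phospho(phospho: OmicsMatrix, proteome: OmicsMatrix
                      ) -> tuple[OmicsMatrix, list]:
    """Subtract parent-protein log2 abundance from each site profile.

    Site feature ids are ``PROTEIN_S123``.  Sites whose parent protein is
    absent from the proteome are passed through unchanged and returned in
    the flagged list.
    """
    ph = phospho.require_log2()
    pr = proteome.require_log2()
    parents = phospho.data.index.to_series().str.rsplit("_", n=1).str[0]
    has_parent = parents.isin(pr.data.index)
    flagged = list(parents.index[~has_parent])
    out = ph.data.copy()
    if has_parent.any():
        parent_vals = pr.data.loc[parents[has_parent].to_numpy()].to_numpy()
        out.loc[has_parent] = ph.data.loc[has_parent].to_numpy() - parent_vals
    if flagged:
        logger.info("normalize_phospho: %d sites without parent protein",
                    len(flagged))
    norm = OmicsMatrix("phosphoproteome", out, ph.design, scale="log2")
    return norm, flagged
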