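"""Proteome depth estimation by in-silico tryptic digestion.

Theoretically observable ("proteotypic") peptides are the fully tryptic
peptides (cleavage after K/R except before P, up to two missed cleavages)
of at least seven residues whose monoisotopic mass and mean Kyte-Doolittle
hydropathy fall in the detectable windows and whose parent gene is
expressed (FPKM > 1).  Coverage statistics compare identified peptides to
this observable space, residue by residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils import molecular_weight
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

logger = logging.getLogger("gliomics")

MAX_MISSED = 2
MIN_LENGTH = 7
DEFAULT_MASS_RANGE = (700.0, 5000.0)      # Da, typical MS-observable window
DEFAULT_HYDROPATHY_RANGE = (-2.0, 2.0)    # mean Kyte-Doolittle index


@dataclass(frozen=True)
class DigestPeptide:
    protein_id: str
    start: int          # 1-based, inclusive
    end: int            # 1-based, inclusive
    sequence: str
    missed_cleavages: int
    monoisotopic_mass: float | None
    hydropathy_index: float | None
    flagged: bool = False   # non-standard residue: mass/hydropathy omitted

    def __len__(self):
        return len(self.sequence)


def _cleavage_points(seq: str) -> list:
    """0-based indices after which trypsin cleaves (K/R not before P)."""
    return [i for i in range(len(seq) - 1)
            if seq[i] in "KR" and seq[i + 1] != "P"]


def _peptide(protein_id: str, seq: str, start0: int, end0: int,
             missed: int) -> DigestPeptide:
    pep = seq[start0:end0]
    nonstandard = any(a not in KYTE_DOOLITTLE for a in pep)
    if nonstandard:
        logger.info("digest: peptide with non-standard residue flagged (%s)",
                    protein_id)
        mass = hydro = None
    else:
        mass = molecular_weight(pep, seq_type="protein", monoisotopic=True)
        hydro = float(np.mean([KYTE_DOOLITTLE[a] for a in pep]))
    return DigestPeptide(protein_id, start0 + 1, end0, pep, missed, mass,
                         hydro, flagged=nonstandard)


def tryptic_digest(protein_id: str, sequence: str,
                   max_missed: int = MAX_MISSED) -> list:
    """All fully tryptic peptides with up to ``max_missed`` missed cleavages."""
    seq = sequence.upper()
    cuts = _cleavage_points(seq)
    boundaries = [0] + [c + 1 for c in cuts] + [len(seq)]
    peptides = []
    n_frag = len(boundaries) - 1
    for i in range(n_frag):
        for missed in range(min(max_missed, n_frag - 1 - i) + 1):
            start0, end0 = boundaries[i], boundaries[i + 1 + missed]
            peptides.append(_peptide(protein_id, seq, start0, end0, missed))
    return peptides


def proteotypic_filter(peptides, detected_transcripts,
                       mass_range=DEFAULT_MASS_RANGE,
                       hydropathy_range=DEFAULT_HYDROPATHY_RANGE,
                       min_length: int = MIN_LENGTH) -> list:
    """Observable peptides: length, mass window, hydropathy window, and
    expressed parent transcript (FPKM > 1 upstream)."""
    detected = set(detected_transcripts)
    out = []
    for p in peptides:
        if len(p) < min_length or p.protein_id not in detected:
            continue
        if p.monoisotopic_mass is None or p.hydropathy_index is None:
            continue
        if not (mass_range[0] <= p.monoisotopic_mass <= mass_range[1]):
            continue
        if not (hydropathy_range[0] <= p.hydropathy_index
                <= hydropathy_range[1]):
            continue
        out.append(p)
    return out


def coverage_stats(identified, observable, protein_lengths: dict) -> dict:
    """Residue-level coverage of the observable space per protein.

    coverage(protein) = |residues in identified AND observable peptides| /
    |residues in observable peptides|.  Proteins with no observable
    peptide are excluded from the mean (undefined coverage).  Also returns
    the peptides-per-protein counts and the fraction of identified
    proteins supported by >=2 identified peptides.
    """
    def residue_sets(peps):
        sets: dict = {}
        for p in peps:
            sets.setdefault(p.protein_id, set()).update(
                range(p.start, p.end + 1))
        return sets

    obs = residue_sets(observable)
    ident = residue_sets(identified)
    coverage = {}
    for prot in protein_lengths:
        if prot not in obs or not obs[prot]:
            continue
        covered = len(ident.get(prot, set()) & obs[prot])
        coverage[prot] = covered / len(obs[prot])
    pep_counts: dict = {}
    for p in identified:
        pep_counts[p.protein_id] = pep_counts.get(p.protein_id, 0) + 1
    n_ident = len(pep_counts)
    frac_two = (sum(1 for n in pep_counts.values() if n >= 2) / n_ident
                if n_ident else 0.0)
    mean_cov = float(np.mean(list(coverage.values()))) if coverage else 0.0
    return {"coverage_by_protein": coverage,
            "mean_coverage": mean_cov,
            "peptides_per_protein": pep_counts,
            "fraction_proteins_ge2_peptides": frac_two}
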