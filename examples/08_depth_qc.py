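"""Proteome depth estimation by in-silico tryptic digestion.

Theoretically observable peptides are fully tryptic (no cut before
proline, <= 2 missed cleavages), >= 7 residues, inside mass and
hydropathy windows, on expressed genes; coverage compares identified
peptides to this observable space residue by residue.
"""

import numpy as np

from gliomics.depth import coverage_stats, proteotypic_filter, tryptic_digest

rng = np.random.default_rng(1)
aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
proteins = {f"P{i:02d}": "".join(rng.choice(aas, size=int(rng.integers(80, 300))))
            for i in range(20)}

peptides = [p for pid, seq in proteins.items()
            for p in tryptic_digest(pid, seq, max_missed=2)]
observable = proteotypic_filter(peptides, detected_transcripts=proteins)
print(f"digest: {len(peptides)} peptides; observable: {len(observable)}")

# emulate an experiment identifying ~60% of observable peptides
identified = [p for p in observable if rng.random() < 0.6]
stats = coverage_stats(identified, observable,
                       {pid: len(s) for pid, s in proteins.items()})
print(f"mean coverage of observable sequence: {stats['mean_coverage']:.0%}")
print(f"proteins with >=2 identified peptides: "
      f"{stats['fraction_proteins_ge2_peptides']:.0%}")
# Coverage is reported against the observable space only: proteins with
# no observable peptide are excluded from the mean rather than counted 0.
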