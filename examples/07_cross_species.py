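"""Cross-species convergence: mouse oncogene-responsive genes in humans.

Mouse genes with a strict NTRK > PDGFRA > cortex transcript ordering
(>= 2-fold NTRK over PDGFRA, t-test p <= 0.05) and a consistent proteome
or phosphoproteome change are intersected, through 1:1 orthology, with
human genes higher in NTRK-fusion than PDGFRA-mutant cases.
"""

from gliomics import generate_study
from gliomics.pipeline import run_cross_species, run_de

study = generate_study(seed=1)
tx_de = run_de(study.transcriptome, n_perm=300, seed=1)
pr_de = run_de(study.proteome, n_perm=300, seed=2)
ph_de = run_de(study.phosphoproteome, n_perm=300, seed=3)

out = run_cross_species(study, tx_de, pr_de, ph_de)
planted = set(study.truth.convergent_genes)
recovered = set(out["convergent"]) & planted
print(f"mouse candidates: {len(out['mouse'])}")
print(f"human candidates: {len(out['human'])}")
print(f"convergent: {len(out['convergent'])} "
      f"({len(recovered)}/{len(planted)} planted recovered)")
# The human cohort is small (3 NTRK-fusion vs 8 PDGFRA-mutant cases), so
# the human-side test is the limiting factor for sensitivity.
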