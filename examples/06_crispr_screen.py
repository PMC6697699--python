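"""Dual-gRNA CRISPR dropout screen analysis with the 2-of-3 hit rule.

Counts are CPM-normalized and log2-transformed; each construct's
log2(final/start) replicate ratios are tested one-sided against the
pooled nontargeting controls; a gene is an essential hit when >= 2 of its
3 constructs drop out significantly.
"""

from gliomics.crispr import call_gene_hits, hit_summary
from gliomics.simulate import generate_grna_screen

genes = [f"GENE{i}" for i in range(1, 10)]
essential = genes[:5]   # plant 5 of 9, mirroring a 56% validation rate
table = generate_grna_screen(genes, essential, dropout_fold=8.0, seed=1)

calls = call_gene_hits(table)
for c in sorted(calls, key=lambda c: c.gene):
    status = "HIT" if c.is_hit else "-"
    print(f"{c.gene:>13}: {c.n_significant_down}/3 constructs down  {status}")
summary = hit_summary(calls)
print(f"\nhit fraction: {summary['n_hits']}/{summary['n_targeted']} "
      f"= {summary['hit_fraction']:.0%}")
# The five planted essentials are recovered (56% of targeted genes) and
# the nontargeting pseudo-gene is never eligible as a hit.
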