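"""Coexpression clustering of DE proteins and pathway-module networks.

DE features are clustered on 1 - max(Pearson r, 0) distance with average
linkage, eigengene merging at 0.15, and membership by best eigengene
correlation.  Each cluster is then tested for pathway enrichment
(right-tailed hypergeometric, BH <= 0.05) and enriched pathways are
linked into modules wherever their gene-membership kappa reaches 0.5.
"""

from gliomics import GeneSetCollection, generate_study
from gliomics.enrichment import hypergeometric_enrichment, kappa_link
from gliomics.pipeline import run_coexpression, run_de

study = generate_study(seed=1)
pr_de = run_de(study.proteome, n_perm=300, seed=1)
clusters = run_coexpression(study.proteome, pr_de)
print("recovered clusters:", [(c.cluster_id, len(c.members))
                              for c in clusters])

# build pathway sets from the planted truth: each planted cluster's genes
# split into two overlapping "pathways", plus unrelated decoys
truth = study.truth.proteome_clusters
universe = set(study.proteome.feature_ids)
sets = {}
for k in range(1, 6):
    genes = sorted(g for g, c in truth.items() if c == k)
    sets[f"pathway_C{k}a"] = genes[:45]
    sets[f"pathway_C{k}b"] = genes[15:]
sets["decoy"] = sorted(universe)[-50:]
collection = GeneSetCollection(sets, universe)

enriched = {}
for cl in clusters:
    enriched[cl.cluster_id] = hypergeometric_enrichment(cl.members,
                                                        collection)
    print(f"cluster {cl.cluster_id}: enriched:",
          [e.set_name for e in enriched[cl.cluster_id]])
pooled = [e for res in enriched.values() for e in res]
modules = kappa_link(pooled, collection)
print("kappa-linked modules:", [m.pathway_nodes for m in modules])
# The overlapping a/b pathways of each planted cluster link into one
# module per cluster (kappa >= 0.5); the decoy set never enriches.
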