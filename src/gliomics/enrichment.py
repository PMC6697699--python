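"""Pathway enrichment of coexpression clusters and kappa-linked modules.

Each cluster's members are tested against pathway gene sets with a
right-sided hypergeometric test (equivalently a one-sided Fisher exact
test), Benjamini-Hochberg corrected at q <= 0.05.  Enriched pathways are
then linked into pathway-to-pathway network modules wherever the Cohen's
kappa agreement of their gene memberships reaches 0.5, and modules are the
connected components of that graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneSetCollection
from .differential import adjust_pvalues

KAPPA_CUT = 0.5
Q_CUT = 0.05


@dataclass
class EnrichedPathway:
    set_name: str
    overlap_count: int
    set_size: int
    cluster_size: int
    universe_size: int
    p_hyper: float
    q_value: float = float("nan")
    overlap_genes: frozenset = field(default_factory=frozenset)


def hypergeometric_enrichment(cluster_genes, sets: GeneSetCollection,
                              q_cut: float = Q_CUT) -> list:
    """Right-tail hypergeometric enrichment of one gene list, BH-filtered.

    Returns the pathways with q <= ``q_cut`` sorted by p.
    """
    cluster = set(cluster_genes) & sets.universe
    if not cluster:
        return []
    M = len(sets.universe)
    N = len(cluster)
    rows = []
    for name, members in sets.sets.items():
        K = len(members)
        k = len(cluster & members)
        # P(X >= k) for X ~ Hypergeom(M, K, N)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append(EnrichedPathway(name, k, K, N, M, p,
                                    overlap_genes=frozenset(cluster & members)))
    qs = adjust_pvalues([r.p_hyper for r in rows])
    for r, q in zip(rows, qs):
        r.q_value = float(q)
    kept = [r for r in rows if r.q_value <= q_cut and r.overlap_count > 0]
    return sorted(kept, key=lambda r: (r.p_hyper, r.set_name))


def cohens_kappa(a: set, b: set, universe: set) -> float:
    """Cohen's kappa between two membership indicator vectors over ``universe``."""
    n = len(universe)
    if n == 0:
        return 0.0
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = n - both - only_a - only_b
    po = (both + neither) / n
    pa = (both + only_a) / n
    pb = (both + only_b) / n
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


@dataclass
class PathwayNetworkModule:
    module_id: int
    pathway_nodes: list
    edges: list  # (a, b, kappa)


def kappa_link(enriched: list, sets: GeneSetCollection,
               kappa_cut: float = KAPPA_CUT) -> list:
    """Link enriched pathways by kappa >= cutoff; modules = components.

    The membership universe is the union of genes of the enriched pathways
    themselves, so kappa measures agreement where it matters.  Module ids
    are assigned by decreasing module size then lexicographic node order,
    independent of input order.
    """
    names = sorted(p.set_name for p in enriched)
    if not names:
        return []
    members = {n: set(sets[n]) for n in names}
    union = set().union(*members.values())
    G = nx.Graph()
    G.add_nodes_from(names)
    edges = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            k = cohens_kappa(members[a], members[b], union)
            if k >= kappa_cut:
                G.add_edge(a, b, kappa=k)
                edges.append((a, b, k))
    comps = [sorted(c) for c in nx.connected_components(G)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    out = []
    for mid, nodes in enumerate(comps, start=1):
        mod_edges = [(a, b, k) for a, b, k in edges if a in nodes]
        out.append(PathwayNetworkModule(mid, nodes, mod_edges))
    return out
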