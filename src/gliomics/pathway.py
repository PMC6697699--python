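"""Functional-phosphosite pathway activity a(P) with a bootstrap null.

The statistic summarizes how strongly a pathway's signaling is engaged in
tumors, using only phosphosites whose regulatory role is curated:

    a(P) = sum_{i=1..k} C_i * F_i / sqrt(k)

where k is the number of pathway proteins with annotated functional
phosphosite changes, F_i is the averaged log2 fold change (tumor vs
normal cortex) of the differentially expressed phosphosites of protein i,
and C_i is +1 when phosphorylation of the annotated residue promotes
tumorigenesis and -1 when it inhibits it.  Sites (and proteins) with
conflicting annotations are excluded.  Significance comes from a
bootstrap null: k fold-change values are redrawn (with replacement) from
the fold changes of all quantified phosphorylation events, the C template
is applied, and the p-value is the fraction of 10,000 such replicates
whose a(P) strictly exceeds the observed value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DataError, OmicsMatrix, parse_site_id

logger = logging.getLogger("gliomics")

N_BOOT = 10_000


@dataclass
class PathwayActivityResult:
    pathway_id: str
    group: str
    k: int
    fi: dict                 # protein -> averaged log2FC of its DE sites
    ci: dict                 # protein -> +1/-1
    ci_by_site: dict         # site -> +1/-1
    aP: float
    bootstrap_p: float = float("nan")
    n_boot: int = 0
    excluded_conflicts: list = field(default_factory=list)


def site_signs(functional_sites) -> tuple[dict, list]:
    """Site -> sign from a functional-annotation RelationMap.

    Rows annotate (regulator=protein, site=residue-position, sign).  Sites
    annotated with both signs conflict and are excluded (returned
    separately).
    """
    signs: dict = {}
    conflicts = set()
    for _, row in functional_sites.edges.iterrows():
        sid = f"{row['regulator']}_{row['site']}" if row["site"] \
            else row["regulator"]
        s = int(row["sign"])
        if sid in signs and signs[sid] != s:
            conflicts.add(sid)
        signs[sid] = s
    for sid in conflicts:
        signs.pop(sid, None)
    return signs, sorted(conflicts)


def protein_fi(phospho_de: pd.DataFrame, protein: str, tumor_group: str,
               signs: dict) -> float | None:
    """Averaged log2FC (tumor vs cortex) of the protein's DE functional sites.

    Conflict-annotated sites were already dropped from ``signs``; returns
    None when no non-conflicting DE site remains.
    """
    col_t, col_c = f"mean_{tumor_group}", "mean_cortex"
    vals = []
    for sid in signs:
        prot, _, _ = parse_site_id(sid)
        if prot != protein or sid not in phospho_de.index:
            continue
        row = phospho_de.loc[sid]
        if bool(row["is_de"]):
            vals.append(float(row[col_t] - row[col_c]))
    return float(np.mean(vals)) if vals else None


def compute_aP(fi, ci) -> float:
    """Evaluate a(P) = sum C_i F_i / sqrt(k) exactly."""
    fi = np.asarray(list(fi), dtype=float)
    ci = np.asarray(list(ci), dtype=float)
    if fi.size == 0:
        raise DataError("a(P) undefined for k = 0")
    if fi.shape != ci.shape:
        raise DataError("Fi and Ci must align")
    if not np.isin(ci, [1.0, -1.0]).all():
        raise DataError("Ci must be +1 or -1")
    k = fi.size
    return float((ci * fi).sum() / np.sqrt(k))


def bootstrap_p(aP_observed: float, fi_pool, ci_template, n_boot: int = N_BOOT,
                seed=0) -> float:
    """Bootstrap p-value of an observed a(P).

    Draws k values with replacement from the pool of all quantified
    phospho fold changes, applies the C template, and counts replicates
    strictly exceeding the observed statistic.
    """
    pool = np.asarray(fi_pool, dtype=float)
    ci = np.asarray(list(ci_template), dtype=float)
    k = ci.size
    if pool.size == 0:
        raise DataError("empty fold-change pool")
    if pool.size < k:
        raise DataError("pool smaller than k")
    if n_boot < 100:
        logger.warning("bootstrap_p: n_boot=%d is very small", n_boot)
    rng = np.random.default_rng(seed)
    draws = rng.choice(pool, size=(n_boot, k), replace=True)
    sims = draws @ ci / np.sqrt(k)
    return float((sims > aP_observed).sum() / n_boot)


def pathway_activity(phospho_de: pd.DataFrame, pathway_proteins,
                     functional_sites, tumor_group: str,
                     pathway_id: str = "pathway", n_boot: int = N_BOOT,
                     seed=0) -> PathwayActivityResult:
    """a(P) of one pathway in one tumor group, with its bootstrap p.

    ``phospho_de`` is the phosphoproteome DE table (with group means);
    ``functional_sites`` a RelationMap of kind functional_sites.  Protein
    C_i is the shared sign of its non-conflicting annotated sites; a
    protein whose sites disagree in sign is excluded as conflicted.
    """
    signs, conflict_sites = site_signs(functional_sites)
    proteins = sorted(set(pathway_proteins))
    fi, ci = {}, {}
    excluded = list(conflict_sites)
    for prot in proteins:
        psigns = {sid: s for sid, s in signs.items()
                  if parse_site_id(sid)[0] == prot}
        if not psigns:
            continue
        uniq = set(psigns.values())
        if len(uniq) > 1:
            excluded.extend(sorted(psigns))
            continue
        f = protein_fi(phospho_de, prot, tumor_group, psigns)
        if f is None:
            continue
        fi[prot] = f
        ci[prot] = uniq.pop()
    if not fi:
        raise DataError(f"no contributing proteins for pathway {pathway_id!r}")
    aP = compute_aP(fi.values(), [ci[p] for p in fi])
    pool = (phospho_de[f"mean_{tumor_group}"]
            - phospho_de["mean_cortex"]).to_numpy(dtype=float)
    p = bootstrap_p(aP, pool, [ci[pr] for pr in fi], n_boot=n_boot, seed=seed)
    site_ci = {sid: s for sid, s in signs.items()
               if parse_site_id(sid)[0] in fi}
    return PathwayActivityResult(pathway_id, tumor_group, len(fi), fi, ci,
                                 site_ci, aP, p, n_boot, excluded)


def pathway_activity_ratio(result_a: PathwayActivityResult,
                           result_b: PathwayActivityResult) -> dict:
    """Ratio of pathway activities between two tumor groups (a over b).

    When the denominator a(P) is not positive the ratio is undefined and
    the difference is reported instead.
    """
    out = {"group_a": result_a.group, "group_b": result_b.group,
           "aP_a": result_a.aP, "aP_b": result_b.aP,
           "p_a": result_a.bootstrap_p, "p_b": result_b.bootstrap_p,
           "ratio": float("nan"), "difference": result_a.aP - result_b.aP}
    if result_b.aP > 0:
        out["ratio"] = result_a.aP / result_b.aP
    else:
        logger.warning("pathway_activity_ratio: denominator a(P) <= 0; "
                       "reporting difference only")
    return out
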