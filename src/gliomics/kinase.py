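"""Substrate-driven kinase activity inference.

The phosphorylation of a substrate site, once normalized for substrate
protein abundance, is modeled as the sum of the activities of the kinases
known to phosphorylate it (additive on the log2 scale):

    site_sj  ~  sum_{k in kinases(s)} A_kj  + noise

Per-sample activities A are estimated by gradient descent on the ridge-
penalized squared error, restarted from ten random initializations; the
spread of the restart solutions is the convergence diagnostic (kinases
whose estimates vary by more than 0.2 SD across restarts are considered
non-converged, which in this convex-but-flat problem flags
non-identifiable kinases).  Accepted kinases must additionally have at
least three mapped substrates (or an upstream kinase with a matching
coactivation pattern) and a BH-corrected activity-difference p <= 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import OmicsMatrix, RelationMap, site_id
from .differential import adjust_pvalues
from .network import CoactivationPattern, pattern_of

logger = logging.getLogger("gliomics")

N_RESTARTS = 10
SD_CUT = 0.2
MIN_SUBSTRATES = 3
RIDGE = 1e-6


@dataclass
class ActivityEstimate:
    regulator_id: str
    activity: pd.Series          # per-sample inferred activity
    restart_sd: float
    n_substrates: int
    rescued_by_upstream: bool = False
    p_value: float = float("nan")
    q_value: float = float("nan")
    accepted: bool = False
    pattern: CoactivationPattern | None = None


def _design_matrix(site_index, ks_map: RelationMap):
    """Binary site x kinase incidence over sites present in the data.

    Relation targets may be composite site ids or (target protein, site)
    pairs; both resolve against the phospho index.
    """
    edges = ks_map.edges
    sids = []
    for _, row in edges.iterrows():
        s = row["site"]
        sid = f"{row['target']}_{s}" if s else row["target"]
        sids.append(sid)
    edges = edges.assign(_sid=sids)
    edges = edges[edges["_sid"].isin(site_index)]
    kinases = sorted(edges["regulator"].unique())
    if not kinases:
        return None, [], edges
    site_list = sorted(edges["_sid"].unique())
    srow = {s: i for i, s in enumerate(site_list)}
    kcol = {k: j for j, k in enumerate(kinases)}
    X = np.zeros((len(site_list), len(kinases)))
    for _, row in edges.iterrows():
        X[srow[row["_sid"]], kcol[row["regulator"]]] = 1.0
    return X, (site_list, kinases), edges


def infer_activities(normalized_phospho: OmicsMatrix, ks_map: RelationMap,
                     n_restarts: int = N_RESTARTS, seed=0,
                     max_iter: int = 400, tol: float = 1e-8,
                     ridge: float = RIDGE) -> list:
    """Estimate per-sample activities for every kinase with mapped sites.

    Kinases whose substrate sites are all absent from the data are excluded
    (logged).  Returns :class:`ActivityEstimate` objects with the restart
    spread but no acceptance decision (see :func:`filter_activities`).
    """
    m = normalized_phospho.require_log2()
    X, names, edges = _design_matrix(m.data.index, ks_map)
    dropped = set(ks_map.edges["regulator"]) - (set(names[1]) if names else set())
    if dropped:
        logger.info("infer_activities: %d kinases without observed substrates",
                    len(dropped))
    if X is None:
        return []
    site_list, kinases = names
    Y = m.data.loc[site_list].to_numpy(dtype=float)  # sites x samples
    n_sites, n_kin = X.shape
    n_samp = Y.shape[1]

    # fixed step from the Lipschitz constant of the gradient
    lam = ridge
    L = np.linalg.norm(X, 2) ** 2 + lam
    eta = 1.0 / L

    rng = np.random.default_rng(seed)
    solutions = np.empty((n_restarts, n_kin, n_samp))
    for r in range(n_restarts):
        A = rng.normal(0.0, 1.0, size=(n_kin, n_samp))
        prev = np.inf
        for _ in range(max_iter):
            resid = X @ A - Y
            grad = X.T @ resid + lam * A
            A -= eta * grad
            obj = 0.5 * (resid ** 2).sum() + 0.5 * lam * (A ** 2).sum()
            if prev - obj < tol * max(1.0, prev):
                break
            prev = obj
        solutions[r] = A

    mean_A = solutions.mean(axis=0)
    sds = solutions.std(axis=0).mean(axis=1)  # per-kinase mean over samples
    sub_counts = edges.groupby("regulator")["_sid"].nunique()
    out = []
    for j, k in enumerate(kinases):
        act = pd.Series(mean_A[j], index=m.data.columns)
        out.append(ActivityEstimate(k, act, float(sds[j]),
                                    int(sub_counts.get(k, 0))))
    return out


def activity_significance(estimates: list, design, seed=0) -> None:
    """Per-kinase one-way ANOVA of activity across groups, BH over kinases.

    Fills p_value/q_value in place.
    """
    groups = [design.samples_of(g) for g in design.group_names]
    ps = []
    for est in estimates:
        arrs = [est.activity[g].to_numpy() for g in groups]
        if all(np.ptp(a) == 0 for a in arrs) and len({a.mean() for a in arrs}) == 1:
            ps.append(1.0)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.f_oneway(*arrs)
        ps.append(1.0 if not np.isfinite(p) else float(p))
    qs = adjust_pvalues(ps)
    for est, p, q in zip(estimates, ps, qs):
        est.p_value = float(p)
        est.q_value = float(q)


def filter_activities(estimates: list, ks_map: RelationMap, design,
                      sd_cut: float = SD_CUT,
                      min_substrates: int = MIN_SUBSTRATES,
                      q_cut: float = 0.05,
                      margin_min: float = 0.0) -> list:
    """Convergence, substrate-count (with upstream rescue), and BH filters.

    A kinase with fewer than ``min_substrates`` substrates is rescued only
    if some upstream kinase (one with a substrate site on this kinase) is
    itself accepted and shares the same coactivation ordering.
    """
    if any(np.isnan(e.p_value) for e in estimates):
        activity_significance(estimates, design)
    for est in estimates:
        est.pattern = pattern_of(est.activity, design, margin_min)

    by_id = {e.regulator_id: e for e in estimates}
    upstream: dict = {}
    for _, row in ks_map.edges.iterrows():
        tgt = row["target"]
        if tgt in by_id and row["regulator"] in by_id and row["regulator"] != tgt:
            upstream.setdefault(tgt, set()).add(row["regulator"])

    base_ok = {e.regulator_id: (e.restart_sd <= sd_cut and e.q_value <= q_cut)
               for e in estimates}
    solid = {k for k, e in by_id.items()
             if base_ok[k] and e.n_substrates >= min_substrates}
    accepted = set(solid)
    # single rescue pass: upstream support must itself be solidly accepted
    for k, e in by_id.items():
        if k in accepted or not base_ok[k]:
            continue
        for up in upstream.get(k, ()):
            if up in solid and by_id[up].pattern.matches(e.pattern):
                e.rescued_by_upstream = True
                accepted.add(k)
                break
    for e in estimates:
        e.accepted = e.regulator_id in accepted
    return [e for e in estimates if e.accepted]


@dataclass
class SuperfamilySummary:
    family: str
    n_activated: int
    n_total: int
    fisher_p: float
    chi2_p_by_pair: dict = field(default_factory=dict)
    significant: bool = False


def superfamily_summary(estimates: list, family_map: dict,
                        design=None, p_cut: float = 0.001) -> list:
    """Kinome-superfamily activation summary.

    For each family a 2x2 table (family vs rest x activated vs not) is
    tested by Fisher's exact test; when a design is given, each pair of
    sample groups is additionally compared by chi-square on which group
    each kinase is more active in (family vs rest).  Kinases without a
    family label fall into "other".
    """
    fams = sorted({family_map.get(e.regulator_id, "other") for e in estimates})
    out = []
    for fam in fams:
        in_fam = [e for e in estimates
                  if family_map.get(e.regulator_id, "other") == fam]
        rest = [e for e in estimates
                if family_map.get(e.regulator_id, "other") != fam]
        if not in_fam:
            continue
        a = sum(e.accepted for e in in_fam)
        b = len(in_fam) - a
        c = sum(e.accepted for e in rest)
        d = len(rest) - c
        _, fisher_p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        chi2_ps = {}
        if design is not None and rest:
            gnames = list(design.group_names)
            for i in range(len(gnames)):
                for j in range(i + 1, len(gnames)):
                    g1, g2 = gnames[i], gnames[j]
                    def n_higher(grp, es):
                        return sum(e.activity[design.samples_of(g1)].mean()
                                   > e.activity[design.samples_of(g2)].mean()
                                   for e in es)
                    tab = np.array([[n_higher(g1, in_fam),
                                     len(in_fam) - n_higher(g1, in_fam)],
                                    [n_higher(g1, rest),
                                     len(rest) - n_higher(g1, rest)]])
                    if (tab.sum(axis=1) > 0).all() and (tab.sum(axis=0) > 0).all():
                        _, p, _, _ = stats.chi2_contingency(tab)
                    else:
                        p = 1.0
                    chi2_ps[f"{g1}_vs_{g2}"] = float(p)
        out.append(SuperfamilySummary(fam, int(a), len(in_fam), float(fisher_p),
                                      chi2_ps, fisher_p <= p_cut))
    return out


def substrate_readout(kinase: ActivityEstimate, normalized_phospho: OmicsMatrix,
                      ks_map: RelationMap, margin_min: float = 0.0) -> list:
    """Substrate sites whose group-mean ordering matches the kinase's.

    The shared consistency definition with the network module: identical
    strict ordering of group means.
    """
    m = normalized_phospho.require_log2()
    kpat = kinase.pattern or pattern_of(kinase.activity, m.design, margin_min)
    hits = []
    for _, row in ks_map.targets_of(kinase.regulator_id).iterrows():
        s = row["site"]
        sid = f"{row['target']}_{s}" if s else row["target"]
        if sid not in m.data.index:
            continue
        spat = pattern_of(m.data.loc[sid], m.design, margin_min)
        if kpat.matches(spat):
            hits.append(sid)
    return sorted(hits)
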