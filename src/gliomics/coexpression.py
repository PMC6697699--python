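"""Coexpression clustering of differentially expressed features.

Implements the weighted-coexpression workflow used to reduce DE proteins
and phosphosites to a handful of clusters: a signed Pearson similarity
(negative correlations clipped to zero), average-linkage hierarchical
clustering with a height cut and minimum cluster size, merging of clusters
whose eigengenes (first principal components) are closer than 0.15 in
correlation distance, and final membership assignment of every DE feature
to the cluster whose eigengene it best correlates with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import OmicsMatrix

logger = logging.getLogger("gliomics")

MERGE_HEIGHT = 0.15    # eigengene correlation-distance below which clusters merge
DEFAULT_CUT = 0.5      # tree cut height on the 1 - max(r,0) distance
MIN_SIZE = 30
R_MIN = 0.3            # minimum eigengene correlation for membership


@dataclass
class CoexpressionCluster:
    cluster_id: int
    members: list
    eigengene: pd.Series            # unit-norm, per sample
    member_r: dict = field(default_factory=dict)


def correlation_distance(matrix: OmicsMatrix) -> tuple[pd.DataFrame, list]:
    """1 - max(Pearson r, 0) between features; constant features excluded.

    Returns (distance DataFrame, excluded feature list).
    """
    m = matrix.require_log2()
    X = m.data.to_numpy(dtype=float)
    sd = X.std(axis=1)
    keep = sd > 0
    excluded = list(m.data.index[~keep])
    if excluded:
        logger.info("correlation_distance: excluded %d constant features",
                    len(excluded))
    X = X[keep]
    idx = m.data.index[keep]
    if X.shape[0] <= 1:
        return pd.DataFrame(np.zeros((X.shape[0],) * 2), index=idx,
                            columns=idx), excluded
    r = np.corrcoef(X)
    sim = np.clip(r, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    dist = 1.0 - sim
    return pd.DataFrame(dist, index=idx, columns=idx), excluded


def _eigengene(X: np.ndarray, samples) -> pd.Series:
    """First principal component of the feature-standardized member matrix,
    unit norm, sign oriented so the mean member correlation is positive."""
    Z = (X - X.mean(axis=1, keepdims=True))
    sd = Z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = Z / sd
    # right singular vector of the standardized matrix = PC over samples
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    e = vt[0]
    corr = Z @ e
    if corr.mean() < 0:
        e = -e
    return pd.Series(e / np.linalg.norm(e), index=samples)


def _member_r(matrix: OmicsMatrix, members, eig: pd.Series) -> dict:
    X = matrix.data.loc[members].to_numpy(dtype=float)
    e = eig.to_numpy()
    Xc = X - X.mean(axis=1, keepdims=True)
    ec = e - e.mean()
    denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(ec)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ ec) / denom
    return dict(zip(members, np.nan_to_num(r)))


def cluster_features(matrix: OmicsMatrix, distance: pd.DataFrame,
                     merge_height: float = MERGE_HEIGHT,
                     cut_height: float = DEFAULT_CUT,
                     min_size: int = MIN_SIZE) -> list:
    """Average-linkage clustering with eigengene merging.

    Features ending up in clusters smaller than ``min_size`` are left
    unassigned (cluster 0 by convention, i.e. simply not returned as
    members); clusters whose eigengene correlation distance falls below
    ``merge_height`` are merged.  Cluster ids are renumbered 1..K by
    decreasing size.
    """
    m = matrix.require_log2()
    feats = list(distance.index)
    if len(feats) < 2:
        logger.info("cluster_features: <2 usable features, nothing to cluster")
        return []
    condensed = squareform(distance.to_numpy(), checks=False)
    Z = linkage(condensed, method="average")
    labels = fcluster(Z, t=cut_height, criterion="distance")

    groups = {}
    for f, lab in zip(feats, labels):
        groups.setdefault(lab, []).append(f)
    clusters = [v for v in groups.values() if len(v) >= min_size]
    if not clusters:
        logger.info("cluster_features: no cluster reached min_size=%d", min_size)
        return []

    # iterative eigengene merging at the stated height
    merged = True
    while merged and len(clusters) > 1:
        merged = False
        eigs = [_eigengene(m.data.loc[c].to_numpy(dtype=float),
                           m.data.columns) for c in clusters]
        best = (None, None, merge_height)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = 1.0 - float(np.corrcoef(eigs[i], eigs[j])[0, 1])
                if d < best[2]:
                    best = (i, j, d)
        if best[0] is not None:
            i, j, _ = best
            clusters[i] = clusters[i] + clusters[j]
            del clusters[j]
            merged = True

    clusters.sort(key=len, reverse=True)
    out = []
    for cid, members in enumerate(clusters, start=1):
        eig = _eigengene(m.data.loc[members].to_numpy(dtype=float),
                         m.data.columns)
        out.append(CoexpressionCluster(cid, list(members), eig,
                                       _member_r(m, members, eig)))
    return out


def assign_members(clusters: list, matrix: OmicsMatrix,
                   r_min: float = R_MIN) -> list:
    """Reassign every feature of ``matrix`` to its best-correlated eigengene.

    Features whose best positive correlation is below ``r_min`` stay
    unassigned; exact ties break deterministically toward the smaller
    cluster id (logged).
    """
    if not clusters:
        return clusters
    m = matrix.require_log2()
    X = m.data.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    R = np.zeros((X.shape[0], len(clusters)))
    for k, cl in enumerate(clusters):
        e = cl.eigengene.to_numpy()
        ec = e - e.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            R[:, k] = np.nan_to_num((Xc @ ec) / (norms * np.linalg.norm(ec)))
    best_k = R.argmax(axis=1)
    best_r = R[np.arange(len(X)), best_k]
    ties = (R >= best_r[:, None] - 1e-12).sum(axis=1) > 1
    if ties.any():
        logger.info("assign_members: %d tie(s) broken by cluster id", ties.sum())
    new_members: dict = {k: [] for k in range(len(clusters))}
    for i, f in enumerate(m.data.index):
        if best_r[i] >= r_min:
            new_members[best_k[i]].append((f, best_r[i]))
    out = []
    for k, cl in enumerate(clusters):
        members = [f for f, _ in new_members[k]]
        if not members:
            continue
        eig = cl.eigengene
        out.append(CoexpressionCluster(cl.cluster_id, members, eig,
                                       dict(new_members[k])))
    return out
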