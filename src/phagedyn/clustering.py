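"""Hierarchical clustering of growth-dynamics derivative profiles.

Profiles are compared with the cosine distance 1 - cos(theta), theta being
the angle between two derivative vectors: strains whose populations change
in the same *direction* at the same dimensionless times cluster together
regardless of the magnitude of the change.  An average-linkage tree is cut
at a fixed height (0.16 by default) to define flat clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .curves import DerivativeProfile, NormalizedCurve, CurveError

#: linkage height below which profiles belong to one cluster.
DEFAULT_LINKAGE_CUT = 0.16


class ClusterError(ValueError):
    pass


@dataclass
class ClusterResult:
    """Average-linkage tree plus flat labels at the chosen cut."""

    linkage: np.ndarray          # scipy linkage matrix (n-1, 4)
    labels: np.ndarray           # flat cluster index per profile, 1-based
    threshold: float
    leaf_order: np.ndarray       # dendrogram leaf permutation
    ids: list[str]               # strain_id per profile, input order

    @property
    def n_clusters(self) -> int:
        return int(len(np.unique(self.labels)))


def cosine_profile_distance(p1: DerivativeProfile, p2: DerivativeProfile) -> float:
    """1 - cos(theta) between two profiles on the same grid; in [0, 2]."""
    if len(p1.tau_grid) != len(p2.tau_grid) or not np.allclose(
            p1.tau_grid, p2.tau_grid):
        raise ClusterError("profiles must share one tau grid")
    v1, v2 = p1.dy, p2.dy
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ClusterError("cosine distance undefined for a zero profile")
    cos = float(np.dot(v1, v2) / (n1 * n2))
    return 1.0 - min(1.0, max(-1.0, cos))


def build_clusters(profiles: list[DerivativeProfile],
                   threshold: float = DEFAULT_LINKAGE_CUT) -> ClusterResult:
    """Agglomerative average-linkage clustering on pairwise cosine distances.

    Flat clusters are the subtrees fully merged below ``threshold``.
    Deterministic: identical inputs give identical trees and labels.
    """
    if len(profiles) < 2:
        raise ClusterError("clustering needs at least 2 profiles")
    grid = profiles[0].tau_grid
    for p in profiles[1:]:
        if len(p.tau_grid) != len(grid) or not np.allclose(p.tau_grid, grid):
            raise ClusterError("profiles must share one tau grid")
    X = np.vstack([p.dy for p in profiles])
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        bad = [profiles[i].strain_id for i in np.flatnonzero(norms == 0)]
        raise ClusterError(f"zero derivative profile(s): {bad}")
    D = pdist(X, metric="cosine")
    Z = hierarchy.linkage(D, method="average")
    labels = hierarchy.fcluster(Z, t=threshold, criterion="distance")
    leaf_order = hierarchy.leaves_list(Z)
    return ClusterResult(
        linkage=Z, labels=labels, threshold=threshold,
        leaf_order=leaf_order, ids=[p.strain_id for p in profiles],
    )


def cluster_average(curves: list[NormalizedCurve],
                    result: ClusterResult) -> dict[int, NormalizedCurve]:
    """Pointwise mean normalized curve per flat cluster.

    ``curves`` must align one-to-one with the profiles that were clustered
    (same order).  Curves are interpolated onto the intersection grid of
    each cluster's members.
    """
    if len(curves) != len(result.labels):
        raise ClusterError(
            f"{len(curves)} curves vs {len(result.labels)} cluster labels"
        )
    out: dict[int, NormalizedCurve] = {}
    for lab in np.unique(result.labels):
        members = [c for c, l in zip(curves, result.labels) if l == lab]
        lo = max(c.tau[0] for c in members)
        hi = min(c.tau[-1] for c in members)
        if hi <= lo:
            raise ClusterError(f"cluster {lab} member tau ranges do not overlap")
        grid = np.linspace(lo, hi, max(len(c.tau) for c in members))
        ys = np.vstack([np.interp(grid, c.tau, c.y) for c in members])
        out[int(lab)] = NormalizedCurve(
            tau=grid, y=ys.mean(axis=0),
            strain_id=f"cluster_{lab}", condition=members[0].condition,
        )
    return out


def linkage_to_newick(Z: np.ndarray, ids: list[str]) -> str:
    """Serialize a linkage tree as Newick, branch lengths = height gaps."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def profile_matrix(profiles: list[DerivativeProfile]) -> tuple[list[str], np.ndarray]:
    """(strain ids, profiles-by-grid matrix) — the clustering heatmap data."""
    if not profiles:
        raise ClusterError("no profiles")
    return [p.strain_id for p in profiles], np.vstack([p.dy for p in profiles])
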