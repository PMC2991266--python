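"""Phosphotransfer-profile normalization and two-way hierarchical clustering.

Band intensities are only comparable within one kinase's profile, so each
kinase row is rescaled to percent of its maximally phosphorylated
regulator.  Regulator profiles (columns) are then clustered with
uncentered-correlation distance and kinase profiles (rows) with Euclidean
distance, and the resulting dendrograms are read against sequence features:
when an internal split of the regulator tree coincides exactly with the
allele of one specificity unit, that unit's depth in the tree measures its
contribution to the phosphotransfer profile (the empirical hierarchy
loop > pos1 > pos2 > pos3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .schemes import SpecificityScheme

_LINKAGES = ("single", "complete", "average", "centroid")


@dataclass
class ProfilePanel:
    """Raw and percent-of-max normalized kinase x regulator intensities."""

    raw: pd.DataFrame
    normalized: pd.DataFrame
    zero_rows: list[str]

    @property
    def kinases(self) -> list[str]:
        return list(self.raw.index)

    @property
    def regulators(self) -> list[str]:
        return list(self.raw.columns)


def normalize_profiles(raw: pd.DataFrame) -> ProfilePanel:
    """Scale each kinase row so its maximum is 100 (percent of max).

    All-zero rows (a kinase with no detectable transfer) are left at zero
    and flagged in ``zero_rows``.
    """
    raw = raw.astype(float)
    if (raw.values < 0).any():
        raise ValueError("band intensities must be non-negative")
    rowmax = raw.max(axis=1)
    zero_rows = list(raw.index[rowmax == 0])
    safe = rowmax.replace(0, 1.0)
    normalized = raw.div(safe, axis=0) * 100.0
    return ProfilePanel(raw=raw, normalized=normalized, zero_rows=zero_rows)


def normalize_to_reference(values: pd.Series, reference_key: str) -> pd.Series:
    """Express each value as a percentage of the reference entry (e.g. wild type)."""
    if reference_key not in values.index:
        raise KeyError(f"reference {reference_key!r} absent")
    ref = float(values[reference_key])
    if ref <= 0:
        raise ValueError(f"reference value for {reference_key!r} must be positive, got {ref}")
    return values.astype(float) * 100.0 / ref


def uncentered_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine-type similarity sum(x*y)/sqrt(sum(x^2) sum(y^2)) in [-1, 1].

    Unlike Pearson correlation the means are not subtracted, so two
    profiles that are proportional score 1 regardless of scale.  The
    clustering distance is 1 - similarity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    nx_ = float(np.dot(x, x))
    ny_ = float(np.dot(y, y))
    if nx_ == 0 or ny_ == 0:
        raise ValueError("uncentered correlation undefined for a zero vector")
    return float(np.clip(np.dot(x, y) / np.sqrt(nx_ * ny_), -1.0, 1.0))


def _condensed_distances(data: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return pdist(data, metric="euclidean")
    if metric == "uncentered_correlation":
        norms = np.sqrt((data**2).sum(axis=1))
        if (norms == 0).any():
            raise ValueError("uncentered correlation undefined for a zero profile")
        unit = data / norms[:, None]
        sim = np.clip(unit @ unit.T, -1.0, 1.0)
        dist = 1.0 - sim
        np.fill_diagonal(dist, 0.0)
        return squareform(dist, checks=False)
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class ClusterTree:
    """Agglomerative dendrogram: labels (leaf items), scipy linkage matrix,
    and the metric/linkage used (recorded so results name their method)."""

    labels: list[str]
    linkage_matrix: np.ndarray
    metric: str
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage_matrix)]

    def root(self) -> hierarchy.ClusterNode:
        return hierarchy.to_tree(self.linkage_matrix)

    def to_newick(self) -> str:
        """Newick string; branch length = parent merge height - child height."""

        def walk(node: hierarchy.ClusterNode, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        root = self.root()
        return f"({walk(root.left, root.dist)},{walk(root.right, root.dist)});"


def hierarchical_cluster(
    data: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterTree:
    """Agglomerative clustering of the DataFrame's rows.

    Rows are sorted lexicographically by label before linkage so that ties
    in the agglomeration are broken reproducibly.
    """
    if method not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}, got {method!r}")
    if len(data) < 2:
        raise ValueError("clustering needs at least 2 items")
    data = data.loc[sorted(data.index.astype(str))]
    condensed = _condensed_distances(data.values.astype(float), metric)
    Z = hierarchy.linkage(condensed, method=method)
    return ClusterTree(list(data.index), Z, metric=metric, method=method)


def two_way_cluster(
    panel: ProfilePanel,
    row_metric: str = "euclidean",
    col_metric: str = "uncentered_correlation",
    method: str = "average",
) -> tuple[ClusterTree, ClusterTree]:
    """Cluster kinases (rows, Euclidean) and regulators (columns, uncentered
    correlation) of the normalized panel; returns (kinase_tree, regulator_tree)."""
    kin = hierarchical_cluster(panel.normalized, metric=row_metric, method=method)
    reg = hierarchical_cluster(panel.normalized.T, metric=col_metric, method=method)
    return kin, reg


@dataclass(frozen=True)
class ConcordantSplit:
    depth: int  # 1 = root
    unit_label: str
    left_leaves: tuple[str, ...]
    right_leaves: tuple[str, ...]
    merge_height: float


def split_concordance(
    tree: ClusterTree,
    scheme: SpecificityScheme,
    detailed: bool = False,
):
    """Units whose alleles exactly reproduce dendrogram bipartitions, ordered
    by the depth of the shallowest concordant split.

    Every leaf name must parse as a variant of ``scheme``.  An internal node
    at depth d (root = 1) is concordant with a unit when, among that node's
    leaves, one child holds only start-allele variants and the other only
    target-allele variants for that unit.  Returns the ordered unit labels
    (the empirical specificity hierarchy); with ``detailed=True`` also the
    per-node records.
    """
    vectors = {label: scheme.parse_name(label) for label in tree.labels}

    splits: list[ConcordantSplit] = []

    def leaves(node) -> list[str]:
        return [tree.labels[i] for i in node.pre_order(lambda n: n.id)]

    def walk(node, depth: int) -> None:
        if node.is_leaf():
            return
        left, right = leaves(node.left), leaves(node.right)
        for ui, unit in enumerate(scheme.units):
            lvals = {vectors[name][ui] for name in left}
            rvals = {vectors[name][ui] for name in right}
            if len(lvals) == 1 == len(rvals) and lvals != rvals:
                splits.append(
                    ConcordantSplit(depth, unit.label, tuple(left), tuple(right), node.dist)
                )
        walk(node.left, depth + 1)
        walk(node.right, depth + 1)

    walk(tree.root(), 1)

    first_depth: dict[str, int] = {}
    for s in splits:
        if s.unit_label not in first_depth or s.depth < first_depth[s.unit_label]:
            first_depth[s.unit_label] = s.depth
    order = [
        label
        for label, _ in sorted(
            first_depth.items(), key=lambda kv: (kv[1], scheme.unit_labels().index(kv[0]))
        )
    ]
    if detailed:
        return order, sorted(splits, key=lambda s: (s.depth, s.unit_label))
    return order
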