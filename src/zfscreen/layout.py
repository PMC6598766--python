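"""Structure-driven ordering and display geometry.

Ward clustering of the Tanimoto matrix, dendrogram leaf order, polar
scatter coordinates (angle from dendrogram rank, radius from screen
category), the thresholded similarity network, and cluster extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .chem import SimilarityMatrix
from .triage import Category, TriageRecord

logger = logging.getLogger(__name__)


@dataclass
class DendrogramOrder:
    """Ward linkage (scipy merge-table convention) and its leaf order."""

    linkage: np.ndarray  # (n-1, 4): left, right, height, size
    leaf_order: np.ndarray  # permutation of 0..n-1


@dataclass
class PolarLayout:
    compound_ids: list[str]
    angle: np.ndarray  # radians in [0, 2*pi)
    radius: np.ndarray
    categories: list[Category]
    jitter_seed: int


@dataclass
class SimilarityNetwork:
    graph: nx.Graph
    threshold: float


def ward_cluster(m: SimilarityMatrix) -> DendrogramOrder:
    """Agglomerative Ward clustering on distance d = 1 - similarity.

    Leaf order is the plain left-to-right dendrogram traversal (no
    optimal-leaf-ordering post-pass). Ward heights are expected to be
    non-decreasing; any inversion is logged.
    """
    n = m.n
    if n == 0:
        raise ValueError("cannot cluster an empty similarity matrix")
    if n == 1:
        return DendrogramOrder(np.empty((0, 4)), np.array([0]))
    dist = 1.0 - np.asarray(m.values, dtype=float)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="ward")
    heights = Z[:, 2]
    if np.any(np.diff(heights) < -1e-9):
        logger.warning("non-monotone merge heights in Ward linkage")
    return DendrogramOrder(Z, leaves_list(Z))


# A (innermost ring) .. G (outermost); radii are 1..7 * ring_width.
CATEGORY_RING_ORDER = [
    Category.A,
    Category.B,
    Category.C,
    Category.D,
    Category.E,
    Category.F,
    Category.G,
]


def polar_layout(
    order: DendrogramOrder,
    compound_ids: list[str],
    categories: list[Category],
    jitter_seed: int = 0,
    jitter: bool = True,
    ring_width: float = 1.0,
) -> PolarLayout:
    """Place compounds on a polar scatter.

    Angle is 2*pi*rank/n for the compound's rank in the dendrogram leaf
    order, plus (optionally) seeded uniform jitter strictly inside half
    the inter-compound spacing so the angular order is preserved; radius
    is the category's ring (A innermost .. G outermost) plus radial
    jitter within +/-30% of the ring width. Same seed, same output.
    """
    n = len(compound_ids)
    if len(categories) != n:
        raise ValueError("categories not aligned to compounds")
    ring = {c: (i + 1) * ring_width for i, c in enumerate(CATEGORY_RING_ORDER)}
    for c in categories:
        if c not in ring:
            raise ValueError(f"unknown category {c!r}")
    rank = np.empty(n, dtype=int)
    rank[order.leaf_order] = np.arange(n)
    spacing = 2.0 * np.pi / n
    angle = rank * spacing
    radius = np.array([ring[c] for c in categories], dtype=float)
    if jitter:
        rng = np.random.default_rng(jitter_seed)
        angle = angle + rng.uniform(-0.45, 0.45, size=n) * spacing
        radius = radius + rng.uniform(-0.3, 0.3, size=n) * ring_width
        angle = np.mod(angle, 2.0 * np.pi)
    return PolarLayout(list(compound_ids), angle, radius, list(categories), jitter_seed)


def build_network(
    m: SimilarityMatrix,
    threshold: float = 0.5,
    node_attrs: dict[str, dict] | None = None,
) -> SimilarityNetwork:
    """Threshold the similarity matrix into an undirected network.

    An edge connects two compounds iff their Tanimoto similarity is
    strictly greater than the threshold (default 0.5); edge weight is
    the similarity. node_attrs maps compound_id -> attribute dict
    (category, mbp_class, library_id ...).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    g = nx.Graph()
    ids = m.compound_ids
    for i, cid in enumerate(ids):
        g.add_node(cid, **(node_attrs.get(cid, {}) if node_attrs else {}))
    values = np.asarray(m.values)
    for i in range(m.n):
        for j in range(i + 1, m.n):
            if values[i, j] > threshold:
                g.add_edge(ids[i], ids[j], weight=float(values[i, j]))
    return SimilarityNetwork(g, threshold)


def extract_clusters(net: SimilarityNetwork, min_size: int = 5) -> list[set[str]]:
    """Connected components with at least min_size members.

    Sorted by size descending; ties broken by smallest member id so the
    output is deterministic.
    """
    comps = [set(c) for c in nx.connected_components(net.graph) if len(c) >= min_size]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def order_heatmap(records: list[TriageRecord]) -> list[TriageRecord]:
    """Order records for the assay heatmap: strongest mbp rescue first.

    Descending by mbp average, ties broken lexicographically by
    compound_id; records with no mbp average go last (flagged by
    position, logged).
    """
    missing = [r for r in records if r.mbp_average is None]
    if missing:
        logger.warning("%d records lack an mbp average; placed last", len(missing))
    present = [r for r in records if r.mbp_average is not None]
    present.sort(key=lambda r: (-r.mbp_average, r.compound_id))
    missing.sort(key=lambda r: r.compound_id)
    return present + missing
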