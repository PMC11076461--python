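"""Maximum-connectivity spanning trees and their topology metrics.

The spanning tree that maximizes total connectivity weight (equivalently the
minimum spanning tree on distance 1 − w) is a density-free backbone of the
functional network: every subject's tree has exactly N − 1 edges, so group
comparisons are not biased by differences in mean connectivity. The metric
set spans the integration–segregation axis: a star (one hub) has maximal
leaf fraction and betweenness and minimal diameter; a path (chain) is the
opposite extreme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix
from .montage import ANTERIOR_CHANNELS, POSTERIOR_CHANNELS, BandSpec

logger = logging.getLogger(__name__)


@dataclass
class SpanningTree:
    """An MST over channels: ordered node labels plus N − 1 edges."""

    channel_labels: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    source_method: str | None = None
    band: BandSpec | None = None

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.edges = tuple(tuple(e) for e in self.edges)
        n = len(self.channel_labels)
        labels = set(self.channel_labels)
        if len(self.edges) != n - 1:
            raise ValueError(f"a tree on {n} nodes needs {n - 1} edges, got {len(self.edges)}")
        g = nx.Graph()
        g.add_nodes_from(self.channel_labels)
        for a, b in self.edges:
            if a == b or a not in labels or b not in labels:
                raise ValueError(f"invalid edge ({a}, {b})")
            g.add_edge(a, b)
        if not nx.is_tree(g):
            raise ValueError("edge set is not a connected acyclic tree")
        self._graph = g

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def n_nodes(self) -> int:
        return len(self.channel_labels)

    def degrees(self) -> dict[str, int]:
        return dict(self._graph.degree())


@dataclass
class RegionSpec:
    """Disjoint anterior/posterior channel sets for regional betweenness."""

    anterior: frozenset[str] = field(default_factory=lambda: ANTERIOR_CHANNELS)
    posterior: frozenset[str] = field(default_factory=lambda: POSTERIOR_CHANNELS)

    def __post_init__(self) -> None:
        self.anterior = frozenset(self.anterior)
        self.posterior = frozenset(self.posterior)
        overlap = self.anterior & self.posterior
        if overlap:
            raise ValueError(f"regions must be disjoint; shared labels: {sorted(overlap)}")


@dataclass
class MstMetricSet:
    """Topology metrics of one tree (or an across-epoch average of trees)."""

    diameter: float            # longest path in edges / (N - 1)
    leaf_fraction: float       # degree-1 nodes / N
    max_degree: float          # highest node degree (integer per epoch)
    max_degree_norm: float     # max degree / (N - 1)
    max_bc: float              # highest betweenness centrality
    mean_bc_global: float
    mean_bc_anterior: float
    mean_bc_posterior: float
    assortativity: float | None  # None when undefined (zero degree variance)

    #: metric names in reporting order
    FIELDS = (
        "diameter", "leaf_fraction", "max_degree", "max_degree_norm",
        "max_bc", "mean_bc_global", "mean_bc_anterior", "mean_bc_posterior",
        "assortativity",
    )


def build_mst(m: ConnectivityMatrix) -> SpanningTree:
    """Spanning tree maximizing total connectivity weight.

    Kruskal on distance 1 − w; ties broken deterministically by ascending
    lexicographic label pair (edges are inserted in that order and the sort
    is stable). Negative weights are legal and simply rank last.
    """
    n = m.n_channels
    if n < 2:
        raise ValueError("need at least 2 channels to build a spanning tree")
    if not np.allclose(m.values, m.values.T, atol=1e-9):
        raise ValueError("connectivity matrix must be symmetric")
    labels = m.channel_labels
    order = sorted(range(n), key=lambda i: labels[i])
    g = nx.Graph()
    g.add_nodes_from(labels)
    for a in range(n):
        for b in range(a + 1, n):
            i, j = order[a], order[b]
            g.add_edge(labels[i], labels[j], distance=1.0 - m.values[i, j])
    t = nx.minimum_spanning_tree(g, weight="distance", algorithm="kruskal")
    edges = tuple(tuple(sorted(e)) for e in sorted(t.edges()))
    return SpanningTree(
        channel_labels=labels, edges=edges, source_method=m.method, band=m.band
    )


def leaf_fraction(t: SpanningTree) -> float:
    """Fraction of nodes with exactly one connection."""
    deg = t.degrees()
    return sum(1 for d in deg.values() if d == 1) / t.n_nodes


def diameter_normalized(t: SpanningTree) -> float:
    """Longest inter-node path length in edges, divided by N − 1."""
    return nx.diameter(t.graph) / (t.n_nodes - 1)


def betweenness(t: SpanningTree) -> dict[str, float]:
    """Per-node betweenness centrality: fraction of the (N−1)(N−2)/2 node
    pairs (excluding the node) whose unique tree path passes through it."""
    if t.n_nodes < 3:
        return {c: 0.0 for c in t.channel_labels}
    return nx.betweenness_centrality(t.graph, normalized=True)


def max_degree(t: SpanningTree) -> tuple[int, float]:
    """(max node degree, max degree / (N − 1))."""
    md = max(t.degrees().values())
    return md, md / (t.n_nodes - 1)


def assortativity(t: SpanningTree) -> float | None:
    """Degree assortativity: Pearson correlation of endpoint degrees over the
    edge list traversed in both directions. ``None`` when undefined (all
    endpoint degrees identical, e.g. a 2-node tree)."""
    deg = t.degrees()
    xs, ys = [], []
    for a, b in t.edges:
        xs += [deg[a], deg[b]]
        ys += [deg[b], deg[a]]
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0.0:
        return None
    return float((xd @ yd) / denom)


def regional_mean_bc(
    bc: dict[str, float], region: RegionSpec, which: str
) -> float:
    """Mean betweenness over the anterior, posterior, or global channel set."""
    if which == "global":
        return float(np.mean(list(bc.values())))
    if which == "anterior":
        sel = region.anterior
    elif which == "posterior":
        sel = region.posterior
    else:
        raise ValueError(f"which must be anterior/posterior/global, got {which!r}")
    missing = [c for c in sorted(sel) if c not in bc]
    if missing:
        raise KeyError(f"region labels not in montage: {missing}")
    return float(np.mean([bc[c] for c in sel]))


def mst_metrics_tree(t: SpanningTree, region: RegionSpec) -> MstMetricSet:
    """All topology metrics of a single tree."""
    bc = betweenness(t)
    md, mdn = max_degree(t)
    return MstMetricSet(
        diameter=diameter_normalized(t),
        leaf_fraction=leaf_fraction(t),
        max_degree=float(md),
        max_degree_norm=mdn,
        max_bc=max(bc.values()),
        mean_bc_global=regional_mean_bc(bc, region, "global"),
        mean_bc_anterior=regional_mean_bc(bc, region, "anterior"),
        mean_bc_posterior=regional_mean_bc(bc, region, "posterior"),
        assortativity=assortativity(t),
    )


def mst_metrics_subject(
    per_epoch_matrices: list[ConnectivityMatrix], region: RegionSpec | None = None
) -> MstMetricSet:
    """One tree per epoch, metrics per epoch, across-epoch arithmetic means.

    Epochs with undefined assortativity are excluded from its mean (count
    logged); if all are undefined the averaged value is ``None``.
    """
    if not per_epoch_matrices:
        raise ValueError("need at least one epoch matrix")
    labels = per_epoch_matrices[0].channel_labels
    for m in per_epoch_matrices[1:]:
        if m.channel_labels != labels:
            raise ValueError("inconsistent channel sets across epochs")
    region = region or RegionSpec()
    per_epoch = [mst_metrics_tree(build_mst(m), region) for m in per_epoch_matrices]
    means = {
        f: float(np.mean([getattr(p, f) for p in per_epoch]))
        for f in MstMetricSet.FIELDS if f != "assortativity"
    }
    asrt = [p.assortativity for p in per_epoch if p.assortativity is not None]
    n_undef = len(per_epoch) - len(asrt)
    if n_undef:
        logger.warning("assortativity undefined in %d of %d epochs", n_undef, len(per_epoch))
    means["assortativity"] = float(np.mean(asrt)) if asrt else None
    return MstMetricSet(**means)
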