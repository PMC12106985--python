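"""State adjacency graphs and the intrinsic CAR (Besag) structure.

The structured spatial effect of the risk model is an intrinsic conditional
autoregressive (ICAR / Besag) Gaussian field over the state neighbourhood
graph.  Its (improper) log-kernel is ``-tau/2 * u' Q u`` with ``Q = D - A``,
the graph Laplacian; the null space of ``Q`` is spanned by the indicator of
each connected component, so one sum-to-zero constraint per component
identifies the field.

Adjacency can be built from labelled polygons (queen or rook contiguity),
from a plain-text edge list, or programmatically.  Node order is always
sorted by label so every downstream matrix is reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyGraph",
    "ICARStructure",
    "adjacency_from_polygons",
    "adjacency_from_geojson",
    "adjacency_from_edgelist",
    "icar_precision",
    "icar_quadform",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected neighbourhood graph over area labels.

    Parameters
    ----------
    node_ids
        Area labels in the fixed (sorted) order used by all matrices.
    edges
        Unordered node pairs, stored as ``(a, b)`` with ``a < b``.
    components
        Partition of the nodes into connected components, each a tuple of
        labels in node order.
    """

    node_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    components: tuple[tuple[str, ...], ...]

    @classmethod
    def from_edges(
        cls, node_ids: Iterable[str], edges: Iterable[tuple[str, str]]
    ) -> "AdjacencyGraph":
        nodes = sorted(str(n) for n in node_ids)
        if len(nodes) != len(set(nodes)):
            raise ValueError("duplicate node labels")
        node_set = set(nodes)
        norm: set[tuple[str, str]] = set()
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
            norm.add((a, b) if a < b else (b, a))
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(norm)
        comps = tuple(
            tuple(sorted(c)) for c in sorted(nx.connected_components(g), key=min)
        )
        return cls(tuple(nodes), frozenset(norm), comps)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, label: str) -> int:
        return self.node_ids.index(label)

    def degree(self) -> np.ndarray:
        idx = {n: i for i, n in enumerate(self.node_ids)}
        deg = np.zeros(self.n_nodes, dtype=int)
        for a, b in self.edges:
            deg[idx[a]] += 1
            deg[idx[b]] += 1
        return deg

    def to_json(self) -> str:
        return json.dumps(
            {"nodes": list(self.node_ids), "edges": sorted(map(list, self.edges))}
        )

    @classmethod
    def from_json(cls, text: str) -> "AdjacencyGraph":
        obj = json.loads(text)
        return cls.from_edges(obj["nodes"], [tuple(e) for e in obj["edges"]])


@dataclass(frozen=True)
class ICARStructure:
    """Intrinsic CAR structure matrix and its identifiability constraints.

    ``Q = D - A`` (degree minus adjacency).  ``rank = n - #components``; the
    indicator vector of each component spans the null space and doubles as
    the sum-to-zero constraint applied to the structured effect.
    """

    graph: AdjacencyGraph
    Q: sp.csr_matrix
    rank: int
    constraints: np.ndarray = field(repr=False)  # (n_components, n) 0/1 rows

    @property
    def n(self) -> int:
        return self.graph.n_nodes

    def edge_indices(self) -> tuple[np.ndarray, np.ndarray]:
        idx = {n: i for i, n in enumerate(self.graph.node_ids)}
        pairs = sorted(self.graph.edges)
        i = np.array([idx[a] for a, _ in pairs], dtype=int)
        j = np.array([idx[b] for _, b in pairs], dtype=int)
        return i, j


def _polygon_items(
    polygons: Mapping[str, BaseGeometry] | Sequence[tuple[str, BaseGeometry]],
) -> list[tuple[str, BaseGeometry]]:
    if isinstance(polygons, Mapping):
        items = [(str(k), v) for k, v in polygons.items()]
    else:
        items = [(str(k), v) for k, v in polygons]
    if not items:
        raise ValueError("empty polygon collection")
    labels = [k for k, _ in items]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate polygon labels")
    for k, g in items:
        if g is None or g.is_empty:
            raise ValueError(f"empty geometry for label {k!r}")
    return items


def adjacency_from_polygons(
    polygons: Mapping[str, BaseGeometry] | Sequence[tuple[str, BaseGeometry]],
    contiguity: str = "queen",
) -> AdjacencyGraph:
    """Build the neighbourhood graph from labelled polygons.

    Queen contiguity (the default) links two areas that share at least one
    boundary point; rook requires a shared boundary segment of positive
    length.  State polygons frequently meet only at corners, which is why
    queen is the default.
    """
    if contiguity not in ("queen", "rook"):
        raise ValueError(f"contiguity must be 'queen' or 'rook', got {contiguity!r}")
    items = _polygon_items(polygons)
    edges = []
    for i in range(len(items)):
        la, ga = items[i]
        for j in range(i + 1, len(items)):
            lb, gb = items[j]
            if not ga.intersects(gb):
                continue
            inter = ga.intersection(gb)
            if inter.is_empty:
                continue
            if contiguity == "queen":
                edges.append((la, lb))
            elif inter.length > 0:
                edges.append((la, lb))
    return AdjacencyGraph.from_edges([k for k, _ in items], edges)


def adjacency_from_geojson(
    path: str | Path, id_property: str = "id", contiguity: str = "queen"
) -> AdjacencyGraph:
    """Read a GeoJSON FeatureCollection and build contiguity adjacency.

    ``id_property`` names the feature property holding the area label; the
    top-level feature ``id`` is used as a fallback.
    """
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    items = []
    for feat in obj.get("features", []):
        props = feat.get("properties") or {}
        label = props.get(id_property, feat.get("id"))
        if label is None:
            raise ValueError(f"feature missing id property {id_property!r}")
        items.append((str(label), shape(feat["geometry"])))
    return adjacency_from_polygons(items, contiguity=contiguity)


def adjacency_from_edgelist(source: str | Path | Iterable[str]) -> AdjacencyGraph:
    """Read a plain-text edge list, one ``a<TAB>b`` pair per line.

    Lines starting with ``#`` are comments; an isolated node may be listed
    on a line by itself.
    """
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = list(source)
    nodes: set[str] = set()
    edges: list[tuple[str, str]] = []
    for ln in lines:
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) == 1:
            nodes.add(parts[0])
        elif len(parts) == 2:
            nodes.update(parts)
            edges.append((parts[0], parts[1]))
        else:
            raise ValueError(f"malformed edge-list line: {ln!r}")
    if not nodes:
        raise ValueError("empty edge list")
    return AdjacencyGraph.from_edges(nodes, edges)


def icar_precision(graph: AdjacencyGraph, scale_icar: bool = False) -> ICARStructure:
    """Construct the ICAR structure matrix ``Q = D - A`` for a graph.

    Islands (degree-0 nodes) are retained with an all-zero row; a warning is
    logged because their structured effect is identified only through the
    component constraint.  ``scale_icar`` is accepted for config symmetry but
    raw ``D - A`` is always used (the precision hyperparameter absorbs scale).
    """
    if scale_icar:
        warnings.warn("scale_icar is not implemented; raw D - A is used")
    n = graph.n_nodes
    idx = {lab: i for i, lab in enumerate(graph.node_ids)}
    deg = graph.degree()
    if n and (deg == 0).any() and graph.n_edges > 0:
        isolated = [graph.node_ids[i] for i in np.flatnonzero(deg == 0)]
        logger.warning(
            "isolated areas %s have zero ICAR rows; identified only via "
            "constraints/iid effects",
            isolated,
        )
    rows, cols, vals = [], [], []
    for a, b in graph.edges:
        i, j = idx[a], idx[b]
        rows += [i, j]
        cols += [j, i]
        vals += [-1, -1]
    rows += list(range(n))
    cols += list(range(n))
    vals += list(deg)
    Q = sp.csr_matrix(
        (np.array(vals, dtype=float), (rows, cols)), shape=(n, n)
    )
    constraints = np.zeros((len(graph.components), n))
    for c, comp in enumerate(graph.components):
        for lab in comp:
            constraints[c, idx[lab]] = 1.0
    return ICARStructure(
        graph=graph,
        Q=Q,
        rank=n - len(graph.components),
        constraints=constraints,
    )


def icar_quadform(u: np.ndarray, structure: ICARStructure) -> float:
    """Evaluate ``u' Q u`` as the pairwise sum ``sum_{i~j} (u_i - u_j)^2``.

    This is the quadratic form in the Besag log-kernel and in the Gamma full
    conditional of the structured-effect precision.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (structure.n,):
        raise ValueError(
            f"u has shape {u.shape}, expected ({structure.n},)"
        )
    i, j = structure.edge_indices()
    d = u[i] - u[j]
    return float(d @ d)
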