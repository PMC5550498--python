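"""Neighbour graphs for areal data: queen contiguity, GAL files, weight styles.

Areas are neighbours under the queen rule when their polygon boundaries
share at least one point — a full edge or a single corner.  Adjacency is
detected by snapping polygon vertices to a tolerance grid and intersecting
the resulting point sets, which is exact for lattices and robust to
floating-point jitter in real boundary files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SpatialWeights",
    "queen_adjacency",
    "row_standardize",
    "read_gal",
    "write_gal",
    "read_geojson",
]


@dataclass(frozen=True)
class SpatialWeights:
    """A symmetric neighbour graph over ``n`` labelled areas.

    ``neighbors[i]`` lists the indices adjacent to area ``i`` and
    ``weights[i]`` the aligned weights (all 1.0 for ``binary`` style,
    ``1/deg(i)`` for ``row_standardized``).  Areas with no neighbours are
    recorded in ``islands``; ``component_labels`` partitions the areas
    into connected components (islands are singleton components).
    """

    ids: tuple
    neighbors: tuple          # tuple of tuples of int
    weights: tuple            # tuple of tuples of float
    style: str                # "binary" | "row_standardized"
    islands: frozenset = field(default_factory=frozenset)
    component_labels: tuple = ()

    def __post_init__(self):
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("area ids must be unique")
        if self.style not in ("binary", "row_standardized"):
            raise ValueError(f"unknown weights style {self.style!r}")
        for i, nbrs in enumerate(self.neighbors):
            if i in nbrs:
                raise ValueError(f"self-neighbour at index {i}")
            for j in nbrs:
                if i not in self.neighbors[j]:
                    raise ValueError(f"asymmetric adjacency: {self.ids[i]!r} lists "
                                     f"{self.ids[j]!r} but not vice versa")
        if self.style == "row_standardized":
            for i, w in enumerate(self.weights):
                if i not in self.islands and abs(sum(w) - 1.0) > 1e-12:
                    raise ValueError(f"row {i} of row-standardized weights sums to {sum(w)}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_components(self) -> int:
        return len(set(self.component_labels))

    def to_sparse(self) -> sp.csr_matrix:
        """Weight matrix W as CSR (binary adjacency or row-standardized)."""
        rows, cols, vals = [], [], []
        for i, (nbrs, ws) in enumerate(zip(self.neighbors, self.weights)):
            rows.extend([i] * len(nbrs))
            cols.extend(nbrs)
            vals.extend(ws)
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def degrees(self) -> np.ndarray:
        return np.array([len(nbrs) for nbrs in self.neighbors])

    @property
    def total_weight(self) -> float:
        """S0, the sum of all weights."""
        return float(sum(sum(w) for w in self.weights))


def _components(n: int, neighbors: Sequence[Sequence[int]]) -> tuple:
    labels = [-1] * n
    comp = 0
    for start in range(n):
        if labels[start] != -1:
            continue
        stack = [start]
        labels[start] = comp
        while stack:
            i = stack.pop()
            for j in neighbors[i]:
                if labels[j] == -1:
                    labels[j] = comp
                    stack.append(j)
        comp += 1
    return tuple(labels)


def _build(ids, neighbor_sets) -> SpatialWeights:
    ids = tuple(ids)
    neighbors = tuple(tuple(sorted(s)) for s in neighbor_sets)
    weights = tuple(tuple(1.0 for _ in nbrs) for nbrs in neighbors)
    islands = frozenset(i for i, nbrs in enumerate(neighbors) if not nbrs)
    return SpatialWeights(ids=ids, neighbors=neighbors, weights=weights,
                          style="binary", islands=islands,
                          component_labels=_components(len(ids), neighbors))


def queen_adjacency(polygons: Mapping, snap_tolerance: float = 1e-8) -> SpatialWeights:
    """Binary queen-contiguity weights from labelled polygons.

    Parameters
    ----------
    polygons
        Mapping label -> polygon, where a polygon is either a sequence of
        (x, y) vertex pairs (one exterior ring) or a GeoJSON-style geometry
        dict of type Polygon/MultiPolygon.
    snap_tolerance
        Vertices are snapped to a grid of this pitch before comparison, so
        coordinates differing by less than the tolerance coincide.

    Two areas are neighbours when their snapped vertex sets intersect —
    the queen rule, under which a shared corner alone suffices.
    """
    labels = list(polygons)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate polygon labels")
    if snap_tolerance <= 0:
        raise ValueError("snap_tolerance must be positive")

    vertex_owners: dict[tuple, set[int]] = {}
    for idx, label in enumerate(labels):
        pts = list(_iter_vertices(polygons[label]))
        if len(pts) < 3:
            raise ValueError(f"empty or degenerate geometry for label {label!r}")
        for x, y in pts:
            key = (round(x / snap_tolerance), round(y / snap_tolerance))
            vertex_owners.setdefault(key, set()).add(idx)

    neighbor_sets = [set() for _ in labels]
    for owners in vertex_owners.values():
        if len(owners) > 1:
            owners = sorted(owners)
            for a in owners:
                for b in owners:
                    if a != b:
                        neighbor_sets[a].add(b)
    return _build(labels, neighbor_sets)


def _iter_vertices(geom) -> Iterable[tuple]:
    if isinstance(geom, dict):
        gtype = geom.get("type")
        coords = geom.get("coordinates")
        if gtype == "Polygon":
            rings = coords
        elif gtype == "MultiPolygon":
            rings = [ring for poly in coords for ring in poly]
        else:
            raise ValueError(f"unsupported geometry type {gtype!r}")
        for ring in rings:
            for pt in ring:
                yield (float(pt[0]), float(pt[1]))
    else:
        for pt in geom:
            yield (float(pt[0]), float(pt[1]))


def as_binary(w: SpatialWeights) -> SpatialWeights:
    """Binary-style view of the same neighbour structure."""
    if w.style == "binary":
        return w
    weights = tuple(tuple(1.0 for _ in nbrs) for nbrs in w.neighbors)
    return SpatialWeights(ids=w.ids, neighbors=w.neighbors, weights=weights,
                          style="binary", islands=w.islands,
                          component_labels=w.component_labels)


def row_standardize(w: SpatialWeights) -> SpatialWeights:
    """Row-standardized copy: each weight becomes 1/deg(i).

    Island rows stay empty (their zero rows cannot be standardized) and
    remain flagged.  Idempotent on already-standardized inputs.
    """
    if w.style == "row_standardized":
        return w
    weights = tuple(tuple(1.0 / len(nbrs) for _ in nbrs) if nbrs else ()
                    for nbrs in w.neighbors)
    return SpatialWeights(ids=w.ids, neighbors=w.neighbors, weights=weights,
                          style="row_standardized", islands=w.islands,
                          component_labels=w.component_labels)


def read_geojson(path, label_property: str = "id") -> dict:
    """Load a GeoJSON FeatureCollection into a label -> geometry mapping."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    polygons = {}
    for feat in doc["features"]:
        props = feat.get("properties") or {}
        if label_property in props:
            label = props[label_property]
        elif "id" in feat:
            label = feat["id"]
        else:
            raise ValueError(f"feature lacks label property {label_property!r}")
        if label in polygons:
            raise ValueError(f"duplicate polygon labels: {label!r}")
        polygons[label] = feat["geometry"]
    return polygons


def read_gal(path) -> SpatialWeights:
    """Read a GAL contiguity file (header ``n``, then per-area id/degree
    line followed by the neighbour ids).  Asymmetric files are rejected."""
    with open(path, encoding="utf-8") as fh:
        tokens_by_line = [ln.split() for ln in fh if ln.strip()]
    if not tokens_by_line:
        raise ValueError("empty GAL file")
    header = tokens_by_line[0]
    # canonical header is the bare count "n"; tolerate the 4-token
    # GeoDa-style header "0 n file key" as well
    n = int(header[1]) if len(header) == 4 else int(header[0])
    flat = [tok for line in tokens_by_line[1:] for tok in line]
    ids: list = []
    neighbor_ids: list[list[str]] = []
    pos = 0
    while pos < len(flat):
        area_id, k = flat[pos], int(flat[pos + 1])
        pos += 2
        ids.append(area_id)
        neighbor_ids.append(flat[pos:pos + k])
        if len(neighbor_ids[-1]) != k:
            raise ValueError(f"truncated neighbour list for area {area_id!r}")
        pos += k
    if len(ids) != n:
        raise ValueError(f"GAL header declares {n} areas but file lists {len(ids)}")
    if len(set(ids)) != n:
        raise ValueError("duplicate area ids in GAL file")
    index = {a: i for i, a in enumerate(ids)}
    neighbor_sets = []
    for a, nbrs in zip(ids, neighbor_ids):
        s = set()
        for b in nbrs:
            if b not in index:
                raise ValueError(f"area {a!r} lists unknown neighbour {b!r}")
            s.add(index[b])
        neighbor_sets.append(s)
    for i, s in enumerate(neighbor_sets):
        for j in s:
            if i not in neighbor_sets[j]:
                raise ValueError(f"asymmetric GAL file: {ids[i]!r} lists {ids[j]!r} "
                                 f"but {ids[j]!r} does not list {ids[i]!r}")
    return _build(ids, neighbor_sets)


def write_gal(w: SpatialWeights, path) -> None:
    """Write the neighbour structure (weights styles are not persisted)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{w.n}\n")
        for i, nbrs in enumerate(w.neighbors):
            fh.write(f"{w.ids[i]} {len(nbrs)}\n")
            fh.write(" ".join(str(w.ids[j]) for j in nbrs) + "\n")
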