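"""Contiguity structures for areal models.

The spatially structured random effect of a disease-mapping model needs a
0/1 neighbourhood ("adjacency") matrix: areas sharing a border get weight 1,
all other pairs 0.  This module builds that structure from regular lattices
(for simulation), from polygon layers (GeoJSON), or from explicit edge
lists, and exposes the graph quantities the intrinsic CAR prior consumes:
per-area neighbour counts, the graph Laplacian, connected components and a
greedy vertex colouring (used to vectorise single-site Metropolis updates).
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric 0/1 neighbour structure over an ordered set of areas.

    ``neighbours[i]`` holds the *indices* (positions in ``area_ids``) of the
    areas adjacent to area ``i``.  The structure is symmetric and has no
    self-loops; both are validated at construction.
    """

    area_ids: tuple
    neighbours: tuple

    def __post_init__(self):
        if len(set(self.area_ids)) != len(self.area_ids):
            raise ValueError("duplicate area ids in adjacency graph")
        m = len(self.area_ids)
        for i, nb in enumerate(self.neighbours):
            if i in nb:
                raise ValueError(f"self-loop at area {self.area_ids[i]!r}")
            for j in nb:
                if not (0 <= j < m):
                    raise ValueError("neighbour index out of range")
                if i not in self.neighbours[j]:
                    raise ValueError(
                        f"asymmetric adjacency between {self.area_ids[i]!r} "
                        f"and {self.area_ids[j]!r}"
                    )

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_i(self) -> np.ndarray:
        """Neighbour count per area (the CAR conditional precision weight)."""
        return np.array([len(nb) for nb in self.neighbours], dtype=int)

    @property
    def n_edges(self) -> int:
        return int(self.n_i.sum()) // 2

    def edges(self) -> Iterator[tuple[int, int]]:
        """Unordered adjacent pairs, each yielded once with i < j."""
        for i, nb in enumerate(self.neighbours):
            for j in nb:
                if i < j:
                    yield (i, j)

    def index_of(self, area_id) -> int:
        try:
            return self.area_ids.index(area_id)
        except ValueError:
            raise KeyError(f"unknown area id {area_id!r}") from None

    def to_sparse(self) -> sparse.csr_matrix:
        """0/1 weights matrix W (symmetric, zero diagonal)."""
        rows, cols = [], []
        for i, nb in enumerate(self.neighbours):
            for j in nb:
                rows.append(i)
                cols.append(j)
        m = self.n_areas
        data = np.ones(len(rows))
        return sparse.csr_matrix((data, (rows, cols)), shape=(m, m))

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian Q = D - W, the ICAR precision kernel."""
        W = self.to_sparse().toarray()
        return np.diag(self.n_i.astype(float)) - W

    def colour_classes(self) -> list[np.ndarray]:
        """Greedy vertex colouring: within a class no two areas are adjacent,
        so their ICAR full conditionals are mutually independent and can be
        Metropolis-updated simultaneously."""
        m = self.n_areas
        colour = np.full(m, -1, dtype=int)
        for i in range(m):
            used = {colour[j] for j in self.neighbours[i] if colour[j] >= 0}
            c = 0
            while c in used:
                c += 1
            colour[i] = c
        return [np.flatnonzero(colour == c) for c in range(colour.max() + 1)]

    def to_edge_dataframe(self) -> pd.DataFrame:
        rows = [
            {"area_i": self.area_ids[i], "area_j": self.area_ids[j]}
            for i, j in self.edges()
        ]
        return pd.DataFrame(rows, columns=["area_i", "area_j"])


def graph_from_neighbour_sets(
    area_ids: Sequence, neighbour_sets: Sequence[Iterable[int]]
) -> AdjacencyGraph:
    return AdjacencyGraph(
        tuple(area_ids), tuple(frozenset(nb) for nb in neighbour_sets)
    )


def graph_from_edges(
    area_ids: Sequence, edges: Iterable[tuple[Hashable, Hashable]]
) -> AdjacencyGraph:
    """Build a graph from (area_id, area_id) pairs; ids not in `area_ids` error."""
    idx = {a: i for i, a in enumerate(area_ids)}
    nb: list[set] = [set() for _ in area_ids]
    for a, b in edges:
        if a not in idx or b not in idx:
            raise ValueError(f"edge ({a!r}, {b!r}) references unknown area id")
        i, j = idx[a], idx[b]
        if i == j:
            raise ValueError(f"self-loop on {a!r}")
        nb[i].add(j)
        nb[j].add(i)
    return graph_from_neighbour_sets(tuple(area_ids), nb)


def make_lattice(rows: int, cols: int) -> AdjacencyGraph:
    """Rook-contiguity graph on a rows x cols grid.

    Area ids are "r{r}c{c}" in row-major order; two cells are neighbours iff
    they share an edge (not merely a corner).
    """
    if rows < 1 or cols < 1:
        raise ValueError(f"lattice dimensions must be positive, got {rows}x{cols}")
    ids = [f"r{r}c{c}" for r in range(rows) for c in range(cols)]
    nb: list[set] = [set() for _ in ids]

    def k(r, c):
        return r * cols + c

    for r in range(rows):
        for c in range(cols):
            if r + 1 < rows:
                nb[k(r, c)].add(k(r + 1, c))
                nb[k(r + 1, c)].add(k(r, c))
            if c + 1 < cols:
                nb[k(r, c)].add(k(r, c + 1))
                nb[k(r, c + 1)].add(k(r, c))
    return graph_from_neighbour_sets(ids, nb)


def lattice_polygons(rows: int, cols: int) -> dict:
    """Unit-square shapely polygons matching :func:`make_lattice` ids."""
    from shapely.geometry import box

    return {
        f"r{r}c{c}": box(c, -(r + 1), c + 1, -r)
        for r in range(rows)
        for c in range(cols)
    }


def adjacency_from_polygons(
    polygons: Mapping, rule: str = "queen", tol: float = 1e-9
) -> AdjacencyGraph:
    """Contiguity graph from an area-id -> polygon mapping.

    queen: any boundary contact (shared point suffices).
    rook:  shared boundary segment of positive length (> tol).
    """
    from shapely import STRtree

    if rule not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity rule {rule!r}")
    if len(polygons) == 0:
        raise ValueError("empty polygon collection")
    ids = list(polygons.keys())
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate area ids")
    geoms = []
    for a in ids:
        g = polygons[a]
        if g is None or g.is_empty:
            raise ValueError(f"empty geometry for area {a!r}")
        if not g.is_valid:
            raise ValueError(f"invalid geometry for area {a!r}")
        geoms.append(g)

    tree = STRtree(geoms)
    nb: list[set] = [set() for _ in ids]
    for i, g in enumerate(geoms):
        for j in tree.query(g, predicate="intersects"):
            j = int(j)
            if j <= i:
                continue
            inter = g.intersection(geoms[j])
            if inter.is_empty:
                continue
            if inter.area > tol:  # overlapping polygons still count as contiguous
                touch = True
            elif rule == "rook":
                touch = inter.length > tol
            else:
                touch = True
            if touch:
                nb[i].add(j)
                nb[j].add(i)
    return graph_from_neighbour_sets(ids, nb)


def components(graph: AdjacencyGraph) -> list[set]:
    """Connected components (breadth-first); isolated areas are singletons."""
    seen = np.zeros(graph.n_areas, dtype=bool)
    out: list[set] = []
    for start in range(graph.n_areas):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            i = q.popleft()
            comp.add(graph.area_ids[i])
            for j in graph.neighbours[i]:
                if not seen[j]:
                    seen[j] = True
                    q.append(j)
        out.append(comp)
    return out


def summary(graph: AdjacencyGraph) -> dict:
    n_i = graph.n_i
    return {
        "areas": graph.n_areas,
        "edges": graph.n_edges,
        "components": len(components(graph)),
        "islands": int((n_i == 0).sum()),
        "min_neighbours": int(n_i.min()) if graph.n_areas else 0,
        "median_neighbours": float(np.median(n_i)) if graph.n_areas else 0.0,
        "max_neighbours": int(n_i.max()) if graph.n_areas else 0,
    }


# --- GeoJSON / CSV I/O ------------------------------------------------------


def read_geojson_polygons(path, id_field: str = "area_id") -> dict:
    """Read a GeoJSON FeatureCollection into an ordered {id: shapely geometry}."""
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    out = {}
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if id_field in props:
            aid = props[id_field]
        elif "id" in feat:
            aid = feat["id"]
        else:
            raise ValueError(f"feature missing id field {id_field!r}")
        if aid in out:
            raise ValueError(f"duplicate area id {aid!r} in GeoJSON")
        out[aid] = shape(feat["geometry"])
    return out


def write_geojson_polygons(path, polygons: Mapping, properties: Mapping | None = None,
                           id_field: str = "area_id") -> None:
    """Write {id: shapely geometry} as RFC 7946 GeoJSON, with optional
    per-area property dicts merged in."""
    from shapely.geometry import mapping as geom_mapping

    feats = []
    for aid, geom in polygons.items():
        props = {id_field: aid}
        if properties is not None and aid in properties:
            props.update(properties[aid])
        feats.append(
            {"type": "Feature", "properties": props,
             "geometry": geom_mapping(geom)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_edge_csv(path, graph: AdjacencyGraph) -> None:
    graph.to_edge_dataframe().to_csv(path, index=False)


def read_edge_csv(path, area_ids: Sequence) -> AdjacencyGraph:
    df = pd.read_csv(path, dtype={"area_i": str, "area_j": str})
    return graph_from_edges(
        tuple(str(a) for a in area_ids),
        zip(df["area_i"], df["area_j"]),
    )
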