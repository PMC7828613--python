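"""Area adjacency graphs for spatial random effects.

The structured spatial term of the regression model places an intrinsic
conditional autoregressive (ICAR) prior on area-level effects, which needs a
symmetric, connected contiguity graph. This module provides the graph
container, lattice generators for tests, a hand-encoded 37-area contiguity
fixture standing in for Nigeria's 36 states plus the federal capital
territory, and edge-list I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "AdjacencyGraph",
    "make_lattice_adjacency",
    "load_area_fixture",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected contiguity graph over ``n_areas`` areas.

    Edges are stored as a frozenset of unordered ``(i, j)`` pairs with
    ``i < j``. Self-loops are rejected; area ids must lie in
    ``[0, n_areas)``. Connectivity is required for ICAR identifiability
    (the ICAR precision of a connected graph has rank ``n_areas - 1``).
    """

    n_areas: int
    edges: frozenset[tuple[int, int]]
    area_labels: tuple[str, ...] | None = None
    region_of_area: tuple[int, ...] | None = field(default=None)
    region_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_areas < 1:
            raise ValueError("n_areas must be >= 1")
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on area {i}")
            if not (0 <= i < self.n_areas and 0 <= j < self.n_areas):
                raise ValueError(f"edge ({i},{j}) outside [0,{self.n_areas})")
            if i > j:
                raise ValueError("edges must be stored with i < j")
        if self.area_labels is not None and len(self.area_labels) != self.n_areas:
            raise ValueError("area_labels length mismatch")

    @classmethod
    def from_edges(
        cls,
        n_areas: int,
        edges,
        area_labels=None,
        region_of_area=None,
        region_labels=None,
    ) -> "AdjacencyGraph":
        norm = frozenset((min(i, j), max(i, j)) for i, j in edges)
        return cls(
            n_areas=n_areas,
            edges=norm,
            area_labels=tuple(area_labels) if area_labels is not None else None,
            region_of_area=tuple(region_of_area) if region_of_area is not None else None,
            region_labels=tuple(region_labels) if region_labels is not None else None,
        )

    def adjacency_matrix(self) -> np.ndarray:
        A = np.zeros((self.n_areas, self.n_areas))
        for i, j in self.edges:
            A[i, j] = A[j, i] = 1.0
        return A

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_areas, dtype=int)
        for i, j in self.edges:
            d[i] += 1
            d[j] += 1
        return d

    def neighbors(self, area: int) -> list[int]:
        out = []
        for i, j in self.edges:
            if i == area:
                out.append(j)
            elif j == area:
                out.append(i)
        return sorted(out)

    def is_connected(self) -> bool:
        return len(self.components()) == 1

    def components(self) -> list[list[int]]:
        """Connected components by breadth-first search, each sorted."""
        adj: list[list[int]] = [[] for _ in range(self.n_areas)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        seen = np.zeros(self.n_areas, dtype=bool)
        comps = []
        for start in range(self.n_areas):
            if seen[start]:
                continue
            stack = [start]
            seen[start] = True
            comp = []
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in adj[u]:
                    if not seen[v]:
                        seen[v] = True
                        stack.append(v)
            comps.append(sorted(comp))
        return comps


def make_lattice_adjacency(rows: int, cols: int) -> AdjacencyGraph:
    """Rook-neighbour rectangular lattice with ``rows * cols`` areas.

    Area ``(r, c)`` gets id ``r * cols + c``; edges connect horizontal and
    vertical neighbours, so the edge count is
    ``rows * (cols - 1) + cols * (rows - 1)``.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be positive")
    edges = []
    for r in range(rows):
        for c in range(cols):
            u = r * cols + c
            if c + 1 < cols:
                edges.append((u, u + 1))
            if r + 1 < rows:
                edges.append((u, u + cols))
    n = rows * cols
    # split areas into 6 contiguous row-major blocks standing in for regions
    n_regions = min(6, n)
    region_of_area = tuple(min(a * n_regions // n, n_regions - 1) for a in range(n))
    region_labels = tuple(f"region_{k}" for k in range(n_regions))
    return AdjacencyGraph.from_edges(
        n, edges, region_of_area=region_of_area, region_labels=region_labels
    )


_FIXTURES = {"nigeria37": "nigeria37.json"}


def load_area_fixture(name: str) -> AdjacencyGraph:
    """Load a packaged contiguity fixture by name.

    ``"nigeria37"`` is a hand-encoded approximate state contiguity graph for
    Nigeria's 36 states plus the federal capital territory, grouped into the
    six geopolitical regions. It is an encoding choice, not survey-grade GIS
    contiguity; model code treats it as an arbitrary connected graph.
    """
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        )
    path = resources.files("hapstar").joinpath("data", _FIXTURES[name])
    payload = json.loads(path.read_text())
    labels = payload["area_labels"]
    index = {lab: k for k, lab in enumerate(labels)}
    edges = [(index[a], index[b]) for a, b in payload["edges"]]
    region_labels = payload["region_labels"]
    rindex = {lab: k for k, lab in enumerate(region_labels)}
    region_of_area = [rindex[payload["region_of_area"][lab]] for lab in labels]
    graph = AdjacencyGraph.from_edges(
        len(labels),
        edges,
        area_labels=labels,
        region_of_area=region_of_area,
        region_labels=region_labels,
    )
    if not graph.is_connected():
        raise ValueError(f"fixture {name!r} is not connected")
    return graph


def write_edge_list(graph: AdjacencyGraph, path: str | Path) -> None:
    """One ``"i j"`` pair per line, preceded by a ``# n_areas`` header."""
    lines = [f"# n_areas {graph.n_areas}"]
    lines += [f"{i} {j}" for i, j in sorted(graph.edges)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> AdjacencyGraph:
    n_areas = None
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts[:1] == ["n_areas"]:
                n_areas = int(parts[1])
            continue
        i, j = map(int, line.split())
        edges.append((i, j))
    if n_areas is None:
        n_areas = 1 + max(max(e) for e in edges) if edges else 1
    return AdjacencyGraph.from_edges(n_areas, edges)
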