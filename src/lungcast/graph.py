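"""Area adjacency graphs: the neighbourhood backbone of the CAR spatial prior.

An :class:`AreaGraph` holds a set of small areas (e.g. local government areas)
and a symmetric adjacency relation between them.  The intrinsic CAR prior on
the structured spatial effect smooths each area's relative risk towards the
mean of its neighbours, so everything spatial in this package is defined
relative to one of these graphs.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import sparse


class GraphError(ValueError):
    """Raised for structurally invalid adjacency specifications."""


class AreaGraph:
    """Undirected adjacency between areas, indexed 0..n-1.

    Parameters
    ----------
    area_ids : sequence of str
        Ordered area labels; position defines the integer index used by all
        vector-valued spatial quantities.
    edges : iterable of (int, int)
        Unordered neighbour pairs given as index pairs.  Self-loops are
        rejected; duplicates (in either order) are collapsed.

    Notes
    -----
    Areas of degree zero ("islands") are permitted but flagged via
    :attr:`islands`; the ICAR prior has nothing to smooth them against, so
    downstream code pins their structured effect to zero.
    """

    def __init__(self, area_ids: Sequence[str], edges: Iterable[tuple[int, int]]):
        self.area_ids = tuple(str(a) for a in area_ids)
        n = len(self.area_ids)
        if n < 1:
            raise GraphError("graph needs at least one area")
        if len(set(self.area_ids)) != n:
            raise GraphError("duplicate area ids")
        seen: set[tuple[int, int]] = set()
        for i, j in edges:
            i, j = int(i), int(j)
            if i == j:
                raise GraphError(f"self-loop on area index {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise GraphError(f"edge ({i},{j}) out of range for {n} areas")
            seen.add((min(i, j), max(i, j)))
        self.edges = tuple(sorted(seen))
        self.n_areas = n

        rows = np.array([e[0] for e in self.edges] + [e[1] for e in self.edges], dtype=int)
        cols = np.array([e[1] for e in self.edges] + [e[0] for e in self.edges], dtype=int)
        data = np.ones(rows.size)
        self._adj = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
        self.neighbor_counts = np.asarray(self._adj.sum(axis=1)).ravel().astype(int)
        self.neighbors = [self._adj.indices[self._adj.indptr[i]:self._adj.indptr[i + 1]]
                          for i in range(n)]

    # -- derived structure -------------------------------------------------

    @property
    def islands(self) -> np.ndarray:
        """Indices of degree-0 areas."""
        return np.flatnonzero(self.neighbor_counts == 0)

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric 0/1 adjacency matrix."""
        return self._adj

    def laplacian(self) -> sparse.csr_matrix:
        """Graph Laplacian D - W, the ICAR precision structure."""
        d = sparse.diags(self.neighbor_counts.astype(float))
        return (d - self._adj).tocsr()

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.edges)
        return g

    def connected_components(self) -> list[np.ndarray]:
        comps = nx.connected_components(self.to_networkx())
        return [np.array(sorted(c), dtype=int) for c in comps]

    def coloring(self) -> list[np.ndarray]:
        """Partition non-island areas into independent sets.

        Within each returned index array no two areas are adjacent, so their
        ICAR full conditionals are mutually independent and the MCMC sampler
        may update them as a block.
        """
        col = nx.greedy_color(self.to_networkx(), strategy="largest_first")
        ncol = max(col.values(), default=0) + 1
        groups = []
        for c in range(ncol):
            idx = np.array(sorted(i for i, ci in col.items() if ci == c
                                  and self.neighbor_counts[i] > 0), dtype=int)
            if idx.size:
                groups.append(idx)
        return groups

    def __repr__(self) -> str:  # pragma: no cover
        return f"AreaGraph(n_areas={self.n_areas}, n_edges={len(self.edges)})"


def make_lattice_graph(rows: int, cols: int) -> AreaGraph:
    """Rook-adjacency rectangular lattice of ``rows x cols`` areas.

    The default study fixture is an 8x10 lattice: 80 areas, close to the 79
    Victorian local government areas, with interior areas having 4 neighbours.
    """
    rows, cols = int(rows), int(cols)
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise GraphError("lattice must contain at least 2 areas")
    ids = [f"A{r * cols + c:03d}" for r in range(rows) for c in range(cols)]
    edges = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                edges.append((i, i + 1))
            if r + 1 < rows:
                edges.append((i, i + cols))
    return AreaGraph(ids, edges)


def read_edge_list(path) -> AreaGraph:
    """Read a two-column whitespace edge list of area labels.

    Areas are indexed in sorted label order, so a written graph reads back
    with the same indexing whenever its ids were ordered to begin with.
    """
    raw = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split()[:2]
            raw.append((a, b))
    ids = sorted({lbl for pair in raw for lbl in pair})
    index = {lbl: i for i, lbl in enumerate(ids)}
    return AreaGraph(ids, [(index[a], index[b]) for a, b in raw])


def write_edge_list(graph: AreaGraph, path) -> None:
    with open(path, "w") as fh:
        for i, j in graph.edges:
            fh.write(f"{graph.area_ids[i]}\t{graph.area_ids[j]}\n")
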