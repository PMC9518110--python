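"""Areal adjacency graphs for disease mapping.

A :class:`RegionGraph` records, for each areal unit (province, district,
lattice cell), the set of its contiguity neighbours.  The neighbour sets
drive the intrinsic CAR prior: the conditional mean of a region's spatial
effect is the average of its neighbours' effects, with conditional variance
inversely proportional to the neighbour count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = ["RegionGraph", "read_adjacency", "lattice_graph"]


class AdjacencyError(ValueError):
    """Raised when an adjacency specification violates graph invariants."""


@dataclass(frozen=True)
class RegionGraph:
    """Symmetric, loop-free contiguity graph over ordered areal units.

    Parameters
    ----------
    region_ids
        Ordered unique labels; index order fixes the layout of every
        spatial vector in the package.
    neighbours
        Per-region tuple of neighbour *indices* (0-based, dense).
    """

    region_ids: tuple
    neighbours: tuple = field(repr=False)

    def __post_init__(self):
        ids = tuple(str(r) for r in self.region_ids)
        object.__setattr__(self, "region_ids", ids)
        if len(set(ids)) != len(ids):
            raise AdjacencyError("region ids are not unique")
        nbrs = tuple(tuple(sorted(set(int(j) for j in s))) for s in self.neighbours)
        object.__setattr__(self, "neighbours", nbrs)
        if len(nbrs) != len(ids):
            raise AdjacencyError("neighbour list length does not match region count")
        n = len(ids)
        for i, s in enumerate(nbrs):
            for j in s:
                if j == i:
                    raise AdjacencyError(f"self-loop at region '{ids[i]}'")
                if not (0 <= j < n):
                    raise AdjacencyError(f"neighbour index {j} out of range for '{ids[i]}'")
                if i not in nbrs[j]:
                    raise AdjacencyError(
                        f"asymmetric adjacency: '{ids[i]}' lists '{ids[j]}' "
                        f"but not conversely"
                    )

    @property
    def n(self) -> int:
        return len(self.region_ids)

    @property
    def n_neighbours(self) -> np.ndarray:
        """Neighbour count n_delta_i per region."""
        return np.array([len(s) for s in self.neighbours], dtype=int)

    def adjacency_matrix(self) -> sp.csr_array:
        """0/1 symmetric sparse adjacency indicator W."""
        rows, cols = [], []
        for i, s in enumerate(self.neighbours):
            rows.extend([i] * len(s))
            cols.extend(s)
        data = np.ones(len(rows))
        return sp.csr_array((data, (rows, cols)), shape=(self.n, self.n))

    @property
    def component_labels(self) -> np.ndarray:
        """Connected-component label per region."""
        if self.n == 0:
            return np.array([], dtype=int)
        _, labels = connected_components(self.adjacency_matrix(), directed=False)
        return labels

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if self.n else 0

    def index_of(self, region_id: str) -> int:
        try:
            return self.region_ids.index(str(region_id))
        except ValueError:
            raise KeyError(f"unknown region id '{region_id}'") from None

    @classmethod
    def from_neighbour_ids(cls, mapping: dict) -> "RegionGraph":
        """Build from {region_id: [neighbour ids]} preserving insertion order."""
        ids = [str(k) for k in mapping]
        index = {r: i for i, r in enumerate(ids)}
        nbrs = []
        for r in ids:
            row = []
            for nb in mapping[r]:
                nb = str(nb)
                if nb not in index:
                    raise AdjacencyError(f"region '{r}' lists unknown neighbour '{nb}'")
                row.append(index[nb])
            nbrs.append(tuple(row))
        return cls(tuple(ids), tuple(nbrs))


def read_adjacency(path, format: str = "list") -> RegionGraph:
    """Read a region adjacency specification from disk.

    ``format="list"``: UTF-8 text, one region per line, ``id: id id ...``;
    blank lines and ``#`` comments allowed.  ``format="matrix"``: square 0/1
    CSV whose first row and first column hold region ids.

    Asymmetry and self-loops are errors — nothing is symmetrized silently.
    """
    if format == "list":
        mapping: dict = {}
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if ":" not in line:
                    raise AdjacencyError(f"malformed adjacency line: {raw!r}")
                rid, rest = line.split(":", 1)
                rid = rid.strip()
                if rid in mapping:
                    raise AdjacencyError(f"duplicate region line '{rid}'")
                mapping[rid] = rest.split()
        return RegionGraph.from_neighbour_ids(mapping)
    if format == "matrix":
        df = pd.read_csv(path, index_col=0)
        ids = [str(c) for c in df.columns]
        if [str(i) for i in df.index] != ids:
            raise AdjacencyError("matrix row ids do not match column ids")
        mat = df.to_numpy()
        if not np.isin(mat, (0, 1)).all():
            raise AdjacencyError("adjacency matrix cells must be 0 or 1")
        mapping = {
            rid: [ids[j] for j in np.flatnonzero(mat[i])] for i, rid in enumerate(ids)
        }
        return RegionGraph.from_neighbour_ids(mapping)
    raise ValueError(f"unknown adjacency format {format!r}")


def lattice_graph(rows: int, cols: int) -> RegionGraph:
    """Rook-contiguity rectangular lattice with ids ``r{i}c{j}``.

    A standard simulation-study fixture: every interior cell has four
    neighbours, edges three, corners two.
    """
    if rows < 1 or cols < 1:
        raise ValueError("lattice dimensions must be positive")
    ids = [f"r{i}c{j}" for i in range(rows) for j in range(cols)]
    nbrs = []
    for i in range(rows):
        for j in range(cols):
            cell = []
            if i > 0:
                cell.append((i - 1) * cols + j)
            if i < rows - 1:
                cell.append((i + 1) * cols + j)
            if j > 0:
                cell.append(i * cols + j - 1)
            if j < cols - 1:
                cell.append(i * cols + j + 1)
            nbrs.append(tuple(cell))
    return RegionGraph(tuple(ids), tuple(nbrs))
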