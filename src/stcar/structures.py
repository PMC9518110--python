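"""GMRF structure matrices for spatial, temporal and interaction effects.

Every random-effect block has prior precision tau * R for a fixed symmetric
positive-semidefinite structure matrix R:

- ICAR (intrinsic CAR): R = D - W with D = diag(neighbour counts), W the 0/1
  adjacency; rank n - (number of connected components).
- RW1 (first-order random walk): tridiagonal second-difference structure;
  quadratic form sum_t (x_t - x_{t-1})^2; rank Z - 1.
- iid: identity, full rank.
- Knorr-Held space-time interactions (region-major layout, all times of
  region 0 first):
    type I   = iid in both factors -> identity of size n*Z;
    type II  = kron(I_n, R_rw1)    -> per-region independent random walks;
    type III = kron(R_icar, I_Z)   -> per-time independent ICAR fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graphs import RegionGraph

__all__ = [
    "StructureMatrix",
    "icar_structure",
    "rw1_structure",
    "iid_structure",
    "interaction_structure",
    "quadratic_form",
    "psi_index",
]

INTERACTION_TYPES = ("I", "II", "III")


@dataclass(frozen=True)
class StructureMatrix:
    """Sparse symmetric PSD structure matrix with its analytic rank."""

    matrix: sp.csr_array = field(repr=False)
    rank: int
    kind: str

    def __post_init__(self):
        m = sp.csr_array(self.matrix)
        if m.shape[0] != m.shape[1]:
            raise ValueError("structure matrix must be square")
        asym = abs(m - m.T)
        if asym.nnz and asym.max() > 1e-12:
            raise ValueError("structure matrix must be symmetric")
        object.__setattr__(self, "matrix", m)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()


def quadratic_form(R: StructureMatrix, x: np.ndarray) -> float:
    """x^T R x via the sparse matrix."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != R.dim:
        raise ValueError(f"field length {x.size} does not match structure dim {R.dim}")
    return float(x @ (R.matrix @ x))


def icar_structure(graph: RegionGraph) -> StructureMatrix:
    """Intrinsic CAR structure D - W for an areal graph.

    The implied conditionals are u_i | u_-i ~ N(mean of neighbours,
    sigma_u^2 / n_delta_i).  Improper: constants on each connected component
    lie in the null space, hence rank n - #components.
    """
    W = graph.adjacency_matrix()
    D = sp.diags_array(graph.n_neighbours.astype(float))
    R = sp.csr_array(D - W)
    return StructureMatrix(R, rank=graph.n - graph.n_components, kind="icar")


def rw1_structure(Z: int) -> StructureMatrix:
    """First-order random-walk structure on Z ordered time points."""
    if Z < 2:
        raise ValueError("RW1 requires at least 2 time points")
    # D^T D for the (Z-1) x Z first-difference operator D
    diff = sp.diags_array([-np.ones(Z - 1), np.ones(Z - 1)], offsets=[0, 1], shape=(Z - 1, Z))
    R = sp.csr_array(diff.T @ diff)
    return StructureMatrix(R, rank=Z - 1, kind="rw1")


def iid_structure(size: int) -> StructureMatrix:
    if size < 1:
        raise ValueError("size must be positive")
    return StructureMatrix(sp.eye_array(size, format="csr"), rank=size, kind="iid")


def psi_index(i: int, t: int, Z: int) -> int:
    """Flatten (region i, time t) to the region-major interaction index.

    Single authority for the layout convention: psi vectors stack all Z
    times of region 0, then region 1, and so on, matching
    ``psi_matrix.reshape(n * Z)`` for a (n, Z) array.
    """
    return i * Z + t


def interaction_structure(type: str, graph: RegionGraph, Z: int) -> StructureMatrix:
    """Knorr-Held interaction structure of the given type (region-major)."""
    if Z < 2:
        raise ValueError("interaction requires at least 2 time points")
    n = graph.n
    if type == "I":
        return StructureMatrix(sp.eye_array(n * Z, format="csr"), rank=n * Z, kind="interaction_I")
    if type == "II":
        R = sp.csr_array(sp.kron(sp.eye_array(n), rw1_structure(Z).matrix))
        return StructureMatrix(R, rank=n * (Z - 1), kind="interaction_II")
    if type == "III":
        icar = icar_structure(graph)
        R = sp.csr_array(sp.kron(icar.matrix, sp.eye_array(Z)))
        return StructureMatrix(R, rank=Z * icar.rank, kind="interaction_III")
    raise ValueError(f"unknown interaction type {type!r}; expected one of {INTERACTION_TYPES}")
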