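"""Coupling operators on a network and their spectral decomposition.

The dynamics couple nodes through two operators built from the adjacency
matrix A: the graph Laplacian L2 = A - diag(k), which generates Fickian
diffusion along links, and the bi-Laplacian L4 = L2 @ L2, which reaches two
steps into the graph and produces short-range inhibition with longer-range
diffusion.  Both are real, symmetric, share a common orthonormal
eigenbasis, and annihilate the constant vector (the interaction currents
conserve total potential).

The combined interaction current is I = -(2 L2 + L4) u, the network
analogue of the Swift-Hohenberg spatial operator -(2 nabla^2 + nabla^4)
= 1 - (1 + nabla^2)^2 acting on u.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graphs import Network

__all__ = [
    "OperatorMatrix",
    "SpectralDecomposition",
    "laplacian",
    "bilaplacian",
    "coupling",
    "interaction_current",
    "spectrum",
    "export_coordinate_format",
]

#: above this size, full dense eigensolves are replaced by partial ones
DENSE_LIMIT = 3000


class InvalidOperatorError(ValueError):
    """Operator violates the symmetric-matrix contract."""


class DimensionError(ValueError):
    """A nodal vector does not match the network size."""


@dataclass(frozen=True)
class OperatorMatrix:
    """A symmetric N x N coupling operator with zero row sums."""

    matrix: sp.csr_array
    kind: str  # 'laplacian' | 'bilaplacian' | 'coupling'

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def __matmul__(self, u: np.ndarray) -> np.ndarray:
        return self.matrix @ u


@dataclass(frozen=True)
class SpectralDecomposition:
    """Eigenvalues (sorted descending, Lambda_1 = 0 on connected graphs)
    and the matching orthonormal eigenvector columns."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    def __len__(self) -> int:
        return len(self.eigenvalues)


def laplacian(net: Network) -> OperatorMatrix:
    """Graph Laplacian L2 = A - diag(k); negative semi-definite."""
    if "laplacian" not in net._cache:
        a = net.adjacency
        l2 = a - sp.diags_array(net.degrees.astype(float), format="csr")
        net._cache["laplacian"] = OperatorMatrix(sp.csr_array(l2), kind="laplacian")
    return net._cache["laplacian"]


def bilaplacian(net: Network) -> OperatorMatrix:
    """Bi-Laplacian L4 = L2 @ L2 (exact matrix square).

    Shares eigenvectors with L2; its eigenvalues are the squares
    Lambda_alpha^2, hence it is positive semi-definite.  Its support is
    exactly the <=2-step neighbourhood of each node.
    """
    if "bilaplacian" not in net._cache:
        l2 = laplacian(net).matrix
        net._cache["bilaplacian"] = OperatorMatrix(
            sp.csr_array(l2 @ l2), kind="bilaplacian"
        )
    return net._cache["bilaplacian"]


def coupling(net: Network) -> OperatorMatrix:
    """The full interaction operator C = -(2 L2 + L4)."""
    if "coupling" not in net._cache:
        l2 = laplacian(net).matrix
        l4 = bilaplacian(net).matrix
        net._cache["coupling"] = OperatorMatrix(
            sp.csr_array(-(2.0 * l2 + l4)), kind="coupling"
        )
    return net._cache["coupling"]


def interaction_current(net: Network, u: np.ndarray) -> np.ndarray:
    """Interaction current I = -(2 L2 + L4) u.

    Vanishes on constant u and sums to zero for any u (each operator has
    zero column sums), so the coupling only redistributes potential.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (net.node_count,):
        raise DimensionError(
            f"state has shape {u.shape}, expected ({net.node_count},)"
        )
    return coupling(net) @ u


def spectrum(op: OperatorMatrix, count: int | str = "all") -> SpectralDecomposition:
    """Eigen-decomposition of a symmetric operator, sorted descending.

    A dense solve is used for ``count='all'`` (permitted up to
    ``DENSE_LIMIT`` nodes); for larger operators request a partial
    decomposition, computed iteratively from the algebraic top of the
    spectrum.
    """
    m = op.matrix
    n = m.shape[0]
    asym = abs(m - m.T)
    if asym.nnz and asym.max() > 1e-10:
        raise InvalidOperatorError("operator is not symmetric")
    if count == "all":
        if n > DENSE_LIMIT:
            raise InvalidOperatorError(
                f"dense solve requested for N={n} > {DENSE_LIMIT}; "
                "request a partial spectrum instead"
            )
        vals, vecs = np.linalg.eigh(m.toarray())
    else:
        k = int(count)
        if k >= n - 1:
            vals, vecs = np.linalg.eigh(m.toarray())
            vals, vecs = vals[-k:], vecs[:, -k:]
        else:
            vals, vecs = spla.eigsh(m.tocsc(), k=k, which="LA")
    order = np.argsort(vals)[::-1]
    return SpectralDecomposition(eigenvalues=vals[order], eigenvectors=vecs[:, order])


def laplacian_spectrum(net: Network, count: int | str = "all") -> SpectralDecomposition:
    """Cached spectral decomposition of the network Laplacian."""
    key = ("laplacian_spectrum", count)
    if key not in net._cache:
        net._cache[key] = spectrum(laplacian(net), count)
    return net._cache[key]


def export_coordinate_format(op: OperatorMatrix, path) -> None:
    """Write the operator as 'row col value' triplets (one per line)."""
    coo = op.matrix.tocoo()
    with open(path, "w") as fh:
        fh.write(f"# {op.kind} {coo.shape[0]} {coo.shape[1]} {coo.nnz}\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i} {j} {v:.17g}\n")
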