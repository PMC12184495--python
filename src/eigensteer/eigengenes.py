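"""Eigengene basis via SVD of the expression matrix and top-d projection.

For a samples x genes matrix ``Y`` the thin SVD ``Y.T = U S V.T`` yields
orthonormal gene-space directions (eigengenes) as the columns of ``U``.
Projection keeps the ``d`` eigengenes with the largest singular values:
``X = Y @ U[:, :d]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EigengeneBasis", "ProjectedData", "compute_basis", "project",
           "variance_remaining"]

DEFAULT_D = 200


@dataclass
class EigengeneBasis:
    U: np.ndarray  # genes x l, orthonormal columns (eigengenes)
    singular_values: np.ndarray  # length l, descending
    V: np.ndarray  # samples x l right factor of Y.T
    l: int

    @property
    def n_genes(self) -> int:
        return self.U.shape[0]


@dataclass
class ProjectedData:
    X: np.ndarray  # samples x d
    d: int
    eigengene_indices: np.ndarray


def compute_basis(Y: np.ndarray, center: bool = False) -> EigengeneBasis:
    """Thin SVD of ``Y.T`` with a deterministic column-sign convention.

    Signs are fixed so the largest-magnitude entry of each eigengene is
    positive (SVD signs are otherwise arbitrary), which makes downstream
    perturbation-library coordinates reproducible.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be a 2-D samples x genes matrix")
    if not np.isfinite(Y).all():
        raise ValueError("Y contains non-finite entries")
    if center:
        Y = Y - Y.mean(axis=0, keepdims=True)

    U, s, Vt = np.linalg.svd(Y.T, full_matrices=False)
    # sign convention: largest-|entry| of each column of U made positive
    flip_idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[flip_idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs
    Vt = Vt * signs[:, None]
    return EigengeneBasis(U=U, singular_values=s, V=Vt.T, l=len(s))


def project(Y: np.ndarray, basis: EigengeneBasis, d: int = DEFAULT_D) -> ProjectedData:
    """Project samples onto the top-``d`` eigengenes: ``X = Y U[:, :d]``."""
    if d > basis.l:
        raise ValueError(f"d={d} exceeds available rank l={basis.l}")
    if d < 0:
        raise ValueError("d must be non-negative")
    X = np.asarray(Y, dtype=float) @ basis.U[:, :d]
    return ProjectedData(X=X, d=d, eigengene_indices=np.arange(d))


def variance_remaining(basis: EigengeneBasis, d: int) -> float:
    """Fraction of squared-singular-value mass beyond the first ``d``."""
    if d > basis.l:
        raise ValueError(f"d={d} exceeds available rank l={basis.l}")
    sq = basis.singular_values**2
    total = sq.sum()
    if total == 0:
        return 0.0
    return float(sq[d:].sum() / total)
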