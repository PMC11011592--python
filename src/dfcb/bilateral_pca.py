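"""Bilateral two-dimensional PCA ((2D)²PCA) and its one-directional variants.

Each subject is represented by one n_edges×U matrix A (edge spectra, or
raw edge time courses). Classical PCA would flatten A and lose its 2-D
structure; 2DPCA instead learns projections directly on the matrix:

* a column-direction (temporal) projection X — the top-d eigenvectors of
  the column covariance G_col = (1/M) Σ_k (A_k − Ā)ᵀ(A_k − Ā)  (U×U);
* a row-direction (spatial) projection Z — the top-q eigenvectors of the
  row covariance   G_row = (1/M) Σ_k (A_k − Ā)(A_k − Ā)ᵀ  (n_edges×n_edges).

The bilateral representation is C = Zᵀ A X (q×d), compressing both the
edge (spatial) and frequency (temporal) directions at once. Retained
dimensions d and q are the smallest counts whose leading eigenvalues
capture a fraction θ of the total eigenvalue mass.

Projection is applied to the raw A, not A − Ā: shifting every subject by
the constant ZᵀĀX leaves two-sample statistics and linear decision rules
unchanged, and keeping the raw projection matches the feature definition
used downstream. Ā is stored for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProjectionPair",
    "mean_matrix",
    "col_covariance",
    "row_covariance",
    "select_dim",
    "fit",
    "project",
    "project_rows_only",
    "project_cols_only",
    "reconstruct",
]


@dataclass
class ProjectionPair:
    """Fitted bilateral projections with eigenvalues and the training mean."""

    Z: np.ndarray  # (n_edges, q) spatial projection
    X: np.ndarray  # (U, d) temporal projection
    eig_row: np.ndarray  # descending, length n_edges
    eig_col: np.ndarray  # descending, length U
    q: int
    d: int
    mean_matrix: np.ndarray  # (n_edges, U)

    @property
    def n_edges(self) -> int:
        return self.Z.shape[0]

    @property
    def U(self) -> int:
        return self.X.shape[0]


def _as_stack(train: list[np.ndarray] | np.ndarray) -> np.ndarray:
    stack = np.asarray(train, dtype=float)
    if stack.ndim != 3:
        raise ValueError("training set must be a list of equal-shape 2-D matrices")
    return stack


def mean_matrix(train: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean Ā of the training matrices."""
    stack = _as_stack(train)
    if stack.shape[0] == 0:
        raise ValueError("empty training set")
    return stack.mean(axis=0)


def col_covariance(train: list[np.ndarray]) -> np.ndarray:
    """U×U column covariance (1/M) Σ (A_k − Ā)ᵀ(A_k − Ā)."""
    stack = _as_stack(train)
    M = stack.shape[0]
    if M < 2:
        raise ValueError("column covariance needs ≥ 2 training matrices")
    centered = stack - stack.mean(axis=0)
    G = np.einsum("kiu,kiv->uv", centered, centered) / M
    return (G + G.T) / 2.0


def row_covariance(train: list[np.ndarray]) -> np.ndarray:
    """n_edges×n_edges row covariance (1/M) Σ (A_k − Ā)(A_k − Ā)ᵀ."""
    stack = _as_stack(train)
    M = stack.shape[0]
    if M < 2:
        raise ValueError("row covariance needs ≥ 2 training matrices")
    centered = stack - stack.mean(axis=0)
    G = np.einsum("kiu,kju->ij", centered, centered) / M
    return (G + G.T) / 2.0


def select_dim(eigenvalues: np.ndarray, theta: float) -> int:
    """Smallest d with Σ_{i≤d} λ_i / Σ λ_i ≥ θ, eigenvalues descending."""
    if not (0 < theta <= 1):
        raise ValueError(f"theta must be in (0, 1], got {theta}")
    lam = np.asarray(eigenvalues, dtype=float)
    lam = np.clip(lam, 0.0, None)  # covariance spectra: tiny negatives are noise
    total = lam.sum()
    if total <= 0:
        raise ValueError("all-zero eigenvalue spectrum: no dimension to retain")
    ratios = np.cumsum(lam) / total
    ratios[-1] = 1.0  # guard against cumsum rounding below θ = 1
    return int(np.searchsorted(ratios, theta, side="left") + 1)


def _sorted_eig(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a symmetric matrix, descending, sign-fixed.

    Sign convention: each eigenvector's largest-magnitude entry is made
    positive (ties by lowest index), so fits are reproducible across
    platforms. Ties in eigenvalues keep ascending-index order within the
    tied block (tied subspaces are basis-dependent regardless).
    """
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(-vals, kind="stable")
    vals = vals[order]
    vecs = vecs[:, order]
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vals, vecs * signs


def fit(
    train: list[np.ndarray], theta_row: float = 0.95, theta_col: float = 0.95
) -> ProjectionPair:
    """Fit the bilateral projection pair on training matrices."""
    stack = _as_stack(train)
    if stack.shape[0] < 2:
        raise ValueError("fitting needs ≥ 2 training matrices")
    G_col = col_covariance(stack)
    G_row = row_covariance(stack)
    eig_col, V_col = _sorted_eig(G_col)
    eig_row, V_row = _sorted_eig(G_row)
    d = select_dim(eig_col, theta_col)
    q = select_dim(eig_row, theta_row)
    return ProjectionPair(
        Z=V_row[:, :q],
        X=V_col[:, :d],
        eig_row=eig_row,
        eig_col=eig_col,
        q=q,
        d=d,
        mean_matrix=stack.mean(axis=0),
    )


def _check_shape(A: np.ndarray, pair: ProjectionPair) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.shape != (pair.n_edges, pair.U):
        raise ValueError(
            f"matrix shape {A.shape} does not match fitted ({pair.n_edges}, {pair.U})"
        )
    return A


def project(A: np.ndarray, pair: ProjectionPair) -> np.ndarray:
    """Bilateral feature matrix C = Zᵀ A X (q×d)."""
    A = _check_shape(A, pair)
    return pair.Z.T @ A @ pair.X


def project_rows_only(A: np.ndarray, pair: ProjectionPair) -> np.ndarray:
    """Temporal-direction 2DPCA variant: Y = A X (n_edges×d)."""
    A = _check_shape(A, pair)
    return A @ pair.X


def project_cols_only(A: np.ndarray, pair: ProjectionPair) -> np.ndarray:
    """Spatial-direction 2DPCA variant: B = Zᵀ A (q×U)."""
    A = _check_shape(A, pair)
    return pair.Z.T @ A


def reconstruct(C: np.ndarray, pair: ProjectionPair) -> np.ndarray:
    """Back-projection Z C Xᵀ; exact when q, d span the full spaces."""
    C = np.asarray(C, dtype=float)
    if C.shape != (pair.q, pair.d):
        raise ValueError(f"feature shape {C.shape} does not match ({pair.q}, {pair.d})")
    return pair.Z @ C @ pair.X.T
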