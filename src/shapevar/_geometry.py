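"""Shared geometric and matrix utilities.

Landmark configurations are (k, 2) arrays; flattened shape vectors use the
interleaved order [x1, y1, x2, y2, ...] so that ``coords.reshape(-1)`` and
``vec.reshape(k, 2)`` are inverses.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import null_space


def centroid(coords: np.ndarray) -> np.ndarray:
    return coords.mean(axis=0)


def centroid_size(coords: np.ndarray) -> float:
    """Root summed squared distances of landmarks from their centroid."""
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


def center(coords: np.ndarray) -> np.ndarray:
    return coords - coords.mean(axis=0)


def normalize(coords: np.ndarray) -> np.ndarray:
    """Center and scale to unit centroid size."""
    c = center(coords)
    size = np.sqrt((c**2).sum())
    if size == 0:
        raise ValueError("degenerate configuration: zero centroid size")
    return c / size


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation matrix R (det +1, no reflection) minimizing ||source @ R - target||.

    Ties in the SVD are broken by forcing det(R) = +1.
    """
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    if d == 0:
        d = 1.0
    s = np.ones(source.shape[1])
    s[-1] = d
    return (u * s) @ vt


def similarity_constraint_basis(mean_shape: np.ndarray) -> np.ndarray:
    """Orthonormal 4 x p basis of the similarity transformations at a shape.

    Rows span translation (2), in-plane rotation (1) and scale (1) directions
    of the flattened coordinate space, evaluated at the centered ``mean_shape``.
    """
    k = mean_shape.shape[0]
    m = center(mean_shape)
    p = 2 * k
    t1 = np.zeros(p)
    t1[0::2] = 1.0
    t2 = np.zeros(p)
    t2[1::2] = 1.0
    scale = m.reshape(-1).astype(float)
    rot = np.column_stack([-m[:, 1], m[:, 0]]).reshape(-1)
    basis = np.stack([t1, t2, scale, rot])
    # Gram-Schmidt; the four are already orthogonal for a centered shape but
    # orthonormalize defensively.
    q, _ = np.linalg.qr(basis.T)
    return q.T[:4]


def tangent_basis(mean_shape: np.ndarray) -> np.ndarray:
    """Orthonormal p x (p-4) basis of the shape tangent space at ``mean_shape``.

    Columns are orthogonal to translation, rotation and scaling of the mean
    shape, i.e. they span the (2k - 4)-dimensional space in which Procrustes
    shape variation lives.
    """
    constraints = similarity_constraint_basis(mean_shape)
    basis = null_space(constraints)
    if basis.shape[1] != mean_shape.shape[0] * 2 - 4:
        raise ValueError("unexpected tangent-space dimension")
    return basis


def project_to_tangent(mat_or_vec: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Project a p-vector or p x p matrix onto span(basis) (still p-dim)."""
    proj = basis @ basis.T
    if mat_or_vec.ndim == 1:
        return proj @ mat_or_vec
    return proj @ mat_or_vec @ proj


# ---------------------------------------------------------------------------
# symmetric-matrix helpers


def vech(mat: np.ndarray) -> np.ndarray:
    """Half-vectorization (lower triangle, column-major over rows)."""
    idx = np.tril_indices(mat.shape[0])
    return mat[idx]


def unvech(v: np.ndarray, p: int) -> np.ndarray:
    mat = np.zeros((p, p))
    idx = np.tril_indices(p)
    mat[idx] = v
    mat = mat + mat.T - np.diag(np.diag(mat))
    return mat


def vech_indices(p: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(p) for j in range(i + 1)]


def wishart_vech_cov(v_mat: np.ndarray, df: float) -> np.ndarray:
    """Asymptotic covariance of vech(S/df) when S ~ Wishart(df, V).

    Cov(V̂_ij, V̂_kl) = (V_ik V_jl + V_il V_jk) / df.
    """
    pairs = vech_indices(v_mat.shape[0])
    n = len(pairs)
    cov = np.empty((n, n))
    for a, (i, j) in enumerate(pairs):
        for b, (k, l) in enumerate(pairs):
            cov[a, b] = (v_mat[i, k] * v_mat[j, l] + v_mat[i, l] * v_mat[j, k]) / df
    return cov


def nearest_psd(mat: np.ndarray) -> tuple[np.ndarray, bool]:
    """Project a symmetric matrix to the nearest PSD matrix (eigenvalue clipping).

    Returns (projected matrix, clipped flag).
    """
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= 0:
        return sym, False
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T, True


def effective_rank(mat: np.ndarray, rel_tol: float = 1e-8) -> int:
    """Number of eigenvalues above rel_tol times the largest."""
    vals = np.linalg.eigvalsh(0.5 * (mat + mat.T))
    top = vals.max(initial=0.0)
    if top <= 0:
        return 0
    return int((vals > rel_tol * top).sum())


def signed_polygon_area(coords: np.ndarray) -> float:
    """Shoelace signed area of the landmark polygon (in landmark order)."""
    x, y = coords[:, 0], coords[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
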