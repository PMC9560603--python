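"""Periodic-distance and rigid-superposition primitives.

Minimum-image distances are implemented for orthorhombic boxes only;
triclinic boxes are rejected upstream.  Superposition is the standard
least-squares (Kabsch) fit via singular value decomposition.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "min_image_sqdist",
    "pairwise_contact_matrix",
    "kabsch",
    "apply_transform",
]


def min_image_sqdist(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Squared minimum-image distances between point sets.

    Parameters
    ----------
    a, b:
        ``(..., na, 3)`` and ``(..., nb, 3)`` coordinates.
    box:
        Orthorhombic box lengths ``(3,)`` (or broadcastable).

    Returns
    -------
    ``(..., na, nb)`` squared distances.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    box = np.asarray(box, dtype=a.dtype)
    d2 = np.zeros(a.shape[:-1] + (b.shape[-2],), dtype=np.result_type(a, b))
    for axis in range(3):
        dx = a[..., :, None, axis] - b[..., None, :, axis]
        L = box[..., axis]
        dx -= L * np.round(dx / L)
        d2 += dx * dx
    return d2


def pairwise_contact_matrix(
    a: np.ndarray, b: np.ndarray, box: np.ndarray, cutoff: float
) -> np.ndarray:
    """Boolean minimum-image contact matrix ``dist(a_i, b_j) <= cutoff``."""
    return min_image_sqdist(a, b, box) <= cutoff * cutoff


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` minimises the RMSD
    to ``reference``.  Requires at least three non-collinear points;
    reflections are excluded by the usual determinant correction.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    Pc = P.mean(axis=0)
    Qc = Q.mean(axis=0)
    P0 = P - Pc
    Q0 = Q - Qc
    # collinearity check: rank of the centred cloud must exceed 1
    if np.linalg.matrix_rank(P0, tol=1e-8 * max(1.0, np.abs(P0).max())) < 2:
        raise ValueError("selection is collinear; rotation underdetermined")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Qc - Pc @ R.T
    return R, t


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ R.T + t
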