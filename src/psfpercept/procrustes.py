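"""Procrustes superimposition of point configurations.

Finds the similarity transform (rotation/reflection, dilation, translation)
of a target configuration that best matches a reference in least squares,
and quantifies concordance via a Tucker-style congruence coefficient on the
aligned coordinates and a distance-based configuration correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist


@dataclass
class ProcrustesResult:
    aligned: np.ndarray  # transformed target, same frame as reference
    rotation: np.ndarray  # orthogonal (det +/- 1 if reflections allowed)
    scale: float
    translation: np.ndarray
    residual: float  # sum of squared coordinate differences
    congruence: float


def _check_pair(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"configuration shapes differ: {X.shape} vs {Y.shape}")
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("configurations must be (n >= 2) x ndim arrays")
    return X, Y


def procrustes_align(
    X: np.ndarray, Y: np.ndarray, allow_reflection: bool = True
) -> ProcrustesResult:
    """Least-squares similarity alignment of Y onto X.

    Solves min over (s > 0, orthogonal Q, t) of
    sum_i || x_i - (s * y_i Q + t) ||^2 in closed form via the SVD of the
    centered cross-covariance. With ``allow_reflection=False`` the rotation
    is constrained to det(Q) = +1 (Kabsch correction).
    """
    X, Y = _check_pair(X, Y)
    xc = X - X.mean(axis=0)
    yc = Y - Y.mean(axis=0)
    norm_y2 = float(np.sum(yc**2))
    norm_x2 = float(np.sum(xc**2))
    if norm_y2 == 0 or norm_x2 == 0:
        raise ValueError("all points coincident; rotation undefined")
    u, sv, vt = np.linalg.svd(yc.T @ xc)
    signs = np.ones(len(sv))
    q = u @ vt
    if not allow_reflection and np.linalg.det(q) < 0:
        signs[-1] = -1.0
        q = (u * signs) @ vt
    trace = float(np.sum(sv * signs))
    scale = trace / norm_y2
    if scale <= 0:
        raise ValueError("optimal dilation is non-positive; configurations oppose")
    translation = X.mean(axis=0) - scale * (Y.mean(axis=0) @ q)
    aligned = scale * (Y @ q) + translation
    residual = float(np.sum((X - aligned) ** 2))
    yprime = aligned - aligned.mean(axis=0)
    congruence = float(
        np.sum(xc * yprime) / np.sqrt(np.sum(xc**2) * np.sum(yprime**2))
    )
    return ProcrustesResult(
        aligned=aligned,
        rotation=q,
        scale=scale,
        translation=translation,
        residual=residual,
        congruence=congruence,
    )


def congruence_coefficient(
    X: np.ndarray, Y: np.ndarray, allow_reflection: bool = True
) -> float:
    """Tucker-style congruence of two configurations after centering and
    Procrustes alignment: sum_i <x_i, y'_i> / sqrt(sum |x_i|^2 sum |y'_i|^2).

    Equals 1 (within rounding) whenever Y is a similarity transform of X.
    """
    return procrustes_align(X, Y, allow_reflection=allow_reflection).congruence


def configuration_correlation(X: np.ndarray, Y: np.ndarray) -> float | None:
    """Pearson correlation between the vectorized inter-point distance
    matrices of X and Y; invariant to similarity transforms by construction.
    Returns None when either distance vector is constant."""
    X, Y = _check_pair(X, Y)
    dx = pdist(X)
    dy = pdist(Y)
    # constant up to floating-point noise counts as constant
    if np.std(dx) <= 1e-12 * max(dx.mean(), 1e-300) or np.std(dy) <= 1e-12 * max(
        dy.mean(), 1e-300
    ):
        return None
    r, _ = stats.pearsonr(dx, dy)
    return float(r)
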