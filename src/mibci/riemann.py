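"""Geometry of symmetric positive-definite (SPD) matrices.

Spatial covariance matrices of EEG epochs live on the SPD manifold; the
classifiers in :mod:`mibci.classify` rely on the affine-invariant
Riemannian metric (AIRM)

    delta(A, B) = || log(A^{-1/2} B A^{-1/2}) ||_F ,

its Fréchet (Karcher) mean, and the logarithmic/exponential maps between
the manifold and the tangent space at a base point. All matrix log/exp
go through eigendecomposition of symmetrized inputs.

``geodesic_filter`` implements tangent-space Fisher filtering: matrices
are mapped to the tangent space at their global Fréchet mean, projected
onto the leading Fisher discriminant subspace (dimension ``d``, default
1 for two classes), and retracted back to the manifold. It denoises the
between-class geometry before a minimum-distance classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .errors import ConvergenceError, ValidationError

logger = logging.getLogger(__name__)

SYM_TOL = 1e-10


def check_spd(a: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Validate symmetry and positive-definiteness; returns the symmetrized array."""
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError(f"{name} must be square, got shape {a.shape}")
    scale = max(np.abs(a).max(), 1.0)
    if np.abs(a - a.T).max() > SYM_TOL * scale:
        raise ValidationError(f"{name} is not symmetric within tolerance")
    a = 0.5 * (a + a.T)
    w = np.linalg.eigvalsh(a)
    if w[0] <= 0:
        raise ValidationError(f"{name} is not positive definite (min eigenvalue {w[0]:.3e})")
    return a


def regularize_spd(a: np.ndarray) -> np.ndarray:
    """Make a symmetric PSD matrix strictly SPD: add eps*I, eps = 1e-10 tr/C."""
    a = 0.5 * (np.asarray(a, dtype=float) + np.asarray(a, dtype=float).T)
    w = np.linalg.eigvalsh(a)
    if w[0] > 0:
        return a
    c = a.shape[0]
    eps = 1e-10 * np.trace(a) / c
    if eps <= 0:
        raise ValidationError("matrix has non-positive trace; cannot regularize")
    while np.linalg.eigvalsh(a + eps * np.eye(c))[0] <= 0:
        eps *= 10.0
    return a + eps * np.eye(c)


def _eigh_fun(a: np.ndarray, fun) -> np.ndarray:
    w, v = np.linalg.eigh(0.5 * (a + a.T))
    return (v * fun(w)) @ v.T


def spd_logm(a: np.ndarray) -> np.ndarray:
    return _eigh_fun(a, np.log)


def spd_expm(s: np.ndarray) -> np.ndarray:
    return _eigh_fun(s, np.exp)


def spd_sqrtm(a: np.ndarray) -> np.ndarray:
    return _eigh_fun(a, np.sqrt)


def spd_invsqrtm(a: np.ndarray) -> np.ndarray:
    return _eigh_fun(a, lambda w: 1.0 / np.sqrt(w))


def airm_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Affine-invariant Riemannian distance between two SPD matrices.

    Computed from the generalized eigenvalues of (B, A):
    delta = sqrt(sum_i log^2 lambda_i), which equals
    ||log(A^{-1/2} B A^{-1/2})||_F and is invariant under congruence
    A -> G A G^T, B -> G B G^T.
    """
    a = check_spd(a, "a")
    b = check_spd(b, "b")
    lam = sla.eigh(b, a, eigvals_only=True)
    return float(np.sqrt(np.sum(np.log(lam) ** 2)))


def frechet_mean(
    matrices, tol: float = 1e-8, max_iter: int = 50
) -> np.ndarray:
    """Karcher/Fréchet mean of SPD matrices under the AIRM.

    Fixed-point iteration M <- M^{1/2} exp(mean_i log(M^{-1/2} S_i
    M^{-1/2})) M^{1/2}, initialized at the arithmetic mean with unit step
    size; converged when the Frobenius norm of the mean tangent vector
    (the gradient) is <= tol.
    """
    mats = [check_spd(m, f"matrix {i}") for i, m in enumerate(matrices)]
    if len(mats) == 0:
        raise ValidationError("need at least one matrix")
    if len(mats) == 1:
        return mats[0].copy()
    arr = np.stack(mats)
    m = arr.mean(axis=0)
    grad_norm = np.inf
    for _ in range(max_iter):
        m_half = spd_sqrtm(m)
        m_ihalf = spd_invsqrtm(m)
        logs = np.stack([spd_logm(m_ihalf @ s @ m_ihalf) for s in arr])
        g = logs.mean(axis=0)
        grad_norm = float(np.linalg.norm(g))
        m = m_half @ spd_expm(g) @ m_half
        m = 0.5 * (m + m.T)
        if grad_norm <= tol:
            return m
    raise ConvergenceError(
        f"Karcher mean did not converge in {max_iter} iterations "
        f"(last gradient norm {grad_norm:.3e})",
        last_gradient_norm=grad_norm,
    )


def tangent_map(base: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Logarithmic map of ``x`` at ``base``: S = log(base^{-1/2} x base^{-1/2})."""
    base = check_spd(base, "base")
    x = check_spd(x, "x")
    b_ihalf = spd_invsqrtm(base)
    s = spd_logm(b_ihalf @ x @ b_ihalf)
    return 0.5 * (s + s.T)


def tangent_retract(base: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Exponential map (inverse of :func:`tangent_map`)."""
    base = check_spd(base, "base")
    b_half = spd_sqrtm(base)
    x = b_half @ spd_expm(0.5 * (s + s.T)) @ b_half
    return 0.5 * (x + x.T)


def tangent_vectorize(s: np.ndarray) -> np.ndarray:
    """Flatten a symmetric matrix to length C(C+1)/2, off-diagonals scaled by sqrt(2).

    The scaling makes the Euclidean norm of the vector equal the
    Frobenius norm of the matrix, so Euclidean classifiers in the vector
    space respect tangent-space geometry.
    """
    s = np.asarray(s, dtype=float)
    c = s.shape[0]
    if np.abs(s - s.T).max() > SYM_TOL * max(np.abs(s).max(), 1.0):
        raise ValidationError("input must be symmetric")
    iu, ju = np.triu_indices(c)
    v = s[iu, ju].copy()
    v[iu != ju] *= np.sqrt(2.0)
    return v


def tangent_devectorize(v: np.ndarray, c: int) -> np.ndarray:
    """Inverse of :func:`tangent_vectorize`."""
    iu, ju = np.triu_indices(c)
    s = np.zeros((c, c))
    vals = np.asarray(v, dtype=float).copy()
    off = iu != ju
    vals[off] /= np.sqrt(2.0)
    s[iu, ju] = vals
    s[ju, iu] = vals
    return s


@dataclass
class GeodesicFilterModel:
    """Fitted tangent-space Fisher filter.

    Attributes
    ----------
    base : ndarray
        Global Fréchet mean of the training matrices (projection point).
    subspace : ndarray, shape (n_features, d)
        Orthonormal basis of the retained discriminant subspace in the
        vectorized tangent space.
    """

    base: np.ndarray
    subspace: np.ndarray

    def transform(self, matrices) -> list[np.ndarray]:
        """Project matrices onto the discriminant subspace and retract."""
        c = self.base.shape[0]
        out = []
        proj = self.subspace @ self.subspace.T
        for m in matrices:
            v = tangent_vectorize(tangent_map(self.base, m))
            out.append(tangent_retract(self.base, tangent_devectorize(proj @ v, c)))
        return out


def geodesic_filter(
    matrices, labels, d: int = 1, ridge: float = 1e-9
) -> tuple[GeodesicFilterModel, list[np.ndarray]]:
    """Fit a tangent-space Fisher filter and return filtered training matrices.

    The training set is mapped to the tangent space at its global Fréchet
    mean; a Fisher discriminant subspace of dimension ``d`` is fit on the
    vectorized tangent vectors (within-class scatter is
    ridge-regularized if singular, with a logged warning); vectors are
    projected onto the subspace and retracted back to the manifold.
    ``d`` equal to the full tangent dimension makes the filter the
    identity.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValidationError(f"geodesic filtering needs exactly 2 classes, got {len(classes)}")
    for cl in classes:
        if np.sum(labels == cl) < 2:
            raise ValidationError(f"class {cl!r} has fewer than 2 matrices")
    base = frechet_mean(matrices)
    vecs = np.stack([tangent_vectorize(tangent_map(base, m)) for m in matrices])
    n_feat = vecs.shape[1]
    if not 1 <= d <= n_feat:
        raise ValidationError(f"subspace dimension d={d} outside 1..{n_feat}")
    if d == n_feat:
        subspace = np.eye(n_feat)
    else:
        mu = [vecs[labels == cl].mean(axis=0) for cl in classes]
        sw = np.zeros((n_feat, n_feat))
        for cl, m in zip(classes, mu):
            x = vecs[labels == cl] - m
            sw += x.T @ x
        diff = mu[0] - mu[1]
        sb = np.outer(diff, diff)
        lam = ridge * np.trace(sw) / n_feat
        if np.linalg.matrix_rank(sw) < n_feat:
            logger.warning("within-class scatter singular; ridge-regularizing")
            lam = max(lam, 1e-6 * max(np.trace(sw) / n_feat, 1.0))
        sw += lam * np.eye(n_feat)
        if d == 1:
            w = np.linalg.solve(sw, diff)
            dirs = w[:, None]
        else:
            evals, evecs = sla.eigh(sb, sw)
            dirs = evecs[:, ::-1][:, :d]
        subspace, _ = np.linalg.qr(dirs)
    model = GeodesicFilterModel(base=base, subspace=subspace)
    return model, model.transform(matrices)
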