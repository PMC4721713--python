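"""Constrained total-least-squares ellipse fitting.

The conic Ax^2 + Bxy + Cy^2 + Dx + Ey + F = 0 is fitted under A + C = 1,
which turns each boundary point into one row of the linear system

    B*(x*y) + C*(y^2 - x^2) + D*x + E*y + F = -x^2.

The intercept F is removed by centering the regressors about their means
and recovered afterwards as F = beta_bar - alpha_bar . tau'.  The centered
system X tau' = Z is solved in the total-least-squares sense,

    tau' = (X^T X - gamma_min^2 I)^(-1) X^T Z,

with gamma_min the smallest singular value of the augmented matrix
L = [-Z, X], obtained from a self-contained cyclic Jacobi eigen solver on
Q = L^T L.  The pupil center follows from the conic coefficients:

    xp = (B*E - 2*C*D) / (4*A*C - B^2),  yp = (B*D - 2*A*E) / (4*A*C - B^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import DetectionError

__all__ = [
    "EllipseParams",
    "TlsSystem",
    "EigenResult",
    "build_system",
    "jacobi_eigen",
    "tls_solve",
    "ls_solve",
    "recover_F",
    "ellipse_center",
    "fit_ellipse",
    "sensitivity_ratio",
    "conic_to_geometric",
]

MIN_POINTS = 6


@dataclass(frozen=True)
class EllipseParams:
    """Conic coefficients under the normalization A + C = 1."""

    b: float
    c: float
    d: float
    e: float
    f: float
    diagnostics: dict = field(default_factory=dict, compare=False)

    @property
    def a(self) -> float:
        return 1.0 - self.c

    @property
    def discriminant(self) -> float:
        return 4.0 * self.a * self.c - self.b * self.b

    @property
    def center(self) -> tuple:
        return ellipse_center(self)

    def residual(self, x, y):
        """Conic value at (x, y); zero on the fitted curve."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (self.a * x * x + self.b * x * y + self.c * y * y
                + self.d * x + self.e * y + self.f)


@dataclass(frozen=True)
class TlsSystem:
    """Centered design matrix X (n×4), centered response Z and the means."""

    X: np.ndarray
    Z: np.ndarray
    alpha_bar: np.ndarray  # means of (xy, y^2-x^2, x, y)
    beta_bar: float        # mean of -x^2

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def L(self) -> np.ndarray:
        """Augmented matrix [-Z, X]."""
        return np.column_stack([-self.Z, self.X])


@dataclass(frozen=True)
class EigenResult:
    eigenvalues: np.ndarray   # descending
    eigenvectors: np.ndarray  # orthonormal columns, matching order
    singular_values: np.ndarray  # sqrt of eigenvalues clipped at 0


def build_system(points) -> TlsSystem:
    """Build the centered regression system from boundary points.

    ``points`` is an (n, 2) array-like of (x, y), or a sequence of objects
    with ``.x``/``.y`` attributes.
    """
    pts = _as_xy(points)
    n = pts.shape[0]
    if n < MIN_POINTS:
        raise DetectionError("fit", f"insufficient boundary points: {n} < {MIN_POINTS}")
    x, y = pts[:, 0], pts[:, 1]
    alpha = np.column_stack([x * y, y * y - x * x, x, y])
    beta = -x * x
    alpha_bar = alpha.mean(axis=0)
    beta_bar = float(beta.mean())
    X = alpha - alpha_bar
    Z = beta - beta_bar
    if _rank(X) < 4:
        raise DetectionError("fit", "degenerate point configuration (rank < 4)")
    return TlsSystem(X=X, Z=Z, alpha_bar=alpha_bar, beta_bar=beta_bar)


def _as_xy(points) -> np.ndarray:
    try:
        pts = np.asarray(points, dtype=float)
    except (TypeError, ValueError):
        pts = None
    if pts is None or pts.ndim != 2 or pts.shape[1] != 2:
        pts = np.array([[p.x, p.y] for p in points], dtype=float)
    return pts


def _rank(X: np.ndarray, rtol: float = 1e-14) -> int:
    # rtol separates exact degeneracy (eigenvalue ratio ~1e-21 for collinear
    # points) from mere bad conditioning at pixel-scale coordinates (~1e-11)
    eig = jacobi_eigen(X.T @ X)
    lam = eig.eigenvalues
    if lam[0] <= 0:
        return 0
    return int(np.sum(lam > rtol * lam[0]))


def jacobi_eigen(Q: np.ndarray, max_sweeps: int = 50, tol: float = 1e-12
                 ) -> EigenResult:
    """Cyclic Jacobi eigen-decomposition of a symmetric matrix.

    Rotations over all index pairs annihilate off-diagonal entries until the
    off-diagonal Frobenius norm falls below ``tol * ||Q||_F`` (or 50 sweeps,
    which is unreachable for the small matrices used here).
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {Q.shape}")
    norm = np.linalg.norm(Q)
    if np.linalg.norm(Q - Q.T) > 1e-9 * max(norm, 1.0):
        raise ValueError("matrix is not symmetric")
    n = Q.shape[0]
    A = 0.5 * (Q + Q.T)
    V = np.eye(n)
    if norm == 0.0:
        return _eigen_sorted(np.zeros(n), V)

    for _ in range(max_sweeps):
        # off-diagonal Frobenius norm, computed directly (no cancellation)
        off = math.sqrt(float(np.sum((A - np.diag(np.diag(A))) ** 2)))
        if off <= tol * norm:
            break
        for s in range(n - 1):
            for t in range(s + 1, n):
                ast = A[s, t]
                if abs(ast) <= 1e-300:
                    continue
                # classic Jacobi rotation annihilating A[s, t]
                theta = (A[t, t] - A[s, s]) / (2.0 * ast)
                sign = 1.0 if theta >= 0 else -1.0
                if abs(theta) > 1e150:  # avoid overflow in theta^2
                    tau = sign / (2.0 * abs(theta))
                else:
                    tau = sign / (abs(theta) + math.sqrt(1.0 + theta * theta))
                c = 1.0 / math.sqrt(1.0 + tau * tau)
                sn = tau * c
                rows, cols = A[s, :].copy(), A[t, :].copy()
                A[s, :] = c * rows - sn * cols
                A[t, :] = sn * rows + c * cols
                cs, ct = A[:, s].copy(), A[:, t].copy()
                A[:, s] = c * cs - sn * ct
                A[:, t] = sn * cs + c * ct
                A[s, t] = A[t, s] = 0.0
                vs, vt = V[:, s].copy(), V[:, t].copy()
                V[:, s] = c * vs - sn * vt
                V[:, t] = sn * vs + c * vt
    else:
        raise ArithmeticError("Jacobi iteration did not converge in 50 sweeps")
    return _eigen_sorted(np.diag(A).copy(), V)


def _eigen_sorted(lam: np.ndarray, V: np.ndarray) -> EigenResult:
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    V = V[:, order]
    sing = np.sqrt(np.clip(lam, 0.0, None))
    return EigenResult(eigenvalues=lam, eigenvectors=V, singular_values=sing)


def tls_solve(X: np.ndarray, Z: np.ndarray, cond_limit: float = 1e12):
    """TLS solution of ``X tau = Z`` via deflated normal equations.

    Returns ``(tau, info)``; ``info`` records gamma_min and any numerical
    fallback applied (ridge, or ordinary least squares when the deflated
    matrix is singular).
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float).ravel()
    L = np.column_stack([-Z, X])
    gamma2 = float(max(jacobi_eigen(L.T @ L).eigenvalues[-1], 0.0))
    XtX = X.T @ X
    XtZ = X.T @ Z
    m = X.shape[1]
    info = {"gamma_min": math.sqrt(gamma2), "ridge": 0.0, "fallback_ls": False}

    def _cond(M):
        lam = jacobi_eigen(M).eigenvalues
        lo = lam[-1]
        return np.inf if lo <= 0 else lam[0] / lo

    A = XtX - gamma2 * np.eye(m)
    if _cond(A) > cond_limit:
        ridge = 1e-10 * np.trace(XtX) / m
        A = A + ridge * np.eye(m)
        info["ridge"] = ridge
        if _cond(A) > cond_limit:
            A = XtX  # gamma_min := 0, plain least squares
            info["fallback_ls"] = True
            info["gamma_min"] = 0.0
    tau = np.linalg.solve(A, XtZ)
    return tau, info


def ls_solve(X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Ordinary least squares on the same centered system (for comparison)."""
    tau, *_ = np.linalg.lstsq(np.asarray(X, float), np.asarray(Z, float).ravel(),
                              rcond=None)
    return tau


def recover_F(tau: np.ndarray, alpha_bar: np.ndarray, beta_bar: float) -> float:
    """F = beta_bar - alpha_bar . tau'."""
    return float(beta_bar - np.dot(np.asarray(alpha_bar, float), np.asarray(tau, float)))


def ellipse_center(params: EllipseParams) -> tuple:
    a, b, c, d, e = params.a, params.b, params.c, params.d, params.e
    disc = 4.0 * a * c - b * b
    if disc <= 1e-12:
        raise DetectionError("fit", f"conic is not an ellipse (4AC - B^2 = {disc:g})")
    xp = (b * e - 2.0 * c * d) / disc
    yp = (b * d - 2.0 * a * e) / disc
    return (xp, yp)


def fit_ellipse(points, cond_limit: float = 1e12) -> EllipseParams:
    """Full fit: build system, TLS solve, recover F, validate ellipse-ness."""
    system = build_system(points)
    tau, info = tls_solve(system.X, system.Z, cond_limit=cond_limit)
    f = recover_F(tau, system.alpha_bar, system.beta_bar)
    params = EllipseParams(b=float(tau[0]), c=float(tau[1]), d=float(tau[2]),
                           e=float(tau[3]), f=f, diagnostics=info)
    ellipse_center(params)  # raises if not an ellipse
    return params


def sensitivity_ratio(system: TlsSystem) -> dict:
    """TLS sensitivity diagnostic r = (sigma_x_min - sigma_l_min) / sigma_x_min.

    ``sigma_x_min`` is the smallest singular value of the design matrix X and
    ``sigma_l_min`` that of the augmented matrix L = [-Z, X].  Large r (near 1)
    means the TLS correction is well conditioned.  Both candidate
    denominators (centered X and the un-centered design) are reported.
    """
    sx = jacobi_eigen(system.X.T @ system.X).singular_values[-1]
    sl = jacobi_eigen(system.L.T @ system.L).singular_values[-1]
    # un-centered design (intercept column included), the Eq.-(10) style matrix
    M = np.column_stack([system.X + system.alpha_bar, np.ones(system.n)])
    sm = jacobi_eigen(M.T @ M).singular_values[-1]
    r = float((sx - sl) / sx) if sx > 0 else 0.0
    r_unc = float((sm - sl) / sm) if sm > 0 else 0.0
    return {"r": r, "sigma_x_min": float(sx), "sigma_l_min": float(sl),
            "sigma_m_min": float(sm), "r_uncentered": r_unc}


def conic_to_geometric(params: EllipseParams) -> tuple:
    """(cx, cy, semi_major, semi_minor, angle_rad) of the conic."""
    a, b, c, d, e, f = params.a, params.b, params.c, params.d, params.e, params.f
    cx, cy = ellipse_center(params)
    # constant after recentering: A cx^2 + B cx cy + C cy^2 + D cx + E cy + F
    f0 = a * cx * cx + b * cx * cy + c * cy * cy + d * cx + e * cy + f
    M = np.array([[a, b / 2.0], [b / 2.0, c]])
    lam = np.sort(jacobi_eigen(M).eigenvalues)  # ascending
    if lam[0] <= 0 or f0 >= 0:
        raise DetectionError("fit", "conic is not a real ellipse")
    axes = np.sqrt(-f0 / lam)  # descending (small eigenvalue -> long axis)
    if abs(b) < 1e-15 and a <= c:
        angle = 0.0
    else:
        angle = 0.5 * math.atan2(b, a - c)
        # align angle with the major axis (eigenvector of the smaller eigenvalue)
        vec = np.array([math.cos(angle), math.sin(angle)])
        if not np.isclose(vec @ M @ vec, lam[0], rtol=1e-6, atol=1e-9):
            angle += math.pi / 2.0
    return (cx, cy, float(axes[0]), float(axes[1]), float(angle))
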