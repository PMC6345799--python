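"""Tail asymptotics of the component-size distribution.

For a non-scale-free degree distribution the probability that a random
node's component has size ``n`` obeys

    w_inf(n) = C1 * n^{-3/2} * exp(-C2 * n),     n >> 1,

with both coefficients functionals of the moment summary ``(mu0, M, T_i)``
alone.  The exponent rate is ``C2 = min_z f(z)`` where, writing
``v(z) = (1 - |z|, z_1, ..., z_{N-1})`` for a point of the unit simplex
(the candidate partition of a large component's edges among colours),

    f(z) = 1/2 * [(M - I) v]^T sigma(v)^{-1} [(M - I) v],
    sigma(v) = sum_i v_i T_i.

``C2 = 0`` exactly when ``(M - I) v = 0`` for some simplex point ``v`` —
the kernel criticality criterion — and then the tail is scale-free with
exponent -3/2.  The minimiser also yields the law of colour fractions in
large finite components: the fraction vector is Gaussian with mean
``m = v(z*)`` and covariance ``Sigma/n`` built from the Hessian of ``f``.

Numerical conventions (documented in the methods note): the scaling
coefficient is evaluated at the leading near-critical order,

    C1 = det(M - I) tr(adj(Q) R) * sqrt(det(H^{-1}) / (2 pi det(sigma*))),

where ``Q = I - G``, ``G_ij = a^T T_i e_j``, ``R_ij = b^T T_i e_j`` with
``a = (M - I)^{-T} sigma*^{-1} (M - I) v*`` and
``b = (M - I)^{-T} sigma*^{-1} mu0``; ``det(Q) = 0`` holds identically,
so ``tr(adj(Q) R)`` is the first-order coefficient of ``det(Q + R/n)``.
At N = 1 this reduces exactly to the classical unicoloured closed forms

    C1 = E[k]^2 / sqrt(2 pi (E[k]E[k^3] - E[k^2]^2)),
    C2 = (E[k^2] - 2 E[k])^2 / (2 (E[k]E[k^3] - E[k^2]^2)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import solve as lin_solve

from .degree_model import MomentSummary, percolate_summary, percolate_summary_coloured

__all__ = [
    "AsymptoteCoefficients",
    "ColourFractionLaw",
    "f_objective",
    "minimise_f",
    "asymptote",
    "colour_fraction_law",
    "C2_profile",
]

_INTERIOR_EPS = 1e-10


# ---------------------------------------------------------------------------
# the large-deviation objective f(z)
# ---------------------------------------------------------------------------


def _simplex_point(z: np.ndarray) -> np.ndarray:
    """v = (1 - |z|, z_1, ..., z_{N-1})."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    return np.concatenate(([1.0 - z.sum()], z))


def _sigma(v: np.ndarray, T: np.ndarray) -> np.ndarray:
    return np.tensordot(v, T, axes=(0, 0))


def _solve_sym(sig: np.ndarray, rhs: np.ndarray, z=None) -> np.ndarray:
    """Solve sig @ y = rhs for symmetric PSD sig.

    Falls back to least squares when sig is (numerically) singular —
    block-structured T_i make sigma exactly singular on simplex faces,
    where the quadratic form still has a finite limit as long as the
    right-hand side stays in the range of sigma.  Raises when it does
    not (the form is genuinely undefined there).
    """
    try:
        y = lin_solve(sig, rhs, assume_a="sym")
        if np.isfinite(y).all():
            return y
    except np.linalg.LinAlgError:
        pass
    y, *_ = np.linalg.lstsq(sig, rhs, rcond=None)
    scale = float(np.linalg.norm(rhs))
    if scale > 0 and np.linalg.norm(sig @ y - rhs) > 1e-8 * max(scale, 1.0):
        raise ValueError(f"sigma(v) is singular and incompatible at z={z!r}")
    return y


def f_objective(z, M: np.ndarray, T: np.ndarray) -> float:
    """Quadratic-form rate f(z) = 1/2 q^T sigma^{-1} q with q = (M-I)v."""
    v = _simplex_point(z)
    if v.size != M.shape[0]:
        raise ValueError("z must have length N - 1")
    sig = _sigma(v, T)
    q = (M - np.eye(M.shape[0])) @ v
    y = _solve_sym(sig, q, z)
    return 0.5 * float(q @ y)


def _f_and_grad(z, B, T):
    """f and its gradient in z (v_1 eliminated as 1 - |z|)."""
    v = _simplex_point(z)
    sig = _sigma(v, T)
    q = B @ v
    y = _solve_sym(sig, q, z)
    f = 0.5 * float(q @ y)
    n = B.shape[0]
    grad = np.empty(n - 1)
    for i in range(n - 1):
        dq = B[:, i + 1] - B[:, 0]
        dS = T[i + 1] - T[0]
        grad[i] = float(dq @ y) - 0.5 * float(y @ dS @ y)
    return f, grad


def hessian_f(z, M: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Analytic Hessian of f(z); (N-1) x (N-1)."""
    n = M.shape[0]
    B = M - np.eye(n)
    v = _simplex_point(z)
    sig = _sigma(v, T)
    q = B @ v
    y = _solve_sym(sig, q, z)
    dq = np.stack([B[:, i + 1] - B[:, 0] for i in range(n - 1)])        # (N-1, N)
    dS = np.stack([T[i + 1] - T[0] for i in range(n - 1)])              # (N-1, N, N)
    dSy = dS @ y                                                        # (N-1, N)
    sol_dq = _solve_sym(sig, dq.T, z).T
    sol_dSy = _solve_sym(sig, dSy.T, z).T
    H = (dq @ sol_dq.T
         + np.einsum("ik,jk->ij", dSy, sol_dSy)
         - dq @ sol_dSy.T
         - sol_dSy @ dq.T)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# constrained minimisation of f over the simplex
# ---------------------------------------------------------------------------


def _perron_tail(M: np.ndarray) -> np.ndarray | None:
    """Tail (v_2.., v_N) of the normalised dominant eigenvector, if usable."""
    vals, vecs = np.linalg.eig(M)
    k = int(np.argmax(vals.real))
    if abs(vals[k].imag) > 1e-9:
        return None
    v = vecs[:, k].real
    v = v / v.sum() if abs(v.sum()) > 1e-12 else None
    if v is None or (v < -1e-9).any():
        return None
    return np.clip(v[1:], _INTERIOR_EPS, None)


def minimise_f(summary: MomentSummary, *, eps: float = _INTERIOR_EPS,
               starts=None, gtol: float = 1e-12):
    """Constrained minimiser of f over {z >= eps, |z| <= 1 - eps}.

    Returns ``(z_star, f_min, H)`` with ``H`` the analytic Hessian at the
    minimiser.  Multistart: the simplex barycentre plus the dominant
    eigenvector tail of ``M`` (f is flat near criticality, where the
    minimiser approaches that eigenvector).
    """
    M, T = summary.M, summary.T
    n = summary.n_colours
    B = M - np.eye(n)
    if n == 1:
        z = np.empty(0)
        return z, f_objective(z, M, T), np.empty((0, 0))

    if starts is None:
        starts = [np.full(n - 1, 1.0 / n)]
        pt = _perron_tail(M)
        if pt is not None:
            starts.append(pt)
        # near-vertex starts: f is multimodal for modular (block) M, with
        # candidate minima at single-colour corners of the simplex
        for i in range(n):
            vz = np.full(n - 1, 10 * eps)
            if i > 0:
                vz[i - 1] = 1.0 - (n - 1) * 10 * eps
            starts.append(vz)
    cons = optimize.LinearConstraint(np.ones((1, n - 1)), -np.inf, 1.0 - eps)
    bounds = [(eps, 1.0 - eps)] * (n - 1)
    best = None
    for z0 in starts:
        res = optimize.minimize(
            _f_and_grad, np.clip(z0, eps, 1 - eps), args=(B, T), jac=True,
            method="SLSQP", bounds=bounds, constraints=[cons],
            options={"maxiter": 500, "ftol": 1e-16},
        )
        if best is None or res.fun < best.fun:
            best = res
    z_star = np.clip(best.x, eps, 1 - eps)
    f_min = max(float(best.fun), 0.0)
    on_boundary = (z_star <= 2 * eps).any() or z_star.sum() >= 1 - 2 * eps
    if on_boundary:
        warnings.warn(
            "minimiser of f lies on the simplex boundary; the tail asymptote "
            "may not be valid for this moment summary", RuntimeWarning,
        )
    try:
        H = hessian_f(z_star, M, T)
    except ValueError:
        if not on_boundary:
            raise
        H = np.full((n - 1, n - 1), np.nan)  # curvature undefined on the face
    return z_star, f_min, H


# ---------------------------------------------------------------------------
# asymptote coefficients
# ---------------------------------------------------------------------------


def _adjugate(A: np.ndarray) -> np.ndarray:
    """Adjugate via cofactors (stable when det(A) ~ 0)."""
    n = A.shape[0]
    if n == 0:
        return np.zeros((0, 0))
    if n == 1:
        return np.ones((1, 1))
    adj = np.empty_like(A, dtype=float)
    idx = np.arange(n)
    for i in range(n):
        for j in range(n):
            minor = A[np.ix_(idx != i, idx != j)]
            adj[j, i] = (-1) ** (i + j) * np.linalg.det(minor)
    return adj


@dataclass(frozen=True)
class AsymptoteCoefficients:
    """Coefficient bundle of w_inf(n) = C1 n^{-3/2} exp(-C2 n)."""

    C1: float
    C2: float
    z_star: np.ndarray
    f_min: float
    sigma_z_star: np.ndarray
    K: np.ndarray
    A: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    a1: float
    boundary_minimiser: bool = False
    meta: dict = field(default_factory=dict)

    def w_inf(self, n) -> np.ndarray:
        """Evaluate the tail asymptote at component sizes ``n``."""
        n = np.asarray(n, dtype=float)
        return self.C1 * n ** -1.5 * np.exp(-self.C2 * n)


def asymptote(summary: MomentSummary) -> AsymptoteCoefficients:
    """Full asymptote coefficient bundle for a (sub)critical summary.

    At exact criticality ``C2 = 0`` (scale-free tail); near-singular linear
    solves are then handled by least squares and the result carries a
    ``meta['critical']`` flag.
    """
    M, T, mu0 = summary.M, summary.T, summary.mu0
    n = summary.n_colours
    B = M - np.eye(n)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        z_star, f_min, H = minimise_f(summary)
        boundary = any(issubclass(w.category, RuntimeWarning) for w in caught)
    v = _simplex_point(z_star) if n > 1 else np.ones(1)
    sig = _sigma(v, T)
    q = B @ v
    y = _solve_sym(sig, q, z_star)

    det_B = np.linalg.det(B)
    critical = abs(det_B) < 1e-12 * max(1.0, np.abs(B).max() ** n)
    solveT = (np.linalg.solve if not critical
              else lambda A_, b_: np.linalg.lstsq(A_, b_, rcond=None)[0])
    a = solveT(B.T, y)
    b = solveT(B.T, _solve_sym(sig, mu0, z_star))
    G = np.einsum("k,ikj->ij", a, T)
    R = np.einsum("k,ikj->ij", b, T)
    Q = np.eye(n) - G
    a1 = det_B * float(np.trace(_adjugate(Q) @ R))

    det_H = np.linalg.det(H) if H.size else 1.0
    det_sig = np.linalg.det(sig)
    if det_H <= 0 or det_sig <= 0:
        raise ValueError("singular Hessian or sigma at the minimiser")
    C1 = a1 * np.sqrt(1.0 / (2.0 * np.pi * det_H * det_sig))
    K = B @ np.linalg.inv(_basis_change(n))
    return AsymptoteCoefficients(
        C1=float(C1), C2=f_min, z_star=z_star, f_min=f_min, sigma_z_star=sig,
        K=K, A=_basis_change(n), H=H, Q=Q, R=R, a1=a1,
        boundary_minimiser=boundary,
        meta={"critical": bool(critical or f_min == 0.0),
              "covariance_convention": "H_inverse"},
    )


def _basis_change(n: int) -> np.ndarray:
    """Matrix with first row all ones, identity below (k -> (|k|, k_2..))."""
    A = np.eye(n)
    A[0, :] = 1.0
    return A


# ---------------------------------------------------------------------------
# colour fractions of finite components
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColourFractionLaw:
    """Gaussian law of per-component edge-colour fractions.

    In a large finite component of size n the fraction vector f is
    ``N(m, Sigma_scale / n)``; rows of ``Sigma_scale`` sum to zero because
    the fractions sum to one.
    """

    m: np.ndarray
    Sigma_scale: np.ndarray
    block_a: float
    block_b: np.ndarray
    meta: dict = field(default_factory=dict)


def colour_fraction_law(summary: MomentSummary) -> ColourFractionLaw:
    """Mean vector and size-scaled covariance of component colour fractions.

    ``m = (1 - |z*|, z*)``; the covariance block for colours 2..N is the
    inverse Hessian of f at the minimiser (the curvature of the
    large-deviation rate sets the fluctuation scale), bordered so every
    row sums to zero.
    """
    z_star, f_min, H = minimise_f(summary)
    n = summary.n_colours
    m = _simplex_point(z_star) if n > 1 else np.ones(1)
    if n == 1:
        return ColourFractionLaw(m, np.zeros((1, 1)), 0.0, np.zeros(0))
    C = np.linalg.inv(H)
    b = -C.sum(axis=1)
    a = float(C.sum())
    Sigma = np.empty((n, n))
    Sigma[0, 0] = a
    Sigma[0, 1:] = b
    Sigma[1:, 0] = b
    Sigma[1:, 1:] = C
    return ColourFractionLaw(
        m, Sigma, a, b, meta={"covariance_convention": "H_inverse",
                              "f_min": f_min},
    )


# ---------------------------------------------------------------------------
# percolation sweeps
# ---------------------------------------------------------------------------


def C2_profile(summary: MomentSummary, p_values) -> np.ndarray:
    """C2 of the percolated summary at each p (scalar grid or p-vectors).

    Accepts a 1-D array of scalar keep-probabilities or a 2-D array whose
    rows are colour-dependent probability vectors.
    """
    p_values = np.asarray(p_values, dtype=float)
    out = np.empty(len(p_values))
    for i, p in enumerate(p_values):
        perc = (percolate_summary(summary, float(p)) if p_values.ndim == 1
                else percolate_summary_coloured(summary, p))
        if (perc.mu0 <= 0).any():
            out[i] = np.nan
            continue
        _, f_min, _ = minimise_f(perc)
        out[i] = f_min
    return out
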