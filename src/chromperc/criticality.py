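"""Criticality criteria, critical probabilities and critical manifolds.

An edge-coloured configuration model is critical — its component-size tail
is scale-free — exactly when the excess-mean matrix ``M`` has a kernel
vector of ``M - I`` that is nonnegative once normalised by its entry sum.
Under simple bond percolation ``M`` becomes ``p M``, so every critical
keep-probability is the reciprocal of a real eigenvalue ``λ > 1`` of ``M``
whose eigenvector passes the sign condition; under colour-dependent
percolation the criterion ``ker[diag{p} M - I]`` defines a critical
manifold inside the unit hypercube.  Restricting connectivity to a colour
subset S masks ``M`` to ``diag{x_S} M diag{x_S}`` and yields secondary
(subset) transitions, hierarchically ordered and — for diagonally dominant
``M`` — batched inside Gershgorin intervals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import optimize
from scipy.linalg import null_space

from .asymptotics import minimise_f
from .degree_model import MomentSummary, percolate_summary_coloured

__all__ = [
    "CriticalityReport",
    "CriticalPoint",
    "CriticalPointSet",
    "ColourSubset",
    "GershgorinIntervals",
    "CriticalManifoldSample",
    "is_critical",
    "critical_probabilities",
    "spectral_pc",
    "necessary_condition",
    "subset_transitions",
    "gershgorin_batches",
    "critical_manifold",
    "optimal_path",
    "is_primitive",
]

#: accept an eigenvalue as real when |Im| is below this
REAL_TOL = 1e-9
#: kernel residual tolerance
KERNEL_TOL = 1e-8
#: slack on certificate nonnegativity after 1-norm normalisation
SIGN_TOL = 1e-8


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CriticalityReport:
    is_critical: bool
    certificate: np.ndarray | None
    eigenvalues: np.ndarray
    primitive: bool
    boundary_zero: bool = False  # certificate touches zero (sign criterion marginal)


@dataclass(frozen=True)
class CriticalPoint:
    p_c: float
    eigenvalue: float
    certificate: np.ndarray


@dataclass(frozen=True)
class CriticalPointSet:
    points: tuple
    subset: "ColourSubset | None" = None

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([pt.p_c for pt in self.points])

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)


@dataclass(frozen=True)
class ColourSubset:
    S: frozenset
    n_colours: int

    def __post_init__(self):
        if not self.S:
            raise ValueError("colour subset must be nonempty")

    @property
    def indicator(self) -> np.ndarray:
        x = np.zeros(self.n_colours)
        x[sorted(self.S)] = 1.0
        return x


@dataclass(frozen=True)
class GershgorinIntervals:
    intervals: np.ndarray  # (N, 2), [lo, hi] in (0, 1]
    radii: np.ndarray

    def covers(self, p: float, atol: float = 1e-12) -> bool:
        lo, hi = self.intervals[:, 0], self.intervals[:, 1]
        return bool(((p >= lo - atol) & (p <= hi + atol)).any())


@dataclass(frozen=True)
class CriticalManifoldSample:
    points: np.ndarray        # (m, N) p-vectors on the manifold
    residuals: np.ndarray     # |det(diag{p}M - I)| at each point
    certificates: np.ndarray  # (m, N) normalised kernel vectors
    grid_resolution: int
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# kernel criterion
# ---------------------------------------------------------------------------


def _check_matrix(M) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be a square matrix")
    if (M < 0).any():
        raise ValueError("M must be entrywise nonnegative")
    return M


def _nonneg_kernel_vector(A: np.ndarray, tol: float = KERNEL_TOL):
    """A kernel vector of A that is nonnegative after 1-norm normalisation.

    Returns (vector, boundary_zero) or (None, False).  For one-dimensional
    kernels this is a sign flip; for higher-dimensional kernels a small
    linear programme searches the kernel for a nonnegative combination.
    """
    scale = max(1.0, np.abs(A).max())
    basis = null_space(A, rcond=tol / scale)
    if basis.shape[1] == 0:
        return None, False
    if basis.shape[1] == 1:
        v = basis[:, 0]
        s = v.sum()
        if abs(s) < tol:
            return None, False
        v = v / s
        if (v >= -SIGN_TOL).all():
            return v, bool((np.abs(v) <= SIGN_TOL).any())
        return None, False
    # kernel dim > 1: find x with basis @ x >= 0, sum = 1 (LP feasibility)
    k = basis.shape[1]
    res = optimize.linprog(
        c=np.zeros(k),
        A_ub=-basis, b_ub=np.zeros(basis.shape[0]),
        A_eq=basis.sum(axis=0, keepdims=True), b_eq=[1.0],
        bounds=[(None, None)] * k, method="highs",
    )
    if not res.success:
        return None, False
    v = basis @ res.x
    return v, bool((np.abs(v) <= SIGN_TOL).any())


def is_critical(M, tol: float = KERNEL_TOL) -> CriticalityReport:
    """Kernel criticality test: 1 in the spectrum of M with a
    sign-consistent kernel vector of ``M - I``."""
    M = _check_matrix(M)
    eigs = np.linalg.eigvals(M)
    v, boundary = _nonneg_kernel_vector(M - np.eye(M.shape[0]), tol)
    return CriticalityReport(
        is_critical=v is not None,
        certificate=v,
        eigenvalues=np.sort(eigs.real[np.abs(eigs.imag) <= REAL_TOL * max(1, np.abs(eigs).max())]),
        primitive=is_primitive(M),
        boundary_zero=boundary,
    )


def critical_probabilities(M, *, include_p1: bool = True) -> CriticalPointSet:
    """All simple-percolation critical points p_c = 1/λ of M.

    Eigenpairs (λ, v) qualify when λ is real, λ ≥ 1 (λ = 1 gives the
    boundary point p_c = 1, kept when ``include_p1``), and v is nonnegative
    after normalisation.  Duplicates within 1e-9 are coalesced.
    """
    M = _check_matrix(M)
    n = M.shape[0]
    eigs = np.linalg.eigvals(M)
    scale = max(1.0, np.abs(eigs).max())
    lams = eigs.real[np.abs(eigs.imag) <= REAL_TOL * scale]
    lo = 1.0 - REAL_TOL if include_p1 else 1.0 + REAL_TOL
    lams = np.unique(np.round(lams[lams >= lo], 12))
    points = []
    for lam in lams:
        v, _ = _nonneg_kernel_vector(M - lam * np.eye(n))
        if v is None:
            continue
        points.append(CriticalPoint(p_c=min(1.0 / lam, 1.0), eigenvalue=lam,
                                    certificate=v))
    points.sort(key=lambda pt: pt.p_c)
    merged = []
    for pt in points:
        if merged and abs(pt.p_c - merged[-1].p_c) < 1e-9:
            continue
        merged.append(pt)
    return CriticalPointSet(tuple(merged))


def is_primitive(M) -> bool:
    """Primitivity (irreducible + aperiodic) of the support pattern of M."""
    M = _check_matrix(M)
    if M.shape[0] == 1:
        return bool(M[0, 0] > 0)
    G = nx.DiGraph(zip(*np.nonzero(M)))
    G.add_nodes_from(range(M.shape[0]))
    return nx.is_strongly_connected(G) and nx.is_aperiodic(G)


def _irreducible_blocks(M: np.ndarray):
    G = nx.DiGraph(zip(*np.nonzero(M)))
    G.add_nodes_from(range(M.shape[0]))
    return [sorted(c) for c in nx.strongly_connected_components(G)]


def spectral_pc(M, *, decompose: bool = False):
    """Reciprocal spectral radius p_c = 1/ρ(M) for primitive M.

    Returns None when ρ(M) ≤ 1 (always subcritical).  A non-primitive M
    raises unless ``decompose`` is set, in which case ρ is taken per
    irreducible block of the support pattern and the smallest valid p_c
    across blocks is returned (blocks may be studied separately).
    """
    M = _check_matrix(M)
    if not is_primitive(M):
        if not decompose:
            raise ValueError(
                "matrix M not primitive; use critical_probabilities or "
                "spectral_pc(..., decompose=True) for per-block analysis"
            )
        pcs = []
        for block in _irreducible_blocks(M):
            sub = M[np.ix_(block, block)]
            rho = np.abs(np.linalg.eigvals(sub)).max() if sub.size else 0.0
            if rho > 1:
                pcs.append(1.0 / rho)
        pcs = np.unique(np.round(pcs, 9))
        return float(pcs.min()) if len(pcs) else None
    rho = np.abs(np.linalg.eigvals(M)).max()
    return 1.0 / float(rho) if rho > 1 else None


def necessary_condition(M, p) -> float | np.ndarray:
    """det(diag{p} M - I): vanishing is necessary (not sufficient) for
    criticality at p.  Scalar p is broadcast; an array of p values returns
    an array of determinants."""
    M = _check_matrix(M)
    n = M.shape[0]
    p = np.asarray(p, dtype=float)
    if p.ndim == 0:
        p = np.full(n, float(p))
    if p.ndim == 1 and p.size == n:
        return float(np.linalg.det(p[:, None] * M - np.eye(n)))
    return np.array([necessary_condition(M, pi) for pi in p])


# ---------------------------------------------------------------------------
# colour-subset (secondary) transitions
# ---------------------------------------------------------------------------


def subset_transitions(M, *, max_colours: int = 16):
    """Critical points of every nonempty colour subset S.

    Masks M to ``diag{x_S} M diag{x_S}`` (connectivity restricted to the
    colours of S) and solves the eigenproblem of the restricted block.
    Returns a list of (ColourSubset, CriticalPointSet), largest subsets
    first; subsets with no transition get an empty point set.
    """
    M = _check_matrix(M)
    n = M.shape[0]
    if n > max_colours:
        raise ValueError(
            f"{n} colours would need {2 ** n - 1} eigenproblems; above the "
            f"configured cap of {max_colours}"
        )
    out = []
    for r in range(n, 0, -1):
        for S in itertools.combinations(range(n), r):
            sub = ColourSubset(frozenset(S), n)
            block = M[np.ix_(S, S)]
            pts = critical_probabilities(block)
            lifted = []
            for pt in pts:
                cert = np.zeros(n)
                cert[list(S)] = pt.certificate
                lifted.append(CriticalPoint(pt.p_c, pt.eigenvalue, cert))
            out.append((sub, CriticalPointSet(tuple(lifted), subset=sub)))
    return out


def gershgorin_batches(M) -> GershgorinIntervals:
    """Gershgorin localisation of all subset transitions.

    Interval i is ``[max(M_ii + r_i, 1)^-1, max(M_ii - r_i, 1)^-1]`` with
    r_i the off-diagonal row sum; for diagonally dominant M every subset
    transition lies in the union of these intervals.
    """
    M = _check_matrix(M)
    n = M.shape[0]
    r = M.sum(axis=1) - np.diag(M)
    if not (np.diag(M) > r).all():
        warnings.warn("M is not strictly diagonally dominant; Gershgorin "
                      "batches may not cover all subset transitions",
                      RuntimeWarning)
    lo = 1.0 / np.maximum(np.diag(M) + r, 1.0)
    hi = 1.0 / np.maximum(np.diag(M) - r, 1.0)
    return GershgorinIntervals(np.column_stack([lo, hi]), r)


# ---------------------------------------------------------------------------
# critical manifolds of colour-dependent percolation
# ---------------------------------------------------------------------------


def critical_manifold(M, grid_resolution: int = 20, residual_tol: float = 1e-8,
                      scan_axes=None) -> CriticalManifoldSample:
    """Point cloud on the critical manifold {p : ker[diag{p}M - I] sign-ok}.

    For each axis in ``scan_axes`` (all axes by default) the complementary
    coordinates run over a regular grid of the open unit cube and the
    determinant det(diag{p}M - I) is root-bracketed and bisected along the
    scanned axis; surviving roots are kept only with a nonnegative kernel
    certificate.  Cost grows as grid_resolution^(N-1) per axis.
    """
    M = _check_matrix(M)
    n = M.shape[0]
    I = np.eye(n)

    def det_at(p):
        return np.linalg.det(p[:, None] * M - I)

    axes = range(n) if scan_axes is None else scan_axes
    grid = np.linspace(0.5 / grid_resolution, 1 - 0.5 / grid_resolution,
                       grid_resolution)
    fine = np.linspace(1e-9, 1 - 1e-9, max(4 * grid_resolution, 64))
    pts, res, certs = [], [], []
    for axis in axes:
        others = [i for i in range(n) if i != axis]
        for combo in itertools.product(grid, repeat=n - 1):
            p = np.empty(n)
            p[others] = combo
            vals = np.empty(fine.size)
            for k, t in enumerate(fine):
                p[axis] = t
                vals[k] = det_at(p)
            sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
            for k in sign_change:
                def f(t, p=p.copy()):
                    p[axis] = t
                    return det_at(p)
                root = optimize.brentq(f, fine[k], fine[k + 1], xtol=1e-13)
                p_hit = p.copy()
                p_hit[axis] = root
                v, _ = _nonneg_kernel_vector(p_hit[:, None] * M - I,
                                             tol=max(residual_tol, 1e-10))
                if v is None:
                    continue
                pts.append(p_hit)
                res.append(abs(det_at(p_hit)))
                certs.append(v)
    if not pts:
        warnings.warn("no manifold points found at this grid resolution",
                      RuntimeWarning)
        return CriticalManifoldSample(np.empty((0, n)), np.empty(0),
                                      np.empty((0, n)), grid_resolution)
    return CriticalManifoldSample(np.array(pts), np.array(res),
                                  np.array(certs), grid_resolution)


# ---------------------------------------------------------------------------
# percolation-path optimisation
# ---------------------------------------------------------------------------


def _path_from_params(theta: np.ndarray, n_colours: int, n_control: int):
    """Monotone piecewise-linear path p(t): squared increments per colour,
    normalised so p(0) = 0 and p(1) = 1 componentwise."""
    inc = theta.reshape(n_colours, n_control + 1) ** 2 + 1e-12
    cum = np.cumsum(inc, axis=1)
    knots_p = np.concatenate([np.zeros((n_colours, 1)), cum / cum[:, -1:]], axis=1)
    knots_t = np.linspace(0.0, 1.0, n_control + 2)
    return knots_t, knots_p


def _staircase_start(summary: MomentSummary, n_control: int) -> np.ndarray | None:
    """Constructed start that rides the critical plane of one colour.

    When some colour alone is supercritical (M_ii > 1), the plane
    p_i = 1/M_ii can carry criticality certificates; a path holding that
    colour at its critical value while the others sweep keeps C2 ~ 0 for
    an extended stretch.  Returns increment parameters or None.
    """
    diag = np.diag(summary.M)
    if not (diag > 1).any():
        return None
    i_star = int(np.argmax(diag))
    pc = 1.0 / diag[i_star]
    n = summary.n_colours
    m = n_control + 1  # increments per colour
    inc = np.full((n, m), 1e-9)  # idle legs stay (numerically) flat
    # colour i*: jump to pc in the first leg, hold, release in the last leg
    inc[i_star, 0] = pc
    inc[i_star, -1] = 1.0 - pc
    # other colours: rise in the middle legs while i* holds
    for j in range(n):
        if j != i_star:
            inc[j, 1:-1] = 1.0 / max(m - 2, 1)
    return np.sqrt(inc).ravel()


def optimal_path(summary: MomentSummary, n_control_points: int = 4,
                 seed: int = 0, *, n_t: int = 25, n_starts: int = 2,
                 maxiter: int = 120, p_floor: float = 1e-6):
    """Percolation path p(t) from full damage p(0)=0 to the intact network
    p(1)=1 minimising the integrated exponent rate ∫ C2(p(t)) dt.

    The path is monotone componentwise and piecewise linear with
    ``n_control_points`` interior knots.  C2 diverges as p -> 0, so the
    integral is discretised on a midpoint t-grid (the common endpoint
    contribution is path-independent at leading order).  A seeded
    derivative-free local optimiser runs from a constructed
    plane-riding start, the uniform diagonal, and seeded perturbations;
    C2 minimisations are warm-started along the path.  Returns a dict
    with knots, the t-grid, the C2 profile, its integral, and the same
    for the straight diagonal path as reference.
    """
    if n_control_points < 1:
        raise ValueError("need at least one interior control point")
    n = summary.n_colours
    rng = np.random.default_rng(seed)
    t_grid = (np.arange(n_t) + 0.5) / n_t

    warm: dict[int, np.ndarray] = {}

    def c2_at(p, k=None):
        p = np.clip(p, p_floor, 1.0)
        perc = percolate_summary_coloured(summary, p)
        starts = [warm[k]] if k in warm else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z, f_min, _ = minimise_f(perc, starts=starts)
        if k is not None:
            warm[k] = z
        return f_min

    def profile(knots_t, knots_p, use_warm=True):
        P = np.stack([np.interp(t_grid, knots_t, knots_p[i]) for i in range(n)])
        return np.array([c2_at(P[:, k], k if use_warm else None)
                         for k in range(n_t)])

    def objective(theta):
        kt, kp = _path_from_params(theta, n, n_control_points)
        return np.trapezoid(profile(kt, kp), t_grid)

    starts = []
    stair = _staircase_start(summary, n_control_points)
    if stair is not None:
        starts.append(stair)
    starts.append(np.ones(n * (n_control_points + 1)))
    while len(starts) < n_starts:
        starts.append(np.ones(n * (n_control_points + 1))
                      + 0.8 * rng.standard_normal(n * (n_control_points + 1)))
    best = None
    for theta0 in starts[:max(n_starts, len(starts))]:
        res = optimize.minimize(objective, theta0, method="Nelder-Mead",
                                options={"maxiter": maxiter, "xatol": 1e-4,
                                         "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success)
    kt, kp = _path_from_params(best.x, n, n_control_points)
    c2_opt = profile(kt, kp)
    diag = np.tile(t_grid, (n, 1))
    warm.clear()
    c2_diag = np.array([c2_at(diag[:, k], k) for k in range(n_t)])
    return {
        "knots_t": kt,
        "knots_p": kp,
        "t_grid": t_grid,
        "C2_profile": c2_opt,
        "integral": float(np.trapezoid(c2_opt, t_grid)),
        "diagonal_C2_profile": c2_diag,
        "diagonal_integral": float(np.trapezoid(c2_diag, t_grid)),
        "converged": converged,
        "seed": seed,
    }
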