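"""Multivariate degree distributions of edge-coloured configuration models.

A node of an edge-coloured configuration model carries a vector of colour
counts ``k = (k_1, ..., k_N)`` — the number of half-edges of each of the N
colours.  The model's single input is the probability table ``u(k)`` of this
vector.  Everything the asymptotic theory needs is condensed into three
moment statistics of ``u``:

* ``mu0``  — expected half-edges per colour, ``mu0_i = E[k_i]``;
* ``M``    — matrix of excess-degree means, ``M_ij = E[k_i k_j]/E[k_j] - d_ij``
  (column *j* is the mean colour-count vector seen after following a random
  *j*-coloured edge, minus the used half-edge);
* ``T_i``  — covariance matrices of the *i*-excess degree distributions.

This module represents finite (or truncated-analytic) degree tables,
computes the moment summary and excess distributions, and applies the exact
bond-percolation transforms — both on the full table (binomial thinning)
and directly on the moment summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "DegreeDistribution",
    "ExcessDistribution",
    "MomentSummary",
    "tabulate",
    "moments",
    "excess",
    "percolate_distribution",
    "percolate_summary",
    "percolate_summary_coloured",
    "drop_colour",
]

#: absolute tolerance used for probability comparisons throughout
PROB_TOL = 1e-8


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegreeDistribution:
    """Finite table of colour-count vectors with probabilities.

    Parameters
    ----------
    counts : (S, N) int array
        Support: one row per state, ``counts[s]`` is a colour-count vector.
    probs : (S,) float array
        Probability of each state.  Must be nonnegative and sum to one
        within ``truncation_tol`` (mass discarded when tabulating an
        analytic generator).
    truncation_tol : float
        Mass allowed to be missing from the table.
    provenance : str
        Free-text record of where the table came from (generator name and
        parameters, file path, "thinned(...)", ...).
    """

    counts: np.ndarray
    probs: np.ndarray
    truncation_tol: float = PROB_TOL
    provenance: str = ""

    def __post_init__(self) -> None:
        counts = np.atleast_2d(np.asarray(self.counts, dtype=np.int64))
        probs = np.asarray(self.probs, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != probs.shape[0]:
            raise ValueError("counts must be (S, N) with one row per probability")
        if (counts < 0).any():
            raise ValueError("colour counts must be nonnegative")
        if (probs < -PROB_TOL).any():
            raise ValueError("probabilities must be nonnegative")
        total = probs.sum()
        if abs(total - 1.0) > max(self.truncation_tol, PROB_TOL):
            raise ValueError(
                f"table mass {total!r} differs from 1 by more than the "
                f"truncation tolerance {self.truncation_tol!r}"
            )
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "probs", np.clip(probs, 0.0, None))

    @property
    def n_colours(self) -> int:
        return self.counts.shape[1]

    # -- expectations ------------------------------------------------------

    def expect(self, values: np.ndarray) -> float | np.ndarray:
        """Expectation of per-state ``values`` (first axis indexes states)."""
        values = np.asarray(values)
        return np.tensordot(self.probs, values, axes=(0, 0))

    def mean(self) -> np.ndarray:
        """E[k] — expected colour-count vector (= mu0)."""
        return self.probs @ self.counts.astype(float)

    def raw_moment2(self) -> np.ndarray:
        """Matrix of second mixed moments E[k_i k_j]."""
        kw = self.counts * self.probs[:, None]
        return kw.T @ self.counts.astype(float)

    def raw_moment3(self) -> np.ndarray:
        """Third mixed moments E[k_i k_j k_l] as an (N, N, N) array."""
        k = self.counts.astype(float)
        return np.einsum("s,si,sj,sl->ijl", self.probs, k, k, k, optimize=True)

    def prob_of(self, k) -> float:
        """Probability of a single colour-count vector (0 if absent)."""
        k = np.asarray(k, dtype=np.int64).reshape(1, -1)
        hit = (self.counts == k).all(axis=1)
        return float(self.probs[hit].sum())

    def to_dense(self) -> np.ndarray:
        """Dense N-dimensional probability array over the bounding box."""
        shape = tuple(self.counts.max(axis=0) + 1) if len(self.counts) else (1,)
        dense = np.zeros(shape)
        dense[tuple(self.counts.T)] += self.probs
        return dense

    @classmethod
    def from_dense(cls, dense: np.ndarray, *, tol: float = 0.0, **kw) -> "DegreeDistribution":
        """Build a table from a dense N-dimensional probability array."""
        dense = np.asarray(dense, dtype=float)
        keep = dense > tol
        counts = np.argwhere(keep)
        return cls(counts, dense[keep], **kw)


@dataclass(frozen=True)
class ExcessDistribution(DegreeDistribution):
    """Degree table seen from the far end of a random ``colour``-edge.

    ``u_i(k) = (k_i + 1) u(k + e_i) / E[k_i]`` — the state of the reached
    node after removing the half-edge used to arrive.
    """

    colour: int = 0


@dataclass(frozen=True)
class MomentSummary:
    """(mu0, M, T_i) — sufficient statistics for the component asymptotics.

    ``T`` is stored as an (N, N, N) array with ``T[i]`` the i-excess
    covariance matrix.
    """

    mu0: np.ndarray
    M: np.ndarray
    T: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mu0 = np.asarray(self.mu0, dtype=float).ravel()
        n = mu0.size
        M = np.asarray(self.M, dtype=float).reshape(n, n)
        T = np.asarray(self.T, dtype=float).reshape(n, n, n)
        if (mu0 < 0).any():
            raise ValueError("mu0 must be nonnegative")
        object.__setattr__(self, "mu0", mu0)
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "T", T)

    @property
    def n_colours(self) -> int:
        return self.mu0.size


# ---------------------------------------------------------------------------
# analytic generators
# ---------------------------------------------------------------------------


def _poisson_pmf(m, lam):
    return stats.poisson.pmf(m, lam) if lam > 0 else np.where(np.asarray(m) == 0, 1.0, 0.0)


def _box_states(caps: np.ndarray) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(c + 1) for c in caps], indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def _tabulate_coupled_poisson(
    weights, lam, truncation_tol, exclude_zero=True, support_cap=200
):
    """Table of u(k) ∝ Poiss(w·k, λ) over k ≥ 0 (optionally k ≠ 0).

    The support box is grown until the unnormalised mass it captures is
    stable to within ``truncation_tol``; the normalisation constant is then
    recomputed on the truncated support.
    """
    weights = np.asarray(weights, dtype=float)
    if (weights <= 0).any() or lam <= 0:
        raise ValueError("coupled_poisson needs positive weights and rate")
    m_max = max(int(lam) + 10, 20)
    prev_mass = -1.0
    while True:
        caps = np.ceil(m_max / weights).astype(int)
        if np.prod(caps + 1.0) > 5e6 or m_max > support_cap * weights.min():
            raise ValueError(
                "truncation tolerance unreachable within the configured support cap"
            )
        k = _box_states(caps)
        w = _poisson_pmf(k @ weights, lam)
        if exclude_zero:
            w = np.where((k == 0).all(axis=1), 0.0, w)
        mass = w.sum()
        if prev_mass >= 0 and mass - prev_mass < truncation_tol * mass:
            keep = w > 0
            return k[keep], w[keep] / mass
        prev_mass = mass
        m_max += 10


def _tabulate_independent_poisson(rates, truncation_tol):
    rates = np.asarray(rates, dtype=float).ravel()
    if (rates < 0).any():
        raise ValueError("poisson rates must be nonnegative")
    # per-colour caps from the univariate Poisson quantile
    caps = np.array(
        [int(stats.poisson.ppf(1 - truncation_tol / max(len(rates), 1), r)) + 2 if r > 0 else 0
         for r in rates]
    )
    k = _box_states(caps)
    w = np.ones(len(k))
    for i, r in enumerate(rates):
        w *= _poisson_pmf(k[:, i], r)
    keep = w > 0
    return k[keep], w[keep] / w[keep].sum()


def _tabulate_modular_poisson(rates=(1.5, 2.5, 5.0), alpha=0.0, truncation_tol=1e-12):
    """Three unicoloured Poisson communities plus a bridging atom.

    Branch *i* places all half-edges in colour *i* with rate ``rates[i]``
    (each branch keeps its k=0 state; the zero states coincide in the
    table), and an atom of unnormalised weight ``alpha`` sits at (1,1,1),
    bridging the communities.  The whole table is normalised at the end.
    """
    rates = np.asarray(rates, dtype=float).ravel()
    if (rates <= 0).any() or alpha < 0:
        raise ValueError("modular_poisson needs positive rates and alpha >= 0")
    n = rates.size
    cap = int(stats.poisson.ppf(1 - truncation_tol / n, rates.max())) + 2
    states: dict[tuple, float] = {}
    for i, r in enumerate(rates):
        pm = _poisson_pmf(np.arange(cap + 1), r)
        for m, w in enumerate(pm):
            key = tuple(m if j == i else 0 for j in range(n))
            states[key] = states.get(key, 0.0) + float(w)
    if alpha > 0:
        key = (1,) * n
        states[key] = states.get(key, 0.0) + alpha
    counts = np.array(sorted(states), dtype=np.int64)
    probs = np.array([states[tuple(c)] for c in counts])
    return counts, probs / probs.sum()


def _tabulate_geometric(q, truncation_tol):
    """Single-colour geometric degrees: u(k) = (1-q) q^k, k >= 0."""
    if not 0 <= q < 1:
        raise ValueError("geometric ratio must be in [0, 1)")
    if q == 0:
        return np.array([[0]]), np.array([1.0])
    kmax = int(np.ceil(np.log(truncation_tol) / np.log(q))) + 1
    k = np.arange(kmax + 1)
    w = (1 - q) * q ** k
    return k[:, None], w / w.sum()


_GENERATORS = {
    "coupled_poisson": _tabulate_coupled_poisson,
    "poisson": _tabulate_independent_poisson,
    "modular_poisson": _tabulate_modular_poisson,
    "geometric": _tabulate_geometric,
}


def tabulate(name: str, truncation_tol: float = 1e-12, **params) -> DegreeDistribution:
    """Tabulate a named analytic degree-distribution generator.

    Built-in generators
    -------------------
    ``coupled_poisson(weights, lam)``
        ``u(k) ∝ Poiss(weights·k, lam)`` for ``k ≠ 0``; all colours are
        coupled through the weighted total.  Defaults: weights (3, 2, 4),
        lam 3 — a three-colour network sitting just below its critical
        point, used as the canonical worked example throughout.
    ``poisson(rates)``
        Independent Poisson counts per colour.
    ``modular_poisson(rates, alpha)``
        Three unicoloured Poisson communities (rates (1.5, 2.5, 5) by
        default) plus an atom of weight ``alpha`` at (1, ..., 1) bridging
        them.
    ``geometric(q)``
        Single-colour geometric degrees.
    """
    if not 0 < truncation_tol < 1:
        raise ValueError("truncation_tol must lie in (0, 1)")
    try:
        gen = _GENERATORS[name]
    except KeyError:
        raise ValueError(
            f"unknown generator {name!r}; available: {sorted(_GENERATORS)}"
        ) from None
    if name == "coupled_poisson":
        params.setdefault("weights", (3.0, 2.0, 4.0))
        params.setdefault("lam", 3.0)
        counts, probs = gen(params["weights"], params["lam"], truncation_tol,
                            exclude_zero=params.get("exclude_zero", True),
                            support_cap=params.get("support_cap", 200))
    elif name == "poisson":
        counts, probs = gen(params["rates"], truncation_tol)
    elif name == "modular_poisson":
        counts, probs = gen(params.get("rates", (1.5, 2.5, 5.0)),
                            params.get("alpha", 0.0), truncation_tol)
    else:
        counts, probs = gen(params["q"], truncation_tol)
    prov = f"{name}({', '.join(f'{k}={v}' for k, v in sorted(params.items()))})"
    return DegreeDistribution(counts, probs, truncation_tol, prov)


# ---------------------------------------------------------------------------
# moments and excess distributions
# ---------------------------------------------------------------------------


def moments(dist: DegreeDistribution) -> MomentSummary:
    """Moment summary (mu0, M, T_i) of a degree table.

    Raises if some colour has zero expected count — such a colour carries
    no edges and must be projected out first (see :func:`drop_colour`).
    """
    mu0 = dist.mean()
    zero = np.flatnonzero(mu0 <= 0)
    if zero.size:
        raise ValueError(
            f"colour {zero[0] + 1} has zero expected count; use drop_colour first"
        )
    e2 = dist.raw_moment2()
    e3 = dist.raw_moment3()
    n = mu0.size
    M = e2 / mu0[None, :] - np.eye(n)
    # T[i] = E[k_i k k^T]/E[k_i] - (E[k_i k]/E[k_i]) (E[k_i k]/E[k_i])^T
    T = e3 / mu0[:, None, None] - np.einsum(
        "ij,il->ijl", e2, e2
    ) / mu0[:, None, None] ** 2
    meta = {"provenance": dist.provenance}
    return MomentSummary(mu0, M, T, meta)


def excess(dist: DegreeDistribution, colour: int) -> ExcessDistribution:
    """i-excess degree table: state of the node reached along a random
    ``colour``-edge, with the used half-edge removed.

    ``colour`` is 0-based.
    """
    i = int(colour)
    mu0 = dist.mean()
    if not 0 <= i < dist.n_colours:
        raise ValueError(f"colour index {i} out of range")
    if mu0[i] <= 0:
        raise ValueError(f"colour {i + 1} has zero expected count; excess undefined")
    sel = dist.counts[:, i] > 0
    counts = dist.counts[sel].copy()
    probs = counts[:, i] * dist.probs[sel] / mu0[i]
    counts[:, i] -= 1
    return ExcessDistribution(
        counts, probs / probs.sum(), dist.truncation_tol,
        f"excess(colour={i + 1}) of {dist.provenance}", colour=i,
    )


def drop_colour(dist: DegreeDistribution, colour: int) -> DegreeDistribution:
    """Project a colour out of the table (marginalise over its counts)."""
    i = int(colour)
    counts = np.delete(dist.counts, i, axis=1)
    uniq, inv = np.unique(counts, axis=0, return_inverse=True)
    probs = np.bincount(inv, weights=dist.probs, minlength=len(uniq))
    return DegreeDistribution(
        uniq, probs, dist.truncation_tol,
        f"drop_colour({i + 1}) of {dist.provenance}",
    )


# ---------------------------------------------------------------------------
# percolation transforms
# ---------------------------------------------------------------------------


def _as_p_vector(p, n: int) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim == 0:
        p = np.full(n, float(p))
    if p.shape != (n,):
        raise ValueError(f"p must be a scalar or a length-{n} vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("percolation probabilities must lie in [0, 1]")
    return p


def percolate_distribution(dist: DegreeDistribution, p) -> DegreeDistribution:
    """Exact degree table after bond percolation (binomial thinning).

    Each half-edge of colour *i* survives independently with probability
    ``p_i`` (scalar ``p`` is broadcast to all colours); the new table is
    the exact binomial mixture over the finite support.
    """
    pvec = _as_p_vector(p, dist.n_colours)
    dense = dist.to_dense()
    for axis, pi in enumerate(pvec):
        kmax = dense.shape[axis] - 1
        k = np.arange(kmax + 1)
        # column k -> thinned count k', rows index k'
        B = stats.binom.pmf(k[:, None], k[None, :], pi)
        dense = np.moveaxis(
            np.tensordot(B, np.moveaxis(dense, axis, 0), axes=(1, 0)), 0, axis
        )
    out = DegreeDistribution.from_dense(
        dense, truncation_tol=dist.truncation_tol,
        provenance=f"thinned(p={np.round(pvec, 12).tolist()}) of {dist.provenance}",
    )
    return out


def percolate_summary(summary: MomentSummary, p: float) -> MomentSummary:
    """Moment summary after simple (colour-blind) bond percolation.

    ``mu0' = p mu0``, ``M' = p M`` and
    ``(T_i')_{jl} = p² (T_i)_{jl} + p(1−p) M_{ji} δ_{jl}``.
    """
    p = float(p)
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    return percolate_summary_coloured(summary, np.full(summary.n_colours, p))


def percolate_summary_coloured(summary: MomentSummary, p) -> MomentSummary:
    """Moment summary after colour-dependent bond percolation.

    ``mu0' = diag{p} mu0``, ``M' = diag{p} M`` and
    ``T_i' = diag{p} T_i diag{p} + diag{p(1−p)} diag{M_{1i}, ..., M_{Ni}}``.
    """
    n = summary.n_colours
    pvec = _as_p_vector(p, n)
    mu0 = pvec * summary.mu0
    M = pvec[:, None] * summary.M
    T = np.empty_like(summary.T)
    for i in range(n):
        T[i] = (pvec[:, None] * summary.T[i] * pvec[None, :]
                + np.diag(pvec * (1 - pvec) * summary.M[:, i]))
    meta = dict(summary.meta)
    meta["percolated_p"] = np.round(pvec, 15).tolist()
    return MomentSummary(mu0, M, T, meta)
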