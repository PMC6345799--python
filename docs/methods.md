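# Methods

## Model and scope

`chromperc` implements the component-structure theory of the
edge-coloured configuration model under weak connectivity (a path may
mix colours).  A network is specified by a multivariate degree
distribution *u*(**k**) over colour-count vectors; the model joins
same-colour half-edges uniformly at random, so self-loops and
multi-edges occur with vanishing density.  All asymptotic results are
functionals of the moment summary (μ₀, **M**, {**T**ᵢ}): the per-colour
means, the matrix whose column *i* is the mean of the *i*-excess degree
distribution, and the excess covariance matrices.  Heavy-tailed degree
distributions are out of scope: the tail asymptote
C₁ n^(−3/2) e^(−C₂ n) presumes all third mixed moments finite, and
analytic generators enforce a configurable support cap.

## Degree tables and analytic generators

Distributions are finite tables (support rows + probabilities).
Analytic generators are tabulated over a growing support box until the
captured unnormalised mass is stable to within `truncation_tol`
(default 1e-12) and renormalised on the truncated support; every
downstream quantity is continuous in total-variation distance, so the
discarded tail propagates at the same order.  Built-ins:

* `coupled_poisson(weights, lam)` — u(**k**) ∝ Poiss(w·**k**, λ),
  **k** ≠ 0.  Defaults `weights=(3,2,4)`, `lam=3`: the canonical
  three-colour example, subcritical with ρ(**M**) ≈ 0.976.  The weight
  *order* fixes the colour labelling; the default order is the one
  under which this network's finite components carry the canonical
  composition **m** = (0.19, 0.74, 0.07).
* `modular_poisson(rates, alpha)` — three unicoloured Poisson branches
  (defaults 1.5, 2.5, 5), each branch contributing its own k = 0 mass
  to a shared zero state, plus an atom of weight α at (1,1,1) bridging
  the communities; normalised at the end.  This convention is recorded
  in the table provenance because other normalisations (zero-truncated
  branches, exclusive zero state) yield slightly different moments —
  reference excess-mean matrices for this family are therefore treated
  as inputs where exact agreement matters.
* `poisson(rates)` (independent colours) and `geometric(q)`
  (single colour), used mainly as oracles.

Colours with zero expected count are rejected with an explicit error
(`drop_colour` projects them out); silently dropping them would
renumber colours under the caller.

## Percolation transforms

Bond percolation thins each colour binomially.  Both the exact table
transform (`percolate_distribution`, a per-axis binomial mixture) and
the closed-form moment transforms are provided; they commute with
moment extraction to ~1e-12 and the test suite asserts it.  For the
colour-dependent transform the diagonal correction of **T**ᵢ uses
column *i* of **M** (diag{p}(1−p) ⊙ M_{·,i}) — the form that the
binomial-thinning oracle confirms.

## The rate function and its minimisation

With B = **M** − **I** and σ(**v**) = Σᵢ vᵢ**T**ᵢ, the exponent rate is
C₂ = min f over the simplex, f(**v**) = ½ (B**v**)ᵀ σ(**v**)⁻¹ (B**v**).
Numerical choices:

* Interior parameterisation **z** = (v₂, …, v_N) with v₁ = 1 − |**z**|;
  SLSQP with the analytic gradient, box constraints z ≥ ε,
  |**z**| ≤ 1 − ε, ε = 1e-10.
* Multistart from the simplex barycentre, the normalised dominant
  eigenvector tail of **M**, and every near-vertex point.  The vertex
  starts matter: for modular (block-structured) **M** the rate is
  multimodal, with candidate minima at single-colour corners.
* σ(**v**) loses rank on simplex faces when the **T**ᵢ are
  block-structured; solves fall back to least squares, which computes
  the correct limit whenever B**v** remains in the range of σ, and
  raise otherwise.
* The Hessian of f is evaluated analytically and cross-checked against
  finite differences in the tests.  At boundary minimisers (flagged
  with a warning — the tail asymptote is not guaranteed there) the
  Hessian may be undefined and is returned as NaN.

C₂ = 0 is equivalent to the kernel criticality criterion; the suite
checks the equivalence on randomised summaries rescaled to ρ(**M**) = 1
and away from 1.

## Scale coefficient C₁

C₁ = det(B) · tr(adj(Q)R) · sqrt(det(H⁻¹)/(2π det σ\*)) with
Q = I − G, Gᵢⱼ = **a**ᵀ**T**ᵢ**e**ⱼ, Rᵢⱼ = **b**ᵀ**T**ᵢ**e**ⱼ,
**a** = B⁻ᵀσ\*⁻¹B**v**\*, **b** = B⁻ᵀσ\*⁻¹μ₀.  Two conventions were
genuinely open and are fixed as follows:

* the matrices Q and R are built with B⁻¹ (not the adjugate of B):
  only then does det(Q) vanish so that tr(adj(Q)R) is the first-order
  coefficient of det(Q + R/n), the combination stays finite at
  criticality, and the N = 1 reduction collapses *exactly* to the
  classical unicoloured closed form
  C₁ = E[k]²/√(2π(E[k]E[k³] − E[k²]²));
* the sub-exponential factor exp(−(B**v**\*)ᵀσ\*⁻¹μ₀) that appears in
  intermediate derivations is dropped: it equals 1 at criticality (the
  only regime where the asymptote is sharp), and keeping it would break
  the exact N = 1 reduction.  For the canonical three-colour example
  the retained convention gives C₁ = 0.8005; with the factor it would
  be 0.837.

At exact criticality (det B = 0) the linear solves switch to pseudo-
inverses and the result carries a `critical` flag; C₂ = 0 is then the
meaningful statement, and the scale coefficient is a regularised limit.

## Colour fractions of finite components

The minimiser is the mean composition, **m** = **v**\*, independent of
component size; the covariance of the fraction vector in a size-n
component is Σ/n, where the (2..N)-block of Σ is the *inverse* Hessian
of f at the minimiser (the curvature of the large-deviation rate sets
the fluctuation scale — the derivation's Gaussian has variance H⁻¹/n,
and this convention reproduces the reported covariance for the worked
example), bordered so that every row of Σ sums to zero (fractions sum
to one).

Finite-size validity: simulations of the canonical network show the
*covariance* law already accurate at n ≈ 50, while the *mean* carries a
genuine O(1/n) offset (~0.02 at n ≈ 50, < 1 standard error by
n ≈ 110).  Tests therefore assert the covariance at n ≈ 50 and the
mean at n ∈ [95, 130] together with the decay of the offset.

## Exact size distributions

The series path iterates the truncated power-series fixed point of the
generating-function system W(x) = x·U[W₁..W_N], Wᵢ(x) = x·Uᵢ[W₁..W_N];
sweep *t* fixes the order-*t* coefficients, so `n_max` sweeps (default
200) are exact, in linear probability space (coefficients are bounded
by 1, no log-space needed).  The convolution-determinant path evaluates
the explicit formula with dense N-dimensional arrays; the convolution
ratios [kⱼuᵢ] \* uᵢ^{\*(−1)} are produced by exact triangular
deconvolution (the bare convolution inverse has exponentially growing
coefficients and is numerically unusable beyond small orders, while the
ratio itself is tame).  It requires uᵢ(0) > 0 and is practical for
N ≤ 3; it exists as an independent oracle, agreeing with the series
path to ~1e-13, and reduces at N = 1 to
w(n) = E[k]/(n−1)·u₁^{\*n}(n−2), which is also the fast route used for
the critical-tail-exponent check at n up to 1000.

## Giant component and weight-average size

The fixed point s is iterated from **s** = 0 (damping 0.5 on detected
oscillation, tolerance 1e-13, cap 1e5 iterations); **s** = 1 is always
a fixed point, and starting at 0 selects the physical branch.  Inputs
whose fixed-point map is the identity (2-regular-type marginal
networks) are rejected as degenerate rather than answered.  Zero-mean
colours carry no edges and get sᵢ = 1 automatically.  The weight-
average size uses the resolvent [diag{p}⁻¹ − X]⁻¹ formed as
[I − X·diag{p}]⁻¹diag{p} (harmless at pᵢ = 0); a condition number above
1e12 sets the `singular` flag.  The divergence constant
lim (p_c − p)·w_avg is estimated on a geometric approach grid with
Richardson extrapolation of the linear-in-δ correction.

## Critical points, subsets, manifolds, paths

Eigenvalues are accepted as real when |Im λ| ≤ 1e-9 (relative to the
spectral scale); kernel certificates are computed by `null_space` with
sign slack −1e-8 after 1-norm normalisation, exact zeros being flagged
as boundary cases rather than adjudicated (the source criteria state
both strict and non-strict inequalities).  Kernels of dimension > 1
are searched for a nonnegative combination by a small linear programme.
Non-primitive **M** is decomposed into strongly connected blocks of its
support pattern, with the reciprocal spectral radius applied per block.
Subset transitions enumerate all 2^N − 1 masked matrices (capped at
N = 16).  The manifold sampler scans a regular grid over all-but-one
coordinate, for every scan axis, brackets sign changes of
det(diag{p}**M** − **I**) along the remaining coordinate, polishes by
bisection, and keeps only roots with nonnegative kernel certificates —
scanning all axes is what recovers axis-aligned plane components of
diagonal **M**.

Percolation-path optimisation uses a monotone componentwise piecewise-
linear family with fixed endpoints **p**(0) = 0, **p**(1) = 1
(nonnegative increments, squared parameterisation).  Because C₂(p)
diverges like 1/p as **p** → 0, the objective ∫C₂ dt is discretised on
a midpoint grid, whose singular-endpoint contribution is path-
independent at leading order.  Nelder–Mead with seeded multistart runs
from a constructed plane-riding start (hold the single most
supercritical colour exactly at its 1/Mᵢᵢ while the others sweep), the
uniform diagonal, and perturbations; C₂ evaluations along a path are
warm-started.  No global-optimality guarantee is claimed.

## Simulator

Node states are drawn i.i.d. from the table; odd per-colour half-edge
totals are repaired by granting one extra half-edge to a uniformly
chosen carrier of that colour (an O(1/n) perturbation recorded in
metadata); matching is a uniform permutation per colour.  Self-loops
and multi-edges are kept — the pure configuration model — so per-
component edge counts can exceed n − 1 and colour fractions
f = v/(n−1) can exceed 1 in small cyclic components.  A master seed
spawns independent streams for state sampling, matching and
percolation, making percolation reproducible conditional on the graph.
Component labelling uses the sparse connected-components routine; the
giant is estimated by the largest-component fraction, and the finite
weight-average excludes the single largest component.

What the simulator does *not* emulate: simple-graph constraints,
degree–degree correlations, temporal rewiring, and any connectivity
notion other than weak.  Agreement of the analytics with these
simulations therefore validates the configuration-model theory, not
its applicability to a particular empirical network.

## Problem sizes used in the shipped checks

Tabulations run at truncation 1e-12 (~3.5e3 states for the canonical
example); exact distributions to n = 200 (N = 3) and n = 1000 (N = 1);
simulations use 1e5-node networks, 12 replicates for the colour-
fraction laws; the randomised criticality equivalence sweep uses 100
matrices.  The full suite runs in a few minutes on one CPU.

## Known limitations

* The tail asymptote is a near-critical (quadratic large-deviation)
  approximation: far from criticality the true exponential rate (the
  log fold-point radius of the generating-function system) deviates
  from C₂ — for the canonical example they agree to 1%, for a Poisson
  network at λ = 0.5 they differ visibly.  The exact series path is
  the reference in that regime.
* C₁ at exact criticality is a regularised limit (see above).
* The convolution path is exponential in N and shipped for N ≤ 3.
* The manifold sampler is a grid method: components thinner than the
  grid can be missed (an empty sample triggers a warning, not an
  error).
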