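# Methods

## Model and assumptions

`hostcycle` implements a deterministic, continuous-time, two-compartment
model of a single clonal microbial lineage.  The compartments — a host and
an environment — communicate through constant per-capita migration rates;
each supports net replication at a constant rate; and crowding is modeled
by quadratic loss terms with intensities $k_{ij}$ (the pressure felt in
compartment $i$ from the abundance in compartment $j$).  The description
is valid when abundances are large enough for differential equations and
the lineage is genetically homogeneous; there is no host demography, no
spatial structure within compartments, and no interaction with other taxa.

Host and environment are mathematically interchangeable: swapping the
labels of all rates, competition terms and abundances maps any solution
onto the swapped solution.  The core types never assume $r_H \le r_E$;
that convention lives only in the presets (with $r_E = 1$ scaling time),
and the relabeling symmetry is enforced by tests down to bitwise equality
of trajectories.

Five named competition patterns are treated as limit cases: none, global
(all $k_{ij} = k$), host-only, environment-only, and equal within each
compartment with no cross terms.  Arbitrary matrices are supported as
`CUSTOM`.

## Fitness measures

* **Asymptotic rate $\lambda$** (no competition): dominant eigenvalue of
  the projection matrix, computed in closed form through the trace and
  determinant.  The discriminant equals $(a_{11}-a_{22})^2 + 4 m_E m_H$
  and is nonnegative for admissible parameters, so $\lambda$ is always
  real; a guard raises if cancellation ever produces a tiny negative
  value beyond round-off.
* **Finite-horizon rate $\Lambda$**: $\log$-ratio of scoped abundance over
  $[0, t_{max}]$ divided by $t_{max}$ (natural logarithm, consistent with
  $\lambda$ as a continuous-time rate).  The scope is the whole lineage by
  default; single-compartment scopes model protocols that harvest only
  host-associated or only free-living microbes.  $\Lambda$ is undefined
  (raises) when the scoped abundance is zero at either endpoint.

## Selection gradients

Three routes produce a `SensitivityVector`, tagged with provenance:

1. **Analytic** ($k=0$): hand-derived partials of the closed-form
   eigenvalue, $\partial\lambda/\partial x = \tfrac12(\partial T +
   (T\,\partial T - 2\,\partial D)/\sqrt{T^2-4D})$ with $T, D$ the trace
   and determinant.  Correctness rests on three-way agreement, asserted in
   tests: the closed form, central finite differences of $\lambda$, and
   the eigenvector perturbation formula
   $(\ell \cdot \partial A \cdot w)/(\ell \cdot w)$.
   At the eigenvalue-collision locus (zero discriminant) $\lambda$ has a
   corner and the function raises rather than returning a one-sided slope.
2. **Finite-difference** (any $k$): forward differences of $\Lambda$ with
   initial step $\delta x = 10^{-4}$ (in units of $r_E$), halved until two
   successive estimates agree to $10^{-6}$; failure to converge within 10
   halvings is flagged on the result, never silent.  Forward differencing
   is the default estimator because it is also well defined on the
   $m = 0$ boundary, where only the positive perturbation direction is
   admissible; a central-difference variant exists for cross-checks and
   falls back to forward at that boundary.
3. **Equilibrium** : partials of the total equilibrium abundance
   $N^* = n_H^* + n_E^*$ — closed-form for host-only / environment-only
   (derived by hand from the equilibrium expressions and validated against
   central differences) and for global competition (where
   $\partial N^*/\partial x = s_x(\lambda)/k$), central differences of the
   root-found state otherwise.  These are the long-horizon limits of the
   finite-difference contours.

## Numerical choices

* **Integrator**: `scipy.integrate.solve_ivp` with DOP853 (adaptive
  explicit Runge–Kutta), defaults rtol $10^{-9}$ / atol $10^{-12}$.  The
  system is smooth and non-stiff at the parameter scales studied.
* **Overflow guard**: with $k = 0$, growth is exponential and raw
  abundances overflow doubles near $t \approx 700/\lambda$.  Such runs are
  integrated by default in the variables $(\log N,\, n_H/N)$, which are
  immune to overflow; the trajectory then carries `log_total` and
  `host_fraction`, and $\Lambda$ is computed directly in log space.
  Accessing raw abundances that are unrepresentable raises — overflow is
  never silently clipped.
* **Negative abundances**: post-hoc clamping to zero is applied only to
  undershoots smaller than the absolute tolerance (round-off); anything
  larger raises as a solver failure.
* **$\Lambda$-probe tolerances**: sensitivity estimation divides solver
  noise by $\delta x$, so probes integrate at rtol $10^{-12}$ by default,
  keeping the noise floor below the $10^{-6}$ refinement tolerance.  Grid
  scans for strategy maps relax to rtol $10^{-9}$ and a single unrefined
  step: region labels depend on the ranking and signs of the components,
  which are far less step-sensitive than their values.
* **Equilibria**: closed forms where available; otherwise a Newton-type
  root find (`scipy.optimize.root`, analytic Jacobian) from the guess
  $(r/k, r/k)$ with three seeded random positive restarts.  Every reported
  state must pass a residual check ($\max|\dot n| < 10^{-9}$); a
  non-converged search raises rather than reporting absence.  "Positive
  equilibrium" means both compartments strictly occupied; boundary states
  are reported as absent with a note.  Local stability (Jacobian
  eigenvalues) is evaluated and reported although the analysis does not
  otherwise use it.
* **Existence thresholds**: bisection of the existence flag, default
  tolerance $10^{-6}$, with an explicit error if the scanned interval does
  not bracket a change.
* **Strategy classification**: the winning trait maximizes $|s_i|$ over
  the non-excluded set; $r_E$ is excluded by default (the lineage is taken
  to be fully adapted to the environment), configurable.  Exact ties are
  flagged as boundary points and broken deterministically in the order
  $r_H, m_H, m_E$.
* **Contours**: region boundaries are the zero set of the deciding
  difference $|s_{m_H}| - |s_{r_H}|$ (or another pair where more regions
  meet), extracted by marching squares with linear interpolation on
  grid-cell edges (`contourpy`) — not a level set of the fitness itself.
  Contour movement is summarized by the symmetric discrete Hausdorff
  distance between polyline vertex sets.

## Grids and default conditions

The standard trait window is $r_H \in [-1, 1]$, symmetric migration
$m \in (0, 2]$, $r_E = 1$, with 101 × 100 nodes for analytic maps; the
exact axis extents of the published maps are not printed anywhere, so
these are a faithful but unverifiable choice.  $r_H \ge -1$ is the window
on which the symmetric-migration growth rate is provably positive for all
$m$.  Finite-difference maps default to coarser grids (21–41 nodes per
axis) because each node costs five integrations; the qualitative
convergence statements tested (contour collapse, monotone approach to the
baseline or equilibrium contour) are insensitive to this resolution, and
grid sizes in tests were chosen to keep the whole suite at about a
minute.  The stage-biased initial conditions $(1,0)$, $(0,1)$ and the
mixed $(0.5, 0.5)$ probe transient effects.

A note on the host-only equilibrium contour: because $N^*$-sensitivities
all scale as $1/k$, the equilibrium-limit contour position is independent
of $k$; on the standard window with $k_{HH}$ competition it lies at
migration rates above $m = 2$, so convergence toward it is tested on an
extended window (and, more robustly, as the monotone draining of strategy
I out of the no-equilibrium strip $m < r_E$, which is how the long-time
behavior manifests inside the standard window).

## What the random fixtures emulate — and what they do not

Property tests draw phenotypes uniformly from $r \in [-1, 2]$,
$m \in [0, 3]$, $k \in (0.1, 2]$: wide enough to cover source–sink
reversals, net death in either compartment, and all competition patterns.
These draws exercise the mathematics, not biology: real life-history rates
are correlated, vary in time, and sit in lineages embedded in communities.
Passing tests therefore validate the solver, the closed forms and the
classification logic — they do not validate the model as a description of
any particular host–microbe system.

Two empirical caveats surfaced by the fixtures are worth recording.
First, "a positive equilibrium always exists under equal per-compartment
competition" holds on the studied region (where the overall growth rate is
positive); a phenotype with $\lambda < 0$ simply goes extinct, and the
package reports that honestly as absence.  Second, with one-compartment
competition the no-equilibrium region's trajectories grow without bound;
$\Lambda$ remains finite and well defined there, which is exactly why the
finite-horizon measure is the right tool for those scans.

## Known limitations

Deterministic and single-taxon only; no demographic stochasticity, no
mutation, no host population dynamics, at most two compartments.
Elasticities (proportional sensitivities) are not provided.  Second-order
sensitivities and sensitivities of the stable distribution are out of
scope.  The bisection for the positivity bound on $r_H$ searches
migration rates only up to $m = 100$; the reported boundary is therefore
accurate to about 1% (the exact bound is approached as the $m$ window
grows).
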