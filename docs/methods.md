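# Methods

## Model class

`bondosc` analyses chemical reaction networks written in the energy-based
(bond-graph) parameterization.  Each species store carries a thermodynamic
constant `K > 0` and a normalized amount `x >= 0`; its chemical potential is
`phi = RT ln(K x)`.  Each reaction element is mass action with a single rate
constant `kappa > 0` and integer stoichiometries, with net flux

    v_r = kappa_r * ( prod_react (K_i x_i)^s_i  -  prod_prod (K_j x_j)^s_j ),

so `v_r = 0` exactly at thermodynamic equilibrium of that reaction and the
closed system is detailed-balance consistent by construction.  Cooperativity
enters as stoichiometric multiplicity of a catalytic species (appearing with
multiplicity `n` on both sides raises its activity to the n-th power without
net consumption).  Chemostats are species whose amount is held constant;
they model open-system boundaries (substrates, sinks) and are also the
device by which the feedback loop is broken.  `RT = 1` by default: all
analysis is performed on amounts rather than potentials, so `RT` only
rescales reported potentials.

The state vector is the vector of dynamic (non-chemostat) species amounts in
declaration order.  This ordering is part of the public contract: Jacobians,
state-space models and trajectories all index into it.

## Loop-broken steady state

Closed-loop equilibria of oscillators are typically unstable, so they cannot
be found by forward simulation of the closed loop.  Instead the designated
product species `P` is clamped as a chemostat at a trial amount `xP`; the
remaining network (assumed open-loop stable) is relaxed to its steady state;
and the net product flux `f_P(xP)` at that state is driven to zero by a
scalar Brent root find.  Implementation details:

- **Relaxation.** The clamped system is integrated with BDF (analytic
  Jacobian supplied) over a doubling horizon, then polished to machine
  precision with a damped Newton step that preserves the conserved-moiety
  totals of the initial condition exactly.  Because the open loop is stable
  by assumption, a Newton solve seeded at the initial condition that lands
  on a non-negative state with a Hurwitz Jacobian (moiety zero modes aside)
  is already the relaxation fixed point; this fast path is taken when it
  succeeds and the integrator is the fallback.  Acceptance of any Newton
  result is decided by the achieved residual, never by the solver's status
  flag.
- **Tolerances.**  Steady-state residuals are differences of one-way
  fluxes, which can be many orders of magnitude larger than the net flux,
  so the residual tolerance is `1e-10 * max(1, largest one-way flux)`.
  The scalar root tolerance on `xP` is `1e-12`.  Both are overridable.
- **Bracketing.**  The default bracket scan is a 25-point geometric grid
  over `[1e-3, 1e3]` times the declared product amount.  With several sign
  changes (the network is multistationary in `xP`), the bracket nearest the
  declared product amount on the log axis is taken, so that parameter
  sweeps follow the continuation of the baseline operating branch rather
  than hopping to a low-activation off state; all brackets found are
  reported in a warning.  A grid point whose residual is exactly zero is
  accepted as the root directly.
- **Cross-check.**  An independent algebraic oracle solves `dx/dt = 0` at
  clamped `xP` with Levenberg-Marquardt, replacing redundant equations by
  moiety-total constraints; the test suite requires relaxation and oracle
  to agree.

## Split-loop linearization

The product's feedback bond carries two variables (amount and flux), so the
loop is split by duplicating `P` into two chemostat ports held at the
steady amount: `Pf` substituted into the declared feedback-side reactions
and `Po` into every remaining product reaction.  Linearizing the split
network about the loop-broken steady state gives a 2-in/2-out state-space
model whose transfer elements are

    [f_f]   [g11 g12] [x_f]        g21: forward (active) gain
    [f_o] = [g21 g22] [x_o]        g11, g12, g22: passive parts

with `f_f`/`f_o` the net product flows through the feedback/output sides.
The single-port loop transfer function is `L0 = -(g11+g12+g21+g22)`; the
loop gain appends the product's integrator, `L = L0/s`, and decomposes as
`L = Lact + Lpas` with `Lact = -g21/s` (the amplifying path) and
`Lpas = -(g11+g12+g22)/s` (admittances and reverse gain — retroactivity).
The feedback/output partition is declared in the model (`LoopSpec`); it is
never inferred automatically.

All `A, B, C, D` blocks are assembled from the closed-form mass-action flux
derivatives; finite differences appear only as a test oracle.  `L0`, `Lact`
and `Lpas` are built directly as state-space models (duplicated-state
constructions rather than polynomial arithmetic) and converted to
zero-pole-gain form via the eigenvalues of `A` and the generalized
eigenvalues of the Rosenbrock pencil, with the gain calibrated by direct
evaluation at real points clear of all roots.  Cancelling pole/zero pairs
(uncontrollable or unobservable modes) are pruned at a relative tolerance
of `1e-8`; `minimal_realization` exposes the same pruning at a caller-chosen
tolerance.  Balanced truncation (Lyapunov Gramians, square-root balancing)
is provided for order reduction of stable models and reports the discarded
Hankel singular values; the classical `2 * sum(discarded)` peak-error bound
is verified in the tests.

## Frequency-domain analysis

- **Phase.**  The phase of a zero-pole-gain model is computed factor by
  factor on a branch that is continuous along the imaginary axis
  (right-half-plane roots are evaluated through the reflected factor), so
  no numerical unwrapping is needed and no grid-resolution jumps occur.
- **Crossover and margin.**  `|L(jw)| = 1` crossings are located on a
  400-point log grid spanning two decades beyond the extreme root
  magnitudes (DC excluded, `w >= 1e-6`) and refined by bisection.  The
  phase margin is `180 + angle(L(jwc))` wrapped into `(-180, 180]`; with
  several crossovers every margin is reported and the minimum is quoted.
  The stability verdict is always taken from the closed-loop poles (roots
  of `den(L) + num(L)`), classifying instabilities as oscillatory (complex
  right-half-plane pair) or monotone (real right-half-plane pole); this
  matters for strongly cooperative positive feedback, where the margin
  alone can mislead near folds of the steady-state branch.
- **Root locus.**  Roots of `1 + kL` over a log gain grid, with branches
  matched by nearest-neighbour continuation (ties broken lexicographically
  on the real part).

## Built-in models

**Illustrative negative-feedback chain** (defaults `N=3`, `n=2`,
`KA=100`, `KZf=1e-6`, `kappa_rf=10`, `Kact=1`, all else unity): a feedback
reaction `Act + E0 <-> E1 + P` (Act, E0 chemostats; `Kact` scales the
lumped source strength) drives a chain of cooperative enzyme-catalysed
conversions `A + n Ei <-> n Ei + E(i+1)`, the last stage producing `P`.
Every stage product (`E2..EN`, `P`) is degraded to the near-zero-potential
sink `Zf` at `kappa_rf`; `E1` is turned over only through the feedback
reaction, which ties `x_E1 x_P = Kact` at steady state.  This wiring is
validated against the reference two-port linearization in the tests (gains
and poles to 3 significant figures).

**Sel'kov glycolytic oscillator** (Table-1 defaults `kappa_r0..r2 = 1e3`,
`kappa_rf = 10`, `K_ATP0 = 1e3`, `kappa_rs = 6e-4`, `KZ = KZf = 1e-10`):
supply `ATP0 <-> ATP`, product activation `E + n P <-> C0`, substrate
binding `ATP + C0 <-> C1`, conversion `C1 <-> C0 + P + Z` (irreversible via
the near-zero-potential chemostat `Z`), and degradation `P <-> Zf`.  All
initial amounts are unity, fixing the conserved enzyme moiety
`E + C0 + C1 = 3`.  The scheme is gated in the tests on reproducing the
reference open-loop poles `{5.365, 910.6, 2210}` and two-port gains
(`g11 -> -717.2`, `g21` gain `4.00e7`, `g22 = -10`) before any margin
regression is trusted.  The throughput is supply-limited at
`kappa_rs * K_ATP0 ~ 0.6`, making the steady product amount
`~ 0.6 / kappa_rf` regardless of the internal kinetics.

**Repressilator.**  The gene-circuit model's 53-species wiring and
parameter table are external inputs; `build_repressilator(path)` loads a
declarative model file when one is supplied and raises `FixtureUnavailable`
otherwise, so pipelines degrade gracefully.

## Parameter sweeps

`phase_margin_grid` re-solves the steady state per grid cell and reports a
margin plus verdict for each; failed cells are flagged, never dropped.  The
packaged sweep windows are chosen to bracket the baseline operating points:
`Kact in {0.2, 1, 5}` by `kappa_rf in [1, 100]` (log-spaced) for the
illustrative chain, and ATP throughput `vATP in [0.3, 0.7]` by
`kappa_rf in [10, 20]` for Sel'kov, with `vATP` swept through
`kappa_rs = vATP / K_ATP0`.  Within these windows the expected qualitative
structure holds and is asserted: removing cooperativity (`n=1`) or a chain
stage (`N=2`) makes every illustrative margin positive while `N=2, n=4`
restores a negative region; Sel'kov is uniformly stable at `n=1`,
oscillatory in a throughput band at `n=2`, and uniformly unstable with a
*real* right-half-plane pole (no oscillation) at `n=3`.  Far outside these
windows the `n=3` branch passes fold points where two equilibria merge and
the margin of the anchored branch is no longer a reliable indicator — a
known limitation of any single-equilibrium frequency-domain analysis.

## Simulation and limit-cycle detection

Nonlinear trajectories use BDF with the analytic Jacobian
(`rtol = 1e-8`, `atol = 1e-11`) on a fixed 1000-point output grid;
chemostat amounts are constants of the integration and conserved totals are
preserved to the integrator tolerance.  Negative state excursions raise a
diagnostic rather than being clipped.  Linearized responses are computed by
eigendecomposition of the closed-loop Jacobian (exact matrix exponential).
The demonstration perturbation is `+1e-3` relative on the product.

Limit-cycle statistics are read from the last 40% of a trajectory: the
period is the median spacing of prominent peaks of the mean-removed product
signal; a cycle is "detected" only if the trajectory spans at least 10
putative periods (shorter trajectories are a precondition error) and the
peak-to-peak amplitude is stationary within 1% over the last three periods.
Detection horizons must cover the linear growth time: `t_end = 40` suffices
for the illustrative chain (growth rate `~1.3 /s`), while Sel'kov needs
`t_end ~ 150` (growth rate `~0.18 /s`).

## Numerical choices and limitations

- Transfer-function extraction via eigen/pencil computations is accurate
  for the moderate orders produced here (up to tens of states); very
  high-order models should be reduced (balanced truncation) before
  zero-pole-gain conversion.
- The phase-margin indicator presumes a stable open loop; no Nyquist
  encirclement counting is performed.  Verdicts therefore always
  cross-check against the closed-loop poles.
- The steady-state branch policy (nearest the declared product amount)
  makes multistationary sweeps deterministic but intentionally ignores
  coexisting branches; a continuation study is out of scope.
- Reported phases are degrees and frequencies rad/s; all internal phase
  arithmetic is in radians.  Time units are carried as trajectory metadata
  and never converted implicitly.
- The synthetic models are normalized (dimensionless amounts, unit RT) and
  noiseless; agreement of the pipeline on them demonstrates correctness of
  the analysis machinery, not robustness to parameter uncertainty or
  stochastic (low-copy-number) effects in real reaction networks.
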