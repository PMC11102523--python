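# Methods

## Model and assumptions

`viralsir` models the audience of a single video as three well-mixed
compartments: susceptibles S (unaware), infecteds I (active sharers) and
recovereds R (watched, permanently stopped sharing).  Person-to-person
contact occurs at rate βIS/N; a contact always removes the susceptible from
S, creating a new sharer with probability β₁/β and otherwise a direct
recovery (someone who watches but never shares), which is why β > β₁ is a
structural requirement.  Advertising converts susceptibles to sharers at
rate γN²/(N+I): equal to γN when no one is sharing and monotonically
decaying as sharers proliferate, capturing a budget that is spent hardest
when organic spread cannot yet sustain itself.  Sharers recover at rate α
(exponentially distributed sharing spells, mean 1/α) and new users enter
the platform at rate bN.

The reference population N is frozen at the initial total S₀+I₀+R₀
throughout ("constant-N model"); the total then grows linearly,
S+I+R = N₀ + bNt, and the (S, I) subsystem is autonomous.  This
approximation is sensible while cumulative inflow is small relative to the
audience and degrades over long horizons.  A fraction-form right-hand side
(s, i, r) = (S, I, R)/N(t) with a genuinely growing N(t) is provided
(`rhs_fractions`) for exploratory integration, but no equilibrium or
stability results are offered for it: its fixed points solve a cubic and
the package deliberately does not extrapolate the constant-N theory there.

## Equilibrium and stability

For α > b > γ (with β > β₁) the reduced system has a unique interior fixed
point: I* is the positive root of f(I) = αI² + (α − (β₁/β)b)NI −
(1 − β₁/β)γN² − (β₁/β)bN², whose constant term is negative, so the root is
the explicit quadratic formula — no iteration is involved.  S* follows from
the S-nullcline.  The implementation asserts (rather than branches on) the
positive discriminant, which the sign of C guarantees.  Reported alongside:
the bracket S₋ = (b−γ/2)N/β < S* < (α−γ/2)N/β₁, the value f(N) > 0 that
certifies I* < N, the Jacobian, and the characteristic coefficients
B̄ = −tr J and C̄ = det J whose positivity certifies local stability;
global convergence is checked dynamically in the test suite rather than
symbolically.  Outside the ordering α > b > γ all equilibrium operations
raise `TheoryRegimeError`: the theory proves nothing there, and silently
returning a root would invite misuse.

The advertising-sweep table (`equilibrium_vs_gamma`) shows the policy
trade-off: S* falls and I* rises monotonically in γ, while S*+I* — and
hence the eventual recovered (total-viewer) share — responds
non-monotonically, so an advertising budget has an interior optimum.

## Agent-based simulation and attribution

The stochastic model advances in steps of length τ (default 1 day, matching
the daily resolution of view counts) with four phases whose intensities are
all frozen at start-of-step values, making the expected one-step increment
exactly τ·(S′, I′, R′) + O(τ²):

1. *contact*: P(t) draws of a sharer, uniform with replacement; each draw
   converts one uniformly chosen susceptible with probability τβ·O(t)/N,
   the convert becoming a sharer with probability β₁/β (else recovered) and
   inheriting the sharer's lineage at generation+1;
2. *advertising*: Poisson(τγN²/(N+P(t))) recruits, capped at the remaining
   susceptibles, each starting a lineage-B chain at generation 1.  The
   Poisson choice makes the one-step mean exact with natural variance;
3. *arrivals*: ⌊bNτ + carry⌋ new susceptibles, the fractional remainder
   carried forward so cumulative inflow matches the ODE exactly;
4. *recovery*: each start-of-step sharer recovers independently with
   probability τα.

Two design points deserve emphasis.  First, the contact phase deliberately
uses the conversion probability τβ·O(t)/N with N the *initial* population,
rather than "pick a uniformly random member of the current population and
convert if susceptible".  The two coincide while the agent count equals N,
but arrivals grow the population (fivefold by t = 200 in the reference
configuration), and the uniform-target rule would dilute the effective
contact rate by the ratio of current to initial population — a diluted
mean-field check shows deviations near 0.4·N by t = 50, destroying the
correspondence with the constant-N ODE that the simulator exists to
realize.  Second, initial sharers (and any initial recovereds) root
lineage-A chains at generation 1; advertising recruits root lineage B.
Since labels are assigned exactly once, at conversion, TypeA + TypeB equals
the total viewer count P+Q at every step.

Per-draw probabilities must not exceed 1: configurations with τβ > 1,
τα > 1, or τβ·O/N > 1 at run time raise an error instructing a smaller τ
instead of silently clipping.

The two attribution measures answer different questions and are never
combined: n_A (the time integral of the advertising function) counts only
*direct* advertising conversions, while the Type B count credits
advertising with every chain it seeded.  In the reference configuration
n_A(100) ≈ 1 670 out of ≈ 28 000 conversions, yet Type B viewers dominate
Type A in essentially every realization — advertising's effect is mostly
indirect.

Ensemble runs derive the seed of realization k as `SeedSequence([seed, k])`,
so single realizations can be reproduced in isolation.

## Calibration

Observed daily views g_i on days 0..n are accumulated into ⟨R⟩_i and
matched to the model's R(t_i) by the normalized cost
Er = Σᵢ(⟨R⟩ᵢ − R(tᵢ))² / ((maxᵢ⟨R⟩ᵢ)²·t_max), which is invariant to jointly
rescaling the data and the population.  Because the audience size is not
observable, S₀ defaults to 2×10⁹ (the platform's public active-user count)
with I₀ = 100 token initial sharers and R₀ = 0; N = S₀+I₀ inside the cost.

The minimizer is Nelder–Mead (adaptive simplex) over a
feasibility-preserving reparameterization: log-coordinates for β, α, γ and
b enforce positivity, and β₁ = β·sigmoid(u) enforces 0 < β₁ < β (when β₁ is
free while β is fixed the positive gap β − β₁ is log-parameterized
instead).  All five rates are free by default — daily-view data clearly
carries information about the inflow b — but any subset can be pinned.
Nelder–Mead is initialization-sensitive and the cost surface is multimodal
(a two-parameter slice already exhibits a spurious local minimum), so the
fit runs 5 restarts jittered by Gaussian noise (σ = 0.35) in the
transformed coordinates, keeps the best, and stops early once the cost
falls below 10⁻⁹ (only reachable on effectively noiseless data).  Inside
the optimizer the model is integrated as the reduced 2-D system with
R recovered from the linear first integral, via LSODA at rtol 10⁻⁷ — the
published-figure-scale R values make tighter tolerances pointless against
observation noise.  Fits are deterministic given (series, configuration,
seed).  No uncertainty quantification is attempted; the cost is a fitting
criterion, not a likelihood.

## Synthetic data

The generator integrates the model at chosen true rates, forms noiseless
daily views G(i) = R(i) − R(i−1) (with G(0) = 0, since R(0) = 0), and
applies mean-preserving multiplicative noise g_i = G(i)·exp(ε_i − σ²/2),
ε_i ~ N(0, σ²), so E[g_i] = G(i) exactly and views stay nonnegative.
Multiplicative log-normal noise is the package's own choice of observation
model — daily views span orders of magnitude over a video's lifetime, which
rules out additive noise; a Poisson option covers small-count regimes.  The
default synthetic regime (S₀ = 10⁶, I₀ = 100, 200 days, σ = 0.05) is small
enough that a full five-parameter recovery runs in seconds while exhibiting
the same rise-peak-decay shape as real view curves.

What passing the recovery tests shows — and does not.  The generator
reproduces the *statistical structure the fit assumes* (the model's own
trajectory plus independent per-day multiplicative noise).  Real view
series additionally contain weekday seasonality, recommendation shocks,
rebounds and model misspecification; recovery on synthetic data therefore
validates the estimation machinery, not the model's adequacy for any
particular video.

## Numerical choices

- Deterministic integration: adaptive Runge–Kutta 4(5) (`solve_ivp`,
  RK45) at rtol 10⁻⁸, atol 10⁻¹⁰·N₀; output sampled on a uniform grid
  (0.1 day for attribution work) while internal steps stay adaptive.
  Sub-tolerance negative undershoot is clipped to zero; anything larger
  aborts with diagnostics.
- Attribution integrals: composite trapezoid on the output grid, with
  linear interpolation of the cumulative integral for off-grid horizons.
  At 0.1-day spacing the quadrature error is far below the 10⁻⁴·N
  flux-balance tolerance used in tests.
- The advertising term γN²/(I+N) is finite at I = 0, so the S-axis needs
  no special casing anywhere.
- Degenerate calibration inputs (all-zero series, single-day series) are
  refused: the normalization max⟨R⟩²·t_max would be undefined.
- Problem sizes in the test suite (N = 10⁴ agents, 20–200 realizations,
  200-day fits, 200 random parameter draws) were chosen so the full suite
  completes in a couple of minutes while keeping Monte-Carlo standard
  errors well inside the asserted tolerances.

## Known limitations

- The constant-N first integral S+I+R = N₀+bNt makes long-horizon
  predictions grow linearly; real view counts eventually fall off this
  trend, so multi-year extrapolation is outside the model's validity.
- No contact-network structure, no heterogeneous agent traits, no
  rebound/forgetting dynamics, no competition between advertisements.
- The equilibrium theory is silent outside α > b > γ, and so is the
  package (by explicit refusal).
- Published best-fit parameter sets for three music videos ship as
  reference fixtures (`case_studies.py`); the underlying daily-view series
  are not redistributable, so those absolute fits are not re-derived here —
  only their β₁/β ratios and the machinery that would produce them are
  exercised.
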