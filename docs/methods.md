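# Methods

## The model

`taexcite` models a type II toxin–antitoxin (TA) module of the *mazEF*
kind: a single operon transcribed at rate `r_F` into a shared mRNA `M`,
translated into an antitoxin `A` (rate `b_1`) and a toxin `T` (rate
`b_2 < b_1`), which associate into a neutral complex `AT` (rate `a_T`).
The mRNA and the free antitoxin are unstable (`d_m`, `d_a`); the toxin and
the complex are only diluted by cell division (`d_c`); antitoxin inside the
complex is partially protected, degrading at `F·d_a` with `F = 0.1` and
releasing its toxin. The defining nonlinearity is *toxin-induced mRNA
cleavage*: above a threshold of `K_t` toxins the transcript's decay rate
rises by up to `d_large`, switched by a Hill function with coefficient `n`
(default 2).

The dimensional four-variable system (`ode_models.rhs_full`) is
nondimensionalized by the mRNA decay rate and the translation ratio
`epsilon = b_2/b_1` (`parameters.normalize`; the resulting groups and the
defaults derived from measured rates are listed in
`data/mazef_reference.yaml`). Because `epsilon ≈ 0.07`, the mRNA and free
antitoxin relax one to two orders of magnitude faster than the toxin and
the complex; setting their time derivatives to zero (quasi-steady-state
approximation, QSSA) closes the system on the slow pair `(x, y)` = (toxin,
complex) (`rhs_reduced`). Two extensions re-open the reduction in
controlled ways: a secondary complex `TAT` (one antitoxin binding two
toxins, `rhs_tat`), and transcriptional repression by DNA-bound complex,
a factor `r/(r + y)` on transcription. Growth-rate and translational
inhibition at high toxin load scale every dilution term by
`f_t = S_t/(1 + B_t·x)` and every translation term by
`f_m = S_m/(1 + B_m·x)`; biochemical degradation (`d_m`, `d_a`, `F·d_a`)
is never scaled by `f_t`, because proteolysis does not slow down when the
cell stops growing. Whether `f_m` should also scale transcription is not
determined by the model statement we implement; we scale translation only.

Nutritional stress acts through Lon-type proteases (raising `d_a`, hence
`delta_a` and — with `F` a property of the complex — `delta_AT`) and
through the toxin translation rate (raising `epsilon`). Stress schedules
are piecewise constant: parameters switch instantly at window boundaries.

## Phase plane and regimes

With `n ≥ 2` the toxin nullcline NC(x) is folded; its middle branch is the
excitation threshold: trajectories pushed across it run a large excursion
(toxin spike) before returning. Fixed points are found by bracketing the
nullcline intersection on a log-spaced grid and polishing with Newton's
method using the analytic Jacobian (chain-ruled through the QSSA
expressions; verified against finite differences in the tests).

Regime classification combines three measurements:

* **oscillatory** — the unique fixed point is unstable (a limit cycle of
  repeated excitations attracts the dynamics);
* **excitable** — the fixed point is stable, a probe displaced to 1.05×
  the threshold-branch `x` at the fixed point's `y` produces an excursion
  with `max x ≥ 10·x*`, **and** the threshold lies within one
  intrinsic-noise standard deviation of the fixed point;
* **monostable** — otherwise.

The noise-reachability condition is essential and deliberate. A
super-threshold kick produces an order-of-magnitude excursion at *every*
stable parameter set with a folded nullcline — the excursion probe alone
cannot separate "monostable" from "excitable". What distinguishes the
regimes in practice is whether the module's own molecular noise can reach
the threshold. We estimate the noise scale from counting statistics: the
toxin count at the fixed point is `x*·epsilon/d_m` molecules, so one
standard deviation is `sqrt(x*·d_m/epsilon)` in `x` units (the anchor
`d_m = 0.002 s^-1` and the cut of 1 SD are exposed as parameters). At the
reference translation ratio this yields threshold distances of 4.3 SD at
`delta_a = 1` (monostable), 3.0 at the unstressed default 1.16, 1.35 at
1.5, and 0.11 at 2 (excitable) — matching the stochastic behavior of the
corresponding Gillespie runs. The estimate is Poissonian and
one-dimensional; translation bursting and fluctuations of `m` and `a` are
not included, so the 1-SD cut is a calibrated operational boundary, not a
first-passage computation.

## Bifurcation analysis

Fixed points are continued naturally in `delta_a` or `epsilon` (previous
solution seeds the next Newton solve; the branch has no folds in the
scanned ranges). Stability changes are refined by bisection on the leading
eigenvalue's real part; a crossing with nonzero imaginary part is a Hopf
point. Criticality is decided empirically — integrating 0.02% past the
crossing and asking whether a bounded small-amplitude cycle exists — which
cannot distinguish supercritical from very weakly subcritical; the onset
period is read from that near-onset cycle. The cycle amplitude explodes to
a full excursion within ~1% of the bifurcation parameter (a Canard
explosion), while the period stays finite at onset (type II excitability).

Two conventions exist for the `epsilon` axis. Sweeping `epsilon` with all
other dimensionless groups frozen (only `delta_AT` co-varying through the
fixed `F`) leaves the `delta_a = 2` fixed point stable for all
`epsilon` in [0.01, 0.3] — no bifurcation exists on that axis. Physically,
however, `epsilon` moves through the toxin translation rate `b_2`, and the
normalization divides by `epsilon`, so `delta_c`, `delta_AT` and `kappa`
(all ∝ 1/epsilon) and `alpha` (∝ epsilon) co-vary. Under this physical
convention the `delta_a = 2` branch has a supercritical Hopf near
`epsilon ≈ 0.078`. `with_stress_parameter` therefore defaults to
`mode="physical"` and offers `mode="normalized"`; `delta_a` sweeps are
identical under both.

Limit-cycle metrics (amplitude, period, excitation time = time spent above
the cleavage threshold `kappa`) are measured on a long integration
(default `500/epsilon` in `tau`, first half discarded as transient),
detecting cycles as successive upward `kappa` crossings.

## Stochastic simulation

The jump process is sampled with the direct Gillespie method (one
propensity sum, two uniforms per event) in a numba-compiled kernel; states
are recorded on a regular grid (default 2–10 s), and runs are reproducible
given a seed. Reaction channels are constructed term-by-term from the
deterministic equations so that stoichiometry-weighted propensities
reproduce the rate equations exactly — this mean-field identity is
asserted in the tests for every variant and is what licenses the
deterministic/stochastic comparisons. DNA binding is a Hill-modulated
transcription propensity `r_c/(r_c + AT)` (with `r_c = r·epsilon/d_m`
converting the normalized repression scale to molecules), not an explicit
operator-binding species; an explicit-operator mode would add
transcriptional bursting noise and is noted as an extension. The cleavage
propensity uses the instantaneous toxin count (no delay). Stress windows
rebuild the channel rates at each boundary and restart the exponential
clock, which is exact because the process is Markov at fixed rates.
Default initial condition: the deterministic fixed point rounded to
integer counts.

### Excitation statistics and event merging

A stochastic excitation is a maximal interval with `T > K_t`, with
edge-truncated events discarded (`metrics.detect_excitations`, crossings
located at sample times for jump paths, by linear interpolation for ODE
output). Raw crossing intervals are however heavily fragmented: shot
noise at the threshold splits one physical spike (≈3700 s at
`delta_a = 3`) into dozens of crossings with a median of ~20 s. A genuine
quiescent interval requires the cleaved transcript pool to recover, which
takes on the order of one mRNA lifetime (`1/d_m` = 500 s, i.e. `tau ≈ 1`);
pooled statistics therefore merge events separated by gaps shorter than
`1/d_m` (`metrics.merge_events`; the raw intervals remain available with
`min_gap=0`). With this convention the stochastic mean excitation time at
`delta_a = 3` agrees with the deterministic limit cycle well within one
stochastic standard deviation, while the stochastic period exceeds the
deterministic one — the expected onset lag, since noise must carry the
state across the threshold before each spike.

### Closed-form excursion

Far above threshold, production is off and the pair `(x, y)` decays by
dilution and complex disassembly; dropping the binding flux `alpha·a·x`
from the complex balance gives the two-exponential excursion
`x(tau) = (x0+y0)·e^(−eps·delta_c·tau) − y0·e^(−eps·(delta_c+delta_AT)·tau)`
(`metrics.analytic_excitation`). The formula is exact when production and
binding are removed (verified to <2% against the integrator), and it
captures the excursion's shape and timescales. It is *not* quantitatively
tight at the reference parameters: the neglected binding flux is 2–6× the
retained dilution flux during the decaying flank, so the closed form
overshoots the peak by ~40% and its pointwise error grows without bound as
`x` approaches `kappa`. (The total `x + y` does decay at exactly
`eps·delta_c`, as the derivation assumes; it is the `x`/`y` split that the
uncoupled-`y` approximation distorts.) The corresponding agreement check in
the acceptance suite asserts a 5% pointwise bound on the decaying flank
and fails for this reason; we keep the formula exactly as stated and the
bound as specified rather than substituting a corrected formula.

## Problem sizes and numerical choices

Deterministic integrations use LSODA with `rtol = 1e-8`,
`atol = 1e-10` (the system mixes `O(1/eps)`, `O(1)` and `O(eps)`
timescales); sub-tolerance negative undershoots are clipped to zero,
larger ones are errors. Newton fixed points are polished to residuals
below 1e-13 and deduplicated at 1e-6 relative. Continuation uses 40 steps
per branch with bisection refinement to 1e-8. Stochastic comparisons use
2×10^5 s runs (≈25–35 deterministic cycles at `delta_a = 3`): 30–100 seeds
for the oscillatory comparison, 8 averaged runs at 100× volume for the
large-volume limit (transcription and the cleavage threshold scale with
volume, the bimolecular rate inversely), and 20 runs of 10^6 s per variant
for the low-stress excitability contrast. These sizes give stable
statistics for every quantity reported while keeping a full reproduction
run in the low minutes on one core.

## The low-stress variant contrast

At `delta_a = 1.5` the minimal and TAT modules never fire in 2×10^7 s of
simulation, while the DNA-binding module (repression scale `r = 4.9`)
fires several times: repression lowers the complex buffer and the absolute
molecule numbers, bringing the threshold within reach of the (relatively
larger) fluctuations. The event rate is low (~1 per 2.5×10^6 s); with the
Hill-modulated repression used here there is no transcriptional bursting,
which in an explicit-operator model would raise it. For the Hill
coefficient contrast, the testable geometric fact is the nullcline fold:
with `n = 1` (hyperbolic cleavage) NC(x) has no fold at the stressed
reference parameters, so no excitation threshold exists; adding
translational inhibition (`S_m = B_m = 1`) restores a two-fold (degree-two)
nullcline and with it the threshold. Growth-rate inhibition
(`S_t = B_t = 1`) lengthens the toxic phase: the measured limit-cycle
excitation time at `delta_a = 3` grows ~2.6× when dilution is suppressed
at high toxin levels.

## What the tests do and do not show

All quantitative checks run on synthetic data generated by the package's
own deterministic and stochastic engines at the reference parameters; they
validate internal consistency (reduction vs full model, stochastic mean
field vs rate equations, closed-form limits) and the regime structure, not
biological measurements. Real cells add extrinsic noise, cell-cycle gating
and partitioning at division, transcriptional bursting, and multi-site
operator regulation, none of which are modeled; single-cell dynamics only,
no population bookkeeping.

## Known limitations

* Criticality classification is phenomenological (simulation just past
  onset), and cannot rule out weak subcriticality.
* The regime boundary depends on the 1-SD noise-reachability cut; the cut
  is calibrated to the reference stress levels, not derived from
  first-passage theory.
* The closed-form excursion is a shape estimate, not a 5%-accurate
  solution (see above).
* Natural-parameter continuation would fail on folded branches; none occur
  in the scanned ranges.
* The re-stabilization of the fixed point at very high stress (a
  toxin-dominated steady state) is observable by extending the branch
  range but is not asserted anywhere, as no reference value exists for it.
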