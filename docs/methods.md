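# Methods

## The gene circuit model

A gene circuit is a hybrid dynamical model of a row of syncytial blastoderm
nuclei along the antero-posterior (A–P) axis.  Each nucleus carries an
identical regulatory network over the trunk gap genes (default *hb*, *Kr*,
*gt*, *kni*); four *external inputs* (maternal gradients Bcd and Cad,
terminal gap genes Tll and Hkb) act on the gap genes but are not regulated
by them.  During interphase the product concentration `v_i^a` of gene `a`
in nucleus `i` obeys

    dv_i^a/dt = R^a g(u_i^a)
                + D^a(n) [(v_{i-1}^a - v_i^a) + (v_{i+1}^a - v_i^a)]
                - lambda^a v_i^a,

    u_i^a = sum_b w^{ba} v_i^b + sum_m e^{ma} v_i^m + h^a,
    g(u)  = (u / sqrt(u^2 + 1) + 1) / 2.

Assumptions worth stating explicitly:

* **Sigmoid form.** `g` is the classic connectionist regulation-expression
  function: strictly increasing, `g(0) = 0.5`, point-symmetric
  (`g(u) + g(-u) = 1`).  Regulation is additive in the total input `u`;
  there is no cooperativity beyond the shared saturation.
* **Hybrid time structure.** A cleavage cycle is interphase → mitosis →
  instantaneous division.  The default schedule runs from early cycle 13
  (t = 0 min) to gastrulation (t = 71.100 min) with mitosis on [16, 21] min.
  During mitosis only synthesis stops; decay and diffusion continue, and
  external inputs remain defined (they only enter through the synthesis
  term).  Mitosis entry/exit and division are implemented as integration
  breakpoints — the solver is stopped and restarted, never stepped across a
  discontinuity.  Whether the original solvers treated mitosis as a
  breakpoint or a smoothed switch is not documented; breakpoints are exact
  for an event of this kind and are the package's choice.
* **Division.** At 21 min each mother nucleus j splits into daughters 2j and
  2j+1 on the doubled lattice, both inheriting the mother's concentration.
  The diffusion rate is rescaled as `D(n) = D * 4^n` (Fickian `D/l^2` scaling
  with the inter-nucleus distance halving, n = divisions so far).
* **Boundaries.** No-flux: the missing neighbour term is omitted at the
  lattice edges.

### Lattice conventions

Nucleus j of a stage with `n_axis` nuclei along the whole axis (50 at C13,
100 at C14A) spans `[100j/n_axis, 100(j+1)/n_axis)` % A–P, half-open; a
nucleus belongs to the modelled lattice iff its span intersects the closed
trunk interval.  For the default 35–87% trunk this gives 27 nuclei (108
ODEs) at C13 and 53 nuclei (212 ODEs) at C14A; the extended 35–92% region
has 58 nuclei.  After division, daughters whose spans leave the trunk are
dropped: for 35–87% that is the single most anterior daughter (axis index
34); for 35–92% one daughter on each side.  (The index convention is what
pins the printed lattice sizes; which side is clipped follows from it.)

### Numerical integration

`scipy.integrate.solve_ivp` with LSODA (adaptive, stiff-capable,
implicit multistep when needed; BDF available via `solver_options`),
defaults `rtol = 1e-6`, `atol = 1e-8`.  A fixed-step RK4 brute-force oracle
at dt = 1e-3 min agrees with the adaptive solution within 1e-4 relative
error on a two-gene toy circuit (tested).  During optimisation the
tolerances are relaxed (`rtol = 1e-3`…`1e-4`) — integration error is then
well below the data noise floor — and every reported fit is re-evaluated and
QC-screened at tight tolerances.

## Data preparation

Expression boundaries are annotated by two anchor points (x0, y0), (x2, y2)
in (% A–P, relative intensity): the positions where staining approaches
background and maximum.  Each boundary is modelled as the unique cubic
through the anchors with zero first derivative at both end knots, normalised
to run 0 → 1 (for three control points with the midpoint at half height this
is the smoothstep polynomial `3s^2 - 2s^3`).  Embryos are aggregated by
coordinate-wise medians of start and end anchors (even group sizes: mean of
the two central values).  Median boundaries are assembled into an integrated
profile per gene and time class: plateau 1 between a rising boundary and the
next falling one, 0 outside, spline values across the spans; a domain with
no annotated anterior (posterior) boundary extends to the anterior
(posterior) end of the axis.

Post-processing, in order: (1) binning to the stage's axis bins (profiles
are evaluated at nucleus centres), (2) spatial intensity scaling
`1 - |x - 50|/100` (×1.0 mid-embryo, ×0.5 at the poles), (3) temporal
scaling by the unique quadratic through (0 min, 0.1), (48 min, 1.0),
(71.1 min, 0.7) — rendering "second-degree spline" through three anchors;
its interior maximum falls at 45 min — and (4) multiplication by 200 to
match the protein-data concentration scale.  The two scalings are
independent multipliers and commute; binning must precede them.

WLS weights approximate expression-level-dependent variance:
`v = 1/(eps + yhat)^2` on the normalised pre-scaling intensity, `eps = 0.1`
(configurable).  The exact original formula is not recoverable; the contract
implemented is a strictly decreasing, bounded weight that maximally
penalises ectopic expression where `yhat = 0`.  The late posterior Kr
domain, which is under terminal/Forkhead control, is removed from fitting
data by dropping its boundary annotations.

The packaged boundary table prints only spline start points; the end anchor
defaults to 5% A–P into the domain (configurable).  Where a printed domain
is narrower than two widths, the width is clipped so the rising and falling
spans meet at the domain midpoint instead of overlapping.

### Initial conditions

Gap gene initial conditions at t = 0 interpolate linearly in time between a
C12 anchor (t = −6.2 min) and the C13 data (t = 10.55 min).  The quantified
dataset has no C12 values; mRNA levels are low at the start of C13, so the
C12 anchor defaults to zeros unless supplied.

## External inputs

All inputs satisfy one contract — a deterministic, non-negative function
f(x % A–P, t min) — and the fitting machinery never branches on measured vs
artificial provenance.  Artificial generators:

* **Bcd**: time-independent anterior exponential `A exp(-x/L)`, least
  squares in linear space on pooled samples (log-space optional); default
  A = 200, L = 20.
* **Cad**: a smooth surface with three qualitative features — complementary
  to Bcd at onset (posterior-rising saturating gradient), abdominal
  (~50–80%) levels non-increasing in time, and a posterior stripe near 80%
  A–P appearing from T6.  Implemented as base gradient × time-growing
  repression bump + ramped Gaussian stripe; the original used thin-plate
  splines over unpublished control points, so the artificial surface is
  validated by the feature predicates, not curve identity.
* **Tll/Hkb**: boundary positions averaged (mean) across all time classes,
  assembled into a time-invariant domain profile.

Amplitudes of artificial inputs relative to the ×200 gap-gene scale are not
published; the default is 200, configurable.

## Fitting

Cost: `S = sum_t sum_i sum_a v (model - data)^2`, with v ≡ 1 for OLS.
Failed simulations receive a large finite penalty (1e6 per data point) so
optimisation can reject them without aborting.  Reported fit quality is the
weight-independent `RMS = sqrt(sum (model - data)^2 / N_d)`.

The global optimiser is a serial adaptive Lam-schedule annealer: single-
coordinate Gaussian moves with per-coordinate scale adaptation toward the
0.44 acceptance plateau, and a temperature steered multiplicatively so the
measured acceptance rate tracks the Lam–Delosme target trajectory (warm
start decaying to the 0.44 plateau by 15% of the run, plateau to 65%, then
a cooling tail); the final 5% of moves accept improvements only, making the
end of every run a greedy descent.  The original massively parallel
deployment (50 cores × 7 h per run) is explicitly not reproduced; desk-scale
budgets need sharper local convergence, so two additional backends share the
same contract: scipy differential evolution, and seeded multistart bounded
trust-region least squares (TRF) on the weighted residual vector.  A TRF
polish is applied after any global phase by default.  All backends are
deterministic given the seed.

Default parameter bounds on the ×200 concentration scale: |w|, |e| ≤ 0.3;
R ∈ [0.01, 30] 1/min-concentration; lambda ∈ [0.005, 0.3] /min (half-lives
of ~2–140 min); D ∈ [0, 0.3] /min; h ∈ [−5, 5].  The default gap-gene mask
fixes h = −2.5 for all gap genes and the Hkb→{Kr, gt, kni} entries of E at 0
(Hkb→hb stays free); the mask system supports per-entry overrides so any
other fixing scheme is a configuration, not a code change.

### Automated quality control

Visual inspection of fits is replaced by three automated screens:
*solver sensitivity* — the largest change in sampled model output when the
integration tolerances are tightened tenfold; *brittleness* — the largest
RMS change under ±0.1% perturbation of each free parameter; and *defect
heuristics* per gene and time class — a missing domain (model below 10% of
the data slice maximum where data exceed 50%), an ectopic domain (model
above 50% where data are below 10%), and violations of the A–P order of the
genes' expression maxima.  Thresholds (10%/50%, and the pass limits of 1.0
concentration unit for sensitivity and 1.0 RMS for brittleness) are
configurable defaults on the ×200 scale.

## Identifiability

With the fitted optimum treated as the truth, the confidence region is the
ellipsoid `||J (theta - theta_hat)||^2 <= Delta`,
`Delta = p s^2 F_alpha(p, N_d - p)`, `s^2 = S/(N_d - p)`, where J is the
Jacobian of the weighted residual vector with respect to the p *free*
parameters (masked parameters contribute no columns; the documented
convention is that p counts free parameters only).  J is computed by central
finite differences with relative step 1e-4 and absolute floor 1e-6 —
validated against the exact design-matrix Jacobian on linear models.
Dependent intervals are axis slices of the ellipsoid
(`sqrt(Delta)/||J e_j||`); independent intervals are its bounding box from
the SVD `J = U S V^T` (`sqrt(Delta sum_k V_jk^2 / sigma_k^2)`).  Dependent ⊆
independent always; on a 1-parameter linear regression both equal the
classical t-interval (tested to 1e-6).  Singular values below 1e-10 of the
largest are treated as zero; parameters carried by null directions get
infinite independent intervals and are reported non-determinable rather than
failing.  alpha defaults to 0.05.

A regulatory weight is *determinable* when its independent interval lies in
one category — repressing (< −0.005), none ([−0.005, 0.005], closed), or
activating (> 0.005) — *weakly determinable* when it excludes exactly one
category, *non-determinable* otherwise.

## Network analysis

Interaction triplets count (repressing / none / activating) classifications
over an ensemble; consensus requires a strict majority, ties are
"ambiguous".  The *net effect* of an interaction is its weight times the
regulator concentration averaged per nucleus-time over the overlap region
(nuclei where both genes exceed 10% of their slice maxima; for multi-domain
genes the posterior-most contiguous run, the one relevant for the shift
analysis).  The integration window defaults to all post-division data times;
per-nucleus-time normalisation keeps regions of different sizes comparable.
The anterior-shift mechanism is scored present when the posterior-to-
anterior net effect is repressive and stronger than the reciprocal one.
Mechanism fractions over an ensemble (alternating cushions, per-gene
auto-activation, the three shift net effects, the hb/Kr net-repression
direction, Bcd+Cad activation, Tll+Hkb inhibition) are averages of
per-circuit booleans, so the ensemble report equals the mean of per-circuit
reports.

Reduced-data experiments: per (gene, time class, boundary) group of n
observations, boundary reduction retains `max(1, round(fraction * n))`
(round half away from zero) drawn uniformly without replacement — at least
one observation always survives; time-class reduction keeps the first and
last classes always and removes intermediates uniformly at random.  Both are
deterministic per seed.

## Synthetic data and the recovery benchmark

The generator simulates a known circuit, adds Gaussian measurement noise to
the sampled concentrations (sigma as a fraction of the dataset maximum,
default 0.05), extracts boundary positions as threshold crossings at 50% of
each slice maximum (the convention used for protein-data boundary tables),
jitters them across pseudo-embryos (sigma_x default 1% A–P, 10 embryos per
boundary), and emits annotations in the exact schema the real pipeline
consumes.  Everything downstream of a (scenario, seed) pair is reproducible
bit for bit.

The default benchmark (`bench2gene`) is a two-gene, one-input, 20-nucleus,
five-time-point circuit without division, sized so a full recovery
experiment runs in minutes on one CPU.  Gene gA forms an anterior domain
under an exponential input gradient; gB is driven more weakly by the same
input and strongly repressed by gA, forming a posterior domain.  The truth
matrix W = [[0.04, −0.15], [−0.04, 0.04]] keeps every gap–gap weight well
clear of the 0.005 classification cutoff, and the benchmark mask fixes h and
D during fitting (mirroring the practice of fixing kinetic nuisance
parameters for determinability), leaving 10 free parameters.  These choices
were made because weaker self/cross weights are not sign-identifiable at the
specified noise level and a 12-parameter landscape is too multimodal for a
minutes-scale optimisation budget; the scenario's stated conditions (network
size, lattice, time points, noise) are fixed.

What passing the recovery test does and does not show: the synthetic data
share the structure of the real data (boundary-shaped domains, per-embryo
position jitter, expression-level-dependent weighting) but not its failure
modes — no staining background, no staging error, no embryo-to-embryo
registration error, and the fitted model class is exactly the generating
class.  Recovery here demonstrates the machinery (simulation, cost,
optimisation, sign read-out) is correct and well-conditioned, not that
four-gene circuits fit to real embryo data are globally identifiable — the
determinability analysis exists precisely because they are not.

## Problem sizes used in the shipped tests

The test suite runs the full hybrid trunk simulation (108/212 ODEs) for
structural checks, and the recovery experiment at the benchmark size
(40 ODEs, 10 seeded runs plus 5 shuffled controls, ~10 minutes total);
oracle comparisons (RK4, closed-form regression intervals) use toy systems
where the oracle is exact.  Ensemble analyses in the tests use hand-built
parameter sets with known classifications.

## Known limitations

* The Lam annealer alone, at desk-scale move budgets, does not reliably
  reach the global basin of even the two-gene benchmark; the multistart
  trust-region backend is the practical default for recovery experiments.
* Confidence intervals assume the local quadratic (linearised) model around
  the optimum; they are not profile-likelihood intervals.
* The artificial Cad surface satisfies the documented qualitative features
  but is not the published protein profile.
* One spatial dimension, one division cycle; no protein–mRNA delay,
  no 2D/3D tissue geometry.
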