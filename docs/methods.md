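# Methods

`dktime` analyses the diffusion-time dependence of apparent diffusivity D(td)
and apparent kurtosis K(td) measured from diffusion-weighted decay curves, the
way such data are acquired by diffusion-weighted MR spectroscopy of water and
intracellular metabolites in gray matter.  This note documents the models, the
estimation choices, the synthetic-data generator, the Monte-Carlo oracles, and
the numerical decisions, in enough detail to reproduce or audit any number the
package computes.

Units are fixed package-wide: times in ms, lengths in µm, diffusivities in
µm²/ms, b-values in ms/µm²; kurtosis is dimensionless.  No unit inference is
performed.

## Signal representation and the two-stage analysis

Stage one fits the cumulant (kurtosis) representation

    S(b) = S0 · exp(−b·D + K·b²·D²/6)

to each decay curve (one subject, one species, one diffusion time), with S0 a
free scale.  Residuals are on the un-logged signal by default (log-domain
fitting is an option).  The b-range is guarded per species (default b ≤ 2.5
for water, b ≤ 8 otherwise, matching the acquisition grids, which encode the
convergence radius of the cumulant expansion); after each fit a warning is
emitted if the quartic term at b_max exceeds half the linear term.
Uncertainties come from the Jacobian covariance with the residual variance
estimated at n−3 degrees of freedom; because n is small (5–7 b-values),
confidence intervals use Student-t quantiles with n−3 dof — with the normal
1.96 quantile the empirical coverage falls well short of nominal at these
sample sizes, and the t quantile restores it (the coverage test measures
this directly).

Stage two fits time-dependence models to the resulting D(td), K(td) series:

* **Power laws** `X(td) = X_inf + C·td^(−θ)` with the dynamical exponent θ
  either frozen (0.5 for 1D short-range disorder, 1 for 2D random disks / 3D
  random rods, both from θ = (p+d)/2) or shared and free in a joint fit to D
  and K.  Free-θ bounds are [0, 2], bracketing all universality classes of
  interest.  In joint fits, residuals of each curve are scaled by the median
  of its observed values so D and K contribute comparably (how the two curves
  should be weighted against each other is not dictated by theory; the
  median scaling is this package's documented choice).  The tail ratio
  ξ = C_K/(C_D/D_inf) is reported with a delta-method standard error.
* **Logarithmic singularity** `A·ln(td/tc)/td + B` (randomly oriented rods).
  tc is fitted, bounded in (10⁻³, 10³) ms, with multi-start over a fixed tc
  grid; A and tc are nearly collinear on narrow td ranges, so a correlation
  |ρ(A, tc)| > 0.999 raises an identifiability flag.
* **Kärger exchange kurtosis**
  `K(td) = K0·(2·tex/td)·[1 − (tex/td)(1 − e^(−td/tex))] (+ K_inf)`
  fitted to K(td) only, for td ≥ 42.5 ms by default so that D(td) is
  approximately constant (an assumption of the model); multi-start over
  tex ∈ {1, 10, 50, 100, 500} ms.  A fitted tex beyond 20× the longest
  sampled td is flagged unidentifiable (no decay within the window).
* **NEXI/SMEX two-compartment exchange signal**, fitted to S(b, td) directly
  (log-signal residuals, mirroring how multi-shell exchange fits are posed).
  Per stick orientation with cos ψ = c the intraneurite pool has apparent
  diffusivity Di·c² and the extraneurite pool De; exchange rates are
  (1−f)/tex out of and f/tex into the neurite pool, so detailed balance
  holds at fractions (f, 1−f) and the residence-weighted mean exchange time
  is tex.  The per-orientation signal is the summed solution of the 2×2
  Kärger system (closed-form eigen-decomposition, evaluated through
  exp(−t·det/(m+s)) for the slow mode so that b = 0 returns exactly 1 and no
  overflow occurs at extreme rates); the powder average uses Gauss–Legendre
  quadrature on c ∈ [0, 1], order 64 by default (minimum 8).  NEXI and SMEX
  are treated as one model: a zero-radius stick compartment exchanging with
  an isotropic compartment.
* **Restricted-geometry mixture** — 20% spheres (soma) + 80% randomly
  oriented cylinders (projections), fractions imposed; free parameters
  R_sphere ∈ [1, 15] µm, R_cyl ∈ [0.1, 5] µm, D0 ∈ (0, 1.5] µm²/ms.  Whether
  the axial cylinder diffusivity should be a separate free parameter is an
  open question; it defaults to D0 and is exposed as an option.

Functional forms fitted to the same series are ranked by the Gaussian
small-sample corrected AIC, cAIC = n·ln(rss/n) + 2k + 2k(k+1)/(n−k−1) —
the standard Gaussian AICc, compared only within, never across, datasets.
For two-component models (separate D and K fits) the ranking sums the two
components' cAIC.

All fits are bounded trust-region least squares (scipy) started from fixed
multi-start grids, so every estimate is deterministic given the data; bounds,
start grids and seeds are recorded in the FitResult.

## Restricted-diffusion cumulants (eigenmode expansion)

The geometry model needs the second and fourth displacement moments along the
gradient axis for diffusion restricted in a sphere, a disk (cylinder cross
section) or an interval, under the narrow-pulse approximation (δ = 3 ms is
small against all metabolite diffusion times ≥ 42.5 ms; finite-δ corrections
are a non-goal).  With reflecting boundaries and equilibrium (uniform)
initial positions the propagator is expanded in Laplacian eigenmodes; only
modes coupling to x (l = 1 sector), and to x² (l = 0 and l = 2 sectors; m = 0
and m = 2 for the disk; even cosine modes for the interval) enter:

    ⟨Δx²⟩(t) = 2μ₂ − (2/V) Σ e^(−λt) (∫x φ)²
    ⟨Δx⁴⟩(t) = 2μ₄ + (6/V)[Vμ₂² + Σ e^(−λt) (∫x² φ)²] − (8/V) Σ e^(−λt) (∫x φ)(∫x³ φ)

Eigenvalues are Neumann roots of J_m' (disk, scipy) and j_l' (sphere, bracketed
Brent root-finding); coupling integrals use Gauss–Legendre quadrature with at
least 14 nodes per radial mode.  Completeness sums (Σ(∫xφ)²/V → μ₂ etc.) are
verified in tests.  Tables are dimensionless (R = 1, D0 = 1) and cached; the
truncation order is chosen so the smallest neglected term carries
e^(−λτ) < e^(−36) at the requested dimensionless time τ = D0·t/R², with at
least 20 modes and at most 1600 (a ConvergenceError is raised beyond that).
For τ < 10⁻⁶ the mode sum is replaced by the surface expansion
D(t)/D0 = 1 − (4/(3√π))·√τ (the geometric coefficient is 1 for all three
shapes with R the radius or half-width), K = 0; at the switch point the two
branches agree to well below 0.1%.

Long-time checks built into the tests: K → −3/7 (sphere), −1/2 (disk), −0.6
(interval) and D → R²/(5t), R²/(4t), R²/(3t) respectively (the variance of
the difference of two independent uniform positions), all reproduced to the
stated tolerances.

Randomly oriented cylinders combine free axial diffusion (default D_axial =
D0) with the restricted transverse moments:
⟨Δx²⟩(c) = c²·2D_ax·t + (1−c²)·m2⊥ and
⟨Δx⁴⟩(c) = c⁴·3(2D_ax t)² + (1−c²)²·m4⊥ + 6c²(1−c²)·2D_ax t·m2⊥,
averaged over c ∈ [0, 1] by Gauss–Legendre quadrature (order 64) before
cumulants are formed.  At long times this tends to the powder-stick values
D → D_ax/3, K → 2.4, which is why the mixture reproduces the experimental
signature of metabolite kurtosis rising with diffusion time.  Non-exchanging
compartments combine by moment additivity: D = Σ f_i D_i,
K = [Σ f_i D_i² (K_i+3)]/D² − 3.

## Monte-Carlo oracles

Three random-walk simulators validate the analytic models independently.
All use Gaussian steps of SD √(2·D·dt), equilibrium initial conditions, and
report D(t) = ⟨Δx²⟩/2t, K(t) = ⟨Δx⁴⟩/⟨Δx²⟩² − 3 with bootstrap standard
errors over walkers (default 200 resamples).  Random numbers come from an
inline xorshift128+ generator seeded per walker through splitmix64 with
Box–Muller pairs — numba's built-in scalar normal draw is several times
slower and would dominate the run time; the custom stream is bit-reproducible
given the seed.

* **1D permeable membranes** (periodic domain).  Transmission per encounter
  uses the Gaussian-step hybrid rule corrected for re-attempts,
  P = q/(1+q) with q = κ√(π·dt/D0); with the uncorrected rule the realized
  permeability is κ/(1−P), which measurably (5–7%) overshoots the exact
  series-resistance plateau D_∞ = D0/(1 + D0/(κ·ā)); with the correction the
  plateau is reproduced within ~1.5%.  Preconditions: step < ā/4 and
  P < 0.5.  Disordered placement is a renewal process with exponential gaps
  shifted by a minimum gap (10% of the mean) — hard-core Poisson, still
  short-range (p = 0) disorder — and gaps are rescaled so the realized mean
  spacing is exact (every realization then shares the same homogenized D_∞).
* **Two-pool exchange**: Markov pool switching with per-step probabilities
  (1−f1)·dt/tex and f1·dt/tex (requires dt ≤ tex/20); reproduces the Kärger
  kurtosis with K0 = 3·f1·f2·(D1−D2)²/D̄² within Monte-Carlo error on the
  full water diffusion-time grid, and its displacement characteristic
  function E[cos(qΔx)] reproduces the exchange signal model per orientation.
* **Restricted walkers** (interval, disk, sphere) with exact specular
  reflection: the proposed step is traced to the boundary crossing and the
  overshoot mirrored across the tangent plane (radial folding leaves an
  O(step/R) kurtosis bias; the specular scheme's residual bias is second
  order and below the 2% oracle tolerance at step ≤ R/10).

## The 1D tail-ratio experiment

The universal prediction for 1D short-range disorder is that the measured
D(t) and K(t) approach their long-time limits as t^(−1/2), with amplitude
ratio ξ = C_K/(C_D/D_∞) = 2.  The experiment estimates ξ from membrane
walks: mean spacing ā = 1 µm, κ = 0.25 µm/ms, D0 = 1 µm²/ms (so D_∞ = 0.2
and the residence time ā/2κ = 2 ms), dt = 0.02 ms, ten log-spaced times in
[60, 480] ms — the diffusion length then spans ≈ 5–14 mean spacings (inside
the asymptotic tail; at 20–40 ms the kurtosis still carries a ≈ +20%
pre-asymptotic excess) and stays far below the 1500 µm periodic box (in a
50 µm box the kurtosis visibly decays too fast once the diffusion length
reaches a quarter of the box).  Because the universal amplitudes describe
the disorder *ensemble* while a single finite realization retains large
sample fluctuations of the kurtosis amplitude (single-box estimates of ξ
ranged from 0.7 to 2.7), displacement moments are pooled over six
independent substrate realizations (40 000 walkers each by default) before
cumulants are formed.  The θ = 0.5 power laws are then fitted jointly with
free long-time limits, constraining K_∞ ≥ 0 (the kurtosis of a permeable-
membrane medium is non-negative and decays to zero; allowing a negative
offset lets noise inflate the fitted tail amplitude, roughly doubling the
estimator's seed-to-seed spread).  The D-curve fit recovers the exactly
known homogenized D_∞ = 0.2, which served as the built-in control when the
window and ensemble sizes were designed.

## Synthetic cohorts

The generator reproduces the two acquisition designs exactly: water — six
diffusion times {20.8, 30, 42.5, 100, 250, 500} ms × five b-values
{0.2, 0.7, 1.2, 2.0, 2.5} ms/µm², 16 repetitions, four subjects typical;
metabolites — four diffusion times {42.5, 100, 250, 500} ms × seven b-values
{0.2, 1.0, 2.0, 3.2, 4.5, 6.0, 8.0} ms/µm², 2–3 blocks of 32 repetitions
(64, 64, 64, 96), seven subjects typical; δ = 3 ms and Δ = td + δ/3
throughout.  Truth models are any forward model in `dktime.models`
(constant-cumulant, power law, Kärger, NEXI, geometry).  Between-subject
variability is log-normal (matched mean and CV) on positive parameters and
clipped normal on fractions; per-repetition noise (Gaussian, or Rician as
magnitude of a complex Gaussian) is applied to the normalized signal and
averaged over the repetition counts, reproducing the effective SNR structure
of averaged spectra.  Defaults for CVs follow typical reported inter-animal
SEM ranges (a few percent on D and K for water, up to ~30% on metabolite K).

What the generator does *not* emulate: spectral-domain effects (lineshape,
baseline, quantification error correlations across b), T1/T2 relaxation
pools, gradient imperfections, motion, and any within-curve correlated
noise.  Passing recovery tests on these cohorts therefore demonstrates the
correctness and statistical behavior of the estimation pipeline under this
noise geometry, not robustness to spectroscopic artifacts.

## Problem sizes used by the test suite and the acceptance script

Simulation sizes are chosen so each check has a comfortable noise margin at
its stated tolerance: two-pool oracle 10⁵ walkers; restricted-limit oracles
2.5×10⁵ walkers at τ = 3; tail-ratio experiment 6 × 40 000 walkers (script)
and 5 × 30 000 (test); staged-recovery study 50 replicate four-subject
cohorts at SNR 100.  Each check compares against fixed tolerances plus the
simulation's own bootstrap error where the quantity is stochastic.

## Known limitations

* The geometry model is narrow-pulse; at δ = 3 ms and the shortest water
  td = 20.8 ms the approximation is mild but not exact.
* cAIC values assume i.i.d. Gaussian residuals; cumulant estimates entering
  stage two are correlated across td only through subject effects, which the
  per-subject fits ignore.
* The exchange-time estimate from the Kärger K(td) fit is imprecise by
  construction on four-point windows — the fit reports the (large) Jacobian
  uncertainties rather than hiding them, and flags boundary-pinned or
  non-decaying solutions.
* The NEXI fit can be degenerate (f → 0/1, or tex at a bound) on
  insufficiently rich grids; such fits are flagged, not suppressed.
* Oracles validate the model mathematics, not gray-matter tissue: no
  microscopic substrate claim is made beyond the disorder class simulated.
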