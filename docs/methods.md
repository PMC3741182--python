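# Methods

This note documents the models, the free parameters and their defaults, the
numerical choices, and what the synthetic-data generators do and do not
emulate.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Worm-like-chain elasticity

The force–extension relation is the WLC interpolation formula with the
standard seventh-order polynomial correction (coefficients α₂…α₇ in
`ptdna.wlc.WLC_ALPHA`, α₄ = +16.07497).  With this set the bracket is
strictly increasing on [0, 1), zero at z = 0 and divergent at z → 1; these
properties are enforced by tests.  Thermal energy defaults to k_BT at 298 K
(≈ 4.11 pN·nm) — tweezers measurements are at ambient temperature, while
incubations are at 37 °C; the temperature is configurable everywhere.

Fitting choices:

* **Residuals in force, not extension.**  In constant-force-step tweezers
  protocols the extension grid is the controlled variable and the force the
  noisy readout, so least squares on force residuals matches the noise model
  of the data (and of the synthetic generator).
* **Initialisation and bounds.**  L₀ starts at 1.02× the largest observed
  extension, P at 50 nm; bounds P ∈ [1, 500] nm, L₀ ∈ [0.5×, 2×] the largest
  extension.  Parameter vectors that would put any point at z ≥ 1 are
  penalised rather than clipped.
* **Confidence intervals.**  95% half-widths from the linearised covariance
  s²(JᵀJ)⁻¹ with a Student-t critical value on n − k degrees of freedom —
  the same convention as the ±95% CI reporting of tweezers persistence
  lengths.
* **Fixed-contour option.**  `fix_contour_um` profiles P alone, for
  time-course analyses where L₀ is known not to drift.
* **Inversion.**  Bracketed Brent root finding on z ∈ [0, 1); the force
  residual at the root is < 1e−9 pN.

## Exponential kinetics

Extension decays are modelled as a plateau plus one or two decaying
exponentials, L(t) = L∞ + Σ Aᵢ e^(−t/Tᵢ) — the only form consistent with an
exponential approach to a nonzero condensed plateau.  A zero-plateau variant
is exposed.  Numerical choices:

* Decay constants are optimised in log space (positivity by construction)
  with multi-start initialisation; amplitudes/plateau are profiled linearly
  at each start.  Constants are sorted ascending after the fit (T₁ < T₂).
  Warnings flag weak identifiability (T₂/T₁ < 3) and component collapse
  (T₂ ≈ T₁ or a negligible amplitude).
* **Model selection** uses small-sample corrected AIC; if the margin is
  below 2 the simpler model is returned with an ambiguity flag.  With this
  margin the false-double rate on single-exponential data is ~10% at the
  2%-noise study condition, and the ≥ 90% correct-selection property is
  verified over 50 seeded trials.
* **Average rate** ν_a(t) = (L(0) − L(t))/t references L(0) to the fitted
  curve at t = 0 by default, because the first recorded samples sit behind
  ~3 min of injection dead time and are the noisiest; the raw first-sample
  origin and an explicit numeric origin are options.  Both raw (µm/min) and
  normalised (fraction of L(0)/min) outputs are available, since rate
  figures in the field appear in either convention.
* **Instantaneous rate** ν_i = −dL/dt by Savitzky–Golay differentiation on a
  uniform resampling at the median sampling interval (defaults: window 11,
  order 2; endpoints use the filter's polynomial extension).
* **Slope discontinuity**: exhaustive search over interior breakpoints of a
  continuous two-segment (hinge) linear fit; significance by an F test
  (2 extra parameters) at α = 0.05.
* **Two-regime split fit**: candidate breakpoints on a coarse grid over the
  interior 20–80% of the span, refined at half the grid step; the head is
  fitted double-exponential and the tail single-exponential *independently*
  (no continuity constraint — the two regimes are separate reactions and
  are fitted as such).  Selection against a plain double-exponential fit of
  the whole series uses n·log(rss/n) + 2 per parameter; when the plain fit
  wins the result is flagged `regime_change = False`.  The tail fit's
  amplitude is referenced to the breakpoint time, which leaves its time
  constant invariant and keeps the exponentials well conditioned.

## Condensation simulator

The three-adduct mechanism is concretised as a pseudo-first-order network
over four site classes (diadduct-capable, micro-loop-capable,
cross-link-capable, isolated).  Each class binds drug at k_mono·c and
converts at its own closure rate.  The site classes are the load-bearing
design choice: a single shared monoadduct pool with branching conversions
makes diadduct and loop counts exactly proportional at all times, which
cannot produce the two well-separated decay constants the data show.  With
parallel classes the diadduct channel runs on the (k_mono·c, k_di) clock and
the loop channel on its own slow clock.

Mapping to mechanics:

* 1/P(t) = 1/P₀ + β·N_di(t)/L₀ — a flexibility-mixing law; β is
  dimensionless and exactly degenerate with the diadduct-site count, so it
  is fixed at 1 and the site count carries the calibration.
* L₀_eff(t) = L₀ − N_loop·(150 bp · 0.34 nm/bp) − N_cross·s_x, floored at 1%
  of L₀.  The cross-link sequestration length s_x is a free parameter of the
  model (nothing in the data pins it); default 500 nm, configurable.
* Extension(t) = WLC extension at the holding force with (P(t), L₀_eff(t)).
* Monoadducts change nothing: they induce no intrinsic bend.
* Cross-links are gated: c ≥ 400 µM **and** P(t) ≤ 25 nm.  The concentration
  threshold is implemented as sharp (a modelling choice; the data cannot
  distinguish a sharp gate from a crossover), and the persistence gate makes
  the later SS onset *emergent*: SS softens more slowly, so it crosses the
  gate later.  The onset time is located by ODE event detection and reported
  on the trace.

Integration: LSODA with rtol 1e−10 / atol 1e−8 on counts, fixed output grid;
the stochastic counterpart is an exact Gillespie direct-method simulation on
integer site counts, reproducible by seed, and its 200-run mean is verified
against the ODE within three standard errors.

**Calibration.**  `calibrate_rates` assigns the loop closure rates directly
from the slow decay constants (k_loop = 1/T₂: 1/473.27 min⁻¹ for RR,
1/1130.61 for SS) and least-squares fits the remaining constants — shared
k_mono, per-enantiomer k_di and diadduct-site counts, and the total
reactive-site density — to the persistence lengths at 60 and 180 min for
both enantiomers (17.4/13.6 nm RR, 19.0/15.9 nm SS from P₀ 45.2/45.3 nm)
and the ~125 bound Pt per 2-kb molecule at 1 h.  Sites scale with contour
length, so one density (calibrated ≈ 66 sites/kb, far below the purine
count — most purines never react) serves both the λ-DNA tweezers geometry
and the 2-kb AFM/ICP-MS geometry.  The diadduct ordering k_di(RR) > k_di(SS)
is imposed as a bound on the rate ratio: it is the mechanistic contrast the
model exists to express, and without the constraint the two SS persistence
points alone would pull k_di(SS) above k_di(RR).  The shipped constants
(`CALIBRATED_RATES`) achieve all five least-squares targets within 5%
(relative residuals are recomputed by the test suite).  Cross-link
parameters (k_cross = 0.01 min⁻¹; cross-link site fractions 0.24%/0.42% for
RR/SS) are not least-squares targets — they set the high-concentration
qualitative regime (SS onset after RR; final condensation degree SS > RR),
which is verified as a property.

Known limitations: with a shared k_mono the bound-Pt curves of the two
enantiomers coincide at all times, so the late-time (12–24 h) RR/SS census
divergence is outside the model; and the early-time micro-loop count ratio
(SS ≈ 2× RR at 60 min) cannot be reproduced jointly with the printed slow
decay constants under any parallel first-order network with physically
bounded loop-site counts — the calibration targets the decay constants and
persistence/census values, and the loop contrast is expressed in the
final counts (SS > RR) instead.

## AFM statistics

* **Stretching distance**: exact point-set diameter via convex hull.
* **Bend detection**: deflection between the chord directions of two
  flanking arms (default 10 nm of contour each), local maxima above
  max(20°, 4 robust σ of the trace's own deflection profile), non-maximum
  suppression within one arm, detector range [20°, 160°].  The adaptive
  floor encodes a physical limit: on a flexible chain (P = 50 nm) the
  thermal deflection over two 10-nm arms is ~25° r.m.s., so bends below
  several tens of degrees are not identifiable there — the quantitative
  bend studies therefore use stiff synthetic backbones, and a ~30° bend is
  shown recoverable on a quiet backbone but not on a flexible one.
* **Micro-loops**: k-d-tree search for non-adjacent vertex pairs within
  3 nm whose contour separation is 50–400 bp at 0.34 nm/bp; overlapping
  pairs merge, and the size estimate is the contour separation of the
  closest pair.  This proximity surrogate replaces the visual
  protuberance-height identification used on real images and is validated
  only against annotated synthetic traces.
* **Condensate volume**: pixels above a 0.3 nm threshold (half the ~0.6 nm
  micro-loop protuberance height) × pixel area × mean height of those
  pixels; "mean" is chosen over "max" for robustness to tip noise, with max
  exposed as an option.  The estimator is exact on plateaus and within 5%
  on hemispheres at pixel ≤ r/20.

## Synthetic data

Generators are pure functions of (parameters, seed).  The 2-D chain uses
independent Gaussian heading increments of variance segment/persistence, so
the tangent correlation decays as e^(−s/2P); this *defines* the trace's
persistence length operationally, and persistence-recovery tests are
internal to the convention (no claim about 3-D→2-D adsorption equilibration
is made).  Loops are inserted as regular polygons with side equal to the
segment length (exact closure, contour conserved); bends rotate the
downstream arm.  Populations derive per-object seeds from a master seed by
a counter scheme (master · 1 000 003 + counter, mod 2³¹) recorded in the
manifest, so regeneration is byte-identical.  Not emulated: tip
convolution, scanner drift, surface-interaction artifacts, excluded volume.

Because kinetic trace amplitudes are not published, the generators use
WLC-consistent values: initial extension 13.7 µm (λ-DNA at the 0.8 pN
holding force), plateaus/amplitudes per condition of (6.0; 3.0, 4.7) µm at
60 µM RR, (4.0; 3.2, 6.5) at 60 µM SS, (5.0; 8.7) at 600 µM RR, and a
two-regime SS trace breaking at 120 min; noise is 2% of the initial
extension, sampling 1 min over 400–600 min records.  Passing recovery tests
on these traces shows the estimators work at the published time constants
and realistic signal-to-noise; it does not certify behaviour under drift,
bead loss or other instrument pathologies absent from the generator.

## Problem sizes

Recovery studies use 30 seeds per condition; SSA/ODE agreement uses 200
stochastic runs on the 2-kb geometry; volume estimation uses 150 maps per
group at 2 nm pixels; loop sizing uses 100 traces; bend/loop detector
scoring uses 50–60 annotated traces.  These sizes match the ~150-molecule
samples of the underlying experiments where applicable and keep the full
suite and the acceptance script in the tens of seconds on one CPU.
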