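# ptdna

Single-molecule analysis of DNA condensation induced by the platinum-DACH
enantiomers — oxaliplatin, Pt(R,R-DACH) ("RR"), and its mirror image
Pt(S,S-DACH) ("SS").  The package is written for biophysicists working with
magnetic-tweezers and AFM data on drug–DNA interactions: it bundles the
elasticity fitting, kinetic decomposition, trace statistics and a mechanistic
simulator needed to go from raw extension traces and molecule images to the
rate constants and adduct censuses that distinguish the two enantiomers.
Because no instrument data are consumed directly, every input format has a
seeded synthetic generator, making all analyses reproducible end-to-end.

## The models at the core

**Worm-like chain.**  A tethered DNA at relative extension *z = L/L₀* resists
with force

&nbsp;&nbsp;&nbsp;&nbsp;*F(z) = (k_B T / P) · [ 1/(4(1−z)²) − 1/4 + z + Σᵢ₌₂⁷ αᵢ zⁱ ]*

where *P* is the persistence length, *L₀* the contour length and the αᵢ the
standard seventh-order correction coefficients.  `ptdna.fit_wlc` estimates
*(P, L₀)* by nonlinear least squares on the force residuals with 95%
confidence intervals; `wlc_extension_at_force` inverts the model.

**Condensation kinetics.**  At fixed force the extension decays as
*L(t) = L∞ + Σᵢ Aᵢ e^(−t/Tᵢ)* with one component per concurrent
pseudo-first-order reaction: fast diadduct formation (T₁), slow micro-loop
formation (T₂), and — above ~400 µM — late long-range cross-linking, which
shows up as a second regime handled by `split_exponential_fit` and as a slope
discontinuity in the instantaneous rate ν_i = −dL/dt.

**Mechanistic simulator.**  `ptdna.condensation` integrates the three-adduct
reaction network (monoadducts → diadducts / micro-loops / gated cross-links)
deterministically or stochastically, maps the adduct census to mechanics
(diadducts soften the chain, loops and cross-links sequester contour) and
reads the extension off the WLC model.  Shipped rate constants are calibrated
against the measured persistence-length time course, decay constants and
bound-platinum census.

**AFM statistics.**  Stretching distance (molecule diameter), sharp-bend
detection with an adaptive thermal-noise floor, proximity-based micro-loop
counting and sizing, condensate volume (thresholded area × mean height), and
group summaries with t-based confidence intervals.

## Worked example

```python
import ptdna

truth = ptdna.WLCParameters(persistence_length_nm=44.0, contour_length_um=16.5)
curve = ptdna.gen_force_extension(
    truth, n_points=40, force_range_pN=(0.05, 6.0),
    noise=ptdna.NoiseModel("multiplicative-gaussian", 0.05), seed=1)
fit = ptdna.fit_wlc(curve)
print(fit.params.persistence_length_nm, fit.ci95_persistence_nm)
```

Running `python examples/fit_wlc_curve.py` (the same computation) prints

```
persistence length P  =  42.95 +/- 3.08 nm   (generator: 44.0)
contour length     L0 = 16.518 +/- 0.048 um   (generator: 16.5)
rss = 0.3654 pN^2 over 40 points; converged = True
```

i.e. with 5% force noise the fitted stiffness lands within its confidence
interval of the generating value.  The other scripts in `examples/` walk
through one capability each: kinetic decomposition
(`decompose_condensation_kinetics.py`), the high-concentration two-regime fit
(`two_regime_split.py`), the calibrated simulator
(`simulate_condensation.py`: P(60 min) ≈ 17 nm for RR at 60 µM, ~125 bound Pt
per 2-kb DNA at 1 h, SS cross-link onset lagging RR, final condensation
degree SS > RR) and the AFM statistics (`afm_statistics.py`: ~150 bp loop
sizes, RR/SS condensate volume ratio ≈ 1.3).

A thin CLI mirrors the library for shell use:
`ptdna fit-wlc curve.tsv`, `ptdna fit-kinetics series.tsv --model auto`,
`ptdna simulate config.yaml --out-prefix run`, `ptdna calibrate`,
`ptdna afm-stats trace.csv --maps map.csv`, `ptdna synth recipe.yaml outdir`.

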