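# Methods

This note records the models implemented in `c3iso`, the conventions
chosen where the underlying procedures are under-specified, and what the
synthetic-data tests do and do not demonstrate.

## Fractionation models

Four forward models map an atmospheric state (pCO₂ in ppmv, δ¹³C_CO₂ in
‰ VPDB) to C₃ plant tissue δ¹³Cₚ.

The Farquhar family uses the linear-in-δ expression
δ¹³Cₚ = δ¹³C_CO₂ − a − (b − a)·(cᵢ/cₐ) with a = 4.4‰ (diffusion of CO₂
through stomata, set by the reduced masses of the isotopologues) and
b = 28.2‰ (net carboxylation discrimination, tuned so the gymnosperm
linear-setpoint model reproduces the modern global plant mean). The three
members differ only in the leaf gas-exchange setpoint:

| model | cᵢ/cₐ | k (scoring) |
|---|---|---|
| Farquhar-1982 | 0.6, constant | 3 |
| Voelker-2016g | 0.00038·cₐ + 0.502 | 4 |
| Voelker-2016a | 0.00031·cₐ + 0.649 | 4 |
| SJ-2012 | (hyperbolic Δ¹³C) | 3 |

The same `b` is used for the angiosperm model as for the gymnosperm one;
the resulting level offset of the angiosperm curve from cellulose
records (~1.4‰) is a property of that constant choice and is accepted
rather than re-tuned.

SJ-2012 is Δ¹³C = A·B·(pCO₂+C)/(A + B·(pCO₂+C)) with A = 28.26‰ (the
high-pCO₂ asymptote), B = 0.22‰/ppmv, C = 23.9 ppmv, converted to δ¹³Cₚ
through the *exact* inversion of
Δ¹³C = (δ¹³C_CO₂ − δ¹³Cₚ)/(1 + δ¹³Cₚ/1000). One consequence of mixing
the linear-in-δ family with the exact inversion: a source-composition
shift s moves the Farquhar-family prediction by exactly s but the SJ-2012
prediction by s/(1 + Δ/1000) (~2% less); the property tests assert the
actual algebra.

Linear setpoints are clamped to (0, 1) with a warning; the calibrations
are never meant to be evaluated where the clamp binds, but extreme
synthetic inputs should not produce unphysical ratios. Photorespiration,
dark respiration and mesophyll-conductance terms are deliberately out of
scope. The modern anchor uses δ¹³C_CO₂ = −8.4‰, the value algebraically
required for the constant-setpoint model to return −27.1‰; it is a named
constant and overridable.

## Monte Carlo average (MCA) splines

Ice-core series are irregular in age with per-sample 1σ errors. Each of
`n_rep` (default 1000) replicates perturbs every sample value by a
Gaussian draw with its own σ (a uniform ±σ option exists; the choice is
recorded in curve metadata), then fits a cubic smoothing spline; the
curve mean and 1σ are per-grid-point statistics over replicates.
Perturbation applies to values only, not ages.

**Cutoff-period convention.** The smoothing strength is expressed as a
cutoff period T_c (0.375 kyr by default). A cubic smoothing spline
minimising Σ(yᵢ−f(xᵢ))² + λ∫f″² acts, in the continuum limit for
sampling density ρ (points per kyr), as a low-pass filter with amplitude
response 1/(1 + (λ/ρ)ω⁴); λ = ρ·(T_c/2π)⁴ puts the 50% response at
ω = 2π/T_c. Empirically (fitting sinusoids through irregular samples)
this attenuates period-T_c signal to ≲0.5 and passes ≥0.95 of signal at
4·T_c. λ can be overridden directly. Note what a cutoff cannot do:
white measurement noise has power at *all* periods, and its
long-period components pass any such filter, so fitted curves carry
residual wiggles of roughly the per-sample σ scale divided by the square
root of the points per resolved period.

Outlier-flagged samples are dropped before fitting; exactly duplicated
ages (multi-core compilations) are averaged within each replicate.
Curves are evaluated on a regular grid (0.1 kyr default) strictly inside
the data span — no extrapolation. Grids requested outside the span, or
fewer than 4 usable samples, are errors.

**Anthropogenic merge.** Modern, densely sampled segments are fitted
with an interpolating cubic spline (no cutoff — the anthropogenic rise
is real signal at short periods) and joined to the pre-industrial curve:
the modern segment wins from its oldest sample toward the present, with
a linear cross-fade over one grid step; a gap larger than one grid step
is an error.

**Propagation and expansion.** Model δ¹³Cₚ curves take their mean from
the model applied to the curve means, and their σ from Monte Carlo draws
of both input curves (independent per point). Draws are moment-matched
(standardised per grid point), a variance-reduction device that makes
linear propagation exact — e.g. the constant-setpoint model's output σ
equals the δ¹³C_CO₂ curve σ identically — while remaining unbiased for
the nonlinear models. The "expanded" band adds, in quadrature, the 1.62‰
1σ spread of the modern global plant data set: it represents the
plausible range of real plants around a model curve, not analytic error.

**Episode detection.** The local rate is a centred finite difference of
the curve mean; maximal contiguous runs with |rate| ≥ 0.25‰/kyr whose
total change reaches 1‰ are reported oldest-first, optionally excluding
the anthropogenic era. On noisy fitted curves, grid-step (0.1 kyr)
differences are noise-dominated (see above), so the difference span is
configurable (`rate_baseline_kyr`; the analysis uses 2 kyr). Even so,
the deglacial ramp's peak rate (~0.45‰/kyr under SJ-2012, with long
stretches near 0.3) sits close to the 0.25 threshold, so detection on a
noisy realisation is seed-dependent; on the noise-free truth curve it is
deterministic. The constructed-ramp tests pin down the detector's
exactness separately from this data limitation.

## Geographic adjustment

Records are shifted to MAP = 1000 mm/yr, altitude = 840 m, latitude =
50°N by adding δ′ = δ_MAP + δ_alt + δ_lat with
δ_MAP = 5.6·(log₁₀(MAP+300) − log₁₀(1300)), δ_alt = 0.00019·(840−alt),
δ_lat = 0.0124·(|lat|−50). The adjustment is exactly invertible; all
terms vanish jointly at the reference. MAP = 0 is legal (the +300 offset
keeps the logarithm finite). Site altitude and modern MAP may be given
directly or looked up nearest-cell in `xarray` lat/lon rasters —
nearest-cell rather than interpolated, because no interpolation rule is
canonical and nearest-cell is reproducible across resolutions.

## Record curation and tissue offsets

Filters: C₃ dominance (site C₃ fraction ≥ 0.9), lichen-feeder exclusion
(lichen carries a non-vascular isotopic signal), industrial-era
exclusion (age < 0.2 kyr BP, i.e. after ~1750 CE — configurable; the
anthropogenic transient would dominate window means). Filters are
idempotent and order-independent; removals are logged.

Tissue conversions toward bulk-leaf (diet) values subtract 5.1‰ from
herbivore collagen (controlled-feeding enrichment ε*) and 1.0‰ from
α-cellulose. The cellulose sign is fixed by consistency: Holocene
collagen − 5.1 and cellulose − 1.0 must agree if fauna ate the leaves,
which also gives the generator's testable collagen-minus-cellulose
cohort difference of 4.1‰.

Window statistics are unweighted means over half-open age windows
(post: 0.2–10 kyr BP; pre: ≥20 kyr BP); no age- or error-weighting is
applied because none is specified for the reference procedure.

## MAP correction and its sign

Δ(δ¹³C_MAP) = −5.6·[log₁₀(MAP_midH+300) − log₁₀(MAP_LGM+300)] is the
MAP contribution to the *Holocene-minus-glacial* difference: negative
when the Holocene is wetter (wetter → more ¹³C-depleted plants), and
antisymmetric under swapping epochs. Ensemble statistics are the mean
and 1σ across GCMs (never a single model). Cohort aggregation weights
each record equally by default, so well-sampled sites count more;
site-equal weighting is a flag. Duplicated (model, site) table rows are
collapsed first, so weighting follows records, never rows. GCM
precipitation flux (kg m⁻² s⁻¹) converts to mm/yr via the Julian-year
constant 31 557 600 s.

## Decomposition and the group test

Δ(δ̄¹³C_adj) ≈ Δ(δ̄¹³C_pCO₂) + Δ(δ̄¹³C_MAP) + Δ(δ̄¹³C_CO₂). The source
term is ≈0.05‰ over this contrast and dropped by default (a flag retains
it, or measures it from a supplied δ¹³C_CO₂ sample table). σ for the
adjusted shift is the standard error of the difference of window means;
the residual's σ combines the inputs in quadrature. The per-100-ppmv
rescaling uses the ~80.5 ppmv deglacial rise (or a rise measured from
the fitted pCO₂ curve). Group separation uses a one-sided Welch
two-sample t-test (alternative: post-glacial more negative); there is no
natural pairing between two different-age cohorts, so no paired variant
is offered.

## Model comparison

Residuals are record minus model curve (linear interpolation at record
ages; out-of-span records skipped with a log entry). RMSE = √(Σr²/n);
AIC = 2k − 2lnL; BIC = ln(n)k − 2lnL with L the zero-mean Gaussian
likelihood at its MLE variance σ̂² = Σr²/n (a fixed-σ option exists).
k counts calibrated constants (table above); it is a convention,
configurable, and always reported with the scores.

A structural caveat the synthetic experiments expose: if records carry a
MAP *time*-trend (drier glacial), residual scoring against curves that
do not model MAP is biased toward the more pCO₂-sensitive candidate —
the trend mimics extra pCO₂ response. The model-selection sanity test
therefore runs on scenarios without a MAP trend; on trend-bearing
scenarios, selection between models of similar sensitivity reflects the
trend as much as the leaf physiology. The same caveat applies to scoring
real records.

## Synthetic scenarios

Defaults mirror the study design: pCO₂ rising 190 → 270 ppmv through a
logistic ramp centred at 14 kyr BP (width 1.2 kyr, so ~80% of the change
spans ~5 kyr); δ¹³C_CO₂ fluctuating ±0.15‰ about −6.5‰ (period 8 kyr,
echoing the ≤0.3‰ observed variability, and giving a small ~0.05‰
window-mean difference); per-sample errors of 1.5 ppmv and 0.08‰ at
~300/220 irregular samples over 0–40 kyr; 521 collagen + 720 cellulose
records (the real compilation sizes) at 40 mid/high-northern-latitude
sites with smooth analytic altitude/MAP fields; record noise 1.0‰
(residual scatter beyond geography, comparable to adjusted real
compilations); a drier LGM (MAP × 0.75); and a 7-member pseudo-GCM
ensemble with a model-level log-bias of 0.25 plus per-site jitter of
0.15, chosen so the inter-model 1σ of cohort effects lands at a few
tenths of ‰, the magnitude real palaeoclimate ensembles show. The
model-level bias component matters: purely site-independent noise would
shrink the cohort-level ensemble spread by √(n_sites) and misrepresent
how GCM uncertainty behaves.

Records are built as: true model on the true atmosphere at the record
age, moved out of the reference environment by the inverse Kohn terms,
shifted by the site's palaeo-MAP deviation (epoch multiplier,
interpolated 10–20 kyr), converted to the archive (+5.1 / +1.0‰), plus
noise; a 5% lichen-feeder and 3% low-C₃ contamination exercise the
filters. All randomness flows from one seed through named sub-streams
(`stream_rng`), so stages are independently reproducible.

What the generator does *not* emulate: age-model and radiocarbon
calibration uncertainty (ages are exact), geographic sampling bias that
changes through time (sites are drawn identically for both windows — so
the geographic adjustment changes the synthetic deglacial shift only
slightly, whereas on real compilations, whose site distribution shifts
between glacial and Holocene, it matters much more), taxon-specific
physiology within a scenario (one true model generates all records), firn
diffusion, and canopy effects. Passing recovery tests therefore
demonstrate the estimator chain is unbiased and calibrated under these
idealisations, not that real compilations are free of the omitted
confounders.

## Problem sizes and numerics

Default test problem sizes: 1000-replicate splines on ~300-point series;
50 seeded scenarios for parameter recovery (observed |bias| well under
0.1‰ per 100 ppmv with ~100% 1σ coverage of the injected effect); 20
scenarios for model selection. Ties and degenerate cases: zero residual
variance is a degeneracy (raised), a single replicate yields σ ≡ 0,
identical groups give t = 0 and p = 0.5, and clamped setpoints warn.
Pseudo-pCO₂ draws in propagation are floored at a tiny positive value to
respect the models' domain.
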