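# c3iso

Quantifying the effect of atmospheric CO₂ on the stable carbon isotope
composition of C₃ plants — and of the fauna that ate them — over the last
deglaciation.

## The problem

The ¹³C/¹²C ratio of C₃ plant tissue (δ¹³Cₚ, ‰ VPDB) is widely used to
reconstruct past environments: mean annual precipitation (MAP), forest
cover, and the C₃/C₄ balance of ancient diets. Those reconstructions
usually assume the atmospheric baseline was constant. But between the
Last Glacial Maximum and the Holocene, pCO₂ rose by ~80 ppmv while the
isotopic composition of atmospheric CO₂ (δ¹³C_CO₂) barely moved — and
several models of leaf gas exchange predict that such a rise alone
depletes plant ¹³C by as much as 2‰. This package implements the full
chain needed to test that prediction against fossil archives:

1. **Fractionation models** (`fractionation_models`). The classical
   diffusion/carboxylation expression

   δ¹³Cₚ = δ¹³C_CO₂ − a − (b − a)·(cᵢ/cₐ),  a = 4.4‰, b = 28.2‰,

   with three leaf gas-exchange strategies — constant cᵢ/cₐ = 0.6
   (*Farquhar-1982*), and cᵢ/cₐ linear in cₐ for gymnosperms
   (0.00038·cₐ + 0.502, *Voelker-2016g*) and woody angiosperms
   (0.00031·cₐ + 0.649, *Voelker-2016a*) — plus the hyperbolic
   discrimination model (*SJ-2012*)

   Δ¹³C = A·B·(pCO₂ + C) / (A + B·(pCO₂ + C)),  A = 28.26, B = 0.22, C = 23.9,

   converted to δ¹³Cₚ through the exact definition
   Δ¹³C = (δ¹³C_CO₂ − δ¹³Cₚ)/(1 + δ¹³Cₚ/1000).
2. **Ice-core curves** (`icecore_curves`). Monte Carlo average smoothing
   splines (1000 error-perturbed replicate fits, 375-yr cutoff period)
   turn irregular ice-core samples into continuous pCO₂ and δ¹³C_CO₂
   curves with 1σ bands; model δ¹³Cₚ curves with propagated and expanded
   uncertainty; detection of rapid high-amplitude episodes (>1‰ at
   >0.25‰/kyr).
3. **Geographic adjustment** (`geo_adjustment`). Every fossil δ¹³C is
   shifted to a reference environment (MAP 1000 mm/yr, 840 m, 50°N)
   using the Kohn regression terms in MAP, altitude and latitude.
4. **Record curation** (`proxy_records`). C₃-dominance and
   lichen-feeder filters, industrial-era exclusion, and tissue offsets:
   collagen − 5.1‰ (diet enrichment), cellulose − 1‰ (bulk leaf).
5. **MAP correction** (`map_correction`). A 7-member GCM ensemble of
   LGM and mid-Holocene MAP becomes the isotopic contribution of
   precipitation change, Δ(δ¹³C_MAP) = −5.6·[log₁₀(MAP_midH + 300) −
   log₁₀(MAP_LGM + 300)], with inter-model 1σ.
6. **Decomposition** (`decomposition_stats`): Δ(δ̄¹³C_adj) ≈
   Δ(δ̄¹³C_pCO₂) + Δ(δ̄¹³C_MAP) + Δ(δ̄¹³C_CO₂); the pCO₂ effect is the
   residual, rescaled to ‰ per 100 ppmv.
7. **Model comparison** (`model_comparison`): RMSE, AIC and BIC of each
   model curve against the adjusted records.
8. **Synthetic data** (`synthetic_data`): every input above, generated
   with known ground truth, so the whole pipeline is testable end to end
   (parameter recovery, model-selection sanity) without downloads.

Real data in the documented CSV schemas (see each module's docstring)
can be substituted for the synthetic inputs at any stage.

## Worked example

The analysis is a chain of numbered scripts; each reads the previous
stage's outputs from `results/` and prints what it found:

```sh
python analysis/01_simulate_inputs.py   --seed 1
python analysis/02_atmosphere_curves.py --seed 1
python analysis/03_adjust_records.py
python analysis/04_map_correction.py
python analysis/05_decompose.py
python analysis/06_compare_models.py
```

With seed 1 this prints, among other lines:

```
  injected truth [sj2012]: pCO2 effect -1.915 permil (-2.41 per 100 ppmv),
      MAP contribution -0.515 permil, source-isotope term +0.047 permil
  SJ-2012        deglacial change -1.94 permil, median propagated 1-sigma 0.082 permil
rapid episode on SJ-2012: 16.2-13.4 kyr BP, 1.17 permil at 0.42 permil/kyr
adjusted shift -2.35 +/- 0.07 permil (one-sided Welch t = -35.7, p = 6.3e-179)
  - MAP contribution -0.31 +/- 0.48, source-isotope term +0.04
  = residual pCO2 effect -2.07 +/- 0.49 permil, i.e. -2.60 +/- 0.61 permil per 100 ppmv
injected truth: -1.91 permil (-2.41 per 100 ppmv) -> recovered within 0.3 sigma
all records (n=1159): best by BIC is SJ-2012 (RMSE 1.09, AIC 3495, BIC 3510)
```

Reading: the synthetic world was generated with the hyperbolic (SJ-2012)
model, so an ~80 ppmv pCO₂ rise injects a −1.9‰ plant-tissue depletion
on top of a −0.5‰ contribution from Holocene wetting. The pipeline
measures a −2.35‰ adjusted shift between the >20 kyr and <10 kyr
cohorts, attributes −0.31 ± 0.48‰ of it to MAP via the GCM ensemble, and
returns a residual pCO₂ effect of −2.07 ± 0.49‰ (−2.60 per 100 ppmv),
consistent with the injected truth; model scoring then correctly picks
the generating model.

## Layout

```
src/c3iso/      library (all computation lives here)
analysis/       numbered narrative drivers writing to results/
tests/          pytest suite (unit, property and end-to-end checks)
scripts/        acceptance.py
docs/methods.md model description, conventions, design choices, limits
```
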