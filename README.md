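# mepflux

Carbon-flux estimation for the plastidic MEP isoprenoid pathway from dynamic
¹³CO₂-labeling of isoprene, plus metabolic control analysis of the pathway's
first enzyme, DXS.

## The problem

In isoprene-emitting trees such as grey poplar, most of the carbon flowing
through the methylerythritol 4-phosphate (MEP) pathway leaves the leaf as
isoprene, produced from DMADP in a single enzymatic step. When the CO₂ feeding
a photosynthesizing leaf is switched to ¹³CO₂, newly fixed labeled carbon
washes through the pathway intermediates and the ¹³C content of emitted
isoprene — measured in real time by proton transfer reaction mass spectrometry
(PTR-MS) — rises toward a plateau. The speed of that rise, together with the
sizes of the intermediate pools, determines the absolute pathway flux.

`mepflux` implements that analysis as a tested pipeline for:

* **Flux estimation.** The pathway between fixed carbon and isoprene is
  modelled as a first-order cascade of the three measurable pools — DXP
  (size *A*), MEcDP (*B*) and IDP+DMADP (*C*), pmol mg⁻¹ DW. The fractional
  labeling of the terminal pool is the closed form

  $$f(t) = m\left[1 - \tfrac{A^2}{(A-B)(A-C)}e^{-Jt/A}
                 - \tfrac{B^2}{(B-A)(B-C)}e^{-Jt/B}
                 - \tfrac{C^2}{(C-A)(C-B)}e^{-Jt/C}\right]$$

  where *J* is the pathway flux (pmol min⁻¹ mg⁻¹ DW) and *m* the maximal
  fractional labeling. Pools are measured independently by LC-MS/MS and held
  fixed; *J* and *m* are fitted to the observed labeling curve by
  Levenberg–Marquardt least squares.

* **Control analysis.** The flux control coefficient of DXS,
  $C^J_v = \mathrm{d}\log J / \mathrm{d}\log v$, is the OLS slope of log flux
  on log DXS activity across genotypes (empty vector, RNAi-silenced,
  overexpressor), per light × temperature condition, with a t-based 95% CI
  that flags estimates indistinguishable from zero.

* **Signal processing.** PTR-MS isotopologue channels (m/z 69–74) are
  normalized to the hydronium primary-ion signal and drift pressure,
  background-subtracted, and converted to atom-weighted fractional labeling;
  LC-MS/MS channel areas are quantified against external standard curves with
  internal-standard matrix correction and natural-¹³C-abundance deconvolution,
  and plastidial pool shares are estimated from final-label ratios.

* **Synthetic studies.** A deterministic generator emulates the full
  3-genotype × 4-condition design (replicate counts, pool sizes, plateaus and
  fluxes anchored to the reference study cells), with a plantable flux control
  coefficient and configurable instrument noise — so the entire chain is
  testable without instrument data.

## Worked example

```python
import numpy as np
from mepflux import PoolSizes, LabelCurve, label_fraction, fit_flux

# empty-vector control, 1000 PPFD / 30 degC: measured plastidial pools
pools = PoolSizes(A=41.65, B=85.59, C=38.09)   # DXP, MEcDP, IDP+DMADP

# predicted labeling 20 min after the switch to a 13CO2 atmosphere
print(label_fraction(20.0, pools, J=28.65, m=0.912))   # 0.9080

# fit flux back from a labeling curve (here model-generated)
t = np.arange(0.0, 50.5, 0.5)
curve = LabelCurve(t, label_fraction(t, pools, J=28.65, m=0.912))
fit = fit_flux(curve, pools, init_J=1.0, init_m=0.5)
print(round(fit.J, 2), round(fit.m, 3))               # 28.65 0.912
```

The predicted 20-min labeling of 0.908 sits inside the 85–95% plateau range
observed for isoprene, and the fit recovers the generating flux of
28.65 pmol min⁻¹ mg⁻¹ DW exactly on a clean curve.

A full synthetic study, from raw tables to per-condition control
coefficients:

```
mepflux all --seed 2 --out results/
```

which prints (with the default planted FCC of 0.18):

```
161 fluxes fitted, 2 samples excluded; tables in results/
   condition      fcc       se   ci_low  ci_high  n       r2  zero_flag
1000PPFD-21C 0.223015 0.031347 0.159377 0.286653 37 0.591191          0
1000PPFD-30C 0.162736 0.038538 0.084847 0.240624 42 0.308332          0
 250PPFD-21C 0.191198 0.039353 0.111308 0.271089 37 0.402790          0
 250PPFD-30C 0.179163 0.032904 0.112805 0.245520 45 0.408106          0
```

Every 95% CI covers the planted coefficient; a sample whose internal-standard
spike could not be isolated from the noise is excluded with a logged reason.
Other subcommands (`simulate`, `ptrms`, `pools`, `fit`, `fcc`) expose the
individual stages; `mepflux <cmd> --help` documents the file schemas.

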