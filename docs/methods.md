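# Methods

## The label-incorporation model

The MEP pathway between carboxylation and isoprene release is treated as a
linear chain of three well-mixed pools at metabolic steady state: DXP
(size *A*), MEcDP (*B*) and IDP+DMADP (*C*), each in pmol mg⁻¹ dry weight,
traversed by a constant flux *J* (pmol min⁻¹ mg⁻¹ DW). After the switch to a
¹³CO₂ atmosphere at *t* = 0, the fractional labeling of each pool obeys

    da/dt = (J/A)(m − a),  db/dt = (J/B)(a − b),  dc/dt = (J/C)(b − c)

with a = b = c = 0 initially. *m* ∈ (0, 1] is the maximal fractional
labeling — below 1 because the Calvin-cycle substrate pool itself never
labels completely. Integrating the chain gives the closed form implemented
in `flux_model.label_fraction`:

    f(t) = m [1 − A²/((A−B)(A−C)) e^(−Jt/A)
                − B²/((B−A)(B−C)) e^(−Jt/B)
                − C²/((C−A)(C−B)) e^(−Jt/C)]

whose three coefficients sum to one (so f(0) = 0) and whose t → ∞ limit
is *m*. Isoprene's labeling is taken as an instantaneous readout of the
IDP+DMADP pool's labeling, justified because isoprene is made from DMADP in
one step and escapes the leaf as a gas.

Assumptions worth stating explicitly:

* the intermediate pools between the three measured ones (MEP, ME-CDP,
  MEP-CDP, HMBDP) are small enough not to delay label transit and are not
  modelled;
* pools and flux are constant over the 50-min labeling window (metabolic
  steady state);
* isotope effects on enzyme kinetics are ignored.

### Degenerate pool sizes

The closed form loses meaning when two pool sizes coincide (repeated
eigenvalues). Rather than special-casing the algebraic limit, evaluation
falls back to direct numerical integration of the cascade
(`scipy.integrate.solve_ivp`, LSODA, rtol 1e−10/atol 1e−12) whenever two
pools agree within a relative tolerance of 1e−6. Robustness was preferred
over a limit formula because real pool measurements essentially never tie
exactly, while near-ties make the closed form numerically treacherous. The
same integrator doubles as an independent oracle for the algebra in the test
suite (agreement ≤1e−6 absolute over the fitting grid).

### Fitting

`fit_flux` estimates *J* and *m* by Levenberg–Marquardt least squares
(lmfit), with pools entered as fixed parameters — only two parameters are
free, so a curve needs at least three points, in practice a resolved
transient. Bounds are J > 0 and 0 < m ≤ 1. Default initial guesses are
m₀ = max observed f and J₀ = C / t_half, where t_half is the time at which
the curve first exceeds half its final value — a time-constant heuristic
that converges from cold for every reference parameter set. Curves that are
all zero, or that contain no point below 90% of their maximum (no resolved
transient), return `converged=False` with a diagnostic message instead of
raising; when the information matrix is singular (e.g. all time constants
below the grid spacing) the standard errors are reported as infinite rather
than pretending precision.

The default sampling grid in the synthetic study is 0–50 min at 0.5-min
steps (101 points). The instrument's true sampling interval is a
configuration choice, not a measured constant; 0.5 min is of the order of a
PTR-MS multi-channel duty cycle and resolves the fastest reference
transients (time constants ≥ 1.2 min) comfortably.

## PTR-MS processing

Channel counts at m/z 69–74 (protonated isoprene with 0–5 ¹³C) are
normalized as

    ncps = cps / (cps₂₁ + w₃₇·cps₃₇ + w₅₅·cps₅₅) × (p_ref / p_drift)

with hydronium dimer/trimer weights w₃₇ = w₅₅ = 1 and reference drift
pressure 2.2 mbar by default; the instrument's exact primary-ion weighting
is vendor-specific, so all three constants are configuration. The formula is
invariant to a common gain on all channels and linear in the isotopologue
channels. The mean empty-cuvette background is subtracted per channel, with
negative results clamped to zero.

Fractional labeling is atom-weighted: f = Σᵢ i·Sᵢ / (5 ΣᵢSᵢ). An optional
correction (on by default) removes the natural-abundance ¹³C₁ shoulder of
unlabeled isoprene by subtracting 5 × 1.1% of the m/z 69 signal from m/z 70
before that computation; this is a first-order correction, exact to O(p₁₃²).
Emission rate is mean steady-state ncps × a user-supplied calibration factor
/ leaf area; no calibration constant ships with the package because it is an
instrument property.

## Pool quantification

LC-MS/MS inputs begin at integrated channel areas (six isotopologue channels
per C5 metabolite). Quantification is by ordinary linear external standard
curves with inverse prediction. Matrix suppression and extraction losses are
corrected from paired analyses of each extract with and without an unlabeled
internal standard: the heavy channels (3–5 ¹³C), which in a post-labeling
extract carry only biological material, scale the endogenous contribution to
the unlabeled channel, and the residual increment is attributed to the
spike; the ratio of that increment to the standard curve's prediction for
the spiked amount is the recovery factor. This isolation algebra is the
package's own formalization of a procedure usually described only
qualitatively; it is deliberately confined to one function
(`istd_matrix_factor`) so an alternative can be swapped in.

Natural-abundance correction solves the binomial convolution system
M·x = areas, where M[i,j] is the probability that a molecule with j labeled
carbons shows i heavy masses given per-atom natural abundance p₁₃ = 0.011;
only carbon is modelled (O/H/N/P isotopes contribute far less at these
masses and resolutions). The solution is clamped at zero and renormalized to
the observed total. Forward convolution followed by correction is an exact
round trip to numerical precision.

Plastidial pools: IDP+DMADP is assumed exclusively plastidial; for DXP and
MEcDP the plastidial share is total × (final label / final label of
IDP+DMADP), capped at the total. Flux fits use plastidial estimates; the
pipeline records totals as well, and a `pool_mode="mean"` switch substitutes
genotype × condition mean pools for per-sample values.

## Control analysis

The flux control coefficient is the OLS slope of log J on log v (natural
logs; the slope is base-invariant), estimated per light × temperature
condition over all genotypes pooled. OLS, not errors-in-variables
regression, is used; measurement error in the activity v therefore
attenuates the slope toward zero, a known limitation of the design (the
activity spread across genotypes — 0.45× to 1.25× — is large against assay
noise, which bounds the attenuation). The 95% CI is t-based with n − 2
degrees of freedom; an estimate whose CI covers zero is flagged. Records
with non-positive J or v cannot be log-transformed and are excluded with a
logged reason; a condition group reduced below three records yields no
estimate. The two-point form (ΔJ/J)/(Δv/v) is provided for single-contrast
checks.

## Synthetic study generator

The generator reproduces the study design: genotypes EV/RNAi/OE with
activity multipliers 1.00/0.45/1.25, four environments (1000/250 PPFD ×
30/21 °C), and per-cell replicate counts of 8–20 matching the reference
study. Condition-level mean pools, plateaus and fluxes are the reference
cell values stored in `REFERENCE_STUDY`.

Two anchoring modes reflect two distinct questions:

* `anchor="table"` pins each genotype × condition cell to its own reference
  row — used to verify that the estimation chain returns known fluxes;
* `anchor="control-law"` derives transgenic fluxes from the EV baseline via
  J = J_EV (v/v_EV)^FCC with a plantable coefficient — used to verify that
  the end-to-end pipeline recovers a known degree of flux control. The two
  modes exist because the reference cells themselves are not consistent with
  any single control law (the silenced line's flux is not depressed), which
  is precisely the scientific finding the control analysis quantifies.

Observation model: per-molecule labeling is treated as five i.i.d. carbon
draws at probability f(t), so channel fractions are binomial(5, f(t))
probabilities — a simplification (real positional labeling is not i.i.d.)
whose atom-weighted labeling is exactly f(t), proven in the tests. Channel
signals are that split times a fixed total isoprene count rate, optionally
convolved with natural abundance, plus a flat empty-cuvette background and
additive Gaussian channel noise. Biological spread is multiplicative
lognormal with default log-sd 0.15 for activity and pools, 0.10 for flux and
0.02 for the plateau, consistent with the coefficient-of-variation scale
implied by the reference cells' standard errors and replicate counts (the
study reports SE, not SD; the conversion uses the printed n). LC-MS runs are
generated in spiked/unspiked pairs with a planted recovery factor (default
0.85) and plastidial fractions of 0.75 (DXP) and 0.85 (MEcDP) — values
chosen as plausible mid-range shares, since the original plastidial
estimates are not tabulated. The DXS activity scale is arbitrary
(EV baseline 100); the FCC is invariant to it.

The `noiseless()` preset zeroes every stochastic term **and** the
deterministic natural-abundance convolution and background, giving an
idealized instrument for exactness tests. All randomness flows from one
`numpy.random.default_rng(seed)`; identical seeds give identical tables on
any platform.

What passing synthetic tests do **not** show about real data: the generator
has no drift in primary-ion intensity, no chromatographic interferences, no
positional labeling structure, no diurnal or stomatal dynamics, and its
noise is uncorrelated across channels and time. Recovery results here bound
estimator behavior under the stated observation model, not under every
instrument pathology.

## Pipeline

Stages run in measurement order: pool quantification → PTR-MS labeling
curves → per-sample flux fits (each sample's own plastidial pools fixed) →
per-condition FCC regression. Every input sample either contributes a flux
row or appears in the exclusion table with a stage and reason
(n_in = n_fit + n_excluded holds for every run); per-sample failures — e.g.
an ISTD spike lost in channel noise — degrade gracefully rather than
aborting. Outputs are TSV tables plus a copy of the run configuration;
re-running with the same config and seed is byte-identical.

## Known limitations

* The plastidial-ratio pool estimate assumes the IDP+DMADP pool is fully
  plateaued at the end of labeling. When flux is low enough that 50 min is
  not a plateau (time constant B/J approaching the window), the ratio — and
  hence the fitted flux — acquires a few-percent upward bias; this is
  visible in the proportional-control synthetic scenario, where halved
  fluxes in the silenced line pull the recovered FCC ≈ 0.97 rather than 1.
* OLS attenuation under activity measurement error (above).
* Flux estimates condition on the measured pools; pool uncertainty is not
  propagated into se(J).
* The three-pool closed form is not exposed for arbitrary chain lengths;
  the internal integrator handles only this cascade.
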