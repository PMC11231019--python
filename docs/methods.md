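# Methods

## Models

### Saturation rate laws

All rate laws describe apparent single-substrate kinetics at fixed
co-substrate concentration; rates are specific activities (U/mg,
µmol·min⁻¹·mg⁻¹) and concentrations are mM.

* **MM** — `v = Vmax·s/(Km+s)`.
* **MM_SI** — uncompetitive substrate inhibition,
  `v = Vmax·s/(Km + s(1+s/Kis))`, algebraically identical to
  `Vmax·s/(Km + s + s²/Kis)`; implemented once in the `1+s/Kis` form. The
  curve peaks at `s* = √(Km·Kis)` with `v* = Vmax/(1+2√(Km/Kis))`; at the
  constraint boundary `Km = Kis` the peak is exactly `Vmax/3`, which is why
  strongly inhibited fits report theoretical `Vmax` values roughly three
  times the highest measurable rate.
* **HILL_SI** — positive cooperativity with the same inhibition term,
  `v = Vmax·sⁿ/(Kmⁿ + sⁿ(1+s/Kis))`. No standard form exists for a
  cooperative law with integrated substrate inhibition; this one was chosen
  because it reduces to MM_SI at `n = 1` and to the plain Hill equation as
  `Kis → ∞`, and it lives behind a single dispatch point so the alternative
  factorised form `v = [Hill]·Kis/(Kis+s)` could be swapped in without
  touching the fitting layer. Parameter values recovered under this form
  are not guaranteed to match numbers obtained with a differently
  parameterised cooperative-inhibition model.

### pH–rate profiles

Built from ionisation terms `10^(pK−pH)`:

* **BELL** — `v = Vlim/(1 + 10^(pKa−pH) + 10^(pH−pKb))`; two ionisations,
  optimum exactly at `(pKa+pKb)/2`, symmetric about it, value `Vlim/3` when
  the pKs coincide.
* **BELL_PLATEAU** —
  `v = Vlim(α + 10^(pKb−pH)) / ((1 + 10^(pKa+pKb−2pH)) + 10^(pKb−pH) + 10^(pH−pKc))`,
  kept verbatim in this grouping (including the combined
  `10^(pKa+pKb−2pH)` term) rather than re-derived; three ionisations with
  an intermediate plateau near `α·Vlim` between pKb and pKc.
* **PLATEAU** —
  `v = (Vplateau + Vlim·10^(pH−pKb)) / (1 + 10^(pKa−pH) + 10^(pH−pKb))`;
  rises from a low-pH plateau to `Vlim` as pH → ∞.

`ph_optimum` uses the closed form for BELL and, for the other models, a
1201-point grid over pH 1–13 refined by bounded golden-section search
(xatol 10⁻⁸); agreement with a brute-force 10⁻⁴-step grid is tested to
10⁻³ pH units.

### Temperature dependence

Below the thermal optimum, activity follows the Arrhenius law
`v = A·e^(−Ea/RT)` with `R = 8.314 J·mol⁻¹·K⁻¹` (shared constant;
interfaces take °C, kelvin is internal only). Above the optimum,
inactivation is modelled by contiguous linear segments. The default
segment builder anchors on three temperatures — optimum 30 °C, knee 60 °C
(retaining 75 % of the optimum rate), complete loss at 75 °C — matching
the qualitative shape of a mesophilic dehydrogenase's profile; no
algorithm locates breakpoints from data, they are configuration. Segments
are constructed to equal the Arrhenius value at the first stitch point, so
the composite curve is continuous by construction.

## Fitting

All fits are nonlinear least squares on the rates themselves (never
log-linearised), run with lmfit's Levenberg–Marquardt from 8 Latin-
hypercube starting points over data-driven ranges (`Km` within
`[min x, max x]·[0.1, 10]`, pKs within the data pH range ± 1, `Vmax`
within 0.2–20× the maximal observed rate); scale-like parameters are
sampled log-uniformly. The default multi-start seed is 1234 and every
fitting entry point takes a `seed` argument, making results reproducible
bit-for-bit at the reported-parameter level. The lowest-SSE converged
start wins. Iterations are capped (500 per start, ×10 function
evaluations); non-convergence from every start raises rather than
returning a silent partial result.

**Weighting.** Unit weights when no per-point sd is supplied; the reduced
χ² then equals the residual mean square. With sd present, residuals are
weighted 1/sd.

**The `Kis ≥ Km` constraint.** Strongly inhibited datasets often have
their unconstrained optimum at `Kis < Km`, which is mechanistically
implausible for the reported enzymes; the constraint is enforced smoothly
by the reparameterisation `Kis = Km·(1+e^θ)` with θ free in [−30, 50].
Because the objective is asymptotically flat in θ as θ → −∞, the exact
stopping point on the flat tail is optimiser-dependent; θ below −10
(i.e. `Kis/Km − 1 < 5·10⁻⁵`) is therefore treated as a binding bound, and
the model is refit on the boundary `Kis ≡ Km` so that constrained results
report the two constants *exactly* equal, with `constraint_active` set.
The unconstrained path is available via `constrain_kis_ge_km=False`.

**Goodness of fit and model selection.** `R² = 1 − SS_res/SS_tot`,
adjusted R² with the `(n−1)/(n−p−1)` penalty, and reduced
χ² = Σ((y−ŷ)/σ)²/(n−p). Candidate pH models are ranked by highest
adjusted R², ties broken by lower reduced χ², then by fewer parameters.
Information criteria (AIC/BIC) are deliberately not used for selection.
Constant-rate datasets have undefined R² (SS_tot = 0): `goodness_of_fit`
raises on them, while fit results degrade to NaN R² and keep χ².

**Arrhenius ascending limb.** Unless a cut temperature is given, points up
to the warmest temperature attaining the empirical rate maximum are used
(so flat profiles keep their whole range). A log-linear regression seeds
the nonlinear fit; at zero noise the two estimates agree to 10⁻⁶ relative,
which is tested as an oracle identity.

**Uncertainties** come from the covariance of the linearised problem at
the optimum (lmfit stderr); for the constrained Kis the delta method maps
θ's stderr through `∂Kis/∂θ = Km·e^θ`. No bootstrap is run by default.

**Degenerate pH data.** A bell fitted to strictly monotone data pushes a
pK beyond the observed range; fitted pKs landing on the edge of the
extended search box are flagged `boundary_pk` (ill-determined limb) rather
than rejected.

## Thermodynamics

`K′ = exp(−ΔG°′/RT)` with ΔG°′ in kJ/mol for the oxidation direction
(alcohol + NAD(P)⁺ → aldehyde + NAD(P)H + H⁺). One proton is released, so
`K′(pH) = K′(7)·10^(pH−7)` (general `protons_released` supported);
applying the correction at the ΔG level instead is consistent to 10⁻⁹
relative and tested as such. The default temperature for equilibrium
arithmetic is 298.15 K.

Two ratio conventions are explicit in the interface:

* **equimolar** — equal starting pools of alcohol and oxidised cofactor,
  no products: aldehyde/alcohol = `√K′`. With ΔG°′ = 15.54 kJ/mol this
  gives 0.0435 → label "1:23" at pH 7 and 0.1376 → "1:7" at pH 8 (the
  value is ≈1:7.3; some reported treatments round this pair to 1:23/1:8 —
  the package prints what it computes and does not force agreement).
* **fixed cofactor poise** — aldehyde/alcohol = `K′·[NAD⁺]/[NADH]`.

`solve_closed_system` solves
`K′ = ([ald]₀+x)([NADH]₀+x)/(([alc]₀−x)([NAD⁺]₀−x))` as a quadratic
(linear at K′ = 1), selecting the unique root inside the physically
admissible extent window; the equilibrium quotient is monotone there, so
admissibility identifies the root. Agreement with a bisection oracle is
tested to 10⁻⁹ mM, and both conserved pairs balance exactly.

## Derived parameters

`kcat = Vmax·M/60` (Vmax in U/mg, M in kDa). The default effective mass
for turnover conversion is **41.6 kDa**, not the 41.4 kDa theoretical
subunit mass: back-calculation from the published kcat column is
self-consistent at 41.5–41.6 kDa (the tagged construct is slightly
heavier), and the mass is always an explicit argument, never buried in
logic. One published kcat entry (benzyl alcohol/NAD⁺, 6.93×10²) is
inconsistent with its own Vmax under any mass near 41 kDa and is treated
as an erratum — excluded from consistency tests. ε₂₈₀ predictions use the
standard residue coefficients Tyr 1490 and Trp 5500 M⁻¹cm⁻¹ with the
cystine contribution omitted, which reproduces both published predictions
exactly.

## Synthetic data

The generator emulates single-curve initial-rate datasets: a model
evaluated on a grid, times (or plus) Gaussian noise, clipped at zero.
Defaults encode the study conditions: substrate grids 0.1–3.5 mM
(alcohol) and 0.1–2.5 mM (aldehyde); a 9-point pH grid 5.0–9.0 in 0.5
steps labelled with the citrate (<6), potassium-phosphate (6–8) and
Tris–Cl (>8) buffer series; multiplicative noise with CV 5 % as a typical
photometric scatter (no replicate statistics were reported to calibrate
against). Generation is a pure function of (parameters, grid, noise spec)
and bit-reproducible under a fixed seed.

What the generator does **not** emulate: buffer-specific activity offsets
at the series boundaries, absorbance-saturation censoring at high
NAD(P)H, enzyme-batch effects, heteroscedasticity beyond a constant CV,
and within-trace autocorrelation. Recovery tests on these data therefore
demonstrate identifiability of the models under the stated designs — that
the fitting machinery finds the generating parameters when the model is
true — not robustness to every artefact of real photometric assays.

## Problem sizes

Recovery checks use the designs the analysis targets: 12-point saturation
curves on 0.25–8 mM, 9-point pH grids, 5-point ascending temperature
limbs (10–30 °C in 5 °C steps), 25 random parameter draws per model
family for the zero-noise sweep, and 100 seeded 5 %-CV replicates for the
noisy pK-recovery study (median |ΔpK| < 0.15). The law-of-large-numbers
check of the noise model uses 10⁴ replicates at a single concentration.

## Known limitations

* Apparent single-substrate kinetics only; no ordered/ping-pong bi-bi
  mechanisms, no global multi-dataset fitting, no Bayesian inference.
* The cooperative-with-inhibition functional form is a modelling choice
  (see above); cross-software parameter comparisons should verify the
  equation.
* Thermal-inactivation breakpoints are configuration, not estimated.
* ΔG°′ is an input; the package does not recompute it from formation
  energies.
* Published pH-profile parameter values were not available for direct
  comparison, so pH-model correctness rests on recovery from synthetic
  data plus the analytic identities (optimum at the pK midpoint,
  `Vlim/3` at coincident pKs, plateau asymptotes).
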