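# badhkin

Kinetic and thermodynamic analysis of dual-cofactor benzyl alcohol
dehydrogenase (BaDH) assays — and, more generally, of single-substrate
initial-rate enzymology data with substrate inhibition, cooperativity,
pH-dependence and temperature-dependence.

BaDH-type enzymes interconvert benzyl alcohol and benzaldehyde using either
NAD(H) or NADP(H), with the phosphorylated cofactors favoured at acidic and
the dephospho forms at alkaline pH. Characterising such an enzyme means
fitting a family of nonlinear models to initial-rate data and deriving a
set of secondary quantities. `badhkin` packages that whole workflow for
anyone analysing photometric dehydrogenase assays:

* **Rate laws** — Michaelis–Menten `v = Vmax·s/(Km+s)`, uncompetitive
  substrate inhibition `v = Vmax·s/(Km + s(1+s/Kis))`, and a cooperative
  Hill variant `v = Vmax·sⁿ/(Kmⁿ + sⁿ(1+s/Kis))`, with constrained
  least-squares fitting that enforces `Kis ≥ Km` and returns the exact
  boundary solution `Km = Kis` when the bound binds.
* **pH–rate profiles** — bell, bell-with-plateau and plateau models built
  from `10^(pK−pH)` ionisation terms, multi-start fitting, and model
  selection by adjusted R² with reduced-χ² and parsimony tie-breaks.
* **Temperature dependence** — nonlinear Arrhenius fits
  (`v = A·e^(−Ea/RT)`) restricted to the ascending limb, plus a piecewise
  model of thermal inactivation above the optimum.
* **Equilibrium thermodynamics** — `K′ = e^(−ΔG°′/RT)` with per-proton pH
  scaling, equilibrium ratio conventions, and an exact closed-system
  equilibrium solver for alcohol/aldehyde/NAD(P) mixtures.
* **Derived parameters** — `kcat = Vmax·M/60`, catalytic efficiencies,
  relative activities, predicted ε₂₈₀ from Tyr/Trp counts, specific
  activity, oligomeric state and cascade yields.
* **Synthetic assays** — a seeded generator of initial-rate datasets for
  parameter-recovery studies, sharing the CSV schema the fitters read.

## Worked example

Fitting the substrate-inhibition rate law to a noise-free synthetic
saturation curve generated from a published benzyl alcohol/NAD⁺ parameter
set (`examples/rate_law_fitting.py`):

```text
generator : Vmax=410.0 U/mg  Km=3.6 mM  Kis=4.37 mM
recovered : Vmax=410.0 U/mg  Km=3.60 mM  Kis=4.37 mM
R2=1.000000  constraint_active=False
curve peak: 145.6 U/mg at 3.97 mM (theoretical Vmax is reached only without substrate inhibition)
```

The fit recovers all three generating parameters exactly, and the analytic
peak `Vmax/(1+2√(Km/Kis))` shows why the highest *measurable* rate
(≈146 U/mg) sits far below the theoretical `Vmax`: with `Kis` close to
`Km`, inhibition sets in before saturation is reached. The equilibrium
example (`examples/equilibrium_thermodynamics.py`) turns
ΔG°′ = +15.54 kJ/mol into K′ = 1.89×10⁻³ at pH 7 — an equimolar
aldehyde:alcohol ratio of 1:23 — and solves a closed 1.3 mM alcohol +
0.75 mM NAD⁺ system at pH 8 to the measured ≈0.10 equilibrium ratio.

Each script in `examples/` is a short narrative of one capability; the
same stages are scriptable from a shell via the thin `badhkin` CLI
(`simulate`, `fit-rate`, `fit-ph`, `fit-temp`, `thermo`, `derive`,
`report`).

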