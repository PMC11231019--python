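"""Derived characterisation parameters from composition and assay numbers.

Pure arithmetic on reported quantities: predicted extinction coefficient
from aromatic-residue counts, specific activity of a purification,
oligomeric state from native vs subunit mass, turnover numbers and
catalytic efficiencies, and the yield of a cofactor-limited cascade.
"""

from badhkin import (
    EnzymeComposition,
    cascade_yield,
    catalytic_efficiency,
    extinction_280,
    kcat_from_vmax,
    oligomeric_state,
    specific_activity,
    table2_fixtures,
)

comp = EnzymeComposition(n_tyr=4, n_trp=0, n_phe=17,
                         subunit_mass=41.4, native_mass=164.0)
print(f"epsilon280 (4 Tyr, no Trp): {extinction_280(comp):.2f} mM^-1 cm^-1")
print(f"epsilon280 with 2 tag Trp : {extinction_280(comp, 2):.2f} mM^-1 cm^-1")

n, resid = oligomeric_state(comp.native_mass, comp.subunit_mass)
print(f"oligomeric state: {n} subunits (residual {resid:.2f}) -> homotetramer")

print(f"purification: {specific_activity(1050.0, 14.8):.0f} U/mg "
      f"from 1050 U / 14.8 mg")

mass = 41.6  # kDa, effective tagged-subunit mass for kcat conversion
p = table2_fixtures()["BAld red NADH pH 7.0"]
kcat = kcat_from_vmax(p.vmax, mass)
print(f"benzaldehyde reduction with NADH: kcat = {kcat:.0f} s^-1, "
      f"kcat/Km = {catalytic_efficiency(kcat, p.km):.0f} mM^-1 s^-1")

print(f"cascade: 0.3 mM product on 1 mM NADH = "
      f"{cascade_yield(0.3, 1.0):.0f}% of the cofactor-limited maximum")
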