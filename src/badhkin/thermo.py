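"""Equilibrium thermodynamics of the alcohol/aldehyde + NAD(P) couple.

The reaction is written in the oxidation direction,

    alcohol + NAD(P)+  ->  aldehyde + NAD(P)H + H+,

so the transformed standard Gibbs energy at pH 7 (ΔG°′, kJ/mol) maps to
K′ = exp(-ΔG°′/RT), and releasing one proton makes K′ grow by a factor of
10 per pH unit above 7. For benzyl alcohol oxidation ΔG°′ is strongly
positive, so equilibrium lies far on the alcohol side at neutral pH.

Two conventions for quoting an equilibrium product:substrate ratio are
provided: the *equimolar* convention (alcohol and oxidised cofactor start
equimolar with no products, giving ratio = sqrt(K′)) and the
*fixed-cofactor-ratio* convention (ratio = K′·[NAD+]/[NADH]). A closed-system
solver computes the exact equilibrium extent for arbitrary finite initial
concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .constants import GAS_CONSTANT, STANDARD_TEMPERATURE_K

__all__ = [
    "SPECIES",
    "ThermoSpec",
    "EquilibriumState",
    "keq_from_dg",
    "dg_from_keq",
    "keq_at_ph",
    "equimolar_ratio",
    "fixed_cofactor_ratio",
    "solve_closed_system",
    "ratio_from_conversion",
    "conversion_from_ratio",
]

SPECIES = ("alcohol", "nad_ox", "aldehyde", "nad_red")


@dataclass(frozen=True)
class ThermoSpec:
    """Thermodynamic description of the oxidation reaction at pH 7."""

    dg0prime_ph7: float  # kJ/mol
    temperature: float = STANDARD_TEMPERATURE_K  # K
    protons_released: int = 1
    gas_constant: float = GAS_CONSTANT  # J/mol/K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.protons_released < 0:
            raise ValueError("protons_released must be >= 0")


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium composition of a closed alcohol/aldehyde/NAD(P) system."""

    extent: float  # mM, signed advancement of the oxidation reaction
    final_conc: dict[str, float] = field(default_factory=dict)
    ratio_ald_alc: float = float("nan")

    def to_dict(self) -> dict:
        return {"extent_mM": self.extent,
                "final_conc_mM": dict(self.final_conc),
                "ratio_ald_alc": self.ratio_ald_alc}


def keq_from_dg(dg_kj_mol: float, t_k: float = STANDARD_TEMPERATURE_K) -> float:
    """K′ = exp(-ΔG°′ / RT) with ΔG°′ in kJ/mol and T in K."""
    if t_k <= 0:
        raise ValueError("temperature must be > 0 K")
    return math.exp(-dg_kj_mol * 1000.0 / (GAS_CONSTANT * t_k))


def dg_from_keq(kprime: float, t_k: float = STANDARD_TEMPERATURE_K) -> float:
    """Inverse of :func:`keq_from_dg`; returns kJ/mol."""
    if kprime <= 0:
        raise ValueError("K' must be > 0")
    return -GAS_CONSTANT * t_k * math.log(kprime) / 1000.0


def keq_at_ph(spec: ThermoSpec, ph: float) -> float:
    """Transformed equilibrium constant at an arbitrary pH.

    Each proton released shifts K′ by one decade per pH unit:
    K′(pH) = K′(7) * 10**(protons_released * (pH - 7)). Equivalently
    ΔG°′(pH) = ΔG°′(7) - n_H+ * RT ln(10) * (pH - 7).
    """
    k7 = keq_from_dg(spec.dg0prime_ph7, spec.temperature)
    return k7 * 10.0 ** (spec.protons_released * (ph - 7.0))


def equimolar_ratio(kprime: float) -> tuple[float, str]:
    """Product:substrate ratio under the equimolar-reactant convention.

    For equal starting pools of alcohol and NAD(P)+ and no products, the
    equilibrium condition x²/(a-x)² = K′ gives aldehyde/alcohol = sqrt(K′).
    The label renders the ratio as "1:n" (n = round(1/ratio)) when products
    are the minority, else "n:1".
    """
    if kprime <= 0:
        raise ValueError("K' must be > 0")
    ratio = math.sqrt(kprime)
    if ratio < 1.0:
        label = f"1:{round(1.0 / ratio)}"
    else:
        label = f"{round(ratio)}:1"
    return ratio, label


def fixed_cofactor_ratio(kprime: float, nad_ox_over_red: float) -> float:
    """Aldehyde/alcohol ratio when the cofactor poise is clamped:
    ratio = K′ * [NAD(P)+]/[NAD(P)H]."""
    if kprime <= 0 or nad_ox_over_red <= 0:
        raise ValueError("K' and cofactor ratio must be > 0")
    return kprime * nad_ox_over_red


def solve_closed_system(kprime: float, init: Mapping[str, float]) -> EquilibriumState:
    """Equilibrium of a closed system from initial concentrations [mM].

    Solves K′ = ([ald]0+x)([NADH]0+x) / (([alc]0-x)([NAD+]0-x)) for the
    unique physically admissible extent x (all four concentrations >= 0) of
    the quadratic (1-K′)x² + bx + c = 0, falling back to the linear case at
    K′ = 1. Mass is conserved within each alcohol/aldehyde and
    NAD+/NADH pair.
    """
    if kprime <= 0:
        raise ValueError("K' must be > 0")
    unknown = set(init) - set(SPECIES)
    if unknown:
        raise ValueError(f"unknown species: {sorted(unknown)}; "
                         f"expected names {SPECIES}")
    alc = float(init.get("alcohol", 0.0))
    nad = float(init.get("nad_ox", 0.0))
    ald = float(init.get("aldehyde", 0.0))
    nadh = float(init.get("nad_red", 0.0))
    for name, v in (("alcohol", alc), ("nad_ox", nad),
                    ("aldehyde", ald), ("nad_red", nadh)):
        if v < 0:
            raise ValueError(f"initial {name} must be >= 0")

    # K'(alc - x)(nad - x) = (ald + x)(nadh + x)
    a = 1.0 - kprime
    b = ald + nadh + kprime * (alc + nad)
    c = ald * nadh - kprime * alc * nad
    lo, hi = -min(ald, nadh), min(alc, nad)  # admissible extent window
    if a == 0.0:
        if b == 0.0:
            raise ValueError("degenerate system: no determinate extent")
        roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise ValueError("no real equilibrium extent for these inputs")
        sq = math.sqrt(disc)
        roots = [(-b + sq) / (2.0 * a), (-b - sq) / (2.0 * a)]
    admissible = [x for x in roots if lo - 1e-12 <= x <= hi + 1e-12]
    if not admissible:
        raise ValueError("no admissible equilibrium extent for these inputs")
    x = min(admissible, key=lambda r: abs(r))
    x = min(max(x, lo), hi)
    final = {"alcohol": alc - x, "nad_ox": nad - x,
             "aldehyde": ald + x, "nad_red": nadh + x}
    ratio = final["aldehyde"] / final["alcohol"] if final["alcohol"] > 0 \
        else float("inf")
    return EquilibriumState(extent=x, final_conc=final, ratio_ald_alc=ratio)


def ratio_from_conversion(f: float) -> float:
    """Residual product:substrate ratio after converting fraction ``f``.

    Converting a fraction f of aldehyde to alcohol leaves
    aldehyde/alcohol = (1-f)/f; e.g. 91.3% conversion leaves a ratio of
    0.095.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("conversion fraction must lie strictly in (0, 1)")
    return (1.0 - f) / f


def conversion_from_ratio(ratio: float) -> float:
    """Inverse of :func:`ratio_from_conversion`: f = 1/(1 + ratio)."""
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    return 1.0 / (1.0 + ratio)
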