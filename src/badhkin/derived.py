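"""Closed-form derived quantities for enzyme characterisation: turnover
numbers, catalytic efficiencies, relative activities, predicted extinction
coefficients, specific activity, oligomeric state and cascade yield.

All operations are pure arithmetic on reported quantities; units follow the
conventions of enzymology tables (U/mg, mM, kDa, s^-1).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EPS_TYR_280",
    "EPS_TRP_280",
    "EnzymeComposition",
    "kcat_from_vmax",
    "catalytic_efficiency",
    "relative_activity",
    "extinction_280",
    "specific_activity",
    "oligomeric_state",
    "cascade_yield",
]

#: residue molar extinction coefficients at 280 nm, M^-1 cm^-1
EPS_TYR_280 = 1490.0
EPS_TRP_280 = 5500.0


@dataclass(frozen=True)
class EnzymeComposition:
    """Chromophore counts and molar masses used for derived parameters.

    Phenylalanine absorbs too weakly at 280 nm to enter the prediction and
    is carried for bookkeeping only. Cystine contributions are omitted.
    """

    n_tyr: int
    n_trp: int
    n_phe: int = 0
    subunit_mass: float = 0.0  # kDa
    native_mass: float | None = None  # kDa
    eps_tyr: float = EPS_TYR_280
    eps_trp: float = EPS_TRP_280

    def __post_init__(self) -> None:
        if min(self.n_tyr, self.n_trp, self.n_phe) < 0:
            raise ValueError("residue counts must be >= 0")
        if self.subunit_mass <= 0:
            raise ValueError("subunit_mass must be > 0 kDa")
        if self.native_mass is not None and self.native_mass <= 0:
            raise ValueError("native_mass must be > 0 kDa")


def kcat_from_vmax(vmax: float, molar_mass_kda: float) -> float:
    """Turnover number [s^-1] from specific activity.

    With vmax in U/mg (µmol min^-1 mg^-1) and the molar mass in kDa
    (mg/µmol), kcat = vmax * mass / 60.
    """
    if vmax <= 0 or molar_mass_kda <= 0:
        raise ValueError("vmax and molar mass must be > 0")
    return vmax * molar_mass_kda / 60.0


def catalytic_efficiency(kcat: float, km: float) -> float:
    """kcat/Km [mM^-1 s^-1]."""
    if km <= 0:
        raise ValueError("km must be > 0")
    return kcat / km


def relative_activity(sa: float, sa_ref: float) -> float:
    """Specific activity as a percentage of a reference substrate's."""
    if sa_ref <= 0:
        raise ValueError("reference specific activity must be > 0")
    if sa < 0:
        raise ValueError("specific activity must be >= 0")
    return 100.0 * sa / sa_ref


def extinction_280(comp: EnzymeComposition, include_tag_trp: int = 0) -> float:
    """Predicted molar extinction coefficient at 280 nm [mM^-1 cm^-1].

    Sum of Tyr and Trp residue contributions, optionally counting extra
    tryptophans contributed by a purification tag.
    """
    if include_tag_trp < 0:
        raise ValueError("include_tag_trp must be >= 0")
    eps_m = comp.n_tyr * comp.eps_tyr + (comp.n_trp + include_tag_trp) * comp.eps_trp
    return eps_m / 1000.0


def specific_activity(total_u: float, total_mg: float) -> float:
    """U per mg protein."""
    if total_mg <= 0:
        raise ValueError("protein amount must be > 0 mg")
    if total_u < 0:
        raise ValueError("activity must be >= 0 U")
    return total_u / total_mg


def oligomeric_state(native_kda: float, subunit_kda: float) -> tuple[int, float]:
    """Nearest-integer subunit count and its residual.

    Returns (n, |native/subunit - n|); e.g. a 164 kDa native mass over a
    41.4 kDa subunit gives a homotetramer (n = 4).
    """
    if native_kda <= 0 or subunit_kda <= 0:
        raise ValueError("masses must be > 0 kDa")
    q = native_kda / subunit_kda
    n = round(q)
    return n, abs(q - n)


def cascade_yield(product_mm: float, limiting_cofactor_mm: float) -> float:
    """Cascade product yield [%] against the limiting cofactor, assuming
    1:1 stoichiometry of cofactor consumption per product formed."""
    if limiting_cofactor_mm <= 0:
        raise ValueError("limiting cofactor must be > 0 mM")
    if product_mm < 0:
        raise ValueError("product concentration must be >= 0 mM")
    return 100.0 * product_mm / limiting_cofactor_mm
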