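"""Closed-form rate laws and activity-profile models for a dual-cofactor
benzyl alcohol dehydrogenase.

Three model families are covered:

* saturation rate laws in substrate (or cofactor) concentration ``s`` [mM] —
  Michaelis-Menten (``MM``), Michaelis-Menten with uncompetitive substrate
  inhibition (``MM_SI``), and a positively cooperative Hill variant with the
  same inhibition term (``HILL_SI``);
* pH-rate profiles built from ionisation terms ``10**(pK - pH)`` — a two-pK
  bell (``BELL``), a three-pK bell with an intermediate plateau
  (``BELL_PLATEAU``), and a profile rising to a limiting plateau at high pH
  (``PLATEAU``);
* an Arrhenius temperature law, optionally stitched to piecewise-linear
  thermal-inactivation segments above the activity optimum.

All evaluators are pure functions of their arguments; rates are in U/mg
(µmol min⁻¹ mg⁻¹) and concentrations in mM throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .constants import GAS_CONSTANT, celsius_to_kelvin

__all__ = [
    "RateLawModel",
    "PhProfileModel",
    "RateLawParams",
    "PhProfileParams",
    "ArrheniusParams",
    "DecaySegment",
    "DecaySegments",
    "eval_rate_law",
    "eval_ph_profile",
    "eval_arrhenius",
    "ph_optimum",
    "eval_temperature_curve",
    "mm_si_peak",
    "default_decay_segments",
]


class RateLawModel(str, Enum):
    """Saturation rate-law families."""

    MM = "MM"
    MM_SI = "MM_SI"
    HILL_SI = "HILL_SI"


class PhProfileModel(str, Enum):
    """pH-rate profile families."""

    BELL = "BELL"
    BELL_PLATEAU = "BELL_PLATEAU"
    PLATEAU = "PLATEAU"


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class RateLawParams:
    """Parameters of a saturation rate law.

    vmax : U/mg, limiting rate.
    km   : mM, half-saturation (Michaelis or Hill) constant.
    kis  : mM, substrate-inhibition constant; required for MM_SI and HILL_SI.
    hill_n : dimensionless cooperativity exponent; required for HILL_SI.
    """

    model_id: RateLawModel
    vmax: float
    km: float
    kis: float | None = None
    hill_n: float | None = None

    def __post_init__(self) -> None:
        _require(self.vmax > 0, "vmax must be > 0")
        _require(self.km > 0, "km must be > 0")
        if self.model_id in (RateLawModel.MM_SI, RateLawModel.HILL_SI):
            _require(self.kis is not None, f"{self.model_id.value} requires kis")
            _require(self.kis > 0, "kis must be > 0")
        else:
            _require(self.kis is None, "kis only applies to MM_SI/HILL_SI")
        if self.model_id is RateLawModel.HILL_SI:
            _require(self.hill_n is not None, "HILL_SI requires hill_n")
            _require(self.hill_n > 0, "hill_n must be > 0")
        else:
            _require(self.hill_n is None, "hill_n only applies to HILL_SI")

    def to_dict(self) -> dict[str, float | str]:
        d: dict[str, float | str] = {
            "model_id": self.model_id.value,
            "vmax": self.vmax,
            "km": self.km,
        }
        if self.kis is not None:
            d["kis"] = self.kis
        if self.hill_n is not None:
            d["hill_n"] = self.hill_n
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, float | str]) -> "RateLawParams":
        return cls(
            model_id=RateLawModel(str(d["model_id"])),
            vmax=float(d["vmax"]),
            km=float(d["km"]),
            kis=float(d["kis"]) if "kis" in d and d["kis"] is not None else None,
            hill_n=float(d["hill_n"]) if "hill_n" in d and d["hill_n"] is not None else None,
        )


@dataclass(frozen=True)
class PhProfileParams:
    """Parameters of a pH-rate profile.

    vlim : U/mg, limiting rate scale.
    pka, pkb : pK of the rising / falling ionisations (bell models) or of the
        two transitions of the plateau model.
    pkc : third pK, BELL_PLATEAU only (high-pH falling limb).
    alpha : dimensionless plateau fraction of vlim, BELL_PLATEAU only.
    vplateau : U/mg, low-pH plateau rate, PLATEAU only.
    """

    model_id: PhProfileModel
    vlim: float
    pka: float
    pkb: float
    pkc: float | None = None
    alpha: float | None = None
    vplateau: float | None = None

    def __post_init__(self) -> None:
        _require(self.vlim > 0, "vlim must be > 0")
        if self.model_id is PhProfileModel.BELL_PLATEAU:
            _require(self.pkc is not None, "BELL_PLATEAU requires pkc")
            _require(self.alpha is not None and self.alpha >= 0, "alpha must be >= 0")
            _require(self.vplateau is None, "vplateau only applies to PLATEAU")
        elif self.model_id is PhProfileModel.PLATEAU:
            _require(self.vplateau is not None and self.vplateau >= 0,
                     "PLATEAU requires vplateau >= 0")
            _require(self.pkc is None and self.alpha is None,
                     "pkc/alpha only apply to BELL_PLATEAU")
        else:
            _require(self.pkc is None and self.alpha is None and self.vplateau is None,
                     "BELL takes only vlim, pka, pkb")

    def to_dict(self) -> dict[str, float | str]:
        d: dict[str, float | str] = {
            "model_id": self.model_id.value,
            "vlim": self.vlim,
            "pka": self.pka,
            "pkb": self.pkb,
        }
        for k in ("pkc", "alpha", "vplateau"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, float | str]) -> "PhProfileParams":
        def opt(k: str) -> float | None:
            return float(d[k]) if k in d and d[k] is not None else None

        return cls(
            model_id=PhProfileModel(str(d["model_id"])),
            vlim=float(d["vlim"]),
            pka=float(d["pka"]),
            pkb=float(d["pkb"]),
            pkc=opt("pkc"),
            alpha=opt("alpha"),
            vplateau=opt("vplateau"),
        )


@dataclass(frozen=True)
class ArrheniusParams:
    """Arrhenius law v = A * exp(-Ea / (R T)).

    prefactor : A, same units as the observed rate (U/mg here).
    ea : apparent activation energy, kJ/mol.
    """

    prefactor: float
    ea: float

    def __post_init__(self) -> None:
        _require(self.prefactor > 0, "prefactor must be > 0")
        _require(self.ea >= 0, "ea must be >= 0")

    def to_dict(self) -> dict[str, float]:
        return {"prefactor": self.prefactor, "ea": self.ea}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ArrheniusParams":
        return cls(prefactor=float(d["prefactor"]), ea=float(d["ea"]))


@dataclass(frozen=True)
class DecaySegment:
    """One linear thermal-inactivation segment: v = intercept + slope * t_C."""

    t_start: float
    t_end: float
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        _require(self.t_start < self.t_end, "t_start must be < t_end")

    def __call__(self, t_c: float) -> float:
        return self.intercept + self.slope * t_c


@dataclass(frozen=True)
class DecaySegments:
    """Contiguous, non-overlapping linear segments above the thermal optimum."""

    segments: tuple[DecaySegment, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        for a, b in zip(segs, segs[1:]):
            _require(abs(a.t_end - b.t_start) < 1e-12,
                     "segments must be contiguous")

    @property
    def t_start(self) -> float:
        return self.segments[0].t_start

    @property
    def t_end(self) -> float:
        return self.segments[-1].t_end


# --- evaluators -----------------------------------------------------------


def eval_rate_law(params: RateLawParams, s) -> float | np.ndarray:
    """Evaluate a saturation rate law at substrate concentration ``s`` [mM].

    MM:      v = vmax*s / (km + s)
    MM_SI:   v = vmax*s / (km + s*(1 + s/kis))
    HILL_SI: v = vmax*s**n / (km**n + s**n*(1 + s/kis))

    HILL_SI reduces to MM_SI at n = 1 and to the plain Hill equation as
    kis -> inf; MM_SI reduces to MM as kis -> inf.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise ValueError("substrate concentration must be >= 0")
    if params.model_id is RateLawModel.MM:
        v = params.vmax * s_arr / (params.km + s_arr)
    elif params.model_id is RateLawModel.MM_SI:
        v = params.vmax * s_arr / (params.km + s_arr * (1.0 + s_arr / params.kis))
    else:  # HILL_SI
        n = params.hill_n
        sn = np.power(s_arr, n)
        v = params.vmax * sn / (params.km ** n + sn * (1.0 + s_arr / params.kis))
    return v if s_arr.ndim else float(v)


def mm_si_peak(params: RateLawParams) -> tuple[float, float]:
    """Closed-form peak of the MM_SI curve.

    The rate is maximal at s* = sqrt(km*kis) with
    v* = vmax / (1 + 2*sqrt(km/kis)); when km = kis (the boundary of the
    Kis >= Km constraint) the peak is exactly vmax/3.
    """
    if params.model_id is not RateLawModel.MM_SI:
        raise ValueError("closed-form peak applies to MM_SI only")
    s_peak = math.sqrt(params.km * params.kis)
    v_peak = params.vmax / (1.0 + 2.0 * math.sqrt(params.km / params.kis))
    return s_peak, v_peak


def eval_ph_profile(params: PhProfileParams, ph) -> float | np.ndarray:
    """Evaluate a pH-rate profile at ``ph``.

    BELL:         v = vlim / (1 + 10**(pka-ph) + 10**(ph-pkb))
    BELL_PLATEAU: v = vlim*(alpha + 10**(pkb-ph))
                      / ((1 + 10**(pka+pkb-2*ph)) + 10**(pkb-ph) + 10**(ph-pkc))
    PLATEAU:      v = (vplateau + vlim*10**(ph-pkb))
                      / (1 + 10**(pka-ph) + 10**(ph-pkb))
    """
    ph_arr = np.asarray(ph, dtype=float)
    if np.any(ph_arr <= 0) or np.any(ph_arr >= 14):
        raise ValueError("ph must lie strictly between 0 and 14")
    if params.model_id is PhProfileModel.BELL:
        v = params.vlim / (1.0 + 10.0 ** (params.pka - ph_arr)
                           + 10.0 ** (ph_arr - params.pkb))
    elif params.model_id is PhProfileModel.BELL_PLATEAU:
        num = params.vlim * (params.alpha + 10.0 ** (params.pkb - ph_arr))
        den = ((1.0 + 10.0 ** (params.pka + params.pkb - 2.0 * ph_arr))
               + 10.0 ** (params.pkb - ph_arr)
               + 10.0 ** (ph_arr - params.pkc))
        v = num / den
    else:  # PLATEAU
        num = params.vplateau + params.vlim * 10.0 ** (ph_arr - params.pkb)
        den = 1.0 + 10.0 ** (params.pka - ph_arr) + 10.0 ** (ph_arr - params.pkb)
        v = num / den
    return v if ph_arr.ndim else float(v)


def eval_arrhenius(params: ArrheniusParams, t_k) -> float | np.ndarray:
    """Evaluate v = A * exp(-Ea/(R*T)) at absolute temperature ``t_k`` [K]."""
    t_arr = np.asarray(t_k, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("absolute temperature must be > 0")
    v = params.prefactor * np.exp(-params.ea * 1000.0 / (GAS_CONSTANT * t_arr))
    return v if t_arr.ndim else float(v)


def ph_optimum(params: PhProfileParams, grid: Sequence[float] | None = None) -> float:
    """pH of maximal activity.

    For BELL the optimum is the closed form (pka + pkb)/2; the other models
    are maximised numerically on a grid refined by golden-section search.
    """
    from scipy.optimize import minimize_scalar

    if params.model_id is PhProfileModel.BELL:
        return 0.5 * (params.pka + params.pkb)
    ph_grid = np.asarray(grid, dtype=float) if grid is not None \
        else np.linspace(1.0, 13.0, 1201)
    vals = eval_ph_profile(params, ph_grid)
    i = int(np.argmax(vals))
    lo = ph_grid[max(i - 1, 0)]
    hi = ph_grid[min(i + 1, len(ph_grid) - 1)]
    if hi <= lo:
        return float(ph_grid[i])
    res = minimize_scalar(lambda p: -eval_ph_profile(params, p),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def default_decay_segments(
    arr: ArrheniusParams,
    t_opt_c: float = 30.0,
    t_knee_c: float = 60.0,
    t_zero_c: float = 75.0,
    frac_at_knee: float = 0.75,
) -> DecaySegments:
    """Build the two-segment thermal-inactivation tail anchored on the
    Arrhenius branch.

    A slow linear decline runs from the optimum (where it matches the
    Arrhenius value exactly) down to ``frac_at_knee`` of that value at the
    knee, then a faster linear decline hits zero activity at ``t_zero_c``.
    Defaults encode an enzyme with maximal activity at 30 degC that retains
    75% of it at 60 degC and is fully inactivated at 75 degC.
    """
    v_opt = eval_arrhenius(arr, celsius_to_kelvin(t_opt_c))
    v_knee = frac_at_knee * v_opt
    slope1 = (v_knee - v_opt) / (t_knee_c - t_opt_c)
    seg1 = DecaySegment(t_opt_c, t_knee_c, slope1, v_opt - slope1 * t_opt_c)
    slope2 = (0.0 - v_knee) / (t_zero_c - t_knee_c)
    seg2 = DecaySegment(t_knee_c, t_zero_c, slope2, v_knee - slope2 * t_knee_c)
    return DecaySegments((seg1, seg2))


def eval_temperature_curve(
    arr: ArrheniusParams, seg: DecaySegments, t_c
) -> float | np.ndarray:
    """Activity vs temperature [degC]: Arrhenius below the first segment,
    piecewise linear (clipped at zero) above, continuous at each stitch
    point by construction of the segments."""
    t_arr = np.asarray(t_c, dtype=float)
    if np.any(t_arr > seg.t_end):
        raise ValueError(
            f"temperature above modelled range (max {seg.t_end} degC)")
    v = np.where(
        t_arr <= seg.t_start,
        eval_arrhenius(arr, celsius_to_kelvin(np.maximum(t_arr, -CELSIUS_MIN))),
        0.0,
    )
    for s in seg.segments:
        in_seg = (t_arr > s.t_start) & (t_arr <= s.t_end)
        v = np.where(in_seg, np.maximum(s.intercept + s.slope * t_arr, 0.0), v)
    return v if t_arr.ndim else float(v)


CELSIUS_MIN = 273.0  # guard: temperature curve not meaningful near 0 K
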