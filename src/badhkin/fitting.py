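"""Constrained nonlinear least-squares fitting of rate laws, pH profiles and
the Arrhenius law, with goodness-of-fit statistics and model selection.

Fits are performed with :mod:`lmfit` (Levenberg-Marquardt on unit-weighted or
sd-weighted residuals) from multiple Latin-hypercube starting points drawn
over data-driven parameter ranges, so that the reported optimum does not
depend on a single initial guess. The substrate-inhibition constraint
Kis >= Km — needed because unconstrained fits of strongly inhibited data can
drive Kis below Km — is enforced smoothly by the reparameterisation
kis = km * (1 + exp(theta)); when the optimum pushes theta to its lower
bound the model is refit on the boundary kis = km exactly and the result is
flagged ``constraint_active``.

Model selection between candidate pH profiles follows adjusted R² with
reduced chi² and parameter count as tie-breaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import lmfit
import numpy as np
from scipy.stats import qmc

from .constants import GAS_CONSTANT, celsius_to_kelvin
from .models import (
    ArrheniusParams,
    PhProfileModel,
    PhProfileParams,
    RateLawModel,
    RateLawParams,
    eval_ph_profile,
    eval_rate_law,
)

__all__ = [
    "AxisKind",
    "AssayDataset",
    "FitResult",
    "ModelSelection",
    "goodness_of_fit",
    "rank_candidates",
    "fit_rate_law",
    "fit_ph_profile",
    "fit_arrhenius",
    "select_ph_model",
]

DEFAULT_MULTISTART_SEED = 1234
N_STARTS = 8
MAX_ITER = 500
#: theta below this means the Kis >= Km constraint binds (kis/km - 1 < 5e-5);
#: the flat exp(theta) tail makes the exact stopping point optimiser-dependent,
#: so detection is deliberately generous and followed by an exact boundary refit
THETA_ACTIVE = -10.0
THETA_MIN = -30.0


class AxisKind(str, Enum):
    SUBSTRATE_MM = "SUBSTRATE_MM"
    PH = "PH"
    TEMPERATURE_C = "TEMPERATURE_C"


@dataclass(frozen=True)
class AssayDataset:
    """One experiment's initial-rate points against a single axis.

    x is substrate/cofactor concentration [mM], pH, or temperature [degC]
    depending on ``axis_kind``; rates are U/mg with optional per-point sd.
    """

    axis_kind: AxisKind
    x: tuple[float, ...]
    rate: tuple[float, ...]
    sd: tuple[float, ...] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = tuple(float(v) for v in self.x)
        rate = tuple(float(v) for v in self.rate)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "rate", rate)
        if len(x) != len(rate):
            raise ValueError("x and rate must have equal length")
        if not all(math.isfinite(v) for v in x):
            raise ValueError("x values must be finite")
        if any(v < 0 for v in rate):
            raise ValueError("rates must be >= 0")
        if self.sd is not None:
            sd = tuple(float(v) for v in self.sd)
            object.__setattr__(self, "sd", sd)
            if len(sd) != len(x):
                raise ValueError("sd must match x in length")
            if any(v <= 0 for v in sd):
                raise ValueError("sd values must be > 0")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class FitResult:
    """Converged least-squares estimate with uncertainties and diagnostics."""

    params: RateLawParams | PhProfileParams | ArrheniusParams
    se: dict[str, float | None]
    r2: float
    adj_r2: float
    red_chi2: float
    n_points: int
    n_params: int
    converged: bool
    constraint_active: bool
    residuals: tuple[float, ...]
    boundary_pk: bool = False

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "se": dict(self.se),
            "gof": {"r2": self.r2, "adj_r2": self.adj_r2,
                    "red_chi2": self.red_chi2},
            "n_points": self.n_points,
            "n_params": self.n_params,
            "converged": self.converged,
            "constraint_active": self.constraint_active,
            "boundary_pk": self.boundary_pk,
            "residuals": list(self.residuals),
        }


@dataclass(frozen=True)
class ModelSelection:
    """Outcome of fitting several candidate models to one dataset."""

    candidates: tuple[tuple[str, FitResult], ...]
    chosen: str

    @property
    def chosen_fit(self) -> FitResult:
        return dict(self.candidates)[self.chosen]

    def criteria(self) -> dict[str, dict[str, float]]:
        return {mid: {"adj_r2": fr.adj_r2, "red_chi2": fr.red_chi2}
                for mid, fr in self.candidates}

    def to_dict(self) -> dict:
        return {
            "chosen": self.chosen,
            "criteria": self.criteria(),
            "candidates": {mid: fr.to_dict() for mid, fr in self.candidates},
        }


def goodness_of_fit(
    observed: Sequence[float],
    predicted: Sequence[float],
    sd: Sequence[float] | None,
    n_params: int,
) -> tuple[float, float, float]:
    """(R², adjusted R², reduced chi²) for a fitted curve.

    R² = 1 - SS_res/SS_tot; adjusted R² applies the (n-1)/(n-p-1) penalty;
    reduced chi² is sum(((y-yhat)/sigma)**2)/(n-p) with sigma = 1 when no
    per-point sd is available (it then equals the residual mean square).
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have equal length")
    n = y.size
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        raise ValueError("degenerate data: zero total sum of squares")
    r2 = 1.0 - ss_res / ss_tot
    if n > n_params + 1:
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)
    else:
        adj_r2 = float("nan")
    sigma = np.asarray(sd, dtype=float) if sd is not None else 1.0
    dof = n - n_params
    red_chi2 = float(np.sum(((y - yhat) / sigma) ** 2) / dof) if dof > 0 \
        else float("nan")
    return r2, adj_r2, red_chi2


def _lhs_starts(rng_seed: int, bounds: dict[str, tuple[float, float]],
                n_starts: int = N_STARTS) -> list[dict[str, float]]:
    """Latin-hypercube starting points over per-parameter ranges.

    Scale-like parameters (ranges spanning decades, strictly positive) are
    sampled log-uniformly; location-like parameters (pK) uniformly.
    """
    names = list(bounds)
    sampler = qmc.LatinHypercube(d=len(names), seed=rng_seed)
    unit = sampler.random(n=n_starts)
    starts = []
    for row in unit:
        s = {}
        for u, name in zip(row, names):
            lo, hi = bounds[name]
            if lo > 0 and hi / lo > 50:
                s[name] = lo * (hi / lo) ** u
            else:
                s[name] = lo + (hi - lo) * u
        starts.append(s)
    return starts


def _run_multistart(model: lmfit.Model, y: np.ndarray, weights,
                    make_params, starts, **indep) -> lmfit.model.ModelResult | None:
    """Fit from every start; keep the lowest-SSE converged result."""
    best = None
    for s in starts:
        params = make_params(s)
        try:
            res = model.fit(y, params, weights=weights, max_nfev=MAX_ITER * 10,
                            **indep)
        except Exception:
            continue
        if not np.all(np.isfinite(res.residual)):
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    return best


def _se_map(res: lmfit.model.ModelResult, names: Sequence[str]) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for n in names:
        p = res.params.get(n)
        out[n] = float(p.stderr) if p is not None and p.stderr is not None else None
    return out


def _finish(params_obj, se, data: AssayDataset, predicted, n_params,
            converged, constraint_active, boundary_pk=False) -> FitResult:
    y = np.asarray(data.rate, dtype=float)
    try:
        r2, adj_r2, red_chi2 = goodness_of_fit(y, predicted, data.sd, n_params)
    except ValueError:
        # constant observed rates: R^2 is undefined, chi^2 still is not
        r2 = adj_r2 = float("nan")
        sigma = np.asarray(data.sd, dtype=float) if data.sd is not None else 1.0
        dof = len(data) - n_params
        red_chi2 = float(np.sum(((y - predicted) / sigma) ** 2) / dof) \
            if dof > 0 else float("nan")
    return FitResult(
        params=params_obj, se=se, r2=r2, adj_r2=adj_r2, red_chi2=red_chi2,
        n_points=len(data), n_params=n_params, converged=converged,
        constraint_active=constraint_active,
        residuals=tuple(float(v) for v in (y - predicted)),
        boundary_pk=boundary_pk,
    )


# --- rate laws ------------------------------------------------------------


def _rate_law_n_params(model_id: RateLawModel) -> int:
    return {RateLawModel.MM: 2, RateLawModel.MM_SI: 3,
            RateLawModel.HILL_SI: 4}[model_id]


def fit_rate_law(
    data: AssayDataset,
    model_id: RateLawModel | str,
    constrain_kis_ge_km: bool = True,
    seed: int = DEFAULT_MULTISTART_SEED,
) -> FitResult:
    """Fit a saturation rate law to substrate-axis data.

    With ``constrain_kis_ge_km`` the inhibition constant is reparameterised
    as kis = km*(1+exp(theta)); if the optimiser drives theta to the lower
    bound the fit is repeated on the boundary kis = km and the result is
    flagged ``constraint_active`` (the fitted Km and Kis are then identical).
    """
    model_id = RateLawModel(model_id)
    if data.axis_kind is not AxisKind.SUBSTRATE_MM:
        raise ValueError("fit_rate_law requires substrate-axis data")
    npar = _rate_law_n_params(model_id)
    if len(data) < npar + 1:
        raise ValueError(f"need at least {npar + 1} points for {model_id.value}")

    s = np.asarray(data.x, dtype=float)
    y = np.asarray(data.rate, dtype=float)
    weights = 1.0 / np.asarray(data.sd, dtype=float) if data.sd is not None else None
    has_kis = model_id in (RateLawModel.MM_SI, RateLawModel.HILL_SI)
    has_n = model_id is RateLawModel.HILL_SI
    constrained = constrain_kis_ge_km and has_kis

    x_pos = s[s > 0]
    x_lo, x_hi = float(np.min(x_pos)), float(np.max(x_pos))
    vmax_scale = float(np.max(y)) if np.max(y) > 0 else 1.0
    bounds = {"vmax": (0.2 * vmax_scale, 20.0 * vmax_scale),
              "km": (0.1 * x_lo, 10.0 * x_hi)}
    if has_kis and not constrained:
        bounds["kis"] = (0.1 * x_lo, 100.0 * x_hi)
    if constrained:
        bounds["theta"] = (-5.0, 5.0)
    if has_n:
        bounds["hill_n"] = (0.5, 4.0)

    def model_fn(s, vmax, km, kis=np.inf, hill_n=1.0, theta=0.0):
        if constrained:
            kis = km * (1.0 + np.exp(theta))
        if model_id is RateLawModel.MM:
            return vmax * s / (km + s)
        if model_id is RateLawModel.MM_SI:
            return vmax * s / (km + s * (1.0 + s / kis))
        sn = np.power(s, hill_n)
        return vmax * sn / (km ** hill_n + sn * (1.0 + s / kis))

    model = lmfit.Model(model_fn, independent_vars=["s"])

    def make_params(start: dict[str, float]) -> lmfit.Parameters:
        p = model.make_params()
        p["vmax"].set(value=start["vmax"], min=1e-12)
        p["km"].set(value=start["km"], min=1e-12)
        if constrained:
            p["theta"].set(value=start["theta"], min=THETA_MIN, max=50.0)
            p["kis"].set(value=1e12, vary=False)
        elif has_kis:
            p["kis"].set(value=start["kis"], min=1e-12)
            p["theta"].set(value=0.0, vary=False)
        else:
            p["kis"].set(value=1e12, vary=False)
            p["theta"].set(value=0.0, vary=False)
        if has_n:
            p["hill_n"].set(value=start["hill_n"], min=0.05, max=10.0)
        else:
            p["hill_n"].set(value=1.0, vary=False)
        return p

    starts = _lhs_starts(seed, bounds)
    best = _run_multistart(model, y, weights, make_params, starts, s=s)
    if best is None:
        raise RuntimeError(f"{model_id.value} fit failed to converge from "
                           f"{N_STARTS} starts")

    constraint_active = False
    if constrained and best.params["theta"].value <= THETA_ACTIVE:
        # boundary optimum: refit on kis = km exactly
        constraint_active = True
        best = _refit_on_boundary(model, y, weights, make_params, starts, s=s)

    vmax = float(best.params["vmax"].value)
    km = float(best.params["km"].value)
    kwargs: dict[str, float] = {}
    if has_kis:
        if constraint_active:
            kis = km
        elif constrained:
            kis = km * (1.0 + math.exp(float(best.params["theta"].value)))
        else:
            kis = float(best.params["kis"].value)
        kwargs["kis"] = kis
    if has_n:
        kwargs["hill_n"] = float(best.params["hill_n"].value)
    fitted = RateLawParams(model_id=model_id, vmax=vmax, km=km, **kwargs)
    predicted = np.asarray(eval_rate_law(fitted, s))
    se_names = ["vmax", "km"] + (["theta" if constrained else "kis"] if has_kis else []) \
        + (["hill_n"] if has_n else [])
    se = _se_map(best, se_names)
    if constrained and "theta" in se:
        se_theta = se.pop("theta")
        # delta-method: d(kis)/d(theta) = km * exp(theta)
        if se_theta is not None and not constraint_active:
            theta_hat = float(best.params["theta"].value)
            se["kis"] = km * math.exp(theta_hat) * se_theta
        else:
            se["kis"] = None
    return _finish(fitted, se, data, predicted, npar, bool(best.success),
                   constraint_active)


def _refit_on_boundary(model, y, weights, make_params, starts, **indep):
    """Refit with theta pinned at the active bound so kis tracks km exactly
    up to the exp(theta) ~ 2e-9 remainder, which is then snapped to zero."""
    best = None
    for s in starts:
        p = make_params(s)
        p["theta"].set(value=-1e9, min=-1e9, max=-1e9 + 1, vary=False)
        try:
            res = model.fit(y, p, weights=weights, max_nfev=MAX_ITER * 10, **indep)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("boundary refit failed")
    return best


# --- pH profiles ----------------------------------------------------------


def _ph_n_params(model_id: PhProfileModel) -> int:
    return {PhProfileModel.BELL: 3, PhProfileModel.PLATEAU: 4,
            PhProfileModel.BELL_PLATEAU: 5}[model_id]


def fit_ph_profile(
    data: AssayDataset,
    model_id: PhProfileModel | str,
    seed: int = DEFAULT_MULTISTART_SEED,
) -> FitResult:
    """Fit one of the three pH-profile models with multi-start over pK
    initialisations spanning the data pH range (+- 1 unit).

    A fitted pK landing on the edge of that extended range marks an
    ill-determined limb (e.g. a bell fitted to monotone data) and is flagged
    ``boundary_pk``.
    """
    model_id = PhProfileModel(model_id)
    if data.axis_kind is not AxisKind.PH:
        raise ValueError("fit_ph_profile requires pH-axis data")
    npar = _ph_n_params(model_id)
    if len(data) < npar + 1:
        raise ValueError(f"need at least {npar + 1} points for {model_id.value}")

    ph = np.asarray(data.x, dtype=float)
    y = np.asarray(data.rate, dtype=float)
    weights = 1.0 / np.asarray(data.sd, dtype=float) if data.sd is not None else None
    ph_lo, ph_hi = float(np.min(ph)) - 1.0, float(np.max(ph)) + 1.0
    vscale = float(np.max(y)) if np.max(y) > 0 else 1.0

    bounds = {"vlim": (0.5 * vscale, 10.0 * vscale),
              "pka": (ph_lo, ph_hi), "pkb": (ph_lo, ph_hi)}
    if model_id is PhProfileModel.BELL_PLATEAU:
        bounds["pkc"] = (ph_lo, ph_hi)
        bounds["alpha"] = (0.0, 1.0)
    if model_id is PhProfileModel.PLATEAU:
        bounds["vplateau"] = (0.0, vscale)

    def model_fn(ph, vlim, pka, pkb, pkc=14.0, alpha=0.0, vplateau=0.0):
        if model_id is PhProfileModel.BELL:
            return vlim / (1.0 + 10.0 ** (pka - ph) + 10.0 ** (ph - pkb))
        if model_id is PhProfileModel.BELL_PLATEAU:
            num = vlim * (alpha + 10.0 ** (pkb - ph))
            den = ((1.0 + 10.0 ** (pka + pkb - 2.0 * ph))
                   + 10.0 ** (pkb - ph) + 10.0 ** (ph - pkc))
            return num / den
        num = vplateau + vlim * 10.0 ** (ph - pkb)
        return num / (1.0 + 10.0 ** (pka - ph) + 10.0 ** (ph - pkb))

    model = lmfit.Model(model_fn, independent_vars=["ph"])

    def make_params(start: dict[str, float]) -> lmfit.Parameters:
        p = model.make_params()
        p["vlim"].set(value=start["vlim"], min=1e-12)
        p["pka"].set(value=min(start["pka"], start["pkb"]), min=ph_lo - 2, max=ph_hi + 2)
        p["pkb"].set(value=max(start["pka"], start["pkb"]), min=ph_lo - 2, max=ph_hi + 2)
        if model_id is PhProfileModel.BELL_PLATEAU:
            p["pkc"].set(value=max(start["pkc"], start["pkb"]), min=ph_lo - 2, max=ph_hi + 2)
            p["alpha"].set(value=start["alpha"], min=0.0)
        else:
            p["pkc"].set(value=14.0, vary=False)
            p["alpha"].set(value=0.0, vary=False)
        if model_id is PhProfileModel.PLATEAU:
            p["vplateau"].set(value=start["vplateau"], min=0.0)
        else:
            p["vplateau"].set(value=0.0, vary=False)
        return p

    starts = _lhs_starts(seed, bounds)
    best = _run_multistart(model, y, weights, make_params, starts, ph=ph)
    if best is None:
        raise RuntimeError(f"{model_id.value} fit failed to converge from "
                           f"{N_STARTS} starts")

    vals = {n: float(best.params[n].value) for n in best.params}
    kwargs: dict[str, float] = {}
    if model_id is PhProfileModel.BELL_PLATEAU:
        kwargs = {"pkc": vals["pkc"], "alpha": vals["alpha"]}
    elif model_id is PhProfileModel.PLATEAU:
        kwargs = {"vplateau": vals["vplateau"]}
    pka, pkb = vals["pka"], vals["pkb"]
    if model_id is PhProfileModel.BELL and pka > pkb:
        pka, pkb = pkb, pka  # BELL is symmetric in (pka, pkb); keep pka <= pkb
    fitted = PhProfileParams(model_id=model_id, vlim=vals["vlim"],
                             pka=pka, pkb=pkb, **kwargs)
    predicted = np.asarray(eval_ph_profile(fitted, ph))
    pk_names = ["pka", "pkb"] + (["pkc"] if model_id is PhProfileModel.BELL_PLATEAU else [])
    boundary = any(
        not (ph_lo - 2 + 1e-3 < vals[n] < ph_hi + 2 - 1e-3) for n in pk_names
    )
    se_names = list(bounds)
    return _finish(fitted, _se_map(best, se_names), data, predicted, npar,
                   bool(best.success), False, boundary_pk=boundary)


def select_ph_model(
    data: AssayDataset,
    candidates: Sequence[PhProfileModel | str],
    seed: int = DEFAULT_MULTISTART_SEED,
) -> ModelSelection:
    """Fit each candidate pH model and choose by highest adjusted R²,
    breaking ties by lower reduced chi², then by fewer parameters."""
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    fits: list[tuple[str, FitResult]] = []
    errors: list[str] = []
    for mid in candidates:
        mid = PhProfileModel(mid)
        try:
            fits.append((mid.value, fit_ph_profile(data, mid, seed=seed)))
        except Exception as exc:  # noqa: BLE001 — candidate failure is data
            errors.append(f"{mid.value}: {exc}")
    if not fits:
        raise RuntimeError("all candidate fits failed: " + "; ".join(errors))
    return ModelSelection(candidates=tuple(fits), chosen=rank_candidates(fits)[0])


def rank_candidates(fits: Sequence[tuple[str, FitResult]]) -> list[str]:
    """Model ids best-first: highest adjusted R², ties broken by lower
    reduced chi², then by fewer parameters."""
    ordered = sorted(fits, key=lambda kv: (-kv[1].adj_r2, kv[1].red_chi2,
                                           kv[1].n_params))
    return [mid for mid, _ in ordered]


# --- Arrhenius ------------------------------------------------------------


def fit_arrhenius(
    data: AssayDataset,
    ascending_limit_c: float | None = None,
    seed: int = DEFAULT_MULTISTART_SEED,
) -> FitResult:
    """Nonlinear fit of v = A*exp(-Ea/(R*T)) to the ascending limb of a
    temperature-activity dataset.

    Points at temperatures up to ``ascending_limit_c`` are used; when absent
    the cut is placed at the temperature of the empirical rate maximum. The
    fit is on rates directly (not log-linearised). Returns Ea in kJ/mol.
    """
    if data.axis_kind is not AxisKind.TEMPERATURE_C:
        raise ValueError("fit_arrhenius requires temperature-axis data")
    t_c = np.asarray(data.x, dtype=float)
    y = np.asarray(data.rate, dtype=float)
    if ascending_limit_c is not None:
        limit = ascending_limit_c
    else:
        # warmest point attaining the empirical maximum, so flat profiles
        # keep their whole range on the ascending limb
        at_max = t_c[y >= np.max(y) * (1.0 - 1e-12)]
        limit = float(np.max(at_max))
    mask = t_c <= limit + 1e-12
    if int(np.sum(mask)) < 3:
        raise ValueError("need at least 3 points on the ascending limb")
    t_k = celsius_to_kelvin(t_c[mask])
    ya = y[mask]
    weights = None
    if data.sd is not None:
        weights = 1.0 / np.asarray(data.sd, dtype=float)[mask]

    # log-linear regression seeds the nonlinear fit
    pos = ya > 0
    if int(np.sum(pos)) >= 2:
        slope, intercept = np.polyfit(1.0 / t_k[pos], np.log(ya[pos]), 1)
        ea0 = max(-slope * GAS_CONSTANT / 1000.0, 0.0)
        a0 = math.exp(intercept)
    else:
        ea0, a0 = 25.0, float(np.max(ya)) if np.max(ya) > 0 else 1.0

    def model_fn(t_k, prefactor, ea):
        return prefactor * np.exp(-ea * 1000.0 / (GAS_CONSTANT * t_k))

    model = lmfit.Model(model_fn, independent_vars=["t_k"])
    bounds = {"prefactor": (max(a0 * 1e-3, 1e-12), a0 * 1e3 + 1.0),
              "ea": (0.0, max(4.0 * ea0, 100.0))}

    def make_params(start: dict[str, float]) -> lmfit.Parameters:
        p = model.make_params()
        p["prefactor"].set(value=start["prefactor"], min=1e-300)
        p["ea"].set(value=start["ea"], min=0.0)
        return p

    starts = [{"prefactor": a0, "ea": ea0}] + _lhs_starts(seed, bounds)
    best = _run_multistart(model, ya, weights, make_params, starts, t_k=t_k)
    if best is None:
        raise RuntimeError("Arrhenius fit failed to converge")

    fitted = ArrheniusParams(prefactor=float(best.params["prefactor"].value),
                             ea=float(best.params["ea"].value))
    predicted = best.eval(t_k=t_k)
    sub = AssayDataset(axis_kind=AxisKind.TEMPERATURE_C,
                       x=tuple(t_c[mask]), rate=tuple(ya),
                       sd=tuple(np.asarray(data.sd)[mask]) if data.sd is not None else None,
                       meta=dict(data.meta))
    return _finish(fitted, _se_map(best, ["prefactor", "ea"]), sub, predicted,
                   2, bool(best.success), False)
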