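"""Assay-table CSV and config YAML handling plus JSON report helpers.

The assay table is a delimited text file with header columns

    axis_kind, x_value, rate, sd, substrate, cofactor, ph, temperature_c, batch

where ``sd`` and the metadata columns may be empty and lines starting with
``#`` are comments (the generator writes its provenance there). A *section*
is a contiguous run of rows sharing all metadata columns; each section must
have a single axis kind and becomes one :class:`~badhkin.fitting.AssayDataset`.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .constants import GAS_CONSTANT, STANDARD_TEMPERATURE_K
from .derived import EnzymeComposition
from .fitting import DEFAULT_MULTISTART_SEED, AssayDataset, AxisKind
from .synthetic import NoiseKind, NoiseSpec

__all__ = [
    "ASSAY_COLUMNS",
    "AssayTableError",
    "Config",
    "read_assay_table",
    "write_assay_table",
    "load_config",
    "write_fit_table",
    "write_json_report",
]

ASSAY_COLUMNS = ("axis_kind", "x_value", "rate", "sd", "substrate",
                 "cofactor", "ph", "temperature_c", "batch")
_META_COLUMNS = ("substrate", "cofactor", "ph", "temperature_c", "batch")


class AssayTableError(ValueError):
    """Malformed assay table; message carries the offending line number."""


@dataclass(frozen=True)
class Config:
    """Pipeline configuration: physical constants, enzyme composition and
    thermodynamic inputs, read from YAML."""

    gas_constant: float = GAS_CONSTANT
    temperature_k: float = STANDARD_TEMPERATURE_K
    composition: EnzymeComposition | None = None
    kcat_molar_mass_kda: float | None = None
    dg0prime_ph7: float | None = None
    noise_default: NoiseSpec = NoiseSpec()
    multistart_seed: int = DEFAULT_MULTISTART_SEED

    def __post_init__(self) -> None:
        if self.gas_constant <= 0 or self.temperature_k <= 0:
            raise ValueError("physical constants must be positive")
        if self.kcat_molar_mass_kda is not None and self.kcat_molar_mass_kda <= 0:
            raise ValueError("kcat molar mass must be positive")


def load_config(path: str | Path) -> Config:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    comp = None
    if "composition" in raw:
        c = raw["composition"]
        comp = EnzymeComposition(
            n_tyr=int(c["n_tyr"]), n_trp=int(c["n_trp"]),
            n_phe=int(c.get("n_phe", 0)),
            subunit_mass=float(c["subunit_mass_kda"]),
            native_mass=float(c["native_mass_kda"]) if "native_mass_kda" in c else None,
            eps_tyr=float(c.get("eps_tyr", EnzymeComposition.eps_tyr)),
            eps_trp=float(c.get("eps_trp", EnzymeComposition.eps_trp)),
        )
    noise = NoiseSpec()
    if "noise" in raw:
        n = raw["noise"]
        noise = NoiseSpec(kind=NoiseKind(n.get("kind", "MULTIPLICATIVE_GAUSSIAN")),
                          cv_or_sd=float(n.get("cv_or_sd", 0.05)),
                          seed=int(n.get("seed", 0)),
                          replicates=int(n.get("replicates", 1)))
    return Config(
        gas_constant=float(raw.get("gas_constant", GAS_CONSTANT)),
        temperature_k=float(raw.get("temperature_k", STANDARD_TEMPERATURE_K)),
        composition=comp,
        kcat_molar_mass_kda=float(raw["kcat_molar_mass_kda"])
        if "kcat_molar_mass_kda" in raw else None,
        dg0prime_ph7=float(raw["dg0prime_ph7"]) if "dg0prime_ph7" in raw else None,
        noise_default=noise,
        multistart_seed=int(raw.get("multistart_seed", DEFAULT_MULTISTART_SEED)),
    )


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)  # full double precision for lossless round-trips
    return str(v)


def write_assay_table(datasets: Iterable[AssayDataset], path: str | Path,
                      header_comments: Sequence[str] = ()) -> None:
    """Write datasets to the assay CSV schema (one section per dataset)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(ASSAY_COLUMNS)
        for ds in datasets:
            meta = ds.meta
            for i, (x, r) in enumerate(zip(ds.x, ds.rate)):
                sd = ds.sd[i] if ds.sd is not None else None
                writer.writerow([
                    ds.axis_kind.value, _fmt(x), _fmt(r), _fmt(sd),
                    _fmt(meta.get("substrate")), _fmt(meta.get("cofactor")),
                    _fmt(meta.get("ph")), _fmt(meta.get("temperature_c")),
                    _fmt(meta.get("batch")),
                ])


def _parse_float(s: str, col: str, lineno: int) -> float:
    try:
        v = float(s)
    except ValueError as exc:
        raise AssayTableError(f"line {lineno}: column '{col}' is not numeric: "
                              f"{s!r}") from exc
    if not math.isfinite(v):
        raise AssayTableError(f"line {lineno}: column '{col}' must be finite")
    return v


def read_assay_table(path: str | Path) -> list[AssayDataset]:
    """Parse an assay CSV into one dataset per section.

    Sections break when any metadata column changes; a section mixing axis
    kinds, a negative rate, or a non-numeric value raises
    :class:`AssayTableError` with the line number.
    """
    path = Path(path)
    rows: list[tuple[int, dict[str, str]]] = []
    with path.open() as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = next(csv.reader([line]))
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in ASSAY_COLUMNS if c not in header]
                if missing:
                    raise AssayTableError(
                        f"line {lineno}: missing columns {missing}")
                continue
            if len(fields) != len(header):
                raise AssayTableError(
                    f"line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}")
            rows.append((lineno, dict(zip(header, fields))))
    if header is None:
        raise AssayTableError("empty file: no header row")

    datasets: list[AssayDataset] = []
    section: list[tuple[int, dict[str, str]]] = []

    def flush() -> None:
        if not section:
            return
        kinds = {r["axis_kind"] for _, r in section}
        if len(kinds) > 1:
            lineno = section[0][0]
            raise AssayTableError(
                f"section starting at line {lineno}: mixed axis kinds {sorted(kinds)}")
        try:
            kind = AxisKind(section[0][1]["axis_kind"])
        except ValueError as exc:
            raise AssayTableError(
                f"line {section[0][0]}: unknown axis_kind "
                f"{section[0][1]['axis_kind']!r}") from exc
        x, rate, sd = [], [], []
        any_sd = any(r["sd"].strip() for _, r in section)
        for lineno, r in section:
            x.append(_parse_float(r["x_value"], "x_value", lineno))
            rv = _parse_float(r["rate"], "rate", lineno)
            if rv < 0:
                raise AssayTableError(f"line {lineno}: negative rate {rv}")
            rate.append(rv)
            if any_sd:
                if not r["sd"].strip():
                    raise AssayTableError(
                        f"line {lineno}: sd missing in a section that has sd")
                sv = _parse_float(r["sd"], "sd", lineno)
                if sv <= 0:
                    raise AssayTableError(f"line {lineno}: sd must be > 0")
                sd.append(sv)
        first = section[0][1]
        meta = {c: first[c] for c in _META_COLUMNS if first[c].strip()}
        datasets.append(AssayDataset(
            axis_kind=kind, x=tuple(x), rate=tuple(rate),
            sd=tuple(sd) if any_sd else None, meta=meta))
        section.clear()

    prev_meta: tuple | None = None
    for lineno, r in rows:
        key = tuple(r[c] for c in _META_COLUMNS)
        if prev_meta is not None and key != prev_meta:
            flush()
        section.append((lineno, r))
        prev_meta = key
    flush()
    return datasets


def write_fit_table(data: AssayDataset, fit, path: str | Path) -> None:
    """CSV of observed vs predicted rates with residuals for one fit."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "observed", "predicted", "residual"])
        for x, obs, res in zip(data.x, data.rate, fit.residuals):
            writer.writerow([_fmt(x), _fmt(obs), _fmt(obs - res), _fmt(res)])


def write_json_report(obj: dict, path: str | Path) -> None:
    """Canonical JSON rendering: sorted keys, fixed separators, newline at
    EOF — byte-identical for identical inputs."""
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n")
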