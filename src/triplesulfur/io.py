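"""Dataset file format: delimited text, one row per (time point × pool).

Columns (fixed header, units in the names; missing values are empty, never
zero-filled)::

    experiment_id,t_h,cells_per_ml,cells_rsd_pct,species,conc_mM_S,
    sd_conc_mM,d34S_permil,D33S_permil,frame,flags

``flags`` holds semicolon-separated ``key=value`` annotations; recognised
time-point-level keys (``control`` marks uninoculated/killed-control rows,
numeric keys such as printed per-point fractionations or rates) are merged
into ``TimePoint.extras``.  File-level metadata travels in ``# key: value``
comment lines before the header (``acceptor``, ``donor``,
``initial_acceptor_S_mM`` and free-form notes).
"""

from __future__ import annotations

import io as _io
import math
from pathlib import Path

import pandas as pd

from .core import (
    MEASURED_SPECIES,
    IsotopeComposition,
    SulfurPool,
)
from .mass_balance import ExperimentDataset, TimePoint

__all__ = [
    "COLUMNS",
    "read_dataset",
    "write_dataset",
    "read_compositions",
    "read_sim_config",
]

COLUMNS = [
    "experiment_id",
    "t_h",
    "cells_per_ml",
    "cells_rsd_pct",
    "species",
    "conc_mM_S",
    "sd_conc_mM",
    "d34S_permil",
    "D33S_permil",
    "frame",
    "flags",
]

_SPECIES_LOOKUP = {s.lower(): s for s in MEASURED_SPECIES}


class DatasetFormatError(ValueError):
    pass


def _parse_flags(raw) -> dict:
    out: dict = {}
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return out
    for item in str(raw).split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, val = item.partition("=")
        key = key.strip()
        val = val.strip()
        try:
            out[key] = float(val)
        except ValueError:
            out[key] = val if val else True
    return out


def _read_text(source) -> str:
    if isinstance(source, (str, Path)):
        return Path(source).read_text()
    return source.read()


def _header_meta(text: str) -> dict:
    meta: dict = {}
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            key = key.strip()
            val = val.strip()
            try:
                meta[key] = float(val)
            except ValueError:
                meta[key] = val
    return meta


def read_dataset(source) -> ExperimentDataset:
    """Parse a dataset file into a validated :class:`ExperimentDataset`.

    Unknown species, non-monotone sampling times and negative
    concentrations raise :class:`DatasetFormatError` naming the offending
    row.
    """
    text = _read_text(source)
    meta = _header_meta(text)
    df = pd.read_csv(_io.StringIO(text), comment="#", dtype={"flags": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing required columns: {missing}")

    grouped: dict = {}
    controls: list[TimePoint] = []
    order: list = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # header line is 1
        sp_raw = str(row["species"]).strip()
        sp = _SPECIES_LOOKUP.get(sp_raw.lower())
        if sp is None:
            raise DatasetFormatError(
                f"row {rowno}: unknown species {sp_raw!r}"
            )
        conc = row["conc_mM_S"]
        if pd.notna(conc) and conc < 0:
            raise DatasetFormatError(
                f"row {rowno}: negative concentration {conc}"
            )
        flags = _parse_flags(row.get("flags"))
        comp = None
        if pd.notna(row["d34S_permil"]):
            frame = row["frame"] if pd.notna(row["frame"]) else "experiment-initial"
            d33cap = row["D33S_permil"] if pd.notna(row["D33S_permil"]) else math.nan
            comp = IsotopeComposition.from_capdelta(
                float(row["d34S_permil"]), d33cap, str(frame)
            )
        pool = SulfurPool(
            sp,
            float(conc) if pd.notna(conc) else 0.0,
            float(row["sd_conc_mM"]) if pd.notna(row["sd_conc_mM"]) else None,
            comp,
        )
        is_control = "control" in flags
        t = float(row["t_h"]) if pd.notna(row["t_h"]) else math.nan
        key = (flags.get("control"), True) if is_control else (t, False)
        if key not in grouped:
            grouped[key] = {
                "t": t,
                "cells": float(row["cells_per_ml"]) if pd.notna(row["cells_per_ml"]) else 0.0,
                "rsd": float(row["cells_rsd_pct"]) if pd.notna(row["cells_rsd_pct"]) else None,
                "pools": [],
                "extras": {},
            }
            order.append(key)
        grouped[key]["pools"].append(pool)
        grouped[key]["extras"].update(flags)

    points = []
    for key in order:
        g = grouped[key]
        tp = TimePoint(
            t=g["t"] if not math.isnan(g["t"]) else math.nan,
            cells=g["cells"],
            cells_rsd=g["rsd"],
            pools=tuple(g["pools"]),
            extras=g["extras"],
        )
        (controls if key[1] else points).append(tp)

    points.sort(key=lambda tp: tp.t)
    ts = [tp.t for tp in points]
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise DatasetFormatError(f"non-monotone sampling times: {ts}")

    acceptor = str(meta.get("acceptor", "sulfate"))
    initial = meta.get("initial_acceptor_S_mM")
    if initial is None:
        raise DatasetFormatError("header must state initial_acceptor_S_mM")
    return ExperimentDataset(
        acceptor=acceptor,
        donor=str(meta.get("donor", "")),
        initial_acceptor_S=float(initial),
        points=tuple(points),
        controls=tuple(controls),
        experiment_id=str(df["experiment_id"].iloc[0]),
        notes={k: v for k, v in meta.items() if k not in ("acceptor", "donor")},
    )


def write_dataset(ds: ExperimentDataset, path) -> None:
    """Write a dataset in the documented schema (read/write round-trips)."""
    lines = [
        f"# acceptor: {ds.acceptor}",
        f"# donor: {ds.donor}",
        f"# initial_acceptor_S_mM: {ds.initial_acceptor_S:g}",
    ]
    for k, v in ds.notes.items():
        if k == "initial_acceptor_S_mM":
            continue
        lines.append(f"# {k}: {v}")
    lines.append(",".join(COLUMNS))

    def fmt(x):
        if x is None:
            return ""
        if isinstance(x, float) and math.isnan(x):
            return ""
        return f"{x:g}" if isinstance(x, float) else str(x)

    def emit(tp: TimePoint, control: str | None):
        first = True
        for p in tp.pools:
            flags = dict(tp.extras) if first else {}
            if control is not None:
                flags["control"] = control
            flag_str = ";".join(
                f"{k}={fmt(v) if not isinstance(v, bool) else k}" if not isinstance(v, bool) else f"{k}={v}"
                for k, v in flags.items()
            )
            d34 = p.comp.delta34 if p.comp is not None else None
            d33cap = p.comp.capdelta33 if p.comp is not None else None
            frame = p.comp.frame if p.comp is not None else None
            lines.append(
                ",".join(
                    [
                        ds.experiment_id,
                        fmt(tp.t),
                        fmt(tp.cells),
                        fmt(tp.cells_rsd),
                        p.species,
                        fmt(p.conc),
                        fmt(p.sd_conc),
                        fmt(d34),
                        fmt(d33cap),
                        fmt(frame),
                        flag_str,
                    ]
                )
            )
            first = False

    for tp in ds.points:
        emit(tp, None)
    for tp in ds.controls:
        ctl = tp.extras.get("control", "control")
        emit(tp, str(ctl))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sim_config(source):
    """Build a :class:`~triplesulfur.synthetic.SimConfig` from a YAML file.

    Keys mirror the dataclass fields (``acceptor``, ``initial_acceptor_S``,
    ``epsilon34`` ...); ``times`` is a list of hours.  A ``scenario`` key
    names one of the canonical pathway builders and is instantiated with
    defaults.
    """
    import yaml

    from . import scenarios as _scen
    from .synthetic import SimConfig

    text = _read_text(source)
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise DatasetFormatError("simulation config must be a YAML mapping")
    if "times" in raw:
        raw["times"] = tuple(float(t) for t in raw["times"])
    if isinstance(raw.get("scenario"), str):
        name = raw["scenario"]
        builder = getattr(_scen, name, None)
        if builder is None:
            raise DatasetFormatError(f"unknown scenario {name!r}")
        raw["scenario"] = builder()
    try:
        return SimConfig(**raw)
    except TypeError as exc:
        raise DatasetFormatError(f"bad simulation config: {exc}") from exc


def read_compositions(source) -> dict:
    """Read a composition-only file (same schema, concentrations optional).

    Returns ``{(experiment_id, t_h, species): IsotopeComposition}``.
    """
    text = _read_text(source)
    df = pd.read_csv(_io.StringIO(text), comment="#", dtype={"flags": str})
    out = {}
    for idx, row in df.iterrows():
        if pd.isna(row["d34S_permil"]):
            continue
        sp = _SPECIES_LOOKUP.get(str(row["species"]).strip().lower())
        if sp is None:
            raise DatasetFormatError(
                f"row {idx + 2}: unknown species {row['species']!r}"
            )
        frame = row["frame"] if pd.notna(row["frame"]) else "experiment-initial"
        d33cap = row["D33S_permil"] if pd.notna(row["D33S_permil"]) else math.nan
        out[(str(row["experiment_id"]), float(row["t_h"]), sp)] = (
            IsotopeComposition.from_capdelta(
                float(row["d34S_permil"]), d33cap, str(frame)
            )
        )
    return out
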