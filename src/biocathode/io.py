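"""File readers and writers for the reactor analysis pipeline.

All tabular inputs are delimited text; the delimiter follows the file
extension (.csv comma, anything else tab). One YAML config binds data
files to reactors and carries the experiment-level defaults. Reports are
written twice: a machine-readable JSON with full nesting and precision,
and a flat TSV summary, both round-trippable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from biocathode.constants import SECONDS_PER_DAY
from biocathode.datatypes import (
    ELECTRON_ACCEPTORS,
    TAXONOMY_RANKS,
    AmpliconTable,
    BiofilmScore,
    CODMeasurement,
    CurrentTrace,
    MetaboliteSeries,
    QPCRResult,
    ReactorRecord,
)

_TIME_FACTORS = {"s": 1.0, "min": 60.0, "h": 3600.0, "d": SECONDS_PER_DAY}
_CURRENT_FACTORS = {"A": 1.0, "mA": 1e-3, "uA": 1e-6}


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_trace(
    path,
    area_cm2: float,
    polarity: str = "cathodic_negative",
    reactor_id: Optional[str] = None,
    time_unit: str = "s",
    current_unit: str = "A",
) -> CurrentTrace:
    """Read a chronoamperometry export: columns ``time`` and ``current``.

    Units are declared by the caller (config), not sniffed from the file.
    Rows must be in strictly increasing time order; the first offending
    row is named otherwise, and duplicate timestamps are rejected.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path))
    for col in ("time", "current"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    time_s = frame["time"].to_numpy(dtype=float) * _TIME_FACTORS[time_unit]
    current_A = frame["current"].to_numpy(dtype=float) * _CURRENT_FACTORS[current_unit]
    diffs = np.diff(time_s)
    if np.any(diffs == 0):
        idx = int(np.argmax(diffs == 0))
        raise ValueError(f"{path}: duplicate timestamp at row {idx + 2}")
    if np.any(diffs < 0):
        idx = int(np.argmax(diffs < 0))
        raise ValueError(f"{path}: time not increasing at row {idx + 2}")
    return CurrentTrace(
        reactor_id=reactor_id or path.stem,
        time_s=time_s,
        current_A=current_A,
        area_cm2=area_cm2,
        polarity_convention=polarity,
    )


def write_trace(trace: CurrentTrace, path) -> None:
    path = Path(path)
    pd.DataFrame({"time": trace.time_s, "current": trace.current_A}).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_metabolites(path, reactor_id: Optional[str] = None) -> list[MetaboliteSeries]:
    """Read a long-format table: compound, time_s, concentration_mM."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path))
    for col in ("compound", "time_s", "concentration_mM"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    rid = reactor_id or path.stem
    out = []
    for compound, grp in frame.groupby("compound", sort=False):
        grp = grp.sort_values("time_s")
        out.append(
            MetaboliteSeries(
                reactor_id=rid,
                compound_name=str(compound),
                timepoints_s=grp["time_s"].to_numpy(dtype=float),
                concentrations_mM=grp["concentration_mM"].to_numpy(dtype=float),
            )
        )
    return out


def write_metabolites(series: list[MetaboliteSeries], path) -> None:
    path = Path(path)
    rows = [
        {"compound": m.compound_name, "time_s": t, "concentration_mM": c}
        for m in series
        for t, c in zip(m.timepoints_s, m.concentrations_mM)
    ]
    pd.DataFrame(rows, columns=["compound", "time_s", "concentration_mM"]).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_cod_table(path) -> dict[str, CODMeasurement]:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path))
    return {
        str(r.reactor_id): CODMeasurement(
            reactor_id=str(r.reactor_id),
            cod_initial_gO2_per_L=float(r.cod_initial_gO2_per_L),
            cod_final_gO2_per_L=float(r.cod_final_gO2_per_L),
        )
        for r in frame.itertuples(index=False)
    }


def read_qpcr_table(path) -> dict[str, QPCRResult]:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path))
    return {
        str(r.reactor_id): QPCRResult(
            reactor_id=str(r.reactor_id),
            bacterial_copies_per_cm2=float(r.bacterial_copies_per_cm2),
            archaeal_copies_per_cm2=float(r.archaeal_copies_per_cm2),
        )
        for r in frame.itertuples(index=False)
    }


def read_biofilm_table(path) -> dict[str, BiofilmScore]:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path))
    return {
        str(r.reactor_id): BiofilmScore(reactor_id=str(r.reactor_id), score=int(r.score))
        for r in frame.itertuples(index=False)
    }


def read_amplicon(counts_path, taxonomy_path) -> AmpliconTable:
    counts_path, taxonomy_path = Path(counts_path), Path(taxonomy_path)
    counts = pd.read_csv(counts_path, sep=_sep_for(counts_path), index_col=0)
    taxonomy = pd.read_csv(
        taxonomy_path, sep=_sep_for(taxonomy_path), index_col=0, dtype=str
    )
    return AmpliconTable(counts=counts, taxonomy=taxonomy)


def write_amplicon(table: AmpliconTable, counts_path, taxonomy_path) -> None:
    counts_path, taxonomy_path = Path(counts_path), Path(taxonomy_path)
    table.counts.rename_axis("asv_id").to_csv(counts_path, sep=_sep_for(counts_path))
    table.taxonomy[list(TAXONOMY_RANKS)].rename_axis("asv_id").to_csv(
        taxonomy_path, sep=_sep_for(taxonomy_path)
    )


def read_reactor_config(path) -> tuple[list[ReactorRecord], dict[str, Any]]:
    """Parse the YAML run config into validated records plus file bindings.

    Omitted per-reactor geometry falls back to ``defaults`` and then to
    the standard H-cell values (0.25 L, 6 d, -0.6 V vs SHE). Paths in the
    returned binding dict are resolved relative to the config file.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    defaults = raw.get("defaults", {}) or {}
    base = path.parent

    def resolve(p):
        return str((base / p).resolve()) if p else None

    records: list[ReactorRecord] = []
    bindings: dict[str, Any] = {"reactors": {}, "tables": {}}
    for entry in raw.get("reactors", []):
        acceptor = entry["electron_acceptor"]
        if acceptor not in ELECTRON_ACCEPTORS:
            raise ValueError(
                f"unknown electron_acceptor {acceptor!r} for "
                f"{entry.get('reactor_id')!r}; allowed: {ELECTRON_ACCEPTORS}"
            )
        kwargs = {}
        for key in (
            "catholyte_volume_L",
            "cathode_area_cm2",
            "cathode_potential_V_SHE",
        ):
            value = entry.get(key, defaults.get(key))
            if value is not None:
                kwargs[key] = float(value)
        duration_d = entry.get("duration_d", defaults.get("duration_d"))
        if duration_d is not None:
            kwargs["duration_s"] = float(duration_d) * SECONDS_PER_DAY
        record = ReactorRecord(
            reactor_id=str(entry["reactor_id"]),
            inoculum=entry["inoculum"],
            temperature_C=float(entry["temperature_C"]),
            ph=float(entry["ph"]),
            electron_acceptor=acceptor,
            **kwargs,
        )
        records.append(record)
        bindings["reactors"][record.reactor_id] = {
            "trace": resolve(entry.get("trace")),
            "metabolites": resolve(entry.get("metabolites")),
        }
    for key, p in (raw.get("tables", {}) or {}).items():
        bindings["tables"][key] = resolve(p)
    bindings["options"] = raw.get("options", {}) or {}
    return records, bindings


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def write_report(report: dict[str, Any], outdir) -> None:
    """Write report.json (nested, full precision) and summary.tsv (flat)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, cls=_ReportEncoder)
        fh.write("\n")
    summary = pd.DataFrame(report.get("summary", []))
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)


def read_report(outdir) -> dict[str, Any]:
    with open(Path(outdir) / "report.json") as fh:
        return json.load(fh)
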