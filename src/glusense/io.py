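"""Readers and writers for the delimited-text formats the pipeline touches.

Input CSVs are comma-separated UTF-8 with a header row (tab-separated via
``delimiter="\\t"``); column names can be remapped through a layout mapping so
instrument exports need only trivial renaming. Concentrations are
canonicalized to uM internally. Result reports serialize to deterministic,
human-diffable JSON that round-trips doubles exactly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calibration import RatioMeasurement
from .isotopes import parse_formula
from .thermal import MeltCurve

logger = logging.getLogger("glusense")

_CONC_FACTORS = {"uM": 1.0, "µM": 1.0, "um": 1.0, "mM": 1e3, "M": 1e6, "nM": 1e-3}

PLATE_REQUIRED = ("well_id", "channel", "value")
PLATE_OPTIONAL = (
    "condition", "analyte_conc_uM", "replicate", "timepoint_s", "construct",
    "conc_unit", "treatment_class", "in_working_range",
)


class FormatError(ValueError):
    """A required column or structural property of an input table is missing."""


def _read_table(source, delimiter: str = ",") -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    return pd.read_csv(source, sep=delimiter)


def _apply_layout(df: pd.DataFrame, layout: Mapping[str, str] | None) -> pd.DataFrame:
    if layout:
        df = df.rename(columns={v: k for k, v in layout.items()})
    return df


def read_plate_measurements(
    source,
    layout: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[RatioMeasurement]:
    """Parse a two-channel plate table into paired ratio measurements.

    Each (well_id, replicate, timepoint) must carry exactly one F405 and one
    F488 row; the measurement ratio is F405/F488. ``layout`` maps canonical
    field names to the file's column names. Unparseable rows raise with their
    line numbers; orphan channels raise a pairing error naming the wells.
    """
    df = _apply_layout(_read_table(source, delimiter), layout)
    missing = [c for c in PLATE_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"plate table is missing required columns: {missing}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    if "timepoint_s" not in df.columns:
        df["timepoint_s"] = np.nan
    if "condition" not in df.columns:
        df["condition"] = ""
    if "construct" not in df.columns:
        df["construct"] = "sensor"
    bad = df.index[~(df["value"] > 0)].tolist()
    if bad:
        lines = [i + 2 for i in bad]  # 1-based + header
        raise ValueError(f"non-positive fluorescence values at lines {lines}")
    if "conc_unit" in df.columns and "analyte_conc_uM" in df.columns:
        factors = df["conc_unit"].map(_CONC_FACTORS)
        if factors.isna().any():
            raise FormatError(
                f"unknown concentration units: "
                f"{sorted(df.loc[factors.isna(), 'conc_unit'].unique())}"
            )
        df["analyte_conc_uM"] = df["analyte_conc_uM"] * factors

    keys = ["well_id", "replicate", "timepoint_s", "construct"]
    measurements: list[RatioMeasurement] = []
    orphans: list[str] = []
    grouped = df.groupby(keys, dropna=False, sort=True)
    for (well, rep, tp, construct), grp in grouped:
        channels = grp.set_index("channel")["value"]
        if channels.index.duplicated().any():
            raise ValueError(
                f"duplicate channel rows for well {well!r} "
                f"(replicate {rep}, timepoint {tp})"
            )
        if "F405" not in channels.index or "F488" not in channels.index:
            orphans.append(str(well))
            continue
        f405, f488 = float(channels["F405"]), float(channels["F488"])
        conc = (
            float(grp["analyte_conc_uM"].iloc[0])
            if "analyte_conc_uM" in grp.columns
            and pd.notna(grp["analyte_conc_uM"].iloc[0])
            else None
        )
        measurements.append(
            RatioMeasurement(
                ratio_R=f405 / f488,
                F405=f405,
                F488=f488,
                condition=str(grp["condition"].iloc[0]),
                analyte_conc_uM=conc,
                replicate=int(rep),
                timepoint_s=None if pd.isna(tp) else float(tp),
                well_id=str(well),
            )
        )
    if orphans:
        raise ValueError(
            f"unpaired channel rows (missing F405 or F488) for wells: "
            f"{sorted(set(orphans))}"
        )
    return measurements


def plate_to_frame(measurements: Sequence[RatioMeasurement]) -> pd.DataFrame:
    """Two-channel plate table from ratio measurements (writer counterpart)."""
    rows = []
    for m in measurements:
        base = {
            "well_id": m.well_id,
            "condition": m.condition,
            "analyte_conc_uM": m.analyte_conc_uM,
            "replicate": m.replicate,
            "timepoint_s": m.timepoint_s,
            "construct": "sensor",
        }
        rows.append({**base, "channel": "F405", "value": m.F405})
        rows.append({**base, "channel": "F488", "value": m.F488})
    return pd.DataFrame(rows)


def read_melt_curve_table(
    source, layout: Mapping[str, str] | None = None, delimiter: str = ","
) -> list[MeltCurve]:
    """Parse a melt-curve export into per-sample curves, sorted by temperature."""
    df = _apply_layout(_read_table(source, delimiter), layout)
    required = ["sample_id", "ligand", "ligand_conc", "temperature_C", "fluorescence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"melt-curve table is missing columns: {missing}")
    curves = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        grp = grp.sort_values("temperature_C")
        temps = grp["temperature_C"].to_numpy(dtype=float)
        if np.any(np.diff(temps) == 0):
            raise ValueError(f"duplicate temperatures in sample {sample_id!r}")
        if len(grp) < 10:
            raise ValueError(
                f"melt curve {sample_id!r} has only {len(grp)} points; need >= 10"
            )
        curves.append(
            MeltCurve(
                sample_id=str(sample_id),
                temperature_C=temps,
                fluorescence=grp["fluorescence"].to_numpy(dtype=float),
                ligand="" if pd.isna(grp["ligand"].iloc[0]) else str(grp["ligand"].iloc[0]),
                ligand_conc_uM=float(grp["ligand_conc"].iloc[0]),
            )
        )
    return curves


@dataclass
class RawIsotopologueRecord:
    """Dense peak-area vector for one (strain, metabolite, replicate)."""

    strain: str
    metabolite: str
    fragment_formula: str
    replicate: int
    areas: np.ndarray


def read_isotopologue_table(
    source,
    layout: Mapping[str, str] | None = None,
    delimiter: str = ",",
    extra_mass_allowance: int = 8,
) -> list[RawIsotopologueRecord]:
    """Parse a GC-MS isotopologue table into dense per-sample area vectors.

    Missing mass shifts are filled with zero; a mass shift beyond the
    fragment's carbon count plus ``extra_mass_allowance`` triggers a warning
    but the row is retained. An absent replicate column defaults to 1 with a
    logged warning.
    """
    df = _apply_layout(_read_table(source, delimiter), layout)
    required = ["strain", "metabolite", "fragment_formula", "mass_shift", "peak_area"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"isotopologue table is missing columns: {missing}")
    if "replicate" not in df.columns:
        logger.warning("no replicate column; treating all rows as replicate 1")
        df["replicate"] = 1
    if (df["peak_area"] < 0).any():
        raise ValueError("negative peak areas are not valid")
    records = []
    for (strain, metabolite, formula, rep), grp in df.groupby(
        ["strain", "metabolite", "fragment_formula", "replicate"], sort=True
    ):
        counts = parse_formula(str(formula))
        limit = counts.get("C", 0) + extra_mass_allowance
        over = grp["mass_shift"] > limit
        if over.any():
            warnings.warn(
                f"{strain}/{metabolite}: mass shifts beyond C-count + "
                f"{extra_mass_allowance} retained "
                f"(max {int(grp['mass_shift'].max())})",
                stacklevel=2,
            )
        shifts = grp["mass_shift"].to_numpy(dtype=int)
        if len(np.unique(shifts)) != len(shifts):
            raise ValueError(
                f"duplicate mass shifts for {strain}/{metabolite} rep {rep}"
            )
        dense = np.zeros(int(shifts.max()) + 1)
        dense[shifts] = grp["peak_area"].to_numpy(dtype=float)
        records.append(
            RawIsotopologueRecord(
                strain=str(strain),
                metabolite=str(metabolite),
                fragment_formula=str(formula),
                replicate=int(rep),
                areas=dense,
            )
        )
    return records


# -- result reports ----------------------------------------------------------


@dataclass
class ResultReport:
    """One analysis result with units and provenance."""

    analysis_kind: str
    parameters: dict[str, dict] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, entry in self.parameters.items():
            if not isinstance(entry, Mapping) or "unit" not in entry:
                raise ValueError(f"parameter {name!r} must carry a unit string")
        for key in ("config_digest", "seed", "software_version"):
            if key not in self.provenance or self.provenance[key] in ("", None):
                raise ValueError(f"provenance field {key!r} must be non-empty")


def make_provenance(config_digest: str, seed: int) -> dict:
    return {
        "config_digest": config_digest,
        "seed": int(seed),
        "software_version": __version__,
    }


def _jsonify(obj):
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_report(results: Sequence[ResultReport] | ResultReport, dest) -> None:
    """Serialize reports to deterministic JSON (sorted keys, exact doubles)."""
    if isinstance(results, ResultReport):
        results = [results]
    payload = {
        "report_version": 1,
        "analyses": [
            {
                "analysis_kind": r.analysis_kind,
                "parameters": r.parameters,
                "diagnostics": r.diagnostics,
                "provenance": r.provenance,
            }
            for r in results
        ],
    }
    text = json.dumps(payload, sort_keys=True, indent=2, default=_jsonify)
    Path(dest).write_text(text + "\n", encoding="utf-8")


def read_report(path) -> list[ResultReport]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        ResultReport(
            analysis_kind=a["analysis_kind"],
            parameters=a["parameters"],
            diagnostics=a["diagnostics"],
            provenance=a["provenance"],
        )
        for a in payload["analyses"]
    ]
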