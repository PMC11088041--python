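"""Tabular input/output for the documented TSV/CSV schemas.

Schemas (tab- or comma-separated, inferred from the file suffix):

``competitions``
    replicate_id, condition, test_initial, ref_initial, test_final,
    ref_final [, strain, passage, density_initial, density_final,
    inoculum_volume, culture_volume].  Counts in [0, 1] across all four
    competitor columns of a row are treated as proportions and scaled by
    a stated total (default 10,000 events).

``plate``
    wide plate-reader export: first column time (h or min), remaining
    columns one OD600 series per well; paired with a plate map
    (well, strain, condition, replicate).

``cfu``
    strain, cfu_treated, cfu_control [, dilution_treated,
    dilution_control, plated_volume].

``fluorescence``
    strain, timepoint, condition, replicate, median_intensity.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .biosensor import FluorescenceMeasurement
from .competition import (
    CompetitionObservation,
    DoublingRecord,
    SerialTransferSeries,
    SurvivalAssay,
)
from .growth import GrowthCurve

__all__ = [
    "read_table",
    "competition_observations",
    "serial_transfer_series",
    "read_plate",
    "read_survival_assays",
    "read_fluorescence",
]

COMPETITION_REQUIRED = ["replicate_id", "condition", "test_initial", "ref_initial", "test_final", "ref_final"]
DOUBLING_COLUMNS = ["density_initial", "density_final", "inoculum_volume", "culture_volume"]


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV by suffix (.tsv/.txt tab, anything else comma)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def _observation_from_row(row: pd.Series, events: float) -> CompetitionObservation:
    vals = [float(row[c]) for c in ("test_initial", "ref_initial", "test_final", "ref_final")]
    if all(0 <= v <= 1 for v in vals):
        vals = [v * events for v in vals]
    return CompetitionObservation(
        test_initial=vals[0],
        ref_initial=vals[1],
        test_final=vals[2],
        ref_final=vals[3],
        condition=str(row.get("condition", "")),
        replicate_id=str(row.get("replicate_id", "")),
    )


def competition_observations(
    df: pd.DataFrame, *, events: float = 10_000
) -> list[tuple[str, CompetitionObservation]]:
    """(strain, observation) pairs from a competitions table."""
    missing = [c for c in COMPETITION_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"competitions table is missing column(s): {missing}")
    out = []
    for _, row in df.iterrows():
        strain = str(row.get("strain", row["replicate_id"]))
        out.append((strain, _observation_from_row(row, events)))
    return out


def serial_transfer_series(
    df: pd.DataFrame, *, events: float = 10_000
) -> dict[tuple[str, str], SerialTransferSeries]:
    """Group a transfers table into one series per (strain, condition).

    Requires the doubling columns and a ``passage`` column ordering the
    transfers within each series.
    """
    needed = COMPETITION_REQUIRED + DOUBLING_COLUMNS + ["passage"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"transfers table is missing column(s): {missing}")
    strain_col = "strain" if "strain" in df.columns else "replicate_id"
    series: dict[tuple[str, str], SerialTransferSeries] = {}
    for (strain, condition), group in df.groupby([strain_col, "condition"], sort=False):
        group = group.sort_values("passage")
        passages = []
        for _, row in group.iterrows():
            obs = _observation_from_row(row, events)
            rec = DoublingRecord(
                density_initial=float(row["density_initial"]),
                density_final=float(row["density_final"]),
                inoculum_volume=float(row["inoculum_volume"]),
                culture_volume=float(row["culture_volume"]),
            )
            passages.append((obs, rec))
        series[(str(strain), str(condition))] = SerialTransferSeries(
            passages=tuple(passages), strain_label=str(strain), condition=str(condition)
        )
    return series


def read_plate(
    plate_path: str | Path,
    map_path: str | Path | None = None,
    *,
    time_unit: str = "h",
) -> list[GrowthCurve]:
    """Growth curves from a wide plate-reader table plus an optional map.

    The first column is time (``time_unit`` "h" or "min"); every other
    column is a well.  The plate map assigns well -> strain, condition,
    replicate; unmapped wells keep the well name as strain label.
    """
    df = read_table(plate_path)
    time = df.iloc[:, 0].astype(float).to_numpy()
    if time_unit == "min":
        time = time / 60.0
    elif time_unit != "h":
        raise ValueError("time_unit must be 'h' or 'min'")
    mapping: dict[str, tuple[str, str, str]] = {}
    if map_path is not None:
        mdf = read_table(map_path)
        for c in ("well", "strain", "condition", "replicate"):
            if c not in mdf.columns:
                raise ValueError(f"plate map is missing column {c!r}")
        for _, row in mdf.iterrows():
            mapping[str(row["well"])] = (str(row["strain"]), str(row["condition"]), str(row["replicate"]))
    curves = []
    for well in df.columns[1:]:
        strain, condition, replicate = mapping.get(str(well), (str(well), "", str(well)))
        curves.append(
            GrowthCurve(
                times=tuple(time.tolist()),
                od600=tuple(df[well].astype(float).tolist()),
                strain_label=strain,
                condition=condition,
                replicate_id=replicate,
            )
        )
    return curves


def read_survival_assays(path: str | Path) -> list[tuple[str, SurvivalAssay]]:
    """(strain, assay) pairs from a CFU table."""
    df = read_table(path)
    for c in ("strain", "cfu_treated", "cfu_control"):
        if c not in df.columns:
            raise ValueError(f"CFU table is missing column {c!r}")
    out = []
    for _, row in df.iterrows():
        out.append(
            (
                str(row["strain"]),
                SurvivalAssay(
                    cfu_treated=float(row["cfu_treated"]),
                    cfu_control=float(row["cfu_control"]),
                    dilution_treated=float(row.get("dilution_treated", 1e-5)),
                    dilution_control=float(row.get("dilution_control", 1e-5)),
                    plated_volume=float(row.get("plated_volume", 1.0)),
                ),
            )
        )
    return out


def read_fluorescence(path: str | Path) -> list[FluorescenceMeasurement]:
    """Fluorescence measurements from a tidy median-intensity table."""
    df = read_table(path)
    for c in ("strain", "timepoint", "condition", "median_intensity"):
        if c not in df.columns:
            raise ValueError(f"fluorescence table is missing column {c!r}")
    return [
        FluorescenceMeasurement(
            strain_label=str(row["strain"]),
            timepoint=str(row["timepoint"]),
            condition=str(row["condition"]),
            median_intensity=float(row["median_intensity"]),
            replicate_id=str(row.get("replicate", "")),
        )
        for _, row in df.iterrows()
    ]
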