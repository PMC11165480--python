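"""Tidy CSV dialects shared by the CLI and the library.

All files are comma-delimited UTF-8 with "." as the decimal separator;
floats are written with 12 significant digits so write -> read round
trips are lossless at that precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import DataError
from .kinetics import KineticPanel, VelocityDataset
from .pathway import VariantRatioTable

FLOAT_FORMAT = "%.12g"

VELOCITY_COLUMNS = ("variant", "substrate", "substrate_conc_mM", "velocity", "replicate")
PANEL_COLUMNS = ("variant", "substrate", "kcat_km", "sd", "measured")
RATIO_COLUMNS = ("variant", "substrate", "vmax_ratio", "km_ratio", "provenance")


def _read_csv(path, required: tuple[str, ...], kind: str) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise DataError(f"cannot read {kind} CSV {path}: {exc}") from exc
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed {kind} CSV {path}: {exc}") from exc
    missing = set(required) - set(frame.columns)
    if missing:
        raise DataError(f"{kind} CSV {path} missing columns {sorted(missing)}")
    return frame


def read_velocity_csv(path) -> list[VelocityDataset]:
    """Read a tidy velocity CSV into one dataset per (variant, substrate)."""
    frame = _read_csv(path, VELOCITY_COLUMNS, "velocity")
    datasets = []
    for (_, _), group in frame.groupby(["variant", "substrate"], sort=True):
        datasets.append(VelocityDataset.from_frame(group.reset_index(drop=True)))
    if not datasets:
        raise DataError(f"velocity CSV {path} contains no rows")
    return datasets


def write_velocity_csv(datasets, path) -> None:
    frame = pd.concat([d.to_frame() for d in datasets], ignore_index=True)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_panel_csv(path) -> KineticPanel:
    return KineticPanel(_read_csv(path, PANEL_COLUMNS, "panel"))


def write_panel_csv(panel: KineticPanel, path) -> None:
    panel.frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_ratio_csv(path) -> VariantRatioTable:
    return VariantRatioTable(_read_csv(path, RATIO_COLUMNS, "ratio"))


def write_ratio_csv(table: VariantRatioTable, path) -> None:
    table.frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_report_csv(report: pd.DataFrame, path) -> None:
    cols = ["variant", "substrate", "reference", "measured", "ratio", "excess", "percent_change"]
    report[cols].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_summary_csv(summaries: pd.DataFrame, path) -> None:
    summaries.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_trajectory_csv(trajectories, path) -> None:
    frame = pd.concat([t.to_frame() for t in trajectories], ignore_index=True)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_provenance(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
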