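"""Delimited-text readers and writers for every table the package exchanges.

All files are comma-separated UTF-8 with '.' decimal separators and a header
row.  Schemas:

* trajectory table   — ``cell_id,time_min,x_um,y_um``, one row per cell per frame
* count table        — ``condition,device_id,motile_count``
* CT table           — ``condition,gene,replicate,ct``
* group table        — ``group,value`` (long-form input for the statistics)
* profile table      — ``position_cm,time_h,concentration,normalized_concentration``
* compartment table  — ``time_h,source_concentration,sink_concentration``

Reading a trajectory table enforces the tracking convention: rows are
time-sorted per cell and cells whose first frame is after t = 0 are dropped
(with a logged count) — they may have appeared by proliferation or drift
into the field of view and would bias the cohort.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError
from .migration import ConditionDataset, Trajectory
from .transport import ConcentrationProfile

logger = logging.getLogger("gradlab")

TRAJECTORY_COLUMNS = ("cell_id", "time_min", "x_um", "y_um")
COUNT_COLUMNS = ("condition", "device_id", "motile_count")
CT_COLUMNS = ("condition", "gene", "replicate", "ct")
GROUP_COLUMNS = ("group", "value")


def _read_table(path: str | Path, columns: tuple[str, ...],
                numeric: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    table = pd.read_csv(path)
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise DataError(f"{path}: missing columns {', '.join(missing)}")
    for col in numeric:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[values.isna() & table[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise DataError(f"{path}: non-numeric {col!r} at line {bad[0] + 2}")
        if table[col].isna().any():
            raise DataError(
                f"{path}: empty {col!r} at line {table.index[table[col].isna()][0] + 2}"
            )
        table[col] = values
    return table


def read_trajectories(path: str | Path) -> list[Trajectory]:
    """Load a trajectory table, applying the present-at-t0 tracking rule."""
    table = _read_table(path, TRAJECTORY_COLUMNS, ("time_min", "x_um", "y_um"))
    trajectories, dropped = [], 0
    for cell_id, rows in table.groupby("cell_id", sort=False):
        rows = rows.sort_values("time_min")
        if rows["time_min"].iloc[0] != 0:
            dropped += 1
            continue
        trajectories.append(
            Trajectory(
                cell_id=str(cell_id),
                times_min=rows["time_min"].to_numpy(),
                positions_um=rows[["x_um", "y_um"]].to_numpy(),
            )
        )
    if dropped:
        logger.info("%s: dropped %d cell(s) not present at t=0", path, dropped)
    return trajectories


def write_trajectories(path: str | Path, trajectories: list[Trajectory]) -> None:
    rows = [
        {"cell_id": t.cell_id, "time_min": tm, "x_um": x, "y_um": y}
        for t in trajectories
        for tm, (x, y) in zip(t.times_min, t.positions_um)
    ]
    pd.DataFrame(rows, columns=list(TRAJECTORY_COLUMNS)).to_csv(path, index=False)


def read_counts(path: str | Path) -> dict[str, ConditionDataset]:
    """Load a transwell count table as one dataset per condition."""
    table = _read_table(path, COUNT_COLUMNS, ("motile_count",))
    return {
        str(cond): ConditionDataset(
            condition=str(cond), platform="ta",
            device_counts=rows["motile_count"].tolist(),
        )
        for cond, rows in table.groupby("condition", sort=False)
    }


def write_counts(path: str | Path, datasets: list[ConditionDataset]) -> None:
    rows = [
        {"condition": d.condition, "device_id": f"{d.condition}_dev{i + 1}",
         "motile_count": c}
        for d in datasets
        for i, c in enumerate(d.device_counts)
    ]
    pd.DataFrame(rows, columns=list(COUNT_COLUMNS)).to_csv(path, index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    return _read_table(path, CT_COLUMNS, ("ct",))


def write_ct_table(path: str | Path, table: pd.DataFrame) -> None:
    table[list(CT_COLUMNS)].to_csv(path, index=False)


def read_groups(path: str | Path) -> dict[str, np.ndarray]:
    """Load a long-form group/value table for the comparison procedure."""
    table = _read_table(path, GROUP_COLUMNS, ("value",))
    return {
        str(g): rows["value"].to_numpy()
        for g, rows in table.groupby("group", sort=False)
    }


def write_groups(path: str | Path, groups: dict[str, np.ndarray]) -> None:
    rows = [{"group": g, "value": v} for g, values in groups.items() for v in values]
    pd.DataFrame(rows, columns=list(GROUP_COLUMNS)).to_csv(path, index=False)


def write_profile(
    profile_path: str | Path,
    compartment_path: str | Path,
    profile: ConcentrationProfile,
) -> None:
    """Write a concentration profile in long form plus compartment courses."""
    x, t = profile.positions_cm, profile.times_h
    xx, tt = np.meshgrid(x, t, indexing="ij")
    pd.DataFrame(
        {
            "position_cm": xx.ravel(),
            "time_h": tt.ravel(),
            "concentration": profile.concentration.ravel(),
            "normalized_concentration": profile.normalized.ravel(),
        }
    ).to_csv(profile_path, index=False)
    pd.DataFrame(
        {
            "time_h": t,
            "source_concentration": profile.source_concentration,
            "sink_concentration": profile.sink_concentration,
        }
    ).to_csv(compartment_path, index=False)
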