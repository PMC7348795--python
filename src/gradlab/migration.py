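"""Cell-migration quantification from trajectories and motile-cell counts.

Trajectories come from time-lapse imaging of cells in the microfluidic
gradient device: every tracked cell is imaged at 30-min intervals over 6 h
(13 frames, 12 intervals), and only cells already present at t = 0 are
tracked, so that proliferation over the recording does not inflate the
cohort.  Transwell assays yield only a per-device count of cells that
crossed the membrane.

The central statistic is the path length

    PL = sum_i sqrt((x_{i+1}-x_i)^2 + (y_{i+1}-y_i)^2),

the accumulated distance over consecutive frames; a cell is called motile
when its movement exceeds 20 µm (about two cell diameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import UsageError

MOTILITY_THRESHOLD_UM = 20.0
FULL_TRACK_FRAMES = 13  # 6 h at 30-min intervals, frame 0 included


@dataclass
class Trajectory:
    """One cell's sampled (x, y) positions over the assay.

    times_min are minutes from the start of imaging and must begin at 0:
    cells first seen later are excluded upstream.  Positions are µm in the
    image frame, +x along the gradient axis toward the source.
    """

    cell_id: str
    times_min: np.ndarray
    positions_um: np.ndarray  # shape (n_frames, 2)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.times_min.ndim != 1 or self.positions_um.shape != (self.times_min.size, 2):
            raise UsageError(f"cell {self.cell_id!r}: positions must be (n, 2) matching times")
        if self.times_min.size < 2:
            raise UsageError(f"cell {self.cell_id!r}: a trajectory needs >= 2 time points")
        if np.any(np.diff(self.times_min) <= 0):
            raise UsageError(f"cell {self.cell_id!r}: times must be strictly increasing")
        if self.times_min[0] != 0:
            raise UsageError(
                f"cell {self.cell_id!r}: first frame at t={self.times_min[0]:g} min; "
                "only cells present at t=0 are tracked"
            )

    @property
    def complete(self) -> bool:
        """True when the track spans the full 13-frame recording."""
        return self.times_min.size >= FULL_TRACK_FRAMES

    @property
    def n_intervals(self) -> int:
        return self.times_min.size - 1


@dataclass
class ConditionDataset:
    """All observations for one experimental condition on one platform.

    platform "gll" carries trajectories; platform "ta" (transwell assay)
    carries per-device motile-cell counts.
    """

    condition: str
    platform: str
    trajectories: list[Trajectory] = field(default_factory=list)
    device_counts: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.platform not in ("gll", "ta"):
            raise UsageError(f"platform must be 'gll' or 'ta', got {self.platform!r}")

    @property
    def n(self) -> int:
        return len(self.trajectories) if self.platform == "gll" else len(self.device_counts)


@dataclass
class MigrationSummary:
    """Per-condition migration statistics."""

    condition: str
    platform: str
    n: int
    mean_path_length_um: float = math.nan
    sd_path_length_um: float = math.nan
    motile_fraction_pct: float = math.nan
    mean_net_displacement_um: float = math.nan
    mean_count: float = math.nan
    sd_count: float = math.nan
    fold_change_vs_control: float = math.nan
    motile_only: bool = False
    degenerate: bool = False


def path_length(traj: Trajectory) -> float:
    """Accumulated distance: sum of Euclidean steps between consecutive frames."""
    steps = np.diff(traj.positions_um, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def net_displacement(traj: Trajectory) -> float:
    """Euclidean distance between the first and last position."""
    delta = traj.positions_um[-1] - traj.positions_um[0]
    return float(np.hypot(delta[0], delta[1]))


def classify_motile(
    traj: Trajectory,
    threshold_um: float = MOTILITY_THRESHOLD_UM,
    use_net_displacement: bool = False,
) -> bool:
    """True iff the cell moved strictly more than the threshold.

    Movement is the path length by default ("greater than 20 µm"); setting
    `use_net_displacement` thresholds the start-to-end displacement instead,
    for sensitivity analysis.
    """
    moved = net_displacement(traj) if use_net_displacement else path_length(traj)
    return moved > threshold_um


def motile_fraction(
    data: ConditionDataset, threshold_um: float = MOTILITY_THRESHOLD_UM
) -> float:
    """Percentage of tracked cells classified motile."""
    if data.platform != "gll":
        raise UsageError("motile_fraction applies to trajectory (gll) datasets")
    if not data.trajectories:
        raise UsageError(f"condition {data.condition!r}: empty dataset")
    motile = sum(classify_motile(t, threshold_um) for t in data.trajectories)
    return 100.0 * motile / len(data.trajectories)


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    # sample SD (n-1 denominator); undefined for a single observation
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return mean, sd


def summarize_condition(
    data: ConditionDataset,
    motile_only: bool = True,
    threshold_um: float = MOTILITY_THRESHOLD_UM,
) -> MigrationSummary:
    """Mean ± SD path length, motile fraction and net displacement for a cohort.

    With `motile_only` (the reporting convention for per-condition path
    lengths) the path-length statistics are restricted to motile cells; the
    motile fraction is always over all tracked cells.  If no cell is motile
    under `motile_only`, the summary is returned with NaN means and the
    `degenerate` flag set.
    """
    if data.platform != "gll":
        raise UsageError("summarize_condition applies to trajectory (gll) datasets")
    if not data.trajectories:
        raise UsageError(f"condition {data.condition!r}: empty dataset")
    pls = np.array([path_length(t) for t in data.trajectories])
    nds = np.array([net_displacement(t) for t in data.trajectories])
    fraction = 100.0 * np.count_nonzero(pls > threshold_um) / pls.size
    subset = pls[pls > threshold_um] if motile_only else pls
    if subset.size == 0:
        return MigrationSummary(
            condition=data.condition, platform="gll", n=pls.size,
            motile_fraction_pct=fraction, mean_net_displacement_um=float(nds.mean()),
            motile_only=motile_only, degenerate=True,
        )
    mean_pl, sd_pl = _mean_sd(subset)
    return MigrationSummary(
        condition=data.condition, platform="gll", n=pls.size,
        mean_path_length_um=mean_pl, sd_path_length_um=sd_pl,
        motile_fraction_pct=fraction, mean_net_displacement_um=float(nds.mean()),
        motile_only=motile_only,
    )


def transwell_summary(
    data: ConditionDataset, control: ConditionDataset | None = None
) -> MigrationSummary:
    """Mean ± SD of per-device motile counts, plus fold change vs control.

    Fold change = condition mean count / control mean count; undefined (NaN,
    `degenerate` flag) when the control mean is zero.  A single device
    yields an undefined SD, also flagged.
    """
    if data.platform != "ta":
        raise UsageError("transwell_summary applies to count (ta) datasets")
    if not data.device_counts:
        raise UsageError(f"condition {data.condition!r}: no device counts")
    counts = np.asarray(data.device_counts, dtype=float)
    mean, sd = _mean_sd(counts)
    summary = MigrationSummary(
        condition=data.condition, platform="ta", n=counts.size,
        mean_count=mean, sd_count=sd if counts.size > 1 else math.nan,
        degenerate=counts.size == 1,
    )
    if control is not None:
        control_counts = np.asarray(control.device_counts, dtype=float)
        if control_counts.size == 0 or control_counts.mean() == 0:
            summary.degenerate = True
        else:
            summary.fold_change_vs_control = mean / float(control_counts.mean())
    return summary
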