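"""Seeded synthetic data with the statistical structure the analyses expect.

No raw recordings are deposited with the study this package models, so the
generator stands in for them:

* **Trajectories** — a biased random walk sampled at the imaging cadence
  (30-min steps, 12 intervals).  Each step is a constant drift along the
  gradient axis plus isotropic Gaussian noise, so the per-step length is
  Rice-distributed and the path-length moments are closed-form.  Because
  iid Rice steps bound the path-length coefficient of variation by
  sqrt((4/pi - 1)/n_steps) (~0.15 at 12 steps), while measured cohorts are
  more dispersed, a per-cell gamma speed multiplier (mean 1) supplies the
  across-cell variance the homogeneous family cannot reach.
* **CT tables** — constructed so that the delta-delta-CT analysis recovers a
  chosen fold-change matrix exactly (noise-free) or in expectation (with
  Gaussian CT noise).
* **Transwell counts** — per-device motile-cell counts, rounded truncated
  Gaussians.

Everything is driven by an explicit integer seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .exceptions import CalibrationError, UsageError
from .migration import ConditionDataset, Trajectory
from .transport import ConcentrationProfile, sample_field

_RAYLEIGH_MEAN = math.sqrt(math.pi / 2.0)
# max CV² of a Rice step length, attained by the pure Rayleigh (zero-drift) walk
_MAX_STEP_CV2 = 4.0 / math.pi - 1.0


@dataclass
class GradientCoupling:
    """Chemotactic coupling of the walk to a simulated concentration field.

    The per-step drift along +x (toward the source) becomes
    sensitivity × (−dC/dx_channel) at the cell's current channel position,
    i.e. proportional to the local steepness of the gradient the cell
    climbs.  `origin_channel_cm` maps image x = 0 onto the channel axis
    (default 1.2 cm, near the sink where cells are seeded); image +x runs
    toward the source, so the channel coordinate decreases as cells advance.
    """

    profile: ConcentrationProfile
    sensitivity: float  # µm/step per (ng/mL/cm)
    origin_channel_cm: float = 1.2
    start_time_h: float = 0.0

    def drift_um(self, image_x_um: float, elapsed_min: float) -> float:
        x_chan = self.origin_channel_cm - image_x_um * 1e-4
        x_chan = float(np.clip(x_chan, self.profile.positions_cm[0],
                               self.profile.positions_cm[-1]))
        t = float(np.clip(self.start_time_h + elapsed_min / 60.0,
                          self.profile.times_h[0], self.profile.times_h[-1]))
        _, grad = sample_field(self.profile, x_chan, t)
        return self.sensitivity * (-grad)


@dataclass
class WalkParams:
    """Biased-random-walk cohort parameters.

    drift_um is the mean displacement per 30-min step along +x; step_sd_um
    the isotropic Gaussian noise SD per axis per step.  speed_dispersion is
    the SD of the per-cell gamma speed multiplier (mean 1) scaling both;
    0 gives a homogeneous cohort.
    """

    n_cells: int = 15
    n_steps: int = 12
    dt_min: float = 30.0
    drift_um: float = 0.0
    step_sd_um: float = 5.0
    seed: int = 0
    speed_dispersion: float = 0.0
    condition: str = "synthetic"
    start_window_um: tuple[float, float, float, float] = (0.0, 0.0, 500.0, 500.0)
    gradient_coupling: GradientCoupling | None = None

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.n_cells < 1:
            raise UsageError("n_cells and n_steps must be >= 1")
        if self.step_sd_um < 0 or self.speed_dispersion < 0 or self.dt_min <= 0:
            raise UsageError("step_sd_um, speed_dispersion >= 0 and dt_min > 0 required")


def simulate_cohort(params: WalkParams) -> ConditionDataset:
    """Generate a cohort of trajectories, fully determined by the seed."""
    rng = np.random.default_rng(params.seed)
    x0, y0, x1, y1 = params.start_window_um
    starts = np.column_stack(
        [rng.uniform(x0, x1, params.n_cells), rng.uniform(y0, y1, params.n_cells)]
    )
    if params.speed_dispersion > 0:
        shape = 1.0 / params.speed_dispersion**2
        speeds = rng.gamma(shape, scale=params.speed_dispersion**2, size=params.n_cells)
    else:
        speeds = np.ones(params.n_cells)
    times = np.arange(params.n_steps + 1) * params.dt_min
    trajectories = []
    for i in range(params.n_cells):
        pos = np.empty((params.n_steps + 1, 2))
        pos[0] = starts[i]
        for j in range(params.n_steps):
            drift = params.drift_um
            if params.gradient_coupling is not None:
                drift = drift + params.gradient_coupling.drift_um(
                    pos[j, 0], times[j]
                )
            noise = rng.normal(0.0, params.step_sd_um, size=2)
            pos[j + 1] = pos[j] + speeds[i] * (np.array([drift, 0.0]) + noise)
        trajectories.append(
            Trajectory(cell_id=f"{params.condition}_{i:03d}", times_min=times,
                       positions_um=pos)
        )
    return ConditionDataset(
        condition=params.condition, platform="gll", trajectories=trajectories
    )


def _rice_mean_unit(k: float) -> float:
    """Mean step length of a Rice(nu=k, sigma=1) variable.

    Large drift-to-noise ratios overflow the Laguerre form, so beyond k=30
    the asymptotic sqrt(k^2+1) (relative error < 1e-6 there) is used.
    """
    if k == 0.0:
        return _RAYLEIGH_MEAN
    if k > 30.0:
        return math.sqrt(k * k + 1.0)
    return float(sps.rice.mean(k))


def _homogeneous_ratio(k: float) -> float:
    """m^2 / E[r^2] for a Rice step with drift-to-noise ratio k.

    Monotone increasing from pi/4 (k=0, pure Rayleigh) toward 1 (pure
    drift); the reachable per-step mean²/(mean²+var) ratios of the family.
    """
    return _rice_mean_unit(k) ** 2 / (2.0 + k * k)


def calibrate_walk(
    target_mean_pl: float,
    target_sd_pl: float,
    n_steps: int = 12,
    drift_to_noise: float = 1.0,
    allow_heterogeneity: bool = True,
    **extra,
) -> WalkParams:
    """Solve walk parameters whose cohort path-length moments hit a target.

    The per-step length of a homogeneous walk is Rice(drift, step_sd); the
    cohort path length (sum of n iid steps) then has mean n·E[r] and
    variance n·Var[r].  The drift-to-noise ratio k is found by root-finding
    on the Rice moment ratio.  When the target SD exceeds what iid Rice
    steps can produce (CV > sqrt((4/pi−1)/n)), the surplus variance is
    assigned to a per-cell gamma speed multiplier with the within-cell
    ratio fixed at `drift_to_noise`; with `allow_heterogeneity=False` such
    targets raise CalibrationError stating the feasible bound.

    Extra keyword arguments (n_cells, seed, condition...) pass through to
    the returned WalkParams.
    """
    if target_mean_pl <= 0 or target_sd_pl < 0:
        raise UsageError("target mean must be > 0 and target SD >= 0")
    m1 = target_mean_pl / n_steps
    if target_sd_pl == 0.0:
        return WalkParams(n_steps=n_steps, drift_um=m1, step_sd_um=0.0, **extra)
    v1_target = target_sd_pl**2 / n_steps
    ratio = m1**2 / (m1**2 + v1_target)
    if ratio >= math.pi / 4.0:
        k = optimize.brentq(lambda kk: _homogeneous_ratio(kk) - ratio, 0.0, 1e4)
        sigma = m1 / _rice_mean_unit(k)
        return WalkParams(
            n_steps=n_steps, drift_um=k * sigma, step_sd_um=sigma, **extra
        )
    if not allow_heterogeneity:
        bound = target_mean_pl * math.sqrt(_MAX_STEP_CV2 / n_steps)
        raise CalibrationError(
            f"target SD {target_sd_pl:g} µm exceeds the iid-Rice bound "
            f"{bound:.3g} µm for mean {target_mean_pl:g} µm at {n_steps} steps"
        )
    k = drift_to_noise
    sigma = m1 / _rice_mean_unit(k)
    v1 = sigma**2 * (2.0 + k * k) - m1**2
    n = n_steps
    tau2 = (target_sd_pl**2 - n * v1) / (n * v1 + n**2 * m1**2)
    return WalkParams(
        n_steps=n_steps, drift_um=k * sigma, step_sd_um=sigma,
        speed_dispersion=math.sqrt(tau2), **extra,
    )


def expected_path_length_moments(params: WalkParams) -> tuple[float, float]:
    """Closed-form cohort path-length mean and SD implied by WalkParams."""
    n = params.n_steps
    if params.step_sd_um == 0.0:
        m1, v1 = params.drift_um, 0.0
    else:
        k = params.drift_um / params.step_sd_um
        m1 = params.step_sd_um * _rice_mean_unit(k)
        v1 = params.step_sd_um**2 * (2.0 + k * k) - m1**2
    tau2 = params.speed_dispersion**2
    mean = n * m1
    var = (1.0 + tau2) * n * v1 + tau2 * (n * m1) ** 2
    return mean, math.sqrt(var)


@dataclass
class FoldTargets:
    """Target fold-change matrix (stimulus × receptor) for CT synthesis."""

    folds: pd.DataFrame
    reference_gene: str = "GAPDH"
    control: str = "C"
    ct_noise_sd: float = 0.0
    reference_ct: float = 18.0
    control_target_ct: float = 25.0

    def __post_init__(self) -> None:
        if (self.folds.to_numpy() <= 0).any():
            raise UsageError("all fold-change targets must be positive")
        if self.ct_noise_sd < 0:
            raise UsageError("ct_noise_sd must be >= 0")


def generate_ct_table(
    targets: FoldTargets, replicates: int = 3, seed: int = 0
) -> pd.DataFrame:
    """CT table whose delta-delta-CT analysis realises the target folds.

    The reference gene sits at a fixed CT in every condition; each target
    gene sits at `control_target_ct` in the control and is shifted by
    −log2(fold) under each stimulus (a doubling of expression amplifies one
    cycle earlier).  Independent Gaussian noise of SD `ct_noise_sd` is added
    to every individual CT replicate.
    """
    if replicates < 1:
        raise UsageError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    conditions = [targets.control, *targets.folds.index]
    for condition in conditions:
        genes = {targets.reference_gene: targets.reference_ct}
        for receptor in targets.folds.columns:
            ct = targets.control_target_ct
            if condition != targets.control:
                ct = ct - math.log2(float(targets.folds.loc[condition, receptor]))
            genes[receptor] = ct
        for gene, base_ct in genes.items():
            for rep in range(1, replicates + 1):
                noise = rng.normal(0.0, targets.ct_noise_sd) if targets.ct_noise_sd else 0.0
                rows.append(
                    {"condition": condition, "gene": gene, "replicate": rep,
                     "ct": base_ct + noise}
                )
    return pd.DataFrame(rows)


def generate_transwell_counts(
    mean: float, sd: float, n_devices: int = 6, seed: int = 0, condition: str = "C"
) -> ConditionDataset:
    """Per-device motile-cell counts: rounded Gaussian, truncated at zero."""
    if mean <= 0:
        raise UsageError("mean count must be positive")
    if sd < 0 or n_devices < 1:
        raise UsageError("sd >= 0 and n_devices >= 1 required")
    rng = np.random.default_rng(seed)
    raw = rng.normal(mean, sd, size=n_devices) if sd > 0 else np.full(n_devices, mean)
    counts = np.clip(np.round(raw), 0.0, None)
    return ConditionDataset(
        condition=condition, platform="ta", device_counts=[float(c) for c in counts]
    )
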