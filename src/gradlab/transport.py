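"""One-dimensional convective–diffusion transport in gradient devices.

Two device families are modelled:

* the two-reservoir microfluidic gradient generator ("gLL"): a source and a
  sink reservoir (98 µL each by default) joined by a 1.3 cm microchannel of
  192.6 µm hydraulic diameter.  Ligand loaded into the source reservoir
  spreads along the channel by diffusion (and optionally advection),

* the transwell / Boyden chamber: two well-mixed compartments separated by a
  thin porous membrane (10 µm thick, 8 µm pores by default); ligand loaded
  into the bottom compartment equilibrates across the membrane.

Both reduce to the linear transport equation

    dC/dt + u * dC/dx = D * d2C/dx2

on the channel (or membrane) axis, with the reservoirs treated as well-mixed
zero-dimensional compartments coupled to the domain ends by flux continuity.
The spatial discretisation is a conservative finite-volume scheme; the
resulting linear ODE system is advanced with the matrix exponential, so the
time integration is exact to rounding and total ligand mass is conserved to
machine precision.

Units at the interface are the laboratory's: µL, cm, µm, ng/mL and hours.
Internally everything is converted to cm / s / cm³ (1 ng/mL == 1 ng/cm³).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .exceptions import NumericalError, UsageError

BOLTZMANN_J_PER_K = 1.380649e-23

#: default scaling-law prefactor for a globular protein's hydrodynamic
#: radius, r_nm = RADIUS_MASS_PREFACTOR * (MW / kDa)**(1/3); 0.79 nm
#: reproduces measured Stokes radii of small globular proteins
#: (e.g. lysozyme, 14.3 kDa -> 1.9 nm) to ~10%.
RADIUS_MASS_PREFACTOR_NM = 0.79
RADIUS_MASS_EXPONENT = 1.0 / 3.0

_UL_TO_CM3 = 1e-3
_UM_TO_CM = 1e-4
_H_TO_S = 3600.0


def stokes_einstein_diffusivity(
    radius_nm: float, temperature_k: float = 310.0, viscosity_pa_s: float = 6.9e-4
) -> float:
    """Diffusivity of a sphere from the Stokes–Einstein relation.

    D = k_B * T / (6 * pi * eta * r), returned in cm²/s.

    Parameters
    ----------
    radius_nm : hydrodynamic radius in nm.
    temperature_k : absolute temperature in K (default 310 K, incubator).
    viscosity_pa_s : dynamic viscosity in Pa·s (default 6.9e-4, water at 37 °C).
    """
    if radius_nm <= 0 or temperature_k <= 0 or viscosity_pa_s <= 0:
        raise UsageError("radius, temperature and viscosity must all be positive")
    d_m2_s = BOLTZMANN_J_PER_K * temperature_k / (
        6.0 * math.pi * viscosity_pa_s * radius_nm * 1e-9
    )
    return d_m2_s * 1e4


def radius_from_mass(
    molecular_weight_kda: float,
    prefactor_nm: float = RADIUS_MASS_PREFACTOR_NM,
    exponent: float = RADIUS_MASS_EXPONENT,
) -> float:
    """Hydrodynamic radius (nm) of a globular protein from its mass (kDa).

    Uses the empirical scaling r = a * M**b with a literature default of
    a = 0.79 nm, b = 1/3 for compact globular folds.
    """
    if molecular_weight_kda <= 0:
        raise UsageError("molecular weight must be positive")
    return prefactor_nm * molecular_weight_kda**exponent


@dataclass
class LigandSpec:
    """A diffusing ligand: name, transport properties and loading.

    At least one of `diffusivity_cm2_s` or `hydrodynamic_radius_nm` must be
    given; a missing diffusivity is estimated by Stokes–Einstein, a missing
    radius may itself come from `molecular_weight_kda` via the globular
    scaling law.
    """

    name: str
    diffusivity_cm2_s: float | None = None
    hydrodynamic_radius_nm: float | None = None
    molecular_weight_kda: float | None = None
    source_concentration_ng_ml: float = 100.0
    temperature_k: float = 310.0
    viscosity_pa_s: float = 6.9e-4

    def __post_init__(self) -> None:
        if (
            self.diffusivity_cm2_s is None
            and self.hydrodynamic_radius_nm is None
            and self.molecular_weight_kda is None
        ):
            raise UsageError(
                f"ligand {self.name!r}: provide diffusivity, hydrodynamic radius "
                "or molecular weight"
            )
        for attr in (
            "diffusivity_cm2_s",
            "hydrodynamic_radius_nm",
            "molecular_weight_kda",
            "source_concentration_ng_ml",
            "temperature_k",
            "viscosity_pa_s",
        ):
            value = getattr(self, attr)
            if value is not None and value <= 0:
                raise UsageError(f"ligand {self.name!r}: {attr} must be positive")

    def resolve_diffusivity(self) -> float:
        """Diffusivity in cm²/s, estimating from radius or mass if needed."""
        if self.diffusivity_cm2_s is not None:
            return self.diffusivity_cm2_s
        radius = self.hydrodynamic_radius_nm
        if radius is None:
            radius = radius_from_mass(self.molecular_weight_kda)
        return stokes_einstein_diffusivity(radius, self.temperature_k, self.viscosity_pa_s)


# reference ligands at the concentrations used in the migration assays
VEGF = LigandSpec("VEGF", diffusivity_cm2_s=9.0e-7, hydrodynamic_radius_nm=3.6,
                  source_concentration_ng_ml=100.0)
EGF = LigandSpec("EGF", diffusivity_cm2_s=2.0e-6, source_concentration_ng_ml=100.0)


@dataclass
class GllGeometry:
    """Two-reservoir microfluidic device: reservoirs joined by a microchannel.

    Defaults are the gLL device: 98 µL reservoirs, 1.3 cm channel, 192.6 µm
    hydraulic diameter.  Only the hydraulic diameter is specified by the
    device, so a square cross-section of side D_H is assumed unless an
    explicit `cross_section_area_cm2` is given.
    """

    reservoir_volume_source_ul: float = 98.0
    reservoir_volume_sink_ul: float = 98.0
    channel_length_cm: float = 1.3
    hydraulic_diameter_um: float = 192.6
    cross_section_area_cm2: float | None = None

    def __post_init__(self) -> None:
        for attr in (
            "reservoir_volume_source_ul",
            "reservoir_volume_sink_ul",
            "channel_length_cm",
            "hydraulic_diameter_um",
        ):
            if getattr(self, attr) <= 0:
                raise UsageError(f"{attr} must be positive")
        if self.cross_section_area_cm2 is None:
            side_cm = self.hydraulic_diameter_um * _UM_TO_CM
            self.cross_section_area_cm2 = side_cm * side_cm
        elif self.cross_section_area_cm2 <= 0:
            raise UsageError("cross_section_area_cm2 must be positive")
        vc = self.channel_volume_ul
        if vc > 0.1 * min(self.reservoir_volume_source_ul, self.reservoir_volume_sink_ul):
            warnings.warn(
                "channel volume exceeds 10% of a reservoir volume; the "
                "well-mixed-reservoir reduction may be inaccurate",
                stacklevel=2,
            )

    @property
    def channel_volume_ul(self) -> float:
        return self.cross_section_area_cm2 * self.channel_length_cm / _UL_TO_CM3


@dataclass
class TranswellGeometry:
    """Boyden-chamber insert: two compartments across a thin porous membrane.

    Membrane defaults follow the polyester insert used for the migration
    assays (8 µm pores, 10 µm thickness).  Compartment volumes default to
    100 µL (top) / 600 µL (bottom); pore density defaults to 1e5 pores/cm²,
    typical of 8 µm track-etched membranes.
    """

    top_volume_ul: float = 100.0
    bottom_volume_ul: float = 600.0
    membrane_thickness_um: float = 10.0
    pore_diameter_um: float = 8.0
    pore_density_per_cm2: float = 1.0e5
    membrane_area_cm2: float = 0.33
    tortuosity: float = 1.0

    def __post_init__(self) -> None:
        for attr in (
            "top_volume_ul", "bottom_volume_ul", "membrane_thickness_um",
            "pore_diameter_um", "pore_density_per_cm2", "membrane_area_cm2",
            "tortuosity",
        ):
            if getattr(self, attr) <= 0:
                raise UsageError(f"{attr} must be positive")
        if not 0.0 < self.effective_porosity < 1.0:
            raise UsageError(
                f"effective porosity {self.effective_porosity:.3g} outside (0, 1); "
                "check pore density and diameter"
            )

    @property
    def effective_porosity(self) -> float:
        pore_area_cm2 = math.pi * (0.5 * self.pore_diameter_um * _UM_TO_CM) ** 2
        return self.pore_density_per_cm2 * pore_area_cm2

    def effective_diffusivity(self, free_diffusivity_cm2_s: float) -> float:
        """Membrane-scale diffusivity referred to total membrane area."""
        return free_diffusivity_cm2_s * self.effective_porosity / self.tortuosity


@dataclass
class TransportParams:
    """Numerical controls for a transport solve.

    `output_times_h` defaults to hourly snapshots over `total_time_h`.
    `boundary_mode` selects finite (mass-conserving, default) or fixed
    (clamped) reservoir concentrations.
    """

    bulk_velocity_m_s: float = 0.0
    grid_points: int = 130
    total_time_h: float = 48.0
    output_times_h: list[float] | None = None
    boundary_mode: str = "finite"

    def __post_init__(self) -> None:
        if self.grid_points < 20:
            raise UsageError("grid_points must be at least 20")
        if self.total_time_h <= 0:
            raise UsageError("total_time_h must be positive")
        if self.bulk_velocity_m_s < 0:
            raise UsageError("bulk_velocity_m_s must be non-negative")
        if self.boundary_mode not in ("finite", "fixed"):
            raise UsageError("boundary_mode must be 'finite' or 'fixed'")
        if self.output_times_h is None:
            n = max(int(round(self.total_time_h)), 1)
            self.output_times_h = list(np.linspace(0.0, self.total_time_h, n + 1))
        times = np.asarray(self.output_times_h, dtype=float)
        if times.size < 1 or np.any(np.diff(times) <= 0) or times[0] < 0:
            raise UsageError("output_times_h must be strictly increasing and >= 0")
        if times[-1] > self.total_time_h + 1e-12:
            raise UsageError("output_times_h must not exceed total_time_h")


@dataclass
class ConcentrationProfile:
    """Concentration field C(x, t) plus compartment time courses.

    positions_cm : cell centres along the transport axis, origin at the
        source-side end (+x toward the sink / top compartment).
    times_h : output time grid.
    concentration : array (n_positions, n_times), ng/mL.
    source_concentration / sink_concentration : compartment values per time.
    cell_volumes_cm3 : solution volume attached to each grid cell, used for
        mass audits.
    """

    positions_cm: np.ndarray
    times_h: np.ndarray
    concentration: np.ndarray
    source_concentration: np.ndarray
    sink_concentration: np.ndarray
    source_volume_cm3: float
    sink_volume_cm3: float
    cell_volumes_cm3: np.ndarray
    reference_concentration: float
    domain_length_cm: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.domain_length_cm == 0.0:
            self.domain_length_cm = float(
                self.positions_cm[-1] + self.positions_cm[0]
            )

    @property
    def normalized(self) -> np.ndarray:
        """C / C0, the profile normalised to the loading concentration."""
        return self.concentration / self.reference_concentration

    def total_mass_ng(self) -> np.ndarray:
        """Total ligand mass (reservoirs + domain) at each output time."""
        channel = self.cell_volumes_cm3 @ self.concentration
        return (
            channel
            + self.source_volume_cm3 * self.source_concentration
            + self.sink_volume_cm3 * self.sink_concentration
        )


def _assemble_system(
    n: int,
    dx_cm: float,
    area_cm2: float,
    diffusivity_cm2_s: float,
    velocity_cm_s: float,
    v_source_cm3: float,
    v_sink_cm3: float,
    cell_volume_cm3: float,
    fixed_boundaries: bool,
) -> np.ndarray:
    """Finite-volume generator matrix for [C_source, C_1..C_n, C_sink].

    Internal interfaces carry diffusive flux -D*A*dC/dx and upwinded
    advective flux u*A*C; the half-cell faces couple the end cells to the
    well-mixed compartments.  Columns of the matrix weighted by the
    respective volumes sum to zero, so mass conservation is built in.
    """
    m = np.zeros((n + 2, n + 2))
    volumes = np.full(n + 2, cell_volume_cm3)
    volumes[0], volumes[-1] = v_source_cm3, v_sink_cm3

    def add_flux(i_from: int, i_to: int, conductance: float, advective: float) -> None:
        # flux (ng/s) = conductance*(C_from - C_to) + advective*C_from
        for coeff, idx in ((conductance, i_from), (-conductance, i_to)):
            m[i_from, idx] -= coeff / volumes[i_from]
            m[i_to, idx] += coeff / volumes[i_to]
        if advective:
            m[i_from, i_from] -= advective / volumes[i_from]
            m[i_to, i_from] += advective / volumes[i_to]

    g_half = diffusivity_cm2_s * area_cm2 / (0.5 * dx_cm)
    g_full = diffusivity_cm2_s * area_cm2 / dx_cm
    q = velocity_cm_s * area_cm2  # u >= 0 flows source -> sink
    add_flux(0, 1, g_half, q)
    for j in range(1, n):
        add_flux(j, j + 1, g_full, q)
    add_flux(n, n + 1, g_half, q)
    if fixed_boundaries:
        m[0, :] = 0.0
        m[-1, :] = 0.0
    return m


def _propagate(matrix: np.ndarray, y0: np.ndarray, times_s: np.ndarray) -> np.ndarray:
    """Advance y' = M y through the output times via the matrix exponential."""
    out = np.empty((y0.size, times_s.size))
    y = y0.copy()
    prev = 0.0
    propagators: dict[float, np.ndarray] = {}
    for k, t in enumerate(times_s):
        dt = t - prev
        if dt > 0:
            key = round(dt, 9)
            if key not in propagators:
                propagators[key] = expm(matrix * dt)
            y = propagators[key] @ y
        out[:, k] = y
        prev = t
    return out


def _check_positivity(conc: np.ndarray, reference: float) -> None:
    if conc.min() < -1e-9 * reference:
        raise NumericalError(
            "negative concentrations beyond tolerance: the discretisation is "
            "unstable; refine the grid or reduce the advective velocity"
        )


def solve_gll(
    geometry: GllGeometry | None = None,
    ligand: LigandSpec = VEGF,
    params: TransportParams | None = None,
) -> ConcentrationProfile:
    """Solve ligand transport along the microchannel of the two-reservoir device.

    The source reservoir starts at the loading concentration C0, the channel
    and sink at zero.  Returns the channel profile at the requested output
    times together with the reservoir time courses.
    """
    geometry = geometry or GllGeometry()
    params = params or TransportParams()
    d = ligand.resolve_diffusivity()
    c0 = ligand.source_concentration_ng_ml
    n = params.grid_points
    dx = geometry.channel_length_cm / n
    area = geometry.cross_section_area_cm2
    v_src = geometry.reservoir_volume_source_ul * _UL_TO_CM3
    v_sink = geometry.reservoir_volume_sink_ul * _UL_TO_CM3
    matrix = _assemble_system(
        n, dx, area, d, params.bulk_velocity_m_s * 100.0, v_src, v_sink,
        area * dx, params.boundary_mode == "fixed",
    )
    y0 = np.zeros(n + 2)
    y0[0] = c0
    times_h = np.asarray(params.output_times_h, dtype=float)
    sol = _propagate(matrix, y0, times_h * _H_TO_S)
    _check_positivity(sol, c0)
    return ConcentrationProfile(
        positions_cm=(np.arange(n) + 0.5) * dx,
        times_h=times_h,
        concentration=np.clip(sol[1:-1, :], 0.0, None),
        source_concentration=sol[0, :],
        sink_concentration=sol[-1, :],
        source_volume_cm3=v_src,
        sink_volume_cm3=v_sink,
        cell_volumes_cm3=np.full(n, area * dx),
        reference_concentration=c0,
        domain_length_cm=geometry.channel_length_cm,
    )


def solve_transwell(
    geometry: TranswellGeometry | None = None,
    ligand: LigandSpec = VEGF,
    params: TransportParams | None = None,
) -> ConcentrationProfile:
    """Solve ligand equilibration across the transwell membrane.

    The ligand is loaded in the bottom compartment (the "source"; x = 0 is
    the bottom face of the membrane, +x toward the top compartment where the
    cells are seeded).  Diffusion through the membrane uses the pore-liquid
    concentration with flux D*(A*porosity/tortuosity)*dC/dx, i.e. an
    effective diffusivity D_eff = D*porosity/tortuosity referred to the
    total membrane area.
    """
    geometry = geometry or TranswellGeometry()
    if params is None:
        params = TransportParams(
            grid_points=20, total_time_h=18.0,
            output_times_h=list(np.linspace(0.0, 18.0, 181)),
        )
    d = ligand.resolve_diffusivity()
    c0 = ligand.source_concentration_ng_ml
    n = params.grid_points
    th_cm = geometry.membrane_thickness_um * _UM_TO_CM
    dx = th_cm / n
    eps = geometry.effective_porosity
    open_area = geometry.membrane_area_cm2 * eps / geometry.tortuosity
    v_bottom = geometry.bottom_volume_ul * _UL_TO_CM3
    v_top = geometry.top_volume_ul * _UL_TO_CM3
    cell_volume = geometry.membrane_area_cm2 * eps * dx  # pore liquid only
    matrix = _assemble_system(
        n, dx, open_area, d, params.bulk_velocity_m_s * 100.0,
        v_bottom, v_top, cell_volume, params.boundary_mode == "fixed",
    )
    y0 = np.zeros(n + 2)
    y0[0] = c0
    times_h = np.asarray(params.output_times_h, dtype=float)
    sol = _propagate(matrix, y0, times_h * _H_TO_S)
    _check_positivity(sol, c0)
    return ConcentrationProfile(
        positions_cm=(np.arange(n) + 0.5) * dx,
        times_h=times_h,
        concentration=np.clip(sol[1:-1, :], 0.0, None),
        source_concentration=sol[0, :],
        sink_concentration=sol[-1, :],
        source_volume_cm3=v_bottom,
        sink_volume_cm3=v_top,
        cell_volumes_cm3=np.full(n, cell_volume),
        reference_concentration=c0,
        domain_length_cm=th_cm,
    )


def steady_state_time(
    profile: ConcentrationProfile,
    threshold: float = 0.05,
    window_h: float = 6.0,
    floor: float = 0.01,
) -> float | None:
    """Earliest output time at which the profile has stopped evolving.

    Returns the first time t such that over the following `window_h` the
    maximum relative change of C(x) — evaluated only where C/C0 exceeds
    `floor`, to avoid 0/0 amplification in the far channel — stays below
    `threshold` (default 5%).  Compartment concentrations are included in
    the check.  Returns None if the criterion is never met within the
    simulated span.
    """
    times = profile.times_h
    span = times[-1] - times[0]
    if window_h > span / 2:
        raise UsageError(
            f"window ({window_h} h) exceeds half the simulated span ({span} h)"
        )
    stacked = np.vstack(
        [profile.source_concentration, profile.concentration, profile.sink_concentration]
    )
    c0 = profile.reference_concentration
    for i, t in enumerate(times):
        if t + window_h > times[-1] + 1e-12:
            break
        now = stacked[:, i]
        later = np.array(
            [np.interp(t + window_h, times, stacked[j, :]) for j in range(stacked.shape[0])]
        )
        mask = now / c0 > floor
        if not mask.any():
            continue
        rel = np.abs(later[mask] - now[mask]) / now[mask]
        if rel.max() < threshold:
            return float(t)
    return None


def sample_field(
    profile: ConcentrationProfile, position_cm: float, time_h: float
) -> tuple[float, float]:
    """Concentration and spatial gradient at an arbitrary (x, t).

    Bilinear interpolation of C on the stored grid; the gradient is the
    centred difference of C along x, interpolated the same way.  Returns
    (concentration ng/mL, gradient ng/mL/cm).
    """
    x, t = profile.positions_cm, profile.times_h
    if not (x[0] <= position_cm <= x[-1]):
        raise UsageError(
            f"position {position_cm} cm outside the sampled domain [{x[0]:.4g}, {x[-1]:.4g}]"
        )
    if not (t[0] <= time_h <= t[-1]):
        raise UsageError(f"time {time_h} h outside the simulated span [{t[0]}, {t[-1]}]")
    conc = profile.concentration
    grad = np.gradient(conc, x, axis=0)
    i = min(np.searchsorted(t, time_h, side="right"), t.size - 1)
    w = 0.0 if t[i] == t[i - 1] else (time_h - t[i - 1]) / (t[i] - t[i - 1])
    c_t = (1 - w) * conc[:, i - 1] + w * conc[:, i]
    g_t = (1 - w) * grad[:, i - 1] + w * grad[:, i]
    return float(np.interp(position_cm, x, c_t)), float(np.interp(position_cm, x, g_t))


def two_compartment_tau_s(geometry: TranswellGeometry, diffusivity_cm2_s: float) -> float:
    """Closed-form equilibration time constant of the transwell.

    tau = (V_top*V_bottom/(V_top+V_bottom)) * Th / (D_eff * A), the decay
    constant of the compartment concentration difference when the membrane
    is quasi-steady (membrane diffusion time << tau).
    """
    v_t = geometry.top_volume_ul * _UL_TO_CM3
    v_b = geometry.bottom_volume_ul * _UL_TO_CM3
    d_eff = geometry.effective_diffusivity(diffusivity_cm2_s)
    th_cm = geometry.membrane_thickness_um * _UM_TO_CM
    return (v_t * v_b / (v_t + v_b)) * th_cm / (d_eff * geometry.membrane_area_cm2)
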