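"""Reduced-order ground-truth WSS generator, inlet waveform and rheology.

This module replaces a transient 3D finite-volume CFD solver with a
quasi-one-dimensional model: it is a *stand-in* that reproduces the
statistical structure of stenotic WSS fields (severity-scaled throat peaks,
circumferential asymmetry of eccentric/oval lesions, post-stenotic wakes),
not a Navier-Stokes solution.  Every numeric claim the package makes about
model performance is relative to this generator.

Backbone: mass conservation gives the section-mean velocity
``U(s) = Q / A(s)`` with ``Q`` fixed by the mean inlet velocity and nominal
area, and the wall shear stress of fully developed laminar pipe flow
``tau = 4 mu U / R`` evaluated at the effective radius ``R(s) = sqrt(A/pi)``.
The effective viscosity follows the Carreau shear-thinning law evaluated at
the local Poiseuille wall shear rate ``4U/R`` (one fixed-point pass).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ShapeError, StenoshearError, ValidationError
from .stenosis import SurfaceLattice


@dataclass
class FlowParams:
    """Inlet flow, blood rheology and outlet condition.

    Defaults: cycle-averaged inlet velocity 0.20 m/s, peak 0.55 m/s,
    period 0.6 s; Carreau constants are standard literature blood values
    (mu0 = 0.056 Pa s, mu_inf = 0.00345 Pa s, lambda = 3.313 s, n = 0.3568);
    outlet pressure 13.3 kPa (100 mmHg).
    """

    mean_inlet_velocity: float = 0.20   # m/s
    peak_inlet_velocity: float = 0.55   # m/s
    cycle_period: float = 0.6           # s
    blood_density: float = 1060.0       # kg/m^3
    carreau_mu0: float = 0.056          # Pa s
    carreau_mu_inf: float = 0.00345     # Pa s
    carreau_lambda: float = 3.313       # s
    carreau_n: float = 0.3568
    outlet_pressure_kpa: float = 13.3
    #: Newtonian mode: when set, use this constant viscosity (Pa s)
    newtonian_mu: float | None = None

    def __post_init__(self):
        for name in (
            "mean_inlet_velocity", "peak_inlet_velocity", "cycle_period",
            "blood_density", "carreau_mu0", "carreau_mu_inf",
            "carreau_lambda", "outlet_pressure_kpa",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.carreau_mu_inf >= self.carreau_mu0:
            raise ValidationError("carreau mu_inf must be < mu0")
        if not (0 < self.carreau_n < 1):
            raise ValidationError("carreau n must lie in (0, 1)")
        if self.peak_inlet_velocity < self.mean_inlet_velocity:
            raise ValidationError("peak velocity must be >= mean velocity")


@dataclass
class WSSField:
    """Per-node WSS magnitude (Pa) on an axial x circumferential grid."""

    values: np.ndarray                    # (n_axial, n_theta), Pa
    station_s: np.ndarray | None = None   # mm
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("WSS values must be 2D (axial x circumferential)")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError("WSS values must be finite and >= 0")


# ---------------------------------------------------------------------------
# inlet waveform

# two-bump shape: small systolic shoulder + dominant diastolic peak, as
# fractions of the cycle; amplitudes are renormalized at construction.
_SYS_CENTER, _SYS_WIDTH, _SYS_AMP = 0.16, 0.045, 0.45
_DIA_CENTER, _DIA_WIDTH = 0.62, 0.11


def _wrapped_gaussian(x, center, width):
    """Periodic (period-1) Gaussian bump; 5 wrap terms suffice for the
    widths used here."""
    total = 0.0
    for m in range(-2, 3):
        total = total + np.exp(-0.5 * ((x - center - m) / width) ** 2)
    return total


class InletWaveform:
    """Diastole-dominant periodic inlet velocity waveform.

    The two-bump parametric shape is renormalized so that the cycle average
    equals ``mean_inlet_velocity`` and the maximum equals
    ``peak_inlet_velocity`` exactly (given a numerically located shape
    maximum).
    """

    def __init__(self, params: FlowParams | None = None):
        self.params = params or FlowParams()
        p = self.params
        # shape mean over one period: wrapped Gaussians integrate to
        # amp * width * sqrt(2 pi) each per unit period.
        shape_mean = (_SYS_AMP * _SYS_WIDTH + _DIA_WIDTH) * np.sqrt(2 * np.pi)
        # locate the shape maximum (near the diastolic center) precisely
        res = minimize_scalar(
            lambda x: -self._shape(x),
            bounds=(_DIA_CENTER - _DIA_WIDTH, _DIA_CENTER + _DIA_WIDTH),
            method="bounded",
            options={"xatol": 1e-12},
        )
        shape_max = float(self._shape(res.x))
        gain = (p.peak_inlet_velocity - p.mean_inlet_velocity) / (
            shape_max - shape_mean
        )
        base = p.mean_inlet_velocity - gain * shape_mean
        if base < 0:
            raise ValidationError(
                "waveform baseline negative for these mean/peak velocities"
            )
        self._gain = gain
        self._base = base

    @staticmethod
    def _shape(x):
        return _SYS_AMP * _wrapped_gaussian(x, _SYS_CENTER, _SYS_WIDTH) + (
            _wrapped_gaussian(x, _DIA_CENTER, _DIA_WIDTH)
        )

    def __call__(self, t):
        """Velocity (m/s) at time(s) ``t`` (s); periodic in the cycle."""
        x = np.asarray(t, dtype=float) / self.params.cycle_period
        x = x - np.floor(x)
        return self._base + self._gain * self._shape(x)


def inlet_waveform(t, params: FlowParams | None = None):
    """Evaluate the default inlet waveform at time(s) ``t`` (s)."""
    return InletWaveform(params)(t)


# ---------------------------------------------------------------------------
# rheology / Poiseuille


def carreau_viscosity(shear_rate, params: FlowParams | None = None):
    """Carreau effective viscosity (Pa s) at shear rate(s) gamma-dot (1/s):

    ``mu = mu_inf + (mu0 - mu_inf) [1 + (lambda gdot)^2]^((n-1)/2)``
    """
    p = params or FlowParams()
    gdot = np.asarray(shear_rate, dtype=float)
    if np.any(gdot < 0):
        raise ValidationError("shear rate must be >= 0")
    mu = p.carreau_mu_inf + (p.carreau_mu0 - p.carreau_mu_inf) * (
        1.0 + (p.carreau_lambda * gdot) ** 2
    ) ** ((p.carreau_n - 1.0) / 2.0)
    return mu if mu.ndim else float(mu)


def poiseuille_wss(mean_velocity: float, radius_mm: float, viscosity: float) -> float:
    """Wall shear stress of fully developed laminar pipe flow:
    ``tau = 4 mu U / R`` (Pa), radius given in mm."""
    if radius_mm <= 0:
        raise ValidationError("radius must be positive")
    return 4.0 * viscosity * mean_velocity / (radius_mm * 1e-3)


def reynolds_number(params: FlowParams, radius_mm: float) -> float:
    """Re = rho U D / mu at the cycle-averaged velocity; mu at the local
    Poiseuille wall shear rate."""
    u = params.mean_inlet_velocity
    r = radius_mm * 1e-3
    mu = params.newtonian_mu or carreau_viscosity(4 * u / r, params)
    return params.blood_density * u * 2 * r / mu


# ---------------------------------------------------------------------------
# oracle WSS field


@dataclass
class OracleConfig:
    """Shape parameters of the reduced-order WSS field.

    ``circ_exponent`` scales the inverse-wall-distance circumferential
    modulation, ``curvature_gain`` the in-plane curvature modulation,
    ``wake_depth``/``wake_recovery_diameters`` the post-stenotic low-WSS
    wake, and ``noise_sigma`` the relative amplitude of the seeded smooth
    multiplicative noise.
    """

    circ_exponent: float = 1.0
    curvature_gain: float = 1.0
    wake_depth: float = 0.6
    wake_recovery_diameters: float = 5.0
    wake_sector_power: float = 2.0
    noise_sigma: float = 0.0
    noise_corr_stations: float = 8.0


def _backbone_wss(lattice: SurfaceLattice, params: FlowParams) -> np.ndarray:
    """Quasi-1D station WSS: tau_i = 4 mu_eff U(s) / R_eq(s)."""
    r0 = float(lattice.station_radius[0])
    area_nominal = np.pi * r0**2
    q = params.mean_inlet_velocity * area_nominal  # mm^2 * m/s (units cancel)
    u = q / lattice.station_area                   # m/s
    r_m = lattice.station_radius * 1e-3
    if params.newtonian_mu is not None:
        mu = np.full_like(u, params.newtonian_mu)
    else:
        mu = carreau_viscosity(4.0 * u / r_m, params)
    return 4.0 * mu * u / r_m


def oracle_wss_field(
    lattice: SurfaceLattice,
    params: FlowParams | None = None,
    config: OracleConfig | None = None,
    seed: int | None = None,
) -> WSSField:
    """Generate a physically plausible WSS field on the full lattice.

    Per-node WSS = station backbone x circumferential modulation
    (inverse wall distance from the section center, normalized to unit ring
    mean) x curvature modulation ``1 + g * kappa * R * cos(angle to the
    curvature direction)`` x post-stenotic wake attenuation, plus optional
    seeded smooth multiplicative noise; clipped at 0.
    """
    params = params or FlowParams()
    config = config or OracleConfig()
    tau_s = _backbone_wss(lattice, params)  # (n_ax,)
    n_ax, nt = lattice.n_axial, lattice.n_theta

    # circumferential modulation: inverse distance of each wall node from the
    # centerline point of its station, normalized to ring mean 1.
    rel = lattice.node_xyz - lattice.centers[:, None, :]
    dist = np.linalg.norm(rel, axis=2)  # (n_ax, nt)
    inv = (1.0 / np.maximum(dist, 1e-9)) ** config.circ_exponent
    circ = inv / inv.mean(axis=1, keepdims=True)

    # curvature modulation in the cross-section plane
    phi = 2 * np.pi * np.arange(nt) / nt
    kr = lattice.station_curvature * lattice.station_radius
    curv = 1.0 + config.curvature_gain * kr[:, None] * np.cos(
        phi[None, :] - lattice.curvature_angle[:, None]
    )
    curv = np.clip(curv, 0.0, None)

    field_vals = tau_s[:, None] * circ * curv

    # post-stenotic wakes
    profile = lattice.profile
    specs = profile.specs if profile is not None else ()
    s = lattice.station_s
    for sp in specs:
        throat_d = 2.0 * np.sqrt(sp.throat_area_mm2 / np.pi)
        rec_len = config.wake_recovery_diameters * throat_d
        start = sp.position_mm + sp.axial_extent_mm / 2.0
        ds = s - start
        axial = np.where(ds > 0, np.exp(-ds / rec_len), 0.0)
        if sp.is_eccentric and sp.eccentric_distance_mm > 0:
            # wake hugs the side the lumen was displaced toward
            sector = (
                0.5 * (1.0 + np.cos(phi - sp.orientation_rad))
            ) ** config.wake_sector_power
        else:
            sector = np.ones(nt)
        field_vals = field_vals * (
            1.0 - config.wake_depth * axial[:, None] * sector[None, :]
        )

    if config.noise_sigma > 0:
        if seed is None:
            raise StenoshearError("noise requested but no seed given")
        rng = np.random.default_rng(seed)
        white = rng.standard_normal((n_ax, nt))
        from scipy.ndimage import gaussian_filter

        smooth = gaussian_filter(
            white,
            sigma=(config.noise_corr_stations, 2.0),
            mode=("nearest", "wrap"),
        )
        smooth /= max(smooth.std(), 1e-12)
        field_vals = field_vals * (1.0 + config.noise_sigma * smooth)

    field_vals = np.clip(field_vals, 0.0, None)
    return WSSField(values=field_vals, station_s=s.copy(),
                    meta={"seed": seed})


# ---------------------------------------------------------------------------
# I/O


def write_wss_h5(field: WSSField, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("wss_pa", data=field.values)
        if field.station_s is not None:
            fh.create_dataset("station_s_mm", data=field.station_s)


def read_wss_h5(path) -> WSSField:
    import h5py

    with h5py.File(path, "r") as fh:
        vals = fh["wss_pa"][()]
        s = fh["station_s_mm"][()] if "station_s_mm" in fh else None
    return WSSField(values=vals, station_s=s)


def write_wss_csv(field: WSSField, path) -> None:
    """Flat CSV: i, k, wss_pa."""
    n_ax, nt = field.values.shape
    i_idx, k_idx = np.meshgrid(np.arange(n_ax), np.arange(nt), indexing="ij")
    table = np.column_stack([i_idx.ravel(), k_idx.ravel(), field.values.ravel()])
    np.savetxt(path, table, delimiter=",", header="i,k,wss_pa", comments="",
               fmt=["%d", "%d", "%.17g"])


def read_wss_csv(path) -> WSSField:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    n_ax = int(data[:, 0].max()) + 1
    nt = int(data[:, 1].max()) + 1
    return WSSField(values=data[:, 2].reshape(n_ax, nt))
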