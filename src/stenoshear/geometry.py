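"""Vessel centerline synthesis and characterization.

A centerline is an arc-length-parameterized 3D path ``r(s)`` with a local
lumen radius ``R(s)``.  This module provides:

* uniform arc-length resampling to a standard representation
  (80 mm, 640 samples by default),
* geometric descriptors — path length ``l``, chord length ``c``, sinuosity
  ``S = l/c``, Frenet–Serret curvature ``kappa(s)`` and torsion ``tau(s)`` —
  computed by central finite differences on the uniform arc grid,
* a descriptor-constrained stochastic deformation that turns a small set of
  template paths into an unlimited cohort of anatomically plausible
  centerlines, and
* CSV / VTP I/O.

Units are mm throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import (
    ConstraintInfeasibleError,
    DegenerateChordError,
    InsufficientSamplesError,
    InvalidGeometryError,
)

STANDARD_LENGTH_MM = 80.0
STANDARD_N_SAMPLES = 640
DEFAULT_RADIUS_MM = 1.5  # nominal lumen radius, D0 = 3 mm


@dataclass
class Centerline:
    """Ordered 3D samples with per-sample radius on a uniform arc grid.

    Attributes
    ----------
    points : (n, 3) array, mm
    radius : (n,) array, mm, all positive
    arc_coord : (n,) array, mm, strictly increasing (uniform after resampling)
    """

    points: np.ndarray
    radius: np.ndarray
    arc_coord: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.arc_coord = np.asarray(self.arc_coord, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InvalidGeometryError("points must be (n, 3)")
        n = self.points.shape[0]
        if self.radius.shape != (n,) or self.arc_coord.shape != (n,):
            raise InvalidGeometryError("radius/arc_coord length mismatch")
        if np.any(np.diff(self.arc_coord) <= 0):
            raise InvalidGeometryError("arc_coord must be strictly increasing")
        if np.any(self.radius <= 0):
            raise InvalidGeometryError("all radii must be positive")

    @property
    def n_samples(self) -> int:
        return self.points.shape[0]

    @property
    def length(self) -> float:
        """Total arc length (arc_coord span)."""
        return float(self.arc_coord[-1] - self.arc_coord[0])

    @property
    def spacing(self) -> float:
        return self.length / (self.n_samples - 1)


@dataclass
class GeometryDescriptors:
    """Scalar and per-sample shape descriptors of a centerline."""

    path_length: float
    chord_length: float
    sinuosity: float
    curvature: np.ndarray
    torsion: np.ndarray
    #: (total curvature  integral(kappa ds),  max kappa) — stand-ins for the
    #: integral curvature measures of the descriptor vector; see docs.
    integral_curvature_measures: np.ndarray = field(default_factory=lambda: np.zeros(2))

    @property
    def total_curvature(self) -> float:
        return float(self.integral_curvature_measures[0])

    @property
    def max_curvature(self) -> float:
        return float(self.integral_curvature_measures[1])


# ---------------------------------------------------------------------------
# resampling


def _polyline_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_centerline(
    points: np.ndarray,
    n: int = STANDARD_N_SAMPLES,
    target_length: float = STANDARD_LENGTH_MM,
    radius: np.ndarray | float | None = None,
) -> Centerline:
    """Rescale a path to ``target_length`` and resample to ``n`` uniform
    arc-length samples (endpoints inclusive, spacing ``target_length/(n-1)``).

    ``radius`` may be a scalar, a per-input-point array (resampled along), or
    None (defaults to 1.5 mm).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 4:
        raise InvalidGeometryError("need at least 4 points of shape (n, 3)")
    s_in = _polyline_arclength(points)
    total = s_in[-1]
    if total <= 0:
        raise InvalidGeometryError("zero-length input path")

    # drop duplicate points (zero-length segments break spline interpolation)
    keep = np.concatenate([[True], np.diff(s_in) > 0])
    points = points[keep]
    s_in = s_in[keep]
    if points.shape[0] < 4:
        raise InvalidGeometryError("fewer than 4 distinct points")

    # scale to target length, then iterate arc-length reparameterization on a
    # dense spline sampling until chord spacing is uniform.
    scale = target_length / total
    pts = points * scale
    s = s_in * scale
    if isinstance(radius, np.ndarray):
        rad_in = np.asarray(radius, dtype=float)[keep]
    else:
        rad_in = None

    for _ in range(6):
        spl = CubicSpline(s, pts, axis=0)
        dense_t = np.linspace(s[0], s[-1], max(8 * n, 4 * len(s)))
        dense = spl(dense_t)
        ds = _polyline_arclength(dense)
        # invert: parameter value at uniform arc fractions
        t_of_arc = np.interp(
            np.linspace(0.0, ds[-1], n), ds, dense_t
        )
        new_pts = spl(t_of_arc)
        new_s = _polyline_arclength(new_pts)
        # rescale chordal length exactly to target
        new_pts = new_pts * (target_length / new_s[-1])
        seg = np.diff(_polyline_arclength(new_pts))
        spread = seg.max() - seg.min()
        converged = spread <= 1e-9 * seg.mean()
        # carry radius via the same parameter mapping
        if rad_in is not None:
            new_rad = np.interp(t_of_arc, s, rad_in)
        pts_out = new_pts
        if converged:
            break
        # reparameterize from the new polyline and iterate
        pts = new_pts
        s = _polyline_arclength(new_pts)
        if rad_in is not None:
            rad_in = new_rad
    arc = np.linspace(0.0, target_length, n)
    if radius is None:
        rad = np.full(n, DEFAULT_RADIUS_MM)
    elif isinstance(radius, np.ndarray):
        rad = new_rad
    else:
        rad = np.full(n, float(radius))
    return Centerline(points=pts_out, radius=rad, arc_coord=arc)


# ---------------------------------------------------------------------------
# descriptors


def _derivatives(points: np.ndarray, h: float):
    """1st/2nd/3rd derivatives wrt arc length by central differences
    (one-sided at the ends)."""
    d1 = np.gradient(points, h, axis=0, edge_order=2)
    d2 = np.gradient(d1, h, axis=0, edge_order=2)
    d3 = np.gradient(d2, h, axis=0, edge_order=2)
    return d1, d2, d3


def compute_descriptors(cl: Centerline) -> GeometryDescriptors:
    """Path length, chord, sinuosity, curvature and torsion of a centerline.

    Curvature: ``kappa = |r' x r''| / |r'|^3``;
    torsion: ``tau = det(r', r'', r''') / |r' x r''|^2`` with the 0/0 case on
    straight segments (``|r' x r''| < 1e-9``) defined as 0.
    """
    if cl.n_samples < 5:
        raise InsufficientSamplesError("need >= 5 samples for derivatives")
    l = cl.length
    chord = float(np.linalg.norm(cl.points[-1] - cl.points[0]))
    if chord <= 0:
        raise DegenerateChordError("zero chord length (closed curve)")
    h = cl.spacing
    d1, d2, d3 = _derivatives(cl.points, h)
    cross = np.cross(d1, d2)
    cross_norm = np.linalg.norm(cross, axis=1)
    speed = np.linalg.norm(d1, axis=1)
    kappa = cross_norm / np.maximum(speed, 1e-300) ** 3
    det = np.einsum("ij,ij->i", cross, d3)
    torsion = np.zeros_like(kappa)
    ok = cross_norm >= 1e-9
    torsion[ok] = det[ok] / cross_norm[ok] ** 2
    total_curv = float(np.trapezoid(kappa, cl.arc_coord))
    measures = np.array([total_curv, float(kappa.max())])
    return GeometryDescriptors(
        path_length=l,
        chord_length=chord,
        sinuosity=l / chord,
        curvature=kappa,
        torsion=torsion,
        integral_curvature_measures=measures,
    )


# ---------------------------------------------------------------------------
# templates and synthesis


def template_centerline(kind: str = "single_bend", n: int = 256) -> np.ndarray:
    """Raw template paths: 'straight', 'single_bend', 's_bend', 'helical'.

    Returned as an (n, 3) point array in arbitrary scale; feed through
    :func:`resample_centerline` for the standard representation.
    """
    t = np.linspace(0.0, 1.0, n)
    if kind == "straight":
        pts = np.stack([np.zeros(n), np.zeros(n), 80.0 * t], axis=1)
    elif kind == "single_bend":
        # gentle planar arc, ~30 degrees of turning
        ang = np.deg2rad(30.0) * t
        rad = 80.0 / np.deg2rad(30.0)
        pts = np.stack([rad * (1 - np.cos(ang)), np.zeros(n), rad * np.sin(ang)], axis=1)
    elif kind == "s_bend":
        pts = np.stack(
            [6.0 * np.sin(2 * np.pi * t), np.zeros(n), 80.0 * t], axis=1
        )
    elif kind == "helical":
        pts = np.stack(
            [4.0 * np.cos(2 * np.pi * t), 4.0 * np.sin(2 * np.pi * t), 80.0 * t],
            axis=1,
        )
    else:
        raise ValueError(f"unknown template kind: {kind!r}")
    return pts


TEMPLATE_KINDS = ("straight", "single_bend", "s_bend", "helical")

#: Descriptor bounds used for rejection during synthesis: measured from the
#: packaged templates (with margin) rather than from a clinical cohort.
DEFAULT_DESCRIPTOR_BOUNDS: dict[str, tuple[float, float]] = {
    "sinuosity": (1.0, 1.6),
    "max_curvature": (0.0, 0.35),   # mm^-1
    "total_curvature": (0.0, 12.0),  # rad
}


def _check_bounds(desc: GeometryDescriptors, bounds: dict) -> str | None:
    """Return the name of the first violated bound, or None."""
    vals = {
        "sinuosity": desc.sinuosity,
        "max_curvature": desc.max_curvature,
        "total_curvature": desc.total_curvature,
    }
    for name, (lo, hi) in bounds.items():
        v = vals[name]
        if not (lo <= v <= hi):
            return name
    return None


def synthesize_centerline(
    template: Centerline,
    amplitude: float,
    seed: int,
    bounds: dict[str, tuple[float, float]] | None = None,
    n: int = STANDARD_N_SAMPLES,
    target_length: float = STANDARD_LENGTH_MM,
    n_bumps: int = 6,
    bump_sigma_mm: float = 10.0,
    max_retries: int = 64,
) -> Centerline:
    """Deform a template path by a sum of Gaussian-smoothed random
    displacement bumps, then rescale/resample to the standard representation.

    The deformed path is rejected (and re-drawn) until its descriptors fall
    inside ``bounds``; a fixed ``seed`` makes the result reproducible.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    bounds = DEFAULT_DESCRIPTOR_BOUNDS if bounds is None else bounds
    if not bounds:
        raise ValueError("bounds must be non-empty")
    rng = np.random.default_rng(seed)
    base = template.points
    s = template.arc_coord
    violated = None
    for _ in range(max_retries):
        disp = np.zeros_like(base)
        if amplitude > 0:
            for _b in range(n_bumps):
                center = rng.uniform(s[0], s[-1])
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                amp = rng.normal(0.0, amplitude)
                kernel = np.exp(-0.5 * ((s - center) / bump_sigma_mm) ** 2)
                disp += amp * kernel[:, None] * direction[None, :]
        cand = resample_centerline(
            base + disp, n=n, target_length=target_length, radius=template.radius
        )
        violated = _check_bounds(compute_descriptors(cand), bounds)
        if violated is None:
            return cand
        if amplitude == 0:
            break
    raise ConstraintInfeasibleError(
        f"could not satisfy descriptor bound {violated!r} "
        f"after {max_retries} attempts",
        violated=violated,
    )


# ---------------------------------------------------------------------------
# I/O


def write_centerline_csv(cl: Centerline, path) -> None:
    """Columns: s_mm, x_mm, y_mm, z_mm, radius_mm."""
    data = np.column_stack([cl.arc_coord, cl.points, cl.radius])
    header = "s_mm,x_mm,y_mm,z_mm,radius_mm"
    np.savetxt(path, data, delimiter=",", header=header, comments="",
               fmt="%.17g")


def read_centerline_csv(path) -> Centerline:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return Centerline(points=data[:, 1:4], radius=data[:, 4], arc_coord=data[:, 0])


def write_centerline_vtp(cl: Centerline, path) -> None:
    """Minimal XML PolyData polyline with radius as point data."""
    n = cl.n_samples
    pts = " ".join(f"{v:.9g}" for v in cl.points.ravel())
    rad = " ".join(f"{v:.9g}" for v in cl.radius)
    conn = " ".join(str(i) for i in range(n))
    xml = f"""<?xml version="1.0"?>
<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">
  <PolyData>
    <Piece NumberOfPoints="{n}" NumberOfLines="1">
      <PointData Scalars="radius_mm">
        <DataArray type="Float64" Name="radius_mm" format="ascii">{rad}</DataArray>
      </PointData>
      <Points>
        <DataArray type="Float64" NumberOfComponents="3" format="ascii">{pts}</DataArray>
      </Points>
      <Lines>
        <DataArray type="Int64" Name="connectivity" format="ascii">{conn}</DataArray>
        <DataArray type="Int64" Name="offsets" format="ascii">{n}</DataArray>
      </Lines>
    </Piece>
  </PolyData>
</VTKFile>
"""
    with open(path, "w") as fh:
        fh.write(xml)
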