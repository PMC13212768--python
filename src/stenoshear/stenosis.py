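"""Focal stenosis sculpting and structured wall-lattice construction.

A lesion is described by its morphology class (concentric/eccentric x
round/oval), a stenotic area ratio ``AR = A_sten / A0`` (smaller = severer:
10% severe, 30% moderate, 50% mild), an axial position, an eccentric offset
``d`` of the throat center within the cross-section plane, and throat
semi-axes ``a >= b`` solved so that ``pi a b = AR * A0``.

The lumen is swept along the centerline in a rotation-minimizing
(parallel-transport) frame; each of the 640 axial stations carries a
cross-section boundary blended by a cosine taper from the nominal circle
(radius D0/2 = 1.5 mm) to the throat shape and back.  40 circumferential
nodes per station give the structured 640 x 40 wall lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidGeometryError, LesionOverlapError, ValidationError
from .geometry import Centerline

D0_MM = 3.0  # nominal lumen diameter
R0_MM = D0_MM / 2.0
N_THETA = 40

MORPHOLOGIES = (
    "concentric_round",
    "eccentric_round",
    "concentric_oval",
    "eccentric_oval",
)

#: severity presets: mild/moderate/severe -> area ratio
SEVERITY_AR = {"mild": 0.50, "moderate": 0.30, "severe": 0.10}

AR_RANGE = (0.1, 0.9)
POSITION_RANGE_MM = (10.0, 70.0)
DEFAULT_AXIAL_EXTENT_MM = 8.0
DEFAULT_ASPECT_RANGE = (1.5, 2.5)  # oval a/b


@dataclass(frozen=True)
class StenosisSpec:
    """Fully resolved description of one focal lesion."""

    morphology: str
    area_ratio: float
    position_mm: float
    eccentric_distance_mm: float
    semi_major_mm: float
    semi_minor_mm: float
    orientation_rad: float
    axial_extent_mm: float = DEFAULT_AXIAL_EXTENT_MM

    @property
    def is_eccentric(self) -> bool:
        return self.morphology.startswith("eccentric")

    @property
    def is_oval(self) -> bool:
        return self.morphology.endswith("oval")

    @property
    def throat_area_mm2(self) -> float:
        return float(np.pi * self.semi_major_mm * self.semi_minor_mm)


def make_stenosis_spec(
    morphology: str,
    area_ratio: float | str = "random",
    position_mm: float | str = "random",
    eccentric_distance_mm: float | str = "random",
    orientation_rad: float | str = "random",
    seed: int | None = None,
    nominal_radius_mm: float = R0_MM,
    aspect_range: tuple[float, float] = DEFAULT_ASPECT_RANGE,
    axial_extent_mm: float = DEFAULT_AXIAL_EXTENT_MM,
) -> StenosisSpec:
    """Resolve a lesion spec, drawing any parameter flagged ``"random"``
    uniformly within its documented range.

    Round classes: ``a = b = sqrt(AR) * R0``.  Oval classes: aspect ratio
    ``a/b`` drawn from ``aspect_range`` and ``(a, b)`` solved so that
    ``pi a b = AR * pi R0^2``.
    """
    if morphology not in MORPHOLOGIES:
        raise ValidationError(
            f"morphology {morphology!r} not one of {MORPHOLOGIES}"
        )
    rng = np.random.default_rng(seed)
    if area_ratio == "random":
        area_ratio = float(rng.uniform(*AR_RANGE))
    if position_mm == "random":
        position_mm = float(rng.uniform(*POSITION_RANGE_MM))
    if orientation_rad == "random":
        orientation_rad = float(rng.uniform(0.0, 2 * np.pi))
    area_ratio = float(area_ratio)
    position_mm = float(position_mm)
    orientation_rad = float(orientation_rad)

    if not (AR_RANGE[0] <= area_ratio <= AR_RANGE[1]):
        raise ValidationError(
            f"area_ratio {area_ratio} outside [{AR_RANGE[0]}, {AR_RANGE[1]}]"
        )
    if not (POSITION_RANGE_MM[0] <= position_mm <= POSITION_RANGE_MM[1]):
        raise ValidationError(
            f"position {position_mm} mm outside "
            f"[{POSITION_RANGE_MM[0]}, {POSITION_RANGE_MM[1]}]"
        )

    r0 = nominal_radius_mm
    if morphology.endswith("round"):
        a = b = float(np.sqrt(area_ratio) * r0)
    else:
        aspect = float(rng.uniform(*aspect_range))
        b = float(r0 * np.sqrt(area_ratio / aspect))
        a = float(aspect * b)

    if morphology.startswith("concentric"):
        d = 0.0
    else:
        d_max = 0.5 * r0
        if eccentric_distance_mm == "random":
            d = float(rng.uniform(0.0, d_max))
        else:
            d = float(eccentric_distance_mm)
        if d < 0 or d > d_max:
            raise ValidationError(
                f"eccentric distance {d} mm exceeds 50% of local radius "
                f"({d_max} mm)"
            )
    return StenosisSpec(
        morphology=morphology,
        area_ratio=area_ratio,
        position_mm=position_mm,
        eccentric_distance_mm=d,
        semi_major_mm=a,
        semi_minor_mm=b,
        orientation_rad=orientation_rad,
        axial_extent_mm=float(axial_extent_mm),
    )


# ---------------------------------------------------------------------------
# cross-section profile


@dataclass
class CrossSectionProfile:
    """Analytic per-station cross-section boundary.

    ``center_offset`` is expressed in the local 2D cross-section frame
    (components along the frame vectors e1, e2).  ``semi_major/minor`` are
    the in-plane ellipse semi-axes, ``orientation`` the major-axis angle.
    """

    station_s: np.ndarray          # (n,)
    center_offset: np.ndarray      # (n, 2) mm
    semi_major: np.ndarray         # (n,) mm
    semi_minor: np.ndarray         # (n,) mm
    orientation: np.ndarray        # (n,) rad
    specs: tuple[StenosisSpec, ...] = ()

    @property
    def area(self) -> np.ndarray:
        """Analytic cross-section area pi*a*b per station (mm^2)."""
        return np.pi * self.semi_major * self.semi_minor

    def boundary_points(self, i: int, n_theta: int = N_THETA) -> np.ndarray:
        """2D boundary polygon of station ``i`` at uniform parameter angles."""
        phi = 2 * np.pi * np.arange(n_theta) / n_theta
        return _ring_2d(
            self.center_offset[i],
            self.semi_major[i],
            self.semi_minor[i],
            self.orientation[i],
            phi,
        )


def _ring_2d(center, a, b, orient, phi):
    """Ellipse boundary at parameter angles ``phi`` (measured in the frame).

    The point at parameter ``phi`` lies at angle ``phi`` for a circle; for an
    ellipse the standard parameterization is rotated by ``orient``.
    """
    psi = phi - orient
    local = np.stack([a * np.cos(psi), b * np.sin(psi)], axis=-1)
    c, s = np.cos(orient), np.sin(orient)
    rot = np.array([[c, -s], [s, c]])
    return center + local @ rot.T


def apply_stenosis(
    cl: Centerline, specs: list[StenosisSpec] | tuple[StenosisSpec, ...] = ()
) -> CrossSectionProfile:
    """Blend 1-2 lesions onto the nominal lumen along the centerline.

    Each lesion morphs the nominal circle into the throat ellipse via a raised
    cosine over its axial extent; stations outside every lesion's extent keep
    the nominal circle of the centerline's local radius.
    """
    specs = tuple(specs)
    if len(specs) > 2:
        raise ValidationError("at most 2 lesions supported")
    s = cl.arc_coord
    length = cl.length
    for sp in specs:
        if sp.position_mm - sp.axial_extent_mm / 2 < s[0] or (
            sp.position_mm + sp.axial_extent_mm / 2 > s[-1]
        ):
            raise ValidationError(
                f"lesion at {sp.position_mm} mm extends outside [0, {length}] mm"
            )
    if len(specs) == 2:
        gap = abs(specs[0].position_mm - specs[1].position_mm)
        min_gap = max(specs[0].axial_extent_mm, specs[1].axial_extent_mm)
        if gap < min_gap:
            raise LesionOverlapError(
                f"throats {gap:.2f} mm apart; need >= {min_gap:.2f} mm"
            )

    n = cl.n_samples
    a = cl.radius.astype(float).copy()
    b = cl.radius.astype(float).copy()
    offset = np.zeros((n, 2))
    orient = np.zeros(n)
    for sp in specs:
        u = (s - sp.position_mm) / (sp.axial_extent_mm / 2.0)
        w = np.where(np.abs(u) < 1.0, 0.5 * (1.0 + np.cos(np.pi * u)), 0.0)
        r_nom = cl.radius
        a = a + w * (sp.semi_major_mm - r_nom)
        b = b + w * (sp.semi_minor_mm - r_nom)
        e = np.array([np.cos(sp.orientation_rad), np.sin(sp.orientation_rad)])
        offset = offset + (w * sp.eccentric_distance_mm)[:, None] * e[None, :]
        orient = np.where(w > 0, sp.orientation_rad, orient)
    return CrossSectionProfile(
        station_s=s.copy(),
        center_offset=offset,
        semi_major=a,
        semi_minor=b,
        orientation=orient,
        specs=specs,
    )


# ---------------------------------------------------------------------------
# surface lattice


@dataclass
class SurfaceLattice:
    """Structured axial x circumferential grid of wall nodes.

    ``node_xyz`` has shape (n_axial, n_theta, 3); ring ``i`` lies in the
    cross-section plane of centerline station ``i``.  Frames are
    rotation-minimizing, so rings do not twist on straight segments.
    """

    node_xyz: np.ndarray         # (n_axial, n_theta, 3) mm
    station_s: np.ndarray        # (n_axial,) mm
    station_radius: np.ndarray   # effective lumen radius sqrt(A/pi), mm
    station_curvature: np.ndarray  # (n_axial,) mm^-1
    station_area: np.ndarray     # analytic pi*a*b, mm^2
    centers: np.ndarray          # (n_axial, 3) centerline points, mm
    frame_e1: np.ndarray         # (n_axial, 3)
    frame_e2: np.ndarray         # (n_axial, 3)
    curvature_angle: np.ndarray  # angle of curvature normal in (e1, e2), rad
    profile: CrossSectionProfile | None = None

    @property
    def n_axial(self) -> int:
        return self.node_xyz.shape[0]

    @property
    def n_theta(self) -> int:
        return self.node_xyz.shape[1]

    def ring_polygon_area(self, i: int) -> float:
        """Shoelace area of ring ``i`` projected on its cross-section frame."""
        pts = self.node_xyz[i] - self.centers[i]
        x = pts @ self.frame_e1[i]
        y = pts @ self.frame_e2[i]
        return float(
            0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        )


def _rotation_minimizing_frames(points: np.ndarray):
    """Parallel-transport frames by the double-reflection method."""
    tang = np.gradient(points, axis=0, edge_order=2)
    norms = np.linalg.norm(tang, axis=1)
    if np.any(norms < 1e-12):
        raise InvalidGeometryError("zero tangent along centerline")
    t = tang / norms[:, None]
    n = points.shape[0]
    e1 = np.zeros((n, 3))
    # initial normal: any vector orthogonal to t[0]
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, t[0])) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = ref - np.dot(ref, t[0]) * t[0]
    e1[0] = v / np.linalg.norm(v)
    for i in range(n - 1):
        v1 = points[i + 1] - points[i]
        c1 = np.dot(v1, v1)
        rL = e1[i] - (2.0 / c1) * np.dot(v1, e1[i]) * v1
        tL = t[i] - (2.0 / c1) * np.dot(v1, t[i]) * v1
        v2 = t[i + 1] - tL
        c2 = np.dot(v2, v2)
        if c2 < 1e-30:
            e1[i + 1] = rL
        else:
            e1[i + 1] = rL - (2.0 / c2) * np.dot(v2, rL) * v2
        # re-orthogonalize against accumulated drift
        e1[i + 1] -= np.dot(e1[i + 1], t[i + 1]) * t[i + 1]
        e1[i + 1] /= np.linalg.norm(e1[i + 1])
    e2 = np.cross(t, e1)
    return t, e1, e2


def build_surface(
    cl: Centerline,
    profile: CrossSectionProfile,
    n_theta: int = N_THETA,
) -> SurfaceLattice:
    """Place node (i, k) on station i's boundary at circumferential parameter
    ``2 pi (k-1)/n_theta`` in the rotation-minimizing frame."""
    if profile.station_s.shape[0] != cl.n_samples:
        raise InvalidGeometryError("profile must cover every centerline station")
    t, e1, e2 = _rotation_minimizing_frames(cl.points)
    n_ax = cl.n_samples
    phi = 2 * np.pi * np.arange(n_theta) / n_theta
    # 2D ring coordinates per station
    node_xyz = np.empty((n_ax, n_theta, 3))
    for i in range(n_ax):
        ring2 = _ring_2d(
            profile.center_offset[i],
            profile.semi_major[i],
            profile.semi_minor[i],
            profile.orientation[i],
            phi,
        )
        node_xyz[i] = (
            cl.points[i][None, :]
            + ring2[:, 0:1] * e1[i][None, :]
            + ring2[:, 1:2] * e2[i][None, :]
        )
    from .geometry import compute_descriptors

    desc = compute_descriptors(cl)
    # curvature-normal direction projected into the frame
    h = cl.spacing
    d1 = np.gradient(cl.points, h, axis=0, edge_order=2)
    d2 = np.gradient(d1, h, axis=0, edge_order=2)
    proj1 = np.einsum("ij,ij->i", d2, e1)
    proj2 = np.einsum("ij,ij->i", d2, e2)
    curv_angle = np.arctan2(proj2, proj1)
    curv_angle[np.hypot(proj1, proj2) < 1e-12] = 0.0

    area = profile.area
    return SurfaceLattice(
        node_xyz=node_xyz,
        station_s=cl.arc_coord.copy(),
        station_radius=np.sqrt(area / np.pi),
        station_curvature=desc.curvature,
        station_area=area,
        centers=cl.points.copy(),
        frame_e1=e1,
        frame_e2=e2,
        curvature_angle=curv_angle,
        profile=profile,
    )


# ---------------------------------------------------------------------------
# export


def lattice_faces(n_axial: int, n_theta: int) -> np.ndarray:
    """Consistent quad-split triangulation of the wall: 2*(n_axial-1)*n_theta
    triangles, circumferential wrap included."""
    idx = lambda i, k: i * n_theta + (k % n_theta)  # noqa: E731
    faces = []
    for i in range(n_axial - 1):
        for k in range(n_theta):
            a = idx(i, k)
            b = idx(i, k + 1)
            c = idx(i + 1, k)
            d = idx(i + 1, k + 1)
            faces.append((a, b, d))
            faces.append((a, d, c))
    return np.asarray(faces, dtype=np.int64)


def export_geometry(
    lattice: SurfaceLattice,
    cl: Centerline,
    stl_path=None,
    vtp_path=None,
    csv_path=None,
    cap_ends: bool = False,
):
    """Write STL wall mesh, VTP centerline and CSV node table.

    Returns the trimesh object for the STL (also when ``stl_path`` is None).
    """
    import trimesh

    verts = lattice.node_xyz.reshape(-1, 3)
    faces = lattice_faces(lattice.n_axial, lattice.n_theta)
    if cap_ends:
        verts = np.vstack([verts, lattice.centers[0], lattice.centers[-1]])
        c0 = len(verts) - 2
        c1 = len(verts) - 1
        nt = lattice.n_theta
        cap0 = [(c0, (k + 1) % nt, k) for k in range(nt)]
        last = (lattice.n_axial - 1) * nt
        cap1 = [(c1, last + k, last + (k + 1) % nt) for k in range(nt)]
        faces = np.vstack([faces, cap0, cap1])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if stl_path is not None:
        mesh.export(str(stl_path))
    if vtp_path is not None:
        from .geometry import write_centerline_vtp

        write_centerline_vtp(cl, vtp_path)
    if csv_path is not None:
        n_ax, nt = lattice.n_axial, lattice.n_theta
        i_idx, k_idx = np.meshgrid(
            np.arange(n_ax), np.arange(nt), indexing="ij"
        )
        angle = 2 * np.pi * k_idx / nt
        table = np.column_stack(
            [
                i_idx.ravel(),
                k_idx.ravel(),
                verts[: n_ax * nt],
                np.repeat(lattice.station_s, nt),
                angle.ravel(),
            ]
        )
        np.savetxt(
            csv_path,
            table,
            delimiter=",",
            header="i,k,x_mm,y_mm,z_mm,s_mm,angle_rad",
            comments="",
            fmt="%.17g",
        )
    return mesh


def read_node_csv(path) -> np.ndarray:
    """Round-trip reader for the node table; returns (n_axial, n_theta, 3)."""
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    n_ax = int(data[:, 0].max()) + 1
    nt = int(data[:, 1].max()) + 1
    return data[:, 2:5].reshape(n_ax, nt, 3)
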