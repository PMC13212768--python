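"""Input tensor, grid mapping, target normalization and the vessel graph.

The analysis grid drops the inlet/outlet transition zones (5 mm at each end)
of the full lattice, keeping the central stations (560 of 640 at the
standard resolution).  Each kept node carries the 8 geometric features
(X, Y, Z, C, A, d, a, b): surface coordinates, station curvature, the
circumferential angle ``A = 2 pi (k-1)/n_theta``, and the station's blended
cross-section parameters (eccentric offset magnitude and semi-axes).

The vessel graph combines 8-connected structured-grid edges (with
circumferential wrap, no axial wrap) with additional spatial-proximity edges;
every edge carries the weight ``w = exp(-dist/0.1)`` (distance in mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .errors import (
    DegenerateStatisticsError,
    ShapeError,
    StenoshearError,
    ValidationError,
)
from .oracle import WSSField
from .stenosis import SurfaceLattice

EDGE_LENGTH_SCALE_MM = 0.1
TRANSITION_ZONE_MM = 5.0
DEFAULT_SPATIAL_RADIUS_MM = 0.3
DEFAULT_MAX_SPATIAL_DEGREE = 6

FEATURE_NAMES = ("X", "Y", "Z", "C", "A", "d", "a", "b")


def crop_slice(n_axial: int, length_mm: float = 80.0,
               zone_mm: float = TRANSITION_ZONE_MM) -> slice:
    """Stations kept after excluding the transition zones: indices
    ``n_zone .. n_axial - n_zone - 1`` with ``n_zone = round(zone / spacing)``
    using the nominal spacing ``length/n_axial`` (640 -> stations 40..599)."""
    n_zone = int(round(zone_mm * n_axial / length_mm))
    return slice(n_zone, n_axial - n_zone)


@dataclass
class InputTensor:
    """(n_axial_cropped, n_theta, 8) feature grid."""

    grid: np.ndarray
    station_s: np.ndarray
    station_radius: np.ndarray
    station_curvature: np.ndarray
    feature_names: tuple = FEATURE_NAMES

    def __post_init__(self):
        if self.grid.ndim != 3 or self.grid.shape[2] != len(FEATURE_NAMES):
            raise ShapeError("feature grid must be (n_ax, n_theta, 8)")

    @property
    def n_axial(self) -> int:
        return self.grid.shape[0]

    @property
    def n_theta(self) -> int:
        return self.grid.shape[1]

    @property
    def n_features_flat(self) -> int:
        return int(np.prod(self.grid.shape))


def build_feature_tensor(lattice: SurfaceLattice) -> InputTensor:
    """Crop the transition zones and fill the 8 feature channels.

    ``d``/``a``/``b`` come from the station's blended cross-section profile
    (0 / R0 / R0 where nominal); they are constant per axial station.
    """
    profile = lattice.profile
    if profile is None:
        raise StenoshearError("lattice carries no cross-section profile")
    keep = crop_slice(lattice.n_axial,
                      length_mm=float(lattice.station_s[-1] - lattice.station_s[0]))
    n_th = lattice.n_theta
    xyz = lattice.node_xyz[keep]
    n_ax = xyz.shape[0]
    grid = np.empty((n_ax, n_th, 8))
    grid[:, :, 0:3] = xyz
    grid[:, :, 3] = lattice.station_curvature[keep, None]
    grid[:, :, 4] = (2 * np.pi * np.arange(n_th) / n_th)[None, :]
    d = np.linalg.norm(profile.center_offset[keep], axis=1)
    grid[:, :, 5] = d[:, None]
    grid[:, :, 6] = profile.semi_major[keep, None]
    grid[:, :, 7] = profile.semi_minor[keep, None]
    return InputTensor(
        grid=grid,
        station_s=lattice.station_s[keep].copy(),
        station_radius=lattice.station_radius[keep].copy(),
        station_curvature=lattice.station_curvature[keep].copy(),
    )


def crop_wss_field(field: WSSField, length_mm: float = 80.0) -> WSSField:
    """Apply the same transition-zone crop to a full-lattice WSS field."""
    keep = crop_slice(field.values.shape[0], length_mm=length_mm)
    s = field.station_s[keep] if field.station_s is not None else None
    return WSSField(values=field.values[keep], station_s=s, meta=dict(field.meta))


# ---------------------------------------------------------------------------
# nearest-neighbor mapping


def map_wss_to_grid(
    sample_points: np.ndarray,
    sample_wss: np.ndarray,
    lattice_xyz: np.ndarray,
) -> WSSField:
    """Assign each grid node the WSS of its nearest sample point (Euclidean);
    exact ties broken by the lowest sample index.

    ``lattice_xyz`` is the (n_ax, n_theta, 3) cropped analysis grid.
    """
    sample_points = np.asarray(sample_points, dtype=float)
    sample_wss = np.asarray(sample_wss, dtype=float)
    if sample_points.ndim != 2 or sample_points.shape[1] != 3:
        raise ShapeError("sample points must be (m, 3)")
    if sample_points.shape[0] == 0:
        raise ValidationError("need at least one sample point")
    if sample_wss.shape[0] != sample_points.shape[0]:
        raise ShapeError("sample point/value count mismatch")
    n_ax, n_th, _ = lattice_xyz.shape
    nodes = lattice_xyz.reshape(-1, 3)
    tree = cKDTree(sample_points)
    k = min(4, sample_points.shape[0])
    dist, idx = tree.query(nodes, k=k)
    if k == 1:
        chosen = idx
    else:
        # among neighbors tied with the nearest (within 1e-12 relative),
        # pick the lowest sample index
        tol = (1e-12 * (1.0 + dist[:, 0]))[:, None]
        tied = dist <= (dist[:, [0]] + tol)
        masked = np.where(tied, idx, np.iinfo(np.int64).max)
        chosen = masked.min(axis=1)
    vals = sample_wss[chosen].reshape(n_ax, n_th)
    return WSSField(values=vals)


# ---------------------------------------------------------------------------
# target normalization

LOG_EPS = 1e-6


class WSSNormalizer:
    """log transform + z-scoring with statistics frozen on the training set:
    ``z = (log(wss + 1e-6) - mean) / sd``."""

    def __init__(self, mean: float, sd: float):
        if sd <= 0 or not np.isfinite(sd):
            raise DegenerateStatisticsError("zero/invalid training variance")
        self.mean = float(mean)
        self.sd = float(sd)

    @classmethod
    def fit(cls, training_fields: np.ndarray) -> "WSSNormalizer":
        """``training_fields``: array of WSS values (any shape), Pa."""
        logs = np.log(np.asarray(training_fields, dtype=float) + LOG_EPS)
        sd = float(logs.std())
        if sd <= 1e-12 * max(abs(float(logs.mean())), 1.0):
            raise DegenerateStatisticsError(
                "constant training targets: normalization undefined"
            )
        return cls(mean=float(logs.mean()), sd=sd)

    def transform(self, wss: np.ndarray) -> np.ndarray:
        return (np.log(np.asarray(wss, dtype=float) + LOG_EPS) - self.mean) / self.sd

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.exp(np.asarray(z, dtype=float) * self.sd + self.mean) - LOG_EPS


def normalize_wss(field: WSSField, normalizer: WSSNormalizer) -> np.ndarray:
    return normalizer.transform(field.values)


# ---------------------------------------------------------------------------
# vessel graph


@dataclass
class VesselGraph:
    """Hybrid grid + spatial-proximity graph over the analysis lattice.

    Edges are stored once per undirected pair (i < j); helper properties
    provide the symmetric sparse operators used by the network layers.
    """

    n_axial: int
    n_theta: int
    grid_edges: np.ndarray       # (E_g, 2) int
    spatial_edges: np.ndarray    # (E_s, 2) int
    edge_weights: np.ndarray     # (E_g + E_s,) in (0, 1]
    node_xyz: np.ndarray         # (N, 3) mm
    length_scale_mm: float = EDGE_LENGTH_SCALE_MM
    node_features: np.ndarray | None = None     # (N, 8)
    node_radius: np.ndarray | None = None       # (N,) station R_eq, mm
    node_curvature: np.ndarray | None = None    # (N,) mm^-1
    node_s: np.ndarray | None = None            # (N,) mm
    node_theta: np.ndarray | None = None        # (N,) rad, angle to curvature plane
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.n_axial * self.n_theta

    @property
    def edges(self) -> np.ndarray:
        if len(self.spatial_edges):
            return np.vstack([self.grid_edges, self.spatial_edges])
        return self.grid_edges

    def adjacency(self, weighted: bool = True) -> sp.csr_matrix:
        key = ("adj", weighted)
        if key not in self._cache:
            e = self.edges
            w = self.edge_weights if weighted else np.ones(len(e))
            n = self.n_nodes
            a = sp.coo_matrix(
                (np.concatenate([w, w]),
                 (np.concatenate([e[:, 0], e[:, 1]]),
                  np.concatenate([e[:, 1], e[:, 0]]))),
                shape=(n, n),
            ).tocsr()
            self._cache[key] = a
        return self._cache[key]

    def gcn_operator(self, weighted: bool = True) -> sp.csr_matrix:
        """Symmetric-normalized adjacency with self-loops:
        ``D^-1/2 (A + I) D^-1/2``."""
        key = ("gcn", weighted)
        if key not in self._cache:
            a = self.adjacency(weighted) + sp.eye(self.n_nodes, format="csr")
            d = np.asarray(a.sum(axis=1)).ravel()
            dinv = 1.0 / np.sqrt(d)
            self._cache[key] = sp.diags(dinv) @ a @ sp.diags(dinv)
        return self._cache[key]

    def mean_operator(self, weighted: bool = True) -> sp.csr_matrix:
        """Row-normalized neighbor aggregation (self excluded); zero rows for
        isolated nodes."""
        key = ("mean", weighted)
        if key not in self._cache:
            a = self.adjacency(weighted)
            d = np.asarray(a.sum(axis=1)).ravel()
            dinv = np.where(d > 0, 1.0 / np.maximum(d, 1e-300), 0.0)
            self._cache[key] = sp.diags(dinv) @ a
        return self._cache[key]


def grid_edge_list(n_axial: int, n_theta: int) -> np.ndarray:
    """8-neighborhood edges with circumferential wrap, no axial wrap,
    each undirected pair listed once."""
    i = np.arange(n_axial)[:, None]
    k = np.arange(n_theta)[None, :]
    nid = (i * n_theta + k)
    edges = []

    def add(src, dst):
        edges.append(np.stack([src.ravel(), dst.ravel()], axis=1))

    # circumferential (k -> k+1 with wrap): one per node, covers all ring edges
    add(nid, i * n_theta + (k + 1) % n_theta)
    # axial (i -> i+1)
    add(nid[:-1], nid[1:])
    # diagonals (i, k) -> (i+1, k+-1)
    add(nid[:-1], (i[:-1] + 1) * n_theta + (k + 1) % n_theta)
    add(nid[:-1], (i[:-1] + 1) * n_theta + (k - 1) % n_theta)
    e = np.vstack(edges)
    return np.sort(e, axis=1)


def build_graph(
    lattice_or_xyz,
    tensor: InputTensor | None = None,
    spatial_radius_mm: float = DEFAULT_SPATIAL_RADIUS_MM,
    max_spatial_degree: int = DEFAULT_MAX_SPATIAL_DEGREE,
    length_scale_mm: float = EDGE_LENGTH_SCALE_MM,
    curvature_angle: np.ndarray | None = None,
) -> VesselGraph:
    """Construct the hybrid vessel graph on the cropped analysis lattice.

    ``lattice_or_xyz`` is either a (n_ax, n_theta, 3) node array (already
    cropped) or a full :class:`SurfaceLattice` (cropped here).  Spatial edges
    connect non-grid-adjacent node pairs within ``spatial_radius_mm``, keeping
    for each node at most ``max_spatial_degree`` nearest candidates.  Both
    ``spatial_radius_mm`` and the weight decay ``length_scale_mm`` are chosen
    relative to the characteristic mesh spacing (0.3 mm / 0.1 mm at the
    standard 0.125 mm axial spacing); coarser presets scale them
    proportionally.
    """
    if spatial_radius_mm <= 0:
        raise ValidationError("spatial_radius must be positive")
    if isinstance(lattice_or_xyz, SurfaceLattice):
        lat = lattice_or_xyz
        keep = crop_slice(lat.n_axial,
                          length_mm=float(lat.station_s[-1] - lat.station_s[0]))
        xyz = lat.node_xyz[keep]
        curv_angle_full = lat.curvature_angle[keep]
    else:
        xyz = np.asarray(lattice_or_xyz, dtype=float)
        curv_angle_full = curvature_angle
    n_ax, n_th, _ = xyz.shape
    nodes = xyz.reshape(-1, 3)
    n = n_ax * n_th

    ge = grid_edge_list(n_ax, n_th)
    grid_set = set(map(tuple, ge))

    tree = cKDTree(nodes)
    pairs = tree.query_pairs(r=spatial_radius_mm, output_type="ndarray")
    if len(pairs):
        pairs = np.sort(pairs, axis=1)
        mask = np.array([tuple(p) not in grid_set for p in pairs])
        pairs = pairs[mask]
    if len(pairs):
        d = np.linalg.norm(nodes[pairs[:, 0]] - nodes[pairs[:, 1]], axis=1)
        order = np.argsort(d, kind="stable")
        degree = np.zeros(n, dtype=int)
        keep_mask = np.zeros(len(pairs), dtype=bool)
        for rank in order:
            a, b = pairs[rank]
            if degree[a] < max_spatial_degree and degree[b] < max_spatial_degree:
                keep_mask[rank] = True
                degree[a] += 1
                degree[b] += 1
        se = pairs[keep_mask]
    else:
        se = np.empty((0, 2), dtype=np.int64)

    # grid edges carry unit weight; spatial edges decay with distance
    if len(se):
        dist = np.linalg.norm(nodes[se[:, 0]] - nodes[se[:, 1]], axis=1)
        weights = np.concatenate(
            [np.ones(len(ge)), np.exp(-dist / length_scale_mm)]
        )
    else:
        weights = np.ones(len(ge))

    graph = VesselGraph(
        n_axial=n_ax,
        n_theta=n_th,
        grid_edges=ge,
        spatial_edges=se,
        edge_weights=weights,
        node_xyz=nodes,
        length_scale_mm=length_scale_mm,
    )
    if tensor is not None:
        if tensor.grid.shape[:2] != (n_ax, n_th):
            raise ShapeError("tensor/lattice shape mismatch")
        graph.node_features = tensor.grid.reshape(n, 8)
        graph.node_radius = np.repeat(tensor.station_radius, n_th)
        graph.node_curvature = np.repeat(tensor.station_curvature, n_th)
        graph.node_s = np.repeat(tensor.station_s, n_th)
        phi = tensor.grid[:, :, 4]
        if curv_angle_full is not None:
            graph.node_theta = (phi - curv_angle_full[:, None]).reshape(n)
        else:
            graph.node_theta = phi.reshape(n)
    return graph


def edge_weight(distance_mm: float) -> float:
    """Exponential-decay edge weight ``exp(-dist/0.1)``."""
    return float(np.exp(-distance_mm / EDGE_LENGTH_SCALE_MM))
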