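"""Core domain containers shared across the pipeline.

Conventions: `RadialGeometry`, `BileParams` and `PressureSolution` are SI
(metres, Pa, mol/m^3); network containers are micrometres, matching how the
reconstructions are reported.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np


# ---------------------------------------------------------------------------
# radial lobule description (SI)
# ---------------------------------------------------------------------------

@dataclass
class RadialGeometry:
    """Radially averaged canalicular geometry across the lobule annulus.

    Attributes
    ----------
    rho : ndarray
        Strictly increasing radii (m), from the central-vein edge ``rho0`` to
        the lobule radius ``L``.
    apical_density : ndarray
        Apical surface area per tissue volume A(rho) (1/m).
    eps_bc : ndarray
        Canalicular volume fraction (dimensionless, < 1).
    r_bc : ndarray
        Effective canalicular radius (m).
    f : ndarray
        Focusing function (free lumen ratio), dimensionless.
    tau : float
        Canalicular tortuosity (>= 1).
    """

    rho: np.ndarray
    apical_density: np.ndarray
    eps_bc: np.ndarray
    r_bc: np.ndarray
    f: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        n = self.rho.size
        for name in ("apical_density", "eps_bc", "r_bc", "f"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim == 0:
                arr = np.full(n, float(arr))
            if arr.size != n:
                raise ValueError(f"{name} has length {arr.size}, grid has {n}")
            setattr(self, name, arr)
        if n < 2:
            raise ValueError("radial grid needs at least 2 points")
        if np.any(np.diff(self.rho) <= 0):
            raise ValueError("radial grid must be strictly increasing")
        if self.rho[0] <= 0:
            raise ValueError("rho0 must be positive")
        for name in ("apical_density", "eps_bc", "r_bc", "f"):
            arr = getattr(self, name)
            if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
                bad = int(np.flatnonzero(~np.isfinite(arr) | (arr <= 0))[0])
                raise ValueError(
                    f"{name} must be finite and positive; offending grid point "
                    f"{bad} at rho = {self.rho[bad]:.6g} m"
                )
        if np.any(self.eps_bc >= 1):
            raise ValueError("eps_bc must be < 1")
        if self.tau < 1:
            raise ValueError("tortuosity must be >= 1")

    @property
    def rho0(self) -> float:
        return float(self.rho[0])

    @property
    def L(self) -> float:
        return float(self.rho[-1])


@dataclass
class BileParams:
    """Physical constants and boundary data of the bile-pressure model (SI).

    ``g`` is the osmolyte secretion rate, either a scalar (constant profile)
    or an array on the geometry grid, in mol/(m^3 s).
    """

    kappa: float
    R: float
    T: float
    c0: float
    mu: float
    p_duct: float
    g: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        for name in ("R", "T", "c0", "mu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        g = np.asarray(self.g, dtype=float)
        if np.any(g < 0):
            raise ValueError("secretion rate g must be non-negative everywhere")

    def g_profile(self, geom: RadialGeometry) -> np.ndarray:
        g = np.asarray(self.g, dtype=float)
        if g.ndim == 0:
            return np.full(geom.rho.size, float(g))
        if g.size != geom.rho.size:
            raise ValueError(
                f"secretion profile length {g.size} does not match grid "
                f"length {geom.rho.size}"
            )
        return g

    @property
    def RT(self) -> float:
        return self.R * self.T


@dataclass
class PressureSolution:
    """Solved radial profiles of the bile-pressure boundary-value problem."""

    rho: np.ndarray  # m
    w: np.ndarray  # radial bulk velocity, m/s
    p: np.ndarray  # canalicular pressure, Pa
    c: np.ndarray  # osmolyte concentration, mol/m^3
    wc: np.ndarray  # canaliculus velocity w/eps_bc, m/s
    G: np.ndarray  # cumulative osmolyte influx, mol/(m^2 s) * m
    K: np.ndarray  # Darcy resistance, Pa s/m^2
    p0: float  # solved central pressure, Pa
    residual: float  # |p(L) - p_duct|, Pa
    iterations: int  # shooting residual evaluations
    dense: Optional[object] = field(default=None, repr=False)  # OdeSolution
    start_offset: float = 0.0  # regularization offset delta (m)


# ---------------------------------------------------------------------------
# spatial canalicular network (micrometres)
# ---------------------------------------------------------------------------

@dataclass
class Landmarks:
    """CV/PV landmark geometry used to define the lobule axis.

    Annulus mode (the synthetic generator's geometry): the central vein runs
    along z through ``cv_center``; the periportal boundary is the ring at
    distance ``pv_edge_radius_um`` from the axis. Two-point mode: ``pv_center``
    is the portal-vein centre and ``pv_vein_radius_um`` its calibre.
    """

    cv_center: np.ndarray
    cv_edge_radius_um: float
    pv_edge_radius_um: Optional[float] = None
    pv_center: Optional[np.ndarray] = None
    pv_vein_radius_um: float = 0.0

    def __post_init__(self) -> None:
        self.cv_center = np.asarray(self.cv_center, dtype=float)
        if self.pv_center is not None:
            self.pv_center = np.asarray(self.pv_center, dtype=float)
        if self.cv_edge_radius_um <= 0:
            raise ValueError("cv_edge_radius_um must be positive")
        if self.pv_edge_radius_um is None and self.pv_center is None:
            raise ValueError("need either pv_edge_radius_um or pv_center")

    @property
    def axis_span_um(self) -> float:
        """CV-edge-to-PV-edge distance (the lobule axis length)."""
        if self.pv_center is not None:
            d = float(np.linalg.norm(self.pv_center - self.cv_center))
            span = d - self.cv_edge_radius_um - self.pv_vein_radius_um
        else:
            span = self.pv_edge_radius_um - self.cv_edge_radius_um
        if span <= 0:
            raise ValueError("coincident or overlapping CV/PV landmarks")
        return span

    def axial_distance_um(self, points: np.ndarray) -> np.ndarray:
        """Distance of each point from the CV edge along the lobule axis."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.pv_center is not None:
            d = np.linalg.norm(pts - self.cv_center, axis=1)
        else:
            d = np.hypot(pts[:, 0] - self.cv_center[0], pts[:, 1] - self.cv_center[1])
        return d - self.cv_edge_radius_um

    def axial_fraction(self, points: np.ndarray) -> np.ndarray:
        """Normalized CV->PV coordinate, clipped to [0, 1]."""
        return np.clip(self.axial_distance_um(points) / self.axis_span_um, 0.0, 1.0)

    @property
    def is_annulus(self) -> bool:
        return self.pv_center is None


@dataclass
class CanalicularNetwork:
    """Spatial canalicular graph: node positions (um), per-edge radius (um).

    Edge lengths are derived from node coordinates at construction and stored
    as the ``length_um`` edge attribute.
    """

    graph: nx.Graph
    landmarks: Landmarks
    tissue_depth_um: float
    strip_width_um: Optional[float] = None  # imaged-strip arc width; None = annulus

    def __post_init__(self) -> None:
        if self.tissue_depth_um <= 0:
            raise ValueError("tissue_depth_um must be positive")
        if self.strip_width_um is not None and self.strip_width_um <= 0:
            raise ValueError("strip_width_um must be positive (or None)")
        g = self.graph
        if any(u == v for u, v in g.edges):
            raise ValueError("network must be a simple graph (self-loop found)")
        pos = {n: np.asarray(d["pos"], dtype=float) for n, d in g.nodes(data=True)}
        for u, v, d in g.edges(data=True):
            r = d.get("radius_um")
            if r is None or r <= 0:
                raise ValueError(f"edge ({u}, {v}) has non-positive radius")
            if "length_um" not in d:
                d["length_um"] = float(np.linalg.norm(pos[u] - pos[v]))
            if d["length_um"] <= 0:
                raise ValueError(f"edge ({u}, {v}) has zero length")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_positions(self) -> tuple[list, np.ndarray]:
        nodes = list(self.graph.nodes)
        pos = np.array([self.graph.nodes[n]["pos"] for n in nodes], dtype=float)
        return nodes, pos

    def edge_arrays(self) -> tuple[list, np.ndarray, np.ndarray, np.ndarray]:
        """Edges with radius, length and 3D midpoint, in graph order."""
        edges = list(self.graph.edges)
        radius = np.array(
            [self.graph.edges[e]["radius_um"] for e in edges], dtype=float
        )
        length = np.array(
            [self.graph.edges[e]["length_um"] for e in edges], dtype=float
        )
        mid = np.array(
            [
                0.5
                * (
                    np.asarray(self.graph.nodes[u]["pos"], dtype=float)
                    + np.asarray(self.graph.nodes[v]["pos"], dtype=float)
                )
                for u, v in edges
            ],
            dtype=float,
        )
        return edges, radius, length, mid

    def total_volume_um3(self) -> float:
        _, r, l, _ = self.edge_arrays()
        return float(np.sum(np.pi * r**2 * l))


@dataclass
class RosetteCounts:
    """Per-zone histogram of rosette radii N_j, j = 3..8 um.

    ``counts[z, k]`` is the number of rosette segments in zone ``z`` whose
    maximal radius lies in [j, j+1) um with j = 3 + k.
    """

    counts: np.ndarray  # (n_zones, 6) integer
    j_values: np.ndarray = field(
        default_factory=lambda: np.arange(3, 9, dtype=float)
    )
    j_off_um: float = 0.2

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != self.j_values.size:
            raise ValueError("counts must be (n_zones, n_bins)")
        if np.any(self.counts < 0):
            raise ValueError("rosette counts must be non-negative")

    @property
    def n_zones(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())
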