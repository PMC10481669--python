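"""Synthetic lobule generators: radial profiles, spatial networks, sections.

These generators emulate the statistical structure of 3D-reconstructed bile
canaliculi networks so the whole pipeline runs without image data: a
cylindrical-annulus lobule (central vein radius rho0, lobule radius L),
zone-dependent canalicular radii around 0.5-1 um diameter dilated in disease,
sparse rosette segments with radii in [3, 8] um, and marker-positive fractions
for Sox9 / pan-CK on 2D sections. Every generator is fully determined by the
config seed.
"""
from __future__ import annotations

import logging
from typing import Optional

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .config import (
    CANALICULAR_TORTUOSITY,
    FREE_LUMEN_RATIO,
    N_ZONES,
    UM,
    SyntheticConfig,
)
from .types import CanalicularNetwork, Landmarks, RadialGeometry

logger = logging.getLogger("biliflow.synthetic")

__all__ = [
    "gen_radial_geometry",
    "gen_network",
    "gen_section_table",
    "gen_lobule_measurements",
    "network_to_geometry",
]

# substream tags so the generators draw from independent streams of one seed
_STREAM_GEOMETRY = 1
_STREAM_NETWORK = 2
_STREAM_SECTIONS = 3
_STREAM_LOBULE = 4


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([abs(int(config.seed)), stream])


def gen_radial_geometry(config: SyntheticConfig) -> RadialGeometry:
    """Radial profiles A, eps_BC, r_BC, f on rho0..L (returned in SI).

    eps_BC carries a mild mid-lobular peak, r_BC a mild periportal increase;
    the disease regime applies the radius dilation factor and the network
    volume-loss factor. The apical surface density is closed with the
    cylinder-bundle identity A = 2 eps_BC / r_BC, and f defaults to the
    constant free lumen ratio 0.28 (an optional linear gradient is available).
    """
    rho_um = np.linspace(config.cv_radius_um, config.lobule_radius_um, config.n_grid)
    t = (rho_um - rho_um[0]) / (rho_um[-1] - rho_um[0])
    eps = (
        config.volume_fraction
        * config.volume_fraction_factor
        * (1.0 + 0.25 * np.sin(np.pi * t))
    )
    if np.any(eps <= 0) or np.any(eps > 0.2):
        raise ValueError("eps_BC profile left (0, 0.2]")
    r_bc_um = config.baseline_radius_um * config.radius_dilation_factor * (1.0 + 0.15 * t)
    if np.any(r_bc_um <= 0):
        raise ValueError("non-positive canalicular radius")
    f = FREE_LUMEN_RATIO * (1.0 + config.focusing_gradient * (t - 0.5))
    a_per_um = 2.0 * eps / r_bc_um  # 1/um
    return RadialGeometry(
        rho=rho_um * UM,
        apical_density=a_per_um / UM,
        eps_bc=eps,
        r_bc=r_bc_um * UM,
        f=np.asarray(f, dtype=float),
        tau=CANALICULAR_TORTUOSITY,
    )


def _annulus_points(
    rng: np.random.Generator, config: SyntheticConfig, n_zones: int
) -> np.ndarray:
    """Volume-uniform points per zone, z uniform over the tissue depth.

    Strip mode (default) emulates the stitched CV->PV tile strip the
    morphometry samples: a wedge of constant arc width, in which the volume
    element is uniform in (rho, y = rho theta, z), so equal per-zone node
    counts mean uniform tissue density. With ``strip_width_um`` unset the
    full annulus is filled (area-uniform per zone ring).
    """
    rho0, L = config.cv_radius_um, config.lobule_radius_um
    edges = np.linspace(rho0, L, n_zones + 1)
    pts = []
    for k in range(n_zones):
        n = config.nodes_per_zone
        if config.strip_width_um is not None:
            r = rng.uniform(edges[k], edges[k + 1], size=n)
            y = rng.uniform(-0.5 * config.strip_width_um,
                            0.5 * config.strip_width_um, size=n)
            theta = y / r
        else:
            r = np.sqrt(rng.uniform(edges[k] ** 2, edges[k + 1] ** 2, size=n))
            theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        z = rng.uniform(0.0, config.tissue_depth_um, size=n)
        pts.append(np.column_stack([r * np.cos(theta), r * np.sin(theta), z]))
    return np.concatenate(pts, axis=0)


def gen_network(config: SyntheticConfig, n_zones: int = N_ZONES) -> CanalicularNetwork:
    """Spatial canalicular graph filling the lobule annulus.

    Construction: area-uniform nodes per zone ring, k-nearest-neighbour edges,
    then the components are stitched into one connected base graph. A seeded
    edge dropout then removes a fraction of edges (emulating the network
    fragmentation seen in disease), and a ``rosette_fraction`` Bernoulli
    subset of the surviving edges is re-assigned radii uniform in the rosette
    range [3, 8] um. Identical config + seed reproduces the graph exactly.
    """
    if config.nodes_per_zone < 2:
        raise ValueError("need at least 2 nodes per zone")
    rng = _rng(config, _STREAM_NETWORK)
    pos = _annulus_points(rng, config, n_zones)
    n = pos.shape[0]

    tree = cKDTree(pos)
    _, idx = tree.query(pos, k=config.knn + 1)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            if i != j:
                edges.add((min(i, int(j)), max(i, int(j))))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(sorted(edges))

    # stitch components into one connected base graph via nearest node pairs
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    main = set(comps[0])
    for comp in comps[1:]:
        main_ids = np.fromiter(main, int)
        sub_ids = np.fromiter(comp, int)
        sub_tree = cKDTree(pos[main_ids])
        d, j = sub_tree.query(pos[sub_ids])
        k = int(np.argmin(d))
        g.add_edge(int(sub_ids[k]), int(main_ids[j[k]]))
        main |= set(comp)

    edge_list = sorted(g.edges)
    n_edges = len(edge_list)

    if config.edge_dropout > 0:
        keep = rng.random(n_edges) >= config.edge_dropout
    else:
        keep = np.ones(n_edges, dtype=bool)
    edge_list = [e for e, k in zip(edge_list, keep) if k]
    n_edges = len(edge_list)

    # baseline radii: multiplicative noise around the (possibly dilated)
    # baseline calibre, kept strictly below the rosette band; radii carry no
    # radial trend, so the per-zone network volume is statistically flat
    # along the axis
    noise = np.clip(rng.normal(1.0, config.radius_noise_cv, size=n_edges), 0.5, 1.5)
    radii = config.baseline_radius_um * config.radius_dilation_factor * noise
    radii = np.clip(radii, 0.05, 2.9)

    is_rosette = np.zeros(n_edges, dtype=bool)
    if config.rosette_fraction > 0:
        lo, hi = config.rosette_radius_range_um
        is_rosette = rng.random(n_edges) < config.rosette_fraction
        radii[is_rosette] = rng.uniform(lo, hi, size=int(is_rosette.sum()))

    # rosette growth consumes neighbouring canaliculi: each baseline edge
    # adjacent to a rosette edge is lost with probability
    # rosette_disconnection, which couples network fragmentation to the
    # local rosette load
    drop_adjacent = np.zeros(n_edges, dtype=bool)
    if config.rosette_disconnection > 0 and is_rosette.any():
        rosette_nodes = set()
        for (u, v), ros in zip(edge_list, is_rosette):
            if ros:
                rosette_nodes.add(u)
                rosette_nodes.add(v)
        for i, (u, v) in enumerate(edge_list):
            if not is_rosette[i] and (u in rosette_nodes or v in rosette_nodes):
                if rng.random() < config.rosette_disconnection:
                    drop_adjacent[i] = True

    out = nx.Graph()
    for i in range(n):
        out.add_node(i, pos=tuple(float(x) for x in pos[i]))
    for (u, v), r, dropped in zip(edge_list, radii, drop_adjacent):
        if dropped:
            continue
        out.add_edge(
            int(u), int(v),
            radius_um=float(r),
            length_um=float(np.linalg.norm(pos[u] - pos[v])),
        )

    landmarks = Landmarks(
        cv_center=np.zeros(3),
        cv_edge_radius_um=config.cv_radius_um,
        pv_edge_radius_um=config.lobule_radius_um,
    )
    return CanalicularNetwork(
        graph=out,
        landmarks=landmarks,
        tissue_depth_um=config.tissue_depth_um,
        strip_width_um=config.strip_width_um,
    )


def gen_section_table(config: SyntheticConfig):
    """2D section table mixing rosette, normal-lumen and duct-like rows.

    Rosette rows satisfy the counting rule (diameter > 6 um and > 2 bounding
    cells); with probability ``sox9_positive_fraction`` one bounding cell's
    Sox9 nuclear intensity is drawn above the 200 threshold (independently
    for pan-CK above 1000). Normal lumina are sub-threshold on both rules and
    duct-like rows are wide but bounded by only 2 cells, so the rule must
    reject them. Per-cell intensities are ';'-joined in the CSV-friendly
    columns.
    """
    import pandas as pd

    rng = _rng(config, _STREAM_SECTIONS)
    rows = []

    def intensity_string(values: np.ndarray) -> str:
        return ";".join(format(float(v), ".6g") for v in values)

    for _ in range(config.n_rosette_lumina):
        n_cells = int(rng.integers(3, 7))
        diameter = float(rng.uniform(6.5, 16.0))
        sox9 = rng.uniform(20.0, 150.0, size=n_cells)
        if rng.random() < config.sox9_positive_fraction:
            sox9[rng.integers(n_cells)] = rng.uniform(250.0, 800.0)
        panck = rng.uniform(50.0, 800.0, size=n_cells)
        if rng.random() < config.panck_positive_fraction:
            panck[rng.integers(n_cells)] = rng.uniform(1100.0, 3000.0)
        rows.append((diameter, n_cells, sox9, panck))

    for _ in range(config.n_normal_lumina):
        n_cells = 2
        diameter = float(rng.uniform(0.5, 1.5))
        rows.append(
            (diameter, n_cells, rng.uniform(20.0, 150.0, 2), rng.uniform(50.0, 800.0, 2))
        )

    for _ in range(config.n_duct_like_lumina):
        n_cells = 2
        diameter = float(rng.uniform(7.0, 15.0))
        rows.append(
            (diameter, n_cells, rng.uniform(150.0, 700.0, 2), rng.uniform(900.0, 3000.0, 2))
        )

    order = rng.permutation(len(rows))
    records = []
    for new_id, k in enumerate(order):
        diameter, n_cells, sox9, panck = rows[k]
        records.append(
            {
                "lumen_id": new_id,
                "diameter_um": diameter,
                "n_bounding_cells": n_cells,
                "sox9_nuclear_intensity": intensity_string(np.atleast_1d(sox9)),
                "panck_cellular_intensity": intensity_string(np.atleast_1d(panck)),
                "section_area_mm2": config.section_area_mm2,
            }
        )
    return pd.DataFrame.from_records(records)


def gen_lobule_measurements(
    config: SyntheticConfig, n_axes: int = 12
) -> np.ndarray:
    """CV-edge-to-PV-edge distance measurements for one synthetic sample (um)."""
    if n_axes < 1:
        raise ValueError("need at least one axis measurement")
    rng = _rng(config, _STREAM_LOBULE)
    span = config.lobule_radius_um
    vals = rng.normal(span, 0.08 * span, size=n_axes)
    return np.clip(vals, 0.2 * span, None)


def network_to_geometry(
    net: CanalicularNetwork,
    tissue_depth_um: Optional[float] = None,
    n_shells: int = 22,
    sector_angle: float = 2.0 * np.pi,
    f: float = FREE_LUMEN_RATIO,
    tau: float = CANALICULAR_TORTUOSITY,
    clamp_diameter_above_um: Optional[float] = 6.0,
) -> RadialGeometry:
    """Radial profiles measured from a spatial network (annulus landmarks).

    Edges are assigned to equal-width radial shells by midpoint; per shell
    eps_BC = sum(pi r^2 l) / V_shell, A = sum(2 pi r l) / V_shell and r_BC is
    the volume-weighted mean edge radius. Empty shells are filled by linear
    interpolation from neighbouring shells with a logged warning. The grid is
    extended to the exact annulus bounds rho0 and L by edge-value extension.

    Rosette-band segments (diameter above ``clamp_diameter_above_um``) enter
    the conducting profiles at the median baseline calibre: the porous-medium
    resistance model describes narrow canaliculi, and the volume-weighted
    effective radius would otherwise be dominated by a handful of
    pathologically dilated segments, while removing them entirely would leave
    artificial conductance gaps. Pass ``None`` to aggregate raw radii.
    """
    if not net.landmarks.is_annulus:
        raise ValueError("network_to_geometry requires annulus landmarks")
    depth = tissue_depth_um if tissue_depth_um is not None else net.tissue_depth_um
    if depth <= 0:
        raise ValueError("tissue depth must be positive")
    if n_shells < 2:
        raise ValueError("need at least 2 shells")

    rho0 = net.landmarks.cv_edge_radius_um
    L = net.landmarks.pv_edge_radius_um
    _, radius, length, mid = net.edge_arrays()
    if radius.size == 0:
        raise ValueError("network has no edges to aggregate")
    if clamp_diameter_above_um is not None:
        wide = 2.0 * radius > clamp_diameter_above_um
        if wide.all():
            raise ValueError("no baseline-calibre edges to clamp against")
        if wide.any():
            radius = radius.copy()
            radius[wide] = float(np.median(radius[~wide]))
    s = np.hypot(mid[:, 0] - net.landmarks.cv_center[0],
                 mid[:, 1] - net.landmarks.cv_center[1])
    edges_r = np.linspace(rho0, L, n_shells + 1)
    shell = np.clip(
        ((s - rho0) / (L - rho0) * n_shells).astype(int), 0, n_shells - 1
    )

    vol = np.pi * radius**2 * length
    area = 2.0 * np.pi * radius * length
    if net.strip_width_um is not None:
        shell_vol = net.strip_width_um * np.diff(edges_r) * depth
    else:
        shell_vol = (
            (sector_angle / 2.0) * (edges_r[1:] ** 2 - edges_r[:-1] ** 2) * depth
        )

    eps = np.zeros(n_shells)
    a = np.zeros(n_shells)
    r_vw = np.full(n_shells, np.nan)
    for k in range(n_shells):
        sel = shell == k
        if not np.any(sel):
            continue
        eps[k] = vol[sel].sum() / shell_vol[k]
        a[k] = area[sel].sum() / shell_vol[k]
        r_vw[k] = np.sum(radius[sel] * vol[sel]) / vol[sel].sum()

    empty = np.isnan(r_vw) | (eps <= 0)
    if np.all(empty):
        raise ValueError("every radial shell is empty")
    if np.any(empty):
        logger.warning(
            "WARN interpolating %d empty radial shell(s) out of %d",
            int(empty.sum()), n_shells,
        )
        centers = 0.5 * (edges_r[:-1] + edges_r[1:])
        ok = ~empty
        for arr in (eps, a, r_vw):
            arr[empty] = np.interp(centers[empty], centers[ok], arr[ok])

    centers = 0.5 * (edges_r[:-1] + edges_r[1:])
    rho_um = np.concatenate([[rho0], centers, [L]])
    eps_g = np.concatenate([[eps[0]], eps, [eps[-1]]])
    a_g = np.concatenate([[a[0]], a, [a[-1]]])
    r_g = np.concatenate([[r_vw[0]], r_vw, [r_vw[-1]]])
    return RadialGeometry(
        rho=rho_um * UM,
        apical_density=a_g / UM,
        eps_bc=eps_g,
        r_bc=r_g * UM,
        f=np.full(rho_um.size, f),
        tau=tau,
    )
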