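"""Zone-resolved morphometry of spatial canalicular networks.

The CV-PV axis is split into equal-width zones (0 pericentral .. 10
periportal by default). Nodes are zoned by their normalized straight-line
CV-edge coordinate, edges by their midpoint. Per zone the module reports the
length-weighted mean radius, lumen volume fraction, surface area per tissue
volume, connectivity (1 / number of disjoint components), boundary-crossing
branch density and junction density.
"""
from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import N_ZONES
from .types import CanalicularNetwork

logger = logging.getLogger("biliflow.netquant")

__all__ = [
    "assign_zones",
    "zone_statistics",
    "sample_median_lobule_radius",
    "lobule_radius_summary",
]


def assign_zones(
    net: CanalicularNetwork, n_zones: int = N_ZONES
) -> tuple[dict, dict]:
    """Zone labels (0..n_zones-1) for nodes and edges.

    Nodes bin by their normalized CV->PV coordinate; edges by midpoint.
    Values at the periportal boundary clamp into the last zone.
    """
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    span = net.landmarks.axis_span_um  # raises on coincident landmarks
    nodes, pos = net.node_positions()
    t = net.landmarks.axial_fraction(pos)
    labels = np.minimum((t * n_zones).astype(int), n_zones - 1)
    node_zones = dict(zip(nodes, (int(z) for z in labels)))

    edges, _, _, mid = net.edge_arrays()
    tm = net.landmarks.axial_fraction(mid) if len(edges) else np.empty(0)
    elabels = np.minimum((tm * n_zones).astype(int), n_zones - 1)
    edge_zones = {e: int(z) for e, z in zip(edges, elabels)}
    return node_zones, edge_zones


def _zone_tissue_volumes_um3(
    net: CanalicularNetwork, n_zones: int, sector_angle: float
) -> np.ndarray:
    lm = net.landmarks
    if not lm.is_annulus:
        raise ValueError(
            "zone tissue volumes require annulus landmarks; pass "
            "zone_tissue_volumes_um3 explicitly for two-point landmarks"
        )
    edges = np.linspace(lm.cv_edge_radius_um, lm.pv_edge_radius_um, n_zones + 1)
    if net.strip_width_um is not None:
        return net.strip_width_um * np.diff(edges) * net.tissue_depth_um
    return (sector_angle / 2.0) * (edges[1:] ** 2 - edges[:-1] ** 2) * net.tissue_depth_um


def zone_statistics(
    net: CanalicularNetwork,
    n_zones: int = N_ZONES,
    zones: Optional[tuple[dict, dict]] = None,
    sector_angle: float = 2.0 * np.pi,
    zone_tissue_volumes_um3: Optional[Sequence[float]] = None,
    boundary_areas_um2: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Per-zone network statistics as one DataFrame row per zone.

    Columns: ``mean_radius_um`` (length-weighted), ``volume_fraction_pct``,
    ``surface_to_volume_um2_per_mm3``, ``connectivity`` (1/#components of the
    zone-induced edge subgraph), ``crossings_per_mm2`` (edges whose endpoint
    zones straddle this zone's CV-side boundary, per boundary area),
    ``junctions_per_um`` (degree>=3 nodes per zone network length), plus raw
    ``n_edges``, ``n_nodes``, ``network_volume_um3``, ``network_length_um``.
    Zones without edges carry NaN statistics and log a warning.
    """
    node_zones, edge_zones = zones if zones is not None else assign_zones(net, n_zones)

    edges, radius, length, _ = net.edge_arrays()
    ez = np.array([edge_zones[e] for e in edges], dtype=int) if edges else np.empty(0, int)

    if zone_tissue_volumes_um3 is None:
        zone_vol = _zone_tissue_volumes_um3(net, n_zones, sector_angle)
    else:
        zone_vol = np.asarray(zone_tissue_volumes_um3, dtype=float)
        if zone_vol.size != n_zones:
            raise ValueError("zone_tissue_volumes_um3 length mismatch")

    lm = net.landmarks
    if boundary_areas_um2 is None:
        if net.strip_width_um is not None:
            boundary = np.full(
                n_zones - 1, net.strip_width_um * net.tissue_depth_um
            )
        elif lm.is_annulus:
            span = lm.axis_span_um
            br = lm.cv_edge_radius_um + np.arange(1, n_zones) * span / n_zones
            boundary = sector_angle * br * net.tissue_depth_um  # arc * depth
        else:
            boundary = np.full(n_zones - 1, np.nan)
    else:
        boundary = np.asarray(boundary_areas_um2, dtype=float)
        if boundary.size != n_zones - 1:
            raise ValueError("boundary_areas_um2 must have n_zones - 1 entries")

    degrees = dict(net.graph.degree)
    # vectorized helpers: endpoint zones per edge, junction zones per node
    if edges:
        zu = np.array([node_zones[u] for u, _ in edges], dtype=int)
        zv = np.array([node_zones[v] for _, v in edges], dtype=int)
        zlo, zhi = np.minimum(zu, zv), np.maximum(zu, zv)
    else:
        zlo = zhi = np.empty(0, int)
    node_zone_values = np.fromiter(node_zones.values(), int, len(node_zones))
    junction_mask = np.fromiter(
        (degrees.get(n, 0) >= 3 for n in node_zones), bool, len(node_zones)
    )

    records = []
    for z in range(n_zones):
        sel = ez == z
        n_e = int(sel.sum())
        n_zone_nodes = int(np.sum(node_zone_values == z))
        if n_e == 0:
            logger.warning("WARN zone %d holds no edges; statistics set to NaN", z)
            records.append(
                dict(
                    zone=z, mean_radius_um=np.nan, volume_fraction_pct=np.nan,
                    surface_to_volume_um2_per_mm3=np.nan, connectivity=np.nan,
                    crossings_per_mm2=np.nan, junctions_per_um=np.nan,
                    n_edges=0, n_nodes=n_zone_nodes,
                    network_volume_um3=0.0, network_length_um=0.0,
                )
            )
            continue
        r, l = radius[sel], length[sel]
        net_vol = float(np.sum(np.pi * r**2 * l))
        net_area = float(np.sum(2.0 * np.pi * r * l))
        net_len = float(l.sum())
        mean_radius = float(np.sum(r * l) / net_len)

        sub = nx.Graph()
        sub.add_edges_from(e for e, s in zip(edges, sel) if s)
        n_comp = nx.number_connected_components(sub)

        if z == 0:
            crossings = np.nan  # zone 0 has no CV-side boundary
        else:
            cnt = int(np.sum((zlo < z) & (z <= zhi)))
            area = boundary[z - 1]
            crossings = cnt / (area * 1e-6) if np.isfinite(area) and area > 0 else np.nan

        n_junctions = int(np.sum(junction_mask & (node_zone_values == z)))

        records.append(
            dict(
                zone=z,
                mean_radius_um=mean_radius,
                volume_fraction_pct=100.0 * net_vol / zone_vol[z],
                surface_to_volume_um2_per_mm3=net_area / zone_vol[z] * 1e9,
                connectivity=1.0 / n_comp,
                crossings_per_mm2=crossings,
                junctions_per_um=n_junctions / net_len,
                n_edges=n_e,
                n_nodes=n_zone_nodes,
                network_volume_um3=net_vol,
                network_length_um=net_len,
            )
        )
    return pd.DataFrame.from_records(records).set_index("zone")


def sample_median_lobule_radius(measurements_um: Sequence[float]) -> float:
    """Median CV-edge-to-PV-edge distance for one sample.

    Even counts take the mean of the middle pair (the standard median).
    """
    arr = np.asarray(list(measurements_um), dtype=float)
    if arr.size == 0:
        raise ValueError("no lobule radius measurements supplied")
    if np.any(arr <= 0):
        raise ValueError("lobule radius measurements must be positive")
    return float(np.median(arr))


def lobule_radius_summary(
    measurements_by_sample: Mapping[str, Sequence[float]],
) -> tuple[dict[str, float], float]:
    """Per-sample median lobule radii and their cohort mean."""
    if not measurements_by_sample:
        raise ValueError("no samples supplied")
    medians = {
        k: sample_median_lobule_radius(v) for k, v in measurements_by_sample.items()
    }
    return medians, float(np.mean(list(medians.values())))
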