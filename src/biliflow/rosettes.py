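"""Rosette detection, volume estimation and 2D-section counting.

Liver cell rosettes are aberrant canalicular lumina wider than 6 um in
diameter, bounded by more than two hepatocytes. In 3D they are contiguous
super-threshold runs of network segments; their volume is estimated from the
per-zone radius histogram N_j (j = 3..8 um) as

    V = sum_j (4/3) pi (j + j_off)^3 N_j,   j_off = 0.2 um,

reflecting that segments binned at [j, j+1) average above j. On 2D sections
rosettes are counted by the diameter > 6 um AND > 2 bounding hepatocytes rule,
and classified Sox9+/pan-CK+ if any bounding cell exceeds the respective
intensity threshold.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import (
    N_ZONES,
    PANCK_CELLULAR_THRESHOLD,
    ROSETTE_BIN_MAX_UM,
    ROSETTE_BIN_MIN_UM,
    ROSETTE_BIN_OFFSET_UM,
    ROSETTE_DIAMETER_THRESHOLD_UM,
    ROSETTE_MIN_CELLS,
    SOX9_NUCLEAR_THRESHOLD,
)
from .netquant import assign_zones
from .types import CanalicularNetwork, RosetteCounts

logger = logging.getLogger("biliflow.rosettes")

__all__ = [
    "RosetteSegment",
    "detect_rosettes",
    "rosette_volume",
    "rosette_network_ratio",
    "count_rosettes_2d",
    "classify_rosette_markers",
    "Rosette2DSummary",
]


@dataclass
class RosetteSegment:
    """One contiguous run of super-threshold edges."""

    edges: list
    max_radius_um: float
    zone: int
    j_bin: int


def detect_rosettes(
    net: CanalicularNetwork,
    diameter_threshold_um: float = ROSETTE_DIAMETER_THRESHOLD_UM,
    n_zones: int = N_ZONES,
    zones: Optional[tuple[dict, dict]] = None,
    merge_adjacent: bool = True,
) -> tuple[list[RosetteSegment], RosetteCounts]:
    """Rosette segments (strictly > 6 um diameter) and per-zone N_j histogram.

    Adjacent super-threshold edges merge into a single segment by default
    (configurable); each segment is characterized by its maximal edge radius,
    binned into j = 3..8 (radii >= 9 um clamp into the top bin with a
    warning), and assigned the zone of its maximal-radius edge.
    """
    node_zones, edge_zones = zones if zones is not None else assign_zones(net, n_zones)
    edges, radius, _, _ = net.edge_arrays()
    radius_threshold = diameter_threshold_um / 2.0
    super_idx = [i for i, r in enumerate(radius) if r > radius_threshold]

    segments: list[RosetteSegment] = []
    if super_idx:
        if merge_adjacent:
            sub = nx.Graph()
            for i in super_idx:
                u, v = edges[i]
                sub.add_edge(u, v, idx=i)
            groups = [
                [d["idx"] for _, _, d in sub.subgraph(c).edges(data=True)]
                for c in nx.connected_components(sub)
            ]
        else:
            groups = [[i] for i in super_idx]
        for grp in groups:
            k = grp[int(np.argmax(radius[grp]))]
            rmax = float(radius[k])
            j = int(np.floor(rmax))
            if rmax >= ROSETTE_BIN_MAX_UM + 1:
                logger.warning(
                    "WARN rosette radius %.2f um exceeds the top histogram bin; "
                    "clamped into j = %d", rmax, ROSETTE_BIN_MAX_UM,
                )
                j = ROSETTE_BIN_MAX_UM
            j = min(max(j, ROSETTE_BIN_MIN_UM), ROSETTE_BIN_MAX_UM)
            segments.append(
                RosetteSegment(
                    edges=[edges[i] for i in grp],
                    max_radius_um=rmax,
                    zone=edge_zones[edges[k]],
                    j_bin=j,
                )
            )

    counts = np.zeros(
        (n_zones, ROSETTE_BIN_MAX_UM - ROSETTE_BIN_MIN_UM + 1), dtype=int
    )
    for seg in segments:
        counts[seg.zone, seg.j_bin - ROSETTE_BIN_MIN_UM] += 1
    return segments, RosetteCounts(counts=counts, j_off_um=ROSETTE_BIN_OFFSET_UM)


def rosette_volume(counts: RosetteCounts) -> tuple[np.ndarray, float]:
    """Estimated rosette volume per zone and in total (um^3).

    V = sum_j (4/3) pi (j + j_off)^3 N_j, evaluated exactly.
    """
    if np.any(counts.counts < 0):
        raise ValueError("rosette counts must be non-negative")
    sphere = (4.0 / 3.0) * np.pi * (counts.j_values + counts.j_off_um) ** 3
    per_zone = counts.counts.astype(float) @ sphere
    return per_zone, float(per_zone.sum())


def rosette_network_ratio(
    rosette_volume_per_zone: Sequence[float],
    network_volume_per_zone: Sequence[float],
) -> np.ndarray:
    """Elementwise rosette / network volume ratio; NaN where the network is empty."""
    v = np.asarray(rosette_volume_per_zone, dtype=float)
    n = np.asarray(network_volume_per_zone, dtype=float)
    if v.shape != n.shape:
        raise ValueError(f"zone-count mismatch: {v.shape} vs {n.shape}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n > 0, v / n, np.nan)
    return ratio


# ---------------------------------------------------------------------------
# 2D section quantification
# ---------------------------------------------------------------------------

def _parse_intensities(value) -> np.ndarray:
    if isinstance(value, str):
        return np.array([float(x) for x in value.split(";") if x != ""])
    return np.atleast_1d(np.asarray(value, dtype=float))


def _rosette_mask(
    sections: pd.DataFrame, diameter_threshold_um: float, min_cells: int
) -> pd.Series:
    return (sections["diameter_um"] > diameter_threshold_um) & (
        sections["n_bounding_cells"] > min_cells
    )


@dataclass
class Rosette2DSummary:
    count: int
    mean_diameter_um: float
    count_per_mm2: float


def count_rosettes_2d(
    sections: pd.DataFrame,
    diameter_threshold_um: float = ROSETTE_DIAMETER_THRESHOLD_UM,
    min_cells: int = ROSETTE_MIN_CELLS,
) -> Rosette2DSummary:
    """Count lumina with diameter > 6 um formed by > 2 hepatocytes.

    Both inequalities are strict; ties are excluded. Density normalizes by the
    total section area (summed over distinct per-row areas, i.e. sections).
    """
    total_area = float(sections["section_area_mm2"].unique().sum())
    if total_area <= 0:
        raise ValueError("total section area must be positive")
    mask = _rosette_mask(sections, diameter_threshold_um, min_cells)
    count = int(mask.sum())
    mean_d = float(sections.loc[mask, "diameter_um"].mean()) if count else float("nan")
    return Rosette2DSummary(
        count=count, mean_diameter_um=mean_d, count_per_mm2=count / total_area
    )


def classify_rosette_markers(
    sections: pd.DataFrame,
    sox9_threshold: float = SOX9_NUCLEAR_THRESHOLD,
    panck_threshold: float = PANCK_CELLULAR_THRESHOLD,
    diameter_threshold_um: float = ROSETTE_DIAMETER_THRESHOLD_UM,
    min_cells: int = ROSETTE_MIN_CELLS,
) -> dict[str, float]:
    """Marker-positive fractions over detected rosettes.

    A rosette is Sox9+ (pan-CK+) if ANY bounding cell exceeds the nuclear
    Sox9 (cellular pan-CK) threshold, strictly. With no detected rosettes the
    fractions are reported as NaN.
    """
    mask = _rosette_mask(sections, diameter_threshold_um, min_cells)
    rosettes = sections.loc[mask]
    n = len(rosettes)
    if n == 0:
        logger.warning("WARN no rosettes detected; marker fractions undefined")
        return {"n_rosettes": 0, "sox9_positive_fraction": float("nan"),
                "panck_positive_fraction": float("nan")}
    sox9_pos = sum(
        _parse_intensities(v).max() > sox9_threshold
        for v in rosettes["sox9_nuclear_intensity"]
    )
    panck_pos = sum(
        _parse_intensities(v).max() > panck_threshold
        for v in rosettes["panck_cellular_intensity"]
    )
    return {
        "n_rosettes": n,
        "sox9_positive_fraction": sox9_pos / n,
        "panck_positive_fraction": panck_pos / n,
    }
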