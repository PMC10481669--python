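"""Readers and writers: GraphML / CSV networks, TSV profiles, JSON config.

All readers validate rather than coerce: self-loops, non-positive radii and
non-monotone radial grids are rejected with context. Writers emit a
provenance comment (tool version, config hash, seed) where the format admits
comments.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .config import UM, RunConfig
from .types import BileParams, CanalicularNetwork, Landmarks, PressureSolution, RadialGeometry

logger = logging.getLogger("biliflow.io")

__all__ = [
    "read_network",
    "write_network_graphml",
    "read_network_graphml",
    "write_network_csv",
    "read_network_csv",
    "write_geometry",
    "read_geometry",
    "write_solution",
    "read_run_config",
    "write_run_config",
    "read_bile_params",
]


def _provenance_line(seed: Optional[int] = None, cfg_hash: Optional[str] = None) -> str:
    parts = [f"biliflow {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config={cfg_hash}")
    return " | ".join(parts)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _landmarks_to_attrs(lm: Landmarks) -> dict:
    attrs = {
        "cv_center": json.dumps([float(x) for x in lm.cv_center]),
        "cv_edge_radius_um": float(lm.cv_edge_radius_um),
    }
    if lm.pv_edge_radius_um is not None:
        attrs["pv_edge_radius_um"] = float(lm.pv_edge_radius_um)
    if lm.pv_center is not None:
        attrs["pv_center"] = json.dumps([float(x) for x in lm.pv_center])
        attrs["pv_vein_radius_um"] = float(lm.pv_vein_radius_um)
    return attrs


def _landmarks_from_attrs(attrs: dict) -> Landmarks:
    return Landmarks(
        cv_center=np.array(json.loads(attrs["cv_center"])),
        cv_edge_radius_um=float(attrs["cv_edge_radius_um"]),
        pv_edge_radius_um=(
            float(attrs["pv_edge_radius_um"]) if "pv_edge_radius_um" in attrs else None
        ),
        pv_center=(
            np.array(json.loads(attrs["pv_center"])) if "pv_center" in attrs else None
        ),
        pv_vein_radius_um=float(attrs.get("pv_vein_radius_um", 0.0)),
    )


def write_network_graphml(net: CanalicularNetwork, path: str | Path) -> None:
    g = nx.Graph()
    g.graph.update(_landmarks_to_attrs(net.landmarks))
    g.graph["tissue_depth_um"] = float(net.tissue_depth_um)
    if net.strip_width_um is not None:
        g.graph["strip_width_um"] = float(net.strip_width_um)
    g.graph["provenance"] = _provenance_line()
    for n, d in net.graph.nodes(data=True):
        x, y, z = (float(v) for v in d["pos"])
        g.add_node(n, x=x, y=y, z=z)
    for u, v, d in net.graph.edges(data=True):
        g.add_edge(u, v, radius_um=float(d["radius_um"]))
    nx.write_graphml(g, str(path))


def read_network_graphml(path: str | Path) -> CanalicularNetwork:
    raw = nx.read_graphml(str(path), node_type=int)
    g = nx.Graph()
    for n, d in raw.nodes(data=True):
        try:
            g.add_node(n, pos=(float(d["x"]), float(d["y"]), float(d["z"])))
        except KeyError as err:
            raise ValueError(f"node {n} lacks coordinate attribute {err}") from err
    for u, v, d in raw.edges(data=True):
        if u == v:
            raise ValueError(f"self-loop at node {u}")
        r = float(d.get("radius_um", -1.0))
        if r <= 0:
            raise ValueError(f"edge ({u}, {v}) has non-positive radius {r}")
        g.add_edge(u, v, radius_um=r)
    strip = raw.graph.get("strip_width_um")
    return CanalicularNetwork(
        graph=g,
        landmarks=_landmarks_from_attrs(raw.graph),
        tissue_depth_um=float(raw.graph["tissue_depth_um"]),
        strip_width_um=float(strip) if strip is not None else None,
    )


def write_network_csv(
    net: CanalicularNetwork,
    nodes_path: str | Path,
    edges_path: str | Path,
    landmarks_path: str | Path,
) -> None:
    nodes, pos = net.node_positions()
    pd.DataFrame(
        {"id": nodes, "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2]}
    ).to_csv(nodes_path, index=False)
    edges, radius, _, _ = net.edge_arrays()
    pd.DataFrame(
        {"u": [e[0] for e in edges], "v": [e[1] for e in edges], "radius_um": radius}
    ).to_csv(edges_path, index=False)
    meta = _landmarks_to_attrs(net.landmarks)
    meta["tissue_depth_um"] = float(net.tissue_depth_um)
    if net.strip_width_um is not None:
        meta["strip_width_um"] = float(net.strip_width_um)
    meta["provenance"] = _provenance_line()
    with open(landmarks_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def read_network_csv(
    nodes_path: str | Path,
    edges_path: str | Path,
    landmarks_path: str | Path,
) -> CanalicularNetwork:
    nodes = pd.read_csv(nodes_path)
    edges = pd.read_csv(edges_path)
    for col in ("id", "x", "y", "z"):
        if col not in nodes.columns:
            raise ValueError(f"node table lacks column {col!r}")
    for col in ("u", "v", "radius_um"):
        if col not in edges.columns:
            raise ValueError(f"edge table lacks column {col!r}")
    g = nx.Graph()
    for row in nodes.itertuples(index=False):
        g.add_node(int(row.id), pos=(float(row.x), float(row.y), float(row.z)))
    for i, row in enumerate(edges.itertuples(index=False)):
        u, v = int(row.u), int(row.v)
        if u == v:
            raise ValueError(f"self-loop in edge row {i} (node {u})")
        if row.radius_um <= 0:
            raise ValueError(f"non-positive radius in edge row {i}")
        if u not in g or v not in g:
            raise ValueError(f"edge row {i} references unknown node")
        g.add_edge(u, v, radius_um=float(row.radius_um))
    with open(landmarks_path) as fh:
        meta = json.load(fh)
    return CanalicularNetwork(
        graph=g,
        landmarks=_landmarks_from_attrs(meta),
        tissue_depth_um=float(meta["tissue_depth_um"]),
        strip_width_um=meta.get("strip_width_um"),
    )


def read_network(path: str | Path, **kwargs) -> CanalicularNetwork:
    """Dispatch on extension: .graphml, or a nodes CSV plus edges/landmarks."""
    p = Path(path)
    if p.suffix == ".graphml":
        return read_network_graphml(p)
    if p.suffix == ".csv":
        edges = kwargs.get("edges_path")
        landmarks = kwargs.get("landmarks_path")
        if edges is None or landmarks is None:
            raise ValueError("CSV networks need edges_path and landmarks_path")
        return read_network_csv(p, edges, landmarks)
    raise ValueError(f"unrecognized network format: {p.suffix!r}")


# ---------------------------------------------------------------------------
# radial profiles and solutions (TSV, interface units um / Pa / mmol/l)
# ---------------------------------------------------------------------------

def write_geometry(
    geom: RadialGeometry,
    path: str | Path,
    seed: Optional[int] = None,
    cfg_hash: Optional[str] = None,
) -> None:
    header = [
        f"# {_provenance_line(seed, cfg_hash)}",
        f"# tau={geom.tau!r}",
        f"# rho0_um={geom.rho0 / UM!r}",
        f"# L_um={geom.L / UM!r}",
        "rho_um\tA_per_um\teps_bc\tr_bc_um\tf",
    ]
    rows = np.column_stack(
        [geom.rho / UM, geom.apical_density * UM, geom.eps_bc, geom.r_bc / UM, geom.f]
    )
    body = "\n".join("\t".join(format(v, ".17g") for v in row) for row in rows)
    Path(path).write_text("\n".join(header) + "\n" + body + "\n")


def read_geometry(path: str | Path) -> RadialGeometry:
    tau = None
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("#"):
            if "tau=" in line:
                tau = float(line.split("tau=")[1].strip())
            continue
        data_lines.append(line)
    if not data_lines:
        raise ValueError("empty geometry file")
    cols = data_lines[0].strip().split("\t")
    required = ["rho_um", "A_per_um", "eps_bc", "r_bc_um", "f"]
    if cols != required:
        raise ValueError(f"geometry file needs columns {required}, found {cols}")
    if tau is None:
        raise ValueError("geometry file lacks the '# tau=' header line")
    arr = np.array(
        [[float(x) for x in line.split("\t")] for line in data_lines[1:]]
    )
    rho = arr[:, 0]
    if np.any(np.diff(rho) <= 0):
        raise ValueError("radial grid in file is not strictly increasing")
    return RadialGeometry(
        rho=rho * UM,
        apical_density=arr[:, 1] / UM,
        eps_bc=arr[:, 2],
        r_bc=arr[:, 3] * UM,
        f=arr[:, 4],
        tau=tau,
    )


def write_solution(
    sol: PressureSolution,
    path: str | Path,
    seed: Optional[int] = None,
    cfg_hash: Optional[str] = None,
) -> None:
    header = [
        f"# {_provenance_line(seed, cfg_hash)}",
        f"# p0_pa={sol.p0!r} residual_pa={sol.residual!r} iterations={sol.iterations}",
        "rho_um\tw_m_s\tp_pa\tc_mmol_l\twc_m_s",
    ]
    rows = np.column_stack([sol.rho / UM, sol.w, sol.p, sol.c, sol.wc])
    body = "\n".join("\t".join(format(v, ".17g") for v in row) for row in rows)
    Path(path).write_text("\n".join(header) + "\n" + body + "\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def read_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = json.load(fh)
    return RunConfig.model_validate(data)  # rejects unknown keys


def write_run_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.model_dump(mode="json"), fh, indent=2, sort_keys=True)


def read_bile_params(path: str | Path, p_duct: float, geom_grid_len: int) -> BileParams:
    """Bile parameter JSON (keys kappa, R, T, c0, mu, g_const) -> BileParams."""
    with open(path) as fh:
        data = json.load(fh)
    g = data.pop("g_const", 0.0)
    allowed = {"kappa", "R", "T", "c0", "mu"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown bile parameter keys: {sorted(unknown)}")
    return BileParams(p_duct=p_duct, g=g, **data)
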