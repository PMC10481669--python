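"""Shared fixtures: hand-built toy networks and canonical synthetic inputs."""
from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

import biliflow as bf
from biliflow.types import CanalicularNetwork, Landmarks

# the hand-built lobule: annulus landmarks rho0 = 10 um, L = 120 um, so with
# 11 zones every zone is 10 um wide and zone membership is readable off the
# node coordinates
TOY_NODES = {
    0: (12.0, 0.0, 0.0),
    1: (18.0, 0.0, 0.0),
    2: (25.0, 0.0, 0.0),
    3: (33.0, 0.0, 5.0),
    4: (37.0, 0.0, 5.0),
    5: (52.0, 0.0, 0.0),
    6: (58.0, 0.0, 0.0),
    7: (56.0, 3.0, 4.0),
    8: (115.0, 0.0, 0.0),
    9: (118.0, 2.0, 0.0),
    10: (14.0, 2.0, 1.0),
    11: (63.0, 0.0, 0.0),
}
TOY_EDGES = [
    (0, 1, 0.5),
    (0, 10, 0.55),
    (1, 10, 0.5),
    (1, 2, 0.7),
    (2, 3, 4.0),  # rosette band, adjacent to the next edge
    (3, 4, 5.0),  # rosette band
    (4, 5, 0.6),
    (5, 6, 0.8),
    (6, 7, 0.9),
    (5, 7, 0.4),
    (8, 9, 7.5),  # isolated rosette segment
    (6, 11, 0.65),
]
TOY_RHO0 = 10.0
TOY_L = 120.0
TOY_DEPTH = 10.0


def build_network(nodes, edges, rho0=TOY_RHO0, L=TOY_L, depth=TOY_DEPTH):
    g = nx.Graph()
    for n, pos in nodes.items():
        g.add_node(n, pos=pos)
    for u, v, r in edges:
        g.add_edge(u, v, radius_um=float(r))
    return CanalicularNetwork(
        graph=g,
        landmarks=Landmarks(
            cv_center=np.zeros(3), cv_edge_radius_um=rho0, pv_edge_radius_um=L
        ),
        tissue_depth_um=depth,
    )


@pytest.fixture
def toy_network():
    return build_network(TOY_NODES, TOY_EDGES)


@pytest.fixture(scope="session")
def control_cfg():
    return bf.SyntheticConfig.for_regime("control", seed=1)


@pytest.fixture(scope="session")
def psc_cfg():
    return bf.SyntheticConfig.for_regime("psc", seed=1)


@pytest.fixture(scope="session")
def control_geometry(control_cfg):
    return bf.gen_radial_geometry(control_cfg)


def make_params(p_duct=1000.0, g=1.0, kappa=4.7e-10):
    return bf.BileParams(
        kappa=kappa, R=8.314462618, T=310.0, c0=300.0, mu=9.2e-4,
        p_duct=p_duct, g=g,
    )


@pytest.fixture
def bile_params():
    return make_params
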