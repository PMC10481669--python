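"""Unit tests for the synthetic lobule generators."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

import biliflow as bf
from biliflow.config import UM
from biliflow.synthetic import network_to_geometry

from conftest import build_network


class TestRadialGeometry:
    def test_regime_lobule_radii(self):
        control = bf.gen_radial_geometry(bf.SyntheticConfig.for_regime("control"))
        psc = bf.gen_radial_geometry(bf.SyntheticConfig.for_regime("psc"))
        assert control.L == pytest.approx(512.0 * UM)
        assert psc.L == pytest.approx(968.0 * UM)

    def test_cylinder_bundle_identity(self, control_cfg):
        geom = bf.gen_radial_geometry(control_cfg)
        np.testing.assert_allclose(
            geom.apical_density * geom.r_bc / (2.0 * geom.eps_bc),
            1.0,
            rtol=1e-12,
        )

    def test_profile_ranges(self, control_cfg):
        geom = bf.gen_radial_geometry(control_cfg)
        assert np.all(geom.eps_bc > 0) and np.all(geom.eps_bc <= 0.2)
        assert np.all(geom.r_bc > 0)
        assert np.all(geom.f == 0.28)
        assert geom.tau == 1.8

    def test_psc_dominates_control_with_matched_seed(self):
        control = bf.gen_radial_geometry(bf.SyntheticConfig.for_regime("control", seed=5))
        psc = bf.gen_radial_geometry(bf.SyntheticConfig.for_regime("psc", seed=5))
        assert psc.L > control.L
        t = np.linspace(0, 1, control.rho.size)
        # compare r_bc at matched normalized positions
        np.testing.assert_array_less(0, psc.r_bc - control.r_bc)

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            bf.SyntheticConfig.for_regime("control", lobule_radius_um=40.0)


class TestGenNetwork:
    def test_seed_determinism(self, control_cfg):
        a = bf.gen_network(control_cfg)
        b = bf.gen_network(control_cfg)
        ea = [(u, v, a.graph.edges[u, v]["radius_um"]) for u, v in a.graph.edges]
        eb = [(u, v, b.graph.edges[u, v]["radius_um"]) for u, v in b.graph.edges]
        assert ea == eb
        pa = [a.graph.nodes[n]["pos"] for n in a.graph.nodes]
        pb = [b.graph.nodes[n]["pos"] for n in b.graph.nodes]
        assert pa == pb

    def test_zero_rosette_fraction_keeps_radii_sub_band(self):
        cfg = bf.SyntheticConfig.for_regime("control", seed=2, rosette_fraction=0.0)
        net = bf.gen_network(cfg)
        _, radius, _, _ = net.edge_arrays()
        assert np.all(radius < 3.0)

    def test_rosette_fraction_within_binomial_interval(self):
        cfg = bf.SyntheticConfig.for_regime(
            "control", seed=3, rosette_fraction=0.05, nodes_per_zone=450,
            edge_dropout=0.0, rosette_disconnection=0.0,
        )
        net = bf.gen_network(cfg)
        _, radius, _, _ = net.edge_arrays()
        n = radius.size
        assert n >= 10000
        k = int(np.sum(radius >= 3.0))
        lo, hi = sps.binom.ppf([0.005, 0.995], n, 0.05)
        assert lo <= k <= hi

    def test_rejects_tiny_zones(self):
        with pytest.raises(ValueError):
            bf.SyntheticConfig.for_regime("control", nodes_per_zone=1)


class TestSectionTable:
    def test_row_counts_conserved(self, control_cfg):
        table = bf.gen_section_table(control_cfg)
        qualifying = (table["diameter_um"] > 6.0) & (table["n_bounding_cells"] > 2)
        assert int(qualifying.sum()) == control_cfg.n_rosette_lumina
        assert len(table) == (
            control_cfg.n_rosette_lumina
            + control_cfg.n_normal_lumina
            + control_cfg.n_duct_like_lumina
        )

    @pytest.mark.parametrize("fraction,expect", [(0.0, 0.0), (1.0, 1.0)])
    def test_marker_fraction_extremes(self, fraction, expect):
        cfg = bf.SyntheticConfig.for_regime(
            "control", seed=4, sox9_positive_fraction=fraction
        )
        table = bf.gen_section_table(cfg)
        res = bf.classify_rosette_markers(table)
        assert res["sox9_positive_fraction"] == expect

    def test_marker_fraction_binomial_recovery(self):
        cfg = bf.SyntheticConfig.for_regime(
            "control", seed=5, n_rosette_lumina=500, sox9_positive_fraction=0.28
        )
        table = bf.gen_section_table(cfg)
        res = bf.classify_rosette_markers(table)
        k = round(res["sox9_positive_fraction"] * res["n_rosettes"])
        lo, hi = sps.binom.ppf([0.005, 0.995], 500, 0.28)
        assert lo <= k <= hi

    def test_determinism(self, control_cfg):
        a = bf.gen_section_table(control_cfg)
        b = bf.gen_section_table(control_cfg)
        assert a.equals(b)


class TestLobuleMeasurements:
    def test_centred_on_regime_radius(self):
        cfg = bf.SyntheticConfig.for_regime("psc", seed=6)
        m = bf.gen_lobule_measurements(cfg, n_axes=200)
        assert np.median(m) == pytest.approx(968.0, rel=0.05)
        assert np.all(m > 0)


class TestNetworkToGeometry:
    def test_single_edge_closed_form(self):
        # one edge of radius r and length l in a strip shell of known volume
        nodes = {0: (14.0, 0.0, 5.0), 1: (14.0, 4.0, 5.0)}
        net = build_network(nodes, [(0, 1, 0.5)], rho0=10.0, L=20.0, depth=10.0)
        geom = network_to_geometry(net, n_shells=2, sector_angle=2.0 * np.pi)
        # the edge midpoint sits in the first shell [10, 15)
        shell_vol = np.pi * (15.0**2 - 10.0**2) * 10.0  # um^3
        eps_expected = np.pi * 0.5**2 * 4.0 / shell_vol
        a_expected = 2.0 * np.pi * 0.5 * 4.0 / shell_vol  # 1/um
        assert geom.eps_bc[1] == pytest.approx(eps_expected, rel=1e-12)
        assert geom.apical_density[1] * UM == pytest.approx(a_expected, rel=1e-12)
        assert geom.r_bc[1] == pytest.approx(0.5 * UM, rel=1e-12)

    def test_uniform_network_recovers_common_radius(self, control_cfg):
        cfg = control_cfg.model_copy(
            update={"radius_noise_cv": 0.0, "rosette_fraction": 0.0}
        )
        net = bf.gen_network(cfg)
        geom = network_to_geometry(net)
        np.testing.assert_allclose(
            geom.r_bc, cfg.baseline_radius_um * UM, rtol=1e-12
        )

    def test_matches_brute_force_shell_sums(self, control_cfg):
        net = bf.gen_network(control_cfg)
        n_shells = 22
        geom = network_to_geometry(net, n_shells=n_shells,
                                   clamp_diameter_above_um=None)
        # independent brute-force per-shell summation over raw radii
        _, radius, length, mid = net.edge_arrays()
        rho0, L = 50.0, 512.0
        s = np.hypot(mid[:, 0], mid[:, 1])
        shell = np.clip(((s - rho0) / (L - rho0) * n_shells).astype(int),
                        0, n_shells - 1)
        width = net.strip_width_um
        edges_r = np.linspace(rho0, L, n_shells + 1)
        for k in range(n_shells):
            sel = shell == k
            if not np.any(sel):
                continue
            vol = np.sum(np.pi * radius[sel] ** 2 * length[sel])
            shell_vol = width * (edges_r[k + 1] - edges_r[k]) * net.tissue_depth_um
            eps = vol / shell_vol
            r_vw = np.sum(radius[sel] * np.pi * radius[sel] ** 2 * length[sel]) / vol
            assert abs(geom.eps_bc[k + 1] - eps) / eps < 1e-12
            assert abs(geom.r_bc[k + 1] / UM - r_vw) / r_vw < 1e-12

    def test_empty_shell_interpolated_with_warning(self, caplog):
        nodes = {0: (12.0, 0.0, 5.0), 1: (14.0, 0.0, 5.0),
                 2: (118.0, 0.0, 5.0), 3: (116.0, 0.0, 5.0)}
        net = build_network(nodes, [(0, 1, 0.5), (2, 3, 0.6)])
        with caplog.at_level("WARNING"):
            geom = network_to_geometry(net, n_shells=11)
        assert "empty" in caplog.text
        assert np.all(np.isfinite(geom.eps_bc)) and np.all(geom.eps_bc > 0)
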