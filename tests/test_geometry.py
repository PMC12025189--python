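"""Implant/femur geometry: offset formula, meshing, feasibility, sampling."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

from stemlattice.geometry import (
    DESIGN_LEVELS, DESIGN_RANGES, DesignVariables, Region, build_conventional,
    build_extended, build_femur, compute_offset, design_grid_size,
    implant_load_case, sample_designs,
)


class TestOffset:
    def test_hand_evaluated_example(self):
        dv = DesignVariables(L1=20, phi2=10, Ltap=20, theta=45, phi1=12,
                             hdist=45, hrem=85, htap=20, alpha_angle=90)
        assert compute_offset(dv) == pytest.approx(33.385, abs=5e-4)

    def test_limit_theta_90(self):
        # cos -> 0, sin -> 1: offset = L1 - phi2/2 + phi1/2 (evaluated off-grid)
        dv = DesignVariables.midrange()
        th = math.radians(dv.theta)
        expected = dv.L1 - dv.phi2 / 2 + dv.Ltap * math.cos(th) + dv.phi1 / 2 * math.sin(th)
        assert compute_offset(dv) == pytest.approx(expected)

    def test_monotone_in_L1_and_Ltap(self):
        base = DesignVariables.midrange().to_array()
        names = DesignVariables.names()
        for var in ("L1", "Ltap"):
            i = names.index(var)
            lo, hi = DESIGN_RANGES[var]
            vals = []
            for v in np.linspace(lo, hi, 7):
                arr = base.copy()
                arr[i] = v
                vals.append(compute_offset(DesignVariables.from_array(arr)))
            assert np.all(np.diff(vals) > 0)


class TestConventionalMesh:
    def test_midrange_feasible_and_partitioned(self, midrange_mesh):
        tags = set(midrange_mesh.region.tolist())
        assert tags == {int(Region.SOLID_TAPER), int(Region.SOLID_DISTAL),
                        int(Region.REMODEL)}
        # integration-point areas sum to the outline area within 0.1%
        assert midrange_mesh.ip_weights.sum() == pytest.approx(
            midrange_mesh.outline.area, rel=1e-3)
        assert midrange_mesh.min_jacobian() > 0

    def test_remodel_band_height(self, midrange_dv, midrange_mesh):
        band = midrange_mesh.ip_region == Region.REMODEL
        ys = midrange_mesh.ip_coords[band, 1]
        assert ys.max() - ys.min() == pytest.approx(midrange_dv.hrem, abs=2.5)

    def test_infeasible_combination_flagged(self):
        # strongly inclined lateral edge over a long band crosses the neck base
        dv = DesignVariables(L1=10, Ltap=10, phi1=10, phi2=5, theta=50,
                             hdist=30, hrem=100, htap=10, alpha_angle=100)
        assert build_conventional(dv, 2.5) is None

    def test_refinement_preserves_region_areas(self, midrange_dv):
        coarse = build_conventional(midrange_dv, 2.5)
        fine = build_conventional(midrange_dv, 1.25)
        for tag in (Region.SOLID_TAPER, Region.SOLID_DISTAL, Region.REMODEL):
            assert fine.region_area(tag) == pytest.approx(
                coarse.region_area(tag), rel=5e-3)


class TestExtendedMesh:
    def test_superset_band_and_more_points(self, midrange_dv, midrange_mesh):
        ext = build_extended(midrange_dv, 2.5)
        assert ext is not None
        assert ext.region_area(Region.REMODEL) >= midrange_mesh.region_area(Region.REMODEL)
        assert ext.n_ip > midrange_mesh.n_ip

    def test_shared_solid_construction(self, midrange_dv, midrange_mesh):
        ext = build_extended(midrange_dv, 2.5)
        for tag in (Region.SOLID_TAPER, Region.SOLID_DISTAL):
            assert ext.region_area(tag) == pytest.approx(
                midrange_mesh.region_area(tag), rel=1e-9)
        # the neck/taper patches share identical node layouts
        conv_taper = midrange_mesh.ip_coords[midrange_mesh.ip_region == Region.SOLID_TAPER]
        ext_taper = ext.ip_coords[ext.ip_region == Region.SOLID_TAPER]
        np.testing.assert_allclose(np.sort(ext_taper, axis=0),
                                   np.sort(conv_taper, axis=0), atol=1e-9)


class TestFemur:
    def test_intact_contains_only_bone(self, midrange_dv, midrange_mesh):
        mesh, load = build_femur(midrange_dv, "intact", implant_mesh=midrange_mesh)
        assert set(mesh.region.tolist()) <= {int(Region.CORTICAL), int(Region.TRABECULAR)}
        assert len(load.fixed_nodes) > 0

    def test_implanted_shares_grid_with_intact(self, midrange_dv, midrange_mesh):
        intact, li = build_femur(midrange_dv, "intact", implant_mesh=midrange_mesh)
        implanted, lp = build_femur(midrange_dv, "implanted",
                                    implant_mesh=midrange_mesh)
        np.testing.assert_array_equal(intact.nodes, implanted.nodes)
        np.testing.assert_array_equal(intact.elements, implanted.elements)
        # load applied at the same x (same node) in both variants
        assert li.load_node == lp.load_node
        imp = np.isin(implanted.region,
                      (Region.SOLID_TAPER, Region.SOLID_DISTAL, Region.REMODEL))
        assert imp.any() and (~imp).any()
        # implant carries a density table covering exactly its points
        vf = implanted.meta["ip_vf"]
        imp_ip = np.isin(implanted.ip_region,
                         (Region.SOLID_TAPER, Region.SOLID_DISTAL, Region.REMODEL))
        assert np.all(np.isfinite(vf[imp_ip]))
        assert np.all(np.isnan(vf[~imp_ip]))

    def test_infeasible_design_raises(self):
        dv = DesignVariables(L1=10, Ltap=10, phi1=10, phi2=5, theta=50,
                             hdist=30, hrem=100, htap=10, alpha_angle=100)
        with pytest.raises(ValueError):
            build_femur(dv, "intact")


class TestSampling:
    def test_grid_cardinality(self):
        assert design_grid_size() == 480_000

    def test_unique_on_grid(self):
        designs = sample_designs(200, seed=3)
        assert len({tuple(d.to_array()) for d in designs}) == 200
        for name, (lo, hi) in DESIGN_RANGES.items():
            levels = np.linspace(lo, hi, DESIGN_LEVELS[name])
            for d in designs:
                assert np.any(np.isclose(getattr(d, name), levels))

    def test_marginals_approximately_uniform(self):
        designs = sample_designs(5000, seed=11)
        arr = np.array([d.to_array() for d in designs])
        for j, name in enumerate(DesignVariables.names()):
            levels = np.linspace(*DESIGN_RANGES[name], DESIGN_LEVELS[name])
            counts = [(np.isclose(arr[:, j], lv)).sum() for lv in levels]
            assert chisquare(counts).pvalue > 1e-4

    def test_seeds_change_order_not_level_sets(self):
        a = sample_designs(300, seed=0)
        b = sample_designs(300, seed=1)
        assert [tuple(d.to_array()) for d in a] != [tuple(d.to_array()) for d in b]
        for j, name in enumerate(DesignVariables.names()):
            va = {getattr(d, name) for d in a}
            vb = {getattr(d, name) for d in b}
            assert va == vb

    def test_oversized_draw_rejected(self):
        with pytest.raises(ValueError):
            sample_designs(480_001, seed=0)
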