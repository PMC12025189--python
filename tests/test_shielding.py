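"""Strain shielding: phi_bar, lazy-zone classification, yield load, F_bar."""

import numpy as np
import pytest

from stemlattice import fem, shielding as sh
from stemlattice.geometry import LoadCase, Region
from stemlattice.materials import TI6AL4V, yield_ratio
from stemlattice.remodeling import DensityField, RemodelParams, run as remodel_run

from conftest import make_grid_mesh


class TestPhiBar:
    def test_basic_values(self):
        assert sh.phi_bar(0.010, 0.010) == pytest.approx(0.0)
        assert sh.phi_bar(0.010, 0.0) == pytest.approx(1.0)
        assert sh.phi_bar(0.010, 0.004) == pytest.approx(0.6)

    def test_near_zero_intact_masked(self):
        out = sh.phi_bar(np.array([1e-12, 0.01]), np.array([0.5, 0.005]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(0.5)

    def test_scale_invariance(self):
        """phi_bar is a ratio: rescaling the strain measure cancels."""
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0.001, 0.01, 50), rng.uniform(0.001, 0.01, 50)
        np.testing.assert_allclose(sh.phi_bar(a, b), sh.phi_bar(2 * a, 2 * b))


class TestClassify:
    @pytest.mark.parametrize("phi, expected", [
        (0.7, sh.BoneResponse.RESORPTION),
        (-0.7, sh.BoneResponse.FORMATION),
        (0.6, sh.BoneResponse.LAZY),      # boundary is closed: lazy
        (-0.6, sh.BoneResponse.LAZY),
        (0.0, sh.BoneResponse.LAZY),
        (float("nan"), sh.BoneResponse.MASKED),
    ])
    def test_zones(self, phi, expected):
        assert sh.classify(phi) == expected

    def test_invalid_stimulus(self):
        with pytest.raises(ValueError):
            sh.classify(0.5, s=0.0)


class TestFBar:
    def test_values(self):
        assert sh.f_bar(100.0, 100.0) == 0.0
        assert sh.f_bar(100.0, 120.0) == pytest.approx(-0.2)
        assert sh.f_bar(100.0, 0.0) == 1.0
        with pytest.raises(ValueError):
            sh.f_bar(0.0, 1.0)


class TestYieldLoad:
    @pytest.fixture()
    def toy(self):
        mesh = make_grid_mesh(10.0, 30.0, 4, 12)
        fixed = np.flatnonzero(mesh.nodes[:, 1] < 1e-9)
        top = mesh.nearest_node(5.0, 30.0)
        load = LoadCase(fixed_nodes=fixed, load_node=top, value=(0.0, -100.0))
        return mesh, load

    def test_matches_incremental_ramp_oracle(self, toy):
        """First-yield load from elastic scaling agrees with a 100-step
        displacement ramp that checks the yield condition at every step."""
        mesh, load = toy
        rng = np.random.default_rng(2)
        vf = rng.uniform(0.3, 0.9, mesh.n_ip)
        estimate = sh.yield_load(mesh, load, vf_ip=vf, displacement=10.0)

        caps = yield_ratio(vf) * TI6AL4V.yield_stress
        from stemlattice.materials import apparent_modulus
        E_ip = apparent_modulus(vf, TI6AL4V)
        ramp_F = None
        for k in range(1, 101):
            d = 10.0 * k / 100
            case = LoadCase(fixed_nodes=load.fixed_nodes, load_node=load.load_node,
                            value=(0.0, -d), mode="displacement")
            r = fem.solve(mesh, case, E_ip, nu=0.3)
            if np.any(r.von_mises_stress >= caps):
                # linear interpolation inside the violating step
                scale = np.min(caps / r.von_mises_stress)
                ramp_F = abs(r.load_reaction[1]) * min(scale, 1.0)
                break
        assert ramp_F is not None
        assert estimate == pytest.approx(ramp_F, rel=0.01)

    def test_doubling_yield_stress_doubles_load(self, toy):
        mesh, load = toy
        vf = np.full(mesh.n_ip, 0.6)
        F1 = sh.yield_load(mesh, load, vf_ip=vf)
        strong = type(TI6AL4V)(youngs_modulus=TI6AL4V.youngs_modulus,
                               yield_stress=2 * TI6AL4V.yield_stress)
        F2 = sh.yield_load(mesh, load, vf_ip=vf, solid=strong)
        assert F2 == pytest.approx(2 * F1, rel=1e-9)

    def test_identical_fields_equal_loads(self, toy):
        mesh, load = toy
        vf = np.full(mesh.n_ip, 0.5)
        F1 = sh.yield_load(mesh, load, vf_ip=vf)
        F2 = sh.yield_load(mesh, load, vf_ip=vf.copy())
        assert sh.f_bar(F1, F2) == 0.0


@pytest.fixture(scope="module")
def outcome(midrange_dv, midrange_mesh, midrange_load):
    field, _ = remodel_run(midrange_mesh, midrange_load, RemodelParams())
    return sh.evaluate_variants(midrange_dv, field)


class TestEvaluateVariants:
    def test_fractions_partition(self, outcome):
        for rep in outcome["reports"].values():
            total = rep.resorption_frac + rep.lazy_frac + rep.formation_frac
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_uniform_mean_matches_graded(self, outcome, midrange_dv,
                                         midrange_mesh, midrange_load):
        field, _ = remodel_run(midrange_mesh, midrange_load, RemodelParams())
        band = midrange_mesh.ip_region == Region.REMODEL
        w = midrange_mesh.ip_weights[band]
        graded_mean = float(np.sum(w * field.vf[band]) / w.sum())
        assert outcome["mean_vf"] == pytest.approx(graded_mean, abs=1e-12)

    def test_solid_implant_shields_most(self, outcome):
        """A fully dense stem is the stiffest variant: porous variants cannot
        shield more of the bone into resorption than the solid control."""
        solid = outcome["reports"]["solid"].resorption_frac
        assert outcome["reports"]["uniform"].resorption_frac <= solid + 1e-9

    def test_strength_outputs_present(self, outcome):
        assert outcome["yield_loads"]["uniform"] > 0
        assert outcome["yield_loads"]["graded"] > 0
        assert np.isfinite(outcome["f_bar"])


class TestCohortSummary:
    def test_solid_vs_solid_control_is_zero(self, midrange_dv, midrange_mesh):
        solid_field = DensityField.solid(midrange_mesh)
        out = sh.evaluate_variants(midrange_dv, solid_field, with_strength=True)
        summary = sh.cohort_summary([out])
        # graded == uniform == solid: no design improves on the control
        assert summary["shares"]["uniform_less_resorption"] == 0.0
        assert summary["shares"]["graded_less_resorption"] == 0.0
        assert out["f_bar"] == pytest.approx(0.0, abs=1e-12)

    def test_identical_designs_give_degenerate_shares(self, midrange_dv,
                                                      midrange_mesh, midrange_load):
        field, _ = remodel_run(midrange_mesh, midrange_load, RemodelParams())
        out = sh.evaluate_variants(midrange_dv, field, with_strength=False)
        summary = sh.cohort_summary([out, out, out])
        for v in summary["shares"].values():
            assert v in (0.0, 1.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            sh.cohort_summary([])
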