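import numpy as np
import pytest

from twoscale import Grid
from twoscale.mhb import MHBParams, build_mhb_model
from twoscale.mirna import (
    MiRNAParams,
    build_extended_model,
    default_m0,
    extended_initial_state,
    mhr_coordinate,
    production_profile,
    scenario_config,
    sharpening_metric,
)
from twoscale.pde import integrate


class TestProductionProfile:
    def test_value_at_offset(self):
        mp = MiRNAParams(p1=0.2, p2=0.25, p4=1.5, l=0.3)
        assert production_profile(0.3, mp) == pytest.approx(0.2 * 1.5)

    def test_saturating_limit(self):
        mp = MiRNAParams()  # p1=0.1, p2=0.3, p4=1
        assert production_profile(-50.0, mp) == pytest.approx(0.2, abs=1e-9)

    def test_half_saturation_point(self):
        mp = MiRNAParams(l=0.45)
        s = 0.45 - 0.3 * np.arctanh(0.5)
        assert production_profile(s, mp) == pytest.approx(0.15, abs=1e-12)

    def test_negative_profile_rejected(self):
        mp = MiRNAParams(p4=0.2)  # tanh can reach -1 < -p4
        with pytest.raises(ValueError):
            production_profile(np.linspace(-2, 2, 50), mp)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            MiRNAParams(p2=0.0)
        with pytest.raises(ValueError):
            MiRNAParams(xi=1.2)
        with pytest.raises(ValueError):
            MiRNAParams(kappa=0.0)


class TestScenarioConfig:
    def test_scenario_i_constraints(self):
        mp = scenario_config("i", MiRNAParams())
        assert mp.beta_m == 0.0 and mp.d_m == 0.0 and mp.xi == 1.0
        assert mp.scenario == "i"

    def test_scenario_ii_constraints(self):
        mp = scenario_config("ii", MiRNAParams(beta_m=0.1))
        assert mp.xi == 0.0 and mp.d_m == 0.0 and mp.beta_m > 0

    def test_scenario_ii_requires_turnover(self):
        with pytest.raises(ValueError):
            scenario_config("ii", MiRNAParams(beta_m=0.0))

    def test_scenario_iii_requires_transport(self):
        with pytest.raises(ValueError):
            scenario_config("iii", MiRNAParams(d_m=0.0))
        mp = scenario_config("iii", MiRNAParams(d_m=0.002))
        assert mp.d_m == 0.002 and mp.xi == 0.0

    def test_contradictory_override(self):
        with pytest.raises(ValueError):
            scenario_config("i", MiRNAParams(scenario="ii"))


@pytest.fixture(scope="module")
def small():
    grid = Grid(L=2.0, N=120)
    from twoscale import find_steady_state, make_initial_conditions

    model = build_mhb_model()
    ss = find_steady_state(
        model,
        grid,
        make_initial_conditions("unimodal", 0.0, grid, widths=0.18, amplitudes=0.7),
        t_max=160.0,
    )
    assert ss.converged
    return grid, ss.profile


class TestExtendedModel:

    def test_species_count(self):
        model = build_extended_model(MHBParams(), MiRNAParams())
        assert len(model.species) == 10
        assert model.species[-2:] == ("miRNA", "complex")

    def test_kappa_zero_limit_decouples(self, small):
        """With vanishing binding the Wnt1 trajectory matches the base model."""
        grid, ss = small
        base = build_mhb_model()
        mp = MiRNAParams(kappa=1e-12, beta_m=0.1)
        ext = build_extended_model(MHBParams(), mp)
        state0 = extended_initial_state(ss, ext, grid)
        t_b = integrate(base, grid, ss, (0.0, 5.0))
        t_e = integrate(ext, grid, state0, (0.0, 5.0))
        np.testing.assert_allclose(
            t_e.state(-1)[3], t_b.state(-1)[3], atol=1e-7
        )

    def test_zero_mirna_reproduces_base_model(self, small):
        """m0 = 0 with production off leaves the base dynamics untouched."""
        grid, ss = small
        base = build_mhb_model()
        mp = scenario_config("i", MiRNAParams())
        ext = build_extended_model(MHBParams(), mp)
        with pytest.raises(ValueError):
            extended_initial_state(ss, ext, grid, m0=np.zeros(grid.N))
        # a custom scenario with zero production and no pool is legitimate
        mp = MiRNAParams(beta_m=0.1, p1=0.0)
        ext = build_extended_model(MHBParams(), mp)
        state0 = extended_initial_state(ss, ext, grid, m0=np.zeros(grid.N))
        t_b = integrate(base, grid, ss, (0.0, 5.0))
        t_e = integrate(ext, grid, state0, (0.0, 5.0))
        np.testing.assert_allclose(t_e.state(-1)[:8], t_b.state(-1), atol=1e-7)
        assert t_e.state(-1)[8:].max() == 0.0

    def test_scenario_i_mass_conservation(self, small):
        """With full recycling and no turnover, m + c is pointwise conserved."""
        grid, ss = small
        mp = scenario_config("i", MiRNAParams(l=0.45))
        ext = build_extended_model(MHBParams(), mp)
        state0 = extended_initial_state(ss, ext, grid)
        total0 = state0[8] + state0[9]
        traj = integrate(ext, grid, state0, (0.0, 20.0), t_eval=[0, 5, 20], rtol=1e-10, atol=1e-12)
        for k in range(len(traj.times)):
            total = traj.states[k, 8] + traj.states[k, 9]
            np.testing.assert_allclose(total, total0, rtol=1e-6, atol=1e-12)

    def test_kappa_monotonicity(self, small):
        """Stronger binding never increases steady Wnt1 anywhere."""
        grid, ss = small
        finals = []
        for kappa in (2.0, 20.0):
            mp = scenario_config("ii", MiRNAParams(kappa=kappa, l=0.45))
            ext = build_extended_model(MHBParams(), mp)
            state0 = extended_initial_state(ss, ext, grid)
            traj = integrate(ext, grid, state0, (0.0, 50.0))
            finals.append(traj.state(-1)[3])
        assert np.all(finals[1] <= finals[0] + 1e-8)

    def test_complex_starts_at_zero_and_builds(self, small):
        grid, ss = small
        mp = scenario_config("ii", MiRNAParams(l=0.45))
        ext = build_extended_model(MHBParams(), mp)
        state0 = extended_initial_state(ss, ext, grid)
        assert state0[9].max() == 0.0
        traj = integrate(ext, grid, state0, (0.0, 10.0))
        assert traj.state(-1)[9].max() > 0.0

    def test_scenario_iii_dirichlet_follows_profile(self, small):
        grid, ss = small
        mp = scenario_config("iii", MiRNAParams(d_m=0.001, l=0.45))
        ext = build_extended_model(MHBParams(), mp)
        state0 = extended_initial_state(ss, ext, grid)
        s_ends = mhr_coordinate(np.array([-grid.L, grid.L]))
        expected = production_profile(s_ends, mp)
        assert state0[8, 0] == pytest.approx(expected[0])
        assert state0[8, -1] == pytest.approx(expected[1])


class TestSharpeningMetric:
    def make_ref(self, grid):
        # Wnt1-like bump anterior of the boundary with a smooth anterior flank
        x = grid.x
        ref = np.exp(-((x + 0.06) ** 2) / (2 * 0.05**2))
        ref[x > 0] = 0.0
        return ref

    def test_identical_profiles_not_sharpened(self):
        g = Grid(N=250)
        ref = self.make_ref(g)
        res = sharpening_metric(ref, ref.copy(), g)
        assert not res["sharpened"]
        assert res["score"] == pytest.approx(0.0, abs=1e-12)

    def test_global_scaling_fails_boundary_condition(self):
        g = Grid(N=250)
        ref = self.make_ref(g)
        res = sharpening_metric(ref, 0.5 * ref, g)
        assert not res["sharpened"]
        assert res["mhb_change"] > 0.4

    def test_selective_flank_reduction_is_sharpening(self):
        g = Grid(N=250)
        ref = self.make_ref(g)
        # suppress the anterior flank only, keep the peak
        factor = 1.0 / (1.0 + np.exp(-(g.x + 0.09) / 0.02))
        ext = ref * factor
        res = sharpening_metric(ref, ext, g)
        assert res["sharpened"]
        assert res["score"] > 0

    def test_grid_mismatch_rejected(self):
        g = Grid(N=250)
        ref = self.make_ref(g)
        with pytest.raises(ValueError):
            sharpening_metric(ref, ref[:-1], g)
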