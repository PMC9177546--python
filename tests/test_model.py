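"""Model engine: fractionation, clarifier, steady-state solver and the
long-horizon ODE-integration oracle."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ifascal import (
    CompositeMeasurements,
    FractionationSettings,
    InfluentState,
    PlantConfig,
    clarifier_split,
    effluent_summary,
    fractionate_influent,
    solve_steady_state,
)
from ifascal.model import _STATE_IDX, _ReducedModel


class TestFractionation:
    def test_cod_and_tkn_reconstruct_exactly(self, calibration_composites):
        state, rec = fractionate_influent(calibration_composites)
        assert state.total_cod == pytest.approx(626.0, abs=1e-12)
        assert rec["cod"] == pytest.approx(626.0, abs=1e-12)
        assert state.tkn == pytest.approx(44.2, abs=1e-12)

    def test_organic_nitrogen_pool_is_tkn_minus_ammonia(self,
                                                        calibration_composites):
        state, _ = fractionate_influent(calibration_composites)
        assert state.s_nd + state.x_nd == pytest.approx(44.2 - 33.7, abs=1e-12)

    def test_all_zero_composites_give_zero_state(self):
        zero = CompositeMeasurements(cod=0, bod=0, tss=0, nh3=0, tkn=0, tn=0)
        state, rec = fractionate_influent(zero)
        assert state.total_cod == 0.0
        assert state.tkn == 0.0
        assert all(v == 0.0 for v in rec.values())

    def test_ammonia_exceeding_tkn_is_rejected(self):
        with pytest.raises(ValueError, match="NH3"):
            CompositeMeasurements(cod=100, bod=50, tss=50, nh3=20, tkn=10, tn=25)

    def test_negative_composite_is_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            CompositeMeasurements(cod=-1, bod=0, tss=0, nh3=0, tkn=0, tn=0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            FractionationSettings(f_ss=0.5, f_xs=0.5, f_si=0.5, f_xi=0.25)


class TestPlantConfig:
    def test_hrt_matches_volume_over_flow(self):
        cfg = PlantConfig(volume_m3=20.0, flow_m3h=1.8)
        assert cfg.hrt_h == pytest.approx(11.1, abs=0.02)

    def test_absolute_ras_flow_wins_over_ratio(self):
        cfg = PlantConfig(ras_ratio=2.5, ras_flow_m3h=3.7)
        assert cfg.ras_m3h == 3.7
        assert PlantConfig(ras_ratio=2.5, ras_flow_m3h=None).ras_m3h == \
            pytest.approx(4.5)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            PlantConfig(clarifier_f_ns=0.0)
        with pytest.raises(ValueError):
            PlantConfig(volume_m3=-1.0)


class TestClarifier:
    def test_conservation_is_exact(self, plant_config):
        eff, under = clarifier_split(2000.0, plant_config)
        assert eff + under == pytest.approx(2000.0, abs=0.0)

    def test_effluent_is_nonsettleable_fraction(self):
        cfg = PlantConfig(clarifier_f_ns=0.01)
        eff, _ = clarifier_split(2000.0, cfg)
        assert eff == pytest.approx(20.0)

    def test_vanishing_f_ns_sends_nothing_over_the_weir(self):
        cfg = PlantConfig(clarifier_f_ns=1e-12)
        eff, under = clarifier_split(2000.0, cfg)
        assert eff == pytest.approx(0.0, abs=1e-6)
        assert under == pytest.approx(2000.0, rel=1e-9)


class TestSteadyState:
    def test_zero_influent_washes_everything_out(self, registry, plant_config):
        zero = InfluentState(s_s=0, x_s=0, s_i=0, x_i=0, s_nh=0, s_nd=0,
                             x_nd=0)
        ss = solve_steady_state(zero, plant_config, registry.defaults())
        assert ss.converged
        np.testing.assert_allclose(ss.state[_STATE_IDX], 0.0, atol=1e-8)
        eff = effluent_summary(ss, plant_config, registry.defaults())
        assert eff.as_array() == pytest.approx([0.0, 0.0, 0.0], abs=1e-8)

    def test_residual_below_tolerance_and_states_nonnegative(
            self, influent, plant_config, registry):
        ss = solve_steady_state(influent, plant_config, registry.defaults())
        assert ss.residual_norm < 1e-10
        assert np.all(ss.state >= 0.0)

    def test_solids_mass_balance_closes(self, influent, plant_config,
                                        registry):
        """Influent + net reaction - (wastage + effluent escape) = 0 for
        every suspended particulate state at steady state."""
        params = registry.defaults()
        ss = solve_steady_state(influent, plant_config, params)
        model = _ReducedModel(influent, plant_config, params)
        np.testing.assert_allclose(model.rhs(ss.state), 0.0, atol=1e-9)

    def test_agrees_with_ode_integration_oracle(self, influent, plant_config,
                                                registry, rng):
        """Newton solution equals long-horizon stiff integration of the same
        balances to <=1e-6 relative on every state variable (absolute floor
        1e-8 for washed-out states), over 5 random parameter draws."""
        for _ in range(5):
            draw = {s.code: rng.uniform(s.low, s.high) for s in registry}
            params = registry.defaults().with_values(draw)
            model = _ReducedModel(influent, plant_config, params)
            ss = solve_steady_state(influent, plant_config, params)

            x = model.seed()
            for _chunk in range(30):
                sol = solve_ivp(lambda t, v: model.residual_batch(v[None])[0],
                                (0.0, 500.0), x, method="BDF",
                                rtol=1e-11, atol=1e-10)
                x = np.maximum(sol.y[:, -1], 0.0)
                if np.max(np.abs(model.residual(x))) < 1e-10:
                    break
            a, b = ss.state[_STATE_IDX], x
            denom = np.maximum(np.maximum(np.abs(a), np.abs(b)), 1e-2)
            assert np.max(np.abs(a - b) / denom) < 1e-6

    def test_increasing_decay_rate_decreases_heterotroph_inventory(
            self, influent, plant_config, registry):
        spec = registry["X16"]
        grid = np.linspace(spec.low, spec.high, 6)
        xbh = []
        for b_h in grid:
            ss = solve_steady_state(influent, plant_config,
                                    registry.defaults().replace(X16=b_h))
            xbh.append(ss["X_BH"])
        assert np.all(np.diff(xbh) < 0.0)

    def test_evaluator_is_bit_deterministic(self, evaluator, registry):
        params = registry.defaults().replace(X52=0.7, X16=0.45)
        a = evaluator(params)
        b = evaluator(params)
        assert np.array_equal(a, b)


class TestEffluentSummary:
    def test_tn_equals_sum_of_declared_nitrogen_components(
            self, evaluator, registry):
        s = evaluator.summary(registry.defaults())
        c = s.components
        expected = (c["S_NH"] + c["S_ND"] + c["S_NO2"] + c["S_NO3"]
                    + c["particulate_N"])
        assert s.tn == pytest.approx(expected, rel=1e-12)

    def test_outputs_nonnegative(self, evaluator, registry):
        out = evaluator(registry.defaults())
        assert np.all(out >= 0.0)

    def test_tiny_f_ns_removes_tss_but_keeps_soluble_outputs(
            self, influent, registry):
        params = registry.defaults()
        cfg_lo = PlantConfig(clarifier_f_ns=1e-12)
        ss = solve_steady_state(influent, cfg_lo, params)
        eff = effluent_summary(ss, cfg_lo, params)
        assert eff.tss == pytest.approx(0.0, abs=1e-6)
        assert eff.bod == pytest.approx(cfg_lo.f_bod * ss["S_S"], rel=1e-6)
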