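from datetime import date, timedelta

import numpy as np
import pytest

from tomtwin.crop_twin import (
    CropModel,
    CropParams,
    CropState,
    StemCohort,
    TrussCohort,
    apply_crop_actions,
    canopy_photosynthesis,
    daily_carbon_update,
    develop_and_harvest,
    fit_juvenile_delay,
    predict_trusses_per_stem,
    transpiration_and_co2_uptake,
    truss_initiation_rate,
)
from tomtwin.strategy import CropPlan


@pytest.fixture
def params():
    return CropParams()


class TestTrussRate:
    def test_anchor_19(self):
        assert truss_initiation_rate(19.0) == pytest.approx(1.1, abs=1e-12)

    def test_anchor_24(self):
        assert truss_initiation_rate(24.0) == pytest.approx(1.47, abs=1e-12)

    def test_midpoint_interpolation(self):
        # linear oracle: 1.1 + 0.074 * 2.5
        assert truss_initiation_rate(21.5) == pytest.approx(1.285, abs=1e-12)

    def test_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            low = truss_initiation_rate(10.0)
        assert low == truss_initiation_rate(15.0)

    def test_slope_recovery_from_constant_temperature_runs(self):
        # simulate truss accumulation at two constant temperatures and fit
        # the rate slope back; must return 0.074 to within 1e-9
        rates = {}
        for t in (19.0, 24.0):
            state = CropState()
            state.stem_cohorts.append(StemCohort(density=1.0, delay_cd_remaining=0.0))
            plan = CropPlan(topping_date=date(2020, 5, 1))
            day = date(2019, 12, 16)
            for _ in range(70):
                develop_and_harvest(state, t, day, plan, CropParams())
                day += timedelta(days=1)
            rates[t] = state.stem_cohorts[0].truss_acc / 10.0  # trusses/week
        slope = (rates[24.0] - rates[19.0]) / 5.0
        assert slope == pytest.approx(0.074, abs=1e-9)


class TestJuvenileDelayFit:
    def test_round_trip(self):
        delay = fit_juvenile_delay(23.8, 21.34, date(2019, 12, 16), date(2020, 4, 30))
        assert 0.5 < delay < 1.0
        back = predict_trusses_per_stem(21.34, date(2019, 12, 16), date(2020, 4, 30), delay)
        assert back == pytest.approx(23.8, abs=1e-12)


class TestCanopyPhotosynthesis:
    def test_zero_par_zero(self, params):
        assert canopy_photosynthesis(0.0, 800.0, 21.0, 3.0, params) == 0.0

    def test_monotone_in_par_and_co2(self, params):
        pars = [50.0, 150.0, 400.0, 900.0]
        co2s = [400.0, 600.0, 900.0]
        for co2 in co2s:
            vals = [canopy_photosynthesis(p, co2, 21.0, 3.0, params) for p in pars]
            assert all(b > a for a, b in zip(vals, vals[1:]))
        for par in pars:
            vals = [canopy_photosynthesis(par, c, 21.0, 3.0, params) for c in co2s]
            assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_diminishing_light_interception_with_lai(self, params):
        # oracle: Beer-law interception gain from LAI 0.5->1.0 exceeds the
        # gain from 3.0->3.5
        def a(lai):
            return canopy_photosynthesis(400.0, 800.0, 21.0, lai, params)
        assert (a(1.0) - a(0.5)) > (a(3.5) - a(3.0))

    def test_flat_within_moderate_range(self, params):
        vals = [canopy_photosynthesis(400.0, 800.0, t, 3.0, params)
                for t in (18.0, 21.0, 24.0)]
        ref = vals[1]
        for v in vals:
            assert abs(v - ref) / ref <= 0.05


def _loaded_state(params, n_trusses=10, fruits=12, density=0.5):
    state = CropState(veg_dm=200.0, fruit_dm=50.0)
    state.stem_cohorts.append(StemCohort(density=4.0, delay_cd_remaining=0.0))
    for k in range(n_trusses):
        state.trusses.append(TrussCohort(
            init_date=date(2020, 2, 1), density=density, fruits_per_truss=fruits,
            age_cd=params.ripening_cd * (k + 0.5) / (n_trusses + 1), dm=5.0))
    return state


class TestDailyCarbonUpdate:
    def test_zero_assimilation_pools_shrink_by_respiration(self, params):
        state = _loaded_state(params)
        veg0, fruit0 = state.veg_dm, state.fruit_dm
        ledger = daily_carbon_update([0.0] * 24, [20.0] * 24, state, params)
        assert ledger["assim"] == 0.0
        assert veg0 - state.veg_dm + fruit0 - state.fruit_dm == pytest.approx(
            ledger["maintenance"], abs=1e-9)

    def test_zero_plant_load_fruit_pool_gets_nothing(self, params):
        state = CropState(veg_dm=200.0, fruit_dm=0.0)
        state.stem_cohorts.append(StemCohort(density=4.0, delay_cd_remaining=0.0))
        fruit0 = state.fruit_dm
        daily_carbon_update([1.0] * 24, [21.0] * 24, state, params)
        assert state.fruit_dm == fruit0

    def test_carbon_ledger_closes(self, params):
        state = _loaded_state(params)
        for assim in ([0.5] * 24, [1.5] * 24, [0.0] * 24):
            led = daily_carbon_update(list(assim), [21.0] * 24, state, params)
            residual = (led["assim"] - led["maintenance"] - led["growth_ch2o"]
                        - led["discarded"] + led["pool_debit"])
            assert residual == pytest.approx(0.0, abs=1e-9)

    def test_season_ledger_closes_daily(self, six_runs):
        for res in six_runs.values():
            for led in res.crop.carbon_ledger:
                residual = (led["assim"] - led["maintenance"] - led["growth_ch2o"]
                            - led["discarded"] + led["pool_debit"])
                assert abs(residual) <= 1e-9 * max(led["assim"], 1.0)


class TestDevelopAndHarvest:
    def test_no_new_trusses_after_topping(self, params):
        state = CropState()
        state.stem_cohorts.append(StemCohort(density=4.0, delay_cd_remaining=0.0))
        plan = CropPlan(topping_date=date(2020, 1, 10))
        day = date(2020, 1, 11)
        develop_and_harvest(state, 21.0, day, plan, params)
        n = len(state.trusses)
        for _ in range(30):
            day += timedelta(days=1)
            develop_and_harvest(state, 21.0, day, plan, params)
        assert len(state.trusses) == n

    def test_colder_regime_lengthens_fruit_growth_period(self, params):
        def fgp_at(temp):
            state = CropState(veg_dm=100.0)
            state.stem_cohorts.append(StemCohort(density=4.0, delay_cd_remaining=0.0))
            plan = CropPlan(topping_date=date(2020, 4, 16))
            day = date(2019, 12, 16)
            records = []
            for _ in range(150):
                daily_carbon_update([1.0] * 24, [temp] * 24, state, params)
                records += develop_and_harvest(state, temp, day, plan, params)
                day += timedelta(days=1)
            return records[0].fruit_growth_period
        assert fgp_at(19.0) > fgp_at(21.0)

    def test_plant_load_integral_identity(self, params):
        # fruits harvested ~= integral of plant load / ripening time, over
        # a steady constant-temperature stretch
        temp = 21.0
        state = CropState(veg_dm=100.0)
        state.stem_cohorts.append(StemCohort(density=4.0, delay_cd_remaining=0.0))
        plan = CropPlan(fruits_per_truss_target=12,
                        topping_date=date(2020, 12, 1),
                        last_harvest_date=date(2020, 12, 20))
        day = date(2019, 12, 16)
        load_integral = 0.0
        harvested_fruits = 0.0
        for i in range(300):
            records = develop_and_harvest(state, temp, day, plan, params)
            if i >= 150:  # steady state only
                load_integral += state.plant_load
                harvested_fruits += sum(r.trusses_harvested for r in records) * 12
            day += timedelta(days=1)
        ripen_days = params.ripening_cd / (temp - params.t_base)
        predicted = load_integral / ripen_days
        assert harvested_fruits == pytest.approx(predicted, rel=0.05)


class TestCropActions:
    def test_pruning_target_never_exceeded(self, six_runs):
        for res in six_runs.values():
            target = min(res.plan.fruits_per_truss_target, 16)
            assert res.crop.max_fruits_per_truss <= target

    def test_cap_enforced_without_target(self, params):
        state = CropState()
        state.stem_cohorts.append(StemCohort(density=4.0, delay_cd_remaining=0.0))
        plan = CropPlan(fruits_per_truss_target=99, topping_date=date(2020, 4, 16))
        # validation would reject this plan; the cap still holds here
        day = date(2020, 1, 1)
        for _ in range(20):
            develop_and_harvest(state, 22.0, day, plan, params)
            apply_crop_actions(state, plan, day, params)
            day += timedelta(days=1)
        assert all(t.fruits_per_truss <= 16 for t in state.trusses)

    def test_stem_density_change_takes_effect(self, params):
        state = CropState()
        state.stem_cohorts.append(StemCohort(density=3.0, delay_cd_remaining=0.0))
        plan = CropPlan(initial_stem_density=3.0,
                        stem_density_changes=[(date(2020, 2, 1), 5.0)],
                        topping_date=date(2020, 4, 16))
        apply_crop_actions(state, plan, date(2020, 1, 15), params)
        assert state.stem_density == 3.0
        apply_crop_actions(state, plan, date(2020, 2, 1), params)
        assert state.stem_density == 5.0
        # new stems wait out the juvenile delay
        assert state.stem_cohorts[-1].delay_cd_remaining > 0

    def test_reference_stem_doubling_raises_labor_driver(self):
        from tomtwin.strategy import make_preset
        _, plan = make_preset(303)
        flat = plan.copy()
        flat.stem_density_changes = []
        assert plan.stem_days_integral() > flat.stem_days_integral()


class TestTranspiration:
    def test_night_fluxes(self, params):
        transp, co2, _ = transpiration_and_co2_uptake(
            3.0, 0.0, 800.0, 20.0, 3.0, 200.0, 50.0, params)
        dark_baseline = params.dark_transp_factor * params.transp_vpd_coeff * 3.0
        assert transp <= dark_baseline + 1e-9
        assert co2 <= 0.0  # respiration release at night

    def test_monotone_in_par(self, params):
        vals = [transpiration_and_co2_uptake(3.0, p, 800.0, 21.0, 3.0, 200.0, 50.0,
                                             params)[0]
                for p in (50.0, 200.0, 600.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_seasonal_uptake_within_printed_envelope(self, six_runs):
        for res in six_runs.values():
            uptake = res.ledger.totals()["water_uptake_l"]
            assert 334.0 <= uptake <= 537.0


class TestSeasonEnvelopes:
    def test_trusses_per_stem_envelope(self, six_runs):
        for res in six_runs.values():
            final = res.crop.daily_rows[-1].trusses_per_stem
            assert 21.0 <= final <= 25.0

    def test_fruits_per_m2_envelope(self, six_runs):
        for res in six_runs.values():
            assert 1100.0 <= res.crop.state.cum_fruits_initiated <= 1650.0

    def test_mean_fruit_weight_envelope(self, six_runs):
        for res in six_runs.values():
            weights = np.array([h.mean_fruit_weight for h in res.harvests])
            masses = np.array([h.fresh_weight for h in res.harvests])
            mean_fw = float(np.average(weights, weights=masses))
            assert 8.0 <= mean_fw <= 12.0

    def test_plant_load_soft_envelope(self, six_runs):
        for res in six_runs.values():
            assert res.crop.max_plant_load <= 850.0

    def test_harvest_record_consistency(self, six_runs):
        res = six_runs[303]
        fpt = res.plan.fruits_per_truss_target
        for h in res.harvests:
            n_fruits = h.trusses_harvested * fpt
            assert h.fresh_weight * 1000.0 == pytest.approx(
                n_fruits * h.mean_fruit_weight, rel=1e-9)
            assert h.fruit_growth_period > 0
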