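"""Scheduler, feedback policies and the closed experiment loop."""

import filecmp

import numpy as np
import pytest

from conftest import make_ideal_twin
from optowell import fixtures, workflows
from optowell.control import (FeedbackPolicy, MeasurementPlan,
                              MeasurementRecord, StimProtocol,
                              apply_feedback, duty_cycle, led_state_at,
                              run_experiment, schedule_epoch)
from optowell.culture import ExpressionCircuit, WellCulture
from optowell.twin import PlateTwin
from optowell.wells import WELLS


class TestWaveform:
    def test_three_on_seven_off_pulse_train(self):
        p = StimProtocol(intensity=1000, t_on=3, t_off=7)
        assert led_state_at(p, 2) == 1000   # within the pulse
        assert led_state_at(p, 5) == 0      # in the dark interval
        assert led_state_at(p, 12) == 1000  # second period
        assert duty_cycle(p) == pytest.approx(30.0)

    def test_zero_off_time_means_always_on(self):
        p = StimProtocol(intensity=500, t_on=5, t_off=0)
        for t in (0, 4.9, 5, 123.4):
            assert led_state_at(p, t) == 500
        assert duty_cycle(p) == 100.0

    def test_quarter_duty_cycle(self):
        assert duty_cycle(StimProtocol(100, 1, 3)) == pytest.approx(25.0)

    def test_long_horizon_on_fraction_equals_duty_cycle(self):
        p = StimProtocol(intensity=1000, t_on=3, t_off=7)
        # sample on a 1 s grid over 1000 full periods: exact for integer
        # durations
        states = [led_state_at(p, t) for t in range(10_000)]
        assert np.mean(np.array(states) > 0) == pytest.approx(0.3)

    def test_inactive_protocol_is_dark(self):
        p = StimProtocol(intensity=1000, t_on=3, t_off=7, active=False)
        assert led_state_at(p, 1) == 0

    def test_zero_period_duty_cycle_rejected(self):
        with pytest.raises(ValueError):
            duty_cycle(StimProtocol(0, 0, 0))


class TestSchedule:
    def test_epoch_count_for_twenty_minute_cadence_over_18_h(self):
        plan = MeasurementPlan(od_period_min=20, fluor_period_min=20,
                               duration_h=18)
        assert len(plan.epoch_times_h()) == 55  # floor(18*60/20) + 1

    def test_measurement_bracket_orders_shaker_and_darkness(self):
        plan = MeasurementPlan()
        actions = schedule_epoch(plan, {}, 0.0)
        assert actions[0] == ("pause_shaker",)
        assert actions[1] == ("stim_dark",)
        assert actions[-2] == ("restore_stim",)
        assert actions[-1] == ("resume_shaker",)
        kinds = [a[1] for a in actions if a[0] == "measure"]
        assert kinds == ["od", "fluorescence"]

    def test_too_fast_cadence_rejected(self):
        with pytest.raises(ValueError, match="shorter than a measurement"):
            MeasurementPlan(od_period_min=0.5, fluor_period_min=0.5)


def _record(fluor=0.0, od_adj=0.0, well="A1"):
    return MeasurementRecord(0.0, well, 0.0, od_adj, fluor)


class TestFeedbackPolicies:
    def test_below_threshold_leaves_protocol_unchanged(self):
        pol = FeedbackPolicy(kind="stop_on_fluorescence", threshold=200.0,
                             wells=("A1",))
        p = StimProtocol(1000, 3, 7)
        assert apply_feedback(pol, p, {"A1": _record(fluor=150.0)}) is p

    def test_crossing_halts_light_and_latches(self):
        pol = FeedbackPolicy(kind="stop_on_fluorescence", threshold=200.0,
                             wells=("A1",))
        p = StimProtocol(1000, 3, 7)
        p = apply_feedback(pol, p, {"A1": _record(fluor=250.0)})
        assert p.intensity == 0
        # a later dip below the threshold must not re-arm the light
        p = apply_feedback(pol, p, {"A1": _record(fluor=100.0)})
        assert p.intensity == 0 and pol.triggered

    def test_start_on_od_activates_once(self):
        pol = FeedbackPolicy(kind="start_on_od", threshold=0.3,
                             wells=("A1",))
        p = StimProtocol(1000, 3, 7, active=False)
        p = apply_feedback(pol, p, {"A1": _record(od_adj=0.1)})
        assert not p.active
        p = apply_feedback(pol, p, {"A1": _record(od_adj=0.35)})
        assert p.active
        p2 = apply_feedback(pol, p, {"A1": _record(od_adj=0.05)})
        assert p2.active  # latched on

    def test_group_input_is_the_replicate_mean(self):
        pol = FeedbackPolicy(kind="stop_on_fluorescence", threshold=200.0,
                             wells=("A1", "A2"))
        p = StimProtocol(1000, 3, 7)
        latest = {"A1": _record(fluor=150.0), "A2": _record(fluor=190.0)}
        assert apply_feedback(pol, p, latest).intensity == 1000  # mean 170
        latest["A2"] = _record(fluor=260.0)  # mean 205
        assert apply_feedback(pol, p, latest).intensity == 0

    def test_missing_records_raise(self):
        pol = FeedbackPolicy(kind="stop_on_fluorescence", threshold=1.0,
                             wells=("A1", "B2"))
        with pytest.raises(KeyError, match="B2"):
            apply_feedback(pol, StimProtocol(100, 1, 1),
                           {"A1": _record()})

    def test_od_policy_without_transform_is_an_error(self):
        pol = FeedbackPolicy(kind="start_on_od", threshold=0.3,
                             wells=("A1",))
        with pytest.raises(ValueError, match="OD transform"):
            apply_feedback(pol, StimProtocol(100, 1, 1, active=False),
                           {"A1": _record(od_adj=float("nan"))})

    def test_custom_policy_is_a_pure_function_contract(self):
        def halve(state, recs, protocol):
            n = state.get("n", 0) + 1
            from dataclasses import replace
            return {"n": n}, replace(protocol,
                                     intensity=protocol.intensity // 2)

        pol = FeedbackPolicy(kind="custom", wells=("A1",), custom_fn=halve)
        p = StimProtocol(1000, 3, 7)
        p = apply_feedback(pol, p, {"A1": _record()})
        p = apply_feedback(pol, p, {"A1": _record()})
        assert p.intensity == 250 and pol.state == {"n": 2}


@pytest.fixture(scope="module")
def calibrated_with_transform():
    twin = PlateTwin(seed=21)
    state = workflows.full_calibration(twin)
    transform = workflows.fit_od_harmonization(
        twin, state, fixtures.turbidity_series())
    return twin, state, transform


def _run(twin, state, fix, transform=None, **kwargs):
    return run_experiment(twin, fix.cultures, fix.circuits, fix.protocols,
                          fix.policies, fix.plan, pd_table=state.photodiode,
                          blue_table=state.blue, uv_table=state.uv,
                          od_transform=transform,
                          inducer_wells=fix.inducer_wells, **kwargs)


class TestRunExperiment:
    def test_requires_calibration_first(self):
        twin = PlateTwin(seed=22)
        fix = fixtures.arabinose_plate()
        with pytest.raises(RuntimeError, match="uncalibrated"):
            run_experiment(twin, fix.cultures, fix.circuits, fix.protocols,
                           fix.policies, fix.plan, pd_table=None,
                           uv_table=None)

    def test_dead_dark_plate_gives_flat_traces(self):
        twin = make_ideal_twin(seed=23)
        state = workflows.full_calibration(twin)
        plan = MeasurementPlan(od_period_min=30, fluor_period_min=30,
                               duration_h=2)
        cultures = {w: WellCulture(turbidity=0.0) for w in WELLS}
        circuits = {w: ExpressionCircuit(kind="none") for w in WELLS}
        protocols = {w: StimProtocol(0) for w in WELLS}
        res = run_experiment(twin, cultures, circuits, protocols, [], plan,
                             pd_table=state.photodiode, uv_table=state.uv)
        od = res.od_raw[list(WELLS)].to_numpy()
        fl = res.fluorescence[list(WELLS)].to_numpy()
        assert np.allclose(od, 0.0, atol=0.01)
        assert np.ptp(fl, axis=0).max() <= 2.0  # constant blank level

    def test_optogenetic_half_plate_discriminates_conditions(
            self, calibrated_with_transform):
        twin, state, transform = calibrated_with_transform
        fix = fixtures.optogenetic_half_plate()
        res = _run(twin, state, fix, transform)
        rise = (res.fluorescence.iloc[-1] - res.fluorescence.iloc[0])
        gains = {cond: np.mean([rise[w] for w in WELLS
                                if fix.condition[w] == cond])
                 for cond in set(fix.condition.values())}
        # expression only where the circuit logic says so
        assert gains["pDawn_light"] > 10 * max(abs(gains["pDawn_dark"]), 5)
        assert gains["pDusk_dark"] > 10 * max(abs(gains["pDusk_light"]), 5)
        assert abs(gains["pDawn_dark"]) < 20
        # growth is seen in every well
        od_rise = res.od_raw.iloc[-1][list(WELLS)].min()
        assert od_rise > 0.2

    def test_same_seed_runs_are_byte_identical(self, tmp_path):
        outs = []
        for name in ("a", "b"):
            twin = PlateTwin(seed=31)
            state = workflows.full_calibration(twin)
            fix = fixtures.arabinose_plate()
            fix.plan.duration_h = 2.0
            out = tmp_path / name
            _run(twin, state, fix, outdir=out)
            outs.append(out)
        for f in ("od_raw.csv", "fluorescence.csv", "od_adjusted.csv"):
            assert filecmp.cmp(outs[0] / f, outs[1] / f, shallow=False)

    def test_shaker_paused_exactly_once_per_epoch(self,
                                                  calibrated_with_transform):
        twin = PlateTwin(seed=33)
        state = workflows.full_calibration(twin)
        fix = fixtures.arabinose_plate()
        fix.plan.duration_h = 1.0
        baseline = len([e for e in twin.shaker_log if e == ("pause",)])
        _run(twin, state, fix)
        pauses = len([e for e in twin.shaker_log if e == ("pause",)])
        n_epochs = len(fix.plan.epoch_times_h())
        # one pause per measurement epoch beyond the calibration workflow
        assert pauses - baseline == n_epochs

    def test_policy_wells_permuted_outputs_permute(self):
        # identical components: relabelling wells relabels results
        def run_with(protocol_map):
            twin = make_ideal_twin(seed=25)
            state = workflows.full_calibration(twin)
            plan = MeasurementPlan(od_period_min=30, fluor_period_min=30,
                                   duration_h=3)
            cultures = {w: WellCulture(turbidity=0.05) for w in WELLS}
            circuits = {w: ExpressionCircuit(kind="pDawn") for w in WELLS}
            return run_experiment(twin, cultures, circuits, protocol_map,
                                  [], plan, pd_table=state.photodiode,
                                  uv_table=state.uv)

        lit = StimProtocol(1000, 3, 7)
        dark = StimProtocol(0)
        a = run_with({"A1": lit, "A2": dark})
        b = run_with({"A1": dark, "A2": lit})
        np.testing.assert_allclose(a.fluorescence["A1"],
                                   b.fluorescence["A2"], atol=1.0)
        np.testing.assert_allclose(a.fluorescence["A2"],
                                   b.fluorescence["A1"], atol=1.0)


@pytest.fixture(scope="module")
def grid_result():
    twin = PlateTwin(seed=27)
    state = workflows.full_calibration(twin)
    transform = workflows.fit_od_harmonization(
        twin, state, fixtures.turbidity_series())
    fix = fixtures.feedback_grid_plate()
    res = run_experiment(twin, fix.cultures, fix.circuits, fix.protocols,
                         fix.policies, fix.plan,
                         pd_table=state.photodiode,
                         blue_table=state.blue, uv_table=state.uv,
                         od_transform=transform)
    return fix, res


class TestClosedLoop:
    @staticmethod
    def _class_means(fix, res, prefix):
        final = res.fluorescence.iloc[-1]
        return [np.mean([final[w] for w in WELLS
                         if fix.condition[w] == f"{prefix}_{i}"])
                for i in range(8)]

    def test_final_reporter_monotone_in_constant_intensity(self, grid_result):
        fix, res = grid_result
        means = self._class_means(fix, res, "constant")
        assert np.all(np.diff(means) > 0)

    def test_final_reporter_nonincreasing_in_od_threshold(self, grid_result):
        fix, res = grid_result
        means = self._class_means(fix, res, "od_start")
        assert np.all(np.diff(means) < 0)

    def test_fluorescence_halt_overshoot_is_bounded(self, grid_result):
        fix, res = grid_result
        final = res.fluorescence.iloc[-1]
        circ = ExpressionCircuit(kind="pDawn")
        # counts/h upper bound on reporter accumulation at full drive and
        # carrying capacity, on the calibrated sensitivity scale
        rate = 13.0 * circ.k_prod * 1.0
        epoch_h = fix.plan.od_period_min / 60.0
        bound = rate * (epoch_h + circ.switch_delay + circ.tau)
        for i, thr in enumerate(fixtures.FLUOR_THRESHOLDS):
            wells = [w for w in WELLS
                     if fix.condition[w] == f"fluor_halt_{i}"]
            mean_final = np.mean([final[w] for w in wells])
            if mean_final >= thr:  # threshold was actually reached
                assert mean_final - thr <= bound

    def test_each_policy_latches_at_most_once(self, grid_result):
        fix, res = grid_result
        # once a stop policy fires, measured fluorescence stops rising
        # beyond the relaxation tail; activation cannot recur, so the last
        # two epochs of every triggered group are flat
        fl = res.fluorescence
        for i in range(8):
            wells = [w for w in WELLS
                     if fix.condition[w] == f"fluor_halt_{i}"]
            trace = fl[wells].mean(axis=1).to_numpy()
            if trace[-1] >= fixtures.FLUOR_THRESHOLDS[i]:
                assert trace[-1] - trace[-2] < 5.0
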