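import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from noxithresh import (
    BlockLog,
    InvalidDesignError,
    ObserverSpec,
    StaircaseConfig,
    ThresholdUnattainableError,
    convergence_accuracy,
    estimate_threshold,
    initial_state,
    prob_correct_detection,
    run_block,
    staircase_update,
    theoretical_threshold,
)
from noxithresh.staircase import StaircaseState, TrialRecord
from noxithresh._rng import block_rng

from conftest import SNR_AT_CONVERGENCE, observer_with_threshold


@pytest.fixture
def config():
    return StaircaseConfig(base_temp=45.0, direction="decrease")


class TestStaircaseUpdate:
    def test_incorrect_steps_up(self, config):
        state = initial_state(config)
        new = staircase_update(state, correct=False, config=config)
        assert new.current_delta == 3.0
        assert new.consecutive_correct == 0

    def test_third_consecutive_correct_steps_down(self, config):
        state = StaircaseState(
            trial_index=2, current_delta=2.5, consecutive_correct=2,
            history=((2.5, True, 1), (2.5, True, 1)),
        )
        new = staircase_update(state, correct=True, config=config)
        assert new.current_delta == 2.0
        assert new.consecutive_correct == 0

    def test_first_correct_leaves_delta(self, config):
        state = initial_state(config)
        new = staircase_update(state, correct=True, config=config)
        assert new.current_delta == 2.5
        assert new.consecutive_correct == 1

    def test_error_resets_counter(self, config):
        state = StaircaseState(
            trial_index=2, current_delta=2.5, consecutive_correct=2,
            history=((2.5, True, 1), (2.5, True, 1)),
        )
        new = staircase_update(state, correct=False, config=config)
        assert new.consecutive_correct == 0
        assert new.current_delta == 3.0

    def test_delta_never_below_step(self, config):
        state = StaircaseState(
            trial_index=2, current_delta=0.5, consecutive_correct=2,
            history=((0.5, True, 1), (0.5, True, 1)),
        )
        new = staircase_update(state, correct=True, config=config)
        assert new.current_delta == 0.5  # clamped at the rule minimum
        assert not new.bound_violation

    def test_ceiling_clamp_sets_flag(self):
        cfg = StaircaseConfig(base_temp=45.0, direction="increase")
        state = StaircaseState(
            trial_index=1, current_delta=5.0, consecutive_correct=0,
            history=((5.0, False, 1),),
        )
        new = staircase_update(state, correct=False, config=cfg)
        assert new.current_delta == 5.0  # 50 C ceiling
        assert new.bound_violation

    def test_update_after_completion_rejected(self, config):
        state = initial_state(config)
        for _ in range(config.n_trials):
            state = staircase_update(state, correct=True, config=config)
        with pytest.raises(InvalidDesignError):
            staircase_update(state, correct=True, config=config)

    def test_history_tracks_trials(self, config):
        state = initial_state(config)
        for correct in (True, False, True):
            state = staircase_update(state, correct, config)
        assert state.trial_index == 3
        assert [h[0] for h in state.history] == [2.5, 2.5, 3.0]


class TestRunBlock:
    def test_block_has_exactly_n_trials(self, config, linear_observer, rng):
        log = run_block(config, linear_observer, rng)
        assert len(log.records) == 30

    def test_always_correct_descends_to_step(self, config, sharp_observer, rng):
        log = run_block(config, sharp_observer, rng)
        deltas = [r.delta_c for r in log.records]
        # hand-simulated: 3 trials at each level from 2.5 down, then pinned at 0.5
        expected = [2.5] * 3 + [2.0] * 3 + [1.5] * 3 + [1.0] * 3 + [0.5] * 18
        assert deltas == expected
        assert all(r.correct for r in log.records)

    def test_guessing_observer_hits_ceiling(self, guessing_observer):
        cfg = StaircaseConfig(base_temp=45.0, direction="increase", n_trials=100,
                              n_discard=10)
        log = run_block(cfg, guessing_observer, np.random.default_rng(3))
        assert log.bound_violation
        assert max(r.delta_c for r in log.records) == 5.0

    def test_first_trial_uses_initial_delta(self, config, linear_observer, rng):
        log = run_block(config, linear_observer, rng)
        assert log.records[0].delta_c == 2.5

    def test_deltas_on_half_degree_grid(self, linear_observer):
        cfg = StaircaseConfig(base_temp=45.0, direction="decrease")
        log = run_block(cfg, linear_observer, np.random.default_rng(9))
        offsets = [(r.delta_c - cfg.initial_delta) / cfg.step for r in log.records]
        assert all(abs(o - round(o)) < 1e-9 for o in offsets)

    def test_discrimination_holds_reference_fixed(self, rng):
        cfg = StaircaseConfig(
            base_temp=45.0, direction="decrease", mode="discrimination",
            reference_delta=1.5, initial_delta=4.0,
        )
        obs = ObserverSpec(gain=1.0, exponent=1.0, offset=35.0, noise=2.0)
        log = run_block(cfg, obs, rng)
        # adaptive deltas stay strictly above the fixed reference
        assert all(r.delta_c >= cfg.reference_delta + cfg.step for r in log.records)

    def test_csv_round_trip(self, config, linear_observer, rng, tmp_path):
        log = run_block(config, linear_observer, rng)
        path = tmp_path / "block.csv"
        log.to_csv(path)
        loaded = BlockLog.from_csv(path, config)
        assert loaded.records == log.records
        assert list(log.to_dataframe().columns) == [
            "trial", "interval_of_change", "delta_c", "response_interval",
            "correct", "confidence", "clamped",
        ]


class TestEstimateThreshold:
    def _log_from_deltas(self, deltas, config):
        records = [
            TrialRecord(i + 1, 1, d, 1, True, 1, False) for i, d in enumerate(deltas)
        ]
        return BlockLog(config=config, records=records)

    def test_constant_tail(self, config):
        deltas = [3.0] * 10 + [2.0] * 20
        est = estimate_threshold(self._log_from_deltas(deltas, config), config)
        assert est.value == 2.0
        assert est.n_retained == 20

    def test_spreadsheet_oracle(self, config):
        rng = np.random.default_rng(4)
        deltas = list(np.round(rng.uniform(0.5, 4.0, 30) * 2) / 2)
        est = estimate_threshold(self._log_from_deltas(deltas, config), config)
        expected = sum(deltas[10:]) / 20  # independent plain-python arithmetic
        assert est.value == pytest.approx(expected)

    def test_invariant_to_first_ten_trials(self, config, rng):
        deltas = list(np.round(rng.uniform(0.5, 4.0, 30) * 2) / 2)
        shuffled = list(rng.permutation(deltas[:10])) + deltas[10:]
        a = estimate_threshold(self._log_from_deltas(deltas, config), config)
        b = estimate_threshold(self._log_from_deltas(shuffled, config), config)
        assert a.value == b.value

    def test_incomplete_log_rejected(self, config):
        with pytest.raises(InvalidDesignError):
            estimate_threshold(self._log_from_deltas([2.5] * 12, config), config)


class TestConvergenceAccuracy:
    def test_three_down(self):
        assert convergence_accuracy(3) == pytest.approx(0.7937005259)
        assert round(convergence_accuracy(3), 3) == 0.794

    def test_one_down(self):
        assert convergence_accuracy(1) == 0.5

    def test_two_down(self):
        assert convergence_accuracy(2) == pytest.approx(np.sqrt(0.5))

    def test_invalid(self):
        with pytest.raises(ValueError):
            convergence_accuracy(0)


class TestTheoreticalThreshold:
    def test_linear_symmetry(self):
        obs = ObserverSpec(gain=1.0, exponent=1.0, offset=35.0, noise=2.0)
        up = theoretical_threshold(obs, "increase", 45.0)
        down = theoretical_threshold(obs, "decrease", 45.0)
        assert up == pytest.approx(down, abs=1e-4)

    def test_closed_form_linear(self):
        # gamma=1, offset 42, base 45 increase: threshold = sqrt(2)*sigma*z(0.794)
        obs = ObserverSpec(gain=1.0, exponent=1.0, offset=42.0, noise=1.5)
        expected = obs.noise * SNR_AT_CONVERGENCE
        assert theoretical_threshold(obs, "increase", 45.0) == pytest.approx(
            expected, abs=1e-4
        )

    def test_matches_grid_scan(self, convex_observer):
        target = convergence_accuracy(3)
        root = theoretical_threshold(convex_observer, "increase", 45.0)
        grid = np.arange(0.01, 5.0, 0.01)
        probs = np.array(
            [prob_correct_detection(d, "increase", 45.0, convex_observer) for d in grid]
        )
        scan = grid[np.argmax(probs >= target)]
        assert abs(root - scan) <= 0.01

    def test_unattainable_signals(self):
        # decrease from 45 saturates at the 42 C offset: max signal 3 < required
        obs = ObserverSpec(gain=1.0, exponent=1.0, offset=42.0, noise=10.0)
        with pytest.raises(ThresholdUnattainableError):
            theoretical_threshold(obs, "decrease", 45.0)

    def test_discrimination_threshold_above_reference(self):
        obs = ObserverSpec(gain=1.0, exponent=1.0, offset=35.0, noise=2.0)
        thr = theoretical_threshold(
            obs, "decrease", 45.0, mode="discrimination", reference_delta=1.5
        )
        det = theoretical_threshold(obs, "decrease", 45.0)
        assert thr == pytest.approx(1.5 + det, abs=1e-3)


class TestStaircaseValidity:
    def test_retained_accuracy_near_convergence_point(self):
        obs = observer_with_threshold(2.0)
        cfg = StaircaseConfig(base_temp=45.0, direction="decrease")
        correct = []
        for i in range(1000):
            log = run_block(cfg, obs, block_rng(101, i, 0))
            correct.extend(r.correct for r in log.records[cfg.n_discard:])
        assert abs(np.mean(correct) - convergence_accuracy(3)) < 0.03

    @pytest.mark.parametrize("threshold", [1.0, 2.0, 3.0])
    def test_parameter_recovery_in_converged_band(self, threshold):
        obs = observer_with_threshold(threshold)
        cfg = StaircaseConfig(base_temp=45.0, direction="decrease")
        ests = [
            estimate_threshold(run_block(cfg, obs, block_rng(77, i, 0)), cfg).value
            for i in range(400)
        ]
        assert abs(np.mean(ests) - threshold) < 0.25


@given(
    responses=st.lists(st.booleans(), min_size=1, max_size=29),
)
@settings(max_examples=60, deadline=None)
def test_delta_stays_on_grid_property(responses):
    cfg = StaircaseConfig(base_temp=45.0, direction="decrease")
    state = initial_state(cfg)
    for correct in responses:
        state = staircase_update(state, correct, cfg)
        offset = (state.current_delta - cfg.initial_delta) / cfg.step
        assert abs(offset - round(offset)) < 1e-9
        assert cfg.step - 1e-12 <= state.current_delta <= cfg.max_delta + 1e-12
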