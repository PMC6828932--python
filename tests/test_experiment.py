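import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from mcisim.experiment import (
    CONDITIONS,
    MethodOfLimitsConfig,
    improvement,
    method_of_limits,
    run_2afc_discrimination,
    run_mci_condition,
    threshold_71,
)
from mcisim.observer import DecoderConfig, PsychometricParams, SimulatedListener

SIGMA_71 = 1.1 / (np.sqrt(2.0) * norm.ppf(0.71))


def deterministic_detector(threshold):
    return lambda v, rng: v >= threshold


class TestMethodOfLimits:
    def test_recovers_known_threshold_within_one_step(self, rng):
        est = method_of_limits(deterministic_detector(0.75), rng=rng)
        assert abs(est - 0.75) <= 0.013

    def test_zero_noise_ascending_descending_endpoints_agree_within_step(self, rng):
        cfg = MethodOfLimitsConfig(n_ascending=1, n_descending=0)
        asc = method_of_limits(deterministic_detector(0.75), cfg, rng)
        cfg = MethodOfLimitsConfig(n_ascending=0, n_descending=1)
        desc = method_of_limits(deterministic_detector(0.75), cfg, rng)
        assert abs(asc - desc) <= 0.013

    def test_simulated_cohort_thresholds_plausible(self, rng):
        # noisy detectors drawn near the motor floor stay above 0.7 V
        for thr in (0.71, 0.765, 0.82):
            listener = SimulatedListener(detect_threshold_v=thr, detect_spread_v=0.005)
            est = method_of_limits(listener.detect, rng=rng)
            assert est >= 0.70
            assert abs(est - thr) < 0.03

    def test_suprathreshold_start_raises(self, rng):
        with pytest.raises(RuntimeError, match="suprathreshold"):
            method_of_limits(deterministic_detector(0.5), rng=rng)

    def test_runaway_sequence_raises(self, rng):
        with pytest.raises(RuntimeError, match="max_steps"):
            method_of_limits(lambda v, r: False, rng=rng)


class TestDiscrimination:
    def test_perfect_listener_scores_100(self, rng):
        listener = SimulatedListener(psychometric=PsychometricParams(sigma=1e-9))
        points = run_2afc_discrimination(listener, rng=rng)
        assert np.all(points["pct_correct"] == 100.0)
        assert np.all(points["n_trials"] == 30)

    def test_near_chance_listener(self, rng):
        listener = SimulatedListener(psychometric=PsychometricParams(sigma=1e6))
        points = run_2afc_discrimination(listener, trials_per_interval=100, sessions=4, rng=rng)
        assert np.all(np.abs(points["pct_correct"] - 50.0) < 13.0)

    def test_planted_69pct_at_1st(self, rng):
        sigma = 1.0 / (np.sqrt(2.0) * norm.ppf(0.69))
        listener = SimulatedListener(psychometric=PsychometricParams(sigma=sigma))
        points = run_2afc_discrimination(listener, rng=rng)
        observed = float(points.loc[points["interval_st"] == 1.0, "pct_correct"].iloc[0])
        # binomial error at n = 30: 3 SDs around 69%
        assert abs(observed - 69.0) <= 3 * 100 * np.sqrt(0.69 * 0.31 / 30)


class TestThreshold71:
    def test_hand_interpolation(self):
        t, _ = threshold_71([(1.0, 69.0), (2.0, 95.0)])
        assert 1.0 < t < 2.0
        assert t == pytest.approx(1.0 + 2.0 / 26.0)

    def test_1p1_semitones_gives_7hz_jnd(self):
        # geometric centering: df = 110*(2**(t/24) - 2**(-t/24))
        t, jnd = threshold_71([(1.0, 71.0 - 0.5), (1.2, 71.0 + 0.5)])
        assert round(110.0 * (2 ** (1.1 / 24) - 2 ** (-1.1 / 24))) == 7
        assert round(jnd) == 7

    def test_sort_invariance(self):
        pts = [(3.0, 99.0), (0.25, 50.0), (1.0, 69.0), (2.0, 95.0), (0.5, 55.0)]
        t1, _ = threshold_71(pts)
        t2, _ = threshold_71(list(reversed(pts)))
        assert t1 == t2

    def test_refuses_extrapolation(self):
        with pytest.raises(ValueError, match="extrapolate"):
            threshold_71([(1.0, 80.0), (2.0, 95.0)])


class TestMciRuns:
    def test_oracle_listener_scores_100_tactile(self, rng, prepared_test_set):
        listener = SimulatedListener(psychometric=PsychometricParams(sigma=1e-9))
        result = run_mci_condition(listener, prepared_test_set, "tactile", rng=rng)
        assert result.percent_correct == 100.0

    def test_presentation_counts_balanced(self, rng, prepared_test_set):
        listener = SimulatedListener()
        result = run_mci_condition(listener, prepared_test_set, "tactile", n_runs=2, rng=rng)
        assert len(result.trials) == 108
        by_pattern = result.trials.groupby("pattern").size()
        assert (by_pattern == 12).all()  # 6 per run x 2 runs
        confusion = result.confusion()
        assert (confusion.sum(axis=1) == 12).all()

    def test_overall_equals_mean_of_cells(self, rng, prepared_test_set):
        listener = SimulatedListener()
        result = run_mci_condition(listener, prepared_test_set, "vocoder8", rng=rng)
        cells = result.tidy()["pct_correct"]
        assert len(cells) == 6
        assert result.percent_correct == pytest.approx(cells.mean())

    def test_uniform_guesser_near_chance(self, rng, prepared_test_set):
        listener = SimulatedListener(psychometric=PsychometricParams(sigma=1e6))
        result = run_mci_condition(listener, prepared_test_set, "tactile", n_runs=10, rng=rng)
        assert result.percent_correct == pytest.approx(100 / 9, abs=4.0)

    def test_duplicate_stimuli_rejected(self, rng, prepared_test_set):
        listener = SimulatedListener()
        with pytest.raises(ValueError, match="duplicate"):
            run_mci_condition(listener, prepared_test_set + prepared_test_set[:1], "tactile", rng=rng)

    def test_unknown_condition_rejected(self, rng, prepared_test_set):
        with pytest.raises(ValueError, match="condition"):
            run_mci_condition(SimulatedListener(), prepared_test_set, "telepathy", rng=rng)

    def test_improvement_of_identical_results_is_zero(self, rng, prepared_test_set):
        listener = SimulatedListener()
        r = run_mci_condition(listener, prepared_test_set, "vocoder4", rng=np.random.default_rng(5))
        r2 = run_mci_condition(listener, prepared_test_set, "vocoder4", rng=np.random.default_rng(5))
        assert improvement(r, r2) == 0.0

    def test_tidy_schema(self, rng, prepared_test_set):
        result = run_mci_condition(SimulatedListener(), prepared_test_set, "combined4", rng=rng)
        tidy = result.tidy(listener_id=3)
        assert list(tidy.columns) == ["listener", "condition", "middle_f0", "interval", "pct_correct"]
        assert set(tidy["condition"]) == {"combined4"}
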