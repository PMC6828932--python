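import numpy as np
import pytest
from scipy.stats import norm

from mcisim.observer import (
    PATTERN_LABELS,
    DecoderConfig,
    PsychometricParams,
    SimulatedListener,
    auditory_pattern_posterior,
    chain_mci_prediction,
    combine_modalities,
    combine_posteriors,
    cue_trajectories,
    decode_contour_vocoded,
    judge_contour_tactile,
    p_correct_2afc,
    tactile_pattern_posterior,
)
from mcisim.stimuli import PATTERNS, ContourSpec, contour_f0_sequence, synthesize_contour
from mcisim.tactile import contour_to_commands
from mcisim.vocoder import VocoderConfig, vocode

# sensory noise putting the 71%-correct 2AFC threshold exactly at 1.1 st
SIGMA_71 = 1.1 / (np.sqrt(2.0) * norm.ppf(0.71))


class TestPCorrect2AFC:
    def test_zero_interval_is_chance(self):
        assert p_correct_2afc(0.0, PsychometricParams(sigma=1.0)) == pytest.approx(0.5)

    def test_asymptote_is_one_minus_lapse(self):
        p = p_correct_2afc(1000.0, PsychometricParams(sigma=1.0, lapse=0.05))
        assert p == pytest.approx(0.95, abs=1e-9)

    def test_value_at_3st_when_threshold_is_1p1(self):
        # closed-form oracle: Phi(3 / (sigma*sqrt(2))) with sigma tuned so
        # Phi(1.1 / (sigma*sqrt(2))) = 0.71
        params = PsychometricParams(sigma=SIGMA_71)
        assert p_correct_2afc(1.1, params) == pytest.approx(0.71, abs=1e-9)
        assert p_correct_2afc(3.0, params) == pytest.approx(0.93438, abs=1e-4)

    def test_monotone_in_interval(self):
        params = PsychometricParams(sigma=1.4)
        ps = [p_correct_2afc(i, params) for i in np.linspace(0, 6, 25)]
        assert np.all(np.diff(ps) >= 0)

    def test_negative_interval_raises(self):
        with pytest.raises(ValueError):
            p_correct_2afc(-1.0, PsychometricParams(sigma=1.0))


class TestChainPrediction:
    def test_paper_worked_example(self):
        # 69% single-step discrimination -> 23% contour identification
        assert round(100 * chain_mci_prediction(0.69)) == 23
        assert chain_mci_prediction(0.69) == pytest.approx(0.22667, abs=1e-4)

    @pytest.mark.parametrize("p,expected", [(1.0, 1.0), (0.5, 0.0625), (0.0, 0.0)])
    def test_closed_form(self, p, expected):
        assert chain_mci_prediction(p) == pytest.approx(expected)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            chain_mci_prediction(1.2)

    def test_chain_lower_bounds_mechanistic_judgment(self, rng):
        # summing two steps before judging a half averages out noise, so the
        # mechanistic contour accuracy should not fall below p_step**4
        params = PsychometricParams(sigma=1.0, flat_criterion=1e-9)
        freqs = np.array([c.freq for c in contour_to_commands(
            contour_f0_sequence(ContourSpec("rising", 220.0, 3)), 220.0)])
        n = 3000
        hits = sum(judge_contour_tactile(freqs, params, rng) == "rising" for _ in range(n))
        acc = hits / n
        p_step = p_correct_2afc(3.0, params)
        assert chain_mci_prediction(p_step) <= acc + 3 * np.sqrt(acc * (1 - acc) / n)


class TestTactileJudgment:
    def _freqs(self, pattern, middle=220.0, interval=3):
        spec = ContourSpec(pattern, middle, interval)
        return np.array(
            [c.freq for c in contour_to_commands(contour_f0_sequence(spec), middle)]
        )

    def test_noiseless_judgment_is_exact_for_every_pattern(self, rng):
        params = PsychometricParams(sigma=1e-9)
        for pattern in PATTERNS:
            assert judge_contour_tactile(self._freqs(pattern), params, rng) == pattern

    def test_infinite_noise_is_chance(self, rng):
        params = PsychometricParams(sigma=1e6)
        n = 4000
        hits = sum(
            judge_contour_tactile(self._freqs(p), params, rng) == p
            for p in PATTERNS
            for _ in range(n // 9)
        )
        assert hits / (9 * (n // 9)) == pytest.approx(1 / 9, abs=0.02)

    def test_accuracy_increases_with_interval(self, rng):
        params = PsychometricParams(sigma=1.4)
        acc = []
        for interval in (1, 3, 5):
            hits = 0
            for pattern in PATTERNS:
                freqs = self._freqs(pattern, interval=interval)
                hits += sum(judge_contour_tactile(freqs, params, rng) == pattern for _ in range(60))
            acc.append(hits / (9 * 60))
        assert acc[0] < acc[1] < acc[2]

    def test_posterior_sums_to_one(self, rng):
        post = tactile_pattern_posterior(self._freqs("rising"), 3, PsychometricParams(sigma=1.4), rng)
        assert post.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(post >= 0)


class TestVocodedDecoder:
    def test_noiseless_8ch_880_5st_all_patterns_correct(self, rng):
        dec = DecoderConfig(noise_sd_env=0.0, noise_sd_centroid=0.0)
        for i, pattern in enumerate(PATTERNS):
            spec = ContourSpec(pattern, 880.0, 5)
            cfg = VocoderConfig(n_channels=8, rng_seed=100 + i)
            voc = vocode(synthesize_contour(spec), cfg)
            assert decode_contour_vocoded(voc, cfg, dec, spec, rng) == pattern

    def test_infinite_noise_is_chance(self, rng, prepared_test_set):
        dec = DecoderConfig(noise_sd_env=1e4, noise_sd_centroid=1e4)
        listener = SimulatedListener(decoder=dec)
        n_rep = 40
        hits = sum(
            listener.identify_vocoded(stim.cues[8], rng) == stim.spec.pattern
            for stim in prepared_test_set
            for _ in range(n_rep)
        )
        assert hits / (54 * n_rep) == pytest.approx(1 / 9, abs=0.03)

    def test_880_accuracy_8ch_not_worse_than_4ch(self, rng, prepared_test_set):
        listener = SimulatedListener()  # default cue noise
        acc = {}
        for nch in (4, 8):
            hits = total = 0
            for stim in prepared_test_set:
                if stim.spec.middle_f0 != 880.0:
                    continue
                for _ in range(20):
                    hits += listener.identify_vocoded(stim.cues[nch], rng) == stim.spec.pattern
                    total += 1
            acc[nch] = hits / total
        assert acc[8] >= acc[4]

    def test_envelope_cue_absent_for_880_present_for_220(self, prepared_test_set):
        # the 500 Hz envelope cutoff removes periodicity for the high range
        for stim in prepared_test_set:
            cues8 = stim.cues[8]
            if stim.spec.middle_f0 == 880.0:
                assert cues8.env_f0_st is None
            else:
                assert cues8.env_f0_st is not None


class TestCombination:
    def test_uniform_times_p_gives_argmax_p(self, rng):
        p = np.zeros(9)
        p[3] = 0.7
        p[5] = 0.3
        uniform = np.full(9, 1 / 9)
        assert combine_modalities(uniform, p, rng) == PATTERN_LABELS[3]

    def test_product_sharpens(self):
        p = np.array([0.4, 0.3, 0.1, 0.05, 0.05, 0.04, 0.03, 0.02, 0.01])
        combined = combine_posteriors(p, p)
        entropy = lambda q: -np.sum(q[q > 0] * np.log(q[q > 0]))
        assert entropy(combined) < entropy(p)

    def test_all_zero_product_falls_back_to_uniform(self):
        a = np.zeros(9)
        a[0] = 1.0
        b = np.zeros(9)
        b[1] = 1.0
        assert np.allclose(combine_posteriors(a, b), 1 / 9)

    def test_posteriors_normalized(self):
        out = combine_posteriors(np.full(9, 1 / 9), np.arange(1.0, 10.0))
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matched_combination_not_worse_than_single_modalities(self, rng, prepared_test_set):
        listener = SimulatedListener()
        n_rep = 10
        scores = {"tactile": 0, "audio": 0, "combined": 0}
        total = 0
        for stim in prepared_test_set:
            for _ in range(n_rep):
                total += 1
                pat = stim.spec.pattern
                scores["tactile"] += listener.identify_tactile(stim.command_freqs, rng) == pat
                scores["audio"] += listener.identify_vocoded(stim.cues[4], rng) == pat
                scores["combined"] += (
                    listener.identify_combined(stim.command_freqs, stim.spec.interval, stim.cues[4], rng)
                    == pat
                )
        margin = 2 * np.sqrt(0.25 / total) * total  # ~2 binomial SDs
        assert scores["combined"] >= scores["tactile"] - margin
        assert scores["combined"] >= scores["audio"] - margin

    def test_seeded_runs_reproducible(self, prepared_test_set):
        stim = prepared_test_set[0]
        listener = SimulatedListener()
        out1 = [
            listener.identify_combined(
                stim.command_freqs, stim.spec.interval, stim.cues[4], np.random.default_rng(99)
            )
        ]
        out2 = [
            listener.identify_combined(
                stim.command_freqs, stim.spec.interval, stim.cues[4], np.random.default_rng(99)
            )
        ]
        assert out1 == out2
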