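"""Simulated listeners.

Three perceptual front-ends are modeled:

* a vibrotactile observer that perceives each note-to-note frequency step in
  semitones corrupted by Gaussian sensory noise, sums the steps within each
  half of the contour, and labels the half rising/flat/falling against a
  symmetric criterion;
* a vocoded-audio decoder that reduces each note of a vocoded stimulus to a
  scalar pitch cue — the periodicity of the summed temporal envelope (only
  informative below the 500 Hz envelope cutoff) or the energy-weighted
  centroid of channel energies — and classifies the noisy five-note cue
  trajectory by nearest canonical contour shape;
* a naive-Bayes combination of the two modalities (element-wise product of
  posteriors).

The audio decoder is an explicit mechanistic stand-in for auditory
perception, not a claim about human hearing; it exists so that the
experiment harness has listeners whose accuracy respects the cue structure
of the stimuli (envelope periodicity for low pitch ranges, spectral place
cues growing with channel count).

The chain heuristic ``p**4`` relates single-step discrimination to
nine-alternative contour identification: a contour judgment can be viewed
as a series of four adjacent-note discriminations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal
from scipy.stats import norm

from .stimuli import PATTERNS, ContourSpec
from .vocoder import VocoderConfig, extract_envelopes

__all__ = [
    "PATTERN_LABELS",
    "PsychometricParams",
    "DecoderConfig",
    "CueSet",
    "p_correct_2afc",
    "chain_mci_prediction",
    "judge_contour_tactile",
    "tactile_pattern_posterior",
    "cue_trajectories",
    "classify_trajectory",
    "auditory_pattern_posterior",
    "decode_contour_vocoded",
    "combine_posteriors",
    "combine_modalities",
    "SimulatedListener",
]

#: Fixed label order used for every 9-vector posterior.
PATTERN_LABELS: tuple[str, ...] = tuple(PATTERNS)

_HALF_DIRECTIONS = {label: dirs for label, dirs in PATTERNS.items()}


@dataclass(frozen=True)
class PsychometricParams:
    """Latent sensitivity of a simulated vibrotactile listener.

    ``sigma`` is the sensory noise SD in semitones on a single perceived
    frequency step. ``flat_criterion`` is the symmetric semitone criterion on
    the summed per-half step for calling a half rising/falling rather than
    flat; the default labels a flat half correctly 90% of the time at
    sigma = 0.5 st. ``lapse`` is the rate of attention lapses (uniform random
    response); ``guess_rate`` is the 2AFC floor.
    """

    sigma: float = 1.405  # st; default puts the 71%-correct 2AFC threshold near 1.1 st
    flat_criterion: float = 1.645  # st (= Phi^-1(0.95) * 2*0.5)
    guess_rate: float = 0.5
    lapse: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0 <= self.lapse < 0.1):
            raise ValueError("lapse must be in [0, 0.1)")
        if self.flat_criterion < 0:
            raise ValueError("flat_criterion must be >= 0")


@dataclass(frozen=True)
class DecoderConfig:
    """Vocoded-audio decoder: cue choice and cue-space noise.

    Cue noise is expressed in each cue's native units: semitones for the
    envelope-periodicity cue, channel indices for the spectral centroid.
    ``flat_eps_*`` are the absolute modulation floors below which a cue
    trajectory reads as flat.
    """

    cue: str = "combined"  # "envelope_f0" | "channel_centroid" | "combined"
    template_patterns: int = 9
    noise_sd_env: float = 1.3  # st
    noise_sd_centroid: float = 0.12  # channel indices
    flat_eps_env: float = 0.5  # st
    flat_eps_centroid: float = 0.08  # channel indices
    fallback: str = "centroid"  # "centroid" | "guess" when envelope cue is absent
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cue not in ("envelope_f0", "channel_centroid", "combined"):
            raise ValueError(f"unknown cue {self.cue!r}")
        if self.fallback not in ("centroid", "guess"):
            raise ValueError(f"unknown fallback {self.fallback!r}")


@dataclass(frozen=True)
class CueSet:
    """Per-note scalar cues of one vocoded stimulus."""

    centroid: np.ndarray  # (5,) energy-weighted mean channel index
    env_f0_st: np.ndarray | None  # (5,) envelope periodicity, semitones re 110 Hz; None if absent


# ---------------------------------------------------------------------------
# analytic psychometrics


def p_correct_2afc(interval: float, params: PsychometricParams) -> float:
    """Probability of a correct two-interval frequency-direction judgment.

    ``p = lapse + (1 - 2*lapse) * Phi(interval / (sigma*sqrt(2)))``: the
    standard equal-variance Gaussian model with sqrt(2) noise scaling for the
    two-interval comparison, lapse-adjusted so p(0) = 0.5 and the asymptote
    is 1 - lapse.
    """
    if interval < 0:
        raise ValueError("interval must be >= 0")
    phi = norm.cdf(interval / (params.sigma * np.sqrt(2.0)))
    return float(params.lapse + (1.0 - 2.0 * params.lapse) * phi)


def chain_mci_prediction(p_step: float) -> float:
    """Contour-identification probability predicted from single-step
    discrimination: ``p_step ** 4`` (four adjacent-note comparisons)."""
    if not (0.0 <= p_step <= 1.0):
        raise ValueError(f"p_step must be in [0, 1], got {p_step}")
    return p_step**4


# ---------------------------------------------------------------------------
# tactile contour judgment


def _half_sums_semitones(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-transition semitone steps and the two per-half sums."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size != 5:
        raise ValueError(f"expected 5 frequencies, got {freqs.size}")
    steps = 12.0 * np.log2(freqs[1:] / freqs[:-1])
    return steps, np.array([steps[0] + steps[1], steps[2] + steps[3]])


def _label_from_halves(d1: int, d2: int) -> str:
    for label, dirs in _HALF_DIRECTIONS.items():
        if dirs == (d1, d2):
            return label
    raise AssertionError("unreachable")


def judge_contour_tactile(
    command_freqs: np.ndarray,
    params: PsychometricParams,
    rng: np.random.Generator | None = None,
) -> str:
    """One simulated trial of tactile contour identification.

    Each of the four frequency transitions is perceived with independent
    Gaussian noise of SD ``sigma*sqrt(2)`` semitones; the two per-half sums
    are compared against ``±flat_criterion`` to call each half rising, flat,
    or falling. A lapse produces a uniform random label.
    """
    rng = np.random.default_rng(params.rng_seed) if rng is None else rng
    if params.lapse > 0 and rng.random() < params.lapse:
        return PATTERN_LABELS[rng.integers(len(PATTERN_LABELS))]
    steps, _ = _half_sums_semitones(command_freqs)
    perceived = steps + rng.normal(0.0, params.sigma * np.sqrt(2.0), size=4)
    halves = np.array([perceived[0] + perceived[1], perceived[2] + perceived[3]])
    dirs = tuple(
        1 if s > params.flat_criterion else (-1 if s < -params.flat_criterion else 0)
        for s in halves
    )
    return _label_from_halves(*dirs)


def tactile_pattern_posterior(
    command_freqs: np.ndarray,
    interval: float,
    params: PsychometricParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Single-trial posterior over the nine patterns from noisy tactile percepts.

    The observer perceives the per-half summed steps with Gaussian noise
    (SD ``2*sigma``) and evaluates the likelihood of each half direction
    assuming the known interval size of the stimulus set; the pattern
    posterior is the outer product of the two half posteriors, mixed with a
    uniform component at the lapse rate.
    """
    rng = np.random.default_rng(params.rng_seed) if rng is None else rng
    steps, _ = _half_sums_semitones(command_freqs)
    perceived = steps + rng.normal(0.0, params.sigma * np.sqrt(2.0), size=4)
    halves = [perceived[0] + perceived[1], perceived[2] + perceived[3]]
    sd = 2.0 * params.sigma
    t = 2.0 * interval  # magnitude of a rising/falling half sum
    half_post = []
    for s in halves:
        lik = np.array(
            [norm.pdf(s, loc=d * t, scale=sd) for d in (1, 0, -1)]
        )  # rising, flat, falling
        total = lik.sum()
        half_post.append(lik / total if total > 0 else np.full(3, 1 / 3))
    dir_index = {1: 0, 0: 1, -1: 2}
    post = np.array(
        [
            half_post[0][dir_index[d1]] * half_post[1][dir_index[d2]]
            for d1, d2 in (_HALF_DIRECTIONS[lab] for lab in PATTERN_LABELS)
        ]
    )
    post = post / post.sum()
    if params.lapse > 0:
        post = (1 - params.lapse) * post + params.lapse / len(post)
    return post


# ---------------------------------------------------------------------------
# vocoded-audio cue extraction and decoding


def _note_cores(spec: ContourSpec, n_samples: int) -> list[slice]:
    fs = spec.sample_rate
    cores = []
    for onset in spec.note_onsets():
        lo = round((onset + spec.ramp_dur) * fs)
        hi = round((onset + spec.note_dur - spec.ramp_dur) * fs)
        cores.append(slice(lo, min(hi, n_samples)))
    return cores


def _autocorr_periodicity(
    segment: np.ndarray, fs: float, f_lo: float = 50.0, f_hi: float = 500.0, r_min: float = 0.25
) -> float | None:
    """Periodicity frequency of a segment via the normalized autocorrelation
    peak in [f_lo, f_hi]; None if no peak exceeds ``r_min``."""
    x = segment - segment.mean()
    denom = float(np.sum(x * x))
    if denom <= 0:
        return None
    ac = sp_signal.correlate(x, x, mode="full")[x.size - 1 :] / denom
    lag_lo = max(2, int(np.floor(fs / f_hi)))
    lag_hi = min(int(np.ceil(fs / f_lo)), ac.size - 2)
    if lag_hi <= lag_lo:
        return None
    window = ac[lag_lo : lag_hi + 1]
    # local maxima only, so the shoulder of the zero-lag peak is not picked
    local = (window[1:-1] >= window[:-2]) & (window[1:-1] >= window[2:])
    idx = np.nonzero(local)[0] + 1
    if idx.size == 0:
        return None
    rmax = float(window[idx].max())
    if rmax < r_min:
        return None
    # period multiples correlate almost as well as the true period; take the
    # shortest lag within 15% of the best correlation
    best = int(idx[window[idx] >= 0.85 * rmax][0])
    lag = lag_lo + best
    a, b, c = ac[lag - 1], ac[lag], ac[lag + 1]
    denom2 = a - 2 * b + c
    delta = 0.5 * (a - c) / denom2 if denom2 != 0 else 0.0
    return float(fs / (lag + np.clip(delta, -0.5, 0.5)))


def cue_trajectories(
    vocoded: np.ndarray, voc_config: VocoderConfig, spec: ContourSpec
) -> CueSet:
    """Reduce a vocoded stimulus to per-note scalar cues.

    The spectral cue is the mean channel index weighted by each channel's
    RMS envelope within the note core. The temporal cue is
    the autocorrelation periodicity of the summed envelope, expressed in
    semitones re 110 Hz; it is reported only if every note yields a
    periodicity below the envelope cutoff, otherwise ``env_f0_st`` is None.
    """
    envs = extract_envelopes(vocoded, voc_config)
    cores = _note_cores(spec, vocoded.size)
    n_ch = voc_config.n_channels
    centroid = np.empty(len(cores))
    env_f0 = np.empty(len(cores))
    env_ok = True
    summed = envs.sum(axis=0)
    for k, core in enumerate(cores):
        # RMS-envelope weights: less sensitive to carrier-noise energy
        # fluctuations than squared-energy weights
        weights = np.array([np.sqrt(np.mean(envs[ch, core] ** 2)) for ch in range(n_ch)])
        total = weights.sum()
        centroid[k] = (
            float(np.sum(np.arange(n_ch) * weights) / total) if total > 0 else (n_ch - 1) / 2
        )
        f = _autocorr_periodicity(summed[core], voc_config.sample_rate)
        if f is None:
            env_ok = False
        else:
            env_f0[k] = 12.0 * np.log2(f / 110.0)
    return CueSet(centroid=centroid, env_f0_st=env_f0 if env_ok else None)


_TEMPLATE_SHAPES: dict[str, np.ndarray] = {}
for _label, (_d1, _d2) in PATTERNS.items():
    _v = np.array([-2.0 * _d1, -_d1, 0.0, _d2, 2.0 * _d2])
    _v = _v - _v.mean()
    _s = _v.std()
    _TEMPLATE_SHAPES[_label] = _v / _s if _s > 0 else _v


def classify_trajectory(
    trajectory: np.ndarray,
    noise_sd: float,
    flat_eps: float,
    rng: np.random.Generator,
) -> tuple[str, np.ndarray]:
    """Noisy nearest-template classification of a five-note cue trajectory.

    Gaussian cue noise (``noise_sd``, raw cue units) is added per note, the
    noisy trajectory is centered and scale-normalized — with the divisor
    floored at ``flat_eps + 1.5*noise_sd`` so weakly modulated trajectories
    shrink toward the flat template instead of being amplified — and the
    nearest of the nine canonical shapes wins. Returns the label and a
    softmax posterior over the nine patterns.
    """
    y = np.asarray(trajectory, dtype=float) + rng.normal(0.0, noise_sd, size=5)
    y = y - y.mean()
    floor = flat_eps + 1.5 * noise_sd
    denom = max(y.std(), floor, 1e-12)
    z = y / denom
    d2 = np.array([np.sum((z - _TEMPLATE_SHAPES[lab]) ** 2) for lab in PATTERN_LABELS])
    tau = max(noise_sd / denom, 0.05)
    logp = -d2 / (2.0 * tau**2)
    post = np.exp(logp - logp.max())
    post /= post.sum()
    label = PATTERN_LABELS[int(np.argmin(d2))]
    return label, post


def _pick_cue(cues: CueSet, config: DecoderConfig) -> tuple[np.ndarray | None, float, float]:
    """Select the active cue trajectory and its (noise_sd, flat_eps)."""
    if config.cue == "envelope_f0":
        traj = cues.env_f0_st
        return traj, config.noise_sd_env, config.flat_eps_env
    if config.cue == "channel_centroid":
        return cues.centroid, config.noise_sd_centroid, config.flat_eps_centroid
    # combined: temporal periodicity when available, spectral place otherwise
    if cues.env_f0_st is not None:
        return cues.env_f0_st, config.noise_sd_env, config.flat_eps_env
    if config.fallback == "centroid":
        return cues.centroid, config.noise_sd_centroid, config.flat_eps_centroid
    return None, 0.0, 0.0


def auditory_pattern_posterior(
    cues: CueSet, config: DecoderConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    traj, noise_sd, flat_eps = _pick_cue(cues, config)
    if traj is None:
        return np.full(len(PATTERN_LABELS), 1.0 / len(PATTERN_LABELS))
    _, post = classify_trajectory(traj, noise_sd, flat_eps, rng)
    return post


def decode_contour_vocoded(
    vocoded: np.ndarray,
    voc_config: VocoderConfig,
    dec_config: DecoderConfig,
    spec: ContourSpec,
    rng: np.random.Generator | None = None,
) -> str:
    """Classify one vocoded stimulus into one of the nine contour patterns."""
    rng = np.random.default_rng(dec_config.rng_seed) if rng is None else rng
    cues = cue_trajectories(vocoded, voc_config, spec)
    traj, noise_sd, flat_eps = _pick_cue(cues, dec_config)
    if traj is None:  # fallback == "guess"
        return PATTERN_LABELS[rng.integers(len(PATTERN_LABELS))]
    label, _ = classify_trajectory(traj, noise_sd, flat_eps, rng)
    return label


# ---------------------------------------------------------------------------
# multisensory combination


def combine_posteriors(p_tactile: np.ndarray, p_auditory: np.ndarray) -> np.ndarray:
    """Naive-Bayes fusion: element-wise product, renormalized; an
    all-zero product falls back to uniform."""
    p = np.asarray(p_tactile, dtype=float) * np.asarray(p_auditory, dtype=float)
    total = p.sum()
    if total <= 0:
        return np.full(p.size, 1.0 / p.size)
    return p / total


def combine_modalities(
    p_tactile: np.ndarray,
    p_auditory: np.ndarray,
    rng: np.random.Generator | None = None,
) -> str:
    """Fused pattern decision: argmax of the combined posterior, ties broken
    at random (seeded)."""
    rng = np.random.default_rng(0) if rng is None else rng
    post = combine_posteriors(p_tactile, p_auditory)
    best = np.nonzero(post >= post.max() - 1e-12)[0]
    return PATTERN_LABELS[int(rng.choice(best))]


# ---------------------------------------------------------------------------
# a full simulated participant


@dataclass(frozen=True)
class SimulatedListener:
    """Parameter bundle driving every procedure of the experiment."""

    psychometric: PsychometricParams = field(default_factory=PsychometricParams)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    detect_threshold_v: float = 0.765  # V
    detect_spread_v: float = 0.0  # V; 0 = deterministic detector

    def detect(self, voltage: float, rng: np.random.Generator) -> bool:
        """Vibration detection at a drive voltage (cumulative-Gaussian model)."""
        if self.detect_spread_v <= 0:
            return voltage >= self.detect_threshold_v
        p = norm.cdf((voltage - self.detect_threshold_v) / self.detect_spread_v)
        return bool(rng.random() < p)

    def respond_2afc(self, interval: float, rng: np.random.Generator) -> bool:
        """One 2AFC trial: perceive the signed step with sqrt(2)-scaled noise,
        pick the interval that felt higher."""
        p = self.psychometric
        if p.lapse > 0 and rng.random() < p.lapse:
            return bool(rng.random() < 0.5)
        percept = interval + rng.normal(0.0, p.sigma * np.sqrt(2.0))
        return bool(percept > 0)

    def identify_tactile(self, command_freqs: np.ndarray, rng: np.random.Generator) -> str:
        return judge_contour_tactile(command_freqs, self.psychometric, rng)

    def identify_vocoded(self, cues: CueSet, rng: np.random.Generator) -> str:
        traj, noise_sd, flat_eps = _pick_cue(cues, self.decoder)
        if traj is None:
            return PATTERN_LABELS[rng.integers(len(PATTERN_LABELS))]
        label, _ = classify_trajectory(traj, noise_sd, flat_eps, rng)
        return label

    def identify_combined(
        self, command_freqs: np.ndarray, interval: float, cues: CueSet, rng: np.random.Generator
    ) -> str:
        p_t = tactile_pattern_posterior(command_freqs, interval, self.psychometric, rng)
        p_a = auditory_pattern_posterior(cues, self.decoder, rng)
        return combine_modalities(p_t, p_a, rng)

    def update(self, spec: ContourSpec, correct_label: str) -> None:
        """Training hook; stationary listeners do not learn."""
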