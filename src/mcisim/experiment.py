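"""Psychophysical procedures and experiment-level scoring.

Implements the classical method of limits for vibration detection
thresholds, the 2AFC vibration-frequency discrimination task with linear
interpolation of the 71%-correct threshold, and the melodic-contour
identification (MCI) runs in five stimulation conditions (vibration alone,
4- or 8-channel vocoder alone, and the two vocoder+vibration combinations),
all driven by :class:`~mcisim.observer.SimulatedListener` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .f0_tracker import TrackerConfig, note_f0s, track_f0
from .observer import PATTERN_LABELS, CueSet, SimulatedListener
from .stimuli import ContourSpec, StimulusSet, contour_f0_sequence
from .tactile import MotorCalibration, contour_to_commands
from .vocoder import VocoderConfig, vocode

__all__ = [
    "CONDITIONS",
    "MethodOfLimitsConfig",
    "MciResult",
    "PreparedStimulus",
    "method_of_limits",
    "run_2afc_discrimination",
    "threshold_71",
    "prepare_stimuli",
    "run_mci_condition",
    "improvement",
]

#: The five stimulation conditions of the design.
CONDITIONS = ("tactile", "vocoder4", "vocoder8", "combined4", "combined8")


@dataclass(frozen=True)
class MethodOfLimitsConfig:
    step: float = 0.013  # V
    n_ascending: int = 3
    n_descending: int = 3
    ascending_start: float = 0.60  # V, must be subthreshold
    descending_start: float = 1.00  # V, must be suprathreshold
    max_steps: int = 500
    alternate: bool = True  # ascending/descending sequences alternate

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")


def method_of_limits(
    detector,
    config: MethodOfLimitsConfig = MethodOfLimitsConfig(),
    rng: np.random.Generator | None = None,
) -> float:
    """Detection threshold by the method of limits.

    ``detector(voltage, rng) -> bool`` is queried along alternating ascending
    and descending voltage staircases in steps of ``config.step``. Each
    sequence's endpoint is the mean of the two voltages straddling the
    response change (last undetected / first detected for ascending, last
    detected / first undetected for descending); the threshold is the mean of
    all endpoints.
    """
    rng = np.random.default_rng(0) if rng is None else rng

    def ascending() -> float:
        v = config.ascending_start
        if detector(v, rng):
            raise RuntimeError(
                f"ascending sequence started suprathreshold at {v:.3f} V; "
                "lower ascending_start"
            )
        for _ in range(config.max_steps):
            prev = v
            v += config.step
            if detector(v, rng):
                return (prev + v) / 2.0
        raise RuntimeError("ascending sequence exceeded max_steps without detection")

    def descending() -> float:
        v = config.descending_start
        if not detector(v, rng):
            raise RuntimeError(
                f"descending sequence started subthreshold at {v:.3f} V; "
                "raise descending_start"
            )
        for _ in range(config.max_steps):
            prev = v
            v -= config.step
            if not detector(v, rng):
                return (prev + v) / 2.0
        raise RuntimeError("descending sequence exceeded max_steps while detecting")

    endpoints: list[float] = []
    if config.alternate:
        for i in range(max(config.n_ascending, config.n_descending)):
            if i < config.n_ascending:
                endpoints.append(ascending())
            if i < config.n_descending:
                endpoints.append(descending())
    else:
        endpoints += [ascending() for _ in range(config.n_ascending)]
        endpoints += [descending() for _ in range(config.n_descending)]
    return float(np.mean(endpoints))


def run_2afc_discrimination(
    listener: SimulatedListener,
    intervals: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 3.0),
    trials_per_interval: int = 10,
    sessions: int = 3,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """2AFC frequency discrimination: each interval tested
    ``trials_per_interval`` times per session in random order, over
    ``sessions`` sessions. Returns percent correct per interval."""
    rng = np.random.default_rng(0) if rng is None else rng
    correct = {i: 0 for i in intervals}
    n = {i: 0 for i in intervals}
    for _ in range(sessions):
        order = np.repeat(intervals, trials_per_interval)
        rng.shuffle(order)
        for interval in order:
            n[interval] += 1
            if listener.respond_2afc(float(interval), rng):
                correct[interval] += 1
    return pd.DataFrame(
        {
            "interval_st": list(intervals),
            "n_trials": [n[i] for i in intervals],
            "pct_correct": [100.0 * correct[i] / n[i] for i in intervals],
        }
    )


def threshold_71(
    points: pd.DataFrame | list[tuple[float, float]],
    pct_level: float = 71.0,
    center_hz: float = 110.0,
) -> tuple[float, float]:
    """Discrimination threshold by linear interpolation of the psychometric
    points at ``pct_level`` percent correct.

    ``points`` holds (interval in semitones, percent correct) pairs in any
    order; they are sorted by interval and the first bracketing pair is
    interpolated. Also returns the equivalent frequency JND at ``center_hz``:
    two frequencies ``t`` semitones apart centered (geometrically) on
    ``center_hz`` differ by ``center_hz * (2**(t/24) - 2**(-t/24))`` Hz.

    Returns ``(threshold_semitones, jnd_hz)``; raises if no pair of adjacent
    points straddles the level (extrapolation is refused).
    """
    if isinstance(points, pd.DataFrame):
        pairs = list(zip(points["interval_st"], points["pct_correct"]))
    else:
        pairs = list(points)
    pairs.sort(key=lambda p: p[0])
    for (x0, y0), (x1, y1) in zip(pairs, pairs[1:]):
        if (y0 - pct_level) * (y1 - pct_level) <= 0 and y0 != y1:
            t = x0 + (pct_level - y0) * (x1 - x0) / (y1 - y0)
            jnd = center_hz * (2.0 ** (t / 24.0) - 2.0 ** (-t / 24.0))
            return float(t), float(jnd)
    raise ValueError(
        f"no adjacent points straddle {pct_level}% correct; refusing to extrapolate"
    )


# ---------------------------------------------------------------------------
# MCI runs


@dataclass(frozen=True)
class PreparedStimulus:
    """One stimulus with everything a listener needs, precomputed once:
    the tracked note F0s, the vibration command frequencies, and the vocoded
    cue trajectories for each channel count."""

    spec: ContourSpec
    note_f0s: np.ndarray  # (5,) tracked consensus F0s, Hz
    command_freqs: np.ndarray  # (5,) vibration frequencies, Hz
    cues: dict[int, CueSet]  # channel count -> cue trajectories


def prepare_stimuli(
    stimset: StimulusSet,
    channel_counts: tuple[int, ...] = (4, 8),
    calib: MotorCalibration = MotorCalibration(),
    tracker_config: TrackerConfig = TrackerConfig(),
    seed: int = 0,
    use_tracker: bool = True,
) -> list[PreparedStimulus]:
    """Run the full signal chain over a stimulus set.

    For each stimulus: track the note F0s (or take the nominal F0s when
    ``use_tracker`` is False), transpose them to vibration commands, vocode
    at each channel count with a per-stimulus noise seed derived from
    ``seed``, and extract the decoder cue trajectories.
    """
    from .observer import cue_trajectories  # local import to avoid cycle at import time

    prepared: list[PreparedStimulus] = []
    for i, (spec, wave) in enumerate(stimset):
        if use_tracker:
            f0s = note_f0s(track_f0(wave, tracker_config), spec)
            if np.any(np.isnan(f0s)):
                raise RuntimeError(f"F0 tracking failed for {spec}")
        else:
            f0s = contour_f0_sequence(spec)
        commands = contour_to_commands(f0s, spec.middle_f0, calib, spec=spec)
        cues: dict[int, CueSet] = {}
        for n_ch in channel_counts:
            cfg = VocoderConfig(
                n_channels=n_ch, sample_rate=spec.sample_rate, rng_seed=seed * 10007 + i * 17 + n_ch
            )
            cues[n_ch] = cue_trajectories(vocode(wave, cfg), cfg, spec)
        prepared.append(
            PreparedStimulus(
                spec=spec,
                note_f0s=f0s,
                command_freqs=np.array([c.freq for c in commands]),
                cues=cues,
            )
        )
    return prepared


@dataclass
class MciResult:
    """Trial-level MCI outcomes of one listener in one condition."""

    condition: str
    trials: pd.DataFrame  # run, pattern, middle_f0, interval, response, correct
    n_runs: int

    @staticmethod
    def _pct(df: pd.DataFrame) -> float:
        return float(100.0 * df["correct"].mean())

    @property
    def percent_correct(self) -> float:
        return self._pct(self.trials)

    def by_middle_f0(self) -> dict[float, float]:
        return {
            f0: self._pct(g) for f0, g in self.trials.groupby("middle_f0")
        }

    def by_interval(self) -> dict[int, float]:
        return {int(i): self._pct(g) for i, g in self.trials.groupby("interval")}

    def confusion(self) -> pd.DataFrame:
        """9x9 confusion matrix (rows: presented, columns: responded)."""
        mat = pd.crosstab(self.trials["pattern"], self.trials["response"])
        return mat.reindex(index=PATTERN_LABELS, columns=PATTERN_LABELS, fill_value=0)

    def tidy(self, listener_id: str | int = 0) -> pd.DataFrame:
        """Tidy per-cell scores: listener, condition, middle_f0, interval, pct_correct."""
        rows = []
        for (f0, iv), g in self.trials.groupby(["middle_f0", "interval"]):
            rows.append(
                {
                    "listener": listener_id,
                    "condition": self.condition,
                    "middle_f0": f0,
                    "interval": int(iv),
                    "pct_correct": self._pct(g),
                }
            )
        return pd.DataFrame(rows)


def _one_trial(
    listener: SimulatedListener, stim: PreparedStimulus, condition: str, rng: np.random.Generator
) -> str:
    if condition == "tactile":
        return listener.identify_tactile(stim.command_freqs, rng)
    if condition in ("vocoder4", "vocoder8"):
        return listener.identify_vocoded(stim.cues[int(condition[-1])], rng)
    if condition in ("combined4", "combined8"):
        return listener.identify_combined(
            stim.command_freqs, stim.spec.interval, stim.cues[int(condition[-1])], rng
        )
    raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


def run_mci_condition(
    listener: SimulatedListener,
    prepared: list[PreparedStimulus],
    condition: str,
    n_runs: int = 2,
    rng: np.random.Generator | None = None,
) -> MciResult:
    """MCI testing in one condition: each run presents every stimulus exactly
    once in a seeded random order (sampling without replacement); scores are
    pooled over runs."""
    rng = np.random.default_rng(0) if rng is None else rng
    specs = [p.spec for p in prepared]
    if len(set(specs)) != len(specs):
        raise ValueError("duplicate stimuli in the presentation set")
    records = []
    for run in range(n_runs):
        order = rng.permutation(len(prepared))
        for idx in order:
            stim = prepared[idx]
            response = _one_trial(listener, stim, condition, rng)
            records.append(
                {
                    "run": run,
                    "pattern": stim.spec.pattern,
                    "middle_f0": stim.spec.middle_f0,
                    "interval": stim.spec.interval,
                    "response": response,
                    "correct": response == stim.spec.pattern,
                }
            )
    return MciResult(condition=condition, trials=pd.DataFrame(records), n_runs=n_runs)


def run_training(
    listener: SimulatedListener,
    prepared: list[PreparedStimulus],
    condition: str,
    n_runs: int = 2,
    rng: np.random.Generator | None = None,
) -> MciResult:
    """Training runs with feedback: identical presentation scheme, but the
    listener's learning hook is called with the correct label after every
    trial (a no-op for stationary listeners)."""
    rng = np.random.default_rng(0) if rng is None else rng
    result = run_mci_condition(listener, prepared, condition, n_runs=n_runs, rng=rng)
    for _, row in result.trials.iterrows():
        spec = next(p.spec for p in prepared if p.spec.pattern == row["pattern"]
                    and p.spec.middle_f0 == row["middle_f0"] and p.spec.interval == row["interval"])
        listener.update(spec, spec.pattern)
    return result


def improvement(combined: MciResult, baseline: MciResult) -> float:
    """Percentage-point change of the combined condition over its vocoder
    baseline (may be negative)."""
    return combined.percent_correct - baseline.percent_correct
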