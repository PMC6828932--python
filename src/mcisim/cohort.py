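"""Synthetic listener cohorts.

Stands in for a participant pool: samples reproducible bundles of
simulated-listener parameters (tactile sensory noise, vibration detection
threshold, audio-decoder cue noise, lapse rate) with the between-subject
structure the analyses assume. The default distributions are calibration
choices — centered so that the median listener's 2AFC discrimination
threshold sits near 1.1 semitones and the detection threshold inside the
0.71-0.82 V band, with audio cue noise set so vibration-alone and 4-channel
accuracies are comparable and 8-channel is better — not measured facts
about any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .observer import DecoderConfig, PsychometricParams, SimulatedListener

__all__ = ["CohortSpec", "sample_cohort", "cohort_summary"]


@dataclass(frozen=True)
class CohortSpec:
    """Distributional description of a simulated cohort.

    Tactile noise ``sigma`` and the two decoder noises are log-normal
    (median, log-SD); detection thresholds are normal, truncated to
    ``threshold_range``. ``salience_log_sd`` scales listener-to-listener
    variation of the audio-to-tactile noise ratio: each listener's decoder
    noises share one log-normal salience factor, so some listeners lean on
    audition and others on touch.
    """

    n_listeners: int = 8
    sigma_median: float = 1.405  # st; median 71% 2AFC threshold ~ 1.1 st
    sigma_log_sd: float = 0.18
    threshold_mean_v: float = 0.765  # V
    threshold_sd_v: float = 0.03
    threshold_range: tuple[float, float] = (0.71, 0.82)
    noise_env_median: float = 1.3  # st
    noise_centroid_median: float = 0.12  # channel indices
    salience_log_sd: float = 0.25
    lapse: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_listeners < 1:
            raise ValueError("n_listeners must be >= 1")
        for name in ("sigma_log_sd", "threshold_sd_v", "salience_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive (degenerate distribution)")
        if self.sigma_median <= 0 or self.noise_env_median <= 0 or self.noise_centroid_median <= 0:
            raise ValueError("distribution medians must be positive")


def sample_cohort(spec: CohortSpec) -> list[SimulatedListener]:
    """Draw ``n_listeners`` parameter bundles; reproducible given the seed."""
    rng = np.random.default_rng(spec.rng_seed)
    listeners = []
    for i in range(spec.n_listeners):
        sigma = spec.sigma_median * np.exp(rng.normal(0.0, spec.sigma_log_sd))
        lo, hi = spec.threshold_range
        thr = float(np.clip(rng.normal(spec.threshold_mean_v, spec.threshold_sd_v), lo, hi))
        salience = np.exp(rng.normal(0.0, spec.salience_log_sd))
        listeners.append(
            SimulatedListener(
                psychometric=PsychometricParams(
                    sigma=float(sigma), lapse=spec.lapse, rng_seed=spec.rng_seed + i
                ),
                decoder=DecoderConfig(
                    noise_sd_env=float(spec.noise_env_median * salience),
                    noise_sd_centroid=float(spec.noise_centroid_median * salience),
                    rng_seed=spec.rng_seed + 1000 + i,
                ),
                detect_threshold_v=thr,
                detect_spread_v=0.005,
            )
        )
    return listeners


def cohort_summary(listeners: list[SimulatedListener]) -> pd.DataFrame:
    """One row per listener with the sampled parameters (stable schema)."""
    return pd.DataFrame(
        {
            "listener": range(len(listeners)),
            "sigma_st": [l.psychometric.sigma for l in listeners],
            "lapse": [l.psychometric.lapse for l in listeners],
            "detect_threshold_v": [l.detect_threshold_v for l in listeners],
            "noise_env_st": [l.decoder.noise_sd_env for l in listeners],
            "noise_centroid_ch": [l.decoder.noise_sd_centroid for l in listeners],
        }
    )
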