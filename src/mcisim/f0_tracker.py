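"""Framewise spectral-peak maximum-likelihood F0 estimation.

Emulates a real-time pitch tracker of the fiddle~ family: each 1024-sample
frame is Hann-windowed, zero-padded to a 2048-point FFT, up to 20 spectral
peaks are picked (with quadratic interpolation over adjacent bins), and the
F0 is the candidate whose harmonic series best matches the peaks, scored by
an amplitude-weighted Gaussian closeness kernel in log-frequency. A frame is
declared voiced only if at least four peaks contribute to the winning
candidate, or the contributing peaks carry at least 1% of the frame power.
A new estimate is made every 512 samples.

Per-note consensus F0s are the median of valid frame estimates whose centers
fall inside the note's steady-state portion (ramps excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks as sp_find_peaks

from .stimuli import ContourSpec

__all__ = [
    "TrackerConfig",
    "F0Track",
    "spectral_peaks",
    "estimate_f0",
    "track_f0",
    "note_f0s",
]


@dataclass(frozen=True)
class TrackerConfig:
    frame_len: int = 1024  # samples
    fft_len: int = 2048  # zero-padded FFT size
    hop: int = 512  # samples between estimates
    max_peaks: int = 20
    min_peaks_valid: int = 4
    power_fraction_valid: float = 0.01
    f0_min: float = 50.0  # Hz, candidate search range
    f0_max: float = 2000.0
    min_peak_spacing_hz: float = 90.0  # window-sidelobe rejection
    kernel_semitones: float = 0.5  # width of the closeness kernel
    tolerance_semitones: float = 0.5  # a peak "contributes" within this of a harmonic
    sample_rate: float = 22050.0

    def __post_init__(self) -> None:
        if self.fft_len < self.frame_len:
            raise ValueError("fft_len must be >= frame_len")
        if self.hop > self.frame_len:
            raise ValueError("hop must be <= frame_len")
        if not (0 < self.power_fraction_valid < 1):
            raise ValueError("power_fraction_valid must be in (0, 1)")


@dataclass
class F0Track:
    """Framewise estimates: time of each frame center, F0 (NaN if invalid),
    and a validity flag per frame."""

    times: np.ndarray  # s
    f0: np.ndarray  # Hz, NaN where invalid
    valid: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.times)


def spectral_peaks(frame: np.ndarray, config: TrackerConfig = TrackerConfig()) -> list[tuple[float, float]]:
    """Pick up to ``max_peaks`` spectral peaks of one frame.

    Returns (frequency Hz, linear amplitude) pairs sorted by descending
    amplitude. Peak frequencies/amplitudes are refined by quadratic
    interpolation over the three bins around each local maximum. Silence
    yields an empty list. Peak picking is relative to the frame's own
    spectral maximum, so the result is invariant to overall scaling.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size != config.frame_len:
        raise ValueError(f"expected frame of {config.frame_len} samples, got {frame.size}")
    window = np.hanning(config.frame_len)
    spec = np.fft.rfft(frame * window, n=config.fft_len)
    mag = np.abs(spec)
    mmax = mag.max()
    if mmax <= 0:
        return []
    floor = 1e-6 * mmax
    # minimum spacing rejects the analysis window's spectral sidelobes, which
    # cluster within a few bins of each true partial
    spacing_bins = max(1, round(config.min_peak_spacing_hz * config.fft_len / config.sample_rate))
    idx, _ = sp_find_peaks(mag, height=floor, distance=spacing_bins)
    idx = idx[(idx > 0) & (idx < mag.size - 1)]
    if idx.size == 0:
        return []
    alpha, beta, gamma = mag[idx - 1], mag[idx], mag[idx + 1]
    denom = alpha - 2 * beta + gamma
    delta = np.where(np.abs(denom) > 0, 0.5 * (alpha - gamma) / np.where(denom == 0, 1, denom), 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    freqs = (idx + delta) * config.sample_rate / config.fft_len
    amps = beta - 0.25 * (alpha - gamma) * delta
    order = np.argsort(amps)[::-1][: config.max_peaks]
    return [(float(freqs[i]), float(amps[i])) for i in order]


def _peak_harmonic_match(
    peak_freqs: np.ndarray, peak_amps: np.ndarray, candidates: np.ndarray, config: TrackerConfig
) -> np.ndarray:
    """Score of every candidate F0: sum over peaks of amplitude times a
    Gaussian kernel in the log-frequency distance to the nearest harmonic."""
    harm = np.maximum(np.round(peak_freqs[None, :] / candidates[:, None]), 1.0)
    dist_st = 12.0 * np.abs(np.log2(peak_freqs[None, :] / (harm * candidates[:, None])))
    kernel = np.exp(-0.5 * (dist_st / config.kernel_semitones) ** 2)
    return (peak_amps[None, :] * kernel).sum(axis=1)


def _contributors(
    peak_freqs: np.ndarray, peak_amps: np.ndarray, f0: float, config: TrackerConfig
) -> np.ndarray:
    harm = np.maximum(np.round(peak_freqs / f0), 1.0)
    dist_st = 12.0 * np.abs(np.log2(peak_freqs / (harm * f0)))
    return dist_st <= config.tolerance_semitones


def estimate_f0(
    peaks: list[tuple[float, float]],
    signal_power: float,
    config: TrackerConfig = TrackerConfig(),
) -> tuple[float | None, list[tuple[float, float]]]:
    """Maximum-likelihood F0 from a set of spectral peaks.

    Candidates on a geometric 1/24-octave grid over the search range are
    scored by harmonic match; near-ties (within 1% of the best score) are
    resolved in favour of the highest candidate, which rejects subharmonic
    (half-F0) errors since a subharmonic matches the same peaks no better.
    The winner is refined by the amplitude-weighted mean of contributing peak
    frequencies divided by their harmonic numbers.

    Returns ``(f0, contributing_peaks)``; ``f0`` is None when neither
    validity rule holds (fewer than ``min_peaks_valid`` contributors and
    contributing power below ``power_fraction_valid`` of ``signal_power``).
    """
    if not peaks:
        return None, []
    pf = np.array([p[0] for p in peaks])
    pa = np.array([p[1] for p in peaks])
    in_range = pf > 0
    pf, pa = pf[in_range], pa[in_range]
    if pf.size == 0:
        return None, []
    n_cand = int(np.ceil(24 * np.log2(config.f0_max / config.f0_min))) + 1
    candidates = config.f0_min * 2.0 ** (np.arange(n_cand) / 24.0)
    candidates = candidates[candidates <= config.f0_max]
    scores = _peak_harmonic_match(pf, pa, candidates, config)
    if scores.max() <= 0:
        return None, []
    # local maxima of the coarse score (grid quantization penalizes high-F0
    # candidates, whose harmonics cannot re-snap; refine before comparing)
    interior = (scores[1:-1] >= scores[:-2]) & (scores[1:-1] >= scores[2:])
    cand_idx = set((np.nonzero(interior)[0] + 1).tolist()) | {0, scores.size - 1, int(np.argmax(scores))}
    top = sorted(cand_idx, key=lambda i: scores[i], reverse=True)[:10]
    # seed with the peak frequencies themselves so a sparse harmonic stack's
    # true F0 is always on the shortlist
    seeds = [float(candidates[i]) for i in top] + [
        float(f) for f in pf if config.f0_min <= f <= config.f0_max
    ]
    refined: list[float] = []
    for c in seeds:
        for _ in range(2):
            sel = _contributors(pf, pa, c, config)
            if not sel.any():
                break
            harm = np.maximum(np.round(pf[sel] / c), 1.0)
            c = float(np.sum(pa[sel] * pf[sel] / harm) / np.sum(pa[sel]))
        refined.append(c)
    exact = _peak_harmonic_match(pf, pa, np.asarray(refined), config)
    best = exact.max()
    if best <= 0:
        return None, []
    # highest refined candidate within 1% of the best score: octave-safe
    # tie-break (a subharmonic matches the same peaks no better)
    f0 = max(c for c, s in zip(refined, exact) if s >= 0.99 * best)
    contrib = _contributors(pf, pa, f0, config)
    contributing = [(float(f), float(a)) for f, a in zip(pf[contrib], pa[contrib])]
    # spectral peak magnitude -> equivalent time-domain power of a sinusoid
    # of amplitude A over the frame: |X| ~ A*sum(w)/2, power = A^2/2 * N
    wsum = np.hanning(config.frame_len).sum()
    amps_td = 2.0 * pa[contrib] / wsum
    contrib_power = float(np.sum(amps_td**2 / 2.0) * config.frame_len)
    valid = (contrib.sum() >= config.min_peaks_valid) or (
        signal_power > 0 and contrib_power >= config.power_fraction_valid * signal_power
    )
    if not valid:
        return None, contributing
    return f0, contributing


def track_f0(waveform: np.ndarray, config: TrackerConfig = TrackerConfig()) -> F0Track:
    """Run the framewise tracker over a waveform.

    Yields ``floor((N - frame_len)/hop) + 1`` estimates; frame ``i`` covers
    samples ``[i*hop, i*hop + frame_len)`` and is stamped at its center.
    """
    waveform = np.asarray(waveform, dtype=float)
    n = waveform.size
    if n < config.frame_len:
        return F0Track(np.empty(0), np.empty(0), np.empty(0, dtype=bool))
    n_frames = (n - config.frame_len) // config.hop + 1
    times = (np.arange(n_frames) * config.hop + config.frame_len / 2) / config.sample_rate
    f0s = np.full(n_frames, np.nan)
    valid = np.zeros(n_frames, dtype=bool)
    for i in range(n_frames):
        frame = waveform[i * config.hop : i * config.hop + config.frame_len]
        power = float(np.sum(frame**2))
        f0, _ = estimate_f0(spectral_peaks(frame, config), power, config)
        if f0 is not None:
            f0s[i] = f0
            valid[i] = True
    return F0Track(times=times, f0=f0s, valid=valid)


def note_f0s(track: F0Track, spec: ContourSpec) -> np.ndarray:
    """Per-note consensus F0s (median over valid frames) for a contour.

    A frame belongs to note ``k`` iff its center lies in the half-open
    steady-state interval ``[onset + ramp, offset - ramp)``. Notes with no
    valid frame get NaN.
    """
    out = np.full(spec.n_notes, np.nan)
    for k, onset in enumerate(spec.note_onsets()):
        lo = onset + spec.ramp_dur
        hi = onset + spec.note_dur - spec.ramp_dur
        sel = (track.times >= lo) & (track.times < hi) & track.valid
        if sel.any():
            out[k] = np.median(track.f0[sel])
    return out
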