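"""Melodic-contour stimulus synthesis.

Each stimulus is a five-note melody of harmonic complex tones. The pitch
direction of the first half (notes 1-3) and of the second half (notes 3-5)
are independently rising, flat, or falling, giving nine contour patterns.
Adjacent notes are separated by a fixed number of semitones, and the middle
(third) note sits at a configurable fundamental frequency (F0).

Notes are 500 ms with 100 ms silent gaps, built from sine-phase harmonics up
to 4 kHz with a -8 dB/octave spectral slope and 20 ms raised-cosine on/off
ramps, sampled at 22,050 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "PATTERNS",
    "ContourSpec",
    "NoteSynthParams",
    "StimulusSet",
    "contour_f0_sequence",
    "synthesize_note",
    "synthesize_contour",
    "generate_test_set",
    "generate_training_set",
    "write_wav",
    "read_wav",
    "write_stimulus_set",
]

#: The nine contour patterns: direction of each half (first-half, second-half).
#: Single-word labels denote the same direction in both halves.
PATTERNS: dict[str, tuple[int, int]] = {
    "rising": (1, 1),
    "rising-flat": (1, 0),
    "rising-falling": (1, -1),
    "flat-rising": (0, 1),
    "flat": (0, 0),
    "flat-falling": (0, -1),
    "falling-rising": (-1, 1),
    "falling-flat": (-1, 0),
    "falling": (-1, -1),
}


@dataclass(frozen=True)
class ContourSpec:
    """One melodic contour: pattern, pitch range and interval, note timing."""

    pattern: str
    middle_f0: float  # Hz, F0 of the third note
    interval: int  # semitones between adjacent notes
    note_dur: float = 0.5  # s
    gap_dur: float = 0.1  # s
    ramp_dur: float = 0.02  # s
    sample_rate: float = 22050.0  # Hz

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(
                f"unknown contour pattern {self.pattern!r}; "
                f"expected one of {sorted(PATTERNS)}"
            )
        if self.middle_f0 <= 0:
            raise ValueError(f"middle_f0 must be positive, got {self.middle_f0}")
        if self.interval <= 0:
            raise ValueError(f"interval must be a positive semitone count, got {self.interval}")
        if self.note_dur <= 2 * self.ramp_dur:
            raise ValueError("note_dur must exceed twice the ramp duration")

    @property
    def n_notes(self) -> int:
        return 5

    @property
    def duration(self) -> float:
        """Total stimulus duration in seconds (no trailing gap)."""
        return self.n_notes * self.note_dur + (self.n_notes - 1) * self.gap_dur

    def note_onsets(self) -> np.ndarray:
        """Onset time of each note on the note/gap grid, in seconds."""
        return np.arange(self.n_notes) * (self.note_dur + self.gap_dur)


@dataclass(frozen=True)
class NoteSynthParams:
    """Harmonic-complex synthesis parameters.

    ``spectral_slope`` is in dB per octave (negative tilts energy toward the
    fundamental); all harmonics are in sine phase up to ``max_harmonic_freq``.
    """

    max_harmonic_freq: float = 4000.0  # Hz
    spectral_slope: float = -8.0  # dB/octave
    target_rms: float = 0.1  # pre-ramp RMS of every note (equal loudness proxy)


@dataclass
class StimulusSet:
    """A collection of (spec, waveform) pairs with a role tag."""

    items: list[tuple[ContourSpec, np.ndarray]]
    role: str  # "test" or "training"

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[tuple[ContourSpec, np.ndarray]]:
        return iter(self.items)

    @property
    def specs(self) -> list[ContourSpec]:
        return [spec for spec, _ in self.items]

    def manifest(self) -> pd.DataFrame:
        """One row per stimulus: pattern, middle_f0, interval, filename."""
        rows = [
            {
                "pattern": s.pattern,
                "middle_f0": s.middle_f0,
                "interval": s.interval,
                "filename": stimulus_filename(s),
            }
            for s in self.specs
        ]
        return pd.DataFrame(rows)


def stimulus_filename(spec: ContourSpec) -> str:
    return f"{spec.pattern}_{spec.middle_f0:g}Hz_{spec.interval}st.wav"


def contour_f0_sequence(spec: ContourSpec) -> np.ndarray:
    """Return the five note F0s (Hz) of a contour.

    The third note equals ``middle_f0``; within each half, adjacent notes
    differ by the half's direction times ``interval`` semitones, i.e. by a
    frequency ratio of ``2**(±interval/12)`` (or 1 for a flat half).
    """
    d1, d2 = PATTERNS[spec.pattern]
    step = 2.0 ** (spec.interval / 12.0)
    mid = spec.middle_f0
    return np.array(
        [
            mid * step ** (-2 * d1),
            mid * step ** (-d1),
            mid,
            mid * step ** (d2),
            mid * step ** (2 * d2),
        ]
    )


def _raised_cosine_ramps(n: int, ramp_samples: int) -> np.ndarray:
    """Unit envelope with raised-cosine onset/offset ramps."""
    env = np.ones(n)
    if ramp_samples > 0:
        t = np.arange(ramp_samples) / ramp_samples
        ramp = 0.5 * (1.0 - np.cos(np.pi * t))
        env[:ramp_samples] = ramp
        env[-ramp_samples:] = ramp[::-1]
    return env


def synthesize_note(
    f0: float,
    dur: float,
    fs: float,
    params: NoteSynthParams = NoteSynthParams(),
    ramp_dur: float = 0.02,
) -> np.ndarray:
    """Synthesize one harmonic complex tone.

    Harmonics ``n*f0 <= max_harmonic_freq`` are summed in sine phase with the
    amplitude of harmonic ``n`` attenuated by ``spectral_slope`` dB per octave
    relative to the fundamental, i.e. ``10**(slope*log2(n)/20)``. The note is
    normalized to ``target_rms`` before the raised-cosine ramps are applied,
    so that all notes of a melody carry equal RMS and level is not a contour
    cue.
    """
    if f0 <= 0:
        raise ValueError(f"f0 must be positive, got {f0}")
    if f0 > params.max_harmonic_freq:
        raise ValueError(
            f"f0={f0:g} Hz exceeds max_harmonic_freq={params.max_harmonic_freq:g} Hz: "
            "no harmonics in band"
        )
    n_samples = round(dur * fs)
    t = np.arange(n_samples) / fs
    n_harm = int(math.floor(params.max_harmonic_freq / f0))
    harmonics = np.arange(1, n_harm + 1)
    # -8 dB/octave => amp(n) = 10**(slope_dB * log2(n) / 20)
    amps = 10.0 ** (params.spectral_slope * np.log2(harmonics) / 20.0)
    wave = (amps[:, None] * np.sin(2.0 * np.pi * f0 * harmonics[:, None] * t)).sum(axis=0)
    rms = np.sqrt(np.mean(wave**2))
    if rms > 0:
        wave *= params.target_rms / rms
    wave *= _raised_cosine_ramps(n_samples, round(ramp_dur * fs))
    return wave


def synthesize_contour(
    spec: ContourSpec, params: NoteSynthParams = NoteSynthParams()
) -> np.ndarray:
    """Render a full five-note contour with silent gaps between notes."""
    fs = spec.sample_rate
    gap = np.zeros(round(spec.gap_dur * fs))
    f0s = contour_f0_sequence(spec)
    pieces: list[np.ndarray] = []
    for i, f0 in enumerate(f0s):
        if i > 0:
            pieces.append(gap)
        pieces.append(
            synthesize_note(f0, spec.note_dur, fs, params=params, ramp_dur=spec.ramp_dur)
        )
    return np.concatenate(pieces)


def _build_set(
    middle_f0s: tuple[float, ...], intervals: tuple[int, ...], role: str
) -> StimulusSet:
    items = [
        (spec, synthesize_contour(spec))
        for spec in (
            ContourSpec(pattern=p, middle_f0=f, interval=i)
            for f in middle_f0s
            for i in intervals
            for p in PATTERNS
        )
    ]
    return StimulusSet(items=items, role=role)


def generate_test_set() -> StimulusSet:
    """The 54-stimulus test set: {220, 880} Hz middle F0 x {1, 3, 5} st x 9 patterns."""
    return _build_set((220.0, 880.0), (1, 3, 5), "test")


def generate_training_set() -> StimulusSet:
    """The 18-stimulus training set: 440 Hz middle F0 x {2, 4} st x 9 patterns."""
    return _build_set((440.0,), (2, 4), "training")


def write_wav(path: str | Path, waveform: np.ndarray, fs: float = 22050.0, *, scale: float | None = None) -> None:
    """Write a mono waveform as 16-bit PCM.

    ``scale`` maps float amplitude to full scale; by default the waveform is
    scaled so its own peak sits at 0.9 of full scale. Pass an explicit scale
    to preserve level relations across a stimulus set.
    """
    path = Path(path)
    if scale is None:
        peak = np.max(np.abs(waveform))
        scale = 0.9 / peak if peak > 0 else 1.0
    data = np.clip(waveform * scale, -1.0, 1.0)
    try:
        wavfile.write(path, int(fs), (data * 32767.0).astype(np.int16))
    except OSError as exc:
        raise OSError(f"failed to write WAV {path}: {exc}") from exc


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a 16-bit PCM WAV back to float in [-1, 1]. Returns (waveform, fs)."""
    path = Path(path)
    try:
        fs, data = wavfile.read(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"failed to read WAV {path}: {exc}") from exc
    if data.dtype == np.int16:
        return data.astype(np.float64) / 32767.0, float(fs)
    return np.asarray(data, dtype=np.float64), float(fs)


def write_stimulus_set(stimset: StimulusSet, out_dir: str | Path) -> pd.DataFrame:
    """Export a set as WAV files plus a manifest CSV.

    One global scale (loudest stimulus at 0.9 of full scale) is applied to
    every file so inter-stimulus level relations survive 16-bit quantization.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    global_peak = max(np.max(np.abs(w)) for _, w in stimset)
    scale = 0.9 / global_peak if global_peak > 0 else 1.0
    for spec, wave in stimset:
        write_wav(out_dir / stimulus_filename(spec), wave, spec.sample_rate, scale=scale)
    manifest = stimset.manifest()
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
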