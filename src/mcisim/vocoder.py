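"""Noise-band vocoder simulating cochlear-implant processing.

The signal chain: first-order Butterworth high-pass pre-emphasis at 1200 Hz,
a bank of fourth-order Butterworth band-pass filters spanning 100-6000 Hz
with cutoffs equally spaced along the cochlea (Greenwood frequency-place
map), per-band temporal-envelope extraction by half-wave rectification and a
fourth-order 500 Hz Butterworth low-pass, modulation of a broadband noise
carrier by each envelope, band-limiting of each modulated carrier by its
analysis filter, and summation across channels.

All filtering is zero-phase (forward-backward, second-order sections) so the
channels stay time-aligned; the nominal filter orders refer to the underlying
transfer function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "GreenwoodParams",
    "VocoderConfig",
    "greenwood_position",
    "greenwood_frequency",
    "channel_edges",
    "bandpass_sos",
    "extract_envelopes",
    "vocode",
]


@dataclass(frozen=True)
class GreenwoodParams:
    """Constants of the human Greenwood map F = A*(10**(a*x) - k).

    ``x`` is cochlear position as a fraction of basilar-membrane length
    (0 = apex, 1 = base).
    """

    A: float = 165.4  # Hz
    a: float = 2.1  # per unit length (position normalized to 0-1)
    k: float = 0.88

    def __post_init__(self) -> None:
        if self.A <= 0 or self.a <= 0 or not (0 < self.k < 1):
            raise ValueError("require A > 0, a > 0, 0 < k < 1")


@dataclass(frozen=True)
class VocoderConfig:
    n_channels: int = 8
    analysis_band: tuple[float, float] = (100.0, 6000.0)  # Hz
    preemph_cutoff: float = 1200.0  # Hz, 1st-order Butterworth high-pass
    bandpass_order: int = 4  # overall transfer-function order
    envelope_cutoff: float = 500.0  # Hz
    envelope_order: int = 4
    sample_rate: float = 22050.0
    greenwood: GreenwoodParams = field(default_factory=GreenwoodParams)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        lo, hi = self.analysis_band
        if not (0 < lo < hi):
            raise ValueError(f"analysis band must be 0 < lo < hi, got {self.analysis_band}")


def greenwood_position(f: float | np.ndarray, p: GreenwoodParams = GreenwoodParams()) -> float | np.ndarray:
    """Cochlear position (0-1 of length) of characteristic frequency ``f`` Hz."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    x = np.log10(f / p.A + p.k) / p.a
    return float(x) if x.ndim == 0 else x


def greenwood_frequency(x: float | np.ndarray, p: GreenwoodParams = GreenwoodParams()) -> float | np.ndarray:
    """Characteristic frequency (Hz) at cochlear position ``x``; inverse of
    :func:`greenwood_position`."""
    x = np.asarray(x, dtype=float)
    f = p.A * (10.0 ** (p.a * x) - p.k)
    return float(f) if f.ndim == 0 else f


def channel_edges(config: VocoderConfig) -> np.ndarray:
    """Band edges (``n_channels + 1`` values, Hz) equally spaced in cochlear
    position between the analysis-band limits; endpoints are exact."""
    lo, hi = config.analysis_band
    x = np.linspace(
        greenwood_position(lo, config.greenwood),
        greenwood_position(hi, config.greenwood),
        config.n_channels + 1,
    )
    edges = greenwood_frequency(x, config.greenwood)
    edges = np.atleast_1d(edges)
    edges[0], edges[-1] = lo, hi  # exact endpoints
    return edges


def _butter_sos(order: int, cutoff, btype: str, fs: float) -> np.ndarray:
    # scipy's N doubles for band-pass designs; halve so `order` is the
    # overall transfer-function order.
    n = order // 2 if btype == "bandpass" else order
    return signal.butter(n, cutoff, btype=btype, fs=fs, output="sos")


def bandpass_sos(config: VocoderConfig) -> list[np.ndarray]:
    """Second-order-section band-pass filters for every channel."""
    edges = channel_edges(config)
    return [
        _butter_sos(config.bandpass_order, [edges[i], edges[i + 1]], "bandpass", config.sample_rate)
        for i in range(config.n_channels)
    ]


def _preemphasize(x: np.ndarray, config: VocoderConfig) -> np.ndarray:
    sos = _butter_sos(1, config.preemph_cutoff, "highpass", config.sample_rate)
    return signal.sosfiltfilt(sos, x)


def extract_envelopes(waveform: np.ndarray, config: VocoderConfig) -> np.ndarray:
    """Per-channel temporal envelopes of a signal, shape (n_channels, n).

    Half-wave rectification of each band-passed signal followed by the
    envelope low-pass; envelopes are clipped to be non-negative (zero-phase
    low-pass filtering can undershoot slightly).
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size == 0:
        raise ValueError("empty signal")
    lp = _butter_sos(config.envelope_order, config.envelope_cutoff, "lowpass", config.sample_rate)
    envs = np.empty((config.n_channels, waveform.size))
    for ch, sos in enumerate(bandpass_sos(config)):
        band = signal.sosfiltfilt(sos, waveform)
        env = signal.sosfiltfilt(lp, np.maximum(band, 0.0))
        envs[ch] = np.maximum(env, 0.0)
    return envs


def vocode(waveform: np.ndarray, config: VocoderConfig) -> np.ndarray:
    """Noise-vocode a mono waveform.

    Deterministic given ``config.rng_seed`` (one fresh broadband-noise carrier
    per channel per call). Output RMS is matched to the input RMS.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size == 0:
        raise ValueError("empty signal")
    rng = np.random.default_rng(config.rng_seed)
    pre = _preemphasize(waveform, config)
    lp = _butter_sos(config.envelope_order, config.envelope_cutoff, "lowpass", config.sample_rate)
    out = np.zeros_like(waveform)
    for sos in bandpass_sos(config):
        band = signal.sosfiltfilt(sos, pre)
        env = np.maximum(signal.sosfiltfilt(lp, np.maximum(band, 0.0)), 0.0)
        carrier = rng.standard_normal(waveform.size)
        out += signal.sosfiltfilt(sos, env * carrier)
    in_rms = np.sqrt(np.mean(waveform**2))
    out_rms = np.sqrt(np.mean(out**2))
    if in_rms > 0 and out_rms > 0:
        out *= in_rms / out_rms
    return out
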