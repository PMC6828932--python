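"""F0-to-vibrotactile encoding.

Note F0s are transposed down by a per-melody power-of-two divisor so that
every melody, whatever its pitch range, lands in the same low-frequency
vibration band centered on 110 Hz: melodies with a 220 Hz middle note are
divided by 2, 440 Hz by 4, 880 Hz by 8. Division by a power of two preserves
semitone intervals exactly, so the vibration contour is an octave-transposed
copy of the melodic contour.

Vibration frequency then determines the drive voltage of an eccentric
rotating mass (ERM) motor via a calibration table; the motor's frequency and
amplitude co-vary with voltage (up to 220 Hz and 1.62 g over 0.7-3.7 V), so
amplitude is not independently controllable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stimuli import ContourSpec

__all__ = [
    "MotorCalibration",
    "VibrationCommand",
    "transposition_divisor",
    "f0_to_command",
    "contour_to_commands",
    "commands_to_dataframe",
    "write_commands_csv",
    "write_commands_json",
    "read_calibration_csv",
]

#: Vibration frequency every melody is centered on after transposition (Hz).
CENTER_VIBRATION_HZ = 110.0


@dataclass(frozen=True)
class MotorCalibration:
    """Voltage -> (vibration frequency, amplitude) calibration of an ERM motor.

    The default is a piecewise-linear stand-in for the motor datasheet (which
    publishes only the 0.7-3.7 V operating range and the 220 Hz / 1.62 g
    maxima): voltage maps linearly to 55-220 Hz and 0.2-1.62 g. Override via
    :func:`read_calibration_csv` for a measured curve.
    """

    voltages: tuple[float, ...] = (0.7, 3.7)  # V
    frequencies: tuple[float, ...] = (55.0, 220.0)  # Hz
    amplitudes: tuple[float, ...] = (0.2, 1.62)  # g

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages)
        f = np.asarray(self.frequencies)
        a = np.asarray(self.amplitudes)
        if not (len(v) == len(f) == len(a) >= 2):
            raise ValueError("calibration needs >= 2 aligned (voltage, freq, amp) rows")
        if np.any(np.diff(v) <= 0) or np.any(np.diff(f) <= 0) or np.any(np.diff(a) < 0):
            raise ValueError("calibration must be monotone in voltage")

    @property
    def voltage_min(self) -> float:
        return self.voltages[0]

    @property
    def voltage_max(self) -> float:
        return self.voltages[-1]

    @property
    def max_freq(self) -> float:
        return self.frequencies[-1]

    def voltage_for_frequency(self, freq: float) -> float:
        """Inverse-interpolate the frequency curve; clamped to the operating range."""
        if not (self.frequencies[0] <= freq <= self.frequencies[-1]):
            raise ValueError(
                f"vibration frequency {freq:.1f} Hz outside calibrated range "
                f"[{self.frequencies[0]:.1f}, {self.frequencies[-1]:.1f}] Hz"
            )
        v = float(np.interp(freq, self.frequencies, self.voltages))
        return min(max(v, self.voltage_min), self.voltage_max)

    def amplitude_at_voltage(self, voltage: float) -> float:
        return float(np.interp(voltage, self.voltages, self.amplitudes))


@dataclass(frozen=True)
class VibrationCommand:
    """One motor command: a constant vibration for one note."""

    onset: float  # s
    dur: float  # s
    freq: float  # Hz
    amp: float  # g
    voltage: float  # V


def transposition_divisor(middle_f0: float) -> int:
    """Power-of-two divisor taking a melody's F0s into the vibration band.

    Routing is per melody by its middle-note F0: 220 -> 2, 440 -> 4,
    880 -> 8, and in general ``middle_f0 / 110`` for any middle F0 of the
    form ``110 * 2**m``.
    """
    ratio = middle_f0 / CENTER_VIBRATION_HZ
    m = math.log2(ratio) if ratio > 0 else -1.0
    if ratio <= 0 or abs(m - round(m)) > 1e-9 or round(m) < 0:
        raise ValueError(
            f"middle F0 {middle_f0:g} Hz is not 110*2^m for integer m >= 0; "
            "no power-of-two transposition reaches the 110 Hz vibration band"
        )
    return int(round(ratio))


def f0_to_command(
    f0: float,
    divisor: int,
    calib: MotorCalibration = MotorCalibration(),
    onset: float = 0.0,
    dur: float = 0.5,
) -> VibrationCommand:
    """Map one note F0 to a vibration command. freq = f0 / divisor."""
    freq = f0 / divisor
    if freq > calib.max_freq:
        raise ValueError(
            f"note F0 {f0:g} Hz / divisor {divisor} = {freq:.1f} Hz exceeds the "
            f"motor maximum {calib.max_freq:g} Hz"
        )
    voltage = calib.voltage_for_frequency(freq)
    return VibrationCommand(
        onset=onset, dur=dur, freq=freq, amp=calib.amplitude_at_voltage(voltage), voltage=voltage
    )


def contour_to_commands(
    note_f0s: np.ndarray,
    middle_f0: float,
    calib: MotorCalibration = MotorCalibration(),
    spec: ContourSpec | None = None,
) -> list[VibrationCommand]:
    """Encode the five consensus note F0s of a contour as motor commands,
    time-aligned to the 0.5 s note / 0.1 s gap grid."""
    note_f0s = np.asarray(note_f0s, dtype=float)
    if note_f0s.size != 5:
        raise ValueError(f"expected 5 note F0s, got {note_f0s.size}")
    divisor = transposition_divisor(middle_f0)
    note_dur = spec.note_dur if spec is not None else 0.5
    gap_dur = spec.gap_dur if spec is not None else 0.1
    return [
        f0_to_command(f0, divisor, calib, onset=k * (note_dur + gap_dur), dur=note_dur)
        for k, f0 in enumerate(note_f0s)
    ]


def commands_to_dataframe(commands: list[VibrationCommand]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [c.onset for c in commands],
            "dur_s": [c.dur for c in commands],
            "freq_hz": [c.freq for c in commands],
            "amp_g": [c.amp for c in commands],
            "voltage_v": [c.voltage for c in commands],
        }
    )


def write_commands_csv(commands: list[VibrationCommand], path: str | Path) -> None:
    commands_to_dataframe(commands).to_csv(path, index=False)


def write_commands_json(commands: list[VibrationCommand], path: str | Path) -> None:
    records = commands_to_dataframe(commands).to_dict(orient="records")
    Path(path).write_text(json.dumps(records, indent=1))


def read_calibration_csv(path: str | Path) -> MotorCalibration:
    """Load a calibration table with columns voltage_v, freq_hz, amp_g."""
    df = pd.read_csv(path)
    missing = {"voltage_v", "freq_hz", "amp_g"} - set(df.columns)
    if missing:
        raise ValueError(f"calibration CSV {path} missing columns: {sorted(missing)}")
    df = df.sort_values("voltage_v")
    return MotorCalibration(
        voltages=tuple(df["voltage_v"]),
        frequencies=tuple(df["freq_hz"]),
        amplitudes=tuple(df["amp_g"]),
    )
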