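"""Encode note F0s as vibrotactile motor commands.

Melodies are transposed down by a power of two chosen from the middle-note
F0 (220 -> /2, 440 -> /4, 880 -> /8), so every pitch range lands in the same
vibration band centered on 110 Hz with semitone intervals preserved exactly.
An ERM-motor calibration maps each vibration frequency to a drive voltage
and its co-varying amplitude.
"""

import numpy as np

from mcisim.stimuli import ContourSpec, contour_f0_sequence
from mcisim.tactile import commands_to_dataframe, contour_to_commands, write_commands_csv

for mid in (220.0, 880.0):
    spec = ContourSpec("rising", mid, 3)
    cmds = contour_to_commands(contour_f0_sequence(spec), mid, spec=spec)
    print(f"\nmiddle F0 {mid:g} Hz -> divisor {int(mid / 110)}")
    print(commands_to_dataframe(cmds).round(3).to_string(index=False))

write_commands_csv(cmds, "scratch/commands_rising_880.csv")
print("\nwrote scratch/commands_rising_880.csv")
# The two tables have identical freq/amp/voltage columns: after
# transposition the 220- and 880-Hz versions of a contour are the same
# vibration stimulus, with the middle note at 110 Hz.
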