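"""Generate the melodic-contour stimulus sets and export them as WAV files.

The test set crosses 2 middle F0s (220/880 Hz) x 3 interval sizes (1/3/5
semitones) x 9 contour patterns = 54 five-note melodies; the training set
uses a 440 Hz middle F0 with 2- or 4-semitone intervals (18 melodies).
"""

import numpy as np

from mcisim.stimuli import (
    ContourSpec,
    contour_f0_sequence,
    generate_test_set,
    generate_training_set,
    write_stimulus_set,
)

test_set = generate_test_set()
training_set = generate_training_set()
print(f"test set: {len(test_set)} stimuli; training set: {len(training_set)} stimuli")

spec = ContourSpec("rising", 220.0, 3)
print(f"\n'{spec.pattern}' contour, middle F0 {spec.middle_f0:g} Hz, {spec.interval} st steps:")
print("note F0s (Hz):", np.round(contour_f0_sequence(spec), 2))
print(f"duration: {spec.duration} s (5 x 0.5 s notes + 4 x 0.1 s gaps)")

manifest = write_stimulus_set(test_set, "scratch/stimuli_test")
print(f"\nwrote {len(manifest)} WAV files + manifest.csv under scratch/stimuli_test/")
# Each row names one stimulus; the F0 ratios between adjacent notes are exact
# powers of 2**(1/12), so the contour shape is carried purely by pitch.
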