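# Methods

This note documents the models implemented in `mcisim`, the parameter
choices that matter, and what the synthetic components do and do not
capture.

## Stimuli

Each melodic contour is five 500 ms harmonic complex tones separated by
100 ms of silence (2.9 s total). The third note carries the nominal middle
F0; within each half of the melody adjacent notes differ by exactly
±`interval` semitones (frequency ratio 2^(±interval/12)) or not at all,
giving nine patterns from the two independent half directions. Tones sum
all sine-phase harmonics n·F0 ≤ 4000 Hz with harmonic n attenuated by
−8 dB/octave re the fundamental, i.e. amplitude 10^(−8·log2(n)/20), and
carry 20 ms raised-cosine ramps.

Level handling is a design choice the stimulus definition leaves open: each
note is normalized to equal RMS *before* ramping, so loudness differences
cannot act as a contour cue; 16-bit WAV export applies one global scale
(loudest stimulus at 0.9 full scale) so relative levels survive
quantization. Presentation level in dB SPL is metadata, not a digital
quantity.

## Vocoder

The CI simulation follows the classic noise-band recipe: first-order
Butterworth high-pass pre-emphasis at 1200 Hz; a bank of fourth-order
Butterworth band-pass filters covering 100–6000 Hz; per-band half-wave
rectification and a fourth-order 500 Hz Butterworth low-pass for the
temporal envelope; envelope-modulated broadband noise re-filtered by the
band filter; summation and RMS matching to the input.

Band edges are spaced evenly in cochlear position using the human
Greenwood map F = A(10^(ax) − k) with A = 165.4 Hz, a = 2.1 (position as a
fraction of cochlear length), k = 0.88; endpoints are pinned to exactly
100 and 6000 Hz. The 8-channel edges therefore interleave the 4-channel
ones exactly.

Numerical choices: all filters are realized as second-order sections and
applied forward-backward (zero-phase), which keeps the channels time
aligned at the cost of doubling the effective roll-off; "fourth-order
band-pass" refers to the overall transfer function (scipy order 2 per
edge). One fresh noise carrier per channel per call is drawn from the
seeded generator, so vocoding is bit-reproducible given `rng_seed` and no
frozen-noise correlation is introduced across stimuli.

The 500 Hz envelope cutoff is the scientifically load-bearing element: the
summed envelopes of a vocoded 220 Hz-range melody still fluctuate at the
note F0s, while an 880 Hz-range melody leaves no envelope periodicity and
must be read from place-of-excitation cues.

## F0 tracker

The tracker emulates a low-cost real-time pitch follower. Each 1024-sample
frame is Hann-windowed and zero-padded to a 2048-point FFT; a new estimate
is made every 512 samples. Up to 20 spectral peaks (local maxima refined by
quadratic interpolation; a ~90 Hz minimum spacing suppresses the analysis
window's sidelobes) vote for candidate F0s on a 1/24-octave grid from 50 to
2000 Hz, scored by amplitude times a Gaussian kernel in log-frequency
distance (0.5 st width) to the nearest harmonic. The top coarse candidates
— plus the peak frequencies themselves, so a sparse two-harmonic stack
always shortlists its true F0 — are refined by the amplitude-weighted mean
of contributing peak frequencies over harmonic numbers, and near-ties
(within 1% of the best score) resolve to the *highest* candidate: a
subharmonic explains the same peaks no better, which removes half-octave
errors without a dedicated penalty term.

A frame is voiced only if ≥ 4 peaks contribute (within 0.5 st of a
harmonic) or the contributing peaks carry ≥ 1% of the frame's power — the
power clause is what keeps the highest test note (1568 Hz, only two
harmonics below 4 kHz) valid. Per-note consensus is the median over voiced
frames whose centers fall in [onset + ramp, offset − ramp), which rejects
onset/offset frames; silent gaps produce no voiced frames. The estimator is
scale invariant because the peak floor, kernel, and power rule are all
relative.

## Tactile encoding

Note F0s are divided by middle_f0/110 — a power of two (220→2, 440→4,
880→8) — so every melody is centered on 110 Hz and, because the divisor is
constant within a melody, semitone intervals are preserved exactly. The
motor calibration (voltage → vibration frequency and amplitude) defaults to
a piecewise-linear stand-in spanning the published operating range: 0.7 V →
55 Hz / 0.2 g up to 3.7 V → 220 Hz / 1.62 g. The true datasheet curve is
not published numerically, so this synthetic table is declared, not
derived; any measured curve can be substituted via a CSV. With the default
table all 54 test melodies (vibration frequencies 61.7–196 Hz) map inside
the voltage range without clamping. Commands are per note, matching the
stepwise drive the experiment used; frequency and amplitude co-vary by
construction of the ERM motor.

## Simulated listeners

**Tactile observer.** A perceived frequency step is the true step plus
Gaussian noise of SD σ√2 semitones (the standard two-interval scaling);
2AFC percent correct is p = λ + (1 − 2λ)Φ(Δ/(σ√2)), which is 0.5 at Δ = 0
and asymptotes at 1 − λ. For contour identification the observer sums the
two perceived steps of each half and calls the half rising/falling when
the sum exceeds ±c, else flat. The default criterion c = 1.645 st labels a
flat half correctly 90% of the time at σ = 0.5 st; the default σ = 1.405 st
puts the 71%-correct discrimination threshold at 1.1 st. The chain
heuristic p⁴ treats a contour judgment as four adjacent-note
discriminations and lower-bounds the mechanistic observer (summing before
judging averages noise out).

**Vocoded-audio decoder.** An explicitly mechanistic stand-in for auditory
perception, used only for qualitative orderings. Each note is reduced to a
scalar cue: the autocorrelation periodicity of the summed envelope
(expressed in semitones re 110 Hz; the shortest lag within 15% of the best
correlation is taken, so period multiples do not alias the estimate; the
cue exists only when every note shows periodicity below the 500 Hz
cutoff), or the channel centroid (mean channel index weighted by RMS
envelope, which is less sensitive to carrier-noise fluctuations than
energy weighting). Gaussian cue noise is added in the cue's native units
*before* shape normalization — this is what makes accuracy grow with
interval size, since larger intervals give larger cue excursions relative
to the same noise. The noisy trajectory is centered and scale-normalized
with the divisor floored at flat_eps + 1.5·noise_sd (weakly modulated
trajectories shrink toward the flat template rather than being amplified)
and classified by the nearest of nine canonical shape templates. Default
cue noises (1.3 st envelope, 0.12 channels centroid) are calibrated so
that vibration-alone and 4-channel accuracies are comparable and 8-channel
is better, as the design requires; they are not fitted to any data.

**Combination.** Naive-Bayes: the per-trial tactile posterior (Gaussian
likelihoods of the perceived half sums over the three directions, assuming
the stimulus interval size is known) is multiplied element-wise with the
decoder's softmax posterior and renormalized; ties break at random under
the trial seed. No inter-modality correlation is modeled.

## Procedures

Method of limits: alternating ascending/descending staircases in 0.013 V
steps (3 + 3 by default); each endpoint is the mean of the two voltages
straddling the response change, and the threshold is the mean of the six
endpoints. Sequences that start on the wrong side of threshold or exceed
500 steps raise. 2AFC discrimination: intervals {0.25, 0.5, 1, 2, 3} st,
10 trials each per session, three sessions. The 71% threshold is the
linear interpolation between the first bracketing psychometric points
(extrapolation is refused); the Hz JND at a 110 Hz center uses geometric
centering, Δf = 110(2^(t/24) − 2^(−t/24)), so 1.1 st → 7 Hz. MCI runs
present all 54 stimuli exactly once per run (seeded shuffle, 2 runs),
yielding overall, per-middle-F0, and per-interval scores plus a 9×9
confusion matrix; training runs exist as a feedback hook but the default
listeners are stationary (no learning model).

## Synthetic cohort

`sample_cohort` draws listener bundles: σ log-normal (median 1.405 st, log
SD 0.18), detection thresholds normal (0.765 ± 0.03 V) truncated to
0.71–0.82 V, a 2% lapse rate, and one log-normal salience factor per
listener scaling both decoder noises (log SD 0.25) so listeners vary in
their audio-versus-touch reliability. These distributions emulate
between-subject variability of the intended magnitude and are calibration
choices, documented as such. What they do not capture: learning/training
effects, attention and memory limits, amplitude-cue use in discrimination,
and any individual-level structure of a real cohort — so passing
cohort-level tests shows the pipeline's orderings are internally forced,
not that human data would match quantitatively.

## Problem sizes and determinism

Everything is seeded: vocoder carriers per stimulus, listener trials, and
cohort sampling all run off explicit `numpy` generators, and repeated runs
are bit-identical. The shipped analyses use the full 54-stimulus set, 8
listeners, and 2 runs per condition (the experiment's own design), which
keeps the complete simulated experiment around a minute on one core;
Monte-Carlo property checks use a few hundred to a few thousand trials,
enough to pin chance levels within ±2 percentage points.
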