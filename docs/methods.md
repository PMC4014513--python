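# Methods

This note documents the models and numerical choices behind `songsim`,
what the synthetic-data generator does and does not emulate, and the
known limitations of both.

## Spectral representation

Audio is analyzed in 9 ms windows advanced in 1 ms steps, restricted to
the 500–8600 Hz band (song energy in zebra finches lies almost entirely
in this range; the band also excludes low-frequency cage noise). Each
window is tapered with DPSS (Slepian) tapers at time-bandwidth product
1.5 and 2 tapers, and the power spectra of the tapers are averaged —
the standard multitaper estimator, which trades a little frequency
resolution (~330 Hz at 9 ms) for substantially lower variance than a
single-taper periodogram. The FFT length is the next power of two at or
above the window length, so bin spacing (~86 Hz at 44.1 kHz) is stable
across sample rates. Frame count is `floor((duration_ms − 9)/1) + 1`;
frame start times are defined in milliseconds and rounded to the nearest
sample, so counts depend only on duration, not on the sample rate.

Six per-frame features are computed from the band-restricted power
spectrum `p_i` at frequencies `b_i`:

| feature | definition | units (raw) |
|---|---|---|
| Wiener entropy | `log(geometric mean p / arithmetic mean p)` | ≤ 0, dimensionless |
| gravity center | `Σ b_i p_i / Σ p_i` | Hz |
| spectral width | `sqrt(Σ p_i (b_i − gc)² / Σ p_i)` | Hz |
| pitch | inverse quefrency of the largest cepstral peak | Hz |
| pitch goodness | cepstral power at that peak | dimensionless |
| frequency modulation | `arctan(‖∂ log p/∂t‖ / ‖∂ log p/∂f‖)` | rad, [0, π/2] |

Numerical choices:

* **Cepstrum.** The cepstrum is the Fourier transform of the
  mean-removed log power spectrum, zero-padded to at least 8× the bin
  count for a fine quefrency grid. The pitch search is restricted to
  fundamentals of 400–3000 Hz (config-exposed), covering zebra finch
  harmonic stacks while rejecting sub-bin quefrencies. Goodness is the
  squared cepstral magnitude at the peak: large when the log spectrum
  has a periodic harmonic ripple, small for noise. Note this definition
  is invariant to uniform amplitude scaling (an amplitude factor only
  shifts the log spectrum's mean).
* **Frequency modulation.** The time- and frequency-derivative fields
  of log power (one-sided differences at edges via `np.gradient`) are
  each aggregated in quadrature across bins before the arctangent.
  This verbal definition admits several aggregations; quadrature
  summation was chosen because it uses all bins, is smooth, and gives
  FM ≈ 0 on stationary sounds and a stable positive plateau on linear
  sweeps. Because a 1 ms hop is not an integer sample count at
  44.1 kHz, sidelobe bins leave a small residual FM (median < 0.1 rad)
  even on a perfectly stationary tone.
* **Log floor.** Log power is floored 100 dB below the spectrogram's
  global peak. A global (not per-frame) floor keeps floored bins
  constant across frames so they contribute no spurious time
  derivative.
* **Digital silence.** All-zero frames are flagged and take fallbacks:
  entropy at its floor (−10), gravity center and pitch at the band
  midpoint, width/goodness/FM at 0. With the generator's noise floor
  (below) such frames essentially never occur.

## Normalization

Each feature is centred on its pooled mean over a reference corpus and
scaled so the median absolute deviation from that mean is one (MAD
about the mean). MAD was preferred over the standard deviation because
heavy-tailed features (pitch goodness especially) would otherwise be
scaled by their outliers; an `sd` convention is available in the config
and the convention used is serialized with the stats. Distances are
only meaningful between feature sets normalized with identical stats;
this is enforced.

## Calibration

All D and L entries from pairwise comparisons of unrelated songs (every
cross-source pair of the calibration corpus; 45 pairs for 10 birds) are
pooled into empirical distributions, stored as 1001-point quantile
tables with linear interpolation (raw pools reach 10⁷ values). `P(x)`
is the probability of an unrelated-song distance *strictly below* x;
queries at or below the pooled minimum return 0, above the maximum 1.
The quantile compression bounds the ECDF error by the inter-quantile
spacing (≤ 10⁻³). A hash of every parameter the null depends on
(spectral settings, diagonal window, feature subset, normalization
stats) is stored with the reference; a mismatch at scoring time is a
hard error, not a warning.

## Similarity matrices and scores

`S_ij = 1 − P(D_ij)` where `P(L_ij) < 0.05` (strict), else 0. The
±25 ms diagonal RMS window for L is truncated at matrix borders rather
than zero-padded, to avoid inflating similarity at song edges. Matrix
orientation is fixed: rows are tutor frames, columns pupil frames.

Syllable intervals are half-open `[i1, i2)` with `N_k = i2 − i1`, so a
perfect diagonal sums to exactly `N_k` and the length-normalized
acoustic score is bounded by 1.

Greedy matching commits the syllable with the highest partial score
first (ties: smallest pupil offset within a syllable; across syllables,
longer syllable first, then lower index — making runs deterministic),
zeroes its rows and matched columns, and recomputes. Offsets whose
pupil fragment would overlap an already-matched fragment are
inadmissible, implementing the rule that a pupil fragment is matched at
most once; in the degenerate case where no admissible offset remains,
the syllable is placed at the least-conflicting offset with score 0 and
flagged. Acoustic matching only evaluates diagonals that fit entirely
inside the segment; clipping applies only inside sequence areas of
interest.

Sequence scoring uses the pristine (un-zeroed) S. For syllable k the
area of interest spans the rows of syllable k+1 and the columns from
the end of fragment k over the tutor offset-to-offset interval plus
50 ms of slack; the partial score is the maximal clipped-diagonal sum
divided by `N_{k+1}`, placing it in [0, 1] and making the mean
comparable to the acoustic score (the raw diagonal sum is otherwise
unbounded, and the SI product would not be a meaningful [0, 1] score).
The last syllable, and syllables matched so close to the segment end
that the area has zero width, are excluded; a single-syllable motif has
no sequence score, and the SI is then reported as the acoustic score
with `sequence_defined=False`.

## Segment selection and experiments

Bouts are tiled with adjacent segments of twice the tutor-motif
duration, starting at one uniform random offset in [0, motif) per bout
per run (seeded); the trailing remainder is discarded. Segment features
are sliced from the whole-bout feature tracks, so segment frames keep
their full 9 ms analysis context.

Self-similarity of a bird is the mean SI of (up to) 25 sampled segments
against 3 of its own motif renditions; cross-similarity uses the same
segments against motifs of up to 10 other birds, sampled without
replacement. Segments are always cut at twice the *pupil* bird's own
motif duration, for both self and cross comparisons, so both use
identical inputs. Contrast is `(self − cross)/(self + cross)`. The
feature-subset sweep reruns the experiment per subset (4–6 of the 6
features → 22 subsets) with shared seeds and per-subset recalibration,
since distances depend on the feature set; normalization stats are
per-feature and therefore shared.

## The synthetic-song generator

The generator emulates the *structural* statistics of adult zebra finch
song, not its production mechanism: motifs of 3–7 syllables drawn from
four acoustic classes (harmonic stacks with 1/h harmonic rolloff, pure
tones, linear sweeps, 1–8 kHz noise bursts), syllable durations of
50–120 ms, gaps of 20–60 ms (motifs ≈ 0.5–1 s), 5 ms raised-cosine
amplitude ramps to avoid spectral splatter, 44.1 kHz sample rate.
Rendition-to-rendition variability defaults to 1% multiplicative pitch
jitter and 2 ms gap jitter — adult-level stereotypy. Every rendering
adds Gaussian noise 50 dB below syllable peak, emulating the microphone
noise floor of a recording chamber: real recordings are never digitally
silent, and exact-zero gaps would make gap frames bit-identical across
songs, distorting the null distributions. Rendered motifs are padded
with 20 ms of surrounding silence, as a recording excerpt would be;
without the pad the final syllable would lose its last analysis frames
to the 9 ms window and be systematically mis-scored. Colonies assign
each bird fundamentals from disjoint slices of a log-spaced 600–2400 Hz
grid, so cross-bird songs share no syllable frequencies.

What passing tests on this generator do **not** show: robustness to
real-world confounds absent from the synthesis — reverberation,
overlapping calls, amplitude modulation within syllables, biologically
realistic syllable morphology, or juvenile subsong. Results on
synthetic colonies characterize the algorithm, not zebra finch biology.

## Problem sizes

The test suite and experiments run at desk scale: reference corpora of
10 songs (45 calibration pairs), colonies of 3 birds × 2 motifs × 2
bouts for experiment tests, 20 seeds × 4 jitter levels for the
degradation test, 1000 seeds for the segmentation-law test. These sizes
give stable statistics for every property tested while keeping the full
suite under a minute of compute.

## Known limitations

* Pitch and FM are noisy on sounds that are neither harmonic stacks nor
  tones; this is why the default feature subset excludes them.
* The greedy assignment is not globally optimal; the greedy order is
  part of the method's definition.
* Gap-to-gap similarity is excluded by construction (tutor gaps are
  never scored), but a pupil segment consisting mostly of silence still
  yields a valid (low) score rather than an error.
* The published procedure's exact cepstral and FM formulas are not
  specified to implementation precision; the definitions above are this
  package's documented choices.
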