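# Methods

## The measurement model

A stimulus stream (face photographs and written names, interleaved at
random) is presented at a base rate F = 4 Hz; every 7th stimulus carries
a different person identity, so identity changes are periodic at
f_odd = F/7 ≈ 0.571 Hz. A neural population that treats all base stimuli
as "the same person" — across both modalities — adapts to the repeated
identity and releases at each change, producing spectral power exactly at
f_odd and its harmonics. Responses at harmonics of F index general visual
synchronization and are analyzed separately.

Three conditions decompose the oddball response. In Face Name (FN) both
modalities carry the base identity; in Face Only (FO) base names are
replaced by other names; in Name Only (NO) base faces are replaced. If
the FN response exceeded the sum FO + NO, the excess is attributed to a
crossmodal (integrative) representation; the package's condition algebra
operates on raw amplitude spectra (sum FO and NO, subtract from FN) and
applies baseline correction or Z-scoring only afterwards.

## Synthetic data

`fpvs.synth` generates sessions with a known decomposition. The periodic
response is modeled directly in the frequency domain as sinusoids at
harmonics k·F (k = 1..9) and m·f_odd (m = 1..6), with condition
amplitudes

    A_FN(m) = face(m) + name(m) + cross(m),   A_FO(m) = face(m),
    A_NO(m) = name(m),

so FN − FO − NO equals the cross component exactly, sample by sample.
Modeling the oddball response as tagged-harmonic sinusoids (rather than a
time-domain transient train) is sufficient because every downstream
statistic reads amplitude spectra; phases are free nuisance parameters
(default 0) for the same reason.

Scalp topography: each component has per-channel gains, zero-mean across
the 16 EEG channels of the default montage — i.e., the source projection
is expressed in the common-average frame, as a dipolar far field would
be. This makes the common average reference an identity on the noiseless
signal, so end-to-end recovery can be checked exactly. The oddball
topography peaks over the occipito-temporal ROI electrodes; the base-rate
topography over midline occipital sites.

Default response magnitudes (per channel of unit gain, summed over
harmonics): FN 1.0 μV decomposed as face 0.38 + name 0.30 + cross
0.32 μV — a strongly integrative occipito-temporal site with a 32%
crossmodal share and controls at 68% of FN — and 2.5 μV of base-rate
response. These sit in the range of reported occipito-temporal oddball
amplitudes (of order 0.3–1 μV summed over six harmonics).

Background noise is 1/f-shaped ("pink") plus a white floor. The pink
amplitude spectrum is calibrated against a fixed 60-s analysis window:
`pink_scale` is the mean per-bin amplitude at 1 Hz in that window
(default 0.15 μV), with shape f^(−α), α = 1. The white floor has
per-sample SD `white_scale` (default 10 μV). Optional artifacts: 50-Hz
line noise (2 μV), biphasic blink transients on the vertical-EOG pair at
0.05/s with 10% leakage to frontal channels, and ±20 μV DC jumps between
stimulation blocks. Under these defaults a single session (4 sequences
per condition averaged) has a per-bin local noise SD of ≈ 0.08 μV around
f_odd at 256 Hz — matching the scale of reported noise SDs.

What the generator does **not** emulate: non-stationary noise, alpha
rhythm, channel-specific noise topographies, muscle or electrode
artifacts, transient (non-sinusoidal) oddball waveshapes, or any
nonlinearity beyond the additive/super-additive composition. Passing
recovery tests therefore validate the *analysis chain*, not robustness
to every property of real EEG.

`NoiseSpec.scaled(1/sqrt(n))` emulates an n-subject grand average: the
response is coherent across subjects under the model while noise and
artifacts average down as 1/sqrt(n). The *group condition* used by the
validation studies is n = 20, the group size of the three-condition
scalp experiment.

SEEG contacts are simulated single-channel at 512 Hz with profile
presets (per-harmonic amplitude `amp`): pure_FN (cross = amp),
unimodal_face / unimodal_name (face or name = amp), mixed
(face = name = amp/2), null (all zero), and nonpure_FN
(face = name = 0.12·amp — sub-threshold unimodal responses whose sum
makes FN detectable with nothing super-additive). A strong unimodal
face response is expected to be significant in FN as well (the FN
sequence carries the same face periodicity), so the truth label of
`unimodal_face` is `FN_and_face`, mirror for names.

## Preprocessing

Scalp chain, in order: block alignment (each continuous block offset so
its first sample continues the previous block, removing inter-trial
drift jumps); 0.1–100 Hz Butterworth band-pass of design order 4 applied
forward–backward (`sosfiltfilt`), i.e. zero-phase with an effective
magnitude order of 8 — "fourth-order zero-phase" is read as design
order, configurable; multi-notch (order-4 band-stop, 0.5 Hz wide) at 50,
100, 150, 200 Hz — the fundamental plus three harmonics, configurable to
include 250 Hz-capable variants; polyphase downsampling to 256 Hz with
event indices rounded half-up; epoching −2 s to +66 s around each
sequence-onset trigger (stimulation spans 0–64 s including 2-s fades).

Blink handling: blinks are counted on the vertical-EOG difference as
excursions beyond 100 μV with a 200-ms refractory period; epochs above
0.15 blinks/s receive ocular correction. The correction is least-squares
regression of each EEG channel on the EOG channels — a deterministic,
testable stand-in for component-based correction, *not equivalent* to it
(regression removes any EOG-correlated brain signal and leaves
non-EOG-correlated blink residue). Bad channels (≤ 5% of the montage)
are replaced by the unweighted mean of 3–6 good neighbors. Epochs are
re-referenced to the common average, excluding EOG channels.

SEEG path: epoch extraction only, at native 512 Hz — no filtering, no
re-referencing.

## Spectral conventions

Epochs are cropped to an integer number of oddball cycles starting 2 s
after stimulation onset (skipping the fade-in) and ending before the
fade-out: 34 cycles = 59.5 s, i.e. 15,232 samples at 256 Hz or 30,464 at
512 Hz. On such a crop f_odd falls exactly on bin 34 and the base rate
on bin 238 = 7 × 34; exact-bin alignment is the governing constraint
because every downstream statistic assumes it. Epochs are averaged in
the time domain per condition before the FFT. Amplitude spectra are
single-sided, normalized 2|X_b|/N (DC and Nyquist not doubled), so a
unit-amplitude exact-bin sinusoid reads 1.0 μV; no window or detrending
is applied (integer-cycle cropping makes windows unnecessary).

## Detection statistics

Local statistics compare a bin against surrounding bins:

* baseline-corrected amplitude: bin minus neighborhood mean (μV);
* local Z: the same difference over the neighborhood SD (n−1
  denominator), tested one-tailed at 1.65 (p < 0.05) or 3.1
  (p < 0.001) — the printed conventional cutoffs, kept as configurable
  constants even though 1.65 ≠ 1.6449.

Neighborhood presets: scalp baseline = 12 bins/side minus the adjacent
bin per side minus the single max and min among the remaining 22 (20
used; ties drop the lowest index — the vectorized implementation uses
sum − max − min, which is tie-independent); scalp Z = 11/side with no
exclusions (22 used); SEEG baseline and Z = 12/side minus adjacent (22
used). Harmonic pooling by chunk-and-sum: fixed-width segments centered
on each harmonic bin are summed element-wise; scalp chunks are 31 bins
(center at the 16th value), SEEG chunks 47 bins (~0.79 Hz, the widest
symmetric window within 0.8 Hz at the 0.0168-Hz resolution). Oddball
multiples coinciding with base harmonics (m = 7, 14, …) are always
excluded.

Two quantification orders are implemented and tagged: the scalp order
baseline-corrects the summed chunk once; the SEEG order sums per-harmonic
baseline-corrected amplitudes. They agree exactly when no extrema are
dropped.

Contact classification: each condition is tested at Z > 3.1 (SEEG
variant). If only FN is significant, the subtraction FN − (FO + NO) of
raw spectra is tested at Z > 1.65 one-tailed: significant → `pure_FN`,
otherwise `nonpure_FN`. Other combinations map to `FN_and_face`,
`FN_and_name`, `mixed_all`, `unimodal_face`, `unimodal_name`,
`mixed_unimodal` (both controls without FN) or `none`. No correction for
multiple contacts is applied; the 3.1 cutoff is the conservative
per-contact threshold.

## Estimator biases measured by the validation studies

Amplitude spectra of noise are Rayleigh-distributed with mean ≈ 1.25·s
per bin (s = per-component complex-noise SD), while a strong signal bin
exceeds its true amplitude only by ≈ s²/2A. Baseline correction
subtracts the neighborhood mean, so baseline-corrected sums are biased
**low** by ≈ 1.25·s per harmonic. Measured recovery ratios (median, SEEG
path): ≈ 0.65 when the summed amplitude is ~6× the chunk noise SD,
≈ 0.89 at a per-harmonic amplitude of 10× the per-bin noise SD (the
"moderate SNR" operating point of the recovery study), ≈ 0.97 at 32×.

The integration fraction 100·(1 − (FO+NO)/FN) is a ratio of two such
biased quantities, and the control-sum spectrum carries √2 larger noise,
so its floor term is larger: the estimate is biased **high**. At the
20-subject group condition the median estimate is ≈ 45% for an injected
32%, converging to 32 only at several-hundred-subject-equivalent SNR
(the noiseless pipeline recovers 32.0 exactly). This is a property of
the amplitude-baseline method itself, worth bearing in mind when
interpreting integration percentages measured on real grand averages.

The subtraction Z inherits a mirror-image bias: at a contact with
genuine responses in all three conditions, the signal bins of all three
spectra lack the Rayleigh floor that the subtraction's neighborhood bins
retain, so the subtraction's center sits ≈ +1.25·s above its
neighborhood even when nothing super-additive was injected. Contacts
with purely additive sub-threshold unimodal responses are therefore
promoted to `pure_FN` in roughly a quarter of simulations; `nonpure_FN`
is intrinsically a boundary category (the two cutoffs satisfy
3.1/1.65 > √3, so no amplitude makes "FN rejects, subtraction does not"
jointly near-certain). The classification study consequently asserts
high recovery only for the five separable profiles and the near-zero
pure-FN rate on *null* contacts, and reports the nonpure profile's label
distribution as a measured characteristic.

Null calibration: the exceedance of Z > 1.65 on 1000 noise-only summed
chunks is ≈ 7% — above the nominal 5% because summed Rayleigh amplitudes
are right-skewed relative to Gaussian. This is the method's actual
per-test false-positive rate at the "p < 0.05" cutoff.

## Numerical and design choices

* Oddball placement: first oddball at index `oddball_period − 1`
  (the 7th stimulus); a configurable phase offset shifts the whole comb.
  Slot modality is an independent fair coin per slot; exemplars are
  drawn uniformly with replacement but without immediate repetition.
* Event resampling rounds half-up; sample SDs use n−1 throughout;
  extrema ties in the baseline neighborhood drop the lowest index.
* Epoch crops default their available duration to the epoch end minus
  the 2-s post-stimulation margin and the 2-s fade-out.
* `simulate_seeg_contact(amp=...)` is a per-harmonic amplitude; studies
  express it in units of the per-bin local noise SD estimated from
  pilot null simulations (3 seeds, median).
* Validation study sizes (20 seeds for the scalp studies, 100 per
  profile for classification, 1000 null draws) keep each study within a
  couple of minutes while leaving the medians stable.
* The pipeline orchestration is a library function plus the numbered
  scripts under `analysis/`; the package deliberately ships no separate
  command-line binary — the scripts and `fpvs.pipeline.run_pipeline`
  are the intended entry points for an analysis-style project.
* EDF/BDF files are read through MNE; the internal HDF5 container is
  the lossless interchange format, and a minimal 24-bit BDF writer is
  provided for export (signal only; BDF quantizes to the 24-bit grid).

## Known limitations

* ICA-based ocular correction is out of scope; the regression stand-in
  behaves differently on real data (see above).
* Group-level inferential statistics (ANOVA/Friedman, post-hoc tests)
  are out of scope; the package emits per-ROI and per-contact tables
  for external analysis.
* The original segment lengths are not exactly recoverable from the
  published bin counts (they are mutually inconsistent with exact-bin
  alignment at the stated rates); the integer-cycle constraint is
  adopted as authoritative, giving 15,232 / 30,464-sample crops.
* Baseline-corrected μV values are floor-biased as quantified above;
  the package reports them as defined by the method rather than
  attempting bias correction.
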