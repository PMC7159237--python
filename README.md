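# fpvs — frequency-tagging crossmodal oddball analysis

Analysis code for fast-periodic-visual-stimulation (FPVS) oddball
experiments on face–name identity integration, for EEG/SEEG researchers
working with frequency-tagged designs. Stimuli appear at a base rate
F = 4 Hz and a different person identity appears every 7th stimulus, so
identity-change responses concentrate at f_odd = F/7 ≈ 0.571 Hz and its
harmonics in the amplitude spectrum. Three conditions — Face Name (FN),
Face Only (FO), Name Only (NO) — decompose the response: a crossmodal
(integrative) representation reveals itself as super-additivity,
FN > FO + NO.

The package provides:

* **paradigm** — seeded generation and validation of stimulation
  schedules (base/oddball structure, condition identity rules);
* **synth** — synthetic scalp-EEG sessions and SEEG contacts with known
  ground truth: tagged-harmonic responses obeying
  FN = FO + NO + crossmodal-extra, 1/f + white noise, line noise,
  blinks, inter-block DC jumps;
* **preprocess** — the scalp chain (block alignment, 0.1–100 Hz
  zero-phase Butterworth, multi-notch at 50 Hz harmonics, downsampling
  to 256 Hz, epoching, blink screening with EOG regression, neighbor
  interpolation, common average reference) and the minimal SEEG path;
* **spectral** — integer-cycle cropping (34 cycles = 59.5 s, putting
  f_odd exactly on bin 34 and F on bin 238), time-domain averaging, and
  calibrated single-sided amplitude spectra (2|X|/N: an exact-bin unit
  sinusoid reads 1 μV);
* **stats** — baseline-corrected amplitudes and local-noise Z-scores
  against surrounding-bin neighborhoods, harmonic chunk-and-sum
  pooling, the FN − (FO + NO) condition algebra, ROI quantification,
  integration fractions, and SEEG contact classification
  (pure/non-pure crossmodal, unimodal, mixed) at one-tailed cutoffs
  Z > 3.1 and Z > 1.65;
* **io / pipeline** — EDF/BDF reading (via MNE), a lossless HDF5
  container, a minimal 24-bit BDF writer, YAML-configured deterministic
  end-to-end runs.

The detection statistic for a channel/contact is the local Z of the
chunk-summed spectrum: segments centered on each of the first six
oddball harmonics are summed element-wise, and the center bin is
compared against the mean and SD of 22 surrounding bins,

    Z = (A_center − mean(neigh)) / SD(neigh),

with amplitude quantified as the baseline-corrected sum over harmonics
(μV). See `docs/methods.md` for conventions, presets and the measured
estimator biases.

## Worked example

Simulate a single SEEG contact of each response profile and classify it
(`python analysis/03_seeg_classification.py`, abbreviated output):

```
single-seed contact table (amp 1.3 μV per harmonic):
      profile       truth       label  z_FN  z_FO  z_NO
        mixed   mixed_all   mixed_all 45.02 23.83 22.94
         null        none        none  0.43 -0.62 -1.73
      pure_FN     pure_FN     pure_FN 47.22 -1.07 -1.33
unimodal_face FN_and_face FN_and_face 41.36 41.36  2.66
unimodal_name FN_and_name FN_and_name 36.25 -0.47 55.07
```

Each row is one simulated contact: `z_FN/z_FO/z_NO` are the local-noise
Z-scores of the summed oddball harmonics per condition. The pure_FN
contact responds only in FN (z = 47.2, controls at noise level) and its
FN − (FO + NO) subtraction is significant — the signature of a purely
crossmodal identity response. A strong unimodal face response is
significant in FO *and* FN (the FN sequence carries the same face
periodicity), hence `FN_and_face`. Over 100 seeds per profile at an
amplitude of 10× the local noise SD, all five separable profiles are
recovered at 99–100% and at most 1% of null contacts are labeled
pure_FN.

The scalp drivers (`analysis/01_simulate.py`, `02_scalp_analysis.py`)
run the full preprocessing chain on a simulated 18-channel session and
print the per-ROI quantification; noiseless input recovers the injected
amplitudes to < 1e-3 μV and an injected 32% crossmodal share exactly,
while at realistic noise the amplitude floor of Rayleigh-distributed
spectra biases the integration estimate upward (quantified in
`docs/methods.md`).

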