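"""Frequency-domain detection statistics and contact classification.

The response at a tagged frequency is judged against the *local* noise
level of the spectrum: the amplitude at the bin of interest is compared
with the bins immediately surrounding it.  Two quantities are derived
from a neighborhood of surrounding bins:

* baseline-corrected amplitude — bin amplitude minus the neighborhood
  mean, in μV; estimates signal above the local noise floor;
* local Z-score — the same difference divided by the neighborhood
  standard deviation (n-1); tested one-tailed against 1.65 (p < 0.05)
  or the conservative 3.1 (p < 0.001).

Responses spread over harmonics are pooled by chunk-and-sum: fixed-width
spectrum segments centered on each harmonic bin are summed element-wise
before the statistic is computed.

Condition algebra operates on raw (uncorrected) spectra: FO and NO
spectra are summed and subtracted from FN, and baseline correction or Z
scoring is applied *after* the algebra.  A contact whose FN response is
significant, whose FO and NO responses are not, and whose FN-(FO+NO)
difference is significant, is a "pure" crossmodal contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .spectral import AmplitudeSpectrum, freq_to_bin

#: One-tailed Z cutoffs used throughout (printed convention: 1.65 for
#: p < 0.05, 3.1 for p < 0.001).
Z_P05 = 1.65
Z_P001 = 3.1

#: Scalp ROI electrode sets.  The three-electrode sets come from the
#: single-condition experiment; the five-electrode sets from the
#: three-condition experiment.
ROI_EXP1 = {
    "LOT": ["P9", "PO9", "PO11"],
    "ROT": ["P10", "PO10", "PO12"],
    "midOT": ["Oz", "OIz", "Iz"],
}
ROI_EXP2 = {
    "LOT": ["I1", "POI1", "PO11", "PO9", "P9"],
    "ROT": ["I2", "POI2", "PO12", "PO10", "P10"],
}


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Which surrounding bins form the local noise estimate.

    ``n_per_side`` bins are taken on each side of the center,
    ``skip_adjacent`` bins immediately next to the center are dropped on
    each side, and with ``drop_extrema`` the single largest and single
    smallest amplitude among the remaining bins are also dropped
    (lowest-index occurrence on ties).
    """

    n_per_side: int
    skip_adjacent: int = 0
    drop_extrema: bool = False

    def __post_init__(self) -> None:
        if self.n_per_side <= self.skip_adjacent:
            raise ValueError("n_per_side must exceed skip_adjacent")
        if self.n_used < 4:
            raise ValueError("fewer than 4 neighborhood bins would remain")

    @property
    def n_used(self) -> int:
        n = 2 * (self.n_per_side - self.skip_adjacent)
        return n - 2 if self.drop_extrema else n


# Presets.  Scalp baseline: 12/side minus adjacent minus global max/min
# -> 20 bins used.  Scalp Z: 11/side, nothing excluded -> 22.  SEEG
# baseline and Z: 12/side minus adjacent -> 22.
SCALP_BASELINE = NeighborhoodSpec(12, skip_adjacent=1, drop_extrema=True)
SCALP_Z = NeighborhoodSpec(11)
SEEG_BASELINE = NeighborhoodSpec(12, skip_adjacent=1)
SEEG_Z = NeighborhoodSpec(12, skip_adjacent=1)

#: Chunk half-widths in bins: scalp chunks are 31 bins wide (center at
#: the 16th value); SEEG chunks are 47 bins (~0.79 Hz at the default
#: resolution, the widest symmetric window within 0.8 Hz).
CHUNK_HALF_WIDTH = {"scalp": 15, "seeg": 23}

VARIANT_PRESETS = {
    "scalp": {"z": SCALP_Z, "baseline": SCALP_BASELINE,
              "half_width": CHUNK_HALF_WIDTH["scalp"]},
    "seeg": {"z": SEEG_Z, "baseline": SEEG_BASELINE,
             "half_width": CHUNK_HALF_WIDTH["seeg"]},
}


def neighborhood(center: int, spec: NeighborhoodSpec,
                 amps: np.ndarray) -> np.ndarray:
    """Indices of the surrounding bins selected by ``spec``.

    Symmetric window around ``center`` (which is never included), minus
    the skipped adjacent bins, minus — if requested — the single max and
    min amplitude bins among the remainder.
    """
    amps = np.asarray(amps)
    lo = center - spec.n_per_side
    hi = center + spec.n_per_side
    if lo < 0 or hi >= amps.shape[-1]:
        raise ValueError(
            f"bin {center} too close to the spectrum edge for "
            f"{spec.n_per_side} bins per side")
    idx = np.concatenate([
        np.arange(lo, center - spec.skip_adjacent),
        np.arange(center + spec.skip_adjacent + 1, hi + 1),
    ])
    if spec.drop_extrema:
        vals = amps[idx]
        imax = int(np.argmax(vals))  # argmax/argmin take the first tie
        imin = int(np.argmin(vals))
        if imax == imin:  # all equal: drop the first two
            drop = {0, 1}
        else:
            drop = {imax, imin}
        idx = np.delete(idx, sorted(drop))
    return idx


def baseline_correct(spec: AmplitudeSpectrum,
                     nb: NeighborhoodSpec) -> AmplitudeSpectrum:
    """Subtract the local neighborhood mean from every interior bin.

    Edge bins without a full neighborhood are NaN and excluded from any
    downstream sum.  The result is a signed spectrum in μV.
    """
    amps = spec.amps
    k = nb.n_per_side
    out = np.full_like(amps, np.nan)
    if amps.shape[1] >= 2 * k + 1:
        # sliding windows: one row per interior bin, columns = offsets -k..k
        win = np.lib.stride_tricks.sliding_window_view(amps, 2 * k + 1, axis=1)
        offs = np.concatenate([np.arange(0, k - nb.skip_adjacent),
                               np.arange(k + nb.skip_adjacent + 1, 2 * k + 1)])
        sel = win[:, :, offs]
        if nb.drop_extrema:
            # mean after removing one max and one min: tie-choice irrelevant
            m = (sel.sum(axis=2) - sel.max(axis=2) - sel.min(axis=2)) \
                / (sel.shape[2] - 2)
        else:
            m = sel.mean(axis=2)
        out[:, k:amps.shape[1] - k] = amps[:, k:amps.shape[1] - k] - m
    return replace(spec, amps=out, signed=True,
                   meta={**spec.meta, "baseline": repr(nb)})


def local_z(spec: AmplitudeSpectrum, bin_index: int, nb: NeighborhoodSpec,
            channel: int = 0) -> float:
    """Z-score of one bin against its local neighborhood.

    ``(amp - mean(neigh)) / sd(neigh)`` with the sample (n-1) SD.  A
    zero neighborhood SD (degenerate, noise-free input) raises.
    """
    row = spec.amps[channel]
    idx = neighborhood(bin_index, nb, row)
    sd = float(np.std(row[idx], ddof=1))
    if sd == 0:
        raise ZeroDivisionError("neighborhood SD is zero (noise-free input)")
    return float((row[bin_index] - row[idx].mean()) / sd)


def noise_sd(spec: AmplitudeSpectrum, bin_index: int, nb: NeighborhoodSpec,
             channel: int = 0) -> float:
    """Local noise level: sample SD (n-1) of the neighborhood amplitudes."""
    row = spec.amps[channel]
    idx = neighborhood(bin_index, nb, row)
    return float(np.std(row[idx], ddof=1))


def harmonic_bins(spec: AmplitudeSpectrum, f_target: float,
                  harmonics: Sequence[int],
                  f_base: float | None = None) -> list[int]:
    """Exact bin indices of ``m * f_target`` for each multiple ``m``.

    If ``f_base`` is given, any multiple whose frequency coincides with
    a harmonic of the base rate is rejected (those bins carry the
    general visual response, not the oddball response).
    """
    bins = []
    for m in harmonics:
        f = m * f_target
        if f_base is not None:
            ratio = f / f_base
            if abs(ratio - round(ratio)) < 1e-9:
                raise ValueError(
                    f"harmonic {m} of {f_target:g} Hz coincides with the "
                    f"{f_base:g}-Hz base rate; exclude it")
        bins.append(freq_to_bin(spec, f, require_exact=True))
    return bins


def chunk_sum(spec: AmplitudeSpectrum, f_target: float,
              harmonics: Sequence[int], half_width_bins: int,
              f_base: float | None = None) -> AmplitudeSpectrum:
    """Element-wise sum of fixed-width chunks centered on each harmonic.

    Returns a ``2 * half_width_bins + 1``-bin spectrum-shaped object
    whose center element pools the harmonic bins; the surrounding
    elements pool the corresponding local noise bins.
    """
    bins = harmonic_bins(spec, f_target, harmonics, f_base=f_base)
    n = spec.n_bins
    for b in bins:
        if b - half_width_bins < 0 or b + half_width_bins >= n:
            raise ValueError(f"harmonic bin {b} lacks a {half_width_bins}-bin margin")
    chunks = [spec.amps[:, b - half_width_bins:b + half_width_bins + 1]
              for b in bins]
    summed = np.sum(chunks, axis=0)
    return AmplitudeSpectrum(
        amps=summed, df=spec.df, n_time_samples=spec.n_time_samples,
        labels=list(spec.labels), normalization=spec.normalization,
        signed=spec.signed,
        meta={**spec.meta, "chunk_center": half_width_bins,
              "harmonics": list(harmonics), "f_target": f_target})


@dataclass
class DetectionResult:
    """Outcome of the harmonic-summed detection test at one channel."""

    z: float
    bc_sum: float  # baseline-corrected amplitude summed over harmonics, μV
    harmonics: list[int]
    threshold: float
    significant: bool
    variant: str
    noise_sd: float

    def __post_init__(self) -> None:
        assert self.significant == (self.z > self.threshold)


def detect_response(spec: AmplitudeSpectrum, f_odd: float,
                    harmonics: Sequence[int] = (1, 2, 3, 4, 5, 6),
                    variant: Literal["scalp", "seeg"] = "scalp",
                    z_threshold: float = Z_P05,
                    f_base: float | None = None,
                    channel: int = 0) -> DetectionResult:
    """Test for a periodic response pooled over harmonics of ``f_odd``.

    The Z statistic is the local Z of the center bin of the
    chunk-and-summed spectrum, using the variant's Z neighborhood.  The
    amplitude estimate ``bc_sum`` follows the variant's quantification
    order: the scalp path baseline-corrects the *summed chunk* at its
    center; the SEEG path sums per-harmonic baseline-corrected
    amplitudes of the full spectrum.  Both use the variant's baseline
    neighborhood and agree exactly when no extrema are dropped.
    """
    presets = VARIANT_PRESETS[variant]
    chunk = chunk_sum(spec, f_odd, harmonics, presets["half_width"],
                      f_base=f_base)
    center = presets["half_width"]
    z = local_z(chunk, center, presets["z"], channel=channel)
    sd = noise_sd(chunk, center, presets["z"], channel=channel)
    nb = presets["baseline"]
    if variant == "scalp":
        row = chunk.amps[channel]
        idx = neighborhood(center, nb, row)
        bc_sum = float(row[center] - row[idx].mean())
    else:
        row = spec.amps[channel]
        bc_sum = 0.0
        for b in harmonic_bins(spec, f_odd, harmonics, f_base=f_base):
            idx = neighborhood(b, nb, row)
            bc_sum += float(row[b] - row[idx].mean())
    return DetectionResult(z=z, bc_sum=bc_sum, harmonics=list(harmonics),
                           threshold=z_threshold, significant=z > z_threshold,
                           variant=variant, noise_sd=sd)


def _check_grids(a: AmplitudeSpectrum, b: AmplitudeSpectrum) -> None:
    if a.amps.shape != b.amps.shape or abs(a.df - b.df) > 1e-12 * a.df \
            or a.labels != b.labels:
        raise ValueError("spectra are not on a common grid")


def spectra_add(a: AmplitudeSpectrum, b: AmplitudeSpectrum) -> AmplitudeSpectrum:
    """Element-wise sum of two raw spectra (before any correction)."""
    _check_grids(a, b)
    return replace(a, amps=a.amps + b.amps)


def spectra_subtract(a: AmplitudeSpectrum,
                     b: AmplitudeSpectrum) -> AmplitudeSpectrum:
    """Element-wise difference ``a - b``; the result is signed."""
    _check_grids(a, b)
    return replace(a, amps=a.amps - b.amps, signed=True)


@dataclass
class ContactClassification:
    """Categorical label of an SEEG contact.

    ``pure_FN``: significant in FN only, and FN - (FO + NO) significant.
    ``nonpure_FN``: significant in FN only, but the subtraction is not.
    The remaining labels encode every other combination of per-condition
    significances.
    """

    label: str
    detections: dict[str, DetectionResult] = field(default_factory=dict)


def classify_contact(fn: AmplitudeSpectrum, fo: AmplitudeSpectrum,
                     no: AmplitudeSpectrum, f_odd: float,
                     harmonics: Sequence[int] = (1, 2, 3, 4, 5, 6),
                     f_base: float | None = None,
                     z_condition: float = Z_P001,
                     z_subtraction: float = Z_P05) -> ContactClassification:
    """Classify one SEEG contact from its three condition spectra.

    Each condition is tested at the conservative one-tailed Z > 3.1.
    When only FN is significant, the raw spectra of the control
    conditions are summed, subtracted from the FN spectrum, and the
    difference is tested at Z > 1.65 one-tailed to separate pure from
    non-pure crossmodal responses.
    """
    det = {
        cond: detect_response(s, f_odd, harmonics, variant="seeg",
                              z_threshold=z_condition, f_base=f_base)
        for cond, s in (("FN", fn), ("FO", fo), ("NO", no))
    }
    sig = {c: d.significant for c, d in det.items()}
    if sig["FN"] and not sig["FO"] and not sig["NO"]:
        diff = spectra_subtract(fn, spectra_add(fo, no))
        det["FN-(FO+NO)"] = detect_response(
            diff, f_odd, harmonics, variant="seeg",
            z_threshold=z_subtraction, f_base=f_base)
        label = "pure_FN" if det["FN-(FO+NO)"].significant else "nonpure_FN"
    elif sig["FN"] and sig["FO"] and sig["NO"]:
        label = "mixed_all"
    elif sig["FN"] and sig["FO"]:
        label = "FN_and_face"
    elif sig["FN"] and sig["NO"]:
        label = "FN_and_name"
    elif sig["FO"] and not sig["NO"]:
        label = "unimodal_face"
    elif sig["NO"] and not sig["FO"]:
        label = "unimodal_name"
    elif sig["FO"] and sig["NO"]:
        label = "mixed_unimodal"
    else:
        label = "none"
    return ContactClassification(label=label, detections=det)


def select_harmonic_range(grand_spec: AmplitudeSpectrum, f_target: float,
                          max_multiple: int,
                          variant: Literal["scalp", "seeg"] = "scalp",
                          z_threshold: float = Z_P05,
                          f_base: float | None = None,
                          channel: int = 0) -> list[int]:
    """Contiguous range 1..M of significant harmonics on a grand average.

    M is the largest multiple not exceeding ``max_multiple`` whose local
    Z exceeds the threshold; interior dips do not break the range (the
    convention is to sum "the first M" harmonics).  Multiples coinciding
    with base-rate harmonics are skipped entirely.
    """
    nb = VARIANT_PRESETS[variant]["z"]
    best = 0
    for m in range(1, max_multiple + 1):
        f = m * f_target
        if f_base is not None:
            ratio = f / f_base
            if abs(ratio - round(ratio)) < 1e-9:
                continue
        b = freq_to_bin(grand_spec, f, require_exact=True)
        if local_z(grand_spec, b, nb, channel=channel) > z_threshold:
            best = m
    if best == 0:
        return []
    return [m for m in range(1, best + 1)
            if f_base is None or abs(m * f_target / f_base
                                     - round(m * f_target / f_base)) > 1e-9]


def summed_oddball_amplitude(spec: AmplitudeSpectrum, f_target: float,
                             harmonics: Sequence[int],
                             variant: Literal["scalp", "seeg"] = "scalp",
                             order: str | None = None,
                             f_base: float | None = None) -> np.ndarray:
    """Per-channel baseline-corrected amplitude summed over harmonics (μV).

    Two quantification orders exist and are tagged by ``order``:

    * ``"chunk_then_correct"`` (scalp default): chunk-and-sum the raw
      spectrum over the harmonics, then baseline-correct the summed
      chunk once at its center;
    * ``"correct_then_sum"`` (seeg default): baseline-correct the full
      spectrum and sum the corrected values at the harmonic bins.

    The orders agree exactly when the baseline neighborhood drops no
    extrema and uses the same window.
    """
    presets = VARIANT_PRESETS[variant]
    nb = presets["baseline"]
    if order is None:
        order = "chunk_then_correct" if variant == "scalp" else "correct_then_sum"
    if order == "chunk_then_correct":
        chunk = chunk_sum(spec, f_target, harmonics, presets["half_width"],
                          f_base=f_base)
        center = presets["half_width"]
        out = np.empty(chunk.amps.shape[0])
        for c, row in enumerate(chunk.amps):
            idx = neighborhood(center, nb, row)
            out[c] = row[center] - row[idx].mean()
        return out
    if order == "correct_then_sum":
        bins = harmonic_bins(spec, f_target, harmonics, f_base=f_base)
        out = np.zeros(spec.amps.shape[0])
        for c, row in enumerate(spec.amps):
            for b in bins:
                idx = neighborhood(b, nb, row)
                out[c] += row[b] - row[idx].mean()
        return out
    raise ValueError(f"unknown quantification order {order!r}")


def roi_quantify(bc: AmplitudeSpectrum, roi: Sequence[str], f_target: float,
                 harmonics: Sequence[int],
                 f_base: float | None = None) -> float:
    """Mean over ROI channels of the summed baseline-corrected amplitude.

    ``bc`` must be a baseline-corrected (signed) spectrum; the value is
    the per-channel sum over harmonic bins, averaged over the ROI, in μV.
    """
    bins = harmonic_bins(bc, f_target, harmonics, f_base=f_base)
    idx = [bc.channel_index(ch) for ch in roi]
    vals = bc.amps[np.ix_(idx, bins)]
    if np.any(np.isnan(vals)):
        raise ValueError("harmonic bin lacks a valid baseline neighborhood")
    return float(vals.sum(axis=1).mean())


def integration_fraction(fn_amp: float, fo_amp: float, no_amp: float) -> float:
    """Percentage of the FN response not explained by FO + NO.

    ``100 * (1 - (FO + NO) / FN)``; negative values (controls exceeding
    FN) are reported as-is.
    """
    if fn_amp <= 0:
        raise ValueError("FN amplitude must be positive")
    return 100.0 * (1.0 - (fo_amp + no_amp) / fn_amp)


def pure_contact_fraction(n_pure: int, n_contacts: int) -> float:
    """Percentage of recorded contacts with a pure crossmodal response."""
    if n_contacts <= 0:
        raise ValueError("contact count must be positive")
    if not 0 <= n_pure <= n_contacts:
        raise ValueError("pure count outside 0..n_contacts")
    return 100.0 * n_pure / n_contacts
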