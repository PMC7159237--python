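"""Self-contained validation studies over the synthetic generators.

Each function simulates data with known ground truth, runs the full
analysis path, and returns the measured quantities.  They define the
package's reference study conditions:

* the *single-session* condition: one simulated session with the
  default background noise (a realistic single subject);
* the *group* condition: the same session with all noise and artifact
  magnitudes scaled by 1/sqrt(20), emulating the grand average of a
  20-subject group (the periodic response is coherent across subjects
  under the model, noise averages down as 1/sqrt(n)).

Amplitude quantification operates on amplitude (not power) spectra, so
baseline-corrected estimates carry a known downward bias of roughly
1.25 times the per-bin complex-noise SD per harmonic (the Rayleigh
noise floor enters the neighborhood mean but only quadratically at the
signal bin).  The recovery and integration studies below measure this
directly; see the methods note for the bias curve.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats

from . import synth
from .paradigm import ScheduleParams
from .pipeline import AnalysisConfig, roi_condition_table, scalp_condition_spectra, seeg_condition_spectra
from .preprocess import Epoch
from .spectral import amplitude_spectrum, freq_to_bin
from . import stats
from .synth import NO_NOISE, QUIET_NOISE, NoiseSpec, ResponseSpec

ODDBALL_HARMONICS = (1, 2, 3, 4, 5, 6)


def one_tailed_z(p: float) -> float:
    """Upper-tail standard-normal quantile for a one-tailed p value."""
    return float(sstats.norm.isf(p))


def design_constants() -> dict:
    """Analytic constants of the paradigm, from the package's own code."""
    params = ScheduleParams()
    return {
        "oddball_freq_hz": params.oddball_freq,
        "third_harmonic_hz": 3 * params.oddball_freq,
        "cycle_ms": params.cycle_duration * 1000.0,
        "z_cutoff_p001": round(one_tailed_z(0.001), 1),
        "chunk_center_position": stats.CHUNK_HALF_WIDTH["scalp"] + 1,
        "pure_contact_pct": stats.pure_contact_fraction(3, 26),
    }


def spectral_calibration() -> dict:
    """Unit-sinusoid calibration on an integer-cycle crop."""
    params = ScheduleParams()
    fs, duration = 256.0, 59.5
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    data = np.sin(2 * np.pi * 4.0 * t) + 0.5 * np.sin(
        2 * np.pi * params.oddball_freq * t)
    ep = Epoch(data=data[None, :], fs=fs, labels=["x"], t0=0.0)
    spec = amplitude_spectrum(ep)
    b_odd = freq_to_bin(spec, params.oddball_freq, require_exact=True)
    b_base = freq_to_bin(spec, params.base_freq, require_exact=True)
    return {
        "unit_sinusoid_amp": float(spec.amps[0, b_base]),
        "oddball_bin": b_odd,
        "base_bin": b_base,
        "base_to_oddball_bin_ratio": b_base / b_odd,
    }


def default_scalp_response() -> ResponseSpec:
    return ResponseSpec.from_totals(
        len(synth.DEFAULT_SCALP_LABELS),
        channel_gains=synth.DEFAULT_ODDBALL_GAINS,
        base_gains=synth.DEFAULT_BASE_GAINS)


GROUP_SIZE = 20  # subjects in the emulated grand average


def scalp_group_noise() -> NoiseSpec:
    return NoiseSpec().scaled(1.0 / np.sqrt(GROUP_SIZE))


def noiseless_recovery() -> dict:
    """Noiseless end-to-end: full scalp chain must return the injected
    summed oddball amplitudes exactly (to numerical tolerance)."""
    spec = default_scalp_response()
    sim = synth.simulate_session(ScheduleParams(), spec, noise=NO_NOISE,
                                 seed=0)
    spectra = scalp_condition_spectra(sim.recording, sim.block_boundaries)
    errs, table = [], roi_condition_table(spectra, AnalysisConfig())
    for cond in ("FN", "FO", "NO"):
        vals = stats.summed_oddball_amplitude(
            spectra[cond], ScheduleParams().oddball_freq, ODDBALL_HARMONICS,
            variant="scalp", f_base=4.0)
        ch = spectra[cond].channel_index("P9")
        errs.append(abs(vals[ch] - sim.injected_oddball_total(cond)))
    return {
        "noiseless_recovery_err_uv": float(max(errs)),
        "noiseless_integration_pct": float(table.loc["LOT",
                                                     "integration_pct"]),
    }


def scalp_group_study(n_seeds: int = 20, seed: int = 0) -> dict:
    """Recovery and integration at the 20-subject grand-average condition.

    Each seed simulates one session (4 sequences per condition, the
    standard three-condition design) with group-level noise, runs the
    scalp path, and reads the left-ROI quantification table.  Returns
    medians over seeds of the FN amplitude recovery ratio and the
    integration fraction (injected: 32%).
    """
    rng = np.random.default_rng(seed)
    spec = default_scalp_response()
    noise = scalp_group_noise()
    cfg = AnalysisConfig()
    ratios, integrations, snrs = [], [], []
    for _ in range(n_seeds):
        s = int(rng.integers(2 ** 31))
        sim = synth.simulate_session(ScheduleParams(), spec, noise=noise,
                                     n_sequences_per_condition=4, seed=s)
        spectra = scalp_condition_spectra(sim.recording,
                                          sim.block_boundaries, cfg=cfg)
        table = roi_condition_table(spectra, cfg)
        ratios.append(table.loc["LOT", "FN"]
                      / sim.injected_oddball_total("FN"))
        integrations.append(table.loc["LOT", "integration_pct"])
        ch = spectra["FN"].channel_index("P9")
        b = freq_to_bin(spectra["FN"], 4.0 / 7.0, require_exact=True)
        snrs.append(spectra["FN"].amps[ch, b]
                    / stats.noise_sd(spectra["FN"], b, stats.SCALP_Z,
                                     channel=ch))
    return {
        "recovery_ratio": float(np.median(ratios)),
        "recovery_err_pct": float(100 * abs(1 - np.median(ratios))),
        "integration_pct": float(np.median(integrations)),
        "per_harmonic_snr": float(np.median(snrs)),
    }


def estimate_seeg_noise_sd(n_pilot: int = 3, seed: int = 0) -> float:
    """Per-bin local noise SD at the oddball bin of a null SEEG contact."""
    sds = []
    for k in range(n_pilot):
        sim = synth.simulate_seeg_contact("null", amp=0.0, noise=QUIET_NOISE,
                                          seed=seed + k)
        spec = seeg_condition_spectra(sim.recording)["FN"]
        b = freq_to_bin(spec, 4.0 / 7.0, require_exact=True)
        sds.append(stats.noise_sd(spec, b, stats.SEEG_Z))
    return float(np.median(sds))


#: Profiles whose expected label is deterministic at high amplitude.
SEPARABLE_PROFILES = ("pure_FN", "unimodal_face", "unimodal_name", "mixed",
                      "null")


def classify_one_contact(profile: str, amp: float,
                         seed: int) -> stats.ContactClassification:
    sim = synth.simulate_seeg_contact(profile, amp=amp, noise=QUIET_NOISE,
                                      seed=seed)
    spectra = seeg_condition_spectra(sim.recording)
    return stats.classify_contact(spectra["FN"], spectra["FO"],
                                  spectra["NO"], 4.0 / 7.0,
                                  harmonics=ODDBALL_HARMONICS, f_base=4.0)


def classification_study(n_seeds: int = 100, seed: int = 0,
                         amp_sigma: float = 10.0,
                         profiles=SEPARABLE_PROFILES) -> dict:
    """Label-recovery rates per contact profile at amp = 10 x noise SD.

    ``amp_sigma`` scales the per-harmonic oddball amplitude in units of
    the per-bin local noise SD (estimated from pilot null contacts).
    Returns per-profile accuracy and the pure-FN false-positive rate on
    null contacts.
    """
    sigma = estimate_seeg_noise_sd(seed=seed)
    amp = amp_sigma * sigma
    rng = np.random.default_rng(seed + 1)
    seeds = rng.integers(2 ** 31, size=(len(profiles), n_seeds))
    accuracy, labels_by_profile = {}, {}
    for i, profile in enumerate(profiles):
        labels = [classify_one_contact(profile, amp, int(s)).label
                  for s in seeds[i]]
        expected = synth.SEEG_EXPECTED_LABEL[profile]
        accuracy[profile] = 100.0 * np.mean([l == expected for l in labels])
        labels_by_profile[profile] = labels
    out = {f"accuracy_{p}": float(a) for p, a in accuracy.items()}
    if "null" in labels_by_profile:
        out["null_pure_fn_rate_pct"] = float(
            100.0 * np.mean([l == "pure_FN"
                             for l in labels_by_profile["null"]]))
    out["noise_sd_uv"] = sigma
    out["amp_uv"] = amp
    return out


def nonpure_study(n_seeds: int = 50, seed: int = 0,
                  amp_sigma: float = 10.0) -> dict:
    """Label distribution for the threshold-bound nonpure profile.

    The nonpure category is defined by a *non-rejected* subtraction test
    while the FN test rejects, so its label is intrinsically stochastic
    at any amplitude; moreover the subtraction Z carries a positive bias
    for contacts with genuine responses in all conditions (signal bins
    lack the Rayleigh floor their neighborhoods retain), which promotes
    a fraction of such contacts to pure_FN.  The stable guarantees are
    that the FN response itself is reliably detected and that labels
    stay within FN-involving categories; the pure-promotion rate is
    reported as a measured characteristic.
    """
    sigma = estimate_seeg_noise_sd(seed=seed)
    rng = np.random.default_rng(seed + 2)
    labels, fn_sig = [], []
    for _ in range(n_seeds):
        cls = classify_one_contact("nonpure_FN", amp_sigma * sigma,
                                   int(rng.integers(2 ** 31)))
        labels.append(cls.label)
        fn_sig.append(cls.detections["FN"].significant)
    return {
        "nonpure_fn_detect_pct": float(100.0 * np.mean(fn_sig)),
        "nonpure_pure_fn_rate_pct": float(
            100.0 * np.mean([l == "pure_FN" for l in labels])),
        "nonpure_label_counts": {l: labels.count(l) for l in set(labels)},
    }


def null_z_calibration(n_draws: int = 1000, seed: int = 0) -> dict:
    """Empirical exceedance of Z > 1.65 on noise-only spectra.

    Amplitude-spectrum noise is Rayleigh-distributed, not Gaussian, so
    the exceedance of the nominal 5% cutoff is expected to deviate from
    5% (typically landing between 3% and 10% for pooled harmonics).
    """
    noise = NoiseSpec(pink_scale=0.0, white_scale=1.0, line_amp=0.0,
                      blink_rate=0.0, block_dc_jump=0.0)
    rng = np.random.default_rng(seed)
    n_exceed = 0
    for _ in range(n_draws):
        x = synth.synth_noise(1, 59.5, 256.0, noise,
                              seed=int(rng.integers(2 ** 31)))
        ep = Epoch(data=x, fs=256.0, labels=["x"], t0=0.0)
        det = stats.detect_response(amplitude_spectrum(ep), 4.0 / 7.0,
                                    harmonics=ODDBALL_HARMONICS,
                                    variant="scalp",
                                    z_threshold=stats.Z_P05, f_base=4.0)
        n_exceed += det.significant
    return {"null_z165_exceedance_pct": 100.0 * n_exceed / n_draws}
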