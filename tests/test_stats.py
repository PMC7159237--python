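"""Detection statistics: neighborhoods, Z-scores, chunk-sum, classification.

The core operations are checked bin-exactly against naive brute-force
re-implementations written independently below (explicit loops and
sorting, no shared code with the package).
"""

import numpy as np
import pytest

from fpvs.spectral import AmplitudeSpectrum
from fpvs import stats
from fpvs.stats import (SCALP_BASELINE, SCALP_Z, SEEG_BASELINE, SEEG_Z,
                        NeighborhoodSpec, baseline_correct, chunk_sum,
                        classify_contact, detect_response, harmonic_bins,
                        integration_fraction, local_z, neighborhood, noise_sd,
                        pure_contact_fraction, select_harmonic_range,
                        spectra_add, spectra_subtract,
                        summed_oddball_amplitude)

F_ODD = 4.0 / 7.0


def make_spectrum(amps, df=4 / 7 / 34, labels=None):
    amps = np.atleast_2d(np.asarray(amps, dtype=float))
    labels = labels or [f"ch{i}" for i in range(amps.shape[0])]
    n_time = int(round(2 * (amps.shape[1] - 1)))
    return AmplitudeSpectrum(amps=amps, df=df, n_time_samples=n_time,
                             labels=labels)


# ---------------------------------------------------------------- oracles

def naive_neighborhood(center, spec, row):
    """Independent re-implementation with explicit loops."""
    idx = []
    for b in range(center - spec.n_per_side, center + spec.n_per_side + 1):
        if b == center or abs(b - center) <= spec.skip_adjacent:
            continue
        idx.append(b)
    if spec.drop_extrema:
        vals = [row[i] for i in idx]
        imax = vals.index(max(vals))
        imin = vals.index(min(vals))
        if imax == imin:
            imax, imin = 0, 1
        for j in sorted({imax, imin}, reverse=True):
            idx.pop(j)
    return idx


def naive_baseline(row, spec):
    out = np.full(len(row), np.nan)
    for b in range(spec.n_per_side, len(row) - spec.n_per_side):
        idx = naive_neighborhood(b, spec, row)
        out[b] = row[b] - sum(row[i] for i in idx) / len(idx)
    return out


def naive_local_z(row, b, spec):
    idx = naive_neighborhood(b, spec, row)
    vals = [row[i] for i in idx]
    m = sum(vals) / len(vals)
    var = sum((v - m) ** 2 for v in vals) / (len(vals) - 1)
    return (row[b] - m) / var ** 0.5


def naive_chunk_sum(row, bins, half):
    out = np.zeros(2 * half + 1)
    for b in bins:
        for j in range(-half, half + 1):
            out[j + half] += row[b + j]
    return out


# ------------------------------------------------------------------ tests

class TestNeighborhood:
    @pytest.mark.parametrize("preset,n_expected", [
        (SCALP_BASELINE, 20), (SCALP_Z, 22), (SEEG_BASELINE, 22),
        (SEEG_Z, 22)])
    def test_preset_sizes(self, preset, n_expected, rng):
        row = rng.random(200)
        idx = neighborhood(100, preset, row)
        assert len(idx) == n_expected == preset.n_used
        assert 100 not in idx

    def test_adjacent_bins_skipped(self, rng):
        row = rng.random(100)
        idx = neighborhood(50, SEEG_Z, row)
        assert 49 not in idx and 51 not in idx
        assert 50 - 12 in idx and 50 + 12 in idx

    def test_extrema_dropped_first_occurrence(self):
        row = np.ones(100)
        row[45] = 9.0   # max within the window
        row[58] = -3.0  # min within the window
        idx = neighborhood(50, SCALP_BASELINE, row)
        assert 45 not in idx and 58 not in idx

    def test_edge_raises(self, rng):
        row = rng.random(30)
        with pytest.raises(ValueError, match="edge"):
            neighborhood(5, SEEG_Z, row)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            NeighborhoodSpec(2, skip_adjacent=2)
        with pytest.raises(ValueError):
            NeighborhoodSpec(3, skip_adjacent=1, drop_extrema=True)

    def test_matches_naive_oracle(self, rng):
        for preset in (SCALP_BASELINE, SCALP_Z, SEEG_BASELINE):
            for _ in range(20):
                row = rng.random(120)
                c = int(rng.integers(20, 100))
                assert list(neighborhood(c, preset, row)) == \
                    naive_neighborhood(c, preset, row)


class TestBaselineCorrect:
    def test_flat_spectrum_corrects_to_zero(self):
        spec = make_spectrum(np.full(120, 3.3))
        out = baseline_correct(spec, SCALP_BASELINE)
        interior = out.amps[0, 12:-12]
        assert np.allclose(interior, 0.0, atol=1e-12)

    def test_isolated_peak_on_flat_background(self):
        amps = np.full(200, 1.0)
        amps[100] = 3.0
        out = baseline_correct(make_spectrum(amps), SEEG_BASELINE)
        assert out.amps[0, 100] == pytest.approx(2.0)

    @pytest.mark.parametrize("preset", [SCALP_BASELINE, SCALP_Z,
                                        SEEG_BASELINE])
    def test_matches_naive_oracle_on_random_spectra(self, preset, rng):
        """Bin-exact equality with the double-loop oracle, 100 spectra."""
        for _ in range(100):
            row = rng.random(80)
            out = baseline_correct(make_spectrum(row), preset)
            expected = naive_baseline(row, preset)
            assert np.allclose(out.amps[0], expected, atol=1e-12,
                               equal_nan=True)

    def test_homogeneity(self, rng):
        row = rng.random(100)
        a = baseline_correct(make_spectrum(row), SEEG_BASELINE).amps
        b = baseline_correct(make_spectrum(10 * row), SEEG_BASELINE).amps
        assert np.allclose(10 * a, b, atol=1e-12, equal_nan=True)


class TestLocalZ:
    def test_alternating_neighborhood_arithmetic(self):
        """Center 2.0 over alternating 0.9/1.1 -> z = 1/(0.1 sqrt(22/21))."""
        row = np.empty(23)
        c = 11
        for k in range(1, 12):
            row[c - k] = 0.9 if k % 2 else 1.1
            row[c + k] = 1.1 if k % 2 else 0.9
        row[c] = 2.0
        z = local_z(make_spectrum(row), c, SCALP_Z)
        assert z == pytest.approx(1.0 / (0.1 * np.sqrt(22 / 21)), rel=1e-9)
        assert z == pytest.approx(9.770, abs=1e-3)

    def test_center_at_mean_gives_zero(self, rng):
        row = rng.random(60)
        idx = neighborhood(30, SEEG_Z, row)
        row[30] = row[idx].mean()
        assert local_z(make_spectrum(row), 30, SEEG_Z) == pytest.approx(0.0,
                                                                        abs=1e-12)

    def test_affine_invariance(self, rng):
        row = rng.random(60) + 0.5
        z0 = local_z(make_spectrum(row), 30, SEEG_Z)
        z_scaled = local_z(make_spectrum(row * 10), 30, SEEG_Z)
        z_shifted = local_z(make_spectrum(row + 7.0), 30, SEEG_Z)
        assert z_scaled == pytest.approx(z0, rel=1e-12)
        assert z_shifted == pytest.approx(z0, rel=1e-9)

    def test_zero_sd_raises(self):
        with pytest.raises(ZeroDivisionError):
            local_z(make_spectrum(np.ones(60)), 30, SEEG_Z)

    def test_matches_naive_oracle(self, rng):
        for _ in range(100):
            row = rng.random(80)
            c = int(rng.integers(15, 65))
            assert local_z(make_spectrum(row), c, SEEG_Z) == pytest.approx(
                naive_local_z(row, c, SEEG_Z), rel=1e-12)


class TestNoiseSd:
    def test_flat_neighborhood_zero(self):
        assert noise_sd(make_spectrum(np.ones(60)), 30, SEEG_Z) == 0.0

    def test_alternating_arithmetic(self):
        row = np.empty(25)
        c = 12
        for k in range(1, 13):
            row[c - k] = 0.9 if k % 2 else 1.1
            row[c + k] = 1.1 if k % 2 else 0.9
        row[c] = 2.0
        row[c - 1] = row[c + 1] = 5.0  # skipped bins must not matter
        assert noise_sd(make_spectrum(row), c, SEEG_Z) == pytest.approx(
            0.1 * np.sqrt(22 / 21), rel=1e-9)

    def test_homogeneity(self, rng):
        row = rng.random(60)
        s1 = noise_sd(make_spectrum(row), 30, SEEG_Z)
        s2 = noise_sd(make_spectrum(2 * row), 30, SEEG_Z)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)


class TestChunkSum:
    def test_scalp_chunk_center_is_16th_value(self, rng):
        row = rng.random(400)
        out = chunk_sum(make_spectrum(row), F_ODD, range(1, 7), 15,
                        f_base=4.0)
        assert out.n_bins == 31
        # center element (index 15, the 16th value) pools the harmonics
        bins = harmonic_bins(make_spectrum(row), F_ODD, range(1, 7))
        assert out.amps[0, 15] == pytest.approx(sum(row[b] for b in bins))

    def test_pure_harmonic_spectrum_sums_to_center(self):
        amps = np.zeros(400)
        for m in range(1, 7):
            amps[34 * m] = 0.25
        out = chunk_sum(make_spectrum(amps), F_ODD, range(1, 7), 15,
                        f_base=4.0)
        expected = np.zeros(31)
        expected[15] = 1.5
        assert np.allclose(out.amps[0], expected)

    def test_base_collision_rejected(self):
        spec = make_spectrum(np.ones(400))
        with pytest.raises(ValueError, match="coincides"):
            chunk_sum(spec, F_ODD, [1, 2, 3, 4, 5, 6, 7], 15, f_base=4.0)

    def test_margin_violation_rejected(self):
        spec = make_spectrum(np.ones(60))
        with pytest.raises(ValueError, match="margin"):
            chunk_sum(spec, F_ODD, [1], 40)

    def test_matches_naive_oracle(self, rng):
        for _ in range(100):
            row = rng.random(300)
            out = chunk_sum(make_spectrum(row), F_ODD, range(1, 7), 10,
                            f_base=4.0)
            bins = [34 * m for m in range(1, 7)]
            assert np.allclose(out.amps[0], naive_chunk_sum(row, bins, 10),
                               atol=1e-12)


class TestSpectraAlgebra:
    def test_add_subtract_roundtrip(self, rng):
        a = make_spectrum(rng.random(100))
        b = make_spectrum(rng.random(100))
        back = spectra_subtract(spectra_add(a, b), b)
        assert np.allclose(back.amps, a.amps, atol=1e-12)

    def test_grid_mismatch_rejected(self, rng):
        a = make_spectrum(rng.random(100))
        b = make_spectrum(rng.random(101))
        with pytest.raises(ValueError, match="grid"):
            spectra_add(a, b)


class TestDetectResponse:
    def test_noiseless_bc_sum_recovers_injected(self):
        """On a noise-free spectrum the Z stat degenerates (zero SD), so
        the amplitude readout alone is checked, per-harmonic and summed."""
        amps = np.full(400, 0.0)
        for m in range(1, 7):
            amps[34 * m] = 0.5 / 6
        vals = summed_oddball_amplitude(make_spectrum(amps), F_ODD,
                                        range(1, 7), variant="seeg",
                                        f_base=4.0)
        assert vals[0] == pytest.approx(0.5, abs=1e-9)

    def test_zero_sd_on_noiseless_raises_in_z(self):
        amps = np.zeros(400)
        amps[34] = 1.0
        with pytest.raises(ZeroDivisionError):
            detect_response(make_spectrum(amps), F_ODD, harmonics=[1],
                            variant="seeg", f_base=4.0)

    def test_quantification_orders_agree_without_extrema_drop(self, rng):
        """correct-then-sum equals chunk-then-correct for no-drop windows."""
        row = rng.random(400) + 1.0
        spec = make_spectrum(row)
        a = summed_oddball_amplitude(spec, F_ODD, range(1, 7), variant="seeg",
                                     order="chunk_then_correct", f_base=4.0)
        b = summed_oddball_amplitude(spec, F_ODD, range(1, 7), variant="seeg",
                                     order="correct_then_sum", f_base=4.0)
        assert a[0] == pytest.approx(b[0], rel=1e-12)


class TestClassifyContact:
    def engineered_spectrum(self, signal, n=700, floor=1.0, wiggle=0.01):
        """Flat-noise spectrum with a deterministic wiggle and a known
        oddball signal per harmonic added on top."""
        amps = floor + wiggle * np.sin(np.arange(n))
        for m in range(1, 7):
            amps[34 * m] += signal
        return make_spectrum(amps, labels=["c"])

    def classify(self, s_fn, s_fo, s_no):
        return classify_contact(self.engineered_spectrum(s_fn),
                                self.engineered_spectrum(s_fo),
                                self.engineered_spectrum(s_no),
                                F_ODD, f_base=4.0)

    def test_decision_table(self):
        hi, lo = 1.0, 0.0  # far above / below the Z thresholds
        assert self.classify(hi, lo, lo).label == "pure_FN"
        assert self.classify(hi, hi, lo).label == "FN_and_face"
        assert self.classify(hi, lo, hi).label == "FN_and_name"
        assert self.classify(hi, hi, hi).label == "mixed_all"
        assert self.classify(lo, hi, lo).label == "unimodal_face"
        assert self.classify(lo, lo, hi).label == "unimodal_name"
        assert self.classify(lo, lo, lo).label == "none"

    def test_pure_vs_nonpure_split_on_subtraction(self):
        """FN-only significance with a null subtraction -> nonpure_FN.

        The controls each carry half the FN signal, but buried in noise
        large enough to stay below the 3.1 cutoff; the subtraction then
        carries no signal at all.  Seeded noise keeps it deterministic.
        """
        rng = np.random.default_rng(4)
        def noisy(signal, noise_sd):
            amps = 1.0 + rng.normal(0, noise_sd, 700)
            for m in range(1, 7):
                amps[34 * m] += signal
            return make_spectrum(np.abs(amps), labels=["c"])
        fn = noisy(1.0, 0.05)
        fo = noisy(0.5, 0.6)
        no = noisy(0.5, 0.6)
        cls = classify_contact(fn, fo, no, F_ODD, f_base=4.0)
        assert cls.label == "nonpure_FN"
        assert "FN-(FO+NO)" in cls.detections
        assert cls.detections["FN-(FO+NO)"].z <= 1.65

    def test_detections_carry_thresholds(self):
        cls = self.classify(1.0, 0.0, 0.0)
        assert cls.detections["FN"].threshold == pytest.approx(3.1)
        assert cls.detections["FN-(FO+NO)"].threshold == pytest.approx(1.65)


class TestSelectHarmonicRange:
    def make_grand(self, active_bins, n=2400):
        # linear ramp background: symmetric neighborhoods give z = 0
        # exactly at every inactive bin, so the outcome is deterministic
        amps = 1.0 + 1e-4 * np.arange(n)
        for b in active_bins:
            amps[b] += 3.0
        return make_spectrum(amps)

    def test_first_six_oddball_harmonics(self):
        spec = self.make_grand([34 * m for m in range(1, 7)])
        assert select_harmonic_range(spec, F_ODD, 8, f_base=4.0) == \
            [1, 2, 3, 4, 5, 6]

    def test_nine_base_harmonics(self):
        spec = self.make_grand([238 * m for m in range(1, 10)])
        assert select_harmonic_range(spec, 4.0, 9) == list(range(1, 10))

    def test_interior_dip_does_not_break_range(self):
        spec = self.make_grand([34 * m for m in (1, 2, 4, 5, 6)])
        assert select_harmonic_range(spec, F_ODD, 6, f_base=4.0) == \
            [1, 2, 3, 4, 5, 6]

    def test_base_coincident_multiple_skipped(self):
        spec = self.make_grand([34 * m for m in range(1, 9) if m != 7])
        got = select_harmonic_range(spec, F_ODD, 8, f_base=4.0)
        assert got == [1, 2, 3, 4, 5, 6, 8]

    def test_pure_noise_gives_empty_set(self):
        spec = self.make_grand([])
        assert select_harmonic_range(spec, F_ODD, 6, f_base=4.0) == []


class TestQuantificationHelpers:
    def test_integration_fraction_arithmetic(self):
        assert integration_fraction(1.0, 0.6, 0.4) == pytest.approx(0.0)
        assert integration_fraction(1.0, 0.40, 0.28) == pytest.approx(32.0)
        assert integration_fraction(1.0, 0.5, 0.3) == pytest.approx(20.0)
        assert integration_fraction(1.0, 0.8, 0.4) == pytest.approx(-20.0)
        with pytest.raises(ValueError):
            integration_fraction(0.0, 0.1, 0.1)

    def test_pure_contact_fraction(self):
        assert pure_contact_fraction(3, 26) == pytest.approx(11.538, abs=1e-3)
        assert round(pure_contact_fraction(3, 26), 1) == 11.5
        with pytest.raises(ValueError):
            pure_contact_fraction(4, 3)

    def test_roi_quantify_mean_over_channels(self):
        amps = np.ones((3, 400))
        for m in range(1, 7):
            amps[0, 34 * m] += 1.0
            amps[1, 34 * m] += 2.0
            amps[2, 34 * m] += 3.0
        spec = make_spectrum(amps, labels=["a", "b", "c"])
        bc = baseline_correct(spec, SEEG_BASELINE)
        val = stats.roi_quantify(bc, ["a", "b", "c"], F_ODD, range(1, 7),
                                 f_base=4.0)
        assert val == pytest.approx(12.0)  # mean of 6, 12, 18
        with pytest.raises(KeyError):
            stats.roi_quantify(bc, ["nope"], F_ODD, range(1, 7))
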