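"""Integer-cycle cropping, time-domain averaging and amplitude spectra.

The whole detection machinery assumes that the tagged frequencies fall
on exact FFT bins.  This is guaranteed by cropping each epoch to an
integer number of oddball cycles: a crop of ``n`` cycles of frequency
``f`` has ``f`` at bin index exactly ``n``, and the base rate (7 f) at
bin ``7 n``.  Spectra are single-sided and calibrated as ``2 |X_b| / N``
so a unit-amplitude sinusoid at an exact bin reads 1 μV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import Epoch


@dataclass
class AmplitudeSpectrum:
    """Per-channel single-sided FFT amplitude spectrum.

    ``amps[c, b]`` is the amplitude in μV of channel ``c`` at frequency
    ``b * df``.  ``signed`` marks derived spectra (baseline-corrected or
    condition differences) whose values may be negative.
    """

    amps: np.ndarray  # channels x bins
    df: float
    n_time_samples: int
    labels: list[str]
    normalization: str = "2/N single-sided"
    signed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.amps = np.atleast_2d(np.asarray(self.amps, dtype=float))

    @property
    def n_bins(self) -> int:
        return self.amps.shape[1]

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.df

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None


def crop_integer_cycles(epoch: Epoch, f_target: float, t_start: float = 2.0,
                        available_duration: float | None = None) -> Epoch:
    """Crop an epoch to an integer number of ``f_target`` cycles.

    The crop starts ``t_start`` seconds after the stimulation onset
    (skipping the 2-s fade-in) and keeps ``floor(available * f_target)``
    full cycles.  ``available_duration`` defaults to the span from
    ``t_start`` to the start of the fade-out: the standard -2..66 s
    epoch has 2 s of post-stimulation margin plus a 2-s fade-out, so
    the default is ``epoch_end - t_start - 4``, i.e. 60 s for the
    standard design, giving 34 cycles = 59.5 s of a 0.571-Hz oddball.
    """
    if available_duration is None:
        available_duration = (epoch.t0 + epoch.duration) - t_start - 4.0
    n_cycles = int(np.floor(available_duration * f_target + 1e-9))
    if n_cycles < 1:
        raise ValueError("epoch does not cover one full target cycle")
    crop_duration = n_cycles / f_target
    start = int(round((t_start - epoch.t0) * epoch.fs))
    n_samples = int(round(crop_duration * epoch.fs))
    if start < 0 or start + n_samples > epoch.n_samples:
        raise ValueError("crop window exceeds epoch bounds")
    # the crop must make f_target an exact bin: f_target / df = n_cycles
    df = epoch.fs / n_samples
    if abs(f_target / df - n_cycles) > 1e-6:
        raise ValueError(
            f"crop of {n_samples} samples at fs={epoch.fs} does not place "
            f"{f_target} Hz on an exact bin")
    meta = dict(epoch.meta)
    meta.update(n_cycles=n_cycles, f_target=f_target, t_start=t_start)
    return replace(epoch, data=epoch.data[:, start:start + n_samples].copy(),
                   t0=t_start, meta=meta)


def average_epochs(epochs: list[Epoch]) -> Epoch:
    """Per-sample arithmetic mean of same-shape epochs (SNR improvement)."""
    if not epochs:
        raise ValueError("no epochs to average")
    first = epochs[0]
    for e in epochs[1:]:
        if e.data.shape != first.data.shape or e.fs != first.fs \
                or e.labels != first.labels:
            raise ValueError("epochs differ in shape, rate or channels")
    data = np.mean([e.data for e in epochs], axis=0)
    meta = dict(first.meta)
    meta["n_averaged"] = len(epochs)
    return replace(first, data=data, meta=meta)


def amplitude_spectrum(epoch: Epoch) -> AmplitudeSpectrum:
    """Single-sided FFT amplitude spectrum, ``2 |X_b| / N`` for b > 0."""
    data = np.asarray(epoch.data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("epoch contains non-finite samples")
    n = data.shape[1]
    spec = np.abs(np.fft.rfft(data, axis=1))
    spec *= 2.0 / n
    spec[:, 0] /= 2.0  # DC is not doubled
    if n % 2 == 0:
        spec[:, -1] /= 2.0  # Nyquist bin is not doubled either
    return AmplitudeSpectrum(amps=spec, df=epoch.fs / n, n_time_samples=n,
                             labels=list(epoch.labels), meta=dict(epoch.meta))


def freq_to_bin(spec: AmplitudeSpectrum, f: float,
                require_exact: bool = False) -> int:
    """Map a frequency to its (nearest) bin index.

    With ``require_exact`` the frequency must coincide with the bin grid
    to within ``df * 1e-6``; tagged frequencies on integer-cycle crops
    always do.
    """
    nyquist = (spec.n_bins - 1) * spec.df
    if not 0 <= f <= nyquist + spec.df * 1e-6:
        raise ValueError(f"frequency {f} Hz outside spectrum (0-{nyquist:.3f} Hz)")
    b = int(round(f / spec.df))
    if require_exact and abs(f - b * spec.df) > spec.df * 1e-6:
        raise ValueError(f"{f} Hz is not an exact bin (df={spec.df} Hz)")
    return b
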