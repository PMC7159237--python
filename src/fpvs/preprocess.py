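"""Scalp-EEG preprocessing chain and SEEG minimal path.

The scalp chain mirrors standard frequency-tagging practice: DC block
alignment across inter-trial pauses, 0.1-100 Hz fourth-order zero-phase
Butterworth band-pass, multi-notch at the line frequency and its
harmonics, downsampling to 256 Hz, epoching from -2 s to +66 s around
each sequence-onset trigger, blink-rate screening with a regression-based
ocular correction, neighbor interpolation of bad channels, and common
average re-reference.

The SEEG path applies no filtering at all: sequences are only segmented
at the native 512 Hz sampling rate.

All operations are deterministic; each returns a new object and appends
a human-readable entry to the ``history`` list of the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal


@dataclass
class Recording:
    """Multichannel time series in microvolts.

    ``events`` is an ordered list of ``(sample_index, code)`` pairs;
    sequence onsets (fade-in start) use code ``"seq"`` by convention.
    ``montage`` optionally maps channel name -> list of neighbor names.
    """

    data: np.ndarray  # channels x samples, μV
    fs: float
    labels: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)
    montage: dict[str, list[str]] | None = None
    rois: dict[str, list[str]] | None = None
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must match channel count")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        last = -1
        for s, _ in self.events:
            if not 0 <= s < self.data.shape[1]:
                raise ValueError(f"event sample {s} out of range")
            if s <= last:
                raise ValueError("event samples must be strictly increasing")
            last = s

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None

    def copy_with(self, data: np.ndarray, note: str, **kw) -> "Recording":
        return replace(self, data=data, history=self.history + [note], **kw)


@dataclass
class Epoch:
    """A fixed window of a recording around one sequence onset.

    ``t0`` is the time of the first sample relative to the trigger
    (-2 s for raw epochs).
    """

    data: np.ndarray  # channels x samples, μV
    fs: float
    labels: list[str]
    t0: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None


def align_blocks(rec: Recording, block_boundaries: Sequence[int]) -> Recording:
    """Remove inter-block DC jumps by chaining blocks to the first.

    Each block (starting at a boundary sample) is offset by a per-channel
    constant so that its first sample equals the last sample of the
    preceding block.  An empty boundary list returns the input unchanged.
    """
    if len(block_boundaries) == 0:
        return rec
    bounds = sorted(int(b) for b in block_boundaries)
    if bounds[0] <= 0 or bounds[-1] >= rec.n_samples:
        raise ValueError("block boundaries must lie strictly inside the recording")
    data = rec.data.copy()
    for b in bounds:
        offset = data[:, b] - data[:, b - 1]
        data[:, b:] -= offset[:, None]
    return rec.copy_with(data, f"align_blocks(boundaries={bounds})")


def bandpass(rec: Recording, low: float = 0.1, high: float = 100.0,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward ``sosfiltfilt``).

    ``order`` is the design order of the underlying filter; the
    forward-backward pass squares its magnitude response and cancels the
    group delay.
    """
    if not 0 < low < high < rec.fs / 2:
        raise ValueError(f"invalid band ({low}, {high}) Hz at fs={rec.fs}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs,
                        output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data, f"bandpass({low}-{high} Hz, order={order}, zero-phase)")


def notch_multi(rec: Recording, line: float = 50.0, n_harmonics: int = 4,
                width: float = 0.5, order: int = 4) -> Recording:
    """Zero-phase band-stop at the line frequency and its harmonics.

    ``n_harmonics`` counts the notched frequencies inclusive of the
    fundamental: the default removes 50, 100, 150 and 200 Hz with
    0.5-Hz-wide stop bands.
    """
    freqs = [line * (k + 1) for k in range(n_harmonics)]
    if freqs and freqs[-1] >= rec.fs / 2:
        raise ValueError(f"notch at {freqs[-1]} Hz is above Nyquist ({rec.fs / 2})")
    data = rec.data
    for f0 in freqs:
        sos = signal.butter(order, [f0 - width / 2, f0 + width / 2],
                            btype="bandstop", fs=rec.fs, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=1)
    return rec.copy_with(data, f"notch_multi({freqs} Hz, width={width})")


def resample_to(rec: Recording, target_fs: float = 256.0) -> Recording:
    """Anti-aliased polyphase resampling; event indices rescale with it.

    Only downsampling is supported.  Event sample indices are multiplied
    by the rate ratio and rounded to the nearest sample (half up).
    """
    if target_fs > rec.fs:
        raise ValueError("upsampling is not supported")
    if target_fs == rec.fs:
        return rec
    from fractions import Fraction
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(rec.data, up, down, axis=1)
    ratio = target_fs / rec.fs
    events = [(int(np.floor(s * ratio + 0.5)), code) for s, code in rec.events]
    return replace(rec, data=data, fs=target_fs, events=events,
                   history=rec.history + [f"resample_to({target_fs} Hz)"])


def segment_epochs(rec: Recording, code: str = "seq", t_min: float = -2.0,
                   t_max: float = 66.0) -> list[Epoch]:
    """Cut one epoch per trigger of the given code.

    Triggers too close to the recording edge are skipped with a warning
    rather than producing short epochs.
    """
    n_pre = int(round(-t_min * rec.fs))
    n_tot = int(round((t_max - t_min) * rec.fs))
    epochs = []
    for s, c in rec.events:
        if c != code:
            continue
        start = s - n_pre
        if start < 0 or start + n_tot > rec.n_samples:
            warnings.warn(f"trigger at sample {s} too close to edge; epoch skipped")
            continue
        epochs.append(Epoch(
            data=rec.data[:, start:start + n_tot].copy(),
            fs=rec.fs, labels=list(rec.labels), t0=t_min,
            meta={"trigger_sample": s, "rois": rec.rois, "montage": rec.montage},
        ))
    return epochs


def blink_rate(epoch: Epoch, eog_channels: Sequence[str],
               threshold_rate: float = 0.15, amp_threshold: float = 100.0,
               refractory: float = 0.2) -> tuple[float, bool]:
    """Count blinks on the vertical EOG difference and flag busy epochs.

    A blink is an excursion of ``|upper - lower|`` (or the single EOG
    channel, if only one is given) beyond ``amp_threshold`` μV, with
    excursions closer than ``refractory`` seconds merged into one.
    Returns ``(blinks_per_second, rate > threshold_rate)``.
    """
    if len(eog_channels) == 0:
        raise ValueError("no EOG channels given")
    idx = [epoch.channel_index(ch) for ch in eog_channels]
    if len(idx) >= 2:
        veog = epoch.data[idx[0]] - epoch.data[idx[1]]
    else:
        veog = epoch.data[idx[0]]
    above = np.abs(veog) > amp_threshold
    # rising edges, separated by at least the refractory period
    edges = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        edges = np.concatenate([[0], edges])
    n_refr = int(round(refractory * epoch.fs))
    count, last = 0, -10 ** 9
    for e in edges:
        if e - last >= n_refr:
            count += 1
            last = e
    rate = count / epoch.duration
    return rate, rate > threshold_rate


def regress_out_eog(epoch: Epoch, eog_channels: Sequence[str]) -> Epoch:
    """Least-squares removal of ocular activity from every EEG channel.

    Each non-EOG channel is replaced by its residual after projection
    onto the span of the (demeaned) EOG channels plus an intercept.  The
    EOG channels themselves are left untouched.  This is a deterministic
    stand-in for component-based ocular correction.
    """
    eog_idx = [epoch.channel_index(ch) for ch in eog_channels]
    eog = epoch.data[eog_idx].T  # samples x n_eog
    design = np.column_stack([np.ones(len(eog)), eog - eog.mean(axis=0)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("EOG regressors are rank-deficient")
    data = epoch.data.copy()
    eeg_idx = [i for i in range(data.shape[0]) if i not in eog_idx]
    y = data[eeg_idx].T
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    data[eeg_idx] = (y - design @ beta).T
    return replace(epoch, data=data)


def interpolate_channels(epoch: Epoch, bad: Sequence[str],
                         neighbors: Mapping[str, Sequence[str]],
                         max_bad_fraction: float = 0.05) -> Epoch:
    """Replace bad channels by the unweighted mean of 3-6 good neighbors."""
    if len(bad) == 0:
        return epoch
    if len(bad) / len(epoch.labels) > max_bad_fraction:
        raise ValueError(
            f"{len(bad)} of {len(epoch.labels)} channels bad "
            f"(> {max_bad_fraction:.0%}); refusing to interpolate")
    data = epoch.data.copy()
    bad_set = set(bad)
    for ch in bad:
        nb = list(neighbors.get(ch, []))
        if not 3 <= len(nb) <= 6:
            raise ValueError(f"channel {ch!r} needs 3-6 neighbors, has {len(nb)}")
        if bad_set.intersection(nb):
            raise ValueError(f"channel {ch!r} has bad neighbors")
        nb_idx = [epoch.channel_index(n) for n in nb]
        data[epoch.channel_index(ch)] = data[nb_idx].mean(axis=0)
    return replace(epoch, data=data)


def rereference_common_average(epoch: Epoch,
                               exclude: Sequence[str] = ()) -> Epoch:
    """Common average reference over all channels not in ``exclude``.

    With fewer than two included channels (the single-contact SEEG case
    with everything excluded) the epoch is returned unchanged.
    """
    incl = [i for i, ch in enumerate(epoch.labels) if ch not in exclude]
    if len(incl) < 2:
        return epoch
    data = epoch.data.copy()
    data[incl] -= data[incl].mean(axis=0, keepdims=True)
    return replace(epoch, data=data)
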