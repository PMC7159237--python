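"""Synthetic EEG/SEEG sessions with known steady-state ground truth.

The simulator embodies the statistical structure the analysis assumes:
a periodic response is a sum of sinusoids at harmonics of the base rate
(k * 4 Hz, general visual synchronization) and of the identity-oddball
rate (m * 4/7 Hz, identity discrimination).  The oddball amplitude per
condition follows the composition hypothesis

    A_FN(m) = face(m) + name(m) + cross(m)
    A_FO(m) = face(m)
    A_NO(m) = name(m)

so ``cross`` is exactly the super-additive (integrative) component:
FN - FO - NO equals the cross signal sample by sample.  The oddball
response is modeled directly as sinusoids at the tagged harmonics, not
as a time-domain transient train; the downstream statistics read
amplitude spectra only, for which this is equivalent.

Background activity is 1/f-shaped ("pink") noise plus a white floor,
with optional 50-Hz line noise, biphasic blink transients on EOG-like
channels, and per-block DC jumps - the artifacts the preprocessing
chain is designed to remove.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .paradigm import CONDITIONS, Condition, ScheduleParams, StimulationSchedule, build_schedule
from .preprocess import Recording

#: Default scalp montage: occipito-temporal ROI electrodes of both
#: experiments, the midline occipital set, a few frontal sites and two
#: vertical EOG electrodes.
DEFAULT_SCALP_LABELS = [
    "P9", "PO9", "PO11", "POI1", "I1",      # left occipito-temporal
    "P10", "PO10", "PO12", "POI2", "I2",    # right occipito-temporal
    "Oz", "OIz", "Iz",                      # midline occipital
    "Fz", "F5", "F6",                       # frontal (blink leakage)
    "VEOGU", "VEOGL",                       # vertical EOG pair
]
EOG_LABELS = ["VEOGU", "VEOGL"]
FRONTAL_LABELS = ["Fz", "F5", "F6"]

#: Default source topographies over DEFAULT_SCALP_LABELS (EOG rows are
#: never driven).  Gains are zero-mean across the 16 EEG channels, i.e.
#: the projection is expressed in the common-average frame (a dipolar
#: source's far field returns with opposite polarity), so the common
#: average reference leaves the noiseless signal unchanged.  The
#: oddball topography peaks over the occipito-temporal ROIs; the
#: base-rate topography peaks over the midline occipital sites.
DEFAULT_ODDBALL_GAINS = np.array(
    [1.0] * 10 + [-1.0] * 3 + [-7.0 / 3] * 3 + [0.0, 0.0])
DEFAULT_BASE_GAINS = np.array(
    [0.5] * 10 + [1.0] * 3 + [-8.0 / 3] * 3 + [0.0, 0.0])

#: Minimal neighbor map (3 neighbors each) for interpolation tests.
DEFAULT_NEIGHBORS = {
    "P9": ["PO9", "PO11", "POI1"],
    "PO9": ["P9", "PO11", "I1"],
    "PO11": ["P9", "PO9", "POI1"],
    "P10": ["PO10", "PO12", "POI2"],
    "PO10": ["P10", "PO12", "I2"],
    "PO12": ["P10", "PO10", "POI2"],
    "Oz": ["OIz", "Iz", "POI1"],
    "OIz": ["Oz", "Iz", "POI2"],
    "Iz": ["Oz", "OIz", "I1"],
}


@dataclass(frozen=True)
class ResponseSpec:
    """Per-channel amplitudes (μV) of the modeled periodic components.

    ``base_amps`` has shape (n_channels, K_base): amplitude at harmonic
    k * base_freq.  ``face_amps``, ``name_amps`` and ``cross_amps`` have
    shape (n_channels, K_odd): amplitude at harmonic m * oddball_freq.
    Phases default to zero; the analysis reads amplitude spectra, which
    are phase-invariant.
    """

    base_amps: np.ndarray
    face_amps: np.ndarray
    name_amps: np.ndarray
    cross_amps: np.ndarray
    base_phases: np.ndarray | None = None
    odd_phases: np.ndarray | None = None
    base_signs: np.ndarray | None = None  # per-channel polarity (+-1)
    odd_signs: np.ndarray | None = None
    oddball_period: int = 7

    def __post_init__(self) -> None:
        for name in ("base_amps", "face_amps", "name_amps", "cross_amps"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            object.__setattr__(self, name, arr)
        if self.face_amps.shape != self.name_amps.shape or \
                self.face_amps.shape != self.cross_amps.shape:
            raise ValueError("oddball amplitude arrays must share a shape")
        if self.base_amps.shape[0] != self.face_amps.shape[0]:
            raise ValueError("channel counts differ between base and oddball amps")
        if self.k_odd >= self.oddball_period * self.k_base:
            raise ValueError(
                "K_odd must stay below oddball_period * K_base so oddball "
                "harmonics remain inside the modeled base range")

    @property
    def n_channels(self) -> int:
        return self.base_amps.shape[0]

    @property
    def k_base(self) -> int:
        return self.base_amps.shape[1]

    @property
    def k_odd(self) -> int:
        return self.face_amps.shape[1]

    def oddball_amps(self, condition: Condition) -> np.ndarray:
        if condition == "FN":
            return self.face_amps + self.name_amps + self.cross_amps
        if condition == "FO":
            return self.face_amps
        if condition == "NO":
            return self.name_amps
        raise ValueError(f"unknown condition {condition!r}")

    @classmethod
    def from_totals(cls, n_channels: int, base_total: float = 2.5,
                    face_total: float = 0.38, name_total: float = 0.30,
                    cross_total: float = 0.32, k_base: int = 9,
                    k_odd: int = 6,
                    channel_gains: np.ndarray | None = None,
                    base_gains: np.ndarray | None = None,
                    oddball_period: int = 7) -> "ResponseSpec":
        """Spread per-condition totals equally over harmonics.

        ``channel_gains`` scales the oddball components per channel and
        ``base_gains`` the base-rate components (both length
        n_channels, default 1).  Amplitudes are clipped at zero, so a
        negative gain (opposite-polarity far field) contributes |gain|
        to the amplitude spectrum, as it would physically.  Totals are
        in μV summed over the harmonics of a unit-gain channel.  The
        defaults place the integrative component at 32% of the FN total
        (0.38 + 0.30 + 0.32 = 1.0 μV), matching a strongly integrative
        occipito-temporal site.
        """
        def gains(g):
            if g is None:
                return np.ones(n_channels)
            g = np.abs(np.asarray(g, dtype=float))
            if g.shape != (n_channels,):
                raise ValueError("gains must have length n_channels")
            return g
        def signs(g):
            if g is None:
                return None
            return np.where(np.asarray(g, dtype=float) < 0, -1.0, 1.0)
        g_odd, g_base = gains(channel_gains), gains(base_gains)
        def spread(g, total, k):
            return np.outer(g, np.full(k, total / k))
        return cls(base_amps=spread(g_base, base_total, k_base),
                   face_amps=spread(g_odd, face_total, k_odd),
                   name_amps=spread(g_odd, name_total, k_odd),
                   cross_amps=spread(g_odd, cross_total, k_odd),
                   base_signs=signs(base_gains), odd_signs=signs(channel_gains),
                   oddball_period=oddball_period)


@dataclass(frozen=True)
class NoiseSpec:
    """Background-noise and artifact parameters.

    ``pink_scale`` sets the mean of the 1/f amplitude spectrum at 1 Hz
    (μV per bin); the shape is f**(-pink_exponent).  ``white_scale`` is
    the per-sample SD (μV) of the white floor.  ``blink_rate`` > 0 adds
    biphasic blink transients to EOG channels (with fractional leakage
    to frontal channels); ``block_dc_jump`` adds a random constant
    offset of that magnitude to each stimulation block.
    """

    pink_exponent: float = 1.0
    pink_scale: float = 0.15
    white_scale: float = 10.0
    line_freq: float = 50.0
    line_amp: float = 2.0
    blink_rate: float = 0.05
    blink_amp: float = 200.0
    blink_leakage: float = 0.1
    block_dc_jump: float = 20.0

    def __post_init__(self) -> None:
        if min(self.pink_scale, self.white_scale, self.line_amp,
               self.blink_rate, self.block_dc_jump) < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0 <= self.pink_exponent <= 2:
            raise ValueError("pink_exponent must lie in [0, 2]")

    def scaled(self, g: float) -> "NoiseSpec":
        """All noise/artifact magnitudes scaled by ``g``.

        ``scaled(1/sqrt(n))`` emulates the grand average of ``n``
        independent subjects: the periodic response is coherent across
        subjects under the model while noise and artifacts average down
        as 1/sqrt(n).
        """
        return dataclasses.replace(
            self, pink_scale=g * self.pink_scale,
            white_scale=g * self.white_scale, line_amp=g * self.line_amp,
            blink_amp=g * self.blink_amp,
            block_dc_jump=g * self.block_dc_jump)


#: Quiet noise spec: background only, no line/artifacts.
QUIET_NOISE = NoiseSpec(line_amp=0.0, blink_rate=0.0, block_dc_jump=0.0)
#: No noise at all (for noiseless end-to-end oracles).
NO_NOISE = NoiseSpec(pink_scale=0.0, white_scale=0.0, line_amp=0.0,
                     blink_rate=0.0, block_dc_jump=0.0)


@dataclass
class SessionSim:
    """A simulated session and the ground truth that generated it."""

    recording: Recording
    schedules: list[StimulationSchedule]
    response: ResponseSpec
    noise: NoiseSpec
    seed: int
    block_boundaries: list[int] = field(default_factory=list)
    condition_order: list[str] = field(default_factory=list)
    truth_label: str | None = None

    def injected_oddball_total(self, condition: Condition,
                               harmonics: Sequence[int] = (1, 2, 3, 4, 5, 6),
                               channel: int = 0) -> float:
        """Sum of injected oddball amplitudes over the given harmonics (μV)."""
        amps = self.response.oddball_amps(condition)[channel]
        return float(sum(amps[m - 1] for m in harmonics))


def _fade_envelope(n: int, fs: float, fade: float) -> np.ndarray:
    env = np.ones(n)
    n_fade = int(round(fade * fs))
    if n_fade > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_fade) / n_fade))
        env[:n_fade] = ramp
        env[-n_fade:] = ramp[::-1]
    return env


def synth_steady_response(schedule: StimulationSchedule, spec: ResponseSpec,
                          fs: float, include_fades: bool = True) -> np.ndarray:
    """Noiseless multichannel steady-state signal for one sequence.

    Returns an (n_channels, n_samples) array covering fade-in +
    stimulation + fade-out when ``include_fades`` (64 s by default),
    or the full-contrast span alone otherwise.  The contrast fades
    are applied as a raised-cosine envelope on the whole response.
    """
    p = schedule.params
    f_base = p.base_freq
    f_odd = p.oddball_freq
    k_max = max(spec.k_base * f_base, spec.k_odd * f_odd)
    if fs <= 2 * k_max:
        raise ValueError(
            f"fs={fs} Hz cannot represent the highest modeled harmonic "
            f"({k_max} Hz)")
    fade = p.fade_duration if include_fades else 0.0
    duration = p.seq_duration + 2 * fade
    n = int(round(duration * fs))
    t = np.arange(n) / fs - fade  # 0 at full-contrast start
    odd = spec.oddball_amps(schedule.condition)
    s_base = np.ones(spec.n_channels) if spec.base_signs is None \
        else np.asarray(spec.base_signs, dtype=float)
    s_odd = np.ones(spec.n_channels) if spec.odd_signs is None \
        else np.asarray(spec.odd_signs, dtype=float)
    out = np.zeros((spec.n_channels, n))
    for k in range(spec.k_base):
        phi = 0.0 if spec.base_phases is None else float(spec.base_phases[k])
        carrier = np.sin(2 * np.pi * (k + 1) * f_base * t + phi)
        out += (s_base * spec.base_amps[:, k])[:, None] * carrier
    for m in range(spec.k_odd):
        phi = 0.0 if spec.odd_phases is None else float(spec.odd_phases[m])
        carrier = np.sin(2 * np.pi * (m + 1) * f_odd * t + phi)
        out += (s_odd * odd[:, m])[:, None] * carrier
    if include_fades:
        out *= _fade_envelope(n, fs, p.fade_duration)
    return out


def synth_noise(n_channels: int, duration: float, fs: float, spec: NoiseSpec,
                seed: int) -> np.ndarray:
    """Stationary background noise: 1/f-shaped plus white floor plus line.

    The pink component is spectrally shaped white noise calibrated so
    that, measured over a 60-s analysis window, the mean single-sided
    amplitude spectrum equals ``pink_scale * f**(-pink_exponent)`` μV
    per bin (the shape is held flat below 0.1 Hz to avoid a DC
    blow-up); per-bin noise amplitude scales as 1/sqrt(window length),
    so the reference window makes the level independent of the session
    duration.  The white component has per-sample SD ``white_scale``.
    Fully reproducible from ``seed``.
    """
    n = duration * fs
    if abs(n - round(n)) > 1e-9:
        raise ValueError("duration x fs must be an integer sample count")
    n = int(round(n))
    rng = np.random.default_rng(seed)
    out = np.zeros((n_channels, n))
    if spec.white_scale > 0:
        out += rng.normal(0.0, spec.white_scale, size=(n_channels, n))
    if spec.pink_scale > 0:
        freqs = np.fft.rfftfreq(n, d=1 / fs)
        shape = np.maximum(freqs, 0.1) ** (-spec.pink_exponent)
        shape[0] = 0.0
        white = rng.normal(0.0, 1.0, size=(n_channels, n))
        x = np.fft.rfft(white, axis=1) * shape
        pink = np.fft.irfft(x, n=n, axis=1)
        # unit white input yields E[2|X|/n] = sqrt(pi / n) * shape(f);
        # calibrate against the 60-s reference window
        n_ref = int(round(60.0 * fs))
        calib = spec.pink_scale / np.sqrt(np.pi / n_ref)
        out += calib * pink
    if spec.line_amp > 0 and spec.line_freq < fs / 2:
        t = np.arange(n) / fs
        phases = rng.uniform(0, 2 * np.pi, size=n_channels)
        out += spec.line_amp * np.sin(
            2 * np.pi * spec.line_freq * t[None, :] + phases[:, None])
    return out


def blink_template(fs: float, amp: float = 200.0) -> np.ndarray:
    """Biphasic ~400-ms blink waveform (positive lobe then undershoot)."""
    t = np.arange(int(round(0.4 * fs))) / fs
    main = amp * np.exp(-0.5 * ((t - 0.12) / 0.04) ** 2)
    under = -0.3 * amp * np.exp(-0.5 * ((t - 0.24) / 0.07) ** 2)
    return main + under


def _inject_blinks(data: np.ndarray, labels: list[str], fs: float,
                   spec: NoiseSpec, rng: np.random.Generator) -> None:
    """Add blink transients in place to EOG (and, attenuated, frontal) rows."""
    if spec.blink_rate <= 0:
        return
    n = data.shape[1]
    tmpl = blink_template(fs, spec.blink_amp)
    n_blinks = rng.poisson(spec.blink_rate * n / fs)
    idx_up = labels.index("VEOGU") if "VEOGU" in labels else None
    idx_lo = labels.index("VEOGL") if "VEOGL" in labels else None
    frontal = [labels.index(ch) for ch in FRONTAL_LABELS if ch in labels]
    starts = rng.integers(0, max(1, n - len(tmpl)), size=n_blinks)
    for s in starts:
        sl = slice(s, s + len(tmpl))
        if idx_up is not None:
            data[idx_up, sl] += tmpl
        if idx_lo is not None:
            data[idx_lo, sl] -= 0.6 * tmpl
        for fi in frontal:
            data[fi, sl] += spec.blink_leakage * tmpl


def simulate_session(params: ScheduleParams, spec: ResponseSpec,
                     noise: NoiseSpec = NoiseSpec(),
                     conditions: Sequence[Condition] = CONDITIONS,
                     n_sequences_per_condition: int = 2,
                     seed: int = 0,
                     fs: float = 512.0,
                     labels: Sequence[str] | None = None,
                     rest_duration: float = 3.0) -> SessionSim:
    """Simulate a full recording session with onset triggers.

    The recording concatenates, per sequence, a rest gap followed by
    fade-in + stimulation + fade-out.  One trigger marks each
    stimulation (fade-in) start with code ``"seq/<condition>"``.
    Conditions are interleaved in a seeded random order.  Blink
    transients and per-block DC jumps are injected as configured.
    """
    if labels is None:
        labels = list(DEFAULT_SCALP_LABELS) if spec.n_channels > 1 else ["SEEG1"]
    labels = list(labels)
    if len(labels) != spec.n_channels:
        raise ValueError("label count must match ResponseSpec channels")
    rng = np.random.default_rng(seed)
    order: list[Condition] = []
    for _ in range(n_sequences_per_condition):
        block = list(conditions)
        rng.shuffle(block)
        order.extend(block)

    n_rest = int(round(rest_duration * fs))
    n_seq = int(round((params.seq_duration + 2 * params.fade_duration) * fs))
    n_unit = n_rest + n_seq
    n_total = n_unit * len(order) + n_rest  # trailing rest for epoch margin

    data = synth_noise(spec.n_channels, n_total / fs, fs, noise,
                       seed=int(rng.integers(2 ** 31)))
    _inject_blinks(data, labels, fs, noise, rng)

    schedules, events, boundaries = [], [], []
    resp_rows = [i for i, ch in enumerate(labels) if ch not in EOG_LABELS]
    for j, cond in enumerate(order):
        sched = build_schedule(params, cond, base_identity="base",
                               seed=int(rng.integers(2 ** 31)))
        schedules.append(sched)
        start = j * n_unit
        if j > 0:
            boundaries.append(start)
        if noise.block_dc_jump > 0:
            jump = noise.block_dc_jump * rng.choice([-1.0, 1.0])
            data[:, start:start + n_unit] += jump
        sig = synth_steady_response(sched, spec, fs, include_fades=True)
        stim_start = start + n_rest
        data[resp_rows, stim_start:stim_start + n_seq] += sig[resp_rows]
        events.append((stim_start, f"seq/{cond}"))

    rec = Recording(data=data, fs=fs, labels=labels, events=events,
                    montage=dict(DEFAULT_NEIGHBORS) if len(labels) > 3 else None,
                    history=[f"simulate_session(seed={seed})"])
    return SessionSim(recording=rec, schedules=schedules, response=spec,
                      noise=noise, seed=seed,
                      block_boundaries=boundaries,
                      condition_order=[str(c) for c in order])


#: SEEG contact profiles: per-harmonic oddball amplitudes as a fraction
#: of ``amp``, given as (face, name, cross).  ``nonpure_FN`` models
#: sub-threshold unimodal responses whose sum drives a (possibly)
#: detectable FN response with no super-additive component; its label
#: under the classifier is intrinsically stochastic near threshold.
SEEG_PROFILES = {
    "pure_FN": (0.0, 0.0, 1.0),
    "nonpure_FN": (0.12, 0.12, 0.0),
    "unimodal_face": (1.0, 0.0, 0.0),
    "unimodal_name": (0.0, 1.0, 0.0),
    "mixed": (0.5, 0.5, 0.0),
    "null": (0.0, 0.0, 0.0),
}

#: Expected classifier label per profile.  A strong unimodal face
#: response is significant in FN as well (the FN sequence carries the
#: same face periodicity), hence "FN_and_face"; mirror for names.
SEEG_EXPECTED_LABEL = {
    "pure_FN": "pure_FN",
    "nonpure_FN": "nonpure_FN",
    "unimodal_face": "FN_and_face",
    "unimodal_name": "FN_and_name",
    "mixed": "mixed_all",
    "null": "none",
}


def simulate_seeg_contact(profile: str, amp: float,
                          noise: NoiseSpec = QUIET_NOISE,
                          n_sequences_per_condition: int = 2,
                          seed: int = 0,
                          params: ScheduleParams | None = None,
                          k_odd: int = 6, base_amp: float = 0.5) -> SessionSim:
    """Single-contact SEEG session with a known response profile.

    ``amp`` is the per-harmonic oddball amplitude in μV of the profile's
    active component(s); each contact also carries a small base-rate
    response.  Recording is single-channel at 512 Hz with the usual
    sequence structure.
    """
    if profile not in SEEG_PROFILES:
        raise ValueError(f"unknown profile {profile!r}; "
                         f"choose from {sorted(SEEG_PROFILES)}")
    params = params or ScheduleParams()
    face, name, cross = SEEG_PROFILES[profile]
    k_base = 9
    spec = ResponseSpec(
        base_amps=np.full((1, k_base), base_amp / k_base),
        face_amps=np.full((1, k_odd), face * amp),
        name_amps=np.full((1, k_odd), name * amp),
        cross_amps=np.full((1, k_odd), cross * amp),
        oddball_period=params.oddball_period)
    sim = simulate_session(params, spec, noise=noise,
                           n_sequences_per_condition=n_sequences_per_condition,
                           seed=seed, fs=512.0, labels=["SEEG1"])
    sim.truth_label = SEEG_EXPECTED_LABEL[profile]
    return sim
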