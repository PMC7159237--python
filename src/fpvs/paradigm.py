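"""Stimulation schedules for the crossmodal face/name oddball paradigm.

Stimuli (a face picture or a written name) appear at a fixed base rate
(4 Hz by default) with sinusoidal contrast modulation.  Every
``oddball_period`` stimuli (7 by default) a different identity is shown,
so identity changes are tagged at ``base_freq / oddball_period``
(0.571 Hz).  Three conditions manipulate which modality carries the base
identity:

* ``FN`` (Face Name): both faces and names of the base identity.
* ``FO`` (Face Only): base faces kept, base names replaced by other
  famous names.
* ``NO`` (Name Only): base names kept, base faces replaced by other
  famous faces.

Only the event timing and identity bookkeeping are modeled; no images
are rendered.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

Condition = Literal["FN", "FO", "NO"]

CONDITIONS: tuple[Condition, ...] = ("FN", "FO", "NO")


class ConfigurationError(ValueError):
    """Invalid paradigm configuration (non-integer event count, empty pools...)."""


@dataclass(frozen=True)
class ScheduleParams:
    """Timing and pool-size parameters of one stimulation sequence.

    Defaults reproduce the standard design: 60 s of 4-Hz stimulation
    (240 stimuli), identity oddballs every 7th stimulus (0.571 Hz),
    2-s contrast fades at both ends, 18 exemplars per base-identity
    pool, 36 distinct oddball identities, and 5 equidistant size steps
    between 80% and 120%.
    """

    base_freq: float = 4.0
    oddball_period: int = 7
    seq_duration: float = 60.0
    fade_duration: float = 2.0
    n_face_exemplars: int = 18
    n_name_exemplars: int = 18
    n_oddball_identities: int = 36
    size_steps: int = 5
    size_min: float = 0.8
    size_max: float = 1.2
    oddball_phase: int = 0  # extra offset added to the first oddball index

    def __post_init__(self) -> None:
        if self.base_freq <= 0:
            raise ConfigurationError("base_freq must be positive")
        if self.oddball_period < 2:
            raise ConfigurationError("oddball_period must be >= 2")
        n = self.seq_duration * self.base_freq
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"seq_duration x base_freq must be a positive integer, got {n}"
            )
        if not self.size_min < self.size_max:
            raise ConfigurationError("size_min must be < size_max")
        if min(self.n_face_exemplars, self.n_name_exemplars,
               self.n_oddball_identities) < 1:
            raise ConfigurationError("stimulus pools must be non-empty")

    @property
    def n_events(self) -> int:
        return int(round(self.seq_duration * self.base_freq))

    @property
    def oddball_freq(self) -> float:
        """Identity-change rate in Hz (base_freq / oddball_period)."""
        return self.base_freq / self.oddball_period

    @property
    def cycle_duration(self) -> float:
        """Stimulus onset asynchrony in seconds (1 / base_freq)."""
        return 1.0 / self.base_freq

    @property
    def size_grid(self) -> np.ndarray:
        return np.linspace(self.size_min, self.size_max, self.size_steps)


@dataclass(frozen=True)
class StimulusEvent:
    index: int
    onset: float
    modality: Literal["face", "name"]
    identity: str
    exemplar: str
    is_oddball: bool
    size_scale: float


@dataclass(frozen=True)
class StimulationSchedule:
    params: ScheduleParams
    condition: Condition
    base_identity: str
    events: tuple[StimulusEvent, ...] = field(default_factory=tuple)

    @property
    def oddball_indices(self) -> np.ndarray:
        return np.array([e.index for e in self.events if e.is_oddball], dtype=int)


def _is_oddball_index(index: int, params: ScheduleParams) -> bool:
    shifted = index + 1 - params.oddball_phase
    return shifted > 0 and shifted % params.oddball_period == 0


def build_schedule(
    params: ScheduleParams,
    condition: Condition,
    base_identity: str,
    seed: int,
) -> StimulationSchedule:
    """Generate a seeded stimulation schedule for one sequence.

    Every draw (slot modality, exemplar, oddball identity, size step) is
    taken from a ``numpy`` generator seeded with ``seed``, so equal seeds
    give identical schedules.  Oddball positions are deterministic:
    indices ``oddball_period - 1, 2*oddball_period - 1, ...`` (optionally
    shifted by ``params.oddball_phase``).

    Identity placement per condition:

    * ``FN``: every non-oddball stimulus carries the base identity.
    * ``FO``: non-oddball faces carry the base identity, non-oddball
      names carry control (non-base) name identities.
    * ``NO``: mirror of ``FO``.

    Oddball stimuli always carry one of ``n_oddball_identities`` control
    identities distinct from the base identity.
    """
    if condition not in CONDITIONS:
        raise ConfigurationError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    grid = params.size_grid
    events = []
    last_exemplar: str | None = None
    for i in range(params.n_events):
        odd = _is_oddball_index(i, params)
        modality = "face" if rng.integers(2) == 0 else "name"
        if odd:
            identity = f"oddball_{rng.integers(params.n_oddball_identities):02d}"
            exemplar = f"{identity}_{modality}"
        else:
            if condition == "FN":
                identity = base_identity
            elif condition == "FO":
                identity = base_identity if modality == "face" else (
                    f"ctrl_name_{rng.integers(params.n_name_exemplars):02d}")
            else:  # NO
                identity = base_identity if modality == "name" else (
                    f"ctrl_face_{rng.integers(params.n_face_exemplars):02d}")
            pool = (params.n_face_exemplars if modality == "face"
                    else params.n_name_exemplars)
            # uniform draw, retrying to forbid immediate exact repetition
            while True:
                exemplar = f"{identity}_{modality}_{rng.integers(pool):02d}"
                if exemplar != last_exemplar:
                    break
        last_exemplar = exemplar
        events.append(StimulusEvent(
            index=i,
            onset=i / params.base_freq,
            modality=modality,
            identity=identity,
            exemplar=exemplar,
            is_oddball=odd,
            size_scale=float(grid[rng.integers(params.size_steps)]),
        ))
    return StimulationSchedule(params=params, condition=condition,
                               base_identity=base_identity,
                               events=tuple(events))


@dataclass
class ScheduleReport:
    n_events: int
    n_oddballs: int
    n_face: int
    n_name: int
    oddball_indices: list[int]
    identity_counts: dict[str, int]
    violations: list[str]

    @property
    def n_violations(self) -> int:
        return len(self.violations)


def schedule_report(schedule: StimulationSchedule) -> ScheduleReport:
    """Summarize a schedule and check every invariant.

    Checks oddball periodicity, onset arithmetic, size-grid membership
    and the per-condition identity placement rules; each violation is
    reported as a human-readable string.
    """
    p = schedule.params
    base = schedule.base_identity
    violations: list[str] = []
    identity_counts: dict[str, int] = {}
    grid = p.size_grid
    for e in schedule.events:
        identity_counts[e.identity] = identity_counts.get(e.identity, 0) + 1
        expected_odd = _is_oddball_index(e.index, p)
        if e.is_oddball != expected_odd:
            violations.append(
                f"event {e.index}: is_oddball={e.is_oddball}, "
                f"periodicity requires {expected_odd}")
        if abs(e.onset - e.index / p.base_freq) > 1e-9:
            violations.append(f"event {e.index}: onset {e.onset} off-grid")
        if not np.any(np.abs(grid - e.size_scale) < 1e-9):
            violations.append(f"event {e.index}: size_scale {e.size_scale} off-grid")
        if e.is_oddball:
            if e.identity == base:
                violations.append(f"event {e.index}: oddball carries base identity")
        else:
            carries_base = e.identity == base
            if schedule.condition == "FN" and not carries_base:
                violations.append(f"event {e.index}: FN base slot lacks base identity")
            elif schedule.condition == "FO":
                if e.modality == "face" and not carries_base:
                    violations.append(f"event {e.index}: FO base face not base identity")
                if e.modality == "name" and carries_base:
                    violations.append(f"event {e.index}: FO base name is base identity")
            elif schedule.condition == "NO":
                if e.modality == "name" and not carries_base:
                    violations.append(f"event {e.index}: NO base name not base identity")
                if e.modality == "face" and carries_base:
                    violations.append(f"event {e.index}: NO base face is base identity")
    return ScheduleReport(
        n_events=len(schedule.events),
        n_oddballs=sum(e.is_oddball for e in schedule.events),
        n_face=sum(e.modality == "face" for e in schedule.events),
        n_name=sum(e.modality == "name" for e in schedule.events),
        oddball_indices=[e.index for e in schedule.events if e.is_oddball],
        identity_counts=identity_counts,
        violations=violations,
    )


_EXPORT_FIELDS = ("index", "onset", "modality", "identity", "exemplar",
                  "is_oddball", "size_scale")


def write_schedule(schedule: StimulationSchedule, path: str | Path) -> None:
    """Export a schedule as a tab-separated table, one event per row."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["# condition", schedule.condition,
                    "base_identity", schedule.base_identity])
        w.writerow(["# params"] + [f"{k}={getattr(schedule.params, k)}"
                                   for k in ScheduleParams.__dataclass_fields__])
        w.writerow(_EXPORT_FIELDS)
        for e in schedule.events:
            w.writerow([e.index, repr(e.onset), e.modality, e.identity,
                        e.exemplar, int(e.is_oddball), repr(e.size_scale)])


def read_schedule(path: str | Path) -> StimulationSchedule:
    """Read back a schedule written by :func:`write_schedule` (lossless)."""
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    condition = rows[0][1]
    base_identity = rows[0][3]
    kwargs = {}
    for item in rows[1][1:]:
        k, v = item.split("=", 1)
        f = ScheduleParams.__dataclass_fields__[k]
        kwargs[k] = f.type and _parse_field(f.name, v)
    params = ScheduleParams(**kwargs)
    events = []
    for row in rows[3:]:
        events.append(StimulusEvent(
            index=int(row[0]), onset=float(row[1]), modality=row[2],
            identity=row[3], exemplar=row[4], is_oddball=bool(int(row[5])),
            size_scale=float(row[6])))
    return StimulationSchedule(params=params, condition=condition,  # type: ignore[arg-type]
                               base_identity=base_identity, events=tuple(events))


def _parse_field(name: str, value: str):
    if name in ("oddball_period", "n_face_exemplars", "n_name_exemplars",
                "n_oddball_identities", "size_steps", "oddball_phase"):
        return int(value)
    return float(value)
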