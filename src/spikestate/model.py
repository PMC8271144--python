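"""Shared domain types for state-resolved spiking analysis.

All times are seconds, intervals half-open ``[start, stop)``. Spike times are
stored as sorted float arrays; waveform snippets in microvolts with an explicit
sampling rate in Hz (30 kHz for the array recordings this package targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recognized behavioral state labels.
#: RS  - rest, eyes open;  RSS - sleepy rest, eyes (half-)closed;
#: M   - spontaneous movement;  PP - preparatory period (task);
#: TM  - task-induced movement; UNCLASSIFIED - unscored behavior.
STATE_LABELS = ("RS", "RSS", "M", "TM", "PP", "UNCLASSIFIED")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass
class SpikeTrain:
    """One unit's sorted spike times within a recording window."""

    unit_id: str
    spike_times: np.ndarray
    t_start: float
    t_stop: float

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.t_stop <= self.t_start:
            raise ValidationError(
                f"unit {self.unit_id}: t_stop ({self.t_stop}) must exceed "
                f"t_start ({self.t_start})"
            )
        if self.spike_times.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: spike_times must be 1-D")
        if np.any(np.diff(self.spike_times) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike times not sorted")
        if self.spike_times.size and (
            self.spike_times[0] < self.t_start or self.spike_times[-1] >= self.t_stop
        ):
            raise ValidationError(
                f"unit {self.unit_id}: spike times outside [t_start, t_stop)"
            )

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def mean_rate(self) -> float:
        """Whole-recording mean firing rate in Hz."""
        return self.n_spikes / self.duration

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return (
            self.unit_id == other.unit_id
            and self.t_start == other.t_start
            and self.t_stop == other.t_stop
            and np.array_equal(self.spike_times, other.spike_times)
        )


@dataclass
class WaveformSet:
    """Per-spike voltage snippets (µV) for one unit.

    ``waveforms`` is an ``n_spikes x n_samples`` matrix; the mean waveform is
    the per-sample arithmetic mean across snippets.
    """

    unit_id: str
    waveforms: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=float))
        if self.waveforms.shape[0] < 1:
            raise ValidationError(f"unit {self.unit_id}: need at least one waveform")
        if self.sampling_rate <= 0:
            raise ValidationError(f"unit {self.unit_id}: sampling_rate must be > 0")

    @property
    def n_spikes(self) -> int:
        return int(self.waveforms.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.waveforms.shape[1])

    @property
    def mean_waveform(self) -> np.ndarray:
        return self.waveforms.mean(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WaveformSet):
            return NotImplemented
        return (
            self.unit_id == other.unit_id
            and self.sampling_rate == other.sampling_rate
            and np.array_equal(self.waveforms, other.waveforms)
        )


@dataclass(frozen=True)
class BehaviorEpoch:
    """A labeled behavioral segment ``[start, stop)`` in seconds."""

    label: str
    start: float
    stop: float

    def __post_init__(self) -> None:
        if self.label not in STATE_LABELS:
            raise ValidationError(f"unknown state label {self.label!r}")
        if self.stop <= self.start:
            raise ValidationError(
                f"epoch {self.label}: stop ({self.stop}) must exceed start ({self.start})"
            )

    @property
    def duration(self) -> float:
        return self.stop - self.start


@dataclass
class SessionRecord:
    """One recording session: spike trains, waveforms, behavioral epochs."""

    session_id: str
    session_type: str  # "REST" or "R2G"
    spike_trains: list[SpikeTrain]
    waveform_sets: dict[str, WaveformSet]
    epochs: list[BehaviorEpoch]

    def __post_init__(self) -> None:
        if self.session_type not in ("REST", "R2G"):
            raise ValidationError(
                f"session_type must be REST or R2G, got {self.session_type!r}"
            )
        # stable unit ordering, lexicographic by unit_id
        self.spike_trains = sorted(self.spike_trains, key=lambda t: t.unit_id)
        ids = [t.unit_id for t in self.spike_trains]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate unit_id in spike_trains")
        for uid in self.waveform_sets:
            if uid not in ids:
                raise ValidationError(
                    f"waveform set for unknown unit {uid!r} (no matching spike train)"
                )
        ordered = sorted(self.epochs, key=lambda e: (e.start, e.stop))
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.stop:
                raise ValidationError(
                    f"overlapping epochs: {a.label} [{a.start}, {a.stop}) and "
                    f"{b.label} [{b.start}, {b.stop})"
                )
        self.epochs = ordered

    @property
    def unit_ids(self) -> list[str]:
        return [t.unit_id for t in self.spike_trains]

    @property
    def n_units(self) -> int:
        return len(self.spike_trains)

    @property
    def t_start(self) -> float:
        return min(t.t_start for t in self.spike_trains)

    @property
    def t_stop(self) -> float:
        return max(t.t_stop for t in self.spike_trains)

    def train(self, unit_id: str) -> SpikeTrain:
        for t in self.spike_trains:
            if t.unit_id == unit_id:
                return t
        raise KeyError(unit_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SessionRecord):
            return NotImplemented
        return (
            self.session_id == other.session_id
            and self.session_type == other.session_type
            and self.spike_trains == other.spike_trains
            and self.waveform_sets == other.waveform_sets
            and self.epochs == other.epochs
        )


@dataclass
class GroundTruth:
    """Planted ground truth attached to synthetic sessions.

    ``true_class`` maps unit_id to "bs", "ns" or "boundary" (drawn width too
    close to the mode midpoint to call); ``planted_bc_sign`` is the sign of the
    configured movement-vs-rest rate modulation (+1, -1 or 0).
    """

    true_class: dict[str, str]
    true_width: dict[str, float]  # ms
    planted_dimensionality: int
    planted_bc_sign: dict[str, int]
    planted_balance_coupling: float

    def __post_init__(self) -> None:
        if self.planted_dimensionality < 0:
            raise ValidationError("planted_dimensionality must be >= 0")
        keys = set(self.true_class)
        for name, d in (
            ("true_width", self.true_width),
            ("planted_bc_sign", self.planted_bc_sign),
        ):
            if set(d) != keys:
                raise ValidationError(f"{name} does not cover every unit")
        if not 0.0 <= self.planted_balance_coupling <= 1.0:
            raise ValidationError("planted_balance_coupling must be in [0, 1]")
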