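"""State vectors, state-homogeneous slices, trial concatenation, binning.

Behavioral epochs come at 1 s scoring resolution for task-free sessions; for
task sessions the 0.5 s trial windows (preparatory period, task movement) play
the role of epochs. Analyses run on equal-length slices cut from epochs
(mostly 3 s), or on k x 0.5 s composites concatenated from consecutive trials.
Bins are half-open ``[t, t + bin)``: a spike on a boundary belongs to the bin
on its right, so every spike is counted exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import BehaviorEpoch, SpikeTrain

_TOL = 1e-9


@dataclass(frozen=True)
class Slice:
    """A state-homogeneous analysis window.

    ``pieces`` lists the contributing ``(start, stop)`` intervals: a single
    interval for a contiguous slice, several for a slice concatenated from
    trials. ``start``/``stop`` of a concatenated slice span the first to the
    last piece; its analysable duration is the summed piece length.
    """

    label: str
    pieces: tuple[tuple[float, float], ...]
    source: str = "contiguous"  # or "concatenated"
    trial_ids: tuple[int, ...] = ()

    @property
    def start(self) -> float:
        return self.pieces[0][0]

    @property
    def stop(self) -> float:
        return self.pieces[-1][1]

    @property
    def duration(self) -> float:
        """Total analysable time (sum of pieces), in seconds."""
        return float(sum(b - a for a, b in self.pieces))


@dataclass
class BinnedCounts:
    """Spike counts of several units in the bins of one slice."""

    counts: np.ndarray  # units x bins, non-negative ints
    bin_size: float
    slice: Slice
    unit_ids: list[str]

    @property
    def n_units(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.counts.shape[1])


def build_state_vector(epochs: list[BehaviorEpoch], duration: float) -> np.ndarray:
    """Per-second +/-1/0 encoding of behavior.

    Second ``t`` maps to -1 inside a rest (RS) epoch, +1 inside a movement (M)
    epoch and 0 otherwise (sleepy rest, unclassified behavior, gaps). Epochs
    must lie on integer-second boundaries.
    """
    n = int(np.floor(duration))
    sv = np.zeros(n, dtype=int)
    for ep in epochs:
        if ep.label not in ("RS", "M"):
            continue
        if abs(ep.start - round(ep.start)) > _TOL or abs(ep.stop - round(ep.stop)) > _TOL:
            raise ValueError(
                f"epoch [{ep.start}, {ep.stop}) not at integer-second boundaries"
            )
        lo = int(round(ep.start))
        hi = min(int(round(ep.stop)), n)
        sv[lo:hi] = -1 if ep.label == "RS" else 1
    return sv


def cut_slices(
    epochs: list[BehaviorEpoch],
    slice_len: float = 3.0,
    exclude_transition_seconds: bool = False,
    labels: tuple[str, ...] | None = None,
) -> list[Slice]:
    """Cut each epoch into as many consecutive ``slice_len`` slices as fit.

    Slices start at the (optionally trimmed) epoch start; the remainder is
    discarded. ``exclude_transition_seconds`` removes the first and last
    second of every epoch before slicing (used for 0.5 s slicing when
    comparing task-free and task statistics). ``labels`` restricts the output
    to the given states; unclassified epochs are never sliced.
    """
    if slice_len <= 0:
        raise ValueError("slice_len must be positive")
    out: list[Slice] = []
    for ep in sorted(epochs, key=lambda e: e.start):
        if ep.label == "UNCLASSIFIED":
            continue
        if labels is not None and ep.label not in labels:
            continue
        lo, hi = ep.start, ep.stop
        if exclude_transition_seconds:
            lo, hi = lo + 1.0, hi - 1.0
        n = int(np.floor((hi - lo) / slice_len + _TOL))
        for i in range(max(n, 0)):
            a = lo + i * slice_len
            out.append(Slice(ep.label, ((a, a + slice_len),)))
    return out


def concatenate_trial_slices(trial_slices: list[Slice], k: int = 6) -> list[Slice]:
    """Concatenate consecutive groups of ``k`` same-label trial slices.

    Groups are formed in temporal order; a leftover group smaller than ``k``
    is dropped. Mixed labels inside a group are an error: composite slices
    must stay state-homogeneous.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(trial_slices, key=lambda s: s.start)
    out: list[Slice] = []
    for g in range(len(ordered) // k):
        group = ordered[g * k : (g + 1) * k]
        labels = {s.label for s in group}
        if len(labels) > 1:
            raise ValueError(f"mixed labels in concatenation group: {sorted(labels)}")
        pieces = tuple(p for s in group for p in s.pieces)
        trial_ids = tuple(
            t for i, s in enumerate(group) for t in (s.trial_ids or (g * k + i,))
        )
        out.append(Slice(group[0].label, pieces, source="concatenated", trial_ids=trial_ids))
    return out


def bin_counts(trains: list[SpikeTrain], slc: Slice, bin_size: float) -> BinnedCounts:
    """Bin each unit's spikes inside ``slc`` into ``bin_size`` bins.

    Each piece of the slice is binned independently and the resulting columns
    concatenated, so no bin ever spans a join between concatenated trials.
    ``bin_size`` must divide every piece length exactly (tolerance 1e-9 s).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    edges_per_piece = []
    for a, b in slc.pieces:
        ratio = (b - a) / bin_size
        n = round(ratio)
        if n < 1 or abs(ratio - n) > 1e-6:
            raise ValueError(
                f"bin size {bin_size} does not divide piece length {b - a} exactly"
            )
        edges_per_piece.append((a, n))
    mats = []
    for train in trains:
        row_parts = []
        for a, n in edges_per_piece:
            # half-open bins [a + i*bin, a + (i+1)*bin)
            idx = np.floor((train.spike_times - a) / bin_size).astype(int)
            ok = (idx >= 0) & (idx < n) & (train.spike_times >= a)
            row_parts.append(np.bincount(idx[ok], minlength=n)[:n])
        mats.append(np.concatenate(row_parts))
    counts = np.asarray(mats, dtype=int)
    return BinnedCounts(counts, bin_size, slc, [t.unit_id for t in trains])


def spikes_in_slice(train: SpikeTrain, slc: Slice) -> np.ndarray:
    """Spike times of ``train`` falling inside the (half-open) slice pieces."""
    parts = [
        train.spike_times[(train.spike_times >= a) & (train.spike_times < b)]
        for a, b in slc.pieces
    ]
    return np.concatenate(parts) if parts else np.empty(0)
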