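"""Per-unit firing statistics per behavioral state, and behavioral correlation.

Statistics: firing rate (FR) per slice; coefficient of variation (CV) and its
local variant CV2 over interspike intervals (ISIs); Fano factor (FF) of spike
counts across same-length slices. CV2 averages 2|ISI_{i+1} - ISI_i| /
(ISI_{i+1} + ISI_i) over consecutive ISI pairs and corrects for slow rate
drift; it equals 1 for Poisson firing, as does the FF.

The behavioral correlation (BC) of a unit is the Spearman rank correlation
between its per-second firing rate and the +/-1 movement/rest state vector,
restricted to seconds scored as movement or rest. Significance across units
uses Holm-corrected p-values at alpha = 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import SpikeTrain
from .slicing import Slice, spikes_in_slice
from .stats import DEFAULT_ALPHA, UNDEFINED, holm_bonferroni, kruskal_wallis, spearman


@dataclass
class UnitStateStats:
    unit_id: str
    state: str
    fr: float  # Hz, mean over slices
    cv: float
    cv2: float
    ff: float
    n_slices: int


@dataclass
class BCResult:
    unit_id: str
    bc: float
    p_value: float
    significant: bool = False


def firing_rate(train: SpikeTrain, slc: Slice) -> float:
    """Spike count inside the slice divided by its duration, in Hz."""
    return spikes_in_slice(train, slc).size / slc.duration


def cv(isis) -> float:
    """Coefficient of variation of ISIs: sample SD (n-1) over mean."""
    isis = np.asarray(isis, dtype=float)
    if isis.size < 2:
        return UNDEFINED
    m = isis.mean()
    if m == 0:
        return UNDEFINED
    return float(np.std(isis, ddof=1) / m)


def cv2(isis) -> float:
    """Local coefficient of variation over consecutive ISI pairs, in [0, 2]."""
    isis = np.asarray(isis, dtype=float)
    if isis.size < 2:
        return UNDEFINED
    a, b = isis[:-1], isis[1:]
    s = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = 2.0 * np.abs(b - a) / s
    terms = terms[s > 0]
    if terms.size == 0:
        return UNDEFINED
    return float(terms.mean())


def fano_factor(counts) -> float:
    """Variance (n-1) over mean of spike counts across same-length slices."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        return UNDEFINED
    m = counts.mean()
    if m == 0:
        return UNDEFINED
    return float(np.var(counts, ddof=1) / m)


def _slice_isis(train: SpikeTrain, slc: Slice) -> list[np.ndarray]:
    """ISIs within each contiguous piece of a slice (none across joins)."""
    out = []
    for a, b in slc.pieces:
        t = train.spike_times[(train.spike_times >= a) & (train.spike_times < b)]
        if t.size >= 2:
            out.append(np.diff(t))
    return out


def unit_state_stats(
    train: SpikeTrain, slices: list[Slice], state: str
) -> UnitStateStats:
    """FR/CV/CV2/FF of one unit over the slices of one state.

    CV and CV2 are computed within each slice (no ISIs spanning slice gaps)
    and averaged over slices with at least 2 ISIs; FF is taken across the
    per-slice spike counts.
    """
    sls = [s for s in slices if s.label == state]
    frs, cvs, cv2s, counts = [], [], [], []
    for s in sls:
        spikes = spikes_in_slice(train, s)
        counts.append(spikes.size)
        frs.append(spikes.size / s.duration)
        isi_parts = _slice_isis(train, s)
        isis = np.concatenate(isi_parts) if isi_parts else np.empty(0)
        c = cv(isis)
        if np.isfinite(c):
            cvs.append(c)
        c2 = cv2(isis)
        if np.isfinite(c2):
            cv2s.append(c2)
    return UnitStateStats(
        unit_id=train.unit_id,
        state=state,
        fr=float(np.mean(frs)) if frs else UNDEFINED,
        cv=float(np.mean(cvs)) if cvs else UNDEFINED,
        cv2=float(np.mean(cv2s)) if cv2s else UNDEFINED,
        ff=fano_factor(counts),
        n_slices=len(sls),
    )


def per_second_rate(train: SpikeTrain, duration: float) -> np.ndarray:
    """Firing rate in consecutive 1 s bins from the recording start."""
    n = int(np.floor(duration))
    idx = np.floor(train.spike_times - train.t_start).astype(int)
    ok = (idx >= 0) & (idx < n)
    return np.bincount(idx[ok], minlength=n)[:n].astype(float)


def behavioral_correlation(
    per_second_fr: np.ndarray, state_vector: np.ndarray, *, seed: int | None = None
) -> BCResult:
    """Spearman correlation of per-second FR with the +/-1 state vector.

    Only seconds with a nonzero state-vector entry enter; fewer than 5 such
    seconds, or a constant FR on them, gives an undefined (NaN) result.
    """
    fr = np.asarray(per_second_fr, dtype=float)
    sv = np.asarray(state_vector)
    if fr.size != sv.size:
        raise ValueError("FR sequence and state vector differ in length")
    mask = sv != 0
    if mask.sum() < 5:
        warnings.warn("fewer than 5 scored movement/rest seconds; BC undefined")
        return BCResult("", UNDEFINED, UNDEFINED)
    res = spearman(fr[mask], sv[mask], seed=seed)
    return BCResult("", res.statistic, res.p_value)


def bc_for_session(
    trains: list[SpikeTrain],
    state_vector: np.ndarray,
    duration: float,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
) -> list[BCResult]:
    """BC per unit with Holm correction across units at ``alpha``."""
    results = []
    for t in trains:
        r = behavioral_correlation(per_second_rate(t, duration), state_vector, seed=seed)
        results.append(BCResult(t.unit_id, r.bc, r.p_value))
    flags, _ = holm_bonferroni([r.p_value for r in results], alpha)
    for r, f in zip(results, flags):
        r.significant = bool(f)
    return results


def per_unit_state_test(slice_frs: dict[str, np.ndarray]) -> float:
    """Kruskal-Wallis p-value for FR differences among a unit's states.

    ``slice_frs`` maps state label to the per-slice FRs of one unit. States
    with fewer than 2 slices are dropped with a warning (a session can lack a
    state entirely); fewer than 2 usable states gives NaN.
    """
    groups = []
    for state, vals in slice_frs.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size >= 2:
            groups.append(vals)
        else:
            warnings.warn(f"state {state}: fewer than 2 slices, dropped from KW test")
    if len(groups) < 2:
        return UNDEFINED
    if all(np.all(g == groups[0][0]) for g in groups):
        return 1.0  # identical constant FRs carry no evidence
    return kruskal_wallis(*groups).p_value


def pairwise_state_comparison(frs_a, frs_b, alpha: float = DEFAULT_ALPHA) -> str:
    """Directional two-state FR comparison for one unit.

    Two-group Kruskal-Wallis (equivalent to a rank test) with the direction
    from the median difference; returns ``"A<B"``, ``"A>B"`` or ``"n.s."``.
    Callers aggregate the per-unit outcomes into percentages per state pair.
    """
    a = np.asarray(frs_a, dtype=float)
    b = np.asarray(frs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        return "n.s."
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return "n.s."
    p = kruskal_wallis(a, b).p_value
    if p >= alpha:
        return "n.s."
    return "A<B" if np.median(a) < np.median(b) else "A>B"


def class_rate_ratio(
    state_stats: list[UnitStateStats], labels: dict[str, str], state: str
) -> float:
    """ns:bs mean firing-rate ratio within one state; NaN if a class is empty."""
    ns = [s.fr for s in state_stats if s.state == state and labels.get(s.unit_id) == "ns"]
    bs = [s.fr for s in state_stats if s.state == state and labels.get(s.unit_id) == "bs"]
    ns = [x for x in ns if np.isfinite(x)]
    bs = [x for x in bs if np.isfinite(x)]
    if not ns or not bs or np.mean(bs) == 0:
        return UNDEFINED
    return float(np.mean(ns) / np.mean(bs))
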