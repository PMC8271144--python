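"""Putative excitatory/inhibitory unit classification from spike waveforms.

Units are split into broad-spiking (bs, putative excitatory) and
narrow-spiking (ns, putative inhibitory) classes by the trough-to-peak width
of their waveforms. Two width thresholds leave the middle of the width
distribution unclassified: widths strictly below ``theta_ns`` are narrow,
strictly above ``theta_bs`` broad. A two-step consistency procedure then
reconciles the label of the mean waveform (step 1) with the majority label of
the single-spike waveforms (step 2): the minimal required consistency is
raised until no unit passing it carries contradictory step-1/step-2 labels.

Quality filters (waveform SNR >= 2.5, whole-recording mean rate >= 1 Hz)
decide inclusion independently of the class label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import SpikeTrain, WaveformSet

#: Default inclusion filters.
SNR_MIN = 2.5
FR_MIN = 1.0  # Hz

#: Default width gap between the narrow and broad thresholds, in ms
#: (one step of the 0.01 ms width grid used to report thresholds).
DEFAULT_GAP = 0.01


class WidthError(ValueError):
    """The trough-to-peak width of a waveform is undefined."""


@dataclass(frozen=True)
class Thresholds:
    """Width thresholds in ms: ``< theta_ns`` narrow, ``> theta_bs`` broad."""

    theta_ns: float
    theta_bs: float

    def __post_init__(self) -> None:
        if self.theta_ns > self.theta_bs:
            raise ValueError("theta_ns must not exceed theta_bs")

    def preliminary_label(self, width_ms: float) -> str:
        if width_ms < self.theta_ns:
            return "ns"
        if width_ms > self.theta_bs:
            return "bs"
        return "unclassified"


@dataclass
class UnitClassification:
    unit_id: str
    mean_width: float  # ms; NaN if undefined
    label: str  # "bs" | "ns" | "unclassified"
    consistency: float  # fraction of single waveforms classified broad
    snr: float
    included: bool = False


def spike_width(waveform: np.ndarray, sampling_rate: float) -> float:
    """Trough-to-peak width of one waveform, in ms.

    The trough is the global minimum; the peak is the maximum *after* the
    trough (robust to capacitive pre-trough peaks). Raises
    :class:`WidthError` if the trough sits at the last sample.
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1 or w.size < 3:
        raise WidthError("waveform must be a vector of at least 3 samples")
    trough = int(np.argmin(w))
    if trough >= w.size - 1:
        raise WidthError("trough at last sample: no post-trough peak")
    peak = trough + 1 + int(np.argmax(w[trough + 1 :]))
    if peak == w.size - 1 and w[peak] > w[peak - 1]:
        # still rising at the window edge: no genuine post-trough turning point
        raise WidthError("no post-trough local maximum inside the window")
    return (peak - trough) / sampling_rate * 1000.0


def compute_snr(ws: WaveformSet) -> float:
    """Waveform signal-to-noise ratio.

    Peak-to-peak amplitude of the mean waveform divided by twice the mean
    (over samples) standard deviation of the residuals around it. Identical
    snippets (zero residual SD) yield ``inf`` with a warning unless the mean
    waveform is also flat, in which case the SNR is 0.
    """
    if ws.n_spikes < 2:
        raise ValueError(f"unit {ws.unit_id}: SNR needs at least 2 waveforms")
    mean_wf = ws.mean_waveform
    ptp = float(np.ptp(mean_wf))
    resid_sd = float(np.std(ws.waveforms - mean_wf, axis=0, ddof=1).mean())
    if resid_sd == 0.0:
        if ptp == 0.0:
            return 0.0
        warnings.warn(f"unit {ws.unit_id}: zero residual SD, SNR is infinite")
        return float("inf")
    return ptp / (2.0 * resid_sd)


def select_thresholds(
    mean_widths,
    gap: float = DEFAULT_GAP,
    grid_step: float = 0.005,
    min_separation: float = 0.05,
) -> Thresholds:
    """Place the width thresholds at the valley of a bimodal width density.

    Mean-waveform widths are quantized to the sampling grid (1/30 ms at
    30 kHz), so a raw histogram is comb-like; a Gaussian kernel density
    estimate smooths over the quantization. The valley is the density minimum
    between the two dominant modes at least ``min_separation`` ms apart, ties
    resolved to the center of the minimal plateau; thresholds are
    ``valley -/+ gap/2``, reported on a 0.01 ms grid. A distribution with no
    interior valley raises, instructing manual thresholds.
    """
    from scipy.stats import gaussian_kde

    widths = np.asarray(mean_widths, dtype=float)
    widths = widths[~np.isnan(widths)]
    if widths.size < 20:
        raise ValueError("need at least 20 unit widths to place thresholds")
    if np.ptp(widths) < min_separation:
        raise ValueError("width distribution has no spread; supply manual thresholds")
    kde = gaussian_kde(widths)
    grid = np.arange(widths.min(), widths.max() + grid_step / 2, grid_step)
    dens = kde(grid)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if grid.size >= 2:  # boundary maxima count as modes too
        if dens[0] > dens[1]:
            peaks = np.concatenate([[0], peaks])
        if dens[-1] > dens[-2]:
            peaks = np.concatenate([peaks, [grid.size - 1]])
    # dominant mode, then the strongest peak far enough away from it
    peaks = peaks[np.argsort(dens[peaks])[::-1]]
    if peaks.size < 2:
        raise ValueError("width distribution is unimodal; supply manual thresholds")
    p1 = peaks[0]
    # a genuine second mode: far enough from the first and not a tail ripple
    far = peaks[
        (np.abs(grid[peaks] - grid[p1]) >= min_separation)
        & (dens[peaks] >= 0.1 * dens[p1])
    ]
    if far.size == 0:
        raise ValueError("width distribution is unimodal; supply manual thresholds")
    p2 = far[0]
    a, b = sorted((int(p1), int(p2)))
    between = dens[a + 1 : b]
    if between.size == 0 or between.min() >= 0.9 * min(dens[a], dens[b]):
        raise ValueError(
            "no interior valley in the width distribution; supply manual thresholds"
        )
    plateau = np.flatnonzero(np.isclose(between, between.min()))
    valley = float(grid[a + 1 + int(plateau[len(plateau) // 2])])
    # report on the conventional 0.01 ms grid, keeping the valley inside the gap
    theta_ns = np.floor((valley - gap / 2) * 100.0 + 1e-9) / 100.0
    theta_bs = np.ceil((valley + gap / 2) * 100.0 - 1e-9) / 100.0
    return Thresholds(float(theta_ns), float(theta_bs))


def _single_widths(ws: WaveformSet) -> np.ndarray:
    out = np.full(ws.n_spikes, np.nan)
    for i in range(ws.n_spikes):
        try:
            out[i] = spike_width(ws.waveforms[i], ws.sampling_rate)
        except WidthError:
            pass
    return out


def classify_units(
    waveform_sets: dict[str, WaveformSet], thresholds: Thresholds
) -> list[UnitClassification]:
    """Two-step iterative consistency classification.

    Step 1 labels each unit from its mean-waveform width. Step 2 computes the
    consistency ``c``: the fraction of single waveforms with width above
    ``theta_bs`` among those outside the gap, labelling bs if c > 0.5, ns if
    c < 0.5. The minimal required consistency is then raised through the
    sorted distinct values of max(c, 1 - c) until no unit passing it has
    contradictory step-1/step-2 labels; units below it, or with mean width
    inside the gap, end up unclassified. Deterministic and independent of
    unit order.
    """
    records = []
    for uid in sorted(waveform_sets):
        ws = waveform_sets[uid]
        if ws.n_spikes == 0:
            warnings.warn(f"unit {uid}: empty waveform set, left unclassified")
            records.append((uid, np.nan, "unclassified", np.nan, None))
            continue
        try:
            mean_width = spike_width(ws.mean_waveform, ws.sampling_rate)
        except WidthError:
            warnings.warn(f"unit {uid}: undefined mean-waveform width")
            mean_width = np.nan
        step1 = (
            thresholds.preliminary_label(mean_width)
            if np.isfinite(mean_width)
            else "unclassified"
        )
        singles = _single_widths(ws)
        singles = singles[~np.isnan(singles)]
        outside = singles[(singles < thresholds.theta_ns) | (singles > thresholds.theta_bs)]
        if outside.size == 0:
            c = np.nan
            step2 = None
        else:
            c = float(np.mean(outside > thresholds.theta_bs))
            step2 = "bs" if c > 0.5 else ("ns" if c < 0.5 else None)
        records.append((uid, mean_width, step1, c, step2))

    # candidate minimal consistencies: distinct observed max(c, 1-c) values
    strengths = {
        uid: max(c, 1 - c)
        for uid, _, step1, c, step2 in records
        if step1 != "unclassified" and step2 is not None and np.isfinite(c)
    }
    candidates = sorted({0.0, *strengths.values()})
    if strengths:
        # sentinel above every observed strength: excludes all units, which is
        # the (contradiction-free) fixed point if contradictions persist at
        # the top of the consistency distribution
        candidates.append(max(strengths.values()) + 1.0)
    c_min = None
    for cand in candidates:
        contradiction = False
        for uid, _, step1, c, step2 in records:
            if uid not in strengths or strengths[uid] < cand:
                continue
            if step1 != "unclassified" and step2 is not None and step1 != step2:
                contradiction = True
                break
        if not contradiction:
            c_min = cand
            break
    if c_min is None:  # only possible if every unit contradicts at every level
        c_min = float("inf")

    out = []
    for uid, mean_width, step1, c, step2 in records:
        passes = uid in strengths and strengths[uid] >= c_min
        label = step1 if (step1 != "unclassified" and passes) else "unclassified"
        snr = compute_snr(waveform_sets[uid]) if waveform_sets[uid].n_spikes >= 2 else np.nan
        out.append(UnitClassification(uid, mean_width, label, c, snr))

    assert not _has_contradiction(records, strengths, c_min)
    return out


def _has_contradiction(records, strengths, c_min) -> bool:
    for uid, _, step1, c, step2 in records:
        if uid in strengths and strengths[uid] >= c_min:
            if step1 != "unclassified" and step2 is not None and step1 != step2:
                return True
    return False


def filter_units(
    trains: list[SpikeTrain],
    classifications: list[UnitClassification],
    snr_min: float = SNR_MIN,
    fr_min: float = FR_MIN,
) -> set[str]:
    """Mark units passing the quality filters; returns the included id set.

    Inclusion requires SNR >= ``snr_min`` and a whole-recording mean rate
    >= ``fr_min``; the bs/ns/unclassified label plays no role.
    """
    rates = {t.unit_id: t.mean_rate() for t in trains}
    included = set()
    for cl in classifications:
        fr = rates.get(cl.unit_id, 0.0)
        cl.included = bool(np.isfinite(cl.snr) and cl.snr >= snr_min and fr >= fr_min) or (
            cl.snr == float("inf") and fr >= fr_min
        )
        if cl.included:
            included.add(cl.unit_id)
    return included
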