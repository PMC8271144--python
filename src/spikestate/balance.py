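"""Excitatory-inhibitory balance of population spiking.

Spike counts of the broad-spiking (bs, putative excitatory) and
narrow-spiking (ns, putative inhibitory) classes are pooled per bin. Two
complementary measures:

* Delta(bs, ns): per-bin difference of the two population series after
  z-scoring each against its own whole-recording mean and SD (never
  state-specific statistics). Delta near 0 means balanced activity; negative
  values indicate ns (inhibitory) domination, positive bs domination.
* rho(bs, ns): "instantaneous balance", the Spearman rank correlation of the
  *raw* bs and ns series across the bins of one slice; the higher, the more
  tightly the two populations co-fluctuate.

A timescale sweep recomputes Delta across bin sizes (1 ms to 10 s) over the
whole recording, and the balance-dimensionality link is the Spearman
correlation between per-slice rho and PR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import SpikeTrain
from .slicing import Slice, bin_counts
from .stats import UNDEFINED, TestResult, spearman


@dataclass
class PopulationSeries:
    bs_counts: np.ndarray
    ns_counts: np.ndarray
    bin_size: float
    slice: Slice | None = None


@dataclass
class BalanceResult:
    slice: Slice
    delta: np.ndarray  # per-bin z-score differences
    rho: float


def population_counts(
    trains: list[SpikeTrain], labels: dict[str, str], slc: Slice, bin_size: float
) -> PopulationSeries:
    """Pooled per-bin spike counts of the bs and ns classes within a slice.

    Unclassified units are excluded; an empty class is an error because both
    balance measures are undefined without it.
    """
    bs_tr = [t for t in trains if labels.get(t.unit_id) == "bs"]
    ns_tr = [t for t in trains if labels.get(t.unit_id) == "ns"]
    for name, group in (("bs", bs_tr), ("ns", ns_tr)):
        if not group:
            raise ValueError(f"no included units in class {name!r}")
    bs = bin_counts(bs_tr, slc, bin_size).counts.sum(axis=0)
    ns = bin_counts(ns_tr, slc, bin_size).counts.sum(axis=0)
    return PopulationSeries(bs, ns, bin_size, slc)


def global_stats(series: np.ndarray) -> tuple[float, float]:
    """Mean and SD (population, n denominator) of a whole-recording series."""
    series = np.asarray(series, dtype=float)
    return float(series.mean()), float(series.std())


def zscore_global(series, global_mean: float, global_sd: float) -> np.ndarray:
    """z-score against whole-recording statistics (never state-specific)."""
    if global_sd <= 0:
        raise ValueError("global SD must be positive (constant recording?)")
    return (np.asarray(series, dtype=float) - global_mean) / global_sd


def balance_difference(z_bs, z_ns) -> np.ndarray:
    """Per-bin Delta(bs, ns) = z_bs - z_ns; negative = ns domination."""
    z_bs = np.asarray(z_bs, dtype=float)
    z_ns = np.asarray(z_ns, dtype=float)
    if z_bs.shape != z_ns.shape:
        raise ValueError("z-scored series differ in length")
    return z_bs - z_ns


def instantaneous_balance(series: PopulationSeries, *, seed: int | None = None) -> float:
    """Spearman rho of raw bs vs ns counts across the bins of one slice.

    Needs at least 3 bins and two non-constant series; otherwise the slice's
    balance is undefined (NaN) and it is excluded from state summaries.
    """
    bs, ns = series.bs_counts, series.ns_counts
    if bs.size < 3:
        return UNDEFINED
    if np.all(bs == bs[0]) or np.all(ns == ns[0]):
        warnings.warn("constant population series; instantaneous balance undefined")
        return UNDEFINED
    return spearman(bs, ns, seed=seed if bs.size <= 20 else None).statistic


def session_balance(
    trains: list[SpikeTrain],
    labels: dict[str, str],
    slices: list[Slice],
    t_start: float,
    t_stop: float,
    bin_size: float = 0.1,
    seed: int | None = None,
) -> list[BalanceResult]:
    """Delta and rho per slice, z-scored against whole-recording statistics."""
    whole = Slice(
        "UNCLASSIFIED", ((t_start, t_start + np.floor((t_stop - t_start) / bin_size) * bin_size),)
    )
    rec = population_counts(trains, labels, whole, bin_size)
    bs_mean, bs_sd = global_stats(rec.bs_counts)
    ns_mean, ns_sd = global_stats(rec.ns_counts)
    out = []
    for slc in slices:
        series = population_counts(trains, labels, slc, bin_size)
        delta = balance_difference(
            zscore_global(series.bs_counts, bs_mean, bs_sd),
            zscore_global(series.ns_counts, ns_mean, ns_sd),
        )
        rho = instantaneous_balance(series, seed=seed)
        out.append(BalanceResult(slc, delta, rho))
    return out


def state_delta_summary(results: list[BalanceResult]) -> dict[str, tuple[float, float]]:
    """Mean and SD of Delta over all bins of each state's slices."""
    by_state: dict[str, list[np.ndarray]] = {}
    for r in results:
        by_state.setdefault(r.slice.label, []).append(r.delta)
    return {
        state: (float(np.concatenate(ds).mean()), float(np.concatenate(ds).std()))
        for state, ds in by_state.items()
    }


def state_rho_summary(results: list[BalanceResult]) -> dict[str, tuple[float, float]]:
    """Mean and SD of rho over each state's slices (undefined slices dropped)."""
    by_state: dict[str, list[float]] = {}
    for r in results:
        if np.isfinite(r.rho):
            by_state.setdefault(r.slice.label, []).append(r.rho)
    return {
        state: (float(np.mean(v)), float(np.std(v))) for state, v in by_state.items()
    }


def timescale_sweep(
    trains: list[SpikeTrain],
    labels: dict[str, str],
    t_start: float,
    t_stop: float,
    bin_sizes=(0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0),
):
    """Mean and SD of Delta per bin size over the whole recording.

    No state slicing: each bin size z-scores and differences the full
    population series. Bin sizes longer than the recording are skipped with a
    warning. Returns records ``{bin_size, mean_delta, sd_delta, n_bins}``.
    """
    duration = t_stop - t_start
    rows = []
    for bs in sorted(bin_sizes):
        n = int(np.floor(duration / bs))
        if n < 2:
            warnings.warn(f"bin size {bs} s too long for a {duration} s recording; skipped")
            continue
        whole = Slice("UNCLASSIFIED", ((t_start, t_start + n * bs),))
        series = population_counts(trains, labels, whole, bs)
        delta = balance_difference(
            zscore_global(series.bs_counts, *global_stats(series.bs_counts)),
            zscore_global(series.ns_counts, *global_stats(series.ns_counts)),
        )
        rows.append(
            {
                "bin_size": bs,
                "mean_delta": float(delta.mean()),
                "sd_delta": float(delta.std()),
                "n_bins": n,
            }
        )
    return rows


def balance_pr_correlation(rhos, prs, *, seed: int | None = None) -> TestResult:
    """Spearman correlation between per-slice rho(bs, ns) and PR."""
    rhos = np.asarray(rhos, dtype=float)
    prs = np.asarray(prs, dtype=float)
    if rhos.size != prs.size:
        raise ValueError("rho and PR lists differ in length")
    ok = np.isfinite(rhos) & np.isfinite(prs)
    if ok.sum() < 5:
        raise ValueError("need at least 5 paired (rho, PR) slices")
    return spearman(rhos[ok], prs[ok], seed=seed)
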