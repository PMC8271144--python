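"""Spike-count covariance and participation-ratio dimensionality.

For a slice binned into ``l`` bins the pairwise covariance of units i and j is

    COV(i, j) = <b_i - m_i, b_j - m_j> / (l - 1),

the sample covariance of the binned count vectors. The participation ratio of
the covariance matrix M with eigenvalues lambda_i,

    PR = (sum_i lambda_i)^2 / sum_i lambda_i^2,

measures the effective dimensionality of the population activity: it equals N
when N eigenvalues share the variance equally and 1 when a single mode
carries it all, so 1 <= PR <= N_SU always.

To compare sessions with different unit counts, the PR of a slice is computed
on random subsamples of a fixed number of units (89 in the reference
experimental setting) and averaged over repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SpikeTrain
from .slicing import BinnedCounts, Slice, bin_counts
from .stats import UNDEFINED

#: Tolerance below which negative numerical eigenvalues are clipped to zero.
EIG_TOL = 1e-10


@dataclass
class CovarianceMatrix:
    matrix: np.ndarray  # N_SU x N_SU, counts^2 per bin
    bin_size: float
    slice: Slice
    unit_ids: list[str]


@dataclass
class PRResult:
    slice: Slice
    pr: float
    n_sub: int
    n_reps: int
    seed: int | None


def covariance_matrix(bc: BinnedCounts) -> CovarianceMatrix:
    """Sample covariance (denominator l - 1) of the binned count rows."""
    if bc.n_bins < 2:
        raise ValueError("need at least 2 bins for a covariance estimate")
    mat = np.cov(bc.counts.astype(float), ddof=1)
    mat = np.atleast_2d(mat)
    return CovarianceMatrix(mat, bc.bin_size, bc.slice, list(bc.unit_ids))


def participation_ratio(m) -> float:
    """PR from a covariance matrix or a vector of eigenvalues.

    Eigenvalues within ``-EIG_TOL`` of zero are clipped up; a significantly
    negative eigenvalue means the input is not a covariance matrix and
    raises. An all-zero spectrum gives NaN.
    """
    if isinstance(m, CovarianceMatrix):
        eig = np.linalg.eigvalsh(m.matrix)
    else:
        m = np.asarray(m, dtype=float)
        eig = np.linalg.eigvalsh(m) if m.ndim == 2 else m
    scale = max(1.0, float(np.abs(eig).max(initial=0.0)))
    if np.any(eig < -EIG_TOL * scale):
        raise ValueError(f"significantly negative eigenvalue: {eig.min()}")
    eig = np.clip(eig, 0.0, None)
    s2 = float(np.sum(eig**2))
    if s2 == 0.0:
        return UNDEFINED
    return float(np.sum(eig) ** 2 / s2)


def _slice_rng(seed: int, slc: Slice) -> np.random.Generator:
    # per-slice substream keyed by the slice start, so results do not depend
    # on the order in which slices are processed
    return np.random.default_rng([seed, int(round(slc.start * 1000))])


def subsampled_pr(
    trains: list[SpikeTrain],
    slc: Slice,
    n_sub: int = 89,
    n_reps: int = 100,
    seed: int | None = None,
    bin_size: float = 0.1,
) -> PRResult:
    """Mean PR over ``n_reps`` random ``n_sub``-unit subsamples of one slice."""
    n = len(trains)
    if n < n_sub:
        raise ValueError(
            f"only {n} units available; choose n_sub <= {n} (got {n_sub})"
        )
    if seed is None:
        raise ValueError("subsampling requires an explicit seed")
    binned = bin_counts(trains, slc, bin_size)
    rng = _slice_rng(seed, slc)
    prs = np.empty(n_reps)
    for r in range(n_reps):
        idx = rng.choice(n, size=n_sub, replace=False)
        sub = BinnedCounts(binned.counts[idx], bin_size, slc, [binned.unit_ids[i] for i in idx])
        prs[r] = participation_ratio(covariance_matrix(sub))
    return PRResult(slc, float(prs.mean()), n_sub, n_reps, seed)


def sliding_pr(
    trains: list[SpikeTrain],
    t_start: float,
    t_stop: float,
    window_len: float = 3.0,
    step: float = 1.0,
    n_sub: int = 89,
    n_reps: int = 100,
    seed: int | None = None,
    bin_size: float = 0.1,
) -> list[tuple[float, PRResult]]:
    """Time-resolved PR in overlapping windows.

    Windows of ``window_len`` start at ``t_start``, ``t_start + step``, ...;
    each result is timestamped at the window center. A recording shorter than
    one window yields an empty series.
    """
    out = []
    start = t_start
    while start + window_len <= t_stop + 1e-9:
        slc = Slice("UNCLASSIFIED", ((start, start + window_len),))
        res = subsampled_pr(trains, slc, n_sub, n_reps, seed, bin_size)
        out.append((start + window_len / 2, res))
        start += step
    return out


def bin_size_robustness(
    trains: list[SpikeTrain],
    slices: list[Slice],
    bin_sizes=(0.05, 0.1, 0.2),
    n_sub: int | None = None,
    n_reps: int = 100,
    seed: int | None = None,
):
    """Mean PR per (state, bin size), normalized by the unit count.

    Used to check that the state ordering of dimensionality is stable across
    bin sizes. Bin sizes that do not divide the slice length are skipped with
    a warning. Returns records ``{state, bin_size, mean_pr_norm, n_slices}``.
    """
    import warnings

    n_units = len(trains)
    n_sub = n_sub or n_units
    rows = []
    states = sorted({s.label for s in slices})
    for bs in bin_sizes:
        per_state: dict[str, list[float]] = {s: [] for s in states}
        skipped = False
        for slc in slices:
            try:
                res = subsampled_pr(trains, slc, n_sub, n_reps, seed, bs)
            except ValueError as err:
                if "does not divide" in str(err):
                    skipped = True
                    continue
                raise
            per_state[slc.label].append(res.pr)
        if skipped:
            warnings.warn(f"bin size {bs}: some slices skipped (length not divisible)")
        for state in states:
            vals = per_state[state]
            rows.append(
                {
                    "state": state,
                    "bin_size": bs,
                    "mean_pr_norm": float(np.mean(vals)) / n_units if vals else UNDEFINED,
                    "n_slices": len(vals),
                }
            )
    return rows
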