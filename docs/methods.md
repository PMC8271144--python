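# Methods

This note documents the models, estimators and numerical conventions in
`spikestate`, the design choices that were genuinely open, and what the
synthetic-data tests do and do not establish about real recordings.

## Scope and data model

The package characterizes parallel single-unit (SU) spiking activity across
behavioral states, of the kind recorded with chronic multielectrode arrays in
motor cortex: task-free sessions scored at 1 s resolution into rest with eyes
open (RS), sleepy rest with eyes (half-)closed (RSS) and spontaneous movement
(M); and instructed reach-to-grasp sessions contributing 0.5 s preparatory
(PP) and movement (TM) windows per trial. All times are seconds; intervals
are half-open `[start, stop)`, which makes binning and slicing unambiguous
(each spike is counted exactly once, boundary spikes belong to the bin on
their right). Sessions are stored as plain-text directories (YAML manifest,
CSV spike/epoch tables, CSV waveform matrices) that round-trip to full IEEE
double precision.

## Unit classification

Units are split into broad-spiking (bs, putative excitatory) and
narrow-spiking (ns, putative inhibitory) classes by the trough-to-peak width
of the spike waveform: the global trough to the *post-trough* maximum, robust
to capacitive pre-trough peaks. At 30 kHz the width is quantized to 1/30 ms.

Two thresholds `(theta_ns, theta_bs)` leave the middle of the width
distribution unclassified. Automatic placement uses a Gaussian KDE of the
mean-waveform widths (a raw 0.01 ms histogram is comb-like because of sample
quantization); the valley between the two dominant modes — at least 0.05 ms
apart, the secondary mode at least 10% of the primary density — becomes the
gap center, reported on the conventional 0.01 ms grid. Unimodal distributions
raise an error instructing manual thresholds; manual thresholds are always
honored verbatim.

The two-step consistency procedure reconciles the mean-waveform label
(step 1) with the single-waveform majority (step 2). The consistency `c` of a
unit is the fraction of its single waveforms wider than `theta_bs` among those
falling outside the gap (gap waveforms are classified as neither and are
excluded from the denominator). The minimal required consistency is raised
through the sorted distinct observed values of `max(c, 1 - c)` — no fixed
grid, so the result is the smallest threshold with zero step-1/step-2
contradictions, found deterministically and independent of unit order. If
contradictions persist at the top of the consistency distribution, the
procedure ends at a sentinel above it and every unit is left unclassified.

Waveform SNR is the peak-to-peak amplitude of the mean waveform over twice
the mean (across samples) standard deviation of the residuals around it — a
convention for chronic-array recordings, stated explicitly here because it
fixes the numbers the inclusion filter produces. Units are included when
SNR ≥ 2.5 **and** whole-recording mean rate ≥ 1 Hz; inclusion ignores the
bs/ns label.

## Slicing and binning

Each behavioral segment is cut into as many consecutive equal-length slices
as fit (default 3 s), remainder discarded; a 7 s segment yields exactly 2
slices. For 0.5 s slicing (used when comparing task-free and task firing
statistics) the first and last second of every segment are removed first,
because scoring transitions are uncertain at the 1 s resolution; 3 s slices
use raw segment boundaries, as the transition exclusion is defined only in
the 0.5 s context. Task trials are concatenated in groups of six 0.5 s
windows into composite 3 s slices; binning never crosses a trial join, so
concatenation cannot manufacture covariance at the seams.

## Single-unit statistics

Per state and unit: firing rate (count/duration per slice, averaged over
slices), ISI coefficient of variation CV (sample SD, `n-1` denominator, over
mean), its local variant CV2 = mean over consecutive ISI pairs of
`2|ISI_{i+1} - ISI_i| / (ISI_{i+1} + ISI_i)` (bounded in [0, 2]; 1 for
Poisson firing), and the Fano factor (variance over mean of spike counts
across same-length slices; 1 for Poisson). ISIs are computed within slices
only — never across slice gaps or trial joins — and the per-unit state value
averages slices with at least 2 ISIs. Degenerate inputs (fewer than 2 ISIs,
zero mean count) return NaN sentinels rather than zeros, so they drop out of
summaries instead of biasing them.

The behavioral correlation (BC) of a unit is the Spearman rank correlation
between its per-second firing rate and the ±1 state vector (−1 for RS, +1
for M, 0 otherwise), restricted to nonzero entries; fewer than 5 scored
seconds yields NaN. Spearman p-values use the large-sample t approximation
for n > 20 and a seeded 10,000-draw permutation otherwise. Per-unit
Kruskal-Wallis tests compare slice firing rates across states; pairwise
comparisons take their direction from the median difference, consistent with
the rank-based test. All per-unit families are Holm-corrected at
alpha = 0.001.

## Covariance and dimensionality

The spike-count covariance of a slice binned into `l` bins (default 100 ms)
is the sample covariance with denominator `l - 1`. The participation ratio

    PR = (sum_i lambda_i)^2 / sum_i lambda_i^2

over the eigenvalues of the covariance matrix measures the effective
dimensionality: PR = N for N equal nonzero eigenvalues, PR = 1 for a
rank-one matrix, and 1 ≤ PR ≤ N_SU always. Eigenvalues come from a symmetric
eigendecomposition with no shrinkage; numerically negative eigenvalues within
−1e−10 (relative) are clipped to zero, anything more negative is an error.

To compare sessions with different unit counts, the PR of a slice is the
mean over repeated random subsamples of a fixed unit count (89 in the
reference experimental setting — the smallest session; configurable, and
synthetic tests use subsample sizes below their generated populations). The
subsampling RNG derives a per-slice substream from the master seed keyed by
the slice start time, so results are reproducible and independent of the
order in which slices are processed. The subsample pool is all included
units regardless of class. A sliding variant (3 s window, 1 s step by
default) timestamps each PR at the window center; a bin-size robustness
table recomputes state-mean PR (normalized by the session unit count) at 50,
100 and 200 ms.

## Excitatory-inhibitory balance

Population series are raw pooled counts per bin over the bs and the ns class
(class sizes differ; the global z-scoring absorbs that). Two measures:

* Δ(bs, ns): per-bin difference of the two series after z-scoring each
  against its own whole-recording mean and SD at the same bin size — never
  state-specific statistics, so state-specific shifts survive. Negative Δ
  means ns (inhibitory) domination. State summaries are mean ± SD over all
  bins of the state's slices.
* ρ(bs, ns): Spearman correlation of the *raw* series across the bins of one
  3 s slice ("instantaneous balance"). Slices with a constant series return
  NaN and are excluded from summaries — a silent 0 would bias state means.

A timescale sweep recomputes Δ at bin sizes from 1 ms to 10 s over the whole
recording. Note that per-bin-size z-scoring bounds SD(Δ) = sqrt(2 − 2·corr)
by 2: the timescale signature of coupling is the correlation rising with bin
size (SD falling), not an unbounded growth of excursions. The
balance-dimensionality link is the Spearman correlation between per-slice
ρ(bs, ns) and PR.

## Synthetic sessions

The generator produces the structure the analysis assumes, with planted
ground truth so every stage is testable without real recordings:

* **State chain.** First-order chain at 1 s resolution with geometric
  segment lengths (means: RS 20 s, RSS 10 s, M 5 s by default) — matching
  the 1 s scoring precision of observational segmentation.
* **Rates.** `rate(u, t) = base(class) x state_gain(u, label(t)) x
  exp(x_u(t) - v_u/2)`, where `x_u` sums shared Gaussian factors refreshed
  every `latent_resolution` seconds (default 0.1 s): one population-wide
  factor scaled by `balance_coupling` plus `n_latent_factors` factors with
  per-unit loading vectors normalized to `factor_loading_scale` (default
  1.0). The log-normal form guarantees positive rates and a controllable
  low-rank log-rate covariance; the `exp(-v/2)` correction keeps expected
  rates on target, and a 0.1 Hz floor keeps units observable. The latent
  time step defaults to the 100 ms analysis bin: coarser latents cannot
  carry dimensionality into a 3 s slice (a 1 s step leaves at most 3 latent
  draws per slice, bounding the recoverable rank at 2 no matter how many
  factors are planted).
* **Defaults as study conditions.** 120 units, 40% narrow-spiking, base
  rates 8.5 (ns) vs 5.0 Hz (bs) — the 1.7x ns:bs asymmetry in the middle of
  the experimentally reported 1.3-2.0 range; 900 s sessions (15 min, the
  experimental session length). Half the units are state-modulated: 40% gain
  2.0 during movement states, 10% the reciprocal. The 2.0 follows from the
  observed population-level M:RS rate ratio of ~1.4 carried by ~40% of units
  (0.6 + 0.4g = 1.4). Under these defaults roughly half the units come out
  BC-significant, matching the reported 41-67% range, and estimated class
  rate ratios land in 1.4-2.0.
* **Spikes.** Piecewise-constant-rate point processes: Poisson by thinning
  against the per-unit ceiling rate (exact for piecewise-constant rates), or
  a gamma(k) renewal process warped through operational time (the cumulative
  rate), giving ISI CV = 1/sqrt(k) at constant rate.
* **Waveforms.** A biphasic template (Gaussian trough, slower Gaussian peak
  trough-to-peak width later; 48 samples at 30 kHz) with per-unit width drawn
  from a two-mode mixture (0.25/0.55 ms, SD 0.03 ms), per-spike width jitter
  (SD 0.02 ms) and additive sample noise whose default SD puts the SNR near
  5 under the adopted definition. Up to `max_waveforms` (default 300)
  snippets are stored per unit: the consistency measure stabilizes far below
  that, and full per-spike matrices for a 900 s session would be hundreds of
  megabytes. Units whose drawn width falls within 0.05 ms of the mode
  midpoint are labeled `boundary` in the ground truth: their class is not a
  fair recovery target.

**What passing tests show — and do not.** Recovery tests demonstrate that the
estimators are correct and well-calibrated under the generative model:
log-normal low-rank comodulation, renewal spiking, stationary templates.
Real recordings violate all three in places (spike-sorting errors, bursting
and refractory structure, electrode drift, waveform nonstationarity), so
passing here validates the *analysis machinery*, not the biological claims
of any particular dataset.

## Numerical conventions

Sample statistics use the `n-1` denominator throughout (CV, FF, covariance),
matching the covariance definition; whole-recording z-scoring uses the
population (`n`) denominator, where the distinction is immaterial at
thousands of bins. Undefined statistics are NaN sentinels, never zeros. The
Kruskal-Wallis p-value uses the chi-square approximation with tie correction
(a seeded permutation fallback exists for very small groups). Holm
correction ignores NaN p-values and returns flags in input order. All
randomized operations take an explicit integer seed in library mode; only
the CLI has a documented default seed (0).

## Problem sizes in the test suite

The suite exercises recovery at deliberately modest scales — 40-150 units,
200-900 s sessions, 10 seeds per condition, subsamples of 50 units with 10
repetitions — chosen so that each planted effect is comfortably detectable
at those sizes (the margins above were verified at generation time, not
tuned to the assertions). Larger populations only tighten the same
estimates.

## Known limitations

* The consistency procedure assumes the width gap is narrow relative to the
  mode separation; heavily overlapping modes end (correctly) in mass
  unclassification rather than a forced split.
* Concatenated task slices treat six 0.5 s windows as one stationary 3 s
  sample; slow inter-trial drift would inflate the covariance estimate.
* The generator plants no transient bursts or cross-class lags; the
  `balance_coupling` knob moves zero-lag comodulation only.
* PR subsampling assumes exchangeable units; spatially structured arrays
  (shared electrodes, local correlations) break that symmetry in real data.
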