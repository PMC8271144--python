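# spikestate

Behavioral-state-resolved analysis of parallel single-unit spiking activity.

Chronic multielectrode arrays record on the order of a hundred single units
(SUs) at once, across behaviors ranging from quiet rest to instructed
movements. `spikestate` implements the full analysis chain used to
characterize such recordings state by state:

* **Unit classification** — broad-spiking (bs, putative excitatory) vs
  narrow-spiking (ns, putative inhibitory) units from the trough-to-peak
  width of the spike waveform, via a two-threshold rule plus an iterative
  consistency procedure that reconciles mean-waveform and single-waveform
  labels; SNR ≥ 2.5 and mean rate ≥ 1 Hz inclusion filters.
* **Segmentation and slicing** — 1 s-resolution behavioral epochs (rest RS,
  sleepy rest RSS, movement M; task states PP and TM), ±1/0 state vectors,
  equal-length state-homogeneous slices, and 6 × 0.5 s trial concatenation.
* **Single-unit statistics** — firing rate, ISI variability CV and CV2, Fano
  factor FF per state, and the behavioral correlation
  BC ∈ [−1, 1] (Spearman correlation of per-second rate with the state
  vector), with Kruskal–Wallis state tests and Holm correction at α = 0.001.
* **Dimensionality** — spike-count covariance per 3 s slice
  (COV(i,j) = ⟨b_i − m_i, b_j − m_j⟩ / (l − 1) over 100 ms bins) and the
  participation ratio PR = (Σᵢλᵢ)² / Σᵢλᵢ², averaged over random fixed-size
  unit subsamples; sliding-window and bin-size-robustness variants.
* **E/I balance** — Δ(bs, ns), the per-bin difference of globally z-scored
  class population counts (negative = inhibitory domination), and the
  instantaneous balance ρ(bs, ns), the Spearman correlation of raw class
  counts within a slice; timescale sweeps and the ρ–PR correlation.
* **Synthetic sessions** — a generator with planted ground truth (class,
  width, latent dimensionality, modulation sign, E/I coupling) emulating the
  statistical structure the analysis assumes, so every stage is testable
  without real recordings.

See `docs/methods.md` for the estimators, conventions, and generator model.

## Worked example

```python
import numpy as np
from spikestate import *
from spikestate.simulate import SimulationConfig, generate_session

cfg = SimulationConfig(n_units=100, total_duration=300.0, seed=1)
session, truth = generate_session(cfg)

# 1. classify units by trough-to-peak width
widths = [spike_width(ws.mean_waveform, ws.sampling_rate)
          for ws in session.waveform_sets.values()]
th = select_thresholds(widths)                     # Thresholds(0.38, 0.40) ms
results = classify_units(session.waveform_sets, th)
included = filter_units(session.spike_trains, results)

# 2. slice, then per-state dimensionality and balance
slices = cut_slices(session.epochs, 3.0)
labels = {r.unit_id: r.label for r in results if r.label != "unclassified"}
rs = [s for s in slices if s.label == "RS"][:20]
prs = [subsampled_pr(session.spike_trains, s, n_sub=89, n_reps=20, seed=1).pr
       for s in rs]
bal = session_balance(session.spike_trains, labels, rs, 0.0, 300.0, seed=1)
print(np.mean(prs), np.nanmean([r.rho for r in bal]))

# 3. behavioral correlation per unit
sv = build_state_vector(session.epochs, 300.0)
bcs = bc_for_session(session.spike_trains, sv, 300.0, seed=1)
print(sum(r.significant for r in bcs))
```

On this session the automatic thresholds land at (0.38, 0.40) ms and split
the 100 units into 64 bs / 36 ns with none unclassified (the planted width
modes are well separated); all units pass the SNR/rate filters. The
state-resolved summaries come out as

```
RS:  mean PR 6.9 ± 2.2   rho(bs,ns) 0.85   (60 slices)
RSS: mean PR 6.6 ± 2.1   rho(bs,ns) 0.83   (24 slices)
M:   mean PR 5.5 ± 2.2   rho(bs,ns) 0.87   ( 7 slices)
BC:  37/100 units significant, mean BC 0.14
```

i.e. movement slices are lower-dimensional than rest, the two class
populations co-fluctuate tightly (this generator config plants strong
coupling), and about a third of units are significantly state-modulated with
a positive mean BC — movement raises rates more often than rest does.

## Command line

```bash
spikestate simulate --config sim.yaml --seed 1 --out session/
spikestate classify --session session/ --auto-thresholds --out classification.csv
spikestate slice    --session session/ --slice-len 3.0 --out slices.json
spikestate stats    --session session/ --slices slices.json --out res
spikestate network  --session session/ --slices slices.json --n-sub 89 --seed 7 --out pr.csv
spikestate balance  --session session/ --slices slices.json \
                    --classification classification.csv --out balance.csv
```

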