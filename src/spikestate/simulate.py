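"""Synthetic multi-unit sessions with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* a population of ~100-150 units split into narrow-/broad-spiking classes,
  with ns base rates 1.5-2x the bs rates;
* a behavioral state sequence at 1 s scoring resolution (rest / sleepy rest /
  movement, or preparatory / movement for task-like sessions) with geometric
  segment lengths;
* state-dependent rate modulation in a configurable fraction of units
  (about half, in the regime the analysis targets);
* low-rank shared log-normal rate fluctuations whose factor count controls
  the dimensionality of the spike-count covariance;
* a single shared factor loaded onto both classes, scaled by
  ``balance_coupling``, controlling the instantaneous E/I balance;
* bimodal trough-to-peak waveform widths with per-spike jitter and additive
  sample noise at 30 kHz.

Everything is deterministic for a fixed config seed; substreams are keyed per
stage so the stages can also be driven independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import BehaviorEpoch, GroundTruth, SessionRecord, SpikeTrain, WaveformSet

#: Substream keys for the per-stage RNGs.
_STREAM = {"states": 1, "classes": 2, "rates": 3, "spikes": 4, "waveforms": 5}


class ConfigError(ValueError):
    """A simulation parameter is outside its admissible range."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic session.

    Defaults describe a task-free session: 120 units, 40% narrow-spiking with
    a 1.7x rate advantage, a rest/sleepy-rest/movement chain with realistic
    mean dwell times, three latent rate factors, and waveforms at
    signal-to-noise ratio ~5 with well-separated width modes.
    """

    n_units: int = 120
    fraction_ns: float = 0.4
    base_rate_bs: float = 5.0  # Hz
    base_rate_ns: float = 8.5  # Hz; ns:bs ratio 1.7
    state_menu: dict = field(
        default_factory=lambda: {"RS": 20.0, "RSS": 10.0, "M": 5.0}
    )  # label -> mean segment duration (s)
    total_duration: float = 900.0  # s
    n_latent_factors: int = 3
    factor_loading_scale: float = 1.0  # SD of log-rate fluctuation per unit
    latent_resolution: float = 0.1  # s; time step of the latent factors
    fraction_modulated: float = 0.5  # units with state-dependent gain
    fraction_down: float = 0.1  # subset modulated downward during movement
    modulated_gain: float = 2.0  # movement-state gain of upmodulated units
    state_gain: dict | None = None  # explicit {unit_index: {label: gain}} override
    class_state_gain: dict = field(default_factory=dict)  # {label: {class: gain}}
    balance_coupling: float = 0.5  # in [0, 1]
    isi_process: str = "poisson"  # or "gamma"
    gamma_shape: float = 4.0
    width_modes: tuple = ((0.25, 0.03), (0.55, 0.03))  # (mean, SD) ms: ns, bs
    boundary_margin: float = 0.05  # ms around the mode midpoint -> "boundary"
    width_jitter_sd: float = 0.02  # ms, per-spike
    waveform_noise_sd: float = 9.0  # µV, per-sample (SNR ~ 5 at default template)
    max_waveforms: int = 300  # snippets stored per unit
    sampling_rate: float = 30_000.0  # Hz
    rate_floor: float = 0.1  # Hz
    seed: int = 0

    def validate(self) -> None:
        if self.n_units < 1:
            raise ConfigError("n_units must be >= 1")
        if not 0.0 <= self.fraction_ns <= 1.0:
            raise ConfigError("fraction_ns must be in [0, 1]")
        if self.base_rate_bs <= 0 or self.base_rate_ns <= 0:
            raise ConfigError("base rates must be positive")
        if not self.state_menu:
            raise ConfigError("state_menu must be non-empty")
        if any(d < 1.0 for d in self.state_menu.values()):
            raise ConfigError("mean state durations must be at least 1 s")
        if self.total_duration <= 0:
            raise ConfigError("total_duration must be positive")
        if not 0.0 <= self.balance_coupling <= 1.0:
            raise ConfigError("balance_coupling must be in [0, 1]")
        if self.isi_process not in ("poisson", "gamma"):
            raise ConfigError(f"unsupported isi_process {self.isi_process!r}")
        if self.gamma_shape <= 0:
            raise ConfigError("gamma shape must be positive")
        min_width = 2.0 / self.sampling_rate * 1000.0
        for mean, _sd in self.width_modes:
            if mean < min_width:
                raise ConfigError(
                    f"width mode {mean} ms below 2 sample intervals ({min_width:.4f} ms)"
                )
        if any(g < 0 for cls in self.class_state_gain.values() for g in cls.values()):
            raise ConfigError("state gains must be non-negative")
        if self.latent_resolution <= 0 or 1.0 / self.latent_resolution != round(
            1.0 / self.latent_resolution
        ):
            raise ConfigError("latent_resolution must divide 1 s evenly")


def _rng(config: SimulationConfig, stage: str, seed: int | None = None) -> np.random.Generator:
    return np.random.default_rng([seed if seed is not None else config.seed, _STREAM[stage]])


def generate_state_sequence(
    config: SimulationConfig, seed: int | None = None
) -> list[BehaviorEpoch]:
    """Tile ``[0, total_duration)`` with integer-second behavioral epochs.

    Labels follow a first-order chain: segment durations are geometric with
    the configured means (support >= 1 s) and the successor state is drawn
    among the *other* states with probability proportional to their mean
    durations.
    """
    config.validate()
    rng = _rng(config, "states", seed)
    labels = list(config.state_menu)
    means = np.array([config.state_menu[s] for s in labels], dtype=float)
    weights = means / means.sum()
    total = int(np.floor(config.total_duration))

    epochs: list[BehaviorEpoch] = []
    t = 0
    current = labels[rng.choice(len(labels), p=weights)] if len(labels) > 1 else labels[0]
    while t < total:
        mean = config.state_menu[current]
        # geometric on {1, 2, ...} with mean `mean`
        dur = int(rng.geometric(p=min(1.0, 1.0 / mean)))
        dur = min(dur, total - t)
        epochs.append(BehaviorEpoch(current, float(t), float(t + dur)))
        t += dur
        if len(labels) > 1:
            others = [i for i, s in enumerate(labels) if s != current]
            w = np.array([means[i] for i in others])
            current = labels[others[rng.choice(len(others), p=w / w.sum())]]
    # merge adjacent same-label epochs (possible when the menu has one state)
    merged: list[BehaviorEpoch] = []
    for ep in epochs:
        if merged and merged[-1].label == ep.label and merged[-1].stop == ep.start:
            merged[-1] = BehaviorEpoch(ep.label, merged[-1].start, ep.stop)
        else:
            merged.append(ep)
    return merged


def _assign_classes(config: SimulationConfig, seed: int | None = None):
    """Unit ids, class labels, true widths, and state gains."""
    rng = _rng(config, "classes", seed)
    unit_ids = [f"u{i:03d}" for i in range(config.n_units)]
    is_ns = rng.random(config.n_units) < config.fraction_ns
    (ns_mean, ns_sd), (bs_mean, bs_sd) = config.width_modes
    widths = np.where(
        is_ns,
        rng.normal(ns_mean, ns_sd, config.n_units),
        rng.normal(bs_mean, bs_sd, config.n_units),
    )
    min_width = 2.0 / config.sampling_rate * 1000.0
    widths = np.clip(widths, min_width, None)
    midpoint = (ns_mean + bs_mean) / 2.0

    true_class = {}
    for uid, ns_flag, w in zip(unit_ids, is_ns, widths):
        if abs(w - midpoint) < config.boundary_margin:
            true_class[uid] = "boundary"
        else:
            true_class[uid] = "ns" if ns_flag else "bs"

    # state gains: a fraction of units up-modulated during movement states,
    # a smaller fraction down-modulated; the rest state-independent
    gains = {uid: {} for uid in unit_ids}
    move_states = [s for s in config.state_menu if s in ("M", "TM")]
    r = rng.random(config.n_units)
    for i, uid in enumerate(unit_ids):
        if config.state_gain is not None and i in config.state_gain:
            gains[uid] = dict(config.state_gain[i])
            continue
        for ms in move_states:
            if r[i] < config.fraction_modulated * config.fraction_down:
                gains[uid][ms] = 1.0 / config.modulated_gain
            elif r[i] < config.fraction_modulated:
                gains[uid][ms] = config.modulated_gain
    for label, per_class in config.class_state_gain.items():
        for i, uid in enumerate(unit_ids):
            cls = "ns" if is_ns[i] else "bs"
            if cls in per_class:
                gains[uid][label] = gains[uid].get(label, 1.0) * per_class[cls]

    bc_sign = {}
    for uid in unit_ids:
        g_m = gains[uid].get("M", 1.0)
        g_rs = gains[uid].get("RS", 1.0)
        bc_sign[uid] = int(np.sign(g_m - g_rs))
    return unit_ids, is_ns, widths, true_class, gains, bc_sign


def generate_latent_rates(
    config: SimulationConfig,
    epochs: list[BehaviorEpoch],
    is_ns: np.ndarray,
    gains: dict,
    seed: int | None = None,
) -> np.ndarray:
    """Per-unit instantaneous rates (Hz) on the latent time grid.

    rate(u, t) = base(class) * state_gain(u, label(t)) * exp(x_u(t) - v_u/2)
    with x_u(t) a sum of shared Gaussian factors refreshed every
    ``latent_resolution`` seconds: one population-wide factor scaled by
    ``balance_coupling`` plus ``n_latent_factors`` factors with random unit
    loadings (per-unit loading vectors normalized to
    ``factor_loading_scale``). The exp(-v/2) correction keeps the expected
    rate on target; rates are floored at ``rate_floor``. The returned matrix
    is units x steps with step width ``latent_resolution``.
    """
    config.validate()
    rng = _rng(config, "rates", seed)
    n = config.n_units
    per_sec = int(round(1.0 / config.latent_resolution))
    total = int(np.floor(config.total_duration)) * per_sec
    d = config.n_latent_factors

    scale = config.factor_loading_scale
    loadings = []
    if config.balance_coupling > 0:
        loadings.append(np.full(n, config.balance_coupling * scale))
    if d > 0:
        g = rng.normal(size=(n, d))
        norms = np.linalg.norm(g, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        loadings.append(g / norms * scale)
    if loadings:
        L = np.column_stack(loadings)  # n x n_factors
    else:
        L = np.zeros((n, 0))

    z = rng.normal(size=(L.shape[1], total))
    x = L @ z  # n x total
    v = (L**2).sum(axis=1)

    base = np.where(is_ns, config.base_rate_ns, config.base_rate_bs)
    label_at = np.empty(total, dtype=object)
    label_at[:] = "UNCLASSIFIED"
    for ep in epochs:
        label_at[int(ep.start) * per_sec : min(int(ep.stop) * per_sec, total)] = ep.label

    unit_ids = [f"u{i:03d}" for i in range(n)]
    gain_mat = np.ones((n, total))
    for i, uid in enumerate(unit_ids):
        g = gains.get(uid, {})
        if g:
            for label in set(label_at):
                gain_mat[i, label_at == label] = g.get(label, 1.0)

    rates = base[:, None] * gain_mat * np.exp(x - v[:, None] / 2.0)
    if np.any(rates < 0):
        raise ConfigError("negative rate encountered (negative gain?)")
    return np.clip(rates, config.rate_floor, None)


def generate_spikes_from_rates(
    rates: np.ndarray,
    isi_process: str = "poisson",
    seed: int | None = None,
    gamma_shape: float = 4.0,
    t_start: float = 0.0,
    resolution: float = 0.1,
) -> list[SpikeTrain]:
    """Spike trains from piecewise-constant rate rows (step = ``resolution`` s).

    ``poisson`` draws a homogeneous train at each unit's ceiling rate and
    thins it against rate(t)/ceiling -- exact for piecewise-constant rates.
    ``gamma`` warps a unit-rate gamma renewal process (shape k, mean ISI 1)
    through the cumulative rate function (operational time), giving ISI
    CV = 1/sqrt(k) at constant rate.
    """
    if seed is None:
        raise ValueError("spike generation requires an explicit seed")
    if isi_process not in ("poisson", "gamma"):
        raise ValueError(f"unsupported isi_process {isi_process!r}")
    rng = np.random.default_rng([seed, _STREAM["spikes"]])
    n, steps = rates.shape
    duration = steps * resolution
    t_stop = t_start + duration
    trains = []
    for i in range(n):
        r = rates[i]
        if isi_process == "poisson":
            ceiling = float(r.max())
            if ceiling == 0.0:
                trains.append(SpikeTrain(f"u{i:03d}", np.empty(0), t_start, t_stop))
                continue
            n_cand = rng.poisson(ceiling * duration)
            cand = np.sort(rng.uniform(0.0, duration, n_cand))
            idx = np.minimum((cand / resolution).astype(int), steps - 1)
            keep = rng.random(n_cand) < r[idx] / ceiling
            times = cand[keep]
        else:
            cum = np.concatenate([[0.0], np.cumsum(r) * resolution])  # op. time at knots
            lam_total = cum[-1]
            # unit-rate gamma renewal in operational time
            n_est = int(lam_total + 6 * np.sqrt(lam_total / gamma_shape) + 20)
            isis = rng.gamma(gamma_shape, 1.0 / gamma_shape, n_est)
            arr = np.cumsum(isis)
            while arr.size and arr[-1] < lam_total:
                more = rng.gamma(gamma_shape, 1.0 / gamma_shape, n_est)
                arr = np.concatenate([arr, arr[-1] + np.cumsum(more)])
            arr = arr[arr < lam_total]
            knots = np.arange(steps + 1, dtype=float) * resolution
            times = np.interp(arr, cum, knots)
        times = times[(times >= 0) & (times < duration)]
        trains.append(SpikeTrain(f"u{i:03d}", t_start + times, t_start, t_stop))
    return trains


def waveform_template(
    width_ms: float,
    sampling_rate: float = 30_000.0,
    n_samples: int = 48,
    trough_index: int = 15,
    trough_amp: float = 60.0,
    peak_amp: float = 30.0,
) -> np.ndarray:
    """Canonical biphasic extracellular template (µV).

    A Gaussian trough followed by a slower Gaussian peak ``width_ms`` later;
    component widths are narrow relative to the trough-to-peak separation so
    the sampled extrema sit within half a sample of their nominal positions.
    """
    t = np.arange(n_samples) / sampling_rate * 1000.0  # ms
    t0 = trough_index / sampling_rate * 1000.0
    sigma_trough, sigma_peak = 0.06, 0.12
    return -trough_amp * np.exp(-((t - t0) ** 2) / (2 * sigma_trough**2)) + peak_amp * np.exp(
        -((t - t0 - width_ms) ** 2) / (2 * sigma_peak**2)
    )


def generate_waveforms(
    config: SimulationConfig,
    spike_trains: list[SpikeTrain],
    widths: np.ndarray,
    seed: int | None = None,
) -> dict[str, WaveformSet]:
    """Per-unit waveform snippets with per-spike width jitter and noise.

    Stores up to ``max_waveforms`` snippets per unit (at least one, even for
    silent units, so every unit has a measurable mean waveform).
    """
    config.validate()
    rng = _rng(config, "waveforms", seed)
    min_width = 2.0 / config.sampling_rate * 1000.0
    out = {}
    for train, width in zip(spike_trains, widths):
        n_wf = int(max(1, min(train.n_spikes, config.max_waveforms)))
        jitter = rng.normal(0.0, config.width_jitter_sd, n_wf) if config.width_jitter_sd else 0.0
        w = np.clip(width + jitter, min_width, None)
        mat = np.empty((n_wf, 48))
        for k in range(n_wf):
            wk = w[k] if np.ndim(w) else w
            mat[k] = waveform_template(float(wk), config.sampling_rate)
        if config.waveform_noise_sd:
            mat += rng.normal(0.0, config.waveform_noise_sd, mat.shape)
        out[train.unit_id] = WaveformSet(train.unit_id, mat, config.sampling_rate)
    return out


def generate_session(config: SimulationConfig) -> tuple[SessionRecord, GroundTruth]:
    """Compose the generators into a full session with ground truth."""
    config.validate()
    epochs = generate_state_sequence(config)
    unit_ids, is_ns, widths, true_class, gains, bc_sign = _assign_classes(config)
    rates = generate_latent_rates(config, epochs, is_ns, gains)
    trains = generate_spikes_from_rates(
        rates,
        config.isi_process,
        seed=config.seed,
        gamma_shape=config.gamma_shape,
        resolution=config.latent_resolution,
    )
    waveforms = generate_waveforms(config, trains, widths)
    session_type = "R2G" if any(s in config.state_menu for s in ("PP", "TM")) else "REST"
    session = SessionRecord(
        session_id=f"synthetic-{config.seed}",
        session_type=session_type,
        spike_trains=trains,
        waveform_sets=waveforms,
        epochs=epochs,
    )
    truth = GroundTruth(
        true_class=true_class,
        true_width={uid: float(w) for uid, w in zip(unit_ids, widths)},
        planted_dimensionality=config.n_latent_factors
        + (1 if config.balance_coupling > 0 else 0),
        planted_bc_sign=bc_sign,
        planted_balance_coupling=config.balance_coupling,
    )
    return session, truth
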