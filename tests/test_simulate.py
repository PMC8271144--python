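"""Synthetic-session generator: chain, rates, point processes, waveforms."""

import numpy as np
import pytest

from spikestate.classify import Thresholds, classify_units, compute_snr, spike_width
from spikestate.simulate import (
    ConfigError,
    SimulationConfig,
    generate_latent_rates,
    generate_session,
    generate_spikes_from_rates,
    generate_state_sequence,
    generate_waveforms,
)
from spikestate.unit_stats import class_rate_ratio, cv, unit_state_stats


class TestStateSequence:
    def test_single_state_covers_whole_duration(self):
        cfg = SimulationConfig(state_menu={"RS": 20.0}, total_duration=100.0)
        epochs = generate_state_sequence(cfg)
        assert len(epochs) == 1
        assert (epochs[0].start, epochs[0].stop) == (0.0, 100.0)

    def test_fixed_seed_reproducible(self):
        cfg = SimulationConfig(seed=3)
        assert generate_state_sequence(cfg) == generate_state_sequence(cfg)

    def test_epochs_tile_duration_at_integer_seconds(self):
        cfg = SimulationConfig(total_duration=500.0, seed=4)
        epochs = generate_state_sequence(cfg)
        assert epochs[0].start == 0.0 and epochs[-1].stop == 500.0
        for a, b in zip(epochs, epochs[1:]):
            assert a.stop == b.start
            assert a.stop == int(a.stop)

    def test_empirical_mean_durations_match_menu(self):
        # Monte-Carlo check against the configured chain, 15% tolerance
        cfg = SimulationConfig(
            state_menu={"RS": 20.0, "M": 5.0}, total_duration=10_000.0, seed=5
        )
        epochs = generate_state_sequence(cfg)
        for label, mean in cfg.state_menu.items():
            durs = [e.duration for e in epochs if e.label == label]
            assert np.mean(durs) == pytest.approx(mean, rel=0.15)

    def test_submean_duration_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(state_menu={"RS": 0.5}).validate()


class TestLatentRates:
    def _parts(self, cfg):
        from spikestate.simulate import _assign_classes

        epochs = generate_state_sequence(cfg)
        unit_ids, is_ns, widths, true_class, gains, bc_sign = _assign_classes(cfg)
        return epochs, is_ns, gains

    def test_no_factors_unit_gains_give_constant_rows(self):
        cfg = SimulationConfig(
            n_units=10,
            n_latent_factors=0,
            balance_coupling=0.0,
            fraction_modulated=0.0,
            total_duration=50.0,
            seed=6,
        )
        epochs, is_ns, gains = self._parts(cfg)
        rates = generate_latent_rates(cfg, epochs, is_ns, gains)
        assert np.all(rates == rates[:, [0]])

    def test_rate_fluctuation_rank_bounded_by_factor_count(self):
        """Log-rate covariance across units has rank <= n_factors (+1 for the
        shared coupling factor), verified by eigendecomposition."""
        cfg = SimulationConfig(
            n_units=30,
            n_latent_factors=3,
            balance_coupling=0.5,
            fraction_modulated=0.0,
            state_menu={"RS": 20.0},
            total_duration=400.0,
            rate_floor=1e-12,  # keep log-rates exactly low-rank (no clipping)
            seed=7,
        )
        epochs, is_ns, gains = self._parts(cfg)
        rates = generate_latent_rates(cfg, epochs, is_ns, gains)
        logdev = np.log(rates) - np.log(rates).mean(axis=1, keepdims=True)
        eig = np.linalg.eigvalsh(np.cov(logdev))[::-1]
        assert eig[4] < eig[3] * 1e-6  # 4 structural modes, the rest numerical

    def test_full_coupling_correlates_class_means(self):
        cfg = SimulationConfig(
            n_units=40,
            n_latent_factors=0,
            balance_coupling=1.0,
            fraction_modulated=0.0,
            state_menu={"RS": 20.0},
            total_duration=500.0,
            seed=8,
        )
        epochs, is_ns, gains = self._parts(cfg)
        rates = generate_latent_rates(cfg, epochs, is_ns, gains)
        bs_mean = rates[~is_ns].mean(axis=0)
        ns_mean = rates[is_ns].mean(axis=0)
        assert np.corrcoef(bs_mean, ns_mean)[0, 1] > 0.9

    def test_rate_floor_enforced(self):
        cfg = SimulationConfig(n_units=5, total_duration=30.0, seed=9)
        epochs, is_ns, gains = self._parts(cfg)
        rates = generate_latent_rates(cfg, epochs, is_ns, gains)
        assert rates.min() >= cfg.rate_floor


class TestSpikeGeneration:
    def test_poisson_count_within_four_sd(self):
        rates = np.full((1, 10_000), 10.0)
        (tr,) = generate_spikes_from_rates(rates, "poisson", seed=10, resolution=1.0)
        expected, sd = 100_000, np.sqrt(100_000)
        assert abs(tr.n_spikes - expected) < 4 * sd

    def test_poisson_tracks_rate_profile(self):
        rates = np.concatenate([np.full(500, 2.0), np.full(500, 20.0)])[None, :]
        (tr,) = generate_spikes_from_rates(rates, "poisson", seed=11, resolution=1.0)
        first = np.sum(tr.spike_times < 500)
        second = tr.n_spikes - first
        assert second / first == pytest.approx(10.0, rel=0.2)

    def test_gamma_renewal_cv_closed_form(self):
        # gamma(k): ISI CV = 1/sqrt(k)
        rates = np.full((1, 3000), 10.0)
        (tr,) = generate_spikes_from_rates(
            rates, "gamma", seed=12, gamma_shape=4.0, resolution=1.0
        )
        assert cv(np.diff(tr.spike_times)) == pytest.approx(0.5, abs=0.03)

    def test_unsupported_process_rejected(self):
        with pytest.raises(ValueError):
            generate_spikes_from_rates(np.ones((1, 10)), "weibull", seed=0)

    def test_rate_floor_keeps_units_spiking(self):
        # at the 0.1 Hz floor a 10,000 s session is silent with p ~ e^-1000
        rates = np.full((5, 10_000), 0.1)
        trains = generate_spikes_from_rates(rates, "poisson", seed=13, resolution=1.0)
        assert all(t.n_spikes > 0 for t in trains)


class TestWaveforms:
    def test_noiseless_width_recovery_within_one_sample(self):
        cfg = SimulationConfig(
            n_units=20, total_duration=30.0, width_jitter_sd=0.0, waveform_noise_sd=0.0, seed=14
        )
        session, truth = generate_session(cfg)
        for uid, ws in session.waveform_sets.items():
            measured = spike_width(ws.mean_waveform, ws.sampling_rate)
            assert measured == pytest.approx(truth.true_width[uid], abs=1.0 / 30.0)

    def test_snr_matches_construction(self):
        # noise SD set for SNR ~ 5 under the adopted definition
        cfg = SimulationConfig(n_units=15, total_duration=60.0, seed=15)
        session, _ = generate_session(cfg)
        snrs = [compute_snr(ws) for ws in session.waveform_sets.values()]
        assert all(4.0 <= s <= 6.0 for s in snrs)

    def test_width_histogram_bimodal(self):
        cfg = SimulationConfig(n_units=120, total_duration=30.0, seed=16)
        session, _ = generate_session(cfg)
        widths = np.array(
            [
                spike_width(ws.mean_waveform, ws.sampling_rate)
                for ws in session.waveform_sets.values()
            ]
        )
        near_ns = np.sum(np.abs(widths - 0.25) < 0.1)
        near_bs = np.sum(np.abs(widths - 0.55) < 0.1)
        in_valley = np.sum(np.abs(widths - 0.40) < 0.04)
        assert near_ns > 10 and near_bs > 10
        assert in_valley < min(near_ns, near_bs) / 3

    def test_too_narrow_mode_rejected(self):
        with pytest.raises(ConfigError, match="sample intervals"):
            SimulationConfig(width_modes=((0.03, 0.01), (0.55, 0.03))).validate()


class TestComposedSession:
    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(n_units=10, total_duration=60.0, seed=17)
        s1, t1 = generate_session(cfg)
        s2, t2 = generate_session(cfg)
        assert s1 == s2 and t1 == t2

    def test_no_ns_units_when_fraction_zero(self):
        cfg = SimulationConfig(n_units=20, fraction_ns=0.0, total_duration=30.0, seed=18)
        _, truth = generate_session(cfg)
        assert "ns" not in set(truth.true_class.values())

    def test_bc_sign_consistent_with_gains(self):
        from spikestate.simulate import _assign_classes

        cfg = SimulationConfig(n_units=50, total_duration=30.0, seed=19)
        _, _, _, _, gains, bc_sign = _assign_classes(cfg)
        for uid, sign in bc_sign.items():
            g_m = gains[uid].get("M", 1.0)
            g_rs = gains[uid].get("RS", 1.0)
            assert sign == np.sign(g_m - g_rs)

    def test_class_rate_ratio_recovered(self):
        """Planted ns:bs base-rate ratio of 1.7 estimated within [1.4, 2.0]."""
        from spikestate.slicing import cut_slices

        cfg = SimulationConfig(n_units=100, total_duration=900.0, max_waveforms=1, seed=20)
        session, truth = generate_session(cfg)
        labels = {u: c for u, c in truth.true_class.items() if c in ("bs", "ns")}
        slices = cut_slices(session.epochs, 3.0, labels=("RS",))
        stats = [unit_state_stats(t, slices, "RS") for t in session.spike_trains]
        ratio = class_rate_ratio(stats, labels, "RS")
        assert 1.4 <= ratio <= 2.0

    def test_positive_bc_sign_recovered(self):
        """Units with a planted movement gain >= 1.5 show positive estimated BC."""
        from spikestate.slicing import build_state_vector
        from spikestate.unit_stats import bc_for_session

        cfg = SimulationConfig(n_units=60, max_waveforms=1, seed=21)
        session, truth = generate_session(cfg)
        dur = session.t_stop - session.t_start
        sv = build_state_vector(session.epochs, dur)
        bcs = {r.unit_id: r for r in bc_for_session(session.spike_trains, sv, dur, seed=0)}
        up = [u for u, s in truth.planted_bc_sign.items() if s > 0]
        assert up, "fixture must contain up-modulated units"
        positive = [u for u in up if bcs[u].bc > 0 and bcs[u].significant]
        assert len(positive) / len(up) >= 0.9
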