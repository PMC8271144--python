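"""Spike-width measurement, SNR, thresholds, and the consistency procedure."""

import numpy as np
import pytest

from spikestate.classify import (
    Thresholds,
    WidthError,
    classify_units,
    compute_snr,
    filter_units,
    select_thresholds,
    spike_width,
)
from spikestate.model import SpikeTrain, WaveformSet
from spikestate.simulate import SimulationConfig, generate_session, waveform_template

FS = 30_000.0


def _waveform(trough: int, peak: int, n: int = 64) -> np.ndarray:
    w = np.zeros(n)
    w[trough] = -10.0
    w[peak] = 5.0
    return w


class TestSpikeWidth:
    def test_trough_to_peak_arithmetic(self):
        # trough sample 30, peak sample 42 at 30 kHz -> 0.4 ms
        assert spike_width(_waveform(30, 42), FS) == pytest.approx(0.4)

    def test_monotone_waveform_has_no_width(self):
        with pytest.raises(WidthError):
            spike_width(np.arange(10.0), FS)

    def test_pre_trough_peak_ignored(self):
        w = _waveform(30, 42)
        w[5] = 100.0  # capacitive artifact before the trough must not win
        assert spike_width(w, FS) == pytest.approx(0.4)

    def test_planted_template_width_recovered_noiselessly(self):
        for width in (0.25, 0.4, 0.55):
            w = waveform_template(width, FS)
            assert spike_width(w, FS) == pytest.approx(width, abs=1.0 / 30.0)


class TestSNR:
    def test_adopted_definition_direct_evaluation(self):
        # mean waveform ptp 100 with residual SD 10 at every sample -> 5.0
        rng = np.random.default_rng(0)
        base = np.zeros(200)
        base[50], base[60] = -60.0, 40.0
        n = 4000
        noise = rng.normal(0, 10.0, (n, 200))
        noise -= noise.mean(axis=0)  # exact zero-mean so ptp is exact
        ws = WaveformSet("u", base + noise, FS)
        sd = np.std(ws.waveforms - base, axis=0, ddof=1).mean()
        assert compute_snr(ws) == pytest.approx(100.0 / (2 * sd))
        assert compute_snr(ws) == pytest.approx(5.0, rel=0.05)

    def test_flat_identical_waveforms_snr_zero(self):
        ws = WaveformSet("u", np.zeros((3, 10)), FS)
        assert compute_snr(ws) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(0, 1, (20, 30)) + np.linspace(-5, 5, 30)
        a = compute_snr(WaveformSet("u", mat, FS))
        b = compute_snr(WaveformSet("u", 2.0 * mat, FS))
        assert a == pytest.approx(b)

    def test_identical_nonflat_waveforms_infinite(self):
        mat = np.tile(_waveform(3, 6, 10), (3, 1))
        with pytest.warns(UserWarning):
            assert np.isinf(compute_snr(WaveformSet("u", mat, FS)))


class TestThresholds:
    def test_manual_thresholds_returned_verbatim(self):
        th = Thresholds(0.40, 0.41)
        assert (th.theta_ns, th.theta_bs) == (0.40, 0.41)
        assert th.preliminary_label(0.405) == "unclassified"
        assert th.preliminary_label(0.39) == "ns"
        assert th.preliminary_label(0.42) == "bs"

    def test_valley_found_between_planted_modes(self):
        rng = np.random.default_rng(2)
        widths = np.concatenate(
            [rng.normal(0.25, 0.03, 60), rng.normal(0.55, 0.03, 60)]
        )
        th = select_thresholds(widths)
        assert 0.30 < th.theta_ns < 0.50
        # narrow gap straddling the valley, reported on the 0.01 ms grid
        assert 0.01 <= round(th.theta_bs - th.theta_ns, 6) <= 0.02

    def test_unimodal_distribution_instructs_manual(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="manual"):
            select_thresholds(rng.normal(0.4, 0.02, 100))

    def test_identical_widths_rejected(self):
        with pytest.raises(ValueError):
            select_thresholds(np.full(30, 0.4))


def _unit_ws(widths_ms):
    mat = np.stack([waveform_template(w, FS) for w in np.atleast_1d(widths_ms)])
    return WaveformSet("u", mat, FS)


class TestConsistencyClassification:
    TH = Thresholds(0.40, 0.41)

    def test_unanimous_broad_unit(self):
        ws = {"u": _unit_ws([0.5, 0.5, 0.5])}
        (res,) = classify_units(ws, self.TH)
        assert res.label == "bs" and res.consistency == 1.0

    def test_mean_width_in_gap_always_unclassified(self):
        # mean in the gap stays unclassified no matter how consistent
        ws = {"u": _unit_ws([0.405] * 5)}
        (res,) = classify_units(ws, self.TH)
        assert res.label == "unclassified"

    def test_contradictory_unit_forces_higher_consistency(self):
        """A step-1 bs unit whose single waveforms are mostly narrow raises
        the minimal consistency until it drops out; coherent units stay."""
        # 11 narrow snippets with small peaks, 9 broad with large peaks: the
        # mean waveform is broad (step 1 bs) but c = 9/20 = 0.45 (step 2 ns)
        narrow = _waveform(30, 39)  # 0.3 ms
        broad = _waveform(30, 58)  # ~0.93 ms
        broad[58] = 20.0
        contradictory = WaveformSet("x", np.stack([narrow] * 11 + [broad] * 9), FS)
        assert spike_width(contradictory.mean_waveform, FS) > 0.41
        coherent_bs = _unit_ws([0.55] * 20)
        coherent_ns = _unit_ws([0.25] * 20)
        ws = {"x": contradictory, "b": coherent_bs, "n": coherent_ns}
        results = {r.unit_id: r for r in classify_units(ws, self.TH)}
        assert results["x"].label == "unclassified"
        assert results["x"].consistency == pytest.approx(0.45)
        assert results["b"].label == "bs"
        assert results["n"].label == "ns"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        ws = {
            f"u{i}": _unit_ws(rng.normal(0.25 if i % 2 else 0.55, 0.02, 10))
            for i in range(8)
        }
        a = {r.unit_id: r.label for r in classify_units(ws, self.TH)}
        shuffled = dict(reversed(list(ws.items())))
        b = {r.unit_id: r.label for r in classify_units(shuffled, self.TH)}
        assert a == b

    def test_noiseless_synthetic_recovery_is_exact(self):
        cfg = SimulationConfig(
            n_units=40,
            total_duration=60.0,
            width_jitter_sd=0.0,
            waveform_noise_sd=0.0,
            seed=5,
        )
        session, truth = generate_session(cfg)
        results = classify_units(session.waveform_sets, self.TH)
        for r in results:
            if truth.true_class[r.unit_id] != "boundary":
                assert r.label == truth.true_class[r.unit_id]

    def test_noise_pulls_consistency_toward_half(self):
        """Mean |c - 0.5| shrinks as waveform noise grows."""
        def mean_strength(noise_sd, seed=6):
            cfg = SimulationConfig(
                n_units=30,
                total_duration=60.0,
                width_modes=((0.38, 0.01), (0.43, 0.01)),
                waveform_noise_sd=noise_sd,
                seed=seed,
            )
            session, _ = generate_session(cfg)
            res = classify_units(session.waveform_sets, self.TH)
            cs = [abs(r.consistency - 0.5) for r in res if np.isfinite(r.consistency)]
            return np.mean(cs)

        assert mean_strength(40.0) < mean_strength(1.0)


class TestInclusionFilters:
    def _train(self, rate, duration=10.0):
        times = np.arange(0, duration, 1.0 / rate)[: int(rate * duration)]
        return SpikeTrain("u", times, 0.0, duration)

    @pytest.mark.parametrize(
        "snr,rate,expect",
        [(2.4, 5.0, False), (3.0, 0.5, False), (3.0, 2.0, True), (2.5, 1.0, True)],
    )
    def test_snr_and_rate_cutoffs(self, snr, rate, expect):
        from spikestate.classify import UnitClassification

        cl = UnitClassification("u", 0.5, "unclassified", 1.0, snr)
        included = filter_units([self._train(rate)], [cl])
        assert (("u" in included) is expect) and (cl.included is expect)

    def test_inclusion_independent_of_label(self, default_session):
        session, _ = default_session
        th = Thresholds(0.40, 0.41)
        results = classify_units(session.waveform_sets, th)
        filter_units(session.spike_trains, results)
        labels_of_included = {r.label for r in results if r.included}
        # high-SNR synthetic session: inclusion must not depend on class
        assert any(r.included for r in results)
        for r in results:
            assert r.included == (
                r.snr >= 2.5 and session.train(r.unit_id).mean_rate() >= 1.0
            )
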