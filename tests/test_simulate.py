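"""Generator properties: determinism, timeline statistics, forward-model closure."""

import numpy as np
import pytest

import natattn as na
from natattn.epoching import block_average
from natattn.preprocess import intensity_to_od, mbll
from natattn.simulate import (
    double_gamma_hrf,
    latent_concentrations,
    read_recording_csv,
    read_recording_snirf,
    write_recording_csv,
    write_recording_snirf,
)


def quiet_cfg(**kw):
    base = dict(
        seed=5,
        noise=na.NoiseSpec().disabled(),
        artifact=na.ArtifactSpec().disabled(),
        effect_between_sd_uM=0.0,
    )
    base.update(kw)
    return na.SimConfig(**base)


class TestBehaviorTimeline:
    def test_zero_session_gives_empty_timeline(self):
        assert na.simulate_behavior(na.SimConfig(session_length_s=0.0), "p01") == []

    def test_negative_session_rejected(self):
        with pytest.raises(ValueError):
            na.SimConfig(session_length_s=-10.0)

    def test_seed_determinism(self):
        cfg = na.SimConfig(seed=1)
        assert na.simulate_behavior(cfg, "p03") == na.simulate_behavior(cfg, "p03")
        assert na.simulate_behavior(cfg, "p03") != na.simulate_behavior(cfg, "p04")

    def test_bouts_sorted_and_non_overlapping(self):
        bouts = na.simulate_behavior(na.SimConfig(seed=2), "p01")
        for a, b in zip(bouts, bouts[1:]):
            assert b.start_s >= a.end_s
            assert a.end_s <= 1200.0

    def test_toy_duration_matches_lognormal_mean(self):
        """Monte-Carlo mean of toy bout durations vs the closed-form lognormal mean."""
        cfg = na.SimConfig(seed=3, session_length_s=1200.0)
        durs = []
        i = 0
        while len(durs) < 10_000:
            durs.extend(
                b.duration_s
                for b in na.simulate_behavior(cfg, f"mc{i}")
                if b.target == "toy"
            )
            i += 1
        durs = np.array(durs[:10_000])
        mu, sigma = cfg.bout_duration_lognorm
        true_mean = np.exp(mu + sigma**2 / 2)
        true_sd = true_mean * np.sqrt(np.exp(sigma**2) - 1.0)
        se = true_sd / np.sqrt(durs.size)
        # session truncation slightly favours shorter bouts; 3 SE still holds
        assert abs(durs.mean() - true_mean) < 3 * se

    def test_toy_dominant_targets(self):
        bouts = []
        for i in range(20):
            bouts += na.simulate_behavior(na.SimConfig(seed=4), f"p{i:02d}")
        toy_frac = np.mean([b.target == "toy" for b in bouts])
        assert 0.6 < toy_frac < 0.8


class TestForwardModel:
    def test_null_signal_flat_recording(self):
        cfg = quiet_cfg(effect_amplitude_uM=0.0)
        bouts = na.simulate_behavior(cfg, "p01")
        rec, gt = na.simulate_recording(cfg, bouts, "p01")
        assert np.allclose(rec.intensity, cfg.baseline_intensity)
        assert np.all(gt.latent_hbo == 0.0)

    def test_recording_determinism(self):
        cfg = na.SimConfig(seed=9)
        bouts = na.simulate_behavior(cfg, "p01")
        r1, _ = na.simulate_recording(cfg, bouts, "p01")
        r2, _ = na.simulate_recording(cfg, bouts, "p01")
        np.testing.assert_array_equal(r1.intensity, r2.intensity)

    def test_inactive_channels_have_zero_latent(self):
        cfg = quiet_cfg()
        bouts = na.simulate_behavior(cfg, "p01")
        _, gt = na.simulate_recording(cfg, bouts, "p01")
        inactive = sorted(set(range(cfg.n_channels)) - cfg.active_channels)
        assert np.all(gt.latent_hbo[inactive] == 0.0)
        assert np.any(gt.latent_hbo[sorted(cfg.active_channels)] > 0.0)

    def test_hbr_is_scaled_negative_copy(self):
        cfg = quiet_cfg()
        bouts = na.simulate_behavior(cfg, "p01")
        _, gt = na.simulate_recording(cfg, bouts, "p01")
        np.testing.assert_allclose(gt.latent_hbr, -gt.latent_hbo / 3.0)

    def test_beer_lambert_round_trip(self):
        """Forward optics then OD->MBLL recovers the latent series (noise off)."""
        cfg = quiet_cfg()
        bouts = na.simulate_behavior(cfg, "p01")
        rec, gt = na.simulate_recording(cfg, bouts, "p01")
        hbo, _ = mbll(intensity_to_od(rec))
        truth = gt.latent_hbo - gt.latent_hbo.mean(axis=1, keepdims=True)
        rms_err = np.sqrt(np.mean((hbo - truth) ** 2))
        rms_sig = np.sqrt(np.mean(truth[sorted(cfg.active_channels)] ** 2))
        assert rms_err / rms_sig < 0.01

    def test_round_trip_peak_amplitude_within_1pct(self):
        cfg = quiet_cfg()
        bouts = [na.LookBout("p01", "toy", 100.0, 112.0)]
        rec, gt = na.simulate_recording(cfg, bouts, "p01")
        hbo, _ = mbll(intensity_to_od(rec))
        ch = min(cfg.active_channels)
        # latent peak vs recovered peak (mean-offset removed in both)
        lat = gt.latent_hbo[ch] - gt.latent_hbo[ch].mean()
        assert abs(hbo[ch].max() - lat.max()) / lat.max() < 0.01

    def test_event_locked_latent_equals_analytic_convolution(self):
        """Recompute the latent series independently with numpy convolution."""
        cfg = quiet_cfg()
        bouts = [
            na.LookBout("p01", "toy", 50.0, 60.0),
            na.LookBout("p01", "toy", 200.0, 213.0),
        ]
        hbo, _ = latent_concentrations(cfg, bouts)
        fs = cfg.sample_rate_hz
        n_t = int(cfg.session_length_s * fs)
        kern = double_gamma_hrf(np.arange(0, 32, 1 / fs))
        expected = np.zeros(n_t)
        for b in bouts:
            box = np.zeros(n_t)
            box[int((b.start_s + 5.0) * fs) : int(b.end_s * fs)] = 1.0
            r = np.convolve(box, kern)[:n_t]
            expected += r / r.max() * cfg.effect_amplitude_uM * 1e-6
        np.testing.assert_allclose(hbo[min(cfg.active_channels)], expected)

    def test_block_average_peak_latency_in_expected_window(self):
        """HRF lag 5 s into the look + ~5.5 s peak delay puts the group peak
        5-12 s after the +3 s shifted onset."""
        cfg = quiet_cfg()
        runs = na.simulate_study(cfg, raw=True)
        hb = {pid: na.preprocess(rec, motion_correction=False) for pid, _, rec, _ in runs}
        bouts = [b for _, pb, _, _ in runs for b in pb]
        events = na.exclude_short_isi(na.apply_shift(na.extract_events(na.merge_bouts(bouts))))
        blocks = []
        for pid, series in hb.items():
            blocks.extend(na.extract_blocks(series, [e for e in events if e.participant_id == pid]))
        resp = na.peak_window_mean(blocks)
        lat = resp[resp.channel.isin(cfg.active_channels)].peak_latency_s.unique()
        assert np.all((lat >= 5.0) & (lat <= 12.0))


class TestHrfKernel:
    def test_unit_peak_at_requested_delay(self):
        t = np.arange(0, 32, 0.2)
        h = double_gamma_hrf(t, peak_delay_s=5.5)
        assert h.max() == pytest.approx(1.0)
        assert t[np.argmax(h)] == pytest.approx(5.5, abs=0.2)

    def test_undershoot_is_negative_and_late(self):
        t = np.arange(0, 32, 0.2)
        h = double_gamma_hrf(t)
        assert h[t > 12].min() < 0


class TestSerialization:
    def test_csv_round_trip(self, tmp_path):
        cfg = quiet_cfg(n_channels=4, session_length_s=60.0, active_channels=frozenset({1}))
        rec, _ = na.simulate_recording(cfg, [na.LookBout("p01", "toy", 10.0, 20.0)], "p01")
        path = tmp_path / "rec.csv"
        write_recording_csv(rec, path)
        back = read_recording_csv(path, participant_id="p01")
        np.testing.assert_allclose(back.intensity, rec.intensity)
        assert back.sample_rate_hz == pytest.approx(5.0)

    def test_snirf_round_trip(self, tmp_path):
        cfg = quiet_cfg(n_channels=4, session_length_s=60.0, active_channels=frozenset({1}))
        rec, _ = na.simulate_recording(cfg, [na.LookBout("p01", "toy", 10.0, 20.0)], "p01")
        path = tmp_path / "rec.snirf"
        write_recording_snirf(rec, path)
        back = read_recording_snirf(path)
        np.testing.assert_allclose(back.intensity, rec.intensity)
        assert back.participant_id == "p01"
        assert back.wavelengths_nm == rec.wavelengths_nm
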