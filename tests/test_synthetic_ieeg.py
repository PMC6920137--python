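"""Synthetic iEEG generator: waveforms, scheduling, and the
generator-detector consistency contract."""

import numpy as np
import pytest

import epievents as ep
from epievents.baseline_detector import EventLabel
from epievents.synthetic_ieeg import (RIPPLE_PASSBANDS, _snap_ripple_freq,
                                      spike_peak_offset)


class TestBackground:
    def test_one_over_f_spectral_slope(self):
        from scipy import signal, stats
        fs = 500.0
        x = ep.make_background(60.0, fs, alpha=1.0, rms=20.0, seed=0)
        f, pxx = signal.welch(x, fs=fs, nperseg=4096)
        m = (f >= 4) & (f <= 200)
        slope = stats.linregress(np.log(f[m]), np.log(pxx[m])).slope
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_exact_target_rms(self):
        x = ep.make_background(30.0, 500.0, 1.0, 20.0, seed=1)
        assert np.sqrt(np.mean(x ** 2)) == pytest.approx(20.0, rel=1e-9)

    def test_rms_doubling_quadruples_band_power(self):
        x1 = ep.make_background(30.0, 500.0, 1.0, 20.0, seed=2)
        x2 = ep.make_background(30.0, 500.0, 1.0, 40.0, seed=2)
        p1 = ep.band_spectrogram(ep.EegRecord(x1[None], 500.0, ["A"])).power
        p2 = ep.band_spectrogram(ep.EegRecord(x2[None], 500.0, ["A"])).power
        np.testing.assert_allclose(p2, 4.0 * p1, rtol=1e-9)

    def test_reproducible_from_seed(self):
        a = ep.make_background(15.0, 500.0, 1.0, 20.0, seed=3)
        b = ep.make_background(15.0, 500.0, 1.0, 20.0, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            ep.make_background(15.0, 500.0, alpha=3.0, rms=20.0)


class TestWaveforms:
    def test_spike_peak_and_near_zero_mean(self):
        w = ep.make_spike(40.0, 150.0, 500.0)
        assert np.abs(w).max() == pytest.approx(150.0)
        assert abs(w.mean()) < 1e-9 * 150.0

    def test_spike_zero_amplitude(self):
        assert np.all(ep.make_spike(40.0, 0.0, 500.0) == 0)

    @pytest.mark.parametrize("bad", [10.0, 80.0])
    def test_spike_duration_bounds(self, bad):
        with pytest.raises(ValueError, match="20-70"):
            ep.make_spike(bad, 100.0, 500.0)

    def test_ripple_duration_is_cycles_over_freq(self):
        w = ep.make_ripple(150.0, 6, 80.0, 500.0)
        assert len(w) == int(round(6 / 150.0 * 500.0))

    def test_ripple_three_cycles_rejected(self):
        with pytest.raises(ValueError, match="3 oscillation cycles"):
            ep.make_ripple(150.0, 3, 80.0, 500.0)

    def test_ripple_in_gap_rejected(self):
        with pytest.raises(ValueError, match="passband"):
            ep.make_ripple(180.0, 6, 80.0, 500.0)

    def test_snap_into_passband(self):
        assert 124 + 3 <= _snap_ripple_freq(120.0) < 176
        for lo, hi in RIPPLE_PASSBANDS:
            f = _snap_ripple_freq((lo + hi) / 2)
            assert lo <= f < hi


class TestDetectorOracleOnWaveforms:
    """Generator-detector consistency at the single-event level: the
    thresholds used for candidate screening recover the injected class."""

    def test_spike_triggers_beta_gamma_not_ripple(self, spike_trials):
        idx = ep.DEFAULT_BANDS
        n_spike_criterion = sum(
            rp[idx.index("beta")] >= 4
            and max(rp[idx.index("gamma1")], rp[idx.index("gamma2")]) >= 4
            for _, rp, _, _, _ in spike_trials)
        n_ripple_quiet = sum(
            max(rp[idx.index(r)] for r in ("rip1", "rip2", "rip3")) < 7
            for _, rp, _, _, _ in spike_trials)
        assert n_spike_criterion >= 95
        assert n_ripple_quiet >= 95

    def test_ripple_triggers_ripple_not_spike(self, ripple_trials):
        idx = ep.DEFAULT_BANDS
        n_ripple = sum(
            max(rp[idx.index(r)] for r in ("rip1", "rip2", "rip3")) >= 7
            for _, rp, _, _, _ in ripple_trials)
        n_spike_quiet = sum(
            not (rp[idx.index("beta")] >= 4
                 and max(rp[idx.index("gamma1")], rp[idx.index("gamma2")]) >= 4)
            for _, rp, _, _, _ in ripple_trials)
        assert n_ripple >= 95
        assert n_spike_quiet >= 95


class TestGenerateSubject:
    def test_rates_give_poisson_like_counts(self):
        spec = ep.SyntheticSpec(n_channels=2, segment_duration=600.0,
                                spike_rate=2.0, ripple_rate=2.0, rons_rate=2.0,
                                seed=0)
        _, log = ep.generate_subject(spec, 0)
        counts = log.counts()
        for lab in ("spike", "ripple", "rons"):
            # expectation 20 per class; allow a generous Poisson band
            assert 8 <= counts.get(lab, 0) <= 40

    def test_events_separated_by_one_second(self):
        spec = ep.SyntheticSpec(n_channels=2, segment_duration=300.0,
                                spike_rate=10.0, ripple_rate=10.0,
                                rons_rate=10.0, seed=1)
        _, log = ep.generate_subject(spec, 0)
        evs = sorted(log, key=lambda i: i.onset_s)
        for a, b in zip(evs, evs[1:]):
            assert b.onset_s >= a.onset_s + a.duration_s + 1.0 - 1e-9

    def test_zero_rons_rate_empty_cell(self):
        spec = ep.SyntheticSpec(n_channels=2, segment_duration=120.0, seed=2)
        _, log = ep.generate_subject(spec, 0, include_rons=False)
        assert "rons" not in log.counts()
        assert log.counts().get("spike", 0) > 0

    def test_subjects_differ_in_morphology_not_structure(self):
        spec = ep.SyntheticSpec(n_channels=1, segment_duration=120.0, seed=3)
        rec0, log0 = ep.generate_subject(spec, 0)
        rec1, log1 = ep.generate_subject(spec, 1)
        assert not np.array_equal(rec0.samples, rec1.samples)
        assert set(log0.counts()) == set(log1.counts())
        # different amplitude offsets
        a0 = np.mean([i.amplitude for i in log0 if i.label is EventLabel.SPIKE])
        a1 = np.mean([i.amplitude for i in log1 if i.label is EventLabel.SPIKE])
        assert a0 != pytest.approx(a1, rel=0.01)

    def test_reproducible_from_spec_and_index(self):
        spec = ep.SyntheticSpec(n_channels=1, segment_duration=60.0, seed=4)
        r1, l1 = ep.generate_subject(spec, 0)
        r2, l2 = ep.generate_subject(spec, 0)
        np.testing.assert_array_equal(r1.samples, r2.samples)
        assert [i.onset_s for i in l1] == [i.onset_s for i in l2]

    def test_line_noise_confined_to_the_gap(self):
        """60 Hz interference sits in the gamma1/gamma2 gap: every band
        except the gap-adjacent gamma2 edge bin is untouched (< 1%), and —
        because a steady tone inflates a band's baseline by the same amount
        as every bin — the relative-threshold detection is unchanged."""
        kw = dict(n_channels=1, segment_duration=120.0, seed=5,
                  spike_rate=3.0, ripple_rate=3.0, rons_rate=3.0)
        r0, log0 = ep.generate_subject(ep.SyntheticSpec(**kw), 0)
        r1, log1 = ep.generate_subject(
            ep.SyntheticSpec(line_noise_amp=20.0, **kw), 0)
        assert [i.onset_s for i in log0] == [i.onset_s for i in log1]
        p0 = ep.band_spectrogram(r0).power.mean(axis=2)
        p1 = ep.band_spectrogram(r1).power.mean(axis=2)
        g2 = ep.DEFAULT_BANDS.index("gamma2")
        keep = [i for i in range(8) if i != g2]
        np.testing.assert_allclose(p1[:, keep], p0[:, keep], rtol=0.01)
        # detection labels identical with and without interference
        labs = []
        for rec in (r0, r1):
            bs = ep.band_spectrogram(ep.preprocess(rec))
            rel = ep.normalize(bs, ep.compute_baseline(bs))
            labs.append([c.label for c in ep.detect_candidates(rel)])
        assert labs[0] == labs[1]

    def test_rons_contains_ripple_frequency(self):
        spec = ep.SyntheticSpec(n_channels=1, segment_duration=300.0,
                                spike_rate=0, ripple_rate=0, rons_rate=6.0,
                                seed=6)
        _, log = ep.generate_subject(spec, 0)
        assert len(log) > 0
        for inj in log:
            assert inj.label is EventLabel.RONS
            assert any(lo <= inj.centre_freq < hi for lo, hi in RIPPLE_PASSBANDS)


class TestGeneratorDetectorContract:
    def test_injected_events_recovered_with_correct_class(self):
        """Core calibration: with default amplitudes (spikes 8-12x SD,
        ripples 4-6x SD, alpha=1 background) the threshold detector finds
        >= 90% of injections at the correct bin +/-1 with the correct
        class, over 10 seeds."""
        hits = total = 0
        for seed in range(10):
            spec = ep.SyntheticSpec(n_channels=2, segment_duration=120.0,
                                    spike_rate=4.0, ripple_rate=4.0,
                                    rons_rate=4.0, seed=seed)
            rec, log = ep.generate_subject(spec, 0)
            rec = ep.preprocess(rec)
            bs = ep.band_spectrogram(rec)
            rel = ep.normalize(bs, ep.compute_baseline(bs))
            nb = {(c.channel, c.bin): c.label
                  for c in ep.detect_candidates(rel)}
            for inj in log:
                b = ep.injection_bin(inj.onset_s, inj.duration_s,
                                     rel.bin_duration, rel.hop_s)
                found = [nb.get((inj.channel, bb)) for bb in (b - 1, b, b + 1)]
                hits += inj.label in found
                total += 1
        assert total > 100
        assert hits / total >= 0.90


class TestFixtures:
    def test_edf_roundtrip_quantization(self, tmp_path):
        spec = ep.SyntheticSpec(n_channels=3, segment_duration=20.0, seed=7)
        rec, log = ep.generate_subject(spec, 0)
        edf, csvp = ep.write_fixture(rec, log, tmp_path / "s.edf")
        back = ep.read_edf(edf)
        assert back.fs == rec.fs
        assert back.n_channels == 3
        amax = np.ceil(np.abs(rec.samples).max())
        lsb = 2 * amax / 65535
        err = np.abs(back.samples[:, :rec.n_times] - rec.samples).max()
        assert err <= lsb

    def test_injection_log_csv_roundtrip(self, tmp_path):
        spec = ep.SyntheticSpec(n_channels=2, segment_duration=60.0, seed=8)
        _, log = ep.generate_subject(spec, 0)
        path = tmp_path / "log.csv"
        log.to_csv(path)
        back = ep.InjectionLog.from_csv(path)
        assert len(back) == len(log)
        assert sum(1 for _ in open(path)) == len(log) + 1
        for a, b in zip(log, back):
            assert a.label == b.label
            assert a.onset_s == pytest.approx(b.onset_s, abs=1e-4)
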