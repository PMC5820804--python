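"""QEEG index computation: filtering, spectra, band powers, ratios, BSI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuromon import qeeg


def _sine_recording(freq, fs=250.0, duration=20.0, amp=10.0, n_channels=2,
                    dc=0.0):
    t = np.arange(int(duration * fs)) / fs
    row = amp * np.sin(2 * np.pi * freq * t) + dc
    data = np.tile(row, (n_channels, 1))
    labels = [f"ch{i}" for i in range(n_channels)]
    return qeeg.EEGRecording(data=data, fs=fs, channel_labels=labels)


class TestBandpass:
    def test_stopband_attenuates_50hz(self):
        rec = _sine_recording(50.0)
        out = qeeg.bandpass(rec, 0.3, 30.0)
        assert np.sqrt((out.data ** 2).mean()) < 0.1 * np.sqrt(
            (rec.data ** 2).mean())

    def test_passband_preserves_10hz(self):
        rec = _sine_recording(10.0)
        out = qeeg.bandpass(rec, 0.3, 30.0)
        ratio = np.sqrt((out.data ** 2).mean() / (rec.data ** 2).mean())
        assert abs(ratio - 1.0) < 0.05

    def test_dc_removed(self):
        rec = _sine_recording(10.0, dc=100.0)
        out = qeeg.bandpass(rec, 0.3, 30.0)
        assert abs(out.data.mean()) < 1.0

    def test_cutoff_above_nyquist_rejected(self):
        rec = _sine_recording(10.0, fs=100.0)
        with pytest.raises(ValueError):
            qeeg.bandpass(rec, 0.3, 60.0)


class TestArtifactRejection:
    def test_clean_recording_unmasked(self):
        rec = _sine_recording(10.0, amp=50.0)
        out = qeeg.reject_artifacts(rec, amplitude_limit=200.0, epoch_len=1.0)
        assert not out.artifact_mask.any()

    def test_spike_epoch_masked_exactly(self):
        rec = _sine_recording(10.0, amp=50.0, duration=10.0)
        rec.data[0, int(3.5 * rec.fs)] = 500.0  # spike inside epoch 3
        out = qeeg.reject_artifacts(rec, amplitude_limit=200.0, epoch_len=1.0)
        n = int(rec.fs)
        masked_epochs = {s // n for s in np.where(out.artifact_mask)[0]}
        assert masked_epochs == {3}

    def test_zero_limit_is_no_analyzable_data(self):
        rec = _sine_recording(10.0)
        with pytest.raises(qeeg.NoAnalyzableDataError):
            qeeg.reject_artifacts(rec, amplitude_limit=0.0)

    def test_masked_epochs_excluded_from_spectrum(self):
        rec = _sine_recording(10.0, amp=50.0, duration=20.0)
        rec.data[0, int(5.2 * rec.fs)] = 900.0
        clean = qeeg.reject_artifacts(rec, 200.0, 1.0)
        spec = qeeg.spectrum(clean)
        assert spec.meta["n_epochs"] < qeeg.spectrum(rec).meta["n_epochs"]


class TestSpectrum:
    def test_white_noise_flat_within_15pct(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((1, int(600 * 250)))
        rec = qeeg.EEGRecording(data=data, fs=250.0, channel_labels=["c"])
        spec = qeeg.spectrum(rec)
        p = spec.power[0]
        assert p.max() / p.mean() < 1.15
        assert p.min() / p.mean() > 0.85

    def test_sine_power_parseval(self):
        amp = 8.0
        rec = _sine_recording(10.0, amp=amp, duration=60.0)
        spec = qeeg.spectrum(rec)
        band_power = spec.power[0].sum() * spec.resolution
        assert band_power == pytest.approx(amp ** 2 / 2, rel=0.02)
        peak_bin = spec.freqs[np.argmax(spec.power[0])]
        assert abs(peak_bin - 10.0) <= spec.resolution / 2

    def test_identical_channels_identical_rows(self, balanced_eeg):
        rec = balanced_eeg.copy_with(
            data=np.tile(balanced_eeg.data[:1], (2, 1)),
            channel_labels=["a", "b"])
        spec = qeeg.spectrum(rec)
        np.testing.assert_array_equal(spec.power[0], spec.power[1])

    def test_too_short_recording_rejected(self):
        rec = _sine_recording(10.0, duration=1.0)
        with pytest.raises(ValueError):
            qeeg.spectrum(rec, epoch_len=2.0)


class TestBandPowers:
    def test_pure_alpha_sine(self):
        rec = _sine_recording(10.0, duration=60.0)
        summ = qeeg.band_powers(qeeg.spectrum(rec))
        assert summ.rap > 0.97
        assert summ.rdp + summ.rtp + summ.rbp < 0.03

    def test_flat_spectrum_bin_counting(self):
        # 1-Hz bins centered 1..30; center-assignment puts 3/4/6/17 bins
        # into delta/theta/alpha/beta
        freqs = np.arange(1.0, 31.0)
        power = np.ones((1, 30))
        spec = qeeg.PowerSpectrum(freqs=freqs, power=power,
                                  channel_labels=["c"], resolution=1.0)
        summ = qeeg.band_powers(spec)
        assert summ.fractions() == pytest.approx(
            (3 / 30, 4 / 30, 6 / 30, 17 / 30))

    def test_fractions_sum_to_one_per_channel(self, balanced_eeg):
        summ = qeeg.band_powers(qeeg.spectrum(balanced_eeg))
        np.testing.assert_allclose(summ.per_channel.sum(axis=1), 1.0,
                                   atol=1e-9)
        assert sum(summ.fractions()) == pytest.approx(1.0, abs=1e-9)

    def test_gain_invariance(self, balanced_eeg):
        s1 = qeeg.band_powers(qeeg.spectrum(balanced_eeg))
        scaled = balanced_eeg.copy_with(data=balanced_eeg.data * 7.3)
        s2 = qeeg.band_powers(qeeg.spectrum(scaled))
        assert s1.fractions() == pytest.approx(s2.fractions(), rel=1e-9)
        assert s1.dar == pytest.approx(s2.dar, rel=1e-9)
        assert s1.dtabr == pytest.approx(s2.dtabr, rel=1e-9)

    def test_zero_power_rejected(self):
        spec = qeeg.PowerSpectrum(freqs=np.arange(1.0, 31.0),
                                  power=np.zeros((1, 30)),
                                  channel_labels=["c"], resolution=1.0)
        with pytest.raises(ValueError):
            qeeg.band_powers(spec)


class TestRatios:
    @pytest.mark.parametrize("fracs, dar, dtabr", [
        # nonsurvivor medians: DAR = 0.744/0.095; survivor medians:
        # DTABR = (0.70+0.095)/(0.119+0.071) — medians do not compose to
        # the printed group medians exactly (7.8, 4.3), ratios of medians do
        ((0.744, 0.084, 0.095, 0.064), 7.832, 5.208),
        ((0.25, 0.25, 0.25, 0.25), 1.0, 1.0),
        ((0.70, 0.095, 0.119, 0.071), 5.882, 4.184),
    ])
    def test_hand_arithmetic(self, fracs, dar, dtabr):
        d, dt = qeeg.dar_dtabr(*fracs)
        assert d == pytest.approx(dar, abs=5e-3)
        assert dt == pytest.approx(dtabr, abs=5e-3)

    def test_zero_alpha_is_explicit_error(self):
        with pytest.raises(ZeroDivisionError):
            qeeg.dar_dtabr(0.9, 0.1, 0.0, 0.0)

    @given(extra=st.floats(0.01, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_dar_increases_with_delta(self, extra):
        base = np.array([0.4, 0.2, 0.3, 0.1])
        d0, _ = qeeg.dar_dtabr(*base)
        bumped = base + np.array([extra, 0, 0, 0])
        bumped /= bumped.sum()
        d1, _ = qeeg.dar_dtabr(*bumped)
        assert d1 > d0


class TestBSI:
    def test_symmetric_spectra_give_zero(self):
        freqs = np.arange(1.0, 31.0)
        p = np.abs(np.random.default_rng(1).standard_normal(30)) + 0.1
        spec = qeeg.PowerSpectrum(freqs=freqs, power=np.vstack([p, p]),
                                  channel_labels=["R", "L"], resolution=1.0)
        assert qeeg.bsi(spec, pairs=[("R", "L")]) == 0.0

    def test_uniform_3to1_ratio_gives_half(self):
        freqs = np.arange(1.0, 31.0)
        base = np.linspace(1.0, 2.0, 30)
        spec = qeeg.PowerSpectrum(freqs=freqs,
                                  power=np.vstack([3 * base, base]),
                                  channel_labels=["R", "L"], resolution=1.0)
        assert qeeg.bsi(spec, pairs=[("R", "L")]) == pytest.approx(0.5)

    def test_one_sided_silence_gives_one(self):
        freqs = np.arange(1.0, 31.0)
        base = np.ones(30)
        spec = qeeg.PowerSpectrum(freqs=freqs,
                                  power=np.vstack([base, 0 * base]),
                                  channel_labels=["R", "L"], resolution=1.0)
        assert qeeg.bsi(spec, pairs=[("R", "L")]) == pytest.approx(1.0)

    def test_matches_hand_computed_double_sum(self, toy_spectrum):
        # mean over pairs of (R-L)/(R+L) per bin, |.|, mean over bins
        expected = np.mean([
            abs(((4 - 2) / 6 + (1 - 3) / 4) / 2),
            abs(((2 - 2) / 4 + (5 - 1) / 6) / 2),
            abs(((1 - 3) / 4 + (2 - 2) / 4) / 2),
            abs(((3 - 1) / 4 + (2 - 6) / 8) / 2),
        ])
        got = qeeg.bsi(toy_spectrum, pairs=[("R1", "L1"), ("R2", "L2")])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_swap_sides_invariant(self, toy_spectrum):
        a = qeeg.bsi(toy_spectrum, pairs=[("R1", "L1"), ("R2", "L2")])
        b = qeeg.bsi(toy_spectrum, pairs=[("L1", "R1"), ("L2", "R2")])
        assert a == pytest.approx(b, abs=1e-12)

    def test_gain_invariant(self, toy_spectrum):
        scaled = qeeg.PowerSpectrum(freqs=toy_spectrum.freqs,
                                    power=5.0 * toy_spectrum.power,
                                    channel_labels=toy_spectrum.channel_labels,
                                    resolution=1.0)
        assert qeeg.bsi(scaled, pairs=[("R1", "L1")]) == pytest.approx(
            qeeg.bsi(toy_spectrum, pairs=[("R1", "L1")]), abs=1e-12)

    def test_missing_homolog_is_error(self, toy_spectrum):
        with pytest.raises(KeyError):
            qeeg.bsi(toy_spectrum, pairs=[("R1", "nope")])

    def test_bounds(self, toy_spectrum):
        v = qeeg.bsi(toy_spectrum, pairs=[("R1", "L1"), ("R2", "L2")])
        assert 0.0 <= v <= 1.0


class TestSummarize:
    def test_delta_injection_raises_rdp_and_dar(self, balanced_eeg):
        s0 = qeeg.summarize(balanced_eeg)
        t = np.arange(balanced_eeg.n_samples) / balanced_eeg.fs
        extra = 12.0 * np.sin(2 * np.pi * 2.0 * t)
        bumped = balanced_eeg.copy_with(data=balanced_eeg.data + extra)
        s1 = qeeg.summarize(bumped)
        assert s1.rdp > s0.rdp
        assert s1.dar > s0.dar

    def test_metadata_provenance(self, balanced_eeg):
        s = qeeg.summarize(balanced_eeg)
        assert s.meta["window"] == "hann"
        assert s.meta["bands_hz"]["delta"] == [1.0, 4.0]
        assert "bsi_pairs" in s.meta
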