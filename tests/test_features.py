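"""Feature extraction: FIR filter against a direct-DFT oracle, rectified
areas, relative band powers against Parseval, the EEG preprocessing
chain, and the 19-parameter vector's symmetries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wavesick.features import (
    EEG_BANDS,
    EMG_BANDS,
    FEATURE_NAMES,
    EpochSet,
    bandpass_fir,
    design_bandpass,
    eeg_band_relpower,
    eeg_layout,
    eeg_preprocess,
    emg_area,
    extract_features,
    hr_stats,
    relative_band_power,
)
from wavesick.recording import Measurement, Recording
from wavesick.simulate import generate_cohort, preset_config


def dft_gain(taps: np.ndarray, f: float, rate: float) -> float:
    """Independent frequency-response oracle: direct DFT of the taps."""
    n = np.arange(taps.size)
    return abs(np.sum(taps * np.exp(-2j * np.pi * f * n / rate)))


def sinusoid_amplitude(y: np.ndarray, f: float, rate: float) -> float:
    """Steady-state amplitude of a filtered sinusoid by least squares
    on the interior (transient-free) samples."""
    t = np.arange(y.size) / rate
    core = slice(200, -200)
    design = np.column_stack([np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)])
    coef, *_ = np.linalg.lstsq(design[core], y[core], rcond=None)
    return float(np.hypot(*coef))


class TestBandpassFir:
    rate = 1600.0

    def test_passband_gain_within_1db(self):
        t = np.arange(int(2 * self.rate)) / self.rate
        y = bandpass_fir(np.sin(2 * np.pi * 250 * t), self.rate)
        gain = sinusoid_amplitude(y, 250, self.rate)
        assert 10 ** (-1 / 20) < gain < 10 ** (1 / 20)

    def test_dc_attenuated_per_frequency_response(self):
        taps = design_bandpass(self.rate, 40.0, 500.0, 50)
        h0 = dft_gain(taps, 0.0, self.rate)
        assert h0 < 0.1  # stopband, though shallow at 51 taps
        y = bandpass_fir(np.full(4000, 5.0), self.rate)
        assert abs(y[2000]) == pytest.approx(5.0 * h0, rel=1e-6)

    def test_stopband_matches_dft_oracle(self):
        t = np.arange(int(4 * self.rate)) / self.rate
        y = bandpass_fir(np.sin(2 * np.pi * 10 * t), self.rate)
        expected = dft_gain(design_bandpass(self.rate, 40.0, 500.0, 50), 10.0, self.rate)
        assert sinusoid_amplitude(y, 10, self.rate) == pytest.approx(expected, abs=1e-6)

    def test_delay_compensation_preserves_length_and_alignment(self):
        x = np.zeros(1000)
        x[500] = 1.0
        y = bandpass_fir(x, self.rate)
        assert y.size == x.size
        assert np.argmax(np.abs(y)) == 500  # symmetric kernel peak stays put

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            bandpass_fir(np.zeros(100), 800.0, 40, 500, clip_high=False)
        with pytest.raises(ValueError):
            bandpass_fir(np.zeros(100), 1600.0, order=51)
        # clipping keeps the call usable at lower rates
        assert bandpass_fir(np.zeros(100), 800.0, 40, 500).shape == (100,)


class TestEmgArea:
    @pytest.mark.parametrize(
        "signal, expected",
        [(np.full(10, 3.0), 3.0), (np.array([2.0, -2.0] * 8), 2.0),
         (np.array([3.0, -4.0, 0.0, 5.0]), 3.0)],
    )
    def test_worked_examples(self, signal, expected):
        assert emg_area(signal) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            emg_area(np.array([]))

    @settings(deadline=None)
    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50),
        st.floats(-100, 100),
    )
    def test_absolute_homogeneity(self, values, c):
        x = np.asarray(values)
        assert emg_area(c * x) == pytest.approx(abs(c) * emg_area(x), rel=1e-9, abs=1e-12)


class TestRelativeBandPower:
    rate = 1600.0

    def test_single_tone_lands_in_its_band(self):
        t = np.arange(int(4 * self.rate)) / self.rate
        shares = relative_band_power(np.sin(2 * np.pi * 80 * t), self.rate)
        assert shares[0] >= 0.99

    def test_two_equal_tones_split_evenly(self):
        t = np.arange(int(4 * self.rate)) / self.rate
        x = np.sin(2 * np.pi * 80 * t) + np.sin(2 * np.pi * 180 * t)
        shares = relative_band_power(x, self.rate)
        assert shares[0] == pytest.approx(0.5, abs=0.02)
        assert shares[1] == pytest.approx(0.5, abs=0.02)
        assert shares[2:].sum() < 0.02

    def test_bad_bands_rejected(self):
        x = np.zeros(int(4 * self.rate))
        with pytest.raises(ValueError):
            relative_band_power(x, self.rate, bands=((40, 900),))
        with pytest.raises(ValueError):
            relative_band_power(x, self.rate, bands=((40, 132), (100, 224)))
        with pytest.raises(ValueError):
            relative_band_power(x, 500.0, bands=EEG_BANDS, method="bogus")

    def test_scale_invariance_and_normalisation(self, rng):
        x = rng.standard_normal(int(4 * self.rate))
        a = relative_band_power(x, self.rate)
        b = relative_band_power(17.3 * x, self.rate)
        assert np.allclose(a, b, atol=1e-12)
        assert a.sum() == pytest.approx(1.0, abs=1e-9)

    def test_periodogram_matches_parseval_dft_oracle(self, rng):
        """Band shares agree within 2 % with direct |FFT|^2 band sums
        (Parseval) on a stationary multi-tone signal."""
        t = np.arange(int(4 * self.rate)) / self.rate
        x = (
            np.sin(2 * np.pi * 80 * t)
            + 0.7 * np.sin(2 * np.pi * 260 * t)
            + 0.4 * np.sin(2 * np.pi * 430 * t)
            + 0.1 * rng.standard_normal(t.size)
        )
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(x.size, 1 / self.rate)
        expected = []
        for i, (lo, hi) in enumerate(EMG_BANDS):
            sel = (freqs >= lo) & ((freqs <= hi) if i == 4 else (freqs < hi))
            expected.append(spec[sel].sum())
        expected = np.array(expected) / sum(expected)
        shares = relative_band_power(x, self.rate)
        assert np.all(np.abs(shares - expected) <= 0.02)


class TestEegPreprocess:
    rate = 500.0

    def clean_recording(self, seconds=120, scale=20.0, seed=0):
        rng = np.random.default_rng(seed)
        n = int(seconds * self.rate)
        labels = tuple(eeg_layout()["label"])
        # band-limited noise so filtering leaves the amplitude sane
        x = scale * rng.standard_normal((64, n))
        return Recording(x, self.rate, labels)

    def test_clean_trial_yields_four_epochs(self):
        rec = self.clean_recording()
        out = eeg_preprocess(rec, self.clean_recording(60, seed=1))
        assert len(out.epochs) == 4
        assert not out.rejected_channels and not out.rejected

    def test_trial_rejected_above_20_percent_bad(self):
        rec = self.clean_recording(scale=10.0)
        t = np.arange(rec.n_samples) / self.rate
        # after the common average reference the 13 contaminated
        # channels keep 51/64 of the artifact (> 300 uV) while clean
        # channels see only 13/64 of it (well below 300 uV)
        rec.samples[:13] += 450.0 * np.sin(2 * np.pi * 1.0 * t)  # 13/64 = 20.3 % > 20 %
        out = eeg_preprocess(rec, self.clean_recording(60, seed=1))
        assert out.rejected and out.epochs == []
        assert len(out.rejected_channels) == 13

    def test_bad_channel_interpolated_against_idw_oracle(self):
        rec = self.clean_recording()
        bad = 10
        rec.samples[bad] = 2000.0 * np.sin(
            2 * np.pi * 5 * np.arange(rec.n_samples) / self.rate
        )
        out = eeg_preprocess(rec, self.clean_recording(60, seed=1))
        bad_label = rec.labels[bad]
        assert out.rejected_channels == (bad_label,)
        assert len(out.epochs) == 4

        # independent inverse-distance oracle on the returned epochs
        layout = eeg_layout().set_index("label")
        kept = [l for l in rec.labels if l != bad_label]
        d = np.linalg.norm(
            layout.loc[kept, ["x", "y", "z"]].to_numpy()
            - layout.loc[bad_label, ["x", "y", "z"]].to_numpy(),
            axis=1,
        )
        order = np.argsort(d)[:4]
        w = (1 / d[order]) / (1 / d[order]).sum()
        ep = out.epochs[0]
        neigh_rows = [list(rec.labels).index(kept[i]) for i in order]
        oracle = w @ ep[neigh_rows]
        assert np.allclose(ep[bad], oracle, atol=1.0)

    def test_rejection_decisions_idempotent(self):
        rec = self.clean_recording()
        t = np.arange(rec.n_samples) / self.rate
        rec.samples[3] += 1500.0 * np.sin(2 * np.pi * 2.0 * t)
        baseline = self.clean_recording(60, seed=1)
        out = eeg_preprocess(rec, baseline)
        again = eeg_preprocess(
            Recording(np.concatenate(out.epochs, axis=1), self.rate, rec.labels),
            baseline,
        )
        assert not again.rejected_channels and not again.rejected_epochs

    def test_wrong_channel_count_rejected(self):
        rec = Recording(np.zeros((32, 1000)), self.rate, tuple(f"c{i}" for i in range(32)))
        with pytest.raises(ValueError):
            eeg_preprocess(rec, rec)


class TestEegBandPower:
    def test_pure_alpha_tone(self):
        rate = 500.0
        t = np.arange(int(30 * rate)) / rate
        ep = np.tile(10 * np.sin(2 * np.pi * 10 * t), (8, 1))
        shares = eeg_band_relpower(
            EpochSet([ep], rate, tuple(f"c{i}" for i in range(8)))
        )
        assert shares[2] >= 0.95

    def test_white_noise_shares_proportional_to_bandwidth(self, rng):
        rate = 500.0
        widths = np.array([hi - lo for lo, hi in EEG_BANDS])
        epochs = [rng.standard_normal((8, int(30 * rate))) for _ in range(4)]
        shares = eeg_band_relpower(
            EpochSet(epochs, rate, tuple(f"c{i}" for i in range(8)))
        )
        assert np.all(np.abs(shares - widths / widths.sum()) <= 0.03)
        assert shares.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_epochs_raises(self):
        with pytest.raises(ValueError):
            eeg_band_relpower(EpochSet([], 500.0, (), rejected_reason="too many bad"))


class TestHrStats:
    def test_worked_examples(self):
        assert hr_stats(np.full(5, 70.0)) == (70.0, 0.0)
        assert hr_stats(np.array([60.0, 80.0]))[0] == pytest.approx(70.0)
        assert hr_stats(np.array([60.0, 70.0, 80.0]))[1] == pytest.approx(10.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hr_stats(np.array([]))


@pytest.fixture(scope="module")
def measurement():
    cohort = generate_cohort(1, [], preset_config("strong", seed=2))
    return cohort[1][0]  # the P1 measurement


class TestFeatureVector:
    def test_nineteen_finite_ordered_values(self, measurement):
        feats = extract_features(measurement)
        assert tuple(feats.index) == FEATURE_NAMES
        assert np.isfinite(feats.to_numpy(dtype=float)).all()
        assert feats[["eeg_delta", "eeg_theta", "eeg_alpha", "eeg_beta", "eeg_lg"]].sum() == pytest.approx(1.0, abs=1e-9)

    def test_left_right_swap_symmetry(self, measurement):
        feats = extract_features(measurement)
        swapped = Measurement(
            measurement.subject_id,
            measurement.protocol,
            measurement.eeg,
            Recording(measurement.emg.samples[::-1], measurement.emg.rate, ("EMG_L", "EMG_R")),
            measurement.hr,
        )
        feats_sw = extract_features(swapped)
        for name in FEATURE_NAMES:
            if "emg_L" in name:
                assert feats_sw[name] == feats[name.replace("_L_", "_R_")]
            elif "emg_R" in name:
                assert feats_sw[name] == feats[name.replace("_R_", "_L_")]

    def test_emg_scale_equivariance(self, measurement):
        doubled = Measurement(
            measurement.subject_id,
            measurement.protocol,
            measurement.eeg,
            Recording(2.0 * measurement.emg.samples, measurement.emg.rate, ("EMG_L", "EMG_R")),
            measurement.hr,
        )
        a, b = extract_features(measurement), extract_features(doubled)
        for side in ("L", "R"):
            assert b[f"emg_{side}_area"] == pytest.approx(2 * a[f"emg_{side}_area"], rel=1e-12)
        band_cols = [n for n in FEATURE_NAMES if "_40_132" in n or "_132_224" in n
                     or "_224_316" in n or "_316_408" in n or "_408_500" in n]
        assert np.allclose(a[band_cols].astype(float), b[band_cols].astype(float), atol=1e-9)

    def test_rejected_eeg_yields_missing_eeg_features_only(self, measurement):
        bad = measurement.eeg.samples.copy()
        t = np.arange(bad.shape[1]) / measurement.eeg.rate
        bad[:20] += 2000.0 * np.sin(2 * np.pi * 3.0 * t)  # 20/64 channels bad
        noisy = Measurement(
            measurement.subject_id, measurement.protocol,
            Recording(bad, measurement.eeg.rate, measurement.eeg.labels),
            measurement.emg, measurement.hr,
        )
        feats = extract_features(noisy)
        eeg_cols = ["eeg_delta", "eeg_theta", "eeg_alpha", "eeg_beta", "eeg_lg"]
        assert feats[eeg_cols].isna().all()
        assert np.isfinite(feats.drop(eeg_cols).to_numpy(dtype=float)).all()
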