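import numpy as np
import pytest

import hpenet as h

LABELS = ("Fpz", "F3", "Fz", "F4", "AF3", "AFz", "AF4", "P3", "Pz", "P4", "POz")
FS = 256


def make_recording(signal_fn, duration=60.0, fs=FS, labels=LABELS, mask=None):
    t = np.arange(0, duration, 1.0 / fs)
    data = np.tile(signal_fn(t), (len(labels), 1))
    return h.EEGRecording(data=data, fs=fs, channel_labels=labels, artifact_mask=mask)


def uniform_powers(overrides=None, n_epochs=5):
    """Band-power table with every (band, group) constant at 1, then overrides."""
    import pandas as pd

    idx = pd.MultiIndex.from_product(
        [["theta", "alpha", "alpha_high", "beta", "gamma"], ["frontal", "parietal"]],
        names=["band", "group"],
    )
    values = pd.DataFrame(1.0, index=idx, columns=range(n_epochs))
    for (band, group), v in (overrides or {}).items():
        values.loc[(band, group)] = v
    return h.BandPowerTable(values=values)


class TestBandpassFilter:
    def test_stopband_rejects_mains(self):
        rec = make_recording(lambda t: np.sin(2 * np.pi * 50 * t), duration=60)
        out = h.bandpass_filter(rec, 2, 30, 5)
        assert np.sqrt((out.data**2).mean()) < 0.05 * np.sqrt((rec.data**2).mean())

    def test_passband_preserves_alpha(self):
        rec = make_recording(lambda t: np.sin(2 * np.pi * 10 * t), duration=10)
        out = h.bandpass_filter(rec, 2, 30, 5)
        ratio = np.sqrt((out.data**2).mean()) / np.sqrt((rec.data**2).mean())
        assert abs(ratio - 1) < 0.1

    @pytest.mark.parametrize("low,high", [(30, 2), (0, 30), (2, 200)])
    def test_invalid_edges_rejected(self, low, high):
        rec = make_recording(lambda t: np.sin(t), duration=2)
        with pytest.raises(ValueError, match="band edges"):
            h.bandpass_filter(rec, low, high)


class TestIAF:
    def test_recovers_generator_frequency(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 60, 1.0 / FS)
        base = np.sin(2 * np.pi * 10 * t)
        data = np.stack(
            [base + rng.standard_normal(len(t)) * 0.3 for _ in LABELS]
        )
        rec = h.EEGRecording(data=data, fs=FS, channel_labels=LABELS)
        assert abs(h.compute_iaf(rec) - 10.0) <= 0.5

    def test_flat_spectrum_ties_to_10hz(self):
        rec = make_recording(lambda t: np.zeros_like(t), duration=20)
        with pytest.warns(UserWarning, match="10 Hz"):
            assert h.compute_iaf(rec) == 10.0

    def test_short_baseline_rejected(self):
        rec = make_recording(lambda t: np.sin(t), duration=3)
        with pytest.raises(ValueError, match="at least 10 s"):
            h.compute_iaf(rec)


class TestBandPower:
    def test_spectral_concentration(self):
        rec = make_recording(lambda t: np.sin(2 * np.pi * 6 * t), duration=30)
        bp = h.band_power(rec, h.BandScheme.from_iaf(10.0))
        theta = bp.get("theta", "frontal").mean()
        alpha = bp.get("alpha", "frontal").mean()
        assert theta > 10 * alpha

    def test_artifact_mask_propagates(self):
        mask = np.ones(10, dtype=bool)
        rec = make_recording(lambda t: np.sin(2 * np.pi * 6 * t), duration=10, mask=mask)
        bp = h.band_power(rec, h.BandScheme.from_iaf(10.0))
        assert np.isnan(bp.values.to_numpy()).all()

    def test_white_noise_equal_width_bands(self):
        # flat spectrum: two disjoint equal-width bands carry equal power
        rng = np.random.default_rng(11)
        t = np.arange(0, 600, 1.0 / FS)
        data = rng.standard_normal((len(LABELS), len(t)))
        rec = h.EEGRecording(data=data, fs=FS, channel_labels=LABELS)
        scheme = h.BandScheme(
            iaf=10.0, band_edges={"lo": (5.0, 10.0), "hi": (15.0, 20.0)}
        )
        bp = h.band_power(rec, scheme)
        lo = bp.get("lo", "frontal").mean()
        hi = bp.get("hi", "frontal").mean()
        assert abs(lo - hi) / lo < 0.2

    def test_amplitude_linearity(self):
        rec = make_recording(lambda t: np.sin(2 * np.pi * 6 * t), duration=10)
        doubled = h.EEGRecording(
            data=2 * rec.data, fs=rec.fs, channel_labels=rec.channel_labels
        )
        bp1 = h.band_power(rec, h.BandScheme.from_iaf(10.0)).values.to_numpy()
        bp2 = h.band_power(doubled, h.BandScheme.from_iaf(10.0)).values.to_numpy()
        np.testing.assert_allclose(bp2, 4 * bp1, rtol=1e-6)

    def test_band_beyond_nyquist_rejected(self):
        rec = make_recording(lambda t: np.sin(t), duration=5, fs=32)
        scheme = h.BandScheme(iaf=10.0, band_edges={"bad": (10.0, 31.0)})
        with pytest.raises(ValueError, match="Nyquist"):
            h.band_power(rec, scheme)


class TestNeurometrics:
    def test_direct_substitution(self):
        bp = uniform_powers(
            {
                ("theta", "frontal"): 2.0,
                ("alpha", "parietal"): 1.0,
                ("alpha", "frontal"): 0.5,
            }
        )
        hf = h.compute_neurometrics(bp)
        row = dict(zip(hf.names, hf.values[:, 0]))
        assert row["mental_workload"] == pytest.approx(2.0)
        assert row["attention"] == pytest.approx(-0.5)
        assert row["effort"] == pytest.approx(2.0)
        assert row["stress"] == pytest.approx(1.0)
        assert row["vigilance"] == pytest.approx(-1.0)

    def test_nan_propagates_only_to_dependent_metrics(self):
        theta = np.ones(5)
        theta[2] = np.nan
        hf = h.compute_neurometrics(uniform_powers({("theta", "frontal"): theta}))
        row = dict(zip(hf.names, hf.values[:, 2]))
        assert np.isnan(row["mental_workload"]) and np.isnan(row["effort"])
        assert not np.isnan(row["stress"]) and not np.isnan(row["vigilance"])

    def test_zero_denominator_guard(self):
        alpha_p = np.ones(5)
        alpha_p[1] = 0.0
        with pytest.warns(UserWarning, match="zero"):
            hf = h.compute_neurometrics(
                uniform_powers({("alpha", "parietal"): alpha_p})
            )
        assert np.isnan(hf.values[0, 1])

    def test_metric_locality_parietal_beta(self):
        base = h.compute_neurometrics(uniform_powers())
        bumped = h.compute_neurometrics(
            uniform_powers({("beta", "parietal"): 3.0})
        )
        changed = [
            name
            for name, a, b in zip(base.names, base.values, bumped.values)
            if not np.array_equal(a, b)
        ]
        assert changed == ["stress"]

    def test_upper_alpha_reading_selectable(self):
        bp = uniform_powers({("alpha_high", "parietal"): 0.5})
        full = h.compute_neurometrics(bp, alpha_parietal_band="alpha")
        high = h.compute_neurometrics(bp, alpha_parietal_band="alpha_high")
        assert full.values[0, 0] == pytest.approx(1.0)
        assert high.values[0, 0] == pytest.approx(2.0)


class TestImputation:
    def test_gap_free_identity(self):
        s = h.HFSeries(values=np.arange(100, dtype=float).reshape(5, 20))
        out = h.impute_missing(s)
        np.testing.assert_array_equal(out.values, s.values)

    def test_equal_neighbours_give_their_value(self):
        row = np.full(20, 3.0)
        row[10] = np.nan
        s = h.HFSeries(values=np.vstack([row, np.ones((4, 20))]))
        assert h.impute_missing(s).values[0, 10] == pytest.approx(3.0)

    def test_matches_weighted_average_oracle(self):
        # neighbours of the gap at t=10: t-1:1.0, t+1:3.0, t-2:0.0, t+2:4.0,
        # t-3:-1.0 (t+3 also missing so exactly these five are nearest)
        row = np.zeros(20)
        row[7:13] = [-1.0, 0.0, 1.0, np.nan, 3.0, 4.0]
        row[13] = np.nan
        row[14] = 0.0
        s = h.HFSeries(values=np.vstack([row, np.ones((4, 20))]))
        out = h.impute_missing(s, k=5)
        w = np.array([1.0, 1.0, 0.5, 0.5, 1 / 3])
        v = np.array([1.0, 3.0, 0.0, 4.0, -1.0])
        assert out.values[0, 10] == pytest.approx(np.sum(w * v) / np.sum(w))

    def test_observed_samples_bit_identical_and_deterministic(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal((5, 50))
        values[:, ::7] = np.nan
        s = h.HFSeries(values=values)
        out1, out2 = h.impute_missing(s), h.impute_missing(s)
        np.testing.assert_array_equal(out1.values, out2.values)
        observed = ~s.mask
        np.testing.assert_array_equal(out1.values[observed], s.values[observed])
        assert not out1.mask.any()

    def test_fully_missing_row_names_the_hf(self):
        values = np.ones((5, 20))
        values[3] = np.nan
        with pytest.raises(ValueError, match="stress"):
            h.impute_missing(h.HFSeries(values=values))


class TestStandardize:
    def test_moments_and_flag(self):
        s = h.HFSeries(values=np.vstack([np.array([1.0, 2.0, 3.0]), np.ones((4, 3)) * [[1, 5, 9]]]))
        out = h.standardize(s)
        assert out.standardized
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        s = h.HFSeries(values=rng.standard_normal((5, 200)))
        once = h.standardize(s)
        twice = h.standardize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-8)

    def test_constant_row_rejected(self):
        values = np.ones((5, 10))
        values[1:] = np.random.default_rng(0).standard_normal((4, 10))
        with pytest.raises(ValueError, match="zero-variance"):
            h.standardize(h.HFSeries(values=values))

    def test_gappy_input_rejected(self):
        values = np.ones((5, 10))
        values[0, 0] = np.nan
        with pytest.raises(ValueError, match="gap-free"):
            h.standardize(h.HFSeries(values=values))
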