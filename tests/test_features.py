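"""Welch band power, session averaging, and feature-table assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

import eegimpact as ei
from eegimpact.features import CONDITIONS, FeatureVector, feature_names
from eegimpact.preprocess import RejectionMask
from eegimpact.simulate import Recording, SessionLabel, session_blocks

from test_preprocess import make_recording


class TestBandScheme:
    def test_default_edges(self):
        scheme = ei.default_bands()
        assert scheme.edges["delta"] == (1.0, 4.0)
        assert scheme.edges["gamma"] == (30.0, 50.0)
        assert scheme.band_of(13.0) == "beta1"   # half-open: 13 belongs up
        assert scheme.band_of(12.99) == "alpha"
        assert scheme.band_of(55.0) is None

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ei.BandScheme({"a": (1.0, 5.0), "b": (4.0, 8.0)})


class TestWelch:
    def test_window_duration(self):
        assert ei.WelchParams(nfft=512).window_duration_s(512.0) == 1.0

    def test_matches_scipy_unmasked(self, quiet_block):
        """Against scipy.signal.welch with identical settings: < 1e-6 rel."""
        rec, _ = quiet_block
        res = ei.welch_band_power(rec)
        f_ref, p_ref = signal.welch(rec.data, fs=rec.fs, window="hann",
                                    nperseg=512, noverlap=256,
                                    detrend=False)
        np.testing.assert_allclose(res.freqs, f_ref)
        np.testing.assert_allclose(res.psd, p_ref, rtol=1e-6)

    def test_sinusoid_parseval(self):
        """150 s unit 10 Hz sinusoid: alpha holds >= 95% of 1-50 Hz power and
        the total band-integrated power is the signal variance 0.5 uV^2."""
        t = np.arange(int(150 * 512)) / 512.0
        rec = make_recording(np.tile(np.sin(2 * np.pi * 10 * t), (2, 1)))
        res = ei.welch_band_power(rec)
        scheme = ei.default_bands()
        total = sum(res.band_power[b][0] * (hi - lo)
                    for b, (lo, hi) in scheme.edges.items())
        alpha = res.band_power["alpha"][0] * 5.0
        assert alpha / total >= 0.95
        assert total == pytest.approx(0.5, rel=0.05)

    def test_white_noise_variance_recovery(self):
        rng = np.random.default_rng(0)
        sigma = 3.0
        rec = make_recording(rng.normal(0, sigma, size=(2, int(100 * 512))))
        res = ei.welch_band_power(rec)
        scheme = ei.default_bands()
        total = sum(res.band_power[b][0] * (hi - lo)
                    for b, (lo, hi) in scheme.edges.items())
        # flat spectrum: in-band (1-50 Hz of 0-256 Hz) share of sigma^2
        expected = sigma ** 2 * (49.0 / 256.0)
        assert total == pytest.approx(expected, rel=0.05)

    def test_fully_masked_flagged_missing(self, quiet_block):
        rec, _ = quiet_block
        clean = ei.CleanRecording(
            recording=rec,
            mask=RejectionMask(np.ones(rec.n_samples, bool), rec.fs))
        res = ei.welch_band_power(clean)
        assert res.missing and res.n_windows == 0
        assert np.isnan(res.band_power["alpha"]).all()

    def test_mask_skips_overlapping_windows(self, quiet_block):
        """A masked span removes exactly the windows that touch it."""
        rec, _ = quiet_block
        excl = np.zeros(rec.n_samples, bool)
        excl[2000:2100] = True
        clean = ei.CleanRecording(recording=rec,
                                  mask=RejectionMask(excl, rec.fs))
        res = ei.welch_band_power(clean)
        starts = np.arange(0, rec.n_samples - 512 + 1, 256)
        valid = [s for s in starts if not excl[s:s + 512].any()]
        assert res.n_windows == len(valid)
        assert res.n_windows < ei.welch_band_power(rec).n_windows

    @given(c=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=10, deadline=None)
    def test_scaling_property(self, c, quiet_block):
        """Scaling the signal by c scales every band power by c^2."""
        rec, _ = quiet_block
        base = ei.welch_band_power(rec)
        import dataclasses
        scaled = ei.welch_band_power(
            dataclasses.replace(rec, data=c * rec.data))
        for b in base.band_power:
            np.testing.assert_allclose(scaled.band_power[b],
                                       c ** 2 * base.band_power[b],
                                       rtol=1e-9)

    def test_channel_permutation_equivariance(self, quiet_block):
        rec, _ = quiet_block
        perm = np.random.default_rng(1).permutation(rec.data.shape[0])
        import dataclasses
        permuted = dataclasses.replace(
            rec, data=rec.data[perm],
            channel_names=tuple(rec.channel_names[i] for i in perm))
        a = ei.welch_band_power(rec).band_power
        b = ei.welch_band_power(permuted).band_power
        for band in a:
            np.testing.assert_allclose(b[band], a[band][perm])


def _block(cond_index: int, value: float, n: int = 2048) -> Recording:
    """Constant-power white-ish block for averaging arithmetic tests."""
    eyes, posture = [("open", "sitting"), ("closed", "sitting"),
                     ("open", "standing"), ("closed", "standing")][cond_index]
    rng = np.random.default_rng(int(value * 1000) % (2 ** 31))
    data = rng.normal(0, np.sqrt(value), size=(2, n))
    return Recording(subject_id="S01", group="kicking",
                     session=SessionLabel("pre", eyes, posture, cond_index + 1),
                     fs=512.0, data=data, channel_names=("Fp1", "Fp2"))


class TestSessionFeatures:
    def test_mean_of_two_blocks(self, quiet_config):
        from conftest import zero_offsets
        from eegimpact.simulate import generate_block
        off = zero_offsets(quiet_config)
        blocks = [generate_block(quiet_config, "S01", s, off)[0]
                  for s in session_blocks("pre")]
        fv = ei.session_features(blocks)
        assert fv.values.size == 768
        assert not fv.missing_conditions
        assert np.isfinite(fv.values).all()
        # mean over the two blocks of a condition, checked directly
        b0 = ei.welch_band_power(blocks[0]).band_power["alpha"][0]
        b4 = ei.welch_band_power(blocks[4]).band_power["alpha"][0]
        key = f"open_sitting.{blocks[0].channel_names[0]}.alpha"
        assert fv.values[key] == pytest.approx((b0 + b4) / 2)

    def test_identical_blocks_idempotent_mean(self):
        a = _block(0, 2.0)
        fv = ei.session_features([a, a])
        single = ei.welch_band_power(a).band_power["alpha"][0]
        assert fv.values["open_sitting.Fp1.alpha"] == pytest.approx(single)

    def test_rejected_block_falls_back_to_survivor(self):
        a, b = _block(1, 2.0), _block(1, 2.0)
        dead = ei.CleanRecording(
            recording=b, mask=RejectionMask(np.ones(b.n_samples, bool), b.fs))
        fv = ei.session_features([a, dead])
        alone = ei.session_features([a])
        pd.testing.assert_series_equal(fv.values, alone.values)
        assert "closed_sitting" not in fv.missing_conditions

    def test_all_conditions_missing_flagged(self):
        a = _block(0, 1.0)
        fv = ei.session_features([a])
        assert set(fv.missing_conditions) == set(CONDITIONS) - {"open_sitting"}

    def test_mixed_sessions_rejected(self, quiet_config):
        from conftest import zero_offsets
        from eegimpact.simulate import generate_block
        off = zero_offsets(quiet_config)
        pre = generate_block(quiet_config, "S01", session_blocks("pre")[0], off)[0]
        post = generate_block(quiet_config, "S01",
                              session_blocks("post1h")[0], off)[0]
        with pytest.raises(ValueError, match="single subject-session"):
            ei.session_features([pre, post])


def _fake_vector(sid, lag, group="kicking", fill=1.0, n=12):
    names = [f"f{i}" for i in range(n)]
    return FeatureVector(subject_id=sid, lag=lag, group=group,
                         values=pd.Series(fill, index=names),
                         missing_conditions=[], n_windows={})


class TestAssembleTable:
    def test_counts_full_design(self):
        vecs = [_fake_vector(f"S{i:02d}", lag)
                for i in range(36) for lag in ("pre", "post24h")]
        table = ei.assemble_table(vecs, lags=("pre", "post24h"))
        assert table.X.shape == (72, 12)
        assert (table.labels == 0).sum() == 36

    def test_single_subject(self):
        vecs = [_fake_vector("S00", "pre"), _fake_vector("S00", "post1h")]
        t = ei.assemble_table(vecs, lags=("pre", "post1h"))
        assert t.X.shape == (2, 12)

    def test_missing_lag_dropped_with_warning(self):
        vecs = [_fake_vector(f"S{i:02d}", lag)
                for i in range(36) for lag in ("pre", "post1h")]
        vecs = [v for v in vecs
                if not (v.subject_id == "S05" and v.lag == "post1h")]
        with pytest.warns(UserWarning, match="dropped 1"):
            t = ei.assemble_table(vecs, lags=("pre", "post1h"))
        assert t.n_obs == 70

    def test_label_mapping(self):
        vecs = [_fake_vector("S00", "pre"), _fake_vector("S00", "post24h")]
        t = ei.assemble_table(vecs, lags=("pre", "post24h"))
        assert t.labels[t.lags == "pre"][0] == 0
        assert t.labels[t.lags == "post24h"][0] == 1

    def test_csv_roundtrip(self, tmp_path):
        vecs = [_fake_vector(f"S{i}", lag, fill=float(i))
                for i in range(6) for lag in ("pre", "post24h")]
        t = ei.assemble_table(vecs, lags=("pre", "post24h"))
        path = tmp_path / "table.csv"
        t.to_csv(path)
        back = ei.FeatureTable.from_csv(path)
        np.testing.assert_allclose(back.X, t.X)
        assert list(back.subject_ids) == list(t.subject_ids)
        assert list(back.labels) == list(t.labels)

    def test_feature_name_order_deterministic(self):
        names = feature_names(("Fp1", "Fp2"), ei.default_bands())
        assert names[0] == "open_sitting.Fp1.delta"
        assert len(names) == 4 * 2 * 6
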