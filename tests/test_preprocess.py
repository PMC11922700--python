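"""Preprocessing: filter response, referencing, ocular ICA, jump rejection."""

import numpy as np
import pytest

import eegimpact as ei
from eegimpact.simulate import Recording, SessionLabel, generate_block, session_blocks

from conftest import QUIET, zero_offsets


def make_recording(data: np.ndarray, fs: float = 512.0) -> Recording:
    names = tuple(f"C{i}" if i > 1 else ("Fp1", "Fp2")[i]
                  for i in range(data.shape[0]))
    return Recording(subject_id="S01", group="kicking",
                     session=SessionLabel("pre", "open", "sitting", 1),
                     fs=fs, data=data, channel_names=names)


class TestBandpass:
    fs = 512.0
    t = np.arange(int(30 * 512)) / 512.0

    def _rms_after(self, freq_hz):
        x = np.sin(2 * np.pi * freq_hz * self.t)
        rec = make_recording(np.tile(x, (2, 1)), self.fs)
        out = ei.bandpass(rec)
        return np.sqrt((out.data[0] ** 2).mean()) / np.sqrt((x ** 2).mean())

    def test_stopband_60hz(self):
        assert self._rms_after(60.0) < 0.10

    def test_passband_10hz(self):
        assert self._rms_after(10.0) == pytest.approx(1.0, abs=0.05)

    def test_zero_in_zero_out(self):
        rec = make_recording(np.zeros((2, 2048)))
        np.testing.assert_allclose(ei.bandpass(rec).data, 0.0, atol=1e-12)

    def test_zero_phase(self):
        """A passband sinusoid keeps its phase (no group delay)."""
        x = np.sin(2 * np.pi * 10.0 * self.t)
        out = ei.bandpass(make_recording(np.tile(x, (2, 1)))).data[0]
        mid = slice(2048, -2048)
        corr = np.corrcoef(x[mid], out[mid])[0, 1]
        assert corr > 0.999

    def test_nyquist_violation(self):
        rec = make_recording(np.zeros((2, 2048)), fs=80.0)
        with pytest.raises(ValueError, match="band edges"):
            ei.bandpass(rec, 0.1, 50.0)


class TestAverageReference:
    def test_zero_mean_and_idempotent(self, quiet_block):
        rec, _ = quiet_block
        out = ei.rereference_average(rec)
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-10)
        again = ei.rereference_average(out)
        np.testing.assert_allclose(again.data, out.data, atol=1e-12)

    def test_two_channel_closed_form(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 1000))
        out = ei.rereference_average(make_recording(np.vstack([a, b])))
        np.testing.assert_allclose(out.data[0], (a - b) / 2, atol=1e-12)
        np.testing.assert_allclose(out.data[1], (b - a) / 2, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="2 channels"):
            ei.rereference_average(make_recording(np.zeros((1, 100))))


def brute_force_jump_mask(data, fs, window_s=0.5, sd_mult=15.0, pad_s=0.5,
                          pooled=True):
    """Direct O(n*w) recomputation of the sliding peak-to-trough rule."""
    n = data.shape[1]
    w = int(round(window_s * fs))
    pad = int(round(pad_s * fs))
    all_series = [np.array([ch[i:i + w].max() - ch[i:i + w].min()
                            for i in range(n - w + 1)]) for ch in data]
    mask = np.zeros(n, dtype=bool)
    if pooled:
        flat = np.concatenate(all_series)
        thr_all = (np.full(len(all_series), np.inf) if flat.std() == 0
                   else np.full(len(all_series),
                                flat.mean() + sd_mult * flat.std()))
    else:
        thr_all = [np.inf if s.std() == 0 else s.mean() + sd_mult * s.std()
                   for s in all_series]
    for series, thr in zip(all_series, thr_all):
        for i in np.flatnonzero(series > thr):
            mask[max(0, i - pad):min(n, i + w + pad)] = True
    return mask


class TestJumpRejection:
    def _noise_block(self, seed, n_ch=4, dur_s=8.0, fs=512.0):
        rng = np.random.default_rng(seed)
        return make_recording(rng.normal(size=(n_ch, int(dur_s * fs))), fs)

    @pytest.mark.parametrize("seed,pooled", [(0, True), (1, True), (2, True),
                                             (1, False)])
    def test_matches_brute_force_oracle(self, seed, pooled):
        """Mask-for-mask agreement with the naive recomputation, with and
        without injected spikes, in both statistic modes."""
        rec = self._noise_block(seed)
        if seed > 0:  # inject a spike in some runs
            rng = np.random.default_rng(100 + seed)
            ch = int(rng.integers(rec.data.shape[0]))
            t0 = int(rng.integers(512, rec.n_samples - 512))
            rec.data[ch, t0:t0 + 100] += 50 * rec.data[ch].std()
        got = ei.reject_jumps(rec, pooled=pooled)
        want = brute_force_jump_mask(rec.data, rec.fs, pooled=pooled)
        np.testing.assert_array_equal(got.excluded, want)

    def test_single_spike_localized(self):
        """A 200 ms 50-sigma spike at t=30 s is excluded (with the 0.5 s
        window reach and 0.5 s padding) and nothing else is."""
        rec = self._noise_block(7, n_ch=8, dur_s=60.0)
        fs = rec.fs
        t0 = int(30.0 * fs)
        dur = int(0.2 * fs)
        rec.data[0, t0:t0 + dur] += 50 * rec.data[0].std()
        mask = ei.reject_jumps(rec)
        assert mask.excluded[t0:t0 + dur].all()
        (start, end), = mask.intervals
        # core reach: window length + padding before onset / after offset
        assert start >= 30.0 - 0.5 - 0.5 - 0.01
        assert end <= 30.0 + 0.2 + 0.5 + 0.5 + 0.01
        assert not mask.excluded[:int(28.5 * fs)].any()
        assert not mask.excluded[int(31.8 * fs):].any()

    def test_gaussian_noise_rarely_excluded(self):
        rec = self._noise_block(11, n_ch=8, dur_s=10.0)
        assert ei.reject_jumps(rec).fraction_excluded < 0.01

    def test_constant_zero_empty_mask(self):
        rec = make_recording(np.zeros((3, 4096)))
        with pytest.warns(UserWarning, match="zero-variance"):
            mask = ei.reject_jumps(rec)
        assert not mask.excluded.any()

    def test_window_too_short(self):
        rec = self._noise_block(0)
        with pytest.raises(ValueError, match="2 samples"):
            ei.reject_jumps(rec, window_s=1e-4)


class TestOcularICA:
    @pytest.fixture(scope="class")
    def blink_block(self):
        # >= 60 s: below that, unmixing error bleeds background into the
        # removed components and distorts non-ocular channels
        cfg = ei.CohortConfig(n_subjects=2, block_duration_s=60.0, seed=23)
        rec, art = generate_block(cfg, "S01", session_blocks("pre")[0],
                                  zero_offsets(cfg))
        assert art.blink_onsets
        filt = ei.rereference_average(ei.bandpass(rec))
        return cfg, filt, art

    def test_blink_removal(self, blink_block):
        """Blink-window variance at Fp1/Fp2 drops by at least half while the
        occipital background is essentially untouched."""
        cfg, filt, art = blink_block
        tpl = ei.default_ocular_templates(cfg.montage)
        out, report = ei.remove_ocular_ica(filt, tpl)
        assert report["converged"]
        assert report["removed"], "no ocular component identified"
        fp = [cfg.montage.index("Fp1"), cfg.montage.index("Fp2")]
        w = int(0.3 * filt.fs)
        var_before = np.mean([filt.data[fp, o:o + w].var()
                              for o in art.blink_onsets])
        var_after = np.mean([out.data[fp, o:o + w].var()
                             for o in art.blink_onsets])
        assert var_after < 0.5 * var_before
        for i in cfg.montage.group_indices("occipital"):
            assert np.corrcoef(filt.data[i], out.data[i])[0, 1] >= 0.95

    def test_report_contents(self, blink_block):
        cfg, filt, _ = blink_block
        tpl = ei.default_ocular_templates(cfg.montage)
        _, report = ei.remove_ocular_ica(filt, tpl)
        for item in report["removed"]:
            assert item["correlation"] >= tpl.threshold
            assert item["template"] in ("vertical", "horizontal")

    def test_clean_block_high_threshold_removes_nothing(self):
        """Artifact-free blocks at threshold 0.99: no component removed in
        at least 9 of 10 seeded runs."""
        cfg = ei.CohortConfig(n_subjects=2, block_duration_s=15.0,
                              effect=ei.EffectSpec(**QUIET), seed=31)
        off = zero_offsets(cfg)
        clean_runs = 0
        for i in range(10):
            rec, _ = generate_block(cfg, "S01", session_blocks("pre")[0], off,
                                    seed_key=(60, i))
            filt = ei.rereference_average(ei.bandpass(rec))
            tpl = ei.default_ocular_templates(cfg.montage, threshold=0.99)
            _, report = ei.remove_ocular_ica(filt, tpl, seed=i)
            if not report["converged"] or not report["removed"]:
                clean_runs += 1
        assert clean_runs >= 9

    def test_removal_cap(self, blink_block):
        cfg, filt, _ = blink_block
        tpl = ei.default_ocular_templates(cfg.montage, threshold=0.01)
        _, report = ei.remove_ocular_ica(filt, tpl, max_removed=2)
        assert len(report["removed"]) <= 2

    def test_threshold_bounds(self, blink_block):
        cfg, _, _ = blink_block
        with pytest.raises(ValueError, match="threshold"):
            ei.default_ocular_templates(cfg.montage, threshold=1.5)


class TestFullPipeline:
    @pytest.fixture(scope="class")
    def cleaned(self):
        cfg = ei.CohortConfig(n_subjects=2, block_duration_s=20.0, seed=23)
        rec, art = generate_block(cfg, "S01", session_blocks("pre")[0],
                                  zero_offsets(cfg))
        return cfg, rec, art, ei.preprocess_block(rec, cfg.montage)

    def test_step_order(self, cleaned):
        _, _, _, clean = cleaned
        steps = [p["step"] for p in clean.provenance]
        assert steps == ["bandpass", "average_reference", "ocular_ica",
                         "jump_rejection"]

    def test_average_reference_holds(self, cleaned):
        _, _, _, clean = cleaned
        np.testing.assert_allclose(clean.recording.data.mean(axis=0), 0.0,
                                   atol=1e-8)

    def test_jumps_masked(self, cleaned):
        _, _, art, clean = cleaned
        for j in art.jumps:
            assert clean.mask.excluded[j["start"]:
                                       j["start"] + j["n_samples"]].any()

    def test_idempotent_without_ica(self, cleaned):
        """Re-running the deterministic steps on their own output changes
        (nearly) nothing: the passband is already isolated and the average
        reference already holds."""
        cfg, rec, _, _ = cleaned
        params = ei.PreprocessParams(run_ica=False)
        once = ei.preprocess_block(rec, cfg.montage, params)
        twice = ei.preprocess_block(once.recording, cfg.montage, params)
        a, b = once.recording.data, twice.recording.data
        corr = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert corr > 0.999
        np.testing.assert_array_equal(once.mask.excluded, twice.mask.excluded)

    def test_mask_alignment_enforced(self, cleaned):
        _, rec, _, clean = cleaned
        with pytest.raises(ValueError, match="mask length"):
            ei.CleanRecording(recording=rec,
                              mask=ei.RejectionMask(np.zeros(5, bool), rec.fs))
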