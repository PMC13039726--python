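"""Six-phase pipeline: ICA, mask design, filtering, windowing, normalization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from imspeech.io_core import Recording
from imspeech.preprocess import (
    FilterSpec,
    ICAConfig,
    PipelineError,
    SpecError,
    WindowSet,
    WindowingScheme,
    apply_filter,
    apply_normalizer,
    design_fd_mask,
    expected_window_count,
    fit_normalizer,
    ica_clean,
    run_pipeline,
    segment,
)
from imspeech.synthetic import SynthConfig, generate_dataset


def _rec(data: np.ndarray, fs: float = 128.0) -> Recording:
    names = tuple(f"ch{i}" for i in range(data.shape[0]))
    return Recording("S01", "A", "characters", data, fs, names)


def _sine(freq: float, n: int = 1280, fs: float = 128.0) -> np.ndarray:
    t = np.arange(n) / fs
    return np.sin(2 * np.pi * freq * t)


# ---------------------------------------------------------------------------
# Phase 3 mask
# ---------------------------------------------------------------------------

class TestMaskDesign:
    @pytest.mark.parametrize("freq,gain", [
        (10.0, 0.0),    # stopband centre
        (3.0, 0.5),     # lower ramp midpoint (2 -> 4 Hz)
        (16.0, 0.5),    # upper ramp midpoint (15 -> 17 Hz)
        (0.5, 1.0),     # low passband
        (30.0, 1.0),    # high passband
    ])
    def test_gain_profile(self, freq, gain):
        mask = design_fd_mask(FilterSpec(), 1280, 128.0)
        freqs = np.fft.rfftfreq(1280, d=1.0 / 128.0)
        assert mask[np.argmin(np.abs(freqs - freq))] == pytest.approx(gain, abs=1e-12)

    def test_mask_bounded_and_zero_through_stopband(self):
        mask = design_fd_mask(FilterSpec(), 1280, 128.0)
        freqs = np.fft.rfftfreq(1280, d=1.0 / 128.0)
        assert np.all((mask >= 0) & (mask <= 1))
        assert np.all(mask[(freqs >= 4.0) & (freqs <= 15.0)] == 0.0)

    def test_squared_gain_is_square_of_single_pass(self):
        single = design_fd_mask(FilterSpec(), 1280, 128.0)
        squared = design_fd_mask(FilterSpec(fd_application="squared_gain"),
                                 1280, 128.0)
        np.testing.assert_allclose(squared, single ** 2, atol=1e-15)

    def test_ramp_beyond_nyquist_rejected(self):
        with pytest.raises(SpecError, match="Nyquist"):
            design_fd_mask(FilterSpec(stop_hi=62.0, ramp=3.0), 1280, 128.0)

    def test_ramp_below_zero_rejected(self):
        with pytest.raises(SpecError):
            FilterSpec(stop_lo=1.0, ramp=2.0)


class TestApplyFilter:
    def test_full_band_is_identity(self, tiny_dataset):
        _, _, recordings, _ = tiny_dataset
        out = apply_filter(recordings[0], FilterSpec(mode="full_band"))
        assert np.array_equal(out.data, recordings[0].data)

    def test_stopband_sinusoid_annihilated(self):
        rec = _rec(np.vstack([_sine(10.0), _sine(8.0)]))
        out = apply_filter(rec, FilterSpec())
        in_rms = np.sqrt(np.mean(rec.data ** 2))
        out_rms = np.sqrt(np.mean(out.data ** 2))
        assert out_rms < 1e-6 * in_rms

    def test_passband_sinusoid_preserved_with_zero_phase(self):
        rec = _rec(_sine(25.0)[None, :])
        out = apply_filter(rec, FilterSpec())
        assert np.max(np.abs(out.data - rec.data)) < 1e-9
        xcorr = np.correlate(rec.data[0], out.data[0], mode="full")
        assert np.argmax(xcorr) == rec.n_samples - 1  # peak at lag 0

    def test_zero_phase_for_any_passband_sinusoid(self):
        for freq in (1.0, 20.0, 30.0, 45.0):
            rec = _rec(_sine(freq)[None, :])
            out = apply_filter(rec, FilterSpec())
            xcorr = np.correlate(rec.data[0], out.data[0], mode="full")
            assert np.argmax(xcorr) == rec.n_samples - 1, freq

    def test_band_energy_removed_and_total_energy_non_increasing(self):
        rng = np.random.default_rng(0)
        rec = _rec(rng.standard_normal((4, 1280)))
        out = apply_filter(rec, FilterSpec())
        freqs = np.fft.rfftfreq(1280, d=1.0 / 128.0)
        band = (freqs >= 4.0) & (freqs <= 15.0)
        spec_in = np.abs(np.fft.rfft(rec.data, axis=1)) ** 2
        spec_out = np.abs(np.fft.rfft(out.data, axis=1)) ** 2
        assert spec_out[:, band].sum() <= 1e-10 * spec_in[:, band].sum()
        assert np.sum(out.data ** 2) <= np.sum(rec.data ** 2) + 1e-9

    def test_fft_round_trip_identity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 1001))  # odd length too
        back = np.fft.irfft(np.fft.rfft(x, axis=1), n=1001, axis=1)
        assert np.max(np.abs(back - x)) < 1e-10

    def test_td_bandreject_attenuates_stopband_zero_phase(self):
        rec = _rec(_sine(10.0)[None, :])
        out = apply_filter(rec, FilterSpec(mode="td_bandreject"))
        assert np.sqrt(np.mean(out.data ** 2)) < 0.05 * np.sqrt(np.mean(rec.data ** 2))


# ---------------------------------------------------------------------------
# Phase 5 segmentation
# ---------------------------------------------------------------------------

def _brute_force_count(n: int, ws: int, stride: int) -> int:
    return sum(1 for s in range(0, n + 1, stride) if s + ws <= n)


class TestSegment:
    def test_scheme_a_1280_gives_157(self):
        rec = _rec(np.zeros((2, 1280)))
        assert len(segment([rec], WindowingScheme.scheme_a())) == 157
        assert expected_window_count(1, 1280, 32, 8) == 157

    def test_scheme_b_1280_gives_160_disjoint(self):
        rec = _rec(np.arange(2 * 1280, dtype=float).reshape(2, 1280))
        ws = segment([rec], WindowingScheme.scheme_b())
        assert len(ws) == 160
        covered = sorted(int(s) + k for s in ws.starts for k in range(8))
        assert covered == list(range(1280))  # partition: no overlap, no gap

    def test_window_equals_recording_length(self):
        rec = _rec(np.zeros((2, 64)))
        ws = segment([rec], WindowingScheme(name="A", ws=64, stride=8))
        assert len(ws) == 1

    def test_window_longer_than_recording_rejected(self):
        rec = _rec(np.zeros((2, 16)))
        with pytest.raises(SpecError, match="window size"):
            segment([rec], WindowingScheme.scheme_a())

    def test_window_content_matches_source(self):
        rng = np.random.default_rng(2)
        rec = _rec(rng.standard_normal((3, 64)))
        ws = segment([rec], WindowingScheme.scheme_a())
        for win, start in zip(ws.windows, ws.starts):
            np.testing.assert_array_equal(win, rec.data[:, start:start + 32].T)

    @settings(max_examples=200, deadline=None)
    @given(n=st.integers(16, 2000), ws_size=st.integers(1, 64),
           stride=st.integers(1, 64))
    def test_count_formula_matches_brute_force(self, n, ws_size, stride):
        """Window-count formula vs start-index enumeration, random triples."""
        if stride > ws_size or ws_size > n:
            return
        assert expected_window_count(1, n, ws_size, stride) == \
            _brute_force_count(n, ws_size, stride)

    def test_scheme_b_partitions_prefix_of_any_length(self):
        rec = _rec(np.zeros((2, 1237)))  # non-divisible length
        scheme = WindowingScheme.scheme_b()
        ws = segment([rec], scheme)
        n_full = 1237 // 8
        assert len(ws) == n_full
        covered = sorted(int(s) + k for s in ws.starts for k in range(8))
        assert covered == list(range(n_full * 8))


# ---------------------------------------------------------------------------
# Phase 6 normalization
# ---------------------------------------------------------------------------

def _window_set(values: np.ndarray, scheme=None) -> WindowSet:
    n = len(values)
    return WindowSet(values, np.zeros(n, dtype=np.int64),
                     np.array(["S"] * n), np.array(["r"] * n),
                     np.zeros(n, dtype=np.int64),
                     scheme or WindowingScheme.scheme_b(), ("A",))


class TestNormalization:
    def test_hand_arithmetic_mean_and_population_sd(self):
        values = np.array([[[0.0]], [[2.0]]])  # 2 windows, 1 timepoint, 1 ch
        stats = fit_normalizer(_window_set(values))
        assert stats.mean[0] == pytest.approx(1.0)
        assert stats.sd[0] == pytest.approx(1.0)

    def test_constant_channel_clamps_to_floor(self):
        values = np.full((4, 8, 2), 3.0)
        values[..., 1] = np.random.default_rng(0).standard_normal((4, 8))
        stats = fit_normalizer(_window_set(values), sd_floor=1e-8)
        assert stats.sd[0] == 1e-8
        out = apply_normalizer(stats, _window_set(values))
        assert np.all(np.isfinite(out.windows))

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal((10, 8, 3))
        perm = rng.permutation(10)
        s1 = fit_normalizer(_window_set(values))
        s2 = fit_normalizer(_window_set(values[perm]))
        np.testing.assert_allclose(s1.mean, s2.mean, atol=1e-12)
        np.testing.assert_allclose(s1.sd, s2.sd, atol=1e-12)

    def test_self_standardization(self):
        rng = np.random.default_rng(4)
        values = rng.standard_normal((50, 8, 3)) * 5 + 2
        ws = _window_set(values)
        out = apply_normalizer(fit_normalizer(ws), ws)
        assert np.max(np.abs(out.windows.mean(axis=(0, 1)))) < 1e-9
        assert np.max(np.abs(out.windows.std(axis=(0, 1)) - 1)) < 1e-6

    def test_direct_formula(self):
        stats = fit_normalizer(_window_set(np.array([[[0.0]], [[2.0]]])))
        out = apply_normalizer(stats, _window_set(np.array([[[3.0]]])))
        assert out.windows[0, 0, 0] == pytest.approx(2.0)

    def test_test_set_shift_is_preserved(self):
        rng = np.random.default_rng(5)
        train = _window_set(rng.standard_normal((50, 8, 2)))
        test = _window_set(rng.standard_normal((50, 8, 2)) + 4.0)
        stats = fit_normalizer(train)
        out = apply_normalizer(stats, test)
        assert np.all(out.windows.mean(axis=(0, 1)) > 1.0)  # shift retained

    def test_double_normalization_guarded(self):
        ws = _window_set(np.random.default_rng(6).standard_normal((4, 8, 2)))
        stats = fit_normalizer(ws)
        out = apply_normalizer(stats, ws)
        with pytest.raises(SpecError, match="already normalized"):
            apply_normalizer(stats, out)

    def test_empty_train_set_rejected(self):
        with pytest.raises(SpecError, match="empty"):
            fit_normalizer(_window_set(np.empty((0, 8, 2))))


# ---------------------------------------------------------------------------
# Phase 1 ICA
# ---------------------------------------------------------------------------

class TestIcaClean:
    def test_infinite_threshold_keeps_pca_projection(self):
        synth = SynthConfig(n_subjects=1, classes=("A", "C"),
                            trials_per_class=2, n_samples=1280, snr_db=10.0,
                            seed=9)
        _, recs, _ = generate_dataset(synth)
        cfg = ICAConfig(reject_threshold_sigma=np.inf, variance_retained=0.9999,
                        fit_scope="per_subject")
        cleaned, reports = ica_clean(recs, cfg)
        assert all(not r.rejected and not r.skipped for r in reports)
        for pre, post in zip(recs, cleaned):
            rel = np.linalg.norm(post.data - pre.data) / np.linalg.norm(pre.data)
            assert rel < 0.01

    def test_blink_power_reduced_class_band_preserved(self):
        cfg = SynthConfig(n_subjects=1, classes=("A", "C"), trials_per_class=4,
                          n_samples=1280, snr_db=10.0,
                          artifact_rates={"blink": 1.0}, seed=5)
        _, recs, _ = generate_dataset(cfg)
        cleaned, _ = ica_clean(recs, ICAConfig())

        def bandpower(data, lo, hi):
            freqs = np.fft.rfftfreq(data.shape[1], d=1.0 / 128.0)
            p = np.abs(np.fft.rfft(data, axis=1)) ** 2
            return p[:, (freqs >= lo) & (freqs <= hi)].sum()

        frontal = slice(0, 6)
        pre_blink = np.mean([bandpower(r.data[frontal], 0.5, 3) for r in recs])
        post_blink = np.mean([bandpower(r.data[frontal], 0.5, 3) for r in cleaned])
        assert post_blink < 0.5 * pre_blink
        pre_cls = np.mean([bandpower(r.data, 18, 40) for r in recs])
        post_cls = np.mean([bandpower(r.data, 18, 40) for r in cleaned])
        assert abs(post_cls - pre_cls) / pre_cls < 0.10

    def test_false_rejection_rate_under_null(self):
        """Pure noise recordings: few fits should reject any component."""
        n_reject = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            data = rng.standard_normal((4, 512))
            rec = _rec(data)
            _, reports = ica_clean([rec], ICAConfig(fit_scope="per_recording",
                                                    seed=seed))
            if any(r.rejected for r in reports):
                n_reject += 1
        assert n_reject / n_seeds <= 0.2

    def test_constant_channel_named_in_error(self):
        data = np.random.default_rng(7).standard_normal((4, 512))
        data[2] = 5.0
        with pytest.raises(PipelineError, match="channel index 2"):
            ica_clean([_rec(data)], ICAConfig(fit_scope="per_recording"))

    def test_short_recording_skipped_with_warning(self):
        data = np.random.default_rng(8).standard_normal((14, 256))
        rec = _rec(data)
        with pytest.warns(UserWarning, match="skipping"):
            cleaned, reports = ica_clean([rec], ICAConfig(fit_scope="per_recording"))
        assert reports[0].skipped
        assert np.array_equal(cleaned[0].data, data)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

class TestRunPipeline:
    def test_full_band_scheme_a_counts(self, tiny_dataset):
        _, manifest, recordings, _ = tiny_dataset
        rec_ids = [e.recording_id for e in manifest.entries]
        train_ids, test_ids = rec_ids[:-2], rec_ids[-2:]
        train_ws, test_ws, report = run_pipeline(
            recordings, rec_ids, (train_ids, test_ids),
            ica=ICAConfig(enabled=False), filt=FilterSpec(mode="full_band"),
            scheme=WindowingScheme.scheme_a())
        per_rec = expected_window_count(1, 256, 32, 8)
        assert len(train_ws) == per_rec * len(train_ids)
        assert len(test_ws) == per_rec * len(test_ids)
        assert not report.ica_reports
        assert train_ws.normalized and test_ws.normalized

    def test_deterministic(self, tiny_dataset):
        _, manifest, recordings, _ = tiny_dataset
        rec_ids = [e.recording_id for e in manifest.entries]
        split = (rec_ids[:-2], rec_ids[-2:])
        kwargs = dict(ica=ICAConfig(enabled=False), filt=FilterSpec(),
                      scheme=WindowingScheme.scheme_b())
        a, _, _ = run_pipeline(recordings, rec_ids, split, **kwargs)
        b, _, _ = run_pipeline(recordings, rec_ids, split, **kwargs)
        assert np.array_equal(a.windows, b.windows)

    def test_overlapping_split_rejected(self, tiny_dataset):
        _, manifest, recordings, _ = tiny_dataset
        rec_ids = [e.recording_id for e in manifest.entries]
        with pytest.raises(SpecError, match="both train and test"):
            run_pipeline(recordings, rec_ids, (rec_ids, rec_ids[-1:]))

    def test_uncovered_recording_rejected(self, tiny_dataset):
        _, manifest, recordings, _ = tiny_dataset
        rec_ids = [e.recording_id for e in manifest.entries]
        with pytest.raises(SpecError, match="neither role"):
            run_pipeline(recordings, rec_ids, (rec_ids[:-2], []))
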