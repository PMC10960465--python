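"""Unit and property tests for the spectral pipeline."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sleepspectra import spectral
from sleepspectra.spectral import (
    EpochedRecording,
    aggregate_state_psd,
    compute_subject_spectra,
    hjorth_parameters,
    periodogram_psd,
    reduce_bins,
    reject_artifacts,
    segment_windows,
)

FS = 256.0
WIN = 1024


# ---------------------------------------------------------------------------
# Hjorth parameters
# ---------------------------------------------------------------------------


class TestHjorth:
    def test_white_noise_activity_is_variance(self, rng):
        x = rng.normal(0, 1, 65536)
        h = hjorth_parameters(x)
        assert h.activity == pytest.approx(np.var(x), rel=1e-12)
        assert h.activity == pytest.approx(1.0, rel=0.05)

    def test_sinusoid_closed_form(self):
        # whole number of cycles: mobility = 2 sin(omega/2), complexity = 1
        f = 13.0
        omega = 2 * np.pi * f / FS
        t = np.arange(WIN)
        x = np.sin(omega * t)
        h = hjorth_parameters(x)
        assert h.mobility == pytest.approx(2 * np.sin(omega / 2), rel=1e-3)
        # finite differencing leaves a boundary-cycle bias of order 1/N
        assert h.complexity == pytest.approx(1.0, rel=5e-3)

    def test_scale_invariance(self, rng):
        x = rng.normal(0, 3, 1024)
        h1 = hjorth_parameters(x)
        h2 = hjorth_parameters(5.0 * x)
        assert h2.activity == pytest.approx(25.0 * h1.activity, rel=1e-12)
        assert h2.mobility == pytest.approx(h1.mobility, rel=1e-12)
        assert h2.complexity == pytest.approx(h1.complexity, rel=1e-12)

    def test_constant_signal_flagged_undefined(self):
        h = hjorth_parameters(np.full(100, 3.2))
        assert h.activity == pytest.approx(0.0, abs=1e-25)
        assert not h.is_defined

    def test_too_short_epoch_raises(self):
        with pytest.raises(ValueError):
            hjorth_parameters(np.array([1.0, 2.0]))


# ---------------------------------------------------------------------------
# Artifact rejection
# ---------------------------------------------------------------------------


def _make_recording(epochs: np.ndarray, stages=None) -> EpochedRecording:
    n, spe = epochs.shape
    fs = spe / 4.0
    stages = stages or ["N2"] * n
    return EpochedRecording(
        subject_id="T", sampling_rate=fs, samples={"C3": epochs.reshape(-1)},
        stage_labels=stages,
    )


class TestRejectArtifacts:
    def test_single_outlier_epoch_flagged(self):
        t = np.arange(64)
        base = np.sin(2 * np.pi * 3 * t / 64)
        epochs = np.tile(base, (101, 1))
        epochs[40] *= 10.0
        rec = reject_artifacts(_make_recording(epochs))
        flags = rec.artifact_flags["C3"]
        assert flags[40]
        assert flags.sum() == 1

    def test_constant_statistics_reject_nothing(self):
        # identical epochs: zero SD must not flag everything
        t = np.arange(64)
        epochs = np.tile(np.sin(2 * np.pi * 2 * t / 64), (50, 1))
        rec = reject_artifacts(_make_recording(epochs))
        assert rec.artifact_flags["C3"].sum() == 0

    def test_matches_bruteforce_zscore_oracle(self, rng):
        # i.i.d. Gaussian epochs: flags must equal an independently computed
        # |z| >= 2 rule on the three per-epoch statistics
        n_epochs, spe = 20_000, 64
        epochs = rng.normal(0, 1, (n_epochs, spe))
        rec = reject_artifacts(_make_recording(epochs))
        flags = rec.artifact_flags["C3"]

        stats = []
        for e in epochs:  # brute-force per-epoch loop, no shared code path
            v0 = e.var()
            d1 = np.diff(e)
            d2 = np.diff(d1)
            mob = np.sqrt(d1.var() / v0)
            stats.append((v0, mob, np.sqrt(d2.var() / d1.var()) / mob))
        stats = np.array(stats)
        z = np.abs(stats - stats.mean(0)) / stats.std(0)
        oracle = np.any(z >= 2.0, axis=1)
        assert np.array_equal(flags, oracle)
        # sanity: a few percent of epochs trip at least one of 3 statistics
        assert 0.01 < flags.mean() < 0.25

    def test_small_stage_skipped_with_warning(self, caplog):
        t = np.arange(64)
        epochs = np.tile(np.sin(2 * np.pi * 2 * t / 64), (6, 1))
        epochs[5] *= 10
        stages = ["N2"] * 4 + ["REM"] * 2
        with caplog.at_level("WARNING"):
            rec = reject_artifacts(_make_recording(epochs, stages))
        assert "no artifact rejection" in caplog.text
        assert rec.artifact_flags["C3"][4:].sum() == 0

    def test_per_channel_flags(self, rng):
        spe = 64
        good = rng.normal(0, 1, (30, spe))
        c3 = good.copy()
        c3[7] *= 10
        rec = EpochedRecording(
            subject_id="T", sampling_rate=16.0,
            samples={"C3": c3.reshape(-1), "C4": good.reshape(-1)},
            stage_labels=["N2"] * 30,
        )
        rec = reject_artifacts(rec)
        assert rec.artifact_flags["C3"][7]
        assert not rec.artifact_flags["C4"][7]


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------


def _bruteforce_windows(n_samples: int, fs: float) -> list[int]:
    """Independent enumeration of the 4-s / 50% / short-segment rule."""
    win = int(4 * fs)
    if n_samples < win:
        return []
    if n_samples < int(6 * fs):
        return [0]
    out = []
    off = 0
    while off + win <= n_samples:
        out.append(off)
        off += win // 2
    return out


class TestSegmentWindows:
    @pytest.mark.parametrize(
        "seconds,expected",
        [(10.0, 4), (5.0, 1), (3.9, 0), (4.0, 1), (6.0, 2), (5.99, 1), (8.0, 3)],
    )
    def test_window_counts(self, seconds, expected):
        assert len(segment_windows(int(seconds * FS), FS)) == expected

    def test_ten_second_run_offsets(self):
        assert segment_windows(int(10 * FS), FS) == [0, 512, 1024, 1536]

    @given(st.integers(min_value=0, max_value=int(60 * FS)))
    def test_matches_bruteforce_enumeration(self, n_samples):
        assert segment_windows(n_samples, FS) == _bruteforce_windows(n_samples, FS)


# ---------------------------------------------------------------------------
# Periodogram
# ---------------------------------------------------------------------------


class TestPeriodogram:
    def test_frequency_grid_and_bin_count(self, rng):
        pxx = periodogram_psd(rng.normal(0, 1, WIN), FS)
        assert pxx.shape == (193,)
        assert spectral.FREQS[1] - spectral.FREQS[0] == pytest.approx(0.25)
        assert spectral.FREQS[-1] == pytest.approx(48.0)

    def test_dc_window_power_only_at_zero(self):
        pxx = periodogram_psd(np.full(WIN, 5.0), FS)
        assert np.argmax(pxx) == 0
        # beyond the Hamming mainlobe (+/- 2 bins) there is no power
        assert np.all(pxx[3:] < 1e-20 * pxx[0])

    def test_sine_bin_alignment(self):
        t = np.arange(WIN) / FS
        pxx = periodogram_psd(np.sin(2 * np.pi * 13.0 * t), FS)
        assert np.argmax(pxx[1:]) + 1 == int(13.0 / 0.25)

    def test_white_noise_density_calibration(self, rng):
        # mean tapered periodogram of N(0, sigma^2) = 2 sigma^2 / fs off DC
        sigma = 2.0
        psds = [
            periodogram_psd(rng.normal(0, sigma, WIN), FS) for _ in range(2000)
        ]
        mean_level = np.mean(np.array(psds)[:, 1:])
        assert mean_level == pytest.approx(2 * sigma**2 / FS, rel=0.02)

    def test_parseval_untapered(self, rng):
        x = rng.normal(0, 1.5, WIN)
        x -= x.mean()
        pxx = periodogram_psd(x, FS, taper=None, max_freq=None)
        assert np.sum(pxx) * 0.25 == pytest.approx(np.var(x), rel=1e-10)

    def test_wrong_length_raises(self, rng):
        with pytest.raises(ValueError):
            periodogram_psd(rng.normal(0, 1, 1000), FS)


# ---------------------------------------------------------------------------
# Aggregation and reduction
# ---------------------------------------------------------------------------


class TestAggregate:
    def test_relativization_sums_to_zero(self, rng):
        psds = rng.gamma(2.0, 1.0, (7, 193))
        rel = aggregate_state_psd(psds)
        assert abs(rel.mean()) < 1e-12

    def test_single_window(self, rng):
        p = rng.gamma(2.0, 1.0, 193)
        rel = aggregate_state_psd(p[None, :])
        expected = np.log10(p) - np.log10(p).mean()
        np.testing.assert_allclose(rel, expected, atol=1e-12)

    def test_average_before_log_order_of_operations(self, rng):
        # contract: log10 of the mean PSD, not the mean of centered logs
        p, q = rng.gamma(2.0, 1.0, (2, 193))
        rel = aggregate_state_psd(np.array([p, q]))
        right = np.log10((p + q) / 2)
        right -= right.mean()
        wrong = 0.5 * (
            (np.log10(p) - np.log10(p).mean()) + (np.log10(q) - np.log10(q).mean())
        )
        np.testing.assert_allclose(rel, right, atol=1e-12)
        assert not np.allclose(rel, wrong, atol=1e-6)

    def test_zero_bins_floored(self, rng, caplog):
        p = rng.gamma(2.0, 1.0, 193)
        p[50] = 0.0
        rel = aggregate_state_psd(p[None, :])
        assert np.all(np.isfinite(rel))

    def test_relativization_idempotent(self, rng):
        rel = aggregate_state_psd(rng.gamma(2.0, 1.0, (3, 193)))
        np.testing.assert_allclose(rel - rel.mean(), rel, atol=1e-12)


class TestReduceBins:
    def test_constant_input(self):
        np.testing.assert_allclose(reduce_bins(np.full(193, 3.7)), np.full(48, 3.7))

    def test_output_length_and_wrong_input(self, rng):
        assert reduce_bins(rng.normal(size=193)).shape == (48,)
        with pytest.raises(ValueError):
            reduce_bins(rng.normal(size=192))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_bruteforce_loop(self, seed):
        v = np.random.default_rng(seed).normal(size=193)
        expected = [np.mean(v[1 + 4 * g : 1 + 4 * (g + 1)]) for g in range(48)]
        np.testing.assert_allclose(reduce_bins(v), expected, atol=1e-12)

    def test_reduced_bin_centers(self):
        np.testing.assert_allclose(spectral.FREQS_REDUCED[:3], [0.625, 1.625, 2.625])
        assert spectral.FREQS_REDUCED[-1] == pytest.approx(47.625)


# ---------------------------------------------------------------------------
# Whole-recording pipeline
# ---------------------------------------------------------------------------


class TestSubjectSpectra:
    def _recording(self, rng, scale=1.0):
        n_epochs = 40
        sig = scale * rng.normal(0, 10, n_epochs * WIN)
        stages = (["N2"] * 25 + ["REM"] * 10 + ["Wake"] * 5)
        return EpochedRecording(
            subject_id="S", sampling_rate=FS,
            samples={"C3": sig, "C4": sig.copy()}, stage_labels=stages,
        )

    def test_pipeline_scale_invariance(self, rng):
        rec1 = reject_artifacts(self._recording(np.random.default_rng(5)))
        rec2 = reject_artifacts(self._recording(np.random.default_rng(5), scale=3.0))
        s1 = compute_subject_spectra(rec1)
        s2 = compute_subject_spectra(rec2)
        np.testing.assert_array_equal(
            rec1.artifact_flags["C3"], rec2.artifact_flags["C3"]
        )
        np.testing.assert_allclose(
            s1.rel_log_psd[("C3", "NREM")], s2.rel_log_psd[("C3", "NREM")], atol=1e-9
        )

    def test_wake_epochs_excluded(self, rng):
        rec = self._recording(rng)
        s = compute_subject_spectra(rec)
        n_wake = sum(1 for st in rec.stage_labels if st == "Wake")
        assert n_wake == 5
        used = s.n_epochs_used[("C3", "NREM")] + s.n_epochs_used[("C3", "REM")]
        rejected = s.n_epochs_rejected[("C3", "NREM")] + s.n_epochs_rejected[("C3", "REM")]
        assert used + rejected == rec.n_epochs - n_wake

    def test_trailing_partial_epoch_dropped(self, rng):
        sig = rng.normal(0, 1, 5 * WIN + 100)
        rec = EpochedRecording(
            subject_id="S", sampling_rate=FS, samples={"C3": sig},
            stage_labels=["N2"] * 5,
        )
        assert rec.n_epochs == 5
        assert len(rec.samples["C3"]) == 5 * WIN

    def test_shorter_than_one_epoch_raises(self, rng):
        with pytest.raises(ValueError):
            EpochedRecording(
                subject_id="S", sampling_rate=FS,
                samples={"C3": rng.normal(0, 1, 100)}, stage_labels=[],
            )
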