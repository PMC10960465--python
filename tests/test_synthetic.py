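"""Tests of the synthetic cohort generator against its ground truth."""

import numpy as np
import pandas as pd
import pytest

from sleepspectra import spectral, synthetic
from sleepspectra.synthetic import CohortGenerator, GeneratorConfig, generate_cohort


def _null_config(**kw) -> GeneratorConfig:
    defaults = dict(
        n_subjects=10,
        n_indicators=4,
        seed=5,
        noise_sd=0.0,
        effect_patterns=[],
        narrowband_effects=[],
        age_spectrum_coeff=0.0,
        prevalence_range=(0.3, 0.6),
        missing_rate=0.0,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


class TestDeterminism:
    def test_equal_seed_equal_outputs(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=60, n_indicators=12, seed=9)
        c1, s1, _ = generate_cohort(cfg)
        c2, s2, _ = generate_cohort(GeneratorConfig(n_subjects=60, n_indicators=12, seed=9))
        pd.testing.assert_frame_equal(c1.to_frame(), c2.to_frame())
        np.testing.assert_array_equal(s1.values, s2.values)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        c1.to_tsv(p1)
        c2.to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self):
        c1, *_ = generate_cohort(GeneratorConfig(n_subjects=30, n_indicators=6, seed=1))
        c2, *_ = generate_cohort(GeneratorConfig(n_subjects=30, n_indicators=6, seed=2))
        assert not np.array_equal(c1.age.values, c2.age.values)


class TestSpectraConstruction:
    def test_zero_noise_zero_effect_gives_baseline(self):
        _, spectra, truth = generate_cohort(_null_config())
        for k, state in enumerate(spectra.states):
            for i in range(10):
                for j in range(2):
                    np.testing.assert_allclose(
                        spectra.values[i, j, k], truth.baseline_rel[state], atol=1e-12
                    )

    def test_effect_recovery_at_zero_noise(self):
        # with a single effect-carrying indicator, positive-minus-negative
        # mean spectra equal the implanted vector exactly
        shape = synthetic.default_pattern_shapes()["acceleration"]
        pattern = synthetic.EffectPattern("acceleration", shape, {"indicator_03": 0.3})
        cfg = GeneratorConfig(
            n_subjects=400, n_indicators=6, seed=3, noise_sd=0.0,
            effect_patterns=[pattern], narrowband_effects=[],
            age_spectrum_coeff=0.0, age_indicator_logodds=0.0,
            prevalence_range=(0.1, 0.5), missing_rate=0.0,
        )
        cohort, spectra, truth = generate_cohort(cfg)
        assert list(truth.cluster_labels[truth.cluster_labels != "none"].index) == [
            "indicator_03"
        ]
        x = cohort.indicators["indicator_03"].values
        j = truth.indicator_names.index("indicator_03")
        for k, state in enumerate(spectra.states):
            diff = (
                spectra.values[x == 1, 0, k].mean(axis=0)
                - spectra.values[x == 0, 0, k].mean(axis=0)
            )
            np.testing.assert_allclose(diff, truth.effect_vectors[state][j], atol=1e-10)

    def test_relativization_contract(self, default_cohort):
        vals = default_cohort["spectra"].values
        np.testing.assert_allclose(vals.sum(axis=-1), 0.0, atol=1e-9)

    def test_pattern_matrix_rank(self, default_cohort):
        truth = default_cohort["truth"]
        assert truth.pattern_matrix_rank() == len(truth.pattern_shapes)

    def test_default_patterns_orthonormal(self):
        shapes = synthetic.default_pattern_shapes()
        a, m = shapes["acceleration"], shapes["midfrequency"]
        for v in (a, m):
            assert abs(v.mean()) < 1e-12
            assert np.linalg.norm(v) == pytest.approx(1.0)
        assert abs(a @ m) < 1e-12


class TestIndicators:
    def test_prevalence_calibration(self):
        # empirical prevalence within the 99% binomial CI of target
        cfg = GeneratorConfig(n_subjects=10_000, n_indicators=20, seed=21, missing_rate=0.0)
        cohort, _, truth = generate_cohort(cfg)
        for ind, p in truth.prevalences.items():
            if ind in truth.low_count_indicators:
                continue
            emp = cohort.indicators[ind].mean()
            half_width = 2.576 * np.sqrt(p * (1 - p) / cfg.n_subjects)
            assert abs(emp - p) <= max(half_width, 2.5 / cfg.n_subjects), ind

    def test_age_confounding_present(self, default_cohort):
        # even-indexed indicators are age-linked by construction
        cohort = default_cohort["cohort"]
        truth = default_cohort["truth"]
        common = [i for i in truth.prevalences.index[::2] if truth.prevalences[i] > 0.1]
        corrs = [
            pd.concat([cohort.indicators[i], cohort.age], axis=1).corr().iloc[0, 1]
            for i in common
        ]
        assert np.mean(corrs) > 0.05

    def test_low_prevalence_resampling_flags(self, caplog):
        cfg = GeneratorConfig(
            n_subjects=20, n_indicators=4, seed=2, prevalence_range=(0.001, 0.01),
            missing_rate=0.0,
        )
        with caplog.at_level("WARNING"):
            _, _, truth = generate_cohort(cfg)
        # at n=20 and p<=1%, at least one indicator cannot reach 2 positives
        assert len(truth.low_count_indicators) >= 1

    def test_macrostructure_shifts_implanted(self):
        cfg = GeneratorConfig(
            n_subjects=4000, n_indicators=20, seed=13, prevalence_range=(0.2, 0.5),
            missing_rate=0.0, age_indicator_logodds=0.0,
        )
        cohort, _, truth = generate_cohort(cfg)
        shifted = truth.macro_effects.loc[
            truth.macro_effects["rem_latency"] > 0
        ].index
        assert len(shifted) > 0
        ind = shifted[0]
        x = cohort.indicators[ind].values
        diff = (
            cohort.macrostructure.loc[x == 1, "rem_latency"].mean()
            - cohort.macrostructure.loc[x == 0, "rem_latency"].mean()
        )
        expected = truth.macro_effects.loc[ind, "rem_latency"]
        assert diff == pytest.approx(expected, abs=6.0)  # +/- sampling error


class TestPointBiserialChain:
    def test_closed_form_matches_large_sample(self):
        # narrowband effect: r = d sqrt(pq) / sqrt(d^2 pq + sigma^2) per bin
        cfg = GeneratorConfig(
            n_subjects=20_000, n_indicators=1, seed=17, noise_sd=0.05,
            effect_patterns=[],
            narrowband_effects=[("hypnotic_use", (12.0, 15.0), 0.2)],
            age_spectrum_coeff=0.0, age_indicator_logodds=0.0,
            prevalence_range=(0.3, 0.3), missing_rate=0.0,
        )
        cohort, spectra, truth = generate_cohort(cfg)
        x = cohort.indicators["hypnotic_use"].values
        p = x.mean()
        effect = truth.effect_vectors["NREM"][0]
        peak = int(np.argmax(np.abs(effect)))
        d = effect[peak]
        expected_r = d * np.sqrt(p * (1 - p)) / np.sqrt(d**2 * p * (1 - p) + cfg.noise_sd**2)
        y = spectra.get("C3", "NREM")[:, peak]
        emp_r = np.corrcoef(x, y)[0, 1]
        assert emp_r == pytest.approx(expected_r, abs=0.02)
        assert emp_r > 0


class TestRawRecordings:
    def test_raw_determinism(self, small_raw_generator):
        r1 = small_raw_generator.raw_recording("S00001")
        r2 = small_raw_generator.raw_recording("S00001")
        np.testing.assert_array_equal(r1.samples["C3"], r2.samples["C3"])
        assert r1.stage_labels == r2.stage_labels

    def test_artifact_bookkeeping(self, small_raw_generator):
        rec = small_raw_generator.raw_recording("S00000")
        cfg = small_raw_generator.config
        assert len(rec.true_artifact_epochs) == round(cfg.artifact_fraction * rec.n_epochs)
        assert np.all(rec.true_artifact_epochs < rec.n_epochs)
        # injected epochs carry ~10x amplitude
        epochs = rec.epochs("C3")
        art_rms = np.sqrt(np.mean(epochs[rec.true_artifact_epochs] ** 2))
        clean_idx = np.setdiff1d(np.arange(rec.n_epochs), rec.true_artifact_epochs)
        clean_rms = np.sqrt(np.mean(epochs[clean_idx] ** 2))
        assert art_rms / clean_rms > 5.0

    def test_raw_spectrum_realises_target(self, small_raw_generator):
        # clean NREM periodogram average matches the subject's target within
        # periodogram estimation error
        _, _, truth = small_raw_generator.generate()
        rec = small_raw_generator.raw_recording("S00002", minutes=12)
        rec = spectral.reject_artifacts(rec)
        spec = spectral.compute_subject_spectra(rec)
        idx = 2
        got = spec.rel_log_psd[("C3", "NREM")]
        target = truth.clean_rel_logpsd[idx, 0, 0]
        rms = np.sqrt(np.mean((got - target) ** 2))
        assert rms < 0.12

    def test_flat_spectrum_block_is_white(self):
        # a flat PSD target must synthesize to white noise at the analytic level
        gen = CohortGenerator(_null_config(mode="raw"))
        # bypass cohort machinery: use the same irfft construction directly
        rng = np.random.default_rng(0)
        fs, length = 256.0, 256 * 512
        target = 0.01  # µV²/Hz, flat
        fgrid = np.fft.rfftfreq(length, 1 / fs)
        amp = np.sqrt(target * fs * length / 2)
        z = (rng.normal(size=len(fgrid)) + 1j * rng.normal(size=len(fgrid))) * np.sqrt(0.5)
        x = np.fft.irfft(z * amp, length)
        psds = [
            spectral.periodogram_psd(x[i * 1024 : (i + 1) * 1024], fs, taper=None)
            for i in range(length // 1024)
        ]
        level = np.mean(np.array(psds)[:, 1:])
        assert level == pytest.approx(2 * (target * fs / 2) / fs, rel=0.05)

    def test_too_short_duration_raises(self, small_raw_generator):
        with pytest.raises(ValueError):
            small_raw_generator.raw_recording("S00000", minutes=0.01)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_subjects": 1},
            {"prevalence_range": (0.0, 0.5)},
            {"prevalence_range": (0.2, 1.0)},
            {"mode": "edf"},
            {"noise_sd": -0.1},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            GeneratorConfig(**kw)
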