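"""Synthetic sleep-EEG cohort generator with known ground truth.

Emulates the structure of a large elderly male polysomnography cohort so
the whole analysis chain (spectral reduction, age-partialled screening,
pattern PCA, clustering) can be exercised and validated without any data
download:

* age ~ N(73.06, 5.55^2) years;
* 88 health indicators by default, mostly binary with prevalences
  log-spaced over 0.1%-62%, plus a few continuous ones (blood pressures,
  coffee cups); indicator probabilities are age-linked (logit linear in
  age), making age a genuine confounder;
* relative log-PSD spectra (C3/C4 x NREM/REM, 193 bins at 0.25 Hz) built
  from a smooth 1/f-like baseline (with an NREM sigma bump), an age
  effect, two implanted zero-mean unit-norm broad-band effect patterns
  ("acceleration": opposite-sign loadings below vs above ~25 Hz;
  "mid-frequency": negative at the spectral extremes, positive in between),
  one NREM-only narrowband sigma effect for a synthetic "hypnotic_use"
  indicator, and i.i.d. Gaussian bin noise;
* a 15-column macrostructure table with indicator-linked shifts
  (e.g. longer REM latency for "accelerated" indicators);
* optionally, raw 256 Hz two-channel recordings whose spectra realise the
  subject's target spectrum (colored noise via spectral factorization),
  with stage labels per 4-s epoch and injected x10-amplitude artifact
  epochs at known indices.

Everything is deterministic given the config seed. The returned
:class:`GroundTruth` carries the implanted effect vectors, macrostructure
shifts, age effect and cluster labels, and is the oracle for all
downstream recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import spectral
from .data import CHANNELS, MACRO_COLUMNS, STATES, CohortTables, SpectraSet
from .spectral import FREQS, N_BINS, EpochedRecording

logger = logging.getLogger(__name__)

AGE_MEAN_DEFAULT = 73.06
AGE_SD_DEFAULT = 5.55

_RAW_STREAM = 7_000_001  # tag separating raw-signal rng streams from cohort streams


# ---------------------------------------------------------------------------
# Effect patterns
# ---------------------------------------------------------------------------


def _normalize_pattern(shape: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-Euclidean-norm version of a 193-bin pattern."""
    v = np.asarray(shape, dtype=float)
    v = v - v.mean()
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("pattern shape is constant")
    return v / norm


@dataclass
class EffectPattern:
    """A broad-frequency spectral effect shared by several indicators.

    ``shape`` is a zero-mean, unit-norm vector over the 193-bin grid
    (enforced at construction); ``sizes`` maps indicator name to the effect
    size in log10-PSD units (the spectrum shift is size * shape for
    indicator-positive subjects, or per SD for continuous indicators).
    ``rem_scale`` scales the effect in REM relative to NREM (0 disables it
    in REM, e.g. for NREM-only sigma effects).
    """

    name: str
    shape: np.ndarray
    sizes: dict[str, float]
    rem_scale: float = 1.0

    def __post_init__(self) -> None:
        self.shape = _normalize_pattern(self.shape)


def default_pattern_shapes() -> dict[str, np.ndarray]:
    """The two default orthogonal broad-band shapes on the 193-bin grid.

    ``acceleration``: smooth sign change around 25 Hz (loss of slow, gain
    of fast activity). ``midfrequency``: positive sigma-beta bump with
    negative lobes at the lowest and highest frequencies. Both are
    zero-mean and unit-norm, and ``midfrequency`` is Gram-Schmidt
    orthogonalised against ``acceleration``.
    """
    f = FREQS
    accel = _normalize_pattern(np.tanh((f - 25.0) / 5.0))
    mid = (
        np.exp(-0.5 * ((f - 16.0) / 7.0) ** 2)
        - 0.6 * np.exp(-0.5 * ((f - 2.0) / 3.0) ** 2)
        - 0.6 * np.exp(-0.5 * ((f - 44.0) / 4.0) ** 2)
    )
    mid = mid - mid.mean()
    mid = mid - (mid @ accel) * accel
    mid = mid / np.linalg.norm(mid)
    return {"acceleration": accel, "midfrequency": mid}


def narrowband_shape(band: tuple[float, float]) -> np.ndarray:
    """Zero-mean unit-norm Gaussian bump covering a frequency band."""
    lo, hi = band
    center = 0.5 * (lo + hi)
    width = max((hi - lo) / 4.0, 0.25)
    return _normalize_pattern(np.exp(-0.5 * ((FREQS - center) / width) ** 2))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulation targets: 2000 subjects, 88 indicators
    with prevalences spanning 0.1%-62%, age 73.06 +/- 5.55 years, per-bin
    log10-PSD noise SD 0.05, two broad-band effect patterns over 7
    "accelerated" and 18 "mid-frequency" indicators (the remaining
    indicators have retained sleep), and one NREM-only sigma-band effect
    for ``hypnotic_use``. ``effect_patterns=None`` / ``narrowband_effects
    =None`` select these defaults; pass ``[]`` to disable.
    """

    n_subjects: int = 2000
    seed: int = 0
    n_indicators: int = 88
    prevalence_range: tuple[float, float] = (0.001, 0.62)
    age_mean: float = AGE_MEAN_DEFAULT
    age_sd: float = AGE_SD_DEFAULT
    noise_sd: float = 0.05
    mode: str = "spectra"
    effect_patterns: list[EffectPattern] | None = None
    narrowband_effects: list[tuple[str, tuple[float, float], float]] | None = None
    age_spectrum_coeff: float = 0.02
    age_indicator_logodds: float = 0.5
    n_continuous: int = 3
    missing_rate: float = 0.01
    raw_minutes: float = 8.0
    artifact_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        lo, hi = self.prevalence_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("prevalences must lie in (0, 1)")
        if self.mode not in ("spectra", "raw"):
            raise ValueError("mode must be 'spectra' or 'raw'")
        if self.n_indicators < 1:
            raise ValueError("need at least one indicator")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """What was implanted: the oracle for recovery tests.

    ``effect_vectors[state]`` is (n_indicators, 193): the shift added to a
    subject's relative log-PSD per unit of the (binary or standardised
    continuous) indicator. ``clean_rel_logpsd`` is the noise-free relative
    spectrum of every subject (the raw-mode synthesis target).
    """

    indicator_names: list[str]
    effect_vectors: dict[str, np.ndarray]
    macro_effects: pd.DataFrame
    age_vector: dict[str, np.ndarray]
    cluster_labels: pd.Series
    pattern_shapes: dict[str, np.ndarray]
    baseline_rel: dict[str, np.ndarray]
    prevalences: pd.Series
    clean_rel_logpsd: np.ndarray
    low_count_indicators: list[str] = field(default_factory=list)

    def pattern_matrix_rank(self) -> int:
        return int(np.linalg.matrix_rank(np.array(list(self.pattern_shapes.values()))))


# ---------------------------------------------------------------------------
# Baseline spectrum
# ---------------------------------------------------------------------------


def baseline_log_psd(freqs: np.ndarray, state: str) -> np.ndarray:
    """Smooth absolute log10-PSD baseline (µV²/Hz), valid for any frequency.

    1/f-like decay; NREM carries a sigma bump near 13.5 Hz (sleep
    spindles), REM a weak alpha bump. Only relative perturbations around
    this baseline matter to the pipeline, so the shape is parameterised,
    not fitted to any dataset.
    """
    f = np.asarray(freqs, dtype=float)
    if state == "NREM":
        base = 2.2 - 2.0 * np.log10(1.0 + f)
        base = base + 0.45 * np.exp(-0.5 * ((f - 13.5) / 1.4) ** 2)
    elif state == "REM":
        base = 1.6 - 1.8 * np.log10(1.0 + f)
        base = base + 0.15 * np.exp(-0.5 * ((f - 9.0) / 1.5) ** 2)
    else:  # Wake: REM-like with extra fast activity; excluded from analyses
        base = 1.5 - 1.6 * np.log10(1.0 + f)
    return base


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


def _solve_logit_intercept(target: float, slope: float) -> float:
    """Intercept a with E_z[expit(a + slope*z)] = target for z ~ N(0,1)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    weights = weights / weights.sum()

    def marginal(a: float) -> float:
        return float(np.sum(weights * expit(a + slope * nodes))) - target

    return brentq(marginal, -40.0, 40.0)


class CohortGenerator:
    """Deterministic cohort factory; resolves config defaults once."""

    def __init__(self, config: GeneratorConfig) -> None:
        self.config = config
        self._resolve_schema()
        self._cached: tuple[CohortTables, SpectraSet, GroundTruth] | None = None

    # -- schema -------------------------------------------------------------

    def _resolve_schema(self) -> None:
        cfg = self.config
        n_cont = min(cfg.n_continuous, 3) if cfg.n_indicators >= 8 else 0
        n_bin = cfg.n_indicators - n_cont
        if n_bin < 1:
            raise ValueError("need at least one binary indicator")
        self.continuous_names = ["systolic_bp", "diastolic_bp", "coffee_cups"][:n_cont]
        lo, hi = cfg.prevalence_range
        self.prevalences = np.geomspace(lo, hi, n_bin) if n_bin > 1 else np.array([hi])
        names = [f"indicator_{i:02d}" for i in range(n_bin)]
        # the sigma-band "hypnotic" indicator: binary, prevalence nearest 5%
        hyp_idx = int(np.argmin(np.abs(self.prevalences - 0.05)))
        names[hyp_idx] = "hypnotic_use"
        self.binary_names = names
        self.indicator_names = names + self.continuous_names

        if cfg.effect_patterns is None:
            self.effect_patterns = self._default_patterns()
        else:
            self.effect_patterns = list(cfg.effect_patterns)
        nb = cfg.narrowband_effects
        if nb is None:
            nb = [("hypnotic_use", (12.0, 15.0), 0.12)] if "hypnotic_use" in names else []
        for ind, band, size in nb:
            self.effect_patterns.append(
                EffectPattern(f"narrowband_{ind}", narrowband_shape(band), {ind: size}, rem_scale=0.0)
            )

        self.cluster_labels = pd.Series("none", index=self.indicator_names, name="cluster")
        for pat in self.effect_patterns:
            if pat.name in ("acceleration", "midfrequency"):
                for ind in pat.sizes:
                    self.cluster_labels[ind] = pat.name

        self.macro_effects = pd.DataFrame(
            0.0, index=self.indicator_names, columns=MACRO_COLUMNS
        )
        shifts = {
            "acceleration": {"rem_latency": 12.0, "rem_latency_nowake": 14.0, "rem_duration": -8.0},
            "midfrequency": {"waso": 8.0, "sws_duration": -5.0},
        }
        for ind in self.indicator_names:
            for col, val in shifts.get(self.cluster_labels[ind], {}).items():
                self.macro_effects.loc[ind, col] = val
        if "hypnotic_use" in self.indicator_names:
            self.macro_effects.loc["hypnotic_use", "sleep_latency"] = -5.0
            self.macro_effects.loc["hypnotic_use", "n2_duration"] = 10.0

    def _default_patterns(self) -> list[EffectPattern]:
        """Two orthogonal broad-band patterns over ~8% / ~20% of indicators.

        Effect carriers are chosen evenly among binary indicators with
        prevalence >= 2% (rarer indicators would be statistically silent),
        with per-indicator sizes spanning 0.15-0.40 log10 units and mixed
        signs for the mid-frequency pattern. Continuous blood-pressure
        indicators get a small positive mid-frequency link.
        """
        shapes = default_pattern_shapes()
        n_bin = len(self.binary_names)
        eligible = [
            n for n, p in zip(self.binary_names, self.prevalences)
            if p >= 0.02 and n != "hypnotic_use"
        ]
        n_accel = max(1, round(n_bin * 7 / 88))
        n_mid = max(1, round(n_bin * 18 / 88))
        n_accel = min(n_accel, max(1, len(eligible) // 3))
        n_mid = min(n_mid, len(eligible) - n_accel)
        picks = [eligible[int(i)] for i in np.linspace(0, len(eligible) - 1, n_accel + n_mid)]
        accel_inds = picks[::3][:n_accel]
        mid_inds = [p for p in picks if p not in accel_inds][:n_mid]
        accel_sizes = np.linspace(0.15, 0.40, len(accel_inds))
        accel_signs = np.where(np.arange(len(accel_inds)) == len(accel_inds) - 1, -1.0, 1.0)
        mid_sizes = np.linspace(0.15, 0.40, len(mid_inds))
        mid_signs = np.where(np.arange(len(mid_inds)) % 2 == 0, 1.0, -1.0)
        mid_map = dict(zip(mid_inds, mid_sizes * mid_signs))
        for cont in self.continuous_names:
            if cont in ("systolic_bp", "diastolic_bp"):
                mid_map[cont] = 0.08
        return [
            EffectPattern("acceleration", shapes["acceleration"],
                          dict(zip(accel_inds, accel_sizes * accel_signs))),
            EffectPattern("midfrequency", shapes["midfrequency"], mid_map),
        ]

    # -- generation ---------------------------------------------------------

    def _effect_matrix(self, state: str) -> np.ndarray:
        """(n_indicators, 193) total implanted effect per indicator."""
        E = np.zeros((len(self.indicator_names), N_BINS))
        for pat in self.effect_patterns:
            scale = 1.0 if state == "NREM" else pat.rem_scale
            for ind, size in pat.sizes.items():
                E[self.indicator_names.index(ind)] += scale * size * pat.shape
        return E

    def generate(self) -> tuple[CohortTables, SpectraSet, GroundTruth]:
        if self._cached is not None:
            return self._cached
        cfg = self.config
        n = cfg.n_subjects
        ss = np.random.SeedSequence([cfg.seed, 1])
        rng_age, rng_ind, rng_noise, rng_macro, rng_miss = (
            np.random.default_rng(c) for c in ss.spawn(5)
        )
        subjects = pd.Index([f"S{i:05d}" for i in range(n)], name="subject_id")

        age = rng_age.normal(cfg.age_mean, cfg.age_sd, n)
        age_z = (age - cfg.age_mean) / cfg.age_sd

        # -- binary indicators: Bernoulli with logit linear in age ----------
        binary = np.zeros((n, len(self.binary_names)))
        low_count: list[str] = []
        for j, (name, prev) in enumerate(zip(self.binary_names, self.prevalences)):
            slope = cfg.age_indicator_logodds if j % 2 == 0 else 0.0
            a = _solve_logit_intercept(prev, slope)
            p = expit(a + slope * age_z)
            col = (rng_ind.random(n) < p).astype(float)
            tries = 0
            while col.sum() < 2 and tries < 20:
                col = (rng_ind.random(n) < p).astype(float)
                tries += 1
            if col.sum() < 2:
                logger.warning(
                    "indicator %s has %d positive subjects after resampling; "
                    "flagged as low-count", name, int(col.sum()),
                )
                low_count.append(name)
            binary[:, j] = col

        # -- continuous indicators ------------------------------------------
        cont_cols = {}
        cont_std = {}
        for name in self.continuous_names:
            if name == "systolic_bp":
                vals = 130.0 + 0.4 * (age - cfg.age_mean) + rng_ind.normal(0, 15, n)
            elif name == "diastolic_bp":
                vals = 75.0 + rng_ind.normal(0, 10, n)
            else:  # coffee_cups
                vals = rng_ind.poisson(0.8, n).astype(float)
            cont_cols[name] = vals
            sd = vals.std()
            cont_std[name] = (vals - vals.mean()) / sd if sd > 0 else np.zeros(n)

        indicators = pd.DataFrame(
            np.column_stack([binary] + [cont_cols[c] for c in self.continuous_names])
            if self.continuous_names else binary,
            index=subjects, columns=self.indicator_names,
        )
        # design matrix that multiplies effect vectors: binary raw 0/1,
        # continuous standardised (effect sizes are per SD)
        X_eff = np.column_stack(
            [binary] + [cont_std[c] for c in self.continuous_names]
        ) if self.continuous_names else binary

        # -- spectra ---------------------------------------------------------
        effect = {st: self._effect_matrix(st) for st in STATES}
        age_vec = {
            st: cfg.age_spectrum_coeff * default_pattern_shapes()["acceleration"]
            for st in STATES
        }
        baseline_abs = {st: baseline_log_psd(FREQS, st) for st in STATES}
        baseline_rel = {st: b - b.mean() for st, b in baseline_abs.items()}

        clean = np.empty((n, len(CHANNELS), len(STATES), N_BINS))
        for k, st in enumerate(STATES):
            signal = (
                baseline_rel[st][None, :]
                + (age - cfg.age_mean)[:, None] * age_vec[st][None, :]
                + X_eff @ effect[st]
            )
            for j in range(len(CHANNELS)):
                clean[:, j, k, :] = signal
        noise = (
            rng_noise.normal(0.0, cfg.noise_sd, clean.shape)
            if cfg.noise_sd > 0 else np.zeros_like(clean)
        )
        values = clean + noise
        values = values - values.mean(axis=-1, keepdims=True)  # relativization
        spectra = SpectraSet(values, subjects)

        # -- macrostructure ---------------------------------------------------
        macro = self._generate_macro(rng_macro, age, X_eff)
        macro.index = subjects

        # -- missingness (table only; spectra/effects use true values) --------
        ind_table = indicators.copy()
        macro_table = macro.copy()
        if cfg.missing_rate > 0:
            ind_mask = rng_miss.random(ind_table.shape) < cfg.missing_rate
            macro_mask = rng_miss.random(macro_table.shape) < cfg.missing_rate
            ind_table = ind_table.mask(ind_mask)
            macro_table = macro_table.mask(macro_mask)

        cohort = CohortTables(
            pd.Series(age, index=subjects, name="age"), ind_table, macro_table
        )
        truth = GroundTruth(
            indicator_names=list(self.indicator_names),
            effect_vectors=effect,
            macro_effects=self.macro_effects.copy(),
            age_vector=age_vec,
            cluster_labels=self.cluster_labels.copy(),
            pattern_shapes={p.name: p.shape for p in self.effect_patterns},
            baseline_rel=baseline_rel,
            prevalences=pd.Series(self.prevalences, index=self.binary_names),
            clean_rel_logpsd=clean - clean.mean(axis=-1, keepdims=True),
            low_count_indicators=low_count,
        )
        self._cached = (cohort, spectra, truth)
        return self._cached

    def _generate_macro(self, rng: np.random.Generator, age: np.ndarray,
                        X_eff: np.ndarray) -> pd.DataFrame:
        cfg = self.config
        n = len(age)
        dev = age - cfg.age_mean
        lat = {
            "sleep_onset_time": rng.normal(0.2, 0.9, n),
            "sleep_latency": np.clip(rng.normal(20, 12, n), 0, None),
            "waso": np.clip(rng.normal(90, 35, n) + 1.0 * dev, 0, None),
            "n1_duration": np.clip(rng.normal(40, 15, n), 5, None),
            "n2_duration": np.clip(rng.normal(200, 40, n), 30, None),
            "sws_duration": np.clip(rng.normal(60, 25, n) - 0.8 * dev, 0, None),
            "rem_duration": np.clip(rng.normal(75, 25, n), 5, None),
            "rem_latency": np.clip(rng.normal(90, 35, n), 10, None),
        }
        lat["rem_latency_nowake"] = np.clip(
            0.85 * lat["rem_latency"] + rng.normal(0, 5, n), 5, None
        )
        # implant indicator-linked shifts on the latent columns
        for col in lat:
            shift = X_eff @ self.macro_effects[col].values
            lat[col] = lat[col] + shift
        tst = (
            lat["n1_duration"] + lat["n2_duration"]
            + lat["sws_duration"] + lat["rem_duration"]
        )
        out = pd.DataFrame(index=range(n))
        out["sleep_onset_time"] = lat["sleep_onset_time"]
        out["tst"] = tst
        out["waso"] = lat["waso"]
        out["sleep_efficiency"] = 100.0 * tst / (tst + lat["waso"] + lat["sleep_latency"])
        out["sleep_latency"] = lat["sleep_latency"]
        out["rem_latency"] = lat["rem_latency"]
        out["rem_latency_nowake"] = lat["rem_latency_nowake"]
        for stage in ("n1", "n2", "sws", "rem"):
            out[f"{stage}_duration"] = lat[f"{stage}_duration"]
            out[f"{stage}_pct"] = 100.0 * lat[f"{stage}_duration"] / tst
        return out[MACRO_COLUMNS]

    # -- raw-signal synthesis -------------------------------------------------

    def _stage_sequence(self, n_epochs: int) -> list[str]:
        # compressed 4-min sleep cycle so even short recordings reach REM
        cycle = (
            ["Wake"] * 4 + ["N1"] * 4 + ["N2"] * 18 + ["SWS"] * 12
            + ["N2"] * 8 + ["REM"] * 14
        )
        reps = n_epochs // len(cycle) + 1
        return (cycle * reps)[:n_epochs]

    def raw_recording(self, subject_id: str, minutes: float | None = None) -> EpochedRecording:
        """Synthesize a raw 256 Hz recording realising the subject's spectrum.

        Each contiguous same-stage block is colored Gaussian noise whose
        expected periodogram equals the subject's absolute target PSD for
        that state (spectral factorization in the frequency domain).
        ``artifact_fraction`` of the epochs are scaled x10 on both channels
        at indices recorded in ``true_artifact_epochs``.
        """
        cfg = self.config
        minutes = cfg.raw_minutes if minutes is None else minutes
        n_epochs = int(round(minutes * 60.0 / spectral.EPOCH_SECONDS))
        if n_epochs < 1:
            raise ValueError("requested duration shorter than one 4-s epoch")
        cohort, _, truth = self.generate()
        idx = cohort.subjects.get_loc(subject_id)
        fs = spectral.DEFAULT_SFREQ
        spe = int(round(spectral.EPOCH_SECONDS * fs))
        stages = self._stage_sequence(n_epochs)
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, _RAW_STREAM, int(idx)])
        )

        # per-state continuous absolute log-PSD target for this subject
        def target_log_psd(fgrid: np.ndarray, stage: str) -> np.ndarray:
            state = spectral.state_of_stage(stage)
            if state is None:
                return baseline_log_psd(fgrid, "Wake")
            # relative clean spectrum + baseline mean restores the absolute scale
            rel = truth.clean_rel_logpsd[idx, 0, STATES.index(state)]
            base_abs = baseline_log_psd(FREQS, state)
            abs_on_grid = rel + base_abs.mean()
            out = baseline_log_psd(fgrid, state)
            inside = fgrid <= FREQS[-1]
            out[inside] = np.interp(fgrid[inside], FREQS, abs_on_grid)
            return out

        samples = {ch: np.empty(n_epochs * spe) for ch in CHANNELS}
        # synthesize per contiguous same-stage block
        block_start = 0
        for i in range(1, n_epochs + 1):
            if i == n_epochs or stages[i] != stages[block_start]:
                length = (i - block_start) * spe
                fgrid = np.fft.rfftfreq(length, 1.0 / fs)
                amp = np.sqrt(10.0 ** target_log_psd(fgrid, stages[block_start]) * fs * length / 2.0)
                for ch in CHANNELS:
                    z = rng.normal(size=len(fgrid)) + 1j * rng.normal(size=len(fgrid))
                    z *= np.sqrt(0.5)
                    spec = z * amp
                    spec[0] = rng.normal() * np.sqrt(10.0 ** target_log_psd(fgrid[:1], stages[block_start])[0] * fs * length)
                    if length % 2 == 0:
                        spec[-1] = spec[-1].real * np.sqrt(2.0)
                    samples[ch][block_start * spe : i * spe] = np.fft.irfft(spec, length)
                block_start = i

        n_art = int(round(cfg.artifact_fraction * n_epochs))
        art_idx = np.sort(rng.choice(n_epochs, size=n_art, replace=False)) if n_art else np.array([], dtype=int)
        for ch in CHANNELS:
            sig = samples[ch].reshape(n_epochs, spe)
            sig[art_idx] *= 10.0
            samples[ch] = sig.reshape(-1)

        return EpochedRecording(
            subject_id=subject_id,
            sampling_rate=fs,
            samples=samples,
            stage_labels=stages,
            true_artifact_epochs=art_idx,
        )


# ---------------------------------------------------------------------------
# Module-level convenience API
# ---------------------------------------------------------------------------


def generate_cohort(config: GeneratorConfig) -> tuple[CohortTables, SpectraSet, GroundTruth]:
    """Generate the full synthetic cohort (tables, spectra, ground truth)."""
    return CohortGenerator(config).generate()


def generate_raw_recording(
    config: GeneratorConfig, subject_id: str, minutes: float | None = None
) -> EpochedRecording:
    """Generate one subject's raw two-channel recording (see CohortGenerator)."""
    return CohortGenerator(config).raw_recording(subject_id, minutes)
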