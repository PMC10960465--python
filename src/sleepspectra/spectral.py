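"""Spectral processing of epoched sleep-EEG recordings.

Turns a stage-labelled, epoched EEG recording into per-vigilance-state
relative log-PSD spectra:

1. Hjorth-parameter artifact rejection (4-s basis, per channel, per stage;
   an epoch is rejected when any of activity/mobility/complexity deviates
   from the stage average by at least 2 SD).
2. Windowing of contiguous artifact-free runs: 4-s Hamming windows with 50%
   overlap; runs shorter than 6 s get a single non-overlapping window; runs
   shorter than 4 s contribute nothing.
3. Single-window periodograms on a 0.25 Hz grid, retaining 0-48 Hz
   (193 bins; the 0 Hz bin is mean voltage).
4. Averaging of window PSDs within state (NREM pools N1+N2+SWS), log10
   transform, and relativization by subtracting the mean over bins, which
   removes between-subject voltage scale.
5. Optional reduction to 48 bins by dropping the DC bin and averaging
   batches of 4 adjacent bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import periodogram as _scipy_periodogram

logger = logging.getLogger(__name__)

#: Nominal sampling rate of the recordings (Hz).
DEFAULT_SFREQ = 256.0
#: Analysis epoch length in seconds.
EPOCH_SECONDS = 4.0
#: Number of retained periodogram bins (0 .. 48 Hz at 0.25 Hz).
N_BINS = 193
#: Number of reduced bins after 4-bin averaging (DC dropped).
N_BINS_REDUCED = 48
#: Frequency grid of the retained bins, Hz.
FREQS = np.arange(N_BINS) * 0.25
#: Centers of the reduced bins, Hz (mean of each batch of 4 post-DC bins).
FREQS_REDUCED = 0.625 + np.arange(N_BINS_REDUCED)

STAGES = ("Wake", "N1", "N2", "SWS", "REM")
NREM_STAGES = frozenset({"N1", "N2", "SWS"})
STATES = ("NREM", "REM")


def state_of_stage(stage: str) -> str | None:
    """Vigilance-state class of a stage label (Wake maps to None)."""
    if stage in NREM_STAGES:
        return "NREM"
    if stage == "REM":
        return "REM"
    return None


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HjorthTriple:
    """Hjorth descriptors of one epoch.

    activity
        Signal variance (µV²).
    mobility
        sqrt(var(Δx) / var(x)) — a normalised mean frequency.
    complexity
        mobility(Δx) / mobility(x) — bandwidth-like shape measure.

    For a constant epoch mobility and complexity are undefined and stored
    as NaN; such epochs are always treated as artifactual downstream.
    """

    activity: float
    mobility: float
    complexity: float

    @property
    def is_defined(self) -> bool:
        return bool(
            np.isfinite(self.activity)
            and np.isfinite(self.mobility)
            and np.isfinite(self.complexity)
        )


@dataclass
class EpochedRecording:
    """A per-subject signal cut into whole 4-s epochs with stage labels.

    ``samples`` maps channel name -> 1-D float array in µV. Any trailing
    partial epoch is dropped (and logged) at construction. ``artifact_flags``
    maps channel -> boolean array over epochs (True = rejected) and is
    filled in by :func:`reject_artifacts`.
    """

    subject_id: str
    sampling_rate: float
    samples: dict[str, np.ndarray]
    stage_labels: list[str]
    epoch_length: float = EPOCH_SECONDS
    artifact_flags: dict[str, np.ndarray] = field(default_factory=dict)
    true_artifact_epochs: np.ndarray | None = None

    def __post_init__(self) -> None:
        spe = self.samples_per_epoch
        n_epochs = min(len(v) // spe for v in self.samples.values())
        if n_epochs < 1:
            raise ValueError("recording shorter than one epoch")
        for ch, sig in self.samples.items():
            sig = np.asarray(sig, dtype=float)
            if len(sig) > n_epochs * spe:
                logger.info(
                    "subject %s channel %s: dropping trailing partial epoch "
                    "(%d samples)", self.subject_id, ch, len(sig) - n_epochs * spe,
                )
            self.samples[ch] = sig[: n_epochs * spe]
        if len(self.stage_labels) != n_epochs:
            raise ValueError(
                f"stage_labels length {len(self.stage_labels)} != epoch count {n_epochs}"
            )

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_length * self.sampling_rate))

    @property
    def channels(self) -> list[str]:
        return list(self.samples)

    @property
    def n_epochs(self) -> int:
        return len(self.stage_labels)

    def epochs(self, channel: str) -> np.ndarray:
        """Signal of one channel reshaped to (n_epochs, samples_per_epoch)."""
        return self.samples[channel].reshape(self.n_epochs, self.samples_per_epoch)


@dataclass
class SubjectSpectra:
    """Per-subject relative log-PSD spectra.

    ``rel_log_psd`` maps (channel, state) -> 193-bin vector that sums to ~0
    (the relativization contract); states with no usable windows hold NaN.
    """

    subject_id: str
    rel_log_psd: dict[tuple[str, str], np.ndarray]
    n_windows: dict[tuple[str, str], int]
    n_epochs_used: dict[tuple[str, str], int]
    n_epochs_rejected: dict[tuple[str, str], int]

    def reduced(self, channel: str, state: str) -> np.ndarray:
        return reduce_bins(self.rel_log_psd[(channel, state)])


# ---------------------------------------------------------------------------
# Hjorth parameters and artifact rejection
# ---------------------------------------------------------------------------


def hjorth_parameters(epoch_signal: np.ndarray) -> HjorthTriple:
    """Hjorth activity, mobility and complexity of one epoch.

    activity = var(x); mobility = sqrt(var(Δx)/var(x));
    complexity = mobility(Δx)/mobility(x).
    """
    x = np.asarray(epoch_signal, dtype=float)
    if x.size < 3:
        raise ValueError("epoch must have at least 3 samples")
    a, m, c = _hjorth_matrix(x[None, :])
    return HjorthTriple(float(a[0]), float(m[0]), float(c[0]))


def _hjorth_matrix(epochs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Hjorth parameters for a (n_epochs, n_samples) array."""
    var0 = epochs.var(axis=1)
    d1 = np.diff(epochs, axis=1)
    var1 = d1.var(axis=1)
    d2 = np.diff(d1, axis=1)
    var2 = d2.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mobility = np.sqrt(var1 / var0)
        mob_d1 = np.sqrt(var2 / var1)
        complexity = mob_d1 / mobility
    mobility = np.where(var0 > 0, mobility, np.nan)
    complexity = np.where((var0 > 0) & (var1 > 0), complexity, np.nan)
    return var0, mobility, complexity


def reject_artifacts(recording: EpochedRecording) -> EpochedRecording:
    """Flag artifact epochs by extreme Hjorth parameters, single pass.

    Per channel and per stage label, the mean and SD of each Hjorth
    parameter are computed across that stage's epochs; an epoch is flagged
    when, for any parameter, its absolute deviation from the stage mean is
    at least 2 SD (and strictly positive, so that degenerate stages whose
    statistics are all identical reject nothing). Stages with fewer than 3
    epochs are left untouched with a warning. Epochs with undefined Hjorth
    parameters (constant signal) are always flagged.
    """
    stages = np.asarray(recording.stage_labels)
    flags: dict[str, np.ndarray] = {}
    for ch in recording.channels:
        act, mob, com = _hjorth_matrix(recording.epochs(ch))
        params = np.column_stack([act, mob, com])
        flagged = ~np.all(np.isfinite(params), axis=1)
        for stage in np.unique(stages):
            idx = np.flatnonzero((stages == stage) & ~flagged)
            if idx.size < 3:
                logger.warning(
                    "subject %s channel %s stage %s: only %d epochs, "
                    "no artifact rejection applied",
                    recording.subject_id, ch, stage, idx.size,
                )
                continue
            p = params[idx]
            mean = p.mean(axis=0)
            sd = p.std(axis=0)
            dev = np.abs(p - mean)
            extreme = np.any((dev >= 2.0 * sd) & (dev > 0), axis=1)
            flagged[idx[extreme]] = True
        flags[ch] = flagged
    return replace(recording, artifact_flags=flags)


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------


def segment_windows(run_samples: int, sampling_rate: float = DEFAULT_SFREQ) -> list[int]:
    """Start offsets (in samples) of 4-s analysis windows within a clean run.

    Runs of at least 6 s are tiled with 4-s windows stepping 2 s (50%
    overlap), keeping only fully contained windows; runs of 4-6 s yield a
    single window at the run start; shorter runs yield none.
    """
    if run_samples < 0:
        raise ValueError("negative run length")
    win = int(round(EPOCH_SECONDS * sampling_rate))
    step = win // 2
    if run_samples < win:
        return []
    if run_samples < int(round(6.0 * sampling_rate)):
        return [0]
    return list(range(0, run_samples - win + 1, step))


def clean_runs(recording: EpochedRecording, channel: str, state: str) -> list[tuple[int, int]]:
    """Contiguous artifact-free epoch runs of one vigilance state.

    Returns (start_sample, n_samples) pairs. A run is a maximal block of
    consecutive epochs that all belong to ``state`` (NREM pools N1/N2/SWS)
    and are not flagged as artifacts on ``channel``.
    """
    flags = recording.artifact_flags.get(channel)
    if flags is None:
        raise ValueError("artifact flags missing; call reject_artifacts first")
    ok = np.array(
        [state_of_stage(s) == state for s in recording.stage_labels]
    ) & ~flags
    spe = recording.samples_per_epoch
    runs: list[tuple[int, int]] = []
    start = None
    for i, good in enumerate(list(ok) + [False]):
        if good and start is None:
            start = i
        elif not good and start is not None:
            runs.append((start * spe, (i - start) * spe))
            start = None
    return runs


# ---------------------------------------------------------------------------
# Periodogram and aggregation
# ---------------------------------------------------------------------------


def periodogram_psd(
    window: np.ndarray,
    sampling_rate: float = DEFAULT_SFREQ,
    taper: str | None = "hamming",
    max_freq: float | None = 48.0,
) -> np.ndarray:
    """One-sided periodogram PSD of a single 4-s window.

    The window must hold exactly ``4 * sampling_rate`` samples (1024 at
    256 Hz, giving a 0.25 Hz grid). The Hamming taper is power-compensated
    (density scaling), so a flat-spectrum white-noise input matches the
    analytic one-sided density 2 sigma^2 / fs off DC. The mean is *not*
    removed: the 0 Hz bin carries mean voltage. With the default
    ``max_freq=48`` exactly 193 bins are returned.
    """
    x = np.asarray(window, dtype=float)
    expected = int(round(EPOCH_SECONDS * sampling_rate))
    if x.size != expected:
        raise ValueError(f"window must have {expected} samples, got {x.size}")
    freqs, pxx = _scipy_periodogram(
        x,
        fs=sampling_rate,
        window=taper if taper is not None else "boxcar",
        detrend=False,
        scaling="density",
    )
    if max_freq is None:
        return pxx
    return pxx[freqs <= max_freq + 1e-9]


def aggregate_state_psd(
    window_psds: np.ndarray, floor_factor: float = 1e-12
) -> np.ndarray:
    """Average window PSDs, log10-transform and relativize.

    ``window_psds`` is (n_windows, n_bins). The mean PSD is floored at
    ``floor_factor`` times its median positive value before the log (zero
    bins are logged), then log10 is taken and the mean over bins subtracted,
    so the result sums to zero. Order matters: the average is taken on the
    linear PSD scale *before* the log transform.
    """
    psds = np.atleast_2d(np.asarray(window_psds, dtype=float))
    if psds.shape[0] < 1:
        raise ValueError("need at least one window")
    mean_psd = psds.mean(axis=0)
    positive = mean_psd[mean_psd > 0]
    if positive.size == 0:
        raise ValueError("all-zero spectrum")
    floor = floor_factor * np.median(positive)
    n_floored = int(np.sum(mean_psd < floor))
    if n_floored:
        logger.info("flooring %d zero/tiny PSD bins at %.3g", n_floored, floor)
        mean_psd = np.maximum(mean_psd, floor)
    log_psd = np.log10(mean_psd)
    return log_psd - log_psd.mean()


def reduce_bins(rel_log_psd: np.ndarray) -> np.ndarray:
    """Reduce 193 bins to 48 by dropping DC and averaging batches of 4.

    The 0 Hz bin is mean voltage and is discarded; the remaining 192 bins
    are averaged in 48 consecutive groups of 4 (centers 0.625, 1.625, ...,
    47.625 Hz).
    """
    v = np.asarray(rel_log_psd, dtype=float)
    if v.shape[-1] != N_BINS:
        raise ValueError(f"expected {N_BINS} bins, got {v.shape[-1]}")
    return v[..., 1:].reshape(*v.shape[:-1], N_BINS_REDUCED, 4).mean(axis=-1)


# ---------------------------------------------------------------------------
# Whole-recording driver
# ---------------------------------------------------------------------------


def compute_subject_spectra(
    recording: EpochedRecording,
    floor_factor: float = 1e-12,
    taper: str | None = "hamming",
) -> SubjectSpectra:
    """Full spectral pipeline for one recording.

    Applies artifact rejection if not already done, then per channel and
    per state (NREM, REM): windows the clean runs, averages single-window
    periodograms, and returns relative log-PSD over the 193-bin grid.
    States with no usable windows get NaN vectors (logged).
    """
    if not recording.artifact_flags:
        recording = reject_artifacts(recording)
    spe = recording.samples_per_epoch
    rel: dict[tuple[str, str], np.ndarray] = {}
    n_windows: dict[tuple[str, str], int] = {}
    n_used: dict[tuple[str, str], int] = {}
    n_rej: dict[tuple[str, str], int] = {}
    stage_state = np.array([state_of_stage(s) for s in recording.stage_labels], dtype=object)
    for ch in recording.channels:
        sig = recording.samples[ch]
        flags = recording.artifact_flags[ch]
        for state in STATES:
            in_state = stage_state == state
            n_rej[(ch, state)] = int(np.sum(in_state & flags))
            n_used[(ch, state)] = int(np.sum(in_state & ~flags))
            psds = []
            for start, length in clean_runs(recording, ch, state):
                for off in segment_windows(length, recording.sampling_rate):
                    psds.append(
                        periodogram_psd(
                            sig[start + off : start + off + spe],
                            recording.sampling_rate,
                            taper=taper,
                        )
                    )
            n_windows[(ch, state)] = len(psds)
            if psds:
                rel[(ch, state)] = aggregate_state_psd(np.array(psds), floor_factor)
            else:
                logger.warning(
                    "subject %s channel %s: no usable %s windows",
                    recording.subject_id, ch, state,
                )
                rel[(ch, state)] = np.full(N_BINS, np.nan)
    return SubjectSpectra(recording.subject_id, rel, n_windows, n_used, n_rej)
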