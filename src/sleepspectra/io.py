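"""File formats: EDF signals, plain-text hypnograms, pipeline config.

EDF reading goes through MNE. Writing uses a minimal 16-bit EDF writer
(standard 256-byte header plus per-signal headers, 1-s data records),
sufficient for the two-channel synthetic recordings this package emits.
Hypnograms are plain text, one stage label per line; 30-s staging epochs
are mapped onto the 4-s analysis grid by the label covering each window's
midpoint.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import spectral
from .spectral import EpochedRecording

logger = logging.getLogger(__name__)

_EDF_DIG_MAX = 32767


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if isinstance(value, float):
        for prec in range(10, 0, -1):
            s = f"{value:.{prec}g}"
            if len(s) <= width:
                break
    if len(s) > width:
        raise ValueError(f"EDF field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, recording: EpochedRecording) -> None:
    """Write a recording as 16-bit EDF with 1-s data records.

    Channel labels are prefixed "EEG " so readers classify them as EEG;
    physical units are µV with a symmetric range covering the signal.
    """
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    channels = recording.channels
    n_samples = min(len(recording.samples[ch]) for ch in channels)
    n_records = n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record")
    ns = len(channels)
    header_bytes = 256 * (1 + ns)

    phys: dict[str, tuple[float, float, float]] = {}
    for ch in channels:
        sig = recording.samples[ch][: n_records * spr]
        amp = max(float(np.max(np.abs(sig))), 1e-6) * 1.0001
        phys[ch] = (-amp, amp, _EDF_DIG_MAX / amp)

    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field(f"subject {recording.subject_id}", 80))
        fh.write(_edf_field("synthetic sleep EEG", 80))
        fh.write(_edf_field("01.01.04", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(header_bytes, 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(n_records, 8))
        fh.write(_edf_field(1, 8))
        fh.write(_edf_field(ns, 4))
        for ch in channels:
            fh.write(_edf_field(f"EEG {ch}", 16))
        for _ in channels:
            fh.write(_edf_field("AgAgCl electrode", 80))
        for _ in channels:
            fh.write(_edf_field("uV", 8))
        for ch in channels:
            fh.write(_edf_field(phys[ch][0], 8))
        for ch in channels:
            fh.write(_edf_field(phys[ch][1], 8))
        for _ in channels:
            fh.write(_edf_field(-_EDF_DIG_MAX - 1, 8))
        for _ in channels:
            fh.write(_edf_field(_EDF_DIG_MAX, 8))
        for _ in channels:
            fh.write(_edf_field("HP:0.15Hz", 80))
        for _ in channels:
            fh.write(_edf_field(spr, 8))
        for _ in channels:
            fh.write(_edf_field("", 32))
        for rec in range(n_records):
            for ch in channels:
                sig = recording.samples[ch][rec * spr : (rec + 1) * spr]
                dig = np.clip(np.round(sig * phys[ch][2]), -_EDF_DIG_MAX - 1, _EDF_DIG_MAX)
                fh.write(dig.astype("<i2").tobytes())


def read_edf(path: str | Path) -> tuple[dict[str, np.ndarray], float]:
    """Read an EDF file via MNE; returns ({channel: signal µV}, sfreq).

    The "EEG " label prefix is stripped from channel names and MNE's
    Volt-scaled EEG data is converted back to µV.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6
    signals = {}
    for name, row in zip(raw.ch_names, data):
        clean = name[4:] if name.startswith("EEG ") else name
        signals[clean] = row
    return signals, float(raw.info["sfreq"])


# ---------------------------------------------------------------------------
# Hypnograms
# ---------------------------------------------------------------------------


def write_hypnogram(path: str | Path, stage_labels: list[str]) -> None:
    """One stage label per line, one line per 4-s analysis epoch."""
    Path(path).write_text("\n".join(stage_labels) + "\n")


def read_hypnogram(
    path: str | Path, staging_epoch_s: float = spectral.EPOCH_SECONDS
) -> list[str]:
    """Read a plain-text hypnogram onto the 4-s analysis grid.

    With ``staging_epoch_s=4`` (default) labels are taken verbatim. For
    coarser visual staging (e.g. 30-s epochs) each 4-s analysis window,
    aligned to the recording start, takes the stage label covering the
    window's midpoint.
    """
    labels = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    if staging_epoch_s == spectral.EPOCH_SECONDS:
        return labels
    total = len(labels) * staging_epoch_s
    n_windows = int(total // spectral.EPOCH_SECONDS)
    out = []
    for w in range(n_windows):
        midpoint = (w + 0.5) * spectral.EPOCH_SECONDS
        out.append(labels[min(int(midpoint // staging_epoch_s), len(labels) - 1)])
    return out


def load_recording(
    edf_path: str | Path,
    hypnogram_path: str | Path,
    subject_id: str | None = None,
    staging_epoch_s: float = spectral.EPOCH_SECONDS,
) -> EpochedRecording:
    """Assemble an EpochedRecording from an EDF file and a hypnogram."""
    signals, fs = read_edf(edf_path)
    stages = read_hypnogram(hypnogram_path, staging_epoch_s)
    spe = int(round(spectral.EPOCH_SECONDS * fs))
    n_epochs = min(min(len(s) for s in signals.values()) // spe, len(stages))
    signals = {ch: sig[: n_epochs * spe] for ch, sig in signals.items()}
    return EpochedRecording(
        subject_id=subject_id or Path(edf_path).stem,
        sampling_rate=fs,
        samples=signals,
        stage_labels=stages[:n_epochs],
    )


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Round-trippable configuration of a full pipeline run."""

    cohort_path: str = ""
    spectra_path: str = ""
    edf_dir: str = ""
    output_dir: str = "sleepspectra_out"
    mode: str = "spectra"
    alpha: float = 0.05
    k: int = 3
    seed: int = 0
    kmeans_restarts: int = 50
    pca_variant: str = "correlation"
    psd_floor_factor: float = 1e-12
    staging_epoch_s: float = 4.0
    run_sensitivity: bool = False
    sensitivity_group: str = ""
    sensitivity_within: str = ""

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Digest of the analysis-relevant fields (output location excluded)."""
        fields = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        payload = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def provenance_header(config_hash: str) -> list[str]:
    from . import __version__

    return [f"sleepspectra v{__version__}", f"config_sha={config_hash}"]
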