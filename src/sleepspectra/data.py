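"""Cohort-level containers: health/macrostructure tables and PSD spectra.

These are thin wrappers around pandas/numpy objects that enforce the
alignment contracts the analysis modules rely on (shared subject index,
fixed channel/state/bin axes) and provide TSV round-trips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import spectral

logger = logging.getLogger(__name__)

#: The 15 sleep-macrostructure variables screened against every indicator.
MACRO_COLUMNS = [
    "sleep_onset_time",
    "tst",
    "waso",
    "sleep_efficiency",
    "sleep_latency",
    "rem_latency",
    "rem_latency_nowake",
    "n1_duration",
    "n2_duration",
    "sws_duration",
    "rem_duration",
    "n1_pct",
    "n2_pct",
    "sws_pct",
    "rem_pct",
]

CHANNELS = ("C3", "C4")
STATES = spectral.STATES

_MACRO_PREFIX = "macro."


@dataclass
class CohortTables:
    """Health-indicator table, macrostructure table and age, aligned on subject.

    ``indicators`` columns are binary (0/1, NaN for missing) or continuous
    (blood pressures, counts); ``macrostructure`` holds the 15 stage-level
    summary variables. All three share the subject index.
    """

    age: pd.Series
    indicators: pd.DataFrame
    macrostructure: pd.DataFrame

    def __post_init__(self) -> None:
        if not (
            self.age.index.equals(self.indicators.index)
            and self.age.index.equals(self.macrostructure.index)
        ):
            raise ValueError("age, indicators and macrostructure must share a subject index")

    @property
    def subjects(self) -> pd.Index:
        return self.age.index

    @property
    def n_subjects(self) -> int:
        return len(self.age)

    def binary_indicators(self) -> list[str]:
        """Indicator columns whose observed values are all in {0, 1}."""
        out = []
        for col in self.indicators.columns:
            vals = self.indicators[col].dropna().unique()
            if len(vals) and np.all(np.isin(vals, (0.0, 1.0))):
                out.append(col)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Single wide table: subject_id, age, indicators, ``macro.``-prefixed macrostructure."""
        macro = self.macrostructure.add_prefix(_MACRO_PREFIX)
        return pd.concat([self.age.rename("age"), self.indicators, macro], axis=1)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortTables":
        macro_cols = [c for c in frame.columns if c.startswith(_MACRO_PREFIX)]
        ind_cols = [c for c in frame.columns if c != "age" and c not in macro_cols]
        macro = frame[macro_cols].rename(columns=lambda c: c[len(_MACRO_PREFIX):])
        return cls(frame["age"].astype(float), frame[ind_cols].astype(float), macro.astype(float))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="subject_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortTables":
        frame = pd.read_csv(path, sep="\t", index_col="subject_id", comment="#")
        return cls.from_frame(frame)


@dataclass
class SpectraSet:
    """Relative log-PSD spectra for a whole cohort.

    ``values`` has shape (n_subjects, n_channels, n_states, n_bins); bins
    are either the 193-bin 0.25 Hz grid or the reduced 48-bin grid.
    """

    values: np.ndarray
    subjects: pd.Index
    channels: tuple[str, ...] = CHANNELS
    states: tuple[str, ...] = STATES
    freqs: np.ndarray = field(default_factory=lambda: spectral.FREQS.copy())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.subjects), len(self.channels), len(self.states), len(self.freqs))
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")

    @property
    def n_bins(self) -> int:
        return len(self.freqs)

    def get(self, channel: str, state: str) -> np.ndarray:
        """(n_subjects, n_bins) slice for one channel and state."""
        return self.values[:, self.channels.index(channel), self.states.index(state), :]

    def reduced(self) -> "SpectraSet":
        """4-bin reduction of a 193-bin set (drops DC, averages batches of 4)."""
        if self.n_bins != spectral.N_BINS:
            raise ValueError("reduced() expects the 193-bin grid")
        return SpectraSet(
            spectral.reduce_bins(self.values),
            self.subjects,
            self.channels,
            self.states,
            spectral.FREQS_REDUCED.copy(),
        )

    @classmethod
    def from_subject_spectra(cls, spectra: list[spectral.SubjectSpectra]) -> "SpectraSet":
        subjects = pd.Index([s.subject_id for s in spectra], name="subject_id")
        values = np.full((len(spectra), len(CHANNELS), len(STATES), spectral.N_BINS), np.nan)
        for i, s in enumerate(spectra):
            for j, ch in enumerate(CHANNELS):
                for k, st in enumerate(STATES):
                    if (ch, st) in s.rel_log_psd:
                        values[i, j, k] = s.rel_log_psd[(ch, st)]
        return cls(values, subjects)

    def to_frame(self) -> pd.DataFrame:
        """Long-over-rows format: one row per subject x channel x state."""
        rows = []
        index = []
        for i, sid in enumerate(self.subjects):
            for j, ch in enumerate(self.channels):
                for k, st in enumerate(self.states):
                    index.append((sid, ch, st))
                    rows.append(self.values[i, j, k])
        cols = [f"bin_{f:.3f}" for f in self.freqs]
        idx = pd.MultiIndex.from_tuples(index, names=["subject_id", "channel", "state"])
        return pd.DataFrame(rows, index=idx, columns=cols)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SpectraSet":
        freqs = np.array([float(c.split("_", 1)[1]) for c in frame.columns])
        subjects = pd.Index(frame.index.get_level_values("subject_id").unique(), name="subject_id")
        channels = tuple(frame.index.get_level_values("channel").unique())
        states = tuple(frame.index.get_level_values("state").unique())
        values = np.full((len(subjects), len(channels), len(states), len(freqs)), np.nan)
        for (sid, ch, st), row in frame.iterrows():
            values[subjects.get_loc(sid), channels.index(ch), states.index(st)] = row.values
        return cls(values, subjects, channels, states, freqs)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpectraSet":
        frame = pd.read_csv(
            path, sep="\t", index_col=["subject_id", "channel", "state"], comment="#"
        )
        frame.index = frame.index.set_levels(
            frame.index.levels[0].astype(str), level="subject_id"
        )
        return cls.from_frame(frame)
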