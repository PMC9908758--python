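"""Core data containers for the factorial evoked-potential pipeline.

The study design is a 2x2 within-subject factorial: *congruency*
(congruent / incongruent: spatial match between executed and displayed
movement) x *synchrony* (synchronous / asynchronous: temporal match).
Every subject contributes all four cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .montage import ElectrodeMontage

__all__ = [
    "CONGRUENCY_LEVELS",
    "SYNCHRONY_LEVELS",
    "CONDITIONS",
    "condition_id",
    "condition_factors",
    "EpochedEEG",
    "EvokedDataset",
    "BehavioralTable",
    "average_reference",
]

CONGRUENCY_LEVELS = ("congruent", "incongruent")
SYNCHRONY_LEVELS = ("synchronous", "asynchronous")

#: Canonical cell order used throughout: CS, CA, IS, IA.
CONDITIONS = tuple(f"{c}-{s}" for c in CONGRUENCY_LEVELS for s in SYNCHRONY_LEVELS)


def condition_id(congruency: str, synchrony: str) -> str:
    if congruency not in CONGRUENCY_LEVELS or synchrony not in SYNCHRONY_LEVELS:
        raise ValueError(f"unknown factor levels ({congruency!r}, {synchrony!r})")
    return f"{congruency}-{synchrony}"


def condition_factors(cond: str) -> tuple[str, str]:
    congruency, synchrony = cond.split("-")
    if condition_id(congruency, synchrony) != cond:
        raise ValueError(f"malformed condition id {cond!r}")
    return congruency, synchrony


def average_reference(data: np.ndarray, axis: int | None = None) -> np.ndarray:
    """Re-reference so the instantaneous spatial mean over channels is zero.

    ``axis`` is the channel axis; by default the last axis of a 1-D
    topography and the second-to-last of (.., channels, samples) arrays.
    """
    data = np.asarray(data, dtype=float)
    if axis is None:
        axis = -1 if data.ndim == 1 else -2
    return data - data.mean(axis=axis, keepdims=True)


@dataclass
class EpochedEEG:
    """Stimulus-locked EEG epochs for one subject x condition cell.

    data : (n_epochs, n_channels, n_samples) potentials in microvolt.
    sfreq : sampling rate in samples/s.
    t0_offset : epoch start relative to stimulus onset in seconds
        (negative = pre-stimulus).  The epoch window is half-open:
        sample k is at time ``t0_offset + k / sfreq``.
    """

    data: np.ndarray
    sfreq: float
    t0_offset: float
    subject_id: str
    condition_id: str
    montage: ElectrodeMontage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochedEEG.data must be (epochs, channels, samples)")
        if self.data.shape[1] != self.montage.n_channels:
            raise ValueError(
                f"channel count {self.data.shape[1]} does not match montage "
                f"({self.montage.n_channels} channels)"
            )
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        condition_factors(self.condition_id)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.n_samples) / self.sfreq


@dataclass
class EvokedDataset:
    """Per subject x condition average (evoked) waveforms.

    evoked : mapping (subject_id, condition_id) -> (n_channels, n_samples)
        average-referenced waveforms in microvolt on a common time base.
    """

    evoked: dict[tuple[str, str], np.ndarray]
    sfreq: float
    t0_offset: float
    montage: ElectrodeMontage
    n_epochs_used: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.evoked:
            raise ValueError("EvokedDataset is empty")
        shapes = set()
        for key, arr in self.evoked.items():
            arr = np.asarray(arr, dtype=float)
            self.evoked[key] = arr
            shapes.add(arr.shape)
            condition_factors(key[1])
        if len(shapes) != 1:
            raise ValueError(f"inconsistent waveform shapes: {sorted(shapes)}")
        (shape,) = shapes
        if shape[0] != self.montage.n_channels:
            raise ValueError("waveform channel count does not match montage")
        missing = [
            (s, c) for s in self.subjects for c in CONDITIONS if (s, c) not in self.evoked
        ]
        if missing:
            raise ValueError(f"incomplete 2x2 design; missing cells: {missing}")
        scale = max(max(np.abs(a).max() for a in self.evoked.values()), 1.0)
        for key, arr in self.evoked.items():
            if np.abs(arr.mean(axis=0)).max() > 1e-9 * scale:
                raise ValueError(f"waveform for {key} is not average-referenced")

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(sorted({s for s, _ in self.evoked}))

    @property
    def n_samples(self) -> int:
        return next(iter(self.evoked.values())).shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.n_samples) / self.sfreq

    def stack(self, condition: str) -> np.ndarray:
        """(n_subjects, n_channels, n_samples) stack for one condition."""
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return np.stack([self.evoked[(s, condition)] for s in self.subjects])

    def grand_average(self, condition: str | None = None) -> np.ndarray:
        """Across-subject mean waveform, optionally for a single condition."""
        if condition is not None:
            return self.stack(condition).mean(axis=0)
        return np.mean([self.stack(c).mean(axis=0) for c in CONDITIONS], axis=0)


#: BehavioralTable outcome columns and their valid ranges (None = no bound).
_BEHAVIORAL_OUTCOMES: Mapping[str, tuple[float | None, float | None]] = {
    "agency_rating": (0.0, 10.0),
    "control_rating": (0.0, 10.0),
    "trajectory_norm_cm": (0.0, None),
    "velocity_cm_s": (0.0, None),
}


@dataclass
class BehavioralTable:
    """Tidy per-subject, per-condition behavioural outcomes.

    One row per subject x condition with columns ``subject``,
    ``congruency``, ``synchrony`` plus the outcome columns.  Missing
    ratings are allowed (NaN) and handled listwise downstream.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table).copy()
        required = {"subject", "congruency", "synchrony"}
        if not required.issubset(df.columns):
            raise ValueError(f"behavioural table needs columns {sorted(required)}")
        for col, (lo, hi) in _BEHAVIORAL_OUTCOMES.items():
            if col not in df.columns:
                continue
            vals = df[col].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if lo is not None and (finite < lo).any():
                raise ValueError(f"{col} below valid minimum {lo}")
            if hi is not None and (finite > hi).any():
                raise ValueError(f"{col} above valid maximum {hi}")
        cells = df.groupby("subject")[["congruency", "synchrony"]].apply(
            lambda g: len(g.drop_duplicates())
        )
        if (cells != 4).any():
            bad = list(cells.index[cells != 4])
            raise ValueError(f"subjects without all four design cells: {bad}")
        self.table = df.reset_index(drop=True)

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(sorted(self.table["subject"].unique()))

    def outcome_columns(self) -> list[str]:
        return [c for c in _BEHAVIORAL_OUTCOMES if c in self.table.columns]
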