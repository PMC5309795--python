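"""Core in-memory containers shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

EVENT_COLUMNS = ("onset_s", "duration_s", "condition", "block")

#: canonical condition labels
AVERSIVE = "aversive"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class ChannelInfo:
    """One depth-electrode contact (or EOG lead)."""

    name: str
    region: str          # e.g. "amygdala-BLA", "hippocampus-CA1", "white-matter", "EOG"
    shaft: str = ""      # electrode shaft id; contacts on a shaft share it
    contact: int = 0     # contact index along the shaft, 1 = most medial
    laterality: str = ""

    @property
    def is_white_matter(self) -> bool:
        return self.region == "white-matter"

    @property
    def is_eog(self) -> bool:
        return self.region.upper() == "EOG"

    @property
    def macro_region(self) -> str:
        """Coarse region ('amygdala', 'hippocampus', ...) from the tag."""
        return self.region.split("-")[0]


@dataclass
class Recording:
    """Continuous multichannel LFP: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    channels: list[ChannelInfo]
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"channel metadata length {len(self.channels)} != "
                f"channel count {self.data.shape[0]}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_names(self) -> list[str]:
        return [ch.name for ch in self.channels]

    def index_of(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    def get(self, name: str) -> np.ndarray:
        return self.data[self.index_of(name)]

    def pick(self, names: Sequence[str]) -> "Recording":
        idx = [self.index_of(n) for n in names]
        return Recording(
            self.data[idx].copy(),
            self.fs,
            [self.channels[i] for i in idx],
            dict(self.annotations),
        )

    def copy_with(self, data: np.ndarray | None = None, **ann) -> "Recording":
        new = Recording(
            self.data.copy() if data is None else data,
            self.fs,
            list(self.channels),
            dict(self.annotations),
        )
        new.annotations.update(ann)
        return new


def validate_events(events: pd.DataFrame, duration_s: float | None = None) -> pd.DataFrame:
    """Check an events table for required columns and in-range onsets."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"events table missing columns: {missing}")
    if (events["duration_s"] <= 0).any():
        raise ValueError("all event durations must be positive")
    if duration_s is not None:
        bad = events.index[
            (events["onset_s"] < 0)
            | (events["onset_s"] + events["duration_s"] > duration_s + 1e-9)
        ].tolist()
        if bad:
            raise ValueError(f"events outside the recording at rows {bad}")
    return events


@dataclass
class Epochs:
    """Event-locked trials: ``data`` is trials x channels x samples."""

    data: np.ndarray
    fs: float
    window: tuple[float, float]          # seconds relative to event onset
    conditions: np.ndarray               # per-trial condition label
    channels: list[ChannelInfo]
    bad: np.ndarray = None               # per-trial bool mask, True = flagged

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.conditions = np.asarray(self.conditions)
        if self.bad is None:
            self.bad = np.zeros(self.data.shape[0], dtype=bool)
        self.bad = np.asarray(self.bad, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if len(self.conditions) != self.data.shape[0]:
            raise ValueError("condition labels must match trial count")
        if len(self.bad) != self.data.shape[0]:
            raise ValueError("bad-trial mask must match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.window[0] + np.arange(n) / self.fs

    def select(self, condition: str, drop_bad: bool = True) -> np.ndarray:
        keep = self.conditions == condition
        if drop_bad:
            keep &= ~self.bad
        return self.data[keep]


@dataclass(frozen=True)
class BandSpec:
    """A subject-specific frequency band."""

    centre_hz: float
    low_hz: float
    high_hz: float
    fallback: bool = False   # True when no oscillatory peak was found

    @classmethod
    def from_centre(cls, centre_hz: float, bandwidth_hz: float = 4.0, **kw) -> "BandSpec":
        half = bandwidth_hz / 2.0
        return cls(centre_hz, centre_hz - half, centre_hz + half, **kw)

    @property
    def bandwidth_hz(self) -> float:
        return self.high_hz - self.low_hz


@dataclass
class AnalyticSignal:
    """Instantaneous amplitude and wrapped phase of one narrow band."""

    amplitude: np.ndarray
    phase: np.ndarray        # radians in (-pi, pi]; 0 = peak, pi = trough (cosine phase)
    band: BandSpec
    fs: float

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase must have the same shape")


__all__ = [
    "AVERSIVE",
    "NEUTRAL",
    "EVENT_COLUMNS",
    "ChannelInfo",
    "Recording",
    "Epochs",
    "BandSpec",
    "AnalyticSignal",
    "validate_events",
    "replace",
]
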