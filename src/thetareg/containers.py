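"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONDITIONS = ("neutral", "maintain", "reappraise")

#: trial timing (seconds, instruction onset = 0)
PICTURE_ONSET = -3.0
BASELINE_WINDOW = (-4.2, -3.2)   # 1.2-0.2 s before picture onset
REGULATION_WINDOW = (1.0, 5.0)
THETA_BAND = (3.5, 8.5)


class DataError(ValueError):
    """Raised for invalid numerical content (non-finite data, bad labels)."""


@dataclass
class Provenance:
    """Processing-state flags carried with an epoched recording."""

    filtered: bool = False
    interpolated: bool = False
    rejected: bool = False
    rereferenced: bool = False
    ica_cleaned: bool = False
    erp_subtracted: bool = False

    def copy(self) -> "Provenance":
        return Provenance(**vars(self))


@dataclass
class ContinuousRecording:
    """Continuous multichannel EEG: ``data`` is (channels, samples) in µV."""

    data: np.ndarray
    sfreq: float
    channel_labels: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.sfreq <= 0:
            raise DataError(f"sfreq must be positive, got {self.sfreq}")
        n = self.data.shape[1]
        for s, m in self.events:
            if not 0 <= s < n:
                raise DataError(f"event {m!r} at sample {s} outside recording (0..{n - 1})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class EpochedRecording:
    """Epoched EEG: ``data`` is (channels, time, trials) in µV.

    ``time_axis`` is in seconds with t = 0 at the onset of the regulation
    instruction; the standard epoch spans [-6, +7] s (picture onset at -3 s).
    """

    data: np.ndarray
    time_axis: np.ndarray
    condition: np.ndarray          # per-trial label in CONDITIONS
    channel_labels: list[str]
    channel_positions: np.ndarray  # (n_channels, 3) m
    sfreq: float
    provenance: Provenance = field(default_factory=Provenance)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.time_axis = np.asarray(self.time_axis, float)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.data.ndim != 3:
            raise DataError("data must be (channels, time, trials)")
        dt = np.diff(self.time_axis)
        if len(dt) and (dt.min() <= 0 or not np.allclose(dt, 1 / self.sfreq, rtol=1e-6)):
            raise DataError("time axis must increase uniformly at 1/sfreq")
        if self.data.shape[1] != len(self.time_axis):
            raise DataError("time axis length does not match data")
        if self.data.shape[2] != len(self.condition):
            raise DataError("one condition label per trial required")
        bad = set(self.condition) - set(CONDITIONS)
        if bad:
            raise DataError(f"unknown condition labels: {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def copy_with(self, data=None, condition=None, provenance=None) -> "EpochedRecording":
        return EpochedRecording(
            data=self.data.copy() if data is None else data,
            time_axis=self.time_axis,
            condition=self.condition.copy() if condition is None else condition,
            channel_labels=list(self.channel_labels),
            channel_positions=self.channel_positions,
            sfreq=self.sfreq,
            provenance=self.provenance.copy() if provenance is None else provenance,
        )

    def select_condition(self, name: str) -> np.ndarray:
        """Boolean trial mask for one condition."""
        if name not in CONDITIONS:
            raise DataError(f"unknown condition {name!r}")
        return self.condition == name

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        return (self.time_axis >= lo - 1e-9) & (self.time_axis <= hi + 1e-9)
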