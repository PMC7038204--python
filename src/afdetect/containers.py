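"""Core in-memory containers shared across the pipeline."""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class RhythmLabel(str, enum.Enum):
    """The four rhythm classes assigned to a 30 s ECG segment."""

    NORMAL = "Normal"
    AF = "AF"
    OTHER = "Other"
    NOISY = "Noisy"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical class order used for confusion matrices and reports.
CLASS_ORDER = (RhythmLabel.NORMAL, RhythmLabel.AF, RhythmLabel.OTHER, RhythmLabel.NOISY)


@dataclass
class EcgRecording:
    """A sampled single-lead voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage in millivolts.
    fs : float
        Sampling rate in Hz.
    record_id : str
        Identifier of the source record (or a synthetic tag).
    channel : int
        Channel index the samples were taken from (0 for single-lead).
    label : RhythmLabel, optional
        Rhythm class, when known.
    """

    samples: np.ndarray
    fs: float
    record_id: str = ""
    channel: int = 0
    label: Optional[RhythmLabel] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN or Inf")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.samples.size) / self.fs


@dataclass
class LabeledDataset:
    """A list of labeled recordings with provenance and split tag."""

    items: list  # list[tuple[EcgRecording, RhythmLabel]]
    provenance: str = ""
    split_tag: str = ""

    def __post_init__(self) -> None:
        for _, lab in self.items:
            if not isinstance(lab, RhythmLabel):
                raise ValueError(f"label {lab!r} is not a RhythmLabel")

    def __len__(self) -> int:
        return len(self.items)

    def labels(self) -> list:
        return [lab for _, lab in self.items]
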