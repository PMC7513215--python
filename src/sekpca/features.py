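"""In-memory containers for epoch-by-channel feature matrices and raw recordings."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

LABEL_COLUMN = "label"


@dataclass
class FeatureMatrix:
    """Epochs x channels matrix of entropy values with optional binary state labels.

    ``values[p, q]`` is the entropy of channel ``q`` within epoch ``p``
    (nats). Labels, when present, code 0 = non-fatigue / alert and
    1 = fatigue, one per epoch row.
    """

    values: np.ndarray
    labels: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("feature matrix must be 2-D (epochs x channels)")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("feature matrix contains non-finite entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.values.shape[0],):
                raise ConfigurationError(
                    f"labels length {self.labels.shape} does not match "
                    f"{self.values.shape[0]} rows"
                )
        if not self.feature_names:
            self.feature_names = [f"ch{q}" for q in range(self.values.shape[1])]
        elif len(self.feature_names) != self.values.shape[1]:
            raise ConfigurationError("feature_names length does not match column count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def require_labels(self) -> np.ndarray:
        if self.labels is None:
            raise ConfigurationError("this operation needs a labelled feature matrix")
        return self.labels

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        if self.labels is not None:
            frame[LABEL_COLUMN] = self.labels
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureMatrix":
        labels = None
        if LABEL_COLUMN in frame.columns:
            labels = frame[LABEL_COLUMN].to_numpy()
            frame = frame.drop(columns=[LABEL_COLUMN])
        return cls(
            values=frame.to_numpy(dtype=float),
            labels=labels,
            feature_names=[str(c) for c in frame.columns],
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class RawSignals:
    """A multichannel recording: samples x channels, with the sampling rate in Hz."""

    values: np.ndarray
    rate: float
    channel_names: list[str] = field(default_factory=list)
    epoch_labels: np.ndarray | None = None  # one label per whole epoch, if known

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("signals must be 2-D (samples x channels)")
        if self.rate <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{q}" for q in range(self.values.shape[1])]
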