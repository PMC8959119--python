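"""In-memory containers for multichannel time series and epoch sets."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


@dataclass
class TimeSeriesBlock:
    """A channels x samples signal matrix with sampling rate and channel kind.

    ``kind`` distinguishes sensor-level (scalp electrode) data, source-level
    data (one row per dipole), and ROI-level data (one row per cortical
    region after parcellation averaging).
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    kind: str = "sensor"  # sensor | source | roi

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if self.kind not in ("sensor", "source", "roi"):
            raise ValueError(f"kind must be sensor|source|roi, got {self.kind!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "TimeSeriesBlock":
        return replace(self, data=data, kind=kind if kind is not None else self.kind)


@dataclass
class EpochSet:
    """Fixed-length consecutive segments of a recording plus a keep mask.

    ``epochs`` has shape (n_epochs, channels, epoch_samples).  The rejection
    metric is filled by :func:`oscinet.preprocessing.reject_epochs`.
    """

    epochs: np.ndarray
    fs: float
    labels: list[str]
    kind: str
    epoch_len: float
    keep_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    rejection_metric: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n_epochs, channels, samples)")
        if self.keep_mask is None:
            self.keep_mask = np.ones(self.n_epochs, dtype=bool)
        self.keep_mask = np.asarray(self.keep_mask, dtype=bool)
        if self.keep_mask.shape != (self.n_epochs,):
            raise ValueError("keep_mask length must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_samples(self) -> int:
        return self.epochs.shape[2]

    @property
    def n_kept(self) -> int:
        return int(self.keep_mask.sum())


def as_channel_pair(x: np.ndarray | Sequence[float]) -> np.ndarray:
    """Coerce a 1-D channel to a float array, validating finiteness."""
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError("channel contains NaN or Inf")
    return arr
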