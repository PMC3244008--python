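"""Raw recordings and the sliding-window framing step.

A recording is a multi-channel acceleration time series; the unit of
classification is a *data frame*: a 512-sample window (6.7 s at the default
76.25 Hz sampling rate) taken with 50% overlap, so a new frame becomes
available every 3.35 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_RATE = 76.25
DEFAULT_FRAME_WIDTH = 512
DEFAULT_OVERLAP = 0.5


@dataclass
class RawRecording:
    """Multi-channel acceleration time series.

    Parameters
    ----------
    samples : ndarray, shape (channels, n_samples)
        Acceleration values (m/s² or g; features are unit-agnostic).
    rate : float
        Sampling frequency in Hz.
    channel_names : list of str, optional
        Ordered channel identifiers; defaults to ``ch0..ch{c-1}``.
    """

    samples: np.ndarray
    rate: float = DEFAULT_RATE
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.shape[0] < 1:
            raise ValueError("recording needs at least one channel")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @classmethod
    def from_csv(cls, path, rate: float = DEFAULT_RATE) -> "RawRecording":
        """Read a recording from delimited text: one column per channel, header row."""
        df = pd.read_csv(path)
        return cls(df.to_numpy().T, rate=rate, channel_names=list(df.columns))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.samples.T, columns=self.channel_names).to_csv(path, index=False)


@dataclass
class AccelFrame:
    """One window of multi-channel acceleration samples."""

    window: np.ndarray  # (channels, width)
    start_index: int
    rate: float = DEFAULT_RATE
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.window = np.atleast_2d(np.asarray(self.window, dtype=float))
        if self.start_index < 0:
            raise ValueError("start_index must be non-negative")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.window.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.window.shape[0]

    @property
    def width(self) -> int:
        return self.window.shape[1]

    @property
    def duration(self) -> float:
        """Frame duration in seconds (512 samples at 76.25 Hz -> 6.7 s)."""
        return self.width / self.rate


def make_frames(
    recording: RawRecording,
    width: int = DEFAULT_FRAME_WIDTH,
    overlap: float = DEFAULT_OVERLAP,
) -> list[AccelFrame]:
    """Cut a recording into overlapping frames.

    Frames start at multiples of the stride ``width * (1 - overlap)``; a
    trailing window that does not fill ``width`` samples is dropped.
    """
    if width < 2:
        raise ValueError("frame width must be at least 2 samples")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    stride = int(round(width * (1.0 - overlap)))
    stride = max(stride, 1)
    frames = []
    start = 0
    while start + width <= recording.n_samples:
        frames.append(
            AccelFrame(
                recording.samples[:, start : start + width],
                start_index=start,
                rate=recording.rate,
                channel_names=recording.channel_names,
            )
        )
        start += stride
    return frames
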