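"""Per-frame feature families.

Four families are computed per frame:

* **DC component** — per-channel mean; dominated by the gravity projection,
  so it separates static postures.
* **energy** — power of the detrended channel, computed in the frequency
  domain (orthonormal DFT, DC bin excluded, divided by the window length) so
  that it equals the time-domain variance of the detrended samples exactly
  (Parseval).
* **frequency-domain entropy** — differential entropy of an Epanechnikov
  kernel density fitted to the magnitudes of the short-time Fourier
  coefficients of the detrended channel. Impact-rich gaits (walking, running)
  spread energy over many frequencies and score high; smooth cyclic motions
  (cycling) concentrate it in a single tone and score low.
* **correlation block** — cosine similarity of every unordered pair of
  detrended channel vectors (self-pairs included), capturing coordination
  between body segments.

For ``c`` channels the assembled vector has ``3c + c(c+1)/2`` components
(85 for the canonical 10-channel, five bi-axial sensor layout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .framing import AccelFrame, RawRecording, make_frames

_DENSITY_FLOOR = 1e-12


@dataclass
class KDEConfig:
    """Settings for the Epanechnikov kernel density used by the entropy feature.

    bandwidth : explicit kernel bandwidth, or None for Silverman's rule
        ``0.9 * min(sd, iqr/1.34) * n**(-1/5)`` on the magnitude sample.
    grid_size : number of equally spaced integration points.
    pad : grid extends ``pad * h`` beyond the sample range on both sides.
    """

    bandwidth: float | None = None
    grid_size: int = 512
    pad: float = 3.0


@dataclass
class FeatureVector:
    """Ordered feature representation of one frame."""

    values: np.ndarray
    names: list[str]
    label: str | None = None
    start_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.names):
            raise ValueError("values and names must align")

    def __len__(self) -> int:
        return self.values.shape[0]


def _detrended(frame: AccelFrame) -> np.ndarray:
    w = frame.window
    return w - w.mean(axis=1, keepdims=True)


def dc_component(frame: AccelFrame) -> np.ndarray:
    """Per-channel signal average (the gravity-dominated DC component)."""
    if frame.width == 0:
        raise ValueError("empty frame")
    return frame.window.mean(axis=1)


def variance_feature(frame: AccelFrame) -> np.ndarray:
    """Per-channel mean of the squared detrended samples."""
    if frame.width == 0:
        raise ValueError("empty frame")
    d = _detrended(frame)
    return (d ** 2).mean(axis=1)


def energy_feature(frame: AccelFrame) -> np.ndarray:
    """Per-channel spectral energy of the detrended signal.

    Sum of squared magnitudes of the orthonormal DFT coefficients, excluding
    the zero-frequency bin, divided by the window length. By Parseval this
    equals the detrended time-domain variance.
    """
    if frame.width == 0:
        raise ValueError("empty frame")
    d = _detrended(frame)
    coeffs = np.fft.fft(d, axis=1, norm="ortho")
    mags2 = np.abs(coeffs) ** 2
    mags2[:, 0] = 0.0  # DC bin excluded (zero after detrending anyway)
    return mags2.sum(axis=1) / frame.width


def _stft_magnitudes(frame: AccelFrame) -> np.ndarray:
    """Magnitudes of the positive-frequency Fourier coefficients, DC excluded.

    A single 512-sample transform per frame (window = frame, no sub-windows).
    """
    d = _detrended(frame)
    coeffs = np.fft.rfft(d, axis=1)
    return np.abs(coeffs[:, 1:])


def _silverman_bandwidth(sample: np.ndarray) -> float:
    n = sample.size
    sd = sample.std()
    q75, q25 = np.percentile(sample, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def _epanechnikov_density(sample: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    u = (grid[:, None] - sample[None, :]) / h
    k = np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u ** 2), 0.0)
    return k.sum(axis=1) / (sample.size * h)


def entropy_feature(frame: AccelFrame, kde_config: KDEConfig | None = None) -> np.ndarray:
    """Per-channel frequency-domain entropy.

    Fits an Epanechnikov kernel density to the STFT coefficient magnitudes of
    each detrended channel and returns the differential entropy
    ``-∫ p ln p`` evaluated by trapezoidal integration on the configured grid.
    An all-zero (constant) channel has a degenerate density; its entropy is
    reported as 0 with a warning.
    """
    cfg = kde_config or KDEConfig()
    if cfg.bandwidth is not None and cfg.bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    mags = _stft_magnitudes(frame)
    out = np.empty(frame.n_channels)
    for i, sample in enumerate(mags):
        if not np.any(sample > 0):
            warnings.warn(f"channel {i}: constant signal, entropy set to 0")
            out[i] = 0.0
            continue
        h = cfg.bandwidth if cfg.bandwidth is not None else _silverman_bandwidth(sample)
        if h <= 0:
            h = max(sample.std(), 1e-12)
        grid = np.linspace(sample.min() - cfg.pad * h, sample.max() + cfg.pad * h, cfg.grid_size)
        density = _epanechnikov_density(sample, grid, h)
        p = np.clip(density, _DENSITY_FLOOR, None)
        out[i] = -np.trapezoid(density * np.log(p), grid)
    return out


def kde_density(frame: AccelFrame, channel: int, kde_config: KDEConfig | None = None):
    """Fitted Epanechnikov density on its grid for one channel (diagnostics)."""
    cfg = kde_config or KDEConfig()
    sample = _stft_magnitudes(frame)[channel]
    h = cfg.bandwidth if cfg.bandwidth is not None else _silverman_bandwidth(sample)
    if h <= 0:
        h = max(sample.std(), 1e-12)
    grid = np.linspace(sample.min() - cfg.pad * h, sample.max() + cfg.pad * h, cfg.grid_size)
    return grid, _epanechnikov_density(sample, grid, h)


def correlation_block(frame: AccelFrame) -> np.ndarray:
    """Normalised dot products of every unordered channel pair (i <= j).

    Detrended channel vectors; cosine similarity, i.e. the Pearson
    correlation coefficient of the raw channels. Self-pairs are included and
    equal 1 for any non-constant channel. A zero-norm (constant) channel
    yields 0 for its pairs, with a warning.
    """
    d = _detrended(frame)
    norms = np.linalg.norm(d, axis=1)
    c = frame.n_channels
    out = []
    warned = False
    for i in range(c):
        for j in range(i, c):
            if norms[i] == 0 or norms[j] == 0:
                if not warned:
                    warnings.warn("constant channel in correlation block; coefficient set to 0")
                    warned = True
                out.append(0.0)
            else:
                out.append(float(np.dot(d[i], d[j]) / (norms[i] * norms[j])))
    return np.clip(np.array(out), -1.0, 1.0)


def feature_names(channel_names: list[str]) -> list[str]:
    names = [f"dc_{ch}" for ch in channel_names]
    names += [f"energy_{ch}" for ch in channel_names]
    names += [f"entropy_{ch}" for ch in channel_names]
    c = len(channel_names)
    for i in range(c):
        for j in range(i, c):
            names.append(f"corr_{channel_names[i]}_{channel_names[j]}")
    return names


def assemble_features(
    frame: AccelFrame,
    kde_config: KDEConfig | None = None,
    label: str | None = None,
) -> FeatureVector:
    """Concatenate [dc | energy | entropy | correlations] with aligned names."""
    values = np.concatenate(
        [
            dc_component(frame),
            energy_feature(frame),
            entropy_feature(frame, kde_config),
            correlation_block(frame),
        ]
    )
    return FeatureVector(values, feature_names(frame.channel_names), label=label,
                         start_index=frame.start_index)


def extract_feature_table(
    recording: RawRecording,
    width: int = 512,
    overlap: float = 0.5,
    kde_config: KDEConfig | None = None,
    label: str | None = None,
) -> pd.DataFrame:
    """Frame a recording and extract one feature row per frame.

    Returns a DataFrame with feature columns plus ``start_index`` and, when a
    label is given, a ``label`` column — the on-disk CSV schema.
    """
    frames = make_frames(recording, width, overlap)
    rows = [assemble_features(f, kde_config, label=label) for f in frames]
    if not rows:
        return pd.DataFrame(columns=feature_names(recording.channel_names) + ["start_index"])
    df = pd.DataFrame([r.values for r in rows], columns=rows[0].names)
    df["start_index"] = [r.start_index for r in rows]
    if label is not None:
        df["label"] = label
    return df
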