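"""Synthetic accelerometer data emulating the study conditions.

The generator reproduces the structure of multi-sensor recordings used to
develop the method: ten channels emulating five bi-axial accelerometers
(hip, wrist, arm, ankle, thigh; two axes each) sampled at 76.25 Hz.

* **Postures** (sitting, lying, standing) are a constant gravity projection
  per channel plus white noise.
* **Dynamic motions** carry periodic components at an activity-specific
  fundamental (and harmonics) with channel-specific gains and phase lags;
  impact-rich gaits (walking, stair climbing, running) additionally receive
  impulsive high-frequency bursts at foot-strike times, which spread spectral
  energy and raise the frequency-domain entropy well above that of smooth
  cyclic motion (cycling).
* **Garbage** frames come from a distinct spec family (off-gravity DC
  offsets, odd fundamentals, heavy broadband noise) standing in for
  activities outside the trained vocabulary.

Virtual experiments chain per-frame feature vectors by sampling, for each
state of an OMM-generated label sequence, one feature vector with replacement
from that activity's frame pool; garbage frames can then be interspersed up
to one per three genuine frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .framing import RawRecording, make_frames, DEFAULT_RATE
from .features import KDEConfig, assemble_features, feature_names
from .markov import MarkovChain, generate_states
from .selection import LabelledFeatureSet

SPURIOUS = "SPURIOUS"
G = 9.81

CHANNELS = [
    "hip_x", "hip_y", "wrist_x", "wrist_y", "arm_x", "arm_y",
    "ankle_x", "ankle_y", "thigh_x", "thigh_y",
]


@dataclass
class ActivitySignalSpec:
    """Recipe for one activity's raw signal.

    dc_profile : per-channel constant (gravity projection, m/s²).
    periodic_components : list of (frequency Hz, amplitude m/s², phase rad),
        applied to every channel scaled by ``ac_gain`` with a fixed
        channel-dependent phase lag.
    impact_burst : (rate Hz, amplitude, decay s) for exponentially decaying
        broadband bursts at Poisson arrival times, or None.
    noise_sd : white-noise standard deviation (m/s²).
    wander_sd : standard deviation of the slow (sub-0.5 Hz) baseline drift
        added per channel — posture adjustments, sensor micro-shifts; this is
        what makes frame-level features vary from frame to frame.
    amp_jitter : relative slow modulation of the periodic amplitudes
        (stride-to-stride variability).
    """

    label: str
    dc_profile: np.ndarray
    periodic_components: list[tuple[float, float, float]] = field(default_factory=list)
    ac_gain: np.ndarray | None = None
    impact_burst: tuple[float, float, float] | None = None
    noise_sd: float = 0.2
    wander_sd: float = 0.5
    amp_jitter: float = 0.15

    def __post_init__(self) -> None:
        self.dc_profile = np.asarray(self.dc_profile, dtype=float)
        if self.ac_gain is None:
            self.ac_gain = np.ones_like(self.dc_profile)
        self.ac_gain = np.asarray(self.ac_gain, dtype=float)
        if (self.ac_gain < 0).any() or self.noise_sd < 0:
            raise ValueError("amplitudes and noise_sd must be non-negative")
        for f, a, _ in self.periodic_components:
            if a < 0:
                raise ValueError("periodic amplitudes must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.dc_profile.shape[0]


# ambulation gain pattern: strong at ankle/thigh, moderate at hip, weak at arm/wrist
_GAIT_GAIN = np.array([0.5, 0.4, 0.15, 0.15, 0.2, 0.2, 1.0, 0.9, 0.8, 0.7])
# stair climbing engages the arms (handrail) and lifts the thigh more
_CLIMB_GAIN = np.array([0.5, 0.4, 0.55, 0.5, 0.6, 0.55, 1.0, 0.9, 1.1, 1.0])
_CYCLE_GAIN = np.array([0.2, 0.2, 0.1, 0.1, 0.1, 0.1, 1.0, 1.0, 0.9, 0.9])

_UPRIGHT = np.array([9.3, 1.5, 2.0, 9.5, 1.0, 9.6, 9.7, 0.8, 9.4, 1.2])
_SEATED = np.array([9.2, 1.8, 3.0, 9.0, 1.5, 9.4, 9.5, 1.0, 2.0, 9.5])
_SUPINE = np.array([0.5, 9.6, 9.3, 1.0, 9.5, 0.7, 0.8, 9.4, 0.6, 9.5])
_CYCLING_DC = np.array([7.5, 5.0, 4.0, 8.5, 3.0, 9.0, 8.0, 4.5, 3.5, 8.8])


def default_activity_specs() -> dict[str, ActivitySignalSpec]:
    """The seven-primitive vocabulary: three postures, four dynamic motions."""
    specs = [
        ActivitySignalSpec("sitting", _SEATED, noise_sd=0.18),
        ActivitySignalSpec("lying", _SUPINE, noise_sd=0.15),
        ActivitySignalSpec("standing", _UPRIGHT, noise_sd=0.22),
        ActivitySignalSpec(
            "walking", _UPRIGHT,
            periodic_components=[(2.0, 2.5, 0.0), (4.0, 0.9, 0.7)],
            ac_gain=_GAIT_GAIN,
            impact_burst=(2.0, 5.0, 0.05),
            noise_sd=0.40,
        ),
        ActivitySignalSpec(
            "climbing", _UPRIGHT * 0.95,
            periodic_components=[(1.6, 3.2, 0.3), (3.2, 1.2, 1.1)],
            ac_gain=_CLIMB_GAIN,
            impact_burst=(1.6, 6.0, 0.06),
            noise_sd=0.65,
        ),
        ActivitySignalSpec(
            "running", _UPRIGHT,
            periodic_components=[(2.9, 4.0, 0.0), (5.8, 1.5, 0.5)],
            ac_gain=_GAIT_GAIN,
            impact_burst=(2.9, 9.0, 0.04),
            noise_sd=0.60,
        ),
        ActivitySignalSpec(
            "cycling", _CYCLING_DC,
            periodic_components=[(1.5, 2.8, 0.0)],
            ac_gain=_CYCLE_GAIN,
            noise_sd=0.25,
        ),
    ]
    return {s.label: s for s in specs}


def garbage_specs() -> list[ActivitySignalSpec]:
    """Out-of-vocabulary signal recipes used as spurious ("garbage") frames."""
    return [
        ActivitySignalSpec(
            "garbage_shake", np.full(10, 5.0),
            periodic_components=[(5.0, 8.0, 0.0)],
            noise_sd=3.0,
        ),
        ActivitySignalSpec("garbage_tilt", -np.linspace(5.0, 8.0, 10), noise_sd=1.0),
        ActivitySignalSpec(
            "garbage_jump", np.full(10, 3.0),
            periodic_components=[(0.7, 6.0, 0.0)],
            impact_burst=(4.0, 15.0, 0.08),
            noise_sd=2.0,
        ),
    ]


def _slow_noise(rng: np.random.Generator, shape: tuple[int, int], rate: float) -> np.ndarray:
    """Unit-variance noise low-passed to ~sub-0.5 Hz (moving-average smoothing)."""
    c, n = shape
    win = max(int(2.0 * rate), 2)  # ~2 s window
    raw = rng.standard_normal((c, n + win))
    kernel = np.hanning(win)
    kernel /= kernel.sum()
    smooth = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, raw)[:, win // 2 : win // 2 + n]
    sd = smooth.std()
    return smooth / (sd if sd > 0 else 1.0)


def synth_recording(
    spec: ActivitySignalSpec,
    duration_s: float,
    rate: float = DEFAULT_RATE,
    seed: int | np.random.Generator = 0,
) -> RawRecording:
    """Synthesise one activity recording from its signal recipe."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    if n < 1:
        raise ValueError("duration too short")
    for f, _, _ in spec.periodic_components:
        if f >= rate / 2:
            raise ValueError(f"component frequency {f} Hz is at or above Nyquist ({rate / 2} Hz)")
    t = np.arange(n) / rate
    c = spec.n_channels
    x = np.repeat(spec.dc_profile[:, None], n, axis=1)
    if spec.wander_sd > 0:
        x += spec.wander_sd * _slow_noise(rng, (c, n), rate)
    lags = 0.4 * np.arange(c)  # fixed per-channel phase lags (rad)
    for f, a, phase in spec.periodic_components:
        amp = a * spec.ac_gain[:, None]
        if spec.amp_jitter > 0:
            amp = amp * (1.0 + spec.amp_jitter * _slow_noise(rng, (1, n), rate))
        x += amp * np.sin(2 * np.pi * f * t[None, :] + phase + lags[:, None])
    if spec.impact_burst is not None:
        burst_rate, amp, decay = spec.impact_burst
        n_events = rng.poisson(burst_rate * duration_s)
        events = np.sort(rng.uniform(0, duration_s, size=n_events))
        for ev in events:
            idx = int(ev * rate)
            length = min(n - idx, max(int(5 * decay * rate), 1))
            if length <= 0:
                continue
            envelope = amp * np.exp(-np.arange(length) / (decay * rate))
            # broadband content: envelope-modulated white noise per channel
            x[:, idx : idx + length] += (
                spec.ac_gain[:, None] * envelope[None, :] * rng.standard_normal((c, length))
            )
    x += spec.noise_sd * rng.standard_normal((c, n))
    names = CHANNELS if c == len(CHANNELS) else [f"ch{i}" for i in range(c)]
    return RawRecording(x, rate=rate, channel_names=list(names))


@dataclass
class FrameLibrary:
    """Per-activity pools of labelled feature vectors."""

    pools: dict[str, np.ndarray]  # label -> (N_label, d)
    feature_names: list[str]

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def labels(self) -> list[str]:
        return list(self.pools)

    def select_features(self, indices: list[int]) -> "FrameLibrary":
        return FrameLibrary(
            {k: v[:, indices] for k, v in self.pools.items()},
            [self.feature_names[i] for i in indices],
        )

    def as_labelled_set(self) -> LabelledFeatureSet:
        mats, labs = [], []
        for label, pool in self.pools.items():
            mats.append(pool)
            labs.extend([label] * pool.shape[0])
        return LabelledFeatureSet(np.vstack(mats), np.array(labs), list(self.feature_names))

    def split(self, per_class: int, seed: int | np.random.Generator = 0):
        """Random per-class split into (first `per_class` frames, remainder)."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        head, tail = {}, {}
        for label, pool in self.pools.items():
            order = rng.permutation(pool.shape[0])
            head[label] = pool[order[:per_class]]
            tail[label] = pool[order[per_class:]]
        return (
            FrameLibrary(head, list(self.feature_names)),
            FrameLibrary(tail, list(self.feature_names)),
        )


def build_frame_library(
    specs: dict[str, ActivitySignalSpec] | list[ActivitySignalSpec],
    frames_per_class: int | tuple[int, int] = 20,
    rate: float = DEFAULT_RATE,
    seed: int | np.random.Generator = 0,
    width: int = 512,
    overlap: float = 0.5,
    kde_config: KDEConfig | None = None,
) -> FrameLibrary:
    """Generate recordings, window them, and pool per-activity feature vectors.

    ``frames_per_class`` may be an integer N or an inclusive (low, high)
    range from which a per-class N is drawn, emulating unequal amounts of
    data per activity.
    """
    if isinstance(specs, dict):
        specs = list(specs.values())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stride = int(round(width * (1 - overlap)))
    pools: dict[str, np.ndarray] = {}
    names: list[str] | None = None
    for spec in specs:
        if isinstance(frames_per_class, tuple):
            n_frames = int(rng.integers(frames_per_class[0], frames_per_class[1] + 1))
        else:
            n_frames = int(frames_per_class)
        if n_frames < 1:
            raise ValueError("frames_per_class must be at least 1")
        n_samples = width + (n_frames - 1) * stride
        rec = synth_recording(spec, n_samples / rate, rate, rng)
        frames = make_frames(rec, width, overlap)[:n_frames]
        vecs = [assemble_features(f, kde_config, label=spec.label) for f in frames]
        pools[spec.label] = np.array([v.values for v in vecs])
        if names is None:
            names = vecs[0].names
    return FrameLibrary(pools, names or [])


@dataclass
class VirtualExperiment:
    """A generated composite activity: per-frame features, labels, spurious mask."""

    features: np.ndarray
    true_labels: list[str]
    spurious_mask: np.ndarray
    seed: int = 0
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.spurious_mask = np.asarray(self.spurious_mask, dtype=bool)
        if not (len(self.true_labels) == self.features.shape[0] == self.spurious_mask.shape[0]):
            raise ValueError("features, labels and mask must have equal length")
        for flag, lab in zip(self.spurious_mask, self.true_labels):
            if flag and lab != SPURIOUS:
                raise ValueError("masked frames must carry the SPURIOUS label")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def genuine(self) -> "VirtualExperiment":
        keep = ~self.spurious_mask
        return VirtualExperiment(
            self.features[keep],
            [l for l, k in zip(self.true_labels, keep) if k],
            np.zeros(int(keep.sum()), dtype=bool),
            seed=self.seed,
            feature_names=list(self.feature_names),
        )


def make_virtual_experiment(
    omm: MarkovChain,
    library: FrameLibrary,
    length: int,
    seed: int | np.random.Generator = 0,
) -> VirtualExperiment:
    """OMM-driven state sequence with one pooled feature vector per state."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    missing = [s for s in omm.labels if s not in library.pools or library.pools[s].shape[0] == 0]
    if missing:
        raise ValueError(f"library has no frames for states: {missing}")
    states = generate_states(omm, length, rng)
    rows = [library.pools[s][rng.integers(library.pools[s].shape[0])] for s in states]
    return VirtualExperiment(
        np.array(rows), states, np.zeros(length, dtype=bool),
        feature_names=list(library.feature_names),
    )


def inject_garbage(
    exp: VirtualExperiment,
    ratio: float,
    garbage_pool: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> VirtualExperiment:
    """Intersperse ``floor(ratio * T)`` garbage frames at random positions.

    ``ratio`` is the spurious-per-genuine insertion rate, at most 1/3 (one
    spurious frame every three genuine frames). The genuine order is
    preserved; masked frames carry the SPURIOUS label.
    """
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    if ratio > 1 / 3 + 1e-12:
        raise ValueError("ratio must not exceed 1/3")
    if ratio == 0:
        return exp
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    garbage_pool = np.atleast_2d(garbage_pool)
    t_genuine = len(exp)
    n_garbage = int(np.floor(ratio * t_genuine))
    total = t_genuine + n_garbage
    slots = np.zeros(total, dtype=bool)
    slots[rng.choice(total, size=n_garbage, replace=False)] = True
    features = np.empty((total, exp.features.shape[1]))
    labels: list[str] = []
    mask = np.zeros(total, dtype=bool)
    gi = 0
    for pos in range(total):
        if slots[pos]:
            features[pos] = garbage_pool[rng.integers(garbage_pool.shape[0])]
            labels.append(SPURIOUS)
            mask[pos] = True
        else:
            features[pos] = exp.features[gi]
            labels.append(exp.true_labels[gi])
            gi += 1
    return VirtualExperiment(features, labels, mask, seed=exp.seed,
                             feature_names=list(exp.feature_names))
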