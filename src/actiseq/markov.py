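"""Observable Markov model of the activity sequence.

A composite activity ("motor sentence") is modelled as a first-order Markov
chain over Q activity primitives. The chain is described by a prior
probability vector π (π_i = Pr[X(t0) = S_i]) and a transition probability
matrix A (a_ij = Pr[X(t_{n+1}) = S_j | X(t_n) = S_i]); rows of A are
non-negative and sum to one. Both are estimated from annotated label
sequences by event counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

ROW_SUM_TOL = 1e-9

# Default seven-primitive chain for lower-limb activities. The printed source
# table's "sitting" row is normalised to unit sum.
DEFAULT_LABELS = ["lying", "cycling", "climbing", "walking", "running", "sitting", "standing"]
_DEFAULT_TPM = [
    [0.9500, 0.0000, 0.0000, 0.0000, 0.0000, 0.0100, 0.0400],
    [0.0001, 0.8999, 0.0000, 0.0400, 0.0000, 0.0100, 0.0500],
    [0.0001, 0.0000, 0.6199, 0.2500, 0.0100, 0.0200, 0.1000],
    [0.0001, 0.0100, 0.0300, 0.7999, 0.0200, 0.0700, 0.0700],
    [0.0001, 0.0100, 0.0100, 0.3500, 0.3999, 0.0100, 0.2200],
    [0.0200, 0.0000, 0.0100, 0.0400, 0.0000, 0.8500, 0.0900],
    [0.0100, 0.0300, 0.0100, 0.1800, 0.0300, 0.1200, 0.6200],
]


@dataclass
class MarkovChain:
    """Observable Markov model (π, A) over a fixed label order."""

    labels: list[str]
    prior: np.ndarray
    tpm: np.ndarray

    def __post_init__(self) -> None:
        self.prior = np.asarray(self.prior, dtype=float)
        self.tpm = np.asarray(self.tpm, dtype=float)
        self.validate()

    def validate(self) -> None:
        q = len(self.labels)
        if self.prior.shape != (q,) or self.tpm.shape != (q, q):
            raise ValueError("prior/TPM shapes inconsistent with the label set")
        if (self.prior < 0).any() or (self.tpm < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(self.prior.sum() - 1.0) > ROW_SUM_TOL:
            raise ValueError(f"prior sums to {self.prior.sum():.10f}, not 1")
        sums = self.tpm.sum(axis=1)
        bad = np.nonzero(np.abs(sums - 1.0) > ROW_SUM_TOL)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"TPM row {i} ({self.labels[i]!r}) sums to {sums[i]:.10f}; rows must sum to 1"
            )

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of A for eigenvalue 1, normalised to a distribution."""
        vals, vecs = np.linalg.eig(self.tpm.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        v = np.real(vecs[:, idx])
        v = np.abs(v)
        return v / v.sum()


def default_activity_chain() -> MarkovChain:
    """The default seven-state chain, with π set to its stationary distribution."""
    tpm = np.asarray(_DEFAULT_TPM)
    tpm = tpm / tpm.sum(axis=1, keepdims=True)
    chain = MarkovChain(list(DEFAULT_LABELS), np.full(7, 1.0 / 7.0), tpm)
    return MarkovChain(list(DEFAULT_LABELS), chain.stationary_distribution(), tpm)


def estimate_omm(
    label_sequences: list[list[str]],
    labels: list[str] | None = None,
    smoothing: float = 0.0,
) -> MarkovChain:
    """Estimate (π, A) by event counting with optional additive smoothing δ.

    a_ij = (count(i→j) + δ) / (departures from i + Qδ);
    π_i = (sequences starting in i + δ) / (sequences + Qδ).
    With δ = 0, a state with no departures falls back to a uniform row.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    if not label_sequences:
        raise ValueError("need at least one label sequence")
    if labels is None:
        seen = []
        for seq in label_sequences:
            for s in seq:
                if s not in seen:
                    seen.append(s)
        labels = seen
    index = {s: i for i, s in enumerate(labels)}
    q = len(labels)
    trans = np.zeros((q, q))
    starts = np.zeros(q)
    for seq in label_sequences:
        for s in seq:
            if s not in index:
                raise ValueError(f"unknown label {s!r}")
        if not seq:
            continue
        starts[index[seq[0]]] += 1
        for a, b in zip(seq[:-1], seq[1:]):
            trans[index[a], index[b]] += 1
    prior = (starts + smoothing) / (starts.sum() + q * smoothing)
    departures = trans.sum(axis=1)
    tpm = np.empty((q, q))
    for i in range(q):
        denom = departures[i] + q * smoothing
        if denom == 0:
            warnings.warn(f"state {labels[i]!r} has no observed departures; uniform row used")
            tpm[i] = 1.0 / q
        else:
            tpm[i] = (trans[i] + smoothing) / denom
    return MarkovChain(list(labels), prior, tpm)


def generate_states(omm: MarkovChain, length: int, seed: int | np.random.Generator = 0) -> list[str]:
    """Sample a state sequence: X(t0) ~ π, X(t_{n+1}) ~ A[X(t_n)]."""
    if length < 1:
        raise ValueError("length must be at least 1")
    omm.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = omm.n_states
    states = np.empty(length, dtype=int)
    states[0] = rng.choice(q, p=omm.prior / omm.prior.sum())
    rows = omm.tpm / omm.tpm.sum(axis=1, keepdims=True)
    for t in range(1, length):
        states[t] = rng.choice(q, p=rows[states[t - 1]])
    return [omm.labels[s] for s in states]
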