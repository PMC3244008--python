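"""Gaussian continuous-emission hidden Markov model (cHMM) sequential classifier.

The model is λ = (π, A, B): an observable Markov chain over Q activity
primitives plus, per state j, a mixture of M multivariate Gaussians
b_j(x) = Σ_m c_jm N(x; μ_jm, Σ_jm) over the frame feature vectors.

Training is supervised and two-phase:

* **first phase** — (π, A) by event counting over the annotated label
  sequences; per-state emission parameters by the same Gaussian-mixture fit
  used for the single-frame GMM classifier's class-conditional densities,
  using only the frames labelled with that state;
* **second phase** — optional Baum-Welch refinement on incoming unlabelled
  sequences, by default re-estimating only (π, A) ("transitions_only", useful
  when the deployed transition structure drifts from the training one) or the
  emissions as well ("all").

Decoding uses the Viterbi algorithm in log space; an optional rejection model
removes spurious frames before decoding (the chain skips them) and labels
them ``SPURIOUS`` in the output.

The module follows the Model/Results convention: build a
:class:`SequentialHMM` with the label vocabulary and configuration, call
``fit(experiments)`` to obtain a :class:`SequentialHMMResults` carrying the
estimated λ, diagnostics, and ``summary()``, ``decode()``, ``refine()``,
``classify()`` and ``simulate()`` methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .classifiers import COV_REG, _regularise_cov, fit_gaussian_mixture, gaussian_logpdf
from .markov import MarkovChain, estimate_omm

SPURIOUS = "SPURIOUS"


@dataclass
class GaussianMixtureEmissions:
    """Per-state Gaussian-mixture emission densities.

    weights : (Q, M) mixing parameters c_jm, each row summing to 1
    means : (Q, M, d) component means μ_jm
    covariances : (Q, M, d, d) component covariances Σ_jm
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.validate()

    def validate(self) -> None:
        q, m = self.weights.shape
        if self.means.shape[:2] != (q, m) or self.covariances.shape[:2] != (q, m):
            raise ValueError("emission parameter shapes inconsistent")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("mixture weights must sum to 1 per state")
        d = self.means.shape[2]
        if self.covariances.shape[2:] != (d, d):
            raise ValueError("covariance shape must be (Q, M, d, d)")

    @property
    def n_states(self) -> int:
        return self.weights.shape[0]

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def n_features(self) -> int:
        return self.means.shape[2]

    def log_density(self, obs: np.ndarray) -> np.ndarray:
        """log b_j(x_t) for every frame and state; returns (T, Q)."""
        obs = np.atleast_2d(np.asarray(obs, dtype=float))
        if obs.shape[1] != self.n_features:
            raise ValueError(
                f"observation dimension {obs.shape[1]} != model dimension {self.n_features}"
            )
        q, m = self.weights.shape
        out = np.empty((obs.shape[0], q))
        for j in range(q):
            comp = np.stack(
                [
                    np.log(self.weights[j, k] + 1e-300)
                    + gaussian_logpdf(obs, self.means[j, k], self.covariances[j, k])
                    for k in range(m)
                ],
                axis=1,
            )
            out[:, j] = logsumexp(comp, axis=1)
        return out


@dataclass
class CHMMParams:
    """Full cHMM parameter set λ = (π, A, B)."""

    omm: MarkovChain
    emissions: GaussianMixtureEmissions

    def __post_init__(self) -> None:
        if self.omm.n_states != self.emissions.n_states:
            raise ValueError("emission state count must equal the chain's Q")

    @property
    def labels(self) -> list[str]:
        return self.omm.labels

    @property
    def n_states(self) -> int:
        return self.omm.n_states

    @property
    def n_features(self) -> int:
        return self.emissions.n_features


def _log_safe(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


def first_phase_train(
    experiments: list[tuple[np.ndarray, list[str]]],
    labels: list[str] | None = None,
    n_components: int = 1,
    smoothing: float = 0.0,
    seed: int = 0,
) -> CHMMParams:
    """Supervised first-phase training from labelled feature sequences.

    Each experiment is a pair ``(features (T, d), frame labels)``. Transition
    parameters come from event counting over the label sequences; each
    state's emission mixture is fitted from the frames carrying that label,
    exactly as the single-frame GMM classifier fits its class-conditional
    density.
    """
    if not experiments:
        raise ValueError("need at least one training experiment")
    seqs = [list(lbls) for _, lbls in experiments]
    omm = estimate_omm(seqs, labels=labels, smoothing=smoothing)
    all_x = np.vstack([np.atleast_2d(x) for x, _ in experiments])
    all_y = np.concatenate([np.asarray(lbls) for _, lbls in experiments])
    missing = [s for s in omm.labels if not np.any(all_y == s)]
    if missing:
        raise ValueError(f"no training frames for states: {missing}")
    d = all_x.shape[1]
    q = omm.n_states
    weights = np.empty((q, n_components))
    means = np.empty((q, n_components, d))
    covs = np.empty((q, n_components, d, d))
    for j, s in enumerate(omm.labels):
        xs = all_x[all_y == s]
        if xs.shape[0] < n_components + 1:
            raise ValueError(f"state {s!r} has too few frames ({xs.shape[0]}) for M={n_components}")
        w, mu, cov = fit_gaussian_mixture(xs, n_components, seed=seed)
        weights[j], means[j], covs[j] = w, mu, cov
    return CHMMParams(omm, GaussianMixtureEmissions(weights, means, covs))


def _lse_cols(m: np.ndarray) -> np.ndarray:
    """logsumexp over axis 0 with per-column max shift (lean inner-loop version)."""
    shift = m.max(axis=0)
    safe = np.where(np.isfinite(shift), shift, 0.0)
    with np.errstate(divide="ignore"):
        out = np.log(np.exp(m - safe).sum(axis=0)) + safe
    return np.where(np.isfinite(shift), out, -np.inf)


def _forward_log(model: CHMMParams, log_b: np.ndarray) -> tuple[np.ndarray, float]:
    log_pi = _log_safe(model.omm.prior)
    log_a = _log_safe(model.omm.tpm)
    t_len = log_b.shape[0]
    alpha = np.empty_like(log_b)
    alpha[0] = log_pi + log_b[0]
    for t in range(1, t_len):
        alpha[t] = _lse_cols(alpha[t - 1][:, None] + log_a) + log_b[t]
    return alpha, float(logsumexp(alpha[-1]))


def forward_loglik(model: CHMMParams, obs: np.ndarray) -> float:
    """log P(obs | λ) by the forward recursion in log space."""
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    if obs.shape[0] == 0:
        raise ValueError("observation sequence is empty")
    log_b = model.emissions.log_density(obs)
    return _forward_log(model, log_b)[1]


def viterbi_decode(model: CHMMParams, obs: np.ndarray) -> tuple[list[str], float]:
    """Most probable state path and its log-probability.

    Ties break toward the lower state index at every backtrack step.
    """
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    if obs.shape[0] == 0:
        raise ValueError("observation sequence is empty")
    log_b = model.emissions.log_density(obs)
    log_pi = _log_safe(model.omm.prior)
    log_a = _log_safe(model.omm.tpm)
    t_len, q = log_b.shape
    delta = np.empty((t_len, q))
    psi = np.zeros((t_len, q), dtype=int)
    delta[0] = log_pi + log_b[0]
    for t in range(1, t_len):
        scores = delta[t - 1][:, None] + log_a
        psi[t] = np.argmax(scores, axis=0)  # first max -> lowest index
        delta[t] = scores[psi[t], np.arange(q)] + log_b[t]
    path = np.empty(t_len, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(t_len - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return [model.labels[s] for s in path], float(delta[-1, path[-1]])


def _forward_backward(model: CHMMParams, log_b: np.ndarray):
    log_a = _log_safe(model.omm.tpm)
    alpha, ll = _forward_log(model, log_b)
    t_len, q = log_b.shape
    beta = np.zeros((t_len, q))
    for t in range(t_len - 2, -1, -1):
        beta[t] = _lse_cols((log_b[t + 1] + beta[t + 1])[:, None] + log_a.T)
    log_gamma = alpha + beta - ll
    # xi[t, i, j] over t = 0..T-2
    log_xi = (
        alpha[:-1, :, None]
        + log_a[None, :, :]
        + (log_b[1:] + beta[1:])[:, None, :]
        - ll
    )
    # probabilities cannot exceed 1; clip tiny positive rounding residue
    return np.exp(np.minimum(log_gamma, 0.0)), np.exp(np.minimum(log_xi, 0.0)), ll


def baum_welch_refine(
    model: CHMMParams,
    obs: np.ndarray,
    mode: str = "transitions_only",
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[CHMMParams, list[float]]:
    """Baum-Welch (EM) refinement of λ on an unlabelled observation sequence.

    ``transitions_only`` re-estimates π and A with emissions held fixed
    (the default second-phase mode: it adapts the chain to transition
    structure unseen in training); ``all`` also updates the emission
    mixtures. Stops when the relative log-likelihood gain drops below
    ``tol`` or after ``max_iter`` iterations. Returns the refined model and
    the per-iteration log-likelihood history (monotone non-decreasing).
    """
    if mode not in ("transitions_only", "all"):
        raise ValueError("mode must be 'transitions_only' or 'all'")
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    if obs.shape[0] < 2:
        raise ValueError("refinement needs at least 2 frames")
    current = model
    history: list[float] = []
    for _ in range(max_iter):
        log_b = current.emissions.log_density(obs)
        gamma, xi, ll = _forward_backward(current, log_b)
        history.append(ll)
        if len(history) > 1 and abs(history[-1] - history[-2]) < tol * abs(history[-2]):
            break
        prior = gamma[0] / gamma[0].sum()
        trans = xi.sum(axis=0)
        denom = trans.sum(axis=1, keepdims=True)
        tpm = np.where(denom > 0, trans / np.where(denom > 0, denom, 1.0), current.omm.tpm)
        tpm = tpm / tpm.sum(axis=1, keepdims=True)
        omm = MarkovChain(list(current.labels), prior, tpm)
        emissions = current.emissions
        if mode == "all":
            emissions = _update_emissions(current.emissions, obs, gamma)
        current = CHMMParams(omm, emissions)
    return current, history


def _update_emissions(em: GaussianMixtureEmissions, obs: np.ndarray, gamma: np.ndarray):
    q, m, d = em.means.shape
    weights = np.empty_like(em.weights)
    means = np.empty_like(em.means)
    covs = np.empty_like(em.covariances)
    for j in range(q):
        comp = np.stack(
            [
                np.log(em.weights[j, k] + 1e-300)
                + gaussian_logpdf(obs, em.means[j, k], em.covariances[j, k])
                for k in range(m)
            ],
            axis=1,
        )
        resp = np.exp(comp - logsumexp(comp, axis=1, keepdims=True)) * gamma[:, j][:, None]
        nk = resp.sum(axis=0) + 1e-12
        weights[j] = nk / nk.sum()
        means[j] = (resp.T @ obs) / nk[:, None]
        for k in range(m):
            diff = obs - means[j, k]
            cov = (resp[:, k][:, None] * diff).T @ diff / nk[k]
            if np.trace(cov) <= 0:
                warnings.warn(f"covariance collapse in state {j}; regularisation floor applied")
            covs[j, k] = _regularise_cov(cov)
    return GaussianMixtureEmissions(weights, means, covs)


def classify_sequence(model: CHMMParams, obs: np.ndarray, rejector=None) -> list[str]:
    """Per-frame activity labels for a feature sequence.

    With a rejection model, frames scoring below its threshold are removed
    before Viterbi decoding (the chain skips them) and labelled ``SPURIOUS``;
    all other frames receive their Viterbi-path label. Output length equals
    input length.
    """
    from .rejection import reject_spurious

    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    if rejector is None:
        return viterbi_decode(model, obs)[0]
    mask = reject_spurious(rejector, model.emissions, obs)
    if mask.all():
        raise ValueError("no classifiable frames: every frame was rejected as spurious")
    kept = viterbi_decode(model, obs[~mask])[0]
    out: list[str] = []
    it = iter(kept)
    for flagged in mask:
        out.append(SPURIOUS if flagged else next(it))
    return out


def simulate_chmm(
    model: CHMMParams, length: int, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, list[str]]:
    """Sample (observations, state labels) of the given length from λ."""
    from .markov import generate_states

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = generate_states(model.omm, length, rng)
    index = {s: i for i, s in enumerate(model.labels)}
    d = model.n_features
    obs = np.empty((length, d))
    for t, s in enumerate(states):
        j = index[s]
        k = rng.choice(model.emissions.n_components, p=model.emissions.weights[j])
        obs[t] = rng.multivariate_normal(
            model.emissions.means[j, k], model.emissions.covariances[j, k]
        )
    return obs, states


class SequentialHMM:
    """Sequential activity classifier model.

    Parameters
    ----------
    labels : state vocabulary (activity primitives), fixing the state order.
    n_components : number of Gaussian components per state (M; default 1).
    smoothing : additive smoothing δ for the event-counting phase.
    seed : seed for the mixture-fit initialisation when M > 1.
    """

    def __init__(self, labels: list[str] | None = None, n_components: int = 1,
                 smoothing: float = 0.0, seed: int = 0):
        self.labels = labels
        self.n_components = n_components
        self.smoothing = smoothing
        self.seed = seed

    def fit(self, experiments: list[tuple[np.ndarray, list[str]]]) -> "SequentialHMMResults":
        """First-phase (supervised) training; returns a results object."""
        params = first_phase_train(
            experiments,
            labels=self.labels,
            n_components=self.n_components,
            smoothing=self.smoothing,
            seed=self.seed,
        )
        train_ll = sum(forward_loglik(params, x) for x, _ in experiments)
        n_frames = sum(np.atleast_2d(x).shape[0] for x, _ in experiments)
        return SequentialHMMResults(self, params, train_loglik=train_ll, n_train_frames=n_frames)


@dataclass
class SequentialHMMResults:
    """Fitted cHMM: estimated λ, training diagnostics, decode/refine/simulate."""

    model: SequentialHMM
    params: CHMMParams
    train_loglik: float
    n_train_frames: int
    refine_history: list[float] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return self.params.labels

    def loglik(self, obs: np.ndarray) -> float:
        return forward_loglik(self.params, obs)

    def decode(self, obs: np.ndarray) -> tuple[list[str], float]:
        return viterbi_decode(self.params, obs)

    def classify(self, obs: np.ndarray, rejector=None) -> list[str]:
        return classify_sequence(self.params, obs, rejector)

    def refine(self, obs: np.ndarray, mode: str = "transitions_only",
               tol: float = 1e-4, max_iter: int = 100) -> "SequentialHMMResults":
        """Second-phase Baum-Welch refinement; returns new results."""
        params, history = baum_welch_refine(self.params, obs, mode=mode, tol=tol, max_iter=max_iter)
        return replace(self, params=params, refine_history=list(history))

    def simulate(self, length: int, seed: int | np.random.Generator = 0):
        return simulate_chmm(self.params, length, seed)

    def summary(self) -> str:
        """Plain-text summary of the fitted model."""
        p = self.params
        lines = [
            "Sequential cHMM activity classifier",
            "=" * 51,
            f"States (Q):            {p.n_states}",
            f"Feature dimension (d): {p.n_features}",
            f"Mixture components (M):{p.emissions.n_components:>2}",
            f"Training frames:       {self.n_train_frames}",
            f"Training log-lik:      {self.train_loglik:.2f}",
        ]
        if self.refine_history:
            lines.append(
                f"Baum-Welch iterations: {len(self.refine_history)}"
                f" (log-lik {self.refine_history[0]:.2f} -> {self.refine_history[-1]:.2f})"
            )
        lines.append("-" * 51)
        lines.append("Transition probability matrix:")
        df = pd.DataFrame(p.omm.tpm, index=p.labels, columns=p.labels)
        lines.append(df.round(4).to_string())
        lines.append("-" * 51)
        lines.append("Prior:")
        lines.append(pd.Series(p.omm.prior, index=p.labels).round(4).to_string())
        return "\n".join(lines)
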