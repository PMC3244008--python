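"""Native single-frame classifiers and confusion-matrix evaluation.

Probabilistic classifiers assign a frame to the class whose class-conditional
density p(x|C_i) is largest (maximum likelihood, no prior weighting by
default; a prior-weighted rule is available behind a flag). Geometric
classifiers work directly on Euclidean distances. Ties always break to the
lowest class index (classes ordered as first fitted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from .selection import LabelledFeatureSet

COV_REG = 1e-6  # scale of the ridge added to covariances, times mean diagonal


def _regularise_cov(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    scale = np.trace(cov) / d
    if scale <= 0:
        scale = 1.0
    return cov + COV_REG * scale * np.eye(d)


def gaussian_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Multivariate normal log-density via Cholesky; x is (n, d)."""
    x = np.atleast_2d(x)
    d = mean.shape[0]
    chol = np.linalg.cholesky(cov)
    diff = x - mean
    sol = np.linalg.solve(chol, diff.T)
    maha = (sol ** 2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def fit_gaussian_mixture(
    x: np.ndarray,
    n_components: int = 1,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit a Gaussian mixture by EM; returns (weights, means, covariances).

    ``n_components=1`` is the closed form (sample mean, regularised sample
    covariance). For larger M the means are seeded on distinct data points
    drawn with a fixed-seed generator and EM runs to relative log-likelihood
    tolerance ``tol``. This same routine fits both the class-conditional
    densities of the single-frame GMM classifier and the per-state emissions
    of the sequential cHMM.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, d = x.shape
    if n_components == 1:
        mean = x.mean(axis=0)
        cov = _regularise_cov(np.cov(x.T, bias=True).reshape(d, d))
        return np.ones(1), mean[None, :], cov[None, :, :]
    if n < n_components:
        raise ValueError("need at least as many points as mixture components")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_components, replace=False)
    means = x[idx].copy()
    # k-means-style seeding: a few assignment/update rounds, then moment init
    for _ in range(10):
        assign = np.argmin(((x[:, None, :] - means[None]) ** 2).sum(axis=2), axis=1)
        for m in range(n_components):
            if np.any(assign == m):
                means[m] = x[assign == m].mean(axis=0)
    weights = np.array([(assign == m).mean() for m in range(n_components)])
    weights = np.clip(weights, 1e-3, None)
    weights /= weights.sum()
    covs = np.empty((n_components, d, d))
    for m in range(n_components):
        xm = x[assign == m]
        if xm.shape[0] > 1:
            covs[m] = _regularise_cov(np.cov(xm.T, bias=True).reshape(d, d))
        else:
            covs[m] = _regularise_cov(np.cov(x.T, bias=True).reshape(d, d))
    prev_ll = -np.inf
    for _ in range(max_iter):
        log_resp = np.stack(
            [np.log(weights[m]) + gaussian_logpdf(x, means[m], covs[m]) for m in range(n_components)],
            axis=1,
        )
        ll = logsumexp(log_resp, axis=1).sum()
        resp = np.exp(log_resp - logsumexp(log_resp, axis=1, keepdims=True))
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        for m in range(n_components):
            diff = x - means[m]
            covs[m] = _regularise_cov((resp[:, m][:, None] * diff).T @ diff / nk[m])
        if np.isfinite(prev_ll) and (ll - prev_ll) < tol * abs(prev_ll):
            break
        prev_ll = ll
    return weights, means, covs


class _BaseClassifier:
    classes_: np.ndarray

    def fit(self, x: np.ndarray, y: np.ndarray):
        raise NotImplementedError

    def predict(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def fit_set(self, data: LabelledFeatureSet):
        return self.fit(data.matrix, data.labels)


class _ProbabilisticClassifier(_BaseClassifier):
    """Shared argmax-density decision rule."""

    use_priors: bool = False

    def class_log_density(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict(self, x: np.ndarray) -> np.ndarray:
        scores = self.class_log_density(np.atleast_2d(x))
        if self.use_priors:
            scores = scores + np.log(self.priors_)
        return self.classes_[np.argmax(scores, axis=1)]  # argmax ties -> lowest index


class NaiveBayesClassifier(_ProbabilisticClassifier):
    """Per-class product of univariate Gaussians (one per feature)."""

    def __init__(self, use_priors: bool = False):
        self.use_priors = use_priors

    def fit(self, x, y):
        x, y = np.atleast_2d(x), np.asarray(y)
        self.classes_ = np.unique(y)
        self.means_, self.vars_, priors = [], [], []
        for c in self.classes_:
            xc = x[y == c]
            if xc.shape[0] < 2:
                raise ValueError(f"class {c!r} needs at least 2 instances")
            self.means_.append(xc.mean(axis=0))
            v = xc.var(axis=0)
            self.vars_.append(np.where(v > 0, v, COV_REG * max(v.mean(), 1.0)))
            priors.append(xc.shape[0] / x.shape[0])
        self.means_ = np.array(self.means_)
        self.vars_ = np.array(self.vars_)
        self.priors_ = np.array(priors)
        return self

    def class_log_density(self, x):
        diff = x[:, None, :] - self.means_[None, :, :]
        return -0.5 * (np.log(2 * np.pi * self.vars_)[None] + diff ** 2 / self.vars_[None]).sum(axis=2)


class GMMClassifier(_ProbabilisticClassifier):
    """Class-conditional Gaussian-mixture densities (M components per class)."""

    def __init__(self, n_components: int = 1, use_priors: bool = False, seed: int = 0):
        self.n_components = n_components
        self.use_priors = use_priors
        self.seed = seed

    def fit(self, x, y):
        x, y = np.atleast_2d(x), np.asarray(y)
        self.classes_ = np.unique(y)
        self.models_, priors = [], []
        for c in self.classes_:
            xc = x[y == c]
            if xc.shape[0] < 2:
                raise ValueError(f"class {c!r} needs at least 2 instances")
            try:
                self.models_.append(fit_gaussian_mixture(xc, self.n_components, seed=self.seed))
            except np.linalg.LinAlgError as exc:
                raise ValueError(f"singular covariance for class {c!r}") from exc
            priors.append(xc.shape[0] / x.shape[0])
        self.priors_ = np.array(priors)
        return self

    def class_log_density(self, x):
        out = np.empty((x.shape[0], len(self.classes_)))
        for i, (w, mu, cov) in enumerate(self.models_):
            comp = np.stack(
                [np.log(w[m]) + gaussian_logpdf(x, mu[m], cov[m]) for m in range(w.size)], axis=1
            )
            out[:, i] = logsumexp(comp, axis=1)
        return out


class ParzenClassifier(_ProbabilisticClassifier):
    """Kernel density estimate per class: Gaussian product kernel, Silverman bandwidths."""

    def __init__(self, bandwidth: float | None = None, use_priors: bool = False):
        self.bandwidth = bandwidth
        self.use_priors = use_priors

    def fit(self, x, y):
        x, y = np.atleast_2d(x), np.asarray(y)
        self.classes_ = np.unique(y)
        self.train_, self.bandwidths_, priors = [], [], []
        d = x.shape[1]
        for c in self.classes_:
            xc = x[y == c]
            self.train_.append(xc)
            if self.bandwidth is not None:
                h = np.full(d, self.bandwidth)
            else:
                n = xc.shape[0]
                sd = xc.std(axis=0)
                sd = np.where(sd > 0, sd, 1.0)
                h = 1.06 * sd * max(n, 2) ** (-1.0 / (d + 4))
            self.bandwidths_.append(h)
            priors.append(xc.shape[0] / x.shape[0])
        self.priors_ = np.array(priors)
        return self

    def class_log_density(self, x):
        out = np.empty((x.shape[0], len(self.classes_)))
        for i, (xc, h) in enumerate(zip(self.train_, self.bandwidths_)):
            u = (x[:, None, :] - xc[None, :, :]) / h
            logk = -0.5 * (u ** 2).sum(axis=2) - np.log(h).sum() - 0.5 * x.shape[1] * np.log(2 * np.pi)
            out[:, i] = logsumexp(logk, axis=1) - np.log(xc.shape[0])
        return out


class NearestMeanClassifier(_BaseClassifier):
    def fit(self, x, y):
        x, y = np.atleast_2d(x), np.asarray(y)
        if x.shape[0] == 0:
            raise ValueError("empty training set")
        self.classes_ = np.unique(y)
        self.centroids_ = np.array([x[y == c].mean(axis=0) for c in self.classes_])
        return self

    def predict(self, x):
        dist = cdist(np.atleast_2d(x), self.centroids_)
        return self.classes_[np.argmin(dist, axis=1)]


class KNNClassifier(_BaseClassifier):
    def __init__(self, k: int = 1):
        if k < 1:
            raise ValueError("k must be at least 1")
        self.k = k

    def fit(self, x, y):
        x, y = np.atleast_2d(x), np.asarray(y)
        if x.shape[0] == 0:
            raise ValueError("empty training set")
        self.classes_ = np.unique(y)
        self.x_, self.y_ = x, y
        return self

    def predict(self, x):
        x = np.atleast_2d(x)
        dist = cdist(x, self.x_)
        k = min(self.k, self.x_.shape[0])
        nn = np.argsort(dist, axis=1)[:, :k]
        out = []
        for row in nn:
            votes = self.y_[row]
            counts = np.array([(votes == c).sum() for c in self.classes_])
            out.append(self.classes_[np.argmax(counts)])  # ties -> lowest class index
        return np.array(out)


def fit_probabilistic(train: LabelledFeatureSet, kind: str, m: int = 1,
                      h: float | None = None, use_priors: bool = False):
    """Fit a probabilistic classifier: kind in {'nb', 'gmm', 'parzen'}."""
    if kind == "nb":
        clf = NaiveBayesClassifier(use_priors=use_priors)
    elif kind == "gmm":
        clf = GMMClassifier(n_components=m, use_priors=use_priors)
    elif kind == "parzen":
        clf = ParzenClassifier(bandwidth=h, use_priors=use_priors)
    else:
        raise ValueError(f"unknown probabilistic classifier {kind!r}")
    return clf.fit_set(train)


def fit_geometric(train: LabelledFeatureSet, kind: str, k: int = 1):
    """Fit a geometric classifier: kind in {'nm', 'knn'}."""
    if kind == "nm":
        clf = NearestMeanClassifier()
    elif kind == "knn":
        clf = KNNClassifier(k=k)
    else:
        raise ValueError(f"unknown geometric classifier {kind!r}")
    return clf.fit_set(train)


@dataclass
class ConfusionMatrix:
    """Counts of (true class, predicted class) outcomes."""

    counts: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be square over the label set")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels=None) -> "ConfusionMatrix":
        y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
        if labels is None:
            labels = sorted(set(y_true) | set(y_pred))
        labels = list(labels)
        index = {c: i for i, c in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(counts, labels)


def evaluate(classifier, test: LabelledFeatureSet, labels=None) -> ConfusionMatrix:
    """Predict every test instance and tabulate the confusion matrix."""
    pred = classifier.predict(test.matrix)
    if labels is None:
        labels = sorted(set(test.labels) | set(classifier.classes_))
    return ConfusionMatrix.from_predictions(test.labels, pred, labels)


def aggregate_confusions(matrices: list[ConfusionMatrix]) -> ConfusionMatrix:
    """Elementwise sum of confusion matrices over identical label sets."""
    if not matrices:
        raise ValueError("nothing to aggregate")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise ValueError("confusion matrices have mismatched label sets")
    counts = np.sum([m.counts for m in matrices], axis=0)
    return ConfusionMatrix(counts, labels)
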