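"""Spurious-frame rejection by emission-likelihood thresholding.

Frames from activities outside the trained vocabulary have low likelihood
under every state's emission density. Each frame is scored by the maximum
over states of its log emission density (alternative rules: log-sum over
states, or a stationary-weighted sum); frames scoring below a threshold are
flagged spurious and withheld from the sequential classifier. The threshold
is calibrated by a ROC sweep over genuine (inlier) and garbage (outlier)
scores, choosing the Youden-optimal point (max sensitivity + specificity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .hmm import GaussianMixtureEmissions

SCORE_RULES = ("max", "sum", "stationary")


@dataclass
class RejectionModel:
    """Calibrated likelihood threshold with its operating point and ROC curve."""

    threshold: float
    score_rule: str = "max"
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    roc_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        if self.score_rule not in SCORE_RULES:
            raise ValueError(f"score_rule must be one of {SCORE_RULES}")
        for v in (self.sensitivity, self.specificity):
            if not np.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError("sensitivity/specificity must lie in [0, 1]")
        self.roc_points = np.asarray(self.roc_points, dtype=float).reshape(-1, 3)

    @property
    def auc(self) -> float:
        """Area under the ROC curve (trapezoid over 1-specificity)."""
        if self.roc_points.shape[0] < 2:
            return float("nan")
        fpr = 1.0 - self.roc_points[:, 2]
        tpr = self.roc_points[:, 1]
        order = np.argsort(fpr)
        return float(np.trapezoid(tpr[order], fpr[order]))


def frame_score(
    emissions: GaussianMixtureEmissions, obs: np.ndarray, score_rule: str = "max",
    stationary: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame anomaly score: larger means more compatible with the model."""
    log_b = emissions.log_density(np.atleast_2d(obs))
    if score_rule == "max":
        return log_b.max(axis=1)
    if score_rule == "sum":
        return logsumexp(log_b, axis=1)
    if score_rule == "stationary":
        if stationary is None:
            raise ValueError("stationary weights required for the 'stationary' rule")
        return logsumexp(log_b + np.log(np.asarray(stationary) + 1e-300)[None, :], axis=1)
    raise ValueError(f"unknown score rule {score_rule!r}")


def calibrate_threshold(
    inlier_scores: np.ndarray, outlier_scores: np.ndarray, score_rule: str = "max"
) -> RejectionModel:
    """ROC sweep over score midpoints; Youden-optimal threshold.

    sensitivity = fraction of outliers below the threshold (rejected);
    specificity = fraction of inliers at/above the threshold (kept).
    Ties on the Youden index resolve to the lower threshold (rejects less).
    """
    inl = np.asarray(inlier_scores, dtype=float)
    out = np.asarray(outlier_scores, dtype=float)
    if inl.size == 0 or out.size == 0:
        raise ValueError("both score lists must be non-empty")
    merged = np.sort(np.unique(np.concatenate([inl, out])))
    mids = (merged[:-1] + merged[1:]) / 2.0
    candidates = np.concatenate([[merged[0] - 1.0], mids, [merged[-1] + 1.0]])
    sens = np.array([(out < t).mean() for t in candidates])
    spec = np.array([(inl >= t).mean() for t in candidates])
    youden = sens + spec
    best = int(np.argmax(youden))  # first max -> lowest threshold
    roc = np.column_stack([candidates, sens, spec])
    return RejectionModel(
        threshold=float(candidates[best]),
        score_rule=score_rule,
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        roc_points=roc,
    )


def reject_spurious(
    rejection: RejectionModel, emissions: GaussianMixtureEmissions, obs: np.ndarray,
    stationary: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask: True where the frame scores below the threshold."""
    scores = frame_score(emissions, obs, rejection.score_rule, stationary)
    return scores < rejection.threshold
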