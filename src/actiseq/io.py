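"""JSON serialisation of models.

All model files are JSON with a ``kind`` tag; floats are written at full
precision (`repr` round trip), so save -> load -> save is byte-identical and
loaded models reproduce in-memory likelihoods exactly. Invariants (row sums,
weight sums, shapes) are re-validated on load by the model constructors.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .classifiers import (
    GMMClassifier,
    KNNClassifier,
    NaiveBayesClassifier,
    NearestMeanClassifier,
    ParzenClassifier,
)
from .hmm import CHMMParams, GaussianMixtureEmissions
from .markov import MarkovChain
from .rejection import RejectionModel


def _arr(x) -> list:
    return np.asarray(x).tolist()


def _encode(model) -> dict:
    if isinstance(model, MarkovChain):
        return {"kind": "omm", "labels": list(model.labels),
                "prior": _arr(model.prior), "tpm": _arr(model.tpm)}
    if isinstance(model, CHMMParams):
        return {
            "kind": "chmm",
            "labels": list(model.labels),
            "prior": _arr(model.omm.prior),
            "tpm": _arr(model.omm.tpm),
            "emissions": {
                "weights": _arr(model.emissions.weights),
                "means": _arr(model.emissions.means),
                "covariances": _arr(model.emissions.covariances),
            },
        }
    if isinstance(model, RejectionModel):
        return {
            "kind": "rejection",
            "threshold": model.threshold,
            "score_rule": model.score_rule,
            "sensitivity": model.sensitivity,
            "specificity": model.specificity,
            "roc_points": _arr(model.roc_points),
        }
    if isinstance(model, NaiveBayesClassifier):
        return {"kind": "nb", "classes": _arr(model.classes_), "means": _arr(model.means_),
                "vars": _arr(model.vars_), "priors": _arr(model.priors_),
                "use_priors": model.use_priors}
    if isinstance(model, GMMClassifier):
        return {
            "kind": "gmm",
            "classes": _arr(model.classes_),
            "use_priors": model.use_priors,
            "priors": _arr(model.priors_),
            "models": [
                {"weights": _arr(w), "means": _arr(mu), "covariances": _arr(cov)}
                for w, mu, cov in model.models_
            ],
        }
    if isinstance(model, ParzenClassifier):
        return {"kind": "parzen", "classes": _arr(model.classes_),
                "train": [_arr(t) for t in model.train_],
                "bandwidths": [_arr(h) for h in model.bandwidths_],
                "priors": _arr(model.priors_), "use_priors": model.use_priors}
    if isinstance(model, NearestMeanClassifier):
        return {"kind": "nm", "classes": _arr(model.classes_), "centroids": _arr(model.centroids_)}
    if isinstance(model, KNNClassifier):
        return {"kind": "knn", "classes": _arr(model.classes_), "k": model.k,
                "x": _arr(model.x_), "y": _arr(model.y_)}
    raise TypeError(f"cannot serialise model of type {type(model).__name__}")


def _decode(doc: dict):
    kind = doc.get("kind")
    if kind == "omm":
        return MarkovChain(list(doc["labels"]), np.array(doc["prior"]), np.array(doc["tpm"]))
    if kind == "chmm":
        omm = MarkovChain(list(doc["labels"]), np.array(doc["prior"]), np.array(doc["tpm"]))
        em = doc["emissions"]
        return CHMMParams(
            omm,
            GaussianMixtureEmissions(
                np.array(em["weights"]), np.array(em["means"]), np.array(em["covariances"])
            ),
        )
    if kind == "rejection":
        return RejectionModel(
            threshold=doc["threshold"],
            score_rule=doc["score_rule"],
            sensitivity=doc["sensitivity"],
            specificity=doc["specificity"],
            roc_points=np.array(doc["roc_points"]),
        )
    if kind == "nb":
        clf = NaiveBayesClassifier(use_priors=doc["use_priors"])
        clf.classes_ = np.array(doc["classes"])
        clf.means_ = np.array(doc["means"])
        clf.vars_ = np.array(doc["vars"])
        clf.priors_ = np.array(doc["priors"])
        return clf
    if kind == "gmm":
        clf = GMMClassifier(use_priors=doc["use_priors"])
        clf.classes_ = np.array(doc["classes"])
        clf.priors_ = np.array(doc["priors"])
        clf.models_ = [
            (np.array(m["weights"]), np.array(m["means"]), np.array(m["covariances"]))
            for m in doc["models"]
        ]
        return clf
    if kind == "parzen":
        clf = ParzenClassifier(use_priors=doc["use_priors"])
        clf.classes_ = np.array(doc["classes"])
        clf.train_ = [np.array(t) for t in doc["train"]]
        clf.bandwidths_ = [np.array(h) for h in doc["bandwidths"]]
        clf.priors_ = np.array(doc["priors"])
        return clf
    if kind == "nm":
        clf = NearestMeanClassifier()
        clf.classes_ = np.array(doc["classes"])
        clf.centroids_ = np.array(doc["centroids"])
        return clf
    if kind == "knn":
        clf = KNNClassifier(k=doc["k"])
        clf.classes_ = np.array(doc["classes"])
        clf.x_ = np.array(doc["x"])
        clf.y_ = np.array(doc["y"])
        return clf
    raise ValueError(f"unrecognised model kind {kind!r}")


def save_model(model, path) -> None:
    """Write a model to JSON at full float precision."""
    doc = _encode(model)
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_model(path):
    """Read a model from JSON, re-validating its invariants."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed model file {path}: {exc}") from exc
    return _decode(doc)
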