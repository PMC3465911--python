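"""Classification stage: an ensemble of extremely randomized trees.

The learner is deliberately pluggable and scale-invariant (tree ensembles
are unaffected by monotone feature rescaling), so the dissimilarity features
need no further normalisation.  The ensemble itself is delegated to
scikit-learn; this module pins the algorithm family, defaults and seed
policy.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier

__all__ = ["ClassifierSpec", "train", "predict"]


@dataclass
class ClassifierSpec:
    algorithm: str = "extra_trees"
    n_estimators: int = 500
    max_features: object = "sqrt"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def train(features, labels, spec: ClassifierSpec | None = None):
    """Fit the ensemble; returns an opaque fitted model handle."""
    spec = spec or ClassifierSpec()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("features must be a non-empty 2D matrix")
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree on sample count")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class; cannot discriminate")
    if spec.algorithm != "extra_trees":
        raise ValueError(f"unknown algorithm {spec.algorithm!r}")
    model = ExtraTreesClassifier(
        n_estimators=spec.n_estimators,
        max_features=spec.max_features,
        random_state=spec.seed,
    )
    model.fit(X, y)
    return model


def predict(model, features) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training ({model.n_features_in_})"
        )
    return model.predict(X)
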