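"""Gaussian-kernel SVM sexing on fin-color histograms, and the
score-derived pigmentation-intensity statistic.

A binary soft-margin SVM with an RBF (Gaussian) kernel is trained on the
concatenated per-channel Lab histograms of the caudal-fin crop.  Its signed
decision value f(x) = sum_i w_i k(X_i, x) + b measures how far (in feature
space) an individual sits from the separating hyperplane; we expose it as a
score pair (s_male = f, s_female = -f) whose difference d = f is the raw
per-individual coloration signal.  Across a cohort, the z-transform of d is
the pigmentation-intensity statistic used by the downstream association
models.

Training delegates to scikit-learn's SVC; the fitted model is stored as its
support vectors, signed dual weights and bias, so scoring is an explicit
kernel sum that can be serialized to JSON and audited independently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from finsex.features import LabHistogram, feature_matrix

logger = logging.getLogger(__name__)

#: Label convention: decision value > 0 means male.
LABELS = ("F", "M")


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        X = np.asarray(features, dtype=float)
        return X.reshape(1, -1) if X.ndim == 1 else X
    if isinstance(features, LabHistogram):
        return features.feature.reshape(1, -1)
    if len(features) and isinstance(features[0], LabHistogram):
        return feature_matrix(list(features))
    return np.asarray(features, dtype=float)


def gaussian_kernel(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """RBF kernel k(x, y) = exp(-gamma * ||x - y||^2), in (0, 1]."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"feature length mismatch: {x.shape} vs {y.shape}")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    return float(np.exp(-gamma * np.sum((x - y) ** 2)))


@dataclass
class SvmModel:
    """Fitted RBF-SVM: support vectors, signed dual weights, bias.

    The decision value of a feature x is
    ``sum_i dual_weights[i] * exp(-gamma ||support_vectors[i] - x||^2) + bias``;
    positive values are classified male.
    """

    support_vectors: np.ndarray
    dual_weights: np.ndarray
    bias: float
    gamma: float
    regularization: float
    bins_per_channel: Optional[int] = None
    label_convention: tuple[str, str] = LABELS

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.regularization <= 0:
            raise ValueError("regularization C must be > 0")
        if not (len(self.dual_weights) and (self.dual_weights > 0).any() and (self.dual_weights < 0).any()):
            raise ValueError("model needs at least one support vector per class")

    def decision_values(self, features) -> np.ndarray:
        """Signed decision value f(x) for each row of ``features``."""
        X = _as_matrix(features)
        if X.shape[1] != self.support_vectors.shape[1]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model "
                f"dimension {self.support_vectors.shape[1]}"
            )
        sq = (
            np.sum(X**2, axis=1)[:, None]
            + np.sum(self.support_vectors**2, axis=1)[None, :]
            - 2.0 * X @ self.support_vectors.T
        )
        K = np.exp(-self.gamma * np.maximum(sq, 0.0))
        return K @ self.dual_weights + self.bias

    def to_json(self, path: str | Path) -> None:
        doc = {
            "kind": "finsex-rbf-svm",
            "support_vectors": self.support_vectors.tolist(),
            "dual_weights": self.dual_weights.tolist(),
            "bias": self.bias,
            "gamma": self.gamma,
            "regularization": self.regularization,
            "bins_per_channel": self.bins_per_channel,
            "label_convention": list(self.label_convention),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "SvmModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            support_vectors=np.asarray(doc["support_vectors"], dtype=float),
            dual_weights=np.asarray(doc["dual_weights"], dtype=float),
            bias=float(doc["bias"]),
            gamma=float(doc["gamma"]),
            regularization=float(doc["regularization"]),
            bins_per_channel=doc.get("bins_per_channel"),
            label_convention=tuple(doc.get("label_convention", LABELS)),
        )


@dataclass
class SexScore:
    """Per-individual sex scores from the SVM decision value.

    ``d = s_male - s_female`` is the raw coloration signal; ``z`` is filled
    by :func:`intensity_scores` once the whole cohort has been scored.
    Predicted male iff d > 0 (exact ties go to female, logged).
    """

    id: str
    s_male: float
    s_female: float
    d: float
    predicted_sex: str
    z: Optional[float] = None


def resolve_gamma(X: np.ndarray, gamma: float | str = "scale") -> float:
    """Default kernel bandwidth: 1 / (n_features * Var(X))."""
    if gamma == "scale":
        var = float(X.var())
        if var == 0:
            raise ValueError("features have zero variance; supply gamma explicitly")
        return 1.0 / (X.shape[1] * var)
    g = float(gamma)
    if g <= 0:
        raise ValueError("gamma must be > 0")
    return g


def train(
    features,
    labels: Sequence[str],
    gamma: float | str = "scale",
    C: float = 1.0,
    bins_per_channel: Optional[int] = None,
) -> SvmModel:
    """Train the RBF-SVM on histogram features with labels in {"M", "F"}.

    Deterministic given inputs and hyperparameters.  Raises on single-class
    input; logs a warning when the classes share identical features.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    present = set(np.unique(y))
    if not {"M", "F"} <= present:
        raise ValueError(f"both classes required, got labels {sorted(present)}")
    if (y == "M").sum() < 2 or (y == "F").sum() < 2:
        raise ValueError("need at least 2 samples per class")
    g = resolve_gamma(X, gamma)
    dup = _classes_share_features(X, y)
    if dup:
        logger.warning("identical feature vectors appear in both classes (%d pairs)", dup)
    svc = SVC(kernel="rbf", gamma=g, C=C)
    svc.fit(X, y)
    # sklearn sorts classes alphabetically -> ('F', 'M'); its decision value
    # is positive for the second class, i.e. male, matching our convention.
    return SvmModel(
        support_vectors=svc.support_vectors_.copy(),
        dual_weights=svc.dual_coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        gamma=g,
        regularization=C,
        bins_per_channel=bins_per_channel,
    )


def _classes_share_features(X: np.ndarray, y: np.ndarray) -> int:
    Xm = {row.tobytes() for row in X[y == "M"]}
    return sum(1 for row in X[y == "F"] if row.tobytes() in Xm)


def score(model: SvmModel, feature, sample_id: str = "") -> SexScore:
    """Score one individual: decision value, score pair, predicted sex."""
    d = float(model.decision_values(feature)[0])
    if d == 0.0:
        logger.warning("sample %s: decision value exactly 0; tie classified F", sample_id)
    return SexScore(
        id=sample_id,
        s_male=d,
        s_female=-d,
        d=d,
        predicted_sex="M" if d > 0 else "F",
    )


def score_cohort(model: SvmModel, features, ids: Sequence[str]) -> list[SexScore]:
    """Score many individuals at once (vectorized decision values)."""
    X = _as_matrix(features)
    if len(ids) != X.shape[0]:
        raise ValueError("ids and features differ in length")
    dvals = model.decision_values(X)
    scores = []
    for sid, d in zip(ids, dvals):
        d = float(d)
        if d == 0.0:
            logger.warning("sample %s: decision value exactly 0; tie classified F", sid)
        scores.append(
            SexScore(id=str(sid), s_male=d, s_female=-d, d=d, predicted_sex="M" if d > 0 else "F")
        )
    return scores


def intensity_scores(scores: list[SexScore], ddof: int = 0) -> list[SexScore]:
    """Fill the pigmentation-intensity z-scores z_i = (d_i - mean d) / sd(d).

    Uses the population (n) denominator by default (``ddof=1`` for the
    sample version).  Requires >= 2 scores with nonzero variance of d.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 scores to z-transform")
    d = np.array([s.d for s in scores], dtype=float)
    sd = d.std(ddof=ddof)
    if sd == 0:
        raise ValueError("decision values have zero variance; z undefined")
    z = (d - d.mean()) / sd
    return [
        SexScore(id=s.id, s_male=s.s_male, s_female=s.s_female, d=s.d,
                 predicted_sex=s.predicted_sex, z=float(zi))
        for s, zi in zip(scores, z)
    ]


def scores_to_frame(scores: list[SexScore]) -> pd.DataFrame:
    """Scores as a DataFrame (id, s_male, s_female, d, z, predicted_sex)."""
    return pd.DataFrame(
        {
            "id": [s.id for s in scores],
            "s_male": [s.s_male for s in scores],
            "s_female": [s.s_female for s in scores],
            "d": [s.d for s in scores],
            "z": [s.z for s in scores],
            "predicted_sex": [s.predicted_sex for s in scores],
        }
    )


def cross_validated_accuracy(
    features,
    labels: Sequence[str],
    gamma: float | str = "scale",
    C: float = 1.0,
    n_splits: int = 5,
    seed: int = 0,
) -> float:
    """Stratified k-fold cross-validated accuracy of the RBF-SVM.

    This is the default reported performance protocol; resubstitution
    (apparent) agreement can be had by scoring the training set directly.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        model = train(X[train_idx], y[train_idx], gamma=gamma, C=C)
        d = model.decision_values(X[test_idx])
        pred = np.where(d > 0, "M", "F")
        correct += int((pred == y[test_idx]).sum())
    return correct / len(y)
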