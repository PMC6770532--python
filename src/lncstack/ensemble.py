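"""Two-layer stacked ensemble: subset-specific random forests whose
positive-class probabilities are averaged by the output layer.

Each of the (by default 10) base classifiers is a random forest trained
on one optimal feature subset; the model's score for a transcript is
the arithmetic mean of the members' lncRNA probabilities, thresholded
at 0.5 (ties resolved toward lncRNA).
"""

from __future__ import annotations

from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .assemble import feature_schema

POSITIVE_CLASS = 1  # lncRNA


class StackedForestClassifier(ClassifierMixin, BaseEstimator):
    """Averaged ensemble of mask-restricted random forests.

    Parameters
    ----------
    masks : sequence of boolean arrays or None
        One mask per member; ``None`` trains ``n_members`` forests on
        all columns (differing only by seed).
    n_members : int
        Member count used when ``masks is None`` (10 by default).
    n_estimators : int
        Trees per member forest.
    threshold : float
        Decision threshold on the averaged score; a score equal to the
        threshold is called lncRNA.
    """

    def __init__(
        self,
        masks: Optional[Sequence] = None,
        n_members: int = 10,
        n_estimators: int = 100,
        threshold: float = 0.5,
        random_state: Optional[int] = None,
    ):
        self.masks = masks
        self.n_members = n_members
        self.n_estimators = n_estimators
        self.threshold = threshold
        self.random_state = random_state

    def _resolved_masks(self, n_features: int) -> list[np.ndarray]:
        if self.masks is None:
            return [np.ones(n_features, dtype=bool)] * self.n_members
        masks = [np.asarray(m, dtype=bool) for m in self.masks]
        for i, m in enumerate(masks):
            if m.shape != (n_features,):
                raise ValueError(f"mask {i} does not match feature count")
            if m.sum() == 0:
                raise ValueError(f"mask {i} is empty")
        return masks

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("StackedForestClassifier is a binary classifier")
        masks = self._resolved_masks(X.shape[1])
        base = 0 if self.random_state is None else int(self.random_state)
        self.members_ = []
        for i, mask in enumerate(masks):
            rf = RandomForestClassifier(
                n_estimators=self.n_estimators,
                random_state=(base + i) % (2**31),
                n_jobs=1,
            )
            rf.fit(X[:, mask], y)
            self.members_.append((mask, rf))
        self.n_features_in_ = X.shape[1]
        return self

    def predict_score(self, X) -> np.ndarray:
        """Mean positive-class (lncRNA) probability across members."""
        check_is_fitted(self, "members_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch with the fitted model")
        scores = np.zeros(X.shape[0])
        for mask, rf in self.members_:
            pos = list(rf.classes_).index(POSITIVE_CLASS)
            scores += rf.predict_proba(X[:, mask])[:, pos]
        return scores / len(self.members_)

    def predict_proba(self, X) -> np.ndarray:
        score = self.predict_score(X)
        proba = np.column_stack([1.0 - score, score])
        # column order must follow classes_
        order = np.argsort(self.classes_)
        return proba[:, order] if not np.array_equal(order, [0, 1]) else proba

    def predict(self, X) -> np.ndarray:
        score = self.predict_score(X)
        return np.where(score >= self.threshold, POSITIVE_CLASS, 0)


def train_stacked(
    X,
    y,
    masks: Sequence,
    n_estimators: int = 100,
    random_state: Optional[int] = None,
) -> StackedForestClassifier:
    """Fit a stacked model with one member per mask."""
    clf = StackedForestClassifier(
        masks=list(masks), n_estimators=n_estimators, random_state=random_state
    )
    return clf.fit(X, y)


def predict_score(model: StackedForestClassifier, X) -> np.ndarray:
    return model.predict_score(X)


def predict_label(model: StackedForestClassifier, X) -> np.ndarray:
    return model.predict(X)


def save_model(model: StackedForestClassifier, path, extractor=None,
               extras: Optional[dict] = None) -> None:
    """Persist the model (plus optional fitted extractor) with the
    schema hash, masks and seed for provenance."""
    check_is_fitted(model, "members_")
    archive = {
        "format": "lncstack-stacked-model",
        "schema_hash": feature_schema().schema_hash,
        "masks": [mask.copy() for mask, _ in model.members_],
        "seed": model.random_state,
        "model": model,
        "extractor": extractor,
        "extras": extras or {},
    }
    joblib.dump(archive, path)


def load_model(path, expect_schema_hash: Optional[str] = None):
    """Load a model archive, verifying the feature-schema hash.

    Returns (model, extractor, archive-dict).
    """
    archive = joblib.load(path)
    if not isinstance(archive, dict) or archive.get("format") != \
            "lncstack-stacked-model":
        raise ValueError("not a lncstack model archive")
    expected = expect_schema_hash or feature_schema().schema_hash
    if archive["schema_hash"] != expected:
        raise ValueError("model was trained against a different feature schema")
    return archive["model"], archive.get("extractor"), archive
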