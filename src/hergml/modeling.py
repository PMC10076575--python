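"""Random-Forest classification over any feature assembly.

Models are binary binder / non-binder classifiers with 100 trees of
unlimited depth by default.  The module also provides seeded stratified
ten-fold cross-validation, a MaxMin diversity split on fingerprint
Tanimoto distance, and minimum-vote consensus prediction across several
models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .evaluation import BINDER, NON_BINDER, EvaluationReport, evaluate, _as_binary
from .lb_features import FeatureMatrix, bulk_tanimoto

PROBABILITY_TIE = 0.5  # probability exactly 0.5 -> binder (favor sensitivity)


@dataclass(frozen=True)
class ModelSpec:
    """Random-Forest settings: ``n_trees`` estimators, ``max_depth`` with
    0 meaning unlimited, and the training seed."""

    n_trees: int = 100
    max_depth: int = 0
    seed: int = 0
    positive_class: str = BINDER

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0 (0 = unlimited)")


@dataclass
class ModelBundle:
    """A fitted classifier plus everything needed to apply it safely:
    the exact feature schema, the training fingerprints (for similarity-
    based applicability assessment) and optional AD reference statistics."""

    classifier: RandomForestClassifier
    feature_names: list[str]
    provenance: dict[str, str]
    spec: ModelSpec
    training_fingerprints: np.ndarray | None = None
    ad_reference: object | None = None

    @property
    def feature_importances(self) -> pd.Series:
        """Mean impurity decrease per feature."""
        return pd.Series(
            self.classifier.feature_importances_, index=self.feature_names
        ).sort_values(ascending=False)

    def save(self, path) -> None:
        path = Path(path)
        joblib.dump(self, path)
        sidecar = {
            "feature_names": self.feature_names,
            "provenance": self.provenance,
            "spec": {
                "n_trees": self.spec.n_trees,
                "max_depth": self.spec.max_depth,
                "seed": self.spec.seed,
            },
        }
        path.with_suffix(path.suffix + ".schema.json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @staticmethod
    def load(path) -> "ModelBundle":
        return joblib.load(path)


def _check_matrix(features: FeatureMatrix) -> pd.DataFrame:
    df = features.values if isinstance(features, FeatureMatrix) else features
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in features: {bad[:5]}")
    return df


def train(
    features: FeatureMatrix,
    labels: Sequence,
    spec: ModelSpec = ModelSpec(),
    training_fingerprints: np.ndarray | None = None,
    ad_reference=None,
) -> ModelBundle:
    """Fit a Random Forest on a feature matrix.

    Deterministic given ``spec.seed``.  Raises if only one class is
    present or features contain missing values.
    """
    df = _check_matrix(features)
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if len(y) != len(df):
        raise ValueError("label / feature row count mismatch")
    clf = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_depth=None if spec.max_depth == 0 else spec.max_depth,
        random_state=spec.seed,
        n_jobs=1,
    )
    clf.fit(df.to_numpy(dtype=float), y)
    prov = features.provenance if isinstance(features, FeatureMatrix) else {}
    return ModelBundle(
        classifier=clf,
        feature_names=list(df.columns),
        provenance=dict(prov),
        spec=spec,
        training_fingerprints=training_fingerprints,
        ad_reference=ad_reference,
    )


def predict(bundle: ModelBundle, features: FeatureMatrix) -> pd.DataFrame:
    """Per-compound (label, binder probability).

    The input columns must match the bundle's schema exactly as a set
    (order is normalised internally); mismatches raise with the missing /
    extra column names.  Probability >= 0.5 maps to binder.
    """
    df = _check_matrix(features)
    have, want = set(df.columns), set(bundle.feature_names)
    if have != want:
        missing = sorted(want - have)
        extra = sorted(have - want)
        raise ValueError(
            f"feature schema mismatch: missing={missing[:5]}, extra={extra[:5]}"
        )
    df = df[bundle.feature_names]
    proba = bundle.classifier.predict_proba(df.to_numpy(dtype=float))
    binder_col = int(np.flatnonzero(bundle.classifier.classes_ == 1)[0])
    p = proba[:, binder_col]
    labels = np.where(p >= PROBABILITY_TIE, BINDER, NON_BINDER)
    return pd.DataFrame(
        {"label": labels, "probability": p}, index=df.index
    )


def ten_fold_cv(
    features: FeatureMatrix,
    labels: Sequence,
    spec: ModelSpec = ModelSpec(),
    seed: int = 0,
    n_folds: int = 10,
    return_predictions: bool = False,
):
    """Stratified ten-fold cross-validation.

    Out-of-fold predictions are pooled over all folds and scored once, so
    every row contributes exactly one held-out prediction.
    """
    df = _check_matrix(features)
    y = _as_binary(labels)
    if len(y) < n_folds:
        raise ValueError(f"need at least {n_folds} rows for {n_folds}-fold CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    X = df.to_numpy(dtype=float)
    oof_label = np.empty(len(y), dtype=object)
    oof_prob = np.full(len(y), np.nan)
    for train_idx, test_idx in skf.split(X, y):
        clf = RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_depth=None if spec.max_depth == 0 else spec.max_depth,
            random_state=spec.seed,
            n_jobs=1,
        )
        clf.fit(X[train_idx], y[train_idx])
        binder_col = int(np.flatnonzero(clf.classes_ == 1)[0])
        p = clf.predict_proba(X[test_idx])[:, binder_col]
        oof_prob[test_idx] = p
        oof_label[test_idx] = np.where(p >= PROBABILITY_TIE, BINDER, NON_BINDER)
    truth = np.where(y == 1, BINDER, NON_BINDER)
    report = evaluate(truth, oof_label, oof_prob)
    if return_predictions:
        preds = pd.DataFrame(
            {"truth": truth, "label": oof_label, "probability": oof_prob},
            index=df.index,
        )
        return report, preds
    return report


def diversity_split(
    compound_ids: Sequence[str],
    fingerprints: np.ndarray,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """MaxMin diversity split on Tanimoto distance.

    The first test compound is picked at random (seeded); the test
    partition is then filled by repeatedly adding the compound whose
    minimum Tanimoto distance to the already-picked set is largest (ties
    by input order).  The picked set becomes the test partition, the rest
    the training partition.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    ids = list(map(str, compound_ids))
    fps = np.asarray(fingerprints).astype(bool)
    n = len(ids)
    if fps.shape[0] != n:
        raise ValueError("fingerprint / id count mismatch")
    n_test = max(1, int(round(test_fraction * n)))
    if n_test >= n:
        n_test = n - 1
    rng = np.random.default_rng(seed)
    anchor = int(rng.integers(n))
    picked: list[int] = [anchor]
    picked_mask = np.zeros(n, dtype=bool)
    picked_mask[anchor] = True
    min_dist = 1.0 - bulk_tanimoto(fps[anchor], fps)
    for _ in range(n_test - 1):
        cand = np.where(picked_mask, -np.inf, min_dist)
        j = int(np.argmax(cand))  # argmax takes the first on ties
        picked.append(j)
        picked_mask[j] = True
        min_dist = np.minimum(min_dist, 1.0 - bulk_tanimoto(fps[j], fps))
    test_ids = [ids[j] for j in sorted(picked)]
    train_ids = [ids[j] for j in range(n) if not picked_mask[j]]
    return train_ids, test_ids


def consensus_predict(votes: Sequence, min_votes: int = 3) -> str:
    """Minimum-vote consensus: binder iff at least ``min_votes`` of the
    individual model votes are binder."""
    if len(votes) == 0:
        raise ValueError("need at least one vote")
    n_binder = int(np.sum(_as_binary(list(votes))))
    return BINDER if n_binder >= min_votes else NON_BINDER


def consensus_predict_table(
    vote_table: pd.DataFrame, min_votes: int = 3
) -> pd.Series:
    """Row-wise consensus over a compounds x models vote table."""
    return vote_table.apply(
        lambda row: consensus_predict(list(row), min_votes), axis=1
    )


def evaluate_on(
    bundle: ModelBundle, features: FeatureMatrix, truth: Sequence
) -> EvaluationReport:
    """Predict and score a labeled set in one step."""
    preds = predict(bundle, features)
    return evaluate(truth, preds["label"].to_numpy(), preds["probability"].to_numpy())
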