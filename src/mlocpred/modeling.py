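"""Unified multiclass classifier suite, grid search, stacking, persistence.

A single model is fitted over all five locales (no one-vs-rest
decomposition).  Two gradient-boosted tree families are exposed behind a
common interface (``gbdt_lgbm`` backed by LightGBM, ``gbdt_xgb`` backed
by XGBoost), alongside a decision tree, Gaussian naive Bayes, a
multilayer perceptron, and a stacking fusion of the two boosters whose
meta-classifier (default: multinomial logistic regression) is trained on
out-of-fold class probabilities.

End-to-end pipelines (encode -> select -> normalize -> fit) are built
with :func:`fit_pipeline`; the resulting :class:`TrainedModel` carries
its full preprocessing chain so inference on raw sequences reproduces
training-time preprocessing exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.base import BaseEstimator, clone
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import StackingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from mlocpred import __version__
from mlocpred.encoders import FeatureMatrix, encode_dataset, normalize_groups
from mlocpred.featureprep import (
    Normalizer,
    PCAReduction,
    SelectionReport,
    apply_normalizer,
    drop_collinear_features,
    drop_constant_features,
    fit_normalizer,
    merge_reports,
    pca_reduce,
)
from mlocpred.seqio import LOCALES, LabeledRecord, NucleotideSequence

logger = logging.getLogger(__name__)

GBDT_FAMILIES = ("gbdt_lgbm", "gbdt_xgb")
FAMILIES = GBDT_FAMILIES + ("decision_tree", "gaussian_nb", "mlp", "stack")


@dataclass(frozen=True)
class ModelSpec:
    """One classifier configuration.

    ``hyperparameters`` are passed through to the backing estimator; the
    special key ``feature_subset`` (list of column indices) restricts a
    member to a column slice, which is useful for ablations and for
    building deliberately complementary stacking members.
    """

    family: str
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    random_seed: int = 42

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; valid: {FAMILIES}"
            )


#: Default hyperparameter grids per family, used when grid_search is
#: called without an explicit grid.  Deliberately small: the original
#: study does not publish its grids.
DEFAULT_GRIDS: dict[str, dict[str, list[Any]]] = {
    "gbdt_lgbm": {"n_estimators": [100, 300], "num_leaves": [31, 63]},
    "gbdt_xgb": {"n_estimators": [100, 300], "max_depth": [4, 6]},
    "decision_tree": {"max_depth": [None, 8, 16]},
    "gaussian_nb": {},
    "mlp": {"hidden_layer_sizes": [(64,), (128,)], "alpha": [1e-4, 1e-3]},
}


def build_estimator(spec: ModelSpec) -> BaseEstimator:
    """Instantiate the sklearn-compatible estimator for a spec.

    Estimators are configured single-threaded and fully seeded so that
    fits are reproducible.
    """
    params = dict(spec.hyperparameters)
    subset = params.pop("feature_subset", None)
    family = spec.family
    if family == "gbdt_lgbm":
        est: BaseEstimator = LGBMClassifier(
            n_estimators=params.pop("n_estimators", 200),
            learning_rate=params.pop("learning_rate", 0.1),
            num_leaves=params.pop("num_leaves", 31),
            random_state=spec.random_seed,
            n_jobs=1,
            verbose=-1,
            **params,
        )
    elif family == "gbdt_xgb":
        est = XGBClassifier(
            n_estimators=params.pop("n_estimators", 200),
            learning_rate=params.pop("learning_rate", 0.1),
            max_depth=params.pop("max_depth", 6),
            tree_method="hist",
            random_state=spec.random_seed,
            n_jobs=1,
            verbosity=0,
            **params,
        )
    elif family == "decision_tree":
        est = DecisionTreeClassifier(random_state=spec.random_seed, **params)
    elif family == "gaussian_nb":
        est = GaussianNB(**params)
    elif family == "mlp":
        est = MLPClassifier(
            hidden_layer_sizes=params.pop("hidden_layer_sizes", (128,)),
            max_iter=params.pop("max_iter", 400),
            random_state=spec.random_seed,
            **params,
        )
    else:
        raise ValueError(f"family {family!r} has no direct estimator")
    if subset is not None:
        est = Pipeline(
            [
                (
                    "subset",
                    ColumnTransformer([("keep", "passthrough", list(subset))]),
                ),
                ("est", est),
            ]
        )
    return est


@dataclass
class TrainedModel:
    """A fitted classifier bundled with its preprocessing chain.

    ``class_labels`` fixes the probability-column order; internally
    labels are integer-encoded in that order.  ``feature_names`` is the
    post-selection column list the estimator was fitted on.
    """

    spec: ModelSpec
    estimator: BaseEstimator
    class_labels: list[str]
    feature_names: list[str]
    normalizer: Normalizer | None = None
    selection: SelectionReport | None = None
    groups: tuple[str, ...] | None = None
    pca: PCAReduction | None = None
    version: str = __version__

    def _check_matrix(self, m: FeatureMatrix) -> np.ndarray:
        if list(m.feature_names) != list(self.feature_names):
            raise ValueError(
                "feature-name mismatch: matrix columns differ from the "
                "columns the model was trained on"
            )
        return m.values

    def predict_matrix(self, m: FeatureMatrix) -> pd.DataFrame:
        """Predict from an already preprocessed matrix.

        Returns a frame with ``predicted_label`` and one probability
        column per class (``p_<label>``), rows summing to 1.
        """
        X = self._check_matrix(m)
        proba = np.asarray(self.estimator.predict_proba(X), dtype=float)
        order = [list(self.estimator.classes_).index(i) for i in range(len(self.class_labels))]
        proba = proba[:, order]
        proba = proba / proba.sum(axis=1, keepdims=True)  # float32 backends
        pred_idx = np.argmax(proba, axis=1)  # argmax breaks ties by class order
        out = pd.DataFrame(
            proba, columns=[f"p_{c}" for c in self.class_labels], index=m.sample_ids
        )
        out.insert(0, "predicted_label", [self.class_labels[i] for i in pred_idx])
        out.index.name = "id"
        return out

    def preprocess_sequences(
        self, sequences: Sequence[NucleotideSequence]
    ) -> tuple[FeatureMatrix, list[tuple[str, str]]]:
        """Apply the stored encode -> select -> normalize chain.

        Returns the preprocessed matrix for the sequences that pass the
        encoder preconditions plus a list of (id, reason) rejections.
        """
        if self.groups is None:
            raise ValueError("model was not trained from raw sequences")
        ok: list[NucleotideSequence] = []
        failures: list[tuple[str, str]] = []
        for s in sequences:
            try:
                encode_dataset([s], groups=self.groups)
            except ValueError as exc:
                failures.append((s.id, str(exc)))
            else:
                ok.append(s)
        if not ok:
            return (
                FeatureMatrix([], list(self.feature_names),
                              ["?"] * len(self.feature_names),
                              np.empty((0, len(self.feature_names)))),
                failures,
            )
        full = encode_dataset(ok, groups=self.groups)
        if self.pca is not None:
            kept = self.selection.kept if self.selection else full.feature_names
            m = full.select_columns(kept)
            m = apply_normalizer(self.normalizer, m) if self.normalizer else m
            scores = self.pca.pca.transform(m.values)[:, : self.pca.n_components]
            m = FeatureMatrix(
                sample_ids=list(m.sample_ids),
                feature_names=list(self.feature_names),
                feature_groups=["PCA"] * len(self.feature_names),
                values=scores,
            )
        else:
            m = full.select_columns(self.feature_names)
            if self.normalizer is not None:
                m = apply_normalizer(self.normalizer, m)
        return m, failures

    def predict_sequences(
        self, sequences: Sequence[NucleotideSequence]
    ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
        """Predict raw sequences; per-record failures do not abort the rest."""
        m, failures = self.preprocess_sequences(sequences)
        if m.n_samples == 0:
            empty = pd.DataFrame(
                columns=["predicted_label"] + [f"p_{c}" for c in self.class_labels]
            )
            return empty, failures
        return self.predict_matrix(m), failures

    def feature_importances(self) -> pd.Series | None:
        """Model-native global feature importances, if the family has any."""
        est = self.estimator
        if hasattr(est, "feature_importances_"):
            return pd.Series(
                est.feature_importances_, index=self.feature_names
            ).sort_values(ascending=False)
        return None

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, TrainedModel):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model


def _encode_labels(labels: Sequence[str], class_labels: Sequence[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_labels)}
    unknown = sorted(set(labels) - set(index))
    if unknown:
        raise ValueError(f"labels outside the class list: {unknown}")
    return np.array([index[l] for l in labels])


def train_model(
    spec: ModelSpec,
    m: FeatureMatrix,
    labels: Sequence[str],
    class_labels: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit one unified multiclass model on a cleaned, normalized matrix."""
    if m.n_samples != len(labels):
        raise ValueError("row count does not match label count")
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 classes to train")
    if not np.all(np.isfinite(m.values)):
        raise ValueError("matrix contains NaN or infinite values")
    if class_labels is None:
        class_labels = sorted(set(labels))
    y = _encode_labels(labels, class_labels)
    est = build_estimator(spec)
    est.fit(m.values, y)
    return TrainedModel(
        spec=spec,
        estimator=est,
        class_labels=list(class_labels),
        feature_names=list(m.feature_names),
    )


def grid_search(
    family: str,
    m: FeatureMatrix,
    labels: Sequence[str],
    grid: Mapping[str, Sequence[Any]] | None = None,
    folds: int = 5,
    seed: int = 42,
    scoring: str = "accuracy",
) -> tuple[ModelSpec, pd.DataFrame]:
    """Exhaustive hyperparameter search by stratified k-fold mean score.

    Ties are broken by enumeration order (the first combination reaching
    the best mean score wins).  Returns the best spec plus the full
    per-combination score table.
    """
    if grid is None:
        grid = DEFAULT_GRIDS.get(family)
    if grid is None:
        raise ValueError(f"no default grid for family {family!r}")
    combos = list(ParameterGrid(dict(grid))) if grid else [{}]
    if not combos:
        raise ValueError("empty hyperparameter grid")
    class_labels = sorted(set(labels))
    y = _encode_labels(labels, class_labels)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    best: tuple[float, int] | None = None
    for i, params in enumerate(combos):
        spec = ModelSpec(family=family, hyperparameters=params, random_seed=seed)
        scores = cross_val_score(
            build_estimator(spec), m.values, y, cv=cv, scoring=scoring, n_jobs=1
        )
        mean = float(scores.mean())
        rows.append({"combination": i, "params": dict(params), "mean_score": mean})
        if best is None or mean > best[0]:
            best = (mean, i)
    table = pd.DataFrame(rows)
    best_spec = ModelSpec(
        family=family, hyperparameters=combos[best[1]], random_seed=seed
    )
    return best_spec, table


def train_stack(
    member_specs: Sequence[ModelSpec],
    m: FeatureMatrix,
    labels: Sequence[str],
    meta_spec: BaseEstimator | None = None,
    folds: int = 5,
    seed: int = 42,
    class_labels: Sequence[str] | None = None,
) -> TrainedModel:
    """Stacking fusion of the gradient-boosting members.

    Member class probabilities are produced out-of-fold (stratified
    ``folds``-fold) so the meta-classifier never sees leakage from a
    member fitted on the same rows.  The default meta-classifier is a
    multinomial logistic regression on the concatenated member
    probabilities.
    """
    if len(member_specs) < 2:
        raise ValueError("stacking needs at least 2 member specs")
    if class_labels is None:
        class_labels = sorted(set(labels))
    y = _encode_labels(labels, class_labels)
    meta = meta_spec if meta_spec is not None else LogisticRegression(
        max_iter=2000, random_state=seed
    )
    members = [
        (f"{s.family}_{i}", build_estimator(s)) for i, s in enumerate(member_specs)
    ]
    stack = StackingClassifier(
        estimators=members,
        final_estimator=meta,
        stack_method="predict_proba",
        cv=StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed),
        n_jobs=1,
    )
    stack.fit(m.values, y)
    spec = ModelSpec(
        family="stack",
        hyperparameters={
            "members": [s.family for s in member_specs],
            "folds": folds,
        },
        random_seed=seed,
    )
    return TrainedModel(
        spec=spec,
        estimator=stack,
        class_labels=list(class_labels),
        feature_names=list(m.feature_names),
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the full encode -> reduce -> fit chain.

    ``selection`` chooses exactly one reduction path: ``"collinearity"``
    (constant-drop, |r| > threshold prune, z-score) or ``"pca"``
    (constant-drop, z-score, PCA at the variance target).
    """

    groups: tuple[str, ...] | None = None
    selection: str = "collinearity"
    collinearity_threshold: float = 0.98
    pca_variance: float = 0.95
    model: ModelSpec = field(default_factory=lambda: ModelSpec("gbdt_lgbm"))
    stack_members: tuple[ModelSpec, ...] = (
        ModelSpec("gbdt_lgbm"),
        ModelSpec("gbdt_xgb"),
    )

    def __post_init__(self) -> None:
        if self.selection not in ("collinearity", "pca"):
            raise ValueError("selection must be 'collinearity' or 'pca'")


def fit_pipeline(
    config: PipelineConfig,
    records: Sequence[LabeledRecord],
    class_labels: Sequence[str] = LOCALES,
) -> TrainedModel:
    """Encode, clean, normalize and fit on labeled records."""
    groups = normalize_groups(config.groups)
    full = encode_dataset(records, groups=groups)
    labels = [r.label for r in records]
    present = [c for c in class_labels if c in set(labels)]

    m1, rep_const = drop_constant_features(full)
    if config.selection == "collinearity":
        m2, rep_coll = drop_collinear_features(
            m1, threshold=config.collinearity_threshold
        )
        selection = merge_reports(rep_const, rep_coll)
        nz = fit_normalizer(m2)
        m3 = apply_normalizer(nz, m2)
        pca = None
        feature_names = list(m3.feature_names)
    else:
        selection = rep_const
        nz = fit_normalizer(m1)
        mz = apply_normalizer(nz, m1)
        pca = pca_reduce(mz, variance_target=config.pca_variance)
        m3 = pca.reduced
        feature_names = list(m3.feature_names)

    if config.model.family == "stack":
        model = train_stack(
            list(config.stack_members),
            m3,
            labels,
            seed=config.model.random_seed,
            class_labels=present,
        )
    else:
        model = train_model(config.model, m3, labels, class_labels=present)
    model.normalizer = nz
    model.selection = selection
    model.groups = groups
    model.pca = pca
    model.feature_names = feature_names
    return model
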