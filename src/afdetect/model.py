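"""Gradient-boosted four-class rhythm model with importance-based selection.

Training follows a five-stage recipe: fit an ensemble on all 31 features,
run stratified 20-fold cross-validation with early stopping on the
validation Matthews correlation coefficient, rank features by ensemble
importance, keep the top k (default 17), and retrain the final model on the
selection with the iteration count fixed to the median per-fold best
iteration.

The backend is LightGBM.  Reference hyperparameters that have a LightGBM
equivalent are mapped directly; ordered-boosting-specific knobs
(bagging_temperature, random_strength, Newton leaf estimation) have no
LightGBM counterpart, are warned about at train time and recorded in the
bundle metadata so the gap is auditable.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .containers import CLASS_ORDER, EcgRecording, RhythmLabel
from .features import FEATURE_NAMES, KsReference, extract_features

logger = logging.getLogger(__name__)

#: Reference hyperparameters with no LightGBM equivalent.
UNSUPPORTED_BY_BACKEND = ("bagging_temperature", "random_strength", "leaf_estimation")


@dataclass(frozen=True)
class HyperParams:
    """Training hyperparameters; defaults follow the reference configuration."""

    learning_rate: float = 0.1
    iterations: int = 276
    early_stopping_rounds: int = 20
    depth: int = 8
    l2_leaf_reg: float = 3.0
    bagging_temperature: float = 0.7
    random_strength: float = 0.2
    leaf_estimation: str = "Newton"
    loss: str = "multiclass"
    eval_metric: str = "mcc"
    random_seed: int = 0


@dataclass
class CvResult:
    """Per-fold validation MCC and best iteration, with summaries."""

    fold_mcc: List[float]
    fold_best_iteration: List[int]

    @property
    def mean_mcc(self) -> float:
        return float(np.mean(self.fold_mcc))

    @property
    def sd_mcc(self) -> float:
        return float(np.std(self.fold_mcc, ddof=1)) if len(self.fold_mcc) > 1 else 0.0

    @property
    def median_best_iteration(self) -> int:
        return int(np.median(self.fold_best_iteration))


def _validate_table(features: pd.DataFrame, labels: Sequence) -> np.ndarray:
    if not np.all(np.isfinite(features.to_numpy(dtype=float))):
        raise ValueError("feature table contains NaN or Inf")
    y = np.asarray([RhythmLabel(l).value for l in labels])
    if len(y) != len(features):
        raise ValueError("features and labels have different lengths")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes to train")
    return y


_warned_unsupported = False


def _make_backend(params: HyperParams, n_estimators: Optional[int] = None) -> lgb.LGBMClassifier:
    global _warned_unsupported
    if not _warned_unsupported:
        for name in UNSUPPORTED_BY_BACKEND:
            logger.warning(
                "hyperparameter %r=%r has no LightGBM equivalent and is ignored "
                "(recorded in bundle metadata)", name, getattr(params, name),
            )
        _warned_unsupported = True
    return lgb.LGBMClassifier(
        learning_rate=params.learning_rate,
        n_estimators=n_estimators or params.iterations,
        max_depth=params.depth,
        num_leaves=2 ** params.depth,
        reg_lambda=params.l2_leaf_reg,
        random_state=params.random_seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbosity=-1,
        metric="None",
    )


def _mcc_eval(y_true: np.ndarray, y_prob: np.ndarray):
    """Custom LightGBM eval: multiclass MCC on argmax predictions."""
    pred = np.argmax(y_prob, axis=1) if y_prob.ndim == 2 else (y_prob > 0.5).astype(int)
    return "mcc", matthews_corrcoef(y_true, pred), True


def train(features: pd.DataFrame, labels: Sequence, params: HyperParams) -> lgb.LGBMClassifier:
    """Fit the multiclass ensemble on the full table (no early stopping)."""
    y = _validate_table(features, labels)
    model = _make_backend(params)
    model.fit(features, y)
    return model


def cross_validate(
    features: pd.DataFrame,
    labels: Sequence,
    params: HyperParams,
    n_folds: int = 20,
    seed: int = 0,
) -> CvResult:
    """Stratified k-fold CV with early stopping on each fold's MCC.

    Each item is used for validation exactly once.  Classes with fewer than
    ``n_folds`` members are stratified best-effort (sklearn emits a warning).
    """
    y = _validate_table(features, labels)
    if len(y) < n_folds:
        raise ValueError(f"need >= {n_folds} items for {n_folds}-fold CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_mcc, fold_best = [], []
    for tr_idx, val_idx in skf.split(features, y):
        model = _make_backend(params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=UserWarning)
            model.fit(
                features.iloc[tr_idx], y[tr_idx],
                eval_set=[(features.iloc[val_idx], y[val_idx])],
                eval_metric=_mcc_eval,
                callbacks=[lgb.early_stopping(params.early_stopping_rounds,
                                              verbose=False)],
            )
        best = model.best_iteration_ or params.iterations
        pred = model.predict(features.iloc[val_idx])
        fold_mcc.append(float(matthews_corrcoef(y[val_idx], pred)))
        fold_best.append(int(best))
    return CvResult(fold_mcc=fold_mcc, fold_best_iteration=fold_best)


def rank_features(model: lgb.LGBMClassifier, feature_manifest: Sequence[str]) -> List[str]:
    """Manifest sorted by ensemble gain importance, descending; ties broken
    by manifest order."""
    check_is_fitted(model, "booster_")
    imp = model.booster_.feature_importance(importance_type="gain")
    if len(imp) != len(feature_manifest):
        raise ValueError("manifest length does not match the trained model")
    order = np.argsort(-np.asarray(imp, dtype=float), kind="stable")
    return [feature_manifest[i] for i in order]


def select_top_k(ranking: Sequence[str], k: int = 17) -> List[str]:
    """First k names of the importance ranking."""
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k={k} out of range [1, {len(ranking)}]")
    return list(ranking[:k])


def importance_curve(
    features: pd.DataFrame,
    labels: Sequence,
    params: HyperParams,
    ranking: Sequence[str],
    ks: Sequence[int],
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated MCC for each top-k feature subset (one row per k)."""
    rows = []
    for k in ks:
        sel = select_top_k(ranking, k)
        cv = cross_validate(features[sel], labels, params, n_folds=n_folds, seed=seed)
        rows.append({"k": int(k), "mcc": cv.mean_mcc})
    return pd.DataFrame(rows)


@dataclass
class ModelBundle:
    """Trained ensemble plus everything needed to classify a raw recording."""

    booster: lgb.Booster
    classes: List[str]  # label order of the booster's probability columns
    params: HyperParams
    feature_manifest: List[str]
    importance_ranking: List[str]
    selected_features: List[str]
    ks_reference: KsReference
    class_order: Tuple[RhythmLabel, ...] = CLASS_ORDER
    backend_info: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.selected_features) <= set(self.feature_manifest):
            raise ValueError("selected_features must be a subset of the manifest")
        if sorted(self.importance_ranking) != sorted(self.feature_manifest):
            raise ValueError("ranking must be a permutation of the manifest")

    def predict_proba_row(self, row: Dict[str, float]) -> Dict[str, float]:
        missing = [f for f in self.selected_features if f not in row]
        if missing:
            raise ValueError(f"missing selected features: {missing}")
        x = np.asarray([[float(row[f]) for f in self.selected_features]])
        out = np.atleast_1d(self.booster.predict(x)[0])
        if out.size == 1 and len(self.classes) == 2:  # binary booster
            out = np.array([1.0 - out[0], out[0]])
        return dict(zip(self.classes, (float(p) for p in out)))

    def predict_recording(
        self, recording: EcgRecording
    ) -> Tuple[RhythmLabel, Dict[str, float]]:
        row = extract_features(recording, self.ks_reference)
        return self.predict_row(row)

    def predict_row(self, row: Dict[str, float]) -> Tuple[RhythmLabel, Dict[str, float]]:
        probs = self.predict_proba_row(row)
        label = RhythmLabel(max(probs, key=probs.get))
        return label, probs

    # -- serialization: a directory with model.txt, manifest.json, ks_reference.csv
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(str(d / "model.txt"))
        manifest = {
            "classes": self.classes,
            "hyperparams": asdict(self.params),
            "feature_manifest": self.feature_manifest,
            "importance_ranking": self.importance_ranking,
            "selected_features": self.selected_features,
            "class_order": [c.value for c in self.class_order],
            "backend": self.backend_info,
            "ks_reference_provenance": self.ks_reference.provenance,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        with open(d / "ks_reference.csv", "w") as fh:
            fh.write("normalized_drr\n")
            for v in self.ks_reference.values:
                fh.write(f"{v:.12g}\n")

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        booster = lgb.Booster(model_file=str(d / "model.txt"))
        ref_vals = np.loadtxt(d / "ks_reference.csv", skiprows=1, ndmin=1)
        return cls(
            booster=booster,
            classes=manifest["classes"],
            params=HyperParams(**manifest["hyperparams"]),
            feature_manifest=manifest["feature_manifest"],
            importance_ranking=manifest["importance_ranking"],
            selected_features=manifest["selected_features"],
            ks_reference=KsReference(
                ref_vals, provenance=manifest.get("ks_reference_provenance", "")
            ),
            backend_info=manifest.get("backend", {}),
        )


def retrain_final(
    features: pd.DataFrame,
    labels: Sequence,
    params: HyperParams,
    selected_features: Sequence[str],
    cv: CvResult,
    ks_reference: KsReference,
    importance_ranking: Optional[Sequence[str]] = None,
) -> ModelBundle:
    """Train the final model on the selected features.

    The iteration count is fixed to the median per-fold best iteration from
    cross-validation (no early stopping at this stage).
    """
    if not selected_features:
        raise ValueError("selection is empty")
    missing = [f for f in selected_features if f not in features.columns]
    if missing:
        raise ValueError(f"selected features absent from table: {missing}")
    y = _validate_table(features, labels)
    model = _make_backend(params, n_estimators=cv.median_best_iteration)
    model.fit(features[list(selected_features)], y)
    ranking = list(importance_ranking) if importance_ranking is not None else \
        list(features.columns)
    return ModelBundle(
        booster=model.booster_,
        classes=[str(c) for c in model.classes_],
        params=params,
        feature_manifest=list(features.columns),
        importance_ranking=ranking,
        selected_features=list(selected_features),
        ks_reference=ks_reference,
        backend_info={
            "backend": "lightgbm",
            "version": lgb.__version__,
            "unsupported_params": {
                name: getattr(params, name) for name in UNSUPPORTED_BY_BACKEND
            },
        },
    )


def predict(
    bundle: ModelBundle, item: Union[EcgRecording, Dict[str, float], pd.Series]
) -> Tuple[RhythmLabel, Dict[str, float]]:
    """Classify a raw recording or an extracted feature row."""
    if isinstance(item, EcgRecording):
        return bundle.predict_recording(item)
    if isinstance(item, pd.Series):
        item = item.to_dict()
    return bundle.predict_row(item)


class BoostedRhythmClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn classifier wrapping the full train/select/retrain recipe.

    ``fit`` accepts the 31-column feature DataFrame (as produced by
    :class:`afdetect.features.EcgFeatureExtractor`) and rhythm labels, and
    runs: full-feature training, stratified ``n_folds``-fold CV with early
    stopping on validation MCC, gain-importance ranking, top-``k_select``
    selection, and a final refit on the selection with iterations fixed to
    the median CV best iteration.

    Fitted attributes: ``classes_``, ``ranking_``, ``selected_features_``,
    ``cv_result_``, ``feature_importances_``, ``booster_``.
    """

    def __init__(
        self,
        learning_rate: float = 0.1,
        iterations: int = 276,
        early_stopping_rounds: int = 20,
        depth: int = 8,
        l2_leaf_reg: float = 3.0,
        bagging_temperature: float = 0.7,
        random_strength: float = 0.2,
        k_select: int = 17,
        n_folds: int = 20,
        random_seed: int = 0,
    ):
        self.learning_rate = learning_rate
        self.iterations = iterations
        self.early_stopping_rounds = early_stopping_rounds
        self.depth = depth
        self.l2_leaf_reg = l2_leaf_reg
        self.bagging_temperature = bagging_temperature
        self.random_strength = random_strength
        self.k_select = k_select
        self.n_folds = n_folds
        self.random_seed = random_seed

    def _hyperparams(self) -> HyperParams:
        return HyperParams(
            learning_rate=self.learning_rate,
            iterations=self.iterations,
            early_stopping_rounds=self.early_stopping_rounds,
            depth=self.depth,
            l2_leaf_reg=self.l2_leaf_reg,
            bagging_temperature=self.bagging_temperature,
            random_strength=self.random_strength,
            random_seed=self.random_seed,
        )

    def fit(self, X: pd.DataFrame, y: Sequence, ks_reference: Optional[KsReference] = None):
        X = pd.DataFrame(X)
        params = self._hyperparams()
        full_model = train(X, y, params)
        self.feature_importances_ = np.asarray(
            full_model.booster_.feature_importance(importance_type="gain"), dtype=float
        )
        self.ranking_ = rank_features(full_model, list(X.columns))
        k = min(self.k_select, len(self.ranking_))
        self.selected_features_ = select_top_k(self.ranking_, k)
        self.cv_result_ = cross_validate(
            X, y, params, n_folds=min(self.n_folds, len(X)), seed=self.random_seed
        )
        if ks_reference is None:
            from .features import default_ks_reference

            ks_reference = default_ks_reference()
        self.bundle_ = retrain_final(
            X, y, params, self.selected_features_, self.cv_result_,
            ks_reference, importance_ranking=self.ranking_,
        )
        self.booster_ = self.bundle_.booster
        self.classes_ = np.asarray(self.bundle_.classes)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "bundle_")
        X = pd.DataFrame(X)
        cols = self.bundle_.selected_features
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise ValueError(f"missing selected features: {missing}")
        probs = self.booster_.predict(X[cols].to_numpy(dtype=float))
        if probs.ndim == 1:  # binary booster emits P(class 1) only
            probs = np.column_stack([1.0 - probs, probs])
        return probs

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]
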