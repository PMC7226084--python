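"""Step 1: balanced binary HFO-vs-background classification.

Five algorithm families are compared: LDA (no hyperparameters), l2 logistic
regression and linear SVM (penalty/cost on a 13-point log grid over
10^-3 … 10^3), KNN (k = 1…20) and random forest (trees x depth x split x leaf
grid).  The protocol per subject and window length:

1. undersample the background class to the HFO count (`balance_binary`),
2. hold out a stratified 30% tuning set; grid-search hyperparameters by mean
   AUC under internal 3-fold CV, ties broken toward the simpler model,
3. stratified 5-fold CV on the remaining 70%, standardizing features on the
   training folds only; report per-fold AUC, sensitivity and specificity.

A learning-curve helper retrains each family on growing stratified subsets
under 10-fold CV, recording train/validation AUC and wall-clock fit time.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .errors import (ConfigurationError, ImbalanceError,
                     ModelCompatibilityError, SizeError, StratificationError)
from .features import WindowSpec, extract_features
from .io import FEATURE_COLUMNS, Recording

ALGORITHM_FAMILIES = ("lda", "lr", "svm", "knn", "rf")

#: 13 points, decade + half-decade steps over exponents -3 … 3.
LOG_GRID = tuple(float(10.0 ** e) for e in np.arange(-3.0, 3.5, 0.5))

LEARNING_CURVE_SIZES = (720, 1440, 2520, 3240)


def hyperparameter_grid(family: str) -> list[dict]:
    """Candidate hyperparameters, ordered from simplest (most regularized,
    smoothest, smallest ensemble) to most complex; the tuner keeps the first
    best-scoring candidate, so ties resolve toward simplicity."""
    if family == "lda":
        return [{}]
    if family in ("lr", "svm"):
        return [{"C": c} for c in LOG_GRID]
    if family == "knn":
        return [{"n_neighbors": k} for k in range(20, 0, -1)]
    if family == "rf":
        return [{"n_estimators": n, "max_depth": d,
                 "min_samples_split": s, "min_samples_leaf": leaf}
                for n in (100, 200) for d in (5, 10, 20)
                for s in (10, 5, 2) for leaf in (4, 2, 1)]
    raise ConfigurationError(
        f"unknown algorithm family {family!r}; expected one of {ALGORITHM_FAMILIES}")


def make_estimator(family: str, params: dict, seed: int = 0) -> Pipeline:
    """A scaler + classifier pipeline, so standardization statistics always
    come from the data the classifier is fitted on."""
    if family == "lda":
        clf = LinearDiscriminantAnalysis()
    elif family == "lr":
        clf = LogisticRegression(max_iter=5000, **params)  # l2 penalty default
    elif family == "svm":
        clf = LinearSVC(**params)
    elif family == "knn":
        clf = KNeighborsClassifier(**params)
    elif family == "rf":
        clf = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    else:
        raise ConfigurationError(f"unknown algorithm family {family!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous decision scores, ``(n,)`` for binary, ``(n, k)`` otherwise."""
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        return proba[:, 1] if proba.shape[1] == 2 else proba
    return model.decision_function(X)


def _macro_ovr_auc(y_true: np.ndarray, scores: np.ndarray,
                   classes: np.ndarray) -> float:
    """Macro-averaged one-vs-rest AUC from arbitrary continuous scores
    (probabilities or margins; a class absent from y_true is skipped)."""
    aucs = []
    for j, cls in enumerate(classes):
        mask = y_true == cls
        if 0 < mask.sum() < len(y_true):
            aucs.append(roc_auc_score(mask, scores[:, j]))
    return float(np.mean(aucs))


@dataclass
class BinaryMetrics:
    """Per-fold AUC / sensitivity / specificity with means and SDs."""

    auc: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    confusions: list[np.ndarray] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean(self.sensitivity))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean(self.specificity))

    def summary(self) -> dict:
        return {
            "auc_mean": self.mean_auc, "auc_sd": float(np.std(self.auc)),
            "sensitivity_mean": self.mean_sensitivity,
            "sensitivity_sd": float(np.std(self.sensitivity)),
            "specificity_mean": self.mean_specificity,
            "specificity_sd": float(np.std(self.specificity)),
        }


# ---------------------------------------------------------------------------
# protocol steps


def balance_binary(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Random undersampling of the background class to the HFO count.

    All HFO rows (R, FR, FRonR collapsed to positive) are kept; exactly as
    many ``noHFO`` rows are drawn uniformly without replacement; the result is
    shuffled.
    """
    pos = table[table["label"] != "noHFO"]
    neg = table[table["label"] == "noHFO"]
    if len(pos) == 0:
        raise ImbalanceError("no HFO-labeled rows to balance against")
    if len(neg) < len(pos):
        raise ImbalanceError(
            f"cannot undersample: {len(neg)} noHFO rows < {len(pos)} HFO rows")
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(neg), size=len(pos), replace=False)
    out = pd.concat([pos, neg.iloc[np.sort(keep)]], ignore_index=True)
    return out.iloc[rng.permutation(len(out))].reset_index(drop=True)


def split_tuning_holdout(table: pd.DataFrame, fraction: float = 0.30,
                         seed: int = 0, stratify_on: str | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified (tuning, development) split; tuning gets ``fraction``.

    ``stratify_on`` defaults to the binary HFO indicator; pass ``"label"`` to
    stratify on the full class column (step 2).
    """
    if not 0 <= fraction < 1:
        raise ConfigurationError(f"holdout fraction must be in [0, 1), got {fraction}")
    if fraction == 0:
        return table.iloc[0:0], table
    strata = (table["label"] if stratify_on == "label"
              else (table["label"] != "noHFO"))
    counts = strata.value_counts()
    if (counts < 2).any():
        raise StratificationError(
            f"every class needs >= 2 rows to stratify; counts: {counts.to_dict()}")
    dev, tune = train_test_split(table, test_size=fraction, stratify=strata,
                                 random_state=seed)
    return tune.reset_index(drop=True), dev.reset_index(drop=True)


def _xy(table: pd.DataFrame, positive: bool = True
        ) -> tuple[np.ndarray, np.ndarray]:
    X = table[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = ((table["label"] != "noHFO").to_numpy().astype(int) if positive
         else table["label"].to_numpy())
    return X, y


def tune(family: str, tuning_table: pd.DataFrame, seed: int,
         folds: int = 3, multiclass: bool = False) -> tuple[dict, float]:
    """Exhaustive grid search scored by mean AUC under internal stratified
    ``folds``-fold CV on the tuning set; returns (params, best mean AUC).

    LDA has no grid and is returned untouched with score ``nan``.  KNN
    candidates whose ``k`` exceeds the training-fold size are skipped.
    """
    grid = hyperparameter_grid(family)
    if family == "lda":
        return {}, float("nan")
    X, y = _xy(tuning_table, positive=not multiclass)
    _, class_counts = np.unique(y, return_counts=True)
    if class_counts.min() < folds:
        raise StratificationError(
            f"tuning set class counts {class_counts.tolist()} cannot fill "
            f"{folds} stratified folds")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    min_train = len(y) - int(np.ceil(len(y) / folds))
    best_params, best_score = None, -np.inf
    for params in grid:
        if family == "knn" and params["n_neighbors"] > min_train:
            continue
        model = make_estimator(family, params, seed=seed)
        scores = []
        for tr, te in cv.split(X, y):
            m = clone(model).fit(X[tr], y[tr])
            s = _scores(m, X[te])
            if multiclass:
                scores.append(_macro_ovr_auc(y[te], s, m[-1].classes_))
            else:
                scores.append(roc_auc_score(y[te], s))
        score = float(np.mean(scores))
        if score > best_score:  # strict: first (simplest) winner is kept
            best_params, best_score = params, score
    if best_params is None:
        raise ConfigurationError(
            f"no feasible hyperparameter candidate for {family} at n={len(y)}")
    return best_params, best_score


def crossval_detect(dev_table: pd.DataFrame, family: str, params: dict,
                    folds: int = 5, seed: int = 0) -> BinaryMetrics:
    """Stratified k-fold CV of the binary detector on the development set."""
    X, y = _xy(dev_table, positive=True)
    _, counts = np.unique(y, return_counts=True)
    if len(counts) < 2 or counts.min() < folds:
        raise StratificationError(
            f"class counts {counts.tolist()} cannot fill {folds} stratified folds")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs, sens, spec, cms = [], [], [], []
    for tr, te in cv.split(X, y):
        model = make_estimator(family, params, seed=seed).fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[te], _scores(model, X[te])))
        cm = confusion_matrix(y[te], model.predict(X[te]), labels=[0, 1])
        (tn, fp), (fn, tp) = cm
        sens.append(tp / (tp + fn))
        spec.append(tn / (tn + fp))
        cms.append(cm)
    return BinaryMetrics(np.array(aucs), np.array(sens), np.array(spec), cms)


def learning_curve(dev_table: pd.DataFrame, family: str, params: dict,
                   sizes: tuple[int, ...] = LEARNING_CURVE_SIZES,
                   folds: int = 10, seed: int = 0) -> pd.DataFrame:
    """Train/validation AUC and fit time over growing stratified subsets.

    Each size is a stratified subsample of the development set evaluated by
    ``folds``-fold CV.  Fit times are reported, never asserted.
    """
    X, y = _xy(dev_table, positive=True)
    rows = []
    for size in sizes:
        if size > len(y):
            raise SizeError(f"requested size {size} > available rows {len(y)}")
        if size == len(y):
            Xs, ys = X, y
        else:
            Xs, _, ys, _ = train_test_split(X, y, train_size=size, stratify=y,
                                            random_state=seed)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        tr_auc, va_auc, fit_t = [], [], []
        for tr, te in cv.split(Xs, ys):
            model = make_estimator(family, params, seed=seed)
            t0 = time.perf_counter()
            model.fit(Xs[tr], ys[tr])
            fit_t.append(time.perf_counter() - t0)
            tr_auc.append(roc_auc_score(ys[tr], _scores(model, Xs[tr])))
            va_auc.append(roc_auc_score(ys[te], _scores(model, Xs[te])))
        rows.append({"size": size,
                     "train_auc_mean": float(np.mean(tr_auc)),
                     "train_auc_sd": float(np.std(tr_auc)),
                     "val_auc_mean": float(np.mean(va_auc)),
                     "val_auc_sd": float(np.std(va_auc)),
                     "fit_time_s": float(np.mean(fit_t))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trained-model bundle and deployment


@dataclass
class TrainedModel:
    """A fitted step-1 detector with the schema it expects."""

    family: str
    params: dict
    model: Pipeline
    window_ms: int
    feature_columns: list[str]
    seed: int
    metrics: BinaryMetrics | None = None


def train_detector(table: pd.DataFrame, family: str, seed: int,
                   tuning_fraction: float = 0.30, folds: int = 5
                   ) -> TrainedModel:
    """Full step-1 protocol on one subject's feature table: balance, hold out
    the tuning set, tune, cross-validate, then refit on the development set."""
    window_ms = int(table["window_ms"].iloc[0])
    balanced = balance_binary(table, seed=seed)
    tuning, dev = split_tuning_holdout(balanced, seed=seed)
    params, _ = tune(family, tuning, seed=seed)
    metrics = crossval_detect(dev, family, params, folds=folds, seed=seed)
    X, y = _xy(dev, positive=True)
    model = make_estimator(family, params, seed=seed).fit(X, y)
    return TrainedModel(family=family, params=params, model=model,
                        window_ms=window_ms,
                        feature_columns=list(FEATURE_COLUMNS),
                        seed=seed, metrics=metrics)


def detect(recording: Recording, trained: TrainedModel,
           window: WindowSpec | None = None) -> pd.DataFrame:
    """Apply a trained detector to a recording; returns merged positive
    intervals as a DataFrame (channel, start_s, end_s, score)."""
    window = window or WindowSpec(trained.window_ms)
    if window.length_ms != trained.window_ms:
        raise ModelCompatibilityError(
            f"model was trained on {trained.window_ms} ms windows, "
            f"got {window.length_ms} ms")
    table = extract_features(recording, [], window)
    if list(trained.feature_columns) != FEATURE_COLUMNS:
        raise ModelCompatibilityError("model feature schema does not match")
    X = table[FEATURE_COLUMNS].to_numpy(dtype=float)
    pred = trained.model.predict(X)
    score = np.asarray(_scores(trained.model, X), dtype=float)
    rows = []
    for cid, sub in table.assign(pred=pred, score=score).groupby("channel",
                                                                sort=False):
        run: list[int] = []
        for i, (_, row) in enumerate(sub.iterrows()):
            if row["pred"] == 1:
                run.append(i)
            if run and (row["pred"] == 0 or i == len(sub) - 1):
                seg = sub.iloc[run]
                rows.append({"channel": cid,
                             "start_s": float(seg["start_s"].iloc[0]),
                             "end_s": float(seg["end_s"].iloc[-1]),
                             "score": float(seg["score"].mean())})
                run = []
    return pd.DataFrame(rows, columns=["channel", "start_s", "end_s", "score"])
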