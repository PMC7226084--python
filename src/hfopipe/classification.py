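"""Step 2: three-class classification of HFO segments (R / FR / FRonR).

The ripple class dominates the HFO pool (~90%), so each minority class is
oversampled with ADASYN before fitting: synthetic minority points are
interpolated between real minority neighbors, with more synthetics generated
around minority points whose neighborhoods are dominated by other classes
(the hard-to-learn boundary region).  Oversampling happens strictly inside
each training fold; synthetic rows are flagged and never reach an evaluation
fold.  Metrics are one-vs-rest sensitivity and specificity per class from
stratified 3-fold CV after a 30% tuning holdout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

from .detection import make_estimator, split_tuning_holdout, tune
from .errors import ConfigurationError, StratificationError
from .io import EVENT_LABELS, FEATURE_COLUMNS


@dataclass(frozen=True)
class ADASYNConfig:
    """K nearest neighbors and balance level beta (1 = equalize fully)."""

    k: int = 5
    beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError(f"ADASYN K must be >= 1, got {self.k}")
        if not 0.0 <= self.beta <= 1.0:
            raise ConfigurationError(f"ADASYN beta must be in [0, 1], got {self.beta}")


def adasyn_oversample(minority: np.ndarray, others: np.ndarray,
                      config: ADASYNConfig,
                      rng: np.random.Generator | None = None,
                      majority_count: int | None = None) -> np.ndarray:
    """Synthetic minority vectors per the adaptive-synthetic-sampling rule.

    With minority count ``m_s`` and majority count ``m_l`` (the size of
    ``others`` unless ``majority_count`` narrows it to one class), the total
    number of synthetics is ``G = round((m_l - m_s) * beta)``.  Each minority
    point x_i receives ``g_i = round(r̂_i G)`` synthetics, where
    ``r_i = Δ_i / K`` counts the non-minority members among its K nearest
    neighbors in the pooled set and ``r̂`` normalizes r to sum to one
    (uniform if all Δ are zero).  Every synthetic is ``x_i + λ (x_z - x_i)``
    with λ ~ U(0, 1) and x_z drawn among x_i's K nearest minority neighbors.
    """
    minority = np.asarray(minority, dtype=float)
    others = np.asarray(others, dtype=float)
    m_s = len(minority)
    m_l = len(others) if majority_count is None else int(majority_count)
    if m_s < 2:
        raise ConfigurationError(f"ADASYN needs >= 2 minority points, got {m_s}")
    if config.k >= m_s:
        raise ConfigurationError(
            f"ADASYN K={config.k} must be < minority count {m_s}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    G = int(round((m_l - m_s) * config.beta))
    if G <= 0:
        return np.empty((0, minority.shape[1]))

    pooled = np.vstack([minority, others])
    is_other = np.arange(len(pooled)) >= m_s
    nn_all = NearestNeighbors(n_neighbors=config.k + 1).fit(pooled)
    _, idx = nn_all.kneighbors(minority)
    delta = is_other[idx[:, 1:]].sum(axis=1)  # drop self at column 0
    r = delta / config.k
    r_hat = (r / r.sum()) if r.sum() > 0 else np.full(m_s, 1.0 / m_s)
    g = np.round(r_hat * G).astype(int)

    nn_min = NearestNeighbors(n_neighbors=config.k + 1).fit(minority)
    _, min_idx = nn_min.kneighbors(minority)
    out = []
    for i in range(m_s):
        for _ in range(g[i]):
            z = minority[min_idx[i, rng.integers(1, config.k + 1)]]
            lam = rng.uniform()
            out.append(minority[i] + lam * (z - minority[i]))
    return np.array(out) if out else np.empty((0, minority.shape[1]))


def balance_multiclass(table: pd.DataFrame, config: ADASYNConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """ADASYN every non-majority class (vs all others) up to the majority
    count.  Distances run on z-scored features; synthetics are mapped back to
    the original feature scale and flagged with ``synthetic=True``.
    """
    counts = table["label"].value_counts()
    missing = set(EVENT_LABELS) - set(counts.index)
    if missing or set(counts.index) - set(EVENT_LABELS):
        raise StratificationError(
            f"step-2 table must contain exactly the classes {EVENT_LABELS}; "
            f"got counts {counts.to_dict()}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    scaler = StandardScaler().fit(table[FEATURE_COLUMNS].to_numpy(dtype=float))
    Z = scaler.transform(table[FEATURE_COLUMNS].to_numpy(dtype=float))
    labels = table["label"].to_numpy()
    majority = counts.idxmax()

    out = table.copy()
    out["synthetic"] = False
    for cls in counts.index:
        if cls == majority:
            continue
        mask = labels == cls
        # clamp K for very small training partitions (K must stay < m_s)
        eff = (config if config.k < mask.sum()
               else ADASYNConfig(max(int(mask.sum()) - 1, 1), config.beta,
                                 config.seed))
        synth = adasyn_oversample(Z[mask], Z[~mask], eff, rng=rng,
                                  majority_count=int(counts[majority]))
        if len(synth):
            rows = pd.DataFrame(scaler.inverse_transform(synth),
                                columns=FEATURE_COLUMNS)
            rows["label"] = cls
            rows["synthetic"] = True
            out = pd.concat([out, rows], ignore_index=True)
    return out


@dataclass
class MulticlassMetrics:
    """One-vs-rest per-class sensitivity/specificity over CV folds."""

    classes: tuple[str, ...]
    sensitivity: dict[str, np.ndarray]
    specificity: dict[str, np.ndarray]
    confusions: list[np.ndarray] = field(default_factory=list)

    def mean_sensitivity(self, cls: str) -> float:
        return float(np.mean(self.sensitivity[cls]))

    def mean_specificity(self, cls: str) -> float:
        return float(np.mean(self.specificity[cls]))

    def summary(self) -> dict:
        return {cls: {"sensitivity": self.mean_sensitivity(cls),
                      "specificity": self.mean_specificity(cls)}
                for cls in self.classes}


def _ovr_metrics(cm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = cm.sum() - tp - fn - fp
    return tp / (tp + fn), tn / (tn + fp)


def crossval_classify(table: pd.DataFrame, family: str, folds: int = 3,
                      seed: int = 0, tuning_fraction: float = 0.30,
                      adasyn: ADASYNConfig | None = None,
                      oversample_before_split: bool = False
                      ) -> MulticlassMetrics:
    """Step-2 protocol on the HFO rows of one subject's 10 ms feature table.

    30% stratified tuning holdout (macro one-vs-rest AUC as tuning score),
    then stratified ``folds``-fold CV on the rest with ADASYN fitted and
    applied inside each training fold only.  ``oversample_before_split=True``
    reproduces the leaky ordering (oversampling the whole development set
    before folding) for comparison; it inflates metrics and is off by default.
    """
    adasyn = adasyn or ADASYNConfig(seed=seed)
    classes = list(EVENT_LABELS)
    if set(table["label"].unique()) - set(classes):
        raise StratificationError("step-2 expects HFO rows only (R/FR/FRonR)")
    counts = table["label"].value_counts()
    if set(counts.index) != set(classes) or (counts < 2 * folds).any():
        raise StratificationError(
            f"every class needs >= {2 * folds} rows for the tuning split plus "
            f"{folds}-fold CV; counts: {counts.to_dict()}")

    tuning, dev = split_tuning_holdout(table, fraction=tuning_fraction,
                                       seed=seed, stratify_on="label")
    params, _ = tune(family, tuning, seed=seed, multiclass=True)

    rng = np.random.default_rng(seed)
    if oversample_before_split:
        dev = balance_multiclass(dev, adasyn, rng=rng)
    X = dev[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = dev["label"].to_numpy()
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    sens = {c: [] for c in classes}
    spec = {c: [] for c in classes}
    cms = []
    for tr, te in cv.split(X, y):
        train = dev.iloc[tr]
        if not oversample_before_split:
            train = balance_multiclass(train, adasyn, rng=rng)
        model = make_estimator(family, params, seed=seed)
        model.fit(train[FEATURE_COLUMNS].to_numpy(dtype=float),
                  train["label"].to_numpy())
        # in the leak-free ordering evaluation folds hold only original rows;
        # the leaky ordering deliberately lets synthetic copies through
        te_rows = dev.iloc[te]
        if not oversample_before_split and "synthetic" in te_rows.columns:
            te_rows = te_rows[~te_rows["synthetic"]]
        cm = confusion_matrix(te_rows["label"],
                              model.predict(te_rows[FEATURE_COLUMNS]
                                            .to_numpy(dtype=float)),
                              labels=classes)
        s, p = _ovr_metrics(cm)
        for j, c in enumerate(classes):
            sens[c].append(s[j])
            spec[c].append(p[j])
        cms.append(cm)
    return MulticlassMetrics(classes=tuple(classes),
                             sensitivity={c: np.array(v) for c, v in sens.items()},
                             specificity={c: np.array(v) for c, v in spec.items()},
                             confusions=cms)
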