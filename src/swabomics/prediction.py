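"""Random-forest prediction under repeated stratified cross-validation.

Classifiers predict community state (or *Lactobacillus* depletion status)
and windowed preterm-birth outcome from metabolic, immune or CLR-transformed
16S profiles; regressors predict log-transformed immune marker levels.  All
models run inside a repeated (default 15x) stratified five-fold CV; every
reported metric is computed exclusively from held-out predictions, pooled
per repeat and averaged across repeats.

Following the source protocol, classifier mtry is p/3 and regressor mtry is
sqrt(p) (the reverse of the common defaults); both are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, KFold

from swabomics.containers import FeatureMatrix


@dataclass
class CVConfig:
    n_repeats: int = 15
    n_folds: int = 5
    n_trees: int = 1000
    positive_class: str = "LDEPL"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least two folds")
        if self.n_trees < 1:
            raise ValueError("need at least one tree")

    def mtry_classification(self, p: int) -> int:
        return max(1, round(p / 3))

    def mtry_regression(self, p: int) -> int:
        return max(1, round(np.sqrt(p)))


@dataclass
class CVResult:
    """Held-out predictions and summary metrics of one CV experiment."""

    task: str
    per_repeat: pd.DataFrame            # one row per repeat with metrics
    oof_predictions: pd.DataFrame       # sample x repeat held-out scores
    metrics: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)


def _classification_metrics(y_true: np.ndarray, score: np.ndarray,
                            threshold: float = 0.5) -> dict:
    """AUC from scores; sensitivity etc. from majority-vote calls.

    ``y_true`` is 1 for the positive class; ``score`` the held-out vote
    fraction for the positive class.
    """
    pred = (score > threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    def safe(a, b):
        return a / b if b else np.nan
    return {
        "auc": float(roc_auc_score(y_true, score)),
        "sensitivity": safe(tp, tp + fn),
        "specificity": safe(tn, tn + fp),
        "accuracy": safe(tp + tn, len(y_true)),
        "ppv": safe(tp, tp + fp),
        "npv": safe(tn, tn + fn),
    }


def _run_classification_cv(X: np.ndarray, y: np.ndarray, config: CVConfig,
                           index: pd.Index, task: str) -> CVResult:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < config.n_folds:
        raise ValueError(
            "stratification impossible: a class has fewer samples than folds"
        )
    rng = np.random.default_rng(config.seed)
    mtry = config.mtry_classification(X.shape[1])
    repeat_rows = []
    oof = pd.DataFrame(index=index)
    for rep in range(config.n_repeats):
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        score = np.empty(len(y))
        for train, test in skf.split(X, y):
            clf = RandomForestClassifier(
                n_estimators=config.n_trees, max_features=mtry,
                random_state=int(rng.integers(2**31 - 1)), n_jobs=1,
            )
            clf.fit(X[train], y[train])
            pos_col = list(clf.classes_).index(1)
            score[test] = clf.predict_proba(X[test])[:, pos_col]
        oof[f"repeat_{rep}"] = score
        repeat_rows.append(_classification_metrics(y, score))
    per_repeat = pd.DataFrame(repeat_rows)
    metrics = per_repeat.mean(axis=0).to_dict()
    return CVResult(task=task, per_repeat=per_repeat, oof_predictions=oof,
                    metrics=metrics)


def run_cst_classifier(
    matrix: FeatureMatrix | pd.DataFrame,
    labels: pd.Series,
    config: CVConfig | None = None,
) -> CVResult:
    """Predict dominance status (or a CST pair) from metabolic profiles.

    The positive class is ``config.positive_class`` if present among the
    labels, otherwise the rarer class.  Metrics are averaged over repeats.
    """
    config = config or CVConfig()
    values = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    labels = labels.loc[values.index]
    classes, counts = np.unique(labels.to_numpy(), return_counts=True)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    if config.positive_class in classes:
        pos = config.positive_class
    else:
        pos = classes[np.argmin(counts)]
    y = (labels.to_numpy() == pos).astype(int)
    res = _run_classification_cv(
        values.to_numpy(dtype=float), y, config, values.index, task="cst"
    )
    res.flags["positive_class"] = str(pos)
    return res


def run_immune_regressor(
    matrix: FeatureMatrix | pd.DataFrame,
    marker: pd.Series,
    config: CVConfig | None = None,
) -> CVResult:
    """Predict log(marker + 1) from metabolic profiles; CV R2 per repeat.

    The headline CV R2 is the squared Pearson correlation between held-out
    predictions and observed targets (the convention of the CV framework
    this mirrors); 1 - SSE/SST is reported alongside.
    """
    config = config or CVConfig()
    values = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    marker = marker.loc[values.index]
    if (marker < 0).any():
        raise ValueError("marker concentrations must be non-negative")
    y = np.log1p(marker.to_numpy(dtype=float))
    X = values.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        res = CVResult(
            task="immune", per_repeat=pd.DataFrame(),
            oof_predictions=pd.DataFrame(index=values.index),
            metrics={"cv_r2": 0.0, "cv_r2_sse": 0.0},
            flags={"constant_target": True},
        )
        return res
    rng = np.random.default_rng(config.seed)
    mtry = config.mtry_regression(X.shape[1])
    rows = []
    oof = pd.DataFrame(index=values.index)
    for rep in range(config.n_repeats):
        kf = KFold(n_splits=config.n_folds, shuffle=True,
                   random_state=int(rng.integers(2**31 - 1)))
        pred = np.empty(len(y))
        for train, test in kf.split(X):
            reg = RandomForestRegressor(
                n_estimators=config.n_trees, max_features=mtry,
                random_state=int(rng.integers(2**31 - 1)), n_jobs=1,
            )
            reg.fit(X[train], y[train])
            pred[test] = reg.predict(X[test])
        oof[f"repeat_{rep}"] = pred
        if np.ptp(pred) == 0:
            r2_corr = 0.0
        else:
            r2_corr = float(np.corrcoef(pred, y)[0, 1] ** 2)
        sst = float(((y - y.mean()) ** 2).sum())
        r2_sse = 1.0 - float(((y - pred) ** 2).sum()) / sst
        rows.append({"cv_r2": r2_corr, "cv_r2_sse": r2_sse})
    per_repeat = pd.DataFrame(rows)
    return CVResult(task="immune", per_repeat=per_repeat, oof_predictions=oof,
                    metrics=per_repeat.mean(axis=0).to_dict())


def clr_transform(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centred log-ratio transform: log(x + pseudocount) minus the row mean
    of logs; every output row sums to zero."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    x = counts.to_numpy(dtype=float) + pseudocount
    if np.any(x <= 0):
        raise ValueError("all values must be positive after the pseudocount")
    logs = np.log(x)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=counts.index, columns=counts.columns)


DEFAULT_WINDOWS = ((0.0, 14.0), (14.0, 24.0), (24.0, 40.0))


def select_window_samples(
    covariates: pd.DataFrame,
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS,
) -> dict[int, pd.Index]:
    """One sample per subject per gestational window.

    Windows are half-open on the left ([lo, hi)) except the last, which is
    closed, so every gestational age maps to exactly one window.  Within a
    window the sample closest to the midpoint is chosen; ties break to the
    earlier sample.  Subjects without an in-window sample are absent from
    that window.
    """
    for (a_lo, a_hi), (b_lo, b_hi) in zip(windows, windows[1:]):
        if b_lo < a_hi:
            raise ValueError("windows may only share bounds, not overlap")
    out: dict[int, list] = {i: [] for i in range(len(windows))}
    ga = covariates["gestational_age"]
    for subject, rows in covariates.groupby("subject_id"):
        for w, (lo, hi) in enumerate(windows):
            last = w == len(windows) - 1
            in_win = rows[(ga.loc[rows.index] >= lo)
                          & ((ga.loc[rows.index] <= hi) if last
                             else (ga.loc[rows.index] < hi))]
            if in_win.empty:
                continue
            mid = 0.5 * (lo + hi)
            dist = (in_win["gestational_age"] - mid).abs()
            best = in_win.loc[dist == dist.min(), "gestational_age"].idxmin()
            out[w].append(best)
    return {w: pd.Index(ix) for w, ix in out.items()}


def run_ptb_classifier(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    config: CVConfig | None = None,
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS,
    min_class_size: int = 5,
) -> dict[int, CVResult]:
    """Windowed preterm-birth classification from one predictor block.

    ``features`` is any sample x predictor frame (CLR 16S, immune or
    metabolic); ``covariates`` must carry ``subject_id``, ``gestational_age``
    and ``outcome``.  For each gestational window, one sample per subject is
    selected and a random-forest classifier with positive class sPTB is run
    under repeated stratified CV.  Windows with fewer than
    ``min_class_size`` subjects in either class are skipped with a warning.
    """
    config = config or CVConfig(positive_class="sPTB")
    selected = select_window_samples(covariates, windows)
    results: dict[int, CVResult] = {}
    for w, idx in selected.items():
        idx = idx.intersection(features.index)
        if len(idx) == 0:
            continue
        y_lab = covariates.loc[idx, "outcome"]
        n_pos = int((y_lab == "sPTB").sum())
        n_neg = int((y_lab != "sPTB").sum())
        if min(n_pos, n_neg) < max(min_class_size, config.n_folds):
            warnings.warn(
                f"window {w}: class too small ({n_pos} sPTB vs {n_neg}); skipped",
                stacklevel=2,
            )
            continue
        y = (y_lab == "sPTB").astype(int).to_numpy()
        res = _run_classification_cv(
            features.loc[idx].to_numpy(dtype=float), y, config, idx,
            task=f"ptb_window_{w}",
        )
        res.flags["positive_class"] = "sPTB"
        results[w] = res
    return results
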