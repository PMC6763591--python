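"""Survival risk classification and per-class survival-day regression.

Two pipelines over a per-subject feature table plus age and overall survival
(OS, days):

* **SP1** — three-step univariate Cox screening (continuous fit, median-
  dichotomized refit, median-split log-rank), then a bagged-tree (random
  forest) model.
* **SP2** — recursive feature selection (RFS) run separately on the Euler
  block and on the remaining features, then an L1/L2-regularized gradient-
  boosted (XGBoost) three-class risk classifier, plus per-class boosted
  survival-day regressors whose features are Cox-screened within each class.
* **modified SP2** — SP2 with an extra pruning pass keeping only features
  whose relative scaled importance exceeds 50% of the maximum.

Risk classes use 30-day months: short < 300 days, medium 300-450 days
(boundaries inclusive), long > 450 days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier, XGBRegressor

RISK_CLASSES = ("short", "medium", "long")
SHORT_DAYS = 300.0
LONG_DAYS = 450.0
CLASS_INTERVALS = {
    "short": (1.0, SHORT_DAYS),
    "medium": (SHORT_DAYS, LONG_DAYS),
    "long": (LONG_DAYS, np.inf),
}

DEFAULT_BOOST_PARAMS = dict(
    max_depth=3, n_estimators=200, learning_rate=0.1, reg_alpha=1.0, reg_lambda=1.0
)
# lighter settings for the inner scoring loop of recursive feature selection
RFS_BOOST_PARAMS = dict(
    max_depth=3, n_estimators=60, learning_rate=0.2, reg_alpha=1.0, reg_lambda=1.0
)


def assign_risk_class(os_days: float) -> str:
    """short < 300 days; medium in [300, 450]; long > 450."""
    if os_days <= 0:
        raise ValueError(f"non-positive survival: {os_days}")
    if os_days < SHORT_DAYS:
        return "short"
    if os_days <= LONG_DAYS:
        return "medium"
    return "long"


def risk_classes(os_days) -> np.ndarray:
    return np.array([assign_risk_class(t) for t in np.asarray(os_days, float)])


# ---------------------------------------------------------------------------
# Cox screening


@dataclass(frozen=True)
class CoxFit:
    coefficient: float
    se: float
    p_value: float
    converged: bool = True


def cox_univariate_fit(x, durations, events=None) -> CoxFit:
    """Univariate Cox proportional-hazards fit (partial likelihood, Breslow ties).

    Returns the coefficient, its standard error and the Wald p-value.
    Constant features are rejected; non-convergence is retried with a small
    ridge penalty and flagged.
    """
    x = np.asarray(x, float)
    durations = np.asarray(durations, float)
    if events is None:
        events = np.ones_like(durations, bool)
    if x.size < 10:
        raise ValueError("need at least 10 subjects")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) feature")
    df = pd.DataFrame({"x": x, "T": durations, "E": np.asarray(events, bool)})
    for penalizer, converged in ((0.0, True), (0.1, False)):
        cph = CoxPHFitter(penalizer=penalizer)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="T", event_col="E")  # Breslow ties
        except (ConvergenceError, ValueError):
            continue
        beta = float(cph.params_["x"])
        se = float(cph.standard_errors_["x"])
        p = float(cph.summary.loc["x", "p"])
        # monotone partial likelihood (e.g., complete separation of a binary
        # covariate) inflates the Wald SE and drives its p toward 1; fall
        # back to the likelihood-ratio test, which stays well-behaved
        if not np.isfinite(p) or abs(beta) > 10 or (se > 0 and se > 50 * abs(beta)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(cph.log_likelihood_ratio_test().p_value)
        return CoxFit(coefficient=beta, se=se, p_value=p, converged=converged)
    return CoxFit(np.nan, np.nan, 1.0, converged=False)


def _prepared(features: pd.DataFrame) -> pd.DataFrame:
    """Median-impute flagged-missing (NaN) entries, column-wise."""
    if features.isna().any().any():
        features = features.fillna(features.median())
    return features


def sp1_select(
    features: pd.DataFrame, clinical: pd.DataFrame, alpha: float = 0.05
) -> list[str]:
    """Three-step Cox feature screen.

    1. univariate Cox on each feature, keep Wald p < alpha;
    2. dichotomize each survivor at its median (>= median -> 1), refit Cox,
       keep p < alpha;
    3. keep only features whose median split separates survival by a
       log-rank test at p < alpha.
    Returns the names passing all three steps, in table order.
    """
    if features.shape[1] == 0:
        raise ValueError("empty feature table")
    features = _prepared(features)
    T = clinical["os_days"].to_numpy(float)
    E = clinical.get("event", pd.Series(True, index=clinical.index)).to_numpy(bool)
    selected = []
    for name in features.columns:
        x = features[name].to_numpy(float)
        if np.ptp(x) == 0:
            continue
        if cox_univariate_fit(x, T, E).p_value >= alpha:
            continue
        hi = (x >= np.median(x)).astype(float)
        if np.ptp(hi) == 0:
            continue
        if cox_univariate_fit(hi, T, E).p_value >= alpha:
            continue
        lr = logrank_test(T[hi == 1], T[hi == 0], E[hi == 1], E[hi == 0])
        if lr.p_value < alpha:
            selected.append(name)
    return selected


# ---------------------------------------------------------------------------
# recursive feature selection (RFS)


def _cv_accuracy(X: np.ndarray, y: np.ndarray, n_folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        clf = XGBClassifier(**RFS_BOOST_PARAMS, random_state=seed)
        clf.fit(X[tr], y[tr])
        accs.append(float((clf.predict(X[te]) == y[te]).mean()))
    return float(np.mean(accs))


def rfs_select(
    features: pd.DataFrame,
    class_labels,
    n_folds: int = 5,
    drop_fraction: float = 0.1,
    seed: int = 0,
    min_features: int = 1,
) -> list[str]:
    """Recursive feature elimination scored by stratified CV accuracy.

    Repeatedly fits a boosted-tree classifier, drops the lowest-importance
    ``drop_fraction`` of the surviving features, and records the stratified
    ``n_folds``-fold CV accuracy of each subset; the best-scoring subset is
    returned (ties favor the smaller subset).  Deterministic under ``seed``.
    """
    y = pd.Categorical(class_labels, categories=RISK_CLASSES).codes
    if np.any(y < 0):
        raise ValueError("unknown class label")
    counts = np.bincount(y, minlength=3)
    if min(counts[counts > 0]) < n_folds:
        raise ValueError("fewer subjects in a class than CV folds")
    features = _prepared(features)
    current = list(features.columns)
    best_score, best_set = -np.inf, current
    while len(current) >= min_features:
        X = features[current].to_numpy(float)
        score = _cv_accuracy(X, y, n_folds, seed)
        if score >= best_score:  # >= : later (smaller) subsets win ties
            best_score, best_set = score, list(current)
        if len(current) == min_features:
            break
        clf = XGBClassifier(**RFS_BOOST_PARAMS, random_state=seed)
        clf.fit(X, y)
        imp = clf.feature_importances_
        n_drop = max(1, int(np.floor(drop_fraction * len(current))))
        order = np.argsort(imp, kind="stable")
        drop = set(order[:n_drop])
        current = [c for i, c in enumerate(current) if i not in drop]
    return best_set


# ---------------------------------------------------------------------------
# models


@dataclass
class RiskClassifier:
    model: object
    feature_names: list[str]
    variant: str

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = _prepared(features[self.feature_names]).to_numpy(float)
        codes = self.model.predict(X)
        return np.asarray(RISK_CLASSES)[codes]

    def importances(self) -> pd.Series:
        return pd.Series(self.model.feature_importances_, index=self.feature_names)


def train_risk_classifier(
    features: pd.DataFrame,
    class_labels,
    variant: str = "sp2",
    seed: int = 0,
    params: dict | None = None,
) -> RiskClassifier:
    """Three-class risk model: regularized XGBoost (sp2) or random forest (sp1)."""
    y = pd.Categorical(class_labels, categories=RISK_CLASSES).codes
    present = np.bincount(y[y >= 0], minlength=3)
    if (present == 0).any():
        missing = [c for c, n in zip(RISK_CLASSES, present) if n == 0]
        raise ValueError(f"missing class(es): {missing}")
    features = _prepared(features)
    X = features.to_numpy(float)
    if variant == "sp2":
        model = XGBClassifier(**(params or DEFAULT_BOOST_PARAMS), random_state=seed)
    elif variant == "sp1":
        model = RandomForestClassifier(
            n_estimators=(params or {}).get("n_estimators", 200), random_state=seed
        )
    else:
        raise ValueError(f"unknown variant {variant!r}")
    model.fit(X, y)
    return RiskClassifier(model, list(features.columns), variant)


@dataclass
class ClassRegressor:
    model: object
    feature_names: list[str]
    interval: tuple[float, float]
    low_confidence: bool = False

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = _prepared(features[self.feature_names]).to_numpy(float)
        lo, hi = self.interval
        return np.clip(self.model.predict(X).astype(float), lo, hi)


def _class_cox_select(
    features: pd.DataFrame, clinical: pd.DataFrame, alpha: float
) -> list[str]:
    T = clinical["os_days"].to_numpy(float)
    E = clinical.get("event", pd.Series(True, index=clinical.index)).to_numpy(bool)
    keep = []
    for name in features.columns:
        x = features[name].to_numpy(float)
        if np.ptp(x) == 0:
            continue
        try:
            if cox_univariate_fit(x, T, E).p_value < alpha:
                keep.append(name)
        except ValueError:
            continue
    return keep


def train_class_regressors(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    seed: int = 0,
    params: dict | None = None,
) -> dict[str, ClassRegressor]:
    """One boosted survival-day regressor per risk class.

    Features are Cox-screened (p < alpha) within each class's subjects; if no
    feature passes, the single smallest-p feature is used.  Predictions are
    clamped to the class's day interval.  Classes with < 5 subjects are
    flagged low-confidence.
    """
    labels = risk_classes(clinical["os_days"])
    out: dict[str, ClassRegressor] = {}
    features = _prepared(features)
    for cls in RISK_CLASSES:
        idx = labels == cls
        if not idx.any():
            raise ValueError(f"class {cls!r} has no subjects")
        sub_f = features.loc[idx]
        sub_c = clinical.loc[idx]
        selected = (
            _class_cox_select(sub_f, sub_c, alpha) if idx.sum() >= 10 else []
        )
        if not selected:
            variances = sub_f.var()
            selected = [variances.idxmax()]
        reg = XGBRegressor(**(params or DEFAULT_BOOST_PARAMS), random_state=seed)
        reg.fit(sub_f[selected].to_numpy(float), sub_c["os_days"].to_numpy(float))
        out[cls] = ClassRegressor(
            reg, selected, CLASS_INTERVALS[cls], low_confidence=int(idx.sum()) < 5
        )
    return out


def predict_survival_days(
    classifier: RiskClassifier,
    regressors: dict[str, ClassRegressor],
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Classify each subject, then dispatch to that class's day regressor."""
    cls = classifier.predict(features)
    days = np.empty(len(features))
    for c in RISK_CLASSES:
        idx = cls == c
        if idx.any():
            days[idx] = regressors[c].predict(features.loc[idx])
    return pd.DataFrame({"risk_class": cls, "predicted_days": days}, index=features.index)


def importance_prune(
    model: RiskClassifier, threshold: float = 0.5
) -> list[str]:
    """Features with relative scaled importance strictly above the threshold.

    Importances are scaled so the maximum is 100%; features above
    ``threshold`` (default 50%) of that maximum survive.  An empty result
    falls back to the single most important feature, with a warning.
    """
    imp = model.importances()
    mx = imp.max()
    if mx <= 0:
        warnings.warn("all importances zero; keeping the first feature")
        return [imp.index[0]]
    scaled = imp / mx
    kept = list(imp.index[scaled > threshold])
    if not kept:
        warnings.warn("importance pruning left no features; keeping the top one")
        kept = [imp.idxmax()]
    return kept


# ---------------------------------------------------------------------------
# evaluation


def confusion_matrix_3x3(
    predicted, reference, class_order: tuple[str, ...] = ("long", "medium", "short")
) -> np.ndarray:
    """3x3 matrix, rows = predictions, columns = reference."""
    m = np.zeros((3, 3), int)
    pi = {c: i for i, c in enumerate(class_order)}
    for p, r in zip(predicted, reference):
        m[pi[p], pi[r]] += 1
    return m


def confusion_stats(
    matrix, class_order: tuple[str, ...] = ("long", "medium", "short")
) -> dict:
    """Per-class one-vs-rest statistics of a predictions x reference matrix.

    sensitivity = TP / reference-column total; specificity = TN / total of
    the other reference columns; balanced accuracy = their mean; PPV = TP /
    prediction-row total; NPV = TN / (TN + FN); overall accuracy = trace /
    total.  All values rounded to 3 decimals for report parity.
    """
    m = np.asarray(matrix, int)
    if m.shape != (3, 3) or (m < 0).any():
        raise ValueError("expected a nonnegative 3x3 matrix")
    total = m.sum()
    col = m.sum(axis=0)
    row = m.sum(axis=1)
    if (col == 0).any():
        raise ValueError("a reference class has zero cases")
    per_class = {}
    for i, cls in enumerate(class_order):
        tp = m[i, i]
        fn = col[i] - tp
        tn = total - row[i] - col[i] + tp
        sens = tp / col[i]
        spec = tn / (total - col[i])
        per_class[cls] = {
            "sensitivity": round(float(sens), 3),
            "specificity": round(float(spec), 3),
            "balanced_accuracy": round(float((sens + spec) / 2), 3),
            "ppv": round(float(tp / row[i]) if row[i] else np.nan, 3),
            "npv": round(float(tn / (tn + fn)) if tn + fn else np.nan, 3),
        }
    return {
        "matrix": m.tolist(),
        "class_order": list(class_order),
        "per_class": per_class,
        "overall_accuracy": round(float(np.trace(m) / total), 3),
    }


def _regression_errors(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    err = y_pred - y_true
    mse = float(np.mean(err**2))
    return {"rmse": float(np.sqrt(mse)), "mse": mse, "mae": float(np.mean(np.abs(err)))}


def loocv_evaluate(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    variant: str = "sp2",
    feature_names: list[str] | None = None,
    nested_selection: bool = False,
    alpha: float = 0.05,
    seed: int = 0,
    params: dict | None = None,
) -> dict:
    """Leave-one-out evaluation of classification and per-class regression.

    By default the feature set (``feature_names``, or all columns) is fixed
    before the loop, mirroring the usual selection-outside-CV protocol;
    ``nested_selection=True`` reruns the SP1 Cox screen inside every fold
    (slower, leakage-free).  Reports the 3x3 confusion statistics, per-class
    regression RMSE/MSE/MAE, and the combined MSE (sum over classes).
    """
    labels = risk_classes(clinical["os_days"])
    features = _prepared(features)
    names = feature_names or list(features.columns)
    n = len(features)
    preds = np.empty(n, dtype=object)
    for i in range(n):
        tr = np.arange(n) != i
        cols = (
            sp1_select(features.iloc[tr], clinical.iloc[tr], alpha) or names
            if nested_selection
            else names
        )
        clf = train_risk_classifier(
            features.iloc[tr][cols], labels[tr], variant=variant, seed=seed, params=params
        )
        preds[i] = clf.predict(features.iloc[[i]][cols])[0]
    matrix = confusion_matrix_3x3(preds, labels)
    report = {"classification": confusion_stats(matrix)}

    regression: dict[str, dict] = {}
    combined_mse = 0.0
    for cls in RISK_CLASSES:
        idx = np.nonzero(labels == cls)[0]
        if len(idx) < 3:
            regression[cls] = {"rmse": np.nan, "mse": np.nan, "mae": np.nan}
            continue
        sub_f = features.iloc[idx]
        sub_c = clinical.iloc[idx]
        cols = _class_cox_select(sub_f, sub_c, alpha) or [sub_f.var().idxmax()]
        y_true = sub_c["os_days"].to_numpy(float)
        y_pred = np.empty(len(idx))
        for j in range(len(idx)):
            tr = np.arange(len(idx)) != j
            reg = XGBRegressor(**(params or DEFAULT_BOOST_PARAMS), random_state=seed)
            reg.fit(sub_f.iloc[tr][cols].to_numpy(float), y_true[tr])
            lo, hi = CLASS_INTERVALS[cls]
            y_pred[j] = np.clip(float(reg.predict(sub_f.iloc[[j]][cols].to_numpy(float))[0]), lo, hi)
        regression[cls] = _regression_errors(y_true, y_pred)
        combined_mse += regression[cls]["mse"]
    report["regression"] = regression
    report["combined_mse"] = combined_mse
    report["accuracy"] = report["classification"]["overall_accuracy"]
    return report


def km_logrank_stratify(
    x, clinical: pd.DataFrame, threshold: float | None = None
) -> dict:
    """Two-group Kaplan-Meier stratification around a feature threshold.

    Default threshold is the feature mean.  Returns the fitted KM estimators
    (with Greenwood 95% bands) for the high and low groups and the two-group
    log-rank chi-squared p-value.
    """
    x = np.asarray(x, float)
    T = clinical["os_days"].to_numpy(float)
    E = clinical.get("event", pd.Series(True, index=clinical.index)).to_numpy(bool)
    thr = float(np.mean(x)) if threshold is None else threshold
    hi = x > thr
    if hi.all() or not hi.any():
        raise ValueError("degenerate split: one group is empty")
    km_hi, km_lo = KaplanMeierFitter(), KaplanMeierFitter()
    km_hi.fit(T[hi], E[hi], label="high")
    km_lo.fit(T[~hi], E[~hi], label="low")
    lr = logrank_test(T[hi], T[~hi], E[hi], E[~hi])
    return {
        "threshold": thr,
        "km_high": km_hi,
        "km_low": km_lo,
        "p_value": float(lr.p_value),
        "n_high": int(hi.sum()),
        "n_low": int((~hi).sum()),
    }
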