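"""Robustness diagnostics: confounder-count sensitivity, treatment
predictability, and composite feature importance.

Three complementary checks on a finished analysis.  The sensitivity scan
re-estimates every (method, outcome) effect with nested top-k confounder
sets and scores concordance — same effect direction and |ΔATE| < 0.001 —
across k-settings.  The predictability suite fits five classifier families
to predict treatment from the selected confounders; uniformly high held-out
accuracy is the signature of confounding by indication (treatment assignment
nearly determined by baseline characteristics) and raises an explicit
warning flag.  The composite importance table averages six normalized
feature-selection scores per covariate to show which baseline factors drive
assignment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, f_classif, mutual_info_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, balanced_accuracy_score,
                             confusion_matrix, f1_score, precision_score,
                             recall_score)
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .estimation import aipw_ate, estimate_propensity, ipw_ate, ipw_weights, trim_weights

__all__ = [
    "SensitivityReport",
    "ClassifierReport",
    "ImportanceReport",
    "DegenerateLabelError",
    "concordant",
    "sensitivity_over_k",
    "treatment_predictability",
    "composite_importance",
    "CONFOUNDING_ACCURACY_FLAG",
]

CONFOUNDING_ACCURACY_FLAG = 0.9  # average held-out accuracy above this flags
#                                  confounding by indication
CONCORDANCE_TOL = 0.001


class DegenerateLabelError(ValueError):
    """Treatment vector contains a single class."""


def concordant(ate_a: float, ate_b: float, tol: float = CONCORDANCE_TOL) -> bool:
    """Two estimates are concordant when their directions match and they
    differ by less than ``tol`` in absolute value."""
    return bool(np.sign(ate_a) == np.sign(ate_b) and abs(ate_a - ate_b) < tol)


@dataclass
class SensitivityReport:
    estimates: pd.DataFrame  # columns: method, outcome, k, ate, n_treated, n_untreated
    pairwise: pd.DataFrame  # columns: method, outcome, k_a, k_b, delta, concordant
    overall_concordance: float
    max_abs_delta: float


def _ipw_point(Y, T, X):
    e = estimate_propensity(X, T).scores
    w = trim_weights(ipw_weights(e, T))
    return ipw_ate(Y, T, w).ate


def sensitivity_over_k(X, T, outcomes, ranked_confounders, ks=(20, 25, 30),
                       methods=("ipw", "aipw")) -> SensitivityReport:
    """Re-estimate effects with nested top-k confounder sets and score
    concordance of every k-pair per (method, outcome).

    ``outcomes`` maps outcome name -> vector; ``ranked_confounders`` is the
    consensus ranking.  If the ranking is shorter than max(ks), the larger
    settings are clamped to the available pool (with a warning).
    """
    X = pd.DataFrame(X) if not isinstance(X, pd.DataFrame) else X
    ks = sorted(set(int(k) for k in ks))
    if len(ranked_confounders) < max(ks):
        warnings.warn(
            f"ranked list has {len(ranked_confounders)} entries < max k {max(ks)}; "
            "clamping", stacklevel=2)
        ks = sorted(set(min(k, len(ranked_confounders)) for k in ks))

    rows = []
    for method, (name, Y), k in itertools.product(
            methods, outcomes.items(), ks):
        cols = list(ranked_confounders[:k])
        Xk = X[cols]
        if method == "ipw":
            ate = _ipw_point(np.asarray(Y, float), np.asarray(T), Xk)
            n1 = int(np.sum(np.asarray(T) == 1))
            n0 = int(np.sum(np.asarray(T) == 0))
        else:
            res = aipw_ate(np.asarray(Y, float), np.asarray(T), Xk)
            ate, n1, n0 = res.ate, res.n_treated, res.n_untreated
        rows.append({"method": method, "outcome": name, "k": k, "ate": ate,
                     "n_treated": n1, "n_untreated": n0})
    est = pd.DataFrame(rows)

    pair_rows = []
    for (method, name), grp in est.groupby(["method", "outcome"]):
        by_k = dict(zip(grp["k"], grp["ate"]))
        for ka, kb in itertools.combinations(sorted(by_k), 2):
            a, b = by_k[ka], by_k[kb]
            pair_rows.append({"method": method, "outcome": name,
                              "k_a": ka, "k_b": kb, "delta": abs(a - b),
                              "concordant": concordant(a, b)})
    pairs = pd.DataFrame(pair_rows)
    overall = float(pairs["concordant"].mean()) if len(pairs) else 1.0
    max_delta = float(pairs["delta"].max()) if len(pairs) else 0.0
    return SensitivityReport(est, pairs, overall, max_delta)


@dataclass
class ClassifierReport:
    metrics: pd.DataFrame  # one row per model family + an "average" row
    confusion_matrices: dict  # family -> 2x2 array (held-out)
    confounding_flag: bool
    average_accuracy: float


def _model_grid(seed):
    """Five families with small grids centered on the stated anchors."""
    return {
        "logistic_l2": (
            LogisticRegression(max_iter=5000),  # ridge (L2) penalty
            {"C": [0.1, 1.0, 10.0]},
        ),
        "random_forest": (
            RandomForestClassifier(n_estimators=200, random_state=seed),
            {"max_depth": [6, 8, 10]},
        ),
        "svm_rbf": (
            SVC(kernel="rbf"),
            {"C": [0.1, 1.0, 10.0]},
        ),
        "xgboost": (
            XGBClassifier(max_depth=6, n_estimators=100, random_state=seed,
                          verbosity=0, eval_metric="logloss"),
            {"learning_rate": [0.05, 0.1, 0.2]},
        ),
        "naive_bayes": (GaussianNB(), {}),
    }


def treatment_predictability(X_conf, T, seed: int = 0, cv_folds: int = 5,
                             test_size: float = 0.30,
                             repeats: int = 1) -> ClassifierReport:
    """How well do the selected confounders predict treatment assignment?

    Five classifier families (L2 logistic, random forest, RBF support-vector,
    gradient-boosted trees, Gaussian naive Bayes) are tuned by K-fold grid
    search on a stratified 70% training split and scored on the held-out
    30%.  With ``repeats`` > 1 the split/tune/score cycle runs on several
    stratified splits and metrics are averaged (confusion matrices come from
    the first split).  Average held-out accuracy above 0.9 sets the
    confounding-by-indication flag.
    """
    Xm = X_conf.to_numpy(dtype=float) if isinstance(X_conf, pd.DataFrame) \
        else np.asarray(X_conf, dtype=float)
    T = np.asarray(T).astype(int)
    if len(np.unique(T)) < 2:
        raise DegenerateLabelError("treatment vector contains a single class")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")

    per_split = []
    cms = {}
    for rep in range(repeats):
        X_tr, X_te, y_tr, y_te = train_test_split(
            Xm, T, test_size=test_size, stratify=T, random_state=seed + rep)
        scaler = StandardScaler().fit(X_tr)
        X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)

        rows = []
        for family, (model, grid) in _model_grid(seed).items():
            if grid:
                search = GridSearchCV(model, grid, cv=cv_folds,
                                      scoring="accuracy", n_jobs=1)
                search.fit(X_tr, y_tr)
                best = search.best_estimator_
            else:
                best = model.fit(X_tr, y_tr)
            pred = best.predict(X_te)
            if rep == 0:
                cms[family] = confusion_matrix(y_te, pred, labels=[0, 1])
            rows.append({
                "family": family,
                "accuracy": accuracy_score(y_te, pred),
                "balanced_accuracy": balanced_accuracy_score(y_te, pred),
                "f1": f1_score(y_te, pred, zero_division=0),
                "precision_treated": precision_score(y_te, pred, zero_division=0),
                "recall_treated": recall_score(y_te, pred, zero_division=0),
            })
        per_split.append(pd.DataFrame(rows).set_index("family"))
    metrics = sum(per_split) / len(per_split)
    avg = metrics.mean(axis=0)
    metrics.loc["average"] = avg
    flag = bool(avg["accuracy"] > CONFOUNDING_ACCURACY_FLAG)
    if flag:
        warnings.warn(
            "average held-out accuracy exceeds 0.9: treatment assignment is "
            "nearly determined by baseline covariates (confounding by "
            "indication)", stacklevel=2)
    return ClassifierReport(metrics, cms, flag, float(avg["accuracy"]))


@dataclass
class ImportanceReport:
    table: pd.DataFrame  # per covariate: six normalized scores + composite, ranked
    ties: list = field(default_factory=list)


def _minmax_100(v):
    v = np.asarray(v, dtype=float)
    v = np.where(np.isfinite(v), v, 0.0)
    span = v.max() - v.min()
    if span == 0:
        return np.zeros_like(v)
    return np.clip(100.0 * (v - v.min()) / span, 0.0, 100.0)


def composite_importance(X, T, seed: int = 0,
                         normalization: str = "minmax") -> ImportanceReport:
    """Six-method feature-importance consensus for treatment assignment.

    Methods: ANOVA F-test, mutual information, random-forest impurity
    importance, absolute standardized logistic coefficients, recursive
    feature elimination (logistic base), and absolute point-biserial
    correlation.  Each method's scores are normalized to [0, 100] — min-max
    by default, ``normalization="rank"`` for a rank-based alternative — and
    the composite is their unweighted mean.  Constant covariates score 0.
    """
    if normalization not in ("minmax", "rank"):
        raise ValueError("normalization must be 'minmax' or 'rank'")
    X = pd.DataFrame(X) if not isinstance(X, pd.DataFrame) else X
    T = np.asarray(T).astype(int)
    if len(np.unique(T)) < 2:
        raise DegenerateLabelError("treatment vector contains a single class")
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    const = Xm.std(axis=0) == 0
    Xz = StandardScaler().fit_transform(Xm)
    Xz[:, const] = 0.0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, _ = f_classif(Xz, T)
    mi = mutual_info_classif(Xz, T, random_state=seed)
    rf = RandomForestClassifier(n_estimators=200, random_state=seed).fit(Xm, T)
    logit = LogisticRegression(max_iter=5000).fit(Xz, T)
    rfe = RFE(LogisticRegression(max_iter=5000), n_features_to_select=1).fit(Xz, T)
    rfe_score = (len(names) - rfe.ranking_ + 1).astype(float)  # higher = kept longer
    corr = np.array([
        0.0 if const[j] else abs(np.corrcoef(Xm[:, j], T)[0, 1])
        for j in range(len(names))
    ])

    raw = {
        "f_test": np.where(const, 0.0, f_stat),
        "mutual_info": np.where(const, 0.0, mi),
        "rf_importance": np.where(const, 0.0, rf.feature_importances_),
        "logistic_coef": np.where(const, 0.0, np.abs(logit.coef_[0])),
        "rfe": np.where(const, 0.0, rfe_score),
        "correlation": corr,
    }
    if normalization == "rank":
        from scipy.stats import rankdata

        def _norm(v):
            v = np.where(np.isfinite(v), v, 0.0)
            r = rankdata(v, method="average") - 1
            return np.zeros_like(v) if r.max() == 0 else 100.0 * r / r.max()
    else:
        _norm = _minmax_100
    table = pd.DataFrame({m: _norm(v) for m, v in raw.items()}, index=names)
    table["composite"] = table.mean(axis=1)
    order = sorted(names, key=lambda nm: (-table.loc[nm, "composite"], nm))
    table = table.loc[order]

    ties = []
    comp = table["composite"].round(12)
    for val, grp in comp.groupby(comp):
        if len(grp) > 1:
            ties.append(sorted(grp.index.tolist()))
    if const.any():
        warnings.warn(f"constant covariates scored 0: "
                      f"{[names[j] for j in np.where(const)[0]]}", stacklevel=2)
    return ImportanceReport(table, ties)
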