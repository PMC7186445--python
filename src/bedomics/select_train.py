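"""Feature selection and classifier training.

Selection is a wrapper method: greedy forward selection where each
candidate feature is scored by the mean out-of-fold binomial deviance of a
logistic GLM in a seeded 5-fold cross-validation (the same fold split is
used for every candidate within a step, so comparisons are paired).

Three classifier families are tuned and trained on the selected features:
an RBF-kernel SVM (box constraint and kernel scale searched on a log
grid), tree-based ensembles (random forest, AdaBoost, LogitBoost,
GentleBoost, RUSBoost with searched cycles / learning rate / leaf size),
and a naive-Bayes classifier with per-feature Gaussian or kernel
densities.  All estimators follow the scikit-learn protocol (``fit``,
``predict``, ``decision_function``/``predict_proba``, ``get_params``) and
are deterministic given their ``random_state``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .synthetic import feature_columns

__all__ = [
    "SelectionSpec",
    "StepwiseDevianceSelector",
    "TunedSVMClassifier",
    "TunedEnsembleClassifier",
    "KernelNaiveBayesClassifier",
    "FittedModel",
    "stepwise_forward_select",
    "train_svm",
    "train_ensemble",
    "train_nb",
]

_EPS = 1e-10


@dataclass(frozen=True)
class SelectionSpec:
    max_vars: int = 4
    folds: int = 5
    allow_backward: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_vars < 1:
            raise ValueError("max_vars must be at least 1")
        if self.folds < 2:
            raise ValueError("folds must be at least 2")


def _binomial_deviance(y_true: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-2.0 * np.sum(y_true * np.log(p) + (1 - y_true) * np.log(1 - p)))


class StepwiseDevianceSelector(BaseEstimator):
    """Greedy forward (optionally stepwise) selection by CV deviance.

    At each step every unused candidate is evaluated by the mean test
    deviance of a logistic GLM over a fixed stratified k-fold split; the
    minimizer is added.  Ties break on lexicographic feature name.  Stops
    when no candidate improves the criterion or ``max_vars`` is reached.

    Attributes
    ----------
    selected_ : list of str
        Ordered names of the selected features.
    history_ : list of (str, float)
        Selection path with the criterion value after each accepted move.
    """

    def __init__(
        self,
        max_vars: int = 4,
        folds: int = 5,
        allow_backward: bool = False,
        random_state: int = 0,
    ):
        self.max_vars = max_vars
        self.folds = folds
        self.allow_backward = allow_backward
        self.random_state = random_state

    def _cv_deviance(self, X, y, cols, splits) -> float:
        if not cols:
            # intercept-only model
            dev = 0.0
            for tr, te in splits:
                p = np.full(len(te), y[tr].mean())
                dev += _binomial_deviance(y[te], p)
            return dev / len(splits)
        glm = LogisticRegression(C=np.inf, max_iter=500, solver="lbfgs")  # unpenalized GLM
        dev = 0.0
        for tr, te in splits:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    glm.fit(X[np.ix_(tr, cols)], y[tr])
                p = glm.predict_proba(X[np.ix_(te, cols)])[:, 1]
            except Exception:
                return float("inf")
            dev += _binomial_deviance(y[te], p)
        return dev / len(splits)

    def fit(self, X, y, feature_names: list[str] | None = None):
        spec = SelectionSpec(self.max_vars, self.folds, self.allow_backward, self.random_state)
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            feature_names = feature_names or [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(y).astype(int)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2 or counts.min() < 2 * spec.folds:
            raise ValueError("need two classes with at least 2 rows per class per fold")

        # standardize once; fixed fold split reused across candidates and steps
        scaler = StandardScaler().fit(X)
        Z = scaler.transform(X)
        skf = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=self.random_state)
        splits = list(skf.split(Z, y))

        order = np.argsort(feature_names)  # lexicographic candidate order → stable ties
        selected: list[int] = []
        history: list[tuple[str, float]] = []
        current = self._cv_deviance(Z, y, selected, splits)
        while len(selected) < spec.max_vars:
            best_j, best_dev = None, current
            for j in order:
                if j in selected:
                    continue
                dev = self._cv_deviance(Z, y, selected + [j], splits)
                if dev < best_dev - 1e-12:
                    best_j, best_dev = j, dev
            if best_j is None:
                break
            selected.append(int(best_j))
            current = best_dev
            history.append((feature_names[best_j], current))
            if spec.allow_backward and len(selected) > 2:
                improved = True
                while improved and len(selected) > 1:
                    improved = False
                    for j in list(selected[:-1]):
                        trial = [s for s in selected if s != j]
                        dev = self._cv_deviance(Z, y, trial, splits)
                        if dev < current - 1e-12:
                            selected = trial
                            current = dev
                            history.append((f"-{feature_names[j]}", current))
                            improved = True
                            break

        self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        self.selected_idx_ = selected
        self.selected_ = [feature_names[j] for j in selected]
        self.history_ = history
        self.criterion_ = current
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_")
        if isinstance(X, pd.DataFrame):
            return X[self.selected_].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)[:, self.selected_idx_]

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "selected_")
        if indices:
            return np.asarray(self.selected_idx_)
        mask = np.zeros(len(self.feature_names_in_), dtype=bool)
        mask[self.selected_idx_] = True
        return mask


def _cv_misclassification(est, Z, y, folds, seed) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    err = 0.0
    for tr, te in skf.split(Z, y):
        m = clone(est)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(Z[tr], y[tr])
        err += np.mean(m.predict(Z[te]) != y[te])
    return err / folds


class TunedSVMClassifier(BaseEstimator, ClassifierMixin):
    """RBF SVM with seeded grid search over box constraint and kernel scale.

    ``budget`` caps the number of (C, γ) grid points evaluated by 5-fold CV
    misclassification; the default 400 corresponds to a 20×20 log grid over
    10⁻³..10³.  Features are z-scored internally; the decision score is the
    signed distance to the separating hyperplane (threshold 0).
    """

    def __init__(self, budget: int = 400, folds: int = 5, random_state: int = 0):
        self.budget = budget
        self.folds = folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("SVM training needs both classes present")
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        side = max(2, int(np.floor(np.sqrt(self.budget))))
        grid = np.logspace(-3, 3, side)
        best = (np.inf, np.inf, np.inf)  # (error, C, gamma) — ties → smaller C, γ
        for C in grid:
            for gamma in grid:
                err = _cv_misclassification(
                    SVC(C=C, gamma=gamma, kernel="rbf"), Z, y, self.folds, self.random_state
                )
                if (err, C, gamma) < best:
                    best = (err, C, gamma)
        self.cv_error_, self.C_, self.gamma_ = best
        self.svc_ = SVC(C=self.C_, gamma=self.gamma_, kernel="rbf").fit(Z, y)
        self.classes_ = self.svc_.classes_
        return self

    def decision_function(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.decision_function(self.scaler_.transform(np.asarray(X, dtype=float)))

    def predict(self, X):
        return (self.decision_function(X) >= 0.0).astype(int)


class _RUSBoost(BaseEstimator, ClassifierMixin):
    """AdaBoost on a random-undersampled (balanced) training set."""

    def __init__(self, n_estimators=50, learning_rate=1.0, min_samples_leaf=1, random_state=0):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        rng = np.random.default_rng(self.random_state)
        classes, counts = np.unique(y, return_counts=True)
        n_min = counts.min()
        keep = []
        for c in classes:
            idx = np.flatnonzero(y == c)
            if len(idx) > n_min:
                idx = rng.choice(idx, size=n_min, replace=False)
            keep.append(idx)
        keep = np.concatenate(keep)
        self.booster_ = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(
                max_depth=3, min_samples_leaf=self.min_samples_leaf
            ),
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            random_state=self.random_state,
        ).fit(X[keep], y[keep])
        self.classes_ = self.booster_.classes_
        return self

    def predict(self, X):
        return self.booster_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        return self.booster_.predict_proba(np.asarray(X, dtype=float))


def _ensemble_candidate(algorithm, n_estimators, learning_rate, min_samples_leaf, seed):
    tree = DecisionTreeClassifier(max_depth=3, min_samples_leaf=min_samples_leaf)
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=n_estimators, min_samples_leaf=min_samples_leaf, random_state=seed
        )
    if algorithm == "adaboost":
        return AdaBoostClassifier(
            estimator=tree, n_estimators=n_estimators,
            learning_rate=learning_rate, random_state=seed,
        )
    if algorithm == "logitboost":  # adaptive logistic regression: stagewise log-loss
        return GradientBoostingClassifier(
            loss="log_loss", n_estimators=n_estimators, learning_rate=learning_rate,
            max_depth=2, min_samples_leaf=min_samples_leaf, random_state=seed,
        )
    if algorithm == "gentleboost":  # exponential-loss stagewise fit
        return GradientBoostingClassifier(
            loss="exponential", n_estimators=n_estimators, learning_rate=learning_rate,
            max_depth=2, min_samples_leaf=min_samples_leaf, random_state=seed,
        )
    if algorithm == "rusboost":
        return _RUSBoost(
            n_estimators=n_estimators, learning_rate=learning_rate,
            min_samples_leaf=min_samples_leaf, random_state=seed,
        )
    raise ValueError(f"unknown ensemble algorithm {algorithm!r}")


ENSEMBLE_ALGORITHMS = ("random_forest", "adaboost", "logitboost", "gentleboost", "rusboost")


class TunedEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Tree-ensemble model with seeded random hyperparameter search.

    Draws ``budget`` configurations over algorithm × (learning cycles,
    learning rate, minimum leaf size) and keeps the one with the lowest
    5-fold CV misclassification.  Score = probability of the positive
    class, threshold 0.5.
    """

    def __init__(self, budget: int = 60, folds: int = 5, random_state: int = 0):
        self.budget = budget
        self.folds = folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("ensemble training needs both classes present")
        rng = np.random.default_rng(self.random_state)
        best = None
        for b in range(self.budget):
            cfg = {
                "algorithm": ENSEMBLE_ALGORITHMS[rng.integers(len(ENSEMBLE_ALGORITHMS))],
                "n_estimators": int(rng.choice([25, 50, 100, 200])),
                "learning_rate": float(10 ** rng.uniform(-2, 0)),
                "min_samples_leaf": int(rng.choice([1, 2, 5, 10, 20])),
            }
            # a boosting config can legitimately fail on small noisy folds
            # ("worse than random"); such draws are skipped
            try:
                est = _ensemble_candidate(**cfg, seed=self.random_state)
                err = _cv_misclassification(est, X, y, self.folds, self.random_state)
                fitted = _ensemble_candidate(**cfg, seed=self.random_state)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fitted.fit(X, y)
            except Exception:
                continue
            key = (err, b)  # earlier draw wins ties → deterministic
            if best is None or key < best[0]:
                best = (key, cfg, fitted)
        if best is None:
            raise ValueError("no ensemble configuration could be fit to this data")
        self.cv_error_ = best[0][0]
        self.config_ = best[1]
        self.model_ = best[2]
        self.classes_ = self.model_.classes_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.decision_function(X) >= 0.5).astype(int)


class KernelNaiveBayesClassifier(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian or kernel densities.

    The density type and the kernel bandwidth factor (× Silverman's rule)
    are chosen by seeded 5-fold CV misclassification.  The score is the
    posterior probability of the positive class under empirical priors;
    threshold 0.5.  A zero-variance feature within a class falls back to a
    minimum-bandwidth kernel density.
    """

    BANDWIDTH_FACTORS = (0.5, 1.0, 2.0)

    def __init__(self, folds: int = 5, random_state: int = 0):
        self.folds = folds
        self.random_state = random_state

    def _fit_densities(self, X, y, kind, bw_factor):
        model = {"kind": kind, "bw_factor": bw_factor, "classes": {}, "priors": {}}
        global_sd = X.std(axis=0)
        global_sd[global_sd == 0] = 1.0
        for c in np.unique(y):
            Xc = X[y == c]
            model["priors"][int(c)] = len(Xc) / len(X)
            params = []
            for j in range(X.shape[1]):
                v = Xc[:, j]
                sd = v.std(ddof=1) if len(v) > 1 else 0.0
                if kind == "gaussian":
                    if sd == 0:
                        # degenerate: minimum-bandwidth kernel on the point mass
                        params.append(("kernel", v.copy(), 1e-3 * global_sd[j]))
                    else:
                        params.append(("gaussian", float(v.mean()), float(sd)))
                else:
                    h = bw_factor * 1.06 * sd * len(v) ** (-1 / 5)
                    if h <= 0:
                        h = 1e-3 * global_sd[j]
                    params.append(("kernel", v.copy(), float(h)))
            model["classes"][int(c)] = params
        return model

    @staticmethod
    def _log_density(params, x):
        kind = params[0]
        if kind == "gaussian":
            _, mu, sd = params
            return norm.logpdf(x, mu, sd)
        _, pts, h = params
        # mean of Gaussian kernels, computed in log space for stability
        z = norm.logpdf(x[:, None], pts[None, :], h)
        m = z.max(axis=1)
        return m + np.log(np.exp(z - m[:, None]).mean(axis=1))

    def _posterior(self, model, X):
        classes = sorted(model["classes"])
        logp = np.zeros((len(X), len(classes)))
        for k, c in enumerate(classes):
            lp = np.log(model["priors"][c])
            for j, params in enumerate(model["classes"][c]):
                lp = lp + self._log_density(params, X[:, j])
            logp[:, k] = lp
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        return p / p.sum(axis=1, keepdims=True), classes

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("naive Bayes training needs both classes present")
        candidates = [("gaussian", 1.0)] + [("kernel", f) for f in self.BANDWIDTH_FACTORS]
        skf = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=self.random_state)
        best = None
        for kind, bw in candidates:
            err = 0.0
            for tr, te in skf.split(X, y):
                model = self._fit_densities(X[tr], y[tr], kind, bw)
                post, classes = self._posterior(model, X[te])
                pred = np.asarray(classes)[post.argmax(axis=1)]
                err += np.mean(pred != y[te])
            err /= self.folds
            if best is None or err < best[0] - 1e-12:
                best = (err, kind, bw)
        self.cv_error_, self.kind_, self.bandwidth_factor_ = best
        self.model_ = self._fit_densities(X, y, self.kind_, self.bandwidth_factor_)
        self.classes_ = np.asarray(sorted(self.model_["classes"]))
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        post, _ = self._posterior(self.model_, np.asarray(X, dtype=float))
        return post

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.decision_function(X) >= 0.5).astype(int)


@dataclass
class FittedModel:
    """A trained classifier bound to its selected features.

    ``score`` is the model's continuous risk score (higher = fibrosis);
    predicted class is ``score ≥ threshold``.
    """

    family: str
    features: list[str]
    estimator: BaseEstimator
    threshold: float
    hyperparameters: dict = field(default_factory=dict)

    def score(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(table, pd.DataFrame):
            missing = [f for f in self.features if f not in table.columns]
            if missing:
                raise KeyError(f"table is missing model features: {missing}")
            X = table[self.features].to_numpy(dtype=float)
        else:
            X = np.asarray(table, dtype=float)
        return np.asarray(self.estimator.decision_function(X), dtype=float)

    def predict(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        return (self.score(table) >= self.threshold).astype(int)

    def save(self, path) -> None:
        import pickle

        with open(path, "wb") as fh:
            pickle.dump({"version": 1, "model": self}, fh)

    @staticmethod
    def load(path) -> "FittedModel":
        import pickle

        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        return payload["model"]


def stepwise_forward_select(
    table: pd.DataFrame, spec: SelectionSpec | None = None
) -> list[str]:
    """Forward-select feature names from a labelled feature table."""
    spec = spec or SelectionSpec()
    feats = feature_columns(table)
    sel = StepwiseDevianceSelector(
        max_vars=spec.max_vars,
        folds=spec.folds,
        allow_backward=spec.allow_backward,
        random_state=spec.seed,
    ).fit(table[feats], table["label"].to_numpy())
    return sel.selected_


def _train(family, est, table, features, threshold) -> FittedModel:
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    est.fit(table[list(features)].to_numpy(dtype=float), table["label"].to_numpy())
    hp: dict = {}
    if family == "svm":
        hp = {"C": est.C_, "gamma": est.gamma_, "cv_error": est.cv_error_}
    elif family == "eml":
        hp = {**est.config_, "cv_error": est.cv_error_}
    elif family == "nb":
        hp = {
            "distribution": est.kind_,
            "bandwidth_factor": est.bandwidth_factor_,
            "cv_error": est.cv_error_,
        }
    return FittedModel(family, list(features), est, threshold, hp)


def train_svm(table, features, seed: int = 0, budget: int = 400) -> FittedModel:
    """Tuned RBF SVM on the selected features (score threshold 0)."""
    return _train("svm", TunedSVMClassifier(budget=budget, random_state=seed),
                  table, features, 0.0)


def train_ensemble(table, features, seed: int = 0, budget: int = 60) -> FittedModel:
    """Tuned tree ensemble on the selected features (probability threshold 0.5)."""
    return _train("eml", TunedEnsembleClassifier(budget=budget, random_state=seed),
                  table, features, 0.5)


def train_nb(table, features, seed: int = 0) -> FittedModel:
    """Naive Bayes with searched density type (posterior threshold 0.5)."""
    return _train("nb", KernelNaiveBayesClassifier(random_state=seed),
                  table, features, 0.5)
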