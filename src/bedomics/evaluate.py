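"""Model evaluation: repeated CV, gate, dose-response vetting, profiling.

The evaluation contract mirrors the clinical acceptance procedure:
per-repeat stratified 5-fold cross-validation yields pooled out-of-fold
sensitivity, specificity and Mann–Whitney AUC; means and empirical 95%
percentile intervals are reported over repeats.  A model is accepted only
if mean sensitivity ≥ 0.75, specificity ≥ 0.75, AUC ≥ 0.85 *and* its score
is monotonically non-decreasing in the chosen BED feature (a model whose
predicted risk falls with increasing dose is biologically inconsistent and
discarded, whatever its discrimination).

Two cross-validation modes exist because oversampling before the fold
split leaks information: ``paper`` augments the whole table once and folds
the augmented rows (the described procedure; optimistic), ``safe``
augments inside each training fold only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .augment import AdasynParams, adasyn, clamp_k
from .select_train import FittedModel
from .synthetic import feature_columns

__all__ = [
    "CVSpec",
    "GateSpec",
    "EvalReport",
    "auc",
    "repeated_cv",
    "evaluate_on_original",
    "univariate_tests",
    "monotonicity_vetting",
    "model_gate",
    "extreme_patients",
]


@dataclass(frozen=True)
class CVSpec:
    folds: int = 5
    repeats: int = 500
    seed: int = 0
    leakage_mode: str = "paper"  # paper: augment once; safe: augment in-fold
    adasyn_params: AdasynParams | None = None

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")
        if self.leakage_mode not in ("paper", "safe"):
            raise ValueError("leakage_mode must be 'paper' or 'safe'")


@dataclass(frozen=True)
class GateSpec:
    min_sensitivity: float = 0.75
    min_specificity: float = 0.75
    min_auc: float = 0.85


@dataclass
class EvalReport:
    sensitivity: tuple[float, float, float]  # (mean, 2.5%, 97.5%)
    specificity: tuple[float, float, float]
    auc: tuple[float, float, float]
    repeats: int
    original: dict | None = None  # sens/spec/auc on the non-augmented table
    monotonicity_pass: bool | None = None
    gate_accept: bool | None = None
    gate_reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "sensitivity": dict(zip(("mean", "ci_low", "ci_high"), self.sensitivity)),
            "specificity": dict(zip(("mean", "ci_low", "ci_high"), self.specificity)),
            "auc": dict(zip(("mean", "ci_low", "ci_high"), self.auc)),
            "repeats": self.repeats,
        }
        if self.original is not None:
            out["original"] = self.original
        if self.monotonicity_pass is not None:
            out["monotonicity_pass"] = self.monotonicity_pass
        if self.gate_accept is not None:
            out["gate"] = {"accept": self.gate_accept, "reasons": self.gate_reasons}
        return out


def auc(scores, labels) -> float:
    """Mann–Whitney AUC: P(score⁺ > score⁻), ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)  # midranks handle ties
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _confusion_metrics(y, pred) -> tuple[float, float]:
    y = np.asarray(y).astype(int)
    pred = np.asarray(pred).astype(int)
    tp = int(((y == 1) & (pred == 1)).sum())
    tn = int(((y == 0) & (pred == 0)).sum())
    fp = int(((y == 0) & (pred == 1)).sum())
    fn = int(((y == 1) & (pred == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def _stratified_folds(y, folds, rng):
    """Seeded stratified fold assignment; every fold holds both classes."""
    y = np.asarray(y).astype(int)
    for _ in range(100):
        assign = np.empty(len(y), dtype=int)
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            idx = idx[rng.permutation(len(idx))]
            assign[idx] = np.arange(len(idx)) % folds
        ok = all(
            len(np.unique(y[assign == f])) == 2 for f in range(folds)
        )
        if ok:
            return assign
    raise ValueError("could not build stratified folds with both classes per fold")


def repeated_cv(
    table: pd.DataFrame,
    recipe: Callable[[pd.DataFrame, int], FittedModel],
    spec: CVSpec | None = None,
) -> EvalReport:
    """Repeated stratified k-fold CV of a train-and-score recipe.

    ``recipe(train_table, seed)`` must return a :class:`FittedModel`.  Per
    repeat, out-of-fold scores are pooled into one sensitivity,
    specificity and AUC; the report carries means and empirical 2.5/97.5
    percentiles over repeats.
    """
    spec = spec or CVSpec()
    ap = spec.adasyn_params or AdasynParams(seed=spec.seed)

    if spec.leakage_mode == "paper":
        work = adasyn(table, clamp_k(table, ap))
    else:
        work = table.reset_index(drop=True)

    y_all = work["label"].to_numpy().astype(int)
    sens_r, spec_r, auc_r = [], [], []
    for rep in range(spec.repeats):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7_001, rep]))
        assign = _stratified_folds(y_all, spec.folds, rng)
        scores = np.empty(len(work))
        preds = np.empty(len(work), dtype=int)
        for f in range(spec.folds):
            te = np.flatnonzero(assign == f)
            tr = np.flatnonzero(assign != f)
            train_tbl = work.iloc[tr].reset_index(drop=True)
            if spec.leakage_mode == "safe":
                fold_params = AdasynParams(
                    ap.k, ap.beta, seed=int((ap.seed + 97 * rep + f) % 2**31)
                )
                train_tbl = adasyn(train_tbl, clamp_k(train_tbl, fold_params))
            model = recipe(train_tbl, int((spec.seed + 1_000_003 * rep + f) % 2**31))
            s = model.score(work.iloc[te])
            scores[te] = s
            preds[te] = (s >= model.threshold).astype(int)
        se, sp = _confusion_metrics(y_all, preds)
        sens_r.append(se)
        spec_r.append(sp)
        auc_r.append(auc(scores, y_all))

    def summarize(v):
        v = np.asarray(v, dtype=float)
        return (float(np.nanmean(v)), float(np.nanpercentile(v, 2.5)),
                float(np.nanpercentile(v, 97.5)))

    return EvalReport(
        sensitivity=summarize(sens_r),
        specificity=summarize(spec_r),
        auc=summarize(auc_r),
        repeats=spec.repeats,
    )


def evaluate_on_original(model: FittedModel, original: pd.DataFrame) -> dict:
    """Resubstitution-style metrics of a final model on the raw cohort."""
    s = model.score(original)
    y = original["label"].to_numpy().astype(int)
    pred = (s >= model.threshold).astype(int)
    sens, spec_ = _confusion_metrics(y, pred)
    return {"sensitivity": sens, "specificity": spec_, "auc": auc(s, y)}


def univariate_tests(table: pd.DataFrame, label_col: str = "label") -> pd.DataFrame:
    """Per-variable association with the outcome.

    Categorical variables (non-numeric or ≤ 5 distinct values) get a
    chi-square test of independence on the variable × outcome contingency
    table; continuous variables get a two-sided Wilcoxon–Mann–Whitney test
    (exact for small samples, tie-corrected normal approximation
    otherwise).  A warning column flags contingency tables with expected
    cells below 1.
    """
    y = table[label_col].to_numpy().astype(int)
    rows = []
    for col in table.columns:
        if col in (label_col, "patient_id", "is_synthetic"):
            continue
        v = table[col]
        is_cat = (not pd.api.types.is_numeric_dtype(v)) or v.nunique() <= 5
        warning = ""
        if is_cat:
            if v.nunique() < 2:
                continue
            ct = pd.crosstab(v, y)
            chi2, p, dof, expected = stats.chi2_contingency(ct)
            if (expected < 1).any():
                warning = "expected cell < 1"
            rows.append({"variable": col, "test": "chi-square", "statistic": chi2,
                         "p_value": p, "warning": warning})
        else:
            a = v[y == 1].to_numpy(dtype=float)
            b = v[y == 0].to_numpy(dtype=float)
            method = "exact" if min(len(a), len(b)) < 15 else "asymptotic"
            try:
                res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            except ValueError:
                res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            rows.append({"variable": col, "test": "wilcoxon", "statistic": float(res.statistic),
                         "p_value": float(res.pvalue), "warning": warning})
    return pd.DataFrame(rows)


def monotonicity_vetting(
    model: FittedModel,
    bed_feature: str,
    table: pd.DataFrame,
    profile: str = "mean",
    n_grid: int = 100,
    fraction: float = 0.05,
) -> dict:
    """Check that the model score rises monotonically with a BED feature.

    The score is evaluated on ``n_grid`` points spanning the observed range
    of ``bed_feature`` with every other selected feature pinned to a
    profile: the cohort mean, or the mean of the extreme low-/high-score
    patients.  Verdict is pass iff the curve is non-decreasing up to
    ``1e-6 ×`` the score range.
    """
    if bed_feature not in model.features:
        raise ValueError(f"{bed_feature!r} is not among the model features {model.features}")
    x = table[bed_feature].to_numpy(dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError(f"{bed_feature!r} has zero observed range")

    if profile == "mean":
        base = {f: float(table[f].mean()) for f in model.features}
    elif profile in ("low_risk", "high_risk"):
        scores = model.score(table)
        y = table["label"].to_numpy().astype(int)
        low_tbl, high_tbl = extreme_patients(scores, y, table, model.features, fraction)
        src = low_tbl if profile == "low_risk" else high_tbl
        base = {f: float(src[f].mean()) for f in model.features}
    else:
        raise ValueError(f"unknown profile {profile!r}")

    grid = np.linspace(lo, hi, n_grid)
    X = pd.DataFrame({f: np.full(n_grid, base[f]) for f in model.features})
    X[bed_feature] = grid
    curve = model.score(X)
    rng_score = float(curve.max() - curve.min())
    eps = 1e-6 * rng_score if rng_score > 0 else 1e-12
    drops = np.flatnonzero(np.diff(curve) < -eps)
    verdict = len(drops) == 0
    return {
        "pass": bool(verdict),
        "feature": bed_feature,
        "profile": profile,
        "grid": grid,
        "curve": curve,
        "first_decrease_at": (float(grid[drops[0] + 1]) if len(drops) else None),
        "n_decreases": int(len(drops)),
    }


def model_gate(report: EvalReport, gate: GateSpec | None = None) -> tuple[bool, list[str]]:
    """Accept/reject with explicit reasons; ≥ semantics at the thresholds."""
    gate = gate or GateSpec()
    reasons = []
    if report.sensitivity[0] < gate.min_sensitivity:
        reasons.append(
            f"sensitivity {report.sensitivity[0]:.3f} < {gate.min_sensitivity}"
        )
    if report.specificity[0] < gate.min_specificity:
        reasons.append(
            f"specificity {report.specificity[0]:.3f} < {gate.min_specificity}"
        )
    if report.auc[0] < gate.min_auc:
        reasons.append(f"AUC {report.auc[0]:.3f} < {gate.min_auc}")
    if report.monotonicity_pass is False:
        reasons.append("non-monotonic dose response")
    accept = not reasons
    report.gate_accept = accept
    report.gate_reasons = reasons
    return accept, reasons


def extreme_patients(
    scores,
    labels,
    table: pd.DataFrame,
    features: list[str] | None = None,
    fraction: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature profiles of the extreme-score patients.

    Returns the bottom ``fraction`` (ceiling-rounded) of negatives by score
    and the top ``fraction`` of positives, each with an appended
    group-average row.  Ties break on stable patient order.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    features = features or feature_columns(table)
    if np.ptp(scores) == 0:
        warnings.warn("all scores identical; extreme subsets are arbitrary", stacklevel=2)

    def pick(cls, take_low):
        idx = np.flatnonzero(labels == cls)
        n = max(1, math.ceil(fraction * len(idx)))
        if len(idx) < 1 / fraction:
            warnings.warn(
                f"class {cls} has fewer than {int(1 / fraction)} members; using all",
                stacklevel=2,
            )
        order = idx[np.argsort(scores[idx], kind="stable")]
        chosen = order[:n] if take_low else order[::-1][:n]
        sub = table.iloc[chosen][features].copy()
        sub.insert(0, "score", scores[chosen])
        avg = sub.mean(numeric_only=True).to_frame().T
        avg.index = ["average"]
        return pd.concat([sub.reset_index(drop=True), avg])

    return pick(0, take_low=True), pick(1, take_low=False)
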