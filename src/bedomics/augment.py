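"""ADASYN oversampling of the minority (fibrosis) class.

Adaptive synthetic sampling allocates new minority points according to the
local density of majority neighbors: for each minority point ``x_i`` with
``Δ_i`` majority points among its ``k`` nearest neighbors (over all
classes), ``r_i = Δ_i / k`` is normalized to ``r̂_i = r_i / Σ r`` and the
point receives ``g_i = round(r̂_i · G)`` synthetic children, where
``G = β (n_maj − n_min)`` is the total deficit.  Each child is a convex
combination ``x_i + λ (x_z − x_i)``, λ ~ U(0,1), of ``x_i`` and a uniformly
chosen member ``x_z`` of its ``k`` nearest *minority* neighbors.

Distances are Euclidean on z-scored features (radiomics columns span many
orders of magnitude); synthesis happens in original units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .synthetic import feature_columns

__all__ = ["AdasynParams", "ADASYN", "adasyn", "verify_augmentation"]


@dataclass(frozen=True)
class AdasynParams:
    k: int = 5
    beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")


class ADASYN(BaseEstimator):
    """Adaptive synthetic minority oversampling.

    Parameters
    ----------
    k : int, default=5
        Neighbor count for both the difficulty estimate and the
        interpolation partner pool.
    beta : float, default=1.0
        Balance level; 1 removes the class imbalance entirely.
    random_state : int, default=0

    Attributes
    ----------
    minority_class_ : int
        The less frequent label in the data passed to :meth:`fit_resample`.
    allocation_ : ndarray
        Synthetic points allotted to each minority sample (``g_i``).
    """

    def __init__(self, k: int = 5, beta: float = 1.0, random_state: int = 0):
        self.k = k
        self.beta = beta
        self.random_state = random_state

    def fit_resample(self, X, y):
        """Return ``(X_aug, y_aug, is_synthetic)`` with originals first, unchanged."""
        import warnings

        params = AdasynParams(self.k, self.beta, self.random_state)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError(f"ADASYN needs exactly 2 classes, got {list(classes)}")
        minority = classes[np.argmin(counts)]
        n_min, n_maj = counts.min(), counts.max()
        if n_min < params.k + 1:
            raise ValueError(
                f"minority class has {n_min} samples; needs at least k+1={params.k + 1}"
            )
        self.minority_class_ = minority

        G = int(round(params.beta * (n_maj - n_min)))
        min_idx = np.flatnonzero(y == minority)
        if G == 0:
            self.allocation_ = np.zeros(len(min_idx), dtype=int)
            return X.copy(), y.copy(), np.zeros(len(y), dtype=bool)

        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd

        # difficulty: majority fraction among k nearest neighbors, all classes
        nn_all = NearestNeighbors(n_neighbors=params.k + 1).fit(Z)
        _, idx_all = nn_all.kneighbors(Z[min_idx])
        r = np.empty(len(min_idx))
        for a, (i, neigh) in enumerate(zip(min_idx, idx_all)):
            neigh = neigh[neigh != i][: params.k]
            r[a] = np.mean(y[neigh] != minority)
        if r.sum() == 0:
            warnings.warn(
                "no minority point has majority neighbors; "
                "falling back to uniform allocation",
                stacklevel=2,
            )
            g = np.full(len(min_idx), G / len(min_idx))
        else:
            g = (r / r.sum()) * G
        g = np.floor(g + 0.5).astype(int)  # round half up
        self.allocation_ = g

        # interpolation partners: minority-only neighborhoods
        k_min = min(params.k, len(min_idx) - 1)
        nn_min = NearestNeighbors(n_neighbors=k_min + 1).fit(Z[min_idx])
        _, idx_min = nn_min.kneighbors(Z[min_idx])

        rng = np.random.default_rng(params.seed)
        new_rows = []
        for a, gi in enumerate(g):
            partners = idx_min[a][idx_min[a] != a][:k_min]
            xi = X[min_idx[a]]
            for _ in range(gi):
                z = min_idx[partners[rng.integers(len(partners))]]
                lam = rng.uniform()
                new_rows.append(xi + lam * (X[z] - xi))
        if new_rows:
            X_aug = np.vstack([X, np.asarray(new_rows)])
            y_aug = np.concatenate([y, np.full(len(new_rows), minority, dtype=y.dtype)])
        else:
            X_aug, y_aug = X.copy(), y.copy()
        flag = np.zeros(len(y_aug), dtype=bool)
        flag[len(y):] = True
        return X_aug, y_aug, flag


def clamp_k(table: pd.DataFrame, params: AdasynParams) -> AdasynParams:
    """Reduce k to what the minority class supports (small training folds)."""
    n_min = int(table["label"].value_counts().min())
    k = min(params.k, max(1, n_min - 1))
    return AdasynParams(k, params.beta, params.seed)


def adasyn(table: pd.DataFrame, params: AdasynParams | None = None) -> pd.DataFrame:
    """Augment a feature table to class balance; synthetic rows flagged.

    The table needs a ``label`` column; feature columns are all
    non-metadata columns.  Original rows are passed through bit-identical,
    synthetic rows get ``is_synthetic=True`` and fresh patient ids.
    """
    params = params or AdasynParams()
    feats = feature_columns(table)
    est = ADASYN(k=params.k, beta=params.beta, random_state=params.seed)
    X_aug, y_aug, flag = est.fit_resample(table[feats].to_numpy(), table["label"].to_numpy())

    out = table.copy().reset_index(drop=True)
    out["is_synthetic"] = False
    n_new = int(flag.sum())
    if n_new:
        syn = pd.DataFrame(X_aug[len(table):], columns=feats)
        syn["label"] = y_aug[len(table):]
        syn["is_synthetic"] = True
        syn["patient_id"] = [f"SYN{i:04d}" for i in range(n_new)]
        out = pd.concat([out, syn], ignore_index=True)
    return out


def verify_augmentation(original: pd.DataFrame, augmented: pd.DataFrame) -> dict:
    """Sanity report on an augmentation run.

    Checks the original rows are unchanged, reports class counts, whether
    each synthetic feature value lies within the minority bounding box, and
    nearest-original distances of the synthetic rows.
    """
    feats = feature_columns(original)
    n_orig = len(original)
    head = augmented.iloc[:n_orig]
    if not np.allclose(
        head[feats].to_numpy(), original[feats].to_numpy(), equal_nan=True
    ) or not (head["label"].to_numpy() == original["label"].to_numpy()).all():
        raise ValueError("original rows were mutated by augmentation")

    syn = augmented[augmented.get("is_synthetic", False) == True]  # noqa: E712
    counts = augmented["label"].value_counts().to_dict()
    minority = original["label"].value_counts().idxmin()
    mins = original.loc[original["label"] == minority, feats].min()
    maxs = original.loc[original["label"] == minority, feats].max()
    if len(syn):
        within = (
            (syn[feats].to_numpy() >= mins.to_numpy() - 1e-9)
            & (syn[feats].to_numpy() <= maxs.to_numpy() + 1e-9)
        ).all()
        d = np.sqrt(
            (
                (syn[feats].to_numpy()[:, None, :] - original[feats].to_numpy()[None, :, :])
                ** 2
            ).sum(-1)
        ).min(axis=1)
        nearest = {"min": float(d.min()), "mean": float(d.mean()), "max": float(d.max())}
    else:
        within, nearest = True, {"min": 0.0, "mean": 0.0, "max": 0.0}
    return {
        "class_counts": {int(k): int(v) for k, v in counts.items()},
        "n_synthetic": int(len(syn)),
        "minority_fraction": float(
            (augmented["label"] == minority).mean()
        ),
        "synthetic_within_minority_box": bool(within),
        "nearest_original_distance": nearest,
    }
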