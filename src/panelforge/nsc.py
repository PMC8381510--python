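"""Nearest-shrunken-centroid classification.

For classes k with sizes n_k, feature-j class centroids x̄_jk and overall
centroid x̄_j, pooled within-class SD s_j (n - K denominator) and fudge
constant s0 = median(s_j), the standardized centroid deviation is

    d_jk = (x̄_jk - x̄_j) / (m_k (s_j + s0)),

with the class SE factor m_k = sqrt(1/n_k + 1/n) by default (the "+"
convention; published descriptions of the statistic differ on the sign of
the 1/n term, so the convention is a parameter).  Soft-thresholding by a
shrinkage threshold Δ,

    d'_jk = sign(d_jk) max(|d_jk| - Δ, 0),

yields shrunken centroids x̄'_jk = x̄_j + m_k (s_j + s0) d'_jk.  A sample
x* is scored by the discriminant

    δ_k(x*) = Σ_j (x*_j - x̄'_jk)² / (s_j + s0)² - 2 log π_k,

with class posteriors exp(-δ_k/2) normalized over classes (computed after
subtracting the minimum δ for numerical stability).  Δ is chosen by
stratified K-fold cross-validation over an evenly spaced grid from 0 to
the largest |d_jk|, taking the largest Δ among ties (fewest surviving
features).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .core_model import OmicsMatrix, PanelforgeError

logger = logging.getLogger(__name__)


@dataclass
class NscModel:
    """A fitted nearest-shrunken-centroid model (features x classes)."""

    classes: list[str]
    feature_ids: list[str]
    n_k: np.ndarray
    centroids: np.ndarray        # x̄_jk, features x classes
    overall_centroid: np.ndarray  # x̄_j
    s: np.ndarray                 # pooled within-class SD per feature
    s0: float
    m_k: np.ndarray
    delta: float
    d: np.ndarray                 # d_jk, features x classes
    d_shrunk: np.ndarray          # d'_jk
    shrunken_centroids: np.ndarray
    priors: np.ndarray

    def surviving_features(self) -> list[str]:
        """Features with a nonzero shrunken deviation in any class."""
        mask = (self.d_shrunk != 0).any(axis=1)
        return [f for f, keep in zip(self.feature_ids, mask) if keep]


def _as_matrix(m: OmicsMatrix | pd.DataFrame) -> pd.DataFrame:
    return m.values if isinstance(m, OmicsMatrix) else m


def nsc_fit(
    m: OmicsMatrix | pd.DataFrame,
    labels: pd.Series,
    delta: float = 0.0,
    priors: str | np.ndarray = "proportional",
    se_convention: str = "+",
) -> NscModel:
    """Fit shrunken centroids at threshold ``delta``.

    ``labels`` maps sample IDs to class labels; classes are ordered by
    first appearance.  ``priors`` is ``"proportional"`` (class frequencies),
    ``"uniform"``, or an explicit vector.  ``se_convention`` selects
    m_k = sqrt(1/n_k + 1/n) (``"+"``) or sqrt(1/n_k - 1/n) (``"-"``).
    """
    if delta < 0:
        raise PanelforgeError("delta must be >= 0")
    if se_convention not in ("+", "-"):
        raise PanelforgeError("se_convention must be '+' or '-'")
    vals = _as_matrix(m)
    labels = pd.Series(labels).reindex(vals.columns)
    if labels.isna().any():
        raise PanelforgeError("labels missing for some samples")
    classes = list(pd.unique(labels))
    if len(classes) < 2:
        raise PanelforgeError("need at least 2 classes")
    x = vals.to_numpy(dtype=float)
    p, n = x.shape
    K = len(classes)
    masks = [labels.to_numpy() == c for c in classes]
    n_k = np.array([mask.sum() for mask in masks])
    if (n_k < 2).any():
        small = [c for c, nk in zip(classes, n_k) if nk < 2]
        raise PanelforgeError(f"class(es) with fewer than 2 samples: {small}")

    centroids = np.column_stack([x[:, mask].mean(axis=1) for mask in masks])
    overall = x.mean(axis=1)
    ss = np.zeros(p)
    for j, mask in enumerate(masks):
        ss += ((x[:, mask] - centroids[:, [j]]) ** 2).sum(axis=1)
    s = np.sqrt(ss / (n - K))
    s0 = float(np.median(s))
    if np.any(s + s0 == 0):
        raise PanelforgeError(
            "degenerate fit: zero pooled within-class SD and zero fudge constant"
        )
    if se_convention == "+":
        m_k = np.sqrt(1.0 / n_k + 1.0 / n)
    else:
        m_k = np.sqrt(np.maximum(1.0 / n_k - 1.0 / n, 0.0))

    denom = np.outer(s + s0, m_k)
    d = (centroids - overall[:, None]) / denom
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = overall[:, None] + denom * d_shrunk

    if isinstance(priors, str):
        if priors == "proportional":
            pri = n_k / n
        elif priors == "uniform":
            pri = np.full(K, 1.0 / K)
        else:
            raise PanelforgeError("priors must be 'proportional', 'uniform' or a vector")
    else:
        pri = np.asarray(priors, dtype=float)
        if pri.shape != (K,) or not np.isclose(pri.sum(), 1.0):
            raise PanelforgeError("prior vector must have one entry per class and sum to 1")

    return NscModel(
        classes=classes,
        feature_ids=list(vals.index),
        n_k=n_k,
        centroids=centroids,
        overall_centroid=overall,
        s=s,
        s0=s0,
        m_k=m_k,
        delta=float(delta),
        d=d,
        d_shrunk=d_shrunk,
        shrunken_centroids=shrunken,
        priors=pri,
    )


def nsc_score(
    model: NscModel, x: pd.DataFrame | pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Score samples against a fitted model.

    ``x`` is a feature x sample frame (or a single-sample Series indexed by
    feature).  Returns ``(discriminants, posteriors, predicted)`` with one
    row per sample and one column per class.
    """
    if isinstance(x, pd.Series):
        x = x.to_frame(name=x.name if x.name is not None else "sample")
    missing = [f for f in model.feature_ids if f not in x.index]
    if missing:
        raise PanelforgeError(f"sample is missing model feature(s): {missing[:5]}")
    xa = x.loc[model.feature_ids].to_numpy(dtype=float)  # p x n
    scale2 = (model.s + model.s0) ** 2
    # delta_k = sum_j (x_j - c'_jk)^2 / (s_j+s0)^2 - 2 log pi_k
    diff = xa[:, :, None] - model.shrunken_centroids[:, None, :]  # p x n x K
    disc = (diff ** 2 / scale2[:, None, None]).sum(axis=0) - 2.0 * np.log(model.priors)[None, :]
    stab = disc - disc.min(axis=1, keepdims=True)
    w = np.exp(-0.5 * stab)
    post = w / w.sum(axis=1, keepdims=True)
    cols = list(model.classes)
    disc_df = pd.DataFrame(disc, index=x.columns, columns=cols)
    post_df = pd.DataFrame(post, index=x.columns, columns=cols)
    pred = post_df.idxmax(axis=1)
    return disc_df, post_df, pred


def nsc_predict(model: NscModel, x: pd.DataFrame) -> pd.Series:
    return nsc_score(model, x)[2]


def threshold_grid(model: NscModel, n_thresholds: int = 30) -> np.ndarray:
    """Evenly spaced shrinkage grid from 0 to max |d_jk| (inclusive)."""
    return np.linspace(0.0, float(np.abs(model.d).max()), n_thresholds)


def nsc_cv_threshold(
    m: OmicsMatrix | pd.DataFrame,
    labels: pd.Series,
    n_folds: int = 10,
    n_thresholds: int = 30,
    seed: int = 0,
    priors: str | np.ndarray = "proportional",
    se_convention: str = "+",
) -> tuple[float, pd.DataFrame]:
    """Choose the shrinkage threshold by stratified K-fold cross-validation.

    The grid is ``n_thresholds`` values evenly spaced on [0, max|d_jk|] of
    the full-data fit.  The chosen Δ* minimizes the per-sample CV
    misclassification error; ties go to the largest Δ (fewest surviving
    features).  If the smallest class has fewer members than ``n_folds``
    the fold count is reduced with a warning.
    """
    vals = _as_matrix(m)
    labels = pd.Series(labels).reindex(vals.columns)
    full = nsc_fit(vals, labels, 0.0, priors, se_convention)
    grid = threshold_grid(full, n_thresholds)

    y = labels.to_numpy()
    min_class = pd.Series(y).value_counts().min()
    folds = int(min(n_folds, min_class))
    if folds < n_folds:
        logger.warning("reducing CV folds from %d to %d (smallest class)", n_folds, folds)
    if folds < 2:
        raise PanelforgeError("need at least 2 samples per class for CV")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    n = vals.shape[1]
    errors = np.zeros((len(grid), ), dtype=float)
    for train_idx, test_idx in skf.split(np.zeros(n), y):
        tr_cols = vals.columns[train_idx]
        te_cols = vals.columns[test_idx]
        base = nsc_fit(vals[tr_cols], labels.loc[tr_cols], 0.0, priors, se_convention)
        for gi, dlt in enumerate(grid):
            d_shrunk = np.sign(base.d) * np.maximum(np.abs(base.d) - dlt, 0.0)
            shr = base.overall_centroid[:, None] + np.outer(base.s + base.s0, base.m_k) * d_shrunk
            sub = NscModel(**{**base.__dict__, "delta": float(dlt),
                              "d_shrunk": d_shrunk, "shrunken_centroids": shr})
            pred = nsc_score(sub, vals[te_cols])[2]
            errors[gi] += int((pred.to_numpy() != y[test_idx]).sum())
    cv_error = errors / n
    best = cv_error.min()
    # ties -> largest delta
    delta_star = float(grid[np.flatnonzero(cv_error == best).max()])
    path = pd.DataFrame({"delta": grid, "cv_error": cv_error})
    return delta_star, path
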