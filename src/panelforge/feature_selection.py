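"""Random-forest backward elimination and consensus panel selection.

One replicate of the selection pipeline, run on the differential features
of one subtype-vs-rest contrast:

1. fit a random forest (``ntree`` trees, mtry = floor(sqrt(p)) *
   ``mtry_factor``) and record OOB permutation importance (mean decrease
   in OOB accuracy, unscaled) once;
2. repeatedly drop the 20 % least-important remaining features (by the
   initial ranking), refitting with ``ntree_iterat`` trees and recording
   the OOB error, down to 2 features;
3. keep the feature set with the lowest OOB error (ties: smaller set);
4. fit nearest shrunken centroids on the kept set, pick the shrinkage
   threshold by 10-fold CV, and take the top five features by |d'| under
   the constraint that at least two are positively and two negatively
   associated with the target subtype.

The replicate is repeated (300 times by default) with fresh algorithmic
seeds on the same training cohort; the most frequent unordered 5-feature
set is the consensus panel.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .core_model import OmicsMatrix, PanelforgeError
from .nsc import NscModel, nsc_cv_threshold, nsc_fit

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# bagging on top of sklearn decision trees
#
# A plain RandomForestClassifier spends most of its time in per-estimator
# introspection (clone / get_params / input re-validation) at these problem
# sizes, so the bagging loop is written out directly: n-of-n bootstrap,
# gini trees with mtry random features per split, OOB prediction by
# averaged leaf class probabilities.  The model is the standard random
# forest; only the orchestration differs.


@dataclass
class BaggedForest:
    """A fitted bootstrap ensemble of decision trees."""

    trees: list
    oob_masks: list[np.ndarray]
    classes_: np.ndarray
    oob_error_: float


def _tree_proba(tree, x32: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-class leaf probabilities aligned to the global class coding."""
    counts = tree.tree_.predict(x32)
    if counts.ndim == 3:
        counts = counts[:, 0, :]
    proba = counts / counts.sum(axis=1, keepdims=True)
    if proba.shape[1] == n_classes:
        return proba
    full = np.zeros((proba.shape[0], n_classes))
    full[:, tree.classes_.astype(int)] = proba
    return full


def _tree_predict(tree, x32: np.ndarray, n_classes: int) -> np.ndarray:
    return _tree_proba(tree, np.ascontiguousarray(x32), n_classes).argmax(axis=1)


def _fit_forest(
    x: np.ndarray, y: np.ndarray, ntree: int, mtry_factor: float, seed: int
) -> BaggedForest:
    n, p = x.shape
    mtry = min(p, max(1, int(math.floor(math.sqrt(p)) * mtry_factor)))
    rng = np.random.RandomState(seed)
    x32 = np.ascontiguousarray(x, dtype=np.float32)
    n_classes = int(y.max()) + 1
    votes = np.zeros((n, n_classes))
    trees: list = []
    masks: list[np.ndarray] = []
    for _ in range(ntree):
        idx = rng.randint(0, n, n)
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        tree = DecisionTreeClassifier(
            max_features=mtry, random_state=rng.randint(2**31)
        )
        tree.fit(x32[idx], y[idx], check_input=False)
        trees.append(tree)
        masks.append(oob)
        if oob.any():
            votes[oob] += _tree_proba(tree, np.ascontiguousarray(x32[oob]), n_classes)
    covered = votes.sum(axis=1) > 0
    oob_error = float((votes[covered].argmax(axis=1) != y[covered]).mean())
    return BaggedForest(trees, masks, np.arange(n_classes), oob_error)


def oob_permutation_importance(
    forest: BaggedForest, x: np.ndarray, y: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Unscaled mean decrease in per-tree OOB accuracy under permutation.

    Trees that do not use a feature contribute a zero decrease; the mean is
    taken over all trees, matching the classic random-forest importance.
    """
    n, p = x.shape
    x32 = np.asarray(x, dtype=np.float32)
    rng = np.random.default_rng(seed)
    n_classes = len(forest.classes_)
    drops = np.zeros(p)
    for tree, oob in zip(forest.trees, forest.oob_masks):
        n_oob = int(oob.sum())
        if n_oob == 0:
            continue
        xo = np.ascontiguousarray(x32[oob])
        yo = y[oob]
        base = (_tree_predict(tree, xo, n_classes) == yo).mean()
        used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
        for j in used:
            col = xo[:, j].copy()
            xo[:, j] = col[rng.permutation(n_oob)]
            perm_acc = (_tree_predict(tree, xo, n_classes) == yo).mean()
            xo[:, j] = col
            drops[j] += base - perm_acc
    return drops / len(forest.trees)


# ---------------------------------------------------------------------------
# backward elimination


@dataclass
class EliminationTrace:
    """Record of one backward-elimination run."""

    steps: list[dict] = field(default_factory=list)  # n_features, oob_error, feature_ids
    initial_ranking: list[str] = field(default_factory=list)  # most to least important
    selected: list[str] = field(default_factory=list)

    @property
    def sizes(self) -> list[int]:
        return [s["n_features"] for s in self.steps]

    @property
    def oob_path(self) -> dict[int, float]:
        return {s["n_features"]: s["oob_error"] for s in self.steps}


def elimination_sizes(p: int, drop_frac: float = 0.2) -> list[int]:
    """Surviving set sizes: drop round(p_t * drop_frac) (half up, >= 1) each
    step down to 2 features.  Pure arithmetic, exposed for testing."""
    sizes = [p]
    while sizes[-1] > 2:
        drop = max(1, int(math.floor(sizes[-1] * drop_frac + 0.5)))
        sizes.append(max(2, sizes[-1] - drop))
    return sizes


def rf_backward_elimination(
    m: OmicsMatrix | pd.DataFrame,
    labels: pd.Series,
    ntree: int = 1000,
    ntree_iterat: int = 500,
    mtry_factor: float = 1.0,
    drop_frac: float = 0.2,
    seed: int = 0,
) -> EliminationTrace:
    """Backward feature elimination by random-forest OOB error.

    Importance is computed once on the initial forest and the ranking is
    reused for every elimination step; each reduced set is refit with
    ``ntree_iterat`` trees to estimate its OOB error.  The selected set is
    the one with the strictly lowest OOB error (ties: smaller set, then the
    earlier step).
    """
    vals = m.values if isinstance(m, OmicsMatrix) else m
    labels = pd.Series(labels).reindex(vals.columns)
    if labels.isna().any():
        raise PanelforgeError("labels missing for some samples")
    classes = pd.unique(labels)
    if len(classes) < 2:
        raise PanelforgeError("need at least 2 label classes")
    feature_ids = list(vals.index)
    p = len(feature_ids)
    if p < 4:
        raise PanelforgeError("need at least 4 features to eliminate")

    x = vals.to_numpy(dtype=float).T  # samples x features
    y = pd.Categorical(labels).codes.astype(np.int64)

    ss = np.random.SeedSequence(seed)
    fit_seeds = [int(s) % (2**31) for s in ss.generate_state(len(elimination_sizes(p, drop_frac)) + 1)]

    forest = _fit_forest(x, y, ntree, mtry_factor, fit_seeds[0])
    importance = oob_permutation_importance(forest, x, y, seed=fit_seeds[0])
    order = np.argsort(-importance, kind="stable")  # most important first
    ranking = [feature_ids[i] for i in order]

    trace = EliminationTrace(initial_ranking=ranking)
    trace.steps.append(
        {"n_features": p, "oob_error": forest.oob_error_, "feature_ids": list(feature_ids)}
    )
    sizes = elimination_sizes(p, drop_frac)
    col_of = {f: i for i, f in enumerate(feature_ids)}
    for step, size in enumerate(sizes[1:], start=1):
        keep_ids = ranking[:size]
        keep_idx = [col_of[f] for f in keep_ids]
        sub = _fit_forest(x[:, keep_idx], y, ntree_iterat, mtry_factor, fit_seeds[step])
        trace.steps.append(
            {"n_features": size, "oob_error": sub.oob_error_, "feature_ids": keep_ids}
        )

    trace.selected = list(select_lowest_oob(trace.steps)["feature_ids"])
    return trace


def select_lowest_oob(steps: list[dict]) -> dict:
    """Pick the elimination step with the lowest OOB error.

    Ties go to the smaller feature set, then to the earlier step.  The
    "within one SE of the minimum" variant is deliberately not the default;
    strictly-lowest matches the selection rule this pipeline documents.
    """
    if not steps:
        raise PanelforgeError("empty elimination trace")
    return min(
        enumerate(steps), key=lambda t: (t[1]["oob_error"], t[1]["n_features"], t[0])
    )[1]


# ---------------------------------------------------------------------------
# constrained top-5 ranking


def pick_top5_balanced(
    model: NscModel,
    target_class: str,
    n_features: int = 5,
    min_per_sign: int = 2,
) -> list[tuple[str, str]]:
    """Top features by |d'| with a two-per-direction quota.

    Candidates are features whose shrunken deviation for the target class
    is nonzero; when shrinkage leaves too few candidates (or too few of one
    sign) the ranking falls back to the unshrunken |d| over all features
    with a warning.  Returns ``[(feature_id, '+'/'-'), ...]`` in rank order.
    """
    if target_class not in model.classes:
        raise PanelforgeError(f"unknown class {target_class!r}")
    k = model.classes.index(target_class)
    d = model.d[:, k]
    d_shrunk = model.d_shrunk[:, k]

    cand = np.flatnonzero(d_shrunk != 0)
    key = np.abs(d_shrunk)
    signs = d >= 0
    enough = (
        cand.size >= n_features
        and signs[cand].sum() >= min_per_sign
        and (~signs[cand]).sum() >= min_per_sign
    )
    if not enough:
        logger.warning(
            "too few features survive shrinkage for %s; re-ranking by unshrunken d",
            target_class,
        )
        cand = np.arange(d.size)
        key = np.abs(d)
    if signs[cand].sum() < min_per_sign or (~signs[cand]).sum() < min_per_sign:
        raise PanelforgeError("sign constraint unsatisfiable: fewer than "
                              f"{min_per_sign} features of one direction")
    if cand.size < n_features:
        raise PanelforgeError(f"only {cand.size} candidate features, need {n_features}")

    ranked = cand[np.argsort(-key[cand], kind="stable")]
    chosen: list[int] = []
    n_pos = n_neg = 0
    for idx in ranked:
        if len(chosen) == n_features:
            break
        is_pos = bool(signs[idx])
        need_pos = max(0, min_per_sign - n_pos - (1 if is_pos else 0))
        need_neg = max(0, min_per_sign - n_neg - (0 if is_pos else 1))
        slots_after = n_features - len(chosen) - 1
        if slots_after >= need_pos + need_neg:
            chosen.append(int(idx))
            n_pos += int(is_pos)
            n_neg += int(not is_pos)
    if len(chosen) < n_features:
        raise PanelforgeError("sign constraint unsatisfiable with available candidates")
    return [(model.feature_ids[i], "+" if signs[i] else "-") for i in chosen]


# ---------------------------------------------------------------------------
# consensus over replicates


@dataclass
class ConsensusResult:
    """Tally of per-replicate panels and the modal (winning) set."""

    replicates: list[dict]              # feature_set (sorted tuple), directions, cv_error
    frequency: Counter
    winning_set: tuple[str, ...]
    winning_features: list[tuple[str, str]]  # with directions, rank order of first win
    n_failed: int
    tie_break: str

    def frequency_table(self) -> pd.DataFrame:
        rows = []
        for fset, count in self.frequency.most_common():
            errs = [r["cv_error"] for r in self.replicates if r["feature_set"] == fset]
            rows.append({
                "features": ";".join(fset),
                "count": count,
                "mean_cv_error": float(np.mean(errs)),
            })
        return pd.DataFrame(rows)


def consensus_panel(
    m: OmicsMatrix | pd.DataFrame,
    labels: pd.Series,
    target_class: str,
    n_replicates: int = 300,
    seed: int = 0,
    ntree: int = 1000,
    ntree_iterat: int = 500,
    mtry_factor: float = 1.0,
    drop_frac: float = 0.2,
    n_folds: int = 10,
    n_thresholds: int = 30,
) -> ConsensusResult:
    """Repeat the elimination + NSC + top-5 pipeline and keep the modal set.

    Replicates differ only in algorithmic randomness (forest bootstraps and
    CV folds) on the fixed training cohort.  Replicates whose candidate set
    cannot satisfy the sign constraint are skipped with a warning.
    Frequency ties go to the set with lower mean CV error, then to the
    lexicographically smallest feature tuple.
    """
    vals = m.values if isinstance(m, OmicsMatrix) else m
    labels = pd.Series(labels).reindex(vals.columns)
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s) % (2**31) for s in ss.generate_state(2 * n_replicates)]

    replicates: list[dict] = []
    n_failed = 0
    for r in range(n_replicates):
        s_rf, s_cv = rep_seeds[2 * r], rep_seeds[2 * r + 1]
        try:
            trace = rf_backward_elimination(
                vals, labels, ntree=ntree, ntree_iterat=ntree_iterat,
                mtry_factor=mtry_factor, drop_frac=drop_frac, seed=s_rf,
            )
            sub = vals.loc[trace.selected]
            delta_star, path = nsc_cv_threshold(
                sub, labels, n_folds=n_folds, n_thresholds=n_thresholds, seed=s_cv
            )
            cv_error = float(path.loc[path["delta"] == delta_star, "cv_error"].iloc[0])
            model = nsc_fit(sub, labels, delta=delta_star)
            try:
                picked = pick_top5_balanced(model, target_class)
            except PanelforgeError:
                # the lowest-OOB set can be tiny (ties at zero error go to
                # the smallest set); widen the ranking to all candidates so
                # a 2+/2- panel of five can still be formed
                if vals.shape[0] <= sub.shape[0]:
                    raise
                logger.warning(
                    "replicate %d: eliminated set of %d cannot satisfy the "
                    "sign quota; re-ranking over all %d candidates",
                    r, sub.shape[0], vals.shape[0],
                )
                delta_star, path = nsc_cv_threshold(
                    vals, labels, n_folds=n_folds, n_thresholds=n_thresholds, seed=s_cv
                )
                cv_error = float(
                    path.loc[path["delta"] == delta_star, "cv_error"].iloc[0]
                )
                model = nsc_fit(vals, labels, delta=delta_star)
                picked = pick_top5_balanced(model, target_class)
        except PanelforgeError as exc:
            logger.warning("replicate %d failed: %s", r, exc)
            n_failed += 1
            continue
        fset = tuple(sorted(f for f, _ in picked))
        replicates.append(
            {"feature_set": fset, "features": picked, "cv_error": cv_error}
        )
    if not replicates:
        raise PanelforgeError("all consensus replicates failed")

    freq = Counter(r["feature_set"] for r in replicates)
    top_count = max(freq.values())
    tied = [fs for fs, c in freq.items() if c == top_count]
    tie_break = "none"
    if len(tied) > 1:
        mean_err = {
            fs: float(np.mean([r["cv_error"] for r in replicates if r["feature_set"] == fs]))
            for fs in tied
        }
        best_err = min(mean_err.values())
        tied = sorted(fs for fs, e in mean_err.items() if e == best_err)
        tie_break = "mean CV error" if len(tied) == 1 else "lexicographic"
    winner = sorted(tied)[0]
    win_features = next(r["features"] for r in replicates if r["feature_set"] == winner)
    return ConsensusResult(
        replicates=replicates,
        frequency=freq,
        winning_set=winner,
        winning_features=win_features,
        n_failed=n_failed,
        tie_break=tie_break,
    )
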