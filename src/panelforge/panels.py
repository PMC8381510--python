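"""Panel estimation by balanced resampling.

Once a subtype's 5-feature set is fixed, its classifier parameters are
estimated by repeatedly drawing subtype-balanced subcohorts (the same
number m of patients per subtype; one-vs-rest, so the target class has m
samples and the pooled control 2m), re-z-scoring the expression features
across each subcohort (M-value features stay on their absolute scale),
fitting plain nearest centroids (no shrinkage — the features are already
selected) and recording per-iteration centroids, scale terms, 10-fold CV
error rate and the AUC of the target-class posterior.  The final panel
stores the across-iteration means, the SE of each centroid, and mean ± SD
of error and AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .core_model import OmicsMatrix, Panel, PanelforgeError, SampleSheet
from .evaluate import roc_auc
from .nsc import NscModel, nsc_fit, nsc_score

logger = logging.getLogger(__name__)

CONTROL_LABEL = "Control"


@dataclass
class IterationRecord:
    """Per-iteration bookkeeping of the balanced-resampling estimator."""

    replicate: int
    subcohort: list[str]
    centroid_target: np.ndarray
    centroid_control: np.ndarray
    scale: np.ndarray
    error_rate: float
    auc: float


def balanced_subcohort(
    sheet: SampleSheet, m: int | None = None, seed: int = 0
) -> list[str]:
    """Draw m patients per subtype without replacement (default: the
    smallest subtype size, so every subtype is fully balanced)."""
    rng = np.random.default_rng(seed)
    counts = sheet.class_counts()
    if m is None:
        m = min(counts.values())
    bad = [s for s, c in counts.items() if c < m]
    if bad:
        raise PanelforgeError(f"m={m} exceeds subtype size(s) for {bad}")
    picked: list[str] = []
    for subtype in sorted(counts):
        ids = sheet.table.loc[sheet.table["subtype"] == subtype, "sample_id"].tolist()
        idx = rng.choice(len(ids), size=m, replace=False)
        picked += [ids[i] for i in sorted(idx)]
    return picked


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    vals = df.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((vals - mean) / sd, index=df.index, columns=df.columns)


def assemble_feature_block(
    features: list[tuple[str, str, str]],
    expr: OmicsMatrix | None,
    mvals: OmicsMatrix | None,
    sample_ids: list[str],
    rescale_expression: bool = True,
) -> pd.DataFrame:
    """Stack panel features into one feature x sample frame.

    Expression features are z-scored across ``sample_ids`` (per-cohort
    re-normalization); methylation features are taken from the M-value
    matrix unscaled.
    """
    rows = []
    for fid, modality, _ in features:
        if modality == "expression" or modality == "zscore":
            if expr is None or fid not in expr.values.index:
                raise PanelforgeError(f"feature {fid!r} absent from expression matrix")
            rows.append(("expr", fid))
        else:
            if mvals is None or fid not in mvals.values.index:
                raise PanelforgeError(f"feature {fid!r} absent from methylation matrix")
            rows.append(("meth", fid))
    parts = []
    expr_ids = [fid for src, fid in rows if src == "expr"]
    meth_ids = [fid for src, fid in rows if src == "meth"]
    if expr_ids:
        block = expr.values.loc[expr_ids, sample_ids]
        parts.append(_zscore_rows(block) if rescale_expression else block)
    if meth_ids:
        parts.append(mvals.values.loc[meth_ids, sample_ids])
    combined = pd.concat(parts, axis=0)
    # restore panel feature order
    return combined.loc[[fid for _, fid in rows]]


def _cv_error_auc(
    block: pd.DataFrame,
    labels: pd.Series,
    target: str,
    n_folds: int,
    seed: int,
    resubstitution: bool = False,
) -> tuple[float, float]:
    y = labels.to_numpy()
    if resubstitution:
        model = nsc_fit(block, labels, delta=0.0)
        _, post, pred = nsc_score(model, block)
        return float((pred.to_numpy() != y).mean()), roc_auc(post[target], y == target)
    folds = int(min(n_folds, pd.Series(y).value_counts().min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    post_target = np.empty(len(y))
    pred = np.empty(len(y), dtype=object)
    for tr, te in skf.split(np.zeros(len(y)), y):
        model = nsc_fit(block.iloc[:, tr], labels.iloc[tr], delta=0.0)
        _, post, prd = nsc_score(model, block.iloc[:, te])
        post_target[te] = post[target].to_numpy()
        pred[te] = prd.to_numpy()
    return float((pred != y).mean()), roc_auc(post_target, y == target)


def estimate_panel(
    features: list[tuple[str, str, str]],
    expr: OmicsMatrix | None,
    mvals: OmicsMatrix | None,
    sheet: SampleSheet,
    target: str,
    n_iter: int = 300,
    seed: int = 0,
    m: int | None = None,
    n_folds: int = 10,
    error_method: str = "cv",
    keep_iterations: bool = False,
) -> Panel | tuple[Panel, list[IterationRecord]]:
    """Estimate a panel's centroids and performance by balanced resampling.

    ``features`` is a list of (feature_id, modality, direction).  Per
    iteration a balanced subcohort is drawn, panel features are assembled
    (expression re-z-scored across the subcohort), a nearest-centroid model
    (one-vs-rest, proportional priors) is fitted, and error/AUC are
    computed — honestly, from stratified 10-fold CV posteriors, or by
    resubstitution when ``error_method="resubstitution"``.
    """
    if error_method not in ("cv", "resubstitution"):
        raise PanelforgeError("error_method must be 'cv' or 'resubstitution'")
    subtype_of = sheet.subtype_of()
    ss = np.random.SeedSequence(seed)
    iter_seeds = [int(s) % (2**31) for s in ss.generate_state(2 * n_iter)]

    records: list[IterationRecord] = []
    for r in range(n_iter):
        sub = balanced_subcohort(sheet, m=m, seed=iter_seeds[2 * r])
        block = assemble_feature_block(features, expr, mvals, sub)
        labels = subtype_of.loc[sub].where(subtype_of.loc[sub] == target, CONTROL_LABEL)
        # fixed class order: target first
        order = np.argsort([0 if v == target else 1 for v in labels], kind="stable")
        block = block.iloc[:, order]
        labels = labels.iloc[order]
        model = nsc_fit(block, labels, delta=0.0)
        err, auc = _cv_error_auc(
            block, labels, target, n_folds, iter_seeds[2 * r + 1],
            resubstitution=(error_method == "resubstitution"),
        )
        kt = model.classes.index(target)
        kc = model.classes.index(CONTROL_LABEL)
        records.append(
            IterationRecord(
                replicate=r,
                subcohort=sub,
                centroid_target=model.centroids[:, kt],
                centroid_control=model.centroids[:, kc],
                scale=model.s + model.s0,
                error_rate=err,
                auc=auc,
            )
        )

    ct = np.vstack([rec.centroid_target for rec in records])
    cc = np.vstack([rec.centroid_control for rec in records])
    sc = np.vstack([rec.scale for rec in records])
    errs = np.array([rec.error_rate for rec in records])
    aucs = np.array([rec.auc for rec in records])
    panel = Panel(
        subtype=target,
        features=list(features),
        centroid_target=ct.mean(axis=0),
        centroid_control=cc.mean(axis=0),
        centroid_se=np.sqrt(ct.var(axis=0, ddof=0)) / np.sqrt(n_iter),
        scale=sc.mean(axis=0),
        priors=(1.0 / 3.0, 2.0 / 3.0),
        mean_error_rate=float(errs.mean()),
        sd_error_rate=float(errs.std(ddof=0)),
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std(ddof=0)),
        n_iterations=n_iter,
    )
    if keep_iterations:
        return panel, records
    return panel


def build_integrative_panel(
    gene_panel_features: list[tuple[str, str, str]],
    cpg_panel_features: list[tuple[str, str, str]],
    expr: OmicsMatrix,
    mvals: OmicsMatrix,
    sheet: SampleSheet,
    target: str,
    **kwargs,
) -> Panel | tuple[Panel, list[IterationRecord]]:
    """10-feature integrative panel: the 5 expression + 5 methylation
    markers, estimated exactly like a single-modality panel (feature
    selection is skipped)."""
    if len(gene_panel_features) != 5 or len(cpg_panel_features) != 5:
        raise PanelforgeError("integrative panel needs 5 expression + 5 methylation features")
    gene_ids = {f[0] for f in gene_panel_features}
    cpg_ids = {f[0] for f in cpg_panel_features}
    if gene_ids & cpg_ids:
        raise PanelforgeError(f"overlapping feature IDs across modalities: {gene_ids & cpg_ids}")
    return estimate_panel(
        list(gene_panel_features) + list(cpg_panel_features), expr, mvals, sheet, target, **kwargs
    )


def build_combined_multiclass(
    features: list[tuple[str, str, str]],
    expr: OmicsMatrix | None,
    mvals: OmicsMatrix | None,
    sheet: SampleSheet,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[NscModel, pd.DataFrame]:
    """Single 3-class nearest-centroid model on the union of panel features.

    Provided for comparison with the one-vs-rest panels: returns the fitted
    model and a per-sample table of stratified-CV posteriors, predicted and
    true labels.
    """
    subtype_of = sheet.subtype_of()
    ids = sheet.sample_ids
    block = assemble_feature_block(features, expr, mvals, ids)
    labels = subtype_of.loc[ids]
    model = nsc_fit(block, labels, delta=0.0)

    y = labels.to_numpy()
    folds = int(min(n_folds, pd.Series(y).value_counts().min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    post_all = pd.DataFrame(index=ids, columns=model.classes, dtype=float)
    pred_all = pd.Series(index=ids, dtype=object)
    for tr, te in skf.split(np.zeros(len(y)), y):
        sub_model = nsc_fit(block.iloc[:, tr], labels.iloc[tr], delta=0.0)
        _, post, pred = nsc_score(sub_model, block.iloc[:, te])
        post_all.iloc[te] = post[model.classes].to_numpy()
        pred_all.iloc[te] = pred.to_numpy()
    table = post_all.copy()
    table["predicted"] = pred_all
    table["truth"] = labels
    return model, table
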