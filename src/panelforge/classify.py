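"""Apply trained panels to bulk cohorts and single cells.

Each subtype panel yields a target-class posterior for every sample from
its stored mean centroids, mean scale terms and priors; the sample is
assigned the subtype whose panel gives the highest score.  Expression is
re-z-scored across the classified cohort before scoring (mirroring the
per-cohort normalization used in training); methylation enters as
M-values on their absolute scale.  Single cells are classified the same
way with the expression panels, cell-wise; per-patient subtype
proportions and a pseudobulk profile (per-gene mean over a patient's
cells) summarize intra-tumor heterogeneity.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core_model import OmicsMatrix, Panel, PanelforgeError, SUBTYPES
from .panels import assemble_feature_block

logger = logging.getLogger(__name__)


def panel_posterior(panel: Panel, x: pd.DataFrame) -> pd.Series:
    """Target-class posterior per sample (columns of ``x``) for one panel."""
    missing = [f for f in panel.feature_ids if f not in x.index]
    if missing:
        raise PanelforgeError(f"missing panel feature(s): {missing[:5]}")
    xa = x.loc[panel.feature_ids].to_numpy(dtype=float)  # p x n
    scale2 = panel.scale**2
    centroids = np.column_stack([panel.centroid_target, panel.centroid_control])
    priors = np.array(panel.priors)
    diff = xa[:, :, None] - centroids[:, None, :]
    disc = (diff**2 / scale2[:, None, None]).sum(axis=0) - 2.0 * np.log(priors)[None, :]
    stab = disc - disc.min(axis=1, keepdims=True)
    w = np.exp(-0.5 * stab)
    post = w / w.sum(axis=1, keepdims=True)
    return pd.Series(post[:, 0], index=x.columns, name=panel.subtype)


def _assign(scores: pd.DataFrame) -> pd.Series:
    """Highest score wins; exact ties resolved in fixed subtype order."""
    cols = [s for s in SUBTYPES if s in scores.columns]
    vals = scores[cols].to_numpy()
    best = vals.max(axis=1)
    ties = (vals == best[:, None]).sum(axis=1) > 1
    if ties.any():
        logger.warning("%d sample(s) with tied subtype scores; fixed-order tie-break", ties.sum())
    return pd.Series([cols[i] for i in vals.argmax(axis=1)], index=scores.index, name="subtype")


def score_sample(panels: list[Panel], x: pd.Series) -> tuple[pd.Series, str]:
    """Score one pre-scaled sample against the three subtype panels.

    ``x`` must already be on the panels' expected scales (expression
    z-scored across a cohort, methylation as M-values).  Returns the
    per-subtype score vector and the assigned label.
    """
    frame = x.to_frame(name="sample")
    scores = pd.DataFrame({p.subtype: panel_posterior(p, frame) for p in panels})
    return scores.iloc[0], _assign(scores).iloc[0]


def classify_cohort(
    panels: list[Panel],
    expr: OmicsMatrix | None,
    mvals: OmicsMatrix | None = None,
    rescale: bool = True,
) -> pd.DataFrame:
    """Classify a cohort: per-sample subtype scores plus assigned label.

    Expression features are z-scored across the classified cohort unless
    ``rescale=False`` (pre-scaled input).  A single-sample cohort cannot be
    re-scaled and is rejected unless ``rescale=False``.
    """
    if not panels:
        raise PanelforgeError("no panels supplied")
    sample_ids = (expr or mvals).sample_ids
    if rescale and len(sample_ids) < 2:
        raise PanelforgeError("cannot z-score a single-sample cohort; pass rescale=False")
    scores = {}
    for p in panels:
        block = assemble_feature_block(
            p.features, expr, mvals, sample_ids, rescale_expression=rescale
        )
        scores[p.subtype] = panel_posterior(p, block)
    table = pd.DataFrame(scores)
    table["subtype"] = _assign(table)
    return table


def classify_cells(
    gene_panels: list[Panel], cells: OmicsMatrix, rescale: bool = True
) -> pd.DataFrame:
    """Per-cell classification with the expression panels (z-scoring genes
    across all cells)."""
    for p in gene_panels:
        if any(mod not in ("expression", "zscore") for _, mod, _ in p.features):
            raise PanelforgeError("classify_cells accepts expression panels only")
    return classify_cohort(gene_panels, cells, None, rescale=rescale)


def subtype_proportions(labels: pd.Series, patient_map: pd.Series) -> pd.DataFrame:
    """Per-patient fraction of cells assigned to each subtype (rows sum to 1)."""
    patient_map = patient_map.reindex(labels.index)
    if patient_map.isna().any():
        raise PanelforgeError("patient map does not cover all cells")
    counts = pd.crosstab(patient_map, labels)
    counts = counts.reindex(columns=list(SUBTYPES), fill_value=0)
    if (counts.sum(axis=1) == 0).any():
        raise PanelforgeError("patient with zero cells")
    return counts.div(counts.sum(axis=1), axis=0)


def predominant_subtype(fractions: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
    """Label whose fraction strictly exceeds ``threshold``, else ``"none"``."""
    best = fractions.max(axis=1)
    label = fractions.idxmax(axis=1)
    return label.where(best > threshold, "none").rename("predominant")


def pseudobulk(cells: OmicsMatrix, patient_map: pd.Series) -> OmicsMatrix:
    """Per-patient simulated bulk profile: the per-gene mean over cells."""
    patient_map = patient_map.reindex(cells.sample_ids)
    if patient_map.isna().any():
        raise PanelforgeError("patient map does not cover all cells")
    grouped = cells.values.T.groupby(patient_map).mean().T
    return OmicsMatrix(grouped, cells.modality)
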