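"""Per-feature differential screening between a subtype and the rest.

Expression is screened on z-scores with the Z-Ratio statistic: the
target-minus-control difference of mean z-scores for feature *j*, divided
by the standard deviation of those differences across all features.
Methylation is screened on M-values with the plain group difference
(delta-M).  Both are paired with a pooled-variance two-sample Student
t-test and Benjamini-Hochberg FDR control.

Significance rules (defaults): |Z-Ratio| > 1.5 (strict) for expression,
|delta-M| >= 1.0 (inclusive) for methylation, and q < 0.05 (strict) for
both.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_model import (
    OmicsMatrix,
    PanelforgeError,
    SampleSheet,
    make_differential_table,
)

logger = logging.getLogger(__name__)


def _group_columns(m: OmicsMatrix, sheet: SampleSheet, subtype: str) -> tuple[list[str], list[str]]:
    sub = sheet.subtype_of().reindex(m.sample_ids)
    if sub.isna().any():
        raise PanelforgeError("sample sheet does not cover all matrix samples")
    target = [s for s, lab in sub.items() if lab == subtype]
    control = [s for s, lab in sub.items() if lab != subtype]
    return target, control


def z_ratio(
    z: OmicsMatrix, target_samples: list[str], control_samples: list[str]
) -> np.ndarray:
    """Z-Ratio per feature: difference of group mean z-scores, scaled by the
    sample SD of those differences over all features."""
    if z.modality != "zscore":
        raise PanelforgeError("z_ratio expects zscore modality")
    if len(target_samples) < 2 or len(control_samples) < 2:
        raise PanelforgeError("both groups need at least 2 samples")
    vals = z.values
    d = vals[target_samples].mean(axis=1).to_numpy() - vals[control_samples].mean(axis=1).to_numpy()
    sd = d.std(ddof=1)
    if sd == 0:
        raise PanelforgeError("degenerate contrast: all per-feature differences equal")
    return d / sd


def feature_ttest(
    m: OmicsMatrix, target_samples: list[str], control_samples: list[str]
) -> np.ndarray:
    """Two-sided pooled-variance Student t-test per feature.

    Degenerate features (zero pooled variance) get p = 1 when the group
    means agree and a floor of 1e-300 when they differ.
    """
    if len(target_samples) < 2 or len(control_samples) < 2:
        raise PanelforgeError("both groups need at least 2 samples")
    a = m.values[target_samples].to_numpy(dtype=float)
    b = m.values[control_samples].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var = denom == 0
    p[zero_var & (m1 == m2)] = 1.0
    p[zero_var & (m1 != m2)] = 1e-300
    return np.clip(p, 1e-300, 1.0)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise PanelforgeError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_deg(
    z: OmicsMatrix,
    sheet: SampleSheet,
    subtype: str,
    zratio_cut: float = 1.5,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Differentially expressed genes for one subtype vs the rest.

    Significant iff |Z-Ratio| > ``zratio_cut`` (strict) and q < ``q_cut``
    (strict).
    """
    target, control = _group_columns(z, sheet, subtype)
    zr = z_ratio(z, target, control)
    p = feature_ttest(z, target, control)
    q = bh_fdr(p)
    sig = (np.abs(zr) > zratio_cut) & (q < q_cut)
    if not sig.any():
        logger.warning("no significant DEG for subtype %s", subtype)
    return make_differential_table(z.feature_ids, zr, p, q, sig)


def select_dms(
    mvals: OmicsMatrix,
    sheet: SampleSheet,
    subtype: str,
    delta_cut: float = 1.0,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Differentially methylated sites for one subtype vs the rest.

    Significant iff |delta-M| >= ``delta_cut`` (inclusive) and q < ``q_cut``
    (strict).
    """
    if mvals.modality != "mvalue":
        raise PanelforgeError("select_dms expects mvalue modality")
    target, control = _group_columns(mvals, sheet, subtype)
    vals = mvals.values
    dm = vals[target].mean(axis=1).to_numpy() - vals[control].mean(axis=1).to_numpy()
    p = feature_ttest(mvals, target, control)
    q = bh_fdr(p)
    sig = (np.abs(dm) >= delta_cut) & (q < q_cut)
    if not sig.any():
        logger.warning("no significant DMS for subtype %s", subtype)
    return make_differential_table(mvals.feature_ids, dm, p, q, sig)
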