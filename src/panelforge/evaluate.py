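"""Evaluation: ROC/AUC, agreement statistics, and panel comparison."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core_model import PanelforgeError


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    ``labels`` are truthy for positives.  Equals
    P(score_pos > score_neg) + 0.5 P(tie), i.e. the trapezoidal ROC area,
    exact in the presence of ties.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise PanelforgeError("roc_auc needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion_matrix(truth, predicted, labels: list[str] | None = None) -> pd.DataFrame:
    """K x K count table, truth in rows, prediction in columns."""
    truth = pd.Series(list(truth))
    predicted = pd.Series(list(predicted))
    if len(truth) != len(predicted):
        raise PanelforgeError("label vectors must have equal length")
    if labels is None:
        labels = sorted(set(truth) | set(predicted))
    table = pd.crosstab(truth, predicted)
    return table.reindex(index=labels, columns=labels, fill_value=0)


def cohen_kappa(labels_a, labels_b) -> float:
    """Unweighted Cohen's kappa, chance agreement from marginal products.

    When both labelings are the same single constant the agreement is
    perfect by construction and kappa is defined as 1.
    """
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise PanelforgeError("label vectors must have equal length")
    if len(a) == 0:
        raise PanelforgeError("empty label vectors")
    cats = sorted(set(a) | set(b))
    n = len(a)
    p_o = float((a.to_numpy() == b.to_numpy()).mean())
    pa = a.value_counts().reindex(cats, fill_value=0).to_numpy() / n
    pb = b.value_counts().reindex(cats, fill_value=0).to_numpy() / n
    p_e = float((pa * pb).sum())
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        raise PanelforgeError("kappa undefined: chance agreement is 1 but labelings differ")
    return (p_o - p_e) / (1.0 - p_e)


def compare_panels(metric_by_panel: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA plus Tukey HSD across panel types.

    ``metric_by_panel`` maps panel names to per-iteration metric vectors
    (e.g. AUC over resampling iterations).  Returns the ANOVA F and p plus
    a DataFrame of pairwise Tukey-adjusted comparisons.
    """
    names = list(metric_by_panel)
    groups = [np.asarray(v, dtype=float) for v in metric_by_panel.values()]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise PanelforgeError("need >=2 groups with >=2 values each")
    if all(g.var(ddof=1) == 0 for g in groups):
        raise PanelforgeError("zero within-group variance in all groups")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*groups)
    values = np.concatenate(groups)
    labels = np.concatenate([[nm] * g.size for nm, g in zip(names, groups)])
    tukey = pairwise_tukeyhsd(values, labels)
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return {"F": float(f_stat), "p": float(p_val), "tukey": tukey_df}
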