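"""End-to-end synthetic benchmark workflows.

These functions run the full pipeline on generated cohorts with known
ground truth and return summary metrics: planted-marker recovery by the
consensus selection, held-out panel AUCs, agreement of cohort
classification with the generating labels, null-control rates, and
batch-correction effect sizes.  They are the basis of the package's
reproducibility checks and usable as templates for real analyses.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd

from .classify import classify_cohort, panel_posterior
from .core_model import SUBTYPES, OmicsMatrix, split_cohort
from .differential import select_deg, select_dms
from .evaluate import cohen_kappa, roc_auc
from .feature_selection import consensus_panel, pick_top5_balanced
from .nsc import nsc_fit
from .panels import assemble_feature_block, build_integrative_panel, estimate_panel
from .preprocess import beta_to_mvalue, combat_correct, filter_low_expression, zscore_normalize
from .synthetic_data import SimConfig, simulate_multiomic

logger = logging.getLogger(__name__)


def _derive(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(tag)]).generate_state(1)[0]) % (2**31)


def recovery_experiment(
    seed: int,
    n_per_subtype: int = 43,
    train_fraction: float = 0.7,
    gene_effect: float = 1.5,
    m_effect: float = 2.0,
    n_informative: int = 50,
    n_genes: int = 2000,
    n_cpgs: int = 2000,
    n_replicates: int = 50,
    meth_replicates: int = 10,
    ntree: int = 100,
    ntree_iterat: int = 50,
    n_thresholds: int = 15,
    n_iter: int = 20,
) -> dict:
    """Marker recovery and held-out performance on one simulated cohort.

    Simulates a three-subtype multi-omic cohort, splits 70/30, runs the
    full selection pipeline per subtype on the training cohort (consensus
    over ``n_replicates`` for expression, ``meth_replicates`` for
    methylation), estimates expression / methylation / integrative panels,
    and scores the held-out cohort.  Returns per-subtype recovery counts
    and AUCs plus the integrative cohort-classification kappa.
    """
    cfg = SimConfig(
        n_per_subtype=n_per_subtype,
        n_genes=n_genes,
        n_cpgs=n_cpgs,
        n_informative_genes=n_informative,
        n_informative_cpgs=n_informative,
        gene_effect=gene_effect,
        m_effect=m_effect,
        seed=_derive(seed, 0),
    )
    expr, beta, sheet, truth = simulate_multiomic(cfg)
    sheet_train, sheet_val = split_cohort(sheet, train_fraction, seed=_derive(seed, 1))
    train_ids, val_ids = sheet_train.sample_ids, sheet_val.sample_ids

    expr_train = filter_low_expression(expr.select_samples(train_ids))
    z_train = zscore_normalize(expr_train)
    mvals_all, _ = combat_correct(beta_to_mvalue(beta), sheet.batch_of())
    mv_train = mvals_all.select_samples(train_ids)
    expr_val = expr.select_samples(val_ids).select_features(expr_train.feature_ids)
    mv_val = mvals_all.select_samples(val_ids)

    sub_train = sheet_train.subtype_of()
    y_val = sheet_val.subtype_of().reindex(val_ids)
    out: dict = {"subtypes": {}}
    integ_panels = []
    for k, subtype in enumerate(SUBTYPES):
        labels = sub_train.reindex(train_ids)
        labels = labels.where(labels == subtype, "Control")

        deg = select_deg(z_train, sheet_train, subtype)
        gene_cand = z_train.select_features(
            sorted(deg.loc[deg["significant"], "feature_id"])
        )
        res_g = consensus_panel(
            gene_cand, labels, subtype, n_replicates=n_replicates,
            seed=_derive(seed, 10 + k), ntree=ntree, ntree_iterat=ntree_iterat,
            n_thresholds=n_thresholds,
        )
        planted = truth.informative_ids(subtype, "expression")
        n_recovered = len(set(res_g.winning_set) & planted)

        dms = select_dms(mv_train, sheet_train, subtype)
        cpg_cand = mv_train.select_features(
            sorted(dms.loc[dms["significant"], "feature_id"])
        )
        res_m = consensus_panel(
            cpg_cand, labels, subtype, n_replicates=meth_replicates,
            seed=_derive(seed, 20 + k), ntree=ntree, ntree_iterat=ntree_iterat,
            n_thresholds=n_thresholds,
        )
        planted_m = truth.informative_ids(subtype, "beta")
        n_recovered_m = len(set(res_m.winning_set) & planted_m)

        gene_feats = [(f, "expression", d) for f, d in res_g.winning_features]
        cpg_feats = [(f, "mvalue", d) for f, d in res_m.winning_features]
        p_g = estimate_panel(gene_feats, expr_train, None, sheet_train, subtype,
                             n_iter=n_iter, seed=_derive(seed, 30 + k))
        p_m = estimate_panel(cpg_feats, None, mv_train, sheet_train, subtype,
                             n_iter=n_iter, seed=_derive(seed, 40 + k))
        p_i = build_integrative_panel(gene_feats, cpg_feats, expr_train, mv_train,
                                      sheet_train, subtype,
                                      n_iter=n_iter, seed=_derive(seed, 50 + k))
        integ_panels.append(p_i)

        y_bin = (y_val == subtype).to_numpy()
        aucs = {}
        for name, panel, e, m in (
            ("expression", p_g, expr_val, None),
            ("methylation", p_m, None, mv_val),
            ("integrative", p_i, expr_val, mv_val),
        ):
            block = assemble_feature_block(panel.features, e, m, val_ids)
            aucs[name] = roc_auc(panel_posterior(panel, block), y_bin)
        out["subtypes"][subtype] = {
            "genes_recovered": n_recovered,
            "cpgs_recovered": n_recovered_m,
            "consensus_frequency": res_g.frequency[res_g.winning_set]
            / max(len(res_g.replicates), 1),
            "auc": aucs,
            "train_auc": {
                "expression": p_g.mean_auc,
                "methylation": p_m.mean_auc,
                "integrative": p_i.mean_auc,
            },
        }

    table = classify_cohort(integ_panels, expr_val, mv_val)
    out["validation_kappa"] = cohen_kappa(y_val, table["subtype"])
    out["validation_accuracy"] = float((y_val == table["subtype"]).mean())
    return out


def null_experiment(
    seed: int,
    n_per_subtype: int = 43,
    n_genes: int = 2000,
    n_cpgs: int = 1000,
    n_iter: int = 10,
) -> dict:
    """Null control: no planted effects anywhere.

    Measures the fraction of features passing the differential thresholds
    and the held-out AUC of a panel built from the apparently top-ranked
    features of the null training data (honest estimate: selection on
    train, evaluation on the held-out 30%).
    """
    cfg = SimConfig(
        n_per_subtype=n_per_subtype,
        n_genes=n_genes,
        n_cpgs=n_cpgs,
        n_informative_genes=1,
        n_informative_cpgs=1,
        gene_effect=0.0,
        m_effect=0.0,
        seed=_derive(seed, 100),
    )
    expr, beta, sheet, _ = simulate_multiomic(cfg)
    sheet_train, sheet_val = split_cohort(sheet, 0.7, seed=_derive(seed, 101))
    train_ids, val_ids = sheet_train.sample_ids, sheet_val.sample_ids

    expr_train = filter_low_expression(expr.select_samples(train_ids))
    z_train = zscore_normalize(expr_train)
    mv_all, _ = combat_correct(beta_to_mvalue(beta), sheet.batch_of())
    mv_train = mv_all.select_samples(train_ids)

    sig_fracs = []
    aucs = []
    sub_train = sheet_train.subtype_of()
    y_val = sheet_val.subtype_of().reindex(val_ids)
    for k, subtype in enumerate(SUBTYPES):
        deg = select_deg(z_train, sheet_train, subtype)
        dms = select_dms(mv_train, sheet_train, subtype)
        sig_fracs.append(deg["significant"].mean())
        sig_fracs.append(dms["significant"].mean())

        # a panel from the top-ranked (noise) features, honestly evaluated
        labels = sub_train.reindex(train_ids)
        labels = labels.where(labels == subtype, "Control")
        model = nsc_fit(z_train, labels, delta=0.0)
        feats = [(f, "expression", d) for f, d in pick_top5_balanced(model, subtype)]
        panel = estimate_panel(feats, expr_train, None, sheet_train, subtype,
                               n_iter=n_iter, seed=_derive(seed, 110 + k))
        expr_val = expr.select_samples(val_ids).select_features(expr_train.feature_ids)
        block = assemble_feature_block(panel.features, expr_val, None, val_ids)
        aucs.append(roc_auc(panel_posterior(panel, block), (y_val == subtype).to_numpy()))
    return {
        "significant_fraction": float(np.mean(sig_fracs)),
        "max_significant_fraction": float(np.max(sig_fracs)),
        "held_out_auc": float(np.mean(aucs)),
        "held_out_auc_per_subtype": [float(a) for a in aucs],
    }


def batch_correction_experiment(seed: int) -> dict:
    """Batch-shift removal and effect preservation at generator defaults.

    Returns the fractional reduction of the mean absolute between-batch
    mean difference on null CpGs and the mean post/pre ratio of the
    subtype effect on planted CpGs (subtype labels are balanced across
    batches by construction).
    """
    cfg = SimConfig(seed=_derive(seed, 200))
    _, beta, sheet, truth = simulate_multiomic(cfg)
    mv = beta_to_mvalue(beta)
    corrected, _ = combat_correct(mv, sheet.batch_of())
    batch = sheet.batch_of()
    levels = list(pd.unique(batch))
    nulls = truth.null_ids(mv.feature_ids, "beta")

    def mean_absolute_batch_diff(m: OmicsMatrix) -> float:
        diffs = []
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                a = m.values.loc[nulls, (batch == levels[i]).to_numpy()].mean(axis=1)
                b = m.values.loc[nulls, (batch == levels[j]).to_numpy()].mean(axis=1)
                diffs.append((a - b).abs().mean())
        return float(np.mean(diffs))

    pre, post = mean_absolute_batch_diff(mv), mean_absolute_batch_diff(corrected)

    sub = sheet.subtype_of()
    ratios = []
    for subtype in SUBTYPES:
        info = sorted(truth.informative_ids(subtype, "beta"))
        t = (sub == subtype).to_numpy()
        d_pre = (mv.values.loc[info, t].mean(axis=1) - mv.values.loc[info, ~t].mean(axis=1))
        d_post = (corrected.values.loc[info, t].mean(axis=1)
                  - corrected.values.loc[info, ~t].mean(axis=1))
        ratios.append(float((d_post / d_pre).mean()))
    return {
        "shift_reduction": 1.0 - post / pre,
        "effect_preservation_ratio": float(np.mean(ratios)),
    }
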