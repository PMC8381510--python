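"""Filtering, normalization, methylation transforms and batch correction.

The preprocessing stages mirror a standard multi-source array workflow:

* drop the lowest-expressed quarter of genes (uninformative background);
* z-score expression per gene across samples;
* convert methylation beta values to M-values, ``M = log2(beta/(1-beta))``,
  turning the bimodal beta distribution into an approximately normal one;
* restrict multiple cohorts to their shared probe core;
* remove source (batch) effects with a parametric empirical-Bayes
  location/scale adjustment (ComBat, Johnson et al. 2007, no covariates).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import OmicsMatrix, PanelforgeError

logger = logging.getLogger(__name__)


def filter_low_expression(expr: OmicsMatrix, fraction: float = 0.25) -> OmicsMatrix:
    """Remove the ``ceil(fraction * p)`` genes with the lowest mean expression.

    Ties at the cut are broken by feature ID order, and surviving genes keep
    their original order, so the result is deterministic.
    """
    if expr.modality != "expression":
        raise PanelforgeError("filter_low_expression expects expression modality")
    if not 0.0 < fraction < 1.0:
        raise PanelforgeError("fraction must be in (0, 1)")
    p = expr.n_features
    if p == 0:
        raise PanelforgeError("empty matrix")
    n_remove = int(math.ceil(fraction * p))
    means = expr.values.mean(axis=1)
    order = sorted(expr.feature_ids, key=lambda f: (means[f], f))
    removed = set(order[:n_remove])
    keep = [f for f in expr.feature_ids if f not in removed]
    logger.info("low-expression filter: removed %d of %d genes, %d remain",
                n_remove, p, len(keep))
    return expr.select_features(keep)


def zscore_normalize(m: OmicsMatrix) -> OmicsMatrix:
    """Per-feature z-score across samples (sample SD, n-1 denominator).

    Constant features map to all-zero rows with a logged warning rather than
    being dropped; they carry no signal and are removed downstream by the
    differential screen.
    """
    if m.n_samples < 2:
        raise PanelforgeError("z-scoring needs at least 2 samples")
    vals = m.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    const = (sd == 0).ravel()
    if const.any():
        logger.warning("%d constant feature(s) mapped to all-zero z-scores", int(const.sum()))
    sd[sd == 0] = 1.0
    return m.with_values((vals - mean) / sd, modality="zscore")


def beta_to_mvalue(beta: OmicsMatrix, eps: float = 1e-6) -> OmicsMatrix:
    """``M = log2(beta / (1 - beta))`` after clipping beta to [eps, 1-eps]."""
    if beta.modality != "beta":
        raise PanelforgeError("beta_to_mvalue expects beta modality")
    if not 0.0 < eps < 0.5:
        raise PanelforgeError("eps must be in (0, 0.5)")
    b = np.clip(beta.values.to_numpy(dtype=float), eps, 1.0 - eps)
    return beta.with_values(np.log2(b / (1.0 - b)), modality="mvalue")


def mvalue_to_beta(mvals: OmicsMatrix) -> OmicsMatrix:
    """Inverse transform, ``beta = 2^M / (2^M + 1)``."""
    if mvals.modality != "mvalue":
        raise PanelforgeError("mvalue_to_beta expects mvalue modality")
    e = np.exp2(mvals.values.to_numpy(dtype=float))
    return mvals.with_values(e / (e + 1.0), modality="beta")


def intersect_common_features(*matrices: OmicsMatrix) -> list[OmicsMatrix]:
    """Restrict matrices to their shared feature IDs, in a common order.

    The shared features keep the order they have in the first matrix; each
    output retains its own samples.
    """
    if len(matrices) < 2:
        raise PanelforgeError("need at least 2 matrices to intersect")
    modality = matrices[0].modality
    if any(m.modality != modality for m in matrices):
        raise PanelforgeError("all matrices must share one modality")
    common = set(matrices[0].feature_ids)
    for m in matrices[1:]:
        common &= set(m.feature_ids)
    if not common:
        raise PanelforgeError("no features shared by all matrices")
    order = [f for f in matrices[0].feature_ids if f in common]
    return [m.select_features(order) for m in matrices]


# ---------------------------------------------------------------------------
# ComBat


@dataclass
class CombatFit:
    """Fitted empirical-Bayes batch-adjustment parameters.

    ``gamma_star`` / ``delta2_star`` are the posterior-mean per-batch,
    per-feature location shifts and scale factors on the standardized scale;
    the hyperparameters are the moment-matched normal (location) and
    inverse-gamma (scale) priors per batch.
    """

    batches: list[str]
    alpha_hat: np.ndarray            # per-feature grand mean
    sigma_hat: np.ndarray            # per-feature pooled SD
    gamma_star: pd.DataFrame         # batch x feature
    delta2_star: pd.DataFrame        # batch x feature
    gamma_bar: pd.Series
    tau2_bar: pd.Series
    a_prior: pd.Series
    b_prior: pd.Series
    iterations_used: int


def _it_sol(
    z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
    g_bar: float, t2: float, a: float, b: float,
    tol: float, max_iter: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Fixed-point iteration of the conditional posterior means for one batch."""
    n = z.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    it = 0
    for it in range(1, max_iter + 1):
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        ss = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * ss + b) / (n / 2.0 + a - 1.0)
        change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    else:
        logger.warning("ComBat EB iteration did not converge in %d steps", max_iter)
    return g_old, d_old, it


def combat_correct(
    m: OmicsMatrix,
    batches: pd.Series | None = None,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> tuple[OmicsMatrix, CombatFit]:
    """Parametric empirical-Bayes batch correction (no covariates).

    Features are standardized by grand mean and pooled SD; per-batch
    location and scale estimates are shrunk toward batch-level priors
    (normal for locations, inverse-gamma for scales, both moment-matched)
    by iterating the conditional posterior means to convergence; the data
    are then adjusted and back-transformed.  Output feature and sample
    order is identical to the input.

    A single-batch input is returned unchanged.
    """
    if m.modality not in ("expression", "mvalue", "zscore"):
        raise PanelforgeError("combat_correct expects expression, mvalue or zscore data")
    if batches is None:
        batches = m.batch
    if batches is None:
        raise PanelforgeError("no batch labels supplied")
    batches = pd.Series(batches).reindex(m.sample_ids)
    if batches.isna().any():
        raise PanelforgeError("batch label missing for some samples")
    levels = list(pd.unique(batches))
    x = m.values.to_numpy(dtype=float)
    p, n = x.shape
    if len(levels) == 1:
        fit = CombatFit(levels, x.mean(axis=1), x.std(axis=1, ddof=0),
                        pd.DataFrame(np.zeros((1, p)), index=levels),
                        pd.DataFrame(np.ones((1, p)), index=levels),
                        pd.Series([0.0], index=levels), pd.Series([0.0], index=levels),
                        pd.Series([0.0], index=levels), pd.Series([0.0], index=levels), 0)
        return m, fit

    masks = {b: (batches == b).to_numpy() for b in levels}
    n_b = {b: int(masks[b].sum()) for b in levels}
    for b, nb in n_b.items():
        if nb < 2:
            raise PanelforgeError(f"batch {b!r} has fewer than 2 samples")

    # standardize: weighted grand mean and pooled SD around batch means
    batch_means = np.column_stack([x[:, masks[b]].mean(axis=1) for b in levels])
    w = np.array([n_b[b] / n for b in levels])
    alpha_hat = batch_means @ w
    fitted = np.empty_like(x)
    for i, b in enumerate(levels):
        fitted[:, masks[b]] = batch_means[:, [i]]
    sigma_hat = np.sqrt(((x - fitted) ** 2).mean(axis=1))
    if (sigma_hat == 0).any():
        sigma_hat = np.where(sigma_hat == 0, 1.0, sigma_hat)
    z = (x - alpha_hat[:, None]) / sigma_hat[:, None]

    gamma_star = np.empty((len(levels), p))
    delta2_star = np.empty((len(levels), p))
    g_bars, t2s, a_ps, b_ps = [], [], [], []
    iterations = 0
    for i, b in enumerate(levels):
        zb = z[:, masks[b]]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        g_bar = float(g_hat.mean())
        t2 = float(g_hat.var(ddof=1))
        dm, dv = float(d_hat.mean()), float(d_hat.var(ddof=1))
        # moment-matched inverse-gamma hyperparameters
        a = (2.0 * dv + dm ** 2) / dv if dv > 0 else 2.0
        bb = (dm * dv + dm ** 3) / dv if dv > 0 else dm
        g_st, d_st, it = _it_sol(zb, g_hat, d_hat, g_bar, t2, a, bb, tol, max_iter)
        gamma_star[i], delta2_star[i] = g_st, d_st
        iterations = max(iterations, it)
        g_bars.append(g_bar); t2s.append(t2); a_ps.append(a); b_ps.append(bb)

    adj = z.copy()
    for i, b in enumerate(levels):
        adj[:, masks[b]] = (z[:, masks[b]] - gamma_star[i][:, None]) / np.sqrt(
            delta2_star[i][:, None]
        )
    corrected = adj * sigma_hat[:, None] + alpha_hat[:, None]

    feats = m.feature_ids
    fit = CombatFit(
        batches=levels,
        alpha_hat=alpha_hat,
        sigma_hat=sigma_hat,
        gamma_star=pd.DataFrame(gamma_star, index=levels, columns=feats),
        delta2_star=pd.DataFrame(delta2_star, index=levels, columns=feats),
        gamma_bar=pd.Series(g_bars, index=levels),
        tau2_bar=pd.Series(t2s, index=levels),
        a_prior=pd.Series(a_ps, index=levels),
        b_prior=pd.Series(b_ps, index=levels),
        iterations_used=iterations,
    )
    return m.with_values(corrected), fit
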