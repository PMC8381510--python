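"""Synthetic multi-omic cohorts with planted subtype structure.

The generator emulates the statistical structure the pipeline assumes in
real data: three molecular subtypes, per-subtype differentially expressed
genes (additive shifts on a log-intensity-like scale), per-subtype
differentially methylated CpG sites (shifts on the M-value scale, mapped
back to bimodal beta values), and additive/multiplicative batch effects
across several data sources sharing one probe core.

Informative feature sets are disjoint across subtypes by default so that
recovery of planted markers can be scored unambiguously.  Effects are
additive on the expression and M-value scales, not on beta values, because
the downstream screening operates on those (approximately normal) scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import OmicsMatrix, PanelforgeError, SampleSheet, SUBTYPES


@dataclass
class SimConfig:
    """Parameters of a bulk multi-omic simulation.

    Effects are expressed per subtype: each subtype receives its own
    disjoint set of ``n_informative_genes`` genes shifted by
    ``gene_effect`` within-class standard deviations (half up, half down)
    and ``n_informative_cpgs`` CpGs shifted by ``m_effect`` on the M scale.
    Batch effects are an additive per-(batch, feature) shift drawn with SD
    ``batch_shift_sd`` plus a multiplicative per-(batch, feature) scale
    ``exp(U(-batch_scale_range, batch_scale_range))``.
    """

    n_per_subtype: int = 30
    n_genes: int = 2000
    n_cpgs: int = 2000
    n_informative_genes: int = 50
    n_informative_cpgs: int = 50
    gene_effect: float = 1.5
    m_effect: float = 2.0
    noise_sd_expr: float = 1.0
    noise_sd_m: float = 1.0
    n_batches: int = 3
    batch_shift_sd: float = 1.0
    batch_scale_range: float = 0.2
    overlapping_signal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_per_subtype",
            "n_genes",
            "n_cpgs",
            "n_informative_genes",
            "n_informative_cpgs",
            "n_batches",
        ):
            if getattr(self, name) <= 0:
                raise PanelforgeError(f"{name} must be positive")
        if not self.overlapping_signal:
            if self.n_informative_genes * len(SUBTYPES) > self.n_genes:
                raise PanelforgeError("informative genes exceed total genes")
            if self.n_informative_cpgs * len(SUBTYPES) > self.n_cpgs:
                raise PanelforgeError("informative CpGs exceed total CpGs")
        if self.batch_scale_range <= 0:
            raise PanelforgeError("batch_scale_range must be > 0")


@dataclass
class SimTruth:
    """Ground truth of a simulation run.

    ``informative`` maps each subtype to a DataFrame (feature_id,
    modality, direction, effect); ``batch_shift`` / ``batch_scale`` map
    (modality, batch label) to per-feature arrays.
    """

    informative: dict[str, pd.DataFrame]
    batch_shift: dict[tuple[str, str], np.ndarray]
    batch_scale: dict[tuple[str, str], np.ndarray]

    def informative_ids(self, subtype: str, modality: str | None = None) -> set[str]:
        t = self.informative[subtype]
        if modality is not None:
            t = t[t["modality"] == modality]
        return set(t["feature_id"])

    def null_ids(self, feature_ids: Sequence[str], modality: str) -> list[str]:
        planted = set()
        for s in self.informative:
            planted |= self.informative_ids(s, modality)
        return [f for f in feature_ids if f not in planted]


def _signed_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Half +1 / half -1 (one extra + when odd), shuffled: guarantees the
    >=2-per-direction panel constraint is attainable for n >= 4."""
    dirs = np.ones(n)
    dirs[: n // 2] = -1.0
    rng.shuffle(dirs)
    return dirs


def _plant(
    rng: np.random.Generator,
    n_features: int,
    n_informative: int,
    overlapping: bool,
) -> dict[str, np.ndarray]:
    """Choose informative feature indices per subtype (disjoint unless overlapping)."""
    picks: dict[str, np.ndarray] = {}
    if overlapping:
        for s in SUBTYPES:
            picks[s] = rng.choice(n_features, size=n_informative, replace=False)
    else:
        pool = rng.permutation(n_features)
        for i, s in enumerate(SUBTYPES):
            picks[s] = pool[i * n_informative : (i + 1) * n_informative]
    return picks


def _modality_block(
    rng: np.random.Generator,
    prefix: str,
    n_features: int,
    n_informative: int,
    effect: float,
    noise_sd: float,
    baseline: np.ndarray,
    subtype_of: np.ndarray,
    batch_of: np.ndarray,
    batches: list[str],
    cfg: SimConfig,
    modality_tag: str,
) -> tuple[np.ndarray, list[str], dict[str, pd.DataFrame], dict, dict]:
    n_samples = subtype_of.size
    feature_ids = [f"{prefix}{i:05d}" for i in range(n_features)]
    picks = _plant(rng, n_features, n_informative, cfg.overlapping_signal)

    x = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_features, n_samples))
    informative: dict[str, pd.DataFrame] = {}
    for s in SUBTYPES:
        idx = picks[s]
        dirs = _signed_directions(idx.size, rng)
        shift = effect * noise_sd * dirs
        member = subtype_of == s
        x[np.ix_(idx, member)] += shift[:, None]
        informative[s] = pd.DataFrame(
            {
                "feature_id": [feature_ids[i] for i in idx],
                "modality": modality_tag,
                "direction": np.where(dirs > 0, "+", "-"),
                "effect": shift,
            }
        )

    batch_shift: dict = {}
    batch_scale: dict = {}
    for b in batches:
        shift = rng.normal(0.0, cfg.batch_shift_sd, size=n_features)
        scale = np.exp(rng.uniform(-cfg.batch_scale_range, cfg.batch_scale_range, size=n_features))
        member = batch_of == b
        x[:, member] = (x[:, member] + shift[:, None]) * scale[:, None]
        batch_shift[(modality_tag, b)] = shift
        batch_scale[(modality_tag, b)] = scale
    return x, feature_ids, informative, batch_shift, batch_scale


def simulate_multiomic(
    cfg: SimConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, SampleSheet, SimTruth]:
    """Simulate paired expression and methylation matrices for one cohort.

    Returns ``(expression, beta, sheet, truth)``.  Expression is generated
    as baseline + subtype shift + batch effects + Gaussian noise on a
    log-intensity-like scale; methylation analogously on the M scale with a
    bimodal baseline (mixture of hypo- and hypermethylated sites), then
    mapped to beta via ``beta = 2^M / (2^M + 1)``.  All samples are labelled
    ``train``; use :func:`panelforge.core_model.split_cohort` to hold out a
    validation cohort.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_per_subtype * len(SUBTYPES)
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    subtype_of = np.repeat(np.array(SUBTYPES, dtype=object), cfg.n_per_subtype)
    batches = [f"batch{b}" for b in range(cfg.n_batches)]
    # balanced assignment of samples to sources, shuffled so batches are not
    # confounded with subtype
    batch_of = np.array([batches[i % cfg.n_batches] for i in range(n_samples)], dtype=object)
    rng.shuffle(batch_of)

    gene_baseline = rng.normal(7.0, 1.0, size=cfg.n_genes)
    expr_vals, gene_ids, info_g, shift_g, scale_g = _modality_block(
        rng, "G", cfg.n_genes, cfg.n_informative_genes, cfg.gene_effect,
        cfg.noise_sd_expr, gene_baseline, subtype_of, batch_of, batches, cfg,
        "expression",
    )

    # bimodal M-value baseline: hypo (M ~ -3) and hyper (M ~ +3) methylated sites
    comp = rng.random(cfg.n_cpgs) < 0.5
    m_baseline = np.where(comp, rng.normal(-3.0, 1.0, cfg.n_cpgs), rng.normal(3.0, 1.0, cfg.n_cpgs))
    m_vals, cpg_ids, info_m, shift_m, scale_m = _modality_block(
        rng, "cg", cfg.n_cpgs, cfg.n_informative_cpgs, cfg.m_effect / max(cfg.noise_sd_m, 1e-12),
        cfg.noise_sd_m, m_baseline, subtype_of, batch_of, batches, cfg,
        "beta",
    )
    beta_vals = np.exp2(m_vals) / (np.exp2(m_vals) + 1.0)

    batch_series = pd.Series(batch_of, index=sample_ids)
    expr = OmicsMatrix(
        pd.DataFrame(expr_vals, index=gene_ids, columns=sample_ids), "expression", batch_series
    )
    beta = OmicsMatrix(
        pd.DataFrame(beta_vals, index=cpg_ids, columns=sample_ids), "beta", batch_series
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "subtype": subtype_of,
                "batch": batch_of,
                "role": "train",
            }
        )
    )
    informative = {s: pd.concat([info_g[s], info_m[s]], ignore_index=True) for s in SUBTYPES}
    truth = SimTruth(informative, {**shift_g, **shift_m}, {**scale_g, **scale_m})
    return expr, beta, sheet, truth


# ---------------------------------------------------------------------------
# single-cell generator


@dataclass
class SimCellConfig:
    """Parameters of a single-cell expression simulation.

    Each patient is a mixture of the three subtype templates; every cell
    carries a latent subtype drawn from the patient's mixture.  ``dirichlet_
    concentration`` is the concentration of the predominant component vs the
    two others when mixtures are drawn rather than supplied.
    """

    n_patients: int = 25
    cells_per_patient: int = 300
    n_genes: int = 2000
    n_informative_genes: int = 50
    gene_effect: float = 1.5
    noise_sd_cell: float = 1.0
    dropout_rate: float = 0.0
    dirichlet_concentration: tuple[float, float, float] = (5.0, 1.0, 1.0)
    mixtures: list | None = None  # optional explicit per-patient proportions
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise PanelforgeError("dropout_rate must be in [0, 1)")
        if self.mixtures is not None:
            for w in self.mixtures:
                if len(w) != len(SUBTYPES) or abs(sum(w) - 1.0) > 1e-9:
                    raise PanelforgeError("each mixture must have 3 proportions summing to 1")
            if len(self.mixtures) != self.n_patients:
                raise PanelforgeError("need one mixture per patient")


def simulate_cells(cfg: SimCellConfig) -> tuple[OmicsMatrix, pd.Series, SimTruth]:
    """Simulate single cells as noisy copies of per-subtype templates.

    Returns ``(cells, patient_map, truth)`` where ``cells`` is a gene x cell
    expression matrix, ``patient_map`` maps cell IDs to patient IDs, and
    ``truth.informative`` records planted markers.  The returned truth also
    carries ``cell_subtype`` (latent label per cell), ``patient_mixture``
    (generating proportions) and ``templates`` (noise-free profiles).
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    baseline = rng.normal(7.0, 1.0, size=cfg.n_genes)
    picks = _plant(rng, cfg.n_genes, cfg.n_informative_genes, overlapping=False)

    templates = {s: baseline.copy() for s in SUBTYPES}
    informative: dict[str, pd.DataFrame] = {}
    for s in SUBTYPES:
        idx = picks[s]
        dirs = _signed_directions(idx.size, rng)
        shift = cfg.gene_effect * dirs
        templates[s][idx] += shift
        informative[s] = pd.DataFrame(
            {
                "feature_id": [gene_ids[i] for i in idx],
                "modality": "expression",
                "direction": np.where(dirs > 0, "+", "-"),
                "effect": shift,
            }
        )

    if cfg.mixtures is not None:
        mixtures = [np.asarray(w, dtype=float) for w in cfg.mixtures]
    else:
        mixtures = []
        for _ in range(cfg.n_patients):
            predominant = rng.integers(len(SUBTYPES))
            alpha = np.full(len(SUBTYPES), cfg.dirichlet_concentration[1])
            alpha[predominant] = cfg.dirichlet_concentration[0]
            mixtures.append(rng.dirichlet(alpha))

    cell_ids: list[str] = []
    patient_of: list[str] = []
    latent: list[str] = []
    blocks: list[np.ndarray] = []
    for p in range(cfg.n_patients):
        pid = f"P{p:03d}"
        ks = rng.choice(len(SUBTYPES), size=cfg.cells_per_patient, p=mixtures[p])
        block = np.empty((cfg.n_genes, cfg.cells_per_patient))
        for c, k in enumerate(ks):
            block[:, c] = templates[SUBTYPES[k]]
        if cfg.noise_sd_cell > 0:
            block += rng.normal(0.0, cfg.noise_sd_cell, size=block.shape)
        if cfg.dropout_rate > 0:
            block[rng.random(block.shape) < cfg.dropout_rate] = 0.0
        blocks.append(block)
        cell_ids += [f"{pid}_c{c:04d}" for c in range(cfg.cells_per_patient)]
        patient_of += [pid] * cfg.cells_per_patient
        latent += [SUBTYPES[k] for k in ks]

    cells = OmicsMatrix(
        pd.DataFrame(np.hstack(blocks), index=gene_ids, columns=cell_ids), "expression"
    )
    patient_map = pd.Series(patient_of, index=cell_ids, name="patient")
    truth = SimTruth(informative, {}, {})
    # attach single-cell ground truth without widening the shared type
    truth.cell_subtype = pd.Series(latent, index=cell_ids, name="subtype")  # type: ignore[attr-defined]
    truth.patient_mixture = pd.DataFrame(  # type: ignore[attr-defined]
        np.vstack(mixtures), index=[f"P{p:03d}" for p in range(cfg.n_patients)], columns=SUBTYPES
    )
    truth.templates = pd.DataFrame(templates, index=gene_ids)  # type: ignore[attr-defined]
    return cells, patient_map, truth
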