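"""Core domain types and file plumbing.

The package works on feature x sample matrices of four modalities:

``expression``
    log-intensity-like gene expression values (microarray RMA scale).
``beta``
    DNA-methylation beta values, the methylated fraction at a CpG site,
    constrained to [0, 1] and typically bimodal across the genome.
``mvalue``
    logit2-transformed beta values, approximately normal.
``zscore``
    per-feature standardized values (mean 0, sd 1 across samples).

Samples carry a subtype label (one of three molecular subtypes), a batch
(data source) label and a cohort role (train / validation) in a
:class:`SampleSheet`.  A trained one-vs-rest classifier is stored as a
:class:`Panel`: a small set of features with averaged class centroids,
scale terms and performance summaries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MODALITIES = ("expression", "beta", "mvalue", "zscore")

#: canonical subtype labels, also the fixed tie-break order
SUBTYPES = ("Classical", "Mesenchymal", "Proneural")

ROLES = ("train", "validation")


class PanelforgeError(ValueError):
    """Base class for user-facing validation errors."""


# ---------------------------------------------------------------------------
# OmicsMatrix


@dataclass
class OmicsMatrix:
    """A feature x sample matrix with a declared modality.

    Parameters
    ----------
    values
        DataFrame with feature IDs as the index and sample IDs as columns.
    modality
        One of :data:`MODALITIES`.
    batch
        Optional per-sample batch (source) labels, aligned with columns.
    """

    values: pd.DataFrame
    modality: str
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise PanelforgeError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise PanelforgeError(f"duplicate feature IDs: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise PanelforgeError(f"duplicate sample IDs: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise PanelforgeError("matrix body must be numeric")
        if self.modality == "beta":
            a = arr[~np.isnan(arr)]
            if a.size and (a.min() < 0.0 or a.max() > 1.0):
                raise PanelforgeError("beta values must lie in [0, 1]")
        if self.batch is not None:
            self.batch = pd.Series(self.batch).reindex(self.values.columns)
            if self.batch.isna().any():
                missing = self.batch.index[self.batch.isna()].tolist()
                raise PanelforgeError(f"batch label missing for samples {missing[:5]}")

    # -- conveniences -------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise PanelforgeError(f"features not in matrix: {missing[:5]}")
        return OmicsMatrix(self.values.loc[list(feature_ids)], self.modality, self.batch)

    def select_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise PanelforgeError(f"samples not in matrix: {missing[:5]}")
        batch = self.batch.loc[list(sample_ids)] if self.batch is not None else None
        return OmicsMatrix(self.values[list(sample_ids)], self.modality, batch)

    def with_values(self, new_values: np.ndarray, modality: str | None = None) -> "OmicsMatrix":
        df = pd.DataFrame(new_values, index=self.values.index, columns=self.values.columns)
        return OmicsMatrix(df, modality or self.modality, self.batch)


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path: str | Path, modality: str, drop_missing: bool = True) -> OmicsMatrix:
    """Read a delimited feature x sample matrix.

    First column holds feature IDs, header row holds sample IDs.  Features
    containing any missing value are dropped (completeness filtering at
    ingestion); set ``drop_missing=False`` to raise instead.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    bad = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
        raise PanelforgeError(
            f"non-numeric value in column {col!r}, row(s) {row[:3]} of {path.name}"
        )
    if df.isna().any().any():
        if drop_missing:
            df = df.dropna(axis=0)
        else:
            raise PanelforgeError(f"missing values in {path.name}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OmicsMatrix(df, modality)


def write_matrix(m: OmicsMatrix, path: str | Path) -> None:
    path = Path(path)
    m.values.to_csv(path, sep=_sep_for(path), index_label="feature_id")


# ---------------------------------------------------------------------------
# SampleSheet


@dataclass
class SampleSheet:
    """Per-sample annotations: subtype, batch and cohort role."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "subtype", "batch", "role")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise PanelforgeError(f"sample sheet missing columns: {missing}")
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise PanelforgeError(f"duplicate sample IDs: {dups[:5]}")
        bad = set(t["subtype"]) - set(SUBTYPES)
        if bad:
            raise PanelforgeError(
                f"unknown subtype labels {sorted(bad)}; expected {SUBTYPES}"
            )
        bad_roles = set(t["role"]) - set(ROLES)
        if bad_roles:
            raise PanelforgeError(f"unknown roles {sorted(bad_roles)}; expected {ROLES}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def subtype_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["subtype"]

    def batch_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["batch"]

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        ids = list(sample_ids)
        sub = self.table.set_index("sample_id").loc[ids].reset_index()
        return SampleSheet(sub)

    def by_role(self, role: str) -> "SampleSheet":
        return SampleSheet(self.table[self.table["role"] == role].reset_index(drop=True))

    def class_counts(self) -> dict[str, int]:
        return self.table["subtype"].value_counts().to_dict()


def read_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    t = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    return SampleSheet(t)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(Path(path), sep=_sep_for(path), index=False)


def split_cohort(
    sheet: SampleSheet, train_fraction: float = 0.7, seed: int = 0
) -> tuple[SampleSheet, SampleSheet]:
    """Stratified train/validation split.

    Per subtype, ``round(n_k * train_fraction)`` samples (round half up) go
    to training; the rest to validation.  Deterministic given ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise PanelforgeError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    val_ids: list[str] = []
    for subtype in SUBTYPES:
        ids = sheet.table.loc[sheet.table["subtype"] == subtype, "sample_id"].tolist()
        if not ids:
            continue
        if len(ids) < 2:
            raise PanelforgeError(f"subtype {subtype!r} has fewer than 2 samples")
        n_train = int(math.floor(len(ids) * train_fraction + 0.5))
        perm = rng.permutation(len(ids))
        train_ids += [ids[i] for i in perm[:n_train]]
        val_ids += [ids[i] for i in perm[n_train:]]

    def _with_role(ids: list[str], role: str) -> SampleSheet:
        t = sheet.table.set_index("sample_id").loc[ids].reset_index()
        t["role"] = role
        return SampleSheet(t)

    return _with_role(train_ids, "train"), _with_role(val_ids, "validation")


# ---------------------------------------------------------------------------
# Panel


@dataclass
class Panel:
    """A subtype's final one-vs-rest classifier.

    Centroids, standard errors and scale terms are averages over the
    balanced-resampling iterations; ``mean_error_rate`` / ``mean_auc`` are
    cross-validated performance summaries over the same iterations.
    """

    subtype: str
    features: list[tuple[str, str, str]]  # (feature_id, modality, direction "+"/"-")
    centroid_target: np.ndarray
    centroid_control: np.ndarray
    centroid_se: np.ndarray
    scale: np.ndarray  # averaged (s_j + s0) per feature
    priors: tuple[float, float]  # (target, control)
    mean_error_rate: float
    sd_error_rate: float
    mean_auc: float
    sd_auc: float
    n_iterations: int

    ALLOWED_SIZES = (5, 10)

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise PanelforgeError(f"unknown subtype {self.subtype!r}")
        k = len(self.features)
        if k not in self.ALLOWED_SIZES:
            raise PanelforgeError(
                f"panel must have 5 (single-modality) or 10 (integrative) features, got {k}"
            )
        for arrname in ("centroid_target", "centroid_control", "centroid_se", "scale"):
            arr = np.asarray(getattr(self, arrname), dtype=float)
            if arr.shape != (k,):
                raise PanelforgeError(f"{arrname} must have length {k}")
            setattr(self, arrname, arr)
        if (self.centroid_se < 0).any():
            raise PanelforgeError("centroid_se must be non-negative")
        if not math.isclose(sum(self.priors), 1.0, abs_tol=1e-9):
            raise PanelforgeError("priors must sum to 1")
        for fid, modality, direction in self.features:
            if modality not in MODALITIES:
                raise PanelforgeError(f"feature {fid}: unknown modality {modality!r}")
            if direction not in ("+", "-"):
                raise PanelforgeError(f"feature {fid}: direction must be '+' or '-'")
        per_modality: dict[str, list[str]] = {}
        for fid, modality, direction in self.features:
            per_modality.setdefault(modality, []).append(direction)
        for modality, dirs in per_modality.items():
            if len(dirs) == 5 and (dirs.count("+") < 2 or dirs.count("-") < 2):
                raise PanelforgeError(
                    f"{modality} features must include >=2 positive and >=2 negative markers"
                )

    @property
    def feature_ids(self) -> list[str]:
        return [f[0] for f in self.features]


_PANEL_FIELDS = (
    "subtype",
    "features",
    "centroid_target",
    "centroid_control",
    "centroid_se",
    "scale",
    "priors",
    "mean_error_rate",
    "sd_error_rate",
    "mean_auc",
    "sd_auc",
    "n_iterations",
)


def write_panel(panel: Panel, path: str | Path) -> None:
    doc = {
        "subtype": panel.subtype,
        "features": [list(f) for f in panel.features],
        "centroid_target": panel.centroid_target.tolist(),
        "centroid_control": panel.centroid_control.tolist(),
        "centroid_se": panel.centroid_se.tolist(),
        "scale": panel.scale.tolist(),
        "priors": list(panel.priors),
        "mean_error_rate": panel.mean_error_rate,
        "sd_error_rate": panel.sd_error_rate,
        "mean_auc": panel.mean_auc,
        "sd_auc": panel.sd_auc,
        "n_iterations": panel.n_iterations,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_panel(path: str | Path) -> Panel:
    doc = json.loads(Path(path).read_text())
    missing = [k for k in _PANEL_FIELDS if k not in doc]
    if missing:
        raise PanelforgeError(f"panel file missing field(s): {missing}")
    return Panel(
        subtype=doc["subtype"],
        features=[tuple(f) for f in doc["features"]],
        centroid_target=np.asarray(doc["centroid_target"], dtype=float),
        centroid_control=np.asarray(doc["centroid_control"], dtype=float),
        centroid_se=np.asarray(doc["centroid_se"], dtype=float),
        scale=np.asarray(doc["scale"], dtype=float),
        priors=tuple(doc["priors"]),
        mean_error_rate=doc["mean_error_rate"],
        sd_error_rate=doc["sd_error_rate"],
        mean_auc=doc["mean_auc"],
        sd_auc=doc["sd_auc"],
        n_iterations=doc["n_iterations"],
    )


# ---------------------------------------------------------------------------
# DifferentialTable helpers

DIFFERENTIAL_COLUMNS = ("feature_id", "effect", "p_value", "q_value", "direction", "significant")


def make_differential_table(
    feature_ids: Sequence[str],
    effect: np.ndarray,
    p_value: np.ndarray,
    q_value: np.ndarray,
    significant: np.ndarray,
) -> pd.DataFrame:
    """Assemble a per-feature differential screening table."""
    direction = np.where(np.asarray(effect) >= 0, "+", "-")
    t = pd.DataFrame(
        {
            "feature_id": list(feature_ids),
            "effect": np.asarray(effect, dtype=float),
            "p_value": np.asarray(p_value, dtype=float),
            "q_value": np.asarray(q_value, dtype=float),
            "direction": direction,
            "significant": np.asarray(significant, dtype=bool),
        }
    )
    return t


def write_differential_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED export of CpG panel features


def export_panel_bed(panel: Panel, probe_map: pd.DataFrame, path: str | Path) -> int:
    """Write panel CpG features as a BED file (0-based, half-open).

    ``probe_map`` needs columns ``probe``, ``chrom``, ``pos0``.  Returns the
    number of features written; expression features are skipped.
    """
    need = {"probe", "chrom", "pos0"}
    if not need.issubset(probe_map.columns):
        raise PanelforgeError(f"probe map needs columns {sorted(need)}")
    pm = probe_map.set_index("probe")
    rows = []
    for fid, modality, direction in panel.features:
        if modality not in ("beta", "mvalue"):
            continue
        if fid not in pm.index:
            raise PanelforgeError(f"probe {fid!r} missing from probe map")
        chrom, pos0 = pm.loc[fid, "chrom"], int(pm.loc[fid, "pos0"])
        rows.append(f"{chrom}\t{pos0}\t{pos0 + 1}\t{fid}\t0\t{'+' if direction == '+' else '-'}")
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))
    return len(rows)
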