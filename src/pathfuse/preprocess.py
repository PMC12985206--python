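"""Omics ingestion, harmonization, staging labels and leakage-safe fold transforms.

Three gene-level modalities are supported: continuous expression
(mitochondrial genes removed, log1p applied), gene-level copy number
(GISTIC-style calls treated as continuous), and binary somatic mutation
matrices pivoted from MAF-like variant records.  Patients are harmonized
to 12-character short identifiers with duplicate aliquots averaged, and
pathologic T/N/M stage strings are binarized to clinically interpretable
endpoints (Tis/T1-2 vs T3-4; N0 vs N1-3; M0 vs M1).

All fold-wise statistics (imputation means, z-scoring) are fitted on
training splits only and applied elsewhere with the stored parameters;
an optional capped Borderline-SMOTE oversamples the minority class
inside training folds only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsMatrix",
    "FoldTransform",
    "load_expression",
    "load_cnv",
    "load_maf",
    "maf_to_binary_matrix",
    "load_clinical",
    "binarize_stage",
    "harmonize",
    "fit_fold_transform",
    "apply_fold_transform",
    "borderline_smote",
]

MODALITIES = ("expression", "cnv", "snv")

#: variant classes carrying no protein-level consequence, dropped before pivoting
NONFUNCTIONAL_CLASSES = frozenset(
    {
        "silent",
        "3'utr",
        "5'utr",
        "3'flank",
        "5'flank",
        "intron",
        "igr",
        "rna",
    }
)

MIN_ALT_READS = 5  # records need t_alt_count > 5 when the column exists


@dataclass
class OmicsMatrix:
    """Sample x gene value matrix for one modality."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    modality: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "snv" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("snv matrix must be binary")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, modality: str) -> "OmicsMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=np.float64), modality)

    def restrict_genes(self, genes: list[str], fill: float = 0.0) -> "OmicsMatrix":
        """Reindex columns to ``genes``; absent genes are filled and logged."""
        df = self.to_frame()
        missing = [g for g in genes if g not in df.columns]
        if missing:
            logger.warning(
                "%s: %d requested gene(s) absent, filled with %g", self.modality,
                len(missing), fill,
            )
        out = df.reindex(columns=genes, fill_value=fill)
        return OmicsMatrix.from_frame(out, self.modality)


# ------------------------------------------------------------------- loaders
def load_expression(path) -> OmicsMatrix:
    """Load an expression TSV (rows samples, columns genes), drop MT-* genes, log1p."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative values")
    keep = [g for g in df.columns if not str(g).upper().startswith("MT-")]
    df = df[keep]
    if df.shape[1] == 0:
        raise ValueError("no genes left after removing mitochondrial (MT-*) genes")
    return OmicsMatrix.from_frame(np.log1p(df), "expression")


def load_cnv(path) -> OmicsMatrix:
    """Load a gene-level copy-number TSV (rows samples, columns genes)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OmicsMatrix.from_frame(df, "cnv")


def load_maf(path) -> pd.DataFrame:
    """Read a MAF-like TSV of one variant record per row."""
    return pd.read_csv(path, sep="\t", comment="#")


def maf_to_binary_matrix(records: pd.DataFrame) -> OmicsMatrix:
    """Pivot MAF-like variant records to a binary sample x gene mutation matrix.

    Non-functional variant classes (silent / UTR / intron / IGR / flank / RNA)
    are excluded; when a ``t_alt_count`` column is present, records with
    alt-read support <= 5 are dropped (otherwise the filter is skipped with a
    logged notice); surviving (sample, gene) pairs are deduplicated and any
    qualifying variant sets the cell to 1.
    """
    required = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]
    for col in required:
        if col not in records.columns:
            raise ValueError(f"MAF input is missing mandatory column {col!r}")
    df = records.copy()
    cls = df["Variant_Classification"].astype(str).str.strip().str.lower()
    df = df[~cls.isin(NONFUNCTIONAL_CLASSES)]
    if "t_alt_count" in df.columns:
        df = df[pd.to_numeric(df["t_alt_count"], errors="coerce") > MIN_ALT_READS]
    else:
        logger.info("MAF has no t_alt_count column; alt-read filter skipped")
    pairs = df[["Tumor_Sample_Barcode", "Hugo_Symbol"]].drop_duplicates()
    if pairs.empty:
        raise ValueError("no qualifying variant records after filtering")
    mat = pd.crosstab(pairs["Tumor_Sample_Barcode"], pairs["Hugo_Symbol"]).clip(upper=1)
    mat = mat.sort_index().sort_index(axis=1)
    return OmicsMatrix.from_frame(mat.astype(float), "snv")


# -------------------------------------------------------------------- labels
_EXCLUDED_STAGES = {"tx", "nx", "mx", "not reported", "unknown", ""}

EXCLUDED = "excluded"


def binarize_stage(raw: str, endpoint: str) -> int | str:
    """Binarize a raw pathologic stage string for one endpoint.

    T: Tis/T1-2 -> 0, T3-4 -> 1.  N: N0 -> 0, N1-3 -> 1.  M: M0 -> 0,
    M1 -> 1.  TX/NX/MX and unreported values map to ``"excluded"``;
    substage suffixes (a/b/c) are honored, matching is case-insensitive.
    Unrecognized strings are excluded with a warning rather than guessed.
    """
    if endpoint not in ("T", "N", "M"):
        raise ValueError(f"endpoint must be T, N or M, got {endpoint!r}")
    s = str(raw).strip().lower()
    if s in _EXCLUDED_STAGES:
        return EXCLUDED
    table = {
        "T": {("tis", "t1", "t2"): 0, ("t3", "t4"): 1},
        "N": {("n0",): 0, ("n1", "n2", "n3"): 1},
        "M": {("m0",): 0, ("m1",): 1},
    }[endpoint]
    for prefixes, label in table.items():
        for prefix in prefixes:
            if s == prefix or (s.startswith(prefix) and s[len(prefix):].isalpha()):
                return label
    warnings.warn(f"unrecognized {endpoint}-stage string {raw!r}; excluding", stacklevel=2)
    return EXCLUDED


def load_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV with patient_id and stage_T/stage_N/stage_M columns."""
    df = pd.read_csv(path, sep="\t")
    if "patient_id" not in df.columns:
        raise ValueError("clinical table is missing a patient_id column")
    return df.drop_duplicates(subset="patient_id")


def stage_labels(clinical: pd.DataFrame, endpoint: str) -> pd.Series:
    """Binary label per patient for one endpoint; excluded patients dropped."""
    col = f"stage_{endpoint}"
    if col not in clinical.columns:
        raise ValueError(f"clinical table is missing column {col!r}")
    lab = clinical.set_index("patient_id")[col].map(lambda s: binarize_stage(s, endpoint))
    lab = lab[lab != EXCLUDED].astype(int)
    lab.index = [str(i)[:12] for i in lab.index]
    return lab[~lab.index.duplicated()]


# --------------------------------------------------------------- harmonization
def _short_id(sample_id: str) -> str:
    return str(sample_id)[:12]


def harmonize(
    matrices: list[OmicsMatrix], labels: pd.Series | None = None
) -> tuple[list[OmicsMatrix], pd.Series | None]:
    """Align modalities (and labels) on the intersection of 12-char short IDs.

    Aliquot rows sharing a short ID are averaged elementwise; binary
    mutation rows are re-binarized (>0) after averaging so any qualifying
    variant still maps to 1.  Row order is identical across all outputs.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    collapsed = []
    for m in matrices:
        df = m.to_frame()
        df.index = [_short_id(s) for s in df.index]
        df = df.groupby(level=0).mean()
        if m.modality == "snv":
            df = (df > 0).astype(float)
        collapsed.append(OmicsMatrix.from_frame(df, m.modality))
    common = set(collapsed[0].sample_ids)
    for m in collapsed[1:]:
        common &= set(m.sample_ids)
    if labels is not None:
        common &= set(labels.index)
    if not common:
        raise ValueError("no samples shared across all modalities (and labels)")
    order = sorted(common)
    out = [OmicsMatrix.from_frame(m.to_frame().loc[order], m.modality) for m in collapsed]
    return out, (labels.loc[order] if labels is not None else None)


# ----------------------------------------------------------- fold transforms
@dataclass
class FoldTransform:
    """Imputation + scaling parameters fitted on one training fold only."""

    means: np.ndarray
    scales: np.ndarray
    modality: str
    fitted_on: str = "train"
    standardize: bool = True


def fit_fold_transform(train: OmicsMatrix, fold_id: str = "train") -> FoldTransform:
    """Fit per-gene imputation means and (for continuous modalities) z-scales.

    Binary mutation matrices are imputed but never rescaled.  Zero-variance
    genes get scale 1 with a warning so transformed values stay finite.
    """
    if train.values.shape[0] < 2:
        raise ValueError("need >= 2 training samples to fit a fold transform")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        means = np.nanmean(train.values, axis=0)
    means = np.where(np.isfinite(means), means, 0.0)
    standardize = train.modality != "snv"
    if standardize:
        filled = np.where(np.isnan(train.values), means, train.values)
        scales = filled.std(axis=0, ddof=0)
        zero = scales == 0
        if zero.any():
            warnings.warn(
                f"{zero.sum()} gene(s) with zero training variance; scale set to 1",
                stacklevel=2,
            )
            scales = np.where(zero, 1.0, scales)
    else:
        scales = np.ones_like(means)
    return FoldTransform(means, scales, train.modality, fold_id, standardize)


def apply_fold_transform(t: FoldTransform, m: OmicsMatrix) -> OmicsMatrix:
    """Impute with training means, then z-score continuous modalities."""
    if m.modality != t.modality:
        raise ValueError(f"transform for {t.modality} applied to {m.modality}")
    vals = np.where(np.isnan(m.values), t.means, m.values)
    if t.standardize:
        vals = (vals - t.means) / t.scales
        return OmicsMatrix(list(m.sample_ids), list(m.gene_ids), vals, m.modality)
    out = OmicsMatrix.__new__(OmicsMatrix)  # skip binary check: imputed snv may be fractional
    out.sample_ids = list(m.sample_ids)
    out.gene_ids = list(m.gene_ids)
    out.values = vals
    out.modality = m.modality
    return out


# -------------------------------------------------------------------- SMOTE
def borderline_smote(
    train_x: np.ndarray,
    train_y: np.ndarray,
    k: int = 5,
    cap: float = 0.15,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Capped Borderline-SMOTE over a training fold.

    Synthetic minority samples are interpolated between *borderline*
    minority points (those whose k-neighborhood in the whole fold is
    half-or-more majority but not entirely majority) and their k nearest
    minority neighbors.  At most ``cap`` x the pre-augmentation fold size
    synthetic rows are appended; originals are returned unmodified first.
    """
    train_x = np.asarray(train_x, dtype=np.float64)
    train_y = np.asarray(train_y)
    classes, counts = np.unique(train_y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"borderline_smote needs binary labels, got classes {classes}")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return train_x, train_y
    if n_min < k + 1:
        warnings.warn(
            f"minority class has {n_min} < k+1={k + 1} members; resampling skipped",
            stacklevel=2,
        )
        return train_x, train_y

    rng = np.random.default_rng(seed)
    n_target = min(n_maj - n_min, int(np.floor(cap * len(train_y))))
    if n_target == 0:
        return train_x, train_y

    min_idx = np.flatnonzero(train_y == minority)
    x_min = train_x[min_idx]
    # danger set: at least half (but not all) of the k whole-fold neighbors are majority
    nn_all = NearestNeighbors(n_neighbors=k + 1).fit(train_x)
    _, neigh = nn_all.kneighbors(x_min)
    n_majority_neigh = (train_y[neigh[:, 1:]] != minority).sum(axis=1)
    danger = (n_majority_neigh >= k / 2.0) & (n_majority_neigh < k)
    seeds = x_min[danger] if danger.any() else x_min  # fall back to all minority points

    nn_min = NearestNeighbors(n_neighbors=min(k + 1, len(x_min))).fit(x_min)
    _, min_neigh = nn_min.kneighbors(seeds)
    synth = np.empty((n_target, train_x.shape[1]))
    pick_seed = rng.integers(0, len(seeds), size=n_target)
    for row, i in enumerate(pick_seed):
        j = min_neigh[i][rng.integers(1, min_neigh.shape[1])]
        lam = rng.uniform()
        synth[row] = seeds[i] + lam * (x_min[j] - seeds[i])
    logger.info("borderline-SMOTE: appended %d synthetic minority sample(s)", n_target)
    return (
        np.vstack([train_x, synth]),
        np.concatenate([train_y, np.full(n_target, minority, dtype=train_y.dtype)]),
    )
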