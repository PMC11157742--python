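"""Omics table I/O, sample alignment across modalities, and feature filters.

The in-memory currency is :class:`OmicsMatrix` (one modality, samples x
features) and :class:`MultiOmicsDataset` (aligned modalities + presence mask +
clinical table).  The four per-modality feature filters implement the
selection rules commonly applied to pan-cancer TCGA-style inputs:

* expression — keep high-variance genes (per-feature SD above a threshold);
* mutation   — keep genes mutated in at least a minimum fraction of samples;
* methylation — drop probes lowly methylated (beta below a cut) in more than
  a stated fraction of samples;
* CNV        — keep segments that are rarely exactly zero, have mean absolute
  log-ratio above a floor and coefficient of variation above a floor.

All filters preserve feature order, never touch the sample axis, and are
idempotent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
BINARY = "binary"


class OmicsValidationError(ValueError):
    """Raised when an omics table violates its contract."""


@dataclass
class OmicsMatrix:
    """One modality's samples x features value table."""

    name: str
    sample_ids: List[str]
    feature_ids: List[str]
    values: np.ndarray
    kind: str = CONTINUOUS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise OmicsValidationError(
                f"{self.name}: values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if self.kind not in (CONTINUOUS, BINARY):
            raise OmicsValidationError(f"{self.name}: unknown kind {self.kind!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise OmicsValidationError(f"{self.name}: duplicate sample ID {dup!r}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dup = _first_duplicate(self.feature_ids)
            raise OmicsValidationError(f"{self.name}: duplicate feature ID {dup!r}")
        if not np.all(np.isfinite(self.values)):
            raise OmicsValidationError(f"{self.name}: non-finite values present")
        if self.kind == BINARY:
            bad = (self.values != 0) & (self.values != 1)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise OmicsValidationError(
                    f"{self.name}: binary matrix has value {self.values[i, j]} at "
                    f"sample {self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def select_features(self, keep: np.ndarray) -> "OmicsMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            feature_ids=[self.feature_ids[i] for i in keep],
            values=self.values[:, keep],
        )

    def reorder_samples(self, order: Sequence[int]) -> "OmicsMatrix":
        order = list(order)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in order],
            values=self.values[order, :],
        )


@dataclass
class MultiOmicsDataset:
    """Aligned multi-modality dataset with per-sample presence mask.

    ``presence_mask[i, m]`` is 1 when sample ``i`` has modality ``m`` observed.
    Rows of a missing modality are retained in storage but must never be read
    by an encoder; the mask is authoritative.
    """

    modalities: Dict[str, OmicsMatrix]
    presence_mask: np.ndarray
    clinical: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.presence_mask = np.asarray(self.presence_mask, dtype=np.float64)
        names = self.modality_names
        n = self.n_samples
        if self.presence_mask.shape != (n, len(names)):
            raise OmicsValidationError(
                f"presence mask shape {self.presence_mask.shape} != ({n}, {len(names)})"
            )
        for m in self.modalities.values():
            if m.sample_ids != self.sample_ids:
                raise OmicsValidationError(
                    f"modality {m.name}: sample order differs from dataset order"
                )
        if (self.presence_mask.sum(axis=1) < 1).any():
            raise OmicsValidationError("every sample must retain >= 1 present modality")

    @property
    def modality_names(self) -> List[str]:
        return list(self.modalities)

    @property
    def sample_ids(self) -> List[str]:
        return next(iter(self.modalities.values())).sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, idx: Sequence[int]) -> "MultiOmicsDataset":
        idx = list(idx)
        clinical = self.clinical.iloc[idx].reset_index(drop=True) if len(self.clinical) else self.clinical
        return MultiOmicsDataset(
            modalities={k: m.reorder_samples(idx) for k, m in self.modalities.items()},
            presence_mask=self.presence_mask[idx, :],
            clinical=clinical,
        )


def _first_duplicate(items: Sequence[str]) -> str:
    seen = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return ""


# -- I/O -------------------------------------------------------------------

def read_omics_table(path, modality_name: str, kind: str = CONTINUOUS) -> OmicsMatrix:
    """Read a CSV/TSV matrix (first column sample ID, header of feature IDs)."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise OmicsValidationError(f"{path}: malformed table ({exc})") from exc
    if df.isna().any().any():
        raise OmicsValidationError(f"{path}: missing entries within the table")
    return OmicsMatrix(
        name=modality_name,
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(f) for f in df.columns],
        values=df.to_numpy(dtype=np.float64),
        kind=kind,
    )


def write_omics_table(matrix: OmicsMatrix, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    matrix.to_frame().to_csv(path, sep=sep, index_label="sample_id")


def write_dataset(dataset: MultiOmicsDataset, out_dir) -> None:
    """Write one CSV per modality, the clinical TSV and the presence mask TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, m in dataset.modalities.items():
        write_omics_table(m, out / f"{name}.csv")
    mask = pd.DataFrame(
        dataset.presence_mask.astype(int),
        index=dataset.sample_ids,
        columns=dataset.modality_names,
    )
    mask.to_csv(out / "presence_mask.tsv", sep="\t", index_label="sample_id")
    if len(dataset.clinical):
        dataset.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)


# -- alignment -------------------------------------------------------------

def align_samples(matrices: Sequence[OmicsMatrix],
                  clinical: pd.DataFrame | None = None) -> MultiOmicsDataset:
    """Align modalities on a common, lexicographic sample order.

    Samples present in at least one modality (and in the clinical table, when
    given) are kept; samples in no modality are dropped and logged.  A sample
    absent from some modality is marked missing in the presence mask and its
    stored row is zero (never read: the mask gates every consumer).
    """
    if not matrices:
        raise OmicsValidationError("align_samples needs at least one matrix")
    union: set = set()
    for m in matrices:
        union |= set(m.sample_ids)
    if clinical is not None and len(clinical):
        clin_ids = set(clinical["sample_id"].astype(str))
        dropped = union - clin_ids
        if dropped:
            logger.info("align_samples: %d samples lack clinical rows; dropped", len(dropped))
        union &= clin_ids
        if not union:
            raise OmicsValidationError("no samples shared between omics and clinical table")
    order = sorted(union)
    index = {s: i for i, s in enumerate(order)}

    aligned: Dict[str, OmicsMatrix] = {}
    mask = np.zeros((len(order), len(matrices)))
    for j, m in enumerate(matrices):
        values = np.zeros((len(order), m.n_features))
        for i_src, sid in enumerate(m.sample_ids):
            i_dst = index.get(sid)
            if i_dst is not None:
                values[i_dst] = m.values[i_src]
                mask[i_dst, j] = 1.0
        aligned[m.name] = OmicsMatrix(m.name, list(order), list(m.feature_ids), values, m.kind)

    clin_out = pd.DataFrame({"sample_id": order})
    if clinical is not None and len(clinical):
        clinical = clinical.copy()
        clinical["sample_id"] = clinical["sample_id"].astype(str)
        clin_out = clin_out.merge(clinical, on="sample_id", how="left")
    return MultiOmicsDataset(aligned, mask, clin_out)


# -- feature filters -------------------------------------------------------

def _check_not_empty(keep: np.ndarray, matrix: OmicsMatrix, which: str):
    if not keep.any():
        raise OmicsValidationError(
            f"{which} removed every feature of {matrix.name}; relax the threshold"
        )


def filter_expression(matrix: OmicsMatrix, sd_threshold: float = 1.0,
                      keep_high_variance: bool = True) -> OmicsMatrix:
    """Keep genes whose per-feature SD exceeds ``sd_threshold``.

    ``keep_high_variance=False`` inverts the direction (keep SD <= threshold).
    """
    if matrix.kind != CONTINUOUS:
        raise OmicsValidationError("expression filter expects a continuous matrix")
    sd = matrix.values.std(axis=0, ddof=0)
    keep = sd > sd_threshold if keep_high_variance else sd <= sd_threshold
    _check_not_empty(keep, matrix, "expression SD filter")
    return matrix.select_features(keep)


def filter_mutation(matrix: OmicsMatrix, min_fraction: float = 0.01) -> OmicsMatrix:
    """Keep genes mutated in at least ``min_fraction`` of samples (inclusive)."""
    if matrix.kind != BINARY:
        raise OmicsValidationError("mutation filter expects a binary matrix")
    frac = matrix.values.mean(axis=0)
    keep = frac >= min_fraction
    _check_not_empty(keep, matrix, "mutation frequency filter")
    return matrix.select_features(keep)


def filter_methylation(matrix: OmicsMatrix, beta_cut: float = 0.3,
                       sample_fraction: float = 0.9) -> OmicsMatrix:
    """Drop probes with beta < ``beta_cut`` in strictly more than
    ``sample_fraction`` of samples."""
    if matrix.kind != CONTINUOUS:
        raise OmicsValidationError("methylation filter expects a continuous matrix")
    if (matrix.values < 0).any() or (matrix.values > 1).any():
        raise OmicsValidationError(f"{matrix.name}: beta values must lie in [0, 1]")
    low_frac = (matrix.values < beta_cut).mean(axis=0)
    keep = low_frac <= sample_fraction
    _check_not_empty(keep, matrix, "methylation filter")
    return matrix.select_features(keep)


def filter_cnv(matrix: OmicsMatrix, max_zero_fraction: float = 0.05,
               min_mean_abs: float = 0.20, min_cv: float = 0.20) -> OmicsMatrix:
    """Keep segments passing all three informativeness criteria.

    Zero fraction strictly below ``max_zero_fraction``; mean absolute value
    strictly above ``min_mean_abs``; coefficient of variation (SD / |mean|)
    strictly above ``min_cv``.  A mean-zero feature has CV = +inf and passes
    the CV criterion.
    """
    if matrix.kind != CONTINUOUS:
        raise OmicsValidationError("CNV filter expects a continuous matrix")
    v = matrix.values
    zero_frac = (v == 0).mean(axis=0)
    mean_abs = np.abs(v).mean(axis=0)
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=0)
    with np.errstate(divide="ignore"):
        cv = np.where(mean == 0, np.inf, sd / np.abs(np.where(mean == 0, 1.0, mean)))
    keep = (zero_frac < max_zero_fraction) & (mean_abs > min_mean_abs) & (cv > min_cv)
    _check_not_empty(keep, matrix, "CNV filter")
    return matrix.select_features(keep)


def filter_report(before: OmicsMatrix, after: OmicsMatrix, path=None) -> dict:
    report = {
        "modality": before.name,
        "n_features_before": before.n_features,
        "n_features_after": after.n_features,
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2))
    return report


# -- fold splitting --------------------------------------------------------

def split_folds_by_subtype(dataset: MultiOmicsDataset, k: int = 5,
                           seed: int = 0) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold split on the clinical subtype label.

    Subtypes with fewer than ``k`` members are pooled into one stratum (and
    logged) so stratification never fails on rare classes.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(dataset.clinical["subtype"])
    n = len(labels)
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    strata = np.array([str(l) for l in labels], dtype=object)
    counts = pd.Series(strata).value_counts()
    rare = counts[counts < k].index
    if len(rare):
        logger.info("split_folds_by_subtype: pooling rare subtypes %s", list(rare))
        pooled = np.isin(strata, rare)
        if (~pooled).any():
            # merge into the largest stratum so no class falls below k
            strata[pooled] = counts.index[0]
        else:
            strata[pooled] = "__pooled__"
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(train, val) for train, val in skf.split(np.zeros(n), strata)]
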