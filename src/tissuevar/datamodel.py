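"""Core data types and I/O for nested tissue-profiling designs.

A study profiles several tissues (endometrium, subcutaneous fat,
endometriotic disease tissue) from a set of individuals.  Each physical
tissue sample may be *split* before extraction (to expose cellular
heterogeneity) and each extracted split may be run on more than one array
(a technical *replicate*).  A sample row is therefore identified by the
nested key ``(individual_id, tissue, split_id, replicate_id)``.

Values are carried in a :class:`ProbeMatrix` (probes x samples), either
methylation beta values in [0, 1] or log2 expression intensities, and the
design labels plus covariates in a per-sample metadata table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BETA",
    "LOG2_INTENSITY",
    "TISSUES",
    "SUBTYPES",
    "PHASES",
    "METADATA_COLUMNS",
    "ProbeMatrix",
    "Dataset",
    "DatasetError",
    "categorize_phase",
    "read_dataset",
    "write_dataset",
    "average_profiles",
]

BETA = "beta"
LOG2_INTENSITY = "log2_intensity"
SCALES = (BETA, LOG2_INTENSITY)

TISSUES = ("endometrium", "fat", "endometriotic")
SUBTYPES = ("none", "peritoneal", "endometrioma")
PHASES = ("menstrual", "proliferative", "secretory")

#: Design labels and covariates carried per sample (one row per array).
METADATA_COLUMNS = [
    "sample_id",
    "individual_id",
    "tissue",
    "subtype",
    "split_id",
    "replicate_id",
    "case_status",
    "age",
    "cycle_day",
    "cycle_length",
    "phase",
    "smoking",
    "bmi",
    "whr",
    "tissue_weight_g",
    "dna_yield_ng",
    "call_rate",
    "rin",
    "housekeeping_signal",
]

#: Covariates that describe the individual/sample and must agree between
#: splits and replicates of the same physical sample.
BIOLOGICAL_COLUMNS = [
    "individual_id",
    "tissue",
    "subtype",
    "case_status",
    "age",
    "cycle_day",
    "cycle_length",
    "phase",
    "smoking",
    "bmi",
    "whr",
]

#: Per-array or per-extraction quality fields; these legitimately differ
#: between replicates and are averaged when profiles are collapsed.
TECHNICAL_COLUMNS = [
    "tissue_weight_g",
    "dna_yield_ng",
    "call_rate",
    "rin",
    "housekeeping_signal",
]


class DatasetError(ValueError):
    """Structural or validation failure in a dataset."""


@dataclass
class ProbeMatrix:
    """Probes x samples value matrix with a scale tag.

    Parameters
    ----------
    probe_ids, sample_ids
        Unique row / column identifiers.
    values
        ``(n_probes, n_samples)`` float array.
    scale
        ``"beta"`` (values constrained to [0, 1]) or ``"log2_intensity"``.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = BETA

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.scale not in SCALES:
            raise DatasetError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise DatasetError("duplicate probe IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DatasetError("duplicate sample IDs")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise DatasetError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            raise DatasetError(
                "missing values in matrix; drop incomplete probes before analysis"
            )
        if self.scale == BETA and self.values.size:
            lo, hi = self.values.min(), self.values.max()
            if lo < 0.0 or hi > 1.0:
                raise DatasetError(
                    f"beta-scale values outside [0, 1] (range {lo:.4g}..{hi:.4g})"
                )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.probe_ids, name="probe_id"),
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scale: str = BETA) -> "ProbeMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float), scale)

    def subset_samples(self, sample_ids: list[str]) -> "ProbeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ProbeMatrix(self.probe_ids, list(sample_ids), self.values[:, idx], self.scale)


@dataclass
class Dataset:
    """A :class:`ProbeMatrix` plus its per-sample metadata table."""

    matrix: ProbeMatrix
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.metadata = self.metadata.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        md = self.metadata
        missing_cols = [c for c in METADATA_COLUMNS if c not in md.columns]
        if missing_cols:
            raise DatasetError(f"metadata missing columns: {missing_cols}")
        md_ids = md["sample_id"].astype(str)
        if md_ids.duplicated().any():
            dups = sorted(md_ids[md_ids.duplicated()].unique())
            raise DatasetError(f"duplicate sample_id in metadata: {dups}")
        matrix_ids = set(self.matrix.sample_ids)
        meta_ids = set(md_ids)
        if matrix_ids != meta_ids:
            missing = sorted(matrix_ids - meta_ids)
            extra = sorted(meta_ids - matrix_ids)
            raise DatasetError(
                f"sample sets differ: missing from metadata {missing}; "
                f"missing from matrix {extra}"
            )
        key = md[["individual_id", "tissue", "split_id", "replicate_id"]].astype(str)
        if key.duplicated().any():
            raise DatasetError(
                "(individual_id, tissue, split_id, replicate_id) is not unique"
            )
        bad_tissue = set(md["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise DatasetError(f"unknown tissue labels: {sorted(bad_tissue)}")
        sub = md["subtype"].fillna("none")
        bad = md[(sub != "none") & (md["tissue"] != "endometriotic")]
        if len(bad):
            raise DatasetError(
                "subtype set for non-endometriotic samples: "
                f"{sorted(bad['sample_id'])}"
            )

    @property
    def n_probes(self) -> int:
        return self.matrix.n_probes

    @property
    def n_samples(self) -> int:
        return self.matrix.n_samples

    def metadata_for(self, sample_id: str) -> pd.Series:
        row = self.metadata.loc[self.metadata["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row.iloc[0]

    def subset_samples(self, sample_ids: list[str]) -> "Dataset":
        md = self.metadata[self.metadata["sample_id"].isin(sample_ids)]
        return Dataset(self.matrix.subset_samples(list(sample_ids)), md)

    def filter_tissue(self, tissue: str) -> "Dataset":
        keep = list(self.metadata.loc[self.metadata["tissue"] == tissue, "sample_id"])
        if not keep:
            raise DatasetError(f"no samples of tissue {tissue!r}")
        return self.subset_samples(keep)


def categorize_phase(cycle_day, cycle_length: float = 28) -> str | None:
    """Assign the menstrual-cycle phase for a self-reported cycle day.

    The day is first rescaled linearly to a canonical 28-day cycle
    (``d' = round(cycle_day * 28 / cycle_length)``), then binned:
    menstrual for days 1-7, proliferative for 8-14, secretory for 15+.

    Returns ``None`` when ``cycle_day`` is missing; no phase is guessed.
    """
    if cycle_day is None or (isinstance(cycle_day, float) and math.isnan(cycle_day)):
        return None
    if cycle_day < 1:
        raise ValueError(f"cycle_day must be >= 1, got {cycle_day}")
    if cycle_length < 21:
        raise ValueError(f"cycle_length must be >= 21 days, got {cycle_length}")
    day = int(round(cycle_day * 28.0 / cycle_length))
    day = max(day, 1)
    if day <= 7:
        return "menstrual"
    if day <= 14:
        return "proliferative"
    return "secretory"


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def _infer_scale(values: np.ndarray) -> str:
    return BETA if values.size and values.min() >= 0.0 and values.max() <= 1.0 else LOG2_INTENSITY


def read_dataset(matrix_path, metadata_path, scale: str | None = None) -> Dataset:
    """Read a matrix TSV (first column ``probe_id``) and a metadata TSV.

    ``scale`` may be given explicitly; otherwise it is inferred from the
    value range (all values in [0, 1] => beta).  Validation errors name the
    offending samples or cells.
    """
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0,
                        float_precision="round_trip")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(frame.columns):
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = coerced.isna() & frame[col].notna()
            if bad.any():
                probe = frame.index[bad.argmax()]
                raise DatasetError(
                    f"non-numeric cell at probe {probe!r}, sample {col!r} "
                    f"in {matrix_path}"
                ) from None
        raise
    metadata = pd.read_csv(metadata_path, sep="\t")
    matrix = ProbeMatrix(
        list(frame.index.astype(str)),
        list(frame.columns.astype(str)),
        values,
        scale or _infer_scale(values),
    )
    return Dataset(matrix, metadata)


def write_dataset(dataset: Dataset, matrix_path, metadata_path) -> None:
    """Write the matrix and metadata TSVs (full float precision)."""
    frame = dataset.matrix.to_frame()
    frame.to_csv(matrix_path, sep="\t", float_format="%.17g")
    dataset.metadata.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Split/replicate averaging
# ---------------------------------------------------------------------------

_LEVEL_KEYS = {
    # collapse replicates of the same extracted split
    "replicate": ["individual_id", "tissue", "split_id"],
    # collapse splits to one profile per individual x tissue
    "split": ["individual_id", "tissue"],
    # collapse everything below individual x tissue in one pass
    "all": ["individual_id", "tissue"],
}


def average_profiles(dataset: Dataset, level: str = "all") -> Dataset:
    """Average probe values across splits and/or replicates.

    ``level``:

    * ``"replicate"`` — average arrays of the same extracted split;
    * ``"split"`` / ``"all"`` — average all rows down to one independent
      profile per individual x tissue.

    Biological covariates must be identical within each collapsed group
    (a conflict raises :class:`DatasetError`); per-array quality fields
    are averaged.
    """
    if level not in _LEVEL_KEYS:
        raise ValueError(f"level must be one of {sorted(_LEVEL_KEYS)}, got {level!r}")
    keys = _LEVEL_KEYS[level]
    md = dataset.metadata
    frame = dataset.matrix.to_frame()

    new_values = []
    new_rows = []
    groups = md.groupby(keys, sort=True, dropna=False)
    for group_key, rows in groups:
        if not isinstance(group_key, tuple):
            group_key = (group_key,)
        bio = rows[[c for c in BIOLOGICAL_COLUMNS if c not in keys]]
        n_distinct = bio.astype(object).nunique(dropna=False)
        conflicts = list(n_distinct.index[n_distinct > 1])
        if conflicts:
            raise DatasetError(
                f"conflicting covariates {conflicts} within group {group_key}"
            )
        sample_ids = list(rows["sample_id"])
        new_values.append(frame[sample_ids].to_numpy().mean(axis=1))
        out = rows.iloc[0].copy()
        for c in TECHNICAL_COLUMNS:
            out[c] = rows[c].astype(float).mean()
        out["sample_id"] = "_".join(str(k) for k in group_key)
        if "split_id" not in keys:
            out["split_id"] = "avg"
        out["replicate_id"] = "avg"
        new_rows.append(out)

    matrix = ProbeMatrix(
        dataset.matrix.probe_ids,
        [r["sample_id"] for r in new_rows],
        np.column_stack(new_values),
        dataset.matrix.scale,
    )
    return Dataset(matrix, pd.DataFrame(new_rows))
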