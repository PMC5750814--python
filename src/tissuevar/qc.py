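"""Sample-level quality-control filters and quality-covariate scans.

DNA arrays are retained when the extraction yielded more than 1000 ng and
the array call rate exceeds 98%; RNA arrays when the RNA Integrity Number
exceeds 7 and the mean housekeeping-gene signal is at least 10,000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import Dataset, DatasetError

__all__ = [
    "DNA_YIELD_MIN_NG",
    "CALL_RATE_MIN",
    "RIN_MIN",
    "HOUSEKEEPING_MIN",
    "QCReport",
    "qc_dna",
    "qc_rna",
    "quality_covariate_scan",
]

DNA_YIELD_MIN_NG = 1000.0   # retain yield > 1000 ng
CALL_RATE_MIN = 0.98        # retain call rate > 98%
RIN_MIN = 7.0               # retain RIN > 7 (RIN = 7.0 is excluded)
HOUSEKEEPING_MIN = 10_000.0  # retain housekeeping signal >= 10,000


@dataclass
class QCReport:
    table: pd.DataFrame  # sample_id, filter, value, threshold, decision
    n_input: int
    n_retained: int

    @property
    def excluded(self) -> list[str]:
        t = self.table
        return sorted(t.loc[t["decision"] == "exclude", "sample_id"].unique())


def _apply_filters(dataset: Dataset, filters) -> tuple[Dataset, QCReport]:
    md = dataset.metadata
    needed = [f[0] for f in filters]
    missing = md[md[needed].isna().any(axis=1)]
    if len(missing):
        raise DatasetError(
            f"missing QC fields {needed} for samples: {sorted(missing['sample_id'])}"
        )
    rows = []
    keep_mask = pd.Series(True, index=md.index)
    for col, threshold, strict in filters:
        vals = md[col].astype(float)
        ok = vals > threshold if strict else vals >= threshold
        keep_mask &= ok
        for sid, v, passed in zip(md["sample_id"], vals, ok):
            rows.append({"sample_id": sid, "filter": col, "value": v,
                         "threshold": threshold,
                         "decision": "retain" if passed else "exclude"})
    report = QCReport(pd.DataFrame(rows), n_input=len(md),
                      n_retained=int(keep_mask.sum()))
    kept = list(md.loc[keep_mask, "sample_id"])
    if not kept:
        raise DatasetError("no samples pass QC")
    return dataset.subset_samples(kept), report


def qc_dna(dataset: Dataset) -> tuple[Dataset, QCReport]:
    """Retain DNA samples with yield > 1000 ng and call rate > 98%."""
    return _apply_filters(dataset, [("dna_yield_ng", DNA_YIELD_MIN_NG, True),
                                    ("call_rate", CALL_RATE_MIN, True)])


def qc_rna(dataset: Dataset) -> tuple[Dataset, QCReport]:
    """Retain RNA samples with RIN > 7 and housekeeping signal >= 10,000."""
    return _apply_filters(dataset, [("rin", RIN_MIN, True),
                                    ("housekeeping_signal", HOUSEKEEPING_MIN, False)])


#: Covariates scanned against a quality field, and how each is tested.
_CONTINUOUS = ["dna_yield_ng", "cycle_day", "tissue_weight_g", "age", "bmi", "whr"]


def quality_covariate_scan(dataset: Dataset, quality_field: str,
                           covariates: list[str] | None = None) -> pd.DataFrame:
    """Association of a per-sample quality metric with study covariates.

    Continuous covariates are tested with Pearson's correlation (two
    sided); tissue type with a one-way ANOVA F test.  A constant covariate
    yields an undefined statistic and is flagged, not dropped.
    """
    md = dataset.metadata
    if quality_field not in md.columns:
        raise DatasetError(f"unknown quality field {quality_field!r}")
    q = md[quality_field].astype(float)
    if covariates is None:
        covariates = [c for c in _CONTINUOUS if c != quality_field] + ["tissue"]
    rows = []
    for cov in covariates:
        if cov == "tissue":
            groups = [q[md["tissue"] == t].dropna().to_numpy()
                      for t in sorted(md["tissue"].unique())]
            groups = [g for g in groups if len(g)]
            if len(groups) < 2 or all(np.ptp(np.concatenate(groups)) == 0 for _ in [0]):
                rows.append({"covariate": cov, "test": "anova", "statistic": np.nan,
                             "p": np.nan, "note": "undefined (fewer than 2 groups or constant)"})
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                f, p = stats.f_oneway(*groups)
            rows.append({"covariate": cov, "test": "anova", "statistic": float(f),
                         "p": float(p), "note": ""})
        else:
            x = md[cov].astype(float)
            mask = x.notna() & q.notna()
            if mask.sum() < 3:
                rows.append({"covariate": cov, "test": "pearson", "statistic": np.nan,
                             "p": np.nan, "note": f"only {int(mask.sum())} non-missing pairs"})
                continue
            if x[mask].nunique() <= 1 or q[mask].nunique() <= 1:
                rows.append({"covariate": cov, "test": "pearson", "statistic": np.nan,
                             "p": np.nan, "note": "constant variable; correlation undefined"})
                continue
            r, p = stats.pearsonr(x[mask], q[mask])
            rows.append({"covariate": cov, "test": "pearson", "statistic": float(r),
                         "p": float(p), "note": ""})
    return pd.DataFrame(rows)
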