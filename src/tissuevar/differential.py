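"""Per-probe differential methylation/expression analysis.

Each probe is tested with an ordinary least-squares linear model on
split/replicate-averaged independent samples: the two-level group
contrast of interest plus optional covariates (age as a linear term,
menstrual phase as indicator contrasts).  Paired designs use the
within-individual differences, which is the fixed-blocking-factor model.
P values are adjusted by Bonferroni (methylation convention) or
Benjamini-Hochberg FDR (expression convention).
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import BETA, LOG2_INTENSITY, Dataset, DatasetError

__all__ = [
    "Contrast",
    "fit_probe_lm",
    "fit_paired",
    "adjust_pvalues",
    "classify_fold_change",
]


class Contrast(NamedTuple):
    """Two-level grouping: ``effect = mean(level_a) - mean(level_b)``."""

    column: str
    level_a: str
    level_b: str


def _direction_labels(scale: str):
    return ("hyper", "hypo") if scale == BETA else ("up", "down")


def _phase_design(series: pd.Series) -> pd.DataFrame:
    """Indicator contrasts for phase vs the menstrual baseline."""
    out = {}
    for level in ("proliferative", "secretory"):
        out[f"phase_{level}"] = (series == level).astype(float)
    return pd.DataFrame(out, index=series.index)


def _build_design(md: pd.DataFrame, contrast: Contrast,
                  covariates: list[str]) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(md)),
            "group": (md[contrast.column].astype(object) == contrast.level_a).astype(float)}
    x = pd.DataFrame(cols, index=md.index)
    for cov in covariates:
        if cov == "phase":
            x = pd.concat([x, _phase_design(md["phase"])], axis=1)
        elif cov in ("smoking", "case_status"):
            ref = sorted(md[cov].astype(object).unique(), key=str)[0]
            x[cov] = (md[cov].astype(object) != ref).astype(float)
        else:
            x[cov] = md[cov].astype(float)
    if x.isna().any().any():
        bad = list(x.columns[x.isna().any()])
        raise DatasetError(f"missing covariate values in design columns {bad}")
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # name the collinear columns via the QR diagonal
        _, rr = np.linalg.qr(x.to_numpy())
        diag = np.abs(np.diag(rr))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        dependent = [c for c, d in zip(x.columns, diag) if d < tol] or list(x.columns)
        raise DatasetError(
            f"design is rank deficient (rank {rank} < {x.shape[1]}); "
            f"collinear terms involve: {dependent}"
        )
    return x


def _ols_all_probes(values: np.ndarray, x: np.ndarray, coef_idx: int):
    """Vectorised OLS over probes; returns effect, se, t, p, zero-resid flag."""
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = values @ x @ xtx_inv.T              # probes x p
    resid = values - beta @ x.T
    df = n - p
    if df < 1:
        raise DatasetError(f"no residual degrees of freedom (n={n}, params={p})")
    rss = np.sum(resid ** 2, axis=1)
    # zero-residual probes (possible in tiny fixtures): exact fit sentinel
    zero = rss <= np.maximum(1e-24, 1e-14 * np.sum(values ** 2, axis=1))
    s2 = rss / df
    se = np.sqrt(np.maximum(s2, 0.0) * xtx_inv[coef_idx, coef_idx])
    effect = beta[:, coef_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / np.where(se > 0, se, 1.0), np.inf * np.sign(effect))
    t = np.where((se == 0) & (effect == 0), 0.0, t)
    p_val = 2.0 * stats.t.sf(np.abs(t), df)
    p_val = np.where(zero, np.where(effect == 0, 1.0, 0.0), p_val)
    return effect, se, t, p_val, zero, df


def fit_probe_lm(dataset_averaged: Dataset, contrast: Contrast,
                 covariates: list[str] | None = None,
                 adjust: str = "bonferroni") -> pd.DataFrame:
    """Per-probe OLS group comparison with covariate adjustment.

    ``dataset_averaged`` must hold one independent (split/replicate
    averaged) profile per individual x tissue; samples outside the two
    contrast levels are ignored.  Returns a DataFrame sorted by p with
    effect, se, t, p, p_adj, direction.
    """
    covariates = list(covariates or [])
    md = dataset_averaged.metadata
    in_contrast = md[contrast.column].astype(object).isin([contrast.level_a, contrast.level_b])
    md = md[in_contrast]
    if md[contrast.column].nunique() < 2:
        raise DatasetError(
            f"contrast {contrast} does not produce two groups "
            f"(levels present: {sorted(md[contrast.column].astype(str).unique())})"
        )
    ds = dataset_averaged.subset_samples(list(md["sample_id"]))
    md = ds.metadata
    x = _build_design(md, contrast, covariates)
    order = [ds.matrix.sample_ids.index(s) for s in md["sample_id"]]
    values = ds.matrix.values[:, order]
    effect, se, t, p, zero, df = _ols_all_probes(values, x.to_numpy(), coef_idx=1)
    pos, neg = _direction_labels(ds.matrix.scale)
    out = pd.DataFrame({
        "probe_id": ds.matrix.probe_ids,
        "effect": effect, "se": se, "t": t, "p": p,
        "p_adj": adjust_pvalues(p, adjust),
        "method_adj": adjust,
        "direction": np.where(effect >= 0, pos, neg),
        "zero_residual": zero,
        "df": df,
    })
    out.attrs["scale"] = ds.matrix.scale
    out.attrs["n_samples"] = ds.n_samples
    return out.sort_values(["p", "probe_id"], kind="stable").reset_index(drop=True)


def fit_paired(dataset_averaged: Dataset, pair_key: str, contrast: Contrast,
               adjust: str = "bonferroni") -> pd.DataFrame:
    """Paired per-probe comparison (individual as a fixed blocking factor).

    Equivalent to the one-sample t test on within-pair differences
    ``level_a - level_b``.  Individuals lacking a sample at either level
    are excluded with a warning; the exclusion count is recorded in
    ``result.attrs['n_unpaired_excluded']``.
    """
    md = dataset_averaged.metadata
    md = md[md[contrast.column].astype(object).isin([contrast.level_a, contrast.level_b])]
    sid_of = {}
    for _, row in md.iterrows():
        sid_of.setdefault(row[pair_key], {})[row[contrast.column]] = row["sample_id"]
    complete = {k: v for k, v in sid_of.items()
                if contrast.level_a in v and contrast.level_b in v}
    dropped = sorted(set(sid_of) - set(complete))
    if dropped:
        warnings.warn(f"excluding {len(dropped)} unpaired individuals: {dropped}",
                      stacklevel=2)
    if len(complete) < 2:
        raise DatasetError("paired analysis needs >= 2 complete pairs")
    frame = dataset_averaged.matrix.to_frame()
    keys = sorted(complete, key=str)
    a = frame[[complete[k][contrast.level_a] for k in keys]].to_numpy()
    b = frame[[complete[k][contrast.level_b] for k in keys]].to_numpy()
    d = a - b
    k = d.shape[1]
    effect = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    zero = sd <= np.maximum(1e-14 * np.abs(effect), 1e-24)
    se = sd / np.sqrt(k)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / np.where(se > 0, se, 1.0), np.inf * np.sign(effect))
    t = np.where((se == 0) & (effect == 0), 0.0, t)
    df = k - 1
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero, np.where(effect == 0, 1.0, 0.0), p)
    pos, neg = _direction_labels(dataset_averaged.matrix.scale)
    out = pd.DataFrame({
        "probe_id": dataset_averaged.matrix.probe_ids,
        "effect": effect, "se": se, "t": t, "p": p,
        "p_adj": adjust_pvalues(p, adjust),
        "method_adj": adjust,
        "direction": np.where(effect >= 0, pos, neg),
        "zero_residual": zero,
        "df": df,
    })
    out.attrs["scale"] = dataset_averaged.matrix.scale
    out.attrs["n_pairs"] = k
    out.attrs["n_unpaired_excluded"] = len(dropped)
    return out.sort_values(["p", "probe_id"], kind="stable").reset_index(drop=True)


def adjust_pvalues(p_list, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: ``bonferroni`` (min(1, m*p)) or ``bh``
    (Benjamini-Hochberg step-up adjusted values)."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def classify_fold_change(results: pd.DataFrame, threshold: float = 4.0) -> pd.DataFrame:
    """Annotate expression results with fold changes.

    ``fold_change = 2**|log2 effect|`` (always >= 1; the sign lives in
    ``direction``); ``fc_flagged`` marks probes with FC strictly above
    ``threshold``.  Calling this on beta-scale results is a scale error.
    """
    scale = results.attrs.get("scale")
    if scale != LOG2_INTENSITY:
        raise ValueError(
            f"fold-change classification requires log2-intensity results, got scale={scale!r}"
        )
    out = results.copy()
    out["fold_change"] = 2.0 ** np.abs(out["effect"].to_numpy())
    out["fc_flagged"] = out["fold_change"] > threshold
    out.attrs.update(results.attrs)
    out.attrs["n_up"] = int((out["direction"] == "up").sum())
    out.attrs["n_down"] = int((out["direction"] == "down").sum())
    return out
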