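"""Sample-structure analysis: PCA, hierarchical clustering, outlier
flagging, and PC-covariate association.

PCA follows the conventions of R's ``prcomp`` with default settings:
samples are observations, probes are (centred, unscaled) features, and
components come from the SVD of the centred matrix.  Component signs are
fixed by making each component's largest-magnitude loading positive, so
results are deterministic.  Clustering is agglomerative with complete
linkage on Euclidean distances between averaged per-individual profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .datamodel import Dataset, DatasetError

__all__ = [
    "PCAResult",
    "ClusterTree",
    "pca",
    "hierarchical_cluster",
    "flag_outliers",
    "pc_covariate_association",
    "reclassify_phase",
]


@dataclass
class PCAResult:
    sample_ids: list[str]
    scores: np.ndarray            # samples x components
    loadings: np.ndarray          # probes x components
    variance_explained: np.ndarray  # fraction per component, non-increasing
    probe_means: np.ndarray = field(repr=False, default=None)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{k + 1}" for k in range(self.n_components)]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


def pca(dataset: Dataset, tissue_filter: str | None = None,
        scale_unit_variance: bool = False) -> PCAResult:
    """Principal component analysis of sample profiles (per tissue).

    Probes are centred (and optionally scaled to unit variance); the full
    SVD rank is returned, so ``variance_explained`` sums to 1.
    """
    ds = dataset.filter_tissue(tissue_filter) if tissue_filter else dataset
    if ds.n_samples < 3:
        raise DatasetError(f"PCA needs >= 3 samples, got {ds.n_samples}")
    x = ds.matrix.values.T.astype(float)        # samples x probes
    means = x.mean(axis=0)
    xc = x - means
    if scale_unit_variance:
        sd = xc.std(axis=0, ddof=1)
        xc = xc / np.where(sd > 0, sd, 1.0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = min(xc.shape[0] - 1, xc.shape[1])
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    # deterministic sign: largest-magnitude loading of each component positive
    flip = np.sign(vt[np.arange(rank), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    u, vt = u * flip, vt * flip[:, None]
    var = s ** 2
    return PCAResult(
        sample_ids=list(ds.matrix.sample_ids),
        scores=u * s,
        loadings=vt.T,
        variance_explained=var / var.sum() if var.sum() > 0 else var,
        probe_means=means,
    )


@dataclass
class ClusterTree:
    """A complete-linkage dendrogram in scipy linkage-matrix layout."""

    leaf_ids: list[str]
    merge: np.ndarray  # scipy (n-1) x 4 linkage matrix

    @property
    def heights(self) -> np.ndarray:
        return self.merge[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        labels = fcluster(self.merge, t=k, criterion="maxclust")
        return dict(zip(self.leaf_ids, labels.tolist()))


def hierarchical_cluster(dataset_averaged: Dataset) -> ClusterTree:
    """Complete-linkage agglomerative clustering on Euclidean distances.

    Samples are sorted lexicographically by sample_id before linkage so
    ties are broken deterministically.
    """
    if dataset_averaged.n_samples < 2:
        raise DatasetError("clustering needs >= 2 samples")
    order = sorted(dataset_averaged.matrix.sample_ids)
    ds = dataset_averaged.subset_samples(order)
    x = ds.matrix.values.T
    z = linkage(pdist(x, metric="euclidean"), method="complete")
    return ClusterTree(leaf_ids=order, merge=z)


def flag_outliers(tree: ClusterTree, metadata: pd.DataFrame) -> list[str]:
    """Samples whose cluster (at the number-of-tissues cut) has a
    different majority tissue label than their own.

    Likely tissue swaps land inside a foreign tissue's cluster; flagging
    them reproduces the exclusion of mislabelled samples before
    downstream analysis.  Ties in the majority vote flag nothing.
    """
    md = metadata.set_index("sample_id")
    tissues = md.loc[tree.leaf_ids, "tissue"]
    k = tissues.nunique()
    if k < 2:
        return []
    assignment = tree.cut(k)
    flagged = []
    clusters = pd.Series(assignment)
    for cl in sorted(clusters.unique()):
        members = clusters.index[clusters == cl]
        counts = tissues.loc[members].value_counts()
        if len(counts) == 1:
            continue
        if counts.iloc[0] == counts.iloc[1]:
            continue  # no strict majority
        majority = counts.index[0]
        flagged.extend(s for s in members if tissues[s] != majority)
    return sorted(flagged)


_CATEGORICAL = {"phase", "case_status", "smoking", "tissue", "subtype"}


def pc_covariate_association(pca_result: PCAResult, metadata: pd.DataFrame,
                             covariates: list[str], n_pcs: int = 2) -> pd.DataFrame:
    """Univariate association between leading PCs and covariates.

    Continuous covariates: Pearson r with two-sided p per PC.  Categorical
    covariates (phase, case/control, smoking, ...): one-way ANOVA F test
    of the PC scores on the factor.  ``min_p`` carries, per covariate, the
    minimum p over the tested PCs.  Single-level covariates are skipped
    with a warning note.
    """
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    n_pcs = min(n_pcs, pca_result.n_components)
    md = metadata.set_index("sample_id").loc[pca_result.sample_ids]
    rows = []
    for cov in covariates:
        if cov not in md.columns:
            raise KeyError(f"unknown covariate {cov!r}")
        for k in range(n_pcs):
            pc = pca_result.scores[:, k]
            if cov in _CATEGORICAL:
                series = md[cov].astype(object)
                mask = series.notna().to_numpy()
                levels = sorted(set(series[mask]), key=str)
                if len(levels) < 2:
                    rows.append({"covariate": cov, "pc": k + 1, "test": "anova",
                                 "statistic": np.nan, "p": np.nan,
                                 "note": "skipped: fewer than 2 levels"})
                    continue
                groups = [pc[mask & (series == lv).to_numpy()] for lv in levels]
                f, p = stats.f_oneway(*groups)
                rows.append({"covariate": cov, "pc": k + 1, "test": "anova",
                             "statistic": float(f), "p": float(p), "note": ""})
            else:
                x = md[cov].astype(float).to_numpy()
                mask = ~np.isnan(x)
                if mask.sum() < 3 or len(set(x[mask])) < 2:
                    rows.append({"covariate": cov, "pc": k + 1, "test": "pearson",
                                 "statistic": np.nan, "p": np.nan,
                                 "note": "skipped: constant or too few values"})
                    continue
                r, p = stats.pearsonr(x[mask], pc[mask])
                rows.append({"covariate": cov, "pc": k + 1, "test": "pearson",
                             "statistic": float(r), "p": float(p), "note": ""})
    table = pd.DataFrame(rows)
    table["min_p"] = table.groupby("covariate")["p"].transform("min")
    return table


def reclassify_phase(dataset_averaged: Dataset, pca_result: PCAResult,
                     day_window: int = 2, k_neighbors: int = 3) -> pd.DataFrame:
    """Re-assign menstrual phase near bin edges from expression structure.

    Samples whose normalised cycle day lies within ``day_window`` days of
    a phase boundary (7/8 or 14/15) are re-labelled with the majority
    phase of their ``k_neighbors`` nearest neighbours in PC1-PC2 space.
    Returns the metadata with a ``phase_reclassified`` column.
    """
    md = dataset_averaged.metadata.set_index("sample_id").loc[pca_result.sample_ids].copy()
    scores = pca_result.scores[:, :2]
    day = (md["cycle_day"].astype(float) * 28.0 /
           md["cycle_length"].astype(float).fillna(28.0)).round()
    near_edge = pd.Series(False, index=md.index)
    for edge in (7.5, 14.5):
        near_edge |= (day - edge).abs() <= day_window
    phases = md["phase"].copy()
    new = phases.copy()
    for i, sid in enumerate(md.index):
        if not near_edge.iloc[i] or pd.isna(phases.iloc[i]):
            continue
        d = np.linalg.norm(scores - scores[i], axis=1)
        d[i] = np.inf
        neigh = np.argsort(d, kind="stable")[:k_neighbors]
        votes = phases.iloc[neigh].dropna()
        if len(votes):
            new.iloc[i] = votes.mode().iloc[0]
    md["phase_reclassified"] = new
    return md.reset_index()
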