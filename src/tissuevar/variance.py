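"""Per-probe nested variance-component decomposition by maximum likelihood.

The model for one probe measured on a nested split/replicate design is

    y_{isr} = mu + a_i + b_{is} + e_{isr}

with independent Gaussian random effects: ``a_i ~ N(0, sigma2_A)`` the
between-individual component, ``b_{is} ~ N(0, sigma2_B)`` the within-tissue
(split, i.e. cellular-heterogeneity) component, and ``e_{isr} ~
N(0, sigma2_E)`` the technical (array replicate) residual.

The Gaussian likelihood factorises over individuals.  Collapsing each
split to its mean w_{is} and its within-split sum of squares gives an
exact expression that needs only O(#splits) work per evaluation:
within-split contrasts are iid N(0, sigma2_E), and the vector of split
means of individual i is multivariate normal with covariance
``sigma2_A * J + diag(v_s)`` where ``v_s = sigma2_B + sigma2_E / n_s``.
The rank-one structure is handled with the Sherman-Morrison identity, and
the grand mean is profiled out by generalised least squares, so the
numerical optimisation is over at most three (log) variances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .datamodel import Dataset, DatasetError

__all__ = [
    "NestedDesign",
    "VarianceDecomposition",
    "VarianceSummary",
    "loglik_nested",
    "fit_nested_ml",
    "decompose_dataset",
    "rank_variable_probes",
    "summarize_components",
]

_NEG_INF = -np.inf


class NestedDesign:
    """Observation -> (individual, split) mapping with cached indices.

    Accepts any pair of label sequences; splits are nested within
    individuals, so the split key is the (individual, split) pair.
    """

    def __init__(self, individual, split):
        individual = np.asarray(individual)
        split = np.asarray(split)
        if individual.shape != split.shape or individual.ndim != 1:
            raise ValueError("individual and split must be equal-length 1-D sequences")
        self.n_obs = individual.size
        pair = np.char.add(np.char.add(individual.astype(str), "\x1f"), split.astype(str))
        # stable integer codes for splits and individuals
        self.split_codes, split_index = pd.factorize(pair, sort=True)
        self.n_splits = len(split_index)
        first = np.zeros(self.n_splits, dtype=int)
        first[self.split_codes[::-1]] = np.arange(self.n_obs)[::-1]
        ind_of_split = individual.astype(str)[first]
        self.ind_codes_of_split, ind_index = pd.factorize(ind_of_split, sort=True)
        self.n_individuals = len(ind_index)
        self.split_sizes = np.bincount(self.split_codes, minlength=self.n_splits)
        self.splits_per_ind = np.bincount(self.ind_codes_of_split, minlength=self.n_individuals)
        self.has_replicates = bool((self.split_sizes > 1).any())
        self.has_multiple_splits = bool((self.splits_per_ind > 1).any())
        self.n_replicate_arrays = int((self.split_sizes - 1).sum())

    @classmethod
    def from_metadata(cls, metadata: pd.DataFrame) -> "NestedDesign":
        return cls(metadata["individual_id"].to_numpy(),
                   metadata["split_id"].to_numpy())

    def suff_stats(self, y: np.ndarray):
        """Split means and pooled within-split sum of squares for one probe."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_obs,):
            raise ValueError(f"y must have length {self.n_obs}")
        sums = np.bincount(self.split_codes, weights=y, minlength=self.n_splits)
        w = sums / self.split_sizes
        ss_within = float(np.sum((y - w[self.split_codes]) ** 2))
        return w, ss_within


def _loglik_from_stats(design: NestedDesign, w, ss_within, mu, s2a, s2b, s2e):
    """Exact nested-model log-likelihood from sufficient statistics."""
    n_s = design.split_sizes
    df_within = design.n_obs - design.n_splits
    ll = -0.5 * design.n_obs * math.log(2.0 * math.pi)
    # within-split contrasts ~ N(0, s2e)
    if df_within > 0:
        if s2e <= 0.0:
            if ss_within > 0.0:
                return _NEG_INF
            # perfect replicate agreement: the within part is degenerate and
            # conventionally contributes 0 (component fixed at exactly zero)
        else:
            ll += -0.5 * (df_within * math.log(s2e) + ss_within / s2e)
    ll += -0.5 * float(np.log(n_s).sum())
    v = s2b + s2e / n_s
    if np.any(v <= 0.0):
        dev = w - np.mean(w)
        if s2a > 0.0 or float(dev @ dev) > 0.0:
            return _NEG_INF
        return ll  # all split means identical, zero-variance degenerate fit
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        inv_v = 1.0 / v
        r = w - mu
        c_i = np.bincount(design.ind_codes_of_split, weights=inv_v,
                          minlength=design.n_individuals)
        u_i = np.bincount(design.ind_codes_of_split, weights=r * inv_v,
                          minlength=design.n_individuals)
        denom = 1.0 + s2a * c_i
        logdet = float(np.log(v).sum() + np.log(denom).sum())
        quad = float((r * r * inv_v).sum() - (s2a * u_i * u_i / denom).sum())
    out = ll - 0.5 * (logdet + quad)
    return out if np.isfinite(out) else _NEG_INF


def _profiled_mu(design: NestedDesign, w, s2a, s2b, s2e):
    """GLS estimate of the grand mean for fixed variance components."""
    v = s2b + s2e / design.split_sizes
    v = np.where(v <= 0.0, np.finfo(float).tiny, v)
    inv_v = 1.0 / v
    c_i = np.bincount(design.ind_codes_of_split, weights=inv_v,
                      minlength=design.n_individuals)
    m_i = np.bincount(design.ind_codes_of_split, weights=w * inv_v,
                      minlength=design.n_individuals)
    denom = 1.0 + s2a * c_i
    wsum = (c_i / denom).sum()
    if wsum <= 0.0:
        return float(np.mean(w))
    return float((m_i / denom).sum() / wsum)


def loglik_nested(y, design, mu, sigma2_A, sigma2_B, sigma2_E) -> float:
    """Exact Gaussian log-likelihood of ``y`` under the nested model.

    Equals the log-density of a multivariate normal with covariance
    ``sigma2_A * J_individual + sigma2_B * J_split + sigma2_E * I``
    evaluated at ``y`` with constant mean ``mu``.  ``design`` is a
    :class:`NestedDesign` or a ``(individual, split)`` pair of label
    sequences.  Returns ``-inf`` when a zero total variance is asserted
    for non-constant data (documented sentinel).
    """
    if not isinstance(design, NestedDesign):
        design = NestedDesign(*design)
    if min(sigma2_A, sigma2_B, sigma2_E) < 0.0:
        raise ValueError("variance components must be >= 0")
    w, ss_within = design.suff_stats(np.asarray(y, dtype=float))
    return _loglik_from_stats(design, w, ss_within, mu, sigma2_A, sigma2_B, sigma2_E)


@dataclass
class VarianceDecomposition:
    """Per-probe ML decomposition into the three nested components.

    Components that the design cannot identify separately are NaN with
    ``confounded`` naming the merged levels and ``sigma2_confounded``
    carrying their combined estimate.
    """

    probe_id: str
    sigma2_individual: float
    sigma2_split: float
    sigma2_technical: float
    prop_individual: float
    prop_split: float
    prop_technical: float
    loglik: float
    converged: bool
    n_individuals: int
    n_splits: int
    n_replicates: int
    mu: float = float("nan")
    confounded: str | None = None
    sigma2_confounded: float = float("nan")

    @property
    def total(self) -> float:
        parts = [self.sigma2_individual, self.sigma2_split, self.sigma2_technical]
        vals = [p for p in parts if not math.isnan(p)]
        tot = sum(vals)
        if not math.isnan(self.sigma2_confounded):
            tot += self.sigma2_confounded
        return tot


def _mom_start(design: NestedDesign, w, ss_within, total_var):
    """Method-of-moments starting values, clamped away from zero."""
    floor = max(total_var, 1e-12) * 1e-3
    df_within = design.n_obs - design.n_splits
    s2e = ss_within / df_within if df_within > 0 else floor
    # split means around their individual means
    ind_mean = np.bincount(design.ind_codes_of_split, weights=w,
                           minlength=design.n_individuals) / design.splits_per_ind
    dev_b = w - ind_mean[design.ind_codes_of_split]
    df_b = design.n_splits - design.n_individuals
    s2b = float(dev_b @ dev_b) / df_b - s2e / max(design.split_sizes.mean(), 1.0) if df_b > 0 else floor
    dev_a = ind_mean - ind_mean.mean()
    s2a = float(dev_a @ dev_a) / max(design.n_individuals - 1, 1) - s2b / max(design.splits_per_ind.mean(), 1.0)
    return tuple(max(x, floor) for x in (s2a, s2b, s2e))


def _maximize(design: NestedDesign, w, ss_within, free, fixed, starts):
    """Maximise the profiled log-likelihood over the ``free`` components.

    ``free`` is a list of component names ("A", "B", "E"); ``fixed`` maps
    the remaining names to constants (typically exact zeros).  Works on the
    log scale, so boundary solutions are reached by the explicit
    zero-candidate refits in :func:`fit_nested_ml`, not by the optimiser.
    """

    def unpack(theta):
        comp = dict(fixed)
        for name, t in zip(free, theta):
            comp[name] = math.exp(t)
        return comp["A"], comp["B"], comp["E"]

    def negll(theta):
        s2a, s2b, s2e = unpack(theta)
        mu = _profiled_mu(design, w, s2a, s2b, s2e)
        ll = _loglik_from_stats(design, w, ss_within, mu, s2a, s2b, s2e)
        return -ll if np.isfinite(ll) else 1e300

    best = None
    for start in starts:
        theta0 = [math.log(max(start[name], 1e-12)) for name in free]
        res = minimize(negll, theta0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    s2a, s2b, s2e = unpack(best.x)
    mu = _profiled_mu(design, w, s2a, s2b, s2e)
    ll = _loglik_from_stats(design, w, ss_within, mu, s2a, s2b, s2e)
    return (s2a, s2b, s2e, mu, ll, bool(best.success))


def fit_nested_ml(y, design, probe_id: str = "probe",
                  reml: bool = False) -> VarianceDecomposition:
    """ML fit of the nested variance components for one probe.

    Profiles the grand mean out by GLS and maximises over log-variances
    with two starts (method-of-moments and an equal split of the total
    variance); candidate models with components pinned at exactly zero are
    refitted whenever an estimate approaches the boundary, so boundary
    solutions come back as exact zeros.

    Identifiability follows the design: without any replicated split the
    split and technical components are confounded (their sum is reported);
    without any multi-split individual the individual and split components
    are confounded.  ``reml=True`` applies the restricted-likelihood
    correction for the estimated mean, removing the leading O(1/I) bias
    of the between-individual component.
    """
    if not isinstance(design, NestedDesign):
        design = NestedDesign(*design)
    y = np.asarray(y, dtype=float)
    if design.n_individuals < 2:
        raise DatasetError("need >= 2 individuals to estimate variance components")
    w, ss_within = design.suff_stats(y)
    total_var = float(np.var(y))
    base = dict(probe_id=probe_id, n_individuals=design.n_individuals,
                n_splits=design.n_splits, n_replicates=design.n_replicate_arrays)

    if total_var == 0.0:
        return VarianceDecomposition(
            sigma2_individual=0.0, sigma2_split=0.0, sigma2_technical=0.0,
            prop_individual=float("nan"), prop_split=float("nan"),
            prop_technical=float("nan"), loglik=float("inf"), converged=True,
            mu=float(y[0]), **base)

    has_rep = design.has_replicates
    has_ms = design.has_multiple_splits
    if has_rep and has_ms:
        free0 = ["A", "B", "E"]
    elif has_ms:
        free0 = ["A", "E"]        # B and E confounded; carried in the E slot
    elif has_rep:
        free0 = ["B", "E"]        # A and B confounded; carried in the B slot
    else:
        free0 = ["E"]             # only the total variance is identified
    fixed0 = {k: 0.0 for k in ("A", "B", "E") if k not in free0}

    mom = dict(zip(("A", "B", "E"), _mom_start(design, w, ss_within, total_var)))
    equal = {k: total_var / len(free0) for k in ("A", "B", "E")}
    if ss_within == 0.0 and design.n_obs > design.n_splits and "E" in free0 and len(free0) > 1:
        # perfect replicate agreement: technical component exactly zero
        fixed0["E"] = 0.0
        free0 = [k for k in free0 if k != "E"]

    # exact-fit degeneracy below the individual level: split means agree
    # perfectly within individuals and there is no technical noise, so the
    # sub-individual components are exactly zero and the likelihood reduces
    # to a one-way layout on the individual means (closed-form ML).
    ind_mean = (np.bincount(design.ind_codes_of_split, weights=w,
                            minlength=design.n_individuals) / design.splits_per_ind)
    ss_b = float(np.sum((w - ind_mean[design.ind_codes_of_split]) ** 2))
    if (ss_within == 0.0 and ss_b == 0.0 and design.has_multiple_splits
            and design.n_splits > design.n_individuals):
        mu_hat = float(ind_mean.mean())
        a_hat = float(np.mean((ind_mean - mu_hat) ** 2))
        ll = float(np.sum(
            -0.5 * (math.log(2.0 * math.pi * a_hat)
                    + (ind_mean - mu_hat) ** 2 / a_hat)))
        if reml:
            ll += -0.5 * math.log(design.n_individuals / a_hat) + 0.5 * math.log(2 * math.pi)
            a_hat *= design.n_individuals / (design.n_individuals - 1)
        tot = a_hat
        return VarianceDecomposition(
            sigma2_individual=a_hat, sigma2_split=0.0, sigma2_technical=0.0,
            prop_individual=1.0 if tot > 0 else float("nan"),
            prop_split=0.0 if tot > 0 else float("nan"),
            prop_technical=0.0 if tot > 0 else float("nan"),
            loglik=ll, converged=True, mu=mu_hat, **base)

    def reml_adjust(ll, s2a, s2b, s2e):
        if not reml or not np.isfinite(ll):
            return ll
        v = s2b + s2e / design.split_sizes
        v = np.where(v <= 0.0, np.finfo(float).tiny, v)
        c_i = np.bincount(design.ind_codes_of_split, weights=1.0 / v,
                          minlength=design.n_individuals)
        xtvx = float((c_i / (1.0 + s2a * c_i)).sum())
        return ll - 0.5 * math.log(xtvx) + 0.5 * math.log(2.0 * math.pi)

    def run(free, fixed):
        if not free:
            mu = float(np.mean(w))
            ll = _loglik_from_stats(design, w, ss_within, mu, fixed["A"], fixed["B"], fixed["E"])
            return (fixed["A"], fixed["B"], fixed["E"], mu, ll, True)
        return _maximize(design, w, ss_within, free, fixed, [mom, equal])

    if reml:
        # optimise the REML objective by wrapping the profiled likelihood
        def run(free, fixed, _run_ml=_maximize):  # noqa: F811
            if not free:
                mu = float(np.mean(w))
                ll = _loglik_from_stats(design, w, ss_within, mu, fixed["A"], fixed["B"], fixed["E"])
                return (fixed["A"], fixed["B"], fixed["E"], mu, ll, True)

            def negll(theta):
                comp = dict(fixed)
                for name, t in zip(free, theta):
                    comp[name] = math.exp(t)
                s2a, s2b, s2e = comp["A"], comp["B"], comp["E"]
                mu = _profiled_mu(design, w, s2a, s2b, s2e)
                ll = reml_adjust(
                    _loglik_from_stats(design, w, ss_within, mu, s2a, s2b, s2e),
                    s2a, s2b, s2e)
                return -ll if np.isfinite(ll) else 1e300

            best = None
            for start in (mom, equal):
                theta0 = [math.log(max(start[name], 1e-12)) for name in free]
                res = minimize(negll, theta0, method="Nelder-Mead",
                               options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
                if best is None or res.fun < best.fun:
                    best = res
            comp = dict(fixed)
            for name, t in zip(free, best.x):
                comp[name] = math.exp(t)
            s2a, s2b, s2e = comp["A"], comp["B"], comp["E"]
            mu = _profiled_mu(design, w, s2a, s2b, s2e)
            ll = reml_adjust(
                _loglik_from_stats(design, w, ss_within, mu, s2a, s2b, s2e),
                s2a, s2b, s2e)
            return (s2a, s2b, s2e, mu, ll, bool(best.success))

    s2a, s2b, s2e, mu, ll, ok = run(free0, fixed0)

    # boundary polish: refit with near-zero components pinned at exactly 0
    tol = 1e-6 * max(total_var, 1e-12)
    est = {"A": s2a, "B": s2b, "E": s2e}
    near_zero = [k for k in free0 if est[k] < tol]
    if "E" in near_zero and ss_within > 0.0:
        near_zero.remove("E")  # a positive within-split SS forbids s2e = 0
    if near_zero:
        import itertools
        for m in range(1, len(near_zero) + 1):
            for drop in itertools.combinations(near_zero, m):
                free = [k for k in free0 if k not in drop]
                fixed = dict(fixed0, **{k: 0.0 for k in drop})
                cand = run(free, fixed)
                if cand[4] >= ll - 1e-9:
                    s2a, s2b, s2e, mu, ll, ok = cand
        est = {"A": s2a, "B": s2b, "E": s2e}
        for k in free0:
            if est[k] < tol:
                est[k] = 0.0
        s2a, s2b, s2e = est["A"], est["B"], est["E"]

    nan = float("nan")
    confounded = None
    s2conf = nan
    if has_rep and has_ms:
        out = (s2a, s2b, s2e)
    elif has_ms:
        combined = s2e  # split + technical, estimated in the E slot
        if combined == 0.0:
            out = (s2a, 0.0, 0.0)
        else:
            out = (s2a, nan, nan)
            confounded = "split+technical"
            s2conf = combined
    elif has_rep:
        combined = s2b  # individual + split, estimated in the B slot
        if combined == 0.0:
            out = (0.0, 0.0, s2e)
        else:
            out = (nan, nan, s2e)
            confounded = "individual+split"
            s2conf = combined
    else:
        combined = s2e
        if combined == 0.0:
            out = (0.0, 0.0, 0.0)
        else:
            out = (nan, nan, nan)
            confounded = "individual+split+technical"
            s2conf = combined

    known = [x for x in out if not math.isnan(x)]
    tot = sum(known) + (0.0 if math.isnan(s2conf) else s2conf)
    if confounded is None and tot > 0.0:
        props = tuple(x / tot for x in out)
    else:
        props = (nan, nan, nan)
    return VarianceDecomposition(
        sigma2_individual=out[0], sigma2_split=out[1], sigma2_technical=out[2],
        prop_individual=props[0], prop_split=props[1], prop_technical=props[2],
        loglik=float(ll), converged=ok, mu=mu,
        confounded=confounded, sigma2_confounded=s2conf, **base)


def decompose_dataset(dataset: Dataset, tissue: str | None = None,
                      reml: bool = False, probes: list[str] | None = None
                      ) -> pd.DataFrame:
    """Fit :func:`fit_nested_ml` for every probe of one tissue.

    Returns a DataFrame indexed by probe_id with the decomposition fields;
    each tissue is decomposed separately (pass ``tissue`` to restrict).
    """
    ds = dataset.filter_tissue(tissue) if tissue else dataset
    design = NestedDesign.from_metadata(ds.metadata)
    order = [ds.matrix.sample_ids.index(s) for s in ds.metadata["sample_id"]]
    values = ds.matrix.values[:, order]
    rows = []
    probe_ids = probes if probes is not None else ds.matrix.probe_ids
    index = {p: k for k, p in enumerate(ds.matrix.probe_ids)}
    for pid in probe_ids:
        fit = fit_nested_ml(values[index[pid]], design, probe_id=pid, reml=reml)
        rows.append(vars(fit))
    return pd.DataFrame(rows).set_index("probe_id")


def rank_variable_probes(dataset_averaged: Dataset, fraction: float = 0.5) -> list[str]:
    """Most-variable probes across independent (averaged) samples.

    Probes are sorted by descending empirical variance (ties broken by
    probe_id, so the ranking is deterministic); the top
    ``ceil(fraction * n_probes)`` IDs are returned.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if dataset_averaged.n_samples < 2:
        raise DatasetError("need >= 2 independent samples to rank probe variability")
    var = dataset_averaged.matrix.values.var(axis=1, ddof=1)
    order = sorted(zip(-var, dataset_averaged.matrix.probe_ids))
    k = math.ceil(fraction * len(order))
    return [pid for _, pid in order[:k]]


@dataclass
class VarianceSummary:
    """Mean/SD of each component (and proportion) over a probe subset."""

    tissue: str
    probe_subset: str
    n_probes: int
    n_nonconverged: int
    stats: pd.DataFrame  # rows: component; columns: mean, sd


_COMPONENT_COLS = [
    "sigma2_individual", "sigma2_split", "sigma2_technical",
    "prop_individual", "prop_split", "prop_technical",
]


def summarize_components(decompositions: pd.DataFrame, probe_subset: list[str],
                         tissue: str = "", label: str = "all") -> VarianceSummary:
    """Summarise fitted components over ``probe_subset``.

    Non-converged probes are excluded from the means and counted in the
    summary.  SDs use ddof=1 (population spread of per-probe estimates).
    """
    if len(probe_subset) == 0:
        raise ValueError("empty probe subset")
    missing = [p for p in probe_subset if p not in decompositions.index]
    if missing:
        raise KeyError(f"no decomposition for probes: {missing[:5]}")
    sub = decompositions.loc[probe_subset]
    n_bad = int((~sub["converged"].astype(bool)).sum())
    ok = sub[sub["converged"].astype(bool)]
    stats = pd.DataFrame({
        "mean": ok[_COMPONENT_COLS].mean(),
        "sd": ok[_COMPONENT_COLS].std(ddof=1),
    })
    return VarianceSummary(tissue=tissue, probe_subset=label,
                           n_probes=len(probe_subset), n_nonconverged=n_bad,
                           stats=stats)
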