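"""Variance-informed power and sample-size calculations.

Power is for the two-sided two-sample t test of a mean difference
(``effect``, a beta difference for methylation or a log2 fold change for
expression) between two equal groups of ``n_per_group`` samples, at a
Bonferroni-corrected per-test alpha.  With per-probe SDs from the
variance decomposition (total single-sample SD
``sqrt(s2_individual + s2_split + s2_technical)``, since a case/control
study takes one sample per individual), the *detectable fraction* is the
share of probes whose SD permits at least the target power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerSpec",
    "PowerResult",
    "bonferroni_alpha",
    "ttest_power",
    "detectable_fraction",
    "required_n",
    "power_curve",
]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a detectable-fraction calculation.

    ``n_total`` is the total sample count, split equally into two groups
    (pass per-group counts through ``n_meaning="per_group"``).
    """

    effect: float
    n_total: int
    alpha_family: float = 0.05
    n_tests: int = 1
    target_power: float = 0.8
    n_meaning: str = "total"   # "total" | "per_group"

    def __post_init__(self):
        if not 0.0 < self.alpha_family < 1.0:
            raise ValueError("alpha_family must be in (0, 1)")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.n_meaning not in ("total", "per_group"):
            raise ValueError("n_meaning must be 'total' or 'per_group'")
        if self.n_meaning == "total" and (self.n_total < 4 or self.n_total % 2):
            raise ValueError("n_total must be even and >= 4")
        if self.n_meaning == "per_group" and self.n_total < 2:
            raise ValueError("per-group n must be >= 2")

    @property
    def n_per_group(self) -> int:
        return self.n_total // 2 if self.n_meaning == "total" else self.n_total

    @property
    def alpha_per_test(self) -> float:
        return bonferroni_alpha(self.alpha_family, self.n_tests)


@dataclass
class PowerResult:
    spec: PowerSpec
    power: np.ndarray                 # per-probe power in [0, 1]
    fraction_detectable: float
    n_detectable: int
    n_probes: int
    curve: pd.DataFrame | None = field(default=None, repr=False)


def bonferroni_alpha(alpha_family: float, n_tests: int) -> float:
    """Per-test significance level ``alpha_family / n_tests`` (exact)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha_family / n_tests


def ttest_power(effect: float, sd, n_per_group: int, alpha: float):
    """Two-sided two-sample t-test power from the noncentral t distribution.

    df = 2n - 2 and noncentrality ``delta = effect / (sd * sqrt(2 / n))``.
    Vectorised over ``sd``.  The sd -> 0 limit is power 1 for a nonzero
    effect and ``alpha`` for a null effect (documented convention).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    sd_arr = np.asarray(sd, dtype=float)
    scalar = sd_arr.ndim == 0
    sd_arr = np.atleast_1d(sd_arr)
    if np.any(sd_arr < 0):
        raise ValueError("sd must be >= 0")
    df = 2 * n_per_group - 2
    tcrit = stats.t.isf(alpha / 2.0, df)
    out = np.empty_like(sd_arr)
    zero = sd_arr == 0.0
    out[zero] = 1.0 if effect > 0 else alpha
    pos = ~zero
    if pos.any():
        delta = effect / (sd_arr[pos] * math.sqrt(2.0 / n_per_group))
        with np.errstate(all="ignore"):
            upper = stats.nct.sf(tcrit, df, delta)
            lower = stats.nct.cdf(-tcrit, df, delta)
        # the far tail opposite a positive noncentrality is numerically 0
        lower = np.where(np.isfinite(lower), lower, 0.0)
        bad = ~np.isfinite(upper)
        if np.any(bad):
            upper = np.array(upper, dtype=float)
            for i in np.flatnonzero(bad):
                upper[i] = _nct_sf_quad(tcrit, df, float(np.atleast_1d(delta)[i]))
        out[pos] = upper + lower
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def _nct_sf_quad(t: float, df: int, delta: float) -> float:
    """P(T' > t) for noncentral t by integrating over the chi-square
    denominator; fallback for extreme (df, delta) where scipy's nct
    loses accuracy."""
    from scipy.integrate import quad

    def integrand(x):
        return stats.chi2.pdf(x, df) * stats.norm.sf(t * math.sqrt(x / df) - delta)

    val, _ = quad(integrand, 0.0, stats.chi2.isf(1e-13, df), limit=200)
    return float(min(max(val, 0.0), 1.0))


def detectable_fraction(sd_per_probe, spec: PowerSpec,
                        n_grid=None) -> PowerResult:
    """Per-probe power at ``spec`` and the fraction reaching target power.

    ``sd_per_probe`` is the per-probe total single-sample SD.  If
    ``n_grid`` is given (total sample sizes, e.g. 100/500/1000), a curve
    of detectable fractions over the grid is attached.
    """
    sds = np.asarray(sd_per_probe, dtype=float)
    if sds.size == 0:
        raise ValueError("empty SD list")
    power = ttest_power(spec.effect, sds, spec.n_per_group, spec.alpha_per_test)
    power = np.atleast_1d(power)
    detect = power >= spec.target_power
    curve = None
    if n_grid is not None:
        rows = []
        for n in n_grid:
            s = PowerSpec(effect=spec.effect, n_total=int(n),
                          alpha_family=spec.alpha_family, n_tests=spec.n_tests,
                          target_power=spec.target_power, n_meaning=spec.n_meaning)
            pw = np.atleast_1d(ttest_power(s.effect, sds, s.n_per_group, s.alpha_per_test))
            nd = int((pw >= s.target_power).sum())
            rows.append({"n": int(n), "effect": spec.effect,
                         "n_detectable": nd, "n_probes": sds.size,
                         "fraction_detectable": nd / sds.size})
        curve = pd.DataFrame(rows)
    return PowerResult(spec=spec, power=power,
                       fraction_detectable=float(detect.mean()),
                       n_detectable=int(detect.sum()),
                       n_probes=int(sds.size), curve=curve)


def required_n(effect: float, sd: float, alpha: float = 0.05,
               target_power: float = 0.8, n_max: int = 10_000_000) -> int:
    """Smallest per-group n with at least ``target_power`` power."""
    if effect <= 0 or sd <= 0:
        raise ValueError("effect and sd must be > 0")
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must be in (0, 1)")
    lo, hi = 2, 2
    while ttest_power(effect, sd, hi, alpha) < target_power:
        lo = hi
        hi *= 2
        if hi > n_max:
            raise ValueError(f"required n exceeds {n_max}; inputs pathological")
    while lo < hi:
        mid = (lo + hi) // 2
        if ttest_power(effect, sd, mid, alpha) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return hi


def power_curve(sd_per_probe, effects, n_grid, alpha_family: float = 0.05,
                n_tests: int = 1, target_power: float = 0.8,
                n_meaning: str = "total") -> pd.DataFrame:
    """Detectable-fraction table over an (effect, n) grid."""
    rows = []
    for eff in effects:
        spec = PowerSpec(effect=float(eff), n_total=int(n_grid[0]),
                         alpha_family=alpha_family, n_tests=n_tests,
                         target_power=target_power, n_meaning=n_meaning)
        res = detectable_fraction(sd_per_probe, spec, n_grid=n_grid)
        rows.append(res.curve)
    return pd.concat(rows, ignore_index=True)
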