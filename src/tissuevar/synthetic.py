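"""Synthetic nested-design methylation/expression datasets with known truth.

The generator emulates a multi-tissue profiling study in which each
physical sample may be split before extraction and a subset of extracted
splits is run on a second array.  Values for probe j on individual i,
split s, replicate r follow

    y = mu_j + tissue_offset_j + x_i' beta_j + a_ij + b_ijs + e_ijsr

with a ~ N(0, sigma2_A), b ~ N(0, sigma2_B), e ~ N(0, sigma2_E).  On the
beta (methylation) scale, probe means are drawn from a low/intermediate/
high mixture (0.1 / 0.5 / 0.9) to mimic the bimodality of array beta
values, and simulated values are truncated to [0, 1] (a logit-normal
variant is available); on the log2-intensity scale values are unbounded.

Every generated dataset is accompanied by a *truth* table holding the
per-probe generating components and spiked effects, so downstream
estimators can be validated by recovery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    BETA,
    LOG2_INTENSITY,
    METADATA_COLUMNS,
    Dataset,
    ProbeMatrix,
    categorize_phase,
)

__all__ = [
    "Individual",
    "CovariateEffect",
    "DifferentialSpike",
    "GeneratorParams",
    "GeneratedData",
    "generate_dataset",
    "spike_qc_failures",
    "study_methylation_params",
    "study_expression_params",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Individual:
    individual_id: str
    case_status: str = "case"          # "case" | "control"
    age: float = 35.0
    cycle_day: float | None = 14.0
    cycle_length: float = 28.0
    smoking: bool = False
    bmi: float = 25.0
    whr: float = 0.80
    subtype: str = "none"              # disease-tissue subtype, if any


@dataclass(frozen=True)
class CovariateEffect:
    """Linear effect of one covariate on a random fraction of probes."""

    sd: float                 # per-probe effect sizes drawn from N(0, sd^2)
    fraction: float = 0.1     # fraction of probes affected

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("affected fraction must be in [0, 1]")
        if self.sd < 0:
            raise ValueError("effect SD must be >= 0")


@dataclass(frozen=True)
class DifferentialSpike:
    """A block of probes with a planted group difference.

    ``column``/``level_a``/``level_b`` define the contrast on the metadata
    (e.g. tissue endometrium vs endometriotic, or case vs control);
    ``effect`` is the mean shift added to ``level_a`` samples (a beta
    difference on the methylation scale, a log2 fold change on the
    expression scale).
    """

    n_probes: int
    column: str
    level_a: str
    level_b: str
    effect: float


@dataclass
class GeneratorParams:
    """Full specification of a simulated nested study.

    ``tissue_samples`` maps each tissue to the individual IDs contributing
    that tissue; ``splits`` maps (individual_id, tissue) to the number of
    pre-extraction splits (default ``default_splits``).  A technical
    replicate is added to ``replicated_fraction`` of all splits (or to
    exactly ``n_replicate_arrays`` randomly chosen splits if given).
    """

    n_probes: int = 1000
    individuals: Sequence[Individual] = ()
    tissue_samples: dict[str, Sequence[str]] = field(default_factory=dict)
    splits: dict[tuple[str, str], int] = field(default_factory=dict)
    default_splits: int = 2
    replicated_fraction: float = 0.5
    n_replicate_arrays: int | None = None
    var_individual: float | Sequence[float] = 0.01
    var_split: float | Sequence[float] = 0.005
    var_technical: float | Sequence[float] = 0.002
    tissue_offset_sd: dict[str, float] = field(default_factory=dict)
    subtype_offset_sd: float = 0.0
    covariate_effects: dict[str, CovariateEffect] = field(default_factory=dict)
    differential: Sequence[DifferentialSpike] = ()
    scale: str = BETA
    logit_normal: bool = False
    probe_mean_levels: Sequence[float] = (0.1, 0.5, 0.9)
    probe_mean_weights: Sequence[float] = (0.35, 0.30, 0.35)
    seed: int = 0

    def validate(self) -> None:
        if not self.individuals:
            raise ValueError("at least one individual is required")
        if not 0.0 <= self.replicated_fraction <= 1.0:
            raise ValueError("replicated_fraction must be in [0, 1]")
        for name, v in (("var_individual", self.var_individual),
                        ("var_split", self.var_split),
                        ("var_technical", self.var_technical)):
            if np.any(np.asarray(v, dtype=float) < 0):
                raise ValueError(f"{name} must be >= 0")
        ids = {ind.individual_id for ind in self.individuals}
        for tissue, members in self.tissue_samples.items():
            unknown = set(members) - ids
            if unknown:
                raise ValueError(f"unknown individuals for tissue {tissue}: {sorted(unknown)}")


class GeneratedData(NamedTuple):
    dataset: Dataset
    truth: pd.DataFrame


def _per_probe(v, n_probes: int, rng: np.random.Generator) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim == 0:
        return np.full(n_probes, float(arr))
    if arr.shape != (n_probes,):
        raise ValueError(f"per-probe variance vector must have length {n_probes}")
    return arr


def _build_design(params: GeneratorParams, rng: np.random.Generator) -> pd.DataFrame:
    """One row per array (observation), fully labelled."""
    by_id = {ind.individual_id: ind for ind in params.individuals}
    tissues = params.tissue_samples or {"endometrium": [i.individual_id for i in params.individuals]}
    rows = []
    for tissue in sorted(tissues):
        for iid in tissues[tissue]:
            ind = by_id[iid]
            n_splits = params.splits.get((iid, tissue), params.default_splits)
            for s in range(1, n_splits + 1):
                rows.append((iid, tissue, f"s{s}"))
    # choose replicated splits
    n_splits_total = len(rows)
    if params.n_replicate_arrays is not None:
        n_rep = params.n_replicate_arrays
    else:
        n_rep = int(round(params.replicated_fraction * n_splits_total))
    rep_idx = set(rng.choice(n_splits_total, size=n_rep, replace=False)) if n_rep else set()

    records = []
    for k, (iid, tissue, split) in enumerate(rows):
        ind = by_id[iid]
        n_reps = 2 if k in rep_idx else 1
        for r in range(1, n_reps + 1):
            records.append({
                "sample_id": f"{iid}_{tissue}_{split}_r{r}",
                "individual_id": iid,
                "tissue": tissue,
                "subtype": ind.subtype if tissue == "endometriotic" else "none",
                "split_id": split,
                "replicate_id": f"r{r}",
                "case_status": ind.case_status,
                "age": ind.age,
                "cycle_day": ind.cycle_day,
                "cycle_length": ind.cycle_length,
                "phase": categorize_phase(ind.cycle_day, ind.cycle_length),
                "smoking": ind.smoking,
                "bmi": ind.bmi,
                "whr": ind.whr,
            })
    return pd.DataFrame.from_records(records)


def _qc_fields(design: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Plausible quality metadata; tissue yields follow field experience
    (fat gives the lowest DNA yields, endometrium the highest)."""
    n = len(design)
    yield_mean = design["tissue"].map(
        {"endometrium": 4200.0, "fat": 2200.0, "endometriotic": 3000.0}).to_numpy()
    design = design.copy()
    design["tissue_weight_g"] = np.clip(rng.normal(0.39, 0.12, n), 0.05, None).round(3)
    # baseline samples pass QC comfortably; failures are spiked explicitly
    design["dna_yield_ng"] = np.clip(rng.normal(yield_mean, yield_mean * 0.25), 1200, None).round(1)
    design["call_rate"] = np.clip(rng.normal(0.995, 0.002, n), 0.90, 1.0).round(4)
    design["rin"] = np.clip(rng.normal(8.5, 0.5, n), 1.0, 10.0).round(2)
    design["housekeeping_signal"] = np.clip(rng.normal(15000, 2000, n), 500, None).round(0)
    return design


def generate_dataset(params: GeneratorParams) -> GeneratedData:
    """Simulate a nested-design dataset with known variance components.

    Returns the dataset plus a per-probe truth table (``mu``, ``sigma2_*``,
    one column per covariate effect and spike).  The same seed and params
    reproduce the output exactly.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    design = _build_design(params, rng)
    design = _qc_fields(design, rng)
    n_obs = len(design)
    n_probes = params.n_probes
    probe_ids = [f"p{j:06d}" for j in range(n_probes)]

    s2a = _per_probe(params.var_individual, n_probes, rng)
    s2b = _per_probe(params.var_split, n_probes, rng)
    s2e = _per_probe(params.var_technical, n_probes, rng)

    # probe baseline means
    if params.scale == BETA:
        levels = rng.choice(np.asarray(params.probe_mean_levels, dtype=float),
                            p=np.asarray(params.probe_mean_weights, dtype=float),
                            size=n_probes)
        mu = levels + rng.normal(0.0, 0.02, n_probes)
    else:
        mu = rng.normal(8.0, 1.5, n_probes)

    truth = pd.DataFrame({"probe_id": probe_ids, "mu": mu,
                          "sigma2_individual": s2a, "sigma2_split": s2b,
                          "sigma2_technical": s2e}).set_index("probe_id")

    # index helpers
    ind_tissue, it_codes = np.unique(
        design["individual_id"].astype(str) + "\x1f" + design["tissue"], return_inverse=True)
    split_key, sp_codes = np.unique(
        design["individual_id"].astype(str) + "\x1f" + design["tissue"] + "\x1f" + design["split_id"],
        return_inverse=True)

    # mean structure: tissue and subtype offsets
    signal = np.tile(mu[:, None], (1, n_obs))
    for tissue in sorted(set(design["tissue"])):
        sd = params.tissue_offset_sd.get(tissue, 0.0)
        offs = rng.normal(0.0, sd, n_probes) if sd > 0 else np.zeros(n_probes)
        truth[f"offset_{tissue}"] = offs
        mask = (design["tissue"] == tissue).to_numpy()
        signal[:, mask] += offs[:, None]
    if params.subtype_offset_sd > 0:
        for subtype in ("peritoneal", "endometrioma"):
            mask = (design["subtype"] == subtype).to_numpy()
            if mask.any():
                offs = rng.normal(0.0, params.subtype_offset_sd, n_probes)
                truth[f"offset_{subtype}"] = offs
                signal[:, mask] += offs[:, None]

    # covariate effects: linear on the analysis scale
    for cov in sorted(params.covariate_effects):
        eff = params.covariate_effects[cov]
        n_hit = int(round(eff.fraction * n_probes))
        hit = rng.choice(n_probes, size=n_hit, replace=False)
        if cov == "phase":
            # two indicator contrasts vs the menstrual baseline
            for level in ("proliferative", "secretory"):
                beta = np.zeros(n_probes)
                beta[hit] = rng.normal(0.0, eff.sd, n_hit)
                truth[f"beta_phase_{level}"] = beta
                x = (design["phase"] == level).to_numpy(dtype=float)
                signal += beta[:, None] * x[None, :]
            continue
        if cov == "case_status":
            x = (design["case_status"] == "case").to_numpy(dtype=float)
        elif cov == "smoking":
            x = design["smoking"].to_numpy(dtype=float)
        else:
            raw = design[cov].to_numpy(dtype=float)
            x = (raw - np.nanmean(raw)) / (np.nanstd(raw) or 1.0)
        beta = np.zeros(n_probes)
        beta[hit] = rng.normal(0.0, eff.sd, n_hit)
        truth[f"beta_{cov}"] = beta
        signal += beta[:, None] * x[None, :]

    # spiked differential probes (assigned to consecutive blocks from probe 0)
    next_probe = 0
    for k, spike in enumerate(params.differential):
        block = np.arange(next_probe, next_probe + spike.n_probes)
        next_probe += spike.n_probes
        col = np.zeros(n_probes, dtype=bool)
        col[block] = True
        truth[f"spike{k}_{spike.column}_{spike.level_a}_vs_{spike.level_b}"] = np.where(
            col, spike.effect, 0.0)
        mask = (design[spike.column] == spike.level_a).to_numpy()
        signal[np.ix_(col, mask)] += spike.effect

    # random effects, drawn per (probe, unit)
    a = rng.normal(0.0, 1.0, (n_probes, len(ind_tissue))) * np.sqrt(s2a)[:, None]
    b = rng.normal(0.0, 1.0, (n_probes, len(split_key))) * np.sqrt(s2b)[:, None]
    e = rng.normal(0.0, 1.0, (n_probes, n_obs)) * np.sqrt(s2e)[:, None]
    values = signal + a[:, it_codes] + b[:, sp_codes] + e

    if params.scale == BETA:
        if params.logit_normal:
            # interpret the linear predictor as logits centred at mu
            eps = 1e-6
            base = np.clip(np.tile(mu[:, None], (1, n_obs)), eps, 1 - eps)
            logit = np.log(base / (1 - base)) + (values - np.tile(mu[:, None], (1, n_obs)))
            values = 1.0 / (1.0 + np.exp(-logit))
        else:
            out_of_range = float(np.mean((values < 0) | (values > 1)))
            if out_of_range > 0.05:
                msg = (f"beta-scale truncation rate {out_of_range:.1%} exceeds 5%; "
                       "generating variances are too large for the beta scale")
                log.warning(msg)
                warnings.warn(msg, stacklevel=2)
            values = np.clip(values, 0.0, 1.0)

    for col in METADATA_COLUMNS:
        if col not in design.columns:
            design[col] = np.nan
    matrix = ProbeMatrix(probe_ids, list(design["sample_id"]), values, params.scale)
    return GeneratedData(Dataset(matrix, design[METADATA_COLUMNS]), truth.reset_index())


def spike_qc_failures(dataset: Dataset, spec: dict[str, dict[str, float]]) -> Dataset:
    """Degrade QC metadata fields for the named samples.

    ``spec`` maps sample_id -> {field: value} where field is one of
    call_rate, dna_yield_ng, rin, housekeeping_signal.  The value matrix is
    unchanged; an unknown sample ID raises ``KeyError``.
    """
    allowed = {"call_rate", "dna_yield_ng", "rin", "housekeeping_signal"}
    md = dataset.metadata.copy()
    ids = set(md["sample_id"])
    for sid, fields in spec.items():
        if sid not in ids:
            raise KeyError(f"unknown sample ID {sid!r}")
        bad = set(fields) - allowed
        if bad:
            raise ValueError(f"cannot degrade fields {sorted(bad)}; allowed: {sorted(allowed)}")
        for f, v in fields.items():
            md.loc[md["sample_id"] == sid, f] = v
    return Dataset(dataset.matrix, md)


# ---------------------------------------------------------------------------
# Reference designs mirroring a two-tissue-split, replicated study layout
# ---------------------------------------------------------------------------

def _study_individuals(rng: np.random.Generator) -> list[Individual]:
    """24 women: 16 endometriosis cases and 8 symptomatic controls."""
    inds = []
    for k in range(24):
        case = k < 16
        subtype = ("endometrioma" if k < 8 else "peritoneal") if case else "none"
        inds.append(Individual(
            individual_id=f"{'case' if case else 'ctrl'}{k + 1:02d}",
            case_status="case" if case else "control",
            age=float(np.round(rng.uniform(25, 47), 1)),
            cycle_day=float(int(rng.integers(1, 29))),
            cycle_length=28.0,
            smoking=bool(rng.random() < 1 / 3),
            bmi=float(np.round(rng.uniform(20.2, 34.0), 1)),
            whr=float(np.round(rng.uniform(0.72, 0.89), 2)),
            subtype=subtype,
        ))
    return inds


def study_methylation_params(seed: int = 0, n_probes: int = 500,
                            **overrides) -> GeneratorParams:
    """The DNA-methylation study layout: 96 arrays from 24 women.

    Endometrium and fat from 8 cases and 8 controls, disease tissue from
    all 16 cases.  All endometrium and disease-tissue samples and 8 of the
    16 fat samples are split in two (88 extractions); 8 technical
    replicate arrays bring the total to 96.
    """
    rng = np.random.default_rng(seed)
    inds = _study_individuals(rng)
    cases = [i.individual_id for i in inds if i.case_status == "case"]
    controls = [i.individual_id for i in inds if i.case_status == "control"]
    shared_cases = cases[:8]           # the 8 cases contributing all 3 tissues
    endo_fat = shared_cases + controls
    splits = {}
    for iid in endo_fat:
        splits[(iid, "endometrium")] = 2
    for k, iid in enumerate(endo_fat):
        splits[(iid, "fat")] = 2 if k < 8 else 1
    for iid in cases:
        splits[(iid, "endometriotic")] = 2
    defaults = dict(
        n_probes=n_probes,
        individuals=inds,
        tissue_samples={"endometrium": endo_fat, "fat": endo_fat, "endometriotic": cases},
        splits=splits,
        default_splits=1,
        n_replicate_arrays=8,
        var_individual=0.003, var_split=0.0008, var_technical=0.0004,
        tissue_offset_sd={"endometrium": 0.03, "fat": 0.03, "endometriotic": 0.03},
        subtype_offset_sd=0.015,
        probe_mean_levels=(0.15, 0.5, 0.85),
        scale=BETA,
        seed=seed,
    )
    defaults.update(overrides)
    return GeneratorParams(**defaults)


def study_expression_params(seed: int = 0, n_probes: int = 500,
                           **overrides) -> GeneratorParams:
    """The expression study layout: 39 endometrium arrays from 16 women.

    The 16 endometrium samples are split in two (32 extractions) and 7
    technical replicate arrays bring the total to 39.
    """
    rng = np.random.default_rng(seed)
    inds = _study_individuals(rng)
    endo = [i.individual_id for i in inds if i.case_status == "control"] + \
           [i.individual_id for i in inds if i.case_status == "case"][:8]
    defaults = dict(
        n_probes=n_probes,
        individuals=[i for i in inds if i.individual_id in endo],
        tissue_samples={"endometrium": endo},
        splits={(iid, "endometrium"): 2 for iid in endo},
        default_splits=1,
        n_replicate_arrays=7,
        var_individual=0.20, var_split=0.10, var_technical=0.12,
        scale=LOG2_INTENSITY,
        seed=seed,
    )
    defaults.update(overrides)
    return GeneratorParams(**defaults)
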