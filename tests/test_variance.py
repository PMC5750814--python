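import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import multivariate_normal

from tissuevar import (
    NestedDesign,
    decompose_dataset,
    fit_nested_ml,
    generate_dataset,
    loglik_nested,
    rank_variable_probes,
    summarize_components,
)
from tissuevar.datamodel import Dataset, DatasetError, ProbeMatrix, average_profiles

from conftest import make_individuals, nested_params


def random_design(rng, max_obs=8):
    """A random small nested design with >= 2 individuals."""
    while True:
        n = int(rng.integers(4, max_obs + 1))
        ind = rng.integers(0, 3, n).astype(str)
        if len(set(ind)) >= 2:
            break
    split = rng.integers(0, 2, n).astype(str)
    return ind, split


def dense_loglik(y, ind, split, mu, a, b, e):
    """Independent oracle: explicit covariance + scipy's MVN density."""
    n = len(y)
    pair = [f"{i}|{s}" for i, s in zip(ind, split)]
    cov = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            cov[i, j] = (a * (ind[i] == ind[j]) + b * (pair[i] == pair[j])
                         + e * (i == j))
    return multivariate_normal(mean=np.full(n, mu), cov=cov,
                               allow_singular=True).logpdf(np.asarray(y))


def brute_force_ml(y, ind, split):
    """Grid + polish maximisation of the dense-covariance likelihood."""
    y = np.asarray(y, dtype=float)
    v = y.var() or 1.0

    def negll(theta):
        a, b, e = np.exp(theta)
        n = len(y)
        pair = [f"{i}|{s}" for i, s in zip(ind, split)]
        cov = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                cov[i, j] = (a * (ind[i] == ind[j]) + b * (pair[i] == pair[j])
                             + e * (i == j))
        one = np.ones(n)
        sol = np.linalg.solve(cov, np.column_stack([y, one]))
        mu = (one @ sol[:, 0]) / (one @ sol[:, 1])
        r = y - mu
        sign, logdet = np.linalg.slogdet(cov)
        quad = r @ np.linalg.solve(cov, r)
        return 0.5 * (n * np.log(2 * np.pi) + logdet + quad)

    grid = v * np.array([1e-6, 0.02, 0.1, 0.3, 0.7, 1.2, 2.5])
    best = None
    for ga in grid:
        for gb in grid:
            for ge in grid[1:]:
                val = negll(np.log([ga, gb, ge]))
                if best is None or val < best[0]:
                    best = (val, np.log([ga, gb, ge]))
    res = minimize(negll, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return -res.fun


class TestLoglikNested:
    def test_single_observation_at_its_mean(self):
        d = NestedDesign(["i1"], ["s1"])
        total = 0.9
        ll = loglik_nested([0.4], d, 0.4, 0.5, 0.3, 0.1)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi * total))

    def test_matches_dense_mvn_oracle(self, rng):
        for _ in range(25):
            ind, split = random_design(rng)
            y = rng.normal(0.2, 1.0, len(ind))
            a, b, e = rng.uniform(0.05, 2.0, 3)
            mu = float(rng.normal())
            mine = loglik_nested(y, (ind, split), mu, a, b, e)
            ref = dense_loglik(y, ind, split, mu, a, b, e)
            assert mine == pytest.approx(ref, abs=1e-8)

    def test_zero_total_variance_sentinel(self):
        d = NestedDesign(["i1", "i2"], ["s1", "s1"])
        assert loglik_nested([0.0, 1.0], d, 0.5, 0.0, 0.0, 0.0) == -np.inf

    def test_negative_variance_rejected(self):
        d = NestedDesign(["i1", "i2"], ["s1", "s1"])
        with pytest.raises(ValueError):
            loglik_nested([0.0, 1.0], d, 0.5, -0.1, 0.0, 0.1)


class TestFitNestedML:
    def test_all_identical_observations(self):
        d = NestedDesign(["i1", "i1", "i2", "i2"], ["a", "b", "a", "b"])
        fit = fit_nested_ml([0.3] * 4, d)
        assert (fit.sigma2_individual, fit.sigma2_split, fit.sigma2_technical) == (0, 0, 0)
        assert fit.converged

    def test_balanced_one_way_closed_form(self):
        """2 individuals x 2 identical splits: residual levels are exactly
        zero and sigma2_A is the ML mean-square deviation 0.25."""
        d = NestedDesign(["i1", "i1", "i2", "i2"], ["a", "b", "a", "b"])
        fit = fit_nested_ml([0.0, 0.0, 1.0, 1.0], d)
        assert fit.sigma2_split == 0.0 and fit.sigma2_technical == 0.0
        assert fit.sigma2_individual == pytest.approx(0.25)

    def test_matches_brute_force_oracle_on_small_designs(self, rng):
        for _ in range(20):
            ind, split = random_design(rng)
            y = rng.normal(0.0, 1.0, len(ind))
            fit = fit_nested_ml(y, (ind, split))
            oracle = brute_force_ml(y, ind, split)
            assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_scale_equivariance(self, rng):
        ind, split = random_design(rng)
        y = rng.normal(0.0, 1.0, len(ind))
        c = 3.0
        f1 = fit_nested_ml(y, (ind, split))
        f2 = fit_nested_ml(y * c, (ind, split))
        for attr in ("sigma2_individual", "sigma2_split", "sigma2_technical"):
            v1, v2 = getattr(f1, attr), getattr(f2, attr)
            if not np.isnan(v1):
                assert v2 == pytest.approx(c ** 2 * v1, rel=1e-3, abs=1e-8)

    def test_loglik_not_below_feasible_starts(self, rng):
        """The reported maximum dominates the likelihood at arbitrary
        feasible parameter values (monotone improvement)."""
        ind, split = random_design(rng)
        y = rng.normal(0.0, 1.0, len(ind))
        d = NestedDesign(ind, split)
        fit = fit_nested_ml(y, d)
        for _ in range(10):
            a, b, e = rng.uniform(0.01, 2.0, 3)
            mu = float(np.mean(y))
            assert fit.loglik >= loglik_nested(y, d, mu, a, b, e) - 1e-9

    def test_single_split_no_replicates_reports_confounding(self, rng):
        ind = [f"i{k}" for k in range(6)]
        split = ["s1"] * 6
        y = rng.normal(0.0, 1.0, 6)
        fit = fit_nested_ml(y, (ind, split))
        assert fit.confounded == "individual+split+technical"
        assert np.isnan(fit.sigma2_split)
        assert fit.sigma2_confounded > 0

    def test_no_replicates_confounds_split_and_technical(self, rng):
        ind = np.repeat([f"i{k}" for k in range(5)], 2)
        split = np.tile(["s1", "s2"], 5)
        y = rng.normal(0.0, 1.0, 10)
        fit = fit_nested_ml(y, (ind, split))
        assert fit.confounded == "split+technical"
        assert np.isnan(fit.sigma2_split) and np.isnan(fit.sigma2_technical)
        assert not np.isnan(fit.sigma2_individual)

    def test_proportions_sum_to_one(self, small_data):
        decomp = decompose_dataset(small_data.dataset)
        props = decomp[["prop_individual", "prop_split", "prop_technical"]]
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-9)

    def test_too_few_individuals_rejected(self):
        with pytest.raises(DatasetError, match=">= 2 individuals"):
            fit_nested_ml([0.1, 0.2], (["i1", "i1"], ["s1", "s2"]))


class TestAgainstLmer:
    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_lme4_maximum_likelihood(self, tmp_path, rng):
        """Independent oracle: the same nested model fitted by lme4's
        lmer (ML) yields the same variance components."""
        inds = make_individuals(12)
        params = nested_params(n_probes=1, n_individuals=12, var_individual=0.8,
                               var_split=0.3, var_technical=0.1, seed=99)
        data = generate_dataset(params)
        ds = data.dataset
        df = ds.metadata[["individual_id", "split_id"]].copy()
        df["y"] = ds.matrix.values[0]
        csv = tmp_path / "probe.csv"
        df.to_csv(csv, index=False)
        rfile = tmp_path / "fit.R"
        rfile.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$split <- interaction(d$individual_id, d$split_id)
            m <- lmer(y ~ 1 + (1 | individual_id) + (1 | split), data = d,
                      REML = FALSE)
            vc <- as.data.frame(VarCorr(m))
            v <- setNames(vc$vcov, vc$grp)
            cat(v[["individual_id"]], v[["split"]], v[["Residual"]],
                as.numeric(logLik(m)), sep = "\\n")
        """))
        out = subprocess.run(["Rscript", str(rfile)], capture_output=True,
                             text=True, check=True)
        r_a, r_b, r_e, r_ll = map(float, out.stdout.split())
        fit = fit_nested_ml(ds.matrix.values[0],
                            NestedDesign.from_metadata(ds.metadata))
        assert fit.sigma2_individual == pytest.approx(r_a, rel=1e-3, abs=1e-5)
        assert fit.sigma2_split == pytest.approx(r_b, rel=1e-3, abs=1e-5)
        assert fit.sigma2_technical == pytest.approx(r_e, rel=1e-3, abs=1e-5)
        assert fit.loglik == pytest.approx(r_ll, abs=1e-4)


class TestRemlBias:
    def test_reml_removes_leading_small_sample_bias(self):
        """ML underestimates the between-individual component by O(1/I);
        REML removes the leading term."""
        truth = 1.0
        params = nested_params(n_probes=300, n_individuals=10,
                               var_individual=truth, var_split=0.2,
                               var_technical=0.1, seed=17)
        data = generate_dataset(params)
        ml = decompose_dataset(data.dataset)["sigma2_individual"].mean()
        reml = decompose_dataset(data.dataset, reml=True)["sigma2_individual"].mean()
        assert ml < reml
        assert abs(reml - truth) < abs(ml - truth)


class TestRanking:
    def test_fraction_one_returns_all(self, small_data):
        averaged = average_profiles(small_data.dataset, level="all")
        assert set(rank_variable_probes(averaged, 1.0)) == set(
            small_data.dataset.matrix.probe_ids)

    def test_constant_probe_ranks_last(self, small_data):
        averaged = average_profiles(small_data.dataset, level="all")
        vals = averaged.matrix.values.copy()
        vals[0] = 5.0  # make the first probe constant
        flat = Dataset(
            ProbeMatrix(averaged.matrix.probe_ids, averaged.matrix.sample_ids,
                        vals, averaged.matrix.scale),
            averaged.metadata)
        ranked = rank_variable_probes(flat, 1.0)
        assert ranked[-1] == averaged.matrix.probe_ids[0]

    def test_top10_nested_in_top50(self, small_data):
        averaged = average_profiles(small_data.dataset, level="all")
        top50 = set(rank_variable_probes(averaged, 0.5))
        top10 = set(rank_variable_probes(averaged, 0.1))
        assert top10 <= top50

    def test_needs_two_samples(self, small_data):
        averaged = average_profiles(small_data.dataset, level="all")
        one = averaged.subset_samples(averaged.matrix.sample_ids[:1])
        with pytest.raises(DatasetError):
            rank_variable_probes(one, 0.5)


class TestSummaries:
    def test_identical_decompositions_have_zero_sd(self):
        rows = [dict(probe_id=f"p{k}", sigma2_individual=0.8, sigma2_split=0.15,
                     sigma2_technical=0.05, prop_individual=0.8, prop_split=0.15,
                     prop_technical=0.05, converged=True) for k in range(5)]
        decomp = pd.DataFrame(rows).set_index("probe_id")
        summ = summarize_components(decomp, list(decomp.index))
        assert (summ.stats["sd"] == 0).all()
        # mean proportions over the subset still sum to 1
        prop_means = summ.stats.loc[
            ["prop_individual", "prop_split", "prop_technical"], "mean"]
        assert prop_means.sum() == pytest.approx(1.0)

    def test_empty_subset_raises(self, small_data):
        decomp = decompose_dataset(small_data.dataset)
        with pytest.raises(ValueError, match="empty"):
            summarize_components(decomp, [])

    def test_nonconverged_probes_counted(self):
        rows = [dict(probe_id=f"p{k}", sigma2_individual=0.8, sigma2_split=0.15,
                     sigma2_technical=0.05, prop_individual=0.8, prop_split=0.15,
                     prop_technical=0.05, converged=(k > 0)) for k in range(4)]
        decomp = pd.DataFrame(rows).set_index("probe_id")
        summ = summarize_components(decomp, list(decomp.index))
        assert summ.n_nonconverged == 1
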