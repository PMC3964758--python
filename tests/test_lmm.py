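"""Kinship mixed model: estimation, oracles, and association tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exergen import (Individual, KinshipTransform, ModelError, Pedigree,
                     SimulationConfig, bonferroni_alpha, fit, fit_lmm,
                     gene_drop, generate_families, joint_test,
                     relationship_matrix, simulate_phenotype, standardize_age)
from exergen.lmm import test_variant as wald_test
from exergen.lmm import _profile
from exergen.pedigree import relationship_blocks


def explicit_mvn_loglik(y, X, beta, sigma2_a, sigma2_e, A):
    """Independent oracle: the raw multivariate-normal log-density."""
    V = sigma2_a * A + sigma2_e * np.eye(len(y))
    return stats.multivariate_normal.logpdf(y, mean=X @ beta, cov=V)


def grid_search_oracle(y, X, A, bounds=(0.0, 4.0), passes=4, grid=41):
    """Brute-force ML over (sigma2_a, sigma2_e) with GLS beta at each node."""
    best = (-np.inf, None)
    lo_a, hi_a = bounds
    lo_e, hi_e = 1e-3, bounds[1]
    for _ in range(passes):
        for sa in np.linspace(lo_a, hi_a, grid):
            for se_ in np.linspace(lo_e, hi_e, grid):
                V = sa * A + se_ * np.eye(len(y))
                Vi = np.linalg.inv(V)
                beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
                ll = explicit_mvn_loglik(y, X, beta, sa, se_, A)
                if ll > best[0]:
                    best = (ll, (sa, se_, beta))
        sa, se_, _ = best[1]
        da = (hi_a - lo_a) / (grid - 1)
        de = (hi_e - lo_e) / (grid - 1)
        lo_a, hi_a = max(0.0, sa - da), sa + da
        lo_e, hi_e = max(1e-4, se_ - de), se_ + de
    return best


def two_family_toy(seed=3):
    """6 individuals, 2 sib-trio families, with a genotype covariate."""
    individuals = []
    for fam in ("f1", "f2"):
        individuals += [
            Individual(f"{fam}-F", fam, in_analysis=False),
            Individual(f"{fam}-M", fam, in_analysis=False),
            Individual(f"{fam}-a", fam, f"{fam}-F", f"{fam}-M", zygosity="DZ"),
            Individual(f"{fam}-b", fam, f"{fam}-F", f"{fam}-M", zygosity="DZ"),
            Individual(f"{fam}-c", fam, f"{fam}-F", f"{fam}-M"),
        ]
    ped = Pedigree(individuals)
    ids = ped.analysis_ids()
    A = relationship_matrix(ped, ids)
    rng = np.random.default_rng(seed)
    g = rng.integers(0, 3, len(ids)).astype(float)
    X = np.column_stack([np.ones(len(ids)), g])
    L = np.linalg.cholesky(A + 1e-10 * np.eye(len(ids)))
    y = 2.0 + 0.5 * g + 1.2 * (L @ rng.standard_normal(len(ids))) \
        + 0.8 * rng.standard_normal(len(ids))
    return ped, ids, A, X, y


class TestFitCore:
    def test_identity_A_reproduces_ols(self, rng):
        n = 120
        individuals = [Individual(f"i{k}", f"f{k}") for k in range(n)]
        ped = Pedigree(individuals)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([1.0, 2.0]) + rng.standard_normal(n)
        transform = KinshipTransform.from_pedigree(ped, [f"i{k}" for k in range(n)])
        res = fit_lmm(y, X, transform)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert res.beta == pytest.approx(ols, rel=1e-8)
        assert res.sigma2_a == pytest.approx(0.0, abs=1e-8)

    def test_toy_fit_matches_grid_search_oracle(self):
        ped, ids, A, X, y = two_family_toy()
        transform = KinshipTransform.from_pedigree(ped, ids)
        res = fit_lmm(y, X, transform)
        ll_oracle, (sa, se_, beta) = grid_search_oracle(y, X, A)
        assert res.loglik == pytest.approx(ll_oracle, abs=1e-4)
        assert res.sigma2_a == pytest.approx(sa, abs=0.02)
        assert res.sigma2_e == pytest.approx(se_, abs=0.02)
        assert res.beta == pytest.approx(beta, abs=0.01)

    def test_profiled_loglik_equals_explicit_mvn_density(self):
        ped, ids, A, X, y = two_family_toy(seed=8)
        transform = KinshipTransform.from_pedigree(ped, ids)
        res = fit_lmm(y, X, transform)
        ll = explicit_mvn_loglik(y, X, res.beta, res.sigma2_a, res.sigma2_e, A)
        assert res.loglik == pytest.approx(ll, abs=1e-6)

    def test_matches_statsmodels_random_intercept_on_sib_pairs(self):
        # For full-sib pairs, sigma2_a*A + sigma2_e*I is exactly a random
        # family intercept with variance sigma2_a/2: cross-check against
        # an independent ML implementation.
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        n_fam = 150
        individuals, groups = [], []
        for f in range(n_fam):
            individuals += [
                Individual(f"f{f}-F", f"f{f}", in_analysis=False),
                Individual(f"f{f}-M", f"f{f}", in_analysis=False),
                Individual(f"f{f}-a", f"f{f}", f"f{f}-F", f"f{f}-M", zygosity="DZ"),
                Individual(f"f{f}-b", f"f{f}", f"f{f}-F", f"f{f}-M", zygosity="DZ"),
            ]
            groups += [f, f]
        ped = Pedigree(individuals)
        ids = ped.analysis_ids()
        n = len(ids)
        x = rng.standard_normal(n)
        u = np.repeat(rng.standard_normal(n_fam), 2)
        y = 1.0 + 0.3 * x + 0.9 * u + rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        res = fit_lmm(y, X, KinshipTransform.from_pedigree(ped, ids))
        sm_fit = statsmodels.MixedLM(y, X, groups=np.array(groups)).fit(reml=False)
        assert res.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        assert res.beta == pytest.approx(sm_fit.fe_params, abs=1e-4)
        # random-intercept variance = half the additive variance
        assert res.sigma2_a / 2 == pytest.approx(float(np.asarray(sm_fit.cov_re)[0, 0]),
                                                 abs=1e-3)

    def test_heritability_recovery(self):
        cfg = SimulationConfig(n_individuals=2000, maf=0.3, effect_r2=0.0,
                               heritability_h2=0.5, phenotype_floor=None,
                               truncation_cap=None, seed=6)
        ped = generate_families(cfg)
        ids = ped.analysis_ids()
        transform = KinshipTransform.from_pedigree(ped, ids)
        ones = np.ones(len(ids))
        h2 = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            codes = gene_drop(ped, cfg.maf, rng)
            y = simulate_phenotype(ped, codes, cfg, rng)
            res = fit_lmm(y, ones[:, None], transform)
            h2.append(res.heritability)
        assert np.mean(h2) == pytest.approx(0.5, abs=0.05)

    def test_rank_deficient_design_rejected(self):
        ped, ids, A, X, y = two_family_toy()
        Xbad = np.column_stack([X, X[:, 1]])
        transform = KinshipTransform.from_pedigree(ped, ids)
        with pytest.raises(ModelError):
            fit_lmm(y, Xbad, transform)

    def test_too_few_cases_rejected(self):
        ped = Pedigree([Individual("a", "f1"), Individual("b", "f2")])
        transform = KinshipTransform.from_pedigree(ped, ["a", "b"])
        with pytest.raises(ModelError):
            fit_lmm(np.array([1.0, 2.0]), np.ones((2, 1)), transform)


class TestHighLevelFit:
    def _dataset(self, seed=0, n=600):
        cfg = SimulationConfig(n_individuals=n, maf=0.3, effect_r2=0.02,
                               heritability_h2=0.4, seed=seed)
        ped = generate_families(cfg)
        rng = np.random.default_rng(seed + 1)
        codes = gene_drop(ped, cfg.maf, rng)
        y = simulate_phenotype(ped, codes, cfg, rng)
        ids = ped.analysis_ids()
        mask = ped.arrays()["in_analysis"]
        data = pd.DataFrame({
            "individual_id": ids,
            "weekly_met_hours": y,
            "sex": [0 if ped[i].sex == "male" else 1 for i in ids],
            "age": [ped[i].age for i in ids],
            "snp": codes[mask].astype(float),
        })
        return ped, data

    def test_fit_reports_all_terms_and_n(self):
        ped, data = self._dataset()
        res = fit(data, ped, variants=["snp"])
        assert res.names == ["intercept", "sex", "age_z", "sex_x_age", "snp"]
        assert res.n_used == len(data)
        assert res.sigma2_a >= 0 and res.sigma2_e > 0

    def test_complete_case_filtering(self):
        ped, data = self._dataset()
        data.loc[data.index[:25], "snp"] = np.nan
        res = fit(data, ped, variants=["snp"])
        assert res.n_used == len(data) - 25

    def test_wald_p_invariant_to_recoding(self):
        ped, data = self._dataset(seed=2)
        res = fit(data, ped, variants=["snp"])
        flipped = data.assign(snp=2.0 - data["snp"])
        res_f = fit(flipped, ped, variants=["snp"])
        t, tf = wald_test(res, "snp"), wald_test(res_f, "snp")
        assert res.coef("snp")[0] == pytest.approx(-res_f.coef("snp")[0], rel=1e-6)
        assert t.p_value == pytest.approx(tf.p_value, rel=1e-6)

    def test_missing_column_named(self):
        ped, data = self._dataset()
        with pytest.raises(ModelError, match="age"):
            fit(data.drop(columns=["age"]), ped, variants=["snp"])


class TestTests:
    def test_zero_estimate_gives_p_one(self):
        from exergen.lmm import LMMFit
        f = LMMFit(names=["intercept", "v"], beta=np.array([1.0, 0.0]),
                   se=np.array([0.1, 0.2]), sigma2_a=1.0, sigma2_e=1.0,
                   loglik=0.0, n_used=10, converged=True)
        assert wald_test(f, "v").p_value == 1.0
        with pytest.raises(ModelError):
            wald_test(f, "absent")

    def test_wald_p_equals_chisq_tail_by_quadrature(self):
        from scipy.integrate import quad
        from exergen.lmm import LMMFit
        f = LMMFit(names=["v"], beta=np.array([0.5]), se=np.array([0.2]),
                   sigma2_a=0.0, sigma2_e=1.0, loglik=0.0, n_used=50,
                   converged=True)
        tr = wald_test(f, "v")
        tail, _ = quad(lambda u: stats.chi2.pdf(u, 1), tr.statistic, np.inf)
        assert tr.p_value == pytest.approx(tail, abs=1e-8)

    def test_joint_test_df_and_degenerate_cases(self):
        ped, data = TestHighLevelFit()._dataset(seed=4)
        data["snp2"] = np.random.default_rng(0).integers(0, 3, len(data)).astype(float)
        full = fit(data, ped, variants=["snp", "snp2"])
        null = fit(data, ped, variants=[])
        tr = joint_test(full, null)
        assert tr.df == 2 and tr.statistic >= 0.0
        ll_ratio = 2 * (full.loglik - null.loglik)
        assert tr.statistic == pytest.approx(ll_ratio)
        assert tr.p_value == pytest.approx(stats.chi2.sf(ll_ratio, 2))
        self_test = joint_test(full, fit(data, ped, variants=["snp", "snp2"]))
        assert self_test.statistic == pytest.approx(0.0, abs=1e-6)
        assert self_test.p_value == 1.0
        with pytest.raises(ModelError):
            joint_test(null, full)  # not nested in that direction

    def test_joint_test_requires_same_sample(self):
        ped, data = TestHighLevelFit()._dataset(seed=5)
        full = fit(data, ped, variants=["snp"])
        null = fit(data.iloc[:-10], ped, variants=[])
        with pytest.raises(ModelError):
            joint_test(full, null)

    def test_type_one_error_calibrated(self):
        # null genotype at alpha = .05: rejection rate within binomial error
        cfg = SimulationConfig(n_individuals=500, maf=0.3, effect_r2=0.0,
                               heritability_h2=0.5, seed=10)
        ped = generate_families(cfg)
        ids = ped.analysis_ids()
        transform = KinshipTransform.from_pedigree(ped, ids)
        mask = ped.arrays()["in_analysis"]
        ones = np.ones(len(ids))
        rejections = 0
        n_runs = 400
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            codes = gene_drop(ped, cfg.maf, rng)
            y = simulate_phenotype(ped, codes, cfg, rng)
            X = np.column_stack([ones, codes[mask].astype(float)])
            res = fit_lmm(y, X, transform, names=["intercept", "snp"])
            if wald_test(res, "snp").p_value < 0.05:
                rejections += 1
        assert abs(rejections / n_runs - 0.05) < 4 * np.sqrt(0.05 * 0.95 / n_runs)


class TestHelpers:
    @pytest.mark.parametrize("family_alpha,n,expected", [
        (0.05, 11, 0.05 / 11),
        (0.05, 1, 0.05),
        (0.10, 4, 0.025),
    ])
    def test_bonferroni(self, family_alpha, n, expected):
        assert bonferroni_alpha(family_alpha, n) == pytest.approx(expected)
        assert round(bonferroni_alpha(0.05, 11), 4) == 0.0045

    def test_bonferroni_rejects_zero_tests(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)

    def test_standardize_age_two_points(self):
        z = standardize_age(np.array([20.0, 40.0]))
        assert z == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])

    def test_standardize_age_moments_and_oracle(self, rng):
        ages = rng.uniform(7, 50, 200)
        z = standardize_age(ages)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)
        direct = (ages - ages.mean()) / ages.std(ddof=1)
        assert z == pytest.approx(direct)

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError):
            standardize_age(np.full(5, 30.0))
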