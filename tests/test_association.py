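import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from bariscore.association import (
    AssociationResult,
    Contrast,
    ModelFit,
    ScanConfig,
    _ols,
    call_risk_allele,
    covariate_design,
    fit_inheritance_models,
    phenotype_direction,
    run_association_scan,
    select_best_model,
    significant_counts,
)
from bariscore.errors import (
    AllModelsSkippedError,
    InsufficientDataError,
    InvalidArgumentError,
)
from bariscore.genotypes import GenotypeMatrix
from bariscore.manifest import SNPManifest, SNPVariant
from bariscore.models import InheritanceModel
from bariscore.phenotypes import derive_phenotype_table

M = InheritanceModel
rng = np.random.default_rng(1234)


def hwe_dosage(n, q, generator=rng):
    return generator.choice([0, 1, 2], size=n, p=[(1 - q) ** 2, 2 * q * (1 - q), q**2])


class TestOLSAgainstStatsmodels:
    """The lean linear fitter must agree with statsmodels OLS."""

    def test_params_bse_llf_match(self):
        n = 120
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = X @ np.array([1.0, 0.5, -0.3, 0.0]) + rng.normal(size=n)
        ours = _ols(X, y)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(ours.params, ref.params, rtol=1e-9)
        np.testing.assert_allclose(ours.bse, ref.bse, rtol=1e-9)
        assert ours.llf == pytest.approx(ref.llf, rel=1e-12)
        # AIC convention: 2k - 2 llf with k = all mean coefficients
        assert 2 * ours.k - 2 * ours.llf == pytest.approx(ref.aic, rel=1e-12)


class TestModelSelection:
    def test_lowest_aic_wins(self):
        aics = {M.CODOMINANT: 1000.2, M.DOMINANT: 998.1, M.RECESSIVE: 1001.0,
                M.OVERDOMINANT: 999.3, M.LOG_ADDITIVE: 999.0}
        assert select_best_model(aics) is M.DOMINANT

    def test_aic_tie_broken_by_fixed_model_order(self):
        # dominant and log_additive tie with equal genetic-parameter count;
        # the fixed order places log_additive first
        aics = {M.CODOMINANT: 1000.2, M.DOMINANT: 998.1, M.RECESSIVE: 1001.0,
                M.OVERDOMINANT: 999.3, M.LOG_ADDITIVE: 998.1}
        assert select_best_model(aics) is M.LOG_ADDITIVE

    def test_tie_prefers_fewer_genetic_parameters(self):
        aics = {M.CODOMINANT: 998.1, M.RECESSIVE: 998.1}
        assert select_best_model(aics) is M.RECESSIVE


class TestFitInheritanceModels:
    def test_log_additive_matches_simple_regression(self):
        """Without covariates the log-additive fit equals plain regression on
        allele count (closed form via scipy.linregress)."""
        n = 200
        d = hwe_dosage(n, 0.3)
        y = 30 - 2.0 * d + rng.normal(0, 3, n)
        res = fit_inheritance_models("rs1", d, y, "linear", None, phenotype_name="twl_6y")
        fit = res.fits[M.LOG_ADDITIVE]
        lin = stats.linregress(d.astype(float), y)
        assert fit.contrasts[0].estimate == pytest.approx(lin.slope, rel=1e-9)

    def test_all_five_models_fitted(self):
        d = hwe_dosage(300, 0.4)
        y = rng.normal(size=300)
        res = fit_inheritance_models("rs1", d, y, "linear", None, phenotype_name="twl_6y")
        assert set(res.fits) == set(M)
        for fit in res.fits.values():
            assert np.isfinite(fit.aic)
            for c in fit.contrasts:
                assert c.ci_low <= c.estimate <= c.ci_high

    def test_monomorphic_snp_raises_all_skipped(self):
        d = np.zeros(200, dtype=int)
        y = rng.normal(size=200)
        with pytest.raises(AllModelsSkippedError):
            fit_inheritance_models("rs1", d, y, "linear", None)

    def test_rare_homozygote_models_skipped_not_fatal(self):
        d = hwe_dosage(300, 0.3).copy()
        d[d == 2] = 1  # remove alt homozygotes: recessive becomes constant
        y = rng.normal(size=300)
        res = fit_inheritance_models("rs1", d, y, "linear", None, phenotype_name="twl_6y")
        assert M.RECESSIVE in res.skipped
        assert M.DOMINANT in res.fits

    def test_insufficient_data_raises(self):
        d = hwe_dosage(12, 0.4)
        y = rng.normal(size=12)
        cov = pd.DataFrame(
            {"age": 45.0, "sex": "female", "bmi0": 44.0, "height": 1.7,
             "t2d": False, "htn": False, "surgery": "mixed"},
            index=[f"p{i}" for i in range(12)],
        )
        with pytest.raises(InsufficientDataError):
            fit_inheritance_models("rs1", d, y, "linear", cov)

    def test_all_missing_genotypes_insufficient(self):
        d = np.full(300, -1)
        y = rng.normal(size=300)
        with pytest.raises(InsufficientDataError):
            fit_inheritance_models("rs1", d, y, "linear", None)

    def test_permutation_invariance(self, covariates_375):
        n = 375
        d = hwe_dosage(n, 0.35)
        y = 30 - 1.5 * (d >= 1) + rng.normal(0, 5, n)
        res1 = fit_inheritance_models("rs1", d, y, "linear", covariates_375,
                                      phenotype_name="twl_6y")
        perm = rng.permutation(n)
        res2 = fit_inheritance_models(
            "rs1", d[perm], y[perm], "linear", covariates_375.iloc[perm],
            phenotype_name="twl_6y",
        )
        for model in res1.fits:
            assert res1.fits[model].aic == pytest.approx(res2.fits[model].aic, rel=1e-9)
            assert res1.fits[model].p_value == pytest.approx(
                res2.fits[model].p_value, rel=1e-6, abs=1e-12
            )
        assert res1.best_model == res2.best_model

    def test_planted_dominant_effect_detected_with_covariates(self, covariates_375):
        n = 375
        d = hwe_dosage(n, 0.3)
        age = covariates_375["age"].to_numpy()
        y = 35 - 5.0 * (d >= 1) - 0.1 * (age - 45) + rng.normal(0, 8, n)
        res = fit_inheritance_models("rs1", d, y, "linear", covariates_375,
                                     phenotype_name="twl_6y")
        assert res.significant
        assert res.best_model in (M.DOMINANT, M.LOG_ADDITIVE, M.CODOMINANT)
        assert res.fits[M.DOMINANT].contrasts[0].estimate < 0

    def test_logistic_family(self, covariates_375):
        n = 375
        d = hwe_dosage(n, 0.4)
        logit = -0.5 + 1.2 * (d >= 1)
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        res = fit_inheritance_models("rs1", d, y, "logistic", covariates_375,
                                     phenotype_name="wr_gt20")
        assert set(res.fits)  # fits exist
        assert res.fits[M.DOMINANT].contrasts[0].estimate > 0

    def test_hwe_and_call_rate_attached(self):
        d = np.array([0] * 50 + [1] * 30 + [2] * 10 + [-1] * 10)
        y = rng.normal(size=100)
        res = fit_inheritance_models("rs1", d, y, "linear", None, phenotype_name="twl_6y")
        assert res.call_rate == pytest.approx(0.9)
        from bariscore.hwe import hwe_exact_test

        assert res.hwe_p == pytest.approx(hwe_exact_test(50, 30, 10))


class TestRiskAlleleCalling:
    def _result(self, model, estimate, p=0.01, significant=True):
        fit = ModelFit(
            model=model,
            contrasts=tuple(
                Contrast("c", e, e - 1, e + 1)
                for e in ([0.1, estimate] if model is M.CODOMINANT else [estimate])
            ),
            p_value=p,
            aic=100.0,
            n_used=300,
        )
        res = AssociationResult(rsid="rs1", gene="G", phenotype="x",
                                fits={model: fit}, best_model=model,
                                significant=significant, p_value=p)
        return res

    def test_lower_loss_in_carriers_means_alt_risk(self):
        res = call_risk_allele(self._result(M.DOMINANT, -3.5), "loss", "T", "A")
        assert res.risk_allele == "A"
        assert res.risk_points == {0: 0, 1: 1, 2: 2}

    def test_higher_loss_in_carriers_means_ref_risk(self):
        res = call_risk_allele(self._result(M.DOMINANT, +3.5), "loss", "T", "A")
        assert res.risk_allele == "T"
        assert res.risk_points == {0: 2, 1: 1, 2: 0}

    def test_higher_regain_in_alt_homs_means_alt_risk(self):
        res = call_risk_allele(self._result(M.RECESSIVE, +4.0), "regain", "C", "G")
        assert res.risk_allele == "G"

    def test_not_significant_returns_none(self):
        res = call_risk_allele(
            self._result(M.DOMINANT, -3.5, p=0.3, significant=False), "loss", "T", "A"
        )
        assert res.risk_allele is None and res.risk_points is None

    def test_overdominant_gets_genotype_rule(self):
        res = call_risk_allele(self._result(M.OVERDOMINANT, -2.0), "loss", "T", "A")
        assert res.risk_allele is None
        assert res.risk_points == {0: 0, 1: 1, 2: 0}
        assert "heterozygote" in res.risk_rule_note

    def test_direction_mapping(self):
        assert phenotype_direction("twl_6y") == "loss"
        assert phenotype_direction("ewl_nadir") == "loss"
        assert phenotype_direction("wr_mwl") == "regain"


class TestScan:
    def test_scan_shape_and_counts(self, null_cohort):
        genotypes, covariates, trajectories, _ = null_cohort
        table = derive_phenotype_table(trajectories, covariates)
        results = run_association_scan(genotypes, table, covariates)
        assert len(results) == 48 * 3
        counts = significant_counts(results)
        assert set(counts) == {
            "per_phenotype", "n_unique_snps", "n_loss_snps", "n_regain_snps"
        }

    def test_low_call_rate_fails_qc_and_blocks_risk_call(self, null_cohort):
        genotypes, covariates, trajectories, _ = null_cohort
        table = derive_phenotype_table(trajectories, covariates)
        # knock one SNP down to 90% call rate
        g = GenotypeMatrix(
            patient_ids=list(genotypes.patient_ids),
            manifest=genotypes.manifest,
            dosage=genotypes.dosage.copy(),
        )
        col = g.manifest.rsids.index("rs6265")
        g.dosage[: int(0.1 * g.n_patients) + 1, col] = -1
        results = run_association_scan(g, table, covariates, ScanConfig(alpha=0.9))
        hits = [r for r in results if r.rsid == "rs6265"]
        assert hits and all(not r.qc_pass for r in hits)
        assert all(r.risk_allele is None for r in hits)

    def test_fdr_flag_adds_adjusted_p(self, null_cohort):
        genotypes, covariates, trajectories, _ = null_cohort
        table = derive_phenotype_table(trajectories, covariates)
        results = run_association_scan(
            genotypes, table, covariates, ScanConfig(fdr=True, phenotypes=("twl_6y",))
        )
        adj = [r.p_adjusted for r in results if r.p_adjusted is not None]
        assert adj and all(0 <= a <= 1 for a in adj)
        raw = [r.p_value for r in results if r.p_adjusted is not None]
        assert all(a >= p - 1e-12 for a, p in zip(adj, raw))

    def test_invalid_phenotype_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ScanConfig(phenotypes=("bogus",)).validate()
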