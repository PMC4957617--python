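import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrpipe.instruments import (
    classify_instrument,
    confounder_screen,
    exposure_regression,
    exposure_table,
    pleiotropy_matrix,
)
from mrpipe.simulate import (
    BiomarkerSpec,
    SimulationConfig,
    SNPSpec,
    simulate_cohort,
)


def _normal_equations_fit(x, y):
    """Independent oracle: simple-regression slope/intercept/t by hand."""
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    beta = sxy / sxx
    alpha = y.mean() - beta * x.mean()
    resid = y - alpha - beta * x
    s2 = np.sum(resid**2) / (n - 2)
    se = np.sqrt(s2 / sxx)
    t = beta / se
    r2 = 1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
    return beta, se, t, r2


class TestExposureRegression:
    def test_noiseless_line(self):
        d = np.tile([0.0, 1.0, 2.0], 5)
        y = 10 + 2 * d
        a = exposure_regression(d, y)
        assert a.beta == pytest.approx(2.0, abs=1e-10)
        assert a.r2 == pytest.approx(1.0, abs=1e-10)

    def test_six_point_hand_oracle(self):
        # padded to 12 points (two copies) to satisfy the n >= 10 precondition;
        # the least-squares solution is unchanged by duplication
        d = np.array([0.0, 0, 1, 1, 2, 2] * 2)
        y = np.array([1.0, 2, 2, 3, 3, 4] * 2)
        beta, se, t, r2 = _normal_equations_fit(d, y)
        assert beta == pytest.approx(1.0, abs=1e-12)  # hand least squares
        a = exposure_regression(d, y)
        assert a.beta == pytest.approx(beta, abs=1e-10)
        assert a.se == pytest.approx(se, rel=1e-10)
        assert a.f_stat == pytest.approx(t**2, rel=1e-10)
        assert a.r2 == pytest.approx(r2, rel=1e-10)

    def test_p_value_is_t_distributed(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, 40).astype(float)
        y = rng.normal(size=40)
        a = exposure_regression(d, y)
        t = np.sign(a.beta) * np.sqrt(a.f_stat)
        assert a.p == pytest.approx(2 * stats.t.sf(abs(t), df=38), rel=1e-9)

    def test_f_equals_t_squared_simple_regression(self, rng):
        d = rng.integers(0, 3, 200).astype(float)
        y = 1.0 + 0.5 * d + rng.normal(size=200)
        a = exposure_regression(d, y)
        _, se, t, _ = _normal_equations_fit(d, y)
        assert a.f_stat == pytest.approx(t**2, rel=1e-9)

    def test_incremental_r2_with_covariates(self, rng):
        n = 500
        d = rng.integers(0, 3, n).astype(float)
        cov = pd.DataFrame({"age": rng.normal(60, 8, n)})
        y = 2.0 * d + 0.5 * cov["age"].to_numpy() + rng.normal(0, 5, n)
        a = exposure_regression(d, y, covariates=cov)
        assert 0.0 <= a.r2 <= 1.0
        # oracle: difference of full and reduced R²
        import statsmodels.api as sm

        full = sm.OLS(y, sm.add_constant(np.column_stack([d, cov["age"]]))).fit()
        red = sm.OLS(y, sm.add_constant(cov["age"].to_numpy())).fit()
        assert a.r2 == pytest.approx(full.rsquared - red.rsquared, abs=1e-10)
        assert a.covariates == ("age",)

    def test_log_transform(self, rng):
        n = 200
        d = rng.integers(0, 3, n).astype(float)
        y = np.exp(0.1 * d + rng.normal(5, 0.2, n))
        a = exposure_regression(d, y, transform="log")
        assert a.transform == "log"
        assert a.beta == pytest.approx(0.1, abs=3.5 * a.se)

    def test_log_transform_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="positive"):
            exposure_regression(np.arange(12) % 3 * 1.0, np.r_[np.zeros(1), np.ones(11)], transform="log")

    def test_too_few_cases(self):
        with pytest.raises(ValueError, match="complete cases"):
            exposure_regression(np.array([0.0, 1, 2]), np.array([1.0, 2, 3]))

    def test_monomorphic_raises(self):
        with pytest.raises(ValueError, match="monomorphic"):
            exposure_regression(np.ones(20), np.random.default_rng(0).normal(size=20))

    def test_singular_design(self, rng):
        d = rng.integers(0, 3, 50).astype(float)
        cov = pd.DataFrame({"c1": d, "c2": 2 * d})  # collinear with dosage
        with pytest.raises(ValueError, match="singular"):
            exposure_regression(d, rng.normal(size=50), covariates=cov)

    def test_missing_dropped(self, rng):
        d = rng.integers(0, 3, 100).astype(float)
        y = 1.0 + d + rng.normal(size=100)
        y[:10] = np.nan
        a = exposure_regression(d, y)
        assert a.n == 90

    def test_f_r2_consistency(self, rng):
        """F = (n-2) r2 / (1 - r2) in simple regression."""
        d = rng.integers(0, 3, 300).astype(float)
        y = 0.8 * d + rng.normal(size=300)
        a = exposure_regression(d, y)
        assert a.f_stat == pytest.approx((a.n - 2) * a.r2 / (1 - a.r2), rel=1e-9)


class TestClassify:
    def test_strong_instrument(self, one_snp_config):
        cohort = simulate_cohort(one_snp_config, seed=2)
        a = exposure_regression(
            cohort.dosages["snp_iv"].to_numpy(), cohort.biomarkers["B2"].to_numpy()
        )
        assert classify_instrument(a) == "strong"

    @pytest.mark.parametrize(
        "f,expected", [(37.8, "strong"), (9.99, "weak"), (10.0, "strong"), (0.0, "weak")]
    )
    def test_boundary_semantics(self, f, expected):
        a = _assoc_with_f(f)
        assert classify_instrument(a) == expected

    def test_nonfinite_f(self):
        with pytest.raises(ValueError):
            classify_instrument(_assoc_with_f(np.nan))


def _assoc_with_f(f):
    from mrpipe.instruments import ExposureAssociation

    return ExposureAssociation(
        snp="s", biomarker="b", beta=1.0, se=0.5, p=0.5, ci_low=0.0, ci_high=2.0,
        f_stat=f, r2=0.01, r2_adj=0.01, n=100,
    )


class TestConfounderScreen:
    def test_null_variables_rarely_flagged(self, rng):
        n = 400
        d = rng.integers(0, 3, n).astype(float)
        variables = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"v{i}" for i in range(10)])
        flagged = sum(
            r.flagged
            for rep in range(5)
            for r in confounder_screen(d, variables.sample(frac=1, random_state=rep), n_tests=50)
        )
        assert flagged == 0

    def test_dosage_itself_flagged(self, rng):
        d = rng.integers(0, 3, 200).astype(float)
        res = confounder_screen(d, pd.DataFrame({"copy": d, "noise": rng.normal(size=200)}))
        by_name = {r.variable: r for r in res}
        assert by_name["copy"].flagged
        assert by_name["copy"].p < 1e-20
        assert not by_name["noise"].flagged

    def test_bonferroni_divisor_arithmetic(self, rng):
        # 49 tests at family alpha 0.05 -> per-test threshold ~0.00102
        d = rng.integers(0, 3, 300).astype(float)
        v = pd.DataFrame({"x": rng.normal(size=300)})
        res = confounder_screen(d, v, alpha=0.05, n_tests=49)
        threshold = 0.05 / 49
        assert threshold == pytest.approx(0.00102, abs=2e-5)
        assert res[0].flagged == (res[0].p < threshold)

    def test_binary_variable_uses_logistic(self, rng):
        n = 500
        d = rng.integers(0, 3, n).astype(float)
        v = pd.DataFrame({"diabetes": rng.integers(0, 2, n).astype(float)})
        res = confounder_screen(d, v)
        assert res[0].kind == "binary"

    def test_constant_variable_skipped_with_warning(self, rng):
        d = rng.integers(0, 3, 100).astype(float)
        v = pd.DataFrame({"const": np.ones(100), "ok": rng.normal(size=100)})
        with pytest.warns(UserWarning, match="constant"):
            res = confounder_screen(d, v)
        assert [r.variable for r in res] == ["ok"]


@pytest.fixture(scope="module")
def two_biomarker_cohort():
    cfg = SimulationConfig(
        n_individuals=800,
        snps=[SNPSpec("pleio", "A", "G", 0.3), SNPSpec("single", "C", "T", 0.4)],
        biomarkers=[
            BiomarkerSpec("B1", 200.0, 50.0),
            BiomarkerSpec("B2", 700.0, 265.0),
        ],
        effects={"pleio": {"B1": 18.0, "B2": 95.0}, "single": {"B1": 16.0}},
    )
    return simulate_cohort(cfg, seed=77)


class TestPleiotropy:
    def test_single_effect_snp_not_pleiotropic(self, two_biomarker_cohort):
        res = pleiotropy_matrix(two_biomarker_cohort.dosages, two_biomarker_cohort.biomarkers)
        assert "single" not in res.pleiotropic_snps
        null = [a for a in res.associations if a.snp == "single" and a.biomarker == "B2"]
        assert null[0].f_stat < 10

    def test_multi_effect_snp_flagged(self, two_biomarker_cohort):
        res = pleiotropy_matrix(two_biomarker_cohort.dosages, two_biomarker_cohort.biomarkers)
        assert "pleio" in res.pleiotropic_snps

    def test_requires_two_biomarkers(self, two_biomarker_cohort):
        with pytest.raises(ValueError):
            pleiotropy_matrix(
                two_biomarker_cohort.dosages, two_biomarker_cohort.biomarkers[["B1"]]
            )

    def test_strong_for_one_weak_for_other(self):
        """A variant with a large effect on one biomarker and none on another
        validates as an instrument only for the first."""
        cfg = SimulationConfig(
            n_individuals=718,
            snps=[SNPSpec("iv", "A", "G", 0.2647)],
            biomarkers=[
                BiomarkerSpec("B2", 700.0, 265.0),
                BiomarkerSpec("B3", 2500.0, 1000.0),
            ],
            effects={"iv": {"B2": 94.78, "B3": 84.0}},
        )
        strong_b2 = weak_b3 = 0
        for rep in range(30):
            cohort = simulate_cohort(cfg, seed=5000 + rep)
            f_b2 = exposure_regression(
                cohort.dosages["iv"].to_numpy(), cohort.biomarkers["B2"].to_numpy()
            ).f_stat
            f_b3 = exposure_regression(
                cohort.dosages["iv"].to_numpy(), cohort.biomarkers["B3"].to_numpy()
            ).f_stat
            strong_b2 += f_b2 >= 10
            weak_b3 += f_b3 < 10
        assert strong_b2 >= 27  # ~F=37 on average
        assert weak_b3 >= 20  # ~F=2.7 on average

    def test_exposure_table_layout(self, two_biomarker_cohort):
        res = pleiotropy_matrix(two_biomarker_cohort.dosages, two_biomarker_cohort.biomarkers)
        tab = exposure_table(res.associations)
        assert list(tab.columns) == [
            "snp", "biomarker", "beta", "se", "ci_low", "ci_high", "p", "F",
            "r2_pct", "n", "transform",
        ]
        assert len(tab) == 4


class TestParameterRecovery:
    def test_mean_beta_unbiased(self, one_snp_config):
        betas = []
        for rep in range(200):
            cohort = simulate_cohort(one_snp_config, seed=40_000 + rep)
            a = exposure_regression(
                cohort.dosages["snp_iv"].to_numpy(), cohort.biomarkers["B2"].to_numpy()
            )
            betas.append(a.beta)
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - 94.78) < 2 * mc_se
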