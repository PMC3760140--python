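"""Per-subject logistic fits, the Laplace GLMM, and Wald contrasts."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import twostep as ts
from oracles import gh_marginal_loglik, logistic_mle
from twostep.hier_logit import (
    _N_RE,
    _N_THETA,
    build_design,
    intercept_only_deviance,
)

ZERO_THETA = np.concatenate([np.full(_N_RE, -8.0), np.zeros(_N_THETA - _N_RE)])


def _rows_from_coefs(coefs, n_rows, rng, subject="s001"):
    rew = np.where(rng.random(n_rows) < 0.5, 1, -1)
    trans = np.where(rng.random(n_rows) < 0.7, 1, -1)
    eta = coefs[0] + coefs[1] * trans + coefs[2] * rew + coefs[3] * trans * rew
    stay = (rng.random(n_rows) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame(
        {
            "subject_id": subject,
            "outcome_trial": np.arange(2, n_rows + 2),
            "stay": stay,
            "rew": rew,
            "trans": trans,
            "rewXtrans": rew * trans,
        }
    )


class TestBuildDesign:
    def test_base_terms_and_order(self):
        rows = _rows_from_coefs([0, 0, 0, 0], 50, np.random.default_rng(0))
        X, names = build_design(rows)
        assert names == ["Intercept", "trans", "rew", "trans:rew"]
        assert np.array_equal(X[:, 3], X[:, 1] * X[:, 2])

    def test_factorial_expansion_with_two_moderators(self):
        rows = _rows_from_coefs([0, 0, 0, 0], 30, np.random.default_rng(0))
        rows["a"] = np.linspace(-1, 1, 30)
        rows["b"] = np.linspace(1, -1, 30) ** 2
        X, names = build_design(rows, ("a", "b"))
        assert len(names) == 16
        assert names[4:8] == ["a", "trans:a", "rew:a", "trans:rew:a"]
        assert names[-1] == "trans:rew:a:b"
        k = names.index("rew:a:b")
        assert np.allclose(X[:, k], rows["rew"] * rows["a"] * rows["b"])

    def test_missing_moderator_column_rejected(self):
        rows = _rows_from_coefs([0, 0, 0, 0], 20, np.random.default_rng(0))
        with pytest.raises(ValueError, match="missing"):
            build_design(rows, ("nope",))


class TestSubjectLogistic:
    def test_recovers_known_coefficients_vs_generic_optimizer(self):
        rng = np.random.default_rng(42)
        truth = np.array([1.0, 0.0, 0.5, 0.3])
        rows = _rows_from_coefs(truth, 5000, rng)
        fit = ts.fit_subject_logistic(rows, ridge=1e-4)
        assert fit.converged
        assert np.abs(fit.coefs - truth).max() < 0.1
        # independent oracle: BFGS on the raw likelihood
        X, _ = build_design(rows)
        oracle = logistic_mle(X, rows["stay"].to_numpy(float))
        assert np.abs(fit.coefs - oracle).max() < 1e-3

    def test_null_data_gives_null_slopes(self):
        rng = np.random.default_rng(1)
        rows = _rows_from_coefs([0.4, 0, 0, 0], 8000, rng)
        fit = ts.fit_subject_logistic(rows)
        assert np.abs(fit.coefs[1:]).max() < 0.08

    def test_separation_kept_finite_by_ridge(self):
        rng = np.random.default_rng(2)
        rows = _rows_from_coefs([0, 0, 0, 0], 40, rng)
        rows["stay"] = (rows["rew"] == 1).astype(int)  # perfectly separated
        fit = ts.fit_subject_logistic(rows, ridge=1e-4)
        assert np.all(np.isfinite(fit.coefs))

    def test_deviance_nesting_inequality(self, null_rows):
        """Full-model deviance never exceeds the intercept-only deviance."""
        for _, sub in list(null_rows.groupby("subject_id"))[:20]:
            fit = ts.fit_subject_logistic(sub)
            dev0 = intercept_only_deviance(sub["stay"].to_numpy())
            assert fit.deviance <= dev0 + 1e-6

    def test_too_few_rows_rejected(self):
        rows = _rows_from_coefs([0, 0, 0, 0], 7, np.random.default_rng(0))
        with pytest.raises(ValueError, match="8 rows"):
            ts.fit_subject_logistic(rows)


class TestMultilevel:
    def test_zero_variance_limit_equals_pooled_fit(self):
        spec = ts.RegressionGenSpec(
            re_cov=tuple(map(tuple, (0.0 * np.eye(4)).tolist())),
            n_subjects=40, n_trials=200,
        )
        rows = ts.simulate_from_regression(spec, np.random.default_rng(7))
        fit = ts.fit_multilevel(rows, fix_theta=ZERO_THETA)
        X, _ = build_design(rows)
        pooled = logistic_mle(X, rows["stay"].to_numpy(float))
        assert np.abs(fit.beta - pooled).max() < 1e-3
        # the freely estimated fit lands close as well
        free = ts.fit_multilevel(rows)
        assert np.abs(free.beta - pooled).max() < 0.02

    def test_laplace_matches_quadrature_on_toy(self):
        """2 subjects x 40 trials: Laplace vs adaptive Gauss-Hermite.

        Both are evaluated at the same well-conditioned parameter point
        (the generating values); within the Laplace approximation's
        accurate regime the two must agree on the log scale.
        """
        from twostep.hier_logit import _LaplaceProblem

        sd = 0.15
        spec = ts.RegressionGenSpec(
            n_subjects=2, n_trials=41,
            re_cov=tuple(map(tuple, (sd * sd * np.eye(4)).tolist())),
        )
        rows = ts.simulate_from_regression(spec, np.random.default_rng(3))
        X, _ = build_design(rows)
        y = rows["stay"].to_numpy(float)
        groups = pd.factorize(rows["subject_id"], sort=True)[0]
        prob = _LaplaceProblem(X, y, groups)
        beta = np.array([1.0, 0.0, 0.198, 0.132])
        theta = np.concatenate([np.full(_N_RE, np.log(sd)), np.zeros(_N_THETA - _N_RE)])
        ll_laplace = -0.5 * prob.laplace_deviance(np.concatenate([beta, theta]))
        ll_gh = gh_marginal_loglik(X, y, groups, beta, sd * sd * np.eye(4))
        assert abs(ll_laplace - ll_gh) < 1e-2

    def test_agreement_with_lme4_glmer(self, tmp_path):
        """Same data, same model, independent implementation (R lme4)."""
        spec = ts.RegressionGenSpec(n_subjects=40, n_trials=120)
        rows = ts.simulate_from_regression(spec, np.random.default_rng(5))
        fit = ts.fit_multilevel(rows)
        csv = tmp_path / "rows.csv"
        out = tmp_path / "out.csv"
        rows.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(stay ~ trans*rew + (1 + trans*rew | subject_id),
                       data=d, family=binomial)
            res <- c(fixef(m), -2*as.numeric(logLik(m)))
            write.csv(data.frame(v=res), "{out}", row.names=FALSE)
        """)
        rpath = tmp_path / "check.R"
        rpath.write_text(script)
        subprocess.run(["Rscript", str(rpath)], check=True, capture_output=True)
        vals = pd.read_csv(out)["v"].to_numpy()
        assert np.abs(fit.beta - vals[:4]).max() < 0.01
        assert fit.deviance < vals[4] + 0.5

    def test_recovery_with_random_effects(self):
        spec = ts.RegressionGenSpec(n_subjects=60, n_trials=200)
        rows = ts.simulate_from_regression(spec, np.random.default_rng(17))
        fit = ts.fit_multilevel(rows)
        truth = {"Intercept": 1.0, "trans": 0.0, "rew": 0.198, "trans:rew": 0.132}
        for term, value in truth.items():
            est = fit[term]
            assert abs(est["estimate"] - value) < 3 * est["se"]
        sds = np.sqrt(np.diag(fit.re_cov))
        assert np.all(sds > 0.1) and np.all(sds < 0.6)  # truth 0.3

    def test_z_and_p_mutually_consistent(self, null_rows):
        fit = ts.fit_multilevel(null_rows)
        expected = 2 * (1 - stats.norm.cdf(np.abs(fit.zvalues)))
        assert np.allclose(fit.pvalues, expected, atol=1e-12)
        assert np.allclose(fit.zvalues, fit.beta / fit.se)

    def test_missing_covariates_rejected(self, null_rows):
        with pytest.raises(ValueError):
            ts.fit_multilevel(null_rows, moderators=("extraversion_z",))


@pytest.fixture(scope="module")
def fit(null_rows):
    return ts.fit_multilevel(null_rows)


class TestWaldContrast:
    def test_single_term_contrast_equals_squared_z(self, fit):
        c = np.zeros(len(fit.terms))
        c[2] = 1.0
        res = ts.wald_contrast(fit, c)
        assert res.chi_square == pytest.approx(fit.zvalues[2] ** 2, rel=1e-10)
        assert res.df == 1

    def test_dict_form_matches_vector_form(self, fit):
        res_d = ts.wald_contrast(fit, {"rew": 1.0, "trans:rew": -1.0})
        c = np.zeros(len(fit.terms))
        c[2], c[3] = 1.0, -1.0
        res_v = ts.wald_contrast(fit, c)
        assert res_d.chi_square == pytest.approx(res_v.chi_square)

    def test_zero_contrast_rejected(self, fit):
        with pytest.raises(ValueError, match="zero variance"):
            ts.wald_contrast(fit, np.zeros(len(fit.terms)))

    def test_difference_contrast_calibrated_under_null(self):
        """Equal true coefficients: the difference contrast rejects at ~5%."""
        spec = ts.RegressionGenSpec(
            fixed_coefs={"Intercept": 0.5, "rew": 0.15, "trans:rew": 0.15},
            re_cov=tuple(map(tuple, (0.04 * np.eye(4)).tolist())),
            n_subjects=40, n_trials=120,
        )
        ss = np.random.SeedSequence(77)
        rejections = 0
        n_rep = 40
        for child in ss.spawn(n_rep):
            rows = ts.simulate_from_regression(spec, np.random.default_rng(child))
            fit = ts.fit_multilevel(rows)
            res = ts.wald_contrast(fit, {"rew": 1.0, "trans:rew": -1.0})
            rejections += res.pvalue < 0.05
        # binomial(40, 0.05): reject if far outside the null band
        assert rejections <= 7
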