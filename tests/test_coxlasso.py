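"""Stratified Cox-LASSO: penalty limits, KKT optimality, oracle agreement,
cross-validation and bootstrap stability selection."""

import numpy as np
import pandas as pd
import pytest

from proteoage import CoxLassoSignature, ValidationError
from proteoage import SimulationConfig, simulate_cohort, validate_cohort

from conftest import make_survival_frame


@pytest.fixture(scope="module")
def fitted_small():
    X, t, e, s, sex = make_survival_frame(n=60, p=8, seed=0)
    model = CoxLassoSignature(X, t, e, s, unpenalized=sex)
    return model, model.fit(n_lambda=40)


class TestPenaltyLimits:
    def test_lambda_max_zeroes_every_protein(self, fitted_small):
        model, res = fitted_small
        assert (res.coef_path.iloc[:, 0] == 0.0).all()
        # just above lambda_max everything stays zero as well
        res_hi = model.fit(lambdas=np.array([model.lambda_max() * 10.0]))
        assert (res_hi.coef_path.to_numpy() == 0.0).all()

    def test_sex_matches_unpenalized_stratified_cox(self, fitted_small):
        from lifelines import CoxPHFitter

        model, res = fitted_small
        X, t, e, s, sex = make_survival_frame(n=60, p=8, seed=0)
        df = pd.DataFrame({"t": t, "e": e, "sex": sex["sex_male"], "s": s})
        cph = CoxPHFitter().fit(df, "t", "e", strata=["s"], formula="sex")
        assert res.gamma_path.iloc[0, 0] == pytest.approx(
            cph.params_.iloc[0], abs=1e-3
        )

    def test_no_events_rejected(self):
        X, t, e, s, sex = make_survival_frame(n=20, p=3, seed=1)
        with pytest.raises(ValidationError):
            CoxLassoSignature(X, t, np.zeros_like(e), s, unpenalized=sex)


class TestUnpenalizedLimit:
    def test_tiny_dataset_matches_direct_likelihood_maximization(self):
        """lambda -> 0 with one binary covariate, 4 subjects, no ties: the
        coefficient must solve the partial-likelihood score equation,
        checked against direct numeric maximization of the likelihood
        written out risk set by risk set."""
        from scipy.optimize import minimize_scalar

        x = np.array([1.0, 0.0, 1.0, 0.0])
        times = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 0])

        def neg_partial_loglik(beta):
            ll = 0.0
            for i in range(4):
                if event[i]:
                    risk = times >= times[i]
                    ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
            return -ll

        direct = minimize_scalar(neg_partial_loglik, bounds=(-5, 5),
                                 method="bounded").x
        model = CoxLassoSignature(
            pd.DataFrame({"P00001": x}), times, event,
            np.array(["A"] * 4), standardize=False,
        )
        res = model.fit(lambdas=np.array([1e-9]))
        assert res.coef_path.iloc[0, 0] == pytest.approx(direct, abs=1e-5)


class TestKKT:
    def test_no_violations_along_the_path(self, fitted_small):
        model, res = fitted_small
        for i, lam in enumerate(res.lambdas):
            beta = res.coef_path.iloc[:, i].to_numpy()
            gamma = res.gamma_path.iloc[:, i].to_numpy()
            assert model.kkt_violations(beta, gamma, lam, tol=1e-5) == 0

    def test_violations_detected_for_wrong_coefficients(self, fitted_small):
        model, res = fitted_small
        lam = res.lambdas[-1]
        wrong = res.coef_path.iloc[:, -1].to_numpy() + 0.5
        gamma = res.gamma_path.iloc[:, -1].to_numpy()
        assert model.kkt_violations(wrong, gamma, lam) > 0


class TestPathOracle:
    def test_matches_reference_coxnet_single_stratum(self):
        """Single stratum, no unpenalized covariate: the whole path must
        agree with an independent glmnet-style implementation."""
        from sksurv.linear_model import CoxnetSurvivalAnalysis

        rng = np.random.default_rng(42)
        n, p = 20, 5
        X = pd.DataFrame(
            rng.normal(size=(n, p)), columns=[f"P{j:05d}" for j in range(1, p + 1)]
        )
        lp = X.iloc[:, 0] * 0.8
        t = rng.exponential(1 / (0.2 * np.exp(lp)))
        e = (t < 6).astype(int)
        t = np.minimum(t, 6.0)
        model = CoxLassoSignature(
            X, t, e, np.array(["A"] * n), standardize=False
        )
        lambdas = model.lambda_grid(n_lambda=20, min_ratio=0.05)
        ours = model.fit(lambdas=lambdas).coef_path.to_numpy()
        y = np.array(
            [(bool(ev), tt) for ev, tt in zip(e, t)],
            dtype=[("event", "?"), ("time", "<f8")],
        )
        ref = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=lambdas, normalize=False, tol=1e-9,
            fit_baseline_model=False,
        ).fit(X.to_numpy(), y)
        assert np.abs(ours - ref.coef_).max() < 1e-4

    def test_stratification_invariance(self):
        """Duplicating every subject into a second identical stratum leaves
        the coefficient path unchanged."""
        X, t, e, s, sex = make_survival_frame(n=40, p=5, seed=3)
        single = CoxLassoSignature(X, t, e, np.array(["A"] * 40), unpenalized=sex,
                                   standardize=False)
        lambdas = single.lambda_grid(n_lambda=15)
        res1 = single.fit(lambdas=lambdas)
        X2 = pd.concat([X, X], ignore_index=True)
        sex2 = pd.concat([sex, sex], ignore_index=True)
        doubled = CoxLassoSignature(
            X2,
            np.concatenate([t, t]),
            np.concatenate([e, e]),
            np.array(["A"] * 40 + ["B"] * 40),
            unpenalized=sex2,
            standardize=False,
        )
        res2 = doubled.fit(lambdas=lambdas)
        assert np.allclose(
            res1.coef_path.to_numpy(), res2.coef_path.to_numpy(), atol=1e-6
        )


class TestCrossValidation:
    def test_fixed_seed_is_reproducible(self, fitted_small):
        model, _ = fitted_small
        cv1 = model.cross_validate(n_folds=5, seed=4, n_lambda=20)
        cv2 = model.cross_validate(n_folds=5, seed=4, n_lambda=20)
        pd.testing.assert_frame_equal(cv1.cv_table, cv2.cv_table)
        assert cv1.lambda_min == cv2.lambda_min

    def test_planted_signal_selected(self):
        X, t, e, s, sex = make_survival_frame(n=104, p=12, beta=(1.0, 1.0), seed=6)
        model = CoxLassoSignature(X, t, e, s, unpenalized=sex)
        cv = model.cross_validate(n_folds=10, seed=0, n_lambda=50)
        assert {"P00001", "P00002"} <= cv.selected("lambda_min")

    def test_one_se_rule_is_sparser(self, fitted_small):
        model, _ = fitted_small
        cv = model.cross_validate(n_folds=5, seed=2, n_lambda=30)
        assert cv.lambda_1se >= cv.lambda_min
        assert len(cv.selected("lambda_1se")) <= len(cv.selected("lambda_min"))

    def test_null_proteins_rarely_selected(self):
        sizes = []
        for seed in range(5):
            X, t, e, s, sex = make_survival_frame(
                n=60, p=10, beta=(), seed=seed, rate=0.15
            )
            model = CoxLassoSignature(X, t, e, s, unpenalized=sex)
            cv = model.cross_validate(n_folds=5, seed=seed, n_lambda=30)
            sizes.append(len(cv.selected("lambda_min")))
        assert np.median(sizes) <= 2


class TestBootstrap:
    def test_planted_protein_has_high_selection_frequency(self):
        X, t, e, s, sex = make_survival_frame(n=80, p=8, beta=(1.2,), seed=9)
        model = CoxLassoSignature(X, t, e, s, unpenalized=sex)
        boot = model.bootstrap_stability(
            n_bootstrap=20, n_folds=5, n_lambda=30, seed=1
        )
        assert boot.frequencies["P00001"] >= 0.9
        # the planted protein outranks every null protein; null proteins do
        # enter individual resamples (CV-min over-selects), so only the
        # ranking is a stable property at this scale
        assert (boot.frequencies["P00001"] > boot.frequencies.drop("P00001")).all()
        assert "P00001" in boot.robust

    def test_threshold_one_means_selected_in_every_resample(self):
        X, t, e, s, sex = make_survival_frame(n=60, p=5, beta=(1.5,), seed=2)
        model = CoxLassoSignature(X, t, e, s, unpenalized=sex)
        boot = model.bootstrap_stability(
            n_bootstrap=10, threshold=1.0, n_folds=5, n_lambda=20, seed=3
        )
        assert boot.robust == set(
            boot.frequencies.index[boot.frequencies == 1.0]
        )

    def test_invalid_threshold_rejected(self, fitted_small):
        model, _ = fitted_small
        with pytest.raises(ValidationError):
            model.bootstrap_stability(n_bootstrap=1, threshold=0.0)


class TestFromCohort:
    def test_young_controls_excluded(self):
        cfg = SimulationConfig(n_proteins=30, seed=13)
        matrix, cohort, truth = simulate_cohort(cfg)
        cohort = validate_cohort(cohort)
        model = CoxLassoSignature.from_cohort(matrix, cohort)
        assert model.n == 104  # 52 + 52 older participants only
        assert set(np.unique(model.strata)) == {"OC", "OP"}
        assert model.unpenalized_names == ["sex_male"]
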