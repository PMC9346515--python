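import copy
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from helpers import dense_grid_joint_loglik
from natprog.jointmodel import (
    JointModelError,
    JointModelFit,
    JointModelSpec,
    _blocks,
    fit_joint,
    fit_lmm,
    joint_loglik,
    predict_band,
    simulate_outcome_paths,
)
from natprog.simulate import mutant_config, simulate_cohort


@pytest.fixture(scope="module")
def fitted_joint(recovery_config):
    cohort = simulate_cohort(replace(recovery_config, n_mice=150, seed=77),
                             with_muscle=False)
    return cohort, fit_joint(cohort)


class TestFitLmm:
    def test_noiseless_limit_equals_ols(self):
        """With vanishing residual and random-effect variance the fixed
        effects coincide with OLS on (1, sqrt(week))."""
        cfg = mutant_config(
            n_mice=30,
            seed=3,
            sigma_e=1e-5,
            re_cov=((1e-12, 0.0), (0.0, 1e-12)),
            haz_scale=1e9,
            decline_loss_mean=0.0,
            decline_loss_sd=0.0,
        )
        cohort = simulate_cohort(cfg, with_muscle=False)
        fit = fit_lmm(cohort)
        w = cohort.observations["week"].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(w), np.sqrt(w)])
        y = np.log(cohort.observations["body_weight"].to_numpy(dtype=float))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)

    def test_matches_statsmodels_mixedlm(self, recovery_config):
        """Cross-check the closed-form marginal ML against an independent
        mixed-model implementation on a no-dropout panel."""
        import statsmodels.formula.api as smf

        cfg = replace(recovery_config, n_mice=80, seed=12, haz_scale=1e9)
        cohort = simulate_cohort(cfg, with_muscle=False)
        fit = fit_lmm(cohort)

        df = cohort.observations.assign(
            y=np.log(cohort.observations["body_weight"]),
            sw=np.sqrt(cohort.observations["week"]),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = smf.mixedlm(
                "y ~ sw", df, groups=df["mouse_id"], re_formula="~sw"
            ).fit(reml=False)
        np.testing.assert_allclose(
            fit.beta, [sm_fit.params["Intercept"], sm_fit.params["sw"]], atol=2e-4
        )
        assert fit.sigma_e**2 == pytest.approx(sm_fit.scale, rel=0.02)
        sm_G = sm_fit.cov_re.to_numpy()
        np.testing.assert_allclose(np.diag(fit.G), np.diag(sm_G), rtol=0.05,
                                   atol=1e-6)

    def test_parameter_recovery_on_balanced_panel(self, recovery_config):
        """Immortal 200-mouse panel over the full week range recovers
        (beta, G diagonal, sigma) within 3 Monte-Carlo SEs over replicates."""
        reps = []
        for s in range(8):
            cfg = replace(recovery_config, seed=400 + s, haz_scale=1e9)
            cohort = simulate_cohort(cfg, with_muscle=False)
            fit = fit_lmm(cohort)
            reps.append(
                [fit.beta[0], fit.beta[1], fit.sigma_e, fit.G[0, 0], fit.G[1, 1]]
            )
        est = np.array(reps)
        truth = np.array(
            [recovery_config.beta0, recovery_config.beta1,
             recovery_config.sigma_e, 0.08**2, 0.025**2]
        )
        bias = est.mean(axis=0) - truth
        se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert (np.abs(bias) < 3 * se).all()

    def test_duplicating_every_mouse_leaves_estimates_unchanged(
        self, recovery_config
    ):
        cfg = replace(recovery_config, n_mice=40, seed=21)
        cohort = simulate_cohort(cfg, with_muscle=False)
        fit1 = fit_lmm(cohort)

        cohort2 = copy.copy(cohort)
        clone = lambda df: pd.concat(  # noqa: E731
            [df, df.assign(mouse_id=df["mouse_id"] + "-dup")], ignore_index=True
        )
        cohort2.mice = clone(cohort.mice)
        cohort2.observations = clone(cohort.observations)
        cohort2.survival = clone(cohort.survival)
        cohort2.muscle = None
        fit2 = fit_lmm(cohort2)
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=2e-4)
        np.testing.assert_allclose(fit1.sigma_e, fit2.sigma_e, atol=1e-4)

    def test_single_week_design_rejected(self):
        from natprog.cohort import CohortDataset

        obs = pd.DataFrame(
            {
                "mouse_id": ["a", "b", "a", "b"][:2] * 1 + ["a", "b"],
                "week": [3, 3, 3, 3],
                "body_weight": [10.0, 11.0, 10.5, 11.5],
                "hang1": 50.0, "hang2": 50.0, "hang3": 50.0,
                "kyphosis": 0.0, "walking": 0.0, "ptosis": 0.0, "breathing": 0.0,
            }
        ).drop_duplicates(subset=["mouse_id", "week"])
        cohort = CohortDataset(
            mice=pd.DataFrame(
                {"mouse_id": ["a", "b"], "genotype": "mutant", "arm": "untreated",
                 "treatment_start_week": np.nan}
            ),
            observations=obs,
            survival=pd.DataFrame(
                {"mouse_id": ["a", "b"], "time": [4.0, 4.0], "event": [1, 1]}
            ),
        )
        with pytest.raises(JointModelError):
            fit_lmm(cohort)


class TestJointLikelihood:
    def test_quadrature_matches_dense_grid_oracle(self, recovery_config):
        """Gauss-Hermite joint log-likelihood vs brute-force 2-D trapezoid
        integration on a 5-mouse cohort, at two parameter settings."""
        cfg = replace(recovery_config, n_mice=5, seed=55)
        cohort = simulate_cohort(cfg, with_muscle=False)
        spec = JointModelSpec()
        blocks = _blocks(cohort, spec)
        for params in (
            dict(beta=[cfg.beta0, cfg.beta1], G=np.array(cfg.re_cov),
                 sigma=cfg.sigma_e, lam=cfg.haz_scale, k=cfg.haz_shape,
                 alpha=cfg.assoc),
            dict(beta=[2.0, 0.22], G=np.array([[0.01, 0.0005], [0.0005, 0.0009]]),
                 sigma=0.05, lam=2.5, k=3.0, alpha=-1.0),
        ):
            fit = JointModelFit(
                outcome="log_weight", beta=np.asarray(params["beta"]),
                G=params["G"], sigma_e=params["sigma"],
                haz_scale=params["lam"], haz_shape=params["k"],
                alpha=params["alpha"], loglik=np.nan, converged=True,
                n_mice=5, n_obs=len(cohort.observations), spec=spec,
            )
            gh = joint_loglik(cohort, fit)
            brute = dense_grid_joint_loglik(blocks, **params)
            assert gh == pytest.approx(brute, abs=1e-4)

    def test_quadrature_converged_at_default_order(self, fitted_joint):
        cohort, fit = fitted_joint
        ll9 = joint_loglik(cohort, fit)
        ll15 = joint_loglik(cohort, fit, spec=replace(fit.spec,
                                                      quadrature_points=15))
        assert abs(ll9 - ll15) < 1e-3

    def test_optimum_improves_on_initializer(self, fitted_joint):
        """The joint optimum's log-likelihood is at least the value at the
        fit_lmm + marginal-Weibull starting point."""
        cohort, fit = fitted_joint
        lmm = fit_lmm(cohort)
        start = JointModelFit(
            outcome="log_weight", beta=lmm.beta, G=lmm.G, sigma_e=lmm.sigma_e,
            haz_scale=2.0, haz_shape=3.0, alpha=0.0, loglik=np.nan,
            converged=True, n_mice=lmm.n_mice, n_obs=lmm.n_obs, spec=fit.spec,
        )
        assert fit.loglik >= joint_loglik(cohort, start) - 1e-6

    def test_no_events_rejected(self, recovery_config):
        cfg = replace(recovery_config, n_mice=10, seed=2, haz_scale=1e9)
        cohort = simulate_cohort(cfg, with_muscle=False)
        with pytest.raises(JointModelError):
            fit_joint(cohort)

    def test_alpha_decouples_when_zero(self, recovery_config):
        """Data generated with alpha = 0: the joint fit agrees with the
        standalone mixed model and the fitted alpha stays near 0."""
        cfg = replace(recovery_config, n_mice=150, seed=81, assoc=0.0)
        cohort = simulate_cohort(cfg, with_muscle=False)
        lmm = fit_lmm(cohort)
        joint = fit_joint(cohort)
        np.testing.assert_allclose(joint.beta, lmm.beta, atol=2e-2)
        assert joint.sigma_e == pytest.approx(lmm.sigma_e, rel=0.05)
        assert abs(joint.alpha) < 1.0


class TestPredictBand:
    def test_level_zero_collapses_to_median(self, fitted_joint):
        _, fit = fitted_joint
        band = predict_band(fit, np.arange(3, 8), level=0.0, n_sim=500, seed=4)
        np.testing.assert_allclose(band.lower, band.median)
        np.testing.assert_allclose(band.upper, band.median)

    def test_bands_nested_in_level(self, fitted_joint):
        _, fit = fitted_joint
        narrow = predict_band(fit, np.arange(3, 8), level=0.5, n_sim=2000, seed=4)
        wide = predict_band(fit, np.arange(3, 8), level=0.95, n_sim=2000, seed=4)
        assert (wide.lower <= narrow.lower).all()
        assert (narrow.upper <= wide.upper).all()

    def test_band_ordering_and_determinism(self, fitted_joint):
        _, fit = fitted_joint
        b1 = predict_band(fit, np.arange(3, 9), n_sim=1000, seed=9)
        b2 = predict_band(fit, np.arange(3, 9), n_sim=1000, seed=9)
        assert (b1.lower <= b1.median).all() and (b1.median <= b1.upper).all()
        np.testing.assert_array_equal(b1.lower, b2.lower)
        np.testing.assert_array_equal(b1.upper, b2.upper)

    def test_median_weight_profile_increasing_without_association(
        self, recovery_config
    ):
        """beta1 > 0 and alpha = 0: the median back-transformed weight
        profile is strictly increasing in week."""
        fit = JointModelFit(
            outcome="log_weight", beta=np.array([2.0, 0.2]),
            G=np.array([[0.0064, 0.0], [0.0, 0.000625]]), sigma_e=0.045,
            haz_scale=3.0, haz_shape=4.0, alpha=0.0, loglik=0.0, converged=True,
            n_mice=1, n_obs=1, spec=JointModelSpec(),
        )
        band = predict_band(fit, np.arange(3, 13), n_sim=4000, seed=6,
                            conditional=False)
        assert (np.diff(band.median) > 0).all()

    def test_dss_band_clamped_to_score_range(self, recovery_config):
        cohort = simulate_cohort(
            mutant_config(n_mice=58, seed=300), with_muscle=False
        )
        fit = fit_joint(cohort, JointModelSpec(outcome="dss"))
        band = predict_band(fit, np.arange(3, 13), n_sim=1000, seed=3,
                            conditional=False)
        assert (band.lower >= 0).all() and (band.upper <= 5).all()

    def test_weight_band_ceiling_under_calibrated_generator(self):
        """The generator is calibrated so mutant weights never reach 20 g;
        the fitted, extrapolated band inherits that ceiling."""
        from natprog.jointmodel import band_from_reference

        cohort = simulate_cohort(mutant_config(n_mice=58, seed=42),
                                 with_muscle=False)
        _, band = band_from_reference(
            cohort, outcome="log_weight", extrapolate_to=12, n_sim=3000, seed=2,
            conditional=False,
        )
        assert band.upper.max() < 20.0

    def test_composition_identity_without_extrapolation(self, fitted_joint):
        from natprog.jointmodel import band_from_reference

        cohort, fit = fitted_joint
        last = int(cohort.observations["week"].max())
        _, band = band_from_reference(
            cohort, outcome="log_weight", extrapolate_to=last, n_sim=800, seed=10,
            conditional=False,
        )
        direct = predict_band(fit, np.arange(3, last + 1), n_sim=800, seed=10,
                              conditional=False)
        np.testing.assert_allclose(band.median, direct.median)
        np.testing.assert_allclose(band.upper, direct.upper)

    def test_truncation_when_survivors_run_out(self):
        cohort = simulate_cohort(mutant_config(n_mice=100, seed=71),
                                 with_muscle=False)
        fit = fit_joint(cohort)
        with pytest.warns(UserWarning, match="truncated"):
            band = predict_band(fit, np.arange(3, 13), n_sim=500, seed=1)
        assert band.weeks[-1] < 12


class TestSerialization:
    def test_fit_round_trip(self, fitted_joint, tmp_path):
        _, fit = fitted_joint
        path = tmp_path / "fit.json"
        fit.write(path)
        back = JointModelFit.read(path)
        np.testing.assert_allclose(back.beta, fit.beta)
        np.testing.assert_allclose(back.G, fit.G)
        assert back.haz_scale == pytest.approx(fit.haz_scale)
        assert back.spec.outcome == fit.spec.outcome

        band1 = predict_band(fit, np.arange(3, 8), n_sim=300, seed=2)
        band2 = predict_band(back, np.arange(3, 8), n_sim=300, seed=2)
        np.testing.assert_allclose(band1.median, band2.median)
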