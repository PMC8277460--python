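"""Weighted least-squares fitting, the baseline prior, and imputation."""

import numpy as np
import pytest

from lactokin.estimation import (
    bayesian_baseline_prior,
    fit_macro,
    fit_micro,
    kinetic_impute,
    weighted_objective,
)
from lactokin.exceptions import InsufficientDataError
from lactokin.synthetic import StudyDesign, generate_horse


class TestBaselinePrior:
    def test_sem_arithmetic(self):
        # SEM of (0.3, 0.4): sample SD (ddof=1) 0.0707 over sqrt(2)
        prior = bayesian_baseline_prior([0.3, 0.4])
        assert prior.mean == pytest.approx(0.35)
        assert prior.sd == pytest.approx(0.05, rel=1e-12)
        assert prior.n_obs == 2

    def test_degenerate_replicates_floored_and_flagged(self):
        prior = bayesian_baseline_prior([0.357] * 13)
        assert prior.mean == pytest.approx(0.357)
        assert prior.sd > 0
        assert prior.degenerate

    def test_single_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            bayesian_baseline_prior([0.4])


class TestWeightedObjective:
    def test_zero_at_generating_parameters(self, clean_unit_dataset, horse5_unit):
        prior = bayesian_baseline_prior(clean_unit_dataset.pre_concentrations)
        assert weighted_objective(
            horse5_unit, clean_unit_dataset, prior
        ) == pytest.approx(0.0, abs=1e-18)

    def test_quadratic_in_residual_scale(self, clean_unit_dataset, horse5_unit):
        """Doubling the model-data discrepancy quadruples the data term."""
        from dataclasses import replace

        p1 = replace(horse5_unit, baseline=horse5_unit.baseline + 0.01)
        p2 = replace(horse5_unit, baseline=horse5_unit.baseline + 0.02)
        o1 = weighted_objective(p1, clean_unit_dataset, prior=None)
        o2 = weighted_objective(p2, clean_unit_dataset, prior=None)
        assert o2 == pytest.approx(4.0 * o1, rel=1e-6)


class TestFitMicro:
    def test_prior_limits(self, noisy_unit_dataset):
        """Tight prior pins the baseline; loose prior matches the
        unpenalized fit."""
        from lactokin.estimation import BaselinePrior

        tight = BaselinePrior(mean=0.40, sd=1e-7, n_obs=13)
        loose = BaselinePrior(mean=0.40, sd=1e4, n_obs=13)
        f_tight = fit_micro(noisy_unit_dataset, "U", prior=tight)
        f_loose = fit_micro(noisy_unit_dataset, "U", prior=loose)
        f_free = fit_micro(noisy_unit_dataset, "U", use_prior=False)
        assert f_tight.estimates["P1"] == pytest.approx(0.40, abs=1e-4)
        assert f_loose.estimates["P1"] == pytest.approx(
            f_free.estimates["P1"], abs=1e-4
        )

    def test_start_at_truth_converges_immediately(
        self, clean_unit_dataset, horse5_unit
    ):
        init = {
            "P1": 0.357, "P2": 0.215, "L01": 0.070, "L21": 0.209, "L12": 0.137,
        }
        fit = fit_micro(clean_unit_dataset, "U", init=init)
        assert fit.converged
        assert fit.objective == pytest.approx(0.0, abs=1e-12)

    def test_s_and_u_fits_equivalent(self, noisy_unit_dataset):
        """Fitting the same physical data in S or U units gives identical
        fractional rates and predictions (K1 = 1/(P2 * weight))."""
        f_s = fit_micro(noisy_unit_dataset, "S")
        f_u = fit_micro(noisy_unit_dataset, "U")
        for k in ("L01", "L21", "L12"):
            assert abs(f_s.estimates[k] - f_u.estimates[k]) < 1e-6
        assert f_s.estimates["K1"] == pytest.approx(
            1.0 / (f_u.estimates["P2"] * noisy_unit_dataset.body_weight), rel=1e-5
        )
        t = np.linspace(1.0, 200.0, 50)
        assert np.abs(f_s.predict(t) - f_u.predict(t)).max() < 1e-6

    def test_covariance_symmetric_psd(self, noisy_unit_dataset):
        fit = fit_micro(noisy_unit_dataset, "U")
        cov = fit.covariance.to_numpy()
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-12)

    def test_report_frame_layout(self, clean_unit_dataset):
        frame = fit_micro(clean_unit_dataset, "U").report_frame()
        assert list(frame.columns) == ["parameter", "value", "error", "cv_percent"]
        assert set(frame["parameter"]) == {"P1", "P2", "L01", "L21", "L12"}


class TestFitMacro:
    def test_noise_free_recovery(self, macro_decay_dataset):
        fit = fit_macro(macro_decay_dataset)
        assert fit.estimates["A"] == pytest.approx(0.698, rel=1e-3)
        assert fit.estimates["alpha"] == pytest.approx(0.202, rel=1e-3)
        assert fit.estimates["B"] == pytest.approx(1.337, rel=1e-3)
        assert fit.estimates["beta"] == pytest.approx(0.011, rel=1e-3)

    def test_alpha_always_faster_than_beta(self, macro_decay_dataset):
        fit = fit_macro(macro_decay_dataset, init={"alpha": 0.005, "beta": 0.3})
        assert fit.estimates["alpha"] > fit.estimates["beta"]

    def test_single_exponential_flagged_degenerate(self):
        from lactokin.estimation import KineticDataset
        from lactokin.infusion import rectangular_infusion

        t_post = 15.0 + np.linspace(1, 200, 20)
        conc = np.concatenate(
            [np.full(13, 0.4), np.full(5, 1.0), 1.2 * np.exp(-0.05 * (t_post - 15)) + 0.4]
        )
        times = np.concatenate([-2.0 * np.arange(13, 0, -1), [3, 6, 9, 12, 15], t_post])
        phase = np.array(["pre"] * 13 + ["infusion"] * 5 + ["post"] * 20, dtype=object)
        ds = KineticDataset(
            times=times, concentrations=conc, phase=phase, body_weight=480.0,
            protocol=rectangular_infusion(1.0, 15.0, "U", 480.0),
        )
        with pytest.warns(RuntimeWarning, match="degenerate"):
            fit = fit_macro(ds)
        assert fit.degenerate

    def test_too_few_points_rejected(self, macro_decay_dataset):
        from lactokin.estimation import KineticDataset

        keep = np.concatenate([np.arange(18), [20, 21, 22]])
        ds = KineticDataset(
            times=macro_decay_dataset.times[keep],
            concentrations=macro_decay_dataset.concentrations[keep],
            phase=macro_decay_dataset.phase[keep],
            body_weight=480.0,
            protocol=macro_decay_dataset.protocol,
        )
        with pytest.raises(InsufficientDataError):
            fit_macro(ds)


class TestKineticImpute:
    def test_reproduces_fitted_curve(self, macro_decay_dataset):
        fit = fit_macro(macro_decay_dataset)
        t_rel = macro_decay_dataset.times[macro_decay_dataset.phase == "post"] - 15.0
        imputed = kinetic_impute(fit, t_rel)
        obs = macro_decay_dataset.concentrations[macro_decay_dataset.phase == "post"]
        assert np.abs(imputed["lactate_mmol_L"].to_numpy() - obs).max() < 1e-4
        assert imputed["imputed"].all()

    def test_extrapolation_warns(self, macro_decay_dataset):
        fit = fit_macro(macro_decay_dataset)
        with pytest.warns(RuntimeWarning, match="extrapolation"):
            kinetic_impute(fit, [900.0], span=(0.0, 300.0))

    def test_horse1_prediction_at_60(self):
        """Direct evaluation of the printed horse-1 constants at t'=60."""
        from lactokin.model import MacroParams, analytic_bolus_solution

        macro = MacroParams(A=0.694, alpha=0.247, B=1.492, beta=0.008)
        expected = 0.694 * np.exp(-14.82) + 1.492 * np.exp(-0.48)
        assert analytic_bolus_solution(macro, 60.0) == pytest.approx(expected, rel=1e-12)

    def test_imputed_refit_leaves_noise_free_estimates_unchanged(self, horse5_unit):
        """Adding macro-imputed midpoints to a noise-free dataset must not
        move the micro estimates (the imputed points lie on the same curve)."""
        design = StudyDesign(noise_cv=0.0, body_weight=480.0, seed=2)
        ds = generate_horse(horse5_unit, design, "U")
        base = fit_micro(ds, "U")
        post_t = ds.times[ds.phase == "post"]
        mids = (post_t[:-1] + post_t[1:]) / 2.0
        # noise-free data: imputing from the micro fit itself is exact
        extra_conc = base.predict(mids)
        import pandas as pd

        from lactokin.estimation import KineticDataset

        frame = pd.DataFrame(
            {
                "t": np.concatenate([ds.times, mids]),
                "c": np.concatenate([ds.concentrations, extra_conc]),
                "p": np.concatenate([ds.phase, np.array(["post"] * len(mids), dtype=object)]),
            }
        ).sort_values("t")
        aug = KineticDataset(
            times=frame["t"].to_numpy(),
            concentrations=frame["c"].to_numpy(),
            phase=frame["p"].to_numpy(),
            body_weight=ds.body_weight,
            protocol=ds.protocol,
        )
        refit = fit_micro(aug, "U")
        for k, v in base.estimates.items():
            assert refit.estimates[k] == pytest.approx(v, rel=1e-4)
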