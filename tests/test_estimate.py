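import shutil
import subprocess

import numpy as np
import pytest

from growthmc.design import (
    ICC_SET_1,
    DesignCondition,
    DesignError,
    FixedEffects,
    GenerationParams,
    VarianceComponents,
    default_variance_components,
)
from growthmc.estimate import (
    ConvergenceStatus,
    FitOptions,
    ModelSpec,
    build_group_covariance,
    classify_convergence,
    fit_ml,
    profile_loglik,
)
from growthmc.oracle import dense_loglik
from growthmc.simulate import LongDataset, generate_dataset, write_csv

SPEC = ModelSpec()


def _random_params(rng) -> GenerationParams:
    vc = VarianceComponents(
        sigma2_e=rng.uniform(0.5, 3.0),
        sigma2_r0=rng.uniform(0.2, 3.0),
        sigma2_r1=rng.uniform(0.05, 1.0),
        sigma2_u00=rng.uniform(0.05, 1.0),
        sigma2_u01=rng.uniform(0.02, 0.5),
        sigma2_u10=rng.uniform(0.02, 0.5),
        sigma2_u11=rng.uniform(0.02, 0.5),
    )
    return GenerationParams(variances=vc)


class TestGroupCovariance:
    def test_pure_residual_noise_gives_scaled_identity(self):
        vc = VarianceComponents(sigma2_e=2.0)
        V = build_group_covariance(vc, x=[0.3, -1.2], n_timepoints=4)
        assert np.allclose(V, 2.0 * np.eye(8))

    def test_single_individual_intercept_structure(self):
        vc = VarianceComponents(sigma2_r0=1.0)
        V = build_group_covariance(vc, x=[0.7], n_timepoints=4)
        assert np.allclose(V, np.ones((4, 4)))

    def test_matches_monte_carlo_covariance(self, rng):
        """Entrywise agreement with brute-force simulation of the model."""
        params = _random_params(rng)
        vc = params.variances
        x = np.array([0.8, -0.5])
        T, n_rep = 4, 200_000
        t = np.tile(np.arange(T), 2)
        xs = np.repeat(x, T)
        u = rng.standard_normal((n_rep, 4)) * np.sqrt(
            [vc.sigma2_u00, vc.sigma2_u01, vc.sigma2_u10, vc.sigma2_u11]
        )
        r = rng.standard_normal((n_rep, 2, 2)) * np.sqrt(
            [vc.sigma2_r0, vc.sigma2_r1]
        )
        e = rng.standard_normal((n_rep, 2 * T)) * np.sqrt(vc.sigma2_e)
        r_obs = np.repeat(r, T, axis=1).reshape(n_rep, 2 * T, 2)
        y = (
            u[:, [0]] + u[:, [1]] * xs
            + (u[:, [2]] + u[:, [3]] * xs) * t
            + r_obs[:, :, 0] + r_obs[:, :, 1] * t
            + e
        )
        emp = np.cov(y, rowvar=False)
        V = build_group_covariance(vc, x=x, n_timepoints=T)
        scale = np.sqrt(np.outer(np.diag(V), np.diag(V))).max()
        assert np.allclose(emp, V, atol=4.5 * scale / np.sqrt(n_rep) * 3)


class TestProfileLoglik:
    def test_agrees_with_dense_oracle_on_random_datasets(self):
        """Profiled block likelihood == dense MVN density at the GLS fit."""
        rng = np.random.default_rng(31)
        for k in range(20):
            params = _random_params(rng)
            cond = DesignCondition(
                n_groups=int(rng.integers(2, 5)),
                group_size_range=(2, 4),
                icc_spec=ICC_SET_1,
            )
            ds = generate_dataset(
                params.fixed, params.variances, cond, seed=1000 + k
            )
            theta = SPEC.pack(params.variances)
            ll, gamma, _ = profile_loglik(theta, ds)
            ref = dense_loglik(ds, gamma, params.variances)
            assert ll == pytest.approx(ref, rel=1e-8)

    def test_reduces_to_pooled_ols_normal_likelihood(self):
        cond = DesignCondition(10, (3, 6), ICC_SET_1)
        ds = generate_dataset(
            FixedEffects(), VarianceComponents(sigma2_e=1.7), cond, seed=6
        )
        d = ds.data
        X = np.column_stack(
            [np.ones(len(d)), d.z, d.x, d.time, d.time * d.z, d.time * d.x]
        )
        beta, *_ = np.linalg.lstsq(X, d.y.to_numpy(), rcond=None)
        resid = d.y.to_numpy() - X @ beta
        s2 = 1.7
        expected = -0.5 * (
            len(d) * np.log(2 * np.pi * s2) + (resid**2).sum() / s2
        )
        theta = np.array([s2, 0, 0, 0, 0, 0, 0], dtype=float)
        ll, gamma, _ = profile_loglik(theta, ds)
        assert gamma == pytest.approx(beta, rel=1e-8)
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_invariant_to_group_permutation(self, icc1_params):
        cond = DesignCondition(6, (2, 4), ICC_SET_1)
        ds = generate_dataset(
            icc1_params.fixed, icc1_params.variances, cond, seed=44
        )
        theta = SPEC.pack(icc1_params.variances)
        ll, *_ = profile_loglik(theta, ds)
        relabel = {g: 10 - g for g in ds.data.group_id.unique()}
        shuffled = ds.data.assign(group_id=ds.data.group_id.map(relabel))
        ds2 = LongDataset(shuffled, ds.n_timepoints)
        ll2, *_ = profile_loglik(theta, ds2)
        assert ll == pytest.approx(ll2, rel=1e-12)

    def test_infeasible_theta_raises(self, small_dataset):
        theta = np.array([-1.0, 0, 0, 0, 0, 0, 0], dtype=float)
        with pytest.raises(DesignError):
            profile_loglik(theta, small_dataset)


class TestFitML:
    def test_recovers_generating_parameters_at_large_j(self, icc1_params):
        cond = DesignCondition(1000, (5, 15), ICC_SET_1, base_seed=0)
        ds = generate_dataset(
            icc1_params.fixed, icc1_params.variances, cond, seed=314
        )
        fit = fit_ml(ds)
        assert fit.converged
        truth = icc1_params.true_values()
        for name, est in fit.fixed_effects.items():
            se = fit.std_errors[name]
            assert abs(est - truth[name]) < 3 * se, name

    def test_matches_ols_when_random_effects_absent(self):
        cond = DesignCondition(100, (8, 12), ICC_SET_1, base_seed=0)
        vc = VarianceComponents(sigma2_e=2.0)
        ds = generate_dataset(FixedEffects(), vc, cond, seed=11)
        fit = fit_ml(ds, options=FitOptions(compute_hessian=False))
        d = ds.data
        X = np.column_stack(
            [np.ones(len(d)), d.z, d.x, d.time, d.time * d.z, d.time * d.x]
        )
        beta, *_ = np.linalg.lstsq(X, d.y.to_numpy(), rcond=None)
        for i, name in enumerate(fit.fixed_effects):
            assert fit.estimates[name] == pytest.approx(
                beta[i], abs=3 * fit.std_errors[name]
            )
        assert fit.estimates["sigma2_e"] == pytest.approx(2.0, rel=0.05)

    def test_scale_equivariance(self, icc1_params):
        cond = DesignCondition(30, (5, 15), ICC_SET_1, base_seed=0)
        ds = generate_dataset(
            icc1_params.fixed, icc1_params.variances, cond, seed=21
        )
        doubled = LongDataset(
            ds.data.assign(y=2.0 * ds.data.y), ds.n_timepoints
        )
        f1 = fit_ml(ds, options=FitOptions(compute_hessian=False))
        f2 = fit_ml(doubled, options=FitOptions(compute_hessian=False))
        for name in f1.fixed_effects:
            assert f2.estimates[name] == pytest.approx(
                2.0 * f1.estimates[name], rel=2e-2, abs=2e-3
            )
            assert f2.std_errors[name] == pytest.approx(
                2.0 * f1.std_errors[name], rel=2e-2
            )
        for name in f1.variance_components:
            assert f2.estimates[name] == pytest.approx(
                4.0 * f1.estimates[name], rel=5e-2, abs=5e-3
            )

    def test_too_few_groups_fails_softly(self, icc1_params):
        cond = DesignCondition(2, (4, 6), ICC_SET_1)
        ds = generate_dataset(
            icc1_params.fixed, icc1_params.variances, cond, seed=2
        )
        one = LongDataset(
            ds.data[ds.data.group_id == 0].reset_index(drop=True),
            ds.n_timepoints,
        )
        fit = fit_ml(one)
        assert not fit.converged
        assert classify_convergence(fit) is ConvergenceStatus.FAILED

    def test_constant_outcome_fails_softly(self, small_dataset):
        const = LongDataset(
            small_dataset.data.assign(y=1.0), small_dataset.n_timepoints
        )
        fit = fit_ml(const)
        assert not fit.converged

    def test_free_covariance_never_fits_worse(self, icc1_params):
        cond = DesignCondition(30, (5, 15), ICC_SET_1, base_seed=0)
        ds = generate_dataset(
            icc1_params.fixed, icc1_params.variances, cond, seed=55
        )
        diag = fit_ml(ds, options=FitOptions(compute_hessian=False))
        free = fit_ml(
            ds,
            spec=ModelSpec(level2_covariance="free"),
            options=FitOptions(compute_hessian=False),
        )
        assert "sigma_r01" in free.estimates
        assert free.loglik >= diag.loglik - 1e-4


class TestClassification:
    def test_classification_rules(self, small_dataset):
        fit = fit_ml(small_dataset)
        status = classify_convergence(fit)
        if fit.converged and fit.admissible:
            assert status is ConvergenceStatus.CONVERGED
        # forced variants
        import dataclasses

        neg = dataclasses.replace(fit, admissible=False)
        assert (
            classify_convergence(neg) is ConvergenceStatus.INADMISSIBLE
            if neg.converged
            else ConvergenceStatus.FAILED
        )
        failed = dataclasses.replace(fit, converged=False)
        assert classify_convergence(failed) is ConvergenceStatus.FAILED

    def test_negative_variance_marks_inadmissible(self, small_dataset):
        fit = fit_ml(small_dataset)
        if fit.converged:
            assert fit.admissible == all(
                v >= 0 for v in fit.variance_components.values()
            )


class TestAgainstLme4:
    def test_matches_lme4_maximum_likelihood(self, tmp_path, icc1_params):
        """Independent ML implementation (lme4) finds the same optimum."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable for the lme4 cross-check")
        cond = DesignCondition(20, (5, 10), ICC_SET_1, base_seed=0)
        ds = generate_dataset(
            icc1_params.fixed, icc1_params.variances, cond, seed=123
        )
        fit = fit_ml(
            ds,
            options=FitOptions(compute_hessian=False, tol=1e-8, max_iter=1000),
        )
        assert fit.converged and fit.admissible
        csv = tmp_path / "ds.csv"
        write_csv(ds, csv)
        r_code = f"""
        d <- read.csv("{csv}")
        d$gi <- factor(d$group_id)
        d$ii <- interaction(d$group_id, d$individual_id)
        suppressMessages(library(lme4))
        m <- lmer(y ~ z + x + time + time:z + time:x
                  + (1 + x + time + x:time || gi) + (1 + time || ii),
                  data=d, REML=FALSE,
                  control=lmerControl(calc.derivs=FALSE))
        cat(sprintf("%.12g", c(as.numeric(logLik(m)), fixef(m))), sep="\\n")
        """
        out = subprocess.run(
            ["Rscript", "-e", r_code], capture_output=True, text=True,
            timeout=600, check=True,
        )
        vals = [float(v) for v in out.stdout.strip().splitlines()]
        ll_r, fixef_r = vals[0], np.array(vals[1:])
        # both maximize the same likelihood; ours is unconstrained so it
        # can only match or exceed the boundary-constrained optimum
        assert fit.loglik >= ll_r - 1e-4
        assert fit.loglik == pytest.approx(ll_r, abs=2e-3)
        ours = np.array(list(fit.fixed_effects.values()))
        assert ours == pytest.approx(fixef_r, abs=5e-3)
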