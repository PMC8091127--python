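"""NLME estimation: likelihood oracles, quadrature, fitting, SEs, shrinkage."""
import dataclasses
import logging

import numpy as np
import pytest
from scipy import stats

from sofaer.data import ObservationRecord, SubjectRecord, TrialDataset
from sofaer.estimation import (
    ExposureResponseModel,
    FitConfig,
    FitResult,
    IdentifiabilityError,
    VarianceParams,
    _fd_hessian,
    ebes_and_shrinkage,
    fit,
    marginal_ofv,
    standard_errors,
    subject_nll,
)
from sofaer.model import StructuralParams, predict_sofa
from sofaer.synthetic import TrialDesign, TruthParams, generate_trial

logging.disable(logging.WARNING)


def _make_subject(sid, arm, base, auc, days, dvs):
    obs = tuple(ObservationRecord(float(d), float(v)) for d, v in zip(days, dvs))
    return SubjectRecord(id=sid, arm=arm, base=base, auc=auc, observations=obs)


class TestSubjectNll:
    def test_standard_normal_at_mode(self, published_params):
        """One observation lying exactly on the curve, sigma=1, omega=0."""
        base = 10.0
        dv = predict_sofa(3.0, base, 0.0, published_params)
        subj = _make_subject("S1", "placebo", base, 0.0, [3.0], [dv])
        val = subject_nll(subj, published_params, VarianceParams(0.0, 1.0), eta=0.0)
        assert val == pytest.approx(0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_doubling_sigma_adds_n_log2(self, published_params):
        base = 10.0
        days = [1.0, 2.0, 3.0]
        dvs = predict_sofa(np.array(days), base, 0.0, published_params)
        subj = _make_subject("S1", "placebo", base, 0.0, days, dvs)
        v1 = subject_nll(subj, published_params, VarianceParams(0.0, 1.0), eta=0.0)
        v2 = subject_nll(subj, published_params, VarianceParams(0.0, 2.0), eta=0.0)
        assert v2 - v1 == pytest.approx(3 * np.log(2.0), abs=1e-12)

    def test_matches_direct_density_product(self, published_params, rng):
        """Independent oracle: product of scipy normal densities."""
        base, auc = 11.0, 900.0
        days = np.array([1.0, 2.0, 4.0, 6.0, 8.0])
        dvs = rng.normal(8.0, 2.0, size=5)
        subj = _make_subject("S1", "0.12", base, auc, days, dvs)
        omega, sigma, eta = 0.08, 1.7, 0.053
        pred = predict_sofa(days, base, auc, published_params, eta_k=eta)
        oracle = -(stats.norm.logpdf(dvs, pred, sigma).sum()
                   + stats.norm.logpdf(eta, 0.0, omega))
        val = subject_nll(subj, published_params, VarianceParams(omega, sigma), eta=eta)
        assert val == pytest.approx(oracle, abs=1e-12)


class TestMarginalOfv:
    def test_omega_zero_equals_closed_form_gaussian(self, five_subject_oracle, published_params):
        """With no random effect the marginal is the plain additive-Gaussian -2LL."""
        sigma = 1.7
        ofv = marginal_ofv(five_subject_oracle, published_params, VarianceParams(0.0, sigma))
        oracle = 0.0
        for s in five_subject_oracle.subjects:
            keep = s.days > 0
            pred = predict_sofa(s.days[keep], s.base, s.auc, published_params)
            oracle += -2.0 * stats.norm.logpdf(s.sofa[keep], pred, sigma).sum()
        assert ofv == pytest.approx(oracle, abs=1e-10)

    def test_agq_matches_bruteforce_quadrature(self, five_subject_oracle, published_params, published_variance):
        """AGQ(31) against a dense trapezoid integral over eta in [-8w, 8w]."""
        vp = published_variance
        ofv_agq = marginal_ofv(five_subject_oracle, published_params, vp, method="agq", n_nodes=31)
        oracle = 0.0
        grid = np.linspace(-8 * vp.omega, 8 * vp.omega, 10_000)
        for s in five_subject_oracle.subjects:
            keep = s.days > 0
            days, dvs = s.days[keep], s.sofa[keep]
            dens = np.empty_like(grid)
            for j, eta in enumerate(grid):
                pred = predict_sofa(days, s.base, s.auc, published_params, eta_k=eta)
                dens[j] = np.exp(stats.norm.logpdf(dvs, pred, vp.sigma).sum()
                                 + stats.norm.logpdf(eta, 0, vp.omega))
            oracle += -2.0 * np.log(np.trapezoid(dens, grid))
        assert ofv_agq == pytest.approx(oracle, abs=1e-6)

    def test_invariant_to_subject_ordering(self, five_subject_oracle, published_params, published_variance):
        shuffled = TrialDataset(subjects=tuple(reversed(five_subject_oracle.subjects)))
        a = marginal_ofv(five_subject_oracle, published_params, published_variance, method="agq")
        b = marginal_ofv(shuffled, published_params, published_variance, method="agq")
        assert a == pytest.approx(b, abs=1e-9)

    def test_foce_close_to_agq(self, five_subject_oracle, small_dataset, published_params, published_variance):
        """Laplace/FOCE approximation gap vs the quadrature reference."""
        for ds in (five_subject_oracle, small_dataset):
            foce = marginal_ofv(ds, published_params, published_variance, method="foce")
            agq = marginal_ofv(ds, published_params, published_variance, method="agq", n_nodes=31)
            assert abs(foce - agq) < 5.0


class TestFit:
    def test_mle_non_inferior_to_generating_parameters(self, small_dataset, truth):
        res = fit(small_dataset, seed=0, n_starts=2, compute_se=False)
        gen_ofv = marginal_ofv(small_dataset, truth.structural, truth.variance)
        assert res.ofv <= gen_ofv + 1e-6

    def test_seed_reproducible(self, small_dataset):
        r1 = fit(small_dataset, seed=5, n_starts=2, compute_se=False)
        r2 = fit(small_dataset, seed=5, n_starts=2, compute_se=False)
        assert r1.estimates() == r2.estimates()
        assert r1.ofv == r2.ofv

    def test_omega_collapses_when_truth_has_no_iiv(self, design, truth):
        no_iiv = TruthParams(structural=truth.structural,
                             variance=VarianceParams(0.0, truth.variance.sigma))
        ds = generate_trial(design, no_iiv, seed=8)
        res = fit(ds, seed=2, n_starts=2, compute_se=False)
        assert res.variance.omega < 1e-3

    def test_all_placebo_dataset_rejected(self, design, truth):
        placebo_only = TrialDesign(arms=(design.arms[0],))
        ds = generate_trial(placebo_only, truth, seed=3)
        with pytest.raises(IdentifiabilityError):
            fit(ds, seed=0)

    def test_profile_likelihood_at_optimum(self, small_dataset):
        """Perturbing any single fixed effect +/-20% never lowers the OFV."""
        res = fit(small_dataset, seed=1, n_starts=3, compute_se=False)
        for name in ("f_placebo", "k", "kin", "eauc50"):
            for fac in (0.8, 1.2):
                values = res.estimates()
                values[name] *= fac
                if name == "f_placebo":
                    values[name] = min(values[name], 0.999999)
                sp = StructuralParams(values["f_placebo"], values["k"], values["kin"], values["eauc50"])
                perturbed = marginal_ofv(small_dataset, sp,
                                         VarianceParams(values["omega"], values["sigma"]))
                assert perturbed >= res.ofv - 1e-6

    def test_large_trial_recovers_identified_quantities(self, design, truth):
        """At ~500 subjects the placebo parameters recover individually,
        and the model recovers at the prediction level: typical-subject
        SOFA predictions across the studied exposure range agree with
        the generating model within 10%.  kin and eauc50 individually
        sit on a flat likelihood ridge (the drug term is close to
        (1-Fp)*Base*AUC*kout*t/EAUC50 over the trial window, so only
        their combination is well identified) and are not asserted."""
        big = TrialDesign(arms=tuple(dataclasses.replace(a, n=a.n * 15) for a in design.arms))
        ds = generate_trial(big, truth, seed=11)
        res = ExposureResponseModel(ds).fit(seed=3, n_starts=3, compute_se=False)
        est, tr = res.params, truth.structural
        assert est.f_placebo == pytest.approx(tr.f_placebo, rel=0.15)
        assert est.k == pytest.approx(tr.k, rel=0.15)
        for t in (3.0, 7.0):
            for auc in (0.0, 295.0, 828.0, 1483.0):
                assert predict_sofa(t, 10.0, auc, est) == pytest.approx(
                    predict_sofa(t, 10.0, auc, tr), rel=0.10)
        assert res.variance.sigma == pytest.approx(truth.variance.sigma, rel=0.1)


class TestStandardErrors:
    def test_iid_normal_closed_form_information(self):
        """The finite-difference information pathway reproduces the
        textbook se(mean) = sigma/sqrt(n) on an iid normal -2LL."""
        rng = np.random.default_rng(4)
        sigma_true, n = 2.0, 400
        y = rng.normal(5.0, sigma_true, size=n)

        def half_m2ll(theta):  # theta = (mu, log sigma)
            mu, sig = theta[0], np.exp(theta[1])
            return -stats.norm.logpdf(y, mu, sig).sum()

        theta_hat = np.array([y.mean(), np.log(y.std())])
        info = _fd_hessian(half_m2ll, theta_hat, np.array([1e-4, 1e-4]))
        se_mu = np.sqrt(np.linalg.inv(info)[0, 0])
        assert se_mu == pytest.approx(y.std() / np.sqrt(n), rel=0.01)

    def test_rse_invariant_to_exposure_rescaling(self):
        """Delta-method consistency: expressing AUC in units 10x larger
        multiplies eauc50 by 10 but leaves its RSE% unchanged.  Uses a
        strong-drug-effect configuration so the information matrix at
        the optimum is positive definite, and evaluates the scaled
        problem at its exact MLE (the transformed original MLE)."""
        from sofaer.synthetic import ArmDesign

        sp = StructuralParams(f_placebo=0.5, k=0.3, kin=0.4, eauc50=800.0)
        vp = VarianceParams(0.09, 1.0)
        d = TrialDesign(arms=(ArmDesign("placebo", 20, 12.0, 3.0, 0.0, 0.0),
                              ArmDesign("0.12", 30, 10.0, 3.0, 830.0, 300.0),
                              ArmDesign("0.24", 30, 10.0, 3.0, 1480.0, 370.0)))
        ds = generate_trial(d, TruthParams(sp, vp), seed=5)
        res = fit(ds, seed=1, n_starts=2, compute_se=True)
        assert np.isfinite(res.rse_pct["eauc50"])

        scaled_ds = TrialDataset(subjects=tuple(
            dataclasses.replace(s, auc=s.auc * 10.0) for s in ds.subjects))
        scaled_params = StructuralParams(res.params.f_placebo, res.params.k,
                                         res.params.kin, res.params.eauc50 * 10.0)
        res_scaled = FitResult(params=scaled_params, variance=res.variance, ofv=res.ofv,
                               method="foce", converged=True, n_function_evals=0)
        standard_errors(res_scaled, dataset=scaled_ds)
        assert res_scaled.rse_pct["eauc50"] == pytest.approx(res.rse_pct["eauc50"], rel=1e-3)

    def test_wald_coverage_of_k(self, design, truth):
        """95% Wald CIs for k cover the generating value in ~95% of
        simulated trials (accept 90-99%)."""
        hits = 0
        n_trials = 200
        init = dict(f_placebo=0.792, k=0.263, kin=0.0569, eauc50=1320.0,
                    omega=truth.variance.omega, sigma=1.96)
        for i in range(n_trials):
            ds = generate_trial(design, truth, seed=30_000 + i)
            res = fit(ds, init=init, seed=i, n_starts=1, compute_se=True)
            se = res.se["k"]
            if not np.isfinite(se):
                continue
            lo, hi = res.params.k - 1.96 * se, res.params.k + 1.96 * se
            hits += lo <= truth.structural.k <= hi
        assert 0.90 <= hits / n_trials <= 0.99


class TestEbesAndShrinkage:
    def test_subject_without_observations_gets_prior_mode(self, published_params, published_variance):
        rich = _make_subject("A", "placebo", 10.0, 0.0, [1.0, 2.0], [9.0, 8.0])
        empty = SubjectRecord(id="B", arm="placebo", base=10.0, auc=0.0, observations=())
        ds = TrialDataset(subjects=(rich, empty))
        res = FitResult(params=published_params, variance=published_variance, ofv=0.0,
                        method="foce", converged=True, n_function_evals=0)
        ebes, _, _ = ebes_and_shrinkage(res, dataset=ds)
        assert ebes["B"] == 0.0

    def test_rich_data_low_eta_shrinkage(self, truth):
        """50 observations per subject with small residual noise pins the
        EBEs down: eta-shrinkage < 10%.  200 subjects keep the sampling
        noise of SD(eta_hat) itself well below the threshold."""
        dense_days = tuple(np.round(np.linspace(0.0, 8.0, 51), 4))
        from sofaer.synthetic import ArmDesign

        d = TrialDesign(
            arms=(ArmDesign("placebo", 100, 12.0, 3.0, 0.0, 0.0),
                  ArmDesign("0.24", 100, 10.0, 3.0, 1480.0, 300.0)),
            days=dense_days,
        )
        small_noise = TruthParams(structural=truth.structural,
                                  variance=VarianceParams(truth.variance.omega, 0.3))
        ds = generate_trial(d, small_noise, seed=21)
        res = FitResult(params=truth.structural, variance=small_noise.variance, ofv=0.0,
                        method="foce", converged=True, n_function_evals=0)
        _, eta_shrink, _ = ebes_and_shrinkage(res, dataset=ds)
        assert eta_shrink < 10.0

    def test_no_information_limit_full_shrinkage(self, design, truth):
        """With residual noise dwarfing the signal the EBEs collapse to 0."""
        noisy = TruthParams(structural=truth.structural,
                            variance=VarianceParams(truth.variance.omega, 200.0))
        ds = generate_trial(design, noisy, seed=22)
        res = FitResult(params=truth.structural, variance=noisy.variance, ofv=0.0,
                        method="foce", converged=True, n_function_evals=0)
        _, eta_shrink, _ = ebes_and_shrinkage(res, dataset=ds)
        assert eta_shrink > 80.0

    def test_omega_zero_shrinkage_is_nan(self, small_dataset, published_params):
        res = FitResult(params=published_params, variance=VarianceParams(0.0, 1.96), ofv=0.0,
                        method="foce", converged=True, n_function_evals=0)
        _, eta_shrink, _ = ebes_and_shrinkage(res, dataset=small_dataset)
        assert np.isnan(eta_shrink)
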