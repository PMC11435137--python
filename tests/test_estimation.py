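"""Likelihood, MAP empirical Bayes, pooled estimation and covariate
screening."""

import numpy as np
import pandas as pd
import pytest

from remipkpd import (Arm, Regimen, StudyDesign, SubjectData, Subject,
                      VariabilitySpec, covariate_screen, generate_dataset,
                      individual_nll, iter_subjects, map_estimate,
                      pooled_fit)


def one_obs_subject(dv_parent, t=0.0):
    """A subject with a single parent observation right after a 1.6 mg
    bolus into V1 = 16 L, so the model prediction is exactly 100 ng/mL."""
    return SubjectData(
        subject=Subject(id=1, WT=60.0),
        regimen=Regimen.bolus(1.6),
        pk_times=np.array([t]),
        dv_parent=np.array([dv_parent], dtype=float),
        dv_metab=np.array([np.nan]),
        bis_times=np.empty(0), dv_bis=np.empty(0),
    )


class TestIndividualNLL:
    def test_gaussian_arithmetic(self, pk, pd_params):
        spec = VariabilitySpec(omega={}, sigma_prop_parent=0.1)
        nll = individual_nll({}, one_obs_subject(110.0), pk, pd_params, spec)
        # z = 1, sd = 10: 1/2 + log(10) + log(2 pi)/2
        expected = 0.5 + np.log(10.0) + 0.5 * np.log(2 * np.pi)
        assert nll == pytest.approx(expected, rel=1e-9)

    def test_empty_data_is_zero(self, pk, pd_params, variability):
        data = SubjectData(subject=Subject(id=1, WT=60.0),
                           regimen=Regimen.bolus(6.0),
                           pk_times=np.empty(0), dv_parent=np.empty(0),
                           dv_metab=np.empty(0), bis_times=np.empty(0),
                           dv_bis=np.empty(0))
        assert individual_nll({}, data, pk, pd_params, variability) == 0.0

    def test_minimum_at_generating_eta(self, pk, pd_params, tiny_noise,
                                       variability):
        eta0 = {"CL_p": 0.15, "V1": -0.2}
        arm = Arm(label="a", n_subjects=1, doses_per_kg=((0.0, 0.1, 0.0),),
                  pk_times=tuple(np.linspace(1, 240, 30)), bis_times=())
        design = StudyDesign(arms=(arm,), wt_range=(60.0, 60.0))
        table, truth = generate_dataset(design, pk, pd_params, tiny_noise,
                                        seed=3)
        data = next(iter_subjects(table)).replace(
            dv_bis=np.empty(0), bis_times=np.empty(0))
        # inject the known eta by regenerating predictions: evaluate the
        # likelihood of noise-free data at truth vs a perturbed point
        spec = VariabilitySpec(omega=variability.omega,
                               sigma_prop_parent=0.232,
                               sigma_prop_metab=0.064, sigma_add_metab=43.13)
        at_truth = individual_nll({}, data, pk, pd_params, spec)
        for delta in ({"CL_p": 0.3}, {"V1": -0.4}, {"K_tr": 0.5}):
            assert individual_nll(delta, data, pk, pd_params, spec) > at_truth


class TestMAP:
    def test_no_observations_gives_prior_mode(self, pk, pd_params,
                                              variability):
        data = SubjectData(subject=Subject(id=1, WT=60.0),
                           regimen=Regimen.bolus(6.0),
                           pk_times=np.empty(0), dv_parent=np.empty(0),
                           dv_metab=np.empty(0), bis_times=np.empty(0),
                           dv_bis=np.empty(0))
        fit = map_estimate(data, pk, None, variability)
        assert all(abs(v) < 1e-6 for v in fit.estimates.values())

    def test_recovers_known_eta_from_dense_noise_free_data(
            self, pk, pd_params, variability):
        eta_true = {"CL_p": 0.18, "V1": -0.30, "Q2": 0.1, "V2": -0.1,
                    "K_tr": 0.25, "CL_m": -0.15, "V5": 0.2, "V6": -0.05}
        times = tuple(float(t) for t in np.linspace(0.5, 480, 120))
        arm = Arm(label="dense", n_subjects=1,
                  doses_per_kg=((0.0, 0.2, 1.0), (1.0, 2.0, 120.0)),
                  pk_times=times, bis_times=())
        design = StudyDesign(arms=(arm,), wt_range=(60.0, 60.0))
        spec_gen = VariabilitySpec(omega={}, sigma_prop_parent=1e-6,
                                   sigma_prop_metab=1e-6,
                                   sigma_add_metab=1e-6)
        from remipkpd import individual_parameters
        pk_true, _ = individual_parameters(pk, None,
                                           Subject(id=1, WT=60.0),
                                           eta=eta_true)
        table, _ = generate_dataset(design, pk_true, pd_params, spec_gen,
                                    seed=1)
        data = next(iter_subjects(table))
        # moderate residual spec for the fit; wide priors
        spec_fit = VariabilitySpec(omega=variability.omega,
                                   sigma_prop_parent=0.01,
                                   sigma_prop_metab=0.01,
                                   sigma_add_metab=0.1)
        fit = map_estimate(data, pk, None, spec_fit)
        for k, v in eta_true.items():
            assert fit.estimates[k] == pytest.approx(v, abs=1e-2)

    def test_shrinkage_grows_with_residual_noise(self, pk, pd_params,
                                                 variability, study_dataset):
        """With a constant (additive) residual SD the whole data likelihood
        flattens as sigma grows, so the omega-weighted prior penalty at the
        MAP mode must shrink monotonically. (With proportional error the
        log sigma(F) term breaks this, so the additive metabolite channel
        is the clean setting for the property.)"""
        table, _ = study_dataset
        data = next(iter_subjects(table[table.ID == 50]))
        penalties = []
        for scale in (1.0, 4.0, 16.0):
            spec = VariabilitySpec(
                omega=variability.omega,
                sigma_add_metab=variability.sigma_add_metab * scale)
            fit = map_estimate(data, pk, None, spec,
                               include=("metabolite",))
            penalties.append(sum(v ** 2 / spec.omega[k] ** 2
                                 for k, v in fit.estimates.items()))
        assert penalties[0] > penalties[1] > penalties[2]

    def test_tiny_omega_pins_eta_to_zero(self, pk, pd_params, variability,
                                         study_dataset):
        table, _ = study_dataset
        data = next(iter_subjects(table[table.ID == 10]))
        omega = dict(variability.omega)
        omega["CL_p"] = 1e-6
        spec = VariabilitySpec(omega=omega,
                               sigma_prop_parent=0.232,
                               sigma_prop_metab=0.064,
                               sigma_add_metab=43.13)
        fit = map_estimate(data, pk, None, spec)
        assert abs(fit.estimates["CL_p"]) < 1e-5


def small_noiseless_study(pk, pd_params):
    """One subject per arm, no BSV, near-zero residual noise."""
    from remipkpd import default_design
    design = default_design()
    arms = tuple(Arm(label=a.label, n_subjects=1,
                     doses_per_kg=a.doses_per_kg, pk_times=a.pk_times,
                     bis_times=a.bis_times) for a in design.arms)
    spec = VariabilitySpec(omega={}, sigma_prop_parent=1e-5,
                           sigma_prop_metab=1e-5, sigma_add_metab=1e-5,
                           sigma_prop_bis=1e-5)
    table, _ = generate_dataset(StudyDesign(arms=arms), pk, pd_params, spec,
                                seed=17)
    return table, spec


class TestPooledFit:
    def test_noiseless_identifiability(self, pk, pd_params):
        table, spec = small_noiseless_study(pk, pd_params)
        fit = pooled_fit(table, pk, spec, map_refine=0, n_starts=2,
                         start_sd=0.2, seed=0)
        for k, v in pk.as_dict().items():
            assert fit.estimates[k] == pytest.approx(v, rel=2e-3), k

    def test_sequential_stages_reduce_joint_objective(self, pk, pd_params):
        table, spec = small_noiseless_study(pk, pd_params)
        fit = pooled_fit(table, pk, spec, map_refine=0, n_starts=1, seed=0)
        ofv = fit.extra["stage_ofv"]
        # joint polish starts at the stage optima, so it cannot be worse
        assert ofv["joint"] <= ofv["parent"] + ofv["metabolite"] + 1e-6

    def test_requires_two_subjects(self, pk, variability, study_dataset):
        table, _ = study_dataset
        with pytest.raises(ValueError):
            pooled_fit(table[table.ID == 1], pk, variability)


class TestCovariateScreen:
    def test_empty_candidates_select_nothing(self, study_dataset, pk,
                                             variability):
        table, _ = study_dataset
        subs = list(iter_subjects(table))[:20]
        selected, ledger = covariate_screen(
            subs, None, spec=variability, pk=pk, candidates=())
        assert selected == []
        assert ledger.empty

    def test_strong_sex_effect_detected(self, pk, pd_params, variability):
        from remipkpd import CovariateEffect, CovariateModel, default_design
        cov_true = CovariateModel(effects=(
            CovariateEffect(parameter="CL_p", covariate="sex", theta=1.5),))
        table, _ = generate_dataset(default_design(), pk, pd_params,
                                    variability, seed=5, cov=cov_true)
        selected, _ = covariate_screen(list(iter_subjects(table)), None,
                                       spec=variability, pk=pk)
        pairs = {(s["parameter"], s["covariate"]) for s in selected}
        assert ("CL_p", "sex") in pairs
        theta = next(s["theta"] for s in selected
                     if (s["parameter"], s["covariate"]) == ("CL_p", "sex"))
        assert theta == pytest.approx(1.5, rel=0.2)

    def test_dofv_ledger_structure(self, study_dataset, pk, variability):
        table, _ = study_dataset
        subs = list(iter_subjects(table))
        _, ledger = covariate_screen(subs, None, spec=variability, pk=pk)
        assert {"step", "phase", "parameter", "covariate", "dofv",
                "included"} <= set(ledger.columns)
        assert (ledger["phase"].isin(["forward", "backward"])).all()
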