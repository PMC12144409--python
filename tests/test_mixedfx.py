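"""Censored likelihood oracle and per-mouse / population estimator behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from hemaflux.cohort import CohortDesign, generate_cohort, scenario_psi
from hemaflux.mixedfx import (
    ChimerismMixedEffects,
    _MouseObjective,
    _make_individual,
    _prepare_mouse,
    fit_individual,
    individual_loglik,
    wald_covariate_test,
    FitResult,
)
from hemaflux.model import observe_cbc, observe_chimerism, simulate
from hemaflux.params import (
    ALL_PSI,
    AgeGroup,
    IndividualParameters,
    Lineage,
    Scenario,
    default_population,
)


def _mouse_obs(pop, ind, weeks=(2.0, 8.0, 24.0), with_cbc=True, rng=None, censor_below=0.001):
    """Noise-free observation table for one mouse (values = model predictions)."""
    traj = simulate(ind, pop, sorted(weeks))
    rows = []
    for lin in Lineage:
        f = observe_chimerism(traj, lin, ind.scenario)
        for w, v in zip(traj.times, f):
            v = float(np.clip(np.nan_to_num(v), 1e-6, 100 - 1e-6))
            censored = v < censor_below
            rows.append((ind.individual_id, ind.age_group.value, ind.scenario.value, lin.value,
                         float(w), "chimerism", censor_below if censored else v, censored, censor_below))
        if with_cbc:
            c = observe_cbc(traj, lin)
            for w, v in zip(traj.times, c):
                rows.append((ind.individual_id, ind.age_group.value, ind.scenario.value, lin.value,
                             float(w), "cbc", float(v), False, censor_below))
    return pd.DataFrame(rows, columns=["individual_id", "age_group", "scenario", "lineage",
                                       "week", "kind", "value", "censored", "limit"])


def _brute_force_loglik(ind, pop, obs):
    """Independent recomputation: scipy normal densities/CDFs, record by record."""
    weeks = sorted(obs.week.unique())
    traj = simulate(ind, pop, weeks)
    pos = {w: i for i, w in enumerate(weeks)}
    total = 0.0
    for _, row in obs.iterrows():
        lin = Lineage(row.lineage)
        if row.kind in ("chimerism", "recipient_chimerism"):
            scen = Scenario.BM if row.kind == "recipient_chimerism" else Scenario(row.scenario)
            f = observe_chimerism(traj, lin, scen)[pos[row.week]]
            f = float(np.clip(np.nan_to_num(f), 1e-6, 100 - 1e-6))
            pred = np.log(f / (100 - f))
            a = pop.aF[lin]
            if row.censored:
                lim = np.log(row.limit / (100 - row.limit))
                total += norm.logcdf(lim, loc=pred, scale=a)
            else:
                y = np.log(row.value / (100 - row.value))
                total += norm.logpdf(y, loc=pred, scale=a)
        else:
            f = max(observe_cbc(traj, lin)[pos[row.week]], 1e-12)
            total += norm.logpdf(np.log(row.value), loc=np.log(f), scale=pop.aT[lin])
    return float(total)


class TestLikelihoodOracle:
    def test_matches_brute_force_on_random_datasets(self, pop):
        """individual_loglik == density/CDF recomputation on 100 random small datasets."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            scen = Scenario.single_LT if trial % 2 else Scenario.single_ST
            scale = {psi: float(np.exp(rng.normal(0, 0.3))) for psi in scenario_psi(scen)}
            ind = IndividualParameters(
                scale=scale,
                LC0=pop.LC0_pop * float(np.exp(rng.normal(0, 0.5))),
                SC0=pop.SC0_pop * float(np.exp(rng.normal(0, 0.5))),
                age_group=AgeGroup.young, scenario=scen, individual_id=f"m{trial}",
            )
            weeks = sorted(rng.choice([2.0, 3.0, 4.0, 8.0, 12.0, 16.0, 24.0], size=3, replace=False))
            obs = _mouse_obs(pop, ind, weeks, with_cbc=(trial % 3 == 0))
            # perturb observed values so residuals are nonzero
            chim = obs.kind == "chimerism"
            obs.loc[chim & ~obs.censored, "value"] = (
                obs.loc[chim & ~obs.censored, "value"] * np.exp(rng.normal(0, 0.2, size=(chim & ~obs.censored).sum()))
            ).clip(upper=99.9)
            got = individual_loglik(ind, pop, obs)
            want = _brute_force_loglik(ind, pop, obs)
            assert got == pytest.approx(want, abs=1e-10)

    def test_fast_objective_equals_reference_loglik(self, pop, lt_individual):
        obs = _mouse_obs(pop, lt_individual)
        md = _prepare_mouse(obs)
        est_psi = scenario_psi(Scenario.single_LT)
        obj = _MouseObjective(md, pop, est_psi, {}, 1e-8, 1e-10)
        x = np.concatenate([np.full(len(est_psi), 0.2), [np.log(2e-6), np.log(5e-7)]])
        ind = _make_individual(md, x, est_psi, {})
        assert obj.loglik(x) == pytest.approx(individual_loglik(ind, pop, obs), abs=1e-9)

    def test_zero_residuals_give_sum_of_normalizing_constants(self, pop, lt_individual):
        obs = _mouse_obs(pop, lt_individual, with_cbc=False)
        obs = obs[~obs.censored]
        ll = individual_loglik(lt_individual, pop, obs)
        aF = np.array([pop.aF[Lineage(l)] for l in obs.lineage])
        expected = np.sum(-np.log(aF * np.sqrt(2 * np.pi)))
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_censored_point_at_the_limit_contributes_log_half(self, pop, lt_individual):
        obs = _mouse_obs(pop, lt_individual, weeks=(8.0,), with_cbc=False)
        row = obs[(obs.lineage == "P")].copy().iloc[[0]]
        traj = simulate(lt_individual, pop, [8.0])
        pred = observe_chimerism(traj, Lineage.P, Scenario.single_LT)[0]
        row["censored"] = True
        row["limit"] = pred  # censoring limit exactly at the predicted value
        row["value"] = pred
        ll = individual_loglik(lt_individual, pop, row)
        assert ll == pytest.approx(np.log(0.5), abs=1e-10)

    def test_scaling_residuals_up_decreases_loglik(self, pop, lt_individual):
        """Inflating every logit residual by a common factor strictly lowers the loglik."""
        obs = _mouse_obs(pop, lt_individual, with_cbc=False)
        obs = obs[~obs.censored].copy()
        pred_logit = np.log(obs.value / (100 - obs.value))  # zero-residual baseline
        lls = []
        for shift in (0.3, 0.6, 1.2):
            o = obs.copy()
            o["value"] = 100 / (1 + np.exp(-(pred_logit + shift)))
            lls.append(individual_loglik(lt_individual, pop, o))
        assert lls[0] > lls[1] > lls[2]

    def test_loglik_is_additive_over_observations(self, pop, lt_individual):
        obs = _mouse_obs(pop, lt_individual)
        part_a = obs.iloc[: len(obs) // 2]
        part_b = obs.iloc[len(obs) // 2 :]
        total = individual_loglik(lt_individual, pop, obs)
        assert total == pytest.approx(
            individual_loglik(lt_individual, pop, part_a) + individual_loglik(lt_individual, pop, part_b),
            abs=1e-9,
        )


class TestFitIndividual:
    def test_recovers_scales_from_noiseless_data(self, pop):
        """With wide priors and exact data the MAP mode sits at the truth."""
        true = IndividualParameters(
            scale={"rS": 1.3, "pSN": 0.8, "pSE": 1.1, "pSP": 0.9, "pSB": 1.2},
            LC0=2e-6, SC0=7e-7, age_group=AgeGroup.young, scenario=Scenario.single_ST,
            individual_id="m",
        )
        obs = _mouse_obs(pop, true, weeks=(2.0, 3.0, 4.0, 8.0, 12.0, 16.0, 24.0))
        obs = obs[~obs.censored]  # censored rows only bound the mode from one side
        wide = pop.copy()
        wide.omega = {psi: 50.0 for psi in ALL_PSI}
        wide.omega_phi = 50.0
        ind, info = fit_individual(obs, wide, n_starts=1, maxiter=600, seed=0, polish=True)
        for psi, v in true.scale.items():
            assert np.log(ind.scale[psi]) == pytest.approx(np.log(v), abs=1e-3)
        # the competitor pools are the flattest direction of the posterior
        assert np.log(ind.LC0) == pytest.approx(np.log(true.LC0), abs=1e-2)

    def test_objective_stationary_at_truth(self, pop, lt_individual):
        obs = _mouse_obs(pop, lt_individual)
        md = _prepare_mouse(obs)
        est_psi = scenario_psi(Scenario.single_LT)
        obj = _MouseObjective(md, pop, est_psi, {}, 1e-8, 1e-10)
        x_true = np.concatenate([np.zeros(len(est_psi)), [np.log(pop.LC0_pop), np.log(pop.SC0_pop)]])
        f0 = obj(x_true)
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert obj(x_true + rng.normal(0, 0.05, size=len(x_true))) >= f0 - 1e-6

    def test_degenerate_prior_pins_scales_to_one(self, pop):
        rng = np.random.default_rng(2)
        true = IndividualParameters(
            scale={psi: float(np.exp(rng.normal(0, 0.3))) for psi in scenario_psi(Scenario.single_ST)},
            LC0=pop.LC0_pop, SC0=pop.SC0_pop,
            age_group=AgeGroup.young, scenario=Scenario.single_ST, individual_id="m",
        )
        obs = _mouse_obs(pop, true)
        tight = pop.copy()
        tight.omega = {psi: 1e-4 for psi in ALL_PSI}
        ind, _ = fit_individual(obs, tight, n_starts=1, maxiter=100, seed=0)
        for psi in scenario_psi(Scenario.single_ST):
            assert ind.scale[psi] == pytest.approx(1.0, abs=5e-3)


class TestPopulationFit:
    def test_single_individual_with_pinned_omegas_reduces_to_individual_fit(self, pop):
        true = IndividualParameters(
            scale={psi: 1.0 for psi in scenario_psi(Scenario.single_ST)},
            LC0=pop.LC0_pop, SC0=pop.SC0_pop,
            age_group=AgeGroup.young, scenario=Scenario.single_ST, individual_id="m1",
        )
        obs = _mouse_obs(pop, true)
        init = pop.copy()
        init.omega = {psi: 1e-4 for psi in ALL_PSI}
        init.omega_phi = 0.5
        est = ChimerismMixedEffects(
            init=init, estimate_omega=False, estimate_error_scales=False,
            refine_population=False, n_starts=1, maxiter=60, max_sweeps=1, seed=0,
        )
        est.fit(obs)
        ind, _ = fit_individual(obs, init, n_starts=1, maxiter=60, seed=0)
        for psi in scenario_psi(Scenario.single_ST):
            # with omega ~ 0 both paths pin the scales to 1 and agree
            assert est.individuals_["m1"].scale[psi] == pytest.approx(ind.scale[psi], abs=1e-3)

    def test_fit_is_deterministic_given_seed(self, pop):
        design = CohortDesign(
            seed=9,
            counts={(Scenario.single_LT, AgeGroup.young): 2, (Scenario.single_ST, AgeGroup.young): 1},
            cbc_counts={},
        )
        obs, _ = generate_cohort(design, pop)
        kw = dict(init=pop.copy(), n_starts=1, maxiter=10, maxiter_warm=5, max_sweeps=2, seed=3)
        a = ChimerismMixedEffects(**kw).fit(obs)
        b = ChimerismMixedEffects(**kw).fit(obs)
        assert a.loglik_ == b.loglik_
        assert a.population_.to_flat() == b.population_.to_flat()
        for iid in a.individuals_:
            assert a.individuals_[iid].scale == b.individuals_[iid].scale


class TestWald:
    def _fit(self, beta, se):
        return FitResult(
            population=default_population(), individuals={}, covariates={"rL": (beta, se)},
            loglik=0.0, converged=True, n_sweeps=1, seed=0,
        )

    def test_two_sided_p_from_normal(self):
        b, s, p = wald_covariate_test(self._fit(1.0, 0.5), "rL")
        assert p == pytest.approx(2 * (1 - norm.cdf(2.0)), abs=1e-12)
        assert p == pytest.approx(0.0455, abs=1e-4)

    def test_zero_beta_gives_p_one(self):
        assert wald_covariate_test(self._fit(0.0, 0.5), "rL")[2] == pytest.approx(1.0)

    def test_sign_invariance(self):
        p_pos = wald_covariate_test(self._fit(0.7, 0.2), "rL")[2]
        p_neg = wald_covariate_test(self._fit(-0.7, 0.2), "rL")[2]
        assert p_pos == pytest.approx(p_neg, abs=1e-15)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            wald_covariate_test(self._fit(1.0, 0.0), "rL")
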