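import math

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from ccsst.multistate import (
    CENSORED, DEATH, HIGH, LOW, TRANSITION_LABELS,
    DataError, IntensityModel, MarkovPanelModel, PanelDataset, PersonRecords,
    _living_propagator, build_panel, fit_ctmc, generator_matrix,
    panel_log_likelihood, transition_probability,
)
from ccsst.synthesis import SimulationConfig, simulate_trajectories


def model_with(q_lh=0.1, q_hl=0.1, q_ld=0.05, q_hd=0.2, beta=None, names=()):
    beta = np.zeros((len(names), 4)) if beta is None else np.asarray(beta, float)
    with np.errstate(divide="ignore"):
        logq = np.log(np.array([q_lh, q_hl, q_ld, q_hd]))
    return IntensityModel(baseline_log_q=logq, beta=beta, covariate_names=tuple(names))


def dataset(records, names=()):
    """records: list of per-person lists of (time, state, zvec)."""
    persons = []
    for i, recs in enumerate(records):
        times = np.array([r[0] for r in recs], float)
        states = np.array([r[1] for r in recs], int)
        z = np.array([r[2] for r in recs], float).reshape(len(recs), len(names))
        persons.append(PersonRecords(i, times, states, z))
    return PanelDataset(persons, tuple(names))


class TestGeneratorMatrix:
    def test_zero_covariates_give_baselines(self):
        m = model_with(0.1, 0.2, 0.3, 0.4)
        Q = generator_matrix(m)
        assert Q[LOW, HIGH] == pytest.approx(0.1)
        assert Q[HIGH, LOW] == pytest.approx(0.2)
        assert Q[LOW, DEATH] == pytest.approx(0.3)
        assert Q[HIGH, DEATH] == pytest.approx(0.4)

    def test_generator_structure(self):
        m = model_with(beta=[[0.5, -0.2, 0.1, 0.3]], names=("x",))
        for z in ([0.0], [1.0], [-2.0]):
            Q = generator_matrix(m, z)
            assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-14)
            assert np.allclose(Q[DEATH], 0.0)

    def test_log_linear_covariate_doubles_intensity(self):
        m = model_with(q_lh=0.1, beta=[[math.log(2), 0, 0, 0]], names=("cf",))
        assert generator_matrix(m, [1.0])[LOW, HIGH] == pytest.approx(0.2)
        assert generator_matrix(m, [0.0])[LOW, HIGH] == pytest.approx(0.1)


class TestTransitionProbability:
    def test_zero_time_is_identity(self):
        Q = generator_matrix(model_with())
        assert np.allclose(transition_probability(Q, 0.0), np.eye(3))

    def test_death_only_closed_form(self):
        Q = np.array([[-0.5, 0.0, 0.5], [0, 0, 0], [0, 0, 0]], float)
        P = transition_probability(Q, 2.0)
        assert P[LOW, LOW] == pytest.approx(math.exp(-1.0), abs=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_probability(np.zeros((3, 3)), -0.1)

    def test_chapman_kolmogorov(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            q = rng.uniform(0.01, 1.0, 4)
            Q = generator_matrix(model_with(*q))
            s, t = rng.uniform(0.1, 3.0, 2)
            assert np.allclose(
                transition_probability(Q, s + t),
                transition_probability(Q, s) @ transition_probability(Q, t),
                atol=1e-10,
            )

    def test_rows_sum_to_one(self):
        Q = generator_matrix(model_with(0.3, 0.2, 0.1, 0.5))
        for t in (0.5, 2.0, 10.0):
            P = transition_probability(Q, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert np.all((P >= 0) & (P <= 1))

    def test_living_block_matches_full_matrix_exponential(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            q = rng.uniform(1e-4, 2.0, 4)
            m = model_with(*q)
            Q = generator_matrix(m)
            A = Q[:2, :2]
            dts = rng.uniform(0.01, 8.0, 5)
            P2 = _living_propagator(A, dts)
            for dt, p2 in zip(dts, P2):
                assert np.allclose(p2, expm(Q * dt)[:2, :2], atol=1e-11)

    def test_living_block_repeated_eigenvalue(self):
        # symmetric no-death generator has a repeated root at a=b boundary
        A = np.array([[-0.3, 0.3], [0.3, -0.3]])
        # eigenvalues 0 and -0.6: distinct; force coincidence with zeros
        A0 = np.zeros((2, 2))
        assert np.allclose(_living_propagator(A0, np.array([1.5]))[0], np.eye(2))
        assert np.allclose(_living_propagator(A, np.array([2.0]))[0],
                           expm(A * 2.0), atol=1e-12)


class TestPanelLogLikelihood:
    def test_single_low_interval_death_only_model(self):
        # only LOW->DEATH possible at rate lam: P_LL(dt) = exp(-lam*dt)
        lam, dt = 0.3, 2.5
        m = model_with(q_lh=0.0, q_hl=0.0, q_ld=lam, q_hd=0.0)
        data = dataset([[(0.0, LOW, []), (dt, LOW, [])]])
        assert panel_log_likelihood(m, data) == pytest.approx(-lam * dt, abs=1e-12)

    def test_empty_dataset(self):
        assert panel_log_likelihood(model_with(), dataset([])) == 0.0

    def test_exact_death_contribution(self):
        # LOW at 0, death at t: integral-free exact-death term
        m = model_with(0.2, 0.1, 0.05, 0.3)
        t = 1.7
        data = dataset([[(0.0, LOW, []), (t, DEATH, [])]])
        Q = generator_matrix(m)
        P = expm(Q * t)
        expected = math.log(P[LOW, LOW] * 0.05 + P[LOW, HIGH] * 0.3)
        assert panel_log_likelihood(m, data) == pytest.approx(expected, abs=1e-10)

    def test_terminal_censored_alive_contribution(self):
        m = model_with(0.2, 0.1, 0.05, 0.3)
        t = 2.0
        data = dataset([[(0.0, HIGH, []), (t, CENSORED, [])]])
        Q = generator_matrix(m)
        P = expm(Q * t)
        expected = math.log(P[HIGH, LOW] + P[HIGH, HIGH])
        assert panel_log_likelihood(m, data) == pytest.approx(expected, abs=1e-10)

    def test_intermediate_censored_contact_marginalizes_exactly(self):
        """Splitting an interval with an uninformative alive contact leaves
        the likelihood unchanged (semigroup property)."""
        m = model_with(0.25, 0.15, 0.03, 0.2)
        direct = dataset([[(0.0, LOW, []), (4.0, HIGH, [])]])
        split = dataset([[(0.0, LOW, []), (1.3, CENSORED, []), (4.0, HIGH, [])]])
        assert panel_log_likelihood(m, split) == pytest.approx(
            panel_log_likelihood(m, direct), abs=1e-10
        )

    def test_truth_beats_perturbation_on_large_sample(self):
        cfg = SimulationConfig(n_persons=2000, seed=21, censoring_prob=0.0,
                               covariate_log_hr={})
        panel, _ = simulate_trajectories(cfg)
        data = build_panel(panel)
        truth = model_with(**{k: cfg.baseline_intensities[l]
                              for k, l in zip(("q_lh", "q_hl", "q_ld", "q_hd"),
                                              TRANSITION_LABELS)})
        ll_true = panel_log_likelihood(truth, data)
        rng = np.random.default_rng(4)
        for _ in range(5):
            pert = IntensityModel(
                baseline_log_q=truth.baseline_log_q + rng.uniform(0.3, 0.7, 4) * rng.choice([-1, 1], 4),
                beta=truth.beta,
            )
            assert ll_true > panel_log_likelihood(pert, data)


class TestBuildPanel:
    def test_three_alive_waves(self, tiny_segmented_panel):
        data = build_panel(tiny_segmented_panel, covariates=["any_cf"])
        by_id = {p.person_id: p for p in data.persons}
        assert list(by_id[1].states) == [LOW, HIGH]
        # person 2: one interview + appended exact death record
        assert list(by_id[2].states) == [HIGH, DEATH]
        assert by_id[2].times[-1] == pytest.approx(3.0)
        # person 3: leading censored contact dropped
        assert list(by_id[3].states) == [LOW]

    def test_death_before_last_observation_rejected(self):
        df = pd.DataFrame([
            dict(person_id="p", interview_time=0.0, health_state="low", death_time=np.nan),
            dict(person_id="p", interview_time=2.0, health_state="low", death_time=1.0),
        ])
        with pytest.raises(DataError, match="p"):
            build_panel(df)

    def test_unsorted_times_rejected(self):
        df = pd.DataFrame([
            dict(person_id="p", interview_time=0.0, health_state="low", death_time=np.nan),
            dict(person_id="p", interview_time=0.0, health_state="low", death_time=np.nan),
        ])
        with pytest.raises(DataError):
            build_panel(df)


@pytest.fixture(scope="module")
def recovered():
    cfg = SimulationConfig(n_persons=2000, seed=5)
    panel, _ = simulate_trajectories(cfg)
    data = build_panel(panel, covariates=["any_cf"])
    return cfg, MarkovPanelModel(data), fit_ctmc(data)


class TestFit:
    def test_baselines_recovered(self, recovered):
        cfg, _, res = recovered
        est = np.log(res.baseline_intensities()["q0"].to_numpy())
        true = np.log([cfg.baseline_intensities[l] for l in TRANSITION_LABELS])
        assert np.all(np.abs(est - true) < 0.25)
        assert res.converged

    def test_hazard_ratio_recovered(self, recovered):
        cfg, _, res = recovered
        hr = res.hazard_ratios().set_index(["covariate", "transition"])
        est = hr.loc[("any_cf", "low->high"), "hr"]
        assert 1.6 < est < 2.5
        lo, hi = hr.loc[("any_cf", "low->high"), ["ci_low", "ci_high"]]
        assert lo <= est <= hi

    def test_hessian_negative_definite_at_optimum(self, recovered):
        from ccsst.multistate import _numerical_hessian
        _, model, res = recovered
        H = _numerical_hessian(lambda x: -model.loglike(x), res.params)
        assert np.all(np.linalg.eigvalsh(H) > 0)  # nll convex at optimum

    def test_frozen_betas_match_no_covariate_fit(self, recovered):
        cfg, model, _ = recovered
        data = model.data
        res_frozen = MarkovPanelModel(data, constrain_beta=[]).fit(compute_cov=False)
        data_nocov = PanelDataset(
            [PersonRecords(p.person_id, p.times, p.states, np.zeros((len(p.times), 0)))
             for p in data.persons], ())
        res_nocov = MarkovPanelModel(data_nocov).fit(compute_cov=False)
        assert res_frozen.llf == pytest.approx(res_nocov.llf, abs=1e-4)
        assert np.allclose(res_frozen.params[:4], res_nocov.params[:4], atol=1e-3)

    def test_summary_renders(self, recovered):
        _, _, res = recovered
        s = res.summary()
        assert "low->high" in s and "Hazard ratios" in s
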