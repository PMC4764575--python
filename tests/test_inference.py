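"""MCMC correctness: conjugate updates, state sampling, recovery, convergence."""

import dataclasses
import itertools

import numpy as np
import pytest

from kinetoswitch import (ChainConfig, ModelParams, PM, MP, Priors,
                          loglik_trajectory, run_chain, sample_state_path,
                          simulate_trajectory, transition_matrix)
from kinetoswitch.core import PairedTrajectory, PP, MM
from kinetoswitch.inference import (design_matrix, obs_loglik_matrix,
                                    update_linear_params, update_noise_var,
                                    update_switch_probs, summarize_posterior)
from kinetoswitch.validation import study_chain_config, study_priors


@pytest.fixture(scope="module")
def noisefree_traj(params):
    p = params.with_(s2=0.0)
    return simulate_trajectory(p, 30, seed=10)


class TestLoglik:
    def test_zero_residual_closed_form(self, params):
        # pure Gaussian normalisation: residuals identically zero
        p = params.with_(s2=0.0)
        traj, truth = simulate_trajectory(p, 20, seed=1)
        p_eval = p.with_(s2=250.0)
        ll = loglik_trajectory(traj, truth.state_path, p_eval)
        n = traj.n_steps
        assert ll == pytest.approx(-n * np.log(2 * np.pi * 250.0), rel=1e-12)

    def test_true_path_is_modal_among_single_flips(self, noisefree_traj,
                                                   params):
        traj, truth = noisefree_traj
        p_eval = params.with_(s2=10.0)
        ll_true = loglik_trajectory(traj, truth.state_path, p_eval)
        for t in range(traj.n_steps):
            for s in range(4):
                if s == truth.state_path[t]:
                    continue
                perturbed = truth.state_path.copy()
                perturbed[t] = s
                assert loglik_trajectory(traj, perturbed, p_eval) < ll_true

    def test_zero_variance_with_residuals_is_minus_inf(self, params):
        traj, truth = simulate_trajectory(params, 20, seed=2)  # noisy data
        assert loglik_trajectory(traj, truth.state_path,
                                 params.with_(s2=0.0)) == -np.inf


class TestConjugateUpdates:
    def test_noise_update_matches_closed_form(self, params):
        rng = np.random.default_rng(0)
        p = params.with_(s2=0.0)
        traj, truth = simulate_trajectory(p, 60, seed=3)
        pri = Priors(s2_shape=3.0, s2_scale=50.0)
        lin = (p.a, p.b, p.c0, p.c_plus, p.c_minus)
        # zero residuals: posterior IG(shape + n/2, scale) exactly
        n_res = 2 * traj.n_steps
        draws = np.array([update_noise_var(traj, truth.state_path, lin, pri,
                                           rng) for _ in range(4000)])
        expect_mean = pri.s2_scale / (pri.s2_shape + n_res / 2 - 1)
        assert draws.mean() == pytest.approx(expect_mean, rel=0.1)

    def test_noise_update_with_known_rss(self, params):
        rng = np.random.default_rng(1)
        traj, truth = simulate_trajectory(params, 200, seed=4)
        pri = Priors(s2_shape=1.0, s2_scale=1.0)
        lin = (params.a, params.b, params.c0, params.c_plus, params.c_minus)
        X, y = design_matrix(traj, truth.state_path)
        beta = np.array([params.c0 + params.c_plus,
                         params.c0 + params.c_minus, params.a, params.b])
        rss = float(((y - X @ beta) ** 2).sum())
        shape = pri.s2_shape + len(y) / 2
        scale = pri.s2_scale + rss / 2
        draws = np.array([update_noise_var(traj, truth.state_path, lin, pri,
                                           rng) for _ in range(4000)])
        assert draws.mean() == pytest.approx(scale / (shape - 1), rel=0.05)

    def test_switch_prob_conjugacy(self):
        rng = np.random.default_rng(2)
        # 3 switches out of coherence in 12 coherent opportunities
        path = np.array([PM] * 5 + [PP] + [MP] * 5 + [MM] + [PM] * 3,
                        dtype=np.int8)
        frm, to = path[:-1], path[1:]
        coh = np.isin(frm, (PM, MP))
        k_c = int((frm[coh] != to[coh]).sum())
        n_c = int(coh.sum())
        draws = np.array([update_switch_probs(path, Priors(), rng)[1]
                          for _ in range(4000)])
        assert draws.mean() == pytest.approx((1 + k_c) / (2 + n_c), abs=0.02)

    def test_no_incoherent_frames_draws_from_prior(self):
        rng = np.random.default_rng(3)
        path = np.full(50, PM, dtype=np.int8)
        draws = np.array([update_switch_probs(path, Priors(), rng)[0]
                          for _ in range(4000)])
        # Beta(1,1) prior: mean 1/2, var 1/12
        assert draws.mean() == pytest.approx(0.5, abs=0.02)
        assert draws.var() == pytest.approx(1 / 12, rel=0.1)


class TestLinearUpdate:
    def test_flat_prior_unconstrained_matches_ols(self, params):
        rng = np.random.default_rng(4)
        traj, truth = simulate_trajectory(params, 51, seed=5)
        pri = Priors(rest_length_sd=np.inf)
        draws = []
        for _ in range(3000):
            (a, b, c0, cp, cm), info = update_linear_params(
                traj, truth.state_path, params, pri, rng, constrain=False)
            draws.append([c0 + cp, c0 + cm, a, b])
        got = np.mean(draws, axis=0)
        X, y = design_matrix(traj, truth.state_path)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        se = np.sqrt(np.diag(params.s2 * np.linalg.inv(X.T @ X)) / 3000)
        assert np.all(np.abs(got - ols) < 5 * se)

    def test_degenerate_path_holds_unvisited_drive(self, params):
        rng = np.random.default_rng(5)
        traj, _ = simulate_trajectory(params, 30, seed=6)
        path = np.full(traj.n_steps, PP, dtype=np.int8)  # never '-' anywhere
        (a, b, c0, cp, cm), info = update_linear_params(
            traj, path, params, Priors(rest_length_sd=np.inf), rng)
        assert 1 in info["held"]          # gamma- column empty
        assert cm + c0 == pytest.approx(params.c_minus + params.c0)

    def test_tight_rest_length_prior_pins_separation(self, params):
        traj, truth = simulate_trajectory(params, 150, seed=7)
        pri = Priors(rest_length_mean=params.equilibrium_separation,
                     rest_length_sd=1.0)
        cfg = ChainConfig(n_burn=300, n_draws=600, n_chains=1, seed=8)
        res = run_chain(traj, pri, cfg)
        m = res.summary.mean
        sep = 2 * m["c0"] / (m["a"] + m["b"])
        assert sep == pytest.approx(params.equilibrium_separation, rel=0.01)


def enumerate_posterior(traj, params):
    """Brute-force posterior over all 4^n state paths of a tiny trajectory."""
    n = traj.n_steps
    L = obs_loglik_matrix(traj, params)
    T4 = transition_matrix(params.p_incoherent, params.p_coherent)
    logpost = []
    paths = list(itertools.product(range(4), repeat=n))
    for path in paths:
        lp = np.log(0.25) + L[0, path[0]]
        for t in range(1, n):
            lp += np.log(T4[path[t - 1], path[t]] + 1e-300) + L[t, path[t]]
        logpost.append(lp)
    w = np.exp(np.array(logpost) - np.max(logpost))
    w /= w.sum()
    marg = np.zeros((n, 4))
    for prob, path in zip(w, paths):
        for t, s in enumerate(path):
            marg[t, s] += prob
    return marg


class TestStateSampling:
    def test_tiny_noise_recovers_true_path(self, params):
        p = params.with_(s2=1.0)
        traj, truth = simulate_trajectory(p, 150, seed=9)
        rng = np.random.default_rng(10)
        path = sample_state_path(traj, p, None, rng, "ffbs")
        assert (path == truth.state_path).mean() > 0.99

    def test_symmetric_data_samples_coherent_states_equally(self, params):
        # mirror-symmetric positions and drives: +- and -+ indistinguishable
        p = params.with_(c_plus=50.0, c_minus=-50.0)
        n = 40
        x1 = np.linspace(400, 500, n)
        traj = PairedTrajectory(frames=np.arange(n), x1=x1, x2=-x1)
        L = obs_loglik_matrix(traj, p)
        assert np.allclose(L[:, PM], L[:, MP])
        rng = np.random.default_rng(11)
        paths = np.array([sample_state_path(traj, p, None, rng, "ffbs")
                          for _ in range(400)])
        f_pm = (paths == PM).mean()
        f_mp = (paths == MP).mean()
        assert abs(f_pm - f_mp) < 0.05

    def test_flat_likelihood_reproduces_prior_chain(self, params):
        # s2 enormous: posterior over paths = prior Markov chain
        p = params.with_(s2=1e12)
        traj, _ = simulate_trajectory(params, 100, seed=12)
        rng = np.random.default_rng(13)
        paths = np.array([sample_state_path(traj, p, None, rng, "ffbs")
                          for _ in range(300)])
        pi, pc = params.p_incoherent, params.p_coherent
        v = 1.0 / (2 * (1 + pc / pi))   # stationary coherent-state weight
        w = v * pc / pi
        freq = np.array([(paths == s).mean() for s in range(4)])
        n_eff = paths.size / 20.0       # autocorrelation-discounted
        for s, expect in zip(range(4), (w, v, v, w)):
            se = np.sqrt(expect * (1 - expect) / n_eff)
            assert abs(freq[s] - expect) < 4 * se

    def test_ffbs_and_single_site_match_enumeration(self, params):
        p = params.with_(s2=4000.0)
        traj, _ = simulate_trajectory(p, 6, seed=14)
        exact = enumerate_posterior(traj, p)
        rng = np.random.default_rng(15)
        n_draw = 4000
        ffbs_counts = np.zeros((traj.n_steps, 4))
        for _ in range(n_draw):
            path = sample_state_path(traj, p, None, rng, "ffbs")
            ffbs_counts[np.arange(traj.n_steps), path] += 1
        gibbs_counts = np.zeros((traj.n_steps, 4))
        path = sample_state_path(traj, p, None, rng, "ffbs")
        for i in range(20 * n_draw):
            path = sample_state_path(traj, p, path, rng, "single_site")
            if i % 20 == 19:
                gibbs_counts[np.arange(traj.n_steps), path] += 1
        for counts, label, n_eff in ((ffbs_counts, "ffbs", n_draw),
                                     (gibbs_counts, "gibbs", n_draw / 4)):
            freq = counts / counts.sum(axis=1, keepdims=True)
            se = np.sqrt(np.maximum(exact * (1 - exact), 1e-6) / n_eff)
            assert np.all(np.abs(freq - exact) < 5 * se), label


class TestRunChain:
    def test_same_seed_identical_samples(self, params):
        traj, _ = simulate_trajectory(params, 120, seed=16)
        cfg = ChainConfig(n_burn=50, n_draws=100, n_chains=2, seed=17)
        r1 = run_chain(traj, study_priors(params), cfg)
        r2 = run_chain(traj, study_priors(params), cfg)
        for c1, c2 in zip(r1.chains, r2.chains):
            for k in c1.draws:
                assert np.array_equal(c1.draws[k], c2.draws[k])

    def test_short_trajectory_is_rejected_by_default(self, params):
        traj, _ = simulate_trajectory(params, 50, seed=18)
        with pytest.raises(ValueError):
            run_chain(traj, study_priors(params), ChainConfig(seed=1))

    def test_degenerate_trajectory_reports_nonconvergence(self, params):
        traj, _ = simulate_trajectory(params, 2, seed=19)
        cfg = ChainConfig(n_burn=20, n_draws=40, n_chains=2, seed=20)
        res = run_chain(traj, study_priors(params), cfg,
                        enforce_min_length=False)
        assert res.excluded

    def test_pure_noise_input_flags_nonconvergence(self, params):
        rng = np.random.default_rng(21)
        x1 = rng.normal(450, 300, 150)
        x2 = rng.normal(-450, 300, 150)
        traj = PairedTrajectory(frames=np.arange(150), x1=x1, x2=x2)
        res = run_chain(traj, Priors(rest_length_sd=np.inf),
                        ChainConfig(n_burn=200, n_draws=400, n_chains=2,
                                    seed=22))
        assert res.excluded

    def test_sign_constraints_hold_for_every_sample(self, params):
        traj, _ = simulate_trajectory(params, 150, seed=23)
        res = run_chain(traj, study_priors(params),
                        ChainConfig(n_burn=200, n_draws=400, n_chains=1,
                                    seed=24))
        d = res.chains[0].draws
        assert np.all(d["c_plus"] > 0)
        assert np.all(d["c_minus"] < 0)
        assert np.all(d["c0"] > 0)
        assert np.all(d["a"] > 0) and np.all(d["b"] > 0)
        assert np.all((d["p_incoherent"] >= 0) & (d["p_incoherent"] <= 1))

    def test_parameter_recovery_within_three_pooled_sds(self, params):
        # scaled-down recovery check: a handful of trajectories
        means, sds = {}, {}
        for i in range(4):
            traj, _ = simulate_trajectory(params, 150, seed=30 + i)
            res = run_chain(traj, study_priors(params),
                            dataclasses.replace(study_chain_config(), seed=i))
            if res.excluded:
                continue
            for k, v in res.summary.mean.items():
                means.setdefault(k, []).append(v)
                sds.setdefault(k, []).append(res.summary.sd[k])
        truth = {"a": params.a, "b": params.b, "c0": params.c0,
                 "c_plus": params.c_plus, "c_minus": params.c_minus,
                 "s2": params.s2, "p_incoherent": params.p_incoherent,
                 "p_coherent": params.p_coherent}
        assert len(means["a"]) >= 2
        for k, true_val in truth.items():
            pooled_mean = np.mean(means[k])
            pooled_sd = np.sqrt(np.mean(np.square(sds[k]))
                                + np.var(means[k], ddof=1))
            assert abs(pooled_mean - true_val) < 3 * pooled_sd, k


class TestSummaries:
    def test_state_marginals_normalised(self, params):
        traj, _ = simulate_trajectory(params, 120, seed=40)
        res = run_chain(traj, study_priors(params),
                        ChainConfig(n_burn=50, n_draws=100, n_chains=2,
                                    seed=41))
        sums = res.summary.state_marginals.sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_single_draw_summary_equals_sample(self, params):
        traj, _ = simulate_trajectory(params, 120, seed=42)
        res = run_chain(traj, study_priors(params),
                        ChainConfig(n_burn=30, n_draws=1, n_chains=1,
                                    seed=43))
        c = res.chains[0]
        summ = summarize_posterior([c])
        for k in c.draws:
            assert summ.mean[k] == pytest.approx(c.draws[k][0])

    def test_credible_interval_coverage_near_nominal(self, params):
        # reduced-replicate calibration on the data-identified coefficient a
        hits = 0
        n_rep = 12
        for i in range(n_rep):
            traj, _ = simulate_trajectory(params, 150, seed=50 + i)
            res = run_chain(traj, study_priors(params),
                            ChainConfig(n_burn=300, n_draws=600, n_chains=1,
                                        seed=60 + i))
            s = res.summary
            if s.ci_low["a"] <= params.a <= s.ci_high["a"]:
                hits += 1
        # 95% interval: expect ~11.4/12; allow generous binomial slack
        assert hits >= 9
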