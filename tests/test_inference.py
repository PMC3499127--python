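"""Likelihoods, MLE, marginal likelihoods, ranking and force matching."""

import numpy as np
import pytest
from scipy.special import betaln

from flockfit.inference import (
    fit_mle,
    force_matching_fit,
    log_marginal_laplace,
    rank_models,
    recovery_harness,
    sequence_loglik,
    switch_probability_profile,
)
from flockfit.ring_sim import RingSimConfig, simulate_ring
from flockfit.switching_models import EPS, get_model
from flockfit.trajdata import SwitchEventSequence, extract_events
from flockfit.vicsek_sim import VicsekConfig, simulate_interaction

from conftest import hand_events


def sim_events(model, params, n_agents=8, n_steps=1000, seed=0, init="half"):
    cfg = RingSimConfig(n_agents=n_agents, n_steps=n_steps, model=model,
                        params=params, seed=seed, init=init)
    return extract_events(simulate_ring(cfg))


class TestSequenceLoglik:
    def test_constant_half_closed_form(self):
        events = hand_events(np.array([1, 0, 1, 0, 0, 1, 0, 1, 0, 0]), np.full(10, 2.0))
        ll = sequence_loglik(get_model("const"), {"p0": 0.5}, events)
        assert ll == pytest.approx(-10 * np.log(2))

    def test_certain_predictions_near_zero(self):
        events = hand_events(np.zeros(20, dtype=int), np.full(20, 2.0))
        ll = sequence_loglik(get_model("const"), {"p0": 0.0}, events)
        assert ll == pytest.approx(0.0, abs=1e-6)

    def test_refractory_matches_manual_enumeration(self):
        """5-step single-series refractory case, threaded by hand."""
        y = np.array([0, 1, 0, 0, 1])
        fwd = np.array([0.1, 2.0, 2.0, 0.3, 2.0])
        params = {"p0": 0.05, "p1": 0.4, "w": 0.5, "tau": 2}
        # manual threading: enc=[T,F,F,T,F]; counter after update:
        # t0: enc -> 2 (p1); t1: 1 (p1); t2: 0 (p0); t3: enc -> 2 (p1); t4: 1 (p1)
        p_manual = np.array([0.4, 0.4, 0.05, 0.4, 0.4])
        expected = float(np.sum(np.where(y, np.log(p_manual), np.log1p(-p_manual))))
        events = hand_events(y, fwd)
        assert sequence_loglik(get_model("d1"), params, events) == pytest.approx(expected)

    def test_additive_over_independent_blocks(self, rng):
        e1 = sim_events("zone", {"p0": 0.02, "p1": 0.2, "w": 0.6}, n_steps=200, seed=1)
        e2 = sim_events("zone", {"p0": 0.02, "p1": 0.2, "w": 0.6}, n_steps=300, seed=2)
        both = SwitchEventSequence.concat([e1, e2])
        params = {"p0": 0.03, "p1": 0.25, "w": 0.5, "tau": 3}
        model = get_model("d1")
        assert sequence_loglik(model, params, both) == pytest.approx(
            sequence_loglik(model, params, e1) + sequence_loglik(model, params, e2)
        )

    def test_out_of_bounds_params_rejected(self):
        events = hand_events(np.array([0, 1]), np.array([2.0, 2.0]))
        with pytest.raises(ValueError, match="bounds"):
            sequence_loglik(get_model("const"), {"p0": 1.5}, events)


class TestFitMLE:
    def test_meanfield_parameter_recovery(self):
        truth = {"p0": 0.05, "k": 0.3}
        events = sim_events("meanfield", truth, n_steps=7000, seed=4)
        fit = fit_mle("meanfield", events, seed=0, compute_marginal=False)
        # bootstrap s.e. oracle: refit on resampled event blocks
        rng = np.random.default_rng(0)
        boots = {"p0": [], "k": []}
        for _ in range(30):
            idx = np.sort(rng.integers(0, len(events), len(events)))
            b = SwitchEventSequence(
                agent=np.arange(len(events)), t_index=np.zeros(len(events), int),
                y=events.y[idx], f_opp=events.f_opp[idx],
                fwd_opp=events.fwd_opp[idx], abs_opp=events.abs_opp[idx],
                nearest_opp=events.nearest_opp[idx],
            )
            f = fit_mle("meanfield", b, n_starts=2, seed=1, compute_marginal=False)
            for k in boots:
                boots[k].append(f.params[k])
        for k, v in truth.items():
            se = np.std(boots[k], ddof=1)
            assert abs(fit.params[k] - v) < 3 * se + 1e-3

    def test_single_parameter_matches_grid_search(self):
        events = sim_events("const", {"p0": 0.13}, n_steps=500, seed=5)
        fit = fit_mle("const", events, seed=0, compute_marginal=False)
        grid = np.linspace(EPS, 1 - EPS, 10_001)
        model = get_model("const")
        lls = [sequence_loglik(model, {"p0": g}, events) for g in grid]
        g_best = grid[int(np.argmax(lls))]
        assert abs(fit.params["p0"] - g_best) <= (grid[1] - grid[0])
        assert fit.log_likelihood >= max(lls) - 1e-9

    def test_degenerate_all_zero_hits_lower_bound(self):
        events = hand_events(np.zeros(200, dtype=int), np.full(200, 2.0))
        fit = fit_mle("const", events, compute_marginal=False)
        assert fit.params["p0"] <= 1e-8

    def test_zone_width_recovery(self):
        truth = {"p0": 0.02, "p1": 0.15, "w": 1.1}
        events = sim_events("zone", truth, n_steps=4000, seed=6)
        fit = fit_mle("zone", events, compute_marginal=False)
        assert abs(fit.params["w"] - truth["w"]) < 0.1
        assert fit.params["p1"] == pytest.approx(truth["p1"], abs=0.05)

    def test_nested_model_likelihood_ordering(self):
        events = sim_events("zone", {"p0": 0.02, "p1": 0.2, "w": 0.7},
                            n_steps=1500, seed=7)
        ll_const = fit_mle("const", events, compute_marginal=False).log_likelihood
        ll_mf = fit_mle("meanfield", events, compute_marginal=False).log_likelihood
        ll_zone = fit_mle("zone", events, compute_marginal=False).log_likelihood
        ll_d1 = fit_mle("d1", events, compute_marginal=False).log_likelihood
        assert ll_mf >= ll_const - 1e-6
        assert ll_zone >= ll_const - 1e-6
        assert ll_d1 >= ll_zone - 1e-6  # d1 with tau=1 contains the zone model


class TestLaplaceMarginal:
    def test_bernoulli_matches_exact_beta_integral(self):
        rng = np.random.default_rng(8)
        n, p = 1000, 0.23
        y = (rng.random(n) < p).astype(int)
        events = hand_events(y, np.full(n, 2.0))
        fit = fit_mle("const", events, compute_marginal=False)
        value, fb = log_marginal_laplace(fit, get_model("const"), events)
        s = int(y.sum())
        exact = betaln(s + 1, n - s + 1)  # uniform-prior Bernoulli evidence
        assert not fb
        assert value == pytest.approx(exact, abs=0.1)

    def test_bic_and_laplace_agree_at_large_n(self):
        rng = np.random.default_rng(9)
        for n in (500, 5000):
            y = (rng.random(n) < 0.1).astype(int)
            events = hand_events(y, np.full(n, 2.0))
            fit = fit_mle("const", events, compute_marginal=False)
            value, fb = log_marginal_laplace(fit, get_model("const"), events)
            assert abs(value - (-fit.bic / 2)) < 0.5 * np.log(n)

    def test_useless_parameter_lowers_marginal(self):
        """Occam: the nested constant-rate model beats mean-field with k=0 truth."""
        wins = 0
        for seed in range(20):
            events = sim_events("const", {"p0": 0.08}, n_steps=600, seed=seed)
            f1 = fit_mle("const", events)
            f2 = fit_mle("meanfield", events)
            wins += f1.log_marginal > f2.log_marginal
        assert wins >= 14

    def test_identical_models_zero_bayes_factor(self):
        events = sim_events("const", {"p0": 0.1}, n_steps=300, seed=11)
        f1 = fit_mle("const", events)
        f2 = fit_mle("const", events)
        assert f1.log_marginal == pytest.approx(f2.log_marginal)


class TestRanking:
    def test_zone_data_prefers_zone_over_meanfield(self):
        wins = 0
        for seed in range(10):
            events = sim_events("zone", {"p0": 0.02, "p1": 0.15, "w": 1.0},
                                n_steps=2000, seed=seed)
            table = rank_models(["meanfield", "zone"], events, seed=seed)
            order = [r.model for r in table.results]
            wins += order[0] == "zone"
        assert wins >= 9

    def test_memory_data_selects_local_nonmarkovian(self):
        events = sim_events("d1", {"p0": 0.01, "p1": 0.15, "w": np.pi / 5, "tau": 5},
                            n_steps=4000, seed=13)
        table = rank_models(["meanfield", "zone", "d1", "d2"], events, seed=0)
        assert table.best.model in ("d1", "d2")
        assert table.best.params["w"] < np.pi / 2
        bf = table.log_bayes_factor_vs("meanfield")
        assert bf[table.best.model] > 0

    def test_permutation_invariance(self):
        events = sim_events("zone", {"p0": 0.02, "p1": 0.2, "w": 0.8},
                            n_steps=800, seed=14)
        a = rank_models(["meanfield", "zone", "d1"], events, seed=5)
        b = rank_models(["d1", "meanfield", "zone"], events, seed=5)
        assert [r.model for r in a.results] == [r.model for r in b.results]
        for ra, rb in zip(a.results, b.results):
            assert ra.log_likelihood == pytest.approx(rb.log_likelihood, abs=1e-6)


class TestSwitchProfile:
    def test_constant_rate_flat_profile(self):
        events = sim_events("const", {"p0": 0.1}, n_steps=3000, seed=15)
        table = switch_probability_profile(events)
        filled = table[~table["empty"]]
        overall = events.y.mean()
        assert ((filled["ci_low"] < overall) & (overall < filled["ci_high"])).mean() >= 0.7
        assert (filled["rate"] - overall).abs().max() < 0.05

    def test_zone_data_elevated_only_inside_zone(self):
        w = 0.6
        events = sim_events("zone", {"p0": 0.02, "p1": 0.3, "w": w},
                            n_steps=4000, seed=16)
        bins = np.array([-np.pi, -w, 0.0, w, np.pi])
        table = switch_probability_profile(events, bins=bins)
        inside = table.iloc[2]
        outside = table.iloc[[0, 1, 3]]
        assert inside["rate"] > outside["rate"].max() + 0.05

    def test_mirrored_events_mirror_profile(self):
        events = sim_events("zone", {"p0": 0.02, "p1": 0.3, "w": 0.6},
                            n_steps=1000, seed=17)
        mirrored = SwitchEventSequence(
            agent=events.agent, t_index=events.t_index, y=events.y,
            f_opp=events.f_opp, fwd_opp=events.fwd_opp, abs_opp=events.abs_opp,
            nearest_opp=-events.nearest_opp,
        )
        bins = np.linspace(-np.pi, np.pi, 9)
        a = switch_probability_profile(events, bins=bins)
        b = switch_probability_profile(mirrored, bins=bins)
        # bin edges are symmetric, so rates should appear in reverse order
        ra = a["rate"].to_numpy()
        rb = b["rate"].to_numpy()[::-1]
        np.testing.assert_allclose(ra, rb, equal_nan=True)


class TestForceMatching:
    def test_exact_recovery_noise_free(self):
        cfg = VicsekConfig(n=12, box=8.0, radius=2.0, speed=0.3, n_steps=40, seed=18)
        traj = simulate_interaction({"alignment": 0.4}, cfg, noise_sd=0.0)
        table = force_matching_fit(traj, {"align": ["alignment"]},
                                   radius=2.0, box=8.0)
        row = table.iloc[0]
        assert row["beta_alignment"] == pytest.approx(0.4, abs=1e-8)
        assert row["rss"] == pytest.approx(0.0, abs=1e-12)

    def test_wrong_model_rejected_in_noisy_replicates(self):
        wins = 0
        reps = 40
        for seed in range(reps):
            cfg = VicsekConfig(n=10, box=8.0, radius=2.0, speed=0.3,
                               n_steps=25, seed=100 + seed)
            traj = simulate_interaction({"alignment": 0.5}, cfg, noise_sd=0.1)
            table = force_matching_fit(
                traj,
                {"true": ["alignment"], "wrong": ["attraction"]},
                radius=2.0, box=8.0,
            ).set_index("model")
            wins += table.loc["true", "rss"] < table.loc["wrong", "rss"]
        assert wins / reps >= 0.95

    def test_standard_error_scales_inverse_sqrt_n(self):
        def se_at(T, seed):
            cfg = VicsekConfig(n=10, box=8.0, radius=2.0, speed=0.3,
                               n_steps=T, seed=seed)
            traj = simulate_interaction({"alignment": 0.5}, cfg, noise_sd=0.2)
            t = force_matching_fit(traj, {"m": ["alignment"]}, radius=2.0, box=8.0)
            return t["se_alignment"].iloc[0]

        short = np.mean([se_at(26, s) for s in range(12)])
        long = np.mean([se_at(101, s) for s in range(12)])
        assert long == pytest.approx(short / 2.0, rel=0.35)


class TestRecoveryHarness:
    def test_bias_shrinks_with_longer_series(self):
        kw = dict(n_agents=8, init="half")
        truth = {"p0": 0.03, "p1": 0.2, "w": 0.9}
        short = recovery_harness("zone", truth, {**kw, "n_steps": 400},
                                 n_reps=6, seed=1)
        long = recovery_harness("zone", truth, {**kw, "n_steps": 4000},
                                n_reps=6, seed=1)
        rs = short.set_index("parameter")["rmse"]
        rl = long.set_index("parameter")["rmse"]
        assert (rl <= rs + 0.02).all()
        assert rl["w"] < rs["w"] + 1e-9

    def test_report_schema(self):
        table = recovery_harness("const", {"p0": 0.1},
                                 {"n_agents": 2, "n_steps": 200}, n_reps=3, seed=2)
        assert set(table.columns) == {
            "parameter", "truth", "mean_estimate", "bias", "rmse", "n_reps"
        }
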