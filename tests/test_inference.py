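"""Hierarchical and MAP estimation: transforms, likelihood, sampling."""

import warnings

import numpy as np
import pandas as pd
import pytest

from revlearn.cohort import GenerativeConfig, generate_cohort
from revlearn.inference import (
    BETA_MAX,
    MCMCConfig,
    PosteriorSummary,
    batch_log_likelihood,
    convergence_check,
    fit_hierarchical,
    fit_individual_map,
    from_native,
    pack_sessions,
    posterior_predictive,
    to_native,
)
from revlearn.model import AgentParameters, RLPolicy, session_log_likelihood
from revlearn.task import TaskConfig, run_session


class TestTransforms:
    def test_zero_maps_to_midpoints(self):
        p = to_native(np.zeros(3))
        assert p.alpha_pos == pytest.approx(0.5)
        assert p.alpha_neg == pytest.approx(0.5)
        assert p.beta == pytest.approx(BETA_MAX / 2)

    def test_round_trip_group_means(self):
        p = AgentParameters(0.72, 0.54, 1.36)
        q = to_native(from_native(p))
        assert q.alpha_pos == pytest.approx(0.72, abs=1e-10)
        assert q.alpha_neg == pytest.approx(0.54, abs=1e-10)
        assert q.beta == pytest.approx(1.36, abs=1e-10)

    def test_boundary_values_rejected(self):
        with pytest.raises(ValueError):
            from_native(AgentParameters(0.0, 0.5, 1.0))
        with pytest.raises(ValueError):
            from_native(AgentParameters(0.5, 0.5, BETA_MAX))


class TestBatchLikelihood:
    def test_matches_per_session_implementation(self, simulated_sessions):
        """The sampler's vectorised likelihood must equal the reference
        trial-loop implementation session by session."""
        data = pack_sessions(simulated_sessions)
        for params in [
            AgentParameters(0.72, 0.54, 1.36),
            AgentParameters(0.9, 0.1, 6.0),
            AgentParameters(0.05, 0.95, 0.2),
        ]:
            P = len(simulated_sessions)
            batch = batch_log_likelihood(
                *data,
                np.full(P, params.alpha_pos),
                np.full(P, params.alpha_neg),
                np.full(P, params.beta),
            )
            ref = [session_log_likelihood(s, params) for s in simulated_sessions]
            assert np.allclose(batch, ref, atol=1e-10)

    def test_compiled_kernel_matches_numpy_path(self, simulated_sessions):
        from revlearn.inference import _theta_log_likelihood

        data = pack_sessions(simulated_sessions)
        P = len(simulated_sessions)
        theta = np.tile(from_native(AgentParameters(0.6, 0.4, 2.0)), (P, 1))
        fast = _theta_log_likelihood(data, theta)
        slow = batch_log_likelihood(*data, np.full(P, 0.6), np.full(P, 0.4), np.full(P, 2.0))
        assert np.allclose(fast, slow, atol=1e-10)

    def test_censoring_masks_trials(self, simulated_sessions):
        import dataclasses

        sessions = [
            dataclasses.replace(
                s,
                trials=[dataclasses.replace(s.trials[0], responded=False)]
                + list(s.trials[1:]),
            )
            for s in simulated_sessions
        ]
        _, _, mask = pack_sessions(sessions, censor_nonresponse=True)
        assert (~mask[:, 0]).all() and mask[:, 1:].all()

    def test_unequal_lengths_rejected(self, simulated_sessions, toy_session):
        with pytest.raises(ValueError):
            pack_sessions([simulated_sessions[0], toy_session])


class TestConvergenceCheck:
    def _summary(self, rhat):
        return PosteriorSummary(
            individual=pd.DataFrame(), group=pd.DataFrame(), rhat=rhat, ess={},
            config=MCMCConfig(),
        )

    def test_all_below_threshold_passes(self):
        ok, offenders = convergence_check(self._summary({"mu": np.array([1.0, 1.002])}), 1.01)
        assert ok and offenders == []

    def test_offender_named(self):
        ok, offenders = convergence_check(
            self._summary({"mu": np.array([1.0, 1.05]), "sigma": np.array([1.0])}), 1.01
        )
        assert not ok and offenders == ["mu[1]"]

    def test_missing_diagnostics_rejected(self):
        with pytest.raises(ValueError):
            convergence_check(self._summary({}), 1.01)


class TestIndividualMAP:
    def test_long_session_recovers_truth(self):
        truth = AgentParameters(0.6, 0.3, 3.0)
        rng = np.random.default_rng(17)
        sess = run_session(RLPolicy(truth, rng), TaskConfig(n_trials=500), rng=rng)
        est, logpost = fit_individual_map(sess, n_restarts=5, seed=0)
        assert est.alpha_pos == pytest.approx(truth.alpha_pos, abs=0.15)
        assert est.alpha_neg == pytest.approx(truth.alpha_neg, abs=0.15)
        assert 0.0 < est.beta < BETA_MAX  # interior optimum
        assert np.isfinite(logpost)


@pytest.fixture(scope="module")
def small_fit():
    """15-participant hierarchical fit shared across sampler tests."""
    cohort, sessions = generate_cohort(GenerativeConfig(n_participants=15), seed=33)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = fit_hierarchical(
            sessions, MCMCConfig(n_chains=2, n_warmup=400, n_samples=400, seed=8)
        )
    return cohort, sessions, summary


class TestHierarchicalFit:
    def test_summary_shapes_and_bounds(self, small_fit):
        _, sessions, summary = small_fit
        assert len(summary.individual) == len(sessions)
        for name in ("alpha_pos", "alpha_neg"):
            assert summary.individual[f"{name}_mean"].between(0, 1).all()
            assert (
                summary.individual[f"{name}_ci_low"]
                <= summary.individual[f"{name}_mean"]
            ).all()
        assert summary.individual["beta_mean"].between(0, BETA_MAX).all()
        assert set(summary.group["parameter"]) == {"alpha_pos", "alpha_neg", "beta"}

    def test_rhat_reported_for_every_quantity(self, small_fit):
        _, sessions, summary = small_fit
        assert set(summary.rhat) == {
            "alpha_pos", "alpha_neg", "beta",
            "mu_alpha_pos", "mu_alpha_neg", "mu_beta",
            "sigma_alpha_pos", "sigma_alpha_neg", "sigma_beta",
        }
        for name in ("alpha_pos", "alpha_neg", "beta"):
            assert summary.rhat[name].shape == (len(sessions),)
        assert np.isfinite(summary.max_rhat())

    def test_posterior_means_track_map_estimates(self, small_fit):
        """Cross-method consistency: the hierarchical posterior means and
        the non-hierarchical MAP estimates must agree in ordering."""
        _, sessions, summary = small_fit
        maps = [fit_individual_map(s, n_restarts=3, seed=1)[0] for s in sessions]
        est = summary.individual
        r = np.corrcoef([m.beta for m in maps], est["beta_mean"])[0, 1]
        assert r > 0.5
        r_neg = np.corrcoef([m.alpha_neg for m in maps], est["alpha_neg_mean"])[0, 1]
        assert r_neg > 0.0

    def test_partial_pooling_shrinks_toward_group_mean(self, small_fit):
        """Individual posterior means sit between the (nearly unpooled)
        MAP estimate and the group mean on the unconstrained scale, for
        a clear majority of participant-parameter pairs."""
        _, sessions, summary = small_fit
        theta = summary.draws["theta"]  # (chains, draws, P, 3)
        mu = summary.draws["mu"]
        maps = [
            from_native(fit_individual_map(s, n_restarts=3, seed=2, prior_scale=5.0)[0])
            for s in sessions
        ]
        shrunk, total = 0, 0
        for k in range(3):
            mu_mean = mu[..., k].mean()
            for i in range(len(sessions)):
                post = theta[:, :, i, k].mean()
                lo, hi = sorted((maps[i][k], mu_mean))
                shrunk += (lo - 0.05) <= post <= (hi + 0.05)
                total += 1
        assert shrunk >= 0.75 * total

    def test_identical_sessions_shrink_group_scale(self, small_fit):
        import dataclasses

        _, sessions, summary = small_fit
        clones = [
            dataclasses.replace(sessions[0], participant_id=f"c{i}") for i in range(12)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clone_fit = fit_hierarchical(
                clones, MCMCConfig(n_chains=2, n_warmup=300, n_samples=300, seed=3)
            )
        scale_clone = clone_fit.group.set_index("parameter").loc["beta", "group_scale"]
        scale_hetero = summary.group.set_index("parameter").loc["beta", "group_scale"]
        assert scale_clone < scale_hetero

    def test_too_few_sessions_rejected(self, simulated_sessions):
        with pytest.raises(ValueError):
            fit_hierarchical(simulated_sessions[:1], MCMCConfig(seed=0))


class TestPosteriorPredictive:
    def _summary_at(self, params_list):
        rows = []
        for i, p in enumerate(params_list):
            rows.append(
                {
                    "participant_id": f"p{i}",
                    "alpha_pos_mean": p.alpha_pos,
                    "alpha_neg_mean": p.alpha_neg,
                    "beta_mean": p.beta,
                }
            )
        return PosteriorSummary(
            individual=pd.DataFrame(rows), group=pd.DataFrame(),
            rhat={"mu": np.array([1.0])}, ess={}, config=MCMCConfig(),
        )

    def test_chance_level_for_random_agents(self):
        summary = self._summary_at([AgentParameters(0.5, 0.5, 0.0)] * 20)
        sim = posterior_predictive(summary, TaskConfig(), n_reps=5, seed=0)
        assert sim["accuracy"].mean() == pytest.approx(0.5, abs=0.03)

    def test_seeded_reproducibility(self):
        summary = self._summary_at([AgentParameters(0.7, 0.5, 1.4)] * 5)
        a = posterior_predictive(summary, TaskConfig(), n_reps=3, seed=11)
        b = posterior_predictive(summary, TaskConfig(), n_reps=3, seed=11)
        pd.testing.assert_frame_equal(a, b)
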