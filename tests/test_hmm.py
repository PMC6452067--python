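"""Movement HMM: track preparation, forward/Viterbi enumeration oracles,
covariate transitions, model selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sonarcee import hmm
from sonarcee import simulate as sim
from sonarcee._geo import destination


def _track_df(steps, turns, ttr=None):
    df = pd.DataFrame({"step_km": steps, "turn_rad": turns})
    if ttr is not None:
        df["ttr_h"] = ttr
    return df


# -----------------------------------------------------------------------------
# track preparation


class TestSpeedFilter:
    def _hourly_track(self, lats, lons):
        t = pd.date_range("2016-06-01", periods=len(lats), freq="h")
        return pd.DataFrame({"time": t, "lat": lats, "lon": lons})

    def test_teleporting_fix_removed(self):
        lats = [71.0, 71.01, 71.5, 71.02, 71.03]  # ~54 km jump and back
        tr = self._hourly_track(lats, [-7.0] * 5)
        out, removed = hmm.speed_filter(tr)
        assert len(removed) == 1
        assert 71.5 not in out["lat"].to_numpy()

    def test_slow_track_unchanged(self):
        lats = 71.0 + 0.01 * np.arange(6)
        tr = self._hourly_track(lats, [-7.0] * 6)
        out, removed = hmm.speed_filter(tr)
        assert removed == [] and len(out) == 6

    def test_generator_outliers_exactly_removed(self):
        cfg = sim.SimConfig(seed=13, duration_h=72.0)
        tr, truth = sim.make_sat_track(cfg, n_steps=72, outlier_count=3)
        out, removed = hmm.speed_filter(tr)
        assert sorted(tr.index.get_loc(i) for i in removed) == \
            truth.extras["outlier_idx"].tolist()

    def test_all_removed_is_error(self):
        lats = [71.0, 75.0]
        tr = self._hourly_track(lats, [-7.0, -7.0])
        with pytest.raises(ValueError):
            hmm.speed_filter(tr)


class TestStepsTurns:
    def test_collinear_points_zero_turns(self):
        lat = 71.0 + 0.02 * np.arange(6)
        hourly = pd.DataFrame({"time": pd.date_range("2016-06-01", periods=6, freq="h"),
                               "lat": lat, "lon": np.full(6, -7.0)})
        st = hmm.steps_turns(hourly)
        assert np.allclose(st["turn_rad"].dropna(), 0.0, atol=1e-9)

    def test_left_turn_is_positive_half_pi(self):
        # north, then west (a 90-degree left turn in the local plane)
        p0 = (71.0, -7.0)
        p1 = destination(*p0, 0.0, 2.0)
        p2 = destination(*p1, -np.pi / 2, 2.0)
        hourly = pd.DataFrame({"lat": [p0[0], p1[0], p2[0]],
                               "lon": [p0[1], p1[1], p2[1]]})
        st = hmm.steps_turns(hourly)
        assert st["turn_rad"].iloc[1] == pytest.approx(np.pi / 2, abs=1e-3)

    def test_latitude_degree_hundredth_step(self):
        hourly = pd.DataFrame({"lat": [71.0, 71.01], "lon": [-7.0, -7.0]})
        st = hmm.steps_turns(hourly)
        assert st["step_km"].iloc[0] == pytest.approx(1.112, abs=1e-3)

    def test_missing_positions_propagate(self):
        hourly = pd.DataFrame({"lat": [71.0, np.nan, 71.02, 71.03],
                               "lon": [-7.0, -7.0, -7.0, -7.0]})
        st = hmm.steps_turns(hourly)
        assert np.isnan(st["step_km"].iloc[0]) and np.isnan(st["step_km"].iloc[1])
        assert np.isfinite(st["step_km"].iloc[2])


class TestTimeToRecovery:
    def test_maximum_at_exposure_step(self):
        assert hmm.time_to_recovery(np.array([10.0]), 10.0)[0] == 8.0

    def test_linear_decay(self):
        assert hmm.time_to_recovery(np.array([14.0]), 10.0)[0] == 4.0
        assert hmm.time_to_recovery(np.array([18.0]), 10.0)[0] == 0.0

    def test_zero_before_exposure(self):
        assert (hmm.time_to_recovery(np.arange(0.0, 10.0), 10.0) == 0.0).all()


# -----------------------------------------------------------------------------
# enumeration oracles


def _enumerate_loglik(logb, P, pi):
    """Exhaustive path-sum likelihood for short sequences."""
    T, S = logb.shape
    total = 0.0
    for path in itertools.product(range(S), repeat=T):
        p = pi[path[0]] * np.exp(logb[0, path[0]])
        for t in range(1, T):
            p *= P[t, path[t - 1], path[t]] * np.exp(logb[t, path[t]])
        total += p
    return np.log(total)


def _enumerate_viterbi(logb, P, pi):
    T, S = logb.shape
    best, arg = -np.inf, None
    for path in itertools.product(range(S), repeat=T):
        lp = np.log(pi[path[0]]) + logb[0, path[0]]
        for t in range(1, T):
            lp += np.log(P[t, path[t - 1], path[t]]) + logb[t, path[t]]
        if lp > best:
            best, arg = lp, path
    return np.array(arg)


class TestForwardOracle:
    def test_two_state_hand_set_parameters(self, rng):
        """Forward likelihood equals the exhaustive sum over all 2^4 paths."""
        logb = rng.normal(-1.0, 0.5, (4, 2))
        P0 = np.array([[0.7, 0.3], [0.4, 0.6]])
        P = np.tile(P0, (4, 1, 1))
        pi = np.array([0.5, 0.5])
        got = hmm._forward(logb, P, pi)
        expect = _enumerate_loglik(logb, P, pi)
        assert got == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("T", [2, 5, 8])
    def test_three_state_time_varying_transitions(self, rng, T):
        logb = rng.normal(-2.0, 1.0, (T, 3))
        P = rng.dirichlet(np.ones(3), size=(T, 3))
        pi = rng.dirichlet(np.ones(3))
        got = hmm._forward(logb, P, pi)
        expect = _enumerate_loglik(logb, P, pi)
        assert got == pytest.approx(expect, rel=1e-10)

    def test_model_loglike_matches_enumeration(self, rng):
        """Full model path (obs densities + covariate transitions) against
        the exhaustive oracle on a length-6 track."""
        truth = sim.HmmTruth(recovery_coef=np.array([0.3, 0.5]))
        states, steps, turns = sim.simulate_step_turn(truth, 6, rng)
        ttr = np.array([0.0, 0.0, 8.0, 7.0, 6.0, 5.0])
        m = hmm.MovementHMM([_track_df(steps, turns, ttr)], "recovery")
        p = hmm.HmmParams(truth.step_mean_km, truth.step_sd_km, truth.turn_mean,
                          truth.turn_kappa, truth.tpm_logits,
                          truth.recovery_coef[None, :] * 0 + 0.4)
        logb = hmm.obs_logdensities(steps, turns, p)
        P = p.transition_matrices(m._X[0])
        expect = _enumerate_loglik(logb, P, p.stationary())
        assert m.loglike(p) == pytest.approx(expect, rel=1e-10)

    def test_permutation_invariance_of_forward(self, rng):
        logb = rng.normal(-1.0, 1.0, (6, 3))
        P = rng.dirichlet(np.ones(3), size=(6, 3))
        pi = rng.dirichlet(np.ones(3))
        perm = np.array([2, 0, 1])
        ll = hmm._forward(logb, P, pi)
        llp = hmm._forward(logb[:, perm], P[:, perm][:, :, perm], pi[perm])
        assert ll == pytest.approx(llp, rel=1e-12)


class TestViterbiOracle:
    def test_three_step_toy_matches_brute_force(self, rng):
        for _ in range(5):
            logb = rng.normal(-1.0, 1.5, (3, 3))
            P = rng.dirichlet(np.ones(3), size=(3, 3))
            pi = rng.dirichlet(np.ones(3))
            got = hmm._viterbi(logb, np.log(P), np.log(pi))
            expect = _enumerate_viterbi(logb, P, pi)
            assert np.array_equal(got, expect)

    def test_tie_broken_toward_lower_state(self):
        logb = np.zeros((3, 2))
        P = np.tile(np.full((2, 2), 0.5), (3, 1, 1))
        pi = np.array([0.5, 0.5])
        path = hmm._viterbi(logb, np.log(P), np.log(pi))
        assert (path == 0).all()

    def test_single_state_model_constant_path(self, rng):
        steps = rng.gamma(4.0, 0.5, 30)
        turns = rng.vonmises(0.0, 2.0, 30)
        p = hmm.HmmParams(
            step_mean=np.array([2.0, 2.0, 2.0]), step_sd=np.array([1.0, 1.0, 1.0]),
            turn_mean=np.zeros(3), turn_kappa=np.array([2.0, 2.0, 2.0]),
            tpm_logits=np.array([[0.0, -99.0, -99.0], [0.0, -99.0, -99.0],
                                 [0.0, -99.0, -99.0]]),
        )
        m = hmm.MovementHMM([_track_df(steps, turns)], "none")
        res = hmm.MovementHMMResults(m, p, m.loglike(p),
                                     type("R", (), {"success": True})())
        assert (res.viterbi()[0] == 1).all()


# -----------------------------------------------------------------------------
# transition structure


class TestTransitions:
    def test_row_stochastic_at_all_covariate_values(self, rng):
        p = hmm.HmmParams(np.array([0.5, 1.8, 4.5]), np.array([0.3, 0.9, 1.5]),
                          np.zeros(3), np.array([0.5, 4.0, 12.0]),
                          rng.normal(0, 1, (3, 3)) * (1 - np.eye(3)),
                          coefs=rng.normal(0, 1, (2, 2)))
        X = np.column_stack([rng.uniform(0, 8, 50), rng.normal(0, 1, 50)])
        P = p.transition_matrices(X)
        assert np.allclose(P.sum(axis=2), 1.0)
        assert (P >= 0).all()

    def test_covariates_act_only_on_state_one_row(self, rng):
        p = hmm.HmmParams(np.array([0.5, 1.8, 4.5]), np.array([0.3, 0.9, 1.5]),
                          np.zeros(3), np.ones(3),
                          np.where(np.eye(3, dtype=bool), 0.0, -1.0),
                          coefs=np.array([[2.0, 1.0]]))
        P0 = p.transition_matrices(np.array([[0.0]]))[0]
        P1 = p.transition_matrices(np.array([[5.0]]))[0]
        assert not np.allclose(P0[0], P1[0])
        assert np.allclose(P0[1:], P1[1:])

    def test_missing_observations_advance_transitions(self, rng):
        truth = sim.HmmTruth()
        _, steps, turns = sim.simulate_step_turn(truth, 20, rng)
        p = hmm.HmmParams(truth.step_mean_km, truth.step_sd_km, truth.turn_mean,
                          truth.turn_kappa, truth.tpm_logits)
        full = hmm.MovementHMM([_track_df(steps, turns)], "none").loglike(p)
        steps2, turns2 = steps.copy(), turns.copy()
        steps2[5] = np.nan
        turns2[5] = np.nan
        partial = hmm.MovementHMM([_track_df(steps2, turns2)], "none").loglike(p)
        assert np.isfinite(partial) and partial > full  # one density dropped


# -----------------------------------------------------------------------------
# fitting and selection


class TestFit:
    def test_parameter_recovery_small(self, rng):
        """State-dependent parameters recovered on 4 x 250-step tracks."""
        truth = sim.HmmTruth()
        tracks = []
        for _ in range(4):
            _, steps, turns = sim.simulate_step_turn(truth, 250, rng)
            tracks.append(_track_df(steps, turns))
        res = hmm.MovementHMM(tracks, "none").fit(n_starts=3, seed=0)
        assert np.allclose(res.params.step_mean, truth.step_mean_km, rtol=0.15)
        assert np.allclose(res.params.step_sd, truth.step_sd_km, rtol=0.3)
        assert res.converged

    def test_states_ordered_by_step_mean(self, rng):
        truth = sim.HmmTruth()
        _, steps, turns = sim.simulate_step_turn(truth, 300, rng)
        res = hmm.MovementHMM([_track_df(steps, turns)], "none").fit(n_starts=3, seed=1)
        assert (np.diff(res.params.step_mean) > 0).all()

    def test_decoding_accuracy_well_separated(self, rng):
        states, steps, turns = sim.simulate_step_turn(sim.HmmTruth(), 400, rng)
        res = hmm.MovementHMM([_track_df(steps, turns)], "none").fit(n_starts=3, seed=2)
        acc = np.mean(res.viterbi()[0] == states)
        assert acc > 0.8


class TestSelection:
    def test_simplest_within_two_rule(self):
        class Fake:
            def __init__(self, k, aic):
                self.k_params, self.aic = k, aic
                self.llf = (2 * k - aic) / 2.0

        fits = {"a": Fake(10, 100.0), "b": Fake(12, 101.5), "c": Fake(14, 108.0)}
        best, tab = hmm.select_model(fits)
        assert best == "a"
        assert tab["delta_aic"].iloc[0] == 0.0

    def test_unique_minimum_selected(self):
        class Fake:
            def __init__(self, k, aic):
                self.k_params, self.aic = k, aic
                self.llf = (2 * k - aic) / 2.0

        fits = {"a": Fake(10, 110.0), "b": Fake(12, 100.0)}
        best, _ = hmm.select_model(fits)
        assert best == "b"

    def test_no_effect_truth_keeps_baseline_model_competitive(self, rng):
        """With zero covariate coefficients in truth, the no-covariate model
        stays within delta-AIC < 2 of the recovery model."""
        truth = sim.HmmTruth()
        tracks = []
        for _ in range(4):
            ttr = hmm.time_to_recovery(np.arange(120.0), 60.0)
            _, steps, turns = sim.simulate_step_turn(truth, 120, rng, ttr)
            tracks.append(_track_df(steps, turns, ttr))
        fits = hmm.fit_candidates(tracks, models=("none", "recovery"),
                                  n_starts=3, seed=3)
        tab = hmm.select_model(fits)[1].set_index("model")
        assert tab.loc["none", "delta_aic"] < 2.0

    def test_leave_out_trivial_case_matches_main_fit(self, rng):
        truth = sim.HmmTruth()
        tracks = []
        for _ in range(3):
            _, steps, turns = sim.simulate_step_turn(truth, 80, rng)
            tracks.append(_track_df(steps, turns))
        tab = hmm.leave_out_sensitivity(tracks, max_omit=1,
                                        models=("none",), n_starts=2)
        assert not tab["changed"].any()
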