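import itertools

import numpy as np
import pytest

from revbandit.grids import HypothesisGrid, default_grid
from revbandit.observer import (MODEL1, MODEL2, BayesianObserver, BeliefState,
                                NumericalDegeneracyError, ObserverTrace,
                                OptionBelief, bayes_update, credible_width,
                                drift_kernels, kl_update, outcome_likelihood,
                                point_estimate, reversal_ev,
                                reversal_probability, transition_drift,
                                transition_reversal)
from revbandit.schedules import LEFT, RIGHT
from revbandit.session import Session

G2 = default_grid("model2")
G1 = default_grid("model1")


def uniform2():
    return OptionBelief.uniform(G2)


# --- analytic anchors (exact values derivable by hand) ----------------------

def test_uniform_prior_expected_reversal_rate():
    # E[H] under uniform on 0..0.3 = 0.15
    assert abs(reversal_probability(uniform2()) - 0.15) < 1e-12


def test_uniform_prior_credible_width_exact():
    assert abs(credible_width(uniform2()) - 0.95) < 1e-12


def test_posterior_mean_after_single_outcome():
    # uniform prior on the 101-point grid, one reward:
    # E[V | x=1] = sum v^2 / sum v = 33.835 / 50.5 = 0.67 exactly
    up = bayes_update(uniform2(), 1)
    assert abs(point_estimate(up, "mean") - 0.67) < 1e-9
    down = bayes_update(uniform2(), 0)
    assert abs(point_estimate(down, "mean") - 0.33) < 1e-9


def test_posterior_mode_after_single_outcome():
    assert point_estimate(bayes_update(uniform2(), 1), "map") == 1.0
    assert point_estimate(bayes_update(uniform2(), 0), "map") == 0.0


def test_reversal_transition_point_mass_mixture():
    # all mass at (v=0.5, h=0.3): new mass at that cell is
    # (1 - 0.3) + 0.3/101 = 0.7029702970...
    pmf = np.zeros(G2.shape)
    i = np.argmin(np.abs(G2.v_values - 0.5))
    pmf[i, -1] = 1.0
    out = transition_reversal(OptionBelief(G2, pmf))
    expected = 0.7 + 0.3 / 101
    assert abs(out.pmf[i, -1] - expected) < 1e-9
    # leaked mass is uniform over the other value cells in the same h slice
    other = np.delete(out.pmf[:, -1], i)
    assert np.allclose(other, 0.3 / 101, atol=1e-12)


def test_kl_of_identical_marginals_is_zero():
    p = uniform2().value_marginal()
    assert kl_update(p, p) == 0.0


def test_post_reward_width_matches_beta_quantiles():
    # after one reward the value marginal is Beta(2,1)-shaped; central 95%
    # width = sqrt(0.975) - sqrt(0.025) = 0.82926...
    up = bayes_update(uniform2(), 1)
    assert abs(credible_width(up) - (np.sqrt(0.975) - np.sqrt(0.025))) < 2e-3


# --- primitive properties ----------------------------------------------------

def test_outcome_likelihood_values():
    assert np.array_equal(outcome_likelihood(G2, 1), G2.v_values)
    assert np.array_equal(outcome_likelihood(G2, 0), 1.0 - G2.v_values)
    with pytest.raises(ValueError):
        outcome_likelihood(G2, 2)


def test_uniform_is_fixed_point_of_reversal_transition():
    out = transition_reversal(uniform2())
    assert np.allclose(out.pmf, uniform2().pmf, atol=1e-14)


def test_transitions_preserve_mass_and_positivity():
    rng = np.random.default_rng(0)
    for grid, trans in ((G2, transition_reversal), (G1, transition_drift)):
        pmf = rng.random(grid.shape)
        pmf /= pmf.sum()
        out = trans(OptionBelief(grid, pmf))
        assert abs(out.pmf.sum() - 1.0) < 1e-12
        assert np.all(out.pmf >= 0)


def test_drift_kernels_structure():
    k = drift_kernels(G1)
    assert k.shape == (G1.n_aux, G1.n_v, G1.n_v)
    # sigma = 0 slice is the identity
    assert np.array_equal(k[0], np.eye(G1.n_v))
    # columns are distributions
    assert np.allclose(k.sum(axis=1), 1.0, atol=1e-12)


def test_drift_transition_spreads_point_mass():
    pmf = np.zeros(G1.shape)
    pmf[50, -1] = 1.0  # v=0.5 under the largest sigma
    out = transition_drift(OptionBelief(G1, pmf))
    marg = out.value_marginal()
    assert marg[50] < 1.0
    assert marg[45] > 0 and marg[55] > 0
    # symmetric spread around the centre
    assert np.allclose(marg, marg[::-1], atol=1e-12)


def test_transition_kind_mismatch_raises():
    with pytest.raises(ValueError):
        transition_reversal(OptionBelief.uniform(G1))
    with pytest.raises(ValueError):
        transition_drift(OptionBelief.uniform(G2))


def test_bayes_update_sharpens_toward_outcome():
    b = uniform2()
    rewarded = bayes_update(b, 1)
    assert point_estimate(rewarded, "mean") > 0.5
    assert credible_width(rewarded) < credible_width(b)


def test_belief_validation():
    with pytest.raises(ValueError):
        OptionBelief(G2, np.ones(G2.shape))  # unnormalised
    with pytest.raises(ValueError):
        OptionBelief(G2, np.ones((3, 3)))


def test_degenerate_update_raises():
    pmf = np.zeros(G2.shape)
    pmf[-1, 0] = 1.0  # point mass at V=1
    with pytest.raises(NumericalDegeneracyError):
        bayes_update(OptionBelief(G2, pmf), 0)  # x=0 has zero likelihood


def test_kl_update_validation():
    p = uniform2().value_marginal()
    with pytest.raises(ValueError):
        kl_update(p, p[:-1])
    with pytest.raises(ValueError):
        kl_update(p, p * 2)
    q = p.copy()
    q[0] = 0.0
    q /= q.sum()
    # posterior with support where prior has none
    with pytest.raises(ValueError):
        kl_update(q, p)


def test_kl_update_positive_for_different():
    prior = uniform2().value_marginal()
    post = bayes_update(uniform2(), 1).value_marginal()
    assert kl_update(prior, post) > 0


def test_reversal_ev_equals_marginal_mean():
    b = bayes_update(uniform2(), 1)
    assert abs(reversal_ev(b) - point_estimate(b, "mean")) < 1e-12


# --- full observer runs ------------------------------------------------------

def _toy_session(n=8, seed=0):
    rng = np.random.default_rng(seed)
    choices = np.array([LEFT if rng.random() < 0.5 else RIGHT
                        for _ in range(n)], dtype=object)
    outcomes = rng.integers(0, 2, n)
    return Session(choices, outcomes, session_id="toy")


def test_observer_trace_shape_and_columns():
    s = _toy_session(12)
    for model in (MODEL1, MODEL2):
        tr = BayesianObserver(model).run(s)
        assert len(tr) == 12
        assert list(tr.frame.columns) == ObserverTrace.TABLE_COLUMNS
        assert tr.model_id == model
        assert (tr.frame["trial"] == np.arange(1, 13)).all()


def test_observer_first_trial_estimates_are_uniform_prior():
    s = _toy_session()
    tr = BayesianObserver(MODEL2).run(s)
    r0 = tr.frame.iloc[0]
    assert abs(r0["left_unc"] - 0.95) < 1e-9
    assert abs(r0["reversal_estimate"] - 0.15) < 1e-9


def test_observer_updates_only_chosen_option():
    s = Session(np.array([LEFT, LEFT], dtype=object), np.array([1, 1]),
                session_id="x")
    tr = BayesianObserver(MODEL2).run(s)
    r1 = tr.frame.iloc[1]
    # right option saw no outcome: its prior stays uniform
    assert abs(r1["right_unc"] - 0.95) < 1e-9
    # left option was rewarded: estimate rises, uncertainty shrinks
    assert r1["left_prob"] > 0.5
    assert r1["left_unc"] < 0.95


def test_model_specific_kl_columns():
    s = _toy_session()
    t2 = BayesianObserver(MODEL2).run(s)
    t1 = BayesianObserver(MODEL1).run(s)
    assert t2.frame["reversal_dkl"].notna().all()
    assert t2.frame["option_dkl"].isna().all()
    assert t1.frame["option_dkl"].notna().all()
    assert t1.frame["reversal_dkl"].isna().all()
    assert t1.frame["reversal_estimate"].isna().all()


def test_observer_rejects_mismatched_grid():
    with pytest.raises(ValueError):
        BayesianObserver(MODEL2, default_grid("model1"))
    with pytest.raises(ValueError):
        BayesianObserver("model3")


def test_reversal_estimate_never_leaves_aux_range():
    s = _toy_session(40, seed=3)
    tr = BayesianObserver(MODEL2).run(s)
    rev = tr.frame["reversal_estimate"]
    assert (rev >= 0).all() and (rev <= 0.3).all()


# --- brute-force oracle on a reduced grid ------------------------------------
# An independent nested-loop implementation of both observers (shared with
# the acceptance tests), compared cellwise at 1e-12 over all 64 outcome
# sequences of length 6 (choices all LEFT so every update hits one belief).

from _oracles import brute_force_observer_run as _brute_force_run  # noqa: E402


@pytest.mark.parametrize("model", [MODEL2, MODEL1])
def test_reduced_grid_brute_force_equivalence(model):
    grid = default_grid(model, n_v=11, n_aux=4)
    obs = BayesianObserver(model, grid)
    for outcomes in itertools.product((0, 1), repeat=6):
        state = obs.init_state()
        for x in outcomes:
            obs.update_with_outcome(state, LEFT, x)
            obs.transition_state(state)
        expected = _brute_force_run(grid, model, outcomes)
        np.testing.assert_allclose(state.left.pmf, expected, atol=1e-12,
                                   rtol=0)
        # the unchosen option only transitions; compare that too
        expected_right = OptionBelief.uniform(grid).pmf
        if model == MODEL2:
            np.testing.assert_allclose(state.right.pmf, expected_right,
                                       atol=1e-12)


def test_belief_state_side_handling():
    obs = BayesianObserver(MODEL2)
    st = obs.init_state()
    assert st.belief(LEFT) is st.left
    with pytest.raises(ValueError):
        st.belief("X")
    with pytest.raises(ValueError):
        st.set_belief("X", st.left)
    with pytest.raises(ValueError):
        BeliefState("model9", st.left, st.right)
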