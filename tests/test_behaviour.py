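import numpy as np
import pandas as pd
import pytest

from revbandit.behaviour import (LMEM1, LMEM2, anova_session_by_errors,
                                 build_design, consecutive_error_switch,
                                 fits_to_frame, group_contrast, holm_adjust,
                                 logistic_irls, overall_switch_rate,
                                 switch_rate_table)
from revbandit.cohorts import (simulate_correlated_cohort,
                               simulate_uncorrelated_cohort)
from revbandit.observer import MODEL1, MODEL2, BayesianObserver
from revbandit.policy import SHAM_M2, simulate_session
from revbandit.schedules import LEFT, RIGHT, gen_correlated_schedule
from revbandit.session import Session


def make_session(choices, outcomes, sid="t"):
    return Session(np.array(list(choices), dtype=object),
                   np.array(outcomes, dtype=int), session_id=sid)


# --- consecutive-error switch rates -----------------------------------------

def test_consecutive_error_toy_example():
    # L rewarded, L error, L error, switch to R: one after-1 event (stay),
    # one after-2 event (switch)
    s = make_session("LLLR", [1, 0, 0, 1])
    tab = consecutive_error_switch(s)
    r1 = tab.set_index("run_length")
    assert r1.loc[1, "n_events"] == 1 and r1.loc[1, "n_switches"] == 0
    assert r1.loc[2, "n_events"] == 1 and r1.loc[2, "n_switches"] == 1
    assert r1.loc[3, "n_events"] == 0 and np.isnan(r1.loc[3, "switch_rate"])


def test_consecutive_error_run_resets_on_reward():
    s = make_session("LLLLL", [0, 1, 0, 0, 0])
    tab = consecutive_error_switch(s).set_index("run_length")
    # errors at t=0 (run 1), reward resets, errors at t=2,3 (runs 1, 2);
    # the final trial's error cannot be scored (no next trial)
    assert tab.loc[1, "n_events"] == 2
    assert tab.loc[2, "n_events"] == 1
    assert tab.loc[1, "n_switches"] == 0


def test_consecutive_error_run_resets_on_switch():
    # error on L, switch to R, error on R: the R error is a fresh run of 1,
    # not a continuation of the L run (the final trial cannot be scored)
    s = make_session("LRRR", [0, 0, 0, 1])
    tab = consecutive_error_switch(s).set_index("run_length")
    assert tab.loc[1, "n_events"] == 2  # t=0 (L) and t=1 (first R error)
    assert tab.loc[1, "n_switches"] == 1  # only the L error led to a switch
    assert tab.loc[2, "n_events"] == 1  # RR errors ending at t=2
    assert tab.loc[3, "n_events"] == 0


def test_consecutive_error_rates_in_unit_interval():
    sched = gen_correlated_schedule(seed=2)
    s = simulate_session(sched, SHAM_M2, seed=2)
    tab = consecutive_error_switch(s)
    rates = tab["switch_rate"].dropna()
    assert ((rates >= 0) & (rates <= 1)).all()
    assert tab["n_switches"].le(tab["n_events"]).all()


def test_overall_switch_rate():
    s = make_session("LRLR", [0, 0, 0, 0])
    assert overall_switch_rate(s) == 1.0


# --- design construction -----------------------------------------------------

@pytest.fixture(scope="module")
def sim():
    sched = gen_correlated_schedule(seed=6)
    session = simulate_session(sched, SHAM_M2, seed=6, session_id="beh0")
    trace2 = BayesianObserver(MODEL2).run(session)
    trace1 = BayesianObserver(MODEL1).run(session)
    return session, trace2, trace1


def test_build_design_lmem1_layout(sim):
    session, trace2, _ = sim
    d = build_design(trace2, session, LMEM1)
    assert d.columns == ["intercept", "dprob", "dunc", "rev"]
    assert d.x.shape == (session.n_trials - 1, 4)
    assert np.array_equal(d.x[:, 0], np.ones(session.n_trials - 1))
    # standardized regressors: mean 0, sd 1
    assert np.allclose(d.x[:, 1:].mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(d.x[:, 1:].std(axis=0), 1.0, atol=1e-12)
    assert set(np.unique(d.response)) <= {0.0, 1.0}


def test_build_design_lmem2_layout(sim):
    session, trace2, _ = sim
    d = build_design(trace2, session, LMEM2)
    assert d.columns == ["intercept", "chosen_prob", "unchosen_prob",
                         "chosen_unc", "unchosen_unc", "rev"]


def test_build_design_unstandardized_regressors_referenced_to_prev(sim):
    session, trace2, _ = sim
    d = build_design(trace2, session, LMEM1, standardize=False)
    # spot-check trial t=5 (design row 4): reference is the choice at t=4
    t = 5
    prev = session.choices[t - 1]
    row = trace2.frame.iloc[t]
    ref, alt = ("left", "right") if prev == LEFT else ("right", "left")
    assert np.isclose(d.x[t - 1, 1],
                      row[f"{ref}_prob"] - row[f"{alt}_prob"])
    assert np.isclose(d.x[t - 1, 3], row[f"{ref}_rev"])
    assert d.response[t - 1] == float(session.choices[t] != prev)


def test_build_design_model1_trace_drops_rev(sim):
    session, _, trace1 = sim
    d = build_design(trace1, session, LMEM1)
    assert d.columns == ["intercept", "dprob", "dunc"]


def test_build_design_external_reversal_trace(sim):
    session, trace2, trace1 = sim
    d = build_design(trace1, session, LMEM1, reversal_trace=trace2)
    assert "rev" in d.columns


def test_build_design_errors(sim):
    session, trace2, _ = sim
    with pytest.raises(ValueError, match="variant"):
        build_design(trace2, session, "lmem3")
    short = make_session("LRLRL", [0, 1, 0, 1, 0])
    tr = BayesianObserver(MODEL2).run(short)
    with pytest.raises(ValueError, match="usable trials"):
        build_design(tr, short, LMEM1)
    other = make_session("LR" * 20, [0, 1] * 20)
    with pytest.raises(ValueError, match="aligned"):
        build_design(trace2, other, LMEM1)


def test_build_design_constant_regressor_raises():
    # deterministic all-left all-reward session makes dunc eventually vary,
    # but a 12-trial alternating zero-outcome session under Model 2 keeps
    # symmetric beliefs => dprob constant at 0
    s = make_session("LR" * 6, [0] * 12)
    tr = BayesianObserver(MODEL2).run(s)
    with pytest.raises(ValueError, match="constant"):
        build_design(tr, s, LMEM1)


# --- logistic IRLS -----------------------------------------------------------

def test_irls_matches_statsmodels_oracle(sim):
    import statsmodels.api as sm
    session, trace2, _ = sim
    d = build_design(trace2, session, LMEM1)
    fit = logistic_irls(d)
    oracle = sm.Logit(d.response, d.x).fit(disp=0)
    assert fit.converged
    np.testing.assert_allclose(fit.coef, oracle.params, atol=1e-6)
    np.testing.assert_allclose(fit.bse, oracle.bse, atol=1e-5)
    assert abs(fit.loglik - oracle.llf) < 1e-8


def test_irls_separation_flagged():
    # perfectly separable data: switch iff the regressor is positive
    rng = np.random.default_rng(0)
    x = rng.normal(size=60)
    from revbandit.behaviour import SwitchDesign
    d = SwitchDesign(session_id="sep", variant=LMEM1,
                     response=(x > 0).astype(float),
                     x=np.column_stack([np.ones(60), x]),
                     columns=["intercept", "dprob"],
                     centers=np.zeros(2), scales=np.ones(2))
    fit = logistic_irls(d)
    assert fit.separation_flag
    assert not fit.converged


def test_irls_summary_and_series(sim):
    session, trace2, _ = sim
    fit = logistic_irls(build_design(trace2, session, LMEM1))
    assert "dprob" in fit.summary()
    s = fit.to_series()
    assert list(s.index) == fit.columns
    frame = fits_to_frame([fit])
    assert set(frame["term"]) == set(fit.columns)


# --- group inference ---------------------------------------------------------

@pytest.fixture(scope="module")
def group_fits():
    obs2 = BayesianObserver(MODEL2)
    fits = []
    for s in simulate_correlated_cohort(5, n_trials=170, seed=21):
        fits.append(logistic_irls(build_design(obs2.run(s), s, LMEM1)))
    for s in simulate_uncorrelated_cohort(5, n_trials=170, seed=22):
        fits.append(logistic_irls(build_design(obs2.run(s), s, LMEM1)))
    return fits


def test_group_contrast_structure(group_fits):
    res = group_contrast(group_fits)
    assert res.n_per_group == {"correlated": 5, "uncorrelated": 5}
    assert ("correlated", "dprob") in res.per_group.index
    assert ("correlated vs uncorrelated", "rev") in res.contrasts.index
    # p-values in [0, 1]
    assert res.per_group["p_t"].between(0, 1).all()
    assert res.contrasts["p_mannwhitney"].between(0, 1).all()
    assert "Two-stage" in res.report()


def test_group_contrast_requires_three_sessions(group_fits):
    with pytest.raises(ValueError, match="too small"):
        group_contrast(group_fits[:4], labels=["a", "a", "a", "b"])


def test_group_contrast_label_mismatch(group_fits):
    with pytest.raises(ValueError, match="labels"):
        group_contrast(group_fits, labels=["a"])


def test_holm_adjustment_monotone():
    p = np.array([0.01, 0.04, 0.03, 0.9])
    adj = holm_adjust(p)
    assert np.all(adj >= p)
    assert np.all(adj <= 1)
    assert adj[0] == pytest.approx(0.04)


# --- switch-rate table and ANOVA ---------------------------------------------

def test_switch_rate_table_long_format(group_fits):
    sessions = simulate_correlated_cohort(3, n_trials=170, seed=30)
    tab = switch_rate_table(sessions)
    assert set(tab.columns) == {"session_id", "condition", "run_length",
                                "switch_rate", "n_events"}
    assert len(tab) == 9  # 3 sessions x run lengths 1..3


def test_anova_interaction_reported():
    corr = simulate_correlated_cohort(8, seed=31)
    unc = simulate_uncorrelated_cohort(8, seed=32)
    res = anova_session_by_errors(switch_rate_table(corr + unc))
    assert res["df"][0] == 2  # (2 conditions - 1) x (3 run lengths - 1)
    assert 0 <= res["p"] <= 1
    assert res["F"] >= 0
    assert isinstance(res["table"], pd.DataFrame)


def test_anova_rejects_empty_cells():
    tab = pd.DataFrame({
        "condition": ["a", "a", "b"],
        "run_length": [1, 2, 1],
        "switch_rate": [0.1, 0.2, 0.3],
    })
    with pytest.raises(ValueError, match="empty cells"):
        anova_session_by_errors(tab)
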