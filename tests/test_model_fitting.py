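"""Window segmentation, the model likelihoods (against a naive oracle),
the profile fitter, BIC, and random-effects model selection."""

import numpy as np
import pandas as pd
import pytest

import huntswitch as hs
from huntswitch import model_fitting as mf
from huntswitch.movement_models import (
    JOYSTICK_ACTIONS, KEYBOARD_ACTIONS, ModelParams, action_probabilities,
    predict_agent_position)


def make_trial(n_frames, rng=None, still_prefix=0, speed=0.006):
    """A trial whose player moves every frame (after an optional still
    prefix) and whose agent wanders smoothly."""
    rng = rng or np.random.default_rng(0)
    player = [np.zeros(2)]
    ang = 0.0
    for _ in range(n_frames - 1):
        if len(player) <= still_prefix:
            player.append(player[-1])
        else:
            ang += rng.normal(0, 0.4)
            player.append(player[-1] +
                          speed * np.array([np.cos(ang), np.sin(ang)]))
    agent = [np.array([0.2, 0.0])]
    aang = rng.uniform(0, 2 * np.pi)
    for _ in range(n_frames - 1):
        aang += rng.normal(0, 0.2)
        agent.append(agent[-1] + 0.004 * np.array([np.cos(aang), np.sin(aang)]))
    return hs.TrialLog(
        subject_id="s0", run_id=0, trial_index=0, condition=hs.HUNT,
        is_switch=False, player_xy=np.array(player), agent_xy=np.array(agent),
        boost_active=np.zeros(n_frames, bool), outcome="failure",
        terminated_by_capture=False, pre_encounter_xy=np.empty((0, 2)))


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------

@pytest.mark.parametrize("n_actions,expected", [
    (90, 5),    # starts 0, 15, 30, 45, 60
    (30, 1),
    (20, 0),
])
def test_window_counts(n_actions, expected):
    trial = make_trial(n_actions + 1)
    wins = hs.segment_windows(trial)
    assert len(wins) == expected
    for i, w in enumerate(wins):
        assert w.start == i * mf.WINDOW_STEP
        assert w.n_frames == 30


def test_windows_start_at_movement_onset():
    trial = make_trial(41, still_prefix=10)
    wins = hs.segment_windows(trial)
    assert len(wins) == 1
    assert wins[0].start == 10
    assert wins[0].anchor_offset == 0
    null = JOYSTICK_ACTIONS.null_index
    assert wins[0].actions[0] != null


def test_no_movement_no_windows():
    trial = make_trial(60, still_prefix=60)
    assert hs.segment_windows(trial) == []


# --------------------------------------------------------------------------
# likelihood vs. naive oracle
# --------------------------------------------------------------------------

def naive_negloglik(window, model_id, params):
    """Frame-by-frame reimplementation using only the public model API."""
    aset = window.action_set
    n = window.n_frames
    o = window.hist_offset
    total = 0.0
    cadence = max(1, int(round(params.theta)))
    first = (-window.anchor_offset) % cadence
    planned = int(window.actions[0])
    for j in range(n):
        hist = window.agent_xy[:o + j + 1]
        if model_id == "M1":
            is_decision, theta = True, 1.0
        elif model_id == "M2":
            is_decision, theta = True, 1.0
        else:
            is_decision = (j - first) % cadence == 0 and j >= first
            theta = params.theta
        obs = int(window.actions[j])
        if is_decision:
            y_pred = predict_agent_position(hist, theta, model_id)
            p = action_probabilities(window.player_xy[j], y_pred,
                                     window.condition, aset, window.speed,
                                     params.tau)[obs]
            planned = obs
        else:
            p = params.mu * (obs == planned) + (1 - params.mu) / aset.size
        total -= np.log(max(p, 1e-300))
    return total


def test_negloglik_matches_naive_oracle():
    rng = np.random.default_rng(3)
    trial = make_trial(140, rng=rng)
    wins = hs.segment_windows(trial)
    count = 0
    for w in wins * 5:
        model = ("M1", "M2", "M3")[count % 3]
        params = ModelParams(theta=float(rng.uniform(1, 29)),
                             tau=float(rng.uniform(-300, 300)),
                             mu=float(rng.uniform(0.05, 0.95)))
        ours = hs.window_negloglik(w, model, params)
        oracle = naive_negloglik(w, model, params)
        assert ours == pytest.approx(oracle, abs=1e-9)
        count += 1
    assert count >= 40


def test_m3_lag_degrades_gracefully_at_trial_start():
    """Windows at the very start of a trial (no lag history) are still
    scorable: velocity/acceleration fall back to zero."""
    trial = make_trial(31)
    w = hs.segment_windows(trial)[0]
    params = ModelParams(theta=25.0, tau=50.0, mu=0.5)
    nll = hs.window_negloglik(w, "M3", params)
    assert np.isfinite(nll)
    assert nll == pytest.approx(naive_negloglik(w, "M3", params), abs=1e-9)


def test_intermediate_frame_contributions():
    # mu = 0.5, |A| = 9: match -> -ln(0.5 + 0.5/9); miss -> -ln(0.5/9)
    assert mf._nll_intermediate(1, 1, 0.5, 9) == \
        pytest.approx(-np.log(0.5 + 0.5 / 9), abs=1e-12)
    assert mf._nll_intermediate(1, 0, 0.5, 9) == \
        pytest.approx(-np.log(0.5 / 9), abs=1e-12)
    assert mf._nll_intermediate(1, 1, 0.5, 9) == pytest.approx(0.5878, abs=2e-4)
    assert mf._nll_intermediate(1, 0, 0.5, 9) == pytest.approx(2.890, abs=1e-3)
    # full momentum and all matches: zero nats
    assert mf._nll_intermediate(10, 10, 1.0, 9) == 0.0


def test_full_momentum_intermediates_contribute_zero():
    trial = make_trial(60)
    w = hs.segment_windows(trial)[0]
    # force intermediates to repeat the planned action
    cadence = 6
    acts = w.actions.copy()
    for j in range(len(acts)):
        if j % cadence != 0:
            acts[j] = acts[(j // cadence) * cadence]
    w.actions = acts
    p = ModelParams(theta=6.0, tau=10.0, mu=1.0)
    dec = mf._decision_frames(30, 6, w.anchor_offset)
    v, a = mf._lagged_kinematics(w, 6)
    q = mf._q_matrix(w, dec, v, a, 6.0)
    assert hs.window_negloglik(w, "M3", p) == \
        pytest.approx(mf._nll_decision(q, w.actions[dec], 10.0), abs=1e-9)


# --------------------------------------------------------------------------
# BIC
# --------------------------------------------------------------------------

def test_model_bic_values():
    assert hs.model_bic(10.0, 3, 30) == pytest.approx(20 + 3 * np.log(30))
    assert hs.model_bic(10.0, 3, 30) == pytest.approx(30.204, abs=1e-3)
    assert hs.model_bic(7.0, 0, 30) == 14.0
    assert hs.model_bic(20.0, 2, 50) - hs.model_bic(10.0, 2, 50) == \
        pytest.approx(20.0)
    with pytest.raises(ValueError):
        hs.model_bic(1.0, 1, 0)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def m3_windows():
    """Windows simulated from a known M3 parameterization."""
    truth = ModelParams(theta=12.0, tau=300.0, mu=0.8)
    pol = hs.MovementPolicy("M3", truth)
    cfg = hs.SessionConfig(n_trials=60, main_duration_range=(2.0, 2.0))
    ses = hs.run_session(cfg, pol, np.random.default_rng(21))
    wins = []
    for tr in ses.trials:
        wins += hs.segment_windows(tr)
    return truth, wins


def test_fit_window_deterministic(m3_windows):
    _, wins = m3_windows
    a = hs.fit_window(wins[0], "M3")
    b = hs.fit_window(wins[0], "M3")
    assert a == b


def test_fitted_nll_not_worse_than_truth(m3_windows):
    truth, wins = m3_windows
    for w in wins[:60]:
        fit = hs.fit_window(w, "M3")
        assert fit.nll <= hs.window_negloglik(w, "M3", truth) + 1e-9
        assert fit.bic == pytest.approx(
            hs.model_bic(fit.nll, 3, fit.n_obs))


def test_m3_never_fits_worse_than_m2(m3_windows):
    """Nested ordering: the M3 search includes the M2 configuration."""
    _, wins = m3_windows
    for w in wins[:60]:
        assert hs.fit_window(w, "M3").nll <= hs.fit_window(w, "M2").nll + 1e-9


def test_parameter_recovery_median(m3_windows):
    """Median fitted parameters across ~200 windows land within 20% of the
    generating values."""
    truth, wins = m3_windows
    assert len(wins) >= 200
    fits = [hs.fit_window(w, "M3") for w in wins]
    theta = np.median([f.params.theta for f in fits])
    tau = np.median([f.params.tau for f in fits])
    mu = np.median([f.params.mu for f in fits])
    assert abs(theta - truth.theta) <= 0.2 * truth.theta
    assert abs(tau - truth.tau) <= 0.2 * truth.tau
    assert abs(mu - truth.mu) <= 0.2 * truth.mu


def test_simulated_data_prefers_generating_params(m3_windows):
    """The generating parameters beat perturbed ones on average."""
    truth, wins = m3_windows
    perturbed = ModelParams(theta=truth.theta / 2, tau=truth.tau / 4,
                            mu=min(1.0, truth.mu * 0.5))
    diffs = [hs.window_negloglik(w, "M3", perturbed) -
             hs.window_negloglik(w, "M3", truth) for w in wins]
    assert np.mean(diffs) > 0
    assert np.mean(np.array(diffs) > 0) > 0.8


# --------------------------------------------------------------------------
# Bayesian model selection
# --------------------------------------------------------------------------

def test_bms_symmetric_evidence():
    res = hs.bms_pxp(np.zeros((12, 3)), seed=0)
    assert res.expected_freq == pytest.approx([1 / 3] * 3, abs=1e-6)
    assert res.protected_exceedance_prob == pytest.approx([1 / 3] * 3,
                                                          abs=0.01)
    assert res.bayes_omnibus_risk > 0.5        # null clearly favored
    assert res.exceedance_prob.sum() == pytest.approx(1.0, abs=0.01)
    assert res.protected_exceedance_prob.sum() == pytest.approx(1.0,
                                                                abs=1e-9)


def test_bms_strong_unanimous_evidence():
    L = np.zeros((20, 3))
    L[:, 2] = 20.0                             # every subject favors M3
    res = hs.bms_pxp(L, seed=1)
    assert res.protected_exceedance_prob[2] > 0.995
    assert res.bayes_omnibus_risk < 1e-4
    assert np.argmax(res.expected_freq) == 2


def test_bms_identity_pxp_ep_bor():
    rng = np.random.default_rng(5)
    L = rng.normal(0, 3, size=(10, 3))
    res = hs.bms_pxp(L, seed=2)
    expect = res.exceedance_prob * (1 - res.bayes_omnibus_risk) + \
        res.bayes_omnibus_risk / 3
    assert res.protected_exceedance_prob == pytest.approx(expect, abs=1e-12)


def test_bms_input_validation():
    with pytest.raises(ValueError):
        hs.bms_pxp(np.zeros((1, 3)))           # one subject
    with pytest.raises(ValueError):
        hs.bms_pxp(np.zeros((5,)))             # not a matrix


def test_model_recovery_and_bic_ranking():
    """Cohorts generated under each model are attributed to their
    generator; mean BIC ranks M3 best on the M3 cohort."""
    gens = {
        "M1": ModelParams(theta=1.0, tau=200.0, mu=1.0),
        "M2": ModelParams(theta=1.0, tau=200.0, mu=1.0),
        "M3": ModelParams(theta=10.0, tau=200.0, mu=0.85),
    }
    winners = {}
    bics = {}
    for gen_id, params in gens.items():
        rows = []
        for s in range(4):
            pol = hs.MovementPolicy(gen_id, params, KEYBOARD_ACTIONS)
            cfg = hs.SessionConfig(n_trials=8, main_duration_range=(2.0, 2.0))
            ses = hs.run_session(cfg, pol, np.random.default_rng(100 + s),
                                 subject_id=f"g{s}")
            for tr in ses.trials:
                for w in hs.segment_windows(tr, KEYBOARD_ACTIONS):
                    for mid in ("M1", "M2", "M3"):
                        f = hs.fit_window(w, mid)
                        rows.append((f"g{s}", mid, f.bic))
        df = pd.DataFrame(rows, columns=["subject", "model", "bic"])
        ev = (df.assign(ev=lambda d: -d.bic / 2)
                .groupby(["subject", "model"])["ev"].sum().unstack())
        res = hs.bms_pxp(ev[["M1", "M2", "M3"]].to_numpy(), seed=7)
        winners[gen_id] = ("M1", "M2", "M3")[int(np.argmax(res.expected_freq))]
        bics[gen_id] = df.groupby("model")["bic"].mean()
    assert winners["M3"] == "M3"
    assert winners["M1"] in ("M1", "M2")
    assert winners["M2"] in ("M1", "M2")
    assert bics["M3"].idxmin() == "M3"


def test_subject_evidence_matrix_shape(fits3):
    ev = hs.subject_evidence_from_fits(fits3, model_ids=("M3",))
    assert ev.shape == (3, 1)
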