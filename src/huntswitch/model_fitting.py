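"""Windowed maximum-likelihood fitting and Bayesian model selection.

Each trial's player trajectory is segmented into 500-ms moving windows (30
frames, step 15 frames), starting at the first frame on which the player
moved.  Every window is fitted separately for each generative model by
maximizing the likelihood of the discretized observed actions, giving a
time course of (theta, tau, mu).  Models are compared by BIC
(2*NLL + k*ln(n)) and by random-effects Bayesian model selection over
subjects, yielding expected model frequencies, exceedance probabilities,
the Bayes omnibus risk, and protected exceedance probabilities.

The M3 likelihood treats the action observed on a planning frame as the
planned action; between planning frames the observation is scored as
mu * 1[observed == planned] + (1 - mu)/|A|.  Given an integer planning
timescale, the momentum mu then has a closed-form maximum-likelihood
estimate and the planning-frame log-likelihood is concave in tau, so the
fitter profiles over integer theta with exact inner maximization and
finally polishes (theta, tau) jointly with the prediction horizon treated
as continuous.  This is deterministic and needs no random restarts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import digamma, gammaln, logsumexp

from .arena_sim import HUNT, ESCAPE, SessionLog, TrialLog
from .movement_models import (
    ActionSet, JOYSTICK_ACTIONS, MODELS, ModelParams, N_FREE_PARAMS,
    MU_BOUNDS, TAU_BOUNDS, THETA_BOUNDS, discretize_trajectory,
)

WINDOW_LEN = 30          # frames (500 ms at 16 ms/frame)
WINDOW_STEP = 15         # frames (~250 ms)
MAX_LAG_HISTORY = 2 * 30  # agent history kept before a window start

PROB_FLOOR = 1e-12


# --------------------------------------------------------------------------
# windows
# --------------------------------------------------------------------------

@dataclass
class Window:
    """One 30-frame segment prepared for likelihood evaluation.

    ``actions[j]`` is the discretized player action taken at window frame j
    (the displacement from frame j to j+1); ``player_xy[j]`` is the player
    position at frame j; ``agent_xy`` holds the agent path from up to
    ``hist_offset`` frames before the window through its last frame, so
    lagged derivatives can reach back without leaving the array.
    """

    trial_key: tuple           # (subject, run, trial)
    condition: str
    start: int                 # absolute frame of window frame 0
    anchor_offset: int         # frames between movement onset and start
    actions: np.ndarray        # (30,) int
    player_xy: np.ndarray      # (30, 2)
    agent_xy: np.ndarray       # (hist_offset + 30, 2)
    hist_offset: int
    action_set: ActionSet = field(default=JOYSTICK_ACTIONS, repr=False)
    speed: float = 0.006

    @property
    def n_frames(self) -> int:
        return len(self.actions)


def segment_windows(trial_log: TrialLog, action_set: ActionSet | None = None,
                    speed: float | None = None) -> list[Window]:
    """Cut a trial into 30-frame windows stepping by 15 frames.

    Windows start at the first frame with a non-null player action (frames
    before movement onset carry no information about the movement
    generation process) and must fit entirely inside the main phase; a
    trial with fewer than 30 scorable frames yields no windows.
    """
    action_set = action_set or JOYSTICK_ACTIONS
    speed = speed if speed is not None else 0.006
    xy = trial_log.player_xy
    if len(xy) < 2:
        return []
    actions = discretize_trajectory(xy, action_set, speed)
    null = action_set.null_index
    moving = np.nonzero(actions != null)[0]
    if len(moving) == 0:
        return []
    first = int(moving[0])
    n_post = len(actions) - first
    if n_post < WINDOW_LEN:
        return []
    key = (trial_log.subject_id, trial_log.run_id, trial_log.trial_index)
    windows = []
    for s in range(first, first + n_post - WINDOW_LEN + 1, WINDOW_STEP):
        hs = max(0, s - MAX_LAG_HISTORY)
        windows.append(Window(
            trial_key=key, condition=trial_log.condition, start=s,
            anchor_offset=s - first,
            actions=actions[s:s + WINDOW_LEN].copy(),
            player_xy=xy[s:s + WINDOW_LEN].copy(),
            agent_xy=trial_log.agent_xy[hs:s + WINDOW_LEN].copy(),
            hist_offset=s - hs, action_set=action_set, speed=speed,
        ))
    return windows


# --------------------------------------------------------------------------
# likelihood machinery
# --------------------------------------------------------------------------

def _lagged_kinematics(window: Window, lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Velocity/acceleration (lagged differences) for every window frame;
    zeros where the recorded history is too short."""
    y = window.agent_xy
    o = window.hist_offset
    n = window.n_frames
    idx = o + np.arange(n)
    v = np.zeros((n, 2))
    a = np.zeros((n, 2))
    ok1 = idx - lag >= 0
    v[ok1] = y[idx[ok1]] - y[idx[ok1] - lag]
    ok2 = idx - 2 * lag >= 0
    a[ok2] = (y[idx[ok2]] - y[idx[ok2] - lag]) - \
             (y[idx[ok2] - lag] - y[idx[ok2] - 2 * lag])
    return v, a


def _q_matrix(window: Window, frames: np.ndarray, v: np.ndarray,
              a: np.ndarray, theta: float) -> np.ndarray:
    """Action values Q for the given window frames under horizon theta."""
    y_now = window.agent_xy[window.hist_offset + frames]
    y_pred = y_now + v[frames] * theta + a[frames] * (theta ** 2) / 2.0
    dirs = window.action_set.directions
    landing = window.player_xy[frames, None, :] + window.speed * dirs[None, :, :]
    if window.action_set.includes_null:
        landing = np.concatenate(
            [landing, window.player_xy[frames, None, :]], axis=1)
    d2 = np.sum((landing - y_pred[:, None, :]) ** 2, axis=2)
    return -d2 if window.condition == HUNT else d2


def _decision_frames(n: int, cadence: int, offset: int = 0) -> np.ndarray:
    """Planning frames within a window whose start lies ``offset`` frames
    after movement onset (the cadence is anchored at onset)."""
    first = (-offset) % cadence
    return np.arange(first, n, cadence)


def _nll_decision(q: np.ndarray, obs: np.ndarray, tau: float) -> float:
    """-sum log softmax(tau*Q)[obs]; computed in log space (no underflow)."""
    tq = tau * q
    m = tq.max(axis=1)
    lse = m + np.log(np.exp(tq - m[:, None]).sum(axis=1))
    return float(np.sum(lse - tq[np.arange(len(obs)), obs]))


def _intermediate_counts(actions: np.ndarray, cadence: int,
                         offset: int = 0) -> tuple[int, int]:
    """(#intermediate frames, #those matching the last planned action).

    The planned action is the one observed at the most recent planning
    frame; frames before the window's first planning frame fall back to
    the window's first observed action as the standing plan.
    """
    n = len(actions)
    n_int = 0
    n_match = 0
    planned = actions[0]
    first = (-offset) % cadence
    for j in range(n):
        if (j - first) % cadence == 0 and j >= first:
            planned = actions[j]
        else:
            n_int += 1
            if actions[j] == planned:
                n_match += 1
    return n_int, n_match


def _nll_intermediate(n_int: int, n_match: int, mu: float, n_actions: int) -> float:
    p_match = mu + (1.0 - mu) / n_actions
    p_miss = (1.0 - mu) / n_actions
    nll = -n_match * math.log(max(p_match, PROB_FLOOR))
    nll -= (n_int - n_match) * math.log(max(p_miss, PROB_FLOOR))
    return nll


def _mu_mle(n_int: int, n_match: int, n_actions: int) -> float:
    """Closed-form maximizer of the intermediate-frame likelihood."""
    if n_int == 0:
        return 1.0
    mu = (n_match * (n_actions - 1) - (n_int - n_match)) / ((n_actions - 1) * n_int)
    return float(np.clip(mu, *MU_BOUNDS))


def window_negloglik(window: Window, model_id: str, params: ModelParams) -> float:
    """Negative log-likelihood (nats) of a window under one model.

    M1/M2 score every frame with the softmax choice rule (M1 targets the
    agent's current position; M2 extrapolates with lag-1 derivatives and
    horizon theta=1).  M3 scores planning frames (every round(theta)
    frames, anchored at the window start) with the softmax and the frames
    in between with the momentum mixture; the planned action is the one
    observed at the most recent planning frame.
    """
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}")
    n = window.n_frames
    a_size = window.action_set.size
    if model_id == "M1":
        frames = np.arange(n)
        v = a = np.zeros((n, 2))
        q = _q_matrix(window, frames, v, a, 0.0)
        return _nll_decision(q, window.actions, params.tau)
    if model_id == "M2":
        frames = np.arange(n)
        v, a = _lagged_kinematics(window, 1)
        q = _q_matrix(window, frames, v, a, 1.0)
        return _nll_decision(q, window.actions, params.tau)
    cadence = params.theta_frames
    v, a = _lagged_kinematics(window, cadence)
    dframes = _decision_frames(n, cadence, window.anchor_offset)
    q = _q_matrix(window, dframes, v, a, params.theta)
    nll = _nll_decision(q, window.actions[dframes], params.tau)
    n_int, n_match = _intermediate_counts(window.actions, cadence,
                                          window.anchor_offset)
    nll += _nll_intermediate(n_int, n_match, params.mu, a_size)
    return nll


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowFit:
    model_id: str
    params: ModelParams
    nll: float
    n_obs: int
    bic: float
    converged: bool


def model_bic(nll: float, k: int, n_obs: int) -> float:
    """BIC = 2*NLL + k*ln(n)."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return 2.0 * nll + k * math.log(n_obs)


def _fit_tau(q: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    """Globally optimal tau for a decision-frame block (objective is convex)."""
    res = minimize_scalar(lambda t: _nll_decision(q, obs, t),
                          bounds=TAU_BOUNDS, method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x), float(res.fun)


def fit_window(window: Window, model_id: str,
               bounds: dict | None = None, starts: int = 1) -> WindowFit:
    """Maximum-likelihood fit of one model to one window.

    M1/M2 reduce to a 1-D concave problem in tau, solved by bounded scalar
    optimization.  M3 is fitted by profiling over the integer planning
    timescale (theta = 1..30): for each value, mu has a closed-form MLE and
    tau a 1-D concave problem; the best profile point is then polished by a
    bounded quasi-Newton search over continuous (theta, tau) with the lag
    structure held at the profiled integer.  Deterministic; ``bounds`` and
    ``starts`` are accepted for interface compatibility and validation.

    Returns the fit with its BIC, where n_obs is the number of scored
    frames (all 30: early frames are scorable thanks to the zero-derivative
    fallback).
    """
    n = window.n_frames
    n_obs = n
    k = N_FREE_PARAMS[model_id]
    if model_id in ("M1", "M2"):
        frames = np.arange(n)
        if model_id == "M1":
            v = a = np.zeros((n, 2))
            theta = 1.0
            q = _q_matrix(window, frames, v, a, 0.0)
        else:
            v, a = _lagged_kinematics(window, 1)
            theta = 1.0
            q = _q_matrix(window, frames, v, a, 1.0)
        tau, nll = _fit_tau(q, window.actions)
        params = ModelParams(theta=theta, tau=tau, mu=1.0)
        return WindowFit(model_id, params, nll, n_obs,
                         model_bic(nll, k, n_obs), True)
    if model_id != "M3":
        raise ValueError(f"unknown model {model_id!r}")

    a_size = window.action_set.size
    best = None   # (nll, cadence, tau, mu)
    for cadence in range(1, int(THETA_BOUNDS[1]) + 1):
        v, arr_a = _lagged_kinematics(window, cadence)
        dframes = _decision_frames(n, cadence, window.anchor_offset)
        q = _q_matrix(window, dframes, v, arr_a, float(cadence))
        tau, nll_dec = _fit_tau(q, window.actions[dframes])
        n_int, n_match = _intermediate_counts(window.actions, cadence,
                                              window.anchor_offset)
        mu = _mu_mle(n_int, n_match, a_size)
        nll = nll_dec + _nll_intermediate(n_int, n_match, mu, a_size)
        if best is None or nll < best[0]:
            best = (nll, cadence, tau, mu)

    nll0, cadence, tau0, mu = best
    # polish (theta, tau) with the continuous prediction horizon, lag fixed
    v, arr_a = _lagged_kinematics(window, cadence)
    dframes = _decision_frames(n, cadence, window.anchor_offset)
    obs = window.actions[dframes]
    n_int, n_match = _intermediate_counts(window.actions, cadence,
                                          window.anchor_offset)
    nll_int = _nll_intermediate(n_int, n_match, mu, a_size)

    def objective(x):
        q = _q_matrix(window, dframes, v, arr_a, x[0])
        return _nll_decision(q, obs, x[1]) + nll_int

    lo = max(THETA_BOUNDS[0], cadence - 0.5)
    hi = min(THETA_BOUNDS[1], cadence + 0.5)
    res = minimize(objective, x0=[float(cadence), tau0], method="L-BFGS-B",
                   bounds=[(lo, hi), TAU_BOUNDS],
                   options={"ftol": 1e-6, "maxiter": 100})
    if res.fun <= nll0 + 1e-12:
        theta, tau = float(res.x[0]), float(res.x[1])
        nll = float(res.fun)
    else:   # polish failed to improve; keep the profile optimum
        theta, tau, nll = float(cadence), tau0, nll0
    params = ModelParams(theta=theta, tau=tau, mu=mu)
    return WindowFit("M3", params, nll, n_obs, model_bic(nll, 3, n_obs),
                     bool(res.success) or nll <= nll0 + 1e-12)


def fit_sessions(sessions: list[SessionLog], model_ids: tuple[str, ...] = MODELS,
                 action_set: ActionSet | None = None,
                 speed: float = 0.006) -> pd.DataFrame:
    """Fit every window of every trial; one row per window x model.

    Columns: subject, run, trial, condition, window (index within trial),
    start (absolute frame), model, theta, tau, mu, nll, n_obs, bic,
    converged.
    """
    rows = []
    for ses in sessions:
        for tr in ses.trials:
            for w_idx, win in enumerate(segment_windows(tr, action_set, speed)):
                for mid in model_ids:
                    fit = fit_window(win, mid)
                    rows.append((tr.subject_id, tr.run_id, tr.trial_index,
                                 tr.condition, w_idx, win.start, mid,
                                 fit.params.theta, fit.params.tau,
                                 fit.params.mu, fit.nll, fit.n_obs, fit.bic,
                                 fit.converged))
    return pd.DataFrame(rows, columns=[
        "subject", "run", "trial", "condition", "window", "start", "model",
        "theta", "tau", "mu", "nll", "n_obs", "bic", "converged"])


# --------------------------------------------------------------------------
# random-effects Bayesian model selection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BMSResult:
    model_ids: tuple
    dirichlet_alpha: np.ndarray
    expected_freq: np.ndarray           # sums to 1
    exceedance_prob: np.ndarray         # Monte-Carlo estimate
    bayes_omnibus_risk: float
    protected_exceedance_prob: np.ndarray   # EP*(1-BOR) + BOR/M


def _dirichlet_ln_beta(alpha: np.ndarray) -> float:
    return float(np.sum(gammaln(alpha)) - gammaln(np.sum(alpha)))


def bms_pxp(subject_evidence: np.ndarray, model_ids: tuple = MODELS,
            n_samples: int = 100_000, seed: int | None = 0,
            max_iter: int = 500, tol: float = 1e-8) -> BMSResult:
    """Random-effects Bayesian model selection over subjects.

    ``subject_evidence`` is an (n_subjects, n_models) matrix of per-subject
    log model evidence (here approximated as -BIC/2 summed over a subject's
    windows).  Model frequencies in the population get a Dirichlet(1)
    prior; variational Bayes estimates the posterior Dirichlet, exceedance
    probabilities come from Monte-Carlo sampling of that posterior, and the
    Bayes omnibus risk (posterior probability that all models are equally
    frequent) protects them: PXP = EP*(1-BOR) + BOR/M.
    """
    L = np.asarray(subject_evidence, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("need an (n_subjects, n_models>=2) evidence matrix")
    n_subj, n_mod = L.shape
    if n_subj < 2:
        raise ValueError("random-effects BMS needs >= 2 subjects")
    alpha0 = np.ones(n_mod)
    alpha = alpha0.copy()
    u = np.full((n_subj, n_mod), 1.0 / n_mod)
    for _ in range(max_iter):
        e_lnr = digamma(alpha) - digamma(alpha.sum())
        log_u = L + e_lnr[None, :]
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        new_alpha = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha

    expected = alpha / alpha.sum()

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    ep = np.bincount(winners, minlength=n_mod) / n_samples

    # free energy of the random-effects model vs. the equal-frequency null
    e_lnr = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ulogu = np.where(u > 0, u * np.log(u), 0.0)
    f1 = float(np.sum(u * (L + e_lnr[None, :])) - np.sum(ulogu))
    # KL(q(r) || p(r)) between Dirichlet posteriors
    kl = (_dirichlet_ln_beta(alpha0) - _dirichlet_ln_beta(alpha)
          + float(np.sum((alpha - alpha0) * e_lnr)))
    f1 -= kl
    f0 = float(np.sum(logsumexp(L, axis=1) - math.log(n_mod)))
    bor = 1.0 / (1.0 + math.exp(min(700.0, max(-700.0, f1 - f0))))

    pxp = ep * (1.0 - bor) + bor / n_mod
    return BMSResult(tuple(model_ids), alpha, expected, ep, bor, pxp)


def subject_evidence_from_fits(fits: pd.DataFrame,
                               model_ids: tuple = MODELS) -> np.ndarray:
    """Per-subject log evidence (-BIC/2 summed over windows) per model."""
    ev = (fits.assign(ev=lambda d: -d.bic / 2.0)
              .groupby(["subject", "model"])["ev"].sum().unstack("model"))
    return ev[list(model_ids)].to_numpy()
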