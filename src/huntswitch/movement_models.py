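"""Generative models of player movement in the hunt/escape task.

Three nested models describe how a player turns the computer agent's
kinematics into a movement decision over a discrete action set (128
joystick directions + no-movement, or 8 keyboard directions + no-movement):

* M1 (reactive): no prediction; the target is the agent's current position.
* M2 (fixed predictive): the agent's position is extrapolated one frame
  ahead (theta fixed at 1) from per-frame velocity and acceleration,
  y_pred = y + y' * theta + y'' * theta^2 / 2; planning happens every frame.
* M3 (variable-timescale predictive): the same extrapolation, but velocity
  and acceleration are lagged differences at timescale theta, planning
  happens only every theta frames, and between decisions the planned action
  is repeated with probability mu (momentum) or replaced by a uniformly
  random action.

The value of an action is the negative (hunt) or positive (escape) squared
distance between its landing point and the predicted agent position; the
decision is a softmax with precision tau over those values.  Each model
doubles as a simulation policy (plugging into ``arena_sim``) and as a
likelihood over discretized observed actions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .arena_sim import HUNT, ESCAPE

MODELS = ("M1", "M2", "M3")

#: free parameters per model (feeds BIC)
N_FREE_PARAMS = {"M1": 1, "M2": 1, "M3": 3}

THETA_BOUNDS = (1e-6, 30.0)
TAU_BOUNDS = (-1000.0, 1000.0)
MU_BOUNDS = (0.0, 1.0)


@dataclass(frozen=True)
class ModelParams:
    """Generative-model parameter triple.

    theta: planning/prediction timescale in frames, (0, 30];
    tau: softmax precision, [-1000, 1000];
    mu: probability of continuing the planned action between decisions, [0, 1].
    """

    theta: float = 1.0
    tau: float = 0.0
    mu: float = 1.0

    def __post_init__(self) -> None:
        if not THETA_BOUNDS[0] <= self.theta <= THETA_BOUNDS[1]:
            raise ValueError(f"theta {self.theta} outside (0, 30]")
        if not TAU_BOUNDS[0] <= self.tau <= TAU_BOUNDS[1]:
            raise ValueError(f"tau {self.tau} outside [-1000, 1000]")
        if not MU_BOUNDS[0] <= self.mu <= MU_BOUNDS[1]:
            raise ValueError(f"mu {self.mu} outside [0, 1]")

    @property
    def theta_frames(self) -> int:
        """theta rounded to integer frames (>= 1) for indexing/cadence."""
        return max(1, int(round(self.theta)))

    def as_array(self) -> np.ndarray:
        return np.array([self.theta, self.tau, self.mu])


@dataclass(frozen=True)
class ActionSet:
    """Discrete action set: n equally spaced unit directions plus an
    optional null (no-movement) action at the last index."""

    directions: np.ndarray        # (n_directions, 2) unit vectors
    includes_null: bool = True

    @property
    def n_directions(self) -> int:
        return len(self.directions)

    @property
    def size(self) -> int:
        return self.n_directions + (1 if self.includes_null else 0)

    @property
    def null_index(self) -> int | None:
        return self.n_directions if self.includes_null else None

    def landing_points(self, player_xy: np.ndarray, speed: float) -> np.ndarray:
        """(size, 2) landing positions; the null action lands in place."""
        pts = np.asarray(player_xy)[None, :] + speed * self.directions
        if self.includes_null:
            pts = np.vstack([pts, np.asarray(player_xy)[None, :]])
        return pts

    def displacement(self, action: int, speed: float) -> np.ndarray:
        if self.includes_null and action == self.null_index:
            return np.zeros(2)
        return speed * self.directions[action]


def make_action_set(n_directions: int = 128, include_null: bool = True) -> ActionSet:
    """Direction k has angle 2*pi*k/n from the +x axis."""
    ang = 2 * np.pi * np.arange(n_directions) / n_directions
    dirs = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    return ActionSet(directions=dirs, includes_null=include_null)


#: joystick modality (expt. 2): 128 directions + null = 129 actions
JOYSTICK_ACTIONS = make_action_set(128)
#: keyboard modality (expt. 1): 8 directions + null = 9 actions
KEYBOARD_ACTIONS = make_action_set(8)


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------

def _lagged_diffs(history: np.ndarray, lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Velocity and acceleration as lagged differences; zeros where the
    history is too short (graceful degradation at trial start)."""
    y = np.asarray(history, dtype=float)
    t = len(y) - 1
    v = y[t] - y[t - lag] if t - lag >= 0 else np.zeros(2)
    if t - 2 * lag >= 0:
        a = v - (y[t - lag] - y[t - 2 * lag])
    else:
        a = np.zeros(2)
    return v, a


def predict_agent_position(history: np.ndarray, theta: float,
                           model_id: str) -> np.ndarray:
    """Extrapolate the agent's position theta frames ahead.

    y_pred = y(t) + y'(t) * theta + y''(t) * theta^2 / 2, with per-frame
    differences for M2 and lag-round(theta) differences for M3.  M1 returns
    the current position unchanged.
    """
    y = np.asarray(history, dtype=float)
    if model_id == "M1":
        return y[-1].copy()
    if model_id == "M2":
        lag = 1
    elif model_id == "M3":
        lag = max(1, int(round(theta)))
    else:
        raise ValueError(f"unknown model {model_id!r}")
    v, a = _lagged_diffs(y, lag)
    return y[-1] + v * theta + a * (theta ** 2) / 2.0


# --------------------------------------------------------------------------
# valuation and choice
# --------------------------------------------------------------------------

def action_values(player_xy: np.ndarray, y_pred: np.ndarray, condition: str,
                  action_set: ActionSet, speed: float) -> np.ndarray:
    """Q(a) = -d(landing, y_pred)^2 in hunt, +d^2 in escape."""
    landing = action_set.landing_points(player_xy, speed)
    d2 = np.sum((landing - np.asarray(y_pred)[None, :]) ** 2, axis=1)
    if condition == HUNT:
        return -d2
    if condition == ESCAPE:
        return d2
    raise ValueError(f"unknown condition {condition!r}")


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - np.max(x)
    e = np.exp(z)
    return e / e.sum()


def action_probabilities(player_xy: np.ndarray, y_pred: np.ndarray,
                         condition: str, action_set: ActionSet,
                         speed: float, tau: float) -> np.ndarray:
    """Softmax choice rule p(a) = exp(tau*Q(a)) / sum_a' exp(tau*Q(a'))."""
    q = action_values(player_xy, y_pred, condition, action_set, speed)
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite action values (corrupt positions?)")
    return softmax(tau * q)


def discretize_movement(frame_displacement: np.ndarray, action_set: ActionSet,
                        speed: float) -> int:
    """Map an observed per-frame displacement onto the action set.

    Displacements shorter than 0.25*speed count as the null action
    (joystick jitter); otherwise the nearest direction by angle wins, ties
    to the lower index.
    """
    d = np.asarray(frame_displacement, dtype=float)
    norm = np.linalg.norm(d)
    if norm < 0.25 * speed:
        if action_set.includes_null:
            return action_set.null_index
        norm = max(norm, 1e-300)
    cos = action_set.directions @ (d / norm)
    return int(np.argmax(np.round(cos, 12)))   # round so exact ties go low


def discretize_trajectory(player_xy: np.ndarray, action_set: ActionSet,
                          speed: float) -> np.ndarray:
    """Actions for frames 0..T-2 of a logged player path (vectorized)."""
    steps = np.diff(np.asarray(player_xy, dtype=float), axis=0)
    norms = np.linalg.norm(steps, axis=1)
    moving = norms >= 0.25 * speed
    out = np.full(len(steps), action_set.null_index
                  if action_set.includes_null else 0, dtype=int)
    if moving.any():
        unit = steps[moving] / norms[moving, None]
        cos = unit @ action_set.directions.T
        out[moving] = np.argmax(np.round(cos, 12), axis=1)
    return out


# --------------------------------------------------------------------------
# simulation policy
# --------------------------------------------------------------------------

class MovementPolicy:
    """A generative model acting as an ``arena_sim`` player policy.

    M1/M2 re-plan every frame.  M3 plans every round(theta) frames; on the
    frames in between it repeats the planned action with probability mu and
    otherwise draws a uniformly random action.
    """

    def __init__(self, model_id: str,
                 params: ModelParams | Callable[[str], ModelParams],
                 action_set: ActionSet | None = None,
                 speed: float = 0.006):
        if model_id not in MODELS:
            raise ValueError(f"unknown model {model_id!r}")
        self.model_id = model_id
        self._params_for = params if callable(params) else (lambda _c: params)
        self.action_set = action_set or JOYSTICK_ACTIONS
        self.speed = speed
        self.condition = HUNT
        self.params = self._params_for(HUNT)
        self._planned_action: int | None = None
        self._frames_since_plan = 0

    def reset(self, condition: str, rng: np.random.Generator) -> None:
        self.condition = condition
        self.params = self._params_for(condition)
        self._planned_action = None
        self._frames_since_plan = 0

    def _decide(self, player_xy: np.ndarray, agent_history: np.ndarray,
                rng: np.random.Generator) -> int:
        theta = 1.0 if self.model_id == "M2" else self.params.theta
        y_pred = predict_agent_position(agent_history, theta, self.model_id)
        p = action_probabilities(player_xy, y_pred, self.condition,
                                 self.action_set, self.speed, self.params.tau)
        return int(rng.choice(len(p), p=p))

    def step(self, frame: int, player_xy: np.ndarray,
             agent_history: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.model_id in ("M1", "M2"):
            action = self._decide(player_xy, agent_history, rng)
        else:
            cadence = self.params.theta_frames
            if self._planned_action is None or self._frames_since_plan >= cadence:
                self._planned_action = self._decide(player_xy, agent_history, rng)
                self._frames_since_plan = 0
                action = self._planned_action
            else:
                if rng.random() < self.params.mu:
                    action = self._planned_action
                else:
                    action = int(rng.integers(self.action_set.size))
            self._frames_since_plan += 1
        return self.action_set.displacement(action, self.speed)


def plan_and_step_player(model_id: str, params: ModelParams,
                         trial_prefix: dict, rng: np.random.Generator,
                         action_set: ActionSet, speed: float) -> np.ndarray:
    """One-shot functional form of :class:`MovementPolicy.step`.

    ``trial_prefix`` carries ``frame``, ``player_xy``, ``agent_history`` and,
    for M3, the mutable ``planned_action``/``frames_since_plan`` slots.
    """
    policy = MovementPolicy(model_id, params, action_set, speed)
    policy.condition = trial_prefix.get("condition", HUNT)
    policy.params = params
    policy._planned_action = trial_prefix.get("planned_action")
    policy._frames_since_plan = trial_prefix.get("frames_since_plan", 0)
    step = policy.step(trial_prefix.get("frame", 0),
                       trial_prefix["player_xy"],
                       trial_prefix["agent_history"], rng)
    trial_prefix["planned_action"] = policy._planned_action
    trial_prefix["frames_since_plan"] = policy._frames_since_plan
    return step
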