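"""Simulator for the 2D circular-arena hunt/escape switching task.

The player (human avatar in the original task, a generative-model policy
here) shares a circular arena with a scripted computer agent: a prey that
flees in the hunt condition, a predator that chases in the escape
condition.  The agent moves greedily every frame by evaluating 30 candidate
positions equally spaced on a circle of radius equal to its speed and
choosing the one minimizing a distance-based cost.  Sessions follow the
trial protocol of the task: a 1-s switch/stay cue (switch probability 0.5),
an optional pre-encounter stage after capture-terminated trials, a main
stage of random 2-10 s duration terminated early by capture, respawning
after capture, random predator speed boosts, and a staircase that
recalibrates agent speed every 4 trials of a condition to hold the player's
success rate near 50%.

Positions are in screen-height units; one frame is 16 ms; the player moves
at 0.006 units/frame.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("huntswitch")

HUNT = "hunt"
ESCAPE = "escape"

N_AGENT_CANDIDATES = 30


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ArenaConfig:
    """Arena geometry, kinematics, and protocol constants.

    Defaults marked (*) are not fixed by the task description and are this
    package's choices; see docs/methods.md.
    """

    radius: float = 0.5                   # (*) arena radius, screen-height units
    frame_dt: float = 0.016               # seconds per frame
    player_speed: float = 0.006           # units per frame
    agent_speed: float = 0.006            # initial agent speed (calibrated online)
    capture_radius: float = 0.02          # (*) capture distance
    center_cost_weight: float = 0.5       # (*) weight of distance-from-center cost
    wall_ramp_weight: float = 0.5         # (*) quadratic cost ramp near the wall
    wall_ramp_start: float = 0.85         # (*) ramp onset, fraction of radius
    n_candidates: int = N_AGENT_CANDIDATES
    boost_prob_per_s: float = 0.5         # (*) predator boost onset rate
    boost_multiplier: float = 1.8         # (*) speed multiplier while boosting
    boost_duration_frames: int = 12       # (*)
    calibration_block: int = 4            # trials per staircase update
    calibration_step: float = 0.0005      # (*) units/frame per update
    target_success: float = 0.5
    agent_speed_min: float = 0.002        # (*) staircase clip range
    agent_speed_max: float = 0.012        # (*)
    cost_sign_literal: bool = False

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if not 0 < self.player_speed < self.radius:
            raise ValueError("player_speed must lie in (0, radius)")
        if not self.capture_radius > 0:
            raise ValueError("capture_radius must be positive")
        if self.center_cost_weight < 0:
            raise ValueError("center_cost_weight must be >= 0")
        if self.boost_multiplier < 1:
            raise ValueError("boost_multiplier must be >= 1")


@dataclass(frozen=True)
class TrialSpec:
    """Schedule entry for one trial."""

    condition: str                         # HUNT or ESCAPE
    is_switch: bool
    cue_duration: float = 1.0              # s
    iti: float = 1.0                       # s, drawn from [0.5, 1.5]
    pre_encounter_duration: float | None = None   # s, or None if absent
    main_duration: float = 6.0             # s, drawn from [2, 10]

    def __post_init__(self) -> None:
        if self.condition not in (HUNT, ESCAPE):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 2.0 <= self.main_duration <= 10.0:
            raise ValueError("main_duration must lie in [2, 10] s")


@dataclass
class TrialLog:
    """Per-frame kinematics and outcome of one trial.

    ``player_xy``/``agent_xy`` are (n_frames, 2) arrays for the main stage;
    frame indices are contiguous from 0.  ``boost_active`` flags frames on
    which the predator's speed boost was in effect.
    """

    subject_id: str
    run_id: int
    trial_index: int
    condition: str
    is_switch: bool
    player_xy: np.ndarray
    agent_xy: np.ndarray
    boost_active: np.ndarray
    outcome: str                           # "success" | "failure"
    terminated_by_capture: bool
    pre_encounter_xy: np.ndarray           # (n_pre, 2); empty if no pre stage

    @property
    def n_frames(self) -> int:
        return len(self.player_xy)

    def validate(self, config: ArenaConfig) -> None:
        r = config.radius * (1 + 1e-9)
        for name in ("player_xy", "agent_xy", "pre_encounter_xy"):
            xy = getattr(self, name)
            if len(xy) and np.linalg.norm(xy, axis=1).max() > r:
                raise ValueError(f"{name} leaves the arena")
        want_success = self.terminated_by_capture if self.condition == HUNT \
            else not self.terminated_by_capture
        if (self.outcome == "success") != want_success:
            raise ValueError("outcome inconsistent with capture flag")


@dataclass
class SessionLog:
    """All trials of one run for one subject, plus the schedule metadata."""

    subject_id: str
    run_id: int
    trials: list[TrialLog]
    config: ArenaConfig
    final_agent_speed: dict[str, float] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class SessionConfig:
    n_trials: int = 121
    switch_prob: float = 0.5
    pre_encounter_prob: float = 0.4        # after capture-terminated trials
    main_duration_range: tuple[float, float] = (2.0, 10.0)
    pre_duration_range: tuple[float, float] = (0.0, 10.0)
    calibrate: bool = True


class PlayerPolicy(Protocol):
    """A player controller; arena_sim is agnostic to how steps are chosen."""

    def reset(self, condition: str, rng: np.random.Generator) -> None: ...

    def step(self, frame: int, player_xy: np.ndarray,
             agent_history: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Return the player displacement for this frame (norm <= speed)."""
        ...


# --------------------------------------------------------------------------
# respawning
# --------------------------------------------------------------------------

def sample_respawn(rng: np.random.Generator,
                   config: ArenaConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw fresh (player, agent) positions after a capture.

    The agent respawns from an isotropic Gaussian centred on the arena
    centre with per-axis SD radius/4 (rejection-sampled into the arena), so
    it tends to appear centrally; the player respawns with radial distance
    uniform on [0, radius] and uniform angle, so hugging the wall is the
    safe pre-encounter strategy in escape trials.
    """
    while True:
        agent = rng.normal(0.0, config.radius / 4.0, size=2)
        if np.linalg.norm(agent) <= config.radius:
            break
    r = rng.uniform(0.0, config.radius)
    phi = rng.uniform(0.0, 2 * np.pi)
    player = np.array([r * np.cos(phi), r * np.sin(phi)])
    return player, agent


# --------------------------------------------------------------------------
# scripted agent
# --------------------------------------------------------------------------

def _center_cost(candidate_xy: np.ndarray, config: ArenaConfig) -> float:
    r = float(np.linalg.norm(candidate_xy))
    cost = config.center_cost_weight * r
    edge = config.wall_ramp_start * config.radius
    if r > edge:
        frac = (r - edge) / (config.radius - edge)
        cost += config.wall_ramp_weight * frac * frac
    return cost


def agent_cost(candidate_xy: np.ndarray, player_xy: np.ndarray,
               role: str, config: ArenaConfig) -> float:
    """Cost of a candidate agent position.

    Predator: cost grows with distance to the player (chase).  Prey: cost
    falls with distance to the player (flee).  Both pay a cost for leaving
    the centre, with a quadratic ramp near the wall.  The task description
    states the sign of the player-distance term inconsistently with the
    described flee/chase behaviour; ``cost_sign_literal`` selects the
    literal reading (prey attracted, predator repelled).
    """
    if role not in ("predator", "prey"):
        raise ValueError(f"unknown role {role!r}")
    if np.linalg.norm(candidate_xy) > config.radius * (1 + 1e-12):
        return math.inf
    d = float(np.linalg.norm(np.asarray(candidate_xy) - np.asarray(player_xy)))
    sign = 1.0 if role == "predator" else -1.0
    if config.cost_sign_literal:
        sign = -sign
    # quantize so exact-symmetry ties resolve to the lowest candidate index
    return round(sign * d + _center_cost(candidate_xy, config), 12)


_CAND_ANGLES = 2 * np.pi * np.arange(N_AGENT_CANDIDATES) / N_AGENT_CANDIDATES
_CAND_UNIT = np.stack([np.cos(_CAND_ANGLES), np.sin(_CAND_ANGLES)], axis=1)


def candidate_positions(agent_xy: np.ndarray, speed: float,
                        n: int = N_AGENT_CANDIDATES) -> np.ndarray:
    """The n candidate positions equally spaced at distance ``speed``;
    candidate 0 points along +x."""
    if n == N_AGENT_CANDIDATES:
        unit = _CAND_UNIT
    else:
        ang = 2 * np.pi * np.arange(n) / n
        unit = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    return np.asarray(agent_xy)[None, :] + speed * unit


def step_agent(agent_xy: np.ndarray, player_xy: np.ndarray, role: str,
               speed: float, rng: np.random.Generator | None,
               config: ArenaConfig) -> np.ndarray:
    """Greedy one-step move: the minimum-cost candidate of the 30 evaluated.

    Ties break to the lowest candidate index; if every candidate would leave
    the arena the agent stays put.  ``speed`` is the effective (possibly
    boosted) speed.  Vectorized equivalent of argmin over ``agent_cost``.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    cand = candidate_positions(agent_xy, speed, config.n_candidates)
    r = np.linalg.norm(cand, axis=1)
    inside = r <= config.radius * (1 + 1e-12)
    if not inside.any():
        return np.asarray(agent_xy, dtype=float).copy()
    d = np.linalg.norm(cand - np.asarray(player_xy)[None, :], axis=1)
    sign = 1.0 if role == "predator" else -1.0
    if config.cost_sign_literal:
        sign = -sign
    cost = sign * d + config.center_cost_weight * r
    edge = config.wall_ramp_start * config.radius
    frac = np.clip((r - edge) / (config.radius - edge), 0.0, None)
    cost = cost + config.wall_ramp_weight * frac * frac
    cost = np.round(cost, 12)   # same quantization as agent_cost
    cost[~inside] = np.inf
    return cand[int(np.argmin(cost))]


# --------------------------------------------------------------------------
# difficulty staircase
# --------------------------------------------------------------------------

def update_difficulty(history: Sequence[bool], agent_speed: float,
                      condition: str, config: ArenaConfig) -> float:
    """Staircase the agent speed toward a 50% player success rate.

    ``history`` holds the player's outcomes for completed trials of this
    condition; every ``calibration_block`` trials the speed moves one
    ``calibration_step`` in the direction that makes the task harder when
    the player is above target and easier when below.  Faster prey are
    harder to hunt; faster predators are harder to escape — so the sign of
    the adjustment is the same for both conditions.
    """
    n = len(history)
    if n == 0 or n % config.calibration_block != 0:
        return agent_speed
    block = history[-config.calibration_block:]
    rate = sum(block) / len(block)
    if rate > config.target_success:
        agent_speed += config.calibration_step
    elif rate < config.target_success:
        agent_speed -= config.calibration_step
    return float(np.clip(agent_speed, config.agent_speed_min,
                         config.agent_speed_max))


# --------------------------------------------------------------------------
# trial and session loops
# --------------------------------------------------------------------------

@dataclass
class SessionState:
    """Mutable cross-trial state: positions persist over non-capture trial
    boundaries; agent speeds are calibrated per condition."""

    player_xy: np.ndarray
    agent_xy: np.ndarray
    agent_speed: dict[str, float]
    outcome_history: dict[str, list[bool]] = field(
        default_factory=lambda: {HUNT: [], ESCAPE: []})
    last_terminated_by_capture: bool = True   # first trial respawns


def _clip_to_arena(xy: np.ndarray, radius: float) -> np.ndarray:
    r = np.linalg.norm(xy)
    if r > radius:
        return xy * (radius / r)
    return xy


def run_trial(spec: TrialSpec, player_policy: PlayerPolicy,
              state: SessionState, rng: np.random.Generator,
              config: ArenaConfig, subject_id: str = "s0", run_id: int = 0,
              trial_index: int = 0) -> TrialLog:
    """Simulate one trial and append its outcome to the session state."""
    role = "prey" if spec.condition == HUNT else "predator"
    if state.last_terminated_by_capture:
        state.player_xy, state.agent_xy = sample_respawn(rng, config)

    player_policy.reset(spec.condition, rng)

    # pre-encounter stage: the player roams alone
    pre_positions: list[np.ndarray] = []
    if spec.pre_encounter_duration is not None:
        n_pre = int(round(spec.pre_encounter_duration / config.frame_dt))
        for t in range(n_pre):
            pre_positions.append(state.player_xy.copy())
            step = np.asarray(player_policy.step(
                t, state.player_xy, state.agent_xy[None, :], rng), dtype=float)
            norm = np.linalg.norm(step)
            if norm > config.player_speed * (1 + 1e-9):
                logger.warning("player step %.4g exceeds speed; renormalized", norm)
                step = step * (config.player_speed / norm)
            state.player_xy = _clip_to_arena(state.player_xy + step, config.radius)
        player_policy.reset(spec.condition, rng)

    n_frames = int(round(spec.main_duration / config.frame_dt))
    player_path = np.empty((n_frames, 2))
    agent_path = np.empty((n_frames, 2))
    boost_flags = np.zeros(n_frames, dtype=bool)
    speed = state.agent_speed[spec.condition]
    boost_left = 0
    captured = False
    t_end = n_frames

    for t in range(n_frames):
        player_path[t] = state.player_xy
        agent_path[t] = state.agent_xy
        if np.linalg.norm(state.player_xy - state.agent_xy) < config.capture_radius:
            captured = True
            t_end = t + 1
            break
        # player moves on the current view of the agent
        step = np.asarray(player_policy.step(
            t, state.player_xy, agent_path[:t + 1], rng), dtype=float)
        norm = np.linalg.norm(step)
        if norm > config.player_speed * (1 + 1e-9):
            logger.warning("player step %.4g exceeds speed; renormalized", norm)
            step = step * (config.player_speed / norm)
        state.player_xy = _clip_to_arena(state.player_xy + step, config.radius)
        # predator boost bookkeeping
        eff_speed = speed
        if role == "predator":
            if boost_left == 0 and rng.random() < config.boost_prob_per_s * config.frame_dt:
                boost_left = config.boost_duration_frames
            if boost_left > 0:
                eff_speed = speed * config.boost_multiplier
                boost_flags[t] = True
                boost_left -= 1
        if eff_speed > 0:   # a zero-speed agent just sits there
            state.agent_xy = step_agent(state.agent_xy, state.player_xy, role,
                                        eff_speed, rng, config)

    player_path = player_path[:t_end]
    agent_path = agent_path[:t_end]
    boost_flags = boost_flags[:t_end]

    success = captured if spec.condition == HUNT else not captured
    state.outcome_history[spec.condition].append(success)
    state.last_terminated_by_capture = captured

    return TrialLog(
        subject_id=subject_id, run_id=run_id, trial_index=trial_index,
        condition=spec.condition, is_switch=spec.is_switch,
        player_xy=player_path, agent_xy=agent_path, boost_active=boost_flags,
        outcome="success" if success else "failure",
        terminated_by_capture=captured,
        pre_encounter_xy=(np.array(pre_positions).reshape(-1, 2)
                          if pre_positions else np.empty((0, 2))),
    )


def run_session(session_config: SessionConfig, player_policy: PlayerPolicy,
                rng: np.random.Generator, config: ArenaConfig | None = None,
                subject_id: str = "s0", run_id: int = 0) -> SessionLog:
    """Simulate a full run of the trial protocol.

    The first trial's condition is drawn at random and carries no
    switch/stay cue; every later trial switches with probability 0.5.  A
    pre-encounter stage is inserted with probability 0.4 when the previous
    trial ended in a capture.  The agent-speed staircase runs per condition.
    """
    config = config or ArenaConfig()
    state = SessionState(
        player_xy=np.zeros(2), agent_xy=np.zeros(2),
        agent_speed={HUNT: config.agent_speed, ESCAPE: config.agent_speed},
    )
    trials: list[TrialLog] = []
    condition = HUNT if rng.random() < 0.5 else ESCAPE
    for i in range(session_config.n_trials):
        if i == 0:
            is_switch = False
        else:
            is_switch = rng.random() < session_config.switch_prob
            if is_switch:
                condition = ESCAPE if condition == HUNT else HUNT
        pre = None
        if (state.last_terminated_by_capture
                and rng.random() < session_config.pre_encounter_prob):
            pre = rng.uniform(*session_config.pre_duration_range)
        spec = TrialSpec(
            condition=condition, is_switch=is_switch,
            iti=rng.uniform(0.5, 1.5),
            pre_encounter_duration=pre,
            main_duration=rng.uniform(*session_config.main_duration_range),
        )
        trial = run_trial(spec, player_policy, state, rng, config,
                          subject_id=subject_id, run_id=run_id, trial_index=i)
        trials.append(trial)
        if session_config.calibrate:
            state.agent_speed[condition] = update_difficulty(
                state.outcome_history[condition],
                state.agent_speed[condition], condition, config)
    return SessionLog(subject_id=subject_id, run_id=run_id, trials=trials,
                      config=config, final_agent_speed=dict(state.agent_speed))


# --------------------------------------------------------------------------
# long-format log I/O
# --------------------------------------------------------------------------

def session_frames_table(sessions: Sequence[SessionLog]) -> pd.DataFrame:
    """One row per logged frame (pre-encounter and main phases)."""
    rows = []
    for ses in sessions:
        for tr in ses.trials:
            for t, xy in enumerate(tr.pre_encounter_xy):
                rows.append((tr.subject_id, tr.run_id, tr.trial_index,
                             tr.condition, tr.is_switch, "pre", t,
                             xy[0], xy[1], np.nan, np.nan, False, tr.outcome))
            for t in range(tr.n_frames):
                rows.append((tr.subject_id, tr.run_id, tr.trial_index,
                             tr.condition, tr.is_switch, "main", t,
                             tr.player_xy[t, 0], tr.player_xy[t, 1],
                             tr.agent_xy[t, 0], tr.agent_xy[t, 1],
                             bool(tr.boost_active[t]), tr.outcome))
    return pd.DataFrame(rows, columns=[
        "subject", "run", "trial", "condition", "is_switch", "phase",
        "frame", "player_x", "player_y", "agent_x", "agent_y",
        "boost", "outcome"])


def session_trials_table(sessions: Sequence[SessionLog]) -> pd.DataFrame:
    rows = []
    for ses in sessions:
        for tr in ses.trials:
            rows.append((tr.subject_id, tr.run_id, tr.trial_index,
                         tr.condition, tr.is_switch, tr.outcome,
                         tr.terminated_by_capture, tr.n_frames,
                         len(tr.pre_encounter_xy)))
    return pd.DataFrame(rows, columns=[
        "subject", "run", "trial", "condition", "is_switch", "outcome",
        "terminated_by_capture", "n_frames", "n_pre_frames"])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_session_logs(sessions: Sequence[SessionLog], out_dir: str | Path) -> None:
    """Write frames.csv + trials.csv plus a manifest with checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session_frames_table(sessions).to_csv(out / "frames.csv", index=False)
    session_trials_table(sessions).to_csv(out / "trials.csv", index=False)
    manifest = {name: _sha256(out / name) for name in ("frames.csv", "trials.csv")}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_session_logs(in_dir: str | Path,
                      config: ArenaConfig | None = None) -> list[SessionLog]:
    """Round-trip reader for :func:`write_session_logs` (verifies checksums)."""
    src = Path(in_dir)
    manifest_path = src / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        for name, digest in manifest.items():
            if _sha256(src / name) != digest:
                raise IOError(f"checksum mismatch for {name}")
    frames = pd.read_csv(src / "frames.csv")
    trials = pd.read_csv(src / "trials.csv")
    config = config or ArenaConfig()
    sessions: list[SessionLog] = []
    for (subj, run), tmeta in trials.groupby(["subject", "run"], sort=False):
        f_ses = frames[(frames.subject == subj) & (frames.run == run)]
        logs = []
        for row in tmeta.itertuples():
            f = f_ses[f_ses.trial == row.trial]
            main = f[f.phase == "main"].sort_values("frame")
            pre = f[f.phase == "pre"].sort_values("frame")
            logs.append(TrialLog(
                subject_id=str(subj), run_id=int(run), trial_index=int(row.trial),
                condition=str(row.condition), is_switch=bool(row.is_switch),
                player_xy=main[["player_x", "player_y"]].to_numpy(float),
                agent_xy=main[["agent_x", "agent_y"]].to_numpy(float),
                boost_active=main["boost"].to_numpy(bool),
                outcome=str(row.outcome),
                terminated_by_capture=bool(row.terminated_by_capture),
                pre_encounter_xy=pre[["player_x", "player_y"]].to_numpy(float),
            ))
        sessions.append(SessionLog(subject_id=str(subj), run_id=int(run),
                                   trials=logs, config=config))
    return sessions
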