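"""Trajectory statistics for hunt/escape behavior.

Four summaries characterize movement in the two conditions: thigmotaxis
(the fraction of time spent in the outer half of the arena by area — the
anxiety-like preparatory behavior expected before escape, because the
predator tends to appear centrally), linearity (mean cosine between the
actual step and the ideal straight-line direction: toward the prey when
hunting, directly away from the predator when escaping), movement
variability (mean absolute frame-to-frame heading change in degrees, with
a direction-changes-per-second variant), and success rates under arbitrary
stratifications.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .arena_sim import ESCAPE, HUNT, SessionLog, TrialLog

#: cap of the direction-changes-per-second variant (display convention)
MAX_CHANGES_PER_S = 59.0


def thigmotaxis(positions: np.ndarray, radius: float) -> float:
    """Fraction of frames outside the circle enclosing 50% of the arena
    area (i.e. at radial distance > radius/sqrt(2); exact boundary counts
    as inside)."""
    xy = np.asarray(positions, dtype=float)
    if len(xy) == 0:
        raise ValueError("thigmotaxis of an empty trajectory is undefined")
    r = np.linalg.norm(xy, axis=1)
    return float(np.mean(r > radius / math.sqrt(2.0)))


def _moving_steps(player_xy: np.ndarray, min_norm: float = 1e-12):
    steps = np.diff(np.asarray(player_xy, dtype=float), axis=0)
    norms = np.linalg.norm(steps, axis=1)
    return steps, norms, norms > min_norm


def linearity(trial_log: TrialLog) -> float:
    """Mean dot product between the unit actual step and the unit ideal
    direction (player->agent in hunt; agent->player in escape).  Frames
    with no player displacement are skipped; an all-null trial is
    undefined (returns NaN, excluded by aggregators)."""
    steps, norms, moving = _moving_steps(trial_log.player_xy)
    if not moving.any():
        return float("nan")
    ideal = trial_log.agent_xy[:-1] - trial_log.player_xy[:-1]
    if trial_log.condition == ESCAPE:
        ideal = -ideal
    ideal_norm = np.linalg.norm(ideal, axis=1)
    ok = moving & (ideal_norm > 1e-12)
    if not ok.any():
        return float("nan")
    cos = np.sum(steps[ok] * ideal[ok], axis=1) / (norms[ok] * ideal_norm[ok])
    return float(np.mean(cos))


def _headings_deg(steps: np.ndarray) -> np.ndarray:
    return np.degrees(np.arctan2(steps[:, 1], steps[:, 0]))


def movement_variability(trial_log: TrialLog, frame_dt: float = 0.016,
                         exclude_boost: bool = False,
                         change_tol_deg: float = 1e-9) -> tuple[float, float]:
    """(mean |heading change| in deg/frame, direction changes per second).

    Headings are defined only on moving frames; a pause breaks the chain
    (no heading change is scored across it).  The per-second variant counts
    frames with any heading change, divides by the trial duration, and is
    capped at 59 to match the display convention of the count-based scale.
    ``exclude_boost`` drops frames on which the predator boost was active.
    """
    steps, norms, moving = _moving_steps(trial_log.player_xy)
    if exclude_boost and len(trial_log.boost_active) >= len(steps):
        moving = moving & ~np.asarray(trial_log.boost_active[:len(steps)], bool)
    if moving.sum() < 2:
        return 0.0, 0.0
    idx = np.nonzero(moving)[0]
    head = _headings_deg(steps[idx])
    consecutive = np.diff(idx) == 1   # chains broken by pauses
    if not consecutive.any():
        return 0.0, 0.0
    dh = np.abs(np.diff(head))[consecutive]
    dh = np.minimum(dh, 360.0 - dh)   # wrap to [0, 180]
    deg_per_frame = float(np.mean(dh))
    duration_s = len(trial_log.player_xy) * frame_dt
    n_changes = int(np.sum(dh > change_tol_deg))
    changes_per_s = min(n_changes / duration_s, MAX_CHANGES_PER_S)
    return deg_per_frame, changes_per_s


def success_rates(session_logs: Sequence[SessionLog],
                  by: Iterable[str] = ("condition",)) -> pd.DataFrame:
    """Per-subject success proportions stratified by the given trial
    columns (any of: condition, is_switch).  Empty strata simply do not
    appear."""
    rows = []
    for ses in session_logs:
        for tr in ses.trials:
            rows.append((tr.subject_id, tr.condition, tr.is_switch,
                         tr.outcome == "success"))
    df = pd.DataFrame(rows, columns=["subject", "condition", "is_switch",
                                     "success"])
    keys = ["subject"] + list(by)
    out = df.groupby(keys, as_index=False).agg(
        success_rate=("success", "mean"), n_trials=("success", "size"))
    return out


def trial_metrics_table(session_logs: Sequence[SessionLog],
                        exclude_boost: bool = False) -> pd.DataFrame:
    """Per-trial metric rows (plus pre-encounter thigmotaxis when the trial
    had a pre-encounter stage)."""
    rows = []
    for ses in session_logs:
        radius = ses.config.radius
        dt = ses.config.frame_dt
        for tr in ses.trials:
            lin = linearity(tr)
            var_deg, var_cps = movement_variability(tr, dt,
                                                    exclude_boost=exclude_boost)
            thig = thigmotaxis(tr.player_xy, radius)
            pre_thig = (thigmotaxis(tr.pre_encounter_xy, radius)
                        if len(tr.pre_encounter_xy) else float("nan"))
            rows.append((tr.subject_id, tr.run_id, tr.trial_index,
                         tr.condition, tr.is_switch, thig, pre_thig, lin,
                         var_deg, var_cps, tr.outcome == "success"))
    return pd.DataFrame(rows, columns=[
        "subject", "run", "trial", "condition", "is_switch", "thigmotaxis",
        "pre_thigmotaxis", "linearity", "variability_deg_per_frame",
        "variability_changes_per_s", "success"])


def subject_condition_means(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate trial metrics to subject x condition means."""
    cols = ["thigmotaxis", "pre_thigmotaxis", "linearity",
            "variability_deg_per_frame", "variability_changes_per_s",
            "success"]
    return (trial_table.groupby(["subject", "condition"], as_index=False)
            [cols].mean())
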