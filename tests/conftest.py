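"""Shared fixtures: small synthetic cohorts reused across test modules.

Everything is generated programmatically at collection time from fixed
seeds; nothing is read from disk.
"""

import numpy as np
import pytest

import huntswitch as hs


@pytest.fixture(scope="session")
def cohort3() -> hs.CohortDataset:
    """3 subjects x 20 two-second trials, joystick modality, default
    condition means."""
    cfg = hs.CohortConfig(n_subjects=3, trials_per_subject=20,
                          trial_duration_s=(2.0, 2.0), master_seed=7)
    return hs.generate_cohort(cfg)


@pytest.fixture(scope="session")
def fits3(cohort3):
    return hs.fit_sessions(cohort3.sessions, ("M3",))


@pytest.fixture(scope="session")
def feats3(fits3):
    return hs.trial_features(fits3)


@pytest.fixture(scope="session")
def loto3(feats3) -> dict:
    return {str(subj): hs.fit_decoder_loto(grp)
            for subj, grp in feats3.groupby("subject")}


@pytest.fixture(scope="session")
def cp_table3(cohort3, fits3, loto3):
    import huntswitch.arena_sim as arena
    cp = hs.cp_tables(fits3, loto3)
    meta = arena.session_trials_table(cohort3.sessions)
    return cp.merge(
        meta[["subject", "run", "trial", "is_switch", "outcome"]],
        on=["subject", "run", "trial"], how="left")


class GreedyPlayer:
    """Fixed-skill scripted player: straight pursuit in hunt; in escape,
    flight away from the predator blending into wall-following so it is
    not pinned against the boundary."""

    def __init__(self, speed: float = 0.006, radius: float = 0.5):
        self.speed = speed
        self.radius = radius
        self.condition = hs.HUNT

    def reset(self, condition, rng):
        self.condition = condition

    def step(self, frame, player_xy, agent_history, rng):
        agent = agent_history[-1]
        d = agent - player_xy
        n = np.linalg.norm(d)
        direction = d / n if n > 1e-12 else np.array([1.0, 0.0])
        if self.condition == hs.ESCAPE:
            direction = -direction
            r = np.linalg.norm(player_xy)
            if r > 0.7 * self.radius:
                tang = np.array([-player_xy[1], player_xy[0]]) / r
                if tang @ direction < 0:
                    tang = -tang
                w = min(1.0, (r - 0.7 * self.radius) / (0.25 * self.radius))
                direction = (1 - w) * direction + w * tang
                direction /= np.linalg.norm(direction)
        return self.speed * direction


@pytest.fixture(scope="session")
def calibrated_session() -> hs.SessionLog:
    """A 200-trial closed-loop session of a fixed-skill scripted player
    with the difficulty staircase on."""
    cfg = hs.SessionConfig(n_trials=200, main_duration_range=(2.0, 6.0))
    return hs.run_session(cfg, GreedyPlayer(), np.random.default_rng(101))
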