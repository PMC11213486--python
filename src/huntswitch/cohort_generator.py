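"""Synthetic cohorts of simulated subjects.

Each subject's player is the variable-timescale predictive model (M3) with
condition-specific parameters drawn around the group condition means
reported for the task (joystick modality: theta 15.5 hunt / 11.4 escape,
tau 322.0 / 49.6, mu 0.68 / 0.74; keyboard modality: theta 15.6 / 10.9,
tau 383.8 / 29.3, mu 0.95 / 0.95).  Between-subject spread defaults to 15%
of each mean, truncated to the parameter bounds.  Subjects play full
sessions against the scripted arena agent (switch probability 0.5,
calibration staircase on), so every downstream stage — window fitting,
decoding, behavioral metrics, switching statistics — can run end-to-end
without any external data.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .arena_sim import (ArenaConfig, ESCAPE, HUNT, SessionConfig, SessionLog,
                        run_session)
from .movement_models import (ActionSet, JOYSTICK_ACTIONS, KEYBOARD_ACTIONS,
                              ModelParams, MovementPolicy, MU_BOUNDS,
                              TAU_BOUNDS, THETA_BOUNDS)

#: group condition means (theta, tau, mu) per modality
CONDITION_MEANS = {
    "joystick-129": {HUNT: (15.5, 322.0, 0.68), ESCAPE: (11.4, 49.6, 0.74)},
    "keyboard-9":   {HUNT: (15.6, 383.8, 0.95), ESCAPE: (10.9, 29.3, 0.95)},
}

_BOUNDS = (THETA_BOUNDS, TAU_BOUNDS, MU_BOUNDS)


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 5
    trials_per_subject: int = 60
    trial_duration_s: tuple[float, float] = (2.0, 4.0)
    modality: str = "joystick-129"
    condition_means: dict | None = None     # overrides CONDITION_MEANS
    between_subject_rel_sd: float = 0.15    # SD as a fraction of each mean
    switch_prob: float = 0.5
    master_seed: int = 0

    @property
    def action_set(self) -> ActionSet:
        return JOYSTICK_ACTIONS if self.modality == "joystick-129" \
            else KEYBOARD_ACTIONS

    def means(self) -> dict:
        if self.condition_means is not None:
            return self.condition_means
        return CONDITION_MEANS[self.modality]


@dataclass
class CohortDataset:
    sessions: list[SessionLog]
    true_params: dict            # subject -> condition -> ModelParams
    config: CohortConfig
    manifest: dict = field(default_factory=dict)


def sample_subject_params(config: CohortConfig,
                          rng: np.random.Generator) -> dict[str, ModelParams]:
    """Draw one subject's (theta, tau, mu) per condition.

    Truncated-normal draws around the condition means with SD equal to
    ``between_subject_rel_sd`` times the |mean| (zero SD reproduces the
    means exactly), truncated to the parameter bounds.  Tau keeps a minimal
    SD so a zero mean stays usable.
    """
    out = {}
    for cond, mean in config.means().items():
        vals = []
        for m, (lo, hi) in zip(mean, _BOUNDS):
            sd = config.between_subject_rel_sd * abs(m)
            if sd == 0:
                vals.append(float(np.clip(m, lo, hi)))
                continue
            a, b = (lo - m) / sd, (hi - m) / sd
            vals.append(float(truncnorm.rvs(a, b, loc=m, scale=sd,
                                            random_state=rng)))
        out[cond] = ModelParams(theta=vals[0], tau=vals[1], mu=vals[2])
    return out


def _config_hash(config: CohortConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def generate_cohort(config: CohortConfig,
                    arena: ArenaConfig | None = None) -> CohortDataset:
    """Simulate the full cohort; reproducible from (config, master_seed)."""
    arena = arena or ArenaConfig()
    sessions = []
    truth = {}
    subject_seeds = {}
    root = np.random.SeedSequence(config.master_seed)
    children = root.spawn(config.n_subjects)
    for i, child in enumerate(children):
        subj = f"s{i:02d}"
        rng = np.random.default_rng(child)
        params = sample_subject_params(config, rng)
        truth[subj] = params
        policy = MovementPolicy(
            "M3", lambda c, p=params: p[c],
            action_set=config.action_set, speed=arena.player_speed)
        ses_cfg = SessionConfig(
            n_trials=config.trials_per_subject,
            switch_prob=config.switch_prob,
            main_duration_range=config.trial_duration_s)
        sessions.append(run_session(ses_cfg, policy, rng, arena,
                                    subject_id=subj, run_id=0))
        subject_seeds[subj] = child.entropy
    manifest = {"config_hash": _config_hash(config),
                "master_seed": config.master_seed,
                "subject_seeds": {k: str(v) for k, v in subject_seeds.items()}}
    return CohortDataset(sessions, truth, config, manifest)


def permute_condition_labels(dataset: CohortDataset,
                             rng: np.random.Generator) -> CohortDataset:
    """Shuffle condition labels within each subject; kinematics untouched.

    Breaks the label-behavior association while preserving each subject's
    label multiset — the null construction for chance-level decoding.
    """
    new_sessions = []
    for ses in dataset.sessions:
        new = copy.copy(ses)
        new.trials = [copy.copy(tr) for tr in ses.trials]
        labels = [tr.condition for tr in new.trials]
        perm = rng.permutation(len(labels))
        for tr, j in zip(new.trials, perm):
            tr.condition = labels[j]
        new_sessions.append(new)
    return CohortDataset(new_sessions, dataset.true_params, dataset.config,
                         dict(dataset.manifest, permuted=True))
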