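"""Decoding the task condition from fitted model parameters, and the
condition-specific state C_p.

The three M3 parameters (theta, tau, mu), averaged over a trial's windows,
form that trial's feature vector.  A linear support-vector machine with
Platt-calibrated probabilistic output is trained per subject and evaluated
by leave-one-trial-out cross-validation; the calibrated posterior converts
into the condition-specific state C_p — the decoder's probability for the
condition the player is actually in (P(hunt) on hunt trials, 1 - P(hunt)
on escape trials).  C_p = 0.5 is an undifferentiated movement-generation
state, C_p = 1 a fully condition-specific one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .arena_sim import HUNT, ESCAPE

FEATURES = ("theta", "tau", "mu")


# --------------------------------------------------------------------------
# features
# --------------------------------------------------------------------------

def trial_features(window_fits: pd.DataFrame, model_id: str = "M3") -> pd.DataFrame:
    """Average the fitted parameters over each trial's windows.

    Returns one row per trial: subject, run, trial, condition, theta, tau,
    mu.  Trials without windows are absent.
    """
    f = window_fits[window_fits.model == model_id]
    agg = (f.groupby(["subject", "run", "trial", "condition"], as_index=False)
             [list(FEATURES)].mean())
    return agg


# --------------------------------------------------------------------------
# leave-one-trial-out decoding
# --------------------------------------------------------------------------

def _zscore_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mean, sd


def _make_calibrated_svm() -> CalibratedClassifierCV:
    # linear-kernel maximum-margin classifier, C = 1, with a sigmoid (Platt)
    # posterior fitted on a 3-fold internal split of the training fold;
    # class-balanced hinge weights keep the leave-one-trial-out estimate
    # centred at chance under label permutation
    return CalibratedClassifierCV(
        SVC(kernel="linear", C=1.0, class_weight="balanced"),
        method="sigmoid", cv=3)


@dataclass
class DecoderFold:
    """Decoder trained with one trial held out, plus the fold's scaler."""

    mean: np.ndarray
    sd: np.ndarray
    clf: CalibratedClassifierCV
    hunt_col: int

    def posterior_hunt(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.mean) / self.sd
        return self.clf.predict_proba(Z)[:, self.hunt_col]


@dataclass
class LotoResult:
    """Per-trial LOTO posteriors and accuracy for one subject."""

    subject_id: str
    table: pd.DataFrame          # run, trial, condition, posterior_hunt, correct
    accuracy: float
    folds: dict = field(default_factory=dict, repr=False)   # trial key -> DecoderFold


def fit_decoder_loto(features: pd.DataFrame, keep_folds: bool = True) -> LotoResult:
    """Leave-one-trial-out decoding of hunt vs. escape for one subject.

    For each trial, an SVM is trained on all other trials (features
    z-scored on the training fold only; Platt calibration inside the
    training fold) and applied to the held-out trial.  Accuracy is the
    fraction of held-out trials whose argmax posterior matches their
    condition.  ``folds`` maps (run, trial) to the fold's decoder so
    window-level C_p can be scored without leakage.
    """
    subjects = features["subject"].unique()
    if len(subjects) != 1:
        raise ValueError("fit_decoder_loto operates on a single subject")
    conds = set(features["condition"])
    if conds != {HUNT, ESCAPE}:
        raise ValueError("need trials from both conditions")
    if features.groupby("condition").size().min() < 2:
        raise ValueError("need >= 2 trials per condition")

    X = features[list(FEATURES)].to_numpy(float)
    y = (features["condition"] == HUNT).to_numpy()
    keys = list(zip(features["run"], features["trial"]))
    n = len(X)
    post = np.empty(n)
    folds: dict = {}
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        mean, sd = _zscore_fit(X[mask])
        clf = _make_calibrated_svm()
        clf.fit((X[mask] - mean) / sd, y[mask])
        hunt_col = int(np.nonzero(clf.classes_ == True)[0][0])  # noqa: E712
        fold = DecoderFold(mean, sd, clf, hunt_col)
        post[i] = fold.posterior_hunt(X[i:i + 1])[0]
        if keep_folds:
            folds[keys[i]] = fold
        mask[i] = True

    pred_hunt = post >= 0.5
    correct = pred_hunt == y
    table = features[["run", "trial", "condition"]].copy()
    table["posterior_hunt"] = post
    table["correct"] = correct
    return LotoResult(str(subjects[0]), table, float(correct.mean()), folds)


def _loto_accuracy_fast(X: np.ndarray, y: np.ndarray) -> float:
    """LOTO accuracy with an uncalibrated linear SVM (for permutation
    nulls, where only the argmax matters)."""
    n = len(X)
    correct = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            mask[i] = True
            continue
        mean, sd = _zscore_fit(X[mask])
        clf = SVC(kernel="linear", C=1.0, class_weight="balanced")
        clf.fit((X[mask] - mean) / sd, y[mask])
        correct += int(clf.predict(((X[i] - mean) / sd)[None, :])[0] == y[i])
        mask[i] = True
    return correct / n


# --------------------------------------------------------------------------
# condition-specific state
# --------------------------------------------------------------------------

def cp_from_posterior(posterior_hunt: float, condition: str) -> float:
    """Task-appropriate decoding probability: the posterior of the
    condition the trial is actually in."""
    if not 0.0 <= posterior_hunt <= 1.0:
        raise ValueError(f"posterior {posterior_hunt} outside [0, 1]")
    if condition == HUNT:
        return float(posterior_hunt)
    if condition == ESCAPE:
        return float(1.0 - posterior_hunt)
    raise ValueError(f"unknown condition {condition!r}")


@dataclass
class CpSeries:
    subject_id: str
    run_id: int
    trial_index: int
    condition: str
    cp: np.ndarray               # per-window C_p
    window_times: np.ndarray     # window starts in s from trial start

    @property
    def initial_cp(self) -> float:
        return float(self.cp[0])

    @property
    def final_cp(self) -> float:
        return float(self.cp[-1])

    @property
    def trial_mean_cp(self) -> float:
        return float(self.cp.mean())


def cp_timecourse(window_fits: pd.DataFrame, fold: DecoderFold,
                  condition: str, subject_id: str = "s0", run_id: int = 0,
                  trial_index: int = 0,
                  frame_dt: float = 0.016) -> CpSeries | None:
    """Score each window of one trial with a leave-that-trial-out decoder.

    ``window_fits`` holds the trial's per-window M3 parameters; ``fold``
    must have been trained with this trial excluded.  Returns None for a
    trial with zero windows (excluded downstream).
    """
    if len(window_fits) == 0:
        return None
    X = window_fits[list(FEATURES)].to_numpy(float)
    post = fold.posterior_hunt(X)
    cp = np.array([cp_from_posterior(p, condition) for p in post])
    times = window_fits["start"].to_numpy(float) * frame_dt
    return CpSeries(subject_id, run_id, trial_index, condition, cp, times)


def cp_tables(window_fits: pd.DataFrame,
              loto_by_subject: dict[str, LotoResult],
              frame_dt: float = 0.016) -> pd.DataFrame:
    """Window-level C_p for every trial of every subject (LOTO discipline).

    Returns one row per window: subject, run, trial, condition, window,
    time_s, cp, plus trial summaries initial/final/mean replicated per row.
    """
    f = window_fits[window_fits.model == "M3"]
    rows = []
    for (subj, run, trial, cond), grp in f.groupby(
            ["subject", "run", "trial", "condition"], sort=False):
        loto = loto_by_subject[str(subj)]
        fold = loto.folds.get((run, trial))
        if fold is None:
            continue
        series = cp_timecourse(grp.sort_values("window"), fold, cond,
                               str(subj), int(run), int(trial), frame_dt)
        if series is None:
            continue
        for w, (cp, t) in enumerate(zip(series.cp, series.window_times)):
            rows.append((subj, run, trial, cond, w, t, cp,
                         series.initial_cp, series.final_cp,
                         series.trial_mean_cp))
    return pd.DataFrame(rows, columns=[
        "subject", "run", "trial", "condition", "window", "time_s", "cp",
        "initial_cp", "final_cp", "trial_mean_cp"])


# --------------------------------------------------------------------------
# permutation null
# --------------------------------------------------------------------------

def decoding_null(features: pd.DataFrame, rng: np.random.Generator,
                  n_perm: int = 100) -> tuple[np.ndarray, float]:
    """Within-subject label-permutation null for LOTO decoding accuracy.

    Labels are shuffled within each subject, the full LOTO pipeline is
    re-run (uncalibrated: the null concerns the argmax decision only), and
    the subject-mean accuracy recorded per permutation.  Returns the null
    distribution and the empirical p-value of the observed (unpermuted)
    accuracy, p = (1 + #null >= obs) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    by_subj = []
    for _, grp in features.groupby("subject", sort=False):
        X = grp[list(FEATURES)].to_numpy(float)
        y = (grp["condition"] == HUNT).to_numpy()
        by_subj.append((X, y))
    observed = float(np.mean([_loto_accuracy_fast(X, y) for X, y in by_subj]))
    null = np.empty(n_perm)
    for p in range(n_perm):
        accs = [_loto_accuracy_fast(X, rng.permutation(y)) for X, y in by_subj]
        null[p] = np.mean(accs)
    p_emp = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return null, p_emp
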