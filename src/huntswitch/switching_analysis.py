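"""Switching statistics on the condition-specific state C_p.

After a switch cue the movement-generation state must travel from the
previous condition's attractor to the new one.  The transition magnitude
for a switch trial is

    transition = initial C_p(current trial) - (1 - final C_p(previous trial)),

i.e. how far the state moved toward the new task beyond where the previous
trial left it (expressed on the current trial's C_p axis: a final C_p of
0.76 on a hunt trial is an initial C_p of 0.24 for the following escape
trial).  Suppression load is probed by regressing the current trial's
initial C_p on the previous trial's final C_p (switch trials only): a
strongly condition-specific previous state should impede the transition.
Time-to-criterion is the time after trial start at which C_p first reaches
0.6.  Success is related to the trial-mean C_p with a mixed-effects
logistic regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

CP_CRITERION = 0.6


def transition_magnitude(prev_final_cp: float, curr_initial_cp: float) -> float:
    """State movement toward the current task across a switch."""
    for v in (prev_final_cp, curr_initial_cp):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"C_p value {v} outside [0, 1]")
    return float(curr_initial_cp - (1.0 - prev_final_cp))


def time_to_criterion(cp_series: np.ndarray, threshold: float = CP_CRITERION,
                      times: np.ndarray | None = None,
                      step_s: float = 0.25) -> tuple[float, bool]:
    """(time of first window with C_p >= threshold, censored flag).

    ``times`` gives each window's start in seconds from trial start; when
    omitted, windows are assumed ``step_s`` apart starting at 0.  Censored
    (never reached) series return (nan, True).
    """
    cp = np.asarray(cp_series, dtype=float)
    if len(cp) == 0:
        raise ValueError("empty C_p series")
    if times is None:
        times = np.arange(len(cp)) * step_s
    hit = np.nonzero(cp >= threshold)[0]
    if len(hit) == 0:
        return float("nan"), True
    return float(times[hit[0]]), False


def transition_table(cp_table: pd.DataFrame,
                     threshold: float = CP_CRITERION) -> pd.DataFrame:
    """Per-trial transition records from a window-level C_p table.

    Requires columns subject, run, trial, condition, is_switch (merged in
    by the caller if absent), window, time_s, cp.  Transition magnitude is
    defined for trials with a predecessor in the same run; trials with zero
    windows are absent from cp_table and hence excluded listwise.
    """
    if "is_switch" not in cp_table:
        raise ValueError("cp_table needs an is_switch column "
                         "(merge the trial metadata in first)")
    per_trial = (cp_table.sort_values("window")
                 .groupby(["subject", "run", "trial"], as_index=False)
                 .agg(condition=("condition", "first"),
                      is_switch=("is_switch", "first"),
                      initial_cp=("cp", "first"), final_cp=("cp", "last"),
                      mean_cp=("cp", "mean")))
    rows = []
    for (subj, run), grp in per_trial.groupby(["subject", "run"], sort=False):
        grp = grp.sort_values("trial")
        prev_final = grp["final_cp"].shift(1)
        prev_trial = grp["trial"].shift(1)
        for i, row in enumerate(grp.itertuples()):
            pf = prev_final.iloc[i]
            contiguous = (not np.isnan(pf)) and prev_trial.iloc[i] == row.trial - 1
            trans = (transition_magnitude(pf, row.initial_cp)
                     if contiguous else float("nan"))
            sub_cp = cp_table[(cp_table.subject == subj) & (cp_table.run == run)
                              & (cp_table.trial == row.trial)].sort_values("window")
            t = sub_cp["time_s"].to_numpy(float)
            ttc, censored = time_to_criterion(sub_cp["cp"].to_numpy(float),
                                              threshold, times=t - t[0])
            rows.append((subj, run, row.trial, row.condition,
                         bool(row.is_switch), pf, row.initial_cp,
                         row.final_cp, row.mean_cp, trans, ttc, censored))
    return pd.DataFrame(rows, columns=[
        "subject", "run", "trial", "condition", "is_switch", "prev_final_cp",
        "initial_cp", "final_cp", "mean_cp", "transition_magnitude",
        "time_to_criterion_s", "ttc_censored"])


# --------------------------------------------------------------------------
# regressions
# --------------------------------------------------------------------------

@dataclass
class RegressionResult:
    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    family: str                      # "linear-mixed" | "logistic-mixed" | fallback
    groups: tuple
    flags: list[str] = field(default_factory=list)

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {"coef": float(self.coef[i]), "se": float(self.se[i]),
                "p": float(self.pvalues[i])}


def _covariate_terms(df: pd.DataFrame) -> list[str]:
    terms = []
    if "age" in df:
        terms.append("age")
    if "sex" in df:
        terms.append("C(sex)")
    return terms


def _mixedlm(formula: str, df: pd.DataFrame, groups: str,
             vc: dict | None) -> RegressionResult:
    flags = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df[groups],
                                vc_formula=vc, re_formula="1")
            fit = model.fit(method="lbfgs", maxiter=200)
        fe = fit.fe_params
        return RegressionResult(list(fe.index), fe.to_numpy(),
                                fit.bse[fe.index].to_numpy(),
                                fit.pvalues[fe.index].to_numpy(),
                                "linear-mixed",
                                (groups,) + tuple(vc or ()), flags)
    except Exception as err:   # singular grouping -> fixed effects, robust SE
        flags.append(f"mixed model failed ({type(err).__name__}); "
                     "cluster-robust OLS fallback")
        fit = smf.ols(formula, df).fit(cov_type="cluster",
                                       cov_kwds={"groups": df[groups]})
        return RegressionResult(list(fit.params.index), fit.params.to_numpy(),
                                fit.bse.to_numpy(), fit.pvalues.to_numpy(),
                                "ols-cluster-robust", (groups,), flags)


def suppression_load_model(transition_records: pd.DataFrame,
                           outcome: str = "initial_cp") -> RegressionResult:
    """Mixed linear regression of the post-switch state on the previous
    trial's final C_p (switch trials only).

    ``outcome`` may be "initial_cp" (suppression load: does a highly
    condition-specific previous state depress the initial state of the new
    task?) or "time_to_criterion_s" (censored trials excluded).  Random
    intercepts for subject, plus run when several runs are present; age and
    sex enter as covariates when the columns exist.
    """
    df = transition_records[transition_records.is_switch].copy()
    df = df.dropna(subset=["prev_final_cp"])
    if outcome == "time_to_criterion_s":
        df = df[~df.ttc_censored].dropna(subset=[outcome])
    if len(df) < 5:
        raise ValueError("too few switch trials for the regression")
    terms = ["prev_final_cp"] + _covariate_terms(df)
    formula = f"{outcome} ~ " + " + ".join(terms)
    vc = {"run": "0 + C(run)"} if df["run"].nunique() > 1 else None
    return _mixedlm(formula, df, "subject", vc)


def success_cp_model(trials: pd.DataFrame) -> RegressionResult:
    """Mixed-effects logistic regression of trial success on trial-mean
    C_p (random intercept per subject; age/sex covariates when present).

    Fitted by the variational-Bayes binomial mixed GLM; on failure or
    complete separation, falls back to a cluster-robust plain logistic
    fit, flagged.
    """
    df = trials.dropna(subset=["mean_cp", "success"]).copy()
    df["success"] = df["success"].astype(int)
    if df["mean_cp"].nunique() <= 1:
        raise ValueError("C_p is constant across trials: slope unidentified")
    terms = ["mean_cp"] + _covariate_terms(df)
    formula = "success ~ " + " + ".join(terms)
    flags = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.BinomialBayesMixedGLM.from_formula(
                formula, {"subject": "0 + C(subject)"}, df)
            fit = model.fit_vb()
        names = list(model.exog_names)
        k = len(names)
        return RegressionResult(names, fit.fe_mean[:k], fit.fe_sd[:k],
                                2 * (1 - _norm_cdf(np.abs(fit.fe_mean[:k] /
                                                          fit.fe_sd[:k]))),
                                "logistic-mixed", ("subject",), flags)
    except Exception as err:
        flags.append(f"mixed logistic failed ({type(err).__name__}); "
                     "cluster-robust Logit fallback")
        fit = smf.logit(formula, df).fit(disp=0, cov_type="cluster",
                                         cov_kwds={"groups": df["subject"]})
        return RegressionResult(list(fit.params.index), fit.params.to_numpy(),
                                fit.bse.to_numpy(), fit.pvalues.to_numpy(),
                                "logit-cluster-robust", ("subject",), flags)


def _norm_cdf(x: np.ndarray) -> np.ndarray:
    from scipy.stats import norm
    return norm.cdf(x)
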