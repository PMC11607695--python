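"""Daily standardization, time budgets, and the candidate DEE model set.

Two families of linear models relate mass-specific daily energy expenditure
(msDEE, kJ day^-1 g^-1) to behaviour:

* time-budget models: msDEE = sum_g MR_g * T_g, with the intercept fixed at
  zero because the grouped times already cover the whole 24 h; the
  coefficients are activity-specific metabolic rates (kJ h^-1 g^-1);
* DBA models: msDEE = alpha + sum_g c_g * DBA_g, with a free intercept alpha
  representing expenditure at zero activity (a BMR-like term).

The default candidate set holds 12 designs: five partitions of the four
activities {colony, commuting, foraging, resting}, each under both predictor
kinds, plus two null models (intercept-only and total-DBA).  Designs are
ranked by AICc, the small-sample-corrected Akaike criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ACTIVITIES = ("col", "com", "for", "rest")

__all__ = [
    "ACTIVITIES", "Design", "DeeModelFit",
    "standardize_daily", "time_budget", "activity_dba",
    "candidate_models", "fit_dee_model", "aicc_rank", "predictive_r",
    "activity_rates", "group_difference", "build_summaries",
]


def standardize_daily(value, sampling_hours: float, min_hours: float = 20.0):
    """Scale a deployment total to a 24-h day: value * 24 / sampling_hours."""
    if sampling_hours <= 0:
        raise ValueError("sampling_hours must be positive")
    if sampling_hours < min_hours:
        warnings.warn(f"only {sampling_hours:.1f} h of sampling; daily "
                      "standardization is unreliable", stacklevel=2)
    return np.asarray(value, dtype=float) * 24.0 / sampling_hours


def time_budget(states, sampling_hours: float | None = None,
                n_states: int = 4) -> np.ndarray:
    """Hours per activity per 24 h from a decoded minute-state sequence."""
    states = np.asarray(states)
    counts = np.bincount(states, minlength=n_states).astype(float)
    hours = counts / 60.0
    if sampling_hours is None:
        sampling_hours = states.size / 60.0
    return standardize_daily(hours, sampling_hours)


def activity_dba(minutes_dba: np.ndarray, states: np.ndarray,
                 sampling_hours: float, n_states: int = 4) -> dict:
    """Daily-standardized total and per-activity DBA from per-minute DBA."""
    total = float(standardize_daily(np.nansum(minutes_dba), sampling_hours))
    per = {}
    for j, act in enumerate(ACTIVITIES[:n_states]):
        per[f"DBA_{act}"] = float(standardize_daily(
            np.nansum(minutes_dba[states == j]), sampling_hours))
    per["DBA_total"] = total
    return per


# ---------------------------------------------------------------------------
# Candidate designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Design:
    """One candidate model: a named activity partition plus a predictor kind."""

    name: str
    kind: str                      # "time" | "dba" | "dba_total" | "intercept"
    groups: tuple = ()             # tuple of tuples of activity codes

    def __post_init__(self):
        if self.kind in ("time", "dba"):
            flat = [a for g in self.groups for a in g]
            if sorted(flat) != sorted(ACTIVITIES):
                raise ValueError(
                    f"design {self.name!r}: groups {self.groups} are not a "
                    "partition of the four activities")

    @property
    def has_intercept(self) -> bool:
        # zero intercept only when the grouped times cover the full day
        return self.kind != "time"


_PARTITIONS = [
    (("col",), ("com",), ("for",), ("rest",)),
    (("col",), ("com", "for", "rest")),
    (("col", "rest"), ("com", "for")),
    (("col",), ("com", "for"), ("rest",)),
    (("col", "rest"), ("com",), ("for",)),
]


def _pname(groups) -> str:
    return " | ".join("+".join(g) for g in groups)


def candidate_models(partitions=None) -> list:
    """The default 12-design candidate set (10 activity models + 2 nulls).

    Five activity partitions x {time-budget, DBA} predictors, plus an
    intercept-only null and a total-DBA null.  Pass ``partitions`` to use a
    different partition set.
    """
    parts = _PARTITIONS if partitions is None else list(partitions)
    designs = []
    for p in parts:
        designs.append(Design(name=f"T: {_pname(p)}", kind="time", groups=tuple(p)))
    for p in parts:
        designs.append(Design(name=f"DBA: {_pname(p)}", kind="dba", groups=tuple(p)))
    designs.append(Design(name="null: intercept", kind="intercept"))
    designs.append(Design(name="null: total DBA", kind="dba_total"))
    return designs


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class DeeModelFit:
    design: Design
    coef: dict                     # predictor name -> estimate
    intercept: float | None
    n: int
    k: int                         # parameters incl. residual variance
    loglik: float
    rss: float
    fitted: np.ndarray
    aicc: float = np.nan
    daicc: float = np.nan
    r: float = np.nan
    se: dict = field(default_factory=dict)


def _design_matrix(design: Design, s: pd.DataFrame):
    names, cols = [], []
    if design.kind == "time":
        for g in design.groups:
            names.append("T_" + "+".join(g))
            cols.append(sum(s[f"T_{a}"].to_numpy(float) for a in g))
    elif design.kind == "dba":
        for g in design.groups:
            names.append("DBA_" + "+".join(g))
            cols.append(sum(s[f"DBA_{a}"].to_numpy(float) for a in g))
    elif design.kind == "dba_total":
        names.append("DBA_total")
        cols.append(s["DBA_total"].to_numpy(float))
    X = np.column_stack(cols) if cols else np.empty((len(s), 0))
    if design.has_intercept:
        X = np.column_stack([np.ones(len(s)), X])
        names = ["intercept"] + names
    return X, names


def fit_dee_model(design: Design, summaries: pd.DataFrame,
                  response: str = "msDEE") -> DeeModelFit:
    """OLS fit of one candidate design on the per-bird daily summaries.

    Time-budget designs are fitted through the origin; DBA designs carry a
    free intercept.  The Gaussian log-likelihood uses the ML variance
    estimate (RSS/n) and the residual variance counts as one parameter in k.
    """
    y = summaries[response].to_numpy(float)
    n = len(y)
    X, names = _design_matrix(design, summaries)
    p = X.shape[1]
    if n < p + 2:
        raise ValueError(f"design {design.name!r}: need at least {p + 2} birds, have {n}")
    if p:
        if np.linalg.matrix_rank(X) < p:
            raise ValueError(f"design {design.name!r}: collinear predictors {names}")
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
    else:
        beta = np.array([])
        fitted = np.full(n, y.mean())
        names = []
    if design.kind == "intercept":
        beta = np.array([y.mean()])
        names = ["intercept"]
        fitted = np.full(n, y.mean())
    rss = float(((y - fitted) ** 2).sum())
    sigma2 = rss / n
    loglik = (-0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
              if sigma2 > 0 else np.inf)
    # conventional OLS standard errors (n - p denominator)
    se = {}
    if p and n > p and rss > 0:
        s2 = rss / (n - p)
        cov = s2 * np.linalg.inv(X.T @ X)
        se = {nm: float(np.sqrt(cov[i, i])) for i, nm in enumerate(names)}
    coef = {nm: float(b) for nm, b in zip(names, beta)}
    intercept = coef.pop("intercept", None)
    k = len(names) + 1  # + residual variance
    return DeeModelFit(design=design, coef=coef, intercept=intercept, n=n, k=k,
                       loglik=loglik, rss=rss, fitted=fitted, se=se)


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        return np.nan
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_rank(fits: list) -> pd.DataFrame:
    """Rank fitted designs by AICc (ascending) with Delta-AICc to the best.

    Designs whose sample-size correction is undefined (n <= k + 1) are
    excluded with a warning.
    """
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError("fits must share one response vector (differing n)")
    kept = []
    for f in fits:
        f.aicc = aicc(f.loglik, f.k, f.n)
        if np.isnan(f.aicc):
            warnings.warn(f"design {f.design.name!r}: AICc undefined "
                          f"(n={f.n}, k={f.k}); excluded", stacklevel=2)
        else:
            kept.append(f)
    best = min(f.aicc for f in kept)
    rows = []
    for f in sorted(kept, key=lambda f: f.aicc):
        f.daicc = f.aicc - best
        rows.append({"design": f.design.name, "kind": f.design.kind, "k": f.k,
                     "logLik": f.loglik, "AICc": f.aicc, "dAICc": f.daicc,
                     "r": f.r})
    return pd.DataFrame(rows)


def predictive_r(fit: DeeModelFit, summaries: pd.DataFrame,
                 response: str = "msDEE") -> float:
    """Pearson correlation between fitted and observed msDEE.

    Undefined (NaN) when the predictions have no variance, e.g. for the
    intercept-only null.
    """
    y = summaries[response].to_numpy(float)
    if np.std(fit.fitted) == 0:
        fit.r = np.nan
        return np.nan
    fit.r = float(np.corrcoef(fit.fitted, y)[0, 1])
    return fit.r


def activity_rates(fit: DeeModelFit, reference_mass_g: float,
                   bmr_w: float) -> pd.DataFrame:
    """Activity-specific metabolic rates from a time-budget fit.

    Per activity group: MR (kJ h^-1 g^-1), whole-animal power at the
    reference mass (W; kJ h^-1 / 3.6), the multiple of the supplied BMR, and
    the ratio to the group containing the colony activity.
    """
    if fit.design.kind != "time":
        raise ValueError("activity rates require a time-budget design fit")
    if bmr_w <= 0 or reference_mass_g <= 0:
        raise ValueError("BMR and reference mass must be positive")
    ref = None
    for g in fit.design.groups:
        if "col" in g:
            ref = fit.coef["T_" + "+".join(g)]
    rows = []
    for g in fit.design.groups:
        name = "T_" + "+".join(g)
        mr = fit.coef[name]
        watts = mr * reference_mass_g / 3.6
        rows.append({"activity": "+".join(g), "MR_kJ_h_g": mr,
                     "watts": watts, "x_bmr": watts / bmr_w,
                     "ratio_vs_colony": mr / ref if ref else np.nan})
    return pd.DataFrame(rows)


def group_difference(values, group_labels) -> dict:
    """Two-group linear-model contrast (equivalent to a two-sample t-test).

    Returns the estimated difference (second group minus first, groups in
    sorted label order), its t statistic and two-sided p-value.
    """
    import statsmodels.api as sm
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    uniq = sorted(pd.unique(labels).tolist())
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    for u in uniq:
        if (labels == u).sum() < 2:
            raise ValueError(f"group {u!r} has fewer than 2 members")
    X = sm.add_constant((labels == uniq[1]).astype(float))
    res = sm.OLS(values, X).fit()
    return {"groups": tuple(uniq), "estimate": float(res.params[1]),
            "t": float(res.tvalues[1]), "p": float(res.pvalues[1]),
            "df": int(res.df_resid)}


# ---------------------------------------------------------------------------
# Replicated recovery experiments
# ---------------------------------------------------------------------------

def is_refinement(fine: Design, coarse: Design) -> bool:
    """True when every group of ``fine`` sits inside one group of ``coarse``."""
    if fine.kind != coarse.kind:
        return False
    return all(any(set(g) <= set(G) for G in coarse.groups) for g in fine.groups)


def grouped_rates(design: Design, rates, occupancy) -> np.ndarray:
    """Collapse per-activity rates onto a design's groups (occupancy-weighted)."""
    rates = np.asarray(rates, dtype=float)
    occ = np.asarray(occupancy, dtype=float)
    out = rates.copy()
    for g in design.groups:
        idx = [ACTIVITIES.index(a) for a in g]
        out[idx] = (rates[idx] * occ[idx]).sum() / occ[idx].sum()
    return out


def aicc_recovery_experiment(scenario, generating: Design, seed: int,
                             n_reps: int = 100) -> dict:
    """Parsimony race: how often AICc prefers the generating design over its
    refinements (designs that split its activity groups further, adding
    pure-noise parameters).

    Cohorts are drawn from the generating partition's grouped rates under the
    scenario's study conditions; candidates are the generating design plus
    every refinement of it in the default set.  Returns the selection
    fraction and the full-12-design winner counts for context.
    """
    from .simulate import simulate_budget_summaries, stationary_distribution
    rng = np.random.default_rng(seed)
    occ = stationary_distribution(scenario.transition_matrix)
    rates = grouped_rates(generating, scenario.activity_rates, occ)
    all_designs = candidate_models()
    refinements = [d for d in all_designs
                   if d.name != generating.name and is_refinement(d, generating)]
    wins = 0
    full_winners: dict = {}
    for _ in range(n_reps):
        s = simulate_budget_summaries(scenario, rng, rates_by_state=rates)
        fits = [fit_dee_model(d, s) for d in [generating] + refinements]
        if aicc_rank(fits).iloc[0]["design"] == generating.name:
            wins += 1
        rank_all = aicc_rank([fit_dee_model(d, s) for d in all_designs])
        w = rank_all.iloc[0]["design"]
        full_winners[w] = full_winners.get(w, 0) + 1
    return {"selection_fraction": wins / n_reps, "n_reps": n_reps,
            "refinements": [d.name for d in refinements],
            "full_set_winners": full_winners}


def mr_recovery_experiment(scenario, seed: int, n_reps: int = 400) -> dict:
    """Activity-rate recovery under the full four-group time-budget design.

    Per replicate a fresh cohort is drawn and the design refitted; reports
    the mean recovered rates, the foraging/colony rate ratio, and the
    fraction of replicates where each rate lies within 2 standard errors of
    its true value.
    """
    from .simulate import simulate_budget_summaries
    rng = np.random.default_rng(seed)
    full = candidate_models()[0]
    truth = np.asarray(scenario.activity_rates)
    coefs = np.empty((n_reps, 4))
    covered = np.zeros(4)
    for i in range(n_reps):
        s = simulate_budget_summaries(scenario, rng)
        f = fit_dee_model(full, s)
        for j, a in enumerate(ACTIVITIES):
            coefs[i, j] = f.coef[f"T_{a}"]
            covered[j] += abs(coefs[i, j] - truth[j]) <= 2 * f.se[f"T_{a}"]
    mean = coefs.mean(axis=0)
    return {"mean_rates": mean, "true_rates": truth,
            "ratio_for_col": float(mean[2] / mean[0]),
            "true_ratio_for_col": float(truth[2] / truth[0]),
            "coverage_2se": covered / n_reps, "n_reps": n_reps}


def predictive_r_experiment(scenario, seed: int, n_reps: int = 15) -> dict:
    """Best-AICc model's predicted-vs-observed Pearson r over replicate cohorts."""
    from .simulate import simulate_budget_summaries
    rng = np.random.default_rng(seed)
    rs = []
    for _ in range(n_reps):
        s = simulate_budget_summaries(scenario, rng)
        fits = []
        for d in candidate_models():
            f = fit_dee_model(d, s)
            predictive_r(f, s)
            fits.append(f)
        rs.append(aicc_rank(fits).iloc[0]["r"])
    rs = np.asarray(rs, dtype=float)
    return {"r_values": rs, "median_r": float(np.median(rs)), "n_reps": n_reps}


# ---------------------------------------------------------------------------
# Summary assembly
# ---------------------------------------------------------------------------

def build_summaries(minutes_by_bird: dict, states_by_bird: dict,
                    dlw_results: pd.DataFrame,
                    dlw_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-bird DailyActivitySummary table joining budgets, DBA and msDEE.

    ``states_by_bird`` maps bird -> integer state sequence (decoded or true);
    DBA is partitioned across activities by those states (it is not an HMM
    stream).  ``dlw_results`` is the table from :func:`plungedee.dlw.process_cohort`.
    """
    rows = []
    ms = dlw_results.set_index("bird")
    for bird, mins in minutes_by_bird.items():
        if bird not in ms.index:
            continue
        states = np.asarray(states_by_bird[bird])
        hours = len(states) / 60.0
        tb = time_budget(states, hours)
        row = {"bird": bird, "sampling_h": hours,
               "T_col": tb[0], "T_com": tb[1], "T_for": tb[2], "T_rest": tb[3]}
        row.update(activity_dba(mins["dba"].to_numpy(float), states, hours))
        row["msDEE"] = float(ms.loc[bird, "msDEE"])
        rows.append(row)
    out = pd.DataFrame(rows)
    if dlw_table is not None:
        dep = dlw_table[dlw_table["set"] == "deployed"].set_index("bird")
        out["mass"] = [0.5 * (dep.loc[b, "mass_initial_g"] + dep.loc[b, "mass_final_g"])
                       for b in out["bird"]]
    return out
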