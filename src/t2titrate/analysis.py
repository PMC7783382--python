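"""Trial outcome estimation: primary, secondary, sensitivity and post-hoc.

Implements the trial's statistical analysis on a :class:`TrialDataset`
(simulated or imported):

* the primary endpoint — proportion of patients on a lower corticosteroid
  dose at week 48 — as an adjusted logistic regression (age, sex, smoking
  status, treatment centre, rescue-steroid use ≥2 courses, baseline
  ACQ-7 ≥ 1.5) with multiple imputation by chained equations for missing
  outcomes, pooled by Rubin's rules;
* unadjusted 2×2 odds ratios with Woolf confidence intervals
  (Haldane–Anscombe 0.5 correction on empty cells);
* best-case / worst-case sensitivity bounds for withdrawals;
* negative-binomial exacerbation and hospitalisation rate ratios with
  log-exposure offset, and Cox proportional-hazards time to first
  exacerbation;
* number needed to treat with a Newcombe hybrid-score interval on the
  risk difference;
* adjusted linear models for the continuous secondary outcomes,
  additionally conditioned on the baseline measurement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.imputation import mice
from statsmodels.stats.proportion import confint_proportions_2indep

from .conduct import TrialDataset
from .populations import PopulationSpec, build_population, classify_dose_reduction

__all__ = [
    "EffectEstimate",
    "NNTEstimate",
    "analysis_frame",
    "unadjusted_odds_ratio",
    "primary_analysis",
    "sensitivity_bounds",
    "exacerbation_models",
    "adherence_exacerbation_cox",
    "refused_ocs_analysis",
    "continuous_outcome",
    "number_needed_to_treat",
    "trial_report",
    "null_rejection_rate",
]

COVARIATES = ["age", "sex_f", "smoke_ex", "rescue_high", "acq_high"]
Z95 = stats.norm.ppf(0.975)


@dataclass
class EffectEstimate:
    """A point estimate with its 95% interval.

    ``scale`` records whether point/lo/hi live on the ratio scale (odds,
    rate, hazard ratios) or the difference scale (linear models).
    """

    estimand: str
    point: float
    lo: float
    hi: float
    population: str = ""
    adjusted: bool = False
    pvalue: float = math.nan
    n_active: int = 0
    n_control: int = 0
    scale: str = "ratio"
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if (
            np.isfinite(self.lo)
            and np.isfinite(self.hi)
            and not (self.lo <= self.point <= self.hi)
        ):
            raise ValueError(
                f"{self.estimand}: interval ({self.lo}, {self.hi}) does not "
                f"bracket the point estimate {self.point}"
            )

    def summary_row(self) -> dict:
        return {
            "estimand": self.estimand,
            "population": self.population,
            "n_biomarker": self.n_active,
            "n_control": self.n_control,
            "estimate": self.point,
            "lo95": self.lo,
            "hi95": self.hi,
            "p": self.pvalue,
            "adjusted": self.adjusted,
            "flags": ";".join(self.flags),
        }


@dataclass
class NNTEstimate:
    """Number needed to treat with a Newcombe-derived interval."""

    nnt: int | None
    lo: int | None
    hi: int | None
    risk_difference: float
    defined: bool = True


# ---------------------------------------------------------------------------
# per-patient analysis table
# ---------------------------------------------------------------------------

def analysis_frame(
    dataset: TrialDataset, population: PopulationSpec | str = "itt"
) -> pd.DataFrame:
    """One row per analysis-population patient, with outcomes and covariates.

    The primary outcome ``dose_reduced`` is 1/0 when the week-48 state was
    observed and NaN for patients lost before the final visit.  Exposure is
    time from randomisation to the last attended visit; exacerbation counts
    and first-event times come from the events table.
    """
    if isinstance(population, str):
        population = PopulationSpec.parse(population)
    ids = build_population(dataset, population)
    patients = dataset.patients.set_index("patient_id").loc[ids]
    visits = dataset.visits[dataset.visits["patient_id"].isin(ids)]

    last = visits.sort_values("week").groupby("patient_id").last()
    final_week = visits.groupby("patient_id")["week"].max()
    wk48 = visits[visits["week"] == 48].set_index("patient_id")

    out = pd.DataFrame(index=patients.index)
    out["trt"] = (patients["arm"] == "biomarker").astype(int)
    out["age"] = patients["age"]
    out["sex_f"] = (patients["sex"] == "F").astype(int)
    out["smoke_ex"] = (patients["smoking"] == "ex").astype(int)
    out["centre"] = patients["centre"].astype(int)
    out["rescue_high"] = patients["rescue_high"].astype(int)
    out["acq_high"] = patients["acq_high"].astype(int)

    out["baseline_step"] = patients["step_baseline"].astype(int)
    out["final_step"] = wk48["step_after"].reindex(out.index)
    out["dose_reduced"] = np.where(
        out["final_step"].notna(),
        [
            float(classify_dose_reduction(int(b), int(f))) if not pd.isna(f) else np.nan
            for b, f in zip(out["baseline_step"], out["final_step"])
        ],
        np.nan,
    )
    out["withdrawn"] = out["final_step"].isna()

    # auxiliary for the imputation model: dose change baseline -> first visit
    wk8 = visits[visits["week"] == 8].set_index("patient_id")
    out["dose_change_first"] = (
        wk8["step_after"].reindex(out.index) - out["baseline_step"]
    ).fillna(0.0)

    out["exposure_years"] = final_week.reindex(out.index).fillna(0) / 52.0
    events = dataset.events[dataset.events["patient_id"].isin(ids)]
    out["n_exacs"] = (
        events.groupby("patient_id").size().reindex(out.index).fillna(0).astype(int)
    )
    out["n_hosp"] = (
        events[events["criterion"] == "hospital_visit"]
        .groupby("patient_id")
        .size()
        .reindex(out.index)
        .fillna(0)
        .astype(int)
    )
    first_event = events.groupby("patient_id")["week"].min().reindex(out.index)
    out["event"] = first_event.notna().astype(int)
    out["time_weeks"] = np.where(
        out["event"] == 1, first_event, final_week.reindex(out.index).fillna(0.0)
    )
    # guard against zero durations for survival fits
    out["time_weeks"] = out["time_weeks"].clip(lower=0.5)

    # end-of-study measurements with their baselines
    for col, base in [
        ("acq7", "acq7_baseline"),
        ("aqlq", "aqlq_baseline"),
        ("fev1_pct", "fev1_pct_baseline"),
    ]:
        out[f"{col}_final"] = wk48[col].reindex(out.index)
        out[f"{col}_base"] = patients[base]
    for col, base in [("feno", "feno0"), ("eos", "eos0"), ("periostin", "periostin0")]:
        out[f"{col}_final"] = wk48[col].reindex(out.index)
        out[f"{col}_base"] = patients[base]
    out["ics_final"] = wk48["ics_after"].reindex(out.index)
    out["ocs_final"] = wk48["ocs_after"].reindex(out.index)
    out["ics_base"] = patients["ics_baseline"]
    out["ocs_base"] = patients["ocs_baseline"]
    out["ocs_user_final"] = (out["ocs_final"] > 0).astype(float).where(
        out["ocs_final"].notna()
    )

    # cumulative doses: 8-weekly dose held between visits (µg/day, mg/day × days)
    v = visits.sort_values(["patient_id", "week"])
    v = v.assign(
        days=np.minimum(48 - v["week"], 8) * 7
    )
    held = v[v["week"] < 48]
    out["cum_ics"] = (
        (held["ics_after"] * held["days"]).groupby(held["patient_id"]).sum()
    ).reindex(out.index)
    out["cum_ocs"] = (
        (held["ocs_after"] * held["days"]).groupby(held["patient_id"]).sum()
    ).reindex(out.index)

    # refused to initiate OCS: among patients ever advised an increase that
    # would start maintenance OCS, never having started it
    v_sorted = visits.sort_values(["patient_id", "week"]).copy()
    v_sorted["ocs_before"] = (
        v_sorted.groupby("patient_id")["ocs_after"]
        .shift(1)
        .fillna(
            v_sorted["patient_id"].map(patients["ocs_baseline"])
        )
    )
    adv = v_sorted[(v_sorted["advisory"] == "increase") & ~v_sorted["deferred"]]
    onto_ocs = adv["refused_ocs_initiation"] | (
        adv["followed"].astype(bool)
        & (adv["ocs_after"] > 0)
        & (adv["ocs_before"] == 0)
    )
    advised_ids = set(adv.loc[onto_ocs, "patient_id"])
    started = set(visits.loc[visits["ocs_after"] > 0, "patient_id"]) - set(
        patients.index[patients["ocs_baseline"] > 0]
    )
    out["ocs_advised"] = out.index.isin(advised_ids)
    out["refused_ocs"] = np.where(
        out["ocs_advised"], (~out.index.isin(started)).astype(float), np.nan
    )
    return out.reset_index().rename(columns={"index": "patient_id"})


# ---------------------------------------------------------------------------
# unadjusted 2x2 odds ratio, NNT
# ---------------------------------------------------------------------------

def unadjusted_odds_ratio(
    a: int, b: int, c: int, d: int, estimand: str = "odds ratio", population: str = ""
) -> EffectEstimate:
    """Odds ratio (a/b)/(c/d) with a Woolf (log-scale normal) 95% CI.

    ``a``/``b`` are active-arm successes/failures, ``c``/``d`` control.
    When any cell is zero the Haldane–Anscombe 0.5 correction is applied
    and flagged; an empty margin is undefined and flagged.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be non-negative")
    flags: list[str] = []
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        return EffectEstimate(
            estimand, math.nan, math.nan, math.nan,
            population=population, flags=("undefined_margin",),
            n_active=int(a + b), n_control=int(c + d),
        )
    if (cells == 0).any():
        cells = cells + 0.5
        flags.append("haldane_corrected")
    a_, b_, c_, d_ = cells
    log_or = math.log((a_ / b_) / (c_ / d_))
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = log_or / se
    return EffectEstimate(
        estimand,
        math.exp(log_or),
        math.exp(log_or - Z95 * se),
        math.exp(log_or + Z95 * se),
        population=population,
        pvalue=2 * stats.norm.sf(abs(z)),
        n_active=int(a + b),
        n_control=int(c + d),
        flags=tuple(flags),
    )


def number_needed_to_treat(
    p_active: float,
    p_control: float,
    n_active: int | None = None,
    n_control: int | None = None,
) -> NNTEstimate:
    """NNT = 1 / risk difference, rounded up to the next integer.

    With arm sizes supplied, a Newcombe hybrid-score 95% interval on the
    risk difference is reciprocated and rounded to give the NNT interval.
    A non-positive risk difference leaves the NNT undefined (flagged via
    ``defined=False``).
    """
    rd = p_active - p_control
    if rd <= 0:
        return NNTEstimate(None, None, None, rd, defined=False)
    nnt = math.ceil(1.0 / rd)
    lo = hi = None
    if n_active and n_control:
        count1 = int(round(p_active * n_active))
        count0 = int(round(p_control * n_control))
        rd_lo, rd_hi = confint_proportions_2indep(
            count1, n_active, count0, n_control, method="newcomb", compare="diff"
        )
        lo = int(math.floor(1.0 / rd_hi + 0.5)) if rd_hi > 0 else 1
        hi = int(math.floor(1.0 / rd_lo + 0.5)) if rd_lo > 0 else None
    return NNTEstimate(nnt, lo, hi, rd)


# ---------------------------------------------------------------------------
# adjusted logistic machinery
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, extra: list[str] | None = None) -> pd.DataFrame:
    """Covariate design matrix: continuous + binary + centre dummies."""
    X = df[COVARIATES].astype(float).copy()
    dummies = pd.get_dummies(df["centre"], prefix="centre", drop_first=True)
    X = pd.concat([X, dummies.astype(float)], axis=1)
    if extra:
        for col in extra:
            X[col] = df[col].astype(float)
    return sm.add_constant(X, has_constant="add")


def _profile_ci(y: np.ndarray, X: pd.DataFrame, trt: np.ndarray) -> tuple[float, float]:
    """Profile-likelihood 95% CI for the treatment log-odds coefficient.

    Re-fits the nuisance parameters with the treatment coefficient fixed via
    an offset and inverts the likelihood-ratio test.  Used when the Wald
    interval is unusable (separation).
    """
    def dev(beta: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(
                y, X, family=sm.families.Binomial(), offset=beta * trt
            ).fit(maxiter=200)
        return fit.deviance

    betas = np.linspace(-12, 12, 49)
    devs = np.array([dev(b) for b in betas])
    dmin = devs.min()
    bhat = betas[devs.argmin()]
    target = dmin + stats.chi2.ppf(0.95, 1)

    def bound(side: int) -> float:
        lo_b, hi_b = (bhat, 15.0) if side > 0 else (-15.0, bhat)
        edge = dev(15.0 * side)
        if edge < target:
            return math.inf * side
        try:
            return optimize.brentq(lambda b: dev(b) - target, lo_b, hi_b, xtol=1e-3)
        except ValueError:
            return math.inf * side

    return bound(-1), bound(+1)


def _fit_adjusted_logit(
    df: pd.DataFrame,
    outcome: str,
    estimand: str,
    population: str,
) -> EffectEstimate:
    """Adjusted logistic regression for a binary outcome, complete rows only."""
    data = df.dropna(subset=[outcome]).copy()
    y = data[outcome].astype(float).to_numpy()
    X = _design(data)
    X.insert(1, "trt", data["trt"].astype(float).to_numpy())
    flags: list[str] = []
    n1 = int(data["trt"].sum())
    n0 = len(data) - n1
    if y.sum() in (0, len(y)) or n1 == 0 or n0 == 0:
        return EffectEstimate(
            estimand, math.nan, math.nan, math.nan, population=population,
            adjusted=True, n_active=n1, n_control=n0, flags=("degenerate",),
        )
    fit = None
    for drop_centre in (False, True):
        Xk = X[[c for c in X.columns if not c.startswith("centre_")]] if drop_centre else X
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, Xk, family=sm.families.Binomial()).fit(maxiter=200)
            if drop_centre:
                flags.append("centre_dropped")
                X = Xk
            break
        except Exception:
            fit = None
    if fit is None:
        return EffectEstimate(
            estimand, math.nan, math.nan, math.nan, population=population,
            adjusted=True, n_active=n1, n_control=n0, flags=("fit_failed",),
        )
    beta = fit.params["trt"]
    se = fit.bse["trt"]
    separated = (not np.isfinite(se)) or se > 100 or abs(beta) > 10
    if separated:
        flags.append("separation_profile_ci")
        lo_b, hi_b = _profile_ci(y, X.drop(columns="trt"), data["trt"].to_numpy(float))
        beta = float(np.clip(beta, lo_b, hi_b))
        lo, hi = math.exp(lo_b) if np.isfinite(lo_b) else 0.0, (
            math.exp(hi_b) if np.isfinite(hi_b) else math.inf
        )
        p = math.nan
    else:
        lo, hi = math.exp(beta - Z95 * se), math.exp(beta + Z95 * se)
        p = 2 * stats.norm.sf(abs(beta / se))
    return EffectEstimate(
        estimand, math.exp(beta), lo, hi, population=population, adjusted=True,
        pvalue=p, n_active=n1, n_control=n0, flags=tuple(flags),
    )


def primary_analysis(
    dataset: TrialDataset,
    population: PopulationSpec | str = "itt",
    imputation: bool = True,
    m: int = 20,
    cycles: int = 10,
    seed: int = 0,
) -> EffectEstimate:
    """Adjusted odds ratio for corticosteroid dose reduction at week 48.

    Logistic regression of the primary outcome on treatment group, adjusted
    for age, sex, smoking status, centre, rescue-steroid use (≥2 courses)
    and baseline ACQ-7 ≥ 1.5.  Missing outcomes (withdrawals, missed final
    visits) are handled by multiple imputation with chained equations —
    the imputation model additionally carries the change in corticosteroid
    dose between baseline and the first visit — pooled over ``m``
    imputations by Rubin's rules.  With ``imputation=False`` (or no missing
    outcomes) a complete-case fit is returned.
    """
    popname = population if isinstance(population, str) else population.kind
    df = analysis_frame(dataset, population)
    n_missing = int(df["dose_reduced"].isna().sum())
    if not imputation or n_missing == 0:
        est = _fit_adjusted_logit(
            df, "dose_reduced", "dose reduction aOR", popname
        )
        if n_missing == 0:
            est.flags = est.flags + ("no_missing_outcomes",)
        else:
            est.flags = est.flags + ("complete_case",)
        return est

    cols = (
        ["dose_reduced", "trt"]
        + COVARIATES
        + ["centre", "dose_change_first"]
    )
    imp_df = df[cols].astype(float)
    np.random.seed(seed % (2**31))  # MICEData draws from the global RNG
    imp = mice.MICEData(imp_df)
    formula = "dose_reduced ~ trt + " + " + ".join(COVARIATES) + " + C(centre)"
    model = mice.MICE(formula, sm.GLM, imp, init_kwds={"family": sm.families.Binomial()})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(n_burnin=cycles, n_imputations=m)
    except Exception:
        est = _fit_adjusted_logit(df, "dose_reduced", "dose reduction aOR", popname)
        est.flags = est.flags + ("mice_failed_complete_case",)
        return est
    names = list(res.model.exog_names) if hasattr(res, "model") else []
    try:
        idx = names.index("trt")
    except ValueError:
        idx = 1
    beta = float(res.params[idx])
    se = float(np.sqrt(np.diag(res.cov_params()))[idx])
    n1 = int(df["trt"].sum())
    n0 = len(df) - n1
    flags = ["mice_pooled"]
    if not np.isfinite(se) or se > 100 or abs(beta) > 10:
        flags.append("separation")
        return EffectEstimate(
            "dose reduction aOR", math.exp(min(beta, 10)), 0.0, math.inf,
            population=popname, adjusted=True, n_active=n1, n_control=n0,
            flags=tuple(flags),
        )
    return EffectEstimate(
        "dose reduction aOR",
        math.exp(beta),
        math.exp(beta - Z95 * se),
        math.exp(beta + Z95 * se),
        population=popname,
        adjusted=True,
        pvalue=2 * stats.norm.sf(abs(beta / se)),
        n_active=n1,
        n_control=n0,
        flags=tuple(flags),
    )


def sensitivity_bounds(
    dataset: TrialDataset, population: PopulationSpec | str = "itt"
) -> tuple[EffectEstimate, EffectEstimate]:
    """Best-case / worst-case bounds for missing primary outcomes.

    Best case sets every withdrawal's outcome to "reduced"; worst case to
    "not reduced"; both are complete-data adjusted logistic fits.
    """
    popname = population if isinstance(population, str) else population.kind
    df = analysis_frame(dataset, population)
    best = df.copy()
    best.loc[best["dose_reduced"].isna(), "dose_reduced"] = 1.0
    worst = df.copy()
    worst.loc[worst["dose_reduced"].isna(), "dose_reduced"] = 0.0
    return (
        _fit_adjusted_logit(best, "dose_reduced", "dose reduction aOR (best case)", popname),
        _fit_adjusted_logit(worst, "dose_reduced", "dose reduction aOR (worst case)", popname),
    )


# ---------------------------------------------------------------------------
# exacerbation models
# ---------------------------------------------------------------------------

def _annualised_rate(df: pd.DataFrame, count_col: str) -> dict[str, float]:
    rates = {}
    for arm, grp in df.groupby("trt"):
        exposure = grp["exposure_years"].sum()
        rates["biomarker" if arm == 1 else "control"] = (
            grp[count_col].sum() / exposure if exposure > 0 else math.nan
        )
    return rates


def exacerbation_models(
    dataset: TrialDataset, population: PopulationSpec | str = "itt"
) -> dict[str, object]:
    """Severe-exacerbation effect estimates.

    Returns annualised per-arm rates (events / patient-years, exact), the
    adjusted negative-binomial rate ratios for exacerbations and hospital
    admissions (log person-years offset), and the adjusted Cox hazard
    ratio for time to first exacerbation.
    """
    from lifelines import CoxPHFitter

    popname = population if isinstance(population, str) else population.kind
    df = analysis_frame(dataset, population)
    df = df[df["exposure_years"] > 0].copy()
    out: dict[str, object] = {
        "annual_rate": _annualised_rate(df, "n_exacs"),
        "annual_hosp_rate": _annualised_rate(df, "n_hosp"),
    }

    for name, col in [("exacerbation rate ratio", "n_exacs"),
                      ("hospitalisation rate ratio", "n_hosp")]:
        X = _design(df)
        X.insert(1, "trt", df["trt"].astype(float).to_numpy())
        flags: list[str] = []
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nb = sm.NegativeBinomial(
                    df[col].to_numpy(),
                    X,
                    exposure=df["exposure_years"].to_numpy(),
                ).fit(disp=0, maxiter=200)
            if not nb.mle_retvals.get("converged", True):
                flags.append("nonconvergence")
            beta, se = nb.params["trt"], nb.bse["trt"]
        except Exception:
            flags.append("nb_failed_poisson_fallback")
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    po = sm.GLM(
                        df[col].to_numpy(), X, family=sm.families.Poisson(),
                        exposure=df["exposure_years"].to_numpy(),
                    ).fit()
                beta, se = po.params["trt"], po.bse["trt"]
            except Exception:
                beta, se = math.nan, math.inf
        if np.isfinite(se) and se < 100:
            out[name] = EffectEstimate(
                name, math.exp(beta), math.exp(beta - Z95 * se),
                math.exp(beta + Z95 * se), population=popname, adjusted=True,
                pvalue=2 * stats.norm.sf(abs(beta / se)),
                n_active=int(df["trt"].sum()),
                n_control=int((1 - df["trt"]).sum()),
                flags=tuple(flags),
            )
        else:
            out[name] = EffectEstimate(
                name, math.exp(beta), math.nan, math.nan, population=popname,
                adjusted=True, flags=tuple(flags) + ("unstable_se",),
            )

    cox_df = df[["time_weeks", "event", "trt"] + COVARIATES].astype(float)
    cph = CoxPHFitter(penalizer=0.01)
    flags = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(cox_df, duration_col="time_weeks", event_col="event")
        beta = cph.params_["trt"]
        se = cph.standard_errors_["trt"]
        out["time to first exacerbation HR"] = EffectEstimate(
            "time to first exacerbation HR", math.exp(beta),
            math.exp(beta - Z95 * se), math.exp(beta + Z95 * se),
            population=popname, adjusted=True,
            pvalue=2 * stats.norm.sf(abs(beta / se)),
            n_active=int(df["trt"].sum()), n_control=int((1 - df["trt"]).sum()),
        )
    except Exception:
        out["time to first exacerbation HR"] = EffectEstimate(
            "time to first exacerbation HR", math.nan, math.nan, math.nan,
            population=popname, adjusted=True, flags=("cox_failed",),
        )
    return out


def adherence_exacerbation_cox(dataset: TrialDataset, arm: str = "biomarker") -> EffectEstimate:
    """Within-arm hazard ratio of first exacerbation for advisory non-followers.

    Classifies each patient in the given arm by whether they ever left an
    (undeferred, non-exempt) advisory unfollowed, and fits an adjusted Cox
    model of time to first severe exacerbation on that indicator.
    """
    from lifelines import CoxPHFitter

    from .populations import count_deviations

    df = analysis_frame(dataset, "itt")
    patients = dataset.patients.set_index("patient_id")
    df = df[df["trt"] == (1 if arm == "biomarker" else 0)].copy()
    dev = count_deviations(dataset)
    df["non_follower"] = (dev.reindex(df["patient_id"]).to_numpy() > 0).astype(float)
    del patients
    cox_df = df[["time_weeks", "event", "non_follower"] + COVARIATES].astype(float)
    cph = CoxPHFitter(penalizer=0.01)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(cox_df, duration_col="time_weeks", event_col="event")
    beta = cph.params_["non_follower"]
    se = cph.standard_errors_["non_follower"]
    return EffectEstimate(
        f"non-follower exacerbation HR ({arm} arm)", math.exp(beta),
        math.exp(beta - Z95 * se), math.exp(beta + Z95 * se),
        population="itt", adjusted=True,
        pvalue=2 * stats.norm.sf(abs(beta / se)),
    )


def refused_ocs_analysis(
    dataset: TrialDataset, population: PopulationSpec | str = "itt"
) -> EffectEstimate:
    """Adjusted OR of refusing to initiate maintenance OCS.

    Among patients who received at least one increase advisory that would
    have started maintenance OCS, models the probability of never starting.
    """
    popname = population if isinstance(population, str) else population.kind
    df = analysis_frame(dataset, population)
    df = df[df["ocs_advised"]].copy()
    return _fit_adjusted_logit(df, "refused_ocs", "refused OCS aOR", popname)


def continuous_outcome(
    dataset: TrialDataset,
    outcome: str,
    population: PopulationSpec | str = "itt",
    log: bool = False,
) -> EffectEstimate:
    """Adjusted linear model for a continuous secondary outcome.

    ``outcome`` is one of acq7, aqlq, fev1_pct, feno, eos, periostin, ics,
    ocs, cum_ics, cum_ocs.  The model conditions on the full covariate set
    plus the baseline measurement of the outcome where one exists; ``log``
    fits on the log scale (geometric-mean ratio), as used for FENO and
    blood eosinophils.
    """
    popname = population if isinstance(population, str) else population.kind
    df = analysis_frame(dataset, population)
    final = f"{outcome}_final" if f"{outcome}_final" in df else outcome
    base = f"{outcome}_base" if f"{outcome}_base" in df else None
    data = df.dropna(subset=[final]).copy()
    y = data[final].astype(float).to_numpy()
    if log:
        y = np.log(np.clip(y, 1e-6, None))
    extra = [base] if base else None
    if base:
        data[base] = data[base].astype(float)
        if log:
            data[base] = np.log(np.clip(data[base], 1e-6, None))
    X = _design(data, extra=extra)
    X.insert(1, "trt", data["trt"].astype(float).to_numpy())
    fit = sm.OLS(y, X).fit()
    beta, se = fit.params["trt"], fit.bse["trt"]
    point, lo, hi = beta, beta - Z95 * se, beta + Z95 * se
    scale = "difference"
    if log:
        point, lo, hi = math.exp(point), math.exp(lo), math.exp(hi)
        scale = "ratio"
    return EffectEstimate(
        f"{outcome} ({'ratio of geometric means' if log else 'mean difference'})",
        point, lo, hi, population=popname, adjusted=True,
        pvalue=fit.pvalues["trt"], scale=scale,
        n_active=int(data["trt"].sum()), n_control=int((1 - data["trt"]).sum()),
    )


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def trial_report(
    dataset: TrialDataset,
    population: PopulationSpec | str = "itt",
    seed: int = 0,
    m: int = 20,
) -> pd.DataFrame:
    """A Table-4-shaped summary for one analysis population.

    Rows: dose-reduction proportions and ORs (unadjusted + adjusted),
    per-arm annualised exacerbation/hospitalisation rates with rate ratios,
    time-to-first-exacerbation hazard ratio, refused-OCS OR, NNT, and the
    continuous secondary outcomes.
    """
    popname = population if isinstance(population, str) else population.kind
    df = analysis_frame(dataset, population)
    rows: list[dict] = []

    obs = df.dropna(subset=["dose_reduced"])
    a = int(obs.loc[obs["trt"] == 1, "dose_reduced"].sum())
    n1 = int((obs["trt"] == 1).sum())
    c = int(obs.loc[obs["trt"] == 0, "dose_reduced"].sum())
    n0 = int((obs["trt"] == 0).sum())
    rows.append(
        {
            "estimand": "dose reduction proportion",
            "population": popname,
            "n_biomarker": n1,
            "n_control": n0,
            "estimate_biomarker": a / n1 if n1 else math.nan,
            "estimate_control": c / n0 if n0 else math.nan,
        }
    )
    rows.append(unadjusted_odds_ratio(
        a, n1 - a, c, n0 - c, "dose reduction OR (unadjusted)", popname
    ).summary_row())
    rows.append(primary_analysis(dataset, population, seed=seed, m=m).summary_row())
    if n1 and n0 and a / n1 > c / n0:
        nnt = number_needed_to_treat(a / n1, c / n0, n1, n0)
        rows.append(
            {
                "estimand": "number needed to treat",
                "population": popname,
                "estimate": nnt.nnt,
                "lo95": nnt.lo,
                "hi95": nnt.hi,
            }
        )
    ex = exacerbation_models(dataset, population)
    rows.append(
        {
            "estimand": "annual exacerbation rate",
            "population": popname,
            "estimate_biomarker": ex["annual_rate"].get("biomarker", math.nan),
            "estimate_control": ex["annual_rate"].get("control", math.nan),
        }
    )
    for key in (
        "exacerbation rate ratio",
        "hospitalisation rate ratio",
        "time to first exacerbation HR",
    ):
        rows.append(ex[key].summary_row())
    try:
        rows.append(refused_ocs_analysis(dataset, population).summary_row())
    except Exception:
        pass
    for outcome, log in [
        ("acq7", False), ("aqlq", False), ("fev1_pct", False),
        ("feno", True), ("eos", True), ("periostin", False),
        ("ics", False), ("ocs", False),
    ]:
        try:
            rows.append(continuous_outcome(dataset, outcome, population, log=log).summary_row())
        except Exception:
            pass
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# null calibration of the adjusted logistic machinery
# ---------------------------------------------------------------------------

def null_rejection_rate(
    n_reps: int = 500,
    n: int = 300,
    p_outcome: float = 0.25,
    seed: int = 0,
    ratio: float = 0.8,
) -> dict[str, float]:
    """Type-I error of the adjusted primary analysis under a true null.

    Simulates ``n_reps`` trials in which both arms share the same true
    outcome probability (with mild covariate effects), fits the adjusted
    logistic model, and reports the fraction of replicates rejecting at
    the two-sided 5% level together with the CI-coverage of the null odds
    ratio of 1 and the Monte-Carlo standard error.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    covered = 0
    fitted = 0
    for _ in range(n_reps):
        trt = (rng.random(n) < ratio).astype(float)
        age = rng.normal(55, 13, n)
        sex_f = (rng.random(n) < 0.64).astype(float)
        smoke = (rng.random(n) < 0.26).astype(float)
        rescue = (rng.random(n) < 0.6).astype(float)
        acqh = (rng.random(n) < 0.6).astype(float)
        centre = rng.integers(0, 12, n)
        eta = (
            math.log(p_outcome / (1 - p_outcome))
            + 0.01 * (age - 55)
            + 0.2 * sex_f
            - 0.2 * acqh
        )
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        df = pd.DataFrame(
            {
                "age": age, "sex_f": sex_f, "smoke_ex": smoke,
                "rescue_high": rescue, "acq_high": acqh, "centre": centre,
            }
        )
        X = _design(df)
        X.insert(1, "trt", trt)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        beta, se = fit.params["trt"], fit.bse["trt"]
        if not np.isfinite(se) or se > 100:
            continue
        fitted += 1
        if abs(beta / se) > Z95:
            rejections += 1
        if beta - Z95 * se <= 0 <= beta + Z95 * se:
            covered += 1
    rate = rejections / fitted if fitted else math.nan
    return {
        "rejection_rate": rate,
        "coverage": covered / fitted if fitted else math.nan,
        "mc_se": math.sqrt(rate * (1 - rate) / fitted) if fitted else math.nan,
        "n_fitted": fitted,
    }
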