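"""Prognostic evaluation: Kaplan–Meier, log-rank, Cox regression.

The cohort is dichotomized into stroma-low and stroma-high; the question is
whether the stroma-high group has worse disease-specific (DSS) or
disease-free (DFS) survival, and whether that effect survives adjustment
for the standard clinicopathological covariates. Covariates follow the
conventional grouped coding: age continuous; male vs female; pT3–4 vs
pT1–2; lymph-node metastases (pN ≥ 1) vs none; poorly vs well/moderately
differentiated; any adjuvant therapy vs none; TSR high vs low with
stroma-low as the reference level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import ParameterError
from .hotspot import STROMA_HIGH

#: covariate columns of the standard multivariate model, in reporting order
MULTIVARIATE_COVARIATES = ("age", "male", "pt34", "ln_metastases",
                           "grade_poor", "adjuvant_any")


def _endpoint_columns(endpoint: str):
    if endpoint not in ("dss", "dfs"):
        raise ParameterError("endpoint must be 'dss' or 'dfs'")
    return f"{endpoint}_years", f"{endpoint}_event"


def recode_covariates(cohort: pd.DataFrame,
                      tsr_label_column: str | None = None) -> pd.DataFrame:
    """Build the model matrix with the grouped covariate coding.

    Emits: ``age`` (continuous), ``male``, ``pt34`` (pT3–4 vs pT1–2),
    ``ln_metastases`` (pN ≥ 1), ``grade_poor`` (poor vs well/moderate),
    ``adjuvant_any`` (radio- or chemoradiotherapy vs none), and — when a
    TSR label column is named — ``stroma_high`` (1 = stroma-high, with
    stroma-low as reference). Survival columns are carried through.
    """
    required = ["age", "gender", "pT", "pN", "grade", "adjuvant"]
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise ParameterError(f"cohort lacks required column(s): {missing}")

    domains = {
        "gender": {"female", "male"},
        "pT": {1, 2, 3, 4},
        "pN": {0, 1, 2},
        "grade": {"well", "moderate", "poor"},
        "adjuvant": {"none", "radiotherapy", "chemoradiotherapy"},
    }
    offenders = []
    for col, dom in domains.items():
        bad = ~cohort[col].isin(dom)
        if bad.any():
            rows = cohort.index[bad].tolist()[:10]
            offenders.append(f"{col}: invalid values at rows {rows}")
    if offenders:
        raise ParameterError("invalid categories — " + "; ".join(offenders))

    out = pd.DataFrame(index=cohort.index)
    out["age"] = cohort["age"].astype(float)
    out["male"] = (cohort["gender"] == "male").astype(int)
    out["pt34"] = cohort["pT"].isin([3, 4]).astype(int)
    out["ln_metastases"] = (cohort["pN"] >= 1).astype(int)
    out["grade_poor"] = (cohort["grade"] == "poor").astype(int)
    out["adjuvant_any"] = cohort["adjuvant"].isin(
        ["radiotherapy", "chemoradiotherapy"]).astype(int)
    if tsr_label_column is not None:
        out["stroma_high"] = (cohort[tsr_label_column] == STROMA_HIGH).astype(int)
    for col in ("dss_years", "dss_event", "dfs_years", "dfs_event"):
        if col in cohort.columns:
            out[col] = cohort[col].to_numpy()
    return out


@dataclass
class KMGroupResult:
    """Per-group Kaplan–Meier fits plus the log-rank comparison."""

    fitters: dict            # group label -> fitted KaplanMeierFitter
    logrank_statistic: float
    logrank_p: float
    n_per_group: dict


def km_logrank(cohort: pd.DataFrame, group_column: str,
               endpoint: str = "dss") -> KMGroupResult:
    """Kaplan–Meier curves per group with a two-sided log-rank test.

    When no events occur at all the log-rank statistic is undefined; the
    result reports p = 1 with a warning rather than failing.
    """
    tcol, ecol = _endpoint_columns(endpoint)
    groups = cohort[group_column]
    levels = sorted(groups.dropna().unique().tolist())
    if len(levels) < 2:
        raise ParameterError(f"{group_column!r} has fewer than 2 groups")
    fitters, n_per_group = {}, {}
    for level in levels:
        sub = cohort[groups == level]
        kmf = KaplanMeierFitter(label=str(level))
        kmf.fit(sub[tcol], event_observed=sub[ecol])
        fitters[level] = kmf
        n_per_group[level] = int(len(sub))
    if int(cohort[ecol].sum()) == 0:
        warnings.warn("no events in any group; log-rank undefined, p set to 1")
        return KMGroupResult(fitters, float("nan"), 1.0, n_per_group)
    res = multivariate_logrank_test(cohort[tcol], groups, cohort[ecol])
    return KMGroupResult(fitters, float(res.test_statistic),
                         float(res.p_value), n_per_group)


def five_year_rate(fitter: KaplanMeierFitter, horizon_years: float = 5.0) -> float:
    """Survival percentage at the horizon, right-continuous step convention.

    If follow-up ends before the horizon with patients still at risk, the
    last available estimate is returned with a warning.
    """
    sf = fitter.survival_function_
    max_t = float(sf.index.max())
    if max_t < horizon_years:
        warnings.warn(
            f"follow-up ends at {max_t:.2f}y, before the {horizon_years:.0f}y "
            "horizon; returning the last available estimate")
    return float(fitter.predict(horizon_years)) * 100.0


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald 95% CIs and p-values."""

    table: pd.DataFrame      # index = covariate; HR, ci_low, ci_high, p
    endpoint: str
    n: int
    n_events: int
    fitter: object  # CoxPHFitter (efron) or statsmodels PHRegResults (breslow)

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "HR"])


def cox_fit(model_matrix: pd.DataFrame, endpoint: str = "dss",
            covariates=None, ties: str = "efron") -> CoxResult:
    """Proportional-hazards fit on the recoded model matrix.

    ``ties`` selects the partial-likelihood tie approximation ("efron" or
    "breslow"). Constant covariates and event-free data are rejected with
    explicit errors.
    """
    tcol, ecol = _endpoint_columns(endpoint)
    if ties not in ("efron", "breslow"):
        raise ParameterError("ties must be 'efron' or 'breslow'")
    covariates = list(covariates) if covariates is not None else [
        c for c in model_matrix.columns
        if c not in (tcol, ecol, "dss_years", "dss_event",
                     "dfs_years", "dfs_event")]
    missing = [c for c in covariates + [tcol, ecol]
               if c not in model_matrix.columns]
    if missing:
        raise ParameterError(f"model matrix lacks column(s): {missing}")
    if int(model_matrix[ecol].sum()) == 0:
        raise ParameterError("no events; Cox model cannot be fitted")
    for c in covariates:
        if model_matrix[c].nunique() < 2:
            raise ParameterError(f"covariate {c!r} is constant across patients")

    df = model_matrix[covariates + [tcol, ecol]].copy()
    if ties == "efron":
        cph = CoxPHFitter()
        cph.fit(df, duration_col=tcol, event_col=ecol)
        s = cph.summary
        table = pd.DataFrame({
            "HR": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        })
        fitter = cph
    else:
        # Breslow tie handling via the proportional-hazards fit in
        # statsmodels (lifelines implements Efron only)
        from statsmodels.duration.hazard_regression import PHReg

        model = PHReg(df[tcol], df[covariates], status=df[ecol],
                      ties="breslow")
        res = model.fit()
        ci = res.conf_int()
        table = pd.DataFrame({
            "HR": np.exp(res.params),
            "ci_low": np.exp(ci[:, 0]),
            "ci_high": np.exp(ci[:, 1]),
            "p": res.pvalues,
        }, index=covariates)
        fitter = res
    return CoxResult(table=table, endpoint=endpoint, n=int(len(df)),
                     n_events=int(df[ecol].sum()), fitter=fitter)


def prognostic_report(cohort: pd.DataFrame, tsr_label_column: str,
                      endpoint: str = "dss", ties: str = "efron") -> dict:
    """Run the full harness for one TSR labelling and one endpoint.

    Emits the univariate TSR hazard ratio, the adjusted multivariate model
    (all standard covariates + TSR), the log-rank comparison and the
    five-year survival rates per group.
    """
    mm = recode_covariates(cohort, tsr_label_column=tsr_label_column)
    uni = cox_fit(mm, endpoint, covariates=["stroma_high"], ties=ties)
    multi = cox_fit(mm, endpoint,
                    covariates=list(MULTIVARIATE_COVARIATES) + ["stroma_high"],
                    ties=ties)
    km = km_logrank(cohort, tsr_label_column, endpoint)
    rates = {str(lvl): five_year_rate(f) for lvl, f in km.fitters.items()}
    return {
        "endpoint": endpoint,
        "univariate": uni,
        "multivariate": multi,
        "logrank_p": km.logrank_p,
        "five_year_rates": rates,
    }
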