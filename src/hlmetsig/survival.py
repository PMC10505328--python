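"""Case-cohort survival association of the metabolite signature.

Case-cohort samples (all cases plus a random subcohort) are analysed with
Barlow-weighted Cox proportional-hazards regression: subcohort person-time
is weighted by the inverse sampling fraction 1/f, case failures enter with
weight 1 just before their event, and variance is estimated with a robust
sandwich clustered by participant. Covariate sets follow three nested
models (minimal / + clinical covariates / + self-reported HL), stratified
by recruitment center and intervention arm. Effect modification by arm is
tested with a 1-df pseudo-likelihood-ratio test on the product term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.stats import chi2
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from ._containers import CaseCohortDesign, DimensionError, ValidationError

#: Nested covariate sets. Model 2 adds clinical covariates; the CVD
#: outcome additionally adjusts for prevalent diabetes. Model 3 adds the
#: self-reported HL (matching the signature's form).
MODEL2_EXTRA = [
    "education", "famhist_chd", "hypercholesterolemia", "chol_lowering_med",
    "hypertension", "antihtn_med", "energy_kcal",
]


@dataclass
class CoxFit:
    """One fitted weighted Cox model."""

    summary: pd.DataFrame  # term, logHR, robust_se, HR, ci_low, ci_high, p
    model_label: str
    n_events: int
    n_participants: int
    log_likelihood: float

    def term(self, name: str) -> pd.Series:
        return self.summary.set_index("term").loc[name]


def expand_barlow(design: CaseCohortDesign) -> pd.DataFrame:
    """Expand a case-cohort design into Barlow-weighted (start, stop] records.

    * subcohort non-case: one record (entry, t] with weight 1/f, no event;
    * subcohort case: (entry, t - eps] with weight 1/f plus (t - eps, t]
      with weight 1 carrying the event;
    * case outside the subcohort: single record (t - eps, t] with weight 1;

    eps is half the smallest positive gap between distinct event times
    (and never larger than half the earliest event time, so starts stay
    nonnegative).
    """
    tab = design.table
    if (tab["is_case"] & ~np.isfinite(tab["event_time"])).any():
        raise ValidationError("case without an event time")
    f = design.sampling_fraction
    etimes = np.sort(tab.loc[tab["is_case"], "event_time"].unique())
    if len(etimes) == 0:
        eps = 0.0
    else:
        gaps = np.diff(etimes)
        pos = gaps[gaps > 0]
        eps = 0.5 * pos.min() if len(pos) else 0.5 * etimes[0]
        eps = min(eps, 0.5 * etimes[0])

    rows = []
    for row in tab.itertuples(index=False):
        t, entry = row.event_time, row.entry_time
        if row.in_subcohort and not row.is_case:
            rows.append((row.id, entry, t, 0, 1.0 / f))
        elif row.in_subcohort and row.is_case:
            if t - eps > entry:
                rows.append((row.id, entry, t - eps, 0, 1.0 / f))
            rows.append((row.id, t - eps, t, 1, 1.0))
        else:  # case outside the subcohort
            rows.append((row.id, t - eps, t, 1, 1.0))
    rec = pd.DataFrame(rows, columns=["id", "start", "stop", "event", "weight"])
    if (rec["start"] >= rec["stop"]).any():
        raise ValidationError("degenerate record with start >= stop")
    return rec


def _encode(df: pd.DataFrame, covariates: list[str], model_label: str) -> tuple[pd.DataFrame, list[str]]:
    """Numeric design columns for the requested covariates (dummy-coding
    string columns, first level as reference)."""
    out = pd.DataFrame(index=df.index)
    terms: list[str] = []
    for cov in covariates:
        if cov not in df.columns:
            raise ValidationError(f"model {model_label}: missing covariate {cov!r}")
        col = df[cov]
        if col.isna().any():
            raise ValidationError(f"model {model_label}: covariate {cov!r} has missing values")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            out[dummies.columns] = dummies
            terms.extend(dummies.columns)
        else:
            out[cov] = col.astype(float)
            terms.append(cov)
    return out, terms


def fit_weighted_cox(
    records: pd.DataFrame,
    covariates: list[str],
    strata: list[str] | None = None,
    model_label: str = "1",
    robust: bool = True,
) -> CoxFit:
    """Maximize the weighted Cox partial likelihood on Barlow records.

    Ties are handled by the Breslow approximation; the variance is the
    robust sandwich clustered by participant id (all records of one
    participant form one cluster)."""
    design, terms = _encode(records, covariates, model_label)
    df = pd.concat(
        [records[["id", "start", "stop", "event", "weight"]].reset_index(drop=True),
         design.reset_index(drop=True)], axis=1,
    )
    strata = list(strata) if strata else None
    if strata:
        for s in strata:
            df[s] = records[s].to_numpy()
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            df,
            duration_col="stop", event_col="event", entry_col="start",
            weights_col="weight", cluster_col="id", robust=robust,
            strata=strata, formula=" + ".join(terms),
        )
    se = cph.standard_errors_
    loghr = cph.params_
    z = loghr / se
    p = chi2.sf(z**2, df=1)  # two-sided Wald
    summary = pd.DataFrame({
        "term": loghr.index,
        "logHR": loghr.to_numpy(),
        "robust_se": se.to_numpy(),
        "HR": np.exp(loghr.to_numpy()),
        "ci_low": np.exp(loghr.to_numpy() - 1.96 * se.to_numpy()),
        "ci_high": np.exp(loghr.to_numpy() + 1.96 * se.to_numpy()),
        "p": p,
    }).reset_index(drop=True)
    return CoxFit(
        summary=summary, model_label=model_label,
        n_events=int(records["event"].sum()),
        n_participants=int(records["id"].nunique()),
        log_likelihood=float(cph.log_likelihood_),
    )


def estimate_propensity(
    cohort: pd.DataFrame,
    covariates: list[str],
    arm_col: str = "arm",
    reference: str = "control",
) -> pd.DataFrame:
    """Propensity scores for a 3-arm assignment: multinomial logistic
    regression of arm on baseline covariates; returns the predicted
    probabilities of the two non-reference arms as columns ``ps_<arm>``.

    Near-separation (explosive coefficients) triggers a warning and a
    ridge-stabilized refit.
    """
    arms = sorted(cohort[arm_col].unique())
    if len(arms) != 3:
        raise ValidationError(f"expected 3 arms, found {arms}")
    design, _ = _encode(cohort, covariates, "propensity")
    X = StandardScaler().fit_transform(design.to_numpy(dtype=float))
    y = cohort[arm_col].to_numpy()
    model = LogisticRegression(C=1e6, max_iter=2000)
    model.fit(X, y)
    if np.abs(model.coef_).max() > 15.0:
        warnings.warn("possible separation in propensity model; "
                      "refitting with ridge stabilization")
        model = LogisticRegression(C=1.0, max_iter=2000)
        model.fit(X, y)
    probs = pd.DataFrame(model.predict_proba(X), columns=model.classes_,
                         index=cohort.index)
    keep = [a for a in arms if a != reference]
    return probs[keep].rename(columns={a: f"ps_{a}" for a in keep})


def _restrict_to_visit(design: CaseCohortDesign, visit: str, visit_time: float = 1.0) -> CaseCohortDesign:
    """For 1-year analyses, drop participants whose follow-up ended before
    the visit (including cases occurring before it) and left-truncate the
    remainder at the visit time."""
    if visit == "baseline":
        return design
    tab = design.table[design.table["event_time"] > visit_time].copy()
    tab["entry_time"] = visit_time
    return CaseCohortDesign(
        table=tab, sampling_fraction=design.sampling_fraction,
        n_full_cohort=design.n_full_cohort,
    )


def run_models(
    design: CaseCohortDesign,
    cohort: pd.DataFrame,
    signature_cont: pd.Series,
    signature_cat: pd.Series,
    hl_total: pd.Series,
    hl_category: pd.Series,
    outcome: str = "t2d",
    visit: str = "baseline",
    propensity_covariates: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[tuple, CoxFit]]:
    """Fit the three nested Barlow-weighted Cox models for both signature
    forms (categorical high-vs-low and continuous per-unit).

    Model 1: signature + age + sex + propensity scores, stratified by
    center and arm. Model 2: + education, family history of CHD,
    hypercholesterolemia, cholesterol-lowering medication, hypertension,
    antihypertensive treatment, total energy intake (+ prevalent diabetes
    for the CVD outcome). Model 3: model 2 + self-reported HL in the
    matching form. Returns a tidy table of the signature term per
    (model, form) plus the fitted models.
    """
    design = _restrict_to_visit(design, visit)
    records = expand_barlow(design)

    ps_covs = propensity_covariates or ["age", "sex"] + MODEL2_EXTRA
    ps = estimate_propensity(cohort, ps_covs)

    covs = cohort.copy()
    covs["sig_cont"] = signature_cont
    covs["sig_cat"] = (signature_cat.astype(str) == "high").astype(float)
    covs["hl_total"] = hl_total
    covs["hl_cat"] = (hl_category.astype(str) == "high").astype(float)
    covs[ps.columns] = ps

    merged = records.merge(covs.reset_index().rename(columns={covs.index.name or "index": "id"}),
                           on="id", how="left")

    base = ["age", "sex"] + list(ps.columns)
    model2 = base + MODEL2_EXTRA + (["diabetes_prev"] if outcome == "cvd" else [])
    rows = []
    fits: dict[tuple, CoxFit] = {}
    for form, sig_term, hl_term in [
        ("categorical", "sig_cat", "hl_cat"),
        ("continuous", "sig_cont", "hl_total"),
    ]:
        specs = {
            "1": [sig_term] + base,
            "2": [sig_term] + model2,
            "3": [sig_term] + model2 + [hl_term],
        }
        for label, cov_list in specs.items():
            fit = fit_weighted_cox(
                merged, cov_list, strata=["center", "arm"], model_label=label,
            )
            fits[(label, form)] = fit
            est = fit.term(sig_term)
            rows.append({
                "outcome": outcome, "visit": visit, "model": label,
                "form": form, "term": sig_term,
                "HR": est["HR"], "ci_low": est["ci_low"],
                "ci_high": est["ci_high"], "p": est["p"],
                "n_events": fit.n_events, "n_participants": fit.n_participants,
            })
    return pd.DataFrame(rows), fits


def interaction_test(
    design: CaseCohortDesign,
    cohort: pd.DataFrame,
    signature_cat: pd.Series,
    base_covariates: list[str] | None = None,
    arm_col: str = "arm",
    reference: str = "control",
) -> pd.DataFrame:
    """Test arm x signature effect modification, one MedDiet arm at a time.

    For each non-reference arm, participants in that arm or the control are
    analysed with a base model (signature + arm indicator + covariates,
    stratified by center) and a model adding the product term; twice the
    weighted partial-log-likelihood difference is referred to chi-square(1)
    (a pseudo-LRT, since the Barlow likelihood is a pseudo-likelihood). A
    robust Wald p-value for the product term is reported alongside.
    """
    records = expand_barlow(design)
    covs = cohort.copy()
    covs["sig_cat"] = (signature_cat.astype(str) == "high").astype(float)
    merged = records.merge(covs.reset_index().rename(columns={covs.index.name or "index": "id"}),
                           on="id", how="left")
    arms = sorted(a for a in cohort[arm_col].unique() if a != reference)
    base_covariates = base_covariates or ["age", "sex"]

    out = []
    for arm in arms:
        sub = merged[merged[arm_col].isin([arm, reference])].copy()
        sub["arm_ind"] = (sub[arm_col] == arm).astype(float)
        sub["product"] = sub["arm_ind"] * sub["sig_cat"]
        if sub["product"].nunique() < 2 or sub["sig_cat"].nunique() < 2:
            raise ValidationError(
                f"degenerate product term for arm {arm!r}: constant covariate"
            )
        base = fit_weighted_cox(
            sub, ["sig_cat", "arm_ind"] + base_covariates,
            strata=["center"], model_label="base", robust=False,
        )
        full = fit_weighted_cox(
            sub, ["sig_cat", "arm_ind", "product"] + base_covariates,
            strata=["center"], model_label="interaction",
        )
        lr = 2.0 * (full.log_likelihood - base.log_likelihood)
        p_lrt = float(chi2.sf(max(lr, 0.0), df=1))
        p_wald = float(full.term("product")["p"])
        out.append({"arm": arm, "lr_stat": lr, "p_lrt": p_lrt, "p_wald": p_wald})
    return pd.DataFrame(out)
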