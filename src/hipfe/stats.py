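"""Survival, discrimination and reclassification statistics.

Implements the statistical battery of the fracture-prediction analysis:
Mann-Whitney group comparisons, Cox proportional-hazards models with
per-SD-decrease hazard ratios (Efron tie handling), Harrell's C with
jackknife confidence intervals and paired jackknife comparison of two
correlated C indices, threshold-based (binary) Cox models, and net
reclassification improvement (NRI) between nested logistic models with a
threshold sweep.

Outcome columns follow the convention ``event_<outcome>`` / ``time_<outcome>``
with ``outcome`` in {"lt", "mof"}; risk-category cutoffs default to 15 %
predicted probability for MOF and 20 % for LT fractures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats as sps

DEFAULT_RISK_CUTOFF = {"mof": 0.15, "lt": 0.20}

#: strength thresholds of the reclassification sweep (N)
SWEEP_THRESHOLDS = tuple(range(2300, 3001, 100))


@dataclass
class CoxFit:
    predictor: str
    hr_per_sd_decrease: float
    ci95: tuple[float, float]
    p_value: float
    adjusted_for: tuple[str, ...]
    c_index: float
    c_index_ci: tuple[float, float]
    risk_score: np.ndarray = field(repr=False, default=None)
    time: np.ndarray = field(repr=False, default=None)
    event: np.ndarray = field(repr=False, default=None)


@dataclass
class ReclassResult:
    dxa_rule: str
    strength_threshold: float
    outcome: str
    nri: float
    se: float
    p_value: float
    n_events: int
    n_nonevents: int


@dataclass
class ReclassPlotData:
    outcome: str
    table: pd.DataFrame          # per-subject t-scores, strength, flags
    t_thresholds: tuple[float, float]
    strength_thresholds: tuple[float, float]
    cell_counts: dict            # (t_bin, s_bin) -> count
    case_percent: dict           # quadrant percentages among fracture cases
    n_dropped: int


# ---------------------------------------------------------------------------
# group comparison


def group_compare(values_controls, values_cases) -> float:
    """Two-sided Mann-Whitney U p-value for a control/case comparison."""
    a = np.asarray(values_controls, float)
    b = np.asarray(values_cases, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        return 1.0  # fully tied, no evidence either way
    return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# concordance (Harrell's C)


def _concordance_parts(time, event, score):
    """Pairwise numerator/denominator matrices for Harrell's C.

    A pair (i, j) is usable when the shorter observed time carries an event;
    concordant pairs have the higher risk score on the earlier event (ties
    in score count 1/2).
    """
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    s = np.asarray(score, float)
    ti, tj = t[:, None], t[None, :]
    ei = e[:, None]
    usable = (ti < tj) & (ei == 1)
    si, sj = s[:, None], s[None, :]
    conc = np.where(si > sj, 1.0, np.where(si == sj, 0.5, 0.0))
    num = np.where(usable, conc, 0.0)
    den = usable.astype(float)
    return num, den


def concordance_index(time, event, score) -> float:
    """Harrell's concordance between a risk score and event ordering."""
    num, den = _concordance_parts(time, event, score)
    d = den.sum()
    if d == 0:
        raise ValueError("no usable (comparable) pairs for concordance")
    return float(num.sum() / d)


def _jackknife_c(num, den):
    """Leave-one-subject-out concordance values from pair matrices."""
    tn, td = num.sum(), den.sum()
    ri_n = num.sum(axis=1) + num.sum(axis=0)
    ri_d = den.sum(axis=1) + den.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_loo = (tn - ri_n) / (td - ri_d)
    c_loo[~np.isfinite(c_loo)] = tn / td
    return c_loo


def harrells_c(fit: CoxFit, alpha: float = 0.05):
    """Harrell's C of a fitted risk score, with a jackknife 95 % CI."""
    num, den = _concordance_parts(fit.time, fit.event, fit.risk_score)
    if den.sum() == 0:
        raise ValueError("no comparable pairs")
    c = float(num.sum() / den.sum())
    loo = _jackknife_c(num, den)
    n = len(loo)
    se = np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum())
    zc = sps.norm.ppf(1 - alpha / 2)
    return c, (c - zc * se, c + zc * se)


def compare_c(fit_a: CoxFit, fit_b: CoxFit) -> float:
    """Two-sided p-value for the difference of two correlated C indices.

    Paired jackknife over subjects: both models must be fitted on the same
    subjects (identical time/event vectors).
    """
    if len(fit_a.time) != len(fit_b.time) or \
            not (np.allclose(fit_a.time, fit_b.time) and
                 np.array_equal(fit_a.event, fit_b.event)):
        raise ValueError("compare_c requires fits on the identical subject set")
    na, da = _concordance_parts(fit_a.time, fit_a.event, fit_a.risk_score)
    nb, db = _concordance_parts(fit_b.time, fit_b.event, fit_b.risk_score)
    diff = na.sum() / da.sum() - nb.sum() / db.sum()
    d_loo = _jackknife_c(na, da) - _jackknife_c(nb, db)
    n = len(d_loo)
    var = (n - 1) / n * ((d_loo - d_loo.mean()) ** 2).sum()
    if var <= 0:
        return 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    return float(2 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Cox models


def _check_outcome(cohort: pd.DataFrame, outcome: str):
    tcol, ecol = f"time_{outcome}", f"event_{outcome}"
    if tcol not in cohort or ecol not in cohort:
        raise ValueError(f"cohort lacks {tcol}/{ecol} columns")
    return tcol, ecol


def _fit_cox(df: pd.DataFrame, tcol: str, ecol: str, covariates: list[str]):
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[[tcol, ecol] + covariates], duration_col=tcol, event_col=ecol)
    return cph


def cox_per_sd(cohort: pd.DataFrame, predictor: str, outcome: str,
               adjust_age: bool = False) -> CoxFit:
    """Cox hazard ratio per SD *decrease* of a continuous predictor.

    The predictor is standardized in-sample and sign-flipped so HR > 1
    means increased risk per SD impairment.  Partial likelihood with Efron
    tie handling; Wald CI and p-value.
    """
    tcol, ecol = _check_outcome(cohort, outcome)
    x = cohort[predictor].to_numpy(float)
    if np.std(x) == 0:
        raise ValueError(f"predictor {predictor!r} has zero variance")
    if cohort[ecol].sum() < 2:
        raise ValueError("need at least 2 events")
    df = pd.DataFrame({
        tcol: cohort[tcol].to_numpy(float),
        ecol: cohort[ecol].to_numpy(int),
        "z_impair": -(x - x.mean()) / x.std(ddof=0),
    })
    covs = ["z_impair"]
    if adjust_age:
        df["age"] = cohort["age"].to_numpy(float)
        covs.append("age")
    cph = _fit_cox(df, tcol, ecol, covs)
    coef = float(cph.params_["z_impair"])
    se = float(cph.standard_errors_["z_impair"])
    score = cph.predict_partial_hazard(df).to_numpy()
    fit = CoxFit(
        predictor=predictor,
        hr_per_sd_decrease=float(np.exp(coef)),
        ci95=(float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se))),
        p_value=float(cph.summary.loc["z_impair", "p"]),
        adjusted_for=tuple(covs[1:]),
        c_index=np.nan, c_index_ci=(np.nan, np.nan),
        risk_score=np.log(score), time=df[tcol].to_numpy(),
        event=df[ecol].to_numpy(),
    )
    fit.c_index, fit.c_index_ci = harrells_c(fit)
    return fit


THRESHOLD_RULES = {
    "th_tscore<=-2.5": lambda df: df["th_tscore"] <= -2.5,
    "fn_tscore<=-2.5": lambda df: df["fn_tscore"] <= -2.5,
    "either": lambda df: (df["th_tscore"] <= -2.5) | (df["fn_tscore"] <= -2.5),
    "strength<3000": lambda df: df["strength_fall"] < 3000.0,
    "strength<2600": lambda df: df["strength_fall"] < 2600.0,
}


def threshold_cox(cohort: pd.DataFrame, rule: str, outcome: str,
                  adjust_age: bool = True) -> CoxFit:
    """Cox model on a binary fragility flag (T-score or strength threshold)."""
    if rule not in THRESHOLD_RULES:
        raise ValueError(f"unknown rule {rule!r}; options: {sorted(THRESHOLD_RULES)}")
    tcol, ecol = _check_outcome(cohort, outcome)
    flag = THRESHOLD_RULES[rule](cohort).astype(int).to_numpy()
    if flag.sum() == 0 or flag.sum() == len(flag):
        raise ValueError(f"rule {rule!r} yields an empty class")
    df = pd.DataFrame({tcol: cohort[tcol].to_numpy(float),
                       ecol: cohort[ecol].to_numpy(int), "flag": flag})
    covs = ["flag"]
    if adjust_age:
        df["age"] = cohort["age"].to_numpy(float)
        covs.append("age")
    cph = _fit_cox(df, tcol, ecol, covs)
    coef = float(cph.params_["flag"])
    if abs(coef) > 8:
        raise RuntimeError(
            f"monotone likelihood detected for rule {rule!r} "
            f"(|log HR| = {abs(coef):.1f}); the flag separates the events")
    se = float(cph.standard_errors_["flag"])
    fit = CoxFit(
        predictor=rule,
        hr_per_sd_decrease=float(np.exp(coef)),
        ci95=(float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se))),
        p_value=float(cph.summary.loc["flag", "p"]),
        adjusted_for=tuple(covs[1:]),
        c_index=np.nan, c_index_ci=(np.nan, np.nan),
        risk_score=np.log(cph.predict_partial_hazard(df).to_numpy()),
        time=df[tcol].to_numpy(), event=df[ecol].to_numpy(),
    )
    fit.c_index, fit.c_index_ci = harrells_c(fit)
    return fit


# ---------------------------------------------------------------------------
# net reclassification improvement


def _nri_from_categories(cat_a, cat_b, event):
    """Two-category NRI and its asymptotic SE from high/low risk bins.

    NRI = [P(up|event) - P(down|event)] + [P(down|non-event) - P(up|non-event)]
    with the standard independent event/non-event binomial variance.
    """
    cat_a = np.asarray(cat_a, int)
    cat_b = np.asarray(cat_b, int)
    event = np.asarray(event, int)
    up = (cat_b > cat_a)
    down = (cat_b < cat_a)
    ev = event == 1
    ne = ~ev
    n_e, n_ne = int(ev.sum()), int(ne.sum())
    if n_e == 0 or n_ne == 0:
        raise ValueError("need both events and non-events for NRI")
    p_up_e = up[ev].mean()
    p_dn_e = down[ev].mean()
    p_up_ne = up[ne].mean()
    p_dn_ne = down[ne].mean()
    nri = (p_up_e - p_dn_e) + (p_dn_ne - p_up_ne)
    var = ((p_up_e + p_dn_e - (p_up_e - p_dn_e) ** 2) / n_e
           + (p_up_ne + p_dn_ne - (p_dn_ne - p_up_ne) ** 2) / n_ne)
    se = float(np.sqrt(var))
    if se == 0:
        p = 1.0 if nri == 0 else 0.0
    else:
        p = float(2 * sps.norm.sf(abs(nri) / se))
    return float(nri), se, p


def _logit_probs(y, X):
    Xc = sm.add_constant(np.asarray(X, float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(np.asarray(y, int), Xc).fit(disp=False, maxiter=200)
        except Exception as exc:  # includes perfect separation
            raise RuntimeError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)) or np.any(np.abs(res.params) > 30):
        raise RuntimeError("separation in logistic fit (diverging coefficients)")
    return res.predict(Xc)


def nri(cohort: pd.DataFrame, dxa_rule: str, strength_threshold: float,
        outcome: str, risk_cutoff: float | None = None) -> ReclassResult:
    """NRI of adding a strength class to a T-score classification.

    Model A: outcome ~ (T-score <= -2.5 at ``dxa_rule`` in {"FN", "TH"}) +
    follow-up duration; model B adds the binary fragile-strength flag
    (fall strength below ``strength_threshold``).  Subjects are binned
    high/low risk by predicted probability against the cutoff (15 % MOF,
    20 % LT by default).
    """
    outcome = outcome.lower()
    cutoff = DEFAULT_RISK_CUTOFF[outcome] if risk_cutoff is None else risk_cutoff
    if not (0 < cutoff < 1):
        raise ValueError("risk_cutoff must lie in (0, 1)")
    tscore_col = {"FN": "fn_tscore", "TH": "th_tscore"}[dxa_rule.upper()]
    y = cohort[f"event_{outcome}"].to_numpy(int)
    t_flag = (cohort[tscore_col] <= -2.5).astype(float).to_numpy()
    s_flag = (cohort["strength_fall"] <= strength_threshold).astype(float).to_numpy()
    fu = cohort["followup_years"].to_numpy(float)

    p_a = _logit_probs(y, np.column_stack([t_flag, fu]))
    if np.array_equal(t_flag, s_flag):
        # the added class duplicates the existing flag: the nested models
        # are identical and nobody can be reclassified
        p_b = p_a
    else:
        p_b = _logit_probs(y, np.column_stack([t_flag, s_flag, fu]))
    cat_a = (p_a > cutoff).astype(int)
    cat_b = (p_b > cutoff).astype(int)
    nri_v, se, p = _nri_from_categories(cat_a, cat_b, y)
    return ReclassResult(
        dxa_rule=dxa_rule.upper(), strength_threshold=float(strength_threshold),
        outcome=outcome, nri=nri_v, se=se, p_value=p,
        n_events=int(y.sum()), n_nonevents=int((1 - y).sum()))


def nri_sweep(cohort: pd.DataFrame, thresholds=SWEEP_THRESHOLDS,
              rules=("FN", "TH"), outcomes=("lt", "mof")) -> pd.DataFrame:
    """NRI for every rule x threshold x outcome cell of the sweep grid."""
    for t in thresholds:
        if not (SWEEP_THRESHOLDS[0] <= t <= SWEEP_THRESHOLDS[-1]):
            raise ValueError(f"threshold {t} outside the sweep grid "
                             f"[{SWEEP_THRESHOLDS[0]}, {SWEEP_THRESHOLDS[-1]}]")
    rows = []
    for rule in rules:
        for thr in thresholds:
            for out in outcomes:
                r = nri(cohort, rule, thr, out)
                rows.append({"dxa_rule": r.dxa_rule, "threshold": thr,
                             "outcome": out, "nri": r.nri, "se": r.se,
                             "p_value": r.p_value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reclassification plot data


def reclass_plot_data(cohort: pd.DataFrame, outcome: str, dxa_rule: str = "FN",
                      strength_thresholds=(3000.0, 2600.0),
                      t_thresholds=(-2.5, -1.0)) -> ReclassPlotData:
    """Per-subject scatter data and quadrant summaries for the
    strength-versus-T-score reclassification plot.

    Quadrants split non-osteoporotic/osteoporotic (T-score against -2.5)
    versus fragile/non-fragile strength; among fracture cases the summary
    reports the percentage in each cell (integers, mirroring narrative
    reporting conventions).
    """
    outcome = outcome.lower()
    tcol = {"FN": "fn_tscore", "TH": "th_tscore"}[dxa_rule.upper()]
    cols = [tcol, "strength_fall", f"event_{outcome}"]
    sub = cohort[cols + (["fracture_site"] if "fracture_site" in cohort else [])].copy()
    n0 = len(sub)
    sub = sub.dropna(subset=cols)
    n_dropped = n0 - len(sub)

    t_osteo = t_thresholds[0]
    s_fragile, s_very = strength_thresholds
    tab = pd.DataFrame({
        "t_score": sub[tcol].to_numpy(float),
        "strength": sub["strength_fall"].to_numpy(float),
        "event": sub[f"event_{outcome}"].to_numpy(int),
    })
    if "fracture_site" in sub:
        tab["site"] = sub["fracture_site"].to_numpy()
    tab["osteoporotic"] = tab["t_score"] <= t_osteo
    tab["fragile"] = tab["strength"] <= s_fragile
    tab["very_fragile"] = tab["strength"] <= s_very

    counts = {}
    for ob in (False, True):
        for fb in (False, True):
            counts[(ob, fb)] = int(((tab["osteoporotic"] == ob) &
                                    (tab["fragile"] == fb)).sum())
    cases = tab[tab["event"] == 1]
    pct = {}
    if len(cases):
        for key, mask in {
            "non_osteoporotic_fragile": (~cases["osteoporotic"]) & cases["fragile"],
            "non_osteoporotic_very_fragile": (~cases["osteoporotic"]) & cases["very_fragile"],
            "osteoporotic_fragile": cases["osteoporotic"] & cases["fragile"],
            "osteoporotic_non_fragile": cases["osteoporotic"] & (~cases["fragile"]),
            "non_osteoporotic_non_fragile": (~cases["osteoporotic"]) & (~cases["fragile"]),
        }.items():
            pct[key] = int(round(100.0 * mask.sum() / len(cases)))
    return ReclassPlotData(
        outcome=outcome, table=tab, t_thresholds=tuple(t_thresholds),
        strength_thresholds=tuple(strength_thresholds), cell_counts=counts,
        case_percent=pct, n_dropped=n_dropped)
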