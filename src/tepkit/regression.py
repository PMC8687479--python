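"""Regression of pandemic mental health on pre-pandemic TMS-EEG reactivity.

The response variable is each subject's mean pandemic PHQ-4 total,
Box-Cox transformed; candidate predictors are local and global reactivity
AUCs, their interactions with the targeting method, demographics, and time
since stimulation.  The stage covers design construction, OLS with full
Gaussian log-likelihood information criteria, a Monte-Carlo Lilliefors
normality check, nested-model likelihood-ratio testing, sequential (Type-I)
variance decomposition, and the standard assumption diagnostics
(VIF, Durbin-Watson, Breusch-Pagan).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import durbin_watson

from .groupstats import mean_pandemic_score
from .io import CohortTable

log = logging.getLogger(__name__)

FULL_PREDICTORS = [
    "local_auc", "global_auc", "local_auc_x_method", "global_auc_x_method",
    "age", "gender", "education_years", "months_since_tms",
]
REDUCED_PREDICTORS = ["local_auc", "education_years"]


@dataclass(frozen=True)
class ModelSpec:
    name: str
    predictors: tuple[str, ...]
    target: str


MODEL_SPECS: dict[str, ModelSpec] = {
    "full_dlpfc": ModelSpec("full_dlpfc", tuple(FULL_PREDICTORS), "DLPFC"),
    "reduced_dlpfc": ModelSpec("reduced_dlpfc", tuple(REDUCED_PREDICTORS), "DLPFC"),
    "full_ipl": ModelSpec("full_ipl", tuple(FULL_PREDICTORS), "IPL"),
    "reduced_plus_baseline": ModelSpec(
        "reduced_plus_baseline",
        tuple(REDUCED_PREDICTORS + ["baseline_activity"]), "DLPFC"),
}


class SingularDesignError(ValueError):
    """Design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(cohort: CohortTable, scores: pd.DataFrame, spec: ModelSpec
                 ) -> tuple[pd.DataFrame, pd.Series, int]:
    """Design matrix (with intercept column ``const``) and response vector.

    Response: mean pandemic PHQ-4 per subject.  Codings: gender female=0 /
    male=1; targeting method anatomical=0 / functional=1; interactions are
    products of the coded method with the AUC.  Subjects missing the spec's
    target or any required predictor are dropped (count returned and logged).
    """
    sc = scores[scores["target"] == spec.target].set_index("subject_id")
    rows = []
    n_dropped = 0
    for _, r in cohort.df.iterrows():
        sid = r["subject_id"]
        if spec.target not in r["completed_targets"] or sid not in sc.index:
            n_dropped += 1
            continue
        s = sc.loc[sid]
        method = 1.0 if r["targeting_method"] == "functional" else 0.0
        values = {
            "local_auc": s["local_auc"],
            "global_auc": s["global_auc"],
            "baseline_activity": s["baseline_activity"],
            "local_auc_x_method": s["local_auc"] * method,
            "global_auc_x_method": s["global_auc"] * method,
            "age": float(r["age"]),
            "gender": 1.0 if r["gender"] == "male" else 0.0,
            "education_years": float(r["education_years"]),
            "months_since_tms": float(r["months_since_tms"]),
        }
        row = {p: values[p] for p in spec.predictors}
        if any(not np.isfinite(v) for v in row.values()):
            n_dropped += 1
            continue
        row["subject_id"] = sid
        row["_response"] = mean_pandemic_score(r["phq_pandemic"])
        rows.append(row)
    if not rows:
        raise ValueError(f"empty design for model {spec.name} after filtering")
    df = pd.DataFrame(rows).set_index("subject_id")
    y = df.pop("_response")
    X = df[list(spec.predictors)]
    X = sm.add_constant(X, prepend=True, has_constant="add")
    if n_dropped:
        log.info("model %s: dropped %d subjects without complete data",
                 spec.name, n_dropped)
    return X, y, n_dropped


# ---------------------------------------------------------------------------
# Box-Cox transform
# ---------------------------------------------------------------------------

def boxcox(y, lam_grid: tuple[float, float, float] = (-5.0, 5.0, 1e-3)
           ) -> tuple[np.ndarray, float, float]:
    """Box-Cox power transform with lambda chosen by profile log-likelihood.

    The grid [lo, hi] with the given step is scanned; a positivity shift of
    ``1 - min(y)`` is applied first when min(y) <= 0.  Returns
    (transformed, lambda, shift).
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("Box-Cox undefined for a constant response")
    shift = 1.0 - y.min() if y.min() <= 0 else 0.0
    yp = y + shift
    lo, hi, step = lam_grid
    lams = np.arange(lo, hi + step / 2, step)
    llf = _boxcox_profile_llf(lams, yp)
    lam = float(lams[np.argmax(llf)])
    return boxcox_transform(yp, lam), lam, shift


def _boxcox_profile_llf(lams: np.ndarray, y_pos: np.ndarray) -> np.ndarray:
    """Profile log-likelihood of the Box-Cox model over a lambda grid:
    (lam - 1) * sum(ln y) - n/2 * ln(sigma_hat^2(lam))."""
    n = len(y_pos)
    log_y = np.log(y_pos)
    sum_log = log_y.sum()
    lams = np.asarray(lams, dtype=float)
    nz = lams != 0
    trans = np.empty((len(lams), n))
    trans[nz] = (np.exp(np.outer(lams[nz], log_y)) - 1.0) / lams[nz, None]
    trans[~nz] = log_y
    var = trans.var(axis=1)
    return (lams - 1.0) * sum_log - 0.5 * n * np.log(var)


def boxcox_transform(y_pos: np.ndarray, lam: float) -> np.ndarray:
    """(y^lam - 1)/lam for lam != 0, ln y for lam = 0; requires y > 0."""
    y_pos = np.asarray(y_pos, dtype=float)
    if np.any(y_pos <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if lam == 0:
        return np.log(y_pos)
    # expm1 form is exact for lam != 0 and stable as lam -> 0
    return np.expm1(lam * np.log(y_pos)) / lam


# ---------------------------------------------------------------------------
# OLS fit
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    name: str
    predictors: list[str]
    params: dict
    tvalues: dict
    pvalues: dict
    fvalue: float
    f_pvalue: float
    df_model: int
    df_resid: int
    rsquared: float
    rsquared_adj: float
    llf: float
    aic: float
    bic: float
    residuals: np.ndarray = field(repr=False)
    n: int
    lam: float | None = None
    shift: float | None = None
    X: pd.DataFrame | None = field(default=None, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "name": self.name, "predictors": self.predictors,
            "coefficients": self.params, "t": self.tvalues, "p": self.pvalues,
            "F": self.fvalue, "F_p": self.f_pvalue,
            "df_model": self.df_model, "df_resid": self.df_resid,
            "r2": self.rsquared, "r2_adj": self.rsquared_adj,
            "log_likelihood": self.llf, "aic": self.aic, "bic": self.bic,
            "boxcox_lambda": self.lam, "boxcox_shift": self.shift,
            "n": self.n,
        }


def fit_ols(X: pd.DataFrame, y, name: str = "model",
            lam: float | None = None, shift: float | None = None) -> RegressionFit:
    """Ordinary least squares with full Gaussian log-likelihood information
    criteria: AIC = -2l + 2k*, BIC = -2l + k* ln n, where k* counts every
    coefficient (including the intercept) plus the error variance.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"n={n} too small for {k} coefficients")
    if np.linalg.matrix_rank(X.values) < k:
        raise SingularDesignError(f"design matrix for {name} is rank deficient")
    res = sm.OLS(y, X).fit()
    k_star = k + 1  # coefficients + sigma^2
    aic = -2.0 * res.llf + 2.0 * k_star
    bic = -2.0 * res.llf + k_star * np.log(n)
    predictors = [c for c in X.columns if c != "const"]
    return RegressionFit(
        name=name, predictors=predictors,
        params={c: float(res.params[c]) for c in X.columns},
        tvalues={c: float(res.tvalues[c]) for c in X.columns},
        pvalues={c: float(res.pvalues[c]) for c in X.columns},
        fvalue=float(res.fvalue), f_pvalue=float(res.f_pvalue),
        df_model=int(res.df_model), df_resid=int(res.df_resid),
        rsquared=float(res.rsquared), rsquared_adj=float(res.rsquared_adj),
        llf=float(res.llf), aic=float(aic), bic=float(bic),
        residuals=np.asarray(res.resid), n=n, lam=lam, shift=shift,
        X=X, y=y,
    )


# ---------------------------------------------------------------------------
# residual normality (Lilliefors, Monte-Carlo null)
# ---------------------------------------------------------------------------

def _lilliefors_statistic(x: np.ndarray) -> float:
    x = np.sort(x)
    n = len(x)
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    return float(max((i / n - cdf).max(), (cdf - (i - 1) / n).max()))


def lilliefors(residuals, n_sim: int = 10_000, seed: int = 0) -> tuple[float, float]:
    """Kolmogorov-Smirnov test of normality with estimated mean and variance.

    The null distribution of D is simulated (``n_sim`` standard-normal
    samples of the same size, seeded), since estimating the parameters
    invalidates the standard KS tables.
    """
    x = np.asarray(residuals, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 residuals")
    d_obs = _lilliefors_statistic(x)
    rng = np.random.default_rng(seed)
    sims = np.sort(rng.normal(size=(n_sim, n)), axis=1)
    z = (sims - sims.mean(axis=1, keepdims=True)) / sims.std(axis=1, ddof=1, keepdims=True)
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_null = np.maximum((i / n - cdf).max(axis=1), (cdf - (i - 1) / n).max(axis=1))
    p = float(((d_null >= d_obs).sum() + 1) / (n_sim + 1))
    return d_obs, p


# ---------------------------------------------------------------------------
# nested-model comparison
# ---------------------------------------------------------------------------

@dataclass
class LRTResult:
    chi2: float
    df: int
    p: float

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "p": self.p}


def likelihood_ratio_test(full: RegressionFit, reduced: RegressionFit) -> LRTResult:
    """chi2 = 2(l_full - l_reduced); requires the same response vector and a
    reduced predictor set strictly nested in the full one."""
    if full.n != reduced.n:
        raise ValueError("models fit on different numbers of subjects")
    if full.y is not None and reduced.y is not None and not np.allclose(full.y, reduced.y):
        raise ValueError("models fit on different response vectors")
    if not set(reduced.predictors) <= set(full.predictors):
        raise ValueError("reduced model predictors are not nested in the full model")
    df = len(full.predictors) - len(reduced.predictors)
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return LRTResult(chi2=chi2, df=df, p=p)


# ---------------------------------------------------------------------------
# variance decomposition and diagnostics
# ---------------------------------------------------------------------------

def anova_percent_variance(fit: RegressionFit, order: list[str] | None = None
                           ) -> dict[str, float]:
    """Sequential (Type-I) sums of squares as percent of total SS.

    Predictors are entered in ``order`` (default: the fitted order); each
    entry's contribution is the drop in residual SS when it is added.  The
    returned dict includes a "residual" entry so the percentages sum to 100.
    """
    if fit.X is None or fit.y is None:
        raise ValueError("fit does not retain its design matrix")
    order = list(order) if order is not None else list(fit.predictors)
    if sorted(order) != sorted(fit.predictors):
        raise ValueError("order must be a permutation of the model's predictors")
    y = fit.y
    tss = float(((y - y.mean()) ** 2).sum())
    out: dict[str, float] = {}
    cols = ["const"]
    rss_prev = tss
    for p in order:
        cols.append(p)
        res = sm.OLS(y, fit.X[cols]).fit()
        rss = float((res.resid**2).sum())
        out[p] = 100.0 * (rss_prev - rss) / tss
        rss_prev = rss
    out["residual"] = 100.0 * rss_prev / tss
    return out


def diagnostics(fit: RegressionFit) -> dict:
    """Multicollinearity (VIF), autocorrelation (Durbin-Watson) and
    heteroscedasticity (Breusch-Pagan) checks on a fitted model."""
    if fit.X is None:
        raise ValueError("fit does not retain its design matrix")
    X = fit.X
    vif = {}
    for i, c in enumerate(X.columns):
        if c == "const":
            continue
        vif[c] = float(variance_inflation_factor(X.values, i))
    dw = float(durbin_watson(fit.residuals))
    bp = het_breuschpagan(fit.residuals, X.values)
    return {"vif": vif, "durbin_watson": dw, "breusch_pagan_p": float(bp[1])}


# ---------------------------------------------------------------------------
# the model suite
# ---------------------------------------------------------------------------

def run_model_suite(cohort: CohortTable, scores: pd.DataFrame,
                    lilliefors_seed: int = 0) -> dict:
    """Fit the four candidate models on the Box-Cox transformed response and
    assemble the comparison report.

    Models: full and reduced for the DLPFC target, the full model for the
    IPL control target, and the reduced DLPFC model plus local baseline
    pre-stimulus activity.  The likelihood-ratio test compares full vs
    reduced DLPFC on the common subject set under a single transform; AIC/BIC
    use the full Gaussian likelihood.  Each model gets a Lilliefors residual
    check, sequential variance decomposition (reduced model), and assumption
    diagnostics.
    """
    report: dict = {"models": {}, "n_subjects": {}}
    fits: dict[str, RegressionFit] = {}
    for name, spec in MODEL_SPECS.items():
        X, y_raw, n_dropped = build_design(cohort, scores, spec)
        yt, lam, shift = boxcox(y_raw.values)
        fit = fit_ols(X, yt, name=name, lam=lam, shift=shift)
        fits[name] = fit
        d, p = lilliefors(fit.residuals, seed=lilliefors_seed)
        entry = fit.to_dict()
        entry["lilliefors"] = {"D": d, "p": p}
        entry["diagnostics"] = diagnostics(fit)
        entry["n_dropped"] = n_dropped
        report["models"][name] = entry
        report["n_subjects"][name] = fit.n
        log.info("model %s: n=%d, F=%.3g (p=%.3g), R2adj=%.3f",
                 name, fit.n, fit.fvalue, fit.f_pvalue, fit.rsquared_adj)

    # LRT on the common subject set under one transform
    Xf, yf, _ = build_design(cohort, scores, MODEL_SPECS["full_dlpfc"])
    Xr, yr, _ = build_design(cohort, scores, MODEL_SPECS["reduced_dlpfc"])
    common = Xf.index.intersection(Xr.index)
    yt, lam, shift = boxcox(yf.loc[common].values)
    full_c = fit_ols(Xf.loc[common], yt, name="full_dlpfc", lam=lam, shift=shift)
    red_c = fit_ols(Xr.loc[common], yt, name="reduced_dlpfc", lam=lam, shift=shift)
    lrt = likelihood_ratio_test(full_c, red_c)
    report["lrt_full_vs_reduced_dlpfc"] = lrt.to_dict()
    report["aic_preference"] = (
        "reduced" if fits["reduced_dlpfc"].aic < fits["full_dlpfc"].aic else "full")
    report["bic_preference"] = (
        "reduced" if fits["reduced_dlpfc"].bic < fits["full_dlpfc"].bic else "full")
    report["anova_reduced_dlpfc"] = anova_percent_variance(
        fits["reduced_dlpfc"], order=["local_auc", "education_years"])
    report["_fits"] = fits
    return report
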