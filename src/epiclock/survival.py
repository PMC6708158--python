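"""Age-acceleration residuals and their association with mortality.

The age acceleration residual (AAR) is the residual from regressing
predicted age on chronological age; positive values mark samples that are
epigenetically "older" than their years.  Its association with death is
estimated with a Cox proportional-hazards model fitted by Newton-Raphson
on the partial likelihood, with the Efron correction for tied event
times (Breslow available by flag).  The hazard ratio for AAR is reported
per 5 years of age acceleration, i.e. exp(5 * beta).

The attenuation experiment reproduces the study design in which one
cohort is permanently held out of clock training: for every training set
in a design, a clock is trained, AAR is computed on the held-out cohort,
and the Cox z statistic is recorded with and without adjustment for the
five measured white-blood-cell counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clocks import TrainingDesign
from .evaluation import _train_for_entry
from .io import TECHNICAL_COLUMNS, WBC_COLUMNS, MethylationMatrix

logger = logging.getLogger("epiclock")


class CoxError(RuntimeError):
    """Raised when the partial likelihood cannot be maximized."""


# ---------------------------------------------------------------------------
# AAR
# ---------------------------------------------------------------------------


def compute_aar(predicted, chronological, sample_ids=None) -> pd.DataFrame:
    """Residuals from regressing predicted age on chronological age.

    Returns a table with columns predicted_age, chronological_age, aar.
    Within the fitted group the residuals sum to zero (the regression
    includes an intercept).
    """
    yhat = np.asarray(predicted, dtype=float).ravel()
    y = np.asarray(chronological, dtype=float).ravel()
    if len(yhat) != len(y):
        raise ValueError("length mismatch")
    if len(y) < 3:
        raise ValueError("need at least 3 samples")
    if y.std() == 0:
        raise ValueError("chronological age is constant; AAR undefined")
    slope, intercept = np.polyfit(y, yhat, 1)
    resid = yhat - (intercept + slope * y)
    if sample_ids is None:
        if isinstance(predicted, pd.Series):
            sample_ids = predicted.index
        else:
            sample_ids = pd.RangeIndex(len(y))
    return pd.DataFrame(
        {
            "predicted_age": yhat,
            "chronological_age": y,
            "aar": resid,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


# ---------------------------------------------------------------------------
# Cox partial-likelihood engine
# ---------------------------------------------------------------------------


def _cox_loglik(beta, X, time, event, ties):
    """Log partial likelihood, gradient and Hessian (Efron or Breslow)."""
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]

    # suffix cumulative sums give risk-set aggregates at each time
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        d_idx = [k for k in range(i, j) if es[k]]
        d = len(d_idx)
        if d:
            s0 = S0[i]
            s1 = S1[i]
            s2 = S2[i]
            w_d = w[d_idx].sum()
            wx_d = wx[d_idx].sum(axis=0)
            wxx_d = wxx[d_idx].sum(axis=0)
            ll += eta[d_idx].sum()
            grad += Xs[d_idx].sum(axis=0)
            for l in range(d):
                frac = l / d if ties == "efron" else 0.0
                den = s0 - frac * w_d
                num1 = s1 - frac * wx_d
                num2 = s2 - frac * wxx_d
                ll -= np.log(den)
                grad -= num1 / den
                hess -= num2 / den - np.outer(num1, num1) / den**2
        i = j
    return ll, grad, hess


@dataclass
class CoxFit:
    """Wald summary of a Cox proportional-hazards fit."""

    coef: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    loglik: float
    n: int
    n_events: int
    ties: str
    converged: bool
    hr_per5: dict = field(default_factory=dict)  # AAR-style 5-year HR + CI

    def hazard_ratio_per_5y(self, term: str = "aar") -> tuple[float, float, float]:
        """(HR, lo, hi) per 5 units of ``term`` — exp(5(beta +- 1.96 SE))."""
        b, s = self.coef[term], self.se[term]
        return (
            float(np.exp(5 * b)),
            float(np.exp(5 * (b - 1.96 * s))),
            float(np.exp(5 * (b + 1.96 * s))),
        )


def cox_newton(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Newton-Raphson maximization of the Cox partial likelihood.

    Returns (beta, covariance, loglik, converged).  A divergence guard
    flags monotone likelihood (separation) when coefficients run away.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise CoxError("no events: partial likelihood is undefined")
    # center columns for conditioning; coefficients are unaffected
    Xc = X - X.mean(axis=0)
    p = Xc.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik(beta, Xc, time, event, ties)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxError(f"singular information matrix: {exc}") from None
        # step-halving keeps the likelihood monotone
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new, g_new, h_new = _cox_loglik(cand, Xc, time, event, ties)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta, ll, grad, hess = cand, ll_new, g_new, h_new
        if np.abs(beta).max() > 50:
            raise CoxError(
                "divergent coefficients — monotone likelihood (separation?)"
            )
        if np.abs(t * step).max() < tol:
            converged = True
            break
    cov = np.linalg.inv(-hess)
    return beta, cov, float(ll), converged


def cox_score_test(x, time, event, ties: str = "efron") -> float:
    """Score chi-square statistic at beta = 0 for a single covariate.

    For a binary covariate without tied event times this equals the
    classical log-rank chi-square statistic.
    """
    X = np.asarray(x, dtype=float).reshape(-1, 1)
    X = X - X.mean(axis=0)
    _, grad, hess = _cox_loglik(
        np.zeros(1), X, np.asarray(time, float), np.asarray(event, int), ties
    )
    return float(grad @ np.linalg.solve(-hess, grad))


# ---------------------------------------------------------------------------
# phenotype-level wrapper
# ---------------------------------------------------------------------------


def _build_design(df: pd.DataFrame, covariates, adjust_wbc: bool) -> pd.DataFrame:
    cols = {}
    cols["aar"] = df["aar"].astype(float)
    for cov in covariates:
        if cov not in df.columns:
            raise ValueError(f"covariate {cov!r} not in phenotype table")
        series = df[cov]
        if series.dtype.kind in "if":
            cols[cov] = series.astype(float)
        else:
            dummies = pd.get_dummies(series.astype(str), prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].astype(float)
    if adjust_wbc:
        for c in WBC_COLUMNS:
            if c not in df.columns:
                raise ValueError(f"WBC adjustment requested but {c!r} missing")
            cols[c] = df[c].astype(float)
    design = pd.DataFrame(cols, index=df.index)
    # numerically-constant columns (e.g. AAR from a fully-shrunk clock)
    const = [c for c in design.columns if design[c].std() <= 1e-9]
    if "aar" in const:
        raise ValueError(
            "AAR has zero variance (a perfect clock yields AAR identically 0); "
            "no association can be estimated"
        )
    if const:
        logger.warning("dropping constant covariate columns: %s", const)
        design = design.drop(columns=const)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("covariate design is rank deficient after one-hot encoding")
    return design


DEFAULT_COX_COVARIATES = ("age", "sex") + TECHNICAL_COLUMNS


def fit_cox(
    pheno: pd.DataFrame,
    aar: pd.DataFrame,
    covariates=DEFAULT_COX_COVARIATES,
    adjust_wbc: bool = False,
    ties: str = "efron",
) -> CoxFit:
    """Cox model of mortality on AAR plus covariates.

    Technical covariates (plate, array, position, hybridization date) and
    sex enter as one-hot fixed-effect factors; ``adjust_wbc`` additionally
    includes the five measured white-blood-cell counts (the sensitivity
    analysis for cell-composition confounding).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    df = pheno.set_index("sample_id") if "sample_id" in pheno.columns else pheno.copy()
    df = df.join(aar[["aar"]], how="inner")
    if df["aar"].isna().any():
        raise ValueError("AAR missing for some samples")
    for col in ("surv_time", "event"):
        if col not in df.columns:
            raise ValueError(f"phenotype table lacks {col!r}")
    covariates = [c for c in covariates if c in df.columns]
    design = _build_design(df, covariates, adjust_wbc)
    time = df["surv_time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    beta, cov, ll, converged = cox_newton(design.to_numpy(), time, event, ties=ties)
    se = np.sqrt(np.diag(cov))
    coef = pd.Series(beta, index=design.columns)
    se_s = pd.Series(se, index=design.columns)
    z = coef / se_s
    pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=design.columns)
    fit = CoxFit(
        coef=coef,
        se=se_s,
        z=z,
        p=pvals,
        loglik=ll,
        n=len(df),
        n_events=int(event.sum()),
        ties=ties,
        converged=converged,
    )
    hr, lo, hi = fit.hazard_ratio_per_5y("aar")
    fit.hr_per5 = {"hr": hr, "ci_low": lo, "ci_high": hi}
    return fit


# ---------------------------------------------------------------------------
# attenuation experiment
# ---------------------------------------------------------------------------


def attenuation_experiment(
    matrix: MethylationMatrix,
    pheno: pd.DataFrame,
    design: TrainingDesign,
    survival_cohort: str,
    method: str = "enet",
    covariates=("age", "sex"),
    transform=None,
    seed: int = 0,
    ties: str = "efron",
    predictors=None,
    **train_kwargs,
) -> pd.DataFrame:
    """AAR-mortality z statistics across training sizes.

    For each design entry (which must not contain the survival cohort), a
    clock is trained, AAR is computed on the survival cohort, and the Cox
    z statistic for AAR is recorded before and after WBC adjustment.
    """
    if any(survival_cohort in e.train_cohorts for e in design):
        raise ValueError("the survival cohort must be excluded from all training sets")
    ages = pheno.set_index("sample_id")["age"] if "sample_id" in pheno.columns else pheno["age"]
    surv_m = matrix.subset_cohorts([survival_cohort])
    surv_ages = ages.loc[surv_m.sample_ids]
    rows = []
    for i, entry in enumerate(design):
        pred = (
            predictors[i]
            if predictors is not None
            else _train_for_entry(
                matrix, ages, entry, method, transform=transform, seed=seed,
                **train_kwargs,
            )
        )
        yhat = pred.predict(surv_m)
        aar = compute_aar(yhat, surv_ages, sample_ids=surv_m.sample_ids)
        row = {
            "method": method,
            "size": entry.size,
            "replicate": entry.replicate,
            "n_train": pred.n_train,
            "z_aar": np.nan,
            "z_aar_wbc_adjusted": np.nan,
            "hr_per5": np.nan,
            "hr_per5_ci_low": np.nan,
            "hr_per5_ci_high": np.nan,
            "n_events": np.nan,
        }
        try:
            fit = fit_cox(pheno, aar, covariates=covariates, adjust_wbc=False, ties=ties)
            fit_w = fit_cox(pheno, aar, covariates=covariates, adjust_wbc=True, ties=ties)
        except (ValueError, CoxError) as exc:
            # a fully-shrunk clock yields constant AAR: no association is
            # estimable for this entry
            logger.warning("attenuation entry size=%d rep=%d skipped: %s",
                           entry.size, entry.replicate, exc)
        else:
            row.update(
                z_aar=float(fit.z["aar"]),
                z_aar_wbc_adjusted=float(fit_w.z["aar"]),
                hr_per5=fit.hr_per5["hr"],
                hr_per5_ci_low=fit.hr_per5["ci_low"],
                hr_per5_ci_high=fit.hr_per5["ci_high"],
                n_events=fit.n_events,
            )
        rows.append(row)
    return pd.DataFrame(rows)
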