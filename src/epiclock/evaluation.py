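"""Scoring of age clocks and training-size curves.

Two accuracy measures are reported for every (clock, test cohort) pair:
the root mean square error between predicted and chronological age, and
the Pearson correlation.  Correlation on a constant vector is reported as
undefined (NaN with a flag) rather than silently coerced to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .clocks import TrainingDesign, train_blup, train_enet
from .io import MethylationMatrix

logger = logging.getLogger("epiclock")

#: RMSE above which points are conventionally excluded *from plots*;
#: statistics always use every point.
RMSE_PLOT_EXCLUSION = 15.0


@dataclass
class EvalResult:
    rmse: float
    pearson_r: float  # NaN when undefined
    r_undefined: bool
    n: int
    mean_predicted: float
    mean_chronological: float


def score(predicted, chronological) -> EvalResult:
    """RMSE and Pearson correlation of predicted vs chronological age."""
    yhat = np.asarray(predicted, dtype=float).ravel()
    y = np.asarray(chronological, dtype=float).ravel()
    if len(yhat) != len(y):
        raise ValueError("length mismatch between predicted and chronological age")
    if len(y) < 2:
        raise ValueError("need at least 2 samples to score")
    rmse = float(np.sqrt(np.mean((yhat - y) ** 2)))
    undefined = yhat.std() == 0 or y.std() == 0
    if undefined:
        r = float("nan")
    else:
        r = float(np.corrcoef(yhat, y)[0, 1])
    return EvalResult(
        rmse=rmse,
        pearson_r=r,
        r_undefined=bool(undefined),
        n=len(y),
        mean_predicted=float(yhat.mean()),
        mean_chronological=float(y.mean()),
    )


def _train_for_entry(matrix, ages, entry, method, transform=None, seed=0, **kwargs):
    train_m = matrix.subset_cohorts(entry.train_cohorts)
    train_y = ages.loc[train_m.sample_ids]
    if method == "blup":
        return train_blup(train_m, train_y, transform=transform, **kwargs)
    if method == "enet":
        return train_enet(train_m, train_y, transform=transform, seed=seed, **kwargs)
    raise ValueError(f"unknown method {method!r}")


def train_design(
    matrix: MethylationMatrix,
    pheno: pd.DataFrame,
    design: TrainingDesign,
    method: str = "enet",
    transform=None,
    seed: int = 0,
    **train_kwargs,
) -> list:
    """One trained clock per design entry (reusable across experiments)."""
    ages = pheno.set_index("sample_id")["age"] if "sample_id" in pheno.columns else pheno["age"]
    return [
        _train_for_entry(
            matrix, ages, entry, method, transform=transform, seed=seed, **train_kwargs
        )
        for entry in design
    ]


def size_curve(
    matrix: MethylationMatrix,
    pheno: pd.DataFrame,
    design: TrainingDesign,
    method: str = "enet",
    transform=None,
    seed: int = 0,
    predictors=None,
    **train_kwargs,
) -> pd.DataFrame:
    """Train one clock per design entry and score it on each test cohort.

    Returns one row per (entry, test cohort) with the design factors used
    downstream by :func:`factor_regression`: training-set size, the
    absolute train/test mean-age difference, and the training-age SD.
    The ``plot_excluded`` column mirrors the display convention of
    dropping points with RMSE > 15 from figures; it never affects any
    computed statistic.
    """
    ages = pheno.set_index("sample_id")["age"] if "sample_id" in pheno.columns else pheno["age"]
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
        train_ages = ages.loc[matrix.subset_cohorts(entry.train_cohorts).sample_ids]
        for test_cohort in entry.test_cohorts:
            test_m = matrix.subset_cohorts([test_cohort])
            yhat = pred.predict(test_m)
            y = ages.loc[test_m.sample_ids]
            res = score(yhat, y)
            rows.append(
                {
                    "method": method,
                    "size": entry.size,
                    "replicate": entry.replicate,
                    "test_cohort": test_cohort,
                    "n_train": pred.n_train,
                    "n_test": res.n,
                    "rmse": res.rmse,
                    "pearson_r": res.pearson_r,
                    "r_undefined": res.r_undefined,
                    "mean_predicted": res.mean_predicted,
                    "mean_chronological": res.mean_chronological,
                    "age_diff": abs(train_ages.mean() - y.mean()),
                    "train_age_sd": float(train_ages.std()),
                    "plot_excluded": res.rmse > RMSE_PLOT_EXCLUSION,
                }
            )
    return pd.DataFrame(rows)


def factor_regression(results: pd.DataFrame, responses=("rmse", "pearson_r")) -> pd.DataFrame:
    """OLS of accuracy on training size, train/test age gap and training-age SD.

    Returns a coefficient table (one row per response x factor) with SEs,
    t statistics and p values; a collinear design is flagged rather than
    silently dropped.
    """
    if len(results) < 10:
        raise ValueError("need at least 10 evaluation rows")
    factors = ["n_train", "age_diff", "train_age_sd"]
    X = sm.add_constant(results[factors].astype(float))
    rows = []
    rank = np.linalg.matrix_rank(X.to_numpy())
    collinear = rank < X.shape[1]
    if collinear:
        logger.warning("factor_regression: design matrix is collinear")
    for resp in responses:
        y = results[resp].astype(float)
        ok = y.notna()
        fit = sm.OLS(y[ok], X[ok]).fit()
        for name in X.columns:
            rows.append(
                {
                    "response": resp,
                    "factor": name,
                    "coef": fit.params[name],
                    "se": fit.bse[name],
                    "t": fit.tvalues[name],
                    "p": fit.pvalues[name],
                    "collinear": collinear,
                }
            )
    return pd.DataFrame(rows)
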