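"""Training of linear age clocks from methylation beta values.

Two estimators are provided, matching the two classic routes to a
methylation clock:

* **BLUP** — all probes get a (shrunken) nonzero weight.  The probe
  effects solve the ridge system ``u = Z'(ZZ' + (m se2/su2) I)^{-1} y_c``,
  i.e. the mixed-model best linear unbiased predictions when the variance
  ratio comes from a REML fit on the training data.  The n x n dual system
  is solved (n << m in every regime of interest) and back-substituted to
  probe effects.
* **Elastic Net** — sparse selection by coordinate descent, with the
  penalty weight chosen by k-fold cross-validation under the minimum-MSE
  rule.  The mixing parameter defaults to alpha = 0.5.

Training standardization statistics (per-probe mean and sample SD) are
computed on the training data only and stored inside the predictor, which
makes the clock portable and leak-free by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning  # noqa: F401  (silenced in train_enet)
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .io import AgePredictor, MethylationMatrix, TransformSpec
from .varcomp import VarCompFit, compute_orm, reml_fit

logger = logging.getLogger("epiclock")

__all__ = [
    "TransformSpec",
    "TrainingDesign",
    "DesignEntry",
    "make_training_design",
    "apply_transform",
    "power_lambda_grid",
    "train_blup",
    "train_enet",
    "prune_probes",
]


# ---------------------------------------------------------------------------
# training designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignEntry:
    train_cohorts: tuple[str, ...]
    test_cohorts: tuple[str, ...]
    size: int
    replicate: int

    def __post_init__(self):
        if set(self.train_cohorts) & set(self.test_cohorts):
            raise ValueError("train and test cohorts overlap")


@dataclass
class TrainingDesign:
    entries: list[DesignEntry]
    cohorts: tuple[str, ...]
    n_replicates: int
    seed: int

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


def make_training_design(cohorts, n_replicates: int, seed: int = 0) -> TrainingDesign:
    """Random cohort-level train/test splits of every size 1..C-1.

    For each training-set size k, ``n_replicates`` draws of k cohorts are
    sampled uniformly without replacement; the unselected cohorts form the
    test set.  With 14 cohorts and 5 replicates this yields the classic
    65 = 13 x 5 training sets.
    """
    cohorts = tuple(cohorts)
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    entries = []
    for size in range(1, len(cohorts)):
        for rep in range(n_replicates):
            train = tuple(
                sorted(rng.choice(len(cohorts), size=size, replace=False))
            )
            train_names = tuple(cohorts[i] for i in train)
            test_names = tuple(c for c in cohorts if c not in train_names)
            entries.append(DesignEntry(train_names, test_names, size, rep))
    return TrainingDesign(entries, cohorts, n_replicates, seed)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def apply_transform(matrix, spec: TransformSpec):
    """Transform a beta matrix (MethylationMatrix, DataFrame or ndarray)."""
    if isinstance(matrix, MethylationMatrix):
        return spec.apply(matrix.beta)
    return spec.apply(matrix)


def power_lambda_grid() -> np.ndarray:
    """The conventional power-transform search grid: 0.1 to 2, step 0.05."""
    return np.round(np.arange(0.1, 2.0 + 1e-9, 0.05), 10)


# ---------------------------------------------------------------------------
# shared standardization
# ---------------------------------------------------------------------------


def _standardized_training(matrix, ages, transform):
    """Returns (Z ndarray, y, probe index, mean, sd) on training data only."""
    if isinstance(matrix, MethylationMatrix):
        values = matrix.beta
    else:
        values = pd.DataFrame(matrix)
    transform = transform or TransformSpec()
    values = transform.apply(values)
    y = np.asarray(ages, dtype=float).ravel()
    if len(y) != values.shape[0]:
        raise ValueError("ages and matrix rows do not match")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d zero-variance probes before training", n_dropped)
    values = values.loc[:, keep]
    mean, sd = mean[keep], sd[keep]
    z = (values - mean) / sd
    return z.to_numpy(), y, values.columns, mean, sd, transform


# ---------------------------------------------------------------------------
# BLUP
# ---------------------------------------------------------------------------


def train_blup(
    matrix,
    ages,
    varcomp: VarCompFit | None = None,
    variance_ratio: float | None = None,
    transform: TransformSpec | None = None,
) -> AgePredictor:
    """BLUP age clock: shrunken effects for every probe.

    The shrinkage strength is the ridge penalty ``m * se2 / su2``.  The
    variance ratio su2/se2 is taken from ``varcomp`` or ``variance_ratio``
    when supplied, otherwise estimated by REML on the training data.
    A zero (or boundary-zero) su2 collapses the clock to the training mean
    age, with a warning.
    """
    z, y, probes, mean, sd, transform = _standardized_training(matrix, ages, transform)
    n, m = z.shape
    if variance_ratio is None:
        if varcomp is None:
            varcomp = reml_fit(compute_orm(pd.DataFrame(z, columns=probes)), y)
        variance_ratio = varcomp.variance_ratio

    intercept = float(y.mean())
    yc = y - intercept
    if variance_ratio <= 0 or not np.isfinite(variance_ratio):
        if variance_ratio <= 0:
            logger.warning("train_blup: sigma2_u = 0; predictor is the mean age")
            weights = np.zeros(m)
        else:  # infinite ratio: no shrinkage beyond the dual system itself
            weights = z.T @ np.linalg.solve(z @ z.T + 1e-10 * np.eye(n), yc)
    else:
        lam = m / variance_ratio  # = m * se2 / su2
        weights = z.T @ np.linalg.solve(z @ z.T + lam * np.eye(n), yc)

    return AgePredictor(
        method="blup",
        intercept=intercept,
        weights=pd.Series(weights, index=probes),
        train_mean=mean,
        train_sd=sd,
        n_train=n,
        transform=transform,
        meta={"variance_ratio": float(variance_ratio)},
    )


# ---------------------------------------------------------------------------
# Elastic Net
# ---------------------------------------------------------------------------


def train_enet(
    matrix,
    ages,
    alpha: float = 0.5,
    lambda_penalty: float | None = None,
    lambda_grid=None,
    cv: int = 10,
    seed: int = 0,
    max_iter: int = 5000,
    tol: float = 1e-4,
    transform: TransformSpec | None = None,
) -> AgePredictor:
    """Elastic Net age clock on the standardized training matrix.

    Minimizes ``(1/2n)||y - a - Z b||^2 + lam (alpha ||b||_1 +
    (1-alpha)/2 ||b||_2^2)``.  When ``lambda_penalty`` is not given, the
    penalty is chosen by k-fold cross-validation (shuffled folds, fixed
    seed) under the minimum mean-squared-error rule.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    z, y, probes, mean, sd, transform = _standardized_training(matrix, ages, transform)
    n = z.shape[0]
    meta: dict = {"alpha": alpha, "cv_folds": None, "cv_seed": seed}

    import warnings

    with warnings.catch_warnings():
        # l1_ratio=0 (pure ridge) is a supported corner of the coordinate
        # descent path but sklearn advertises it loudly
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        if lambda_penalty is not None:
            model = ElasticNet(
                alpha=lambda_penalty, l1_ratio=alpha, max_iter=max_iter, tol=tol
            )
            model.fit(z, y)
            lam = float(lambda_penalty)
        else:
            if n < cv:
                raise ValueError(f"fewer samples ({n}) than CV folds ({cv})")
            folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
            cv_kwargs = {} if lambda_grid is None else {"alphas": lambda_grid}
            model = ElasticNetCV(
                l1_ratio=alpha,
                cv=folds,
                max_iter=max_iter,
                tol=tol,
                **cv_kwargs,
            )
            model.fit(z, y)
            lam = float(model.alpha_)
            meta["cv_folds"] = cv

    weights = pd.Series(model.coef_, index=probes)
    meta.update({"lambda_penalty": lam, "n_selected": int((weights != 0).sum())})
    return AgePredictor(
        method="enet",
        intercept=float(model.intercept_),
        weights=weights,
        train_mean=mean,
        train_sd=sd,
        n_train=n,
        transform=transform,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# correlation pruning
# ---------------------------------------------------------------------------


def prune_probes(
    matrix,
    r2_threshold: float = 0.2,
    window: int = 500,
) -> list:
    """Greedy windowed correlation pruning of probes.

    Probes are scanned in column order; a probe is dropped when its squared
    correlation with any *retained* probe within the trailing ``window``
    positions exceeds ``r2_threshold``.  Deterministic given the ordering.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must lie in (0, 1]")
    if window < 1:
        raise ValueError("window must be >= 1")
    if isinstance(matrix, MethylationMatrix):
        values = matrix.beta
    else:
        values = pd.DataFrame(matrix)
    x = values.to_numpy(dtype=float)
    n, m = x.shape
    sd = x.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (x - x.mean(axis=0)) / sd_safe
    kept: list[int] = []
    kept_z: list[np.ndarray] = []
    for j in range(m):
        if sd[j] == 0:
            continue
        zj = z[:, j]
        lo = j - window
        conflict = False
        for idx, kz in zip(reversed(kept), reversed(kept_z)):
            if idx < lo:
                break
            r = float(kz @ zj) / (n - 1)
            if r * r > r2_threshold:
                conflict = True
                break
        if not conflict:
            kept.append(j)
            kept_z.append(zj)
    return [values.columns[j] for j in kept]
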