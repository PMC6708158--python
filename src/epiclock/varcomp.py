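"""REML estimation of the age variance fraction captured by methylation.

The model is the standard single-component mixed model used to estimate
how much phenotypic variance all probes explain jointly:

    y = W b + g + e,   g ~ N(0, K su2),   e ~ N(0, I se2)

where ``K = Z Z' / m`` is the omics relationship matrix built from the
column-standardized beta matrix Z, ``W`` holds the fixed effects (always
including an intercept), and the quantity of interest is

    rho2 = su2 / (su2 + se2).

The restricted likelihood is maximized exactly: the fixed effects are
projected out by an orthonormal rotation, ``K`` is eigendecomposed once,
and the likelihood — profiled over the total variance — is optimized over
``rho2`` in [0, 1] by bounded Brent search.  This is robust at the
boundaries (rho2 = 0 or 1), which real methylation data does reach.
Standard errors come from the Fisher information in (su2, se2) with the
delta method; estimates at a boundary are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh, null_space
from scipy.optimize import minimize_scalar

from .io import MethylationMatrix

logger = logging.getLogger("epiclock")

_BOUNDARY_TOL = 1e-6


@dataclass
class RelationshipMatrix:
    """n x n similarity matrix K = ZZ'/m from standardized probe values."""

    values: np.ndarray
    sample_ids: list[str]
    m_probes: int

    def __post_init__(self):
        K = self.values
        if K.shape[0] != K.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class VarCompFit:
    """REML estimates for the single-component model."""

    sigma2_u: float
    sigma2_e: float
    rho2: float
    se_rho2: float
    loglik: float
    converged: bool
    boundary: bool
    n: int
    m: int

    @property
    def variance_ratio(self) -> float:
        """su2 / se2; infinite at the rho2 = 1 boundary."""
        if self.sigma2_e <= 0:
            return np.inf
        return self.sigma2_u / self.sigma2_e


def standardize_columns(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize (mean 0, sample SD 1); returns (Z, keep_mask).

    Zero-variance columns cannot be standardized and are dropped.
    Sample SD (n-1 denominator) is the convention throughout.
    """
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    keep = sd > 0
    z = (values[:, keep] - mean[keep]) / sd[keep]
    return z, keep


def compute_orm(matrix: MethylationMatrix | pd.DataFrame | np.ndarray) -> RelationshipMatrix:
    """Omics relationship matrix K = ZZ'/m from a beta matrix.

    Probes with zero variance are dropped (with a warning) and ``m`` is
    updated accordingly.
    """
    if isinstance(matrix, MethylationMatrix):
        values = matrix.beta.to_numpy(dtype=float)
        ids = matrix.sample_ids
    elif isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
        ids = list(matrix.index)
    else:
        values = np.asarray(matrix, dtype=float)
        ids = [str(i) for i in range(values.shape[0])]
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for a relationship matrix")
    z, keep = standardize_columns(values)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("compute_orm: dropped %d zero-variance probes", n_dropped)
    m = z.shape[1]
    if m == 0:
        raise ValueError("all probes have zero variance")
    K = (z @ z.T) / m
    K = (K + K.T) / 2.0
    return RelationshipMatrix(K, ids, m)


def _rotate(K: np.ndarray, y: np.ndarray, covariates: np.ndarray | None):
    """Project fixed effects out and diagonalize: returns (d, zstar, nstar)."""
    n = len(y)
    W = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        W = np.column_stack([W, C])
    A = null_space(W.T)  # n x (n - p), orthonormal, A'W = 0
    M = A.T @ K @ A
    M = (M + M.T) / 2.0
    d, U = eigh(M)
    d = np.clip(d, 0.0, None)
    zstar = U.T @ (A.T @ y)
    return d, zstar, A.shape[1]


def _neg_profiled_reml(rho2, d, z2, nstar):
    v = rho2 * d + (1.0 - rho2)
    if np.any(v <= 0):
        return np.inf
    sp2 = float(np.sum(z2 / v) / nstar)
    if sp2 <= 0:
        return np.inf
    ll = -0.5 * (
        np.sum(np.log(v)) + nstar * np.log(sp2) + nstar * (1.0 + np.log(2 * np.pi))
    )
    return -ll


def reml_fit(
    K: RelationshipMatrix | np.ndarray,
    y,
    covariates=None,
) -> VarCompFit:
    """Single-component REML fit of y on a relationship matrix.

    ``covariates`` is an optional n x q design of extra fixed effects; an
    intercept is always included.  Returns variance components, rho2 with
    a delta-method SE, and the restricted log-likelihood at the optimum.
    """
    if isinstance(K, RelationshipMatrix):
        Kv, m = K.values, K.m_probes
    else:
        Kv, m = np.asarray(K, dtype=float), 0
    y = np.asarray(y, dtype=float).ravel()
    if Kv.shape[0] != len(y):
        raise ValueError("K and y dimensions do not match")
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")
    if y.std() == 0:
        raise ValueError("phenotype has no variance")

    d, zstar, nstar = _rotate(Kv, y, covariates)
    z2 = zstar**2

    res = minimize_scalar(
        _neg_profiled_reml,
        bounds=(0.0, 1.0),
        args=(d, z2, nstar),
        method="bounded",
        options={"xatol": 1e-12},
    )
    candidates = [(res.x, res.fun)]
    for r_edge in (0.0, 1.0 - 1e-12):
        candidates.append((r_edge, _neg_profiled_reml(r_edge, d, z2, nstar)))
    rho2_hat, negll = min(candidates, key=lambda c: c[1])
    if not np.isfinite(negll):
        raise ValueError("restricted likelihood is non-finite at the optimum")
    rho2_hat = float(np.clip(rho2_hat, 0.0, 1.0))

    v = rho2_hat * d + (1.0 - rho2_hat)
    sp2 = float(np.sum(z2 / v) / nstar)
    sigma2_u = rho2_hat * sp2
    sigma2_e = (1.0 - rho2_hat) * sp2
    boundary = rho2_hat < _BOUNDARY_TOL or rho2_hat > 1.0 - _BOUNDARY_TOL

    # Fisher information in (su2, se2) at the (possibly constrained) optimum
    vfull = sigma2_u * d + sigma2_e
    vfull = np.maximum(vfull, 1e-300)
    i_uu = 0.5 * np.sum(d**2 / vfull**2)
    i_ue = 0.5 * np.sum(d / vfull**2)
    i_ee = 0.5 * np.sum(1.0 / vfull**2)
    info = np.array([[i_uu, i_ue], [i_ue, i_ee]])
    cov = np.linalg.pinv(info)
    total = sigma2_u + sigma2_e
    grad = np.array([sigma2_e, -sigma2_u]) / total**2
    var_rho2 = float(grad @ cov @ grad)
    se_rho2 = float(np.sqrt(max(var_rho2, 0.0)))
    if boundary:
        logger.info("reml_fit: estimate at boundary (rho2=%.4f)", rho2_hat)

    return VarCompFit(
        sigma2_u=float(sigma2_u),
        sigma2_e=float(sigma2_e),
        rho2=rho2_hat,
        se_rho2=se_rho2,
        loglik=float(-negll),
        converged=bool(res.success or boundary),
        boundary=bool(boundary),
        n=len(y),
        m=m,
    )


@dataclass
class PermutationResult:
    observed_rho2: float
    null_rho2: np.ndarray
    p_value: float
    n_perm: int


def permutation_test(
    K: RelationshipMatrix | np.ndarray,
    y,
    n_perm: int,
    seed: int = 0,
    covariates=None,
) -> PermutationResult:
    """Permutation null for rho2: shuffle ages across individuals and refit.

    The empirical p-value is (1 + #{rho2_perm >= rho2_obs}) / (n_perm + 1),
    so the smallest attainable p is 1 / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float).ravel()
    observed = reml_fit(K, y, covariates=covariates).rho2
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = reml_fit(K, rng.permutation(y), covariates=covariates).rho2
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return PermutationResult(observed, null, float(p), n_perm)
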