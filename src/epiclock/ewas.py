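"""Per-probe association of methylation with AAR, and cell-heterogeneity
enrichment of the hits.

The scan regresses each probe's beta value on the age-acceleration
residual (simple linear regression with intercept; two-sided p from the
t distribution with n-2 degrees of freedom) and applies a Bonferroni
threshold of 0.05 divided by the number of probes actually tested.  The
genomic-inflation factor lambda_median — the median observed chi-square
over its null median — summarizes systematic inflation of the scan.

Enrichment of the significant probes in a designated cellular-
heterogeneity probe set uses Fisher's exact test; the odds ratio is the
conditional maximum-likelihood estimate with an exact confidence
interval (the convention of mainstream exact-test routines), and the
plain sample cross-product ratio is also reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .clocks import TrainingDesign
from .evaluation import _train_for_entry
from .io import MethylationMatrix
from .survival import compute_aar

logger = logging.getLogger("epiclock")

_CHI2_NULL_MEDIAN = stats.chi2.ppf(0.5, 1)  # ~0.4549


# ---------------------------------------------------------------------------
# EWAS scan
# ---------------------------------------------------------------------------


def ewas_scan(matrix: MethylationMatrix | pd.DataFrame, aar) -> pd.DataFrame:
    """Probe-by-probe regression of beta on AAR.

    Returns a table (probe_id, slope, se, t, p, significant) whose attrs
    carry n_tested, the Bonferroni threshold, lambda_median and the count
    of zero-variance probes skipped.
    """
    beta = matrix.beta if isinstance(matrix, MethylationMatrix) else matrix
    if isinstance(aar, pd.DataFrame):
        aar = aar["aar"]
    if isinstance(aar, pd.Series):
        aar = aar.reindex(beta.index)
        if aar.isna().any():
            raise ValueError("AAR missing for some samples in the matrix")
    x = np.asarray(aar, dtype=float).ravel()
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples for an EWAS scan")
    if x.std() == 0:
        raise ValueError("AAR is constant; per-probe association undefined")

    Y = beta.to_numpy(dtype=float)
    syy = Y.var(axis=0) * n  # total sum of squares per probe
    tested = syy > 0
    n_skipped = int((~tested).sum())
    if n_skipped:
        logger.warning("ewas_scan: skipped %d zero-variance probes", n_skipped)
    Yt = Y[:, tested]
    xc = x - x.mean()
    sxx = float(xc @ xc)
    sxy = xc @ (Yt - Yt.mean(axis=0))
    slope = sxy / sxx
    rss = (Yt.var(axis=0) * n) - slope**2 * sxx
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(np.maximum(sigma2 / sxx, 1e-300))
    tstat = slope / se
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.maximum(p, np.finfo(float).tiny)  # keep p in (0, 1]

    m_tested = int(tested.sum())
    threshold = 0.05 / m_tested
    out = pd.DataFrame(
        {
            "slope": slope,
            "se": se,
            "t": tstat,
            "p": p,
            "significant": p < threshold,
        },
        index=pd.Index(beta.columns[tested], name="probe_id"),
    )
    out.attrs.update(
        {
            "n_samples": n,
            "n_tested": m_tested,
            "n_skipped": n_skipped,
            "bonferroni_threshold": threshold,
            "lambda_median": float(np.median(tstat**2) / _CHI2_NULL_MEDIAN),
        }
    )
    return out


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    """2x2 enrichment of significant probes in the heterogeneity set.

    Table layout: rows = (significant, not significant), columns =
    (heterogeneity, not heterogeneity).
    """

    table: np.ndarray
    odds_ratio: float  # conditional MLE
    ci_low: float
    ci_high: float
    p_value: float
    sample_odds_ratio: float
    sample_odds_ratio_corrected: float  # Haldane-Anscombe (+0.5), always finite
    n_tested: int
    n_dropped_het: int = 0

    @property
    def significant_in_het(self) -> int:
        return int(self.table[0, 0])


def fisher_enrichment(ewas: pd.DataFrame, het_probes) -> EnrichmentResult:
    """Fisher's exact test for enrichment of EWAS hits among heterogeneity probes.

    Heterogeneity probes not present among the tested probes are dropped
    (and counted).  The two-sided p sums hypergeometric probabilities of
    tables as or less probable than the observed one.
    """
    tested = set(ewas.index)
    het = set(het_probes)
    dropped = het - tested
    if dropped:
        logger.warning(
            "fisher_enrichment: %d heterogeneity probes not tested, dropped",
            len(dropped),
        )
    het &= tested
    sig = set(ewas.index[ewas["significant"]])
    a = len(sig & het)
    b = len(sig - het)
    c = len(het - sig)
    d = len(tested) - a - b - c
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError(f"degenerate 2x2 table with an empty margin: {table.tolist()}")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    orr = _odds_ratio(table, kind="conditional")
    ci = orr.confidence_interval(confidence_level=0.95)
    with np.errstate(divide="ignore", invalid="ignore"):
        sample_or = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    corrected = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return EnrichmentResult(
        table=table,
        odds_ratio=float(orr.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=float(p),
        sample_odds_ratio=float(sample_or),
        sample_odds_ratio_corrected=float(corrected),
        n_tested=len(tested),
        n_dropped_het=len(dropped),
    )


# ---------------------------------------------------------------------------
# enrichment across training sizes
# ---------------------------------------------------------------------------


def enrichment_vs_size(
    matrix: MethylationMatrix,
    pheno: pd.DataFrame,
    design: TrainingDesign,
    het_probes,
    ewas_cohort: str,
    method: str = "enet",
    transform=None,
    seed: int = 0,
    predictors=None,
    **train_kwargs,
) -> pd.DataFrame:
    """Enrichment odds ratio as a function of training-set size.

    For each design entry (which must exclude the EWAS cohort) a clock is
    trained, AAR is computed on the EWAS cohort, the scan is run on that
    cohort's matrix and the hits are tested for heterogeneity enrichment.
    Entries whose scan yields no significant probe produce a degenerate
    table; they are reported with odds_ratio NaN, CI (0, inf) and p = 1.
    """
    if any(ewas_cohort in e.train_cohorts for e in design):
        raise ValueError("the EWAS cohort must be excluded from all training sets")
    ages = pheno.set_index("sample_id")["age"] if "sample_id" in pheno.columns else pheno["age"]
    ewas_m = matrix.subset_cohorts([ewas_cohort])
    ewas_ages = ages.loc[ewas_m.sample_ids]
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
        yhat = pred.predict(ewas_m)
        aar = compute_aar(yhat, ewas_ages, sample_ids=ewas_m.sample_ids)
        if aar["aar"].std() <= 1e-9:
            # fully-shrunk clock: constant AAR, nothing to scan
            n_het = len(set(het_probes) & set(ewas_m.beta.columns))
            rows.append(
                {
                    "method": method,
                    "size": entry.size,
                    "replicate": entry.replicate,
                    "n_train": pred.n_train,
                    "n_significant": 0,
                    "sig_het": 0,
                    "sig_nonhet": 0,
                    "nonsig_het": n_het,
                    "nonsig_nonhet": ewas_m.n_probes - n_het,
                    "lambda_median": np.nan,
                    "odds_ratio": np.nan,
                    "odds_ratio_corrected": np.nan,
                    "ci_low": 0.0,
                    "ci_high": np.inf,
                    "p": 1.0,
                }
            )
            continue
        scan = ewas_scan(ewas_m, aar)
        n_sig = int(scan["significant"].sum())
        het = set(het_probes) & set(scan.index)
        sig = set(scan.index[scan["significant"]])
        a = len(sig & het)
        row = {
            "method": method,
            "size": entry.size,
            "replicate": entry.replicate,
            "n_train": pred.n_train,
            "n_significant": n_sig,
            "sig_het": a,
            "sig_nonhet": n_sig - a,
            "nonsig_het": len(het) - a,
            "nonsig_nonhet": len(scan) - len(het) - (n_sig - a),
            "lambda_median": scan.attrs["lambda_median"],
        }
        try:
            enr = fisher_enrichment(scan, het_probes)
            row.update(
                odds_ratio=enr.odds_ratio,
                odds_ratio_corrected=enr.sample_odds_ratio_corrected,
                ci_low=enr.ci_low,
                ci_high=enr.ci_high,
                p=enr.p_value,
            )
        except ValueError:
            # no hits (or all hits): the exact test is undefined, and there
            # is trivially no evidence of enrichment
            row.update(
                odds_ratio=np.nan, odds_ratio_corrected=np.nan,
                ci_low=0.0, ci_high=np.inf, p=1.0,
            )
        rows.append(row)
    return pd.DataFrame(rows)
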