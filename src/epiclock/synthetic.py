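"""Simulation of multi-cohort DNA methylation worlds with known ground truth.

The generator emulates the structure of a multi-cohort blood-methylation
study of chronological age:

* several cohorts with distinct age ranges and sample sizes;
* a minority of *causal* probes whose (logit-scale) methylation tracks age,
  with the aggregate signal calibrated so that the realized fraction of age
  variance captured by methylation hits a configurable target ``rho2``;
* five blood cell types whose per-sample proportions vary between
  individuals, optionally drift with age (the confounding channel), shift
  methylation at a designated *heterogeneity* probe subset, and raise or
  lower the mortality hazard;
* cohort-level batch effects and iid measurement noise, both on the logit
  scale so beta values stay inside (0, 1) without hard clipping;
* a survival process whose log hazard is linear in age and in the
  deviation of a chosen cell-type proportion, with administrative
  censoring plus uniform early dropout.

Because effects are added on the logit scale and inverse-transformed, the
generated betas are valid by construction and the age signal survives the
transform essentially linearly at the calibrated effect sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io import (
    WBC_COLUMNS,
    MethylationMatrix,
    _read_table,
    _write_table,
    validate_phenotypes,
)

logger = logging.getLogger("epiclock")


class ConfigError(ValueError):
    """Raised for an inconsistent simulation configuration."""


# default cohort layout: six cohorts whose sizes and age ranges echo the
# typical composition of large blood-methylation consortia — two narrow
# elderly birth cohorts, one young/wide family study, and three broad
# adult case-control or population cohorts.
_DEFAULT_N = (60, 240, 70, 160, 70, 300)
_DEFAULT_RANGES = (
    (77.8, 90.6),
    (67.7, 77.7),
    (9.9, 74.9),
    (23.0, 104.0),
    (17.0, 76.0),
    (18.0, 94.5),
)

# baseline log-abundance of the five WBC types (basophils, eosinophils,
# monocytes, lymphocytes, neutrophils) — roughly 0.5/2.5/8/33/56 percent.
_CELL_BASE_LOGW = np.log(np.array([0.005, 0.025, 0.08, 0.33, 0.56]))
# direction of the age drift in cell composition: with age, neutrophil and
# monocyte fractions rise while the lymphocyte fraction falls.
_CELL_AGE_DIRECTION = np.array([0.0, 0.0, 0.2, -0.8, 0.5])


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a simulated methylation world.

    The defaults describe the reference world used throughout the test
    suite: six cohorts (900 samples), 2000 probes of which 200 are causal
    for age, a high but imperfect joint age signal (rho2 = 0.9), moderate
    age-composition confounding and a composition effect on mortality.
    """

    n_samples: tuple[int, ...] = _DEFAULT_N
    age_ranges: tuple[tuple[float, float], ...] = _DEFAULT_RANGES
    cohort_names: tuple[str, ...] | None = None
    n_probes: int = 2000
    n_causal: int = 200
    target_rho2: float = 0.9
    n_celltypes: int = 5
    heterogeneity_fraction: float = 0.23
    celltype_effect_sd: float = 0.8
    confounding_strength: float = 0.6
    mortality_cell_effect: float = 0.7
    mortality_cell_index: int = 4
    age_hazard: float = 0.085
    baseline_hazard: float = 0.03
    horizon: float = 15.0
    dropout_fraction: float = 0.1
    survival_dist: str = "exponential"
    weibull_shape: float = 1.5
    batch_sd: float = 0.05
    noise_sd: float = 0.3
    cell_noise_sd: float = 0.15
    wbc_cv: float = 0.10
    disease_fraction: float = 0.1
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.n_samples) == 0:
            raise ConfigError("at least one cohort is required")
        if len(self.n_samples) != len(self.age_ranges):
            raise ConfigError("n_samples and age_ranges must have equal length")
        if any(n <= 0 for n in self.n_samples):
            raise ConfigError("cohort sizes must be positive")
        for lo, hi in self.age_ranges:
            if not lo < hi:
                raise ConfigError(f"cohort age range ({lo}, {hi}) needs min < max")
        if self.n_probes <= 0:
            raise ConfigError("n_probes must be positive")
        if self.n_causal < 0 or self.n_causal > self.n_probes:
            raise ConfigError("n_causal must lie in [0, n_probes]")
        for name in ("target_rho2", "heterogeneity_fraction", "dropout_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name}={val} outside [0, 1]")
        if self.horizon <= 0:
            raise ConfigError("censoring horizon must be positive")
        if self.survival_dist not in ("exponential", "weibull"):
            raise ConfigError(f"unknown survival_dist {self.survival_dist!r}")
        if not 0 <= self.mortality_cell_index < self.n_celltypes:
            raise ConfigError("mortality_cell_index out of range")
        if self.cohort_names is not None and len(self.cohort_names) != len(
            self.n_samples
        ):
            raise ConfigError("cohort_names length mismatch")

    @property
    def cohorts(self) -> tuple[str, ...]:
        if self.cohort_names is not None:
            return tuple(self.cohort_names)
        return tuple(f"C{i + 1}" for i in range(len(self.n_samples)))

    @property
    def n_heterogeneity(self) -> int:
        return int(round(self.heterogeneity_fraction * self.n_probes))


@dataclass
class GroundTruth:
    """What the generator actually planted, for validating downstream stages."""

    causal_probes: list[str]
    causal_effects: pd.Series  # probe id -> logit-scale effect per SD of age
    heterogeneity_probes: list[str]
    cell_proportions: pd.DataFrame  # samples x cell types, rows sum to 1
    realized_rho2: float
    signal_scale: float
    event_fraction: float | None = None


def _seed_for(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def _cell_proportions(config, rng, z_age_within, cohort_codes) -> np.ndarray:
    """Logistic-normal cell proportions, optionally coupled to age.

    The real generative relation between age and blood composition is
    unknown; a linear drift on the log-abundance scale is assumed, with a
    *per-cohort* coupling coefficient of random magnitude and sign.  This
    mirrors how the observable age-composition association differs between
    real cohorts (recruitment, disease makeup, processing), so that a clock
    trained on one cohort can exploit its local composition-age
    correlation while pooling many cohorts averages the channel away.
    """
    k = config.n_celltypes
    base = _CELL_BASE_LOGW[:k] if k <= 5 else np.concatenate(
        [_CELL_BASE_LOGW, np.full(k - 5, np.log(0.02))]
    )
    direction = _CELL_AGE_DIRECTION[:k] if k <= 5 else np.concatenate(
        [_CELL_AGE_DIRECTION, np.zeros(k - 5)]
    )
    n = len(z_age_within)
    n_cohorts = int(cohort_codes.max()) + 1 if n else 1
    coupling = config.confounding_strength * rng.standard_normal(n_cohorts)
    eta = (
        base[None, :]
        + (coupling[cohort_codes] * z_age_within)[:, None] * direction[None, :]
        + rng.normal(0.0, config.cell_noise_sd, size=(n, k))
    )
    w = np.exp(eta - eta.max(axis=1, keepdims=True))
    return w / w.sum(axis=1, keepdims=True)


def simulate_world(
    config: SimulationConfig,
) -> tuple[MethylationMatrix, pd.DataFrame, GroundTruth]:
    """Generate a full world: beta matrix, phenotype table, ground truth.

    The aggregate age signal is calibrated *after* all non-age variation
    has been realized: the scalar multiplier on the causal effect sizes is
    solved (by root finding on the sample R^2 of age regressed on the
    causal linear score of the final beta matrix) so that the realized
    variance fraction equals ``target_rho2`` up to root-finding tolerance.
    """
    cfg = config
    rng_pheno = _seed_for(cfg, 0)
    rng_probe = _seed_for(cfg, 1)
    rng_wbc = _seed_for(cfg, 2)

    cohorts = cfg.cohorts
    n_total = int(sum(cfg.n_samples))
    m = cfg.n_probes

    # --- samples: ages, cohorts, demographics -----------------------------
    ages = []
    cohort_labels = []
    for name, n_c, (lo, hi) in zip(cohorts, cfg.n_samples, cfg.age_ranges):
        ages.append(rng_pheno.uniform(lo, hi, size=n_c))
        cohort_labels.extend([name] * n_c)
    age = np.concatenate(ages)
    cohort = np.array(cohort_labels)
    sample_ids = [f"S{i:05d}" for i in range(n_total)]
    z_age = (age - age.mean()) / age.std()

    sex = rng_pheno.choice(["F", "M"], size=n_total)
    disease = np.where(
        rng_pheno.random(n_total) < cfg.disease_fraction, "case", "control"
    )
    plate = rng_pheno.choice([f"P{i}" for i in range(1, 7)], size=n_total)
    array_id = rng_pheno.choice([f"A{i}" for i in range(1, 9)], size=n_total)
    position = rng_pheno.choice([f"R{i:02d}" for i in range(1, 13)], size=n_total)
    hyb_date = rng_pheno.choice([f"D{i}" for i in range(1, 6)], size=n_total)

    # --- cell composition ---------------------------------------------------
    cohort_codes_pre = pd.Categorical(cohort, categories=cohorts).codes
    z_within = np.empty(n_total)
    for code in range(len(cohorts)):
        mask = cohort_codes_pre == code
        a_c = age[mask]
        z_within[mask] = (a_c - a_c.mean()) / a_c.std() if a_c.std() > 0 else 0.0
    props = _cell_proportions(cfg, rng_pheno, z_within, cohort_codes_pre)

    # --- probes -------------------------------------------------------------
    probe_ids = [f"cg{j:07d}" for j in range(m)]
    # bimodal logit baselines: most CpGs sit near fully methylated or fully
    # unmethylated, a minority is intermediate
    mode = rng_probe.choice([-2.5, 0.0, 2.5], size=m, p=[0.4, 0.2, 0.4])
    mu = mode + rng_probe.normal(0.0, 0.7, size=m)

    order = rng_probe.permutation(m)
    causal_idx = np.sort(order[: cfg.n_causal])
    if cfg.allow_overlap:
        het_pool = np.sort(rng_probe.permutation(m)[: cfg.n_heterogeneity])
    else:
        remaining = np.sort(order[cfg.n_causal :])
        if cfg.n_heterogeneity > len(remaining):
            raise ConfigError(
                "heterogeneity_fraction too large for disjoint probe sets; "
                "set allow_overlap=True to permit overlap"
            )
        het_pool = np.sort(remaining[: cfg.n_heterogeneity])
    het_idx = het_pool

    # non-age variation, fully realized before the signal is calibrated
    batch = rng_probe.normal(0.0, cfg.batch_sd, size=(len(cohorts), m))
    cohort_codes = pd.Categorical(cohort, categories=cohorts).codes
    L = mu[None, :] + batch[cohort_codes, :]
    noise = rng_probe.normal(0.0, cfg.noise_sd, size=(n_total, m))
    L = L + noise
    if len(het_idx):
        delta = rng_probe.normal(
            0.0, cfg.celltype_effect_sd, size=(len(het_idx), cfg.n_celltypes)
        )
        L[:, het_idx] += props @ delta.T

    # equal-magnitude, random-sign effect directions for the causal probes
    effects = rng_probe.choice([-1.0, 1.0], size=cfg.n_causal)

    # --- calibrate the aggregate age signal ---------------------------------
    # The causal block follows the *conditional law of the forward mixed
    # model*: x | age ~ N(a c z_age, s^2 I - a^2 c c').  The negative
    # rank-one noise correction cancels the marginal inter-probe
    # correlation the age factor would otherwise induce, so the probes
    # are marginally exchangeable (as the mixed model assumes) and the
    # causal index is the optimal linear predictor of age with
    # population R^2 = a^2 m_c / s^2.  The correction shrinks the
    # index-aligned component of the iid noise by beta(a):
    #     e = eps - beta (c'eps / m_c) c,  2 beta - beta^2 = a^2 m_c / s^2.
    mc = cfg.n_causal
    sig = cfg.noise_sd
    eps_c = noise[:, causal_idx] if mc else np.zeros((n_total, 0))
    proj = (eps_c @ effects) / mc if mc else np.zeros(n_total)

    def causal_logits(a: float) -> np.ndarray:
        r = min((a * a * mc) / (sig * sig), 1.0) if sig > 0 else 1.0
        beta_corr = 1.0 - np.sqrt(max(1.0 - r, 0.0))
        e = eps_c - beta_corr * np.outer(proj, effects)
        base = mu[causal_idx][None, :] + batch[cohort_codes][:, causal_idx]
        return base + e + a * np.outer(z_age, effects)

    def realized_r2(a: float) -> float:
        if mc == 0:
            return 0.0
        bc = expit(causal_logits(a))
        sd = bc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        score = ((bc - bc.mean(axis=0)) / sd) @ effects
        if score.std() == 0:
            return 0.0
        r = np.corrcoef(age, score)[0, 1]
        return float(r * r)

    if mc == 0 or cfg.target_rho2 == 0.0:
        k_signal = 0.0
    else:
        a_max = sig / np.sqrt(mc) if sig > 0 else 1.0
        if realized_r2(a_max) < cfg.target_rho2:
            # beyond a_max the rank-one correction saturates (beta = 1);
            # keep growing the signal with fully de-noised index direction
            a_hi = a_max * 2
            while realized_r2(a_hi) < cfg.target_rho2 and a_hi < 1e3:
                a_hi *= 2.0
            if realized_r2(a_hi) < cfg.target_rho2:
                logger.warning(
                    "simulate_world: target rho2=%.3f unattainable, using "
                    "signal scale %.2f",
                    cfg.target_rho2,
                    a_hi,
                )
                k_signal = a_hi
            else:
                k_signal = brentq(
                    lambda a: realized_r2(a) - cfg.target_rho2, a_max, a_hi, xtol=1e-12
                )
        else:
            k_signal = brentq(
                lambda a: realized_r2(a) - cfg.target_rho2, 0.0, a_max, xtol=1e-12
            )
    if mc:
        L[:, causal_idx] = causal_logits(k_signal)
    rho2_real = realized_r2(k_signal) if mc else 0.0
    beta = expit(L)
    matrix = MethylationMatrix(
        pd.DataFrame(beta, index=sample_ids, columns=probe_ids),
        pd.Series(cohort, index=sample_ids, name="cohort"),
    )

    causal_probes = [probe_ids[j] for j in causal_idx]
    het_probes = [probe_ids[j] for j in het_idx]
    causal_effects = pd.Series(k_signal * effects, index=causal_probes)
    truth = GroundTruth(
        causal_probes=causal_probes,
        causal_effects=causal_effects,
        heterogeneity_probes=het_probes,
        cell_proportions=pd.DataFrame(
            props,
            index=pd.Index(sample_ids, name="sample_id"),
            columns=list(WBC_COLUMNS[: cfg.n_celltypes]),
        ),
        realized_rho2=rho2_real,
        signal_scale=float(k_signal),
    )

    # --- phenotypes ----------------------------------------------------------
    total_wbc = rng_wbc.lognormal(np.log(6.0), 0.2, size=n_total)
    meas_sd = np.sqrt(np.log1p(cfg.wbc_cv**2))
    counts = (
        total_wbc[:, None]
        * props
        * rng_wbc.lognormal(0.0, meas_sd, size=props.shape)
    )
    pheno = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": age,
            "sex": sex,
            "cohort": cohort,
            "disease_status": disease,
            "plate": plate,
            "array": array_id,
            "position": position,
            "hyb_date": hyb_date,
        }
    )
    for j, col in enumerate(WBC_COLUMNS[: cfg.n_celltypes]):
        pheno[col] = counts[:, j]

    pheno = simulate_mortality(pheno, truth, cfg)
    truth.event_fraction = float(pheno["event"].mean())
    return matrix, pheno, truth


def _causal_score(matrix: MethylationMatrix, causal_effects: pd.Series) -> np.ndarray:
    """The true causal linear score: standardized causal betas dotted with effects."""
    b = matrix.beta[causal_effects.index].to_numpy()
    sd = b.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (b - b.mean(axis=0)) / sd
    w = causal_effects.to_numpy()
    norm = np.linalg.norm(w)
    return z @ (w / norm) if norm else np.zeros(matrix.n_samples)


def realized_variance_fraction(
    matrix: MethylationMatrix, pheno: pd.DataFrame, truth: GroundTruth
) -> float:
    """R^2 of age regressed on the true causal linear score (the ground-truth
    analogue of the REML variance fraction)."""
    age = pheno.set_index("sample_id").loc[matrix.sample_ids, "age"] \
        if "sample_id" in pheno.columns else pheno.loc[matrix.sample_ids, "age"]
    score = _causal_score(matrix, truth.causal_effects)
    if score.std() == 0:
        return 0.0
    return float(np.corrcoef(age.to_numpy(dtype=float), score)[0, 1] ** 2)


def simulate_mortality(
    pheno: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Attach survival time and event indicator to a phenotype table.

    Log hazard = age_hazard * (age - mean age) + mortality_cell_effect *
    (standardized proportion of the designated cell type).  Times are
    exponential (or Weibull, proportional-hazards parametrization),
    administratively censored at ``horizon`` years, with a uniform-dropout
    fraction censored earlier.
    """
    if config.horizon <= 0:
        raise ConfigError("censoring horizon must be positive")
    rng = (
        np.random.default_rng(seed)
        if seed is not None
        else _seed_for(config, 3)
    )
    df = pheno.copy()
    age = df["age"].to_numpy(dtype=float)
    props = truth.cell_proportions
    if len(props) != len(df):
        raise ConfigError("cell proportions do not match the phenotype table")
    p = props.iloc[:, config.mortality_cell_index].to_numpy()
    z_cell = (p - p.mean()) / p.std() if p.std() > 0 else np.zeros_like(p)
    log_hr = config.age_hazard * (age - age.mean()) + config.mortality_cell_effect * z_cell
    rate = config.baseline_hazard * np.exp(log_hr)
    e_unit = rng.exponential(1.0, size=len(df))
    if config.survival_dist == "weibull":
        t_event = (e_unit / rate) ** (1.0 / config.weibull_shape)
    else:
        t_event = e_unit / rate
    censor = np.full(len(df), config.horizon)
    n_drop = int(round(config.dropout_fraction * len(df)))
    if n_drop:
        drop_idx = rng.choice(len(df), size=n_drop, replace=False)
        censor[drop_idx] = rng.uniform(0.0, config.horizon, size=n_drop)
    surv = np.minimum(t_event, censor)
    surv = np.maximum(surv, 1e-6)
    df["surv_time"] = surv
    df["event"] = (t_event <= censor).astype(int)
    return df


# ---------------------------------------------------------------------------
# sidecar I/O for ground truth
# ---------------------------------------------------------------------------


def write_ground_truth(truth: GroundTruth, prefix) -> None:
    """Write ground truth as two delimited sidecar tables (<prefix>.probes.tsv,
    <prefix>.cells.tsv); scalars travel in the probe table's attrs row."""
    prefix = Path(prefix)
    all_probes = sorted(set(truth.causal_probes) | set(truth.heterogeneity_probes))
    probe_df = pd.DataFrame(index=pd.Index(all_probes, name="probe_id"))
    probe_df["causal_effect"] = truth.causal_effects.reindex(all_probes).fillna(0.0)
    probe_df["is_causal"] = probe_df.index.isin(truth.causal_probes).astype(int)
    probe_df["is_heterogeneity"] = probe_df.index.isin(
        truth.heterogeneity_probes
    ).astype(int)
    probe_df["realized_rho2"] = truth.realized_rho2
    probe_df["signal_scale"] = truth.signal_scale
    _write_table(probe_df, prefix.with_suffix(".probes.tsv"), index_label="probe_id")
    _write_table(
        truth.cell_proportions, prefix.with_suffix(".cells.tsv"), index_label="sample_id"
    )


def read_ground_truth(prefix) -> GroundTruth:
    prefix = Path(prefix)
    probe_df = _read_table(prefix.with_suffix(".probes.tsv"))
    cells = _read_table(prefix.with_suffix(".cells.tsv"))
    causal = probe_df.index[probe_df["is_causal"] == 1].tolist()
    het = probe_df.index[probe_df["is_heterogeneity"] == 1].tolist()
    return GroundTruth(
        causal_probes=causal,
        causal_effects=probe_df.loc[causal, "causal_effect"],
        heterogeneity_probes=het,
        cell_proportions=cells,
        realized_rho2=float(probe_df["realized_rho2"].iloc[0]) if len(probe_df) else 0.0,
        signal_scale=float(probe_df["signal_scale"].iloc[0]) if len(probe_df) else 0.0,
    )
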