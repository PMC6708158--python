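"""End-to-end orchestration: simulate -> variance components -> clocks ->
evaluation -> AAR/Cox -> EWAS enrichment, from a single YAML config.

Every run writes its outputs under one directory together with a JSON
manifest recording the config hash, the per-stage seeds, per-file MD5
checksums and wall-clock times, so a run can be verified or any single
stage re-derived.  One global seed fans out to per-stage seeds through a
fixed counter scheme (stage index -> spawn key), so disabling one stage
never shifts another stage's random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clocks, evaluation, ewas, io, survival, synthetic, varcomp

logger = logging.getLogger("epiclock")

_STAGE_INDEX = {"simulate": 0, "varcomp": 1, "train": 2, "survival": 3, "ewas": 4}


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence(base_seed, spawn_key=(_STAGE_INDEX[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.md5(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def default_config() -> dict:
    """The demo configuration: a ~900-sample, 2000-probe world."""
    return {
        "seed": 0,
        "simulate": {},
        "varcomp": {"enabled": True, "cohorts": None, "n_perm": 0},
        "train": {
            "methods": ["enet", "blup"],
            "n_replicates": 3,
            "holdout": None,  # cohort excluded from all training, for AAR
            "variance_ratio": None,  # BLUP override when varcomp is disabled
        },
        "survival": {"enabled": True, "covariates": ["age", "sex"]},
        "ewas": {"enabled": True},
        "figures": True,
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config, outdir) -> dict:
    """Run every enabled stage; returns the manifest (also written to disk).

    ``config`` is a YAML path or a dict; missing keys fall back to the
    demo defaults.  A stage failure aborts with the stage name while
    preserving the outputs already written.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _merge(default_config(), config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.StreamHandler(sys.stderr)
    if not logger.handlers:
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)

    seed = int(cfg["seed"])
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in _STAGE_INDEX},
        "files": {},
        "timings": {},
    }

    def _record(path: Path):
        manifest["files"][path.name] = _md5(path)

    def _stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest["timings"][name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                logger.info(
                    "stage %s: done in %.1fs", name, manifest["timings"][name]
                )

        return _Timer()

    # ------------------------------------------------------------------ simulate
    with _stage("simulate"):
        sim_kwargs = dict(cfg["simulate"] or {})
        for key in ("n_samples", "cohort_names"):
            if key in sim_kwargs and sim_kwargs[key] is not None:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        if "age_ranges" in sim_kwargs and sim_kwargs["age_ranges"] is not None:
            sim_kwargs["age_ranges"] = tuple(map(tuple, sim_kwargs["age_ranges"]))
        sim_kwargs.setdefault("seed", stage_seed(seed, "simulate"))
        sim_config = synthetic.SimulationConfig(**sim_kwargs)
        matrix, pheno, truth = synthetic.simulate_world(sim_config)
        io.write_matrix(matrix, outdir / "matrix.tsv")
        io.write_phenotypes(pheno, outdir / "pheno.tsv")
        synthetic.write_ground_truth(truth, outdir / "truth")
        for f in ("matrix.tsv", "pheno.tsv", "truth.probes.tsv", "truth.cells.tsv"):
            _record(outdir / f)

    cohorts = sim_config.cohorts
    ages = pheno.set_index("sample_id")["age"]

    # ------------------------------------------------------------------ varcomp
    variance_ratio = cfg["train"].get("variance_ratio")
    if cfg["varcomp"].get("enabled", True):
        with _stage("varcomp"):
            vc_cohorts = cfg["varcomp"].get("cohorts") or list(cohorts)
            sub = matrix.subset_cohorts(vc_cohorts)
            K = varcomp.compute_orm(sub)
            fit = varcomp.reml_fit(K, ages.loc[sub.sample_ids])
            result = dataclasses.asdict(fit)
            n_perm = int(cfg["varcomp"].get("n_perm") or 0)
            if n_perm:
                perm = varcomp.permutation_test(
                    K, ages.loc[sub.sample_ids], n_perm,
                    seed=stage_seed(seed, "varcomp"),
                )
                result["permutation_p"] = perm.p_value
                result["null_rho2_mean"] = float(perm.null_rho2.mean())
            with open(outdir / "varcomp.json", "w") as fh:
                json.dump(result, fh, indent=2)
            _record(outdir / "varcomp.json")
            variance_ratio = fit.variance_ratio
    else:
        logger.info("varcomp disabled; BLUP uses configured variance ratio %s",
                    variance_ratio)

    # ------------------------------------------------------------------ train/evaluate
    with _stage("train"):
        holdout = cfg["train"].get("holdout")
        train_cohorts = [c for c in cohorts if c != holdout]
        design = clocks.make_training_design(
            train_cohorts,
            n_replicates=int(cfg["train"].get("n_replicates", 3)),
            seed=stage_seed(seed, "train"),
        )
        predictors: dict[str, list] = {}
        curves = []
        for method in cfg["train"].get("methods", ["enet", "blup"]):
            kwargs = {}
            if method == "blup" and variance_ratio is not None and not np.isinf(
                variance_ratio
            ):
                kwargs["variance_ratio"] = float(variance_ratio)
            predictors[method] = evaluation.train_design(
                matrix, pheno, design, method=method,
                seed=stage_seed(seed, "train"), **kwargs,
            )
            curves.append(
                evaluation.size_curve(
                    matrix, pheno, design, method=method,
                    predictors=predictors[method],
                )
            )
        curve = pd.concat(curves, ignore_index=True)
        io._write_table(curve, outdir / "rmse_vs_ntrain.tsv", index_label="row")
        _record(outdir / "rmse_vs_ntrain.tsv")

    # ------------------------------------------------------------------ survival
    if cfg["survival"].get("enabled", True) and holdout is not None:
        with _stage("survival"):
            att = []
            for method in cfg["train"].get("methods", ["enet", "blup"]):
                att.append(
                    survival.attenuation_experiment(
                        matrix, pheno, design, holdout, method=method,
                        covariates=tuple(cfg["survival"].get("covariates", ("age", "sex"))),
                        predictors=predictors[method],
                    )
                )
            att = pd.concat(att, ignore_index=True)
            io._write_table(att, outdir / "z_vs_ntrain.tsv", index_label="row")
            _record(outdir / "z_vs_ntrain.tsv")
    else:
        att = None

    # ------------------------------------------------------------------ ewas
    if cfg["ewas"].get("enabled", True) and holdout is not None:
        with _stage("ewas"):
            enr = []
            for method in cfg["train"].get("methods", ["enet", "blup"]):
                enr.append(
                    ewas.enrichment_vs_size(
                        matrix, pheno, design, truth.heterogeneity_probes, holdout,
                        method=method, predictors=predictors[method],
                    )
                )
            enr = pd.concat(enr, ignore_index=True)
            io._write_table(enr, outdir / "or_vs_ntrain.tsv", index_label="row")
            _record(outdir / "or_vs_ntrain.tsv")
    else:
        enr = None

    # ------------------------------------------------------------------ figures
    if cfg.get("figures", True):
        _make_figures(outdir, curve, att, enr)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _make_figures(outdir: Path, curve, att, enr) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    shown = curve[~curve["plot_excluded"]]
    for method, g in shown.groupby("method"):
        means = g.groupby("n_train")["rmse"].mean()
        ax.plot(means.index, means.values, "o-", label=method)
    ax.set_xlabel("training sample size")
    ax.set_ylabel("test RMSE (years)")
    if ax.get_legend_handles_labels()[0]:
        ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "fig_rmse_vs_ntrain.png", dpi=120)
    plt.close(fig)

    if att is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        for method, g in att.groupby("method"):
            means = g.groupby("n_train")["z_aar"].apply(lambda s: s.abs().mean())
            ax.plot(means.index, means.values, "o-", label=f"{method} |z|")
            means_w = g.groupby("n_train")["z_aar_wbc_adjusted"].apply(
                lambda s: s.abs().mean()
            )
            ax.plot(means_w.index, means_w.values, "s--", label=f"{method} |z| WBC-adj")
        ax.set_xlabel("training sample size")
        ax.set_ylabel("|z| for AAR-mortality")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / "fig_z_vs_ntrain.png", dpi=120)
        plt.close(fig)

    if enr is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        for method, g in enr.groupby("method"):
            col = "odds_ratio_corrected" if "odds_ratio_corrected" in g else "odds_ratio"
            means = g.groupby("n_train")[col].mean()
            ax.plot(means.index, means.values, "o-", label=method)
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_xlabel("training sample size")
        ax.set_ylabel("heterogeneity enrichment OR")
        if ax.get_legend_handles_labels()[0]:
            ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "fig_or_vs_ntrain.png", dpi=120)
        plt.close(fig)
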