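# epiclock

Tools for building and stress-testing **epigenetic clocks** — linear
predictors of chronological age from DNA methylation — and for asking a
question that matters to anyone using such clocks as ageing biomarkers:
*what happens to the association between age acceleration and mortality
as the clock itself gets better?*

The package is aimed at methylation researchers and statistical
geneticists who want a fully reproducible, simulation-driven harness for
the whole analysis chain:

1. **Variance components.** How much of the variance of chronological
   age is captured jointly by all CpG probes?  With the mixed model
   `y = Wb + g + e`, `g ~ N(0, K σu²)`, `e ~ N(0, I σe²)` on the omics
   relationship matrix `K = ZZ′/m` (Z the column-standardized beta
   matrix), REML estimates `ρ² = σu²/(σu² + σe²)`, with a permutation
   null obtained by shuffling ages across individuals.
2. **Clock construction.** Age predictors trained by **BLUP** (every
   probe gets a shrunken weight, `û = Z′(ZZ′ + (m σe²/σu²) I)⁻¹ y_c`,
   the ridge/mixed-model solution) and by the **Elastic Net**
   (coordinate descent, penalty chosen by cross-validation), over
   training designs that sample 1…C−1 cohorts out of C with replicates
   (the classic 65 = 13 × 5 layout at C = 14).  Beta-value transforms
   (power grid λ ∈ [0.1, 2] in steps of 0.05, M-value, arcsine-sqrt,
   log) and correlation-based probe pruning are included.
3. **Evaluation.** Test-cohort RMSE and Pearson correlation, training-
   size curves, and a regression of accuracy on training size, train/
   test age-gap and training-age SD.
4. **Mortality association.** The age acceleration residual (AAR) — the
   residual of predicted age regressed on chronological age — enters a
   Cox proportional-hazards model (own Newton–Raphson engine, Efron
   ties) with hazard ratios reported per 5 years of acceleration, plus
   the sensitivity analysis adjusting for the five measured white-blood-
   cell counts.
5. **EWAS + enrichment.** Probe-by-probe regression of methylation on
   AAR with a Bonferroni threshold (0.05 / probes tested) and
   λ_median inflation, then Fisher's exact test for enrichment of the
   hits in a cellular-heterogeneity probe set.

Because the real multi-cohort datasets behind such analyses are
access-restricted, everything runs on a **synthetic-data generator**
with known ground truth: multi-cohort worlds with distinct age ranges,
a calibrated fraction of age variance carried by a causal probe subset,
blood cell-type composition that shifts a designated heterogeneity
probe subset and the mortality hazard, batch effects, and censored
survival times.  See `docs/methods.md` for the generative model and its
limitations.

## Worked example

```python
import epiclock as ec

# a 6-cohort world: 900 samples, 2000 probes, rho2 = 0.9 age signal
cfg = ec.SimulationConfig(seed=7)
matrix, pheno, truth = ec.simulate_world(cfg)
ages = pheno.set_index("sample_id")["age"]

# 1. how much age variance do all probes capture jointly?
fit = ec.reml_fit(ec.compute_orm(matrix), ages.loc[matrix.sample_ids])
print(f"rho2 = {fit.rho2:.3f} (SE {fit.se_rho2:.3f})")

# 2. train a clock on five cohorts, test on the held-out one
train = matrix.subset_cohorts(["C1", "C3", "C4", "C5", "C6"])
clock = ec.train_enet(train, ages.loc[train.sample_ids], seed=0, cv=5)
test = matrix.subset_cohorts(["C2"])
res = ec.score(clock.predict(test), ages.loc[test.sample_ids])
print(f"test RMSE = {res.rmse:.2f} years, r = {res.pearson_r:.3f}")

# 3. does age acceleration predict death?
aar = ec.compute_aar(clock.predict(test), ages.loc[test.sample_ids],
                     sample_ids=test.sample_ids)
cox = ec.fit_cox(pheno, aar, covariates=("age", "sex"))
hr = cox.hr_per5
print(f"HR per 5y AAR = {hr['hr']:.2f} ({hr['ci_low']:.2f}-{hr['ci_high']:.2f})")
```

prints (seed 7):

```
rho2 = 0.844 (SE 0.045)
test RMSE = 13.04 years, r = 0.058
HR per 5y AAR = 1.06 (0.97-1.15)
```

The variance-component fit says most of the age variance is captured
jointly by the probes — a much better clock is possible in principle —
yet the 660-sample clock transfers poorly to the held-out narrow-age
elderly cohort (13 years RMSE, near-zero within-cohort correlation),
and its age-acceleration residual shows no significant mortality
association here.  In confounded worlds, small-training clocks *do*
show such associations, driven by cell composition rather than ageing,
and they attenuate as the training set grows; `run_pipeline` (or
`epiclock pipeline config.yaml --outdir out/`) sweeps training sizes
and writes the three trend tables and figures.

## Command line

Every stage is exposed as a thin subcommand over the library:

```bash
epiclock varcomp  --matrix m.tsv --pheno p.tsv --out fit.json --perm 100
epiclock train    --method enet --matrix m.tsv --pheno p.tsv --out clock.tsv
epiclock predict  --pred clock.tsv --matrix m.tsv --out ages.tsv
epiclock evaluate --pred clock.tsv --matrix m.tsv --pheno p.tsv --out eval.tsv
epiclock aar      --pred clock.tsv --matrix m.tsv --pheno p.tsv --out aar.tsv
epiclock coxph    --pheno p.tsv --aar aar.tsv [--adjust-wbc] --out cox.json
epiclock ewas     --matrix m.tsv --aar aar.tsv --out ewas.tsv
epiclock enrich   --ewas ewas.tsv --probeset het.txt --out enrich.json
epiclock pipeline config.yaml --outdir runs/demo
```

All file formats are tab-delimited text with a provenance checksum
line; clock coefficient files are portable (probe id, weight, training
mean, training SD, plus an intercept row).

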