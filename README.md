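# mbtemporal

Longitudinal **quantitative** gut-microbiome analysis: how much does a
person's microbiota vary day to day, in absolute numbers, and what drives
that variation?

Most microbiome time-series work uses relative abundances, which hide
changes in total biomass and entangle taxa through compositional closure.
`mbtemporal` implements the analysis stack for dense (near-daily) 16S time
series with matched flow-cytometry cell counts, where each sample carries a
microbial load L (cells per gram) and genus abundances can be expressed in
cells/g. It is written for microbial ecologists and biostatisticians
designing or analyzing repeated-measurement cohorts.

## What it computes

- **Profiles.** Relative microbiome profiles (RMP; reads rarefied to
  10,000) and quantitative microbiome profiles (QMP): 16S copy-number
  corrected counts rarefied to an even *sampling depth*
  d_s = (Σ_g x_g / cn_g) / L_s (corrected reads per cell), with the target
  depth optimized to exclude as few samples as possible while keeping
  ≥ 500 corrected reads per sample, then scaled to cells/g.
- **Within- vs. between-subject variation.** Intraclass correlation from
  one-way ANOVA variance components,
  ICC = σ²_among / (σ²_among + σ²_within), with the unbalanced-design k₀
  correction; temporal coefficients of variation; maximum overall and
  consecutive-sample fold changes and rank coverage; augmented
  Dickey–Fuller stationarity screening; Taylor's law
  log σ²_g = b·log μ_g + c per genus across hosts (b = 2 ⇔ constant CV);
  the error-on-the-median subsampling curve and its elbow.
- **Core membership.** Temporal core (> 95% of a person's samples),
  persistent, transient, cross-sectional core and person-specific genera,
  plus core size as a function of sampling effort.
- **Community structure.** Bray–Curtis dissimilarity BC = Σ|x−y|/Σ(x+y),
  PCoA with negative eigenvalues retained, betadisper-style homogeneity of
  group dispersions, and similarity-decay regression of log(1−BC) on
  elapsed days with per-day balanced subsampling.
- **Enterotype dynamics.** Dirichlet-multinomial mixture (DMM) clustering
  by EM with monotone likelihood, model selection over K, iterative
  assignment of longitudinal samples against a cross-sectional background,
  and a rank-sum mislabeling/swap screen; expected-vs-observed transition
  rates from enterotype prevalence with a χ² goodness-of-fit test; a
  continuous-time Markov model with covariate-modulated intensities
  q_rs(z) = q⁰_rs·exp(β_rs·z), risk ratios exp(β) with 95% CIs, and
  likelihood-ratio covariate tests.
- **Host covariates.** Energy intake (9/4/4 kcal/g), per-participant
  dietary lag from P/C–moisture cross-correlation, and menstrual-cycle
  hormone profiles aligned to cycle length.
- **Synthetic cohorts.** A generator emulating the study design (20
  participants, ~36 near-daily samples, log-normally fluctuating genus
  abundances with Taylor-law scaling, four Dirichlet community states,
  loads of 6–22 × 10¹⁰ cells/g, moisture coupled to load and lagged diet),
  with ground truth for recovery tests. See `docs/methods.md` for the
  model and its limits.

## Worked example

```python
from mbtemporal import CohortSpec, generate_cohort, profiling, variability

spec = CohortSpec(n_participants=10, n_days=28, n_genera=80, seed=42)
cohort, truth = generate_cohort(spec)
build = profiling.build_qmp(cohort.table, cohort.copy_numbers,
                            cohort.meta["load"], min_reads=500, seed=0)
print(f"retained {len(build.retained)}/{len(cohort.table.sample_ids)} samples "
      f"at target depth D = {build.target_depth:.3e} reads/cell")

alpha = profiling.alpha_diversity_table(build.qmp)
icc = variability.icc(alpha["shannon"], build.qmp.samples["participant_id"])
print(f"Shannon diversity ICC = {icc.icc:.3f}")

genera = profiling.filter_genera(build.qmp, 0.005, min_participants=5, min_samples=3)
taylor = variability.taylor_per_genus(build.qmp, genera)
print(f"Taylor's law over {taylor['slope'].notna().sum()} genera: "
      f"mean slope = {taylor['slope'].mean():.2f}, "
      f"mean adj R^2 = {taylor['adj_r2'].mean():.2f}")
```

prints

```
retained 269/269 samples at target depth D = 1.588e-08 reads/cell
Shannon diversity ICC = 0.406
Taylor's law over 80 genera: mean slope = 2.21, mean adj R^2 = 0.86
```

An ICC of 0.41 means only 41% of the variance in Shannon diversity lies
*between* participants — day-to-day variation within a person dominates. A
mean Taylor slope slightly above 2 says temporal variance grows a bit
faster than the square of the mean, i.e. genera are (mildly) less stable
where they are more abundant; the high adjusted R² shows the power law
holds tightly across hosts.

The same stages are scriptable from a shell:

```bash
mbtemporal simulate --out sim/ --seed 1
mbtemporal qmp --counts sim/counts.tsv --meta sim/meta.tsv \
    --copy-numbers sim/copy_numbers.tsv --out results/ --seed 1
mbtemporal run-all --counts sim/counts.tsv --meta sim/meta.tsv \
    --diet sim/diet.tsv --copy-numbers sim/copy_numbers.tsv \
    --out results/ --seed 1
```

`run-all` chains profiling → variability → core → community →
enterotyping → transitions → covariates and writes a manifest with the
derived per-stage seeds, so two runs with the same config and seed are
byte-identical.

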