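# stimulome

Transcriptome decomposition of bacterial RNA-seq compendia into
**iModulons** (independently modulated gene sets) and **stimulons**
(clusters of co-activated iModulons), with the downstream statistics
used to study stress responses in high cell-density *E. coli*
fermentations: differential iModulon activity against a replicate-noise
null, coverage of differentially expressed genes by iModulon membership,
proteome-allocation summaries from genome-scale model solutions, and
fed-batch process metrics.

It is written for systems biologists and fermentation scientists who
want the full analysis chain — decomposition, testing, clustering,
process context — as a tested, reproducible library rather than a
collection of notebooks.

## The model

Expression is decomposed as

```
X ≈ S · A
```

where `X` is the genes × samples log-TPM matrix, `S` the genes ×
components matrix of gene weights, and `A` the components × samples
activity matrix. Each retained column of `S` plus its thresholded member
gene set is an iModulon; its row of `A` traces the iModulon's activity
across conditions.

The estimation pipeline:

1. **Robust ICA.** FastICA (log-cosh contrast, symmetric decorrelation)
   is run from many random initialisations; pooled components are
   density-clustered on the `1 − |Pearson|` gene-weight distance, and
   only clusters recurring in more than half the restarts are kept
   (centroid, unit norm, sign-oriented). Member genes are the
   largest-|weight| prefix whose removal renders the remaining weights
   Gaussian (D'Agostino K² test).
2. **Differential activity.** Per component, absolute activity
   differences between paired biological replicates form an empirical
   null, fitted as a log-normal. For a contrast, `ΔA` (group-mean
   difference) gets `p = SF_lognormal(|ΔA|)`, Benjamini–Hochberg
   q-values across components, and a *highly active* flag when
   `|ΔA| > 5` and `q < 0.1`.
3. **Stimulons.** Pairwise Spearman correlations of activities over the
   flagged components; edges where `|ρ| ≥ 0.7` and `p < 0.05` (negative
   correlations connect too); connected components with ≥ 2 nodes are
   stimulon clusters, named after their largest-membership node.
4. **DEG coverage.** Welch tests per gene (`|Δlog-TPM| > 2`, BH
   `q < 0.1`); coverage is the fraction of significant genes inside at
   least one member set.
5. **Process & allocation.** Exponential feeding `F(t) = F0·e^(μ_set·t)`
   (defaults 0.535 mL/h, 0.11 /h), OD600 → CDW at 0.34 g/L per unit,
   CO2 yield per biomass, and the ME-model mass-flux ratios
   `% proteome` and `% damaged proteome`.

A synthetic-data generator plants all of this structure (sparse
heavy-tailed gene weights, condition-block activities, paired-replicate
noise, activity shifts, correlated blocks) so every stage is validated
against known ground truth.

## Worked example

```python
import stimulome as sm

design = sm.SyntheticDesign(
    n_genes=1000, n_components=6, n_conditions=10, n_batch_conditions=4,
    replicates_per_condition=4,
    shifts=(sm.PlantedShift(component=2, delta=12.0),),
)
X, truth = sm.simulate_dataset(design, seed=7)
Xc = sm.center_to_reference(X, X.samples_where(phase="batch"))

results = sm.RobustICA(Xc, dimensionality=6, n_restarts=10).fit(seed=7)
print(results.summary())

null = sm.DifferentialActivity(results.activities, X.replicate_pairs()).fit()
contrast = sm.SampleContrast(
    frozenset(X.samples_where(phase="batch")),
    frozenset(X.samples_where(phase="fedbatch")),
    label="batch_vs_fedbatch",
)
print(null.test_contrast(results.activities, contrast).round(4))
```

prints

```
Robust ICA decomposition
  genes x samples:     1000 x 40
  dimensionality:      6
  restarts (converged): 10 (10)
  robust components:   6
  reconstruction err:  0.0478
      occurrence  n_members top_gene
IC01         1.0         20    g0283
IC02         1.0         20    g0552
IC03         1.0         20    g0030
IC04         1.0         20    g0377
IC05         1.0         20    g0360
IC06         1.0         20    g0071

      delta_A  pvalue  qvalue  high_activity
IC01  -0.4919  0.6722  0.6722          False
IC02  -5.3084  0.0486  0.0973           True
IC03   2.9101  0.0484  0.0973          False
IC04  12.4992  0.0004  0.0025           True
IC05  -0.7027  0.3448  0.4138          False
IC06   2.8989  0.1178  0.1767          False
```

All six planted components are recovered in every restart (occurrence
1.0) with their 20 member genes each, and the reconstruction error
matches the 5% expression noise the generator added. IC04 is the
planted shift (`ΔA = 12.5 ≈ 12` planted, strongly flagged). IC02
illustrates an important property of the replicate-pair null: it models
replicate noise only, so genuine condition-to-condition baseline
variation (SD 3 in this design) occasionally carries an unshifted
component past the `|ΔA| > 5` flag — a feature to keep in mind when
interpreting flags on real compendia.

The same pipeline is available from the shell:

```sh
stimulome run-all --config config.yaml --seed 7 --out run/
```

which writes the expression matrix, fitted weights and member sets,
activities, per-contrast differential-activity tables, the stimulon
edge list and clusters, DEG coverage, and a provenance record; rerunning
the same config reproduces every result file byte-for-byte.

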