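# Methods

This note records the statistical model behind `stimulome`, the
parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions taken where the
design was genuinely open.

## The decomposition model

Expression is modelled as `X = S·A + E` on the log-TPM (log2) scale:
`S` (genes × k) holds sparse gene-weight vectors, `A` (k × samples) the
per-sample activities, `E` i.i.d. measurement noise. ICA is applied
with *genes as observations*: each gene's expression profile is a
mixture of the k activity programs, so the recovered sources are the
gene-weight columns of `S`. This orientation is what makes the sparse,
heavy-tailed weight vectors (a few strongly weighted member genes over
a near-Gaussian background) maximally non-Gaussian and hence
identifiable by an ICA contrast.

### Robustness over restarts

A single ICA run depends on its random rotation initialisation. We run
`n_restarts` independent fits (default 100; 10–20 suffice on clean
synthetic data), pool all components, and cluster them with DBSCAN at
radius ε = 0.1 on the distance `1 − |Pearson(w_i, w_j)|` (minimum
cluster size 2). A cluster is retained iff it appears in **more than**
`min_occurrence` (default 0.5) of the restarts, counting distinct
restarts rather than pooled columns so a restart contributing two
near-duplicate columns is not double-counted. The retained component is
the sign-aligned cluster centroid, re-normalised to unit norm and
oriented so its largest-|weight| entry is positive. Components are
ordered by occurrence (ties by first appearance) and named IC01, IC02…
Non-convergent restarts (FastICA hitting max_iter = 500 at
tol = 1e-6) are dropped with a warning; if more than half drop the fit
aborts.

### Membership thresholding

Member genes are found by iterative outlier stripping: remove the gene
with the largest |weight|, recompute D'Agostino's K² normality
statistic on the remainder, stop when K² ≤ cutoff. The member set is
therefore always a prefix of the |weight| ranking. The default cutoff
of 20 was calibrated on i.i.d.-normal null weight vectors: K² is
asymptotically χ²(2) under normality, for which 20 has tail probability
≈ 5·10⁻⁵, so pure-noise components get empty or near-empty member sets
(≤ 1% of genes, verified by simulation at n = 1000–2000). Membership is
capped at 20% of genes with a warning if the cutoff is never reached.
The exact thresholding rule used in published compendium workflows
lives in external protocols; this calibrated rule is this package's
own, chosen to make the behaviour testable.

### Activities

Given fitted `S`, activities are the least-squares solution
`A = pinv(S)·X`, the unique minimiser of the Frobenius reconstruction
error for full-column-rank `S` (rank deficiency raises an error).

## Differential activity

For each component, the absolute activity differences `d` between
paired biological replicates — pooled over all conditions' pairs, since
nothing restricts which pairs inform the null — are fitted with a
log-normal via the mean and SD of `log d` (also the MLE). A contrast's
`ΔA` (group-b mean − group-a mean) gets
`p = 1 − Φ((log|ΔA| − μ_ln)/σ_ln)`, BH correction across the
components of the contrast, and a flag when `|ΔA| > 5` and `q < 0.1`.

Three numerical points:

- **Zero floor ε = 0.05 activity units.** `log d` is unboundedly
  negative for near-zero differences; a single pair difference of
  ~10⁻⁵ (which occurs by chance every few hundred pairs) otherwise
  inflates σ_ln enough to mask genuine |ΔA| ≈ 15 shifts. The floor is
  two orders of magnitude below the flag cutoff, so it cannot create
  significance; it only stabilises the fit. A degenerate σ_ln = 0
  (identical replicates) is floored at 10⁻⁶ with a warning.
- **Conservatism.** The null is the distribution of a *single* pair
  difference, but `ΔA` is a mean over several samples per group, whose
  replicate-noise component is smaller. Under a pure replicate-noise
  null the test's false-flag rate is therefore far below nominal
  (measured ≈ 0 at q < 0.1 over 500 simulations).
- **The log-normal is a heavy-tailed surrogate.** For Gaussian
  replicate noise the true |difference| is half-normal; the fitted
  log-normal's 95th percentile is ≈ 68% larger than the half-normal's
  (closed form: exp(μ_ln + 1.645σ_ln) with μ_ln = log√2 − (γ+log2)/2,
  σ_ln = π/√8, versus 1.96·√2). This adds to the conservatism above and
  is inherent to the procedure, not a fitting artefact.

Because the null contains replicate noise only, *any* condition-level
variation counts as signal: components whose baselines genuinely move
between conditions can be flagged without a planted shift. That is the
intended semantics (those activities did differ), but it means flags
should be read as "activity differs between these groups", not
"a specific intervention caused it".

## Stimulon detection

Spearman correlations (signed) are computed between activity rows over
the selected components; p-values use the t-approximation for n ≥ 10
samples and the exact permutation distribution of ρ (full enumeration,
cached per n) below that, falling back to the t-approximation when ties
are present. Edges require `|ρ| ≥ 0.7` and `p < 0.05`; the threshold is
applied to the signed coefficient, and negative edges connect nodes
exactly like positive ones — an anti-correlated pair is one coordinated
trade-off. Clusters are connected components with ≥ 2 nodes (an
average-linkage hierarchical alternative is available behind
`method="hierarchy"`, without a default), named by the node with the
largest member set, ties broken by degree then lexicographic id — a
total order, so naming is deterministic. Qualifying negative edges are
additionally reported as an "opposition" list; note they necessarily
lie *inside* a connected component (an edge that qualifies joins its
endpoints), so opposition structure is sub-cluster structure.

Constant activity rows have undefined rank correlation; their pairs are
recorded as missing and excluded from the graph.

## DEG coverage

Per-gene Welch t-tests on log-TPM with BH correction; significance
requires `q < 0.1` and `|Δlog-TPM| > 2`. The gene-level test is a
convention choice (only the thresholds are fixed by convention); a
replicate-null variant mirroring the activity-level test is provided
(`method="replicate_null"`) and needs a decent pair count (≈ 20) to
stabilise its per-gene σ_ln. Coverage is
`|significant ∩ ∪ member_sets| / |significant|` per direction, reported
as missing when no gene is significant. Log base 2 with pseudo-count 1
is used throughout for TPM; thresholds quoted in "log tpm" units are
interpreted on this scale.

## Proteome allocation and ROS scaling

`% proteome` and `% damaged proteome` are mass-flux ratios
(Σ mw·V over a pathway or over the damage reactions, divided by total
Σ mw·V of translation), so any consistent unit system cancels;
validation checks only positivity and the `damage_` id prefix. An
exhaustive pathway partition sums to 100% to machine precision, and the
ratios are invariant to common flux rescaling. Basal intracellular ROS
defaults are 0.2 nmol/L superoxide and 50 nmol/L H2O2 for the reference
strain, scaled linearly by the strain/reference oxygen-uptake ratio
(steady-state ROS is proportional to its formation rate). Building or
solving the metabolism-and-expression model itself is out of scope; the
module consumes exported solution tables.

## Process metrics

`F(t) = F0·e^(μ_set·t)` with defaults F0 = 0.535 mL/h and
μ_set = 0.11 /h; OD600 → CDW at 0.34 g/L per unit; CO2 yield per
biomass as trapezoid-integrated CO2 rate over ΔCDW × volume (default
0.25 L). Phase boundaries (I/II at 0 h, II/III at 10 h, III/IV at 20 h)
are configuration labels, not detected — real phase calls integrate
several process signals. An optional detector for the batch→fed-batch
switch (first 50% decline of the smoothed CO2 rate from its running
maximum) is provided with a configurable smoothing window, because the
right window depends on the off-gas sampling rate; it is not used by
the pipeline.

## The synthetic-data generator

The generator emulates exactly the structure the pipeline estimates:

- **Sources:** per component, `m` disjoint member genes (default 20)
  with weights sign·(scale + |N(0, 0.1·scale)|) over an N(0,
  background_sd) background, columns unit-normed. The ±jitter form
  guarantees member/background separation, making membership
  thresholding well-posed. The weight distribution of real iModulons is
  not documented anywhere; this sparse heavy-tailed form is a modelling
  stand-in.
- **Activities:** condition baselines N(0, condition_sd = 3), with
  planted blocks sharing a latent condition factor at a target |ρ| and
  per-component signs, planted batch→fed-batch mean shifts, and
  N(0, 1) replicate noise per sample. Replicate pairing is explicit
  metadata (pair ids), never inferred from sample names.
- **Expression:** `X = S·A + E` with E i.i.d. Gaussian at a fraction
  (default 5%) of the signal RMS.
- **Seeding:** one global seed is split into per-stage substreams
  (sources / activities / expression noise / ICA restarts), so
  identical (design, seed) gives byte-identical serialized output and
  changing one stage's consumer never perturbs another stage's draws.

Default sizes — 2000 genes, 10 components, 15 conditions (5 batch) in
paired duplicates (60 samples) — are the workload at which the
pipeline's recovery behaviour is characterised; correlation-block
studies use 50 conditions in paired duplicates because a sample
Spearman over few independent conditions has SE ≈ 0.07–0.1 and a
2-node block whose single edge sits at realized ρ ≈ 0.86 would
otherwise drop below the 0.7 threshold in a nontrivial fraction of
runs.

What the generator does **not** emulate: count-level sampling noise and
library-size/GC biases (expression is generated directly on the
log-TPM scale), compositional effects, batch effects between
experiments, regulatory overlap between components (member sets are
disjoint), and non-Gaussian replicate noise. Passing tests therefore
demonstrate correctness of the estimation machinery under the stated
model, not robustness to the full messiness of real RNA-seq compendia.

## Simulation-study conditions

- **Recovery:** 2000 genes × 60 samples, k = 10, 20 restarts, 5%
  expression noise; score = worst-case matched |Pearson| (Hungarian
  assignment) and worst-case member-set Jaccard.
- **Calibration:** 500 datasets, no shifts, zero condition-level
  variation (the null world of the replicate-pair test is replicate
  noise only — condition variation is signal by construction),
  12 components, 30 pairs, 6-vs-6 contrast; false-flag fraction at
  q < 0.1 compared against 0.1 + 3 Monte-Carlo SE.
- **Power:** same frame with 5 of 12 components shifted by ΔA = 10;
  power = fraction of shifted components flagged over 200 datasets.
- **Stimulon recovery:** 3 planted blocks (sizes 3, 3, 2; one with
  mixed signs) at target |ρ| = 0.9 among 10 components, 50 conditions;
  requires exactly 3 clusters matching the planted partition and
  deterministic naming.
- **Coverage:** 3 of 8 components shifted by ΔA = 25 (≈ 5 log-TPM per
  member gene, comfortably past the |Δlog-TPM| > 2 gene threshold —
  ΔA = 10 would put member genes right at the cutoff); coverage of the
  fitted member sets over significant genes in both directions.
- **Pipeline demo:** 2000 genes, k = 10, 60 samples, five shifted
  components forming two planted blocks; run twice and compared
  byte-for-byte. Because all flagged components share the
  batch→fed-batch transition, their activities correlate across blocks
  near the edge threshold, so the demo checks that each planted block
  lands inside one recovered cluster rather than demanding the blocks
  stay separate; clean partition recovery is the stimulon study's job,
  which has no planted shifts.

## Known limitations

- The restart-clustering distance, the membership rule and the
  dimensionality choice in published compendium analyses live in
  external protocols; the defaults here are calibrated stand-ins, and
  the cross-dimensionality search is reduced to a user-set
  `dimensionality`.
- The replicate-pair null is shared across all conditions; per-condition
  nulls are not fitted (pairs are pooled to maximise n).
- DBSCAN restart clustering is O(p²) in pooled components; at compendium
  scale (hundreds of restarts × hundreds of components) the distance
  matrix becomes the bottleneck.
- The pipeline's stimulon stage runs on the flagged components of the
  supplied contrasts; if fewer than two components are flagged it falls
  back to all components.
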