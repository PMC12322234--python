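# Methods

## Model and rationale

The package treats a targeted metabolomics experiment on a cell-line
panel as a three-layer observation model on the log10 scale: a
metabolite-specific baseline, structured unwanted variation (run/batch
effects shared by all samples of a batch, plus a global per-sample
scaling from cell amount and extraction efficiency), and the biological
signal of interest — coordinated shifts of pathway product metabolites
relative to their pathway precursor. Because metabolite conversion forms
a cascade, the ratio of a downstream product to an upstream precursor is
a more direct readout of pathway behavior than either concentration
alone; on the log scale it is a simple difference, which makes it exactly
invariant to the per-sample scaling layer.

## Pipeline stages

**Log transformation.** Concentrations are log10-transformed. Missing or
non-positive cells are a hard error by default; the optional
limit-of-detection imputation replaces them with half the minimum
positive value of that metabolite, the standard metabolomics LOD
convention. The default is strict because silent imputation changes
ratios invisibly.

**RUV-III.** Cell lines measured in several runs are technical
replicates; their within-group contrasts span the unwanted-variation
subspace. With replicate membership matrix M (samples × groups, one 1
per row), the algorithm residualizes Y on replicate means,
`Y0 = (I − M(MᵀM)⁻¹Mᵀ)Y`, takes the top-k left singular vectors U_k of
Y0, sets loadings `α = U_kᵀY`, scores `W = Y_c α_cᵀ(α_c α_cᵀ)⁻¹` on the
control features, and returns `Y − Wα`. k = 0 is the identity. Defaults:
k = 9 unwanted factors and *all* metabolites as controls (no designated
negative controls exist in a 50-metabolite targeted panel; with
replicate-based estimation this is standard practice). k is bounded by
`samples − replicate groups` and by the control count; a control loading
Gram matrix with condition number above 1e12 raises an error suggesting a
smaller k. Replicates are kept through correction and averaged per cell
line immediately afterwards, since clustering operates on cell lines.
A quality gate (`replicate_cocluster_report`) checks that cross-batch
replicates of a cell line co-cluster after correction and warns
otherwise.

**Ratio transform.** One feature per (pathway, member): `log10 numerator
− log10 precursor`. A metabolite listed in several pathways yields one
feature per pathway; members absent from the matrix are skipped with a
warning, an absent precursor is an error. Features from all pathways are
concatenated with equal weight. Before clustering, each feature is
z-scored (mean 0, sd 1, n−1 denominator); zero-variance features are
dropped with a warning. The unscaled matrix is also kept for contrast
statistics, which are more interpretable in natural log-ratio units.

**Consensus clustering.** Correlation K-means is realized as Lloyd
iterations on row-standardized data with k-means++ initialization:
for rows standardized to mean 0 and unit sd, squared Euclidean distance
is `2m(1 − r)`, so the distance is monotone in `1 − Pearson r` while
centroids stay well defined; centroids are re-standardized after each
update, and an emptied cluster is re-seeded at the farthest point. The
procedure is repeated `n_reps` times (seeds `seed, seed+1, …`), the
co-association matrix C records pairwise co-assignment fractions, and the
consensus partition is the average-linkage cut of `1 − C` into k groups —
deterministic given the seed. Exact invariance of the consensus to sample
order is not guaranteed per repetition (k-means++ draws depend on row
order), but the consensus is empirically order-invariant on structured
data and is tested as such.

**Cluster-number selection.** Three heuristics are computed over the
candidate range (default 2–8, with k = 1 added to the dispersion and gap
curves):

- *Gap statistic*: `Gap(k) = mean_B log W_k(ref) − log W_k`, with W the
  pooled within-cluster dispersion (equal to within-cluster sum of
  squares in Euclidean geometry), B = 50 reference sets drawn uniformly
  over each feature's observed range (the simple uniform-box variant;
  no PCA rotation), and the usual `s_k = sd_B √(1+1/B)` simulation error.
  Chosen k: smallest k with `Gap(k) ≥ Gap(k+1) − s_{k+1}`, falling back
  to the argmax. The gap statistic clusters the matrix exactly as given
  (plain Euclidean K-means); the pipeline hands it the row-standardized
  ratio matrix, where this coincides with correlation K-means.
- *Elbow*: k maximizing the perpendicular distance from the dispersion
  curve to the chord joining its endpoints; ties break to the smallest k.
- *Silhouette*: `s(i) = (b−a)/max(a,b)` under the Pearson distance, with
  singletons scored 0; chosen k maximizes the mean width.

The combined choice is the majority vote, with a three-way tie deferring
to the silhouette (the only one of the three that directly measures
separation of the final partition).

**Contrasts.** Feature-wise unpaired pooled-variance t-tests (Welch
behind a flag; the equal-variance form is the field's default for
cluster comparisons of this size), with `t = 0, p = 1` defined for the
degenerate constant-and-equal case. The FDR family is all features of one
contrast. The Benjamini–Krieger–Yekutieli two-stage linear step-up runs
BH at `q′ = q/(1+q)`, estimates `m0 = m − r1` from the first-stage
rejections, and reruns the step-up with slope `q′ i/m0`; r1 ∈ {0, m}
short-circuits. Adjusted q-values are the monotone step-up envelope of
`p·m0(1+q)/rank`, so `reject ⇔ q ≤ q*` holds exactly.

**Screen mining.** Screens are long tables (cell line, target, score,
database) with a declared direction; fitness scores and dose–response
AUCs both read lower-is-more-sensitive. After filtering to labeled cell
lines and pathway-annotated targets, each target's scores are z-scored
across the screen's full filtered cell-line set (raw scores behind a
flag, the natural choice for fitness scores that share a scale), and the
differential is the mean z of cluster A minus cluster B, ranked
most-A-vulnerable first with lexicographic tie-breaks. Targets measured
in fewer than two cell lines of either cluster, or with zero variance,
are excluded. The pathway consolidation score — counting each pathway's
targets in every database's top-20, normalizing by the list length and
summing over databases — is this package's own definition of a
"top-list consolidation" and is deliberately simple and pluggable.

## Synthetic data generator

The generator emulates the study design: 5 clusters × 12 cell lines,
triplicates over 6 batches, 3 anchor cell lines present in every batch,
and a 50-metabolite panel spanning seven pathways (glycolysis and the
pentose phosphate pathway ratioed to glucose, the TCA cycle to pyruvate,
and glutamine, serine, proline and methionine pathways to their name
metabolites) plus three unassigned nucleotides. The log10 abundance of
metabolite j in sample i of cell line c is

    x = μ0_j + δ(cluster(c), pathway(j)) + batch(b, j) + s_i + ε

with defaults μ0 ~ N(1.0, 0.4²) per metabolite, batch ~ N(0, 0.3²) per
(batch, metabolite), s ~ N(0, 0.3²) per sample, ε ~ N(0, 0.08²), and a
deterministic cluster-shift table in which cluster g raises pathway
(g−1 mod P) and lowers pathway (g mod P) by 0.5 log10 units — adjacent
clusters disagree in sign on a shared pathway, keeping all profiles
distinct. δ applies to pathway members only, never to precursors, so the
planted "pathway activity" is by construction a product-to-precursor
ratio shift, and a metabolite in several pathways accumulates their
shifts. Screens are simulated per database as
`baseline + effect·1[vulnerable] + noise` with each cluster vulnerable to
its up-shifted pathway. The emitted ground truth is never consumed by the
pipeline under test.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: cell-line-specific metabolite idiosyncrasies
uncorrelated with cluster structure, non-Gaussian measurement error,
missing values, media composition effects, and isotope or ion-intensity
artifacts. One consequence is documented in the acceptance suite: because
the planted cluster shift is additive on member abundances, the clusters
are recoverable from the corrected abundance matrix as well as from the
ratio matrix. The per-sample scaling cannot mask them — it is a per-row
constant, to which the Pearson distance is exactly invariant — so the
real-data phenomenon that abundance-level clustering fails to reveal
pathway structure while ratio clustering does is beyond this additive
generator, and the corresponding check is expected to fail. The ratio
transform's exact cancellation of per-sample scaling, by contrast, is a
theorem and is tested to 1e-12.

## Numerical choices and problem sizes

- Row standardization uses the population sd; feature z-scoring the
  sample sd (n−1) — each matches the convention of its consumer.
- Lloyd iterations cap at 300; convergence is assignment stability.
- The WSS curve for the elbow uses the best of 5 restarts per k.
- Consensus runs use 1000 repetitions by default in the pipeline; the
  test and acceptance analyses use 200 (co-association entries are
  already binary on separated data well below that).
- Summary statistics over generator seeds use 20 panels for recovery
  rates and 5 panels (median) for the clustering-by-batch contrast,
  whose single-panel value varies widely across draws.
- Derived seeds are the base seed plus small offsets; all stay below 2³¹.

## Known limitations

- RUV-III requires a complete matrix; impute before correction.
- Consensus average-linkage cuts can return fewer than k groups on
  degenerate co-association matrices; labels are then relabeled
  consecutively and k reflects the realized number.
- The consolidation score is one reasonable definition among several;
  rank-weighted or size-adjusted variants may behave differently when
  pathway sizes are very unequal.
- No missing-value-aware RUV, no Welch default, no model-based
  clustering, no flux inference from ratios.
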