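# Methods

This note documents the models, defaults, numerical conventions and design
choices behind panelkit, and what the synthetic-data tests do and do not
demonstrate about real data.

## Data model and preprocessing

The reference is a cells × genes matrix of raw non-negative integer counts
with one cell-type label per cell, optional planar coordinates, and an
optional log-normalized layer. On disk, counts are MatrixMarket triplets
stored genes × cells (the 10x convention; transposed to cells × genes on
load) with identifier sidecars, or a dense CSV with genes as the header and
cell identifiers in the first column. Gene symbols match case-sensitively
by default; an opt-in flag relaxes this.

Three filters run in a fixed order — genes with totals below 10 counts,
then cells with totals below 200, then cell types with fewer than 10 cells
— with totals recomputed after each step and removals logged. "Below" is
strict: a total equal to the threshold survives. The defaults suit
deeply-sequenced scRNA-seq references; the synthetic fixtures are shallower
and are filtered with smaller thresholds (or not at all) in the tests.

Normalization is counts-per-10k followed by natural log1p:
`lognorm[i,g] = ln(1 + 1e4 · counts[i,g] / total_i)`. This is the
single-cell convention; every correlation, clustering and classification
metric operates on this layer. Detection-rate quantities (the gsc) use raw
counts, where "detected" means a nonzero count — detection is a property of
the measurement, not of the depth scaling.

## Specificity metrics

**gsc.** `gsc(g,t) = log2((p_in + ε)/(p_out + ε))` on detection rates,
ε = 0.01 on both proportions. "Expression proportion" is deliberately the
detection rate rather than mean expression: detection differences are what
a targeted assay with limited dynamic range can actually exploit, and the
pseudocount bounds the score at ±log2(101) ≈ ±6.66 for all-or-nothing
genes.

**Panel entropy.** The gsc matrix is hierarchically clustered on both axes
(average linkage, Euclidean distance, leaf order as produced by the linkage
with ties broken by input index), reordered, and scored by Moran's I over
the grid of entries with binary rook (4-neighbor) adjacency. With p₀ the
fraction of low-specificity genes — genes whose gsc is non-positive in
every type — the score is `0.5·(1 − (I+1)/2) + 0.5·p₀ ∈ [0,1]`, an equally
weighted convex combination that stays defined when either term
degenerates (a zero-variance matrix gets I := 0 and a degenerate flag).
p₀ is counted per gene, not per entry: a perfectly type-specific gene
still has negative gsc in every *other* type, so an entry-wise count would
grow with the number of types and penalize exactly the panels the score is
meant to reward.

A scale caveat: for small panels over few types (e.g. 15 genes × 3 types)
the grid-Moran term discriminates weakly — an ideal block matrix caps near
I ≈ 0.25 while clustering alone lifts pure-noise matrices into the same
range — so ordering comparisons at that scale are made on medians over
replicate simulations. At realistic scale (hundreds of genes, tens of
types) the blocky structure dominates and single evaluations are stable.

**Variation recovery.** NMI (arithmetic-mean normalization,
`2·I(U;V)/(H(U)+H(V))`) between the annotation labels and k-means on the
top `min(20, n_panel_genes − 1)` principal components of the panel-gene
lognorm submatrix; k defaults to the number of cell types, 10 restarts,
seeded. The labels are the reference partition because they are the
quantity a panel is asked to recover and keep the metric deterministic; a
flag substitutes a seeded full-matrix k-means reference instead. NMI from
very small panels fluctuates with sampling; treat small-panel values with
caution.

**Classification.** Random forest (500 trees, default feature subsampling)
under stratified k-fold cross-validation (k = 5, seeded shuffling).
Balanced accuracy is the unweighted mean of per-type recall pooled over
folds; per-fold balanced accuracies are retained for error bars. Any
estimator with fit/predict can be injected; no hyperparameter tuning is
attempted.

## Diversity

Pairwise Spearman ρ over cells on lognorm for every unordered panel-gene
pair; a pair is redundant iff |ρ| ≥ τ (τ = 0.3), and
`D = (n_orthogonal − n_redundant)/n_pairs`. The signed form is used so a
fully redundant panel reads −1 rather than 0, making redundancy visible at
a glance. Rank-based correlation makes D invariant to strictly monotone
per-gene transforms; zero-variance genes cannot be ranked and their pairs
are assigned ρ = 0 with a warning.

## Biological inference

Over-representation uses the one-sided hypergeometric tail (equivalently
one-sided Fisher) of the panel/pathway overlap within a stated universe —
by default all genes of the filtered reference — with Benjamini–Hochberg
q-values across all tested pathways and significance at q < α (α = 0.05).
Pathways with no universe member are skipped with a warning. The
enriched-gene fraction uses the panel-within-universe size as denominator
(both counts are reported). Pathway diversity visits significant pathways
by ascending q (ties: descending overlap, then name) and greedily keeps a
pathway iff its Jaccard similarity on full member sets (intersected with
the universe) is ≤ 0.7 against everything already kept; the score is
kept/significant, defined as 1 for ≤ 1 significant pathway. Full member
sets (rather than panel-overlap sets) make the similarity stable for small
panels. Ligand/receptor composition is read from a flat gene→category
table; a gene annotated as both counts once, in its own bucket.

## Spatial information

The spatial graph is exact k-NN under Euclidean distance (k = 6, the
hexagonal-packing convention for tissue), ties broken toward the lower
cell index so duplicate coordinates stay deterministic; weights are
row-standardized for Moran's I. Moran's I follows the standard form
`I = (N/W)·Σ w_ij z_i z_j / Σ z_i²`; zero-variance genes return 0 with a
degenerate flag and are excluded from panel aggregation. Neighbor
correlation is Pearson between a gene's lognorm and the mean over each
cell's k neighbors — "nearest neighbors" as the k-NN set, not the single
nearest cell. The panel-level spatial score is the mean over
non-degenerate genes of (I + 1)/2.

## Forward compatibility

Perturbation scoring is defined against a minimal contract — a set of
covered genes and a `respond(gene)` method returning per-gene effect
magnitudes — so that any simulator's exported response matrix (CSV, rows =
perturbed, columns = responding) plugs in unchanged. A gene's score is the
thresholded L1 mass `Σ_{j≠g} |Δ_j|·1[|Δ_j| ≥ δ]` (δ = 0.1), combining the
number and the magnitude of influenced genes in one number. Panel scores
rank-normalize per-gene scores against *all* covered genes via
`(rank − 1)/(n − 1)` with average ranks for ties (the top gene scores 1, a
fully tied model 0.5 everywhere) and average over covered panel genes;
coverage is reported. A seeded sparse linear-response generator, with
optional hub genes wired to 10× more targets, serves as the test model.

## Aggregation

Category scores on [0, 1]: specificity = mean(balanced accuracy,
1 − entropy, NMI); diversity = (D + 1)/2; biology = mean(enriched-gene
fraction, pathway diversity, LR proportion); spatial = mean (I + 1)/2;
forward = panel perturbation score. The overall score is the weighted mean
over *available* categories with weights renormalized to sum to 1 (equal
by default), so scaling all weights is a no-op and missing optional inputs
simply drop their category. Per-gene importance min-max normalizes each
category's per-gene sub-scores *within the panel* (importance is a
contribution to this panel, not a global property); a single-gene panel is
degenerate and reads 0.5 with a warning.

The optimizer's objective is a deliberately cheaper five-term mean —
feature diversity, pathway diversity, 1 − entropy, the spatial term
(omitted without coordinates), NMI — excluding the classifier and the
perturbation model so a single evaluation stays fast; per-term weights are
overridable. The overall report score and the optimizer objective are
distinct, separately documented quantities.

## Genetic algorithm

Population of 50 fixed-size (default 200), duplicate-free panels sampled
uniformly from the candidate pool; each iteration scores all panels
(memoized on panel content), carries the top ⌈20%⌉ unchanged, and refills
by mutating uniformly chosen elites — replacing `max(1, round(0.05·size))`
genes with uniform draws from pool∖panel. Optional single-point
set-crossover of two elites (off by default) precedes mutation; children
are trimmed/filled to size and kept duplicate-free. Elitism makes the best
trajectory non-decreasing by construction. Termination: `max_iters`
(default 5000) or no best-score improvement > 1e−6 for 200 consecutive
iterations. All randomness flows from one seeded generator, so a run is a
pure function of (objective, config). Any callable mapping a panel to
[0, 1] may replace the default objective.

## Synthetic data

The generator emulates exactly the structure the metrics assume, with
ground truth encoded in gene names (`M{t}_{i}`, `HK_{i}`, `NZ_{i}`):

- counts are gamma-Poisson (negative binomial, var = μ + 0.5·μ²);
  markers have mean 4× base (base mean 1.0) in their own type;
- housekeeping genes share one per-cell log-normal latent factor
  (log-sd 1.2 on a base mean of 2.0). The factor is strong because the
  block is a large share of each cell's library: depth normalization
  partially cancels a shared factor, and a weaker one would not leave the
  pairwise correlation the block exists to provide;
- noise genes are independent with base mean;
- per-cell library sizes are log-normal with CV 0.3;
- cell types sit in Gaussian spatial blobs (sd 1.0) around centers spaced
  6 units on a circle, so type-linked genes are spatially clustered;
- the pathway database holds one pathway per type (its markers plus 2
  sampled noise fillers), a housekeeping pathway, and random extra sets;
  the filler count keeps marker panels enriched at q < 0.05 inside the
  small 60-gene universe. The LR table annotates a random 30% of genes,
  split evenly.

Defaults produce 3 types × 100 cells × 60 genes — small enough that every
test and the acceptance script run in seconds, large enough that the
marker/housekeeping/noise contrasts are stable.

What passing on this fixture shows: the metrics detect the structure they
claim to measure, with the expected orderings (markers beat matched noise
panels on classification, NMI, entropy, enrichment, spatial signal; the
housekeeping block is less diverse than noise; pure dilution genes never
increase the significant-pathway count). What it does not show: behavior
under batch effects, ambient contamination, doublets, annotation errors,
realistic pathway-database redundancy, or tissue morphology — none of
which the generator models.

## Numerical conventions and degenerate inputs

- Zero-variance inputs: Moran's I := 0 with a degenerate flag; spearman
  pairs := 0 with a warning; constant gsc matrices flagged degenerate.
- Tie-breaking is deterministic everywhere: k-NN ties by lower index,
  clustering leaf order by linkage input order, pathway pruning by
  (q, −overlap, name), rank normalization by average ranks.
- All stochastic components (k-means, cross-validation folds, forests, the
  GA, the generator) are seeded through explicit parameters; reports echo
  every parameter and seed, and identical configurations produce
  byte-identical outputs.
- Thresholds (ε, τ, α, Jaccard cut, δ, k) are package-level defaults in
  `MetricConfig`, chosen once as field-conventional values and exposed in
  the config file and CLI.

## Known limitations

- The entropy score's grid-Moran term is weakly discriminative for small
  panels over few cell types (see above).
- The hypergeometric model treats genes as exchangeable; correlated gene
  sets inflate significance as in any ORA.
- NMI depends on the annotation granularity; panels can only be as good as
  the labels they are scored against.
- The GA is a single-population mutation-first design; it finds good
  panels quickly at test scale but no optimality guarantee exists beyond
  the enumerable toy used in the tests.
- Perturbation scoring is only as good as the supplied response model; the
  bundled linear model is a synthetic stand-in for testing the scoring
  contract, not a biological simulator.
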