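# Methods

This note documents the models implemented in `driverscope`, the
assumptions behind them, the defaults that matter, and the places where a
genuinely open design choice had to be made. Numbers quoted here are
defaults or definitions, not empirical claims; everything measurable is
measured by the test suite and `scripts/acceptance.py`.

## Gene-set scoring

**ssGSEA.** Per sample, genes are ordered by decreasing expression, ties
broken by gene identifier so results are bit-reproducible. The rank
statistic assigns the top gene the value G (universe size) and the bottom
gene 1. For a set S, the running sum steps up by rᵅ / Σ_{g∈S} rᵅ at in-set
genes and down by 1/(G−|S|) elsewhere; the enrichment score is the sum of
the running sum over all G positions (the single-sample integral form, not
the max-deviation GSEA form). α defaults to 0.25, the common single-sample
convention; it is exposed because published analyses differ. NES divides
every ES by (max − min) over the entire ES matrix — a cross-matrix
normalization, so NES values are only comparable within one scored matrix.
Sets overlapping the matrix by fewer than `min_overlap` (default 5) genes
are skipped with a warning.

**AUCell.** With cutoff n_top = ⌈k·G⌉ (k = 0.05 by default, the
top-ranking fraction a droplet-based cell's reliable signal occupies), the
score is the area under the cumulative set-gene recovery curve over ranks
1..n_top divided by the maximum attainable area (all |S| genes at the very
top). The score is 1 exactly when the set fully occupies the top ranks and
0 when it is absent from them. Note a consequence of this normalization:
the score is not monotone in k, because the normalizer grows with the
cutoff; the un-normalized area is monotone, and that is the property the
suite asserts.

Both scores depend on ranks only, hence are invariant to monotone
per-sample transformations (library-size scaling, log transforms).

## Bulk survival modeling

**Cohort splitting.** Subjects within ±90 days of a landmark (365, 1095,
1825 days) are guaranteed representation in both partitions whenever at
least two are eligible; the rest are split 7:3 stratified by event status
with largest-remainder rounding. The ±90-day tolerance is a package
decision (the convention "close to a landmark" needs an operational
definition) and is configurable.

**Cox solver.** Newton iterations on the Breslow partial likelihood with
step-halving, convergence at gradient norm < 1e-8, at most 100 iterations.
Breslow ties (rather than Efron) were chosen because they match the
elastic-net Cox convention used downstream and are the easiest to verify
against an independent oracle; the solver is cross-checked in the suite
against both a grid-search maximization of a hand-coded likelihood and
scikit-survival's Breslow implementation. Monotone likelihoods (perfect
separation) are detected by |β| > 20 and reported as errors rather than
silently returned. An optional ridge penalty supports the shipped
penalized-Cox learner.

**Univariate screen.** One single-covariate fit per feature, Wald p,
Benjamini–Hochberg adjustment, retain q ≤ 0.05. Zero-variance and
unfittable features are reported as skipped, never silently dropped.

**Stability selection.** Per resample, 70% of subjects drawn *with
replacement*; an elastic-net Cox path (l1_ratio = 0.1, 50 log-spaced λ
from the data-derived λ_max down to 0.01·λ_max) is fitted via
scikit-survival's Coxnet, and a feature counts as selected if its
coefficient is non-zero at any λ. A structural limitation of this
selection rule deserves emphasis: when subjects far outnumber features,
the low-λ end of the path is essentially unpenalized, every feature's
coefficient is non-zero somewhere on the path, and all selection
frequencies saturate near 1 — the rule discriminates only when features
are numerous relative to subjects (its original setting). The suite
documents this behavior rather than hiding it; frequencies are still
reported exactly as defined.

**Discrimination.** Harrell's C counts event-anchored comparable pairs
(event at tᵢ vs later follow-up, or equal-time censoring), risk ties 0.5,
and returns 0.5 with a warning when no pair is comparable. Time-dependent
AUC is the cumulative-case / dynamic-control IPCW estimator: cases by
horizon t weighted by 1/Ĝ(Tᵢ⁻) with Ĝ the Kaplan–Meier estimator of the
censoring distribution, controls unweighted; horizons at or beyond the
maximum follow-up are undefined (NaN), not errors.

**Benchmark harness.** Learners enter through a minimal contract —
`fit(features, survival)` and `risk(features)`, higher risk = worse — with
a declared hyperparameter space. Hyperparameters are drawn by seeded
uniform random search (a deliberate replacement for adaptive tuners:
reproducible, contract-agnostic) and scored by mean 5-fold CV C-index; the
winner is refit on the full training set and evaluated (C, td-AUC) on all
supplied cohorts. The shipped reference learner is the in-package ridge
Cox; external learners (random survival forests, gradient boosting, etc.)
plug in through the same contract and are intentionally not
re-implemented.

**Attribution.** Monte-Carlo Shapley: per sampled feature ordering,
features flip one at a time from the baseline (training mean) to the
patient's value and the marginal risk change is credited to the flipped
feature. Credits sum exactly to prediction − baseline prediction per
permutation, so additivity holds by construction; for additive models the
estimate collapses to coefficient × (value − baseline). Global importance
is the per-feature mean over patients, positive = risk-increasing.

## Single-cell malignancy

**QC.** Cells pass with 200–10,000 detected genes, ≤20% mitochondrial and
≤15% hemoglobin count fractions; genes detected in fewer than 50 surviving
cells are dropped when gene filtering is on.

**CNV surrogate.** On log-normalized expression in (chrom, start) gene
order: subtract the reference-cell mean per gene, clamp residuals to ±3
(so a single outlying gene cannot mimic a focal event), and smooth with a
centered 100-gene running mean within each chromosome, truncated at ends
(min-periods 1). Chromosomes with fewer than 10 annotated genes are
excluded. The per-cell CNV score is the mean squared smoothed deviation —
a declared convention, since "CNV score" has no canonical formula. The
expected behavior of this surrogate: a planted fold-f block appears as a
plateau with half-window ramps; cell-type expression differences also leak
into it, which is why calls are anchored to a non-malignant reference.

**Focal calls.** Per driver gene, robust Z against the reference:
(value − median) / (1.4826·MAD, floored at 1e-6). Gain iff Z ≥ 2, loss iff
Z ≤ −2. The ±2 threshold is the conventional robust outlier cut (the
labeling rule needed a number); under a clean reference it implies a
nominal ≈4.6% false-call rate per gene, which is exactly what the
simulations measure. Missing driver genes are reported, not fatal.

**Resolution selection.** Community detection runs through an injectable
partitioner contract `(adjacency, resolution, seed) → labels`; the default
is Leiden (RB-configuration). Each partition is scored by Euclidean
silhouette on the *supplied* embedding (single-cluster partitions score
−1) and the argmax resolution wins, ties to the smallest. Which embedding
to hand in (expression PCA vs CNV-profile PCA) is the caller's recorded
choice.

**Labeling.** A query cluster is tumor-like iff its mean CNV score exceeds
the reference mean by ≥2 reference SDs OR ≥30% of its cells carry any
driver gain/loss; reference cells are always labeled "reference". Both
thresholds are package decisions for a rule the source analyses describe
only qualitatively.

## Co-expression modules

Unsigned adjacency |cor|^β with β the smallest power whose signed
scale-free fit R² (log-binned degree distribution, ≥5 occupied bins)
reaches 0.85, else the argmax with a warning. TOM similarity
(Lᵢⱼ + aᵢⱼ)/(min(kᵢ,kⱼ) + 1 − aᵢⱼ), average-linkage clustering of 1 − TOM,
*static* cut at height 0.99 — a deliberate simplification over dynamic
tree cutting: fully specified, oracle-checkable, and adequate for planted
block structure, at the cost of less adaptive branch detection on real
dendrograms (a declared limitation). Branches under 30 genes go to grey;
modules whose eigengenes (first PC of standardized member expression,
sign-oriented to positive mean member correlation) correlate above
1 − 0.25 are merged iteratively. Module–trait statistics are Pearson
correlations with t-approximation p-values; constant traits report NA.

## Prioritization

**Differential expression** is a Welch t-test on log-scale values with BH
adjustment: the single-cell rule q < 0.05 & |log2FC| > 1, the bulk rule
q < 0.05 & |log2FC| > 0.5. Empirical-Bayes moderation is intentionally not
used — the thresholds, not the variance model, drive the downstream
intersection — and this is the main fidelity gap for very small groups.

**Diffusion pseudotime.** kNN graph (k = 15) on the top principal
components, adaptive Gaussian kernel (bandwidth = distance to the k-th
neighbor), density normalization, symmetric normalization,
eigendecomposition; pseudotime is the diffusion distance (components
weighted λ/(1−λ)) from the root cell, rescaled to [0, 1]. The root is an
explicit cell id, or the argmax of a user-supplied potency score —
automated potency inference is out of scope, so the choice is surfaced
rather than hidden. Disconnected graphs raise an error advising a larger
k.

**Trends** are per-gene Spearman correlations with pseudotime (BH over
non-constant genes), hence invariant to monotone reparameterizations of
the pseudotime axis.

**Intersection.** The candidate table covers the union of the four
evidence sets (co-expression module, single-cell DE, up in bulk cohort 1,
up in bulk cohort 2), optionally restricted to a catalog (e.g. a
deubiquitinase list); core candidates are the exact four-way intersection,
ordered by evidence count then gene id.

## Communication and motifs

**Ligand–receptor.** Score = mean(ligand | sender) × mean(receptor |
receiver); null = group labels permuted over all cells; p uses the add-one
estimator (1 + #{null ≥ obs})/(1 + N), so p ∈ [1/(N+1), 1]. Significance
additionally requires ligand log2FC > 1 versus all non-sender cells
(pseudocount 1e-9 guards empty means). This single-score permutation
construction deliberately replaces multi-method consensus aggregation
frameworks; the permutation null and the joint rule are the portable core.

**Axis score.** Mean of per-gene min-max-scaled expression over the
available axis genes (absent or constant genes dropped and recorded). The
formula is a declared package definition: composite "axis scores" in the
literature are typically named but not defined.

**Promoters.** Strand-aware windows of −1000/+100 around the TSS (gene
start on +, gene end on −, minus-strand sequences reverse-complemented),
truncated at contig bounds. Coordinates are 0-based half-open throughout.

**Motif scanning.** Log2-odds PWM scores (probabilities floored at 1e-9)
are integerized at scale 1000 (rounding error < 0.001 bits/position); the
null distribution of the integer score under the background model is
computed *exactly* by dynamic programming over motif columns, and a window
is a hit iff P(score ≥ s) < 0.01 on either strand (reverse-strand scores
come from the reverse-complement matrix against the forward sequence).
N bases contribute zero score. Because the null is exact and discrete, the
background hit rate is at most — and typically well below — the threshold;
note that a per-window threshold of 0.01 still implies up to ~1 hit per
100 background windows, so downstream analyses should treat hits as
candidates, not confirmations.

## Synthetic data: what it emulates, and what it does not

**Bulk cohorts.** Latent pathway activities a_p ~ N(0,1) per sample map
onto member genes plus N(0, noise_sd²) noise (noise_sd = 1, log2 scale —
member-gene correlation ≈ 0.5, typical for curated pathways). Survival is
exponential proportional hazards with linear predictor Σ θ_p a_p and
baseline rate ln2/365 per day (median survival ≈ 1 year at baseline, an
aggressive-carcinoma scale); censoring is independent exponential with
rate calibrated to the target censored fraction (0.3) at the baseline
predictor, so the achieved fraction fluctuates and is recorded in the
ground truth. Defaults: 200 samples, 2000 genes, 20 disjoint pathways of
20 genes.

**Single-cell data.** Negative-binomial counts (dispersion r = 2, a
typical droplet value) with log-normal library sizes (mean 5000, sd 0.2 on
the log scale), per-type marker blocks (8×) for clustering signal, and
planted effects applied multiplicatively to expected counts: CNV blocks
(fold f on contiguous genomic ranges in malignant cells — applied after
library scaling so a 2× block truly doubles expected counts, as a genuine
copy-number gain would), DE genes (2^log2FC), ligand/receptor elevation in
sender/receiver types, and pseudotime trends on a uniform latent u ∈ [0,1]
over malignant cells: "late-up" = logistic rise centered at u = 0.6,
"down" = logistic fall at 0.4, "early-peak" = Gaussian bump at 0.25
(amplitude 3 on log2 scale). Genes sit 2 kb apart on evenly split
chromosomes.

**Promoters.** I.i.d. uniform background with consensus-sampled motif
instances planted at recorded positions in a chosen fraction of
sequences.

**What passing these simulations does not show.** No batch effects,
doublets, ambient RNA, spatial structure, gene–gene correlation beyond the
planted blocks, non-proportional hazards, or informative censoring.
Recovery rates measured here are upper bounds on real-data performance;
the simulations validate the *computations*, not biological discovery
power.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run at desk scale, chosen as
the smallest sizes at which each statistical claim is decidable: 100
cohorts of n = 300 for log-HR recovery, 50 pathways / 100 bootstrap
resamples for stability frequencies, ~650 cells / 1000 genes for the CNV
pipeline, 200 genes in two 50-gene blocks for module recovery, 100
promoters of 200 bp for motif recovery, 1000 permutations for the planted
ligand–receptor pair. Tie-breaks are lexicographic everywhere a rank is
taken; all stochastic steps consume an explicit seed; MAD floors (1e-6),
PWM probability floors (1e-9) and the ±3 residual clamp are the only
numerical guards, each stated where it acts.
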