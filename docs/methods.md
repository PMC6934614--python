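# Methods

## Model and estimation

The outcome for sample *i* is a vector of taxa read counts `x_i` with depth
`N_i`. Within any node of the tree the samples are modeled as i.i.d.
Dirichlet-multinomial (DM) with mean composition `π` and overdispersion
`θ ∈ [0, 1)`. The pmf is evaluated in log space throughout; the rising-factor
products are rewritten with log-gamma identities,

```
Σ_{r=1..x} log(a + (r−1)θ) = x·log θ + lgamma(a/θ + x) − lgamma(a/θ),
```

so the cost of a likelihood evaluation is independent of read depth (depths
of 5×10⁴ are routine). The `x·log θ` terms of numerator and denominator
cancel exactly and are dropped. Multinomial coefficients are parameter-free
and are excluded from all likelihood-ratio computations by default (they
cancel in every ratio); `include_coefficient=True` restores them for oracle
checks against the plain multinomial pmf.

Estimation is by the method of moments. `π̂` is the pooled proportion
vector. `θ̂` equates depth-weighted between-sample and within-sample variance
components:

```
S_j = 1/(N−1) Σ_i N_i (p_ij − π̂_j)²           (between)
G_j = 1/Σ_i(N_i−1) Σ_i N_i p_ij (1 − p_ij)     (within)
n_c = (Σ_i N_i − Σ_i N_i²/Σ_i N_i)/(N−1)
θ̂  = Σ_j (S_j − G_j) / Σ_j (S_j + (n_c − 1) G_j)
```

with `p_ij = x_ij/N_i`. Negative estimates (under-dispersion) clamp to 0 and
estimates ≥ 1 clamp to `1 − 1e-9`; a single-sample group, or a group where
every sample has one read, yields `θ̂ = 0`. MLE fitting is deliberately out
of scope — MoM is orders of magnitude cheaper inside the split search and is
the estimator this model family is normally used with. Taxa absent from a
node get `π̂_j = 0` and contribute empty products to the pmf; no pseudocounts
are added. A consequence of the finite-sample `(N−1)`-style weights worth
knowing: the fit of a group and the fit of that group duplicated are not
identical, so the LLR of a split into two copy-identical halves is near but
not exactly zero.

## Split search

Candidate cuts for a covariate are the midpoints between adjacent distinct
observed values within the node; cuts leaving fewer than `min_bucket`
(default 5) samples on either side are skipped, and nodes smaller than
`min_split` (default 10, constrained to ≥ 2·min_bucket) are not split. Each
cut is scored by `|LLR| = |LL_parent − (LL_left + LL_right)|` with per-group
MoM fits (DM mode) or by the weighted Gini impurity decrease (classification
mode). Ties break by covariate column order, then by smaller cut point, which
together with midpoint cuts makes growth deterministic and invariant to
sample order. The literal largest-`|LLR|` rule is used; because MoM fits are
not likelihood maximizers, a split can occasionally have `LLR > 0` (children
fit worse in deviance). Such splits are admitted at growth time and are the
first branches removed by pruning (below).

The split scan is vectorized: samples are sorted by the covariate once, all
left/right MoM fits are obtained from prefix sums, and the lgamma sums for
all cuts are evaluated as a (cuts × samples × taxa) tensor cumulated over
samples, chunked to bound memory at a few tens of MB. This is what makes
repeated cross-validation at N of a few hundred affordable.

Routing is `value ≤ cut → left`, serialized with the tree. Rows missing a
covariate are excluded from that covariate's evaluation; at assignment and
prediction time a missing value follows the child with more non-missing
training samples (ties → left). Surrogate splits are not implemented. Only
binary categorical covariates are supported, pre-encoded 0/1 (a declared
string mapping is available at load time); multi-level factors must be
dummy-encoded by the user.

## Pruning and tree selection

Node scores are misclassification counts (classification) or node deviance
`−LL` without coefficients (DM). Weakest-link pruning repeatedly collapses
the internal node(s) minimizing

```
g(t) = (S_t − Σ_{leaves under t} S_l) / (|leaves under t| − 1),
```

giving the unique nested sequence of subtrees. Alphas are reported relative
to the root error; the CP-table row for subtree `T_k` carries the `g` at
which the next larger subtree collapses into `T_k`, and the full tree carries
α = 0 — so α is non-increasing as complexity grows, and only weakest-link-
attainable sizes appear as rows. Relative error is the error ratio to the
unsplit root (exactly 1 on the root row); in DM mode this is a deviance
ratio, which, unlike the classification case, is not guaranteed monotone in
tree size when positive-LLR splits were admitted. Negative `g` values (from
such splits) clamp to α = 0 and collapse first.

Cross-validation follows the all-data-α procedure: fit the full tree on all
data and record its α levels; per repetition, split the samples into
`folds` (default 10) random near-equal subsets without stratification; per
fold, refit the full tree on the remaining data and prune *that* tree at each
recorded α level (each fold tree's own weakest-link sequence, its g values
normalized by its own root error; no geometric-mean smoothing of α). Held-out
samples are routed through the pruned fold tree and scored by the mean
squared Euclidean distance between their frequency vectors and the terminal
`π̂` of the fold fit — the PRESS statistic ("mean" rather than "total" so
fold sizes do not weight the score); classification mode substitutes the
misclassification rate. Fold means are averaged, repetitions (`M`, default
100) are averaged, and the SE across repetition means feeds the 1-SE rule.
Selection: `min_cv` takes the smallest mean CV error (ties → smaller tree);
`one_se` takes the simplest subtree within one SE of that minimum. Either may
return the root, reported as "no split". CV-error columns are printed on the
root-relative scale in classification mode and on the absolute PRESS scale in
DM mode, matching how such tables are conventionally displayed; selection is
invariant to the scaling.

## Synthetic data

The simulator compounds `p ~ Dirichlet(π(1−θ)/θ)` with
`counts ~ Multinomial(reads, p)` (`θ = 0` goes straight to the multinomial;
zero-π taxa keep zero mass). The default study design mirrors a three
body-site experiment: three groups with distinct compositions, equal group
sizes (40/80/120 per group), shared `θ ∈ {0.08, 0.2, 0.6}`, 50,000 reads per
sample, and one normal covariate per sample with group means −1/0/1 and
shared SD ∈ {0.2, 0.35, 0.5}; group labels are never shown to the fit. The
three composition presets are a J = 20 log-linear abundance decay, a cyclic
shift of it, and its reversal — deterministic stand-ins for body-site MoM
estimates that are not publicly tabulated, so the study's absolute error
values are not comparable to any published table; only the direction of its
trends is meaningful. The study driver uses common random numbers (replicate
*r* shares its seed across cells) to sharpen between-cell contrasts.

What the generator does *not* emulate: variable read depth, zero-inflation
beyond what DM sampling produces, taxon-taxon correlation structure other
than the compositional constraint, multiple informative covariates, or
covariate measurement error. Passing tests therefore demonstrate correctness
of the machinery and sensible behavior on DM-generated data, not performance
on real sequencing runs.

The evaluation metric is the terminal-node MSE: the average over terminal
nodes of the mean squared Euclidean distance between member frequency vectors
and the node `π̂`; for held-out data, membership is by routing. Empty
terminal nodes are excluded with a warning.

## Numerical and design choices

- θ clamps: `[0, 1 − 1e-9]`; split-score improvement threshold `1e-9`;
  pruning tie tolerance `1e-12`.
- Heap node ids (root 1, children 2k/2k+1) so pruned trees keep stable ids.
- Fold assignment is a permuted `i mod folds` pattern, giving near-equal
  folds for any N.
- The worked-α convention `(re_small − re_large)/(size_large − size_small)`
  is exposed as `cost_complexity_alpha` and is the same arithmetic the
  CP table rows are built from.
- Scaled problem sizes in the shipped study and trend checks (20 replicates
  per cell, CV repetitions M = 3, five design cells) keep a full run in
  minutes; `CVConfig.repetitions` defaults to 100 for real analyses.
- Known limitations: no surrogate splits; no multiway splits; no BIOM/QIIME
  ingestion (TSV/CSV only); no significance testing of the selected tree —
  the tree is an exploratory device, and any hypothesis it suggests should be
  confirmed on independent data.
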