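# Methods

`clonotrace` implements the computational side of single-cell clonal assays
used to map lineage restriction in sorted human haematopoietic stem/progenitor
compartments: colony lineage calling from gated flow counts, normalization of
index-sorted surface-marker intensities, in-silico derivation of sorting gates,
quiescence-exit kinetics, limiting-dilution repopulation-frequency estimation,
and scRNA-seq quality control with spike-in-anchored highly-variable-gene
selection. This note records the models, the parameters that matter, and the
choices made where the design was genuinely open.

## Colony and engraftment calling (`flow_readout`)

Inputs are already-gated event counts per well (no FCS parsing). A well holds a
colony when CD45-total plus GlyA+ events reach 30 cells; each lineage is called
from its own gate at the same 30-cell threshold (Ery: CD45−GlyA+; Meg: CD41+;
My: CD45+CD14+ plus CD45+CD15+; NK: CD45+CD56+; in the B/NK assay B:
CD45+CD19++, My: CD45+CD11b+). Myeloid colonies are sub-typed as Mono, Gran or
MonoGran from the CD14/CD15 gates; the published rules use both "≥ 30" and
"≤ 30" and therefore overlap at exactly 30 cells, which we resolve by
precedence (MonoGran, then Gran, then Mono), configurable via the threshold
argument. Three further conventions the count rules do not pin down:

* colony *presence* uses the total CD45+ gate plus GlyA+ events (the CD45
  subset gates are sub-gates of CD45-total);
* colony *size* additionally counts CD41+ (Meg) events;
* bias within My/NK and My/Ery colonies (partner-lineage count vs My count) is
  `unbiased` on an exact tie.

Xenograft marrow is engrafted when (%CD45++ + %GlyA+) ≥ 0.01% with at least 30
recorded human cells; graft lineages use 20-cell gates (My: CD33+, Ly: CD19++,
Ery: either GlyA+ gate variant), and multilineage means all three at once. All
thresholds are arguments with these defaults.

## Index-sort normalization (`indexsort`)

Raw index-sort intensities span decades and can be negative near zero, so each
channel is mapped to the logicle (biexponential) scale. With A = 0 the forward
map for y ≥ W is

    B(y) = T · 10^−(M−W) · (10^(y−W) − p²·10^−((y−W)/p) + p² − 1),

extended odd-symmetrically about y = W, with p the root of
W = 2p·log10(p)/(p+1). Parameters are estimated per channel: T is the channel
maximum (instrument top-of-scale is not recorded in index CSVs; overridable),
M defaults to 5.1 decades, and W = max(0, (M − log10(T/|r|))/2) with r the 5th
percentile of the negative events — the common data-driven heuristic behind
the estimator this module mirrors; channels without negatives get W = 0. The
inverse (`logicle`) is computed by bracketed root-finding on [0, M] to
|B(y) − x| ≤ 1e−8·max(1, |x|); `transform_table` clamps values outside
[B(0), T] to the range edge, as flow display software does. Note that under
this forward map B(M) differs from T by O(T·10^−2M), so `logicle(T)` equals M
only to ~1e−3; the round-trip identity is exact to tolerance everywhere.

Multi-day sorts are harmonized with a parametric empirical-Bayes
location/scale adjustment: features are standardized against the
batch-structure fit, per-batch feature means and variances receive
moment-matched normal and inverse-gamma priors, and posterior estimates are
iterated to a 1e−4 relative tolerance before adjusting and restoring scale (no
covariates — the sort design has none). Two deliberate deviations from the
textbook procedure: a single batch returns the input unchanged, and after
adjustment every feature is recentred *exactly* to its original grand mean
(the EB adjustment preserves grand means only approximately; downstream
consumers assume exact preservation). A cross-check against an independent
Bioconductor implementation agrees to numerical precision after centring.
One calibration caveat worth recording: when a planted batch shift is
*identical across all features*, the EB hyperprior variance reflects only
sampling noise, shrinkage toward the common mean is heavy, and ~0.03 residual
batch-mean differences remain — in any implementation of this adjustment, not
just ours. Removal is effectively complete when batch effects differ across
features, which is the realistic regime and the one our recovery tests plant
(per-feature shifts N(2, 0.8²), scales U(0.7, 1.5)).

PCA runs on mean-centered (not variance-scaled, by default) normalized
intensities via SVD; loadings are unit-norm with the largest-magnitude loading
of each component made positive so signs are reproducible. Group comparisons
dispatch to standard implementations: Kruskal–Wallis with Dunn z-tests and
Bonferroni adjustment (the publication names no post hoc; Dunn/Bonferroni is
the conventional default), one-way ANOVA with Tukey HSD, Mann–Whitney, paired
t, and the two-sided Fisher exact test. Median shifts between groups are
reported on raw intensities (the scale is unstated in the source; raw is the
interpretable one for instrument units).

## Gate optimization (`gates`)

The sorting-gate derivation is an exhaustive scan: candidate thresholds are
all observed values of the two markers (CLEC9A and CD34 by default, on the
normalized scale), gates are axis-aligned rectangles (one of two corner
orientations), and for every threshold pair meeting a minimum occupancy
(default 0.10 of the compartment, preventing trivial one-cell gates) the
enrichment of a target outcome among gated cells is computed from 2-D
cumulative counts. The argmax is returned; ties break toward larger occupancy,
then smaller x-threshold. Because many threshold values describe the same cell
set (any value inside a data gap), the best gate is reported in its *tightest*
representation — thresholds at the extreme member values — which leaves
membership unchanged and makes recovery checks well-posed. For the same
reason, recovery distance (`threshold_step_distance`) is counted in
*gate-relevant* cells between recovered and planted thresholds rather than in
marginal order statistics: cells that do not satisfy the other marker's
condition cannot move a gate boundary, and counting them would make the metric
depend on noise the scan cannot resolve. Enrichment is computed over
colony-forming cells only, matching how colony percentages are defined.

## First-division kinetics (`kinetics`)

Wells are observed every 12 h for 4 days; the cumulative fraction divided by
time t uses all non-empty wells in the denominator (censored wells never enter
the numerator), so never-dividing wells depress the plateau rather than being
discarded. The curve is summarized by a Hill sigmoid in linear time with
bottom fixed at zero,

    F(t) = plateau / (1 + (ec50/t)^hill),

fitted by ordinary unweighted least squares with multi-start initialization
(ec50 at the increment-weighted time quartiles, hill in {1, 2, 4}, plateau at
the maximum observed fraction; bounds keep ec50 positive, hill in
[0.05, 60], plateau in (0, 1]). The exact sigmoid family behind the published
"non-linear fit (non-log)" is not printed; the Hill form in linear time with a
free plateau is its minimal three-parameter realization. Internally time is
rescaled by max(t) and the fitted ec50 mapped back, which makes unit changes
(hours → minutes) rescale ec50 *exactly* and leave hill and plateau
bit-identical.

Two curves are compared by the extra-sum-of-squares F-test: the null model
fits one sigmoid to the pooled points (df₀ = nₐ + n_b − 3), the alternative
fits each curve separately (df₁ = nₐ + n_b − 6), and
F = ((RSS₀ − RSS₁)/3)/(RSS₁/df₁) is referred to F(3, df₁). The test's nominal
calibration assumes roughly independent point errors; our null simulations
accordingly add i.i.d. Gaussian noise (σ = 0.02) around one sigmoid and land
at a 4–6% rejection rate at α = 0.05. Cumulative curves built from counts have
serially dependent errors, so on real well data the p-values are indicative,
as they are in the standard practice this reproduces. Parameter recovery under
realistic well-sampling noise (150 wells drawn from the model, the
per-experiment scale of these screens) gives a median EC50 error of ~4–5%.

## Limiting dilution (`lda`)

Engraftment follows the single-hit Poisson model: a graft of d cells from a
population with repopulating-cell frequency f is negative with probability
exp(−f·d). The log-likelihood over cohort rows (dose, mice, engrafted) is
strictly concave in f whenever any mouse engrafted; `SingleHitModel.fit()`
finds the MLE as the root of the score by bracketed Brent iteration (matching
the single-dose closed form −ln((n−k)/n)/d to 1e−10 and a 10⁶-point likelihood
grid to 1e−6 relative). Interior confidence intervals are Wald on log f,
exp-transformed — the conventional default in extreme-limiting-dilution
practice; the source names only the method family, not the interval. Boundary
cohorts are flagged: with no engrafted mice the 95% upper bound solves the
one-sided profile equation f·Σ(n·d) = χ²₁(0.95)/2 (the "1.92/(n·d)" rule);
with all mice engrafted a symmetric profile lower bound is reported. Interval
coverage at f = 1/100 with 3 doses × 8 mice is 94–96% over 1000 simulated
cohorts. Two cohorts are compared by a likelihood-ratio test against a pooled
single-frequency model (χ²₁); its type-I error calibrates to 5–7% and its
power in the published frequency regime (1/13 vs 1/685, 24 vs 21 mice over 3
doses) exceeds 95%. Mice failing the engraftment call count as negatives; no
intermediate category exists. The exact published dose levels live in
supplementary material not bundled here, so the published point estimates are
reproduced in regime (via simulation at those frequencies) rather than from
the original table; `io.read_lda_csv` ingests any such table directly when
available.

## scRNA-seq QC and HVG selection (`scqc`)

Cells pass QC when more than 2×10⁵ reads map to gene features, the
gene-mapping fraction exceeds 0.20, and mitochondrial reads are below 0.20 of
mitochondrial + nuclear reads. The middle criterion's published phrasing is
ambiguous ("> 20% of genes over the total number of reads"); we read it as the
mapping fraction, with a `detected_genes` switch implementing the alternative
(fraction of endogenous genes detected). Depth normalization uses
median-of-ratios size factors on endogenous genes only (spike-ins excluded by
construction), rescaled so the factors' geometric mean is 1 — which makes
factor *ratios* exactly equivariant under scaling one cell's counts.

Highly variable genes are selected against a technical-noise baseline
anchored on ERCC spike-ins: per gene, the mean and CV (natural scale, logs
base 10) of size-factor-normalized counts; an ordinary least-squares quadratic
of log10 CV on log10 mean fitted over spike-ins with normalized mean above
`mean_for_fit` = 10; a gene is an HVG when its log10 CV exceeds the prediction
by more than `margin` (default 0, i.e. strictly above the curve — increasing
the margin can only shrink the set). The published pipeline fits the same
quadratic relationship inside a GAM wrapper; OLS is that relationship's
minimal form. Published HVG counts depend on the deposited matrices and are
not recomputed here. ComBat-style batch adjustment of expression applies the
`indexsort` adjustment to genes with total count > 1, passing the rest through
untouched.

## Synthetic data (`synthetic`)

The generators produce every input type with the structure the analysis
assumes, always alongside the planted truth, and are byte-identical under a
fixed seed.

**Index sort.** Each cell has a 1-D latent state s ~ U(0, 1) — the polarized
differentiation continuum; richer latent structure is out of scope. CLEC9A
log10-intensity falls (slope −1.2/unit s) and CD34 rises (+1.2) with Gaussian
log-noise (σ = 0.25); the other seven markers are pure noise around fixed
baselines chosen clear of the near-zero linear zone so the gradient, not
background, carries the PCA structure (additive instrument noise σ = 8 raw
units still produces occasional negative events on the dimmest channels, so
the W-estimation path stays exercised). Two sort batches carry planted log10
shifts (0, 0.15). Colony outcomes follow a softmax of per-class linear logits
in s − ½ with symmetric defaults: Ery-containing classes decrease in s,
NK-containing increase, My and quadrilineage flat, ~10% empty wells — so the
intermediate zone contains My/Ery and My/NK in near-equal proportions.
Division times are lognormal (σ = 0.35) around fate-class medians — not
printed in the source, so chosen once to encode its qualitative finding that
Ery-containing cells exit quiescence slowest: Ery 66 h > quadri/trilineage
60 h > My 54 h > NK 42 h — with a 0.9 dividing fraction, snapped up to the
12 h grid and censored at 96 h. Gated colony counts are Poisson around 120
cells per present lineage (My split across Mono/Gran/MonoGran patterns), far
enough from the 30-cell rules that classification recovers the planted
outcome except in rare tail draws. `plant_gate_outcomes` labels cells
deterministically by the 70th/30th percentile corner rule for gate-recovery
tests.

**Limiting dilution.** Each mouse engrafts independently with
1 − exp(−f·dose); the cohort layouts used in tests mirror the published
design (2–3 dose levels, 7–8 mice per dose).

**Counts.** Endogenous gene g in cell j is negative-binomial with mean
μ_g·depth_j·batch_shift_j and dispersion φ_g = a/μ_g + b (a = 0.5, b = 0.05);
gene means are lognormal (median 100, log-sd 1.2) over 2000 genes × 200
cells by default. Spike-ins (50) share one expected value per gene across all
cells — no depth or batch scaling, as for a constant input dilution. Planted
HVGs (100 genes) have dispersion scaled ×8 and are drawn among genes with
mean above the HVG fit window, so the sensitivity check measures the
selector, not shot noise at unmeasurable means. Mitochondrial gene means are
rescaled to hold the configured share (default 5%) of endogenous reads in
expectation.

**What the generators do not emulate** — and hence what passing tests do not
show about real data: doublets and ambient RNA; non-rectangular or compensated
flow populations; batch effects that interact with the latent state;
interval-censoring subtleties beyond the 12 h grid; multi-hit or heterogeneous
engraftment; overdispersion structure beyond NB with a two-parameter mean–
dispersion trend. Recovery results certify the estimators under their stated
models, not robustness to these violations.

## Pipeline and sizes

`run_demo` chains simulate → classify → normalize → gate scan → kinetics →
limiting dilution → scQC on one seed and writes a manifest with SHA-256
checksums; re-running with the same seed reproduces every output checksum.
Default problem sizes (400-cell demo screens, 800-cell gate-recovery screens
matching the published 819-cell experiment, 150-well kinetics, 1000/500/200
Monte-Carlo replicates for coverage/calibration/power) keep a full run to
about a minute on one core while holding Monte-Carlo bands a few times tighter
than the quantities they check.

## Known limitations

* The Wald-on-log-f interval can undercover for very small cohorts with
  near-boundary responses; profile intervals are used only at exact
  boundaries.
* The F-test on cumulative curves inherits the serial dependence caveat above.
* `logicle` inverts by per-value root-finding (vectorized over arrays but not
  closed-form); for ~10⁵ values per channel this costs seconds, which is
  acceptable for index-sort scales.
* The gate scan is O(U²) in unique marker values with the full grid retained;
  at 10⁴ cells the grid alone holds 10⁸ tuples — beyond the intended
  index-sort scale, subsample before scanning.
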