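# clonotrace

Analysis toolkit for single-cell clonal assays of haematopoietic stem and
progenitor cells (HSC/MPP). When single cells are index-sorted into
differentiation assays, each cell leaves three linked records: its full
surface-marker intensity vector at sort time, the lineage composition of the
colony it founded (read out as gated flow-cytometry counts), and the time it
took to exit quiescence and divide. Together with limiting-dilution
transplantation and single-cell RNA-seq, these measurements map where lineage
restriction arises inside phenotypic HSC compartments — for example, along an
anti-correlated CLEC9A/CD34 surface-expression gradient separating multipotent
from myelo-lymphoid-restricted cells. `clonotrace` implements the complete
computational pipeline for such studies:

* **Colony & engraftment calling** — fixed cell-count rules (colony: ≥ 30
  cells; graft lineage: ≥ 20 cells; engraftment: ≥ 0.01% human cells) applied
  to gated count tables, with My sub-typing and lineage-bias calls.
* **Index-sort normalization** — per-channel logicle (biexponential)
  transform with data-driven parameters (m = 5.1 decades by default),
  empirical-Bayes batch correction across sort days, PCA with loadings, and
  standard group tests (Kruskal–Wallis/Dunn, Tukey, Mann–Whitney, paired t,
  Fisher).
* **Gate optimization** — exhaustive in-silico scan of two-marker threshold
  pairs maximizing enrichment of a target colony outcome, the procedure that
  derives CLEC9A-hi/CD34-lo vs CLEC9A-lo/CD34-hi sorting gates.
* **Division kinetics** — cumulative first-division curves on the 12 h
  observation grid, Hill-sigmoid fits (EC50 = mean time to first division),
  and extra-sum-of-squares F-tests between curves.
* **Limiting dilution** — single-hit Poisson model
  P(negative) = exp(−f·dose): maximum-likelihood repopulating-cell
  frequencies, Wald/profile confidence intervals robust to 0%/100% cohorts,
  and likelihood-ratio group comparisons (ELDA-style).
* **scRNA-seq QC** — read-count/mapping/mito filters, median-of-ratios size
  factors on endogenous genes, and highly-variable-gene selection against a
  quadratic log-CV vs log-mean baseline fitted to ERCC spike-ins.
* **Synthetic data** — generators for every input type with planted ground
  truth (latent differentiation gradient, single-hit cohorts,
  negative-binomial counts with spike-ins), driving all recovery tests.

## Worked example: repopulating-cell frequency by limiting dilution

Two sorted subpopulations are transplanted at several cell doses and mice are
scored engrafted/not at 20 weeks. Fit the single-hit model per cohort and
compare frequencies:

```python
from clonotrace import LDACohort, SingleHitModel, compare_frequencies

subset1 = LDACohort("Subset1", dose=[1, 3, 10],      n=[8, 8, 8], k_engrafted=[1, 2, 5])
subset2 = LDACohort("Subset2", dose=[100, 300, 1000], n=[7, 7, 7], k_engrafted=[1, 2, 5])

res1 = SingleHitModel(subset1).fit()
print(res1.summary())
chi2, p, fold = compare_frequencies(subset1, subset2)
print(f"fold = {fold:.1f}, chi2 = {chi2:.2f}, p = {p:.2e}")
```

```
Single-hit limiting dilution fit
================================
group:                 Subset1
dose levels:           3
mice (engrafted/total): 8/24
frequency f:           0.101008
1 in N:                9.9
95% CI on 1/f:        [4.858, 20.18]
log-likelihood:        -12.8456
boundary:              interior
fold = 81.1, chi2 = 47.48, p = 5.55e-12
```

Reading the output: about 1 in 10 Subset1 cells is a long-term repopulating
cell (95% CI roughly 1 in 5 to 1 in 20), Subset2's frequency is ~80-fold
lower, and the likelihood-ratio test rejects a shared frequency decisively.
`fit()` flags cohorts where no (or every) mouse engrafted and switches to
one-sided profile-likelihood bounds for them.

## Command line

Every stage is a subcommand over CSV/TSV/MTX tables:

```bash
clonotrace simulate           --seed 1 --out sim/        # synthetic experiment + truth
clonotrace classify-colonies  --counts sim/colony_counts.csv --out calls/
clonotrace normalize-index    --index sim/indexsort.csv  --out norm/
clonotrace optimize-gates     --index joined.csv         --out gates/
clonotrace fit-kinetics       --division divisions.csv   --out kin/
clonotrace lda                --cohorts cohorts.csv      --out lda/
clonotrace engraftment        --records mice.csv         --out eng/
clonotrace scqc               --counts counts.tsv        --out qc/
clonotrace demo               --seed 1 --out demo/       # full pipeline, manifest + checksums
```

Configuration is a YAML file (`--config`) holding every analysis constant
(logicle decades, the 30/20-cell rules, the 0.01% engraftment threshold, QC
thresholds, MeanForFit = 10); unknown keys are rejected.

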