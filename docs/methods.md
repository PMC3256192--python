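# Methods

## Data model

Subjects × categorical factors, status ∈ {case, control}, free-text stratum
tags. SNPs are coded ordinally: 0 = homozygous wild type, 1 = heterozygous,
2 = homozygous variant; genotype display labels (amino-acid names) ride
along on the factor definition. Environmental exposures are categorical
factors on the same footing — tobacco habit defaults to three levels
(no habit / tobacco only / tobacco + alcohol) with an optional any-tobacco
binarisation, since published MDR reports are ambiguous about the coding.
Missing values are a single sentinel (-1 internally, `NA` in TSV, `0 0` in
PED). Analysis is *available-case* throughout: no imputation anywhere.

Subjects missing more than `max_missing` (default 5) factor values are
excluded before interaction analysis; a subject at exactly the threshold is
retained.

### Fixture construction from marginal counts

`from_marginal_counts` expands printed per-SNP genotype-by-status counts to
an individual-level dataset whose per-SNP tabulation is exact. When panels
have unequal totals each column is filled independently and the shortfall
is missing. The joint multi-SNP distribution is *not* reconstructed —
only marginals are published — so these fixtures validate univariate
statistics, never interaction results. The packaged panels' case totals
differ from the stratum sizes (e.g. 109 genotyped of 113 cases); the gap is
represented as missing genotypes, since per-SNP dropout was not reported.

## Univariate statistics

* **Collapse models.** heterozygous = genotype 1 vs 0 (2 dropped), extreme
  = 2 vs 0 (1 dropped), dominant = 1+2 vs 0.
* **Odds ratio.** Cross product with Woolf (log) 95% CI using the
  conventional z = 1.96. Zero-cell policy: by default a zero yields OR 0 or
  +∞ and the finite CI bound is computed from Haldane–Anscombe-corrected
  (+0.5) cells; full correction is opt-in and always flagged. Both cells of
  a diagonal zero → the OR is undefined and an error is raised. Published
  CIs of this kind mix exact and covariate-adjusted intervals, so only OR
  point estimates are treated as reproducible; CIs are method-tagged
  output.
* **Fisher exact test.** Two-sided by the point-probability rule
  (scipy's `fisher_exact`); a mid-P variant is available. The packaged
  panels reproduce the published p-values to the printed 3 decimals, which
  confirms the original analysis used this test.
* **Adjusted OR.** `statsmodels` Logit of status on the collapsed exposure
  indicator plus covariates; Wald CI; separation or non-convergence returns
  a flagged NaN result rather than a number.
* **HWE.** χ² goodness of fit on the three genotype classes against
  (p², 2pq, q²)·n, 1 df. Monomorphic input is defined as χ² = 0, p = 1.
* **LD.** Haplotype frequencies by EM on unphased two-locus genotypes; only
  the double heterozygote is ambiguous and is split cis/trans
  proportionally to current frequencies. Initialisation at linkage
  equilibrium makes the algorithm deterministic; convergence at max
  |Δf| < 1e-8 or 1000 iterations. D is computed on variant alleles,
  D′ = |D|/D_max, r² = D²/(p_A p_a p_B p_b); a 3×3 genotype χ² is reported
  alongside. No multiple-testing correction is applied anywhere (a
  Bonferroni-style user decision, not baked in), mirroring the MDR
  rationale that the final model is selected, not tested repeatedly.

## The MDR engine

* **Threshold.** T = training-set case:control ratio (generalising the
  classic T = 1 to unbalanced cohorts). A cell at exactly T is high-risk.
  Cells with cases and no controls are high; controls and no cases low;
  neither, empty. Test subjects in cells empty during training are
  classified low-risk (conservative) and count in the denominator.
* **Folds.** 10 status-stratified folds taken as consecutive blocks of the
  current subject order (`np.array_split` semantics per stratum). Shuffling
  the subject order is therefore the *only* randomness in the protocol:
  repeat r permutes subjects with seed `master + r`. A fold with zero test
  subjects raises.
* **Available-case.** Each combination is evaluated on subjects complete
  for exactly its factors, so fold assignments differ per combination; the
  stratified-block rule keeps them deterministic given the order.
* **Scoring.** Accuracy is (correct cases + correct controls)/n — plain,
  not balanced, matching the original formulation; per fold the winning
  combination maximises training accuracy with ties broken by test
  accuracy, then lexicographic factor order. CVC = folds won. Per-k winner:
  maximal CVC, tie → maximal fold-mean test accuracy. Across shuffles the
  modal per-k winner is reported with CVC/accuracies averaged over all
  repeats and its selection count; overall best model: maximal mean CVC,
  tie → maximal mean test accuracy.
* **Reported accuracy.** The per-k row reports the winner model's fold-mean
  accuracies. Note this carries winner's-curse selection bias under the
  null (~+0.05–0.08 at k ≥ 3 when ~10³ models compete); the unbiased
  cross-validated estimate — the held-out accuracy of each fold's winner —
  is exposed via `CVResult.per_fold_test_accuracy` and is the quantity that
  calibrates to 0.5 on permuted labels.
* **OR-MDR.** On the full available-case data of the final model, each
  non-empty cell j gets OR_j = (a_j/b_j)/(a₀/b₀) against the pooled
  low-risk reference (a₀, b₀), CI = exp(ln OR ± 1.96·√(1/a_j+1/b_j+1/a₀+1/b₀)).
  A single-lowest-cell reference is available (`reference="lowest"`)
  because the pooling convention in the literature is ambiguous; pooled is
  the default. Zero cells are Haldane-corrected and flagged.

The engine is vectorised (one `bincount` per combination over
cell × fold × status) but validated cell-for-cell against a deliberately
naive nested-loop reimplementation in the test suite.

## Simulator

What it emulates: independent biallelic SNPs in HWE at stated MAFs, a
categorical exposure, disease via a k-way penetrance table, case–control
ascertainment by rejection sampling from the population model (clinic-style
accrual until quotas fill), MCAR genotype dropout, and two-locus haplotype
draws at specified frequencies for LD tests. What it does not emulate:
linkage between analysis SNPs and causal variants, population
stratification, genotyping batch effects, or non-random missingness — a
green recovery test therefore establishes correctness of the search under
the model's own assumptions, not robustness to confounding.

The headline benchmark is a carrier-XOR model: risk is elevated iff
exactly one of two loci carries a variant allele (penetrance 0.45 vs 0.05,
MAF 0.5, 200 cases + 200 controls). Ten noise SNPs at MAF 0.3 — a typical
candidate-gene minor-allele frequency — pad the search space. With MAF 0.5
the carrier-XOR has modest marginal effects, so the k = 1 search finds a
weak signal while the causal pair dominates k = 2 with mean CVC 10/10 and
held-out accuracy ≈ 0.78 (theoretical optimum ≈ 0.80).

## Determinism

Every stochastic step consumes an explicit seed; per-repeat seeds are
master + repeat index; the EM is deterministic. Two pipeline runs with the
same config and seed produce byte-identical JSON apart from the provenance
timestamp, and the config hash (SHA-256 of the canonical config JSON) is
embedded in every report.

## Known limitations

* Published cohort-level MDR numbers (e.g. a mean CVC of 8.3) cannot be
  reproduced: individual-level genotypes were never deposited. The test
  suite substitutes oracle-equivalence, recovery, null-calibration and
  missingness-contract checks.
* The heterozygous/extreme collapse discards a genotype class, so their
  2×2 margins differ from the dominant model's by construction.
* `from_marginal_counts` datasets have no joint structure across SNPs;
  running MDR on them answers nothing biological.
* PED/MAP ingestion assumes biallelic loci and phenotype codes 1/2; a tie
  in allele counts designates the lexicographically smaller allele as the
  variant, which is arbitrary but deterministic.
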