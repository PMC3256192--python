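# mdrkit

Case–control association and gene–gene / gene–environment interaction
analysis for categorical genotype data, built around an **"Available"
Multifactor Dimensionality Reduction (MDR)** engine.

## Who this is for

Molecular-epidemiology studies of candidate SNPs — for example tobacco-related
cancer cohorts genotyped at a couple of dozen polymorphisms in xenobiotic
metabolism, DNA repair and cell-cycle genes, together with a categorical
exposure such as tobacco habit — where the questions are:

1. Does any single SNP shift disease odds under a genetic model?
2. Do combinations of SNPs and exposure interact beyond what logistic
   regression can resolve at these sample sizes?

## What it computes

**Univariate.** For each SNP, the 3×2 genotype-by-status table is collapsed
under three genetic models — *heterozygous* (Aa vs AA), *extreme* (aa vs AA)
and *dominant* (Aa+aa vs AA) — and the crude odds ratio

OR = (a·d)/(b·c),  95% CI = exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))

is reported with a two-sided Fisher exact p-value (point-probability rule).
Age/gender-adjusted ORs come from maximum-likelihood logistic regression.
Genotyping quality is checked by a 1-df χ² test of Hardy–Weinberg
equilibrium in controls, and pairwise linkage disequilibrium (D, D′, r²) is
estimated from unphased genotypes by EM over haplotype frequencies.

**MDR.** Every k-way combination of factors (k = 1…5) partitions subjects
into genotype/exposure cells; a cell is high-risk when its training-set
case:control ratio reaches the training threshold T. Performance is
assessed by 10-fold status-stratified cross-validation; the
cross-validation consistency (CVC) of a combination is the number of folds
in which it achieves the best training accuracy. The *Available* variant
evaluates each combination on all subjects complete for exactly its
factors, so missing data cost only the affected combinations (subjects
missing more than 5 values are excluded up front). The whole search is
repeated 10 times after shuffling the subject order and CVC/accuracies are
averaged; the overall best model maximises mean CVC, then mean test
accuracy. **OR-MDR** then attaches an odds ratio and 95% CI to every cell
of the final model, relative to the pooled low-risk cells.

**Simulator.** Cohorts are generated from HWE genotype frequencies, a
categorical exposure, an arbitrary k-way penetrance table, case–control
ascertainment by rejection sampling, and MCAR missingness — including a
two-locus carrier-XOR benchmark that MDR should solve and single-locus
tests should not.

**Fixtures.** The published genotype-by-status count panels for seven SNPs
(MPO, SULT1A1, mEH, hOGG1, XRCC1, BRCA2, Cyclin D1) in two case strata are
packaged and can be expanded into individual-level datasets whose per-SNP
marginals are exact.

## Worked example

```python
import mdrkit as mk

# published counts -> crude OR for the SULT1A1 panel, dominant model
ds = mk.published_fixture("SULT1A1_Arg213His", mk.GROUP_UADT_INSIDE)
t = mk.collapse(mk.tabulate(ds, "SULT1A1_Arg213His",
                            case_group=mk.GROUP_UADT_INSIDE), "dominant")
r = mk.crude_odds_ratio(t)
print(f"OR={r.or_estimate:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f}) p={r.p_value:.3f}")
# OR=1.74 (1.07-2.82) p=0.026

# simulated two-locus interaction recovered by the MDR search
sim = mk.simulate_case_control(mk.xor_simulation_config(seed=42))
rep = mk.repeat_with_shuffles(sim, repeats=10, k_min=1, k_max=5, seed=42)
print("/".join(rep.best.combination), round(rep.best.cvc, 1),
      round(rep.best.test_accuracy, 3))
# SNP_A/SNP_B 10.0 0.777
```

The first block reproduces a published crude OR from the packaged counts:
carriers of the SULT1A1 His allele have 1.74-fold disease odds, with a CI
excluding 1. The second shows the interaction search ranking the causal
pair first in every fold of every shuffle (mean CVC 10 of 10) with held-out
accuracy 0.78.

A CLI wraps the same functions:

```sh
mdrkit univariate data.tsv --model all --out univariate.tsv
mdrkit mdr data.tsv --kmin 1 --kmax 4 --repeats 10 --seed 42 --out mdr.json
mdrkit run --config run.yaml --input data.tsv --out results/
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes everything from scratch: all packaged count panels through
tabulation → collapse → odds ratio → Fisher p and the HWE test, then a
fresh carrier-XOR cohort through the full repeated-shuffle MDR search and
OR-MDR. It prints the resulting tables and writes the JSON result map.

## Layout

- `mdrkit.data` — dataset model, TSV and PLINK PED/MAP readers, missing-data
  policy, fixture construction from marginal counts
- `mdrkit.univariate` — collapse models, ORs, Fisher, logistic adjustment,
  HWE, LD
- `mdrkit.mdr` — Available-MDR search, CVC, shuffle averaging, OR-MDR
- `mdrkit.simulate` — penetrance-model simulator and packaged fixtures
- `mdrkit.pipeline` / `mdrkit.cli` — end-to-end runs, reports, CLI

See `docs/methods.md` for modelling assumptions and numerical choices.
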