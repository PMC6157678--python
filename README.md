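# matechoice

Analysis toolkit for testing MHC-based mate-choice hypotheses in small
wild populations, built around the study design used for giant pandas:
long-term field observation of *mating sites* (one estrous female plus
1–6 competing males, exactly one of which wins dominance and mating
access) combined with MHC class II exon-2 genotypes (DRB1/DQA1/DQA2-style
loci) and multilocus microsatellite genotypes.

The package implements the four classical hypotheses and the statistics
used to test them:

- **Heterosis** — preference for MHC-heterozygous males; per-locus 0/1
  indicator at the allele or protein level.
- **Genetic diversity** — amino-acid Hamming distance between an
  individual's two exon-2 alleles, over all columns or restricted to the
  antigen-binding sites (ABS).
- **Genetic compatibility** — pairwise dissimilarity between female and
  male:
  - *compatibility1* (Landry): mean of the four cross-allele amino-acid
    distances, (P_CD + P_Cd + P_cD + P_cd)/4, all-sites or ABS-masked;
  - *compatibility2* (Wetton band-sharing): D = 2·F_ab/(F_a + F_b) over
    the distinct protein classes each individual carries.
- **Good gene** — Pearson chi-square comparing allele distributions
  between dominant and subordinate males, with synonymous alleles
  collapsed to protein classes first.

Microsatellite covariates follow the standard definitions: standardized
individual heterozygosity SH (observed heterozygous proportion divided
by mean expected heterozygosity of the typed loci), internal relatedness
IR = (2H − Σf)/(2N − Σf), and symmetrized Queller–Goodnight pairwise
relatedness.

Inference proceeds as in the field's standard pipeline:

1. a Pearson **correlation screen** removes one member of each
   significantly correlated pair of explanatory variables (priority
   ordered; constant columns are flagged inapplicable);
2. a **logistic mixed model** of mate-pair formation (response 1 for the
   site's dominant male, 0 for subordinates) with crossed random
   intercepts for year, mating site and male identity, fit by maximum
   likelihood under the Laplace approximation (agrees with `lme4::glmer`
   to numerical precision); Wald z tests per coefficient;
3. per-locus **chi-square good-gene tests**;
4. a **Monte Carlo randomization test** comparing the mean pairwise
   dissimilarity of real parent pairs with pairings reshuffled among the
   adult candidates (10,000 shuffles, add-one p-value).

A synthetic-data generator reproduces the whole data structure (adults,
allele sets with synonymous pairs, Hardy–Weinberg genotypes, mating
sites with softmax dominance, parent pairs under a parameterized choice
regime), so every stage runs and can be power-analyzed without field
data.

## Worked example

```bash
matechoice simulate --seed 42 --out bundle/
matechoice run --data bundle/config.yaml --seed 11 --out results/
```

`results/report.json` contains the full analysis; `glmm_table.tsv` holds
the coefficient table. For the seed-42 bundle the mixed model (48 design
rows over 16 sites) prints, among others:

```
term                 estimate              std_error            z_value     p_value
DRB1_heterosis       2.2180099075423674    2.107343157021566    1.0525148   0.2925634
DRB1_compatibility1  -0.027451052284998036 0.15534344006186018  -0.1767120  0.8597346
```

and the 10,000-shuffle randomization test for the 9 parent pairs gives
observed vs null means of 8.667 vs 8.720 amino-acid differences
(p = 0.96) all-sites and 5.111 vs 5.287 (p = 0.71) within the ABS. The
bundle was generated under random mating, and no covariate is
significant — but that is also the expected outcome at this design
scale even when a true preference exists, as the power analysis shows:

```bash
matechoice power --test glmm --regime dissimilarity --beta 0.5 \
    --n-sites 16 --replicates 200 --seed 1
```

reports `"power": 0.13` at 16 sites for a moderate standardized effect
(β = 0.5); at `--n-sites 200` the same effect is detected in >95% of
replicates. The randomization test and chi-square
test behave the same way at 9 parent pairs / 16 sites. A null result at
this scale is therefore weak evidence against MHC-based choice.

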