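# Methods

## Data model

The unit of observation is the *mating site*: one estrous female and
1–6 candidate males, exactly one of whom is dominant (validated on
construction). Individuals carry genotypes at a small number of MHC
class II loci — each an exon-2 allele pair from a locus-level allele
database — and at up to 14 microsatellite loci (integer fragment
sizes). Parent pairs (mother, father) come from assigned parentage and
are analyzed separately from mating sites.

Exon-2 alleles at a locus are assumed pre-aligned and indel-free: class
II exon-2 alleles are length-conserved, so unequal amino-acid lengths
are rejected rather than aligned internally. Reading frame is a
per-locus configuration value (`frame_offset`, default 0) because
amplicons may start mid-codon. Translation uses the standard nuclear
code; ambiguity codes are not accepted and an internal stop raises a
pseudogene error naming the codon. Antigen-binding-site (ABS) masks are
per-locus lists of 1-based amino-acid alignment columns supplied in
configuration; every "ABS" variant of a metric is the same computation
restricted to those columns, so masked ≤ unmasked holds identically.

Synonymous alleles (identical protein) are collapsed into *protein
classes*, numbered 1..K by first appearance. The Wetton band-sharing
index and the good-gene test operate on protein classes; the heterosis
indicator defaults to the allele (nucleotide) level with a protein-level
option, since genotype heterozygosity is conventionally scored on
alleles while the protein level is what matters for the good-gene
comparison.

## Metrics

- Landry compatibility: mean of the four cross-pair Hamming distances
  between female alleles {C, c} and male alleles {D, d}; homozygotes
  contribute their allele twice. Units: amino-acid differences.
- Wetton D = 2·F_ab/(F_a+F_b) with F counting distinct protein classes
  per individual at the locus (1 or 2). D is a *similarity* in [0, 1];
  it is used as printed, with a configuration flag to model 1−D instead
  (the literature is ambiguous about the direction).
- SH divides the observed heterozygous proportion of the typed loci by
  the mean expected heterozygosity (1 − Σf²) of those same loci, so
  individuals typed at different locus subsets are comparable.
- IR = (2H − Σf)/(2N − Σf) over typed loci; equals 1 iff fully
  homozygous and weights homozygosity for common alleles more heavily.
- Pairwise relatedness is the Queller–Goodnight moment estimator,
  computed in both reference-individual directions with numerators and
  denominators pooled across loci, then averaged. Expectation ≈ 0 for
  unrelated pairs, ≈ 0.5 for parent–offspring. The estimator is
  configurable in principle; Queller–Goodnight is the default because it
  is the field's default for small panels.
- Allele frequencies for SH/IR/relatedness are estimated from all typed
  adults in the dataset unless a table is supplied.

Missing genotypes are handled by listwise exclusion per analysis: an
individual missing any variable used in a given model is dropped from
that model only, and the drop count is logged.

## Correlation screen

Pearson r with two-sided t-distribution p-values (df = n − 2) on
pairwise-complete rows, for two variable families separately: male
diversity measures (SH, IR, per-locus diversity and ABS diversity) and
pair measures (relatedness, per-locus compatibility1, ABS compatibility1,
compatibility2). Pruning is greedy in a configured priority order
(default: SH before IR, all-sites before ABS, compatibility1 before the
others): scanning pairs in priority order, whenever both members of a
significant pair (p < α, default α = 0.05) are still retained, the
lower-priority member is dropped. Constant (near-monomorphic) columns
are reported as inapplicable and never trigger a drop. Heterosis
indicators bypass the screen and always enter the model (unless
constant, in which case the model drops them with a note).

## Mixed model

logit P(dominant) = Xβ + Σ_k u_k, with independent random intercepts per
grouping factor (year, site, male id by default; female id optional —
female is confounded with site, so male identity is the default
"individual" factor). Maximum likelihood under the Laplace
approximation: an inner Newton solve for the conditional mode of the
random effects and an outer L-BFGS-B over the fixed effects and log
standard deviations jointly, starting from β = 0, u = 0, σ = 0.5;
log σ is bounded in [−6, 3], so a variance can collapse to effectively
zero. The objective agrees with `lme4::glmer` (Laplace, nAGQ = 1) to
numerical precision, which the test suite pins against an independently
computed reference fit.

Wald standard errors are taken from the fixed-effect block of the
inverse finite-difference Hessian of the Laplace objective over
(β, log σ) jointly — the same quantity the reference mixed-model
software reports — which propagates variance-parameter uncertainty into
the SEs. When a variance estimate sits on the boundary, those
coordinates are excluded and, if needed, the conditional Schur
complement X'WX − X'WZ(Z'WZ+Σ⁻¹)⁻¹Z'WX is the fallback (flagged on the
fit). p-values are two-sided normal. Non-convergence and suspected
complete separation are reported as flags/messages on the returned fit,
never as exceptions. Covariates enter on their raw scale by default
with an optional z-standardization flag.

## Good-gene test

Allele copies are counted per (site, male) participation — a male
competing at two sites contributes twice, matching how design rows are
counted — split by dominant/subordinate status, collapsed to protein
classes, zero-total classes dropped. Pearson chi-square without
continuity correction, df = K − 1; expected counts below 5 set a
warning flag (small-sample chi-squares are anticonservative, which is
reported rather than "fixed").

## Randomization test

Observed statistic: mean pairwise metric (default: Landry compatibility
at a configured locus, all-sites and ABS variants) over real parent
pairs. Null: each shuffle samples len(pairs) females and males without
replacement from the adult candidate pools and records the mean; pools
contain each adult once plus extra copies for parents appearing in
multiple real pairs (individuals, not pairs, are what get shuffled).
p = (k+1)/(n+1) with k the number of null means at least as extreme as
the observed; two-sided extremeness is distance from the null median;
lower/upper tails available. The add-one rule avoids p = 0. Individuals
with undefined metrics (missing genotypes) are excluded from pools and
from the observed mean, with logging.

## Synthetic generator

Defaults emulate the motivating study design: 40 adults (26 M / 14 F),
16 mating sites, 9 parent pairs, three MHC loci with 5/8/3 alleles (the
3-allele locus carrying one synonymous pair), 14 microsatellite loci
with 4–10 alleles each (Dirichlet(1) frequencies), site sizes 1–6 with
mean ≈ 2.8 males. Genotypes are Hardy–Weinberg draws; MHC and
microsatellite loci are unlinked. Exon-2 alleles are generated by
mutating a base protein with higher per-column substitution probability
at ABS columns (0.30) than elsewhere (0.04), mimicking the elevated ABS
polymorphism balancing selection maintains — this is also why ABS and
all-sites variants of a metric are strongly correlated, as they are in
real data.

Choice regimes inject effects through a softmax model: within a site,
male i is dominant with probability ∝ exp(quality_i + β·z_i), where z
is the z-scored regime metric (heterozygosity, diversity, Landry
compatibility, or carriage of a designated allele) and quality is 0
unless the latent-quality dominance model is selected (then per-male
N(0, 1)). β is therefore a standardized, logit-linear effect size
directly comparable to the mixed model's coefficients. Parent pairs
weight fathers by exp(β·z) per mother. β = 0 reduces both to uniform
randomness.

What the generator does *not* emulate: genotyping error and allelic
dropout, population structure, linkage, age/experience effects on
dominance, non-independence of sites across years beyond the shared
male pool. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness of the
field study to those complications.

## Power analysis

`matechoice.power.detection_power` simulates datasets under a regime and
effect size and reports how often the matching test rejects at α =
0.05. The GLMM power model uses the focal covariate alone (intercept +
focal, full random structure), which isolates the question "can this
design detect this effect at all". At the default design scale a
standardized β = 0.5 is detected in roughly 10% (GLMM), ~10–15%
(chi-square), and ~20% (permutation, 9 pairs) of replicates; at 200
sites the GLMM detects the same effect in >95%. Simulation sizes in the
test suite: 500 replicates at study scale, 100 at 200 sites (where
measured power is ~7 standard errors above the 0.80 criterion).

## Numerical and design choices

- 1-based coordinates in all user-facing amino-acid positions.
- Chi-square and Pearson correlation p-values come from scipy; the
  permutation p is exact Monte Carlo counting, never a normal
  approximation.
- Screen alpha 0.05 by default, configurable; no multiple-testing
  correction anywhere (matching standard practice for this pipeline,
  where the endpoint is a joint model, not a family of claims).
- TSV (UTF-8, header row) and FASTA are the only on-disk formats;
  writes are byte-deterministic (fixed column order, `repr` floats) so
  reruns can be compared by hash.
- All commands accepting `--seed` are bit-reproducible; internal seeds
  derive from `numpy.random.SeedSequence` and stay below 2^31.

## Known limitations

- The Laplace approximation is biased for binary data with very small
  cluster sizes; at the default scale (sites of 1–6) variance estimates
  frequently collapse to the boundary. This mirrors the behavior of the
  standard tools on such data and is flagged on the fit rather than
  corrected (no adaptive quadrature for crossed designs).
- The good-gene chi-square treats allele copies as independent, ignoring
  the two-copies-per-male and repeated-male dependence; expected-count
  warnings are the only guard. This is the field-standard test, applied
  as published.
- Wetton D on a single locus takes few distinct values (0, 1/2, 2/3, 1),
  so its correlations at small n are coarse.
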