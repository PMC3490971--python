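# Methods

## The problem and the model

A cohort of 7 diploid individuals contributes n = 14 alleles per autosomal
biallelic SNP. For each site with an alternate-allele count x (failed
genotypes drop both of a sample's alleles from the denominator, so n can be
locally smaller) and a continental reference-panel frequency p, the scan
asks whether x is extreme under X ~ Binomial(n, p). Two one-tailed exact
tests are run per continent — P(X ≥ x) for higher frequency, P(X ≤ x) for
lower — with the observed count included in the tail and no normal
approximation. The panel frequency enters as a fixed, known parameter; its
own sampling noise is handled not by propagating uncertainty through the
binomial but by the second condition of the combined call, a minimum level
of differentiation measured by Fst.

### Fst estimator

We use the Weir–Cockerham (1984) two-deme θ in its haploid (allele-count)
parameterization. With allele samples of sizes n₁, n₂, frequencies p₁, p₂,
p̄ the pooled frequency and n_c = 2n₁n₂/(n₁+n₂):

    MSP = n₁(p₁−p̄)² + n₂(p₂−p̄)²            (among populations, df = 1)
    MSG = [n₁p₁(1−p₁) + n₂p₂(1−p₂)] / (n₁+n₂−2)
    θ̂  = (MSP − MSG) / (MSP + (n_c − 1) MSG)

The raw θ̂ can be negative (sampling noise around zero differentiation) and
is undefined (0/0) when both samples are monomorphic for the same allele;
thresholding uses a floored-at-zero copy, with the undefined case flagged
and floored too. Hudson's estimator is available as an alternative and as a
cross-check. For genome-wide parameter estimation the multi-locus
ratio-of-sums combination is exposed separately (`fst_multilocus`): summing
numerator and denominator components over loci before dividing recovers the
generating divergence consistently, whereas averaging per-locus θ̂ is biased
downward (≈0.08 at a true 0.10 in our simulations).

### Multiple testing

Storey q-values: with order statistics p₍₁₎ ≤ … ≤ p₍ₘ₎,
q₍ᵢ₎ = min_{j≥i} π₀ m p₍ⱼ₎ / j. The default π₀ = 1 makes q-values exactly
equal to Benjamini–Hochberg adjusted p-values (verified against statsmodels
in the test suite). The optional smoother estimates π₀(λ) = #{p > λ}/(m(1−λ))
on the grid λ = 0.05, 0.10, …, 0.95, fits a cubic polynomial trend and reads
it off at λ = 0.95, capped into (0, 1]; a non-positive fit falls back to the
smallest positive grid estimate (conservative). Families are formed per
continent, and separately per direction by default — the two one-tailed
tests of a site are different hypotheses; a pooled-per-continent family is
available as a switch since either reading of the procedure is defensible.

### The combined call

A site is enriched against a continent when Fst > 0.25 **and** the
directional q-value < 0.05, both strict, and "enriched" overall when that
holds for at least one continent. If both directions pass (possible only
for degenerate nulls), the higher direction wins with a warning. Setting
the Fst threshold below 0 and the FDR threshold above 1 disables the
respective filter; the strict inequalities mean the nominal boundary values
(0 and 1) do not, because clamped Fst is exactly 0 and q-values exactly 1
occur routinely.

Sites without a panel frequency in any continent ("novel") are excluded
from testing and reported as a separate stratum; sites missing one
continent's frequency are simply not tested against that continent. Degenerate
panel frequencies (0 or 1) are tested exactly; the resulting zero p-values
are legal and propagate through the q-values.

## Functional triage

Categories follow the fixed severity order nonsense > splice > missense >
silent > noncoding across transcripts. The deleteriousness flag is the
liberal union: missense and (SIFT = deleterious OR PolyPhen2 ∈ {probably,
possibly damaging}). Restricting eligibility to missense follows the
procedure's definition; a switch extends it to splice/nonsense for
sensitivity analyses. Tier 3 (SNP previously health-linked) is matched by
rsID or, for records without rsIDs, by gene + three-letter amino-acid
substitution, case-insensitively; tier 3 takes precedence over tier 2
(gene-only), so the tiers partition the deleterious set. Displayed
percentages round half-up (4.76% prints as 5%); full precision is kept
internally.

## Representativeness inference

Pearson r with the Fisher-z 95% interval tanh(atanh r ± 1.96/√(n−3)) — the
normal quantile is fixed at 1.96 — and the two-sided Student t-test with
n − 2 df. At |r| = 1 the transform diverges and the interval degenerates to
a point. On the packaged 10-SNP validation table the full-precision r is
0.7577 with interval (0.2449, 0.9392); the printed-style endpoints (0.25,
0.94) arise when the transform is applied to the 2-dp rounded r = 0.76, and
both views are asserted in the tests. Subsampling replicates draw the small
sample uniformly without replacement (optionally as a mixture across
populations); the large comparator excludes the small sample's individuals
by default, as a validation cohort would. Sites monomorphic within a
replicate are dropped from that replicate (r undefined there); replicate
seeds are spawned from the master seed by counter.

## Synthetic data

Balding–Nichols is the minimal generative model matching the study's
structure: an ancestral frequency p₀ ~ Uniform(0.05, 0.95) per site (the
bounds avoid degenerate Beta parameters), population frequencies Beta
distributed around p₀ with divergence F, diploid genotypes Binomial(2, p).
Defaults, chosen once:

| parameter | default | why |
|---|---|---|
| panel sizes | 379/296/185/242 individuals | continental panel sizes of the reference dataset the design mirrors |
| panel F | 0.08/0.10/0.12/0.08 (EUR/ASN/AFR/AMR) | continental-scale Fst magnitudes |
| cohort | 3 + 2 + 2 individuals | the three-subgroup small-cohort design |
| subgroup F | 0.02 above the source panel | modest within-region divergence of an admixed population |
| missing rate | 0.02 | a few failed genotypes per site, as real panels show |
| category mix | 50/15/30/3.5/1.5% (noncoding/silent/missense/splice/nonsense) | exome-scale proportions with roughly half of missense flagged |
| deleterious fraction | 0.52 of missense | the observed share of missense sites flagged by the predictor union |
| tier mix | 0.72/0.24/0.04 | the observed tier split of deleterious sites |

Spiked sites move every cohort subgroup's source frequency to
clip(mean panel frequency ± displacement, 0.02, 0.98) and redraw the cohort
genotypes there; displacement 0 only labels sites. The annotation/health-DB
generator gives each site its own synthetic gene (so gene-level records
cannot leak across sites) and realises tier 3 alternately through rsID and
gene+substitution records, exercising both query paths.

What the generator does *not* emulate: linkage disequilibrium, realistic
site-frequency spectra (frequencies are uniform-ancestral, not neutral-SFS
shaped), runs of homozygosity/consanguinity, genotyping error, and
admixture at the individual level (each subgroup is a discrete population).
Passing tests therefore demonstrate the statistical machinery's correctness
and calibration under the stated model, not performance on real exomes.

## Calibration studies and problem sizes

The null study draws the cohort from the panel's own frequencies (subgroup
F = 0, one panel), 20 replicates of 10,000 sites; every enriched call is
false by construction, and the observed false-enrichment rate is ~10⁻⁵ —
far below the 0.05 target, as expected when an Fst floor is stacked on FDR
control. The power study spikes 100 of 10,000 sites at +0.5 displacement
(5 replicates): detection ≈ 0.73 with empirical FDR ≈ 0.03 against the
source panel, and power rises monotonically over displacements 0.1 → 0.4.
The subsampling study uses 120–200 individuals and 200–300 sites with 25–50
replicates. These sizes give Monte-Carlo standard errors comfortably below
the margins being tested while keeping the whole suite fast; all are
parameters, not constants, so larger studies are one argument away.

## Numerical and design notes

- Genotype codes: int8 dosage 0/1/2 with −1 missing; half-called diploid
  VCF genotypes (e.g. `0/.`) become fully missing so denominators count
  whole diploid genotypes (cyvcf2's `gt_types` would silently keep the
  called allele, so parsing reads the raw genotype tuples).
- Multi-allelic and non-SNP records are rejected with a count by default
  (strict mode raises); X/Y/MT are excluded.
- Panel allele counts are reconstructed as rint(p·n) when a scan needs
  counts from a frequency table — the table's invariant (p·n within 0.5 of
  an integer) makes this exact.
- All simulation randomness flows from one seed through named
  `SeedSequence` children, so toggling one feature never shifts another
  stream and identical configs give byte-identical outputs.
- Tie-breaks: equal severity categories resolve to the fixed order's
  maximum; q-value ties share a value by construction of the step-up
  minimum.

## Known limitations

The binomial null treats the panel frequency as exact; with very small
panels the Fst floor compensates only partly. The q-value families are per
continent and direction — pooling changes individual q-values and is left
as an explicit switch. The classification stage consumes predictor labels;
it does not compute SIFT/PolyPhen2 scores. Correlation inference assumes
approximately bivariate-normal frequency pairs, which is rough for strongly
skewed frequency distributions at small n.
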