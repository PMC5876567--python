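# Methods

`susgwas` implements the statistical machinery of a herd-scale case/control
genetic screen for a binary congenital trait in pigs — scrotal hernia is the
motivating phenotype — on SNP-array genotypes in PLINK text PED/MAP format.
This note documents the models, parameter choices, numerical conventions and
the limits of what the bundled simulator can demonstrate.

## Data model and conventions

Genotypes are minor-allele counts (0/1/2, `-1` missing) in a samples ×
markers `int8` matrix; marker and sample metadata live in pandas DataFrames.
Coordinates are 1-based and intervals closed on both ends. Chromosomes are
string labels, autosomes "1".."18" sorting numerically with "X" after "18".
After loading, and again after sample QC, allele 1 is re-set to the minor
allele on the current samples, so all downstream counts are minor-allele
counts. Phenotypes use PLINK coding (1 control, 2 case, −9 missing). One
limitation of the text format is irreducible: a marker monomorphic in the
written samples cannot carry the code of its unobserved allele, so
round-trip identity is guaranteed for polymorphic markers only.

## Quality control

Samples with more than 10% missing calls are removed first; marker
statistics are then computed on the survivors. Markers fail on call rate
(> 10% missing), minor allele frequency (< 1%), or the exact
Hardy–Weinberg test (p < 9.5×10⁻⁷). Call-rate and MAF failures are
tabulated jointly (callrate-only / MAF-only / both) so the attrition report
partitions removed markers into auditable categories; the HWE filter applies
only to markers passing both, and the report exposes counts both before and
after it. HWE uses the Levene–Haldane conditional distribution of the
heterozygote count given the allele counts, two-sided in the standard
sum-of-no-more-probable-outcomes sense, without a mid-p correction; it is
evaluated on all surviving samples (cases included), as nothing in the study
design restricts it to controls. MAF is computed on non-missing calls only.

Excess-heterozygosity screening (a cross-contamination signature) computes
per-sample F = 1 − observed/expected heterozygosity, with the expectation
from panel allele frequencies, and flags samples more than 3 SD below the
mean F.

LD pruning is greedy and windowed (defaults 50 SNPs, step 5, r² ≥ 0.2
prunes): within a window the lower-MAF member of the worst pair is dropped
(tie → later position; zero-variance markers go first). Windows slide over
the *currently kept* markers and passes repeat to a fixed point, which makes
pruning idempotent and guarantees no surviving within-window pair violates
the threshold. The window/step defaults are the conventional ones for this
tooling family and are exposed in configuration. Only autosomes enter,
because recombination on the sex chromosomes distorts r².

## Relatedness and background outliers

The IBS allele-sharing distance is 1 − mean(IBS)/2 over pairwise-complete
markers. Classical (Torgerson) MDS double-centers the squared distances and
eigendecomposes; coordinates are scaled by √eigenvalue, with the
largest-magnitude loading of each dimension made positive for
reproducibility.

The study design this package supports removed genetic-background outliers
by visual MDS inspection; the package replaces that with a deterministic
rule. Each of MDS dimensions 1–2 is reduced to a robust z-score,
|x − median| / (1.4826·MAD), and a sample exceeding 4 on either axis is
flagged. Per-axis scoring was chosen over an isotropic distance-from-centroid
rule after the latter proved blind to a divergent group whenever the herd's
own family structure spread the orthogonal axis; the threshold 4 is set from
the normal tail (per-sample false-flag probability ≈ 10⁻⁴) while breed-level
divergence (allele-frequency shifts of ±0.3) scores above 6. An explicit
override list short-circuits the rule.

IBD is the classical method-of-moments estimator: expected IBS-state counts
under IBD states 0/1/2 are accumulated from panel allele frequencies, the
moment equations solved in order Z0, Z1, Z2, each clipped to [0,1] and the
triple renormalised; PI_HAT = Z1/2 + Z2. Frequencies are estimated on the
analysis panel; the small-sample bias this induces (the estimator sees ~50
animals) is accepted and visible in tests as a tolerance of ±0.02 around
zero for unrelated pairs. Note that mean PI_HAT comparisons before/after
outlier removal depend on which panel the frequencies come from; the
package's tests demonstrate the dilution effect (cross-background pairs pull
the mean down) within a single estimation run.

## Runs of homozygosity and FROH

ROH detection follows the sliding-window scheme of the standard array
tooling: a window of 50 consecutive SNPs is homozygous-compatible if it
contains at most 1 heterozygote and 1 missing call; each SNP's hit rate is
the fraction of overlapping windows that are compatible; SNPs with hit rate
≥ 0.05 are eligible; maximal runs of eligible SNPs are reported if they
contain ≥ 100 SNPs and span ≥ 1,000 kb. The X chromosome is excluded. The
heterozygote/missing tolerance applies inside scanning windows only — the
run itself is a maximal stretch of eligible SNPs — and no density or
maximum-gap constraint is imposed; both are deliberate, documented
differences from some other pipelines. Segment length is end − start in kb
(not +1 bp), immaterial at the 1,000-kb threshold but fixed for testability.

FROH for an animal is the summed length of its ROH divided by total
autosomal genome length L, defaulting to the Sus scrofa build-10.2 value
L = 2,808,525 kb; simulations pass their own map length. Group comparison
is a Welch two-sample t-test (two-sided), chosen over the pooled-variance
form because case/control group sizes are unequal by design (35 vs 18).

Detection requires ≥ 100 SNPs per run, so FROH is only informative at
marker densities where autozygous tracts of the expected length (~10–20 Mb
for recent inbreeding) contain that many markers. The desk-scale pipeline
fixture (300 markers per 130-Mb autosome) is below that density and
correctly reports FROH ≈ 0; inbreeding-recovery tests use a dense map
(20 markers/Mb), where first-cousin offspring recover mean FROH within
0.02 of the pedigree F = 1/16.

## Pairwise segment sharing and the permutation test

Two animals share a segment where their genotypes are IBS-compatible — at
most 1 opposite-homozygote marker and 1 marker missing in either animal per
50-SNP window, with the same 5% hit-fraction, ≥ 100 SNPs and ≥ 1,000 kb run
filters as the ROH scan (the tolerance mirrors the ROH scan because no
separate genotyping-error allowance is specified for sharing; it is
configurable). The scan runs on the LD-pruned autosomal panel.

The test statistic at each pruned-panel position is the number of case/case
pairs whose segment overlaps it; control-involving counts are tabulated for
diagnostics. The null distribution permutes case/control labels over
animals with group sizes fixed — segments are label-free and not recomputed,
and permuting animals (not pairs) preserves the dependence between pairs
sharing an animal. Per-position empirical p-values use the add-one rule
(1 + #{perm ≥ obs})/(1 + n_perm), with floor 1/(n_perm+1); a per-chromosome
p is computed the same way on the within-chromosome maximum count
(max-statistic correction, which handles the strong correlation of
neighbouring positions without Bonferroni). The library default is 10,000
permutations (desk scale); the study-scale 100,000 is a flag away. Because
the statistic is integer-valued, ties at the observed value make the test
mildly conservative; calibration tests measure a pooled type-I error of
~4–5% at nominal 5% on pedigreed null panels.

## Case/control association

Per marker, the 2×2 minor/major × case/control allele-count table is tested
with the 1-df Pearson chi-square (no continuity correction); the odds ratio
is the cross-product with the Haldane–Anscombe +0.5 on all cells if and only
if any cell is zero, so alleles absent from one group still report a
direction. Genome-wide significance is declared at p < 5×10⁻⁵, with no
further multiple-testing correction by default (a Bonferroni option exists).
The genomic inflation factor is λ_GC = median(χ²)/median(χ²₁df)
(denominator 0.45494 computed exactly), and QQ data use the (rank−0.5)/n
expected quantiles. X-chromosome genotypes of castrated males are tested as
the diploid calls the array delivers; no hemizygosity handling is applied —
a documented limitation.

Multi-marker (2–3 SNP) haplotype association estimates per-group haplotype
frequencies from unphased genotypes by EM: starting uniform, the E-step
distributes each multilocus genotype over compatible ordered haplotype
pairs in proportion to current frequency products, the M-step re-estimates,
convergence at max |Δf| < 10⁻⁸ or 1,000 iterations (non-convergence returns
the last iterate, flagged; the log-likelihood is non-decreasing and
asserted so in tests). Expected haplotype counts (2n·f per group) feed a
haplotype-vs-rest 2×2 chi-square per haplotype plus an omnibus (h−1)-df
test; haplotypes with expected count < 1 in both groups are reported
descriptively, untested. This EM + expected-count formulation was chosen as
the standard construction for "testing associated markers as a haplotype"
and yields the familiar %-in-cases / %-in-controls report.

Per-marker effects on the log-odds scale come from single-predictor
logistic regression with intercept, fitted by Newton–Raphson (tolerance
10⁻¹⁰, ≤ 50 iterations). Complete or quasi-complete separation — diverging
slope (|β| > 15), a vanishing information matrix, or a singular Newton
step — is flagged and no Wald p-value is emitted. The implementation is
cross-checked against statsmodels' Newton fit in the test suite.

## The synthetic-data generator

The generator gene-drops a pedigreed herd: founder haplotypes carry alleles
drawn per marker from a configurable frequency distribution (uniform on
[0.05, 0.5] by default); offspring gametes form by Haldane (no-interference)
recombination — Poisson crossover counts on a 1 cM/Mb map, both
configurable — and every haplotype is recorded as founder-ancestry segments,
so true autozygosity, true pairwise IBD and true carrier status are exact
by construction rather than re-inferred. Defaults: 18 autosomes × 300
markers plus X × 150 (evenly spaced with jitter over 130/125 Mb), 40
founders, three bred generations (80/160/240), full-sib matings avoided but
cousin-level loops arising naturally, 0.2% missing calls. The final cohort
stands for the screened herd; a study is ascertained from it by the
penetrance model below. Pedigree inbreeding coefficients come from the
tabular kinship method; realized autozygosity is the genome fraction where
an animal's two haplotypes share a founder source, and matches pedigree
expectation within ±0.02 at the default scale.

The implanted trait haplotype occupies 10 consecutive mid-chromosome
markers on chromosome 2 and consists of the minor allele at each; founder
haplotypes carry it with probability 0.35, and its markers' background
minor-allele frequencies are drawn low (0.02–0.08), making the combination
distinctive of the founding haplotype — the in-silico analogue of a tagged
QTL region. Phenotypes are penetrance-based: carriers of at least one
intact copy are affected with probability 0.02, non-carriers with 0.70 —
i.e. the implant is strongly *protective*, emulating the empirical pattern
this class of study reports, where one haplotype is essentially absent
among affected animals while segregating widely among healthy ones, and the
complementary haplotype class is correspondingly enriched in cases
(realized carrier rates in ascertained 35/18 studies: ~0–10% of cases vs
~60–90% of controls carry the protective haplotype). A carrier-enrichment
pattern alone, at frequencies like 83% vs 38% carriers, yields allelic
chi-squares around 10–13 — short of the p < 5×10⁻⁵ threshold at n = 53 —
so the near-absence pattern is also what makes the mapping power
demonstrable at study scale, consistent with the single-marker p-values
(~10⁻⁷) such studies report. Ascertainment draws exactly 35 affected and
18 unaffected animals; since a fixed case quota conditions on enough
affected animals existing, the convenience wrapper rejection-samples whole
populations (derived seeds) until the margins are feasible.

What the generator does not emulate: background linkage disequilibrium
beyond what the pedigree induces (founder haplotypes are in linkage
equilibrium), realistic swine recombination maps, sex-specific X
transmission (the X is dropped like an autosome and all animals are male),
genotyping batch effects, and array ascertainment bias in allele
frequencies. Passing tests therefore demonstrate algorithmic correctness
and statistical calibration under pedigree-induced structure, not
performance on real array data.

A separate unstructured generator (unrelated animals, independent HWE
markers, labels assigned at random) provides the null panels for
calibration checks: λ_GC ≈ 1 and ~5% type-I error of the allelic test.

## Problem sizes in tests

The test suite and acceptance checks run at desk scale, chosen so the full
suite completes in a few minutes: 2,000–4,000-marker null panels for
calibration; 20 replicate 35/18 studies for mapping power (the implanted
chromosome must carry the genome-wide top marker at p < 5×10⁻⁵ in ≥ 80%);
20 pedigreed null replicates at 400 permutations for permutation-test
calibration; six first-cousin pedigrees on 10 × 100 Mb chromosomes at 20
markers/Mb for FROH recovery; brute-force oracle comparisons at ≤ 500 SNPs.
The pipeline itself handles the study-scale 100,000 permutations.

## Known limitations

* Association is uncorrected for relatedness (no mixed model), faithfully
  reproducing the screen it implements; on pedigreed panels λ_GC > 1 is
  expected and the permutation test, which respects the dependence
  structure, is the primary inference for sharing.
* The permutation test's per-position p-values are mildly conservative
  under heavy ties (integer statistic).
* PED/MAP only; no VCF, no binary BED, no multi-allelic markers, no phased
  input.
* Monomorphic markers cannot round-trip their unobserved allele code
  through PED text.
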