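# Methods

## The question the package operationalises

Adding a small population-specific ("local") panel of phased haplotypes to
a large cosmopolitan ("global") reference panel improves genotype
imputation in the study population, most strongly for less common variants
and for populations genetically distant from the global panel. The
package reproduces this design end to end on synthetic data: simulate a
structured pair of populations, QC the called genotypes, impute every
sequenced subject twice (global panel alone; global plus leave-one-out
local panel), and score per-SNP dosage accuracy against the truth.

## Population simulator

**LD by founder mosaics.** A pool of `n_founders` (default 120) founder
haplotypes is built first; every simulated haplotype is a mosaic of that
pool, with the copied founder changing between adjacent sites with
probability `1 − exp(−mosaic_switch_rate · Δd)`, `Δd` the inter-site
distance in Morgans. On a switch the new donor is uniform over the other
founders. This yields block LD that a copying-model imputation engine can
exploit, at a small fraction of the cost of a coalescent simulation, and
is bit-reproducible from a single seed.

**Allele ages via carrier blocks.** Per-site founder allele frequencies
are drawn from a discretised spectrum with density ∝ f^(−α) on
[1/(2·n_founders), 0.5] (α = 1 by default, so rare variants dominate), and
the carriers of each variant form a contiguous block in a fixed circular
ordering of the founders. The block plays the role of a clade: a common
(old) variant is carried by a wide arc of mutually similar founders and is
therefore robust to approximate donor identification, while a rare (young)
variant marks a narrow arc. This is what makes baseline imputation
accuracy rise with MAF, as in real data; with independent Bernoulli
carriers that gradient disappears entirely (tag-ability would not grow
with allele age), which is why the block construction is load-bearing.

**Bottleneck and drift.** The local population starts from a random
founder subset (`local_founder_fraction`, default 0.3 — a founding
bottleneck that shifts frequencies immediately) as a pool of
`drift_pool_haps` (default 600) haplotypes, then drifts for
`drift_generations` (default 10) rounds of re-mosaicking of the previous
pool at `drift_switch_rate` (default 25) switches per Morgan per round.
Each round therefore (i) resamples haplotypes — classical drift — and
(ii) deposits junctions the global panel has never seen — haplotype-
structure divergence. A "generation" is best read as an epoch worth a few
dozen meioses; with a literal one-crossover-per-Morgan rate the 3 cM
region would accumulate essentially no new structure at desk scale, and
with the full mosaic rate all trackable LD would be destroyed within a
few rounds. The sequenced cohort (90 subjects) is drawn from the drifted
pool at the end, so cohort coalescence stays realistic and the MAF-bin
composition is stable across drift settings.

**Ascertainment.** Array sites are a random fraction (`array_density`,
default 0.5) of the SNVs whose *global-panel* MAF is at least
`array_ascertainment_maf` (default 0.10) — commercial arrays are designed
on cosmopolitan frequencies and are sparse subsets of common SNPs. Exome
target sites are all variants inside capture windows covering
`exome_fraction` (default 0.7) of the region. Small fractions of sites
are emitted as indels (2%) and flagged multi-mapping (1%) purely so the
corresponding QC exclusions have work to do.

**Error and quality model.** Called genotypes are the truth perturbed at
`genotype_error_rate` (default 0.001, matching the ≥99.9% array–sequence
concordances typical of QC'd exome data) with one-step dosage moves;
an injected error receives a low GQ with probability `flag_prob` so
GQ-masking catches a tunable share. Site QUAL straddles the usual
threshold of 40 for a configurable site fraction. Phasing is consumed as
truth; `phase_switch_rate` can inject switch errors (genotypes invariant)
for sensitivity analyses, and defaults to 0.

**What the generator does not emulate:** genotype-calling artefacts
correlated across sites or subjects, pedigree structure, strand ambiguity,
multi-allelic sites, selection, gene conversion, and mutation after the
founder pool (every local variant exists in the founder pool, so
cohort-private variants arise only by frequency, not by origin). Passing
tests therefore demonstrate the mechanism — local haplotype capture
improving rare-variant tagging — not calibrated real-data effect sizes.

## QC cascade

Order (each stage logged with removals): site QUAL ≥ 40 → per-call GQ < 20
masked missing → site call rate ≥ 50% → MAF ≥ 0.75% of non-missing alleles
(with ~99 diploids this is "at least two minor alleles") → exact
Hardy-Weinberg p ≥ 1e-4 → multi-mapping sites dropped → non-SNVs dropped.
MAF is computed after GQ masking because masking precedes the frequency
filter in the cascade. The HWE test is the exact conditional test: the
two-sided p-value sums the probabilities of all heterozygote counts no
more probable than the observed one, computed with the standard ratio
recurrence and verified against closed-form enumeration to 1e-12 for all
sample sizes up to 200.

Array and sequence calls for the shared subjects are merged on the site
union; mismatches on overlapping sites are counted per subject and per
variant *before* exclusion, subjects with > 50 and variants with > 30
mismatches are dropped (values at the threshold retained — the published
thresholds are strict inequalities), and at retained overlaps the sequence
call wins, the sequence being the downstream gold standard (array calls
fill sequence-missing genotypes). Minor-allele concordance is reported
count-based per MAF band — the fraction of overlapping call pairs in
which either source carries ≥ 1 minor allele that agree exactly; the
denominator convention is stated here because published concordance
figures often leave it implicit. Finally the matrix is intersected with
the global panel on (position, ref, alt) — allele-code mismatches counted
separately from absence — and subjects called at fewer than 80% of the
combined panel are dropped (exactly 80% is retained).

## Imputation engine

Haploid Li–Stephens HMM over the full site grid; array sites emit, other
sites are silent, so posteriors at untyped sites are exact rather than
interpolated. No-switch probability `exp(−4·Ne·d/H)` per interval with
the switch mass uniform over all `H` states (self included); `Ne` defaults
to 20,000. Miscopy probability λ derives from Watterson's θ:
`θ = 1/Σ_{i<H} 1/i`, `λ = θ/(2(H+θ))`; emissions are `1−λ` on match, `λ`
on mismatch, 0.5 for a missing panel allele, 1 for a missing observation.
The recursion is scaled per site in linear space (normalisation is a
tested invariant; log-space is unnecessary at these lengths and ~2×
slower). Posteriors are verified against brute-force enumeration of all
`H^L` copying paths for panels up to 4 haplotypes and 6 sites at 1e-9.

Two panels are combined by haplotype concatenation on the primary panel's
site grid — deliberately *not* consensus-merged — with λ recomputed for
the combined count; sites absent from the secondary panel carry missing
alleles. A guard refuses to impute any subject whose haplotypes are
present in a panel, which is what makes the cross-validation non-circular
by construction. Chunking is unnecessary at desk scale (single chunk; the
region is far below the ~5 Mb chunks used for genome-scale runs).

## Evaluation

For each of the 90 sequenced subjects: observations are the subject's
phased alleles at array sites; dosages are imputed under both panel
configurations, the local panel with that subject's two haplotypes
removed. Targets are exomic, non-array SNV sites polymorphic in the
global panel (cohort-private variation is excluded by construction, as a
meta-analysis-oriented evaluation requires). Per target SNP, r² is the
squared Pearson correlation between dosage and truth genotype across
subjects, complete-case over missing truth; SNPs monomorphic among the
cohort or with degenerate dosage variance are recorded as undefined and
excluded from summaries.

Summaries bin on the cohort (gold-standard) MAF into √10-spaced bins
(1–3.2%, 3.2–10%, 10–32%, >32%; lower-inclusive, top bin closed at 0.5;
MAF < 1% excluded from the table), reporting n, per-configuration means
and medians, mean/SD/SE of the per-SNP increase, a two-sided one-sample
t-test of the increase against zero and a Welch test between adjacent
bins, and the ESS increase `100·(mean₂/mean₁ − 1)` rounded to whole
percent — defined on the ratio of bin means, the definition consistent
with the published derived cells. A secondary stratification uses
global-panel MAF bands (<1%, 1–3.2%, >3.2%); the improvement grid crosses
local MAF 1–10% rows with global-MAF columns including a <1% band.

## Problem sizes and reproducibility

The reference configuration — 1,200 sites over 3 Mb / 3 cM, 500 global
haplotypes, 90 local subjects, ~190 array sites — keeps one simulation
plus double cross-validation near 20 s on one CPU, so the five-seed
experiment and its doubled-drift twin complete in a few minutes; these
sizes were chosen as the smallest at which every MAF bin keeps tens of
SNPs per seed. All randomness flows from a single integer seed through
`numpy` seed sequences; identical configs are bit-reproducible, and every
output file header carries the tool version, config hash and seed.

## Known limitations

* Magnitudes are not calibrated to any real cohort: divergence knobs are
  free parameters, and the published absolute r² values are reproducible
  only in their derived-cell arithmetic, not from individual-level data.
* The two-panel concatenation is one defensible reading of "two reference
  panels, unmerged"; production tools may weight panels internally.
* The ESS-vs-ratio-of-means definition reproduces the published derived
  cells except one internally inconsistent printed cell (the Orkney >32%
  sample-increase entry), which this package does not attempt to match.
* Switch-error injection exists but the default evaluation consumes truth
  phase; real pre-phasing errors would shrink the measured gains.
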