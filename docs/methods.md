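# Methods

This note documents the statistical models implemented in `introsel`, the
choices made where the methods literature leaves room, and what the
simulation-based validation does and does not establish.

## Genotype model, filtering, polarization

Internally every dataset is a biallelic-SNP matrix of alt-allele dosages
(0/1/2, −1 missing) over samples grouped into populations.  Coordinates are
0-based half-open everywhere inside the package; VCF (1-based) and GFF3
(1-based closed) are converted on read, BED is native.  All per-site
quantities are computed over *called* alleles only, so missing genotypes
shrink the local sample size instead of biasing frequencies.

Site filters (applied on VCF read, both optional): keep sites with missing
rate strictly below `max_missing` (default 0.1) and minor-allele frequency
strictly above `min_maf` (default 0.05).  The unfiltered mode
(`SiteFilterSpec.none()`) exists because MAF filtering preferentially removes
the rare derived alleles that carry ABBA/BABA information and biases D-type
statistics; the D/f_dM pipeline uses it by default.

Polarization defines the derived allele as the minor allele **in the
outgroup** (frequency < 0.5).  Sites with an all-missing outgroup or an
exactly 50/50 outgroup are excluded and counted; a configurable
outgroup-polymorphism ceiling can exclude further sites.  Because the rule
only uses the outgroup, flipping the ref/alt encoding of the input leaves
every derived-allele frequency unchanged (tested as an invariant).

## Four-taxon statistics

**Patterson's D** follows the frequency form over polarized sites; sites
where the denominator term vanishes contribute zero to both sums (this is
automatic: a zero denominator term forces a zero numerator term).
Significance comes from a delete-one block jackknife over contiguous blocks
of equal SNP counts (default 20 blocks): SE² = (g−1)/g · Σ(θ₋ⱼ − θ̄)²,
Z = D/SE, normal p-value (two-sided by default, one-sided mode for the
directional excess-ABBA hypothesis).  Blocks with no informative sites are
dropped and logged; identical blocks yield SE = 0 and a flagged result.

**f4-ratio**: the donor P3 is split into disjoint random halves P3a/P3b
(⌈n/2⌉, ⌊n/2⌋, seeded).  The ratio is implemented exactly as the pipeline's
standard form, Σ(p̂3a−p̂O)(p̂2−p̂1) / Σ(p̂3a−p̂O)(p̂3b−p̂1).  A `form="f4"` flag
evaluates the same quantity written as explicit quartet statistics
f4(P1,P2;P3a,O)/f4(P1,P3b;P3a,O); the two agree term by term (each is the
other with numerator and denominator negated), which the tests assert — the
flag is a cross-check, not a correction.

**f_dM windows** (default 50 SNPs, step 25, per chromosome, over sites where
all four populations have data): numerator S(P1,P2,P3,O) =
Σ(1−p1)p2p3(1−pO) − Σp1(1−p2)p3(1−pO); the denominator substitutes a
dynamic donor P_d — when p2 ≥ p1 (P2–P3 sharing) p_d = max(p2,p3) in the
P2 and P3 slots, otherwise p_d = max(p1,p3) in the P1 and P3 slots with the
sign flipped — giving values bounded in [−1, 1], positive for P2–P3 and
negative for P1–P3 sharing.  Window calling offers both published rules:
top-5% quantile (default) or one-tailed Z-transform p < 0.05, in both cases
gated on genome-wide D > 0; called windows are merged into regions.

## Five-taxon DFOIL

Taxa (P1, P2, P3, P4, O) on (((P1,P2),(P3,P4)),O) with the P1–P2 split the
more recent.  The four statistics are (L−R)/(L+R) over fixed left/right
groups of eight derived-allele presence patterns; the groups are stored as a
data table in `introsel.dfoil.PATTERN_GROUPS` so they can be audited, and
their taxon-swap symmetries (1↔2 exchanges DFO/DIL and negates DFI/DOL;
3↔4 exchanges DFI/DOL and negates DFO/DIL) are asserted in tests.
Significance is a 1-df chi-squared test on the (L, R) totals.  The sign
vector of significant statistics maps to a direction through the published
truth table (`DIRECTION_TABLE`); `compatible_directions` additionally
returns every row not contradicted by the significant signs, the practical
reading when individual components lack power.

Two counting modes: *frequency-weighted* (pattern weight = product of p or
1−p across the five populations; the natural generalization for
population-frequency data; default) and *binarized* (population scored B at
frequency ≥ threshold; exactly the per-genome site counting of the original
five-taxon tool when inputs are single genomes).  The two coincide on
fixed-difference data (tested).

Power note: on desk-scale simulations the DFI/DOL components (which
diagnose *which* of P1/P2 received the flow) are recovered essentially
always, while DFO — whose introgression signal is diluted by the large
wild-lineage singleton pattern counts — is the limiting component; its
significance rate grows only with total sequence length.  The direction
validation therefore checks sign-vector *compatibility* with the expected
truth-table row (no significant contradiction, DFI required), and reports
the exact-match rate alongside.  The recovery scenario uses a symmetric
N_e = 2000 — the low-ILS regime the five-taxon test assumes (equal P3/P4
N_e matters: an asymmetric donor N_e alone creates spurious DFO/DIL
signal) — and the original tool's α = 0.01.

## Diversity and differentiation

π is the per-site unbiased heterozygosity 2p(1−p)·n/(n−1) summed over
usable sites; d_xy counts between-population allele mismatches over valid
comparisons.  Both offer two denominators: window length in bp (treats
non-SNP positions as invariant; the default, appropriate when the window is
fully accessible) and usable-SNP count (flagged `variant_only`).  For ≤5
samples both equal an explicit all-pairs allele-comparison oracle exactly
(tested).

Two F_ST estimators: Hudson (per-site numerator (pA−pB)² − pA(1−pA)/(nA−1)
− pB(1−pB)/(nB−1), denominator pA(1−pB)+pB(1−pA)) and Weir–Cockerham θ
(two-level variance components with observed heterozygosity).  Both are
ratio-of-sums within windows; negative estimates are reported raw (no
clamping) so window averages stay unbiased.  Defaults: WC for diversity
scans and uniparental loci, Hudson inside PBS.

Haplotype diversity h = n/(n−1)(1 − Σpᵢ²) with Nei's (1987) large-sample
variance 2/(n(n−1)) · {2(n−2)(Σp³ − (Σp²)²) + Σp² − (Σp²)²}.  (Printed sd
values in comparable wild-sheep tables do not follow from this formula and
were presumably produced by a resampling procedure; only the h values are
treated as checkable.)

Permutation significance shuffles population labels over pooled samples
(sizes preserved) and uses the add-one estimator p = (1+k)/(n+1), so p is
never exactly 0; degenerate statistics (undefined on >50% of permutations)
flag the result.

## PBS

Per window (50 SNPs, step 25) Hudson F_ST is computed for focal–ref1,
focal–ref2, ref1–ref2 as ratios of sums over the same sites (sites need ≥2
called alleles in all three populations, and — by default — polymorphism
across the three populations jointly, as in PBScan; monomorphic sites carry
no differentiation information and create degenerate windows).  Then
PBS = (T^SM + T^SG − T^MG)/2 with T = −ln(1−F_ST), natural log.

Numerical policy: inside scans, raw (possibly negative) window F_ST enters
the log — −ln(1−F) is well defined below 0 — because flooring at zero
creates a point mass at PBS = 0 that visibly breaks the uniformity of
permutation p-values under the null.  The scalar helper `pbs_from_fst`
keeps the conventional flooring/capping (floored at 0, capped at 1−1e−9,
logged) for reporting hand-computed values.

The Monte-Carlo null permutes individuals jointly across the three
populations (sizes preserved; default 2000 cycles) and recomputes all
window PBS values per cycle with cumulative-sum window arithmetic; p-values
use the add-one rule against either the pooled global null (default) or
each window's own null.  Calibration caveat: permutation exchanges
individuals, so the null is exact only when the three groups are
exchangeable.  On genuinely diverged populations the observed PBS
distribution differs from the permuted-mixture null by construction; the
calibration check therefore uses three pseudo-populations split from one
panmictic population, and p-values on real structure should be read as
enrichment ranks rather than strict error rates.  Selected regions are the
top 1% of windows by PBS (≥100 valid windows required; an all-equal PBS
vector is refused), merged.

## Region algebra

Region sets are sorted, merged interval collections.  Multi-set
intersection counts per-base coverage with a breakpoint sweep, so "common
regions across k populations" (min_support = k) is base-pair exact even
when the contributing window grids differ.  Annotation reports all
overlapping features (distance 0) or else the single nearest feature within
`max_distance`, with coordinate-signed distance (negative = feature left of
the region); ties break toward the smaller start coordinate; book-ended
features are reported as nearest with distance 0.

## Simulator

msprime coalescent with a fixed topology: outgroup; wild subpopulations W1,
W2 splitting at 2,189 generations; a domestic ancestor splitting from the
wild lineage at 3,330 generations; a reference population (MEN) plus
candidate populations radiating at 1,000 generations; one admixture pulse
from W2 into a configurable subset of candidates at generation 500
(~1,500–2,000 years ago, consistent with ancient post-domestication gene
flow).  Pulse age matters at desk scale: the migrant-lineage configuration
decorrelates along the genome at scale ~1/(r·t_pulse), so a very recent
pulse leaves only a handful of independent realizations in a 10–20 Mb
replicate and the realized genome-wide signal then varies strongly between
replicates.  The
wild and wild/domestic split times follow the published SMC++ estimates at
3 years/generation and μ = 1e-8/site/generation; the domestic radiation
time, all N_e values (default 10,000), and the outgroup split (50,000
generations — compressed relative to a realistic bighorn split) are
illustrative round numbers, not inferred quantities.  Generation time only
converts generations to years in reports.

Truth tracts are exact: migration records at the pulse time are mapped down
to sampled haplotypes through `tskit.link_ancestors`, giving per-haplotype
donor-ancestry segments whose mean per-haplotype genome fraction has
expectation f (the merged union across haplotypes approaches 1−(1−f)ⁿ and
is the right object for region-recovery checks).  The sweep model is a
deterministic frequency distortion — in-interval derived frequencies move
`strength` of the way to fixation and genotypes are resampled — which
creates a PBS signal at a tiny fraction of the cost of forward simulation
but has no linked-selection footprint (no haplotype structure, no local
diversity trough beyond the frequency shift).

What the simulations do not emulate: real recombination-rate and mutation-
rate heterogeneity, genotyping error, reference bias, population growth or
bottlenecks beyond constant N_e, and multi-pulse or continuous migration.
Passing the validation suite therefore demonstrates correctness of the
statistics and calling logic under the stated model, not robustness to
real-data artifacts.

## Validation experiments (problem sizes)

Chosen as desk-scale study conditions; all seeds derive from one input seed.

- **Null calibration of D**: 100 pulse-free replicates, 10 Mb each
  (~35–40k SNPs, 5 populations × 4 diploids), 20-block jackknife; the
  two-sided test's rejection rate at α = 0.05 must sit in 5% ± 3% and mean
  Z near 0.
- **PBS permutation uniformity**: 10 replicates of 2 Mb with 24 diploids of
  one population split 8/8/8; pooled, thinned window p-values pass a KS
  test against U(0,1) at α = 0.01.
- **f4-ratio recovery**: f = 0.3 pulse at generation 100, 20 replicates of
  10 Mb; the mean estimate must land within ±0.1 of truth.  The recent
  pulse is the estimator's validity condition: migrants from an older pulse
  miss the donor drift accumulated after their departure, deflating the
  numerator relative to the split-donor denominator (measured: a
  500-generation pulse at f = 0.3 yields ≈ 0.21) — a property of the
  f4-ratio itself, shared by any tool computing it.
- **Recipient flagging**: f = 0.2 into 2 of 4 candidates, 20 replicates,
  ~22 Mb (~115k SNPs) with 8 diploids per population (matching the
  per-population sample sizes typical of the motivating study); the
  D > 0 ∧ f4 > 0 ∧ p < 0.05 rule (two-sided jackknife p, no
  multiple-testing correction) must identify exactly the two recipients in
  ≥90% of replicates.  Note the uncorrected rule's exact-set rate is
  bounded near 0.93 by design: each null candidate is falsely flagged with
  probability ≈ α/2 (positive tail) × P(f4 > 0).
- **Sweep recovery**: strength 0.9 sweep over a 200-kb interval, 20
  replicates of 5 Mb; the top-PBS window must overlap the interval in ≥90%.
- **f_dM tract recovery**: f = 0.5, 20 replicates of 2 Mb; a called region
  must overlap a truth tract in ≥90%.
- **DFOIL direction**: f = 0.2 W2→C1 at generation 100 (recent-pulse
  regime, as for the f4-ratio above), 20 replicates of 20 Mb at
  N_e = 2000, binarized counting, α = 0.01; the sign vector must be
  compatible with the P3→P1 row in ≥80%.

## Known limitations

- The f4-ratio with a split donor is noisy for small donor samples; its
  variance scales with the inverse of the P3a/P3b split sizes.
- DFOIL's DFO component is underpowered at desk scale (see above); on real
  whole-genome data (hundreds of Mb) this is not limiting.
- The permutation null for PBS is not calibrated under real population
  structure (inherent to the method, documented above).
- Windows are defined per chromosome on SNP counts; chromosomes with fewer
  SNPs than one window yield a single short window rather than none.
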