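# Methods

## Scope and data model

The package analyses two kinds of data. The *array stage* works on diploid
biallelic genotype calls (0/1/2 = alternate-allele count, NA = missing) for
hundreds of individuals at ~10²  nuclear SNPs plus a few chloroplast SNPs,
with individuals annotated by population and coordinates. The *pool stage*
works on per-pool alternate-allele frequencies estimated from read depths
in a small number of pools of equal numbers of diploids (canonically four
pools of 20). All genomic coordinates are 1-based inclusive internally;
BED export is the only 0-based half-open surface.

## Sample QC

Three filters run in the fixed order hybrids → clones → missingness and
the chain is idempotent.

- **Hybrid exclusion.** A diagnostic panel maps each panel locus to the
  genotype the focal species is fixed for; an individual's foreign-allele
  fraction is (non-focal alleles)/(2 × called panel loci) and individuals
  strictly above the cutoff (default 0.1) are removed. An F1 interspecific
  hybrid is heterozygous at every panel locus (foreign fraction 0.5), so
  the default removes F1s and early backcrosses while tolerating
  occasional genotyping error. The real assay logic behind such panels is
  proprietary; this fraction rule is the natural parameterization.
- **Clone removal.** Two individuals are clonemates when their genotypes
  mismatch at ≤ `max_mismatch` loci, ignoring loci missing in either.
  `max_mismatch` (default 0) absorbs genotyping error if raised. Groups
  form greedily in input order and the first member is kept — a stable,
  reproducible tie-break.
- **Missingness.** An individual is removed iff its missing fraction is
  *strictly greater* than the threshold (default 0.10): at 93 loci, 10
  missing (10.75%) is removed, 9 missing (9.68%) is kept.

## Diversity and differentiation

Per locus and population, H<sub>O</sub> is the heterozygote fraction and
H<sub>S</sub> = 2p(1−p), optionally multiplied by Nei's small-sample
factor 2n/(2n−1). H<sub>T</sub> = 2p̄(1−p̄) uses the unweighted mean of
population frequencies. Multilocus aggregation is the low-bias ratio of
sums: G<sub>ST</sub> = (ΣH<sub>T</sub> − ΣH<sub>S</sub>)/ΣH<sub>T</sub>.
Negative per-locus values stay in the sums; only the headline value is
truncated at zero (the raw value is reported alongside). The
Weir–Cockerham θ is computed from the standard per-locus variance
components a, b, c with multilocus θ = Σa/Σ(a+b+c), populations with no
data at a locus dropping out locus-wise. Both estimators are reported
because the field mixes them freely: G<sub>ST</sub> is the definition used
at the pool stage, θ the estimator behind most array-stage software.
G<sub>ST</sub> carries the classical (r−1)/r downward bias at small deme
number r, so the two agree closely only for many demes — the tests compare
them on a 10-deme balanced design.

**Hierarchical AMOVA.** Each allele copy is a 0/1 observation; the
three-level decomposition (among groups / among populations within groups
/ within populations) uses the textbook sums of squares and
unequal-sample-size coefficients per locus, summing components over loci.
F<sub>CT</sub> = σ²<sub>a</sub>/σ²<sub>tot</sub>,
F<sub>SC</sub> = σ²<sub>b</sub>/(σ²<sub>b</sub>+σ²<sub>c</sub>),
F<sub>ST</sub> = (σ²<sub>a</sub>+σ²<sub>b</sub>)/σ²<sub>tot</sub>, so
(1−F<sub>CT</sub>)(1−F<sub>SC</sub>) = (1−F<sub>ST</sub>) holds
algebraically; the tests assert it to 1e−10 and check the components
against a brute-force allele-copy oracle. Permutation p-values shuffle
whole populations among groups (for F<sub>CT</sub>) and individuals among
populations within their group (for F<sub>SC</sub>). The default is 999
permutations — the F<sub>SC</sub> permutation re-aggregates the full
individual × locus matrix per replicate, and 999 gives p-value resolution
of 0.001, ample for the screening role these tests play here; pass
`n_permutations=10_000` for publication-grade precision.

## Lineage classes and supervised admixture

An individual is *pure* for its max-Q cluster at threshold t iff
Q<sub>max</sub> > t strictly, otherwise admixed; values exactly at a
threshold are admixed (the conventions "Q > 0.667" and "Q < 0.9" are both
strict). The nested thresholds 0.667 and 0.9 are the shipped defaults.
Ties in max-Q go to the lowest cluster index.

The supervised EM estimator maximizes the binomial mixture likelihood of
an individual's genotypes over admixture proportions q, holding reference
lineage frequencies fixed (clamped to [1e−4, 1−1e−4]). Each of the two
allele copies at a locus is attributed to lineage k with responsibility
proportional to q<sub>k</sub>p<sub>k</sub> (alternate copy) or
q<sub>k</sub>(1−p<sub>k</sub>) (reference copy); the M-step averages
responsibilities. The log-likelihood is checked non-decreasing every
iteration. Identical references across lineages make q unidentifiable: the
estimator returns uniform 1/K with a warning. This is deliberately *not* a
replacement for unsupervised model-based clustering, which stays with
external software; it exists so the pipeline can run end to end.

## Cytonuclear discordance

Chloroplast SNPs are haploid; a heterozygous-style organellar call is an
error, reported with individual and locus. The haplotype is the ordered
allele string over retained cp loci; individuals with any missing cp call
are excluded (not imputed) and listed. Each haplotype maps to the modal
nuclear lineage among its pure (default Q > 0.9) carriers, with confidence
= modal fraction; even splits map to the lowest lineage index with a
warning, and haplotypes without pure carriers stay unmapped. A capture
event i→j is an individual pure (default Q > 0.667, configurable) for
lineage j carrying a haplotype mapped to lineage i ≠ j; counts are
reported per ordered pair with the asymmetry ratio, and admixed or
unmapped-haplotype carriers are tallied separately so discordant +
concordant + excluded = haplotyped individuals.

## Pool-seq stage

**Filtering.** A SNP survives iff it is biallelic, lies on a named
chromosome (scaffolds dropped; default rule accepts `Chr`-prefixed or
plain numeric names, or an explicit list), has quality ≥ 20, is called in
*every* individual pool with coverage inside [150, 500] inclusive, and is
supported by the merged pool at coverage ≥ 200. Each rejected SNP is
charged to the first rule it fails, in that order. Frequencies strictly
below the detection limit (default 2%) are set to zero — the limit of what
pooled sequencing distinguishes from error — and the operation is
idempotent and order-independent of the coverage rule.

**Endemic SNPs.** A SNP is polymorphic in a pool iff 0 < f < 1.
Categories: invariant, polymorphic-in-all, endemic to one pool,
shared-subset. When an admixed pool is designated, endemic counts are also
recomputed over the non-admixed pools only, since alleles segregating in
an admixed pool echo its source groups.

**F<sub>ST</sub>.** Per SNP, H<sub>S</sub> is the mean of 2p(1−p) over the
two sides of the contrast and H<sub>T</sub> = 2p̄(1−p̄) with p̄ the
unweighted mean across sides; multilocus F<sub>ST</sub> =
(ΣH<sub>T</sub> − ΣH<sub>S</sub>)/ΣH<sub>T</sub>. Monomorphic SNPs
contribute zeros to both sums, so including them never moves the value.
For one-vs-rest contrasts the "rest" frequency is the unweighted mean of
the other pools (equal pool sizes make this the pooled mean). This
two-side Nei form is algebraically non-negative per SNP, so no truncation
arises. Frequencies, not read counts, feed the estimator, and no
pool-size/coverage variance correction is applied — a known limitation
shared with the frequency-based convention; unbiased pool-seq estimators
are out of scope.

**Genome scans.** Half-open windows (default 500 kb, ≥ 5 scored SNPs) tile
each chromosome; windows strictly above the chosen quantile (default
0.99) of window means are peaks and adjacent peaks merge into regions,
exported as BED. A constant track yields no peaks by the strict-inequality
tie rule.

## Joint allele-frequency spectra

For pools of N and M diploids the spectrum is a (2N+1) × (2M+1) count
matrix; a SNP's cell is (round(f<sub>A</sub>·2N), round(f<sub>B</sub>·2M))
with half-away-from-zero rounding, chosen over flooring so the class
boundaries are symmetric around each allele count. Polarization is
alternate-vs-reference — the only option without an outgroup — and is
recorded in the grid metadata. Masking removes cells with frequency ≤
cutoff (default 5%) on *both* axes: a 3×3 corner for 20-diploid pools.
Counts are conserved under masking.

Expected spectra come from a two-deme forward Wright–Fisher simulation:
ancestral frequency per locus ~ Beta(0.5, 0.5) (mass at both intermediate
and extreme frequencies, like a standing site-frequency spectrum), both
demes start there, and each generation applies deterministic migration
(m<sub>12</sub> = fraction of deme 1's parents from deme 2) followed by
binomial resampling of 2N<sub>e</sub> chromosomes. Migration epochs define
the four scenarios: always off (isolation), always on
(isolation-with-migration), on only before T_switch generations ago
(ancient migration), on only after (secondary contact). No new mutation is
introduced, so shared variants under isolation trace to the ancestral
pool. Deme frequencies are binomially down-sampled to 2N/2M draws,
accumulated over replicates, and normalized over unmasked cells.

Model scoring uses the Jensen–Shannon divergence between normalized
observed and expected grids over the observed grid's unmasked cells — a
symmetric, bounded proper divergence; the underlying comparison in the
field is visual, so any proper divergence is defensible. Candidates within
`tie_tol` (default 10% relative) of the minimum are reported as a tie set:
migration-timing variants with matched recent migration are genuinely
near-indistinguishable and the scorer must say so rather than pick
arbitrarily.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not the biology of any particular river system.

- **Lineages.** A shared ancestral frequency per locus ~ Uniform(0.05,
  0.95); lineage frequencies are Balding–Nichols Beta deviates around it
  with per-lineage divergence F (default 0.15, in the range implied by
  strong intraspecific structure). Pure individuals carry admixture vector
  e<sub>k</sub>; a configurable fraction are two-lineage mixtures with
  weight ~ Uniform(0.2, 0.8) (weights nearer 0/1 would be
  indistinguishable from pure). Genotypes ~ Binomial(2, q·p).
- **Chloroplasts.** Each lineage gets a distinct haploid allele pattern
  over the cp loci; an individual's haplotype is its nuclear (max-Q)
  lineage's pattern except for planted captures, which replace it with
  another lineage's pattern with the per-direction probabilities in
  `capture_rates` and are recorded in the truth ledger. Captures are
  planted only on pure, non-hybrid individuals so planted counts are
  exactly recoverable by the detector; they are planted as haplotype
  replacement, not via a mechanistic seed-dispersal model.
- **Clones, hybrids, missingness.** Clones copy an earlier individual of
  the same population; F1 hybrids get one genome from the focal gene pool
  and one drawn at ½ per locus, and are heterozygous at every diagnostic
  panel locus; missing calls are masked independently after cloning.
- **Pool sequencing.** Coverage ~ negative binomial (mean, gamma shape;
  empirical pool-seq coverage is overdispersed relative to Poisson); the
  alternate-read count ~ Binomial(coverage, f′) with f′ = f(1−e) + (1−f)e
  for per-read error e. Estimation from these counts is unbiased to within
  ±0.005 at 300× over 1,000 SNPs (asserted in tests).

What the generator does *not* emulate: linkage between loci, geographic
spatial autocorrelation beyond the lineage level, reference bias or
mapping artefacts in pool depths, and locus-specific selection. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated generative model, not robustness to those real-data features.

## Problem sizes and numerical choices

Defaults mirror the emulated study design: 3 lineages, ~1,000 trees spread
over ~250 localities of ~4 trees each, 93 nuclear + 3 cp SNPs, pools of 20
diploids at ~300× mean coverage; tests use smaller explicit configurations
where scale is irrelevant to the property under test. Divergence simulations in the shipped tests and acceptance
script use N<sub>e</sub> = 250, T = 500 generations and 2,000–5,000 loci
with 30–40 replicate trials — sizes chosen to make the recovery and tie
experiments statistically decisive while keeping a full run comfortable on
a laptop; all seeds are explicit and every simulation is deterministic
given its seed. EM convergence is |Δ log L| < 1e−6 with a 500-iteration
cap (non-convergence is flagged, best estimate returned). Reference
frequencies and mixture weights are clamped away from 0/1 to keep
likelihoods finite. Degenerate inputs (all-masked grids, contrasts with
ΣH<sub>T</sub> = 0, haplotypes without pure carriers) are flagged or raise
with specific messages rather than returning silent zeros.

## Known limitations

- Pool F<sub>ST</sub> ignores the sampling variance contributed by finite
  pool size and finite coverage; values at low coverage are upward-noisy.
- The AMOVA treats allele copies as independent observations (no
  within-individual level); inbreeding inflates σ²<sub>within</sub>
  slightly.
- Divergence-model scoring is a screening tool: it compares spectrum
  shapes, not likelihoods, and cannot separate scenarios whose spectra
  coincide (reported as ties).
- Unsupervised clustering, outlier scans against simulated null
  distributions, and genotype–environment association are intentionally
  out of scope; their outputs (Q-matrices) are inputs here.
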