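# Methods

This note documents the models, numerical choices, and open design
decisions behind `rilmap`, in the order the pipeline runs.

## Population model (simulator)

A line starts as the F1 of a Zhang gu × A2 cross (one haplotype per
parent, fully heterozygous) and is selfed by single seed descent — one
offspring per line per generation, no selection, no line loss — to a
target generation (default F10, i.e. nine selfing meioses). Meiosis
follows the Haldane model: the number of crossovers per chromosome is
Poisson with mean equal to the genetic length in Morgans, crossover
positions are uniform on the genetic map, and there is no interference.
Genetic length 0 is legal and yields non-recombinant parental
chromosomes.

The cM↔bp relation is linear by default and piecewise linear when
anchor points are supplied (to emulate recombination deserts or
pericentromeric suppression). SNP positions are either given explicitly
or drawn uniformly without replacement from the chromosome, emulating
the irregular marker spacing of reduced-representation sequencing; they
are drawn from the same seeded RNG as the meioses, so the entire
simulation is a pure function of the seed.

Expected properties used as oracles in the tests:

- heterozygosity halves per selfing generation, (1/2)^(t−1) at F_t
  (≈ 0.00195 at F10);
- the recombinant fraction between homozygous genotypes of selfed RILs
  follows Haldane–Waddington, R = 2r/(1+2r);
- the realized junction list per line is returned with continuous
  positions; `resolvable_breakpoints` projects it onto the SNP grid
  (junctions in the same inter-SNP gap collapse to their net effect),
  which is the strongest truth an SNP-based caller can be compared to.

The degradation model sets each call to missing independently (default
20%) and flips each surviving homozygous call to the opposite parent
(default 1%). Heterozygous calls are never flipped: at F10
heterozygotes are ~0.2% of calls and the error model represents
misassigned parental reads. What the simulator does *not* emulate:
read-level noise at heterozygous sites (real low-coverage data shows a
het region as a ~50:50 mixture of `a`/`b` calls rather than `h` calls),
crossover interference, segregation-distorting selection during
inbreeding (a per-locus gamete transmission bias is provided as a
hook), and non-additive or GxE trait architecture. Passing tests
therefore demonstrate correctness of the pipeline's logic under its
stated assumptions, not robustness to every artifact of real data.

Phenotypes are additive: y = Σ a_q·x_q + ε with x_q ∈ {+1, 0, −1} for
Zhang gu / het / A2 at the SNP nearest the planted QTL and ε Gaussian.
A positive effect means the Zhang gu allele increases the trait — the
package-wide sign convention. Planted QTL are placed on the simulator's
*true* genetic coordinates (the generating map), not on an estimated
linkage map, so parameter-recovery tests compare against truth.

## Sliding-window genotype calling

Windows span 15 consecutive SNPs and slide one SNP at a time. A window
is classified from its informative (parental) calls: Zhang gu when the
Zhang gu fraction is ≥ 11/15, A2 when ≤ 4/15, heterozygous between —
the printed thresholds, scaled as fractions so windows containing het
or missing calls degrade gracefully. A window needs at least 8
informative calls, except that a window in which het calls hold an
absolute majority is classified heterozygous outright (such windows are
the signature of a real het tract, where parental calls are scarce by
construction).

Each SNP then takes a consensus over the up-to-15 windows containing
it, keyed on the *composition* of the votes:

- **Conflicting parental votes** (both Zhang gu- and A2-classified
  windows contain the SNP) identify a crossover transition zone — the
  middle band of the window rule necessarily fires on windows mixing
  the two parents. The parental majority wins, ties → het. This
  localizes a clean junction exactly between its flanking SNPs.
- **Single-sided parental votes** compete with het votes; the larger
  count wins (tie → het). This keeps the edges of real het tracts
  exact, where flank-dominated and het-dominated windows overlap.
- Only het votes → het; no called windows → the SNP keeps its raw call.

Simple alternatives fail measurably: a plain plurality over window
votes turns *every* clean junction into a spurious ~4-SNP het band
(the transition windows outnumber each parental side), and a rule where
het needs only an absolute majority breaks at 20% missingness, where
the middle band stochastically widens past half the votes at ~1/3 of
junctions. The composition rule recovers ≥ 99.8% of per-SNP genotypes
at 1% error + 20% missingness with ≤ 3% breakpoint-count inflation.

Maximal runs of identical smoothed calls become blocks (missing calls
never split a block); blocks supported by fewer than 3 called SNPs
(configurable) are absorbed into the longer neighbour as a noise guard.
Breakpoints are reported at the first SNP of the downstream block, with
the full (last upstream SNP, first downstream SNP) interval retained.

**Resolution limit.** A true parental block spanning fewer SNPs than
the window cannot survive any implementation of the 15-SNP 11:4 rule:
blocks of ≤ 4 SNPs are absorbed (every window containing them is
majority-opposite), and 5–14-SNP blocks are called heterozygous with
edges shifted by a few SNPs. At ~2 junctions per Morgan (the selfed-RIL
junction density) and ~25 SNPs/cM, about 1% of true junctions sit in
such blocks, which bounds error-free breakpoint recovery near 99%
rather than 100%. Chromosomes with fewer informative SNPs than one
window fall back to a whole-chromosome majority call.

## Bin map

Reported breakpoint positions are pooled per chromosome and clustered
by single linkage with a 50 kb minimal interval (the merge radius used
for the study data; the alternative 10 kb reading is available via
`min_interval`). Each cluster is replaced by its midpoint — unbiased
under symmetric placement error. The boundaries partition the
chromosome; per line, an interval's genotype is the consensus of its
smoothed calls there, and adjacent intervals with identical genotype
columns across all lines merge into maximal bins.

The consensus threshold defaults to 1.0 (any disagreement → missing):
because the input is already smoothed, within-interval disagreement
almost always means the line truly recombines inside the bin (its
junction was displaced by the cluster midpoint), and a definite
genotype there would be wrong — and would break the reconstruction
guarantee that the bin matrix reproduces the smoothed calls wherever
both are called. A laxer threshold (e.g. 0.8) is available for
unsmoothed input. Intervals containing no SNPs merge toward the
chromosome start (logged). Coordinates are 1-based inclusive; bins tile
each chromosome exactly and are named `bin1…binK` in genome order.

## Linkage map

Marker order is physical: bins derive from a reference assembly, so
ordering algorithms are out of scope. Distances between adjacent bins
come from two-point recombinant fractions corrected by
Haldane–Waddington (r = R/(2(1−R))) and a mapping function — Kosambi by
default (standard for crop maps), Haldane selectable; both invert to
1e−10 over r ∈ [0, 0.49].

The public two-point estimator counts opposite homozygotes over
pairwise-complete homozygous lines. Map *assembly*, however, uses an
extended adjacent-pair count: genotypes score 0 / 0.5 / 1 (A2 / het /
Zhang gu) and a line missing at the right bin of a pair defers to its
next informative bin rightward. The two extensions exist because plain
hom/hom counting systematically loses junctions — each residual het
tract contributes two hom↔het transitions that pairwise exclusion
discards (~9% of breakpoints at F10), and a line straddling a merged
boundary is missing in exactly the bin where it recombines — and those
losses shortened maps by ~15%; with consensus 1.0 they removed up to
90% of map length, since the excluded lines are precisely the
recombinants. The extended count attributes every observed junction to
exactly one adjacent pair. Pairs with fewer than 20 informative lines,
or R ≥ 0.5 (treated as estimation noise, clamped), are flagged and
receive a distance interpolated from the nearest unflagged pair's
cM-per-bp rate on that chromosome. Measured recovery on simulated
defaults is within ±6% of true per-chromosome lengths.

## QTL scans

Genotype probabilities on a 1-cM grid (plus all bin positions) follow a
two-state Markov chain over the homozygote states along the RIL mosaic,
with transition probability R(d) = 2r/(1+2r), r from the inverse
mapping function of the separating map distance. Observed bins are
degenerate (including observed hets); missing flanks widen to the
nearest informative bins; a line with no informative bin on a
chromosome gets the uniform homozygote prior. Residual heterozygosity
between bins is ignored (P_het = 0 there): at F10 it affects ~0.2% of
genotype mass. Het bins score 0 on the ±1 scale.

Scans are Haley–Knott regressions of phenotype on the expected score
x = P(ZG) − P(A2): LOD = (n/2)·log₁₀(RSS₀/RSS₁), additive effect = the
coefficient of x, R² = 1 − RSS₁/RSS₀ in percent. This is a deliberate
departure from EM maximum-likelihood interval mapping: for RILs (no
dominance, near-complete information) the LOD curves are practically
identical and the regression form vectorizes over permutations.
RSS₁ is floored at RSS₀·1e−12, capping LOD at 6n for perfect fits;
grid positions with no score variance get LOD 0; a zero-variance
phenotype yields a flat curve with a warning.

Composite interval mapping conditions on background bin cofactors
chosen once per trait by forward stepwise regression — capped at 5
(WinQTLCart Model-6 convention) *and* gated by an F-to-enter test at
p < 0.01. The gate matters: unconditionally adding five cofactors to
200 lines lets pure-noise cofactors shrink the residual genome-wide,
and when one is dropped inside the 10-cM blocking window its chance
association reappears as a ghost peak at the test position (observed:
marginal LOD 1.5 inflated to conditional LOD 4.2). At each grid point
cofactors within the blocking window are dropped and the model is
refit; grid points are grouped by retained-cofactor set so each group
is a single batched projection. With zero cofactors the code path is
identical to plain interval mapping, bit for bit.

Significance thresholds are empirical (1−α) quantiles (upper order
statistic) of the genome-wide maximum LOD over phenotype permutations
(default 1000, α = 0.05), seeded and deterministic. Permutations
re-run the *same* model as the real scan — for CIM including cofactor
re-selection per permutation, since the null must be given the same
opportunity to overfit background markers. Measured genome-wide type-I
error with IM thresholds is ~5% per trait.

QTL are declared per maximal above-threshold segment at the LOD peak
(ties toward the smaller cM), with a 1.5-LOD support interval, named
`q` + lowercase trait abbreviation + chromosome number, suffixed
`-1`, `-2`, … in cM order when one trait has several QTL on a
chromosome. Thresholds are per trait and per environment; the two
photoperiod environments are scanned separately.

## Segregation distortion and trait statistics

Each bin's Zhang gu / A2 counts (hets and missing excluded) are tested
against 1:1 with a 1-df χ² goodness-of-fit test; bins with fewer than
20 informative lines report a missing p-value. Bonferroni correction
across bins is the default — the flag exists to highlight regions, not
to claim a calibrated genome-wide test. Trait correlations are Pearson
product-moment coefficients on pairwise-complete observations
(Spearman by flag) flagged at 0.05/0.01; constant traits report a
missing coefficient.

## Sizes used in the shipped checks

The test-suite and acceptance-script simulations are desk-scaled
versions of the study design, chosen to keep each check's sampling
error well inside its asserted tolerance: 200 lines on nine ~1-Morgan
chromosomes of 2500 SNPs for breakpoint/bin/map recovery; 200 null
traits × 200 permutations for type-I calibration; 100 replicates for
detection power of a 10%-variance QTL; 300 lines for the
heterozygosity-decay check. The full pipeline is deterministic given
the configuration seed, and the run manifest records config, seed,
version, and per-artifact checksums.

## Known limitations

- Junctions in true blocks narrower than the 15-SNP window are not
  recoverable (see the resolution limit above); breakpoint recovery on
  error-free data saturates near 99%, not 100%.
- Two-point map assembly is not multipoint maximum likelihood; with
  very sparse bins or heavy missingness the flagged-pair interpolation
  is only as good as the local cM/bp rate.
- CIM here is Haley–Knott with fixed conventions (5 cofactors, 10 cM
  window, 1 cM step); it is not a reimplementation of any particular
  legacy tool's likelihood machinery, and multiple-QTL models,
  epistasis, and QTL×environment tests are out of scope.
- VCF input goes through a thin converter (biallelic SNVs at which the
  two parents are homozygous and different); the ab dialect is the
  canonical input and the converter does no filtering beyond that rule.
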