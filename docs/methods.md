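# Methods

This note records the models implemented in `ryekit`, the choices made where
the underlying procedures left details open, and what the synthetic-data
generators do and do not emulate about real sequencing data. No empirical
claim is made here beyond what the test suite and `scripts/acceptance.py`
compute.

## Depth karyotyping

### rpmm and r

Per-sample read counts in non-overlapping 1-Mb bins of a combined wheat+rye
reference are expressed as rpmm = log₂(count / (total_mapped / 10⁶)).
Zero-count bins receive a pseudocount of 0.5 reads before the log; the
pseudocount only needs to keep the track finite, and any fixed small value
cancels in comparisons between samples with zero coverage in the same bin.
The normalized track r subtracts a designated reference sample's rpmm bin by
bin, removing mappability structure shared with the reference. The reference
track is an explicit input, never hard-coded (historically a 'Chinese
Spring'-type hexaploid wheat sample).

### Features and the min-substitution rule

featureA = −log[(mean r¹ᴬ_I − mean r¹ᴬ_N)·(mean r¹ᴿ_I − mean r¹ᴿ_N)] and
featureB analogously with 1B. Window means use only bins lying wholly inside
the I window (terminal 200 Mb of the normally introgressed end) or N window
(terminal 300 Mb of the opposite end); bins straddling a boundary are
excluded — the conservative reading, since windows are defined in bp and
bins in whole Mb. The logarithm is natural; the formula is written with an
unqualified "log", and the base only rescales both features monotonically,
which cannot change the separability seen by a kernel classifier. The base
is nonetheless configurable.

When the log argument is ≤ 0 the feature is undefined and is replaced by the
minimum of the defined values of that feature across the cohort, with a flag
recorded. Note this rule fires *systematically* for true introgression
carriers: a 1AL.1RS sample has a strongly negative 1A factor and strongly
positive 1R factor, so its featureA argument is negative. The geometry that
results — carriers pinned at the per-feature substitution value, ambiguous
and non-introgressed samples spread along distinct ridges — is deliberately
left to the classifier rather than reinterpreted.

### Classifier

A soft-margin SVM with RBF kernel and cost C = 1 on the two (standardized)
features. The kernel bandwidth uses the median heuristic
γ = 1/median(‖x−x′‖²) computed on the standardized features with coincident
points excluded (coincidence is common after min-substitution); the original
analysis relied on its toolkit's internal bandwidth estimation, which is not
specified further, and any reasonable data-driven bandwidth separates these
features equally well. Train-size cross-validation draws random training
subsets without replacement (sizes 50–600, 100 repeats per size by default),
fits on the subset and scores accuracy on the remainder, reporting the
per-size distribution (mean and quartiles).

## Synthetic depth cohorts

`DepthSimConfig` defaults define the study conditions used throughout the
tests: chromosomes 1A = 590 Mb, 1B = 690 Mb, 1R = 980 Mb; 2×10⁶ reads per
sample; negative-binomial per-bin counts with variance μ(1 + αμ), α = 0.1
(α = 0 gives deterministic expectations for exact tests); introgressed
chromatin attains 80% of reference depth (foreign chromatin maps less
efficiently); absent chromatin retains a 1% cross-mapping residual;
ambiguous samples carry a mild 15% 1RS elevation with no A/B depletion.
Introgression replaces the terminal 250 Mb of the wheat chromosome and adds
the terminal 350 Mb of 1R.

Each sample additionally carries a protocol-bias coefficient
b ~ N(0.35, 0.10) multiplying a fixed distal-to-proximal mappability
gradient (±0.5 log₂ units along each chromosome); the normalization
reference is generated bias-free. This models the sample-consistent residual
deviation from the reference that survives rpmm normalization in real
multi-panel data, where study samples and the reference run differ in
library protocol and trimming. It matters structurally: without *any*
sample-consistent component, the sign of the near-zero window-mean
differences in non-carrier chromosomes is an independent coin flip per
sample, the min-substitution rule fires at random, and distinct karyotypes
collapse onto identical feature points — no classifier could then reach the
accuracy the real analysis reports. The real panels' noise levels are not
published; these values are this package's calibration choice, fixed once.

The generator draws binned counts directly; it does not emulate read-level
artifacts (GC bias within bins, PCR duplicates, multi-mapping ambiguity) or
segregating partial introgressions. Passing tests therefore demonstrate the
pipeline's statistical machinery, not robustness to every artifact of real
GBS libraries.

## Hi-C asymmetry and inversion calling

Links shorter than two bins (default) are dropped as self-ligation/short-
range noise. Each retained intra-chromosomal link increments `right` in the
bin of its smaller coordinate and `left` in the bin of its larger
coordinate, so Σleft = Σright = retained links exactly (a conservation
identity the tests assert). The per-bin statistic is
a = log₂(left+ψ) − log₂(right+ψ) with ψ = 1; computing the difference of
logs (not the log of a ratio) makes coordinate reflection negate the track
bitwise. Orientation is a convention — with this sign an inversion produces
an *ascending* ramp, strongly negative at its left edge — and is recorded in
output headers.

The detector subtracts a running median (window 4·min_len+1 bins) to remove
the slow chromosome-scale tilt that power-law contact decay produces near
chromosome ends, excludes 5 edge bins, then scores every interval of
min_len–max_len bins by closed-form least squares: candidates need fitted
rise ≥ 2.0 log₂ units and R² ≥ 0.85, and overlaps are resolved greedily by
R². Defaults were set against the simulator at its default link depth
(5×10⁵ links per 800-Mb chromosome) and verified to keep a flat null
chromosome call-free.

The link simulator draws contact distances from p(d) ∝ d^a with a = −1
(default) truncated to [1 Mb, chromosome length], places links in the
sequenced genotype's own coordinates, and maps them through the planted
inversions by integer reflection; overlapping truth inversions are rejected
as unsupported. The exact decay shape is immaterial to the asymmetry logic.
No Hi-C matrix normalization (ICE etc.) is performed, matching the
count-based statistic.

### Regional enrichment

The statistic is the number of calls whose midpoint lies in the region set
(a count statistic with an exactly simulable null); an overlap-based
statistic can be obtained by testing against midpoints of interest instead.
The null redraws each call uniformly within its own chromosome, length
preserved, 10,000 times by default, and P uses the add-one convention, so
the attainable floor is 1/10001 and zero calls give P = 1. Region sets
covering none or all of the genome are rejected as degenerate.
Pericentromeric boundaries for real genomes are user inputs.

## Windowed population genetics

All SNP-windowed statistics share one scheme: windows of 100 consecutive
sites advanced by 25, per chromosome, trailing partial windows dropped,
window position = mean position of the member sites. Missing data are
handled pairwise-complete for IBS and with per-site complete-within-group
frequencies for F_st and D — standard practice for these estimators.

*Filters.* The per-call depth filter (calls with depth < threshold set
missing) applies before site-level missingness is computed, so depth and
missingness interact the way they do in real pipelines. Filtering is
idempotent. Presets: lenient (≤30% missing, MAF ≥ 1%) and stringent
(depth ≥ 6, ≤5% missing, site quality ≥ 250).

*F_st.* The Weir & Hill (2002) variance-components estimator is implemented
as the two-level allele-count ANOVA with unequal sample sizes: per site,
MSP = Σmᵢ(pᵢ−p̄)²/(r−1), MSG = Σmᵢpᵢ(1−pᵢ)/Σ(mᵢ−1),
n_c = (M−Σmᵢ²/M)/(r−1), and the window estimate is the ratio of summed
numerators (MSP−MSG) to summed denominators (MSP+(n_c−1)MSG) — a ratio of
sums, which is stabler than averaging per-site ratios and is the accepted
reading of the method. Sites with an uncalled group are skipped within the
window.

*Polarization.* The ancestral allele is the allele appearing at least twice
in the three outgroup-subgenome alleles; triples with three distinct alleles
(no majority), or whose majority matches neither ref nor alt, are flagged
and omitted from polarized analyses.

*P_n/P_s.* A site counts toward P_n (P_s) when it is annotated
nonsynonymous (synonymous), polarized, and its derived allele is present in
the group with the site polymorphic within the group (site counting;
whether to require polymorphism is configurable). Bins with P_n + P_s < 10
are suppressed; P_s = 0 in a reported bin yields an explicitly flagged
infinite value rather than a silent overflow.

*D statistic.* Allele-frequency ABBA-BABA with the outgroup fixed ancestral.
The standard error uses a weighted delete-one block jackknife over
contiguous 5-Mb genomic intervals, with per-block weights equal to the
number of informative sites (ABBA+BABA > 0); blocks without informative
sites are skipped, and with fewer than two blocks the s.e. is flagged
undefined. Under the no-gene-flow simulation the resulting Z is
approximately standard normal (checked over 200 replicate panels in the
test suite).

*Clustering.* PCA on the mean-imputed, centered genotype matrix; k-means
with k = 7 on the first three components, 25 restarts with a fixed seed
(a single restart is seed-fragile).

## Synthetic genotype panels

Cluster allele frequencies follow a Balding–Nichols Beta spread around
shared ancestral derived-allele frequencies q ~ Beta(0.8, 2) with drift
parameter F (`divergence`, default 0.15; F = 0 reproduces q exactly — the
panmictic limit used for calibration). Gene-flow tracts copy the donor
cluster's frequencies into the recipient within a genomic interval.
Genotypes are Binomial(2, p); per-call depth is gamma-Poisson around 12×,
site quality uniform on [50, 500], and 8% of calls missing, so the stated
filters are genuinely exercised. `sel_differential` ∈ (0,1] scales
nonsynonymous derived frequencies in one designated cluster, emulating
stronger purifying selection. Outgroup triples have their majority equal to
the ancestral allele except at `outgroup_error` (default 5%) of sites, where
the triple carries three distinct alleles. The generator draws sites
independently (no linkage), so jackknife blocks contain independent sites;
real data's within-block correlation is exactly what the block jackknife is
for, and is not emulated.

For the planted-gene-flow demonstration the tests use divergence 0.3 and an
80-Mb tract (a quarter of the simulated chromosome 1) — within the range of
differentiation observed between wild and domesticated-like rye clusters —
because the ABBA excess from a tract scales with both drift variance and
tract mass.

## Synteny identity profiles

Best hits order by (E-value ascending, bitscore descending, alignment length
descending); residual ties fall back to subject-id lexicographic order and
are flagged, keeping the selection deterministic and row-order invariant.
Reciprocal best matches are computed separately per subject (sub)genome. The
identity profile uses sliding bins of 100 consecutive matches advanced by
20 matches — "increments of 20" is read as a match-step between successive
bins, which produces the smooth overlapping profiles the approach is used
for; the step is an explicit parameter rather than a silent guess. Bins
never span chromosomes; a gene's position is its annotated start coordinate.

## Flow cytometry

2C pg = sample G1 peak mean × standard 2C pg / standard G1 peak mean,
aggregated as the mean of per-replicate ratios (replicates are separate-day
runs; ratio-of-means is available), converted at 1 pg = 0.978 Gb, halved
for 1C. The estimate is invariant to common rescaling of both peaks.

## Problem sizes

The test suite and acceptance script run at desk scale: depth cohorts of
200–800 samples over three chromosomes (2,260 bins), Hi-C tracks of
5×10⁵–2×10⁶ links on an 800-Mb chromosome, genotype panels of 30–140
samples × 2,000–8,000 sites, and 200-replicate calibration loops — sizes
chosen so the full suite completes in about a minute while leaving every
statistical check well-powered.

## Known limitations

* The feature construction inherits the documented tension of the original
  formulation: near-zero rye signal makes −log of a tiny product large, not
  small, so "no rye" samples sit far from the origin; the classifier, not
  the features, carries the interpretation.
* The inversion detector assumes clean single-ramp signatures; nested or
  overlapping rearrangements and translocation breakpoints are out of scope.
* P_n/P_s uses site counts and annotated effects as inputs; no effect
  prediction is performed.
* The simulators are calibrated for structural fidelity (what each
  estimator assumes), not for matching any particular instrument's noise.
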