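# Methods

## Assay model

A panel is an ordered set of SNP loci, each carrying two allele probes and
one locus probe. The universal tails are single-sourced program constants:
the allele-probe 5' tail `TGGAGTTCAGACGTGTGCTCTTCCGATCT` (29 nt) and the
locus-probe 3' tail `AGATCGGAAGAGCGTCGTGTAGGGAAAGAGT` (31 nt). A ligation
product is therefore

    tail5p | barcode4 | allele_target (20–29 nt) | locus_target (20–28 nt) | barcode8 | tail3p

with length 72 + La + Ll. PCR is modeled as exact-match annealing: the
P7-side primer (`CAAGCAGAAGACGGCATACGAGAT` + 5-nt i7 + `GTGACTGGAGTTCAGACGTGT`,
50 nt) shares its terminal 16 nt with the start of tail5p, and the P5-side
primer (`AATGATACGGCGACCACCGAGATCTACAC` + 6-nt i5 + `ACACTCTTTCCCTACACGAC`,
55 nt) shares its terminal 18 nt with the reverse complement of tail3p.
Both overlaps are located at run time by string search rather than hard-coded,
so corrupted constants raise instead of silently producing wrong amplicons.
The amplicon is product + (50−16) + (55−18) = product + 71 bp, i.e.
143 + La + Ll, which over the permitted target lengths spans 183–200 bp and
always sits inside the 170–230 bp size-selection window; the panel validator
checks this window per amplicon anyway, so the invariant also guards custom
constants.

No thermodynamics, cross-hybridisation or probe-design scoring is modeled;
probe design is out of scope. Indel alleles ("+"/"−") are carried as symbols
only — assignment is barcode-based and never reads the variant itself.

Barcode combinatorics force a design rule: only 256 distinct 4-mers exist,
so allele barcodes are unique only *within* a locus, while the 8-nt locus
barcode is unique across the panel; the pair (barcode8, barcode4) then
resolves to at most one allele. `validate_panel` reports violations
(duplicate locus barcodes, identical allele barcodes within a locus, target
lengths out of range, amplicon size out of window) instead of raising, so a
parsed third-party panel can be QC'd as a whole.

## Read simulator

The generator emulates de-multiplexed single-end 126-nt sequencing of the
amplicons. Reads in the default `allele-first` orientation start right after
the sequencing primer, i.e. at the allele barcode:

    barcode4 | allele_target | locus_target | barcode8 | tail3p | revcomp(P5 flank incl. i5) | GGG…

(G-padding emulates the no-signal base of two-channel instruments once the
short amplicon is read through). The `locus-first` orientation is the
opposite strand read from the locus-probe side, in which both barcodes
appear reverse-complemented. The true on-instrument orientation is not
modeled as a fact; it is a configuration choice, and the assigner accepts
either layout.

Per (sample, locus) the depth is negative-binomial with mean `depth_mean`
(default 50) and dispersion `depth_dispersion` (default 10; `inf` selects
the Poisson limit), zeroed with probability `dropout_rate` (default 0;
intended to emulate loci absent from diverse germplasm) and always zero for
a U genotype. The allele-1 count is Binomial(depth, q) with q = 1 / 
`het_balance` / 0 for A / H / B (`het_balance` default 0.5); the alternative
`het_split="exact"` uses round(depth·q) and exists to build a *fully*
noise-free control in which genotype recovery must be exact. Substitution
errors are i.i.d. per base at `base_error_rate` (default 0.2%); with
probability `chimera_rate` (default 1%) a read's locus half
(locus_target + barcode8) is swapped for that of a uniformly chosen other
locus, emulating incorrect ligation products. Depth dispersion, error and
chimera defaults are plausible for a well-behaved Illumina amplicon run but
are not measured values; every one is exposed in `SimulationConfig`.

Population models: F2 draws loci independently at 1:2:1; RIL uses
P(A)=P(B)=(1−h)/2 with residual heterozygosity h = 0.02 by default;
germplasm draws per-locus allele frequencies from U(0.05, 0.95) and samples
homozygous lines. Loci are independent — no linkage map is simulated, since
map construction is outside the package's scope. Consequences for
interpretation: passing tests show the pipeline's correctness under
independent loci, uniform per-locus behavior and purely substitution-type
noise; they say nothing about locus-specific amplification bias, index
hopping, quality-correlated errors or real chimera-formation preferences,
none of which are modeled. Quality strings are constant ('I'); the pipeline
ignores qualities.

Determinism: one `numpy` Generator seeded from the config drives the whole
simulation in a fixed iteration order, so identical (config, seed) give
byte-identical FASTQ files.

## Read assignment

The assigner scans only the design gap set: for each distinct gap g in the
panel it tests the 8-mer at offset 4 + g against the locus-barcode index,
then requires the read's leading 4-mer to match one of that locus' allele
barcodes and g to equal that allele's design gap. Exactly one surviving
(locus, allele) is an assignment; several are `ambiguous`; none yields the
most specific rejection seen (`gap_mismatch` > `unknown_allele_barcode` >
`unknown_locus_barcode`), with `too_short` for reads shorter than
12 + min-gap. Barcode matching is exact by default; a 1-mismatch mode
(neighbor-index lookup, ambiguity → rejection) exists behind a flag but the
4-nt allele barcode leaves it little headroom. The gap comparison is strict
equality — sequencing indels are not modeled, and the filter is a distance
check, not an alignment. Target sequences are *not* compared during
assignment; an optional `verify_targets` mode additionally requires ≥ 90%
target identity. A chimera whose accidental gap equals a valid design gap
and whose allele barcode happens to match is accepted — an inherent
limitation of barcode-distance filtering; the simulator's truth table makes
this coincidence rate measurable.

The count table covers the full sample × locus grid in sample-sheet/panel
order; per-sample rejection tallies are written to a sidecar file, and
assigned + rejected = total holds per sample by construction (tested).

## Genotype calling

r = count1/(count1+count2); depth < `min_depth` (default 10) gives U,
r ≥ 0.90 A, r ≤ 0.10 B, 0.30 ≤ r ≤ 0.70 H, and the two open intervals in
between give C ("B or H") and D ("A or H") when `emit_intermediates` is on,
otherwise U. These boundary values are configuration defaults chosen to
separate the three ratio clusters cleanly at depth ≥ 10 — they are not a
published standard, so QC reports should always state the boundary set used.
Intermediates default to U in all QC metrics so that call-rate and
concordance denominators use the 4-symbol alphabet {A,B,H,U}. allele-1 is
the panel file's first-listed allele, making r's orientation deterministic.
Per-locus boundary overrides implement manual adjustment for loci with
skewed allele ratios. Boundary symmetry gives the mirror property
call(c1,c2) = mirror(call(c2,c1)), and at fixed depth the call is monotone
in count1 through B→C→H→D→A (both property-tested).

## QC metrics

Call rate is the non-U fraction of all sample × locus slots, overall or per
dataset. Concordance intersects two matrices on (sample, locus) id equality
(explicit id maps support cross-assay comparisons), builds the full
unordered pair contingency over {A,B,H,U}, and computes the rate over slots
called in both — U-containing pairs count toward the total but not the
denominator. Reproducibility averages per-duplicate-pair rates with equal
pair weights (the datapoint-weighted alternative differs only when pairs
share few slots; the unweighted mean is the simpler, documented choice).
Percentages are reported to one decimal, round-half-up, matching standard
table conventions.

## Marker filtering and subset selection

The filter chain order is fixed: missingness, overrepresentation,
segregation. Missingness uses all samples as denominator and removes
markers with U fraction strictly greater than the threshold (25% F2, 5%
RIL — RILs are harder to map, so stricter). Overrepresentation is computed
over *called* genotypes (missingness was already filtered) and removes
markers whose top class reaches ≥ 90% — "keep iff strictly below" — with
zero-called markers removed here as uninformative. The segregation test is
a plain chi-square GOF: F2 (nA,nH,nB) vs n(¼,½,¼) on 2 df; RIL A/B vs 1:1
on 1 df with residual H calls excluded (a 1:2:1-with-h model is out of
scope). p-values come from `scipy.stats.chi2.sf`; tests cross-check the
df=2 closed form exp(−x/2) and a df=1 erfc oracle to 1e-10. The p < 10⁻⁶
removal threshold keeps the false-removal expectation at ~10⁻³ per 1,000
undistorted markers while removing strong distortion (e.g. 0.7/0.2/0.1 at
n=190, noncentral mean ≈ 205 ≫ the 27.63 critical value) essentially always
— both calibrations are measured by the acceptance script.

"Segregates" has no standard definition; here a locus segregates in a
dataset when at least two called classes each reach ≥ 5% of called
genotypes, a threshold chosen to be robust to stray miscalls and exposed as
a parameter. Subset selection takes loci with < 25% U in ≥ 1 dataset,
tiers them by the number of datasets in which they segregate (≥ 2 / 1 / 0),
and fills the target plex tier by tier, deterministically in locus order;
it reports the tier composition and errors on a shortfall. No further
information-content ranking within a tier is attempted.

## Problem sizes and numerical choices

The simulated validation condition used throughout testing is 96 samples ×
96 loci at depth 50 (≈ 4.6·10⁵ reads), which gives binomial standard errors
of ~0.1 percentage points on call-rate estimates; the zero-noise control
uses Poisson depth and the exact het split because any stochastic noise
source (overdispersed depth below min-depth, binomial het draws outside the
H band) makes literal 100% recovery unattainable by design rather than by
defect. Oracle-equivalence checks use 1,000 reads (valid, mutated and
random) over four random 40-plex panels; amplicon-geometry checks include
the forced extreme target-length combinations so the printed 183/200 bp
bounds are hit exactly. Ties and degenerate inputs: zero-depth ratio scores
are undefined and excluded from ratio plots; empty count tables call U
everywhere; an empty genotype matrix is an error for call rate; concordance
requires a non-empty intersection.

## Known limitations

- Barcode-distance assignment cannot detect chimeras whose observed gap
  coincides with a valid design gap for a matching allele barcode.
- The simulator's noise model is substitution-only and locus-uniform; no
  indels, no per-locus amplification bias, no index hopping.
- The RIL segregation test ignores residual heterozygotes rather than
  modeling them.
- Reproducing the published real-data marker-filter trace requires the
  original supplementary F2 genotype table, which is third-party data not
  shipped with the package; the corresponding check runs only when that
  file is provided locally.
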