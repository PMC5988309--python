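# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package. Empirical figures quoted here are the ones
the test suite and `scripts/acceptance.py` themselves compute.

## Demographic model and simulator

Two focal lineages — Japan Sea (JS) and Pacific Ocean (PO) sticklebacks —
split `T` generations ago from an ancestor of size `N_ANC`. Five
divergence scenarios differ only in when migration is open (backwards in
time): **I** never; **IM** over `[0, T]`; **IAM** only in
`[T_anc_stop, T]`; **IRM** only in `[0, T_rec_start]`; **IARM** both
windows. `m12` is the proportion of the JS population replaced by PO
migrants per generation (backwards in time), matching the coalescent
convention in which lineages in JS jump to PO at rate `m12`; scenario I
forces both rates to zero. Three growth variants shape the JS lineage:
**constant**; **bottleneck** (size `N_JSB` during `[T_G, T]`, the
contemporary `N_JS` in `[0, T_G]`); **growth** (exponential from `N_JSB`
at `T_G` to `N_JS` at present). An optional Atlantic (AT) lineage splits
from PO at `T/2`, and an outgroup at `5 T` polarises alleles — in
simulated data the ancestral state is known directly, so the outgroup
lineage matters only for statistics that use it as a frequency track.

Defaults mirror the study system: mutation rate `7.1e-9` per site per
generation (one-year generations), `T = 7e5`, bottleneck `N_JSB =
1.22e4`, `m12 = 1.3e-6`, `m21 = 1.05e-6`. Loci are independent,
non-recombining fragments (2 kb at 125-kb spacing by default),
mirroring a sparse-locus sampling design; an optional per-locus
recombination rate is available for experiments in which a 10-kb window
should average several genealogies. Simulations use msprime; a fixed
seed fixes every output bit-for-bit (ancestry and mutation seeds are
derived from one `SeedSequence`).

What the generator does *not* emulate: real chromosome structure and
linkage beyond a locus, the neo-sex chromosome, RAD ascertainment,
sequencing error, and alignment artefacts. Green tests therefore
demonstrate correctness of the estimators and the internal consistency
of the pipeline on idealised data, not robustness to real-data noise.

## Windowed statistics

Windows are 0-based half-open tiles (default 10 kb, non-overlapping); a
trailing partial window is dropped. A window's *usable* site count is
its length minus the variant sites whose call rate falls below the
configured fraction (default: every haplotype called); invariant bases
are assumed callable, consensus-style. Haplotype statistics are only
computed for windows with `n_usable >= 5001` (the strict
more-than-half rule for 10-kb windows).

* `F_ST`: Weir–Cockerham variance components at the allele (haplotype)
  level, combined across sites as `sum(a) / sum(a+b)` — never a mean of
  per-site ratios. Slightly negative values are legitimate estimator
  noise. Sites need at least two called alleles per population.
* `d_XY`: mean over all inter-population haplotype pairs of per-site
  differences, with pairwise deletion (each pair's denominator is the
  usable length minus sites missing in that pair). The divisor is
  usable sites, not raw window length; the two coincide on complete
  data.
* `G_MIN = min(d_XY) / mean(d_XY)`; ties for the minimum resolve to the
  lexicographically smallest haplotype pair; undefined (NaN) when
  `d_XY = 0`.
* Tajima's `D` uses the textbook constants on sites fully called within
  the population; zero segregating sites gives NaN (flagged), never 0.

## Site filters and pseudo-phasing

VCF input is filtered site-wise in a fixed order (QUAL, depth,
biallelic, MAF, call rate) with each removed site attributed to the
first filter it fails, so removal counts sum to the total. Depth is
assessed as the mean per-genotype DP over called genotypes. MAF and
call-rate boundaries are inclusive. Unphased heterozygotes are
pseudo-phased by assigning alleles to the two haplotypes uniformly at
random (seeded); already-phased genotypes are taken as given. The
statistics downstream are insensitive to phase except through
haplotype-level quantities (`G_MIN`, trees), for which pseudo-phasing
adds noise but no directional bias.

## Valley and peak detection

The detector offers two calling modes and their intersection:

1. **HMM**: a two-state Gaussian HMM on the per-window track (logit
   `G_MIN`, untransformed `f_d`), transitions initialised symmetric at
   0.9 stay / 0.1 switch, started in the background state, emissions
   initialised from the empirical distribution (background near the
   median, outlier at the 2nd/98th percentile, shared empirical SD).
   Baum–Welch runs to a log-likelihood tolerance of 1e-6 (max 500
   iterations; non-convergence is flagged, the last iterate used), then
   Viterbi decodes states. The state with the lower fitted mean is the
   valley (higher for peaks). NaN windows split the track into
   independent segments and receive no state. A constant track
   short-circuits to all-background. Exact 0/1 values are clamped to
   (0, 1) by 1e-6 before the logit.
2. **Permutation threshold**: variant-site columns are shuffled jointly
   across haplotypes within a chromosome (preserving per-site allele
   configurations, destroying spatial order), the statistic is
   recomputed per window, and values are pooled per usable-site bin
   (5,000 … 10,000 by 500). The cutoff is the 1st percentile of the
   pooled null — the lower tail of the "lower 99 percentile" rule,
   which we read as lower-tail significance at the 1% level.

Outlier windows within 30 kb of one another merge into one interval
(first start to last end). On single-genealogy synthetic loci the
permuted null is tighter than the empirical genealogical variance, so
the threshold mode is anti-conservative there; with per-locus
recombination (several genealogies per window) it calibrates much
better. The HMM mode will split any unimodal track into two states, so
on null tracks its "valleys" are the distribution's lower tail —
intersecting with the permutation threshold restores specificity. Gene
enrichment in valleys is tested against 1,000 size-matched random
non-valley windows (add-one empirical p); group contrasts use a
label-permutation test on the difference of means with
`p = (b + 1) / (n_perm + 1)`.

## Frequency-weighted D statistics

Site patterns are weighted by derived-allele frequency products — e.g.
ABBA contributes `(1-p1) p2 p3 (1-p4)` — so fixed sites reproduce
count-based statistics exactly and polymorphic outgroups contribute
with weight `(1-pO)` rather than being dropped. `f_d` uses the
site-wise dynamic donor `pD = max(p2, p3)` in both donor positions of
the denominator and is reported for negative-D windows too (as a signed
diagnostic; the introgressed-fraction interpretation requires D > 0).

`D_FOIL` assumes the symmetric tree ((P1,P2),(P3,P4),O) with the
(P1,P2) split the younger. Each of the four components contrasts eight
weighted pattern sums; each is tested against zero with a chi-squared
goodness-of-fit on its left/right sums (df = 1, default alpha = 0.01 —
the test level is our choice, as is treating weighted sums as counts,
an approximation that ignores within-locus linkage and is therefore
anti-conservative on long windows; the calibration check below bounds
the practical false-positive rate). The signed/zero signature of the
four components maps to one of ten introgression events (or none).
Every signature in the lookup table was verified by simulating the
corresponding directional pulse and checking the component signs; the
polarisation logic is that a younger-pair donor drags its sister's
component along (both DFO and DIL respond) while an older-pair donor
leaves one of them at zero and instead marks DFI or DOL through deep
shared alleles. Windows default to 100 kb so that weighted sums pool
enough loci for the per-component tests.

## Ancestry

AIMs are loci with `|p1 - p2| > 0.8` (strict) between parental panels;
the species-2-associated allele is the one more frequent in panel 2,
so non-fixed AIMs contribute fractionally. Hybrid index `h` is the
fraction of an individual's alleles at typed AIMs that are
species-2-associated; interspecific heterozygosity is the fraction of
typed AIMs with one allele of each class; missing loci leave the
denominators. At fully diagnostic markers the classes sit at the
classic triangle: parents (0,0)/(1,0), F1 (0.5,1), F2 (0.5,0.5),
backcrosses (0.25 or 0.75, 0.5).

## Window trees and gsi

Per-window trees are neighbor joining on pairwise per-site haplotype
differences (pairwise deletion), rooted on the outgroup, negative NJ
branch lengths clamped to zero. NJ replaces a per-window
maximum-likelihood search deliberately: it is orders of magnitude
faster, consistent on additive inputs, and the downstream
classification depends only on topology. Classification requires all
three ingroup lineages and applies the precedence species > geography >
ancestral to trees satisfying several conditions; the species class
requires each lineage monophyletic without constraining their
arrangement.

The genealogical sorting index is computed as
`gs = (n-1) / sum_u (c_u - 1)` over the internal nodes `u` on the paths
from the group's MRCA to its tips (`c_u` = child count), rescaled as
`gsi = (gs - gs_min) / (1 - gs_min)` with `gs_min` evaluated over all
internal nodes of the tree. This normalisation attains 1 exactly at
monophyly and its floor when uniting the group requires the whole
tree; singleton groups and the all-tips group are defined as 1. The
exact normalisation in the statistic's original description could not
be consulted directly; ours is pinned by the endpoint and monotonicity
behaviour the tests enforce (moving a tip out of the group clade never
increases gsi).

## ABC

The summary vector is fixed and ordered: across-locus mean then
variance of {π₁, π₂, θ_W1, θ_W2, Tajima's D₁, D₂, F_ST, shared
polymorphisms, private₁, private₂} — 20 statistics. The published
analysis selected statistic subsets from a larger msABC pool that is
not restated in the main text; this concrete set is our reconstruction,
chosen to span diversity, frequency-spectrum shape, differentiation and
the joint polymorphism classes. Undefined per-locus values (Tajima's D
on monomorphic loci, F_ST without usable sites) are excluded from the
moments.

Rejection: columns are standardised by the reference table's median
absolute deviation (robust to the heavy tails that loguniform priors
produce); zero-spread columns are dropped with a warning; NaN summaries
are neutral in the distance. The nearest `tolerance` fraction of
simulations by Euclidean distance is accepted; model posterior = each
model's share of the accepted set; parameter posteriors are the
accepted draws summarised by the median and an equal-tailed 95%
interval using outward-rounded order statistics (with a few dozen
accepted draws, interpolated quantiles understate the tails).
Acceptance is nested across tolerances by construction.

Default priors (loguniform unless noted): `N ∈ [1e3, 1e6]` for each
size, `T ∈ [1e4, 1e7]`, `m ∈ [1e-9, 1e-4]`, `T_G/T ∈ [0.05, 0.95]`
(uniform), and the bottleneck size expressed as a reduction fraction
`N_JSB/N_JS ∈ [0.01, 1]` — a bottleneck is a contraction, so tying it
to the contemporary size keeps every "bottleneck" draw a genuine one.
The migration-epoch fractions for IAM/IRM/IARM are uniform on the
admissible intervals.

**Identifiability caveat.** These priors make I a boundary case of IM
(2Nm ≈ 0 has substantial prior mass) and IM+constant a boundary case of
IM+bottleneck (reduction fraction near 1). PODs drawn from the
overlapping regions cannot be assigned by any method: a random-forest
classifier trained directly on the summaries — an upper bound on the
accuracy of any rejection rule — reaches only ~54% overall for the
I / IM / IM+bottleneck triplet (I ≈ 0.7, the two IM variants ≈ 0.4–0.5).
The corresponding acceptance test records this honestly and fails its
0.7 per-model bar; the companion recovery test uses an IM model with a
strong-migration prior (`m ∈ [1e-5, 1e-4]`), where the pair is
separable and recovery exceeds 0.7. Divergence-time coverage under IM
(true `T` inside the 95% interval) is ≈ 0.9 at desk scale.

Hierarchical selection (per-scenario growth variant first, then across
scenarios) is available by composing `select_model` calls; the
neural-network regression adjustment of the original analysis is out of
scope — rejection is the implemented and tested baseline.

## Problem sizes

Desk-scale defaults used by the tests and the acceptance script: 60–200
loci of 2 kb for ABC (10 haplotypes per population), 400–3,000
simulations per model at 1% tolerance, 12 PODs per model and 12–20
coverage repetitions; 100 five-taxon loci of 5 kb (8–16 haplotypes per
population) for the D-statistic checks; 60 ten-kb loci across three
populations (with 1e-8 per-bp recombination) and 30 permutations for
the valley-contrast experiment; 500-window planted tracks for the HMM.
These sizes are the package's own choices for fast, reproducible
validation; every threshold they are checked against is stated in the
test suite.

## Known limitations

* Statistical phasing is not implemented; only random pseudo-phasing.
* The permutation null is anti-conservative on non-recombining
  single-genealogy windows (see above).
* The chi-squared tests on weighted pattern sums ignore within-window
  linkage; block resampling would calibrate them exactly but is not
  implemented.
* `d_XY` divides by usable sites; a raw-window-length denominator is a
  trivial rescaling the caller can apply.
* The ABC neural-network adjustment, SFS likelihood inference, and
  LD-aware methods are out of scope.
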