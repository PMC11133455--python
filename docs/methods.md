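# Methods

## The question and the model

A deletion inside or at a TAD boundary changes a Hi-C map in two
conceptually different ways: (i) every pair of loci flanking the deletion
moves closer, so their contact frequency rises along the genome-wide distance
decay P(s); (ii) the folding machinery itself may be perturbed — e.g. loss of
a CTCF-anchored boundary fuses two TADs. `svhic` separates the two by
constructing the *distance-only null* V\* for a wild-type map under a given
deletion and scoring the observed mutant map against it.

### Balanced liftover

The null is built by composition. First the wild-type map is remapped onto
the deleted genome under the **balanced** model: a contact between bins at
separation s that lands at separation s′ is multiplied by P(s′)/P(s), where
P is the distance-decay profile estimated from the *same* map (arithmetic
mean of values per bin separation, no smoothing by default so the operation
is exact on distance-only maps). Then the result is remapped back to
reference coordinates under the **easy** model (coordinates only, no
rescaling), which restores the original bin frame and masks the deletion.
On a map that is a pure function of separation, the composition returns
exactly P(s′) at every surviving pair, and pairs with both ends on the same
side of the deletion are returned unchanged — these identities are tested.

Assumptions: contacts are cis-only within one capture region; the decay
profile is stationary across the region (TAD structure enters P(s) only as
an averaged attenuation); and the deletion is small relative to the region so
P(s′) is defined at all surviving separations. When P(s) is undefined (no
unmasked pairs at s) or zero, the affected pairs are dropped (mask semantics
at pair level are approximated by zero contributions, since masks are
per-bin). P is never extrapolated beyond the map extent; consequently a
reverse balanced liftover can only reconstruct pairs whose original
separation lies within the smaller genome's support.

### Bin mapping

Synteny blocks (equal-length source/target intervals, codirected or
inverted) are decomposed into (source bin, target bin, overlap weight)
triples; a bin straddling a block or deletion edge redistributes its
contacts by overlap fraction rather than being dropped. Typical boundary
deletions (multiples of the 5 kb bin) map bins one-to-one; sub-bin deletions
(e.g. a 300 bp CTCF-site deletion) lose exactly the deleted fraction of the
straddled bin's contacts. Target bins receiving no weight from unmasked
source bins are masked. Gap filling between codirected blocks merges
neighbors whose source and target gaps are equal and below 1 Mb, mirroring
how sparse whole-genome alignments are consolidated before liftover.

## Normalization

Maps are balanced with VC_SQRT: W_ij = V_ij / √(r_i r_j) with r_i the bin
marginal, then rescaled by one global constant to preserve the total matrix
sum (keeping subtraction maps in count-like units; the method itself fixes
only relative values). Bins with zero marginal are masked and stay masked
downstream — deletion regions in mutant maps have no coverage, so this
propagates naturally. Note that VC_SQRT is a *half* correction: it maps a
rank-one matrix c·cᵀ to a matrix proportional to √(c_i c_j) rather than to a
constant; only full VC (dividing by r_i·r_j) flattens rank-one structure.

## Differential contact enrichment D(k, f)

D(k, f) is the arithmetic mean of natural-log ratios log(V_ij/V\*_ij) over
the index window i ∈ [k−f, k), j ∈ (k, k+f], restricted to pairs positive in
both maps, with windows truncated at the region ends. Before the ratio, the
two maps are scaled to equal totals over their jointly positive pairs (the
common target is the mean of the two totals, keeping the statistic
antisymmetric under swapping its inputs); this removes the constant offset a
sequencing-depth difference would add to every D. D is then Z-transformed
over all defined positions (population SD; if the SD is zero — identical
inputs — Z is reported as all-zero rather than NaN). A position with no
valid pair is undefined, not zero. The log base is irrelevant after the
Z-transform; natural log is used.

Calls: maximal runs of consecutive defined bins with |Z| ≥ threshold
(default 2.0) and constant sign, annotated with the peak Z. Gains mark
increased cross-position contacts relative to the null (boundary fusion);
losses mark new insulation.

Default window f = 20 bins (100 kb at 5 kb resolution): wide enough to
average ~400 pairs per position at full coverage, narrow enough to stay
inside one TAD. f is a free parameter of the method and is echoed into every
output manifest.

## Subtraction maps

Observed and null are scaled to equal totals over jointly unmasked bins,
aggregated by summation into coarser bins (default 10 kb), and differenced.
The operation is exactly antisymmetric in its inputs and zero for inputs
equal up to a scalar.

## Allelic expression

Per-SNP allelic activity is (musculus coverage + 1)/(castaneus coverage + 1);
the pseudocount avoids division by zero and makes zero-coverage SNPs neutral
(ratio 1). Genes are summarized as mean ± sample SD over SNPs (SD reported
as 0 when n = 1, with n flagging it). Genotypes are compared by a two-tailed
Mann–Whitney U test on the per-SNP ratio sets — SNPs, not replicates, are the
sampling unit. The exact null distribution is used when min(n₁, n₂) ≤ 8 and
the pooled ratios are tie-free; otherwise the tie-corrected normal
approximation (pseudocount ratios tie frequently at low coverage). The
implementation is scipy's; an independent full-enumeration oracle verifies
the exact path in the test suite.

The pseudocount estimator is biased low at extreme ratios with moderate
coverage: at a true ratio of ~50 and coverage 100 per SNP its expectation is
≈43 (−13%), because the castaneus pseudocount dominates a near-zero count.
The derived allele *fraction* r/(1+r) is robust to this (97.7% vs 98.0%).

## Synthetic data generator

Expected contacts follow E[i,j] ∝ (1+|i−j|)^(−α) · Π δ_b · (1 + loop bumps),
with δ_b multiplying every pair spanning boundary b. Counts are independent
Poisson per unordered pair, scaled so the expected total equals the target
depth (an overdispersion knob gamma-jitters the Poisson means; off by
default, matching the analysis's lack of overdispersion modeling). The
default template is a 455-bin × 5 kb capture region (2.275 Mb) with strong
boundaries (δ = 0.2) at bins 150 and 300 and milder nested sub-TAD
boundaries (δ = 0.6) at bins 200 and 250; α = 1.0, a typical cis decay
exponent at the 10 kb–1 Mb scale; depth 5 × 10⁶ contacts, representative of
a deep capture experiment over a few megabases.

A deletion experiment simulates the mutant on the collapsed grid — distances
recomputed after the deletion, the contained boundary either retained at the
fusion point or removed (`fused`) — and re-expresses it in reference
coordinates with the deletion masked, as mutant reads aligned to the
reference genome would appear. The default deletion is 30 kb (6 bins)
centered on the bin-300 boundary.

SNP tables draw musculus counts as Binomial(coverage, r/(1+r)) per SNP
(optionally beta-binomial).

What the generator does *not* emulate: restriction-fragment granularity and
capture-probe bias, spatially correlated noise, loop-extrusion dynamics,
translocations/inversions at the locus, trans contacts, and allelic
imbalance in Hi-C itself. Passing tests therefore demonstrate correctness
and calibration of the computations under the block model's idealized noise,
not robustness to every artifact of real capture Hi-C.

## Validation choices and problem sizes

Calibration and power are assessed on 20 seeded replicates at the default
template and depth: under an architecture-preserving deletion the Z track is
centered (|mean Z| ≤ 0.2) with at most 10% of positions beyond |Z| = 2 in
every replicate; under a boundary fusion (δ 0.2 → 1.0) a gain call with
peak Z ≥ 3 overlaps the boundary (±2 bins) in ≥ 18/20 replicates. Oracle
equivalence of the vectorized liftover and D(k, f) implementations against
per-pair enumeration is checked on 50 random cases of up to 30 bins with 2–3
block synteny maps and f ∈ {1, 2, 3}. All simulations are pure functions of
(parameters, seed).

## Numerical conventions

- Coordinates are 0-based half-open internally; region strings
  (`chr5:74,135,000-76,410,000`) are parsed as 1-based inclusive.
- Triplet contact text stores the upper triangle once; reading mirrors and
  sums duplicates.
- Matrix symmetry is restored after aggregation by averaging with the
  transpose (removes float summation-order asymmetry, ~1 ulp).
- Mutual scaling targets the mean of the two totals wherever two maps are
  depth-matched (subtraction, D score), which makes both operations exactly
  antisymmetric.
- Degenerate inputs are rejected with specific errors: double normalization,
  fully masked maps, all-zero map pairs, f outside [1, n_bins), deletions not
  aligned to bins in the simulator, negative counts.

## Known limitations

- Pair-level masking in the balanced model is approximated by zero
  contributions (the container's mask is per-bin).
- Only deletions are first-class in the rearrangement model; the synteny
  container expresses inversions and is tested for them, but duplications
  and translocations are out of scope.
- The expected-profile smoothing option (log-spaced geometric running mean)
  is provided for sparse maps but is not part of the validated default path.
- VC_SQRT is the only balancing method implemented (no KR/ICE).
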