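# Methods

## Sequence model and site policies

All computations operate on pre-aligned, equal-length sequences over the
IUPAC nucleotide alphabet plus the gap character; alignment itself is out of
scope (inputs are assumed aligned, and the generator emits gap-free aligned
data).  Coordinates are 1-based alignment columns throughout.  Lower case
and U are normalized (U→T); any other character is a hard error rather than
being silently read as N, because a stray character in a barcode submission
usually indicates a corrupted record rather than missing data.

Every pairwise comparison is governed by an explicit `SitePolicy`:

* **Gaps** are pairwise-deleted by default (a column is dropped only for
  pairs in which either sequence is gapped); complete deletion is available
  for reproducibility studies.
* **Ambiguity codes** are compared through their base-set semantics.  Under
  the default `intersect-is-match` policy a site matches when the two base
  sets share a base — a hybrid's Y matches both parental C and T, which is
  what makes hybrids nearly equally similar to both parental species and is
  the mechanism behind the loss of the barcode gap.  The strict `mismatch`
  policy scores only identical characters as matches, and `fractional`
  scores the probability that bases drawn uniformly from each set are equal.
  Mismatch weight is apportioned between transitions and transversions by
  the composition of unequal cross-pairs of the two base sets, so
  p = P + Q holds exactly under every policy.

Distances: p-distance with its (P, Q) decomposition, Jukes–Cantor, Kimura
2-parameter d = −½ ln(1−2P−Q) − ¼ ln(1−2Q), and Tamura–Nei with separate
purine/pyrimidine transition classes.  TN93 base frequencies are estimated
per pair by default (the upstream GUI tools do not state their choice); a
whole-alignment override exists and is what the test suite uses when
checking against R's `ape::dist.dna`, which estimates frequencies globally.
Saturated pairs (non-positive logarithm argument) are flagged, not raised.

## Hybrid detection

A diagnostic panel is the set of columns at which every reference of
species A carries one fixed, unambiguous base and every reference of
species B a different one.  A record is a putative hybrid when its IUPAC
base set contains *both* parental alleles at at least `min_het_sites`
panel columns; records matching one parent exactly everywhere are pure, and
anything else is undetermined.  A gap at a panel column counts toward
neither parent nor the heterozygote tally.

`min_het_sites` defaults to 1: field data show individuals heterozygous at
a single diagnostic site that still carry hybrid ancestry, and backcrosses
are expected to be heterozygous at only a subset of sites.  The het-site
count is reported but deliberately not interpreted as an F1/backcross
stage — a single nuclear locus cannot distinguish hybrid generations.

## Identification methods

All methods are evaluated leave-one-out within the labelled set (the study
design queries each individual against all others); `no_match` and
`putative_hybrid` outcomes are folded into the "ambiguous" column of the
summary unless configured otherwise.

* **DSC** assigns species S when the minimum query-to-S-reference percent
  similarity strictly exceeds the threshold (default 98 %) and no second
  species qualifies; two qualifying species → ambiguous, none → no_match.
  Queries pre-flagged by hybrid detection pass through as putative hybrids:
  a similarity criterion cannot place a sequence that matches both species.
* **BCM** computes the threshold as the 95th percentile (linear
  interpolation) of all intraspecific pairwise K2P distances among the
  references, then assigns the species of the closest reference(s); a
  minimum distance beyond the threshold is no_match, a cross-species tie at
  the minimum is ambiguous.
* **AB** additionally requires the top |conspecific| ranked references to
  be exactly the conspecific set.  The threshold applies to the best match,
  as in BCM; this follows the method's standard definition, whereby AB is
  never stricter than BCM on the threshold and strictly stricter on the
  ranking.  Fewer than two conspecific references is no_match.
* **ABGD** (simplified): sort all pairwise distances; a candidate gap must
  end above the prior maximum intraspecific divergence `prior_P` (default
  0.01, inside the conventional 0.001–0.1 sweep range) and exceed
  X (=1.5) times the *largest* jump among the distances below it; split by
  single-linkage at the gap midpoint and recurse into each group.  Two
  numerical choices matter on a short amplicon: distances are
  near-quantized to multiples of 1/length, so comparing the candidate
  against the largest (not the mean) preceding jump prevents every
  quantization step from looking like a barcode gap; and a gap that
  single-linkage chaining bridges (hybrids sit between the species and link
  them) leaves the group unsplit, which is exactly the observed failure
  mode of gap-based partitioning in the presence of hybrids.  When used as
  a classifier, groups are named by their majority nominal label; a
  single-group partition carries no species signal, so every individual is
  scored ambiguous.
* **FINS** builds a neighbour-joining tree (Saitou–Nei agglomeration on
  Q(i,j) = (n−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k), deterministic lexicographic
  tie-breaking, negative branch lengths clamped to zero with the deficit
  moved to the sibling) on TN93 distances, with column-resampling bootstrap
  support per bipartition.  A query is assigned the species of its smallest
  clade containing a reference iff all references in the clade are
  conspecific and the clade's support reaches `min_support` (default 70 %,
  a conventional cutoff; the source workflow states only a "minimum
  threshold confidence").  Trees are rooted on an outgroup when one exists;
  synthetic data has none, so midpoint rooting is the fallback.  The
  pipeline default of 200 bootstrap replicates resolves support to ±~3
  points, sufficient for a 70 % cutoff; the replicate count is exposed for
  publication-grade runs.

In the pipeline, the distance-threshold methods (BCM/AB) use the strict
`mismatch` ambiguity policy — barcode-gap software conventionally scores a
Sanger ambiguity against a plain base as a difference — while DSC, ABGD and
FINS use `intersect-is-match`, which is required for hybrids to be similar
to both parents (DSC), to bridge the species (ABGD), and to sit inside the
main clade (FINS).  Both policies are exposed per method.

## Agreement statistics

Cohen's κ = (p₀ − pₑ)/(1 − pₑ) over the union of both methods' categories;
categories only one method emits (no_match, putative_hybrid) enter as
ordinary categories with zero marginal for the other method.  The 95 %
interval is κ ± 1.96·se with the large-sample
se = √(p₀(1−p₀)/(n(1−pₑ)²)); the one-sided p-value for κ > 0 uses the
Fleiss null-hypothesis standard error.  The multiclass MCC is Gorodkin's
R_K, which reduces to the classical MCC on 2×2 tables (asserted against
scikit-learn in the tests).  Families of p-values are adjusted by
Benjamini–Hochberg step-up via statsmodels.  Landis–Koch bands label κ
(<0 poor, ≤0.2 slight, ≤0.4 fair, ≤0.6 moderate, ≤0.8 substantial, >0.8
almost perfect), with "perfect" reserved for κ = 1 exactly.

## Synthetic data generator

The generator emulates a two-species-plus-hybrids barcode sample:

* an ancestor sequence drawn uniformly over a 397 bp amplicon;
* the two species consensuses differ at max(k, round(length × divergence))
  columns, k of which form the diagnostic panel.  The divergent-column
  count is fixed at its expectation rather than drawn per replicate:
  consensus divergence is a structural property of the species pair, and a
  single Poisson draw would make whole datasets swing between regimes where
  the 98 % DSC threshold does and does not separate the species.  Sampling
  noise enters through individuals instead;
* individuals mutate from their consensus at Poisson(length × θ/2)
  positions with a 2:1 transition:transversion bias, giving an expected
  *pairwise* intraspecific p-distance of θ (default 0.005, i.e. ≤1 %
  polymorphism).  Diagnostic columns are excluded from within-species
  mutation so the panel invariant — every pure individual fixed for its
  species' allele — holds by construction, as it did for the five fixed
  sites in real data;
* F1 hybrids carry the IUPAC code combining the parental alleles at every
  divergent column, on a parental background that alternates between the
  species to avoid artifactual asymmetry, plus their own background
  mutations.

Defaults (7 + 42 pure individuals, 12 hybrids, 5 diagnostic sites, 2 %
divergence, θ = 0.005) mirror the study's sample structure;
`simulate_paperlike` additionally attaches the HRM-like labelling scheme
(9/52, with the twelve hybrids hidden as 2 + 10).  Same seed, same bytes.

What the generator does *not* emulate: indels and end-trimming artefacts
(the amplicon analysis is gap-free at the reported sites), population
substructure (every individual is an independent draw around one species
consensus, so intraspecific distances are Poisson-like rather than
continuously spread), sequencing error, and later-generation hybrids.
Passing tests therefore demonstrate the machinery under the study's
statistical structure, not robustness to messy real-world reference sets.

Two derived regimes are used in the tests, chosen from the study's own
numbers rather than tuned: a *low-diversity* study-shaped regime
(θ = 0.002) consistent with the 0.25 % intraspecific threshold the
hybrid-free dataset yields — required for a detectable barcode gap, which
θ = 0.005 almost closes even without hybrids — and a *clean* two-species
regime (8 + 8 references, θ = 0.002, no hybrids) for the error-free
baseline.  Small reference panels matter for the latter: with eight
references per species each individual contributes more than 5 % of the
intraspecific pairs, so the 95th-percentile threshold provably covers every
individual's nearest-neighbour distance and the threshold-based classifiers
are structurally error-free.

## Numerical choices and degenerate inputs

* Percentiles use numpy's linear interpolation.
* Distance ties (BCM minimum, AB ranking) are compared with a 1e-12
  absolute tolerance, and AB uses the same threshold arithmetic as BCM so
  floating-point noise can never make AB stricter.
* NJ selects among exactly-tied Q values by the lexicographically smallest
  pair of representative leaf labels, making trees invariant to record
  order; Q's floating asymmetry is normalized before tie-breaking.
* κ is undefined (reported as NaN with a flag) when both methods are
  constant on the same category; a degenerate null (empty marginal) reports
  p = 0.5 for κ = 0.  MCC reports 0 on zero-denominator tables.
* Saturated distance pairs propagate as flagged NaN cells; ABGD and NJ
  refuse matrices containing them.
* An all-gap column overlap (zero comparable sites) is an explicit error.

## Known limitations

* The published p-values for κ are not reproduced by the standard one-sided
  normal test (the upstream tool's exact formula is unknown); p-values are
  computed and reported but never compared against published values.
* The simplified ABGD reproduces the qualitative gap/no-gap behaviour of
  the original, not its coalescent-calibrated recursion.
* FINS support values depend on the bootstrap replicate count; the
  package default (200) trades resolution for desk-scale runtime.
* Agreement statistics on very small or heavily degenerate tables
  (single-category methods) are reported with NaN/0 conventions rather than
  exact small-sample inference.
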