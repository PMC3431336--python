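# Methods

This note documents the models, estimators and design choices behind
`trireg`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The three-layer model

The object of study is a directed network with tumor-suppressor and
oncogene *modulators* on top, *transcription factors* in the middle and
*target genes* at the bottom. Modulation edges (modulator → TF) encode a
post-translational influence on TF activity inferred from expression;
regulation edges (TF → target) encode transcriptional regulation
supported both by expression and by promoter sequence. A gene may occupy
several layers (a regulated oncogene, a TF regulated by another TF);
layer membership is structural — a gene is a modulator/TF/target exactly
when it sources or receives the corresponding edge kind. A consequence is
an automatic "demotion": a candidate TF that ends up with no surviving
regulation edges holds no TF role, and if it is itself regulated it
appears as a plain target.

## Modulator inference

### Statistic

For a triplet (M, T, G), samples are ranked by M's expression (stable
sort, so ties resolve by sample order); the top and bottom ⌊f·n⌋ samples
form the conditioning subsets (default f = 0.35, the customary subset
fraction for conditional-MI modulator screens; exposed in
`InferenceConfig`). The statistic is ΔI = I_high − I_low, the difference
of TF–target mutual information between the two subsets. The sign is
kept: positive ΔI means M's abundance enhances the dependence,
negative means it attenuates it; tests are two-sided on |ΔI|.

### MI estimators

* **Gaussian copula** (default): ρ_s (Spearman) → ρ′ = 2 sin(πρ_s/6)
  (the Gaussian-copula correlation consistent with that rank
  correlation) → I = −½ ln(1 − ρ′²) nats. Exact under any monotone
  marginal transform, closed form, and well behaved at the benchmark's
  per-tail n ≈ 171. It measures monotone dependence only — a deliberate
  trade-off documented under limitations.
* **Equal-frequency binning** (cross-check): plug-in MI on an
  equal-frequency discretisation (default 6 bins). Bin edges are interior
  quantiles; values equal to an edge fall in the lower bin. The plug-in
  estimate is biased upward at small n, which is harmless here because
  the permutation null carries the same bias.

Constant vectors yield MI 0 with a warning. Vectors shorter than 8 (and
tails smaller than 8 samples) are rejected.

### Permutation null and p-values

The null permutes the modulator's sample assignment, which is equivalent
to drawing random disjoint high/low subsets of the same size. Two
consequences are exploited:

1. The null distribution of ΔI depends only on (T, G) and the tail size,
   never on which modulator is tested. `infer_modulations` therefore
   computes one shared n_perm-draw null per (T, G) pair and reuses the
   same subset draws across pairs. Each triplet's p-value is still
   computed against a correct null for that triplet; only independence
   *across* triplets is given up, which BH does not require.
2. For a (T, G) pair with marginal dependence (e.g. a genuinely
   regulated target tested against the wrong modulator), the random-subset
   null automatically inherits the extra variance that marginal
   dependence induces, keeping those "cousin" triplets calibrated.

The empirical p-value is (1 + #{|Δ_null| ≥ |Δ_obs|}) / (n_perm + 1)
(`permutation_pvalue`, default method), whose smallest value is
1/(n_perm + 1). That floor is far too coarse for FDR control over
thousands of triplets — with n_perm = 1000 and m = 7500 tests no
discovery could ever survive BH at 0.05 — so the batch driver defaults to
a hybrid rule (`null_tail="auto"`): when at least 10 null values reach
the observation the empirical value is used unchanged; otherwise the
null's upper tail is extended by a generalized Pareto distribution fitted
to the top 25% of null values (threshold-excess method). Two numerical
safeguards matter:

* The fitted GPD shape is constrained to ξ ≥ 0. The ΔI null is
  approximately a scaled product of two standard normals (difference of
  two χ²₁ variables), whose tail is exponential-like; an unconstrained
  fit occasionally returns ξ < 0, i.e. a bounded support that assigns
  probability zero — p ≈ 0 — to perfectly attainable observations. When
  ξ < 0 the exponential member (ξ = 0, maximum-likelihood scale) is used
  instead. This makes extreme p-values conservative rather than explosive.
* Tail p-values are floored at 1e-300 and never allowed to exceed the
  empirical bound.

A Gaussian tail was considered and rejected: the product-normal tail is
heavier than Gaussian by orders of magnitude at |z| ≈ 3–4, exactly the
region that decides borderline discoveries.

BH (step-up) is applied over all tested triplets; self-triplets
(M = T, T = G, M = G) are skipped and logged. Default FDR level 0.05.

## PWM scanning

Frequencies are column-normalised counts with pseudocount 1e-3 (so
ln f is finite; exposed). Information weights use the natural logarithm,
making scores reproducible bit-for-bit from the definitions. The core is
the 5 consecutive positions maximising summed information, leftmost on
ties. Scores are min–max normalised weighted sums; a consensus window
scores exactly 1.0 because its per-position terms are identical floats to
the maximum sum's terms (same pairwise summation order) — the stringent
core threshold 1.00 therefore means "core spells the consensus", with no
epsilon. An all-uniform matrix has Max = Min and raises an
undefined-score error rather than returning 0/0.

Both strands are scanned by default; minus-strand windows are scored
against the reverse-complemented matrix and reported in forward
coordinates (0-based, half-open), sorted by position then strand.
Windows containing `N` are skipped under the default ambiguity policy;
the `min-frequency` policy scores `N` with the position's smallest
frequency (most pessimistic defined value). A TF → target edge requires
at least one hit of one of the TF's matrices in the target's promoter;
supporting hit counts are kept.

The promoter set is an explicit FASTA input: promoter definitions (TSS
source, length) vary between studies and are deliberately outside this
package's scope.

## Network assembly and statistics

Triplets surviving FDR are intersected with the PWM edge set on their
(TF, target) pair — the confirmation step that suppresses expression-only
false positives. Edge multiplicity is collapsed; the number of supporting
triplets is an edge attribute. Feedback loops are mutual pairs
(gene modulates TF, TF regulates the gene back); dual-role genes are
those occupying ≥ 2 layers. The TF in/out-degree association uses
Pearson correlation with a two-sided p; it is reported as not computable
(None) when fewer than 3 TFs exist or either degree vector is constant.

## Profiles and clustering

Modulator profiles are binary incidence vectors over all TFs (direct
modulation) or all targets (two-hop reachability). Clustering is
agglomerative on Euclidean distance with complete linkage — the stock
defaults of the common statistical environments — with Jaccard distance
and average linkage exposed because binary data often warrants them; the
class-separation conclusion is checked under both settings in the
acceptance suite. All-zero rows are retained and flagged. Branch purity
at a k-branch cut is the majority-class fraction per branch. The Jaccard
distance between two all-zero rows is defined as 0.

## Topology, resampling and enrichment

Centralities follow standard conventions: betweenness normalised by the
number of ordered pairs excluding the node (raw counts via a flag, since
the normalisation convention of desktop tools is often unstated);
closeness computed within a node's component and scaled by
(reachable−1)/(n−1), 0 for isolated nodes. KS comparisons are two-sided
with the asymptotic two-sample distribution.

The resampling p-value for a gene set's mean metric draws same-size sets
without replacement from a background pool and counts draws *strictly*
exceeding the observed mean; p = N/R. A zero count is reported with the
caveat "p < 1/R" rather than as evidence of p = 0. Draws are generated
from uniform keys via partial argsort, making the result invariant to
pool ordering and deterministic given the seed.

Enrichment is the exact hypergeometric upper tail with BH adjustment.
The background defaults to the union of the collection's genes and is
user-overridable (annotation-server backgrounds are not reproducible);
terms with no background members are dropped before testing, which
affects the BH divisor and is logged. The k−1 "EASE-style" penalised
overlap is available behind a flag, off by default. The random-gene-list
comparison enriches n_random same-size draws from a candidate pool
(default 10) and KS-compares adjusted-p distributions, truncating ECDFs
at 0.05 for display parity.

## Process subnetworks

Bottom-up, three passes: process genes → bottom layer; their regulators →
middle layer (TFs not themselves process-annotated are flagged *added*);
process-annotated modulators of those TFs → top layer. Induced edges
only. Overlap fractions between two subnetworks use the first argument's
role set as denominator (the directional convention such percentages
imply); an empty denominator reports 0 with a warning.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the package's reference study conditions:
489 samples; 30 modulators (18 TSG + 12 OCG, ≈ 2:1 as in curated cancer
gene sets), 5 TFs, 50 candidate targets inside a 100-gene, scale-free
(preferential-attachment) PPI network; 40 planted triplets with coupling
β_high = 0.8 in the modulator's own top-0.35 quantile and β_low = 0
elsewhere, unit noise; every gene row re-standardised. The piecewise-
constant coupling is the simplest mechanism with the conditional-
dependence structure ΔI detects, and it makes the within-subset TF–target
correlation closed form (ρ = β/√(β² + σ²)), which the tests exploit.
Middle (non-tail) samples get β_low so the high/low contrast is
interpretable. Promoters are 1 kb of i.i.d. background at GC 0.5 with
motif occurrences sampled column-wise from the PWM and inserted without
overlap; PWM planting defaults to consensus stringency (infinite
concentration), the regime in which the fixed 1.00/0.95 thresholds
guarantee recovery.

What passing tests on this world do **not** show about real data: no
batch or platform structure, no heavy-tailed or censored expression, no
correlated modulators, no TF combinatorics (each planted target has one
regulator), promoters with uniform background rather than real sequence
composition, and annotation sets drawn at random rather than curated.
The benchmark demonstrates the machinery is correct and calibrated, not
that effect sizes in tumors match β = 0.8.

## Problem sizes and runtime choices

The test suite and acceptance script run the reference benchmark
(7,500 triplets × 1,000 permutations) in seconds by vectorising the rank
computations: all subsets of all permutations are ranked in one array
operation and Spearman correlations become one matrix product per
subset batch. End-to-end recovery is checked on five pipeline seeds at
β_high = 1.0 — the strong-coupling, consensus-motif regime in which
exact chain recovery (no missing, no extra edges) is the designed
outcome; power at the weaker reference coupling is measured separately
as benchmark sensitivity/precision. The scanner-vs-oracle comparison
uses 1,000 random (sequence, matrix) pairs at 120 bp; the resampling
calibration uses 200 repetitions at R = 200.

## Known limitations

* Copula MI is blind to non-monotone dependence; the binning estimator
  catches gross cases but at lower power.
* The GPD tail is an extrapolation: p-values far below 1/n_perm are
  approximate (deliberately conservative under the ξ ≥ 0 constraint).
  With BH at 0.05, borderline triplets whose true p sits near the BH
  cutoff can flip either way — an irreducible property of FDR control,
  visible as occasional single-edge differences between runs at
  different seeds.
* Layer roles are structural, so a modulator with no surviving edges
  disappears from the network rather than appearing isolated.
* SIF export does not carry base-class labels; the JSON export is the
  lossless round-trip format.
* The pipeline's checkpoint consistency assumes outputs are reloaded
  from the same directory they were written to; expression values are
  serialised at full precision so rank statistics survive the round
  trip.
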