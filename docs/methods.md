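# Methods

This note documents the models, algorithms, numerical conventions and design
choices behind `traitorder`, in the spirit of a statistical package's methods
appendix. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## The statistic

Write a rooted bifurcating tree in Newick form; each tip gets a 1-based
left-to-right position. With trait ranks r (average ranks for ties), the
statistic is Kendall's τ between positions and ranks, maximized over the
2^(n−1) rotation states (a rotation reverses one internal node's child
list; it changes tip order, never topology).

The maximization is exact and cheap. Under every rotation state a subtree
occupies a contiguous block of positions, so the relative order of two tips
is decided by the orientation of their most recent common ancestor and by
nothing else. Each tip pair is therefore "owned" by exactly one internal
node, per-node orientation choices are independent, and choosing each node's
better orientation (more concordant cross-subtree pairs) yields the global
maximum regardless of visiting order. Cross-pair counts use sorted-array
merging (`numpy.searchsorted`), O(n log² n) overall; a quadratic all-pairs
path (`order._tau_of_sequence`) and a full 2^(n−1) enumeration
(`brute_force_tau`, n ≤ 14) are kept as test oracles.

Conventions:

- **Ties.** Trait ties make perfect order impossible and would silently
  deflate a τ-a denominator, so τ-b (tie-corrected) is used throughout and
  tied species trigger a warning. With no ties τ-b equals the plain
  (C − D) / (n(n−1)/2).
- **Orientation ties.** A node whose two orientations are equally good keeps
  its input orientation, making reported orientations deterministic; τ_max
  is unaffected.
- **Degenerate inputs.** Polytomies are rejected with a pointer to
  `resolve_polytomies` (seeded random resolution with zero-length branches);
  missing trait values raise an error naming the species — only the
  screening pipeline prunes unmeasured species, under its explicit coverage
  rule.

**Perfect orderability** (τ_max = 1 with no discordant pair) is decided by
the equivalent recursive criterion: at every internal node the two child
subtrees' rank sets must be separable (all ranks of one strictly below the
other).

## The Monte-Carlo test

The null model is Brownian motion on the observed tree: child value =
parent value + Normal(0, σ²·branch length). Each of the s null replicates is
passed through the *same* rotation maximization as the data — using
unmaximized null draws would bias the test anti-conservatively. With s\*
null draws strictly exceeding the observed τ_max (ties count as
non-exceeding, the anti-conservative direction for the observed value),

    p = (s* + 1) / (s + 1),   so  1/(s+1) ≤ p ≤ 1.

Defaults: s = 1000 (p-floor 1/1001), root state 0, σ² = 1. The σ² default is
immaterial: scaling a Brownian motion rescales trait space monotonically and
leaves all ranks unchanged, so the null τ distribution is exactly
rate-invariant (the suite also verifies this empirically by a two-sample KS
test between σ² = 1 and σ² = 10 draws, α = 0.01). What the null *is*
sensitive to is topology and branching times; the suite checks that balanced
and pectinate 16-tip trees give KS-distinguishable null distributions.

Calibration is verified directly: across 500 simulated BM datasets on a
fixed 25-tip tree, the empirical CDF of p stays within the
Dvoretzky–Kiefer–Wolfowitz band at α = 0.01.

## Simulators

**Yule trees.** Test phylogenies come from a pure-birth sampler: starting
from the crown split (2 lineages), k extant lineages wait
Exponential(k·birth rate) for the next split (a uniformly random lineage
splits), and the tree is cut at the moment the would-be (n+1)-th lineage is
born. Every internode interval then follows the constant-rates law
g_k ~ Exp(k·λ), which is what keeps the γ statistic centred at zero on
simulated trees; the expected crown age is Σ_{k=2..n} 1/(kλ). All ensemble
summaries quoted anywhere in the package (perfect-order frequencies,
crossing counts) are averages over this ensemble; real clades with other
branching-time distributions will differ quantitatively.

**Character displacement.** The alternative model is deliberately minimal,
since the hypothesis constrains only whether lineages may share a value.
Brownian motion is discretized on a time grid (default step: crown
age/1000). At each step every coexisting (co-extant) lineage proposes an
independent BM increment; whenever a pair's proposed values would swap their
current order — i.e. the two trajectories would cross — the crossing is
permitted with probability `p_c`, and otherwise the two increments are
exchanged. Exchanging the two i.i.d. increments provably preserves the
pair's order (reflection) and leaves each lineage's marginal BM law intact.
Newly split sisters start at equal values and may order themselves freely on
their first step (their relative order does not yet exist, so this is not a
crossing). The endpoints interpolate the two hypotheses exactly:

- `p_c = 1`: every crossing permitted — unconstrained BM;
- `p_c = 0`: no crossing ever — implemented in closed form by assigning the
  sorted proposals back in the current order, so tip values are perfectly
  ordered on the tree and τ_max = 1 on every replicate.

The suite verifies the p_c = 1 endpoint distributionally (KS against the
analytic Normal tip contrast), the p_c = 0 endpoint exactly, and that median
τ_max is non-increasing in p_c. Power at 25 tips: rejection at α = 0.05 is
100% at p_c = 0 and decays monotonically to ≈5% (the nominal level) at
p_c = 1.

## Traitgrams, reconstruction, crossings

A traitgram draws each branch as a straight segment from (parent time,
parent value) to (child time, child value). A *branch crossing* is a proper
intersection of two segments away from shared tree nodes; it implies two
lineages held equal trait values at that instant. τ_max and the crossing
count are two views of the same geometry: the suite checks their negative
association across BM replicates, and the exact equivalence "a zero-crossing
embedding exists ⟺ tips perfectly orderable". The embedding check is
constructive — orient by τ maximization, place each internal node in the
middle of the gap between its child subtrees' value ranges, count crossings
— so it exercises a different code path than the separability recursion it
must agree with.

Numerical conventions for crossing counts: coordinates are normalized to the
unit box (hence affine invariance in both axes); orientation predicates use
a relative epsilon of 1e-12; endpoint contacts are never "proper" and so
never counted; tangency (touching without sign change, measure-zero under
diffusion) warns and is not counted; collinear overlap warns and counts
once. The default counter is a vectorized all-pairs test with a
time-overlap prefilter, validated against a plain double loop.

For observed data, internal states come from ML ancestral reconstruction
under BM, computed by the standard two-pass precision-weighted message
scheme (validated against the dense GLS solution built from the BM
covariance matrix; the root estimate is the phylogenetic mean). A caveat is
attached wherever reconstruction-based counts are reported: ML
reconstruction minimizes change, so it *undercounts* true historical
crossings. Ensemble crossing summaries therefore always use true simulated
node states. Zero-length branches are floored at 1e-12 of the crown depth so
hard polytomies with conflicting tips average instead of becoming singular.

## γ statistic

With g_k the duration during which exactly k lineages existed (k = 2..n) and
T = Σ j·g_j,

    γ = [ (1/(n−2)) Σ_{i=2}^{n−1} Σ_{k=2}^{i} k·g_k  −  T/2 ] / ( T·√(1/(12(n−2))) ).

Negative γ means internal nodes crowd the root (slowdown). γ is invariant to
rescaling time. The hand-evaluated anchor `γ("((A:1,B:1):1,C:2);") =
−0.346410` is frozen as a regression test, the implementation is
cross-checked against dendropy's independent one on random trees, and Yule
simulation confirms mean ≈ 0 with variance ≈ 1. Tied node depths are allowed
(zero-length intervals contribute nothing).

## Clade screening

Criteria (all configurable; defaults follow common supertree practice):
n ≥ 10 species — the verbal description "greater than 10" vs "a minimum
of 10" is ambiguous in common usage, so the threshold is inclusive and
configurable; crown age ≤ 15 time units; trait coverage ≥ 80%. Species
without trait values count toward n and crown age but are pruned before τ.
When nested clades qualify, only the most inclusive one is tested, avoiding
pseudo-replicated tests on shared tips. Per-clade seeds are derived
deterministically from the root seed and clade id, so parallel and serial
runs agree, and per-clade failures are recorded on their row rather than
aborting the batch.

Multiple testing is corrected within a user-declared family (e.g. birds and
mammals separately): Bonferroni (min(1, m·p)) and Benjamini–Hochberg FDR,
with Benjamini–Yekutieli available behind a flag; all three delegate to
statsmodels. The optional geographic filter consumes a precomputed
species-pair overlap table and requires at least `min_overlapping` clade
members to overlap ≥ 1 other member (no single shared locality is implied);
computing overlap from range polygons is out of scope.

## Problem sizes and what the tests show

The suite's ensemble summaries use 10,000 replicates (10-tip perfect-order
frequency), 2,000 replicates (crossing counts at 10 and 100 tips), 500
datasets × 1,000 null draws (calibration), 500 instances (oracle
equivalences) and 200 replicates per `p_c` (power); the whole suite runs in
well under a minute of CPU apart from the Monte-Carlo acceptance tests.
These sizes give Monte-Carlo standard errors comfortably inside the asserted
bands (e.g. ±3.4 crossings on the 100-tip mean).

Because every synthetic dataset is a Yule tree with exact BM (or
crossing-thinned BM) traits, passing tests demonstrate correctness of the
algorithms and calibration *under the stated models* — they do not show
robustness to phylogenetic error, non-ultrametric trees, measurement noise
in traits, or non-Brownian null evolution (an OU or early-burst null would
change the branching-time sensitivity; hooks exist but only BM ships).

## Known limitations

- The displacement simulator is one concretization of a verbal model;
  `p_c` is a per-proposed-crossing thinning probability at grid resolution,
  so its numerical value is not directly comparable across grid steps.
- Crossing counts on a Yule ensemble sit near, but not exactly at, the
  round figures often quoted for such simulations (about 9 at 10 tips, about
  690 at 100 tips here); the ensemble, not the counter, is the sensitive
  ingredient — the counter itself is validated exactly.
- The order test assumes the tree is correct; for borderline p-values the
  tree's uncertainty and a more realistic evolutionary model should be
  considered before drawing conclusions.
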