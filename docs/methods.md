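# Methods

## Likelihood machinery

The reference tree is an unrooted bifurcating phylogeny with fixed branch
lengths, stored rooted-for-traversal at the internal node adjacent to the
lexicographically smallest leaf. Children are ordered by the smallest leaf
label in their subtree, so edge numbering (preorder, 0 … 2n−4) is fully
deterministic, identical across runs and machines, and survives
serialization; no reported quantity depends on this traversal root (tested
by recombining the caches across every edge). Polytomies in input trees are
resolved with zero-length edges under a warning; rooted inputs are unrooted
by merging the two root-adjacent branches, with their lengths summed.

Substitution models are reversible: GTR for nucleotides and the published
LG and WAG tables for amino acids (exchangeabilities and frequencies
embedded as data), with discrete-Γ rate heterogeneity using
equal-probability categories represented by their slice mean (the PHYML /
RAxML convention whose parameter files we import; slice medians are
available behind a flag). Q is normalized to unit expected rate, so branch
lengths are expected substitutions per site. Transition probabilities come
from the symmetric eigendecomposition of diag(π)^½ Q diag(π)^−½, computed
once per model and reused for every branch length and rate category.

Per edge, three conditional likelihood vectors are cached in two traversals
(postorder for the distal side, preorder for the proximal side), each a
sites × categories × states array with a per-site log scaling ledger;
scaling triggers when a site's maximum partial likelihood falls below
10⁻⁵⁰ (results are checked to be invariant to this threshold). The
center-of-edge vector is the elementwise product of the distal and proximal
vectors each propagated half the branch length toward the middle, so a
query's quick midpoint score is a single weighted dot product with its
pendant-flow vector — and is exactly the three-part likelihood at
a = Aᵢ/2, b = b₀.

Query columns with no known state are masked out. The masked-out columns
contribute an identical reference-only factor to every candidate edge, so
the likelihood weight ratios, posteriors and EDPL are unchanged (tested
against an oracle that keeps gap columns as missing-data tips); run time
then scales with the informative read length only. IUPAC ambiguity codes
become uniform indicators over their compatible states; gaps and N/X are
treated identically as missing.

## Optimization choices

Per-edge ML attachment maximizes ℒ over a ∈ [0, Aᵢ] and b ∈ [0, b_max]
(default 2.0) by bounded coordinate descent (alternating 1-D Brent
searches, logL tolerance 10⁻⁶) followed by a bounded L-BFGS-B polish. The
polish matters: coordinate descent alone stalls ~10⁻⁵ above the optimum on
correlated (a, b) ridges, which would make warm-started (friend) and
cold-started runs disagree beyond the 10⁻⁶ logL agreement we guarantee.
Inside the optimizer, site likelihoods are floored at 10⁻³⁰⁰ because the
exact a = 0, b = 0 corner of a pendant edge can be strictly impossible for
a read mismatching that leaf; the floor pushes the search away smoothly.
The optimizer is validated against 200 × 200 grid searches: its logL must
never fall below the grid maximum by more than the grid's own resolution
(it may exceed it — grid points are feasible starting points).

Branch-length re-estimation for the leave-one-out study is coordinate
ascent: one derivative-free search per edge on the log-length scale
(bounds 10⁻⁶ … 10), swept until the sweep's total logL gain drops below
10⁻³; topology and numbering are untouched, and a sweep cap returns the
best lengths found with a warning.

## Bayesian quadrature

The per-edge marginal averages ℒ·P(b) over the attachment rectangle:
Gauss–Legendre in a on [0, Aᵢ], and in b through the prior's CDF transform
so that integral runs over the unit interval. A single 15-node panel in the
transformed coordinate is not reliable: with an exponential prior a
mismatched read's likelihood keeps rising with pendant length against the
thin prior tail, concentrating the integrand near u = 1; with a uniform
prior a sharp optimum near b = 0 concentrates it near u = 0. The b
quadrature therefore uses composite Gauss–Legendre with 15 nodes per panel
on panels graded geometrically toward the relevant end (down to 10⁻⁸ from
it); truncation beyond the last panel is bounded by the prior tail mass
times the saturated likelihood and is ≤ 10⁻⁸ relative. Against dense-grid
oracles this lands within ~10⁻⁵ of the true log marginal. Zero-length
edges are treated as a point mass at a = 0 with the 1/Aᵢ factor dropped
(the limit value). Priors: exponential with mean 0.1 substitutions/site
(default) or uniform on [0, 2.0], matching b_max.

Posteriors are the softmax of log marginals over the *evaluated* edge set;
when the baseball heuristics truncate the search this is an approximation
to the all-edges sum, and exhaustive mode (`BaseballParams(enabled=False)`
or `--no-baseball`) recovers the literal normalization. EDPL sums over
ordered candidate pairs — the expected distance between two independent
draws from the placement distribution — using distances between attachment
*points* (a-offsets along their edges, not edge midpoints), divided by the
total tree length (a flag disables the normalization).

## Heuristic defaults

Strike box D = 6, 6 strikes, 40 pitches; the strike reference is the first
fully evaluated edge's logL (a flag switches to the running best). The
quick-evaluation pendant length b₀ = 0.1. Friends require ≥ 90% identity
over the jointly informative columns, predecessors ranked by mismatches
then matches-to-gaps; friend search is skippable since it is quadratic in
the number of reads. These defaults are deliberately conservative —
`fantasy_baseball` exists to tune D and the strike count per dataset by
replaying recorded exhaustive searches without re-optimizing.

## Synthetic data and the leave-one-out study

The generator emulates a single-gene reference: a random bifurcating
topology by uniform sequential edge attachment, branch lengths exponential
with mean 0.15 (floored at 0.02) — typical single-gene depths — and
sequences evolved from stationarity with one Γ category drawn per site. It
does **not** emulate alignment error, homopolymer/sequencing error,
compositional heterogeneity, indel structure (reference rows are ungapped),
or model misspecification: passing tests show the placement machinery is
correct and calibrated when its model assumptions hold, not that real
alignments are this clean.

The leave-one-out pipeline removes each taxon, prunes its pendant branch
(merging the two branches at the attachment node, lengths summed as the
starting value), re-estimates branch lengths on the fixed pruned topology,
simulates fragments of truncated-normal length (minimum 10 residues) and
uniform position from the held-out ungapped row, and places them back.
Fragments carry their true reference-column coordinates, isolating
placement error from alignment error; an `align_hook` lets callers swap in
an external aligner to reproduce the full original protocol. The true edge
after pruning is the merged edge — the only well-defined choice in the
pruned tree. Accuracy is the count of internal nodes strictly between the
placed and true edges (correct = 0, sister = 1).

The bundled study size is 12 taxa × 800 nucleotide columns × 10 fragments
per taxon, with a long (200 ± 60) and a short (30 ± 7) condition sharing
pruned trees and seeds; this keeps the full pipeline to a few minutes on
one core while leaving every qualitative contrast measurable. At 120 reads
per condition the ten confidence bins are individually sparse, so the
headline checks pool them into three bands (< 0.5, 0.5–0.9, ≥ 0.9) and
require the fraction of correct placements to increase strictly across
bands for both LWR and posterior binning, alongside the long-beats-short
contrast; the full ten-bin tables are still produced.

## Known limitations

- Reference branch lengths stay fixed during placement (that approximation
  is what buys linearity); trees with severely misestimated lengths will
  misplace confidently.
- Posterior normalization under heuristic truncation omits unevaluated
  edges (see above).
- The friend comparison is O(reads²); disable it for very large runs.
- EDPL uses the optimal attachment point per edge; marginalizing over
  attachment positions is out of scope.
- No codon models, partitioned models, or per-site rate (CAT-style)
  approximations.
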