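# Methods

## Quartet tallies on a fixed species tree

All support and conflict metrics operate on the unrooted view of a given
species tree; a degree-2 root is suppressed. For an internal branch e, the
four neighbour groups A, B, C, D are the components obtained by deleting e
and splitting each endpoint: A, B hang off one endpoint, C, D off the other,
so the displayed resolution is AB|CD. Branches adjacent to a polytomy (an
endpoint with more than two remaining neighbours) have no canonical quartet
decomposition and are reported as uninformative (m = 0, frequencies NA)
rather than forced into an arbitrary convention. Branches whose groups
contain no sampled gene-tree copy at all are likewise NA.

A quadruple takes one gene-tree copy of one species from each group. Species
with several copies (paralogs, homeologs) contribute every copy with equal
weight; no attempt is made to reproduce any particular reconciliation-aware
weighting scheme, and exact numerical equality with quartet scores printed
by species-tree programs is not claimed. A quadruple is informative when the
induced unrooted quartet in the gene tree is resolved; resolution is decided
by the four-point condition on topological (unit-edge) distances, which is
exact on trees. Per gene, topology counts over informative quadruples are
normalised to a frequency vector; the branch frequency vector is the
unweighted mean over genes with at least one informative quadruple, so each
gene tree counts once regardless of its copy number. A pooled mode (raw
quadruple counts summed across genes) is available behind a flag for
sensitivity analysis. Enumeration is exact; sample mode draws K quadruples
per gene per branch (default K = 2000) from a single seeded generator whose
seed is recorded in the tally metadata.

## QC and QD

QC = s·(1 + Σ fᵢ log₃ fᵢ) with 0·log 0 := 0. Log base 3 is chosen because
there are three outcomes, giving QC(1,0,0) = 1 and QC(⅓,⅓,⅓) = 0. The sign
s is +1 when f1 strictly exceeds max(f2,f3), −1 when some alternative
strictly exceeds f1, and QC := 0 at an exact tie: maximal ambiguity should
not claim support for either side. When the annotated tree displays each
branch's majority resolution, QC is therefore non-negative everywhere.

QD = min(f2,f3)/max(f2,f3) ∈ [0,1]; it is 1 when the two discordant
resolutions are equally frequent and approaches 0 under skew. At zero
observed discordance (f2 = f3 = 0) QD is NA — not 0 and not 1 — so the
skew flag can never fire without observed discordance.

Flags: `strong_support` ⇔ QC > 0.2; `conflicted` ⇔ 0 ≤ QC ≤ 0.2;
`skewed_conflict` ⇔ QC ≤ 0.2 and QD < 0.5. The thresholds are the
conventional interpretation values and are overridable in the CLI.

## Signed plastome QC and cyto-nuclear conflict

Plastome bootstrap trees are treated as single-copy gene trees and tallied
against the nuclear tree after both sets are reduced to their shared
(matched) tip set; tips can be matched through an explicit map (accession
matching with a species-name fallback) or taken as identical labels. The
signed QC is +1 when every bootstrap tree displays the nuclear quartet and
−1 when every tree supports one alternative. A branch is a supported
conflict when nuclear QC > 0.2 and plastome QC < −0.2. The Pearson
correlation between the two QC vectors is computed over branches where both
are defined (NA below three such branches), with t = r·√((n−2)/(1−r²)) and
a two-sided p-value.

## Transfer bootstrap expectation

For a reference bipartition with lighter side p, the transfer index δ
against a bootstrap tree is the minimum Hamming distance (taxa on differing
sides, taking the smaller orientation) over all edges of that tree, pendant
edges included — which guarantees δ ≤ p−1 and makes cherry support equal the
classical presence proportion. Support is 1 − mean(δ/(p−1)). The naive
O(edges²·taxa) scan is used deliberately: it is exact, simple to audit, and
fast at the tree sizes this package targets; the published linear-time
algorithm is unnecessary here. Bootstrap trees missing taxa are scored on
the restricted bipartition and skipped where the restriction is trivial.

## Transfer summarisation

Records (gene, donor branch, recipient branch, count) are aggregated per
unordered branch pair after excluding transfers to or from the root (they
may involve unsampled outgroup lineages). Support is the number of distinct
gene ids by default — the conservative reading when events within a gene
family are listed repeatedly — with raw event counts behind a flag. The
highlight cutoff is the upper nearest-rank (1 − q) quantile of supported
pairs' supports (q = 0.10), i.e. the smallest support whose cumulative share
reaches 1 − q; this convention reproduces the intended behaviour that with
supports {6×9, 20} only the 20-support pair is highlighted. A flag computes
the quantile over all pairs instead. Directionality uses |a−b|/(a+b) > 0.5
on per-direction counts, with |a−b|/max(a,b) available as an alternative
formalisation. Clade (tribe)-level summaries remap branch ids through a
collapsed tree; note the counts then combine gene-tree tips from all species
in a clade.

## Filter cascade

Missing means gap or N (or ?). Hit filters are strict inequalities as
printed in their presets; the column-trimming rule is inclusive (drop when
missing fraction ≥ 0.9), matching gap-threshold trimming semantics; the
occupancy rule (≥ 50% of genes) and the plastome rule (≥ 25% coverage for
≥ 5 genes) are inclusive; plastome samples with ≥ 95% missing supermatrix
sites are dropped. The 200-bp sequence filter counts non-missing characters
after trimming (aligned span would over-count gappy sequences). Consensus
calling emits N below the depth floor, the unique base reaching the call
fraction otherwise, and the IUPAC code of the tied set at an exact tie —
a consensus never calls a two-allele ambiguity except at ties, which is how
collapsed paralog differences end up coded as ambiguities. All filters are
idempotent and order-stable, which the tests assert.

## Paralog validation

Candidate assemblies within an orthogroup are deduplicated (exact,
case-insensitive, ungapped duplicates and exact substrings removed; the
longest candidate is retained, ties broken by label). The accession-specific
reference is the reference sequence with most bases covered (ties broken
lexicographically) plus all reference sequences of the same species.
Validation roots the guide tree on its longest branch (ties: first edge in
preorder) and requires, for each assigned reference lineage, that the
candidates assigned to it together with that lineage's reference sequences
form a monophyletic group; if any lineage fails, only the longest candidate
is kept. "Corresponding references" is read per assigned lineage; a joint
criterion (all candidates plus all their references monophyletic at once) is
available as an option. "Longest" means ungapped length. When no external
tree is supplied, a neighbour-joining tree on uncorrected p-distances over
pre-aligned sequences serves as the guide; an externally estimated
(likelihood) tree always takes precedence — the contract is the monophyly
decision, not the tree.

## Synthetic data

The simulator provides every input with known truth. Species trees are
balanced or Yule-shaped with branch lengths in coalescent units (2N
generations ≡ 1), constant internal length t by default or drawn uniformly
from a range when branch-support heterogeneity is wanted. Gene trees follow
the standard MSC: one lineage per species, pairwise coalescence at rate 1
per pair per unit within each branch, forced coalescence above the root.
On this scale the closed form f1 = 1 − (2/3)e^(−t) applies directly, and the
simulator is cross-checked against an independent coalescent simulator
(msprime) in the test suite. Gene-tree branch lengths are written as unit
lengths: no consumer in this package reads them, only topologies and copy
multiplicities.

Introgression is whole-gene topology replacement: with probability π a gene
is simulated under the MSC on the species tree after one NNI at the target
branch, which matches the quartet-level signature being tested (QC ≤ 0.2
with QD < 0.5) while keeping coalescent variance; migration bands are not
modelled. Duplications attach an extra copy of a uniformly chosen species as
a sister tip and register it in the taxon map — both copies then occupy the
same quartet position, exercising the paralog weighting. Bootstrap
surrogates are seeded random-NNI perturbations of a reference tree
(0 moves = identical copies; 1 move changes exactly one bipartition).

Sequence-side fixtures are pattern-constructed, not evolved: alignments with
planted gap patterns straddling each trimming threshold, pileups with known
consensus strings, hit tables on both sides of each preset boundary
(including the inclusive 166-of-331 occupancy edge), transfer tables with
planted supported/highlighted/directional pairs and root transfers, and
paralog scenarios with a planted shared duplication and a planted chimera.
A JSON manifest records every expected outcome, and the bundle is
byte-identical under a fixed seed. What passing these tests shows is that
the implementation applies its stated rules exactly on data whose truth is
known by construction; it does not show robustness to real-data features the
generator omits (alignment error, rate variation, missing data correlated
with phylogeny, gene-tree estimation error, migration-band introgression).

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale by design:
quartet oracle checks use ≤ 8 species with 20 multi-copy gene trees across
25 seeded instances; coalescent frequency-recovery checks use 1000 genes on
a 4-taxon quartet tree; conflict detection uses a 10-taxon tree with 100
bootstrap surrogates. These sizes make exact brute-force oracles feasible;
the implementation itself scales to hundreds of taxa. Every stochastic step
(simulation, quadruple sampling, NNI perturbation) derives from a single
integer seed through one generator per call, and outputs embed the seed and
configuration, so all runs are byte-reproducible.

## Known limitations

* Quartet weighting is uniform over copy quadruples; reconciliation-aware
  per-quartet weighting used inside species-tree programs is not replicated.
* Branches adjacent to polytomies are not scored.
* The NJ guide-tree fallback assumes pre-aligned, equal-length sequences and
  uncorrected distances; it is meant for validation-scale problems.
* Transfer summaries inherit the reconciliation's inability to separate
  reticulation from ILS between rapidly diverging lineages; the summary
  thresholds flag repeatable signal, they do not test a model.
* The introgression model replaces whole-gene topologies; it does not
  simulate partial-locus introgression or migration.
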