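# Methods

This note documents the models and procedures the package implements,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic-data experiments do and do
not establish.

## Distances

Pairwise divergence is the Kimura two-parameter distance
`d = -1/2·ln[(1-2P-Q)·sqrt(1-2Q)]`, with `P` the transition (A↔G, C↔T)
and `Q` the transversion proportion. Sites are compared under
**pairwise deletion**: any alignment column holding a gap or a
non-ACGT symbol in either member of the pair is excluded. Transitions
and transversions are classified on unambiguous bases only. When
`1-2P-Q ≤ 0`, `1-2Q ≤ 0`, or no sites remain, the distance is
UNDEFINED; UNDEFINED values are carried explicitly (NaN in matrices, a
flagged side-list) and are never silently replaced — only the
barcode-gap stage maps them to the capped value, and the pipeline log
records every such event. The correction is monotone and can only
inflate the uncorrected p-distance, which the tests verify on random
pairs.

## Alignment groups

Homology between ITS sequences beyond ~20% divergence is ambiguous, so
distances are only computed inside *alignment groups*. Groups are built
greedily: sequences are considered one at a time and joined to the
existing group containing the highest-identity member among those
meeting **both** thresholds — overlap identity ≥ `min_identity`
(default 0.80) and doubly-occupied overlap length ≥ `min_overlap`
(default 100 bp) — otherwise a new group is opened. Choices made here:

- **Single-linkage joining** (best single member), not
  identity-to-consensus: reproducible and directly testable, whereas
  consensus construction introduces an extra, underdetermined model.
- **Identity semantics**: the denominator is the doubly-occupied
  overlap region of an optimal overlap alignment (terminal overhangs
  free and excluded); a column matches only if both symbols are
  identical non-gaps, so internal gap columns inside the overlap count
  against identity and degenerate codes never match other codes.
- **Canonical processing order** (descending length, ties by id) makes
  the result a pure function of the input set. Greedy clustering is
  inherently order-sensitive; `grouping_order_sensitivity` re-runs the
  construction under seeded shuffles in input-order mode and reports
  the fraction agreeing with the canonical partition together with the
  distinct partitions observed. Ties between equally good groups go to
  the earlier-created group (arbitrary but documented).

Raising `min_identity` can only refine a partition obtained under the
same processing order, never merge groups; this monotonicity is tested.

## Pairwise and multiple alignment

The aligner is linear-gap dynamic programming (match +1, mismatch −1,
gap −2) in two modes: global, and overlap (terminal gaps free) for
clustering identities. Affine gaps were deliberately not used: the 80%
threshold operates at coarse resolution and a linear penalty keeps the
DP exactly checkable against brute-force enumeration. Traceback ties
prefer diagonal, then up, then left, so reported alignments are
deterministic. Row-wise the recurrence is vectorized by solving the
within-row left-gap chain with a running maximum, which keeps 600-bp
alignments at a few milliseconds without compiled code.

The multiple aligner is progressive: a neighbor-joining guide tree on
pairwise alignment distances (1 − identity), then profile–profile DP
under mean-pairwise column scoring (gap/gap scores 0, gap/base the gap
penalty) with no position-specific gap penalties. For substitution-only
inputs at the divergences in scope this produces gapless alignments
and MSA identities equal to pairwise identities; at high divergence
with many rows, score averaging can occasionally admit a compensated
gap-column pair. The effect on K2P distances is at the fourth decimal
in the regimes tested, but it is why within-group distances — not
MSA column counts — are the unit of analysis.

## Preprocessing

**ITS.** Reads are trimmed to begin at the first occurrence of the
conserved SSU-terminal motif (default `CATTA`) and end at the *last*
occurrence of the LSU-terminal motif (default `GACCT`), motifs
retained; absent or inverted motifs raise distinct errors and trimming
is idempotent. The 5.8S gene is excised by explicit per-record
coordinates (1-based, closed; ITS1 end and ITS2 start) supplied from
annotation — no built-in 5.8S model is attempted, because the
coordinates are reliably available from annotated records and a
sequence model would add an unvalidated component.

**COI introns.** Insertions relative to an intron-free reference exon
are located by anchor-and-chain: all exact 12-mers unique in both
sequences (unique-in-both keeps chaining linear and discards repeats),
chained by longest increasing subsequence on (reference, query)
positions, with two guards: chain elements whose query-minus-reference
offset matches neither neighbor are dropped (these are chance k-mer
hits inside inserted blocks — genuine exon anchors share their
segment's offset), and any inter-anchor query surplus ≥ `min_intron_len`
(default 50) becomes a call. The call position is the 1-based reference
coordinate of the last anchored base before the gap (0 for insertions
preceding the first anchored base), matching the convention of marking
intron sites as points on the exon. The default anchor length 12 is
long enough that chance matches in a ~450 bp exon are rare and short
enough to survive ~5% query–reference divergence. Calls carry the query
coordinate of the first inserted base so excision is exact; excision
refuses overlapping calls. When an insertion's first base happens to
equal the following exon base the junction is ambiguous by homology;
detection then reports one of the equivalent placements and excision
still restores a sequence identical to the reference.

**Primers.** Degeneracy is the product of IUPAC class sizes. Mapping
scans every window of the plus strand; reverse primers are matched as
their reverse complement; template degeneracies are matched permissively
(non-empty class intersection). Amplicon length spans from the forward
window start to the last base of the reverse window, both primers
included. Under this convention the packaged panel's 11F/2eR pair spans
675 bp on its reference coordinates; published amplicon sizes for these
pairs are not mutually consistent with any single coordinate
convention, so they are reported, not asserted.

## Barcode-gap statistics

Per species and locus: intra-specific statistics (max, mean, median)
over conspecific pairs co-resident in a group — NA when fewer than two
conspecifics share a group; conspecific pairs split across groups are
simply never compared. The inter-specific minimum is the smallest
distance from any member to any heterospecific sequence in the same
group (nearest-neighbor reading; a tree-reconciled "sister taxon" would
require a tree-building step that distance-only groups do not have, and
the NJ tree is written alongside for inspection). Values strictly above
`cap_threshold` (0.20), UNDEFINED distances, and species with no
heterospecific group-mate are recorded at `cap_value` (0.21) with a
capped flag. The boundary value 0.20 passes through unchanged
(strictly-greater rule). Capping is idempotent and monotone.

Summaries per locus report the extrema and moments of the per-species
columns: the minimum inter-specific divergence **excludes** capped
entries (they are bounds, not measurements) while means and medians
**include** them at 0.21, the convention under which capped values were
defined. Locus comparison uses the intra:inter ratio (0 when intra is
0, infinite when inter is 0, TIE when equal); both ratio orientations
are available, and the barcode-gap pass criterion is inter/intra > 1.
On the packaged survey the mechanical least-ratio rule disagrees with
the published per-row highlight for many capped rows;
`flag_highlight_disagreements` annotates these rather than suppressing
either reading, and no fixed agreement count is asserted.

The packaged survey keeps all 38 printed rows, including the five
multi-species rows whose intra cells are NA; reconciling the printed
row count with any stated species subset is left to the analyst.

## Synthetic data

The generator emulates the structure the analysis assumes: a root
sequence, one ancestor per species, and members below ancestors, all
under continuous-time Jukes–Cantor substitution (per-site change
probability `3/4·(1 − e^(−4t/3))`). Branch lengths are chosen so the
**expected member–member divergence is exactly σ within species and δ
between species** (ancestor branches (δ−σ)/2, member branches σ/2);
σ and δ are therefore directly estimable by mean K2P distances, which
the tests check with standard errors taken across seeds — seeds are the
independent replicates, since pairs within a dataset share ancestral
draws. Defaults (600 bp, σ = 0.005, δ = 0.08, indel rate 0.001) mirror
species-level ITS variation: intra-specific divergence of order 0–2%
against inter-specific divergence of order 2–25%. Indels are rare
single-base insertions/deletions; the genealogy is a star of stars, the
simplest shape exhibiting a barcode gap. What passing these tests does
**not** show: robustness to coalescent genealogies, rate variation
across sites or lineages, alignment-length heterogeneity, chimeras, or
sequencing error — none of which the generator emulates.

Perturbation ("dummy") sequences measure divergence in edit operations
relative to the base length: `SUBS_RANDOM` substitutes `round(d·L)`
distinct positions; `GAPS_RANDOM` makes that many single-base
insertions; `GAPS_EVEN` inserts one base after every `⌈1/d⌉`-th
position (d = 0.125 → every 8th), which generalizes the even-spacing
scheme to the whole 1–20% grid; `GAP_BLOCK` inserts one contiguous
block. Operation-count semantics were chosen because "percent
divergent" is otherwise undefined for mixed edits. The robustness
experiment re-clusters the dataset with one dummy at a time and reports
co-clustering. Substitution-only dummies at ≤ 19% divergence retain
≥ 81% identity and must co-cluster at the 0.80 threshold — the only
asserted outcome. Gap-mode failures are reported, not asserted: the
greedy single-linkage clustering here need not share the failure modes
of any proprietary assembler, so the experiment's gap-mode rows are an
empirical readout of *this* algorithm.

## Trees

Neighbor joining is plain Saitou–Nei with the standard Q-criterion.
BioNJ's variance-weighted reduction was not used: on the near-additive,
low-divergence within-group matrices in scope the two are topologically
equivalent, and plain NJ recovers random additive trees exactly
(verified to RF 0 and 1e−9 on branch lengths). Q-ties are broken by the
lexicographically smallest joined pair (clusters keyed by their
smallest leaf label), replacing random tie-breaking so runs are
reproducible; negative branch-length estimates are clamped to 0.
Reciprocal monophyly of a species is the existence of an edge whose
removal separates exactly that species' leaves; singletons are
monophyletic by convention.

## Problem sizes and determinism

Every stochastic component takes an explicit seed and is reproducible
bit-for-bit. The bundled experiments use 500 pairs for the K2P oracle
check, 100 random additive trees for NJ, 200 short pairs for exhaustive
alignment enumeration, 100 constructed queries for intron round-trips,
20 seeds of 6 species × 3 sequences for full-pipeline parameter
recovery, and an 80-cell perturbation grid — sizes at which each check
is statistically meaningful while the whole suite completes in minutes
on one CPU.

## Known limitations

- The 5.8S locator is annotation-driven; unannotated inputs need
  coordinates from an external source.
- Intron detection assumes exact 12-mer anchors survive between
  insertions; queries more than ~8% divergent from the reference exon,
  or insertions closer than the anchor length, degrade detection.
- The progressive MSA has no iterative refinement; ambiguous gap
  placement near indels can locally perturb within-group distances.
- Greedy grouping is order-sensitive by construction; the canonical
  order fixes the interface but does not make the underlying partition
  problem well-posed near the identity threshold.
- The capped value 0.21 is a convention, not an estimate; summary means
  that include capped entries inherit it.
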