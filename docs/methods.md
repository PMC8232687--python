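# Methods

## Locus model and coordinates

All coordinates are 0-based, half-open; the cut is an inter-base
position `cut` (the bond between `reference[cut-1]` and
`reference[cut]`). For a 20-nt protospacer with an NGG PAM, the blunt
SpCas9 cut is placed 3 nt 5′ of the PAM on the protospacer strand —
between protospacer positions 17|18 (1-based). For a `-`-strand
protospacer the cut and all derived windows are mapped into reference
coordinates, and the PAM-distal/PAM-proximal ends swap left/right sides;
downstream logic only ever speaks of `EndLabel`, never left/right, so
reporting is strand-safe.

Derived sequences, all exact substrings of the unedited reference:

| window | default | role |
|---|---|---|
| indicator | 12 nt, near edge 70 nt from the cut, each side | selects reads spanning that break end |
| WT marker | ±5 nt around the cut (10 nt) | intact ⇒ unedited (or perfectly restored) allele |
| junction flank | 10 nt abutting the cut, each side | the genomic half of each junction window |

Two readings of "an indicator 70 nt from the cleavage" are possible
(cut→near edge vs cut→far edge of the 12-mer); the near-edge reading is
the default and the far-edge one is `offset=58` away. The ±5 marker is
read as 5 nt on *each side* of the inter-base cut, giving an even 10-nt
window; the halfwidth is configurable.

## Classification contract

Classes are assigned with precedence **wild type > dsODN-inserted >
mutation**, in the order the filters are applied:

1. wild type ⇔ the WT marker occurs exactly in the read. These reads are
   excluded from every accuracy denominator (an uncut allele carries no
   repair information).
2. dsODN-inserted ⇔ any contiguous 10-mer of the tag, in either
   orientation, occurs exactly. Any 10-mer (rather than only the tag
   termini) keeps reads with resected tag ends in the denominator;
   orientation is resolved by which strand matched, forward preferred on
   ties.
3. mutation ⇔ neither.

A junction is **accurate** iff the read contains, as one contiguous
exact substring, the 10-nt genomic flank for that end immediately
abutting the 10-nt terminal segment of the orientation-resolved tag.
This single 20-nt exact-match window simultaneously enforces "no indels
in either the genomic DNA or the dsODN" at the junction without any
alignment: an inserted, deleted or substituted base anywhere in the
window breaks it, and edits outside the window are ignored (junction
accuracy is local by construction). Note the useful corollary that an
edit which is *equivalent* to an out-of-window edit (e.g. deleting one
base of a repeat that straddles the window boundary) leaves the window
present — which is the right call, since the junction sequence is
genuinely intact.

Per-end accuracy is `n_accurate(end) / n_assessable(end)`, count-weighted,
where assessable means "selected by that end's indicator"; the
all-dsODN-denominator variant is reported alongside, and a zero
denominator yields an explicit undefined (`None`), never 0.

Dual-guide deletions reuse the same machinery on one shared reference: a
deletion-junction read must contain both outer indicators and neither
cut's WT marker; it is precise iff the two outer 5-nt flanks
(`ref[cut_a-5:cut_a] + ref[cut_b:cut_b+5]`) occur joined as one exact
10-mer. Configurations are named by the retained ends: PAM-in (two
PAM-distal), PAM-out (two PAM-proximal), PAM-in/out (mixed).

## Read preparation

Pairs are joined by a quality-aware ungapped overlap merge: all overlap
lengths ≥ `min_overlap` (10) are scanned, candidates with mismatch
fraction ≤ 0.1 are kept, and the candidate with the most matching bases
wins (ties to the longer overlap); disagreements take the higher-quality
base. This implements the contract of a read joiner, not any particular
published tool's heuristics — only the merged amplicon sequence matters
downstream. Unmergeable pairs are a counted outcome, not an error.

Merged reads are collapsed to distinct sequences with counts, and
sequences seen once are removed (`min_count=2`). Singleton removal is
applied *before* indicator selection (the printed step order); both
orders are available for sensitivity checks. Indicator matching is exact
by default with an optional Hamming tolerance; reverse-complement hits
are canonicalised to reference orientation so all later searches are
single-stranded.

## Indel profiling

dsODN-free mutation reads (both indicators present, WT marker absent,
tag absent) are aligned globally to the reference under affine-gap
scoring (match 5, mismatch −4, gap open −10, gap extend −1; a gap of
length L costs 10 + L). The alignment itself is delegated to Biopython's
`PairwiseAligner`; gap runs are then extracted, **left-aligned** through
repeat context (so score-equivalent gap placements yield identical
calls), and kept only if their reference footprint intersects
[cut−5, cut+5] — the same locality convention as the WT marker.

Reads are typed insertion / deletion / complex (both) / none. The
insertion fraction is `n_ins / (n_ins + n_del)`; complex reads are
excluded from that denominator and reported separately, matching a
two-way insertion:deletion summary. Among single 1-bp insertions the
inserted base is compared, strand-resolved, to the **N4 base**
(protospacer position 17, the base immediately 5′ of the cut), the
template of the canonical staggered-cut duplication.

## Statistics

- Dispatch: parametric tests (paired *t*, one-way ANOVA) only when every
  sample passes Shapiro–Wilk at α = 0.05 (conventional default,
  configurable); otherwise Wilcoxon signed-rank / Kruskal–Wallis. All
  tests two-sided; no multiple-testing correction by default (a
  Benjamini–Hochberg helper exists in scipy if users want it — raw
  p-values are the reported quantity here).
- Wilcoxon signed-rank: zero differences dropped (Wilcoxon's original
  treatment), |d| ranked with average ties, statistic W⁺. For n ≤ 25 the
  two-sided p is **exact**: ranks are doubled to integers (average ties
  give .5 steps), the full distribution of W⁺ over all 2ⁿ sign
  assignments is built by subset-sum convolution in exact integer
  arithmetic, and the p-value sums all assignments at least as far from
  the symmetry centre T/2 as observed. Above n = 25 the tie-corrected
  normal approximation is used. A degenerate all-zero vector reports
  p = 1 with a flag.
- Spearman: ρ from average ranks; for n ≤ 9 the two-sided p is exact
  over all n! orderings, above that the t approximation with n−2 df.
  Signed ρ is reported (rank correlations are signed quantities, even
  where source material labels them "R²"). Constant vectors yield a
  flagged undefined result.
- `compare_ends` runs the gated dispatch on distal−proximal differences
  by default; a `test=` override forces a branch, for reproducing
  comparisons that report a fixed test choice.

## The simulator

`simulate_pool` emulates one target's merged amplicon pool with known
ground truth. Class totals (wild type / dsODN / mutation / junk) are an
exact multinomial draw at `n_reads`; each class total is partitioned
into alleles with PCR multiplicities drawn from a categorical
distribution (default 1–5 copies, 15% singletons), so Σ multiplicities
= n_reads exactly and the truth table has one row per allele.

- dsODN alleles: `ref[:cut] ⊕ tag(orientation) ⊕ ref[cut:]`, each
  junction independently accurate with its configured probability
  (per-end reporting implies marginal quantities; independence is the
  simplest recoverable model). Inaccurate junctions carry one indel of
  1–10 nt at the joint — genomic-side deletion, tag-side deletion
  (capped so an intact tag 10-mer always survives, keeping detection
  denominators interpretable), or random insertion.
- mutation alleles: one indel at the cut; insertion with probability
  `mut_insertion_fraction` (length 1 with 90% weight, and a 1-bp
  insertion equals N4 with probability `p_n4_identity`, else uniform on
  the other three bases), otherwise a deletion of 1–10 nt covering the
  cut.
- substitution sequencing error is applied per *copy*, after
  replication (default 10⁻³/base). Error-bearing copies are therefore
  mostly unique sequences, which the duplicate-collapse + singleton
  filter removes — this is precisely the cleanup that filtering step
  exists to perform, and it keeps accuracy recovery essentially
  unbiased at realistic error rates.
- synthetic references are random 220-mers with homopolymer runs capped
  at 3 (bounding left-alignment shifts, so simulated events cannot
  drift out of the ±5 calling window), sharing no 10-mer with the tag.
  The default 34-nt tag is itself synthetic — constructed for these
  properties, not a published reagent sequence; users supply their real
  dsODN for real data.

`simulate_dual_pool` emits deletion-junction reads (precise with
probability `p_precise`; imprecise joints lose or gain 1–10 nt), plus
wild-type, single-cut-indel and junk contaminants.

Default study conditions (`nhejacc.study`): 18 targets; PAM-distal
accuracy ~ Beta(mean 0.7418, SD 0.15); PAM-proximal accuracy declining
with the target's insertion fraction (slope −0.55, noise SD 0.08 around
a 0.3862 centre); insertion fractions uniform on [0.05, 0.95];
dual-guide precise-ligation probability modelled as the product of the
two retained ends' accuracies, giving PAM-in (0.55) > PAM-in/out (0.29)
> PAM-out (0.15). Pool sizes: 20,000 reads per accuracy pool, 8,000 per
dsODN-free profiling pool, 10,000 per dual pool — large enough that
binomial error on recovered fractions is ≲1%, small enough that the full
study, test suite and acceptance script each run in well under a minute
on one CPU.

## What the simulations do and do not show

The simulator reproduces the *logical* structure of dsODN-capture data:
class mixture, independent per-end junction errors, indel spectra with
N4-templated 1-bp insertions, PCR duplicate structure, uniform
substitution error, and either-orientation tag integration. It does not
model PCR chimeras, position- or motif-dependent error profiles,
quality-score structure beyond a constant, microhomology-driven deletion
spectra, or large structural variants other than the programmed dual-cut
deletion. Passing tests therefore demonstrate that the pipeline measures
what it claims on data obeying its stated assumptions — not that those
assumptions exhaust real sequencing artefacts.

## Numerical and degenerate-input choices

- Undefined fractions (zero denominators) are `None`/flagged, never 0.
- Exact-test arithmetic is integer until the final division; oracle
  agreement is asserted to 1e-12.
- Alignment tie-breaks: mismatches beat gaps by construction of the
  scores (a substitution costs 9 less than the cheapest indel pair);
  remaining gap-placement ambiguity is removed by left-alignment before
  event calling, so calls are placement-invariant.
- `merge_pair` prefers R1's base on equal quality; no-merge is a normal
  outcome.
- Config validation happens before any output is produced; invalid
  fractions, unnormalised distributions and impossible geometries raise
  typed errors (`TargetError`, `GeometryError`, `ContractError`).
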