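# Methods

## Scope and data model

`rgcscan` operates on a gapped multiple sequence alignment of plastomes
(aligned FASTA) in which structural mutations appear as gap runs. All
coordinates are 0-based, half-open, in alignment-column space unless a
function states otherwise (published table captions use 1-based inclusive
ranges; `rgcscan.io.to_zero_based`/`to_one_based` convert). Input is
case-folded to upper case; the gap character is `-` (`.` is normalized to
`-`, `?` to `N`, each with a warning). Trees are `dendropy.Tree` objects;
genome records are gap-free sequences with optional features read from
GenBank flat files via Biopython.

Because plastomes carry two identical inverted-repeat copies, the IRa is
conventionally excised before analysis to avoid counting IR mutations
twice; `excise_interval` performs this on alignments or records.

## Event detection and culling

A *gap run* is a maximal run of `-` in one taxon's row. Runs touching the
first or last column are flagged *terminal* and excluded by default: a
terminal gap is indistinguishable from missing data (sequence truncation),
the standard treatment in indel coding. Runs with identical column
intervals are clustered into one *event* whose member set is the union of
taxa; `boundary_slop` (default 0 columns) optionally merges runs whose
boundaries differ by at most that amount, with the first-seen interval as
canonical. Identical-boundary sharing is the strictest defensible
mechanization of homology between indels; it is deliberately conservative.

A taxon's *condition* over a span is read with gap-fraction tolerances:
*present* if ≤ 20% of the span is gapped, *absent* if ≥ 80%, *partial*
otherwise. The tolerances matter: large real deletions routinely contain
small independent indels in other taxa, and demanding literally all-residue
or all-gap spans would discard exactly the events the method exists to
find. 20/80 leaves a wide partial band so that genuinely uncertain rows are
scored as missing rather than forced to a state; a row half-gapped over a
span is always partial.

An event is culled as **ambiguous** when any of:

* **(a) homology conflict** — another event's interval overlaps it and
  neither strictly contains the other. Boundary-sharing or boundary-
  crossing overlap means the gaps cannot be aligned one-to-one; a strictly
  nested event, by contrast, is an independent smaller indel inside the
  larger span and poisons neither party.
* **(b) indel-riddled region** — more than 50% of the taxa outside the
  event have a *partial* condition over its span, i.e. the region is so
  churned by independent indels that presence/absence of the span cannot be
  read in most of the sample.
* **(c) unreadable outgroup** — a designated outgroup taxon is *partial*
  over the span, so no ancestral condition can be assigned.

Non-ambiguous events of at least `min_rgc_len` (default 50 bp) form the RGC
set; the threshold is inclusive because observed RGC length distributions
start exactly at the 50 bp boundary that separates rare genomic changes
from microstructural changes. Shorter non-ambiguous events are reported in
a separate microstructural list and never coded.

## Mechanism classification

Classification precedence is fixed: **ISD > SSM > presumed recombination**.
A junction can satisfy both repeat patterns; dispersed-repeat evidence is
the diagnostic of interest and wins. All searches run in the *ungapped*
coordinates of each *reference row* (a taxon whose condition over the span
is present — for deletions the non-deleted relatives, for insertions the
inserted lineage itself), because repeats are properties of sequence, not
of alignment columns; results are mapped back to columns for reporting.

**ISD.** The search enumerates copy-start positions within
`max_boundary_offset` (default 5 columns) of the span's 5′ boundary (inside
the span) against positions within the same offset downstream of the 3′
boundary (retained sequence), extending exact matches greedily; the mirror
arrangement (copies anchored at the 3′ edge of the span and upstream of the
5′ boundary) is also scanned. Copies may not overlap. The longest repeat
≥ `min_repeat_len` (default 8 bp) across all reference rows wins, ties
broken by alphabetical reference label, making the call independent of row
order. Defaults: the two documented ISD repeats in the bundled examples are
9 and 10 bp, so 8 retains both, while the chance of a spurious exact 8-mer
at the fixed offsets is ≈ 4⁻⁸ per comparison (~10⁻³ per event after the
~72 offset pairs); matching is exact (`max_mismatches` is 0 and only 0 is
supported). The 5-column offset absorbs aligner placement wobble of the
junction copy — in the bundled *psbE–petL* example the retained 3′ copy is
split by a 4-column alignment gap.

**SSM.** The deleted/inserted span must be a whole number of copies of a
unit — the span's primitive period (computed by the KMP failure function)
when that divides the span, otherwise the whole span (the tandem-
duplication case) — with one copy tandemly adjacent to the span in the same
reference row. Units shorter than `min_tandem_unit` (default 2 bp) are
rejected, so homopolymer slippage is not called SSM.

## Binary coding and export

The outgroup consensus over the event span fixes the ancestral condition
(present → ancestral state `span_present`, polarity *deletion*; absent →
`span_absent`, polarity *insertion*). Multiple outgroups that disagree, or
any partial outgroup, drop the character with a warning — conflicts are
never guessed. Each taxon scores 0 (matches ancestral), 1 (full opposite
condition) or `?` (partial; uncertain homology is treated as missing data,
the conservative convention). Characters with no derived taxon after
polarization are dropped from exports but retained in reports. By
construction outgroup taxa never score 1.

Exports: a NEXUS `DATA` block with
`FORMAT DATATYPE=RESTRICTION MISSING=? SYMBOLS="01"` (labels quoted per
NEXUS rules when needed; the writer/reader pair is round-trip tested), and
a concatenated relaxed-PHYLIP matrix of nucleotide columns followed by
binary columns with a RAxML-style partition file naming the `DNA` and `BIN`
ranges as 1-based inclusive spans. Gap-column stripping (default
`any_gap`: drop every column containing any gap) is applied to the
nucleotide matrix only *after* events are characterized — the gaps are the
signal, the stripped matrix is for tree inference.

## Marker mapping

Minimum change counts come from unit-cost Sankoff dynamic programming —
exact small parsimony for two states, valid on polytomies (where the
classic set-intersection pass is not guaranteed minimal) — with `?` leaves
free in both states. The count is root-independent; classification roots
the tree on the outgroup edge so the ancestral state is basal, preferring
state 0 at the root on cost ties. One minimal reconstruction is committed
using the ACCTRAN convention (on ties a change is placed as close to the
root as possible), which fixes *where* changes sit, not how many there are;
the 0→1 edges become the supporting edges. Classes follow the counts: 0 =
invariant, 1 on an internal edge (≥2 leaves) = synapomorphy, 1 on a
terminal edge = autapomorphy, ≥2 = homoplasy. Marker codes number clades
in order of first appearance and letter the series of markers within each
clade (A1, B1, … for clade 1; A2, … for clade 2).

## Plastome descriptors

%AT is 100·(A+T+U)/(A+C+G+T+U) over unambiguous bases only, rounded
half-up to one decimal. Inverted repeats are found by seeding forward
k-mers (k = 21, capped at `min_len`) against an index of the reverse
complement and extending exact matches bidirectionally, with per-diagonal
coverage tracking to skip redundant seeds and symmetric trimming of
self-overlapping (palindromic) hits; only exact matches are considered,
since plastid IR copies are near-identical and exactness keeps the
brute-force oracle meaningful. The default `min_len` of 1000 bp reflects
genuine plastome IR scale (~20–26 kb) while tolerating reduced IRs. The
two inter-IR segments of the circle become LSC (longer) and SSC (shorter);
an exact tie takes the origin-containing segment as LSC, with a warning.
Detected boundaries are maximal exact-match boundaries and may differ by a
few bases from published annotations produced with other boundary methods;
total length and %AT are method-independent.

## Simulator

The generator evolves a root sequence (uniform or AT-biased to a target
%AT) along a user tree under JC69 — per branch, a Poisson number of
single-site substitutions with mean rate × branch length × sites, each to a
uniformly chosen different base, which realizes the JC69 process exactly —
and *plants* structural events rather than drawing them from an indel
process, because the tests need exact truth, not realistic indel rates.
Planting happens in the root sequence (so every reference lineage carries
the pre-event context, matching the evidence pattern where repeats appear
in all references); the lineage-specific edit happens on the specified
branch, identified by its child clade:

* ISD: a random repeat of `repeat_len` (≥ 8, the detectability floor) is
  written at both ends of the span; the lineage deletes from the first
  copy's start through the second copy's start, leaving one copy.
* SSM: a primitive unit over {A,C} is seeded as a tandem array flanked by
  {G,T} guard windows; the lineage contracts or expands the array by
  `|copy_delta|` copies, always retaining exactly one adjacent copy. The
  disjoint alphabets and single retained copy guarantee (not just make
  likely) that the flanking-repeat scan cannot reach 8 bp through the
  array, so planted SSM is never misclassified as ISD.
* Recombination deletions/insertions: plain span edits whose junction
  windows are built from disjoint base sets ({A,C} span edges, {G,T}
  retained flanks), making planted recombination events repeat-free by
  construction — the "no false ISD/SSM" property is deterministic.
* Micro-indels: deletions < 50 bp, below the RGC window.

Events are placed at margin-separated, globally non-overlapping positions
(margin 30 bp), which is stricter than the required per-path non-overlap
and keeps the truth table unambiguous. The TRUE alignment is derived from
the edit history via persistent column identities (insertions splice new
columns next to their anchor), so detection is tested independently of any
aligner; an unaligned FASTA is emitted for users who want to exercise their
own. Fixed seed ⇒ byte-identical outputs.

What the simulator does **not** emulate: alignment error (true alignments
only — detection performance under a real aligner's gap placement is not
measured), rate heterogeneity or richer substitution models (JC69 suffices
for mechanism/coding tests; model realism matters for tree inference, which
this package does not perform), stochastic indel processes, inversions, and
IR boundary shifts. Passing tests therefore demonstrate correctness of the
detection/classification/coding logic under known truth, not robustness to
alignment artifacts in real data.

## Problem sizes and determinism

The test suite and the acceptance script run the pipeline over 20 seeded
noise-free replicates (six-taxon tree, 12 kb root, six planted events per
replicate — sizes chosen so a full run completes in seconds while every
event kind and both polarities are exercised per replicate), exhaustive
parsimony enumeration on trees of ≤ 12 leaves, and quadratic brute-force
oracles for the repeat searches on ≤ 300-column windows and ≤ 5 kb
sequences. All randomness flows from explicit seeds; reports use stable
sort orders (events by start column, taxa by input order) and reruns with
identical config are byte-identical.

## Known limitations

* Shared-event homology is exact-boundary identity (slop 0) by default;
  real aligner output can scatter one biological event across slightly
  different intervals, which this will split. The culling rules are stated
  formalizations of manual curation practice, not a reproduction of any
  particular curator's protocol.
* Mechanism calls are qualitative (longest exact repeat), not
  probabilistic; hairpin-mediated deletion classes and mechanism inference
  for insertions without reference context are out of scope.
* Dollo parsimony — arguably natural for deletions — is not implemented;
  classification uses unordered two-state parsimony.
* IR detection assumes exact copies; a plastome with diverged IR copies
  (or none) yields only length and %AT, with the partition reported
  missing.
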