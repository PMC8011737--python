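# Methods

## Scope and model

`prokannot` implements similarity-driven structural and functional
annotation of prokaryotic genomes: open-reading-frame delimitation, transfer
of product names, gene acronyms and ontology payload from a protein
reference database, automatic start-site refinement, overlap resolution, and
pre-curation filtering, with EMBL as the exchange format. The underlying
model is deliberately simple: a gene is an in-frame start-to-stop span whose
translation aligns well to a known protein. No coding statistics (hexamer
models, GC skew), no ribosome-binding-site detection, and no
covariance-model RNA search are used; those are explicit non-goals.

All internal coordinates are 0-based, half-open, on the forward strand, for
both strands; EMBL/GenBank's 1-based inclusive `complement()` convention
exists only at (de)serialization. An ORF interval includes its stop codon.

## ORF delimitation

A single left-to-right pass drives six finite-state machines, one per frame.
Forward frames segment the contig at stop codons; an ORF opens at the first
start codon of a segment. Reverse frames are handled in the same pass by
observing that right-to-left reading order shows the scanner the stop first
and the start last, so the machine tracks the most recent reverse-strand
start codon and emits when the next reverse stop (or the contig end)
arrives.

Two rules refine delimitation:

* **Methionine preference.** An ORF opened by an alternative (Val/Leu) start
  is moved to the first in-frame ATG when the ATG-to-stop coding span still
  reaches the minimum length. (The promotion condition is read as *at least*
  the minimum; the opposite reading would promote only starts that violate
  the global length floor, which would be self-contradictory.)
* **Minimum length.** ORFs whose coding span — start through the last sense
  codon, stop excluded — is under `min_orf_nt` (default 60 nt) are
  discarded, i.e. the full interval including the stop is at least 63 nt.

The default start-codon set is {ATG, GTG, TTG, CTG}: ATG plus the common
bacterial Val/Leu starts. The full Val/Leu codon sets are available via
configuration (`start_codons: full_val_leu`), and the codon table is
selectable by NCBI table number (default 11). Codons containing N are
opaque: never a start, never a stop, translated as X. Nested ORFs sharing a
stop are not enumerated separately — one ORF per stop segment; alternative
starts are revisited by the resize step.

## Scoring

Two metrics drive every downstream decision; both are stored as fractions
in [0, 1] and rendered as percentages only at reporting boundaries.

**Accuracy**: `ACC = ID · (ML/SL) · (ML/OL)`, with identity `ID`, match
(aligned) length `ML`, subject length `SL` and ORF length `OL`, all length
terms in amino acids. `OL` counts codons excluding the stop, the only unit
choice under which `ACC = ID` holds at full mutual coverage. For gapped
alignments `ML` is the alignment column count and the gapless span-equality
constraint relaxes to "both aligned spans ≤ ML".

**Similarity**: `S = (L − D)/L` for equal-length strings with Levenshtein
distance `D` (computed with edlib; an independent quadratic-DP oracle backs
it in the tests). Unequal lengths are a domain error by design — the tool
compares only equal-length tails.

## Similarity search

Search is a pluggable provider. The default provider aligns the translated
ORF against every database protein with Smith–Waterman local alignment
(BLOSUM62, affine gap open 11 / extend 1 — blast-family conventions),
keeping the best alignment per protein; identity is matches over alignment
columns, entries below `min_identity` (default 0.3) are dropped, and ties
break by (identity desc, subject length asc, entry id asc). Searching
protein space in the ORF's own frame is equivalent to a frame-restricted
translated search, which is what the identity/coordinate model describes. A
deterministic fixture provider (exact query lookup) scripts engine tests. A
remote or external-binary backend can be slotted in through the same
contract but is never required.

Caveat for practitioners: a *local* aligner will find short high-identity
segments between unrelated proteins. With the permissive default
`min_identity`, "no homolog in the database" manifests as a low-accuracy
hit rather than an empty hit list; raise `search.min_identity` (or rely on
the low-accuracy filter) when that distinction matters.

## Start-site resizing

When the best entry's subject is entirely matched but lengths disagree, the
start (never the stop) is moved:

* **Shrink** (`OL > SL`, `ML = SL`): among in-frame start codons downstream
  of the current start, choose the one minimizing `|new OL − SL|`, provided
  it does not cut into the aligned query span and keeps the minimum length.
  Ties prefer the longer ORF, then the smaller coordinate (conservative:
  keep more sequence).
* **Extend** (`OL < SL`, `ML = OL`): search upstream start codons within
  `SL − OL + 10` codons (the 10-codon slack bounds the search and keeps it
  deterministic). A candidate is accepted only if the new length is closer
  to `SL`, the extension contains no in-frame stop, and its translation
  scores `S ≥ tail_similarity_min` (default 0.90) against the unmatched
  subject region directly upstream (5') of the matched span. When the match
  is subject-suffix-anchored — the generic geometry — that region is
  exactly the subject prefix. The `compare_region="downstream"` argument of
  the extend operation switches to the region after the match. The
  similarity gate deliberately replaces a re-search.

A similarity-validated extension is folded into the match itself (`ML` grows
by the extension length), so the entry's accuracy reflects the validated
alignment; candidates re-expressed after *another* entry's resize only have
their coordinates shifted, never their match grown, because no validation
was performed for them.

Disagreeing stop positions are only flagged (`unmatched_stop` in the
qualifiers); no automatic stop adjustment is ever attempted.

## Annotation engine

Candidate ORFs wait in a queue ordered by decreasing nucleotide length. The
loop: pop the head; if not yet searched, search it, score every entry with
its eventual resized length, select the best entry by ordered criteria —
(i) survivors within `tolerance` (default 0.02) of the maximum accuracy,
(ii) gene-bearing over gene-less, (iii) named product over hypothetical
("hypothetical" = product name matching /hypothetical|uncharacterized/,
case-insensitive), (iv) higher accuracy, (v) shorter match, (vi) input
order — and apply that entry's resize. If the resize made the ORF shorter
than the new queue head, reinsert it by length, keeping its results (an ORF
is never searched twice); otherwise clean overlaps immediately.

An ORF whose best entry is hypothetical or scores below
`borf_min_accuracy` (default 0.90) is confirmed as-is but does not clean
its neighbourhood, so overlapping ORFs are still searched in their own
turn. Otherwise, for every queued ORF overlapping the confirmed one by at
least `min_overlap_nt` (default 4 — overlaps of ≤ 3 nt are routine
stop/start sharing in prokaryotes):

* already searched with accuracy < `oorf_remove_accuracy` (0.80): removed;
* never searched, same-direction with the confirmed stop upstream of the
  overlapper's stop, or head-to-head with compatible stop ordering: the
  overlapper is truncated to the first in-frame start codon clearing the
  overlap — scanning from the confirmed ORF's boundary toward the
  overlapper's stop, i.e. preserving as much of the overlapper as possible
  — or removed when no start exists or the remainder is under the minimum
  length;
* otherwise, an overlap exceeding `overlap_fraction_max` (0.50) of the
  overlapper's length removes it.

Provider failures park the ORF in an `unresolved` list and processing
continues. ORFs with zero hits are dropped in de-novo mode and retained
with a `no_hit` flag in re-annotation mode, where imported coordinates are
authoritative. Termination is guaranteed: every iteration confirms or
removes the head, flips it candidate→searched at most once, or strictly
shortens a truncated overlapper.

## Pre-curation filters

Fixed order: low-accuracy → overlap → intergenic reduction.

1. **Low accuracy**: drop features below `low_accuracy_cutoff` (default
   0.80).
2. **Overlap, step 1**: for each overlapping pair, try swapping either
   member (greedily, one at a time) to an alternative entry with a shorter
   subject whose post-resize accuracy stays within `tolerance` of the
   member's best, when the shrink dissolves the overlap without creating
   another. **Step 2**: remove one member by ordered criteria — accuracy
   difference beyond `tolerance` (the lower goes), gene acronym beats none,
   characterized beats uncharacterized — and finally an uncharacterized
   feature overlapping two or more others is removed. Anything still
   overlapping is flagged `overlap_unresolved`, never silently kept-and-
   hidden. (The step-2 accuracy criterion is stated here in the only
   reading that makes it discriminative: remove the weaker member when the
   gap *exceeds* the tolerance.)
3. **Intergenic reduction**: swap a feature to an equivalent-class
   alternative (same gene-bearing and hypothetical status, post-resize
   accuracy within `tolerance`) with a longer subject when the validated
   extension shrinks the flanking gaps without creating any overlap. Total
   intergenic length is non-increasing and the overlap count unchanged.

## RNA annotation

tRNA/rRNA features come from plain local alignment of user-supplied
reference sequences (FASTA with a `kind=` header tag) against both strands
(match 2 / mismatch −3 / gap −5,−2), gated by identity ≥ 0.9 over ≥ 0.9 of
the reference; multiple copies are found by masking accepted intervals and
re-aligning (bounded at 16 copies per reference). RNA features bypass CDS
overlap cleaning and are merged at export. Covariance models, anticodon
calling and pseudo-gene classification are out of scope.

## Synthetic fixtures

The generator produces the conditions the tests measure: a reference
database of random proteins (length 100–300 aa, half carrying gene
acronyms, 20% named "hypothetical protein") and a genome in which a chosen
subset is planted — back-translated with uniform random synonymous codons,
random strand, separated by random 60–200 nt spacers, with an optional
per-residue nonsynonymous mutation rate for identity-gradient experiments.
Spacers are scrubbed post-hoc: accidental ORFs that are neither planted
genes nor their in-frame upstream extensions are broken by writing an
in-frame stop at a spacer position (iterated to a fixed point, bounded at
60 rounds). Reverse-strand "shadow" ORFs inside genes cannot be patched
without touching gene bases and are left in place; the pipeline is expected
to discard them, and recovery tests confirm that it does. Opposite-strand
decoys overlapping a gene head can be planted on request; infeasible
geometries (no workable reverse start codon on the gene's own bases) raise
a domain error rather than silently degrading the truth.

What the generator does **not** emulate: real codon usage, GC content,
operon structure, pseudogenes, frameshifts, or homologous gene families
(every planted gene has exactly one true database entry). Passing recovery
tests therefore demonstrates the correctness of the machinery — exact
coordinate recovery, scoring, overlap resolution — not annotation quality
on real genomes, where paralogy and divergence dominate.

## Numerical and design choices

* Problem sizes in the test suite and acceptance script (30-gene recovery
  genomes, 100 × 2 kb oracle sequences, 500 resize fixtures, 1000
  similarity pairs) keep a full run in seconds on one CPU while exercising
  every code path; they are the package's default study conditions, all
  reproducible from a single seed.
* Thresholds default to: tolerance 0.02, engine gate 0.90, overlapper
  removal 0.80, tail similarity 0.90, overlap fraction 0.50, low-accuracy
  cutoff 0.80, minimum ORF 60 nt, minimum counted overlap 4 nt.
* Circular topology is carried through I/O but features never span the
  origin; contigs are treated as linear for ORF scanning. `join()`
  locations are rejected, not flattened — explicit failure beats silent
  corruption of the single-exon CDS model.
* Determinism everywhere: fixed tie-breaks in entry ranking and resize,
  sorted queue insertion, seeded generators. Two runs on identical inputs
  produce byte-identical EMBL output.

## Known limitations

* The local-alignment provider is O(|query| · Σ|subjects|) per ORF; for
  real genomes against large databases an external search backend behind
  the provider contract is the practical route.
* Re-annotation skips CDS with lengths not divisible by 3 (with a warning)
  rather than attempting frameshift repair.
* The overlap filter's step-1 swap is greedy and one-member-at-a-time; a
  pair that could only be dissolved by swapping both members simultaneously
  falls through to step 2.
* Hypothetical-product detection is lexical; databases with unusual naming
  conventions may need the pattern adjusted.
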