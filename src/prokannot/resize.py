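"""Automatic start-site resizing against the selected database subject.

When the best hit's subject is fully matched but the query and subject
lengths disagree, the start site (never the stop) is moved to an alternative
in-frame start codon:

* shrink — query longer than subject: choose the downstream start codon whose
  resulting ORF length is closest to the subject length, without cutting into
  the aligned query span or dropping below the minimum ORF length;
* extend — query shorter than subject: choose an upstream start codon, but
  only when the translated extension has a Levenshtein similarity of at least
  ``tail_similarity_min`` against the corresponding unmatched subject region
  and contains no in-frame stop. Re-running the search is deliberately
  avoided: the similarity gate stands in for it.

When the query and subject stops disagree nothing is changed automatically;
:func:`flag_unmatched_stop` only marks the ORF for curation.
"""

from __future__ import annotations

from dataclasses import replace

from .genetics import GeneticCode, revcomp
from .orfs import Orf, orf_len_aa
from .scoring import HitEntry, Thresholds, similarity_score
from .seqio import GenomeRecord

#: codons searched upstream beyond the SL - OL deficit during extension
EXTEND_SLACK_CODONS = 10


def _start_codon_at(seq: str, pos: int, strand: str, code: GeneticCode) -> bool:
    codon = seq[pos : pos + 3]
    if len(codon) < 3:
        return False
    if strand == "-":
        codon = revcomp(codon)
    return code.is_start(codon)


def _stop_codon_at(seq: str, pos: int, strand: str, code: GeneticCode) -> bool:
    codon = seq[pos : pos + 3]
    if len(codon) < 3:
        return False
    if strand == "-":
        codon = revcomp(codon)
    return code.is_stop(codon)


def shrink_to_subject(
    orf: Orf,
    entry: HitEntry,
    genome: GenomeRecord,
    code: GeneticCode,
    thresholds: Thresholds,
) -> Orf:
    """Move the start downstream so the ORF length approaches the subject length.

    Applies only when the subject is entirely matched (ML = SL) and the ORF is
    longer; a no-op otherwise. The chosen start minimizes \\|new OL - SL\\|,
    preferring the longer ORF then the earlier coordinate on ties, and must
    not cut into the aligned query span.
    """
    ol, sl = orf_len_aa(orf), entry.subject_len
    if entry.ml != sl or ol <= sl:
        return orf
    seq = genome.sequence
    best: tuple | None = None  # (|diff|, -new_ol, k)
    # k = codons trimmed from the start; must stay left of the aligned span
    max_k = min(entry.start_query, ol - 1)
    for k in range(1, max_k + 1):
        new_ol = ol - k
        if new_ol * 3 < thresholds.min_orf_nt:
            break
        if orf.strand == "+":
            pos = orf.start + 3 * k
        else:
            pos = orf.end - 3 * k - 3
        if not _start_codon_at(seq, pos, orf.strand, code):
            continue
        key = (abs(new_ol - sl), -new_ol, k)
        if best is None or key < best:
            best = key
    if best is None:
        return orf
    k = best[2]
    if orf.strand == "+":
        return replace(orf, start=orf.start + 3 * k)
    return replace(orf, end=orf.end - 3 * k)


def _extension_translation(
    orf: Orf, genome: GenomeRecord, code: GeneticCode, k: int
) -> str | None:
    """Translate the k-codon upstream extension; None if it contains a stop."""
    seq = genome.sequence
    if orf.strand == "+":
        region = seq[orf.start - 3 * k : orf.start]
    else:
        region = revcomp(seq[orf.end : orf.end + 3 * k])
    aa = []
    for i in range(k):
        codon = region[3 * i : 3 * i + 3]
        if code.is_stop(codon):
            return None
        aa.append(code.translate_codon(codon))
    return "".join(aa)


def extend_to_subject(
    orf: Orf,
    entry: HitEntry,
    genome: GenomeRecord,
    code: GeneticCode,
    thresholds: Thresholds,
    compare_region: str = "upstream",
) -> Orf:
    """Move the start upstream so the ORF length approaches the subject length.

    Applies only when the query is entirely matched (ML = OL) and the subject
    is longer. A candidate start is accepted iff the new length is closer to
    SL, the extension contains no in-frame stop, and its translation scores at
    least ``tail_similarity_min`` against the unmatched subject region
    adjacent to the match (upstream of it by default; ``compare_region=
    "downstream"`` compares against the region after the match instead).
    """
    ol, sl = orf_len_aa(orf), entry.subject_len
    if entry.ml != ol or ol >= sl:
        return orf
    seq = genome.sequence
    best: tuple | None = None  # (|diff|, -new_ol, k)
    for k in range(1, sl - ol + EXTEND_SLACK_CODONS + 1):
        new_ol = ol + k
        if abs(new_ol - sl) >= abs(ol - sl):
            continue
        if orf.strand == "+":
            pos = orf.start - 3 * k
            if pos < 0:
                break
        else:
            pos = orf.end + 3 * k - 3
            if pos + 3 > len(seq):
                break
        if not _start_codon_at(seq, pos, orf.strand, code):
            continue
        ext = _extension_translation(orf, genome, code, k)
        if ext is None:
            continue
        if compare_region == "upstream":
            if entry.start_match < k:
                continue
            sub = entry.subject_seq[entry.start_match - k : entry.start_match]
        else:
            if entry.end_match + k > sl:
                continue
            sub = entry.subject_seq[entry.end_match : entry.end_match + k]
        if similarity_score(ext, sub) < thresholds.tail_similarity_min:
            continue
        key = (abs(new_ol - sl), -new_ol, k)
        if best is None or key < best:
            best = key
    if best is None:
        return orf
    k = best[2]
    if orf.strand == "+":
        return replace(orf, start=orf.start - 3 * k)
    return replace(orf, end=orf.end + 3 * k)


def resize_to_subject(
    orf: Orf,
    entry: HitEntry,
    genome: GenomeRecord,
    code: GeneticCode,
    thresholds: Thresholds,
    compare_region: str = "upstream",
) -> Orf:
    """Dispatch to shrink or extend as the length relation dictates."""
    ol, sl = orf_len_aa(orf), entry.subject_len
    if ol > sl:
        return shrink_to_subject(orf, entry, genome, code, thresholds)
    if ol < sl:
        return extend_to_subject(
            orf, entry, genome, code, thresholds, compare_region=compare_region
        )
    return orf


def shifted_entry(entry: HitEntry, delta_codons: int, new_orf_len: int) -> HitEntry:
    """Re-express query coordinates after the start moved by ``delta_codons``.

    Positive delta = start moved downstream (query shortened); negative =
    upstream extension. The match span is left untouched; the accuracy is
    recomputed for the new ORF length.
    """
    e = replace(
        entry,
        start_query=entry.start_query - delta_codons,
        end_query=entry.end_query - delta_codons,
    )
    return e.with_accuracy(new_orf_len)


def extended_entry(entry: HitEntry, k_codons: int, new_orf_len: int) -> HitEntry:
    """Fold a similarity-validated k-codon extension into the match itself.

    The extension was checked against the subject region directly upstream of
    the match, so both the matched subject span and the matched query span
    grow by k without re-running the search.
    """
    if entry.start_match < k_codons:
        return shifted_entry(entry, -k_codons, new_orf_len)
    e = replace(
        entry,
        start_match=entry.start_match - k_codons,
        end_query=entry.end_query + k_codons,
        match_len=None if entry.match_len is None else entry.match_len + k_codons,
    )
    return e.with_accuracy(new_orf_len)


def adjusted_entry(entry: HitEntry, old_len_aa: int, new_orf: Orf) -> HitEntry:
    """Entry re-expressed after this entry's own resize of the ORF."""
    new_len = orf_len_aa(new_orf)
    delta = old_len_aa - new_len
    if delta < 0:
        return extended_entry(entry, -delta, new_len)
    return shifted_entry(entry, delta, new_len) if delta else entry.with_accuracy(new_len)


def flag_unmatched_stop(orf: Orf, entry: HitEntry) -> bool:
    """True iff the query and subject stop positions disagree.

    Either the query runs past the matched subject end, or the subject runs
    past the matched query end. No coordinate is ever changed.
    """
    ol = orf_len_aa(orf)
    return entry.end_query != ol or entry.end_match != entry.subject_len
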