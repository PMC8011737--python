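"""The optimized annotation strategy.

Candidate ORFs wait in a queue ordered by decreasing length. The head is
searched against the database, every entry is scored with its eventual resized
length, the best entry is selected and the resize applied. If the resize made
the ORF shorter than the new queue head it is reinserted by length (keeping
its results — it is never searched twice); otherwise overlap cleaning starts
immediately. An ORF whose best entry is hypothetical or scores below the
accuracy gate is confirmed as-is and does not clean its neighbours, so they
will be searched in their own turn.

Overlap cleaning removes or truncates never-searched ORFs overlapping a
confirmed, characterized, high-accuracy ORF ("BORF"): already-searched
overlappers below the removal accuracy are dropped; otherwise the geometric
cases pick a new start codon clearing the overlap (same-direction stop
ordering, or the two head-to-head configurations), and failing those, an
overlap exceeding half the overlapper's length removes it.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

from .errors import DomainError
from .genetics import GeneticCode
from .orfs import Orf, orf_len_aa, translate
from .resize import (
    adjusted_entry,
    flag_unmatched_stop,
    resize_to_subject,
    shifted_entry,
)
from .scoring import HitEntry, Thresholds
from .search import SearchProvider
from .seqio import FeatureKind, FeatureRecord, GenomeRecord

logger = logging.getLogger(__name__)


@dataclass
class AnnotatedFeature:
    """A confirmed ORF bound to its selected entry and candidate list."""

    orf: Orf
    entry: Optional[HitEntry]
    candidates: list = field(default_factory=list)
    flags: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return self.entry.accuracy if self.entry and self.entry.accuracy else 0.0

    @property
    def is_hypothetical(self) -> bool:
        return self.entry is None or self.entry.is_hypothetical

    @property
    def has_gene(self) -> bool:
        return self.entry is not None and self.entry.has_gene

    def to_feature_record(self) -> FeatureRecord:
        quals: dict = {}
        if self.entry is not None:
            quals["product"] = self.entry.product_name
            if self.entry.gene_name:
                quals["gene"] = self.entry.gene_name
            if self.entry.ec_numbers:
                quals["EC_number"] = list(self.entry.ec_numbers)
            xrefs = [gid for gid, _ in self.entry.go_terms]
            xrefs += [f"KEGG:{k}" for k in self.entry.kegg_pathways]
            if xrefs:
                quals["db_xref"] = xrefs
            note = f"accuracy={100 * self.accuracy:.2f};entry={self.entry.entry_id}"
        else:
            quals["product"] = "hypothetical protein"
            note = "accuracy=0.00"
        flags = [k for k, v in sorted(self.flags.items()) if v]
        if flags:
            note += ";" + ";".join(flags)
        quals["note"] = note
        return FeatureRecord(
            kind=FeatureKind.CDS,
            contig_id=self.orf.contig_id,
            start=self.orf.start,
            end=self.orf.end,
            strand=self.orf.strand,
            qualifiers=quals,
        )


@dataclass
class AnnotationState:
    """Working state of one annotation run.

    Every ORF is in exactly one of queue / confirmed / removed / unresolved.
    The queue is kept sorted by decreasing nt length.
    """

    queue: list[Orf] = field(default_factory=list)
    confirmed: list[AnnotatedFeature] = field(default_factory=list)
    removed: list[Orf] = field(default_factory=list)
    unresolved: list[Orf] = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds)
    provider: Optional[SearchProvider] = None
    max_hits: int = 10
    retain_no_hit: bool = False

    @classmethod
    def from_orfs(cls, orfs: list[Orf], provider: SearchProvider, **kw) -> "AnnotationState":
        state = cls(provider=provider, **kw)
        state.queue = sorted(orfs, key=lambda o: (-o.length, o.contig_id, o.start))
        return state

    def reinsert(self, orf: Orf) -> None:
        keys = [-o.length for o in self.queue]
        self.queue.insert(bisect.bisect_right(keys, -orf.length), orf)


def select_best_entry(entries: list[HitEntry], thresholds: Thresholds) -> HitEntry:
    """Rank entries and return the winner.

    Criteria, in order: (i) only entries within Tolerance of the highest
    accuracy survive; (ii) gene-bearing beats gene-less; (iii) named product
    beats hypothetical; (iv) higher accuracy; (v) shorter matching sequence;
    (vi) first in input order.
    """
    if not entries:
        raise DomainError("select_best_entry: empty entry list")
    for e in entries:
        if e.accuracy is None:
            raise DomainError(f"entry {e.entry_id} has no accuracy")
    max_acc = max(e.accuracy for e in entries)
    pool = [e for e in entries if e.accuracy >= max_acc - thresholds.tolerance]
    if any(e.has_gene for e in pool):
        pool = [e for e in pool if e.has_gene]
    elif any(not e.is_hypothetical for e in pool):
        pool = [e for e in pool if not e.is_hypothetical]
    order = {id(e): i for i, e in enumerate(entries)}
    return min(pool, key=lambda e: (-e.accuracy, e.ml, order[id(e)]))


def _evaluate_entries(
    orf: Orf,
    hits: list[HitEntry],
    genome: GenomeRecord,
    code: GeneticCode,
    thresholds: Thresholds,
) -> tuple[list[HitEntry], dict[str, Orf]]:
    """Score every entry with its eventual resized ORF length."""
    scored: list[HitEntry] = []
    resized: dict[str, Orf] = {}
    for e in hits:
        new_orf = resize_to_subject(orf, e, genome, code, thresholds)
        scored.append(adjusted_entry(e, orf_len_aa(orf), new_orf))
        resized[e.entry_id] = new_orf
    return scored, resized


def _first_start_scan(
    genome: GenomeRecord,
    code: GeneticCode,
    strand: str,
    anchor_frame_pos: int,
    lo: int,
    hi: int,
    from_high: bool,
) -> Optional[int]:
    """First in-frame start-codon position in [lo, hi), scanning from the
    given end; positions are congruent to anchor_frame_pos mod 3."""
    from .resize import _start_codon_at

    first = lo + ((anchor_frame_pos - lo) % 3)
    positions = range(first, hi - 2, 3)
    if from_high:
        positions = reversed(positions)
    for p in positions:
        if _start_codon_at(genome.sequence, p, strand, code):
            return p
    return None


def clean_overlaps(
    borf: Orf,
    state: AnnotationState,
    genomes: Mapping[str, GenomeRecord],
    code: GeneticCode,
) -> None:
    """Resolve queued ORFs overlapping a confirmed high-accuracy BORF.

    Mutates ``state``: overlappers are removed, or truncated to a start codon
    clearing the overlap and reinserted by their new length.
    """
    th = state.thresholds
    genome = genomes[borf.contig_id]
    survivors: list[Orf] = []
    changed: list[Orf] = []
    for oorf in state.queue:
        ov = borf.overlap_nt(oorf)
        if ov < th.min_overlap_nt:
            survivors.append(oorf)
            continue
        if oorf.status == "blasted":
            acc = oorf.selected_entry.accuracy if oorf.selected_entry else 0.0
            if acc < th.oorf_remove_accuracy:
                oorf.status = "removed"
                oorf.qualifiers["removed_reason"] = "overlap_low_accuracy"
                state.removed.append(oorf)
            else:
                survivors.append(oorf)
            continue
        new_orf = _geometric_truncation(borf, oorf, genome, code, th)
        if new_orf is oorf:  # no geometric case applied
            if ov / oorf.length > th.overlap_fraction_max:
                oorf.status = "removed"
                oorf.qualifiers["removed_reason"] = "overlap_fraction"
                state.removed.append(oorf)
            else:
                survivors.append(oorf)
        elif new_orf is None:
            oorf.status = "removed"
            oorf.qualifiers["removed_reason"] = "overlap_no_start"
            state.removed.append(oorf)
        else:
            changed.append(new_orf)
    state.queue = survivors
    for orf in changed:
        state.reinsert(orf)


def _geometric_truncation(
    borf: Orf,
    oorf: Orf,
    genome: GenomeRecord,
    code: GeneticCode,
    th: Thresholds,
) -> Optional[Orf]:
    """Apply the geometric overlap case matching (borf, oorf).

    Returns the truncated ORF, None when the case applies but no start codon
    is available (remove), or ``oorf`` itself when no case matches.
    """

    def check_min(new_orf: Orf) -> Optional[Orf]:
        if new_orf.length - 3 < th.min_orf_nt:
            return None
        return new_orf

    if borf.strand == "+" and oorf.strand == "+" and borf.end < oorf.end:
        # same direction, BORF stop first: restart OORF beyond the BORF stop
        p = _first_start_scan(
            genome, code, "+", oorf.start, borf.end, oorf.end - 3, from_high=False
        )
        if p is None:
            return None
        return check_min(replace(oorf, start=p))
    if borf.strand == "-" and oorf.strand == "-" and oorf.start < borf.start:
        # same direction (reverse), OORF stop first: new start left of BORF stop
        p = _first_start_scan(
            genome, code, "-", oorf.end - 3, oorf.start + 3, borf.start, from_high=True
        )
        if p is None:
            return None
        return check_min(replace(oorf, end=p + 3))
    if borf.strand == "+" and oorf.strand == "-" and oorf.start < borf.start:
        # head-to-head: OORF stop before BORF start
        p = _first_start_scan(
            genome, code, "-", oorf.end - 3, oorf.start + 3, borf.start, from_high=True
        )
        if p is None:
            return None
        return check_min(replace(oorf, end=p + 3))
    if borf.strand == "-" and oorf.strand == "+" and oorf.start > borf.start:
        # head-to-head: OORF start after BORF stop
        p = _first_start_scan(
            genome, code, "+", oorf.start, borf.end, oorf.end - 3, from_high=False
        )
        if p is None:
            return None
        return check_min(replace(oorf, start=p))
    return oorf


def process_queue(
    state: AnnotationState,
    genomes: Mapping[str, GenomeRecord],
    code: GeneticCode,
) -> AnnotationState:
    """Run the queue to exhaustion; every ORF ends confirmed or removed."""
    th = state.thresholds
    while state.queue:
        orf = state.queue.pop(0)
        genome = genomes[orf.contig_id]
        if orf.status != "blasted":
            try:
                hits = state.provider.search(translate(orf, genome, code), state.max_hits)
            except Exception as exc:  # provider failure: keep going
                logger.warning("search failed for ORF %s:%d-%d: %s",
                               orf.contig_id, orf.start, orf.end, exc)
                orf.qualifiers["unresolved"] = str(exc)
                state.unresolved.append(orf)
                continue
            if not hits:
                if state.retain_no_hit:
                    orf.status = "confirmed"
                    state.confirmed.append(
                        AnnotatedFeature(orf, None, [], flags={"no_hit": True})
                    )
                else:
                    orf.status = "removed"
                    orf.qualifiers["removed_reason"] = "no_hit"
                    state.removed.append(orf)
                continue
            scored, resized = _evaluate_entries(orf, hits, genome, code, th)
            best = select_best_entry(scored, th)
            new_orf = resized[best.entry_id]
            delta = orf_len_aa(orf) - orf_len_aa(new_orf)
            # re-express every candidate on the chosen resized ORF (the best
            # entry already is); drop candidates the resize cut out entirely
            final_candidates: list[HitEntry] = []
            for e in hits:
                if e.entry_id == best.entry_id:
                    final_candidates.append(best)
                    continue
                try:
                    final_candidates.append(
                        shifted_entry(e, delta, orf_len_aa(new_orf))
                    )
                except DomainError:
                    pass
            orf = replace(new_orf, status="blasted", selected_entry=best,
                          candidates=final_candidates,
                          qualifiers=dict(orf.qualifiers))
            if flag_unmatched_stop(orf, best):
                orf.qualifiers["unmatched_stop"] = True
            if state.queue and orf.length < state.queue[0].length:
                state.reinsert(orf)
                continue
        best = orf.selected_entry
        orf.status = "confirmed"
        feature = AnnotatedFeature(
            orf,
            best,
            orf.candidates,
            flags={k: True for k in ("unmatched_stop",) if orf.qualifiers.get(k)},
        )
        state.confirmed.append(feature)
        if best.is_hypothetical or (best.accuracy or 0.0) < th.borf_min_accuracy:
            continue  # leave overlappers queued; they get searched themselves
        clean_overlaps(orf, state, genomes, code)
    return state
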