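"""Six-frame ORF prediction.

A single left-to-right pass over the contig drives six finite-state machines,
one per frame. On the forward strand a frame segment runs from one stop codon
to the next; the ORF opens at the first start codon of the segment and closes
at the terminating stop. On the reverse strand the reading direction is
right-to-left, so the scan sees the stop first and the start last: the machine
remembers the most recent reverse-strand start codon and closes the segment
when the next reverse-strand stop (or the end of the contig) arrives.

Two delimitation rules apply:

* methionine preference — an ORF opened by a valine/leucine start is moved to
  the first in-frame ATG when the ATG-to-stop coding span still reaches the
  minimum length;
* minimum length — ORFs whose coding span (start through last sense codon,
  stop excluded) is shorter than ``min_len_nt`` are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Optional

from .errors import IntegrityError
from .genetics import GeneticCode, revcomp
from .seqio import GenomeRecord

if TYPE_CHECKING:  # pragma: no cover
    from .scoring import HitEntry

DEFAULT_MIN_LEN_NT = 60


@dataclass
class Orf:
    """A candidate or confirmed coding interval.

    ``start``/``end`` are 0-based half-open forward-strand coordinates; the
    interval includes the stop codon. ``frame`` is the reading offset relative
    to the ORF's own strand (0/1/2).
    """

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    status: str = "candidate"  # candidate | blasted | confirmed | removed
    selected_entry: Optional["HitEntry"] = None
    candidates: list = field(default_factory=list)
    qualifiers: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        """Interval length in nt, stop codon included."""
        return self.end - self.start

    @property
    def stop_coordinate(self) -> int:
        """Forward coordinate anchoring the stop codon (never moved by resize)."""
        return self.end if self.strand == "+" else self.start

    def coding_seq(self, genome: GenomeRecord) -> str:
        """Nucleotides in reading order, stop codon included."""
        s = genome.sequence[self.start : self.end]
        return s if self.strand == "+" else revcomp(s)

    def overlap_nt(self, other: "Orf") -> int:
        if self.contig_id != other.contig_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _coding_ok(span_excl_stop: int, min_len_nt: int) -> bool:
    return span_excl_stop >= min_len_nt


def find_orfs(
    genome: GenomeRecord, code: GeneticCode, min_len_nt: int = DEFAULT_MIN_LEN_NT
) -> list[Orf]:
    """All qualifying ORFs in the six frames of one contig, sorted by start.

    Codons containing N never open or close an ORF. Contigs shorter than 6 nt
    yield an empty list.
    """
    seq = genome.sequence
    n = len(seq)
    orfs: list[Orf] = []
    if n < 6:
        return orfs

    rc_starts = {revcomp(c) for c in code.start_codons}
    rc_stops = {revcomp(c) for c in code.stop_codons}
    rc_met = revcomp("ATG")

    # forward FSM state per frame: first start / first ATG since last stop
    f_start: list[Optional[int]] = [None, None, None]
    f_atg: list[Optional[int]] = [None, None, None]
    # reverse FSM state per frame (indexed by position % 3): position of the
    # most recent reverse stop, and last (rightmost) reverse start / ATG since
    r_stop: list[Optional[int]] = [None, None, None]
    r_start: list[Optional[int]] = [None, None, None]
    r_atg: list[Optional[int]] = [None, None, None]

    def emit_forward(fr: int, stop_pos: int) -> None:
        start = f_start[fr]
        if start is None:
            return
        chosen = start
        if seq[start : start + 3] != "ATG":
            atg = f_atg[fr]
            if atg is not None and _coding_ok(stop_pos - atg, min_len_nt):
                chosen = atg
        if _coding_ok(stop_pos - chosen, min_len_nt):
            orfs.append(
                Orf(genome.id, chosen, stop_pos + 3, "+", chosen % 3)
            )

    def emit_reverse(fr: int, next_stop: Optional[int]) -> None:
        stop = r_stop[fr]
        start = r_start[fr]
        if stop is None or start is None or start <= stop:
            return
        chosen = start
        if seq[start : start + 3] != rc_met:
            atg = r_atg[fr]
            if atg is not None and stop < atg and _coding_ok(atg - stop, min_len_nt):
                chosen = atg
        if _coding_ok(chosen - stop, min_len_nt):
            end = chosen + 3
            orfs.append(Orf(genome.id, stop, end, "-", (n - end) % 3))

    for i in range(n - 2):
        codon = seq[i : i + 3]
        fr = i % 3
        # forward strand
        if codon in code.stop_codons:
            emit_forward(fr, i)
            f_start[fr] = None
            f_atg[fr] = None
        elif f_start[fr] is None and codon in code.start_codons:
            f_start[fr] = i
            if codon == "ATG":
                f_atg[fr] = i
        elif f_atg[fr] is None and codon == "ATG" and f_start[fr] is not None:
            f_atg[fr] = i
        # reverse strand (reading right-to-left: stop seen first, start last)
        if codon in rc_stops:
            emit_reverse(fr, i)
            r_stop[fr] = i
            r_start[fr] = None
            r_atg[fr] = None
        elif r_stop[fr] is not None and codon in rc_starts:
            r_start[fr] = i
            if codon == rc_met:
                r_atg[fr] = i

    for fr in range(3):
        emit_reverse(fr, None)

    orfs.sort(key=lambda o: (o.contig_id, o.start, o.end, o.strand))
    return orfs


def _inframe_positions(orf: Orf, genome: GenomeRecord):
    """(forward_position, codon_in_reading_order) for every codon of the ORF."""
    seq = genome.sequence
    if orf.strand == "+":
        for p in range(orf.start, orf.end - 2, 3):
            yield p, seq[p : p + 3]
    else:
        for e in range(orf.end, orf.start + 2, -3):
            yield e - 3, revcomp(seq[e - 3 : e])


def apply_met_preference(
    orf: Orf,
    genome: GenomeRecord,
    code: GeneticCode,
    min_len_nt: int = DEFAULT_MIN_LEN_NT,
) -> Orf:
    """Move a Val/Leu-started ORF to its first in-frame ATG when long enough.

    The move happens only if the ATG-to-stop coding span is at least
    ``min_len_nt``. Idempotent: an ORF already starting with ATG is returned
    unchanged.
    """
    first = orf.coding_seq(genome)[:3]
    if first == "ATG":
        return orf
    for pos, codon in _inframe_positions(orf, genome):
        if codon != "ATG":
            continue
        if orf.strand == "+":
            if _coding_ok((orf.end - 3) - pos, min_len_nt):
                return replace(orf, start=pos)
        else:
            if _coding_ok(pos - orf.start, min_len_nt):
                return replace(orf, end=pos + 3)
        return orf  # first ATG too close to the stop
    return orf


def translate(orf: Orf, genome: GenomeRecord, code: GeneticCode) -> str:
    """Amino-acid sequence of the ORF, stop excluded, no forced leading M."""
    cds = orf.coding_seq(genome)
    if len(cds) % 3 != 0:
        raise IntegrityError(
            f"ORF [{orf.start},{orf.end}) length {len(cds)} not divisible by 3"
        )
    aa = []
    n_codons = len(cds) // 3
    for i in range(n_codons - 1):
        codon = cds[3 * i : 3 * i + 3]
        if code.is_stop(codon):
            raise IntegrityError(
                f"internal stop codon {codon} at codon {i} of ORF "
                f"[{orf.start},{orf.end}){orf.strand}"
            )
        aa.append(code.translate_codon(codon))
    return "".join(aa)


def orf_len_aa(orf: Orf) -> int:
    """ORF length in amino acids (codons excluding the stop)."""
    return (orf.end - orf.start) // 3 - 1
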