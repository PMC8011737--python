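"""Similarity-search providers.

The engine consumes hits through a minimal provider contract
(``search(query_aa, max_hits) -> list[HitEntry]`` sorted by descending
identity, deterministic for a fixed database). Two providers ship:

* :class:`LocalSearchProvider` — Smith–Waterman local alignment of the
  translated ORF against every database protein (BLOSUM62, affine gaps
  11/1 by default, blast-family conventions);
* :class:`FixtureSearchProvider` — an exact scripted lookup used to make
  engine behaviour fully deterministic in tests.
"""

from __future__ import annotations

from typing import Mapping, Protocol, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import DomainError
from .scoring import HitEntry
from .seqio import ReferenceProtein


class SearchProvider(Protocol):
    def search(self, query_aa: str, max_hits: int = 10) -> list[HitEntry]: ...


class LocalSearchProvider:
    """Local alignment against an in-memory protein database.

    Per protein the best local alignment is kept; identity is matches over
    alignment columns (gaps included) and the aligned spans give the query and
    subject coordinates. Hits below ``min_identity`` are dropped; ties are
    broken by (identity desc, subject length asc, entry id asc).
    """

    def __init__(
        self,
        db: Sequence[ReferenceProtein],
        matrix: str = "BLOSUM62",
        gap_open: float = 11.0,
        gap_extend: float = 1.0,
        min_identity: float = 0.3,
    ):
        if not db:
            raise DomainError("empty protein database")
        self.db = list(db)
        self.min_identity = min_identity
        self._aligner = Align.PairwiseAligner(
            mode="local",
            substitution_matrix=substitution_matrices.load(matrix),
            open_gap_score=-gap_open,
            extend_gap_score=-gap_extend,
        )

    def _best_hit(self, query: str, prot: ReferenceProtein) -> HitEntry | None:
        try:
            alignments = self._aligner.align(query, prot.sequence)
        except ValueError:
            return None  # residues outside the matrix alphabet
        if len(alignments) == 0 or alignments.score <= 0:
            return None
        aln = alignments[0]
        counts = aln.counts()
        columns = counts.identities + counts.mismatches + counts.gaps
        if columns == 0:
            return None
        identity = counts.identities / columns
        if identity < self.min_identity:
            return None
        q_blocks, s_blocks = aln.aligned
        start_q, end_q = int(q_blocks[0][0]), int(q_blocks[-1][1])
        start_s, end_s = int(s_blocks[0][0]), int(s_blocks[-1][1])
        return HitEntry(
            entry_id=prot.entry_id,
            product_id=prot.entry_id,
            product_name=prot.product_name,
            gene_name=prot.gene_name,
            organism=prot.organism,
            go_terms=list(prot.go_terms),
            kegg_pathways=list(prot.kegg_pathways),
            ec_numbers=list(prot.ec_numbers),
            subject_seq=prot.sequence,
            start_query=start_q,
            end_query=end_q,
            start_match=start_s,
            end_match=end_s,
            identity=identity,
            match_len=int(columns),
        ).with_accuracy(len(query))

    def search(self, query_aa: str, max_hits: int = 10) -> list[HitEntry]:
        if not query_aa:
            raise DomainError("empty query")
        hits = []
        for prot in self.db:
            hit = self._best_hit(query_aa, prot)
            if hit is not None:
                hits.append(hit)
        hits.sort(key=lambda h: (-h.identity, h.subject_len, h.entry_id))
        return hits[:max_hits]


class FixtureSearchProvider:
    """Deterministic scripted provider: exact query lookup, [] on miss.

    Entries are validated at table construction; an invariant-violating entry
    is rejected immediately rather than surfacing mid-run.
    """

    def __init__(self, table: Mapping[str, Sequence[HitEntry]]):
        self.table: dict[str, list[HitEntry]] = {}
        for query, entries in table.items():
            self.table[query] = [e.validate() for e in entries]

    def search(self, query_aa: str, max_hits: int = 10) -> list[HitEntry]:
        return list(self.table.get(query_aa, []))[:max_hits]
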