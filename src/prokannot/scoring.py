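"""The two decision metrics: accuracy and the Levenshtein similarity score.

Accuracy combines alignment identity with the mutual coverage of subject and
query::

    ACC = ID * (ML / SL) * (ML / OL)

with ID the identity fraction, ML the aligned (match) length, SL the subject
length and OL the ORF length, all length terms in amino acids. When the match
covers both sequences entirely (ML = SL = OL) the accuracy equals the
identity. Every fraction in this package lives in [0, 1]; percentages appear
only at reporting boundaries.

The similarity score of two equal-length strings is S = (L - D) / L with D
their Levenshtein edit distance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

import edlib

from .errors import DomainError

_HYPOTHETICAL_RE = re.compile(r"hypothetical|uncharacterized", re.IGNORECASE)


@dataclass(frozen=True)
class Thresholds:
    """Tunable decision thresholds, all fractions in [0, 1]."""

    tolerance: float = 0.02  # accuracy band around MaxAcc for entry ranking
    borf_min_accuracy: float = 0.90  # gate for an ORF to drive overlap cleaning
    oorf_remove_accuracy: float = 0.80  # blasted overlapping ORFs below this go
    tail_similarity_min: float = 0.90  # extension-tail similarity gate
    overlap_fraction_max: float = 0.50  # overlap/OORF-length removal threshold
    low_accuracy_cutoff: float = 0.80  # pre-curation accuracy filter
    min_orf_nt: int = 60  # minimum coding span, stop excluded
    min_overlap_nt: int = 4  # overlaps below this are biologically routine

    def __post_init__(self) -> None:
        for name in (
            "tolerance",
            "borf_min_accuracy",
            "oorf_remove_accuracy",
            "tail_similarity_min",
            "overlap_fraction_max",
            "low_accuracy_cutoff",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name}={v} outside [0,1]")


@dataclass
class HitEntry:
    """One similarity-search result against a reference protein.

    Query coordinates are amino-acid positions on the translated ORF, subject
    coordinates on the database protein, both 0-based half-open. For gapped
    alignments ``match_len`` holds the alignment column count; for gapless
    ones it equals both span lengths.
    """

    entry_id: str
    product_name: str
    subject_seq: str
    start_query: int
    end_query: int
    start_match: int
    end_match: int
    identity: float
    product_id: str = ""
    gene_name: Optional[str] = None
    organism: str = ""
    go_terms: list = field(default_factory=list)
    kegg_pathways: list = field(default_factory=list)
    ec_numbers: list = field(default_factory=list)
    match_len: Optional[int] = None  # alignment columns when gapped
    accuracy: Optional[float] = None

    @property
    def subject_len(self) -> int:
        return len(self.subject_seq)

    @property
    def ml(self) -> int:
        """Match length in aa (alignment columns for gapped alignments)."""
        if self.match_len is not None:
            return self.match_len
        return self.end_query - self.start_query

    @property
    def is_hypothetical(self) -> bool:
        return bool(_HYPOTHETICAL_RE.search(self.product_name))

    @property
    def has_gene(self) -> bool:
        return bool(self.gene_name)

    def validate(self) -> "HitEntry":
        """Check the structural invariants; returns self for chaining."""
        if not 0.0 <= self.identity <= 1.0:
            raise DomainError(f"identity {self.identity} outside [0,1]")
        if not self.subject_seq:
            raise DomainError("empty subject sequence")
        q_span = self.end_query - self.start_query
        m_span = self.end_match - self.start_match
        if self.start_query < 0 or self.start_match < 0 or q_span <= 0 or m_span <= 0:
            raise DomainError("degenerate alignment spans")
        if self.end_match > self.subject_len:
            raise DomainError("subject span exceeds subject length")
        if self.match_len is None:
            if q_span != m_span:
                raise DomainError(
                    f"gapless hit with unequal spans ({q_span} vs {m_span})"
                )
        else:
            if q_span > self.match_len or m_span > self.match_len:
                raise DomainError("aligned spans exceed alignment column count")
        if self.ml > self.subject_len:
            raise DomainError("match length exceeds subject length")
        return self

    def with_accuracy(self, orf_len: int) -> "HitEntry":
        return replace(self, accuracy=accuracy(self.identity, self.ml, self.subject_len, orf_len))


def accuracy(
    identity: float, match_len_aa: int, subject_len_aa: int, orf_len_aa: int
) -> float:
    """ACC = ID * (ML/SL) * (ML/OL); lies in [0, ID]."""
    if subject_len_aa <= 0 or orf_len_aa <= 0:
        raise DomainError("subject and ORF lengths must be positive")
    if not 0 < match_len_aa <= min(subject_len_aa, orf_len_aa):
        raise DomainError(
            f"match length {match_len_aa} outside (0, min(SL={subject_len_aa}, "
            f"OL={orf_len_aa})]"
        )
    if not 0.0 <= identity <= 1.0:
        raise DomainError(f"identity {identity} outside [0,1]")
    return identity * (match_len_aa / subject_len_aa) * (match_len_aa / orf_len_aa)


def levenshtein(a: str, b: str) -> int:
    """Edit distance (substitutions, insertions, deletions)."""
    return edlib.align(a, b, task="distance")["editDistance"]


def similarity_score(a: str, b: str) -> float:
    """S = (L - D)/L for equal-length strings; 1 iff the strings are equal."""
    if not a or not b:
        raise DomainError("similarity_score requires non-empty strings")
    if len(a) != len(b):
        raise DomainError(
            f"similarity_score compares only equal-length strings "
            f"({len(a)} vs {len(b)})"
        )
    return (len(a) - levenshtein(a, b)) / len(a)
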