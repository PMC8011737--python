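from __future__ import annotations

import random

import pytest

from prokannot.genetics import default_code, revcomp
from prokannot.orfs import Orf
from prokannot.scoring import HitEntry, Thresholds
from prokannot.seqio import GenomeRecord

# one fixed non-start, non-stop codon per amino acid, so test DNA contains a
# start codon exactly where a test puts one
SAFE_CODONS = {
    "A": "GCA", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC", "G": "GGA",
    "H": "CAC", "I": "ATC", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAC",
    "P": "CCA", "Q": "CAA", "R": "CGT", "S": "TCA", "T": "ACA", "V": "GTC",
    "W": "TGG", "Y": "TAC",
}

SAFE_AA = "ACDEFGHIKNPQRSTWY"  # no M (=start), no L/V (codons can be starts)


def encode(aa_seq: str, start: bool = True) -> str:
    """DNA for an amino-acid string using only non-start codons (except a
    leading ATG when start=True)."""
    dna = []
    for i, aa in enumerate(aa_seq):
        if i == 0 and start:
            assert aa == "M"
            dna.append("ATG")
        else:
            dna.append(SAFE_CODONS[aa])
    return "".join(dna)


def plain_genome(parts: list[str], contig_id: str = "c1") -> GenomeRecord:
    return GenomeRecord(id=contig_id, sequence="".join(parts))


def make_entry(
    subject: str,
    identity: float = 1.0,
    start_query: int = 0,
    end_query: int | None = None,
    start_match: int = 0,
    end_match: int | None = None,
    **kw,
) -> HitEntry:
    if end_match is None:
        end_match = len(subject)
    if end_query is None:
        end_query = start_query + (end_match - start_match)
    return HitEntry(
        entry_id=kw.pop("entry_id", "E1"),
        product_name=kw.pop("product_name", "test product"),
        subject_seq=subject,
        start_query=start_query,
        end_query=end_query,
        start_match=start_match,
        end_match=end_match,
        identity=identity,
        **kw,
    )


def forward_orf(start: int, end: int, contig: str = "c1", status: str = "candidate") -> Orf:
    return Orf(contig, start, end, "+", start % 3, status=status)


def reverse_orf(start: int, end: int, n: int, contig: str = "c1", status: str = "candidate") -> Orf:
    return Orf(contig, start, end, "-", (n - end) % 3, status=status)


def random_protein(rng: random.Random, length: int) -> str:
    return "M" + "".join(rng.choice(SAFE_AA) for _ in range(length - 1))


@pytest.fixture(scope="session")
def code():
    return default_code()


@pytest.fixture
def thresholds():
    return Thresholds()


@pytest.fixture
def rng():
    return random.Random(20240917)


__all__ = [
    "SAFE_CODONS",
    "SAFE_AA",
    "encode",
    "plain_genome",
    "make_entry",
    "forward_orf",
    "reverse_orf",
    "random_protein",
    "revcomp",
]
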