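"""Genetic-code handling.

The codon table is taken from the NCBI translation tables (default: table 11,
bacterial/archaeal). The start-codon set is configurable independently of the
table: by default it contains ATG plus the common bacterial valine/leucine
starts GTG, TTG and CTG; the full valine + leucine codon sets can be enabled
for permissive scanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

#: ATG plus the most common alternative bacterial starts (Val: GTG; Leu: TTG, CTG).
DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG", "CTG"})

#: Every valine and leucine codon, plus ATG.
FULL_VAL_LEU_START_CODONS = frozenset(
    {"ATG", "GTA", "GTC", "GTG", "GTT", "TTA", "TTG", "CTA", "CTC", "CTG", "CTT"}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """A codon table restricted to what ORF scanning needs.

    Codons containing N are opaque: they never match a start or a stop and
    translate to X.
    """

    start_codons: frozenset[str]
    stop_codons: frozenset[str]
    translation: dict[str, str] = field(repr=False)

    @classmethod
    def from_table(
        cls, table_id: int = 11, start_codons: frozenset[str] | None = None
    ) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(
            start_codons=frozenset(start_codons or DEFAULT_START_CODONS),
            stop_codons=frozenset(table.stop_codons),
            translation=dict(table.forward_table),
        )

    def is_start(self, codon: str) -> bool:
        return codon in self.start_codons

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def is_met(self, codon: str) -> bool:
        return codon == "ATG"

    def translate_codon(self, codon: str) -> str:
        """One-letter amino acid for ``codon``; X for ambiguous codons."""
        return self.translation.get(codon, "X")


def default_code() -> GeneticCode:
    """Bacterial table 11 with the default start-codon set."""
    return GeneticCode.from_table(11)
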