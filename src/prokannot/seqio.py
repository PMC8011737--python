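"""Reading and writing the exchange formats.

Genomes come in as FASTA, existing annotations as EMBL or GenBank flat files,
and the final annotation goes out as EMBL. The reference protein database is
plain FASTA with a structured header carrying the annotation payload::

    >entry_id|product name|gene=dnaA|org=Escherichia coli|go=GO:0003677;...|ec=2.7.7.7|kegg=eco02024

Empty optional fields may be omitted. Internally every coordinate is 0-based,
half-open, on the forward strand, for both strands; the 1-based inclusive
``complement()`` convention of EMBL/GenBank exists only at (de)serialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, UnsupportedLocationError

_DNA_ALPHABET = set("ACGTN")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class Topology(str, Enum):
    linear = "linear"
    circular = "circular"


@dataclass
class GenomeRecord:
    """One contig: identifier, uppercase DNA sequence, topology."""

    id: str
    sequence: str
    topology: Topology = Topology.linear

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("contig id must be non-empty")
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise FormatError(f"contig {self.id!r}: empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise FormatError(
                f"contig {self.id!r}: characters outside A/C/G/T/N: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceProtein:
    """One database protein with its annotation payload."""

    entry_id: str
    product_name: str
    sequence: str
    gene_name: str | None = None
    organism: str = ""
    go_terms: list[tuple[str, str]] = field(default_factory=list)
    ec_numbers: list[str] = field(default_factory=list)
    kegg_pathways: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"protein {self.entry_id!r}: empty sequence")
        bad = set(self.sequence) - _AA_ALPHABET
        if bad:
            raise FormatError(
                f"protein {self.entry_id!r}: non-standard residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class FeatureKind(str, Enum):
    CDS = "CDS"
    tRNA = "tRNA"
    rRNA = "rRNA"


@dataclass
class FeatureRecord:
    """A located feature in internal coordinates (0-based, half-open, forward)."""

    kind: FeatureKind
    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    qualifiers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature on {self.contig_id}: bad interval [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: Union[str, Path]) -> list[GenomeRecord]:
    """Read a genome FASTA into GenomeRecords.

    Sequences are uppercased; characters outside {A,C,G,T,N} and duplicate
    contig ids are rejected.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def _parse_db_header(header: str) -> dict:
    parts = header.split("|")
    if len(parts) < 2 or not parts[0]:
        raise FormatError(f"protein DB header must be 'entry_id|product|...': {header!r}")
    info: dict = {"entry_id": parts[0], "product_name": parts[1]}
    for fieldstr in parts[2:]:
        if not fieldstr:
            continue
        if "=" not in fieldstr:
            raise FormatError(f"malformed header field {fieldstr!r} in {header!r}")
        key, value = fieldstr.split("=", 1)
        if key == "gene" and value:
            info["gene_name"] = value
        elif key == "org":
            info["organism"] = value
        elif key == "go" and value:
            terms = []
            for tok in value.split(";"):
                if not tok:
                    continue
                if ":" in tok[3:]:  # GO:0003677:DNA binding
                    go_id, desc = tok[: tok.index(":", 3)], tok[tok.index(":", 3) + 1 :]
                else:
                    go_id, desc = tok, ""
                terms.append((go_id, desc))
            info["go_terms"] = terms
        elif key == "ec" and value:
            info["ec_numbers"] = [t for t in value.split(";") if t]
        elif key == "kegg" and value:
            info["kegg_pathways"] = [t for t in value.split(";") if t]
        elif key in ("gene", "go", "ec", "kegg", "org"):
            pass  # explicitly empty
        else:
            raise FormatError(f"unknown header field {key!r} in {header!r}")
    return info


def read_protein_db(path: Union[str, Path]) -> list[ReferenceProtein]:
    """Parse the structured protein-database FASTA dialect."""
    proteins: list[ReferenceProtein] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        info = _parse_db_header(rec.description)
        if info["entry_id"] in seen:
            raise FormatError(f"duplicate entry id {info['entry_id']!r} in {path}")
        seen.add(info["entry_id"])
        proteins.append(ReferenceProtein(sequence=str(rec.seq), **info))
    if not proteins:
        raise FormatError(f"no protein records in {path}")
    return proteins


def write_protein_db(proteins: Iterable[ReferenceProtein], path: Union[str, Path]) -> None:
    """Write proteins in the structured header dialect (inverse of read_protein_db)."""
    with open(path, "w") as fh:
        for p in proteins:
            go = ";".join(
                f"{gid}:{desc}" if desc else gid for gid, desc in p.go_terms
            )
            header = "|".join(
                [
                    p.entry_id,
                    p.product_name,
                    f"gene={p.gene_name or ''}",
                    f"org={p.organism}",
                    f"go={go}",
                    f"ec={';'.join(p.ec_numbers)}",
                    f"kegg={';'.join(p.kegg_pathways)}",
                ]
            )
            fh.write(f">{header}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def write_fasta(records: Iterable[GenomeRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Flat files

_KIND_BY_TYPE = {"CDS": FeatureKind.CDS, "tRNA": FeatureKind.tRNA, "rRNA": FeatureKind.rRNA}

#: qualifiers copied verbatim between flat files and FeatureRecord.qualifiers
_SCALAR_QUALIFIERS = ("product", "gene", "note")
_LIST_QUALIFIERS = ("db_xref", "EC_number")


def read_flatfile(
    path: Union[str, Path], dialect: str = "embl"
) -> tuple[list[GenomeRecord], list[FeatureRecord]]:
    """Read an EMBL or GenBank flat file into genome + feature lists.

    Coordinates are converted from the file's 1-based inclusive convention
    (with ``complement()`` marking the reverse strand) to internal 0-based
    half-open forward coordinates. Only CDS, tRNA and rRNA features are kept;
    join()/multi-exon locations are rejected.
    """
    if dialect not in ("embl", "genbank"):
        raise FormatError(f"dialect must be 'embl' or 'genbank', got {dialect!r}")
    genomes: list[GenomeRecord] = []
    features: list[FeatureRecord] = []
    try:
        seq_records = list(SeqIO.parse(str(path), dialect))
    except ValueError as exc:
        raise FormatError(f"cannot parse {path} as {dialect}: {exc}") from exc
    if not seq_records:
        raise FormatError(f"no records in {path}")
    for rec in seq_records:
        topology = Topology(rec.annotations.get("topology", "linear") or "linear")
        genome = GenomeRecord(id=rec.id, sequence=str(rec.seq), topology=topology)
        genomes.append(genome)
        for feat in rec.features:
            if feat.type not in _KIND_BY_TYPE:
                continue
            if isinstance(feat.location, CompoundLocation):
                raise UnsupportedLocationError(
                    f"{feat.type} at {feat.location} in {rec.id}: "
                    "join()/multi-exon locations are not supported"
                )
            start, end = int(feat.location.start), int(feat.location.end)
            if end > len(genome):
                raise FormatError(
                    f"{feat.type} [{start},{end}) exceeds contig {rec.id} "
                    f"length {len(genome)}"
                )
            strand = "-" if feat.location.strand == -1 else "+"
            quals: dict = {}
            for key in _SCALAR_QUALIFIERS:
                if key in feat.qualifiers:
                    quals[key] = feat.qualifiers[key][0]
            for key in _LIST_QUALIFIERS:
                if key in feat.qualifiers:
                    quals[key] = list(feat.qualifiers[key])
            features.append(
                FeatureRecord(
                    kind=_KIND_BY_TYPE[feat.type],
                    contig_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    qualifiers=quals,
                )
            )
    features.sort(key=lambda f: (f.contig_id, f.start, f.end))
    return genomes, features


def _feature_identity(f: FeatureRecord) -> tuple:
    return (f.kind, f.contig_id, f.start, f.end, f.strand, f.qualifiers.get("product"))


def write_embl(
    genome: Sequence[GenomeRecord],
    features: Iterable,
    path: Union[str, Path],
) -> None:
    """Write the annotation as an EMBL flat file.

    ``features`` may mix FeatureRecord with anything exposing
    ``to_feature_record()`` (annotated features from the engine). Identical
    duplicates are dropped with a warning. Features are emitted sorted by
    contig, then start.
    """
    flat: list[FeatureRecord] = []
    for f in features:
        if hasattr(f, "to_feature_record"):
            f = f.to_feature_record()
        flat.append(f)

    by_contig: dict[str, list[FeatureRecord]] = {g.id: [] for g in genome}
    contig_len = {g.id: len(g) for g in genome}
    seen: set[tuple] = set()
    for f in sorted(flat, key=lambda f: (f.contig_id, f.start, f.end)):
        if f.contig_id not in by_contig:
            raise FormatError(f"feature references unknown contig {f.contig_id!r}")
        if f.end > contig_len[f.contig_id]:
            raise FormatError(
                f"feature [{f.start},{f.end}) exceeds contig {f.contig_id!r}"
            )
        key = _feature_identity(f)
        if key in seen:
            warnings.warn(f"dropping duplicate feature {key}", stacklevel=2)
            continue
        seen.add(key)
        by_contig[f.contig_id].append(f)

    out_records = []
    for g in genome:
        rec = SeqRecord(
            Seq(g.sequence),
            id=g.id,
            name=g.id,
            description="",
            annotations={
                "molecule_type": "DNA",
                "topology": g.topology.value,
                "data_file_division": "PRO",
            },
        )
        for f in by_contig[g.id]:
            quals: dict[str, list[str]] = {}
            for key in _SCALAR_QUALIFIERS:
                if key in f.qualifiers and f.qualifiers[key] is not None:
                    quals[key] = [str(f.qualifiers[key])]
            for key in _LIST_QUALIFIERS:
                if f.qualifiers.get(key):
                    quals[key] = [str(v) for v in f.qualifiers[key]]
            loc = SimpleLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1)
            rec.features.append(SeqFeature(loc, type=f.kind.value, qualifiers=quals))
        out_records.append(rec)
    SeqIO.write(out_records, str(path), "embl")
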