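"""Deterministic synthetic databases and genomes with planted ground truth.

The generator emulates what the annotation pipeline consumes in practice: a
protein reference database (with gene acronyms, named products and a
hypothetical fraction) and a genome in which a chosen subset of those
proteins is planted as genes — back-translated with uniformly random
synonymous codons, on random strands, separated by random spacers. A
point-mutation rate introduces nonsynonymous changes for identity-gradient
experiments. Spacers are scrubbed: accidental open reading frames that are
neither planted genes (nor their in-frame upstream extensions, which the
resize step is expected to correct) are broken by writing an in-frame stop
codon at a spacer position, so recovery tests have unambiguous truth.

No codon-usage or GC-content realism is attempted.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .errors import DomainError
from .genetics import GeneticCode, default_code, revcomp
from .orfs import find_orfs
from .seqio import FeatureKind, FeatureRecord, GenomeRecord, ReferenceProtein

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

_PRODUCT_WORDS = (
    "DNA-binding protein",
    "membrane transport protein",
    "ATP synthase subunit",
    "ribosomal protein",
    "response regulator",
    "oxidoreductase",
    "aminotransferase",
    "cell division protein",
    "RNA polymerase subunit",
    "peptidase",
)


@dataclass
class PlantedTruth:
    """A synthetic genome with its exact ground truth."""

    features: list[FeatureRecord]
    db: list[ReferenceProtein]
    genome: list[GenomeRecord]
    seed: int
    decoys: list[FeatureRecord] = field(default_factory=list)


def synth_protein_db(
    n: int,
    len_range: tuple[int, int] = (100, 300),
    gene_fraction: float = 0.5,
    hypothetical_fraction: float = 0.2,
    seed: int = 0,
) -> list[ReferenceProtein]:
    """``n`` random proteins (always starting with M), deterministic per seed."""
    if n < 1:
        raise DomainError("n must be >= 1")
    for name, frac in (
        ("gene_fraction", gene_fraction),
        ("hypothetical_fraction", hypothetical_fraction),
    ):
        if not 0.0 <= frac <= 1.0:
            raise DomainError(f"{name}={frac} outside [0,1]")
    rng = random.Random(seed)
    proteins = []
    n_gene = round(n * gene_fraction)
    n_hypo = round(n * hypothetical_fraction)
    for i in range(n):
        length = rng.randint(*len_range)
        seq = "M" + "".join(rng.choice(_AA20) for _ in range(length - 1))
        gene = None
        if i < n_gene:
            gene = "".join(rng.choice("abcdefghijklmnopqrstuvwxyz") for _ in range(3))
            gene += rng.choice("ABCDEFGH")
        if i >= n - n_hypo:
            product = "hypothetical protein"
        else:
            product = f"{rng.choice(_PRODUCT_WORDS)} {i + 1}"
        proteins.append(
            ReferenceProtein(
                entry_id=f"SYN{i + 1:05d}",
                product_name=product,
                gene_name=gene,
                organism="Synthetica testensis",
                sequence=seq,
                go_terms=[(f"GO:{7000000 + i:07d}", "synthetic term")] if i % 3 == 0 else [],
                ec_numbers=[f"1.1.1.{i + 1}"] if i % 4 == 0 else [],
                kegg_pathways=[f"syn{i % 9 + 1:05d}"] if i % 5 == 0 else [],
            )
        )
    return proteins


def _backtranslate(
    aa_seq: str, rng: random.Random, codons_by_aa: dict[str, list[str]]
) -> str:
    out = ["ATG" if aa_seq[0] == "M" else rng.choice(codons_by_aa[aa_seq[0]])]
    for aa in aa_seq[1:]:
        out.append(rng.choice(codons_by_aa[aa]))
    return "".join(out)


def _mutate(aa_seq: str, rate: float, rng: random.Random) -> str:
    if rate <= 0:
        return aa_seq
    out = list(aa_seq)
    for i in range(1, len(out)):  # keep the initiator M
        if rng.random() < rate:
            out[i] = rng.choice([a for a in _AA20 if a != out[i]])
    return "".join(out)


def _codons_by_aa(code: GeneticCode) -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    for codon, aa in sorted(code.translation.items()):
        table.setdefault(aa, []).append(codon)
    return table


def _matches_truth(orf, protected: list[FeatureRecord]) -> bool:
    """ORF is a planted feature or an in-frame upstream extension of one."""
    for f in protected:
        if f.strand != orf.strand:
            continue
        if orf.strand == "+" and orf.end == f.end and orf.start <= f.start:
            if (f.start - orf.start) % 3 == 0:
                return True
        if orf.strand == "-" and orf.start == f.start and orf.end >= f.end:
            if (orf.end - f.end) % 3 == 0:
                return True
    return False


def _scrub(
    seq: list[str],
    contig_id: str,
    protected: list[FeatureRecord],
    code: GeneticCode,
    max_rounds: int = 60,
) -> None:
    """Break accidental ORFs by writing in-frame stop codons in spacers."""

    def in_protected(lo: int, hi: int) -> bool:
        return any(f.start < hi and lo < f.end for f in protected)

    for _ in range(max_rounds):
        genome = GenomeRecord(id=contig_id, sequence="".join(seq))
        offenders = [
            o for o in find_orfs(genome, code) if not _matches_truth(o, protected)
        ]
        if not offenders:
            return
        patched = False
        for o in offenders:
            if o.strand == "+":
                positions = range(o.start, o.end - 3, 3)
                stop = "TAA"
            else:
                positions = range(o.end - 3, o.start + 2, -3)
                stop = "TTA"  # reverse-strand TAA
            for pos in positions:
                if not in_protected(pos, pos + 3):
                    seq[pos : pos + 3] = stop
                    patched = True
                    break
        if not patched:
            return  # only unpatchable shadows (inside genes) remain


def _plant_decoy(
    seq: list[str],
    gene: FeatureRecord,
    spec: dict,
    protected: list[FeatureRecord],
    code: GeneticCode,
    rng: random.Random,
) -> FeatureRecord:
    """Plant an opposite-strand decoy ORF overlapping a forward gene's head.

    The decoy runs on the reverse strand, its stop in the spacer before the
    gene and its start codon on the gene's own bases; only spacer bases are
    written. Raises DomainError when the geometry cannot be realized.
    """
    if gene.strand != "+":
        raise DomainError("decoys are planted against forward-strand genes")
    overlap = spec.get("overlap_nt", 30)
    if overlap < 6 or overlap >= gene.length:
        raise DomainError(f"impossible decoy overlap {overlap} for gene {gene.length} nt")
    body_len = spec.get("length_nt", 90)
    if body_len % 3 != 0 or body_len < 63:
        raise DomainError(f"decoy length_nt={body_len} must be a multiple of 3, >= 63")

    def body_feasible(start: int, end: int) -> bool:
        # in-frame codons touching gene bases cannot be rewritten; a reverse
        # stop there makes this geometry infeasible
        for pos in range(start + 3, end - 3, 3):
            if pos + 3 > gene.start and code.is_stop(
                revcomp("".join(seq[pos : pos + 3]))
            ):
                return False
        return True

    # try every reverse-strand start codon on gene bases near gene.start+overlap
    chosen = None
    for e in range(gene.start + overlap, gene.start + 5, -1):
        if not code.is_start(revcomp("".join(seq[e - 3 : e]))):
            continue
        start = e - body_len
        if start < 3 or any(f.start < start + 3 and start < f.end for f in protected):
            continue
        if body_feasible(start, e):
            chosen = (start, e)
            break
    if chosen is None:
        raise DomainError(
            "impossible decoy geometry: no workable reverse start codon on the gene head"
        )
    start, end = chosen
    # clear reverse-frame stops in the spacer-only part of the decoy body
    for pos in range(start + 3, end - 3, 3):
        if pos + 3 <= gene.start and code.is_stop(
            revcomp("".join(seq[pos : pos + 3]))
        ):
            seq[pos : pos + 3] = list(rng.choice(["AAA", "GAA", "AGA"]))
    seq[start : start + 3] = "TTA"  # reverse-strand stop
    return FeatureRecord(
        kind=FeatureKind.CDS,
        contig_id=gene.contig_id,
        start=start,
        end=end,
        strand="-",
        qualifiers={"note": "decoy"},
    )


def synth_genome(
    db: list[ReferenceProtein],
    n_genes: int,
    spacer_range: tuple[int, int] = (60, 200),
    overlap_spec: list[dict] | None = None,
    mutation_rate: float = 0.0,
    seed: int = 0,
    contig_id: str = "synthetic_contig_1",
    code: GeneticCode | None = None,
) -> PlantedTruth:
    """Plant the first ``n_genes`` database proteins into one synthetic contig."""
    if n_genes > len(db):
        raise DomainError(f"n_genes={n_genes} exceeds database size {len(db)}")
    if not 0.0 <= mutation_rate <= 1.0:
        raise DomainError(f"mutation_rate={mutation_rate} outside [0,1]")
    code = code or default_code()
    rng = random.Random(seed)
    codons = _codons_by_aa(code)
    stops = sorted(code.stop_codons)

    chunks: list[str] = []
    features: list[FeatureRecord] = []
    pos = 0

    def spacer() -> str:
        length = rng.randint(*spacer_range)
        return "".join(rng.choice("ACGT") for _ in range(length))

    lead = spacer()
    chunks.append(lead)
    pos += len(lead)
    for i in range(n_genes):
        prot = db[i]
        aa = _mutate(prot.sequence, mutation_rate, rng)
        cds = _backtranslate(aa, rng, codons) + rng.choice(stops)
        strand = rng.choice("+-") if overlap_spec is None else "+"
        insert = cds if strand == "+" else revcomp(cds)
        features.append(
            FeatureRecord(
                kind=FeatureKind.CDS,
                contig_id=contig_id,
                start=pos,
                end=pos + len(insert),
                strand=strand,
                qualifiers={"product": prot.product_name, "note": f"entry={prot.entry_id}"},
            )
        )
        chunks.append(insert)
        pos += len(insert)
        gap = spacer()
        chunks.append(gap)
        pos += len(gap)

    seq = list("".join(chunks))
    decoys: list[FeatureRecord] = []
    if overlap_spec:
        for spec in overlap_spec:
            gene = features[spec.get("gene", 0)]
            decoys.append(_plant_decoy(seq, gene, spec, features + decoys, code, rng))
    _scrub(seq, contig_id, features + decoys, code)

    genome = GenomeRecord(id=contig_id, sequence="".join(seq))
    return PlantedTruth(
        features=features, db=list(db), genome=[genome], seed=seed, decoys=decoys
    )
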