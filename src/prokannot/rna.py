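"""tRNA/rRNA annotation by similarity to reference sequence sets.

Each reference sequence is locally aligned against both strands of the
contig; alignments reaching the identity and reference-coverage gates become
features. Multiple copies of the same reference are found by masking accepted
intervals and re-aligning. Covariance-model search is deliberately out of
scope: this is plain sequence matching against user-supplied reference sets.

Reference FASTA headers carry a ``kind=`` tag, e.g. ``>tRNA-Ala-1|kind=tRNA``.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Union

from Bio import Align, SeqIO

from .errors import FormatError
from .genetics import revcomp
from .seqio import FeatureKind, FeatureRecord, GenomeRecord

_MAX_COPIES_PER_REF = 16


def read_rna_refs(path: Union[str, Path]) -> list[tuple[str, str, str]]:
    """Parse an RNA reference FASTA with kind= header tags into
    (id, kind, sequence) tuples."""
    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        kind = None
        name = rec.id
        for tok in rec.description.split("|"):
            if tok.startswith("kind="):
                kind = tok[5:]
        if kind not in ("tRNA", "rRNA"):
            raise FormatError(
                f"RNA reference {rec.id!r} needs a '|kind=tRNA' or '|kind=rRNA' tag"
            )
        name = name.split("|")[0]
        refs.append((name, kind, str(rec.seq).upper()))
    if not refs:
        raise FormatError(f"no RNA references in {path}")
    return refs


def _dna_aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="local",
        match_score=2.0,
        mismatch_score=-3.0,
        open_gap_score=-5.0,
        extend_gap_score=-2.0,
    )


def annotate_rna(
    genome: GenomeRecord,
    refs: list[tuple[str, str, str]],
    min_identity: float = 0.9,
    min_cov: float = 0.9,
) -> list[FeatureRecord]:
    """Locate reference tRNA/rRNA copies on either strand of one contig.

    A hit must reach ``min_identity`` over alignment columns and cover at
    least ``min_cov`` of the reference. Overlapping hits from the same
    reference keep the best identity only.
    """
    if not refs:
        warnings.warn("annotate_rna called with no references", stacklevel=2)
        return []
    aligner = _dna_aligner()
    hits: list[tuple[float, FeatureRecord]] = []
    for name, kind, ref_seq in refs:
        if set(ref_seq) - set("ACGTN"):
            raise FormatError(f"RNA reference {name!r} is not DNA")
        for strand in ("+", "-"):
            query = ref_seq if strand == "+" else revcomp(ref_seq)
            masked = genome.sequence
            for _ in range(_MAX_COPIES_PER_REF):
                alns = aligner.align(masked, query)
                if len(alns) == 0 or alns.score <= 0:
                    break
                aln = alns[0]
                counts = aln.counts()
                columns = counts.identities + counts.mismatches + counts.gaps
                if columns == 0:
                    break
                identity = counts.identities / columns
                g_blocks, q_blocks = aln.aligned
                g0, g1 = int(g_blocks[0][0]), int(g_blocks[-1][1])
                coverage = (int(q_blocks[-1][1]) - int(q_blocks[0][0])) / len(ref_seq)
                if identity < min_identity or coverage < min_cov:
                    break
                hits.append(
                    (
                        identity,
                        FeatureRecord(
                            kind=FeatureKind(kind),
                            contig_id=genome.id,
                            start=g0,
                            end=g1,
                            strand=strand,
                            qualifiers={
                                "product": name,
                                "note": f"identity={100 * identity:.2f}",
                            },
                        ),
                    )
                )
                masked = masked[:g0] + "#" * (g1 - g0) + masked[g1:]

    # deduplicate overlapping hits of the same reference, best identity wins
    hits.sort(key=lambda t: (-t[0], t[1].start))
    accepted: list[FeatureRecord] = []
    for identity, feat in hits:
        clash = any(
            f.qualifiers["product"] == feat.qualifiers["product"]
            and min(f.end, feat.end) - max(f.start, feat.start) > 0
            for f in accepted
        )
        if not clash:
            accepted.append(feat)
    accepted.sort(key=lambda f: (f.start, f.end))
    return accepted
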