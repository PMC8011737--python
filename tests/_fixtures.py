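"""Engineered (genome, orf, entry) fixtures for resize behaviour.

DNA is assembled from per-amino-acid codons that are never start codons, so
each fixture contains alternative start sites exactly where it plants them.
"""

from __future__ import annotations

import random

from conftest import SAFE_AA, SAFE_CODONS

from prokannot.genetics import GeneticCode, revcomp
from prokannot.orfs import Orf, translate
from prokannot.scoring import HitEntry
from prokannot.seqio import GenomeRecord

NEUTRAL = "CCC"  # proline: neither start nor stop in any fixture


def _safe_codons(rng: random.Random, n: int) -> list[str]:
    return [SAFE_CODONS[rng.choice(SAFE_AA)] for _ in range(n)]


def _entry(subject, sq, eq, sm, em, identity=1.0) -> HitEntry:
    return HitEntry(
        entry_id="FIX",
        product_name="engineered product",
        subject_seq=subject,
        start_query=sq,
        end_query=eq,
        start_match=sm,
        end_match=em,
        identity=identity,
    )


def shrink_fixture(rng: random.Random, code: GeneticCode, strand: str = "+"):
    """ORF with a junk prefix; the subject matches the suffix after a planted
    in-frame GTG, so shrink should land exactly on it."""
    extra = rng.randint(2, 8)
    body = rng.randint(25, 60)
    codons = ["ATG"] + _safe_codons(rng, extra - 1) + ["GTG"] + _safe_codons(rng, body - 1)
    cds = "".join(codons) + "TAA"
    lead, tail = NEUTRAL * rng.randint(2, 6), NEUTRAL * rng.randint(2, 6)
    if strand == "+":
        seq = lead + cds + tail
        orf = Orf("f", len(lead), len(lead) + len(cds), "+", len(lead) % 3)
    else:
        seq = lead + revcomp(cds) + tail
        start = len(lead)
        end = start + len(cds)
        orf = Orf("f", start, end, "-", (len(lead) + len(cds) + len(tail) - end) % 3)
    genome = GenomeRecord(id="f", sequence=seq)
    aa = translate(orf, genome, code)
    subject = aa[extra:]
    entry = _entry(subject, extra, len(aa), 0, len(subject))
    return genome, orf, entry, orf_start_moved_by(orf, extra)


def orf_start_moved_by(orf: Orf, codons: int) -> tuple[int, int]:
    """Expected (start, end) after trimming ``codons`` from the reading start."""
    if orf.strand == "+":
        return orf.start + 3 * codons, orf.end
    return orf.start, orf.end - 3 * codons


def extend_fixture(
    rng: random.Random,
    code: GeneticCode,
    strand: str = "+",
    poison_stop: bool = False,
    tail_similarity: float = 1.0,
):
    """ORF whose subject carries ``ext`` extra upstream residues; an in-frame
    ATG sits exactly ext codons upstream of the current start."""
    ext = rng.randint(3, 12)
    body = rng.randint(25, 60)
    ext_codons = ["ATG"] + _safe_codons(rng, ext - 1)
    if poison_stop and ext >= 2:
        ext_codons[rng.randint(1, ext - 1)] = "TAA"
    body_codons = ["ATG"] + _safe_codons(rng, body - 1)
    cds = "".join(body_codons) + "TAA"
    upstream = "".join(ext_codons)
    lead, tail = NEUTRAL * rng.randint(2, 6), NEUTRAL * rng.randint(2, 6)
    if strand == "+":
        seq = lead + upstream + cds + tail
        start = len(lead) + len(upstream)
        orf = Orf("f", start, start + len(cds), "+", start % 3)
    else:
        seq = lead + revcomp(upstream + cds) + tail
        start = len(lead)
        orf = Orf("f", start, start + len(cds), "-", 0)
        orf.frame = (len(seq) - orf.end) % 3
    genome = GenomeRecord(id="f", sequence=seq)
    ext_aa = "".join(code.translate_codon(c) for c in ext_codons)
    body_aa = translate(orf, genome, code)
    subject = list(ext_aa + body_aa)
    n_corrupt = round(ext * (1.0 - tail_similarity))
    for pos in rng.sample(range(ext), n_corrupt):
        subject[pos] = "W" if subject[pos] != "W" else "Y"
    subject = "".join(subject)
    entry = _entry(subject, 0, body, ext, ext + body)
    if strand == "+":
        expected = (orf.start - 3 * ext, orf.end)
    else:
        expected = (orf.start, orf.end + 3 * ext)
    return genome, orf, entry, expected
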