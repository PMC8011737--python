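"""Pre-curation passes applied between the engine and human review.

Three passes run in a fixed order:

1. low-accuracy filter — drop every feature scoring below a cutoff;
2. overlap filter — first try to dissolve each overlapping pair by swapping a
   member to a near-best alternative entry with a shorter subject (shrinking
   the ORF out of the overlap), then, if unresolved, remove one member by
   ordered criteria (accuracy gap beyond tolerance, gene over non-gene,
   characterized over uncharacterized, and finally an uncharacterized ORF
   bridging two others); overlaps nothing resolves are flagged, never hidden;
3. intergenic reduction — swap a feature to an equivalent-class alternative
   with a longer subject when the extension shrinks the flanking gaps without
   creating any overlap.
"""

from __future__ import annotations

from typing import Mapping

from .engine import AnnotatedFeature
from .genetics import GeneticCode
from .orfs import Orf, orf_len_aa
from .resize import adjusted_entry, resize_to_subject
from .scoring import HitEntry, Thresholds
from .seqio import GenomeRecord


def low_accuracy_filter(
    features: list[AnnotatedFeature], cutoff: float
) -> tuple[list[AnnotatedFeature], list[AnnotatedFeature]]:
    """Split features into (kept, removed) by the accuracy cutoff; order kept."""
    kept = [f for f in features if f.accuracy >= cutoff]
    removed = [f for f in features if f.accuracy < cutoff]
    return kept, removed


def _overlap(a: AnnotatedFeature, b: AnnotatedFeature) -> int:
    return a.orf.overlap_nt(b.orf)


def _overlapping_pairs(
    features: list[AnnotatedFeature], min_overlap: int
) -> list[tuple[int, int]]:
    pairs = []
    ordered = sorted(range(len(features)), key=lambda i: (features[i].orf.contig_id, features[i].orf.start))
    for ii, i in enumerate(ordered):
        for j in ordered[ii + 1 :]:
            if (
                features[j].orf.contig_id != features[i].orf.contig_id
                or features[j].orf.start >= features[i].orf.end
            ):
                break
            if _overlap(features[i], features[j]) >= min_overlap:
                pairs.append((i, j))
    return pairs


def _try_swap_shorter(
    feat: AnnotatedFeature,
    partner: AnnotatedFeature,
    others: list[AnnotatedFeature],
    thresholds: Thresholds,
    genomes: Mapping[str, GenomeRecord],
    code: GeneticCode,
) -> bool:
    """Swap ``feat`` to a near-best alternative with a shorter subject that,
    after re-resize, clears the overlap with ``partner`` without creating a
    new one. Mutates feat on success."""
    if feat.entry is None or not feat.candidates:
        return False
    best_acc = max(
        [feat.accuracy] + [(c.accuracy or 0.0) for c in feat.candidates]
    )
    genome = genomes[feat.orf.contig_id]
    alts = [
        c
        for c in feat.candidates
        if c is not feat.entry and c.subject_len < feat.entry.subject_len
    ]
    alts.sort(key=lambda c: (c.subject_len, c.entry_id))
    for alt in alts:
        new_orf = resize_to_subject(feat.orf, alt, genome, code, thresholds)
        resized = adjusted_entry(alt, orf_len_aa(feat.orf), new_orf)
        # judged at its eventual resized length, as the engine judged entries
        if (resized.accuracy or 0.0) < best_acc - thresholds.tolerance:
            continue
        if new_orf.overlap_nt(partner.orf) >= thresholds.min_overlap_nt:
            continue
        if any(
            new_orf.overlap_nt(o.orf) >= thresholds.min_overlap_nt
            for o in others
            if o is not feat and o is not partner
        ):
            continue
        feat.orf = new_orf
        feat.entry = resized
        return True
    return False


def overlap_filter(
    features: list[AnnotatedFeature],
    thresholds: Thresholds,
    genomes: Mapping[str, GenomeRecord],
    code: GeneticCode,
) -> tuple[list[AnnotatedFeature], list[AnnotatedFeature]]:
    """Two-step overlap resolution; returns (kept, removed)."""
    features = list(features)
    removed: list[AnnotatedFeature] = []
    dead: set[int] = set()

    pairs = _overlapping_pairs(features, thresholds.min_overlap_nt)
    # step 1: entry swaps
    for i, j in pairs:
        if i in dead or j in dead:
            continue
        a, b = features[i], features[j]
        if _overlap(a, b) < thresholds.min_overlap_nt:
            continue  # an earlier swap already cleared it
        others = [f for k, f in enumerate(features) if k not in dead]
        if _try_swap_shorter(a, b, others, thresholds, genomes, code):
            continue
        _try_swap_shorter(b, a, others, thresholds, genomes, code)

    # step 2: ordered removal criteria on still-overlapping pairs
    for i, j in pairs:
        if i in dead or j in dead:
            continue
        a, b = features[i], features[j]
        if _overlap(a, b) < thresholds.min_overlap_nt:
            continue
        loser: int | None = None
        if abs(a.accuracy - b.accuracy) > thresholds.tolerance:
            loser = i if a.accuracy < b.accuracy else j
        elif a.has_gene != b.has_gene:
            loser = j if a.has_gene else i
        elif a.is_hypothetical != b.is_hypothetical:
            loser = i if a.is_hypothetical else j
        if loser is not None:
            dead.add(loser)
            features[loser].orf.qualifiers["removed_reason"] = "overlap_filter"
            removed.append(features[loser])

    # final criterion: an uncharacterized ORF bridging two or more others
    for i, f in enumerate(features):
        if i in dead or not f.is_hypothetical:
            continue
        touching = [
            j
            for j, g in enumerate(features)
            if j != i and j not in dead and _overlap(f, g) >= thresholds.min_overlap_nt
        ]
        if len(touching) >= 2:
            dead.add(i)
            f.orf.qualifiers["removed_reason"] = "overlap_bridge"
            removed.append(f)

    kept = [f for k, f in enumerate(features) if k not in dead]
    # anything still overlapping is flagged for the curator
    for i, j in _overlapping_pairs(kept, thresholds.min_overlap_nt):
        kept[i].flags["overlap_unresolved"] = True
        kept[j].flags["overlap_unresolved"] = True
    return kept, removed


def _same_class(a: HitEntry, b: HitEntry) -> bool:
    return a.has_gene == b.has_gene and a.is_hypothetical == b.is_hypothetical


def _flanking_gap(orf: Orf, others: list[Orf]) -> int:
    """Total gap to the nearest neighbour on each side (contig edge counts)."""
    genome_ahead = [o.start for o in others if o.start >= orf.end]
    genome_behind = [o.end for o in others if o.end <= orf.start]
    gap_after = (min(genome_ahead) - orf.end) if genome_ahead else 0
    gap_before = (orf.start - max(genome_behind)) if genome_behind else 0
    return gap_before + gap_after


def reduce_intergenic(
    features: list[AnnotatedFeature],
    thresholds: Thresholds,
    genomes: Mapping[str, GenomeRecord],
    code: GeneticCode,
) -> list[AnnotatedFeature]:
    """Swap features to equivalent-class longer-subject entries that shrink
    the flanking intergenic gaps without creating overlaps."""
    features = sorted(features, key=lambda f: (f.orf.contig_id, f.orf.start))
    for feat in features:
        if feat.entry is None or not feat.candidates:
            continue
        genome = genomes[feat.orf.contig_id]
        same_contig = [
            f.orf for f in features if f is not feat and f.orf.contig_id == feat.orf.contig_id
        ]
        current_gap = _flanking_gap(feat.orf, same_contig)
        if current_gap <= 0:
            continue
        alts = [
            c
            for c in feat.candidates
            if c is not feat.entry
            and _same_class(c, feat.entry)
            and c.subject_len > feat.entry.subject_len
        ]
        alts.sort(key=lambda c: (-c.subject_len, c.entry_id))
        for alt in alts:
            new_orf = resize_to_subject(feat.orf, alt, genome, code, thresholds)
            if new_orf.length <= feat.orf.length:
                continue
            resized = adjusted_entry(alt, orf_len_aa(feat.orf), new_orf)
            if (resized.accuracy or 0.0) < feat.accuracy - thresholds.tolerance:
                continue
            if any(
                new_orf.overlap_nt(o) >= thresholds.min_overlap_nt for o in same_contig
            ):
                continue
            if _flanking_gap(new_orf, same_contig) >= current_gap:
                continue
            feat.orf = new_orf
            feat.entry = resized
            break
    return features
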