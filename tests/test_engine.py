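import random

import pytest

from conftest import encode, forward_orf, make_entry, plain_genome, reverse_orf

from prokannot.engine import (
    AnnotatedFeature,
    AnnotationState,
    clean_overlaps,
    process_queue,
    select_best_entry,
)
from prokannot.errors import DomainError
from prokannot.orfs import Orf, find_orfs, translate
from prokannot.scoring import Thresholds
from prokannot.search import FixtureSearchProvider, LocalSearchProvider
from prokannot.seqio import GenomeRecord, ReferenceProtein
from prokannot.synth import synth_genome, synth_protein_db


def _scored(acc, gene=None, product="some product", ml=50, entry_id="E"):
    e = make_entry("M" * ml, identity=1.0, entry_id=entry_id,
                   product_name=product, gene_name=gene)
    return e.with_accuracy(ml) if acc is None else e.__class__(**{**e.__dict__, "accuracy": acc})


class TestSelectBestEntry:
    def test_gene_preferred_inside_tolerance_band(self, thresholds):
        a = _scored(0.955, entry_id="A")
        b = _scored(0.950, gene="dnaA", entry_id="B")
        assert select_best_entry([a, b], thresholds).entry_id == "B"

    def test_outside_tolerance_band_higher_accuracy_wins(self, thresholds):
        a = _scored(0.97, entry_id="A")
        b = _scored(0.90, gene="dnaA", entry_id="B")
        assert select_best_entry([a, b], thresholds).entry_id == "A"

    def test_named_product_beats_hypothetical(self, thresholds):
        a = _scored(0.95, product="hypothetical protein", entry_id="A")
        b = _scored(0.945, product="DNA polymerase", entry_id="B")
        assert select_best_entry([a, b], thresholds).entry_id == "B"

    def test_equal_accuracy_shorter_match_wins(self, thresholds):
        a = _scored(0.95, gene="g1", ml=80, entry_id="A")
        b = _scored(0.95, gene="g2", ml=70, entry_id="B")
        assert select_best_entry([a, b], thresholds).entry_id == "B"

    def test_full_tie_keeps_input_order(self, thresholds):
        a = _scored(0.95, ml=70, entry_id="A")
        b = _scored(0.95, ml=70, entry_id="B")
        assert select_best_entry([a, b], thresholds).entry_id == "A"

    def test_single_entry_returned(self, thresholds):
        e = _scored(0.5, entry_id="only")
        assert select_best_entry([e], thresholds) is e

    def test_empty_list_rejected(self, thresholds):
        with pytest.raises(DomainError):
            select_best_entry([], thresholds)


def _neutral_genome(n):
    # lysine codons only: no start, no stop anywhere
    return GenomeRecord(id="c1", sequence="AAA" * (n // 3))


def _state(queue, thresholds=None):
    st = AnnotationState(thresholds=thresholds or Thresholds())
    for orf in sorted(queue, key=lambda o: -o.length):
        st.queue.append(orf)
    return st


def _borf(start, end, strand, n=None):
    orf = (
        forward_orf(start, end, status="confirmed")
        if strand == "+"
        else reverse_orf(start, end, n, status="confirmed")
    )
    orf.selected_entry = _scored(1.0, product="characterized thing", entry_id="B0")
    return orf


class TestCleanOverlapsGeometry:
    """Each case is hand-traced on an inert genome with one planted codon."""

    def test_same_direction_truncates_to_first_start_after_borf_stop(self, code):
        genome = _neutral_genome(900)
        seq = list(genome.sequence)
        seq[421:424] = "GTG"  # in OORF frame: (421-340) % 3 == 0
        genome.sequence = "".join(seq)
        borf = _borf(100, 400, "+")
        oorf = forward_orf(340, 640)
        state = _state([oorf])
        clean_overlaps(borf, state, {"c1": genome}, code)
        assert state.removed == []
        (kept,) = state.queue
        assert (kept.start, kept.end, kept.strand) == (421, 640, "+")

    def test_same_direction_removed_when_no_start_codon(self, code):
        genome = _neutral_genome(900)
        borf = _borf(100, 400, "+")
        oorf = forward_orf(340, 640)
        state = _state([oorf])
        clean_overlaps(borf, state, {"c1": genome}, code)
        assert state.queue == []
        assert state.removed == [oorf]

    def test_same_direction_removed_when_remainder_too_short(self, code):
        genome = _neutral_genome(900)
        seq = list(genome.sequence)
        seq[610:613] = "GTG"  # remainder 640-610 = 30 nt < minimum
        genome.sequence = "".join(seq)
        borf = _borf(100, 400, "+")
        oorf = forward_orf(340, 640)
        state = _state([oorf])
        clean_overlaps(borf, state, {"c1": genome}, code)
        assert state.removed == [oorf]

    def test_reverse_oorf_reanchored_before_forward_borf_start(self, code):
        # BORF forward, OORF reverse, OORF stop (low coord) before BORF start
        n = 900
        genome = _neutral_genome(n)
        seq = list(genome.sequence)
        # OORF [100, 361): in-frame reverse positions are == 358 mod 3 == 1
        seq[292:295] = "CAT"  # revcomp ATG; new end 295 <= borf.start 300
        genome.sequence = "".join(seq)
        borf = _borf(300, 600, "+")
        oorf = reverse_orf(100, 361, n)
        state = _state([oorf])
        clean_overlaps(borf, state, {"c1": genome}, code)
        (kept,) = state.queue
        assert (kept.start, kept.end, kept.strand) == (100, 295, "-")

    def test_forward_oorf_reanchored_after_reverse_borf(self, code):
        # BORF reverse (stop at its low coordinate), OORF forward starting
        # inside it: new start = first in-frame start codon past BORF end
        n = 900
        genome = _neutral_genome(n)
        seq = list(genome.sequence)
        seq[412:415] = "TTG"  # (412 - 340) % 3 == 0
        genome.sequence = "".join(seq)
        borf = _borf(100, 400, "-", n)
        oorf = forward_orf(340, 640)
        state = _state([oorf])
        clean_overlaps(borf, state, {"c1": genome}, code)
        (kept,) = state.queue
        assert (kept.start, kept.end, kept.strand) == (412, 640, "+")

    def test_large_overlap_fraction_removes_oorf(self, code):
        # fully nested same-direction OORF: no geometric case, 100% overlap
        genome = _neutral_genome(900)
        borf = _borf(100, 700, "+")
        oorf = forward_orf(200, 500)
        state = _state([oorf])
        clean_overlaps(borf, state, {"c1": genome}, code)
        assert state.removed == [oorf]
        assert oorf.qualifiers["removed_reason"] == "overlap_fraction"

    def test_small_overlap_below_threshold_ignored(self, code):
        genome = _neutral_genome(900)
        borf = _borf(100, 400, "+")
        oorf = forward_orf(397, 700)  # 3 nt: routine stop/start sharing
        state = _state([oorf])
        clean_overlaps(borf, state, {"c1": genome}, code)
        assert state.queue == [oorf]

    def test_blasted_low_accuracy_oorf_removed(self, code):
        genome = _neutral_genome(900)
        borf = _borf(100, 400, "+")
        oorf = forward_orf(340, 640, status="blasted")
        oorf.selected_entry = _scored(0.5, entry_id="weak")
        state = _state([oorf])
        clean_overlaps(borf, state, {"c1": genome}, code)
        assert state.removed == [oorf]

    def test_blasted_high_accuracy_oorf_kept(self, code):
        genome = _neutral_genome(900)
        borf = _borf(100, 400, "+")
        oorf = forward_orf(340, 640, status="blasted")
        oorf.selected_entry = _scored(0.95, entry_id="strong")
        state = _state([oorf])
        clean_overlaps(borf, state, {"c1": genome}, code)
        assert state.queue == [oorf]


class TestProcessQueue:
    def _planted(self, code, proteins):
        """Genome with the given proteins planted back-to-back, spacer-separated."""
        parts, feats, pos = [], [], 0
        spacer = "CCC" * 10
        for aa in proteins:
            parts.append(spacer)
            pos += len(spacer)
            cds = encode(aa) + "TAA"
            feats.append((pos, pos + len(cds)))
            parts.append(cds)
            pos += len(cds)
        parts.append(spacer)
        return plain_genome(parts), feats

    def test_three_planted_genes_all_confirmed(self, code, thresholds):
        rng = random.Random(0)
        prots = ["M" + "".join(rng.choice("ACDEFGHIKNPQRSTWY") for _ in range(40))
                 for _ in range(3)]
        genome, coords = self._planted(code, prots)
        table = {
            aa: [make_entry(aa, entry_id=f"P{i}", product_name=f"enzyme {i}").with_accuracy(len(aa))]
            for i, aa in enumerate(prots)
        }
        orfs = find_orfs(genome, code)
        planted = [o for o in orfs if (o.start, o.end) in coords]
        assert len(planted) == 3
        state = AnnotationState.from_orfs(
            orfs, FixtureSearchProvider(table), thresholds=thresholds
        )
        process_queue(state, {"c1": genome}, code)
        confirmed = {(f.orf.start, f.orf.end) for f in state.confirmed}
        assert set(coords) <= confirmed
        assert all(f.accuracy == 1.0 for f in state.confirmed
                   if (f.orf.start, f.orf.end) in coords)
        assert not state.queue

    def test_hypothetical_best_hit_does_not_clean_overlaps(self, code, thresholds):
        # BORF-quality accuracy but hypothetical product: the overlapping ORF
        # must still be searched rather than removed
        genome = _neutral_genome(900)
        seq = list(genome.sequence)
        seq[502:505] = "AAC"  # distinguish the two ORF translations
        genome.sequence = "".join(seq)
        a = forward_orf(100, 400)
        b = forward_orf(340, 640)
        entry_a = make_entry("M" * 99, identity=0.95, entry_id="HYP",
                             product_name="hypothetical protein").with_accuracy(99)
        entry_b = make_entry("M" * 99, identity=0.95, entry_id="REAL",
                             product_name="kinase").with_accuracy(99)
        table = {
            translate(a, genome, code): [entry_a],
            translate(b, genome, code): [entry_b],
        }
        state = AnnotationState.from_orfs(
            [a, b], FixtureSearchProvider(table), thresholds=thresholds
        )
        process_queue(state, {"c1": genome}, code)
        ids = {f.entry.entry_id for f in state.confirmed}
        assert ids == {"HYP", "REAL"}
        assert state.removed == []

    def test_no_hit_orfs_removed_by_default_retained_on_request(self, code, thresholds):
        genome = _neutral_genome(300)
        orf = forward_orf(0, 90)
        provider = FixtureSearchProvider({})
        state = AnnotationState.from_orfs([orf], provider, thresholds=thresholds)
        process_queue(state, {"c1": genome}, code)
        assert state.removed and not state.confirmed

        orf2 = forward_orf(0, 90)
        state2 = AnnotationState.from_orfs(
            [orf2], provider, thresholds=thresholds, retain_no_hit=True
        )
        process_queue(state2, {"c1": genome}, code)
        assert state2.confirmed[0].flags.get("no_hit")

    def test_provider_failure_leaves_orf_unresolved(self, code, thresholds):
        class Boom:
            def search(self, q, max_hits=10):
                raise RuntimeError("backend down")

        genome = _neutral_genome(300)
        orf = forward_orf(0, 90)
        state = AnnotationState.from_orfs([orf], Boom(), thresholds=thresholds)
        process_queue(state, {"c1": genome}, code)
        assert state.unresolved == [orf]
        assert not state.confirmed and not state.removed

    def test_parameter_recovery_on_synthetic_genome(self, code):
        db = synth_protein_db(16, seed=11)
        truth = synth_genome(db, 10, seed=11)
        g = truth.genome[0]
        state = AnnotationState.from_orfs(
            find_orfs(g, code), LocalSearchProvider(db)
        )
        process_queue(state, {g.id: g}, code)
        confirmed = {(f.orf.start, f.orf.end, f.orf.strand) for f in state.confirmed}
        truth_set = {(f.start, f.end, f.strand) for f in truth.features}
        assert truth_set <= confirmed

    def test_rerun_of_clean_overlaps_is_noop(self, code):
        db = synth_protein_db(10, seed=5)
        truth = synth_genome(db, 6, seed=5)
        g = truth.genome[0]
        state = AnnotationState.from_orfs(find_orfs(g, code), LocalSearchProvider(db))
        process_queue(state, {g.id: g}, code)
        before = [(f.orf.start, f.orf.end) for f in state.confirmed]
        for f in state.confirmed:
            if f.entry and not f.is_hypothetical and f.accuracy >= 0.9:
                clean_overlaps(f.orf, state, {g.id: g}, code)
        assert [(f.orf.start, f.orf.end) for f in state.confirmed] == before
        assert state.queue == []
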