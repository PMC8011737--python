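import copy

from conftest import forward_orf, make_entry

from prokannot.engine import AnnotatedFeature
from prokannot.precuration import (
    low_accuracy_filter,
    overlap_filter,
    reduce_intergenic,
)
from prokannot.seqio import GenomeRecord


def _genome(n=1500, planted=()):
    seq = list("AAA" * (n // 3))
    for pos, codon in planted:
        seq[pos : pos + 3] = codon
    return GenomeRecord(id="c1", sequence="".join(seq))


def _feature(start, end, acc=1.0, gene=None, product="characterized product",
             subject_len=None, candidates=(), entry_id="E"):
    ol = (end - start) // 3 - 1
    sl = subject_len or ol
    entry = make_entry(
        "M" * sl, identity=acc, entry_id=entry_id, product_name=product,
        gene_name=gene, start_query=0,
    ).with_accuracy(ol)
    orf = forward_orf(start, end, status="confirmed")
    return AnnotatedFeature(orf, entry, [entry, *candidates])


class TestLowAccuracyFilter:
    def test_splits_on_cutoff(self):
        feats = [_feature(0, 303, acc=0.95), _feature(400, 703, acc=0.60)]
        kept, removed = low_accuracy_filter(feats, 0.80)
        assert [f.accuracy for f in kept] == [0.95]
        assert [f.accuracy for f in removed] == [0.60]

    def test_empty_input(self):
        assert low_accuracy_filter([], 0.8) == ([], [])

    def test_all_above_cutoff_removes_nothing(self):
        feats = [_feature(0, 303, acc=0.9), _feature(400, 703, acc=0.85)]
        kept, removed = low_accuracy_filter(feats, 0.8)
        assert kept == feats and removed == []

    def test_no_retained_feature_below_cutoff(self):
        feats = [_feature(i * 400, i * 400 + 303, acc=a)
                 for i, a in enumerate([0.1, 0.5, 0.79, 0.8, 0.99])]
        kept, _ = low_accuracy_filter(feats, 0.8)
        assert all(f.accuracy >= 0.8 for f in kept)


class TestOverlapFilterSwap:
    def test_shorter_alternative_entry_dissolves_overlap(self, code, thresholds):
        # second entry with a shorter subject lets the downstream member
        # shrink past the overlap; both survive
        genome = _genome(planted=[(403, "GTG")])
        a = _feature(100, 400, entry_id="A")
        alt = make_entry("V" + "M" * 77, identity=1.0, entry_id="Balt",
                         product_name="characterized product",
                         start_query=21, end_query=99,
                         start_match=0, end_match=78).with_accuracy(99)
        b = _feature(340, 640, entry_id="B", candidates=[alt])
        kept, removed = overlap_filter([a, b], thresholds, {"c1": genome}, code)
        assert removed == []
        swapped = next(f for f in kept if f.entry.entry_id == "Balt")
        assert (swapped.orf.start, swapped.orf.end) == (403, 640)
        assert swapped.orf.overlap_nt(a.orf) == 0


class TestOverlapFilterRemoval:
    def test_accuracy_gap_beyond_tolerance_removes_weaker(self, code, thresholds):
        a = _feature(100, 400, acc=0.95)
        b = _feature(340, 640, acc=0.85)
        kept, removed = overlap_filter([a, b], thresholds, {"c1": _genome()}, code)
        assert removed == [b] and kept == [a]

    def test_gene_acronym_member_kept(self, code, thresholds):
        a = _feature(100, 400, acc=0.95, gene="yacG")
        b = _feature(340, 640, acc=0.95, product="Uncharacterized protein")
        kept, removed = overlap_filter([a, b], thresholds, {"c1": _genome()}, code)
        assert removed == [b] and kept == [a]

    def test_characterized_member_kept(self, code, thresholds):
        a = _feature(100, 400, acc=0.95, product="tRNA ligase")
        b = _feature(340, 640, acc=0.95, product="hypothetical protein")
        kept, removed = overlap_filter([a, b], thresholds, {"c1": _genome()}, code)
        assert removed == [b] and kept == [a]

    def test_uncharacterized_bridge_over_two_orfs_removed(self, code, thresholds):
        left = _feature(100, 400, acc=0.9, product="hypothetical protein")
        bridge = _feature(340, 700, acc=0.9, product="hypothetical protein")
        right = _feature(640, 940, acc=0.9, product="hypothetical protein")
        kept, removed = overlap_filter(
            [left, bridge, right], thresholds, {"c1": _genome()}, code
        )
        assert removed == [bridge]
        assert kept == [left, right]

    def test_unresolved_overlap_is_flagged_not_hidden(self, code, thresholds):
        a = _feature(100, 400, acc=0.95, gene="aaaA")
        b = _feature(340, 640, acc=0.95, gene="bbbB")
        kept, removed = overlap_filter([a, b], thresholds, {"c1": _genome()}, code)
        assert removed == []
        assert all(f.flags.get("overlap_unresolved") for f in kept)


class TestOverlapFilterProperties:
    def _count_overlaps(self, feats, min_ov=4):
        return sum(
            1
            for i, a in enumerate(feats)
            for b in feats[i + 1 :]
            if a.orf.overlap_nt(b.orf) >= min_ov
        )

    def test_idempotent_and_never_increases_overlaps(self, code, thresholds):
        genome = _genome(planted=[(403, "GTG")])
        feats = [
            _feature(100, 400, acc=0.95, gene="aaaA"),
            _feature(340, 640, acc=0.85),
            _feature(620, 920, acc=0.95, product="hypothetical protein"),
            _feature(1000, 1300, acc=0.99),
        ]
        before = self._count_overlaps(feats)
        kept, _ = overlap_filter(copy.deepcopy(feats), thresholds, {"c1": genome}, code)
        assert self._count_overlaps(kept) <= before
        again, removed2 = overlap_filter(
            copy.deepcopy(kept), thresholds, {"c1": genome}, code
        )
        assert removed2 == []
        assert [(f.orf.start, f.orf.end, f.entry.entry_id) for f in again] == [
            (f.orf.start, f.orf.end, f.entry.entry_id) for f in kept
        ]


class TestReduceIntergenic:
    def _phor_like(self, ext_ok=True):
        # feature at [400,700); an in-frame ATG 20 codons upstream; the
        # alternative subject carries exactly those 20 extra residues
        genome = _genome(planted=[(340, "ATG")])
        left = _feature(100, 280 if ext_ok else 360, entry_id="L")
        alt_subject = "M" + "K" * 19 + "M" * 99
        alt = make_entry(alt_subject, identity=1.0, entry_id="Falt",
                         product_name="characterized product", gene_name="phoR",
                         start_query=0, end_query=99,
                         start_match=20, end_match=119).with_accuracy(99)
        feat = _feature(400, 700, gene="phoR", entry_id="F", candidates=[alt])
        return genome, left, feat

    def test_longer_equivalent_entry_fills_gap(self, code, thresholds):
        genome, left, feat = self._phor_like(ext_ok=True)
        out = reduce_intergenic([left, feat], thresholds, {"c1": genome}, code)
        moved = next(f for f in out if f.entry.entry_id == "Falt")
        assert (moved.orf.start, moved.orf.end) == (340, 700)
        assert moved.accuracy == 1.0

    def test_no_swap_when_extension_would_collide(self, code, thresholds):
        genome, left, feat = self._phor_like(ext_ok=False)
        out = reduce_intergenic([left, feat], thresholds, {"c1": genome}, code)
        assert all(f.entry.entry_id != "Falt" for f in out)
        assert {(f.orf.start, f.orf.end) for f in out} == {(100, 360), (400, 700)}

    def test_no_alternatives_is_noop(self, code, thresholds):
        genome = _genome()
        feats = [_feature(100, 400), _feature(500, 800)]
        out = reduce_intergenic(copy.deepcopy(feats), thresholds, {"c1": genome}, code)
        assert {(f.orf.start, f.orf.end) for f in out} == {(100, 400), (500, 800)}

    def test_idempotent_and_gap_non_increasing(self, code, thresholds):
        genome, left, feat = self._phor_like(ext_ok=True)
        def total_gap(fs):
            fs = sorted(fs, key=lambda f: f.orf.start)
            return sum(
                max(0, b.orf.start - a.orf.end) for a, b in zip(fs, fs[1:])
            )
        feats = [left, feat]
        g0 = total_gap(feats)
        once = reduce_intergenic(feats, thresholds, {"c1": genome}, code)
        g1 = total_gap(once)
        assert g1 <= g0
        twice = reduce_intergenic(copy.deepcopy(once), thresholds, {"c1": genome}, code)
        assert [(f.orf.start, f.orf.end, f.entry.entry_id) for f in twice] == [
            (f.orf.start, f.orf.end, f.entry.entry_id) for f in once
        ]
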