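"""Catalog assignment, novel-locus discovery, TSD classification, CPM."""
import numpy as np
import pytest

from hervkmap.catalog import Catalog, LocusRecord
from hervkmap.flankmap import FlankAlignment
from hervkmap.locuscall import (
    assign_to_catalog,
    call_novel,
    classify_novel,
    discover_novel,
    quantify,
    saturation,
)


def _aln(contig, junction, side="left_of_flank", ltr_end="three_prime",
         length=100, rid="r"):
    pos = junction if side == "left_of_flank" else junction - length + 1
    return FlankAlignment(rid, ltr_end, contig, pos,
                          "+" if side == "left_of_flank" else "-",
                          length, length, 1, side)


def _cat(*intervals):
    return Catalog(
        [
            LocusRecord(f"L{i}", c, s, e)
            for i, (c, s, e) in enumerate(intervals)
        ]
    )


class TestAssign:
    def test_window_boundary(self):
        cat = _cat(("chr1", 100, 1100))
        inside, _, _ = assign_to_catalog([_aln("chr1", 1109)], cat, 10)
        outside, un, _ = assign_to_catalog([_aln("chr1", 1110)], cat, 10)
        assert inside == {"L0": 1}
        assert outside == {} and len(un) == 1

    def test_each_read_counted_once_nearest_edge_wins(self):
        cat = _cat(("chr1", 100, 200), ("chr1", 215, 300))
        # junction 207: distance 8 from L0's last base (199), 8 from L1's
        # start -> exact tie -> lower-coordinate locus, counted as tie
        counts, _, stats = assign_to_catalog([_aln("chr1", 207)], cat, 10)
        assert counts == {"L0": 1} and stats["ties"] == 1
        counts, _, _ = assign_to_catalog([_aln("chr1", 206)], cat, 10)
        assert counts == {"L0": 1}
        counts, _, _ = assign_to_catalog([_aln("chr1", 208)], cat, 10)
        assert counts == {"L1": 1}

    def test_matches_brute_force_on_random_junctions(self, rng):
        records = []
        for i in range(40):
            s = int(rng.integers(0, 50_000))
            records.append(LocusRecord(f"L{i}", "c", s, s + int(rng.integers(4, 900))))
        # rebuild dropping overlapping-id duplicates is unnecessary; ids unique
        cat = Catalog(records)
        alns = [_aln("c", int(rng.integers(0, 52_000)), rid=f"r{k}")
                for k in range(800)]
        counts, unassigned, _ = assign_to_catalog(alns, cat, 10)

        def brute(j):
            cands = [
                r for r in records if r.start - 10 <= j <= r.end - 1 + 10
            ]
            if not cands:
                return None
            def dist(r):
                return 0 if r.start <= j < r.end else min(
                    abs(j - r.start), abs(j - (r.end - 1))
                )
            dmin = min(dist(r) for r in cands)
            return min(
                (r for r in cands if dist(r) == dmin),
                key=lambda r: (r.start, r.locus_id),
            ).locus_id

        expected = {}
        n_un = 0
        for a in alns:
            lid = brute(a.junction)
            if lid is None:
                n_un += 1
            else:
                expected[lid] = expected.get(lid, 0) + 1
        assert counts == expected and len(unassigned) == n_un

    def test_conservation(self, rng):
        cat = _cat(("c", 100, 300), ("c", 5000, 5400))
        alns = [_aln("c", int(rng.integers(0, 10_000)), rid=f"r{k}")
                for k in range(300)]
        counts, unassigned, stats = assign_to_catalog(alns, cat, 10)
        assert sum(counts.values()) + len(unassigned) == len(alns)
        assert stats["assigned"] == sum(counts.values())


class TestNovel:
    def test_two_kb_rule_boundary(self):
        cat = _cat(("c", 100, 1100))
        # cluster at distance 2001 from the locus's last base (1099)
        novel_j = 1099 + 2001
        ambiguous_j = 1099 + 1999
        for j, is_novel in [(novel_j, True), (ambiguous_j, False)]:
            alns = [_aln("c", j, rid="a"), _aln("c", j + 3, rid="b")]
            candidates, ambiguous = discover_novel(alns, cat)
            if is_novel:
                assert len(candidates) == 1 and not ambiguous
            else:
                assert not candidates and len(ambiguous) == 1

    def test_no_unassigned_reads_empty(self):
        assert discover_novel([], _cat(("c", 0, 10))) == ([], [])

    def test_min_reads_threshold(self):
        cat = _cat(("c", 100, 200))
        single = [_aln("c", 50_000)]
        assert discover_novel(single, cat) == ([], [])
        pair = [_aln("c", 50_000, rid="a"), _aln("c", 50_010, rid="b")]
        cands, _ = discover_novel(pair, cat)
        assert len(cands) == 1 and cands[0].supporting_reads == 2

    def test_cluster_gap_single_linkage(self):
        cat = _cat(("c", 100, 200))
        js = [50_000, 50_050, 50_100, 50_200]  # last is 100 > gap away
        alns = [_aln("c", j, rid=f"r{j}") for j in js] + [
            _aln("c", 50_205, rid="r5")
        ]
        cands, _ = discover_novel(alns, cat, cluster_gap=50)
        assert sorted(c.supporting_reads for c in cands) == [2, 3]

    def test_published_tsd_footprint_recovered(self):
        """5' junctions ending at 32,643,464 and 3' junctions starting at
        32,643,459 (1-based) delimit a 6-base duplication."""
        five = [
            _aln("chr6", 32_643_463, side="right_of_flank",
                 ltr_end="five_prime", rid=f"f{k}")
            for k in range(3)
        ]
        three = [
            _aln("chr6", 32_643_458, ltr_end="three_prime", rid=f"t{k}")
            for k in range(3)
        ]
        cands, _ = discover_novel(five + three, _cat(("chr6", 100, 200)))
        assert len(cands) == 1
        call = classify_novel(cands[0], max_tsd=10)
        assert call.classification == "novel_non_reference"
        assert call.tsd == (32_643_459, 32_643_464)
        assert call.tsd_len == 6

    def test_single_end_support_is_ambiguous(self):
        alns = [_aln("c", 50_000, ltr_end="five_prime", rid=f"r{k}")
                for k in range(4)]
        cands, _ = discover_novel(alns, _cat(("c", 100, 200)))
        call = classify_novel(cands[0])
        assert call.classification == "ambiguous" and call.tsd is None

    def test_annotated_element_gives_novel_reference_merged_call(self):
        cat = _cat(("c", 100, 200))
        elem = ("c", 50_000, 50_968)
        five = [_aln("c", 49_999, side="right_of_flank",
                     ltr_end="five_prime", rid=f"f{k}") for k in range(2)]
        three = [_aln("c", 50_968, ltr_end="three_prime", rid=f"t{k}")
                 for k in range(2)]
        novel, _ = call_novel(five + three, cat, ltr_annotation=[elem])
        assert len(novel) == 1
        call = novel[0]
        assert call.classification == "novel_reference"
        assert (call.start, call.end) == (50_000, 50_967)
        assert call.supporting_reads == 4


class TestQuantify:
    def test_single_locus_gets_million(self):
        q = quantify({"a": 42}, 42)
        assert q.cpm["a"] == pytest.approx(1e6)

    def test_threshold_at_exactly_fifty(self):
        q = quantify({"a": 5, "b": 4}, 100_000)
        assert q.cpm["a"] == pytest.approx(50.0)
        assert q.detected_filtered["a"] and not q.detected_filtered["b"]
        assert q.detected["b"]

    def test_cpm_ratio_equals_count_ratio(self, rng):
        counts = {f"l{i}": int(rng.integers(1, 500)) for i in range(20)}
        q = quantify(counts, 1_000_000)
        ks = list(counts)
        for a, b in zip(ks, ks[1:]):
            assert q.cpm[a] / q.cpm[b] == pytest.approx(counts[a] / counts[b])

    def test_zero_library_errors(self):
        with pytest.raises(ValueError):
            quantify({}, 0)

    def test_universe_fills_zeros(self):
        q = quantify({"a": 3}, 10, locus_universe=["a", "b"])
        assert q.counts["b"] == 0 and not q.detected["b"]


class TestSaturation:
    @staticmethod
    def _fake_pipeline(pairs):
        # deterministic stand-in: loci = distinct first letters observed
        counts = {}
        for p in pairs:
            counts[p[0]] = counts.get(p[0], 0) + 1
        return quantify(counts, max(len(pairs), 1), cpm_min=0)

    def test_rows_in_input_order_with_na_overflow(self):
        pairs = [f"{c}{i}" for i, c in enumerate("abcabcabca")]
        out = saturation(pairs, [0, 4, 10, 99], self._fake_pipeline, seed=1)
        assert list(out["depth"]) == [0, 4, 10, 99]
        assert out["n_detected"].iloc[0] == 0
        assert np.isnan(out["n_detected"].iloc[3])

    def test_monotone_under_nesting(self, rng):
        pairs = [rng.choice(list("abcdefgh")) + str(i) for i in range(400)]
        depths = [10, 50, 100, 200, 400]
        out = saturation(pairs, depths, self._fake_pipeline, seed=3)
        det = out["n_detected"].tolist()
        assert det == sorted(det)

    def test_unsorted_depths_rejected(self):
        with pytest.raises(ValueError):
            saturation([], [10, 5], self._fake_pipeline, seed=1)
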