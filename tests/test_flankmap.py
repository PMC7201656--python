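"""Genome indexing, unique mapping, SAM interchange."""
import numpy as np
import pytest

from hervkmap.chimera import ChimericHit
from hervkmap.dna import encode, random_seq, revcomp
from hervkmap.flankmap import (
    align_flank,
    build_index,
    export_alignments,
    import_alignments,
    map_flanks,
)


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(42)
    cassette = random_seq(rng, 5000)
    return {
        "c1": random_seq(rng, 30_000),
        "rep": cassette + random_seq(rng, 1000) + cassette
               + random_seq(rng, 1000) + cassette,
    }


@pytest.fixture(scope="module")
def index(genome):
    return build_index(genome, k=13)


def _hit(flank, ltr_end="three_prime", rid="r"):
    return ChimericHit(rid, ltr_end, "x_end", "+", 0, 1.0,
                       flank_seq=flank, flank_qual="I" * len(flank))


def exhaustive_align(flank, genome, max_frac=0.06):
    """All best placements by direct scan of every position and strand."""
    L = len(flank)
    max_mm = int(np.floor(max_frac * L + 1e-9))
    placements = []
    for strand, query in (("+", flank), ("-", revcomp(flank))):
        q = encode(query)
        for contig, seq in genome.items():
            s = encode(seq)
            for pos in range(len(seq) - L + 1):
                mm = int(np.count_nonzero(
                    (s[pos : pos + L] != q) | (s[pos : pos + L] > 3) | (q > 3)
                ))
                if mm <= max_mm:
                    placements.append((mm, strand, contig, pos))
    if not placements:
        return None, "unmapped"
    best_mm = min(p[0] for p in placements)
    best = [p for p in placements if p[0] == best_mm]
    if len(best) > 1:
        return None, "multi_mapped"
    return best[0], "mapped"


class TestIndex:
    def test_lookup_matches_exhaustive_scan(self, rng):
        contigs = {"c": random_seq(rng, 1000)}
        idx = build_index(contigs, k=13)
        seq = contigs["c"]
        for start in range(0, 1000 - 13, 37):
            kmer = seq[start : start + 13]
            true_pos = [
                p for p in range(1000 - 12) if seq[p : p + 13] == kmer
            ]
            assert sorted(idx.lookup(kmer).tolist()) == true_pos

    def test_empty_genome_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_index({})

    def test_short_contigs_skipped_with_survivor(self, rng):
        idx = build_index({"tiny": "ACGT", "ok": random_seq(rng, 100)}, k=13)
        assert idx.names == ["ok"]
        with pytest.raises(ValueError, match="length >= k"):
            build_index({"tiny": "ACGT"}, k=13)

    def test_repeated_cassette_kmers_have_three_positions(self, genome, index):
        kmer = genome["rep"][100:113]
        hits = index.lookup(kmer)
        assert len(hits) == 3


class TestAlign:
    def test_unique_flank_maps_to_its_position(self, genome, index):
        flank = genome["c1"][5000:5200]
        aln, reason = align_flank(_hit(flank), index)
        assert reason == "mapped"
        assert (aln.contig, aln.pos, aln.strand) == ("c1", 5000, "+")
        assert aln.n_best == 1 and aln.junction == 5000
        assert aln.junction_side == "left_of_flank"

    def test_reverse_strand_junction_at_right_edge(self, genome, index):
        flank = revcomp(genome["c1"][5000:5200])
        aln, reason = align_flank(_hit(flank), index)
        assert reason == "mapped" and aln.strand == "-"
        assert aln.junction == 5000 + 200 - 1
        assert aln.junction_side == "right_of_flank"

    def test_cassette_flank_is_multi_mapped(self, genome, index):
        flank = genome["rep"][1000:1250]
        aln, reason = align_flank(_hit(flank), index)
        assert aln is None and reason == "multi_mapped"

    def test_random_flank_unmapped(self, index, rng):
        aln, reason = align_flank(_hit(random_seq(rng, 80)), index)
        assert aln is None and reason == "unmapped"

    def test_short_flank_counted(self, index):
        aln, reason = align_flank(_hit("ACGTACGTA"), index)
        assert aln is None and reason == "too_short"

    def test_oracle_equivalence_with_mismatches(self, rng):
        genome = {"g": random_seq(rng, 8000)}
        idx = build_index(genome, k=13)
        for _ in range(60):
            L = int(rng.integers(20, 220))
            pos = int(rng.integers(0, 8000 - L))
            flank = genome["g"][pos : pos + L]
            # inject up to ~8% mismatches (sometimes beyond the tolerance)
            nmm = int(rng.integers(0, max(2, int(0.08 * L))))
            flank = list(flank)
            for p in rng.choice(L, min(nmm, L), replace=False):
                flank[p] = "ACGT"[("ACGT".index(flank[p]) + 1) % 4]
            flank = "".join(flank)
            if rng.random() < 0.5:
                flank = revcomp(flank)
            want, want_reason = exhaustive_align(flank, genome)
            aln, reason = align_flank(_hit(flank), idx)
            assert reason == want_reason
            if aln is not None:
                mm, strand, contig, p = want
                assert (aln.contig, aln.pos, aln.strand) == (contig, p, strand)
                assert aln.score == len(flank) - mm

    def test_deterministic(self, genome, index):
        flank = genome["c1"][100:260]
        a1, _ = align_flank(_hit(flank), index)
        a2, _ = align_flank(_hit(flank), index)
        assert a1 == a2


class TestSam:
    def test_round_trip(self, genome, index, tmp_path, rng):
        hits = []
        for i in range(30):
            pos = int(rng.integers(0, 25_000))
            L = int(rng.integers(30, 200))
            flank = genome["c1"][pos : pos + L]
            if i % 2:
                flank = revcomp(flank)
            hits.append(_hit(flank, ltr_end="five_prime" if i % 3 else "three_prime",
                             rid=f"r{i}"))
        alignments, _ = map_flanks(hits, index)
        assert alignments
        sam = tmp_path / "flanks.sam"
        export_alignments(
            alignments, sam, {n: len(s) for n, s in genome.items()}
        )
        back, stats = import_alignments(sam)
        assert stats["imported"] == len(alignments)
        assert set(back) == set(alignments)

    def test_mapq_zero_and_secondary_excluded(self, tmp_path):
        sam = tmp_path / "t.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:c1\tLN:1000\n"
            "good|end=five_prime\t0\tc1\t1001\t60\t50M\t*\t0\t0\t*\t*\n"
            "zero|end=five_prime\t0\tc1\t101\t0\t50M\t*\t0\t0\t*\t*\n"
            "sec|end=five_prime\t256\tc1\t201\t60\t50M\t*\t0\t0\t*\t*\n"
            "notag\t0\tc1\t301\t60\t50M\t*\t0\t0\t*\t*\n"
        )
        out, stats = import_alignments(sam)
        assert len(out) == 1
        assert out[0].pos == 1000  # SAM 1-based -> 0-based
        assert stats["excluded_nonunique"] == 2 and stats["missing_tag"] == 1


def test_no_reported_alignment_is_multi_best(small_study, small_result):
    """Uniqueness invariant over a whole study's alignments is enforced by
    construction; repeat-embedded loci consequently go undetected."""
    man = small_study.manifest
    rep_loci = [s.locus_id for s in man.insertions if s.in_repeat]
    assert rep_loci
    for quant in small_result.quants.values():
        for lid in rep_loci:
            assert quant.counts[lid] == 0
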