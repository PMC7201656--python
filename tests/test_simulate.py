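"""Protocol simulator: genome construction, genotypes, read generation."""
import pytest

from hervkmap.dna import revcomp
from hervkmap.simulate import (
    InsertionSpec,
    ProtocolParams,
    build_genome,
    design_experiment,
    simulate_reads,
    _draw_fragment_lengths,
)


def _spec(lid="ins1", site=5000, **kw):
    return InsertionSpec(locus_id=lid, contig="ctg1", site=site, **kw)


class TestBuildGenome:
    def test_zero_insertions_reference_equals_background(self):
        build = build_genome(2, 20_000, [], seed=4)
        assert build.reference == build.background
        assert build.manifest.insertions == []

    def test_nonref_solo_tsd_duplicated_in_carrier_only(self):
        spec = _spec(tsd_len=6, in_reference_sequence=False, age_mya=0.0)
        build = build_genome(1, 20_000, [spec], seed=4)
        lib = build.lib
        # reference assembly lacks the element
        assert lib.consensus["LTR5_Hs"] not in build.reference["ctg1"]
        hap = build.haplotype("A", 0)
        contig, lo, hi = hap["coords"]["ins1"]
        seq = hap["seqs"][contig]
        assert seq[lo:hi] == lib.consensus["LTR5_Hs"]
        assert seq[lo - 6 : lo] == seq[hi : hi + 6]  # duplicated 6-mer

    def test_age_zero_element_equals_consensus(self):
        spec = _spec(age_mya=0.0, ltr_subtype="LTR5A")
        build = build_genome(1, 20_000, [spec], seed=4)
        assert build.manifest.element_seqs["ins1"] == build.lib.consensus["LTR5A"]

    def test_aged_element_accumulates_mutations(self):
        spec = _spec(age_mya=30.0)
        build = build_genome(1, 20_000, [spec], seed=4)
        cons = build.lib.consensus["LTR5_Hs"]
        elem = build.manifest.element_seqs["ins1"]
        diff = sum(a != b for a, b in zip(cons, elem))
        assert diff > 0

    def test_provirus_structure_and_minus_strand(self):
        spec = _spec(element_type="provirus", age_mya=0.0, strand="-")
        build = build_genome(1, 30_000, [spec], seed=4)
        lib = build.lib
        elem = build.manifest.element_seqs["ins1"]
        assert elem == lib.consensus["LTR5_Hs"] + lib.internal + lib.consensus["LTR5_Hs"]
        contig, lo, hi = build.manifest.ref_intervals["ins1"]
        assert build.reference[contig][lo:hi] == revcomp(elem)

    def test_too_close_insertions_error(self):
        with pytest.raises(ValueError, match="1 kb"):
            build_genome(1, 20_000, [_spec("a", 5000), _spec("b", 5500)], seed=4)

    def test_site_outside_contig_error(self):
        with pytest.raises(ValueError, match="contig edge"):
            build_genome(1, 20_000, [_spec(site=19_900)], seed=4)


class TestDesign:
    def test_zero_polymorphic_fraction_identical_genotypes(self):
        specs = [_spec(f"i{k}", 2000 + 1500 * k) for k in range(4)]
        man = design_experiment(specs, 3, 3, 0.0, seed=1)
        for s in specs:
            gts = {man.genotypes[(i, s.locus_id)] for i in man.individuals}
            assert gts == {"hom"}

    def test_paper_scale_design_yields_nine_samples(self):
        man = design_experiment([_spec()], 3, 3, 0.0, seed=1)
        assert len(man.sample_ids) == 9
        assert man.individual_of("B3") == "B"

    def test_polymorphic_loci_have_discordant_pair(self):
        specs = [_spec(f"i{k}", 2000 + 1500 * k, allele_frequency=0.5)
                 for k in range(12)]
        man = design_experiment(specs, 3, 2, 1.0, seed=5)
        for s in specs:
            present = [man.present(i, s.locus_id) for i in man.individuals]
            assert any(present) and not all(present)

    def test_single_individual_with_polymorphism_errors(self):
        with pytest.raises(ValueError, match="2 individuals"):
            design_experiment([_spec()], 1, 3, 0.5, seed=1)


@pytest.fixture(scope="module")
def tiny():
    params = ProtocolParams(seq_error_rate=0.0, ltr_mutation_rate_per_mya=0.0,
                            pcr_duplicate_rate=0.0)
    specs = [_spec("solo1", 5000, age_mya=0.0),
             _spec("prov1", 20_000, element_type="provirus", age_mya=0.0)]
    man = design_experiment(specs, 1, 1, 0.0, seed=9)
    build = build_genome(1, 40_000, specs, seed=9, manifest=man, params=params)
    return build, params


class TestReads:
    def test_fragment_lengths_respect_size_selection(self, rng):
        params = ProtocolParams()
        frags = _draw_fragment_lengths(rng, 10_000, params)
        total = frags + len(params.linker_seq)
        assert total.min() >= 250 and total.max() <= 450

    def test_reads_are_pe150(self, tiny):
        build, params = tiny
        pairs = simulate_reads(build, "A1", "A", params, depth=500, seed=1)
        assert all(len(p.seq1) == 150 and len(p.seq2) == 150 for p in pairs)

    def test_same_seed_byte_identical(self, tiny):
        build, params = tiny
        a = simulate_reads(build, "A1", "A", params, depth=400, seed=7)
        b = simulate_reads(build, "A1", "A", params, depth=400, seed=7)
        assert [(p.read_id, p.seq1, p.seq2) for p in a] == [
            (p.read_id, p.seq1, p.seq2) for p in b
        ]

    def test_depth_zero_errors(self, tiny):
        build, params = tiny
        with pytest.raises(ValueError, match="depth"):
            simulate_reads(build, "A1", "A", params, depth=0, seed=1)

    def test_error_free_flanks_occur_verbatim_in_haplotype(self, tiny):
        """The host portion of every chimeric molecule is a substring of
        the source haplotype (possibly reverse-complemented)."""
        build, params = tiny
        pairs = simulate_reads(build, "A1", "A", params, depth=300, seed=3)
        hap = build.haplotype("A", 0)["seqs"]["ctg1"]
        both = hap + "#" + revcomp(hap)
        checked = 0
        for p in pairs[:120]:
            if "cls=host" not in p.read_id:
                continue
            # R1 = LTR carry (55 nt) + flank start
            flank_piece = p.seq1[params.ltr_carry :]
            assert flank_piece in both
            checked += 1
        assert checked > 10

    def test_counts_scale_with_depth(self, tiny):
        build, params = tiny
        lo = simulate_reads(build, "L", "A", params, depth=2000, seed=5)
        hi = simulate_reads(build, "H", "A", params, depth=8000, seed=5)
        n_lo = build.manifest.sample_stats["L"]["per_insertion_molecules"]["solo1"]
        n_hi = build.manifest.sample_stats["H"]["per_insertion_molecules"]["solo1"]
        assert 3.0 < n_hi / n_lo < 5.3

    def test_internal_molecules_only_from_proviruses(self, tiny):
        build, params = tiny
        pairs = simulate_reads(build, "A2", "A", params, depth=2000, seed=2)
        for p in pairs:
            if "cls=internal" in p.read_id:
                assert "ins=prov1" in p.read_id


def test_study_respects_composition(small_study):
    from hervkmap.catalog import count_by_category

    counts = count_by_category(small_study.catalog)
    assert counts["reference/solo_LTR"] == 12 + 2   # panel solos + repeat-embedded
    assert counts["reference/provirus"] == 3
    assert counts["non_reference/solo_LTR"] == 2
    full = count_by_category(small_study.full_catalog)
    assert full["novel_reference/solo_LTR"] == 1
    assert full["novel_non_reference/solo_LTR"] == 1


def test_offtarget_fraction_tagged_background(small_study):
    pairs = small_study.sample_reads("A3")
    frac = sum("cls=bg" in p.read_id for p in pairs) / len(pairs)
    assert 0.15 < frac < 0.25
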