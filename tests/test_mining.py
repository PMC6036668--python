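"""Seed-and-extend mining, hit merging, RBH classification, flanks, chimeras."""

import numpy as np
import pytest

from htscan.formats import GenomeInterval, SeqRecord, revcomp
from htscan.mining import (
    RawHit,
    TECopy,
    detect_chimeras,
    extract_flanks,
    is_full_length,
    merge_hits,
    mine_genome,
    rbh_classify,
    seed_extend_search,
)
from htscan.phylo import scored_global_align
from htscan.simulate import (
    SimConfig,
    _decode_dna,
    _encode_dna,
    evolve,
    evolve_sequence,
    generate_species_tree,
    make_master_te,
)

from conftest import mutate_substitutions, random_dna


def _plant(query_seq, rng, bg=6000, strand="+"):
    insert = query_seq if strand == "+" else revcomp(query_seq)
    left = random_dna(bg // 2, rng)
    right = random_dna(bg // 2, rng)
    return SeqRecord("scaf1", left + insert + right), bg // 2, bg // 2 + len(insert)


class TestSeedExtend:
    def test_verbatim_plant_exact(self):
        rng = np.random.default_rng(21)
        query = SeqRecord("Q", random_dna(1500, rng))
        genome, start, end = _plant(query.seq, rng)
        hits = seed_extend_search(genome, query)
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.start, hit.end, hit.strand) == (start, end, "+")
        assert hit.identity == 1.0

    def test_reverse_complement_plant(self):
        rng = np.random.default_rng(22)
        query = SeqRecord("Q", random_dna(1500, rng))
        genome, start, end = _plant(query.seq, rng, strand="-")
        hits = seed_extend_search(genome, query)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].strand) == (start, end, "-")

    @pytest.mark.parametrize("seed", range(5))
    def test_ten_percent_divergence_recovered(self, seed):
        rng = np.random.default_rng(300 + seed)
        query = SeqRecord("Q", random_dna(1000, rng))
        mutated = mutate_substitutions(query.seq, 100, rng)
        genome, start, end = _plant(mutated, rng)
        hits = seed_extend_search(genome, query)
        assert len(hits) == 1
        hit = hits[0]
        assert 0.86 <= hit.identity <= 0.94
        # overlap with the planted interval
        assert hit.start < end and start < hit.end
        # identity within 0.02 of the score-based full-DP oracle
        ra, rb = scored_global_align(query.seq, mutated)
        cols = sum(1 for x, y in zip(ra, rb) if x != "-" or y != "-")
        matches = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
        assert abs(hit.identity - matches / cols) <= 0.02

    def test_no_hit_in_random_background(self):
        rng = np.random.default_rng(23)
        query = SeqRecord("Q", random_dna(1000, rng))
        genome = SeqRecord("scaf1", random_dna(20_000, rng))
        assert seed_extend_search(genome, query) == []

    def test_small_word_size_rejected(self):
        with pytest.raises(ValueError):
            seed_extend_search(SeqRecord("g", "ACGT" * 100), SeqRecord("q", "ACGT" * 10), word_size=4)


def _hit(start, end, strand="+", family="BovB", scaffold="s", identity=0.9, q=None):
    q_start, q_end = q if q is not None else (start, end)
    return RawHit(
        scaffold=scaffold,
        start=start,
        end=end,
        strand=strand,
        q_start=q_start,
        q_end=q_end,
        identity=identity,
        score=100.0,
        family=family,
    )


class TestMergeHits:
    def test_abutting_hits_merge(self):
        loci = merge_hits([_hit(0, 100), _hit(100, 220)], max_gap=500)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (0, 220)

    def test_opposite_strands_never_merge(self):
        loci = merge_hits([_hit(0, 100), _hit(100, 200, strand="-")], max_gap=500)
        assert len(loci) == 2

    def test_gap_rule(self):
        loci = merge_hits(
            [_hit(0, 100), _hit(150, 250), _hit(5250, 5350)], max_gap=500
        )
        assert len(loci) == 2

    def test_identity_is_length_weighted(self):
        loci = merge_hits(
            [_hit(0, 100, identity=1.0), _hit(100, 400, identity=0.8)], max_gap=10
        )
        assert loci[0].identity == pytest.approx((100 * 1.0 + 300 * 0.8) / 400)

    def test_tandem_copies_with_restarting_query_stay_separate(self):
        # two full-length copies of the same query 200 bp apart: the second
        # hit restarts query coverage, so they are distinct loci
        loci = merge_hits(
            [_hit(0, 3200, q=(0, 3200)), _hit(3400, 6600, q=(0, 3200))], max_gap=500
        )
        assert len(loci) == 2

    def test_fragmented_copy_rejoins(self):
        # one copy split by a genomic deletion: query coverage advances
        loci = merge_hits(
            [_hit(0, 1500, q=(0, 1500)), _hit(1500, 3100, q=(1550, 3150))],
            max_gap=500,
        )
        assert len(loci) == 1


@pytest.fixture(scope="module")
def library():
    return [
        make_master_te(3200, seed=31, family="BovB"),
        make_master_te(3500, seed=32, family="L1"),
        make_master_te(3200, seed=33, family="RTE"),
    ]


class TestRBHClassify:

    def test_bovb_locus_confirmed(self, library):
        rng = np.random.default_rng(24)
        locus = _decode_dna(
            evolve_sequence(_encode_dna(library[0].seq), 0.05, 2.0, rng)
        )
        family, confirmed = rbh_classify(locus, library, "BovB")
        assert (family, confirmed) == ("BovB", True)

    def test_cross_family_relabelling(self, library):
        # a locus actually derived from RTE but mined with the BovB query
        rng = np.random.default_rng(25)
        locus = _decode_dna(
            evolve_sequence(_encode_dna(library[2].seq), 0.05, 2.0, rng)
        )
        family, confirmed = rbh_classify(locus, library, "BovB")
        assert family == "RTE"
        assert confirmed is False

    def test_random_sequence_unclassified(self, library):
        rng = np.random.default_rng(26)
        family, confirmed = rbh_classify(random_dna(2000, rng), library, "BovB")
        assert (family, confirmed) == ("unclassified", False)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            rbh_classify("ACGT" * 100, [], "BovB")


class TestFlanks:
    def _copy(self, start, end, strand="+"):
        return TECopy(
            copy_id="c1",
            species="sp1",
            interval=GenomeInterval("scaf1", start, end, strand),
            family="BovB",
            identity_to_query=0.9,
            seq="A" * (end - start),
        )

    def test_interior_copy_full_flanks(self):
        rng = np.random.default_rng(27)
        genome = SeqRecord("scaf1", random_dna(5000, rng))
        flanks = extract_flanks(self._copy(2000, 2500), genome, flank_len=1000)
        assert len(flanks.left) == len(flanks.right) == 1000
        assert not flanks.left_truncated and not flanks.right_truncated
        assert flanks.left == genome.seq[1000:2000]
        assert flanks.right == genome.seq[2500:3500]

    def test_scaffold_start_truncates_left(self):
        rng = np.random.default_rng(28)
        genome = SeqRecord("scaf1", random_dna(3000, rng))
        flanks = extract_flanks(self._copy(100, 700), genome, flank_len=1000)
        assert flanks.left_truncated
        assert len(flanks.left) == 100

    def test_minus_strand_orientation(self):
        rng = np.random.default_rng(29)
        genome = SeqRecord("scaf1", random_dna(4000, rng))
        flanks = extract_flanks(self._copy(1500, 2000, strand="-"), genome, flank_len=500)
        # 5' flank of a minus-strand element is the downstream genomic region
        assert flanks.left == revcomp(genome.seq[2000:2500])
        assert flanks.right == revcomp(genome.seq[1000:1500])


class TestChimeras:
    def test_nested_insertion_reported(self):
        rng = np.random.default_rng(30)
        bovb = make_master_te(3200, seed=41, family="BovB")
        l1 = make_master_te(3500, seed=42, family="L1")
        genome = SeqRecord(
            "scafX",
            random_dna(4000, rng)
            + bovb.seq[:1600]
            + l1.seq
            + bovb.seq[1600:]
            + random_dna(4000, rng),
        )
        loci = []
        for q in (bovb, l1):
            loci.extend(merge_hits(seed_extend_search(genome, q)))
        chimeras = detect_chimeras(loci)
        nested = [c for c in chimeras if c.relation == "nested"]
        assert len(nested) == 1
        assert (nested[0].outer_family, nested[0].inner_family) == ("BovB", "L1")

    def test_disjoint_loci_not_chimeric(self):
        loci = [_hit(0, 3000, family="BovB"), _hit(10_000, 13_000, family="L1")]
        assert detect_chimeras(loci) == []

    def test_same_family_overlap_ignored(self):
        loci = [_hit(0, 3000, family="BovB"), _hit(2900, 5900, family="BovB")]
        assert detect_chimeras(loci) == []


class TestFullLengthFilter:
    def test_bovb_bounds_verbatim(self):
        lengths = [2300, 2400, 3999, 4000]
        kept = [l for l in lengths if is_full_length("BovB", l)]
        assert kept == [2400, 3999]

    def test_l1_bounds(self):
        assert not is_full_length("L1", 2999)
        assert is_full_length("L1", 3000)
        assert is_full_length("L1", 8999)
        assert not is_full_length("L1", 9000)


class TestMineGenomeOnSimulation:
    @pytest.mark.parametrize("seed", range(3))
    def test_recall_and_precision(self, seed):
        tree = generate_species_tree(6, seed=seed, height=0.18)
        config = SimConfig(
            species_tree=tree, seed=seed + 400, background_genome_length=40_000
        )
        result = evolve(config)
        library = [config.master_te]
        total = found = 0
        for species, genome in result.genomes.items():
            copies = mine_genome(genome, library, species)
            truth = [t for t in result.truth if t.species == species and t.interval]
            total += len(truth)
            for t in truth:
                if any(
                    c.interval.start < t.interval.end
                    and t.interval.start < c.interval.end
                    for c in copies
                ):
                    found += 1
            for c in copies:  # precision: every locus overlaps a truth interval
                assert any(
                    c.interval.start < t.interval.end
                    and t.interval.start < c.interval.end
                    for t in truth
                )
        assert found / total >= 0.95

    def test_copy_sequences_are_strand_normalised_slices(self, sim_vertical):
        result, _, _ = sim_vertical
        genome = result.genomes["sp1"]
        copies = mine_genome(genome, [result.config.master_te], "sp1")
        for c in copies:
            assert c.seq == c.interval.extract(genome.seq)
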