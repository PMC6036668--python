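"""K2P distances, MSA, conserved blocks, NJ/bootstrap trees, landscapes."""

import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from htscan.formats import SeqRecord, revcomp, tree_from_string
from htscan.phylo import (
    DistanceMatrix,
    SaturationError,
    align_progressive,
    bootstrap,
    conserved_blocks,
    divergence_landscape,
    k2p,
    k2p_pair,
    nj_tree,
    rf_distance,
    scored_global_align,
    tree_splits,
)
from htscan.simulate import (
    _decode_dna,
    _encode_dna,
    evolve_sequence,
    generate_species_tree,
    make_master_te,
)

from conftest import random_dna


def _pair_with_counts(n_sites, n_transitions, n_transversions):
    a = "A" * n_sites
    b = (
        "G" * n_transitions
        + "C" * n_transversions
        + "A" * (n_sites - n_transitions - n_transversions)
    )
    return a, b


class TestK2P:
    def test_closed_form_matches_independent_evaluation(self):
        a, b = _pair_with_counts(100, 10, 5)
        p, q, k = k2p(a, b)
        assert (p, q) == (0.10, 0.05)
        expected = -0.5 * math.log((1 - 2 * 0.10 - 0.05) * math.sqrt(1 - 2 * 0.05))
        assert k == pytest.approx(expected, abs=1e-12)

    def test_identical_pair_is_exactly_zero(self):
        p, q, k = k2p("ACGTACGT", "ACGTACGT")
        assert (p, q, k) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("p_frac,q_frac", [(0.45, 0.10), (0.10, 0.50)])
    def test_saturation_raises(self, p_frac, q_frac):
        a, b = _pair_with_counts(100, int(100 * p_frac), int(100 * q_frac))
        with pytest.raises(SaturationError):
            k2p(a, b)

    def test_gap_and_n_columns_excluded(self):
        p, q, k = k2p("ACG-NT", "ACGTAT")
        assert (p, q, k) == (0.0, 0.0, 0.0)

    def test_k_dominates_p_distance(self):
        # Jensen: the K2P correction can only stretch observed divergence
        rng = np.random.default_rng(0)
        for t in (0.05, 0.2, 0.4):
            a = _encode_dna(random_dna(2000, rng))
            b = evolve_sequence(a, t, 2.0, rng)
            p, q, k = k2p(_decode_dna(a), _decode_dna(b))
            assert k >= p + q

    def test_k2p_estimator_recovers_simulated_distance(self):
        rng = np.random.default_rng(1)
        a = _encode_dna(random_dna(5000, rng))
        b = evolve_sequence(a, 0.25, 2.0, rng)
        _, _, k = k2p(_decode_dna(a), _decode_dna(b))
        assert k == pytest.approx(0.25, abs=0.03)


class TestScoredAlignment:
    def test_substitution_only_pair_aligns_gapless(self):
        rng = np.random.default_rng(2)
        a = random_dna(500, rng)
        b = _decode_dna(evolve_sequence(_encode_dna(a), 0.1, 2.0, rng))
        ra, rb = scored_global_align(a, b)
        assert "-" not in ra and "-" not in rb

    def test_terminal_overhang_becomes_end_gaps(self):
        a = "ACGTACGTAC"
        b = "GGG" + a
        ra, rb = scored_global_align(a, b)
        assert ra == "---" + a
        assert rb == b


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        # unrooted tree: a,b joined to u; c,d to v; u-v internal edge 2
        m = np.array(
            [[0, 3, 6, 7], [3, 0, 7, 8], [6, 7, 0, 7], [7, 8, 7, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(["a", "b", "c", "d"], m))
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, x in enumerate("abcd"):
            for j, y in enumerate("abcd"):
                if i < j:
                    assert pdm.patristic_distance(taxa[x], taxa[y]) == pytest.approx(
                        m[i, j], abs=1e-9
                    )

    def test_three_taxa_star(self):
        m = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], m))
        assert len(tree.leaf_nodes()) == 3
        assert len(tree.seed_node.child_nodes()) == 3

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_random_tree_topologies(self, seed):
        tree = generate_species_tree(8, seed=seed, height=0.5)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
        n = len(taxa)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
        recovered = nj_tree(DistanceMatrix([t.label for t in taxa], m))
        assert rf_distance(tree, recovered) == 0

    def test_ultrametric_matrix_matches_upgma_topology(self):
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        tree = generate_species_tree(6, seed=5, height=1.0)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
        n = len(taxa)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
        nj = nj_tree(DistanceMatrix([t.label for t in taxa], m))
        Z = hierarchy.linkage(squareform(m, checks=False), method="average")
        # rebuild the UPGMA tree as newick and compare splits
        labels = [t.label for t in taxa]
        nodes = {i: labels[i] for i in range(n)}
        for k, (a, b, _, _) in enumerate(Z):
            nodes[n + k] = f"({nodes.pop(int(a))},{nodes.pop(int(b))})"
        upgma = tree_from_string(next(iter(nodes.values())) + ";")
        assert rf_distance(nj, upgma) == 0


class TestRFDistance:
    def test_identical_zero(self):
        t = generate_species_tree(7, seed=2, height=0.4)
        assert rf_distance(t, t) == 0

    def test_four_taxon_swap(self):
        t1 = tree_from_string("((a,b),(c,d));")
        t2 = tree_from_string("((a,c),(b,d));")
        assert rf_distance(t1, t2) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dendropy_oracle(self, seed):
        t1 = generate_species_tree(8, seed=seed, height=0.4)
        t2 = generate_species_tree(8, seed=seed + 50, height=0.4)
        ns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(
            data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=ns
        )
        b = dendropy.Tree.get(
            data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=ns
        )
        a.encode_bipartitions()
        b.encode_bipartitions()
        expected = treecompare.symmetric_difference(a, b)
        assert rf_distance(t1, t2) == expected


class TestProgressiveAlignment:
    def test_identical_sequences_gapless(self):
        seqs = [SeqRecord(f"s{i}", "ACGTACGTAACCGGTT") for i in range(4)]
        msa = align_progressive(seqs)
        assert all("-" not in r.seq for r in msa)

    def test_substitution_only_family_aligns_gapless(self):
        # simulated copies carry no indels, so homologous columns line up 1:1
        rng = np.random.default_rng(3)
        base = _encode_dna(random_dna(400, rng))
        seqs = [
            SeqRecord(f"s{i}", _decode_dna(evolve_sequence(base, 0.05, 2.0, rng)))
            for i in range(10)
        ]
        msa = align_progressive(seqs)
        assert all(len(r.seq) == 400 for r in msa)
        assert all("-" not in r.seq for r in msa)

    def test_two_sequences_handle_indel(self):
        msa = align_progressive(
            [SeqRecord("a", "ACGTACGTACGT"), SeqRecord("b", "ACGTACGT")]
        )
        assert len(msa[0].seq) == len(msa[1].seq)
        assert msa[0].seq.replace("-", "") == "ACGTACGTACGT"
        assert msa[1].seq.replace("-", "") == "ACGTACGT"

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            align_progressive([SeqRecord("a", "ACGT")])


class TestConservedBlocks:
    def test_fully_conserved_unchanged(self):
        msa = [SeqRecord(f"s{i}", "ACGTACGTAC") for i in range(4)]
        out = conserved_blocks(msa, min_block=5)
        assert [r.seq for r in out] == ["ACGTACGTAC"] * 4

    def test_alternating_columns_yield_nothing(self):
        # conserved columns never run 5 in a row
        rows = ["ANANANANAN", "ACACACACAC", "AGAGAGAGAG", "ATATATATAT"]
        msa = [SeqRecord(f"s{i}", r) for i, r in enumerate(rows)]
        assert conserved_blocks(msa, min_block=5) == []

    def test_planted_block_extracted_exactly(self):
        rng = np.random.default_rng(4)
        block = random_dna(20, rng)
        noise_cols = 8
        rows = []
        for i in range(8):
            # noise columns cycle bases so no character reaches half
            left = "".join("ACGT"[(i + j) % 4] for j in range(noise_cols))
            right = "".join("ACGT"[(i + j + 1) % 4] for j in range(noise_cols))
            rows.append(left + block + right)
        msa = [SeqRecord(f"s{i}", r) for i, r in enumerate(rows)]
        out = conserved_blocks(msa, min_block=5)
        assert [r.seq for r in out] == [block] * 8


@pytest.fixture(scope="module")
def two_clade_msa():
    rng = np.random.default_rng(5)
    base = _encode_dna(random_dna(800, rng))
    anc1 = evolve_sequence(base, 0.15, 2.0, rng)
    anc2 = evolve_sequence(base, 0.15, 2.0, rng)
    return [
        SeqRecord(f"t{i}", _decode_dna(evolve_sequence(anc, 0.02, 2.0, rng)))
        for i, anc in enumerate([anc1] * 3 + [anc2] * 3)
    ]


class TestBootstrap:
    def test_clean_split_has_high_support(self, two_clade_msa):
        tree = bootstrap(two_clade_msa, n_reps=100, seed=0)
        focal = frozenset({"t3", "t4", "t5"})
        supports = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None or node.label is None:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            supports[side] = float(node.label)
        assert supports.get(focal, supports.get(frozenset({"t0", "t1", "t2"}), 0)) >= 0.95

    def test_single_replicate_supports_binary(self, two_clade_msa):
        tree = bootstrap(two_clade_msa, n_reps=1, seed=3)
        for node in tree.preorder_node_iter():
            if node.label is not None and not node.is_leaf():
                assert float(node.label) in (0.0, 1.0)

    def test_same_seed_reproducible(self, two_clade_msa):
        t1 = bootstrap(two_clade_msa, n_reps=20, seed=9)
        t2 = bootstrap(two_clade_msa, n_reps=20, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


class TestDivergenceLandscape:
    def test_identical_copies_in_first_bin(self, master):
        copies = [SeqRecord(f"c{i}", master.seq) for i in range(3)]
        profile = divergence_landscape(copies, master)
        assert profile.modal_bin() == 0
        assert set(profile.coverage) == {0}

    def test_total_coverage_equals_aligned_length(self, master):
        rng = np.random.default_rng(6)
        codes = _encode_dna(master.seq)
        copies = [
            SeqRecord(f"c{i}", _decode_dna(evolve_sequence(codes, 0.08, 2.0, rng)))
            for i in range(5)
        ]
        profile = divergence_landscape(copies, master)
        # coverage is the aligned copy length; end-gap-free alignment may
        # release a handful of terminal mismatch columns
        assert 0.99 * 5 * len(master.seq) <= profile.total_coverage <= 5 * len(master.seq)
        assert profile.n_excluded == 0

    def test_unrelated_copy_excluded(self, master):
        rng = np.random.default_rng(7)
        junk = SeqRecord("junk", random_dna(3000, rng))
        profile = divergence_landscape([junk], master)
        assert profile.n_excluded == 1
        assert profile.total_coverage == 0


class TestDistanceMatrixValidation:
    def test_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_infinite_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, np.inf], [np.inf, 0.0]]))

    def test_incomparable_pair_raises_not_inf(self):
        # homopolymer pair: no alignable homology, so the distance cannot be
        # formed — an error, never an infinite entry
        a = SeqRecord("a", "A" * 300)
        b = SeqRecord("b", "G" * 300)
        with pytest.raises(ValueError):
            DistanceMatrix.from_k2p([a, b])
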