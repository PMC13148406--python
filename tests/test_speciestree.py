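import itertools

import dendropy
import numpy as np
import pytest
from helpers import (
    all_topologies_newick,
    induced_quartet_split,
    random_binary_newick,
)

from markerphylo.alignment import MarkerAlignment
from markerphylo.errors import InputError
from markerphylo.speciestree import (
    Supermatrix,
    bipartitions,
    bootstrap_support,
    check_monophyly,
    concat_supermatrix,
    infer_consensus_tree,
    quartet_score,
    read_newick,
    rf_distance,
    site_concordance,
    tree_tips,
    write_newick,
)


def msa(marker, rows, taxa=None, seqtype="pep"):
    taxa = taxa or [f"t{i}" for i in range(len(rows))]
    return MarkerAlignment(marker, taxa, rows, seqtype)


class TestSupermatrix:
    def test_widths_and_partitions(self):
        a = msa("a", ["M" * 10] * 4)
        b = msa("b", ["K" * 15] * 4)
        sm = concat_supermatrix([b, a])  # order must come out sorted
        assert sm.alignment.width == 25
        assert sm.partitions == [("a", 1, 10), ("b", 11, 25)]
        sm.validate()

    def test_missing_taxon_filled_with_gaps(self):
        a = msa("a", ["MMM"] * 4, taxa=["t0", "t1", "t2", "t3"])
        b = msa("b", ["KK"] * 3, taxa=["t0", "t1", "t2"])
        sm = concat_supermatrix([a, b])
        row = sm.alignment.row("t3")
        assert row == "MMM--"

    def test_single_marker_identity(self):
        a = msa("a", ["MKV"] * 4)
        sm = concat_supermatrix([a])
        assert sm.alignment.rows == a.rows
        assert sm.partitions == [("a", 1, 3)]

    def test_conflicting_seqtypes_rejected(self):
        a = msa("a", ["MKV"] * 4)
        b = msa("b", ["ACG"] * 4, seqtype="cds-codon")
        with pytest.raises(InputError):
            concat_supermatrix([a, b])

    def test_partition_file_roundtrip(self, tmp_path):
        a = msa("a", ["M" * 7] * 4)
        b = msa("b", ["K" * 5] * 4)
        sm = concat_supermatrix([a, b])
        p = tmp_path / "parts.txt"
        sm.write_partitions(p)
        assert Supermatrix.read_partitions(p) == sm.partitions


class TestQuartetScore:
    def test_identical_trees_score_all_quartets(self):
        nwk = "((a,b),(c,d),e);"
        species = read_newick(nwk)
        genes = [read_newick(nwk) for _ in range(3)]
        # C(5,4) = 5 quartets per tree
        assert quartet_score(species, genes) == 15

    def test_symmetric_on_equal_tip_sets(self, rng):
        labels = [f"t{i}" for i in range(6)]
        t1 = read_newick(random_binary_newick(rng, labels))
        t2 = read_newick(random_binary_newick(rng, labels))
        assert quartet_score(t1, [t2]) == quartet_score(t2, [t1])

    def test_matches_split_based_oracle(self, rng):
        """Random 6-taxon pairs vs an independent all-quartets comparison
        driven by bipartition separation rather than distances."""
        labels = [f"t{i}" for i in range(6)]
        for _ in range(10):
            sp = read_newick(random_binary_newick(rng, labels))
            gt = read_newick(random_binary_newick(rng, labels))
            expected = 0
            sp_splits, gt_splits = bipartitions(sp), bipartitions(gt)
            all_tips = frozenset(labels)
            for quartet in itertools.combinations(labels, 4):
                qs = induced_quartet_split(sp_splits, all_tips, *quartet)
                qg = induced_quartet_split(gt_splits, all_tips, *quartet)
                if qs is not None and qs == qg:
                    expected += 1
            assert quartet_score(sp, [gt]) == expected

    def test_unknown_tip_rejected(self):
        sp = read_newick("((a,b),(c,d),e);")
        gt = read_newick("((a,b),(c,z),e);")
        with pytest.raises(InputError):
            quartet_score(sp, [gt])


class TestConsensus:
    def test_unanimous_gene_trees_recovered(self, rng):
        labels = [f"t{i}" for i in range(7)]
        nwk = random_binary_newick(rng, labels)
        genes = [read_newick(nwk) for _ in range(5)]
        est = infer_consensus_tree(genes)
        assert rf_distance(est, read_newick(nwk))[0] == 0

    def test_matches_exhaustive_search(self, rng):
        """The returned topology achieves the maximum quartet score over an
        independently enumerated set of all 6-taxon topologies."""
        labels = [f"t{i}" for i in range(6)]
        topologies = all_topologies_newick(labels)
        assert len(topologies) == 105
        for _ in range(5):
            genes = [read_newick(random_binary_newick(rng, labels)) for _ in range(10)]
            est = infer_consensus_tree(genes)
            best = max(quartet_score(read_newick(t), genes) for t in topologies)
            assert quartet_score(est, genes) == best

    def test_majority_beats_disjoint_minorities(self):
        major = "((a,b),(c,d),(e,f));"
        minor1 = "((a,c),(b,d),(e,f));"
        minor2 = "((a,b),(c,e),(d,f));"
        genes = [read_newick(major)] * 6 + [read_newick(minor1)] * 2 + [read_newick(minor2)] * 2
        est = infer_consensus_tree(genes)
        assert rf_distance(est, read_newick(major))[0] == 0

    def test_gene_trees_with_missing_taxa_supported(self, rng):
        labels = [f"t{i}" for i in range(6)]
        full = random_binary_newick(rng, labels)
        genes = [read_newick(full)]
        # prune two taxa from a second tree by rebuilding from 4 labels
        sub = read_newick("((t0,t1),(t2,t3));")
        est = infer_consensus_tree(genes + [sub] * 3)
        assert set(tree_tips(est)) == set(labels)

    def test_large_taxon_sets_use_hill_climbing(self, rng):
        labels = [f"t{i:02d}" for i in range(10)]
        nwk = random_binary_newick(rng, labels)
        genes = [read_newick(nwk) for _ in range(8)]
        est = infer_consensus_tree(genes)
        assert rf_distance(est, read_newick(nwk))[0] == 0

    def test_too_few_tips_rejected(self):
        with pytest.raises(InputError):
            infer_consensus_tree([read_newick("(a,b,c);")])


class TestRobinsonFoulds:
    def test_identical_trees(self, rng):
        labels = [f"t{i}" for i in range(8)]
        t = random_binary_newick(rng, labels)
        assert rf_distance(read_newick(t), read_newick(t)) == (0, 0.0)

    def test_four_taxon_maximum(self):
        t1 = read_newick("((a,b),(c,d));")
        t2 = read_newick("((a,c),(b,d));")
        assert rf_distance(t1, t2) == (2, 1.0)

    def test_symmetry_and_triangle_inequality(self, rng):
        labels = [f"t{i}" for i in range(7)]
        trees = [read_newick(random_binary_newick(rng, labels)) for _ in range(6)]
        for a, b in itertools.combinations(trees, 2):
            assert rf_distance(a, b)[0] == rf_distance(b, a)[0]
        for a, b, c in itertools.combinations(trees, 3):
            assert rf_distance(a, c)[0] <= rf_distance(a, b)[0] + rf_distance(b, c)[0]

    def test_agrees_with_dendropy(self, rng):
        """Cross-check raw symmetric difference against dendropy's
        implementation on a shared taxon namespace."""
        labels = [f"t{i}" for i in range(8)]
        ns = dendropy.TaxonNamespace()
        for _ in range(5):
            n1 = random_binary_newick(rng, labels)
            n2 = random_binary_newick(rng, labels)
            ours = rf_distance(read_newick(n1), read_newick(n2))[0]
            d1 = dendropy.Tree.get(data=n1, schema="newick", taxon_namespace=ns)
            d2 = dendropy.Tree.get(data=n2, schema="newick", taxon_namespace=ns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            theirs = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert ours == theirs

    def test_differing_tip_sets_rejected(self):
        with pytest.raises(InputError):
            rf_distance(read_newick("((a,b),(c,d));"), read_newick("((a,b),(c,e));"))

    def test_newick_roundtrip_preserves_topology_and_lengths(self, rng, tmp_path):
        labels = [f"t{i}" for i in range(6)]
        tree = read_newick(random_binary_newick(rng, labels))
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        assert rf_distance(tree, back)[0] == 0
        from helpers import split_length_map

        for split, length in split_length_map(tree).items():
            assert split_length_map(back)[split] == pytest.approx(length, abs=1e-9)


class TestMonophyly:
    def test_clade_group_is_monophyletic(self):
        tree = read_newick("(((a1,a2),a3),(b1,b2),c1);")
        groups = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "c1": "C"}
        status = check_monophyly(tree, groups)
        assert status == {"A": True, "B": True, "C": True}

    def test_interleaved_groups_on_caterpillar(self):
        tree = read_newick("(a1,b1,(a2,(b2,(a3,b3))));")
        groups = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
        status = check_monophyly(tree, groups)
        assert status == {"A": False, "B": False}

    def test_singleton_is_monophyletic_by_convention(self):
        tree = read_newick("((a,b),(c,d));")
        status = check_monophyly(tree, {"a": "G1", "b": "G2", "c": "G2", "d": "G2"})
        assert status["G1"] is True

    def test_unlabeled_tip_rejected(self):
        tree = read_newick("((a,b),(c,d));")
        with pytest.raises(InputError):
            check_monophyly(tree, {"a": "G", "b": "G", "c": "G"})


def _evolve_on_tree(nwk, n_sites, rng, rate=0.3):
    """Tiny peptide evolver for support tests (independent of fixtures)."""
    from markerphylo.fixtures import evolve_marker_alignments, SimulationSpec

    tree = read_newick(nwk)
    spec = SimulationSpec(n_taxa=len(tree_tips(tree)), n_markers=1,
                          marker_length=n_sites, substitution_rate=rate,
                          seed=int(rng.integers(0, 2**31)))
    return tree, evolve_marker_alignments(tree, spec)[0]


class TestBranchSupport:
    NWK = "((a:0.05,b:0.05):0.1,(c:0.05,d:0.05):0.1,(e:0.05,f:0.05):0.1);"

    def test_bootstrap_deterministic_given_seed(self, rng):
        _, aln = _evolve_on_tree(self.NWK, 200, rng)
        sm = concat_supermatrix([aln])
        t1 = bootstrap_support(sm, B=20, seed=5)
        t2 = bootstrap_support(sm, B=20, seed=5)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_supports_within_range_and_strong_signal_high(self, rng):
        tree, aln = _evolve_on_tree(self.NWK, 2000, rng)
        sm = concat_supermatrix([aln])
        est = bootstrap_support(sm, B=50, seed=3)
        supports = [float(nd.label) for nd in est.preorder_node_iter()
                    if not nd.is_leaf() and nd.parent_node is not None and nd.label]
        assert supports and all(0.0 <= s <= 100.0 for s in supports)
        # conflict-free, long alignment: every true split strongly supported
        assert rf_distance(est, tree)[0] == 0
        assert all(s >= 95.0 for s in supports)

    def test_scf_high_without_homoplasy(self, rng):
        """Sites generated by single mutations on tree edges can only
        support splits of the tree itself."""
        tree = read_newick(self.NWK)
        tips = tree_tips(tree)
        splits = list(bipartitions(tree)) + [frozenset([t]) for t in tips]
        all_tips = set(tips)
        rows = {t: [] for t in tips}
        for j in range(400):
            side = splits[int(rng.integers(0, len(splits)))]
            for t in tips:
                rows[t].append("W" if t in side else "A")
        aln = MarkerAlignment("m", tips, ["".join(rows[t]) for t in tips], "pep")
        sm = concat_supermatrix([aln])
        scf = site_concordance(tree, sm, q=30, seed=9)
        assert scf, "no internal branches assessed"
        for split, value in scf.items():
            assert value is not None and value > 90.0

    def test_scf_missing_on_constant_alignment(self, rng):
        tree = read_newick(self.NWK)
        aln = MarkerAlignment("m", tree_tips(tree), ["AAAA"] * 6, "pep")
        sm = concat_supermatrix([aln])
        scf = site_concordance(tree, sm, q=10, seed=1)
        assert all(v is None for v in scf.values())

    def test_scf_deterministic_given_seed(self, rng):
        _, aln = _evolve_on_tree(self.NWK, 300, rng)
        sm = concat_supermatrix([aln])
        assert site_concordance(_tree(self.NWK), sm, q=20, seed=4) == \
            site_concordance(_tree(self.NWK), sm, q=20, seed=4)


def _tree(nwk):
    return read_newick(nwk)
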