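import itertools

import pytest

from coaltest.trees import (
    NewickError,
    TreeError,
    internal_supports,
    leaf_labels,
    nrfd,
    parse_newick,
    prune_to_common_leaves,
    prune_to_taxa,
    rf_distance,
    root_by_outgroup,
    write_newick,
)


class TestParseNewick:
    def test_rooted_three_leaves(self):
        t = parse_newick("((A,B),C);")
        assert leaf_labels(t) == {"A", "B", "C"}
        assert t.is_rooted
        assert len(t.seed_node.child_nodes()) == 2

    def test_supports_and_lengths(self):
        t = parse_newick("((A:1,B:1)0.95:0.5,C:2);")
        assert internal_supports(t) == [0.95]
        (leaf_c,) = [l for l in t.leaf_node_iter() if l.taxon.label == "C"]
        assert leaf_c.edge.length == 2

    def test_duplicate_label_error(self):
        with pytest.raises(NewickError, match="A"):
            parse_newick("((A,B),(A,C));")

    def test_empty_input_error(self):
        with pytest.raises(NewickError):
            parse_newick("")
        with pytest.raises(NewickError):
            parse_newick("   ")

    def test_malformed_error(self):
        with pytest.raises(NewickError):
            parse_newick("((A,B),C;")

    def test_trifurcating_root_is_unrooted(self):
        assert not parse_newick("(A,B,(C,D));").is_rooted


class TestWriteNewick:
    def test_round_trip_topology(self):
        t = parse_newick("((A,B),C);")
        t2 = parse_newick(write_newick(t))
        assert leaf_labels(t2) == leaf_labels(t)
        assert rf_distance(t, t2, rooted=True) == 0

    def test_round_trip_lengths_and_supports(self):
        s = "((A:1,B:1)0.95:0.5,C:2);"
        t2 = parse_newick(write_newick(parse_newick(s)))
        assert internal_supports(t2) == [0.95]
        lengths = {l.taxon.label: l.edge.length for l in t2.leaf_node_iter()}
        assert lengths == {"A": 1, "B": 1, "C": 2}

    def test_precision(self):
        t = parse_newick("(A:0.123456789,B:1);")
        assert "0.123457" in write_newick(t)
        assert "0.123" in write_newick(t, precision=3)

    def test_empty_tree_error(self):
        with pytest.raises(TreeError):
            write_newick(None)


class TestRootByOutgroup:
    def test_single_outgroup(self):
        r = root_by_outgroup(parse_newick("(A,B,(C,D));"), "D")
        assert r.is_rooted
        sides = [frozenset(l.taxon.label for l in k.leaf_iter())
                 for k in r.seed_node.child_nodes()]
        assert frozenset(["D"]) in sides
        assert frozenset(["A", "B", "C"]) in sides

    def test_outgroup_pair(self):
        r = root_by_outgroup(parse_newick("(A,(B,(C,D)));"), {"C", "D"})
        sides = [frozenset(l.taxon.label for l in k.leaf_iter())
                 for k in r.seed_node.child_nodes()]
        assert frozenset(["C", "D"]) in sides

    def test_missing_outgroup_error(self):
        with pytest.raises(TreeError, match="X"):
            root_by_outgroup(parse_newick("((A,B),C);"), "X")

    def test_non_monophyletic_error(self):
        with pytest.raises(TreeError, match="monophyletic"):
            root_by_outgroup(parse_newick("((A,C),(B,D));"), {"A", "B"})

    def test_drop_outgroup(self):
        r = root_by_outgroup(parse_newick("(A,B,(C,D));"), "D", drop_outgroup=True)
        assert leaf_labels(r) == {"A", "B", "C"}

    def test_edge_length_split(self):
        r = root_by_outgroup(parse_newick("(A:1,B:1,(C:1,D:1):0.8);"), {"C", "D"})
        kids = r.seed_node.child_nodes()
        assert sum(k.edge.length for k in kids) == pytest.approx(0.8)


class TestPrune:
    def test_shared_leaves(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,B),(C,E));")
        p1, p2 = prune_to_common_leaves(t1, t2)
        assert leaf_labels(p1) == leaf_labels(p2) == {"A", "B", "C"}

    def test_merged_edge_lengths_sum(self):
        t = parse_newick("((A:0.1,B:1):0.2,(C:1,D:1):1);")
        p = prune_to_taxa(t, {"A", "C", "D"})
        (leaf_a,) = [l for l in p.leaf_node_iter() if l.taxon.label == "A"]
        assert leaf_a.edge.length == pytest.approx(0.3)

    def test_disjoint_error(self):
        with pytest.raises(TreeError, match="0 shared"):
            prune_to_common_leaves(parse_newick("((A,B),C);"),
                                   parse_newick("((X,Y),Z);"))

    def test_path_length_preservation(self):
        # pruning must preserve leaf-to-leaf path lengths among survivors
        t = parse_newick("(((A:0.1,B:0.2):0.3,C:0.4):0.5,(D:0.6,E:0.7):0.8);")
        full = t.phylogenetic_distance_matrix()
        dist_full = {
            frozenset((a.label, b.label)): full.distance(a, b)
            for a, b in itertools.combinations(t.taxon_namespace, 2)
        }
        p = prune_to_taxa(t, {"A", "C", "E"})
        pm = p.phylogenetic_distance_matrix()
        for a, b in itertools.combinations(p.taxon_namespace, 2):
            assert pm.distance(a, b) == pytest.approx(
                dist_full[frozenset((a.label, b.label))])


def _all_quintet_topologies():
    """The 15 unrooted binary 5-taxon trees, each with its 2 non-trivial splits.

    An unrooted binary tree on 5 leaves is exactly an unordered pair of
    disjoint cherries; the remaining leaf sits on the internal path.
    """
    leaves = ["A", "B", "C", "D", "E"]
    seen = set()
    out = []
    for p1 in itertools.combinations(leaves, 2):
        rest = [x for x in leaves if x not in p1]
        for p2 in itertools.combinations(rest, 2):
            key = frozenset((frozenset(p1), frozenset(p2)))
            if key in seen:
                continue
            seen.add(key)
            (odd,) = [x for x in rest if x not in p2]
            nwk = f"(({p1[0]},{p1[1]}),({p2[0]},{p2[1]}),{odd});"
            out.append((nwk, {frozenset(p1), frozenset(p2)}))
    assert len(out) == 15
    return out


class TestRFDistance:
    def test_identity(self, quartet_pair):
        t1, _ = quartet_pair
        assert rf_distance(t1, t1) == 0

    def test_quartet_alternatives(self, quartet_pair):
        assert rf_distance(*quartet_pair) == 2

    def test_five_taxon_pair(self):
        t1 = parse_newick("((A,B),(C,(D,E)));")
        t2 = parse_newick("((A,C),(B,(D,E)));")
        assert rf_distance(t1, t2) == 2

    def test_leaf_mismatch_error(self):
        with pytest.raises(TreeError, match="D.*E|E.*D"):
            rf_distance(parse_newick("((A,B),(C,D));"),
                        parse_newick("((A,B),(C,E));"))

    def test_oracle_all_quintet_pairs(self):
        # independent oracle: the symmetric difference of the explicitly
        # enumerated cherry pairs defining each topology
        tops = _all_quintet_topologies()
        for (nwk1, splits1), (nwk2, splits2) in itertools.combinations_with_replacement(tops, 2):
            expected = len(splits1 ^ splits2)
            assert rf_distance(parse_newick(nwk1), parse_newick(nwk2)) == expected

    def test_symmetry_random_trees(self):
        from coaltest.coalsim import simulate_gene_tree
        from coaltest.fixtures import random_species_tree

        sp = random_species_tree(8, (0.2, 1.0), seed=5)
        trees = [simulate_gene_tree(sp, rng=i) for i in range(6)]
        for a, b in itertools.combinations(trees, 2):
            assert rf_distance(a, b) == rf_distance(b, a)
            assert rf_distance(a, a) == 0

    def test_binary_tree_has_n_minus_3_bipartitions(self):
        from coaltest.coalsim import simulate_gene_tree
        from coaltest.fixtures import random_species_tree
        from coaltest.trees import _nontrivial_bipartitions

        for n in (4, 5, 7, 10):
            sp = random_species_tree(n, (0.5, 1.0), seed=n)
            t = simulate_gene_tree(sp, rng=0)
            assert len(_nontrivial_bipartitions(t)) == n - 3


class TestNRFD:
    def test_identical_binary(self, quartet_pair):
        t1, _ = quartet_pair
        assert nrfd(t1, t1) == 0.0

    def test_quartet_max(self, quartet_pair):
        assert nrfd(*quartet_pair) == 1.0

    def test_five_taxon_half(self):
        t1 = parse_newick("((A,B),(C,(D,E)));")
        t2 = parse_newick("((A,C),(B,(D,E)));")
        assert nrfd(t1, t2) == 0.5

    def test_star_trees_zero(self):
        t = parse_newick("(A,B,C,D);")
        assert nrfd(t, t) == 0.0

    def test_bounds_random_pairs(self):
        from coaltest.coalsim import simulate_gene_tree
        from coaltest.fixtures import random_species_tree

        sp = random_species_tree(7, (0.1, 0.5), seed=2)
        trees = [simulate_gene_tree(sp, rng=i) for i in range(5)]
        for a, b in itertools.combinations(trees, 2):
            assert 0.0 <= nrfd(a, b) <= 1.0
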