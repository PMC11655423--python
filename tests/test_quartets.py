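import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phyloqc import quartets as qt
from phyloqc import treecore as tc
from phyloqc.synthdata import SimConfig, simulate_gene_trees, simulate_species_tree


# ---------------------------------------------------------------------------
# independent brute-force oracle: prune each copy quadruple out of the gene
# tree and read its split directly (no distance matrices involved)
# ---------------------------------------------------------------------------

def oracle_tally(species_tree, gene_trees, tmap):
    ctxs = [c for c in qt.branch_contexts(species_tree) if c.groups is not None]
    out = {}
    for ctx in ctxs:
        vecs = []
        for gt in gene_trees:
            tips = gt.tip_labels
            byg = [[t for t in tips if (tmap or {}).get(t, t) in g]
                   for g in ctx.groups]
            if any(not x for x in byg):
                continue
            counts = [0, 0, 0]
            for a, b, c, d in itertools.product(*byg):
                sub = tc.prune_to_tips(gt, {a, b, c, d})
                sps = tc.splits(sub)
                if not sps:
                    continue
                (bip,) = sps
                pair = bip.side if len(bip.side) == 2 else bip.other
                if pair in (frozenset({a, b}), frozenset({c, d})):
                    counts[0] += 1
                elif pair in (frozenset({a, c}), frozenset({b, d})):
                    counts[1] += 1
                else:
                    counts[2] += 1
            tot = sum(counts)
            if tot:
                vecs.append(np.array(counts) / tot)
        out[ctx.key] = (np.mean(vecs, axis=0) if vecs else None, len(vecs))
    return out


def random_instance(seed, n_genes=20, duplication_rate=0.5):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 9))
    sp = simulate_species_tree(SimConfig(n_species=n, shape="yule", t=0.5,
                                         seed=seed))
    gts, tmap, _ = simulate_gene_trees(sp, SimConfig(
        n_species=n, shape="yule", t=0.5, seed=seed + 1000,
        n_genes=n_genes, duplication_rate=duplication_rate))
    return sp, gts, tmap


class TestQcScore:
    @pytest.mark.parametrize("f,expected", [
        ((1, 0, 0), 1.0),
        ((1 / 3, 1 / 3, 1 / 3), 0.0),
        ((0.6, 0.3, 0.1), 0.1826546),      # frozen from a high-precision oracle
        ((0.1, 0.6, 0.3), -0.1826546),     # alternative preferred -> negative
        ((0.4, 0.4, 0.2), 0.0),            # tie with best alternative -> 0
    ])
    def test_examples(self, f, expected):
        assert qt.qc_score(*f) == pytest.approx(expected, abs=1e-6)

    def test_bad_sum_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            qt.qc_score(0.5, 0.4, 0.3)

    @given(st.tuples(st.floats(0.001, 1), st.floats(0.001, 1), st.floats(0.001, 1)))
    def test_symmetric_in_alternatives_and_bounded(self, raw):
        s = sum(raw)
        f1, f2, f3 = (x / s for x in raw)
        a, b = qt.qc_score(f1, f2, f3), qt.qc_score(f1, f3, f2)
        assert a == pytest.approx(b, abs=1e-12)
        assert -1 <= a <= 1

    @given(st.tuples(st.floats(0.001, 1), st.floats(0.001, 1), st.floats(0.001, 1)))
    def test_nonnegative_when_displayed_quartet_is_weak_maximum(self, raw):
        s = sum(raw)
        f = sorted(x / s for x in raw)[::-1]     # f1 = max
        assert qt.qc_score(*f) >= 0


class TestQdScore:
    @pytest.mark.parametrize("f2,f3,expected", [
        (0.25, 0.25, 1.0),
        (0.4, 0.0, 0.0),
        (0.3, 0.1, 1 / 3),
    ])
    def test_examples(self, f2, f3, expected):
        assert qt.qd_score(f2, f3) == pytest.approx(expected)

    def test_undefined_without_observed_discordance(self):
        assert math.isnan(qt.qd_score(0.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            qt.qd_score(-0.1, 0.2)

    @given(st.floats(0, 1), st.floats(0.001, 1))
    def test_symmetric(self, a, b):
        assert qt.qd_score(a, b) == qt.qd_score(b, a)


class TestTally:
    def test_concordant_genes_give_unanimous_branches(self, balanced6):
        genes = [balanced6.copy() for _ in range(20)]
        tally = qt.tally_quartets(balanced6, genes)
        assert len(tally.branches) == 3
        for bt in tally.branches.values():
            assert bt.f == (1.0, 0.0, 0.0)
            assert bt.m == 20 and bt.M == 20

    def test_two_copies_in_same_position_agree(self):
        (sp,) = tc.parse_newick("((x,y),(z,w));")
        (g,) = tc.parse_newick("((x1,x2),(y1,(z1,w1)));")
        tmap = {"x1": "x", "x2": "x", "y1": "y", "z1": "z", "w1": "w"}
        tally = qt.tally_quartets(sp, [g], tmap)
        (bt,) = tally.branches.values()
        assert bt.f == (1.0, 0.0, 0.0) and bt.m == 1

    def test_frequencies_sum_to_one_and_unmapped_copy_rejected(self):
        sp, gts, tmap = random_instance(3)
        tally = qt.tally_quartets(sp, gts, tmap)
        for bt in tally.branches.values():
            if bt.f is not None:
                assert sum(bt.f) == pytest.approx(1.0, abs=1e-9)
                assert bt.m <= bt.M
        bad = dict(tmap)
        first = gts[0].tips()[0].label
        del bad[first]
        with pytest.raises(tc.UnknownTaxonError):
            qt.tally_quartets(sp, gts, bad)

    def test_branch_with_absent_group_is_uninformative(self):
        (sp,) = tc.parse_newick("((a,b),((c,d),(e,f)));")
        genes = tc.parse_newick("((a,b),(c,d));((a,c),(b,d));")
        tally = qt.tally_quartets(sp, genes)
        ef = frozenset({"e", "f"})
        bt = next(b for k, b in tally.branches.items() if k.side == ef)
        assert bt.m == 0 and bt.f is None

    @pytest.mark.parametrize("seed", range(5))
    def test_enumerate_matches_bruteforce_oracle(self, seed):
        sp, gts, tmap = random_instance(seed)
        tally = qt.tally_quartets(sp, gts, tmap)
        ora = oracle_tally(sp, gts, tmap)
        for ctx in tally.contexts:
            if ctx.groups is None:
                continue
            bt = tally.branches[ctx.bipartition]
            of, om = ora[ctx.key]
            if bt.f is None:
                assert of is None
            else:
                assert om == bt.m
                assert np.allclose(bt.f, of, atol=1e-12)

    def test_sample_mode_close_to_enumeration_and_seeded(self):
        sp, gts, tmap = random_instance(11)
        exact = qt.tally_quartets(sp, gts, tmap)
        samp = qt.tally_quartets(sp, gts, tmap, mode="sample", K=2000, seed=4)
        again = qt.tally_quartets(sp, gts, tmap, mode="sample", K=2000, seed=4)
        for k in exact.branches:
            fe, fs, fa = exact.branches[k].f, samp.branches[k].f, again.branches[k].f
            assert fs == fa  # same seed -> identical
            if fe and fs:
                assert max(abs(x - y) for x, y in zip(fe, fs)) <= 0.02


class TestAnnotation:
    def test_flags_from_frequency_triples(self):
        assert qt.branch_flags(1.0, float("nan")) == ["strong_support"]
        tot = 0.453 + 0.474 + 0.073
        f = (0.453 / tot, 0.474 / tot, 0.073 / tot)
        qc, qd = qt.qc_score(*f), qt.qd_score(f[1], f[2])
        assert qc == pytest.approx(-0.1774711, abs=1e-6)
        assert qd == pytest.approx(0.1540084, abs=1e-6)
        assert qt.branch_flags(qc, qd) == ["skewed_conflict"]

    def test_annotated_tree_and_table(self, balanced6):
        genes = [balanced6.copy() for _ in range(5)]
        tally = qt.tally_quartets(balanced6, genes)
        ann = qt.annotate_tree(balanced6, tally)
        annotated = [nd for nd in ann.preorder() if nd.annotations]
        assert annotated and all(nd.annotations["QC"] == 1.0 for nd in annotated)
        table = qt.branch_table(tally)
        assert set(table["flags"]) == {"strong_support"}
        assert (table["m"] == 5).all()

    def test_uninformative_branch_annotated_na(self):
        (sp,) = tc.parse_newick("((a,b),((c,d),(e,f)));")
        genes = tc.parse_newick("((a,b),(c,d));")
        tally = qt.tally_quartets(sp, genes)
        table = qt.branch_table(tally)
        na = table[table["m"] == 0]
        assert len(na) >= 1 and na["flags"].eq("").all()


class TestPlastomeQc:
    def test_identical_bootstraps_give_unit_support(self):
        nt = simulate_species_tree(SimConfig(n_species=10, seed=1))
        pqc, _, _ = qt.plastome_signed_qc(nt, [nt.copy() for _ in range(100)])
        assert all(v == pytest.approx(1.0) for v in pqc.values())

    def test_single_nni_gives_minus_one_at_that_branch_only(self):
        nt = simulate_species_tree(SimConfig(n_species=10, seed=1))
        ctx = next(c for c in qt.branch_contexts(nt) if c.groups is not None)
        alt = tc.nni(nt, ctx.key, 0)
        pqc, _, _ = qt.plastome_signed_qc(nt, [alt.copy() for _ in range(100)])
        assert pqc[ctx.key] == pytest.approx(-1.0)
        assert all(v == pytest.approx(1.0)
                   for k, v in pqc.items() if k != ctx.key)

    def test_even_mixture_hits_the_tie_rule(self):
        nt = simulate_species_tree(SimConfig(n_species=10, seed=1))
        ctx = next(c for c in qt.branch_contexts(nt) if c.groups is not None)
        alt = tc.nni(nt, ctx.key, 0)
        boots = [nt.copy() for _ in range(50)] + [alt.copy() for _ in range(50)]
        pqc, _, _ = qt.plastome_signed_qc(nt, boots)
        assert pqc[ctx.key] == 0.0

    def test_disjoint_tip_sets_rejected(self):
        (a,) = tc.parse_newick("((a,b),(c,d));")
        (b,) = tc.parse_newick("((w,x),(y,z));")
        with pytest.raises(tc.TreeError, match="shared"):
            qt.plastome_signed_qc(a, [b])


class TestConflictClassification:
    @pytest.mark.parametrize("nq,pq,expected", [
        (0.5, -0.5, True),
        (0.5, 0.5, False),
        (0.1, -0.5, False),     # nuclear support insufficient
    ])
    def test_conflict_rule(self, nq, pq, expected):
        key = frozenset({"x", "y"})
        other = {frozenset({"p", "q"}): 0.3, frozenset({"r", "s"}): 0.4}
        nqc = {key: nq, **other}
        pqc = {key: pq, **{k: v for k, v in other.items()}}
        rep = qt.classify_branches(nqc, pqc)
        row = rep.table[rep.table["side"] == "x,y"]
        assert bool(row["conflict"].iloc[0]) is expected

    def test_correlation_needs_three_defined_branches(self):
        nqc = {frozenset({"a"}): 0.5, frozenset({"b"}): 0.1}
        pqc = dict(nqc)
        rep = qt.classify_branches(nqc, pqc)
        assert math.isnan(rep.r)

    def test_correlation_statistics(self):
        keys = [frozenset({c}) for c in "abcdefgh"]
        nqc = {k: i / 10 for i, k in enumerate(keys)}
        pqc = {k: i / 10 + 0.01 * (-1) ** i for i, k in enumerate(keys)}
        rep = qt.classify_branches(nqc, pqc)
        assert rep.r > 0.99 and rep.t > 0 and rep.p < 1e-4
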