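import numpy as np
import pandas as pd
import pytest

from phyloqc import filters as flt


def make_msa(rows):
    return flt.MSA([f"s{i+1}" for i in range(len(rows))], rows)


class TestHitFilter:
    def hits(self, rows):
        return pd.DataFrame(rows, columns=["qseqid", "sseqid", "pident",
                                           "coverage", "evalue"])

    def test_reference_preset_strict_boundaries(self):
        h = self.hits([("q", "keep", 61.0, 0.66, 1e-9),
                       ("q", "drop_cov", 90.0, 0.65, 1e-9),
                       ("q", "drop_id", 60.0, 0.90, 1e-9)])
        out = flt.filter_hit_table(h, "reference")
        assert list(out["sseqid"]) == ["keep"]

    def test_transcriptome_preset_strict_boundaries(self):
        h = self.hits([("q", "keep", 71.0, 0.51, 1e-9),
                       ("q", "drop_id", 70.0, 0.51, 1e-9),
                       ("q", "drop_cov", 90.0, 0.50, 1e-9)])
        out = flt.filter_hit_table(h, "transcriptome")
        assert list(out["sseqid"]) == ["keep"]

    def test_empty_and_unknown_preset(self):
        empty = self.hits([])
        assert len(flt.filter_hit_table(empty, "reference")) == 0
        with pytest.raises(ValueError, match="preset"):
            flt.filter_hit_table(empty, "plastome")

    def test_idempotent_and_order_stable(self):
        h = self.hits([("q", f"s{i}", 50 + i * 5.0, 0.5 + i * 0.05, 1e-9)
                       for i in range(8)])
        once = flt.filter_hit_table(h, "reference")
        twice = flt.filter_hit_table(once, "reference")
        pd.testing.assert_frame_equal(once, twice)
        assert list(once.index) == sorted(once.index)

    def test_blast6_reader_computes_coverage(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\t95.0\t80\t4\t0\t1\t80\t1\t80\t1e-30\t150\n")
        df = flt.read_blast6(p, {"q1": 100})
        assert df["coverage"].iloc[0] == pytest.approx(0.8)
        with pytest.raises(ValueError, match="q1"):
            flt.read_blast6(p, {})


class TestTrim:
    def test_column_threshold_is_inclusive_at_90_percent(self):
        # col 0: 9/10 missing -> dropped; col 1: 8/10 -> kept
        rows = [("-" if i < 9 else "A") + ("-" if i < 8 else "A") + "A" * 600
                for i in range(10)]
        msa = make_msa(rows)
        out, rep = flt.trim_and_filter_alignment(msa)
        assert rep.columns_kept == 601
        assert out.length == 601

    def test_short_sequences_removed_after_trimming(self):
        rows = ["A" * 600 for _ in range(9)] + ["A" * 150 + "-" * 450]
        out, rep = flt.trim_and_filter_alignment(make_msa(rows))
        assert rep.seqs_kept == 9
        assert "s10" not in out.ids
        boundary = ["A" * 600 for _ in range(9)] + ["A" * 200 + "-" * 400]
        out2, rep2 = flt.trim_and_filter_alignment(make_msa(boundary))
        assert rep2.seqs_kept == 10  # exactly 200 bp is kept

    def test_gene_rejected_below_500(self):
        out, rep = flt.trim_and_filter_alignment(make_msa(["A" * 450] * 5))
        assert out is None and rep.rejected and "450" in rep.reason

    def test_idempotent_and_invariants(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACGT-N"), 700)) for _ in range(12)]
        out, _ = flt.trim_and_filter_alignment(make_msa(rows))
        if out is not None:
            miss = out.missing_mask()
            assert (miss.mean(axis=0) < 0.9).all()
            assert ((~miss).sum(axis=1) >= 200).all()
            out2, rep2 = flt.trim_and_filter_alignment(out)
            assert out2.length == out.length and rep2.seqs_kept == out.n_seqs

    def test_rectangularity_enforced(self):
        with pytest.raises(ValueError, match="rectangular"):
            flt.MSA(["a", "b"], ["ACGT", "ACG"])


class TestOccupancy:
    def test_inclusive_half_threshold_at_331_genes(self):
        G = 331
        m = pd.DataFrame(
            [[1] * 166 + [0] * (G - 166), [1] * 165 + [0] * (G - 165),
             [1] * G],
            index=["edge", "below", "full"])
        kept = flt.filter_occupancy(m)
        assert kept == ["edge", "full"]

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            flt.filter_occupancy(pd.DataFrame(index=["a"]), total_genes=0)

    def test_binary_enforced(self):
        m = pd.DataFrame([[2, 0]], index=["a"])
        with pytest.raises(ValueError, match="binary"):
            flt.filter_occupancy(m)


class TestPlastomeSelection:
    def cov(self):
        return pd.DataFrame(
            {"g1": [0.3, 0.3, 0.3], "g2": [0.3, 0.3, 0.3],
             "g3": [0.3, 0.3, 0.3], "g4": [0.3, 0.3, 0.3],
             "g5": [0.25, 0.1, 0.3], "g6": [0.0, 0.0, 0.3]},
            index=["five_genes", "four_genes", "gappy"])

    def test_two_stage_rules(self):
        sm = flt.MSA(["five_genes", "four_genes", "gappy"],
                     ["A" * 100, "A" * 100, "A" * 4 + "-" * 96])
        sel = flt.select_plastome_samples(self.cov(), sm)
        assert sel.retained == ["five_genes"]
        assert sel.stage1_failed == ["four_genes"]
        assert sel.stage2_failed == ["gappy"]


class TestConsensus:
    def pileup(self, rows):
        return pd.DataFrame(rows, columns=["pos", "A", "C", "G", "T"])

    def test_call_rules(self):
        rows = [(1, 0, 0, 0, 0),    # depth 0 -> N
                (2, 3, 1, 0, 0),    # 0.75 -> A
                (3, 2, 2, 0, 0),    # tie -> M
                (4, 1, 1, 1, 1),    # four-way tie -> N code
                (5, 1, 1, 1, 0)]    # top below call fraction -> N
        rows += [(i, 5, 0, 0, 0) for i in range(6, 206)]
        seq = flt.consensus_from_pileup(self.pileup(rows))
        assert seq[:5] == "NAMNN"
        assert set(seq[5:]) == {"A"}

    def test_min_length_rejection(self):
        rows = [(i, 5, 0, 0, 0) for i in range(1, 100)]
        assert flt.consensus_from_pileup(self.pileup(rows)) is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            flt.consensus_from_pileup(self.pileup([(1, -1, 0, 0, 0)]))


class TestFixtureBundleFilters:
    """Planted fixtures reproduce their manifest outcomes exactly."""

    def test_alignment_fixtures(self, fixture_bundle):
        outdir, man = fixture_bundle
        msa = flt.MSA.from_fasta(outdir / "aln_pass.fasta")
        out, rep = flt.trim_and_filter_alignment(msa)
        exp = man["aln_pass"]
        assert (rep.columns_kept, rep.seqs_kept, rep.rejected) == \
            (exp["columns_kept"], exp["seqs_kept"], exp["rejected"])
        _, rep2 = flt.trim_and_filter_alignment(
            flt.MSA.from_fasta(outdir / "aln_reject.fasta"))
        assert rep2.rejected is True

    def test_pileup_fixtures(self, fixture_bundle):
        outdir, man = fixture_bundle
        seq = flt.consensus_from_pileup(flt.read_pileup(outdir / "pileup_pass.tsv"))
        assert seq == man["pileup_pass"]["consensus"]
        assert flt.consensus_from_pileup(
            flt.read_pileup(outdir / "pileup_short.tsv")) is None

    def test_hit_and_occupancy_fixtures(self, fixture_bundle):
        outdir, man = fixture_bundle
        ql = {"q1": 100, "q2": 100}
        for name, preset in (("hits_reference", "reference"),
                             ("hits_transcriptome", "transcriptome")):
            df = flt.read_blast6(outdir / f"{name}.tsv", ql)
            kept = flt.filter_hit_table(df, preset)
            assert list(kept["sseqid"]) == man[name]["kept"]
        occ = pd.read_csv(outdir / "occupancy.tsv", sep="\t", index_col=0)
        assert flt.filter_occupancy(occ) == man["occupancy"]["retained"]

    def test_plastome_fixture(self, fixture_bundle):
        outdir, man = fixture_bundle
        cov = pd.read_csv(outdir / "plastome_coverage.tsv", sep="\t", index_col=0)
        sm = flt.MSA.from_fasta(outdir / "plastome_supermatrix.fasta")
        sel = flt.select_plastome_samples(cov, sm)
        assert sel.retained == man["plastome"]["retained"]
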