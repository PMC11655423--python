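"""Command-line orchestration of the analysis stages.

Thin wrappers binding the library stages into the three analyses (nuclear
quartet concordance, cyto-nuclear conflict, reticulation summary) plus the
supporting utilities (TBE, gene filtering, paralog validation, simulation).
Every output file starts with a header echoing the tool version, the
configuration and the seed, so runs are traceable and reproducible.
"""
from __future__ import annotations

import json
import math
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import pandas as pd

from . import __version__
from . import filters as flt
from . import quartets as qt
from . import reticulation as ret
from . import synthdata as syn
from . import tbe as tbe_mod
from .treecore import (PhyloTree, TreeError, assign_branch_ids,
                       read_clade_map, read_taxon_map, read_trees,
                       write_trees)

EXIT_VALIDATION = 2
EXIT_IO = 3


@dataclass
class RunConfig:
    """Thresholds for the full pipeline, defaulting to the published values."""
    qc_strong: float = 0.2
    qd_skew: float = 0.5
    plastome_qc_conflict: float = -0.2
    min_transfer_support: int = 5
    top_quantile: float = 0.10
    skew_threshold: float = 0.5
    max_col_missing: float = 0.9
    min_seq_len: int = 200
    min_gene_len: int = 500
    min_occupancy: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.max_col_missing <= 1 and 0 <= self.min_occupancy <= 1
                and 0 < self.top_quantile < 1):
            raise ValueError("threshold out of range")


def _header(config: dict, seed=None) -> str:
    items = dict(config)
    if seed is not None:
        items["seed"] = seed
    body = " ".join(f"{k}={v}" for k, v in items.items())
    return f"# phyloqc {__version__} | {body}\n"


def _write_table(df: pd.DataFrame, path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


@click.group()
@click.version_option(__version__)
def main():
    """Quartet concordance, conflict and reticulation analysis toolkit."""


def _fail(stage: str, exc: Exception):
    click.echo(f"error [{stage}]: {exc}", err=True)
    code = EXIT_IO if isinstance(exc, (OSError, FileNotFoundError)) else EXIT_VALIDATION
    sys.exit(code)


@main.command()
@click.option("--species-tree", required=True, type=click.Path())
@click.option("--gene-trees", required=True, type=click.Path())
@click.option("--taxon-map", type=click.Path(), default=None,
              help="copy->species map; identity if omitted")
@click.option("--mode", type=click.Choice(["enumerate", "sample"]),
              default="enumerate")
@click.option("--budget", "-k", default=2000, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out-prefix", required=True)
def annotate(species_tree, gene_trees, taxon_map, mode, budget, seed, out_prefix):
    """Annotate a species tree with QC/QD quartet support from gene trees."""
    try:
        sp = read_trees(species_tree)[0]
        genes = read_trees(gene_trees)
        tmap = read_taxon_map(taxon_map) if taxon_map else None
    except Exception as exc:
        _fail("input", exc)
    try:
        tally = qt.tally_quartets(sp, genes, tmap, mode=mode, K=budget, seed=seed)
        annotated = qt.annotate_tree(sp, tally)
        table = qt.branch_table(tally)
    except Exception as exc:
        _fail("tally", exc)
    write_trees([annotated], f"{out_prefix}.annotated.nwk")
    hdr = _header({"mode": mode, "K": budget, "genes": len(genes)}, seed)
    _write_table(table, f"{out_prefix}.branches.tsv", hdr)
    strong = int((table["QC"] > qt.QC_STRONG).sum())
    skewed = int(table["flags"].fillna("").str.contains("skewed_conflict").sum())
    click.echo(f"branches={len(table)} strong_support={strong} "
               f"skewed_conflict={skewed}")


@main.command()
@click.option("--nuclear-tree", required=True, type=click.Path())
@click.option("--nuclear-gene-trees", required=True, type=click.Path())
@click.option("--bootstrap-trees", required=True, type=click.Path())
@click.option("--match", type=click.Path(), default=None,
              help="bootstrap tip -> nuclear tip map (accession matching)")
@click.option("--out-prefix", required=True)
def conflict(nuclear_tree, nuclear_gene_trees, bootstrap_trees, match, out_prefix):
    """Cyto-nuclear conflict: plastome signed QC vs nuclear QC per branch."""
    try:
        nuc = read_trees(nuclear_tree)[0]
        genes = read_trees(nuclear_gene_trees)
        boots = read_trees(bootstrap_trees)
        mmap = read_taxon_map(match) if match else None
    except Exception as exc:
        _fail("input", exc)
    try:
        pqc, pruned, _ = qt.plastome_signed_qc(nuc, boots, mmap)
        from .treecore import prune_to_tips
        shared = pruned.tip_labels
        genes = [prune_to_tips(g, shared & g.tip_labels) for g in genes]
        tally = qt.tally_quartets(pruned, genes, None)
        nqc = {}
        for ctx in tally.contexts:
            bt = tally.branches[ctx.bipartition]
            nqc[ctx.key] = qt.qc_score(*bt.f) if bt.f else float("nan")
        report = qt.classify_branches(nqc, pqc,
                                      matched_tips=len(pruned.tip_labels))
    except Exception as exc:
        _fail("conflict", exc)
    hdr = _header({"bootstraps": len(boots), "matched_tips": report.matched_tips})
    _write_table(report.table, f"{out_prefix}.conflict.tsv", hdr)
    with open(f"{out_prefix}.correlation.json", "w") as fh:
        json.dump({"r": report.r, "t": report.t, "p": report.p, "n": report.n},
                  fh, indent=1)
    click.echo(f"conflicts={int(report.table['conflict'].sum())} "
               f"r={report.r:.3f}")


@main.command("tbe")
@click.option("--reference", required=True, type=click.Path())
@click.option("--bootstrap-trees", required=True, type=click.Path())
@click.option("--out-prefix", required=True)
def tbe_cmd(reference, bootstrap_trees, out_prefix):
    """Transfer bootstrap expectation support for a reference tree."""
    try:
        ref = read_trees(reference)[0]
        boots = read_trees(bootstrap_trees)
    except Exception as exc:
        _fail("input", exc)
    try:
        support = tbe_mod.tbe_support(ref, boots)
    except Exception as exc:
        _fail("tbe", exc)
    write_trees([tbe_mod.annotate_tbe(ref, support)], f"{out_prefix}.tbe.nwk")
    _write_table(tbe_mod.tbe_table(support), f"{out_prefix}.tbe.tsv",
                 _header({"bootstraps": len(boots)}))
    click.echo(f"scored_branches={len(support)}")


@main.command("filter-genes")
@click.option("--alignments", required=True, multiple=True, type=click.Path())
@click.option("--out-dir", required=True, type=click.Path())
@click.option("--max-col-missing", default=0.9, show_default=True)
@click.option("--min-seq-len", default=200, show_default=True)
@click.option("--min-gene-len", default=500, show_default=True)
def filter_genes(alignments, out_dir, max_col_missing, min_seq_len, min_gene_len):
    """Trim alignment columns and apply sequence/gene length thresholds."""
    outdir = Path(out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for path in alignments:
        try:
            msa = flt.MSA.from_fasta(path)
        except Exception as exc:
            _fail("input", exc)
        trimmed, report = flt.trim_and_filter_alignment(
            msa, max_col_missing, min_seq_len, min_gene_len)
        name = Path(path).stem
        if trimmed is not None:
            trimmed.to_fasta(outdir / f"{name}.trimmed.fasta")
        rows.append({"gene": name, "columns_in": report.columns_in,
                     "columns_kept": report.columns_kept,
                     "seqs_in": report.seqs_in, "seqs_kept": report.seqs_kept,
                     "rejected": report.rejected, "reason": report.reason})
    _write_table(pd.DataFrame(rows), outdir / "filter_report.tsv",
                 _header({"max_col_missing": max_col_missing,
                          "min_seq_len": min_seq_len,
                          "min_gene_len": min_gene_len}))
    kept = sum(1 for r in rows if not r["rejected"])
    click.echo(f"genes_in={len(rows)} genes_kept={kept}")


@main.command("validate-paralogs")
@click.option("--candidates", required=True, type=click.Path())
@click.option("--candidate-lineages", required=True, type=click.Path(),
              help="2-column TSV: candidate label, assigned reference lineage")
@click.option("--references", required=True, type=click.Path())
@click.option("--reference-info", required=True, type=click.Path(),
              help="3-column TSV: ref id, species, lineage")
@click.option("--guide-tree", type=click.Path(), default=None)
@click.option("--accession", default="sample")
@click.option("--orthogroup", default="OG0")
@click.option("--out", required=True, type=click.Path())
def validate_paralogs_cmd(candidates, candidate_lineages, references,
                          reference_info, guide_tree, accession, orthogroup, out):
    """Dedupe candidate assemblies and validate paralogs by monophyly."""
    from Bio import SeqIO
    from . import paralogs as par
    try:
        cand_seqs = {r.id: str(r.seq) for r in SeqIO.parse(candidates, "fasta")}
        lineages = read_taxon_map(candidate_lineages)
        ref_seqs = {r.id: str(r.seq) for r in SeqIO.parse(references, "fasta")}
        info = {}
        with open(reference_info) as fh:
            for line in fh:
                if line.strip():
                    rid, species, lineage = line.split()
                    info[rid] = (species, lineage)
        gtree = read_trees(guide_tree)[0] if guide_tree else None
    except Exception as exc:
        _fail("input", exc)
    try:
        aset = par.AssemblySet(accession, orthogroup, [
            par.Candidate(k, v, lineages[k]) for k, v in cand_seqs.items()])
        aset = par.dedupe_assemblies(aset)
        refs = par.OrthogroupReference(orthogroup, [
            par.RefSeq(k, info[k][0], info[k][1], v) for k, v in ref_seqs.items()])
        result = par.validate_paralogs(aset, refs, gtree)
    except Exception as exc:
        _fail("paralogs", exc)
    _write_table(result.report, out, _header({"accession": accession,
                                              "orthogroup": orthogroup}))
    click.echo(f"retained={','.join(c.label for c in result.retained)} "
               f"validated={result.validated}")


@main.command()
@click.option("--records", required=True, type=click.Path())
@click.option("--species-tree", required=True, type=click.Path())
@click.option("--clade-map", type=click.Path(), default=None)
@click.option("--min-support", default=5, show_default=True)
@click.option("--top-quantile", default=0.10, show_default=True)
@click.option("--skew-threshold", default=0.5, show_default=True)
@click.option("--out-prefix", required=True)
def transfers(records, species_tree, clade_map, min_support, top_quantile,
              skew_threshold, out_prefix):
    """Summarize reconciliation transfer events (species and clade level)."""
    try:
        recs = ret.read_transfer_records(records)
        tree = assign_branch_ids(read_trees(species_tree)[0])
        cmap = read_clade_map(clade_map) if clade_map else None
    except Exception as exc:
        _fail("input", exc)
    try:
        summary = ret.summarize_transfers(recs, tree, min_support,
                                          top_quantile, skew_threshold)
        hdr = _header({"min_support": min_support, "top_quantile": top_quantile,
                       "skew_threshold": skew_threshold,
                       "root_excluded": summary.root_excluded})
        _write_table(summary.table, f"{out_prefix}.transfers.tsv", hdr)
        if cmap:
            csum = ret.collapse_and_summarize(
                recs, tree, cmap, min_support=min_support,
                top_quantile=top_quantile, skew_threshold=skew_threshold)
            _write_table(csum.table, f"{out_prefix}.transfers.clades.tsv", hdr)
    except Exception as exc:
        _fail("transfers", exc)
    n_sup = int(summary.table["supported"].sum()) if len(summary.table) else 0
    if n_sup == 0:
        click.echo("no branch pair reaches the support threshold")
    else:
        click.echo(f"supported_pairs={n_sup} "
                   f"highlighted={int(summary.table['highlighted'].sum())}")


@main.command()
@click.option("--n-species", default=8, show_default=True)
@click.option("--shape", type=click.Choice(["balanced", "yule"]),
              default="balanced")
@click.option("--t", default=1.0, show_default=True,
              help="internal branch length in coalescent units")
@click.option("--genes", default=100, show_default=True)
@click.option("--duplication-rate", default=0.0, show_default=True)
@click.option("--introgression", default=0.0, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out-dir", required=True, type=click.Path())
def simulate(n_species, shape, t, genes, duplication_rate, introgression,
             seed, out_dir):
    """Generate an MSC bundle: species tree, gene trees, map, fixtures."""
    outdir = Path(out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = syn.SimConfig(n_species=n_species, shape=shape, t=t,
                           n_genes=genes, duplication_rate=duplication_rate,
                           introgression=introgression, seed=seed)
    try:
        sp = syn.simulate_species_tree(config)
        gts, tmap, meta = syn.simulate_gene_trees(sp, config)
    except Exception as exc:
        _fail("simulate", exc)
    write_trees([sp], outdir / "species.nwk")
    write_trees(gts, outdir / "genes.nwk")
    with open(outdir / "taxon_map.tsv", "w") as fh:
        for k, v in sorted(tmap.items()):
            fh.write(f"{k}\t{v}\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    syn.make_fixture_bundle(outdir / "fixtures", seed=seed)
    click.echo(f"wrote bundle to {outdir} (seed={seed})")


if __name__ == "__main__":
    main()
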