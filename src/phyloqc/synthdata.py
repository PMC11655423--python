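"""Synthetic inputs with known ground truth.

Gene trees are simulated under the multispecies coalescent (MSC): one
lineage per species at the tips, pairwise coalescence at rate 1 per lineage
pair per coalescent unit within each species-tree branch, and forced
coalescence above the root.  Times are in coalescent units (2N generations),
so for an internal branch of length t the probability that a gene tree
displays the species-tree quartet around that branch is 1 - (2/3) e^{-t},
and each minor topology has probability e^{-t}/3.

Introgression is modelled as whole-gene topology replacement: with
probability pi a gene is simulated under the MSC on the species tree after
one NNI at the target branch, which forces one of the two discordant
resolutions while keeping coalescent variance.  Duplications attach an extra
copy of a uniformly chosen species as a sister tip, registering the copy in
the taxon map (both copies then occupy the same quartet position, the
paralog-weighting edge case).

Gene-tree branch lengths are not used by any consumer in this package and
are written as unit lengths; only topologies and tip multiplicities carry
signal.  Sequence-side fixtures (alignments, pileups, hit tables, transfer
tables, paralog scenarios) are pattern-constructed with their expected
filter outcomes recorded in a manifest, not evolved under a substitution
model.
"""
from __future__ import annotations

import json
import math
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .treecore import (Node, PhyloTree, TreeError, internal_edges, nni,
                       write_trees)
from .quartets import branch_contexts


def expected_concordant_fraction(t: float) -> float:
    """MSC probability of the species-tree quartet across a branch of length t."""
    return 1.0 - (2.0 / 3.0) * math.exp(-t)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    n_species: int = 8
    shape: str = "balanced"            # "balanced" | "yule"
    t: float = 1.0                     # internal branch length, coalescent units
    t_range: tuple | None = None       # optional U(lo, hi) internal lengths (yule)
    pendant: float = 1.0
    n_genes: int = 100
    duplication_rate: float = 0.0      # Poisson mean duplications per gene
    introgression: float = 0.0         # pi: fraction of genes forced discordant
    introgression_branch: frozenset | None = None  # side; default: first eligible
    bootstrap_moves: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if not 0.0 <= self.introgression <= 1.0:
            raise ValueError("introgression fraction must be in [0, 1]")
        if self.duplication_rate < 0:
            raise ValueError("duplication rate must be >= 0")
        if self.shape not in ("balanced", "yule"):
            raise ValueError(f"unknown shape {self.shape!r}")


def _species_labels(n: int) -> list[str]:
    if n <= 26:
        return list(string.ascii_lowercase[:n])
    return [f"s{i + 1}" for i in range(n)]


# ---------------------------------------------------------------------------
# species trees
# ---------------------------------------------------------------------------

def simulate_species_tree(config: SimConfig) -> PhyloTree:
    """Binary rooted species tree with coalescent-unit branch lengths."""
    if config.n_species < 4:
        raise ValueError("need at least 4 species")
    labels = _species_labels(config.n_species)
    rng = np.random.default_rng(config.seed)

    def ilen() -> float:
        if config.t_range is not None:
            lo, hi = config.t_range
            return float(rng.uniform(lo, hi))
        return config.t

    if config.shape == "balanced":
        def build(names: list[str]) -> Node:
            if len(names) == 1:
                return Node(names[0], config.pendant)
            mid = (len(names) + 1) // 2
            nd = Node(None, ilen())
            nd.add_child(build(names[:mid]))
            nd.add_child(build(names[mid:]))
            return nd

        root = Node(None)
        mid = (len(labels) + 1) // 2
        root.add_child(build(labels[:mid]))
        root.add_child(build(labels[mid:]))
    else:
        # Yule shape: split a uniformly chosen pending lineage until n tips
        root = Node(None)
        a, b = Node(None, ilen()), Node(None, ilen())
        root.add_child(a)
        root.add_child(b)
        pending = [a, b]
        while len(pending) < config.n_species:
            i = int(rng.integers(len(pending)))
            nd = pending.pop(i)
            c1, c2 = Node(None, ilen()), Node(None, ilen())
            nd.add_child(c1)
            nd.add_child(c2)
            pending.extend([c1, c2])
        for nd, name in zip(pending, labels):
            nd.label = name
            nd.length = config.pendant
    return PhyloTree(root, rooted=True)


def quartet_species_tree(t: float) -> PhyloTree:
    """Four-taxon caterpillar whose single unrooted internal edge has length t."""
    root = Node(None)
    inner = root.add_child(Node(None, 1.0))
    ab = inner.add_child(Node(None, t))
    ab.add_child(Node("a", 1.0))
    ab.add_child(Node("b", 1.0))
    inner.add_child(Node("c", 1.0 + t))
    root.add_child(Node("d", 2.0 + t))
    return PhyloTree(root, rooted=True)


# ---------------------------------------------------------------------------
# MSC gene trees
# ---------------------------------------------------------------------------

def _coalesce(lineages: list[Node], duration: float, rng) -> list[Node]:
    pool = list(lineages)
    elapsed = 0.0
    while len(pool) > 1:
        k = len(pool)
        rate = k * (k - 1) / 2.0
        elapsed += rng.exponential(1.0 / rate)
        if elapsed > duration:
            break
        i, j = rng.choice(k, size=2, replace=False)
        i, j = int(i), int(j)
        parent = Node(None)
        parent.add_child(pool[i])
        parent.add_child(pool[j])
        pool = [nd for idx, nd in enumerate(pool) if idx not in (i, j)]
        pool.append(parent)
    return pool


def _simulate_msc(species_tree: PhyloTree, rng) -> PhyloTree:
    """One single-copy MSC gene tree; tips labelled by species."""
    lineages: dict[int, list[Node]] = {}
    for nd in species_tree.postorder():
        if nd.is_leaf():
            pool = [Node(nd.label)]
        else:
            pool = []
            for c in nd.children:
                pool.extend(lineages.pop(id(c)))
        if nd.parent is not None:
            if nd.length is None:
                raise TreeError("species tree needs branch lengths in coalescent units")
            pool = _coalesce(pool, nd.length, rng)
        else:
            pool = _coalesce(pool, math.inf, rng)
        lineages[id(nd)] = pool
    root_pool = lineages[id(species_tree.root)]
    assert len(root_pool) == 1
    root = root_pool[0]
    for nd in root.preorder():
        nd.length = None if nd is root else 1.0
    return PhyloTree(root, rooted=True)


def _duplicate_tip(tree: PhyloTree, rng, counters: dict[str, int],
                   taxon_map: dict[str, str]) -> None:
    """Attach a duplicate copy of a uniformly chosen tip as its sister."""
    tips = tree.tips()
    tip = tips[int(rng.integers(len(tips)))]
    species = taxon_map[tip.label]
    counters[species] = counters.get(species, 1) + 1
    new_label = f"{species}^{counters[species]}"
    taxon_map[new_label] = species
    inner = Node(None, tip.length)
    twin = Node(new_label, 1.0)
    parent = tip.parent
    idx = parent.children.index(tip)
    parent.children[idx] = inner
    inner.parent = parent
    tip.length = 1.0
    inner.add_child(tip)
    inner.add_child(twin)


def default_introgression_branch(species_tree: PhyloTree) -> frozenset:
    """First internal branch (preorder) with well-defined quartet groups."""
    for ctx in branch_contexts(species_tree):
        if ctx.groups is not None:
            return ctx.key
    raise TreeError("species tree has no branch eligible for introgression")


def simulate_gene_trees(species_tree: PhyloTree, config: SimConfig):
    """MSC gene trees with optional introgression and duplications.

    Returns ``(gene_trees, taxon_map, manifest)``.  The manifest records, per
    gene, which tree the gene followed ("species" or "introgressed") and its
    copy count; all randomness derives from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    taxon_map = {sp: sp for sp in species_tree.tip_labels}

    alt_tree = None
    target = None
    if config.introgression > 0:
        target = config.introgression_branch or default_introgression_branch(species_tree)
        alt_tree = nni(species_tree, frozenset(target), variant=0)

    gene_trees, manifest = [], []
    for g in range(config.n_genes):
        introgressed = bool(alt_tree is not None
                            and rng.random() < config.introgression)
        source = alt_tree if introgressed else species_tree
        gt = _simulate_msc(source, rng)
        counters: dict[str, int] = {}
        if config.duplication_rate > 0:
            for _ in range(int(rng.poisson(config.duplication_rate))):
                _duplicate_tip(gt, rng, counters, taxon_map)
        gene_trees.append(gt)
        manifest.append({
            "gene": f"g{g + 1}",
            "source": "introgressed" if introgressed else "species",
            "n_tips": gt.n_tips(),
        })
    meta = {
        "seed": config.seed,
        "introgression_branch": sorted(target) if target else None,
        "pi": config.introgression,
        "genes": manifest,
    }
    return gene_trees, taxon_map, meta


# ---------------------------------------------------------------------------
# bootstrap surrogates
# ---------------------------------------------------------------------------

def perturb_bootstrap(tree: PhyloTree, moves: int, M: int,
                      seed: int = 0) -> list[PhyloTree]:
    """M copies of *tree*, each rearranged by the given number of random NNIs."""
    if not tree.is_binary():
        raise TreeError("bootstrap perturbation requires a binary tree")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(M):
        cur = tree.copy()
        for _ in range(moves):
            edges = [nd for nd in internal_edges(cur)
                     if nd.parent is not None and len(nd.children) >= 2]
            nd = edges[int(rng.integers(len(edges)))]
            cur = nni(cur, nd, variant=int(rng.integers(2)))
        out.append(cur)
    return out


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def _write(path: Path, text: str) -> None:
    path.write_text(text)


def make_fixture_bundle(outdir, seed: int = 0) -> dict:
    """Write filter/consensus/transfer/paralog fixtures plus a manifest.

    Every file is deterministic given *seed*; the manifest states the exact
    expected outcome of each fixture under the package's default thresholds
    (survivor counts, consensus strings, supported/highlighted/directional
    transfer pairs, retained paralog candidates).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed}

    # --- (a) alignments with planted gap patterns --------------------------
    n, L = 10, 620
    rows = [["A"] * L for _ in range(n)]
    for col in range(30):            # 9/10 missing -> column dropped
        for r in range(9):
            rows[r][col] = "-"
    for col in range(30, 50):        # 8/10 missing -> column kept
        for r in range(8):
            rows[r][col] = "-"
    # seq10: data only in dropped columns plus 170 kept columns -> removed
    for col in range(L):
        rows[9][col] = "-"
    for col in range(200):   # keeps cols 30-49 at 8/10 missing
        rows[9][col] = "A"
    ids = [f"s{i + 1}" for i in range(n)]
    fasta = "".join(f">{i}\n{''.join(r)}\n" for i, r in zip(ids, rows))
    _write(out / "aln_pass.fasta", fasta)
    manifest["aln_pass"] = {"columns_in": L, "columns_kept": L - 30,
                            "seqs_in": n, "seqs_kept": 9, "rejected": False}

    fasta = "".join(f">t{i + 1}\n{'A' * 450}\n" for i in range(5))
    _write(out / "aln_reject.fasta", fasta)
    manifest["aln_reject"] = {"columns_in": 450, "columns_kept": 450,
                              "rejected": True}

    # --- (b) pileups with known consensus ----------------------------------
    lines = ["1\t0\t0\t0\t0",      # depth 0 -> N
             "2\t2\t2\t0\t0",      # tie A/C -> M
             "3\t3\t1\t0\t0"]      # majority -> A
    for pos in range(4, 211):
        lines.append(f"{pos}\t5\t0\t0\t0")
    _write(out / "pileup_pass.tsv", "\n".join(lines) + "\n")
    manifest["pileup_pass"] = {"consensus": "NMA" + "A" * 207, "called": 209,
                               "rejected": False}
    lines = [f"{pos}\t5\t0\t0\t0" for pos in range(1, 101)]
    _write(out / "pileup_short.tsv", "\n".join(lines) + "\n")
    manifest["pileup_short"] = {"rejected": True}

    # --- (c) hit tables straddling the preset boundaries -------------------
    def hit_row(q, s, pident, cov, qlen=100):
        length = int(round(cov * qlen))
        return (f"{q}\t{s}\t{pident}\t{length}\t0\t0\t1\t{length}\t1\t{length}"
                f"\t1e-20\t{length}")

    ref_rows = [hit_row("q1", "hitA", 61.0, 0.66),   # kept
                hit_row("q1", "hitB", 90.0, 0.65),   # cov not > 0.65
                hit_row("q1", "hitC", 60.0, 0.90),   # ident not > 60
                hit_row("q1", "hitD", 60.1, 0.70)]   # kept
    _write(out / "hits_reference.tsv", "\n".join(ref_rows) + "\n")
    manifest["hits_reference"] = {"kept": ["hitA", "hitD"], "dropped": 2}

    tr_rows = [hit_row("q2", "hitE", 71.0, 0.51),    # kept
               hit_row("q2", "hitF", 70.0, 0.51),    # ident not > 70
               hit_row("q2", "hitG", 90.0, 0.50),    # cov not > 0.50
               hit_row("q2", "hitH", 70.1, 0.80)]    # kept
    _write(out / "hits_transcriptome.tsv", "\n".join(tr_rows) + "\n")
    manifest["hits_transcriptome"] = {"kept": ["hitE", "hitH"], "dropped": 2}
    _write(out / "query_lengths.tsv", "q1\t100\nq2\t100\n")

    # --- (d) occupancy matrix at the inclusive boundary ---------------------
    G = 331
    occ_lines = ["accession\t" + "\t".join(f"g{i + 1}" for i in range(G))]
    for acc, count in (("acc_full", 331), ("acc_edge", 166), ("acc_low", 165)):
        flags = ["1"] * count + ["0"] * (G - count)
        occ_lines.append(acc + "\t" + "\t".join(flags))
    _write(out / "occupancy.tsv", "\n".join(occ_lines) + "\n")
    manifest["occupancy"] = {"total_genes": G,
                             "retained": ["acc_full", "acc_edge"],
                             "dropped": ["acc_low"]}

    # --- (e) plastome sample selection --------------------------------------
    cov_lines = ["sample\tg1\tg2\tg3\tg4\tg5\tg6",
                 "s_pass\t0.3\t0.3\t0.3\t0.3\t0.25\t0",
                 "s_fewgenes\t0.3\t0.3\t0.3\t0.3\t0.1\t0",
                 "s_gappy\t0.3\t0.3\t0.3\t0.3\t0.3\t0.3"]
    _write(out / "plastome_coverage.tsv", "\n".join(cov_lines) + "\n")
    sm = {"s_pass": "A" * 100,
          "s_fewgenes": "A" * 100,
          "s_gappy": "A" * 4 + "-" * 96}     # 96% missing -> dropped
    _write(out / "plastome_supermatrix.fasta",
           "".join(f">{k}\n{v}\n" for k, v in sm.items()))
    manifest["plastome"] = {"retained": ["s_pass"],
                            "stage1_failed": ["s_fewgenes"],
                            "stage2_failed": ["s_gappy"]}

    # --- (f) transfer records ------------------------------------------------
    sp_newick = "((A:1,B:1)N2:1,(C:1,D:1)N3:1)N1;"
    _write(out / "transfer_species_tree.nwk", sp_newick + "\n")
    tlines = []
    gid = 0

    def add(donor, recip, ngenes):
        nonlocal gid
        for _ in range(ngenes):
            gid += 1
            tlines.append(f"g{gid}\t{donor}\t{recip}\t1")

    # balanced pair: 3 genes each way -> supported, not directional
    add("A", "B", 3)
    add("B", "A", 3)
    # eight one-way pairs at support 6 -> supported + directional
    for donor, recip in (("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"),
                         ("C", "D"), ("N2", "C"), ("N2", "D"), ("N3", "B")):
        add(donor, recip, 6)
    # the dominant pair: 18 one way, 2 back -> highlighted + directional
    # supported supports are then {6 x 9, 20}: the top-decile cutoff (upper
    # nearest rank) is 20, so only this pair is highlighted
    add("N2", "N3", 18)
    add("N3", "N2", 2)
    # below threshold
    add("A", "N3", 4)
    # root transfers, excluded before aggregation
    add("N1", "A", 1)
    add("B", "N1", 1)
    _write(out / "transfers.tsv", "\n".join(tlines) + "\n")
    manifest["transfers"] = {
        "root_excluded": 2,
        "supported_pairs": [["A", "B"], ["A", "C"], ["A", "D"], ["B", "C"],
                            ["B", "D"], ["B", "N3"], ["C", "D"], ["C", "N2"],
                            ["D", "N2"], ["N2", "N3"]],
        "unsupported_pairs": [["A", "N3"]],
        "highlighted_pairs": [["N2", "N3"]],
        "directional": {"N2|N3": "N2->N3", "A|B": "", "B|N3": "N3->B"},
    }

    # --- (g) paralog validation scenarios -------------------------------------
    base = list("A" * 300)
    l2 = base.copy()
    for i in range(60):
        l2[i] = "G"

    def mut(seq, positions, ch="T"):
        s = seq.copy()
        for p in positions:
            s[p] = ch
        return "".join(s)

    refs = {
        "R1_L1": mut(base, [100, 101]),
        "R2_L1": mut(base, [110, 111]),
        "R1_L2": mut(l2, [120, 121]),
        "R2_L2": mut(l2, [130, 131]),
    }
    ref_lineage = {"R1_L1": "L1", "R2_L1": "L1", "R1_L2": "L2", "R2_L2": "L2"}
    ref_species = {"R1_L1": "R1", "R2_L1": "R1", "R1_L2": "R2", "R2_L2": "R2"}
    _write(out / "paralog_refs.fasta",
           "".join(f">{k}\n{v}\n" for k, v in refs.items()))
    _write(out / "paralog_ref_info.tsv",
           "".join(f"{k}\t{ref_species[k]}\t{ref_lineage[k]}\n" for k in refs))

    # chimera: carries 45 of the 60 lineage-2 diagnostic sites, so it nests
    # with the L2 cluster although it is assigned to L1
    chim = base.copy()
    for i in range(45):
        chim[i] = "G"
    chim_seq = "".join(chim[:290]) + "-" * 10
    cands = {
        "good": {"X_c1": (mut(base, [140, 141]), "L1"),
                 "X_c2": (mut(l2, [150, 151]), "L2")},
        "chimeric": {"X_c1": (mut(base, [140, 141]), "L1"),
                     "X_chim": (chim_seq, "L1")},
    }
    for scen, cc in cands.items():
        _write(out / f"paralog_candidates_{scen}.fasta",
               "".join(f">{k}\n{v[0]}\n" for k, v in cc.items()))
        _write(out / f"paralog_candidates_{scen}.tsv",
               "".join(f"{k}\t{v[1]}\n" for k, v in cc.items()))
    manifest["paralogs"] = {
        "good": {"retained": ["X_c1", "X_c2"], "validated": True},
        "chimeric": {"retained": ["X_c1"], "validated": False},
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
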