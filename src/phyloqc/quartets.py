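"""Paralog-weighted quartet frequencies and QC/QD branch support.

For every internal branch of an (unrooted view of the) species tree, the
four neighbour tip groups A, B, C, D are the components left after deleting
the branch and splitting each endpoint.  A quadruple takes one gene-tree
*copy* of one species from each group; species with several copies
contribute every copy, which is the paralog weighting.  A quadruple is
informative when its induced unrooted gene-tree quartet is resolved.  Each
gene tree contributes one normalised frequency vector (topology counts over
informative quadruples) and the branch frequencies are the unweighted mean
over contributing genes; ``pooled=True`` instead pools raw quadruple counts
across genes.

Scores per branch:

* QC (quartet concordance) = s * (1 + sum_i f_i log3 f_i), with 0 log 0 = 0.
  The sign s is +1 when f1 strictly exceeds both alternatives, -1 when some
  alternative strictly exceeds f1, and QC = 0 when f1 ties the best
  alternative.  Log base 3 makes QC(1,0,0) = 1 and QC(1/3,1/3,1/3) = 0.
* QD (quartet differential) = min(f2,f3)/max(f2,f3); NA when f2 = f3 = 0,
  so skew can never be claimed without observed discordance.

Flag semantics: strong_support when QC > 0.2; conflicted when 0 <= QC <= 0.2;
skewed_conflict when QC <= 0.2 and QD < 0.5 (the signature of a second
preferred alternative, as under introgression or hybridisation).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .treecore import (Bipartition, Node, PhyloTree, TreeError,
                       UnknownTaxonError, prune_to_tips, relabel_tips)

QC_STRONG = 0.2
QD_SKEW = 0.5
PLASTOME_QC_CONFLICT = -0.2

_LOG3 = math.log(3.0)


# ---------------------------------------------------------------------------
# unrooted adjacency and branch contexts
# ---------------------------------------------------------------------------

def _unrooted_adjacency(tree: PhyloTree):
    """Adjacency map of the unrooted view (degree-2 root suppressed)."""
    adj: dict[int, list[Node]] = {}
    nodes: dict[int, Node] = {}

    def link(a: Node, b: Node):
        adj.setdefault(id(a), []).append(b)
        adj.setdefault(id(b), []).append(a)
        nodes[id(a)] = a
        nodes[id(b)] = b

    root = tree.root
    suppress = len(root.children) == 2
    for nd in tree.preorder():
        nodes.setdefault(id(nd), nd)
        adj.setdefault(id(nd), [])
        for c in nd.children:
            if suppress and nd is root:
                continue
            link(nd, c)
    if suppress:
        link(root.children[0], root.children[1])
    return adj, nodes


def _tipset_away(adj, start: Node, avoid: Node) -> frozenset:
    """Tips reachable from *start* without crossing the start--avoid edge."""
    out = []
    stack = [(start, avoid)]
    while stack:
        nd, prev = stack.pop()
        if nd.is_leaf():
            out.append(nd.label)
        for nb in adj[id(nd)]:
            if nb is not prev:
                stack.append((nb, nd))
    return frozenset(out)


@dataclass
class BranchContext:
    """An internal species-tree branch and its four neighbour tip groups."""
    node: Node                       # child-side node in the rooted input
    bipartition: Bipartition
    groups: tuple | None             # (A, B, C, D) frozensets of species, or None
    reason: str = ""

    @property
    def key(self) -> frozenset:
        return self.bipartition.side


def branch_contexts(tree: PhyloTree) -> list[BranchContext]:
    """All internal unrooted branches with their neighbour groups, in preorder.

    Branches adjacent to a polytomy (an endpoint with more than two other
    neighbours in the unrooted view) carry ``groups=None`` and are reported
    as uninformative rather than forced into a quartet convention.
    """
    adj, _ = _unrooted_adjacency(tree)
    universe = tree.tip_labels
    root = tree.root
    suppress = len(root.children) == 2
    out = []
    seen: set[frozenset] = set()
    for nd in tree.preorder():
        if nd is root or nd.is_leaf():
            continue
        if suppress and nd.parent is root:
            partner = next(c for c in root.children if c is not nd)
        else:
            partner = nd.parent
        side = nd.tip_set()
        if len(side) < 2 or len(universe - side) < 2:
            continue
        bip = Bipartition(universe, side)
        if bip.side in seen:
            continue
        seen.add(bip.side)
        if partner.is_leaf():
            continue
        near = [w for w in adj[id(nd)] if w is not partner]
        far = [w for w in adj[id(partner)] if w is not nd]
        if len(near) != 2 or len(far) != 2:
            out.append(BranchContext(nd, bip, None, "polytomy at branch endpoint"))
            continue
        groups_near = sorted((_tipset_away(adj, w, nd) for w in near),
                             key=lambda s: min(s))
        groups_far = sorted((_tipset_away(adj, w, partner) for w in far),
                            key=lambda s: min(s))
        a, b = groups_near
        c, d = groups_far
        out.append(BranchContext(nd, bip, (a, b, c, d)))
    return out


# ---------------------------------------------------------------------------
# tallying
# ---------------------------------------------------------------------------

@dataclass
class BranchTally:
    bipartition: Bipartition
    f: tuple | None          # (f1, f2, f3) or None when m == 0
    m: int                   # gene trees informative for the branch
    M: int                   # gene trees in total
    counts: tuple = (0, 0, 0)  # pooled quadruple counts (diagnostic)


@dataclass
class QuartetTally:
    branches: dict            # Bipartition -> BranchTally, insertion-ordered
    contexts: list            # list[BranchContext] in preorder
    M: int
    mode: str
    K: int | None
    seed: int | None
    pooled: bool = False


def _gene_preprocess(gene_tree: PhyloTree, taxon_map: dict[str, str] | None,
                     species: frozenset):
    """Tip indices, species assignment, and topological distance matrix."""
    tips = gene_tree.tips()
    labels = [t.label for t in tips]
    if taxon_map is None:
        sp = labels
    else:
        missing = [l for l in labels if l not in taxon_map]
        if missing:
            raise UnknownTaxonError(f"gene-tree copies without mapping: {missing[:5]}")
        sp = [taxon_map[l] for l in labels]
    bad = sorted({s for s in sp if s not in species})
    if bad:
        raise UnknownTaxonError(f"mapped species absent from species tree: {bad[:5]}")

    adj, _ = _unrooted_adjacency(gene_tree)
    index = {id(t): i for i, t in enumerate(tips)}
    n = len(tips)
    D = np.zeros((n, n), dtype=np.int32)
    for i, t in enumerate(tips):
        # BFS with unit edge weights over the unrooted graph
        dist = {id(t): 0}
        frontier = [t]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[id(u)]:
                    if id(v) not in dist:
                        dist[id(v)] = dist[id(u)] + 1
                        nxt.append(v)
            frontier = nxt
        for j, t2 in enumerate(tips):
            D[i, j] = dist[id(t2)]

    by_species: dict[str, list[int]] = {}
    for i, s in enumerate(sp):
        by_species.setdefault(s, []).append(i)
    return by_species, D


def _quartet_counts_enumerate(D, ia, ib, ic, idx):
    s1 = D[np.ix_(ia, ib)][:, :, None, None] + D[np.ix_(ic, idx)][None, None, :, :]
    s2 = D[np.ix_(ia, ic)][:, None, :, None] + D[np.ix_(ib, idx)][None, :, None, :]
    s3 = D[np.ix_(ia, idx)][:, None, None, :] + D[np.ix_(ib, ic)][None, :, :, None]
    n1 = int(((s1 < s2) & (s1 < s3)).sum())
    n2 = int(((s2 < s1) & (s2 < s3)).sum())
    n3 = int(((s3 < s1) & (s3 < s2)).sum())
    return n1, n2, n3


def _quartet_counts_sample(D, ia, ib, ic, idx, K, rng):
    a = rng.choice(ia, K)
    b = rng.choice(ib, K)
    c = rng.choice(ic, K)
    d = rng.choice(idx, K)
    s1 = D[a, b] + D[c, d]
    s2 = D[a, c] + D[b, d]
    s3 = D[a, d] + D[b, c]
    n1 = int(((s1 < s2) & (s1 < s3)).sum())
    n2 = int(((s2 < s1) & (s2 < s3)).sum())
    n3 = int(((s3 < s1) & (s3 < s2)).sum())
    return n1, n2, n3


def tally_quartets(species_tree: PhyloTree, gene_trees: list[PhyloTree],
                   taxon_map: dict[str, str] | None = None,
                   mode: str = "enumerate", K: int = 2000,
                   seed: int | None = 0, pooled: bool = False) -> QuartetTally:
    """Per-branch paralog-weighted quartet frequencies across gene trees.

    mode="enumerate" is exact over all copy quadruples; mode="sample" draws
    K quadruples per gene per branch with a generator seeded by *seed*.
    """
    if mode not in ("enumerate", "sample"):
        raise ValueError(f"unknown mode: {mode}")
    contexts = branch_contexts(species_tree)
    species = species_tree.tip_labels
    rng = np.random.default_rng(seed)

    per_branch_vectors: dict[frozenset, list[np.ndarray]] = {c.key: [] for c in contexts}
    per_branch_counts: dict[frozenset, np.ndarray] = {
        c.key: np.zeros(3, dtype=np.int64) for c in contexts}

    group_idx_cache: list[tuple[BranchContext, tuple]] = []
    for gt in gene_trees:
        by_species, D = _gene_preprocess(gt, taxon_map, species)
        for ctx in contexts:
            if ctx.groups is None:
                continue
            idx_groups = []
            for g in ctx.groups:
                idxs = [i for s in sorted(g) for i in by_species.get(s, [])]
                if not idxs:
                    idx_groups = None
                    break
                idx_groups.append(np.asarray(idxs))
            if idx_groups is None:
                continue
            ia, ib, ic, idx = idx_groups
            if mode == "enumerate":
                n1, n2, n3 = _quartet_counts_enumerate(D, ia, ib, ic, idx)
            else:
                n1, n2, n3 = _quartet_counts_sample(D, ia, ib, ic, idx, K, rng)
            tot = n1 + n2 + n3
            if tot == 0:
                continue  # all sampled quadruples unresolved
            per_branch_vectors[ctx.key].append(np.array([n1, n2, n3]) / tot)
            per_branch_counts[ctx.key] += (n1, n2, n3)

    M = len(gene_trees)
    branches: dict[Bipartition, BranchTally] = {}
    for ctx in contexts:
        vecs = per_branch_vectors[ctx.key]
        counts = per_branch_counts[ctx.key]
        m = len(vecs)
        if m == 0:
            branches[ctx.bipartition] = BranchTally(ctx.bipartition, None, 0, M)
            continue
        if pooled:
            f = counts / counts.sum()
        else:
            f = np.mean(vecs, axis=0)
        branches[ctx.bipartition] = BranchTally(
            ctx.bipartition, tuple(float(x) for x in f), m, M, tuple(int(x) for x in counts))
    return QuartetTally(branches, contexts, M, mode,
                        K if mode == "sample" else None,
                        seed if mode == "sample" else None, pooled)


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def qc_score(f1: float, f2: float, f3: float, tol: float = 1e-6) -> float:
    """Quartet concordance of a frequency triple (f1 = displayed quartet)."""
    f = (f1, f2, f3)
    if any(x < -tol for x in f):
        raise ValueError(f"negative frequency: {f}")
    if abs(sum(f) - 1.0) > max(tol, 1e-9):
        raise ValueError(f"frequencies must sum to 1, got {sum(f)!r}")
    ent = 0.0
    for x in f:
        if x > 0:
            ent += x * math.log(x) / _LOG3
    mag = 1.0 + ent
    best_alt = max(f2, f3)
    if f1 > best_alt:
        return mag
    if best_alt > f1:
        return -mag
    return 0.0


def qd_score(f2: float, f3: float) -> float:
    """Quartet differential min/max of the two alternatives; NaN at 0/0."""
    if f2 < 0 or f3 < 0:
        raise ValueError(f"negative frequency: {(f2, f3)}")
    hi = max(f2, f3)
    if hi == 0:
        return float("nan")
    return min(f2, f3) / hi


def branch_flags(qc: float, qd: float) -> list[str]:
    flags = []
    if qc > QC_STRONG:
        flags.append("strong_support")
    elif qc >= 0:
        flags.append("conflicted")
    if qc <= QC_STRONG and not math.isnan(qd) and qd < QD_SKEW:
        flags.append("skewed_conflict")
    return flags


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_tree(species_tree: PhyloTree, tally: QuartetTally) -> PhyloTree:
    """Copy of the species tree with QC/QD/m/M annotations per internal branch."""
    out = species_tree.copy()
    by_side = {ctx.key: ctx.bipartition for ctx in tally.contexts}
    universe = out.tip_labels
    for nd in out.preorder():
        if nd is out.root or nd.is_leaf():
            continue
        side = nd.tip_set()
        if len(side) < 2 or len(universe - side) < 2:
            continue
        key = Bipartition(universe, side).side
        bip = by_side.get(key)
        if bip is None:
            continue
        bt = tally.branches[bip]
        if bt.f is None:
            nd.annotations.update({"QC": "NA", "QD": "NA", "m": 0, "M": bt.M})
            continue
        qc = qc_score(*bt.f)
        qd = qd_score(bt.f[1], bt.f[2])
        nd.annotations.update({
            "QC": round(qc, 4),
            "QD": "NA" if math.isnan(qd) else round(qd, 4),
            "m": bt.m, "M": bt.M,
        })
        flags = branch_flags(qc, qd)
        if flags:
            nd.annotations["flags"] = "+".join(flags)
    return out


def branch_table(tally: QuartetTally) -> pd.DataFrame:
    """Tabular per-branch report (one row per internal branch)."""
    rows = []
    for i, ctx in enumerate(tally.contexts, 1):
        bt = tally.branches[ctx.bipartition]
        side = ",".join(sorted(ctx.key))
        row = {
            "branch": f"b{i}",
            "tipset_hash": f"{hash(ctx.key) & 0xFFFFFFFF:08x}",
            "side": side,
            "m": bt.m, "M": bt.M,
        }
        if bt.f is None:
            row.update({"f1": np.nan, "f2": np.nan, "f3": np.nan,
                        "QC": np.nan, "QD": np.nan, "flags": ""})
        else:
            qc = qc_score(*bt.f)
            qd = qd_score(bt.f[1], bt.f[2])
            row.update({"f1": bt.f[0], "f2": bt.f[1], "f3": bt.f[2],
                        "QC": qc, "QD": qd,
                        "flags": "+".join(branch_flags(qc, qd))})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plastome signed QC and cyto-nuclear conflict
# ---------------------------------------------------------------------------

def plastome_signed_qc(nuclear_tree: PhyloTree, bootstrap_trees: list[PhyloTree],
                       match: dict[str, str] | None = None):
    """Signed QC per nuclear branch from a set of (plastome) bootstrap trees.

    Bootstrap trees are treated as single-copy gene trees tallied against the
    nuclear tree after both are reduced to the shared (matched) tip set.
    +1 means unanimous agreement with the nuclear quartet, -1 unanimous
    support for one alternative.  Returns ``(qc_by_side, pruned_tree, tally)``
    where keys of *qc_by_side* are canonical bipartition sides of the pruned
    nuclear tree; branches with an empty neighbour group map to NaN.
    """
    boots = bootstrap_trees
    if match:
        boots = [relabel_tips(bt, match) for bt in boots]
    shared = nuclear_tree.tip_labels
    for bt in boots:
        shared = shared & bt.tip_labels
    if len(shared) < 4:
        raise TreeError(f"shared matched tip set too small ({len(shared)} tips)")
    pruned = prune_to_tips(nuclear_tree, shared)
    pruned_boots = [prune_to_tips(bt, shared) for bt in boots]
    tally = tally_quartets(pruned, pruned_boots, taxon_map=None, mode="enumerate")
    qc_by_side: dict[frozenset, float] = {}
    for ctx in tally.contexts:
        bt = tally.branches[ctx.bipartition]
        qc_by_side[ctx.key] = qc_score(*bt.f) if bt.f is not None else float("nan")
    return qc_by_side, pruned, tally


@dataclass
class ConflictReport:
    table: pd.DataFrame
    r: float
    t: float
    p: float
    n: int
    matched_tips: int = 0

    @property
    def conflicts(self) -> pd.DataFrame:
        return self.table[self.table["conflict"]]


def classify_branches(nuclear_qc: dict, plastome_qc: dict,
                      nuclear_min: float = QC_STRONG,
                      plastome_max: float = PLASTOME_QC_CONFLICT,
                      matched_tips: int = 0) -> ConflictReport:
    """Flag cyto-nuclear conflicts and correlate the two QC vectors.

    A branch is in conflict when the nuclear QC exceeds *nuclear_min* and the
    plastome signed QC is below *plastome_max*.  Pearson correlation (r, t,
    two-sided p) is computed over branches where both values are defined;
    fewer than 3 such branches gives NaN statistics.
    """
    keys = [k for k in nuclear_qc if k in plastome_qc]
    rows = []
    for k in sorted(keys, key=lambda s: sorted(s)):
        nq, pq = nuclear_qc[k], plastome_qc[k]
        defined = not (math.isnan(nq) or math.isnan(pq))
        rows.append({
            "side": ",".join(sorted(k)),
            "nuclear_qc": nq, "plastome_qc": pq,
            "conflict": bool(defined and nq > nuclear_min and pq < plastome_max),
        })
    table = pd.DataFrame(rows)
    both = table.dropna(subset=["nuclear_qc", "plastome_qc"])
    n = len(both)
    if n < 3 or both["nuclear_qc"].nunique() < 2 or both["plastome_qc"].nunique() < 2:
        r = t = p = float("nan")
    else:
        r, p = stats.pearsonr(both["nuclear_qc"], both["plastome_qc"])
        if abs(r) >= 1.0:
            t = math.inf if r > 0 else -math.inf
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return ConflictReport(table, float(r), float(t), float(p), n, matched_tips)
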