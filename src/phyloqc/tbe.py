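"""Transfer bootstrap expectation (TBE) branch support.

For a reference bipartition b with lighter side of size p, the transfer
index against a bootstrap tree is the minimum, over all edges of that tree
(pendant edges included, which guarantees delta <= p-1), of the number of
taxa that must switch sides to turn the edge's bipartition into b.  TBE
support is 1 - mean(delta/(p-1)) over bootstrap trees: 1 for a branch found
in every bootstrap tree, and a gradual value (rather than presence/absence)
otherwise.  A naive O(edges^2 * taxa) scan is used; it is exact and more
than fast enough at the tree sizes this package targets.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .treecore import Bipartition, PhyloTree, TreeError, splits


def transfer_index(b: Bipartition, tree: PhyloTree) -> int:
    """Minimum number of taxa to move so some edge of *tree* displays *b*."""
    if tree.tip_labels != b.universe:
        diff = tree.tip_labels ^ b.universe
        raise TreeError(f"taxon universe mismatch: {sorted(diff)[:10]}")
    side = b.side
    n = len(b.universe)
    best = min(len(side), n - len(side))  # trivial edge (empty side) bound
    for s in splits(tree, include_pendant=True):
        h = len(side ^ s.side)
        h = min(h, n - h)
        if h < best:
            best = h
            if best == 0:
                break
    return best


@dataclass
class TbeBranch:
    bipartition: Bipartition
    p: int                    # lighter-side size
    mean_delta: float
    support: float
    n_boots: int


def tbe_support(ref: PhyloTree, bootstraps: list[PhyloTree]) -> dict:
    """TBE support for every internal branch of *ref*.

    Bootstrap trees lacking some of the reference taxa are skipped for the
    branches they cannot score (their taxa are restricted per tree).
    Returns a mapping canonical side -> :class:`TbeBranch`.
    """
    if not bootstraps:
        raise TreeError("at least one bootstrap tree required")
    ref_splits = sorted(splits(ref), key=lambda b: sorted(b.side))
    if not ref_splits:
        raise TreeError("reference tree has no internal branches to score")

    # cache split sets per bootstrap tree
    boot_data = []
    for bt in bootstraps:
        boot_data.append((bt.tip_labels,
                          [s.side for s in splits(bt, include_pendant=True)]))

    out: dict[frozenset, TbeBranch] = {}
    universe = ref.tip_labels
    n = len(universe)
    for b in ref_splits:
        p = b.lighter_size()
        if p < 2:
            continue
        deltas = []
        for taxa, sides in boot_data:
            if taxa != universe:
                # restrict the reference bipartition to the bootstrap's taxa
                bside = b.side & taxa
                if not bside or bside == taxa:
                    continue
                rb = Bipartition(taxa, bside)
                if rb.lighter_size() < 2:
                    continue
                tree_univ, pp = taxa, rb.lighter_size()
                target = rb.side
            else:
                tree_univ, pp, target = universe, p, b.side
            nn = len(tree_univ)
            best = min(len(target), nn - len(target))
            for s in sides:
                h = len(target ^ s)
                h = min(h, nn - h)
                if h < best:
                    best = h
                    if best == 0:
                        break
            deltas.append(best / (pp - 1))
        if not deltas:
            continue
        mean_norm = sum(deltas) / len(deltas)
        out[b.side] = TbeBranch(b, p, mean_norm * (p - 1), 1.0 - mean_norm,
                                len(deltas))
    if not out:
        raise TreeError("no scorable branches")
    return out


def annotate_tbe(ref: PhyloTree, support: dict) -> PhyloTree:
    """Copy of *ref* with TBE support attached as internal-branch annotations."""
    out = ref.copy()
    universe = out.tip_labels
    for nd in out.preorder():
        if nd is out.root or nd.is_leaf():
            continue
        side = nd.tip_set()
        if len(side) < 2 or len(universe - side) < 2:
            continue
        key = Bipartition(universe, side).side
        if key in support:
            nd.annotations["TBE"] = round(support[key].support, 4)
    return out


def tbe_table(support: dict) -> pd.DataFrame:
    rows = [{"side": ",".join(sorted(k)), "p": tb.p,
             "mean_transfer_index": tb.mean_delta, "support": tb.support,
             "n_bootstraps": tb.n_boots}
            for k, tb in sorted(support.items(), key=lambda kv: sorted(kv[0]))]
    return pd.DataFrame(rows)
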