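"""Core tree model: newick I/O, bipartitions, monophyly, rooting, clade collapsing.

Every stage of the package works on :class:`PhyloTree`, a small parent/child
node structure carrying optional branch lengths and free-form per-branch
annotations.  Newick parsing is delegated to dendropy; writing is done
in-package so annotations serialize as internal-node labels of the form
``key=value|key=value`` and survive a read/write round trip.

Conventions
-----------
* Internal newick labels are branch annotations (e.g. bootstrap support),
  never taxon names.  Quoted labels are honoured.
* Unrooted operations (bipartitions, quartets) view a degree-2 root as
  suppressed; rooted operations (monophyly, clade collapsing) require an
  explicitly rooted tree.
* All argmax/tie situations are broken by a deterministic preorder (then
  lexicographic) rule so repeated runs are identical.
"""
from __future__ import annotations

import re
from typing import Callable, Iterable, Iterator

import dendropy


class TreeError(ValueError):
    """Base class for tree-structure and tree-input errors."""


class NewickParseError(TreeError):
    pass


class DuplicateTipError(TreeError):
    pass


class UnknownTaxonError(TreeError):
    pass


# ---------------------------------------------------------------------------
# node / tree model
# ---------------------------------------------------------------------------

class Node:
    __slots__ = ("label", "length", "children", "parent", "annotations")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.annotations: dict[str, object] = {}

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return reversed(out)

    def tip_set(self) -> frozenset:
        return frozenset(nd.label for nd in self.preorder() if nd.is_leaf())

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.label!r} len={self.length}>"


class PhyloTree:
    """Rooted or unrooted labelled tree with branch lengths and annotations."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self.validate()

    # -- basic accessors ----------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def tips(self) -> list[Node]:
        return [nd for nd in self.preorder() if nd.is_leaf()]

    @property
    def tip_labels(self) -> frozenset:
        return frozenset(nd.label for nd in self.tips())

    def internal_nodes(self) -> list[Node]:
        return [nd for nd in self.preorder() if not nd.is_leaf()]

    def n_tips(self) -> int:
        return len(self.tips())

    def validate(self) -> None:
        labels = [nd.label for nd in self.tips()]
        if len(labels) != len(set(labels)):
            seen, dup = set(), set()
            for x in labels:
                (dup if x in seen else seen).add(x)
            raise DuplicateTipError(f"duplicate tip labels: {sorted(dup)}")
        for nd in self.preorder():
            if nd.length is not None and nd.length < 0:
                raise TreeError(f"negative branch length on {nd.label!r}")

    def copy(self) -> "PhyloTree":
        def _copy(nd: Node) -> Node:
            new = Node(nd.label, nd.length)
            new.annotations = dict(nd.annotations)
            for c in nd.children:
                new.add_child(_copy(c))
            return new

        return PhyloTree(_copy(self.root), rooted=self.rooted)

    def is_binary(self) -> bool:
        for nd in self.preorder():
            if nd.is_leaf():
                continue
            k = len(nd.children)
            if nd is self.root:
                if k not in (2, 3):
                    return False
            elif k != 2:
                return False
        return True

    # -- serialization ------------------------------------------------------
    def newick(self, annotations: bool = True, precision: int = 6) -> str:
        return _to_newick(self, annotations=annotations, precision=precision) + ";"

    def __str__(self):
        return self.newick()


_QUOTE_NEEDED = re.compile(r"[\s()\[\]{}:;,'\"=|]")


def _quote(label: str) -> str:
    if _QUOTE_NEEDED.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_len(x: float, precision: int) -> str:
    s = f"{x:.{precision}g}"
    return s


def _node_label(nd: Node, annotations: bool) -> str:
    if annotations and nd.annotations:
        parts = []
        for k, v in nd.annotations.items():
            if isinstance(v, float):
                v = f"{v:.4g}"
            parts.append(f"{k}={v}")
        return _quote("|".join(parts))
    if nd.label is not None:
        return _quote(str(nd.label))
    return ""


def _to_newick(tree: PhyloTree, annotations: bool, precision: int) -> str:
    def rec(nd: Node) -> str:
        if nd.is_leaf():
            s = _quote(str(nd.label))
        else:
            s = "(" + ",".join(rec(c) for c in nd.children) + ")"
            s += _node_label(nd, annotations)
        if nd.length is not None:
            s += ":" + _fmt_len(nd.length, precision)
        return s

    return rec(tree.root)


_ANNOT_RE = re.compile(r"^[\w.+-]+=[^|]*(\|[\w.+-]+=[^|]*)*$")


def _maybe_parse_annotations(nd: Node) -> None:
    if nd.label and "=" in nd.label and _ANNOT_RE.match(nd.label):
        annots = {}
        for part in nd.label.split("|"):
            k, _, v = part.partition("=")
            annots[k] = v
        nd.annotations = annots
        nd.label = None


def _from_dendropy(dtree: dendropy.Tree) -> Node:
    def conv(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        nd = Node(label, dnode.edge.length)
        for c in dnode.child_nodes():
            nd.add_child(conv(c))
        if not nd.is_leaf():
            _maybe_parse_annotations(nd)
        return nd

    return conv(dtree.seed_node)


def parse_newick(text: str, rooted: bool = True) -> list[PhyloTree]:
    """Parse one or more newick statements from a string."""
    try:
        tlist = dendropy.TreeList.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy error messages carry line numbers
        raise NewickParseError(str(exc)) from exc
    trees = []
    for dt in tlist:
        trees.append(PhyloTree(_from_dendropy(dt), rooted=rooted))
    return trees


def read_trees(path, rooted: bool = True) -> list[PhyloTree]:
    """Read all newick trees from a file (one or many statements)."""
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        return []
    return parse_newick(text, rooted=rooted)


def write_trees(trees: Iterable[PhyloTree], path, annotations: bool = True) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.newick(annotations=annotations) + "\n")


# ---------------------------------------------------------------------------
# taxon / clade maps
# ---------------------------------------------------------------------------

def read_taxon_map(path) -> dict[str, str]:
    """Read a copy->species map: two whitespace- or tab-separated columns."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{i}: expected 2 columns, got {len(parts)}")
            mapping[parts[0]] = parts[1]
    return mapping


read_clade_map = read_taxon_map


def check_taxon_map(map_: dict[str, str], gene_tips: Iterable[str],
                    species_tips: Iterable[str]) -> list[str]:
    """Return a list of problems (unmapped copies / unknown species)."""
    problems = []
    species = set(species_tips)
    for tip in gene_tips:
        if tip not in map_:
            problems.append(f"unmapped copy: {tip}")
        elif map_[tip] not in species:
            problems.append(f"species not in species tree: {map_[tip]} (copy {tip})")
    return problems


# ---------------------------------------------------------------------------
# bipartitions
# ---------------------------------------------------------------------------

class Bipartition:
    """Unrooted split of a taxon universe, stored in canonical form.

    The canonical side is the one *not* containing the lexicographically
    smallest universe label, so equality and hashing are orientation-free.
    """

    __slots__ = ("universe", "side")

    def __init__(self, universe: Iterable[str], side: Iterable[str]):
        universe = frozenset(universe)
        side = frozenset(side)
        if not side or side == universe:
            raise ValueError("bipartition sides must be nonempty proper subsets")
        if not side <= universe:
            raise ValueError("side is not a subset of the universe")
        if min(universe) in side:
            side = universe - side
        self.universe = universe
        self.side = side

    @property
    def other(self) -> frozenset:
        return self.universe - self.side

    def lighter_size(self) -> int:
        return min(len(self.side), len(self.universe) - len(self.side))

    def is_trivial(self) -> bool:
        return self.lighter_size() < 2

    def __eq__(self, o):
        return (isinstance(o, Bipartition)
                and self.universe == o.universe and self.side == o.side)

    def __hash__(self):
        return hash((self.universe, self.side))

    def __repr__(self):
        a = ",".join(sorted(self.side))
        b = ",".join(sorted(self.other))
        return f"Bipartition({a} | {b})"


def splits(tree: PhyloTree, include_pendant: bool = False) -> set[Bipartition]:
    """All bipartitions of the unrooted interpretation of *tree*.

    One bipartition per internal edge; a degree-2 root's two edges are the
    same unrooted edge and are deduplicated by canonicalization.
    """
    universe = tree.tip_labels
    if len(universe) < 2:
        return set()
    out: set[Bipartition] = set()
    for nd in tree.preorder():
        if nd is tree.root:
            continue
        side = nd.tip_set()
        if len(side) == len(universe):  # degenerate unary chain above
            continue
        bip = Bipartition(universe, side)
        if include_pendant or not bip.is_trivial():
            out.add(bip)
    return out


# ---------------------------------------------------------------------------
# rooted operations
# ---------------------------------------------------------------------------

def is_monophyletic(tree: PhyloTree, tipset: Iterable[str]) -> bool:
    """True iff some clade of the rooted tree equals *tipset* exactly."""
    if not tree.rooted:
        raise TreeError("monophyly requires a rooted tree")
    tipset = frozenset(tipset)
    unknown = tipset - tree.tip_labels
    if unknown:
        raise UnknownTaxonError(f"labels not in tree: {sorted(unknown)}")
    for nd in tree.preorder():
        if nd.tip_set() == tipset:
            return True
    return False


def _suppress_unary(node: Node) -> None:
    """Collapse unary internal nodes below *node* in place, merging lengths."""
    stack = [node]
    while stack:
        nd = stack.pop()
        changed = True
        while changed:
            changed = False
            for i, c in enumerate(nd.children):
                if len(c.children) == 1:
                    g = c.children[0]
                    if g.length is not None or c.length is not None:
                        g.length = (g.length or 0.0) + (c.length or 0.0)
                    g.parent = nd
                    nd.children[i] = g
                    changed = True
        stack.extend(nd.children)


def root_on_longest_branch(tree: PhyloTree) -> PhyloTree:
    """Reroot so the root subdivides the longest edge (midpoint of that edge).

    Ties are broken by the first edge encountered in a preorder traversal of
    the input, so the result is stable across runs.  All edges must have
    branch lengths.
    """
    work = tree.copy()
    candidates = [nd for nd in work.preorder() if nd is not work.root]
    if not candidates:
        raise TreeError("tree has no edges to root on")
    missing = [nd.label for nd in candidates if nd.length is None]
    if missing:
        raise TreeError(f"branch lengths required on all edges; missing on {missing[:5]}")
    best = max(candidates, key=lambda nd: nd.length)  # max keeps first on ties

    half = best.length / 2.0
    parent = best.parent
    parent.children.remove(best)
    new_root = Node()
    new_root.add_child(best)
    best.length = half

    # reverse the parent chain: the old parent side hangs off the new root
    prev = new_root
    carry = half
    cur = parent
    while cur is not None:
        nxt = cur.parent
        nxt_len = cur.length
        if nxt is not None:
            nxt.children.remove(cur)
        cur.parent = None
        prev.add_child(cur)
        cur.length = carry
        carry = nxt_len
        prev = cur
        cur = nxt

    # the old root may now be unary; suppress it
    root_tree = PhyloTree(new_root, rooted=True)
    _suppress_unary(new_root)
    if len(new_root.children) == 1:
        only = new_root.children[0]
        only.parent = None
        only.length = None
        root_tree.root = only
    root_tree.validate()
    assert root_tree.tip_labels == tree.tip_labels
    return root_tree


def collapse_to_clades(tree: PhyloTree, clades: dict[str, str],
                       mode: str = "strict") -> PhyloTree:
    """Replace maximal monophyletic same-clade tip groups by one clade tip.

    strict   -- error if any clade is split across several maximal blocks.
    majority -- the largest block (ties: first in preorder) keeps the clade
                label; remaining blocks are relabelled ``<clade>_outlierN``.
    """
    if mode not in ("strict", "majority"):
        raise ValueError(f"unknown mode: {mode}")
    if not tree.rooted:
        raise TreeError("clade collapsing requires a rooted tree")
    work = tree.copy()
    unmapped = [t for t in work.tip_labels if t not in clades]
    if unmapped:
        raise UnknownTaxonError(f"tips without a clade mapping: {sorted(unmapped)[:5]}")

    # a node is "pure" if all tips below belong to one clade
    pure: dict[int, str | None] = {}
    for nd in work.postorder():
        if nd.is_leaf():
            pure[id(nd)] = clades[nd.label]
        else:
            kid_clades = {pure[id(c)] for c in nd.children}
            pure[id(nd)] = kid_clades.pop() if len(kid_clades) == 1 else None
            if pure[id(nd)] is None:
                pure[id(nd)] = None

    # maximal pure nodes in preorder
    blocks: list[tuple[Node, str]] = []

    def walk(nd: Node):
        cl = pure[id(nd)]
        if cl is not None:
            blocks.append((nd, cl))
            return
        for c in nd.children:
            walk(c)

    walk(work.root)

    by_clade: dict[str, list[Node]] = {}
    for nd, cl in blocks:
        by_clade.setdefault(cl, []).append(nd)

    relabel: dict[int, str] = {}
    for cl, nds in by_clade.items():
        if len(nds) == 1:
            relabel[id(nds[0])] = cl
            continue
        if mode == "strict":
            raise TreeError(f"clade {cl!r} is not monophyletic ({len(nds)} blocks)")
        sizes = [len(nd.tip_set()) for nd in nds]
        keep = nds[sizes.index(max(sizes))]  # first preorder block on ties
        relabel[id(keep)] = cl
        i = 0
        for nd in nds:
            if nd is keep:
                continue
            i += 1
            relabel[id(nd)] = f"{cl}_outlier{i}"

    for nd, _ in blocks:
        nd.children = []
        nd.label = relabel[id(nd)]
        nd.annotations = {}
    _suppress_unary(work.root)
    if len(work.root.children) == 1:
        only = work.root.children[0]
        only.parent = None
        work.root = only
    collapsed = PhyloTree(work.root, rooted=True)
    return collapsed


# ---------------------------------------------------------------------------
# pruning / rearrangement
# ---------------------------------------------------------------------------

def prune_to_tips(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Restrict the tree to *keep*, suppressing unary nodes (lengths merged)."""
    keep = frozenset(keep)
    unknown = keep - tree.tip_labels
    if unknown:
        raise UnknownTaxonError(f"labels not in tree: {sorted(unknown)[:5]}")
    if len(keep) < 2:
        raise TreeError("need at least 2 tips after pruning")
    work = tree.copy()

    def rec(nd: Node) -> Node | None:
        if nd.is_leaf():
            return nd if nd.label in keep else None
        new_children = []
        for c in nd.children:
            kept = rec(c)
            if kept is not None:
                new_children.append(kept)
        if not new_children:
            return None
        nd.children = []
        for c in new_children:
            nd.add_child(c)
        return nd

    root = rec(work.root)
    _suppress_unary(root)
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = None
    return PhyloTree(root, rooted=tree.rooted)


def relabel_tips(tree: PhyloTree, mapping: dict[str, str]) -> PhyloTree:
    work = tree.copy()
    for nd in work.tips():
        if nd.label in mapping:
            nd.label = mapping[nd.label]
    work.validate()
    return work


def internal_edges(tree: PhyloTree) -> list[Node]:
    """Child-side nodes of internal edges, in preorder.

    For a rooted tree with a degree-2 root, only the first root child is
    reported (both root edges are the same unrooted edge).
    """
    out = []
    universe = tree.tip_labels
    seen: set[frozenset] = set()
    for nd in tree.preorder():
        if nd is tree.root or nd.is_leaf():
            continue
        side = nd.tip_set()
        if len(side) < 2 or len(universe - side) < 2:
            continue
        key = Bipartition(universe, side).side
        if key in seen:
            continue
        seen.add(key)
        out.append(nd)
    return out


def nni(tree: PhyloTree, edge_child: Node | frozenset, variant: int = 0) -> PhyloTree:
    """One nearest-neighbour interchange across the internal edge above a node.

    *edge_child* is the child-side node of the edge (or its tip set, resolved
    on the tree).  ``variant`` (0 or 1) selects which of the node's children
    is swapped with the node's sibling.
    """
    work = tree.copy()
    if isinstance(edge_child, (frozenset, set)):
        target_set = frozenset(edge_child)
    else:
        target_set = edge_child.tip_set()
    universe = work.tip_labels
    node = next((nd for nd in work.preorder()
                 if not nd.is_leaf() and nd is not work.root
                 and nd.tip_set() in (target_set, universe - target_set)), None)
    if node is None:
        raise TreeError("no internal edge with that tip set")
    parent = node.parent
    if len(node.children) < 2:
        raise TreeError("edge is not eligible for NNI")
    if parent is work.root and len(work.root.children) == 2:
        # the edge crosses the (suppressed) root: the exchange partner must
        # come from inside the other root child, not be that child itself
        partner = next(c for c in work.root.children if c is not node)
        if partner.is_leaf() or not partner.children:
            raise TreeError("edge is not eligible for NNI")
        other, holder = partner.children[0], partner
    else:
        sibs = [c for c in parent.children if c is not node]
        if not sibs:
            raise TreeError("edge is not eligible for NNI")
        other, holder = sibs[0], parent
    child = node.children[variant % len(node.children)]
    hi = holder.children.index(other)
    ni = node.children.index(child)
    holder.children[hi], node.children[ni] = child, other
    child.parent, other.parent = holder, node
    return PhyloTree(work.root, rooted=work.rooted)


def assign_branch_ids(tree: PhyloTree, prefix: str = "N") -> PhyloTree:
    """Label unlabelled internal nodes ``N1..Nk`` in preorder (in place)."""
    i = 0
    for nd in tree.preorder():
        if not nd.is_leaf() and not nd.label and not nd.annotations:
            i += 1
            nd.label = f"{prefix}{i}"
    return tree
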