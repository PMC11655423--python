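"""Aggregate reconciliation transfer events into a reticulation summary.

Duplication-transfer-loss reconciliation of gene trees against a species
tree yields transfer events between pairs of species-tree branches.  This
module applies the summary rules used downstream of such reconciliations:

* transfers to or from the root branch are excluded (they may involve
  unsampled outgroup lineages);
* a branch pair is *supported* when at least ``min_support`` distinct gene
  trees contribute a transfer between its branches (a flag allows counting
  raw events instead, admitting within-family multiplicity);
* *highlighted* pairs are the supported pairs whose support reaches the top
  ``top_quantile`` of supported-pair supports (upper nearest-rank cutoff);
* a pair is *directional* when its per-direction counts a, b satisfy
  |a - b| / (a + b) > ``skew_threshold`` (an alternative |a - b| / max(a, b)
  formalisation is available behind a flag).

Branch ids are node labels of the species tree: tip labels for pendant
branches and internal-node labels for internal ones (use
:func:`phyloqc.treecore.assign_branch_ids` to label a bare tree).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treecore import PhyloTree, TreeError, collapse_to_clades


@dataclass(frozen=True)
class TransferRecord:
    gene: str
    donor: str
    recipient: str
    count: int = 1

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("transfer count must be >= 1")
        if self.donor == self.recipient:
            raise ValueError(f"donor equals recipient: {self.donor}")


def read_transfer_records(path) -> list[TransferRecord]:
    """Read tab-separated records: gene, donor branch, recipient branch, count."""
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 4):
                raise ValueError(f"{path}:{i}: expected 3-4 columns")
            count = int(parts[3]) if len(parts) == 4 else 1
            records.append(TransferRecord(parts[0], parts[1], parts[2], count))
    return records


@dataclass
class TransferSummary:
    table: pd.DataFrame            # one row per unordered branch pair
    root_excluded: int             # records dropped for touching the root
    min_support: int
    top_quantile: float
    skew_threshold: float

    @property
    def supported(self) -> pd.DataFrame:
        return self.table[self.table["supported"]]

    @property
    def highlighted(self) -> pd.DataFrame:
        return self.table[self.table["highlighted"]]


def _branch_ids(tree: PhyloTree) -> tuple[set, str]:
    ids = set()
    for nd in tree.preorder():
        if nd.label:
            ids.add(nd.label)
    root_id = tree.root.label or "root"
    ids.add(root_id)
    return ids, root_id


def summarize_transfers(records: list[TransferRecord], tree: PhyloTree,
                        min_support: int = 5, top_quantile: float = 0.10,
                        skew_threshold: float = 0.5,
                        count_mode: str = "genes",
                        skew_mode: str = "sum",
                        quantile_over: str = "supported") -> TransferSummary:
    """Threshold and flag transfer events on the species tree.

    count_mode="genes" counts distinct gene ids per pair/direction (the
    conservative reading); "events" sums raw event counts.  skew_mode="sum"
    uses |a-b|/(a+b), "max" uses |a-b|/max(a,b).  quantile_over selects
    whether the highlight cutoff is taken over supported pairs only
    (default) or over all pairs.
    """
    if count_mode not in ("genes", "events"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    if skew_mode not in ("sum", "max"):
        raise ValueError(f"unknown skew_mode {skew_mode!r}")
    if quantile_over not in ("supported", "all"):
        raise ValueError(f"unknown quantile_over {quantile_over!r}")
    valid_ids, root_id = _branch_ids(tree)

    root_excluded = 0
    directed: dict[tuple[str, str], dict] = {}
    for rec in records:
        for b in (rec.donor, rec.recipient):
            if b not in valid_ids:
                raise TreeError(f"branch id not on species tree: {b!r}")
        if rec.donor == root_id or rec.recipient == root_id:
            root_excluded += 1
            continue
        d = directed.setdefault((rec.donor, rec.recipient),
                                {"genes": set(), "events": 0})
        d["genes"].add(rec.gene)
        d["events"] += rec.count

    pairs: dict[tuple[str, str], dict] = {}
    for (donor, recip), d in directed.items():
        key = tuple(sorted((donor, recip)))
        p = pairs.setdefault(key, {"genes": set(), "events": 0,
                                   "dir": {key[0]: 0, key[1]: 0}})
        p["genes"] |= d["genes"]
        p["events"] += d["events"]
        n = len(d["genes"]) if count_mode == "genes" else d["events"]
        p["dir"][donor] += n

    rows = []
    for (x, y), p in sorted(pairs.items()):
        support = len(p["genes"]) if count_mode == "genes" else p["events"]
        a, b = p["dir"][x], p["dir"][y]
        denom = (a + b) if skew_mode == "sum" else max(a, b)
        skew = abs(a - b) / denom if denom else 0.0
        directional = skew > skew_threshold
        rows.append({
            "branch_a": x, "branch_b": y,
            "support": support,
            "n_genes": len(p["genes"]), "n_events": p["events"],
            "count_a_to_b": a, "count_b_to_a": b,
            "skew": skew,
            "directional": directional,
            "direction": (f"{x}->{y}" if a > b else f"{y}->{x}") if directional else "",
            "supported": support >= min_support,
        })
    table = pd.DataFrame(rows, columns=[
        "branch_a", "branch_b", "support", "n_genes", "n_events",
        "count_a_to_b", "count_b_to_a", "skew", "directional", "direction",
        "supported"])

    if len(table):
        pool = table[table["supported"]] if quantile_over == "supported" else table
        if len(pool):
            cutoff = float(np.quantile(pool["support"].to_numpy(),
                                       1.0 - top_quantile, method="higher"))
            table["highlighted"] = table["supported"] & (table["support"] >= cutoff)
        else:
            table["highlighted"] = False
    else:
        table["highlighted"] = pd.Series(dtype=bool)
    return TransferSummary(table, root_excluded, min_support, top_quantile,
                           skew_threshold)


def collapse_and_summarize(records: list[TransferRecord], tree: PhyloTree,
                           clades: dict[str, str], mode: str = "strict",
                           **kwargs) -> TransferSummary:
    """Clade (tribe)-level summary: remap branch ids through the collapsed tree.

    Species-level branch ids are mapped to the collapsed tree: a branch whose
    descendant species all belong to one clade maps to that clade's pendant
    branch; a deeper branch maps to the collapsed branch with the same clade
    tip set.  Note the resulting counts combine gene-tree tips from all
    species within a clade.
    """
    collapsed = collapse_to_clades(tree, clades, mode=mode)
    collapsed_sets = {}
    for nd in collapsed.preorder():
        if nd.label:
            collapsed_sets[frozenset(nd.tip_set())] = nd.label

    species_node = {}
    for nd in tree.preorder():
        if nd.label:
            species_node[nd.label] = nd

    def remap(branch_id: str) -> str:
        nd = species_node.get(branch_id)
        if nd is None:
            raise TreeError(f"branch id not on species tree: {branch_id!r}")
        clade_set = frozenset(clades.get(t, t) for t in nd.tip_set())
        label = collapsed_sets.get(clade_set)
        if label is None:
            raise TreeError(f"branch {branch_id!r} has no image in the collapsed tree")
        return label

    remapped = []
    for rec in records:
        donor, recip = remap(rec.donor), remap(rec.recipient)
        if donor == recip:   # transfer entirely within one clade
            continue
        remapped.append(TransferRecord(rec.gene, donor, recip, rec.count))
    return summarize_transfers(remapped, collapsed, **kwargs)
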