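"""Post-assembly paralog handling for low-coverage mapping-consensus data.

After consensus calling, an accession may carry several assemblies for one
orthogroup.  These are treated as putative paralogs and pass through three
steps: (1) removal of exact duplicates and exact substrings, (2) selection
of the best-covered reference sequence (plus its same-species paralogs) as
the accession-specific reference, and (3) phylogenetic validation: the
candidate set is accepted as true paralogs only if, for each assigned
reference lineage, the candidates assigned to it form a monophyletic group
with that lineage's reference sequences on a tree rooted on its longest
branch.  Otherwise only the longest assembly is retained.

A guide tree can be supplied; when it is absent, one is built by neighbour
joining on uncorrected p-distances (sequences must be pre-aligned to equal
length).  An external maximum-likelihood tree, when available, always takes
precedence over this fallback.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from .treecore import PhyloTree, TreeError, is_monophyletic, parse_newick, \
    root_on_longest_branch


@dataclass
class RefSeq:
    id: str
    species: str
    lineage: str
    seq: str | None = None


@dataclass
class OrthogroupReference:
    orthogroup: str
    sequences: list[RefSeq]

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("orthogroup reference needs at least one sequence")
        ids = [s.id for s in self.sequences]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate reference sequence ids")

    def by_lineage(self, lineage: str) -> list[RefSeq]:
        return [s for s in self.sequences if s.lineage == lineage]

    def by_species(self, species: str) -> list[RefSeq]:
        return [s for s in self.sequences if s.species == species]

    def get(self, seq_id: str) -> RefSeq:
        for s in self.sequences:
            if s.id == seq_id:
                return s
        raise KeyError(seq_id)


@dataclass
class Candidate:
    label: str
    seq: str
    lineage: str

    @property
    def ungapped_length(self) -> int:
        return sum(1 for c in self.seq if c not in "-Nn?")


@dataclass
class AssemblySet:
    accession: str
    orthogroup: str
    candidates: list[Candidate]

    def __post_init__(self):
        labels = [c.label for c in self.candidates]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate candidate labels")
        for c in self.candidates:
            if c.ungapped_length == 0:
                raise ValueError(f"candidate {c.label} has no sequence data")


# ---------------------------------------------------------------------------
# dedupe
# ---------------------------------------------------------------------------

def _core(seq: str) -> str:
    return seq.upper().replace("-", "")


def dedupe_assemblies(candidates: AssemblySet) -> AssemblySet:
    """Drop exact duplicates and exact substrings of longer candidates.

    Comparison is case-insensitive and ungapped.  Retention is deterministic:
    candidates are considered longest-first (label order on ties) and a
    candidate is kept unless its sequence is contained in one already kept.
    """
    if not candidates.candidates:
        raise ValueError("empty candidate set")
    ordered = sorted(candidates.candidates,
                     key=lambda c: (-len(_core(c.seq)), c.label))
    kept: list[Candidate] = []
    for cand in ordered:
        core = _core(cand.seq)
        if any(core in _core(k.seq) for k in kept):
            continue
        kept.append(cand)
    keep_labels = {c.label for c in kept}
    return AssemblySet(candidates.accession, candidates.orthogroup,
                       [c for c in candidates.candidates if c.label in keep_labels])


# ---------------------------------------------------------------------------
# reference selection
# ---------------------------------------------------------------------------

@dataclass
class SelectedReference:
    primary: RefSeq
    paralogs: list[RefSeq]    # same-species reference paralogs / homeologs

    @property
    def all_sequences(self) -> list[RefSeq]:
        return [self.primary] + self.paralogs


def select_accession_reference(coverage: dict[str, int],
                               refs: OrthogroupReference) -> SelectedReference | None:
    """Best-covered reference plus its same-species paralogs; None if no signal."""
    if not coverage:
        raise ValueError("empty coverage table")
    unknown = sorted(set(coverage) - {s.id for s in refs.sequences})
    if unknown:
        raise ValueError(f"coverage ids not in orthogroup reference: {unknown[:5]}")
    if all(v == 0 for v in coverage.values()):
        return None
    best_id = min(coverage, key=lambda k: (-coverage[k], k))
    primary = refs.get(best_id)
    paralogs = [s for s in refs.by_species(primary.species) if s.id != best_id]
    return SelectedReference(primary, paralogs)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _p_distance(a: str, b: str) -> float:
    """Uncorrected p-distance over jointly non-missing positions."""
    if len(a) != len(b):
        raise ValueError("p-distance needs equal-length (aligned) sequences")
    shared = diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-N?" or y in "-N?":
            continue
        shared += 1
        if x != y:
            diff += 1
    if shared == 0:
        return 1.0
    return diff / shared


def nj_guide_tree(labels: list[str], seqs: list[str]) -> PhyloTree:
    """Neighbour-joining tree on p-distances (desk-scale internal fallback)."""
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 sequences for a guide tree")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _p_distance(seqs[i], seqs[j])
    dm = DistanceMatrix(mat, ids=labels)
    newick = str(nj(dm)).strip()
    tree = parse_newick(newick, rooted=True)[0]
    for nd in tree.preorder():  # NJ can emit tiny negative lengths
        if nd.length is not None and nd.length < 0:
            nd.length = 0.0
    return tree


@dataclass
class ValidationResult:
    retained: list[Candidate]
    validated: bool
    report: pd.DataFrame
    tree: PhyloTree | None = None


def validate_paralogs(candidates: AssemblySet, refs: OrthogroupReference,
                      guide_tree: PhyloTree | None = None,
                      criterion: str = "per_lineage") -> ValidationResult:
    """Monophyly-based paralog validation with longest-assembly fallback.

    criterion="per_lineage" (default) requires, for every assigned lineage L,
    that the candidates assigned to L together with L's reference sequences
    are monophyletic on the guide tree rooted on its longest branch.
    criterion="joint" instead requires all candidates plus all their assigned
    references to be jointly monophyletic.
    """
    if criterion not in ("per_lineage", "joint"):
        raise ValueError(f"unknown criterion {criterion!r}")
    cands = candidates.candidates
    rows = []
    if len(cands) == 1:
        rows.append({"candidate": cands[0].label, "lineage": cands[0].lineage,
                     "decision": "retained", "reason": "single candidate"})
        return ValidationResult(list(cands), True, pd.DataFrame(rows))

    if guide_tree is None:
        labels = [c.label for c in cands] + [r.id for r in refs.sequences]
        seqs = [c.seq for c in cands] + [r.seq for r in refs.sequences]
        if any(s is None for s in seqs):
            raise ValueError("sequences required to build the internal guide tree")
        guide_tree = nj_guide_tree(labels, seqs)
    missing = [c.label for c in cands if c.label not in guide_tree.tip_labels]
    if missing:
        raise TreeError(f"candidates missing from guide tree: {missing}")

    rooted = root_on_longest_branch(guide_tree)

    if criterion == "per_lineage":
        checks = {}
        for lineage in sorted({c.lineage for c in cands}):
            tipset = {c.label for c in cands if c.lineage == lineage}
            tipset |= {r.id for r in refs.by_lineage(lineage)
                       if r.id in rooted.tip_labels}
            checks[lineage] = is_monophyletic(rooted, tipset)
        ok = all(checks.values())
    else:
        tipset = {c.label for c in cands}
        for c in cands:
            tipset |= {r.id for r in refs.by_lineage(c.lineage)
                       if r.id in rooted.tip_labels}
        ok = is_monophyletic(rooted, tipset)
        checks = {"joint": ok}

    if ok:
        for c in cands:
            rows.append({"candidate": c.label, "lineage": c.lineage,
                         "decision": "retained",
                         "reason": "monophyletic with references"})
        return ValidationResult(list(cands), True, pd.DataFrame(rows), rooted)

    longest = min(cands, key=lambda c: (-c.ungapped_length, c.label))
    for c in cands:
        if c is longest:
            reason = "longest assembly retained after failed validation"
            decision = "retained"
        else:
            failed = ",".join(k for k, v in checks.items() if not v)
            reason = f"monophyly failed for lineage(s): {failed}"
            decision = "rejected"
        rows.append({"candidate": c.label, "lineage": c.lineage,
                     "decision": decision, "reason": reason})
    return ValidationResult([longest], False, pd.DataFrame(rows), rooted)
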