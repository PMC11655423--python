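"""Data-filter cascade: homology hits, alignment trimming, occupancy,
plastome sample selection, and majority-consensus calling from pileups.

Threshold semantics follow the source pipeline exactly: hit filters are
strict inequalities; the column-trimming rule removes columns with >= 90%
missing data; the occupancy and "at least five genes" rules are inclusive.
A character is missing when it is a gap (``-``), ``N`` or ``?``.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

MISSING_CHARS = b"-Nn?"

HIT_PRESETS = {
    # preset -> (min query-coverage fraction, min percent identity), strict >
    "reference": (0.65, 60.0),
    "transcriptome": (0.50, 70.0),
}

BLAST6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                  "gapopen", "qstart", "qend", "sstart", "send",
                  "evalue", "bitscore"]


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

class MSA:
    """Rectangular nucleotide alignment held as a byte matrix."""

    def __init__(self, ids: list[str], seqs: list[str]):
        if not ids:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"alignment is not rectangular: lengths {sorted(lengths)}")
        self.ids = list(ids)
        self.matrix = np.frombuffer(
            "".join(s.upper() for s in seqs).encode(), dtype="S1"
        ).reshape(len(seqs), -1).copy()
        allowed = set(b"ACGTURYSWKMBDHVN-?")
        bad = set(self.matrix.tobytes()) - {c for c in allowed}
        if bad:
            raise ValueError(f"unexpected characters in alignment: "
                             f"{sorted(chr(c) for c in bad)}")

    @classmethod
    def from_fasta(cls, path) -> "MSA":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, sid in enumerate(self.ids):
                fh.write(f">{sid}\n{self.matrix[i].tobytes().decode()}\n")

    @property
    def n_seqs(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def missing_mask(self) -> np.ndarray:
        m = np.zeros(self.matrix.shape, dtype=bool)
        for ch in (b"-", b"N", b"?"):
            m |= self.matrix == ch
        return m

    def subset(self, rows=None, cols=None) -> "MSA":
        mat = self.matrix
        ids = self.ids
        if cols is not None:
            mat = mat[:, cols]
        if rows is not None:
            mat = mat[rows, :]
            ids = [ids[i] for i in np.flatnonzero(rows)] if np.asarray(rows).dtype == bool \
                else [ids[i] for i in rows]
        out = object.__new__(MSA)
        out.ids = ids
        out.matrix = mat.copy()
        return out


@dataclass
class TrimReport:
    columns_in: int = 0
    columns_kept: int = 0
    seqs_in: int = 0
    seqs_kept: int = 0
    rejected: bool = False
    reason: str = ""


def trim_and_filter_alignment(msa: MSA, max_col_missing: float = 0.9,
                              min_seq_len: int = 200,
                              min_aln_len: int = 500):
    """Column trim -> short-sequence removal -> whole-gene length gate.

    Returns ``(trimmed_msa | None, TrimReport)``; None means the gene is
    rejected (trimmed length below *min_aln_len* or nothing survives).
    """
    report = TrimReport(columns_in=msa.length, seqs_in=msa.n_seqs)
    miss = msa.missing_mask()
    col_missing = miss.mean(axis=0)
    keep_cols = col_missing < max_col_missing  # drop when >= threshold
    report.columns_kept = int(keep_cols.sum())
    if report.columns_kept < min_aln_len:
        report.rejected = True
        report.reason = (f"trimmed length {report.columns_kept} < {min_aln_len}")
        return None, report
    trimmed = msa.subset(cols=keep_cols)
    present = ~trimmed.missing_mask()
    keep_rows = present.sum(axis=1) >= min_seq_len
    report.seqs_kept = int(keep_rows.sum())
    if report.seqs_kept == 0:
        report.rejected = True
        report.reason = "no sequences with enough data after trimming"
        return None, report
    return trimmed.subset(rows=keep_rows), report


# ---------------------------------------------------------------------------
# homology hit tables
# ---------------------------------------------------------------------------

def read_blast6(path, query_lengths: dict[str, int]) -> pd.DataFrame:
    """Read a 12-column tabular homology-search file.

    Query coverage fraction is computed as alignment length over query
    length, which must be supplied per query id.
    """
    df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")
    missing = sorted(set(df["qseqid"]) - set(query_lengths))
    if missing:
        raise ValueError(f"query lengths missing for: {missing[:5]}")
    qlen = df["qseqid"].map(query_lengths)
    out = pd.DataFrame({
        "qseqid": df["qseqid"], "sseqid": df["sseqid"],
        "pident": df["pident"].astype(float),
        "coverage": df["length"].astype(float) / qlen,
        "evalue": df["evalue"].astype(float),
    })
    return out


def filter_hit_table(hits: pd.DataFrame, preset: str) -> pd.DataFrame:
    """Strict-inequality coverage/identity filter; row order preserved."""
    if preset not in HIT_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; options: {sorted(HIT_PRESETS)}")
    min_cov, min_ident = HIT_PRESETS[preset]
    if len(hits) == 0:
        return hits.copy()
    bad_id = ~hits["pident"].between(0, 100)
    bad_cov = (hits["coverage"] < 0) | (hits["coverage"] > 1)
    if bad_id.any() or bad_cov.any():
        raise ValueError("identity must be in [0,100] and coverage in [0,1]")
    mask = (hits["coverage"] > min_cov) & (hits["pident"] > min_ident)
    return hits[mask].copy()


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

def filter_occupancy(matrix: pd.DataFrame, min_fraction: float = 0.5,
                     total_genes: int | None = None) -> list[str]:
    """Accessions (rows) with at least *min_fraction* of the gene set.

    The gene total defaults to the number of columns; the threshold is
    inclusive, so at 331 genes an accession with 166 is kept and one with
    165 is dropped.
    """
    G = total_genes if total_genes is not None else matrix.shape[1]
    if G == 0:
        raise ValueError("total gene count is zero")
    vals = matrix.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("occupancy matrix must be binary")
    counts = matrix.sum(axis=1)
    return [acc for acc, c in counts.items() if c / G >= min_fraction]


# ---------------------------------------------------------------------------
# plastome sample selection
# ---------------------------------------------------------------------------

@dataclass
class PlastomeSelection:
    retained: list[str]
    stage1_failed: list[str]
    stage2_failed: list[str]


def select_plastome_samples(per_gene_coverage: pd.DataFrame, concatenated: MSA,
                            min_cov: float = 0.25, min_genes: int = 5,
                            max_missing: float = 0.95) -> PlastomeSelection:
    """Two-stage plastome sample filter.

    Stage 1 keeps samples covering at least *min_cov* of the reference length
    for at least *min_genes* genes; stage 2 drops samples whose supermatrix
    row has *max_missing* or more missing sites.
    """
    ok1 = (per_gene_coverage >= min_cov).sum(axis=1) >= min_genes
    stage1 = [s for s in per_gene_coverage.index if ok1[s]]
    stage1_failed = [s for s in per_gene_coverage.index if not ok1[s]]

    miss = concatenated.missing_mask().mean(axis=1)
    miss_by_id = dict(zip(concatenated.ids, miss))
    retained, stage2_failed = [], []
    for s in stage1:
        frac = miss_by_id.get(s, 1.0)
        (stage2_failed if frac >= max_missing else retained).append(s)
    return PlastomeSelection(retained, stage1_failed, stage2_failed)


# ---------------------------------------------------------------------------
# consensus from pileup
# ---------------------------------------------------------------------------

_IUPAC_BY_BASESET = {frozenset(v.upper()): k.upper()
                     for k, v in ambiguous_dna_values.items()}

PILEUP_COLUMNS = ["pos", "A", "C", "G", "T"]


def read_pileup(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", names=PILEUP_COLUMNS, comment="#")
    if (df[["A", "C", "G", "T"]] < 0).any().any():
        raise ValueError("negative pileup counts")
    return df


def consensus_from_pileup(pileup: pd.DataFrame, min_depth: int = 1,
                          call_fract: float = 0.5, min_len: int = 200):
    """Majority consensus string, or None when too few positions are called.

    Per position: N below *min_depth*; otherwise the unique base reaching
    *call_fract* of the depth; an exact tie among top bases is written as
    the IUPAC ambiguity code of the tied set (differences coded as
    ambiguities).  Sequences with fewer than *min_len* called (non-N)
    positions are rejected.
    """
    counts = pileup[["A", "C", "G", "T"]].to_numpy()
    if (counts < 0).any():
        raise ValueError("negative pileup counts")
    bases = "ACGT"
    out = []
    for row in counts:
        depth = int(row.sum())
        if depth < min_depth or depth == 0:
            out.append("N")
            continue
        top = row.max()
        if top / depth < call_fract:
            out.append("N")
            continue
        winners = frozenset(bases[i] for i in range(4) if row[i] == top)
        if len(winners) == 1:
            out.append(next(iter(winners)))
        else:
            out.append(_IUPAC_BY_BASESET[winners])
    seq = "".join(out)
    called = sum(1 for c in seq if c != "N")
    if called < min_len:
        return None
    return seq
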