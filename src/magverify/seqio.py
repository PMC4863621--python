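"""Scaffold sequence I/O, bin membership, and assembly summary statistics.

Sequences are stored uppercase over the alphabet {A, C, G, T, N}; any other
IUPAC code is mapped to N on read (counted and logged). Bin membership can
come from one-FASTA-per-bin loading or from a two-column TSV
(``scaffold_id<TAB>bin_id``); the TSV wins on conflict.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_ALLOWED = set("ACGTN")
_CLEAN_TABLE = str.maketrans(
    {c: "N" for c in "RYSWKMBDHVU"} | {c: "N" for c in "ryswkmbdhvu"}
)


@dataclass
class ScaffoldRecord:
    """One assembled scaffold, optionally assigned to a bin."""

    scaffold_id: str
    sequence: str
    bin_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"scaffold {self.scaffold_id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AssemblyStats:
    """Per-bin assembly summary (lengths in bp; GC over an N-free denominator)."""

    n_scaffolds: int
    total_bp: int
    n50_bp: int
    gc_fraction: float
    min_bp: int
    median_bp: float
    max_bp: int


def _clean_sequence(raw: str, scaffold_id: str) -> str:
    seq = raw.upper().translate(_CLEAN_TABLE)
    bad = set(seq) - _ALLOWED
    if bad:
        # Unknown non-IUPAC characters also fold to N.
        seq = "".join(c if c in _ALLOWED else "N" for c in seq)
    n_subst = sum(1 for a, b in zip(raw.upper(), seq) if a != b)
    if n_subst:
        logger.warning(
            "scaffold %s: %d non-ACGTN characters replaced by N", scaffold_id, n_subst
        )
    return seq


def read_fasta(path: str | Path, bin_id: str | None = None) -> list[ScaffoldRecord]:
    """Read scaffolds from a FASTA file.

    The header token before the first whitespace becomes the scaffold id.
    Raises ``ValueError`` on an empty file or a duplicated scaffold id.
    """
    records: list[ScaffoldRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        if sid in seen:
            raise ValueError(f"duplicate scaffold_id {sid!r} in {path}")
        seen.add(sid)
        records.append(ScaffoldRecord(sid, _clean_sequence(str(rec.seq), sid), bin_id))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[ScaffoldRecord], path: str | Path, width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.scaffold_id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_bin_table(path: str | Path) -> dict[str, str]:
    """Read a scaffold_id -> bin_id membership TSV (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["scaffold_id", "bin_id"]:
        raise ValueError(
            f"{path}: expected header 'scaffold_id<TAB>bin_id', got {list(df.columns)}"
        )
    return dict(zip(df["scaffold_id"], df["bin_id"]))


def write_bin_table(records: Iterable[ScaffoldRecord], path: str | Path) -> None:
    rows = [(r.scaffold_id, r.bin_id if r.bin_id is not None else "") for r in records]
    pd.DataFrame(rows, columns=["scaffold_id", "bin_id"]).to_csv(
        path, sep="\t", index=False
    )


def assign_bins(
    records: Sequence[ScaffoldRecord], membership: dict[str, str]
) -> list[ScaffoldRecord]:
    """Apply a membership table to records; the table wins on conflict."""
    out = []
    for r in records:
        bin_id = membership.get(r.scaffold_id, r.bin_id)
        if (
            r.bin_id is not None
            and r.scaffold_id in membership
            and membership[r.scaffold_id] != r.bin_id
        ):
            logger.warning(
                "scaffold %s: TSV bin %r overrides FASTA bin %r",
                r.scaffold_id,
                membership[r.scaffold_id],
                r.bin_id,
            )
        out.append(ScaffoldRecord(r.scaffold_id, r.sequence, bin_id))
    return out


def compute_n50(lengths: Sequence[int]) -> int:
    """N50: the length at which the cumulative sum of descending-sorted lengths
    first reaches >= half the total."""
    if len(lengths) == 0:
        raise ValueError("compute_n50: empty length list")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if arr[-1] <= 0:
        raise ValueError("compute_n50: lengths must be positive")
    half = arr.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[idx])


def compute_gc(sequence: str) -> float:
    """GC fraction with N excluded from numerator and denominator.

    Returns NaN (with a warning) when the sequence has no unambiguous bases.
    """
    gc = sequence.count("G") + sequence.count("C")
    at = sequence.count("A") + sequence.count("T")
    if gc + at == 0:
        logger.warning("compute_gc: no unambiguous bases; GC undefined")
        return math.nan
    return gc / (gc + at)


def summarize_assembly(records: Sequence[ScaffoldRecord]) -> AssemblyStats:
    """Assembly statistics for a set of scaffolds (typically one bin)."""
    if not records:
        raise ValueError("summarize_assembly: no records")
    lengths = [len(r) for r in records]
    gc = at = 0
    for r in records:
        gc += r.sequence.count("G") + r.sequence.count("C")
        at += r.sequence.count("A") + r.sequence.count("T")
    gc_fraction = math.nan if gc + at == 0 else gc / (gc + at)
    return AssemblyStats(
        n_scaffolds=len(records),
        total_bp=int(sum(lengths)),
        n50_bp=compute_n50(lengths),
        gc_fraction=gc_fraction,
        min_bp=int(min(lengths)),
        median_bp=float(np.median(lengths)),
        max_bp=int(max(lengths)),
    )


def stats_report(bins: dict[str, Sequence[ScaffoldRecord]]) -> pd.DataFrame:
    """One row of assembly statistics per bin."""
    rows = []
    for bin_id, recs in sorted(bins.items()):
        s = summarize_assembly(recs)
        rows.append(
            {
                "bin_id": bin_id,
                "n_scaffolds": s.n_scaffolds,
                "total_bp": s.total_bp,
                "n50_bp": s.n50_bp,
                "gc_fraction": round(s.gc_fraction, 4),
                "min_bp": s.min_bp,
                "median_bp": s.median_bp,
                "max_bp": s.max_bp,
            }
        )
    return pd.DataFrame(rows)
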