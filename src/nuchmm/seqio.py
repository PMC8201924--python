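"""Genome, dyad-map and query-sequence I/O.

Coordinate convention: 1-based, inclusive at both ends, everywhere.  A dyad at
position ``pos`` implies the 147-bp footprint ``[pos-73, pos+73]``; the dyad
is nucleosomal position 74.  BED-style half-open inputs must be shifted with
:func:`bed_start_to_dyad_pos` before use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import DYAD_OFFSET, encode_sequence

Category = Literal["unique", "redundant"]


@dataclass
class GenomeSequence:
    """Named chromosomes over {A,C,G,T,N}, uppercased at load."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        self._codes: dict[str, np.ndarray] = {}

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    def codes(self, chrom: str) -> np.ndarray:
        """Integer-encoded chromosome (cached)."""
        if chrom not in self._codes:
            self._codes[chrom] = encode_sequence(self.records[chrom])
        return self._codes[chrom]


@dataclass(frozen=True, order=True)
class DyadRecord:
    chrom: str
    pos: int        # 1-based dyad coordinate
    score: float = 1.0

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.pos - DYAD_OFFSET, self.pos + DYAD_OFFSET)


@dataclass
class DyadMap:
    records: list[DyadRecord]
    category: Category = "unique"

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.chrom, r.pos))
        if self.category == "unique":
            seen = set()
            for r in self.records:
                key = (r.chrom, r.pos)
                if key in seen:
                    raise ValueError(
                        f"duplicate dyad {r.chrom}:{r.pos} in unique map")
                seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def by_chrom(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for r in self.records:
            out.setdefault(r.chrom, []).append(r.pos)
        return {c: np.asarray(p, dtype=np.int64) for c, p in out.items()}


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a multi-record FASTA; bases uppercased, alphabet {A,C,G,T,N}."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            encode_sequence(seq)
        except ValueError as e:
            raise ValueError(f"record {rec.id!r}: {e}") from None
        if rec.id in records:
            raise ValueError(f"duplicate record name {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return GenomeSequence(records)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, seq in genome.records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_dyad_map(path: str | Path, category: Category = "unique") -> DyadMap:
    """Read a dyad-map TSV: columns chrom, pos[, score]; '#' lines ignored.

    A missing score column means every record scores 1.0.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("dyad map needs at least 2 columns (chrom, pos)")
    pos = df.iloc[:, 1]
    as_num = pd.to_numeric(pos, errors="coerce")
    bad = as_num.isna() | (as_num % 1 != 0)
    if bad.any():
        raise ValueError(f"non-integer dyad position {pos[bad].iloc[0]!r}")
    pos = as_num.astype(np.int64)
    if (pos < 1).any():
        raise ValueError("dyad position < 1")
    if df.shape[1] >= 3:
        scores = pd.to_numeric(df.iloc[:, 2]).astype(float)
    else:
        scores = pd.Series(1.0, index=df.index)
    records = [DyadRecord(c, int(p), float(s))
               for c, p, s in zip(df.iloc[:, 0], pos, scores)]
    return DyadMap(records, category=category)


def write_dyad_map(dyads: DyadMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#chrom\tpos\tscore\n")
        for r in dyads.records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.score!r}\n")


def fetch_window(genome: GenomeSequence, chrom: str, center: int,
                 flank: int) -> str:
    """Return the ``2*flank + 1`` bases of ``[center-flank, center+flank]``."""
    if chrom not in genome.records:
        raise KeyError(f"unknown chromosome {chrom!r}")
    n = len(genome.records[chrom])
    lo, hi = center - flank, center + flank
    if lo < 1 or hi > n:
        raise IndexError(
            f"window [{lo},{hi}] out of range for {chrom} (length {n})")
    return genome.records[chrom][lo - 1 : hi]


def read_query(source: str | Path) -> str:
    """Load a query sequence: a FASTA path (first record) or a literal string."""
    return read_named_query(source)[1]


def read_named_query(source: str | Path) -> tuple[str, str]:
    """Like :func:`read_query` but also returns the query name (the FASTA
    record id, or "query" for a literal string)."""
    p = Path(str(source))
    try:
        is_file = p.exists()
    except OSError:                      # e.g. literal longer than NAME_MAX
        is_file = False
    if is_file:
        genome = read_fasta(p)
        name = next(iter(genome.records))
        return name, genome.records[name]
    seq = str(source).upper()
    encode_sequence(seq)
    return "query", seq


def bed_start_to_dyad_pos(bed_start: int) -> int:
    """Convert a 0-based BED start to this package's 1-based coordinate."""
    return bed_start + 1
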