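"""Readers and writers for the external formats the curation pipeline touches.

Every function in this module converts to/from a single internal coordinate
convention: **1-based, fully inclusive** intervals, matching the way assembly
papers print coordinates (e.g. a satellite array at 281,785-473,916 has length
``end - start + 1``).  Formats that are natively 0-based half-open (BED, PAF)
are converted here, at the I/O boundary, and nowhere else.

Supported formats
-----------------
- FASTA (via Biopython; 60-column wrapping on write)
- Tandem Repeats Finder ``.dat`` output
- PAF alignments (minimap2 dialect, 12 mandatory columns)
- 4-column TSV window tracks (scaffold, start, end, value)
- BED (export only)
- COO TSV contact matrices with a companion bin-map TSV
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ParseError, ValidationError

_VALID_SEQ = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive interval on a named scaffold."""

    scaffold: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"invalid region {self.scaffold}:{self.start}-{self.end}: "
                "require 1 <= start <= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Region") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class ScaffoldRecord:
    """One assembly sequence, uppercased, over the alphabet {A,C,G,T,N}."""

    name: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TrfRecord:
    """One data line of Tandem Repeats Finder ``.dat`` output."""

    scaffold: str
    start: int
    end: int
    period: int
    copy_number: float
    consensus: str
    score: int

    def __post_init__(self) -> None:
        if self.period < 1:
            raise ParseError(f"TRF record with period {self.period} < 1")
        if self.start > self.end:
            raise ParseError(
                f"TRF record with start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class PafAlignment:
    """A PAF alignment with target coordinates converted to 1-based inclusive."""

    query: str
    query_len: int
    target: str
    target_start: int
    target_end: int
    strand: str
    matches: int
    block_len: int

    @property
    def length(self) -> int:
        return self.target_end - self.target_start + 1


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, allow_ambiguous: bool = False) -> dict[str, ScaffoldRecord]:
    """Read a FASTA file into an ordered mapping of ScaffoldRecord.

    Sequences are uppercased.  Duplicate headers are rejected.  Characters
    outside {A,C,G,T,N} are rejected unless ``allow_ambiguous`` is set, in
    which case they are preserved verbatim.
    """
    path = Path(path)
    records: dict[str, ScaffoldRecord] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        seq = str(rec.seq).upper()
        if rec.id in records:
            raise ParseError(f"{path}: duplicate FASTA header '{rec.id}'")
        if not allow_ambiguous and not _VALID_SEQ.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ParseError(
                f"{path}: record '{rec.id}' contains non-ACGTN characters {bad}; "
                "pass allow_ambiguous=True to keep them"
            )
        records[rec.id] = ScaffoldRecord(rec.id, seq)
    if n == 0:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ScaffoldRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with fixed-width line wrapping."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Tandem Repeats Finder .dat

#: field count of a TRF data line:
#: start end period copies consensus_size pct_match pct_indel score A C G T entropy consensus repeat
_TRF_NFIELDS = 15


def read_trf_dat(path: str | Path) -> list[TrfRecord]:
    """Parse the Tandem Repeats Finder ``.dat`` dialect.

    ``Sequence:`` header lines set the scaffold for the data lines that
    follow.  Everything else that does not look like a data line (parameter
    echo, blank lines, banner text) is skipped.
    """
    path = Path(path)
    out: list[TrfRecord] = []
    scaffold: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                scaffold = line.split(None, 1)[1].split()[0]
                continue
            fields = line.split()
            # data lines start with the integer start coordinate
            if not fields[0].isdigit():
                continue
            if len(fields) != _TRF_NFIELDS:
                raise ParseError(
                    f"{path}:{lineno}: expected {_TRF_NFIELDS} fields in TRF "
                    f"data line, got {len(fields)}"
                )
            if scaffold is None:
                raise ParseError(f"{path}:{lineno}: data line before any 'Sequence:' header")
            out.append(
                TrfRecord(
                    scaffold=scaffold,
                    start=int(fields[0]),
                    end=int(fields[1]),
                    period=int(fields[2]),
                    copy_number=float(fields[3]),
                    consensus=fields[13].upper(),
                    score=int(fields[7]),
                )
            )
    return out


def write_trf_dat(records: Iterable[TrfRecord], path: str | Path) -> None:
    """Write TrfRecords in the ``.dat`` dialect accepted by :func:`read_trf_dat`.

    Composition fields not carried by TrfRecord (percent match/indel, base
    percentages, entropy) are emitted as nominal placeholders; the repeat
    sequence column repeats the consensus.
    """
    path = Path(path)
    by_scaffold: dict[str, list[TrfRecord]] = {}
    for rec in records:
        by_scaffold.setdefault(rec.scaffold, []).append(rec)
    with open(path, "w") as fh:
        for scaffold, recs in by_scaffold.items():
            fh.write(f"Sequence: {scaffold}\n\n")
            fh.write("Parameters: 2 7 7 80 10 500 6\n\n")
            for r in sorted(recs, key=lambda x: x.start):
                fh.write(
                    f"{r.start} {r.end} {r.period} {r.copy_number:.1f} "
                    f"{len(r.consensus)} 100 0 {r.score} 25 25 25 25 2.00 "
                    f"{r.consensus} {r.consensus}\n"
                )


# ---------------------------------------------------------------------------
# PAF


def read_paf(path: str | Path) -> list[PafAlignment]:
    """Read minimap2-style PAF; target coordinates become 1-based inclusive."""
    path = Path(path)
    out: list[PafAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(
                    f"{path}:{lineno}: PAF line has {len(f)} fields, expected >= 12"
                )
            tstart, tend = int(f[7]), int(f[8])
            if tstart >= tend:
                raise ParseError(
                    f"{path}:{lineno}: target_start {tstart} >= target_end {tend} "
                    "in half-open PAF coordinates"
                )
            out.append(
                PafAlignment(
                    query=f[0],
                    query_len=int(f[1]),
                    target=f[5],
                    target_start=tstart + 1,
                    target_end=tend,
                    strand=f[4],
                    matches=int(f[9]),
                    block_len=int(f[10]),
                )
            )
    return out


def write_paf(alignments: Iterable[PafAlignment], path: str | Path, target_lens: dict[str, int]) -> None:
    """Write PAF (converting internal 1-based inclusive back to half-open)."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a.query,
                        a.query_len,
                        0,
                        a.query_len,
                        a.strand,
                        a.target,
                        target_lens[a.target],
                        a.target_start - 1,
                        a.target_end,
                        a.matches,
                        a.block_len,
                        60,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# window tracks (TSV) and BED export

TRACK_COLUMNS = ["scaffold", "start", "end", "value"]


def read_track(path: str | Path) -> pd.DataFrame:
    """Read a 4-column TSV window track (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: track is missing columns {missing}")
    return df[TRACK_COLUMNS + [c for c in df.columns if c not in TRACK_COLUMNS]]


def write_track(track: pd.DataFrame, path: str | Path) -> None:
    """Write a window track as TSV with a header line."""
    track.to_csv(path, sep="\t", index=False)


def write_bed(regions: Iterable[Region], path: str | Path) -> None:
    """Export regions as BED (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for r in regions:
            name = r.label or "."
            fh.write(f"{r.scaffold}\t{r.start - 1}\t{r.end}\t{name}\n")


# ---------------------------------------------------------------------------
# COO contact matrices

BINMAP_COLUMNS = ["bin", "scaffold", "start", "end"]


def read_binmap(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BINMAP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: bin map is missing columns {missing}")
    if sorted(df["bin"]) != list(range(len(df))):
        raise ParseError(f"{path}: bin ids must be exactly 0..n-1")
    return df.sort_values("bin").reset_index(drop=True)


def read_coo_matrix(path: str | Path, binmap: pd.DataFrame) -> np.ndarray:
    """Read a COO TSV (bin_i, bin_j, count) into a dense symmetric matrix.

    Entries may be given in either or both triangles; conflicting duplicate
    values for a mirrored pair raise :class:`ParseError`.
    """
    n = len(binmap)
    mat = np.zeros((n, n))
    seen = np.zeros((n, n), dtype=bool)
    df = pd.read_csv(path, sep="\t")
    for col in ("bin_i", "bin_j", "count"):
        if col not in df.columns:
            raise ParseError(f"{path}: COO matrix is missing column '{col}'")
    for i, j, c in df[["bin_i", "bin_j", "count"]].itertuples(index=False):
        i, j = int(i), int(j)
        if not (0 <= i < n and 0 <= j < n):
            raise ParseError(f"{path}: bin index ({i},{j}) outside bin map of size {n}")
        if seen[i, j] and mat[i, j] != c:
            raise ParseError(f"{path}: conflicting duplicate entry for bins ({i},{j})")
        mat[i, j] = c
        mat[j, i] = c
        seen[i, j] = seen[j, i] = True
    return mat


def write_coo_matrix(mat: np.ndarray, path: str | Path) -> None:
    """Write the upper triangle (incl. diagonal) of a symmetric matrix as COO TSV."""
    if mat.shape[0] != mat.shape[1]:
        raise ValidationError("contact matrix must be square")
    iu, ju = np.triu_indices(mat.shape[0])
    vals = mat[iu, ju]
    keep = vals != 0
    pd.DataFrame({"bin_i": iu[keep], "bin_j": ju[keep], "count": vals[keep]}).to_csv(
        path, sep="\t", index=False
    )


def write_binmap(binmap: pd.DataFrame, path: str | Path) -> None:
    binmap[BINMAP_COLUMNS].to_csv(path, sep="\t", index=False)
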