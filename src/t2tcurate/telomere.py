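"""Telomere calling from Tandem Repeats Finder records.

Vertebrate telomeres are tandem arrays of the hexamer TTAGGG (CCCTAA on the
reverse strand).  TRF reports such arrays with an arbitrary phase, so a
record qualifies as telomeric when its period-6 consensus is any circular
rotation of TTAGGG or CCCTAA.  Qualifying records that overlap or sit
within a small slack of each other are merged (TRF fragments long arrays),
and merged regions longer than a minimum (600 bp by default) are called.

Short terminal arrays are genuinely telomeric even below the length cutoff
when they sit at a scaffold end — e.g. a 214-bp array of 32 exact hexamers
at position 1 of a scaffold — so sub-threshold regions near an end can be
"rescued" down to a smaller terminal minimum.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from .errors import ValidationError
from .seqio import Region, TrfRecord

MOTIF = "TTAGGG"
MOTIF_RC = "CCCTAA"


def _rotations(s: str) -> set[str]:
    return {s[i:] + s[:i] for i in range(len(s))}


TELOMERIC_CONSENSI = _rotations(MOTIF) | _rotations(MOTIF_RC)

_round_half_up = lambda x: math.floor(x + 0.5)  # noqa: E731


@dataclass(frozen=True)
class TelomereCall:
    region: Region
    est_copies: int
    terminal: str  # {"5prime", "3prime", "internal"}
    rescued: bool = False
    exact_copies: int | None = None

    @property
    def length(self) -> int:
        return self.region.length


def is_telomeric_consensus(consensus: str) -> bool:
    """True iff the TRF consensus is a rotation of TTAGGG or CCCTAA."""
    return consensus.upper() in TELOMERIC_CONSENSI


def count_exact_motifs(seq: str) -> int:
    """Non-overlapping exact occurrences of TTAGGG plus CCCTAA in ``seq``."""
    seq = seq.upper()
    return len(re.findall(MOTIF, seq)) + len(re.findall(MOTIF_RC, seq))


def _classify_terminal(start: int, end: int, scaffold_len: int, end_window: int) -> str:
    if start <= end_window:
        return "5prime"
    if end >= scaffold_len - end_window + 1:
        return "3prime"
    return "internal"


def call_telomeres(
    records: list[TrfRecord],
    scaffold_lengths: dict[str, int],
    min_len: int = 600,
    end_window: int = 10_000,
    terminal_rescue_min: int = 150,
    merge_slack: int = 100,
    sequences: dict[str, str] | None = None,
) -> list[TelomereCall]:
    """Call telomeric regions from TRF records.

    Records whose consensus is a telomeric hexamer rotation are merged per
    scaffold when overlapping or separated by at most ``merge_slack`` bp.
    Merged regions longer than ``min_len`` are called; shorter regions are
    rescued if they are at least ``terminal_rescue_min`` bp and terminal
    (within ``end_window`` of a scaffold end).  ``est_copies`` is the region
    length divided by 6, rounded half up; when ``sequences`` are supplied,
    ``exact_copies`` additionally counts exact non-overlapping motifs.
    """
    by_scaffold: dict[str, list[TrfRecord]] = {}
    for rec in records:
        if rec.scaffold not in scaffold_lengths:
            raise ValidationError(f"TRF record on unknown scaffold '{rec.scaffold}'")
        if is_telomeric_consensus(rec.consensus):
            by_scaffold.setdefault(rec.scaffold, []).append(rec)

    calls: list[TelomereCall] = []
    for scaffold, recs in by_scaffold.items():
        recs.sort(key=lambda r: (r.start, r.end))
        merged: list[list[int]] = []
        for r in recs:
            if merged and r.start - merged[-1][1] - 1 <= merge_slack:
                merged[-1][1] = max(merged[-1][1], r.end)
            else:
                merged.append([r.start, r.end])
        slen = scaffold_lengths[scaffold]
        for start, end in merged:
            length = end - start + 1
            terminal = _classify_terminal(start, end, slen, end_window)
            rescued = False
            if length > min_len:
                pass
            elif length >= terminal_rescue_min and terminal != "internal":
                rescued = True
            else:
                continue
            exact = None
            if sequences is not None and scaffold in sequences:
                exact = count_exact_motifs(sequences[scaffold][start - 1 : end])
            calls.append(
                TelomereCall(
                    region=Region(scaffold, start, end, label="telomere"),
                    est_copies=_round_half_up(length / len(MOTIF)),
                    terminal=terminal,
                    rescued=rescued,
                    exact_copies=exact,
                )
            )
    calls.sort(key=lambda c: (c.region.scaffold, c.region.start))
    return calls


def end_status(calls: list[TelomereCall], scaffold_lengths: dict[str, int],
               end_window: int = 10_000) -> dict[str, int]:
    """Per-scaffold count of distinct ends (5' and 3') covered by terminal calls.

    Both conditions are checked from coordinates, so a single call spanning
    an entire short scaffold counts both ends.  Scaffolds without calls
    score 0.
    """
    status = {name: set() for name in scaffold_lengths}
    for c in calls:
        slen = scaffold_lengths[c.region.scaffold]
        if c.region.start <= end_window:
            status[c.region.scaffold].add("5prime")
        if c.region.end >= slen - end_window + 1:
            status[c.region.scaffold].add("3prime")
    return {name: len(ends) for name, ends in status.items()}
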