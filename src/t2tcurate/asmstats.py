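"""Assembly summary statistics: contiguity, N-gaps, windowed GC, macro/micro split.

N50 is the length of the sequence at which the cumulative sum of
descending-sorted lengths first reaches >= 50% of the total; L50 is the
number of sequences up to and including that point (N90/L90 analogous at
90%).  Gaps are maximal runs of N.  GC is computed in non-overlapping
fixed-width windows with N excluded from the denominator by default.

Reptile and bird karyotypes are bimodal: a few long, GC-poorer
macrochromosomes and many short, GC-richer microchromosomes.
:func:`classify_macro_micro` recovers that split from scaffold length and
median window GC by cutting at the largest gap in the sorted GC values.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .seqio import Region, ScaffoldRecord

_GAP_RE_CACHE: dict[int, re.Pattern] = {}


@dataclass(frozen=True)
class AssemblyMetrics:
    total_len: int
    n_seqs: int
    n50: int
    n90: int
    l50: int
    l90: int
    mean_len: int
    median_len: float
    longest: int
    shortest: int
    gc_pct: float | None = None
    n_gaps: int | None = None


@dataclass(frozen=True)
class GapRun:
    region: Region

    @property
    def length(self) -> int:
        return self.region.length


def _nl_at(sorted_desc: np.ndarray, total: int, frac: float) -> tuple[int, int]:
    cum = np.cumsum(sorted_desc)
    idx = int(np.searchsorted(cum, frac * total))
    return int(sorted_desc[idx]), idx + 1


def contiguity_metrics(lengths: list[int] | np.ndarray) -> AssemblyMetrics:
    """Compute N50/N90/L50/L90 and summary lengths from sequence lengths."""
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.size == 0:
        raise ValidationError("no sequence lengths given")
    if np.any(arr <= 0):
        raise ValidationError("sequence lengths must be positive")
    desc = np.sort(arr)[::-1]
    total = int(desc.sum())
    n50, l50 = _nl_at(desc, total, 0.5)
    n90, l90 = _nl_at(desc, total, 0.9)
    return AssemblyMetrics(
        total_len=total,
        n_seqs=int(arr.size),
        n50=n50,
        n90=n90,
        l50=l50,
        l90=l90,
        mean_len=int(round(total / arr.size)),
        median_len=float(np.median(arr)),
        longest=int(desc[0]),
        shortest=int(desc[-1]),
    )


def find_gaps(scaffold: ScaffoldRecord | str, min_run: int = 10, name: str = "seq") -> list[GapRun]:
    """Maximal N-runs of length >= ``min_run``, as 1-based inclusive regions."""
    if isinstance(scaffold, ScaffoldRecord):
        seq, name = scaffold.seq, scaffold.name
    else:
        seq = scaffold
    if min_run not in _GAP_RE_CACHE:
        _GAP_RE_CACHE[min_run] = re.compile("N{%d,}" % min_run)
    return [
        GapRun(Region(name, m.start() + 1, m.end(), label="gap"))
        for m in _GAP_RE_CACHE[min_run].finditer(seq)
    ]


def gc_windows(scaffold: ScaffoldRecord | str, window: int = 10_000, name: str = "seq") -> pd.DataFrame:
    """Per-window GC%% track: (G+C)/(A+C+G+T) * 100, N excluded.

    The trailing partial window is included and flagged in the ``partial``
    column.  An all-N window has no defined GC and is emitted as NaN.
    """
    if isinstance(scaffold, ScaffoldRecord):
        seq, name = scaffold.seq, scaffold.name
    else:
        seq = scaffold
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = (codes == ord("G")) | (codes == ord("C"))
    is_acgt = is_gc | (codes == ord("A")) | (codes == ord("T"))
    rows = []
    for start0 in range(0, len(seq), window):
        end0 = min(start0 + window, len(seq))
        denom = int(is_acgt[start0:end0].sum())
        gc = 100.0 * is_gc[start0:end0].sum() / denom if denom else np.nan
        rows.append((name, start0 + 1, end0, gc, end0 - start0 < window))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "value", "partial"])


def median_gc(track: pd.DataFrame) -> float:
    """Median of the per-window GC values, ignoring undefined (all-N) windows."""
    vals = track["value"].dropna()
    if vals.empty:
        raise ValidationError("GC track has no defined windows")
    return float(vals.median())


def classify_macro_micro(
    scaffolds: list[tuple[str, int, float]], min_scaffold: int = 1_000_000
) -> pd.DataFrame:
    """Split chromosome-scale scaffolds into macro/micro classes by GC.

    ``scaffolds`` is a list of (name, length, median window GC%%).  Among
    scaffolds >= ``min_scaffold``, the GC threshold is the midpoint of the
    largest gap in sorted GC values; the lower-GC side is labelled ``macro``
    (macrochromosomes are GC-poorer and longer), the upper ``micro``.
    Scaffolds below ``min_scaffold`` are labelled ``small``.  Returns a
    DataFrame with a ``gc_threshold`` attribute in ``.attrs``.
    """
    df = pd.DataFrame(scaffolds, columns=["scaffold", "length", "gc"])
    big = df[df["length"] >= min_scaffold]
    if len(big) < 2:
        raise ValidationError(
            f"need >= 2 scaffolds of at least {min_scaffold} bp to classify, got {len(big)}"
        )
    gc_sorted = np.sort(big["gc"].to_numpy())
    diffs = np.diff(gc_sorted)
    labels = pd.Series("small", index=df.index)
    if np.all(diffs == 0):
        warnings.warn("all chromosome-scale scaffolds have identical GC; single group")
        labels[big.index] = "macro"
        threshold = None
    else:
        i = int(np.argmax(diffs))
        threshold = float((gc_sorted[i] + gc_sorted[i + 1]) / 2)
        labels[big.index] = np.where(big["gc"] < threshold, "macro", "micro")
    out = df.assign(label=labels)
    out.attrs["gc_threshold"] = threshold
    return out


def assembly_metrics(
    records: dict[str, ScaffoldRecord], gap_min_run: int = 10
) -> AssemblyMetrics:
    """Full Table-style assembly metrics from sequences (incl. GC and gap count)."""
    lengths = [r.length for r in records.values()]
    base = contiguity_metrics(lengths)
    gc_num = gc_den = 0
    n_gaps = 0
    for rec in records.values():
        codes = np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8)
        is_gc = (codes == ord("G")) | (codes == ord("C"))
        is_acgt = is_gc | (codes == ord("A")) | (codes == ord("T"))
        gc_num += int(is_gc.sum())
        gc_den += int(is_acgt.sum())
        n_gaps += len(find_gaps(rec, min_run=gap_min_run))
    return AssemblyMetrics(
        **{
            **base.__dict__,
            "gc_pct": round(100.0 * gc_num / gc_den, 1) if gc_den else None,
            "n_gaps": n_gaps,
        }
    )
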