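"""K-mer histogram statistics: peak detection, genome size, QV arithmetic.

A k-mer multiplicity histogram from a diploid individual shows (after the
low-multiplicity sequencing-error mass) two peaks: heterozygous k-mers at
roughly half the homozygous coverage depth c, and homozygous k-mers at c.
Genome size follows from the total read bases T, mean read length L, k-mer
length k and the homozygous peak position c via the k-mer coverage
correction

    G = T * (L - k + 1) / (L * c)

because each read of length L contributes L - k + 1 k-mers, so k-mer depth
underestimates base depth by the factor (L - k + 1)/L.

Consensus quality values (QV) convert between per-base error rate and the
expected spacing between consecutive errors:

    QV = -10 * log10(error_rate),    spacing_bp = 10 ** (QV / 10)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema

from .errors import ValidationError


@dataclass(frozen=True)
class KmerHistogram:
    """Multiplicity -> frequency table for a fixed k."""

    k: int
    counts: dict[int, int]

    def __post_init__(self) -> None:
        if any(m < 1 for m in self.counts):
            raise ValidationError("k-mer multiplicities must be >= 1")
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError("k-mer frequencies must be >= 0")

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense (multiplicity, frequency) arrays covering 1..max multiplicity."""
        mmax = max(self.counts)
        freq = np.zeros(mmax + 1)
        for m, c in self.counts.items():
            freq[m] = c
        return np.arange(1, mmax + 1), freq[1:]


@dataclass(frozen=True)
class PeakCalls:
    """Detected histogram peaks, ordered by increasing multiplicity."""

    peaks: list[tuple[int, float]]
    error_trough: int | None
    het_peak: int | None = None
    hom_peak: int | None = None


def _smooth(y: np.ndarray, width: int = 3) -> np.ndarray:
    """Centered moving average; endpoints use the available window."""
    kernel = np.ones(width)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def detect_peaks(
    hist: KmerHistogram, min_multiplicity: int = 1, min_peak_frac: float = 0.01
) -> PeakCalls:
    """Locate coverage peaks of a k-mer histogram above the error trough.

    The frequency curve is smoothed with a width-3 moving average.  When the
    curve starts on a descending slope (the sequencing-error component), the
    error trough is the first strict local minimum scanning up from the
    smallest multiplicity, and maxima at or below it are attributed to error
    and discarded; a curve that starts rising has no error component and no
    trough.  Peaks shorter than ``min_peak_frac`` of the tallest peak are
    treated as smoothing noise.  With two surviving peaks the lower one is
    classified heterozygous and the higher homozygous; with one, homozygous.
    """
    mult, freq = hist.to_arrays()
    mask = mult >= min_multiplicity
    mult, freq = mult[mask], freq[mask]
    if len(mult) == 0 or not np.any(freq > 0):
        raise ValidationError("histogram is empty or all-zero")
    smooth = _smooth(freq)

    trough_idx: int | None = None
    descending_start = len(smooth) >= 2 and smooth[0] > smooth[1]
    if descending_start:
        for i in range(1, len(smooth) - 1):
            if smooth[i] < smooth[i - 1] and smooth[i] < smooth[i + 1]:
                trough_idx = i
                break

    (max_idx,) = argrelextrema(smooth, np.greater_equal, order=1)
    # deduplicate plateaus and drop flat endpoints
    peaks: list[tuple[int, float]] = []
    for i in max_idx:
        if 0 < i < len(smooth) - 1 and smooth[i] > min(smooth[i - 1], smooth[i + 1]):
            if trough_idx is not None and i <= trough_idx:
                continue
            if peaks and peaks[-1][0] == mult[i] - 1 and peaks[-1][1] == smooth[i]:
                continue
            peaks.append((int(mult[i]), float(smooth[i])))
    if descending_start and trough_idx is None:
        # monotone decreasing: pure error histogram, nothing above a trough
        peaks = []
    if peaks:
        tallest = max(h for _, h in peaks)
        peaks = [p for p in peaks if p[1] >= min_peak_frac * tallest]

    het = hom = None
    if len(peaks) == 1:
        hom = peaks[0][0]
    elif len(peaks) >= 2:
        # homozygous peak = the largest-multiplicity peak among the two
        # tallest; heterozygous = a peak near half its position, if any
        tallest = sorted(peaks, key=lambda p: -p[1])[:2]
        hom = max(p[0] for p in tallest)
        candidates = [p for p in peaks if p[0] < hom and abs(p[0] / hom - 0.5) <= 0.25]
        if candidates:
            het = max(candidates, key=lambda p: p[1])[0]
    trough = int(mult[trough_idx]) if trough_idx is not None else None
    return PeakCalls(peaks=peaks, error_trough=trough, het_peak=het, hom_peak=hom)


@dataclass(frozen=True)
class GenomeSizeEstimate:
    total_bases: float
    mean_read_len: float
    k: int
    hom_peak: float
    size_bp: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "size_bp",
            estimate_genome_size(self.total_bases, self.mean_read_len, self.k, self.hom_peak),
        )

    @property
    def size_gbp(self) -> float:
        """Genome size in Gbp rounded to 2 decimals, as reported in papers."""
        return round(self.size_bp / 1e9, 2)


def estimate_genome_size(total_bases: float, read_len: float, k: int, hom_peak: float) -> float:
    """Genome size in bp: G = T * (L - k + 1) / (L * c).

    ``hom_peak`` is the homozygous-peak k-mer multiplicity c; the factor
    (L - k + 1)/L corrects k-mer depth back to base depth.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if read_len < k:
        raise ValidationError(f"read length {read_len} must be >= k ({k})")
    if hom_peak <= 0:
        raise ValidationError(f"homozygous peak must be > 0, got {hom_peak}")
    if total_bases <= 0:
        raise ValidationError(f"total bases must be > 0, got {total_bases}")
    return total_bases * (read_len - k + 1) / (read_len * hom_peak)


def qv_to_error_spacing(qv: float) -> float:
    """Expected bp between consecutive errors at consensus quality ``qv``."""
    if not math.isfinite(qv):
        raise ValidationError("QV must be finite")
    return 10 ** (qv / 10)


def error_rate_to_qv(rate: float) -> float:
    """Consensus QV from a per-base error rate in (0, 1]."""
    if not 0 < rate <= 1:
        raise ValidationError(f"error rate must be in (0, 1], got {rate}")
    return -10 * math.log10(rate)
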