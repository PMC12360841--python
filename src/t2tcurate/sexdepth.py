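"""Sex-scaffold identification from read depth.

In a sequenced ZW female the Z- and W-specific scaffolds are present in one
copy against two for autosomes, so their read depth sits near half the
autosomal baseline.  Scaffolds above a size threshold are summarized by the
median of their 10-kbp window depths; a scaffold is labelled haploid-depth
when its ratio to the autosomal baseline falls in a configurable band
around 0.5 (default 0.35-0.65).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class DepthClassification:
    scaffold: str
    median_depth: float
    ratio: float
    label: str  # {"diploid-depth", "haploid-depth", "ambiguous"}


def scaffold_median_depth(
    depth_track: pd.DataFrame, min_scaffold: int = 1_000_000
) -> dict[str, float]:
    """Median window depth per scaffold, for scaffolds >= ``min_scaffold`` bp.

    Scaffold extent is taken as the end of its last window.  numpy's median
    averages the two central values for even window counts.
    """
    medians: dict[str, float] = {}
    for scaffold, g in depth_track.groupby("scaffold"):
        if len(g) == 0:
            warnings.warn(f"scaffold '{scaffold}' has no depth windows; excluded")
            continue
        if g["end"].max() < min_scaffold:
            continue
        medians[str(scaffold)] = float(np.median(g["value"]))
    return medians


def classify_sex_scaffolds(
    medians: dict[str, float],
    band: tuple[float, float] = (0.35, 0.65),
    diploid_band: tuple[float, float] = (0.8, 1.2),
) -> list[DepthClassification]:
    """Label scaffolds haploid- or diploid-depth relative to the autosomal baseline.

    The baseline is the median of scaffold medians; after a first pass, the
    baseline is re-estimated excluding scaffolds flagged haploid-depth (so
    that a genome with several sex scaffolds does not drag the baseline
    down), and labels are assigned from the refined baseline.
    """
    if len(medians) < 3:
        raise ValidationError(f"need >= 3 scaffolds for a robust baseline, got {len(medians)}")
    values = np.array(list(medians.values()))
    baseline = float(np.median(values))
    if baseline == 0:
        raise ValidationError("autosomal depth baseline is 0")
    flagged = {
        name for name, m in medians.items() if band[0] <= m / baseline <= band[1]
    }
    remaining = [m for name, m in medians.items() if name not in flagged]
    if remaining and flagged:
        baseline = float(np.median(remaining))
        if baseline == 0:
            raise ValidationError("autosomal depth baseline is 0 after re-estimation")
    out = []
    for name, m in medians.items():
        ratio = m / baseline
        if band[0] <= ratio <= band[1]:
            label = "haploid-depth"
        elif diploid_band[0] < ratio < diploid_band[1]:
            label = "diploid-depth"
        else:
            label = "ambiguous"
        out.append(DepthClassification(name, m, ratio, label))
    return out
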