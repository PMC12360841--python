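"""Satellite-repeat region processing from unit-vs-genome alignments.

Satellite discovery tools emit candidate tandem repeat units; aligning the
assembly back to those units yields fragmented hits that must be
post-processed into satellite regions:

1. :func:`merge_alignments` — merge consecutive hits to the same unit
   separated by < 10 bp (strict);
2. :func:`filter_regions` — retain regions > 100 bp long AND at least 10%
   of the unit length;
3. :func:`resolve_overlaps` — where regions of different repeat classes
   overlap, keep the longer (ties: smaller class id);
4. :func:`group_classes` — collapse units into classes as connected
   components of the all-vs-all similarity graph;
5. :func:`estimate_copies` — copy number = region length / unit length,
   rounded half up, with 1-based inclusive lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import ValidationError
from .seqio import PafAlignment, Region


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class SatelliteRegion:
    region: Region
    unit: str
    unit_len: int
    class_id: str | None = None

    @property
    def length(self) -> int:
        return self.region.length

    @property
    def copies(self) -> int:
        return estimate_copies(self.length, self.unit_len)


def estimate_copies(region_len: int, unit_len: int) -> int:
    """Copy number of a tandem array: round(region_len / unit_len), half up."""
    if unit_len < 1:
        raise ValidationError(f"unit length must be >= 1, got {unit_len}")
    return _round_half_up(region_len / unit_len)


def merge_alignments(alns: list[PafAlignment], max_gap: int = 10) -> list[SatelliteRegion]:
    """Merge consecutive same-unit alignments separated by < ``max_gap`` bp.

    The gap between alignments is ``next.start - prev.end - 1``; overlapping
    or abutting hits always merge.  Hits to different units never merge.
    """
    groups: dict[tuple[str, str], list[PafAlignment]] = {}
    for a in alns:
        groups.setdefault((a.target, a.query), []).append(a)
    out: list[SatelliteRegion] = []
    for (scaffold, unit), hits in sorted(groups.items()):
        hits.sort(key=lambda a: (a.target_start, a.target_end))
        unit_len = hits[0].query_len
        merged: list[list[int]] = []
        for h in hits:
            if merged and h.target_start - merged[-1][1] - 1 < max_gap:
                merged[-1][1] = max(merged[-1][1], h.target_end)
            else:
                merged.append([h.target_start, h.target_end])
        for start, end in merged:
            out.append(
                SatelliteRegion(
                    region=Region(scaffold, start, end, label=unit),
                    unit=unit,
                    unit_len=unit_len,
                )
            )
    return out


def filter_regions(
    regions: list[SatelliteRegion], min_len: int = 100, min_unit_frac: float = 0.10
) -> list[SatelliteRegion]:
    """Retain regions with length > ``min_len`` AND >= ``min_unit_frac`` of unit length."""
    return [
        r
        for r in regions
        if r.length > min_len and r.length >= min_unit_frac * r.unit_len
    ]


def resolve_overlaps(regions: list[SatelliteRegion]) -> list[SatelliteRegion]:
    """Resolve overlaps between regions of different repeat classes.

    Regions are considered longest-first (ties broken by smaller class id,
    then coordinates); a region survives unless it overlaps an already-kept
    region of a *different* class.  The output is pairwise non-overlapping
    across classes and the procedure is idempotent.
    """
    for r in regions:
        if r.class_id is None:
            raise ValidationError(f"region {r.region} has no class id")
    order = sorted(
        regions,
        key=lambda r: (-r.length, r.class_id, r.region.scaffold, r.region.start),
    )
    kept: list[SatelliteRegion] = []
    for r in order:
        if any(
            r.region.overlaps(k.region) and r.class_id != k.class_id for k in kept
        ):
            continue
        kept.append(r)
    kept.sort(key=lambda r: (r.region.scaffold, r.region.start, r.class_id))
    return kept


def group_classes(
    units: list[str], pairwise_hits: list[tuple[str, str]]
) -> dict[str, str]:
    """Group repeat units into classes by similarity-graph connected components.

    ``pairwise_hits`` lists unit pairs deemed similar by an upstream
    all-vs-all alignment (symmetrized here).  Each component becomes one
    class named ``class-<n>``, numbered in order of each component's
    lexicographically smallest member; singletons form their own class.
    """
    parent = {u: u for u in units}

    def find(u: str) -> str:
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for a, b in pairwise_hits:
        for u in (a, b):
            if u not in parent:
                raise ValidationError(f"similarity hit names unknown unit '{u}'")
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    components: dict[str, list[str]] = {}
    for u in units:
        components.setdefault(find(u), []).append(u)
    assignment: dict[str, str] = {}
    for i, root in enumerate(sorted(components, key=lambda r: min(components[r])), start=1):
        for u in components[root]:
            assignment[u] = f"class-{i}"
    return assignment


def assign_classes(
    regions: list[SatelliteRegion], classes: dict[str, str]
) -> list[SatelliteRegion]:
    """Attach class ids (from :func:`group_classes`) to satellite regions."""
    out = []
    for r in regions:
        if r.unit not in classes:
            raise ValidationError(f"region unit '{r.unit}' has no class assignment")
        out.append(replace(r, class_id=classes[r.unit]))
    return out


def satellite_pipeline(
    alns: list[PafAlignment],
    classes: dict[str, str],
    max_gap: int = 10,
    min_len: int = 100,
    min_unit_frac: float = 0.10,
) -> list[SatelliteRegion]:
    """merge -> filter -> class-assign -> resolve, in the documented order."""
    merged = merge_alignments(alns, max_gap=max_gap)
    kept = filter_regions(merged, min_len=min_len, min_unit_frac=min_unit_frac)
    classed = assign_classes(kept, classes)
    return resolve_overlaps(classed)
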