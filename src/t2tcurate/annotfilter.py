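"""Annotation-support filters.

Two small, rule-based filters used during genome annotation:

- full-length transcript selection: a transcript is full-length when its
  translated ORF has both start and stop codons and its length is between
  95% and 105% (inclusive) of its best protein database hit;
- rDNA unit detection: an rDNA unit is an ordered run of 18S, 5.8S and 28S
  subunit alignments on the same scaffold and strand within a bounded span
  (vertebrate rDNA units are ~9.5-45 kbp).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .seqio import Region


@dataclass(frozen=True)
class TranscriptEvidence:
    transcript_id: str
    translated_len: int  # amino acids
    best_hit_len: int  # amino acids
    has_start: bool
    has_stop: bool

    def __post_init__(self) -> None:
        if self.translated_len <= 0 or self.best_hit_len <= 0:
            raise ValidationError(
                f"transcript {self.transcript_id}: lengths must be > 0"
            )


def is_full_length(ev: TranscriptEvidence, lo: float = 0.95, hi: float = 1.05) -> bool:
    """Full-length iff start AND stop codons present and lo <= len ratio <= hi."""
    ratio = ev.translated_len / ev.best_hit_len
    return ev.has_start and ev.has_stop and lo <= ratio <= hi


@dataclass(frozen=True)
class RdnaUnit:
    region: Region
    strand: str
    components: tuple[Region, Region, Region]  # 18S, 5.8S, 28S in order
    unit_len: int | None = None  # distance to the next unit's 18S start


_COMPONENTS = ("18S", "5.8S", "28S")


def detect_rdna_units(
    subunit_alignments: list[tuple[str, Region, str]], max_span: int = 20_000
) -> list[RdnaUnit]:
    """Find ordered (18S, 5.8S, 28S) triplets per scaffold and strand.

    ``subunit_alignments`` holds (component, region, strand) with component
    in {18S, 5.8S, 28S}.  Scanning left to right, each 18S is paired with
    the next unused 5.8S starting after it, then the next unused 28S after
    that, provided the triplet spans at most ``max_span`` bp.  Each
    alignment is used at most once.  ``unit_len`` is the distance between
    successive units' 18S starts within the same scaffold/strand tandem
    array (None for the last unit).
    """
    for comp, _, _ in subunit_alignments:
        if comp not in _COMPONENTS:
            raise ValidationError(f"unknown rDNA component '{comp}'")
    groups: dict[tuple[str, str], dict[str, list[Region]]] = {}
    for comp, region, strand in subunit_alignments:
        key = (region.scaffold, strand)
        groups.setdefault(key, {c: [] for c in _COMPONENTS})[comp].append(region)

    units: list[RdnaUnit] = []
    for (scaffold, strand), comps in sorted(groups.items()):
        for c in _COMPONENTS:
            comps[c].sort(key=lambda r: r.start)
        used: dict[str, set[int]] = {c: set() for c in _COMPONENTS}
        found: list[RdnaUnit] = []
        for i, s18 in enumerate(comps["18S"]):
            if i in used["18S"]:
                continue
            s58 = next(
                (
                    (j, r)
                    for j, r in enumerate(comps["5.8S"])
                    if j not in used["5.8S"] and r.start > s18.start
                ),
                None,
            )
            if s58 is None:
                continue
            s28 = next(
                (
                    (j, r)
                    for j, r in enumerate(comps["28S"])
                    if j not in used["28S"] and r.start > s58[1].start
                ),
                None,
            )
            if s28 is None:
                continue
            if s28[1].end - s18.start + 1 > max_span:
                continue
            used["18S"].add(i)
            used["5.8S"].add(s58[0])
            used["28S"].add(s28[0])
            found.append(
                RdnaUnit(
                    region=Region(scaffold, s18.start, s28[1].end, label="rDNA"),
                    strand=strand,
                    components=(s18, s58[1], s28[1]),
                )
            )
        # period between successive units in the tandem array
        for a, b in zip(found, found[1:]):
            units.append(
                RdnaUnit(
                    region=a.region,
                    strand=a.strand,
                    components=a.components,
                    unit_len=b.components[0].start - a.components[0].start,
                )
            )
        if found:
            units.append(found[-1])
    units.sort(key=lambda u: (u.region.scaffold, u.region.start))
    return units
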