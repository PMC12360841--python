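"""Haplotype-to-reference scaffold selection.

Given two haplotype assemblies whose chromosome-scale scaffolds are paired
(pairing is an explicit input; the haplotypes of a trio-free diploid
assembly are pairable by construction), the reference takes the better
scaffold of each pair by a fixed rule cascade:

1. strictly more telomere-bearing ends wins;
2. else strictly fewer gaps wins;
3. else strictly longer wins;
4. else haplotype 1.

Z- and W-specific scaffolds are appended as-is, and all sub-threshold
(< 1 Mbp by default) scaffolds are drawn from haplotype 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError


@dataclass(frozen=True)
class ScaffoldSummary:
    name: str
    haplotype: int  # 1 or 2
    length: int
    telomere_ends: int  # 0, 1 or 2
    n_gaps: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"scaffold {self.name}: length must be > 0")
        if self.telomere_ends not in (0, 1, 2):
            raise ValidationError(f"scaffold {self.name}: telomere_ends must be 0, 1 or 2")
        if self.haplotype not in (1, 2):
            raise ValidationError(f"scaffold {self.name}: haplotype must be 1 or 2")


@dataclass(frozen=True)
class SelectionDecision:
    pair_id: str
    chosen: str  # "hap1" or "hap2"
    rule_fired: str  # {"telomere", "gaps", "length", "default"}
    chosen_name: str


def select_scaffold(pair_id: str, h1: ScaffoldSummary, h2: ScaffoldSummary) -> SelectionDecision:
    """Apply the rule cascade to one scaffold pair.

    Exactly one rule fires: the first whose comparison is strict.
    """
    if h1.haplotype != 1 or h2.haplotype != 2:
        raise ValidationError(
            f"pair {pair_id}: summaries must be (haplotype 1, haplotype 2), "
            f"got ({h1.haplotype}, {h2.haplotype})"
        )
    if h1.telomere_ends != h2.telomere_ends:
        winner = h1 if h1.telomere_ends > h2.telomere_ends else h2
        rule = "telomere"
    elif h1.n_gaps != h2.n_gaps:
        winner = h1 if h1.n_gaps < h2.n_gaps else h2
        rule = "gaps"
    elif h1.length != h2.length:
        winner = h1 if h1.length > h2.length else h2
        rule = "length"
    else:
        winner, rule = h1, "default"
    return SelectionDecision(
        pair_id=pair_id,
        chosen=f"hap{winner.haplotype}",
        rule_fired=rule,
        chosen_name=winner.name,
    )


def assemble_reference(
    pairs: list[tuple[str, ScaffoldSummary, ScaffoldSummary]],
    sex_scaffolds: dict[str, str],
    small_scaffolds_h1: list[str],
) -> tuple[list[str], list[SelectionDecision]]:
    """Compose the reference scaffold list.

    ``pairs`` holds (pair_id, hap1 summary, hap2 summary); ``sex_scaffolds``
    maps scaffold name -> {"Z", "W"}; ``small_scaffolds_h1`` lists the
    haplotype-1 scaffolds below the pairing size threshold.  Returns the
    ordered reference names (chosen autosomes by descending length, then Z,
    then W, then small scaffolds) and the per-pair decision log.
    """
    paired_names = {s.name for _, h1, h2 in pairs for s in (h1, h2)}
    clash = paired_names & set(sex_scaffolds)
    if clash:
        raise ValidationError(f"scaffolds appear in both a pair and the sex set: {sorted(clash)}")
    decisions = [select_scaffold(pid, h1, h2) for pid, h1, h2 in pairs]
    chosen = []
    for (pid, h1, h2), dec in zip(pairs, decisions):
        summary = h1 if dec.chosen == "hap1" else h2
        chosen.append((summary.length, dec.chosen_name))
    chosen.sort(key=lambda t: -t[0])
    reference = [name for _, name in chosen]
    for label in ("Z", "W"):
        reference.extend(sorted(n for n, lab in sex_scaffolds.items() if lab == label))
    reference.extend(small_scaffolds_h1)
    return reference, decisions
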