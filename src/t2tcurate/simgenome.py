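"""Seeded synthetic diploid genome generator with machine-readable truth.

Generates a miniature diploid genome with the structural features the
curation pipeline is built to detect, each recorded in a truth table:

- macro- and microchromosome scaffolds with distinct GC content (the
  default configuration has 6 macro + 10 micro scaffolds, GC 0.41/0.46,
  matching the bimodal reptile karyotype);
- terminal TTAGGG/CCCTAA telomere tracts on both ends of autosomes and one
  end of each sex scaffold;
- interior runs of 100 N marking scaffolding gaps;
- tandem satellite arrays at declared positions;
- a per-scaffold centromere, realized as a local dip in heterozygous-site
  density and a boosted interchromosomal Hi-C contact row;
- a Z/W scaffold pair at half read depth;
- a two-peak k-mer multiplicity histogram (heterozygous peak at about half
  the homozygous peak position).

Scaffold lengths default to a few Mbp — a deliberate scale-down of
chromosome-scale assemblies so simulation stays tractable; every other
default matches the full-scale setting it emulates.  Noise models: window
depth ~ Poisson, heterozygous sites ~ Bernoulli per bp, Hi-C counts ~
Poisson.  One master seed; per-artifact streams are derived with fixed
spawn keys so adding an artifact never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .kmerstats import KmerHistogram
from .seqio import (
    PafAlignment,
    Region,
    ScaffoldRecord,
    TrfRecord,
    write_binmap,
    write_coo_matrix,
    write_fasta,
    write_paf,
    write_track,
    write_trf_dat,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_N = ord("N")


@dataclass(frozen=True)
class SatelliteSpec:
    unit_len: int
    copies: int
    scaffold: str
    start: int  # 1-based


@dataclass
class SimConfig:
    seed: int = 1
    n_macro: int = 6
    n_micro: int = 10
    macro_len_range: tuple[int, int] = (3_000_000, 6_000_000)
    micro_len_range: tuple[int, int] = (1_200_000, 2_500_000)
    gc_macro: float = 0.41
    gc_micro: float = 0.46
    telomere_len_range: tuple[int, int] = (2_430, 6_000)
    telomere_noise: float = 0.0  # substitution rate inside telomere tracts
    n_gap_runs: int = 1
    gap_len: int = 100
    hap2_extra_gaps: int = 1
    satellite_specs: list[SatelliteSpec] = field(
        default_factory=lambda: [
            SatelliteSpec(98, 500, "macro1", 1_000_000),
            SatelliteSpec(398, 150, "macro2", 800_000),
        ]
    )
    centromere_positions: dict[str, int] | None = None  # default: 0.45 * length
    het_rate: float = 0.0198  # per-bp Bernoulli; the species is ~2% heterozygous
    het_dip_width: int = 1_000_000  # full width of suppression around centromere
    depth_mean: float = 40.0
    sex_pair: bool = True
    z_len: int = 2_780_000
    w_len: int = 4_640_000
    hic_bin: int = 50_000
    hic_background: float = 5.0
    hic_intra_factor: float = 10.0
    centro_boost: float = 5.0
    kmer_k: int = 17
    read_len: int = 134

    def validate(self) -> None:
        for name in ("macro_len_range", "micro_len_range", "telomere_len_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name}: require 0 < low <= high, got ({lo}, {hi})")
        for name in ("gc_macro", "gc_micro"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.n_macro < 1 or self.n_micro < 0:
            raise ValidationError("need n_macro >= 1 and n_micro >= 0")
        if self.gap_len < 1:
            raise ValidationError(f"gap_len must be >= 1, got {self.gap_len}")
        if not 0 <= self.het_rate < 1:
            raise ValidationError(f"het_rate must be in [0, 1), got {self.het_rate}")
        if self.kmer_k >= self.read_len:
            raise ValidationError("kmer_k must be < read_len")


@dataclass
class TruthTables:
    scaffold_lengths: dict[str, int]
    telomeres: list[Region]
    satellites: list[Region]  # label = unit id
    satellite_units: dict[str, int]  # unit id -> unit length
    centromeres: dict[str, int]  # scaffold -> centromere position (bp)
    sex_scaffolds: dict[str, str]  # scaffold -> {"Z", "W"}
    genome_size: int
    het_sites: dict[str, np.ndarray]  # scaffold -> 1-based positions
    gaps_hap1: list[Region] = field(default_factory=list)
    gaps_hap2: list[Region] = field(default_factory=list)

    @property
    def autosomes(self) -> list[str]:
        return [s for s in self.scaffold_lengths if s not in self.sex_scaffolds]


def _stream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _tile_motif(motif: str, length: int) -> np.ndarray:
    arr = np.frombuffer((motif * (length // len(motif) + 1)).encode(), dtype=np.uint8)
    return arr[:length].copy()


def _plan_lengths(config: SimConfig, rng: np.random.Generator) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for i in range(config.n_macro):
        lengths[f"macro{i + 1}"] = int(rng.integers(*config.macro_len_range, endpoint=True))
    for i in range(config.n_micro):
        lengths[f"micro{i + 1}"] = int(rng.integers(*config.micro_len_range, endpoint=True))
    if config.sex_pair:
        lengths["Z"] = config.z_len
        lengths["W"] = config.w_len
    return lengths


def generate_truth(config: SimConfig) -> TruthTables:
    """Plan the genome layout and truth tables without synthesizing sequence.

    Deterministic for a fixed config; :func:`generate_genome` realizes the
    same plan into base-level sequences.  Useful when only tracks/matrices
    are needed (they depend on the truth tables, not the bases).
    """
    config.validate()
    rng = _stream(config.seed, 0)
    lengths = _plan_lengths(config, rng)
    sex = {"Z": "Z", "W": "W"} if config.sex_pair else {}

    telomeres: list[Region] = []
    telo_lens: dict[tuple[str, str], int] = {}
    for name, slen in lengths.items():
        lo, hi = config.telomere_len_range
        for which in ("5prime", "3prime"):
            tlen = 6 * int(rng.integers(lo // 6, hi // 6, endpoint=True))
            telo_lens[(name, which)] = tlen
        if name == "Z":
            del telo_lens[(name, "3prime")]
        elif name == "W":
            del telo_lens[(name, "5prime")]
    for (name, which), tlen in telo_lens.items():
        slen = lengths[name]
        if which == "5prime":
            telomeres.append(Region(name, 1, tlen, label="telomere"))
        else:
            telomeres.append(Region(name, slen - tlen + 1, slen, label="telomere"))

    satellites: list[Region] = []
    units: dict[str, int] = {}
    for i, spec in enumerate(config.satellite_specs):
        if spec.scaffold not in lengths:
            raise ValidationError(
                f"satellite_specs[{i}]: unknown scaffold '{spec.scaffold}'"
            )
        end = spec.start + spec.unit_len * spec.copies - 1
        if spec.start < 1 or end > lengths[spec.scaffold]:
            raise ValidationError(
                f"satellite_specs[{i}]: array {spec.start}-{end} outside "
                f"scaffold '{spec.scaffold}' (length {lengths[spec.scaffold]})"
            )
        unit_id = f"unit-{i + 1}"
        units[unit_id] = spec.unit_len
        satellites.append(Region(spec.scaffold, spec.start, end, label=unit_id))

    if config.centromere_positions is not None:
        centromeres = dict(config.centromere_positions)
        for name in centromeres:
            if name not in lengths:
                raise ValidationError(f"centromere_positions: unknown scaffold '{name}'")
    else:
        centromeres = {
            name: int(0.45 * slen) for name, slen in lengths.items() if name not in sex
        }

    # feature mask per scaffold: telomeres and satellite arrays are het-free
    feature_blocks: dict[str, list[tuple[int, int]]] = {n: [] for n in lengths}
    for r in telomeres:
        feature_blocks[r.scaffold].append((r.start, r.end))
    for r in satellites:
        feature_blocks[r.scaffold].append((r.start, r.end))

    gaps1: list[Region] = []
    gaps2: list[Region] = []
    for name, slen in lengths.items():
        blocked = sorted(feature_blocks[name])
        placed: list[int] = []

        def place(n_runs: int, out: list[Region]) -> None:
            margin = 10_000
            tries = 0
            while len(placed_local) < n_runs and tries < 1000:
                tries += 1
                pos = int(rng.integers(margin, slen - margin - config.gap_len))
                lo, hi = pos, pos + config.gap_len - 1
                if any(lo <= b_hi + margin and b_lo - margin <= hi for b_lo, b_hi in blocked):
                    continue
                if any(abs(pos - p) < config.gap_len + margin for p in placed):
                    continue
                placed.append(pos)
                placed_local.append(pos)
                out.append(Region(name, lo, hi, label="gap"))

        placed_local: list[int] = []
        place(config.n_gap_runs, gaps1)
        # hap2 shares hap1's gaps and gets extra ones of its own
        gaps2.extend(Region(name, p, p + config.gap_len - 1, label="gap") for p in placed_local)
        placed_local = []
        place(config.hap2_extra_gaps, gaps2)

    # heterozygous sites: Bernoulli per bp, suppressed near the centromere
    # and inside telomere/satellite/gap features
    het: dict[str, np.ndarray] = {}
    for name, slen in lengths.items():
        if config.het_rate == 0:
            het[name] = np.empty(0, dtype=np.int64)
            continue
        draws = rng.random(slen) < config.het_rate
        mask = np.ones(slen, dtype=bool)
        for b_lo, b_hi in feature_blocks[name]:
            mask[b_lo - 1 : b_hi] = False
        for g in gaps1 + gaps2:
            if g.scaffold == name:
                mask[g.start - 1 : g.end] = False
        if name in centromeres:
            half = config.het_dip_width // 2
            c = centromeres[name]
            mask[max(0, c - half - 1) : min(slen, c + half)] = False
        het[name] = np.flatnonzero(draws & mask).astype(np.int64) + 1

    return TruthTables(
        scaffold_lengths=lengths,
        telomeres=telomeres,
        satellites=satellites,
        satellite_units=units,
        centromeres=centromeres,
        sex_scaffolds=sex,
        genome_size=int(sum(lengths.values())),
        het_sites=het,
        gaps_hap1=sorted(gaps1, key=lambda r: (r.scaffold, r.start)),
        gaps_hap2=sorted(gaps2, key=lambda r: (r.scaffold, r.start)),
    )


def generate_genome(
    config: SimConfig,
) -> tuple[dict[str, ScaffoldRecord], dict[str, ScaffoldRecord], TruthTables]:
    """Realize the genome plan into two haplotype sequence sets plus truth.

    Haplotype 2 differs from haplotype 1 by a substitution at every truth
    heterozygous site and by its extra gap runs; telomeres, satellites and
    shared gaps are identical between haplotypes.
    """
    truth = generate_truth(config)
    rng = _stream(config.seed, 1)
    hap1: dict[str, ScaffoldRecord] = {}
    hap2: dict[str, ScaffoldRecord] = {}
    sat_units: dict[str, np.ndarray] = {}
    for unit_id, ulen in truth.satellite_units.items():
        sat_units[unit_id] = _random_bases(rng, ulen, 0.5)

    for name, slen in truth.scaffold_lengths.items():
        gc = config.gc_macro if name.startswith("macro") else config.gc_micro
        seq = _random_bases(rng, slen, gc)
        for r in truth.telomeres:
            if r.scaffold != name:
                continue
            motif = "CCCTAA" if r.start == 1 else "TTAGGG"
            tract = _tile_motif(motif, r.length)
            if config.telomere_noise > 0:
                noisy = rng.random(r.length) < config.telomere_noise
                tract[noisy] = _BASES[rng.integers(0, 4, size=int(noisy.sum()))]
            seq[r.start - 1 : r.end] = tract
        for r in truth.satellites:
            if r.scaffold != name:
                continue
            unit = sat_units[r.label]
            reps = r.length // len(unit)
            seq[r.start - 1 : r.end] = np.tile(unit, reps)

        seq2 = seq.copy()
        pos0 = truth.het_sites.get(name, np.empty(0, dtype=np.int64)) - 1
        if pos0.size:
            # deterministic transversion-style map: A->C, C->G, G->T, T->A
            sub = {65: 67, 67: 71, 71: 84, 84: 65}
            lut = np.arange(256, dtype=np.uint8)
            for k, v in sub.items():
                lut[k] = v
            seq2[pos0] = lut[seq2[pos0]]

        for g in truth.gaps_hap1:
            if g.scaffold == name:
                seq[g.start - 1 : g.end] = _N
        for g in truth.gaps_hap2:
            if g.scaffold == name:
                seq2[g.start - 1 : g.end] = _N

        hap1[name] = ScaffoldRecord(name, seq.tobytes().decode("ascii"))
        hap2[name] = ScaffoldRecord(name, seq2.tobytes().decode("ascii"))
    return hap1, hap2, truth


def generate_depth_track(
    truth: TruthTables, depth_mean: float, window: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """Per-window read depth: Poisson(depth_mean), halved on sex scaffolds."""
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    rows = []
    for name, slen in truth.scaffold_lengths.items():
        lam = depth_mean / 2 if name in truth.sex_scaffolds else depth_mean
        n_win = max(1, math.ceil(slen / window))
        vals = rng.poisson(lam, n_win) if lam > 0 else np.zeros(n_win, dtype=int)
        for i in range(n_win):
            rows.append((name, i * window + 1, min((i + 1) * window, slen), int(vals[i])))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "value"])


def generate_kmer_histogram(
    genome_size: int,
    coverage: float,
    read_len: int,
    k: int,
    het_rate: float,
    seed: int = 0,
    error_frac: float = 0.3,
) -> KmerHistogram:
    """Simulate a diploid k-mer multiplicity histogram.

    Homozygous k-mer loci receive Poisson(c) counts with
    c = coverage * (read_len - k + 1) / read_len; a locus overlapping a
    heterozygous site (probability 1 - (1 - het_rate)^k) splits into two
    distinct k-mers at Poisson(c/2) each.  ``error_frac`` * genome_size
    spurious error k-mers with geometric low multiplicities form the error
    slope below the trough.
    """
    if coverage <= 0:
        raise ValidationError("coverage must be > 0")
    if k >= read_len:
        raise ValidationError("k must be < read_len")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    lam = coverage * (read_len - k + 1) / read_len
    p_het = 1 - (1 - het_rate) ** k
    n_het = int(round(genome_size * p_het))
    n_hom = genome_size - n_het
    counts = [rng.poisson(lam, n_hom), rng.poisson(lam / 2, 2 * n_het)]
    if error_frac > 0:
        counts.append(rng.geometric(0.75, int(error_frac * genome_size)))
    allc = np.concatenate(counts)
    allc = allc[allc > 0]
    freq = np.bincount(allc)
    return KmerHistogram(k=k, counts={int(m): int(c) for m, c in enumerate(freq) if m >= 1 and c > 0})


def generate_hic_matrix(
    truth: TruthTables,
    bin_size: int = 50_000,
    background: float = 5.0,
    centro_boost: float = 5.0,
    seed: int = 0,
    intra_factor: float = 10.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Binned Hi-C contact matrix with centromeric interchromosomal boost.

    Counts are Poisson with mean ``background`` for interchromosomal pairs
    (+``centro_boost`` per pair when either bin overlaps a truth
    centromere) and ``background * intra_factor`` for intrachromosomal
    pairs.  Returns (symmetric matrix, bin map DataFrame).
    """
    if bin_size < 1:
        raise ValidationError(f"bin size must be >= 1, got {bin_size}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
    rows = []
    bin_id = 0
    for name, slen in truth.scaffold_lengths.items():
        for i in range(max(1, math.ceil(slen / bin_size))):
            rows.append((bin_id, name, i * bin_size + 1, min((i + 1) * bin_size, slen)))
            bin_id += 1
    binmap = pd.DataFrame(rows, columns=["bin", "scaffold", "start", "end"])
    n = len(binmap)
    scf = binmap["scaffold"].to_numpy()
    same = scf[:, None] == scf[None, :]
    mean = np.where(same, background * intra_factor, background)
    centro_bins = [
        int(binmap[(binmap["scaffold"] == s) & (binmap["start"] <= p) & (binmap["end"] >= p)]["bin"].iloc[0])
        for s, p in truth.centromeres.items()
    ]
    for b in centro_bins:
        mean[b, ~same[b]] += centro_boost
        mean[~same[b], b] += centro_boost
    upper = np.triu(rng.poisson(mean)).astype(float)
    mat = upper + np.triu(upper, 1).T
    return mat, binmap


def _trf_records_from_truth(truth: TruthTables) -> list[TrfRecord]:
    recs = []
    for r in truth.telomeres:
        motif = "CCCTAA" if r.start == 1 else "TTAGGG"
        recs.append(
            TrfRecord(
                scaffold=r.scaffold,
                start=r.start,
                end=r.end,
                period=6,
                copy_number=round(r.length / 6, 1),
                consensus=motif,
                score=2 * r.length,
            )
        )
    return recs


def _satellite_paf_from_truth(truth: TruthTables) -> list[PafAlignment]:
    """Emulate fragmented unit-vs-genome alignments: chunks of 20 units
    separated by 5-bp gaps, which the merge step (< 10 bp) reassembles."""
    alns = []
    for r in truth.satellites:
        ulen = truth.satellite_units[r.label]
        chunk = 20 * ulen
        pos = r.start
        while pos <= r.end:
            end = min(pos + chunk - 1, r.end)
            alns.append(
                PafAlignment(
                    query=r.label,
                    query_len=ulen,
                    target=r.scaffold,
                    target_start=pos,
                    target_end=end,
                    strand="+",
                    matches=end - pos + 1,
                    block_len=end - pos + 1,
                )
            )
            pos = end + 1 + 5
    return alns


def truth_to_json(truth: TruthTables) -> dict:
    return {
        "scaffold_lengths": truth.scaffold_lengths,
        "telomeres": [[r.scaffold, r.start, r.end] for r in truth.telomeres],
        "satellites": [
            [r.scaffold, r.start, r.end, r.label, truth.satellite_units[r.label]]
            for r in truth.satellites
        ],
        "satellite_units": truth.satellite_units,
        "centromeres": truth.centromeres,
        "sex_scaffolds": truth.sex_scaffolds,
        "genome_size": truth.genome_size,
        "n_het_sites": {s: int(p.size) for s, p in truth.het_sites.items()},
        "gaps_hap1": [[r.scaffold, r.start, r.end] for r in truth.gaps_hap1],
        "gaps_hap2": [[r.scaffold, r.start, r.end] for r in truth.gaps_hap2],
    }


def write_fixtures(outdir: str | Path, config: SimConfig) -> dict[str, str]:
    """Generate and write the full fixture set; returns {path: sha256} manifest.

    Files: hap1.fa, hap2.fa, telomeres.dat (TRF dialect), depth.tsv,
    het.tsv, satellites.paf, hic_matrix.tsv + hic_bins.tsv, kmer_hist.tsv,
    truth.json, manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hap1, hap2, truth = generate_genome(config)

    write_fasta(hap1.values(), outdir / "hap1.fa")
    write_fasta(hap2.values(), outdir / "hap2.fa")
    write_trf_dat(_trf_records_from_truth(truth), outdir / "telomeres.dat")

    depth = generate_depth_track(truth, config.depth_mean, seed=config.seed)
    write_track(depth, outdir / "depth.tsv")

    het_rows = [
        (s, int(p)) for s, arr in truth.het_sites.items() for p in arr
    ]
    pd.DataFrame(het_rows, columns=["scaffold", "pos"]).to_csv(
        outdir / "het.tsv", sep="\t", index=False
    )

    write_paf(
        _satellite_paf_from_truth(truth),
        outdir / "satellites.paf",
        target_lens=truth.scaffold_lengths,
    )

    mat, binmap = generate_hic_matrix(
        truth,
        bin_size=config.hic_bin,
        background=config.hic_background,
        centro_boost=config.centro_boost,
        seed=config.seed,
        intra_factor=config.hic_intra_factor,
    )
    write_coo_matrix(mat, outdir / "hic_matrix.tsv")
    write_binmap(binmap, outdir / "hic_bins.tsv")

    hist = generate_kmer_histogram(
        genome_size=truth.genome_size,
        coverage=config.depth_mean,
        read_len=config.read_len,
        k=config.kmer_k,
        het_rate=config.het_rate,
        seed=config.seed,
    )
    pd.DataFrame(
        sorted(hist.counts.items()), columns=["multiplicity", "count"]
    ).to_csv(outdir / "kmer_hist.tsv", sep="\t", index=False)

    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_to_json(truth), fh, indent=1, sort_keys=True)

    manifest: dict[str, str] = {}
    for p in sorted(outdir.iterdir()):
        if p.name == "manifest.json":
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
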