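# Methods

This note documents the models, conventions and numerical choices behind
t2tcurate, and what the synthetic-data tests do and do not establish.

## Coordinate convention

All modules exchange 1-based fully inclusive intervals (`length =
end − start + 1`), matching how assembly reports print coordinates.
BED (0-based half-open) and PAF (0-based half-open target coordinates) are
converted in `seqio` at the I/O boundary and nowhere else. Copy-number
rounding is half-up (`floor(x + 0.5)`); both published satellite worked
examples (192,132/98 = 1,960.5 → 1,961 and 423,159/398 = 1,063.2 → 1,063)
pin this combination of conventions.

## K-mer statistics

Genome size uses the standard k-mer coverage correction
`G = T·(L−k+1)/(L·c)`: a read of length L yields `L−k+1` k-mers, so the
k-mer depth c underestimates base depth by `(L−k+1)/L`. The estimator is
exactly linear in T and inversely proportional to c (asserted in tests).

Peak detection smooths the multiplicity histogram with a centered width-3
moving average. If the curve starts on a descending slope, that slope is
sequencing error: the first strict local minimum is the error trough and
maxima at or below it are discarded. A curve that starts rising has no
error component, and no trough is imposed — otherwise the valley between
the heterozygous and homozygous peaks would be mistaken for it. Peaks
below 1% of the tallest peak are treated as smoothing noise in the sparse
tail. With two surviving peaks, the lower is heterozygous if it sits
within ±25% of half the homozygous position.

## Assembly statistics

N50 is "first cumulative ≥ half" on descending-sorted lengths, ties
resolved by sort order — the convention of common assembly-stats tools.
Window GC excludes N from the denominator by default (an all-N window is
emitted as missing); the trailing partial window is included and flagged.
The macro/micro classification cuts at the midpoint of the largest gap in
sorted median-GC values among scaffolds ≥1 Mbp, because real data show
ranges (macros ~40.7–41.8%, micros ~42.6–47.6%), not a universal
threshold. This requires the between-class GC gap to exceed the
within-class spacing — true for karyotypes with enough scaffolds per
class, degenerate for sparse inputs (a warning is emitted when all GC
values are identical).

## Telomere calling

Tandem Repeats Finder reports arrays with arbitrary phase, so "contains
the telomeric motif" is implemented as: the period-6 consensus is a
circular rotation of TTAGGG or CCCTAA. Qualifying records separated by
≤100 bp merge (TRF fragments long arrays; configurable). Merged regions
longer than 600 bp are called; shorter regions ≥150 bp touching a scaffold
end within 10 kbp are rescued with a flag — terminal arrays as short as
214 bp (32 exact motifs) are genuinely telomeric. Two copy estimators are
exposed because both conventions appear in practice: `length/6` rounded
half up, and exact non-overlapping motif counting on sequence; for
degenerate arrays these differ and neither is canonical.

## Reference selection

The cascade (telomere ends, then gaps, then length, then haplotype 1) is
applied with strict comparisons, so exactly one rule fires per pair. The
telomere rule is generalized from the documented 2-vs-1 case to "strictly
more ends" (covering 2-vs-0 and 1-vs-0). Pairing between haplotypes is an
explicit input table: the haplotypes of a diploid assembly are pairable by
construction, and no homology inference is attempted here.

## Satellite regions

Merging uses strict `gap < 10 bp` where `gap = next.start − prev.end − 1`
(9 bp merges, 10 bp does not). Retention is the conjunction
`length > 100 bp AND length ≥ 0.10 × unit_len`. Cross-class overlap
resolution keeps the longest region, ties broken by lexicographically
smaller class id (deterministic; no published tie rule exists); same-class
overlaps are left intact. The pipeline merge → filter → resolve is
idempotent. Unit-to-class grouping is connected components of the
similarity graph; similarity hits are an input — unit discovery and
all-vs-all alignment are external tools' work.

## Centromere inference

Interchromosomal z: per bin, `s` = summed contacts to bins on other
scaffolds, `t = log10(s + 1)` (the +1 handles empty bins; the log base
cancels in the z up to the offset), standardized within each scaffold
(population sd; sd = 0 ⇒ z = 0). Standardization is per chromosome, not
across chromosomes. LOESS is degree-1 local regression with tricube
weights over the `ceil(span·n)` nearest points (spans: 0.4 for z, 0.5 for
heterozygosity — plotting-convention defaults). A centromere is called
when the smoothed-z argmax and smoothed-het argmin bin centers lie within
2 Mbp, excluding the terminal 5% of bins on each side, since telomeres
also cluster in the nucleus and inflate interchromosomal contact.
The call interval is the union of the two extremal bins.

Known limitation: on scaffolds with no true centromeric signal (e.g. the
synthetic Z/W, which are given none), noise extrema can colocalize by
chance when the scaffold is short relative to the 2-Mbp tolerance; calls
carry their z-peak, het-min and offset so such calls can be triaged.

## Sex-scaffold classification

Scaffolds ≥1 Mbp are summarized by the median of their 10-kbp window
depths (numpy convention: even counts average the central pair). The
autosomal baseline is the median of scaffold medians, re-estimated once
after excluding first-pass haploid-depth flags so multiple sex scaffolds
cannot drag it down. "Approximately half" is quantified as ratio ∈
[0.35, 0.65] (configurable; no published number exists); diploid-depth is
(0.8, 1.2); anything else is flagged ambiguous. Labels are invariant to
uniform depth rescaling.

## Annotation filters

Full-length transcripts require both start and stop codons and a
translated/best-hit length ratio within [0.95, 1.05] — bounds inclusive
("between 95% and 105%"), compared on amino-acid lengths. rDNA units are
ordered 18S < 5.8S < 28S triplets on one scaffold and strand within
20 kbp, assigned greedily left-to-right with each alignment used once;
the unit period is the distance between successive 18S starts.

## Synthetic genome generator

`simgenome` emulates the structures the pipeline detects, not real
sequence evolution. Defaults state the emulated world: 6 macro + 10 micro
scaffolds (the dragon karyotype), GC 0.41/0.46, per-bp heterozygosity
0.0198, depth 40×, Z/W scaffolds of 2.78/4.64 Mbp at half depth, hexamer
telomere tracts of 2,430–6,000 bp, 100-N gap runs, 50-kbp Hi-C bins,
k = 17. Scaffold lengths are scaled to a few Mbp so the suite runs on one
CPU in minutes; length-independent signals (depth ratios, GC, z-scores,
peak ratios) are unaffected by the scaling, while length-dependent ones
(e.g. the ±2 Mbp centromere tolerance relative to scaffold length) are
correspondingly easier — a green recovery test establishes the machinery,
not full-scale sensitivity.

Noise models are the simplest matching the qualitative structure: window
depth ~ Poisson(depth), het sites ~ Bernoulli(rate) per bp (suppressed
within ±0.5 Mbp of the centromere and inside telomere/satellite/gap
features), Hi-C counts ~ Poisson with a constant intra/inter contrast and
a per-pair interchromosomal mean boost on centromeric bins. The k-mer
histogram draws Poisson(c) per homozygous locus and two Poisson(c/2)
k-mers per heterozygous locus (p = 1−(1−h)^k), plus a geometric
low-multiplicity error component. Not modeled: distance-dependent Hi-C
decay, read-level errors, indels, repeat-induced mapping noise, GC bias.

Haplotype 2 equals haplotype 1 except for a deterministic substitution at
every heterozygous site and extra gap runs (to exercise the gap rule in
reference selection). One master seed drives per-artifact child streams
with fixed spawn keys, so adding an artifact never perturbs the others;
identical configs give byte-identical outputs.

## Numerical and degenerate-input choices

- Round half up everywhere copy numbers are derived from lengths.
- `estimate_genome_size` rejects L < k; L = k is valid (one k-mer/read).
- Zero-variance z within a scaffold ⇒ z = 0, never NaN.
- LOESS requires ≥5 points; exact on collinear input (asserted to 1e-9,
  and cross-checked against statsmodels' lowess where both are exact).
- Flat smoothed signals produce no centromere call rather than an
  arbitrary argmax.
- An all-N GC window is missing, not 0%.
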