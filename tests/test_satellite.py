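"""Satellite region processing: merge, filter, overlap resolution, classes, copies."""

import numpy as np
import pytest

from t2tcurate import satellite
from t2tcurate.errors import ValidationError
from t2tcurate.satellite import SatelliteRegion, estimate_copies
from t2tcurate.seqio import PafAlignment, Region


def aln(unit, start, end, scaffold="s1", unit_len=98):
    return PafAlignment(unit, unit_len, scaffold, start, end, "+", end - start + 1, end - start + 1)


def sat(start, end, unit="u1", unit_len=98, class_id=None, scaffold="s1"):
    return SatelliteRegion(Region(scaffold, start, end, unit), unit, unit_len, class_id)


class TestEstimateCopies:
    def test_published_98bp_unit(self):
        """W-scaffold array 281,785-473,916 with a 98-bp unit: 1,961 copies."""
        assert estimate_copies(473_916 - 281_785 + 1, 98) == 1961

    def test_published_398bp_unit(self):
        """Scaffold-1 array 181,407,117-181,830,275, 398-bp unit: 1,063 copies."""
        assert estimate_copies(181_830_275 - 181_407_117 + 1, 398) == 1063

    def test_single_unit(self):
        assert estimate_copies(98, 98) == 1

    def test_half_rounds_up(self):
        assert estimate_copies(147, 98) == 2  # 1.5 -> 2

    def test_zero_unit_rejected(self):
        with pytest.raises(ValidationError):
            estimate_copies(100, 0)


class TestMergeAlignments:
    def test_single_unchanged(self):
        (r,) = satellite.merge_alignments([aln("u1", 100, 200)])
        assert (r.region.start, r.region.end) == (100, 200)

    def test_gap_boundary_strict(self):
        """Gap of 9 bp merges; gap of 10 bp does not (strict < 10)."""
        merged = satellite.merge_alignments([aln("u1", 100, 200), aln("u1", 210, 300)])
        assert len(merged) == 1  # 210 - 200 - 1 = 9
        not_merged = satellite.merge_alignments([aln("u1", 100, 200), aln("u1", 211, 300)])
        assert len(not_merged) == 2  # gap = 10

    def test_chain_against_interval_oracle(self):
        """Chain of 5 with gaps {3, 9, 10, 2} -> 2 merged regions."""
        starts_ends = []
        pos = 100
        for gap in [3, 9, 10, 2]:
            starts_ends.append((pos, pos + 49))
            pos = pos + 49 + gap + 1
        starts_ends.append((pos, pos + 49))
        merged = satellite.merge_alignments([aln("u1", s, e) for s, e in starts_ends])
        assert len(merged) == 2

        # brute-force interval-merge oracle over bp sets with <10 bridging
        def oracle(intervals, max_gap=10):
            intervals = sorted(intervals)
            out = [list(intervals[0])]
            for s, e in intervals[1:]:
                if s - out[-1][1] - 1 < max_gap:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            return [tuple(x) for x in out]

        assert [(r.region.start, r.region.end) for r in merged] == oracle(starts_ends)

    def test_different_units_never_merge(self):
        merged = satellite.merge_alignments([aln("u1", 100, 200), aln("u2", 202, 300)])
        assert len(merged) == 2

    def test_random_against_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(1, 20))
            starts = np.sort(rng.integers(1, 5000, n))
            alns = [aln("u1", int(s), int(s + rng.integers(10, 120))) for s in starts]
            merged = satellite.merge_alignments(alns)
            # oracle: mark covered bp plus <10-bp bridges
            covered = np.zeros(10_000, dtype=bool)
            for a in alns:
                covered[a.target_start : a.target_end + 1] = True
            # bridge gaps < 10
            runs = []
            i = 1
            while i < len(covered):
                if covered[i]:
                    j = i
                    while j + 1 < len(covered) and covered[j + 1]:
                        j += 1
                    runs.append([i, j])
                    i = j + 1
                i += 1
            fused = [runs[0]]
            for s, e in runs[1:]:
                if s - fused[-1][1] - 1 < 10:
                    fused[-1][1] = e
                else:
                    fused.append([s, e])
            assert [[r.region.start, r.region.end] for r in merged] == fused


class TestFilterRegions:
    def test_small_unit_kept(self):
        """98-bp unit, 150-bp region: passes both conditions."""
        assert satellite.filter_regions([sat(1, 150, unit_len=98)])

    def test_large_unit_fraction_drops(self):
        """2,190-bp unit, 150-bp region: fails the 10%-of-unit condition."""
        assert satellite.filter_regions([sat(1, 150, unit_len=2190)]) == []

    def test_exactly_100bp_dropped(self):
        """The length condition is strictly > 100."""
        assert satellite.filter_regions([sat(1, 100, unit_len=98)]) == []
        assert satellite.filter_regions([sat(1, 101, unit_len=98)])


class TestResolveOverlaps:
    def test_longer_region_wins(self):
        kept = satellite.resolve_overlaps(
            [sat(1, 500, class_id="c1"), sat(400, 700, class_id="c2")]
        )
        assert len(kept) == 1 and kept[0].class_id == "c1"

    def test_disjoint_all_kept(self):
        kept = satellite.resolve_overlaps(
            [sat(1, 200, class_id="c1"), sat(300, 500, class_id="c2")]
        )
        assert len(kept) == 2

    def test_equal_length_tiebreak_smaller_class(self):
        kept = satellite.resolve_overlaps(
            [
                sat(1, 400, class_id="c2"),
                sat(100, 499, class_id="c1"),
                sat(300, 499, class_id="c3"),
            ]
        )
        assert [k.class_id for k in kept] == ["c1"]

    def test_same_class_overlaps_allowed(self):
        kept = satellite.resolve_overlaps(
            [sat(1, 400, class_id="c1"), sat(300, 600, class_id="c1")]
        )
        assert len(kept) == 2

    def test_output_nonoverlapping_across_classes(self):
        rng = np.random.default_rng(9)
        regions = [
            sat(int(s), int(s + rng.integers(50, 400)), class_id=f"c{rng.integers(1, 5)}")
            for s in rng.integers(1, 3000, 40)
        ]
        kept = satellite.resolve_overlaps(regions)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                if a.class_id != b.class_id:
                    assert not a.region.overlaps(b.region)

    def test_missing_class_rejected(self):
        with pytest.raises(ValidationError):
            satellite.resolve_overlaps([sat(1, 100)])


class TestGroupClasses:
    def test_no_hits_all_singletons(self):
        classes = satellite.group_classes(list("ABCDE"), [])
        assert len(set(classes.values())) == 5

    def test_transitive_closure(self):
        classes = satellite.group_classes(list("ABCD"), [("A", "B"), ("B", "C")])
        assert classes["A"] == classes["B"] == classes["C"]
        assert classes["D"] != classes["A"]

    def test_67_units_45_components(self):
        """67 units wired into 45 connected components yield 45 classes."""
        rng = np.random.default_rng(5)
        units = [f"u{i}" for i in range(67)]
        # components: 22 pairs (44 units) + 23 singletons = 45 components
        hits = [(units[2 * i], units[2 * i + 1]) for i in range(22)]
        classes = satellite.group_classes(units, hits)
        assert len(set(classes.values())) == 45

    def test_matches_bruteforce_transitive_closure(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(2, 100))
            units = [f"u{i}" for i in range(n)]
            m = int(rng.integers(0, n))
            hits = [
                (units[int(rng.integers(n))], units[int(rng.integers(n))])
                for _ in range(m)
            ]
            classes = satellite.group_classes(units, hits)
            # oracle: repeated relaxation over an adjacency matrix
            adj = np.eye(n, dtype=np.int64)
            idx = {u: i for i, u in enumerate(units)}
            for a, b in hits:
                adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = 1
            prev = np.zeros_like(adj)
            while not np.array_equal(prev, adj):
                prev = adj.copy()
                adj = ((adj @ adj) > 0).astype(np.int64)
            for a in units:
                for b in units:
                    assert (classes[a] == classes[b]) == bool(adj[idx[a], idx[b]])

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValidationError):
            satellite.group_classes(["A"], [("A", "Z")])


class TestPipeline:
    def make_inputs(self):
        alns = [
            aln("u1", 100, 2000),
            aln("u1", 2005, 4000),  # gap 4 -> merges
            aln("u2", 3900, 4300, unit_len=398),
            aln("u3", 10_000, 10_050, unit_len=2190),  # too short after filter
        ]
        classes = {"u1": "class-1", "u2": "class-2", "u3": "class-3"}
        return alns, classes

    def test_idempotence(self):
        """Re-running merge -> filter -> resolve on its own output is a no-op."""
        alns, classes = self.make_inputs()
        first = satellite.satellite_pipeline(alns, classes)
        again = satellite.resolve_overlaps(
            satellite.filter_regions(first)
        )
        assert again == first

    def test_retained_bp_never_exceeds_merged(self):
        alns, classes = self.make_inputs()
        merged = satellite.merge_alignments(alns)
        final = satellite.satellite_pipeline(alns, classes)
        assert sum(r.length for r in final) <= sum(r.length for r in merged)

    def test_fixture_round_trip(self, fixture_dir, small_truth):
        """Fragmented fixture alignments reassemble into the truth arrays."""
        from t2tcurate import seqio

        outdir, _ = fixture_dir
        alns = seqio.read_paf(outdir / "satellites.paf")
        units = sorted({a.query for a in alns})
        classes = satellite.group_classes(units, [])
        regions = satellite.satellite_pipeline(alns, classes)
        truth_spans = {
            (r.scaffold, r.start, r.end) for r in small_truth.satellites
        }
        got = {(r.region.scaffold, r.region.start, r.region.end) for r in regions}
        assert got == truth_spans
        for r in regions:
            assert r.copies == r.length // r.unit_len
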