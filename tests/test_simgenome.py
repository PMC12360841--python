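"""Synthetic diploid genome generator: determinism, truth consistency, noise models."""

import dataclasses
import json

import numpy as np
import pytest

from t2tcurate import kmerstats as km
from t2tcurate import simgenome as sg
from t2tcurate.errors import ValidationError


def tiny_config(**kw):
    base = dict(
        seed=5,
        n_macro=1,
        n_micro=1,
        macro_len_range=(400_000, 500_000),
        micro_len_range=(200_000, 250_000),
        satellite_specs=[],
        sex_pair=False,
        het_rate=0.002,
        het_dip_width=100_000,
    )
    base.update(kw)
    return sg.SimConfig(**base)


class TestDeterminism:
    def test_same_config_same_bytes(self):
        a = sg.generate_genome(tiny_config())
        b = sg.generate_genome(tiny_config())
        assert {n: r.seq for n, r in a[0].items()} == {n: r.seq for n, r in b[0].items()}
        assert {n: r.seq for n, r in a[1].items()} == {n: r.seq for n, r in b[1].items()}

    def test_different_seed_differs(self):
        a = sg.generate_genome(tiny_config(seed=5))
        b = sg.generate_genome(tiny_config(seed=6))
        assert a[0]["macro1"].seq != b[0]["macro1"].seq

    def test_manifest_stable_under_fixed_seed(self, tmp_path):
        m1 = sg.write_fixtures(tmp_path / "a", tiny_config())
        m2 = sg.write_fixtures(tmp_path / "b", tiny_config())
        assert m1 == m2


class TestTruthConsistency:
    def test_configured_telomere_length_gives_405_copies(self):
        """telomere_len 2,430 -> a truth tract of exactly 405 hexamers."""
        cfg = tiny_config(telomere_len_range=(2_430, 2_430))
        hap1, _, truth = sg.generate_genome(cfg)
        for r in truth.telomeres:
            assert r.length == 2_430
            seq = hap1[r.scaffold].seq[r.start - 1 : r.end]
            motif = "CCCTAA" if r.start == 1 else "TTAGGG"
            assert seq == motif * 405

    def test_truth_intervals_within_scaffolds(self, small_truth):
        for r in small_truth.telomeres + small_truth.satellites:
            assert 1 <= r.start <= r.end <= small_truth.scaffold_lengths[r.scaffold]

    def test_motif_content_of_truth_telomeres(self, small_genome):
        """Truth telomere slices are >= 90% canonical hexamer."""
        hap1, _, truth = small_genome
        for r in truth.telomeres:
            seq = hap1[r.scaffold].seq[r.start - 1 : r.end]
            hexamers = seq.count("TTAGGG") + seq.count("CCCTAA")
            assert hexamers * 6 >= 0.9 * r.length

    def test_forced_gap_runs(self):
        cfg = tiny_config(n_gap_runs=26, n_micro=0, macro_len_range=(2_000_000, 2_000_000))
        hap1, _, truth = sg.generate_genome(cfg)
        from t2tcurate import asmstats

        gaps = asmstats.find_gaps(hap1["macro1"])
        assert len(gaps) == 26
        assert all(g.length == 100 for g in gaps)
        assert len(truth.gaps_hap1) == 26

    def test_gaps_never_overlap_telomeres(self, small_truth):
        for g in small_truth.gaps_hap1 + small_truth.gaps_hap2:
            for t in small_truth.telomeres:
                assert not g.overlaps(t)

    def test_haplotypes_differ_exactly_at_het_sites(self):
        cfg = tiny_config()
        hap1, hap2, truth = sg.generate_genome(cfg)
        for name in truth.scaffold_lengths:
            a = np.frombuffer(hap1[name].seq.encode(), dtype=np.uint8)
            b = np.frombuffer(hap2[name].seq.encode(), dtype=np.uint8)
            diff = np.flatnonzero((a != b) & (a != ord("N")) & (b != ord("N"))) + 1
            assert np.array_equal(diff, truth.het_sites[name])

    def test_het_suppressed_near_centromere(self, small_truth):
        half = 1_000_000 // 2
        for name, pos in small_truth.centromeres.items():
            sites = small_truth.het_sites[name]
            assert not np.any((sites > pos - half) & (sites < pos + half))

    def test_satellite_outside_scaffold_rejected(self):
        cfg = tiny_config(
            satellite_specs=[sg.SatelliteSpec(98, 10_000, "macro1", 100_000)]
        )
        with pytest.raises(ValidationError, match="satellite_specs"):
            sg.generate_truth(cfg)

    def test_unknown_satellite_scaffold_rejected(self):
        cfg = tiny_config(satellite_specs=[sg.SatelliteSpec(98, 5, "nope", 1)])
        with pytest.raises(ValidationError, match="satellite_specs"):
            sg.generate_truth(cfg)


class TestDepthTrack:
    def test_autosome_mean_recovered(self):
        cfg = tiny_config(macro_len_range=(10_000_000, 10_000_000), n_micro=0, het_rate=0)
        truth = sg.generate_truth(cfg)
        track = sg.generate_depth_track(truth, 40.0, seed=1)
        assert len(track) >= 1_000
        assert track["value"].mean() == pytest.approx(40.0, rel=0.05)

    def test_sex_scaffold_half_depth(self, small_truth):
        track = sg.generate_depth_track(small_truth, 40.0, seed=2)
        auto = track[track["scaffold"].isin(small_truth.autosomes)]["value"].mean()
        zw = track[track["scaffold"].isin(["Z", "W"])]["value"].mean()
        assert zw / auto == pytest.approx(0.5, abs=0.05)

    def test_zero_depth_all_zero(self, small_truth):
        track = sg.generate_depth_track(small_truth, 0.0, seed=3)
        assert (track["value"] == 0).all()


class TestKmerHistogram:
    def test_no_heterozygosity_single_coverage_peak(self):
        hist = sg.generate_kmer_histogram(
            500_000, 40.0, 134, 17, het_rate=0.0, seed=4, error_frac=0.0
        )
        calls = km.detect_peaks(hist)
        assert calls.het_peak is None
        assert calls.hom_peak == pytest.approx(40 * 118 / 134, abs=1.5)

    def test_two_peaks_at_half_ratio(self):
        hist = sg.generate_kmer_histogram(1_000_000, 40.0, 134, 17, 0.0198, seed=4)
        calls = km.detect_peaks(hist)
        assert calls.het_peak / calls.hom_peak == pytest.approx(0.5, abs=0.1)

    def test_distinct_kmer_mass_near_genome_size(self):
        hist = sg.generate_kmer_histogram(
            1_000_000, 40.0, 134, 17, het_rate=0.0, seed=4, error_frac=0.0
        )
        assert sum(hist.counts.values()) == pytest.approx(1_000_000, rel=0.01)


class TestHicMatrix:
    def test_symmetry(self, small_truth):
        mat, _ = sg.generate_hic_matrix(small_truth, seed=5)
        assert np.array_equal(mat, mat.T)

    def test_null_flat_zscores(self):
        """No boost: per-scaffold z-scores show no multiplicity-adjusted
        outliers at ~500 bins (max of 500 standard normals ~ 3.0)."""
        from t2tcurate import centromere as cm

        cfg = sg.SimConfig(
            seed=0, n_macro=3, n_micro=2,
            macro_len_range=(6_000_000, 7_000_000),
            micro_len_range=(2_000_000, 3_000_000),
            sex_pair=False, satellite_specs=[], het_rate=0.0,
        )
        truth = sg.generate_truth(cfg)
        mat, bm = sg.generate_hic_matrix(truth, centro_boost=0.0, seed=0)
        assert len(bm) == 500
        z = cm.interchrom_zscores(mat, bm)
        assert np.abs(z["z"]).max() < 4.0
        assert np.quantile(np.abs(z["z"]), 0.99) < 3.0

    def test_boosted_bin_max_rowsum(self, small_truth):
        mat, bm = sg.generate_hic_matrix(small_truth, seed=6, centro_boost=8.0)
        scf = bm["scaffold"].to_numpy()
        for name, pos in small_truth.centromeres.items():
            idx = np.flatnonzero(scf == name)
            inter = mat[idx].sum(axis=1) - mat[np.ix_(idx, idx)].sum(axis=1)
            best_bin = bm.iloc[idx[np.argmax(inter)]]
            assert best_bin["start"] <= pos <= best_bin["end"]


class TestFixtures:
    def test_round_trip_files(self, fixture_dir, small_truth, small_genome):
        from t2tcurate import seqio

        outdir, manifest = fixture_dir
        hap1, _, _ = small_genome
        back = seqio.read_fasta(outdir / "hap1.fa")
        assert {n: r.seq for n, r in back.items()} == {n: r.seq for n, r in hap1.items()}
        trf = seqio.read_trf_dat(outdir / "telomeres.dat")
        assert len(trf) == len(small_truth.telomeres)
        binmap = seqio.read_binmap(outdir / "hic_bins.tsv")
        mat = seqio.read_coo_matrix(outdir / "hic_matrix.tsv", binmap)
        assert np.array_equal(mat, mat.T)
        assert set(manifest) >= {
            "hap1.fa", "hap2.fa", "telomeres.dat", "depth.tsv", "het.tsv",
            "satellites.paf", "hic_matrix.tsv", "hic_bins.tsv",
            "kmer_hist.tsv", "truth.json",
        }

    def test_truth_json_schema(self, fixture_dir):
        outdir, _ = fixture_dir
        truth = json.loads((outdir / "truth.json").read_text())
        required = {
            "scaffold_lengths", "telomeres", "satellites", "satellite_units",
            "centromeres", "sex_scaffolds", "genome_size", "n_het_sites",
            "gaps_hap1", "gaps_hap2",
        }
        assert required <= set(truth)
        for scaffold, start, end in truth["telomeres"]:
            assert 1 <= start <= end <= truth["scaffold_lengths"][scaffold]

    def test_config_validation_names_field(self):
        with pytest.raises(ValidationError, match="gc_macro"):
            sg.SimConfig(gc_macro=1.5).validate()
        with pytest.raises(ValidationError, match="macro_len_range"):
            sg.SimConfig(macro_len_range=(0, 10)).validate()
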