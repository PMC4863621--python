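import json

import numpy as np
import pytest

from magverify.coverage import detect_anomalous_regions, read_depth_bedgraph
from magverify.kmer import profile_sequence
from magverify.seqio import compute_gc, read_fasta
from magverify.simulate import (
    CommunityConfig,
    GenomeModel,
    fragment_genome,
    make_benchmark,
    plant_chimera,
    plant_misbinned,
    simulate_community,
    simulate_depth_tracks,
    simulate_genome,
)
from magverify.synteny import read_features


class TestSimulateGenome:
    def test_gc_within_band(self):
        seq = simulate_genome(GenomeModel("g", 100_000, gc_target=0.50, seed=1))
        assert abs(compute_gc(seq) - 0.50) <= 0.02

    def test_same_seed_identical(self):
        m = GenomeModel("g", 20_000, gc_target=0.45, seed=7)
        assert simulate_genome(m) == simulate_genome(m)

    def test_distinct_biases_separate_profiles(self):
        # inter-genome tetranucleotide distance must exceed intra-genome
        # window-to-window distance, else no downstream test has power
        a = simulate_genome(GenomeModel("a", 100_000, gc_target=0.45, seed=1))
        b = simulate_genome(GenomeModel("b", 100_000, gc_target=0.55, seed=2))

        def windows(seq):
            return [
                profile_sequence(seq[i : i + 10_000], 4).freqs
                for i in range(0, len(seq) - 10_000, 10_000)
            ]

        wa, wb = windows(a), windows(b)
        intra = np.mean(
            [np.abs(x - y).sum() for i, x in enumerate(wa) for y in wa[i + 1 :]]
        )
        inter = np.mean([np.abs(x - y).sum() for x in wa for y in wb])
        assert inter > intra

    def test_short_genome_errors(self):
        with pytest.raises(ValueError):
            simulate_genome(GenomeModel("g", 5_000, gc_target=0.5, seed=1))


class TestFragmentGenome:
    def test_tiles_genome_exactly(self):
        rng = np.random.default_rng(2)
        seq = "ACGT" * 50_000
        pieces = fragment_genome(seq, rng)
        assert "".join(pieces) == seq
        assert all(len(p) >= 5_000 for p in pieces)

    def test_length_distribution_median(self):
        rng = np.random.default_rng(3)
        draws = [
            len(p)
            for _ in range(20)
            for p in fragment_genome("A" * 1_000_000, rng)
        ]
        assert abs(np.median(draws) - 40_000) / 40_000 <= 0.25


class TestPlanting:
    def test_plant_misbinned_zero_is_identity(self, small_community):
        bins = {b: list(rs) for b, rs in small_community.bins.items()}
        before = {b: [r.scaffold_id for r in rs] for b, rs in bins.items()}
        plant_misbinned(bins, small_community.truth, 0, np.random.default_rng(0))
        assert before == {b: [r.scaffold_id for r in rs] for b, rs in bins.items()}

    def test_moved_scaffold_in_wrong_bin_and_truth(self, small_community):
        c = small_community
        assert len(c.truth.planted_misbinned) == 2
        for sid, wrong_bin, true_genome in c.truth.planted_misbinned:
            assert any(r.scaffold_id == sid for r in c.bins[wrong_bin])
            assert c.truth.scaffold_genome[sid] == true_genome
            assert wrong_bin != f"bin_{true_genome}"

    def test_chimera_breakpoint_and_profile_betweenness(self):
        a = simulate_genome(GenomeModel("a", 30_000, gc_target=0.40, seed=1))
        b = simulate_genome(GenomeModel("b", 30_000, gc_target=0.60, seed=2))
        chimera, bp = plant_chimera(a[:15_000], b[:15_000])
        assert bp == 15_000
        pa = profile_sequence(a, 4).freqs
        pb = profile_sequence(b, 4).freqs
        pc = profile_sequence(chimera, 4).freqs
        d_ab = np.abs(pa - pb).sum()
        assert np.abs(pc - pa).sum() < d_ab
        assert np.abs(pc - pb).sum() < d_ab

    def test_chimera_segment_minimum(self):
        with pytest.raises(ValueError):
            plant_chimera("A" * 5_000, "C" * 20_000)


class TestDepthTracks:
    def test_mean_depth_near_expectation(self, small_community, small_tracks):
        c = small_community
        for t in small_tracks[:10]:
            gid = c.truth.scaffold_genome[t.scaffold_id]
            expected = 30.0 * c.abundance.loc[gid, t.sample_id]
            if any(t.scaffold_id == s for s, *_ in c.truth.coverage_anomalies):
                continue
            assert abs(t.depth.mean() - expected) / expected <= 0.10

    def test_same_genome_scaffolds_correlate(self, small_community, small_tracks):
        c = small_community
        recs = [
            r
            for r in c.bins["bin_g2"]
            if c.truth.scaffold_genome[r.scaffold_id] == "g2"
        ][:2]
        profiles = []
        for rec in recs:
            means = [
                np.log2(t.depth.mean() + 1)
                for t in small_tracks
                if t.scaffold_id == rec.scaffold_id
            ]
            profiles.append(means)
        corr = np.corrcoef(profiles[0], profiles[1])[0, 1]
        assert corr > 0.95

    def test_zero_abundance_genome_zero_tracks(self, small_config):
        c = simulate_community(small_config, seed=5)
        c.abundance.loc["g3"] = 0.0
        tracks = simulate_depth_tracks(c, seed=5)
        g3 = [
            t
            for t in tracks
            if c.truth.scaffold_genome[t.scaffold_id] == "g3"
            and not t.scaffold_id.startswith("chimera")
        ]
        assert g3 and all(t.depth.sum() == 0 for t in g3)

    def test_planted_anomaly_detected(self, small_community, small_tracks):
        sid, start, end, mult = small_community.truth.coverage_anomalies[0]
        hits = 0
        for t in small_tracks:
            if t.scaffold_id != sid:
                continue
            regions = detect_anomalous_regions(t)
            if any(r.start_bp < end and start < r.end_bp for r in regions):
                hits += 1
        assert hits >= 1


class TestMakeBenchmark:
    CFG = CommunityConfig(
        n_genomes=2,
        genome_length_bp=120_000,
        n_misbinned=0,
        n_chimeras=0,
        annotations="comammox",
        scaffold_median_bp=50_000,
    )

    def test_files_roundtrip_and_manifest(self, tmp_path):
        out = tmp_path / "bench"
        community = make_benchmark(out, self.CFG, seed=1)
        manifest = json.loads((out / "truth.json").read_text())
        assert manifest["seed"] == 1
        fasta_records = {
            r.scaffold_id
            for b in community.bins
            for r in read_fasta(out / f"{b}.fasta")
        }
        assert fasta_records == set(manifest["scaffold_genome"])
        lengths = community.scaffold_lengths()
        tracks = read_depth_bedgraph(out / "depth_sample_1.bedGraph", lengths, "s1")
        assert set(tracks) == set(lengths)
        feats = read_features(out / "annotations.gff3")
        assert len(feats) == manifest["n_annotations"]

    def test_refuses_nonempty_dir(self, tmp_path):
        out = tmp_path / "bench"
        out.mkdir()
        (out / "x.txt").write_text("occupied")
        with pytest.raises(FileExistsError):
            make_benchmark(out, self.CFG, seed=1)

    def test_same_seed_byte_identical(self, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        make_benchmark(a, self.CFG, seed=3)
        make_benchmark(b, self.CFG, seed=3)
        for name in ("bin_g1.fasta", "bins.tsv", "truth.json"):
            assert (a / name).read_bytes() == (b / name).read_bytes()
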