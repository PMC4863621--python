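from itertools import combinations

import numpy as np
import pytest

from magverify.simulate import _aob_like_features, _comammox_features
from magverify.synteny import (
    ACCESSORY_CLUSTER,
    AMO_CLUSTER,
    GeneFeature,
    GenePattern,
    JoinCandidate,
    find_join_candidates,
    match_pattern,
    read_features,
    screen_comammox,
)

LABELS = ["amoA", "hao", "bfr", "copC", "ccmA"]


def make_features(labels, gaps=None, strands=None, scaffold="s1", gene_len=500):
    gaps = gaps or [100] * len(labels)
    strands = strands or ["+"] * len(labels)
    feats, pos = [], 0
    for lab, gap, strand in zip(labels, gaps, strands):
        feats.append(GeneFeature(scaffold, pos, pos + gene_len, strand, lab))
        pos += gene_len + gap
    return feats


def oracle_has_match(features, pattern):
    """Independent brute force: enumerate every increasing index tuple of the
    required size and check label slots, gap limits, and orientation."""
    feats = sorted(features, key=lambda f: f.start_bp)
    slot_labels = []
    for labels, lo, _hi in pattern.elements:
        slot_labels += [labels] * lo
    m, n = len(slot_labels), len(feats)

    def ok(idxs, elements):
        for slot, j in zip(elements, idxs):
            if feats[j].label not in slot:
                return False
        for a, b in zip(idxs, idxs[1:]):
            if b - a - 1 > pattern.max_intervening_genes:
                return False
            if feats[b].start_bp - feats[a].end_bp > pattern.max_gap_bp:
                return False
            if (
                pattern.orientation_mode == "co-oriented"
                and feats[a].strand != feats[b].strand
            ):
                return False
        return True

    for idxs in combinations(range(n), m):
        if ok(idxs, slot_labels) or ok(idxs, slot_labels[::-1]):
            return True
    return False


class TestReadFeatures:
    def test_gff3_coordinate_conversion(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text(
            "##gff-version 3\ns1\tx\tgene\t101\t200\t.\t+\t.\tID=f1;gene=amoA\n"
        )
        (f,) = read_features(p)
        assert (f.start_bp, f.end_bp, f.label) == (100, 200, "amoA")

    def test_product_keyword_fallback(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text(
            "s1\tx\tgene\t1\t900\t.\t+\t.\t"
            "ID=f1;product=hydroxylamine dehydrogenase\n"
        )
        (f,) = read_features(p)
        assert f.label == "hao"

    def test_unknown_label_preserved(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text("s1\tx\tgene\t1\t90\t.\t-\t.\tgene=mysteryX\n")
        (f,) = read_features(p)
        assert f.label == "other:mysteryX"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text("##gff-version 3\n")
        assert read_features(p) == []

    def test_tsv_roundtrip_with_partial(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text(
            "scaffold_id\tstart_bp\tend_bp\tstrand\tlabel\tpartial\n"
            "s1\t0\t350\t+\tamoC\t5p\n"
        )
        (f,) = read_features(p)
        assert f.partial_5p and not f.partial_3p


class TestMatchPattern:
    def test_accessory_cluster_example(self):
        feats = make_features(["bfr", "bfr", "amoD", "amoD", "amoE", "copC", "copD"])
        matches = match_pattern(feats, ACCESSORY_CLUSTER)
        assert len(matches) == 1
        assert [f.label for f in matches[0].matched_features] == [
            "bfr", "bfr", "amoD", "amoD", "amoE", "copC", "copD",
        ]
        assert not matches[0].reversed_order

    def test_reversed_layout_matches_with_flag(self):
        feats = make_features(["copD", "copC", "amoE", "amoD", "amoD", "bfr", "bfr"])
        matches = match_pattern(feats, ACCESSORY_CLUSTER)
        assert len(matches) == 1 and matches[0].reversed_order

    def test_empty_features_no_match(self):
        assert match_pattern([], AMO_CLUSTER) == []

    def test_gap_bp_limit_blocks_match(self):
        feats = make_features(["amoC", "amoA", "amoB"], gaps=[20_000, 100, 100])
        assert match_pattern(feats, AMO_CLUSTER) == []

    def test_intervening_gene_limit(self):
        pattern = GenePattern(
            "p",
            [(frozenset({"amoA"}), 1, 1), (frozenset({"hao"}), 1, 1)],
            max_intervening_genes=1,
        )
        ok = make_features(["amoA", "bfr", "hao"])
        blocked = make_features(["amoA", "bfr", "bfr", "hao"])
        assert match_pattern(ok, pattern)
        assert match_pattern(blocked, pattern) == []

    def test_translation_invariance(self):
        feats = make_features(["bfr", "bfr", "amoD", "amoD", "amoE", "copC", "copD"])
        shifted = [
            GeneFeature(f.scaffold_id, f.start_bp + 12345, f.end_bp + 12345, f.strand, f.label)
            for f in feats
        ]
        a = match_pattern(feats, ACCESSORY_CLUSTER)
        b = match_pattern(shifted, ACCESSORY_CLUSTER)
        assert len(a) == len(b) == 1
        assert b[0].span_start_bp - a[0].span_start_bp == 12345

    @pytest.mark.parametrize(
        "pattern",
        [
            GenePattern(
                "two",
                [(frozenset({"amoA"}), 1, 1), (frozenset({"hao"}), 1, 1)],
                max_intervening_genes=1,
                max_gap_bp=5_000,
            ),
            GenePattern(
                "mult",
                [(frozenset({"bfr"}), 2, 2), (frozenset({"copC"}), 1, 1)],
                max_intervening_genes=2,
                max_gap_bp=5_000,
            ),
        ],
        ids=["pair", "multiplicity"],
    )
    def test_oracle_equivalence_random_lists(self, pattern):
        rng = np.random.default_rng(1)
        agree = 0
        for _ in range(150):
            n = int(rng.integers(2, 10))
            labels = [LABELS[i] for i in rng.integers(0, 5, size=n)]
            gaps = [int(g) for g in rng.choice([100, 900, 7_000], size=n)]
            feats = make_features(labels, gaps=gaps)
            assert bool(match_pattern(feats, pattern)) == oracle_has_match(
                feats, pattern
            )
            agree += 1
        assert agree == 150


class TestScreenComammox:
    def test_comammox_tier_full(self):
        feats = _comammox_features("scafA", 40_000, "scafB", 15_000)
        report = screen_comammox(feats)
        assert report.tier == "full"
        assert sorted(report.patterns_present) == [
            "P1_amoCAB", "P2_ccm_hao", "P3_bfr_amoDE_copCD",
        ]

    def test_amo_only_tier_partial(self):
        feats = make_features(["amoC", "amoA", "amoB"])
        report = screen_comammox(feats)
        assert report.tier == "partial"
        assert report.pattern_matches["P2_ccm_hao"] == []
        assert report.pattern_matches["P3_bfr_amoDE_copCD"] == []

    def test_aob_like_lacks_ccm_before_hao(self):
        feats = _aob_like_features("sc1", 40_000)
        report = screen_comammox(feats)
        assert report.pattern_matches["P2_ccm_hao"] == []
        assert report.pattern_matches["P1_amoCAB"]

    def test_no_recognized_labels_absent(self):
        feats = make_features(["other:a", "other:b", "other:c"])
        assert screen_comammox(feats).tier == "absent"


class TestJoinCandidates:
    def test_comammox_pair_yields_one_amoc_join(self):
        feats = _comammox_features("scafA", 40_000, "scafB", 15_000)
        joins = find_join_candidates(feats, {"scafA": 40_000, "scafB": 15_000})
        assert len(joins) == 1
        j = joins[0]
        assert (j.scaffold_a, j.scaffold_b, j.label) == ("scafA", "scafB", "amoC")
        assert j.strand_compatible

    def test_label_mismatch_no_join(self):
        feats = [
            GeneFeature("A", 39_700, 40_000, "+", "amoC", partial_3p=True),
            GeneFeature("B", 0, 300, "+", "amoB", partial_5p=True),
        ]
        assert find_join_candidates(feats, {"A": 40_000, "B": 20_000}) == []

    def test_interior_partials_excluded(self):
        feats = [
            GeneFeature("A", 20_000, 20_300, "+", "amoC", partial_3p=True),
            GeneFeature("B", 5_000, 5_300, "+", "amoC", partial_5p=True),
        ]
        assert find_join_candidates(feats, {"A": 40_000, "B": 20_000}) == []
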