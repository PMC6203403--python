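"""Genotype encoding, filtering, IBS and homogeneous-line removal."""

import numpy as np
import pandas as pd
import pytest

from varsync.core_io import ReferenceGenome, SampleVariantSet, VariantCall
from varsync.encoder import (
    MISSING,
    PRESETS,
    GenotypeMatrix,
    encode_indels,
    encode_orfs,
    encode_snps,
    filter_markers,
    ibs_matrix,
    ld_prune,
    remove_homogeneous,
)
from varsync.synchronizer import SyncResult


def make_sync(samples, calls_by_sample, markers, genotypes):
    varsets = {}
    for s in samples:
        vs = SampleVariantSet(s)
        for c in calls_by_sample.get(s, []):
            vs.add(c)
        varsets[s] = vs
    return SyncResult(samples, varsets, markers, np.asarray(genotypes, np.int8),
                      pd.DataFrame())


def marker_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "kind", "length", "ref", "alt"])


class TestEncodeSnps:
    def test_biallelic_site_coded_against_reference(self):
        markers = marker_frame([("c", 10, "snp", 1, "A", "G")])
        sync = make_sync(["a", "b"], {}, markers, [[1], [0]])
        gm = encode_snps(sync)
        assert gm.values.tolist() == [[1], [0]]

    def test_multiallelic_snp_site_dropped(self):
        markers = marker_frame(
            [("c", 10, "snp", 1, "A", "G"), ("c", 10, "snp", 1, "A", "T"),
             ("c", 20, "snp", 1, "C", "T")]
        )
        sync = make_sync(["a", "b"], {}, markers, [[1, 0, 1], [0, 1, 0]])
        gm = encode_snps(sync)
        assert list(gm.markers.pos) == [20]

    def test_low_support_and_het_become_missing(self):
        markers = marker_frame([("c", 10, "snp", 1, "A", "G")])
        sync = make_sync(["a", "b"], {}, markers, [[1], [1]])
        inputs = [
            SampleVariantSet("a"), SampleVariantSet("b"),
        ]
        inputs[0].add(VariantCall("c", 10, "A", "G", "a", support=1))
        inputs[1].add(VariantCall("c", 10, "A", "G", "b", support=5, het=True))
        gm = encode_snps(sync, input_varsets=inputs)
        assert gm.values.tolist() == [[MISSING], [MISSING]]

    def test_deletion_overlap_masks_snp(self):
        markers = marker_frame([("c", 10, "snp", 1, "A", "G")])
        dels = {"b": [VariantCall("c", 8, "TTAAT", "", "b")]}
        sync = make_sync(["a", "b"], dels, markers, [[1], [0]])
        gm = encode_snps(sync)
        assert gm.values.tolist() == [[1], [MISSING]]


class TestEncodeIndels:
    def test_same_position_same_length_is_one_marker(self):
        markers = marker_frame([("c", 100, "del", 2, "AT", "")])
        calls = {
            "a": [VariantCall("c", 100, "AT", "", "a")],
            "b": [VariantCall("c", 100, "AT", "", "b")],
        }
        sync = make_sync(["a", "b"], calls, markers, [[1], [1]])
        gm = encode_indels(sync)
        assert gm.n_markers == 1 and gm.values.tolist() == [[1], [1]]

    def test_partial_overlap_by_different_indel_is_missing(self):
        markers = marker_frame(
            [("c", 99, "del", 4, "GATC", ""), ("c", 100, "del", 2, "AT", "")]
        )
        calls = {
            "a": [VariantCall("c", 100, "AT", "", "a")],
            "b": [VariantCall("c", 100, "AT", "", "b")],
            "d": [VariantCall("c", 99, "GATC", "", "d")],
        }
        sync = make_sync(["a", "b", "d"], calls, markers,
                         [[0, 1], [0, 1], [1, 0]])
        gm = encode_indels(sync)
        col = list(gm.markers.pos).index(100)
        other = list(gm.markers.pos).index(99)
        assert gm.values[2, col] == MISSING  # d's deletion covers the marker
        assert gm.values[0, other] == MISSING and gm.values[1, other] == MISSING
        assert gm.values[0, col] == 1 and gm.values[1, col] == 1

    def test_reference_haplotype_codes_zero(self):
        markers = marker_frame([("c", 100, "del", 2, "AT", "")])
        calls = {"a": [VariantCall("c", 100, "AT", "", "a")]}
        sync = make_sync(["a", "b"], calls, markers, [[1], [0]])
        gm = encode_indels(sync)
        assert gm.values[1, 0] == 0

    def test_insertion_anchor_rules(self):
        markers = marker_frame(
            [("c", 50, "ins", 3, "", "AAA"), ("c", 50, "ins", 5, "", "CCCCC")]
        )
        calls = {
            "a": [VariantCall("c", 50, "", "AAA", "a")],
            "b": [VariantCall("c", 50, "", "CCCCC", "b")],
        }
        sync = make_sync(["a", "b"], calls, markers, [[1, 0], [0, 1]])
        gm = encode_indels(sync)
        # each sample is missing at the other's same-anchor different-length marker
        a_row = dict(zip(zip(gm.markers.pos, gm.markers.length), gm.values[0]))
        b_row = dict(zip(zip(gm.markers.pos, gm.markers.length), gm.values[1]))
        assert a_row[(50, 3)] == 1 and a_row[(50, 5)] == MISSING
        assert b_row[(50, 5)] == 1 and b_row[(50, 3)] == MISSING


class TestFilterMarkers:
    def _random_gm(self, rng, n=40, L=1000):
        vals = rng.integers(0, 2, size=(n, L)).astype(np.int8)
        miss = rng.random((n, L)) < rng.uniform(0, 0.6, L)
        vals[miss] = MISSING
        markers = pd.DataFrame(
            {"chrom": "c", "pos": np.arange(L) * 10, "kind": "snp",
             "length": 1, "allele": "A"}
        )
        return GenotypeMatrix([f"s{i}" for i in range(n)], markers, vals)

    @pytest.mark.parametrize("preset", ["athaliana", "dmelanogaster"])
    def test_matches_brute_force_oracle(self, preset):
        rng = np.random.default_rng(5)
        gm = self._random_gm(rng)
        p = PRESETS[preset]
        kept = filter_markers(gm, **p)
        survivors = set(kept.markers.pos)
        for j in range(gm.n_markers):
            col = gm.values[:, j]
            called = col[col != MISSING]
            n1 = int((called == 1).sum())
            n0 = int((called == 0).sum())
            freq = n1 / len(called) if len(called) else 0.0
            maf = min(freq, 1 - freq)
            miss = 1 - len(called) / len(col)
            mac = min(n0, n1)
            expect = (maf >= p["maf_min"]) and (miss <= p["miss_max"]) and (mac >= p["mac_min"])
            assert (gm.markers.pos[j] in survivors) == expect

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        gm = self._random_gm(rng, L=300)
        once = filter_markers(gm)
        twice = filter_markers(once)
        assert once.markers.equals(twice.markers)
        assert (once.values == twice.values).all()

    def test_region_exclusion(self):
        rng = np.random.default_rng(7)
        gm = self._random_gm(rng, L=100)
        kept = filter_markers(gm, maf_min=0, miss_max=1, mac_min=0,
                              exclude=[("c", 0, 500)])
        assert (kept.markers.pos >= 500).all()


class TestIbs:
    def test_identical_samples_score_one(self):
        vals = np.tile(np.array([0, 1, 1, 0, 1], np.int8), (2, 1))
        gm = GenotypeMatrix(["a", "b"], pd.DataFrame(
            {"chrom": "c", "pos": range(5), "kind": "snp", "length": 1, "allele": ""}), vals)
        ibs = ibs_matrix(gm)
        assert ibs.loc["a", "b"] == 1.0

    def test_half_different_scores_half(self):
        vals = np.array([[0, 0, 1, 1], [0, 1, 1, 0]], np.int8)
        gm = GenotypeMatrix(["a", "b"], pd.DataFrame(
            {"chrom": "c", "pos": range(4), "kind": "snp", "length": 1, "allele": ""}), vals)
        assert ibs_matrix(gm).loc["a", "b"] == 0.5

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(8)
        vals = rng.integers(0, 2, (5, 50)).astype(np.int8)
        vals[rng.random((5, 50)) < 0.2] = MISSING
        gm = GenotypeMatrix([f"s{i}" for i in range(5)], pd.DataFrame(
            {"chrom": "c", "pos": range(50), "kind": "snp", "length": 1, "allele": ""}), vals)
        ibs = ibs_matrix(gm)
        assert np.allclose(ibs.values, ibs.values.T)
        assert (np.diag(ibs.values) == 1).all()
        for i in range(5):
            for j in range(i + 1, 5):
                ok = (vals[i] != MISSING) & (vals[j] != MISSING)
                expect = (vals[i, ok] == vals[j, ok]).mean() if ok.any() else 0.0
                assert ibs.iloc[i, j] == pytest.approx(expect)


class TestLdPrune:
    def test_duplicate_column_dropped_keeping_earlier(self):
        rng = np.random.default_rng(9)
        col = rng.integers(0, 2, 30).astype(np.int8)
        other = rng.integers(0, 2, 30).astype(np.int8)
        vals = np.column_stack([col, col, other])
        gm = GenotypeMatrix([f"s{i}" for i in range(30)], pd.DataFrame(
            {"chrom": "c", "pos": [100, 600, 1200], "kind": "snp",
             "length": 1, "allele": ""}), vals)
        pruned = ld_prune(gm)
        assert list(pruned.markers.pos) == [100, 1200]


class TestRemoveHomogeneous:
    def _ibs(self, names, mat):
        return pd.DataFrame(mat, index=names, columns=names)

    def test_higher_quality_wins_in_pair(self):
        ibs = self._ibs(["a", "b"], [[1.0, 0.95], [0.95, 1.0]])
        assert remove_homogeneous(ibs, {"a": 14000, "b": 13000}) == ["a"]
        assert remove_homogeneous(ibs, {"a": 13000, "b": 14000}) == ["b"]

    def test_all_distinct_all_retained(self):
        ibs = self._ibs(["a", "b", "c"],
                        [[1, 0.5, 0.2], [0.5, 1, 0.3], [0.2, 0.3, 1]])
        assert remove_homogeneous(ibs, {}) == ["a", "b", "c"]

    def test_chain_component_keeps_single_sample(self):
        ibs = self._ibs(["a", "b", "c"],
                        [[1, 0.92, 0.85], [0.92, 1, 0.93], [0.85, 0.93, 1]])
        kept = remove_homogeneous(ibs, {"a": 3, "b": 2, "c": 1})
        assert kept == ["a"]

    def test_duplicate_id_removed_preferentially(self):
        ibs = self._ibs(["a", "b"], [[1.0, 0.95], [0.95, 1.0]])
        kept = remove_homogeneous(ibs, {"a": 14000, "b": 1},
                                  duplicate_flags={"a": True})
        assert kept == ["b"]


def test_encode_orfs_shapes_and_missing():
    m = pd.DataFrame([[0.0, 1.0], [np.nan, 0.0]], index=["g1", "g2"],
                     columns=["a", "b"])
    gm = encode_orfs(m)
    assert gm.samples == ["a", "b"]
    assert gm.values.tolist() == [[0, MISSING], [1, 0]]
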