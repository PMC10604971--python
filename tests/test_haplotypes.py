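import numpy as np
import pandas as pd
import pytest

from conftest import make_genotypes
from epiblup.grm_builders import center_additive, grm_first_order
from epiblup.haplotypes import (
    BlockDefinition,
    blocks_by_count,
    blocks_by_window,
    blocks_from_regions,
    enumerate_haplotypes,
    grm_haplotype,
)


def genotypes_with_positions(pos, chrom=None, n=4, seed=0):
    rng = np.random.default_rng(seed)
    m = len(pos)
    haps = rng.integers(0, 2, size=(n, m, 2)).astype(np.int8)
    return make_genotypes(haps, chrom=chrom or ["1"] * m, pos=pos)


class TestBlockSchemes:
    def test_by_count_partial_block_kept(self):
        gd = genotypes_with_positions(list(range(1000, 26000, 1000)))  # 25 SNPs
        bd = blocks_by_count(gd, 12)
        sizes = [e - s for _, s, e in bd.blocks]
        assert sizes == [12, 12, 1]

    def test_by_count_respects_chromosomes(self):
        pos = list(range(1000, 13000, 1000)) * 2
        chrom = ["1"] * 12 + ["2"] * 12
        gd = genotypes_with_positions(pos, chrom=chrom)
        bd = blocks_by_count(gd, 12)
        assert bd.n_blocks == 2
        assert all(gd.variants["chrom"][s:e].nunique() == 1
                   for _, s, e in bd.blocks)

    def test_by_count_is_partition(self, small_dataset):
        gd = small_dataset[0]
        bd = blocks_by_count(gd, 4)
        idx = bd.snp_indices()
        assert sorted(idx) == list(range(gd.n_variants))

    def test_by_window_boundary(self):
        # position 50 000 belongs to window 1; 60 000 starts window 2
        gd = genotypes_with_positions([10_000, 50_000, 60_000])
        bd = blocks_by_window(gd, 50_000)
        assert bd.n_blocks == 2
        assert [e - s for _, s, e in bd.blocks] == [2, 1]

    def test_by_window_single_block(self):
        gd = genotypes_with_positions([100, 20_000, 49_999])
        bd = blocks_by_window(gd, 50_000)
        assert bd.n_blocks == 1

    def test_by_window_formula(self, small_dataset):
        gd = small_dataset[0]
        width = 30_000
        bd = blocks_by_window(gd, width)
        pos = gd.variants["pos"].to_numpy()
        for chrom, s, e in bd.blocks:
            win = (pos[s:e] - 1) // width
            assert len(set(win)) == 1

    def test_regions(self):
        gd = genotypes_with_positions([1000, 2000, 3000, 9000, 20_000])
        bed = pd.DataFrame({"chrom": ["1"], "start": [500], "end": [3500]})
        bd = blocks_from_regions(gd, bed)
        assert bd.blocks == [("1", 0, 3)]

    def test_overlapping_regions_merged(self):
        gd = genotypes_with_positions([1000, 2000, 3000, 4000])
        bed = pd.DataFrame({"chrom": ["1", "1"],
                            "start": [500, 1500], "end": [2500, 4500]})
        bd = blocks_from_regions(gd, bed)
        assert bd.n_blocks == 1
        assert bd.blocks[0] == ("1", 0, 4)

    def test_region_assignment_matches_interval_scan(self, small_dataset):
        gd = small_dataset[0]
        pos = gd.variants["pos"].to_numpy()
        rng = np.random.default_rng(4)
        starts = np.sort(rng.choice(np.arange(0, pos.max(), 5000), 6,
                                    replace=False))
        bed = pd.DataFrame({"chrom": "1", "start": starts,
                            "end": starts + 12_000})
        try:
            bd = blocks_from_regions(gd, bed)
        except ValueError:
            pytest.skip("random regions caught < 2 SNPs")
        # brute-force interval scan over merged regions
        merged = []
        for s, e in zip(starts + 1, starts + 12_000):
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        expected = set()
        for lo, hi in merged:
            hits = [i for i, p in enumerate(pos) if lo <= p <= hi]
            if len(hits) >= 2:
                expected.update(hits)
        assert set(bd.snp_indices()) == expected


class TestEnumerate:
    def test_observed_alleles(self):
        haps = np.array([
            [[0, 0], [0, 1]],   # gametes 00, 01
            [[0, 1], [0, 1]],   # gametes 00->? rows are per-SNP: ind1 = (0,0)/(1,1)
            [[1, 1], [1, 1]],   # gametes 11, 11
        ], dtype=np.int8)
        gd = make_genotypes(haps)
        bd = BlockDefinition(blocks=[("1", 0, 2)], scheme="by_count", parameter=2)
        hat = enumerate_haplotypes(gd, bd)
        assert sorted(hat.alleles[0]) == ["00", "01", "11"]
        assert hat.counts.sum() == 6  # 2 per individual

    def test_double_heterozygote_counts(self):
        # individual carrying 01|01 has count 2 for allele "01"
        haps = np.array([
            [[0, 0], [1, 1]],
            [[0, 1], [1, 0]],
        ], dtype=np.int8)
        gd = make_genotypes(haps)
        bd = BlockDefinition(blocks=[("1", 0, 2)], scheme="by_count", parameter=2)
        hat = enumerate_haplotypes(gd, bd)
        j = hat.alleles[0].index("01")
        assert hat.counts[0, j] == 2

    def test_alleles_subset_of_founder_pool(self, small_dataset):
        from epiblup.haplotypes import blocks_by_count

        gd = small_dataset[0]
        bd = blocks_by_count(gd, 6)
        hat = enumerate_haplotypes(gd, bd)
        for labels, freq in zip(hat.alleles, hat.frequencies):
            assert freq.sum() == pytest.approx(1.0)
            assert len(labels) <= 2 * gd.n_samples

    def test_missing_raises(self):
        haps = np.array([[[0, 0], [0, -1]], [[0, 1], [1, 1]]], dtype=np.int8)
        gd = make_genotypes(haps)
        bd = BlockDefinition(blocks=[("1", 0, 2)], scheme="by_count", parameter=2)
        with pytest.raises(ValueError, match="missing genotypes inside block"):
            enumerate_haplotypes(gd, bd)

    def test_unphased_raises(self):
        haps = np.array([[[0, 0], [0, 1]], [[0, 1], [1, 1]]], dtype=np.int8)
        gd = make_genotypes(haps)
        gd.phased[1] = False
        bd = BlockDefinition(blocks=[("1", 0, 2)], scheme="by_count", parameter=2)
        with pytest.raises(ValueError, match="unphased"):
            enumerate_haplotypes(gd, bd)

    def test_rare_pooling(self, small_dataset):
        gd = small_dataset[0]
        bd = blocks_by_count(gd, 6)
        pooled = enumerate_haplotypes(gd, bd, min_freq=0.1)
        plain = enumerate_haplotypes(gd, bd)
        assert pooled.counts.shape[1] <= plain.counts.shape[1]
        # counts still sum to 2 per block (checked by the constructor)


class TestHaplotypeGRM:
    def test_single_snp_block_equals_additive(self, small_dataset):
        gd = small_dataset[0]
        bd = BlockDefinition(blocks=[("1", 0, 1)], scheme="by_region",
                             parameter=None)
        hat = enumerate_haplotypes(gd, bd)
        GH = grm_haplotype(hat).matrix
        gd1 = gd.subset_variants(np.array([0]))
        GA = grm_first_order(center_additive(gd1)).matrix
        iu = np.triu_indices(gd.n_samples, 1)
        assert np.corrcoef(GH[iu], GA[iu])[0, 1] == pytest.approx(1.0)

    def test_monomorphic_block_errors(self):
        haps = np.zeros((4, 2, 2), dtype=np.int8)
        gd = make_genotypes(haps)
        bd = BlockDefinition(blocks=[("1", 0, 2)], scheme="by_count", parameter=2)
        hat = enumerate_haplotypes(gd, bd)
        with pytest.raises(ValueError, match="not positive"):
            grm_haplotype(hat)

    def test_psd_unit_diag(self, small_dataset):
        gd = small_dataset[0]
        bd = blocks_by_count(gd, 6)
        G = grm_haplotype(enumerate_haplotypes(gd, bd)).matrix
        assert np.diag(G).mean() == pytest.approx(1.0, abs=1e-12)
        w = np.linalg.eigvalsh(G)
        assert w.min() >= -1e-8 * w.max()

    def test_invariant_to_allele_order(self, small_dataset):
        gd = small_dataset[0]
        bd = blocks_by_count(gd, 6)
        hat = enumerate_haplotypes(gd, bd)
        G1 = grm_haplotype(hat).matrix
        rng = np.random.default_rng(0)
        perm = rng.permutation(hat.counts.shape[1])
        hat2 = hat
        hat2.counts = hat.counts[:, perm]
        # block slices no longer align with columns, but the Gram matrix
        # over all columns is permutation invariant
        C = hat2.counts - hat2.counts.mean(axis=0, keepdims=True)
        raw = C @ C.T
        np.testing.assert_allclose(raw / np.diag(raw).mean(), G1, atol=1e-10)
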