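import numpy as np
import pytest

from conftest import make_genotypes
from epiblup.core_data import GRM, EffectType
from epiblup.grm_builders import (
    CodeMatrix,
    center_additive,
    center_dominance,
    grm_epistasis_bruteforce,
    grm_epistasis_exact,
    grm_epistasis_hadamard,
    grm_first_order,
    normalize_grm,
)
from epiblup.pipeline import effect_type_catalog

EPISTASIS_TYPES = [et for et in effect_type_catalog(4) if et.order >= 2]


def _eigmin_ok(M):
    w = np.linalg.eigvalsh(M)
    return w.min() >= -1e-8 * max(w.max(), 1.0)


class TestCodings:
    def test_additive_centering(self):
        gd = make_genotypes([[[0, 0]], [[0, 1]], [[1, 1]]])
        cm = center_additive(gd)
        np.testing.assert_allclose(cm.values[:, 0], [-1.0, 0.0, 1.0])

    def test_dominance_centering(self):
        gd = make_genotypes([[[0, 0]], [[0, 1]], [[1, 1]]])
        cm = center_dominance(gd)
        np.testing.assert_allclose(cm.values[:, 0], [-1 / 3, 2 / 3, -1 / 3])

    def test_monomorphic_column_is_zero(self):
        gd = make_genotypes([[[1, 1]], [[1, 1]], [[1, 1]]])
        assert np.all(center_additive(gd).values == 0)
        assert np.all(center_dominance(gd).values == 0)

    def test_columns_centered(self, small_dataset):
        gd = small_dataset[0]
        for cm in (center_additive(gd), center_dominance(gd)):
            assert np.abs(cm.values.sum(axis=0)).max() < 1e-9

    def test_het_mean_approaches_2pq_under_hwe(self):
        from epiblup.synthetic_data import ArchitectureConfig, simulate_genotypes

        cfg = ArchitectureConfig(n=2000, n_blocks=10, snps_per_block=6,
                                 variance_fractions={}, seed=3)
        gd = simulate_genotypes(cfg)
        het = (gd.dosage == 1).mean(axis=0)
        p = gd.alt_freq
        np.testing.assert_allclose(het, 2 * p * (1 - p), atol=0.05)


class TestFirstOrder:
    def test_identical_genotypes_identical_rows(self):
        gd = make_genotypes([[[0, 1], [1, 1]], [[0, 1], [1, 1]], [[0, 0], [0, 1]]])
        G = grm_first_order(center_additive(gd)).matrix
        np.testing.assert_allclose(G[0], G[1])

    def test_hand_example(self):
        gd = make_genotypes([[[0, 0], [0, 1]], [[0, 1], [1, 1]], [[1, 1], [0, 0]]])
        W = center_additive(gd).values
        G = grm_first_order(center_additive(gd))
        raw = np.array([[W[i] @ W[j] for j in range(3)] for i in range(3)])
        np.testing.assert_allclose(G.matrix, raw / np.diag(raw).mean())
        assert G.normalizer == pytest.approx(np.diag(raw).mean())

    def test_psd_and_unit_diagonal(self, small_dataset):
        gd = small_dataset[0]
        G = grm_first_order(center_additive(gd)).matrix
        assert np.diag(G).mean() == pytest.approx(1.0, abs=1e-12)
        assert _eigmin_ok(G)

    def test_monomorphic_panel_errors(self):
        gd = make_genotypes([[[1, 1]], [[1, 1]], [[1, 1]]])
        with pytest.raises(ValueError, match="not positive"):
            grm_first_order(center_additive(gd))

    def test_vanraden_proportionality(self, small_dataset):
        gd = small_dataset[0]
        W = center_additive(gd).values
        p = gd.alt_freq
        vanraden = (W @ W.T) / (2 * np.sum(p * (1 - p)))
        ours = grm_first_order(center_additive(gd)).matrix
        iu = np.triu_indices(gd.n_samples, 1)
        r = np.corrcoef(vanraden[iu], ours[iu])[0, 1]
        assert r > 0.999


class TestNormalize:
    def test_identity_unchanged(self):
        g = GRM(label="A", matrix=np.eye(4), sample_ids=list("abcd"))
        out = normalize_grm(g)
        np.testing.assert_allclose(out.matrix, np.eye(4))
        assert out.normalizer == 1.0

    def test_scaled_identity(self):
        g = GRM(label="A", matrix=2 * np.eye(4), sample_ids=list("abcd"))
        out = normalize_grm(g)
        np.testing.assert_allclose(out.matrix, np.eye(4))
        assert out.normalizer == 2.0

    def test_zero_matrix_errors(self):
        g = GRM(label="AA", matrix=np.zeros((3, 3)), sample_ids=list("abc"))
        with pytest.raises(ValueError, match="not positive"):
            normalize_grm(g)


class TestHadamard:
    def test_ad_is_elementwise_product(self, random_codes):
        W, H = random_codes
        GA = grm_first_order(W)
        GD = grm_first_order(H)
        got = grm_epistasis_hadamard(EffectType(1, 1), GA, GD)
        expected = GA.matrix * GD.matrix
        np.testing.assert_allclose(got.matrix,
                                   expected / np.diag(expected).mean())

    def test_psd(self, random_codes):
        W, H = random_codes
        GA, GD = grm_first_order(W), grm_first_order(H)
        for et in EPISTASIS_TYPES:
            M = grm_epistasis_hadamard(et, GA, GD).matrix
            assert _eigmin_ok(M), et.label

    def test_order_guard(self, random_codes):
        W, H = random_codes
        GA, GD = grm_first_order(W), grm_first_order(H)
        with pytest.raises(ValueError, match="order 2-4"):
            grm_epistasis_hadamard(EffectType(1, 0), GA, GD)


class TestExactEpistasis:
    @pytest.mark.parametrize("et", EPISTASIS_TYPES, ids=lambda e: e.label)
    def test_matches_bruteforce(self, et, random_codes):
        W, H = random_codes
        exact = grm_epistasis_exact(et, W, H).matrix
        brute = grm_epistasis_bruteforce(et, W, H).matrix
        err = np.linalg.norm(exact - brute) / np.linalg.norm(brute)
        assert err < 1e-10

    def test_single_locus_pair_is_zero(self):
        # with one locus no distinct pair exists: the exact AxA matrix is
        # zero while the Hadamard approximation is not
        rng = np.random.default_rng(0)
        v = rng.standard_normal(6)
        v -= v.mean()
        W = CodeMatrix("additive", v[:, None], ["v0"], [f"s{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="no distinct-locus tuple"):
            out = grm_epistasis_exact(EffectType(2, 0), W, None)
        assert np.all(out.matrix == 0)
        with pytest.raises(ValueError):
            normalize_grm(out)
        GA = grm_first_order(W)
        had = grm_epistasis_hadamard(EffectType(2, 0), GA, None)
        assert np.abs(had.matrix).max() > 0

    def test_intra_locus_removal_identity(self, random_codes):
        # raw exact AxA = 1/2 [ (WW')o(WW') - (WoW)(WoW)' ]
        W, _ = random_codes
        Wv = W.values
        G1 = Wv @ Wv.T
        W2 = Wv * Wv
        expected = 0.5 * (G1 * G1 - W2 @ W2.T)
        expected /= np.diag(expected).mean()
        got = grm_epistasis_exact(EffectType(2, 0), W, None).matrix
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_bruteforce_column_counts(self, random_codes):
        W, H = random_codes
        # AxD over m loci has m(m-1) role-assigned distinct pairs
        m = len(W.snp_ids)
        import itertools

        n_ad = sum(1 for sa in itertools.combinations(range(m), 1)
                   for sd in itertools.combinations(
                       [j for j in range(m) if j not in sa], 1))
        assert n_ad == m * (m - 1)

    def test_approx_converges_to_exact_with_many_loci(self):
        rng = np.random.default_rng(42)
        n = 40
        diffs = []
        for m in (10, 1000):
            dos = rng.binomial(2, 0.4, size=(n, m)).astype(float)
            Wv = dos - dos.mean(axis=0)
            W = CodeMatrix("additive", Wv, [f"v{j}" for j in range(m)],
                           [f"s{i}" for i in range(n)])
            GA = grm_first_order(W)
            had = grm_epistasis_hadamard(EffectType(2, 0), GA, None).matrix
            exact = grm_epistasis_exact(EffectType(2, 0), W, None).matrix
            diffs.append(np.linalg.norm(had - exact) / np.linalg.norm(exact))
        assert diffs[1] < diffs[0]

    def test_exact_psd_and_unit_diag(self, random_codes):
        W, H = random_codes
        for et in EPISTASIS_TYPES:
            M = grm_epistasis_exact(et, W, H).matrix
            assert np.diag(M).mean() == pytest.approx(1.0, abs=1e-12), et.label
            assert _eigmin_ok(M), et.label
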