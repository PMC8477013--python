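import math

import numpy as np
import pytest

from breedrisk import (
    GenotypeDataset,
    SimConfig,
    bootstrap_summary,
    hind,
    kinship_matrix,
    kinship_summaries,
    pair_coancestry,
    psa_matrix,
    self_coancestry,
    simulate,
)
from breedrisk.coancestry import pooled_pic_weights

from conftest import random_dataset
from oracles import naive_kinship_summaries, naive_pair_coancestry, naive_psa


def g(*pairs):
    return np.array(pairs)


class TestPairCoancestry:
    def test_identical_homozygotes(self):
        assert pair_coancestry(g((1, 1)), g((1, 1))) == 1.0

    def test_shared_heterozygote_and_disjoint(self):
        assert pair_coancestry(g((1, 2)), g((1, 2))) == 0.5
        assert pair_coancestry(g((1, 2)), g((3, 4))) == 0.0

    def test_no_shared_typed_locus_raises(self):
        with pytest.raises(ValueError, match="no locus"):
            pair_coancestry(g((1, 1), (0, 0)), g((0, 0), (2, 2)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matrix_equals_indicator_enumeration(self, seed):
        ds = random_dataset(seed, n_breeds=1, max_n=3, n_loci=2)
        km = kinship_matrix(ds, weights="uniform")
        genos = [[tuple(ds.calls[i, l]) for l in range(ds.n_loci)]
                 for i in range(ds.n_individuals)]
        for i in range(ds.n_individuals):
            for j in range(ds.n_individuals):
                assert km.values[i, j] == pytest.approx(
                    naive_pair_coancestry(genos[i], genos[j]),
                    abs=1e-12, nan_ok=True,
                )


class TestSelfCoancestry:
    def test_fully_homozygous(self):
        s, f = self_coancestry(g((1, 1), (2, 2)))
        assert s == 1.0 and f == 1.0

    def test_fully_heterozygous(self):
        s, f = self_coancestry(g((1, 2), (3, 4)))
        assert s == 0.5 and f == 0.0

    def test_relates_to_hind_algebraically(self):
        geno = g((1, 2), (3, 3), (4, 4), (5, 6))
        h = 2 / 4
        s, _ = self_coancestry(geno)
        assert s == pytest.approx(1 - h / 2, abs=1e-12)


class TestHind:
    def test_half_heterozygous(self):
        calls = np.zeros((2, 14, 2), dtype=int)
        calls[:, :, 0] = 1
        calls[:, :, 1] = 1
        calls[0, :7, 1] = 2  # 7 of 14 loci heterozygous
        ds = GenotypeDataset(["x", "y"], ["A", "A"], [f"L{i}" for i in range(14)], calls)
        hs = hind(ds)
        assert hs.per_individual.loc[0, "Hind"] == 0.5

    def test_identical_individuals_have_zero_spread(self):
        calls = np.tile(np.array([[1, 2], [3, 3]]), (4, 1, 1))
        ds = GenotypeDataset(list("wxyz"), ["A"] * 4, ["L1", "L2"], calls)
        row = hind(ds).per_breed.iloc[0]
        assert row["sd"] == 0.0 and row["min"] == row["max"]

    def test_inbreeding_depresses_hind(self):
        cfg = SimConfig(
            n_breeds=2, sample_sizes=[400, 400], n_loci=6,
            alleles_per_locus=[6] * 6, fst=0.0, fis=[0.0, 0.5],
            null_freq=[0.0] * 6, seed=50,
        )
        ds, truth = simulate(cfg)
        hw_het = np.mean(
            [1 - sum(f ** 2 for f in truth.breed_freqs[0][l].values()) for l in range(6)]
        )
        pb = hind(ds).per_breed.set_index("breed_id")
        assert pb.loc["B01", "mean"] == pytest.approx(hw_het, abs=0.05)
        assert pb.loc["B02", "mean"] == pytest.approx(0.5 * hw_het, abs=0.05)

    def test_breed_inbreeding_identity_with_uniform_weights(self):
        ds = random_dataset(12, n_breeds=2, max_n=8, n_loci=4)
        # the identity I_B = 1 - mean(Hind)/2 requires complete genotypes
        keep = np.flatnonzero(~ds.missing_mask.any(axis=1))
        ds = ds.subset(keep)
        hs = hind(ds).per_breed.set_index("breed_id")
        ks = kinship_summaries(ds, weights="uniform").per_breed.set_index("breed_id")
        for b in ds.breeds:
            assert ks.loc[b, "I_B"] == pytest.approx(
                1 - hs.loc[b, "mean"] / 2, abs=1e-12
            )


class TestKinshipSummaries:
    def test_identical_homozygous_breed(self):
        calls = np.tile(np.array([[4, 4]]), (4, 1, 1))
        ds = GenotypeDataset(list("wxyz"), ["A"] * 2 + ["B"] * 2, ["L1"], calls)
        ks = kinship_summaries(ds, weights="uniform")
        assert ks.per_breed.set_index("breed_id").loc["A", "K_BW"] == 1.0

    def test_disjointly_fixed_breeds(self):
        calls = np.array([[[1, 1]], [[1, 1]], [[2, 2]], [[2, 2]]])
        ds = GenotypeDataset(list("wxyz"), ["A", "A", "B", "B"], ["L1"], calls)
        ks = kinship_summaries(ds, weights="uniform")
        pb = ks.per_breed.set_index("breed_id")
        assert pb.loc["A", "K_BW"] == 1.0 and pb.loc["A", "K_BB_mean"] == 0.0

    @pytest.mark.parametrize("weights", ["uniform", "pic"])
    @pytest.mark.parametrize("seed", [0, 3])
    def test_equals_bruteforce_enumeration(self, seed, weights):
        ds = random_dataset(seed, n_breeds=3, max_n=4, n_loci=3)
        w = None if weights == "uniform" else pooled_pic_weights(ds).tolist()
        genos = [[tuple(ds.calls[i, l]) for l in range(ds.n_loci)]
                 for i in range(ds.n_individuals)]
        oracle = naive_kinship_summaries(genos, ds.breed_ids, w)
        ks = kinship_summaries(ds, weights=weights)
        assert ks.K_G == pytest.approx(oracle["K_G"], abs=1e-12)
        np.testing.assert_allclose(
            ks.per_individual["K_IW"], oracle["K_IW"], atol=1e-12
        )
        np.testing.assert_allclose(
            ks.per_individual["K_IB"], oracle["K_IB"], atol=1e-12
        )
        pb = ks.per_breed.set_index("breed_id")
        for b in ds.breeds:
            assert pb.loc[b, "K_BW"] == pytest.approx(oracle["K_BW"][b], abs=1e-12)
        for (b, c), v in oracle["K_BB"].items():
            assert ks.between.loc[b, c] == pytest.approx(v, abs=1e-12)

    def test_global_kinship_is_mean_of_individual_kinship(self):
        ds = random_dataset(21, n_breeds=3, max_n=6, n_loci=3)
        ks = kinship_summaries(ds)
        assert ks.K_G == pytest.approx(ks.per_individual["K_IW"].mean(), abs=1e-9)

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_matrix_symmetry_and_diagonal_bounds(self, seed):
        ds = random_dataset(seed, n_breeds=2, max_n=8, n_loci=4)
        km = kinship_matrix(ds)
        v = km.values
        np.testing.assert_allclose(v, v.T, atol=1e-12)
        d = np.diag(v)
        ok = ~np.isnan(d)
        assert ((d[ok] >= 0.5 - 1e-12) & (d[ok] <= 1 + 1e-12)).all()
        off = v[~np.eye(len(v), dtype=bool)]
        off = off[~np.isnan(off)]
        assert ((off >= -1e-12) & (off <= 1 + 1e-12)).all()


class TestPSA:
    def test_pointwise_values(self):
        calls = np.array([[[1, 2]], [[1, 3]], [[1, 2]], [[3, 4]]])
        ds = GenotypeDataset(list("wxyz"), ["A"] * 4, ["L1"], calls)
        pm = psa_matrix(ds).values
        assert pm[0, 1] == 0.5          # (1,2) vs (1,3)
        assert pm[0, 2] == 1.0          # identical genotypes
        assert pm[1, 3] == 0.5          # (1,3) vs (3,4) share allele 3
        assert pm[0, 3] == 0.0          # disjoint

    def test_hom_vs_het_shares_half(self):
        calls = np.array([[[1, 1]], [[1, 2]]])
        ds = GenotypeDataset(["x", "y"], ["A", "A"], ["L1"], calls)
        assert psa_matrix(ds).values[0, 1] == 0.5

    @pytest.mark.parametrize("seed", [4, 5])
    def test_matches_multiset_intersection_oracle(self, seed):
        ds = random_dataset(seed, n_breeds=2, max_n=4, n_loci=3)
        genos = [[tuple(ds.calls[i, l]) for l in range(ds.n_loci)]
                 for i in range(ds.n_individuals)]
        pm = psa_matrix(ds).values
        for i in range(ds.n_individuals):
            for j in range(ds.n_individuals):
                assert pm[i, j] == pytest.approx(
                    naive_psa(genos[i], genos[j]), abs=1e-12
                )

    def test_agrees_with_coancestry_at_extremes(self):
        calls = np.array([[[1, 1]], [[1, 1]], [[2, 2]]])
        ds = GenotypeDataset(["x", "y", "z"], ["A"] * 3, ["L1"], calls)
        km, pm = kinship_matrix(ds, "uniform").values, psa_matrix(ds).values
        assert km[0, 1] == pm[0, 1] == 1.0
        assert km[0, 2] == pm[0, 2] == 0.0


class TestBootstrap:
    @staticmethod
    def _kbw(ds):
        return float(
            kinship_summaries(ds, weights="uniform").per_breed["K_BW"].mean()
        )

    def test_degenerate_dataset_has_zero_se(self):
        calls = np.tile(np.array([[1, 2]]), (6, 1, 1))
        ds = GenotypeDataset([f"i{k}" for k in range(6)], ["A"] * 3 + ["B"] * 3,
                             ["L1"], calls)
        out = bootstrap_summary(ds, self._kbw, n_boot=10, sample_size=4, seed=1)
        assert out["se"] == 0.0

    def test_same_seed_reproduces_replicates(self, three_breed_sim):
        ds, _ = three_breed_sim
        a = bootstrap_summary(ds, self._kbw, n_boot=8, sample_size=10, seed=42)
        b = bootstrap_summary(ds, self._kbw, n_boot=8, sample_size=10, seed=42)
        np.testing.assert_array_equal(a["replicates"], b["replicates"])

    def test_bootstrap_mean_near_point_estimate(self, three_breed_sim):
        ds, _ = three_breed_sim
        point = self._kbw(ds)
        out = bootstrap_summary(ds, self._kbw, n_boot=30, sample_size=12, seed=7)
        assert abs(out["mean"] - point) <= 2 * out["se"] + 0.02

    def test_tiny_sample_size_rejected(self, three_breed_sim):
        ds, _ = three_breed_sim
        with pytest.raises(ValueError):
            bootstrap_summary(ds, self._kbw, n_boot=5, sample_size=1, seed=0)
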