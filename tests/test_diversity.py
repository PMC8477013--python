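import math

import numpy as np
import pytest

from breedrisk import (
    GenotypeDataset,
    SimConfig,
    allele_frequencies,
    breed_summary_table,
    effective_alleles,
    expected_het,
    low_freq_fraction,
    observed_het,
    pic,
    private_alleles,
    rarefied_richness,
    simulate,
    wright_f,
)
from breedrisk.genotype_io import allele_copy_counts

from conftest import random_dataset
from oracles import exhaustive_rarefaction


@pytest.mark.parametrize(
    "freqs, he",
    [({1: 0.5, 2: 0.5}, 0.5), ({1: 1.0}, 0.0), ({1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}, 0.75)],
)
def test_expected_het(freqs, he):
    assert expected_het(freqs) == pytest.approx(he)


@pytest.mark.parametrize(
    "freqs, ne",
    [({1: 0.5, 2: 0.5}, 2.0), ({1: 0.9, 2: 0.1}, 1 / 0.82),
     ({a: 0.2 for a in range(5)}, 5.0)],
)
def test_effective_alleles(freqs, ne):
    assert effective_alleles(freqs) == pytest.approx(ne, rel=1e-9)


@pytest.mark.parametrize(
    "freqs, val",
    [
        ({1: 0.5, 2: 0.5}, 0.375),
        ({1: 1.0}, 0.0),
        ({1: 1 / 3, 2: 1 / 3, 3: 1 / 3}, 1 - 1 / 3 - 6 / 81),
    ],
)
def test_pic(freqs, val):
    assert pic(freqs) == pytest.approx(val, rel=1e-9)


class TestObservedHet:
    def test_two_hets_of_four(self):
        ds = GenotypeDataset(
            list("wxyz"), ["A"] * 4, ["L1"],
            np.array([[[1, 2]], [[1, 1]], [[2, 2]], [[1, 2]]]),
        )
        assert observed_het(ds, "A", "L1") == 0.5

    def test_all_homozygous(self):
        ds = GenotypeDataset(
            ["x", "y"], ["A", "A"], ["L1"], np.array([[[1, 1]], [[2, 2]]])
        )
        assert observed_het(ds, "A", "L1") == 0.0

    def test_hardy_weinberg_expectation_large_n(self):
        cfg = SimConfig(
            n_breeds=2, sample_sizes=[1000, 2], n_loci=1,
            alleles_per_locus=[2], fst=0.0, fis=[0.0, 0.0],
            dirichlet_concentration=100.0,  # freqs close to (0.5, 0.5)
            null_freq=[0.0], seed=31,
        )
        ds, truth = simulate(cfg)
        p = list(truth.breed_freqs[0][0].values())
        expect = 2 * p[0] * p[1]
        assert observed_het(ds, "B01", "L01") == pytest.approx(expect, abs=0.05)


class TestRarefaction:
    def test_monomorphic_is_one(self):
        assert rarefied_richness({5: 10}, 3) == pytest.approx(1.0)

    def test_full_sample_equals_allele_count(self):
        counts = {1: 3, 2: 5, 3: 2}
        assert rarefied_richness(counts, 5) == pytest.approx(3.0)

    def test_small_case_matches_exhaustive_enumeration(self):
        counts = {1: 3, 2: 1}
        assert rarefied_richness(counts, 1) == pytest.approx(1.5)
        assert rarefied_richness(counts, 1) == pytest.approx(
            exhaustive_rarefaction(counts, 2)
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_on_random_counts(self, seed):
        rng = np.random.default_rng(seed)
        counts = {a: int(c) for a, c in enumerate(rng.integers(1, 4, size=3), 1)}
        N = sum(counts.values())
        for k in range(2, N + 1, 2):
            assert rarefied_richness(counts, k // 2) == pytest.approx(
                exhaustive_rarefaction(counts, k), rel=1e-12
            )

    def test_nondecreasing_in_g_and_caps_at_na(self):
        counts = {1: 6, 2: 3, 3: 1}
        vals = [rarefied_richness(counts, g) for g in range(1, 6)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(len(counts))

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            rarefied_richness({1: 2, 2: 2}, 3)


class TestWrightF:
    @pytest.mark.parametrize("ho, he", [(0.45, 0.56), (0.39, 0.49)])
    def test_published_rows_round_to_020(self, ho, he):
        assert round(wright_f(ho, he), 2) == 0.20

    def test_equal_het_gives_zero(self):
        assert wright_f(0.37, 0.37) == 0.0

    def test_monomorphic_convention(self):
        assert wright_f(0.0, 0.0) == 0.0


class TestPrivateAlleles:
    def test_identical_breeds_have_none(self):
        calls = np.array([[[1, 2]], [[1, 2]], [[1, 2]], [[1, 2]]])
        ds = GenotypeDataset(list("wxyz"), ["A", "A", "B", "B"], ["L1"], calls)
        assert private_alleles(ds)["Np"].tolist() == [0, 0]

    def test_symmetric_one_each(self):
        calls = np.array([[[1, 2]], [[1, 2]], [[2, 3]], [[2, 3]]])
        ds = GenotypeDataset(list("wxyz"), ["A", "A", "B", "B"], ["L1"], calls)
        df = private_alleles(ds).set_index("breed_id")
        assert df.loc["A", "Np"] == 1 and df.loc["B", "Np"] == 1
        assert df.loc["A", "carrier_pct"] == 100.0

    def test_injected_private_allele_is_flagged(self):
        cfg = SimConfig(
            n_breeds=3, sample_sizes=[30, 30, 30], n_loci=2,
            alleles_per_locus=[3, 3], fst=0.05, fis=[0.0] * 3,
            null_freq=[0.0, 0.0], private_alleles=[(1, 0, 0.4)], seed=9,
        )
        ds, truth = simulate(cfg)
        breed, locus, code, _ = truth.private_alleles[0]
        df = private_alleles(ds).set_index("breed_id")
        assert (locus, code) in df.loc[breed, "private_alleles"]
        for other in ds.breeds:
            if other != breed:
                assert (locus, code) not in df.loc[other, "private_alleles"]


def test_low_freq_fraction():
    assert low_freq_fraction([{1: 0.5, 2: 0.5}]) == 0.0
    assert low_freq_fraction([{1: 0.96, 2: 0.04}]) == 0.5
    assert low_freq_fraction([{1: 0.96, 2: 0.04}, {1: 1.0}]) == pytest.approx(1 / 3)


class TestBreedSummaryTable:
    def test_monomorphic_dataset_degenerates_cleanly(self):
        calls = np.tile(np.array([[5, 5], [5, 5]]), (4, 1, 1)).reshape(4, 2, 2)
        ds = GenotypeDataset(list("wxyz"), ["A", "A", "B", "B"], ["L1", "L2"], calls)
        df = breed_summary_table(ds).set_index("breed_id")
        for b in ("A", "B"):
            assert df.loc[b, "Na"] == df.loc[b, "Ne"] == df.loc[b, "Rt"] == 1.0
            assert df.loc[b, "Ho"] == df.loc[b, "He"] == 0.0
            assert df.loc[b, "P"] == 0.0

    @pytest.mark.parametrize("seed", [3, 4])
    def test_internal_consistency(self, seed):
        ds = random_dataset(seed, n_breeds=4, max_n=10, n_loci=4)
        df = breed_summary_table(ds)
        body = df[df["breed_id"] != "Mean Breed"]
        assert (body["Ne"] <= body["Na"] + 1e-12).all()
        assert (body["Rt"] <= body["Na"] + 1e-12).all()
        assert ((body["Ne"] >= 1 - 1e-12) & (body["Rt"] >= 1 - 1e-12)).all()
        assert ((body["He"] >= 0) & (body["He"] < 1)).all()
        assert (body["PIC"] <= body["He"] + 1e-12).all()
        for _, row in body.iterrows():
            assert row["F"] == pytest.approx(
                wright_f(row["Ho"], row["He"]), abs=1e-12
            )

    def test_per_breed_per_locus_bounds(self):
        ds = random_dataset(8, n_breeds=3, max_n=8, n_loci=4)
        for b in ds.breeds:
            ft = allele_frequencies(ds, b)
            for l in range(ds.n_loci):
                if not ft.freqs[l]:
                    continue
                na = len(ft.freqs[l])
                ne = effective_alleles(ft.freqs[l])
                assert 1 - 1e-12 <= ne <= na + 1e-12
                if na >= 2:
                    assert pic(ft.freqs[l]) < expected_het(ft.freqs[l])

    def test_mean_row_averages_unrounded_breed_values(self):
        ds = random_dataset(6, n_breeds=3, max_n=8, n_loci=3)
        df = breed_summary_table(ds)
        body = df[df["breed_id"] != "Mean Breed"]
        mean = df[df["breed_id"] == "Mean Breed"].iloc[0]
        assert mean["Ne"] == pytest.approx(body["Ne"].mean(), abs=1e-12)
        assert mean["Ho"] == pytest.approx(body["Ho"].mean(), abs=1e-12)
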