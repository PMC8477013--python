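import numpy as np
import pytest

from breedrisk import GenotypeDataset, SimConfig, simulate


@pytest.fixture
def toy_two_breeds():
    """Two small breeds, two loci, one missing call — hand-checkable."""
    calls = np.array(
        [
            [[1, 1], [3, 4]],
            [[1, 2], [3, 3]],
            [[2, 2], [0, 0]],
            [[1, 2], [4, 4]],
            [[2, 3], [3, 4]],
            [[3, 3], [4, 4]],
        ]
    )
    return GenotypeDataset(
        individual_ids=[f"i{k}" for k in range(6)],
        breed_ids=["A", "A", "A", "B", "B", "B"],
        loci=["L1", "L2"],
        calls=calls,
    )


@pytest.fixture
def three_breed_sim():
    """Mid-sized simulated dataset with known generator truth."""
    cfg = SimConfig(
        n_breeds=3,
        sample_sizes=[12, 20, 16],
        n_loci=5,
        alleles_per_locus=[4, 6, 3, 5, 8],
        fst=0.15,
        fis=[0.0, 0.1, 0.3],
        missing_rate=0.03,
        null_freq=[0.0] * 5,
        seed=2024,
    )
    return simulate(cfg)


def random_dataset(seed, n_breeds=3, max_n=6, n_loci=3):
    """Small random dataset for property checks (some missing calls)."""
    rng = np.random.default_rng(seed)
    sizes = rng.integers(2, max_n + 1, size=n_breeds).tolist()
    cfg = SimConfig(
        n_breeds=n_breeds,
        sample_sizes=sizes,
        n_loci=n_loci,
        alleles_per_locus=rng.integers(2, 6, size=n_loci).tolist(),
        fst=float(rng.uniform(0.02, 0.4)),
        fis=rng.uniform(0, 0.6, size=n_breeds).tolist(),
        missing_rate=float(rng.uniform(0, 0.15)),
        null_freq=[0.0] * n_loci,
        seed=int(rng.integers(2**31)),
    )
    ds, _ = simulate(cfg)
    return ds
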