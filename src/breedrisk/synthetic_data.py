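"""Synthetic microsatellite genotype datasets with known truth.

The generator follows the Balding–Nichols drift model: ancestral allele
frequencies at each locus are drawn from a Dirichlet, and each breed's
frequencies from a Dirichlet centred on the ancestral vector with
concentration (1 - F_ST) / F_ST, so breeds behave like island populations
differentiated to a target F_ST.  Genotypes within a breed are drawn with
inbreeding F_IS:

    P(a/a) = p_a^2 + F_IS p_a (1 - p_a)
    P(a/b) = 2 p_a p_b (1 - F_IS)        (a != b)

Null alleles are simulated as one hidden extra allele per affected locus at
frequency r — exactly the model the EM estimator assumes — so null/visible
carriers type as homozygotes and null/null individuals as missing.
Additional genotypes are knocked out at the configured missing rate, and
breed-private alleles can be injected at known frequencies.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeDataset

__all__ = ["SimConfig", "SimTruth", "simulate", "survey_config"]

#: internal sentinel for the hidden null allele during simulation
_NULL = -1


@dataclass
class SimConfig:
    """Generator settings; defaults give a mid-sized differentiated panel."""

    n_breeds: int = 8
    sample_sizes: list[int] = field(default_factory=lambda: [50] * 8)
    n_loci: int = 14
    alleles_per_locus: list[int] = field(default_factory=lambda: [8] * 14)
    dirichlet_concentration: float = 1.0
    fst: float = 0.15
    fis: list[float] = field(default_factory=lambda: [0.0] * 8)
    missing_rate: float = 0.0
    null_freq: list[float] = field(default_factory=lambda: [0.0] * 14)
    #: (breed index, locus index, frequency) triples of alleles to inject
    private_alleles: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int | None = None

    def validate(self) -> None:
        if self.n_breeds < 1 or len(self.sample_sizes) != self.n_breeds:
            raise ValueError("sample_sizes must have one entry per breed")
        if any(s < 2 for s in self.sample_sizes):
            raise ValueError("sample sizes must be >= 2")
        if len(self.alleles_per_locus) != self.n_loci:
            raise ValueError("alleles_per_locus must have one entry per locus")
        if any(k < 1 for k in self.alleles_per_locus):
            raise ValueError("each locus needs >= 1 allele")
        if not (0 <= self.fst < 1):
            raise ValueError("fst must be in [0, 1)")
        if len(self.fis) != self.n_breeds or any(not (0 <= f <= 1) for f in self.fis):
            raise ValueError("fis needs one value in [0, 1] per breed")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if len(self.null_freq) != self.n_loci or any(
            not (0 <= r < 1) for r in self.null_freq
        ):
            raise ValueError("null_freq needs one value in [0, 1) per locus")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        for b, l, f in self.private_alleles:
            if not (0 <= b < self.n_breeds and 0 <= l < self.n_loci and 0 < f < 1):
                raise ValueError(f"bad private-allele injection {(b, l, f)}")


@dataclass
class SimTruth:
    """Ground truth behind a simulated dataset."""

    config: SimConfig
    ancestral_freqs: list[np.ndarray]
    #: breed_freqs[b][l] maps allele code -> frequency (includes injected
    #: private alleles; excludes the null allele)
    breed_freqs: list[list[dict[int, float]]]
    null_freq: list[float]
    private_alleles: list[tuple[str, str, int, float]]  # breed, locus, code, freq


def _draw_genotypes(rng, codes: np.ndarray, p: np.ndarray, fis: float, n: int) -> np.ndarray:
    """(n, 2) genotype draws with within-breed inbreeding ``fis``."""
    a1 = codes[rng.choice(codes.size, size=n, p=p)]
    a2 = codes[rng.choice(codes.size, size=n, p=p)]
    if fis > 0:
        ibd = rng.random(n) < fis
        a2 = np.where(ibd, a1, a2)
    return np.stack([a1, a2], axis=1)


def simulate(config: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Draw a genotype dataset (and its truth) from ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    loci = [f"L{l + 1:02d}" for l in range(config.n_loci)]
    breeds = [f"B{b + 1:02d}" for b in range(config.n_breeds)]

    ancestral = []
    for k in config.alleles_per_locus:
        ancestral.append(rng.dirichlet(np.full(k, config.dirichlet_concentration)))

    # Balding-Nichols: breed freqs ~ Dirichlet(p * (1 - Fst) / Fst)
    breed_freqs: list[list[dict[int, float]]] = []
    next_code = [k + 1 for k in config.alleles_per_locus]  # for private injections
    injected: list[tuple[str, str, int, float]] = []
    for b in range(config.n_breeds):
        per_locus = []
        for l, p_anc in enumerate(ancestral):
            if config.fst == 0:
                p = p_anc.copy()
            else:
                conc = p_anc * (1 - config.fst) / config.fst
                # Dirichlet with tiny concentrations can underflow; floor it
                p = rng.dirichlet(np.maximum(conc, 1e-8))
            per_locus.append({a + 1: float(x) for a, x in enumerate(p)})
        breed_freqs.append(per_locus)
    for b, l, f in config.private_alleles:
        code = next_code[l]
        next_code[l] += 1
        fmap = breed_freqs[b][l]
        scale = 1.0 - f
        for a in list(fmap):
            fmap[a] *= scale
        fmap[code] = f
        injected.append((breeds[b], loci[l], code, f))

    n_total = sum(config.sample_sizes)
    calls = np.zeros((n_total, config.n_loci, 2), dtype=np.int64)
    ids: list[str] = []
    breed_ids: list[str] = []
    row = 0
    for b, n in enumerate(config.sample_sizes):
        fis = config.fis[b]
        ids.extend(f"{breeds[b]}_i{i + 1:03d}" for i in range(n))
        breed_ids.extend([breeds[b]] * n)
        for l in range(config.n_loci):
            fmap = breed_freqs[b][l]
            r = config.null_freq[l]
            codes = np.fromiter(fmap.keys(), dtype=np.int64)
            p = np.fromiter(fmap.values(), dtype=float)
            if r > 0:
                codes = np.append(codes, _NULL)
                p = np.append(p * (1 - r), r)
            p = p / p.sum()
            g = _draw_genotypes(rng, codes, p, fis, n)
            null1 = g[:, 0] == _NULL
            null2 = g[:, 1] == _NULL
            g[null1 & null2] = MISSING             # null homozygote: no signal
            only1 = null1 & ~null2
            only2 = null2 & ~null1
            g[only1, 0] = g[only1, 1]              # apparent homozygote
            g[only2, 1] = g[only2, 0]
            calls[row:row + n, l] = g
        row += n
    if config.missing_rate > 0:
        knockout = rng.random((n_total, config.n_loci)) < config.missing_rate
        calls[knockout] = MISSING

    dataset = GenotypeDataset(ids, breed_ids, loci, calls)
    truth = SimTruth(
        config=config,
        ancestral_freqs=ancestral,
        breed_freqs=breed_freqs,
        null_freq=list(config.null_freq),
        private_alleles=injected,
    )
    return dataset, truth


def survey_config(seed: int | None = None) -> SimConfig:
    """A configuration shaped like the motivating survey: 17 closed local
    chicken breeds (645 birds, samples of 17–99), 14 microsatellites with
    5–39 alleles, strong differentiation and moderate within-breed
    inbreeding, light missingness, and null alleles concentrated at one
    problem locus."""
    sample_sizes = [23, 72, 64, 24, 44, 77, 99, 19, 22, 21, 23, 17, 23, 23, 42, 30, 22]
    # allele counts spanning 5-39 with a mean near 15
    alleles = [5, 39, 9, 12, 18, 7, 15, 22, 10, 13, 26, 8, 16, 11]
    null_freq = [0.0] * 14
    null_freq[4] = 0.15      # one badly behaved marker
    null_freq[9] = 0.05
    return SimConfig(
        n_breeds=17,
        sample_sizes=sample_sizes,
        n_loci=14,
        alleles_per_locus=alleles,
        dirichlet_concentration=0.5,
        fst=0.34,
        fis=[0.09] * 17,
        missing_rate=0.02,
        null_freq=null_freq,
        private_alleles=[],
        seed=seed,
    )
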