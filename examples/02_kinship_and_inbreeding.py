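"""Molecular kinship and inbreeding summaries.

Computes individual heterozygosity (Hind), self-coancestry-based breed
inbreeding I_B, within-breed kinship K_BW, between-breed kinship, the
proportion of shared alleles PSA, and the global kinship K_G, with a
size-adjusted bootstrap for K_BW.  A breed whose members are close
relatives shows high K_BW and PSA and a left-shifted Hind distribution.
"""

from breedrisk import SimConfig, bootstrap_summary, hind, kinship_summaries, simulate

cfg = SimConfig(
    n_breeds=3,
    sample_sizes=[30, 30, 30],
    n_loci=10,
    alleles_per_locus=[8] * 10,
    fst=0.25,
    fis=[0.0, 0.0, 0.6],        # B03 is strongly inbred
    null_freq=[0.0] * 10,
    seed=2,
)
dataset, _ = simulate(cfg)

h = hind(dataset)
print("Hind per breed (mean/median/min/max):")
print(h.per_breed.round(2).to_string(index=False))

ks = kinship_summaries(dataset, weights="pic")
print(f"\nGlobal kinship K_G = {ks.K_G:.3f}")
print(ks.per_breed.round(3).to_string(index=False))

boot = bootstrap_summary(
    dataset,
    lambda d: float(kinship_summaries(d, weights="pic").per_breed["K_BW"].mean()),
    n_boot=50, sample_size=20, seed=3,
)
print(f"\nmean K_BW bootstrap: {boot['mean']:.3f} +/- {boot['se']:.3f}")
print(
    "\nThe inbred breed (B03) shows depressed Hind and elevated I_B; K_BB"
    "\nstays low because kinship *between* breeds reflects divergence, not"
    "\nwithin-breed mating."
)
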