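"""Diversity partition, breed-removal contributions, and extinction risk.

The coancestry-based diversity GD_total splits into within- and
between-breed components; each breed's conservation value is the percentage
change (GD_W, GD_B, and their sum GD_T) when it is removed from the
dataset.  Negative GD_T = diversity lost with the breed.  The Extinction
Risk Index then sums five unit-bounded indicators (F, I_B, K_BW, PSA,
1 - Ho); breeds above 2.5 are flagged at risk.
"""

from breedrisk import (
    SimConfig,
    breed_removal_contributions,
    eri_table,
    global_diversity,
    simulate,
)

cfg = SimConfig(
    n_breeds=5,
    sample_sizes=[40, 40, 40, 40, 40],
    n_loci=10,
    alleles_per_locus=[3, 10, 3, 10, 3, 10, 3, 10, 3, 10],
    fst=0.25,
    fis=[0.0, 0.0, 0.3, 0.6, 0.0],
    null_freq=[0.0] * 10,
    seed=8,
)
dataset, _ = simulate(cfg)

part = global_diversity(dataset, weights="pic")
print(f"GD_total = {part.GD_total:.3f} "
      f"(within {part.within:.3f} + between {part.between:.3f})")

contrib = breed_removal_contributions(dataset, weights="pic")
print("\nbreed-removal contributions (% of full-dataset GD_total):")
print(contrib.round(2).to_string(index=False))

eri = eri_table(dataset)
print("\nExtinction Risk Index:")
print(eri[["breed_id", "F", "I_B", "K_BW", "PSA", "O", "ERI",
           "risk_class"]].round(2).to_string(index=False))
print(
    "\nThe strongly inbred breed (B04) tops the ERI ranking; diverse outbred"
    "\nbreeds show negative GD_T (their loss would cost diversity)."
)
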