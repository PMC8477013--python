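"""Per-breed diversity table on a small simulated panel.

Draws four breeds diverged to F_ST = 0.2 with different inbreeding levels,
then prints the standard diversity summary: sample size N, marker
informativeness PIC, % polymorphic loci P, allele counts Na (and rarefied
richness Rt at the common sample size), effective alleles Ne, observed and
expected heterozygosity Ho/He, and Wright's F = 1 - Ho/He.  Breeds with
higher configured inbreeding should show lower Ho and higher F.
"""

from breedrisk import SimConfig, breed_summary_table, simulate

cfg = SimConfig(
    n_breeds=4,
    sample_sizes=[40, 40, 40, 40],
    n_loci=8,
    alleles_per_locus=[6] * 8,
    fst=0.2,
    fis=[0.0, 0.1, 0.3, 0.5],   # increasingly inbred breeds
    null_freq=[0.0] * 8,
    seed=1,
)
dataset, _ = simulate(cfg)

table = breed_summary_table(dataset)
cols = ["breed_id", "N", "PIC", "P", "Na", "Rt", "Ne", "Ho", "He", "F"]
print(table[cols].round(2).to_string(index=False))
print(
    "\nF climbs with the configured inbreeding (B01 -> B04), while He stays"
    "\nroughly flat: inbreeding removes heterozygotes, not alleles."
)
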