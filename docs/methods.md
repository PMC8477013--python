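# Methods

This note documents the statistical models behind `breedrisk`, the defaults
and why they were chosen, the numerical conventions, and what validation on
synthetic data does and does not establish.

## Data model

A dataset is a set of diploid individuals, each belonging to exactly one
breed, typed at L codominant loci. Allele codes are opaque positive
integers (fragment sizes); no binning, recoding, or mutation-model
(allele-size) information is used, so all statistics are identity-in-state
statistics. A call is either a full unordered allele pair or missing —
half-calls are rejected on input (Genepop half-missing codes are collapsed
to missing). Allele frequencies count each non-missing gene copy once; a
homozygote contributes two copies.

The Genepop dialect carries no breed names, only `pop` blocks; our writer
embeds the breed label in the individual name (`breed|id`) so round trips
are lossless, and the reader falls back to `pop1…popN` labels for foreign
files. The table dialect stores the breed explicitly and uses a
configurable missing sentinel (default `0`), since surveys differ in their
missing-data encoding.

## Diversity statistics

Per locus within a scope (one breed, or pooled): expected heterozygosity is
the plug-in gene diversity `He = 1 − Σp²` with **no** small-sample (Nei)
correction; effective allele number `Ne = 1/Σp²`; PIC is Botstein's
`1 − Σp² − Σ_{i<j} 2p_i²p_j²`; observed heterozygosity is the heterozygote
fraction among non-missing calls. Per-breed values are **unweighted means
over loci** (the GenAlEx convention); loci with no data in a breed are
dropped from that breed's means with a warning rather than propagating
NaNs. The summary table's mean row averages unrounded per-breed values —
re-averaging the rounded column can differ in the last printed digit.

Wright's `F = 1 − Ho/He` is computed from the breed's mean Ho and mean He.
A monomorphic scope (He = 0) returns `F = 0` by convention: there is no
heterozygosity to be deficient in. This convention caps the extinction
score (below) at 4 for fully monomorphic breeds and is deliberate — such a
breed is flagged by its homozygosity and kinship components instead.

Allelic richness is rarefied hypergeometrically to a standardized sample of
g diploid individuals: `Rt = Σ_a [1 − C(N−N_a, 2g)/C(N, 2g)]`, the expected
number of distinct alleles in a random draw of 2g gene copies without
replacement. The default g is the smallest per-breed count of individuals
with complete genotypes at every locus, overridable; within a breed a locus
with fewer copies than 2g (from missing data) is rarefied at its own
maximum. Computation uses exact integer binomials, so Rt is exact.

## Coancestry, kinship, PSA

Molecular coancestry between genotypes (a,b) and (c,d) at a locus is
`f = (I_ac + I_ad + I_bc + I_bd)/4`; self-coancestry is the same formula of
an individual with itself (1 for a homozygote, 0.5 for a heterozygote),
giving `F_i = 2s_i − 1` and the exact identity `I_B = 1 − mean(Hind)/2`
under uniform locus weights on complete genotypes. Multi-locus values
average over loci typed in both individuals, either uniformly or weighted
by each marker's PIC. PIC weights are computed **once on the pooled
dataset** (a single weight per marker, treated as a marker property) and
renormalized per pair over the loci the pair shares, so weights always sum
to one under missingness.

Kinship summaries include the self-pair: `K_IW` averages an individual's
coancestry with everyone including itself, `K_BW` averages all
within-breed pairs including self-pairs, and `K_G` is the mean `K_IW`.
This "includes itself" convention inflates within-breed kinship slightly
for small breeds relative to the off-diagonal-only alternative; the
conventional variant is available (`include_self=False` /
`--exclude-self`). PSA — the per-locus multiset overlap of the two
genotypes (0, 0.5, 1), averaged uniformly — excludes self-pairs in its
within-breed mean, since PSA of an individual with itself is 1 by
construction.

Bootstrap uncertainty for any kinship or F-statistic resamples individuals
**within each breed with replacement to a fixed size** (default 100
replicates of 50), which removes the dependence of sampling variance on
the very unequal breed sizes typical of conservation surveys; the reported
SE is the standard deviation of replicates.

## Wright's F-statistics

The headline indices use the gene-diversity hierarchy per locus, with
breeds weighted equally regardless of sample size: `H_O` is the unweighted
breed mean of observed heterozygosity, `H_S` the mean within-breed `He`,
`H_T` the `He` of the breed-averaged allele frequencies. Then
`F_IS = (H_S − H_O)/H_S`, `F_ST = (H_T − H_S)/H_T`,
`F_IT = (H_T − H_O)/H_T`, which satisfy
`(1 − F_IT) = (1 − F_IS)(1 − F_ST)` exactly per locus. Global values are
PIC-weighted means over polymorphic loci. Bootstrap p-values are the
one-sided fraction of replicates at or below zero.

Two scale caveats are worth knowing. First, with r breeds entering `H_T`
the gene-diversity `F_ST` is deflated by roughly `(r−1)/r` relative to the
variance-components parameter (≈ 12% low at r = 8, half at r = 2). Second,
the separate pairwise matrix uses the Weir–Cockerham theta (variance
components summed over alleles and loci, ratio of sums), which targets the
undeflated parameter — so a two-breed theta is expected to be about twice
the corresponding two-breed gene-diversity value, and the test suite checks
exactly that relation rather than raw equality.

## Exact Hardy–Weinberg tests

Conditional on allele counts, every pairing of the 2n gene copies into n
genotypes is equally likely under HWE, inducing
`P(T) ∝ 2^H / Π t_ab!` over genotype tables. Rather than a table-switch
sampler with delicate acceptance ratios, the chain operates on an explicit
arrangement of the 2n copies into n slots-pairs and swaps two uniformly
chosen slots: the proposal is symmetric and the stationary law uniform, so
every move is accepted and the induced table distribution is exactly the
conditional one. The deficit (excess) p-value is the visited-state fraction
with heterozygote count ≤ (≥) the observed; the `global` alternative uses
the table-probability tail. P-values are averaged over batches, with the
between-batch standard error as the Monte-Carlo SE. Defaults follow the
classic protocol (10,000 dememorization steps, 500 batches × 5,000
iterations); the orchestrated full-table run and the examples use lighter
chains, which the MC SE makes visible. Global tests combine per-locus
p-values by Fisher's method (−2Σln p against χ² with 2k d.f.), skipping
monomorphic entries and flooring MC p-values at 1e−12 to keep the
combination finite.

Allele relabeling leaves the test distribution unchanged; because the
chain's initial arrangement is built from the (sorted) table keys, the
realized trajectory under a fixed seed can differ after relabeling — the
invariance holds statistically (within MC error), and is tested that way.

## Null alleles

The EM estimator assumes one non-amplifying allele per locus at frequency
r under HWE: null/visible carriers type as homozygotes and null/null as
missing. Missing calls are *not* treated as evidence of null homozygotes
(they may be failed reactions); instead the null/null class enters as a
truncated category, so the EM maximizes the likelihood of the visible
genotypes. Each observed homozygote is split between true a/a and a/null
in the E-step; the observed-data log-likelihood is verified nondecreasing
at every iteration. Near the r = 0 boundary plain EM converges only
sublinearly (its linear rate is `λ = (1/n)Σ_a n_aa/p_a`, exactly 1 for
HW-conforming counts), so after the loop the implementation snaps to r = 0
whenever `λ ≤ 1`, which is precisely the condition for the boundary to be
the maximum.

The F_ST robustness check strips the estimated null mass from each
breed × locus frequency map, renormalizes the visible frequencies, and
recompares global and pairwise F_ST. Because only frequencies (not
genotypes) exist after correction, this path uses the gene-diversity
estimator on both sides; it reports the differences rather than asserting
a bound on real data.

## Diversity partition and breed contributions

With `f_kl` the mean coancestry over all pairs with one individual in breed
k and one in l (`f_kk` includes self-pairs, consistent with `K_BW`), and N
breeds weighted equally:

    GD_total = 1 − (1/N²) Σ_k Σ_l f_kl
    GD_within = 1 − (1/N) Σ_k f_kk
    GD_between = GD_total − GD_within

Removing breed k and recomputing gives percentage changes
`GD_W = 100·(within₋ₖ − within)/GD_total` and likewise `GD_B`; their sum
`GD_T` is additive **by construction, to machine precision**, because both
terms share the full-dataset `GD_total` as denominator. A positive `GD_T`
means the remaining dataset is more diverse without the breed.

One consequence of equal breed weights deserves emphasis: removing one
copy of a *duplicated* breed does not give `GD_T = 0`, because removal
reweights the remaining breeds (1/N → 1/(N−1)). What does hold exactly —
and is tested — is that a dataset of identical breed copies yields
`GD_T = 0` for every breed, and that the two copies of a duplicated breed
produce identical removal rows. The raw `GD_T` (plus rank) is the
canonical output; no rescaling to a "percentage contribution" is applied,
as no such mapping is uniquely defined.

## Extinction Risk Index

`ERI = F + I_B + K_BW + PSA + O` with `O = 1 − Ho`: five unit-bounded
indicators, each increasing with variability loss, summed without weights
to a 0–5 score. Components are pulled with the conventions above: F and Ho
uniform-weighted from the diversity table, `I_B` and `K_BW` PIC-weighted,
PSA uniform. A negative F (heterozygote excess) enters as-is by default —
it genuinely lowers risk — with an optional clip at 0 to preserve the
nominal range. Classification: `> 2.5` at risk, `[2.0, 2.5]` intermediate
(both ends closed), `< 2.0` ok; the 2.5 midpoint is a convention and both
thresholds are configurable. The table also flags breeds with `He > Ho` —
heterozygosity that a managed mating plan could still recover.

## Synthetic data generator

The generator is the package's source of ground truth. Ancestral allele
frequencies per locus are Dirichlet(c) draws (default concentration 0.5,
giving the skewed frequency spectra typical of microsatellite panels);
breed frequencies follow the Balding–Nichols model,
Dirichlet(p·(1−F_ST)/F_ST), so breeds behave like islands differentiated
to the target F_ST. Genotypes are drawn with within-breed inbreeding
(second allele copies the first with probability F_IS). Null alleles are
one hidden extra allele per affected locus — exactly the EM's model, which
makes parameter-recovery tests sharp but says nothing about model
mismatch. Missingness is uniform at random.

`survey_config()` reproduces a real survey design: 17 breeds with
sample sizes 17–99 (645 total), 14 loci with 5–39 alleles, target F_ST
0.34, F_IS 0.09 in every breed, 2% missingness, and null alleles at two
loci (0.15 at one "problem" marker, 0.05 at another) — matching a survey
where one marker nulled badly. What the generator does **not** emulate:
allele-size (stepwise) mutation structure, linkage, family structure
within breeds beyond a single inbreeding coefficient, locus-specific
genotyping error, and non-random missingness. Passing recovery tests
therefore validates the estimators under their own assumptions, not their
robustness on real data.

## Validation choices and problem sizes

Tolerances in the test suite are derived, not tuned: exact identities are
asserted at 1e−12 (machine precision through the vectorized paths), MC
estimates at 3 MC standard errors against full enumeration (feasible up to
~6 genotypes), and parameter recovery at ±0.05 absolute — the sampling
noise scale of the simulated designs (8 breeds × 50 for F_ST, n = 500 for
the null EM, n = 200 per breed for F_IS). The type-I error of the HWE test
is measured over 500 null replicates at α = 0.05 and required to land in
[0.03, 0.07]; the one-sided heterozygote-count tail is slightly
conservative on discrete tables, so values near the lower edge are
expected. The acceptance script runs the full pipeline at the survey's own
size (645 × 14) and the recovery studies at the sizes above, completing in
well under a minute on one core.

## Known limitations

* All statistics are identity-in-state; panels with strong size homoplasy
  are summarized but not modeled.
* The HWE chain records after every proposal (including no-ops); its MC SE
  reflects between-batch variation only, so severely autocorrelated chains
  (tiny batches) understate uncertainty — the defaults are far from that
  regime.
* The null-allele EM fits one null allele per locus per breed
  independently; pooled-breed or multi-null variants are out of scope.
* `K_BW` with self-pairs included is systematically above the
  off-diagonal-only version by ≈ (s̄ − K)/n_breed; comparisons across
  differently-sized breeds should use the bootstrap (which fixes n).
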