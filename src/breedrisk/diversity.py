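"""Per-breed and per-locus diversity statistics for codominant markers.

All estimators are the classic plug-in forms used throughout livestock
diversity surveys: expected heterozygosity (gene diversity) He = 1 - sum p_i^2
with no small-sample correction, effective allele number Ne = 1 / sum p_i^2,
Botstein's polymorphic information content, hypergeometric rarefaction of
allelic richness to a standardized sample size, and Wright's inbreeding
coefficient F = 1 - Ho/He.  Per-breed values are unweighted means over loci;
loci with no data in a breed are excluded from that breed's means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    POOLED,
    GenotypeDataset,
    allele_copy_counts,
    allele_frequencies,
)

__all__ = [
    "BreedSummary",
    "observed_het",
    "expected_het",
    "effective_alleles",
    "pic",
    "rarefied_richness",
    "wright_f",
    "private_alleles",
    "low_freq_fraction",
    "default_rarefaction_g",
    "breed_summary_table",
]


# ---------------------------------------------------------------------------
# per-locus estimators


def observed_het(dataset: GenotypeDataset, breed_id: str, locus: str) -> float:
    """Observed heterozygosity: heterozygous / non-missing individuals.

    Returns NaN when the breed has no non-missing call at the locus (such a
    locus is excluded from breed means).
    """
    rows = dataset.breed_indices(breed_id)
    l = dataset.loci.index(locus)
    calls = dataset.calls[rows, l, :]
    typed = calls[:, 0] != MISSING
    if not typed.any():
        return math.nan
    het = calls[typed, 0] != calls[typed, 1]
    return float(het.mean())


def expected_het(freqs: dict[int, float]) -> float:
    """Gene diversity ``1 - sum p_i^2`` (plug-in, no bias correction)."""
    if not freqs:
        return math.nan
    p = np.fromiter(freqs.values(), dtype=float)
    return float(1.0 - (p ** 2).sum())


def effective_alleles(freqs: dict[int, float]) -> float:
    """Effective allele number ``1 / sum p_i^2``: the count of equally
    frequent alleles giving the same gene diversity."""
    if not freqs:
        return math.nan
    p = np.fromiter(freqs.values(), dtype=float)
    return float(1.0 / (p ** 2).sum())


def pic(freqs: dict[int, float]) -> float:
    """Polymorphic information content (Botstein et al. marker score).

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2.
    """
    if not freqs:
        return math.nan
    p = np.fromiter(freqs.values(), dtype=float)
    sq = p ** 2
    cross = (sq.sum() ** 2 - (sq ** 2).sum())  # == sum_{i != j} p_i^2 p_j^2
    return float(1.0 - sq.sum() - cross)


def rarefied_richness(allele_copy_counts: dict[int, int], g: int) -> float:
    """Allelic richness rarefied to a standardized sample of ``g`` diploid
    individuals (``2g`` gene copies), by hypergeometric expectation:

        Rt = sum_a [1 - C(N - N_a, 2g) / C(N, 2g)]

    where ``N`` is the total copy count and ``N_a`` the copies of allele
    ``a``.  This is the expected number of distinct alleles in a random
    subsample of ``2g`` copies without replacement.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    counts = np.fromiter(allele_copy_counts.values(), dtype=np.int64)
    N = int(counts.sum())
    k = 2 * g
    if k > N:
        raise ValueError(f"2g = {k} exceeds available gene copies N = {N}")
    denom = math.comb(N, k)
    total = 0.0
    for Na in counts:
        total += 1.0 - math.comb(N - int(Na), k) / denom
    return total


def wright_f(ho: float, he: float) -> float:
    """Wright's inbreeding coefficient ``F = 1 - Ho/He``.

    A monomorphic scope (He = 0) returns 0 by convention — there is no
    heterozygosity left to be deficient in.
    """
    if he < 0:
        raise ValueError("He must be nonnegative")
    if he == 0:
        return 0.0
    return 1.0 - ho / he


def low_freq_fraction(freqs_by_locus: list[dict[int, float]], threshold: float = 0.05) -> float:
    """Share of distinct alleles, pooled over loci, with frequency below
    ``threshold`` — a proxy for variability at imminent risk of drift loss."""
    n_alleles = 0
    n_rare = 0
    for f in freqs_by_locus:
        n_alleles += len(f)
        n_rare += sum(1 for p in f.values() if p < threshold)
    if n_alleles == 0:
        return math.nan
    return n_rare / n_alleles


# ---------------------------------------------------------------------------
# private alleles


def private_alleles(dataset: GenotypeDataset) -> pd.DataFrame:
    """Alleles observed in exactly one breed.

    Returns one row per breed with the private (locus, allele) list, its
    count Np, and the percentage of the breed's individuals carrying at
    least one private allele.
    """
    breeds = dataset.breeds
    if len(breeds) < 2:
        warnings.warn("single breed: every allele is trivially private")
    seen: dict[tuple[int, int], set[str]] = {}
    for b in breeds:
        rows = dataset.breed_indices(b)
        for l in range(dataset.n_loci):
            col = dataset.calls[rows, l, :].ravel()
            for a in np.unique(col[col != MISSING]):
                seen.setdefault((l, int(a)), set()).add(b)
    records = []
    for b in breeds:
        priv = sorted((l, a) for (l, a), bs in seen.items() if bs == {b})
        rows = dataset.breed_indices(b)
        carriers = 0
        for i in rows:
            if any(
                a in (dataset.calls[i, l, 0], dataset.calls[i, l, 1])
                for l, a in priv
            ):
                carriers += 1
        records.append(
            {
                "breed_id": b,
                "Np": len(priv),
                "private_alleles": [(dataset.loci[l], a) for l, a in priv],
                "carrier_pct": 100.0 * carriers / len(rows),
            }
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# breed summary table


@dataclass
class BreedSummary:
    """One breed's row of the standard diversity table."""

    breed_id: str
    N: int
    PIC: float
    P: float                     # % polymorphic loci
    Na: float
    Na_se: float
    Rt: float
    Ne: float
    Ne_se: float
    Ho: float
    Ho_se: float
    He: float
    He_se: float
    F: float
    F_se: float
    Np: int
    low_freq_fraction: float
    monomorphic: bool = False
    n_loci_used: int = 0
    extra: dict = field(default_factory=dict)


def _se(values: np.ndarray) -> float:
    values = values[~np.isnan(values)]
    if values.size < 2:
        return math.nan
    return float(values.std(ddof=1) / math.sqrt(values.size))


def default_rarefaction_g(dataset: GenotypeDataset) -> int:
    """Standardized rarefaction size: the smallest per-breed count of
    individuals with complete genotypes at every locus."""
    complete = ~dataset.missing_mask.any(axis=1)
    gs = []
    for b in dataset.breeds:
        gs.append(int(complete[dataset.breed_indices(b)].sum()))
    g = min(gs)
    if g < 1:
        raise ValueError(
            "some breed has no fully genotyped individual; pass an explicit g"
        )
    return g


def breed_summary_table(
    dataset: GenotypeDataset,
    rarefaction_g: int | None = None,
    low_freq_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-breed diversity statistics plus a mean-across-breeds row.

    Per-breed values are unweighted means over loci with data in that breed;
    standard errors are across loci.  The mean row averages the (unrounded)
    per-breed values with its standard error across breeds.
    """
    if rarefaction_g is None:
        rarefaction_g = default_rarefaction_g(dataset)
    priv = private_alleles(dataset).set_index("breed_id")
    rows = []
    for b in dataset.breeds:
        ft = allele_frequencies(dataset, b)
        counts = allele_copy_counts(dataset, b)
        used = [l for l in range(dataset.n_loci) if ft.gene_copies[l] > 0]
        if len(used) < dataset.n_loci:
            warnings.warn(
                f"breed {b!r}: {dataset.n_loci - len(used)} loci with no data excluded"
            )
        na = np.array([len(ft.freqs[l]) for l in used], dtype=float)
        ne = np.array([effective_alleles(ft.freqs[l]) for l in used])
        he = np.array([expected_het(ft.freqs[l]) for l in used])
        pic_l = np.array([pic(ft.freqs[l]) for l in used])
        ho = np.array(
            [observed_het(dataset, b, dataset.loci[l]) for l in used]
        )
        rt = np.array(
            [
                rarefied_richness(counts[l], min(rarefaction_g, ft.gene_copies[l] // 2))
                for l in used
            ]
        )
        mean_ho, mean_he = float(np.nanmean(ho)), float(np.nanmean(he))
        f_per_locus = np.array(
            [wright_f(h, e) for h, e in zip(ho, he)], dtype=float
        )
        rows.append(
            BreedSummary(
                breed_id=b,
                N=len(dataset.breed_indices(b)),
                PIC=float(np.nanmean(pic_l)),
                P=100.0 * float((na >= 2).mean()),
                Na=float(na.mean()),
                Na_se=_se(na),
                Rt=float(rt.mean()),
                Ne=float(ne.mean()),
                Ne_se=_se(ne),
                Ho=mean_ho,
                Ho_se=_se(ho),
                He=mean_he,
                He_se=_se(he),
                F=wright_f(mean_ho, mean_he),
                F_se=_se(f_per_locus),
                Np=int(priv.loc[b, "Np"]),
                low_freq_fraction=low_freq_fraction([ft.freqs[l] for l in used],
                                                    low_freq_threshold),
                monomorphic=mean_he == 0.0,
                n_loci_used=len(used),
            )
        )
    df = pd.DataFrame([vars(r) for r in rows]).drop(columns=["extra"])
    num = ["PIC", "P", "Na", "Rt", "Ne", "Ho", "He", "F", "low_freq_fraction"]
    mean_row = {"breed_id": "Mean Breed", "N": int(df["N"].sum())}
    for c in num:
        vals = df[c].to_numpy(dtype=float)
        mean_row[c] = float(np.nanmean(vals))
        mean_row[c + "_se"] = _se(vals)
    mean_row["Np"] = int(df["Np"].sum())
    out = pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
    return out
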