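"""Coancestry-based genetic diversity, its within/between-breed partition,
and breed-removal contribution analysis.

With f_kl the mean molecular coancestry between breeds k and l (f_kk over
within-breed pairs, self-pairs included) and N breeds, total diversity and
its decomposition are

    GD_total = 1 - (1/N^2) sum_k sum_l f_kl
    GD_within = 1 - (1/N) sum_k f_kk
    GD_between = GD_total - GD_within

Each breed's conservation value is measured by recomputing the partition
without it: GD_W and GD_B are the percentage changes of the within and
between components relative to the full-dataset GD_total, and their sum GD_T
is the net percentage change — negative when removing the breed loses
diversity, positive when the remaining dataset is *more* diverse without it
(a redundant or highly inbred breed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coancestry import kinship_matrix
from .diversity import private_alleles
from .genotype_io import MISSING, GenotypeDataset

__all__ = [
    "GDPartition",
    "GDContribution",
    "global_diversity",
    "breed_removal_contributions",
    "allelic_contribution",
]


@dataclass
class GDPartition:
    GD_total: float
    within: float
    between: float
    breed_ids: list[str]
    f_within: np.ndarray       # per-breed f_kk
    f_between: pd.DataFrame    # breed x breed f_kl


@dataclass
class GDContribution:
    breed_id: str
    GD_remaining: float
    GD_W: float   # % change of within component upon removal
    GD_B: float   # % change of between component upon removal
    GD_T: float   # GD_W + GD_B


def global_diversity(dataset: GenotypeDataset, weights: str = "pic") -> GDPartition:
    """Total coancestry-based diversity and its within/between partition."""
    breeds = dataset.breeds
    if len(breeds) < 2:
        raise ValueError("need at least 2 breeds")
    km = kinship_matrix(dataset, weights)
    F = km.values
    k = len(breeds)
    fkl = np.empty((k, k))
    for i, b in enumerate(breeds):
        idx = dataset.breed_indices(b)
        if len(idx) < 2:
            warnings.warn(f"breed {b!r} has a single individual")
        for j, c in enumerate(breeds):
            jdx = dataset.breed_indices(c)
            fkl[i, j] = float(np.nanmean(F[np.ix_(idx, jdx)]))
    gd_total = 1.0 - fkl.mean()
    within = 1.0 - np.diag(fkl).mean()
    return GDPartition(
        GD_total=float(gd_total),
        within=float(within),
        between=float(gd_total - within),
        breed_ids=breeds,
        f_within=np.diag(fkl).copy(),
        f_between=pd.DataFrame(fkl, index=breeds, columns=breeds),
    )


def breed_removal_contributions(dataset: GenotypeDataset, weights: str = "pic") -> pd.DataFrame:
    """One row per breed: the diversity partition after removing it.

    GD_W, GD_B and GD_T are percentages of the full-dataset GD_total; GD_T =
    GD_W + GD_B holds to machine precision before rounding.
    """
    breeds = dataset.breeds
    if len(breeds) < 3:
        raise ValueError("need at least 3 breeds (removal leaves >= 2)")
    full = global_diversity(dataset, weights)
    rows = []
    for b in breeds:
        part = global_diversity(dataset.drop_breed(b), weights)
        gd_w = 100.0 * (part.within - full.within) / full.GD_total
        gd_b = 100.0 * (part.between - full.between) / full.GD_total
        rows.append(
            GDContribution(
                breed_id=b,
                GD_remaining=part.GD_total,
                GD_W=gd_w,
                GD_B=gd_b,
                GD_T=gd_w + gd_b,
            )
        )
    return pd.DataFrame([vars(r) for r in rows])


def allelic_contribution(dataset: GenotypeDataset) -> pd.DataFrame:
    """Private-allele richness per breed as % of all distinct (locus, allele)
    pairs in the dataset, with the carrier percentage."""
    if len(dataset.breeds) < 2:
        raise ValueError("need at least 2 breeds")
    total = 0
    for l in range(dataset.n_loci):
        col = dataset.calls[:, l, :].ravel()
        total += np.unique(col[col != MISSING]).size
    priv = private_alleles(dataset)
    priv["pct_of_global_richness"] = 100.0 * priv["Np"] / total if total else math.nan
    priv["total_alleles"] = total
    return priv
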