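"""Molecular coancestry, kinship summaries, shared-allele proportions and
individual heterozygosity.

Molecular coancestry f_ij between two diploid genotypes (a,b) and (c,d) at a
locus is the probability that one allele drawn from each individual is
identical in state:

    f = (I_ac + I_ad + I_bc + I_bd) / 4

with indicator I = 1 for identical allele codes.  Self-coancestry s_i (f of an
individual with itself) is 1 for a homozygote and 0.5 for a heterozygote, and
gives the molecular inbreeding coefficient F_i = 2 s_i - 1.  Multi-locus
values average the per-locus values over loci typed in both individuals,
either uniformly or weighted by each marker's polymorphic information content
(PIC, computed once on the pooled dataset, renormalized per pair over the
shared loci).

Kinship summaries follow the usual breed-survey nesting: K_IW (individual vs
whole dataset, itself included), K_IB (vs own breed), K_BW (breed mean of
within-breed pairs, self-pairs included — set ``include_self=False`` for the
conventional alternative), K_BB (cross-breed pairs), and K_G = mean K_IW.

PSA, the proportion of shared alleles, is the multiset overlap of the two
genotypes per locus (0, 0.5 or 1), averaged uniformly over co-typed loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import pic as _pic
from .genotype_io import MISSING, POOLED, GenotypeDataset, allele_frequencies

__all__ = [
    "KinshipMatrix",
    "KinshipSummary",
    "HindSummary",
    "pair_coancestry",
    "self_coancestry",
    "kinship_matrix",
    "psa_matrix",
    "hind",
    "kinship_summaries",
    "bootstrap_summary",
]


def pooled_pic_weights(dataset: GenotypeDataset) -> np.ndarray:
    """Per-locus PIC on the pooled dataset, used as marker weights."""
    ft = allele_frequencies(dataset, POOLED)
    w = np.array([_pic(f) if f else 0.0 for f in ft.freqs], dtype=float)
    if not np.any(w > 0):
        # fully monomorphic panel: fall back to uniform weights
        w = np.ones(dataset.n_loci)
    return w


def _locus_weights(dataset: GenotypeDataset, weights: str) -> np.ndarray:
    if weights == "uniform":
        return np.ones(dataset.n_loci)
    if weights == "pic":
        return pooled_pic_weights(dataset)
    raise ValueError(f"weights must be 'uniform' or 'pic', got {weights!r}")


# ---------------------------------------------------------------------------
# pairwise matrices


@dataclass
class KinshipMatrix:
    """Symmetric individual x individual molecular coancestry.

    The diagonal holds self-coancestries s_i in [0.5, 1]; off-diagonal
    entries are pairwise f_ij in [0, 1].  ``values`` is NaN for pairs with no
    co-typed locus.
    """

    individual_ids: list[str]
    values: np.ndarray
    weighting: str


def _per_locus_coancestry(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n, n, L) per-locus coancestry and (n, n, L) co-typed mask."""
    a1 = calls[:, :, 0]  # (n, L)
    a2 = calls[:, :, 1]
    typed = a1 != MISSING
    f = (
        (a1[:, None] == a1[None, :]).astype(np.float64)
        + (a1[:, None] == a2[None, :])
        + (a2[:, None] == a1[None, :])
        + (a2[:, None] == a2[None, :])
    ) / 4.0
    mask = typed[:, None] & typed[None, :]
    return f, mask


def _weighted_mean(per_locus: np.ndarray, mask: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Mask-aware weighted mean over the last (locus) axis."""
    wm = mask * w  # broadcast (n, n, L)
    denom = wm.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (per_locus * wm).sum(axis=-1) / denom
    out[denom == 0] = np.nan
    return out


def kinship_matrix(dataset: GenotypeDataset, weights: str = "pic") -> KinshipMatrix:
    """Full molecular coancestry matrix, self-coancestry on the diagonal."""
    w = _locus_weights(dataset, weights)
    f, mask = _per_locus_coancestry(dataset.calls)
    vals = _weighted_mean(f, mask, w)
    return KinshipMatrix(list(dataset.individual_ids), vals, weights)


def psa_matrix(dataset: GenotypeDataset) -> KinshipMatrix:
    """Pairwise proportion of shared alleles (uniform locus weights)."""
    a1 = dataset.calls[:, :, 0]
    a2 = dataset.calls[:, :, 1]
    typed = a1 != MISSING
    m11 = a1[:, None] == a1[None, :]
    m12 = a1[:, None] == a2[None, :]
    m21 = a2[:, None] == a1[None, :]
    m22 = a2[:, None] == a2[None, :]
    # multiset overlap of two unordered pairs = best of the two matchings
    shared = np.maximum(m11.astype(np.int8) + m22, m12.astype(np.int8) + m21) / 2.0
    mask = typed[:, None] & typed[None, :]
    vals = _weighted_mean(shared, mask, np.ones(dataset.n_loci))
    return KinshipMatrix(list(dataset.individual_ids), vals, "uniform")


def pair_coancestry(
    genotype_i: np.ndarray,
    genotype_j: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Molecular coancestry between two individuals' call arrays (L, 2).

    ``weights`` are per-locus weights (uniform if omitted), renormalized over
    the loci typed in both.  Raises if the pair shares no typed locus.
    """
    gi = np.asarray(genotype_i)
    gj = np.asarray(genotype_j)
    typed = (gi[:, 0] != MISSING) & (gj[:, 0] != MISSING)
    if not typed.any():
        raise ValueError("no locus typed in both individuals")
    if weights is None:
        weights = np.ones(gi.shape[0])
    f = (
        (gi[:, 0] == gj[:, 0]).astype(float)
        + (gi[:, 0] == gj[:, 1])
        + (gi[:, 1] == gj[:, 0])
        + (gi[:, 1] == gj[:, 1])
    ) / 4.0
    w = weights * typed
    return float((f * w).sum() / w.sum())


def self_coancestry(genotype_i: np.ndarray, weights: np.ndarray | None = None) -> tuple[float, float]:
    """(s_i, F_i) for one individual: s = 1 (hom) or 0.5 (het) per locus,
    averaged over typed loci; F_i = 2 s_i - 1."""
    s = pair_coancestry(genotype_i, genotype_i, weights)
    return s, 2.0 * s - 1.0


# ---------------------------------------------------------------------------
# individual heterozygosity


@dataclass
class HindSummary:
    per_individual: pd.DataFrame    # individual_id, breed_id, Hind
    per_breed: pd.DataFrame         # mean, median, SD, SE, min, max


def hind(dataset: GenotypeDataset) -> HindSummary:
    """Individual heterozygosity Hind = heterozygous loci / typed loci,
    with per-breed summary statistics (SD with n-1 denominator)."""
    typed = ~dataset.missing_mask
    het = (dataset.calls[:, :, 0] != dataset.calls[:, :, 1]) & typed
    n_typed = typed.sum(axis=1)
    with np.errstate(invalid="ignore"):
        h = np.where(n_typed > 0, het.sum(axis=1) / np.maximum(n_typed, 1), np.nan)
    per_ind = pd.DataFrame(
        {
            "individual_id": dataset.individual_ids,
            "breed_id": dataset.breed_ids,
            "Hind": h,
            "n_typed_loci": n_typed,
        }
    )
    rows = []
    for b in dataset.breeds:
        v = per_ind.loc[per_ind["breed_id"] == b, "Hind"].dropna().to_numpy()
        rows.append(
            {
                "breed_id": b,
                "mean": float(v.mean()),
                "median": float(np.median(v)),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "se": float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else 0.0,
                "min": float(v.min()),
                "max": float(v.max()),
                "n": int(v.size),
            }
        )
    return HindSummary(per_individual=per_ind, per_breed=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# kinship summaries


@dataclass
class KinshipSummary:
    per_individual: pd.DataFrame   # K_IW, K_IB, s_i, F_i per individual
    per_breed: pd.DataFrame        # K_BW, mean K_BB, I_B, mean PSA per breed
    between: pd.DataFrame          # breed x breed K_BB matrix
    K_G: float
    weighting: str


def kinship_summaries(
    dataset: GenotypeDataset,
    weights: str = "pic",
    include_self: bool = True,
) -> KinshipSummary:
    """Individual, breed and global kinship summaries.

    K_IW and K_IB average an individual's coancestry with every individual of
    the dataset / its breed, itself included.  K_BW averages all within-breed
    pairs (self-pairs included unless ``include_self=False``); K_BB averages
    all cross-breed pairs; K_G is the mean K_IW.  Mean PSA per breed excludes
    self-pairs.
    """
    km = kinship_matrix(dataset, weights)
    pm = psa_matrix(dataset)
    F = km.values
    n = dataset.n_individuals
    breeds = dataset.breeds
    breed_arr = np.asarray(dataset.breed_ids)

    k_iw = np.nanmean(F, axis=1)
    s_i = np.diag(F)
    k_ib = np.empty(n)
    for b in breeds:
        idx = dataset.breed_indices(b)
        k_ib[idx] = np.nanmean(F[np.ix_(idx, np.arange(n))][:, idx], axis=1)

    per_ind = pd.DataFrame(
        {
            "individual_id": dataset.individual_ids,
            "breed_id": dataset.breed_ids,
            "K_IW": k_iw,
            "K_IB": k_ib,
            "s_i": s_i,
            "F_i": 2 * s_i - 1,
        }
    )

    kbb = np.full((len(breeds), len(breeds)), np.nan)
    rows = []
    for bi, b in enumerate(breeds):
        idx = dataset.breed_indices(b)
        block = F[np.ix_(idx, idx)]
        psa_block = pm.values[np.ix_(idx, idx)]
        if include_self:
            k_bw = float(np.nanmean(block))
        else:
            off = ~np.eye(len(idx), dtype=bool)
            k_bw = float(np.nanmean(block[off])) if len(idx) > 1 else math.nan
        off = ~np.eye(len(idx), dtype=bool)
        mean_psa = float(np.nanmean(psa_block[off])) if len(idx) > 1 else math.nan
        for bj, c in enumerate(breeds):
            if bj == bi:
                kbb[bi, bj] = k_bw
                continue
            jdx = dataset.breed_indices(c)
            kbb[bi, bj] = float(np.nanmean(F[np.ix_(idx, jdx)]))
        others = [kbb[bi, bj] for bj in range(len(breeds)) if bj != bi]
        rows.append(
            {
                "breed_id": b,
                "K_BW": k_bw,
                "K_BB_mean": float(np.mean(others)) if others else math.nan,
                "I_B": float(np.nanmean(s_i[idx])),
                "mean_PSA": mean_psa,
                "n": len(idx),
            }
        )
    return KinshipSummary(
        per_individual=per_ind,
        per_breed=pd.DataFrame(rows),
        between=pd.DataFrame(kbb, index=breeds, columns=breeds),
        K_G=float(np.nanmean(k_iw)),
        weighting=weights,
    )


# ---------------------------------------------------------------------------
# bootstrap


def resample_within_breeds(
    dataset: GenotypeDataset, sample_size: int, rng: np.random.Generator
) -> GenotypeDataset:
    """Resample every breed to ``sample_size`` individuals with replacement
    (the size adjustment that removes unequal-sample-size bias)."""
    rows: list[int] = []
    for b in dataset.breeds:
        idx = dataset.breed_indices(b)
        rows.extend(rng.choice(idx, size=sample_size, replace=True))
    ids = [f"bs{k}_{dataset.individual_ids[i]}" for k, i in enumerate(rows)]
    return dataset.subset(np.asarray(rows), ids=ids)


def bootstrap_summary(
    dataset: GenotypeDataset,
    statistic,
    n_boot: int = 100,
    sample_size: int = 50,
    seed: int | None = None,
) -> dict:
    """Bootstrap mean and standard error of ``statistic(dataset)``.

    Each replicate resamples individuals within each breed with replacement
    to ``sample_size`` and recomputes the statistic (a callable returning a
    float).  Seed-reproducible.
    """
    if sample_size < 2:
        raise ValueError("sample_size must be >= 2")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for r in range(n_boot):
        vals[r] = statistic(resample_within_breeds(dataset, sample_size, rng))
    return {
        "mean": float(vals.mean()),
        "se": float(vals.std(ddof=1)) if n_boot > 1 else 0.0,
        "replicates": vals,
    }
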