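"""Wright's F-statistics for a breed-partitioned dataset.

The headline fixation indices use the gene-diversity (Nei-style) hierarchy:
per locus, with breeds weighted equally regardless of sample size,

    H_O = mean over breeds of observed heterozygosity,
    H_S = mean over breeds of within-breed expected heterozygosity,
    H_T = expected heterozygosity of the breed-averaged allele frequencies,

    F_IS = (H_S - H_O) / H_S,   F_ST = (H_T - H_S) / H_T,
    F_IT = (H_T - H_O) / H_T,

which satisfy (1 - F_IT) = (1 - F_IS)(1 - F_ST) exactly per locus.  Global
values are PIC-weighted means over loci; uncertainty comes from a bootstrap
that resamples each breed to a fixed size (removing unequal-sample-size
bias), with a one-sided bootstrap p-value (fraction of replicates at or
below zero).

Pairwise differentiation additionally uses the Weir–Cockerham
variance-components estimator (theta), combined across alleles and loci as a
ratio of sums.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coancestry import _locus_weights, resample_within_breeds
from .diversity import expected_het, observed_het
from .genotype_io import MISSING, GenotypeDataset, allele_frequencies

__all__ = ["FStatReport", "f_statistics", "pairwise_fst", "fst_from_frequencies"]


@dataclass
class FStatReport:
    per_locus: pd.DataFrame     # locus, H_O, H_S, H_T, F_IS, F_ST, F_IT, weight
    global_: dict               # F_IS/F_ST/F_IT point estimates
    bootstrap: pd.DataFrame | None   # statistic, mean, se, p_value
    pairwise: pd.DataFrame | None    # breed x breed F_ST (Weir-Cockerham)
    weighting: str


def _breed_frequency_arrays(dataset: GenotypeDataset):
    """Per-locus allele code list plus (n_breeds, n_alleles) frequency and
    observed-het arrays."""
    breeds = dataset.breeds
    tables = [allele_frequencies(dataset, b) for b in breeds]
    out = []
    for l, locus in enumerate(dataset.loci):
        codes = sorted({a for t in tables for a in t.freqs[l]})
        P = np.zeros((len(breeds), len(codes)))
        ho = np.full(len(breeds), np.nan)
        typed = np.zeros(len(breeds), dtype=bool)
        for bi, (b, t) in enumerate(zip(breeds, tables)):
            if t.gene_copies[l] == 0:
                continue
            typed[bi] = True
            for ai, a in enumerate(codes):
                P[bi, ai] = t.freqs[l].get(a, 0.0)
            ho[bi] = observed_het(dataset, b, locus)
        out.append((codes, P, ho, typed))
    return out


def _locus_hierarchy(P: np.ndarray, ho: np.ndarray, typed: np.ndarray):
    """(H_O, H_S, H_T) for one locus from per-breed frequencies."""
    P = P[typed]
    ho = ho[typed]
    h_o = float(np.nanmean(ho))
    h_s = float(np.mean(1.0 - (P ** 2).sum(axis=1)))
    pbar = P.mean(axis=0)
    h_t = float(1.0 - (pbar ** 2).sum())
    return h_o, h_s, h_t


def fst_from_frequencies(freqs_by_breed: list[list[dict[int, float]]]) -> float:
    """Gene-diversity global F_ST from per-breed, per-locus frequency maps
    (ratio of summed H_T - H_S over summed H_T across loci).

    Accepts the output of a null-allele correction, where no genotype-level
    data exist any more.
    """
    num = den = 0.0
    n_loci = len(freqs_by_breed[0])
    for l in range(n_loci):
        maps = [fb[l] for fb in freqs_by_breed if fb[l]]
        if len(maps) < 2:
            continue
        codes = sorted({a for m in maps for a in m})
        P = np.array([[m.get(a, 0.0) for a in codes] for m in maps])
        h_s = float(np.mean(1.0 - (P ** 2).sum(axis=1)))
        pbar = P.mean(axis=0)
        h_t = float(1.0 - (pbar ** 2).sum())
        num += h_t - h_s
        den += h_t
    if den == 0:
        return math.nan
    return num / den


def _point_fstats(dataset: GenotypeDataset, weights: str) -> tuple[pd.DataFrame, dict]:
    w = _locus_weights(dataset, weights)
    rows = []
    for l, (codes, P, ho, typed) in enumerate(_breed_frequency_arrays(dataset)):
        if typed.sum() < 2:
            warnings.warn(f"locus {dataset.loci[l]!r}: fewer than 2 breeds typed; skipped")
            continue
        h_o, h_s, h_t = _locus_hierarchy(P, ho, typed)
        if h_t == 0.0:
            warnings.warn(f"locus {dataset.loci[l]!r} monomorphic across breeds; skipped")
            continue
        rows.append(
            {
                "locus": dataset.loci[l],
                "H_O": h_o,
                "H_S": h_s,
                "H_T": h_t,
                "F_IS": (h_s - h_o) / h_s if h_s > 0 else math.nan,
                "F_ST": (h_t - h_s) / h_t,
                "F_IT": (h_t - h_o) / h_t,
                "weight": w[l],
            }
        )
    per_locus = pd.DataFrame(rows)
    if per_locus.empty:
        raise ValueError("no polymorphic locus; F-statistics undefined")
    wl = per_locus["weight"].to_numpy()
    glob = {}
    for stat in ("F_IS", "F_ST", "F_IT"):
        v = per_locus[stat].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if ok.any() and wl[ok].sum() > 0:
            glob[stat] = float((v[ok] * wl[ok]).sum() / wl[ok].sum())
        else:
            glob[stat] = math.nan
    return per_locus, glob


def f_statistics(
    dataset: GenotypeDataset,
    weights: str = "pic",
    n_boot: int = 100,
    sample_size: int = 50,
    seed: int | None = None,
    pairwise: bool = True,
) -> FStatReport:
    """Per-locus and global F_IS/F_ST/F_IT with size-adjusted bootstrap.

    Set ``n_boot=0`` to skip the bootstrap, ``pairwise=False`` to skip the
    Weir–Cockerham pairwise matrix.
    """
    if len(dataset.breeds) < 2:
        raise ValueError("F-statistics need at least 2 breeds")
    per_locus, glob = _point_fstats(dataset, weights)

    boot = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = {"F_IS": [], "F_ST": [], "F_IT": []}
        for _ in range(n_boot):
            rs = resample_within_breeds(dataset, sample_size, rng)
            try:
                _, g = _point_fstats(rs, weights)
            except ValueError:
                continue
            for k in reps:
                reps[k].append(g[k])
        rows = []
        for k, v in reps.items():
            v = np.asarray(v)
            rows.append(
                {
                    "statistic": k,
                    "point": glob[k],
                    "boot_mean": float(v.mean()),
                    "boot_se": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                    # one-sided: evidence the index exceeds zero
                    "p_value": float((v <= 0).mean()) if v.size else math.nan,
                    "n_reps": int(v.size),
                }
            )
        boot = pd.DataFrame(rows)

    pw = pairwise_fst(dataset) if pairwise else None
    return FStatReport(per_locus=per_locus, global_=glob, bootstrap=boot,
                       pairwise=pw, weighting=weights)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta


def _wc_components(dataset: GenotypeDataset, breed_pair: tuple[str, str]):
    """Summed Weir–Cockerham a and a+b+c components over alleles and loci."""
    sum_a = sum_abc = 0.0
    breeds = list(breed_pair)
    r = len(breeds)
    for l in range(dataset.n_loci):
        n_i = []
        p_i = []
        h_i = []
        codes: set[int] = set()
        data = []
        for b in breeds:
            rows = dataset.breed_indices(b)
            calls = dataset.calls[rows, l, :]
            calls = calls[calls[:, 0] != MISSING]
            data.append(calls)
            codes.update(np.unique(calls).tolist())
        codes.discard(MISSING)
        if len(codes) < 2:
            continue
        if any(len(c) == 0 for c in data):
            continue
        codes = sorted(codes)
        for calls in data:
            n = len(calls)
            n_i.append(n)
            freq = np.array(
                [np.count_nonzero(calls == a) / (2 * n) for a in codes]
            )
            hetf = np.array(
                [
                    np.count_nonzero(
                        (calls[:, 0] != calls[:, 1])
                        & ((calls[:, 0] == a) | (calls[:, 1] == a))
                    )
                    / n
                    for a in codes
                ]
            )
            p_i.append(freq)
            h_i.append(hetf)
        n_i = np.asarray(n_i, dtype=float)
        p_i = np.asarray(p_i)      # (r, n_alleles)
        h_i = np.asarray(h_i)
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        pbar = (n_i[:, None] * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i[:, None] * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        sum_a += a.sum()
        sum_abc += (a + b + c).sum()
    return sum_a, sum_abc


def pairwise_fst(dataset: GenotypeDataset) -> pd.DataFrame:
    """Breed x breed Weir–Cockerham theta, multi-locus ratio of sums;
    diagonal zero, NaN where theta is undefined (no shared polymorphism)."""
    breeds = dataset.breeds
    if len(breeds) < 2:
        raise ValueError("need at least 2 breeds")
    M = np.zeros((len(breeds), len(breeds)))
    for i in range(len(breeds)):
        for j in range(i + 1, len(breeds)):
            a, abc = _wc_components(dataset, (breeds[i], breeds[j]))
            M[i, j] = M[j, i] = a / abc if abc > 0 else np.nan
    return pd.DataFrame(M, index=breeds, columns=breeds)
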