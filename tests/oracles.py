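"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive — double loops, full enumeration,
generic optimizers — and shares no code with the package's vectorized or
iterative implementations.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
from scipy.optimize import minimize


# ---------------------------------------------------------------------------
# coancestry / PSA by explicit indicator sums


def naive_pair_coancestry(gi, gj, weights=None):
    """f_ij by literal indicator averaging over co-typed loci."""
    L = len(gi)
    if weights is None:
        weights = [1.0] * L
    num = den = 0.0
    for l in range(L):
        (a, b), (c, d) = [int(x) for x in gi[l]], [int(x) for x in gj[l]]
        if 0 in (a, b) or 0 in (c, d):
            continue
        f = (int(a == c) + int(a == d) + int(b == c) + int(b == d)) / 4.0
        num += weights[l] * f
        den += weights[l]
    return num / den if den else math.nan


def naive_psa(gi, gj):
    """Proportion of shared alleles by multiset intersection per locus."""
    vals = []
    for (a, b), (c, d) in zip(gi, gj):
        if 0 in (a, b) or 0 in (c, d):
            continue
        inter = Counter([a, b]) & Counter([c, d])
        vals.append(sum(inter.values()) / 2.0)
    return sum(vals) / len(vals)


def naive_kinship_summaries(genotypes, breed_of, weights=None):
    """K_IW, K_IB, K_BW, K_BB, K_G by explicit pair enumeration.

    ``genotypes`` is a list of per-individual call lists; self-pairs are
    included everywhere except PSA means, mirroring the package policy.
    """
    n = len(genotypes)
    f = [[naive_pair_coancestry(genotypes[i], genotypes[j], weights)
          for j in range(n)] for i in range(n)]
    breeds = list(dict.fromkeys(breed_of))
    k_iw = [sum(f[i]) / n for i in range(n)]
    k_ib = []
    for i in range(n):
        mem = [j for j in range(n) if breed_of[j] == breed_of[i]]
        k_ib.append(sum(f[i][j] for j in mem) / len(mem))
    k_bw = {}
    kbb = {}
    for b in breeds:
        mem = [i for i in range(n) if breed_of[i] == b]
        k_bw[b] = sum(f[i][j] for i in mem for j in mem) / len(mem) ** 2
        for c in breeds:
            if c == b:
                continue
            oth = [i for i in range(n) if breed_of[i] == c]
            kbb[(b, c)] = sum(f[i][j] for i in mem for j in oth) / (
                len(mem) * len(oth)
            )
    return {
        "f": f,
        "K_IW": k_iw,
        "K_IB": k_ib,
        "K_BW": k_bw,
        "K_BB": kbb,
        "K_G": sum(k_iw) / n,
    }


def naive_gd_partition(genotypes, breed_of, weights=None):
    """GD_total / within / between from the brute-force f matrix."""
    s = naive_kinship_summaries(genotypes, breed_of, weights)
    breeds = list(dict.fromkeys(breed_of))
    N = len(breeds)
    fkl = {}
    for b in breeds:
        fkl[(b, b)] = s["K_BW"][b]
        for c in breeds:
            if c != b:
                fkl[(b, c)] = s["K_BB"][(b, c)]
    gd_total = 1 - sum(fkl[(b, c)] for b in breeds for c in breeds) / N ** 2
    within = 1 - sum(fkl[(b, b)] for b in breeds) / N
    return gd_total, within, gd_total - within


# ---------------------------------------------------------------------------
# HWE: full enumeration of genotype tables with fixed allele counts


def enumerate_hwe_tables(counts):
    """All genotype tables sharing the observed allele counts, with their
    conditional probabilities under random pairing."""
    copies = []
    for (a, b), c in counts.items():
        copies += [a, b] * c
    n = len(copies) // 2
    allele_counts = Counter(copies)
    alleles = sorted(allele_counts)
    pairs = [(a, b) for i, a in enumerate(alleles) for b in alleles[i:]]
    tables = []

    def rec(i, remaining, table):
        if i == len(pairs):
            if all(v == 0 for v in remaining.values()):
                tables.append(dict(table))
            return
        a, b = pairs[i]
        if a == b:
            maxc = remaining[a] // 2
        else:
            maxc = min(remaining[a], remaining[b])
        for c in range(maxc + 1):
            remaining[a] -= c * 2 if a == b else c
            if a != b:
                remaining[b] -= c
            if c:
                table[(a, b)] = c
            rec(i + 1, remaining, table)
            remaining[a] += c * 2 if a == b else c
            if a != b:
                remaining[b] += c
            table.pop((a, b), None)

    rec(0, dict(allele_counts), {})
    weighted = []
    for t in tables:
        if sum(t.values()) != n:
            continue
        h = sum(c for (a, b), c in t.items() if a != b)
        lw = h * math.log(2) - sum(math.lgamma(c + 1) for c in t.values())
        weighted.append((t, h, lw))
    z = sum(math.exp(lw) for _, _, lw in weighted)
    return [(t, h, math.exp(lw) / z) for t, h, lw in weighted]


def exact_hwe_p(counts, alternative="deficit"):
    """Exact tail probability over the full table enumeration."""
    obs_het = sum(c for (a, b), c in counts.items() if a != b)
    total = 0.0
    for t, h, p in enumerate_hwe_tables(counts):
        if alternative == "deficit" and h <= obs_het:
            total += p
        elif alternative == "excess" and h >= obs_het:
            total += p
    return total


# ---------------------------------------------------------------------------
# rarefaction by exhaustive subsampling


def exhaustive_rarefaction(copy_counts, k):
    """Mean distinct-allele count over all C(N, k) copy subsamples."""
    copies = []
    for a, c in copy_counts.items():
        copies += [a] * c
    vals = [len(set(sub)) for sub in itertools.combinations(copies, k)]
    return sum(vals) / len(vals)


# ---------------------------------------------------------------------------
# null-allele likelihood maximized by a generic optimizer


def ml_null_frequency(counts):
    """Maximize the visible-genotype likelihood over (p, r) directly."""
    alleles = sorted({x for ab in counts for x in ab})
    k = len(alleles)
    idx = {a: i for i, a in enumerate(alleles)}
    n = sum(counts.values())

    def negll(theta):
        w = np.exp(theta - theta.max())
        q = w / w.sum()          # softmax over k visible + 1 null class
        p, r = q[:k], q[k]
        ll = -n * math.log1p(-(r ** 2))
        for (a, b), c in counts.items():
            if a == b:
                ll += c * math.log(p[idx[a]] ** 2 + 2 * p[idx[a]] * r + 1e-300)
            else:
                ll += c * math.log(2 * p[idx[a]] * p[idx[b]] + 1e-300)
        return -ll

    best = None
    for s in range(5):
        x0 = np.random.default_rng(s).normal(size=k + 1)
        res = minimize(negll, x0, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    w = np.exp(best.x - best.x.max())
    q = w / w.sum()
    return float(q[k]), -float(best.fun)
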