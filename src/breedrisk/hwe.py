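"""Exact Hardy–Weinberg tests by Monte-Carlo Markov chain.

The test conditions on the observed allele counts: under HWE every pairing of
the 2n gene copies into n genotypes is equally likely, which induces the
classical conditional distribution over genotype tables

    P(T | allele counts) = n! * prod_a m_a! * 2^H / ((2n)! * prod t_ab!)

with H heterozygotes.  The chain operates directly on an arrangement of the
2n gene copies into n pairs and proposes a swap of two uniformly chosen slot
positions — a symmetric proposal with a uniform stationary law over
arrangements, hence the induced table distribution is exactly the HWE
conditional one and every move is accepted.  This sidesteps the delicate
acceptance-ratio bookkeeping of table-switch samplers.

The one-sided deficit (excess) p-value is the probability of a table with at
most (at least) as many heterozygotes as observed; the global alternative
uses the table-probability tail.  P-values are averaged over batches with a
between-batch Monte-Carlo standard error, matching the classic
dememorization / batches / iterations-per-batch protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeDataset

__all__ = [
    "HWEResult",
    "genotype_counts",
    "hwe_exact_mc",
    "hwe_global",
    "hwe_table",
]


@dataclass
class HWEResult:
    breed_id: str
    locus_id: str
    p_value: float
    mc_se: float
    alternative: str
    monomorphic: bool = False
    chain: dict = field(default_factory=dict)


def genotype_counts(dataset: GenotypeDataset, breed_id: str, locus: str) -> dict[tuple[int, int], int]:
    """Genotype table {(a, b): count} with a <= b for one breed x locus."""
    rows = dataset.breed_indices(breed_id)
    l = dataset.loci.index(locus)
    calls = dataset.calls[rows, l, :]
    calls = calls[calls[:, 0] != MISSING]
    out: dict[tuple[int, int], int] = {}
    for a, b in calls:
        key = (int(a), int(b))
        out[key] = out.get(key, 0) + 1
    return out


def _het_count(counts: dict[tuple[int, int], int]) -> int:
    return sum(c for (a, b), c in counts.items() if a != b)


def _log_table_prob(counts: dict[tuple[int, int], int]) -> float:
    """log P(T | allele counts) up to a table-independent constant."""
    h = _het_count(counts)
    return h * math.log(2.0) - sum(math.lgamma(c + 1) for c in counts.values())


def hwe_exact_mc(
    genotype_counts: dict[tuple[int, int], int],
    alternative: str = "deficit",
    dememorization: int = 10000,
    batches: int = 500,
    iterations: int = 5000,
    seed: int | None = None,
    breed_id: str = "",
    locus_id: str = "",
) -> HWEResult:
    """Monte-Carlo exact HWE test for one genotype table.

    ``alternative`` is ``"deficit"`` (heterozygote deficiency, the usual H1
    in inbreeding surveys), ``"excess"``, or ``"global"`` (probability
    test).  The defaults mirror the customary chain protocol of 10,000
    dememorization steps and 500 batches of 5,000 iterations.
    """
    if alternative not in ("deficit", "excess", "global"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if dememorization <= 0 or batches <= 0 or iterations <= 0:
        raise ValueError("chain parameters must be positive")
    counts = {(min(a, b), max(a, b)): c for (a, b), c in genotype_counts.items()}
    alleles = sorted({x for ab in counts for x in ab})
    n = sum(counts.values())
    if n == 0:
        raise ValueError("empty genotype table")
    if len(alleles) < 2:
        return HWEResult(breed_id, locus_id, 1.0, 0.0, alternative, monomorphic=True)

    # arrangement of the 2n gene copies; slots (2i, 2i+1) form genotype i
    arr = np.empty(2 * n, dtype=np.int64)
    k = 0
    for (a, b), c in counts.items():
        for _ in range(c):
            arr[k], arr[k + 1] = a, b
            k += 2
    arr = arr.tolist()

    obs_het = _het_count(counts)
    if alternative == "global":
        obs_logp = _log_table_prob(counts)
        table = dict(counts)
        sum_lgam = sum(math.lgamma(c + 1) for c in table.values())

    het = obs_het
    rng = np.random.default_rng(seed)
    total_steps = dememorization + batches * iterations
    # pre-drawn proposal positions, in blocks to bound memory
    BLOCK = 1 << 18

    def step_stream():
        remaining = total_steps
        while remaining > 0:
            m = min(BLOCK, remaining)
            idx = rng.integers(0, 2 * n, size=(m, 2))
            yield from map(tuple, idx)
            remaining -= m

    eps = math.log(2.0) * 1e-9  # tie tolerance on log-probabilities
    batch_hits = np.zeros(batches)
    stream = step_stream()
    step_no = 0
    batch = -1
    hits = 0
    for (i, j) in stream:
        pi, pj = i >> 1, j >> 1
        if pi != pj and arr[i] != arr[j]:
            if alternative == "global":
                for p in (pi, pj):
                    a, b = arr[2 * p], arr[2 * p + 1]
                    key = (a, b) if a <= b else (b, a)
                    c = table[key]
                    sum_lgam -= math.lgamma(c + 1) - math.lgamma(c)
                    if c == 1:
                        del table[key]
                    else:
                        table[key] = c - 1
            if arr[2 * pi] != arr[2 * pi + 1]:
                het -= 1
            if arr[2 * pj] != arr[2 * pj + 1]:
                het -= 1
            arr[i], arr[j] = arr[j], arr[i]
            if arr[2 * pi] != arr[2 * pi + 1]:
                het += 1
            if arr[2 * pj] != arr[2 * pj + 1]:
                het += 1
            if alternative == "global":
                for p in (pi, pj):
                    a, b = arr[2 * p], arr[2 * p + 1]
                    key = (a, b) if a <= b else (b, a)
                    c = table.get(key, 0)
                    sum_lgam += math.lgamma(c + 2) - math.lgamma(c + 1)
                    table[key] = c + 1
        step_no += 1
        if step_no <= dememorization:
            continue
        k = step_no - dememorization - 1
        b_idx = k // iterations
        if b_idx != batch:
            batch = b_idx
            hits = 0
        if alternative == "deficit":
            extreme = het <= obs_het
        elif alternative == "excess":
            extreme = het >= obs_het
        else:
            logp = het * math.log(2.0) - sum_lgam
            extreme = logp <= obs_logp + eps
        if extreme:
            hits += 1
        if (k + 1) % iterations == 0:
            batch_hits[batch] = hits / iterations

    p = float(batch_hits.mean())
    se = float(batch_hits.std(ddof=1) / math.sqrt(batches)) if batches > 1 else 0.0
    return HWEResult(
        breed_id,
        locus_id,
        p,
        se,
        alternative,
        chain={
            "dememorization": dememorization,
            "batches": batches,
            "iterations": iterations,
            "seed": seed,
        },
    )


def hwe_global(results: list[HWEResult]) -> dict:
    """Fisher combination of per-test p-values: -2 sum ln p ~ chi2(2k).

    Monomorphic entries carry no information and are skipped; if everything
    is monomorphic the combined p is undefined (NaN, flagged).
    """
    ps = [r.p_value for r in results if not r.monomorphic and np.isfinite(r.p_value)]
    if not ps:
        return {"p_value": math.nan, "k": 0, "all_monomorphic": True}
    # Monte-Carlo p-values can be exactly 0; floor at one chain sample
    ps = [max(p, 1e-12) for p in ps]
    x = -2.0 * sum(math.log(p) for p in ps)
    return {
        "p_value": float(stats.chi2.sf(x, df=2 * len(ps))),
        "statistic": x,
        "k": len(ps),
        "all_monomorphic": False,
    }


def hwe_table(
    dataset: GenotypeDataset,
    alternative: str = "deficit",
    dememorization: int = 10000,
    batches: int = 500,
    iterations: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Breed x locus exact-test p-values, with per-breed Fisher-combined
    global p and the count of loci deviating at ``alpha``."""
    ss = np.random.SeedSequence(seed)
    rows = []
    results: dict[str, list[HWEResult]] = {}
    for b in dataset.breeds:
        results[b] = []
        for locus in dataset.loci:
            child = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            r = hwe_exact_mc(
                genotype_counts(dataset, b, locus),
                alternative=alternative,
                dememorization=dememorization,
                batches=batches,
                iterations=iterations,
                seed=child,
                breed_id=b,
                locus_id=locus,
            )
            results[b].append(r)
            rows.append(
                {
                    "breed_id": b,
                    "locus": locus,
                    "p_value": r.p_value,
                    "mc_se": r.mc_se,
                    "monomorphic": r.monomorphic,
                }
            )
    df = pd.DataFrame(rows)
    glob = []
    for b in dataset.breeds:
        g = hwe_global(results[b])
        n_dev = sum(
            1 for r in results[b] if not r.monomorphic and r.p_value < alpha
        )
        glob.append(
            {
                "breed_id": b,
                "global_p": g["p_value"],
                "n_loci_deviating": n_dev,
            }
        )
    df.attrs["per_breed_global"] = pd.DataFrame(glob)
    return df
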