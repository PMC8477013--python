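"""Extinction Risk Index (ERI): a composite score for breed prioritization.

ERI sums five unit-bounded per-breed statistics, each increasing with loss
of variability:

    ERI = F + I_B + K_BW + PSA + O

* F     — Wright's inbreeding coefficient 1 - Ho/He (homozygote excess),
* I_B   — mean self-coancestry (molecular inbreeding level),
* K_BW  — mean within-breed molecular kinship,
* PSA   — mean within-breed proportion of shared alleles,
* O     — homozygosity, 1 - Ho.

The score ranges 0–5 when F >= 0.  A breed scoring above 2.5 is flagged at
risk; scores in [2.0, 2.5] are intermediate; below 2.0 the breed is
considered safe.  The 2.5 midpoint is a convention, not an estimated
threshold, and is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .coancestry import kinship_summaries
from .diversity import breed_summary_table
from .genotype_io import GenotypeDataset

__all__ = ["ERIRecord", "eri_score", "classify_risk", "eri_table"]

COMPONENTS = ("F", "I_B", "K_BW", "PSA", "O")


@dataclass
class ERIRecord:
    breed_id: str
    F: float
    I_B: float
    K_BW: float
    PSA: float
    O: float
    ERI: float
    risk_class: str
    recoverable_het: bool = False   # He > Ho: variability a mating plan could recover


def classify_risk(eri_value: float, threshold: float = 2.5,
                  lower: float = 2.0) -> str:
    """Risk band for an ERI value: > threshold -> 'at_risk'; [lower,
    threshold] -> 'intermediate' (both ends closed); below -> 'ok'."""
    if not math.isfinite(eri_value):
        raise ValueError("ERI must be finite")
    if eri_value > threshold:
        return "at_risk"
    if eri_value >= lower:
        return "intermediate"
    return "ok"


def eri_score(
    components: dict[str, float],
    breed_id: str = "",
    clip_f: bool = False,
    threshold: float = 2.5,
    lower: float = 2.0,
) -> ERIRecord:
    """Sum the five named components into an ERI record.

    ``clip_f=True`` floors a negative F (heterozygote excess) at zero,
    preserving the nominal 0–5 range; by default F enters as-is.
    """
    missing = [c for c in COMPONENTS if c not in components]
    if missing:
        raise ValueError(f"missing ERI component(s): {', '.join(missing)}")
    vals = {c: float(components[c]) for c in COMPONENTS}
    for c, v in vals.items():
        if not math.isfinite(v):
            raise ValueError(f"ERI component {c} is not finite: {v}")
    if clip_f:
        vals["F"] = max(vals["F"], 0.0)
    eri = sum(vals.values())
    return ERIRecord(
        breed_id=breed_id,
        **vals,
        ERI=eri,
        risk_class=classify_risk(eri, threshold, lower),
    )


def eri_table(
    dataset: GenotypeDataset,
    clip_f: bool = False,
    threshold: float = 2.5,
    lower: float = 2.0,
    rarefaction_g: int | None = None,
) -> pd.DataFrame:
    """ERI for every breed, sorted by descending score.

    Components are pulled from the diversity table (F and Ho with uniform
    locus weights) and the kinship summaries (I_B and K_BW PIC-weighted,
    PSA uniform), matching how each statistic is conventionally reported.
    """
    summary = breed_summary_table(dataset, rarefaction_g=rarefaction_g)
    summary = summary[summary["breed_id"] != "Mean Breed"].set_index("breed_id")
    kin = kinship_summaries(dataset, weights="pic").per_breed.set_index("breed_id")
    records = []
    for b in dataset.breeds:
        rec = eri_score(
            {
                "F": summary.loc[b, "F"],
                "I_B": kin.loc[b, "I_B"],
                "K_BW": kin.loc[b, "K_BW"],
                "PSA": kin.loc[b, "mean_PSA"],
                "O": 1.0 - summary.loc[b, "Ho"],
            },
            breed_id=b,
            clip_f=clip_f,
            threshold=threshold,
            lower=lower,
        )
        rec.recoverable_het = bool(summary.loc[b, "He"] > summary.loc[b, "Ho"])
        records.append(rec)
    df = pd.DataFrame([vars(r) for r in records])
    return df.sort_values("ERI", ascending=False, ignore_index=True)
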