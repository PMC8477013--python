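"""Reading, writing and validating multi-locus codominant genotype datasets.

The central container is :class:`GenotypeDataset`: diploid allele-pair calls
(positive integer allele codes, e.g. microsatellite fragment sizes) for a set
of individuals partitioned into breeds.  Two on-disk dialects are supported:

* ``genepop`` — the classic Genepop text format (header line, one locus name
  per line, ``pop`` separators, 2- or 3-digit diploid codes, ``00``/``000``
  for missing).
* ``table``  — a delimited table with columns ``individual_id``, ``breed_id``
  followed by two columns per locus; a configurable sentinel (default ``0``)
  marks missing calls.

Allele codes are kept verbatim; no binning or recoding is performed — allele
calling is upstream laboratory work.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "POOLED",
    "GenotypeDataset",
    "AlleleFrequencyTable",
    "GenotypeParseError",
    "GenotypeFormatError",
    "GenotypeValidationError",
    "read_genotypes",
    "write_genotypes",
    "allele_frequencies",
]

#: Internal sentinel for a missing diploid call (both slots).
MISSING = 0

#: Scope label for statistics over the whole dataset rather than one breed.
POOLED = "POOLED"


class GenotypeParseError(ValueError):
    """A line of an input file could not be decoded."""


class GenotypeFormatError(ValueError):
    """The file structure (not a single line) violates the dialect."""


class GenotypeValidationError(ValueError):
    """The decoded dataset violates a container invariant."""


@dataclass
class GenotypeDataset:
    """Individuals x loci diploid calls with a breed partition.

    Parameters
    ----------
    individual_ids, breed_ids
        Parallel sequences, one entry per individual.
    loci
        Locus identifiers, one per marker.
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)``.  Allele codes
        are positive; a missing call has ``0`` in both slots (half-calls are
        rejected).  Call pairs are unordered: ``(1, 2)`` and ``(2, 1)`` are
        the same genotype (codominant markers carry no phase).
    """

    individual_ids: list[str]
    breed_ids: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individual_ids), len(self.loci)
        if len(self.breed_ids) != n:
            raise GenotypeValidationError("breed_ids and individual_ids differ in length")
        if self.calls.shape != (n, L, 2):
            raise GenotypeValidationError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if n < 2 or L < 1:
            raise GenotypeValidationError("need at least 2 individuals and 1 locus")
        if len(set(self.individual_ids)) != n:
            dupes = pd.Series(self.individual_ids).value_counts()
            raise GenotypeValidationError(
                f"duplicate individual_id: {dupes[dupes > 1].index.tolist()}"
            )
        if (self.calls < 0).any():
            raise GenotypeValidationError("allele codes must be positive (0 = missing)")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise GenotypeValidationError(
                f"half-missing call for individual {self.individual_ids[i]!r} "
                f"at locus {self.loci[l]!r}; MISSING applies to the whole call"
            )
        # canonical order within a pair: makes equality and round trips stable
        self.calls = np.sort(self.calls, axis=2)

    # -- basic views ------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def breeds(self) -> list[str]:
        """Breed labels in first-appearance order."""
        return list(dict.fromkeys(self.breed_ids))

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` array, True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def breed_indices(self, breed_id: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.breed_ids) == breed_id)
        if idx.size == 0:
            raise KeyError(f"unknown breed {breed_id!r}")
        return idx

    def subset(self, individuals: Sequence[int] | np.ndarray,
               ids: Sequence[str] | None = None) -> "GenotypeDataset":
        """Row subset (e.g. one breed, or a bootstrap resample).

        ``ids`` overrides individual identifiers, which is required when the
        same row is sampled more than once.
        """
        individuals = np.asarray(individuals)
        if ids is None:
            ids = [self.individual_ids[i] for i in individuals]
        return GenotypeDataset(
            individual_ids=list(ids),
            breed_ids=[self.breed_ids[i] for i in individuals],
            loci=list(self.loci),
            calls=self.calls[individuals].copy(),
        )

    def drop_breed(self, breed_id: str) -> "GenotypeDataset":
        keep = np.flatnonzero(np.asarray(self.breed_ids) != breed_id)
        if keep.size == self.n_individuals:
            raise KeyError(f"unknown breed {breed_id!r}")
        return self.subset(keep)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.breed_ids == other.breed_ids
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class AlleleFrequencyTable:
    """Relative allele frequencies per locus for one breed or the pooled set.

    ``freqs[l]`` maps allele code -> relative frequency at locus ``l``;
    ``gene_copies[l]`` is the (even) number of non-missing allele copies the
    frequencies were computed from.  A locus with no data has an empty map
    and zero copies.
    """

    scope: str
    loci: list[str]
    freqs: list[dict[int, float]]
    gene_copies: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self) -> None:
        self.gene_copies = np.asarray(self.gene_copies, dtype=np.int64)
        for l, f in enumerate(self.freqs):
            if self.gene_copies[l] > 0:
                s = sum(f.values())
                if abs(s - 1.0) > 1e-9:
                    raise GenotypeValidationError(
                        f"frequencies at locus {self.loci[l]!r} sum to {s}, not 1"
                    )
            if self.gene_copies[l] % 2:
                raise GenotypeValidationError("gene_copies must be even (diploid)")


# ---------------------------------------------------------------------------
# allele frequencies


def allele_frequencies(dataset: GenotypeDataset, scope: str = POOLED) -> AlleleFrequencyTable:
    """Per-locus relative allele frequencies within ``scope``.

    Each non-missing allele copy counts once: a homozygote contributes two
    copies of its allele.  ``scope`` is a breed id or :data:`POOLED`.
    """
    if scope == POOLED:
        rows = np.arange(dataset.n_individuals)
    else:
        rows = dataset.breed_indices(scope)
    calls = dataset.calls[rows]
    freqs: list[dict[int, float]] = []
    copies = np.zeros(dataset.n_loci, dtype=np.int64)
    for l in range(dataset.n_loci):
        col = calls[:, l, :].ravel()
        col = col[col != MISSING]
        copies[l] = col.size
        if col.size == 0:
            freqs.append({})
            continue
        codes, counts = np.unique(col, return_counts=True)
        freqs.append({int(a): c / col.size for a, c in zip(codes, counts)})
    return AlleleFrequencyTable(scope=scope, loci=list(dataset.loci),
                                freqs=freqs, gene_copies=copies)


def allele_copy_counts(dataset: GenotypeDataset, scope: str = POOLED) -> list[dict[int, int]]:
    """Raw allele copy counts per locus (used by rarefaction)."""
    if scope == POOLED:
        rows = np.arange(dataset.n_individuals)
    else:
        rows = dataset.breed_indices(scope)
    out: list[dict[int, int]] = []
    for l in range(dataset.n_loci):
        col = dataset.calls[rows, l, :].ravel()
        col = col[col != MISSING]
        codes, counts = np.unique(col, return_counts=True)
        out.append({int(a): int(c) for a, c in zip(codes, counts)})
    return out


# ---------------------------------------------------------------------------
# genepop dialect

_GENEPOP_POP = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _read_genepop(text: str, source: str) -> GenotypeDataset:
    lines = text.splitlines()
    if not lines:
        raise GenotypeFormatError(f"{source}: empty file")
    # line 0 is a free-text title
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _GENEPOP_POP.match(lines[i]):
        # locus names: one per line, or comma-separated on one line
        part = lines[i].strip()
        if part:
            loci.extend(x.strip() for x in part.split(",") if x.strip())
        i += 1
    if not loci:
        raise GenotypeFormatError(f"{source}: no locus names before first 'pop'")
    if i == len(lines):
        raise GenotypeFormatError(f"{source}: no 'pop' separator found")

    ids: list[str] = []
    breeds: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_idx = 0
    digits: int | None = None
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        if _GENEPOP_POP.match(raw):
            pop_idx += 1
            continue
        if not raw.strip():
            continue
        if "," not in raw:
            raise GenotypeParseError(
                f"{source}:{lineno + 1}: expected '<id> , <genotypes>'"
            )
        name, _, geno = raw.partition(",")
        fields = geno.split()
        if len(fields) != len(loci):
            raise GenotypeParseError(
                f"{source}:{lineno + 1}: {len(fields)} genotype fields for "
                f"{len(loci)} loci"
            )
        row: list[tuple[int, int]] = []
        for f in fields:
            if not f.isdigit() or len(f) not in (4, 6):
                raise GenotypeParseError(
                    f"{source}:{lineno + 1}: bad diploid code {f!r} "
                    "(need 4 or 6 digits)"
                )
            w = len(f) // 2
            if digits is None:
                digits = w
            elif w != digits:
                raise GenotypeParseError(
                    f"{source}:{lineno + 1}: mixed 2- and 3-digit codes"
                )
            a, b = int(f[:w]), int(f[w:])
            if (a == 0) != (b == 0):
                # genepop half-missing codes collapse to missing
                a = b = 0
            row.append((a, b))
        name = name.strip()
        # our writer encodes the breed label (genepop itself has none) as
        # "breed|individual"; foreign files fall back to pop1..popN labels
        if "|" in name:
            breed, _, name = name.partition("|")
        else:
            breed = f"pop{pop_idx}"
        ids.append(name)
        breeds.append(breed)
        rows.append(row)
    if not rows:
        raise GenotypeFormatError(f"{source}: no individuals")
    return GenotypeDataset(ids, breeds, loci, np.array(rows, dtype=np.int64))


def _write_genepop(dataset: GenotypeDataset, digits: int = 3, title: str = "breedrisk export") -> str:
    cap = 10 ** digits - 1
    if dataset.calls.max(initial=0) > cap:
        raise GenotypeFormatError(
            f"allele code {int(dataset.calls.max())} exceeds {digits}-digit capacity {cap}"
        )
    out = io.StringIO()
    out.write(title + "\n")
    for locus in dataset.loci:
        out.write(locus + "\n")
    for breed in dataset.breeds:
        out.write("pop\n")
        for i in dataset.breed_indices(breed):
            codes = "\t".join(
                f"{a:0{digits}d}{b:0{digits}d}" for a, b in dataset.calls[i]
            )
            out.write(f"{breed}|{dataset.individual_ids[i]} ,\t{codes}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# delimited table dialect


def _read_table(text: str, source: str, sep: str = "\t", missing: int = 0) -> GenotypeDataset:
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
    cols = list(df.columns)
    if len(cols) < 4 or cols[0] != "individual_id" or cols[1] != "breed_id":
        raise GenotypeFormatError(
            f"{source}: first columns must be individual_id, breed_id"
        )
    allele_cols = cols[2:]
    if len(allele_cols) % 2:
        raise GenotypeFormatError(
            f"{source}: odd number of allele columns ({len(allele_cols)})"
        )
    loci = []
    for k in range(0, len(allele_cols), 2):
        name = allele_cols[k]
        # accept "Locus_1"/"Locus_2" or "Locus.1"/"Locus.2" column pairs
        loci.append(re.sub(r"[._][12]$", "", name))
    try:
        vals = df[allele_cols].to_numpy(dtype=float)
    except ValueError as exc:
        raise GenotypeParseError(f"{source}: non-numeric allele code ({exc})") from exc
    if np.isnan(vals).any():
        r, c = np.argwhere(np.isnan(vals))[0]
        raise GenotypeParseError(
            f"{source}: empty allele cell at row {r + 2}, column {allele_cols[c]!r}"
        )
    vals = vals.astype(np.int64)
    vals[vals == missing] = MISSING
    calls = vals.reshape(len(df), len(loci), 2)
    # table files may carry half-calls; collapse them to missing up front
    half = (calls == MISSING).sum(axis=2) == 1
    calls[half] = MISSING
    return GenotypeDataset(
        individual_ids=df["individual_id"].tolist(),
        breed_ids=df["breed_id"].tolist(),
        loci=loci,
        calls=calls,
    )


def _write_table(dataset: GenotypeDataset, sep: str = "\t") -> str:
    cols: dict[str, list] = {
        "individual_id": dataset.individual_ids,
        "breed_id": dataset.breed_ids,
    }
    for l, locus in enumerate(dataset.loci):
        cols[f"{locus}_1"] = dataset.calls[:, l, 0].tolist()
        cols[f"{locus}_2"] = dataset.calls[:, l, 1].tolist()
    return pd.DataFrame(cols).to_csv(sep=sep, index=False)


# ---------------------------------------------------------------------------
# public entry points


def read_genotypes(path: str | Path, format: str = "genepop", *,
                   sep: str = "\t", missing: int = 0) -> GenotypeDataset:
    """Read a genotype file.

    ``format`` is ``"genepop"`` or ``"table"``.  For the table dialect,
    ``sep`` is the field delimiter and ``missing`` the allele sentinel that
    marks a missing copy (default 0).
    """
    path = Path(path)
    text = path.read_text()
    if format == "genepop":
        return _read_genepop(text, str(path))
    if format == "table":
        return _read_table(text, str(path), sep=sep, missing=missing)
    raise ValueError(f"unknown format {format!r}")


def write_genotypes(dataset: GenotypeDataset, path: str | Path,
                    format: str = "genepop", *, digits: int = 3,
                    sep: str = "\t") -> None:
    """Write ``dataset`` so that :func:`read_genotypes` round-trips it."""
    if dataset.n_loci == 0:
        raise GenotypeFormatError("cannot write a dataset with no loci")
    path = Path(path)
    if format == "genepop":
        path.write_text(_write_genepop(dataset, digits=digits))
    elif format == "table":
        path.write_text(_write_table(dataset, sep=sep))
    else:
        raise ValueError(f"unknown format {format!r}")
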