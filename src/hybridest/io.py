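"""CSV file formats for genotypes, allele frequencies and results.

Two genotype dialects are supported.  The codominant dialect has an ``id``
column followed by exactly two allele columns per locus, named
``<locus>_1`` and ``<locus>_2``; the dominant dialect has one binary
(band present = 1 / absent = 0) column per marker.  Allele identifiers are
opaque strings.  The frequency file is long format with columns
``locus, allele`` and one frequency column per ancestral population, plus
an optional ``dominant`` column (0/1) flagging the dominant allele for
markers scored as dominant.  Missing data use the configurable token
(default ``NA``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .likelihood import AlleleFrequencyTable, CodominantGenotype, DominantPhenotype

__all__ = [
    "GenotypeFileSpec",
    "read_genotypes",
    "write_genotypes",
    "read_frequencies",
    "write_frequencies",
    "write_results",
]

CODOMINANT = "codominant-two-column"
DOMINANT = "dominant-binary"


@dataclasses.dataclass(frozen=True)
class GenotypeFileSpec:
    dialect: str = CODOMINANT
    delimiter: str = ","
    missing: str = "NA"
    id_column: str = "id"

    def __post_init__(self):
        if self.dialect not in (CODOMINANT, DOMINANT):
            raise ValueError(f"unknown genotype dialect {self.dialect!r}")


def _read_table(path, delimiter) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def read_genotypes(
    path,
    spec: GenotypeFileSpec = GenotypeFileSpec(),
    frequencies: Optional[AlleleFrequencyTable] = None,
) -> dict[str, CodominantGenotype | DominantPhenotype]:
    """Read a genotype CSV into per-individual genotype objects.

    For the dominant dialect, ``frequencies`` must carry the dominant
    allele of each marker (``dominant_alleles``).
    """
    df = _read_table(path, spec.delimiter)
    if spec.id_column not in df.columns:
        raise ValueError(f"{path}: missing identifier column {spec.id_column!r}")
    data_cols = [c for c in df.columns if c != spec.id_column]
    if spec.dialect == CODOMINANT:
        loci = []
        for c in data_cols:
            if not c.endswith("_1"):
                continue
            locus = c[:-2]
            if f"{locus}_2" not in df.columns:
                raise ValueError(
                    f"{path}: column {c!r} has no matching {locus}_2 column"
                )
            loci.append(locus)
        paired = {f"{l}_{k}" for l in loci for k in (1, 2)}
        stray = [c for c in data_cols if c not in paired]
        if stray or not loci:
            raise ValueError(
                f"{path}: codominant files need <locus>_1/<locus>_2 column "
                f"pairs; unexpected columns {stray!r}"
            )
        out: dict[str, CodominantGenotype | DominantPhenotype] = {}
        for row_i, row in enumerate(df.itertuples(index=False), start=2):
            rec = dict(zip(df.columns, row))
            calls = {}
            for locus in loci:
                a, b = rec[f"{locus}_1"], rec[f"{locus}_2"]
                if a == spec.missing and b == spec.missing:
                    calls[locus] = None
                elif a == spec.missing or b == spec.missing:
                    raise ValueError(
                        f"{path}, line {row_i}: locus {locus!r} has one "
                        "missing allele of a pair"
                    )
                else:
                    calls[locus] = (a, b)
            out[rec[spec.id_column]] = CodominantGenotype(calls)
        return out

    # dominant dialect
    if frequencies is None or not frequencies.dominant_alleles:
        raise ValueError(
            "dominant genotype files require a frequency table that names "
            "the dominant allele of each marker"
        )
    out = {}
    for row_i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        bands = {}
        for marker in data_cols:
            v = rec[marker]
            if v == spec.missing:
                bands[marker] = None
            elif v in ("0", "1"):
                bands[marker] = int(v)
            else:
                raise ValueError(
                    f"{path}, line {row_i}: marker {marker!r} has non-binary "
                    f"band state {v!r}"
                )
        out[rec[spec.id_column]] = DominantPhenotype(
            bands, {m: frequencies.dominant_alleles[m] for m in data_cols}
        )
    return out


def write_genotypes(
    path,
    genotypes: dict[str, CodominantGenotype | DominantPhenotype],
    spec: GenotypeFileSpec = GenotypeFileSpec(),
) -> None:
    if not genotypes:
        raise ValueError("nothing to write")
    first = next(iter(genotypes.values()))
    loci = first.loci
    rows = []
    for ident, g in genotypes.items():
        rec = {spec.id_column: ident}
        if spec.dialect == CODOMINANT:
            for locus in loci:
                pair = g.calls[locus]  # type: ignore[union-attr]
                if pair is None:
                    rec[f"{locus}_1"] = rec[f"{locus}_2"] = spec.missing
                else:
                    rec[f"{locus}_1"], rec[f"{locus}_2"] = pair
        else:
            for locus in loci:
                state = g.bands[locus]  # type: ignore[union-attr]
                rec[locus] = spec.missing if state is None else str(state)
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep=spec.delimiter, index=False)


def read_frequencies(path, delimiter: str = ",") -> AlleleFrequencyTable:
    """Read a long-format allele-frequency CSV.

    Expected columns: ``locus``, ``allele``, then one numeric column per
    ancestral population (two or more), optionally ``dominant``.
    """
    df = _read_table(path, delimiter)
    for col in ("locus", "allele"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    pop_cols = [c for c in df.columns if c not in ("locus", "allele", "dominant")]
    if len(pop_cols) < 2:
        raise ValueError(f"{path}: need at least two population columns")
    freqs: dict[str, dict[str, list[float]]] = {}
    dominant: dict[str, str] = {}
    for row_i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        locus, allele = rec["locus"], rec["allele"]
        try:
            vec = [float(rec[c]) for c in pop_cols]
        except ValueError:
            raise ValueError(
                f"{path}, line {row_i}: non-numeric frequency at locus {locus!r}"
            ) from None
        freqs.setdefault(locus, {})[allele] = vec
        if "dominant" in rec and str(rec["dominant"]) == "1":
            dominant[locus] = allele
    return AlleleFrequencyTable(
        freqs, populations=tuple(pop_cols), dominant_alleles=dominant or None
    )


def write_frequencies(path, freqs: AlleleFrequencyTable, delimiter: str = ",") -> None:
    rows = []
    for locus in freqs.loci:
        for allele in freqs.alleles(locus):
            rec = {"locus": locus, "allele": allele}
            vec = freqs.lookup(locus, allele)
            for pop, f in zip(freqs.populations, vec):
                rec[pop] = repr(float(f))
            if freqs.dominant_alleles:
                rec["dominant"] = int(freqs.dominant_alleles.get(locus) == allele)
            rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def write_results(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)
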