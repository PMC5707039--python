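"""Germline-vs-somatic classification for tumor-only candidates.

With no matched normal, germline variants are recognized from population
references. Two independent rules, both strict:

* carrier rule — an allele observed in more than 3 reference-cohort normal
  subjects is germline;
* subset-frequency rule — an allele at >1% frequency in either the
  African-American or European-American reference subset is germline, unless
  it is recurrent in COSMIC more than twice (a somatic hotspot can coincide
  with a rare polymorphism; COSMIC recurrence rescues only this rule, the
  carrier rule has no such clause).

A candidate absent from the catalog is never germline-flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd

from .screen import (
    FLAG_GERMLINE_CARRIERS,
    FLAG_GERMLINE_POPULATION,
    STATUS_SOMATIC,
    VariantCandidate,
)

CATALOG_COLUMNS = [
    "contig",
    "pos",
    "ref",
    "alt",
    "af_overall",
    "af_african_american",
    "af_european_american",
    "normal_carrier_count",
    "cosmic_count",
]


@dataclass(frozen=True)
class PopulationRecord:
    """One catalog allele: population frequencies plus COSMIC recurrence."""

    contig: str
    pos: int
    ref: str
    alt: str
    af_overall: float
    af_african_american: float
    af_european_american: float
    normal_carrier_count: int
    cosmic_count: int

    def __post_init__(self) -> None:
        for af in (self.af_overall, self.af_african_american, self.af_european_american):
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency out of [0,1]: {af}")
        if self.normal_carrier_count < 0 or self.cosmic_count < 0:
            raise ValueError("counts must be non-negative")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.alt)


class PopulationCatalog:
    """In-memory lookup over a merged population-frequency table."""

    def __init__(self, records: Iterable[PopulationRecord]):
        self._by_key: dict[tuple[str, int, str], PopulationRecord] = {}
        for rec in records:
            self._by_key[rec.key] = rec

    def lookup(self, contig: str, pos: int, alt: str) -> PopulationRecord | None:
        return self._by_key.get((contig, pos, alt))

    @property
    def snp_sites(self) -> frozenset[tuple[str, int, str]]:
        """(contig, pos, alt) triples, for the recurrence-filter exemption."""
        return frozenset(self._by_key)

    def records(self) -> list[PopulationRecord]:
        return list(self._by_key.values())

    @classmethod
    def read_tsv(cls, path: str | Path | IO[str]) -> "PopulationCatalog":
        df = pd.read_csv(path, sep="\t", dtype={"contig": str})
        missing = set(CATALOG_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"population catalog missing columns: {sorted(missing)}")
        return cls(
            PopulationRecord(
                contig=row.contig,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                af_overall=float(row.af_overall),
                af_african_american=float(row.af_african_american),
                af_european_american=float(row.af_european_american),
                normal_carrier_count=int(row.normal_carrier_count),
                cosmic_count=int(row.cosmic_count),
            )
            for row in df.itertuples(index=False)
        )

    def write_tsv(self, out: IO[str]) -> None:
        out.write("\t".join(CATALOG_COLUMNS) + "\n")
        for rec in sorted(self._by_key.values(), key=lambda r: (r.contig, r.pos, r.alt)):
            out.write(
                f"{rec.contig}\t{rec.pos}\t{rec.ref}\t{rec.alt}\t{rec.af_overall:.6g}"
                f"\t{rec.af_african_american:.6g}\t{rec.af_european_american:.6g}"
                f"\t{rec.normal_carrier_count}\t{rec.cosmic_count}\n"
            )


def classify_germline(
    candidate: VariantCandidate,
    record: PopulationRecord | None,
    max_normal_carriers: int = 3,
    max_subset_af: float = 0.01,
    cosmic_rescue_min: int = 2,
) -> VariantCandidate:
    """Apply the carrier and subset-frequency germline rules to one candidate.

    ``record`` is the catalog entry matching the candidate's site and allele,
    or None when absent. A candidate that survives both rules (and carries no
    prior artifact flags) is promoted to somatic status. Pure function.
    """
    if record is not None and (
        record.contig != candidate.position.contig
        or record.pos != candidate.position.pos
        or record.alt != candidate.alt
    ):
        raise ValueError(
            f"catalog record {record.key} does not match candidate "
            f"({candidate.position.contig}, {candidate.position.pos}, {candidate.alt})"
        )
    flags = []
    if record is not None:
        if record.normal_carrier_count > max_normal_carriers:
            flags.append(FLAG_GERMLINE_CARRIERS)
        if (
            record.af_african_american > max_subset_af
            or record.af_european_american > max_subset_af
        ) and record.cosmic_count <= cosmic_rescue_min:
            flags.append(FLAG_GERMLINE_POPULATION)
    if flags:
        return candidate.with_flags(*flags)
    if not candidate.filter_flags:
        from dataclasses import replace

        return replace(candidate, status=STATUS_SOMATIC)
    return candidate


def classify_all(
    candidates: Iterable[VariantCandidate], catalog: PopulationCatalog
) -> list[VariantCandidate]:
    """Classify each candidate against its catalog record (if any)."""
    return [
        classify_germline(
            cand, catalog.lookup(cand.position.contig, cand.position.pos, cand.alt)
        )
        for cand in candidates
    ]
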