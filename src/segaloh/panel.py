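"""Target-panel definition: gene intervals and coding exons.

Intervals follow BED conventions (0-based, half-open) on disk and are
converted to 1-based inclusive coordinates only when positions are compared,
so all coordinate conversion happens at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a contig (BED convention)."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval {self.contig}:{self.start}-{self.end}")

    def contains(self, contig: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        return contig == self.contig and self.start < pos <= self.end

    def positions(self) -> range:
        """The 1-based positions covered."""
        return range(self.start + 1, self.end + 1)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneRegion:
    """One panel gene: its captured interval and coding-exon sub-intervals."""

    name: str
    interval: Interval
    coding_exons: list[Interval] = field(default_factory=list)

    def contains(self, contig: str, pos: int) -> bool:
        return self.interval.contains(contig, pos)


@dataclass
class PanelDefinition:
    """The capture panel: a set of named gene regions."""

    genes: dict[str, GeneRegion]

    def gene_at(self, contig: str, pos: int) -> str | None:
        for gene in self.genes.values():
            if gene.contains(contig, pos):
                return gene.name
        return None

    def coding_positions(self, gene_names: Iterable[str] | None = None) -> Iterator[tuple[str, int]]:
        """All 1-based (contig, pos) pairs in coding exons of the named genes."""
        names = list(gene_names) if gene_names is not None else list(self.genes)
        for name in names:
            gene = self.genes[name]
            for exon in gene.coding_exons:
                for pos in exon.positions():
                    yield exon.contig, pos

    @classmethod
    def read_bed(cls, path: str | Path | IO[str]) -> "PanelDefinition":
        """Read a panel BED: columns contig, start, end, name[, feature].

        Rows whose 5th column is ``coding`` become coding exons of the named
        gene; rows without it (or with ``capture``) define the gene interval.
        """
        if hasattr(path, "read"):
            lines = path.read().splitlines()
        else:
            lines = Path(path).read_text().splitlines()
        genes: dict[str, GeneRegion] = {}
        exons: dict[str, list[Interval]] = {}
        for line in lines:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            contig, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            feature = fields[4] if len(fields) > 4 else "capture"
            iv = Interval(contig, start, end)
            if feature == "coding":
                exons.setdefault(name, []).append(iv)
            else:
                genes[name] = GeneRegion(name=name, interval=iv)
        for name, ivs in exons.items():
            if name not in genes:
                raise ValueError(f"coding exon for unknown gene {name!r}")
            genes[name].coding_exons = sorted(ivs, key=lambda iv: iv.start)
        return cls(genes=genes)

    def write_bed(self, out: IO[str]) -> None:
        for gene in self.genes.values():
            iv = gene.interval
            out.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{gene.name}\tcapture\n")
            for exon in gene.coding_exons:
                out.write(f"{exon.contig}\t{exon.start}\t{exon.end}\t{gene.name}\tcoding\n")
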