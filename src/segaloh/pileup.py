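"""Single-sample samtools-mpileup text parsing into strand-oriented base counts.

The pileup read-bases string encodes, per aligned read, the base observed at a
position together with its read orientation: ``.``/uppercase letters are
forward-strand observations, ``,``/lowercase are reverse-strand. An insertion
or deletion relative to the reference is written immediately after the base of
the read it occurred on, as ``+<len><seq>`` / ``-<len><seq>``. ``^q`` marks a
read start (the following byte is a mapping quality, not a base) and ``$`` a
read end. ``*`` (``#`` on the reverse strand) is the placeholder printed inside
a deletion.

Every counted read contributes exactly one allele observation: a read whose
base is followed by an indel string counts as one observation of that indel
allele (keyed ``+SEQ`` / ``-SEQ``, uppercased), not as a reference match plus
an indel. This keeps per-orientation depth equal to the number of reads and
makes allele fractions directly comparable across substitutions and indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

REF_KEY = "ref"
"""Allele key used for reference-matching reads."""

_GAP_KEYS = frozenset({"N", "*"})
"""Keys counted into depth but never emitted as alleles (no allele identity)."""

_FORWARD_SUBS = frozenset("ACGTN")
_REVERSE_SUBS = frozenset("acgtn")


class PileupParseError(ValueError):
    """Malformed pileup input; message names the offending line number."""


@dataclass(frozen=True, order=True)
class GenomicPosition:
    """1-based coordinate on a named contig."""

    contig: str
    pos: int

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass
class OrientedBaseCounts:
    """Per-position allele counts split by read orientation.

    ``counts_forward`` / ``counts_reverse`` map allele keys (a substitution
    base, :data:`REF_KEY`, ``+SEQ``, ``-SEQ``, or the depth-only keys ``N`` and
    ``*``) to read counts. Depths equal the sum of the corresponding counts.
    """

    position: GenomicPosition
    ref_base: str
    counts_forward: dict[str, int] = field(default_factory=dict)
    counts_reverse: dict[str, int] = field(default_factory=dict)

    @property
    def depth_forward(self) -> int:
        return sum(self.counts_forward.values())

    @property
    def depth_reverse(self) -> int:
        return sum(self.counts_reverse.values())

    @property
    def depth_total(self) -> int:
        return self.depth_forward + self.depth_reverse

    def count(self, allele: str) -> int:
        """Total reads supporting ``allele`` over both orientations."""
        return self.counts_forward.get(allele, 0) + self.counts_reverse.get(allele, 0)


@dataclass(frozen=True)
class AlleleObservation:
    """A non-reference allele seen at a position, with its read support."""

    position: GenomicPosition
    ref: str
    alt: str
    count_forward: int
    count_reverse: int
    depth_total: int

    @property
    def frequency(self) -> float:
        if self.depth_total == 0:
            return 0.0
        return (self.count_forward + self.count_reverse) / self.depth_total


def _parse_indel(bases: str, i: int, line_no: int) -> tuple[str, int]:
    """Parse ``+<len><seq>`` / ``-<len><seq>`` starting at ``bases[i]``.

    Returns the uppercased allele key (sign + sequence) and the index of the
    first character after the indel.
    """
    sign = bases[i]
    j = i + 1
    while j < len(bases) and bases[j].isdigit():
        j += 1
    if j == i + 1:
        raise PileupParseError(f"line {line_no}: indel length not parseable at column {i}")
    length = int(bases[i + 1 : j])
    seq = bases[j : j + length]
    if len(seq) < length:
        raise PileupParseError(f"line {line_no}: indel sequence truncated at column {i}")
    return sign + seq.upper(), j + length


def parse_read_bases(bases: str, ref_base: str, line_no: int = 0) -> tuple[dict[str, int], dict[str, int]]:
    """Walk a read-bases string once, returning (forward, reverse) count maps."""
    fwd: dict[str, int] = {}
    rev: dict[str, int] = {}
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupParseError(f"line {line_no}: dangling '^' at end of read-bases string")
            i += 2  # skip the mapping-quality byte
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            raise PileupParseError(f"line {line_no}: indel with no anchoring base at column {i}")

        if c == ".":
            key, counts = REF_KEY, fwd
        elif c == ",":
            key, counts = REF_KEY, rev
        elif c in _FORWARD_SUBS:
            key, counts = c, fwd
        elif c in _REVERSE_SUBS:
            key, counts = c.upper(), rev
        elif c == "*":
            key, counts = "*", fwd
        elif c == "#":
            key, counts = "*", rev
        else:
            raise PileupParseError(f"line {line_no}: unrecognized pileup symbol {c!r} at column {i}")
        i += 1
        # an indel immediately after a base replaces that read's allele call
        if i < n and bases[i] in "+-":
            key, i = _parse_indel(bases, i, line_no)
        counts[key] = counts.get(key, 0) + 1
    return fwd, rev


def parse_pileup(stream: Iterable[str] | IO[str], sample_index: int = 0) -> Iterator[OrientedBaseCounts]:
    """Parse single-sample mpileup text into per-position oriented counts.

    Each line carries ``contig  pos  ref  depth  read-bases  qualities``; with
    a multi-sample pileup, ``sample_index`` selects which trio of
    (depth, bases, quals) columns to read. The stated depth must equal the
    number of reads parsed from the bases string.
    """
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            fields = line.split()
        base = 3 + 3 * sample_index
        if len(fields) < base + 3:
            raise PileupParseError(f"line {line_no}: expected at least {base + 3} columns, got {len(fields)}")
        contig, pos_s, ref = fields[0], fields[1], fields[2]
        depth_s, bases = fields[base], fields[base + 1]
        try:
            pos = int(pos_s)
            depth = int(depth_s)
        except ValueError as exc:
            raise PileupParseError(f"line {line_no}: non-integer position or depth") from exc
        fwd, rev = parse_read_bases(bases, ref, line_no)
        parsed_depth = sum(fwd.values()) + sum(rev.values())
        if parsed_depth != depth:
            raise PileupParseError(
                f"line {line_no}: depth field {depth} disagrees with {parsed_depth} parsed reads"
            )
        yield OrientedBaseCounts(
            position=GenomicPosition(contig, pos),
            ref_base=ref.upper(),
            counts_forward=fwd,
            counts_reverse=rev,
        )


def allele_observations(counts: OrientedBaseCounts) -> list[AlleleObservation]:
    """Non-reference alleles at a position with frequencies over total depth.

    ``N`` and the deletion placeholder ``*`` contribute to depth but are never
    emitted (they carry no allele identity). Results are sorted by descending
    frequency, ties broken lexicographically by allele key; zero total depth
    yields an empty list.
    """
    depth = counts.depth_total
    if depth == 0:
        return []
    keys = (set(counts.counts_forward) | set(counts.counts_reverse)) - {REF_KEY} - _GAP_KEYS
    obs = [
        AlleleObservation(
            position=counts.position,
            ref=counts.ref_base,
            alt=key,
            count_forward=counts.counts_forward.get(key, 0),
            count_reverse=counts.counts_reverse.get(key, 0),
            depth_total=depth,
        )
        for key in keys
    ]
    obs.sort(key=lambda o: (-o.frequency, o.alt))
    return obs


def write_counts_tsv(counts_list: Iterable[OrientedBaseCounts], out: IO[str]) -> None:
    """Write the pipeline's intermediate per-position counts table."""
    out.write("contig\tpos\tref\tallele\tfwd\trev\tdepth\tfreq\n")
    for counts in counts_list:
        depth = counts.depth_total
        keys = sorted(set(counts.counts_forward) | set(counts.counts_reverse))
        for key in keys:
            f = counts.counts_forward.get(key, 0)
            r = counts.counts_reverse.get(key, 0)
            freq = (f + r) / depth if depth else 0.0
            out.write(
                f"{counts.position.contig}\t{counts.position.pos}\t{counts.ref_base}"
                f"\t{key}\t{f}\t{r}\t{depth}\t{freq:.6g}\n"
            )
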