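"""Artifact screening of allele observations in tumor-only panel data.

Three rules separate plausible variants from sequencing artifacts before any
germline reasoning is attempted:

* a review threshold — only alleles at a frequency strictly above 1% of reads
  are considered further;
* a strand-orientation rule — a real variant on a double-stranded template is
  expected on both read orientations, so an allele supported by a single
  orientation is flagged as an artifact;
* a cross-sample recurrence rule — an identical non-SNP allele recurring in
  several independent tumors points at a systematic process artifact
  (alignment slippage, oxidation, FFPE damage) rather than coincident somatic
  mutation. Known population SNPs legitimately recur and are exempt.

Filters flag rather than delete so that every elimination remains auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping

from .pileup import AlleleObservation, GenomicPosition

FLAG_BELOW_THRESHOLD = "below_threshold"
FLAG_SINGLE_ORIENTATION = "single_orientation"
FLAG_RECURRENT_ARTIFACT = "recurrent_artifact"
FLAG_GERMLINE_POPULATION = "germline_population"
FLAG_GERMLINE_CARRIERS = "germline_carriers"

STATUS_CANDIDATE = "candidate"
STATUS_FILTERED = "filtered"
STATUS_SOMATIC = "somatic"


@dataclass(frozen=True)
class ScreenThresholds:
    """Artifact-screen knobs.

    ``min_frequency`` is strict (frequency must exceed it); the default 0.01
    is the 1%-of-reads review threshold. ``recurrence_min_samples`` is the
    number of samples an identical allele must appear in before it is treated
    as a process artifact; 3 by default because bona fide hotspot mutations do
    recur in pairs of tumors.
    """

    min_frequency: float = 0.01
    require_both_orientations: bool = True
    recurrence_min_samples: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.min_frequency < 1:
            raise ValueError("min_frequency must be in (0, 1)")
        if self.recurrence_min_samples < 2:
            raise ValueError("recurrence_min_samples must be >= 2")


@dataclass
class VariantCandidate:
    """An allele call with orientation support, flags and somatic status."""

    sample_id: str
    position: GenomicPosition
    ref: str
    alt: str
    count_forward: int
    count_reverse: int
    depth_total: int
    frequency: float
    filter_flags: frozenset[str] = field(default_factory=frozenset)
    status: str = STATUS_CANDIDATE

    def with_flags(self, *flags: str) -> "VariantCandidate":
        """Copy with extra flags; any flag forces filtered status."""
        new = self.filter_flags | set(flags)
        status = STATUS_FILTERED if new else self.status
        return replace(self, filter_flags=frozenset(new), status=status)


def call_candidates(
    observations: Iterable[AlleleObservation],
    sample_id: str,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> list[VariantCandidate]:
    """Turn one sample's allele observations into flagged candidates.

    Every observation becomes a candidate; nothing is dropped. Flags:
    ``below_threshold`` when frequency <= min_frequency, ``single_orientation``
    when either strand has zero supporting reads (if required).
    """
    out = []
    for obs in observations:
        cand = VariantCandidate(
            sample_id=sample_id,
            position=obs.position,
            ref=obs.ref,
            alt=obs.alt,
            count_forward=obs.count_forward,
            count_reverse=obs.count_reverse,
            depth_total=obs.depth_total,
            frequency=obs.frequency,
        )
        flags = []
        if cand.frequency <= thresholds.min_frequency:
            flags.append(FLAG_BELOW_THRESHOLD)
        if thresholds.require_both_orientations and (
            cand.count_forward == 0 or cand.count_reverse == 0
        ):
            flags.append(FLAG_SINGLE_ORIENTATION)
        if flags:
            cand = cand.with_flags(*flags)
        out.append(cand)
    return out


def flag_recurrent(
    candidates_by_sample: Mapping[str, list[VariantCandidate]],
    known_snp_sites: frozenset[tuple[str, int, str]] = frozenset(),
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> dict[str, list[VariantCandidate]]:
    """Flag alleles recurring across samples as process artifacts.

    ``known_snp_sites`` holds (contig, pos, alt) triples present in the
    population catalog; these are exempt — real polymorphisms recur across
    samples legitimately. With fewer than two samples the input is returned
    unchanged (recurrence is undefined).
    """
    if len(candidates_by_sample) < 2:
        import logging

        logging.getLogger(__name__).warning(
            "recurrence filter skipped: needs >= 2 samples, got %d", len(candidates_by_sample)
        )
        return {s: list(c) for s, c in candidates_by_sample.items()}

    carriers: dict[tuple[str, int, str], set[str]] = {}
    for sample_id, cands in candidates_by_sample.items():
        for cand in cands:
            key = (cand.position.contig, cand.position.pos, cand.alt)
            carriers.setdefault(key, set()).add(sample_id)
    recurrent = {
        key
        for key, samples in carriers.items()
        if len(samples) >= thresholds.recurrence_min_samples and key not in known_snp_sites
    }
    out: dict[str, list[VariantCandidate]] = {}
    for sample_id, cands in candidates_by_sample.items():
        out[sample_id] = [
            cand.with_flags(FLAG_RECURRENT_ARTIFACT)
            if (cand.position.contig, cand.position.pos, cand.alt) in recurrent
            else cand
            for cand in cands
        ]
    return out


def write_candidates_vcf(candidates: Iterable[VariantCandidate], out: IO[str]) -> None:
    """Minimal VCF-like audit report of all candidates with their flags."""
    out.write("##fileformat=VCFv4.2-like\n")
    out.write("##INFO=AF:allele fraction,ADF:forward depth,ADR:reverse depth,DP:total depth\n")
    out.write("#CHROM\tPOS\tREF\tALT\tFILTER\tINFO\n")
    for c in sorted(candidates, key=lambda c: (c.position.contig, c.position.pos, c.alt)):
        filt = ";".join(sorted(c.filter_flags)) if c.filter_flags else "PASS"
        info = f"AF={c.frequency:.6g};ADF={c.count_forward};ADR={c.count_reverse};DP={c.depth_total}"
        out.write(f"{c.position.contig}\t{c.position.pos}\t{c.ref}\t{c.alt}\t{filt}\t{info}\n")


def write_candidates_tsv(candidates: Iterable[VariantCandidate], out: IO[str]) -> None:
    out.write("sample\tcontig\tpos\tref\talt\tfwd\trev\tdepth\tfreq\tflags\tstatus\n")
    for c in candidates:
        flags = ",".join(sorted(c.filter_flags)) if c.filter_flags else "."
        out.write(
            f"{c.sample_id}\t{c.position.contig}\t{c.position.pos}\t{c.ref}\t{c.alt}"
            f"\t{c.count_forward}\t{c.count_reverse}\t{c.depth_total}\t{c.frequency:.6g}"
            f"\t{flags}\t{c.status}\n"
        )
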