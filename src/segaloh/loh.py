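"""Copy-neutral LOH inference from tumor-only allele fractions.

Under the two-hit model a tumor that has duplicated its mutant haplotype
(copy-neutral LOH) shows two complementary signals, both scaled by tumor
purity p:

* the mutant allele fraction at the mutation site rises toward p, above the
  50% ceiling of a heterozygous mutation;
* every germline heterozygous SNP in the gene drifts away from 50:50 — its
  minor allele fraction falls toward (1 - p)/2.

The decision rule mirrors both signals: CN-LOH is called when either the
mutant allele fraction exceeds 55% or the median minor allele fraction over
informative SNPs falls below 40%. Both inequalities are strict. Informative
SNPs are catalog polymorphisms with population allele frequency above 0.05%
that are actually observed in the sample (alt fraction within [1%, 99%]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .germline import PopulationCatalog
from .pileup import AlleleObservation, GenomicPosition, OrientedBaseCounts

BRANCH_MAF = "maf_branch"
BRANCH_SNP = "snp_branch"
BRANCH_BOTH = "both"
BRANCH_NONE = "none"


class LohError(ValueError):
    """Sample unevaluable for LOH (no mutation fraction and no SNPs)."""


@dataclass(frozen=True)
class LohThresholds:
    """Decision-rule cutoffs, defaulting to the published rule.

    maf_cutoff: mutant-allele-fraction branch, strict ">", default 55%.
    median_minor_cutoff: median SNP minor-AF branch, strict "<", default 40%.
    snp_population_af_min: catalog floor for informative SNPs (0.05%).
    snp_observed_min: an allele must be seen at >= this fraction (and its
    complement) to count as identified in the sample, default 1%.
    """

    maf_cutoff: float = 0.55
    median_minor_cutoff: float = 0.40
    snp_population_af_min: float = 0.0005
    snp_observed_min: float = 0.01

    def __post_init__(self) -> None:
        for v in (self.maf_cutoff, self.median_minor_cutoff, self.snp_population_af_min, self.snp_observed_min):
            if not 0 < v < 1:
                raise ValueError("all LOH cutoffs must be in (0, 1)")


@dataclass(frozen=True)
class SnpObservation:
    """An informative SNP's observed fractions in the tumor sample."""

    position: GenomicPosition
    population_af: float
    observed_alt_frequency: float

    @property
    def minor_allele_fraction(self) -> float:
        return min(self.observed_alt_frequency, 1.0 - self.observed_alt_frequency)


@dataclass
class LohAssessment:
    """Outcome of the CN-LOH rule for one gene in one sample."""

    gene: str
    mutation_maf: float | None
    snp_observations: list[SnpObservation]
    median_minor_af: float | None
    cn_loh: bool
    branch: str


def mutant_allele_fraction(counts_at_site: OrientedBaseCounts, mutant_allele: str) -> float:
    """Fraction of reads carrying exactly ``mutant_allele`` at the site.

    Exact-string matching: an insertion key "+A" never matches "+AG". For
    indels this reproduces a grep-style count of mutant vs. wild-type reads.
    A mutant allele absent from the counts yields 0.0; zero depth is an error.
    """
    depth = counts_at_site.depth_total
    if depth == 0:
        raise LohError(f"zero depth at {counts_at_site.position}; fraction undefined")
    return counts_at_site.count(mutant_allele) / depth


def select_informative_snps(
    observations_by_position: Mapping[tuple[str, int], Sequence[AlleleObservation]],
    catalog: PopulationCatalog,
    thresholds: LohThresholds = LohThresholds(),
) -> list[SnpObservation]:
    """Pick catalog SNPs actually identified in the sample.

    A site qualifies when its catalog population AF strictly exceeds the floor
    and the catalog alt allele is observed at a fraction within
    [snp_observed_min, 1 - snp_observed_min] — i.e. neither absent nor fixed,
    so the site is informative about allelic balance.
    """
    kept: list[SnpObservation] = []
    for rec in catalog.records():
        if rec.af_overall <= thresholds.snp_population_af_min:
            continue
        obs_list = observations_by_position.get((rec.contig, rec.pos), ())
        freq = 0.0
        for obs in obs_list:
            if obs.alt == rec.alt:
                freq = obs.frequency
                break
        if thresholds.snp_observed_min <= freq <= 1.0 - thresholds.snp_observed_min:
            kept.append(
                SnpObservation(
                    position=GenomicPosition(rec.contig, rec.pos),
                    population_af=rec.af_overall,
                    observed_alt_frequency=freq,
                )
            )
    kept.sort(key=lambda s: (s.position.contig, s.position.pos))
    return kept


def call_cnloh(
    mutation_maf: float | None,
    snps: Sequence[SnpObservation],
    thresholds: LohThresholds = LohThresholds(),
    gene: str = "",
) -> LohAssessment:
    """Apply the two-branch CN-LOH rule.

    The mutant-fraction branch fires when mutation_maf > maf_cutoff; the SNP
    branch when the median minor allele fraction (even-length median = mean of
    the central pair) < median_minor_cutoff. Either branch firing is evidence
    of CN-LOH. With no mutation fraction and no SNPs the sample is
    unevaluable and a LohError is raised.
    """
    if mutation_maf is None and not snps:
        raise LohError(f"gene {gene or '?'}: no mutation MAF and no informative SNPs")
    median_minor = (
        float(np.median([s.minor_allele_fraction for s in snps])) if snps else None
    )
    maf_fired = mutation_maf is not None and mutation_maf > thresholds.maf_cutoff
    snp_fired = median_minor is not None and median_minor < thresholds.median_minor_cutoff
    if maf_fired and snp_fired:
        branch = BRANCH_BOTH
    elif maf_fired:
        branch = BRANCH_MAF
    elif snp_fired:
        branch = BRANCH_SNP
    else:
        branch = BRANCH_NONE
    return LohAssessment(
        gene=gene,
        mutation_maf=mutation_maf,
        snp_observations=list(snps),
        median_minor_af=median_minor,
        cn_loh=branch != BRANCH_NONE,
        branch=branch,
    )


def write_loh_report(assessments: Iterable[tuple[str, str, LohAssessment]], out: IO[str]) -> None:
    """Per-sample LOH report: (sample, mutation description, assessment) rows."""
    out.write("sample\tgene\tmutation\tmaf\tn_snps\tmedian_minor_af\tcn_loh\tbranch\n")
    for sample_id, mutation, a in assessments:
        maf = f"{a.mutation_maf:.4g}" if a.mutation_maf is not None else "."
        med = f"{a.median_minor_af:.4g}" if a.median_minor_af is not None else "."
        out.write(
            f"{sample_id}\t{a.gene}\t{mutation or '.'}\t{maf}\t{len(a.snp_observations)}"
            f"\t{med}\t{str(a.cn_loh).lower()}\t{a.branch}\n"
        )
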