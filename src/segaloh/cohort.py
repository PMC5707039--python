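"""Per-sample classification and cohort tallies for two-hit panel screening.

Each sample is QC-gated on median coding-exon depth, assigned a gene based on
its somatic calls, combined with the CN-LOH assessment, and given a summary
label from a closed vocabulary; the cohort tally counts samples per gene,
per LOH status, and the two-mutation pattern, with round-half-up percentages.

A sample whose only finding is a "possible" (uncertain) mutation counts as
NMI — no mutation identified — in the tally, with the annotation preserved in
its label. A sample with CN-LOH but no point mutation also tallies as NMI,
with the LOH gene recorded separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .loh import LohAssessment
from .panel import PanelDefinition
from .pileup import OrientedBaseCounts

GENE_NMI = "NMI"

LABEL_POINT_LOH = "point+CN-LOH"
LABEL_POINT_NO_LOH = "point no LOH"
LABEL_TWO_POINTS = "2 points"
LABEL_LARGE_DEL_LOH = "large del+CN-LOH"
LABEL_LOH_NO_POINT = "CN-LOH, no point"
LABEL_POSSIBLE = "possible mutation, no CN-LOH"
LABEL_NMI = "NMI"

MUTATION_TYPES = {
    "nonsense",
    "missense",
    "insertion",
    "deletion",
    "in-frame deletion",
    "splice",
    "genomic deletion",
    "possible-initiator",
}

QC_MIN_MEDIAN_DEPTH = 20.0


class QcError(ValueError):
    """QC cannot be evaluated (e.g. no coding-exon intervals)."""


class MultiGeneConflictError(ValueError):
    """Somatic calls in more than one screened gene — surfaced, not guessed."""


@dataclass(frozen=True)
class Mutation:
    """One reported mutation: a free-form description, type, and MAF in %."""

    description: str
    mutation_type: str
    maf_percent: float | None = None

    @property
    def is_possible(self) -> bool:
        return self.mutation_type == "possible-initiator"


@dataclass
class SampleResult:
    """Per-sample outcome mirroring one row of the cohort summary table."""

    sample_id: str
    gene: str  # TSC1 / TSC2 / NMI (tally assignment)
    mutations: list[Mutation] = field(default_factory=list)
    cn_loh: bool = False
    cn_loh_gene: str | None = None
    qc_median_depth: float | None = None
    qc_pass: bool = True
    summary_label: str = LABEL_NMI


@dataclass
class CohortSummary:
    n_samples: int
    n_tsc1: int
    n_tsc2: int
    n_nmi: int
    n_tsc1_with_loh: int
    n_tsc2_with_loh: int
    n_nmi_with_loh: int
    n_two_point: int
    pct_tsc1: int
    pct_tsc2: int
    pct_nmi: int


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def qc_median_depth(
    counts: Sequence[OrientedBaseCounts],
    panel: PanelDefinition,
    gene_names: Iterable[str] | None = None,
    min_median: float = QC_MIN_MEDIAN_DEPTH,
) -> tuple[float, bool]:
    """Median total depth over all coding-exon positions; pass iff >= 20x.

    Coding positions with no pileup row count as depth 0.
    """
    coding = list(panel.coding_positions(gene_names))
    if not coding:
        raise QcError("panel defines no coding-exon intervals")
    depth_at = {(c.position.contig, c.position.pos): c.depth_total for c in counts}
    depths = [depth_at.get(key, 0) for key in coding]
    median = float(np.median(depths))
    return median, median >= min_median


def summarize_sample(
    sample_id: str,
    somatic_mutations: Mapping[str, Sequence[Mutation]],
    loh: Mapping[str, LohAssessment],
    qc_median: float | None = None,
    qc_pass: bool = True,
) -> SampleResult:
    """Combine somatic calls and per-gene LOH into a labeled sample result.

    ``somatic_mutations`` maps gene name to its confirmed (non-"possible")
    and possible mutations; ``loh`` maps gene name to its CN-LOH assessment.
    Somatic calls in two screened genes at once are a conflict the caller must
    resolve — this pattern was never observed and is surfaced as an error.
    """
    confirmed = {
        g: [m for m in muts if not m.is_possible]
        for g, muts in somatic_mutations.items()
    }
    confirmed = {g: muts for g, muts in confirmed.items() if muts}
    possible = [
        m for muts in somatic_mutations.values() for m in muts if m.is_possible
    ]
    if len(confirmed) > 1:
        raise MultiGeneConflictError(
            f"sample {sample_id}: somatic mutations in multiple genes: {sorted(confirmed)}"
        )
    loh_genes = [g for g, a in loh.items() if a.cn_loh]

    if confirmed:
        gene = next(iter(confirmed))
        muts = sorted(confirmed[gene], key=lambda m: -(m.maf_percent or 0.0))
        has_loh = gene in loh_genes
        large_del = any(m.mutation_type == "genomic deletion" for m in muts)
        if has_loh:
            label = LABEL_LARGE_DEL_LOH if large_del else LABEL_POINT_LOH
        elif len(muts) >= 2:
            label = LABEL_TWO_POINTS
        else:
            label = LABEL_POINT_NO_LOH
        return SampleResult(
            sample_id=sample_id,
            gene=gene,
            mutations=muts + possible,
            cn_loh=has_loh,
            cn_loh_gene=gene if has_loh else None,
            qc_median_depth=qc_median,
            qc_pass=qc_pass,
            summary_label=label,
        )
    if loh_genes:
        return SampleResult(
            sample_id=sample_id,
            gene=GENE_NMI,
            mutations=possible,
            cn_loh=True,
            cn_loh_gene=loh_genes[0],
            qc_median_depth=qc_median,
            qc_pass=qc_pass,
            summary_label=LABEL_LOH_NO_POINT,
        )
    label = LABEL_POSSIBLE if possible else LABEL_NMI
    return SampleResult(
        sample_id=sample_id,
        gene=GENE_NMI,
        mutations=possible,
        cn_loh=False,
        cn_loh_gene=None,
        qc_median_depth=qc_median,
        qc_pass=qc_pass,
        summary_label=label,
    )


def tally_cohort(results: Sequence[SampleResult]) -> CohortSummary:
    """Cohort counts and round-half-up percentages; permutation-invariant."""
    if not results:
        raise ValueError("cannot tally an empty cohort")
    n = len(results)
    tsc1 = [r for r in results if r.gene == "TSC1"]
    tsc2 = [r for r in results if r.gene == "TSC2"]
    nmi = [r for r in results if r.gene == GENE_NMI]
    return CohortSummary(
        n_samples=n,
        n_tsc1=len(tsc1),
        n_tsc2=len(tsc2),
        n_nmi=len(nmi),
        n_tsc1_with_loh=sum(r.cn_loh for r in tsc1),
        n_tsc2_with_loh=sum(r.cn_loh for r in tsc2),
        n_nmi_with_loh=sum(r.cn_loh for r in nmi),
        n_two_point=sum(
            len([m for m in r.mutations if not m.is_possible]) >= 2 and not r.cn_loh
            for r in results
        ),
        pct_tsc1=_round_half_up(100 * len(tsc1) / n),
        pct_tsc2=_round_half_up(100 * len(tsc2) / n),
        pct_nmi=_round_half_up(100 * len(nmi) / n),
    )


FIXTURE_COLUMNS = [
    "case",
    "gene",
    "nucleotide_change",
    "maf_percent",
    "mutation_type",
    "protein_change",
    "cn_loh",
    "summary",
]


def read_results_fixture(path: str | Path | IO[str]) -> list[SampleResult]:
    """Read a published-style per-sample results table into SampleResults.

    The TSV has one row per reported mutation (a sample with two mutations
    spans two rows sharing the case id); empty nucleotide_change means no
    mutation. A row typed ``possible-initiator`` does not count as an
    identified mutation. The cn_loh column (yes/no/empty) is taken as given —
    for externally transcribed results it is the evidence of record.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(FIXTURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"results fixture missing columns: {sorted(missing)}")
    results: list[SampleResult] = []
    for case, grp in df.groupby("case", sort=False):
        mutations: list[Mutation] = []
        gene = GENE_NMI
        cn_loh = False
        cn_loh_gene: str | None = None
        for row in grp.itertuples(index=False):
            if row.cn_loh.strip().lower() == "yes":
                cn_loh = True
                if row.gene and row.gene != GENE_NMI:
                    cn_loh_gene = row.gene
            if row.nucleotide_change:
                mutations.append(
                    Mutation(
                        description=row.nucleotide_change,
                        mutation_type=row.mutation_type,
                        maf_percent=float(row.maf_percent) if row.maf_percent else None,
                    )
                )
                if row.mutation_type != "possible-initiator" and row.gene != GENE_NMI:
                    gene = row.gene
        confirmed = [m for m in mutations if not m.is_possible]
        possible = [m for m in mutations if m.is_possible]
        if gene != GENE_NMI:
            large_del = any(m.mutation_type == "genomic deletion" for m in confirmed)
            if cn_loh:
                label = LABEL_LARGE_DEL_LOH if large_del else LABEL_POINT_LOH
            elif len(confirmed) >= 2:
                label = LABEL_TWO_POINTS
            else:
                label = LABEL_POINT_NO_LOH
        elif cn_loh:
            label = LABEL_LOH_NO_POINT
        elif possible:
            label = LABEL_POSSIBLE
        else:
            label = LABEL_NMI
        results.append(
            SampleResult(
                sample_id=str(case),
                gene=gene,
                mutations=mutations,
                cn_loh=cn_loh,
                cn_loh_gene=cn_loh_gene if gene == GENE_NMI else (gene if cn_loh else None),
                summary_label=label,
            )
        )
    return results


def write_cohort_report(results: Sequence[SampleResult], summary: CohortSummary, out: IO[str]) -> None:
    """TSV of per-sample rows followed by a human-readable tally block."""
    out.write("sample\tgene\tmutations\tmaf_percent\tcn_loh\tcn_loh_gene\tqc_pass\tsummary\n")
    for r in results:
        desc = ";".join(m.description for m in r.mutations) or "."
        mafs = ";".join(
            f"{m.maf_percent:g}" if m.maf_percent is not None else "." for m in r.mutations
        ) or "."
        out.write(
            f"{r.sample_id}\t{r.gene}\t{desc}\t{mafs}\t{str(r.cn_loh).lower()}"
            f"\t{r.cn_loh_gene or '.'}\t{str(r.qc_pass).lower()}\t{r.summary_label}\n"
        )
    out.write("\n")
    out.write(f"# samples: {summary.n_samples}\n")
    out.write(f"# TSC2 mutant: {summary.n_tsc2} ({summary.pct_tsc2}%), with CN-LOH: {summary.n_tsc2_with_loh}\n")
    out.write(f"# TSC1 mutant: {summary.n_tsc1} ({summary.pct_tsc1}%), with CN-LOH: {summary.n_tsc1_with_loh}\n")
    out.write(f"# NMI: {summary.n_nmi} ({summary.pct_nmi}%), with CN-LOH: {summary.n_nmi_with_loh}\n")
    out.write(f"# two-mutation samples without LOH: {summary.n_two_point}\n")
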