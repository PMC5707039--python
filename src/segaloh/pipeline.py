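"""End-to-end orchestration: counts -> screen -> germline -> LOH -> cohort.

Stages communicate through the documented TSV formats so each is
independently runnable and testable; outputs are deterministic for identical
inputs (no timestamps in data files).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import cohort as cohort_mod
from .cohort import Mutation, SampleResult, qc_median_depth, summarize_sample, tally_cohort
from .germline import PopulationCatalog, classify_all
from .loh import LohAssessment, LohError, LohThresholds, call_cnloh, select_informative_snps
from .panel import PanelDefinition
from .pileup import OrientedBaseCounts, allele_observations, parse_pileup
from .screen import (
    STATUS_SOMATIC,
    ScreenThresholds,
    VariantCandidate,
    call_candidates,
    flag_recurrent,
    write_candidates_vcf,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated pipeline settings; thresholds default to the published rule."""

    panel: PanelDefinition
    catalog: PopulationCatalog
    screen: ScreenThresholds = field(default_factory=ScreenThresholds)
    loh: LohThresholds = field(default_factory=LohThresholds)
    qc_min_median_depth: float = 20.0
    tumor_suppressor_genes: tuple[str, ...] = ("TSC1", "TSC2")
    allow_qc_fail: bool = False
    # candidates above the 1% review threshold stay in the audit output, but a
    # mutation is only assigned to a sample at or above this fraction — the
    # screen's reliable sensitivity range; below it, isolated error reads can
    # mimic low-level variants.
    min_somatic_frequency: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        version = doc.get("schema_version", 1)
        if version != 1:
            raise ValueError(f"unsupported config schema_version {version}")
        base = Path(path).parent
        panel_path = Path(doc["panel_bed"])
        catalog_path = Path(doc["catalog_tsv"])
        if not panel_path.is_absolute():
            panel_path = base / panel_path
        if not catalog_path.is_absolute():
            catalog_path = base / catalog_path
        if not panel_path.exists():
            raise FileNotFoundError(f"panel BED not found: {panel_path}")
        if not catalog_path.exists():
            raise FileNotFoundError(f"population catalog not found: {catalog_path}")
        return cls(
            panel=PanelDefinition.read_bed(panel_path),
            catalog=PopulationCatalog.read_tsv(catalog_path),
            screen=ScreenThresholds(**doc.get("screen", {})),
            loh=LohThresholds(**doc.get("loh", {})),
            qc_min_median_depth=float(doc.get("qc_min_median_depth", 20)),
            min_somatic_frequency=float(doc.get("min_somatic_frequency", 0.05)),
            tumor_suppressor_genes=tuple(doc.get("tumor_suppressor_genes", ("TSC1", "TSC2"))),
            allow_qc_fail=bool(doc.get("allow_qc_fail", False)),
        )


@dataclass
class SampleAnalysis:
    """All per-sample artifacts produced by one pipeline run."""

    sample_id: str
    counts: list[OrientedBaseCounts]
    candidates: list[VariantCandidate]
    loh_by_gene: dict[str, LohAssessment]
    result: SampleResult


@dataclass
class PipelineResult:
    samples: dict[str, SampleAnalysis]
    summary: cohort_mod.CohortSummary | None
    excluded_qc: list[str]


def _mutation_from_candidate(cand: VariantCandidate) -> Mutation:
    if cand.alt.startswith("+"):
        mtype = "insertion"
    elif cand.alt.startswith("-"):
        mtype = "deletion"
    else:
        mtype = "substitution"
    desc = f"{cand.position.contig}:{cand.position.pos}{cand.ref}>{cand.alt}"
    return Mutation(description=desc, mutation_type=mtype, maf_percent=100 * cand.frequency)


def analyze_counts(
    sample_id: str,
    counts: list[OrientedBaseCounts],
    candidates: list[VariantCandidate],
    config: PipelineConfig,
) -> SampleAnalysis:
    """Germline-classify, assess LOH per gene and summarize one sample.

    ``candidates`` must already carry any cross-sample recurrence flags.
    """
    candidates = classify_all(candidates, config.catalog)
    qc_median, qc_pass = qc_median_depth(
        counts,
        config.panel,
        [g for g in config.tumor_suppressor_genes if g in config.panel.genes],
        min_median=config.qc_min_median_depth,
    )

    obs_by_pos: dict[tuple[str, int], list] = {}
    counts_by_pos: dict[tuple[str, int], OrientedBaseCounts] = {}
    for c in counts:
        key = (c.position.contig, c.position.pos)
        counts_by_pos[key] = c
        obs_by_pos[key] = allele_observations(c)

    somatic_by_gene: dict[str, list[VariantCandidate]] = {}
    for cand in candidates:
        if cand.status != STATUS_SOMATIC or cand.frequency < config.min_somatic_frequency:
            continue
        gene = config.panel.gene_at(cand.position.contig, cand.position.pos)
        if gene is not None:
            somatic_by_gene.setdefault(gene, []).append(cand)

    loh_by_gene: dict[str, LohAssessment] = {}
    for gene_name in config.tumor_suppressor_genes:
        gene = config.panel.genes.get(gene_name)
        if gene is None:
            continue
        gene_catalog = PopulationCatalog(
            r for r in config.catalog.records() if gene.contains(r.contig, r.pos)
        )
        snps = select_informative_snps(obs_by_pos, gene_catalog, config.loh)
        somatics = somatic_by_gene.get(gene_name, [])
        maf = max((c.frequency for c in somatics), default=None)
        try:
            loh_by_gene[gene_name] = call_cnloh(maf, snps, config.loh, gene=gene_name)
        except LohError:
            logger.info("sample %s gene %s unevaluable for LOH", sample_id, gene_name)

    somatic_mutations = {
        g: [_mutation_from_candidate(c) for c in cands]
        for g, cands in somatic_by_gene.items()
        if g in config.tumor_suppressor_genes
    }
    result = summarize_sample(sample_id, somatic_mutations, loh_by_gene, qc_median, qc_pass)
    return SampleAnalysis(
        sample_id=sample_id,
        counts=counts,
        candidates=candidates,
        loh_by_gene=loh_by_gene,
        result=result,
    )


def run_pipeline(
    config: PipelineConfig,
    pileup_texts: Mapping[str, str | Sequence[str]],
) -> PipelineResult:
    """Run all stages over a cohort of single-sample pileup texts.

    Samples failing the median-depth QC gate are excluded from the tally
    (with a logged reason) unless ``config.allow_qc_fail`` is set; their
    per-sample artifacts are still produced for audit.
    """
    if not pileup_texts:
        raise ValueError("no samples given")
    counts_by_sample: dict[str, list[OrientedBaseCounts]] = {}
    raw_candidates: dict[str, list[VariantCandidate]] = {}
    for sample_id, text in pileup_texts.items():
        lines = text.splitlines() if isinstance(text, str) else text
        counts = list(parse_pileup(lines))
        counts_by_sample[sample_id] = counts
        obs = [o for c in counts for o in allele_observations(c)]
        raw_candidates[sample_id] = call_candidates(obs, sample_id, config.screen)

    if len(raw_candidates) >= 2:
        raw_candidates = flag_recurrent(raw_candidates, config.catalog.snp_sites, config.screen)

    samples: dict[str, SampleAnalysis] = {}
    excluded: list[str] = []
    for sample_id in pileup_texts:
        analysis = analyze_counts(
            sample_id, counts_by_sample[sample_id], raw_candidates[sample_id], config
        )
        samples[sample_id] = analysis
        if not analysis.result.qc_pass and not config.allow_qc_fail:
            logger.warning(
                "sample %s excluded: median coding depth %.1f below %.0fx",
                sample_id,
                analysis.result.qc_median_depth or 0.0,
                config.qc_min_median_depth,
            )
            excluded.append(sample_id)

    kept = [a.result for sid, a in samples.items() if sid not in excluded]
    summary = tally_cohort(kept) if kept else None
    return PipelineResult(samples=samples, summary=summary, excluded_qc=excluded)


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write per-sample audit files and the cohort report under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    loh_rows = []
    for sample_id, analysis in result.samples.items():
        with open(out / f"{sample_id}.candidates.vcf", "w") as fh:
            write_candidates_vcf(analysis.candidates, fh)
        for gene, assessment in analysis.loh_by_gene.items():
            muts = [m.description for m in analysis.result.mutations]
            loh_rows.append((sample_id, ";".join(muts), assessment))
    from .loh import write_loh_report

    with open(out / "loh_report.tsv", "w") as fh:
        write_loh_report(loh_rows, fh)
    if result.summary is not None:
        kept = [
            a.result for sid, a in result.samples.items() if sid not in result.excluded_qc
        ]
        with open(out / "cohort_report.tsv", "w") as fh:
            cohort_mod.write_cohort_report(kept, result.summary, fh)
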