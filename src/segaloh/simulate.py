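"""Targeted-panel tumor read-count simulator with known truth.

Emulates what a targeted capture of two tumor-suppressor genes plus a control
oncogene interval yields after alignment and pileup: per-position read depths
(Poisson), read orientations (fair binomial split except at strand-biased
artifact positions), germline heterozygous SNPs, an optional somatic mutation
with an optional second hit, recurrent cross-sample artifact alleles, and a
uniform per-base substitution error rate.

Closed-form expected allele fractions under tumor purity p (copy-neutral
two-hit genetics):

* somatic mutation, heterozygous, no LOH: p/2;
* somatic mutation with copy-neutral LOH (mutant haplotype duplicated): p;
* germline het SNP, no LOH: 1/2;
* germline het SNP under CN-LOH: (1 + p)/2 or (1 - p)/2 depending on phase,
  i.e. minor allele fraction (1 - p)/2.

The simulator first draws integer allele counts and then encodes them as
pileup text, so parsing recovers the planted counts exactly; identical
(config, seed, sample index) yields byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .germline import PopulationCatalog, PopulationRecord
from .panel import GeneRegion, Interval, PanelDefinition

_BASES = "ACGT"


def reference_base(pos: int) -> str:
    """Deterministic pseudo-reference base at a 1-based position."""
    return _BASES[pos % 4]


def _alt_base(ref: str, offset: int = 1) -> str:
    return _BASES[(_BASES.index(ref) + offset) % 4]


@dataclass(frozen=True)
class MutationSpec:
    """A somatic mutation to plant: site, allele key, and reported type."""

    gene: str
    contig: str
    pos: int
    alt: str  # substitution base, "+SEQ" insertion, or "-SEQ" deletion
    mutation_type: str = "nonsense"
    description: str = ""

    @property
    def ref(self) -> str:
        return reference_base(self.pos)


@dataclass(frozen=True)
class ArtifactSpec:
    """Recurrent process-artifact model shared across cohort samples."""

    n_recurrent_positions: int = 0
    artifact_frequency: float = 0.03
    strand_bias: float = 1.0  # fraction of artifact reads on the forward strand


@dataclass
class SampleSpec:
    """Per-sample truth to plant: the mutation (or None) and the second hit.

    ``loh_gene`` lets a sample carry CN-LOH without any point mutation (the
    "CN-LOH, no point" pattern); it defaults to the mutation's gene.
    """

    mutation: MutationSpec | None = None
    second_hit: str = "none"  # cn_loh | second_point | none
    second_mutation: MutationSpec | None = None
    loh_gene: str | None = None


@dataclass
class SimulationConfig:
    panel: PanelDefinition
    snps: list[PopulationRecord]
    n_samples: int = 1
    purity: float = 0.7
    depth_mean: float = 100.0
    mutation_spec: MutationSpec | None = None
    second_hit: str = "none"
    het_snp_rate: float = 0.5
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        for frac in (self.het_snp_rate, self.error_rate):
            if not 0 <= frac <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.second_hit not in ("cn_loh", "second_point", "none"):
            raise ValueError(f"unknown second_hit {self.second_hit!r}")
        if self.mutation_spec is not None:
            m = self.mutation_spec
            if self.panel.gene_at(m.contig, m.pos) != m.gene:
                raise ValueError(
                    f"mutation at {m.contig}:{m.pos} is not inside panel gene {m.gene}"
                )


@dataclass
class SampleTruth:
    """What was planted in one simulated sample."""

    sample_id: str
    purity: float
    mutation: MutationSpec | None
    second_mutation: MutationSpec | None
    second_hit: str
    cn_loh: bool
    loh_gene: str | None
    expected_mutant_af: float | None
    expected_snp_minor_af_loh_gene: float | None
    het_snps: list[tuple[str, int, str, int]]  # (contig, pos, alt, phase)
    artifact_positions: list[tuple[str, int, str]]
    seed: int

    def to_json(self) -> str:
        d = asdict(self)
        d["mutation"] = asdict(self.mutation) if self.mutation else None
        d["second_mutation"] = asdict(self.second_mutation) if self.second_mutation else None
        return json.dumps(d, indent=1, sort_keys=True)


def default_panel() -> PanelDefinition:
    """A compact panel emulating TSC1/TSC2 capture plus a BRAF control exon."""
    genes = {
        "TSC1": GeneRegion(
            "TSC1",
            Interval("chr9", 135771000, 135771240),
            [Interval("chr9", 135771020, 135771120), Interval("chr9", 135771140, 135771220)],
        ),
        "TSC2": GeneRegion(
            "TSC2",
            Interval("chr16", 2110000, 2110240),
            [Interval("chr16", 2110020, 2110120), Interval("chr16", 2110140, 2110220)],
        ),
        "BRAF": GeneRegion(
            "BRAF",
            Interval("chr7", 140453000, 140453120),
            [Interval("chr7", 140453020, 140453110)],
        ),
    }
    return PanelDefinition(genes=genes)


_SNP_AF_CYCLE = (0.35, 0.20, 0.10, 0.05, 0.01)


def default_snps(panel: PanelDefinition, per_gene: int = 20, spacing: int | None = None) -> list[PopulationRecord]:
    """Evenly spaced catalog SNPs inside each gene interval.

    Population AFs cycle through common-to-rare values; all are well above
    the 0.05% informativeness floor. Carrier counts and subset AFs are set so
    the germline rules recognize them (and the recurrence filter exempts them).
    """
    records: list[PopulationRecord] = []
    for gene in panel.genes.values():
        iv = gene.interval
        step = spacing or max(1, len(iv) // (per_gene + 1))
        positions = [iv.start + 1 + (k + 1) * step for k in range(per_gene)]
        positions = [p for p in positions if iv.contains(iv.contig, p)]
        for k, pos in enumerate(positions[:per_gene]):
            ref = reference_base(pos)
            af = _SNP_AF_CYCLE[k % len(_SNP_AF_CYCLE)]
            records.append(
                PopulationRecord(
                    contig=iv.contig,
                    pos=pos,
                    ref=ref,
                    alt=_alt_base(ref),
                    af_overall=af,
                    af_african_american=af,
                    af_european_american=af,
                    normal_carrier_count=1000,
                    cosmic_count=0,
                )
            )
    return records


def artifact_positions(config: SimulationConfig) -> list[tuple[str, int, str]]:
    """Cohort-wide recurrent artifact sites, deterministic in config.seed.

    Positions are drawn from the panel away from catalog SNPs and the planted
    mutation; the artifact allele is a fixed non-reference base.
    """
    spec = config.artifact_spec
    if spec.n_recurrent_positions == 0:
        return []
    rng = np.random.default_rng([config.seed % (2**31), 7919])
    taken = {(r.contig, r.pos) for r in config.snps}
    if config.mutation_spec:
        taken.add((config.mutation_spec.contig, config.mutation_spec.pos))
    pool = [
        (iv.contig, pos)
        for g in config.panel.genes.values()
        for iv in [g.interval]
        for pos in iv.positions()
        if (iv.contig, pos) not in taken
    ]
    idx = rng.choice(len(pool), size=min(spec.n_recurrent_positions, len(pool)), replace=False)
    out = []
    for i in sorted(idx):
        contig, pos = pool[i]
        ref = reference_base(pos)
        out.append((contig, pos, _alt_base(ref, 2)))
    return out


def _encode_reads(ref_symbol: str, counts: dict[str, int], forward: bool) -> str:
    """Encode one orientation's allele counts as pileup read-base symbols."""
    chunks: list[str] = []
    for allele in sorted(counts):
        n = counts[allele]
        if allele == "ref":
            chunks.append(ref_symbol * n)
        elif allele[0] in "+-":
            seq = allele[1:] if forward else allele[1:].lower()
            chunks.append((ref_symbol + allele[0] + str(len(seq)) + seq) * n)
        else:
            base = allele if forward else allele.lower()
            chunks.append(base * n)
    return "".join(chunks)


def simulate_sample(
    config: SimulationConfig,
    sample_index: int = 0,
    sample_spec: SampleSpec | None = None,
) -> tuple[str, SampleTruth]:
    """Simulate one tumor sample; returns (pileup text, truth record).

    ``sample_spec`` overrides the config's cohort-wide mutation/second-hit
    choice for this sample (used when composing mixed cohorts).
    """
    if sample_spec is None:
        sample_spec = SampleSpec(
            mutation=config.mutation_spec,
            second_hit=config.second_hit,
        )
    mutation = sample_spec.mutation
    second_hit = sample_spec.second_hit
    if mutation is not None and config.panel.gene_at(mutation.contig, mutation.pos) != mutation.gene:
        raise ValueError(f"mutation at {mutation.contig}:{mutation.pos} outside panel gene {mutation.gene}")

    p = config.purity
    rng = np.random.default_rng([config.seed % (2**31), 104729, sample_index])
    sample_id = f"S{sample_index:03d}"

    loh_gene = sample_spec.loh_gene or (mutation.gene if mutation else None)
    cn_loh = second_hit == "cn_loh" and loh_gene is not None
    expected_maf = None if mutation is None else (p if cn_loh else p / 2)

    # germline het SNPs for this sample; phase 1 = alt on the kept haplotype
    het_snps: list[tuple[str, int, str, int]] = []
    snp_af: dict[tuple[str, int], tuple[str, float]] = {}
    for rec in config.snps:
        if rng.random() >= config.het_snp_rate:
            continue
        phase = int(rng.random() < 0.5)
        gene = config.panel.gene_at(rec.contig, rec.pos)
        if cn_loh and gene == loh_gene:
            af = (1 + p) / 2 if phase else (1 - p) / 2
        else:
            af = 0.5
        het_snps.append((rec.contig, rec.pos, rec.alt, phase))
        snp_af[(rec.contig, rec.pos)] = (rec.alt, af)

    planted: dict[tuple[str, int], tuple[str, float]] = {}
    if mutation is not None:
        planted[(mutation.contig, mutation.pos)] = (mutation.alt, expected_maf)
    second = sample_spec.second_mutation
    if second_hit == "second_point" and second is not None:
        planted[(second.contig, second.pos)] = (second.alt, p / 2)

    artifacts = artifact_positions(config)
    artifact_at = {(c, pos): alt for c, pos, alt in artifacts}
    spec = config.artifact_spec

    lines: list[str] = []
    for gene in config.panel.genes.values():
        iv = gene.interval
        for pos in iv.positions():
            depth = int(rng.poisson(config.depth_mean))
            if depth == 0:
                continue
            d_f = int(rng.binomial(depth, 0.5))
            d_r = depth - d_f
            ref = reference_base(pos)
            key = (iv.contig, pos)

            # orientation-specific allele probabilities
            probs_f: dict[str, float] = {}
            probs_r: dict[str, float] = {}
            for b in _BASES:
                if b != ref and config.error_rate > 0:
                    probs_f[b] = probs_r[b] = config.error_rate / 3
            for source in (snp_af, planted):
                if key in source:
                    alt, af = source[key]
                    probs_f[alt] = probs_f.get(alt, 0.0) + af
                    probs_r[alt] = probs_r.get(alt, 0.0) + af
            if key in artifact_at:
                alt = artifact_at[key]
                probs_f[alt] = probs_f.get(alt, 0.0) + min(
                    1.0, spec.artifact_frequency * 2 * spec.strand_bias
                )
                probs_r[alt] = probs_r.get(alt, 0.0) + min(
                    1.0, spec.artifact_frequency * 2 * (1 - spec.strand_bias)
                )

            counts_f = _draw_counts(rng, d_f, probs_f)
            counts_r = _draw_counts(rng, d_r, probs_r)
            bases = _encode_reads(".", counts_f, True) + _encode_reads(",", counts_r, False)
            quals = "I" * depth
            lines.append(f"{iv.contig}\t{pos}\t{ref}\t{depth}\t{bases}\t{quals}")

    truth = SampleTruth(
        sample_id=sample_id,
        purity=p,
        mutation=mutation,
        second_mutation=second if second_hit == "second_point" else None,
        second_hit=second_hit,
        cn_loh=cn_loh,
        loh_gene=loh_gene if cn_loh else None,
        expected_mutant_af=expected_maf,
        expected_snp_minor_af_loh_gene=(1 - p) / 2 if cn_loh else (0.5 if het_snps else None),
        het_snps=het_snps,
        artifact_positions=artifacts,
        seed=config.seed,
    )
    return "\n".join(lines) + "\n", truth


def _draw_counts(rng: np.random.Generator, depth: int, alt_probs: dict[str, float]) -> dict[str, int]:
    """Multinomial split of one orientation's reads over ref + alt alleles."""
    if depth == 0:
        return {}
    alleles = sorted(alt_probs)
    p_alt = np.array([alt_probs[a] for a in alleles], dtype=float)
    p_ref = max(0.0, 1.0 - p_alt.sum())
    pvec = np.concatenate([[p_ref], p_alt])
    pvec = pvec / pvec.sum()
    draws = rng.multinomial(depth, pvec)
    counts = {"ref": int(draws[0])}
    for allele, c in zip(alleles, draws[1:]):
        if c > 0:
            counts[allele] = int(c)
    if counts["ref"] == 0:
        del counts["ref"]
    return counts


@dataclass
class CohortSimulation:
    """A simulated cohort: pileups + truths per sample, shared catalog/panel."""

    pileups: dict[str, str]
    truths: dict[str, SampleTruth]
    catalog: PopulationCatalog
    panel: PanelDefinition


def simulate_cohort(
    config: SimulationConfig,
    sample_specs: Sequence[SampleSpec] | None = None,
) -> CohortSimulation:
    """Simulate ``n_samples`` tumors sharing artifact sites and SNP catalog.

    ``sample_specs``, when given, fixes each sample's planted mutation and
    second hit (its length overrides ``config.n_samples``); otherwise all
    samples follow the cohort-wide config.
    """
    n = len(sample_specs) if sample_specs is not None else config.n_samples
    if n < 1:
        raise ValueError("need at least one sample")
    pileups: dict[str, str] = {}
    truths: dict[str, SampleTruth] = {}
    for i in range(n):
        spec = sample_specs[i] if sample_specs is not None else None
        text, truth = simulate_sample(config, i, spec)
        pileups[truth.sample_id] = text
        truths[truth.sample_id] = truth
    catalog = PopulationCatalog(config.snps)
    return CohortSimulation(pileups=pileups, truths=truths, catalog=catalog, panel=config.panel)
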