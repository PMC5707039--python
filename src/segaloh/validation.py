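"""Seeded validation experiments exercising the full pipeline on planted truth.

These routines regenerate synthetic cohorts from scratch, run the pipeline,
and score it against the simulator's closed-form truth: a wild-type negative
control over a BRAF-like exon, CN-LOH sensitivity/specificity and mutation
recovery at fixed purity and depth, high-depth convergence to the closed-form
allele fractions, and agreement between the pileup parser and an independent
construction oracle.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np

from .germline import PopulationCatalog
from .panel import GeneRegion, Interval, PanelDefinition
from .pileup import allele_observations, parse_pileup
from .pipeline import PipelineConfig, run_pipeline
from .screen import STATUS_SOMATIC
from .simulate import (
    MutationSpec,
    SampleSpec,
    SimulationConfig,
    default_panel,
    default_snps,
    reference_base,
    simulate_cohort,
    simulate_sample,
)

MAX_SEED = 2**31


def _sub_alt(pos: int) -> str:
    ref = reference_base(pos)
    return "ACGT"[("ACGT".index(ref) + 1) % 4]


def single_gene_panel(n_snps: int = 50) -> tuple[PanelDefinition, list, MutationSpec]:
    """A one-gene panel sized for ``n_snps`` catalog SNPs plus a mutation site."""
    length = 6 * (n_snps + 2)
    panel = PanelDefinition(
        genes={
            "TSC2": GeneRegion(
                "TSC2",
                Interval("chr16", 2110000, 2110000 + length),
                [Interval("chr16", 2110000, 2110000 + length)],
            )
        }
    )
    snps = default_snps(panel, per_gene=n_snps, spacing=6)
    snp_pos = {r.pos for r in snps}
    mut_pos = next(
        p for p in range(2110003, 2110000 + length) if p not in snp_pos
    )
    mutation = MutationSpec("TSC2", "chr16", mut_pos, _sub_alt(mut_pos))
    return panel, snps, mutation


def braf_negative_control(
    seed: int, n_samples: int = 31, depth: float = 100.0, error_rate: float = 0.002,
    min_frequency: float = 0.05,
) -> dict:
    """Screen wild-type samples over the BRAF-like interval.

    Returns the number of somatic candidates at or above ``min_frequency``
    across all samples — the published screen saw none even at 5-10%
    sensitivity.
    """
    full = default_panel()
    panel = PanelDefinition(genes={"BRAF": full.genes["BRAF"]})
    snps = default_snps(panel, per_gene=5)
    config = SimulationConfig(
        panel=panel,
        snps=snps,
        n_samples=n_samples,
        depth_mean=depth,
        error_rate=error_rate,
        het_snp_rate=0.5,
        seed=seed % MAX_SEED,
    )
    sim = simulate_cohort(config)
    pipe = PipelineConfig(panel=panel, catalog=sim.catalog, tumor_suppressor_genes=("BRAF",))
    result = run_pipeline(pipe, sim.pileups)
    n_hits = sum(
        1
        for analysis in result.samples.values()
        for cand in analysis.candidates
        if cand.status == STATUS_SOMATIC and cand.frequency >= min_frequency
    )
    return {"n_samples": n_samples, "n_somatic_ge_threshold": n_hits}


@dataclass
class RecoveryResult:
    n_replicates: int
    sensitivity: float
    specificity: float
    mutation_recovery: float


def cnloh_parameter_recovery(
    seed: int,
    n_replicates: int = 200,
    purity: float = 0.7,
    depth: float = 100.0,
    n_snps: int = 50,
) -> RecoveryResult:
    """Score CN-LOH calling and mutation recovery over seeded replicates.

    Each replicate simulates two tumors carrying the same point mutation —
    one with copy-neutral LOH as the second hit, one without — runs the full
    single-sample pipeline on each, and records whether LOH was called and
    whether the planted mutation surfaced as a somatic candidate.
    """
    panel, snps, mutation = single_gene_panel(n_snps)
    catalog = PopulationCatalog(snps)
    pipe = PipelineConfig(panel=panel, catalog=catalog)
    loh_called = no_loh_called = recovered = planted = 0
    for r in range(n_replicates):
        config = SimulationConfig(
            panel=panel,
            snps=snps,
            purity=purity,
            depth_mean=depth,
            het_snp_rate=1.0,
            seed=(seed + 1_000_003 * r) % MAX_SEED,
        )
        for second_hit, is_loh in (("cn_loh", True), ("none", False)):
            text, _truth = simulate_sample(
                config, 0, SampleSpec(mutation=mutation, second_hit=second_hit)
            )
            result = run_pipeline(pipe, {"s": text})
            analysis = result.samples["s"]
            if analysis.result.cn_loh:
                if is_loh:
                    loh_called += 1
                else:
                    no_loh_called += 1
            planted += 1
            if any(
                c.status == STATUS_SOMATIC
                and c.position.pos == mutation.pos
                and c.alt == mutation.alt
                for c in analysis.candidates
            ):
                recovered += 1
    return RecoveryResult(
        n_replicates=n_replicates,
        sensitivity=loh_called / n_replicates,
        specificity=1.0 - no_loh_called / n_replicates,
        mutation_recovery=recovered / planted,
    )


def closed_form_limits(seed: int, purity: float = 0.7, depth: float = 10_000.0, n_snps: int = 50) -> dict:
    """High-depth convergence of realized allele fractions to closed forms.

    Under CN-LOH at purity p the mutant allele fraction approaches p and the
    median SNP minor allele fraction approaches (1 - p)/2.
    """
    panel, snps, mutation = single_gene_panel(n_snps)
    config = SimulationConfig(
        panel=panel,
        snps=snps,
        purity=purity,
        depth_mean=depth,
        het_snp_rate=1.0,
        mutation_spec=mutation,
        second_hit="cn_loh",
        seed=seed % MAX_SEED,
    )
    text, _ = simulate_sample(config, 0)
    counts_by_pos = {c.position.pos: c for c in parse_pileup(text.splitlines())}
    mutant_af = counts_by_pos[mutation.pos].count(mutation.alt) / counts_by_pos[mutation.pos].depth_total

    from .loh import select_informative_snps

    obs_by_pos = {
        (c.position.contig, c.position.pos): allele_observations(c)
        for c in parse_pileup(text.splitlines())
    }
    informative = select_informative_snps(obs_by_pos, PopulationCatalog(snps))
    median_minor = float(np.median([s.minor_allele_fraction for s in informative]))
    return {
        "mutant_af": mutant_af,
        "expected_mutant_af": purity,
        "median_minor_af": median_minor,
        "expected_median_minor_af": (1 - purity) / 2,
        "n_informative_snps": len(informative),
    }


def random_line_tokens(rng: random.Random, max_symbols: int = 50):
    """Random pileup read tokens plus their expected oriented counts.

    The expected counts come from the construction itself — each token's
    meaning is fixed when it is generated — so they are independent of any
    parsing code and serve as an enumeration oracle for the parser.
    """
    n = rng.randint(1, max_symbols)
    fwd: dict[str, int] = {}
    rev: dict[str, int] = {}
    chunks: list[str] = []
    bases = "ACGT"
    for _ in range(n):
        if rng.random() < 0.15:
            chunks.append("^" + chr(rng.randint(33, 126)))
        forward = rng.random() < 0.5
        r = rng.random()
        if r < 0.45:
            sym, key = (".", "ref") if forward else (",", "ref")
        elif r < 0.75:
            b = rng.choice(bases + "N")
            sym, key = (b, b) if forward else (b.lower(), b)
        elif r < 0.85:
            sym, key = ("*", "*") if forward else ("#", "*")
        else:
            sign = rng.choice("+-")
            seq = "".join(rng.choice(bases) for _ in range(rng.randint(1, 4)))
            anchor = "." if forward else ","
            written = seq if forward else seq.lower()
            sym = anchor + sign + str(len(seq)) + written
            key = sign + seq
        chunks.append(sym)
        target = fwd if forward else rev
        target[key] = target.get(key, 0) + 1
        if rng.random() < 0.1:
            chunks.append("$")
    return "".join(chunks), fwd, rev, n


def parser_oracle_agreement(seed: int, n_cases: int = 1000) -> dict:
    """Fraction of randomized pileup lines where parsed counts equal the
    construction oracle's expected counts exactly."""
    rng = random.Random(seed % MAX_SEED)
    agree = 0
    for _ in range(n_cases):
        bases, fwd, rev, depth = random_line_tokens(rng)
        line = f"chrX\t100\tC\t{depth}\t{bases}\t{'I' * depth}"
        counts = next(parse_pileup([line]))
        if counts.counts_forward == fwd and counts.counts_reverse == rev:
            agree += 1
    return {"n_cases": n_cases, "n_agree": agree, "agreement": agree / n_cases}
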