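"""Simulator truth: determinism, closed-form allele fractions, construction."""

from __future__ import annotations

import numpy as np
import pytest

from segaloh.loh import LohThresholds, call_cnloh, select_informative_snps
from segaloh.germline import PopulationCatalog
from segaloh.pileup import allele_observations, parse_pileup
from segaloh.simulate import (
    ArtifactSpec,
    MutationSpec,
    SampleSpec,
    SimulationConfig,
    artifact_positions,
    default_panel,
    default_snps,
    reference_base,
    simulate_cohort,
    simulate_sample,
)


def make_config(panel=None, snps=None, **kw):
    panel = panel or default_panel()
    snps = snps if snps is not None else default_snps(panel)
    return SimulationConfig(panel=panel, snps=snps, **kw)


def tsc1_mutation(pos: int = 135771030, alt: str | None = None) -> MutationSpec:
    ref = reference_base(pos)
    alt = alt or "ACGT"[("ACGT".index(ref) + 1) % 4]
    return MutationSpec(gene="TSC1", contig="chr9", pos=pos, alt=alt)


def planted_fraction(pileup_text: str, pos: int, alt: str) -> float:
    for counts in parse_pileup(pileup_text.splitlines()):
        if counts.position.pos == pos:
            return counts.count(alt) / counts.depth_total
    raise AssertionError(f"position {pos} not simulated")


class TestDeterminism:
    def test_same_seed_same_bytes(self):
        cfg = make_config(seed=9, purity=0.6, mutation_spec=tsc1_mutation(), second_hit="cn_loh")
        a, _ = simulate_sample(cfg, 0)
        b, _ = simulate_sample(cfg, 0)
        assert a == b

    def test_different_sample_index_differs(self):
        cfg = make_config(seed=9)
        a, _ = simulate_sample(cfg, 0)
        b, _ = simulate_sample(cfg, 1)
        assert a != b

    def test_artifact_positions_deterministic_and_disjoint(self):
        cfg = make_config(
            seed=4,
            mutation_spec=tsc1_mutation(),
            artifact_spec=ArtifactSpec(n_recurrent_positions=3),
        )
        arts = artifact_positions(cfg)
        assert arts == artifact_positions(cfg)
        snp_pos = {(r.contig, r.pos) for r in cfg.snps}
        for contig, pos, _alt in arts:
            assert (contig, pos) not in snp_pos
            assert (contig, pos) != ("chr9", 135771030)


class TestClosedForms:
    def test_cnloh_mutant_fraction_near_purity(self):
        """Planted-site mutant fraction lies within 4 binomial SDs of p."""
        p, depth = 0.7, 100.0
        cfg = make_config(purity=p, depth_mean=depth, seed=21,
                          mutation_spec=tsc1_mutation(), second_hit="cn_loh")
        text, truth = simulate_sample(cfg, 0)
        assert truth.expected_mutant_af == pytest.approx(p)
        frac = planted_fraction(text, 135771030, truth.mutation.alt)
        tol = 4 * np.sqrt(p * (1 - p) / depth)
        assert abs(frac - p) < tol

    def test_pure_het_tumor_without_second_hit(self):
        cfg = make_config(purity=1.0, depth_mean=400, seed=2,
                          mutation_spec=tsc1_mutation(), second_hit="none")
        text, truth = simulate_sample(cfg, 0)
        assert truth.expected_mutant_af == pytest.approx(0.5)
        frac = planted_fraction(text, 135771030, truth.mutation.alt)
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / 400)

    def test_high_depth_convergence_within_one_percent(self):
        """At depth 10,000 both closed forms are recovered within 1%:
        mutant AF -> p under CN-LOH, median SNP minor AF -> (1-p)/2."""
        p = 0.7
        cfg = make_config(purity=p, depth_mean=10_000, seed=33, het_snp_rate=1.0,
                          mutation_spec=tsc1_mutation(), second_hit="cn_loh")
        text, truth = simulate_sample(cfg, 0)
        frac = planted_fraction(text, 135771030, truth.mutation.alt)
        assert abs(frac - p) < 0.01

        obs_by_pos = {}
        for counts in parse_pileup(text.splitlines()):
            obs_by_pos[(counts.position.contig, counts.position.pos)] = allele_observations(counts)
        tsc1_catalog = PopulationCatalog(r for r in cfg.snps if r.contig == "chr9")
        snps = select_informative_snps(obs_by_pos, tsc1_catalog)
        assert len(snps) == len(tsc1_catalog.records())
        median = float(np.median([s.minor_allele_fraction for s in snps]))
        assert abs(median - (1 - p) / 2) < 0.01

    def test_snps_balanced_without_loh(self):
        cfg = make_config(purity=0.7, depth_mean=10_000, seed=34, het_snp_rate=1.0,
                          mutation_spec=tsc1_mutation(), second_hit="none")
        text, _ = simulate_sample(cfg, 0)
        obs_by_pos = {
            (c.position.contig, c.position.pos): allele_observations(c)
            for c in parse_pileup(text.splitlines())
        }
        tsc1_catalog = PopulationCatalog(r for r in cfg.snps if r.contig == "chr9")
        snps = select_informative_snps(obs_by_pos, tsc1_catalog)
        median = float(np.median([s.minor_allele_fraction for s in snps]))
        assert abs(median - 0.5) < 0.01


class TestConstruction:
    def test_fully_biased_artifact_on_one_orientation_only(self):
        cfg = make_config(
            seed=6,
            depth_mean=150,
            artifact_spec=ArtifactSpec(n_recurrent_positions=1, artifact_frequency=0.05, strand_bias=1.0),
        )
        text, truth = simulate_sample(cfg, 0)
        (contig, pos, alt) = truth.artifact_positions[0]
        for counts in parse_pileup(text.splitlines()):
            if counts.position.pos == pos and counts.position.contig == contig:
                assert counts.counts_reverse.get(alt, 0) == 0
                assert counts.counts_forward.get(alt, 0) > 0
                return
        raise AssertionError("artifact position missing from pileup")

    def test_recurrent_artifacts_shared_across_cohort(self):
        cfg = make_config(
            seed=6,
            n_samples=8,
            depth_mean=150,
            artifact_spec=ArtifactSpec(n_recurrent_positions=2, artifact_frequency=0.05),
        )
        sim = simulate_cohort(cfg)
        arts = {a for t in sim.truths.values() for a in t.artifact_positions}
        assert len(arts) == 2
        for contig, pos, alt in arts:
            carrying = sum(
                any(
                    c.position.pos == pos and c.count(alt) > 0
                    for c in parse_pileup(text.splitlines())
                )
                for text in sim.pileups.values()
            )
            assert carrying >= 3

    def test_parse_recovers_depth_and_truth_json_round_trips(self):
        cfg = make_config(seed=8, depth_mean=60, mutation_spec=tsc1_mutation(135771031, alt="+TT"))
        text, truth = simulate_sample(cfg, 0)
        total_positions = sum(
            len(g.interval) for g in cfg.panel.genes.values()
        )
        parsed = list(parse_pileup(text.splitlines()))
        assert 0 < len(parsed) <= total_positions
        import json

        doc = json.loads(truth.to_json())
        assert doc["mutation"]["alt"] == "+TT"
        assert doc["purity"] == cfg.purity

    def test_mutation_outside_panel_rejected(self):
        with pytest.raises(ValueError, match="not inside panel gene"):
            make_config(mutation_spec=MutationSpec("TSC1", "chr1", 5, "A"))

    def test_loh_only_sample_spec(self):
        cfg = make_config(seed=12, depth_mean=10_000, het_snp_rate=1.0)
        _, truth = simulate_sample(cfg, 0, SampleSpec(second_hit="cn_loh", loh_gene="TSC2"))
        assert truth.cn_loh and truth.loh_gene == "TSC2" and truth.mutation is None

    def test_config_validation(self):
        with pytest.raises(ValueError):
            make_config(purity=0.0)
        with pytest.raises(ValueError):
            make_config(second_hit="bogus")
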