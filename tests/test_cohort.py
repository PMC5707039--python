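"""QC gating, sample summarization and cohort tallies."""

from __future__ import annotations

import io
import random

import pytest

from segaloh.cohort import (
    LABEL_LARGE_DEL_LOH,
    LABEL_LOH_NO_POINT,
    LABEL_NMI,
    LABEL_POINT_LOH,
    LABEL_POINT_NO_LOH,
    LABEL_POSSIBLE,
    LABEL_TWO_POINTS,
    Mutation,
    MultiGeneConflictError,
    QcError,
    SampleResult,
    qc_median_depth,
    read_results_fixture,
    summarize_sample,
    tally_cohort,
    write_cohort_report,
)
from segaloh.loh import LohAssessment
from segaloh.pileup import GenomicPosition, OrientedBaseCounts


def flat_counts(panel, depth: int, genes=("TSC1", "TSC2")):
    out = []
    for contig, pos in panel.coding_positions([g for g in genes if g in panel.genes]):
        half = depth // 2
        out.append(
            OrientedBaseCounts(
                GenomicPosition(contig, pos),
                "A",
                {"ref": half},
                {"ref": depth - half},
            )
        )
    return out


def loh(gene: str, yes: bool) -> LohAssessment:
    return LohAssessment(
        gene=gene,
        mutation_maf=None,
        snp_observations=[],
        median_minor_af=0.2 if yes else 0.48,
        cn_loh=yes,
        branch="snp_branch" if yes else "none",
    )


class TestQcMedianDepth:
    def test_cohort_typical_depth_passes(self, panel):
        median, ok = qc_median_depth(flat_counts(panel, 107), panel)
        assert median == 107 and ok

    def test_below_20x_fails(self, panel):
        _, ok = qc_median_depth(flat_counts(panel, 19), panel)
        assert not ok

    def test_exactly_20x_passes(self, panel):
        median, ok = qc_median_depth(flat_counts(panel, 20), panel)
        assert median == 20 and ok

    def test_uncovered_positions_count_as_zero(self, panel):
        counts = flat_counts(panel, 100)[:10]
        median, ok = qc_median_depth(counts, panel)
        assert median == 0 and not ok

    def test_no_coding_intervals_is_an_error(self, panel):
        from segaloh.panel import GeneRegion, Interval, PanelDefinition

        bare = PanelDefinition(
            genes={"X": GeneRegion("X", Interval("chr1", 0, 10), [])}
        )
        with pytest.raises(QcError):
            qc_median_depth([], bare)


class TestSummarizeSample:
    def test_point_with_cnloh(self):
        r = summarize_sample(
            "s1",
            {"TSC2": [Mutation("c.3412C>T", "nonsense", 68.0)]},
            {"TSC2": loh("TSC2", True)},
        )
        assert r.summary_label == LABEL_POINT_LOH
        assert r.gene == "TSC2" and r.cn_loh and r.cn_loh_gene == "TSC2"

    def test_point_without_loh(self):
        r = summarize_sample(
            "s1",
            {"TSC2": [Mutation("c.4375C>T", "nonsense", 50.0)]},
            {"TSC2": loh("TSC2", False)},
        )
        assert r.summary_label == LABEL_POINT_NO_LOH and not r.cn_loh

    def test_two_mutations_same_gene_without_loh(self):
        r = summarize_sample(
            "s1",
            {
                "TSC2": [
                    Mutation("c.3814+1G>C", "splice", 47.0),
                    Mutation("c.1831C>T", "missense", 15.0),
                ]
            },
            {"TSC2": loh("TSC2", False)},
        )
        assert r.summary_label == LABEL_TWO_POINTS
        assert r.mutations[0].maf_percent == 47.0  # sorted, higher MAF first

    def test_loh_without_mutation_is_nmi_with_loh(self):
        r = summarize_sample("s1", {}, {"TSC2": loh("TSC2", True)})
        assert r.gene == "NMI"
        assert r.summary_label == LABEL_LOH_NO_POINT
        assert r.cn_loh_gene == "TSC2"

    def test_large_deletion_with_loh(self):
        r = summarize_sample(
            "s1",
            {"TSC1": [Mutation("exon 6-23 del", "genomic deletion", 78.0)]},
            {"TSC1": loh("TSC1", True)},
        )
        assert r.summary_label == LABEL_LARGE_DEL_LOH

    def test_possible_mutation_only_is_nmi(self):
        r = summarize_sample(
            "s1",
            {"TSC1": [Mutation("c.1-7G>A", "possible-initiator", 50.0)]},
            {},
        )
        assert r.gene == "NMI" and r.summary_label == LABEL_POSSIBLE

    def test_nothing_found_is_nmi(self):
        r = summarize_sample("s1", {}, {"TSC1": loh("TSC1", False)})
        assert r.summary_label == LABEL_NMI

    def test_mutations_in_both_genes_is_a_conflict(self):
        with pytest.raises(MultiGeneConflictError):
            summarize_sample(
                "s1",
                {
                    "TSC1": [Mutation("a", "nonsense", 40.0)],
                    "TSC2": [Mutation("b", "nonsense", 30.0)],
                },
                {},
            )


class TestTally:
    def test_published_cohort_counts(self, cohort_fixture_path):
        """The 34-sample transcription reproduces the reported tallies."""
        summary = tally_cohort(read_results_fixture(cohort_fixture_path))
        assert (summary.n_tsc2, summary.n_tsc1, summary.n_nmi) == (19, 10, 5)
        assert summary.n_tsc1_with_loh == 9
        assert summary.n_tsc2_with_loh == 14
        assert summary.n_nmi_with_loh == 3
        assert summary.n_two_point == 1

    def test_published_cohort_percentages_round_half_up(self, cohort_fixture_path):
        summary = tally_cohort(read_results_fixture(cohort_fixture_path))
        assert (summary.pct_tsc2, summary.pct_tsc1, summary.pct_nmi) == (56, 29, 15)

    def test_permutation_invariant(self, cohort_fixture_path):
        results = read_results_fixture(cohort_fixture_path)
        shuffled = results[:]
        random.Random(3).shuffle(shuffled)
        assert tally_cohort(shuffled) == tally_cohort(results)

    def test_single_nmi_sample(self):
        summary = tally_cohort([SampleResult("s", "NMI")])
        assert summary.n_samples == summary.n_nmi == 1
        assert summary.n_tsc1 == summary.n_tsc2 == summary.n_two_point == 0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            tally_cohort([])

    def test_report_writer_includes_tallies(self, cohort_fixture_path):
        results = read_results_fixture(cohort_fixture_path)
        buf = io.StringIO()
        write_cohort_report(results, tally_cohort(results), buf)
        text = buf.getvalue()
        assert "# TSC2 mutant: 19 (56%), with CN-LOH: 14" in text
        assert "# TSC1 mutant: 10 (29%), with CN-LOH: 9" in text


class TestFixtureReader:
    def test_two_row_sample_collapses_to_one_result(self, cohort_fixture_path):
        results = read_results_fixture(cohort_fixture_path)
        assert len(results) == 34
        (two_point,) = [r for r in results if r.summary_label == LABEL_TWO_POINTS]
        assert len(two_point.mutations) == 2

    def test_possible_initiator_row_is_nmi(self, cohort_fixture_path):
        results = read_results_fixture(cohort_fixture_path)
        by_id = {r.sample_id: r for r in results}
        assert by_id["2"].gene == "NMI"
        assert by_id["2"].summary_label == LABEL_POSSIBLE

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            read_results_fixture(io.StringIO("case\tgene\n1\tNMI\n"))
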