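"""Tally the bundled 34-sample results table (transcribed study summaries).

The table carries one row per reported mutation (case, gene, nucleotide
change, mutant allele fraction, type, CN-LOH flag); the classifier groups
rows into per-sample results and the tally reproduces the reported cohort
composition.
"""

import sys
from importlib.resources import files

from segaloh import read_results_fixture, tally_cohort
from segaloh.cohort import write_cohort_report

fixture = str(files("segaloh").joinpath("data/sega_cohort_results.tsv"))
results = read_results_fixture(fixture)
summary = tally_cohort(results)
write_cohort_report(results, summary, sys.stdout)

# The footer reports 19/34 TSC2-mutant (56%, 14 with CN-LOH), 10/34
# TSC1-mutant (29%, 9 with CN-LOH), 5/34 with no mutation identified
# (3 of them showing CN-LOH), and one sample with two mutations.
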