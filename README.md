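# segaloh

Tumor-only detection of biallelic tumor-suppressor inactivation — somatic point
mutation plus copy-neutral loss of heterozygosity (CN-LOH) — from targeted
deep-sequencing pileups, built around the *TSC1*/*TSC2* genetics of
subependymal giant cell astrocytoma (SEGA).

SEGAs are brain tumors of tuberous sclerosis complex. The two-hit model
predicts that each tumor carries a first inactivating mutation in *TSC1* or
*TSC2* and a second hit that removes the remaining wild-type allele; in these
tumors the second hit is typically copy-neutral LOH rather than a deletion, so
it is invisible to coverage-based copy-number analysis and must be inferred
from allele fractions. This package implements that inference for tumor-only
targeted sequencing (no matched normal), end to end:

- **`segaloh.pileup`** — parse samtools-mpileup single-sample text into
  strand-oriented allele counts (substitutions, insertions, deletions, read
  starts/ends), preserving the invariant that depth equals the sum of counts.
- **`segaloh.screen`** — flag candidate variants as likely artifacts:
  frequency ≤ 1%, support on only one strand orientation, or recurrence of the
  same allele across ≥ 3 samples (known SNP sites exempt). Flags are recorded,
  never deleted, so every call is auditable.
- **`segaloh.germline`** — classify candidates as germline vs. somatic from a
  population catalog: seen in > 3 normal controls, or population allele
  frequency > 1% in either ancestry subset unless the site is recurrently
  somatic in a cancer catalog (> 2 entries).
- **`segaloh.loh`** — call CN-LOH per gene. Let *m* be the mutant allele
  fraction and *q* the median minor-allele fraction over informative germline
  SNPs (catalog population AF > 0.05%, observed in the sample between 1% and
  99%). CN-LOH is called iff **m > 0.55 or q < 0.40**; the report records
  which branch fired.
- **`segaloh.cohort`** — per-sample QC (median coding-exon depth ≥ 20×),
  gene assignment, a closed vocabulary of summary labels
  (`point+CN-LOH`, `point no LOH`, `2 points`, `large del+CN-LOH`,
  `CN-LOH, no point`, `possible mutation, no CN-LOH`, `NMI`), and cohort
  tallies with round-half-up percentages. A transcription of the published
  34-sample results table ships as a package fixture.
- **`segaloh.simulate`** — a read-count simulator with known truth. At tumor
  purity *p*, a heterozygous somatic mutation has expected AF *p*/2; after
  CN-LOH duplicating the mutant haplotype the mutant AF is *p* and each
  germline het SNP splits (1 ± *p*)/2 by phase, so the minor AF is
  (1 − *p*)/2. Sequencing error, strand-biased recurrent artifacts, and
  germline SNPs are planted per sample.
- **`segaloh.cli`** — a thin `segaloh` command (`simulate`, `counts`,
  `screen`, `loh`, `classify`, `summarize`, `run-all`) over the library API,
  with YAML configuration for `run-all`.

See [docs/methods.md](docs/methods.md) for the full model, thresholds, and
limitations.

## Worked example

`examples/03_call_cnloh.py` simulates one tumor of purity 0.7 whose mutant
haplotype has been duplicated, then recovers both CN-LOH signals from the
pileup text alone:

```text
planted: purity 0.7, second hit cn_loh, expected mutant AF 0.7
measured mutant allele fraction: 0.695
informative SNPs: 50, median minor allele fraction: 0.149 (expected 0.150)
CN-LOH call: True via branch 'both'
```

`examples/04_cohort_pipeline.py` runs the full pipeline over six simulated
tumors covering every reported pattern and checks each call against the
planted truth:

```text
S000: gene=TSC1 loh=True  label='point+CN-LOH' mutations: chr9:135771030G>T (73%)  [truth: TSC1+LOH]
S001: gene=TSC2 loh=True  label='point+CN-LOH' mutations: chr16:2110035T>-CA (73%)  [truth: TSC2+LOH]
S002: gene=TSC2 loh=False label='point no LOH' mutations: chr16:2110065C>G (37%)  [truth: TSC2]
S003: gene=TSC2 loh=False label='2 points' mutations: chr16:2110095T>A (38%), chr16:2110107T>A (37%)  [truth: TSC2]
S004: gene=NMI  loh=True  label='CN-LOH, no point' mutations: -  [truth: NMI+LOH]
S005: gene=NMI  loh=False label='NMI' mutations: -  [truth: NMI]

cohort: 6 samples | TSC2 3 (50%), TSC1 1 (17%), NMI 2 (33%) | with CN-LOH: TSC1 1, TSC2 1, NMI 1
```

`examples/05_published_cohort.py` tallies the bundled 34-sample results table
and reproduces the reported cohort composition:

```text
# samples: 34
# TSC2 mutant: 19 (56%), with CN-LOH: 14
# TSC1 mutant: 10 (29%), with CN-LOH: 9
# NMI: 5 (15%), with CN-LOH: 3
# two-mutation samples without LOH: 1
```

The other examples cover pileup parsing (`01`) and the artifact screen (`02`).
Run any of them with `python examples/<name>.py`.

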