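# Methods

## Problem and model

Tumor-only targeted deep sequencing of a tumor-suppressor panel (*TSC1*,
*TSC2*, plus control genes) is used to detect biallelic inactivation in a
tumor: a first somatic point mutation or small indel, and a second hit that is
usually **copy-neutral loss of heterozygosity (CN-LOH)** — duplication of the
mutant haplotype with loss of the wild-type one, leaving total copy number
unchanged. Without a matched normal, both the somatic status of a variant and
the presence of CN-LOH must be inferred from allele fractions alone.

At tumor purity *p* (fraction of cells that are tumor), with the normal
contamination diploid and heterozygous where the tumor is:

| Quantity | No LOH | CN-LOH (mutant haplotype duplicated) |
|---|---|---|
| somatic mutant AF | *p*/2 | *p* |
| germline het SNP AF | 1/2 | (1 ± *p*)/2 by phase |
| germline het SNP **minor** AF | 1/2 | (1 − *p*)/2 |

Two independent signals therefore mark CN-LOH: the mutant allele fraction
rises above the heterozygous ceiling of 0.5, and germline heterozygous SNPs
across the gene shift away from 50:50.

## Pipeline stages and decision rules

### 1. Pileup parsing (`segaloh.pileup`)

samtools-mpileup single-sample text is parsed character by character into
per-position, per-strand allele counts. `.`/`,` are reference matches on the
forward/reverse strand; upper/lowercase letters are substitutions by strand;
`+n SEQ` / `-n SEQ` are insertions/deletions anchored to the preceding base;
`^q` (with its quality byte) and `$` mark read starts/ends; `*`/`#` are
deletion placeholders. An anchor base followed by an indel counts as **one
read carrying the indel allele**, so the invariant *depth = sum of allele
counts* holds exactly; `N` and deletion placeholders count into depth but are
never emitted as alleles. The parser verifies the parsed read count against
the line's depth field and raises with the offending line number on any
inconsistency.

### 2. Artifact screen (`segaloh.screen`)

Every non-reference allele becomes a candidate with zero or more flags:

- `below_threshold` — allele fraction ≤ 1% (strict `> 0.01` required to pass).
  Sequencing error at the 0.1–0.2% per-base level produces abundant calls
  below this line; the method's practical sensitivity is in the 5–10% range.
- `single_orientation` — all supporting reads on one strand. Genuine variants
  at these depths are seen on both orientations; strand-exclusive support is
  the classic signature of ligation/FFPE artifacts.
- `recurrent_artifact` — the same (position, allele) appears in ≥ 3 samples
  of the cohort (default `recurrence_min_samples = 3`). Sites present in the
  population SNP catalog are exempt, since real polymorphisms recur by
  nature. With fewer than 2 samples the rule is skipped with a warning.

Flags are annotations, not deletions: filtered candidates are written to the
VCF/TSV outputs with their flags, so every decision is auditable.

### 3. Germline classification (`segaloh.germline`)

A candidate matched to a population-catalog record is germline if either:

- **carriers rule** — observed in more than 3 normal controls
  (`normal_carrier_count > 3`), or
- **population rule** — allele frequency above 1% in either the African-American
  or European-American subset, *unless* the allele is recurrently somatic in a
  cancer catalog (`cosmic_count > 2`), which rescues it back to somatic.

The cancer-catalog rescue applies only to the population rule. A candidate
with no catalog record is never germline. Unflagged, non-germline candidates
get status `somatic`.

### 4. CN-LOH call (`segaloh.loh`)

Per gene, with *m* the mutant allele fraction (exact string count of the
mutant allele, including indel keys, over site depth) and *q* the median
minor-allele fraction over informative SNPs:

> **CN-LOH iff m > 0.55 or q < 0.40** (both strict).

An SNP is *informative* if its catalog population AF exceeds 0.05% and its
observed alternate fraction in the sample lies in [1%, 99%] — i.e. it is
actually heterozygous-looking in this tumor, which is how heterozygosity must
be established without a normal. The assessment records which branch fired
(`maf`, `snp`, `both`, `none`); medians of even-length lists are the mean of
the central pair (numpy convention). If neither a mutation MAF nor any
informative SNP is available, the call raises rather than guessing.

### 5. Sample and cohort classification (`segaloh.cohort`)

QC requires median depth ≥ 20× over the gene's coding exons (positions absent
from the pileup count as depth 0); failing samples are excluded from tallies
unless explicitly kept. Confirmed somatic mutations in more than one
tumor-suppressor gene raise a conflict error — under the two-hit model that
indicates an upstream filtering failure, not biology. Summary labels come
from a closed vocabulary (`point+CN-LOH`, `point no LOH`, `2 points`,
`large del+CN-LOH`, `CN-LOH, no point`, `possible mutation, no CN-LOH`,
`NMI`). Samples whose only finding is a *possible* (unconfirmed) mutation
tally as NMI, as do NMI samples with CN-LOH (the affected gene is still
recorded). Percentages are round-half-up (`floor(x + 0.5)`).

The bundled 34-sample results fixture is a transcription of a published SEGA
cohort table; its printed CN-LOH column is taken as given when tallying
(counts are the surface of record; one printed MAF of exactly 55 does not
fire the strict `> 0.55` branch, a rounding artifact of the printed value).

## Simulator (`segaloh.simulate`)

The simulator emits mpileup *text* with known truth, at the read-count level:

- per-position depth ~ Poisson(depth_mean), strand split ~ Binomial(depth, ½);
- per orientation, allele counts are multinomial with per-base error
  `error_rate/3` to each non-reference base (default error 0.2%);
- germline het SNPs planted at catalog sites (carrier probability
  `het_snp_rate`), shifted to (1 ± *p*)/2 under CN-LOH;
- somatic mutations (substitution or indel) at AF *p*/2, or *p* under CN-LOH;
- recurrent strand-biased artifacts: at bias *b*, forward/reverse allele
  probabilities are 2·af·*b* and 2·af·(1 − *b*), so bias 1.0 puts every
  artifact read on one strand;
- counts are drawn first and then encoded, so parsing recovers them exactly.

Seeding uses `numpy.random.default_rng` with spawn-key-style sequences
`[seed mod 2^31, stream-constant, sample-index]`, making every sample
independent and the whole cohort reproducible from one integer.

**Scope**: the simulator models read counts, not reads — no base qualities,
mapping ambiguity, capture GC bias, FFPE deamination spectra, or
deletion-type LOH (copy-number change); purity is a single scalar with no
subclonal structure. That is sufficient to exercise every decision rule above
and to verify the closed forms, and nothing more is claimed.

## Numerical and design choices

- All thresholds are **strict** inequalities exactly as stated
  (`> 0.01`, `> 3`, `> 0.55`, `< 0.40`, `> 0.0005`); QC is inclusive (≥ 20×).
- `min_somatic_frequency = 0.05`: the pipeline assigns a mutation to a sample
  only at AF ≥ 5%, matching the stated 5–10% sensitivity. Without it,
  isolated error reads at ~2% occasionally pass the 1% screen on both strands
  and masquerade as second-gene somatic calls. All > 1% candidates still
  appear in the audit outputs.
- Allele observations are sorted by (descending frequency, allele string) for
  deterministic output; indel allele keys are the uppercased inserted/deleted
  sequence prefixed with `+`/`-`.
- Validation problem sizes (chosen as this package's own benchmarks): 31
  wild-type negative controls at 100× for the false-positive check; 200
  replicates at purity 0.7, 100×, 50 SNPs for sensitivity/specificity/
  recovery; 10,000× single samples for the closed-form limits; 1,000 random
  lines against a construction oracle for the parser.

## Limitations

- Tumor-only CN-LOH detection measures **allelic imbalance**; without copy
  number or a matched normal it cannot distinguish copy-neutral LOH from a
  high-fraction subclonal duplication, and low purity (*p* ≲ 0.2) pushes both
  signals inside the thresholds.
- Printed/rounded allele fractions can straddle the strict cutoffs (the
  MAF-55 case above); the pipeline operates on exact fractions, tables of
  rounded values may not re-fire identically.
- The germline rules depend entirely on catalog coverage: a true germline
  variant absent from the catalog will be reported somatic.
- The recurrence filter assumes independent samples; a cohort of related
  samples sharing a true mutation at ≥ 3 occurrences would flag it.
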