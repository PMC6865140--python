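# Methods

## Scope and data model

The pipeline operates on biallelic SNVs identified by the exact key
(chrom, pos, ref, alt) after uppercase normalization; no allele flipping or
left-normalization is attempted (if panels are not ref-aligned, harmonize
them upstream). VCF positions are 1-based inclusive, BED intervals 0-based
half-open, and all internal coordinates 1-based. Genotypes are stored as
allele dosages 0/1/2 with missing as NaN; a half-called genotype counts as
missing for call-rate purposes (conservative).

## QC

The "high-quality SNV" working set is produced by three independently
switchable filters, applied in a fixed order so each removed record is
attributed to exactly one filter: (1) FILTER must be PASS — records with
FILTER `.` (no filter applied) also pass, since upstream cohort VCFs are
frequently unfiltered; (2) biallelic SNVs only — multiallelic records are
dropped, not split, because allele-matching after splitting is ambiguous and
downstream statistics are defined on biallelic SNVs; (3) genotype call rate
≥ 0.9 (default). The defaults are a reasonable reconstruction of standard
cohort QC; every threshold is exposed in `QCConfig`.

## Consequence classification

Splice windows are the 2 intronic bases on either side of every internal
exon boundary of a coding transcript; exonic boundary bases are not
splice-site (the window targets the canonical donor/acceptor dinucleotides).
Windows on non-coding transcripts are not considered. Codon effects
substitute the alternate base into the strand-corrected CDS and translate
the affected codon with the standard genetic code: stop introduced ⇒
stop_gained, terminal stop removed ⇒ stop_lost, residue changed ⇒ missense,
unchanged ⇒ synonymous. Start-codon-disrupting SNVs classify as missense —
the three-class scheme enumerates only stop-gain/stop-loss/splice as high,
and we do not invent a category. Exonic positions outside any CDS (UTRs)
are `exonic_unknown` (low).

Across overlapping transcripts the most severe call is reported (the three
high terms rank equally; then missense > synonymous > exonic_unknown), with
ties broken by lexicographically smallest transcript id for determinism. A
REF allele disagreeing with the reference sequence raises an error rather
than being skipped: silent skips hide coordinate bugs. Transcript models
failing structural validation (overlapping exons, CDS outside exons, CDS
length not divisible by 3) are rejected with named reasons at index build
time.

The classifier is verified against an independent oracle that mutates the
chromosome, re-extracts and translates the entire CDS, and diffs the mutated
protein against the reference protein; the test suite requires 100%
agreement on several hundred injected variants across both strands.

## Frequency statistics

MAF is the folded frequency min(AF, 1−AF); AN excludes missing genotypes; a
record with AN = 0 is "absent" with undefined AF/MAF. Rarity classes
partition [0, 0.5] ∪ {absent}: very_rare strictly below 0.01 (absent
included), rare in [0.01, 0.05), common at or above 0.05; both boundaries
are configurable. MMAF over a panel set is the maximum MAF among panels
where the variant was observed, absent-everywhere giving 0; for novelty
(as opposed to rarity) absence is tracked separately, because "never seen
in any catalog" and "seen but rare" are different questions.

A variant is population-specific when focal MAF > 0.01 (strict) and every
reference MAF < 0.01, absent counting as below. Folded MAF is used
throughout; the thresholds are parameters, so an alt-frequency convention
can be emulated if needed.

## Gene prioritization

Each qualifying variant is attributed to exactly one gene — that of its most
severe consequence call — so per-gene counts sum to the number of attributed
variants (conservation). Gene length is the genomic span from the smallest
exon start to the largest exon end over the gene's transcripts. Outlier
genes are removed by a robust rule, burden > median + k·MAD over nonzero
burdens (default k = 5), plus an explicit blacklist; both are reported with
reasons. RVIS prioritization keeps genes at or below a percentile cutoff
with at least a minimum burden, sorted by (burden desc, percentile asc,
gene id); genes without an RVIS record are excluded and logged rather than
silently assigned a percentile. A variant is "deleterious" when the score
table labels it "D", or when only numeric scores are given, when score >
0.5 (the usual convention for ensemble logistic-regression predictors whose
output is a probability).

## Cohort screens

The incidental-findings screen reports high-impact variants in a configured
gene panel that are carried by at least one cohort member (a site record
with no observed alternate allele is not a finding), optionally restricted
to variants at or below a cohort-MAF cap (the pipeline default caps at
0.01, i.e. very rare). The rate is distinct carriers of ≥ 1 finding divided
by cohort size, as a percent to two decimals — 2 distinct carriers in 128
gives 1.56%.

The case screen applies three predicates — predicted deleterious; present
(dosage ≥ 1, no zygosity requirement) in at least `min_cases` cases
(default 3); very rare under the configured MMAF panel source — in that
fixed order so per-stage removal counts are deterministic; the surviving
set is the intersection of the predicates and therefore order-invariant.
Because MMAF is monotone in the panel set, enlarging the source can only
remove survivors; the reduction statistic (extra removals and percent of
baseline survivors, one decimal plus nearest integer) quantifies the gain
from adding the focal panel.

## Synthetic cohort generator

The generator emulates the target study design; its defaults are the
conditions under which the package is validated.

* **Frequencies.** Ancestral frequency p ~ Beta(0.2, 0.2) truncated to
  (0.001, 0.5) — a U-shaped spectrum enriched for rare variants; each
  population diverges by Balding–Nichols, Beta(p(1−F)/F, (1−p)(1−F)/F).
  Default F: 0.05 for the focal population (stronger drift, consistent with
  a founder history) and 0.01–0.02 for the references.
* **Founder set.** 100 planted variants (default) are overwritten after the
  drift draw: focal frequency uniform in (0.011, 0.10), reference
  frequencies uniform in (0, 0.002). The reference ceiling reflects the
  founder-variant picture — alleles enriched to a few percent in the focal
  population are typically near-absent elsewhere. A quarter of the planted
  set (configurable) lands on coding sites so founder-driven burden and
  screen signals exist downstream. Non-planted variants whose true
  frequencies happen to satisfy the population-specific criterion are
  redrawn, making the planted set exactly the set of true positives; without
  this, drift at F = 0.05 produces genuine unplanted specific variants and
  truth-level sensitivity/specificity of 1 would be unattainable by
  construction.
* **Genotypes.** Dosage ~ Binomial(2, population frequency) independently
  per individual (Hardy–Weinberg), 128 individuals per population by
  default; a 49-sample case cohort is drawn from the focal frequencies.
  Singletons arise naturally from binomial sampling of rare variants; there
  is no explicit singleton knob.
* **Gene models.** One chromosome of contiguous, non-overlapping
  single-transcript genes (default 24), each a 5′ UTR + ORF (ATG, no
  internal stops, terminal stop, length divisible by 3) + 3′ UTR split
  across 2–5 exons with GT..AG introns; a configurable fraction (default
  0.4) on the minus strand. Coordinates stay small and auditable.
* **Injected consequences.** For each requested term, positions and alleles
  are constructed so the full-protein-diff oracle yields that term
  (stop-gained sites create an in-frame TAA/TAG/TGA, splice variants sit at
  intronic offsets 1–2, and so on); filler variants are placed only outside
  exons and splice windows so they acquire no consequence call.
* **Scores.** Truly deleterious variants (all high-impact plus half of
  missense, by default) score ~ Normal(0.9, 0.05) clipped to [0, 1], others
  Normal(0.1, 0.05); label "D" iff score > 0.5, giving ≥ 99% label accuracy
  against truth.

What the generator does **not** emulate: linkage disequilibrium, realistic
mutation spectra and gene structure, sequencing error, relatedness, or
demographic history beyond a single-parameter drift model. Passing tests
therefore demonstrate the correctness of the statistics and filters under
the stated sampling model, not robustness to real-data artifacts such as
strand-flip mismatches between panels, batch-differential missingness, or
misannotated transcripts.

## Problem sizes and numerical choices

The validation suites use sizes chosen to make sampling properties
measurable while keeping runs quick: the classifier-vs-oracle suite injects
520 variants across 22 genes on both strands; founder recovery pools 20
simulated cohorts of 2,000 variants with five populations of 128 (where the
detector's pooled sensitivity on planted focal MAF ≥ 0.03 is about 0.98 and
the false-positive rate about 0.004); MMAF monotonicity is checked over
1,000 variants and five nested panel sets. Percentages are reported to one
decimal (reductions additionally as nearest integer); rarity boundaries are
strict-left as documented; all simulation randomness flows from a single
integer seed through `numpy.random.default_rng`, and every generator output
is a pure function of (config, seed) — verified by byte-identity of two
pipeline reruns.

## Known limitations

Indel consequences, NMD prediction, HGVS naming, LD-aware statistics,
FST estimation from data, phasing and imputation are out of scope. The
screen's recurrence predicate ("present in ≥ k cases") interacts with the
very-rare predicate: at small case-cohort sizes the two are nearly
exclusive unless the cohort is enriched (as founder cohorts are), which is
precisely the effect the reduction statistic measures.
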