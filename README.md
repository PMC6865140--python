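# exopop — population-aware exome variant analysis

`exopop` is a pipeline for asking what a founder-history population's own
exome reference panel buys you that a genetically related surrogate panel
does not. It targets the study design in which a focal cohort (for example
~128 whole exomes from a founder population) is compared against reference
population panels (European, African, East and South Asian), with three
goals:

1. **Characterize** the focal cohort: QC to a high-quality biallelic-SNV
   working set, classify each variant's functional consequence from gene
   models, and measure sharing/novelty against the reference panels.
2. **Detect population-specific variants** — minor allele frequency (MAF)
   above 1% in the focal population yet below 1% (or absent) in every
   reference population — and prioritize the genes that accumulate them,
   combining burden counts with the residual variation intolerance score
   (RVIS) and per-variant deleteriousness predictions.
3. **Quantify the filtering gain**: screen a case cohort for candidate
   causal variants (predicted deleterious, recurrent in ≥ 3 cases, very
   rare) and measure how many extra candidates are removed when the focal
   panel joins the maximum-MAF (MMAF) rarity source.

## Model and definitions

For a biallelic site with alternate-allele frequency *p*, the folded MAF is
min(*p*, 1 − *p*). Over a set *S* of panels, MMAF(v, S) = max over panels in
*S* of MAF(v), with absence counting as 0 — so MMAF is weakly increasing in
*S*, and the "very rare" set (MAF < 1%) shrinks as panels are added; that
monotonicity is the entire mechanism of the filtering gain.

Consequence classes follow a three-level severity scheme: **high** =
stop-gained, stop-lost, or within 2 bp of a splicing junction (intronic
side); **moderate** = missense; **low** = synonymous or exonic of unknown
type. Codon effects are computed by substituting the alternate base into the
strand-corrected coding sequence and translating with the standard genetic
code.

The synthetic cohort generator draws ancestral frequencies from a U-shaped
Beta(0.2, 0.2) spectrum and diverges each population under the
Balding–Nichols model — population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F)
for divergence parameter F — then plants a founder-effect variant set
(focal MAF 1–10%, near-absent elsewhere) and emits Hardy–Weinberg genotype
panels, toy coding genes on both strands, deleteriousness scores correlated
with truth, and complete truth tables. Every pipeline stage is validated
against that planted truth.

## Worked example

Run the full pipeline on a freshly generated synthetic dataset (five
populations of 128 individuals, 2,000 variants, 100 planted founder
variants, a 49-sample case cohort):

```sh
cat > pipeline.yaml <<'YAML'
outdir: demo_out
seed: 5
simulate: {}
YAML
exopop run pipeline.yaml
exopop report demo_out/summary.json
```

Selected output from `demo_out/summary.json` at seed 5:

```
impact_counts        high 20 (8 splice-site), moderate 40, low 32
overlap (EUR)        1401 / 1524 focal variants shared (0.9193)
specific_variants    102 (6.7% of observed focal variants)
incidental           acmg_like: 2 findings, rate 2.34%
rarity (very rare)   references-only MMAF: 30.0%  ->  + focal panel: 8.3%
case screen          references: 6 survivors; + focal panel: 0 survivors
reduction            6 extra variants removed (100% of baseline survivors)
```

Reading this: the classifier recovers the planted consequence mix exactly
(20/40/32 is the generator's high/moderate/low truth); roughly 90% of focal
variants are shared with each diverged reference panel; 102 variants pass
the population-specific criterion (the planted founder set plus sampling
noise); and adding the focal panel to the MMAF source collapses the
very-rare fraction from 30% to 8.3%, which in the case screen removes all
six remaining candidates — founder variants masquerading as "very rare"
under reference-only frequencies. The incidental screen reports carriers of
high-impact, very rare variants in the panel genes: 3 of 128 individuals
(2.34%) for the ACMG-style panel here.

Each stage is also available separately (`exopop simulate`, `qc`,
`annotate`, `popstats`, `prioritize`, `screen`) and as library functions
(`exopop.read_variants`, `classify_consequence`, `population_specific`,
`screen_cases`, ...).

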