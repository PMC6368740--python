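# oncoamp

Targeted amplicon panel analysis for tumor-only and circulating-tumor-DNA
(ctDNA) sequencing in breast cancer: panel design bookkeeping and candidate
scoring, multi-stage somatic variant filtering, pooled-reference gene-level
copy-number calling, clinical actionability tiering, and cohort-level
reporting — with a truth-labelled synthetic-cohort generator so every stage
is verifiable without patient data.

## Who it is for

Groups running small hotspot amplicon panels (tens of genes, hundreds of
amplicons, ~0.08 Mb footprints) on solid-tumor biopsies or liquid biopsies,
without a matched-normal design for the tumor cohort. Sequencing like this
calls thousands of raw variants per cohort; almost all are inherited
variants, common SNPs, or platform artifacts. `oncoamp` implements the
rule-based triage that separates them from somatic mutations, and the
downstream copy-number and actionability layers a molecular tumor board
actually consumes.

## The methods at the core

**Somatic filter cascade** (tumor-only cohorts). In fixed order, with
per-stage accounting:

1. patient-matched germline subtraction (ctDNA only) — a ctDNA call is
   removed iff its variant key appears in the *same patient's* buffy-coat
   germline calls;
2. recurrence — a key seen in more than `k` distinct samples
   (solid default `k=10`, ctDNA `k=4`) is a platform artifact or common
   SNP and is removed from every sample;
3. non-coding, then synonymous, then unannotated calls;
4. population — known in ExAC or 1000 Genomes at > 1% population AF;
5. germline allele fraction — AF > 90% is presumed inherited;
6. strand bias — forward-strand fraction outside the closed window
   [0.5, 0.6] marks a sequencing artifact.

All comparative thresholds are strict inequalities; boundary values
(AF = 0.90, strand bias = 0.5 or 0.6, exactly `k` samples, population
AF = 1%) survive.

**Copy number.** Per-amplicon read counts are normalized to library size
and ratioed against a pooled normal reference (per-amplicon median of ≥ 2
germline profiles). A gene's log2 ratio is the median over its amplicons
(genes need ≥ 4 amplicons to be called); absolute copy number is
CN = 2·2^log2. Reporting thresholds: amplified iff CN > 6
(log2 > 1.58), deleted iff CN < 1 (log2 < −1).

**Actionability.** SNVs match a local knowledge-base TSV on exact
(gene, protein change) after HGVS normalization; amplified genes match
(gene, "Amplification"). Evidence levels follow the OncoKB convention
(1 = FDA-recognized biomarker … 4 = biological evidence); a sample is
classified by its most actionable alteration.

## Worked example

```python
from oncoamp import attach_annotations, run_cascade
from oncoamp.synthetic_data import CohortSpec, generate_cohort

cohort = generate_cohort(CohortSpec(seed=1))           # 46 samples
calls = attach_annotations(cohort.calls, cohort.annotations)
survivors, report = run_cascade(calls, cohort="solid")
print(report.to_frame().to_string(index=False))
print("survivors match planted somatic truth:",
      {c.key for c in survivors} == cohort.truth.somatic_keys)
```

prints

```
        stage  input  surviving  removed
   recurrence    770        478      292
   non_coding    478        464       14
   synonymous    464        456        8
  unannotated    456        456        0
population_af    456        444       12
  germline_af    444        439        5
  strand_bias    439        389       50
survivors match planted somatic truth: True
```

770 raw calls enter; shared germline keys fall at the recurrence stage,
consequence/population/AF/strand-bias stages remove the other planted
contaminant classes, and the 389 survivors are exactly the planted somatic
mutations — the cascade's sensitivity and specificity on a separable
cohort are both 1.0.

The same flows are available from the shell: `oncoamp synth cohort`,
`oncoamp variants import`, `oncoamp filter run`, `oncoamp cnv reference`,
`oncoamp cnv call`, `oncoamp actionability annotate`, `oncoamp report
burden`, and friends (`oncoamp --help`).

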