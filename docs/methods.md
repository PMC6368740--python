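# Methods

## Scope and data model

`oncoamp` operates downstream of primary variant calling: its inputs are
per-sample variant calls (VCF with per-sample depth/alt-observation/
strand-bias FORMAT fields), a side table of annotations (gene, protein
change, coding consequence, ExAC and 1000 Genomes population allele
frequencies), BED-like amplicon intervals, per-amplicon read-count
matrices, and a knowledge-base TSV of actionable alterations. Read
alignment, primary calling, and deleteriousness scoring are out of scope;
annotations are consumed, never computed. Coordinates follow each
format's native dialect: BED intervals are 0-based half-open, variant
positions 1-based (VCF); converters are explicit and hg19 is assumed
throughout (no liftover).

A variant's identity is its `(chrom, pos, ref, alt)` key, independent of
sample. Multi-allelic records are split into one call per alt allele;
allele fraction is taken from the per-sample `AF` field or recomputed as
`AO/DP`. FORMAT floats are stored by VCF libraries as float32, so allele
fractions are rounded to 6 decimals on read — this makes boundary
comparisons (a call at exactly the 4% floor) behave as written.

## Panel module

Footprint is the size of the union of amplicon intervals, merged per
chromosome; cross-panel overlap reports gene-set intersection and the
size of the interval intersection. Candidate hotspots are scored 0–5,
one point per criterion: membership in the significantly-mutated-gene
list, clinical actionability (an FDA-approved drug exists), functional
importance (e.g. kinase), observation in more than 5 primary **or** more
than 2 metastatic tumors (strict inequalities), and occurrence in both
settings. The criteria are unweighted; how they combine into an
inclusion decision is left to the caller (the raw score is always
emitted, and a configurable threshold defaults to 2). Finalization drops
targets whose probe design failed and reports genes that vanish
entirely.

Burden-estimation suitability uses the 0.5 Mb footprint rule: panels
below 500,000 bp (boundary inclusive) are flagged unsuitable for
tumor-mutational-burden estimation.

## Filter cascade

Stage order is frozen: germline subtraction (ctDNA only) → recurrence →
non-coding → synonymous → unannotated → population AF → germline AF →
strand bias. The order matters only for attribution (each removed key is
logged at the first stage that rejects it); the per-call stages
(population, germline-AF, strand-bias) commute, which the test suite
asserts by permutation.

Decisions that were genuinely open, and how they were fixed:

* **Strict thresholds.** "More than 10 samples", "more than 1% of the
  population", "above 90% AF" are strict; a call at the boundary
  survives. The strand-bias window [0.5, 0.6] is closed at both ends.
  The asymmetric window reflects the forward-strand enrichment typical
  of the semiconductor amplicon chemistry; it is configurable.
* **Recurrence removes the key everywhere**, not only beyond the
  threshold-th sample: a key recurrent across unrelated tumors is
  untrustworthy in every sample.
* **Unannotated calls** (no consequence available) are removed by
  default but counted as their own stage, so the accounting never
  silently mixes them into the non-coding count.
* **Missing population AF is treated as 0**: a variant absent from the
  population databases cannot be removed by the population filter.
* **Missing strand bias retains the call** — there is nothing to judge.
* The ctDNA defaults (recurrence threshold 4, AF floor 1%) are
  research-grade; the CLI prints a warning that a sub-4% floor is not
  clinically validated.

Germline subtraction requires an explicit ctDNA-sample → germline-sample
map; several serial draws of one patient may share one germline sample.
Removal is strictly patient-matched: a key present only in another
patient's germline is never subtracted.

## Copy number

Gene-level copy number from amplicon depths against a pooled normal
reference: each sample's counts are divided by its total (library-size
normalization, which makes calls invariant to scaling a sample's
counts), the reference is the per-amplicon **median** across ≥ 2 normals
(robust to a single aberrant normal), per-amplicon log2 ratios are
`log2(sample fraction / reference fraction)`, and a gene's log2 ratio is
the median over its amplicons. Genes with fewer than 4 amplicons are not
called — a gene-level median over 2–3 amplicons is too fragile. (The
source convention this mirrors states the rule once as "more than 3
amplicons" and once as "less than 3"; the ≥ 4 reading is used and the
threshold is a parameter.)

Absolute CN = 2·2^log2. Reporting thresholds are strict: amplified iff
CN > 6 (log2 > 1.58), deleted iff CN < 1 (log2 < −1); CN exactly 6 or 1
is neutral. No GC, antitarget, or segmentation corrections are applied —
at gene resolution on a hotspot panel the pooled reference absorbs the
dominant per-amplicon efficiency bias, and this estimator is
deterministic. One residual bias is worth knowing: planting a CN change
rescales the sample's total read count, so an amplified gene's observed
ratio is shifted down by `log2(total weight change)`; with few altered
amplicons per sample this is ≪ one copy-state step.

## Actionability

The knowledge base is a versioned local TSV (gene, alteration, level
1–4, drugs), shipped with the package, not a live service query —
deterministic and offline. Matching is exact-string on the protein
change after HGVS-style normalization (strip `p.`, uppercase); there is
no positional or fuzzy matching, so an unknown variant of a known codon
produces no call. Amplified genes match the `Amplification` entry.
Sample classification is the minimum level number present (level 1
outranks 4); cohort summaries count *distinct samples* per level, with
the cohort size as an explicit denominator because samples with no
actionable alteration emit no calls. A breast-cancer evidence scope is
assumed; a tumor-type dimension is reserved but unused.

## Cohort reports

* **Burden outliers**: a sample is flagged iff its mutation count
  exceeds `median + 1.5·IQR`. Quantiles use linear interpolation
  (NumPy's default, type 7) — stated explicitly because the rule's
  outcome depends on the quantile definition. With fewer than 4 samples
  no flags are raised.
* **Burden–CNV correlation**: standard Pearson r with the two-sided
  t-test p-value; zero variance in either vector is reported as
  undefined rather than silently NaN-propagated. "Copy-number burden" is
  the count of amplified plus deleted gene calls per sample.
* **Serial-draw trends**: per-variant Pearson r between the
  allele-fraction trajectory and the tumor-marker trajectory (CA
  27.29-like), using only draws where both exist (no interpolation);
  AFs below the 0.1% detection limit are censored to 0 and counted.
* **Oncoprint**: gene × sample matrix with cells in {mutation,
  amplification, deletion, multiple, none}, genes ordered by altered-
  sample count.
* **Platform concordance**: R² of an ordinary least-squares fit between
  paired allele fractions of identical variant keys, plus the fraction
  of keys with concordant detection status.

## Synthetic cohorts: what they emulate and what they do not

The generator's defaults emulate the study conditions the package
targets: 46 samples, ~3 somatic mutations in a typical sample with 4
hypermutated samples (Poisson mean 60) carrying most of the cohort's
burden, somatic AFs uniform on [0.04, 0.90], read depths Poisson around
2311×, shared germline variants recurring in more samples than the
recurrence threshold, recurrent artifacts with strand bias outside
[0.5, 0.6], common SNPs with population AF in [0.02, 0.40], private
near-homozygous germline variants (AF 0.92–0.99), and synonymous and
non-coding calls. The ctDNA mode adds serial draws sharing one germline
sample per patient. Coverage simulation draws multinomial counts over a
log-normal per-amplicon efficiency profile scaled by CN/2 per gene.

Every planted class violates **exactly one** filter stage
(separability), so cascade truth recovery is exact by construction, and
boundary plants can be added in tests to exercise inclusivity. This is
the point, and also the limit: passing these tests shows the rules are
implemented as specified, *not* that the rules themselves are sufficient
on real data, where artifact strand bias is continuous, germline AFs
overlap somatic AFs in impure tumors, and population databases are
incomplete. Likewise the coverage model has no GC waves or
amplicon-dropout structure, so copy-number recovery results bound only
sampling noise, not real-panel bias. Quantities that depend on patient
data — cohort-level survivor counts, AF-vs-marker correlations in real
draws, cross-platform R² — are therefore validated structurally
(recovery of configured truth) rather than against cohort values.

For planted copy number the recovery criterion is the nearest level on
the planted grid {1, 2, 4, 6, 8}: CN 6 and CN 1 sit exactly on the
strict reporting boundaries, where threshold status at finite depth is
undefined by construction; threshold-status recovery is checked with
off-boundary plants (CN 8 amplified, CN 0.5 deleted).

Serial draws are generated as `r·marker_z + sqrt(1−r²)·noise` in
standardized space, so a configured correlation of ±1 is recovered
exactly and intermediate values within sampling error.

All generation is deterministic for a fixed seed (NumPy Generator,
PCG64), and emitted files (VCF, TSVs) are byte-identical across runs.

## Problem sizes used in the checks

The test suite and acceptance script run on 46-sample solid cohorts
(~770 calls), 14-draw ctDNA cohorts, 148-amplicon toy panels at 500×
simulated depth with 14 normals, and 5–60-point serial-draw series;
these sizes keep every stochastic check well above its separability
margins while the whole suite completes in seconds.

## Known limitations

* Tumor-only filtering cannot distinguish a rare germline variant at
  moderate AF from a somatic mutation; the cascade's rules are
  heuristics, not a probabilistic joint model (no UMI error suppression,
  no tumor-normal likelihoods).
* Copy-number calls have no purity/ploidy correction and no
  segmentation; allele-specific CN and structural variants are out of
  scope.
* Knowledge-base matching is exact-string; variants are not re-levelled
  from trial evidence, and the shipped table is a frozen snapshot.
* The recurrence filter counts samples after the read-stage AF floor;
  cohorts merged across floors should re-run the cascade from raw calls.
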