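# Methods

## Model and assumptions

The pipeline treats a cohort as a set of paired samples: each patient
contributes one non-remodelled (N) and one remodelled (R) microdissected
epithelial sample, and each patient belongs to one clinical group
(non-COPD or COPD). Upstream alignment, variant calling and CNA
segmentation are out of scope: inputs are per-sample call sets (VCF 4.2)
and segment tables (SEG-like TSV, 1-based inclusive), plus a gene model
(BED), optional gene-set annotations (GMT), an optional reference gene
list, and an optional gene × sample log2 expression matrix with a
sample-to-group map.

Three modelling commitments drive everything downstream:

1. **Variant identity is the normalized allele quadruple.** Keys are
   `(chrom, pos, ref, alt)` after trimming the common suffix, then the
   common prefix (advancing `pos`), always keeping at least one base per
   allele. Position-only identity would merge distinct substitutions at
   a site; allele-aware identity is what "identical variant" means here.
   Equal-length multi-base substitutions are classified as SNV
   (substitution); insertions/deletions by allele-length difference.
2. **CNA locus identity is exact coordinate equality.** Two segments are
   the same locus iff chromosome, start and end match exactly; copy
   state is ignored by default because the identity rule is positional.
   A strict mode additionally requires matching state, and a
   reciprocal-overlap matcher (`--locus-match overlap:F`) exists for
   robustness studies only — exact matching is the method, since paired
   samples from one segmentation run reproduce coordinates exactly.
3. **Genes are the join unit.** Gene symbols (upper-cased everywhere)
   connect variants, segments, gene sets, reference lists and
   expression. A gene counts once per sample regardless of how many of
   its variants/segments are present. Strand is read but ignored — all
   analyses are strand-agnostic gene-level set operations.

Coordinates are 0-based half-open internally; VCF (1-based) and SEG
(1-based inclusive) are converted exactly once on read and back on
write.

## Comparative analyses and filters

*Global* analysis counts all keys/loci per sample; *comparative*
analysis removes keys/loci shared with a reference before counting. The
default reference is the patient's paired sample (`WITHIN_PATIENT`);
`CROSS_GROUP` removes anything present in the other clinical group. Per
sample the conservation identity `global = comparative + shared` holds
by construction and is asserted in tests.

The remodelled-only filter requires a key present in **exactly one** R
sample and absent from that patient's N sample at the same key. The
single-R restriction is applied within the clinical group by default;
whether it should span the whole cohort is genuinely open, so it is a
flag (`r1_scope`). The group-exclusive recurrent filter requires a key
in both N and R of at least `min_samples` (default 2) patients of one
group and in no sample of the other group; support of 3 is flagged bold,
and HIGH-impact entries are flagged for underlining in reports.

Recurrent CNA genes are computed for two comparisons. Against the
paired N samples, removal is locus-exact per patient (the comparative
rule). Against the other group's R samples, removal is gene-level
(segment coordinates never coincide across patients, so locus-level
removal would be vacuous; the group-level Venn is likewise gene-level).

Impact severity uses a shipped, editable consequence-term tier table
(Sequence Ontology vocabulary → HIGH/MODERATE/LOW/MODIFIER); unknown
terms fall back to MODIFIER with a warning.

## Enrichment and expression cross-reference

Enrichment of a query gene list against GMT terms uses the
observed/expected convention: `expected = |query|·|term|/|background|`,
`strength = log10(observed/expected)`, hypergeometric upper-tail
p-value P(X ≥ observed), BH FDR across terms; terms with zero observed
overlap are omitted, and the background defaults to all genes in the
supplied gene model (the natural universe when annotations come from a
service whose background is unknown).

The expression cross-reference computes, per gene of interest present
in the matrix, `log2fc = mean(COPD) − mean(non-COPD)` on the already
log2-scaled values, a two-sample t-test, and BH FDR over the detected
genes; "deregulated" means FDR < 0.05. The default test is Welch
(unequal variance): the whole-lung expression groups this stage is
designed for are independent cohorts of different sizes and cannot be
paired; `student` (pooled) and `paired` modes are retained for data
that warrant them. Zero-variance/zero-difference genes get p = 1.

Fold changes between group means are reported at one decimal with
half-up rounding, fixed for reproducibility. SEM is sd/√n with the n−1
denominator, 0 by convention for singletons. BH correction is the
standard step-up with cumulative-minimum enforcement, input order
preserved, p required in (0, 1].

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not real human genomes:

* **Gene model** — `n_genes` (default 3000) disjoint gene bodies of
  1.5–3 kb with 0.2–2 kb gaps on a two-chromosome 50 Mb genome.
* **Variants** — per patient, `germline_shared_per_patient` (default
  430) keys identical in N and R; `private_variants_per_sample`
  (default 25) per sample; extra R-only plantings (default 8 per COPD,
  4 per non-COPD patient); `group_exclusive_recurrent_per_group`
  (default 5) keys planted into N∧R of 2 or 3 patients of one group.
  Defaults reproduce the magnitude of the real design: ~460 variants
  per sample globally, ~25–35 after within-patient comparative removal,
  4 + 3 patients. Positions are globally distinct unless sharing is
  intended, so recurrence cannot arise by coincidence and planted-truth
  recovery is an exact-set property. Consequence terms are sampled with
  HIGH probability 0.2 (configurable).
* **CNA** — per patient, `cna_background_per_sample` (default 60)
  segments shared with exact coordinates between N and R;
  `cna_unique_per_sample` (default 50) private segments per sample,
  multiplied by `copd_r_unique_cna_excess` (default 2.4) in COPD R;
  planted recurrent genes with support 2 (default 6 genes) and 3
  (default 4, the bold tier) in COPD R. Every segment covers exactly
  one gene and background genes are drawn without replacement
  cohort-wide — again making recovery exact. Defaults give ~110 loci
  per sample (~130+ in COPD R), unique fractions of roughly 45% vs
  65–70%, and a comparative COPD-R/non-COPD-N locus fold around 2.4–2.6.
* **Expression** — an independent whole-lung-style matrix over all
  genes, default 20 samples per group, per-gene baseline N(7, 1),
  Gaussian noise sd 0.2, and 30 planted genes at ±1.0 log2 fold change,
  preferentially drawn from the planted variant/CNA truth genes so the
  cross-reference stage has signal.
* **Annotations** — a synthetic GMT whose first term collects up to 30
  truth genes plus 30 random genes (a planted enrichment), eight random
  terms, and a synthetic reference gene list overlapping the truth.

Truth tables record, per patient, every gene recoverable by the
remodelled-only filter — explicitly planted events *and* R-private
background variants, which satisfy the filter by construction — plus
the planted recurrent variant genes, recurrent CNA genes with their
supporting patients, and the signed expression effects.

What the generator does **not** model: read-level errors and FFPE
artifacts, realistic gene annotation, linkage or mutational signatures,
multi-gene CNA segments, germline sharing *between* patients, and
population allele frequencies. Passing tests therefore demonstrate
correctness of the set logic, filters and statistics under the assumed
structure — not robustness to caller noise or annotation ambiguity in
real cohorts.

## Numerical and design choices

* Determinism: all randomness flows from one integer seed through
  per-component `numpy` generators; output files are byte-identical
  across reruns of the same configuration.
* Hypergeometric p-values are floored at the smallest positive double
  to keep them in (0, 1] for BH.
* Degenerate t-tests: zero variance with equal means → t = 0, p = 1;
  zero variance with unequal means → the p → 0 limit, flagged.
* Counts in the generator are exact (not Poisson-drawn), so the
  monotone effect of the excess factor and the equality at excess = 1
  are deterministic properties.
* Problem sizes in the test-suite and acceptance checks: the
  brute-force oracle and directional studies use a reduced cohort
  (~80–100 variants, ~25–50 segments per sample, 400 genes) because the
  nested-loop oracles are quadratic and the properties they certify are
  size-independent; recovery checks run at the full default shape.

## Known limitations

* The remodelled-only and recurrence filters are purely set-theoretic:
  no allele-frequency, depth or quality evidence is weighed, so real
  call sets should be pre-filtered upstream.
* Exact-coordinate locus identity is appropriate within one
  segmentation run but brittle across callers; the reciprocal-overlap
  mode exists precisely for that sensitivity analysis.
* The enrichment background choice materially affects p-values; using
  the supplied gene model as the universe is a convention, not a truth.
* With three patients per group, recurrence thresholds of 2/3 sit at
  the edge of what the design can support; the thresholds are exposed
  as parameters rather than tuned.
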