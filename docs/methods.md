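# Methods

## The question and the data model

A patient presents with several thyroid lesions — typically a papillary
carcinoma (PTC) and one or more benign adenomatoid nodules — plus normal
thyroid tissue and blood. Whole-exome sequencing of every sample against the
single blood germline reference yields, at each candidate site and sample, a
pair of read counts (ref_depth, alt_depth). The package asks whether the
lesions descend from a common mutated clone (a shared "trunk" of somatic
mutations) or arose independently, and whether their transcriptomes carry the
corresponding differentiation and MAPK-activity character.

Two simplifying assumptions run through the genomic arm:

* **Diploid heterozygous sites.** The expected variant allele fraction (VAF)
  of a clonal mutation is purity × CCF / 2; local copy number is not
  modelled. This is adequate for near-diploid thyroid lesions and keeps VAF
  comparable across samples.
* **A single germline reference per patient.** Somatic status is always
  defined relative to the one blood sample; each tissue is filtered
  independently against it ("single-normal–multi-tumour"), so a mutation can
  legitimately be somatic in one lesion and absent in another.

## Somatic filtering

A (site, sample) observation is called somatic iff all rules hold:

| rule | default | unit |
|---|---|---|
| tissue depth and blood depth | ≥ 10 | reads |
| VAF | ≥ 0.10 (≥ 0.05 if tissue depth > 50) | fraction |
| supporting reads in tissue | ≥ 3 | reads |
| supporting reads in blood | ≤ 2 | reads |
| χ² (case vs germline 2×2, 1 df) | p < 0.05 | — |
| 1000 Genomes MAF | ≤ 0.05 | fraction |
| ExAC MAF | ≤ 0.01 | fraction |
| dbSNP-common flag | absent | — |
| region class | ∉ {intergenic, intronic} | — |

The χ² significance level is a free parameter (0.05 is the conventional
choice; nothing downstream is sensitive to it at ~160× because true somatic
sites separate from germline by dozens of reads). The test is the plain
Pearson statistic; the Yates correction is available but off, and a 2×2
table with an all-zero allele column is defined as statistic 0 / p 1
(no evidence) rather than an error. The 5% VAF relaxation at depth > 50 does
**not** relax the 3-read minimum. Missing annotation fields can either skip
their rule (lenient, default — the skip is recorded in the trace) or reject
the site (strict). Multi-allelic records are decomposed into biallelic
records before filtering; coordinates are 1-based VCF conventions.

Every rule outcome is recorded per call, so any printed mutation can be
audited back to the exact rule set that admitted it.

## Mutation statistics

* **Density** divides a mutation count by a fixed 30 Mb exome.
* **Spectra** reduce SNVs to the pyrimidine-reference convention (purine
  reference ⇒ reverse-complement the substitution *and* swap/complement the
  flanking bases), giving 6 substitution classes and 96 trinucleotide
  contexts keyed like `A[C>T]G`. Indels and flank-less SNVs are counted and
  excluded rather than guessed.
* **Overlap** between two lesions' call sets defaults to Jaccard
  (|∩| / |∪|); the |∩| / min(|a|, |b|) convention is selectable and the
  convention used is stored in every result, because the two can differ by a
  factor of ~2 on typical set sizes. Mutations also present in the matched
  normal are reported separately. Two empty sets give ratio 0, flagged
  degenerate.
* **Cohort frequencies** are reported on both the per-patient and the
  per-sample denominator; the two differ whenever patients contribute
  multiple lesions, and neither is silently preferred.
* **Mutual exclusivity** of a gene set is the count of patients mutated in
  ≥ 2 listed genes (exclusive iff 0). The optional permutation test redraws
  each gene's patient set uniformly with per-gene totals fixed; small tables
  are enumerated exhaustively (exact p), larger ones use Monte Carlo with the
  add-one estimator.

## VAF phylogenetics

The VAF matrix for a patient spans the union of somatic calls across all
tissue samples. A sample that lacks a call still contributes that site's raw
VAF: 0 when the site is covered at ≥ 10× (evidence of absence), missing when
it is not (absence of evidence). This distinction is what makes the Pearson
correlation between samples meaningful. Distances are d = 1 − r over
pairwise-complete rows, with pairs under 3 complete rows or with a
zero-variance column reported missing (with the reason) rather than imputed;
the pipeline can impute such pairs to d = 1 on request. The germline is an
explicit all-zero column placed at d = 1 from every tissue sample and used
as the outgroup.

Trees are built by neighbour joining (default) or UPGMA — the standard
distance methods for such a matrix; taxa are sorted before construction so
ties break deterministically, and negative NJ length estimates are clamped
to 0 and flagged. Two length systems coexist and are never conflated: the
correlation branch lengths from the tree, and per-branch *mutation counts*
from the annotation step, which assigns to each branch the mutations carried
by exactly the clade below it (present in every leaf of the clade, absent
from every other tissue leaf).

A tumour–benign pair is classified by its exclusive shared set: mutations
called in both pair members and in no other sample of the patient. Default
mode calls *shared-branch* on ≥ 1 such mutation; `coding-only` mode requires
≥ 1 coding (exonic/splicing) shared mutation, guarding against recurrent
non-coding artefacts. Whether the pair forms a cherry in the tree is
reported as corroborating evidence, but the verdict rests on the mutation
sets — a mutation-free pair can sit adjacent in the tree by chance.

## Expression scoring

FPKM = counts · 10⁹ / (gene length · library size); genes below 1 FPKM are
dropped (in *all* samples under the default `max` mode, by mean under the
alternative `mean` mode — both conventions appear in practice and the mode
is recorded); values are log₂(FPKM + 0.1).

Paired differential expression is a paired t-test on the per-patient log₂
differences with Benjamini–Hochberg adjustment, thresholded at
|fold change| > 1.5 and FDR < 0.01. This is a deliberate, documented
stand-in for count-based negative-binomial DE machinery: the package's scope
is the decision layer (thresholds, pairing, list overlaps), not DE
internals. Difference vectors constant to ~machine precision (relative
tolerance 1e-9) cannot be t-tested: p is 1 when the shift is zero, and an
exact non-zero shift is flagged `exact_shift` with p 0 (the limit of the
test as noise → 0).

Scores, per sample over log₂ expression:

* **TDS** = Σ_g (x_gs − median_s x_gs) over the 16-gene thyroid set —
  invariant to per-gene additive shifts; low values mark de-differentiation.
* **EAS** = Σ_g z_gs over the 52-gene ERK set, z computed per gene across
  samples with the n−1 standard deviation — invariant to per-gene affine
  transforms. Sum aggregation is the default (giving cohort-scale dynamic
  ranges of tens of units); mean is available. Zero-variance genes
  contribute 0 and are flagged.
* **BRAF–RAS character** is displayed by hierarchical clustering (average
  linkage by default, configurable) on 1 − r distances over the 71-gene set.

The three published signature gene lists are not shipped: real analyses
supply them as one-gene-per-line files, and all tests run on the generator's
own synthetic signatures of the same sizes (16 / 52 / 71).

## The synthetic cohort generator

The generator reproduces the statistical skeleton of the targeted study
design; its defaults are the package's study conditions.

| parameter | default | rationale |
|---|---|---|
| layout | blood + normal + 1 benign + 1 tumour | the matched-lesion design |
| mean depth | 160× | the design's exome coverage |
| depth dispersion (var/mean) | 1 (Poisson) | central depth range ≈ 135–185× |
| private mutations / lesion | Poisson(10) | ≈ 0.33/Mb × 30 Mb |
| normal-tissue mutations | Poisson(3.6) | ≈ 0.12/Mb × 30 Mb |
| trunk mutations | 0 (configurable) | independent origin unless planted |
| purity | 0.8 | high-cellularity dissection |
| CCF | 1.0 | clonal mutations |
| germline error rate | 10⁻³ /read | free parameter, not an estimate |
| noise sites / het sites | 25 / 5 | exercise the error and germline rules |
| TDS / ERK / BRAF–RAS planted log₂ effects | −1.5 / +1.5 / ±1.0 (tumours) | the score structure the analysis must recover |

Alt reads at a truth site are Binomial(depth, purity × CCF / 2) in carrier
lesions (purity 1 in normal tissue, whose mutations are clonal patches);
non-carrier samples and blood see Binomial(depth, error rate); inherited
heterozygous sites see Binomial(depth, 0.5) everywhere including blood.
Expression counts are gamma-Poisson (negative binomial, var = μ + 0.05 μ²)
around log-normal baseline means shared across a cohort seed; tumours get
the planted signature shifts — the BRAF–RAS effect uses a fixed mixed
up/down sign pattern because a uniform shift would be invisible to
correlation distances. Dispersion 0 is the exact noise-free limit. Ground
truth (the trunk/private partition, with the realised Poisson draws) is
written to a separate JSON that no analysis stage reads.

What the generator does **not** emulate — and hence what green tests do not
establish about real data: copy-number alterations and their effect on VAF,
subclonal structure beyond one trunk + private sets, mapping artefacts and
strand bias, batch effects between sequencing sets, realistic mutational
signatures (flanking bases are uniform), and driver-gene biology (gene
labels are uniform draws from a synthetic namespace).

## Calibration experiments and problem sizes

The recovery suite (`nodulomics.recovery`) measures, at sizes chosen to
keep the default test run fast while leaving Monte-Carlo error well inside
the decision margins:

* **Origin classification**: 200 patients per condition at 160×, purity
  0.6 — the fraction classified independent should be ≥ 0.95 with no trunk
  and ≤ 0.05 with a 5-mutation coding trunk (coding-only mode).
* **Overlap calibration**: 500 single-patient replicates at trunk t = 4,
  private rate λ = 10. The observed mean Jaccard is compared to the exact
  expectation E[t / (t + A + B)], A + B ~ Poisson(2λ), computed by direct
  summation. The plug-in value t/(t + 2λ) sits ~0.006 below the exact
  expectation (Jensen, convexity in the private count) — larger than the
  ~0.0015 Monte-Carlo SE at this size, which is why the exact sum is the
  reference.
* **Score sign recovery**: 100 replicates of a 4-patient cohort; success =
  mean TDS(tumour) < mean TDS(benign) and mean EAS(tumour) > mean
  EAS(normal).
* **DE null calibration**: 200 simulations of 2,000 genes × 6 pairs with no
  planted effects; the mean fraction of (necessarily false) DEG calls at
  FDR < 0.01 must stay ≤ 0.02.

## Known limitations

* The paired t-test stand-in is anti-conservative for low counts relative
  to a negative-binomial model; with FPKM ≥ 1 filtering and ≥ 3 pairs it is
  calibrated on the generator's data, but real low-count genes deserve a
  count model.
* Origin classification treats any pair-exclusive shared call as trunk
  evidence; recurrent artefacts shared between two lesions (absent from the
  generator) would require the coding-only mode or manual review.
* Tree branch lengths from 1 − r distances are not additive in mutation
  counts; the per-branch mutation counts are provided precisely so the two
  scales are never conflated.
* The pipeline infers tissue types from sample-name suffixes
  (`*_blood`, `*_normal`, `*_benignK`, `*_tumourK`); real cohorts must be
  renamed to this convention or driven through the library API.
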