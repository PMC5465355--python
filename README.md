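# nodulomics

Multi-lesion genomic comparison of matched thyroid samples: did a papillary
thyroid carcinoma (PTC) and a coincident benign (adenomatoid) nodule arise
from a shared clone, or independently?

Each patient contributes a blood sample (germline reference), normal thyroid,
one or more benign nodules and optionally PTC foci, whole-exome sequenced at
~160×. The package implements the analysis layer that sits downstream of
alignment and raw genotyping:

* **Somatic filtering** against the single blood reference, jointly across all
  of a patient's tissues ("single-normal–multi-tumour"): depth ≥ 10× in
  tissue and blood, VAF ≥ 10% (relaxed to 5% when local depth > 50×), ≥ 3
  supporting reads, ≤ 2 blood reads, a Pearson χ² test on the 2×2
  case/germline allele-depth table, and exclusion of common polymorphisms
  (dbSNP-common, 1000 Genomes MAF > 5%, ExAC MAF > 1%) and
  intergenic/intronic sites. Every rule's outcome is kept in a per-call trace.
* **Mutation statistics**: exome-wide density (n/30 Mb), the six-class and
  96-trinucleotide-context substitution spectrum in the pyrimidine-reference
  convention, tumour–benign overlap (Jaccard by default, |∩|/min selectable,
  always tagged), per-gene cohort frequencies on both per-patient and
  per-sample denominators, and mutual exclusivity of a gene set with an
  exhaustive or Monte-Carlo permutation test.
* **VAF phylogenetics**: per patient, a sites × samples matrix of variant
  allele fractions over the union of somatic calls (0 where covered but
  unmutated, missing where under-covered), pairwise distances d = 1 − r
  (Pearson), neighbour-joining or UPGMA trees rooted on the germline, branch
  annotation with each clade's exclusive mutation set, and classification of
  every tumour–benign pair as *shared-branch* (trunk carries ≥ 1 mutation;
  optionally ≥ 1 coding mutation) or *independent*.
* **Expression scoring**: FPKM = counts · 10⁹/(length · library size), the
  FPKM ≥ 1 expression floor, log₂(FPKM + 0.1), paired differential expression
  at |FC| > 1.5 and BH FDR < 0.01 with patients as replicates, hierarchical
  clustering on 1 − r distances, the 16-gene thyroid differentiation score
  (TDS, summed median-centred log₂ expression), the 52-gene ERK-activity
  score (EAS, aggregated per-gene z-scores) and clustering on the 71-gene
  BRAF–RAS signature.
* **A synthetic-cohort generator** with known clonal architecture (trunk vs
  private mutations, binomial allele sampling at purity × CCF/2,
  configurable depth and germline noise, signature-structured expression), so
  every stage is testable end to end without any controlled-access download.

## Worked example

```python
from nodulomics.somatic_filter import FilterConfig, call_somatic_multi_sample, passing_calls
from nodulomics.lineage import classify_origin
from nodulomics.synthdata import SimConfig, simulate_patient

cfg = SimConfig(n_patients=1, trunk_mutations=3, seed=42)
patient = simulate_patient(cfg, 0)
calls = call_somatic_multi_sample(
    patient.observations, patient.annotations,
    FilterConfig(), blood_sample=patient.blood_sample)
somatic = passing_calls(calls)
print(somatic.groupby("sample").size())

sets = {s: g for s, g in somatic.groupby("sample")}
coding = set(zip(*(somatic[somatic["region"].isin({"exonic", "splicing"})][c]
                   for c in ["chrom", "pos", "ref", "alt"])))
verdict = classify_origin(("P00_tumour1", "P00_benign1"), sets,
                          coding=coding, mode="coding-only")
print(verdict.classification, len(verdict.shared_coding))
```

prints

```
sample
P00_benign1    19
P00_normal      2
P00_tumour1     8
dtype: int64
shared-branch 3
```

— the benign nodule carries 19 somatic calls and the tumour 8 (each its
private mutations plus the 3-mutation trunk both lesions inherited), the
normal thyroid 2; because the pair's exclusive shared branch carries 3
coding mutations the pair is classified as sharing a clonal origin. With
`trunk_mutations=0` the same code reports `independent 0`.

## Analysis scripts

`analysis/01_simulate_cohort.py` … `05_expression_scores.py` run the whole
study design as a narrative: simulate a 20-patient cohort (16 independent,
4 with a planted 3-mutation trunk), call somatic mutations (510 calls, 100%
sensitivity against truth, densities 0.38/0.34/0.14 per Mb for
tumour/benign/normal), summarise spectra and overlap (median tumour–benign
Jaccard 0), build trees and classify origins (16/20 independent — exactly
the planted architectures), and score expression (mean TDS −26.7 in tumours
vs +4.6 in benign nodules; mean EAS +60 in tumours vs −29 in normal).
Outputs land under `results/analysis/`.

A `nodulomics` CLI wraps the same pipeline (`simulate`, `filter`,
`mutstats`, `lineage`, `exprscore`, `run-all`), driven by a YAML config with
`--seed`/`--outdir` overrides; every run writes a manifest with per-output
checksums.

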