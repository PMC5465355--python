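#!/usr/bin/env python
"""Summarise the mutation landscape: spectra, overlap, recurrence.

From the calls of step 02: the six-class / 96-context substitution
spectrum, tumour-vs-benign overlap per patient (highlighting mutations
also present in the matched normal), per-gene cohort frequencies, and a
mutual-exclusivity check on the most recurrent benign-nodule genes.

Writes spectrum, overlap and cohort-frequency tables under results/analysis/.
"""

from pathlib import Path

import pandas as pd

from nodulomics.mutstats import (
    cohort_frequency,
    mutual_exclusivity,
    pairwise_overlap,
    substitution_spectrum,
)
from nodulomics.synthdata import tissue_of

OUT = Path("results/analysis")


def main() -> None:
    calls = pd.read_csv(OUT / "calls.tsv", sep="\t", dtype={"chrom": str})
    somatic = calls[calls["filter_pass"]]

    spec = substitution_spectrum(somatic)
    spec.class_counts.rename_axis("class").rename("count").to_frame().assign(
        frequency=spec.class_frequencies.round(4)
    ).to_csv(OUT / "spectrum_classes.tsv", sep="\t")
    spec.context_counts.rename_axis("context").rename("count").to_frame().to_csv(
        OUT / "spectrum_contexts.tsv", sep="\t")

    rows = []
    for pid, pcalls in somatic.groupby("patient"):
        by_sample = {s: g for s, g in pcalls.groupby("sample")}
        tum = next((s for s in by_sample if tissue_of(s) == "tumour"), None)
        ben = next((s for s in by_sample if tissue_of(s) == "benign"), None)
        nor = next((s for s in by_sample if tissue_of(s) == "normal"), None)
        if not (tum and ben):
            continue
        res = pairwise_overlap(by_sample[tum], by_sample[ben],
                               by_sample.get(nor), sample_a=tum, sample_b=ben)
        rows.append({"patient": pid, "n_tumour": res.n_a, "n_benign": res.n_b,
                     "n_shared": res.n_shared,
                     "jaccard": round(res.overlap_ratio, 4),
                     "n_shared_with_normal": res.n_shared_with_normal})
    overlap = pd.DataFrame(rows).sort_values("jaccard", ascending=False)
    overlap.to_csv(OUT / "overlap.tsv", sep="\t", index=False)

    lesion = somatic[somatic["sample"].map(tissue_of).isin(["benign", "tumour"])]
    patients = sorted(somatic["patient"].unique())
    table = (lesion.assign(flag=True)
             .pivot_table(index="patient", columns="gene", values="flag",
                          aggfunc="any", fill_value=False)
             .reindex(patients, fill_value=False))
    freq = pd.DataFrame({
        "gene": table.columns,
        "n_patients": table.sum(axis=0).to_numpy(),
        "pct_patients": [round(cohort_frequency(table, g), 2) for g in table.columns],
    }).sort_values("n_patients", ascending=False)
    freq.to_csv(OUT / "cohort_frequency.tsv", sep="\t", index=False)

    top = list(freq["gene"].head(3))
    me = mutual_exclusivity(table, top, n_permutations=2000, method="auto")

    print("substitution classes:\n", spec.class_frequencies.round(3).to_string())
    print(f"\ntumour-benign jaccard: median {overlap['jaccard'].median():.3f}, "
          f"range {overlap['jaccard'].min():.3f}-{overlap['jaccard'].max():.3f}")
    print(f"most recurrent lesion genes: {', '.join(top)}")
    print(f"mutual exclusivity of top 3: co-occurrence {me.co_occurrence}, "
          f"exclusive={me.exclusive}, p={me.p_value}")


if __name__ == "__main__":
    main()
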