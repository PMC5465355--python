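#!/usr/bin/env python
"""Transcriptome scoring: FPKM, paired DE, TDS / EAS, signature clustering.

Reads the per-patient expression counts from step 01, normalises to FPKM,
drops unexpressed genes, calls paired differential expression
(tumour vs normal and benign vs normal, patients as replicates), and
computes the thyroid-differentiation and ERK-activity scores plus the
BRAF-RAS signature clustering that should separate tumours from benign
nodules and normal thyroid.

Writes scores.tsv, de_*.tsv and deg_overlap.json under results/analysis/.
"""

import json
from pathlib import Path

import pandas as pd

from nodulomics import io as nio
from nodulomics.exprscore import (
    effective_gene_overlap,
    erk_activity_score,
    filter_expressed,
    fpkm_from_counts,
    hierarchical_cluster,
    log_transform,
    paired_de,
    tds_score,
)
from nodulomics.synthdata import SimConfig, make_signatures, tissue_of

OUT = Path("results/analysis")
FIXTURES = OUT / "fixtures"


def main() -> None:
    mats, lengths = [], None
    for path in sorted(FIXTURES.glob("*.expression.tsv")):
        mat, lengths = nio.read_expression(path)
        mats.append(mat)
    counts = pd.concat(mats, axis=1)
    fpkm = filter_expressed(fpkm_from_counts(counts, lengths))
    log2 = log_transform(fpkm)

    sigs = make_signatures(SimConfig(n_genes=400))
    scores = pd.DataFrame({
        "tds": tds_score(log2, sigs["tds"]).round(3),
        "eas": erk_activity_score(log2, sigs["erk"]).round(3),
    })
    scores.index.name = "sample"
    scores["tissue"] = [tissue_of(s) for s in scores.index]
    scores.to_csv(OUT / "scores.tsv", sep="\t")

    tissues = {s: tissue_of(s) for s in log2.columns}
    patient_of = {s: s.rsplit("_", 1)[0] for s in log2.columns}

    def pairs(ta, tb):
        by = {}
        for s, t in tissues.items():
            if t in (ta, tb):
                by.setdefault(patient_of[s], {})[t] = s
        return [(d[ta], d[tb]) for d in by.values() if ta in d and tb in d]

    de = {}
    for name, (ta, tb) in {"tumour_vs_normal": ("tumour", "normal"),
                           "benign_vs_normal": ("benign", "normal")}.items():
        de[name] = paired_de(log2, pairs(ta, tb))
        de[name].rename_axis("gene").to_csv(OUT / f"de_{name}.tsv", sep="\t")

    venn = effective_gene_overlap(de["tumour_vs_normal"], de["benign_vs_normal"])
    (OUT / "deg_overlap.json").write_text(json.dumps(venn, indent=1))

    cl = hierarchical_cluster(log2, genes=list(sigs["braf_ras"].genes))
    labels = cl.flat_clusters(3)
    composition = pd.crosstab(
        pd.Series({s: tissues[s] for s in labels.index}, name="tissue"), labels)
    composition.to_csv(OUT / "braf_ras_clusters.tsv", sep="\t")

    print(scores.groupby("tissue")[["tds", "eas"]].mean().round(2))
    for name, d in de.items():
        up, down = (d["direction"] == "up") & d["is_deg"], (d["direction"] == "down") & d["is_deg"]
        print(f"{name}: {int(up.sum())} up, {int(down.sum())} down DEGs")
    print(f"up-DEG overlap tumour/benign: {venn['up']['pct_overlap']:.1f}% "
          f"of tumour-effective genes")
    print("BRAF-RAS signature clusters (tissue x cluster):\n", composition)


if __name__ == "__main__":
    main()
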