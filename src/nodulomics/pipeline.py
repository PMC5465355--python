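"""End-to-end pipeline: filtering → mutation statistics → phylogeny → expression.

`run_pipeline` consumes a :class:`PipelineConfig` (paths to observation /
annotation / expression tables, or a simulation block that generates them),
executes the stages in order, writes every stage's tables under the output
directory and records a run manifest (config snapshot, per-file checksums,
warnings) so identical inputs provably give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from . import __version__
from .exprscore import (
    erk_activity_score,
    filter_expressed,
    fpkm_from_counts,
    hierarchical_cluster,
    log_transform,
    paired_de,
    tds_score,
)
from .lineage import (
    GERMLINE_LABEL,
    build_tree,
    build_vaf_matrix,
    classify_origin,
    correlation_distance,
    root_and_annotate,
)
from .mutstats import (
    cohort_frequency,
    mutation_density,
    pairwise_overlap,
    substitution_spectrum,
)
from .somatic_filter import FilterConfig, call_somatic_multi_sample, passing_calls
from .synthdata import SimConfig, simulate_cohort, tissue_of

logger = logging.getLogger("nodulomics")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one run needs; round-trips through YAML."""

    outdir: str = "results"
    observations_path: str | None = None
    annotations_path: str | None = None
    expression_path: str | None = None
    #: simulate a cohort instead of reading observation files
    simulate: SimConfig | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    tree_method: str = "nj"
    origin_mode: str = "default"
    #: what to do with undefined sample-pair distances: "error" or "impute_one"
    vaf_missing_policy: str = "impute_one"
    min_vaf_depth: int = 10
    expr_filter_mode: str = "max"
    cluster_linkage: str = "average"
    eas_aggregate: str = "sum"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if raw.get("simulate") is not None:
            raw["simulate"] = SimConfig(**raw["simulate"])
        if raw.get("filter") is not None:
            f = dict(raw["filter"])
            if "excluded_regions" in f:
                f["excluded_regions"] = frozenset(f["excluded_regions"])
            raw["filter"] = FilterConfig(**f)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.snapshot(), sort_keys=True))

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("filter"):
            d["filter"]["excluded_regions"] = sorted(d["filter"]["excluded_regions"])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _blood_of(samples, patient: str) -> str:
    bloods = [s for s in samples if tissue_of(s) == "blood"]
    if len(bloods) != 1:
        raise ValueError(f"patient {patient}: need exactly one blood sample, found {bloods}")
    return bloods[0]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the run manifest (also written).

    Stages with absent inputs (e.g. no expression table) are skipped and the
    skip is noted in the manifest.  Any stage failure aborts with the stage
    name in the exception.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_warnings: list[str] = []
    outputs: dict[str, str] = {}
    manifest: dict = {
        "version": __version__,
        "config": config.snapshot(),
        "skipped": [],
    }

    def emit(name: str, path: Path) -> None:
        outputs[name] = str(path)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # ---- stage: inputs -------------------------------------------------
        stage = "input"
        try:
            expression = gene_lengths = None
            if config.simulate is not None:
                cohort = simulate_cohort(config.simulate)
                observations = pd.concat(
                    [p.observations for p in cohort], ignore_index=True)
                annotations = (
                    pd.concat([p.annotations for p in cohort], ignore_index=True)
                    .drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
                )
                expression = pd.concat([p.expression for p in cohort], axis=1)
                gene_lengths = cohort[0].gene_lengths
            elif config.observations_path:
                observations = nio.read_observations(config.observations_path)
                annotations = (nio.read_annotations(config.annotations_path)
                               if config.annotations_path else None)
                if config.expression_path:
                    expression, gene_lengths = nio.read_expression(config.expression_path)
            else:
                raise ValueError("config needs observations_path or a simulate block")

            # ---- stage: somatic filtering ---------------------------------
            stage = "somatic_filter"
            all_calls = []
            patients = sorted(observations["patient"].unique())
            blood_by_patient = {}
            for pid in patients:
                pobs = observations[observations["patient"] == pid]
                blood = _blood_of(pobs["sample"].unique(), pid)
                blood_by_patient[pid] = blood
                all_calls.append(call_somatic_multi_sample(
                    pobs, annotations, config.filter, blood_sample=blood))
            calls = pd.concat(all_calls, ignore_index=True)
            calls_path = outdir / "calls.tsv"
            calls.to_csv(calls_path, sep="\t", index=False)
            emit("calls", calls_path)
            somatic = calls[calls["filter_pass"]]

            # ---- stage: mutation statistics -------------------------------
            stage = "mutstats"
            dens = (
                somatic.groupby(["patient", "sample"], as_index=False)
                .size().rename(columns={"size": "n_mutations"})
            )
            dens["per_mb"] = dens["n_mutations"].map(mutation_density)
            p = outdir / "density.tsv"
            dens.to_csv(p, sep="\t", index=False)
            emit("density", p)

            spec = substitution_spectrum(somatic)
            p = outdir / "spectrum_classes.tsv"
            spec.class_counts.rename_axis("class").rename("count").to_frame().assign(
                frequency=spec.class_frequencies).to_csv(p, sep="\t")
            emit("spectrum_classes", p)
            p = outdir / "spectrum_contexts.tsv"
            spec.context_counts.rename_axis("context").rename("count").to_frame().assign(
                frequency=spec.context_frequencies).to_csv(p, sep="\t")
            emit("spectrum_contexts", p)

            overlap_rows = []
            for pid in patients:
                pcalls = somatic[somatic["patient"] == pid]
                by_sample = {s: g for s, g in pcalls.groupby("sample")}
                tumours = sorted(s for s in by_sample if tissue_of(s) == "tumour")
                benigns = sorted(s for s in by_sample if tissue_of(s) == "benign")
                normals = sorted(s for s in by_sample if tissue_of(s) == "normal")
                normal_calls = by_sample.get(normals[0]) if normals else None
                for t in tumours:
                    for b in benigns:
                        res = pairwise_overlap(
                            by_sample.get(t, pcalls.iloc[0:0]),
                            by_sample.get(b, pcalls.iloc[0:0]),
                            normal_calls, sample_a=t, sample_b=b)
                        overlap_rows.append({
                            "patient": pid, "tumour": t, "benign": b,
                            "n_tumour": res.n_a, "n_benign": res.n_b,
                            "n_shared": res.n_shared,
                            "overlap_ratio": res.overlap_ratio,
                            "convention": res.convention,
                            "n_shared_with_normal": res.n_shared_with_normal,
                        })
                overlaps = pd.DataFrame(overlap_rows)
            p = outdir / "overlap.tsv"
            overlaps.to_csv(p, sep="\t", index=False)
            emit("overlap", p)

            lesion_calls = somatic[somatic["sample"].map(tissue_of).isin(["benign", "tumour"])]
            cohort_tbl = (
                lesion_calls.assign(flag=True)
                .pivot_table(index="patient", columns="gene", values="flag",
                             aggfunc="any", fill_value=False)
                .reindex(patients, fill_value=False)
            )
            n_samples = lesion_calls["sample"].nunique()
            freq_rows = []
            for gene in sorted(cohort_tbl.columns):
                n_pat = int(cohort_tbl[gene].sum())
                n_sam = int(lesion_calls[lesion_calls["gene"] == gene]["sample"].nunique())
                freq_rows.append({
                    "gene": gene,
                    "n_patients_mutated": n_pat,
                    "pct_patients": cohort_frequency(cohort_tbl, gene),
                    "n_samples_mutated": n_sam,
                    "pct_samples": 100.0 * n_sam / n_samples if n_samples else 0.0,
                })
            p = outdir / "cohort_frequency.tsv"
            pd.DataFrame(freq_rows).to_csv(p, sep="\t", index=False)
            emit("cohort_frequency", p)

            # ---- stage: lineage -------------------------------------------
            stage = "lineage"
            treedir = outdir / "trees"
            treedir.mkdir(exist_ok=True)
            origin_rows = []
            coding_regions = {"exonic", "splicing"}
            for pid in patients:
                pobs = observations[observations["patient"] == pid]
                pcalls = calls[calls["patient"] == pid]
                psomatic = pcalls[pcalls["filter_pass"]]
                blood = blood_by_patient[pid]
                vaf = build_vaf_matrix(pobs, psomatic, blood_sample=blood,
                                       min_depth=config.min_vaf_depth)
                vaf.to_csv(treedir / f"{pid}.vaf_matrix.tsv", sep="\t")
                emit(f"vaf_matrix/{pid}", treedir / f"{pid}.vaf_matrix.tsv")
                if len(vaf) == 0:
                    manifest["skipped"].append(f"lineage:{pid}:no somatic sites")
                    continue
                dist, reasons = correlation_distance(vaf)
                if reasons:
                    if config.vaf_missing_policy == "error":
                        raise ValueError(f"{pid}: undefined distances {reasons}")
                    for pair, why in reasons.items():
                        run_warnings.append(f"{pid}: distance {pair} imputed to 1.0 ({why})")
                    dist = dist.fillna(1.0)
                    np.fill_diagonal(dist.values, 0.0)
                dist.to_csv(treedir / f"{pid}.distances.tsv", sep="\t")
                emit(f"distances/{pid}", treedir / f"{pid}.distances.tsv")
                tree = build_tree(dist, method=config.tree_method)
                sets = {s: g for s, g in psomatic.groupby("sample")}
                rooted, branches = root_and_annotate(tree, GERMLINE_LABEL, sets)
                nwk = treedir / f"{pid}.tree.nwk"
                rooted.write(str(nwk))
                emit(f"tree/{pid}", nwk)
                branches.to_csv(treedir / f"{pid}.branches.tsv", sep="\t", index=False)
                emit(f"branches/{pid}", treedir / f"{pid}.branches.tsv")

                coding = set(zip(*(psomatic[psomatic["region"].isin(coding_regions)][c]
                                   for c in ["chrom", "pos", "ref", "alt"]))) \
                    if len(psomatic) else set()
                tumours = sorted(s for s in sets if tissue_of(s) == "tumour")
                benigns = sorted(s for s in sets if tissue_of(s) == "benign")
                for t in tumours:
                    for b in benigns:
                        oc = classify_origin((t, b), sets, coding=coding,
                                             mode=config.origin_mode, tree=rooted)
                        origin_rows.append({
                            "patient": pid, "tumour": t, "benign": b,
                            "classification": oc.classification, "mode": oc.mode,
                            "n_shared": len(oc.shared),
                            "n_shared_coding": len(oc.shared_coding),
                            "n_shared_noncoding": len(oc.shared_noncoding),
                            "pair_is_cherry": oc.pair_is_cherry,
                        })
            p = outdir / "origin_calls.tsv"
            pd.DataFrame(origin_rows, columns=[
                "patient", "tumour", "benign", "classification", "mode",
                "n_shared", "n_shared_coding", "n_shared_noncoding", "pair_is_cherry",
            ]).to_csv(p, sep="\t", index=False)
            emit("origin_calls", p)

            # ---- stage: expression ----------------------------------------
            stage = "exprscore"
            if expression is None:
                manifest["skipped"].append("exprscore:no expression input")
            else:
                if gene_lengths is not None:
                    fpkm = fpkm_from_counts(expression, gene_lengths)
                else:
                    fpkm = expression
                fpkm = filter_expressed(fpkm, mode=config.expr_filter_mode)
                log2 = log_transform(fpkm)
                from .synthdata import make_signatures
                sim = config.simulate or SimConfig()
                sigs = make_signatures(sim)
                scores = pd.DataFrame({
                    "tds": tds_score(log2, sigs["tds"]),
                    "eas": erk_activity_score(log2, sigs["erk"],
                                              aggregate=config.eas_aggregate),
                })
                scores.index.name = "sample"
                scores["tissue"] = [tissue_of(s) for s in scores.index]
                p = outdir / "scores.tsv"
                scores.to_csv(p, sep="\t")
                emit("scores", p)

                tissues = {s: tissue_of(s) for s in log2.columns}
                patient_of = {s: s.rsplit("_", 1)[0] for s in log2.columns}

                def pairs_for(t_a: str, t_b: str):
                    by_pat: dict[str, dict[str, str]] = {}
                    for s, t in tissues.items():
                        if t in (t_a, t_b):
                            by_pat.setdefault(patient_of[s], {}).setdefault(t, s)
                    return [(d[t_a], d[t_b]) for d in by_pat.values()
                            if t_a in d and t_b in d]

                for name, (ta, tb) in {
                    "de_tumour_vs_normal": ("tumour", "normal"),
                    "de_benign_vs_normal": ("benign", "normal"),
                    "de_tumour_vs_benign": ("tumour", "benign"),
                }.items():
                    prs = pairs_for(ta, tb)
                    if len(prs) < 3:
                        manifest["skipped"].append(f"exprscore:{name}:<3 pairs")
                        continue
                    de = paired_de(log2, prs)
                    p = outdir / f"{name}.tsv"
                    de.rename_axis("gene").to_csv(p, sep="\t")
                    emit(name, p)

                cl = hierarchical_cluster(log2, genes=list(sigs["braf_ras"].genes),
                                          linkage=config.cluster_linkage)
                p = outdir / "braf_ras_cluster.tsv"
                pd.DataFrame({
                    "merge": range(len(cl.merge_heights)),
                    "height": cl.merge_heights,
                }).to_csv(p, sep="\t", index=False)
                emit("braf_ras_cluster", p)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

        run_warnings.extend(str(w.message) for w in caught)

    manifest["warnings"] = run_warnings
    manifest["outputs"] = {k: _sha256(Path(v)) for k, v in outputs.items()}
    manifest["output_paths"] = outputs
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
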