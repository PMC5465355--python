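"""Readers and writers for the pipeline's file formats.

Observation tables travel either as VCF 4.x with per-sample ``AD`` (ref,alt
allele depths) and ``DP`` fields, or as a flat TSV dialect with columns
``patient, chrom, pos, ref, alt, sample, ref_depth, alt_depth``.
Multi-allelic VCF records are decomposed into biallelic records on read.
All TSVs are tab-delimited UTF-8 with '#'-prefixed comment lines and fixed
column orders, so outputs diff cleanly between runs.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

OBS_COLUMNS = ["patient", "chrom", "pos", "ref", "alt", "sample", "ref_depth", "alt_depth"]
ANN_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "region", "func",
               "dbsnp_common", "kg_maf", "exac_maf", "flank5", "flank3"]

__all__ = [
    "OBS_COLUMNS", "ANN_COLUMNS",
    "read_observations", "write_observations_tsv", "write_observations_vcf",
    "read_annotations", "write_annotations",
    "read_expression", "write_expression",
    "read_signature", "write_signature",
    "read_truth",
]


def read_observations(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a site-observation table from VCF or the flat TSV dialect.

    ``dialect`` is inferred from the file extension when not given
    (``.vcf`` -> vcf, otherwise tsv).  Returns one row per (site, sample)
    with 1-based positions; multi-allelic records are decomposed so each row
    is biallelic, sharing the record's reference depth.
    """
    path = Path(path)
    if dialect is None:
        dialect = "vcf" if path.suffix == ".vcf" else "tsv"
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#",
                         dtype={"chrom": str, "patient": str, "sample": str})
        missing = set(OBS_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing observation columns {sorted(missing)}")
        return df[OBS_COLUMNS]
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vcf(path: Path) -> pd.DataFrame:
    rows = []
    n_bad = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            patient = rec.info.get("PATIENT", ".")
            alts = rec.alts or ()
            for s in samples:
                call = rec.samples[s]
                ad = call.get("AD")
                if ad is None or len(ad) != len(alts) + 1 or any(a is None for a in ad):
                    n_bad += 1
                    continue
                for i, alt in enumerate(alts):
                    rows.append({
                        "patient": patient, "chrom": rec.chrom, "pos": rec.pos,
                        "ref": rec.ref, "alt": alt, "sample": s,
                        "ref_depth": int(ad[0]), "alt_depth": int(ad[i + 1]),
                    })
    if n_bad:
        warnings.warn(f"{path}: skipped {n_bad} record/sample entries with malformed AD",
                      stacklevel=2)
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def write_observations_tsv(observations: pd.DataFrame, path: str | Path) -> None:
    observations[OBS_COLUMNS].to_csv(path, sep="\t", index=False)


def write_observations_vcf(
    observations: pd.DataFrame, path: str | Path, *, samples: list[str] | None = None
) -> None:
    """Write a site-observation table as a minimal VCF with AD/DP fields.

    One record per site; each sample's genotype column carries its allele
    depths.  A sample without an observation at a site gets a missing AD.
    """
    obs = observations
    if samples is None:
        samples = sorted(obs["sample"].unique())
    key = ["chrom", "pos", "ref", "alt"]
    contigs = sorted(obs["chrom"].astype(str).unique(),
                     key=lambda c: (len(c), c))
    lines = ["##fileformat=VCFv4.2",
             '##INFO=<ID=PATIENT,Number=1,Type=String,Description="Patient id">',
             '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
             '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">']
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    indexed = obs.set_index(key + ["sample"]).sort_index()
    sites = obs[key + ["patient"]].drop_duplicates(subset=key)
    sites = sites.sort_values(key, kind="stable")
    for _, site in sites.iterrows():
        k = (site["chrom"], site["pos"], site["ref"], site["alt"])
        cols = []
        for s in samples:
            try:
                row = indexed.loc[k + (s,)]
            except KeyError:
                cols.append(".:.")
                continue
            ad = f"{int(row['ref_depth'])},{int(row['alt_depth'])}"
            dp = int(row["ref_depth"]) + int(row["alt_depth"])
            cols.append(f"{ad}:{dp}")
        lines.append("\t".join([
            str(site["chrom"]), str(site["pos"]), ".", str(site["ref"]),
            str(site["alt"]), ".", ".", f"PATIENT={site['patient']}", "AD:DP",
        ] + cols))
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = set(ANN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    df["dbsnp_common"] = df["dbsnp_common"].astype(bool)
    return df[ANN_COLUMNS]


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations[ANN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> tuple[pd.DataFrame, pd.Series | None]:
    """Read an expression TSV (genes x samples; optional ``length`` column).

    Returns ``(matrix, gene_lengths)``; lengths are ``None`` when the file
    has no length column (e.g. an already-normalised FPKM table).
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    lengths = None
    if "length" in df.columns:
        lengths = df.pop("length")
    return df, lengths


def write_expression(
    matrix: pd.DataFrame, path: str | Path, *, gene_lengths: pd.Series | None = None
) -> None:
    out = matrix.copy()
    out.index.name = "gene"
    if gene_lengths is not None:
        out.insert(0, "length", gene_lengths.reindex(out.index))
    out.to_csv(path, sep="\t")


def read_signature(path: str | Path, name: str | None = None,
                   expected_size: int | None = None):
    """Read a one-gene-per-line signature file."""
    from .exprscore import GeneSignature

    path = Path(path)
    genes = [
        ln.strip() for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    return GeneSignature(name or path.stem, tuple(genes), expected_size)


def write_signature(signature, path: str | Path) -> None:
    Path(path).write_text("\n".join(signature.genes) + "\n")


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
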