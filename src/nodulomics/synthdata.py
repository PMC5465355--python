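"""Synthetic multi-lesion cohorts with known clonal architecture.

Generates patients that mirror the sampling design the pipeline targets: a
blood sample (germline reference), a normal thyroid sample, and one or more
benign-nodule and carcinoma samples per patient, whole-exome sequenced at
~160x.  Each lesion carries private somatic mutations (Poisson counts) and,
optionally, a trunk of mutations shared with a designated partner lesion —
the dial between shared and independent clonal origin.  Read counts follow
the standard diploid sampling model: at a truth site in lesion L, alternate
reads ~ Binomial(depth, purity_L x CCF / 2); elsewhere alternate reads arise
only through a per-read error process.  Sequencing depth is drawn around the
mean with configurable overdispersion.

Ground truth (the clonal architecture) is stored separately from the
observable tables so no downstream stage can consume it by accident; it is
the reference for parameter-recovery checks.

Expression data are generated per cohort: log-normal baseline gene means,
negative-binomial counts, and planted lesion-type effects on signature
genes — tumour samples are shifted down on the thyroid-differentiation
(TDS-like) set and up on the ERK-activity set, the structure the score
functions are expected to recover.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exprscore import GeneSignature

__all__ = [
    "SimConfig",
    "ClonalArchitecture",
    "SimulatedPatient",
    "make_signatures",
    "simulate_patient",
    "simulate_expression",
    "simulate_cohort",
    "write_fixture_set",
    "tissue_of",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults emulate the targeted study design: 20 patients, each with
    blood + normal thyroid + one benign nodule + one carcinoma, ~160x mean
    exome depth, ~10 private somatic mutations per lesion (0.33 per Mb over
    a 30 Mb exome) and ~3.6 in normal tissue (0.12 per Mb), high lesion
    purity, clonal mutations (CCF 1).  ``trunk_mutations`` plants a shared
    trunk between the first benign and first tumour sample; 0 means fully
    independent origins.
    """

    n_patients: int = 20
    n_benign: int = 1
    n_tumour: int = 1
    include_normal: bool = True
    include_blood: bool = True
    trunk_mutations: int = 0
    trunk_coding: bool = True
    private_mutation_rate: float = 10.0
    normal_mutation_rate: float = 3.6
    mean_depth: float = 160.0
    #: variance-to-mean ratio of the per-site depth distribution; 1 gives
    #: Poisson depths (sd ~ 12.6 at 160x, central range ~135-185x); 0 fixes
    #: every depth at ``mean_depth`` exactly; >1 overdisperses.
    depth_dispersion: float = 1.0
    purity: float = 0.8
    ccf: float = 1.0
    #: per-read error probability; a free parameter of the generator, not an
    #: estimate from any real dataset.
    germline_error_rate: float = 1e-3
    #: error-only sites with no truth mutation anywhere (sequencing noise).
    n_noise_sites: int = 25
    #: inherited heterozygous sites (VAF ~ 0.5 in every sample incl. blood);
    #: exercises the germline-removal rules.
    n_germline_het_sites: int = 5
    # expression block
    n_genes: int = 2000
    tds_log2_effect: float = 1.5
    erk_log2_effect: float = 1.5
    #: BRAF-like expression character planted on the 71-gene signature in
    #: tumour samples: a fixed mixed up/down pattern of this magnitude, so
    #: correlation-based signature clustering has signal (a uniform shift
    #: would be invisible to 1 - Pearson distances).
    braf_ras_log2_effect: float = 1.0
    #: negative-binomial dispersion d, var = mu + d * mu^2; 0 = noise-free.
    expr_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.include_blood:
            raise ValueError("a blood germline reference is mandatory")
        for name in ("trunk_mutations", "private_mutation_rate",
                     "normal_mutation_rate", "germline_error_rate",
                     "n_noise_sites", "n_germline_het_sites",
                     "depth_dispersion", "expr_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.purity <= 1):
            raise ValueError("purity must be in (0, 1]")
        if not (0 < self.ccf <= 1):
            raise ValueError("ccf must be in (0, 1]")
        if self.n_benign + self.n_tumour < 1:
            raise ValueError("need at least one lesion sample")
        if self.trunk_mutations > 0 and (self.n_benign < 1 or self.n_tumour < 1):
            raise ValueError("a trunk needs both a benign and a tumour sample")

    def sample_names(self, patient_index: int) -> list[str]:
        pid = f"P{patient_index:02d}"
        names = [f"{pid}_blood"]
        if self.include_normal:
            names.append(f"{pid}_normal")
        names += [f"{pid}_benign{i + 1}" for i in range(self.n_benign)]
        names += [f"{pid}_tumour{i + 1}" for i in range(self.n_tumour)]
        return names


def tissue_of(sample: str) -> str:
    """Tissue type encoded in a simulated sample name (suffix after '_')."""
    suffix = sample.rsplit("_", 1)[-1]
    for t in ("blood", "normal", "benign", "tumour"):
        if suffix.startswith(t):
            return t
    raise ValueError(f"cannot infer tissue type from sample name {sample!r}")


@dataclass
class ClonalArchitecture:
    """Ground-truth mutation partition of one simulated patient."""

    patient: str
    #: lesion sample -> {"trunk": [...], "private": [...]} of variant keys
    lesions: dict[str, dict[str, list[str]]]
    #: variant key -> attributes (gene, region, func, flank5, flank3, ccf)
    mutations: dict[str, dict]
    #: Poisson draws actually used for the private counts, recorded exactly
    private_draws: dict[str, int] = field(default_factory=dict)

    def mutation_set(self, lesion: str) -> set[str]:
        part = self.lesions[lesion]
        return set(part["trunk"]) | set(part["private"])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulatedPatient:
    patient: str
    samples: list[str]
    blood_sample: str
    observations: pd.DataFrame
    annotations: pd.DataFrame
    truth: ClonalArchitecture
    expression: pd.DataFrame          # genes x samples counts (tissue samples)
    gene_lengths: pd.Series


def _variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


def _draw_depth(rng: np.random.Generator, config: SimConfig, size: int) -> np.ndarray:
    mu, phi = config.mean_depth, config.depth_dispersion
    if phi == 0.0:
        d = np.full(size, int(round(mu)))
    elif phi <= 1.0:
        d = rng.poisson(mu, size=size)
    else:
        r = mu / (phi - 1.0)
        d = rng.negative_binomial(r, 1.0 / phi, size=size)
    return np.maximum(d, 1)


def _new_site(rng, used_pos: set, *, region: str, func: str, gene: str) -> dict:
    while True:
        chrom = str(rng.integers(1, 23))
        pos = int(rng.integers(1_000_000, 50_000_000))
        if (chrom, pos) not in used_pos:
            used_pos.add((chrom, pos))
            break
    ref = str(rng.choice(_BASES))
    alt = str(rng.choice([b for b in _BASES if b != ref]))
    return {
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "flank5": str(rng.choice(_BASES)), "flank3": str(rng.choice(_BASES)),
        "gene": gene, "region": region, "func": func,
    }


_EXONIC_FUNCS = np.array(["missense", "synonymous", "stopgain", "frameshift"])
_EXONIC_PROBS = np.array([0.65, 0.20, 0.10, 0.05])


def simulate_patient(config: SimConfig, patient_index: int) -> SimulatedPatient:
    """Simulate one patient's observation, annotation and expression tables.

    Deterministic for a given (config, patient_index): identical inputs give
    byte-identical tables.
    """
    if not 0 <= patient_index < config.n_patients:
        raise ValueError("patient_index out of range")
    rng = np.random.default_rng([config.seed % (2**31), 11, patient_index])
    samples = config.sample_names(patient_index)
    pid = f"P{patient_index:02d}"
    blood = f"{pid}_blood"
    lesion_samples = [s for s in samples if tissue_of(s) in ("benign", "tumour")]
    normal_samples = [s for s in samples if tissue_of(s) == "normal"]

    used_pos: set = set()
    mutations: dict[str, dict] = {}
    lesions: dict[str, dict[str, list[str]]] = {
        s: {"trunk": [], "private": []} for s in lesion_samples + normal_samples
    }
    private_draws: dict[str, int] = {}

    # trunk between the designated pair: first benign and first tumour
    trunk_keys: list[str] = []
    if config.trunk_mutations > 0:
        pair = (f"{pid}_benign1", f"{pid}_tumour1")
        region = "exonic" if config.trunk_coding else "UTR3"
        for _ in range(config.trunk_mutations):
            func = (str(rng.choice(_EXONIC_FUNCS, p=_EXONIC_PROBS))
                    if config.trunk_coding else ".")
            site = _new_site(rng, used_pos, region=region, func=func,
                             gene=f"G{int(rng.integers(0, 500)):04d}")
            key = _variant_key(site["chrom"], site["pos"], site["ref"], site["alt"])
            mutations[key] = {**site, "ccf": config.ccf}
            trunk_keys.append(key)
        for s in pair:
            lesions[s]["trunk"] = list(trunk_keys)

    for s in lesion_samples + normal_samples:
        rate = (config.normal_mutation_rate if tissue_of(s) == "normal"
                else config.private_mutation_rate)
        n_private = int(rng.poisson(rate))
        private_draws[s] = n_private
        for _ in range(n_private):
            site = _new_site(
                rng, used_pos, region="exonic",
                func=str(rng.choice(_EXONIC_FUNCS, p=_EXONIC_PROBS)),
                gene=f"G{int(rng.integers(0, 500)):04d}",
            )
            key = _variant_key(site["chrom"], site["pos"], site["ref"], site["alt"])
            mutations[key] = {**site, "ccf": config.ccf}
            lesions[s]["private"].append(key)

    truth = ClonalArchitecture(pid, lesions, mutations, private_draws)

    # non-truth sites: pure-noise and inherited-heterozygous
    noise_sites, het_sites = [], []
    for _ in range(config.n_noise_sites):
        region = str(rng.choice(["exonic", "intronic", "intergenic"], p=[0.4, 0.4, 0.2]))
        site = _new_site(rng, used_pos, region=region,
                         func="synonymous" if region == "exonic" else ".",
                         gene=f"G{int(rng.integers(0, 500)):04d}")
        site["dbsnp_common"] = bool(rng.random() < 0.3)
        noise_sites.append(site)
    for _ in range(config.n_germline_het_sites):
        site = _new_site(rng, used_pos, region="exonic", func="synonymous",
                         gene=f"G{int(rng.integers(0, 500)):04d}")
        site["dbsnp_common"] = True
        site["kg_maf"] = float(np.round(rng.uniform(0.1, 0.5), 3))
        het_sites.append(site)

    site_records: list[dict] = []
    for key, mut in mutations.items():
        carriers = {s for s in lesions if key in truth.mutation_set(s)}
        site_records.append({**mut, "kind": "truth", "carriers": carriers})
    for site in noise_sites:
        site_records.append({**site, "kind": "noise", "carriers": set()})
    for site in het_sites:
        site_records.append({**site, "kind": "het", "carriers": set()})

    obs_rows, ann_rows = [], []
    for rec in site_records:
        ann_rows.append({
            "chrom": rec["chrom"], "pos": rec["pos"], "ref": rec["ref"],
            "alt": rec["alt"], "gene": rec["gene"], "region": rec["region"],
            "func": rec["func"], "dbsnp_common": rec.get("dbsnp_common", False),
            "kg_maf": rec.get("kg_maf", 0.0), "exac_maf": rec.get("exac_maf", 0.0),
            "flank5": rec["flank5"], "flank3": rec["flank3"],
        })
        depths = _draw_depth(rng, config, len(samples))
        for s, depth in zip(samples, depths):
            if rec["kind"] == "het":
                p_alt = 0.5
            elif s in rec["carriers"]:
                pur = 1.0 if tissue_of(s) == "normal" else config.purity
                p_alt = pur * rec["ccf"] / 2.0
            else:
                p_alt = config.germline_error_rate
            alt_reads = int(rng.binomial(depth, p_alt))
            obs_rows.append({
                "patient": pid, "chrom": rec["chrom"], "pos": rec["pos"],
                "ref": rec["ref"], "alt": rec["alt"], "sample": s,
                "ref_depth": int(depth) - alt_reads, "alt_depth": alt_reads,
            })

    key_cols = ["chrom", "pos", "ref", "alt"]
    observations = (
        pd.DataFrame(obs_rows, columns=["patient"] + key_cols + ["sample", "ref_depth", "alt_depth"])
        .sort_values(key_cols + ["sample"], kind="stable").reset_index(drop=True)
    )
    ann_columns = key_cols + ["gene", "region", "func", "dbsnp_common",
                              "kg_maf", "exac_maf", "flank5", "flank3"]
    annotations = (
        pd.DataFrame(ann_rows, columns=ann_columns)
        .sort_values(key_cols, kind="stable").reset_index(drop=True)
    )

    signatures = make_signatures(config)
    tissue_samples = [s for s in samples if s != blood]
    expression, gene_lengths = simulate_expression(
        config, list(signatures.values()),
        {s: tissue_of(s) for s in tissue_samples},
        patient_index=patient_index,
    )
    return SimulatedPatient(
        patient=pid, samples=samples, blood_sample=blood,
        observations=observations, annotations=annotations, truth=truth,
        expression=expression, gene_lengths=gene_lengths,
    )


def make_signatures(config: SimConfig) -> dict[str, GeneSignature]:
    """Synthetic stand-ins for the three published signature gene sets.

    Sizes follow the published sets (16 thyroid-differentiation genes, 52
    ERK-responsive genes, 71 BRAF–RAS character genes); membership is the
    first genes of the synthetic namespace, mutually disjoint so planted up-
    and down-shifts never collide on one gene.
    """
    if config.n_genes < 16 + 52 + 71:
        raise ValueError("n_genes too small to host the three signatures")
    names = [f"EXPR{i:05d}" for i in range(config.n_genes)]
    return {
        "tds": GeneSignature("tds", tuple(names[:16]), 16),
        "erk": GeneSignature("erk", tuple(names[16:68]), 52),
        "braf_ras": GeneSignature("braf_ras", tuple(names[68:139]), 71),
    }


def simulate_expression(
    config: SimConfig,
    signatures: Sequence[GeneSignature],
    sample_tissues: Mapping[str, str],
    *,
    patient_index: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Signature-structured count matrix for one patient's tissue samples.

    Baseline per-gene means are log-normal and shared across the cohort
    (drawn from the config seed alone); tumour samples get a ``2**-effect``
    shift on the TDS-like genes and ``2**+effect`` on the ERK-like genes.
    Counts are negative-binomial around the shifted means
    (var = mu + d*mu^2); dispersion 0 is the noise-free limit where counts
    equal their means exactly.  Gene lengths accompany the matrix for FPKM
    normalisation.  A gene listed in both a down- and an up-shifted
    signature would receive contradictory effects and is rejected.

    Returns ``(counts, gene_lengths)``.
    """
    sig_by_name = {s.name: s for s in signatures}
    tds = sig_by_name.get("tds")
    erk = sig_by_name.get("erk")
    braf = sig_by_name.get("braf_ras")
    if tds is None or erk is None:
        raise ValueError("signatures must include 'tds' and 'erk' gene lists")
    up_genes = set(erk.genes if config.erk_log2_effect else ())
    if braf is not None and config.braf_ras_log2_effect:
        up_genes |= set(braf.genes)
    if config.tds_log2_effect and set(tds.genes) & up_genes:
        raise ValueError("a gene cannot carry both a down (TDS) and up planted effect")

    base_rng = np.random.default_rng([config.seed % (2**31), 23])
    genes = [f"EXPR{i:05d}" for i in range(config.n_genes)]
    base_mean = np.exp(base_rng.normal(np.log(80.0), 1.0, size=config.n_genes))
    lengths = base_rng.integers(500, 5001, size=config.n_genes)
    braf_sign = base_rng.choice([-1.0, 1.0], size=config.n_genes)
    gene_lengths = pd.Series(lengths, index=genes, name="length")

    rng = np.random.default_rng([config.seed % (2**31), 29, patient_index])
    tds_idx = [genes.index(g) for g in tds.genes]
    erk_idx = [genes.index(g) for g in erk.genes]
    braf_idx = [genes.index(g) for g in braf.genes] if braf is not None else []
    cols = {}
    for sample in sample_tissues:
        mu = base_mean.copy()
        if sample_tissues[sample] == "tumour":
            mu[tds_idx] *= 2.0 ** (-config.tds_log2_effect)
            mu[erk_idx] *= 2.0 ** (config.erk_log2_effect)
            mu[braf_idx] *= 2.0 ** (config.braf_ras_log2_effect * braf_sign[braf_idx])
        d = config.expr_dispersion
        if d == 0:
            counts = mu
        else:
            # NB via gamma-Poisson: shape 1/d, scale mu*d
            lam = rng.gamma(1.0 / d, mu * d)
            counts = rng.poisson(lam).astype(float)
        cols[sample] = counts
    counts_df = pd.DataFrame(cols, index=genes)
    return counts_df, gene_lengths


def simulate_cohort(config: SimConfig) -> list[SimulatedPatient]:
    """All patients of the configured cohort."""
    return [simulate_patient(config, i) for i in range(config.n_patients)]


def write_fixture_set(patient: SimulatedPatient, directory: str | Path) -> dict[str, Path]:
    """Write one patient's fixture files; returns the 4-file manifest.

    Emits the VCF-style observation file, the annotation TSV, the expression
    TSV (counts with gene lengths) and the ground-truth JSON.  Everything
    round-trips losslessly through the package's readers.
    """
    from . import io as nio  # local import to avoid a cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pid = patient.patient
    manifest = {
        "observations": directory / f"{pid}.observations.vcf",
        "annotations": directory / f"{pid}.annotations.tsv",
        "expression": directory / f"{pid}.expression.tsv",
        "truth": directory / f"{pid}.truth.json",
    }
    nio.write_observations_vcf(patient.observations, manifest["observations"],
                               samples=patient.samples)
    nio.write_annotations(patient.annotations, manifest["annotations"])
    nio.write_expression(patient.expression, manifest["expression"],
                         gene_lengths=patient.gene_lengths)
    with open(manifest["truth"], "w") as fh:
        json.dump(patient.truth.to_dict(), fh, indent=1, sort_keys=True)
    return manifest
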