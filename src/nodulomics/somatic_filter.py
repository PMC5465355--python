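"""Somatic-mutation filtering against a single blood germline reference.

Each patient contributes one blood sample (the germline reference) and one or
more tissue samples (normal thyroid, benign nodule, carcinoma).  Candidate
sites are evaluated jointly: every (site, sample) pair is tested against the
same blood observation, so a variant may be called somatic in one lesion and
absent in another — the comparison that downstream overlap and phylogeny
analyses rely on.

Filtering rules (all must hold for a call):

* tissue depth and blood depth both >= ``min_depth_both`` (default 10x);
* tissue VAF >= ``min_vaf`` (10%), relaxed to ``relaxed_vaf`` (5%) when the
  tissue depth exceeds ``relaxed_depth_threshold`` (50x);
* at least ``min_alt_reads`` (3) supporting reads in the tissue;
* at most ``max_blood_alt_reads`` (2) supporting reads in the blood;
* a Pearson chi-squared test on the 2x2 (case/germline x ref/alt) allele-depth
  table rejects at ``chi2_alpha``, separating somatic events from shared
  germline signal;
* the variant is not a common polymorphism (dbSNP-common flag, 1000 Genomes
  MAF > 5%, ExAC MAF > 1%) and does not fall in an excluded region class
  (intergenic or intronic by default).

Every rule's outcome is recorded in a filter trace so each printed call is
auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterConfig",
    "VariantAnnotation",
    "UndefinedVAFError",
    "compute_vaf",
    "chi_square_case_germline",
    "apply_site_filters",
    "call_somatic_multi_sample",
    "passing_calls",
]


class UndefinedVAFError(ValueError):
    """Raised when a VAF is requested at a site with zero total depth."""


def compute_vaf(alt_depth: int, ref_depth: int) -> float:
    """Variant allele fraction ``alt / (alt + ref)``.

    Raises
    ------
    UndefinedVAFError
        If ``alt_depth + ref_depth == 0``.
    """
    total = alt_depth + ref_depth
    if total <= 0:
        raise UndefinedVAFError(
            f"VAF undefined at zero total depth (alt={alt_depth}, ref={ref_depth})"
        )
    if alt_depth < 0 or ref_depth < 0:
        raise ValueError("read depths must be non-negative")
    return alt_depth / total


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    degenerate: bool = False


def chi_square_case_germline(
    case: tuple[int, int],
    germline: tuple[int, int],
    *,
    correction: bool = False,
) -> Chi2Result:
    """Pearson chi-squared test on the 2x2 case/germline allele-depth table.

    Rows are (case, germline), columns are (ref, alt) read counts; 1 degree
    of freedom.  A column whose total is zero carries no evidence of an
    allele-frequency difference: the result is statistic 0, p 1, flagged
    ``degenerate``.

    Parameters
    ----------
    case, germline :
        ``(ref_depth, alt_depth)`` pairs.
    correction :
        Apply the Yates continuity correction (off by default).
    """
    a, b = case
    c, d = germline
    if min(a, b, c, d) < 0:
        raise ValueError("read depths must be non-negative")
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if r1 == 0 or r2 == 0:
        raise ValueError("both case and germline must have positive total depth")
    if c1 == 0 or c2 == 0:
        return Chi2Result(0.0, 1.0, degenerate=True)
    delta = abs(a * d - b * c)
    if correction:
        delta = max(delta - n / 2.0, 0.0)
    statistic = n * delta * delta / (r1 * r2 * c1 * c2)
    p_value = float(stats.chi2.sf(statistic, df=1))
    return Chi2Result(float(statistic), p_value)


@dataclass(frozen=True)
class VariantAnnotation:
    """Functional annotation attached to one (chrom, pos, ref, alt) variant.

    ``dbsnp_common``, ``kg_maf`` (1000 Genomes MAF) and ``exac_maf`` may be
    ``None`` when the annotation source had no entry; how missing fields are
    treated is governed by ``FilterConfig.missing_annotation``.
    """

    gene: str = "."
    region: str | None = None
    func: str | None = None
    dbsnp_common: bool | None = None
    kg_maf: float | None = None
    exac_maf: float | None = None
    flank5: str | None = None
    flank3: str | None = None


@dataclass(frozen=True)
class FilterConfig:
    min_depth_both: int = 10
    min_vaf: float = 0.10
    relaxed_vaf: float = 0.05
    relaxed_depth_threshold: int = 50
    min_alt_reads: int = 3
    max_blood_alt_reads: int = 2
    chi2_alpha: float = 0.05
    chi2_correction: bool = False
    thousand_genomes_max_maf: float = 0.05
    exac_max_maf: float = 0.01
    excluded_regions: frozenset[str] = frozenset({"intergenic", "intronic"})
    #: "lenient": a rule whose annotation field is missing is skipped (and the
    #: skip recorded); "strict": a missing field rejects the site.
    missing_annotation: str = "lenient"

    def __post_init__(self) -> None:
        if not (0 < self.relaxed_vaf <= self.min_vaf):
            raise ValueError("need 0 < relaxed_vaf <= min_vaf")
        if self.missing_annotation not in ("lenient", "strict"):
            raise ValueError("missing_annotation must be 'lenient' or 'strict'")
        for name in ("min_depth_both", "min_alt_reads", "max_blood_alt_reads",
                     "relaxed_depth_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _trace(rule: str, outcome: str) -> str:
    return f"{rule}:{outcome}"


def apply_site_filters(
    tissue_ref: int,
    tissue_alt: int,
    blood_ref: int,
    blood_alt: int,
    annotation: VariantAnnotation | None,
    config: FilterConfig = FilterConfig(),
) -> tuple[bool, list[str]]:
    """Evaluate every filtering rule for one (site, sample) observation.

    Returns ``(passed, trace)`` where ``trace`` lists each rule as
    ``"rule:PASS"``, ``"rule:FAIL"`` or ``"rule:SKIP"`` (annotation field
    missing under the lenient policy).  The trace always contains every rule,
    in a fixed order, regardless of where the site fails.
    """
    if annotation is None:
        annotation = VariantAnnotation()
    trace: list[str] = []
    ok = True

    def record(rule: str, passed: bool | None) -> None:
        nonlocal ok
        if passed is None:
            strict = config.missing_annotation == "strict"
            trace.append(_trace(rule, "FAIL(missing)" if strict else "SKIP"))
            if strict:
                ok = False
        else:
            trace.append(_trace(rule, "PASS" if passed else "FAIL"))
            if not passed:
                ok = False

    tissue_depth = tissue_ref + tissue_alt
    blood_depth = blood_ref + blood_alt

    record("tissue_depth", tissue_depth >= config.min_depth_both)
    record("blood_depth", blood_depth >= config.min_depth_both)

    if tissue_depth > 0:
        vaf = tissue_alt / tissue_depth
        threshold = (
            config.relaxed_vaf
            if tissue_depth > config.relaxed_depth_threshold
            else config.min_vaf
        )
        record("vaf", vaf >= threshold)
    else:
        record("vaf", False)

    record("alt_reads", tissue_alt >= config.min_alt_reads)
    record("blood_alt_reads", blood_alt <= config.max_blood_alt_reads)

    if tissue_depth > 0 and blood_depth > 0:
        chi2 = chi_square_case_germline(
            (tissue_ref, tissue_alt),
            (blood_ref, blood_alt),
            correction=config.chi2_correction,
        )
        record("chi2", chi2.p_value < config.chi2_alpha)
    else:
        record("chi2", False)

    record(
        "dbsnp",
        None if annotation.dbsnp_common is None else not annotation.dbsnp_common,
    )
    record(
        "thousand_genomes",
        None if annotation.kg_maf is None or (isinstance(annotation.kg_maf, float) and math.isnan(annotation.kg_maf))
        else annotation.kg_maf <= config.thousand_genomes_max_maf,
    )
    record(
        "exac",
        None if annotation.exac_maf is None or (isinstance(annotation.exac_maf, float) and math.isnan(annotation.exac_maf))
        else annotation.exac_maf <= config.exac_max_maf,
    )
    record(
        "region",
        None if annotation.region is None
        else annotation.region not in config.excluded_regions,
    )
    return ok, trace


VARIANT_KEY = ["chrom", "pos", "ref", "alt"]

_ANN_COLS = {
    "gene": "gene", "region": "region", "func": "func",
    "dbsnp_common": "dbsnp_common", "kg_maf": "kg_maf", "exac_maf": "exac_maf",
    "flank5": "flank5", "flank3": "flank3",
}


def _annotation_from_row(row: Mapping | None) -> VariantAnnotation:
    if row is None:
        return VariantAnnotation()
    kw = {}
    for col, fld in _ANN_COLS.items():
        val = row.get(col)
        if isinstance(val, float) and math.isnan(val):
            val = None
        if col == "dbsnp_common" and val is not None:
            val = bool(val)
        kw[fld] = val
    return VariantAnnotation(**kw)


def call_somatic_multi_sample(
    observations: pd.DataFrame,
    annotations: pd.DataFrame | None,
    config: FilterConfig = FilterConfig(),
    *,
    blood_sample: str,
) -> pd.DataFrame:
    """Apply the site filters per (site, sample) for one patient.

    The single-normal–multi-tumour strategy: every tissue sample of the
    patient is filtered against the one shared blood observation, so a site
    may be called in one lesion and rejected in another.

    Parameters
    ----------
    observations :
        Long table with columns ``chrom, pos, ref, alt, sample, ref_depth,
        alt_depth`` for one patient (a ``patient`` column is carried through
        if present).  The blood sample must appear exactly once per site.
    annotations :
        Table keyed by ``chrom, pos, ref, alt`` with the columns of
        :class:`VariantAnnotation`; ``None`` means unannotated.
    blood_sample :
        Sample id of the germline reference.

    Returns
    -------
    DataFrame with one row per (site, tissue sample), columns including
    ``vaf`` (NaN at zero depth), ``filter_pass`` and the semicolon-joined
    ``filter_trace``.
    """
    required = set(VARIANT_KEY + ["sample", "ref_depth", "alt_depth"])
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    samples = observations["sample"].unique()
    if blood_sample not in samples:
        raise ValueError(
            f"blood sample {blood_sample!r} absent: a germline reference is mandatory"
        )
    if observations.empty:
        return observations.assign(vaf=[], filter_pass=[], filter_trace=[])

    ann_lookup: dict[tuple, Mapping] = {}
    if annotations is not None and not annotations.empty:
        for _, row in annotations.iterrows():
            ann_lookup[tuple(row[k] for k in VARIANT_KEY)] = row

    blood = (
        observations[observations["sample"] == blood_sample]
        .set_index(VARIANT_KEY)[["ref_depth", "alt_depth"]]
    )
    if blood.index.has_duplicates:
        raise ValueError("blood sample appears more than once at a site")

    tissue = observations[observations["sample"] != blood_sample]
    if tissue.empty:
        raise ValueError("need at least one non-blood sample")

    rows = []
    for _, row in tissue.iterrows():
        key = tuple(row[k] for k in VARIANT_KEY)
        try:
            b = blood.loc[key]
        except KeyError as exc:
            raise ValueError(f"no blood observation at site {key}") from exc
        ann_row = ann_lookup.get(key)
        annotation = _annotation_from_row(ann_row)
        passed, trace = apply_site_filters(
            int(row["ref_depth"]), int(row["alt_depth"]),
            int(b["ref_depth"]), int(b["alt_depth"]),
            annotation, config,
        )
        total = row["ref_depth"] + row["alt_depth"]
        out = dict(row)
        out["vaf"] = row["alt_depth"] / total if total > 0 else np.nan
        out["blood_ref_depth"] = int(b["ref_depth"])
        out["blood_alt_depth"] = int(b["alt_depth"])
        for col in _ANN_COLS:
            out[col] = getattr(annotation, _ANN_COLS[col])
        out["filter_pass"] = passed
        out["filter_trace"] = ";".join(trace)
        rows.append(out)
    result = pd.DataFrame(rows)
    return result.sort_values(["sample"] + VARIANT_KEY, kind="stable").reset_index(drop=True)


def passing_calls(calls: pd.DataFrame, sample: str | None = None) -> pd.DataFrame:
    """Subset of ``call_somatic_multi_sample`` output that passed all filters."""
    out = calls[calls["filter_pass"]]
    if sample is not None:
        out = out[out["sample"] == sample]
    return out.reset_index(drop=True)
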