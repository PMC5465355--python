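"""Mutation-level summary statistics.

Covers the descriptive layer of a multi-lesion cohort analysis: exome-wide
mutation density, the six-class / 96-trinucleotide-context substitution
spectrum (pyrimidine-reference convention), pairwise mutation overlap between
lesions of one patient, cohort-level per-gene mutation frequencies, and
mutual exclusivity of a gene set with an optional permutation test.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SUBSTITUTION_CLASSES",
    "CONTEXTS_96",
    "SpectrumTable",
    "OverlapResult",
    "MutualExclusivityResult",
    "mutation_density",
    "substitution_spectrum",
    "pairwise_overlap",
    "merge_foci",
    "cohort_frequency",
    "mutual_exclusivity",
    "variant_keys",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYRIMIDINES = {"C", "T"}
_BASES = ("A", "C", "G", "T")

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 trinucleotide contexts, keys like ``A[C>T]G``, in the conventional
#: order (classes as above, flanks lexicographic).
CONTEXTS_96 = tuple(
    f"{f5}[{cls}]{f3}"
    for cls in SUBSTITUTION_CLASSES
    for f5 in _BASES
    for f3 in _BASES
)


def mutation_density(n_mutations: float, exome_mb: float = 30.0) -> float:
    """Mutations per megabase under a fixed exome-size convention.

    The default assumes a 30 Mb protein-coding exome, so e.g. an average of
    11.4 mutations per sample corresponds to 0.38 mutations per Mb.
    """
    if n_mutations < 0:
        raise ValueError("mutation count must be >= 0")
    if exome_mb <= 0:
        raise ValueError("exome size must be positive")
    return n_mutations / exome_mb


def _pyrimidine_context(ref: str, alt: str, flank5: str, flank3: str):
    """Map an SNV to (class, context) in the pyrimidine-reference convention.

    Purine-reference substitutions are reverse-complemented, which also swaps
    and complements the flanking bases, so every class has a C or T reference.
    """
    if ref not in _PYRIMIDINES:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        flank5, flank3 = _COMPLEMENT[flank3], _COMPLEMENT[flank5]
    cls = f"{ref}>{alt}"
    return cls, f"{flank5}[{cls}]{flank3}"


@dataclass
class SpectrumTable:
    """Counts over the 6 substitution classes and 96 trinucleotide contexts."""

    class_counts: pd.Series
    context_counts: pd.Series
    n_snv: int
    n_skipped_indel: int = 0
    n_missing_flank: int = 0

    @property
    def class_frequencies(self) -> pd.Series:
        total = self.class_counts.sum()
        return self.class_counts / total if total > 0 else self.class_counts * 0.0

    @property
    def context_frequencies(self) -> pd.Series:
        total = self.context_counts.sum()
        return self.context_counts / total if total > 0 else self.context_counts * 0.0


def substitution_spectrum(calls: pd.DataFrame) -> SpectrumTable:
    """Six-class and 96-context substitution spectrum of a call set.

    Parameters
    ----------
    calls :
        Table with ``ref``, ``alt``, ``flank5``, ``flank3`` columns.  Indels
        (ref or alt not a single base) are skipped and counted; SNVs with a
        missing flanking base are excluded from the context table (and from
        the class table, to keep both totals equal) and counted.
    """
    class_counts = pd.Series(0, index=list(SUBSTITUTION_CLASSES), dtype=int)
    context_counts = pd.Series(0, index=list(CONTEXTS_96), dtype=int)
    n_snv = n_indel = n_missing = 0
    for row in calls.itertuples(index=False):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            n_indel += 1
            continue
        n_snv += 1
        f5 = getattr(row, "flank5", None)
        f3 = getattr(row, "flank3", None)
        f5 = None if f5 is None or (isinstance(f5, float) and math.isnan(f5)) else str(f5).upper()
        f3 = None if f3 is None or (isinstance(f3, float) and math.isnan(f3)) else str(f3).upper()
        if f5 not in _BASES or f3 not in _BASES:
            n_missing += 1
            continue
        cls, ctx = _pyrimidine_context(ref, alt, f5, f3)
        class_counts[cls] += 1
        context_counts[ctx] += 1
    if n_indel:
        warnings.warn(f"skipped {n_indel} non-SNV record(s) in spectrum", stacklevel=2)
    return SpectrumTable(class_counts, context_counts, n_snv, n_indel, n_missing)


def variant_keys(calls: pd.DataFrame | Iterable[Hashable]) -> set:
    """Set of (chrom, pos, ref, alt) identities from a call table (or pass through a set)."""
    if isinstance(calls, pd.DataFrame):
        return set(zip(calls["chrom"], calls["pos"], calls["ref"], calls["alt"]))
    return set(calls)


@dataclass
class OverlapResult:
    sample_a: str
    sample_b: str
    n_a: int
    n_b: int
    n_shared: int
    overlap_ratio: float
    convention: str
    n_shared_with_normal: int | None = None
    shared: set = field(default_factory=set)
    shared_with_normal: set = field(default_factory=set)
    degenerate: bool = False


def pairwise_overlap(
    calls_a,
    calls_b,
    calls_normal=None,
    *,
    convention: str = "jaccard",
    sample_a: str = "A",
    sample_b: str = "B",
) -> OverlapResult:
    """Mutation-set overlap between two lesions of one patient.

    ``convention="jaccard"`` (default) uses |shared| / |union|; ``"min"``
    uses |shared| / min(|a|, |b|).  The convention is recorded in the result
    so every printed ratio is attributable.  When a matched-normal call set
    is supplied, the subset of shared mutations also present in the normal is
    reported separately.  Two empty sets give ratio 0, flagged degenerate.
    """
    a, b = variant_keys(calls_a), variant_keys(calls_b)
    shared = a & b
    union = a | b
    if convention == "jaccard":
        ratio = len(shared) / len(union) if union else 0.0
    elif convention == "min":
        denom = min(len(a), len(b))
        ratio = len(shared) / denom if denom else 0.0
    else:
        raise ValueError(f"unknown overlap convention {convention!r}")
    shared_normal = None
    shared_normal_set: set = set()
    if calls_normal is not None:
        shared_normal_set = shared & variant_keys(calls_normal)
        shared_normal = len(shared_normal_set)
    return OverlapResult(
        sample_a, sample_b, len(a), len(b), len(shared), ratio, convention,
        n_shared_with_normal=shared_normal,
        shared=shared, shared_with_normal=shared_normal_set,
        degenerate=not union,
    )


def merge_foci(area_calls: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Combine calls from multiple sampled areas of a single focus.

    The merged set is the union keyed by variant identity; ``vaf`` is the
    maximum across areas, with per-area values retained in ``area_vafs`` as
    ``sample=vaf`` pairs.
    """
    if not area_calls:
        raise ValueError("need at least one area")
    key = ["chrom", "pos", "ref", "alt"]
    stacked = pd.concat(area_calls, ignore_index=True)
    rows = []
    for k, grp in stacked.groupby(key, sort=True):
        best = grp.loc[grp["vaf"].idxmax()].copy()
        best["area_vafs"] = ";".join(
            f"{s}={v:.4g}" for s, v in zip(grp["sample"], grp["vaf"])
        )
        best["vaf"] = grp["vaf"].max()
        rows.append(best)
    return pd.DataFrame(rows).reset_index(drop=True)


def cohort_frequency(table: pd.DataFrame, gene: str) -> float:
    """Percentage of patients carrying a mutation in ``gene``.

    ``table`` is a patients x genes boolean indicator.  An unlisted gene
    counts zero mutated patients (with a warning) rather than erroring, so
    cohort summaries over external gene lists stay total.
    """
    n_patients = len(table.index)
    if n_patients == 0:
        raise ValueError("empty cohort")
    if gene not in table.columns:
        warnings.warn(f"gene {gene!r} absent from cohort table; frequency 0", stacklevel=2)
        return 0.0
    return 100.0 * int(table[gene].astype(bool).sum()) / n_patients


@dataclass
class MutualExclusivityResult:
    co_occurrence: int
    exclusive: bool
    p_value: float | None = None
    method: str | None = None
    n_permutations: int | None = None


def _co_occurrence(table: np.ndarray) -> int:
    """Patients mutated in >= 2 of the listed genes (columns)."""
    return int((table.sum(axis=1) >= 2).sum())


def mutual_exclusivity(
    table: pd.DataFrame,
    genes: Sequence[str],
    *,
    n_permutations: int = 0,
    method: str = "auto",
    rng: np.random.Generator | None = None,
    exhaustive_limit: int = 200_000,
) -> MutualExclusivityResult:
    """Co-occurrence count and mutual-exclusivity flag for a gene set.

    Co-occurrence is the number of patients mutated in at least two of the
    listed genes; the set is exclusive iff that count is zero.  The optional
    permutation test redraws each gene's mutated-patient set uniformly,
    preserving per-gene totals, and reports the fraction of arrangements
    whose co-occurrence is <= the observed one (small p = fewer co-mutations
    than chance).  For small tables (``method="auto"`` or ``"exhaustive"``)
    all arrangements are enumerated exactly; otherwise Monte Carlo with the
    add-one estimator is used.
    """
    if len(genes) < 2:
        raise ValueError("mutual exclusivity needs >= 2 genes")
    n_patients = len(table.index)
    if n_patients == 0:
        raise ValueError("empty cohort")
    missing = [g for g in genes if g not in table.columns]
    if missing:
        raise ValueError(f"genes absent from table: {missing}")
    sub = table[list(genes)].astype(bool).to_numpy()
    observed = _co_occurrence(sub)
    result = MutualExclusivityResult(observed, observed == 0)
    if n_permutations <= 0 and method != "exhaustive":
        return result

    totals = sub.sum(axis=0)
    n_arrangements = int(np.prod([math.comb(n_patients, int(t)) for t in totals]))
    use_exhaustive = method == "exhaustive" or (
        method == "auto" and n_arrangements <= exhaustive_limit
    )
    if use_exhaustive:
        count = 0
        pools = [
            list(itertools.combinations(range(n_patients), int(t))) for t in totals
        ]
        for assignment in itertools.product(*pools):
            mat = np.zeros((n_patients, len(genes)), dtype=bool)
            for j, patients in enumerate(assignment):
                mat[list(patients), j] = True
            if _co_occurrence(mat) <= observed:
                count += 1
        result.p_value = count / n_arrangements
        result.method = "exhaustive"
        result.n_permutations = n_arrangements
    else:
        if rng is None:
            rng = np.random.default_rng()
        count = 0
        for _ in range(n_permutations):
            mat = np.zeros((n_patients, len(genes)), dtype=bool)
            for j, t in enumerate(totals):
                mat[rng.choice(n_patients, size=int(t), replace=False), j] = True
            if _co_occurrence(mat) <= observed:
                count += 1
        result.p_value = (count + 1) / (n_permutations + 1)
        result.method = "monte_carlo"
        result.n_permutations = n_permutations
    return result
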