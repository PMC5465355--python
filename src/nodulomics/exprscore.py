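"""Expression normalisation, differential expression and gene-set scores.

The transcriptome arm of the pipeline: FPKM normalisation of gene-level
counts, the low-expression filter (FPKM >= 1), log2(FPKM + 0.1) transform,
paired differential-expression calling at |fold change| > 1.5 and BH
FDR < 0.01, hierarchical clustering on 1 − Pearson distances, and three
gene-set scores:

* **TDS** (thyroid differentiation score): per sample, the sum over a
  16-gene thyroid-function set of median-centred log2 FPKM.  Low TDS marks
  de-differentiated (malignant) tissue.
* **EAS** (ERK-activity score): per sample, the aggregate of per-gene
  z-scored expression over a 52-gene MEK/ERK-responsive set.  High EAS
  marks MAPK-pathway activation (e.g. BRAF V600E tumours).
* **BRAF–RAS signature clustering**: hierarchical clustering restricted to
  a 71-gene set that separates BRAF-like from RAS-like expression character.

The paired DE caller is a paired t-test on log2(FPKM + 0.1) with
Benjamini–Hochberg adjustment — a deliberately simple, documented stand-in
for a count-based negative-binomial model; the decision thresholds
(FC > 1.5, FDR < 0.01) are the ones applied downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSignature",
    "ClusterResult",
    "fpkm_from_counts",
    "filter_expressed",
    "log_transform",
    "paired_de",
    "effective_gene_overlap",
    "hierarchical_cluster",
    "tds_score",
    "erk_activity_score",
]


@dataclass(frozen=True)
class GeneSignature:
    """A named gene list (e.g. the 16-gene TDS set, 52-gene ERK set)."""

    name: str
    genes: tuple[str, ...]
    expected_size: int | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature gene list is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")
        if self.expected_size is not None and len(self.genes) != self.expected_size:
            raise ValueError(
                f"signature {self.name!r} has {len(self.genes)} genes, "
                f"expected {self.expected_size}"
            )

    def present_in(self, matrix: pd.DataFrame) -> list[str]:
        present = [g for g in self.genes if g in matrix.index]
        if not present:
            raise ValueError(f"no gene of signature {self.name!r} present in matrix")
        missing = set(self.genes) - set(present)
        if missing:
            warnings.warn(
                f"signature {self.name!r}: {len(missing)} gene(s) absent from matrix",
                stacklevel=3,
            )
        return present


def fpkm_from_counts(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads.

    ``fpkm = counts * 1e9 / (length_bases * library_size)``; library sizes
    default to per-sample column sums.  Genes without a (positive) length are
    dropped with a warning.
    """
    lengths = gene_lengths.reindex(counts.index)
    bad = lengths.isna() | (lengths <= 0)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} gene(s) without a positive length",
            stacklevel=2,
        )
        counts = counts.loc[~bad]
        lengths = lengths.loc[~bad]
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.mul(1e9).div(lengths, axis=0).div(library_sizes, axis=1)


def filter_expressed(
    fpkm: pd.DataFrame, min_fpkm: float = 1.0, mode: str = "max"
) -> pd.DataFrame:
    """Drop genes below the expression floor.

    ``mode="max"`` keeps genes whose FPKM reaches ``min_fpkm`` in at least
    one sample (i.e. removes genes below the floor in *all* samples);
    ``mode="mean"`` keeps genes whose mean FPKM reaches it.  Both conventions
    appear in practice; the caller records which was used.
    """
    if fpkm.empty:
        return fpkm
    if mode == "max":
        keep = fpkm.max(axis=1) >= min_fpkm
    elif mode == "mean":
        keep = fpkm.mean(axis=1) >= min_fpkm
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return fpkm.loc[keep]


def log_transform(fpkm: pd.DataFrame, pseudo: float = 0.1) -> pd.DataFrame:
    """``log2(fpkm + pseudo)``; the 0.1 offset avoids log of zero."""
    if (fpkm < 0).any().any():
        raise ValueError("FPKM values must be non-negative")
    return np.log2(fpkm + pseudo)


def paired_de(
    log2fpkm: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Paired per-gene differential expression between two tissue types.

    ``pairs`` lists (group A sample, group B sample) per patient; patients
    are the biological replicates.  Per gene, a paired t-test on the log2
    differences (A − B) gives the raw p; Benjamini–Hochberg adjustment
    across tested genes gives the FDR; a gene is a DEG iff
    ``|fold change| > fc_threshold`` and ``fdr < fdr_threshold``.

    Zero-variance difference vectors cannot be tested: p is set to 1, unless
    every difference is identical and non-zero — an exact shift, flagged in
    ``exact_shift`` with p 0 (infinitely strong paired evidence in the
    t-test limit).

    Returns a per-gene table with ``log2fc``, ``p``, ``fdr``, ``direction``
    (up/down/none, A relative to B) and ``is_deg``.
    """
    if len(pairs) < 3:
        raise ValueError("paired DE needs >= 3 complete pairs")
    a_cols = [a for a, _ in pairs]
    b_cols = [b for _, b in pairs]
    missing = (set(a_cols) | set(b_cols)) - set(log2fpkm.columns)
    if missing:
        raise ValueError(f"samples absent from matrix: {sorted(missing)}")
    diffs = log2fpkm[a_cols].to_numpy() - log2fpkm[b_cols].to_numpy()
    log2fc = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    p = np.ones(len(log2fc))
    exact_shift = np.zeros(len(log2fc), dtype=bool)
    # differences constant to ~machine precision count as zero-variance
    nonzero_sd = sd > 1e-9 * np.maximum(1.0, np.abs(log2fc))
    if nonzero_sd.any():
        res = stats.ttest_rel(
            log2fpkm[a_cols].to_numpy()[nonzero_sd].T,
            log2fpkm[b_cols].to_numpy()[nonzero_sd].T,
        )
        p[nonzero_sd] = res.pvalue
    shift = (~nonzero_sd) & (log2fc != 0)
    exact_shift[shift] = True
    p[shift] = 0.0
    fdr = multipletests(p, method="fdr_bh")[1]
    log2_thresh = np.log2(fc_threshold)
    is_deg = (np.abs(log2fc) > log2_thresh) & (fdr < fdr_threshold)
    direction = np.where(~is_deg, "none", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "direction": direction,
            "is_deg": is_deg,
            "exact_shift": exact_shift,
        },
        index=log2fpkm.index,
    )


def _deg_lists(de: pd.DataFrame) -> tuple[set, set]:
    up = set(de.index[(de["is_deg"]) & (de["direction"] == "up")])
    down = set(de.index[(de["is_deg"]) & (de["direction"] == "down")])
    return up, down


def effective_gene_overlap(
    de_tumour_vs_normal: pd.DataFrame,
    de_benign_vs_normal: pd.DataFrame,
    de_tumour_vs_benign: pd.DataFrame | None = None,
) -> dict:
    """Venn counts between tumour-effective and benign-effective DEG lists.

    Percentages use the tumour-effective list as denominator (the convention
    is recorded under ``"denominator"``).  When the tumour-vs-benign contrast
    is supplied, its overlap with the tumour-effective lists is reported the
    same way.
    """
    t_up, t_down = _deg_lists(de_tumour_vs_normal)
    b_up, b_down = _deg_lists(de_benign_vs_normal)

    def pct(shared: set, denom: set) -> float:
        return 100.0 * len(shared) / len(denom) if denom else 0.0

    out = {
        "denominator": "tumour_effective",
        "up": {
            "n_tumour": len(t_up), "n_benign": len(b_up),
            "n_overlap": len(t_up & b_up), "pct_overlap": pct(t_up & b_up, t_up),
            "genes": sorted(t_up & b_up),
        },
        "down": {
            "n_tumour": len(t_down), "n_benign": len(b_down),
            "n_overlap": len(t_down & b_down), "pct_overlap": pct(t_down & b_down, t_down),
            "genes": sorted(t_down & b_down),
        },
    }
    if de_tumour_vs_benign is not None:
        tb_up, tb_down = _deg_lists(de_tumour_vs_benign)
        out["tumour_vs_benign"] = {
            "up": {"n": len(tb_up), "n_overlap_tumour_effective": len(tb_up & t_up),
                   "pct_of_tumour_effective": pct(tb_up & t_up, t_up)},
            "down": {"n": len(tb_down), "n_overlap_tumour_effective": len(tb_down & t_down),
                     "pct_of_tumour_effective": pct(tb_down & t_down, t_down)},
        }
    return out


@dataclass
class ClusterResult:
    linkage: np.ndarray        # scipy linkage matrix over retained samples
    samples: list[str]         # leaf ids in linkage order (input order)
    leaf_order: list[str]      # deterministic dendrogram leaf ordering
    excluded: list[str]        # zero-variance samples left out
    merge_heights: np.ndarray  # heights of successive merges

    def flat_clusters(self, n_clusters: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.samples, name="cluster")


def hierarchical_cluster(
    log2fpkm: pd.DataFrame,
    genes: Sequence[str] | None = None,
    linkage: str = "average",
) -> ClusterResult:
    """Cluster samples on 1 − Pearson correlation distances.

    ``genes`` restricts the matrix to a signature subset (e.g. the 71-gene
    BRAF–RAS set).  Samples with zero expression variance over the selected
    genes have no defined correlation and are excluded with a warning.
    Leaf order is deterministic for a given input.
    """
    mat = log2fpkm.loc[[g for g in genes if g in log2fpkm.index]] if genes is not None else log2fpkm
    if mat.shape[0] < 2:
        raise ValueError("need >= 2 genes to correlate samples")
    variances = mat.var(axis=0)
    excluded = list(mat.columns[variances == 0])
    if excluded:
        warnings.warn(f"excluding zero-variance sample(s): {excluded}", stacklevel=2)
        mat = mat.drop(columns=excluded)
    if mat.shape[1] < 2:
        raise ValueError("need >= 2 samples with expression variance")
    corr = np.corrcoef(mat.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    condensed = dist[np.triu_indices(dist.shape[0], k=1)]
    Z = hierarchy.linkage(condensed, method=linkage)
    order = hierarchy.leaves_list(Z)
    samples = list(mat.columns)
    return ClusterResult(
        linkage=Z,
        samples=samples,
        leaf_order=[samples[i] for i in order],
        excluded=excluded,
        merge_heights=Z[:, 2].copy(),
    )


def tds_score(log2fpkm: pd.DataFrame, signature: GeneSignature) -> pd.Series:
    """Thyroid differentiation score: summed median-centred expression.

    For each signature gene, that gene's median across samples is subtracted
    from each sample's log2 value; the centred values are summed over genes
    per sample.  The score is invariant to per-gene additive shifts.
    """
    genes = signature.present_in(log2fpkm)
    sub = log2fpkm.loc[genes]
    centered = sub.sub(sub.median(axis=1), axis=0)
    return centered.sum(axis=0).rename("tds")


def erk_activity_score(
    log2fpkm: pd.DataFrame,
    signature: GeneSignature,
    aggregate: str = "sum",
) -> pd.Series:
    """ERK-activity score: aggregated per-gene z-scores.

    Each signature gene is z-scored across samples (sample SD, n − 1
    denominator); scores are aggregated per sample by ``sum`` (default) or
    ``mean``.  A zero-variance gene carries no ranking information and
    contributes 0 (flagged with a warning).  Invariant to per-gene affine
    transforms of the expression values.
    """
    if aggregate not in ("sum", "mean"):
        raise ValueError(f"unknown aggregation {aggregate!r}")
    genes = signature.present_in(log2fpkm)
    sub = log2fpkm.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance signature gene(s) contribute 0",
            stacklevel=2,
        )
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd.where(~flat, 1.0), axis=0)
    z.loc[flat] = 0.0
    agg = z.sum(axis=0) if aggregate == "sum" else z.mean(axis=0)
    return agg.rename("eas")
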