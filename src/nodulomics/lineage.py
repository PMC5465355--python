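"""VAF-correlation phylogenetics for multi-lesion patients.

For each patient, somatic variant allele fractions over the union of called
sites form a sites x samples matrix; 1 − Pearson correlation between sample
columns gives a distance matrix; a distance tree (neighbour joining by
default, UPGMA optionally) is built, rooted on the germline, and each branch
is annotated with the mutations private to exactly the clade below it.  The
trunk branch of a tumour–benign pair then carries the evidence for a shared
clonal origin: a pair whose exclusive shared branch is empty is classified
as independently arisen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .mutstats import variant_keys

__all__ = [
    "GERMLINE_LABEL",
    "OriginCall",
    "build_vaf_matrix",
    "correlation_distance",
    "build_tree",
    "root_and_annotate",
    "classify_origin",
]

#: Name of the implicit germline column added to every VAF matrix.  The
#: germline has, by definition, VAF 0 at every somatic site; it serves as the
#: outgroup when rooting.
GERMLINE_LABEL = "germline"

_KEY = ["chrom", "pos", "ref", "alt"]


def build_vaf_matrix(
    observations: pd.DataFrame,
    calls: pd.DataFrame,
    *,
    blood_sample: str,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Sites x samples VAF matrix over the union of a patient's somatic calls.

    Rows are the variants called (post-filter) in *any* tissue sample of the
    patient.  For every tissue sample — whether or not it carries the call —
    the VAF is recomputed from that sample's raw depths at the site: 0 when
    the site is covered (depth >= ``min_depth``) without alternate reads,
    missing (NaN) when coverage is insufficient.  This distinguishes absence
    of evidence from evidence of absence.  A ``germline`` column of zeros is
    appended for rooting.

    Sites with no adequate coverage in any tissue sample are dropped with a
    warning.
    """
    passing = calls[calls["filter_pass"]] if "filter_pass" in calls.columns else calls
    union = sorted(variant_keys(passing))
    tissue_samples = sorted(s for s in observations["sample"].unique() if s != blood_sample)
    if len(tissue_samples) < 2:
        raise ValueError("need >= 2 tissue samples for a VAF matrix")
    depth_lookup = observations.set_index(_KEY + ["sample"])[["ref_depth", "alt_depth"]]
    mat = pd.DataFrame(index=pd.MultiIndex.from_tuples(union, names=_KEY) if union
                       else pd.MultiIndex.from_tuples([], names=_KEY),
                       columns=tissue_samples, dtype=float)
    for key in union:
        for s in tissue_samples:
            try:
                ref, alt = depth_lookup.loc[key + (s,)]
            except KeyError:
                mat.loc[key, s] = np.nan
                continue
            total = ref + alt
            mat.loc[key, s] = alt / total if total >= min_depth else np.nan
    uncovered = mat.index[mat.isna().all(axis=1)]
    if len(uncovered):
        warnings.warn(
            f"dropping {len(uncovered)} site(s) with no adequate coverage in any sample",
            stacklevel=2,
        )
        mat = mat.drop(index=uncovered)
    mat[GERMLINE_LABEL] = 0.0
    return mat


def correlation_distance(
    vaf_matrix: pd.DataFrame,
    *,
    min_complete: int = 3,
) -> tuple[pd.DataFrame, dict[tuple[str, str], str]]:
    """Pairwise 1 − Pearson distance between sample columns.

    Correlations use pairwise-complete rows (sites non-missing in both
    samples).  A pair with fewer than ``min_complete`` complete rows, or with
    a zero-variance column over those rows, gets a missing distance with the
    reason recorded; the germline column (constant 0) is exempted from the
    variance rule by treating its correlation against a varying column as 0
    would be wrong — instead the germline is placed at distance 1 (r = 0, no
    co-variation) from every tissue sample, the natural outgroup position
    under the 1 − r convention.

    Returns
    -------
    (distances, reasons) :
        Square symmetric DataFrame (NaN where undefined) and a dict mapping
        unordered pairs to the reason their distance is missing.
    """
    samples = list(vaf_matrix.columns)
    dist = pd.DataFrame(0.0, index=samples, columns=samples)
    reasons: dict[tuple[str, str], str] = {}
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            if GERMLINE_LABEL in (a, b):
                d = 1.0
            else:
                sub = vaf_matrix[[a, b]].dropna()
                if len(sub) < min_complete:
                    d = np.nan
                    reasons[(a, b)] = f"only {len(sub)} complete site(s)"
                elif sub[a].std() == 0 or sub[b].std() == 0:
                    d = np.nan
                    reasons[(a, b)] = "zero-variance VAF column"
                else:
                    r = float(np.corrcoef(sub[a], sub[b])[0, 1])
                    d = 1.0 - r
            dist.loc[a, b] = dist.loc[b, a] = d
    np.fill_diagonal(dist.values, 0.0)
    return dist, reasons


def build_tree(distances: pd.DataFrame, method: str = "nj") -> TreeNode:
    """Distance tree over samples by neighbour joining (default) or UPGMA.

    Taxa are sorted lexicographically before construction so ties resolve
    deterministically.  Negative neighbour-joining branch-length estimates
    are clamped to 0 and flagged on the node (``negative_clamped``).  Two
    taxa yield the trivial cherry with the distance split evenly.
    """
    if distances.isna().any().any():
        missing = [
            (a, b)
            for a in distances.index
            for b in distances.columns
            if pd.isna(distances.loc[a, b])
        ]
        raise ValueError(
            f"distance matrix has missing entries {missing[:4]}...: impute or drop "
            "those samples before tree building"
        )
    order = sorted(str(s) for s in distances.index)
    d = distances.loc[order, order]
    if len(order) < 2:
        raise ValueError("need >= 2 taxa")
    if len(order) == 2:
        a, b = order
        half = float(d.loc[a, b]) / 2.0
        tree = TreeNode.read([f"({a}:{half},{b}:{half});"])
        return tree
    if method == "nj":
        tree = nj(DistanceMatrix(d.to_numpy(), order))
    elif method == "upgma":
        condensed = d.to_numpy()[np.triu_indices(len(order), k=1)]
        Z = hierarchy.linkage(condensed, method="average")
        tree = TreeNode.from_linkage_matrix(Z, order)
    else:
        raise ValueError(f"unknown tree method {method!r}")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            node.negative_clamped = True
    return tree


def _tissue_leaves(tree: TreeNode, outgroup: str) -> list[str]:
    return [t.name for t in tree.tips() if t.name != outgroup]


def root_and_annotate(
    tree: TreeNode,
    outgroup: str,
    calls_by_sample: Mapping[str, Iterable[Hashable]],
) -> tuple[TreeNode, pd.DataFrame]:
    """Root the tree on the germline edge and annotate branch mutation sets.

    Each branch (clade) is assigned the mutations carried by *exactly* the
    tissue leaves below it: present in every leaf of the clade and in no
    other tissue leaf.  Pendant branches therefore carry a sample's private
    mutations and internal branches the shared trunk of their clade.  The
    annotation table reports, per branch, the leaf set, the mutation count
    (a branch-length system in its own right, alongside the correlation
    distances) and the mutation identities.
    """
    tip_names = [t.name for t in tree.tips()]
    if outgroup not in tip_names:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    rooted = tree.root_at(outgroup, above=True, reset=True)
    sets = {s: variant_keys(c) if isinstance(c, pd.DataFrame) else set(c)
            for s, c in calls_by_sample.items()}
    tissue = [n for n in _tissue_leaves(rooted, outgroup)]
    records = []
    for node in rooted.postorder():
        if node is rooted:
            continue
        clade = sorted(t.name for t in ([node] if node.is_tip() else node.tips())
                       if t.name != outgroup)
        if not clade:
            continue  # the outgroup pendant branch carries no somatic set
        inside = set.intersection(*(sets.get(s, set()) for s in clade))
        outside = set().union(*(sets.get(s, set()) for s in tissue if s not in clade)) \
            if len(clade) < len(tissue) else set()
        branch = inside - outside
        node.mutation_count = len(branch)
        records.append({
            "clade": ",".join(clade),
            "n_leaves": len(clade),
            "distance_length": node.length,
            "mutation_count": len(branch),
            "mutations": ";".join("_".join(map(str, m)) for m in sorted(branch)),
        })
    table = pd.DataFrame(records, columns=[
        "clade", "n_leaves", "distance_length", "mutation_count", "mutations",
    ])
    return rooted, table


@dataclass
class OriginCall:
    """Outcome of the shared- vs independent-origin test for a lesion pair."""

    classification: str  # "independent" | "shared-branch"
    mode: str
    shared: set = field(default_factory=set)
    shared_coding: set = field(default_factory=set)
    shared_noncoding: set = field(default_factory=set)
    pair_is_cherry: bool | None = None


def classify_origin(
    pair: tuple[str, str],
    calls_by_sample: Mapping[str, Iterable[Hashable]],
    *,
    coding: Iterable[Hashable] = (),
    mode: str = "default",
    tree: TreeNode | None = None,
) -> OriginCall:
    """Classify a tumour–benign pair as shared-branch or independent origin.

    The pair's exclusive shared branch carries the mutations present in both
    pair members and in no other sample of the patient.  The pair is
    ``shared-branch`` iff that set is non-empty — restricted to coding
    mutations under ``mode="coding-only"`` (the stricter criterion, since
    isolated shared non-coding variants can arise from recurrent artefacts).
    If a rooted tree is supplied, whether the pair forms a cherry is reported
    as corroborating evidence; the classification itself rests on the
    mutation sets, which remain defined when a mutation-free pair happens to
    be adjacent by chance.
    """
    if mode not in ("default", "coding-only"):
        raise ValueError(f"unknown origin mode {mode!r}")
    a, b = pair
    sets = {s: variant_keys(c) if isinstance(c, pd.DataFrame) else set(c)
            for s, c in calls_by_sample.items()}
    if a not in sets or b not in sets:
        raise ValueError(f"pair members {pair} must both have call sets")
    others = [s for s in sets if s not in pair]
    shared = sets[a] & sets[b]
    if others:
        shared -= set().union(*(sets[s] for s in others))
    coding_set = set(coding)
    shared_coding = shared & coding_set
    shared_noncoding = shared - coding_set
    evidence = shared_coding if mode == "coding-only" else shared
    cherry = None
    if tree is not None:
        for node in tree.non_tips(include_self=True):
            names = sorted(t.name for t in node.tips())
            if names == sorted(pair):
                cherry = True
                break
        else:
            cherry = False
    return OriginCall(
        classification="shared-branch" if evidence else "independent",
        mode=mode,
        shared=shared,
        shared_coding=shared_coding,
        shared_noncoding=shared_noncoding,
        pair_is_cherry=cherry,
    )
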