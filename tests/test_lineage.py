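"""Tests for VAF matrices, correlation distances, trees and origin calls."""

import numpy as np
import pandas as pd
import pytest

from nodulomics.lineage import (
    GERMLINE_LABEL,
    build_tree,
    build_vaf_matrix,
    classify_origin,
    correlation_distance,
    root_and_annotate,
)
from nodulomics.somatic_filter import FilterConfig, call_somatic_multi_sample, passing_calls
from nodulomics.synthdata import SimConfig, simulate_patient

from conftest import toy_calls


# ---------------------------------------------------------------------------
# VAF matrix


def _obs(rows):
    return pd.DataFrame(rows, columns=["patient", "chrom", "pos", "ref", "alt",
                                       "sample", "ref_depth", "alt_depth"])


def _calls(keys_by_sample):
    rows = []
    for s, keys in keys_by_sample.items():
        for c, p, r, a in keys:
            rows.append({"chrom": c, "pos": p, "ref": r, "alt": a,
                         "sample": s, "filter_pass": True})
    return pd.DataFrame(rows)


def test_disjoint_calls_full_coverage_make_block_matrix():
    obs = _obs([
        ("P", "1", 1, "A", "T", "blood", 100, 0),
        ("P", "1", 1, "A", "T", "t", 50, 50),
        ("P", "1", 1, "A", "T", "b", 100, 0),
        ("P", "1", 2, "C", "G", "blood", 100, 0),
        ("P", "1", 2, "C", "G", "t", 100, 0),
        ("P", "1", 2, "C", "G", "b", 60, 40),
    ])
    calls = _calls({"t": [("1", 1, "A", "T")], "b": [("1", 2, "C", "G")]})
    vaf = build_vaf_matrix(obs, calls, blood_sample="blood")
    assert vaf.shape == (2, 3)
    assert vaf.loc[("1", 1, "A", "T"), "t"] == pytest.approx(0.5)
    assert vaf.loc[("1", 1, "A", "T"), "b"] == 0.0
    assert vaf.loc[("1", 2, "C", "G"), "t"] == 0.0
    assert (vaf[GERMLINE_LABEL] == 0).all()


def test_undercovered_site_is_missing_not_zero():
    obs = _obs([
        ("P", "1", 1, "A", "T", "blood", 100, 0),
        ("P", "1", 1, "A", "T", "t", 50, 50),
        ("P", "1", 1, "A", "T", "b", 5, 0),   # below min_depth
    ])
    calls = _calls({"t": [("1", 1, "A", "T")]})
    vaf = build_vaf_matrix(obs, calls, blood_sample="blood")
    assert np.isnan(vaf.loc[("1", 1, "A", "T"), "b"])


def test_vaf_matrix_rows_match_detected_union_on_simulation(small_patient, small_calls):
    vaf = build_vaf_matrix(small_patient.observations, small_calls,
                           blood_sample=small_patient.blood_sample)
    passing = small_calls[small_calls["filter_pass"]]
    union = set(zip(passing["chrom"], passing["pos"], passing["ref"], passing["alt"]))
    assert set(vaf.index) == union


# ---------------------------------------------------------------------------
# correlation distance


def test_identical_columns_distance_zero_and_negation_two():
    x = np.array([0.1, 0.5, 0.2, 0.4, 0.3])
    mat = pd.DataFrame({"a": x, "b": x, "c": 2 * x.mean() - x})
    dist, reasons = correlation_distance(mat)
    assert dist.loc["a", "b"] == pytest.approx(0.0)
    assert dist.loc["a", "c"] == pytest.approx(2.0)
    assert not reasons


def test_three_sample_distances_match_hand_pearson():
    mat = pd.DataFrame({
        "a": [0.5, 0.4, 0.0, 0.1],
        "b": [0.45, 0.38, 0.05, 0.0],
        "c": [0.0, 0.1, 0.5, 0.42],
    })
    dist, _ = correlation_distance(mat)
    for x, y in [("a", "b"), ("a", "c"), ("b", "c")]:
        r = np.corrcoef(mat[x], mat[y])[0, 1]
        assert dist.loc[x, y] == pytest.approx(1 - r, abs=1e-12)
    # symmetry, zero diagonal
    assert np.allclose(dist.values, dist.values.T)
    assert np.allclose(np.diag(dist.values), 0.0)


def test_pairs_with_too_few_complete_rows_reported_missing():
    mat = pd.DataFrame({
        "a": [0.5, np.nan, np.nan, 0.1],
        "b": [0.45, 0.38, 0.05, np.nan],
        "c": [0.2, 0.1, 0.5, 0.42],
    })
    dist, reasons = correlation_distance(mat)
    assert np.isnan(dist.loc["a", "b"])
    assert ("a", "b") in reasons


def test_zero_variance_column_reported():
    mat = pd.DataFrame({"a": [0.2, 0.2, 0.2, 0.2], "b": [0.1, 0.2, 0.3, 0.4],
                        "c": [0.4, 0.3, 0.2, 0.1]})
    dist, reasons = correlation_distance(mat)
    assert np.isnan(dist.loc["a", "b"])
    assert "zero-variance" in reasons[("a", "b")]


# ---------------------------------------------------------------------------
# trees


def _dist(df_dict, labels):
    return pd.DataFrame(df_dict, index=labels)


def _tip_distances(tree):
    tips = sorted(t.name for t in tree.tips())
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1:]:
            out[(a, b)] = tree.find(a).distance(tree.find(b))
    return out


def test_three_taxon_pendant_lengths_follow_three_point_formula():
    d = _dist({"A": [0, 2, 3], "B": [2, 0, 3], "C": [3, 3, 0]}, ["A", "B", "C"])
    tree = build_tree(d, method="nj")
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 2.0})


@pytest.mark.parametrize("newick", [
    "((A:1,B:2):0.5,(C:0.7,D:1.3):0.9);",
    "(((A:1.2,B:0.4):0.6,C:2.1):0.3,(D:0.9,E:1.7):0.8);",
])
def test_nj_reproduces_additive_metrics_exactly(newick):
    """Cophenetic distances on the NJ tree equal the additive input metric."""
    from skbio import TreeNode

    source = TreeNode.read([newick])
    tips = sorted(t.name for t in source.tips())
    d = pd.DataFrame(0.0, index=tips, columns=tips)
    for i, a in enumerate(tips):
        for b in tips[i + 1:]:
            val = source.find(a).distance(source.find(b))
            d.loc[a, b] = d.loc[b, a] = val
    tree = build_tree(d, method="nj")
    got = _tip_distances(tree)
    for (a, b), val in got.items():
        assert val == pytest.approx(d.loc[a, b], abs=1e-9)


def test_upgma_is_fixed_point_on_ultrametric_input():
    # heights: (A,B) at 1, ((A,B),C) at 2 -> cophenetics 2,4,4... use distances
    d = _dist({"A": [0, 2, 4], "B": [2, 0, 4], "C": [4, 4, 0]}, ["A", "B", "C"])
    tree = build_tree(d, method="upgma")
    got = _tip_distances(tree)
    assert got[("A", "B")] == pytest.approx(2.0)
    assert got[("A", "C")] == pytest.approx(4.0)
    assert got[("B", "C")] == pytest.approx(4.0)


def test_two_taxa_trivial_cherry():
    d = _dist({"A": [0, 3.0], "B": [3.0, 0]}, ["A", "B"])
    tree = build_tree(d)
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == pytest.approx({"A": 1.5, "B": 1.5})


def test_missing_distances_raise_with_guidance():
    d = _dist({"A": [0, np.nan, 1], "B": [np.nan, 0, 1], "C": [1, 1, 0]},
              ["A", "B", "C"])
    with pytest.raises(ValueError, match="impute"):
        build_tree(d)


# ---------------------------------------------------------------------------
# rooting + branch annotation


def _patient_tree(calls_by_sample):
    samples = sorted(calls_by_sample) + [GERMLINE_LABEL]
    # crude distances: 1 - jaccard over call sets, germline at 1
    import itertools
    d = pd.DataFrame(0.0, index=samples, columns=samples)
    for a, b in itertools.combinations(samples, 2):
        if GERMLINE_LABEL in (a, b):
            val = 1.0
        else:
            sa, sb = set(calls_by_sample[a]), set(calls_by_sample[b])
            val = 1.0 - (len(sa & sb) / len(sa | sb) if sa | sb else 0.0)
        d.loc[a, b] = d.loc[b, a] = val
    return build_tree(d)


def test_private_only_lesions_annotate_pendant_branches():
    sets = {"t": {("1", 1, "A", "T")}, "b": {("1", 2, "C", "G")},
            "n": {("1", 3, "G", "C")}}
    tree = _patient_tree(sets)
    rooted, table = root_and_annotate(tree, GERMLINE_LABEL, sets)
    by_clade = table.set_index("clade")["mutation_count"]
    assert by_clade["t"] == 1 and by_clade["b"] == 1 and by_clade["n"] == 1
    internal = table[table["n_leaves"] > 1]
    assert (internal["mutation_count"] == 0).all()


def test_trunk_mutation_lands_on_shared_internal_branch():
    trunk = ("1", 9, "T", "A")
    sets = {"t": {("1", 1, "A", "T"), trunk}, "b": {("1", 2, "C", "G"), trunk},
            "n": {("1", 3, "G", "C")}}
    tree = _patient_tree(sets)
    rooted, table = root_and_annotate(tree, GERMLINE_LABEL, sets)
    row = table[table["clade"] == "b,t"]
    assert len(row) == 1
    assert row["mutation_count"].item() == 1
    assert "1_9_T_A" in row["mutations"].item()


def test_simulated_trunk_recovered_from_truth(small_patient, small_calls):
    """The annotated trunk branch equals the planted truth trunk."""
    passing = small_calls[small_calls["filter_pass"]]
    sets = {s: g for s, g in passing.groupby("sample")}
    vaf = build_vaf_matrix(small_patient.observations, passing,
                           blood_sample=small_patient.blood_sample)
    dist, reasons = correlation_distance(vaf)
    assert not reasons
    tree = build_tree(dist)
    rooted, table = root_and_annotate(tree, GERMLINE_LABEL, sets)
    pid = small_patient.patient
    clade = f"{pid}_benign1,{pid}_tumour1"
    row = table[table["clade"] == clade]
    truth_trunk = {
        tuple(k.split(":")) for k in small_patient.truth.lesions[f"{pid}_benign1"]["trunk"]
    }
    truth_trunk = {(c, int(p), r, a) for c, p, r, a in truth_trunk}
    assert len(row) == 1
    got = set()
    for m in row["mutations"].item().split(";"):
        c, p, r, a = m.split("_")
        got.add((c, int(p), r, a))
    assert got == truth_trunk


def test_outgroup_must_be_a_leaf():
    sets = {"t": {("1", 1, "A", "T")}, "b": {("1", 2, "C", "G")},
            "n": set()}
    tree = _patient_tree(sets)
    with pytest.raises(ValueError, match="leaf"):
        root_and_annotate(tree, "nope", sets)


# ---------------------------------------------------------------------------
# origin classification


def test_zero_shared_mutations_is_independent():
    sets = {"t": {("1", 1, "A", "T")}, "b": {("1", 2, "C", "G")}}
    oc = classify_origin(("t", "b"), sets)
    assert oc.classification == "independent"
    assert not oc.shared


def test_noncoding_shared_variant_modes():
    shared = ("1", 9, "T", "A")
    sets = {"t": {("1", 1, "A", "T"), shared}, "b": {("1", 2, "C", "G"), shared}}
    default = classify_origin(("t", "b"), sets, coding=set())
    strict = classify_origin(("t", "b"), sets, coding=set(), mode="coding-only")
    assert default.classification == "shared-branch"
    assert default.shared_noncoding == {shared}
    assert strict.classification == "independent"


def test_shared_variant_present_in_normal_is_not_pair_exclusive():
    shared = ("1", 9, "T", "A")
    sets = {"t": {shared}, "b": {shared}, "n": {shared}}
    oc = classify_origin(("t", "b"), sets)
    assert oc.classification == "independent"


def test_simulated_independent_pair_classified_independent():
    cfg = SimConfig(n_patients=1, trunk_mutations=0, n_genes=160, seed=21)
    p = simulate_patient(cfg, 0)
    calls = call_somatic_multi_sample(p.observations, p.annotations,
                                      blood_sample=p.blood_sample)
    passing = passing_calls(calls)
    sets = {s: g for s, g in passing.groupby("sample")}
    coding = set(zip(*(passing[passing["region"].isin({"exonic", "splicing"})][c]
                       for c in ["chrom", "pos", "ref", "alt"])))
    oc = classify_origin((f"{p.patient}_tumour1", f"{p.patient}_benign1"), sets,
                         coding=coding, mode="coding-only")
    assert oc.classification == "independent"
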