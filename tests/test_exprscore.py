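"""Tests for FPKM normalisation, paired DE, clustering and gene-set scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nodulomics.exprscore import (
    GeneSignature,
    effective_gene_overlap,
    erk_activity_score,
    filter_expressed,
    fpkm_from_counts,
    hierarchical_cluster,
    log_transform,
    paired_de,
    tds_score,
)


def _mat(data, samples=None):
    df = pd.DataFrame(data).T if isinstance(data, dict) else pd.DataFrame(data)
    if samples is not None:
        df.columns = samples
    return df


# ---------------------------------------------------------------------------
# FPKM


def test_fpkm_worked_example():
    counts = pd.DataFrame({"s": [10]}, index=["g"])
    lengths = pd.Series({"g": 1000})
    fpkm = fpkm_from_counts(counts, lengths, pd.Series({"s": 1_000_000}))
    assert fpkm.loc["g", "s"] == pytest.approx(10.0)


def test_fpkm_zero_counts_and_scale_invariance():
    rng = np.random.default_rng(3)
    counts = pd.DataFrame(rng.integers(0, 500, (20, 4)).astype(float),
                          index=[f"g{i}" for i in range(20)],
                          columns=list("abcd"))
    counts.iloc[0] = 0.0
    lengths = pd.Series(rng.integers(300, 4000, 20), index=counts.index)
    libs = counts.sum(axis=0)
    one = fpkm_from_counts(counts, lengths, libs)
    two = fpkm_from_counts(2 * counts, lengths, 2 * libs)
    assert (one.iloc[0] == 0).all()
    assert np.allclose(one, two)


def test_fpkm_drops_genes_without_length():
    counts = pd.DataFrame({"s": [1.0, 2.0]}, index=["g1", "g2"])
    lengths = pd.Series({"g1": 1000})
    with pytest.warns(UserWarning):
        fpkm = fpkm_from_counts(counts, lengths)
    assert list(fpkm.index) == ["g1"]


# ---------------------------------------------------------------------------
# expression filter and log transform


def test_filter_expressed_max_vs_mean_modes():
    fpkm = _mat({"low": [0.5, 0.5, 0.5], "spike": [1.2, 0.1, 0.1],
                 "high": [4, 5, 6]}, samples=list("xyz"))
    assert list(filter_expressed(fpkm, mode="max").index) == ["spike", "high"]
    assert list(filter_expressed(fpkm, mode="mean").index) == ["high"]
    assert filter_expressed(fpkm.iloc[0:0]).empty


@pytest.mark.parametrize("value,expected", [(0.0, np.log2(0.1)), (0.9, 0.0), (3.9, 2.0)])
def test_log_transform_offsets_by_point_one(value, expected):
    out = log_transform(pd.DataFrame({"s": [value]}, index=["g"]))
    assert out.loc["g", "s"] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# paired DE


def _paired_matrix(n_genes, n_pairs, shift_genes=(), shift=1.0, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.normal(5.0, 1.0, size=(n_genes, n_pairs))
    a = base + rng.normal(0, noise, size=(n_genes, n_pairs))
    b = base + rng.normal(0, noise, size=(n_genes, n_pairs))
    genes = [f"g{i}" for i in range(n_genes)]
    for g in shift_genes:
        a[genes.index(g)] += shift
    cols_a = [f"pa{i}_A" for i in range(n_pairs)]
    cols_b = [f"pa{i}_B" for i in range(n_pairs)]
    mat = pd.DataFrame(np.hstack([a, b]), index=genes, columns=cols_a + cols_b)
    return mat, list(zip(cols_a, cols_b))


def test_identical_groups_are_not_degs():
    mat, pairs = _paired_matrix(50, 6, noise=0.0)
    de = paired_de(mat, pairs)
    assert (de["log2fc"] == 0).all()
    assert not de["is_deg"].any()
    # zero-variance, zero-shift differences get p = 1
    assert (de["p"] == 1.0).all()


def test_planted_two_fold_shift_called_up():
    mat, pairs = _paired_matrix(200, 6, shift_genes=["g0", "g1"], shift=1.0,
                                noise=0.05, seed=1)
    de = paired_de(mat, pairs)
    assert de.loc["g0", "is_deg"] and de.loc["g0", "direction"] == "up"
    assert de.loc["g1", "is_deg"]
    assert de.loc["g0", "log2fc"] == pytest.approx(1.0, abs=0.15)
    others = de.drop(["g0", "g1"])
    assert others["is_deg"].mean() < 0.05


def test_exact_shift_without_noise_is_flagged():
    mat, pairs = _paired_matrix(10, 4, shift_genes=["g3"], shift=2.0, noise=0.0)
    de = paired_de(mat, pairs)
    assert de.loc["g3", "exact_shift"]
    assert de.loc["g3", "p"] == 0.0
    assert de.loc["g3", "is_deg"]


def test_fdr_dominates_raw_p_and_needs_three_pairs():
    mat, pairs = _paired_matrix(100, 5, seed=2, noise=0.2)
    de = paired_de(mat, pairs)
    assert (de["fdr"] >= de["p"] - 1e-15).all()
    assert de["fdr"].between(0, 1).all()
    with pytest.raises(ValueError):
        paired_de(mat, pairs[:2])


# ---------------------------------------------------------------------------
# DEG list overlap


def _fake_de(up, down, universe):
    df = pd.DataFrame(index=sorted(universe),
                      columns=["log2fc", "p", "fdr", "direction", "is_deg"])
    df["is_deg"] = False
    df["direction"] = "none"
    df.loc[list(up), ["is_deg", "direction"]] = [True, "up"]
    df.loc[list(down), ["is_deg", "direction"]] = [True, "down"]
    return df


def test_effective_overlap_percentages():
    universe = {f"g{i}" for i in range(10)}
    t = _fake_de({"g0", "g1", "g2", "g3"}, {"g8"}, universe)
    b = _fake_de({"g2", "g3", "g4"}, {"g9"}, universe)
    out = effective_gene_overlap(t, b)
    assert out["up"]["n_overlap"] == 2
    assert out["up"]["pct_overlap"] == pytest.approx(50.0)
    assert out["down"]["pct_overlap"] == pytest.approx(0.0)
    # identical lists -> 100%, disjoint -> 0%
    same = effective_gene_overlap(t, t)
    assert same["up"]["pct_overlap"] == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# hierarchical clustering


def test_identical_samples_merge_at_height_zero():
    rng = np.random.default_rng(4)
    base = rng.normal(0, 1, 30)
    mat = pd.DataFrame({"a": base, "b": base, "c": rng.normal(0, 1, 30)})
    res = hierarchical_cluster(mat)
    assert res.merge_heights[0] == pytest.approx(0.0, abs=1e-12)
    assert set(res.flat_clusters(2)[["a", "b"]]) == {res.flat_clusters(2)["a"]}


def test_duplicated_columns_are_nearest_neighbours():
    rng = np.random.default_rng(5)
    mat = pd.DataFrame(rng.normal(0, 1, (40, 3)), columns=["x", "y", "z"])
    mat["x_dup"] = mat["x"]
    res = hierarchical_cluster(mat)
    labels = res.flat_clusters(3)
    assert labels["x"] == labels["x_dup"]


def test_average_linkage_merge_heights_match_hand_trace():
    """4 samples engineered so 1-r distances are simple; trace UPGMA by hand."""
    t = np.linspace(0, 1, 12)
    mat = pd.DataFrame({
        "a": t, "b": t + 0.01 * np.sin(10 * t), "c": -t, "d": -t + 0.01 * np.cos(9 * t),
    })
    corr = np.corrcoef(mat.to_numpy().T)
    d = 1 - corr
    # hand trace: merge the two closest pairs, then average-link the blocks
    dab, dcd = d[0, 1], d[2, 3]
    cross = np.mean([d[0, 2], d[0, 3], d[1, 2], d[1, 3]])
    res = hierarchical_cluster(mat)
    got = sorted(res.merge_heights)
    assert got[0] == pytest.approx(min(dab, dcd), abs=1e-12)
    assert got[1] == pytest.approx(max(dab, dcd), abs=1e-12)
    assert got[2] == pytest.approx(cross, abs=1e-12)


def test_zero_variance_sample_excluded():
    mat = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 1, 3], "flat": [1.0, 1, 1]})
    with pytest.warns(UserWarning):
        res = hierarchical_cluster(mat)
    assert res.excluded == ["flat"]


# ---------------------------------------------------------------------------
# signatures and scores


def test_signature_validation():
    with pytest.raises(ValueError):
        GeneSignature("dup", ("a", "a"))
    with pytest.raises(ValueError):
        GeneSignature("short", ("a",), expected_size=16)
    with pytest.raises(ValueError):
        GeneSignature("empty", ())


def test_tds_one_gene_example_and_missing_genes():
    mat = pd.DataFrame({"s1": [1.0], "s2": [3.0]}, index=["g"])
    sig = GeneSignature("tds", ("g", "absent"))
    with pytest.warns(UserWarning):
        scores = tds_score(mat, sig)
    assert scores["s1"] == pytest.approx(-1.0)
    assert scores["s2"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        tds_score(mat, GeneSignature("none", ("missing",)))


@settings(derandomize=True, max_examples=40)
@given(
    values=arrays(np.float64, (4, 3),
                  elements=st.floats(0.0, 1e4, allow_nan=False)),
    shift=st.floats(0.01, 100.0),
)
def test_fpkm_scale_invariance_and_log_monotonicity(values, shift):
    """Rescaling counts and library sizes together leaves FPKM unchanged;
    the log transform preserves ordering within a sample."""
    counts = pd.DataFrame(values, index=list("wxyz"), columns=list("abc"))
    lengths = pd.Series([500, 1000, 1500, 2000], index=counts.index)
    libs = pd.Series(1e6, index=counts.columns)
    one = fpkm_from_counts(counts, lengths, libs)
    two = fpkm_from_counts(counts * shift, lengths, libs * shift)
    assert np.allclose(one, two, rtol=1e-9)
    logged = log_transform(one)
    for c in one.columns:
        # weakly monotone: the +0.1 offset may merge near-zero values
        order = np.argsort(one[c].to_numpy(), kind="stable")
        assert (np.diff(logged[c].to_numpy()[order]) >= 0).all()


def test_tds_invariant_to_per_gene_additive_shift():
    rng = np.random.default_rng(6)
    mat = pd.DataFrame(rng.normal(0, 1, (5, 6)),
                       index=[f"g{i}" for i in range(5)],
                       columns=[f"s{i}" for i in range(6)])
    sig = GeneSignature("tds", tuple(mat.index))
    shifted = mat.add(pd.Series(rng.normal(0, 10, 5), index=mat.index), axis=0)
    assert np.allclose(tds_score(mat, sig), tds_score(shifted, sig))
    flat = pd.DataFrame(np.tile(mat.iloc[:, 0].to_numpy()[:, None], 6),
                        index=mat.index, columns=mat.columns)
    assert np.allclose(tds_score(flat, sig), 0.0)


def test_eas_one_gene_example_and_affine_invariance():
    mat = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0]}, index=["g"])
    sig = GeneSignature("erk", ("g",))
    scores = erk_activity_score(mat, sig)
    assert np.allclose(scores, [-1.0, 0.0, 1.0])
    # affine rescaling per gene leaves z-scores unchanged
    assert np.allclose(erk_activity_score(7 * mat + 3, sig), scores)
    # zero-variance gene contributes 0
    flat = pd.DataFrame({"s1": [5.0], "s2": [5.0], "s3": [5.0]}, index=["g"])
    with pytest.warns(UserWarning):
        assert np.allclose(erk_activity_score(flat, sig), 0.0)


def test_eas_mean_aggregation_scales_sum():
    rng = np.random.default_rng(7)
    mat = pd.DataFrame(rng.normal(5, 2, (4, 5)),
                       index=list("wxyz"), columns=[f"s{i}" for i in range(5)])
    sig = GeneSignature("erk", tuple(mat.index))
    total = erk_activity_score(mat, sig, aggregate="sum")
    mean = erk_activity_score(mat, sig, aggregate="mean")
    assert np.allclose(total / 4, mean)
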