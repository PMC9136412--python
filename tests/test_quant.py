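"""quant_stats: batch correction, CV, normalisation, PCA, HCA, Dunnett."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conglutin.quant import (
    AbundanceMatrix,
    anova_dunnett,
    correlation_distance,
    cumulative_variance,
    family_abundance,
    hca,
    linkage_to_newick,
    pca,
    percent_of_average,
    prepare_multivariate,
    remove_batch_effect,
    replicate_cv,
)
from conglutin.synth import generate_abundance_matrix


def _matrix(accessions=("D1", "D2", "D3", "D4"), seed=0, **kw):
    marker_map = {"PEPAK": "alpha1", "PEPBK": "beta2", "PEPCK": "beta4+6"}
    matrix, truth = generate_abundance_matrix(
        marker_map, list(accessions), seed=seed, **kw
    )
    return matrix, truth, marker_map


# ------------------------------------------------------------ the container


def test_from_long_round_trip():
    matrix, *_ = _matrix()
    again = AbundanceMatrix.from_long(matrix.to_long())
    pd.testing.assert_frame_equal(matrix.areas, again.areas)


def test_rejects_nonpositive_areas():
    matrix, *_ = _matrix()
    areas = matrix.areas.copy()
    areas.iloc[0, 0] = 0.0
    with pytest.raises(ValueError):
        AbundanceMatrix(areas, matrix.runs)


def test_rejects_duplicate_injection_order():
    matrix, *_ = _matrix()
    runs = matrix.runs.copy()
    runs.iloc[0, runs.columns.get_loc("injection_order")] = runs.iloc[1][
        "injection_order"
    ]
    with pytest.raises(ValueError):
        AbundanceMatrix(matrix.areas, runs)


# -------------------------------------------------------- batch correction


def test_batch_offset_removed_exactly_without_noise():
    matrix, _, _ = _matrix(replicate_cv=0.0, batch_offsets=(0.0, 0.3))
    corr = remove_batch_effect(matrix)
    batch = matrix.runs["batch"]
    for pep in corr.log10.index:
        values = corr.log10.loc[pep]
        b1 = values[batch[values.index] == "B1"].mean()
        b2 = values[batch[values.index] == "B2"].mean()
        assert b1 == pytest.approx(b2, abs=1e-9)


def test_batch_effect_estimates_offset():
    matrix, truth, _ = _matrix(
        accessions=tuple(f"A{i}" for i in range(10)),
        replicate_cv=0.0,
        batch_offsets=(0.0, 0.3),
    )
    corr = remove_batch_effect(matrix)
    est = corr.batch_effects["B2"] - corr.batch_effects["B1"]
    assert np.allclose(est, 0.3, atol=1e-9)


def test_constant_peptide_unchanged():
    matrix, _, _ = _matrix(replicate_cv=0.0, batch_offsets=(0.0, 0.0))
    corr = remove_batch_effect(matrix)
    assert np.allclose(corr.log10.to_numpy(), np.log10(matrix.areas.to_numpy()))


def test_within_batch_contrasts_preserved():
    matrix, _, _ = _matrix(replicate_cv=10.0, batch_offsets=(0.0, 0.3), seed=3)
    corr = remove_batch_effect(matrix)
    log_before = np.log10(matrix.areas)
    same_batch = matrix.runs[matrix.runs["batch"] == "B1"].index[:2]
    before = log_before[same_batch[0]] - log_before[same_batch[1]]
    after = corr.log10[same_batch[0]] - corr.log10[same_batch[1]]
    assert np.allclose(before, after, atol=1e-9)


def test_single_batch_rejected():
    matrix, *_ = _matrix()
    runs = matrix.runs.copy()
    runs["batch"] = "B1"
    with pytest.raises(ValueError):
        remove_batch_effect(AbundanceMatrix(matrix.areas, runs))


# ------------------------------------------------------------ replicate CV


def test_cv_exact_arithmetic():
    rows = []
    for rep, area in enumerate((8.0, 10.0, 12.0), start=1):
        rows.append(
            {
                "peptide": "PEPK",
                "accession": "D1",
                "replicate": rep,
                "batch": "B1",
                "injection_order": rep,
                "area": area,
            }
        )
    for rep, area in enumerate((10.0, 10.0, 10.0), start=1):
        rows.append(
            {
                "peptide": "PEPK",
                "accession": "D2",
                "replicate": rep,
                "batch": "B2",
                "injection_order": 3 + rep,
                "area": area,
            }
        )
    matrix = AbundanceMatrix.from_long(pd.DataFrame(rows))
    cv = replicate_cv(matrix)
    assert cv.loc["PEPK", "D1"] == pytest.approx(20.0)
    assert cv.loc["PEPK", "D2"] == pytest.approx(0.0)


def test_cv_matches_generator_target():
    matrix, _, _ = _matrix(
        accessions=tuple(f"A{i}" for i in range(20)), replicate_cv=10.0, seed=8
    )
    cv = replicate_cv(matrix)
    assert 8.0 <= np.nanmedian(cv.to_numpy()) <= 12.0


# --------------------------------------------------- percent of average


def test_percent_equal_values():
    out = percent_of_average(pd.Series([3.0, 3.0, 3.0]))
    assert np.allclose(out, 100.0)


def test_percent_one_three():
    out = percent_of_average(pd.Series([1.0, 3.0]))
    assert list(out) == [50.0, 150.0]


def test_percent_mean_is_100():
    rng = np.random.default_rng(12)
    out = percent_of_average(pd.Series(rng.uniform(1, 100, size=46)))
    assert out.mean() == pytest.approx(100.0)


def test_percent_all_zero_rejected():
    with pytest.raises(ValueError):
        percent_of_average(pd.Series([0.0, 0.0]))


def test_percent_suppressed_accession_is_small():
    # factor 0.01 in a 46-accession panel: percent ~= 1/(45.01/46) percent-ish
    values = pd.Series([1.0] * 45 + [0.01])
    out = percent_of_average(values)
    assert out.iloc[-1] < 5.0


# ------------------------------------------------------ family aggregation


def test_single_peptide_family_equals_peptide_percent():
    matrix, _, marker_map = _matrix(replicate_cv=0.0, batch_offsets=(0.0, 0.0))
    profile = family_abundance(matrix, marker_map)
    pep_means = matrix.accession_means().loc["PEPAK"]
    expected = percent_of_average(pep_means)
    assert np.allclose(profile.family_percent["alpha"], expected)


def test_family_total_linearity():
    matrix, _, marker_map = _matrix(replicate_cv=0.0, batch_offsets=(0.0, 0.0))
    doubled = matrix.areas.copy()
    beta_peps = [p for p, t in marker_map.items() if t.startswith("beta")]
    d1_runs = matrix.runs.index[matrix.runs["accession"] == "D1"]
    doubled.loc[beta_peps, d1_runs] *= 2.0
    before = family_abundance(matrix, marker_map).family_raw
    after = family_abundance(AbundanceMatrix(doubled, matrix.runs), marker_map).family_raw
    assert after.loc["D1", "beta"] == pytest.approx(2.0 * before.loc["D1", "beta"])
    assert after.loc["D2", "beta"] == pytest.approx(before.loc["D2", "beta"])


def test_family_invariant_to_peptide_order():
    matrix, _, marker_map = _matrix()
    shuffled = AbundanceMatrix(matrix.areas.iloc[::-1], matrix.runs)
    a = family_abundance(matrix, marker_map).family_percent
    b = family_abundance(shuffled, marker_map).family_percent
    pd.testing.assert_frame_equal(a.sort_index(axis=1), b.sort_index(axis=1))


def test_group_peptides_contribute_to_family():
    matrix, _, marker_map = _matrix(replicate_cv=0.0, batch_offsets=(0.0, 0.0))
    profile = family_abundance(matrix, marker_map)
    means = matrix.accession_means()
    expected = means.loc["PEPBK"] + means.loc["PEPCK"]  # beta2 + beta4+6 group
    assert np.allclose(profile.family_raw["beta"], expected)


def test_unmapped_marker_rejected():
    matrix, _, marker_map = _matrix()
    with pytest.raises(ValueError, match="PEPCK"):
        family_abundance(matrix, {k: v for k, v in marker_map.items() if k != "PEPCK"})


def test_suppressed_accessions_rank_lowest():
    suppression = {("D1", "beta2"): 0.01, ("D1", "beta4"): 0.01, ("D1", "beta6"): 0.01}
    matrix, _, marker_map = _matrix(
        accessions=("D1", "D2", "D3", "D4", "D5", "D6"),
        replicate_cv=5.0,
        suppression=suppression,
        seed=9,
    )
    profile = family_abundance(matrix, marker_map)
    assert profile.family_percent["beta"].idxmin() == "D1"


# ---------------------------------------------------------------------- PCA


def test_pca_variance_sums_to_100():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(size=(12, 6)))
    res = pca(X)
    assert res.explained_pct.sum() == pytest.approx(100.0)
    assert cumulative_variance(res.explained_pct, 2) == pytest.approx(
        res.explained_pct[:2].sum()
    )


def test_pca_rank_one_two_groups():
    # two identical groups of points: PC1 captures all the variance
    base = np.array([1.0, 2.0, 3.0, 4.0])
    X = pd.DataFrame(np.vstack([base] * 4 + [base + 2.0] * 4))
    res = pca(X, scaling="center")
    assert res.explained_pct[0] == pytest.approx(100.0)
    scores = res.scores["PC1"].to_numpy()
    assert np.allclose(scores[:4], scores[0]) and np.allclose(scores[4:], scores[4])
    assert not np.isclose(scores[0], scores[4])


def test_pca_covariance_eigen_oracle():
    rng = np.random.default_rng(17)
    X = pd.DataFrame(rng.normal(size=(10, 8)))
    res = pca(X, scaling="unit-variance")
    Z = (X - X.mean()) / X.std(ddof=1)
    cov = np.cov(Z.to_numpy(), rowvar=False, ddof=1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    for k in range(3):
        load = res.loadings[f"PC{k + 1}"].to_numpy()
        ref = v[:, k]
        assert np.allclose(np.abs(load @ ref), 1.0, atol=1e-8)
        # scores match the projection onto the eigenvector up to sign
        proj = Z.to_numpy() @ ref
        got = res.scores[f"PC{k + 1}"].to_numpy()
        assert np.allclose(np.abs(proj @ got) / (np.linalg.norm(proj) * np.linalg.norm(got)), 1.0)


def test_pca_sign_convention():
    rng = np.random.default_rng(18)
    X = pd.DataFrame(rng.normal(size=(9, 5)))
    res = pca(X)
    for col in res.loadings.columns:
        load = res.loadings[col].to_numpy()
        assert load[np.argmax(np.abs(load))] > 0


def test_pca_too_few_samples():
    with pytest.raises(ValueError):
        pca(pd.DataFrame([[1.0, 2.0]]))


def test_pca_zero_variance_feature_named():
    X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    with pytest.raises(ValueError, match="b"):
        pca(X)


# ---------------------------------------------------------------------- HCA


def test_distance_identical_profiles_zero():
    X = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]], index=["a", "b"])
    d = correlation_distance(X)
    assert d.loc["a", "b"] == pytest.approx(0.0)


def test_distance_anticorrelated_two():
    X = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], index=["a", "b"])
    d = correlation_distance(X)
    assert d.loc["a", "b"] == pytest.approx(2.0)


def test_zero_variance_sample_named():
    X = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["ok", "flat"])
    with pytest.raises(ValueError, match="flat"):
        correlation_distance(X)


def test_hca_recovers_planted_partition():
    rng = np.random.default_rng(23)
    profile_a = rng.normal(0, 1, size=20)
    profile_b = rng.normal(0, 1, size=20)
    rows, labels = [], []
    for i in range(6):
        rows.append(profile_a + rng.normal(0, 0.05, size=20))
        labels.append(f"a{i}")
    for i in range(6):
        rows.append(profile_b + rng.normal(0, 0.05, size=20))
        labels.append(f"b{i}")
    X = pd.DataFrame(rows, index=labels)
    clusters = hca(X).cut(2)
    assert len(set(clusters[labels[:6]])) == 1
    assert len(set(clusters[labels[6:]])) == 1
    assert clusters[labels[0]] != clusters[labels[6]]


def test_linkage_newick_has_all_leaves():
    rng = np.random.default_rng(24)
    X = pd.DataFrame(rng.normal(size=(5, 8)), index=list("abcde"))
    res = hca(X)
    newick = linkage_to_newick(res.linkage_matrix, res.labels)
    for leaf in "abcde":
        assert leaf in newick
    assert newick.endswith(";")


# ----------------------------------------------------------- prepare/impute


def test_prepare_multivariate_policy():
    matrix, *_ = _matrix()
    areas = matrix.areas.copy()
    # peptide missing in >50% of runs is dropped
    areas.iloc[0, : areas.shape[1] - 2] = np.nan
    # peptide with one missing value gets half-minimum imputation
    areas.iloc[1, 0] = np.nan
    m2 = AbundanceMatrix(areas, matrix.runs)
    X = prepare_multivariate(m2)
    assert areas.index[0] not in X.columns
    imputed = 10.0 ** X.iloc[0][areas.index[1]]
    assert imputed == pytest.approx(areas.iloc[1].min() / 2.0)


# ------------------------------------------------------------ ANOVA+Dunnett


def test_dunnett_single_comparison_matches_t_test():
    rng = np.random.default_rng(31)
    a = rng.normal(0, 1, size=8)
    b = rng.normal(0.8, 1, size=8)
    res = anova_dunnett({"ctl": a, "trt": b}, control="ctl", mc_draws=200_000, seed=0)
    t_p = stats.ttest_ind(b, a).pvalue
    assert res.comparisons.iloc[0]["p_adj"] == pytest.approx(t_p, abs=0.002)


def test_dunnett_agrees_with_scipy():
    rng = np.random.default_rng(32)
    control = rng.normal(0, 1, size=6)
    g1 = rng.normal(0.5, 1, size=6)
    g2 = rng.normal(1.5, 1, size=6)
    res = anova_dunnett(
        {"ctl": control, "g1": g1, "g2": g2}, control="ctl", mc_draws=400_000, seed=1
    )
    ref = stats.dunnett(g1, g2, control=control)
    ours = res.comparisons.set_index("group")["p_adj"]
    assert ours["g1"] == pytest.approx(ref.pvalue[0], abs=0.01)
    assert ours["g2"] == pytest.approx(ref.pvalue[1], abs=0.01)


def test_dunnett_planted_shift_detected():
    # 5 groups of n=3, one shifted by 3 pooled sd: the exact power of the
    # Dunnett test here is ~0.75 (measured over 1,000 simulations), so the
    # test bounds the rate from both sides rather than asserting near-certain
    # detection.
    rng = np.random.default_rng(33)
    hits = 0
    null_hits = 0
    n_sim = 200
    for _ in range(n_sim):
        groups = {f"g{i}": rng.normal(0, 1, size=3) for i in range(4)}
        groups["shifted"] = rng.normal(3.0, 1, size=3)
        res = anova_dunnett(groups, control="g0", mc_draws=100_000, seed=0)
        table = res.comparisons.set_index("group")
        hits += bool(table.loc["shifted", "significant"])
        null_hits += int(table.drop("shifted")["significant"].sum())
    assert 0.60 <= hits / n_sim <= 0.90
    assert null_hits / (3 * n_sim) < 0.05  # per-comparison null rate stays small


def test_dunnett_control_missing():
    with pytest.raises(ValueError):
        anova_dunnett({"a": [1.0, 2.0], "b": [2.0, 3.0]}, control="zzz")


def test_dunnett_small_group_rejected():
    with pytest.raises(ValueError):
        anova_dunnett({"a": [1.0], "b": [2.0, 3.0]}, control="a")
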