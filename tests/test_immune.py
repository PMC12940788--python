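"""Tests of immunophenotype discovery: preprocessing, region comparison,
correlation, Ward clustering, k selection, ARI, bootstrap stability, PCA
and the PD-L1/TLS/IMP-naming rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from chondroprofiler import immune
from chondroprofiler.immune import (
    MarkerDensityTable,
    adjusted_rand_index,
    bootstrap_stability,
    call_tls,
    compare_regions,
    correlation_map,
    name_imps,
    pca_contributions,
    preprocess_densities,
    score_pdl1,
    select_k,
    ward_cluster,
)
from chondroprofiler.synth import DENSITY_COLUMNS

from oracles import (
    ari_contingency,
    partitions_from_linkage,
    ward_greedy_partitions,
    wilcoxon_exact_p,
)


def make_table(matrix: np.ndarray, **aux) -> MarkerDensityTable:
    df = pd.DataFrame(matrix, columns=list(DENSITY_COLUMNS))
    df.insert(0, "sample", [f"P{i}" for i in range(len(df))])
    df["subtype"] = aux.get("subtype", "G2")
    df["pdl1_percent"] = aux.get("pdl1", 0.0)
    df["tls_cd3"] = df["tls_cd20"] = df["tls_lamp3"] = 0
    return MarkerDensityTable(df)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def test_preprocess_log1p_and_zscore(rng):
    X = rng.gamma(2.0, 50.0, size=(30, 40))
    X[:, 0] = [0.0] + [np.e - 1] * 29  # log1p values {0, 1}
    table = make_table(X)
    feats, params = preprocess_densities(table)
    logged = np.log1p(X[:, 0])
    assert logged[0] == 0.0 and logged[1] == 1.0
    assert np.allclose(feats.mean(), 0.0, atol=1e-12)
    assert np.allclose(feats.var(ddof=0), 1.0, atol=1e-12)


def test_preprocess_constant_feature_warns_not_divides():
    X = np.ones((10, 40))
    with pytest.warns(RuntimeWarning, match="constant"):
        feats, params = preprocess_densities(make_table(X))
    assert np.isfinite(feats.to_numpy()).all()
    assert (params.scale == 1.0).all()


def test_preprocess_drops_mostly_missing_patients_and_imputes(rng):
    X = rng.gamma(2.0, 50.0, size=(20, 40))
    df = make_table(X).data
    df.loc[0, list(DENSITY_COLUMNS)[:30]] = np.nan   # 75% missing: dropped
    df.loc[1, DENSITY_COLUMNS[0]] = np.nan           # single gap: imputed
    feats, params = preprocess_densities(MarkerDensityTable(df))
    assert params.dropped_samples == ["P0"]
    assert len(feats) == 19 and np.isfinite(feats.to_numpy()).all()


# ---------------------------------------------------------------------------
# region comparison
# ---------------------------------------------------------------------------

def test_identical_regions_give_p_one(rng):
    X = rng.gamma(2.0, 50.0, size=(12, 40))
    X = X.reshape(12, 20, 2)
    X[:, :, 1] = X[:, :, 0]  # peripheral == central
    out = compare_regions(make_table(X.reshape(12, 40)))
    assert (out["p"] == 1.0).all()


def test_wilcoxon_matches_exhaustive_enumeration(rng):
    n = 6
    X = rng.gamma(2.0, 50.0, size=(n, 40))
    out = compare_regions(make_table(X))
    row = out[out["marker"] == "CD45"].iloc[0]
    diffs = X[:, 1] - X[:, 0]  # CD45 peripheral - central
    assert row["p"] == pytest.approx(wilcoxon_exact_p(diffs), abs=1e-9)


def test_cd45_higher_in_periphery_on_synthetic_cohort(default_cohort):
    out = compare_regions(MarkerDensityTable(default_cohort.densities))
    row = out[out["marker"] == "CD45"].iloc[0]
    assert row["direction"] == "peripheral>central"
    assert row["q"] < 0.05


# ---------------------------------------------------------------------------
# correlation map
# ---------------------------------------------------------------------------

def test_correlation_monotone_and_antitone(rng):
    X = rng.gamma(2.0, 50.0, size=(15, 40))
    X[:, 1] = 2 * X[:, 0] + 1
    X[:, 2] = X[:, 2].max() + 1 - X[:, 2]
    cm = correlation_map(make_table(X))
    c = list(DENSITY_COLUMNS)
    assert cm.rho.loc[c[0], c[1]] == pytest.approx(1.0)
    assert np.allclose(np.diag(cm.rho), 1.0)
    assert ((cm.rho.fillna(0) - cm.rho.fillna(0).T).abs() < 1e-12).all().all()


def test_correlation_with_ties_matches_midrank_formula():
    x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
    y = np.array([2.0, 2.0, 5.0, 5.0, 6.0])
    X = np.tile(np.linspace(1, 2, 5)[:, None], (1, 40))
    X[:, 0], X[:, 1] = x, y

    def midrank(v):
        order = sps.rankdata(v, method="average")
        return order

    rx, ry = midrank(x), midrank(y)
    expected = np.corrcoef(rx, ry)[0, 1]
    cm = correlation_map(make_table(X))
    assert cm.rho.iloc[0, 1] == pytest.approx(expected, abs=1e-12)


def test_constant_feature_reported_missing():
    X = np.ones((10, 40))
    X[:, 1:] = np.random.default_rng(0).gamma(2, 50, size=(10, 39))
    cm = correlation_map(make_table(X))
    assert np.isnan(cm.rho.iloc[0, 1])


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

def test_separable_clouds_recovered():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(5, 0.1, (8, 3))])
    _, labels = ward_cluster(X, 2)
    assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
    assert labels[0] != labels[-1]


def test_k_equals_n_singletons(rng):
    X = rng.normal(size=(6, 4))
    _, labels = ward_cluster(X, 6)
    assert len(set(labels)) == 6


def test_k_larger_than_n_rejected(rng):
    with pytest.raises(ValueError):
        ward_cluster(rng.normal(size=(4, 2)), 5)


def test_ward_merge_sequence_matches_exhaustive_search():
    rng = np.random.default_rng(42)
    for _ in range(12):
        X = rng.normal(size=(7, 2))
        Z, _ = ward_cluster(X, 2)
        assert partitions_from_linkage(Z, 7) == ward_greedy_partitions(X)


# ---------------------------------------------------------------------------
# k selection
# ---------------------------------------------------------------------------

def test_three_spherical_clusters_give_k3():
    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(c, 0.2, (20, 5)) for c in (0.0, 4.0, 8.0)])
    X[:, 1:] = rng.normal(0, 0.2, (60, 4))
    X[:20, 1] += 4.0  # break collinearity
    k, votes = select_k(X, seed=0)
    assert k == 3


def test_single_blob_null_referenced_indices_nominate_k_min():
    # on unstructured Gaussian data the indices with a null reference (gap,
    # Hartigan) nominate k_min; the reference-free ratio indices are known
    # to drift toward k_max on noise, so no true-k consensus emerges
    rng = np.random.default_rng(8)
    X = rng.normal(size=(60, 5))
    k, votes = select_k(X, seed=0)
    nom = dict(zip(votes["index"], votes["best_k"]))
    assert nom["gap"] == 2
    assert nom["hartigan"] == 2
    assert (votes["best_k"] == 3).sum() == 0  # never hallucinates k=3


def test_index_values_match_direct_formulas(rng):
    # brute-force re-evaluation of each ratio index at k=2 on a small set
    from scipy.spatial.distance import pdist, squareform
    from sklearn.metrics import silhouette_score

    X = rng.normal(size=(14, 3))
    X[7:] += 4.0
    k, votes = select_k(X, k_min=2, k_max=4, seed=0)
    vals = votes.set_index("index")["k=2"]
    from chondroprofiler.immune import ward_cluster
    _, labels = ward_cluster(X, 2)
    d = squareform(pdist(X))
    iu = np.triu_indices(14, 1)
    same = (labels[:, None] == labels[None, :])[iu]
    dw, db = d[iu][same], d[iu][~same]
    # Dunn: min between-cluster distance over max within-cluster diameter
    assert vals["dunn"] == pytest.approx(db.min() / dw.max())
    # McClain-Rao: mean within / mean between
    assert vals["mcclain_rao"] == pytest.approx(dw.mean() / db.mean())
    # C-index: (S_w - S_min) / (S_max - S_min) over n_w smallest/largest
    ds = np.sort(d[iu])
    nw = len(dw)
    assert vals["c_index"] == pytest.approx(
        (dw.sum() - ds[:nw].sum()) / (ds[-nw:].sum() - ds[:nw].sum()))
    # point-biserial: correlation of distances with the between indicator
    assert vals["point_biserial"] == pytest.approx(
        np.corrcoef(d[iu], (~same).astype(float))[0, 1])
    # Calinski-Harabasz from explicit between/within dispersions
    overall = X.mean(axis=0)
    w_disp = sum(((X[labels == c] - X[labels == c].mean(axis=0)) ** 2).sum()
                 for c in np.unique(labels))
    b_disp = sum(len(X[labels == c]) *
                 ((X[labels == c].mean(axis=0) - overall) ** 2).sum()
                 for c in np.unique(labels))
    assert vals["calinski_harabasz"] == pytest.approx(
        (b_disp / 1) / (w_disp / (14 - 2)))
    assert vals["silhouette"] == pytest.approx(silhouette_score(X, labels))


def test_default_synthetic_cohort_selects_k3(default_cohort):
    table = MarkerDensityTable(default_cohort.densities)
    feats, _ = preprocess_densities(table)
    k, _ = select_k(feats, seed=0)
    assert k == 3


# ---------------------------------------------------------------------------
# adjusted Rand index
# ---------------------------------------------------------------------------

def test_ari_identity_and_relabeling():
    labels = [1, 1, 2, 2, 3, 3]
    assert adjusted_rand_index(labels, labels) == pytest.approx(1.0)
    assert adjusted_rand_index(labels, ["b", "b", "c", "c", "a", "a"]) == pytest.approx(1.0)


def test_ari_known_value_and_oracle():
    assert adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)
    assert ari_contingency([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)


def test_ari_length_mismatch():
    with pytest.raises(ValueError):
        adjusted_rand_index([1, 2], [1, 2, 3])


@settings(deadline=None, max_examples=50)
@given(st.lists(st.integers(0, 3), min_size=2, max_size=24))
def test_ari_matches_contingency_oracle_and_sklearn(labels):
    rng = np.random.default_rng(len(labels))
    other = rng.integers(0, 3, size=len(labels))
    ours = adjusted_rand_index(labels, other)
    assert ours == pytest.approx(ari_contingency(labels, other), abs=1e-12)
    assert ours == pytest.approx(adjusted_rand_score(labels, other), abs=1e-9)


# ---------------------------------------------------------------------------
# bootstrap stability
# ---------------------------------------------------------------------------

def test_perfectly_separated_clusters_fully_stable(rng):
    X = np.vstack([rng.normal(0, 0.05, (15, 40)), rng.normal(30, 0.05, (15, 40))])
    table = make_table(np.abs(X))
    feats, _ = preprocess_densities(table)
    _, labels = ward_cluster(feats, 2)
    orig = pd.Series(labels, index=table.samples.to_numpy())
    stab = bootstrap_stability(table, orig, k=2, B=30, seed=0)
    assert stab.mean == pytest.approx(1.0)


def test_bootstrap_b_zero_flagged():
    table = make_table(np.random.default_rng(0).gamma(2, 50, (10, 40)))
    stab = bootstrap_stability(table, pd.Series(1, index=table.samples.to_numpy()),
                               k=2, B=0, seed=0)
    assert len(stab.aris) == 0 and np.isnan(stab.mean)


def test_structureless_data_unstable(rng):
    X = rng.uniform(10, 1000, size=(40, 40))
    table = make_table(X)
    feats, _ = preprocess_densities(table)
    _, labels = ward_cluster(feats, 3)
    orig = pd.Series(labels, index=table.samples.to_numpy())
    stab = bootstrap_stability(table, orig, k=3, B=60, seed=1)
    assert stab.mean < 0.3


def test_stability_discriminates_structure(default_cohort, rng):
    table = MarkerDensityTable(default_cohort.densities)
    feats, _ = preprocess_densities(table)
    _, labels = ward_cluster(feats, 3)
    orig = pd.Series(labels, index=table.samples.to_numpy())
    real = bootstrap_stability(table, orig, k=3, B=40, seed=0).mean
    # destroy structure by shuffling each feature independently
    shuffled = table.data.copy()
    for c in DENSITY_COLUMNS:
        shuffled[c] = rng.permutation(shuffled[c].to_numpy())
    tab2 = MarkerDensityTable(shuffled)
    feats2, _ = preprocess_densities(tab2)
    _, lab2 = ward_cluster(feats2, 3)
    fake = bootstrap_stability(tab2, pd.Series(lab2, index=tab2.samples.to_numpy()),
                               k=3, B=40, seed=0).mean
    assert real > fake


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_collinear_data_one_component(rng):
    t = rng.normal(size=40)
    X = np.outer(t, [1.0, -2.0, 0.5])
    _, evr = pca_contributions(X)
    assert evr[0] == pytest.approx(1.0)


def test_isotropic_data_flat_spectrum(rng):
    X = rng.normal(size=(4000, 3))
    _, evr = pca_contributions(X)
    assert evr.max() - evr.min() < 0.05
    assert evr.sum() == pytest.approx(1.0)


def test_loadings_match_eigendecomposition(rng):
    X = rng.normal(size=(4, 3)) @ np.diag([3.0, 1.0, 0.2])
    loadings, evr = pca_contributions(X)
    C = np.cov(X, rowvar=False, ddof=1)
    w, v = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    for i in range(3):
        ours = loadings.iloc[:, i].to_numpy()
        ref = v[:, i]
        assert np.allclose(np.abs(ours), np.abs(ref), atol=1e-8)
    assert np.allclose(evr, w / w.sum(), atol=1e-8)


def test_pca_requires_two_rows():
    with pytest.raises(ValueError):
        pca_contributions(np.ones((1, 3)))


# ---------------------------------------------------------------------------
# PD-L1, TLS, IMP naming
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("pct,score", [
    (0.0, 0), (0.5, 0), (0.99, 0), (1.0, 1), (15.0, 1), (29.99, 1),
    (30.0, 2), (95.0, 2), (100.0, 2),
])
def test_pdl1_scale(pct, score):
    assert score_pdl1(pct) == score


def test_pdl1_out_of_range():
    with pytest.raises(ValueError):
        score_pdl1(101.0)
    with pytest.raises(ValueError):
        score_pdl1(-0.1)


@pytest.mark.parametrize("flags,expected", [
    ((True, True, True), True),
    ((True, True, False), False),
    ((False, False, False), False),
    ((False, True, True), False),
])
def test_tls_conjunction(flags, expected):
    assert call_tls(*flags) is expected


def test_imp_naming_orders_by_density(default_cohort):
    table = MarkerDensityTable(default_cohort.densities)
    feats, _ = preprocess_densities(table)
    _, labels = ward_cluster(feats, 3)
    named, mapping = name_imps(labels, table)
    truth = default_cohort.densities.set_index("sample")["imp_true"]
    agreement = (named == truth.reindex(named.index)).mean()
    assert agreement > 0.9  # permutation-correct naming vs ground truth


def test_imp_naming_generic_for_k_not_3(rng):
    table = make_table(rng.gamma(2, 50, (12, 40)))
    _, labels = ward_cluster(preprocess_densities(table)[0], 4)
    with pytest.warns(RuntimeWarning, match="generically"):
        named, mapping = name_imps(labels, table)
    assert set(named) == {"IMP1", "IMP2", "IMP3", "IMP4"}
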