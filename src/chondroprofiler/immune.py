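"""Immunophenotype discovery from immune-marker densities.

The tumor immune microenvironment is profiled by IHC densities of 20
markers in the central and peripheral tumor regions (cells/mm2).  This
module preprocesses the 40-feature density matrix (log1p + z-score),
compares regions per marker, builds a Spearman correlation map, clusters
patients hierarchically (Ward D2 on Euclidean distances), selects the
number of clusters by a majority vote of validity indices, quantifies
cluster stability by bootstrap adjusted Rand indices, and names the
resulting immunophenotypes IMP1 ("cold"), IMP2 ("hot") and IMP3
("intermediate") by total immune-cell density.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)
from statsmodels.stats.multitest import multipletests

from .synth import DENSITY_COLUMNS, MARKERS, REGIONS

log = logging.getLogger(__name__)

__all__ = [
    "MarkerDensityTable",
    "CorrelationMap",
    "ImmunophenotypeModel",
    "preprocess_densities",
    "compare_regions",
    "correlation_map",
    "ward_cluster",
    "select_k",
    "adjusted_rand_index",
    "bootstrap_stability",
    "pca_contributions",
    "score_pdl1",
    "call_tls",
    "name_imps",
]

VALIDITY_INDICES = (
    "calinski_harabasz", "silhouette", "davies_bouldin", "dunn", "c_index",
    "mcclain_rao", "point_biserial", "gap", "hartigan",
)


# ---------------------------------------------------------------------------
# container types
# ---------------------------------------------------------------------------

@dataclass
class MarkerDensityTable:
    """Patients x (marker, region) density matrix with auxiliary calls.

    ``data`` is wide with one row per patient: the 40 canonical density
    columns plus pdl1_percent, tls_cd3/cd20/lamp3 and subtype.  Missing
    cores are NaN, never zero-filled.
    """

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in DENSITY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing density columns: {missing[:4]}...")
        if (self.data[list(DENSITY_COLUMNS)] < 0).any().any():
            raise ValueError("densities must be non-negative")

    @classmethod
    def from_long_csv(cls, path) -> "MarkerDensityTable":
        """Read the long density CSV dialect (patient_id, marker, region, ...)."""
        long = pd.read_csv(path)
        wide = long.pivot_table(
            index="patient_id", columns=["marker", "region"],
            values="density_per_mm2", aggfunc="first", dropna=False,
        )
        wide.columns = [f"{m}_{r}" for m, r in wide.columns]
        aux = long.groupby("patient_id").first()[
            ["pdl1_percent", "tls_cd3", "tls_cd20", "tls_lamp3", "subtype"]
        ]
        df = wide.join(aux).reset_index().rename(columns={"patient_id": "sample"})
        return cls(df)

    @property
    def samples(self) -> pd.Series:
        return self.data["sample"]

    def density_matrix(self) -> pd.DataFrame:
        return self.data.set_index("sample")[list(DENSITY_COLUMNS)]


@dataclass
class CorrelationMap:
    rho: pd.DataFrame    # 40x40 Spearman rho
    q: pd.DataFrame      # BH-adjusted over the strict upper triangle


@dataclass
class PreprocessParams:
    center: pd.Series
    scale: pd.Series
    feature_medians: pd.Series  # log1p-scale medians used for imputation
    dropped_samples: list = field(default_factory=list)


@dataclass
class ImmunophenotypeModel:
    params: PreprocessParams
    linkage: np.ndarray
    k: int
    labels: pd.Series              # patient -> IMP name
    votes: pd.DataFrame | None = None
    stability: "StabilityResult | None" = None
    cluster_to_imp: dict | None = None


@dataclass
class StabilityResult:
    aris: np.ndarray
    n_skipped: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.aris)) if len(self.aris) else float("nan")


# ---------------------------------------------------------------------------
# preprocessing and univariate analyses
# ---------------------------------------------------------------------------

def preprocess_densities(
    table: MarkerDensityTable, max_missing_fraction: float = 0.25
) -> tuple[pd.DataFrame, PreprocessParams]:
    """log(1 + density) then per-feature z-scoring.

    Patients missing more than ``max_missing_fraction`` of features are
    excluded; remaining gaps are imputed with the feature median on the
    log scale (both logged).  An all-constant feature keeps scale 1 with a
    warning rather than dividing by zero.
    """
    raw = table.density_matrix()
    frac_missing = raw.isna().mean(axis=1)
    dropped = raw.index[frac_missing > max_missing_fraction].tolist()
    if dropped:
        log.info("excluding %d patients with >%.0f%% missing cores: %s",
                 len(dropped), 100 * max_missing_fraction, dropped)
    kept = raw.drop(index=dropped)
    logged = np.log1p(kept)
    medians = logged.median()
    if logged.isna().any().any():
        log.info("imputing %d missing values with feature medians",
                 int(logged.isna().sum().sum()))
    logged = logged.fillna(medians)
    center = logged.mean()
    scale = logged.std(ddof=0)
    constant = scale <= 0
    if constant.any():
        warnings.warn(
            f"constant features scaled by 1: {list(scale.index[constant])}",
            RuntimeWarning, stacklevel=2,
        )
        scale = scale.mask(constant, 1.0)
    features = (logged - center) / scale
    return features, PreprocessParams(center, scale, medians, dropped)


def compare_regions(table: MarkerDensityTable) -> pd.DataFrame:
    """Paired central-vs-peripheral comparison per marker.

    Two-sided Wilcoxon signed-rank on patients with both regions present,
    Benjamini-Hochberg correction across markers.  Direction reports which
    region has the larger median density.
    """
    raw = table.density_matrix()
    rows = []
    for m in MARKERS:
        pair = raw[[f"{m}_central", f"{m}_peripheral"]].dropna()
        if len(pair) < 2:
            log.info("marker %s skipped in region comparison (<2 complete pairs)", m)
            continue
        c, p = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
        if np.allclose(c, p):
            stat, pval = 0.0, 1.0
        else:
            res = stats.wilcoxon(c, p, zero_method="wilcox", alternative="two-sided")
            stat, pval = float(res.statistic), float(res.pvalue)
        direction = "peripheral>central" if np.median(p - c) > 0 else (
            "central>peripheral" if np.median(p - c) < 0 else "none")
        rows.append({"marker": m, "statistic": stat, "p": pval, "direction": direction})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def correlation_map(table: MarkerDensityTable, min_pairs: int = 3) -> CorrelationMap:
    """Spearman correlation between all 40 density features with BH q-values.

    Ranks use midranks on ties.  Pairs involving a constant feature (rho
    undefined) are reported as missing; q-values are adjusted over the
    strict upper triangle.
    """
    raw = table.density_matrix()
    cols = list(DENSITY_COLUMNS)
    n = len(cols)
    rho = np.full((n, n), np.nan)
    pmat = np.full((n, n), np.nan)
    np.fill_diagonal(rho, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            pair = raw[[cols[i], cols[j]]].dropna()
            if len(pair) < min_pairs:
                continue
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.nunique() < 2 or y.nunique() < 2:
                continue  # constant feature: rho undefined
            r, p = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    iu = np.triu_indices(n, k=1)
    pvec = pmat[iu]
    qmat = np.full((n, n), np.nan)
    ok = ~np.isnan(pvec)
    if ok.any():
        qvec = np.full(len(pvec), np.nan)
        qvec[ok] = multipletests(pvec[ok], method="fdr_bh")[1]
        qmat[iu] = qvec
        qmat[(iu[1], iu[0])] = qvec
    return CorrelationMap(
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        q=pd.DataFrame(qmat, index=cols, columns=cols),
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def ward_cluster(features: pd.DataFrame | np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Ward-D2 agglomeration on Euclidean distances, cut at k clusters.

    Returns (linkage matrix, labels in 1..k).  Deterministic given input
    order; scipy breaks merge ties by the pair found first at the minimal
    Ward increase.
    """
    X = np.asarray(features, dtype=float)
    if np.isnan(X).any():
        raise ValueError("features contain missing values; preprocess first")
    if k > len(X):
        raise ValueError(f"k={k} exceeds n={len(X)}")
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return Z, labels


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected Rand agreement from the contingency table.

    ARI = (sum_ij C(n_ij,2) - E) / (M - E), where E and M follow from the
    row/column marginals; 1 iff the partitions agree up to relabelling.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    n = len(a)
    ct = pd.crosstab(a, b).to_numpy()
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(ct).sum()
    sum_a = comb(ct.sum(axis=1)).sum()
    sum_b = comb(ct.sum(axis=0)).sum()
    total = comb(n)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _within_dispersion(X, labels):
    w = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        w += ((pts - pts.mean(axis=0)) ** 2).sum()
    return w


def _index_values(X, dists, sq, labels_by_k, ks, name, rng):
    """Value of one validity index for each candidate k (same ward labels)."""
    vals = {}
    if name == "calinski_harabasz":
        return {k: calinski_harabasz_score(X, labels_by_k[k]) for k in ks}, "max"
    if name == "silhouette":
        return {k: silhouette_score(X, labels_by_k[k]) for k in ks}, "max"
    if name == "davies_bouldin":
        return {k: davies_bouldin_score(X, labels_by_k[k]) for k in ks}, "min"
    if name == "dunn":
        for k in ks:
            labs = labels_by_k[k]
            same = labs[:, None] == labs[None, :]
            iu = np.triu_indices(len(labs), 1)
            within = sq[iu][same[iu]]
            between = sq[iu][~same[iu]]
            vals[k] = between.min() / within.max() if len(within) and len(between) else np.nan
        return vals, "max"
    if name == "c_index":
        iu = np.triu_indices(len(X), 1)
        d = np.sort(sq[iu])
        for k in ks:
            labs = labels_by_k[k]
            same = (labs[:, None] == labs[None, :])[iu]
            nw = int(same.sum())
            sw = sq[iu][same].sum()
            smin, smax = d[:nw].sum(), d[-nw:].sum()
            vals[k] = (sw - smin) / (smax - smin) if smax > smin else np.nan
        return vals, "min"
    if name == "mcclain_rao":
        iu = np.triu_indices(len(X), 1)
        for k in ks:
            labs = labels_by_k[k]
            same = (labs[:, None] == labs[None, :])[iu]
            dw, db = sq[iu][same], sq[iu][~same]
            vals[k] = (dw.mean() / db.mean()) if len(dw) and len(db) else np.nan
        return vals, "min"
    if name == "point_biserial":
        iu = np.triu_indices(len(X), 1)
        dv = sq[iu]
        for k in ks:
            labs = labels_by_k[k]
            between = (~(labs[:, None] == labs[None, :])[iu]).astype(float)
            vals[k] = float(np.corrcoef(dv, between)[0, 1]) if between.std() else np.nan
        return vals, "max"
    if name == "gap":
        B = 50
        lo, hi = X.min(axis=0), X.max(axis=0)
        ref_logw = np.zeros((B, len(ks)))
        for b in range(B):
            R = rng.uniform(lo, hi, size=X.shape)
            Zr = linkage(R, method="ward")
            for idx, k in enumerate(ks):
                ref_logw[b, idx] = np.log(
                    _within_dispersion(R, fcluster(Zr, t=k, criterion="maxclust"))
                )
        logw = np.array([np.log(_within_dispersion(X, labels_by_k[k])) for k in ks])
        gap = ref_logw.mean(axis=0) - logw
        s = ref_logw.std(axis=0) * np.sqrt(1 + 1.0 / B)
        # Tibshirani rule: smallest k with Gap(k) >= Gap(k+1) - s(k+1)
        for idx, k in enumerate(ks[:-1]):
            if gap[idx] >= gap[idx + 1] - s[idx + 1]:
                return {k: 1.0}, "vote"
        return {ks[-1]: 1.0}, "vote"
    if name == "hartigan":
        W = {k: _within_dispersion(X, labels_by_k[k]) for k in ks + [ks[-1] + 1]}
        n = len(X)
        for k in ks:
            h = (W[k] / W[k + 1] - 1.0) * (n - k - 1)
            if h <= 10.0:
                return {k: 1.0}, "vote"
        return {ks[-1]: 1.0}, "vote"
    raise ValueError(f"unknown validity index {name!r}")


def select_k(
    features,
    k_min: int = 2,
    k_max: int = 8,
    indices: tuple = VALIDITY_INDICES,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the cluster number by majority vote of validity indices.

    Each index nominates one k in [k_min, k_max] from the Ward-tree labels;
    the winner is the k with the most nominations, ties broken toward the
    smaller k.  Returns (k, vote table with per-index values).
    """
    X = np.asarray(features, dtype=float)
    if k_max >= len(X):
        raise ValueError("k_max must be smaller than the number of patients")
    rng = np.random.default_rng(seed)
    Z = linkage(X, method="ward")
    ks = list(range(k_min, k_max + 1))
    labels_by_k = {k: fcluster(Z, t=k, criterion="maxclust") for k in ks + [k_max + 1]}
    dists = pdist(X)
    sq = squareform(dists)
    rows, nominations = [], []
    for name in indices:
        vals, rule = _index_values(X, dists, sq, labels_by_k, ks, name, rng)
        if rule == "vote":
            best = next(iter(vals))
        else:
            clean = {k: v for k, v in vals.items() if np.isfinite(v)}
            if not clean:
                continue
            # ties toward the smaller k: iterate candidate ks in order
            if rule == "max":
                best = max(sorted(clean), key=lambda k: clean[k])
            else:
                best = min(sorted(clean), key=lambda k: clean[k])
        nominations.append(best)
        rows.append({"index": name, "best_k": best,
                     **{f"k={k}": vals.get(k, np.nan) for k in ks}})
    if not nominations:
        raise ValueError("all validity indices undefined on this data")
    votes = pd.Series(nominations).value_counts()
    top = votes.max()
    k = min(votes[votes == top].index)
    return int(k), pd.DataFrame(rows)


def bootstrap_stability(
    table: MarkerDensityTable,
    original_labels: pd.Series,
    k: int,
    B: int = 1000,
    seed: int = 0,
) -> StabilityResult:
    """Bootstrap cluster stability against the original solution.

    Each of B iterations resamples patients with replacement, re-runs
    preprocessing and Ward clustering at fixed k on the resample, and
    computes the ARI between the resample's labels and the original labels
    restricted to the distinct resampled patients (first occurrence per
    patient).  Iterations whose resample has fewer than k distinct
    patients are skipped and logged.
    """
    rng = np.random.default_rng(seed)
    data = table.data.reset_index(drop=True)
    idx_of = {s: i for i, s in enumerate(data["sample"])}
    orig = original_labels
    aris, skipped = [], 0
    for _ in range(B):
        draw = rng.integers(0, len(data), size=len(data))
        first = pd.unique(draw)  # first occurrence per distinct patient
        if len(first) < k:
            skipped += 1
            log.info("bootstrap resample with <k distinct patients skipped")
            continue
        sub = MarkerDensityTable(data.iloc[first].reset_index(drop=True))
        feats, _ = preprocess_densities(sub)
        _, labs = ward_cluster(feats, k)
        ref = orig.iloc[[idx_of[s] for s in sub.data["sample"]]].to_numpy()
        aris.append(adjusted_rand_index(labs, ref))
    return StabilityResult(np.array(aris), n_skipped=skipped)


def pca_contributions(features) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA loadings and explained-variance fractions of the feature matrix.

    Loadings are orthonormal; the largest-magnitude loading of each
    component is made positive so signs are reproducible.
    """
    X = np.asarray(features, dtype=float)
    if len(X) < 2:
        raise ValueError("PCA requires at least 2 patients")
    pca = PCA()
    pca.fit(X)
    load = pca.components_
    for i in range(load.shape[0]):
        j = np.argmax(np.abs(load[i]))
        if load[i, j] < 0:
            load[i] = -load[i]
    cols = features.columns if hasattr(features, "columns") else range(X.shape[1])
    loadings = pd.DataFrame(
        load.T, index=cols, columns=[f"PC{i+1}" for i in range(load.shape[0])]
    )
    return loadings, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# scoring and naming
# ---------------------------------------------------------------------------

def score_pdl1(percent_positive: float) -> int:
    """Ordinal PD-L1 score: 0 (<1%), 1 (1-30%), 2 (>=30%)."""
    if not 0.0 <= percent_positive <= 100.0:
        raise ValueError(f"percent positive out of range: {percent_positive}")
    if percent_positive < 1.0:
        return 0
    if percent_positive < 30.0:
        return 1
    return 2


def call_tls(cd3_pos: bool, cd20_pos: bool, lamp3_pos: bool) -> bool:
    """Tertiary lymphoid structure: T cells, B cells and DCs all present."""
    return bool(cd3_pos) and bool(cd20_pos) and bool(lamp3_pos)


def name_imps(labels: np.ndarray, table: MarkerDensityTable) -> tuple[pd.Series, dict]:
    """Name clusters by mean total raw density: lowest IMP1, highest IMP2.

    With three clusters the middle one is IMP3 ("intermediate").  For k !=
    3 clusters are named IMP1..IMPk in increasing density order, with a
    warning.  Ties are broken by cluster index (logged).
    """
    raw = table.density_matrix()
    labels = np.asarray(labels)
    total = raw.sum(axis=1).to_numpy()
    clusters = sorted(np.unique(labels))
    means = {c: float(total[labels == c].mean()) for c in clusters}
    if len(set(means.values())) < len(clusters):
        log.info("tied cluster mean densities; breaking ties by cluster index")
    order = sorted(clusters, key=lambda c: (means[c], c))
    if len(clusters) == 3:
        mapping = {order[0]: "IMP1", order[2]: "IMP2", order[1]: "IMP3"}
    else:
        warnings.warn(
            f"{len(clusters)} clusters: naming generically IMP1..IMP{len(clusters)}",
            RuntimeWarning, stacklevel=2,
        )
        mapping = {c: f"IMP{i+1}" for i, c in enumerate(order)}
    named = pd.Series([mapping[c] for c in labels], index=table.samples.to_numpy(),
                      name="imp")
    return named, mapping
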