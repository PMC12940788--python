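"""Cohort-level association statistics for mutation and TMB profiles.

Builds the patient-by-gene mutation matrix from cascade output (a gene
counts as mutated when it carries any retained SNV/INDEL or a CNV event),
tests per-gene prevalence differences across histological subtypes with
exact tests, compares TMB between groups, screens gene pairs for
co-occurrence / mutual exclusivity, and maps altered genes onto curated
signalling pathways.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "MutationMatrix",
    "build_mutation_matrix",
    "fisher_exact_table",
    "gene_subtype_test",
    "tmb_by_group",
    "cooccurrence",
    "PathwayMap",
    "load_pathway_map",
    "pathway_deregulation",
]


# ---------------------------------------------------------------------------
# mutation matrix
# ---------------------------------------------------------------------------

@dataclass
class MutationMatrix:
    """Patients x genes binary flags with per-cell variant-class labels."""

    flags: pd.DataFrame    # 0/1, index = samples
    classes: pd.DataFrame  # "", "SNV", "INDEL", "Amp", "Del" or "Multi"

    def gene_prevalence(self) -> pd.Series:
        return self.flags.mean().sort_values(ascending=False)


def build_mutation_matrix(profiles: dict, cnv: pd.DataFrame | None = None) -> MutationMatrix:
    """Assemble the oncoprint matrix from per-sample cascade profiles.

    ``profiles`` maps sample -> SampleVariantProfile.  A CNV event table
    (sample, gene, type) contributes Amp/Del calls; a cell with both a
    small variant and a CNV is labelled "Multi".
    """
    samples = sorted(profiles)
    cells: dict = {}
    for s in samples:
        for rec in profiles[s].final:
            if rec.gene is None:
                continue
            label = "INDEL" if rec.var_class == "INDEL" else "SNV"
            prev = cells.get((s, rec.gene))
            cells[(s, rec.gene)] = label if prev in (None, label) else "Multi"
    if cnv is not None:
        for _, row in cnv.iterrows():
            if row["sample"] not in profiles:
                continue
            label = "Amp" if row["type"] == "amp" else "Del"
            prev = cells.get((row["sample"], row["gene"]))
            cells[(row["sample"], row["gene"])] = label if prev is None else "Multi"
    genes = sorted({g for _, g in cells})
    flags = pd.DataFrame(0, index=samples, columns=genes, dtype=int)
    classes = pd.DataFrame("", index=samples, columns=genes, dtype=object)
    for (s, g), label in cells.items():
        flags.loc[s, g] = 1
        classes.loc[s, g] = label
    return MutationMatrix(flags=flags, classes=classes)


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

def _log_comb(n, k):
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact_table(table) -> float:
    """Two-sided Fisher exact p for an r x c contingency table.

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more probable than the observed table (the
    standard exact-network two-sided definition; for 2 x 2 this equals
    the classical two-sided Fisher test).
    """
    t = np.asarray(table, dtype=int)
    if t.min() < 0:
        raise ValueError("negative cell count")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())
    if n == 0:
        return 1.0
    # probability of a table with fixed margins:
    #   P(T) = [prod_i r_i! * prod_j c_j!] / [n! * prod_ij t_ij!]
    log_const = (
        sum(math.lgamma(r + 1) for r in rows)
        + sum(math.lgamma(c + 1) for c in cols)
        - math.lgamma(n + 1)
    )

    def log_p(cells):
        return log_const - sum(math.lgamma(x + 1) for x in cells)

    obs_lp = log_p(t.ravel())
    if t.shape[0] == 2:
        return _fisher_2xc(t, obs_lp, log_const)
    # enumerate tables row by row with running column remainders
    total = 0.0
    r_, c_ = len(rows), len(cols)

    def rec(i, col_rem, acc):
        nonlocal total
        if i == r_ - 1:
            cells = acc + list(col_rem)
            if all(x >= 0 for x in col_rem):
                lp = log_p(cells)
                if lp <= obs_lp + 1e-9:
                    total += math.exp(lp)
            return
        def fill(j, rem_row, partial):
            if j == c_ - 1:
                if 0 <= rem_row <= col_rem[j]:
                    rec(i + 1,
                        tuple(col_rem[q] - (partial + [rem_row])[q] for q in range(c_)),
                        acc + partial + [rem_row])
                return
            for v in range(min(rem_row, col_rem[j]) + 1):
                fill(j + 1, rem_row - v, partial + [v])
        fill(0, int(rows[i]), [])

    rec(0, tuple(int(c) for c in cols), [])
    return min(total, 1.0)


def _fisher_2xc(t, obs_lp, log_const):
    """Vectorized exact enumeration for 2 x c tables."""
    from scipy.special import gammaln

    cols = t.sum(axis=0)
    r0 = int(t[0].sum())
    # grid over the first c-1 cells of row 0; the last is determined
    axes = [np.arange(min(r0, c) + 1) for c in cols[:-1]]
    grids = np.meshgrid(*axes, indexing="ij") if axes else []
    partial = sum(grids) if axes else np.zeros(())
    last = r0 - partial
    valid = (last >= 0) & (last <= cols[-1])
    lp = np.full(partial.shape, -np.inf)
    acc = np.zeros(partial.shape)
    for g, c in zip(grids, cols[:-1]):
        acc = acc + gammaln(g + 1) + gammaln(c - g + 1)
    safe_last = np.clip(last, 0, cols[-1])
    acc = acc + gammaln(safe_last + 1) + gammaln(cols[-1] - safe_last + 1)
    lp = np.where(valid, log_const - acc, -np.inf)
    mask = lp <= obs_lp + 1e-9
    return float(min(np.exp(lp[mask & np.isfinite(lp)]).sum(), 1.0))


def gene_subtype_test(
    matrix: MutationMatrix, subtypes: pd.Series, min_mutated: int = 3
) -> pd.DataFrame:
    """Exact test of mutation prevalence across subtypes, per gene, with FDR.

    Each gene's 2 x (number of subtypes) table (mutated / wild-type by
    subtype) is tested exactly; Benjamini-Hochberg correction runs across
    the tested genes.  Genes mutated in fewer than ``min_mutated``
    patients are skipped (logged).
    """
    subtypes = pd.Series(subtypes).reindex(matrix.flags.index)
    if subtypes.nunique() < 2:
        raise ValueError("at least two subtypes required")
    levels = sorted(subtypes.dropna().unique())
    rows = []
    for g in matrix.flags.columns:
        flag = matrix.flags[g]
        if flag.sum() == 0:
            log.info("gene %s mutated in no patient; skipped", g)
            continue
        if flag.sum() < min_mutated:
            continue
        table = np.array([
            [int(((subtypes == s) & (flag == 1)).sum()) for s in levels],
            [int(((subtypes == s) & (flag == 0)).sum()) for s in levels],
        ])
        p = fisher_exact_table(table)
        prev = {f"n_{s}": int(table[0, i]) for i, s in enumerate(levels)}
        rows.append({"gene": g, "p": p, "n_mutated": int(flag.sum()), **prev})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values("q").reset_index(drop=True)
    return out


def tmb_by_group(tmb_values, groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test of TMB between groups; returns (H, p).

    Tie-corrected H with a chi-square reference on k-1 df.  Degenerate
    all-tied data yields H = 0, p = 1.
    """
    tmb_values = np.asarray(tmb_values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("at least two groups required")
    samples = [tmb_values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if len(np.unique(tmb_values)) == 1:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def cooccurrence(matrix: MutationMatrix, min_mutated: int = 1) -> pd.DataFrame:
    """Pairwise co-occurrence / mutual exclusivity of gene mutations.

    2 x 2 Fisher exact test per gene pair; the direction comes from the
    odds ratio (co-occurring when OR > 1).  Raw p and BH-adjusted q are
    both reported.
    """
    genes = [g for g in matrix.flags.columns if matrix.flags[g].sum() >= min_mutated]
    rows = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1:]:
            a = matrix.flags[ga].to_numpy()
            b = matrix.flags[gb].to_numpy()
            t = np.array([
                [int(((a == 1) & (b == 1)).sum()), int(((a == 1) & (b == 0)).sum())],
                [int(((a == 0) & (b == 1)).sum()), int(((a == 0) & (b == 0)).sum())],
            ])
            odds, p = stats.fisher_exact(t, alternative="two-sided")
            rows.append({
                "gene_a": ga, "gene_b": gb, "n_both": int(t[0, 0]),
                "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
                "p": float(p),
                "direction": "co-occurring" if odds > 1 else (
                    "exclusive" if odds < 1 else "independent"),
            })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values("p").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# pathway mapping
# ---------------------------------------------------------------------------

@dataclass
class PathwayMap:
    """gene -> primary pathway label, loaded from an editable CSV."""

    mapping: dict

    def pathway_of(self, gene: str) -> str | None:
        return self.mapping.get(gene)


def load_pathway_map(path=None) -> PathwayMap:
    """Load the pathway curation CSV (columns gene, pathway)."""
    if path is None:
        ref = resources.files("chondroprofiler.data") / "pathway_map.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    dup = df["gene"][df["gene"].duplicated()]
    if len(dup):
        raise ValueError(f"gene mapped to multiple pathways: {sorted(set(dup))}")
    return PathwayMap(dict(zip(df["gene"], df["pathway"])))


def pathway_deregulation(
    matrix: MutationMatrix, pmap: PathwayMap, strata: pd.Series | None = None
) -> tuple[pd.DataFrame, list]:
    """Percentage of patients with any altered gene per pathway, by stratum.

    A patient counts for a pathway when any mapped gene is altered.  Genes
    absent from the map are excluded and returned in the unmapped ledger.
    Percentages are invariant to patient and gene order.
    """
    if not pmap.mapping:
        raise ValueError("empty pathway map")
    unmapped = sorted(g for g in matrix.flags.columns if pmap.pathway_of(g) is None)
    if unmapped:
        log.info("genes without pathway mapping: %s", unmapped)
    pathways = sorted({pmap.pathway_of(g) for g in matrix.flags.columns} - {None})
    hit = pd.DataFrame(index=matrix.flags.index, columns=pathways, data=0)
    for g in matrix.flags.columns:
        pw = pmap.pathway_of(g)
        if pw is not None:
            hit[pw] |= matrix.flags[g]
    strata = (pd.Series("all", index=matrix.flags.index)
              if strata is None else pd.Series(strata).reindex(matrix.flags.index))
    rows = []
    for level in sorted(strata.dropna().unique()):
        sub = hit[strata == level]
        for pw in pathways:
            rows.append({"stratum": str(level), "pathway": pw,
                         "percent_altered": 100.0 * sub[pw].mean(),
                         "n_patients": len(sub)})
    return pd.DataFrame(rows), unmapped
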