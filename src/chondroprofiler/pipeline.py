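"""End-to-end orchestration: simulate -> cluster -> variants -> stats ->
survival -> immunograms, with a reproducible manifest.

Each stage reads the plain-text outputs of its upstream stages from the
run directory, so stages can be re-run individually; a stage whose inputs
are missing aborts with the missing path named.  The manifest records the
configuration, seeds and a SHA-256 digest of every output file, and two
runs with the same configuration produce identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import immune, immunogram, stats, survival as surv, synth, variants as var

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "STAGES"]

STAGES = ("simulate", "cluster", "variants", "stats", "survive", "immunogram")


@dataclass
class RunConfig:
    """Pipeline configuration; every cascade threshold is a named key."""

    outdir: str = "run"
    seed: int = 0
    stages: tuple = STAGES
    generator: dict = field(default_factory=dict)     # GeneratorConfig overrides
    thresholds: dict = field(default_factory=dict)    # FilterThresholds overrides
    k: int | None = None                              # fixed cluster count; None = select
    k_min: int = 2
    k_max: int = 8
    bootstrap_B: int = 1000
    lasso_folds: int = 10
    min_mutated: int = 3
    pathway_map: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def generator_config(self) -> synth.GeneratorConfig:
        params = dict(self.generator)
        params.setdefault("seed", self.seed)
        return synth.GeneratorConfig(**params)

    def filter_thresholds(self) -> var.FilterThresholds:
        th = var.FilterThresholds()
        for k, v in self.thresholds.items():
            if not hasattr(th, k):
                raise ValueError(f"unknown threshold {k!r}")
            default = getattr(th, k)
            setattr(th, k, type(default)(v))
        return th


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' requires missing input {path}; run its upstream stage"
        )
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = out / "inputs"
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {}}

    def record(stage, paths):
        manifest["stages"].append(stage)
        for name, p in paths.items():
            p = Path(p)
            if p.is_file():
                manifest["outputs"][f"{stage}/{name}"] = _digest(p)

    try:
        if "simulate" in config.stages:
            cohort = synth.generate_cohort(config.generator_config())
            paths = cohort.write(inputs)
            record("simulate", paths)

        if "cluster" in config.stages:
            table = immune.MarkerDensityTable.from_long_csv(
                _require(inputs / "densities.csv", "cluster")
            )
            feats, params = immune.preprocess_densities(table)
            if config.k is None:
                k, votes = immune.select_k(feats, config.k_min, config.k_max,
                                           seed=config.seed)
            else:
                k, votes = config.k, None
            _, labels = immune.ward_cluster(feats, k)
            named, mapping = immune.name_imps(labels, table)
            stab = immune.bootstrap_stability(table, named, k, B=config.bootstrap_B,
                                              seed=config.seed)
            comp = immune.compare_regions(table)
            cmap = immune.correlation_map(table)
            loadings, evr = immune.pca_contributions(feats)
            named.rename("imp").to_frame().rename_axis("sample").to_csv(out / "imp_assignments.csv")
            cmap.rho.to_csv(out / "correlation_map.csv")
            comp.to_csv(out / "region_comparison.csv", index=False)
            loadings.iloc[:, :5].to_csv(out / "pca_loadings.csv")
            (out / "stability.json").write_text(json.dumps({
                "k": int(k), "B": int(config.bootstrap_B),
                "mean_ari": stab.mean, "n_skipped": stab.n_skipped,
                "explained_variance_pc1": float(evr[0]),
                "votes": None if votes is None else votes["best_k"].tolist(),
            }, indent=1))
            record("cluster", {
                "imp_assignments": out / "imp_assignments.csv",
                "correlation_map": out / "correlation_map.csv",
                "region_comparison": out / "region_comparison.csv",
                "pca_loadings": out / "pca_loadings.csv",
                "stability": out / "stability.json",
            })

        if "variants" in config.stages:
            th = config.filter_thresholds()
            vdir = _require(inputs / "vcf", "variants")
            meta_df = pd.read_csv(_require(inputs / "sample_meta.csv", "variants"))
            pool = var.parse_caller_vcf(_require(vdir / "pool.vcf", "variants"), "GATK")
            pool_keys = {r.key for r in pool}
            ledger_rows, tmb_rows = [], []
            profiles = {}
            fdir = out / "final_variants"
            fdir.mkdir(exist_ok=True)
            for _, mrow in meta_df.iterrows():
                s = mrow["sample"]
                meta = var.SampleMeta(sample=s,
                                      deamination_score=mrow["deamination_score"],
                                      preliminary_tmb=mrow["preliminary_tmb"])
                sets = {d: var.parse_caller_vcf(_require(vdir / f"{s}.{d}.vcf", "variants"), d)
                        for d in var.DIALECTS}
                prof = var.run_cascade(sets, pool_keys, meta, th)
                profiles[s] = prof
                var.write_vcf(prof.final, fdir / f"{s}.final.vcf", s)
                tmb_rows.append({"sample": s, "n_final": prof.n_final, "tmb": prof.tmb})
                for stage, keys in prof.ledger.items():
                    for kkey in keys:
                        ledger_rows.append({"sample": s, "stage": stage,
                                            "chrom": kkey[0], "pos": kkey[1],
                                            "ref": kkey[2], "alt": kkey[3]})
            pd.DataFrame(tmb_rows).to_csv(out / "tmb.csv", index=False)
            pd.DataFrame(ledger_rows).to_csv(out / "removal_ledger.tsv", sep="\t", index=False)
            cnv = pd.read_csv(_require(inputs / "cnv.csv", "variants"))
            clinical = pd.read_csv(_require(inputs / "clinical.csv", "variants"))
            (out / "cnv_summary.json").write_text(
                json.dumps(var.summarize_cnv(cnv, clinical), indent=1)
            )
            matrix = stats.build_mutation_matrix(profiles, cnv)
            matrix.classes.T.to_csv(out / "oncoprint.tsv", sep="\t")
            record("variants", {
                "tmb": out / "tmb.csv", "removal_ledger": out / "removal_ledger.tsv",
                "cnv_summary": out / "cnv_summary.json", "oncoprint": out / "oncoprint.tsv",
            })

        if "stats" in config.stages:
            clinical = pd.read_csv(_require(inputs / "clinical.csv", "stats"))
            onco = pd.read_csv(_require(out / "oncoprint.tsv", "stats"), sep="\t", index_col=0)
            flags = (onco.T.fillna("") != "").astype(int)
            matrix = stats.MutationMatrix(flags=flags, classes=onco.T.fillna(""))
            subtypes = clinical.set_index("sample")["subtype"]
            gst = stats.gene_subtype_test(matrix, subtypes, config.min_mutated)
            gst.to_csv(out / "gene_subtype_tests.csv", index=False)
            cooc = stats.cooccurrence(matrix, min_mutated=1)
            cooc.to_csv(out / "cooccurrence.csv", index=False)
            tmb = pd.read_csv(_require(out / "tmb.csv", "stats")).set_index("sample")
            h, p = stats.tmb_by_group(tmb["tmb"].reindex(subtypes.index),
                                      subtypes.to_numpy())
            pmap = stats.load_pathway_map(config.pathway_map)
            pw, unmapped = stats.pathway_deregulation(matrix, pmap, subtypes)
            pw.to_csv(out / "pathway_summary.csv", index=False)
            (out / "stats_summary.json").write_text(json.dumps({
                "tmb_kruskal_H": h, "tmb_kruskal_p": p, "unmapped_genes": unmapped,
            }, indent=1))
            record("stats", {
                "gene_subtype_tests": out / "gene_subtype_tests.csv",
                "cooccurrence": out / "cooccurrence.csv",
                "pathway_summary": out / "pathway_summary.csv",
                "stats_summary": out / "stats_summary.json",
            })

        if "survive" in config.stages:
            clinical = pd.read_csv(_require(inputs / "clinical.csv", "survive"))
            imp_path = _require(out / "imp_assignments.csv", "survive")
            imp = pd.read_csv(imp_path).set_index("sample")["imp"]
            onco = pd.read_csv(_require(out / "oncoprint.tsv", "survive"), sep="\t", index_col=0)
            flags = (onco.T.fillna("") != "").astype(int)
            clin = clinical.set_index("sample")
            km_rows = []
            for level in sorted(clin["subtype"].unique()):
                sub = clin[clin["subtype"] == level]
                km = surv.km_estimate(sub["os_months"], sub["os_event"])
                km_rows += [{"stratum": level, "time": t, "survival": sv}
                            for t, sv in zip(km.times, km.survival)]
            pd.DataFrame(km_rows).to_csv(out / "km_curves.csv", index=False)
            gene_cols = [g for g in flags.columns if flags[g].sum() >= config.min_mutated]
            uni = surv.univariate_screen(flags[gene_cols].reindex(clin.index),
                                         clin["os_months"], clin["os_event"],
                                         config.min_mutated)
            uni.to_csv(out / "cox_univariate.csv", index=False)
            X = surv.build_design(clinical, imp=imp)
            for g in gene_cols:
                X[g] = flags[g].reindex(X.index).fillna(0.0)
            X = X.loc[:, X.nunique() > 1]
            res = surv.lasso_cox(X, clin["os_months"], clin["os_event"],
                                 folds=config.lasso_folds, seed=config.seed)
            res.coef_path.to_csv(out / "lasso_path.csv")
            final = {
                "alpha_min": res.alpha_min, "alpha_1se": res.alpha_1se,
                "selected": res.selected,
                "model": None if res.refit is None else
                res.refit.summary.round(6).to_dict(orient="index"),
            }
            (out / "final_model.json").write_text(json.dumps(final, indent=1))
            record("survive", {
                "km_curves": out / "km_curves.csv",
                "cox_univariate": out / "cox_univariate.csv",
                "lasso_path": out / "lasso_path.csv",
                "final_model": out / "final_model.json",
            })

        if "immunogram" in config.stages:
            table = immune.MarkerDensityTable.from_long_csv(
                _require(inputs / "densities.csv", "immunogram")
            )
            tmb = pd.read_csv(_require(out / "tmb.csv", "immunogram")).set_index("sample")["tmb"]
            onco = pd.read_csv(_require(out / "oncoprint.tsv", "immunogram"), sep="\t", index_col=0)
            flags = (onco.T.fillna("") != "").astype(int)
            idh1 = flags["IDH1"] if "IDH1" in flags.columns else pd.Series(
                0, index=tmb.index)
            imp = pd.read_csv(_require(out / "imp_assignments.csv", "immunogram")
                              ).set_index("sample")["imp"]
            ig = immunogram.build_immunograms(table, idh1.reindex(tmb.index).fillna(0),
                                              tmb)
            ig.to_csv(out / "immunograms.csv")
            immunogram.summarize_by_imp(ig, imp).to_csv(out / "imp_profiles.csv")
            record("immunogram", {
                "immunograms": out / "immunograms.csv",
                "imp_profiles": out / "imp_profiles.csv",
            })
    except Exception:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def validate_inputs(paths: dict) -> list:
    """Schema-check the study inputs; returns a violation list (no abort).

    ``paths`` may contain densities, clinical, cnv (CSV paths) and vcfs (a
    list of VCF paths).  Unreadable files raise; schema violations are
    collected with row/record context.
    """
    violations = []
    if "densities" in paths:
        df = pd.read_csv(paths["densities"])
        need = {"patient_id", "marker", "region", "density_per_mm2"}
        missing = need - set(df.columns)
        if missing:
            violations.append(f"densities: missing columns {sorted(missing)}")
        else:
            bad = df.index[df["density_per_mm2"] < 0]
            violations += [f"densities: negative density at row {i}" for i in bad]
    if "clinical" in paths:
        df = pd.read_csv(paths["clinical"])
        for col in ("sample", "subtype", "os_months", "os_event"):
            if col not in df.columns:
                violations.append(f"clinical: missing column {col}")
        if "os_months" in df.columns:
            bad = df.index[df["os_months"] <= 0]
            violations += [f"clinical: non-positive os_months at row {i}" for i in bad]
    if "cnv" in paths:
        df = pd.read_csv(paths["cnv"])
        if set(df.columns) >= {"sample", "gene", "type"}:
            bad = df.index[~df["type"].isin(["amp", "del"])]
            violations += [f"cnv: unknown event type at row {i}" for i in bad]
        else:
            violations.append("cnv: expected columns sample, gene, type")
    for vcf_path in paths.get("vcfs", []):
        try:
            recs = var.parse_caller_vcf(vcf_path, "GATK")
        except Exception as exc:  # malformed record: report, keep validating
            violations.append(f"{vcf_path}: {exc}")
            continue
        for r in recs:
            if r.af is not None and not 0 <= r.af <= 1:
                violations.append(f"{vcf_path}: AF out of range at {r.chrom}:{r.pos}")
    return violations
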