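"""Synthetic chondrosarcoma-cohort generator with known ground truth.

Emulates the statistical structure of a 99-patient chondrosarcoma study so
that every downstream stage (immunophenotype clustering, variant cascade,
cohort statistics, survival modelling, immunograms) can be exercised and
validated without patient data:

* histological subtypes G1/G2/G3/DD in proportions 28/37/24/10;
* three latent immunophenotypes ("cold" IMP1, "hot" IMP2, "intermediate"
  IMP3) driving log-normal immune-marker densities with a low-rank
  latent-factor covariance (a macrophage factor and a T-cell factor);
* grade-dependent driver-gene mutation frequencies (IDH1/2 combined 41%,
  TP53 16%, RNF213 12%, TAF1 11%, MN1 10%) with IDH1-TP53/UBR5 and
  IDH2-PTCH1 co-occurrence;
* per-sample call sets for three caller dialects plus a pool-of-normals
  set, with true somatic variants passing every cascade threshold and
  injected contaminants each tagged with the cascade stage expected to
  remove it;
* overall survival from an exponential proportional-hazards model with
  true hazard ratios 3.3 (IMP2 vs IMP1) and 3.8 (IDH1-mutant), calibrated
  so the marginal survival hits the configured subtype 3-year and
  immunophenotype 5-year anchors.

All randomness flows from a single seed through per-component child
streams, so each output block is bit-reproducible and independent of which
blocks are requested.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .variants import FilterThresholds, SampleMeta, VariantRecord, write_vcf

__all__ = [
    "SUBTYPES",
    "IMP_NAMES",
    "MARKERS",
    "REGIONS",
    "GeneratorConfig",
    "PatientTruth",
    "Contaminant",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_marker_densities",
    "generate_variant_calls",
    "generate_survival",
    "survival_calibration",
    "expected_log_density",
]

SUBTYPES = ("G1", "G2", "G3", "DD")
IMP_NAMES = ("IMP1", "IMP2", "IMP3")
REGIONS = ("central", "peripheral")

#: the 20 immunohistochemistry markers scored per tumor region (cells/mm2)
MARKERS = (
    "CD45", "CD3", "CD4", "CD8", "FOXP3", "CD20", "CD68", "CD68_KP1", "CD163",
    "CD14", "CD80", "HLA_DR", "CD1A", "CD141", "LAMP3", "PD1", "TIM3", "LAG3",
    "GAL9", "PDL1",
)

DENSITY_COLUMNS = tuple(f"{m}_{r}" for m in MARKERS for r in REGIONS)

# baseline log density (log cells/mm2) per marker
_BASE_LOG = {
    "CD45": 4.8, "CD3": 4.0, "CD4": 3.8, "CD8": 3.6, "FOXP3": 2.5, "CD20": 2.3,
    "CD68": 5.2, "CD68_KP1": 4.8, "CD163": 5.2, "CD14": 5.3, "CD80": 2.0,
    "HLA_DR": 5.5, "CD1A": 1.5, "CD141": 2.8, "LAMP3": 1.2, "PD1": 3.2,
    "TIM3": 4.6, "LAG3": 1.8, "GAL9": 5.0, "PDL1": 1.0,
}
_MACRO = {"CD14", "CD68", "CD68_KP1", "CD163", "HLA_DR", "GAL9", "TIM3"}
_TCELL = {"CD3", "CD4", "CD8", "PD1"}
_PERIPH_UP = {"CD45", "CD3", "CD4", "PD1", "CD141"}  # peripheral > central cohort-wide
_IMP2_CENTRAL_BOOST = {"HLA_DR", "CD163", "GAL9", "PD1", "CD8"}
# lymphoid vs myeloid/checkpoint split: IMP3 ("intermediate") is lymphoid-rich
# but myeloid/checkpoint-poor, so the three phenotypes are not collinear
_LYMPHOID = {"CD45", "CD3", "CD4", "CD8", "CD20", "FOXP3", "CD1A", "CD141", "LAMP3", "CD80"}
_MYELOID_ICP = {"CD14", "CD68", "CD68_KP1", "CD163", "HLA_DR", "GAL9", "TIM3", "LAG3", "PD1", "PDL1"}

#: genes carried on the synthetic panel, with an anchor coordinate (hg19-like)
PANEL_GENES = {
    "IDH1": ("2", 209100000), "IDH2": ("15", 90630000), "TP53": ("17", 7570000),
    "RNF213": ("17", 78230000), "TAF1": ("X", 70580000), "MN1": ("22", 28140000),
    "UBR5": ("8", 103280000), "EPHA7": ("6", 93950000), "PTCH1": ("9", 98200000),
    "EGFR": ("7", 55240000), "PIK3CA": ("3", 178930000), "CDKN2A": ("9", 21970000),
    "ATM": ("11", 108110000), "SETD2": ("3", 47080000), "ATRX": ("X", 76880000),
    "COL2A1": ("12", 48370000), "KMT2D": ("12", 49420000), "ARID1A": ("1", 27050000),
    "NRAS": ("1", 115250000), "KRAS": ("12", 25390000), "PTEN": ("10", 89690000),
    "RB1": ("13", 48940000), "BRCA2": ("13", 32910000), "NOTCH1": ("9", 139390000),
    "FGFR3": ("4", 1800000), "ALK": ("2", 29440000), "MTOR": ("1", 11200000),
    "APC": ("5", 112170000), "SMARCA4": ("19", 11090000), "CREBBP": ("16", 3780000),
}

_CONTAMINANT_STAGE = {
    "gatk_quality": "gatk_filter",
    "indel_af": "gatk_filter",
    "pool": "pool",
    "annotation": "annotation_low_benign",
    "population": "population_af",
    "read_support": "read_support",
    "post_filter": "post_filter",
}
CONTAMINANT_CLASSES = tuple(_CONTAMINANT_STAGE)


class ConfigurationError(ValueError):
    """Raised when a generator parameter is invalid; names the field."""


def _default_subtype_proportions():
    return {"G1": 28 / 99, "G2": 37 / 99, "G3": 24 / 99, "DD": 10 / 99}


def _default_imp_given_subtype():
    return {
        "G1": {"IMP1": 0.80, "IMP2": 0.05, "IMP3": 0.15},
        "G2": {"IMP1": 0.42, "IMP2": 0.20, "IMP3": 0.38},
        "G3": {"IMP1": 0.18, "IMP2": 0.47, "IMP3": 0.35},
        "DD": {"IMP1": 0.05, "IMP2": 0.80, "IMP3": 0.15},
    }


def _default_gene_freqs():
    # IDH1/IDH2 are mutually exclusive; their subtype profiles sum to the
    # combined 41% cohort frequency (IDH1 ~31%, IDH2 ~10%).
    return {
        "IDH1": {"G1": 0.18, "G2": 0.37, "G3": 0.40, "DD": 0.25},
        "IDH2": {"G1": 0.00, "G2": 0.095, "G3": 0.12, "DD": 0.37},
        "TP53": {"G1": 0.00, "G2": 0.13, "G3": 0.35, "DD": 0.25},
        "RNF213": 0.12, "TAF1": 0.11, "MN1": 0.10, "UBR5": 0.07, "EPHA7": 0.06,
        "PTCH1": 0.06, "EGFR": 0.05, "PIK3CA": 0.05, "CDKN2A": 0.05, "ATM": 0.05,
        "SETD2": 0.04, "ATRX": 0.04, "COL2A1": 0.08, "KMT2D": 0.04, "ARID1A": 0.04,
    }


def _default_true_log_hazards():
    return {
        "IMP2": math.log(3.3),
        "IDH1": math.log(3.8),
        "size_per_cm": math.log(1.07),
    }


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort; defaults follow the study design."""

    n_patients: int = 99
    subtype_proportions: dict = field(default_factory=_default_subtype_proportions)
    imp_given_subtype: dict = field(default_factory=_default_imp_given_subtype)
    gene_freqs: dict = field(default_factory=_default_gene_freqs)
    #: gene -> (partner gene, odds multiplier); marginal frequency preserved
    cooccurrence: dict = field(
        default_factory=lambda: {"TP53": ("IDH1", 3.0), "UBR5": ("IDH1", 3.0),
                                 "PTCH1": ("IDH2", 3.0)}
    )
    true_log_hazards: dict = field(default_factory=_default_true_log_hazards)
    #: 3-year overall-survival probability by subtype
    subtype_survival_anchors: dict = field(
        default_factory=lambda: {"G1": 0.913, "G2": 0.773, "G3": 0.407, "DD": 0.114}
    )
    #: 5-year overall-survival probability by immunophenotype
    imp_survival_anchors: dict = field(
        default_factory=lambda: {"IMP1": 0.86, "IMP2": 0.29, "IMP3": 0.44}
    )
    censoring_rate: float = 0.30
    #: negative binomial (r, p) for the retained-variant count; calibrated so
    #: the cohort median retained count is 4 (median TMB 4/1.7 mut/Mb)
    final_variant_count_dist: tuple = (1.1, 0.164551)
    panel_size_mb: float = 1.7
    contaminants_per_class: int = 2
    density_noise_scale: float = 1.0
    #: mean tumor size is log-normal per subtype: exp(N(log_size_mu, sd))
    log_size_mu: dict = field(
        default_factory=lambda: {"G1": math.log(5.0), "G2": math.log(6.5),
                                 "G3": math.log(8.0), "DD": math.log(9.5)}
    )
    log_size_sd: float = 0.35
    pdl1_positive_prob: dict = field(default_factory=lambda: {"IMP2": 0.75, "IMP3": 0.40})
    tls_prob: dict = field(default_factory=lambda: {"IMP2": 0.55, "IMP3": 0.25})
    cnv_carrier_prob: dict = field(
        default_factory=lambda: {"G1": 0.10, "G2": 0.20, "G3": 0.50, "DD": 0.40}
    )
    cnv_extra_events_mean: float = 4.9
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if self.panel_size_mb <= 0:
            raise ConfigurationError("panel_size_mb must be > 0")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ConfigurationError("censoring_rate must be in [0, 1]")
        if abs(sum(self.subtype_proportions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("subtype_proportions must sum to 1")
        for s, d in self.imp_given_subtype.items():
            if abs(sum(d.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"imp_given_subtype[{s}] must sum to 1")
            if any(not 0 <= v <= 1 for v in d.values()):
                raise ConfigurationError(f"imp_given_subtype[{s}] outside [0, 1]")
        for name, anchors in (
            ("subtype_survival_anchors", self.subtype_survival_anchors),
            ("imp_survival_anchors", self.imp_survival_anchors),
        ):
            for k, v in anchors.items():
                if not 0.0 < v < 1.0:
                    raise ConfigurationError(f"{name}[{k}] must be in (0, 1)")
        for g, p in self.gene_freqs.items():
            vals = p.values() if isinstance(p, dict) else [p]
            if any(not 0 <= v <= 1 for v in vals):
                raise ConfigurationError(f"gene_freqs[{g}] outside [0, 1]")

    def gene_prob(self, gene: str, subtype: str) -> float:
        p = self.gene_freqs[gene]
        return p[subtype] if isinstance(p, dict) else p


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class Contaminant:
    record: VariantRecord
    contaminant_class: str
    stage: str  # cascade stage expected to remove it


@dataclass
class PatientTruth:
    sample: str
    subtype: str
    imp: str
    size_cm: float = float("nan")
    genes: set = field(default_factory=set)
    variants: list = field(default_factory=list)
    contaminants: list = field(default_factory=list)
    true_time_months: float = float("nan")


@dataclass
class GroundTruth:
    patients: list

    def by_sample(self) -> dict:
        return {p.sample: p for p in self.patients}

    def to_json(self) -> str:
        def enc(p: PatientTruth):
            d = dataclasses.asdict(p)
            d["genes"] = sorted(p.genes)
            return d
        return json.dumps([enc(p) for p in self.patients], indent=1, default=str)


@dataclass
class SyntheticCohort:
    config: GeneratorConfig
    clinical: pd.DataFrame
    truth: GroundTruth
    densities: pd.DataFrame | None = None
    caller_sets: dict | None = None       # sample -> {dialect: [VariantRecord]}
    pool: list | None = None              # pool-of-normals records
    cnv: pd.DataFrame | None = None
    meta: dict | None = None              # sample -> SampleMeta

    def write(self, outdir) -> dict:
        """Write all study inputs as plain-text files; returns path map."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"clinical": out / "clinical.csv", "truth": out / "truth.json"}
        self.clinical.to_csv(paths["clinical"], index=False)
        paths["truth"].write_text(self.truth.to_json())
        if self.densities is not None:
            paths["densities"] = out / "densities.csv"
            densities_to_long(self.densities).to_csv(paths["densities"], index=False)
        if self.cnv is not None:
            paths["cnv"] = out / "cnv.csv"
            self.cnv.to_csv(paths["cnv"], index=False)
        if self.caller_sets is not None:
            vdir = out / "vcf"
            vdir.mkdir(exist_ok=True)
            for sample, sets in self.caller_sets.items():
                for dialect, recs in sets.items():
                    write_vcf(recs, vdir / f"{sample}.{dialect}.vcf", sample)
            write_vcf(self.pool, vdir / "pool.vcf", "POOL")
            paths["vcf_dir"] = vdir
        if self.meta is not None:
            paths["meta"] = out / "sample_meta.csv"
            pd.DataFrame(
                [
                    {"sample": m.sample, "deamination_score": m.deamination_score,
                     "preliminary_tmb": m.preliminary_tmb}
                    for m in self.meta.values()
                ]
            ).to_csv(paths["meta"], index=False)
        return paths


def densities_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    """Convert the wide density table to the long CSV dialect."""
    rows = []
    for _, r in wide.iterrows():
        for m in MARKERS:
            for reg in REGIONS:
                rows.append(
                    {
                        "patient_id": r["sample"], "marker": m, "region": reg,
                        "density_per_mm2": r[f"{m}_{reg}"],
                        "pdl1_percent": r["pdl1_percent"],
                        "tls_cd3": int(r["tls_cd3"]), "tls_cd20": int(r["tls_cd20"]),
                        "tls_lamp3": int(r["tls_lamp3"]), "subtype": r["subtype"],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# density model
# ---------------------------------------------------------------------------

def expected_log_density(marker: str, region: str, imp: str) -> float:
    """Noise-free log density for a (marker, region, immunophenotype) cell."""
    mu = _BASE_LOG[marker]
    if marker in _PERIPH_UP and region == "peripheral":
        mu += 0.35
    if imp == "IMP1":
        mu -= 1.0
        if marker in _PERIPH_UP and region == "central":
            mu -= 0.8
    elif imp == "IMP2":
        mu += 1.2
        if region == "central":
            mu += 0.4
            if marker in _IMP2_CENTRAL_BOOST:
                mu += 0.5
    else:  # IMP3: lymphoid-rich, myeloid/checkpoint-poor
        mu += 1.1 if marker in _LYMPHOID else -0.6
    return mu


def _factor_loadings(marker: str, region: str) -> tuple[float, float, float]:
    """(macrophage loading, T-cell loading, idiosyncratic sd)."""
    lm = lt = 0.0
    if marker in {"CD68", "CD68_KP1", "CD163"}:
        lm = 0.7 if region == "central" else 0.35
    elif marker in _MACRO:
        lm = 0.5 if region == "central" else 0.35
    if marker in _TCELL:
        lt = 0.45
    elif marker == "CD45":
        lm, lt = 0.2, 0.35
    elif marker in {"CD20", "FOXP3"}:
        lt = 0.25
    sd = 0.30 if (marker in {"CD68", "CD68_KP1", "CD163"} and region == "central") else 0.40
    return lm, lt, sd


def generate_marker_densities(truth: GroundTruth, config: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Per-patient immune marker densities, PD-L1 percent and TLS flags.

    Densities are log-normal per (marker, region, IMP) with a shared
    macrophage factor and T-cell factor.  PD-L1 percent-positive is zero
    for IMP1 patients; jointly positive TLS component flags occur only in
    G2/G3/DD tumors with a non-cold phenotype.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    scale = config.density_noise_scale
    rows = []
    for p in truth.patients:
        f_mac, f_t = rng.normal(size=2) * scale
        row = {"sample": p.sample, "subtype": p.subtype, "imp_true": p.imp}
        for m in MARKERS:
            for reg in REGIONS:
                lm, lt, sd = _factor_loadings(m, reg)
                mu = expected_log_density(m, reg, p.imp)
                eps = rng.normal() * sd * scale
                row[f"{m}_{reg}"] = round(
                    float(np.exp(mu + lm * f_mac + lt * f_t + eps)), 2
                )
        # PD-L1 percent positive: absent in IMP1, high values concentrate in DD
        pct = 0.0
        if p.imp in config.pdl1_positive_prob and rng.random() < config.pdl1_positive_prob[p.imp]:
            base = 2.0 if p.imp == "IMP2" else 1.2
            pct = float(np.exp(rng.normal(base, 0.8)))
            if p.subtype == "DD":
                pct *= 5.0
            pct = round(min(pct, 95.0), 1)
        row["pdl1_percent"] = pct
        tls_allowed = p.subtype != "G1" and p.imp in config.tls_prob
        if tls_allowed and rng.random() < config.tls_prob[p.imp]:
            c3 = c20 = lamp = 1
        else:
            c3, c20, lamp = (int(rng.random() < 0.25) for _ in range(3))
            if c3 and c20 and lamp:  # joint positivity only via the TLS branch
                lamp = 0
        row["tls_cd3"], row["tls_cd20"], row["tls_lamp3"] = c3, c20, lamp
        rows.append(row)
    cols = ["sample", "subtype", "imp_true", *DENSITY_COLUMNS,
            "pdl1_percent", "tls_cd3", "tls_cd20", "tls_lamp3"]
    return pd.DataFrame(rows)[cols]


# ---------------------------------------------------------------------------
# survival model
# ---------------------------------------------------------------------------

_CALIBRATION_CACHE: dict = {}


def _calibration_key(config: GeneratorConfig) -> str:
    payload = {
        "sub": sorted(config.subtype_proportions.items()),
        "imp": sorted((s, sorted(d.items())) for s, d in config.imp_given_subtype.items()),
        "idh1": sorted(
            (s, config.gene_prob("IDH1", s)) for s in config.subtype_proportions
        ),
        "haz": sorted(config.true_log_hazards.items()),
        "anch_s": sorted(config.subtype_survival_anchors.items()),
        "anch_m": sorted(config.imp_survival_anchors.items()),
        "size": (sorted(config.log_size_mu.items()), config.log_size_sd),
    }
    return json.dumps(payload)


def survival_calibration(config: GeneratorConfig) -> dict:
    """Calibrate baseline log-hazards so marginal survival hits the anchors.

    The individual hazard (per month) is

        lambda_i = exp(c_subtype + c_IMP + beta_IDH1 * IDH1 + beta_size * (size - 7))

    with c_IMP1 = 0, c_IMP2 = log 3.3 and beta_IDH1 = log 3.8 fixed by
    configuration.  The four subtype baselines and the IMP3 log-hazard are
    solved by weighted least squares so the marginal mixture survival (over
    IMP, IDH1 and size within each stratum) matches the subtype 3-year and
    immunophenotype 5-year anchors.  Seven anchors constrain five free
    parameters, so the match is a compromise; residuals stay within +-0.02.
    """
    key = _calibration_key(config)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]

    subtypes = list(config.subtype_proportions)
    imps = list(IMP_NAMES)
    b_imp2 = config.true_log_hazards["IMP2"]
    b_idh = config.true_log_hazards["IDH1"]
    b_size = config.true_log_hazards["size_per_cm"]
    xh, wh = np.polynomial.hermite_e.hermegauss(24)
    wh = wh / wh.sum()

    def cells(x):
        lcs = dict(zip(subtypes, x[: len(subtypes)]))
        lim = {"IMP1": 0.0, "IMP2": b_imp2, "IMP3": x[len(subtypes)]}
        out = []
        for s in subtypes:
            ws = config.subtype_proportions[s]
            q1 = config.gene_prob("IDH1", s)
            for m in imps:
                wm = config.imp_given_subtype[s].get(m, 0.0)
                if wm == 0.0:
                    continue
                for idh, pi in ((0, 1 - q1), (1, q1)):
                    for i in range(len(xh)):
                        size = math.exp(config.log_size_mu[s] + config.log_size_sd * xh[i])
                        lam = math.exp(lcs[s] + lim[m] + b_idh * idh + b_size * (size - 7.0))
                        out.append((ws * wm * pi * wh[i], lam, s, m))
        return out

    def marginal(cs, which, value, t):
        sel = [(w, l) for w, l, s, m in cs if (s if which == "s" else m) == value]
        tot = sum(w for w, _ in sel)
        if tot == 0.0:  # stratum absent from the configured mixture
            return None
        return sum(w * math.exp(-l * t) for w, l in sel) / tot

    w_sub = {s: (3.0 if s == "G1" else 1.0) for s in subtypes}
    w_imp = {"IMP1": 3.0, "IMP2": 3.0, "IMP3": 2.0}

    def resid(x):
        cs = cells(x)
        r = []
        for s in subtypes:
            v = marginal(cs, "s", s, 36.0)
            r.append(0.0 if v is None else w_sub[s] * (v - config.subtype_survival_anchors[s]))
        for m in imps:
            v = marginal(cs, "m", m, 60.0)
            r.append(0.0 if v is None else w_imp[m] * (v - config.imp_survival_anchors[m]))
        return r

    x0 = np.array(
        [math.log(-math.log(a) / 36.0) for a in
         (config.subtype_survival_anchors[s] for s in subtypes)]
        + [math.log(1.8)]
    )
    sol = least_squares(resid, x0)
    fitted = cells(sol.x)
    result = {
        "c_subtype": dict(zip(subtypes, (float(v) for v in sol.x[: len(subtypes)]))),
        "c_imp": {"IMP1": 0.0, "IMP2": b_imp2, "IMP3": float(sol.x[len(subtypes)])},
        "beta_idh1": b_idh,
        "beta_size_per_cm": b_size,
        "size_center_cm": 7.0,
        "fitted_anchors": {
            **{f"{s}@36mo": marginal(fitted, "s", s, 36.0) for s in subtypes},
            **{f"{m}@60mo": marginal(fitted, "m", m, 60.0) for m in imps},
        },
    }
    _CALIBRATION_CACHE[key] = result
    return result


def patient_hazard(subtype: str, imp: str, idh1: bool, size_cm: float,
                   calib: dict) -> float:
    """True event hazard per month for one patient."""
    return math.exp(
        calib["c_subtype"][subtype]
        + calib["c_imp"][imp]
        + calib["beta_idh1"] * bool(idh1)
        + calib["beta_size_per_cm"] * (size_cm - calib["size_center_cm"])
    )


def generate_survival(covariates: pd.DataFrame, config: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Draw OS/DFS times and event flags under the calibrated hazard model.

    ``covariates`` needs columns sample, subtype, imp_true, idh1, size_cm.
    Event flag 1 means death (OS) or progression/death (DFS) observed.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    calib = survival_calibration(config)
    lam = np.array([
        patient_hazard(r.subtype, r.imp_true, bool(r.idh1), r.size_cm, calib)
        for r in covariates.itertuples()
    ])
    n = len(lam)
    t_death = rng.exponential(1.0 / lam)
    t_prog = rng.exponential(1.0 / (0.7 * lam))
    censored = rng.random(n) < config.censoring_rate
    t_cens = np.where(censored, rng.exponential(60.0, n), np.inf)
    os_t = np.minimum(t_death, t_cens)
    dfs_raw = np.minimum(t_prog, t_death)
    dfs_t = np.minimum(dfs_raw, t_cens)
    return pd.DataFrame(
        {
            "sample": covariates["sample"].to_numpy(),
            "os_months": np.round(np.maximum(os_t, 0.05), 2),
            "os_event": (t_death <= t_cens).astype(int),
            "dfs_months": np.round(np.maximum(dfs_t, 0.05), 2),
            "dfs_event": (dfs_raw <= t_cens).astype(int),
            "true_time_months": t_death,
        }
    )


# ---------------------------------------------------------------------------
# variant-call generation
# ---------------------------------------------------------------------------

def _pool_catalog(rng) -> list:
    """Fixed catalog of germline-like loci shared by the pool of normals."""
    genes = sorted(PANEL_GENES)
    records = []
    for i in range(40):
        gene = genes[int(rng.integers(len(genes)))]
        chrom, base = PANEL_GENES[gene]
        pos = base + 50000 + int(rng.integers(0, 10000))
        ref, alt = _draw_snv_alleles(rng)
        records.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt, dp=int(rng.integers(200, 900)),
                af=round(float(rng.uniform(0.42, 0.58)), 6), tlod=round(float(rng.uniform(40, 300)), 2),
                callers=frozenset({"GATK"}), gene=gene,
                dbsnp=f"rs{int(rng.integers(10**6, 10**8))}",
            )
        )
    # de-duplicate keys
    seen, out = set(), []
    for r in records:
        if r.key not in seen:
            seen.add(r.key)
            out.append(r)
    return out


_BASES = ("A", "C", "G", "T")


def _draw_snv_alleles(rng):
    ref = _BASES[int(rng.integers(4))]
    alt = _BASES[int(rng.integers(4))]
    while alt == ref:
        alt = _BASES[int(rng.integers(4))]
    return ref, alt


def _passing_annotations(rng):
    """Annotation block that survives every pathogenicity rule."""
    impact = "HIGH" if rng.random() < 0.3 else "MODERATE"
    clnsig = ["pathogenic", "uncertain", None][int(rng.integers(3))]
    if rng.random() < 0.7:
        sift, polyphen = "deleterious", "damaging"
        am = "pathogenic" if rng.random() < 0.6 else "ambiguous"
    else:
        sift = polyphen = None
        am = "pathogenic"
    kg = round(float(rng.uniform(0, 0.05)), 6) if rng.random() < 0.2 else None
    return dict(impact=impact, clnsig=clnsig, sift=sift, polyphen=polyphen,
                alphamissense=am, kg_af=kg)


def _supporting_reads(rng, dp, af):
    alt = max(int(round(af * dp)), 5)
    alt = min(alt, dp)
    fwd = int(rng.binomial(alt, 0.5))
    fwd = min(max(fwd, 2), alt - 2)
    return fwd, alt - fwd


def _true_variant(rng, gene, used, strict, indel_ok=True):
    chrom, base = PANEL_GENES[gene]
    pos = _fresh_pos(rng, base, 0, 5000, chrom, used)
    kind = "SNP"
    if indel_ok and gene not in ("IDH1", "IDH2"):
        u = rng.random()
        kind = "INDEL" if u < 0.10 else ("MNP" if u < 0.15 else "SNP")
    if kind == "INDEL":
        dp = int(rng.integers(150, 1500))
        af = round(float(rng.uniform(0.36, 0.54)), 6)
        anchor = _BASES[int(rng.integers(4))]
        if rng.random() < 0.5:
            ref, alt = anchor + "".join(_BASES[int(rng.integers(4))] for _ in range(int(rng.integers(1, 4)))), anchor
        else:
            ref, alt = anchor, anchor + "".join(_BASES[int(rng.integers(4))] for _ in range(int(rng.integers(1, 4))))
    else:
        dp = int(rng.integers(120, 1900))
        af = round(float(rng.uniform(0.78, 0.95) if strict else rng.uniform(0.10, 0.60)), 6)
        if kind == "MNP":
            r1, a1 = _draw_snv_alleles(rng)
            r2, a2 = _draw_snv_alleles(rng)
            ref, alt = r1 + r2, a1 + a2
        else:
            ref, alt = _draw_snv_alleles(rng)
    fwd, rev = _supporting_reads(rng, dp, af)
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, dp=dp, af=af,
        tlod=round(float(rng.uniform(30, 800)), 2), sb_fwd=fwd, sb_rev=rev,
        gene=gene, **_passing_annotations(rng),
    )


def _fresh_pos(rng, base, lo, hi, chrom, used):
    while True:
        pos = base + lo + int(rng.integers(0, hi - lo))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return pos


def _contaminant(rng, cls, used, pool_entry=None):
    """One injected contaminant record of the given class."""
    gene = sorted(PANEL_GENES)[int(rng.integers(len(PANEL_GENES)))]
    chrom, base = PANEL_GENES[gene]
    if cls == "pool":
        fwd, rev = _supporting_reads(rng, pool_entry.dp, pool_entry.af)
        return dataclasses.replace(
            pool_entry, sb_fwd=fwd, sb_rev=rev, callers=frozenset(),
            **_passing_annotations(rng),
        )
    pos = _fresh_pos(rng, base, 10000, 40000, chrom, used)
    common = dict(chrom=chrom, pos=pos, gene=gene, **_passing_annotations(rng))
    ref, alt = _draw_snv_alleles(rng)
    if cls == "gatk_quality":
        which = int(rng.integers(3))
        dp = int(rng.integers(5, 15)) if which == 0 else int(rng.integers(120, 900))
        af = round(float(rng.uniform(0.002, 0.0149)), 6) if which == 1 else round(float(rng.uniform(0.1, 0.5)), 6)
        tlod = round(float(rng.uniform(0, 13.9)), 2) if which == 2 else round(float(rng.uniform(20, 200)), 2)
        fwd, rev = _supporting_reads(rng, dp, max(af, 0.05))
        return VariantRecord(ref=ref, alt=alt, dp=dp, af=af, tlod=tlod,
                             sb_fwd=fwd, sb_rev=rev, **common)
    if cls == "indel_af":
        anchor = _BASES[int(rng.integers(4))]
        ref2, alt2 = anchor + _BASES[int(rng.integers(4))], anchor
        dp = int(rng.integers(120, 900))
        af = round(float(rng.uniform(0.60, 0.90) if rng.random() < 0.5 else rng.uniform(0.06, 0.30)), 6)
        fwd, rev = _supporting_reads(rng, dp, af)
        return VariantRecord(ref=ref2, alt=alt2, dp=dp, af=af,
                             tlod=round(float(rng.uniform(20, 200)), 2),
                             sb_fwd=fwd, sb_rev=rev, **common)
    dp = int(rng.integers(150, 900))
    af = round(float(rng.uniform(0.10, 0.45)), 6)
    tlod = round(float(rng.uniform(20, 400)), 2)
    fwd, rev = _supporting_reads(rng, dp, af)
    rec = VariantRecord(ref=ref, alt=alt, dp=dp, af=af, tlod=tlod,
                        sb_fwd=fwd, sb_rev=rev, **common)
    if cls == "annotation":
        return dataclasses.replace(rec, impact="LOW", clnsig="benign")
    if cls == "population":
        return dataclasses.replace(rec, kg_af=round(float(rng.uniform(0.06, 0.45)), 6),
                                   dbsnp=f"rs{int(rng.integers(10**6, 10**8))}")
    if cls == "read_support":
        rev2 = int(rng.integers(10, 40))
        dp2 = (1 + rev2) * 10  # AF 0.10: passes every AF/DP gate, fails min-strand
        return dataclasses.replace(rec, sb_fwd=1, sb_rev=rev2, dp=dp2,
                                   af=round((1 + rev2) / dp2, 6))
    if cls == "post_filter":
        return dataclasses.replace(rec, af=round(float(rng.uniform(0.016, 0.045)), 6),
                                   sb_fwd=None, sb_rev=None)
    raise ValueError(f"unknown contaminant class {cls!r}")


def generate_variant_calls(truth: GroundTruth, config: GeneratorConfig, rng=None):
    """Per-sample caller sets, pool-of-normals set and sample metadata.

    True somatic variants appear in the TS and GATK sets with fields that
    pass every cascade threshold in force for the sample (including the
    strict deamination policy when the sample triggers it); a random half
    also appear in IR.  Contaminants are injected per class with the
    cascade stage expected to remove them recorded in the ground truth.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    r_count, p_count = config.final_variant_count_dist
    pool = _pool_catalog(rng)
    passenger_pool = sorted(set(PANEL_GENES) - set(config.gene_freqs))
    caller_sets, metas = {}, {}
    for p in truth.patients:
        used: set = set()
        n_total = max(int(rng.negative_binomial(r_count, p_count)), len(p.genes))
        deam = round(float(rng.uniform(0.0, 9.5)), 2)
        prelim_tmb = round(n_total / config.panel_size_mb, 2)
        meta = SampleMeta(sample=p.sample, deamination_score=deam,
                          preliminary_tmb=prelim_tmb)
        strict = 10.0 <= deam <= 25.0 or 11.0 <= prelim_tmb <= 50.0
        variants = [
            _true_variant(rng, g, used, strict, indel_ok=True) for g in sorted(p.genes)
        ]
        for _ in range(n_total - len(p.genes)):
            g = passenger_pool[int(rng.integers(len(passenger_pool)))]
            variants.append(_true_variant(rng, g, used, strict))
        contaminants = []
        for cls in CONTAMINANT_CLASSES:
            n_cls = min(config.contaminants_per_class, len(pool)) if cls == "pool" else config.contaminants_per_class
            if cls == "pool":
                picks = rng.choice(len(pool), size=n_cls, replace=False)
            for j in range(n_cls):
                entry = pool[int(picks[j])] if cls == "pool" else None
                rec = _contaminant(rng, cls, used, entry)
                stage = _CONTAMINANT_STAGE[cls]
                # under the strict deamination policy the raised GATK AF floor
                # catches low-AF records before their nominal stage
                if (
                    strict
                    and rec.var_class in ("SNP", "MNP")
                    and rec.af is not None
                    and rec.af < FilterThresholds().strict_gatk_snp_af
                    and stage != "gatk_filter"
                ):
                    stage = "gatk_filter"
                contaminants.append(Contaminant(rec, cls, stage))
        p.variants = variants
        p.contaminants = contaminants
        all_records = variants + [c.record for c in contaminants]
        ts = [dataclasses.replace(r, tlod=None, sb_fwd=None, sb_rev=None,
                                  callers=frozenset({"TS"})) for r in all_records]
        gatk = [dataclasses.replace(r, callers=frozenset({"GATK"})) for r in all_records]
        ir = [dataclasses.replace(r, tlod=None, sb_fwd=None, sb_rev=None,
                                  callers=frozenset({"IR"}))
              for r in variants if rng.random() < 0.5]
        caller_sets[p.sample] = {"TS": ts, "GATK": gatk, "IR": ir}
        metas[p.sample] = meta
    return caller_sets, pool, metas


def _generate_cnv(truth: GroundTruth, config: GeneratorConfig, rng) -> pd.DataFrame:
    # CNV events live on panel genes outside the configured driver set so
    # that configured mutation frequencies stay interpretable
    pool = sorted(set(PANEL_GENES) - set(config.gene_freqs))
    rows = []
    for p in truth.patients:
        if rng.random() < config.cnv_carrier_prob.get(p.subtype, 0.0):
            n = 1 + int(rng.poisson(config.cnv_extra_events_mean))
            genes = list(rng.choice(pool, size=min(n, len(pool)), replace=False))
            for g in genes:
                rows.append({"sample": p.sample, "gene": str(g),
                             "type": "amp" if rng.random() < 0.5 else "del"})
    return pd.DataFrame(rows, columns=["sample", "gene", "type"])


# ---------------------------------------------------------------------------
# whole-cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    config: GeneratorConfig | None = None,
    with_densities: bool = True,
    with_variants: bool = True,
) -> SyntheticCohort:
    """Generate a complete synthetic cohort with ground truth.

    Deterministic for a fixed ``config.seed``; each output block draws from
    its own child random stream, so disabling a block never changes the
    others.
    """
    config = config or GeneratorConfig()
    ss = np.random.SeedSequence(config.seed)
    rng_clin, rng_dens, rng_var, rng_surv, rng_cnv = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )

    subtypes = list(config.subtype_proportions)
    probs = np.array([config.subtype_proportions[s] for s in subtypes])
    patients = []
    for i in range(config.n_patients):
        sample = f"CHS-{i + 1:03d}"
        subtype = subtypes[int(rng_clin.choice(len(subtypes), p=probs))]
        imp_d = config.imp_given_subtype[subtype]
        imp = list(imp_d)[int(rng_clin.choice(len(imp_d), p=np.array(list(imp_d.values()))))]
        size = round(float(np.exp(rng_clin.normal(config.log_size_mu[subtype],
                                                  config.log_size_sd))), 1)
        genes = _draw_genes(rng_clin, config, subtype)
        patients.append(PatientTruth(sample=sample, subtype=subtype, imp=imp,
                                     size_cm=size, genes=genes))
    truth = GroundTruth(patients)

    clin_rows = []
    for p in truth.patients:
        clin_rows.append(
            {
                "sample": p.sample,
                "age": int(np.clip(round(rng_clin.normal(52, 15)), 18, 88)),
                "sex": "M" if rng_clin.random() < 0.54 else "F",
                "subtype": p.subtype,
                "site": "axial" if rng_clin.random() < 0.4 else "extremity",
                "margins": "R0" if rng_clin.random() < 0.7 else "R1",
                "size_cm": p.size_cm,
                "imp_true": p.imp,
                "idh1": int("IDH1" in p.genes),
            }
        )
    clinical = pd.DataFrame(clin_rows)
    for g in sorted(config.gene_freqs):
        clinical[f"mut_{g}"] = [int(g in p.genes) for p in truth.patients]

    surv = generate_survival(clinical, config, rng_surv)
    clinical = clinical.merge(surv.drop(columns=["true_time_months"]), on="sample")
    for p, t in zip(truth.patients, surv["true_time_months"]):
        p.true_time_months = float(t)

    cohort = SyntheticCohort(config=config, clinical=clinical, truth=truth)
    if with_densities:
        cohort.densities = generate_marker_densities(truth, config, rng_dens)
    if with_variants:
        cohort.caller_sets, cohort.pool, cohort.meta = generate_variant_calls(
            truth, config, rng_var
        )
        cohort.cnv = _generate_cnv(truth, config, rng_cnv)
    return cohort


def _draw_genes(rng, config: GeneratorConfig, subtype: str) -> set:
    genes: set = set()
    # IDH1 and IDH2 are mutually exclusive: one categorical draw
    p1 = config.gene_prob("IDH1", subtype) if "IDH1" in config.gene_freqs else 0.0
    p2 = config.gene_prob("IDH2", subtype) if "IDH2" in config.gene_freqs else 0.0
    u = rng.random()
    if u < p1:
        genes.add("IDH1")
    elif u < p1 + p2:
        genes.add("IDH2")
    for g in sorted(config.gene_freqs):
        if g in ("IDH1", "IDH2"):
            continue
        p = config.gene_prob(g, subtype)
        if g in config.cooccurrence:
            partner, mult = config.cooccurrence[g]
            q = config.gene_prob(partner, subtype) if partner in config.gene_freqs else 0.0
            p0 = p / (1.0 - q + mult * q) if p > 0 else 0.0
            p = min(mult * p0, 0.95) if partner in genes else p0
        if rng.random() < p:
            genes.add(g)
    return genes
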