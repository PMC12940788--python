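"""Somatic-variant consensus cascade for panel sequencing of chondrosarcoma.

Tumor-only panel sequencing without matched normals produces call sets that
mix true somatic variants with germline leak-through, FFPE deamination
artifacts and sequencing noise.  The cascade implemented here consumes the
*outputs* of three callers per sample (Torrent Suite "TS", GATK/Mutect2
"GATK", Ion Reporter "IR"), applies per-branch quality filters, merges the
branches as (TS ∩ GATK) ∪ IR, subtracts a pool-of-normals call set, applies
post-filtration and annotation-based pathogenicity rules, and reports the
tumor mutational burden (TMB) as final variants per megabase of panel.

Every removal is recorded in a per-stage ledger so that the stages partition
the difference between the input and the final call set.
"""

from __future__ import annotations

import dataclasses
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VariantRecord",
    "SampleMeta",
    "SampleVariantProfile",
    "FilterThresholds",
    "parse_caller_vcf",
    "write_vcf",
    "normalize_left_align",
    "filter_gatk_branch",
    "filter_ir_branch",
    "apply_deamination_policy",
    "check_sample_admission",
    "merge_callers",
    "subtract_pool",
    "post_filter",
    "pathogenicity_filter",
    "run_cascade",
    "compute_tmb",
    "summarize_cnv",
]

DIALECTS = ("TS", "GATK", "IR")

#: ledger stage names, in cascade order
STAGES = (
    "gatk_filter",
    "ir_filter",
    "merge",
    "pool",
    "post_filter",
    "annotation_low_benign",
    "annotation_predictor",
    "unclassifiable",
    "population_af",
    "read_support",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One candidate somatic call with caller provenance and annotations.

    Coordinates are 1-based as in VCF.  Quality fields that a caller did not
    emit are ``None`` (absent), never zero.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: str | None = None  # SNP | MNP | INDEL
    dp: int | None = None
    af: float | None = None
    tlod: float | None = None
    sb_fwd: int | None = None
    sb_rev: int | None = None
    callers: frozenset = frozenset()
    impact: str | None = None          # HIGH | MODERATE | LOW | MODIFIER
    clnsig: str | None = None          # ClinVar clinical significance
    sift: str | None = None            # deleterious | tolerated
    polyphen: str | None = None        # damaging | benign
    alphamissense: str | None = None   # pathogenic | benign | ambiguous
    dbsnp: str | None = None
    kg_af: float | None = None         # 1000 Genomes allele frequency
    gene: str | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.dp is not None and self.dp < 0:
            raise ValueError("DP must be non-negative")
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise ValueError(f"AF out of [0,1] at {self.chrom}:{self.pos}: {self.af}")
        if (
            self.sb_fwd is not None
            and self.sb_rev is not None
            and self.dp is not None
            and self.sb_fwd + self.sb_rev > self.dp
        ):
            raise ValueError("strand support exceeds DP")
        if self.var_class is None:
            object.__setattr__(self, "var_class", classify_alleles(self.ref, self.alt))

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def alt_reads(self) -> int | None:
        if self.sb_fwd is None or self.sb_rev is None:
            return None
        return self.sb_fwd + self.sb_rev


def classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "SNP" if len(ref) == 1 else "MNP"
    return "INDEL"


@dataclass
class SampleMeta:
    """Per-sample sequencing metadata used for admission and the strict policy."""

    sample: str
    deamination_score: float = 0.0
    preliminary_tmb: float = 0.0
    chip_loading: float | None = None       # percent; admission: >= 80
    polyclonality: float | None = None      # percent; admission: <= 30
    uniformity: float | None = None         # percent; admission: >= 80
    mapped_reads: float | None = None       # admission: >= 10e6
    mean_coverage: float | None = None      # admission: >= 1000

    def __post_init__(self):
        if self.deamination_score < 0:
            raise ValueError("deamination score must be >= 0")


@dataclass
class FilterThresholds:
    """Every numeric threshold of the cascade, exposed by name.

    Defaults follow the published tumor-only panel workflow.  The strict
    GATK SNP/MNP allele-fraction floor applied under the deamination policy
    is configurable; its published value is 0.75.
    """

    gatk_snp_dp: int = 15
    gatk_snp_af: float = 0.015
    gatk_tlod: float = 14.0
    gatk_indel_dp: int = 70
    gatk_indel_af_low: float = 0.35
    gatk_indel_af_high: float = 0.55
    ir_af: float = 0.05
    post_af: float = 0.05
    post_dp: int = 50
    kg_af_max: float = 0.05
    min_alt_reads: int = 5
    min_strand_reads: int = 2
    panel_size_mb: float = 1.7
    # strict (deamination) policy
    strict_ir_af: float = 0.10
    strict_gatk_snp_af: float = 0.75
    deamination_qualify: float = 10.0
    deamination_strict_low: float = 10.0
    deamination_strict_high: float = 25.0
    tmb_strict_low: float = 11.0
    tmb_strict_high: float = 50.0
    annotation_profile: str = "Oncomine Extended"

    def copy(self) -> "FilterThresholds":
        return replace(self)


@dataclass
class SampleVariantProfile:
    """Final filtered variants of one sample plus TMB, flags and the removal ledger."""

    sample: str
    final: list
    tmb: float
    gene_flags: set
    cnv_events: list = field(default_factory=list)
    ledger: "OrderedDict[str, list]" = field(default_factory=OrderedDict)

    @property
    def n_final(self) -> int:
        return len(self.final)


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

_INFO_FIELDS = [
    ("DP", "1", "Integer", "Total read depth"),
    ("AF", "A", "Float", "Allele fraction"),
    ("TLOD", "A", "Float", "Tumor log-odds score"),
    ("SB_FWD", "1", "Integer", "Forward-strand alt read count"),
    ("SB_REV", "1", "Integer", "Reverse-strand alt read count"),
    ("IMPACT", "1", "String", "Predicted impact"),
    ("CLNSIG", "1", "String", "ClinVar clinical significance"),
    ("SIFT", "1", "String", "SIFT classification"),
    ("POLYPHEN", "1", "String", "PolyPhen-2 classification"),
    ("AM_CLASS", "1", "String", "AlphaMissense classification"),
    ("DBSNP", "1", "String", "dbSNP identifier"),
    ("KG_AF", "1", "Float", "1000 Genomes allele frequency"),
    ("GENE", "1", "String", "Gene symbol"),
]

_STR_INFO = {
    "IMPACT": "impact",
    "CLNSIG": "clnsig",
    "SIFT": "sift",
    "POLYPHEN": "polyphen",
    "AM_CLASS": "alphamissense",
    "DBSNP": "dbsnp",
    "GENE": "gene",
}


def write_vcf(records: Sequence[VariantRecord], path, sample: str = "SAMPLE") -> None:
    """Write records to an uncompressed VCF 4.2 file with the cascade INFO keys."""
    lines = ["##fileformat=VCFv4.2", f"##source=chondroprofiler;sample={sample}"]
    chroms = []
    for r in records:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    for c in sorted(chroms, key=_chrom_sort_key):
        lines.append(f"##contig=<ID={c}>")
    for key, num, typ, desc in _INFO_FIELDS:
        lines.append(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in sorted(records, key=lambda r: (_chrom_sort_key(r.chrom), r.pos, r.ref, r.alt)):
        info = []
        if r.dp is not None:
            info.append(f"DP={r.dp}")
        if r.af is not None:
            info.append(f"AF={r.af:.6g}")
        if r.tlod is not None:
            info.append(f"TLOD={r.tlod:.6g}")
        if r.sb_fwd is not None:
            info.append(f"SB_FWD={r.sb_fwd}")
        if r.sb_rev is not None:
            info.append(f"SB_REV={r.sb_rev}")
        for key, attr in _STR_INFO.items():
            val = getattr(r, attr)
            if val is not None:
                info.append(f"{key}={val.replace(' ', '_')}")
        if r.kg_af is not None:
            info.append(f"KG_AF={r.kg_af:.6g}")
        rid = r.dbsnp or "."
        lines.append(
            f"{r.chrom}\t{r.pos}\t{rid}\t{r.ref}\t{r.alt}\t.\tPASS\t"
            + (";".join(info) if info else ".")
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _chrom_sort_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


def parse_caller_vcf(path, dialect: str) -> list:
    """Parse one caller's VCF into :class:`VariantRecord` objects.

    Multi-allelic sites are split into one record per alternate allele
    (per-allele INFO values are indexed accordingly); missing INFO keys are
    stored as ``None``.
    """
    import pysam

    if dialect not in DIALECTS:
        raise ValueError(f"unknown caller dialect: {dialect!r}")
    def _get(info, key):
        try:
            return info.get(key)
        except ValueError:  # INFO key absent from this file's header
            return None

    records = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                info = rec.info
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        dp=_scalar(_get(info, "DP")),
                        af=_per_allele(_get(info, "AF"), i),
                        tlod=_per_allele(_get(info, "TLOD"), i),
                        sb_fwd=_scalar(_get(info, "SB_FWD")),
                        sb_rev=_scalar(_get(info, "SB_REV")),
                        callers=frozenset({dialect}),
                        impact=_string(_get(info, "IMPACT")),
                        clnsig=_string(_get(info, "CLNSIG")),
                        sift=_string(_get(info, "SIFT")),
                        polyphen=_string(_get(info, "POLYPHEN")),
                        alphamissense=_string(_get(info, "AM_CLASS")),
                        dbsnp=_string(_get(info, "DBSNP")),
                        kg_af=_scalar(_get(info, "KG_AF")),
                        gene=_string(_get(info, "GENE")),
                    )
                )
    return records


def _scalar(v):
    if v is None:
        return None
    if isinstance(v, tuple):
        v = v[0]
    return float(f"{v:.6g}") if isinstance(v, float) else v


def _per_allele(v, i):
    if v is None:
        return None
    if isinstance(v, tuple):
        v = v[i] if i < len(v) else v[0]
    return float(f"{v:.6g}") if isinstance(v, float) else v


def _string(v):
    if v is None:
        return None
    if isinstance(v, tuple):
        v = v[0]
    return str(v)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_left_align(
    records: Iterable[VariantRecord],
    reference: Mapping[str, str] | None = None,
) -> list:
    """Trim shared allele context and left-align INDELs.

    ``reference`` maps chromosome name to its (synthetic or real) sequence,
    1-based position ``p`` at index ``p - 1``.  Pure prefix/suffix trimming
    needs no reference; left-shifting an INDEL through repeat sequence does,
    and raises if the reference is absent or disagrees with the record.
    """
    out = []
    for r in records:
        chrom, pos, ref, alt = r.chrom, r.pos, r.ref, r.alt
        if reference is not None and chrom in reference:
            seq = reference[chrom]
            if seq[pos - 1 : pos - 1 + len(ref)].upper() != ref.upper():
                raise ValueError(f"reference mismatch at {chrom}:{pos} (REF {ref})")
        # vt-style normalization loop: trim shared trailing base, extending
        # left from the reference when an allele would empty out.
        while True:
            if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
                ref, alt = ref[:-1], alt[:-1]
                if not ref or not alt:
                    if reference is None or chrom not in reference:
                        raise ValueError(
                            f"reference context required to left-align {chrom}:{r.pos} {r.ref}>{r.alt}"
                        )
                    if pos <= 1:
                        raise ValueError(f"cannot left-shift past start of {chrom}")
                    base = reference[chrom][pos - 2].upper()
                    ref, alt, pos = base + ref, base + alt, pos - 1
            else:
                break
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt, pos = ref[1:], alt[1:], pos + 1
        out.append(
            replace(r, pos=pos, ref=ref, alt=alt, var_class=classify_alleles(ref, alt))
        )
    return out


# ---------------------------------------------------------------------------
# per-branch filters and the deamination policy
# ---------------------------------------------------------------------------

def filter_gatk_branch(
    records: Iterable[VariantRecord], thresholds: FilterThresholds | None = None
) -> tuple[list, list]:
    """Quality-filter the GATK/Mutect2 branch.

    SNP/MNP: DP >= 15, AF >= 0.015, TLOD >= 14.  INDEL: DP >= 70 and
    0.35 <= AF <= 0.55.  All bounds inclusive.  Returns (kept, removed)
    where removed entries are ``(record, reason)`` pairs.
    """
    th = thresholds or FilterThresholds()
    kept, removed = [], []
    for r in records:
        if r.var_class in ("SNP", "MNP"):
            if r.dp is None or r.af is None or r.tlod is None:
                removed.append((r, "missing_quality_field"))
            elif r.dp >= th.gatk_snp_dp and r.af >= th.gatk_snp_af and r.tlod >= th.gatk_tlod:
                kept.append(r)
            else:
                removed.append((r, "gatk_snp_thresholds"))
        else:  # INDEL
            if r.dp is None or r.af is None:
                removed.append((r, "missing_quality_field"))
            elif r.dp >= th.gatk_indel_dp and th.gatk_indel_af_low <= r.af <= th.gatk_indel_af_high:
                kept.append(r)
            else:
                removed.append((r, "gatk_indel_thresholds"))
    return kept, removed


def filter_ir_branch(
    records: Iterable[VariantRecord], thresholds: FilterThresholds | None = None
) -> tuple[list, list]:
    """Apply the Ion Reporter minimum allele-fraction floor (default 0.05)."""
    th = thresholds or FilterThresholds()
    kept, removed = [], []
    for r in records:
        if r.af is not None and r.af >= th.ir_af:
            kept.append(r)
        else:
            removed.append((r, "ir_af_floor"))
    return kept, removed


def check_sample_admission(meta: SampleMeta, thresholds: FilterThresholds | None = None) -> tuple[bool, list]:
    """Run-level QC admission: deamination score and sequencing-run metrics.

    Samples with deamination score >= 10 fail admission outright; the other
    run metrics (chip loading >= 80%, polyclonality <= 30%, uniformity >=
    80%, >= 10 M mapped reads, mean coverage >= 1000x) are checked when
    present.
    """
    th = thresholds or FilterThresholds()
    reasons = []
    if meta.deamination_score >= th.deamination_strict_high:
        reasons.append("deamination_score")
    if meta.chip_loading is not None and meta.chip_loading < 80:
        reasons.append("chip_loading")
    if meta.polyclonality is not None and meta.polyclonality > 30:
        reasons.append("polyclonality")
    if meta.uniformity is not None and meta.uniformity < 80:
        reasons.append("uniformity")
    if meta.mapped_reads is not None and meta.mapped_reads < 10e6:
        reasons.append("mapped_reads")
    if meta.mean_coverage is not None and meta.mean_coverage < 1000:
        reasons.append("mean_coverage")
    return (not reasons, reasons)


def apply_deamination_policy(
    meta: SampleMeta, thresholds: FilterThresholds | None = None
) -> FilterThresholds:
    """Return thresholds adjusted for FFPE deamination risk.

    For a deamination score in [10, 25] and/or a preliminary TMB in
    [11, 50] mut/Mb, the IR AF floor rises from 0.05 to 0.10, the GATK
    SNP/MNP AF floor is replaced by the configured strict value, and the
    annotation-filter profile switches from "Oncomine Extended" to
    "Oncomine Variants".  Otherwise thresholds are returned unchanged.
    """
    th = (thresholds or FilterThresholds()).copy()
    strict = (
        th.deamination_strict_low <= meta.deamination_score <= th.deamination_strict_high
        or th.tmb_strict_low <= meta.preliminary_tmb <= th.tmb_strict_high
    )
    if strict:
        th.ir_af = th.strict_ir_af
        th.gatk_snp_af = th.strict_gatk_snp_af
        th.post_af = max(th.post_af, th.strict_ir_af)
        th.annotation_profile = "Oncomine Variants"
    return th


# ---------------------------------------------------------------------------
# merge and downstream filters
# ---------------------------------------------------------------------------

_CALLER_PRECEDENCE = ("GATK", "TS", "IR")
_QUALITY_ATTRS = ("dp", "af", "tlod", "sb_fwd", "sb_rev")
_ANNOT_ATTRS = (
    "impact", "clnsig", "sift", "polyphen", "alphamissense", "dbsnp", "kg_af", "gene",
)


def merge_callers(ts: Sequence, gatk: Sequence, ir: Sequence) -> list:
    """Consensus merge: (keys(TS) ∩ keys(GATK)) ∪ keys(IR).

    A merged record unions caller provenance; field values are taken by
    caller precedence GATK > TS > IR (first non-absent wins).  Output is
    sorted by genomic key, so the result is independent of input order.
    """
    by_caller = {"TS": _index(ts), "GATK": _index(gatk), "IR": _index(ir)}
    keys = (set(by_caller["TS"]) & set(by_caller["GATK"])) | set(by_caller["IR"])
    merged = []
    for key in sorted(keys, key=lambda k: (_chrom_sort_key(k[0]), k[1], k[2], k[3])):
        sources = [by_caller[c][key] for c in _CALLER_PRECEDENCE if key in by_caller[c]]
        refs = {s.ref for s in sources}
        if len(refs) > 1:  # same (chrom,pos,ref,alt) key always shares ref; guard anyway
            raise ValueError(f"conflicting REF alleles at {key[0]}:{key[1]}")
        fields = {}
        for attr in _QUALITY_ATTRS + _ANNOT_ATTRS:
            for s in sources:
                v = getattr(s, attr)
                if v is not None:
                    fields[attr] = v
                    break
        prov = frozenset().union(*(s.callers for s in sources))
        merged.append(replace(sources[0], callers=prov, **fields))
    return merged


def _index(records: Sequence) -> dict:
    idx = {}
    for r in records:
        if r.key in idx:
            raise ValueError(f"duplicate record key {r.key} within one caller set")
        idx[r.key] = r
    return idx


def subtract_pool(records: Iterable[VariantRecord], pool_keys) -> tuple[list, list]:
    """Remove records whose (chrom, pos, ref, alt) key is in the pool of normals."""
    pool = {k.key if hasattr(k, "key") else tuple(k) for k in pool_keys}
    kept, removed = [], []
    for r in records:
        (removed if r.key in pool else kept).append(r)
    return kept, removed


def post_filter(
    records: Iterable[VariantRecord], thresholds: FilterThresholds | None = None
) -> tuple[list, list]:
    """Post-merge filtration: AF >= 0.05 (policy-adjustable) and DP >= 50."""
    th = thresholds or FilterThresholds()
    kept, removed = [], []
    for r in records:
        if r.af is None or r.dp is None:
            removed.append((r, "missing_quality_field"))
        elif r.af >= th.post_af and r.dp >= th.post_dp:
            kept.append(r)
        else:
            removed.append((r, "post_thresholds"))
    return kept, removed


def pathogenicity_filter(
    records: Iterable[VariantRecord], thresholds: FilterThresholds | None = None
) -> tuple[list, dict]:
    """Annotation-based pathogenicity cascade.

    In order: (1) drop LOW-impact ClinVar-benign records; (2) keep only
    records classified deleterious by SIFT *and* damaging by PolyPhen-2, or
    pathogenic by AlphaMissense (records with all three predictors absent
    are dropped as unclassifiable); (3) drop 1000 Genomes AF > 0.05; (4)
    drop records with fewer than 5 alt reads in total or fewer than 2 on
    either strand.  Returns (kept, {rule: [records]}).
    """
    th = thresholds or FilterThresholds()
    removed = {
        "annotation_low_benign": [],
        "annotation_predictor": [],
        "unclassifiable": [],
        "population_af": [],
        "read_support": [],
    }
    kept = []
    for r in records:
        if r.impact == "LOW" and (r.clnsig or "").lower() == "benign":
            removed["annotation_low_benign"].append(r)
            continue
        sift_poly = r.sift == "deleterious" and r.polyphen == "damaging"
        am = r.alphamissense == "pathogenic"
        if r.sift is None and r.polyphen is None and r.alphamissense is None:
            removed["unclassifiable"].append(r)
            continue
        if not (sift_poly or am):
            removed["annotation_predictor"].append(r)
            continue
        if r.kg_af is not None and r.kg_af > th.kg_af_max:
            removed["population_af"].append(r)
            continue
        alt_reads = r.alt_reads
        if alt_reads is not None and (
            alt_reads < th.min_alt_reads
            or min(r.sb_fwd, r.sb_rev) < th.min_strand_reads
        ):
            removed["read_support"].append(r)
            continue
        kept.append(r)
    return kept, removed


# ---------------------------------------------------------------------------
# whole cascade, TMB, CNV summary
# ---------------------------------------------------------------------------

def run_cascade(
    caller_sets: Mapping[str, Sequence],
    pool_keys,
    meta: SampleMeta | None = None,
    thresholds: FilterThresholds | None = None,
    cnv_events: Sequence | None = None,
) -> SampleVariantProfile:
    """Run one sample through the full filtration cascade.

    ``caller_sets`` maps dialect -> normalized records.  The removal ledger
    attributes each input key to the first stage that removed it; ledger
    stages partition (input keys − final keys).
    """
    sample = meta.sample if meta is not None else "SAMPLE"
    th = apply_deamination_policy(meta, thresholds) if meta is not None else (
        (thresholds or FilterThresholds()).copy()
    )
    ts = list(caller_sets.get("TS", ()))
    gatk = list(caller_sets.get("GATK", ()))
    ir = list(caller_sets.get("IR", ()))
    all_keys = {r.key for recs in (ts, gatk, ir) for r in recs}

    ledger: OrderedDict[str, list] = OrderedDict((s, []) for s in STAGES)
    gatk_kept, gatk_removed = filter_gatk_branch(gatk, th)
    ir_kept, ir_removed = filter_ir_branch(ir, th)

    merged = merge_callers(ts, gatk_kept, ir_kept)
    merged_keys = {r.key for r in merged}
    # attribute keys lost before/at the merge
    gatk_removed_keys = {r.key for r, _ in gatk_removed}
    ir_removed_keys = {r.key for r, _ in ir_removed}
    for key in sorted(all_keys - merged_keys, key=lambda k: (_chrom_sort_key(k[0]), k[1], k[2], k[3])):
        if key in gatk_removed_keys:
            stage = "gatk_filter"
        elif key in ir_removed_keys:
            stage = "ir_filter"
        else:
            stage = "merge"
        ledger[stage].append(key)

    kept, pooled = subtract_pool(merged, pool_keys)
    ledger["pool"].extend(r.key for r in pooled)

    kept, post_removed = post_filter(kept, th)
    ledger["post_filter"].extend(r.key for r, _ in post_removed)

    final, patho_removed = pathogenicity_filter(kept, th)
    for rule, recs in patho_removed.items():
        ledger[rule].extend(r.key for r in recs)

    tmb = compute_tmb(final, th.panel_size_mb)
    gene_flags = {r.gene for r in final if r.gene is not None}
    return SampleVariantProfile(
        sample=sample,
        final=final,
        tmb=tmb,
        gene_flags=gene_flags,
        cnv_events=list(cnv_events or ()),
        ledger=ledger,
    )


def compute_tmb(final_records, panel_size_mb: float = 1.7) -> float:
    """TMB in mut/Mb: number of final variants (CNVs excluded) / panel size."""
    if panel_size_mb <= 0:
        raise ValueError("panel size must be positive")
    n = final_records if isinstance(final_records, int) else len(final_records)
    return n / panel_size_mb


def summarize_cnv(cnv_table: pd.DataFrame, cohort: pd.DataFrame) -> dict:
    """Summarize copy-number events by subtype and type.

    ``cnv_table`` has columns (sample, gene, type in {amp, del}); ``cohort``
    has one row per patient with columns (sample, subtype).  Returns counts
    by (subtype, type), total events, and the fraction of patients with at
    least one event.
    """
    known = set(cohort["sample"])
    unknown = set(cnv_table["sample"]) - known if len(cnv_table) else set()
    if unknown:
        raise ValueError(f"unknown sample ids in CNV table: {sorted(unknown)[:5]}")
    subtype_of = dict(zip(cohort["sample"], cohort["subtype"]))
    counts: dict = {}
    for _, row in cnv_table.iterrows():
        key = (subtype_of[row["sample"]], row["type"])
        counts[key] = counts.get(key, 0) + 1
    carriers = cnv_table["sample"].nunique() if len(cnv_table) else 0
    return {
        "n_events": int(len(cnv_table)),
        "counts_by_subtype": {f"{s}:{t}": int(c) for (s, t), c in sorted(counts.items())},
        "fraction_patients_with_cnv": carriers / len(cohort) if len(cohort) else 0.0,
    }
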