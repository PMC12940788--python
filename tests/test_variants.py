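"""Tests of the somatic-variant cascade: VCF round-trips, normalization,
per-branch filters, merge algebra, pool subtraction, pathogenicity rules,
TMB and CNV summaries."""

import dataclasses
import itertools
import random

import numpy as np
import pandas as pd
import pytest

from chondroprofiler.variants import (
    FilterThresholds,
    SampleMeta,
    VariantRecord,
    apply_deamination_policy,
    compute_tmb,
    filter_gatk_branch,
    merge_callers,
    normalize_left_align,
    parse_caller_vcf,
    pathogenicity_filter,
    post_filter,
    run_cascade,
    subtract_pool,
    summarize_cnv,
    write_vcf,
)


def rec(**kw):
    base = dict(chrom="1", pos=100, ref="A", alt="T", dp=500, af=0.3, tlod=80.0,
                sb_fwd=60, sb_rev=60, sift="deleterious", polyphen="damaging",
                impact="MODERATE", gene="TP53")
    base.update(kw)
    if (
        "sb_fwd" not in kw and "sb_rev" not in kw
        and base["dp"] is not None and base["dp"] < 120
    ):
        base["sb_fwd"] = base["sb_rev"] = base["dp"] // 2
    return VariantRecord(**base)


# ---------------------------------------------------------------------------
# record invariants and VCF IO
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kw", [
    dict(ref="A", alt="A"),
    dict(af=1.2),
    dict(dp=-1),
    dict(sb_fwd=400, sb_rev=400, dp=500),
])
def test_invalid_records_rejected(kw):
    with pytest.raises(ValueError):
        rec(**kw)


def test_vcf_round_trip_preserves_fields(tmp_path, default_cohort):
    sample = default_cohort.truth.patients[0].sample
    records = default_cohort.caller_sets[sample]["GATK"]
    path = tmp_path / "x.vcf"
    write_vcf(records, path, sample)
    back = parse_caller_vcf(path, "GATK")
    key = lambda r: r.key
    for a, b in zip(sorted(records, key=key), sorted(back, key=key)):
        assert dataclasses.replace(a, callers=frozenset({"GATK"})) == b


def test_empty_vcf_parses_to_empty_list(tmp_path):
    path = tmp_path / "empty.vcf"
    write_vcf([], path)
    assert parse_caller_vcf(path, "TS") == []


def test_multiallelic_site_split_per_alt(tmp_path):
    path = tmp_path / "multi.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">\n'
        '##INFO=<ID=AF,Number=A,Type=Float,Description="a">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "1\t100\t.\tA\tC,T\t.\tPASS\tDP=100;AF=0.2,0.3\n"
    )
    out = parse_caller_vcf(path, "GATK")
    assert [(r.alt, r.af) for r in out] == [("C", 0.2), ("T", 0.3)]
    assert all(r.dp == 100 for r in out)


def test_unknown_dialect_rejected(tmp_path):
    with pytest.raises(ValueError, match="dialect"):
        parse_caller_vcf(tmp_path / "x.vcf", "CALLER9")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_shared_prefix_trimmed():
    out = normalize_left_align([rec(pos=100, ref="CT", alt="CA")])
    assert (out[0].pos, out[0].ref, out[0].alt) == (101, "T", "A")


def test_homopolymer_deletion_left_aligned():
    # reference 1-based: G A A A A C; deletion of one A written at pos 4
    ref = {"1": "GAAAAC"}
    out = normalize_left_align([rec(pos=4, ref="AA", alt="A")], ref)
    assert (out[0].pos, out[0].ref, out[0].alt) == (1, "GA", "G")


def test_reference_mismatch_raises():
    with pytest.raises(ValueError, match="reference mismatch"):
        normalize_left_align([rec(pos=2, ref="T", alt="G")], {"1": "GAAAAC"})


def test_equivalent_indel_encodings_share_canonical_key(rng):
    bases = "ACGT"
    for _ in range(20):
        seq = "".join(rng.choice(list(bases)) for _ in range(30))
        reference = {"1": seq}
        pos = int(rng.integers(5, 20))
        dellen = int(rng.integers(1, 3))
        canonical = normalize_left_align(
            [rec(pos=pos, ref=seq[pos - 1: pos + dellen], alt=seq[pos - 1])],
            reference,
        )[0]
        # re-encode with extra shared context on both sides
        for pad in range(1, 4):
            start = pos - pad
            if start < 1:
                continue
            padded = rec(
                pos=start,
                ref=seq[start - 1: pos + dellen],
                alt=seq[start - 1: pos] + "",
            )
            out = normalize_left_align([padded], reference)[0]
            assert out.key == canonical.key


# ---------------------------------------------------------------------------
# branch filters and policy
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kw,kept", [
    (dict(dp=15, af=0.015, tlod=14.0), True),       # inclusive boundaries
    (dict(dp=14, af=0.9, tlod=100.0), False),
    (dict(dp=1000, af=0.014, tlod=100.0), False),
    (dict(dp=1000, af=0.5, tlod=13.9), False),
])
def test_gatk_snp_thresholds(kw, kept):
    out, removed = filter_gatk_branch([rec(**kw)])
    assert (len(out) == 1) is kept


@pytest.mark.parametrize("kw,kept", [
    (dict(ref="AT", alt="A", dp=70, af=0.35, sb_fwd=10, sb_rev=10), True),
    (dict(ref="AT", alt="A", dp=70, af=0.55, sb_fwd=10, sb_rev=10), True),
    (dict(ref="AT", alt="A", dp=70, af=0.56, sb_fwd=10, sb_rev=10), False),
    (dict(ref="AT", alt="A", dp=69, af=0.45, sb_fwd=10, sb_rev=10), False),
])
def test_gatk_indel_af_window(kw, kept):
    out, _ = filter_gatk_branch([rec(**kw)])
    assert (len(out) == 1) is kept


def test_missing_tlod_rejected_with_reason():
    out, removed = filter_gatk_branch([rec(tlod=None)])
    assert out == [] and removed[0][1] == "missing_quality_field"


@pytest.mark.parametrize("deam,tmb,strict", [
    (9.0, 5.0, False),
    (12.0, 5.0, True),
    (0.0, 20.0, True),
    (9.9, 10.9, False),
    (25.0, 0.0, True),
])
def test_deamination_policy_triggers(deam, tmb, strict):
    meta = SampleMeta(sample="S", deamination_score=deam, preliminary_tmb=tmb)
    th = apply_deamination_policy(meta)
    if strict:
        assert th.ir_af == 0.1
        assert th.gatk_snp_af == th.strict_gatk_snp_af
        assert th.annotation_profile == "Oncomine Variants"
    else:
        assert th.ir_af == 0.05 and th.gatk_snp_af == 0.015
        assert th.annotation_profile == "Oncomine Extended"


# ---------------------------------------------------------------------------
# merge, pool, post-filter, pathogenicity
# ---------------------------------------------------------------------------

def test_merge_set_algebra_over_all_membership_patterns():
    # enumerate every (TS, GATK, IR) membership pattern; merged membership
    # must equal (TS and GATK) or IR
    records = {}
    ts, gatk, ir = [], [], []
    for i, (in_ts, in_gatk, in_ir) in enumerate(itertools.product([0, 1], repeat=3)):
        if not (in_ts or in_gatk or in_ir):
            continue
        r = rec(pos=1000 + i)
        records[r.key] = (in_ts, in_gatk, in_ir)
        if in_ts:
            ts.append(dataclasses.replace(r, callers=frozenset({"TS"}), tlod=None))
        if in_gatk:
            gatk.append(dataclasses.replace(r, callers=frozenset({"GATK"})))
        if in_ir:
            ir.append(dataclasses.replace(r, callers=frozenset({"IR"}), tlod=None))
    merged = {r.key: r for r in merge_callers(ts, gatk, ir)}
    for key, (in_ts, in_gatk, in_ir) in records.items():
        expected = (in_ts and in_gatk) or in_ir
        assert (key in merged) is bool(expected)
    # provenance union and GATK-precedence TLOD
    full = [k for k, v in records.items() if v == (1, 1, 1)][0]
    assert merged[full].callers == {"TS", "GATK", "IR"}
    assert merged[full].tlod is not None


def test_merge_order_insensitive(rng):
    ts = [rec(pos=1000 + i) for i in range(10)]
    gatk = [rec(pos=1000 + i) for i in range(0, 10, 2)]
    ir = [rec(pos=2000 + i) for i in range(3)]
    a = merge_callers(ts, gatk, ir)
    shuffled = [list(x) for x in (ts, gatk, ir)]
    for s in shuffled:
        random.Random(0).shuffle(s)
    b = merge_callers(*shuffled)
    assert [r.key for r in a] == [r.key for r in b]


def test_pool_subtraction():
    pool = [rec(pos=500)]
    keep, removed = subtract_pool([rec(pos=500), rec(pos=501)], pool)
    assert [r.pos for r in keep] == [501] and [r.pos for r in removed] == [500]
    keep2, removed2 = subtract_pool([rec(pos=500)], [])
    assert len(keep2) == 1 and removed2 == []


@pytest.mark.parametrize("af,dp,kept", [
    (0.05, 50, True),
    (0.049, 500, False),
    (0.5, 49, False),
])
def test_post_filter_boundaries(af, dp, kept):
    out, _ = post_filter([rec(af=af, dp=dp, sb_fwd=min(10, dp // 2), sb_rev=min(10, dp // 2))])
    assert (len(out) == 1) is kept


@pytest.mark.parametrize("kw,rule", [
    (dict(impact="LOW", clnsig="benign"), "annotation_low_benign"),
    (dict(sift="tolerated", polyphen="damaging", alphamissense="benign"),
     "annotation_predictor"),
    (dict(sift=None, polyphen=None, alphamissense=None), "unclassifiable"),
    (dict(kg_af=0.06), "population_af"),
    (dict(sb_fwd=1, sb_rev=10, dp=110, af=0.1), "read_support"),
    (dict(sb_fwd=2, sb_rev=2, dp=80, af=0.05), "read_support"),  # <5 total
])
def test_pathogenicity_rules(kw, rule):
    kept, removed = pathogenicity_filter([rec(**kw)])
    assert kept == []
    assert len(removed[rule]) == 1


def test_pathogenicity_alphamissense_rescues_missing_predictors():
    kept, _ = pathogenicity_filter(
        [rec(sift=None, polyphen=None, alphamissense="pathogenic")])
    assert len(kept) == 1


def test_pathogenicity_kg_af_boundary_inclusive():
    kept, _ = pathogenicity_filter([rec(kg_af=0.05)])
    assert len(kept) == 1  # removal requires AF strictly above 0.05


# ---------------------------------------------------------------------------
# TMB, CNV, full cascade
# ---------------------------------------------------------------------------

def test_tmb_values():
    assert compute_tmb([], 1.7) == 0.0
    assert compute_tmb(17, 1.7) == pytest.approx(10.0)
    assert compute_tmb(4, 1.7) == pytest.approx(4 / 1.7)
    assert compute_tmb([rec(pos=i) for i in range(4)]) == pytest.approx(2.352941176)
    with pytest.raises(ValueError):
        compute_tmb(3, 0.0)


def test_tmb_scales_linearly():
    records = [rec(pos=100 + i) for i in range(6)]
    assert compute_tmb(records * 2) == pytest.approx(2 * compute_tmb(records))


def test_cnv_summary_counts():
    cohort = pd.DataFrame({"sample": ["a", "b", "c", "d"],
                           "subtype": ["G1", "G2", "G3", "G3"]})
    empty = pd.DataFrame(columns=["sample", "gene", "type"])
    s = summarize_cnv(empty, cohort)
    assert s["n_events"] == 0 and s["fraction_patients_with_cnv"] == 0.0
    one = pd.DataFrame({"sample": ["c"], "gene": ["RB1"], "type": ["del"]})
    s = summarize_cnv(one, cohort)
    assert s["fraction_patients_with_cnv"] == 0.25
    assert s["counts_by_subtype"] == {"G3:del": 1}
    with pytest.raises(ValueError, match="unknown sample"):
        summarize_cnv(pd.DataFrame({"sample": ["zz"], "gene": ["X"], "type": ["amp"]}),
                      cohort)


def test_cascade_monotone_and_ledger_partition(default_cohort):
    pool_keys = {r.key for r in default_cohort.pool}
    for p in default_cohort.truth.patients[:20]:
        sets = default_cohort.caller_sets[p.sample]
        prof = run_cascade(sets, pool_keys, default_cohort.meta[p.sample])
        all_keys = {r.key for d in sets.values() for r in d}
        final_keys = {r.key for r in prof.final}
        assert final_keys <= all_keys
        ledgered = [k for keys in prof.ledger.values() for k in keys]
        assert len(ledgered) == len(set(ledgered))
        assert set(ledgered) == all_keys - final_keys


def test_cascade_order_insensitive(default_cohort):
    p = default_cohort.truth.patients[0]
    sets = default_cohort.caller_sets[p.sample]
    pool_keys = {r.key for r in default_cohort.pool}
    prof_a = run_cascade(sets, pool_keys, default_cohort.meta[p.sample])
    shuffled = {d: list(v) for d, v in sets.items()}
    for v in shuffled.values():
        random.Random(7).shuffle(v)
    prof_b = run_cascade(shuffled, pool_keys, default_cohort.meta[p.sample])
    assert [r.key for r in prof_a.final] == [r.key for r in prof_b.final]


def test_cascade_separates_truth_on_default_cohort(default_cohort):
    pool_keys = {r.key for r in default_cohort.pool}
    for p in default_cohort.truth.patients:
        prof = run_cascade(default_cohort.caller_sets[p.sample], pool_keys,
                           default_cohort.meta[p.sample])
        assert {r.key for r in prof.final} == {v.key for v in p.variants}
        for cont in p.contaminants:
            assert cont.record.key in prof.ledger[cont.stage]
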