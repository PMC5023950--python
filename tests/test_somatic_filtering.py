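"""Somatic filter rules: Fisher test, matched/unmatched rule sets."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lymphomut.errors import ConfigurationError, UndefinedValueError
from lymphomut.somatic_filtering import (
    FilterConfig,
    VariantRecord,
    allele_frequency,
    filter_matched,
    filter_unmatched,
    filter_variants,
    fisher_somatic_p,
)


def hypergeom_tail_p(t_ref, t_alt, n_ref, n_alt):
    """Exact one-sided Fisher p by hypergeometric enumeration (oracle).

    Conditions on the margins of [[t_alt, t_ref], [n_alt, n_ref]] and sums
    the probability of tables with tumour alt count >= observed.
    """
    n_total = t_ref + t_alt + n_ref + n_alt
    alt_total = t_alt + n_alt
    t_depth = t_ref + t_alt
    lo = max(0, alt_total - (n_ref + n_alt))
    hi = min(t_depth, alt_total)
    p = Fraction(0)
    denom = math.comb(n_total, t_depth)
    for k in range(t_alt, hi + 1):
        p += Fraction(math.comb(alt_total, k)
                      * math.comb(n_total - alt_total, t_depth - k), denom)
    assert lo <= t_alt
    return float(p)


def make_variant(t_ref, t_alt, n_ref, n_alt, pop_maf=None, fp=False,
                 gene="G1", func_class="missense"):
    return VariantRecord(chrom="chr1", pos=100, ref="C", alt="T", gene=gene,
                         func_class=func_class, t_ref=t_ref, t_alt=t_alt,
                         n_ref=n_ref, n_alt=n_alt, pop_maf=pop_maf,
                         fp_gene_flag=fp)


# --- allele_frequency -------------------------------------------------------

@pytest.mark.parametrize("ref,alt,expected", [
    (78, 22, Fraction(22, 100)),
    (0, 10, Fraction(1)),
    (10, 0, Fraction(0)),
])
def test_allele_frequency_exact_fraction(ref, alt, expected):
    assert allele_frequency(ref, alt) == expected


def test_allele_frequency_zero_depth_is_undefined():
    with pytest.raises(UndefinedValueError):
        allele_frequency(0, 0)


# --- fisher_somatic_p -------------------------------------------------------

def test_fisher_matches_enumeration_oracle_spot_checks():
    for table in [(10, 10, 20, 0), (50, 30, 98, 2), (39, 11, 10, 0),
                  (5, 5, 5, 5), (12, 0, 9, 3)]:
        assert fisher_somatic_p(*table) == pytest.approx(
            hypergeom_tail_p(*table), abs=1e-12)


def test_fisher_no_signal_is_symmetric():
    assert fisher_somatic_p(5, 5, 5, 5) >= 0.5


def test_fisher_zero_tumour_alt_is_tail_boundary():
    # t_alt = 0 includes the entire one-sided tail.
    assert fisher_somatic_p(12, 0, 9, 3) == pytest.approx(1.0, abs=1e-12)


def test_fisher_zero_depth_is_undefined():
    with pytest.raises(UndefinedValueError):
        fisher_somatic_p(0, 0, 10, 10)


# --- toy table and rule-by-rule oracle --------------------------------------

# Each row exercises one rule of the matched WES filter; several rows flip
# outcome between modes (boundaries differ).
TOY_ROWS = [
    # (t_ref, t_alt, n_ref, n_alt, pop_maf, fp_flag, note)
    (50, 30, 98, 2, None, False, "clean pass"),
    (79, 21, 100, 0, None, False, "tumour AF 0.21 < 22%"),
    (50, 50, 84, 16, None, False, "normal AF 0.16"),
    (70, 30, 90, 10, None, False, "AF diff 0.20 < 0.22"),
    (15, 85, 100, 0, None, False, "tumour ref reads 15 < 18"),
    (18, 5, 100, 0, None, False, "5 alt reads (not more than 5)"),
    (39, 11, 10, 0, None, False, "somatic p 0.109 > 0.1, rest pass"),
    (60, 40, 100, 0, None, True, "false-positive-list gene"),
    (60, 40, 100, 0, 0.30, False, "common population SNP"),
    (56, 44, 99, 1, None, False, "clean pass, no annotation"),
    (6, 2, 100, 0, None, False, "tumour depth 8 < 10"),
    (60, 40, 50, 50, None, False, "germline-like normal AF 0.5"),
]


def toy_variants():
    return [make_variant(*row[:6]) for row in TOY_ROWS]


def oracle_failing_rules(v, cfg):
    """Independent rule audit: evaluates every rule, returns all failures."""
    failures = []
    t_depth, n_depth = v.t_ref + v.t_alt, v.n_ref + v.n_alt
    matched = cfg.mode in ("wes_matched", "targeted_matched")
    if matched:
        if t_depth < cfg.min_coverage or n_depth < cfg.min_coverage:
            failures.append("coverage")
        t_af = v.t_alt / t_depth if t_depth else 0.0
        n_af = v.n_alt / n_depth if n_depth else 0.0
        if t_af < cfg.caller_min_vaf:
            failures.append("caller_min_vaf")
        passes_af = (t_af >= cfg.min_tumour_af if cfg.tumour_af_inclusive
                     else t_af > cfg.min_tumour_af)
        if not passes_af:
            failures.append("tumour_af")
        if n_af >= cfg.max_normal_af:
            failures.append("normal_af")
        if t_af - n_af < cfg.min_af_diff - 1e-12:
            failures.append("af_diff")
        if v.t_ref < cfg.min_ref_reads:
            failures.append("ref_reads")
        if v.t_alt < cfg.min_alt_reads:
            failures.append("alt_reads")
        if t_depth and n_depth and (
                hypergeom_tail_p(v.t_ref, v.t_alt, v.n_ref, v.n_alt)
                > cfg.somatic_p_threshold):
            failures.append("somatic_p")
    else:
        if t_depth < cfg.min_coverage:
            failures.append("coverage")
        t_af = v.t_alt / t_depth if t_depth else 0.0
        passes_af = (t_af >= cfg.min_tumour_af if cfg.tumour_af_inclusive
                     else t_af > cfg.min_tumour_af)
        if not passes_af:
            failures.append("tumour_af")
    if cfg.exclude_fp_genes and v.fp_gene_flag:
        failures.append("fp_gene")
    if v.pop_maf is not None:
        if cfg.literal_maf_rule and v.pop_maf < cfg.pop_maf_threshold:
            failures.append("pop_maf")
        if not cfg.literal_maf_rule and v.pop_maf >= cfg.pop_maf_threshold:
            failures.append("pop_maf")
    return failures


@pytest.mark.parametrize("mode", ["wes_matched", "targeted_matched",
                                  "targeted_unmatched"])
def test_toy_table_matches_rule_audit(mode):
    cfg = FilterConfig.for_mode(mode)
    variants = toy_variants()
    with pytest.warns(UserWarning) if mode == "targeted_unmatched" else _nullcontext():
        result = filter_variants(variants, cfg)
    expected_kept = [v for v in variants if not oracle_failing_rules(v, cfg)]
    assert result.kept == expected_kept
    assert len(result.kept) + len(result.rejected) == len(variants)
    for v, reason in result.rejected:
        assert reason in oracle_failing_rules(v, cfg)


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *args):
        return False


def test_wes_keeps_only_the_clean_rows():
    result = filter_matched(toy_variants(), FilterConfig.for_mode("wes_matched"))
    assert [TOY_ROWS[toy_variants().index(v)][6] for v in result.kept] == [
        "clean pass", "clean pass, no annotation"]


def test_tumour_af_boundary_is_inclusive_at_22pct():
    # AF exactly 22/100 passes; 21/100 is rejected with the AF reason.
    cfg = FilterConfig.for_mode("wes_matched")
    ok = make_variant(78, 22, 100, 0)
    result = filter_matched([ok], cfg)
    assert result.kept == [ok]
    rejected = filter_matched([make_variant(79, 21, 100, 0)], cfg)
    assert rejected.rejected[0][1] == "tumour_af"


def test_targeted_tumour_af_boundary_is_strict():
    cfg = FilterConfig.for_mode("targeted_matched")
    at_15 = make_variant(85, 15, 100, 0)
    result = filter_matched([at_15], cfg)
    assert result.rejected and result.rejected[0][1] == "tumour_af"


def test_unmatched_coverage_boundary():
    cfg = FilterConfig.for_mode("targeted_unmatched")
    with pytest.warns(UserWarning):
        kept = filter_unmatched([make_variant(105, 45, 0, 0)], cfg).kept
    assert len(kept) == 1
    with pytest.warns(UserWarning):
        res = filter_unmatched([make_variant(50, 49, 0, 0)], cfg)
    assert res.rejected[0][1] == "coverage"


def test_literal_maf_rule_flips_snp_exclusion():
    rare = make_variant(50, 30, 98, 2, pop_maf=0.01)
    common = make_variant(50, 30, 98, 2, pop_maf=0.30)
    default_cfg = FilterConfig.for_mode("wes_matched")
    literal_cfg = FilterConfig.for_mode("wes_matched", literal_maf_rule=True)
    assert filter_matched([rare, common], default_cfg).kept == [rare]
    assert filter_matched([rare, common], literal_cfg).kept == [common]


def test_mode_mismatch_raises():
    with pytest.raises(ConfigurationError):
        filter_matched([], FilterConfig.for_mode("targeted_unmatched"))
    with pytest.raises(ConfigurationError):
        filter_unmatched([], FilterConfig.for_mode("wes_matched"))


# --- properties -------------------------------------------------------------

@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    d_taf=st.floats(0.0, 0.3),
    d_naf=st.floats(-0.10, 0.3),
    d_diff=st.floats(0.0, 0.3),
    d_ref=st.integers(0, 30),
)
def test_tightening_thresholds_never_grows_kept_set(d_taf, d_naf, d_diff, d_ref):
    base = FilterConfig.for_mode("wes_matched")
    tighter = FilterConfig.for_mode(
        "wes_matched",
        min_tumour_af=min(1.0, base.min_tumour_af + d_taf),
        max_normal_af=max(0.0, base.max_normal_af - d_naf)
        if d_naf > 0 else base.max_normal_af,
        min_af_diff=min(1.0, base.min_af_diff + d_diff),
        min_ref_reads=base.min_ref_reads + d_ref,
    )
    variants = toy_variants()
    kept_base = set(id(v) for v in filter_matched(variants, base).kept)
    kept_tight = set(id(v) for v in filter_matched(variants, tighter).kept)
    assert kept_tight <= kept_base


def test_kept_and_rejected_partition_the_input():
    variants = toy_variants()
    result = filter_matched(variants, FilterConfig.for_mode("wes_matched"))
    rejected_vs = [v for v, _ in result.rejected]
    assert sorted(map(id, result.kept + rejected_vs)) == sorted(map(id, variants))


# --- behaviour on synthetic cohorts -----------------------------------------

def test_sensitivity_and_germline_rejection_on_synthetic_cohort(small_cohort):
    """True clonal somatic variants pass; germline hets never survive."""
    from conftest import records_from_frame

    cfg = FilterConfig.for_mode("wes_matched")
    for patient in small_cohort.patients:
        frame = small_cohort.variants[patient]
        records = records_from_frame(frame, patient)
        result = filter_matched(records, cfg)
        kept_pos = {(v.chrom, v.pos) for v in result.kept}

        truth = small_cohort.truth.somatic_variants[patient]
        strong = [t for t in truth if t.true_vaf >= 0.3]
        recovered = sum((t.chrom, t.pos) in kept_pos for t in strong)
        assert recovered / max(1, len(strong)) > 0.95

        germline = frame[frame["func_class"] == "silent"]
        germline_pos = {(c, p) for c, p in zip(germline["chrom"], germline["pos"])}
        assert not (kept_pos & germline_pos)
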