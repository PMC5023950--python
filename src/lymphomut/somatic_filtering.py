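"""Tumour-normal somatic variant selection.

Candidate sites arrive as read-count records (one tumour and, in matched
modes, one normal sample per site).  Selection combines a one-sided Fisher's
exact test for tumour alt-allele enrichment with explicit allele-frequency,
read-support and annotation post-filters.  Three modes are supported:

``wes_matched``
    Whole-exome discovery filtering: tumour AF >= 22%, normal AF < 15%,
    AF difference >= 22%, >= 18 tumour reference reads, > 5 tumour variant
    reads, somatic Fisher p <= 0.1, plus false-positive-gene and
    population-SNP exclusion.
``targeted_matched``
    Deep-amplicon validation with a matched normal: tumour AF > 15%,
    normal AF < 10%, AF difference >= 15%, same read-support rules.
``targeted_unmatched``
    Tumour-only panels: coverage >= 100 and tumour AF >= 15%.

Allele frequencies are compared as exact read-count fractions; thresholds
are encoded with the printed boundary semantics (">= 22%" inclusive,
"< 15%" strict, "more than 5 reads" strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Optional, Sequence

from scipy.stats import fisher_exact

from .errors import ConfigurationError, UndefinedValueError

__all__ = [
    "VariantRecord",
    "FilterConfig",
    "FilterResult",
    "allele_frequency",
    "fisher_somatic_p",
    "filter_matched",
    "filter_unmatched",
    "filter_variants",
]

MATCHED_MODES = ("wes_matched", "targeted_matched")
ALL_MODES = MATCHED_MODES + ("targeted_unmatched",)


@dataclass(frozen=True)
class VariantRecord:
    """One candidate somatic site with tumour/normal read counts."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    func_class: str = "other"
    t_ref: int = 0
    t_alt: int = 0
    n_ref: int = 0
    n_alt: int = 0
    pop_maf: Optional[float] = None
    fp_gene_flag: bool = False
    patient: str = ""

    def __post_init__(self) -> None:
        for name in ("t_ref", "t_alt", "n_ref", "n_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pop_maf is not None and not (0.0 <= self.pop_maf <= 1.0):
            raise ValueError("pop_maf must lie in [0, 1]")

    @property
    def tumour_depth(self) -> int:
        return self.t_ref + self.t_alt

    @property
    def normal_depth(self) -> int:
        return self.n_ref + self.n_alt

    @property
    def tumour_af(self) -> Fraction:
        return allele_frequency(self.t_ref, self.t_alt)

    @property
    def normal_af(self) -> Fraction:
        return allele_frequency(self.n_ref, self.n_alt)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for one filtering mode.

    ``tumour_af_inclusive`` records whether the tumour-AF threshold is met at
    equality (WES ">= 22%") or must be exceeded (targeted "> 15%").
    ``literal_maf_rule`` flips the population-SNP exclusion to the literal
    "MAF < 2%" reading instead of the conventional ">= 2%" common-SNP removal.
    ``somatic_p_mode`` in unmatched filtering: "ignore" (default, no normal to
    test against) or "pseudo_normal" (test against an error-rate pseudo-normal
    at ``pseudo_normal_error`` and require p <= ``somatic_p_threshold``).
    """

    mode: str = "wes_matched"
    min_tumour_af: float = 0.22
    tumour_af_inclusive: bool = True
    max_normal_af: float = 0.15
    min_af_diff: float = 0.22
    min_ref_reads: int = 18
    min_alt_reads: int = 6
    min_coverage: int = 10
    somatic_p_threshold: float = 0.1
    exclude_fp_genes: bool = True
    pop_maf_threshold: float = 0.02
    literal_maf_rule: bool = False
    caller_min_vaf: float = 0.08
    tumour_purity: float = 0.9
    somatic_p_mode: str = "ignore"
    pseudo_normal_error: float = 0.01

    def __post_init__(self) -> None:
        if self.mode not in ALL_MODES:
            raise ConfigurationError(f"mode: unknown filtering mode {self.mode!r}")
        for name in ("min_tumour_af", "max_normal_af", "min_af_diff",
                     "somatic_p_threshold", "pop_maf_threshold",
                     "caller_min_vaf", "pseudo_normal_error"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}: must lie in [0, 1], got {v}")
        if not (0.0 < self.tumour_purity <= 1.0):
            raise ConfigurationError("tumour_purity: must lie in (0, 1]")
        for name in ("min_ref_reads", "min_alt_reads", "min_coverage"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: must be >= 0")
        if self.somatic_p_mode not in ("ignore", "pseudo_normal"):
            raise ConfigurationError("somatic_p_mode: must be 'ignore' or 'pseudo_normal'")

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "FilterConfig":
        """Default thresholds for each published filtering mode."""
        if mode == "wes_matched":
            base = cls(mode=mode)
        elif mode == "targeted_matched":
            base = cls(mode=mode, min_tumour_af=0.15, tumour_af_inclusive=False,
                       max_normal_af=0.10, min_af_diff=0.15)
        elif mode == "targeted_unmatched":
            base = cls(mode=mode, min_tumour_af=0.15, tumour_af_inclusive=True,
                       min_coverage=100)
        else:
            raise ConfigurationError(f"mode: unknown filtering mode {mode!r}")
        return replace(base, **overrides) if overrides else base


@dataclass
class FilterResult:
    kept: list = field(default_factory=list)
    rejected: list = field(default_factory=list)  # (VariantRecord, reason code)

    @property
    def reject_reasons(self) -> dict:
        tally: dict = {}
        for _, reason in self.rejected:
            tally[reason] = tally.get(reason, 0) + 1
        return tally


def allele_frequency(ref_reads: int, alt_reads: int) -> Fraction:
    """Variant allele frequency alt/(ref+alt) as an exact fraction.

    Raises :class:`UndefinedValueError` at zero depth rather than returning
    a sentinel, so boundary comparisons never see a fabricated value.
    """
    if ref_reads < 0 or alt_reads < 0:
        raise UndefinedValueError("read counts must be non-negative")
    depth = ref_reads + alt_reads
    if depth == 0:
        raise UndefinedValueError("allele frequency undefined at zero depth")
    return Fraction(alt_reads, depth)


def fisher_somatic_p(t_ref: int, t_alt: int, n_ref: int, n_alt: int) -> float:
    """One-sided Fisher's exact p for tumour alt-fraction exceeding normal.

    The 2x2 table is [[t_alt, t_ref], [n_alt, n_ref]]; the alternative is
    enrichment of alt reads in the tumour row.
    """
    if min(t_ref, t_alt, n_ref, n_alt) < 0:
        raise UndefinedValueError("read counts must be non-negative")
    if t_ref + t_alt == 0 or n_ref + n_alt == 0:
        raise UndefinedValueError("somatic p undefined at zero depth")
    _, p = fisher_exact([[t_alt, t_ref], [n_alt, n_ref]], alternative="greater")
    return float(p)


def _failing_rule_matched(v: VariantRecord, cfg: FilterConfig) -> Optional[str]:
    # Rule order is fixed so rejection reasons are reproducible:
    # coverage -> allele frequencies -> read support -> somatic p -> annotations.
    if v.tumour_depth < cfg.min_coverage or v.normal_depth < cfg.min_coverage:
        return "coverage"
    if v.tumour_depth == 0:
        return "coverage"
    t_af = v.tumour_af
    n_af = v.normal_af if v.normal_depth > 0 else Fraction(0)
    if t_af < Fraction(cfg.caller_min_vaf).limit_denominator(10**6):
        return "caller_min_vaf"
    thr = Fraction(cfg.min_tumour_af).limit_denominator(10**6)
    if (t_af < thr) if cfg.tumour_af_inclusive else (t_af <= thr):
        return "tumour_af"
    if n_af >= Fraction(cfg.max_normal_af).limit_denominator(10**6):
        return "normal_af"
    if t_af - n_af < Fraction(cfg.min_af_diff).limit_denominator(10**6):
        return "af_diff"
    if v.t_ref < cfg.min_ref_reads:
        return "ref_reads"
    if v.t_alt < cfg.min_alt_reads:
        return "alt_reads"
    if fisher_somatic_p(v.t_ref, v.t_alt, v.n_ref, v.n_alt) > cfg.somatic_p_threshold:
        return "somatic_p"
    if cfg.exclude_fp_genes and v.fp_gene_flag:
        return "fp_gene"
    if v.pop_maf is not None:
        if cfg.literal_maf_rule:
            if v.pop_maf < cfg.pop_maf_threshold:
                return "pop_maf"
        elif v.pop_maf >= cfg.pop_maf_threshold:
            return "pop_maf"
    return None


def _failing_rule_unmatched(v: VariantRecord, cfg: FilterConfig) -> Optional[str]:
    if v.tumour_depth < cfg.min_coverage:
        return "coverage"
    thr = Fraction(cfg.min_tumour_af).limit_denominator(10**6)
    t_af = v.tumour_af
    if (t_af < thr) if cfg.tumour_af_inclusive else (t_af <= thr):
        return "tumour_af"
    if cfg.somatic_p_mode == "pseudo_normal":
        pseudo_depth = v.tumour_depth
        pseudo_alt = round(cfg.pseudo_normal_error * pseudo_depth)
        p = fisher_somatic_p(v.t_ref, v.t_alt, pseudo_depth - pseudo_alt, pseudo_alt)
        if p > cfg.somatic_p_threshold:
            return "somatic_p"
    if cfg.exclude_fp_genes and v.fp_gene_flag:
        return "fp_gene"
    if v.pop_maf is not None:
        if cfg.literal_maf_rule:
            if v.pop_maf < cfg.pop_maf_threshold:
                return "pop_maf"
        elif v.pop_maf >= cfg.pop_maf_threshold:
            return "pop_maf"
    return None


def filter_matched(variants: Iterable[VariantRecord], config: FilterConfig) -> FilterResult:
    """Apply the matched tumour-normal rules; keep iff every rule passes.

    Rejected records carry the first failing rule's code in the documented
    evaluation order.
    """
    if config.mode not in MATCHED_MODES:
        raise ConfigurationError(f"mode: {config.mode!r} is not a matched mode")
    result = FilterResult()
    for v in variants:
        reason = _failing_rule_matched(v, config)
        if reason is None:
            result.kept.append(v)
        else:
            result.rejected.append((v, reason))
    return result


def filter_unmatched(variants: Iterable[VariantRecord], config: FilterConfig) -> FilterResult:
    """Tumour-only panel filtering: coverage and tumour AF rules.

    The published unmatched rule set names a somatic Fisher p condition, but
    with no matched normal there is no second sample to test against; by
    default that rule is skipped (with a warning) and a `pseudo_normal` mode
    tests tumour counts against a configurable error-rate reference.
    """
    if config.mode != "targeted_unmatched":
        raise ConfigurationError(f"mode: {config.mode!r} is not targeted_unmatched")
    if config.somatic_p_mode == "ignore":
        warnings.warn(
            "unmatched mode: somatic-p rule skipped (no matched normal); "
            "set somatic_p_mode='pseudo_normal' to apply it against an "
            "error-rate pseudo-normal",
            stacklevel=2,
        )
    result = FilterResult()
    for v in variants:
        reason = _failing_rule_unmatched(v, config)
        if reason is None:
            result.kept.append(v)
        else:
            result.rejected.append((v, reason))
    return result


def filter_variants(variants: Sequence[VariantRecord], config: FilterConfig) -> FilterResult:
    """Dispatch to the matched or unmatched rule set by config.mode."""
    if config.mode in MATCHED_MODES:
        return filter_matched(variants, config)
    return filter_unmatched(variants, config)
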