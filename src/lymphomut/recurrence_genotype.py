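"""Mutational-spectrum summaries, gene recurrence and hit accounting.

Substitutions are collapsed to the six pyrimidine-context classes
(C>A, C>G, C>T, T>A, T>C, T>G) by complementing purine-reference changes,
the standard convention for exome spectra.  Per-gene recurrence is row
arithmetic on the binary event matrix.  Hit classification captures the
tumour-suppressor accounting used for genes such as SETD2: a patient is a
double hit when it carries two mutations in the gene, or one mutation plus
deletion of the locus; union arithmetic (inclusion-exclusion) gives the
total altered count.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

from .errors import DomainError

__all__ = [
    "SPECTRUM_CLASSES",
    "MutationSpectrum",
    "HitClassification",
    "mutation_spectrum",
    "per_gene_recurrence",
    "classify_hits",
    "altered_union",
    "truncating_fraction",
    "pct_half_up",
]

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
TRUNCATING_CLASSES = ("nonsense", "frameshift", "splice")


def pct_half_up(numerator: float, denominator: float) -> int:
    """Percentage rounded half-up to the nearest integer (93, 69, ...)."""
    if denominator == 0:
        raise DomainError("percentage undefined for zero denominator")
    value = Decimal(numerator) / Decimal(denominator) * 100
    return int(value.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class MutationSpectrum:
    """Counts and proportions of the six substitution classes plus indels."""

    counts: Dict[str, int]
    indels: int = 0
    skipped: int = 0

    @property
    def n_substitutions(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> Dict[str, float]:
        total = self.n_substitutions
        if total == 0:
            return {c: 0.0 for c in SPECTRUM_CLASSES}
        return {c: self.counts.get(c, 0) / total for c in SPECTRUM_CLASSES}


def _substitution_class(ref: str, alt: str) -> str:
    if ref in "GA":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def mutation_spectrum(variants: pd.DataFrame) -> MutationSpectrum:
    """Tally the substitution spectrum of a variant table.

    Single-base A/C/G/T ref-alt pairs are classified (purine-reference
    changes complemented into the pyrimidine classes); longer alleles count
    as indels; anything else is skipped with a warning.
    """
    counts: Counter = Counter()
    indels = 0
    skipped = 0
    for ref, alt in zip(variants["ref"], variants["alt"]):
        ref, alt = str(ref).upper(), str(alt).upper()
        if len(ref) == 1 and len(alt) == 1 and ref in "ACGT" and alt in "ACGT":
            if ref == alt:
                skipped += 1
                continue
            counts[_substitution_class(ref, alt)] += 1
        elif set(ref) <= set("ACGT-") and set(alt) <= set("ACGT-") and ref != alt:
            indels += 1
        else:
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped} variant(s) with unusable alleles skipped",
                      stacklevel=2)
    return MutationSpectrum(dict(counts), indels=indels, skipped=skipped)


def per_gene_recurrence(mb) -> pd.DataFrame:
    """Per-gene mutated-patient counts and cohort fractions from M_B."""
    n_patients = len(mb.patients)
    n_mutated = mb.values.sum(axis=1)
    return pd.DataFrame({
        "gene": mb.genes,
        "n_mutated": n_mutated.astype(int),
        "fraction": n_mutated / n_patients if n_patients else 0.0,
    }).sort_values(["n_mutated", "gene"], ascending=[False, True],
                   ignore_index=True)


@dataclass(frozen=True)
class HitClassification:
    """Per-patient alteration status of one gene."""

    patient: str
    gene: str
    n_mutations: int
    locus_deleted: bool
    hit_class: str

    @staticmethod
    def classify(n_mutations: int, locus_deleted: bool) -> str:
        if n_mutations < 0:
            raise DomainError("n_mutations must be >= 0")
        if n_mutations >= 2:
            return "double_mutation"
        if n_mutations == 1:
            return "mutation_plus_deletion" if locus_deleted else "single_mutation"
        return "deletion_only" if locus_deleted else "wild_type"


def classify_hits(records: Iterable[Tuple[str, int, bool]],
                  gene: str = "") -> Tuple[List[HitClassification], Dict[str, int]]:
    """Classify each patient's (mutation count, deletion flag) pair.

    Returns the per-patient classifications and cohort tallies, including
    the derived ``double_hit`` count (double mutations plus
    mutation-with-deletion cases).
    """
    out = []
    tallies: Counter = Counter()
    for patient, n_mutations, locus_deleted in records:
        cls = HitClassification.classify(n_mutations, bool(locus_deleted))
        out.append(HitClassification(patient, gene, n_mutations,
                                     bool(locus_deleted), cls))
        tallies[cls] += 1
    result = dict(tallies)
    result["double_hit"] = tallies["double_mutation"] + tallies["mutation_plus_deletion"]
    return out, result


def altered_union(n_mutated: int, n_deleted: int, n_both: int) -> int:
    """Patients altered by mutation or deletion: inclusion-exclusion."""
    if min(n_mutated, n_deleted, n_both) < 0:
        raise DomainError("counts must be >= 0")
    if n_both > min(n_mutated, n_deleted):
        raise DomainError("overlap cannot exceed either margin")
    return n_mutated + n_deleted - n_both


def truncating_fraction(type_counts: Mapping[str, int]) -> Tuple[int, int, int]:
    """Loss-of-function fraction of a mutation-type tally.

    Nonsense, frameshift and splice-site changes count as truncating (splice
    grouped with truncating for the protein-impairing fraction).  Returns
    (n_truncating, total, integer percentage rounded half-up).
    """
    if any(c < 0 for c in type_counts.values()):
        raise DomainError("counts must be >= 0")
    total = sum(type_counts.values())
    if total == 0:
        raise DomainError("no mutations to summarize")
    n_trunc = sum(type_counts.get(c, 0) for c in TRUNCATING_CLASSES)
    return n_trunc, total, pct_half_up(n_trunc, total)
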