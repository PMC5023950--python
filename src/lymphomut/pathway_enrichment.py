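"""Permutation-null gene-set enrichment on a binary alteration matrix.

The cohort's alterations are summarized as a binary event matrix M_B
(genes x patients; 1 iff the patient carries at least one qualifying event
in the gene).  For each gene signature, the per-patient signature frequency
is the number of member genes with an event; the observed per-patient
frequencies are compared against frequencies computed from row-permuted
copies of M_B (gene labels reassigned uniformly at random, which preserves
both the multiset of row sums and every patient's column sum).  A one-sided
t-test asks whether the observed mean frequency exceeds the permutation
null; p-values across signatures are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, StructuralError

__all__ = [
    "EventMatrix",
    "SignatureSet",
    "EnrichmentResult",
    "build_event_matrix",
    "signature_frequency_matrix",
    "permute_event_matrix",
    "enrichment_test",
    "bh_adjust",
    "run_enrichment",
    "read_gmt",
    "write_gmt",
]


@dataclass
class EventMatrix:
    """Binary gene x patient alteration matrix M_B."""

    genes: List[str]
    patients: List[str]
    values: np.ndarray  # shape (n_genes, n_patients), entries in {0, 1}
    cnv_skipped: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.genes), len(self.patients)):
            raise StructuralError("event matrix shape does not match labels")
        if len(set(self.genes)) != len(self.genes):
            raise StructuralError("gene labels must be unique")
        if len(set(self.patients)) != len(self.patients):
            raise StructuralError("patient labels must be unique")
        if not np.isin(self.values, (0, 1)).all():
            raise StructuralError("event matrix entries must be 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.patients)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())


@dataclass
class SignatureSet:
    """Named gene sets (e.g. parsed from a GMT collection)."""

    sets: Dict[str, List[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise StructuralError(f"signature {name!r} has no members")

    def matched(self, gene_universe: Sequence[str]) -> Dict[str, List[str]]:
        """Member lists restricted to the event-matrix gene universe."""
        universe = set(gene_universe)
        return {name: [g for g in members if g in universe]
                for name, members in self.sets.items()}


@dataclass
class EnrichmentResult:
    signature: str
    size: int  # matched member genes
    observed: np.ndarray  # per-patient signature frequencies
    observed_mean: float
    null_mean: float
    null_sd: float
    p_value: float
    adjusted_p: float = np.nan
    proportion_with_event: float = np.nan


def build_event_matrix(variants: pd.DataFrame,
                       patients: Sequence[str],
                       genes: Sequence[str],
                       segments_by_patient: Optional[dict] = None,
                       gene_loci: Optional[dict] = None,
                       include_cnv: bool = False) -> EventMatrix:
    """Assemble M_B from kept variants and (optionally) CNV segment calls.

    ``variants`` needs columns ``patient, gene, func_class``; silent changes
    do not count as events.  With ``include_cnv``, a gene also scores an
    event when its locus (from ``gene_loci``: gene -> (chrom, start, end))
    overlaps a gain or loss segment of that patient; genes without a known
    locus are recorded in ``cnv_skipped`` rather than failing the build.
    """
    from .cnv_segmentation import locus_overlap

    gene_list = list(genes)
    patient_list = list(patients)
    gene_index = {g: i for i, g in enumerate(gene_list)}
    patient_index = {p: j for j, p in enumerate(patient_list)}
    values = np.zeros((len(gene_list), len(patient_list)), dtype=np.int8)

    if len(variants):
        non_silent = variants[variants["func_class"] != "silent"]
        for _, row in non_silent.iterrows():
            gi = gene_index.get(row["gene"])
            pj = patient_index.get(row["patient"])
            if gi is not None and pj is not None:
                values[gi, pj] = 1

    skipped: List[str] = []
    if include_cnv:
        if segments_by_patient is None or gene_loci is None:
            raise StructuralError("include_cnv requires segments and gene loci")
        for gene in gene_list:
            locus = gene_loci.get(gene)
            if locus is None:
                skipped.append(gene)
                continue
            for patient, segments in segments_by_patient.items():
                pj = patient_index.get(patient)
                if pj is None:
                    continue
                try:
                    status = locus_overlap(segments, locus)
                except DomainError:
                    continue
                if status["call"] in ("gain", "loss"):
                    values[gene_index[gene], pj] = 1
    return EventMatrix(gene_list, patient_list, values, cnv_skipped=skipped)


def signature_frequency_matrix(mb: EventMatrix, sigs: SignatureSet,
                               normalized: bool = False) -> pd.DataFrame:
    """Signature x patient event-frequency matrix (M_sig x patient).

    Count mode (default): entry (s, p) is the number of member genes of s
    with an event in patient p.  Normalized mode divides by the matched
    signature size.  Signatures with no matched genes are dropped with a
    warning.
    """
    matched = sigs.matched(mb.genes)
    gene_index = {g: i for i, g in enumerate(mb.genes)}
    rows = {}
    for name, members in matched.items():
        if not members:
            warnings.warn(f"signature {name!r} has no genes in the matrix; excluded",
                          stacklevel=2)
            continue
        idx = [gene_index[g] for g in members]
        freq = mb.values[idx].sum(axis=0).astype(float)
        if normalized:
            freq = freq / len(members)
        rows[name] = freq
    if not rows:
        return pd.DataFrame(columns=mb.patients)
    return pd.DataFrame.from_dict(rows, orient="index", columns=mb.patients)


def permute_event_matrix(mb: EventMatrix, n_perm: int = 1000,
                         rng: Optional[np.random.Generator] = None,
                         ) -> Iterator[np.ndarray]:
    """Yield ``n_perm`` row-permuted copies of M_B's value matrix.

    Row permutation reassigns rows to gene labels while leaving each row
    (and hence every column sum and the row-sum multiset) intact.
    """
    if n_perm < 1:
        raise DomainError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    n_genes = len(mb.genes)
    for _ in range(n_perm):
        yield mb.values[rng.permutation(n_genes)]


def enrichment_test(observed: Sequence[float], null_values: np.ndarray,
                    method: str = "welch") -> tuple:
    """One-sided test of observed signature frequencies against the null.

    ``welch`` (default): two-sample Welch t-test of the observed per-patient
    frequencies against all pooled permuted frequencies, alternative
    "observed mean greater".  ``perm_mean``: permutation p-value of the
    observed mean within the distribution of per-permutation null means.
    Returns (p, null_mean, null_sd).
    """
    obs = np.asarray(observed, dtype=float)
    null = np.asarray(null_values, dtype=float)
    if obs.size < 2:
        raise DomainError("need >= 2 patients")
    if null.ndim != 2 or null.shape[0] < 2:
        raise DomainError("need >= 2 permutations of null frequencies")
    pooled = null.ravel()
    null_mean = float(pooled.mean())
    null_sd = float(pooled.std(ddof=1))
    if method == "welch":
        if obs.std(ddof=1) == 0.0 and null_sd == 0.0:
            p = 1.0 if obs.mean() <= null_mean else 0.0
        else:
            p = float(stats.ttest_ind(obs, pooled, equal_var=False,
                                      alternative="greater").pvalue)
    elif method == "perm_mean":
        perm_means = null.mean(axis=1)
        p = (1 + int(np.sum(perm_means >= obs.mean()))) / (1 + null.shape[0])
    else:
        raise DomainError(f"unknown method {method!r}")
    return float(p), null_mean, null_sd


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_i = min_{k: p_(k) >= p_(i)} m * p_(k) / k, capped at 1; ties and
    original order are preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def run_enrichment(mb: EventMatrix, sigs: SignatureSet, n_perm: int = 1000,
                   rng: Optional[np.random.Generator] = None,
                   seed: Optional[int] = None,
                   method: str = "welch", normalized: bool = False,
                   min_matched: int = 2) -> List[EnrichmentResult]:
    """Full enrichment test over a signature collection.

    Signatures with fewer than ``min_matched`` genes in the matrix are
    skipped (a one-gene "set" degenerates the t-test).  Results are sorted
    by adjusted p, then raw p, then name.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    matched = sigs.matched(mb.genes)
    names = [n for n, members in matched.items() if len(members) >= min_matched]
    dropped = [n for n in matched if n not in names]
    if dropped:
        warnings.warn(
            f"{len(dropped)} signature(s) with < {min_matched} matched genes skipped",
            stacklevel=2,
        )
    if not names:
        return []

    gene_index = {g: i for i, g in enumerate(mb.genes)}
    n_pat = len(mb.patients)
    membership = np.zeros((len(names), len(mb.genes)), dtype=np.int32)
    sizes = {}
    for si, name in enumerate(names):
        idx = [gene_index[g] for g in matched[name]]
        membership[si, idx] = 1
        sizes[name] = len(idx)

    observed = membership @ mb.values.astype(np.int32)  # n_sig x n_pat
    null = np.empty((n_perm, len(names), n_pat), dtype=np.float64)
    for r, perm_values in enumerate(permute_event_matrix(mb, n_perm, rng)):
        null[r] = membership @ perm_values.astype(np.int32)
    if normalized:
        scale = np.array([sizes[n] for n in names], dtype=float)[:, None]
        observed = observed / scale
        null = null / scale[None, :, :]

    results = []
    for si, name in enumerate(names):
        obs = np.asarray(observed[si], dtype=float)
        p, null_mean, null_sd = enrichment_test(obs, null[:, si, :], method=method)
        member_idx = membership[si].astype(bool)
        prop = float((mb.values[member_idx].sum(axis=0) > 0).mean())
        results.append(EnrichmentResult(
            signature=name, size=sizes[name], observed=obs,
            observed_mean=float(obs.mean()), null_mean=null_mean,
            null_sd=null_sd, p_value=p, proportion_with_event=prop,
        ))
    adjusted = bh_adjust([r.p_value for r in results])
    for r, adj in zip(results, adjusted):
        r.adjusted_p = float(adj)
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.signature))
    return results


def read_gmt(path) -> SignatureSet:
    """Parse a GMT file: name <tab> description <tab> member genes..."""
    sets: Dict[str, List[str]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise StructuralError(f"malformed GMT line: {line[:80]!r}")
            name = fields[0]
            members = [g for g in fields[2:] if g]
            sets[name] = members
    return SignatureSet(sets, provenance=str(path))


def write_gmt(sigs: SignatureSet, path) -> None:
    with open(path, "w") as handle:
        for name, members in sigs.sets.items():
            handle.write("\t".join([name, sigs.provenance or "na", *members]) + "\n")


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "signature": r.signature, "size": r.size,
                "observed_mean": r.observed_mean, "null_mean": r.null_mean,
                "null_sd": r.null_sd, "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "proportion_with_event": r.proportion_with_event,
            }
            for r in results
        ]
    )
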