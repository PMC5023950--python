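"""Readers for the pipeline's tabular and VCF inputs."""

from __future__ import annotations

import math
from typing import List, Optional

import pandas as pd

from .errors import StructuralError
from .somatic_filtering import VariantRecord

__all__ = [
    "read_variant_tsv",
    "read_variant_vcf",
    "read_coverage_bins",
    "read_het_sites",
    "variants_to_frame",
]

_TSV_REQUIRED = {"chrom", "pos", "ref", "alt", "t_ref", "t_alt"}


def read_variant_tsv(path, patient: str = "") -> List[VariantRecord]:
    """Read the tab-separated variant dialect into records.

    Columns: chrom, pos (1-based), ref, alt, gene, func_class, t_ref,
    t_alt, n_ref, n_alt, pop_maf, fp_gene_flag.  Normal counts and
    annotations may be absent (tumour-only panels).
    """
    table = pd.read_csv(path, sep="\t")
    missing = _TSV_REQUIRED - set(table.columns)
    if missing:
        raise StructuralError(f"variant table lacks columns: {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        pop_maf = row.get("pop_maf")
        if pop_maf is not None and isinstance(pop_maf, float) and math.isnan(pop_maf):
            pop_maf = None
        records.append(VariantRecord(
            chrom=str(row["chrom"]), pos=int(row["pos"]),
            ref=str(row["ref"]), alt=str(row["alt"]),
            gene=str(row.get("gene", "") or ""),
            func_class=str(row.get("func_class", "other") or "other"),
            t_ref=int(row["t_ref"]), t_alt=int(row["t_alt"]),
            n_ref=int(row.get("n_ref", 0) or 0), n_alt=int(row.get("n_alt", 0) or 0),
            pop_maf=None if pop_maf is None else float(pop_maf),
            fp_gene_flag=bool(row.get("fp_gene_flag", False)),
            patient=patient,
        ))
    return records


def read_variant_vcf(path, tumour: str = "TUMOR", normal: Optional[str] = "NORMAL",
                     patient: str = "") -> List[VariantRecord]:
    """Read a VCF v4.2 with per-sample AD (ref, alt) fields.

    ``tumour``/``normal`` name the sample columns; pass ``normal=None`` for
    tumour-only files.  Gene, functional class, population frequency and
    the false-positive-gene flag are taken from the INFO fields GENE,
    FCLASS, PMAF and FPGENE when present.
    """
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if tumour not in samples:
            raise StructuralError(f"tumour sample {tumour!r} not in VCF ({samples})")
        if normal is not None and normal not in samples:
            raise StructuralError(f"normal sample {normal!r} not in VCF ({samples})")
        for rec in vcf:
            if rec.alts is None:
                continue
            t_ad = rec.samples[tumour].get("AD")
            if t_ad is None or len(t_ad) < 2:
                continue
            n_ref = n_alt = 0
            if normal is not None:
                n_ad = rec.samples[normal].get("AD")
                if n_ad is not None and len(n_ad) >= 2:
                    n_ref, n_alt = int(n_ad[0]), int(n_ad[1])
            pmaf = rec.info.get("PMAF")
            records.append(VariantRecord(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                gene=str(rec.info.get("GENE", "") or ""),
                func_class=str(rec.info.get("FCLASS", "other") or "other"),
                t_ref=int(t_ad[0]), t_alt=int(t_ad[1]),
                n_ref=n_ref, n_alt=n_alt,
                pop_maf=None if pmaf is None else float(pmaf),
                fp_gene_flag=bool(rec.info.get("FPGENE", False)),
                patient=patient,
            ))
    return records


def read_coverage_bins(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = {"chrom", "bin_start", "t_count", "n_count"} - set(table.columns)
    if missing:
        raise StructuralError(f"bin table lacks columns: {sorted(missing)}")
    return table


def read_het_sites(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = {"chrom", "pos", "n_ref", "n_alt", "t_ref", "t_alt"} - set(table.columns)
    if missing:
        raise StructuralError(f"het-site table lacks columns: {sorted(missing)}")
    return table


def variants_to_frame(records) -> pd.DataFrame:
    """Records back to the TSV dialect (plus the patient column)."""
    return pd.DataFrame([
        {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene": v.gene, "func_class": v.func_class,
            "t_ref": v.t_ref, "t_alt": v.t_alt,
            "n_ref": v.n_ref, "n_alt": v.n_alt,
            "pop_maf": v.pop_maf, "fp_gene_flag": v.fp_gene_flag,
            "patient": v.patient,
        }
        for v in records
    ])
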