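"""Seeded synthetic tumour-normal cohorts with known ground truth.

The generator emulates the read-count level of a paired tumour-normal
exome study of an aggressive intestinal T-cell lymphoma: binomially
sampled allele counts at somatic, germline-heterozygous and artifact
sites given tumour purity and sequencing depth; Poisson coverage bins
over piecewise-constant copy-number profiles (single-copy loss, neutral,
single-copy gain, copy-neutral LOH); a gene x patient alteration layer
with optionally planted pathway enrichment; and genotype-linked IHC/FISH
phenotypes keyed to the alteration status of a designated driver gene
(single/double mutation, locus deletion).

Everything is deterministic given ``CohortConfig.seed``.  Each patient
draws from an independently spawned random stream keyed by patient index,
so growing the cohort leaves earlier patients untouched.

Expected tumour VAF of a variant with ``m`` mutant copies in a region of
tumour copy number ``c`` at purity ``p`` is ``p*m / (p*c + 2*(1-p))``;
germline het BAF in the tumour follows the same accounting with the alt
allele assigned to a random parental haplotype, which in copy-neutral LOH
regions shifts the BAF to 0.5*(1 +/- p).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .recurrence_genotype import HitClassification

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "TrueVariant",
    "Cohort",
    "sample_site_reads",
    "generate_fish_nuclei",
    "generate_cohort",
    "write_cohort",
]

COPY_STATES = {"loss": 1, "neutral": 2, "gain": 3, "cnLOH": 2}
DEPTH_MULTIPLIERS = {"loss": 0.5, "neutral": 1.0, "gain": 1.5, "cnLOH": 1.0}
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "func_class",
                   "t_ref", "t_alt", "n_ref", "n_alt", "pop_maf", "fp_gene_flag"]
DEFAULT_FUNC_CLASS_PROBS = {
    # Mix of loss-of-function and missense changes typical of a tumour
    # suppressor's mutation spectrum (6 nonsense : 9 frameshift : 3 splice :
    # 8 missense), used for driver-gene mutations.
    "nonsense": 6 / 26, "frameshift": 9 / 26, "splice": 3 / 26, "missense": 8 / 26,
}
_BASES = np.array(list("ACGT"))


@dataclass
class TrueVariant:
    patient: str
    chrom: str
    pos: int
    gene: str
    true_vaf: float
    func_class: str
    kind: str = "somatic"  # somatic | germline | artifact


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    somatic_variants: Dict[str, List[TrueVariant]]
    cnv_segments: Dict[str, List[Tuple[str, int, int, str]]]
    enriched_signatures: List[str]
    hit_classes: Dict[str, str]  # patient -> driver-gene hit class
    driver_gene: str
    gene_loci: Dict[str, Tuple[str, int, int]]
    fish_deleted_fraction: Dict[str, float]

    def to_json(self) -> str:
        payload = {
            "somatic_variants": {
                p: [asdict(v) for v in vs] for p, vs in self.somatic_variants.items()
            },
            "cnv_segments": self.cnv_segments,
            "enriched_signatures": self.enriched_signatures,
            "hit_classes": self.hit_classes,
            "driver_gene": self.driver_gene,
            "gene_loci": self.gene_loci,
            "fish_deleted_fraction": self.fish_deleted_fraction,
        }
        return json.dumps(payload, indent=1)


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a 15-patient paired tumour-normal FFPE exome study:
    ~195x / 213x mean tumour / normal depth, tumour purity 0.9 after
    microdissection, a median-scale load of ~57 somatic coding variants
    per patient, and 100 kb coverage bins.
    """

    n_patients: int = 15
    n_genes: int = 200
    genome: List[Tuple[str, int]] = field(default_factory=lambda: [
        ("chr1", 10_000_000), ("chr2", 10_000_000), ("chr3", 10_000_000),
    ])
    mean_depth_tumour: float = 195.0
    mean_depth_normal: float = 213.0
    tumour_purity: float = 0.9
    somatic_rate: float = 57.0
    germline_het_rate: float = 2e-5
    artifact_rate: float = 1e-5
    planted_signatures: List[Tuple[str, List[str], float]] = field(default_factory=list)
    cnv_truth: Dict[str, List[Tuple[str, int, int, str]]] = field(default_factory=dict)
    seed: int = 0
    bin_width: int = 100_000
    driver_gene: Optional[str] = None
    driver_mut_prob: float = 0.85
    driver_second_mut_prob: float = 0.5
    func_class_probs: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FUNC_CLASS_PROBS))
    fp_genes: List[str] = field(default_factory=list)
    normal_error_rate: float = 0.001
    fish_n_nuclei: int = 200
    fish_miss_rate: float = 0.02
    fish_background_fraction: float = 0.04
    fish_deleted_detect_fraction: float = 0.7

    def gene_names(self) -> List[str]:
        names = [f"G{i:04d}" for i in range(self.n_genes)]
        if self.driver_gene:
            names[0] = self.driver_gene
        return names

    def gene_loci(self) -> Dict[str, Tuple[str, int, int]]:
        """Deterministic gene placement: genes evenly spread over the genome,
        each spanning 20 kb."""
        loci = {}
        total = sum(length for _, length in self.genome)
        spacing = total / self.n_genes
        offset = 0.0
        bounds = []
        acc = 0
        for chrom, length in self.genome:
            bounds.append((chrom, acc, acc + length))
            acc += length
        for i, name in enumerate(self.gene_names()):
            gpos = int(i * spacing + spacing / 4)
            for chrom, lo, hi in bounds:
                if lo <= gpos < hi:
                    start = gpos - lo
                    end = min(start + 20_000, hi - lo)
                    loci[name] = (chrom, start, end)
                    break
        return loci

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients: must be >= 1")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes: must be >= 1")
        if not self.genome:
            raise ConfigurationError("genome: must list at least one chromosome")
        chrom_len = dict(self.genome)
        for chrom, length in self.genome:
            if length <= 0:
                raise ConfigurationError(f"genome: chromosome {chrom} has length <= 0")
        if not (0.0 < self.tumour_purity <= 1.0):
            raise ConfigurationError("tumour_purity: must lie in (0, 1]")
        for name in ("mean_depth_tumour", "mean_depth_normal", "somatic_rate",
                     "germline_het_rate", "artifact_rate", "normal_error_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: must be >= 0")
        for name in ("driver_mut_prob", "driver_second_mut_prob",
                     "fish_miss_rate", "fish_background_fraction",
                     "fish_deleted_detect_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}: must lie in [0, 1]")
        genes = set(self.gene_names())
        for sig_name, members, uplift in self.planted_signatures:
            if not set(members) <= genes:
                raise ConfigurationError(
                    f"planted_signatures: {sig_name} members outside gene universe")
            if not (0.0 <= uplift <= 1.0):
                raise ConfigurationError(
                    f"planted_signatures: {sig_name} uplift outside [0, 1]")
        for patient, segments in self.cnv_truth.items():
            by_chrom: Dict[str, List[Tuple[int, int]]] = {}
            for chrom, start, end, state in segments:
                if state not in COPY_STATES:
                    raise ConfigurationError(
                        f"cnv_truth: unknown copy state {state!r} for {patient}")
                if chrom not in chrom_len:
                    raise ConfigurationError(
                        f"cnv_truth: chromosome {chrom!r} not in genome")
                if not (0 <= start < end <= chrom_len[chrom]):
                    raise ConfigurationError(
                        f"cnv_truth: interval outside genome bounds for {patient}")
                by_chrom.setdefault(chrom, []).append((start, end))
            for chrom, ivs in by_chrom.items():
                ivs.sort()
                for (s1, e1), (s2, e2) in zip(ivs[:-1], ivs[1:]):
                    if s2 < e1:
                        raise ConfigurationError(
                            f"cnv_truth: overlapping intervals for {patient} on {chrom}")


@dataclass
class Cohort:
    config: CohortConfig
    variants: Dict[str, pd.DataFrame]       # patient -> variant table
    coverage_bins: Dict[str, pd.DataFrame]  # patient -> bin table
    ihc: pd.DataFrame
    fish: pd.DataFrame
    truth: GroundTruth

    @property
    def patients(self) -> List[str]:
        return list(self.variants)


def sample_site_reads(true_vaf: float, depth: int,
                      rng: np.random.Generator) -> Tuple[int, int]:
    """Binomial read sampling at one site: (ref_reads, alt_reads)."""
    if not (0.0 <= true_vaf <= 1.0):
        raise DomainError("true_vaf must lie in [0, 1]")
    if depth < 0:
        raise DomainError("depth must be >= 0")
    alt = int(rng.binomial(depth, true_vaf))
    return depth - alt, alt


def generate_fish_nuclei(true_deleted_fraction: float, n_nuclei: int,
                         miss_rate: float,
                         rng: np.random.Generator) -> List[Tuple[int, int]]:
    """Per-nucleus (orange, green) FISH signal counts.

    Deleted nuclei carry 1 target (orange) and 2 control (green) signals,
    non-deleted nuclei 2 and 2; each signal is independently missed with
    probability ``miss_rate`` (hybridization failure / truncation).
    """
    for name, v in (("true_deleted_fraction", true_deleted_fraction),
                    ("miss_rate", miss_rate)):
        if not (0.0 <= v <= 1.0):
            raise DomainError(f"{name} must lie in [0, 1]")
    if n_nuclei < 1:
        raise DomainError("n_nuclei must be >= 1")
    deleted = rng.random(n_nuclei) < true_deleted_fraction
    base_orange = np.where(deleted, 1, 2)
    orange = rng.binomial(base_orange, 1.0 - miss_rate)
    green = rng.binomial(2, 1.0 - miss_rate, size=n_nuclei)
    return [(int(o), int(g)) for o, g in zip(orange, green)]


def _patient_rng(seed: int, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(index, stream)))


def _copy_state_at(segments: Sequence[Tuple[str, int, int, str]],
                   chrom: str, pos0: int) -> str:
    for seg_chrom, start, end, state in segments:
        if seg_chrom == chrom and start <= pos0 < end:
            return state
    return "neutral"


def expected_somatic_vaf(purity: float, copy_state: str,
                         mutant_copies: int = 1) -> float:
    """purity * copy-adjusted allele fraction of a clonal somatic variant."""
    c = COPY_STATES[copy_state]
    return purity * mutant_copies / (purity * c + 2.0 * (1.0 - purity))


def germline_tumour_baf(purity: float, copy_state: str, alt_on_a: bool) -> float:
    """Tumour BAF of a germline het, with the alt allele on haplotype A.

    Haplotype A is the one affected by the copy change (lost in "loss",
    duplicated in "gain"/"cnLOH").
    """
    p = purity
    alt_copies_tumour = {
        "neutral": 1,
        "loss": 0 if alt_on_a else 1,
        "gain": 2 if alt_on_a else 1,
        "cnLOH": 2 if alt_on_a else 0,
    }[copy_state]
    c = COPY_STATES[copy_state]
    return (p * alt_copies_tumour + (1 - p)) / (p * c + 2 * (1 - p))


def _random_substitution(rng: np.random.Generator) -> Tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = ref
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return str(ref), str(alt)


def _draw_depth(rng: np.random.Generator, mean_depth: float) -> int:
    return max(1, int(rng.poisson(mean_depth)))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort: variant tables, coverage bins, phenotypes,
    and the planted ground truth.  Deterministic given ``config.seed``."""
    config.validate()
    genes = config.gene_names()
    loci = config.gene_loci()
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    fp_gene_set = set(config.fp_genes)

    base_event_prob = min(1.0, config.somatic_rate / config.n_genes)
    uplift_by_gene: Dict[str, float] = {}
    for _, members, uplift in config.planted_signatures:
        for g in members:
            uplift_by_gene[g] = max(uplift_by_gene.get(g, 0.0), uplift)

    variants: Dict[str, pd.DataFrame] = {}
    bins: Dict[str, pd.DataFrame] = {}
    truth_variants: Dict[str, List[TrueVariant]] = {}
    hit_classes: Dict[str, str] = {}
    ihc_rows = []
    fish_rows = []
    fish_truth: Dict[str, float] = {}

    for pi, patient in enumerate(patients):
        rng = _patient_rng(config.seed, pi, 0)
        segments = list(config.cnv_truth.get(patient, []))
        rows = []
        p_truth: List[TrueVariant] = []

        # --- somatic events per gene ---
        driver_muts = 0
        for gene in genes:
            chrom, gstart, gend = loci[gene]
            if gene == config.driver_gene:
                if rng.random() >= config.driver_mut_prob:
                    continue
                n_muts = 2 if rng.random() < config.driver_second_mut_prob else 1
            else:
                p_event = 1.0 - (1.0 - base_event_prob) * (1.0 - uplift_by_gene.get(gene, 0.0))
                if rng.random() >= p_event:
                    continue
                n_muts = 1
            for _ in range(n_muts):
                pos0 = int(rng.integers(gstart, gend))
                state = _copy_state_at(segments, chrom, pos0)
                vaf = expected_somatic_vaf(config.tumour_purity, state)
                func_classes = list(config.func_class_probs)
                probs = np.array([config.func_class_probs[c] for c in func_classes])
                func = str(rng.choice(func_classes, p=probs / probs.sum()))
                ref, alt = _random_substitution(rng)
                if func == "frameshift":
                    ref, alt = ref, ref + alt  # 1-bp insertion
                t_depth = _draw_depth(rng, config.mean_depth_tumour)
                n_depth = _draw_depth(rng, config.mean_depth_normal)
                t_ref, t_alt = sample_site_reads(vaf, t_depth, rng)
                n_ref, n_alt = sample_site_reads(config.normal_error_rate, n_depth, rng)
                rows.append((chrom, pos0 + 1, ref, alt, gene, func, t_ref, t_alt,
                             n_ref, n_alt, np.nan, gene in fp_gene_set))
                p_truth.append(TrueVariant(patient, chrom, pos0 + 1, gene,
                                           vaf, func, "somatic"))
                if gene == config.driver_gene:
                    driver_muts += 1

        # --- germline heterozygous sites ---
        for chrom, length in config.genome:
            n_hets = rng.poisson(config.germline_het_rate * length)
            positions = np.sort(rng.integers(0, length, size=n_hets))
            for pos0 in positions:
                state = _copy_state_at(segments, chrom, int(pos0))
                alt_on_a = bool(rng.random() < 0.5)
                t_vaf = germline_tumour_baf(config.tumour_purity, state, alt_on_a)
                ref, alt = _random_substitution(rng)
                t_depth = _draw_depth(rng, config.mean_depth_tumour)
                n_depth = _draw_depth(rng, config.mean_depth_normal)
                t_ref, t_alt = sample_site_reads(t_vaf, t_depth, rng)
                n_ref, n_alt = sample_site_reads(0.5, n_depth, rng)
                gene = ""
                for g, (gc, gs, ge) in loci.items():
                    if gc == chrom and gs <= pos0 < ge:
                        gene = g
                        break
                pop_maf = float(rng.uniform(0.05, 0.5))
                rows.append((chrom, int(pos0) + 1, ref, alt, gene, "silent",
                             t_ref, t_alt, n_ref, n_alt, pop_maf, False))

        # --- artifact / noise sites ---
        for chrom, length in config.genome:
            n_art = rng.poisson(config.artifact_rate * length)
            for pos0 in np.sort(rng.integers(0, length, size=n_art)):
                vaf = float(rng.uniform(0.02, 0.12))
                ref, alt = _random_substitution(rng)
                t_depth = _draw_depth(rng, config.mean_depth_tumour)
                n_depth = _draw_depth(rng, config.mean_depth_normal)
                t_ref, t_alt = sample_site_reads(vaf, t_depth, rng)
                n_ref, n_alt = sample_site_reads(vaf, n_depth, rng)
                rows.append((chrom, int(pos0) + 1, ref, alt, "", "other",
                             t_ref, t_alt, n_ref, n_alt, np.nan, False))

        table = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
        table = table.sort_values(["chrom", "pos"], ignore_index=True)
        variants[patient] = table
        truth_variants[patient] = p_truth

        # --- coverage bins ---
        bin_rng = _patient_rng(config.seed, pi, 1)
        bin_rows = []
        p = config.tumour_purity
        for chrom, length in config.genome:
            for start in range(0, length, config.bin_width):
                state = _copy_state_at(segments, chrom, start)
                mult = DEPTH_MULTIPLIERS[state]
                t_mean = config.mean_depth_tumour * (p * mult + (1 - p))
                t_count = int(bin_rng.poisson(t_mean))
                n_count = int(bin_rng.poisson(config.mean_depth_normal))
                bin_rows.append((chrom, start, t_count, n_count))
        bins[patient] = pd.DataFrame(
            bin_rows, columns=["chrom", "bin_start", "t_count", "n_count"])

        # --- driver-gene hit class and linked phenotypes ---
        pheno_rng = _patient_rng(config.seed, pi, 2)
        locus_deleted = False
        if config.driver_gene:
            chrom, gstart, gend = loci[config.driver_gene]
            locus_deleted = any(
                sc == chrom and s < gend and gstart < e and st == "loss"
                for sc, s, e, st in segments)
        hit_class = HitClassification.classify(driver_muts, locus_deleted)
        hit_classes[patient] = hit_class

        functional_loss = driver_muts >= 1  # even monoallelic mutations impair function
        ihc_rows.extend(_ihc_observations(patient, functional_loss,
                                          locus_deleted, pheno_rng))
        true_frac = (config.fish_deleted_detect_fraction if locus_deleted
                     else config.fish_background_fraction)
        fish_truth[patient] = true_frac
        for ni, (o, g) in enumerate(generate_fish_nuclei(
                true_frac, config.fish_n_nuclei, config.fish_miss_rate, pheno_rng)):
            fish_rows.append((patient, "tumour", ni, o, g))

    # --- FISH negative controls (shared stream, not per patient) ---
    control_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(999, 0)))
    for ci in range(5):
        frac = float(control_rng.uniform(0.02, 0.06))
        for ni, (o, g) in enumerate(generate_fish_nuclei(
                frac, 2 * config.fish_n_nuclei, config.fish_miss_rate, control_rng)):
            fish_rows.append((f"CTRL{ci + 1}", "control", ni, o, g))

    truth = GroundTruth(
        somatic_variants=truth_variants,
        cnv_segments={p: list(config.cnv_truth.get(p, [])) for p in patients},
        enriched_signatures=[name for name, _, _ in config.planted_signatures],
        hit_classes=hit_classes,
        driver_gene=config.driver_gene or "",
        gene_loci=loci,
        fish_deleted_fraction=fish_truth,
    )
    ihc = pd.DataFrame(ihc_rows, columns=["case_id", "marker", "extent_pct",
                                          "intensity", "interpretable"])
    fish = pd.DataFrame(fish_rows, columns=["case_id", "role", "nucleus_index",
                                            "orange", "green"])
    return Cohort(config=config, variants=variants, coverage_bins=bins,
                  ihc=ihc, fish=fish, truth=truth)


def _ihc_observations(patient: str, functional_loss: bool, locus_deleted: bool,
                      rng: np.random.Generator) -> List[tuple]:
    """IHC extent/intensity draws linked to the driver genotype.

    Mutated cases show low driver-protein expression and defective
    trimethylation; deletion-only and wild-type cases keep trimethylation
    (one retained allele suffices), with reduced expression when one copy
    is lost.  Dimethylation is preserved throughout.
    """
    def draw(extent_lo, extent_hi, intensities):
        extent = float(rng.uniform(extent_lo, extent_hi))
        intensity = int(rng.choice(intensities))
        return extent, intensity

    if functional_loss:
        setd2 = draw(0, 15, [0, 1])
        me3 = draw(0, 12, [0, 1])
    elif locus_deleted:
        setd2 = draw(25, 55, [1, 2])
        me3 = draw(60, 95, [2, 3])
    else:
        setd2 = draw(70, 100, [2, 3])
        me3 = draw(70, 100, [3])
    me2 = draw(55, 95, [2, 3])
    h3 = draw(85, 100, [3])
    return [
        (patient, "SETD2", *setd2, True),
        (patient, "H3K36me3", *me3, True),
        (patient, "H3K36me2", *me2, True),
        (patient, "H3_total", *h3, True),
    ]


# ---------------------------------------------------------------------------
# Writers


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write a cohort to disk: per-patient variant TSV + VCF, coverage-bin
    TSV, phenotype CSVs and ground-truth JSON."""
    import os

    os.makedirs(outdir, exist_ok=True)
    for patient, table in cohort.variants.items():
        table.to_csv(os.path.join(outdir, f"{patient}.variants.tsv"),
                     sep="\t", index=False)
        write_vcf(table, os.path.join(outdir, f"{patient}.vcf"),
                  genome=cohort.config.genome)
    for patient, table in cohort.coverage_bins.items():
        table.to_csv(os.path.join(outdir, f"{patient}.bins.tsv"),
                     sep="\t", index=False)
    cohort.ihc.to_csv(os.path.join(outdir, "ihc.csv"), index=False)
    cohort.fish.to_csv(os.path.join(outdir, "fish.csv"), index=False)
    with open(os.path.join(outdir, "truth.json"), "w") as handle:
        handle.write(cohort.truth.to_json())


def write_vcf(table: pd.DataFrame, path,
              genome: Optional[Sequence[Tuple[str, int]]] = None,
              tumour_name: str = "TUMOR", normal_name: str = "NORMAL") -> None:
    """Write a variant table as VCF v4.2 with AD/DP per sample.

    Site-level annotations (gene, functional class, population frequency,
    false-positive-gene flag) go into INFO so the round trip through VCF
    loses nothing the filters need.
    """
    lines = ["##fileformat=VCFv4.2"]
    if genome:
        for chrom, length in genome:
            lines.append(f"##contig=<ID={chrom},length={length}>")
    lines += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=FCLASS,Number=1,Type=String,Description="Functional class">',
        '##INFO=<ID=PMAF,Number=1,Type=Float,Description="Population allele frequency">',
        '##INFO=<ID=FPGENE,Number=0,Type=Flag,Description="Gene on false-positive list">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        f"{tumour_name}\t{normal_name}",
    ]
    for _, row in table.iterrows():
        info = []
        if row["gene"]:
            info.append(f"GENE={row['gene']}")
        info.append(f"FCLASS={row['func_class']}")
        if pd.notna(row["pop_maf"]):
            info.append(f"PMAF={row['pop_maf']:.6g}")
        if bool(row["fp_gene_flag"]):
            info.append("FPGENE")
        t_dp = int(row["t_ref"]) + int(row["t_alt"])
        n_dp = int(row["n_ref"]) + int(row["n_alt"])
        lines.append("\t".join([
            str(row["chrom"]), str(int(row["pos"])), ".", str(row["ref"]),
            str(row["alt"]), ".", "PASS", ";".join(info) or ".", "DP:AD",
            f"{t_dp}:{int(row['t_ref'])},{int(row['t_alt'])}",
            f"{n_dp}:{int(row['n_ref'])},{int(row['n_alt'])}",
        ]))
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")
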