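import math

import numpy as np
import pytest

from lymphomut.somatic_filtering import VariantRecord


def records_from_frame(frame, patient=""):
    """Variant-table DataFrame (TSV dialect) -> VariantRecord list."""
    records = []
    for row in frame.itertuples(index=False):
        pop_maf = row.pop_maf
        if isinstance(pop_maf, float) and math.isnan(pop_maf):
            pop_maf = None
        records.append(VariantRecord(
            chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
            gene=row.gene, func_class=row.func_class,
            t_ref=int(row.t_ref), t_alt=int(row.t_alt),
            n_ref=int(row.n_ref), n_alt=int(row.n_alt),
            pop_maf=pop_maf, fp_gene_flag=bool(row.fp_gene_flag),
            patient=patient,
        ))
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-patient cohort with a planted loss, cnLOH and a driver gene."""
    from lymphomut.synthetic_data import CohortConfig, generate_cohort

    config = CohortConfig(
        n_patients=4,
        n_genes=60,
        genome=[("chr1", 6_000_000), ("chr2", 6_000_000)],
        seed=7,
        driver_gene="SETD2",
        cnv_truth={
            "P01": [("chr1", 0, 1_500_000, "loss")],       # driver locus lost
            "P02": [("chr2", 1_000_000, 4_000_000, "cnLOH")],
            "P03": [("chr2", 2_000_000, 4_000_000, "gain")],
        },
    )
    return generate_cohort(config)
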