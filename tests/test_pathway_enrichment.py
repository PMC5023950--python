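"""Event matrix construction, permutation null, t-test and BH adjustment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lymphomut.cnv_segmentation import SegmentCall, call_segments
from lymphomut.errors import DomainError
from lymphomut.pathway_enrichment import (
    EventMatrix,
    SignatureSet,
    bh_adjust,
    build_event_matrix,
    enrichment_test,
    permute_event_matrix,
    run_enrichment,
    signature_frequency_matrix,
)


def bh_oracle(p):
    """Direct-formula BH: adj(i) = min over sorted ranks k >= i of m*p(k)/k."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj_sorted = []
    for i in range(m):
        adj_sorted.append(min(m * p[order[k]] / (k + 1) for k in range(i, m)))
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = min(1.0, adj_sorted[rank])
    return out


# --- build_event_matrix -----------------------------------------------------

def variant_frame(rows):
    return pd.DataFrame(rows, columns=["patient", "gene", "func_class"])


def test_single_variant_single_cell():
    mb = build_event_matrix(variant_frame([("P1", "GENE1", "missense")]),
                            ["P1"], ["GENE1"])
    assert mb.values.tolist() == [[1]]


def test_empty_variants_all_zero():
    mb = build_event_matrix(variant_frame([]), ["P1", "P2"], ["A", "B"])
    assert mb.values.sum() == 0


def test_silent_variants_are_not_events():
    mb = build_event_matrix(variant_frame([("P1", "A", "silent")]),
                            ["P1"], ["A"])
    assert mb.values.sum() == 0


def test_matrix_with_cnv_matches_hand_built_oracle():
    variants = variant_frame([
        ("P1", "GENE1", "missense"),
        ("P2", "GENE2", "nonsense"),
        ("P3", "GENE1", "frameshift"),
        ("P3", "GENE2", "silent"),
    ])
    loss = call_segments([SegmentCall("chr1", 0, 2_000_000, 20, -0.6)])
    segments = {"P2": loss}
    loci = {"GENE1": ("chr2", 0, 10_000), "GENE2": ("chr2", 50_000, 60_000),
            "GENE3": ("chr1", 100_000, 120_000)}
    mb = build_event_matrix(variants, ["P1", "P2", "P3"],
                            ["GENE1", "GENE2", "GENE3", "GENE4"],
                            segments_by_patient=segments, gene_loci=loci,
                            include_cnv=True)
    # Hand-built: GENE1 mutated in P1, P3; GENE2 in P2; GENE3 deleted in P2;
    # GENE4 has no locus -> skipped from the CNV layer.
    expected = [
        [1, 0, 1],
        [0, 1, 0],
        [0, 1, 0],
        [0, 0, 0],
    ]
    assert mb.values.tolist() == expected
    assert mb.cnv_skipped == ["GENE4"]


# --- signature_frequency_matrix --------------------------------------------

def toy_matrix():
    values = np.array([
        [1, 0, 1],
        [1, 1, 0],
        [0, 0, 0],
        [1, 1, 1],
        [0, 1, 0],
    ])
    return EventMatrix([f"G{i}" for i in range(5)], ["P1", "P2", "P3"], values)


def test_counts_match_hand_computation():
    sigs = SignatureSet({"both": ["G0", "G1"], "rest": ["G2", "G3", "G4"]})
    freq = signature_frequency_matrix(toy_matrix(), sigs)
    assert freq.loc["both"].tolist() == [2, 1, 1]
    assert freq.loc["rest"].tolist() == [1, 2, 1]
    normalized = signature_frequency_matrix(toy_matrix(), sigs, normalized=True)
    assert normalized.loc["rest"].tolist() == pytest.approx([1 / 3, 2 / 3, 1 / 3])


def test_all_zero_matrix_gives_zero_frequencies():
    mb = EventMatrix(["A", "B"], ["P1", "P2"], np.zeros((2, 2)))
    freq = signature_frequency_matrix(mb, SignatureSet({"s": ["A", "B"]}))
    assert not freq.to_numpy().any()


def test_unmatched_signature_excluded_with_warning():
    with pytest.warns(UserWarning):
        freq = signature_frequency_matrix(
            toy_matrix(), SignatureSet({"ghost": ["NOPE"]}))
    assert freq.empty


# --- permute_event_matrix ---------------------------------------------------

def test_permutation_preserves_row_multiset_and_column_sums(rng):
    mb = toy_matrix()
    row_multiset = sorted(mb.values.sum(axis=1))
    col_sums = mb.values.sum(axis=0)
    for perm in permute_event_matrix(mb, 50, rng):
        assert sorted(perm.sum(axis=1)) == row_multiset
        assert (perm.sum(axis=0) == col_sums).all()


def test_single_row_permutation_is_identity(rng):
    mb = EventMatrix(["A"], ["P1", "P2", "P3"], np.array([[1, 0, 1]]))
    for perm in permute_event_matrix(mb, 5, rng):
        assert (perm == mb.values).all()


def test_two_row_orders_equally_likely(rng):
    mb = EventMatrix(["A", "B"], ["P1", "P2"], np.array([[1, 0], [0, 1]]))
    n = 4000
    identity = sum(
        (perm == mb.values).all() for perm in permute_event_matrix(mb, n, rng))
    # Binomial(4000, 0.5): 4 s.e. ~ 0.032
    assert abs(identity / n - 0.5) < 0.04


# --- enrichment_test --------------------------------------------------------

def test_observed_equal_to_null_has_no_signal(rng):
    obs = np.array([2.0, 3.0, 1.0, 4.0])
    null = np.tile(obs, (10, 1))
    p, null_mean, _ = enrichment_test(obs, null)
    assert p >= 0.5
    assert null_mean == pytest.approx(obs.mean())


def test_large_margin_gives_tiny_p():
    obs = np.array([10.0, 11.0, 12.0, 10.5, 11.5])
    null = np.random.default_rng(0).uniform(0, 1, size=(50, 5))
    p, _, _ = enrichment_test(obs, null)
    assert p < 1e-4


def test_welch_matches_hand_computation():
    # 3 patients, 5 permutations, integer frequencies.
    obs = np.array([4.0, 5.0, 6.0])
    null = np.array([
        [1.0, 2.0, 3.0],
        [2.0, 2.0, 2.0],
        [0.0, 1.0, 2.0],
        [3.0, 1.0, 2.0],
        [1.0, 1.0, 1.0],
    ])
    pooled = null.ravel()
    # Welch statistic and Welch-Satterthwaite df assembled by the textbook
    # formulas, with the t tail from scipy's distribution function.
    se2_a = obs.var(ddof=1) / obs.size
    se2_b = pooled.var(ddof=1) / pooled.size
    t_stat = (obs.mean() - pooled.mean()) / np.sqrt(se2_a + se2_b)
    df = (se2_a + se2_b) ** 2 / (
        se2_a ** 2 / (obs.size - 1) + se2_b ** 2 / (pooled.size - 1))
    expected_p = float(stats.t.sf(t_stat, df))
    p, _, _ = enrichment_test(obs, null)
    assert p == pytest.approx(expected_p, rel=1e-12)


def test_degenerate_zero_variance_equal_means_is_one():
    obs = np.array([2.0, 2.0, 2.0])
    null = np.full((5, 3), 2.0)
    p, _, _ = enrichment_test(obs, null)
    assert p == 1.0


def test_perm_mean_variant(rng):
    obs = np.array([5.0, 5.0, 5.0])
    null = rng.uniform(0, 2, size=(99, 3))
    p, _, _ = enrichment_test(obs, null, method="perm_mean")
    assert p == pytest.approx(1 / 100)


# --- bh_adjust --------------------------------------------------------------

def test_single_p_unchanged():
    assert bh_adjust([0.03]).tolist() == [0.03]


def test_known_sequence_matches_oracle():
    p = [0.01, 0.02, 0.03, 0.04]
    assert bh_adjust(p).tolist() == pytest.approx(bh_oracle(p))


def test_ties_all_equal():
    assert bh_adjust([0.2, 0.2, 0.2]).tolist() == pytest.approx([0.2] * 3)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8))
def test_bh_matches_direct_formula_enumeration(p):
    ours = bh_adjust(p)
    assert ours.tolist() == pytest.approx(bh_oracle(p), abs=1e-12)
    assert (ours >= np.asarray(p) - 1e-12).all()
    assert (ours <= 1.0).all()


def test_bh_agrees_with_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(4)
    for _ in range(20):
        p = rng.uniform(0, 1, size=rng.integers(1, 30))
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        assert bh_adjust(p).tolist() == pytest.approx(adj.tolist(), abs=1e-12)


# --- run_enrichment ---------------------------------------------------------

def planted_matrix(seed, n_genes=200, n_patients=15, uplift=0.9, size=10):
    g = np.random.default_rng(seed)
    values = (g.random((n_genes, n_patients)) < 0.2).astype(np.int8)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    for i in range(size):
        values[i] = (g.random(n_patients) < uplift).astype(np.int8)
    mb = EventMatrix(genes, [f"P{j:02d}" for j in range(n_patients)], values)
    sig_rng = np.random.default_rng(seed + 10_000)
    sigs = {f"S{k:02d}": list(sig_rng.choice(genes[size:], size, replace=False))
            for k in range(19)}
    sigs["PLANTED"] = genes[:size]
    return mb, SignatureSet(sigs)


def test_planted_signature_recovered():
    mb, sigs = planted_matrix(seed=1)
    results = run_enrichment(mb, sigs, n_perm=1000, seed=1)
    top = results[0]
    assert top.signature == "PLANTED"
    assert top.adjusted_p <= 0.05
    assert 0.0 <= top.proportion_with_event <= 1.0
    assert all(r.adjusted_p >= r.p_value - 1e-12 for r in results)


def test_empty_signature_set_gives_empty_results():
    mb, _ = planted_matrix(seed=2)
    with pytest.warns(UserWarning):
        results = run_enrichment(mb, SignatureSet({"one": ["G0000"]}),
                                 n_perm=10, seed=0)
    assert results == []


def test_requires_two_permutations():
    with pytest.raises(DomainError):
        enrichment_test([1.0, 2.0], np.ones((1, 2)))
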