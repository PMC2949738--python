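"""Haplotype tabulation, the three design matrices, and LD statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapscan.design import (
    HaplotypeTable,
    adjacent_inclusion_mask,
    build_haplotype,
    build_main_adj,
    build_main_effects,
    inclusion_mask_from_table,
    mean_abs_r,
    pairwise_ld,
    tabulate_haplotypes,
)
from hapscan.phasing import em_frequencies, phase_posteriors


def _posterior(dosage, table=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    if table is None:
        table = em_frequencies(dosage)
    return phase_posteriors(dosage, table)


def _uniform_table(m):
    codes = np.arange(1 << m)
    haps = ((codes[:, None] >> np.arange(m)) & 1).astype(np.uint8)
    return HaplotypeTable(haps, np.full(1 << m, 1.0))


class TestTabulate:
    def test_phased_counts(self):
        t = tabulate_haplotypes(np.array([[0, 0], [0, 0], [0, 1]]))
        assert t.counts.tolist() == [2.0, 1.0]
        np.testing.assert_allclose(t.freqs, [2 / 3, 1 / 3])

    def test_posterior_expected_counts(self):
        # double-het under a uniform table: 0.5 on (00,11), 0.5 on (01,10)
        post = _posterior([[1, 1]], _uniform_table(2))
        t = tabulate_haplotypes(post)
        np.testing.assert_allclose(t.counts, [0.5, 0.5, 0.5, 0.5])

    def test_expected_counts_sum_to_two_per_individual(self, rng):
        dosage = rng.integers(0, 3, size=(60, 4))
        t = tabulate_haplotypes(_posterior(dosage))
        assert t.counts.sum() == pytest.approx(120.0)


class TestMainEffects:
    def test_phased_identity(self):
        X = np.array([[0, 1], [1, 0]], dtype=np.uint8)
        d = build_main_effects(X)
        assert d.unit == "haplotype-copy"
        np.testing.assert_array_equal(d.tested(), X)

    def test_individual_dosage_row(self):
        post = _posterior([[2, 1], [0, 0]])
        d = build_main_effects(post)
        assert d.unit == "individual"
        np.testing.assert_allclose(d.tested()[0], [2, 1])

    def test_es_equals_phased_when_phase_certain(self, rng):
        # at most one heterozygous site per individual: phase is certain,
        # so ES rows must equal the sum of the two phased copy rows
        h1 = rng.integers(0, 2, size=(30, 3)).astype(np.uint8)
        h2 = h1.copy()
        h2[:, 0] = rng.integers(0, 2, size=30)  # het possible only at SNP 0
        post = _posterior(h1 + h2)
        d_es = build_main_adj(post, min_count=0)
        d_ph = build_main_adj(np.vstack([h1, h2]), min_count=0)
        expected = d_ph.tested()[:30] + d_ph.tested()[30:]
        np.testing.assert_allclose(d_es.tested(), expected, atol=1e-8)

    def test_monomorphic_column_dropped(self):
        X = np.array([[0, 1], [0, 0]], dtype=np.uint8)
        with pytest.warns(UserWarning, match="monomorphic"):
            d = build_main_effects(X)
        assert d.terms == ["intercept", "main:1"]


class TestAdjacentInclusion:
    @pytest.mark.parametrize(
        "counts,expected",
        [((1400, 70, 20, 10), True), ((1490, 5, 3, 2), False)],
    )
    def test_count_threshold(self, counts, expected):
        haps = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=np.uint8)
        t = HaplotypeTable(haps, counts)
        assert inclusion_mask_from_table(t)[0] == expected

    def test_complete_ld_excluded(self):
        # D' = 1: one 2-SNP haplotype cell is empty
        col = np.repeat([0, 1], 50).astype(np.uint8)
        X = np.column_stack([col, col])
        assert not adjacent_inclusion_mask(X)[0]


class TestMainAdj:
    def test_phased_product_term(self):
        X = np.repeat(
            np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8), 6, axis=0
        )
        d = build_main_adj(X, min_count=5)
        assert "adj:0,1" in d.terms
        np.testing.assert_array_equal(d.values[:, -1], X[:, 0] * X[:, 1])

    def test_reduces_to_main_when_excluded(self, rng):
        X = rng.integers(0, 2, size=(30, 3)).astype(np.uint8)
        d_adj = build_main_adj(X, min_count=10**6)
        d_main = build_main_effects(X)
        np.testing.assert_array_equal(d_adj.values, d_main.values)

    def test_es_product_distinguishes_phase(self):
        # genotype (1,1): coupling phase (11/00) gives 1, repulsion (10/01) gives 0
        haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
        coupling = HaplotypeTable(haps, [10, 0, 0, 10])
        repulsion = HaplotypeTable(haps, [0, 10, 10, 0])
        post_c = _posterior([[1, 1]], coupling)
        post_r = _posterior([[1, 1]], repulsion)
        assert post_c.expected_product(0, 1)[0] == pytest.approx(1.0)
        assert post_r.expected_product(0, 1)[0] == pytest.approx(0.0)


class TestHaplotypeDesign:
    def test_rare_merging(self):
        haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
        t = HaplotypeTable(haps, [980, 15, 9, 6])
        from hapscan.design import haplotype_categories

        labels, groups, counts = haplotype_categories(t)
        assert labels == ["hap:00", "hap:01", "hap:rare"]
        assert counts.tolist() == [980, 15, 15]

    def test_phased_indicator_rows(self):
        X = np.array([[0, 0]] * 12 + [[1, 1]] * 11, dtype=np.uint8)
        d = build_haplotype(X, min_count=10, drop_reference=False)
        assert d.reference == "hap:00"
        np.testing.assert_array_equal(d.tested().sum(axis=1), np.ones(23))

    def test_degenerate_single_category(self):
        X = np.zeros((30, 2), dtype=np.uint8)
        with pytest.raises(ValueError, match="degenerate"):
            build_haplotype(X)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_individual_rows_sum_to_two(self, seed):
        rng = np.random.default_rng(seed)
        dosage = rng.integers(0, 3, size=(40, 3))
        post = _posterior(dosage)
        d = build_haplotype(post, min_count=5, drop_reference=False)
        np.testing.assert_allclose(d.tested().sum(axis=1), 2.0, atol=1e-9)


class TestLD:
    def test_identical_columns(self):
        col = np.array([0, 0, 1, 1, 1, 0], dtype=np.uint8)
        ld = pairwise_ld(col, col)
        assert ld.r == pytest.approx(1.0)
        assert ld.d_prime == pytest.approx(1.0)

    def test_equilibrium(self):
        a = np.array([0, 0, 1, 1], dtype=np.uint8)
        b = np.array([0, 1, 0, 1], dtype=np.uint8)
        ld = pairwise_ld(a, b)
        assert ld.r == pytest.approx(0.0)
        assert ld.d_prime == pytest.approx(0.0)

    def test_r2_equals_sample_correlation(self, rng):
        a = rng.integers(0, 2, 200)
        b = (a + (rng.random(200) < 0.3)) % 2
        ld = pairwise_ld(a, b)
        assert ld.r2 == pytest.approx(np.corrcoef(a, b)[0, 1] ** 2, abs=1e-12)

    def test_monomorphic_flagged(self):
        ld = pairwise_ld(np.zeros(10, dtype=np.uint8), np.arange(10) % 2)
        assert not ld.defined and np.isnan(ld.r)


class TestMeanAbsR:
    def test_causal_duplicated(self):
        c = np.array([0, 1, 0, 1, 1, 0], dtype=np.uint8)
        assert mean_abs_r(np.column_stack([c, c, c]), c) == pytest.approx(1.0)

    def test_known_mixture(self):
        c = np.repeat([0, 1], 4).astype(np.uint8)
        m1 = c.copy()                                   # |r| = 1
        m2 = np.tile([0, 0, 1, 1], 2).astype(np.uint8)  # |r| = 0
        m3 = np.array([0, 0, 0, 1, 0, 1, 1, 1], dtype=np.uint8)  # |r| = 0.5
        got = mean_abs_r(np.column_stack([m1, m2, m3]), c)
        assert got == pytest.approx(0.5)

    def test_monomorphic_causal_is_error(self):
        with pytest.raises(ValueError):
            mean_abs_r(np.eye(4), np.zeros(4))
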