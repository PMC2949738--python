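"""EM haplotype-frequency estimation and phase posteriors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapscan.design import HaplotypeTable, pack_codes, tabulate_haplotypes
from hapscan.phasing import em_frequencies, phase_posteriors


def _grid_max_loglik_2snp(dosage, coarse=0.02, fine=0.002):
    """Brute-force maximum of the 2-SNP pair likelihood over the frequency
    simplex (independent oracle: direct enumeration, no EM)."""
    dosage = np.asarray(dosage)

    def loglik(p):  # p = freqs of haplotypes (00, 10, 01, 11) -> codes 0,1,2,3
        ll = np.zeros(p.shape[0])
        for g in dosage:
            code_pairs = []
            het = [j for j in range(2) if g[j] == 1]
            base = sum((1 << j) for j in range(2) if g[j] == 2)
            if len(het) == 0:
                pairs = [(base, base, 1.0)]
            elif len(het) == 1:
                pairs = [(base, base | (1 << het[0]), 2.0)]
            else:
                pairs = [(0, 3, 2.0), (1, 2, 2.0)]
            lik = sum(m * p[:, a] * p[:, b] for a, b, m in pairs)
            ll += np.log(np.maximum(lik, 1e-300))
        return ll

    def simplex(step):
        vals = np.arange(0, 1 + step / 2, step)
        pts = []
        for a in vals:
            for b in vals:
                if a + b > 1 + 1e-12:
                    continue
                for c in vals:
                    d = 1 - a - b - c
                    if d < -1e-12:
                        continue
                    pts.append((a, b, c, max(d, 0.0)))
        return np.asarray(pts)

    pts = simplex(coarse)
    best = pts[int(np.argmax(loglik(pts)))]
    lo = np.maximum(best - 2 * coarse, 0)
    vals = [np.arange(l, min(l + 4 * coarse, 1) + fine / 2, fine) for l in lo[:3]]
    pts = []
    for a in vals[0]:
        for b in vals[1]:
            for c in vals[2]:
                d = 1 - a - b - c
                if d >= -1e-12:
                    pts.append((a, b, c, max(d, 0.0)))
    pts = np.asarray(pts)
    return float(np.max(loglik(pts)))


class TestEM:
    def test_equals_counting_without_double_hets(self):
        dosage = np.array([[0, 0], [2, 2], [1, 0], [0, 1], [2, 0]])
        t = em_frequencies(dosage)
        # phase is certain: EM must match direct haplotype counting
        got = {tuple(h): f for h, f in zip(t.haplotypes, t.freqs)}
        assert got[(0, 0)] == pytest.approx(0.4)
        assert got[(1, 0)] == pytest.approx(0.3)
        assert got[(1, 1)] == pytest.approx(0.2)
        assert got[(0, 1)] == pytest.approx(0.1)

    def test_double_het_symmetry(self):
        # only double heterozygotes: the symmetric stationary point
        t = em_frequencies(np.array([[1, 1]] * 8))
        post = phase_posteriors(np.array([[1, 1]]), t)
        probs = sorted(pr for _, pr in post.pairs_for(0))
        np.testing.assert_allclose(probs, [0.5, 0.5], atol=1e-9)

    def test_loglik_matches_grid_oracle(self):
        dosage = np.array([[1, 1], [2, 0], [1, 0]])
        t = em_frequencies(dosage, tol=1e-12)
        oracle = _grid_max_loglik_2snp(dosage)
        assert t.loglik == pytest.approx(oracle, abs=1e-4)

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.integers(0, 10_000))
    def test_loglik_monotone(self, seed):
        rng = np.random.default_rng(seed)
        dosage = rng.integers(0, 3, size=(25, 4))
        t = em_frequencies(dosage)
        assert np.all(np.diff(t.loglik_path) >= -1e-8)

    def test_frequency_recovery(self, rng):
        true = {0: 0.4, 1: 0.2, 2: 0.3, 3: 0.1}  # codes over 2 SNPs
        codes = rng.choice(list(true), p=list(true.values()), size=4000)
        bits = ((codes[:, None] >> np.arange(2)) & 1).astype(np.int8)
        dosage = bits[0::2] + bits[1::2]
        t = em_frequencies(dosage)
        est = dict(zip(pack_codes(t.haplotypes), t.freqs))
        for code, p in true.items():
            se = np.sqrt(p * (1 - p) / 4000)
            assert abs(est[code] - p) < 3 * se + 1e-3

    def test_posterior_counts_equal_em_counts(self, rng):
        dosage = rng.integers(0, 3, size=(80, 3))
        t = em_frequencies(dosage, tol=1e-12)
        t2 = tabulate_haplotypes(phase_posteriors(dosage, t))
        np.testing.assert_allclose(t2.counts, t.counts, atol=1e-6)

    def test_missing_rows_dropped(self):
        dosage = np.array([[1, 0], [0, 1], [2, 2]])
        missing = np.array([[False, False], [True, False], [False, False]])
        t = em_frequencies(dosage, missing=missing)
        assert t.n_used == 2

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="no individuals"):
            em_frequencies(np.zeros((0, 2), dtype=int))
        with pytest.raises(ValueError, match="cap"):
            em_frequencies(np.zeros((3, 9), dtype=int))


class TestPosteriors:
    def test_homozygous_single_pair(self):
        t = em_frequencies(np.array([[0, 2], [0, 2], [2, 0]]))
        post = phase_posteriors(np.array([[0, 2]]), t)
        pairs = post.pairs_for(0)
        assert len(pairs) == 1
        (ha, hb), pr = pairs[0]
        assert pr == pytest.approx(1.0)
        assert ha.tolist() == [0, 1] and hb.tolist() == [0, 1]

    def test_double_het_with_coupling_table(self):
        haps = np.array([[0, 0], [1, 1]], dtype=np.uint8)
        t = HaplotypeTable(haps, [1.0, 1.0])
        post = phase_posteriors(np.array([[1, 1]]), t)
        pairs = {(tuple(a), tuple(b)): pr for (a, b), pr in post.pairs_for(0)}
        assert pairs[((0, 0), (1, 1))] == pytest.approx(1.0)

    def test_double_het_uniform_table(self):
        codes = np.arange(4)
        haps = ((codes[:, None] >> np.arange(2)) & 1).astype(np.uint8)
        t = HaplotypeTable(haps, np.ones(4))
        post = phase_posteriors(np.array([[1, 1]]), t)
        for (_, _), pr in post.pairs_for(0):
            assert pr == pytest.approx(0.5)

    def test_zero_probability_genotype_uniform_fallback(self):
        haps = np.array([[0, 0]], dtype=np.uint8)
        t = HaplotypeTable(haps, [1.0])
        with pytest.warns(UserWarning, match="zero probability"):
            post = phase_posteriors(np.array([[1, 1]]), t)
        probs = [pr for _, pr in post.pairs_for(0)]
        np.testing.assert_allclose(probs, [0.5, 0.5])
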