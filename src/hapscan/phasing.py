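"""EM haplotype-frequency estimation and phase posteriors for short windows.

For a window of m <= 8 SNPs the 2^m possible haplotypes are enumerable, so
the multinomial likelihood over unordered haplotype pairs under
Hardy-Weinberg random pairing can be maximized with a plain EM: the
E-step distributes each genotype's count over its compatible pairs in
proportion to p_a * p_b (doubled for heterozygous pairs), and the M-step
re-normalizes the expected haplotype counts.  Initialization is the
product-of-marginals (linkage-equilibrium) table, which is deterministic;
on exactly symmetric data the symmetric stationary point is returned.

The resulting posteriors P(pair | genotype) are the inputs of
expectation-substitution: every downstream design entry is an expectation
over them.  Individuals with a missing genotype anywhere in the window
are excluded from that window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .design import HaplotypeTable, unpack_codes

MAX_WINDOW = 8


@lru_cache(maxsize=100_000)
def _compatible_pairs(genotype: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unordered haplotype-pair codes (a <= b) compatible with a genotype.

    Returns (a codes, b codes, multiplicity) where multiplicity is 2 for
    heterozygous pairs, 1 for homozygous ones.
    """
    m = len(genotype)
    base = 0
    het = []
    for j, g in enumerate(genotype):
        if g == 2:
            base |= 1 << j
        elif g == 1:
            het.append(j)
    if not het:
        a = np.array([base], dtype=np.int64)
        return a, a.copy(), np.ones(1)
    k = len(het)
    a_list, b_list = [], []
    # fix the first het site on haplotype a to break the ordering symmetry
    first = het[0]
    for mask in range(1 << (k - 1)):
        a = base | (1 << first)
        b = base
        for t, j in enumerate(het[1:]):
            if (mask >> t) & 1:
                a |= 1 << j
            else:
                b |= 1 << j
        a_list.append(min(a, b))
        b_list.append(max(a, b))
    a_arr = np.asarray(a_list, dtype=np.int64)
    b_arr = np.asarray(b_list, dtype=np.int64)
    return a_arr, b_arr, np.where(a_arr != b_arr, 2.0, 1.0)


def _drop_missing(genotypes_window, missing=None) -> np.ndarray:
    g = np.asarray(genotypes_window)
    if hasattr(genotypes_window, "dosage"):  # GenotypeMatrix
        missing = genotypes_window.missing
        g = genotypes_window.dosage
    g = np.atleast_2d(g)
    if missing is not None:
        keep = ~np.asarray(missing, dtype=bool).any(axis=1)
        g = g[keep]
    return g.astype(np.int8)


def em_frequencies(
    genotypes_window,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed=None,
    missing=None,
) -> HaplotypeTable:
    """Maximum-likelihood window haplotype frequencies by EM.

    ``genotypes_window`` is an (n, m) dosage array (or a GenotypeMatrix
    slice); rows with missing data are dropped.  The observed-data
    log-likelihood is non-decreasing across iterations; convergence is
    max absolute frequency change < ``tol``.  ``seed`` is accepted for
    interface symmetry but unused: the linkage-equilibrium initialization
    is deterministic.
    """
    g = _drop_missing(genotypes_window, missing)
    n, m = g.shape
    if n == 0:
        raise ValueError("no individuals with complete genotypes in window")
    if m > MAX_WINDOW:
        raise ValueError(f"window of {m} SNPs exceeds the {MAX_WINDOW}-SNP enumeration cap")

    patterns, inv = np.unique(g, axis=0, return_inverse=True)
    c = np.bincount(inv, minlength=len(patterns)).astype(float)

    pair_a, pair_b, mult, pat_id = [], [], [], []
    for pi, pat in enumerate(patterns):
        a, b, mlt = _compatible_pairs(tuple(int(x) for x in pat))
        pair_a.append(a)
        pair_b.append(b)
        mult.append(mlt)
        pat_id.append(np.full(len(a), pi))
    A = np.concatenate(pair_a)
    B = np.concatenate(pair_b)
    MULT = np.concatenate(mult)
    PID = np.concatenate(pat_id)
    n_pat = len(patterns)
    n_codes = 1 << m

    # product-of-marginals initialization
    f = g.mean(axis=0) / 2.0
    f = np.clip(f, 1e-12, 1 - 1e-12)
    bits = ((np.arange(n_codes)[:, None] >> np.arange(m)) & 1).astype(float)
    p = np.exp(bits @ np.log(f) + (1 - bits) @ np.log(1 - f))
    p /= p.sum()

    loglik_path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = p[A] * p[B] * MULT
        s = np.bincount(PID, weights=w, minlength=n_pat)
        if np.any(s <= 0):
            bad = np.flatnonzero(s <= 0)
            raise FloatingPointError(f"zero likelihood for genotype pattern(s) {bad}")
        loglik_path.append(float(c @ np.log(s)))
        wn = w / s[PID] * c[PID]
        exp_counts = np.bincount(A, weights=wn, minlength=n_codes)
        exp_counts += np.bincount(B, weights=wn, minlength=n_codes)
        p_new = exp_counts / (2.0 * n)
        delta = np.abs(p_new - p).max()
        p = p_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations (window of {m} SNPs)")

    # final observed-data log-likelihood at the returned frequencies
    w = p[A] * p[B] * MULT
    s = np.bincount(PID, weights=w, minlength=n_pat)
    loglik = float(c @ np.log(np.maximum(s, 1e-300)))
    loglik_path.append(loglik)

    # frequencies within two orders of magnitude of the convergence tolerance
    # are numerical zeros left by the EM's linear approach to the boundary
    keep = p > 100.0 * tol
    haps = unpack_codes(np.flatnonzero(keep), m)
    freqs = p[keep] / p[keep].sum()
    return HaplotypeTable(
        haps,
        counts=freqs * 2.0 * n,
        freqs=freqs,
        loglik=loglik,
        converged=converged,
        n_iter=it,
        n_used=n,
        loglik_path=loglik_path,
    )


@dataclass
class PhasePosterior:
    """Per-individual posterior over compatible (unordered) haplotype pairs.

    Individuals are grouped by genotype pattern; ``pattern_index[i]`` maps
    individual i to its pattern.  ``codes`` lists the haplotype codes with
    non-zero table frequency, aligned with the EM table.
    """

    m: int
    dosage: np.ndarray                   # (n, m) complete genotypes used
    pattern_index: np.ndarray            # (n,)
    patterns: np.ndarray                 # (P, m)
    pair_a: list                         # per pattern: codes of first haplotype
    pair_b: list
    pair_prob: list                      # per pattern: posterior probabilities
    codes: np.ndarray                    # haplotype codes present in the table
    n_warned: int = 0                    # genotypes with zero table probability

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    def pairs_for(self, i: int):
        """List of ((hap_a, hap_b) allele arrays, probability) for individual i."""
        pi = self.pattern_index[i]
        out = []
        for a, b, pr in zip(self.pair_a[pi], self.pair_b[pi], self.pair_prob[pi]):
            out.append(
                ((unpack_codes([a], self.m)[0], unpack_codes([b], self.m)[0]), float(pr))
            )
        return out

    def _pattern_code_dosage(self) -> tuple[np.ndarray, dict]:
        code_ix = {int(cc): k for k, cc in enumerate(self.codes)}
        P = len(self.patterns)
        D = np.zeros((P, len(self.codes)))
        for pi in range(P):
            for a, b, pr in zip(self.pair_a[pi], self.pair_b[pi], self.pair_prob[pi]):
                if int(a) in code_ix:
                    D[pi, code_ix[int(a)]] += pr
                if int(b) in code_ix:
                    D[pi, code_ix[int(b)]] += pr
        return D, code_ix

    def expected_code_dosage(self) -> np.ndarray:
        """(n, h) expected number of copies of each table haplotype per individual."""
        D, _ = self._pattern_code_dosage()
        return D[self.pattern_index]

    def expected_code_counts(self) -> np.ndarray:
        """Expected haplotype counts over the sample (sums to 2n)."""
        D, _ = self._pattern_code_dosage()
        c = np.bincount(self.pattern_index, minlength=len(self.patterns)).astype(float)
        return c @ D

    def expected_product(self, j: int, k: int) -> np.ndarray:
        """ES value of sum over copies of (allele at j) * (allele at k)."""
        bit_j = (self.codes >> j) & 1
        bit_k = (self.codes >> k) & 1
        sel = (bit_j & bit_k).astype(float)
        return self.expected_code_dosage() @ sel

    def expected_category_dosage(self, groups: list[np.ndarray]) -> np.ndarray:
        """ES category dosages; rows over all categories sum to 2 exactly."""
        E = self.expected_code_dosage()
        out = np.zeros((E.shape[0], len(groups)))
        for k, g in enumerate(groups):
            sel = np.isin(self.codes, g)
            out[:, k] = E[:, sel].sum(axis=1)
        return out


def phase_posteriors(genotypes_window, table: HaplotypeTable, missing=None) -> PhasePosterior:
    """P(haplotype pair | genotype) under the table frequencies.

    Probabilities are proportional to p_a * p_b (times 2 for a != b),
    restricted to genotype-compatible pairs and renormalized.  A genotype
    with zero probability under the table falls back to a uniform
    distribution over its compatible pairs, with a warning.
    """
    g = _drop_missing(genotypes_window, missing)
    n, m = g.shape
    p_full = np.zeros(1 << m)
    p_full[table.codes] = table.freqs
    patterns, inv = np.unique(g, axis=0, return_inverse=True)
    pair_a, pair_b, pair_prob = [], [], []
    n_warned = 0
    for pat in patterns:
        a, b, mlt = _compatible_pairs(tuple(int(x) for x in pat))
        w = p_full[a] * p_full[b] * mlt
        s = w.sum()
        if s <= 0:
            n_warned += 1
            w = np.ones_like(w) / len(w)
        else:
            w = w / s
        pair_a.append(a)
        pair_b.append(b)
        pair_prob.append(w)
    if n_warned:
        warnings.warn(
            f"{n_warned} genotype pattern(s) had zero probability under the table; "
            "used uniform posteriors over compatible pairs"
        )
    return PhasePosterior(
        m=m,
        dosage=g,
        pattern_index=inv,
        patterns=patterns,
        pair_a=pair_a,
        pair_b=pair_b,
        pair_prob=pair_prob,
        codes=table.codes,
        n_warned=n_warned,
    )
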