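"""Quality-control battery for case-control genotype data.

Filters mirror standard GWAS practice for multimarker analyses, where a
genotyping artefact at one SNP can fabricate a spurious haplotype:

* per-SNP missingness (> 3 % excluded);
* differential missingness between cases and controls (flag at p < 1e-4),
  since case-biased errors create case-only haplotypes;
* SNP Hardy-Weinberg equilibrium (1-df chi-square, optional exact test);
* haplotype HWE for a window, treating the pooled haplotype categories as
  alleles of one multi-allelic locus (Weir's multi-allele chi-square),
  with EM-expected pair counts standing in for the unobserved true pairs;
* LD pruning by sliding-window variance-inflation factor, removing SNPs
  nearly determined by their neighbours (the same SNPs that would force a
  generalized inverse in the score test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import design, phasing
from .datatypes import GenotypeMatrix


@dataclass
class QCReport:
    snp_ids: list[str]
    missing_rate: np.ndarray
    diff_missing_p: np.ndarray
    hwe_p: np.ndarray
    pruned: np.ndarray                  # True = removed by LD pruning

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "missing_rate": self.missing_rate,
                "diff_missing_p": self.diff_missing_p,
                "hwe_p": self.hwe_p,
                "pruned": self.pruned,
            }
        )


def missingness_filter(gm: GenotypeMatrix, max_rate: float = 0.03) -> np.ndarray:
    """Indices of SNPs with missing fraction <= max_rate (strictly more is excluded)."""
    return np.flatnonzero(gm.missing_rates() <= max_rate)


def differential_missingness(gm: GenotypeMatrix, phenotype) -> np.ndarray:
    """Per-SNP Pearson chi-square p for missing-vs-observed by case status."""
    y = np.asarray(getattr(phenotype, "y", phenotype))
    if y.min() == y.max():
        raise ValueError("both phenotype classes required")
    ps = np.ones(gm.n_snps)
    for j in range(gm.n_snps):
        miss = gm.missing[:, j]
        if miss.sum() == 0:
            continue
        tab = np.array(
            [
                [np.sum(miss & (y == 1)), np.sum(~miss & (y == 1))],
                [np.sum(miss & (y == 0)), np.sum(~miss & (y == 0))],
            ]
        )
        if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
            continue
        ps[j] = stats.chi2_contingency(tab, correction=False)[1]
    return ps


def _hwe_chisq(n_aa: int, n_ab: int, n_bb: int) -> float:
    n = n_aa + n_ab + n_bb
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, 1))


def _hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p-value: sum of heterozygote-count probabilities <= observed."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_a = min(n_a, 2 * n - n_a)
    if n_a == 0:
        return 1.0
    hets = np.arange(n_a % 2, n_a + 1, 2)
    logp = np.zeros(len(hets))
    from scipy.special import gammaln

    for k, h in enumerate(hets):
        na = (n_a - h) // 2
        nb = n - na - h
        logp[k] = (
            h * np.log(2)
            + gammaln(n + 1)
            - gammaln(na + 1)
            - gammaln(h + 1)
            - gammaln(nb + 1)
        )
    logp -= logp.max()
    pr = np.exp(logp)
    pr /= pr.sum()
    obs_h = n_ab if (2 * n_aa + n_ab) <= n else n_ab
    p_obs = pr[np.searchsorted(hets, obs_h)]
    return float(min(1.0, pr[pr <= p_obs * (1 + 1e-12)].sum()))


def snp_hwe(gm: GenotypeMatrix, phenotype=None, mode: str = "chisq", controls_only: bool = False) -> np.ndarray:
    """Per-SNP HWE p-values from genotype counts.

    ``mode``: ``"chisq"`` (1-df goodness of fit) or ``"exact"``.  With
    ``controls_only`` the test uses control individuals only.
    """
    rows = slice(None)
    if controls_only:
        if phenotype is None:
            raise ValueError("controls_only requires a phenotype")
        rows = np.asarray(getattr(phenotype, "y", phenotype)) == 0
    ps = np.ones(gm.n_snps)
    test = _hwe_chisq if mode == "chisq" else _hwe_exact
    for j in range(gm.n_snps):
        d = gm.dosage[rows, j]
        ok = ~gm.missing[rows, j]
        d = d[ok]
        counts = np.bincount(d, minlength=3)
        if counts[1] + counts[2] == 0 or counts[0] + counts[1] == 0:
            continue  # monomorphic
        ps[j] = test(int(counts[2]), int(counts[1]), int(counts[0]))
    return ps


def haplotype_hwe(
    genotypes_window,
    min_count: int = design.DEFAULT_MIN_COUNT,
    pool_expected: float = 5.0,
) -> float:
    """Multi-allele HWE chi-square for a window's haplotype categories.

    The EM-fitted categories (rare pooled) act as alleles of one locus;
    observed pair counts are EM-expected posterior pair counts, expected
    counts are N p_i^2 and 2 N p_i p_j.  Cells with expected count below
    ``pool_expected`` are pooled.  df = h(h-1)/2.
    """
    table = phasing.em_frequencies(genotypes_window)
    post = phasing.phase_posteriors(genotypes_window, table)
    labels, groups, counts = design.haplotype_categories(table, min_count)
    h = len(labels)
    if h < 2:
        return 1.0
    # map each haplotype code to its category
    code_cat = {}
    for k, g in enumerate(groups):
        for cc in g:
            code_cat[int(cc)] = k
    n_ind = post.n_individuals
    obs = np.zeros((h, h))
    pat_counts = np.bincount(post.pattern_index, minlength=len(post.patterns))
    for pi in range(len(post.patterns)):
        for a, b, pr in zip(post.pair_a[pi], post.pair_b[pi], post.pair_prob[pi]):
            ka, kb = code_cat.get(int(a)), code_cat.get(int(b))
            if ka is None or kb is None:
                continue
            i, j = min(ka, kb), max(ka, kb)
            obs[i, j] += pr * pat_counts[pi]
    freqs = counts / counts.sum()
    exp = np.zeros((h, h))
    for i in range(h):
        exp[i, i] = n_ind * freqs[i] ** 2
        for j in range(i + 1, h):
            exp[i, j] = 2 * n_ind * freqs[i] * freqs[j]
    iu = np.triu_indices(h)
    o, e = obs[iu], exp[iu]
    small = e < pool_expected
    if small.any() and (~small).any():
        o = np.append(o[~small], o[small].sum())
        e = np.append(e[~small], e[small].sum())
    chi2 = float((((o - e) ** 2) / np.maximum(e, 1e-12)).sum())
    df = h * (h - 1) // 2
    return float(stats.chi2.sf(chi2, df))


def _window_vifs(X: np.ndarray) -> np.ndarray:
    """VIF of each column regressed on the others (intercept included)."""
    n, k = X.shape
    vifs = np.ones(k)
    for j in range(k):
        y = X[:, j]
        sst = ((y - y.mean()) ** 2).sum()
        if sst <= 0:
            continue  # monomorphic: keep
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        resid = y - others @ np.linalg.lstsq(others, y, rcond=None)[0]
        r2 = 1.0 - (resid**2).sum() / sst
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def ld_prune(
    gm: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    vif_threshold: float = 2.0,
) -> np.ndarray:
    """Retained SNP indices after sliding-window VIF pruning.

    Within each window the SNP with the highest VIF is removed (ties:
    later position) until all VIFs are <= threshold; passes repeat until
    stable, so pruning is idempotent and deterministic.  Missing entries
    are mean-imputed for the regressions only.
    """
    d = np.where(gm.missing, np.nan, gm.dosage).astype(float)
    col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(col_mean, inds[1])

    retained = list(range(gm.n_snps))
    changed = True
    while changed:
        changed = False
        start = 0
        while start < max(len(retained) - 1, 1):
            win = retained[start : start + window]
            if len(win) >= 2:
                while True:
                    vifs = _window_vifs(d[:, win])
                    if np.nanmax(vifs) <= vif_threshold:
                        break
                    worst = len(vifs) - 1 - int(np.argmax(vifs[::-1]))
                    removed = win.pop(worst)
                    retained.remove(removed)
                    changed = True
                    if len(win) < 2:
                        break
            start += step
            if start + window > len(retained) and start >= len(retained):
                break
    return np.asarray(retained, dtype=int)


def run_qc(
    gm: GenotypeMatrix,
    phenotype,
    max_missing: float = 0.03,
    diff_missing_alpha: float = 1e-4,
    prune: bool = True,
    hwe_mode: str = "chisq",
) -> tuple[QCReport, np.ndarray]:
    """Full battery; returns (report, indices of SNPs passing every filter)."""
    miss = gm.missing_rates()
    diff_p = differential_missingness(gm, phenotype)
    hwe_p = snp_hwe(gm, phenotype, mode=hwe_mode)
    keep = (miss <= max_missing) & (diff_p >= diff_missing_alpha)
    pruned = np.zeros(gm.n_snps, dtype=bool)
    if prune:
        idx = np.flatnonzero(keep)
        sub = GenotypeMatrix(
            gm.dosage[:, idx], gm.positions[idx],
            [gm.snp_ids[j] for j in idx], gm.missing[:, idx],
        )
        kept_local = ld_prune(sub)
        removed = np.setdiff1d(np.arange(len(idx)), kept_local)
        pruned[idx[removed]] = True
        keep[idx[removed]] = False
    report = QCReport(list(gm.snp_ids), miss, diff_p, hwe_p, pruned)
    return report, np.flatnonzero(keep)
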