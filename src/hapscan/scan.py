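"""Sliding-window scan driver tying QC, phasing, designs and tests together.

For every window of consecutive post-QC SNPs (default width 6, step 1 —
widths of 5-6 are near-optimal for haplotype testing), the scan EM-phases
the window, builds the expectation-substitution designs and computes the
Rao score test for each requested model, unadjusted and (if covariates
are supplied) covariate-adjusted.  Single-SNP 1-df tests and the window
minimum p are emitted alongside.  A per-run inflation summary reports
lambda-hat per model at that model's modal df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from . import assoc, design, phasing
from .datatypes import GenotypeMatrix, ResultRecord, results_to_frame


@dataclass
class ScanConfig:
    window_size: int = 6
    step: int = 1
    models: tuple = ("main", "main+adj", "haplotype", "single")
    min_hap_count: int = design.DEFAULT_MIN_COUNT
    significance_threshold: float = 1e-4
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 2 <= self.window_size <= phasing.MAX_WINDOW:
            raise ValueError(f"window size must be in [2, {phasing.MAX_WINDOW}]")
        if self.step < 1:
            raise ValueError("step must be >= 1")


def sliding_windows(m: int, size: int = 6, step: int = 1) -> list[np.ndarray]:
    """Consecutive index windows; count = floor((m - size)/step) + 1."""
    if m < size:
        raise ValueError(f"need at least {size} SNPs, got {m}")
    return [np.arange(s, s + size) for s in range(0, m - size + 1, step)]


def _window_models(gm, cols, y, covariates, cfg):
    """Score tests for one window; returns list of (model, TestResult, adj TestResult)."""
    sub = gm.dosage[:, cols]
    miss = gm.missing[:, cols]
    keep = ~miss.any(axis=1)
    if keep.sum() < 2:
        raise ValueError("too few complete individuals in window")
    dose = sub[keep]
    y_w = np.asarray(getattr(y, "y", y))[keep]
    if y_w.min() == y_w.max():
        raise ValueError("window retains a single phenotype class")
    cov_w = None
    if covariates is not None:
        C = getattr(covariates, "values", covariates)
        cov_w = np.asarray(C)[keep]
    table = phasing.em_frequencies(dose)
    post = phasing.phase_posteriors(dose, table)
    null_plain = assoc.fit_null(y_w)
    null_adj = assoc.fit_null(y_w, cov_w) if cov_w is not None else None

    designs = {}
    if "main" in cfg.models:
        designs["main"] = design.build_main_effects(post)
    if "main+adj" in cfg.models:
        designs["main+adj"] = design.build_main_adj(post, cfg.min_hap_count)
    if "haplotype" in cfg.models:
        designs["haplotype"] = design.build_haplotype(post, cfg.min_hap_count)

    out = []
    for mdl, d in designs.items():
        res = assoc.score_test(d, null_plain)
        res_adj = assoc.score_test(d, null_adj) if null_adj is not None else None
        out.append((mdl, res, res_adj))
    return out


def _per_snp_tests(gm, y, covariates):
    """1-df score test per SNP (complete cases per SNP); returns p arrays."""
    y_all = np.asarray(getattr(y, "y", y))
    C = None if covariates is None else np.asarray(getattr(covariates, "values", covariates))
    ps = np.ones(gm.n_snps)
    ps_adj = np.ones(gm.n_snps) if C is not None else None
    for j in range(gm.n_snps):
        keep = ~gm.missing[:, j]
        g = gm.dosage[keep, j].astype(float)[:, None]
        y_j = y_all[keep]
        if y_j.min() == y_j.max() or np.ptp(g) == 0:
            continue
        ps[j] = assoc.score_test(g, assoc.fit_null(y_j), model="single").p
        if C is not None:
            ps_adj[j] = assoc.score_test(g, assoc.fit_null(y_j, C[keep]), model="single").p
    return ps, ps_adj


def run_scan(
    genotypes: GenotypeMatrix,
    phenotype,
    covariates=None,
    cfg: ScanConfig | None = None,
):
    """Scan all windows; returns (records, summary dict).

    Window-level failures are logged and skipped; the summary carries
    skip counts and per-model lambda-hat at the modal df.
    """
    cfg = cfg or ScanConfig()
    windows = sliding_windows(genotypes.n_snps, cfg.window_size, cfg.step)
    records: list[ResultRecord] = []
    stats_by_model: dict[str, list] = {}
    skipped = 0
    snp_ps = snp_ps_adj = None
    if "single" in cfg.models:
        snp_ps, snp_ps_adj = _per_snp_tests(genotypes, phenotype, covariates)
        # lambda for single-SNP tests uses the per-SNP 1-df statistics
        stats_by_model["single"] = [
            (float(_sps.chi2.isf(p, 1)) if p < 1 else 0.0, 1) for p in snp_ps
        ]
    for cols in windows:
        first = int(cols[0])
        try:
            results = _window_models(genotypes, cols, phenotype, covariates, cfg)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"window at SNP {genotypes.snp_ids[first]} skipped: {exc}")
            skipped += 1
            continue
        for mdl, res, res_adj in results:
            records.append(
                ResultRecord(
                    first_snp=genotypes.snp_ids[first],
                    pos=int(genotypes.positions[first]),
                    model=mdl,
                    stat=res.statistic,
                    df=res.df,
                    p=res.p,
                    p_adjusted=None if res_adj is None else res_adj.p,
                )
            )
            stats_by_model.setdefault(mdl, []).append((res.statistic, res.df))
        if snp_ps is not None:
            # window record: minimum single-SNP p over the window's SNPs
            min_p = float(snp_ps[cols].min())
            records.append(
                ResultRecord(
                    first_snp=genotypes.snp_ids[first],
                    pos=int(genotypes.positions[first]),
                    model="single",
                    stat=float(_sps.chi2.isf(min_p, 1)) if min_p < 1 else 0.0,
                    df=1,
                    p=min_p,
                    p_adjusted=None if snp_ps_adj is None else float(snp_ps_adj[cols].min()),
                )
            )
    summary = {"n_windows": len(windows), "skipped": skipped, "lambda": {}}
    for mdl, pairs in stats_by_model.items():
        arr = np.asarray(pairs, dtype=float)
        dfs = arr[:, 1].astype(int)
        ok = dfs > 0
        if not ok.any():
            continue
        modal = int(_sps.mode(dfs[ok], keepdims=False).mode)
        use = ok & (dfs == modal)
        summary["lambda"][mdl] = {
            "lambda": assoc.inflation_lambda(arr[use, 0], modal),
            "df": modal,
            "n_windows": int(use.sum()),
        }
    summary["n_significant"] = {
        mdl: int(sum(1 for r in records if r.model == mdl and r.p < cfg.significance_threshold))
        for mdl in {r.model for r in records}
    }
    return records, summary
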