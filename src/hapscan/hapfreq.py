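"""Log-linear modelling of haplotype frequencies: main vs main+adj codings.

The observed haplotypes of a window are treated as a categorical response
with multinomial log-likelihood sum_i n_i log p_i.  The frequencies are
parameterized log-linearly relative to a reference haplotype,

    log(p_i / p_ref) = x_i' beta,

where x_i holds haplotype i's minor-allele indicators (main coding) and,
for the main+adj coding, additionally the products of adjacent indicator
pairs (only pairs whose rarest 2-SNP haplotype count is >= 10, the same
inclusion rule the association models use).  The main coding is exactly
the independence (product-of-marginals) model; the interactions capture
adjacent LD.  Nested fits are compared with the likelihood-ratio test
(chi^2 with df = number of added interaction parameters) and with the
change in AIC.

The fit is an own Newton iteration on the softmax parameterization (the
likelihood is strictly concave after the design is reduced to a linearly
independent, centred column set), so that thousands of window fits run in
well under a second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import (
    DEFAULT_MIN_COUNT,
    HaplotypeTable,
    inclusion_mask_from_table,
    tabulate_haplotypes,
)


@dataclass
class HapFreqFit:
    coding: str
    beta: np.ndarray
    loglik: float                  # sum n_i log p_i, up to the shared constant
    fitted_freqs: np.ndarray
    n_params: int
    included_pairs: list[int]
    dropped_terms: list[str]
    converged: bool = True

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


def _coding_design(table: HaplotypeTable, coding: str, min_count: int):
    """Centred, independent design on the observed haplotype categories."""
    H = table.haplotypes.astype(float)
    cols, names = [], []
    for j in range(table.m):
        cols.append(H[:, j])
        names.append(f"main:{j}")
    included = []
    if coding == "main+adj":
        mask = inclusion_mask_from_table(table, min_count)
        for j, inc in enumerate(mask):
            if inc:
                cols.append(H[:, j] * H[:, j + 1])
                names.append(f"adj:{j},{j + 1}")
                included.append(j)
    elif coding != "main":
        raise ValueError(f"unknown coding {coding!r}")
    X = np.column_stack(cols) if cols else np.zeros((table.h, 0))
    X = X - X.mean(axis=0)  # softmax is shift-invariant; centring aids conditioning
    # drop non-identifiable (constant or linearly dependent) columns
    dropped = []
    keep = []
    from .assoc import _independent_columns

    if X.shape[1]:
        span = list(_independent_columns(X))
        for k in range(X.shape[1]):
            if k in span:
                keep.append(k)
            else:
                dropped.append(names[k])
    X = X[:, keep]
    names = [names[k] for k in keep]
    return X, names, included, dropped


def fit_hapfreq(
    table: HaplotypeTable, coding: str = "main", min_count: int = DEFAULT_MIN_COUNT
) -> HapFreqFit:
    """Maximize sum n_i log p_i with p = softmax(X beta) over the categories.

    Zero-count haplotypes contribute nothing to the likelihood and are
    excluded from the response.  Deterministic: the likelihood is concave
    on the reduced design and Newton starts from beta = 0.
    """
    obs = table.counts > 0
    sub = HaplotypeTable(table.haplotypes[obs], table.counts[obs])
    if sub.h < 2:
        raise ValueError("need at least two observed haplotype categories")
    X, names, included, dropped = _coding_design(sub, coding, min_count)
    n = sub.counts
    N = n.sum()
    k = X.shape[1]
    beta = np.zeros(k)
    if k == 0:
        p = np.full(sub.h, 1.0 / sub.h)
        return HapFreqFit(coding, beta, float(n @ np.log(p)), p, 0, included, dropped)

    def probs(b):
        eta = X @ b
        eta -= eta.max()
        e = np.exp(eta)
        return e / e.sum()

    def ll(b):
        return float(n @ np.log(np.maximum(probs(b), 1e-300)))

    cur = ll(beta)
    converged = False
    for _ in range(100):
        p = probs(beta)
        grad = X.T @ (n - N * p)
        Xp = X.T @ p
        H = N * ((X * p[:, None]).T @ X - np.outer(Xp, Xp))
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(k), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            new = ll(beta + t * step)
            if new >= cur - 1e-12:
                break
            t /= 2.0
        beta = beta + t * step
        if new < cur - 1e-6:
            break
        gain = new - cur
        cur = new
        if np.abs(grad).max() < 1e-8 * max(N, 1.0) and gain < 1e-12 * max(abs(cur), 1.0):
            converged = True
            break
    if not converged and np.abs(X.T @ (n - N * probs(beta))).max() < 1e-6 * max(N, 1.0):
        converged = True
    if not converged:
        raise RuntimeError(f"haplotype-frequency Newton fit did not converge ({coding})")
    p = probs(beta)
    return HapFreqFit(coding, beta, float(n @ np.log(p)), p, k, included, dropped)


@dataclass
class CodingComparison:
    applicable: bool
    lr: float = np.nan
    df: int = 0
    p: float = np.nan
    delta_aic: float = np.nan      # AIC_main - AIC_main+adj; positive favours interactions
    n_interactions: int = 0


def compare_codings(
    table: HaplotypeTable, min_count: int = DEFAULT_MIN_COUNT
) -> CodingComparison:
    """LR test and AIC change for adding the included adjacent interactions.

    Marker sets where no adjacent pair passes the count rule (or where
    every interaction column is aliased with the main effects) are flagged
    not-applicable and excluded from study denominators.
    """
    fit_main = fit_hapfreq(table, "main", min_count)
    fit_adj = fit_hapfreq(table, "main+adj", min_count)
    df = fit_adj.n_params - fit_main.n_params
    if not fit_adj.included_pairs or df < 1:
        return CodingComparison(applicable=False)
    lr = max(0.0, 2.0 * (fit_adj.loglik - fit_main.loglik))
    p = float(stats.chi2.sf(lr, df))
    delta_aic = lr - 2.0 * df
    return CodingComparison(True, lr, df, p, delta_aic, len(fit_adj.included_pairs))


@dataclass
class HapFreqStudyResult:
    spacing: int
    n_sets: int
    sets_with_interactions: int
    n_significant: int
    n_aic_improved: int
    alpha: float

    @property
    def pct_significant(self) -> float:
        return 100.0 * self.n_significant / max(self.sets_with_interactions, 1)

    @property
    def pct_aic_improved(self) -> float:
        return 100.0 * self.n_aic_improved / max(self.sets_with_interactions, 1)

    def to_row(self) -> dict:
        return {
            "spacing": self.spacing,
            "n_sets": self.n_sets,
            "sets_with_interactions": self.sets_with_interactions,
            "n_significant": self.n_significant,
            "pct_significant": self.pct_significant,
            "n_aic_improved": self.n_aic_improved,
            "pct_aic_improved": self.pct_aic_improved,
        }


def hapfreq_study(
    panel,
    n_sets: int = 1000,
    n_obs: int = 1500,
    window: int = 6,
    spacing: int = 5,
    maf_min: float = 0.05,
    alpha: float = 0.05,
    min_count: int = DEFAULT_MIN_COUNT,
    seed=None,
) -> HapFreqStudyResult:
    """Sample marker sets from a phased panel and score interaction benefit.

    Each set takes ``window`` markers at every ``spacing``-th common
    (MAF >= ``maf_min``) SNP from a random start, samples ``n_obs``
    haplotype rows, and compares the main vs main+adj codings.  Reported:
    how many sets include at least one interaction, and of those how many
    improve significantly at ``alpha`` and how many reduce AIC.
    """
    rng = np.random.default_rng(seed)
    maf = panel.minor_allele_freqs()
    common = np.flatnonzero(maf >= maf_min)
    span = (window - 1) * spacing
    if len(common) <= span:
        raise ValueError(
            f"only {len(common)} common SNPs; need > {span} for spacing {spacing}"
        )
    n_rows = panel.n_haplotypes
    with_int = n_sig = n_aic = 0
    for _ in range(n_sets):
        start = int(rng.integers(0, len(common) - span))
        markers = common[start : start + span + 1 : spacing]
        rows = rng.choice(n_rows, size=n_obs, replace=False)
        table = tabulate_haplotypes(panel.alleles[np.ix_(rows, markers)])
        cmp_res = compare_codings(table, min_count)
        if not cmp_res.applicable:
            continue
        with_int += 1
        if cmp_res.p < alpha:
            n_sig += 1
        if cmp_res.delta_aic > 0:
            n_aic += 1
    return HapFreqStudyResult(spacing, n_sets, with_int, n_sig, n_aic, alpha)
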