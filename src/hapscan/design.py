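"""Design matrices for the three multimarker logistic models, plus LD.

Three codings of a window of m SNPs are supported:

* **main-effects** — intercept plus one minor-allele column per SNP;
* **main+adj** — main effects plus a product term for each *included*
  adjacent SNP pair.  A pair is included only if the rarest of its four
  2-SNP haplotypes has count >= 10 (with fewer observations the extra
  parameter is poorly estimated, and at D' = 1 it is not identifiable);
* **haplotype** — one indicator column per haplotype category, with
  haplotypes seen fewer than 10 times pooled into a single "rare"
  category and the most frequent category used as the reference.

Observation units are either phased haplotype copies (rows carry 0/1) or
individuals.  For individuals with uncertain phase the design entries are
the *expectation-substitution* (ES) values: the expected row under the
phase posterior, so e.g. the adjacent product term is the expected number
of haplotype copies carrying both minor alleles — not the product of the
two dosages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_MIN_COUNT = 10


def pack_codes(alleles: np.ndarray) -> np.ndarray:
    """Encode 0/1 haplotype rows as integers (SNP j on bit j)."""
    m = alleles.shape[-1]
    weights = (1 << np.arange(m)).astype(np.int64)
    return alleles.astype(np.int64) @ weights


def unpack_codes(codes: np.ndarray, m: int) -> np.ndarray:
    codes = np.asarray(codes, dtype=np.int64)
    return ((codes[:, None] >> np.arange(m)) & 1).astype(np.uint8)


# ---------------------------------------------------------------------------
# haplotype tables
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeTable:
    """Distinct window haplotypes with (possibly expected) counts."""

    haplotypes: np.ndarray          # (h, m) uint8, lexicographically sorted
    counts: np.ndarray              # (h,) float; expected counts allowed
    freqs: np.ndarray = None        # (h,), sums to 1
    # populated by the EM routine:
    loglik: float | None = None
    converged: bool | None = None
    n_iter: int | None = None
    n_used: int | None = None
    loglik_path: list | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.atleast_2d(np.asarray(self.haplotypes, dtype=np.uint8))
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < -1e-9):
            raise ValueError("haplotype counts must be non-negative")
        self.counts = np.maximum(self.counts, 0.0)
        order = np.lexsort(self.haplotypes.T[::-1])
        self.haplotypes = self.haplotypes[order]
        self.counts = self.counts[order]
        total = self.counts.sum()
        if self.freqs is None:
            if total <= 0:
                raise ValueError("haplotype table has zero total count")
            self.freqs = self.counts / total
        else:
            self.freqs = np.asarray(self.freqs, dtype=float)[order]
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")

    @property
    def h(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def m(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def codes(self) -> np.ndarray:
        return pack_codes(self.haplotypes)

    def pair_margin(self, j: int) -> np.ndarray:
        """Counts of the four 2-SNP haplotypes at adjacent pair (j, j+1).

        Order: (0,0), (1,0), (0,1), (1,1) on (SNP j, SNP j+1).
        """
        cell = self.haplotypes[:, j].astype(int) + 2 * self.haplotypes[:, j + 1].astype(int)
        return np.bincount(cell, weights=self.counts, minlength=4)


def tabulate_haplotypes(window_data) -> HaplotypeTable:
    """Tabulate distinct haplotypes from a phased slice or phase posteriors.

    Phased 0/1 rows give integer counts; a phase posterior gives expected
    counts (each individual contributes its posterior pair probabilities,
    summing to 2 copies).
    """
    if _is_phased(window_data):
        alleles = _phased_alleles(window_data)
        if alleles.shape[1] < 1 or alleles.shape[0] < 1:
            raise ValueError("empty window")
        codes = pack_codes(alleles)
        counts_full = np.bincount(codes, minlength=1 << alleles.shape[1]).astype(float)
        keep = counts_full > 0
        haps = unpack_codes(np.flatnonzero(keep), alleles.shape[1])
        return HaplotypeTable(haps, counts_full[keep])
    # phase posterior
    post = window_data
    counts = post.expected_code_counts()
    keep = counts > 1e-12
    haps = unpack_codes(post.codes[keep], post.m)
    return HaplotypeTable(haps, counts[keep])


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Labelled observation x term matrix for one model coding."""

    values: np.ndarray
    terms: list[str]
    unit: str                       # "haplotype-copy" | "individual"
    model: str = ""
    categories: list[str] | None = None
    reference: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.terms):
            raise ValueError("terms must label every column")

    def tested(self) -> np.ndarray:
        """Columns excluding the intercept (the tested block)."""
        keep = [k for k, t in enumerate(self.terms) if t != "intercept"]
        return self.values[:, keep]


def _is_phased(window_data) -> bool:
    from .datatypes import HaplotypePanel

    return isinstance(window_data, (np.ndarray, HaplotypePanel))


def _phased_alleles(window_data) -> np.ndarray:
    from .datatypes import HaplotypePanel

    if isinstance(window_data, HaplotypePanel):
        return window_data.alleles
    a = np.asarray(window_data, dtype=np.uint8)
    if a.ndim != 2:
        raise ValueError("phased window data must be 2-D")
    return a


def _main_columns(window_data):
    """(values, unit): allele columns for copies, dosages for individuals."""
    if _is_phased(window_data):
        return _phased_alleles(window_data).astype(float), "haplotype-copy"
    return window_data.dosage.astype(float), "individual"


def build_main_effects(window_data) -> DesignMatrix:
    """Intercept + one minor-allele column per polymorphic SNP."""
    X, unit = _main_columns(window_data)
    n, m = X.shape
    cols, terms = [np.ones(n)], ["intercept"]
    for j in range(m):
        if np.ptp(X[:, j]) == 0:
            warnings.warn(f"dropping monomorphic SNP column {j} from main effects")
            continue
        cols.append(X[:, j])
        terms.append(f"main:{j}")
    return DesignMatrix(np.column_stack(cols), terms, unit, model="main")


def adjacent_inclusion_mask(window_data, min_count: int = DEFAULT_MIN_COUNT) -> np.ndarray:
    """Per adjacent SNP pair: include iff the rarest 2-SNP haplotype count >= min_count.

    Counts are observed counts for phased data and EM-expected counts for
    phase posteriors (the ES analogue of counting observations).
    """
    table = tabulate_haplotypes(window_data)
    return inclusion_mask_from_table(table, min_count)


def inclusion_mask_from_table(table: HaplotypeTable, min_count: int = DEFAULT_MIN_COUNT) -> np.ndarray:
    return np.array(
        [table.pair_margin(j).min() >= min_count for j in range(table.m - 1)], dtype=bool
    )


def build_main_adj(window_data, min_count: int = DEFAULT_MIN_COUNT) -> DesignMatrix:
    """Main effects plus products for included adjacent pairs.

    For individual units the product term is the ES expectation of the sum
    over the two haplotype copies of the within-copy allele product.
    """
    base = build_main_effects(window_data)
    mask = adjacent_inclusion_mask(window_data, min_count)
    cols = [base.values]
    terms = list(base.terms)
    phased = _is_phased(window_data)
    alleles = _phased_alleles(window_data).astype(float) if phased else None
    for j, inc in enumerate(mask):
        if not inc:
            continue
        if phased:
            col = alleles[:, j] * alleles[:, j + 1]
        else:
            col = window_data.expected_product(j, j + 1)
        cols.append(col[:, None])
        terms.append(f"adj:{j},{j + 1}")
    return DesignMatrix(np.hstack(cols), terms, base.unit, model="main+adj")


def haplotype_categories(
    table: HaplotypeTable, min_count: int = DEFAULT_MIN_COUNT
) -> tuple[list[str], list[np.ndarray], np.ndarray]:
    """Pool haplotypes with count < min_count into one 'rare' category.

    Returns (labels, code groups, category counts).  The rare category is
    formed whenever any haplotype falls below the threshold, regardless of
    its pooled total.
    """
    labels, groups, counts = [], [], []
    rare_codes, rare_count = [], 0.0
    codes = table.codes
    for k in range(table.h):
        if table.counts[k] >= min_count:
            labels.append("hap:" + "".join(map(str, table.haplotypes[k])))
            groups.append(np.array([codes[k]]))
            counts.append(table.counts[k])
        else:
            rare_codes.append(codes[k])
            rare_count += table.counts[k]
    if rare_codes:
        labels.append("hap:rare")
        groups.append(np.asarray(rare_codes))
        counts.append(rare_count)
    return labels, groups, np.asarray(counts)


def build_haplotype(
    window_data,
    min_count: int = DEFAULT_MIN_COUNT,
    drop_reference: bool = True,
) -> DesignMatrix:
    """Haplotype-category indicator design with rare pooling.

    The most frequent category (ties broken lexicographically) is the
    reference; with ``drop_reference`` the design holds an intercept plus
    one column per non-reference category, giving df = categories - 1.
    Individual-unit entries are expected category dosages (rows over all
    categories sum to 2 exactly, under any phase uncertainty).
    """
    table = tabulate_haplotypes(window_data)
    labels, groups, counts = haplotype_categories(table, min_count)
    if len(labels) < 2:
        raise ValueError("degenerate haplotype model: fewer than two categories")
    ref = int(np.argmax(counts))  # first occurrence = lexicographically first on ties

    if _is_phased(window_data):
        alleles = _phased_alleles(window_data)
        codes = pack_codes(alleles)
        values = np.column_stack([np.isin(codes, g).astype(float) for g in groups])
        unit = "haplotype-copy"
    else:
        values = window_data.expected_category_dosage(groups)
        unit = "individual"

    keep = [k for k in range(len(labels)) if not (drop_reference and k == ref)]
    cols = [np.ones(values.shape[0])] + [values[:, k] for k in keep]
    terms = ["intercept"] + [labels[k] for k in keep]
    return DesignMatrix(
        np.column_stack(cols),
        terms,
        unit,
        model="haplotype",
        categories=labels,
        reference=labels[ref],
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


@dataclass
class LDStats:
    d_prime: float
    r: float
    r2: float
    defined: bool = True


def pairwise_ld(col_a: np.ndarray, col_b: np.ndarray) -> LDStats:
    """D', r and r^2 from the 2-SNP haplotype frequencies of phased columns."""
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return LDStats(np.nan, np.nan, np.nan, defined=False)
    pab = (a * b).mean()
    d = pab - pa * pb
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = 0.0 if d == 0 else abs(d) / dmax
    r = d / np.sqrt(pa * (1 - pa) * pb * (1 - pb))
    return LDStats(d_prime, r, r * r)


def mean_abs_r(marker_cols: np.ndarray, causal_col: np.ndarray) -> float:
    """Mean |r| between each marker column and the causal column."""
    causal = np.asarray(causal_col, dtype=float)
    if np.ptp(causal) == 0:
        raise ValueError("causal column is monomorphic; |r| undefined")
    vals = []
    for j in range(np.asarray(marker_cols).shape[1]):
        ld = pairwise_ld(np.asarray(marker_cols)[:, j], causal)
        if not ld.defined:
            warnings.warn(f"marker {j} monomorphic; excluded from mean |r|")
            continue
        vals.append(abs(ld.r))
    if not vals:
        raise ValueError("no polymorphic markers for mean |r|")
    return float(np.mean(vals))
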