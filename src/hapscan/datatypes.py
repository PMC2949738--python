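"""Core containers and readers/writers for case-control SNP data.

Conventions used throughout the package:

* Allele coding is *minor-allele* dosage: 1 counts the rarer allele in the
  read sample (ties at frequency 0.5 keep the file's alternate/second
  allele).  Haplotype copies carry 0/1, individuals carry 0/1/2.
* Physical coordinates are 1-based bp, matching VCF.
* Missing genotypes live in an explicit boolean mask (`GenotypeMatrix.missing`),
  never a numeric sentinel, so missing entries can never leak into arithmetic.

Supported formats: VCF (GT field only), a simple SNP-major text dialect
(header ``id pos a1 a2`` then one 0/1/2/NA column per individual), a
row-per-haplotype 0/1 text format, and ms-style ``segsites:``/``positions:``
blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Raised for malformed input records; names the offending line."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePanel:
    """Phased 0/1 allele matrix; one row per haplotype copy."""

    alleles: np.ndarray                 # (n, m) uint8 in {0, 1}
    positions: np.ndarray               # (m,) int, strictly increasing, 1-based bp
    snp_ids: list[str] | None = None
    group: np.ndarray | None = None     # optional per-row population label

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] < 1 or self.alleles.shape[1] < 1:
            raise ValueError("allele matrix must be 2-D with n >= 1, m >= 1")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.shape != (self.alleles.shape[1],):
            raise ValueError("positions length must equal the number of SNPs")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.snp_ids is None:
            self.snp_ids = [f"snp{j}" for j in range(self.alleles.shape[1])]
        if self.group is not None:
            self.group = np.asarray(self.group)
            if self.group.shape != (self.alleles.shape[0],):
                raise ValueError("group labels must have one entry per haplotype row")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Frequency of the coded (1) allele per SNP."""
        return self.alleles.mean(axis=0)

    def minor_allele_freqs(self) -> np.ndarray:
        f = self.allele_freqs()
        return np.minimum(f, 1.0 - f)


@dataclass
class GenotypeMatrix:
    """Per-individual minor-allele dosages with an explicit missingness mask."""

    dosage: np.ndarray                  # (n, m) int8; undefined where missing
    positions: np.ndarray
    snp_ids: list[str] | None = None
    missing: np.ndarray | None = None   # (n, m) bool
    group: np.ndarray | None = None     # optional per-individual label

    def __post_init__(self) -> None:
        self.dosage = np.ascontiguousarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x SNPs)")
        n, m = self.dosage.shape
        if self.missing is None:
            self.missing = np.zeros((n, m), dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != (n, m):
            raise ValueError("missing mask shape must match dosage")
        ok = np.isin(self.dosage, (0, 1, 2)) | self.missing
        if not ok.all():
            raise ValueError("non-missing dosages must be in {0, 1, 2}")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.shape != (m,):
            raise ValueError("positions length must equal the number of SNPs")
        if self.snp_ids is None:
            self.snp_ids = [f"snp{j}" for j in range(m)]
        if self.group is not None:
            self.group = np.asarray(self.group)

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Coded-allele frequency per SNP among non-missing genotypes."""
        d = np.where(self.missing, 0, self.dosage).astype(float)
        n_obs = (~self.missing).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return d.sum(axis=0) / np.maximum(2 * n_obs, 1)

    def missing_rates(self) -> np.ndarray:
        return self.missing.mean(axis=0)


@dataclass
class Phenotype:
    """Binary case (1) / control (0) status per individual."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.y.ndim != 1:
            raise ValueError("phenotype must be a vector")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("phenotype values must be 0/1")

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class CovariateMatrix:
    """Real-valued per-individual covariates, e.g. principal-component scores."""

    values: np.ndarray
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if not np.isfinite(self.values).all():
            raise ValueError("covariates must be finite")
        if self.names is None:
            self.names = [f"cov{j}" for j in range(self.values.shape[1])]


@dataclass
class ResultRecord:
    """One test result for one window/model combination."""

    first_snp: str
    pos: int
    model: str
    stat: float
    df: int
    p: float
    p_adjusted: float | None = None
    chrom: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")
        if self.df < 0:
            raise ValueError("df must be >= 0")


def results_to_frame(records: list[ResultRecord]) -> pd.DataFrame:
    cols = ["chrom", "first_snp", "pos", "model", "stat", "df", "p", "p_adjusted"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


def write_results(records: list[ResultRecord], path) -> None:
    results_to_frame(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------


def _recode_to_minor(dosage: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Flip columns so the coded allele is the minor one (ties keep coding)."""
    d = np.where(missing, 0, dosage).astype(float)
    n_obs = (~missing).sum(axis=0)
    freq = d.sum(axis=0) / np.maximum(2 * n_obs, 1)
    flip = freq > 0.5
    out = dosage.copy()
    out[:, flip] = 2 - out[:, flip]
    out[missing] = 0
    return out


def read_genotypes(path, dialect: str = "vcf") -> GenotypeMatrix:
    """Read unphased genotypes as minor-allele dosages.

    ``dialect`` is ``"vcf"`` (GT field only; non-biallelic sites skipped with a
    warning) or ``"snp-major-text"`` (alias ``"text"``).
    """
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect in ("snp-major-text", "text"):
        return _read_snp_major(path)
    raise ValueError(f"unknown genotype dialect: {dialect!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    rows, miss_rows, positions, ids = [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            warnings.warn(f"skipping non-biallelic site {v.CHROM}:{v.POS}")
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(v.gt_types)
        miss = gt == 2
        dose = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=0)
        rows.append(dose)
        miss_rows.append(miss)
        positions.append(v.POS)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
    if not rows:
        raise ParseError(f"no usable biallelic records in {path}")
    dosage = np.asarray(rows, dtype=np.int8).T
    missing = np.asarray(miss_rows, dtype=bool).T
    dosage = _recode_to_minor(dosage, missing)
    return GenotypeMatrix(dosage, np.asarray(positions), ids, missing)


def _read_snp_major(path) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"empty genotype file: {path}")
    header = lines[0].split()
    if header[:4] != ["id", "pos", "a1", "a2"]:
        raise ParseError(f"{path}:1: expected header 'id pos a1 a2 ...'")
    rows, miss_rows, positions, ids = [], [], [], []
    n_ind = None
    for lineno, ln in enumerate(lines[1:], start=2):
        toks = ln.split()
        if len(toks) < 5:
            raise ParseError(f"{path}:{lineno}: record has no genotype columns")
        snp_id, pos = toks[0], toks[1]
        geno = toks[4:]
        if n_ind is None:
            n_ind = len(geno)
        elif len(geno) != n_ind:
            raise ParseError(f"{path}:{lineno}: expected {n_ind} genotypes, got {len(geno)}")
        dose = np.zeros(len(geno), dtype=np.int8)
        miss = np.zeros(len(geno), dtype=bool)
        for k, g in enumerate(geno):
            if g == "NA":
                miss[k] = True
            elif g in ("0", "1", "2"):
                dose[k] = int(g)
            else:
                raise ParseError(f"{path}:{lineno}: bad genotype {g!r}")
        try:
            positions.append(int(pos))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad position {pos!r}") from exc
        rows.append(dose)
        miss_rows.append(miss)
        ids.append(snp_id)
    dosage = np.asarray(rows, dtype=np.int8).T
    missing = np.asarray(miss_rows, dtype=bool).T
    dosage = _recode_to_minor(dosage, missing)
    return GenotypeMatrix(dosage, np.asarray(positions), ids, missing)


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    """Write the SNP-major text dialect (lossless for minor-coded data)."""
    with open(path, "w") as fh:
        samples = " ".join(f"s{i}" for i in range(gm.n_individuals))
        fh.write(f"id pos a1 a2 {samples}\n")
        for j in range(gm.n_snps):
            cells = [
                "NA" if gm.missing[i, j] else str(int(gm.dosage[i, j]))
                for i in range(gm.n_individuals)
            ]
            fh.write(f"{gm.snp_ids[j]} {gm.positions[j]} A B " + " ".join(cells) + "\n")


# ---------------------------------------------------------------------------
# haplotype I/O
# ---------------------------------------------------------------------------


def read_haplotypes(path, dialect: str = "text", length: float = 1_000_000.0) -> HaplotypePanel:
    """Read phased haplotypes.

    ``dialect``: ``"text"`` (one 0/1 string per row, optional leading
    ``#positions ...`` line) or ``"ms"`` (``segsites:``/``positions:`` block;
    fractional positions are scaled by ``length`` and rounded to bp).
    """
    if dialect == "text":
        return _read_hap_text(path)
    if dialect in ("ms", "ms-style"):
        return _read_ms(path, length)
    raise ValueError(f"unknown haplotype dialect: {dialect!r}")


def _dedupe_increasing(pos: np.ndarray) -> np.ndarray:
    """Bump duplicate integer positions so the sequence is strictly increasing."""
    pos = pos.astype(np.int64).copy()
    for i in range(1, len(pos)):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return pos


def _parse_binary_rows(rows: list[tuple[int, str]], path) -> np.ndarray:
    width = None
    out = []
    for lineno, ln in rows:
        if set(ln) - {"0", "1"}:
            raise ParseError(f"{path}:{lineno}: non-binary character in haplotype row")
        if width is None:
            width = len(ln)
        elif len(ln) != width:
            raise ParseError(f"{path}:{lineno}: ragged haplotype row")
        out.append(np.frombuffer(ln.encode(), dtype=np.uint8) - ord("0"))
    if not out:
        raise ParseError(f"no haplotype rows in {path}")
    return np.asarray(out, dtype=np.uint8)


def _read_hap_text(path) -> HaplotypePanel:
    positions = None
    rows = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#positions"):
                positions = np.asarray([int(t) for t in ln.split()[1:]], dtype=np.int64)
                continue
            rows.append((lineno, ln))
    alleles = _parse_binary_rows(rows, path)
    if positions is None:
        positions = np.arange(1, alleles.shape[1] + 1)
    return HaplotypePanel(alleles, positions)


def _read_ms(path, length: float) -> HaplotypePanel:
    with open(path) as fh:
        lines = fh.readlines()
    segsites = None
    positions = None
    rows = []
    for lineno, ln in enumerate(lines, start=1):
        s = ln.strip()
        if s.startswith("segsites:"):
            segsites = int(s.split()[1])
        elif s.startswith("positions:"):
            positions = np.asarray([float(t) for t in s.split()[1:]])
        elif segsites is not None and positions is not None:
            if not s:
                if rows:
                    break  # first replicate only
                continue
            if s.startswith("//"):
                if rows:
                    break
                continue
            rows.append((lineno, s))
    if segsites is None or positions is None:
        raise ParseError(f"{path}: no segsites/positions block found")
    alleles = _parse_binary_rows(rows, path)
    if alleles.shape[1] != segsites or len(positions) != segsites:
        raise ParseError(f"{path}: segsites does not match row width/positions")
    if positions.max() <= 1.0:
        positions = positions * length
    pos = _dedupe_increasing(np.maximum(np.round(positions).astype(np.int64), 1))
    return HaplotypePanel(alleles, pos)


def write_haplotypes(panel: HaplotypePanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("#positions " + " ".join(str(p) for p in panel.positions) + "\n")
        for row in panel.alleles:
            fh.write("".join("1" if a else "0" for a in row) + "\n")


# ---------------------------------------------------------------------------
# pairing haplotypes into individuals
# ---------------------------------------------------------------------------


def pair_into_individuals(panel: HaplotypePanel, seed=None) -> GenotypeMatrix:
    """Randomly pair haplotype rows within each group into unphased individuals.

    Dosage of each individual is the sum of its two haplotype rows, so
    per-SNP allele counts are conserved exactly.  Deterministic under a
    fixed seed.  Raises if any group has an odd number of rows.
    """
    rng = np.random.default_rng(seed)
    if panel.group is None:
        groups = [(None, np.arange(panel.n_haplotypes))]
    else:
        labels = pd.unique(panel.group)
        groups = [(g, np.flatnonzero(panel.group == g)) for g in labels]
    dosage_rows = []
    ind_groups = []
    for label, idx in groups:
        if len(idx) % 2:
            raise ValueError(f"group {label!r} has an odd number of haplotypes")
        perm = rng.permutation(idx)
        a = panel.alleles[perm[0::2]].astype(np.int8)
        b = panel.alleles[perm[1::2]].astype(np.int8)
        dosage_rows.append(a + b)
        ind_groups.extend([label] * (len(idx) // 2))
    dosage = np.vstack(dosage_rows)
    group = None if panel.group is None else np.asarray(ind_groups)
    return GenotypeMatrix(dosage, panel.positions, list(panel.snp_ids), group=group)
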