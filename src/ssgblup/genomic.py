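"""Genomic relationship algebra for single-step evaluation.

Genotype QC (MAF, call rate, Hardy–Weinberg deviation), the VanRaden genomic
relationship matrix G = M D M' / 2 Σ p_j (1 - p_j), blending/tuning of G
against the pedigree block A22, and assembly of the single-step inverse

    H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1]

restricted to the genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "GenotypeMatrix",
    "QCThresholds",
    "QCReport",
    "qc_filter",
    "build_G",
    "blend_and_tune_G",
    "build_H_inverse",
]


@dataclass
class GenotypeMatrix:
    """Allele dosages (count of the A1 allele) for animals x SNPs.

    ``dosages`` is a float array with values in {0, 1, 2} and ``nan`` for
    missing calls.  Allele frequencies are "current" observed frequencies
    computed from the non-missing calls.
    """

    animal_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = len(self.animal_ids), len(self.snp_ids)
        if self.dosages.shape != (n, m):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{n} animals x {m} SNPs"
            )
        if len(set(self.animal_ids)) != n:
            raise ValueError("duplicate animal ids in genotype matrix")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (nan)")
        self._index = {a: i for i, a in enumerate(self.animal_ids)}

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def allele_freq(self) -> np.ndarray:
        """Frequency of the A1 allele per SNP from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    @property
    def maf(self) -> np.ndarray:
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: j for j, s in enumerate(self.snp_ids)}
        try:
            cols = [index[s] for s in snp_ids]
        except KeyError as exc:
            raise KeyError(f"SNP {exc.args[0]!r} not in genotype matrix") from None
        return GenotypeMatrix(
            animal_ids=list(self.animal_ids),
            snp_ids=[self.snp_ids[j] for j in cols],
            dosages=self.dosages[:, cols],
        )

    def subset_animals(self, animal_ids: Sequence[str]) -> "GenotypeMatrix":
        rows = [self._index[a] for a in animal_ids]
        return GenotypeMatrix(
            animal_ids=list(animal_ids),
            snp_ids=list(self.snp_ids),
            dosages=self.dosages[rows, :],
        )

    def centered(self, p: np.ndarray | None = None) -> np.ndarray:
        """M: dosages mean-imputed to 2p then centered by 2p."""
        if p is None:
            p = self.allele_freq
        X = self.dosages.copy()
        miss = np.isnan(X)
        if miss.any():
            X[miss] = np.broadcast_to(2.0 * p, X.shape)[miss]
        return X - 2.0 * p


@dataclass(frozen=True)
class QCThresholds:
    """Retention rules: MAF > maf_min, call rate > call_rate_min,
    |observed het freq - 2p(1-p)| < hwe_dev_max."""

    maf_min: float = 0.05
    call_rate_min: float = 0.90
    hwe_dev_max: float = 0.15

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_dev_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    n_fail_maf: int
    n_fail_call_rate: int
    n_fail_hwe: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def hwe_deviation(geno: GenotypeMatrix) -> np.ndarray:
    """|observed heterozygote frequency - expected 2p(1-p)| per SNP."""
    p = geno.allele_freq
    het = (geno.dosages == 1.0).sum(axis=0)
    called = (~np.isnan(geno.dosages)).sum(axis=0)
    obs_het = np.divide(
        het, called, out=np.zeros(geno.n_snps), where=called > 0
    )
    return np.abs(obs_het - 2.0 * p * (1.0 - p))


def qc_filter(geno: GenotypeMatrix, marker_map, thr: QCThresholds = QCThresholds()):
    """Drop SNPs failing MAF / call-rate / HWE-deviation criteria.

    Returns (filtered GenotypeMatrix, filtered marker map, QCReport); the
    report counts failures per criterion independently (a SNP may fail
    several).  An empty surviving panel raises with advice to relax
    thresholds.
    """
    fail_maf = geno.maf <= thr.maf_min
    fail_cr = geno.call_rate <= thr.call_rate_min
    fail_hwe = hwe_deviation(geno) >= thr.hwe_dev_max
    keep = ~(fail_maf | fail_cr | fail_hwe)
    report = QCReport(
        n_input=geno.n_snps,
        n_retained=int(keep.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_fail_call_rate=int(fail_cr.sum()),
        n_fail_hwe=int(fail_hwe.sum()),
    )
    if not keep.any():
        raise ValueError(
            "QC removed every SNP; relax maf_min / call_rate_min / hwe_dev_max"
        )
    kept_ids = [s for s, k in zip(geno.snp_ids, keep) if k]
    return geno.subset_snps(kept_ids), marker_map.subset(kept_ids), report


def build_G(
    geno: GenotypeMatrix,
    weights: np.ndarray | None = None,
    p: np.ndarray | None = None,
) -> np.ndarray:
    """VanRaden genomic relationship matrix G = M D M' / 2 Σ p_j(1-p_j).

    M is the dosage matrix centered by twice the allele frequencies (missing
    dosages mean-imputed first); D = diag(weights), identity by default.
    Monomorphic SNPs make the denominator term vanish and must be removed by
    QC beforehand.
    """
    if p is None:
        p = geno.allele_freq
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        j = int(np.argmax((p <= 0.0) | (p >= 1.0)))
        raise ValueError(
            f"monomorphic SNP {geno.snp_ids[j]!r} (p={p[j]:.3f}); run qc_filter first"
        )
    if weights is None:
        weights = np.ones(geno.n_snps)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (geno.n_snps,):
        raise ValueError("weights must be one value per SNP")
    M = geno.centered(p)
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (M * weights) @ M.T / denom
    return 0.5 * (G + G.T)


def blend_and_tune_G(
    G: np.ndarray,
    A22: np.ndarray,
    blend_beta: float = 0.05,
    tune: bool = True,
) -> np.ndarray:
    """Tune G to the scale of A22, then blend: G* = (1-beta) G_tuned + beta A22.

    Tuning solves for a, b in  a + b*G  such that the mean diagonal and mean
    off-diagonal match A22's (the usual compatibility adjustment between
    genomic and pedigree base populations); blending guarantees
    invertibility of G*.
    """
    G = np.asarray(G, dtype=float)
    A22 = np.asarray(A22, dtype=float)
    if G.shape != A22.shape or G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError(f"dimension mismatch: G {G.shape} vs A22 {A22.shape}")
    n = G.shape[0]
    Gt = G
    if tune and n > 1:
        off = ~np.eye(n, dtype=bool)
        gd, go = G.diagonal().mean(), G[off].mean()
        ad, ao = A22.diagonal().mean(), A22[off].mean()
        # [1 gd; 1 go] [a b]' = [ad ao]'
        det = gd - go
        if abs(det) > 1e-12:
            b = (ad - ao) / det
            a = ad - b * gd
            Gt = a + b * G
    return (1.0 - blend_beta) * Gt + blend_beta * A22


def build_H_inverse(
    A_inv: sparse.spmatrix,
    A22_inv: np.ndarray,
    G_inv: np.ndarray,
    genotyped_index: np.ndarray,
) -> sparse.csr_matrix:
    """Single-step H^-1: add (G^-1 - A22^-1) into the genotyped block of A^-1.

    ``genotyped_index`` maps rows of G (and A22) to rows of A; with an empty
    genotyped set, H^-1 = A^-1.
    """
    A_inv = sparse.csr_matrix(A_inv)
    n = A_inv.shape[0]
    genotyped_index = np.asarray(genotyped_index, dtype=np.int64)
    if genotyped_index.size == 0:
        return A_inv.copy()
    if genotyped_index.min() < 0 or genotyped_index.max() >= n:
        raise IndexError("genotyped_index out of range for A^-1")
    q = genotyped_index.size
    G_inv = np.asarray(G_inv, dtype=float)
    A22_inv = np.asarray(A22_inv, dtype=float)
    if G_inv.shape != (q, q) or A22_inv.shape != (q, q):
        raise ValueError("G^-1 / A22^-1 dimensions must match genotyped_index")
    delta = G_inv - A22_inv
    rows = np.repeat(genotyped_index, q)
    cols = np.tile(genotyped_index, q)
    H_inv = A_inv + sparse.coo_matrix(
        (delta.ravel(), (rows, cols)), shape=(n, n)
    ).tocsr()
    return H_inv.tocsr()
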