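"""Linkage disequilibrium, LD decay and effective population size.

Pairwise r² within chromosomes (per-pair EM haplotype-frequency estimation
from unphased genotypes by default, or the composite genotype-correlation
estimator), per-chromosome LD summaries, Sved's decay curve
E[r²] = 1/(1 + 4 Ne d), the closed-form Ne of Saura et al.
(Ne_t = (4 d_t)^-1 [(r²_t - n^-1)^-1 - α], α = 2 by default) and the number
of independent chromosome segments Me = 4 Ne L.

Map distances convert bp -> Morgan at a configurable uniform rate,
1 cM/Mb by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .genomic import GenotypeMatrix
from .io_formats import MarkerMap

__all__ = [
    "LDResult",
    "DecayModel",
    "PopGenSummary",
    "FitError",
    "pairwise_r2",
    "mean_ld_per_chromosome",
    "genome_mean_r2",
    "fit_sved_decay",
    "ne_saura",
    "compute_Me",
    "population_summary",
]

_EM_ITERS = 60


class FitError(RuntimeError):
    """Sved-curve fit failed to converge; carries the best iterate."""

    def __init__(self, message: str, best_ne: float | None = None):
        super().__init__(message)
        self.best_ne = best_ne


@dataclass
class LDResult:
    """Pairwise LD table plus the count of skipped (monomorphic) pairs.

    ``pairs`` columns: snp_a, snp_b, chromosome, dist_bp, d, r2, p_a, p_b.
    """

    pairs: pd.DataFrame
    n_skipped: int = 0


def pairwise_r2(
    geno: GenotypeMatrix,
    marker_map: MarkerMap,
    max_dist_bp: int | None = None,
    within_chromosome: bool = True,
    method: str = "em",
) -> LDResult:
    """r² for all within-chromosome SNP pairs closer than ``max_dist_bp``.

    ``method='em'`` estimates the haplotype frequency P_AB per pair by EM
    from unphased genotypes and returns r² = D²/(P_A P_a P_B P_b) with
    D = P_AB - P_A P_B; ``method='composite'`` squares the Pearson
    correlation of dosages (PLINK's convention).  Pairs containing a
    monomorphic SNP are skipped and counted.
    """
    if not within_chromosome:
        raise NotImplementedError("only within-chromosome LD is supported")
    if method not in ("em", "composite"):
        raise ValueError(f"unknown method {method!r}")
    frames = []
    n_skipped = 0
    order = marker_map.sorted_within_chromosome()
    geno = geno.subset_snps(order.snp_id)
    for chrom in pd.unique(order.chromosome):
        sel = np.flatnonzero(order.chromosome == chrom)
        if len(sel) < 2:
            continue
        pos = order.position_bp[sel]
        X = geno.dosages[:, sel]
        ids = [order.snp_id[j] for j in sel]
        ia, ib = np.triu_indices(len(sel), k=1)
        dist = pos[ib] - pos[ia]
        if max_dist_bp is not None:
            keep = dist <= max_dist_bp
            ia, ib, dist = ia[keep], ib[keep], dist[keep]
        if ia.size == 0:
            continue
        if method == "em":
            d_ld, r2, pa, pb, ok = _em_pairs(X, ia, ib)
        else:
            d_ld, r2, pa, pb, ok = _composite_pairs(X, ia, ib)
        n_skipped += int((~ok).sum())
        frames.append(
            pd.DataFrame(
                {
                    "snp_a": [ids[i] for i in ia[ok]],
                    "snp_b": [ids[j] for j in ib[ok]],
                    "chromosome": chrom,
                    "dist_bp": dist[ok],
                    "d": d_ld[ok],
                    "r2": r2[ok],
                    "p_a": pa[ok],
                    "p_b": pb[ok],
                }
            )
        )
    cols = ["snp_a", "snp_b", "chromosome", "dist_bp", "d", "r2", "p_a", "p_b"]
    pairs = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=cols)
    )
    return LDResult(pairs=pairs, n_skipped=n_skipped)


def _genotype_counts(X: np.ndarray, ia: np.ndarray, ib: np.ndarray):
    """9-cell two-locus genotype counts for the requested pairs.

    Computed with indicator-matrix products so all pairs of a chromosome are
    counted at once; missing dosages drop the animal from that pair only.
    """
    ind = [(~np.isnan(X)) & (X == v) for v in (0.0, 1.0, 2.0)]
    N = {}
    for x in range(3):
        for y in range(3):
            full = ind[x].astype(float).T @ ind[y].astype(float)
            N[x, y] = full[ia, ib]
    return N


def _em_pairs(X, ia, ib):
    N = _genotype_counts(X, ia, ib)
    n_pair = sum(N.values())
    two_n = 2.0 * n_pair
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = (2 * (N[2, 0] + N[2, 1] + N[2, 2]) + (N[1, 0] + N[1, 1] + N[1, 2])) / two_n
        pb = (2 * (N[0, 2] + N[1, 2] + N[2, 2]) + (N[0, 1] + N[1, 1] + N[2, 1])) / two_n
    ok = (n_pair > 0) & (pa > 0) & (pa < 1) & (pb > 0) & (pb < 1)
    nAB = 2 * N[2, 2] + N[2, 1] + N[1, 2]
    nAb = 2 * N[2, 0] + N[2, 1] + N[1, 0]
    naB = 2 * N[0, 2] + N[0, 1] + N[1, 2]
    ndh = N[1, 1]
    pAB = np.where(ok, pa * pb, 0.25)  # start at linkage equilibrium
    for _ in range(_EM_ITERS):
        pAb = pa - pAB
        paB = pb - pAB
        pab = 1.0 - pa - pb + pAB
        num = pAB * pab
        den = num + pAb * paB
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(den > 0, num / den, 0.5)
        with np.errstate(invalid="ignore", divide="ignore"):
            pAB_new = (nAB + ndh * w) / two_n
        pAB_new = np.clip(pAB_new, np.maximum(0.0, pa + pb - 1.0), np.minimum(pa, pb))
        pAB = np.where(ok, pAB_new, pAB)
    d_ld = pAB - pa * pb
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = d_ld**2 / (pa * (1 - pa) * pb * (1 - pb))
    r2 = np.clip(r2, 0.0, 1.0)
    return d_ld, r2, pa, pb, ok


def _composite_pairs(X, ia, ib):
    """Squared Pearson correlation of dosages; D reported as cov/2."""
    ok_mask = ~np.isnan(X)
    Xz = np.where(ok_mask, X, 0.0)
    n = ok_mask.astype(float).T @ ok_mask.astype(float)
    s1 = Xz.T @ ok_mask.astype(float)
    s2 = ok_mask.astype(float).T @ Xz
    s11 = Xz.T @ Xz
    sq = (Xz**2).T @ ok_mask.astype(float)
    sq2 = ok_mask.astype(float).T @ (Xz**2)
    n_p = n[ia, ib]
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = s1[ia, ib] / n_p
        my = s2[ia, ib] / n_p
        cov = s11[ia, ib] / n_p - mx * my
        vx = sq[ia, ib] / n_p - mx**2
        vy = sq2[ia, ib] / n_p - my**2
        r2 = np.where((vx > 0) & (vy > 0), cov**2 / (vx * vy), np.nan)
    ok = (n_p > 1) & (vx > 0) & (vy > 0)
    pa = mx / 2.0
    pb = my / 2.0
    return cov / 2.0, np.clip(r2, 0.0, 1.0), pa, pb, ok


def mean_ld_per_chromosome(ld: LDResult) -> pd.DataFrame:
    """Arithmetic mean r² per chromosome (chromosomes with no pairs absent).

    Columns: chromosome, n_pairs, mean_r2.
    """
    if ld.pairs.empty:
        raise ValueError("empty LD table")
    g = ld.pairs.groupby("chromosome", sort=False)["r2"]
    out = pd.DataFrame(
        {"n_pairs": g.size(), "mean_r2": g.mean()}
    ).reset_index()
    return out


def genome_mean_r2(ld: LDResult, how: str = "chromosome_means") -> float:
    """Genome-wide mean r²: mean of chromosome means (default) or of all pairs."""
    if how == "chromosome_means":
        return float(mean_ld_per_chromosome(ld)["mean_r2"].mean())
    if how == "all_pairs":
        return float(ld.pairs["r2"].mean())
    raise ValueError(f"unknown aggregation {how!r}")


@dataclass
class DecayModel:
    """Fitted Sved curve E[r²] = 1/(1 + 4 Ne d) for one chromosome."""

    ne: float
    chromosome: str
    n_pairs: int
    cm_per_mb: float
    at_boundary: bool = False

    def predict(self, d_morgan: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + 4.0 * self.ne * np.asarray(d_morgan, dtype=float))


def fit_sved_decay(
    ld: LDResult, chromosome, cm_per_mb: float = 1.0
) -> DecayModel:
    """Nonlinear least squares of r² on map distance via Sved's equation."""
    sub = ld.pairs[ld.pairs["chromosome"].astype(str) == str(chromosome)]
    if len(sub) < 20:
        raise ValueError(
            f"chromosome {chromosome}: need >= 20 pairs, have {len(sub)}"
        )
    d = sub["dist_bp"].to_numpy(dtype=float) / 1e6 * cm_per_mb / 100.0
    r2 = sub["r2"].to_numpy(dtype=float)

    def sved(dd, ne):
        return 1.0 / (1.0 + 4.0 * ne * dd)

    r2bar = max(np.mean(r2), 1e-6)
    ne0 = max((1.0 / r2bar - 1.0) / (4.0 * max(np.mean(d), 1e-9)), 1e-6)
    try:
        popt, _ = curve_fit(
            sved, d, r2, p0=[ne0], bounds=(0.0, np.inf), maxfev=10000
        )
    except RuntimeError as exc:
        raise FitError(
            f"Sved fit did not converge on chromosome {chromosome}", best_ne=ne0
        ) from exc
    ne = float(popt[0])
    return DecayModel(
        ne=ne,
        chromosome=str(chromosome),
        n_pairs=len(sub),
        cm_per_mb=cm_per_mb,
        at_boundary=ne < 1e-6,
    )


def ne_saura(mean_r2: float, d_t_morgan: float, n: int, alpha: float = 2.0) -> float:
    """Closed-form effective population size from mean chromosome LD.

    Ne_t = (4 d_t)^-1 [ (r²_t - n^-1)^-1 - α ], where d_t is the average
    chromosome length in Morgan, n the sample-size adjustment count and
    α = 2 in the presence of mutation (1 without).
    """
    if d_t_morgan <= 0:
        raise ValueError("d_t_morgan must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    adj = mean_r2 - 1.0 / n
    if adj <= 0:
        raise ValueError(
            f"mean r² ({mean_r2}) must exceed the sample-size term 1/n ({1.0 / n})"
        )
    return (1.0 / (4.0 * d_t_morgan)) * (1.0 / adj - alpha)


def compute_Me(ne: float, L_morgan: float) -> float:
    """Independent chromosome segments Me = 4 Ne L."""
    if ne <= 0 or L_morgan <= 0:
        raise ValueError("Ne and L must be > 0")
    return 4.0 * ne * L_morgan


@dataclass
class PopGenSummary:
    """Per-chromosome LD/Ne table plus genome-wide aggregates."""

    per_chromosome: pd.DataFrame  # chromosome, n_snps, size_bp, n_pairs, mean_r2, ne
    mean_r2_of_chromosome_means: float
    mean_r2_all_pairs: float
    ne_mean: float
    genome_length_morgan: float
    me: float


def population_summary(
    geno: GenotypeMatrix,
    marker_map: MarkerMap,
    max_dist_bp: int | None = None,
    cm_per_mb: float = 1.0,
    alpha: float = 2.0,
    method: str = "em",
    genome_length_morgan: float | None = None,
) -> PopGenSummary:
    """Table-style LD/Ne summary: per-chromosome mean r² and Saura Ne, the
    genome-wide means, and Me = 4 Ne_mean L.

    d_t for each chromosome is its map extent in Morgan under the uniform
    cM/Mb conversion; n is the number of genotyped animals.
    """
    ld = pairwise_r2(
        geno, marker_map, max_dist_bp=max_dist_bp, method=method
    )
    per = mean_ld_per_chromosome(ld)
    mm = marker_map.sorted_within_chromosome()
    rows = []
    for _, row in per.iterrows():
        chrom = row["chromosome"]
        sel = mm.chromosome == chrom
        size_bp = int(mm.position_bp[sel].max() - mm.position_bp[sel].min())
        d_t = size_bp / 1e6 * cm_per_mb / 100.0
        try:
            ne = ne_saura(row["mean_r2"], d_t, n=geno.n_animals, alpha=alpha)
        except ValueError:
            ne = np.nan
        rows.append(
            {
                "chromosome": chrom,
                "n_snps": int(sel.sum()),
                "size_bp": size_bp,
                "n_pairs": int(row["n_pairs"]),
                "mean_r2": float(row["mean_r2"]),
                "ne": ne,
            }
        )
    per_chrom = pd.DataFrame(rows)
    ne_mean = float(per_chrom["ne"].mean(skipna=True))
    if genome_length_morgan is None:
        genome_length_morgan = float(
            sum(r["size_bp"] for r in rows) / 1e6 * cm_per_mb / 100.0
        )
    me = compute_Me(ne_mean, genome_length_morgan) if ne_mean > 0 else np.nan
    return PopGenSummary(
        per_chromosome=per_chrom,
        mean_r2_of_chromosome_means=genome_mean_r2(ld, "chromosome_means"),
        mean_r2_all_pairs=genome_mean_r2(ld, "all_pairs"),
        ne_mean=ne_mean,
        genome_length_morgan=genome_length_morgan,
        me=me,
    )
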