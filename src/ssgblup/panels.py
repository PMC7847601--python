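"""Reduced-density SNP panels.

Two reduction routes: (a) PLINK-style windowed LD pruning
(``--indep-pairwise window step r2``), and (b) ranking SNPs by the
percentage of additive genetic variance they explain, from a single
back-solve of SNP effects out of genomic breeding values

    u_hat = k D M' G^-1 a_hat_g,   k = 1 / (2 sum p_j (1 - p_j)),

with per-SNP variance share d_j = u_hat_j^2 2 p_j (1 - p_j) expressed as a
percentage of the total.  A sweep re-runs the cross-validation per panel on
the same fold partition and flags panels whose fold predictive abilities
differ from the full panel (paired t-test, p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cv import run_cv
from .evaluation import EvalData, VarianceComponents, run_evaluation
from .genomic import GenotypeMatrix, blend_and_tune_G, build_G
from .io_formats import MarkerMap
from .ldpopgen import _composite_pairs
from .pedigree import build_A22_and_inverse

__all__ = [
    "PanelSubset",
    "SnpVariance",
    "ld_prune_windowed",
    "backsolve_snp_effects",
    "select_by_variance",
    "panel_sweep",
]


@dataclass
class PanelSubset:
    """A named SNP subset of the QC'd panel."""

    tag: str
    snp_ids: list[str]
    criterion_value: float

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def ld_prune_windowed(
    geno: GenotypeMatrix,
    marker_map: MarkerMap,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.5,
) -> PanelSubset:
    """Greedy windowed LD pruning, PLINK ``--indep-pairwise`` style.

    Within each window of ``window`` consecutive SNPs, pairs of surviving
    SNPs with composite r² above ``r2_max`` are resolved by dropping the
    member with the lower MAF (tie: the higher map index); the window then
    advances by ``step`` SNPs.  After pruning, no within-window pair among
    the survivors exceeds ``r2_max``.
    """
    if window < 2:
        raise ValueError("window must span at least 2 SNPs")
    if not 0.0 < r2_max < 1.0:
        raise ValueError("r2_max must be in (0, 1)")
    order = marker_map.sorted_within_chromosome()
    geno_o = geno.subset_snps(order.snp_id)
    maf = geno_o.maf
    X = geno_o.dosages
    keep = np.ones(order.n_snps, dtype=bool)
    for chrom in pd.unique(order.chromosome):
        idx = np.flatnonzero(order.chromosome == chrom)
        start = 0
        while start < len(idx):
            win = idx[start : start + window]
            if len(win) >= 2:
                _prune_window(X, maf, keep, win, r2_max)
            if start + window >= len(idx):
                break
            start += step
    kept_ids = [order.snp_id[j] for j in np.flatnonzero(keep)]
    # restore original map order
    original = [s for s in marker_map.snp_id if s in set(kept_ids)]
    return PanelSubset(tag=f"r2>{r2_max}", snp_ids=original, criterion_value=r2_max)


def _prune_window(X, maf, keep, win, r2_max) -> None:
    """Drop SNPs inside one window until no surviving pair exceeds r2_max."""
    while True:
        live = win[keep[win]]
        if len(live) < 2:
            return
        ia, ib = np.triu_indices(len(live), k=1)
        _, r2, _, _, ok = _composite_pairs(X[:, live], ia, ib)
        r2 = np.where(ok, r2, 0.0)
        over = np.flatnonzero(r2 > r2_max)
        if over.size == 0:
            return
        j = over[0]
        a, b = live[ia[j]], live[ib[j]]
        # drop the lower-MAF member; tie -> the higher index
        drop = b if (maf[b] < maf[a] or maf[a] == maf[b]) else a
        keep[drop] = False


@dataclass
class SnpVariance:
    """Back-solved SNP effects and their additive-variance shares."""

    snp_ids: list[str]
    u_hat: np.ndarray
    d_weight: np.ndarray              # u^2 * 2p(1-p)
    pct_additive_variance: np.ndarray  # sums to 100 (nan when degenerate)
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "u_hat": self.u_hat,
                "d_weight": self.d_weight,
                "pct_additive_variance": self.pct_additive_variance,
            }
        )


def backsolve_snp_effects(
    gebv_genotyped: np.ndarray,
    G: np.ndarray,
    M: np.ndarray,
    allele_freq: np.ndarray,
    weights: np.ndarray | None = None,
    snp_ids: Sequence[str] | None = None,
) -> SnpVariance:
    """One back-solve pass from genotyped-animal GEBV to SNP effects.

    ``G`` must be the (blended, invertible) matrix actually used in the
    evaluation and ``M`` the centered genotype matrix behind it.  An all-zero
    GEBV vector gives zero effects and undefined percentages (flagged).
    """
    a = np.asarray(gebv_genotyped, dtype=float)
    G = np.asarray(G, dtype=float)
    M = np.asarray(M, dtype=float)
    p = np.asarray(allele_freq, dtype=float)
    nq, m = M.shape
    if G.shape != (nq, nq) or a.shape != (nq,) or p.shape != (m,):
        raise ValueError("inconsistent GEBV / G / M / allele_freq dimensions")
    if weights is None:
        weights = np.ones(m)
    k = 1.0 / (2.0 * np.sum(p * (1.0 - p)))
    try:
        Ginv_a = np.linalg.solve(G, a)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "G is singular; blend it with A22 (blend_and_tune_G) first"
        ) from None
    u = k * weights * (M.T @ Ginv_a)
    het = 2.0 * p * (1.0 - p)
    d = u**2 * het
    total = d.sum()
    if total > 0:
        pct = 100.0 * d / total
        degenerate = False
    else:
        pct = np.full(m, np.nan)
        degenerate = True
    ids = list(snp_ids) if snp_ids is not None else [f"snp{j}" for j in range(m)]
    return SnpVariance(
        snp_ids=ids, u_hat=u, d_weight=d, pct_additive_variance=pct,
        degenerate=degenerate,
    )


def select_by_variance(snpvar: SnpVariance, pct_threshold: float) -> PanelSubset:
    """SNPs whose additive-variance share exceeds ``pct_threshold`` percent
    (a non-positive threshold keeps the full panel)."""
    if snpvar.degenerate:
        raise ValueError("variance percentages are undefined (all effects zero)")
    if pct_threshold <= 0:
        ids = list(snpvar.snp_ids)
    else:
        sel = snpvar.pct_additive_variance > pct_threshold
        ids = [s for s, k in zip(snpvar.snp_ids, sel) if k]
    if not ids:
        raise ValueError(
            f"no SNP explains more than {pct_threshold}% of additive variance"
        )
    return PanelSubset(
        tag=f"var>{pct_threshold}%", snp_ids=ids, criterion_value=pct_threshold
    )


def panel_sweep(
    data: EvalData,
    trait: str,
    vc: VarianceComponents,
    thresholds: Sequence[float],
    mode: str = "ld",
    k: int = 5,
    seed: int = 0,
    window: int = 50,
    step: int = 5,
    blend_beta: float = 0.05,
    tune: bool = True,
) -> pd.DataFrame:
    """Cross-validated predictive ability per reduced panel.

    ``mode='ld'`` prunes at each r² threshold; ``mode='variance'`` ranks
    SNPs by back-solved additive-variance share from a full-panel ssGBLUP
    fit of this trait and keeps those above each percentage threshold.
    Every panel is validated on the same fold partition as the full panel;
    the paired t-test across folds flags significant differences.

    Returns one row per panel (full panel first): threshold, n_snps,
    predictive_ability, se, b1, p_vs_full.
    """
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    if mode not in ("ld", "variance"):
        raise ValueError(f"unknown mode {mode!r}")
    if data.genotypes is None or data.marker_map is None:
        raise ValueError("panel sweep needs genotypes and a marker map")

    full = run_cv(
        data, trait, vc, model="ssgblup", panel_tag="full",
        k=k, seed=seed, blend_beta=blend_beta, tune=tune,
    )
    rows = [
        {
            "threshold": np.nan,
            "tag": "full",
            "n_snps": data.genotypes.n_snps,
            "predictive_ability": full.predictive_ability_mean,
            "se": full.predictive_ability_se,
            "b1": full.b1,
            "p_vs_full": np.nan,
        }
    ]
    snpvar = None
    if mode == "variance":
        fit = run_evaluation(data, trait, vc, model="ssgblup")
        geno = data.genotypes
        A22, _ = build_A22_and_inverse(data.pedigree, geno.animal_ids)
        G = blend_and_tune_G(build_G(geno), A22, blend_beta=blend_beta, tune=tune)
        snpvar = backsolve_snp_effects(
            fit.ebv.loc[geno.animal_ids].to_numpy(),
            G,
            geno.centered(),
            geno.allele_freq,
            snp_ids=geno.snp_ids,
        )
    full_pa = full.folds["predictive_ability"].to_numpy()
    for thr in thresholds:
        if mode == "ld":
            subset = ld_prune_windowed(
                data.genotypes, data.marker_map, window=window, step=step,
                r2_max=thr,
            )
        else:
            subset = select_by_variance(snpvar, thr)
        rep = run_cv(
            data, trait, vc, model="ssgblup", panel=subset.snp_ids,
            panel_tag=subset.tag, k=k, seed=seed,
            blend_beta=blend_beta, tune=tune,
        )
        pa = rep.folds["predictive_ability"].to_numpy()
        if np.allclose(pa, full_pa):
            p_val = 1.0
        else:
            p_val = float(stats.ttest_rel(pa, full_pa).pvalue)
        rows.append(
            {
                "threshold": thr,
                "tag": subset.tag,
                "n_snps": subset.n_snps,
                "predictive_ability": rep.predictive_ability_mean,
                "se": rep.predictive_ability_se,
                "b1": rep.b1,
                "p_vs_full": p_val,
            }
        )
    return pd.DataFrame(rows)
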