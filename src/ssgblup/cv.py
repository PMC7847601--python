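"""Five-fold cross-validation: predictive ability and inflation.

Phenotyped (and, when genotypes are present, genotyped) animals are split
into k mutually exclusive folds; each fold's phenotypes are removed in turn,
the model is re-solved with fixed variance components, and the validation
animals' (G)EBV are correlated with their fixed-effect-adjusted phenotypes

    y* = y - X b_hat,    predictive ability = cor(y*, (G)EBV),

with inflation assessed as the slope b1 of y* = b0 + b1 (G)EBV + e
(b1 < 1: inflated, b1 > 1: deflated predictions).  b_hat comes from the
full-data PBLUP fit by default (a flag switches to training-only
adjustment); b1 is reported from the validation pairs pooled across folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .evaluation import (
    EvalData,
    VarianceComponents,
    assemble_mme,
    build_model_spec,
    relationship_inverse,
    solve_mme,
)

__all__ = [
    "CVReport",
    "kfold_split",
    "adjust_phenotypes",
    "predictive_ability",
    "inflation_b1",
    "run_cv",
]


def kfold_split(ids: Sequence[str], k: int = 5, seed: int = 0) -> pd.Series:
    """Deterministic k-fold partition: mutually exclusive, exhaustive folds
    whose sizes differ by at most one."""
    ids = list(ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} available animals")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.empty(len(ids), dtype=np.int64)
    folds[perm] = np.arange(len(ids)) % k
    return pd.Series(folds, index=pd.Index(ids, name="animal_id"), name="fold")


def adjust_phenotypes(y: np.ndarray, X: np.ndarray, b_hat: np.ndarray) -> np.ndarray:
    """y* = y - X b_hat."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    b_hat = np.asarray(b_hat, dtype=float)
    if X.shape != (len(y), len(b_hat)):
        raise ValueError(
            f"dimension mismatch: y {y.shape}, X {X.shape}, b_hat {b_hat.shape}"
        )
    return y - X @ b_hat


def predictive_ability(y_star: np.ndarray, ebv: np.ndarray) -> float:
    """Pearson correlation between adjusted phenotypes and (G)EBV."""
    y_star = np.asarray(y_star, dtype=float)
    ebv = np.asarray(ebv, dtype=float)
    if len(y_star) != len(ebv) or len(y_star) < 3:
        raise ValueError("need >= 3 aligned (y*, EBV) pairs")
    if np.std(y_star) == 0 or np.std(ebv) == 0:
        raise ValueError("zero variance in y* or EBV")
    return float(np.corrcoef(y_star, ebv)[0, 1])


def inflation_b1(y_star: np.ndarray, ebv: np.ndarray) -> tuple[float, float]:
    """OLS intercept b0 and slope b1 of y* on (G)EBV."""
    y_star = np.asarray(y_star, dtype=float)
    ebv = np.asarray(ebv, dtype=float)
    if len(y_star) != len(ebv) or len(y_star) < 3:
        raise ValueError("need >= 3 aligned (y*, EBV) pairs")
    if np.var(ebv) == 0:
        raise ValueError("zero EBV variance; slope undefined")
    b1, b0 = np.polyfit(ebv, y_star, 1)
    return float(b0), float(b1)


@dataclass
class CVReport:
    """Per-fold and aggregate cross-validation results for one run."""

    trait: str
    model_tag: str
    panel_tag: str
    seed: int
    folds: pd.DataFrame          # fold, n_validation, predictive_ability, b1
    predictive_ability_mean: float
    predictive_ability_se: float          # sd over folds / sqrt(k)
    predictive_ability_se_analytic: float  # sqrt((1 - r^2)/(n - 2)), pooled n
    b0: float
    b1: float                    # pooled over validation pairs of all folds
    validation: pd.DataFrame | None = None  # animal_id, repeat, fold, y_star, ebv

    def as_row(self) -> dict:
        return {
            "trait": self.trait,
            "model": self.model_tag,
            "panel": self.panel_tag,
            "predictive_ability": self.predictive_ability_mean,
            "se": self.predictive_ability_se,
            "b1": self.b1,
        }


def run_cv(
    data: EvalData,
    trait: str,
    vc: VarianceComponents,
    model: str = "pblup",
    panel: Sequence[str] | None = None,
    panel_tag: str = "full",
    k: int = 5,
    seed: int = 0,
    repeats: int = 1,
    adjust: str = "full",
    validation_ids: Sequence[str] | None = None,
    blend_beta: float = 0.05,
    tune: bool = True,
    K_inv: sparse.spmatrix | None = None,
) -> CVReport:
    """k-fold cross-validation of one trait x model x panel combination.

    Masked validation phenotypes never enter the training solutions; the
    same ``seed`` gives identical folds across models/panels, which is the
    pairing contract used by the panel sweep.  ``repeats > 1`` re-partitions
    and pools the folds (the stricter reading of "5 replicates").
    """
    if adjust not in ("full", "training"):
        raise ValueError(f"unknown adjustment mode {adjust!r}")
    if K_inv is None:
        K_inv = relationship_inverse(
            data, model=model, panel=panel, blend_beta=blend_beta, tune=tune
        )
    # animals eligible for validation: phenotyped, and genotyped when
    # genomic data are in play (the paper's "genotyped animals with
    # phenotypes"); explicit validation_ids override
    phen_ids = data.phenotypes.phenotyped_ids(trait)
    if validation_ids is None:
        if data.genotypes is not None:
            gset = set(data.genotypes.animal_ids)
            validation_ids = [a for a in phen_ids if a in gset]
        else:
            validation_ids = phen_ids
    validation_ids = [str(a) for a in validation_ids]

    # full-data fit for the fixed-effect adjustment (PBLUP by design)
    full_spec = build_model_spec(data.phenotypes, data.pedigree, trait)
    A_inv = relationship_inverse(data, model="pblup")
    full_fit = solve_mme(assemble_mme(full_spec, vc, A_inv), model_tag="pblup")
    df = data.phenotypes.data
    row_of = {a: i for i, a in enumerate(df["animal_id"])}

    def adjusted_for(ids: list[str], spec, fit) -> np.ndarray:
        rows = [row_of[a] for a in ids]
        yv = df[trait].to_numpy(dtype=float)[rows]
        # rebuild the fit's design on exactly these animals
        Xv = _design_for(df.iloc[rows], fit.fixed_solutions.index)
        return adjust_phenotypes(yv, Xv, fit.fixed_solutions.to_numpy())

    fold_rows = []
    pooled_y, pooled_ebv = [], []
    val_rows = []
    for rep in range(repeats):
        folds = kfold_split(validation_ids, k=k, seed=seed + rep)
        for f in range(k):
            val_ids = folds.index[folds == f].tolist()
            if len(val_ids) < 3:
                raise ValueError(
                    f"fold {f} has only {len(val_ids)} validation animals"
                )
            spec = build_model_spec(
                data.phenotypes, data.pedigree, trait, mask_ids=val_ids
            )
            fit = solve_mme(
                assemble_mme(spec, vc, K_inv), model_tag=model, panel_tag=panel_tag
            )
            if adjust == "training":
                y_star = adjusted_for(val_ids, spec, fit)
            else:
                y_star = adjusted_for(val_ids, full_spec, full_fit)
            ebv_val = fit.ebv.loc[val_ids].to_numpy()
            r = predictive_ability(y_star, ebv_val)
            _, b1_f = inflation_b1(y_star, ebv_val)
            fold_rows.append(
                {
                    "repeat": rep,
                    "fold": f,
                    "n_validation": len(val_ids),
                    "predictive_ability": r,
                    "b1": b1_f,
                }
            )
            pooled_y.append(y_star)
            pooled_ebv.append(ebv_val)
            val_rows.append(
                pd.DataFrame(
                    {
                        "animal_id": val_ids,
                        "repeat": rep,
                        "fold": f,
                        "y_star": y_star,
                        "ebv": ebv_val,
                    }
                )
            )
    folds_df = pd.DataFrame(fold_rows)
    pa = folds_df["predictive_ability"].to_numpy()
    yp = np.concatenate(pooled_y)
    ep = np.concatenate(pooled_ebv)
    b0, b1 = inflation_b1(yp, ep)
    n_val = len(yp)
    r_mean = float(pa.mean())
    se_analytic = float(np.sqrt(max(1.0 - r_mean**2, 0.0) / max(n_val - 2, 1)))
    return CVReport(
        trait=trait,
        model_tag=model,
        panel_tag=panel_tag,
        seed=seed,
        folds=folds_df,
        predictive_ability_mean=r_mean,
        predictive_ability_se=float(pa.std(ddof=1) / np.sqrt(len(pa))),
        predictive_ability_se_analytic=se_analytic,
        b0=b0,
        b1=b1,
        validation=pd.concat(val_rows, ignore_index=True),
    )


def _design_for(sub: pd.DataFrame, x_names) -> np.ndarray:
    """Fixed-effect design rows for given animals, matching fitted columns."""
    X = np.zeros((len(sub), len(x_names)))
    for j, name in enumerate(x_names):
        if name == "intercept":
            X[:, j] = 1.0
        else:
            factor, lev = name.split(":", 1)
            X[:, j] = (sub[factor].astype(str) == lev).to_numpy(dtype=float)
    return X
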