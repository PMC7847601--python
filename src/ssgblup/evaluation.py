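"""Mixed-model engine: Henderson's equations, BLUP solutions and REML.

The animal model is

    y = X b + Z1 a + Z2 c + e

with fixed effects of hatch-year and harvest group (first level of each
factor constrained to zero), additive genetic effect a ~ N(0, sigma2_a K)
where K is A (PBLUP) or H (ssGBLUP), a common-environment (full-sib family
tank) effect c ~ N(0, sigma2_c I) and residual e ~ N(0, sigma2_e I).

Henderson's mixed-model equations in the variance-ratio form:

    [X'X      X'Z1                X'Z2          ] [b]   [X'y ]
    [Z1'X     Z1'Z1 + la K^-1     Z1'Z2         ] [a] = [Z1'y]
    [Z2'X     Z2'Z1               Z2'Z2 + lc I  ] [c]   [Z2'y]

with la = sigma2_e/sigma2_a, lc = sigma2_e/sigma2_c.  Heritability is
h2 = sigma2_a / (sigma2_a + sigma2_c + sigma2_e).

Variance components are estimated by EM-REML (default) or by
average-information REML with exact gradients and EM fallback steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, sparse
from scipy.linalg import cho_factor, cho_solve, get_lapack_funcs
from scipy.sparse.linalg import cg as sparse_cg

from .genomic import GenotypeMatrix, blend_and_tune_G, build_G, build_H_inverse
from .io_formats import MarkerMap, PhenotypeTable
from .pedigree import Pedigree, build_A22_and_inverse, build_A_inverse

__all__ = [
    "VarianceComponents",
    "ModelSpec",
    "MMESystem",
    "EvaluationResult",
    "EvalData",
    "SingularSystemError",
    "REMLError",
    "heritability",
    "build_model_spec",
    "assemble_mme",
    "solve_mme",
    "reml_estimate",
    "relationship_inverse",
    "run_evaluation",
]


class SingularSystemError(np.linalg.LinAlgError):
    pass


class REMLError(RuntimeError):
    def __init__(self, message: str, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory or []


@dataclass
class VarianceComponents:
    """Additive, common-environment and residual variances."""

    sigma2_a: float
    sigma2_c: float
    sigma2_e: float
    se: dict | None = None
    boundary: tuple[str, ...] = ()
    n_iterations: int | None = None

    def __post_init__(self) -> None:
        if self.sigma2_a < 0 or self.sigma2_c < 0 or self.sigma2_e <= 0:
            raise ValueError("variances must be non-negative, sigma2_e > 0")

    @property
    def h2(self) -> float:
        return heritability(self)

    def as_dict(self) -> dict:
        return {
            "sigma2_a": self.sigma2_a,
            "sigma2_c": self.sigma2_c,
            "sigma2_e": self.sigma2_e,
            "h2": self.h2,
        }


def heritability(vc: VarianceComponents) -> float:
    """h2 = sigma2_a / (sigma2_a + sigma2_c + sigma2_e)."""
    total = vc.sigma2_a + vc.sigma2_c + vc.sigma2_e
    if total <= 0:
        raise ValueError("total variance must be > 0")
    return vc.sigma2_a / total


@dataclass
class ModelSpec:
    """Design matrices for one trait, aligned to a pedigree."""

    trait: str
    y: np.ndarray                 # (n,)
    X: np.ndarray                 # (n, p), full column rank
    x_names: list[str]
    animal_index: np.ndarray      # (n,) row of the pedigree per observation
    family_index: np.ndarray | None  # (n,) or None when no c effect
    family_labels: list[str]
    pedigree_ids: list[str]

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_animals(self) -> int:
        return len(self.pedigree_ids)

    @property
    def n_families(self) -> int:
        return len(self.family_labels)

    def Z1(self) -> sparse.csr_matrix:
        n = self.n_obs
        return sparse.csr_matrix(
            (np.ones(n), (np.arange(n), self.animal_index)),
            shape=(n, self.n_animals),
        )

    def Z2(self) -> sparse.csr_matrix | None:
        if self.family_index is None:
            return None
        n = self.n_obs
        return sparse.csr_matrix(
            (np.ones(n), (np.arange(n), self.family_index)),
            shape=(n, self.n_families),
        )


def build_model_spec(
    phenotypes: PhenotypeTable,
    pedigree: Pedigree,
    trait: str,
    use_common_env: bool = True,
    mask_ids: Sequence[str] | None = None,
) -> ModelSpec:
    """Build y, X, Z maps for a trait; ``mask_ids`` phenotypes are excluded
    (the cross-validation device for removing validation records)."""
    df = phenotypes.data
    if trait not in df.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    keep = df[trait].notna()
    if mask_ids is not None:
        keep &= ~df["animal_id"].isin(set(map(str, mask_ids)))
    sub = df.loc[keep].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no phenotyped animals left for trait {trait!r}")
    y = sub[trait].to_numpy(dtype=float)
    # fixed effects: intercept + hatch-year + harvest-group dummies,
    # first level of each factor constrained to zero
    X_parts = [np.ones((len(sub), 1))]
    names = ["intercept"]
    for factor in ("hatch_year", "harvest_group"):
        levels = sorted(sub[factor].astype(str).unique())
        for lev in levels[1:]:
            X_parts.append(
                (sub[factor].astype(str) == lev).to_numpy(dtype=float)[:, None]
            )
            names.append(f"{factor}:{lev}")
    X = np.hstack(X_parts)
    X, names = _drop_collinear_columns(X, names)
    animal_index = pedigree.index_of(sub["animal_id"].tolist())
    family_index = None
    family_labels: list[str] = []
    if use_common_env:
        family_labels = sorted(sub["family"].astype(str).unique())
        fmap = {f: k for k, f in enumerate(family_labels)}
        family_index = sub["family"].astype(str).map(fmap).to_numpy(dtype=np.int64)
    return ModelSpec(
        trait=trait,
        y=y,
        X=X,
        x_names=names,
        animal_index=animal_index,
        family_index=family_index,
        family_labels=family_labels,
        pedigree_ids=list(pedigree.ids),
    )


def _drop_collinear_columns(X: np.ndarray, names: list[str]):
    """QR with column pivoting; dependent columns are constrained out."""
    if X.shape[1] == 0:
        return X, names
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        dropped = [names[j] for j in piv[rank:]]
        warnings.warn(
            f"rank-deficient fixed-effect design; constrained out: {dropped}",
            stacklevel=3,
        )
        keep = sorted(piv[:rank])
        return X[:, keep], [names[j] for j in keep]
    return X, names


@dataclass
class MMESystem:
    """Assembled mixed-model equations (variance-ratio form)."""

    C: sparse.csr_matrix
    rhs: np.ndarray
    spec: ModelSpec
    vc: VarianceComponents
    p: int
    q_a: int
    q_c: int

    @property
    def size(self) -> int:
        return self.C.shape[0]

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return (
            slice(0, self.p),
            slice(self.p, self.p + self.q_a),
            slice(self.p + self.q_a, self.p + self.q_a + self.q_c),
        )


def assemble_mme(
    spec: ModelSpec, vc: VarianceComponents, K_inv: sparse.spmatrix
) -> MMESystem:
    """Henderson blocks with la = sigma2_e/sigma2_a, lc = sigma2_e/sigma2_c.

    K_inv is A^-1 (PBLUP) or H^-1 (ssGBLUP) over all pedigree animals.
    sigma2_c = 0 (or a spec without families) drops the c equations.
    """
    if vc.sigma2_a <= 0:
        raise ValueError("sigma2_a must be > 0 to form the variance ratio")
    K_inv = sparse.csr_matrix(K_inv)
    if K_inv.shape != (spec.n_animals, spec.n_animals):
        raise ValueError(
            f"K_inv shape {K_inv.shape} does not cover the "
            f"{spec.n_animals}-animal pedigree"
        )
    lam_a = vc.sigma2_e / vc.sigma2_a
    X = sparse.csr_matrix(spec.X)
    Z1 = spec.Z1()
    Z2 = spec.Z2()
    use_c = Z2 is not None and vc.sigma2_c > 0
    blocks = [X, Z1] + ([Z2] if use_c else [])
    W = sparse.hstack(blocks, format="csr")
    p, q_a = spec.X.shape[1], spec.n_animals
    q_c = spec.n_families if use_c else 0
    reg = [sparse.csr_matrix((p, p)), lam_a * K_inv]
    if use_c:
        lam_c = vc.sigma2_e / vc.sigma2_c
        reg.append(lam_c * sparse.eye(q_c, format="csr"))
    C = (W.T @ W) + sparse.block_diag(reg, format="csr")
    rhs = W.T @ spec.y
    return MMESystem(C=C.tocsr(), rhs=np.asarray(rhs).ravel(), spec=spec, vc=vc,
                     p=p, q_a=q_a, q_c=q_c)


@dataclass
class EvaluationResult:
    """Solutions of one evaluation run."""

    trait: str
    model_tag: str
    panel_tag: str
    fixed_solutions: pd.Series
    ebv: pd.Series                      # every pedigree animal
    common_env_solutions: pd.Series | None
    relative_residual: float


def solve_mme(
    system: MMESystem,
    method: str = "direct",
    model_tag: str = "pblup",
    panel_tag: str = "full",
    rtol: float = 1e-8,
) -> EvaluationResult:
    """Solve the assembled equations.

    ``direct`` uses a dense Cholesky factorization (the systems here are at
    most a few thousand equations); ``cg`` runs Jacobi-preconditioned
    conjugate gradients to the same relative residual.
    """
    C, rhs = system.C, system.rhs
    if method == "direct":
        Cd = C.toarray()
        try:
            cho = cho_factor(Cd, lower=True, check_finite=False)
            sol = cho_solve(cho, rhs, check_finite=False)
        except np.linalg.LinAlgError:
            diag = Cd.diagonal()
            suspect = [
                system.spec.x_names[j]
                for j in range(system.p)
                if diag[j] <= np.finfo(float).eps * diag.max()
            ]
            raise SingularSystemError(
                "singular mixed-model equations after constraints; "
                f"confounded effects: {suspect or 'non-fixed block'}"
            ) from None
    elif method == "cg":
        Dinv = 1.0 / C.diagonal()
        M = sparse.diags(Dinv)
        sol, info = sparse_cg(C, rhs, rtol=rtol * 1e-2, maxiter=20 * system.size, M=M)
        if info != 0:
            raise SingularSystemError(f"conjugate gradients failed (info={info})")
    else:
        raise ValueError(f"unknown solver {method!r}")
    rel = float(np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))
    sb, sa, sc = system.slices
    spec = system.spec
    fixed = pd.Series(sol[sb], index=spec.x_names, name="fixed")
    ebv = pd.Series(sol[sa], index=pd.Index(spec.pedigree_ids, name="animal_id"))
    cenv = (
        pd.Series(sol[sc], index=spec.family_labels, name="common_env")
        if system.q_c
        else None
    )
    return EvaluationResult(
        trait=spec.trait,
        model_tag=model_tag,
        panel_tag=panel_tag,
        fixed_solutions=fixed,
        ebv=ebv,
        common_env_solutions=cenv,
        relative_residual=rel,
    )


# ----------------------------------------------------------------------
# REML


def _spd_inverse(Cd: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Cholesky solve helper: returns (solution-ready factor, inverse, logdet)."""
    potrf, potri = get_lapack_funcs(("potrf", "potri"), (Cd,))
    L, info = potrf(Cd, lower=1, overwrite_a=False)
    if info != 0:
        raise SingularSystemError("coefficient matrix not positive definite")
    logdet = 2.0 * np.log(np.diag(L)).sum()
    inv, info = potri(L, lower=1)
    if info != 0:
        raise SingularSystemError("inverse of coefficient matrix failed")
    inv = np.tril(inv) + np.tril(inv, -1).T
    return L, inv, logdet


def reml_estimate(
    spec: ModelSpec,
    K_inv: sparse.spmatrix,
    start: VarianceComponents | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    method: str = "em",
) -> VarianceComponents:
    """Estimate (sigma2_a, sigma2_c, sigma2_e) by REML.

    ``method='em'``: expectation-maximisation updates (monotone, robust,
    slow near the optimum).  ``method='ai'``: average-information steps with
    exact first derivatives; any step leaving the parameter space falls back
    to an EM update.  Convergence: max relative parameter change < tol.
    """
    if method not in ("em", "ai"):
        raise ValueError(f"unknown REML method {method!r}")
    K_inv = sparse.csr_matrix(K_inv)
    use_c = spec.family_index is not None and spec.n_families > 1
    y = spec.y
    n, p = spec.n_obs, spec.X.shape[1]
    q_a = spec.n_animals
    q_c = spec.n_families if use_c else 0
    X = sparse.csr_matrix(spec.X)
    blocks = [X, spec.Z1()] + ([spec.Z2()] if use_c else [])
    W = sparse.hstack(blocks, format="csr")
    WtW = (W.T @ W).toarray()
    Wty = np.asarray(W.T @ y).ravel()
    yty = float(y @ y)
    K_dense = K_inv.toarray()

    vy = float(np.var(y, ddof=1))
    if start is None:
        theta = np.array([0.3 * vy, 0.1 * vy if use_c else 0.0, 0.6 * vy])
        if not use_c:
            theta[2] = 0.7 * vy
    else:
        theta = np.array([start.sigma2_a, start.sigma2_c, start.sigma2_e])
    floor = 1e-8 * vy
    theta = np.maximum(theta, [floor, floor if use_c else 0.0, floor])
    a_sl = slice(p, p + q_a)
    c_sl = slice(p + q_a, p + q_a + q_c)
    trajectory = [theta.copy()]

    def iterate(theta):
        sa, sc, se = theta
        C = WtW.copy()
        C[a_sl, a_sl] += (se / sa) * K_dense
        if use_c:
            C[c_sl, c_sl] += (se / sc) * np.eye(q_c)
        L, Cinv, _ = _spd_inverse(C)
        sol = cho_solve((L, True), Wty, check_finite=False)
        a_hat = sol[a_sl]
        aKa = float(a_hat @ (K_inv @ a_hat))
        tr_a = float(np.sum(K_dense * Cinv[a_sl, a_sl]))
        if use_c:
            c_hat = sol[c_sl]
            cc = float(c_hat @ c_hat)
            tr_c = float(np.trace(Cinv[c_sl, c_sl]))
        else:
            c_hat, cc, tr_c = None, 0.0, 0.0
        resid_ss = yty - float(sol @ Wty)
        return sol, Cinv, a_hat, c_hat, aKa, tr_a, cc, tr_c, resid_ss

    converged = False
    for it in range(max_iter):
        sa, sc, se = theta
        sol, Cinv, a_hat, c_hat, aKa, tr_a, cc, tr_c, resid_ss = iterate(theta)
        em = np.array(
            [
                (aKa + tr_a * se) / q_a,
                (cc + tr_c * se) / q_c if use_c else 0.0,
                resid_ss / (n - p),
            ]
        )
        new = em
        if method == "ai":
            ai_step = _ai_step(
                theta, use_c, n, p, q_a, q_c, aKa, tr_a, cc, tr_c,
                sol, Cinv, W, y, se,
            )
            if ai_step is not None:
                cand = theta + ai_step
                t = 1.0
                while t > 1 / 64 and (
                    cand[0] <= 0 or cand[2] <= 0 or (use_c and cand[1] <= 0)
                ):
                    t /= 2.0
                    cand = theta + t * ai_step
                if cand[0] > 0 and cand[2] > 0 and (not use_c or cand[1] > 0):
                    new = cand
        new = np.maximum(new, [floor, floor if use_c else 0.0, floor])
        rel = np.max(np.abs(new - theta) / np.maximum(np.abs(theta), floor))
        theta = new
        trajectory.append(theta.copy())
        if rel < tol:
            converged = True
            break
    if not converged:
        raise REMLError(
            f"REML did not converge in {max_iter} iterations "
            f"(last change {rel:.2e})",
            trajectory=trajectory,
        )
    boundary = tuple(
        name
        for name, v in zip(("sigma2_a", "sigma2_c"), theta[:2])
        if use_c or name == "sigma2_a"
        if v <= 2 * floor
    )
    return VarianceComponents(
        sigma2_a=float(theta[0]),
        sigma2_c=float(theta[1]) if use_c else 0.0,
        sigma2_e=float(theta[2]),
        boundary=boundary,
        n_iterations=it + 1,
    )


def _ai_step(theta, use_c, n, p, q_a, q_c, aKa, tr_a, cc, tr_c, sol, Cinv, W, y, se):
    """Average-information step for (sigma2_a[, sigma2_c], sigma2_e).

    Gradients use the standard MME identities
    tr(P Z1 K Z1') = (q_a - la tr(K^-1 C^aa)) / sigma2_a etc.; the AI matrix
    is 0.5 f_i' P f_j with f_a = Z1 a_hat / sigma2_a, f_c = Z2 c_hat /
    sigma2_c, f_e = P y.
    """
    sa, sc, _ = theta
    la = se / sa
    lc = se / sc if use_c else 0.0
    Py = (y - W @ sol) / se
    tr_PVa = (q_a - la * tr_a) / sa
    yPVaPy = aKa / sa**2
    g = [-0.5 * (tr_PVa - yPVaPy)]
    idx = [0]
    Z1aw = W[:, p : p + q_a] @ sol[p : p + q_a]
    f_list = [np.asarray(Z1aw).ravel() / sa]
    if use_c:
        tr_PVc = (q_c - lc * tr_c) / sc
        yPVcPy = cc / sc**2
        g.append(-0.5 * (tr_PVc - yPVcPy))
        idx.append(1)
        Z2cw = W[:, p + q_a :] @ sol[p + q_a :]
        f_list.append(np.asarray(Z2cw).ravel() / sc)
    tr_P = (n - p - q_a + la * tr_a - (q_c - lc * tr_c if use_c else 0.0)) / se
    yPPy = float(Py @ Py)
    g.append(-0.5 * (tr_P - yPPy))
    idx.append(2)
    f_list.append(Py)
    F = np.column_stack(f_list)
    T = np.asarray(W.T @ F)
    PF = (F - np.asarray(W @ (Cinv @ T))) / se
    AI = 0.5 * (F.T @ PF)
    g = np.array(g)
    try:
        delta_red = np.linalg.solve(AI, g)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(delta_red)):
        return None
    delta = np.zeros(3)
    for k, j in enumerate(idx):
        delta[j] = delta_red[k]
    return delta


# ----------------------------------------------------------------------
# high-level orchestration


@dataclass
class EvalData:
    """Everything one evaluation needs, in memory."""

    pedigree: Pedigree
    phenotypes: PhenotypeTable
    genotypes: GenotypeMatrix | None = None
    marker_map: MarkerMap | None = None


def relationship_inverse(
    data: EvalData,
    model: str = "pblup",
    panel: Sequence[str] | None = None,
    blend_beta: float = 0.05,
    tune: bool = True,
) -> sparse.csr_matrix:
    """A^-1 for PBLUP or the single-step H^-1 for ssGBLUP.

    ``panel`` restricts ssGBLUP to a SNP subset (empty panel or missing
    genotypes degrade to A^-1, i.e. PBLUP).
    """
    A_inv = build_A_inverse(data.pedigree)
    if model == "pblup":
        return A_inv
    if model != "ssgblup":
        raise ValueError(f"unknown model {model!r}")
    geno = data.genotypes
    if geno is None or (panel is not None and len(panel) == 0):
        return A_inv
    if panel is not None:
        geno = geno.subset_snps(list(panel))
    A22, A22_inv = build_A22_and_inverse(data.pedigree, geno.animal_ids)
    G = build_G(geno)
    G_star = blend_and_tune_G(G, A22, blend_beta=blend_beta, tune=tune)
    G_inv = np.linalg.inv(G_star)
    G_inv = 0.5 * (G_inv + G_inv.T)
    idx = data.pedigree.index_of(geno.animal_ids)
    return build_H_inverse(A_inv, A22_inv, G_inv, idx)


def run_evaluation(
    data: EvalData,
    trait: str,
    vc: VarianceComponents,
    model: str = "pblup",
    panel: Sequence[str] | None = None,
    panel_tag: str = "full",
    mask_ids: Sequence[str] | None = None,
    use_common_env: bool = True,
    solver: str = "direct",
    K_inv: sparse.spmatrix | None = None,
) -> EvaluationResult:
    """Assemble and solve one PBLUP/ssGBLUP run (``K_inv`` may be supplied
    to reuse a previously built relationship inverse)."""
    if K_inv is None:
        K_inv = relationship_inverse(data, model=model, panel=panel)
    spec = build_model_spec(
        data.phenotypes, data.pedigree, trait,
        use_common_env=use_common_env, mask_ids=mask_ids,
    )
    system = assemble_mme(spec, vc, K_inv)
    return solve_mme(system, method=solver, model_tag=model, panel_tag=panel_tag)
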