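"""Shared fixtures and independent oracles for the test suite.

The heavier Monte-Carlo experiments (multi-seed genomic-gain comparison,
REML recovery at n = 2000) are session-scoped so several tests can share
one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import ssgblup as sg
from ssgblup.pedigree import Pedigree, build_A


# ----------------------------------------------------------------------
# oracles (kept independent of the implementation paths they check)


def random_pedigree(n: int, seed: int, n_founders: int | None = None) -> Pedigree:
    """Random multi-generation pedigree for relationship-algebra oracles."""
    rng = np.random.default_rng(seed)
    n_founders = n_founders or max(4, n // 5)
    sire = [-1] * n_founders
    dam = [-1] * n_founders
    for i in range(n_founders, n):
        s, d = rng.choice(i, size=2, replace=False)
        sire.append(int(s))
        dam.append(int(d))
    ids = [f"P{i + 1}" for i in range(n)]
    return Pedigree(ids=ids, sire=np.array(sire), dam=np.array(dam))


def gls_solutions(spec, vc, K):
    """Direct generalized-least-squares animal-model solutions via the dense
    phenotypic covariance V = Z1 K Z1' sa + Z2 Z2' sc + I se (textbook BLUE/
    BLUP formulas, no mixed-model equations)."""
    Z1 = spec.Z1().toarray()
    X, y = spec.X, spec.y
    V = vc.sigma2_a * (Z1 @ K @ Z1.T) + vc.sigma2_e * np.eye(len(y))
    Z2 = spec.Z2().toarray() if spec.family_index is not None else None
    if Z2 is not None and vc.sigma2_c > 0:
        V += vc.sigma2_c * (Z2 @ Z2.T)
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = y - X @ b
    a = vc.sigma2_a * (K @ Z1.T @ (Vi @ resid))
    c = (
        vc.sigma2_c * (Z2.T @ (Vi @ resid))
        if Z2 is not None and vc.sigma2_c > 0
        else None
    )
    return b, a, c


def dense_reml_oracle(spec, K, start=(0.3, 0.1, 0.6)):
    """REML variance components by direct maximisation of the restricted
    likelihood with dense V — independent of the MME-based estimator."""
    Z1 = spec.Z1().toarray()
    Z2 = spec.Z2().toarray()
    X, y = spec.X, spec.y
    n = len(y)
    G1 = Z1 @ K @ Z1.T
    G2 = Z2 @ Z2.T

    def negll(logtheta):
        sa, sc, se = np.exp(logtheta)
        V = sa * G1 + sc * G2 + se * np.eye(n)
        sign, ld_V = np.linalg.slogdet(V)
        if sign <= 0:
            return 1e10
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        Py = Vi_y - Vi_X @ beta
        return 0.5 * (ld_V + np.linalg.slogdet(XtViX)[1] + y @ Py)

    res = minimize(
        negll,
        np.log(np.asarray(start) * np.var(y, ddof=1)),
        method="Nelder-Mead",
        options=dict(xatol=1e-9, fatol=1e-11, maxiter=5000),
    )
    return np.exp(res.x)


def direct_H(A: np.ndarray, G: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Textbook single-step H built directly from A and G (not via H^-1):
    the joint pedigree/genomic covariance after conditioning the
    non-genotyped animals on the genotyped block."""
    n = A.shape[0]
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    nidx = np.flatnonzero(~mask)
    A22 = A[np.ix_(idx, idx)]
    A12 = A[np.ix_(nidx, idx)]
    A11 = A[np.ix_(nidx, nidx)]
    A22i = np.linalg.inv(A22)
    H = np.zeros_like(A)
    H[np.ix_(idx, idx)] = G
    H[np.ix_(nidx, idx)] = A12 @ A22i @ G
    H[np.ix_(idx, nidx)] = H[np.ix_(nidx, idx)].T
    H[np.ix_(nidx, nidx)] = A11 + A12 @ A22i @ (G - A22) @ A22i @ A12.T
    return H


# ----------------------------------------------------------------------
# shared data fixtures


@pytest.fixture(scope="session")
def small_sim() -> sg.SimOutput:
    """Desk-scale population reused by read-only tests."""
    return sg.simulate_population(
        sg.SimConfig(
            seed=11,
            n_founders=60,
            families_per_generation=25,
            offspring_per_family=8,
            snps_per_chromosome=12,
        )
    )


@pytest.fixture(scope="session")
def reml_recovery_n2000():
    """AI-REML heritability recovery for both traits at 2000 phenotyped
    animals, shared by the module test and the acceptance suite."""
    sim = sg.simulate_population(
        sg.SimConfig(
            seed=42,
            n_founders=200,
            n_generations=2,
            families_per_generation=100,
            offspring_per_family=10,
            snps_per_chromosome=20,
            n_qtl_per_trait=100,
        )
    )
    data = sg.EvalData(sim.pedigree, sim.phenotypes, sim.genotypes, sim.marker_map)
    A_inv = sg.relationship_inverse(data, model="pblup")
    out = {}
    for trait in ("fillet_yield", "fillet_firmness"):
        spec = sg.build_model_spec(data.phenotypes, data.pedigree, trait)
        out[trait] = sg.reml_estimate(spec, A_inv, method="ai", tol=1e-6)
    return sim, out


@pytest.fixture(scope="session")
def genomic_gain_experiment() -> pd.DataFrame:
    """Ten independent populations (~1450 animals, ~3000 SNPs, h2 = 0.25):
    cross-validated predictive ability of PBLUP vs ssGBLUP (full panel and a
    ~50-SNP thinned panel) plus validation-animal accuracy against true
    breeding values.  Shared by the directional acceptance checks."""
    trait = "fillet_yield"
    vc = sg.VarianceComponents(sigma2_a=0.25, sigma2_c=0.10, sigma2_e=0.65)
    rows = []
    for seed in range(10):
        sim = sg.simulate_population(
            sg.SimConfig(
                seed=100 + seed,
                n_founders=150,
                n_generations=2,
                families_per_generation=65,
                offspring_per_family=10,
                snps_per_chromosome=104,
                n_qtl_per_trait=150,
            )
        )
        data = sg.EvalData(
            sim.pedigree, sim.phenotypes, sim.genotypes, sim.marker_map
        )
        small_panel = sim.marker_map.snp_id[::60]  # ~50 SNPs, evenly spaced
        rep_p = sg.run_cv(data, trait, vc, model="pblup", seed=seed)
        rep_g = sg.run_cv(data, trait, vc, model="ssgblup", seed=seed)
        rep_s = sg.run_cv(
            data, trait, vc, model="ssgblup", panel=small_panel,
            panel_tag="thin50", seed=seed,
        )
        tbv = sim.true_breeding_values[trait]

        def acc(rep):
            v = rep.validation
            return float(np.corrcoef(v["ebv"], tbv.loc[v["animal_id"]].to_numpy())[0, 1])

        rows.append(
            {
                "seed": seed,
                "pa_pblup": rep_p.predictive_ability_mean,
                "pa_ssgblup": rep_g.predictive_ability_mean,
                "pa_thin50": rep_s.predictive_ability_mean,
                "acc_pblup": acc(rep_p),
                "acc_ssgblup": acc(rep_g),
            }
        )
    return pd.DataFrame(rows)
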