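"""Synthetic breeding-population generator.

Emulates the statistical structure the evaluation assumes: a multi-generation
full-sib family pedigree, biallelic SNPs on 29 chromosomes with long-range LD
(founder-haplotype Markov correlation plus a small founder pool), two
polygenic traits with configurable heritability and a common-environment
(family tank) variance, and fixed effects of hatch-year and harvest group.

Founder haplotypes follow a first-order Markov chain along each chromosome so
LD decays with map distance; descendants receive gametes by gene dropping
with recombination between adjacent markers at the Haldane map-function rate
(the exact marker-resolution marginal of a Poisson crossover process with
uniform crossover positions).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .genomic import GenotypeMatrix
from .io_formats import (
    MarkerMap,
    PhenotypeTable,
    RawGenotypes,
    write_pedigree,
    write_phenotypes,
    write_plink_ped_map,
)
from .pedigree import Pedigree, build_A_inverse

__all__ = ["SimConfig", "SimOutput", "simulate_population", "empirical_h2"]

GENOME_LENGTH_MORGAN = 32.3  # trout genome map length used throughout


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic population.

    Defaults give a small desk-scale population; heritabilities default to
    the two fillet traits (0.25 yield, 0.38 firmness) with a 0.10
    common-environment fraction each, on a unit-phenotypic-variance scale.
    """

    n_founders: int = 80
    n_generations: int = 2          # offspring generations after the founders
    families_per_generation: int = 30
    offspring_per_family: int = 8
    n_chromosomes: int = 29
    snps_per_chromosome: int = 24
    chromosome_length_morgan: float = GENOME_LENGTH_MORGAN / 29
    n_qtl_per_trait: int = 50
    h2_per_trait: tuple[float, ...] = (0.25, 0.38)
    c2_per_trait: tuple[float, ...] = (0.10, 0.10)
    genetic_correlation: float = 0.0
    trait_names: tuple[str, ...] = ("fillet_yield", "fillet_firmness")
    phenotyped_generations: tuple[int, ...] | None = None  # default: last two
    genotyped_fraction: float = 1.0
    n_harvest_groups: int = 5
    founder_ld_corr: float = 0.92   # adjacent-marker haplotype copy probability
    fixed_effect_sd: float = 0.3
    tbv_scale: str = "base"         # 'base': t'A^-1 t / n = h2 (what REML sees)
                                    # 'realized': var(TBV | phenotyped) = h2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.h2_per_trait) != len(self.trait_names) or len(
            self.c2_per_trait
        ) != len(self.trait_names):
            raise ValueError("h2/c2 must have one entry per trait")
        for h2, c2 in zip(self.h2_per_trait, self.c2_per_trait):
            if not 0.0 <= h2 < 1.0 or not 0.0 <= c2 < 1.0:
                raise ValueError("h2 and c2 must lie in [0, 1)")
            if h2 + c2 >= 1.0:
                raise ValueError(f"h2 + c2 must be < 1 per trait (got {h2 + c2})")
        if not -1.0 <= self.genetic_correlation <= 1.0:
            raise ValueError("genetic_correlation must be in [-1, 1]")
        if not 0.0 < self.genotyped_fraction <= 1.0:
            raise ValueError("genotyped_fraction must be in (0, 1]")
        if self.tbv_scale not in ("base", "realized"):
            raise ValueError("tbv_scale must be 'base' or 'realized'")
        for name in (
            "n_founders",
            "n_generations",
            "families_per_generation",
            "offspring_per_family",
            "n_chromosomes",
            "snps_per_chromosome",
            "n_harvest_groups",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.families_per_generation > self.n_founders // 2:
            raise ValueError(
                "families_per_generation cannot exceed founders of each sex"
            )

    @property
    def phenotyped_gens(self) -> tuple[int, ...]:
        if self.phenotyped_generations is not None:
            return tuple(self.phenotyped_generations)
        g0 = max(1, self.n_generations - 1)
        return tuple(range(g0, self.n_generations + 1))


@dataclass
class SimOutput:
    """Everything the downstream stages (and their tests) need."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    phenotypes: PhenotypeTable
    true_breeding_values: pd.DataFrame     # index animal_id, one column per trait
    true_qtl: pd.DataFrame                 # trait, snp_id, effect
    fixed_part: pd.DataFrame               # fixed-effect contribution per phenotyped animal
    generation: pd.Series                  # generation number per animal id
    config: SimConfig

    def write(self, outdir) -> dict[str, Path]:
        """Write PED/MAP + pedigree + phenotypes (+ TBV) under ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "ped": out / "genotypes.ped",
            "map": out / "genotypes.map",
            "pedigree": out / "pedigree.csv",
            "phenotypes": out / "phenotypes.csv",
            "tbv": out / "true_breeding_values.tsv",
        }
        fam = dict(
            zip(self.phenotypes.data["animal_id"], self.phenotypes.data["family"])
        )
        recs = []
        ped_index = {a: i for i, a in enumerate(self.pedigree.ids)}
        for i, animal in enumerate(self.genotypes.animal_ids):
            k = ped_index[animal]
            s = self.pedigree.sire[k]
            d = self.pedigree.dam[k]
            calls = []
            for dos in self.genotypes.dosages[i]:
                if np.isnan(dos):
                    calls.append(("0", "0"))
                elif dos == 2:
                    calls.append(("1", "1"))
                elif dos == 1:
                    calls.append(("1", "2"))
                else:
                    calls.append(("2", "2"))
            recs.append(
                RawGenotypes(
                    animal_id=animal,
                    family_id=fam.get(animal, "0"),
                    sire_id=self.pedigree.ids[s] if s >= 0 else "0",
                    dam_id=self.pedigree.ids[d] if d >= 0 else "0",
                    sex="0",
                    phenotype="-9",
                    calls=calls,
                )
            )
        write_plink_ped_map(recs, self.marker_map, paths["ped"], paths["map"])
        write_pedigree(self.pedigree, paths["pedigree"])
        write_phenotypes(self.phenotypes, paths["phenotypes"])
        self.true_breeding_values.to_csv(paths["tbv"], sep="\t")
        return paths


def simulate_population(config: SimConfig) -> SimOutput:
    """Simulate pedigree, genotypes and phenotypes under ``config``."""
    rng = np.random.default_rng(config.seed)
    cfg = config

    # ---------------- pedigree ----------------
    ids: list[str] = []
    sire = []
    dam = []
    sex = []            # 0 male, 1 female
    generation = []
    family = []         # full-sib family label ('' for founders)
    by_generation: list[np.ndarray] = []

    for _ in range(cfg.n_founders):
        ids.append(f"A{len(ids) + 1}")
        sire.append(-1)
        dam.append(-1)
        generation.append(0)
        family.append("")
    sex = list(np.arange(cfg.n_founders) % 2)  # alternating: balanced sexes
    by_generation.append(np.arange(cfg.n_founders))

    for g in range(1, cfg.n_generations + 1):
        prev = by_generation[g - 1]
        males = prev[np.asarray(sex)[prev] == 0]
        females = prev[np.asarray(sex)[prev] == 1]
        nfam = cfg.families_per_generation
        if nfam > min(len(males), len(females)):
            raise ValueError(
                f"generation {g}: need {nfam} sires and dams, have "
                f"{len(males)} males / {len(females)} females"
            )
        chosen_s = rng.choice(males, size=nfam, replace=False)
        chosen_d = rng.choice(females, size=nfam, replace=False)
        gen_idx = []
        for f in range(nfam):
            lab = f"FAM{g}_{f + 1}"
            for _ in range(cfg.offspring_per_family):
                idx = len(ids)
                ids.append(f"A{idx + 1}")
                sire.append(int(chosen_s[f]))
                dam.append(int(chosen_d[f]))
                generation.append(g)
                family.append(lab)
                sex.append(int(rng.integers(0, 2)))
                gen_idx.append(idx)
        by_generation.append(np.array(gen_idx))

    n_animals = len(ids)
    sire = np.array(sire)
    dam = np.array(dam)
    generation = np.array(generation)
    year_class = np.array([f"YC{2002 + 2 * g}" for g in generation], dtype=object)
    ped = Pedigree(ids=list(ids), sire=sire, dam=dam, year_class=year_class)

    # ---------------- marker map ----------------
    m_per = cfg.snps_per_chromosome
    chrom_len_bp = int(round(cfg.chromosome_length_morgan * 100 * 1e6))  # 1 cM/Mb
    snp_id: list[str] = []
    chrom_col: list[str] = []
    pos_col: list[int] = []
    for c in range(1, cfg.n_chromosomes + 1):
        pos = np.linspace(1, chrom_len_bp, m_per).round().astype(np.int64)
        pos = np.maximum.accumulate(pos + np.arange(m_per))  # break any ties
        snp_id += [f"C{c}S{k + 1}" for k in range(m_per)]
        chrom_col += [str(c)] * m_per
        pos_col += pos.tolist()
    mmap = MarkerMap(
        snp_id=snp_id, chromosome=np.array(chrom_col), position_bp=np.array(pos_col)
    )
    m_total = mmap.n_snps

    # ---------------- haplotypes: founders + gene dropping ----------------
    dosages = np.zeros((n_animals, m_total), dtype=np.int8)
    founders = by_generation[0]
    for c in range(cfg.n_chromosomes):
        cols = slice(c * m_per, (c + 1) * m_per)
        pos_morgan = mmap.position_bp[cols] / 1e6 / 100.0  # 1 cM/Mb
        rec_rate = 0.5 * (1.0 - np.exp(-2.0 * np.diff(pos_morgan)))

        H = np.zeros((n_animals, 2, m_per), dtype=np.int8)
        p_founder = rng.uniform(0.1, 0.9, size=m_per)
        nh = 2 * len(founders)
        fh = np.zeros((nh, m_per), dtype=np.int8)
        fh[:, 0] = rng.random(nh) < p_founder[0]
        for j in range(1, m_per):
            copy = rng.random(nh) < cfg.founder_ld_corr
            fresh = rng.random(nh) < p_founder[j]
            fh[:, j] = np.where(copy, fh[:, j - 1], fresh)
        H[founders] = fh.reshape(len(founders), 2, m_per)

        for g in range(1, cfg.n_generations + 1):
            off = by_generation[g]
            for slot, parent_idx in ((0, sire[off]), (1, dam[off])):
                ph = H[parent_idx]  # (k, 2, m)
                k = len(off)
                switch = rng.random((k, m_per - 1)) < rec_rate
                start = rng.integers(0, 2, size=k)
                src = (start[:, None] + np.concatenate(
                    [np.zeros((k, 1), dtype=np.int64),
                     np.cumsum(switch, axis=1)], axis=1)) % 2
                H[off, slot] = ph[np.arange(k)[:, None], src, np.arange(m_per)]
        dosages[:, cols] = H.sum(axis=1)

    # ---------------- QTL effects and true breeding values ----------------
    n_traits = len(cfg.trait_names)
    tbv = np.zeros((n_animals, n_traits))
    qtl_rows = []
    if cfg.n_qtl_per_trait > 0:
        n_qtl = min(cfg.n_qtl_per_trait, m_total)
        shared = cfg.genetic_correlation != 0.0
        qtl_idx_shared = rng.choice(m_total, size=n_qtl, replace=False)
        if shared:
            rho = cfg.genetic_correlation
            cov = np.array([[1.0, rho], [rho, 1.0]])
            eff = rng.multivariate_normal(np.zeros(2), cov, size=n_qtl)
        for t, trait in enumerate(cfg.trait_names):
            if shared:
                qtl_idx = qtl_idx_shared
                effects = eff[:, min(t, 1)]
            else:
                qtl_idx = rng.choice(m_total, size=n_qtl, replace=False)
                effects = rng.normal(size=n_qtl)
            raw = dosages[:, qtl_idx].astype(float) @ effects
            tbv[:, t] = raw
            for j, e in zip(qtl_idx, effects):
                qtl_rows.append((trait, mmap.snp_id[j], float(e)))
    true_qtl = pd.DataFrame(qtl_rows, columns=["trait", "snp_id", "effect"])

    # ---------------- phenotypes ----------------
    pheno_gens = cfg.phenotyped_gens
    pheno_mask = np.isin(generation, pheno_gens)
    pheno_idx = np.flatnonzero(pheno_mask)
    fam_labels = sorted({family[i] for i in pheno_idx if family[i]})
    fam_of = {lab: k for k, lab in enumerate(fam_labels)}

    harvest = rng.integers(1, cfg.n_harvest_groups + 1, size=len(pheno_idx))
    A_inv = build_A_inverse(ped) if cfg.n_qtl_per_trait > 0 else None
    trait_cols: dict[str, np.ndarray] = {}
    fixed_cols: dict[str, np.ndarray] = {}
    for t, trait in enumerate(cfg.trait_names):
        h2, c2 = cfg.h2_per_trait[t], cfg.c2_per_trait[t]
        # calibrate the additive variance to h2 on the unit-total scale:
        # 'base' uses the pedigree quadratic form t'A^-1 t / n (the base-
        # population variance a REML animal model estimates); 'realized'
        # uses the sample variance among phenotyped animals
        if cfg.tbv_scale == "base" and A_inv is not None:
            v = float(tbv[:, t] @ (A_inv @ tbv[:, t])) / n_animals
        else:
            v = tbv[pheno_idx, t].var(ddof=1) if len(pheno_idx) > 1 else 0.0
        if v > 0 and h2 > 0:
            tbv[:, t] *= np.sqrt(h2 / v)
            tbv[:, t] -= tbv[pheno_idx, t].mean()
        else:
            tbv[:, t] = 0.0
            h2 = 0.0
        hy_eff = {g: rng.normal(0.0, cfg.fixed_effect_sd) for g in pheno_gens}
        hg_eff = rng.normal(0.0, cfg.fixed_effect_sd, size=cfg.n_harvest_groups)
        fam_dev = rng.normal(0.0, np.sqrt(c2), size=len(fam_labels)) if c2 > 0 else (
            np.zeros(len(fam_labels))
        )
        resid_sd = np.sqrt(max(1.0 - h2 - c2, 1e-12))
        e = rng.normal(0.0, resid_sd, size=len(pheno_idx))
        fixed = np.array(
            [hy_eff[generation[i]] for i in pheno_idx]
        ) + hg_eff[harvest - 1]
        y = fixed + tbv[pheno_idx, t] + np.array(
            [fam_dev[fam_of[family[i]]] for i in pheno_idx]
        ) + e
        trait_cols[trait] = y
        fixed_cols[trait] = fixed

    pheno_animals = [ids[i] for i in pheno_idx]
    pheno_df = pd.DataFrame({"animal_id": pheno_animals})
    for trait in cfg.trait_names:
        pheno_df[trait] = trait_cols[trait]
    pheno_df["hatch_year"] = [year_class[i] for i in pheno_idx]
    pheno_df["harvest_group"] = [f"HG{h}" for h in harvest]
    pheno_df["family"] = [family[i] for i in pheno_idx]
    phenotypes = PhenotypeTable(data=pheno_df)
    fixed_part = pd.DataFrame(fixed_cols, index=pd.Index(pheno_animals, name="animal_id"))

    # ---------------- genotyped set ----------------
    if cfg.genotyped_fraction < 1.0:
        keep = rng.random(len(pheno_idx)) < cfg.genotyped_fraction
        core = pheno_idx[keep]
        if core.size == 0:
            core = pheno_idx[:1]
    else:
        core = pheno_idx
    parents = np.unique(np.concatenate([sire[core], dam[core]]))
    parents = parents[parents >= 0]
    genotyped = np.unique(np.concatenate([core, parents]))
    genotyped.sort()
    geno = GenotypeMatrix(
        animal_ids=[ids[i] for i in genotyped],
        snp_ids=list(mmap.snp_id),
        dosages=dosages[genotyped].astype(float),
    )

    tbv_df = pd.DataFrame(
        tbv, index=pd.Index(ids, name="animal_id"), columns=list(cfg.trait_names)
    )
    return SimOutput(
        pedigree=ped,
        genotypes=geno,
        marker_map=mmap,
        phenotypes=phenotypes,
        true_breeding_values=tbv_df,
        true_qtl=true_qtl,
        fixed_part=fixed_part,
        generation=pd.Series(generation, index=ids),
        config=cfg,
    )


def empirical_h2(sim: SimOutput, trait: str) -> float:
    """Realized narrow-sense heritability: var(TBV) / var(y - fixed effects)
    among phenotyped animals."""
    df = sim.phenotypes.data
    if len(df) < 100:
        raise ValueError("need >= 100 phenotyped animals for a stable estimate")
    y = df[trait].to_numpy(dtype=float)
    fixed = sim.fixed_part[trait].to_numpy()
    adj = y - fixed
    v_p = adj.var(ddof=1)
    if v_p <= 0:
        raise ValueError("zero phenotypic variance")
    tbv = sim.true_breeding_values.loc[df["animal_id"], trait].to_numpy()
    return float(tbv.var(ddof=1) / v_p)
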