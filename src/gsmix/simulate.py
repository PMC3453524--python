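"""Synthetic heterogeneous-stock-style mouse populations.

The generator mirrors the structure the downstream models assume: a cross of
a handful of inbred founder strains, many generations of random mating to
build up linkage disequilibrium, then a recorded three-generation pedigree
(grandparents, parents, one generation of phenotyped full-sib offspring)
with cages nested inside families and a trait combining marker-linked QTL
effects, a pedigree polygenic term, cage effects, fixed effects and noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .data_model import (
    GenotypePanel,
    MarkerMap,
    Pedigree,
    PhenotypeTable,
    encode_design,
)


@dataclass
class SimulationConfig:
    """Knobs of the population generator.

    Variance fractions (``h2_qtl``, ``h2_polygenic``, ``cage_fraction``)
    are proportions of the total phenotypic variance ``sigma2_p`` and must
    sum to less than 1; the residual takes the remainder.
    """

    n_founder_strains: int = 8
    n_burnin_generations: int = 50
    burnin_population: int = 200  # diploid breeders per burn-in generation
    n_families: int = 175
    mean_offspring: float = 11.0  # Poisson mean, truncated below at 2
    fixed_family_size: int | None = None
    cages_per_family_mean: float = 3.1
    n_markers: int = 400
    n_chromosomes: int = 5
    chromosome_length_bp: int = 100_000_000
    recomb_rate_cM_per_Mb: float = 0.5
    n_qtl: int = 20
    qtl_effect_distribution: str = "reflected-gamma"  # or "normal"
    h2_qtl: float = 0.3
    h2_polygenic: float = 0.2
    cage_fraction: float = 0.2
    sigma2_p: float = 100.0
    sex_effect: float = 2.0
    covariate_slope: float = 1.0
    seed: int = 0

    def __post_init__(self):
        fracs = (self.h2_qtl, self.h2_polygenic, self.cage_fraction)
        if any(f < 0 for f in fracs) or sum(fracs) >= 1.0:
            raise ValueError("variance fractions must be >= 0 and sum below 1")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")

    @property
    def sigma2_qtl(self) -> float:
        return self.h2_qtl * self.sigma2_p

    @property
    def sigma2_u(self) -> float:
        return self.h2_polygenic * self.sigma2_p

    @property
    def sigma2_c(self) -> float:
        return self.cage_fraction * self.sigma2_p

    @property
    def sigma2_e(self) -> float:
        return (1.0 - self.h2_qtl - self.h2_polygenic - self.cage_fraction) * self.sigma2_p


@dataclass
class TruePopulation:
    """Simulated data plus the ground truth behind it."""

    pedigree: Pedigree
    panel: GenotypePanel
    phenotypes: PhenotypeTable
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray  # per-marker effect on the dosage scale (0 off QTLs)
    breeding_values: pd.Series  # genomic + polygenic, per phenotyped animal
    genomic_values: pd.Series
    polygenic_values: pd.Series
    variance_components: dict[str, float]


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


def simulate_pedigree(config: SimulationConfig, seed: int) -> Pedigree:
    """Three recorded generations: each family has its own parent pair and
    each parent its own grandparent pair, so families are unrelated in the
    recorded pedigree (relatedness beyond that lives in the genotypes)."""
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str | None, str | None]] = []
    for f in range(config.n_families):
        for role in ("s", "d"):
            records.append((f"GP{f}{role}1", None, None))
            records.append((f"GP{f}{role}2", None, None))
        records.append((f"P{f}s", f"GP{f}s1", f"GP{f}s2"))
        records.append((f"P{f}d", f"GP{f}d1", f"GP{f}d2"))
        if config.fixed_family_size is not None:
            size = config.fixed_family_size
        else:
            size = max(2, int(rng.poisson(config.mean_offspring)))
        for k in range(size):
            records.append((f"F{f}O{k}", f"P{f}s", f"P{f}d"))
    return Pedigree.from_records(records)


def offspring_ids(pedigree: Pedigree) -> list[str]:
    """Animals of the phenotyped generation (both parents recorded)."""
    return [
        a
        for i, a in enumerate(pedigree.ids)
        if pedigree.sire[i] >= 0 and pedigree.dam[i] >= 0 and a.startswith("F")
    ]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _marker_layout(config: SimulationConfig, rng) -> MarkerMap:
    per = np.full(config.n_chromosomes, config.n_markers // config.n_chromosomes)
    per[: config.n_markers % config.n_chromosomes] += 1
    ids, chrom, pos = [], [], []
    for c in range(config.n_chromosomes):
        # evenly spaced with jitter, strictly increasing
        base = np.linspace(1, config.chromosome_length_bp, per[c] + 2)[1:-1]
        jitter = rng.uniform(-0.3, 0.3, per[c]) * np.diff(base, prepend=0).min()
        p = np.sort((base + jitter).astype(np.int64))
        p = np.maximum.accumulate(p) + np.arange(per[c])  # enforce strict increase
        for k in range(per[c]):
            ids.append(f"M{c}_{k}")
            chrom.append(str(c + 1))
            pos.append(int(p[k]))
    return MarkerMap(tuple(ids), tuple(chrom), np.array(pos))


def _interval_recomb_probs(mm: MarkerMap, rate_cM_per_Mb: float) -> np.ndarray:
    """Per adjacent-marker-interval recombination probability, Haldane map
    function r = (1 - exp(-2d))/2 with d the interval length in Morgans;
    the first marker of each chromosome gets r = 0.5 (independent start)."""
    pos = mm.pos.astype(np.float64)
    morgans = np.zeros(len(mm))
    prev_chrom = None
    for j in range(len(mm)):
        if mm.chrom[j] != prev_chrom:
            morgans[j] = np.inf
            prev_chrom = mm.chrom[j]
        else:
            d_bp = pos[j] - pos[j - 1]
            morgans[j] = d_bp / 1e6 * rate_cM_per_Mb / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * morgans))


def _meiosis(h1: np.ndarray, h2: np.ndarray, rec: np.ndarray, rng) -> np.ndarray:
    """One gamete: Markov walk over markers switching parental haplotype
    with the interval recombination probability (Haldane model)."""
    switch = rng.uniform(size=rec.size) < rec
    current = np.cumsum(switch) % 2  # switch[0] ~ Bernoulli(0.5) randomises start
    return np.where(current == 0, h1, h2)


def simulate_genotypes(
    pedigree: Pedigree, config: SimulationConfig, seed: int
) -> GenotypePanel:
    """Founder-strain haplotypes -> burn-in random mating -> gene dropping.

    Each inbred founder strain contributes one haplotype with alleles drawn
    Bernoulli(0.5) per marker.  A closed population of ``burnin_population``
    diploids then mates at random for ``n_burnin_generations`` generations
    with Haldane recombination, which builds distance-dependent LD.  Recorded
    founders (grandparents) are sampled from matings of the final burn-in
    generation, and alleles drop through the recorded pedigree by meiosis,
    so Mendelian consistency holds exactly.
    """
    rng = np.random.default_rng(seed)
    mm = _marker_layout(config, rng)
    rec = _interval_recomb_probs(mm, config.recomb_rate_cM_per_Mb)
    m = len(mm)

    strains = rng.integers(0, 2, size=(config.n_founder_strains, m)).astype(np.int8)
    if not np.any(strains.min(axis=0) != strains.max(axis=0)):
        raise ValueError(
            "no polymorphic markers among founder strains; increase founder diversity"
        )

    B = config.burnin_population
    pick = rng.integers(0, config.n_founder_strains, size=(B, 2))
    pop = strains[pick]  # (B, 2, m) haplotypes
    for _ in range(config.n_burnin_generations):
        sires = rng.integers(0, B, size=B)
        dams = rng.integers(0, B, size=B)
        nxt = np.empty_like(pop)
        for i in range(B):
            nxt[i, 0] = _meiosis(pop[sires[i], 0], pop[sires[i], 1], rec, rng)
            nxt[i, 1] = _meiosis(pop[dams[i], 0], pop[dams[i], 1], rec, rng)
        pop = nxt

    haplo = np.empty((len(pedigree), 2, m), dtype=np.int8)
    s, d = pedigree.sire, pedigree.dam
    for i in range(len(pedigree)):
        if s[i] < 0:  # recorded founder: offspring of a random burn-in mating
            a, b = rng.integers(0, B, size=2)
            haplo[i, 0] = _meiosis(pop[a, 0], pop[a, 1], rec, rng)
            haplo[i, 1] = _meiosis(pop[b, 0], pop[b, 1], rec, rng)
        else:
            haplo[i, 0] = _meiosis(haplo[s[i], 0], haplo[s[i], 1], rec, rng)
            haplo[i, 1] = _meiosis(haplo[d[i], 0], haplo[d[i], 1], rec, rng)

    calls = (haplo[:, 0, :] + haplo[:, 1, :]).astype(np.int8)
    return GenotypePanel(pedigree.ids, calls, mm)


# ---------------------------------------------------------------------------
# Trait
# ---------------------------------------------------------------------------


def _draw_qtl_effects(n_qtl: int, distribution: str, rng) -> np.ndarray:
    if distribution == "reflected-gamma":
        # few-large / many-small architecture
        mags = rng.gamma(shape=0.4, scale=1.0, size=n_qtl)
        signs = rng.choice([-1.0, 1.0], size=n_qtl)
        return mags * signs
    if distribution == "normal":
        return rng.normal(size=n_qtl)
    raise ValueError(f"unknown QTL effect distribution {distribution!r}")


def simulate_trait(
    pedigree: Pedigree,
    panel: GenotypePanel,
    config: SimulationConfig,
    seed: int,
) -> TruePopulation:
    """Phenotypes for the offspring generation.

    y = mu + sex + slope*covariate + cage + sum_q dosage*effect + u + e,
    with QTL effects rescaled so the realised genomic variance among the
    phenotyped animals equals the configured target, the polygenic term
    propagated through the pedigree by gene flow (founders N(0, sigma2_u),
    offspring = parent average + Mendelian deviation of variance sigma2_u/2)
    and cage effects drawn per cage nested within family.
    """
    rng = np.random.default_rng(seed)
    pheno_ids = offspring_ids(pedigree)
    n = len(pheno_ids)
    idx = pedigree.index_of(pheno_ids)

    # --- QTL effects on centred dosages of the phenotyped generation
    sub = panel.subset_animals(pheno_ids)
    freq = sub.allele_frequency()
    maf = np.minimum(freq, 1 - freq)
    eligible = np.flatnonzero(maf > 0.05)
    if eligible.size < config.n_qtl:
        eligible = np.argsort(-maf)[: config.n_qtl]
    qtl = np.sort(rng.choice(eligible, size=config.n_qtl, replace=False))
    raw = _draw_qtl_effects(config.n_qtl, config.qtl_effect_distribution, rng)
    dosage = sub.calls[:, qtl].astype(np.float64)
    dosage -= dosage.mean(axis=0)
    gv = dosage @ raw
    realised = gv.var()
    if config.sigma2_qtl > 0:
        if realised <= 0:
            raise ValueError(
                "QTL genomic variance target unreachable: selected QTLs are "
                "monomorphic in the phenotyped generation"
            )
        scale = np.sqrt(config.sigma2_qtl / realised)
    else:
        scale = 0.0
    effects = np.zeros(panel.n_markers)
    effects[qtl] = raw * scale
    gv = gv * scale

    # --- polygenic gene flow down the whole pedigree
    u = np.zeros(len(pedigree))
    su = np.sqrt(config.sigma2_u)
    for i in range(len(pedigree)):
        si, di = pedigree.sire[i], pedigree.dam[i]
        if si < 0 or di < 0:
            u[i] = rng.normal(0.0, su)
        else:
            u[i] = 0.5 * (u[si] + u[di]) + rng.normal(0.0, su * np.sqrt(0.5))

    # --- cages nested in families
    fam = pedigree.family[idx]
    cage_labels = np.empty(n, dtype=object)
    for f in np.unique(fam):
        members = np.flatnonzero(fam == f)
        n_cages = max(1, int(rng.poisson(config.cages_per_family_mean - 1.0)) + 1)
        n_cages = min(n_cages, members.size)
        assign = rng.integers(0, n_cages, size=members.size)
        assign[rng.permutation(members.size)[:n_cages]] = np.arange(n_cages)
        for k, mi in enumerate(members):
            cage_labels[mi] = f"C{f}_{assign[k]}"
    cages = pd.unique(cage_labels)
    cage_eff = dict(zip(cages, rng.normal(0.0, np.sqrt(config.sigma2_c), len(cages))))

    # --- fixed effects and residual
    sex = rng.integers(0, 2, size=n)
    covariate = rng.normal(size=n)
    resid = rng.normal(0.0, np.sqrt(config.sigma2_e), size=n)
    mu = 50.0
    y = (
        mu
        + config.sex_effect * sex
        + config.covariate_slope * covariate
        + np.array([cage_eff[c] for c in cage_labels])
        + gv
        + u[idx]
        + resid
    )

    df = pd.DataFrame(
        {
            "value": y,
            "cage": cage_labels,
            "family": [f"FAM{f}" for f in fam],
            "sex": np.where(sex == 1, "M", "F"),
            "covariate": covariate,
        },
        index=pd.Index(pheno_ids, name="animal"),
    )
    phenos = PhenotypeTable(df, fixed_effects=["sex"], covariates=["covariate"])
    tbv = gv + u[idx]
    return TruePopulation(
        pedigree=pedigree,
        panel=panel,
        phenotypes=phenos,
        qtl_indices=qtl,
        qtl_effects=effects,
        breeding_values=pd.Series(tbv, index=pheno_ids),
        genomic_values=pd.Series(gv, index=pheno_ids),
        polygenic_values=pd.Series(u[idx], index=pheno_ids),
        variance_components={
            "sigma2_qtl": config.sigma2_qtl,
            "sigma2_u": config.sigma2_u,
            "sigma2_c": config.sigma2_c,
            "sigma2_e": config.sigma2_e,
            "sigma2_p": config.sigma2_p,
        },
    )


def simulate_population(config: SimulationConfig, seed: int) -> TruePopulation:
    """Pedigree + genotypes + trait in one call (stage seeds derived from
    ``seed`` by fixed offsets so stages are independently reproducible)."""
    ped = simulate_pedigree(config, seed)
    panel = simulate_genotypes(ped, config, seed + 1)
    return simulate_trait(ped, panel, config, seed + 2)


def write_population(pop: TruePopulation, outdir: str | Path) -> None:
    from .data_model import write_genotypes, write_pedigree, write_phenotypes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pedigree(pop.pedigree, outdir / "pedigree.csv")
    write_genotypes(pop.panel, outdir / "genotypes.csv")
    # the matrix CSV carries no marker map; the ped/map pair preserves it
    write_genotypes(pop.panel, outdir / "genotypes.ped", dialect="plink-ped-map")
    write_phenotypes(pop.phenotypes, outdir / "phenotypes.csv")
    mm = pop.panel.marker_map
    truth = pd.DataFrame(
        {
            "marker": mm.marker_ids,
            "chrom": mm.chrom,
            "pos": mm.pos,
            "is_qtl": np.isin(np.arange(len(mm)), pop.qtl_indices),
            "effect": pop.qtl_effects,
        }
    )
    truth.to_csv(outdir / "truth_markers.csv", index=False)
    pd.DataFrame([pop.variance_components]).to_csv(
        outdir / "truth_variances.csv", index=False
    )
    pd.DataFrame(
        {
            "breeding_value": pop.breeding_values,
            "genomic_value": pop.genomic_values,
            "polygenic_value": pop.polygenic_values,
        }
    ).to_csv(outdir / "truth_breeding_values.csv", index_label="animal")
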