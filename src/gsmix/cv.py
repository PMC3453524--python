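"""Within-family and between-family cross-validation of genetic prediction.

The split design mirrors common practice in genomic-selection studies of
full-sib populations: only animals from families with at least two
phenotyped members are eligible for validation; the eligible animals are
split into five disjoint validation sets (a 1:5 validation:training ratio)
and the whole exercise is repeated once more, giving ten validation sets.
Under the within-family routine families are split across training and
validation so full sibs connect the two; under the between-family routine
whole families go to one side only, removing close genetic links.

Predictive ability is the Pearson correlation between each validation
animal's predicted breeding value (u, g or u+g depending on the model,
fitted with validation phenotypes masked) and its realized observation,
the phenotype corrected for the training fit's fixed-effect and covariate
estimates (cage and genetic terms are not removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .data_model import DesignEncoding, Pedigree, PhenotypeTable
from .sampler import ChainSettings, ModelSpec, PosteriorDraws, fit, genetic_values

SplitMode = Literal["within-family", "between-family"]


@dataclass(frozen=True)
class SplitPlan:
    mode: str
    splits: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train, validation)
    eligible: tuple[str, ...]
    eligible_fraction: float
    seed: int


@dataclass(frozen=True)
class PAResult:
    mode: str
    model: str
    per_split: pd.DataFrame  # columns: split, pa, n_validation
    mean_pa: float
    se_pa: float


def make_splits(
    phenotypes: PhenotypeTable, mode: SplitMode, seed: int, n_groups: int = 5,
    n_rounds: int = 2,
) -> SplitPlan:
    """Two rounds of five disjoint validation sets over eligible animals."""
    if mode not in ("within-family", "between-family"):
        raise ValueError(f"unknown split mode {mode!r}")
    df = phenotypes.data[phenotypes.observed]
    fam_sizes = df.groupby("family").size()
    multi = fam_sizes[fam_sizes >= 2].index
    if len(multi) < 2:
        raise ValueError("need at least two families with >= 2 phenotyped members")
    if mode == "between-family" and len(multi) < n_groups * n_rounds:
        raise ValueError(
            f"between-family mode needs at least {n_groups * n_rounds} "
            f"multi-member families; found {len(multi)}"
        )
    eligible = df.index[df["family"].isin(multi)]
    all_pheno = set(df.index)
    rng = np.random.default_rng(seed)

    splits = []
    for _ in range(n_rounds):
        groups: list[list[str]] = [[] for _ in range(n_groups)]
        if mode == "within-family":
            # round-robin within each family with a random start, so every
            # group holds at most ceil(k/5) members of a k-sib family and at
            # least one sib always remains in training
            for f in multi:
                members = list(df.index[df["family"] == f])
                rng.shuffle(members)
                start = int(rng.integers(n_groups))
                for k, a in enumerate(members):
                    groups[(start + k) % n_groups].append(a)
        else:
            # whole families: greedy largest-first into the smallest group
            fams = list(multi)
            rng.shuffle(fams)
            fams.sort(key=lambda f: -fam_sizes[f])
            for f in fams:
                g = min(range(n_groups), key=lambda i: len(groups[i]))
                groups[g].extend(df.index[df["family"] == f])
        for g in groups:
            val = tuple(sorted(g))
            train = tuple(sorted(all_pheno - set(val)))
            splits.append((train, val))
    return SplitPlan(
        mode=mode,
        splits=tuple(splits),
        eligible=tuple(sorted(eligible)),
        eligible_fraction=len(eligible) / len(df),
        seed=seed,
    )


@dataclass(frozen=True)
class FixedSolutions:
    """Training-fit estimates of the mean, fixed effects and covariates."""

    mu: float
    coefficients: dict[str, float]  # design-column name -> estimate
    factor_levels: dict[str, list[str]]
    covariates: list[str]


def fixed_solutions(draws: PosteriorDraws) -> FixedSolutions:
    covs = [n for n in draws.fixed_names if "[" not in n]
    return FixedSolutions(
        mu=float(draws.mu.mean()),
        coefficients=dict(zip(draws.fixed_names, draws.fixed.mean(axis=0))),
        factor_levels=draws.factor_levels,
        covariates=covs,
    )


def corrected_phenotype(
    phenotypes: PhenotypeTable, solutions: FixedSolutions,
    animal_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Realized observation: y minus mu-hat, fixed-effect and covariate
    estimates; cage and genetic terms stay in."""
    df = phenotypes.data
    if animal_ids is not None:
        df = df.loc[list(animal_ids)]
    y = df["value"].to_numpy(dtype=np.float64)
    adj = np.full(len(df), solutions.mu)
    for f, levels in solutions.factor_levels.items():
        vals = df[f].astype(str)
        unseen = set(vals) - set(levels)
        if unseen:
            raise ValueError(
                f"factor {f!r} has level(s) {sorted(unseen)} absent from the "
                "training fit"
            )
        for l in levels[1:]:
            adj += np.where(vals == l, solutions.coefficients[f"{f}[{l}]"], 0.0)
    for cvar in solutions.covariates:
        adj += df[cvar].to_numpy(dtype=np.float64) * solutions.coefficients[cvar]
    return pd.Series(y - adj, index=df.index)


def predictive_ability(predicted: Sequence[float], realized: Sequence[float]) -> float:
    """Pearson correlation between predictions and realized observations."""
    p = np.asarray(predicted, dtype=np.float64)
    r = np.asarray(realized, dtype=np.float64)
    if p.shape != r.shape or p.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(p) == 0 or np.ptp(r) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(p, r)[0, 1])


def run_cv(
    spec: ModelSpec,
    phenotypes: PhenotypeTable,
    plan: SplitPlan,
    encoding: DesignEncoding | None = None,
    pedigree: Pedigree | None = None,
    chain: ChainSettings | None = None,
    encoding_animal_ids: Sequence[str] | None = None,
) -> PAResult:
    """Fit on each training set (validation phenotypes masked as missing),
    predict validation animals from their posterior-mean genetic values,
    and correlate with training-corrected realized observations."""
    chain = chain or ChainSettings()
    which = {"polygenic": "polygenic", "genomic": "genomic", "combined": "total"}[
        spec.model
    ]
    rows = []
    for k, (train, val) in enumerate(plan.splits):
        masked = phenotypes.mask_values(val)
        draws = fit(
            spec,
            masked,
            encoding=encoding,
            pedigree=pedigree,
            chain=ChainSettings(
                chain.iterations, chain.burn_in, chain.thinning,
                seed=chain.seed + 1000 * k,
            ),
            encoding_animal_ids=encoding_animal_ids,
        )
        pred = genetic_values(draws, which).reindex(list(val))
        if pred.isna().any():
            missing = pred.index[pred.isna()][0]
            raise ValueError(f"no prediction available for animal {missing!r}")
        realized = corrected_phenotype(phenotypes, fixed_solutions(draws), val)
        rows.append(
            {
                "split": k,
                "pa": predictive_ability(pred.to_numpy(), realized.to_numpy()),
                "n_validation": len(val),
            }
        )
    per_split = pd.DataFrame(rows)
    pa = per_split["pa"].to_numpy()
    return PAResult(
        mode=plan.mode,
        model=spec.model,
        per_split=per_split,
        mean_pa=float(pa.mean()),
        se_pa=float(pa.std(ddof=1) / np.sqrt(len(pa))),
    )
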