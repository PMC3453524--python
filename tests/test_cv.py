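import numpy as np
import pandas as pd
import pytest

from gsmix import ChainSettings, ModelSpec, fit, make_splits, predictive_ability, run_cv
from gsmix.cv import FixedSolutions, corrected_phenotype, fixed_solutions
from gsmix.data_model import PhenotypeTable
from gsmix.simulate import SimulationConfig, simulate_population


def _table(families, seed=0):
    """Tiny phenotype table: families maps family label -> member count."""
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for fam, size in families.items():
        for _ in range(size):
            rows.append(
                {"animal": f"a{k}", "value": rng.normal(), "cage": f"c{fam}",
                 "family": fam, "sex": "F", "covariate": 0.0}
            )
            k += 1
    df = pd.DataFrame(rows).set_index("animal")
    return PhenotypeTable(df, ["sex"], ["covariate"])


class TestMakeSplits:
    def test_one_to_five_ratio(self):
        tab = _table({f"f{i}": 5 for i in range(24)})  # 120 animals, all eligible
        plan = make_splits(tab, "within-family", seed=1)
        assert len(plan.splits) == 10
        for train, val in plan.splits:
            assert 18 <= len(val) <= 30  # ~120/5
            assert len(train) + len(val) == 120
            assert not set(train) & set(val)

    def test_validation_sets_disjoint_within_round(self):
        tab = _table({f"f{i}": 4 for i in range(15)})
        plan = make_splits(tab, "within-family", seed=2)
        for r in range(2):
            seen = set()
            for _, val in plan.splits[5 * r: 5 * r + 5]:
                assert not seen & set(val)
                seen |= set(val)

    def test_between_family_never_splits_a_family(self):
        tab = _table({f"f{i}": 3 + i % 4 for i in range(14)})
        plan = make_splits(tab, "between-family", seed=3)
        fam = tab.data["family"]
        for _, val in plan.splits:
            for f in fam.unique():
                members = set(fam.index[fam == f])
                inter = members & set(val)
                assert inter in (set(), members)

    def test_singletons_never_validated(self):
        tab = _table({"f0": 1, "f1": 1, "f2": 4, "f3": 4, "f4": 5})
        plan = make_splits(tab, "within-family", seed=4)
        singles = {"a0", "a1"}
        for train, val in plan.splits:
            assert not singles & set(val)
            assert singles <= set(train)
        assert plan.eligible_fraction == pytest.approx(13 / 15)

    def test_within_family_keeps_a_sib_in_training(self):
        tab = _table({f"f{i}": 2 + i % 6 for i in range(12)})
        for seed in range(50):
            plan = make_splits(tab, "within-family", seed=seed)
            fam = tab.data["family"]
            for train, val in plan.splits:
                for f in fam.unique():
                    members = set(fam.index[fam == f])
                    if members & set(val):
                        assert members & set(train)

    def test_between_family_needs_ten_families(self):
        tab = _table({f"f{i}": 4 for i in range(8)})
        with pytest.raises(ValueError, match="10"):
            make_splits(tab, "between-family", seed=1)


class TestCorrectedPhenotype:
    def test_zero_solutions_subtract_mu_only(self):
        tab = _table({"f0": 3, "f1": 3})
        sol = FixedSolutions(mu=2.0, coefficients={}, factor_levels={}, covariates=[])
        out = corrected_phenotype(tab, sol)
        assert np.allclose(out, tab.data["value"] - 2.0)

    def test_sex_effect_applied_to_matching_animals_only(self):
        df = pd.DataFrame(
            {"value": [1.0, 1.0], "cage": ["c", "c"], "family": ["f", "f"],
             "sex": ["F", "M"], "covariate": [0.0, 0.0]},
            index=pd.Index(["x", "y"], name="animal"),
        )
        tab = PhenotypeTable(df, ["sex"], ["covariate"])
        sol = FixedSolutions(
            mu=0.0, coefficients={"sex[M]": 0.4, "covariate": 0.0},
            factor_levels={"sex": ["F", "M"]}, covariates=["covariate"],
        )
        out = corrected_phenotype(tab, sol)
        assert out["x"] == pytest.approx(1.0)
        assert out["y"] == pytest.approx(0.6)

    def test_hand_computed_covariate_case(self):
        # y - mu - x*beta for four animals, worked by hand
        df = pd.DataFrame(
            {"value": [5.0, 7.0, 4.0, 6.0], "cage": ["c"] * 4, "family": ["f"] * 4,
             "sex": ["F"] * 4, "covariate": [1.0, 2.0, -1.0, 0.5]},
            index=pd.Index(list("abcd"), name="animal"),
        )
        tab = PhenotypeTable(df, ["sex"], ["covariate"])
        sol = FixedSolutions(
            mu=3.0, coefficients={"covariate": 2.0}, factor_levels={},
            covariates=["covariate"],
        )
        out = corrected_phenotype(tab, sol)
        assert np.allclose(out, [0.0, 0.0, 3.0, 2.0])

    def test_unseen_level_raises(self):
        tab = _table({"f0": 3})
        sol = FixedSolutions(
            mu=0.0, coefficients={"sex[M]": 1.0},
            factor_levels={"sex": ["M"]}, covariates=[],
        )
        with pytest.raises(ValueError, match="F"):
            corrected_phenotype(tab, sol)


class TestPredictiveAbility:
    def test_perfect_and_anti_correlation(self):
        x = [1.0, 2.0, 5.0, 3.0]
        assert predictive_ability(x, x) == pytest.approx(1.0)
        assert predictive_ability(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_direct_formula_value(self):
        assert predictive_ability([1, 2, 3], [2, 4, 7]) == pytest.approx(
            0.9934, abs=5e-5
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            predictive_ability([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRunCV:
    def test_pure_noise_trait_pa_near_zero(self):
        cfg = SimulationConfig(
            n_families=25, fixed_family_size=10, n_markers=120,
            n_burnin_generations=15, burnin_population=80,
            n_qtl=0, h2_qtl=0.0, h2_polygenic=0.0, cage_fraction=0.1,
        )
        pop = simulate_population(cfg, seed=71)
        from gsmix import encode_design

        sub = pop.panel.subset_animals(list(pop.phenotypes.animal_ids))
        enc = encode_design(sub, "dosage-centered")
        plan = make_splits(pop.phenotypes, "within-family", seed=5)
        res = run_cv(
            ModelSpec(model="genomic", pi1=0.1), pop.phenotypes, plan,
            encoding=enc, chain=ChainSettings(600, 200, 4, seed=2),
        )
        assert abs(res.mean_pa) < 3 * max(res.se_pa, 0.02)

    def test_same_seed_identical_result(self, qtl_population, qtl_encoding):
        _, pop = qtl_population
        plan = make_splits(pop.phenotypes, "within-family", seed=6)
        kw = dict(encoding=qtl_encoding, chain=ChainSettings(400, 150, 5, seed=9))
        a = run_cv(ModelSpec(model="genomic", pi1=0.1), pop.phenotypes, plan, **kw)
        b = run_cv(ModelSpec(model="genomic", pi1=0.1), pop.phenotypes, plan, **kw)
        assert a.per_split.equals(b.per_split)

    def test_masked_phenotypes_equivalent_to_dropped_records(self, poly_population):
        """Masking a validation animal's phenotype must be equivalent to its
        record being absent: training-animal posteriors match (no leakage
        through the residual of a masked record)."""
        _, pop = poly_population
        tab = pop.phenotypes
        fam = tab.data["family"]
        val = list(fam.index[fam == fam.unique()[1]])
        fv = {"sigma2_e": 30.0, "sigma2_c": 10.0, "sigma2_u": 40.0}
        chain = ChainSettings(100_000, 20_000, 4, seed=3)
        masked = fit(ModelSpec(model="polygenic"), tab.mask_values(val),
                     pedigree=pop.pedigree, chain=chain, fix_variances=fv)
        dropped_tab = PhenotypeTable(
            tab.data.drop(index=val), list(tab.fixed_effects), list(tab.covariates)
        )
        dropped = fit(ModelSpec(model="polygenic"), dropped_tab,
                      pedigree=pop.pedigree, chain=chain, fix_variances=fv)
        keep = [a for a in tab.animal_ids if a not in set(val)]
        idx = pop.pedigree.index_of(keep)
        diff = np.abs(masked.u.mean(axis=0)[idx] - dropped.u.mean(axis=0)[idx])
        # identical in expectation; only Monte Carlo noise remains
        assert diff.max() < 0.05 * np.sqrt(fv["sigma2_u"])
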