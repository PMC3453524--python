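import numpy as np
import pandas as pd
import pytest

from gsmix import (
    ChainSettings,
    ModelSpec,
    encode_design,
    fit,
    genetic_values,
    marker_inclusion_probability,
)
from gsmix.relationship import relationship_inverse


def _mme_solution(pop, ve, vc, vu):
    """Henderson's mixed-model equations solved directly (dense)."""
    tab = pop.phenotypes
    y = tab.data["value"].to_numpy()
    sex = (tab.data["sex"].astype(str) == "M").to_numpy(float)
    cov = tab.data["covariate"].to_numpy(float)
    X = np.column_stack([np.ones_like(y), sex, cov])
    cages, labels = pd.factorize(tab.data["cage"].astype(str))
    Xc = np.zeros((len(y), len(labels)))
    Xc[np.arange(len(y)), cages] = 1
    idx = pop.pedigree.index_of(list(tab.animal_ids))
    Z = np.zeros((len(y), len(pop.pedigree)))
    Z[np.arange(len(y)), idx] = 1
    Ainv = relationship_inverse(pop.pedigree).toarray()
    W = np.hstack([X, Xc, Z])
    lhs = W.T @ W / ve
    p, nc = X.shape[1], Xc.shape[1]
    lhs[p:p + nc, p:p + nc] += np.eye(nc) / vc
    lhs[p + nc:, p + nc:] += Ainv / vu
    sol = np.linalg.solve(lhs, W.T @ y / ve)
    return sol[:p], sol[p + nc:]


class TestOracleEquivalence:
    def test_polygenic_matches_mme(self, poly_population):
        """With variances fixed at truth, Gibbs posterior means of fixed and
        polygenic effects converge to the direct MME solve."""
        cfg, pop = poly_population
        ve, vc, vu = cfg.sigma2_e, cfg.sigma2_c, cfg.sigma2_u
        b_mme, u_mme = _mme_solution(pop, ve, vc, vu)
        draws = fit(
            ModelSpec(model="polygenic"), pop.phenotypes, pedigree=pop.pedigree,
            chain=ChainSettings(120_000, 20_000, 4, seed=7),
            fix_variances={"sigma2_e": ve, "sigma2_c": vc, "sigma2_u": vu},
        )
        gsd = np.sqrt(vu)
        assert np.max(np.abs(draws.fixed.mean(axis=0) - b_mme[1:])) / gsd < 0.02
        assert np.max(np.abs(draws.u.mean(axis=0) - u_mme)) / gsd < 0.03

    def test_genomic_frozen_scaling_matches_ridge(self, qtl_population, qtl_encoding):
        """Indicators frozen at 1 and scaling frozen at s0 reduce the marker
        layer to ridge regression with penalty sigma2_e / s0^2."""
        cfg, pop = qtl_population
        enc = qtl_encoding
        y = pop.phenotypes.data["value"].to_numpy()
        s0, ve = 1.5, cfg.sigma2_e
        Q = enc.matrix
        ridge = np.linalg.solve(
            Q.T @ Q + (ve / s0**2) * np.eye(Q.shape[1]), Q.T @ (y - y.mean())
        )
        spec = ModelSpec(model="genomic", pi1=1.0, include_cage=False,
                         fixed_effects=[], covariates=[])
        draws = fit(
            spec, pop.phenotypes, encoding=enc,
            chain=ChainSettings(40_000, 8_000, 4, seed=5),
            fix_variances={"sigma2_e": ve, "sigma2_g1": 1.0},
            freeze_delta=True, freeze_s=s0,
        )
        diff = np.abs(draws.avec.mean(axis=0) - ridge) / y.std()
        assert diff.max() < 0.02

    def test_prior_reproduction(self, qtl_population, qtl_encoding):
        """With the likelihood disabled the chain reproduces its own prior:
        E[delta] = pi1 and E[s | delta=1] = sigma_g1 * sqrt(2/pi)."""
        _, pop = qtl_population
        pi1, vg1 = 0.1, 4.0
        spec = ModelSpec(model="genomic", pi1=pi1, include_cage=False,
                         fixed_effects=[], covariates=[])
        draws = fit(
            spec, pop.phenotypes, encoding=qtl_encoding,
            chain=ChainSettings(2500, 500, 1, seed=9),
            fix_variances={"sigma2_e": 1.0, "sigma2_g1": vg1},
            likelihood=False,
        )
        n_draws = draws.delta.size
        se_d = np.sqrt(pi1 * (1 - pi1) / n_draws)
        assert abs(draws.delta.mean() - pi1) < 3 * se_d
        s_in = draws.s[draws.delta.astype(bool)]
        expect = np.sqrt(vg1) * np.sqrt(2 / np.pi)
        se_s = np.sqrt(vg1 * (1 - 2 / np.pi)) / np.sqrt(s_in.size)
        assert abs(s_in.mean() - expect) < 3 * se_s


class TestChainBehaviour:
    def test_identical_seed_bit_identical_draws(self, qtl_population, qtl_encoding):
        _, pop = qtl_population
        spec = ModelSpec(model="genomic", pi1=0.1)
        kw = dict(encoding=qtl_encoding, chain=ChainSettings(400, 100, 2, seed=21))
        a = fit(spec, pop.phenotypes, **kw)
        b = fit(spec, pop.phenotypes, **kw)
        assert np.array_equal(a.avec, b.avec)
        assert np.array_equal(a.sigma2_e, b.sigma2_e)
        assert np.array_equal(a.delta, b.delta)

    def test_encoding_equivalence_dosage_vs_per_allele(self, qtl_population):
        """Dosage-centred and per-allele codings span the same marker space;
        posterior-mean genomic values agree up to stochastic error."""
        _, pop = qtl_population
        sub = pop.panel.subset_animals(list(pop.phenotypes.animal_ids))
        spec = ModelSpec(model="genomic", pi1=0.4)
        # long enough that Monte Carlo error does not mask the comparison
        chain = ChainSettings(8000, 2500, 4, seed=13)
        g = {}
        for mode in ("dosage-centered", "per-allele"):
            enc = encode_design(sub, mode)
            draws = fit(spec, pop.phenotypes, encoding=enc, chain=chain)
            gv = genetic_values(draws, "genomic")
            g[mode] = gv - gv.mean()
        psd = pop.phenotypes.data["value"].std()
        diff = (g["dosage-centered"] - g["per-allele"]).abs().max()
        assert diff / psd < 0.05

    def test_missing_phenotypes_still_predicted(self, qtl_population, qtl_encoding):
        _, pop = qtl_population
        animals = list(pop.phenotypes.animal_ids)
        masked = pop.phenotypes.mask_values(animals[:30])
        draws = fit(ModelSpec(model="genomic", pi1=0.1), masked,
                    encoding=qtl_encoding, chain=ChainSettings(600, 200, 2, seed=3))
        gv = genetic_values(draws, "genomic")
        assert not gv.loc[animals[:30]].isna().any()

    def test_polygenic_requires_pedigree(self, qtl_population):
        _, pop = qtl_population
        with pytest.raises(ValueError, match="Pedigree"):
            fit(ModelSpec(model="polygenic"), pop.phenotypes)

    def test_genomic_requires_encoding(self, qtl_population):
        _, pop = qtl_population
        with pytest.raises(ValueError, match="DesignEncoding"):
            fit(ModelSpec(model="genomic"), pop.phenotypes)


class TestDerivedQuantities:
    def test_inclusion_probability_clamped(self, qtl_population, qtl_encoding):
        _, pop = qtl_population
        draws = fit(ModelSpec(model="genomic", pi1=0.05), pop.phenotypes,
                    encoding=qtl_encoding, chain=ChainSettings(600, 200, 2, seed=4))
        p1 = marker_inclusion_probability(draws)
        S = draws.n_stored
        assert np.all(p1 >= 1 / (2 * S)) and np.all(p1 <= 1 - 1 / (2 * S))
        always_in = draws.delta.mean(axis=0) == 1.0
        if always_in.any():
            assert np.all(p1[always_in] == 1 - 1 / (2 * S))

    def test_inclusion_probability_rejects_non_mixture(self, qtl_population,
                                                       qtl_encoding):
        _, pop = qtl_population
        draws = fit(ModelSpec(model="genomic", pi1=1.0), pop.phenotypes,
                    encoding=qtl_encoding, chain=ChainSettings(300, 100, 2, seed=4))
        with pytest.raises(ValueError, match="pi1 < 1"):
            marker_inclusion_probability(draws)

    def test_total_is_polygenic_plus_genomic(self, qtl_population, qtl_encoding):
        _, pop = qtl_population
        draws = fit(ModelSpec(model="combined", pi1=0.4), pop.phenotypes,
                    encoding=qtl_encoding, pedigree=pop.pedigree,
                    chain=ChainSettings(400, 100, 2, seed=6))
        total = genetic_values(draws, "total")
        upart = genetic_values(draws, "polygenic")
        gpart = genetic_values(draws, "genomic")
        both = (upart.reindex(gpart.index).fillna(0) + gpart)
        pd.testing.assert_series_equal(total, both)

    def test_polygenic_values_absent_from_genomic_model(self, qtl_population,
                                                        qtl_encoding):
        _, pop = qtl_population
        draws = fit(ModelSpec(model="genomic", pi1=1.0), pop.phenotypes,
                    encoding=qtl_encoding, chain=ChainSettings(300, 100, 2, seed=4))
        with pytest.raises(ValueError, match="polygenic"):
            genetic_values(draws, "polygenic")


class TestDrawsPersistence:
    def test_hdf5_round_trip(self, qtl_population, qtl_encoding, tmp_path):
        from gsmix.sampler import load_draws, save_draws

        _, pop = qtl_population
        draws = fit(ModelSpec(model="genomic", pi1=0.1), pop.phenotypes,
                    encoding=qtl_encoding,
                    chain=ChainSettings(300, 100, 2, seed=11))
        path = tmp_path / "draws.h5"
        save_draws(draws, path)
        back = load_draws(path)
        assert back.model == draws.model and back.pi1 == draws.pi1
        assert np.array_equal(back.avec, draws.avec)
        assert np.array_equal(back.delta, draws.delta)
        assert back.fixed_names == draws.fixed_names
        pd.testing.assert_series_equal(
            genetic_values(back, "genomic"), genetic_values(draws, "genomic")
        )
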