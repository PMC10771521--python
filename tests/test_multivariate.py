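"""Multivariate CTD: worked examples, FIML fit, genetic correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize as sopt
from scipy import stats as sps

from twintaste import simulate as sim
from twintaste.multivariate import (MultivariateTwinModel,
                                    bivariate_heritability,
                                    cross_twin_cross_trait_correlations,
                                    fit_multivariate, genetic_correlation,
                                    make_multitrait_pairs,
                                    saturated_minus2ll)
from twintaste.univariate import compare_models


def _bivariate_pairs(a1=0.35, a2=0.31, a12=0.18, e12=0.09, n_mz=500,
                     n_dz=200, seed=0):
    cfg = sim.bivariate_ae_config(a1, a2, a12, e12, n_mz_pairs=n_mz,
                                  n_dz_pairs=n_dz, seed=seed)
    tr = sim.simulate_twin_traits(cfg)
    return make_multitrait_pairs(tr, ["trait1", "trait2"])


class TestDerivedQuantities:
    def test_bivariate_heritability_worked_example(self):
        """h2_b from A covariance 0.18 and E covariance 0.09 is 0.67."""
        assert round(bivariate_heritability(0.18, 0.0, 0.09), 2) == 0.67

    def test_genetic_correlation_worked_example(self):
        """rhoA from covariance 0.18 and variances 0.35, 0.31 is 0.55."""
        assert round(genetic_correlation(0.18, 0.35, 0.31), 2) == 0.55

    def test_bivariate_heritability_arithmetic(self):
        assert bivariate_heritability(0.0, 0.1, 0.2) == 0.0
        assert bivariate_heritability(0.1, 0.1, 0.2) == pytest.approx(0.25)
        with pytest.raises(ValueError):
            bivariate_heritability(0.0, 0.0, 0.0)
        with pytest.warns(UserWarning, match="outside"):
            assert bivariate_heritability(0.3, 0.0, -0.1) == 1.0

    def test_perfect_pleiotropy(self):
        assert genetic_correlation(np.sqrt(0.35 * 0.31), 0.35, 0.31) == \
            pytest.approx(1.0)
        with pytest.raises(ValueError, match="nonpositive"):
            genetic_correlation(0.1, 0.0, 0.3)

    @pytest.mark.parametrize("seed", range(4))
    def test_correlation_from_random_psd_matrix(self, seed):
        """Matches the brute-force covariance-to-correlation conversion."""
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(2, 4))
        cov = m @ m.T + 0.1 * np.eye(2)
        expected = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        assert genetic_correlation(cov[0, 1], cov[0, 0], cov[1, 1]) == \
            pytest.approx(expected, abs=1e-12)


class TestCrossTwinCrossTrait:
    def test_null_generator_gives_zero_correlations(self):
        cfg = sim.trait_only_config(
            sigma_a=np.zeros((2, 2)), sigma_e=np.eye(2),
            trait_names=("trait1", "trait2"), n_mz_pairs=800, n_dz_pairs=400,
            seed=1)
        pairs = make_multitrait_pairs(sim.simulate_twin_traits(cfg),
                                      ["trait1", "trait2"])
        mats = cross_twin_cross_trait_correlations(pairs, ["trait1", "trait2"])
        for zyg in ("MZ", "DZ"):
            assert np.abs(mats[zyg].to_numpy()).max() < 0.12

    def test_rank_one_genetic_covariance_moment_formula(self):
        """MZ cross-twin cross-trait correlation approaches sigma_A12/total."""
        a = np.array([[0.5, 0.45], [0.45, 0.5]])  # near rank-1
        cfg = sim.trait_only_config(
            sigma_a=a, sigma_e=np.eye(2) * 0.5,
            trait_names=("trait1", "trait2"), n_mz_pairs=4000, n_dz_pairs=500,
            seed=2)
        pairs = make_multitrait_pairs(sim.simulate_twin_traits(cfg),
                                      ["trait1", "trait2"])
        mats = cross_twin_cross_trait_correlations(pairs, ["trait1", "trait2"])
        assert mats["MZ"].loc["trait1", "trait2"] == pytest.approx(0.45, abs=0.04)

    def test_symmetrization_under_twin_order_swap(self):
        pairs = _bivariate_pairs(seed=3)
        swapped = pairs.copy()
        for t in ("trait1", "trait2"):
            swapped[[f"y_{t}_1", f"y_{t}_2"]] = pairs[[f"y_{t}_2", f"y_{t}_1"]].to_numpy()
        m1 = cross_twin_cross_trait_correlations(pairs, ["trait1", "trait2"])
        m2 = cross_twin_cross_trait_correlations(swapped, ["trait1", "trait2"])
        for zyg in ("MZ", "DZ"):
            pd.testing.assert_frame_equal(m1[zyg], m2[zyg], atol=1e-12)


class TestFit:
    def test_null_cross_covariance_estimated_near_zero(self):
        pairs = _bivariate_pairs(a12=0.0, e12=0.0, n_mz=900, n_dz=350, seed=4)
        fit = fit_multivariate(pairs, ["trait1", "trait2"],
                               include={"A": None, "E": None}, restarts=0)
        assert abs(fit.sigma["A"].loc["trait1", "trait2"]) < 0.08
        assert abs(fit.genetic_correlation("trait1", "trait2")) < 0.25

    def test_path_value_recovery_rho_a(self):
        """Data at the printed path values recover rhoA ~ 0.55 on average."""
        vals = []
        for seed in (5, 6, 7):
            pairs = _bivariate_pairs(n_mz=1070, n_dz=430, seed=seed)
            fit = fit_multivariate(pairs, ["trait1", "trait2"],
                                   include={"A": None, "E": None}, restarts=0)
            vals.append(fit.genetic_correlation("trait1", "trait2"))
        assert np.mean(vals) == pytest.approx(
            genetic_correlation(0.18, 0.35, 0.31), abs=0.07)

    def test_minus2ll_matches_second_optimizer_on_small_fixture(self):
        """Direct search over the naive stacked likelihood agrees to 1e-5."""
        pairs = _bivariate_pairs(n_mz=70, n_dz=30, seed=8)
        model = MultivariateTwinModel(pairs, ["trait1", "trait2"],
                                      include={"A": None, "E": None})
        fit = model.fit()

        def naive(theta):
            # independent likelihood: loop over families, explicit 4x4 blocks
            a = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
            e = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
            mu = np.array(theta[6:8])
            total = 0.0
            y = model._y
            for fam in range(len(y)):
                w = 1.0 if model._zyg[fam] == "MZ" else 0.5
                sig = np.block([[a + e, w * a], [w * a, a + e]])
                try:
                    total += -2 * sps.multivariate_normal(
                        mean=np.tile(mu, 2), cov=sig).logpdf(y[fam])
                except (np.linalg.LinAlgError, ValueError):
                    return 1e10
            return total

        res = sopt.minimize(naive, np.array([0.4, 0.1, 0.4, 0.6, 0.1, 0.6,
                                             0.0, 0.0]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-10,
                                     "maxiter": 40000, "maxfev": 40000})
        assert fit.minus2ll == pytest.approx(res.fun, abs=1e-5)

    def test_implied_phenotypic_covariance_matches_empirical(self):
        pairs = _bivariate_pairs(n_mz=2000, n_dz=800, seed=9)
        fit = fit_multivariate(pairs, ["trait1", "trait2"],
                               include={"A": None, "E": None}, restarts=0)
        y = np.column_stack([pairs["y_trait1_1"], pairs["y_trait2_1"]])
        emp = np.cov(y.T)
        # traits standardized inside the model: compare correlation shape
        emp_r = emp[0, 1] / np.sqrt(emp[0, 0] * emp[1, 1])
        implied = fit.phenotypic_covariance.to_numpy()
        implied_r = implied[0, 1] / np.sqrt(implied[0, 0] * implied[1, 1])
        assert implied_r == pytest.approx(emp_r, abs=0.05)
        assert np.allclose(np.diag(implied), 1.0, atol=0.05)

    def test_per_trait_component_inclusion_zeroes_rows(self):
        cfg = sim.trait_only_config(
            sigma_a=np.diag([0.4, 0.0]), sigma_c=np.diag([0.0, 0.3]),
            sigma_e=np.diag([0.6, 0.7]),
            trait_names=("t1", "t2"), n_mz_pairs=700, n_dz_pairs=350, seed=10)
        pairs = make_multitrait_pairs(sim.simulate_twin_traits(cfg), ["t1", "t2"])
        fit = fit_multivariate(pairs, ["t1", "t2"],
                               include={"A": ["t1"], "C": ["t2"], "E": None},
                               restarts=0)
        assert fit.sigma["A"].loc["t2", "t2"] == 0.0
        assert fit.sigma["A"].loc["t1", "t2"] == 0.0
        assert fit.sigma["C"].loc["t1", "t1"] == 0.0
        assert fit.sigma["A"].loc["t1", "t1"] == pytest.approx(0.4, abs=0.1)
        assert fit.sigma["C"].loc["t2", "t2"] == pytest.approx(0.3, abs=0.1)

    def test_model_chain_delta_df_and_monotonicity(self):
        """Saturated -> full ACE (ddf 17 bivariate) -> AE, -2LL non-decreasing."""
        pairs = _bivariate_pairs(n_mz=400, n_dz=200, seed=11)
        sat = saturated_minus2ll(pairs, ["trait1", "trait2"])
        full = fit_multivariate(pairs, ["trait1", "trait2"],
                                include={"A": None, "C": None, "E": None},
                                restarts=0)
        ae = fit_multivariate(pairs, ["trait1", "trait2"],
                              include={"A": None, "E": None}, restarts=0)
        chain1 = compare_models(sat, full)
        chain2 = compare_models(full, ae)
        assert chain1["delta_df"] == 17
        assert chain2["delta_df"] == 3
        assert sat.minus2ll <= full.minus2ll + 1e-6 <= ae.minus2ll + 2e-6

    def test_spec_validation(self):
        pairs = _bivariate_pairs(n_mz=50, n_dz=30, seed=12)
        with pytest.raises(ValueError, match="C and D"):
            MultivariateTwinModel(pairs, ["trait1", "trait2"],
                                  include={"C": None, "D": None, "E": None})
        with pytest.raises(ValueError, match="unknown traits"):
            MultivariateTwinModel(pairs, ["trait1", "trait2"],
                                  include={"A": ["nope"], "E": None})
        with pytest.raises(ValueError, match="at least two"):
            MultivariateTwinModel(pairs, ["trait1"])


def test_profile_ci_brackets_rho_a():
    pairs = _bivariate_pairs(n_mz=1070, n_dz=430, seed=13)
    fit = fit_multivariate(pairs, ["trait1", "trait2"],
                           include={"A": None, "E": None}, restarts=0)
    rho = fit.genetic_correlation("trait1", "trait2")
    lo, hi = fit.profile_ci("rhoA", "trait1", "trait2")
    assert lo < rho < hi
    assert 0.05 < hi - lo < 0.6
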