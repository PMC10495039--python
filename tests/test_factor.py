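import numpy as np
import pytest

import perflink as pl
from perflink.polychoric import PolychoricMatrix, polychoric_rho


def _ogive_rm(loadings, n, rng, cuts=(-1.0, -0.2, 0.5, 1.3), factor=None):
    """Normal-ogive 1-factor ordinal data with known loadings."""
    G = rng.normal(size=n) if factor is None else factor
    X = np.empty((n, len(loadings)), dtype=int)
    for j, lam in enumerate(loadings):
        prop = lam * G + np.sqrt(1 - lam * lam) * rng.normal(size=n)
        X[:, j] = np.searchsorted(np.asarray(cuts), prop)
    return pl.ResponseMatrix(X, [f"i{j}" for j in range(len(loadings))])


class TestPolychoric:
    def test_recovers_generating_correlation(self, rng):
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=5000)
        cuts = np.array([-1.0, -0.2, 0.5, 1.3])
        x = np.searchsorted(cuts, z[:, 0])
        y = np.searchsorted(cuts, z[:, 1])
        r, avar, n = polychoric_rho(x, y)
        assert r == pytest.approx(0.6, abs=0.04)
        assert avar > 0 and n == 5000

    def test_independent_items_near_zero(self, rng):
        x = rng.integers(0, 5, 4000)
        y = rng.integers(0, 5, 4000)
        r, _, _ = polychoric_rho(x, y)
        assert abs(r) < 0.05

    def test_duplicated_column_near_one(self, rng):
        x = rng.integers(0, 5, 2000)
        r, _, _ = polychoric_rho(x, x.copy())
        assert r >= 0.99

    def test_single_category_item_rejected(self, rng):
        x = np.zeros(100, dtype=int)
        y = rng.integers(0, 3, 100)
        with pytest.raises(ValueError, match="single observed category"):
            polychoric_rho(x, y)

    def test_matrix_symmetry_and_diagonal(self, rm2000):
        pm = pl.polychoric_matrix(rm2000, rm2000.item_ids[:5])
        assert np.allclose(pm.rho, pm.rho.T)
        assert np.allclose(np.diag(pm.rho), 1.0)
        assert (np.abs(pm.rho[np.triu_indices(5, 1)]) < 1).all()


class TestConfirmatoryFactorModel:
    def test_loading_recovery_and_close_fit(self, rng):
        loadings = np.array([0.5, 0.6, 0.7, 0.8, 0.85, 0.65, 0.75, 0.55])
        rm = _ogive_rm(loadings, 2000, rng)
        sol = pl.fit_factor_model(pl.polychoric_matrix(rm), {"g": list(rm.item_ids)})
        est = sol.loadings["g"].to_numpy()
        assert np.mean(np.abs(est - loadings)) < 0.05
        assert sol.fit["CFI"] > 0.99
        assert sol.fit["SRMSR"] < 0.03
        assert sol.converged

    def test_self_consistency_on_model_implied_matrix(self):
        """Fitting the model to its own implied correlations reproduces the
        loadings essentially exactly."""
        lam = np.array([0.5, 0.65, 0.8, 0.7, 0.6])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        pm = PolychoricMatrix(
            rho=R,
            thresholds=[np.array([0.0])] * 5,
            item_ids=[f"i{j}" for j in range(5)],
            pairwise_n=np.full((5, 5), 1000),
            avar=np.full((5, 5), 1e-4),
            n_obs=1000,
        )
        sol = pl.fit_factor_model(pm, {"g": pm.item_ids})
        assert np.allclose(sol.loadings["g"].to_numpy(), lam, atol=1e-4)
        assert sol.fit["chi2"] < 1e-8
        assert sol.fit["SRMSR"] < 1e-5

    def test_two_factor_correlation_recovery(self, rng):
        F = rng.multivariate_normal([0, 0], [[1, 0.66], [0.66, 1]], size=2000)
        lam = rng.uniform(0.55, 0.85, 10)
        X = np.empty((2000, 10), dtype=int)
        cuts = np.array([-1.0, -0.2, 0.5, 1.3])
        for j in range(10):
            f = F[:, 0] if j < 4 else F[:, 1]
            prop = lam[j] * f + np.sqrt(1 - lam[j] ** 2) * rng.normal(size=2000)
            X[:, j] = np.searchsorted(cuts, prop)
        rm = pl.ResponseMatrix(X, [f"i{j}" for j in range(10)])
        r = pl.latent_instrument_correlation(rm, rm.item_ids[:4], rm.item_ids[4:])
        assert r == pytest.approx(0.66, abs=0.05)

    def test_same_factor_data_correlate_near_one(self, rng):
        rm = _ogive_rm(np.full(8, 0.75), 2000, rng)
        r = pl.latent_instrument_correlation(rm, rm.item_ids[:4], rm.item_ids[4:])
        assert r > 0.95

    def test_independent_constructs_correlate_near_zero(self, rng):
        a = _ogive_rm(np.full(4, 0.75), 2000, rng)
        b = _ogive_rm(np.full(4, 0.75), 2000, rng)
        X = np.hstack([a.responses, b.responses])
        rm = pl.ResponseMatrix(X, [f"i{j}" for j in range(8)])
        r = pl.latent_instrument_correlation(rm, rm.item_ids[:4], rm.item_ids[4:])
        assert abs(r) < 0.08

    def test_single_item_factor_rejected(self, rm2000):
        pm = pl.polychoric_matrix(rm2000, rm2000.item_ids[:4])
        with pytest.raises(ValueError, match="not identified"):
            pl.fit_factor_model(
                pm, {"f1": [rm2000.item_ids[0]], "f2": list(rm2000.item_ids[1:4])}
            )

    def test_too_few_instrument_items_rejected(self, rm2000):
        with pytest.raises(ValueError, match="at least 2"):
            pl.latent_instrument_correlation(
                rm2000, [rm2000.item_ids[0]], rm2000.item_ids[1:]
            )


class TestBifactor:
    def test_puc_counting_formula(self):
        ids = [f"i{j}" for j in range(13)]
        part = {"a": ids[:4], "b": ids[4:7], "c": ids[7:10], "d": ids[10:13]}
        assert pl.puc_from_partition(part, ids) == pytest.approx(63 / 78)

    def test_puc_requires_exact_cover(self):
        ids = ["a", "b", "c"]
        with pytest.raises(ValueError):
            pl.puc_from_partition({"s": ["a", "b"]}, ids)

    def test_indices_match_hand_arithmetic_on_fixed_loadings(self):
        """g = 0.7 everywhere, one 3-item group with specifics 0.4."""
        ids = [f"i{j}" for j in range(6)]
        g = np.full(6, 0.7)
        spec = np.zeros((6, 2))
        spec[:3, 0] = 0.4
        part = {"s1": ids[:3], "s2": ids[3:]}
        ecv, omega_h, puc = pl.bifactor_indices_from_loadings(
            g, spec, {"s1": 0, "s2": 1}, part, ids
        )
        ssg = 6 * 0.49
        sss = 3 * 0.16
        assert ecv == pytest.approx(ssg / (ssg + sss), abs=1e-12)
        h2 = np.array([0.49 + 0.16] * 3 + [0.49] * 3)
        expected_omega = (6 * 0.7) ** 2 / (
            (6 * 0.7) ** 2 + (3 * 0.4) ** 2 + np.sum(1 - h2)
        )
        assert omega_h == pytest.approx(expected_omega, abs=1e-12)
        assert puc == pytest.approx((15 - 3 - 3) / 15, abs=1e-12)

    def test_pure_general_factor_yields_high_ecv(self, bank13):
        ids = bank13.item_ids
        part = {"s1": ids[:4], "s2": ids[4:7], "s3": ids[7:10], "s4": ids[10:13]}
        sc = pl.SimScenario(
            n_persons=5000, general_loadings={i: 0.7 for i in ids}, seed=9
        )
        bf = pl.BifactorAnalyzer(specific_groups=part).fit(pl.simulate_bifactor(bank13, sc))
        assert bf.ecv_ >= 0.95
        assert 0 <= bf.ecv_ <= 1 and 0 <= bf.omega_h_ <= 1 and 0 <= bf.puc_ <= 1
        assert (bf.general_loadings_ > 0.5).all()
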