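import itertools

import numpy as np
import pytest
from scipy import integrate, stats

import perflink as pl
from perflink.data import MISSING
from perflink.grm import _cat_probs


class TestCategoryProbs:
    def test_symmetry_at_threshold(self):
        item = pl.Item("x", "new", 1.0, (0.0,))
        assert pl.grm_category_probs(item, 0.0) == pytest.approx([0.5, 0.5])

    def test_three_category_logistic_values(self):
        item = pl.Item("x", "new", 1.0, (-1.0, 1.0))
        p = pl.grm_category_probs(item, 0.0)
        assert p == pytest.approx([0.26894, 0.46212, 0.26894], abs=1e-5)

    def test_cumulative_half_at_each_threshold(self):
        item = pl.Item("x", "new", 1.7, (-0.8, 0.2, 1.4))
        for k, b in enumerate(item.thresholds):
            p = pl.grm_category_probs(item, b)
            assert p[k + 1 :].sum() == pytest.approx(0.5, abs=1e-12)

    def test_probabilities_sum_to_one_everywhere(self, bank13):
        thetas = np.linspace(-6, 6, 41)
        for item in bank13:
            p = pl.grm_category_probs(item, thetas)
            assert np.allclose(p.sum(axis=0), 1.0, atol=1e-14)
            assert (p >= 0).all()


class TestPatternLoglik:
    def test_all_missing_is_zero(self, bank13):
        assert pl.pattern_loglik(np.full(13, MISSING), bank13, 0.7) == 0.0

    def test_single_item_matches_category_prob(self, bank3):
        pat = np.array([1, MISSING, MISSING])
        ll = pl.pattern_loglik(pat, bank3, 0.4)
        assert ll == pytest.approx(np.log(pl.grm_category_probs(bank3[0], 0.4)[1]))

    def test_additivity_over_item_blocks(self, bank3):
        full = np.array([1, 0, 2])
        a = np.array([1, MISSING, MISSING])
        b = np.array([MISSING, 0, 2])
        th = -0.3
        assert pl.pattern_loglik(full, bank3, th) == pytest.approx(
            pl.pattern_loglik(a, bank3, th) + pl.pattern_loglik(b, bank3, th)
        )

    def test_out_of_range_code_rejected(self, bank3):
        with pytest.raises(ValueError):
            pl.pattern_loglik(np.array([5, 0, 0]), bank3, 0.0)


class TestGrid:
    def test_weights_normalized_symmetric_centered(self):
        g = pl.make_grid(61, 6.0)
        assert g.weights.sum() == pytest.approx(1.0, abs=1e-14)
        assert np.allclose(g.weights, g.weights[::-1])
        assert g.weights @ g.nodes == pytest.approx(0.0, abs=1e-12)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            pl.make_grid(2)


class TestEAP:
    def test_all_missing_returns_prior(self, bank13, grid):
        sp = pl.eap_score(np.full(13, MISSING), bank13, grid)
        assert sp.theta_eap == pytest.approx(0.0, abs=1e-9)
        assert sp.t_score == pytest.approx(50.0, abs=1e-7)
        assert sp.se_eap == pytest.approx(1.0, abs=0.01)

    def test_agrees_with_continuous_integration_oracle(self, bank13):
        """EAP on a fine grid matches adaptive quadrature to 1e-6."""
        fine = pl.make_grid(1001, 8.0)
        rng = np.random.default_rng(3)
        for _ in range(20):
            pat = np.array([rng.integers(0, it.n_cat) for it in bank13])
            sp = pl.eap_score(pat, bank13, fine)
            shift = pl.pattern_loglik(pat, bank13, sp.theta_eap)

            def f(t):
                return np.exp(pl.pattern_loglik(pat, bank13, t) - shift) * stats.norm.pdf(t)

            num = integrate.quad(lambda t: t * f(t), -10, 10, limit=400,
                                 epsabs=1e-13, epsrel=1e-12)[0]
            den = integrate.quad(f, -10, 10, limit=400,
                                 epsabs=1e-13, epsrel=1e-12)[0]
            assert abs(sp.theta_eap - num / den) < 1e-6

    def test_monotone_in_responses_exhaustive(self, bank3, grid):
        """Raising any single response never lowers the EAP estimate."""
        scores = {}
        for pat in itertools.product(range(3), repeat=3):
            scores[pat] = pl.eap_score(np.array(pat), bank3, grid).theta_eap
        for pat, th in scores.items():
            for j in range(3):
                if pat[j] < 2:
                    up = list(pat)
                    up[j] += 1
                    assert scores[tuple(up)] >= th

    def test_se_decreases_with_added_items(self, bank13, grid):
        pat = np.full(13, MISSING)
        prev = pl.eap_score(pat, bank13, grid).se_eap
        for j in range(13):
            pat[j] = 2
            se = pl.eap_score(pat, bank13, grid).se_eap
            assert se <= prev + 1e-9
            prev = se


class TestTscore:
    def test_reference_points(self):
        assert pl.to_tscore(0.0) == 50.0
        assert pl.to_tscore(1.0) == 60.0
        assert pl.to_tscore(-2.8) == pytest.approx(22.0)

    def test_affine_order_preserving(self, rng):
        x = rng.normal(size=50)
        t = pl.to_tscore(x)
        assert np.array_equal(np.argsort(x), np.argsort(t))


class TestLordWingersky:
    def test_single_item_equals_category_probs(self, bank3):
        sub = pl.ItemBank([bank3[0]])
        assert np.allclose(
            pl.lw_sumscore_dist(sub, 0.3), pl.grm_category_probs(bank3[0], 0.3)
        )

    def test_sums_to_one(self, bank13):
        for th in (-2.0, 0.0, 1.5):
            f = pl.lw_sumscore_dist(bank13, th)
            assert f.sum() == pytest.approx(1.0, abs=1e-12)
            assert len(f) == bank13.max_sum_score + 1

    def test_matches_exhaustive_pattern_enumeration(self, bank3):
        """27-pattern enumeration oracle at several trait values."""
        for th in (-1.0, 0.2, 2.0):
            probs = [pl.grm_category_probs(it, th) for it in bank3]
            brute = np.zeros(7)
            for pat in itertools.product(range(3), repeat=3):
                brute[sum(pat)] += np.prod([probs[j][k] for j, k in enumerate(pat)])
            assert np.allclose(pl.lw_sumscore_dist(bank3, th), brute, atol=1e-12)


class TestEMCalibration:
    def test_all_fixed_returns_bank_unchanged(self, bank13, rm2000, grid):
        res = pl.em_calibrate(rm2000, bank13, grid, fix_mask=np.ones(13, bool))
        assert res.n_cycles == 0
        assert res.converged
        assert res.bank_out == bank13
        assert len(res.loglik_trace) == 1

    def test_recovery_and_monotone_loglik(self, bank13, calibration):
        est = calibration.bank_out
        free = [i for i in bank13.item_ids if not bank13[i].fixed]
        mae_a = np.mean([abs(est[i].slope - bank13[i].slope) for i in free])
        mae_b = np.mean(
            [
                np.mean(np.abs(np.array(est[i].thresholds) - np.array(bank13[i].thresholds)))
                for i in free
            ]
        )
        assert mae_a < 0.15
        assert mae_b < 0.15
        trace = np.array(calibration.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8)
        assert calibration.converged

    def test_anchors_byte_identical(self, bank13, calibration):
        for iid in ("ANC_1", "ANC_2", "ANC_3", "ANC_4"):
            assert calibration.bank_out[iid] == bank13[iid]

    def test_stationary_near_truth(self):
        """One EM cycle started at the generating truth barely moves in
        aggregate (each parameter's own movement is bounded by its sampling
        error, so the mean absolute change is the stationarity measure)."""
        items = [
            pl.Item(f"a{j}", "anchor", a, tuple(b), fixed=j < 4)
            for j, (a, b) in enumerate(
                [
                    (1.8, (-2.0, -0.8, 0.5, 1.7)),
                    (1.2, (-1.5, -0.4, 0.8, 2.0)),
                    (2.2, (-1.8, -0.6, 0.4, 1.5)),
                    (1.5, (-2.2, -1.0, 0.2, 1.4)),
                    (1.0, (-1.6, -0.5, 0.6, 1.8)),
                    (1.7, (-2.1, -0.9, 0.3, 1.6)),
                    (2.0, (-1.4, -0.3, 0.7, 1.9)),
                ]
            )
        ]
        bank = pl.ItemBank(items)
        rm = pl.simulate_unidimensional(bank, 10000, seed=77)
        with pytest.warns(RuntimeWarning, match="EM did not converge"):
            res = pl.em_calibrate(rm, bank, pl.make_grid(), tol=1e-12, max_cycles=1)
        free = [i.item_id for i in bank if not i.fixed]
        moves = []
        for iid in free:
            moves.append(abs(res.bank_out[iid].slope - bank[iid].slope))
            moves.extend(
                np.abs(np.array(res.bank_out[iid].thresholds) - np.array(bank[iid].thresholds))
            )
        assert np.mean(moves) < 0.02

    def test_empty_category_collapse(self, grid):
        bank = pl.ItemBank(
            [
                pl.Item("a", "anchor", 1.5, (-1.0, 0.0, 1.0), fixed=True),
                pl.Item("f", "new", 1.5, (-1.0, 0.0, 8.0)),
            ]
        )
        rm = pl.simulate_unidimensional(bank, 400, seed=5)
        assert (rm.responses[:, 1] == 3).sum() == 0  # top category unattained
        res = pl.em_calibrate(rm, bank, grid)
        assert "f" in res.collapsed
        assert res.bank_out["f"].n_cat == 3


class TestStandardErrors:
    def test_observed_information_ses_scale_with_n(self, grid):
        """SEs are positive and shrink roughly like 1/sqrt(n)."""
        bank = pl.ItemBank(
            [
                pl.Item("a1", "anchor", 1.5, (-1.5, 0.0, 1.5), fixed=True),
                pl.Item("a2", "anchor", 1.2, (-1.0, 0.2, 1.2), fixed=True),
                pl.Item("f1", "new", 1.8, (-1.2, -0.2, 1.0)),
            ]
        )
        ses = {}
        for n in (400, 1600):
            rm = pl.simulate_unidimensional(bank, n, seed=61)
            ses[n] = pl.calibration_standard_errors(rm, bank, grid)["f1"]
            assert (ses[n] > 0).all()
        ratio = ses[400] / ses[1600]
        assert np.all(ratio > 1.4) and np.all(ratio < 3.0)


class TestSX2:
    def test_statistic_nonnegative_with_df(self, bank13, rm2000, grid):
        fits = pl.s_x2_itemfit(rm2000, bank13, grid)
        assert len(fits) == 13
        for f in fits:
            assert f.s_x2 >= 0
            assert f.p is None or f.df >= 1

    def test_gross_misfit_detected(self, grid):
        """An item generated with slope 3 but scored at slope 0.8 misfits."""
        items = [
            pl.Item(f"a{j}", "anchor", 1.5, (-1.5, -0.5, 0.5, 1.5), fixed=True)
            for j in range(5)
        ]
        true_bank = pl.ItemBank(items + [pl.Item("bad", "new", 3.0, (-1.0, 0.0, 1.0))])
        rm = pl.simulate_unidimensional(true_bank, 2000, seed=19)
        wrong = true_bank.replace_item(pl.Item("bad", "new", 0.8, (-1.0, 0.0, 1.0)))
        fits = {f.item_id: f for f in pl.s_x2_itemfit(rm, wrong, grid)}
        assert fits["bad"].p < 0.001
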