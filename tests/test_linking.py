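import itertools

import numpy as np
import pytest

import perflink as pl
from perflink.data import MISSING


class TestFixedAnchorLink:
    def test_anchor_rows_identical_to_input(self, bank13, calibration):
        for it in bank13:
            if it.fixed:
                assert calibration.bank_out[it.item_id] == it

    def test_metric_follows_anchors_exact_equivariance(self, bank13, rm2000, grid):
        """Shifting the anchors AND the reference population by +1 shifts
        every free-item threshold by exactly +1 (change of variables in the
        marginal likelihood): the link inherits the anchor metric."""
        free = [i for i in bank13.item_ids if not bank13[i].fixed]
        base = pl.fixed_anchor_link(
            rm2000, pl.ItemBank([it for it in bank13 if it.fixed]), free, grid
        )
        shifted_anchors = pl.ItemBank(
            [it.with_shifted_thresholds(1.0) for it in bank13 if it.fixed]
        )
        shifted_grid = pl.QuadratureGrid(grid.nodes + 1.0, grid.weights)
        shifted = pl.fixed_anchor_link(rm2000, shifted_anchors, free, shifted_grid)
        for i in free:
            assert np.allclose(
                np.array(shifted.bank_out[i].thresholds),
                np.array(base.bank_out[i].thresholds) + 1.0,
                atol=5e-4,
            )
            assert shifted.bank_out[i].slope == pytest.approx(
                base.bank_out[i].slope, abs=5e-4
            )

    def test_fixed_prior_shrinks_anchor_shift(self, bank13, rm2000, grid):
        """With the prior held at N(0,1) a +1 anchor mis-scaling still pulls
        the free thresholds up, but shrinkage keeps the shift below +1."""
        free = [i for i in bank13.item_ids if not bank13[i].fixed]
        base = pl.fixed_anchor_link(
            rm2000, pl.ItemBank([it for it in bank13 if it.fixed]), free, grid
        )
        shifted_anchors = pl.ItemBank(
            [it.with_shifted_thresholds(1.0) for it in bank13 if it.fixed]
        )
        shifted = pl.fixed_anchor_link(rm2000, shifted_anchors, free, grid)
        deltas = [
            np.mean(
                np.array(shifted.bank_out[i].thresholds)
                - np.array(base.bank_out[i].thresholds)
            )
            for i in free
        ]
        assert 0.3 < np.mean(deltas) < 1.0

    def test_zero_free_items_rejected(self, bank13, rm2000):
        with pytest.raises(ValueError, match="no free items"):
            pl.fixed_anchor_link(rm2000, bank13, [])

    def test_anchor_absent_from_data_rejected(self, bank13, rm2000):
        extra = pl.ItemBank(
            list(bank13) + [pl.Item("GHOST", "anchor", 1.0, (0.0,), fixed=True)]
        )
        with pytest.raises(ValueError, match="absent"):
            pl.fixed_anchor_link(rm2000, extra, ["NEW_1"])


class TestCrosswalk:
    def test_single_item_crosswalk_equals_pattern_eap(self, bank3, grid):
        sub = pl.ItemBank([bank3[0]])
        xw = pl.build_crosswalk(sub, grid)
        for k in range(3):
            sp = pl.eap_score(np.array([k]), sub, grid)
            row = xw.lookup(k)
            assert row["theta"] == pytest.approx(sp.theta_eap, abs=1e-12)
            assert row["se"] == pytest.approx(sp.se_eap, abs=1e-12)

    def test_matches_brute_force_bayes_by_sum_score(self, bank3, grid):
        """Enumerate all 27 patterns, group by sum score, average the
        posterior directly — must match the recursion-based table."""
        xw = pl.build_crosswalk(bank3, grid)
        probs = [
            np.stack([pl.grm_category_probs(it, th) for th in grid.nodes], axis=1)
            for it in bank3
        ]
        num = np.zeros(7)
        den = np.zeros(7)
        for pat in itertools.product(range(3), repeat=3):
            like = probs[0][pat[0]] * probs[1][pat[1]] * probs[2][pat[2]]
            mass = like * grid.weights
            num[sum(pat)] += mass @ grid.nodes
            den[sum(pat)] += mass.sum()
        brute_theta = num / den
        assert np.allclose(xw.table["theta"], brute_theta, atol=1e-10)

    def test_monotone_with_consistent_endpoints(self, bank13, grid):
        xw = pl.build_crosswalk(bank13, grid)
        th = xw.table["theta"].to_numpy()
        assert np.all(np.diff(th) > 0)
        assert xw.table["t_score"].iloc[0] == xw.table["t_score"].min()
        assert xw.table["t_score"].iloc[-1] == xw.table["t_score"].max()
        assert len(xw.table) == bank13.max_sum_score + 1

    def test_round_trip_is_bit_identical(self, bank13, grid, tmp_path):
        """CSV round trip of the bank, then rebuild: identical crosswalk."""
        p = tmp_path / "bank.csv"
        bank13.write_csv(p)
        again = pl.ItemBank.read_csv(p)
        xw1 = pl.build_crosswalk(bank13, grid)
        xw2 = pl.build_crosswalk(again, grid)
        assert xw1.table.equals(xw2.table)
        # and the table itself round-trips through CSV with metadata
        q = tmp_path / "xw.csv"
        xw1.write_csv(q)
        back = pl.CrosswalkTable.read_csv(q)
        assert back.item_subset == xw1.item_subset
        assert back.bank_hash == xw1.bank_hash
        assert np.allclose(back.table["theta"], xw1.table["theta"])

    def test_t_to_sum_ties_to_lower(self, bank3, grid):
        xw = pl.build_crosswalk(bank3, grid)
        t = xw.table["t_score"]
        assert xw.t_to_sum(float(t.iloc[2])) == 2
        midpoint = float((t.iloc[2] + t.iloc[3]) / 2)
        assert xw.t_to_sum(midpoint) == 2


class TestConvertScores:
    def test_complete_responses_use_lookup(self, bank3, grid):
        xw = pl.build_crosswalk(bank3, grid)
        rm = pl.ResponseMatrix(np.array([[0, 0, 0], [2, 2, 2], [1, 0, 2]]), bank3.item_ids)
        scored = pl.convert_scores(rm, xw, bank3, grid)
        assert all(s.method == "sumscore_lookup" for s in scored)
        assert scored[0].t_score == pytest.approx(float(xw.table["t_score"].iloc[0]))
        assert scored[1].t_score == pytest.approx(float(xw.table["t_score"].iloc[-1]))
        assert scored[2].t_score == pytest.approx(float(xw.lookup(3)["t_score"]))

    def test_incomplete_pattern_uses_pattern_eap(self, bank3, grid):
        xw = pl.build_crosswalk(bank3, grid)
        rm = pl.ResponseMatrix(np.array([[1, MISSING, 2]]), bank3.item_ids)
        scored = pl.convert_scores(rm, xw, bank3, grid)
        assert scored[0].method == "pattern_eap"
        assert scored[0].items_used == 2
        sp = pl.eap_score(np.array([1, MISSING, 2]), bank3, grid)
        assert scored[0].theta_eap == pytest.approx(sp.theta_eap, abs=1e-12)

    def test_pattern_and_sumscore_eap_agree_in_rms(self, grid):
        """The two scoring routes are close (documented consistency, not
        equality): RMS difference under 0.15 theta on a 9-item battery of
        reasonably discriminating items."""
        bank = pl.make_item_bank(4, 9, 5, slope_range=(1.3, 2.5), seed=42)
        rm = pl.simulate_unidimensional(bank, 2000, seed=43)
        new_ids = [i for i in bank.item_ids if not bank[i].fixed]
        sub = bank.subset(new_ids)
        X = rm.columns(new_ids)
        theta_pat, _, _ = pl.eap_score_matrix(X, sub, grid)
        xw = pl.build_crosswalk(sub, grid)
        theta_sum = xw.table["theta"].to_numpy()[X.sum(axis=1)]
        rms = np.sqrt(np.mean((theta_pat - theta_sum) ** 2))
        assert rms < 0.15


class TestGRMLinkerEstimator:
    def test_fit_transform_and_crosswalk(self, bank13, rm2000):
        anchors = pl.ItemBank([it for it in bank13 if it.fixed])
        linker = pl.GRMLinker(anchor_bank=anchors, max_cycles=200).fit(rm2000)
        assert linker.converged_
        scores = linker.transform(rm2000)
        assert set(scores.columns) >= {"theta", "se", "t_score", "items_used"}
        assert np.allclose(scores["t_score"], 10 * scores["theta"] + 50)
        xw = linker.crosswalk()
        assert len(xw.table) == 9 * 4 + 1
        assert linker.get_params()["n_nodes"] == 61
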