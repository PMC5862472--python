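import numpy as np
import pytest

from polycat.cat_engine import (
    CatConfig,
    CatSession,
    age_equivalent,
    check_stop,
    map_estimate,
    run_cat,
    select_next_item,
)
from polycat.gpcm import ThetaEstimate, category_probabilities, item_information
from polycat.item_bank import MISSING, ItemBank, ItemParameters
from polycat.simulate import simulate_responses


class TestMapEstimate:
    def test_no_responses_returns_prior(self, recovery_bank):
        est = map_estimate(recovery_bank, [MISSING] * 10)
        assert est.theta == 0.0 and est.se == 1.0 and est.reliability == 0.0

    def test_matches_fine_grid_search(self, recovery_bank):
        rng = np.random.default_rng(42)
        grid = np.arange(-6, 6 + 1e-9, 1e-4)
        for _ in range(25):
            resp = np.array(
                [
                    rng.integers(0, it.n_categories) if rng.random() > 0.3 else MISSING
                    for it in recovery_bank
                ]
            )
            if np.all(resp == MISSING):
                continue
            est = map_estimate(recovery_bank, resp)
            lp = -0.5 * grid**2
            for it, k in zip(recovery_bank, resp):
                if k != MISSING:
                    lp += np.log(category_probabilities(it, grid)[:, k])
            assert abs(est.theta - grid[np.argmax(lp)]) < 1e-4

    def test_extreme_responses_shrunk_finite(self, recovery_bank):
        resp = [it.max_category for it in recovery_bank]
        est = map_estimate(recovery_bank, resp)
        assert np.isfinite(est.theta) and 0 < est.theta < 6
        resp0 = [0] * len(recovery_bank)
        assert map_estimate(recovery_bank, resp0).theta < 0

    def test_ci_and_reliability_consistent(self, recovery_bank):
        est = map_estimate(recovery_bank, [1, 0, 1, MISSING, 0, 1, 2, 0, 1, 2])
        lo, hi = est.ci95
        assert lo == pytest.approx(est.theta - 1.96 * est.se)
        assert hi == pytest.approx(est.theta + 1.96 * est.se)
        assert est.reliability == pytest.approx(1 - est.se**2, abs=1e-12)

    def test_item_order_invariance(self, recovery_bank):
        resp = [1, 0, 1, 1, 0, 1, 2, 0, 1, 2]
        est = map_estimate(recovery_bank, resp)
        perm = [7, 2, 9, 0, 4, 1, 8, 3, 6, 5]
        shuffled = ItemBank([recovery_bank.items[i] for i in perm], "perm")
        est2 = map_estimate(shuffled, [resp[i] for i in perm])
        assert est2.theta == pytest.approx(est.theta, abs=1e-10)


class TestSelection:
    def test_first_item_identical_for_everyone(self, recovery_bank):
        first = select_next_item(recovery_bank, CatSession(), 0.0)
        info = {it.item_id: item_information(it, 0.0) for it in recovery_bank}
        assert first == max(info, key=info.get)

    def test_tie_breaks_to_earlier_index(self):
        twin = ItemParameters("TWIN1", 1.5, (0.0,), 2)
        twin2 = ItemParameters("TWIN2", 1.5, (0.0,), 2)
        bank = ItemBank([twin, twin2])
        assert select_next_item(bank, CatSession(), 0.0) == "TWIN1"

    def test_administered_item_excluded(self, recovery_bank):
        sess = CatSession()
        first = select_next_item(recovery_bank, sess, 0.0)
        sess.administered.append(first)
        assert select_next_item(recovery_bank, sess, 0.0) != first

    def test_exhausted_bank_raises(self):
        bank = ItemBank([ItemParameters("A", 1.0, (0.0,), 2)])
        sess = CatSession()
        sess.administered.append("A")
        with pytest.raises(RuntimeError, match="exhausted"):
            select_next_item(bank, sess, 0.0)


class TestStopping:
    def make_session(self, reliability, n_items):
        sess = CatSession()
        for i in range(n_items):
            sess.administered.append(f"I{i}")
            sess.responses.append(0)
            se = float(np.sqrt(1 - reliability)) if reliability < 1 else 1e-6
            sess.theta_trajectory.append(
                ThetaEstimate(0.0, se, reliability, (-1.0, 1.0))
            )
        return sess

    def test_reliability_rule(self):
        sess = self.make_session(0.91, 5)
        assert check_stop(sess, CatConfig()) == "stop_reliability"

    def test_max_items_rule(self):
        sess = self.make_session(0.85, 14)
        assert check_stop(sess, CatConfig()) == "stop_max_items"

    def test_continue(self):
        sess = self.make_session(0.89, 13)
        assert check_stop(sess, CatConfig()) == "continue"

    def test_reliability_has_precedence(self):
        sess = self.make_session(0.95, 14)
        assert check_stop(sess, CatConfig()) == "stop_reliability"


class TestRunCat:
    def responder_for(self, bank, theta, seed=0):
        rng = np.random.default_rng(seed)

        def responder(iid):
            p = category_probabilities(bank[iid], theta)
            return int(rng.choice(len(p), p=p))

        return responder

    def test_average_respondent_stops_by_reliability(self, recovery_bank):
        from polycat.synthetic import generate_bank

        bank = generate_bank()  # default 56-item bank
        session, report = run_cat(bank, self.responder_for(bank, 0.0, seed=5))
        assert report.stop_reason == "reliability"
        assert report.n_items <= 14
        assert report.final.reliability >= 0.9
        assert report.items_saved_fraction == pytest.approx(1 - report.n_items / 56)

    def test_max_items_one_boundary(self, recovery_bank):
        cfg = CatConfig(max_items=1)
        session, report = run_cat(
            recovery_bank, self.responder_for(recovery_bank, 0.0, seed=1), cfg
        )
        assert report.n_items == 1
        assert report.stop_reason == "max_items"

    def test_deterministic_replay(self, recovery_bank):
        thetas = np.array([0.3])
        rm = simulate_responses(recovery_bank, thetas, 9)
        row = rm.values[0]

        def responder(iid):
            return int(row[recovery_bank.position(iid)])

        s1, r1 = run_cat(recovery_bank, responder)
        s2, r2 = run_cat(recovery_bank, responder)
        assert s1.administered == s2.administered
        assert s1.responses == s2.responses
        assert r1.final.theta == r2.final.theta

    def test_posterior_information_strictly_increases(self, recovery_bank):
        thetas = np.array([-0.5])
        rm = simulate_responses(recovery_bank, thetas, 10)
        row = rm.values[0]
        cfg = CatConfig(reliability_threshold=0.99, max_items=10)
        session, _ = run_cat(
            recovery_bank, lambda iid: int(row[recovery_bank.position(iid)]), cfg
        )
        info = [1.0 / est.se**2 for est in session.theta_trajectory]
        assert np.all(np.diff(info) > 0)

    def test_reliability_stop_bounds_final_se(self, recovery_bank):
        from polycat.synthetic import generate_bank

        bank = generate_bank()
        cfg = CatConfig()
        _, report = run_cat(bank, self.responder_for(bank, 1.0, seed=2), cfg)
        if report.stop_reason == "reliability":
            assert report.final.se <= np.sqrt(1 - cfg.reliability_threshold) + 1e-12

    def test_out_of_range_responder_aborts_with_context(self, recovery_bank):
        with pytest.raises(ValueError, match="responder returned"):
            run_cat(recovery_bank, lambda iid: 9)

    def test_session_lengths_consistent(self, recovery_bank):
        session, report = run_cat(
            recovery_bank, self.responder_for(recovery_bank, 0.5, seed=3)
        )
        assert (
            len(session.administered)
            == len(session.responses)
            == len(session.theta_trajectory)
            == report.n_items
        )
        assert len(set(session.administered)) == report.n_items


class TestAgeEquivalent:
    TABLE = [(1.0, -2.0), (3.0, -1.0), (5.0, 0.0), (8.0, 1.5), (12.0, 3.0)]

    def estimate(self, theta, se=0.25):
        return ThetaEstimate.from_theta_se(theta, se)

    def test_node_is_exact(self):
        res = age_equivalent(self.estimate(0.0, 0.1), self.TABLE)
        assert res.value == pytest.approx(5.0)

    def test_midpoint_interpolation(self):
        res = age_equivalent(self.estimate(-0.5, 0.1), self.TABLE)
        assert res.value == pytest.approx(4.0)

    def test_below_range_clamps_and_flags(self):
        res = age_equivalent(self.estimate(-5.0, 0.1), self.TABLE)
        assert res.value == pytest.approx(1.0)
        assert res.clamped

    def test_ci_maps_through_interpolation(self):
        est = self.estimate(0.0, 0.25)
        res = age_equivalent(est, self.TABLE)
        lo, hi = res.ci95
        assert lo < res.value < hi

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            age_equivalent(self.estimate(0.0), [])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CatConfig(reliability_threshold=1.5)
        with pytest.raises(ValueError):
            CatConfig(max_items=0)
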