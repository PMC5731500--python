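"""BDS kernel, calibration densities and the incremental prior transactions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import gammaln

from chronosite import (
    BDSParams,
    CalibrationSpec,
    PriorState,
    bds_cdf,
    bds_inverse_cdf,
    bds_pdf,
    calibration_logpdf,
    full_log_prior,
    parse_newick,
)
from chronosite.prior import segment_count, segment_log_gprime, segment_log_h
from conftest import random_bds_tree

PARAM_GRID = [
    BDSParams(2.0, 1.0, 0.5),
    BDSParams(1.0, 0.2, 1.0),
    BDSParams(1.0, 1.0, 0.3),   # lam == mu branch
    BDSParams(0.5, 1.5, 0.8),   # subcritical
]


class TestBDSKernel:
    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_pdf_integrates_to_one(self, params):
        total, _ = quad(lambda t: bds_pdf(t, params, 1.3), 0, 1.3, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_cdf_endpoints_and_monotone(self, params):
        t_R = 0.9
        assert bds_cdf(0.0, params, t_R) == pytest.approx(0.0, abs=1e-12)
        assert bds_cdf(t_R, params, t_R) == pytest.approx(1.0, abs=1e-12)
        grid = np.linspace(0, t_R, 200)
        assert (np.diff(bds_cdf(grid, params, t_R)) > 0).all()

    def test_cdf_derivative_matches_pdf(self, rng):
        params = BDSParams(2.0, 1.0, 0.5)
        t_R, h = 1.0, 1e-6
        for t in rng.uniform(0.01, 0.99, size=50):
            fd = (bds_cdf(t + h, params, t_R) - bds_cdf(t - h, params, t_R)) / (2 * h)
            assert fd == pytest.approx(float(bds_pdf(t, params, t_R)), abs=1e-6, rel=1e-5)

    def test_equal_rates_closed_form_is_the_limit(self):
        """lam == mu branch equals the lam -> mu limit of the general form."""
        t_R, mu = 1.0, 1.0
        eps = 1e-7
        for t in (0.1, 0.4, 0.8):
            for f in (bds_pdf, bds_cdf):
                hi = float(f(t, BDSParams(mu * (1 + eps), mu, 0.5), t_R))
                lo = float(f(t, BDSParams(mu * (1 - eps), mu, 0.5), t_R))
                exact = float(f(t, BDSParams(mu, mu, 0.5), t_R))
                assert 0.5 * (hi + lo) == pytest.approx(exact, abs=1e-8)

    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_inverse_cdf_round_trip(self, params, rng):
        q = rng.uniform(0.001, 0.999, size=100)
        t = bds_inverse_cdf(q, params, 2.0)
        assert np.allclose(bds_cdf(t, params, 2.0), q, atol=1e-10)

    def test_domain_errors(self):
        p = BDSParams()
        with pytest.raises(ValueError):
            bds_pdf(-0.1, p, 1.0)
        with pytest.raises(ValueError):
            bds_cdf(1.5, p, 1.0)


class TestCalibrationDensity:
    SPEC = CalibrationSpec(frozenset("AB"), 0.5, 1.0, tail_prob=0.025)

    def test_total_mass_one(self):
        total, _ = quad(
            lambda t: math.exp(calibration_logpdf(self.SPEC, t)), -10, 40, limit=500
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_plateau_height(self):
        expected = math.log((1 - 2 * 0.025) / (1.0 - 0.5))
        assert calibration_logpdf(self.SPEC, 0.75) == pytest.approx(expected, abs=1e-12)

    def test_tail_mass(self):
        below, _ = quad(
            lambda t: math.exp(calibration_logpdf(self.SPEC, t)), -10, 0.5, limit=500
        )
        above, _ = quad(
            lambda t: math.exp(calibration_logpdf(self.SPEC, t)), 1.0, 40, limit=500
        )
        assert below == pytest.approx(0.025, abs=1e-6)
        assert above == pytest.approx(0.025, abs=1e-6)

    def test_continuity_at_bounds(self):
        eps = 1e-9
        for b in (0.5, 1.0):
            assert calibration_logpdf(self.SPEC, b - eps) == pytest.approx(
                calibration_logpdf(self.SPEC, b + eps), abs=1e-6
            )


class TestSegmentEvaluators:
    def test_adjacent_calibrations_empty_segment(self):
        assert segment_log_h(1, [3, 4], 10, 2) == 0.0  # 0! between adjacent ranks

    def test_hand_enumeration_n6_c1(self):
        # n = 6 leaves -> 4 sorted ages; calibration at rank 2 splits them
        # into segments of 1 and 2 non-calibration ages
        assert segment_count(0, [2], 6) == 1
        assert segment_count(1, [2], 6) == 2
        assert segment_log_h(0, [2], 6, 1) == pytest.approx(math.log(1))
        assert segment_log_h(1, [2], 6, 1) == pytest.approx(math.log(2))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.data())
    def test_partition_identity(self, data):
        n = data.draw(st.integers(4, 60))
        c = data.draw(st.integers(0, min(6, n - 2)))
        ranks = sorted(
            data.draw(
                st.lists(
                    st.integers(1, n - 2), min_size=c, max_size=c, unique=True
                )
            )
        )
        total = sum(segment_count(i, ranks, n) for i in range(c + 1))
        assert total == n - 2 - c

    def test_gprime_zero_exponent(self):
        # adjacent ranks: empty segment, ln G' = 0 regardless of the base
        assert segment_log_gprime(1, [0.7, 0.7], [3, 4], 10, 2) == 0.0

    def test_gprime_c1_substitution(self):
        n, R, G = 8, 3, 0.42
        total = segment_log_gprime(0, [G], [R], n, 1) + segment_log_gprime(
            1, [G], [R], n, 1
        )
        expected = (R - 1) * math.log(G) + (n - 2 - R) * math.log(1 - G)
        assert total == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_base_signals_invalid_state(self):
        assert segment_log_gprime(1, [0.7, 0.4], [2, 5], 10, 2) == -math.inf

    def test_order_statistic_marginal_against_monte_carlo(self, rng):
        """Reassembled rank density matches simulation on a 5-age toy.

        The marginal of the k-th order statistic of m i.i.d. draws from g is
        m!/(h(0) h(1)) * G^{k-1} (1-G)^{m-k} * g, i.e. exactly the one-
        calibration segment terms.  Compare against a histogram of sorted
        kernel draws (coarse 5% tolerance on well-filled bins).
        """
        params = BDSParams(2.0, 1.0, 0.5)
        m, k, t_R = 5, 2, 1.0   # 5 ages = 7-leaf tree; rank 2
        n = m + 2
        draws = np.sort(
            bds_inverse_cdf(rng.uniform(size=(200_000, m)), params, t_R), axis=1
        )[:, k - 1]
        hist, edges = np.histogram(draws, bins=25, range=(0, t_R), density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        G = bds_cdf(centers, params, t_R)
        dens = np.array(
            [
                math.exp(
                    gammaln(m + 1)
                    - segment_log_h(0, [k], n, 1)
                    - segment_log_h(1, [k], n, 1)
                    + segment_log_gprime(0, [g], [k], n, 1)
                    + segment_log_gprime(1, [g], [k], n, 1)
                )
                * bds_pdf(t, params, t_R)
                for t, g in zip(centers, G)
            ]
        )
        well_filled = hist > 0.2
        assert np.allclose(hist[well_filled], dens[well_filled], rtol=0.05)


def build_state(n, cal_fracs, seed, bds=BDSParams()):
    """Random BDS tree with calibrations at given age-quantile positions."""
    tree = random_bds_tree(n, seed)
    internals = sorted(
        (i for i in tree.internal_ids() if i != tree.root_id),
        key=lambda i: tree.nodes[i].age,
    )
    cals = {}
    for frac in cal_fracs:
        nid = internals[int(frac * (len(internals) - 1))]
        if nid in cals:
            continue
        a = tree.nodes[nid].age
        cals[nid] = CalibrationSpec(
            tree.leaves_below(nid), max(1e-4, 0.8 * a), 1.2 * a + 1e-3
        )
    cals[tree.root_id] = CalibrationSpec(
        tree.leaves_below(tree.root_id), 0.9, 1.1
    )
    return tree, PriorState(tree, cals, bds)


class TestPriorState:
    def test_no_internal_calibrations_collapses_to_sum_log_g(self):
        tree, state = build_state(8, [], seed=3)
        assert len(state.cdv_log_h) == 1
        expected = sum(
            math.log(float(bds_pdf(tree.nodes[i].age, state.params, tree.root.age)))
            for i in tree.internal_ids()
            if i != tree.root_id
        ) + calibration_logpdf(state.specs[tree.root_id], tree.root.age)
        assert state.total_log_prior == pytest.approx(expected, abs=1e-10)

    def test_four_leaf_one_calibration_sizes(self):
        tree, state = build_state(4, [0.0], seed=5)
        assert len(state.order) == 2          # APV covers the n-2 free ages
        assert len(state.cdv_log_h) == 2      # c+1 segments

    def test_apv_sorted_ascending(self):
        _, state = build_state(25, [0.2, 0.7], seed=9)
        ages = [state.ages[nid] for nid in state.order]
        assert ages == sorted(ages)

    def test_missing_root_calibration_rejected(self):
        tree = random_bds_tree(6, 4)
        with pytest.raises(ValueError, match="root"):
            PriorState(tree, {}, BDSParams())

    def test_init_matches_full_recompute(self):
        for seed in (1, 2, 3):
            _, state = build_state(12, [0.3, 0.8], seed=seed)
            assert state.total_log_prior == pytest.approx(
                full_log_prior(state), abs=1e-10
            )


def random_proposal(tree, rng):
    internals = tree.internal_ids()
    nid = internals[int(rng.integers(len(internals)))]
    node = tree.nodes[nid]
    lo = max(tree.nodes[c].age for c in node.children)
    hi = (
        tree.nodes[node.parent].age
        if node.parent is not None
        else node.age + rng.uniform(0, 0.3)
    )
    return nid, float(rng.uniform(lo, hi))


class TestTransactions:
    def test_reproposing_current_age_is_neutral(self):
        tree, state = build_state(10, [0.5], seed=7)
        nid = state.order[1]
        delta = state.propose_age_update(nid, state.ages[nid])
        assert delta == pytest.approx(0.0, abs=1e-12)
        state.commit()

    def test_incremental_matches_oracle_all_classes(self, rng):
        classes_seen = set()
        for seed in range(6):
            tree, state = build_state(
                int(rng.integers(5, 41)),
                list(rng.uniform(0, 1, size=int(rng.integers(0, 6)))),
                seed=seed,
            )
            for _ in range(300):
                nid, age = random_proposal(tree, rng)
                state.propose_age_update(nid, age)
                assert state.total_log_prior == pytest.approx(
                    full_log_prior(state), abs=1e-9
                )
                if rng.uniform() < 0.5:
                    state.commit()
                else:
                    state.revert()
            classes_seen |= {
                k for k, v in state.transaction_counts.items() if v > 0 and k != "root"
            }
        assert classes_seen == {1, 2, 3, 4}

    def test_propose_revert_identity(self, rng):
        tree, state = build_state(15, [0.4, 0.9], seed=11)
        before = state.total_log_prior
        for _ in range(1000):
            nid, age = random_proposal(tree, rng)
            state.propose_age_update(nid, age)
            state.revert()
        assert state.total_log_prior == before
        fresh = PriorState(tree, state.specs, state.params)
        assert fresh.order == state.order
        assert fresh.total_log_prior == pytest.approx(state.total_log_prior, abs=1e-12)

    def test_revert_restores_class_specific_caches(self, rng):
        tree, state = build_state(12, [0.3, 0.7], seed=13)
        snap = state._snapshot()
        for _ in range(50):
            nid, age = random_proposal(tree, rng)
            state.propose_age_update(nid, age)
            state.revert()
        now = state._snapshot()
        for key in snap:
            assert snap[key] == now[key], key

    def test_noncal_crossing_two_calibrations_touches_three_cdv_entries(self):
        # balanced 8-leaf tree: the four cherry ancestors are mutually
        # unconstrained, so one of them can slide past two calibrated ones
        tree = parse_newick(
            "(((A,B),(C,D)),((E,F),(G,H)));"
        )
        ab = tree.mrca({"A", "B"})
        cd = tree.mrca({"C", "D"})
        ef = tree.mrca({"E", "F"})
        gh = tree.mrca({"G", "H"})
        abcd = tree.mrca({"A", "B", "C", "D"})
        efgh = tree.mrca({"E", "F", "G", "H"})
        for nid, age in [
            (ab, 0.10), (cd, 0.15), (ef, 0.20), (gh, 0.30),
            (abcd, 0.6), (efgh, 0.7),
        ]:
            tree.nodes[nid].age = age
        tree.root.age = 1.0
        cals = {
            cd: CalibrationSpec(tree.leaves_below(cd), 0.05, 0.5),
            ef: CalibrationSpec(tree.leaves_below(ef), 0.05, 0.5),
            tree.root_id: CalibrationSpec(tree.leaves_below(tree.root_id), 0.9, 1.1),
        }
        state = PriorState(tree, cals, BDSParams())
        delta = state.propose_age_update(ab, 0.25)  # crosses cd and ef
        assert state.last_cdv_recomputes == 3
        assert state.transaction_counts[2] == 1
        assert state.total_log_prior == pytest.approx(full_log_prior(state), abs=1e-10)
        state.commit()

    def test_calibration_move_without_reorder_single_cdf(self):
        """Class-3 transaction: one new CDF value, two G' entries refreshed."""
        tree, state = build_state(14, [0.5], seed=17)
        cid = state.cals[0]
        node = tree.nodes[cid]
        lo = max(tree.nodes[c].age for c in node.children)
        hi = tree.nodes[node.parent].age
        # nudge inside its own APV slot
        idx = state.pos[cid]
        neigh_lo = state.ages[state.order[idx - 1]] if idx > 0 else lo
        neigh_hi = (
            state.ages[state.order[idx + 1]]
            if idx < len(state.order) - 1
            else hi
        )
        new_age = 0.5 * (max(lo, neigh_lo) + min(hi, neigh_hi))
        state.propose_age_update(cid, new_age)
        assert state.transaction_counts[3] == 1
        assert state.last_cdv_recomputes == 2
        # the shortcut's result must equal directly recomputed segments
        j = state.cals.index(cid)
        ranks = state.ranks()
        gvals = [state.G[x] for x in state.cals]
        for seg in (j, j + 1):
            assert state.cdv_log_gp[seg] == pytest.approx(
                segment_log_gprime(seg, gvals, ranks, state.n, state.c), abs=1e-12
            )
        assert state.total_log_prior == pytest.approx(full_log_prior(state), abs=1e-10)
        state.commit()

    def test_root_age_change_refreshes_kernels(self):
        tree, state = build_state(9, [0.5], seed=19)
        delta = state.propose_age_update(tree.root_id, tree.root.age * 1.1)
        assert state.transaction_counts["root"] == 1
        assert state.total_log_prior == pytest.approx(full_log_prior(state), abs=1e-10)
        assert delta != 0.0
        state.revert()
        assert state.total_log_prior == pytest.approx(full_log_prior(state), abs=1e-10)
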