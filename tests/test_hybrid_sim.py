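"""Tests of the tip-agent layer: movement, branching, anastomosis, runs."""

import numpy as np
import pytest
from scipy.stats import chisquare

import angiopatch as ap
from angiopatch.hybrid_sim import ACTIVE, ANASTOMOSED, ARRIVED
from angiopatch.scheme import DualLattice


def make_tip(tip_id=0, site=(5, 5), birth=0.0, parent=None):
    return ap.TipAgent(id=tip_id, site=site, birth_time=birth, parent_id=parent)


class TestBranchingProbability:
    @pytest.mark.parametrize("c, expected", [
        (0.0, 0.0), (0.1, 0.0), (0.24999, 0.0),
        (0.25, 0.3), (0.40, 0.3),
        (0.45, 0.4), (0.50, 0.4), (0.599, 0.4),
        (0.60, 0.5), (0.699, 0.5),
        (0.70, 1.0), (0.99, 1.0), (1.5, 1.0),  # >= 1 clamps to top bracket
    ])
    def test_table(self, c, expected):
        assert ap.branching_probability(c, ct_sign=1.0, age=1.0,
                                        t_branching=0.5) == expected

    def test_falling_vegf_gates_off(self):
        assert ap.branching_probability(0.8, ct_sign=-1.0, age=5.0,
                                        t_branching=0.5) == 0.0
        assert ap.branching_probability(0.8, ct_sign=0.0, age=5.0,
                                        t_branching=0.5) == 0.0

    def test_young_sprout_gates_off(self):
        assert ap.branching_probability(0.8, ct_sign=1.0, age=0.2,
                                        t_branching=0.5) == 0.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            ap.branching_probability(-0.1, 1.0, 1.0, 0.5)


class TestInitialization:
    def test_default_placement(self):
        cfg = ap.SimConfig(seed=12)
        tips = ap.initialize_tips(cfg, np.random.default_rng(cfg.seed))
        assert len(tips) == 20
        assert all(t.site[0] == cfg.n_cells - 1 for t in tips)
        assert len({t.site for t in tips}) == 20  # without replacement
        assert all(t.birth_time == 0.0 for t in tips)

    def test_determinism(self):
        cfg = ap.SimConfig(seed=99)
        a = ap.initialize_tips(cfg, np.random.default_rng(cfg.seed))
        b = ap.initialize_tips(cfg, np.random.default_rng(cfg.seed))
        assert [t.site for t in a] == [t.site for t in b]

    def test_single_tip(self):
        cfg = ap.SimConfig(n_tips=1, seed=0)
        tips = ap.initialize_tips(cfg, np.random.default_rng(0))
        assert len(tips) == 1

    def test_overfull_boundary_rejected(self):
        with pytest.raises(ValueError):
            ap.SimConfig(n_tips=30, n_cells=25)


class TestMoveTip:
    def test_certain_stay(self):
        tip = make_tip()
        rng = np.random.default_rng(0)
        for _ in range(100):
            assert ap.move_tip(tip, (1.0, 0, 0, 0, 0), rng) == (5, 5)

    def test_uniform_neighbor_frequencies(self):
        tip = make_tip()
        rng = np.random.default_rng(8)
        probs = (0.0, 0.25, 0.25, 0.25, 0.25)
        draws = [ap.move_tip(tip, probs, rng) for _ in range(100_000)]
        counts = {s: 0 for s in [(4, 5), (6, 5), (5, 4), (5, 6)]}
        for d in draws:
            counts[d] += 1
        for c in counts.values():
            assert abs(c / 100_000 - 0.25) < 0.01  # ~3 sigma binomial band

    def test_empirical_frequencies_match_biased_tuple(self):
        tip = make_tip()
        rng = np.random.default_rng(21)
        probs = (0.35, 0.30, 0.05, 0.10, 0.20)
        sites = [(5, 5), (4, 5), (6, 5), (5, 4), (5, 6)]
        n_draws = 50_000
        counts = dict.fromkeys(sites, 0)
        for _ in range(n_draws):
            counts[ap.move_tip(tip, probs, rng)] += 1
        observed = [counts[s] for s in sites]
        expected = [p * n_draws for p in probs]
        assert chisquare(observed, expected).pvalue > 0.01


class TestBranchingDraws:
    def _rate(self, p, trials=10_000, seed=5):
        rng = np.random.default_rng(seed)
        net = ap.VesselNetwork()
        tip = make_tip()
        hits = sum(
            ap.apply_branching(tip, p, rng, net, t=1.0, new_id=k) is not None
            for k in range(trials))
        return hits / trials

    def test_zero_probability_never_branches(self):
        assert self._rate(0.0) == 0.0

    def test_unit_probability_always_branches(self):
        assert self._rate(1.0) == 1.0

    def test_intermediate_rate(self):
        assert abs(self._rate(0.4) - 0.4) < 0.02

    def test_daughter_is_distinct_vessel_at_same_site(self):
        rng = np.random.default_rng(0)
        net = ap.VesselNetwork()
        tip = make_tip(tip_id=3)
        d = ap.apply_branching(tip, 1.0, rng, net, t=2.5, new_id=7)
        assert d.site == tip.site and d.parent_id == 3 and d.id == 7
        assert d.birth_time == 2.5 and d.state == ACTIVE


class TestAnastomosis:
    def test_moving_onto_foreign_trail_terminates_mover(self):
        net = ap.VesselNetwork()
        occupant = make_tip(tip_id=0, site=(3, 3))
        net.claim((3, 3), 0)
        mover = make_tip(tip_id=1, site=(3, 4))
        net.claim((3, 4), 1)
        assert ap.apply_anastomosis(mover, (3, 3), net, t=1.0)
        assert mover.state == ANASTOMOSED
        assert occupant.state == ACTIVE
        assert net.occupant((3, 3)) == 0  # occupancy never reassigned

    def test_stay_is_exempt(self):
        net = ap.VesselNetwork()
        tip = make_tip(tip_id=1, site=(3, 4))
        assert not ap.apply_anastomosis(tip, (3, 4), net, t=1.0)
        assert tip.state == ACTIVE

    def test_own_trail_is_exempt(self):
        net = ap.VesselNetwork()
        tip = make_tip(tip_id=1, site=(3, 4))
        net.claim((3, 4), 1)
        ap.apply_anastomosis(tip, (3, 5), net, t=1.0)
        assert not ap.apply_anastomosis(tip, (3, 4), net, t=2.0)  # revisit
        assert tip.state == ACTIVE

    def test_simultaneous_proposal_tie_break(self):
        # two tips propose the same empty site: ascending id admits the
        # first; the second anastomoses against the updated occupancy
        net = ap.VesselNetwork()
        first = make_tip(tip_id=0, site=(2, 3))
        second = make_tip(tip_id=1, site=(4, 3))
        net.claim((2, 3), 0)
        net.claim((4, 3), 1)
        target = (3, 3)
        assert not ap.apply_anastomosis(first, target, net, t=1.0)
        assert ap.apply_anastomosis(second, target, net, t=1.0)
        assert first.state == ACTIVE and second.state == ANASTOMOSED


class TestPatchArrival:
    def test_inside_patch_arrives(self, default_params):
        lat = DualLattice(100)
        tip = make_tip(site=(4, 49))  # centre (0.045, 0.495), rp ~ 0.045
        assert ap.check_patch_arrival(tip, default_params, lat, t=3.0)
        assert tip.state == ARRIVED and tip.arrival_time == 3.0

    def test_far_tip_stays_active(self, default_params):
        lat = DualLattice(100)
        tip = make_tip(site=(50, 49))  # rp ~ 0.5
        assert not ap.check_patch_arrival(tip, default_params, lat, t=3.0)
        assert tip.state == ACTIVE


class TestRunSimulation:
    def test_degenerate_config_rejected(self):
        cfg = ap.SimConfig(d=0.0, beta=0.0, n_cells=20, n_tips=5)
        with pytest.raises(ap.StabilityError):
            ap.run_simulation(cfg)

    def test_bit_identical_for_same_seed(self):
        a = ap.run_simulation(ap.SimConfig(seed=17))
        b = ap.run_simulation(ap.SimConfig(seed=17))
        assert len(a.tips) == len(b.tips)
        for ta, tb in zip(a.tips, b.tips):
            assert ta.trajectory == tb.trajectory
            assert ta.state == tb.state and ta.parent_id == tb.parent_id
        assert a.arrival_times == b.arrival_times
        assert a.network.occupancy == b.network.occupancy

    def test_different_seeds_differ(self):
        a = ap.run_simulation(ap.SimConfig(seed=0))
        b = ap.run_simulation(ap.SimConfig(seed=1))
        assert any(ta.trajectory != tb.trajectory
                   for ta, tb in zip(a.tips, b.tips))

    def test_state_counts_partition_tips(self, default_ensemble):
        for result in default_ensemble[:10]:
            states = result.tips_by_state()
            assert sum(states.values()) == len(result.tips)

    def test_trajectory_steps_are_lattice_neighbors(self, default_ensemble):
        result = default_ensemble[0]
        for tip in result.tips:
            for (t0, i0, j0), (t1, i1, j1) in zip(tip.trajectory,
                                                  tip.trajectory[1:]):
                assert t1 > t0
                assert abs(i1 - i0) + abs(j1 - j0) == 1

    def test_no_branching_during_rest_periods(self, default_ensemble):
        for result in default_ensemble[:10]:
            for tip in result.tips:
                if tip.parent_id is not None:
                    rate = ap.temporal_rate_factor(tip.birth_time,
                                                   result.config.vegf)
                    assert float(rate) > 0

    def test_arrival_after_birth(self, default_ensemble):
        for result in default_ensemble:
            for tip_id, t_arr in result.arrival_times.items():
                tip = next(t for t in result.tips if t.id == tip_id)
                assert t_arr >= tip.birth_time
                assert tip.state == ARRIVED

    def test_snapshots_cover_all_days(self, default_ensemble):
        result = default_ensemble[0]
        assert [s.t for s in result.snapshots] == [float(k) for k in range(15)]


class TestDisplacementBias:
    """Single-step statistics of the movement distribution."""

    def _displacements(self, t, site, n_draws=10_000, seed=31):
        cfg = ap.SimConfig()
        lat = DualLattice(cfg.n_cells)
        grid = ap.potential_grid(cfg.n_cells, t, cfg.vegf, cfg.beta)
        vel = ap.velocity_on_main_lattice(grid.values, lat.h)
        tau = ap.stable_timestep(cfg.d, lat.h, vel, cfg.safety)
        probs = ap.transition_probabilities(vel, cfg.d, lat.h, tau)
        rng = np.random.default_rng(seed)
        tip = ap.TipAgent(id=0, site=site)
        p = probs.at(*site)
        dx = np.empty(n_draws)
        for k in range(n_draws):
            new = ap.move_tip(tip, p, rng)
            dx[k] = new[0] - site[0]
        return dx, p

    def test_unbiased_during_rest(self):
        dx, p = self._displacements(t=3.0, site=(89, 49))
        move_prob = p[1] + p[2]
        sigma = np.sqrt(move_prob / 10_000)  # std of the mean x-displacement
        assert abs(dx.mean()) < 3 * sigma

    def test_patchward_drift_during_growth(self):
        dx, _ = self._displacements(t=0.0, site=(89, 49))  # x ~ 0.9
        assert dx.mean() < 0
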