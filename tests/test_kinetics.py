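import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from vtsim.constants import molar_rate_to_um3
from vtsim.kinetics import (AgentPool, ReactionRule, contact_rule,
                            first_order_probability, first_order_sweep,
                            pair_reaction_sweep, reaction_volume,
                            shell_thickness)


class TestFirstOrderProbability:
    def test_zero_rate(self):
        assert first_order_probability(0.0, 0.1) == 0.0

    def test_limit_one(self):
        assert first_order_probability(1e9, 1.0) == pytest.approx(1.0)

    def test_closed_form_value(self):
        assert first_order_probability(0.1, 0.01) == pytest.approx(
            9.995e-4, rel=1e-3)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            first_order_probability(-1.0, 0.1)


class TestContactRule:
    def test_zero_rate_zero_probability(self):
        d, p = contact_rule(0.05, 0.05, 0.0, 0.01, overlap_allowed=True)
        assert d == pytest.approx(0.1)
        assert p == 0.0
        d, p = contact_rule(0.05, 0.05, 0.0, 0.01, overlap_allowed=False)
        assert d == pytest.approx(0.1)  # delta = 0

    def test_probability_linear_in_dt(self):
        _, p1 = contact_rule(0.05, 0.05, 1e7, 0.01, overlap_allowed=True)
        _, p2 = contact_rule(0.05, 0.05, 1e7, 0.02, overlap_allowed=True)
        assert p2 == pytest.approx(2 * p1)

    def test_shell_volume_matches_reaction_volume(self):
        k, dt = 1e8, 0.01
        d, p = contact_rule(0.05, 0.05, k, dt, overlap_allowed=False)
        assert p == 1.0
        r = 0.1
        shell = 4 * math.pi / 3 * (d ** 3 - r ** 3)
        assert shell == pytest.approx(reaction_volume(k, dt), rel=1e-9)

    def test_clamp_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="vtsim.kinetics"):
            _, p = contact_rule(0.001, 0.001, 1e9, 1.0, overlap_allowed=True)
        assert p == 1.0
        assert any("clamp" in r.message for r in caplog.records)

    def test_shell_thickness_inverse(self):
        delta = shell_thickness(0.1, 1e-3)
        vol = 4 * math.pi / 3 * ((0.1 + delta) ** 3 - 0.1 ** 3)
        assert vol == pytest.approx(1e-3)


def _well_mixed_bimolecular(n_a, n_b, k_molar, radius, box, dt, t_end, rng,
                            overlap_allowed=True):
    """Ideally mixed A+B->C: positions redrawn uniformly every sweep."""
    pool = AgentPool({"A": radius, "B": radius, "C": radius})
    pool.add("A", rng.uniform(0, box, (n_a, 3)))
    pool.add("B", rng.uniform(0, box, (n_b, 3)))
    rule = ReactionRule(("A", "B"), ("C",), k_molar,
                        overlap_allowed=overlap_allowed)
    traj = []
    steps = int(round(t_end / dt))
    vol = box ** 3
    for step in range(steps):
        for sp in ("A", "B"):
            n = pool.count(sp)
            pool.positions[sp] = rng.uniform(0, box, size=(n, 3))
        if not overlap_allowed:
            # hard exclusion: the shell rule presumes non-overlapping agents
            from scipy.spatial import cKDTree
            for _ in range(6):
                ta = cKDTree(pool.positions["A"], boxsize=box)
                bad = [j for j, near in enumerate(ta.query_ball_point(
                    pool.positions["B"], 2 * radius)) if near]
                if not bad:
                    break
                pool.positions["B"][bad] = rng.uniform(0, box, (len(bad), 3))
        pair_reaction_sweep(pool, [rule], dt, rng, boxsize=box)
        traj.append((step + 1) * dt)
    return pool, vol


class TestPairReactionSweep:
    def test_no_pairs_in_range_no_events(self, rng):
        pool = AgentPool({"A": 0.01, "B": 0.01})
        pool.add("A", np.array([[0.0, 0, 0]]))
        pool.add("B", np.array([[5.0, 0, 0]]))
        rule = ReactionRule(("A", "B"), ("C",), 1e6)
        events = pair_reaction_sweep(pool, [rule], 0.01, rng)
        assert events == []
        assert pool.count("A") == 1 and pool.count("B") == 1

    def test_agent_consumed_at_most_once(self, rng):
        pool = AgentPool({"A": 0.05, "B": 0.05})
        pool.add("A", np.zeros((1, 3)))
        pool.add("B", np.array([[0.01, 0, 0], [0.0, 0.01, 0], [0.0, 0, 0.01]]))
        rule = ReactionRule(("A", "B"), ("C",), 1e12)
        events = pair_reaction_sweep(pool, [rule], 0.1, rng)
        assert len(events) == 1
        assert pool.count("A") == 0
        assert pool.count("B") == 2
        assert pool.count("C") == 1

    def test_mass_conservation_per_event(self, rng):
        pool = AgentPool({"A": 0.05, "B": 0.05, "C": 0.05})
        pool.add("A", rng.uniform(0, 1, (40, 3)))
        pool.add("B", rng.uniform(0, 1, (40, 3)))
        rule = ReactionRule(("A", "B"), ("C",), 5e8)
        for _ in range(20):
            events = pair_reaction_sweep(pool, [rule], 0.01, rng)
            assert pool.count("A") == pool.count("B")
            assert pool.count("A") + pool.count("C") == 40

    @pytest.mark.parametrize("overlap_allowed", [True, False])
    @pytest.mark.parametrize("k_molar,n0", [(2e8, 150), (5e8, 100), (1e9, 60)])
    def test_matches_mass_action_ode(self, rng, k_molar, n0, overlap_allowed):
        # ODE oracle for A+B->C (equal counts): y(t) = n0 / (1 + kv*n0*t/V),
        # checked at the half-life where y = n0/2, in the dilute regime
        radius, box, dt = 0.05, 2.0, 5e-4
        vol = box ** 3
        kv = molar_rate_to_um3(k_molar)
        t_half = vol / (kv * n0)
        remaining = []
        for rep in range(8):
            r2 = np.random.default_rng(1000 + rep)
            p2, _ = _well_mixed_bimolecular(n0, n0, k_molar, radius, box, dt,
                                            t_half, r2, overlap_allowed)
            remaining.append(p2.count("A"))
        assert np.mean(remaining) == pytest.approx(n0 / 2, rel=0.05)

    def _seed_positions(self, pool, rng, box):
        for sp in pool.positions:
            pool.positions[sp] = rng.uniform(0, box, (pool.count(sp), 3))

    def test_equilibrium_matches_gillespie(self, rng):
        # A+B->C with C->A+B vs an SSA oracle, mean C occupancy within 3 sigma
        box, dt = 1.0, 0.005
        k2, k1 = 6e8, 2.0  # association 1/(M*s), dissociation 1/s
        n0 = 30
        kv = molar_rate_to_um3(k2) / box ** 3

        def ssa(rng_o, t_end):
            a = b = n0
            c = 0
            t = 0.0
            cs = []
            while t < t_end:
                r_assoc = kv * a * b
                r_diss = k1 * c
                tot = r_assoc + r_diss
                t += rng_o.exponential(1 / tot)
                if rng_o.uniform() < r_assoc / tot:
                    a -= 1
                    b -= 1
                    c += 1
                else:
                    a += 1
                    b += 1
                    c -= 1
                if t > 5.0:
                    cs.append(c)
            return np.mean(cs)

        oracle = np.mean([ssa(np.random.default_rng(50 + i), 40.0)
                          for i in range(4)])

        pool = AgentPool({"A": 0.05, "B": 0.05, "C": 0.05})
        pool.add("A", rng.uniform(0, box, (n0, 3)))
        pool.add("B", rng.uniform(0, box, (n0, 3)))
        rules = [ReactionRule(("A", "B"), ("C",), k2),
                 ReactionRule(("C",), ("A", "B"), k1)]
        cs = []
        t = 0.0
        while t < 60.0:
            self._seed_positions(pool, rng, box)
            pair_reaction_sweep(pool, rules, dt, rng)
            first_order_sweep(pool, rules, dt, rng)
            t += dt
            if t > 5.0:
                cs.append(pool.count("C"))
        mean_c = np.mean(cs)
        sigma = np.std(cs) / math.sqrt(len(cs) / 200)  # correlated samples
        assert abs(mean_c - oracle) < max(3 * sigma, 1.5)


class TestFirstOrderSweep:
    def test_decay_recovers_rate(self, rng):
        # closed-form decay oracle: fit k from the survival curve
        pool = AgentPool({"A": 0.01})
        pool.add("A", np.zeros((10_000, 3)))
        rule = ReactionRule(("A",), (), 0.1)
        dt, times, counts = 0.05, [], []
        for step in range(1, 201):
            first_order_sweep(pool, [rule], dt, rng)
            times.append(step * dt)
            counts.append(pool.count("A"))
        k_fit = -np.polyfit(times, np.log(np.array(counts)), 1)[0]
        assert k_fit == pytest.approx(0.1, rel=0.02)

    def test_zero_rate_no_events(self, rng):
        pool = AgentPool({"A": 0.01})
        pool.add("A", np.zeros((100, 3)))
        assert first_order_sweep(pool, [ReactionRule(("A",), ("B",), 0.0)],
                                 0.1, rng) == []
        assert pool.count("A") == 100

    def test_competing_channels_split_evenly(self, rng):
        pool = AgentPool({"A": 0.01, "B": 0.01, "C": 0.01})
        pool.add("A", np.zeros((20_000, 3)))
        rules = [ReactionRule(("A",), ("B",), 0.5),
                 ReactionRule(("A",), ("C",), 0.5)]
        for _ in range(100):
            first_order_sweep(pool, rules, 0.1, rng)
        nb, nc = pool.count("B"), pool.count("C")
        frac = nb / (nb + nc)
        assert frac == pytest.approx(0.5, abs=3 * 0.5 / math.sqrt(nb + nc))

    def test_timestep_robustness(self):
        # halving dt (doubling steps) changes the trajectory < MC error
        def run(dt, seed):
            rng = np.random.default_rng(seed)
            pool = AgentPool({"A": 0.01})
            pool.add("A", np.zeros((5000, 3)))
            rule = ReactionRule(("A",), (), 0.2)
            for _ in range(int(round(5.0 / dt))):
                first_order_sweep(pool, [rule], dt, rng)
            return pool.count("A")

        coarse = np.mean([run(0.1, s) for s in range(5)])
        fine = np.mean([run(0.05, s + 100) for s in range(5)])
        expect = 5000 * math.exp(-1.0)
        mc_err = 3 * math.sqrt(5000 * math.exp(-1.0) * (1 - math.exp(-1.0)) / 5)
        assert abs(coarse - fine) < 2 * mc_err
        assert abs(coarse - expect) < mc_err
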