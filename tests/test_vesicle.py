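import math

import numpy as np
import pytest

from vtsim.config import InternalReaction, load_config
from vtsim.constants import molar_rate_to_um3
from vtsim.motion import Mode
from vtsim.vesicle import (VesicleAgent, apply_class_saturation,
                           catcher_binding_rate, cluster_capture_radius,
                           cluster_to_vesicle, CoatCluster, depolymerize_coat,
                           initiate_budding, internal_reaction_sweep,
                           load_on_separation, make_compartment,
                           polymerize_coat_step, sphere_surface, sphere_volume)


def _vesicle(r=0.5, **counts):
    v = VesicleAgent(identity="V", position=np.zeros(3),
                     volume=sphere_volume(r), surface=sphere_surface(r))
    for group, d in counts.items():
        for sp, n in d.items():
            v.add(group, sp, n)
    return v


class TestVesicleAgent:
    def test_radius_from_volume(self):
        v = _vesicle(r=0.3)
        assert v.radius == pytest.approx(0.3)

    def test_surplus_surface_allowed(self):
        v = _vesicle(r=0.3)
        v.surface *= 1.5
        assert v.surface >= sphere_surface(v.radius)

    def test_negative_counts_rejected(self):
        v = _vesicle()
        with pytest.raises(ValueError):
            v.add("snare", "s", -1)


class TestCatcherBindingRate:
    def test_zero_catchers_zero_rate(self):
        assert catcher_binding_rate(5e7, 0) == 0.0

    def test_linear_in_catcher_count(self):
        assert catcher_binding_rate(5e7, 10) == pytest.approx(
            2 * catcher_binding_rate(5e7, 5))

    def test_two_state_occupancy_matches_markov_oracle(self, rng):
        # bound/free ratio of a two-state on/off process: k_on_eff/k_off
        k_on, k_off, dt = 2.0, 0.5, 0.01
        p_on = 1 - math.exp(-k_on * dt)
        p_off = 1 - math.exp(-k_off * dt)
        bound = False
        n_bound = 0
        steps = 400_000
        for _ in range(steps):
            if bound:
                if rng.uniform() < p_off:
                    bound = False
            else:
                if rng.uniform() < p_on:
                    bound = True
            n_bound += bound
        ratio = n_bound / (steps - n_bound)
        assert ratio == pytest.approx(k_on / k_off, rel=0.03)


class TestInternalReactionSweep:
    def test_zero_rates_no_change(self, minimal_config, rng):
        v = _vesicle(cargo_lum={"lum1": 30})
        rxns = [InternalReaction(["lum1"], [], 0.0)]
        internal_reaction_sweep(v, rxns, minimal_config, 0.1, rng)
        assert v.get("cargo_lum", "lum1") == 30

    def test_first_order_decay_matches_closed_form(self, minimal_doc, rng):
        minimal_doc["species"].append(
            {"name": "lum2", "klass": "cargo_lumen", "radius": 0.004})
        cfg = load_config(minimal_doc)
        k, dt, t_end, reps = 0.05, 0.1, 20.0, 300
        rxn = [InternalReaction(["lum1"], ["lum2"], k)]
        finals = []
        for _ in range(reps):
            v = _vesicle(cargo_lum={"lum1": 50})
            for _ in range(int(t_end / dt)):
                internal_reaction_sweep(v, rxn, cfg, dt, rng)
            finals.append(v.get("cargo_lum", "lum1"))
        expect = 50 * math.exp(-k * t_end)
        sigma = math.sqrt(50 * math.exp(-k * t_end)
                          * (1 - math.exp(-k * t_end)) / reps)
        assert abs(np.mean(finals) - expect) < 3 * sigma

    def test_bimolecular_matches_gillespie(self, minimal_doc, rng):
        # A+B->C inside one vesicle vs an SSA oracle (chi-square, p > 0.01)
        from scipy import stats

        minimal_doc["species"].extend([
            {"name": "bL", "klass": "cargo_lumen", "radius": 0.004},
            {"name": "cL", "klass": "cargo_lumen", "radius": 0.004}])
        cfg = load_config(minimal_doc)
        k_molar = 1e7
        n0a, n0b, t_end, dt = 12, 8, 4.0, 0.02
        r = 0.5
        kv = molar_rate_to_um3(k_molar) / sphere_volume(r)

        def ssa(rng_o):
            a, b, t = n0a, n0b, 0.0
            while a > 0 and b > 0:
                rate = kv * a * b
                t += rng_o.exponential(1 / rate)
                if t > t_end:
                    break
                a -= 1
                b -= 1
            return a

        oracle = np.array([ssa(np.random.default_rng(7000 + i))
                           for i in range(800)])
        rxn = [InternalReaction(["lum1", "bL"], ["cL"], k_molar)]
        sim = []
        for _ in range(800):
            v = _vesicle(r=r, cargo_lum={"lum1": n0a, "bL": n0b})
            for _ in range(int(t_end / dt)):
                internal_reaction_sweep(v, rxn, cfg, dt, rng)
            sim.append(v.get("cargo_lum", "lum1"))
        sim = np.array(sim)
        values = np.arange(n0a - n0b, n0a + 1)
        obs = np.array([(sim == x).sum() for x in values])
        exp = np.array([(oracle == x).sum() for x in values])
        keep = (exp + obs) >= 10
        exp_f = exp[keep] * obs.sum() / exp[keep].sum()
        chi2 = ((obs[keep] - exp_f) ** 2 / exp_f).sum()
        p = 1 - stats.chi2.cdf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_mass_conservation(self, minimal_doc, rng):
        minimal_doc["species"].append(
            {"name": "lum2", "klass": "cargo_lumen", "radius": 0.004})
        cfg = load_config(minimal_doc)
        rxn = [InternalReaction(["lum1"], ["lum2"], 0.3)]
        v = _vesicle(cargo_lum={"lum1": 100})
        for _ in range(100):
            internal_reaction_sweep(v, rxn, cfg, 0.05, rng)
            assert v.get("cargo_lum", "lum1") + v.get("cargo_lum", "lum2") == 100


class TestBudding:
    def test_zero_cargo_never_initiates(self, minimal_config, rng):
        v = _vesicle(coat_bound={"coatA": 20})
        for _ in range(2000):
            assert initiate_budding(v, minimal_config, 0.1, rng) is None

    def test_zero_coat_never_initiates(self, minimal_config, rng):
        v = _vesicle(cargo_mem={"cargo1": 100})
        for _ in range(2000):
            assert initiate_budding(v, minimal_config, 0.1, rng) is None

    def test_initiation_rate_linear_in_cargo(self, minimal_config, rng):
        # Monte-Carlo check of dimer-propensity linearity (sub-saturation)
        def rate(n_cargo, trials=6000):
            fired = 0
            for _ in range(trials):
                v = _vesicle(coat_bound={"coatA": 10},
                             cargo_mem={"cargo1": n_cargo})
                if initiate_budding(v, minimal_config, 0.01, rng) is not None:
                    fired += 1
            return fired / trials

        r1, r2 = rate(20), rate(40)
        assert r2 == pytest.approx(2 * r1, rel=0.2)

    def test_initiation_consumes_one_coat(self, minimal_config, rng):
        v = _vesicle(coat_bound={"coatA": 10}, cargo_mem={"cargo1": 500})
        while v.budding is None:
            initiate_budding(v, minimal_config, 0.1, rng)
        assert v.get("coat_bound", "coatA") == 9
        assert v.budding.n_pol == 1


class TestPolymerization:
    def test_shell_size_one_completes_immediately(self, minimal_doc, rng):
        minimal_doc["interactions"]["shell_size"] = 1
        cfg = load_config(minimal_doc)
        v = _vesicle(coat_bound={"coatA": 10}, cargo_mem={"cargo1": 100})
        while v.budding is None:
            initiate_budding(v, cfg, 0.1, rng)
        assert polymerize_coat_step(v, cfg, 0.01, rng)  # n_pol already = 1

    def test_zero_k_poly_never_completes(self, minimal_doc, rng):
        minimal_doc["interactions"]["k_poly"] = 0.0
        cfg = load_config(minimal_doc)
        v = _vesicle(coat_bound={"coatA": 10}, cargo_mem={"cargo1": 100})
        while v.budding is None:
            initiate_budding(v, cfg, 0.1, rng)
        for _ in range(500):
            assert not polymerize_coat_step(v, cfg, 0.1, rng)

    def test_mean_budding_time_matches_death_process_oracle(self, minimal_doc,
                                                            rng):
        # pure-death oracle: E[t_bud] = sum over the depletion sequence of
        # 1/(k_poly * n_m), starting after the dimer's first monomer
        minimal_doc["interactions"]["shell_size"] = 5
        minimal_doc["interactions"]["k_poly"] = 0.5
        cfg = load_config(minimal_doc)
        n0 = 12
        times = []
        for _ in range(400):
            v = _vesicle(coat_bound={"coatA": n0}, cargo_mem={"cargo1": 400})
            while v.budding is None:
                initiate_budding(v, cfg, 0.05, rng)
            while not polymerize_coat_step(v, cfg, 0.02, rng):
                pass
            times.append(v.budding.t_bud)
        # after initiation one monomer is polymerized; 4 more fire from a
        # bound pool of n0-1, n0-2, ...
        expect = sum(1.0 / (0.5 * (n0 - 1 - m)) for m in range(4))
        sem = np.std(times) / math.sqrt(len(times))
        assert abs(np.mean(times) - expect) < 3 * sem + 0.02


class TestClassSaturation:
    def test_at_limit_unchanged(self):
        assert apply_class_saturation({"a": 15, "b": 5}, 20) == {"a": 15, "b": 5}

    def test_proportional_scaling(self):
        assert apply_class_saturation({"a": 30, "b": 10}, 20) == {"a": 15, "b": 5}

    def test_single_species_clipped(self):
        assert apply_class_saturation({"a": 100}, 7) == {"a": 7}

    def test_zero_limit(self):
        assert apply_class_saturation({"a": 3}, 0) == {"a": 0}

    def test_largest_remainder_sum_exact(self, rng):
        for _ in range(200):
            tries = {f"s{i}": int(rng.integers(0, 40)) for i in range(4)}
            limit = int(rng.integers(1, 50))
            out = apply_class_saturation(tries, limit)
            assert all(out[k] <= tries[k] + 1 for k in tries)
            assert sum(out.values()) == min(sum(tries.values()), limit) or \
                sum(tries.values()) <= limit


class TestLoading:
    def _donor(self, config, n_cargo=200, n_snare=150, n_motor=20):
        v = _vesicle(r=0.5, coat_bound={"coatA": 20},
                     cargo_mem={"cargo1": n_cargo},
                     snare={"snareX": n_snare}, motor={"motor1": n_motor})
        return v

    def _bud(self, config, rng, donor, t_bud=2.0):
        from vtsim.vesicle import BuddingProcess

        donor.budding = BuddingProcess(
            coat_species="coatA", site_normal=np.array([1.0, 0, 0]),
            n_pol=config.tables.shell_size, t_bud=t_bud)
        return load_on_separation(donor, config, rng)

    def test_zero_rates_empty_vesicle(self, minimal_doc, rng):
        minimal_doc["interactions"]["k_coat_cargo"] = {"coatA": {"cargo1": 0.0}}
        minimal_doc["interactions"]["k_coat_snare"] = {}
        minimal_doc["interactions"]["k_coat_motor"] = {}
        cfg = load_config(minimal_doc)
        donor = self._donor(cfg)
        ves = self._bud(cfg, rng, donor)
        assert sum(ves.counts["cargo_mem"].values()) == 0
        assert sum(ves.counts["snare"].values()) == 0
        assert ves.get("coat_pol", "coatA") == cfg.tables.shell_size

    def test_mean_transfer_matches_binomial_oracle(self, minimal_config, rng):
        # binomial oracle with p from the loading-probability formula
        cfg = minimal_config
        t_bud = 2.0
        k = cfg.tables.k_coat_cargo["coatA"]["cargo1"]
        shell = cfg.tables.shell_size
        n_j = 100
        transferred = []
        for _ in range(400):
            donor = self._donor(cfg, n_cargo=n_j, n_snare=0, n_motor=0)
            rate = k * (shell / 2.0) / donor.surface
            ves = self._bud(cfg, rng, donor, t_bud=t_bud)
            transferred.append(sum(ves.counts["cargo_mem"].values()))
        p = 1 - math.exp(-k * (shell / 2.0) * t_bud / sphere_surface(0.5))
        expect = n_j * p
        sigma = math.sqrt(n_j * p * (1 - p) / len(transferred))
        assert abs(np.mean(transferred) - expect) < 3 * sigma

    def test_transfer_linear_in_donor_cargo(self, minimal_config, rng):
        def mean_load(n_cargo, reps=300):
            out = []
            for _ in range(reps):
                donor = self._donor(minimal_config, n_cargo=n_cargo,
                                    n_snare=0, n_motor=0)
                ves = self._bud(minimal_config, rng, donor)
                out.append(sum(ves.counts["cargo_mem"].values()))
            return np.mean(out)

        m1, m2 = mean_load(50), mean_load(100)
        assert m2 == pytest.approx(2 * m1, rel=0.25)

    def test_saturation_limit_never_exceeded(self, minimal_doc, rng):
        minimal_doc["interactions"]["class_limits"] = {"cargo": 5, "snare": 3,
                                                       "motor": 2}
        minimal_doc["interactions"]["k_coat_cargo"] = {"coatA": {"cargo1": 10.0}}
        minimal_doc["interactions"]["k_coat_snare"] = {"coatA": {"snareX": 10.0}}
        minimal_doc["interactions"]["k_coat_motor"] = {"coatA": {"motor1": 10.0}}
        cfg = load_config(minimal_doc)
        for _ in range(50):
            donor = self._donor(cfg)
            ves = self._bud(cfg, rng, donor, t_bud=10.0)
            assert sum(ves.counts["cargo_mem"].values()) <= 5
            assert sum(ves.counts["snare"].values()) <= 3
            assert sum(ves.counts["motor"].values()) <= 2

    def test_volume_surface_taken_from_donor(self, minimal_config, rng):
        donor = self._donor(minimal_config)
        v0, s0 = donor.volume, donor.surface
        ves = self._bud(minimal_config, rng, donor)
        assert donor.volume + ves.volume == pytest.approx(v0)
        assert donor.surface + ves.surface == pytest.approx(s0)


class TestDepolymerization:
    def test_no_release_before_lag(self):
        v = _vesicle(r=0.05, coat_pol={"coatA": 10})
        out = depolymerize_coat(v, 0.5, 10, depol_time=5.0, t_lag=1.0)
        assert out == {}
        assert v.n_pol == 10

    def test_shell_gone_at_lag_plus_depol_time(self):
        v = _vesicle(r=0.05, coat_pol={"coatA": 10})
        released = {}
        for _ in range(601):
            for sp, m in depolymerize_coat(v, 0.01, 10, 5.0, 1.0).items():
                released[sp] = released.get(sp, 0) + m
        assert v.n_pol == 0
        assert released == {"coatA": 10}

    def test_linear_decay_midpoint(self):
        v = _vesicle(r=0.05, coat_pol={"coatA": 10})
        for _ in range(350):  # t = 3.5 s = lag + depol/2
            depolymerize_coat(v, 0.01, 10, 5.0, 1.0)
        assert v.n_pol == 5


class TestEndocyticCluster:
    def test_capture_radius_strictly_increasing(self):
        radii = [cluster_capture_radius(s, 0.02, 0.01) for s in range(1, 10)]
        assert all(b > a for a, b in zip(radii, radii[1:]))

    def test_cluster_to_vesicle_bookkeeping(self, minimal_config):
        pm = VesicleAgent(identity="PM", position=np.zeros(3), volume=5.0,
                          surface=100.0, mobile=False, is_boundary=True)
        cl = CoatCluster(anchor=np.array([0.0, 0, 1.0]), coat_species="coatA")
        for _ in range(5):
            cl.add_member("coatA", True)
        for _ in range(3):
            cl.add_member("cargo1", False)
        cl.add_member("snareX", False)
        ves = cluster_to_vesicle(cl, minimal_config, 3.0, pm)
        assert ves.get("coat_pol", "coatA") == 5
        assert ves.get("cargo_mem", "cargo1") == 3
        assert ves.get("snare", "snareX") == 1
        assert ves.motion.mode is Mode.BOOSTED
        assert ves.motion.boost_direction @ np.array([0.0, 0, 1.0]) == -1.0
        assert pm.volume + ves.volume == pytest.approx(5.0)
        assert pm.surface + ves.surface == pytest.approx(100.0)
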