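"""Main simulation loop and run-level bookkeeping.

Each iteration executes, in order: (1) advance time, (2) move all agents
(diffusion, motor transport, actin boost; steps into obstacles rejected),
(3) every ``reaction_stride``-th step with effective dt = stride*dt:
second-order reactions (recruitment, filament binding, fusion contacts,
endocytic capture), first-order reactions (dissociation, activation,
release), and the vesicle actions (internal chemistry, depolymerization,
budding progression, docking completion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import fusion as fus
from . import signaling as sig
from . import vesicle as ves
from .config import Config, Klass
from .geometry import (CellGeometry, Filament, StructureField, build_cell,
                       generate_cytoskeleton)
from .kinetics import first_order_probability, reaction_volume, shell_thickness
from .motion import (Mode, MotionState, boost_step, diffusion_step, motor_step,
                     sphere_surface_step, stokes_einstein_D, tug_of_war_velocity,
                     uniform_steps)
from .vesicle import GROUP_OF_CLASS, VesicleAgent

FOUR_PI_3 = 4.0 * math.pi / 3.0


@dataclass
class Event:
    time: float
    kind: str                       # bud | fuse | endocytose | bind | unbind
    agent: int = -1
    donor: Optional[int] = None
    target: Optional[int] = None
    direction: Optional[str] = None  # forward | backward (fusions)
    travel_time: Optional[float] = None
    t_bud: Optional[float] = None
    n_pairs: Optional[float] = None
    manifest: dict = field(default_factory=dict)


@dataclass
class RunMetrics:
    n_fusions: int = 0
    n_forward: int = 0
    n_backward: int = 0
    n_buds: int = 0
    mean_travel_time: float = float("nan")
    fusion_times: list = field(default_factory=list)
    timeseries: Optional[pd.DataFrame] = None

    @property
    def backward_fraction(self) -> float:
        return self.n_backward / self.n_fusions if self.n_fusions else float("nan")


def events_to_frame(events: list[Event]) -> pd.DataFrame:
    return pd.DataFrame([{
        "time": e.time, "kind": e.kind, "agent": e.agent, "donor": e.donor,
        "target": e.target, "direction": e.direction,
        "travel_time": e.travel_time, "t_bud": e.t_bud, "n_pairs": e.n_pairs,
        "manifest": e.manifest} for e in events])


def summarize(events: list[Event], timeseries: Optional[pd.DataFrame] = None,
              first_n: Optional[int] = None) -> RunMetrics:
    """Recompute run metrics from the raw event log."""
    m = RunMetrics(timeseries=timeseries)
    fusions = [e for e in events if e.kind in ("fuse", "exocytose")]
    if first_n is not None:
        fusions = fusions[:first_n]
    travel = []
    for e in fusions:
        m.n_fusions += 1
        if e.direction == "backward":
            m.n_backward += 1
        else:
            m.n_forward += 1
        if e.travel_time is not None:
            travel.append(e.travel_time)
        m.fusion_times.append(e.time)
    m.n_buds = sum(1 for e in events if e.kind in ("bud", "endocytose"))
    if travel:
        m.mean_travel_time = float(np.mean(travel))
    return m


class SimState:
    """Mutable state of one run."""

    def __init__(self, config: Config, seed: Optional[int] = None):
        ves.reset_agent_ids()
        self.config = config
        p = config.params
        seed = p.seed if seed is None else seed
        ss = np.random.SeedSequence(seed)
        kids = ss.spawn(4)
        self.rng_motion = np.random.default_rng(kids[0])
        self.rng_react = np.random.default_rng(kids[1])
        self.rng_vesicle = np.random.default_rng(kids[2])
        self.rng_signal = np.random.default_rng(kids[3])

        self.cell: CellGeometry = build_cell(config.scenario.cell)
        self.filaments: list[Filament] = generate_cytoskeleton(
            config.scenario.cytoskeleton, self.cell,
            config.scenario.compartments, np.random.default_rng(ss.spawn(1)[0]))
        self.sfield = StructureField(self.cell, self.filaments)

        self.t = 0.0
        self.n_micro_events = 0   # recruitment/unbind/depol state changes
        self.events: list[Event] = []
        self.samples: list[dict] = []
        self.record_trajectories = False
        self.trajectory: list[tuple] = []
        self.clusters: list[ves.CoatCluster] = []

        # vesicle agents (compartments first)
        self.vesicles: list[VesicleAgent] = [
            ves.make_compartment(c, config) for c in config.scenario.compartments]
        self.by_id = {v.id: v for v in self.vesicles}

        # plasma membrane pseudo-compartment, if any species lives there
        pm_used = any("PM" in s.initial_counts for s in config.species) or (
            config.scenario.signaling is not None)
        self.pm: Optional[VesicleAgent] = None
        self.pm_agents: dict[str, np.ndarray] = {}
        if pm_used:
            R = self.cell.cell_radius
            self.pm = VesicleAgent(
                identity="PM", position=np.zeros(3),
                volume=ves.sphere_surface(R) * 0.05,
                surface=ves.sphere_surface(R), mobile=False, is_boundary=True)
            self.pm.motion.mode = Mode.FIXED
            self.vesicles.append(self.pm)
            self.by_id[self.pm.id] = self.pm

        # explicit cytosolic agents
        self.cyto: dict[str, np.ndarray] = {}
        for s in config.species:
            n = s.initial_counts.get("cytosol", 0)
            self.cyto[s.name] = self._random_cyto_points(n)
            n_pm = s.initial_counts.get("PM", 0)
            if n_pm > 0:
                u = self.rng_motion.normal(size=(n_pm, 3))
                self.pm_agents[s.name] = u / np.linalg.norm(u, axis=1, keepdims=True)
            elif pm_used:
                self.pm_agents.setdefault(s.name, np.zeros((0, 3)))

        # nucleus-bound and intra-nuclear signaling molecules
        self.nuc_bound: dict[str, np.ndarray] = {}
        self.nuc_inside: dict[str, np.ndarray] = {}

        self._D_cache: dict[str, float] = {}
        self._species = {s.name: s for s in config.species}

    # -- helpers ------------------------------------------------------------
    def _random_cyto_points(self, n: int) -> np.ndarray:
        pts = np.zeros((0, 3))
        rng = self.rng_motion
        R = self.cell.cell_radius
        while len(pts) < n:
            cand = rng.uniform(-R, R, size=(max(2 * (n - len(pts)), 16), 3))
            ok = self.cell.contains(cand)
            # keep points outside the initial compartments
            for v in self.vesicles:
                if not v.is_boundary:
                    ok &= np.linalg.norm(cand - v.position, axis=1) > v.radius
            pts = np.concatenate([pts, cand[ok]])
        return pts[:n]

    def species_D(self, name: str) -> float:
        if name not in self._D_cache:
            s = self._species[name]
            p = self.config.params
            if s.diffusion_coeff == "stokes_einstein":
                self._D_cache[name] = stokes_einstein_D(s.radius, p.ref_radius, p.ref_D)
            else:
                self._D_cache[name] = float(s.diffusion_coeff)
        return self._D_cache[name]

    def vesicle_D(self, v: VesicleAgent) -> float:
        p = self.config.params
        return stokes_einstein_D(v.radius, p.ref_radius, p.ref_D)

    def membrane_D(self, name: str) -> float:
        # lateral diffusion in the plasma membrane (slow vs. the cytosol)
        return self._species[name].membrane_D

    def alive_vesicles(self) -> list[VesicleAgent]:
        return [v for v in self.vesicles if v.volume > 0]

    def total_species_counts(self) -> dict[str, int]:
        """Global per-species totals across every pool (conservation audit)."""
        tot: dict[str, int] = {s.name: 0 for s in self.config.species}
        for sp, pts in self.cyto.items():
            tot[sp] += len(pts)
        for sp, pts in self.pm_agents.items():
            tot[sp] += len(pts)
        for sp, pts in self.nuc_bound.items():
            tot[sp] += len(pts)
        for sp, pts in self.nuc_inside.items():
            tot[sp] += len(pts)
        for v in self.vesicles:
            for group in v.counts.values():
                for sp, n in group.items():
                    tot[sp] += n
            if v.budding is not None:
                tot[v.budding.coat_species] += v.budding.n_pol
        for c in self.clusters:
            for sp, n in c.members.items():
                tot[sp] += n
        return tot

    def total_volume_surface(self) -> tuple[float, float]:
        vol = sum(v.volume for v in self.vesicles)
        sur = sum(v.surface for v in self.vesicles)
        return vol, sur


# ---------------------------------------------------------------------------
# movement
# ---------------------------------------------------------------------------

def _move_molecules(state: SimState, dt: float) -> None:
    rng = state.rng_motion
    for sp, pts in state.cyto.items():
        if len(pts) == 0:
            continue
        D = state.species_D(sp)
        if D == 0:
            continue
        prop = diffusion_step(pts, D, dt, rng)
        ok = state.cell.contains(prop, margin=state._species[sp].radius)
        pts[ok] = prop[ok]
    R = state.cell.cell_radius
    for sp, units in state.pm_agents.items():
        if len(units) == 0:
            continue
        state.pm_agents[sp] = sphere_surface_step(
            units, R, state.membrane_D(sp), dt, rng)
    if state.cell.nucleus_radius > 0:
        for sp, pts in state.nuc_inside.items():
            if len(pts) == 0:
                continue
            prop = diffusion_step(pts, state.species_D(sp), dt, rng)
            ok = state.cell.in_nucleus(prop, margin=state._species[sp].radius)
            pts[ok] = prop[ok]


def _vesicle_velocity(state: SimState, v: VesicleAgent) -> float:
    n_plus = n_minus = 0
    v_plus = v_minus = 0.0
    for sp, n in v.counts["motor"].items():
        s = state._species[sp]
        if s.motor_direction > 0:
            n_plus += n
            v_plus = s.motor_speed
        else:
            n_minus += n
            v_minus = s.motor_speed
    return tug_of_war_velocity(n_plus, v_plus, n_minus, v_minus)


def _exclusion_arrays(state: SimState):
    """Start-of-step positions/radii of solid vesicles, for vectorized
    overlap rejection."""
    solid = [o for o in state.vesicles if o.volume > 0 and not o.is_boundary]
    if not solid:
        return None
    pos = np.array([o.position for o in solid])
    rad = np.array([o.radius for o in solid])
    ids = np.array([o.id for o in solid])
    return pos, rad, ids


def _vesicle_blocked(state: SimState, v: VesicleAgent, pos: np.ndarray,
                     excl=None) -> bool:
    """Vesicles are self-exclusive and stay inside the cell."""
    r = v.radius
    if np.linalg.norm(pos) + r > state.cell.cell_radius:
        return True
    if state.cell.nucleus_radius > 0:
        if np.linalg.norm(pos - state.cell.nucleus_center) < (
                state.cell.nucleus_radius + r):
            return True
    if excl is None:
        excl = _exclusion_arrays(state)
    if excl is None:
        return False
    opos, orad, oids = excl
    d2 = ((opos - pos) ** 2).sum(axis=1)
    hit = d2 < (r + orad) ** 2
    hit &= oids != v.id
    return bool(hit.any())


def _move_vesicles(state: SimState, dt: float) -> None:
    p = state.config.params
    excl = _exclusion_arrays(state)
    for v in state.vesicles:
        if not v.mobile or v.volume <= 0:
            continue
        mode = v.motion.mode
        if mode in (Mode.FIXED, Mode.DOCKED):
            continue
        if mode is Mode.BOOSTED:
            pos = boost_step(v.position, v.motion, p.boost_speed, v.n_pol, dt)
            if not _vesicle_blocked(state, v, pos, excl):
                v.position = pos
            continue
        if mode is Mode.ON_FILAMENT:
            v_eff = _vesicle_velocity(state, v)
            pos = motor_step(v.motion, v_eff, dt, stall_time=p.stall_time)
            if _vesicle_blocked(state, v, pos, excl):
                v.motion.stall_clock += dt
                if v.motion.stall_clock >= p.stall_time:
                    v.motion.detach()
            else:
                v.position = pos
            continue
        # diffusing
        D = state.vesicle_D(v)
        pos = diffusion_step(v.position, D, dt, state.rng_motion)
        if not _vesicle_blocked(state, v, pos, excl):
            v.position = pos


# ---------------------------------------------------------------------------
# second-order sweeps
# ---------------------------------------------------------------------------

def _recruitment_sweep(state: SimState, dt: float) -> None:
    """Cytosolic coats/motors bind vesicles (catcher rule) and the PM."""
    cfg = state.config
    rng = state.rng_react
    targets = [v for v in state.vesicles
               if v.volume > 0 and not v.is_boundary]
    recruitable = [s for s in cfg.species if s.klass in (Klass.COAT, Klass.MOTOR)]
    for s in recruitable:
        pts = state.cyto.get(s.name)
        if pts is None or len(pts) == 0:
            continue
        taken = np.zeros(len(pts), dtype=bool)
        group = "coat_bound" if s.klass is Klass.COAT else "motor"
        for v in targets:
            k_on = ves.recruitment_rate(v, s.name, cfg)
            if k_on == 0:
                continue
            d_crit = v.radius + s.radius
            v_int = FOUR_PI_3 * d_crit ** 3
            p_acc = min(reaction_volume(k_on, dt) / v_int, 1.0)
            if p_acc <= 0:
                continue
            dists = np.linalg.norm(pts - v.position, axis=1)
            near = np.nonzero((dists <= d_crit) & ~taken)[0]
            for i in near:
                if rng.uniform() < p_acc:
                    taken[i] = True
                    v.add(group, s.name, 1)
                    state.n_micro_events += 1
        # plasma membrane recruitment via explicit catcher agents
        if state.pm is not None and not taken.all():
            k_on = _pm_recruitment_rate(state, s.name)
            if k_on > 0:
                R = state.cell.cell_radius
                v_r = reaction_volume(k_on, dt)
                delta = v_r / state.pm.surface
                dists = R - np.linalg.norm(pts, axis=1)
                near = np.nonzero((dists <= delta + s.radius) & ~taken)[0]
                for i in near:
                    taken[i] = True
                    u = pts[i] / np.linalg.norm(pts[i])
                    state.pm_agents.setdefault(s.name, np.zeros((0, 3)))
                    state.pm_agents[s.name] = np.concatenate(
                        [state.pm_agents[s.name], u[None, :]])
        if taken.any():
            state.cyto[s.name] = pts[~taken]


def _pm_recruitment_rate(state: SimState, species: str) -> float:
    cfg = state.config
    s = cfg.species_by_name(species)
    table = (cfg.tables.catcher_rate if s.klass is Klass.COAT
             else cfg.tables.motor_catcher_rate)
    base = (cfg.tables.coat_on_off if s.klass is Klass.COAT
            else cfg.tables.motor_on_off).get(species)
    k = base.k_on if base else 0.0
    for catcher, row in table.items():
        kc = row.get(species, 0.0)
        if kc > 0:
            k += ves.catcher_binding_rate(kc, len(state.pm_agents.get(catcher, ())))
    return k


def _unbinding_sweep(state: SimState, dt: float) -> None:
    """Bound coats/motors dissociate back into the cytosol."""
    cfg = state.config
    rng = state.rng_react
    for v in state.vesicles:
        if v.volume <= 0 or v.is_boundary:
            continue
        for group, table in (("coat_bound", cfg.tables.coat_on_off),
                             ("motor", cfg.tables.motor_on_off)):
            for sp in list(v.counts[group]):
                oo = table.get(sp)
                if oo is None or oo.k_off == 0:
                    continue
                n = v.get(group, sp)
                m = int(rng.binomial(n, first_order_probability(oo.k_off, dt)))
                if m:
                    v.add(group, sp, -m)
                    _spawn_cyto_at_surface(state, sp, v, m)
                    state.n_micro_events += m
    # PM membrane agents unbind the same way
    if state.pm is not None:
        for sp in list(state.pm_agents):
            s = state._species[sp]
            table = (cfg.tables.coat_on_off if s.klass is Klass.COAT
                     else cfg.tables.motor_on_off if s.klass is Klass.MOTOR
                     else None)
            oo = table.get(sp) if table else None
            if oo is None or oo.k_off == 0:
                continue
            units = state.pm_agents[sp]
            if len(units) == 0:
                continue
            fire = rng.uniform(size=len(units)) < first_order_probability(oo.k_off, dt)
            if fire.any():
                R = state.cell.cell_radius
                released = units[fire] * (R - 2 * s.radius)
                state.cyto[sp] = np.concatenate([state.cyto.get(sp, np.zeros((0, 3))),
                                                 released])
                state.pm_agents[sp] = units[~fire]


def _spawn_cyto_at_surface(state: SimState, sp: str, v: VesicleAgent,
                           m: int) -> None:
    u = state.rng_react.normal(size=(m, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = v.position + u * (v.radius + 2 * state._species[sp].radius)
    ok = state.cell.contains(pts)
    pts[~ok] = v.position  # fall back to the centre-side if outside the cell
    state.cyto[sp] = np.concatenate([state.cyto.get(sp, np.zeros((0, 3))), pts])


def _filament_sweep(state: SimState, dt: float) -> None:
    """Diffusing vesicles with motors bind nearby filaments; bound vesicles
    may randomly switch to a crossing track."""
    if not state.filaments:
        return
    cfg = state.config
    rng = state.rng_react
    for v in state.vesicles:
        if not v.mobile or v.volume <= 0:
            continue
        if v.motion.mode not in (Mode.DIFFUSING, Mode.ON_FILAMENT):
            continue
        n_mot = sum(v.counts["motor"].values())
        if n_mot == 0:
            continue
        v_r = reaction_volume(cfg.tables.k_fil_bind * n_mot, dt)
        delta = shell_thickness(v.radius, v_r)
        cutoff = v.radius + delta
        hits = state.sfield.filaments_within(v.position, cutoff)
        if not hits:
            continue
        # a bound vesicle only occasionally switches to a crossing track
        if v.motion.mode is Mode.ON_FILAMENT and rng.uniform() >= 0.15:
            continue
        hit = hits[int(rng.integers(len(hits)))]
        if (v.motion.mode is Mode.ON_FILAMENT and hit.filament is v.motion.filament):
            continue
        v.motion.mode = Mode.ON_FILAMENT
        v.motion.filament = hit.filament
        v.motion.arc = hit.arc
        v.motion.stall_clock = 0.0


def _fusion_sweep(state: SimState, dt: float) -> None:
    """SNARE-governed docking between uncoated mobile vesicles and targets."""
    cfg = state.config
    rng = state.rng_react
    layer = cfg.params.interaction_layer
    mobiles = [v for v in state.vesicles
               if v.mobile and v.volume > 0 and v.motion.mode is not Mode.DOCKED
               and fus.fusion_allowed(v)]
    order = list(range(len(mobiles)))
    rng.shuffle(order)
    # vectorized pre-filter: solid partners within 0.2 µm surface gap
    solid = [o for o in state.vesicles if o.volume > 0 and not o.is_boundary]
    spos = (np.array([o.position for o in solid]) if solid
            else np.zeros((0, 3)))
    srad = np.array([o.radius for o in solid])
    for i in order:
        v = mobiles[i]
        if v.motion.mode is Mode.DOCKED or v.volume <= 0:
            continue
        gaps = np.linalg.norm(spos - v.position, axis=1) - v.radius - srad
        near = [solid[j] for j in np.nonzero(gaps <= 0.2)[0]]
        if state.pm is not None:
            near.append(state.pm)
        for o in near:
            if o.id == v.id or o.volume <= 0:
                continue
            if o.motion.mode is Mode.DOCKED:
                continue
            if o.mobile and not fus.fusion_allowed(o):
                continue
            if o.is_boundary:
                gap = state.cell.cell_radius - np.linalg.norm(v.position) - v.radius
                counts_o = sig.pm_local_snares(state, v, layer)
                r_o = state.cell.cell_radius
            else:
                gap = float(np.linalg.norm(v.position - o.position)
                            ) - v.radius - o.radius
                counts_o = None
                r_o = o.radius
            if gap > 0.2:      # beyond any fusion layer (PM case)
                continue
            a_int = fus.contact_patch_area(v.radius, r_o, layer)
            counts_v = fus.local_snare_counts(v, a_int)
            if counts_o is None:
                counts_o = fus.local_snare_counts(o, a_int)
            n_pairs = fus.snare_pairs_from_counts(counts_v, counts_o,
                                                  cfg.tables)
            k_fus, t_fus = fus.fusion_rate(n_pairs, cfg.tables.k_fus_pair,
                                           cfg.tables.tau_pair)
            if k_fus == 0:
                continue
            delta = shell_thickness(v.radius + (0 if o.is_boundary else o.radius),
                                    reaction_volume(k_fus, dt))
            if gap <= delta:
                v.motion.mode = Mode.DOCKED
                v.docked_partner = o.id
                v.dock_until = state.t + t_fus
                v.motion.filament = None
                setattr(v, "_dock_n_pairs", n_pairs)
                if o.mobile and not o.is_boundary:
                    o.motion.mode = Mode.DOCKED
                    o.docked_partner = v.id
                    o.dock_until = v.dock_until
                break


def _complete_fusions(state: SimState) -> None:
    for v in list(state.vesicles):
        if v.motion.mode is not Mode.DOCKED or v.docked_partner is None:
            continue
        if state.t < v.dock_until:
            continue
        o = state.by_id.get(v.docked_partner)
        if o is None or o.volume <= 0 or v.volume <= 0:
            v.motion.detach()
            v.docked_partner = None
            continue
        # the smaller partner is absorbed into the larger
        small, big = (v, o) if v.volume <= o.volume else (o, v)
        direction = fus.classify_fusion(small, big)
        travel = state.t - small.birth_time if small.donor_id is not None else None
        kind = "exocytose" if big.is_boundary else "fuse"
        if big.is_boundary:
            sig.deposit_on_pm(state, small)
            big.volume += small.volume
            big.surface += small.surface
            small.counts = {g: {} for g in small.counts}
        else:
            fus.merge_vesicles(big, small)
        state.events.append(Event(
            time=state.t, kind=kind, agent=small.id, donor=small.donor_id,
            target=big.id, direction=direction, travel_time=travel,
            n_pairs=getattr(v, "_dock_n_pairs", None)))
        small.volume = 0.0
        small.surface = 0.0
        small.mobile = False
        small.motion.mode = Mode.FIXED
        small.docked_partner = None
        if big.mobile and not big.is_boundary:
            big.motion.detach()
        big.docked_partner = None
        state.vesicles = [w for w in state.vesicles if w.volume > 0]
        state.by_id = {w.id: w for w in state.vesicles}


# ---------------------------------------------------------------------------
# budding & endocytosis progression (vesicle actions)
# ---------------------------------------------------------------------------

def _budding_site(state: SimState, donor: VesicleAgent) -> Optional[np.ndarray]:
    """Budding-site normal: anchored to a filament touching the donor.

    If the nearest filament passes through the compartment the anchor is one
    of its surface crossings (picked at random); otherwise the nearest
    filament point, when close enough to the surface.
    """
    if not state.filaments:
        return None
    hit = state.sfield.nearest_filament(donor.position)
    if hit is None:
        return None
    r_ves = state.config.params.vesicle_radius
    if hit.distance > donor.radius + 4 * r_ves:
        return None
    fil = hit.filament
    if hit.distance >= donor.radius:
        d = fil.point_at(hit.arc) - donor.position
        return d / np.linalg.norm(d)
    # walk outward along the filament to its surface crossings
    exits = []
    for sign in (+1.0, -1.0):
        s = hit.arc
        while 0.0 <= s <= fil.length:
            pt = fil.point_at(s)
            if np.linalg.norm(pt - donor.position) >= donor.radius + 0.5 * r_ves:
                exits.append(pt)
                break
            s += sign * r_ves
    if not exits:
        return None
    pt = exits[int(state.rng_vesicle.integers(len(exits)))]
    d = pt - donor.position
    return d / np.linalg.norm(d)


def _vesicle_actions(state: SimState, dt: float) -> None:
    cfg = state.config
    rng = state.rng_vesicle
    p = cfg.params
    for v in list(state.vesicles):
        if v.volume <= 0:
            continue
        # 1) internal chemistry
        if cfg.reactions and not v.is_boundary:
            ves.internal_reaction_sweep(v, cfg.reactions, cfg, dt, rng)
        # 2) coat depolymerization (post-budding shells)
        if v.n_pol > 0 and v.budding is None:
            released = ves.depolymerize_coat(v, dt, cfg.tables.shell_size,
                                             p.depol_time, p.depol_lag)
            for sp, m in released.items():
                _spawn_cyto_at_surface(state, sp, v, m)
                state.n_micro_events += m
            if v.n_pol == 0 and v.motion.mode is Mode.BOOSTED:
                v.motion.mode = Mode.DIFFUSING
        # 3) budding progression / initiation (only sizeable donors bud)
        if v.is_boundary or v.motion.mode is Mode.DOCKED:
            continue
        if v.budding is not None:
            done = ves.polymerize_coat_step(v, cfg, dt, rng)
            if done:
                proc = v.budding
                new = ves.load_on_separation(v, cfg, rng, birth_time=state.t)
                state.vesicles.append(new)
                state.by_id[new.id] = new
                manifest = {g: dict(new.counts[g]) for g in
                            ("snare", "motor", "cargo_mem", "cargo_lum")}
                state.events.append(Event(
                    time=state.t, kind="bud", agent=new.id, donor=v.id,
                    t_bud=proc.t_bud, manifest=manifest))
                # a filament-anchored bud engages the track right away
                if sum(new.counts["motor"].values()) > 0 and state.filaments:
                    hit = state.sfield.nearest_filament(new.position)
                    if hit is not None and hit.distance <= new.radius * 2:
                        new.motion.mode = Mode.ON_FILAMENT
                        new.motion.filament = hit.filament
                        new.motion.arc = hit.arc
        elif (v.radius > 2 * p.vesicle_radius
              and v.surface > 2.0 * ves.sphere_surface(p.vesicle_radius)):
            # membrane (surface) is the conserved budget: an exhausted donor
            # cannot bud until fusions return lipids
            site = _budding_site(state, v)
            ves.initiate_budding(v, cfg, dt, rng, site_normal=site)


def _endocytosis_sweep(state: SimState, dt: float) -> None:
    """Coat clustering of explicit membrane agents; complete clusters pinch
    off as boosted vesicles."""
    if state.pm is None:
        return
    cfg = state.config
    rng = state.rng_vesicle
    R = state.cell.cell_radius
    layer = cfg.params.interaction_layer
    coat_species = [s.name for s in cfg.species if s.klass is Klass.COAT]

    # growth of existing clusters
    for cl in list(state.clusters):
        radius = ves.cluster_capture_radius(
            cl.size, 3 * state._species[cl.coat_species].radius, layer)
        anchor_pt = cl.anchor * R
        rates = _cluster_affinities(cfg, cl.coat_species)
        for sp, k in rates.items():
            units = state.pm_agents.get(sp)
            if units is None or len(units) == 0 or k == 0:
                continue
            d = np.linalg.norm(units * R - anchor_pt, axis=1)
            near = np.nonzero(d <= radius)[0]
            if len(near) == 0:
                continue
            keep = np.ones(len(units), dtype=bool)
            for i in near:
                if cl.size >= cfg.tables.shell_size and sp in coat_species:
                    break
                keep[i] = False
                cl.add_member(sp, sp in coat_species)
            state.pm_agents[sp] = units[keep]
        if cl.size >= cfg.tables.shell_size:
            new = ves.cluster_to_vesicle(cl, cfg, R, state.pm, birth_time=state.t)
            state.vesicles.append(new)
            state.by_id[new.id] = new
            state.events.append(Event(
                time=state.t, kind="endocytose", agent=new.id, donor=state.pm.id,
                manifest={g: dict(new.counts[g]) for g in
                          ("snare", "motor", "cargo_mem", "cargo_lum")}))
            state.clusters.remove(cl)

    # nucleation: membrane coat meets membrane cargo
    for coat in coat_species:
        units_c = state.pm_agents.get(coat)
        if units_c is None or len(units_c) == 0:
            continue
        for cargo, k in cfg.tables.k_coat_cargo.get(coat, {}).items():
            sp = cfg.species_by_name(cargo)
            if sp.klass is not Klass.CARGO_MEMBRANE or k == 0:
                continue
            units_g = state.pm_agents.get(cargo)
            if units_g is None or len(units_g) == 0:
                continue
            d_nuc = math.sqrt(k * dt / math.pi) + state._species[coat].radius \
                + sp.radius
            taken_c = np.zeros(len(units_c), dtype=bool)
            taken_g = np.zeros(len(units_g), dtype=bool)
            for i, u in enumerate(units_c):
                d = np.linalg.norm((units_g - u) * R, axis=1)
                cand = np.nonzero((d <= d_nuc) & ~taken_g)[0]
                if len(cand) == 0:
                    continue
                # same initiation damping as for compartment budding
                if rng.uniform() >= cfg.tables.bud_init_scale:
                    continue
                j = cand[0]
                taken_c[i] = True
                taken_g[j] = True
                anchor = u + units_g[j]
                anchor /= np.linalg.norm(anchor)
                cl = ves.CoatCluster(anchor=anchor, coat_species=coat)
                cl.add_member(coat, True)
                cl.add_member(cargo, False)
                state.clusters.append(cl)
            if taken_c.any():
                state.pm_agents[coat] = units_c[~taken_c]
                state.pm_agents[cargo] = units_g[~taken_g]
                units_c = state.pm_agents[coat]
                if len(units_c) == 0:
                    break


def _cluster_affinities(cfg: Config, coat: str) -> dict[str, float]:
    rates = {coat: 1.0}
    for table in (cfg.tables.k_coat_cargo, cfg.tables.k_coat_snare,
                  cfg.tables.k_coat_motor):
        for sp, k in table.get(coat, {}).items():
            if k > 0:
                rates[sp] = k
    return rates


# ---------------------------------------------------------------------------
# sampling / run
# ---------------------------------------------------------------------------

def _sample(state: SimState) -> None:
    row: dict = {"time": state.t}
    for v in state.vesicles:
        if v.mobile and not v.is_boundary:
            continue
        for group, d in v.counts.items():
            for sp, n in d.items():
                row[f"{v.identity}:{sp}"] = row.get(f"{v.identity}:{sp}", 0) + n
    for sp, pts in state.cyto.items():
        row[f"cytosol:{sp}"] = len(pts)
    for sp, units in state.pm_agents.items():
        row[f"PM:{sp}"] = len(units)
    # in-transit totals over mobile vesicles
    transit: dict[str, int] = {}
    for v in state.vesicles:
        if not v.mobile or v.is_boundary or v.volume <= 0:
            continue
        for group, d in v.counts.items():
            for sp, n in d.items():
                transit[sp] = transit.get(sp, 0) + n
    for sp, n in transit.items():
        row[f"transit:{sp}"] = n
    for sp, pts in state.nuc_inside.items():
        row[f"nucleus:{sp}"] = len(pts)
    for sp, pts in state.nuc_bound.items():
        row[f"nucleus_surface:{sp}"] = len(pts)
    for cl in state.clusters:
        for sp, n in cl.members.items():
            row[f"cluster:{sp}"] = row.get(f"cluster:{sp}", 0) + n
    state.samples.append(row)
    if state.record_trajectories:
        for v in state.vesicles:
            if v.mobile and v.volume > 0:
                state.trajectory.append(
                    (state.t, v.id, v.position[0], v.position[1],
                     v.position[2], v.motion.mode.value))


@dataclass
class SimResult:
    events: list[Event]
    metrics: RunMetrics
    state: SimState

    @property
    def timeseries(self) -> pd.DataFrame:
        return self.metrics.timeseries


def run_simulation(config: Config, seed: Optional[int] = None,
                   max_fusions: Optional[int] = None,
                   record_trajectories: bool = False) -> SimResult:
    """Execute the full loop; fully reproducible given (config, seed)."""
    state = SimState(config, seed=seed)
    state.record_trajectories = record_trajectories
    p = config.params
    dt = p.dt
    stride = p.reaction_stride
    dt_r = dt * stride
    n_steps = int(round(p.t_end / dt))
    sample_every = max(int(round(p.sample_interval / dt)), 1)
    _sample(state)
    for step in range(1, n_steps + 1):
        state.t = step * dt
        _move_molecules(state, dt)
        _move_vesicles(state, dt)
        if step % stride == 0:
            _recruitment_sweep(state, dt_r)
            _filament_sweep(state, dt_r)
            _fusion_sweep(state, dt_r)
            _endocytosis_sweep(state, dt_r)
            if config.scenario.signaling is not None:
                sig.signaling_sweep(state, dt_r)
            _unbinding_sweep(state, dt_r)
            _vesicle_actions(state, dt_r)
            _complete_fusions(state)
        if step % sample_every == 0:
            _sample(state)
        if max_fusions is not None:
            n_fus = sum(1 for e in state.events if e.kind in ("fuse", "exocytose"))
            if n_fus >= max_fusions:
                break
    tsdf = pd.DataFrame(state.samples).fillna(0.0)
    metrics = summarize(state.events, timeseries=tsdf)
    return SimResult(events=state.events, metrics=metrics, state=state)
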