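"""Per-vesicle machinery: well-mixed internal chemistry, coat recruitment,
budding with coat polymerization, saturating cargo/SNARE/motor loading,
coat depolymerization, and endocytic coat clustering.

Vesicle agents represent both compartments and transport vesicles
(compartments are just large vesicles).  Volume and surface area are both
conserved in every budding and fusion event; the sphere radius is derived
from the volume and surplus surface is allowed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import Config, InternalReaction, Klass, SpeciesDef
from .constants import molar_rate_to_um3
from .kinetics import first_order_probability
from .motion import Mode, MotionState

log = logging.getLogger(__name__)

FOUR_PI = 4.0 * math.pi

#: count-group key per species class for molecules held inside a vesicle
GROUP_OF_CLASS = {
    Klass.SNARE: "snare",
    Klass.MOTOR: "motor",
    Klass.CARGO_MEMBRANE: "cargo_mem",
    Klass.CARGO_LUMEN: "cargo_lum",
    Klass.CYTOSOLIC: "cargo_lum",
}

#: groups whose reaction propensities are surface-area based
MEMBRANE_GROUPS = {"coat_bound", "coat_pol", "snare", "motor", "cargo_mem"}

_ids = itertools.count(1)


def reset_agent_ids() -> None:
    """Restart the agent-id sequence (run reproducibility)."""
    global _ids
    _ids = itertools.count(1)


def sphere_volume(r: float) -> float:
    return FOUR_PI / 3.0 * r ** 3


def sphere_surface(r: float) -> float:
    return FOUR_PI * r ** 2


@dataclass(eq=False)
class BuddingProcess:
    coat_species: str
    site_normal: np.ndarray          # unit vector from the donor centre
    n_pol: int = 1                   # the initiating coat-cargo dimer coat
    t_bud: float = 0.0


@dataclass(eq=False)
class VesicleAgent:
    """A compartment or transport vesicle."""

    identity: str
    position: np.ndarray
    volume: float
    surface: float
    id: int = field(default_factory=lambda: next(_ids))
    donor_id: Optional[int] = None
    mobile: bool = True
    counts: dict[str, dict[str, int]] = field(default_factory=lambda: {
        "coat_bound": {}, "coat_pol": {}, "snare": {}, "motor": {},
        "cargo_mem": {}, "cargo_lum": {}})
    motion: MotionState = field(default_factory=MotionState)
    budding: Optional[BuddingProcess] = None
    depol_clock: float = 0.0
    birth_time: float = 0.0
    docked_partner: Optional[int] = None
    dock_until: float = 0.0
    is_boundary: bool = False        # the plasma membrane pseudo-compartment

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)

    @property
    def radius(self) -> float:
        return (3.0 * self.volume / FOUR_PI) ** (1.0 / 3.0)

    @property
    def n_pol(self) -> int:
        return sum(self.counts["coat_pol"].values())

    def get(self, group: str, species: str) -> int:
        return self.counts[group].get(species, 0)

    def add(self, group: str, species: str, n: int) -> None:
        cur = self.counts[group].get(species, 0) + n
        if cur < 0:
            raise ValueError(f"negative count for {species} in {group}")
        if cur == 0:
            self.counts[group].pop(species, None)
        else:
            self.counts[group][species] = cur

    def class_counts(self, group: str) -> dict[str, int]:
        return dict(self.counts[group])

    def total_count(self, species: str) -> int:
        return sum(g.get(species, 0) for g in self.counts.values())


def make_compartment(spec, config: Config) -> VesicleAgent:
    """Instantiate an initial compartment with its configured contents."""
    r = spec.radius
    v = VesicleAgent(identity=spec.identity, position=np.asarray(spec.center, float),
                     volume=sphere_volume(r), surface=sphere_surface(r),
                     mobile=spec.mobile)
    if not spec.mobile:
        v.motion.mode = Mode.FIXED
    for sp in config.species:
        n = sp.initial_counts.get(spec.id, 0)
        if n > 0:
            group = ("coat_bound" if sp.klass is Klass.COAT
                     else GROUP_OF_CLASS[sp.klass])
            v.add(group, sp.name, n)
    return v


# ---------------------------------------------------------------------------
# recruitment
# ---------------------------------------------------------------------------

def catcher_binding_rate(k_catch: float, n_catcher: int) -> float:
    """Recruitment rate of a cytosolic coat/motor to a compartment.

    Linear in the number of compartment-resident catcher molecules.
    """
    if n_catcher < 0:
        raise ValueError("catcher count must be >= 0")
    return k_catch * n_catcher


def recruitment_rate(vesicle: VesicleAgent, species: str, config: Config) -> float:
    """Total on-rate (1/(M*s)) of a cytosolic species to this vesicle."""
    sp = config.species_by_name(species)
    if sp.klass is Klass.COAT:
        table = config.tables.catcher_rate
        base = config.tables.coat_on_off.get(species)
    elif sp.klass is Klass.MOTOR:
        table = config.tables.motor_catcher_rate
        base = config.tables.motor_on_off.get(species)
    else:
        return 0.0
    k = base.k_on if base else 0.0
    for catcher, row in table.items():
        k_catch = row.get(species, 0.0)
        if k_catch > 0:
            n_catch = vesicle.total_count(catcher)
            k += catcher_binding_rate(k_catch, n_catch)
    return k


# ---------------------------------------------------------------------------
# internal well-mixed chemistry
# ---------------------------------------------------------------------------

def _group_for(species: str, config: Config, vesicle: VesicleAgent) -> str:
    sp = config.species_by_name(species)
    if sp.klass is Klass.COAT:
        return "coat_bound"
    return GROUP_OF_CLASS[sp.klass]


def _pair_propensity(vesicle: VesicleAgent, rxn: InternalReaction,
                     config: Config) -> float:
    g0 = _group_for(rxn.educts[0], config, vesicle)
    n0 = vesicle.get(g0, rxn.educts[0])
    if len(rxn.educts) == 1:
        return rxn.k * n0
    g1 = _group_for(rxn.educts[1], config, vesicle)
    n1 = vesicle.get(g1, rxn.educts[1])
    if rxn.educts[0] == rxn.educts[1]:
        pairs = n0 * (n0 - 1) / 2.0
    else:
        pairs = n0 * n1
    if rxn.basis == "surface":
        return rxn.k * pairs / vesicle.surface
    return molar_rate_to_um3(rxn.k) * pairs / vesicle.volume


def internal_reaction_sweep(vesicle: VesicleAgent, reactions: list[InternalReaction],
                            config: Config, dt: float,
                            rng: np.random.Generator) -> int:
    """Stochastic integration of the vesicle-internal reactions.

    Each educt molecule reacts with per-molecule probability a*dt/n; counts
    (and thus propensities) are updated immediately after each event.
    Returns the number of fired events.
    """
    fired = 0
    for rxn in reactions:
        if rxn.k == 0:
            continue
        if len(rxn.educts) == 1:
            g0 = _group_for(rxn.educts[0], config, vesicle)
            n0 = vesicle.get(g0, rxn.educts[0])
            if n0 == 0:
                continue
            p = first_order_probability(rxn.k, dt)
            m = int(rng.binomial(n0, p))
            if m:
                _apply(vesicle, rxn, config, m)
                fired += m
            continue
        # second order: sequential per-molecule test with immediate update
        g0 = _group_for(rxn.educts[0], config, vesicle)
        n0 = vesicle.get(g0, rxn.educts[0])
        for _ in range(n0):
            n_now = vesicle.get(g0, rxn.educts[0])
            if n_now == 0:
                break
            a = _pair_propensity(vesicle, rxn, config)
            if a == 0:
                break
            p_mol = a * dt / n_now
            if p_mol > 0.1:
                log.warning("per-molecule reaction probability %.3g > 0.1; "
                            "dt too coarse", p_mol)
            if rng.uniform() < p_mol:
                _apply(vesicle, rxn, config, 1)
                fired += 1
    return fired


def _apply(vesicle: VesicleAgent, rxn: InternalReaction, config: Config,
           m: int) -> None:
    for e in rxn.educts:
        vesicle.add(_group_for(e, config, vesicle), e, -m)
    for p in rxn.products:
        vesicle.add(_group_for(p, config, vesicle), p, +m)


# ---------------------------------------------------------------------------
# budding
# ---------------------------------------------------------------------------

def budding_initiation_propensity(vesicle: VesicleAgent, coat: str,
                                  config: Config) -> float:
    """Propensity (1/s) of coat-cargo dimer formation for one coat species."""
    n_coat = vesicle.get("coat_bound", coat)
    if n_coat == 0:
        return 0.0
    a = 0.0
    for cargo, k in config.tables.k_coat_cargo.get(coat, {}).items():
        if k == 0:
            continue
        sp = config.species_by_name(cargo)
        group = GROUP_OF_CLASS[sp.klass]
        n_cargo = vesicle.get(group, cargo)
        if n_cargo == 0:
            continue
        if group == "cargo_lum":
            a += molar_rate_to_um3(k) * n_coat * n_cargo / vesicle.volume
        else:
            a += k * n_coat * n_cargo / vesicle.surface
    return a


def initiate_budding(vesicle: VesicleAgent, config: Config, dt: float,
                     rng: np.random.Generator,
                     site_normal: Optional[np.ndarray] = None
                     ) -> Optional[BuddingProcess]:
    """Try to nucleate a bud: a coat-cargo dimer forms with the Eq-(8) scheme.

    Budding is cargo-dependent ("on demand"): zero cargo or zero bound coat
    monomers never initiate.  The budding site is the caller-supplied
    filament-anchored normal if any, else uniform random on the surface.
    """
    if vesicle.budding is not None:
        return None
    scale = config.tables.bud_init_scale
    props = {coat: scale * budding_initiation_propensity(vesicle, coat, config)
             for coat in vesicle.counts["coat_bound"]}
    a_tot = sum(props.values())
    if a_tot == 0:
        return None
    if rng.uniform() >= first_order_probability(a_tot, dt):
        return None
    coats = list(props)
    weights = np.array([props[c] for c in coats]) / a_tot
    coat = coats[int(rng.choice(len(coats), p=weights))]
    if site_normal is None:
        v = rng.normal(size=3)
        site_normal = v / np.linalg.norm(v)
    vesicle.add("coat_bound", coat, -1)     # the dimer's coat starts the shell
    proc = BuddingProcess(coat_species=coat, site_normal=np.asarray(site_normal))
    vesicle.budding = proc
    return proc


def polymerize_coat_step(vesicle: VesicleAgent, config: Config, dt: float,
                         rng: np.random.Generator) -> bool:
    """Advance an active budding process by one reaction interval.

    Monomers move bound -> polymerized with propensity k_poly * n_bound.
    Stalls when the donor runs out of bound monomers.  Returns True when the
    shell is complete.
    """
    proc = vesicle.budding
    assert proc is not None
    shell = config.tables.shell_size
    proc.t_bud += dt
    n_bound = vesicle.get("coat_bound", proc.coat_species)
    if n_bound > 0 and proc.n_pol < shell:
        p = first_order_probability(config.tables.k_poly * n_bound, dt)
        need = shell - proc.n_pol
        m = 0
        # sequential firings with depletion within the interval
        for _ in range(need):
            if n_bound - m == 0:
                break
            p = first_order_probability(config.tables.k_poly * (n_bound - m), dt)
            if rng.uniform() < p:
                m += 1
            else:
                break
        if m:
            vesicle.add("coat_bound", proc.coat_species, -m)
            proc.n_pol += m
    return proc.n_pol >= shell


def nascent_offset(proc: BuddingProcess, shell_size: int, r_ves: float) -> float:
    """Push-out distance of the nascent vesicle, tied to shell progress."""
    return 2.0 * r_ves * proc.n_pol / shell_size


def apply_class_saturation(try_numbers: dict[str, int], limit: int
                           ) -> dict[str, int]:
    """Scale per-species transfer numbers so their sum does not exceed limit.

    Uses largest-remainder rounding so the final sum equals the limit when
    the raw sum exceeds it.
    """
    if any(m < 0 for m in try_numbers.values()) or limit < 0:
        raise ValueError("try numbers and limit must be >= 0")
    total = sum(try_numbers.values())
    if total <= limit:
        return dict(try_numbers)
    f = limit / total
    scaled = {sp: m * f for sp, m in try_numbers.items()}
    floors = {sp: int(math.floor(x)) for sp, x in scaled.items()}
    short = limit - sum(floors.values())
    order = sorted(scaled, key=lambda sp: scaled[sp] - floors[sp], reverse=True)
    for sp in order[:short]:
        floors[sp] += 1
    return floors


def load_on_separation(donor: VesicleAgent, config: Config,
                       rng: np.random.Generator, birth_time: float = 0.0
                       ) -> VesicleAgent:
    """Complete a budding event: create the vesicle and load its contents.

    For each species j of class c in {cargo, snare, motor} the number of
    transferred molecules is Binomial(n_j, p_j) with
    p_j = 1 - exp(-k_load * <n_pol> * t_bud / denom), <n_pol> = shell/2,
    denom the donor surface (membrane species) or volume (luminal species);
    the per-class saturation loop is applied afterwards.  Volume and surface
    of the standard-size vesicle are subtracted from the donor.
    """
    proc = donor.budding
    assert proc is not None
    tables = config.tables
    shell = tables.shell_size
    r_ves = config.params.vesicle_radius
    coat = proc.coat_species

    ves = VesicleAgent(
        identity=f"ves({donor.identity})",
        position=donor.position + proc.site_normal * (donor.radius + r_ves),
        volume=sphere_volume(r_ves), surface=sphere_surface(r_ves),
        donor_id=donor.id, birth_time=birth_time)
    ves.add("coat_pol", coat, proc.n_pol)
    donor.volume -= ves.volume
    donor.surface -= ves.surface

    n_pol_avg = shell / 2.0
    loading_tables = {
        "cargo": tables.k_coat_cargo, "snare": tables.k_coat_snare,
        "motor": tables.k_coat_motor}
    for cls, table in loading_tables.items():
        tries: dict[str, int] = {}
        for j, k_load in table.get(coat, {}).items():
            if k_load == 0:
                continue
            sp = config.species_by_name(j)
            group = GROUP_OF_CLASS[sp.klass]
            n_j = donor.get(group, j)
            if n_j == 0:
                continue
            denom = donor.volume if group == "cargo_lum" else donor.surface
            if denom <= 0:
                continue
            if group == "cargo_lum":
                rate = molar_rate_to_um3(k_load) * n_pol_avg / denom
            else:
                rate = k_load * n_pol_avg / denom
            p_j = -math.expm1(-rate * proc.t_bud)
            tries[j] = int(rng.binomial(n_j, p_j))
        final = apply_class_saturation(tries, tables.class_limits.get(cls, 0))
        for j, m in final.items():
            if m == 0:
                continue
            sp = config.species_by_name(j)
            group = GROUP_OF_CLASS[sp.klass]
            m = min(m, donor.get(group, j))
            donor.add(group, j, -m)
            ves.add(group, j, +m)
    donor.budding = None
    return ves


# ---------------------------------------------------------------------------
# coat depolymerization
# ---------------------------------------------------------------------------

def depolymerize_coat(vesicle: VesicleAgent, dt: float, shell_size: int,
                      depol_time: float, t_lag: float = 0.0
                      ) -> dict[str, int]:
    """Linear shell decay after an optional lag; returns released monomers.

    n_pol(t) = shell_size * max(0, 1 - (t - t_lag)/depol_time); released
    monomers go back to the cytosolic pool (handled by the caller).
    """
    released: dict[str, int] = {}
    if vesicle.n_pol == 0:
        return released
    vesicle.depol_clock += dt
    t = vesicle.depol_clock
    if t <= t_lag:
        return released
    if depol_time <= 0:
        frac = 0.0
    else:
        frac = max(0.0, 1.0 - (t - t_lag) / depol_time)
    n_target = int(math.ceil(shell_size * frac - 1e-12))
    excess = vesicle.n_pol - n_target
    if excess <= 0:
        return released
    for sp in list(vesicle.counts["coat_pol"]):
        take = min(excess, vesicle.get("coat_pol", sp))
        if take > 0:
            vesicle.add("coat_pol", sp, -take)
            released[sp] = released.get(sp, 0) + take
            excess -= take
        if excess == 0:
            break
    return released


# ---------------------------------------------------------------------------
# endocytosis: coat clustering at the plasma membrane
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class CoatCluster:
    """A growing patch of membrane-bound machinery molecules."""

    anchor: np.ndarray               # unit vector to the patch centre
    coat_species: str
    members: dict[str, int] = field(default_factory=dict)   # species -> count
    size: int = 0                    # current coat count

    def add_member(self, species: str, is_coat: bool) -> None:
        self.members[species] = self.members.get(species, 0) + 1
        if is_coat:
            self.size += 1


def cluster_capture_radius(size: int, footprint_radius: float,
                           layer: float) -> float:
    """Capture radius of a cluster: disc footprint plus the reaction layer.

    Footprint area grows proportionally to the coat count, so the radius
    grows with sqrt(size); strictly increasing in size.
    """
    return footprint_radius * math.sqrt(max(size, 1)) + layer


def cluster_to_vesicle(cluster: CoatCluster, config: Config, cell_radius: float,
                       pm: VesicleAgent, birth_time: float = 0.0
                       ) -> VesicleAgent:
    """Convert a complete cluster into a boosted endocytic vesicle."""
    r_ves = config.params.vesicle_radius
    pos = cluster.anchor * (cell_radius - r_ves)
    ves = VesicleAgent(identity=f"ves({pm.identity})", position=pos,
                       volume=sphere_volume(r_ves), surface=sphere_surface(r_ves),
                       donor_id=pm.id, birth_time=birth_time)
    for sp_name, n in cluster.members.items():
        sp = config.species_by_name(sp_name)
        group = ("coat_pol" if sp.klass is Klass.COAT
                 else GROUP_OF_CLASS[sp.klass])
        ves.add(group, sp_name, n)
    pm.volume -= ves.volume
    pm.surface -= ves.surface
    ves.motion.mode = Mode.BOOSTED
    ves.motion.boost_direction = -cluster.anchor
    return ves
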