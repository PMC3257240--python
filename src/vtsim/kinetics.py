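"""Particle-based reaction kinetics between explicit agents.

Second-order reactions fire when two agents are within a critical distance
derived from the reaction volume V_r = k*dt: for non-overlapping agents the
volume is wrapped around the contact sphere as a thin reaction layer of
thickness delta (acceptance probability 1 inside it); for overlapping
agents the collision distance r_i + r_j is used with acceptance probability
P = V_r / V_int.  First-order reactions fire anywhere with probability
1 - exp(-k*dt).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constants import molar_rate_to_um3

log = logging.getLogger(__name__)

FOUR_PI_3 = 4.0 * math.pi / 3.0


def first_order_probability(k: float, dt: float) -> float:
    """p = 1 - exp(-k*dt)."""
    if k < 0:
        raise ValueError("rate must be >= 0")
    return -math.expm1(-k * dt)


def reaction_volume(k_molar: float, dt: float) -> float:
    """Reaction volume V_r = k*dt in µm³ for k in 1/(M*s)."""
    return molar_rate_to_um3(k_molar) * dt


def shell_thickness(r_contact: float, v_r: float) -> float:
    """Thickness delta of the layer around ``r_contact`` holding volume v_r.

    Solves (4*pi/3) * ((r+delta)^3 - r^3) = v_r.
    """
    return (r_contact ** 3 + v_r / FOUR_PI_3) ** (1.0 / 3.0) - r_contact


def contact_rule(r_i: float, r_j: float, k_molar: float, dt: float,
                 overlap_allowed: bool) -> tuple[float, float]:
    """Critical distance and acceptance probability for a bimolecular pair.

    Non-overlapping agents: critical distance r_i + r_j + delta with the
    reaction volume wrapped as a thin shell, acceptance 1.  Overlapping
    agents: critical distance r_i + r_j, acceptance V_r/V_int clamped to 1
    (with a warning: the time step is too large for this rate).
    """
    if r_i < 0 or r_j < 0:
        raise ValueError("radii must be >= 0")
    if k_molar < 0:
        raise ValueError("rate must be >= 0")
    v_r = reaction_volume(k_molar, dt)
    r_sum = r_i + r_j
    if not overlap_allowed:
        return r_sum + shell_thickness(r_sum, v_r), 1.0 if k_molar > 0 else 0.0
    v_int = FOUR_PI_3 * r_sum ** 3
    if v_int == 0:
        return r_sum, 0.0
    p = v_r / v_int
    if p > 1.0:
        log.warning("reaction probability %.3g clamped to 1 (dt too large "
                    "for k=%.3g /M/s)", p, k_molar)
        p = 1.0
    return r_sum, p


@dataclass
class ReactionRule:
    """A reaction between explicit agents (or an agent and a structure)."""

    educts: tuple[str, ...]          # 1 or 2 species names
    products: tuple[str, ...]
    k: float                         # 1/s (order 1) or 1/(M*s) (order 2)
    overlap_allowed: bool = True
    rule_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.educts = tuple(self.educts)
        self.products = tuple(self.products)
        if len(self.educts) not in (1, 2):
            raise ValueError("1 or 2 educts required")
        if self.k < 0:
            raise ValueError("rate must be >= 0")

    @property
    def order(self) -> int:
        return len(self.educts)


@dataclass
class ReactionEvent:
    time: float
    rule: ReactionRule
    agent_indices: tuple[int, ...]
    location: np.ndarray


class AgentPool:
    """Point agents of several species sharing one coordinate array.

    Molecule agents can overlap each other, so positions are plain arrays;
    removal is by boolean mask compaction at the end of each sweep.
    """

    def __init__(self, species_radius: dict[str, float]):
        self.radius = dict(species_radius)
        self.positions: dict[str, np.ndarray] = {
            sp: np.zeros((0, 3)) for sp in species_radius
        }

    def add(self, species: str, pts: np.ndarray) -> None:
        pts = np.atleast_2d(pts)
        if species not in self.positions:
            self.positions[species] = np.zeros((0, 3))
            self.radius.setdefault(species, 0.0)
        self.positions[species] = np.concatenate([self.positions[species], pts])

    def count(self, species: str) -> int:
        return len(self.positions.get(species, ()))


def pair_reaction_sweep(pool: AgentPool, rules: Sequence[ReactionRule], dt: float,
                        rng: np.random.Generator, time: float = 0.0,
                        boxsize: Optional[float] = None
                        ) -> list[ReactionEvent]:
    """Fire second-order reactions between agents of a pool.

    Candidate pairs come from a KD-tree neighborhood query with cutoff equal
    to the rule's critical distance.  Pairs are visited in randomized order
    and each agent is consumed at most once per sweep (first match wins).
    Products are placed at the pair midpoint.  ``boxsize`` switches to
    periodic (minimum-image) distances for well-mixed box validation.
    """
    events: list[ReactionEvent] = []
    consumed: dict[str, set[int]] = {sp: set() for sp in pool.positions}
    removals: dict[str, set[int]] = {sp: set() for sp in pool.positions}
    additions: dict[str, list[np.ndarray]] = {}

    candidates: list[tuple[ReactionRule, int, int, float]] = []
    for rule in rules:
        if rule.order != 2 or rule.k == 0:
            continue
        a, b = rule.educts
        pa, pb = pool.positions.get(a), pool.positions.get(b)
        if pa is None or pb is None or len(pa) == 0 or len(pb) == 0:
            continue
        d_crit, p_acc = contact_rule(pool.radius.get(a, 0.0), pool.radius.get(b, 0.0),
                                     rule.k, dt, rule.overlap_allowed)
        ta = cKDTree(pa, boxsize=boxsize)
        pairs = ta.query_ball_point(pb, d_crit)
        for jb, near in enumerate(pairs):
            for ia in near:
                if a == b and ia == jb:
                    continue
                candidates.append((rule, ia, jb, p_acc))

    rng.shuffle(candidates)
    for rule, ia, jb, p_acc in candidates:
        a, b = rule.educts
        if ia in consumed[a] or jb in consumed[b]:
            continue
        if a == b and (jb in consumed[a] or ia in consumed[b]):
            continue
        if p_acc < 1.0 and rng.uniform() >= p_acc:
            continue
        consumed[a].add(ia)
        consumed[b].add(jb)
        removals[a].add(ia)
        removals[b].add(jb)
        mid = (pool.positions[a][ia] + pool.positions[b][jb]) / 2.0
        for prod in rule.products:
            additions.setdefault(prod, []).append(mid)
        events.append(ReactionEvent(time, rule, (ia, jb), mid))

    for sp, idx in removals.items():
        if idx:
            keep = np.ones(len(pool.positions[sp]), dtype=bool)
            keep[list(idx)] = False
            pool.positions[sp] = pool.positions[sp][keep]
    for sp, pts in additions.items():
        pool.add(sp, np.array(pts))
    return events


def first_order_sweep(pool: AgentPool, rules: Sequence[ReactionRule], dt: float,
                      rng: np.random.Generator, time: float = 0.0
                      ) -> list[ReactionEvent]:
    """Fire first-order conversions, each agent testing all its channels.

    Competing channels for the same educt species are resolved by a single
    categorical draw per agent using the exact exponential race
    probabilities.
    """
    events: list[ReactionEvent] = []
    by_educt: dict[str, list[ReactionRule]] = {}
    for rule in rules:
        if rule.order == 1 and rule.k > 0:
            by_educt.setdefault(rule.educts[0], []).append(rule)

    additions: list[tuple[str, np.ndarray]] = []
    for sp, chans in by_educt.items():
        pos = pool.positions.get(sp)
        if pos is None or len(pos) == 0:
            continue
        k_tot = sum(r.k for r in chans)
        p_any = first_order_probability(k_tot, dt)
        fire = rng.uniform(size=len(pos)) < p_any
        if not fire.any():
            continue
        # channel choice proportional to k (exact exponential race)
        weights = np.array([r.k for r in chans]) / k_tot
        choice = rng.choice(len(chans), size=int(fire.sum()), p=weights)
        for (pt, ci) in zip(pos[fire], choice):
            rule = chans[ci]
            for prod in rule.products:
                additions.append((prod, pt))
            events.append(ReactionEvent(time, rule, (-1,), pt))
        pool.positions[sp] = pos[~fire]
    for prod, pt in additions:
        pool.add(prod, pt[None, :])
    return events
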