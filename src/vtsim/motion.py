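"""Agent propagation: Brownian steps, motor transport, actin boost.

The Brownian step uses a uniform step distribution with the same mean and
variance as the Gaussian (per-axis increment sqrt(2*D*dt)*xi with xi uniform
on [-sqrt(3), sqrt(3)]); by the central limit theorem the displacement
distribution converges to the Gaussian within a few iterations.  Steps into
an obstacle are rejected (the agent keeps its position for that step).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import Filament

SQRT3 = math.sqrt(3.0)


class Mode(enum.Enum):
    DIFFUSING = "diffusing"
    ON_FILAMENT = "on_filament"
    BOOSTED = "boosted"
    DOCKED = "docked"
    FIXED = "fixed"


@dataclass
class MotionState:
    mode: Mode = Mode.DIFFUSING
    filament: Optional[Filament] = None
    arc: float = 0.0
    boost_direction: np.ndarray = field(default_factory=lambda: np.zeros(3))
    stall_clock: float = 0.0

    def detach(self) -> None:
        self.mode = Mode.DIFFUSING
        self.filament = None
        self.arc = 0.0
        self.stall_clock = 0.0


def uniform_steps(rng: np.random.Generator, shape) -> np.ndarray:
    """Unit-variance, zero-mean uniform step factors."""
    return rng.uniform(-SQRT3, SQRT3, size=shape)


def diffusion_step(position: np.ndarray, D: float, dt: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Propose Brownian displacement(s); obstacle rejection is the caller's.

    Works on a single point (3,) or a batch (n, 3).
    """
    if D == 0:
        return np.array(position, copy=True)
    return position + math.sqrt(2.0 * D * dt) * uniform_steps(rng, np.shape(position))


def stokes_einstein_D(radius: float, ref_radius: float, ref_D: float) -> float:
    """D inversely proportional to radius, scaled to a reference object."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    return ref_D * ref_radius / radius


def tug_of_war_velocity(n_plus: int, v_plus: float, n_minus: int,
                        v_minus: float) -> float:
    """Signed net speed along filament polarity for opposing motor teams.

    v_eff = (n+*v+ - n-*v-)/(n+ + n-); 0 with no motors.  Provisional
    closed form (the source's detailed tug-of-war law is not public).
    """
    if n_plus < 0 or n_minus < 0:
        raise ValueError("motor counts must be >= 0")
    total = n_plus + n_minus
    if total == 0:
        return 0.0
    return (n_plus * v_plus - n_minus * v_minus) / total


def motor_step(state: MotionState, v_eff: float, dt: float,
               stall_time: float = float("inf")) -> np.ndarray:
    """Advance along the filament; detach at either end or after stalling.

    Returns the new cartesian position.  ``state`` is updated in place.
    """
    assert state.mode is Mode.ON_FILAMENT and state.filament is not None
    fil = state.filament
    if v_eff == 0.0:
        state.stall_clock += dt
        pos = fil.point_at(state.arc)
        if state.stall_clock >= stall_time:
            state.detach()
        return pos
    state.stall_clock = 0.0
    s = state.arc + v_eff * dt
    if s <= 0.0 or s >= fil.length:
        pos = fil.point_at(min(max(s, 0.0), fil.length))
        state.detach()
        return pos
    state.arc = s
    return fil.point_at(s)


def boost_step(position: np.ndarray, state: MotionState, v_boost: float,
               n_pol: int, dt: float) -> np.ndarray:
    """Directed push while the coat shell persists; hand off to diffusion."""
    assert state.mode is Mode.BOOSTED
    if n_pol <= 0:
        state.mode = Mode.DIFFUSING
        return np.array(position, copy=True)
    return position + v_boost * dt * state.boost_direction


def sphere_surface_step(units: np.ndarray, R: float, D: float, dt: float,
                        rng: np.random.Generator) -> np.ndarray:
    """2D diffusion of membrane agents on a sphere of radius R.

    ``units`` are unit direction vectors; a tangent-plane uniform step is
    applied and the result renormalized (valid for steps << R).
    """
    if D == 0 or len(units) == 0:
        return units
    step = math.sqrt(2.0 * D * dt) * uniform_steps(rng, units.shape)
    # remove the radial component
    radial = np.einsum("ij,ij->i", step, units)[:, None] * units
    p = units * R + (step - radial)
    return p / np.linalg.norm(p, axis=1, keepdims=True)
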