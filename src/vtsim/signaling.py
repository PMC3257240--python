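"""Receptor-mediated endocytosis coupled to a one-stage MAPK cascade.

The ligand is an implicit bulk concentration: after the addition time,
plasma-membrane receptors R activate to the receptor-ligand complex RL as a
first-order process.  RL is deactivated enzymatically only inside the
endosome.  RL anywhere on a membrane (PM, transport vesicle, endosome)
activates nearby cytosolic MAPK; MAPKp deactivates first-order with
separate constants in the cytoplasm and the nucleus; both MAPK forms bind
the nucleus surface and are released to either side.
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .config import Klass
from .constants import molar_rate_to_um3
from .kinetics import first_order_probability, reaction_volume
from .vesicle import GROUP_OF_CLASS, VesicleAgent

if TYPE_CHECKING:
    from .driver import SimState

FOUR_PI_3 = 4.0 * math.pi / 3.0


def _pool(state: "SimState", store: dict[str, np.ndarray], sp: str) -> np.ndarray:
    return store.setdefault(sp, np.zeros((0, 3)))


def pm_local_snares(state: "SimState", vesicle: VesicleAgent,
                    layer: float) -> dict[str, float]:
    """SNARE counts of the plasma membrane within the vesicle's contact patch.

    The patch is the spherical cap of the vesicle footprint plus the
    interaction layer around the contact point.
    """
    R = state.cell.cell_radius
    norm = np.linalg.norm(vesicle.position)
    if norm == 0:
        return {}
    anchor = vesicle.position / norm * R
    patch = vesicle.radius + layer
    counts: dict[str, float] = {}
    for sp, units in state.pm_agents.items():
        if state._species[sp].klass is not Klass.SNARE or len(units) == 0:
            continue
        d = np.linalg.norm(units * R - anchor, axis=1)
        n = int((d <= patch).sum())
        if n:
            counts[sp] = float(n)
    return counts


def deposit_on_pm(state: "SimState", vesicle: VesicleAgent) -> None:
    """Exocytosis: re-instantiate vesicle contents as explicit PM agents.

    Membrane species land near the fusion site (within the vesicle
    footprint); luminal content is kept as counts of the PM pseudo-
    compartment (released to the exterior in reality, retained here for
    global conservation).  Bound coats/motors become membrane agents that
    can dissociate back to the cytosol.
    """
    R = state.cell.cell_radius
    rng = state.rng_react
    norm = np.linalg.norm(vesicle.position)
    anchor = (vesicle.position / norm) if norm > 0 else np.array([0.0, 0.0, 1.0])
    spread = max(vesicle.radius / R, 1e-3)
    for group in ("snare", "motor", "cargo_mem", "coat_bound", "coat_pol"):
        for sp, n in vesicle.counts[group].items():
            jitter = anchor[None, :] + rng.normal(scale=spread, size=(n, 3))
            jitter /= np.linalg.norm(jitter, axis=1, keepdims=True)
            pool = _pool(state, state.pm_agents, sp)
            state.pm_agents[sp] = np.concatenate([pool, jitter])
    for sp, n in vesicle.counts["cargo_lum"].items():
        state.pm.add("cargo_lum", sp, n)


def signaling_sweep(state: "SimState", dt: float) -> None:
    sc = state.config.scenario.signaling
    assert sc is not None
    rng = state.rng_signal
    R_name, RL_name = sc.receptor, sc.receptor_ligand
    MAPK, MAPKp = sc.mapk, sc.mapk_p

    # r1: ligand binding at the plasma membrane (implicit bulk ligand)
    if state.t >= sc.t_ligand and sc.k_RL_on > 0:
        units = state.pm_agents.get(R_name)
        if units is not None and len(units):
            fire = rng.uniform(size=len(units)) < first_order_probability(
                sc.k_RL_on, dt)
            if fire.any():
                pool = _pool(state, state.pm_agents, RL_name)
                state.pm_agents[RL_name] = np.concatenate([pool, units[fire]])
                state.pm_agents[R_name] = units[~fire]

    # r2: enzymatic deactivation, only where the enzyme is present (endosome)
    enzyme_names = list(sc.enzyme_count)
    for v in state.vesicles:
        if v.volume <= 0 or v.is_boundary:
            continue
        n_rl = v.get("cargo_mem", RL_name)
        if n_rl == 0:
            continue
        n_e = sum(v.get("cargo_lum", e) for e in enzyme_names)
        if n_e == 0:
            continue
        p = min(sc.k_cat * n_e * dt / (sc.K_M + n_rl), 1.0)
        m = int(rng.binomial(n_rl, p))
        if m:
            v.add("cargo_mem", RL_name, -m)
            v.add("cargo_mem", R_name, +m)

    # r11: MAPK activation by RL-bearing membranes
    pts = state.cyto.get(MAPK)
    if pts is not None and len(pts):
        taken = np.zeros(len(pts), dtype=bool)
        r_m = state._species[MAPK].radius
        for v in state.vesicles:
            if v.volume <= 0 or v.is_boundary:
                continue
            n_rl = v.get("cargo_mem", RL_name)
            if n_rl == 0:
                continue
            d_crit = v.radius + r_m
            p_acc = min(reaction_volume(sc.k_MAPK_act_vesicle * n_rl, dt)
                        / (FOUR_PI_3 * d_crit ** 3), 1.0)
            d = np.linalg.norm(pts - v.position, axis=1)
            for i in np.nonzero((d <= d_crit) & ~taken)[0]:
                if rng.uniform() < p_acc:
                    taken[i] = True
        # PM: thin reaction layer holding the reaction volume of all PM RL
        n_rl_pm = len(state.pm_agents.get(RL_name, ()))
        if n_rl_pm and sc.k_MAPK_act_PM > 0:
            delta = reaction_volume(sc.k_MAPK_act_PM * n_rl_pm, dt) / (
                state.pm.surface)
            gap = state.cell.cell_radius - np.linalg.norm(pts, axis=1)
            for i in np.nonzero((gap <= delta + r_m) & ~taken)[0]:
                taken[i] = True
        if taken.any():
            pool = _pool(state, state.cyto, MAPKp)
            state.cyto[MAPKp] = np.concatenate([pool, pts[taken]])
            state.cyto[MAPK] = pts[~taken]

    # r12: deactivation of MAPKp, cytoplasm vs nucleus interior
    for store, k in ((state.cyto, sc.k_dephos_cyt),
                     (state.nuc_inside, sc.k_dephos_nuc)):
        pts_p = store.get(MAPKp)
        if pts_p is None or len(pts_p) == 0 or k == 0:
            continue
        fire = rng.uniform(size=len(pts_p)) < first_order_probability(k, dt)
        if fire.any():
            pool = _pool(state, store, MAPK)
            store[MAPK] = np.concatenate([pool, pts_p[fire]])
            store[MAPKp] = pts_p[~fire]

    # r13/r14: nucleus-surface binding and two-sided release
    if state.cell.nucleus_radius > 0 and sc.k_nuc_bind > 0:
        r_nuc = state.cell.nucleus_radius
        nc = state.cell.nucleus_center
        area = 4.0 * math.pi * r_nuc ** 2
        delta = reaction_volume(sc.k_nuc_bind, dt) / area
        for sp in (MAPK, MAPKp):
            r_m = state._species[sp].radius
            for store, inside in ((state.cyto, False), (state.nuc_inside, True)):
                pts_s = store.get(sp)
                if pts_s is None or len(pts_s) == 0:
                    continue
                rad = np.linalg.norm(pts_s - nc, axis=1)
                if inside:
                    near = (r_nuc - rad) <= (delta + r_m)
                else:
                    near = (rad - r_nuc) <= (delta + r_m)
                if near.any():
                    anchors = (pts_s[near] - nc)
                    anchors /= np.linalg.norm(anchors, axis=1, keepdims=True)
                    pool = _pool(state, state.nuc_bound, sp)
                    state.nuc_bound[sp] = np.concatenate([pool, anchors])
                    store[sp] = pts_s[~near]
        # release
        k_tot = sc.k_nuc_in + sc.k_nuc_out
        if k_tot > 0:
            p_any = first_order_probability(k_tot, dt)
            for sp in (MAPK, MAPKp):
                anchors = state.nuc_bound.get(sp)
                if anchors is None or len(anchors) == 0:
                    continue
                u = rng.uniform(size=len(anchors))
                go_in = u < p_any * (sc.k_nuc_in / k_tot)
                go_out = (~go_in) & (u < p_any)
                r_m = state._species[sp].radius
                if go_in.any():
                    pts_in = nc + anchors[go_in] * (r_nuc - 3 * r_m)
                    pool = _pool(state, state.nuc_inside, sp)
                    state.nuc_inside[sp] = np.concatenate([pool, pts_in])
                if go_out.any():
                    pts_out = nc + anchors[go_out] * (r_nuc + 3 * r_m)
                    pool = _pool(state, state.cyto, sp)
                    state.cyto[sp] = np.concatenate([pool, pts_out])
                state.nuc_bound[sp] = anchors[~(go_in | go_out)]


def receptor_flux_report(events: list, timeseries: pd.DataFrame,
                         receptor: str = "R", receptor_ligand: str = "RL",
                         mapk_p: str = "MAPKp") -> dict:
    """Summary of receptor location fluxes and vesicle cargo loads."""
    cols = {c for c in timeseries.columns}
    def series(prefix: str, sp: str) -> pd.Series:
        name = f"{prefix}:{sp}"
        return timeseries[name] if name in cols else pd.Series(
            0.0, index=timeseries.index)

    loads = []
    bud_times = []
    for e in events:
        if e.kind in ("bud", "endocytose"):
            cargo = e.manifest.get("cargo_mem", {})
            loads.append(sum(cargo.values()))
            bud_times.append(e.time)
    freq = (len(bud_times) / (timeseries["time"].iloc[-1] - timeseries["time"].iloc[0])
            if len(timeseries) > 1 else 0.0)
    return {
        "time": timeseries["time"],
        "R_PM": series("PM", receptor),
        "RL_PM": series("PM", receptor_ligand),
        "R_transit": series("transit", receptor),
        "RL_transit": series("transit", receptor_ligand),
        "R_endosome": series("E", receptor),
        "RL_endosome": series("E", receptor_ligand),
        "MAPKp_cyt": series("cytosol", mapk_p),
        "MAPKp_nuc": series("nucleus", mapk_p),
        "cargo_loads": loads,
        "budding_frequency": freq,
    }
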