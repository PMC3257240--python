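"""Ready-made scenario configurations.

All presets are desk-scale: geometry mirrors the published two-compartment
and endo/exocytosis setups, but molecule numbers and durations are reduced
so a scenario completes in seconds to minutes on one core.  Every rate
value is a provisional default (the original parameter supplement is not
public); they are chosen so that the machinery is functional — budding on
demand, recruitment turnover, motor transport, SNARE-selective fusion.
"""

from __future__ import annotations

from typing import Optional

from .config import Config, load_config


def two_compartment(style: str = "none", diffusion: str = "slow",
                    t_end: float = 200.0, seed: int = 0,
                    depol_time: float = 5.0, n_filaments: Optional[int] = None,
                    pool_scale: float = 1.0, motor_supply: float = 1.0,
                    **overrides) -> Config:
    """Two-compartment cell: donor/target spheres exchanging vesicles.

    ``style`` selects the cytoskeleton architecture (none/random/direct/
    linear/dipole); ``diffusion`` 'slow' or 'fast' selects the vesicle
    diffusion set.  Motors are loaded whenever filaments exist.
    ``pool_scale`` multiplies the compartment cargo/v-SNARE pools so long
    runs keep forming vesicles without depleting the donors ("sufficiently
    loaded" protocol); counts are bookkeeping only, so this is free.
    """
    if diffusion not in ("slow", "fast"):
        raise ValueError("diffusion must be 'slow' or 'fast'")
    ref_D = 0.0025 if diffusion == "slow" else 0.025
    # diffusion-only: compartments closer together than in all other setups
    x = 1.0 if style == "none" else 1.5
    if n_filaments is None:
        n_filaments = 32 if style == "linear" else 24
    n_cargo = int(round(250 * pool_scale))
    n_vsnare = int(round(150 * pool_scale))
    # motor_supply > 1 enlarges the cytosolic motor pool and its recruitment
    # so multi-hour runs do not slowly drain the donor-bound motors
    n_motor_cyt = int(round(60 * motor_supply))
    k_mcatch = 4.0e6 * motor_supply
    doc = {
        "species": [
            {"name": "coatA", "klass": "coat", "radius": 0.01,
             "diffusion_coeff": 2.0, "initial_counts": {"cytosol": 150, "C1": 25}},
            {"name": "coatB", "klass": "coat", "radius": 0.01,
             "diffusion_coeff": 2.0, "initial_counts": {"cytosol": 150, "C2": 25}},
            {"name": "cargo1", "klass": "cargo_membrane", "radius": 0.005,
             "diffusion_coeff": 0.0, "initial_counts": {"C1": n_cargo}},
            {"name": "cargo2", "klass": "cargo_membrane", "radius": 0.005,
             "diffusion_coeff": 0.0, "initial_counts": {"C2": n_cargo}},
            {"name": "catC1", "klass": "cargo_membrane", "radius": 0.005,
             "diffusion_coeff": 0.0, "initial_counts": {"C1": 60}},
            {"name": "catC2", "klass": "cargo_membrane", "radius": 0.005,
             "diffusion_coeff": 0.0, "initial_counts": {"C2": 60}},
            {"name": "snareX", "klass": "snare", "radius": 0.005,
             "diffusion_coeff": 0.0, "initial_counts": {"C1": n_vsnare}},
            {"name": "snareU", "klass": "snare", "radius": 0.005,
             "diffusion_coeff": 0.0, "initial_counts": {"C1": 120}},
            {"name": "snareY", "klass": "snare", "radius": 0.005,
             "diffusion_coeff": 0.0, "initial_counts": {"C2": 120}},
            {"name": "snareV", "klass": "snare", "radius": 0.005,
             "diffusion_coeff": 0.0, "initial_counts": {"C2": n_vsnare}},
            {"name": "motor1", "klass": "motor", "radius": 0.01,
             "diffusion_coeff": 2.0, "motor_direction": 1, "motor_speed": 1.0,
             "initial_counts": {"cytosol": n_motor_cyt, "C1": 25}},
            {"name": "motor2", "klass": "motor", "radius": 0.01,
             "diffusion_coeff": 2.0, "motor_direction": -1, "motor_speed": 1.0,
             "initial_counts": {"cytosol": n_motor_cyt, "C2": 25}},
        ],
        "interactions": {
            "k_coat_cargo": {"coatA": {"cargo1": 2.0e-2},
                             "coatB": {"cargo2": 2.0e-2}},
            "k_coat_snare": {"coatA": {"snareX": 1.5e-2, "snareV": 1.2e-2},
                             "coatB": {"snareV": 1.5e-2, "snareX": 1.2e-2}},
            "k_coat_motor": {"coatA": {"motor1": 4.0e-2},
                             "coatB": {"motor2": 4.0e-2}},
            "snare_strength": {
                "snareX": {"snareY": 1.0, "snareU": 0.4},
                "snareY": {"snareX": 1.0, "snareV": 0.4},
                "snareU": {"snareX": 0.4, "snareV": 1.0},
                "snareV": {"snareU": 1.0, "snareY": 0.4},
            },
            "catcher_rate": {"catC1": {"coatA": 3.0e7},
                             "catC2": {"coatB": 3.0e7}},
            "motor_catcher_rate": {"catC1": {"motor1": k_mcatch},
                                   "catC2": {"motor2": k_mcatch}},
            "coat_on_off": {"coatA": {"k_off": 0.4}, "coatB": {"k_off": 0.4}},
            "motor_on_off": {"motor1": {"k_off": 0.02}, "motor2": {"k_off": 0.02}},
            "k_poly": 0.3,
            # initiation propensity scales with the cargo pool; divide the
            # damping by pool_scale so the budding rate is pool-invariant
            "bud_init_scale": 2.0e-2 / pool_scale,
            "k_fil_bind": 7.0e6,
            "k_fus_pair": 3.0e9,
            "tau_pair": 0.5,
            "class_limits": {"cargo": 20, "snare": 10, "motor": 6},
            "shell_size": 10,
        },
        "scenario": {
            "cell": {"radius": 3.0},
            "cytoskeleton": {"style": style, "n_filaments": n_filaments,
                             "donor": "C1", "target": "C2",
                             "bundle_radius": 0.3, "spread": 0.9},
            "compartments": [
                {"id": "C1", "center": [x, 0.0, 0.0], "radius": 0.5},
                {"id": "C2", "center": [-x, 0.0, 0.0], "radius": 0.5},
            ],
        },
        "params": {"dt": 0.02, "reaction_stride": 5, "t_end": t_end,
                   "seed": seed, "ref_radius": 0.05, "ref_D": ref_D,
                   "vesicle_radius": 0.05, "depol_time": depol_time,
                   "depol_lag": 1.0, "interaction_layer": 0.01},
    }
    _apply_overrides(doc, overrides)
    return load_config(doc)


def endo_exo(style: str = "radial", t_end: float = 150.0, seed: int = 0,
             boost_speed: float = 0.5, depol_time: float = 5.0,
             n_filaments: int = 48, ligand: bool = False,
             **overrides) -> Config:
    """Plasma membrane + central endosome connected by endo-/exocytosis.

    Endocytic vesicles form by coat clustering at the PM (receptor cargo),
    get the actin boost, and are carried inward by minus-directed motors on
    a radial cytoskeleton; recycling vesicles bud from the endosome and
    exocytose receptors back to the PM.
    """
    doc = {
        "species": [
            {"name": "R", "klass": "cargo_membrane", "radius": 0.005,
             "diffusion_coeff": 0.5, "membrane_D": 0.005,
             "initial_counts": {"PM": 160, "E": 80}},
            {"name": "coatC", "klass": "coat", "radius": 0.012,
             "diffusion_coeff": 2.0, "membrane_D": 0.25,
             "initial_counts": {"cytosol": 400}},
            {"name": "coatD", "klass": "coat", "radius": 0.01,
             "diffusion_coeff": 2.0, "initial_counts": {"cytosol": 120, "E": 25}},
            {"name": "snareE", "klass": "snare", "radius": 0.005,
             "diffusion_coeff": 0.0, "membrane_D": 0.08,
             "initial_counts": {"PM": 140}},
            {"name": "snareT", "klass": "snare", "radius": 0.005,
             "diffusion_coeff": 0.0, "initial_counts": {"E": 150}},
            {"name": "snareV2", "klass": "snare", "radius": 0.005,
             "diffusion_coeff": 0.0, "initial_counts": {"E": 150}},
            {"name": "snareP", "klass": "snare", "radius": 0.005,
             "diffusion_coeff": 0.0, "membrane_D": 0.005,
             "initial_counts": {"PM": 150}},
            {"name": "motorIn", "klass": "motor", "radius": 0.01,
             "diffusion_coeff": 2.0, "membrane_D": 0.08,
             "motor_direction": -1, "motor_speed": 1.0,
             "initial_counts": {"cytosol": 60, "PM": 30}},
            {"name": "motorOut", "klass": "motor", "radius": 0.01,
             "diffusion_coeff": 2.0, "motor_direction": 1, "motor_speed": 1.0,
             "initial_counts": {"cytosol": 60, "E": 25}},
        ],
        "interactions": {
            "k_coat_cargo": {"coatC": {"R": 3.0e-2},
                             "coatD": {"R": 2.0e-2}},
            "k_coat_snare": {"coatC": {"snareE": 2.5e-2},
                             "coatD": {"snareV2": 5.0e-2, "snareE": 6.0e-3}},
            "k_coat_motor": {"coatC": {"motorIn": 5.0e-2},
                             "coatD": {"motorOut": 1.5e-1}},
            "snare_strength": {
                "snareE": {"snareT": 1.0, "snareP": 0.25},
                "snareT": {"snareE": 1.0, "snareV2": 0.25},
                "snareV2": {"snareP": 1.0, "snareT": 0.25},
                "snareP": {"snareV2": 1.0, "snareE": 0.25},
            },
            "catcher_rate": {"R": {"coatC": 2.5e7, "coatD": 5.0e7}},
            "motor_catcher_rate": {"R": {"motorIn": 1.5e6, "motorOut": 4.0e6}},
            "coat_on_off": {"coatC": {"k_off": 0.3}, "coatD": {"k_off": 0.3}},
            "motor_on_off": {"motorIn": {"k_off": 0.02},
                             "motorOut": {"k_off": 0.02}},
            "k_poly": 0.15,
            "bud_init_scale": 2.0e-2,
            "k_fil_bind": 7.0e6,
            "k_fus_pair": 3.0e9,
            "tau_pair": 0.5,
            "class_limits": {"cargo": 20, "snare": 10, "motor": 6},
            "shell_size": 6,
        },
        "scenario": {
            "cell": {"radius": 3.0},
            "cytoskeleton": {"style": style, "n_filaments": n_filaments},
            "compartments": [
                {"id": "E", "center": [0.0, 0.0, 0.0], "radius": 0.6},
            ],
        },
        "params": {"dt": 0.02, "reaction_stride": 5, "t_end": t_end,
                   "seed": seed, "ref_radius": 0.05, "ref_D": 0.01,
                   "vesicle_radius": 0.05, "boost_speed": boost_speed,
                   "depol_time": depol_time, "depol_lag": 1.0,
                   "interaction_layer": 0.01},
    }
    _apply_overrides(doc, overrides)
    return load_config(doc)


def signaling_cell(style: str = "radial", t_end: float = 120.0, seed: int = 0,
                   t_ligand: float = 10.0, polarization: float = 3.0,
                   **overrides) -> Config:
    """Receptor-mediated endocytosis coupled to the one-stage MAPK cascade.

    Extends :func:`endo_exo` with R/RL activation at the PM, enzymatic RL
    deactivation in the endosome, MAPK activation by RL-bearing membranes,
    and nucleus-surface shuttling.  ``style='polarized'`` gives the
    cell-polarization scenario.
    """
    doc_cfg = endo_exo(style=style, t_end=t_end, seed=seed)
    import yaml

    from .config import serialize
    doc = yaml.safe_load(serialize(doc_cfg))
    doc["species"].extend([
        {"name": "RL", "klass": "cargo_membrane", "radius": 0.005,
         "diffusion_coeff": 0.5, "membrane_D": 0.005, "initial_counts": {}},
        {"name": "MAPK", "klass": "cytosolic", "radius": 0.004,
         "diffusion_coeff": 2.0, "initial_counts": {"cytosol": 200}},
        {"name": "MAPKp", "klass": "cytosolic", "radius": 0.004,
         "diffusion_coeff": 2.0, "initial_counts": {}},
        {"name": "Enz", "klass": "cytosolic", "radius": 0.004,
         "diffusion_coeff": 0.0, "initial_counts": {"E": 394}},
    ])
    inter = doc["interactions"]
    # endocytosis is receptor-mediated: the active complex RL is the coat
    # catcher and the preferred endocytic cargo
    inter["k_coat_cargo"]["coatC"] = {"RL": 4.0e-2, "R": 4.0e-3}
    inter["k_coat_cargo"]["coatD"] = {"R": 8.0e-3}
    inter["catcher_rate"] = {"RL": {"coatC": 2.5e7}, "R": {"coatD": 5.0e7}}
    inter["motor_catcher_rate"] = {"RL": {"motorIn": 2.0e6},
                                   "R": {"motorOut": 4.0e6}}
    doc["scenario"]["cell"] = {"radius": 3.0, "nucleus_radius": 0.7,
                               "nucleus_center": [1.3, 0.0, 0.0]}
    doc["scenario"]["cytoskeleton"]["style"] = style
    doc["scenario"]["cytoskeleton"]["polarization"] = polarization
    doc["scenario"]["cytoskeleton"]["pole"] = [-1.0, 0.0, 0.0]
    if style == "polarized":
        # cell-polarization variant: strong receptor recycling flux so the
        # polarized delivery visibly reshapes the PM distribution
        inter["k_coat_cargo"]["coatD"] = {"R": 4.0e-2}
        for sp in doc["species"]:
            if sp["name"] in ("R", "RL"):
                sp["membrane_D"] = 0.003
    doc["scenario"]["signaling"] = {
        "t_ligand": t_ligand,
        "k_RL_on": 0.5,
        "enzyme_count": {"Enz": 394},
        "k_cat": 1.0,
        "K_M": 50.0,
        "k_MAPK_act_PM": 6.0e7,
        "k_MAPK_act_vesicle": 6.0e7,
        "k_dephos_cyt": 0.08,
        "k_dephos_nuc": 0.08,
        "k_nuc_bind": 1.0e9,
        "k_nuc_in": 1.0,
        "k_nuc_out": 0.4,
        "D_signal": 2.0,
    }
    _apply_overrides(doc, overrides)
    return load_config(doc)


PRESETS = {
    "two_compartment": two_compartment,
    "endo_exo": endo_exo,
    "signaling": signaling_cell,
}


def get_preset(name: str, **kwargs) -> Config:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name](**kwargs)


def _apply_overrides(doc: dict, overrides: dict) -> None:
    """Apply ``section__key=value`` style overrides to the raw document."""
    for key, value in overrides.items():
        parts = key.split("__")
        node = doc
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
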