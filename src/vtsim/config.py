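"""Model configuration: species registry, interaction tables, scenario, parameters.

A single structured-text (YAML) document defines the whole model: the cell,
the molecule species with their properties and initial abundances, the
interaction-rate tables of the vesicle machinery, the initial compartments,
an optional signaling block, and the simulation parameters.  The loader
validates all invariants and fills documented defaults for omitted optional
blocks, so that ``load_config(serialize(cfg)) == cfg`` for any valid config.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Optional, Union

import networkx as nx
import yaml


class ConfigError(ValueError):
    """A mandatory field is missing or a value violates an invariant."""


class Klass(str, enum.Enum):
    """Functional class of a molecular species."""

    COAT = "coat"
    SNARE = "snare"
    MOTOR = "motor"
    CARGO_MEMBRANE = "cargo_membrane"
    CARGO_LUMEN = "cargo_lumen"
    CYTOSOLIC = "cytosolic"


#: classes that reside in/on a membrane (2D, surface-based propensities)
MEMBRANE_CLASSES = {Klass.COAT, Klass.SNARE, Klass.MOTOR, Klass.CARGO_MEMBRANE}

#: classes competing for space in a budding vesicle, keyed by limit name
LOADING_CLASSES = {
    "cargo": (Klass.CARGO_MEMBRANE, Klass.CARGO_LUMEN),
    "snare": (Klass.SNARE,),
    "motor": (Klass.MOTOR,),
}


@dataclass
class SpeciesDef:
    """One molecular species.

    ``diffusion_coeff`` is either an explicit value in µm²/s or the string
    ``"stokes_einstein"``, in which case D is derived from the radius
    relative to the reference object of :class:`SimParams`.
    Motor species additionally carry a walking ``motor_speed`` (µm/s) and a
    ``motor_direction`` (+1 toward the filament plus end, -1 toward minus).
    """

    name: str
    klass: Klass
    radius: float
    diffusion_coeff: Union[float, str] = "stokes_einstein"
    initial_counts: dict[str, int] = field(default_factory=dict)
    membrane_D: float = 0.02
    motor_speed: float = 1.0
    motor_direction: int = +1

    def __post_init__(self) -> None:
        self.klass = Klass(self.klass)
        if self.radius <= 0:
            raise ConfigError(f"species {self.name!r}: radius must be > 0")
        if isinstance(self.diffusion_coeff, str):
            if self.diffusion_coeff != "stokes_einstein":
                raise ConfigError(
                    f"species {self.name!r}: diffusion_coeff must be a number "
                    f"or 'stokes_einstein'"
                )
        elif self.diffusion_coeff < 0:
            raise ConfigError(f"species {self.name!r}: diffusion_coeff must be >= 0")
        if self.motor_direction not in (+1, -1):
            raise ConfigError(f"species {self.name!r}: motor_direction must be +1 or -1")
        for where, n in self.initial_counts.items():
            if int(n) != n or n < 0:
                raise ConfigError(
                    f"species {self.name!r}: initial count at {where!r} must be a "
                    f"nonnegative integer"
                )
            self.initial_counts[where] = int(n)


def _as_rate_matrix(raw: Optional[dict], what: str) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for a, row in (raw or {}).items():
        out[a] = {}
        for b, k in row.items():
            k = float(k)
            if k < 0:
                raise ConfigError(f"{what}[{a}][{b}] must be >= 0")
            out[a][b] = k
    return out


@dataclass
class OnOff:
    """Baseline binding/unbinding rates of a cytosolic species to membranes.

    ``k_on`` is a baseline second-order rate in 1/(M*s) (usually 0; the
    catcher mechanism provides the actual recruitment rate), ``k_off`` is a
    first-order dissociation rate in 1/s.
    """

    k_on: float = 0.0
    k_off: float = 0.0

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise ConfigError("on/off rates must be >= 0")


@dataclass
class InteractionTables:
    """All rate matrices of the vesicle machinery.

    Membrane-phase bimolecular constants (coat-cargo, coat-snare, coat-motor
    loading) are in µm²/s per pair; catcher rates are in 1/(M*s) per catcher
    molecule; ``k_fus_pair`` is in 1/(M*s) per effective SNARE pair;
    ``snare_strength`` is a dimensionless symmetric matrix.
    """

    k_coat_cargo: dict[str, dict[str, float]] = field(default_factory=dict)
    k_coat_snare: dict[str, dict[str, float]] = field(default_factory=dict)
    k_coat_motor: dict[str, dict[str, float]] = field(default_factory=dict)
    snare_strength: dict[str, dict[str, float]] = field(default_factory=dict)
    catcher_rate: dict[str, dict[str, float]] = field(default_factory=dict)
    motor_catcher_rate: dict[str, dict[str, float]] = field(default_factory=dict)
    coat_on_off: dict[str, OnOff] = field(default_factory=dict)
    motor_on_off: dict[str, OnOff] = field(default_factory=dict)
    k_poly: float = 0.5
    #: scale on the coat-cargo dimer (initiation) propensity, decoupling
    #: budding frequency from the loading rates sharing the same matrix
    bud_init_scale: float = 1.0
    k_fil_bind: float = 5.0e8
    k_fus_pair: float = 2.0e8
    tau_pair: float = 1.0
    class_limits: dict[str, int] = field(default_factory=lambda: {"cargo": 20, "snare": 15, "motor": 8})
    shell_size: int = 10

    def __post_init__(self) -> None:
        for name in ("k_coat_cargo", "k_coat_snare", "k_coat_motor",
                     "snare_strength", "catcher_rate", "motor_catcher_rate"):
            setattr(self, name, _as_rate_matrix(getattr(self, name), name))
        for name in ("coat_on_off", "motor_on_off"):
            d = getattr(self, name)
            setattr(self, name, {
                sp: oo if isinstance(oo, OnOff) else OnOff(**oo) for sp, oo in d.items()
            })
        for u, row in self.snare_strength.items():
            for v, s in row.items():
                mirror = self.snare_strength.get(v, {})
                if u not in mirror or mirror[u] != s:
                    raise ConfigError(
                        f"snare_strength must be symmetric: [{u}][{v}]={s} but "
                        f"[{v}][{u}]={mirror.get(u)!r}"
                    )
        for val, name in ((self.k_poly, "k_poly"), (self.k_fus_pair, "k_fus_pair"),
                          (self.tau_pair, "tau_pair"), (self.k_fil_bind, "k_fil_bind")):
            if val < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.shell_size < 1:
            raise ConfigError("shell_size must be >= 1")
        for cls, lim in self.class_limits.items():
            if lim < 0:
                raise ConfigError(f"class_limits[{cls}] must be >= 0")

    def snare_s(self, u: str, v: str) -> float:
        return self.snare_strength.get(u, {}).get(v, 0.0)


@dataclass
class SimParams:
    """Global simulation parameters."""

    dt: float = 0.02
    reaction_stride: int = 5
    t_end: float = 100.0
    seed: int = 0
    boost_speed: float = 0.5
    depol_time: float = 5.0
    depol_lag: float = 1.0
    ref_radius: float = 0.05
    ref_D: float = 0.0025
    vesicle_radius: float = 0.05
    interaction_layer: float = 0.01
    stall_time: float = 2.0
    motor_speed_saturation: bool = False
    sample_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        if self.reaction_stride < 1:
            raise ConfigError("reaction_stride must be >= 1")
        if self.t_end < 0:
            raise ConfigError("t_end must be >= 0")


@dataclass
class CellParams:
    radius: float = 3.0
    nucleus_radius: float = 0.0
    nucleus_center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.nucleus_center = tuple(float(x) for x in self.nucleus_center)
        if self.radius <= 0:
            raise ConfigError("cell radius must be > 0")


@dataclass
class CompartmentSpec:
    """Initial state of one compartment (a large vesicle agent)."""

    id: str
    center: tuple[float, float, float]
    radius: float
    identity: Optional[str] = None
    mobile: bool = False

    def __post_init__(self) -> None:
        self.center = tuple(float(x) for x in self.center)
        if self.radius <= 0:
            raise ConfigError(f"compartment {self.id!r}: radius must be > 0")
        if self.identity is None:
            self.identity = self.id


@dataclass
class SignalingConfig:
    """Receptor/MAPK coupling parameters (all rates provisional defaults)."""

    receptor: str = "R"
    receptor_ligand: str = "RL"
    mapk: str = "MAPK"
    mapk_p: str = "MAPKp"
    t_ligand: float = 10.0
    k_RL_on: float = 0.5
    enzyme_count: dict[str, int] = field(default_factory=lambda: {"E": 394})
    k_cat: float = 1.0
    K_M: float = 50.0
    k_MAPK_act_PM: float = 1.0e8
    k_MAPK_act_vesicle: float = 1.0e8
    k_dephos_cyt: float = 0.1
    k_dephos_nuc: float = 0.1
    k_nuc_bind: float = 1.0e8
    k_nuc_in: float = 0.5
    k_nuc_out: float = 0.5
    D_signal: float = 2.0

    def __post_init__(self) -> None:
        for f_ in dataclasses.fields(self):
            v = getattr(self, f_.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise ConfigError(f"signaling.{f_.name} must be >= 0")


@dataclass
class CytoskeletonParams:
    style: str = "none"
    n_filaments: int = 32
    #: donor/target compartment ids for direct/linear/dipole styles
    donor: Optional[str] = None
    target: Optional[str] = None
    bundle_radius: float = 0.3
    spread: float = 1.0
    persistence: float = 1.0
    length: float = 4.0
    step: float = 0.05
    pole: tuple[float, float, float] = (-1.0, 0.0, 0.0)
    polarization: float = 3.0

    def __post_init__(self) -> None:
        self.pole = tuple(float(x) for x in self.pole)
        if self.style not in ("none", "random", "direct", "linear", "dipole",
                              "radial", "polarized"):
            raise ConfigError(f"unknown cytoskeleton style {self.style!r}")


@dataclass
class ScenarioSpec:
    cell: CellParams = field(default_factory=CellParams)
    cytoskeleton: CytoskeletonParams = field(default_factory=CytoskeletonParams)
    compartments: list[CompartmentSpec] = field(default_factory=list)
    signaling: Optional[SignalingConfig] = None

    def __post_init__(self) -> None:
        import numpy as np

        R = self.cell.radius
        for c in self.compartments:
            if float(np.linalg.norm(c.center)) + c.radius > R + 1e-12:
                raise ConfigError(f"compartment {c.id!r} does not fit inside the cell")
        for a_i in range(len(self.compartments)):
            for b_i in range(a_i + 1, len(self.compartments)):
                a, b = self.compartments[a_i], self.compartments[b_i]
                d = float(np.linalg.norm(np.subtract(a.center, b.center)))
                if d < a.radius + b.radius - 1e-12:
                    raise ConfigError(f"compartments {a.id!r} and {b.id!r} overlap")


@dataclass
class InternalReaction:
    """A reaction running in the well-mixed interior of vesicle agents.

    ``basis`` selects the density normalization: ``volume`` (luminal/3D,
    k in 1/(M*s)) or ``surface`` (membrane-bound/2D, k in µm²/s per pair).
    """

    educts: list[str]
    products: list[str]
    k: float
    basis: str = "volume"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ConfigError("reaction rate must be >= 0")
        if len(self.educts) not in (1, 2):
            raise ConfigError("reactions must have 1 or 2 educts")
        if self.basis not in ("volume", "surface"):
            raise ConfigError("reaction basis must be 'volume' or 'surface'")


@dataclass
class Config:
    species: list[SpeciesDef]
    tables: InteractionTables
    scenario: ScenarioSpec
    params: SimParams
    reactions: list[InternalReaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ConfigError("species names must be unique")
        known = set(names)
        for matname in ("k_coat_cargo", "k_coat_snare", "k_coat_motor",
                        "snare_strength", "catcher_rate", "motor_catcher_rate"):
            for a, row in getattr(self.tables, matname).items():
                for b in row:
                    if a not in known or b not in known:
                        raise ConfigError(
                            f"interaction {matname}[{a}][{b}] references unknown species"
                        )
        for r in self.reactions:
            for sp in list(r.educts) + list(r.products):
                if sp not in known:
                    raise ConfigError(f"reaction references unknown species {sp!r}")

    # -- convenience lookups -------------------------------------------------
    def species_by_name(self, name: str) -> SpeciesDef:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def species_of_class(self, klass: Klass) -> list[SpeciesDef]:
        return [s for s in self.species if s.klass is klass]


# ---------------------------------------------------------------------------
# loading / serialization
# ---------------------------------------------------------------------------

_MANDATORY = ("species",)


def _build(doc: dict) -> Config:
    for key in _MANDATORY:
        if key not in doc:
            raise ConfigError(f"missing mandatory field {key!r}")
    species = [SpeciesDef(**s) for s in doc["species"]]
    tables = InteractionTables(**doc.get("interactions", {}))
    scen_raw = dict(doc.get("scenario", {}))
    cell = CellParams(**scen_raw.get("cell", {}))
    cytos = CytoskeletonParams(**scen_raw.get("cytoskeleton", {}))
    comps = [CompartmentSpec(**c) for c in scen_raw.get("compartments", [])]
    sig = scen_raw.get("signaling")
    signaling = SignalingConfig(**sig) if sig is not None else None
    scenario = ScenarioSpec(cell=cell, cytoskeleton=cytos, compartments=comps,
                            signaling=signaling)
    params = SimParams(**doc.get("params", {}))
    reactions = [InternalReaction(**r) for r in doc.get("reactions", [])]
    return Config(species=species, tables=tables, scenario=scenario,
                  params=params, reactions=reactions)


def load_config(source: Union[str, dict]) -> Config:
    """Parse and validate a configuration document.

    ``source`` may be a YAML string, a path to a YAML file, or an
    already-parsed mapping.  Raises :class:`ConfigError` on any violated
    invariant, naming the offending field.
    """
    if isinstance(source, dict):
        return _build(source)
    text = source
    if "\n" not in source and (source.endswith((".yaml", ".yml")) or "/" in source):
        with open(source) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    return _build(doc)


def _clean(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _clean(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    return obj


def serialize(config: Config) -> str:
    """Render a config back to YAML.  ``load_config(serialize(c)) == c``."""
    doc = {
        "species": [_clean(s) for s in config.species],
        "interactions": _clean(config.tables),
        "scenario": {
            "cell": _clean(config.scenario.cell),
            "cytoskeleton": _clean(config.scenario.cytoskeleton),
            "compartments": [_clean(c) for c in config.scenario.compartments],
        },
        "params": _clean(config.params),
        "reactions": [_clean(r) for r in config.reactions],
    }
    if config.scenario.signaling is not None:
        doc["scenario"]["signaling"] = _clean(config.scenario.signaling)
    return yaml.safe_dump(doc, sort_keys=False)


# ---------------------------------------------------------------------------
# module structure
# ---------------------------------------------------------------------------

@dataclass
class ModuleReport:
    """Connected components of the machinery interaction graph.

    Each component couples a set of coat/snare/motor/cargo species through
    nonzero rates and acts as one independent transport module.
    """

    modules: list[set[str]]

    @property
    def n_modules(self) -> int:
        return len(self.modules)


def validate_module_structure(tables: InteractionTables) -> ModuleReport:
    """Find the independent sub-matrices (transport modules) of the tables.

    Builds the graph whose nodes are species appearing in any nonzero
    interaction entry and whose edges are those entries, then returns its
    connected components.
    """
    g = nx.Graph()
    mats = (tables.k_coat_cargo, tables.k_coat_snare, tables.k_coat_motor,
            tables.snare_strength, tables.catcher_rate, tables.motor_catcher_rate)
    for mat in mats:
        for a, row in mat.items():
            for b, k in row.items():
                if k > 0:
                    g.add_edge(a, b)
    return ModuleReport(modules=[set(c) for c in nx.connected_components(g)])
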