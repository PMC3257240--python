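import numpy as np
import pytest

from vtsim.config import load_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


MINIMAL_DOC = {
    "species": [
        {"name": "coatA", "klass": "coat", "radius": 0.01,
         "diffusion_coeff": 2.0, "initial_counts": {"cytosol": 10, "C1": 5}},
        {"name": "cargo1", "klass": "cargo_membrane", "radius": 0.005,
         "diffusion_coeff": 0.0, "initial_counts": {"C1": 50}},
        {"name": "lum1", "klass": "cargo_lumen", "radius": 0.004,
         "diffusion_coeff": 1.0, "initial_counts": {"C1": 30}},
        {"name": "snareX", "klass": "snare", "radius": 0.005,
         "diffusion_coeff": 0.0, "initial_counts": {"C1": 40}},
        {"name": "snareY", "klass": "snare", "radius": 0.005,
         "diffusion_coeff": 0.0, "initial_counts": {"C2": 40}},
        {"name": "motor1", "klass": "motor", "radius": 0.01,
         "diffusion_coeff": 2.0, "motor_direction": 1,
         "initial_counts": {"C1": 8}},
    ],
    "interactions": {
        "k_coat_cargo": {"coatA": {"cargo1": 2e-2}},
        "k_coat_snare": {"coatA": {"snareX": 1.5e-2}},
        "k_coat_motor": {"coatA": {"motor1": 4e-2}},
        "snare_strength": {"snareX": {"snareY": 1.0},
                           "snareY": {"snareX": 1.0}},
        "catcher_rate": {"cargo1": {"coatA": 1e7}},
        "coat_on_off": {"coatA": {"k_off": 0.4}},
        "k_poly": 0.3,
        "shell_size": 5,
        "class_limits": {"cargo": 20, "snare": 10, "motor": 6},
    },
    "scenario": {
        "cell": {"radius": 3.0},
        "compartments": [
            {"id": "C1", "center": [1.0, 0.0, 0.0], "radius": 0.5},
            {"id": "C2", "center": [-1.0, 0.0, 0.0], "radius": 0.5},
        ],
    },
    "params": {"dt": 0.02, "t_end": 10.0, "vesicle_radius": 0.05},
}


@pytest.fixture
def minimal_doc():
    import copy

    return copy.deepcopy(MINIMAL_DOC)


@pytest.fixture
def minimal_config(minimal_doc):
    return load_config(minimal_doc)
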