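"""Shared fixtures: synthetic structures and their derived objects.

Everything is generated at test time; expensive stages (network, pebble
game, modes, trajectories) are session-scoped so the suite stays fast.
"""

import warnings

import pytest

from pdiflex.enm import build_enm, compute_modes
from pdiflex.geomsim import build_ghosts, run_trajectory
from pdiflex.network import build_network
from pdiflex.pebble import pebble_game
from pdiflex.synth import SyntheticSpec, default_annotation, make_structure


@pytest.fixture(scope="session")
def dumbbell_spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def dumbbell(dumbbell_spec):
    return make_structure(dumbbell_spec)


@pytest.fixture(scope="session")
def dumbbell_annotation(dumbbell_spec):
    return default_annotation(dumbbell_spec)


@pytest.fixture(scope="session")
def dumbbell_network(dumbbell):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_network(dumbbell)


@pytest.fixture(scope="session")
def dumbbell_decomposition(dumbbell_network):
    return pebble_game(dumbbell_network)


@pytest.fixture(scope="session")
def dumbbell_ghosts(dumbbell, dumbbell_decomposition, dumbbell_network):
    return build_ghosts(dumbbell, dumbbell_decomposition, dumbbell_network)


@pytest.fixture(scope="session")
def dumbbell_modes(dumbbell):
    return build_enm(dumbbell, 10.0), compute_modes(build_enm(dumbbell, 10.0), 5)


@pytest.fixture(scope="session")
def dumbbell_closing_run(dumbbell, dumbbell_ghosts, dumbbell_modes):
    """Mode-7 run in each direction until jamming or budget, plus metadata."""
    enm, ms = dumbbell_modes
    runs = {}
    for direction in ("+", "-"):
        runs[direction] = run_trajectory(dumbbell, ms.mode(7), direction,
                                         ghosts=dumbbell_ghosts, max_conformers=400,
                                         mode_index=7)
    return runs


@pytest.fixture(scope="session")
def horseshoe_spec():
    return SyntheticSpec(n_domains=4, geometry="horseshoe", plant_active_sites=True)


@pytest.fixture(scope="session")
def horseshoe(horseshoe_spec):
    return make_structure(horseshoe_spec)
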