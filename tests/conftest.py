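import numpy as np
import pytest

from smorepars.abm import ABMConfig, ABMState, initialize
from smorepars.vasculature import Vasculature


@pytest.fixture
def small_config():
    """Small, fast ABM configuration for unit tests (20^3 lattice)."""
    return ABMConfig(
        n_stem_init=4, n_prog_init=16, tumor_lattice_n=20, vessel_lattice_n=200,
        n_iterations=20, seed=11,
    )


def make_state(positions, config, phenotype=None, vessels=None, hypoxic=None):
    """Hand-built ABM state for operation-level tests."""
    pos = np.asarray(positions, dtype=np.int64).reshape(-1, 3)
    n = len(pos)
    lat = config.tumor_lattice_n
    occ = np.zeros((lat, lat, lat), dtype=bool)
    if n:
        occ[tuple(pos.T)] = True
    phen = np.asarray(
        phenotype if phenotype is not None else np.ones(n), dtype=np.uint8
    )
    return ABMState(
        iteration=0,
        pos=pos,
        phenotype=phen,
        divisions_used=np.zeros(n, dtype=np.int64),
        migratory=np.zeros(n, dtype=np.uint8),
        senescent=np.zeros(n, dtype=bool),
        hypoxic=np.asarray(hypoxic if hypoxic is not None else np.zeros(n), dtype=bool),
        occ=occ,
        vessels=vessels if vessels is not None else Vasculature([]),
        origin=pos.mean(axis=0) if n else np.zeros(3),
    )
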