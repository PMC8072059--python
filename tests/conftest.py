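"""Shared fixtures: small deterministic ensembles and restraint sets."""

import numpy as np
import pytest

import ddrensemble as dd


@pytest.fixture(scope="session")
def grid():
    return dd.default_grid()


@pytest.fixture(scope="session")
def lc_sequence():
    """A 40-residue glycine/serine-rich low-complexity test sequence."""
    return "GSSGYGQSSGYGQQSSGSYGQSSYGGSSQSYGGQSSYGGS"


@pytest.fixture(scope="session")
def truth_ensemble():
    """Ground-truth backbone ensemble sampled from coil statistics."""
    return dd.build_raw_ensemble(
        "GSSGYGQSSGYGQQSSGSYGQSSYGGSSQSYGGQSSYGGS", n_target=80, rng_seed=21
    )


@pytest.fixture(scope="session")
def truth_restraints(truth_ensemble):
    pairs = [(2, 18), (10, 30), (2, 39), (22, 39), (5, 35)]
    return dd.simulate_restraints(truth_ensemble, pairs, seed=2)


@pytest.fixture(scope="session")
def three_conformer_truth():
    """3 freely-jointed conformers with populations (0.5, 0.3, 0.2) and
    5 self-simulated distance-distribution restraints."""
    ens = dd.make_ideal_chain_ensemble(40, 3, seed=11)
    ens.populations = np.array([0.5, 0.3, 0.2])
    pairs = [(2, 20), (10, 30), (2, 38), (20, 38), (5, 35)]
    restraints = dd.simulate_restraints(ens, pairs, seed=1)
    return ens, restraints
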