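import numpy as np
import pytest

from nscodon.codes import codon_state_space
from nscodon.likelihood import CodonAlignment
from nscodon.models import (
    CodonFreqs,
    EdgeProcess,
    build_gnc_generator,
    stationary_distribution,
)
from nscodon.simulate import SimSpec, simulate_alignment
from nscodon.trees import Topology, TreeModel


@pytest.fixture(scope="session")
def space():
    return codon_state_space()


@pytest.fixture(scope="session")
def space_with_stops():
    return codon_state_space(include_stops=True)


def transition_biased_rates(kappa: float = 4.0) -> np.ndarray:
    """Symmetric nucleotide rates with a transition/transversion bias."""
    r = np.ones((4, 4))
    # A<->G and C<->T are the transitions; indices follow A,C,G,T
    r[0, 2] = r[2, 0] = kappa
    r[1, 3] = r[3, 1] = kappa
    np.fill_diagonal(r, 0.0)
    return r


def gnc_triad_model(
    space,
    taus=(0.3, 0.4, 0.5),
    omegas=(0.3, 0.3, 0.3),
    rates=None,
    taxa=("A", "B", "C"),
) -> TreeModel:
    """A node-rooted GNC model with known parameters, rooted at the
    stationary composition of the first edge's process."""
    if rates is None:
        rates = [transition_biased_rates()] * 3
    Q0 = build_gnc_generator(rates[0], omegas[0], space)
    pi_root = CodonFreqs(stationary_distribution(Q0))
    topo = Topology.node_rooted(taxa)
    procs = {
        t: EdgeProcess.gnc(r, w, tau, pi_root, space)
        for t, r, w, tau in zip(taxa, rates, omegas, taus)
    }
    return TreeModel(topology=topo, root_freqs=pi_root, edge_processes=procs)


@pytest.fixture(scope="session")
def triad_model(space):
    return gnc_triad_model(space)


@pytest.fixture(scope="session")
def triad_alignment(space, triad_model) -> CodonAlignment:
    return simulate_alignment(SimSpec(model=triad_model, n_codons=600, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
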