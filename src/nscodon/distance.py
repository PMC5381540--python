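"""Genetic distance as the expected number of substitutions per codon.

Under a nonstationary process the scale parameter tau is not the expected
number of substitutions; the distance on an edge with calibrated generator Q,
scale tau, and parent-node codon distribution pi_a is

    d = -pi_a . [ integral_0^tau exp(Q s) ds ] . diag(Q)

which reduces to tau when pi_a is the stationary distribution of a calibrated
process (the time-reversible case).  The integral is evaluated through the
augmented block identity: the top-right block of ``exp([[Q, I], [0, 0]] tau)``
equals ``integral_0^tau exp(Q s) ds``, robust even for defective generators.
Distances add along paths, each edge weighted by the distribution at its own
parent node.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .likelihood import ModelFit
from .models import CodonFreqs
from .trees import TreeModel, node_distribution

__all__ = [
    "expected_substitutions_edge",
    "edge_distances",
    "path_distance",
    "distance_bias",
    "omega_bias",
]


def integrated_expm(Q: np.ndarray, tau: float) -> np.ndarray:
    """integral_0^tau exp(Q s) ds via one block matrix exponential."""
    n = Q.shape[0]
    A = np.zeros((2 * n, 2 * n))
    A[:n, :n] = Q
    A[:n, n:] = np.eye(n)
    return expm(A * tau)[:n, n:]


def expected_substitutions_edge(
    pi_a: CodonFreqs | np.ndarray, Q: np.ndarray, tau: float
) -> float:
    """Expected substitutions per codon on one edge (see module docstring)."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    if tau == 0:
        return 0.0
    p = pi_a.pi if isinstance(pi_a, CodonFreqs) else np.asarray(pi_a, dtype=float)
    J = integrated_expm(Q, tau)
    return float(-(p @ J @ np.diag(Q)))


def edge_distances(model: TreeModel) -> dict[str, float]:
    """Expected substitutions per codon for every edge, keyed by child node."""
    out: dict[str, float] = {}
    for parent, child in model.topology.edges:
        proc = model.edge_processes[child]
        pi_parent = node_distribution(model, parent)
        out[child] = expected_substitutions_edge(pi_parent, proc.Q, proc.tau)
    return out


def path_distance(fit_or_model: ModelFit | TreeModel, taxon1: str, taxon2: str) -> float:
    """Expected substitutions per codon along the path between two taxa."""
    model = fit_or_model.model if isinstance(fit_or_model, ModelFit) else fit_or_model
    if taxon1 == taxon2:
        if taxon1 not in model.topology.taxa:
            raise ValueError(f"unknown taxon {taxon1!r}")
        return 0.0
    per_edge = edge_distances(model)
    return float(
        sum(per_edge[child] for _, child in model.topology.path_between(taxon1, taxon2))
    )


def distance_bias(
    fit_tr: ModelFit | TreeModel,
    fit_gnc: ModelFit | TreeModel,
    taxon_pair: tuple[str, str],
) -> float:
    """d(time-reversible) - d(GNC) for a taxon pair; positive means the
    time-reversible model overestimates the distance relative to GNC."""
    m_tr = fit_tr.model if isinstance(fit_tr, ModelFit) else fit_tr
    m_gnc = fit_gnc.model if isinstance(fit_gnc, ModelFit) else fit_gnc
    if set(m_tr.topology.taxa) != set(m_gnc.topology.taxa):
        raise ValueError("fits are over different taxa")
    a, b = taxon_pair
    return path_distance(m_tr, a, b) - path_distance(m_gnc, a, b)


def omega_bias(
    fit_gnc: ModelFit | TreeModel, fit_tr: ModelFit | TreeModel, edge: str
) -> float:
    """omega(GNC) - omega(time-reversible) on one edge; positive means the
    time-reversible model underestimates omega relative to GNC."""
    m_gnc = fit_gnc.model if isinstance(fit_gnc, ModelFit) else fit_gnc
    m_tr = fit_tr.model if isinstance(fit_tr, ModelFit) else fit_tr
    for m in (m_gnc, m_tr):
        if edge not in m.edge_processes:
            raise ValueError(f"edge {edge!r} missing from fit")
    return m_gnc.edge_processes[edge].omega - m_tr.edge_processes[edge].omega
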