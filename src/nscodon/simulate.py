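"""Alignment simulation and the synthetic nonstationary fixture generator.

Sites evolve independently and identically: a root codon is drawn from the
root distribution, then propagated along each directed edge by sampling from
the corresponding row of that edge's transition matrix.  Internal states are
discarded.  Randomness is driven by a ``SeedSequence`` keyed on
``(seed, replicate_id)`` so replicates are reproducible independently of
execution order.

The fixture generator builds an edge-rooted GNC model whose ingroup
processes drift in GC content, emulating triads chosen for maximal
compositional divergence.  At divergence level zero all edges share a single
process started from its stationary distribution, so leaf compositions agree
in expectation; increasing the level tilts the ingroup nucleotide rates
toward G/C, raising the expected pairwise compositional divergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codes import NUC_INDEX, CodonStateSpace, codon_state_space
from .likelihood import CodonAlignment
from .models import CodonFreqs, EdgeProcess, stationary_distribution
from .trees import Topology, TreeModel

__all__ = [
    "SimSpec",
    "simulate_alignment",
    "simulate_sequences",
    "make_nonstationary_fixture",
    "bias_experiment",
]


@dataclass(frozen=True)
class SimSpec:
    model: TreeModel
    n_codons: int
    seed: int
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")


def _simulate_leaf_indices(
    model: TreeModel, n_codons: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    n_states = model.root_freqs.pi.shape[0]
    states: dict[str, np.ndarray] = {
        model.topology.root: rng.choice(n_states, size=n_codons, p=model.root_freqs.pi)
    }
    # edges are stored root-outward, so parents are simulated before children
    for parent, child in model.topology.edges:
        P = model.edge_processes[child].P
        parent_states = states[parent]
        child_states = np.empty(n_codons, dtype=np.int64)
        for s in np.unique(parent_states):
            mask = parent_states == s
            row = np.clip(P[s], 0.0, None)
            child_states[mask] = rng.choice(
                n_states, size=int(mask.sum()), p=row / row.sum()
            )
        states[child] = child_states
    return {t: states[t] for t in model.topology.taxa}


def simulate_alignment(spec: SimSpec) -> CodonAlignment:
    """Simulate a codon alignment under a parameterized model."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), int(spec.replicate_id)])
    )
    leaves = _simulate_leaf_indices(spec.model, spec.n_codons, rng)
    space = _model_space(spec.model)
    idx = np.column_stack([leaves[t] for t in spec.model.topology.taxa])
    return CodonAlignment.from_index_arrays(
        tuple(spec.model.topology.taxa), space, idx
    )


def simulate_sequences(spec: SimSpec) -> dict[str, str]:
    """Simulate and return the leaf nucleotide sequences (for FASTA output)."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), int(spec.replicate_id)])
    )
    leaves = _simulate_leaf_indices(spec.model, spec.n_codons, rng)
    space = _model_space(spec.model)
    return {
        t: "".join(space.codons[i] for i in leaves[t])
        for t in spec.model.topology.taxa
    }


def _model_space(model: TreeModel) -> CodonStateSpace:
    n = model.root_freqs.pi.shape[0]
    space = codon_state_space(1, include_stops=(n == 64))
    if space.n != n:
        raise ValueError(f"no standard-code state space with {n} states")
    return space


# ---------------------------------------------------------------------------
# nonstationary fixture


#: default edge scales for the fixture triad (expected substitutions per
#: codon at the root composition): a distant outgroup, a short internal edge,
#: and two moderately diverged ingroup tips
FIXTURE_TAUS = {"outgroup": 0.5, "internal": 0.15, "ingroup1": 0.25, "ingroup2": 0.25}
FIXTURE_OMEGA = 0.3
#: GC-drift strength multiplier at divergence level 1
FIXTURE_TILT = 1.6


def _base_nuc_rates(rng: np.random.Generator | None = None) -> np.ndarray:
    """A transition-biased, mildly asymmetric neutral nucleotide rate matrix."""
    r = np.ones((4, 4))
    for a, b in (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")):
        r[NUC_INDEX[a], NUC_INDEX[b]] = 4.0
    np.fill_diagonal(r, 0.0)
    return r


def _gc_tilted(r: np.ndarray, level: float) -> np.ndarray:
    """Tilt rates toward G/C targets by exp(+-FIXTURE_TILT * level / 2)."""
    out = r.copy()
    up = np.exp(0.5 * FIXTURE_TILT * level)
    for j, nuc in enumerate("ACGT"):
        out[:, j] *= up if nuc in "GC" else 1.0 / up
    np.fill_diagonal(out, 0.0)
    return out


def make_nonstationary_fixture(
    divergence_level: float,
    n_codons: int,
    seed: int,
    taus: dict[str, float] | None = None,
    omega: float = FIXTURE_OMEGA,
) -> tuple[TreeModel, CodonAlignment]:
    """An edge-rooted GNC model with GC-drifting ingroup edges, plus one
    simulated alignment.

    All non-scale parameters are shared between the outgroup edge and the
    internal edge (the identifiability-motivated constraint scheme for
    edge-rooted simulation); the two ingroup edges carry the GC tilt
    proportional to ``divergence_level`` in [0, 1].  At level zero the root
    distribution is the shared process's stationary distribution, so the
    model is stationary and leaf compositions coincide in expectation.
    """
    if not 0.0 <= divergence_level <= 1.0:
        raise ValueError("divergence_level must be in [0, 1]")
    space = codon_state_space()
    taus = dict(FIXTURE_TAUS if taus is None else taus)
    base_r = _base_nuc_rates()
    # root composition: stationary distribution of the shared base process
    from .models import build_gnc_generator

    Q_base = build_gnc_generator(base_r, omega, space)
    pi_root = CodonFreqs(stationary_distribution(Q_base))
    topo = Topology.edge_rooted("outgroup", ("ingroup1", "ingroup2"))
    procs: dict[str, EdgeProcess] = {}
    for _, child in topo.edges:
        if child in ("outgroup", "internal"):
            r = base_r
        else:
            r = _gc_tilted(base_r, divergence_level)
        procs[child] = EdgeProcess.gnc(r, omega, taus[child], pi_root, space)
    model = TreeModel(
        topology=topo,
        root_freqs=pi_root,
        edge_processes=procs,
        sharing="outgroup/internal share all non-scale parameters",
    )
    aln = simulate_alignment(SimSpec(model=model, n_codons=n_codons, seed=seed))
    return model, aln


# ---------------------------------------------------------------------------
# bias experiment


def bias_experiment(
    fixture: tuple[TreeModel, CodonAlignment],
    config_overrides: dict | None = None,
    omega_exclude_above: float = 10.0,
):
    """Fit GNC (node-rooted), Y98 and CNFGTR to a fixture alignment and
    tabulate true and proxy bias for genetic distance and omega.

    True bias is (time-reversible estimate - generating value); proxy bias is
    (time-reversible estimate - node-rooted GNC estimate).  For the node-rooted
    fit the outgroup edge corresponds to the generating internal + outgroup
    path.  Time-reversible fits with omega above ``omega_exclude_above`` on
    any edge are flagged excluded.
    """
    import pandas as pd

    from .distance import edge_distances
    from .likelihood import FitConfig, fit

    model_true, aln = fixture
    overrides = config_overrides or {}
    fits = {
        fam: fit(aln, FitConfig(model_family=fam, min_codons=1, **overrides))
        for fam in ("GNC", "Y98", "CNFGTR")
    }
    d_true_edges = edge_distances(model_true)
    taxa = tuple(aln.taxa)
    outgroup = next(
        t for t in taxa
        if (model_true.topology.root, t) in model_true.topology.edges
    )
    true_d: dict[str, float] = {}
    true_w: dict[str, float] = {}
    for t in taxa:
        if t == outgroup:
            true_d[t] = d_true_edges[t] + d_true_edges["internal"]
        else:
            true_d[t] = d_true_edges[t]
        true_w[t] = model_true.edge_processes[t].omega
    d_gnc = edge_distances(fits["GNC"].model)
    rows = []
    for fam in ("Y98", "CNFGTR"):
        f = fits[fam]
        excluded = any(f.omega(t) > omega_exclude_above for t in taxa)
        d_tr = edge_distances(f.model)
        for t in taxa:
            rows.append(
                {
                    "model": fam,
                    "edge": t,
                    "quantity": "distance",
                    "estimate": d_tr[t],
                    "true_bias": d_tr[t] - true_d[t],
                    "proxy_bias": d_tr[t] - d_gnc[t],
                    "excluded": excluded,
                }
            )
            rows.append(
                {
                    "model": fam,
                    "edge": t,
                    "quantity": "omega",
                    "estimate": f.omega(t),
                    "true_bias": f.omega(t) - true_w[t],
                    "proxy_bias": f.omega(t) - fits["GNC"].omega(t),
                    "excluded": excluded,
                }
            )
    table = pd.DataFrame(rows).sort_values(["model", "edge", "quantity"])
    return table.reset_index(drop=True), fits
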