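"""FASTA input, result serialization, and tabular export."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .codes import codon_state_space
from .likelihood import CodonAlignment, FitConfig, ModelFit, _Objective
from .trees import Topology

__all__ = [
    "read_fasta_triad",
    "write_fasta",
    "fit_to_dict",
    "config_from_dict",
    "fit_from_dict",
    "save_fit",
    "load_fit",
    "matrix_to_tsv",
]


def read_fasta_triad(path: str | Path) -> dict[str, str]:
    """Read exactly three equal-length sequences from a FASTA file.

    Labels must be unique; lowercase and U are normalised to uppercase DNA.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 3:
        raise ValueError(f"expected 3 sequences, found {len(records)}")
    names = [r.id for r in records]
    if len(set(names)) != 3:
        raise ValueError("sequence labels must be unique")
    seqs = {r.id: str(r.seq).upper().replace("U", "T") for r in records}
    if len({len(s) for s in seqs.values()}) != 1:
        raise ValueError("sequences must be of equal length (aligned)")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fit_to_dict(model_fit: ModelFit) -> dict:
    """JSON-serializable representation of a fit; floats keep full precision
    so a reload is bit-identical."""
    m = model_fit.model
    cfg = model_fit.config
    return {
        "family": cfg.model_family,
        "taxa": list(m.topology.taxa),
        "topology_kind": m.topology.kind,
        "sharing": m.sharing,
        "lnL": model_fit.lnL,
        "n_free_params": model_fit.n_free_params,
        "converged": model_fit.converged,
        "at_bound": model_fit.at_bound,
        "evaluations": model_fit.evaluations,
        "theta": [float(x) for x in model_fit.theta],
        "config": {
            "model_family": cfg.model_family,
            "table_id": cfg.table_id,
            "include_stops": cfg.include_stops,
            "omega_shared_edges": list(cfg.omega_shared_edges)
            if cfg.omega_shared_edges
            else None,
            "tau_min": cfg.tau_min,
            "tau_max": cfg.tau_max,
            "omega_bounds": list(cfg.omega_bounds),
            "kappa_bounds": list(cfg.kappa_bounds),
            "rate_log_bounds": list(cfg.rate_log_bounds),
            "restarts": cfg.restarts,
            "seed": cfg.seed,
            "tol": cfg.tol,
            "maxiter": cfg.maxiter,
            "min_codons": cfg.min_codons,
            "stop_policy": cfg.stop_policy,
        },
        "root_freqs": [float(x) for x in m.root_freqs.pi],
        "edges": {
            child: {"omega": proc.omega, "tau": proc.tau}
            for child, proc in m.edge_processes.items()
        },
    }


def config_from_dict(c: dict) -> FitConfig:
    """Rebuild a FitConfig from its serialized form."""
    return FitConfig(
        model_family=c["model_family"],
        table_id=c["table_id"],
        include_stops=c["include_stops"],
        omega_shared_edges=tuple(c["omega_shared_edges"])
        if c["omega_shared_edges"]
        else None,
        tau_min=c["tau_min"],
        tau_max=c["tau_max"],
        omega_bounds=tuple(c["omega_bounds"]),
        kappa_bounds=tuple(c["kappa_bounds"]),
        rate_log_bounds=tuple(c["rate_log_bounds"]),
        restarts=c["restarts"],
        seed=c["seed"],
        tol=c["tol"],
        maxiter=c["maxiter"],
        min_codons=c["min_codons"],
        stop_policy=c["stop_policy"],
    )


def fit_from_dict(data: dict, aln: CodonAlignment) -> ModelFit:
    """Rebuild a ModelFit from its serialized form and the source alignment."""
    cfg = config_from_dict(data["config"])
    theta = np.array(data["theta"], dtype=float)
    obj = _Objective(cfg.model_family, aln, cfg)

    class _Res:
        fun = -data["lnL"]
        success = data["converged"]
        x = theta

    topology = Topology.node_rooted(tuple(data["taxa"]))
    rebuilt = obj.build_fit(theta, _Res, aln, topology)
    rebuilt.evaluations = data["evaluations"]
    return rebuilt


def save_fit(model_fit: ModelFit, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(fit_to_dict(model_fit), fh, indent=1)


def load_fit(path: str | Path, aln: CodonAlignment) -> ModelFit:
    with open(path) as fh:
        return fit_from_dict(json.load(fh), aln)


def matrix_to_tsv(M: np.ndarray, path: str | Path, table_id: int = 1,
                  include_stops: bool = False) -> None:
    """Write a codon-labelled matrix (generator or P) as TSV."""
    import pandas as pd

    space = codon_state_space(table_id, include_stops)
    if M.shape != (space.n, space.n):
        raise ValueError("matrix does not match the codon state space")
    pd.DataFrame(M, index=space.codons, columns=space.codons).to_csv(
        path, sep="\t", float_format="%.12g"
    )
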