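"""Consistency diagnostics and the compositional nonstationarity measure.

A general Markov fit on a node-rooted tree is only identified up to
relabelling of the unobserved root states; demanding that every fitted
transition matrix be Diagonal Largest in Column (DLC) pins down the labelling.
A second hazard is the embedding problem: one transition probability matrix
can correspond to zero, one, several, or a continuum of rate matrices, so a
fitted generator is only trusted when a conservative sufficient condition
certifies uniqueness.  Two certificates are used: ``det(P) > 1/2``, and all
eigenvalues real, distinct and positive with the principal logarithm a valid
generator; anything else is declined (nonunique or undetermined).

Compositional divergence between sequences is measured by the Jensen–Shannon
divergence (base-2 logarithm, bounded [0, 1]) between observed codon
frequency vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import jensenshannon

from .likelihood import CodonAlignment, ModelFit

__all__ = [
    "DiagnosticVerdict",
    "is_dlc",
    "generator_unique",
    "jsd",
    "max_pairwise_jsd",
    "screen_fit",
]

_STOCH_TOL = 1e-8


def _check_stochastic(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if np.any(P < -_STOCH_TOL) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("P is not row-stochastic")
    return P


def is_dlc(P: np.ndarray) -> bool:
    """True iff every diagonal entry strictly exceeds the rest of its column."""
    P = _check_stochastic(P)
    d = np.diag(P)
    off = P.copy()
    np.fill_diagonal(off, -np.inf)
    return bool(np.all(d > off.max(axis=0)))


def generator_unique(P: np.ndarray) -> tuple[bool, str]:
    """Conservatively certify that at most one generator Q has exp(Q) = P.

    Returns ``(flag, certificate)``; certificate is ``"determinant"`` when
    ``det(P) > 1/2``, ``"principal-logarithm"`` when all eigenvalues are real,
    distinct and positive and the principal matrix logarithm is a valid
    generator, and ``"none"`` when uniqueness cannot be certified.
    """
    P = _check_stochastic(P)
    det = float(np.linalg.det(P))
    if det > 0.5:
        return True, "determinant"
    eig = np.linalg.eigvals(P)
    real = np.abs(eig.imag) < 1e-10
    if np.all(real):
        lam = np.sort(eig.real)
        if np.all(lam > 1e-12) and np.all(np.diff(lam) > 1e-10):
            from scipy.linalg import logm

            L = logm(P).real
            rows_zero = np.max(np.abs(L.sum(axis=1))) < 1e-8
            off = L - np.diag(np.diag(L))
            if rows_zero and np.all(off >= -1e-10):
                return True, "principal-logarithm"
    return False, "none"


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen–Shannon divergence (base 2) between two probability vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("vectors must have equal length")
    for v in (p, q):
        if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-8:
            raise ValueError("inputs must be probability vectors")
    val = float(jensenshannon(p, q, base=2) ** 2)
    # numerical guard: exact bounds are [0, 1]
    return min(max(val, 0.0), 1.0)


def max_pairwise_jsd(aln: CodonAlignment) -> tuple[tuple[str, str], float]:
    """The taxon pair with maximal codon-composition JSD, and its value.

    Ties are broken by lexicographic pair order.
    """
    if aln.n_codons == 0:
        raise ValueError("empty alignment")
    freqs = {t: aln.taxon_frequencies(t) for t in aln.taxa}
    best_pair, best = None, -1.0
    for a, b in sorted(combinations(sorted(aln.taxa), 2)):
        v = jsd(freqs[a], freqs[b])
        if v > best + 1e-15:
            best_pair, best = (a, b), v
    return best_pair, best


@dataclass(frozen=True)
class DiagnosticVerdict:
    """Per-edge DLC and generator-uniqueness outcomes for a fitted model."""

    dlc_ok: dict[str, bool]
    unique_ok: dict[str, bool]
    certificates: dict[str, str]
    excluded: bool

    @property
    def all_ok(self) -> bool:
        return not self.excluded


def screen_fit(fit: ModelFit) -> DiagnosticVerdict:
    """Apply the DLC and uniqueness checks to every edge of a fit.

    An alignment whose fit fails either check on any edge is marked for
    exclusion from downstream comparisons.
    """
    dlc: dict[str, bool] = {}
    uniq: dict[str, bool] = {}
    certs: dict[str, str] = {}
    for child, proc in fit.model.edge_processes.items():
        dlc[child] = is_dlc(proc.P)
        ok, cert = generator_unique(proc.P)
        uniq[child] = ok
        certs[child] = cert
    excluded = not (all(dlc.values()) and all(uniq.values()))
    return DiagnosticVerdict(
        dlc_ok=dlc, unique_ok=uniq, certificates=certs, excluded=excluded
    )
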