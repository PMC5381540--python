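"""Markov generators and transition matrices for codon substitution models.

Three model families are provided:

* **GNC** (general nucleotide codon) — nonstationary.  The off-diagonal rate
  for a single-nucleotide codon change is the corresponding entry of a general
  4x4 nucleotide rate matrix ``r``, multiplied by the selection parameter
  ``omega`` when the change is nonsynonymous; changes at more than one codon
  position have rate zero.  Codon frequencies do not enter the generator at
  all: they appear only as the free root distribution and in calibration.

* **Y98** — time-reversible.  Rates are proportional to the frequency of the
  target codon, with a transition/transversion ratio ``kappa`` and ``omega``
  on nonsynonymous changes.

* **CNFGTR** — time-reversible.  Rates combine symmetric GTR nucleotide
  exchangeabilities with the conditional frequency of the target nucleotide
  given the two unchanged codon positions.

Generators are calibrated by scaling so that the expected substitution rate
under a reference codon distribution is one, making the scale parameter
``tau`` the expected number of substitutions per codon at that composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import expm

from .codes import (
    NUC_INDEX,
    NUCLEOTIDES,
    TRANSITIONS,
    CodonStateSpace,
    codon_state_space,
    normalize_codon,
)

__all__ = [
    "NucRates",
    "CodonFreqs",
    "EdgeProcess",
    "build_gnc_generator",
    "build_y98_generator",
    "build_cnfgtr_generator",
    "conditional_nucleotide_freq",
    "calibrate",
    "transition_matrix",
    "stationary_distribution",
]

#: symmetric GTR nucleotide pairs in canonical order; the last is the
#: reference exchangeability fixed at 1 in fitting
GTR_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# structure tables, cached per state space


class _Structure:
    """Precomputed index/mask matrices describing single-nucleotide codon moves."""

    def __init__(self, space: CodonStateSpace):
        n = space.n
        pos = -np.ones((n, n), dtype=np.int8)
        fr = np.zeros((n, n), dtype=np.int8)
        to = np.zeros((n, n), dtype=np.int8)
        nonsyn = np.zeros((n, n), dtype=bool)
        transition = np.zeros((n, n), dtype=bool)
        aas = [space.aa(c) for c in space.codons]
        for i, ci in enumerate(space.codons):
            for j, cj in enumerate(space.codons):
                if i == j:
                    continue
                diffs = [k for k in range(3) if ci[k] != cj[k]]
                if len(diffs) != 1:
                    continue
                k = diffs[0]
                pos[i, j] = k
                fr[i, j] = NUC_INDEX[ci[k]]
                to[i, j] = NUC_INDEX[cj[k]]
                nonsyn[i, j] = aas[i] != aas[j]
                transition[i, j] = (ci[k], cj[k]) in TRANSITIONS
        self.single = pos >= 0
        self.pos, self.fr, self.to = pos, fr, to
        self.nonsyn, self.transition = nonsyn, transition

        # CNF context groups: codons sharing two positions, varying the third.
        group_of: dict[tuple[int, str], int] = {}
        group_id = np.zeros((n, 3), dtype=np.int64)
        for j, cj in enumerate(space.codons):
            for k in range(3):
                key = (k, cj[:k] + cj[k + 1:])
                group_id[j, k] = group_of.setdefault(key, len(group_of))
        members = np.zeros((len(group_of), n))
        for j in range(n):
            for k in range(3):
                members[group_id[j, k], j] = 1.0
        self.group_id = group_id
        #: (n_groups, n) indicator; denom = members @ pi
        self.group_members = members
        # per-pair group of the *target* codon at the changed position
        gid_pair = np.zeros((n, n), dtype=np.int64)
        ii, jj = np.nonzero(self.single)
        gid_pair[ii, jj] = group_id[jj, pos[ii, jj]]
        self.gid_pair = gid_pair


@lru_cache(maxsize=None)
def _structure_cached(table_id: int, include_stops: bool) -> _Structure:
    return _Structure(codon_state_space(table_id, include_stops))


def structure(space: CodonStateSpace) -> _Structure:
    # cached lookup for spaces built from NCBI tables; fall back to direct build
    try:
        return _structure_cached(_ncbi_id_of(space.code.name), space.include_stops)
    except KeyError:
        return _Structure(space)


@lru_cache(maxsize=None)
def _ncbi_id_of(name: str) -> int:
    from Bio.Data import CodonTable

    for tid, table in CodonTable.unambiguous_dna_by_id.items():
        if name in table.names:
            return tid
    raise KeyError(name)


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class NucRates:
    """A 4x4 nonnegative matrix of nucleotide rates (diagonal unused)."""

    r: np.ndarray
    symmetric: bool = False

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.shape != (4, 4):
            raise ModelError("nucleotide rates must be 4x4")
        off = r[~np.eye(4, dtype=bool)]
        if np.any(off < 0):
            raise ModelError("nucleotide rates must be nonnegative")
        if self.symmetric and not np.allclose(r, r.T):
            raise ModelError("rates declared symmetric are not")
        object.__setattr__(self, "r", r)

    @classmethod
    def from_gtr(cls, exchange: dict[tuple[str, str], float] | np.ndarray) -> "NucRates":
        """Symmetric rates from the six GTR exchangeabilities (AC..GT order)."""
        r = np.zeros((4, 4))
        if isinstance(exchange, dict):
            values = [exchange[p] for p in GTR_PAIRS]
        else:
            values = list(np.asarray(exchange, dtype=float))
        for (a, b), v in zip(GTR_PAIRS, values):
            r[NUC_INDEX[a], NUC_INDEX[b]] = r[NUC_INDEX[b], NUC_INDEX[a]] = v
        return cls(r=r, symmetric=True)


@dataclass(frozen=True)
class CodonFreqs:
    """A probability vector over the codon state space."""

    pi: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if np.any(pi < 0):
            raise ModelError("codon frequencies must be nonnegative")
        s = pi.sum()
        if not np.isfinite(s) or abs(s - 1.0) > 1e-8:
            raise ModelError(f"codon frequencies sum to {s}, not 1")
        object.__setattr__(self, "pi", pi / s)


# ---------------------------------------------------------------------------
# generators


def build_gnc_generator(
    rates: NucRates | np.ndarray, omega: float, space: CodonStateSpace
) -> np.ndarray:
    """Uncalibrated GNC generator.

    Single-nucleotide changes get rate ``r[from, to]``, multiplied by ``omega``
    when nonsynonymous; multi-position changes are impossible.  Codon
    frequencies play no role here.
    """
    if omega <= 0:
        raise ModelError("omega must be positive")
    r = rates.r if isinstance(rates, NucRates) else NucRates(np.asarray(rates)).r
    st = structure(space)
    Q = np.where(st.single, r[st.fr, st.to], 0.0)
    Q[st.nonsyn] *= omega
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def build_y98_generator(
    pi: CodonFreqs, kappa: float, omega: float, space: CodonStateSpace
) -> np.ndarray:
    """Uncalibrated Y98 generator (target-codon-frequency rates)."""
    if kappa <= 0 or omega <= 0:
        raise ModelError("kappa and omega must be positive")
    p = pi.pi if isinstance(pi, CodonFreqs) else CodonFreqs(np.asarray(pi)).pi
    st = structure(space)
    Q = np.where(st.single, p[np.newaxis, :], 0.0)
    Q[st.transition] *= kappa
    Q[st.nonsyn] *= omega
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def conditional_nucleotide_freq(
    pi: CodonFreqs,
    position: int,
    context: str,
    target: str,
    space: CodonStateSpace,
) -> float:
    """P(target nucleotide at ``position`` | the two context nucleotides).

    ``context`` is the two fixed nucleotides in 5'->3' order.  The probability
    is the codon frequency of (target in context) normalised over the
    nucleotides that make a codon present in the state space.
    """
    if position not in (1, 2, 3):
        raise ModelError("position must be 1, 2 or 3")
    if len(context) != 2:
        raise ModelError("context must give the two unchanged nucleotides")
    p = pi.pi if isinstance(pi, CodonFreqs) else CodonFreqs(np.asarray(pi)).pi
    k = position - 1
    ctx = normalize_codon(context + "A")[:2]  # normalises case/U

    def codon_with(x: str) -> str:
        parts = list(ctx)
        parts.insert(k, x)
        return "".join(parts)

    admissible = [x for x in NUCLEOTIDES if codon_with(x) in space]
    if not admissible:
        raise ModelError(f"context {context!r} admits no codon in the state space")
    tgt = normalize_codon(target * 3)[0]
    num_codon = codon_with(tgt)
    if num_codon not in space:
        raise ModelError(f"codon {num_codon} not in state space")
    denom = sum(p[space.index[codon_with(x)]] for x in admissible)
    if denom <= 0:
        raise ModelError("context has zero total frequency")
    return p[space.index[num_codon]] / denom


def build_cnfgtr_generator(
    pi: CodonFreqs,
    rates: NucRates,
    omega: float,
    space: CodonStateSpace,
) -> np.ndarray:
    """Uncalibrated CNFGTR generator (conditional-nucleotide-frequency GTR)."""
    if omega <= 0:
        raise ModelError("omega must be positive")
    if not isinstance(rates, NucRates):
        rates = NucRates(np.asarray(rates), symmetric=True)
    if not rates.symmetric:
        raise ModelError("CNFGTR requires symmetric nucleotide rates")
    p = pi.pi if isinstance(pi, CodonFreqs) else CodonFreqs(np.asarray(pi)).pi
    st = structure(space)
    denom = st.group_members @ p
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = p[np.newaxis, :] / denom[st.gid_pair]
    Q = np.where(st.single, rates.r[st.fr, st.to] * cond, 0.0)
    Q[st.nonsyn] *= omega
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


# ---------------------------------------------------------------------------
# calibration, exponentiation, stationary distribution


def calibrate(Q: np.ndarray, pi_ref: CodonFreqs | np.ndarray) -> tuple[np.ndarray, float]:
    """Scale ``Q`` so the expected rate under ``pi_ref`` is one.

    Returns ``(Q_scaled, factor)`` with ``Q_scaled = Q / factor`` and
    ``factor = -pi_ref . diag(Q)``.
    """
    p = pi_ref.pi if isinstance(pi_ref, CodonFreqs) else np.asarray(pi_ref, dtype=float)
    factor = float(-(p @ np.diag(Q)))
    if factor <= 1e-300:
        raise ModelError("cannot calibrate: expected rate is not positive")
    return Q / factor, factor


def transition_matrix(Q: np.ndarray, tau: float) -> np.ndarray:
    """P = exp(Q tau); row-stochastic for a valid generator and tau >= 0."""
    if tau < 0:
        raise ModelError("tau must be nonnegative")
    if tau == 0:
        return np.eye(Q.shape[0])
    return expm(Q * tau)


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """The probability vector solving pi Q = 0 (left null vector of Q)."""
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# edge process


@dataclass(frozen=True)
class EdgeProcess:
    """The substitution process on one directed edge.

    ``Q`` is the calibrated generator, ``tau`` the scale (expected
    substitutions per codon at the calibration composition), ``P`` the
    transition matrix ``exp(Q tau)``.  ``params`` retains the family-specific
    inputs (rates / kappa / omega) for reporting and serialization.
    """

    family: str
    omega: float
    tau: float
    Q: np.ndarray
    P: np.ndarray
    params: dict

    @classmethod
    def gnc(
        cls,
        rates: NucRates | np.ndarray,
        omega: float,
        tau: float,
        pi_ref: CodonFreqs | np.ndarray,
        space: CodonStateSpace,
    ) -> "EdgeProcess":
        Q0 = build_gnc_generator(rates, omega, space)
        Q, _ = calibrate(Q0, pi_ref)
        r = rates.r if isinstance(rates, NucRates) else np.asarray(rates, float)
        return cls(
            family="GNC", omega=omega, tau=tau, Q=Q,
            P=transition_matrix(Q, tau), params={"rates": r},
        )

    @classmethod
    def y98(
        cls,
        pi: CodonFreqs | np.ndarray,
        kappa: float,
        omega: float,
        tau: float,
        space: CodonStateSpace,
    ) -> "EdgeProcess":
        pi = pi if isinstance(pi, CodonFreqs) else CodonFreqs(np.asarray(pi))
        Q0 = build_y98_generator(pi, kappa, omega, space)
        Q, _ = calibrate(Q0, pi)
        return cls(
            family="Y98", omega=omega, tau=tau, Q=Q,
            P=transition_matrix(Q, tau), params={"kappa": kappa, "pi": pi.pi},
        )

    @classmethod
    def cnfgtr(
        cls,
        pi: CodonFreqs | np.ndarray,
        rates: NucRates,
        omega: float,
        tau: float,
        space: CodonStateSpace,
    ) -> "EdgeProcess":
        pi = pi if isinstance(pi, CodonFreqs) else CodonFreqs(np.asarray(pi))
        Q0 = build_cnfgtr_generator(pi, rates, omega, space)
        Q, _ = calibrate(Q0, pi)
        return cls(
            family="CNFGTR", omega=omega, tau=tau, Q=Q,
            P=transition_matrix(Q, tau), params={"rates": rates.r, "pi": pi.pi},
        )
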