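"""Site-pattern likelihood and maximum-likelihood fitting for codon models.

Alignments of three in-frame coding sequences are reduced to counts of codon
site patterns (one codon per taxon).  The likelihood of a pattern on the
node-rooted triad sums over the unobserved root state::

    P(x, y, z) = sum_c  pi_r[c] * P_1[c, x] * P_2[c, y] * P_3[c, z]

Fitting maximises the log-likelihood over the root distribution (60 free
simplex coordinates) and family-specific parameters.  The default
parameter-sharing scheme follows the three-taxon setup used throughout this
package: codon frequencies global, exchangeabilities global for the
time-reversible families, scale and selection free per edge, everything free
per edge for GNC.  The resulting free-parameter counts are 67 (Y98),
71 (CNFGTR) and 99 (GNC).

For GNC the twelve nucleotide rates of an edge absorb the edge scale: the
transition matrix is ``exp(Q_raw)`` where ``Q_raw`` carries the product of
rates and time, and the scale ``tau`` is recovered afterwards as the expected
rate ``-pi_r . diag(Q_raw)``.  This keeps the transition matrices independent
of the root frequencies and removes the rate/time scale redundancy without an
explicit constraint, giving 12 identifiable rate/time parameters plus omega
per edge.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm, expm_frechet
from scipy.optimize import minimize
from scipy.stats import chi2

from .codes import CodonStateSpace, codon_state_space
from .models import (
    CodonFreqs,
    EdgeProcess,
    NucRates,
    build_cnfgtr_generator,
    build_y98_generator,
    calibrate,
    structure,
)
from .trees import Topology, TreeModel, validate_fittable

__all__ = [
    "CodonAlignment",
    "FitConfig",
    "ModelFit",
    "AlignmentFilterError",
    "pattern_counts",
    "log_likelihood",
    "pattern_probs",
    "fit",
    "lrt_omega_equality",
]

FAMILIES = ("GNC", "Y98", "CNFGTR")

_LOG_FLOOR = 1e-300


class AlignmentFilterError(ValueError):
    """Raised when an alignment fails the data-filtering rules."""


# ---------------------------------------------------------------------------
# alignment container


@dataclass
class CodonAlignment:
    """A three-taxon in-frame alignment reduced to site-pattern counts."""

    taxa: tuple[str, str, str]
    space: CodonStateSpace
    counts: dict[tuple[str, str, str], int]

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != 3:
            raise AlignmentFilterError("exactly three distinct taxa required")
        for pat, c in self.counts.items():
            if c <= 0 or c != int(c):
                raise AlignmentFilterError("pattern counts must be positive integers")
            for codon in pat:
                if codon not in self.space:
                    raise AlignmentFilterError(f"codon {codon} not in state space")
        self._arrays: tuple[np.ndarray, ...] | None = None

    @property
    def n_codons(self) -> int:
        return int(sum(self.counts.values()))

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Pattern index arrays (ix, iy, iz, counts) in sorted pattern order."""
        if self._arrays is None:
            idx = self.space.index
            pats = sorted(self.counts)
            ix = np.array([idx[p[0]] for p in pats], dtype=np.int64)
            iy = np.array([idx[p[1]] for p in pats], dtype=np.int64)
            iz = np.array([idx[p[2]] for p in pats], dtype=np.int64)
            ns = np.array([self.counts[p] for p in pats], dtype=float)
            self._arrays = (ix, iy, iz, ns)
        return self._arrays

    def taxon_frequencies(self, taxon: str) -> np.ndarray:
        """Observed codon frequency vector of one aligned sequence."""
        k = self.taxa.index(taxon)
        freqs = np.zeros(self.space.n)
        for pat, c in self.counts.items():
            freqs[self.space.index[pat[k]]] += c
        return freqs / freqs.sum()

    @classmethod
    def from_index_arrays(
        cls,
        taxa: tuple[str, str, str],
        space: CodonStateSpace,
        codon_indices: np.ndarray,
    ) -> "CodonAlignment":
        """Build from an (n_sites, 3) array of codon indices."""
        counts: dict[tuple[str, str, str], int] = {}
        for row in np.asarray(codon_indices):
            pat = tuple(space.codons[i] for i in row)
            counts[pat] = counts.get(pat, 0) + 1
        return cls(taxa=tuple(taxa), space=space, counts=counts)


def pattern_counts(
    seqs: dict[str, str],
    space: CodonStateSpace | None = None,
    min_codons: int = 500,
    stop_policy: str = "drop",
) -> CodonAlignment:
    """Tally codon site patterns from three equal-length in-frame sequences.

    Codon columns containing any non-ACGT character in any sequence are
    dropped.  In a sense-only state space, columns containing a stop codon are
    dropped (``stop_policy="drop"``) or raise (``"error"``).  Fewer than
    ``min_codons`` retained columns rejects the alignment, mirroring the
    standard length filter for triad analyses.
    """
    if space is None:
        space = codon_state_space()
    if len(seqs) != 3:
        raise AlignmentFilterError("exactly three sequences required")
    taxa = tuple(seqs)
    cleaned = [seqs[t].upper().replace("U", "T") for t in taxa]
    lengths = {len(s) for s in cleaned}
    if len(lengths) != 1:
        raise AlignmentFilterError("sequences must be of equal length")
    (length,) = lengths
    if length % 3:
        raise AlignmentFilterError("alignment length must be a multiple of 3")
    counts: dict[tuple[str, str, str], int] = {}
    for k in range(length // 3):
        pat = tuple(s[3 * k : 3 * k + 3] for s in cleaned)
        if any(ch not in "ACGT" for codon in pat for ch in codon):
            continue
        if any(codon not in space for codon in pat):
            if stop_policy == "error":
                raise AlignmentFilterError(f"stop codon in column {k}")
            continue
        counts[pat] = counts.get(pat, 0) + 1
    n = sum(counts.values())
    if n < min_codons:
        raise AlignmentFilterError(
            f"only {n} codons retained after filtering; at least {min_codons} required"
        )
    return CodonAlignment(taxa=taxa, space=space, counts=counts)


# ---------------------------------------------------------------------------
# likelihood


def pattern_probs(model: TreeModel, aln: CodonAlignment) -> np.ndarray:
    """Model probability of each stored pattern (sorted pattern order).

    Generic pruning over the rooted topology: leaf partials are indicators of
    the observed codons; each internal node multiplies the child messages
    ``P_child @ partial_child``; the root contracts with the root distribution.
    """
    if tuple(model.topology.taxa) != tuple(aln.taxa) and set(
        model.topology.taxa
    ) != set(aln.taxa):
        raise AlignmentFilterError("model taxa do not match alignment taxa")
    ix, iy, iz, _ = aln.arrays()
    leaf_idx = dict(zip(aln.taxa, (ix, iy, iz)))
    children: dict[str, list[str]] = {}
    for par, child in model.topology.edges:
        children.setdefault(par, []).append(child)

    def partial(node: str) -> np.ndarray:
        if node in leaf_idx:
            eye = np.eye(aln.space.n)
            return eye[:, leaf_idx[node]]
        msg = None
        for child in children[node]:
            m = model.edge_processes[child].P @ partial(child)
            msg = m if msg is None else msg * m
        return msg

    probs = model.root_freqs.pi @ partial(model.topology.root)
    return np.asarray(probs)


def log_likelihood(model: TreeModel, aln: CodonAlignment) -> float:
    """Sum over patterns of count * log P(pattern)."""
    probs = pattern_probs(model, aln)
    _, _, _, ns = aln.arrays()
    if np.any(probs <= 0):
        import warnings

        warnings.warn("zero-probability site pattern; log-likelihood is -inf")
        probs = np.clip(probs, _LOG_FLOOR, None)
    return float(ns @ np.log(probs))


# ---------------------------------------------------------------------------
# fit configuration and result


@dataclass(frozen=True)
class FitConfig:
    """Settings for a maximum-likelihood fit."""

    model_family: str = "GNC"
    table_id: int = 1
    include_stops: bool = False
    omega_shared_edges: tuple[str, str] | None = None
    tau_min: float = 1e-6
    tau_max: float = 10.0
    omega_bounds: tuple[float, float] = (1e-4, 100.0)
    kappa_bounds: tuple[float, float] = (1e-3, 1e3)
    rate_log_bounds: tuple[float, float] = (-18.0, 5.0)
    restarts: int = 3
    seed: int = 0
    tol: float = 1e-6
    maxiter: int = 1000
    min_codons: int = 500
    stop_policy: str = "drop"

    def __post_init__(self) -> None:
        if self.model_family not in FAMILIES:
            raise ValueError(f"unknown model family {self.model_family!r}")
        if self.tau_max <= 0 or not np.isfinite(self.tau_max):
            raise ValueError("tau_max must be positive and finite")


@dataclass
class ModelFit:
    """A fitted model with its likelihood and convergence metadata."""

    model: TreeModel
    lnL: float
    n_free_params: int
    converged: bool
    at_bound: dict[str, bool]
    evaluations: int
    config: FitConfig
    theta: np.ndarray

    def omega(self, taxon: str) -> float:
        return self.model.edge_processes[taxon].omega

    def tau(self, taxon: str) -> float:
        return self.model.edge_processes[taxon].tau


def n_free_params(family: str, omega_shared: bool = False) -> int:
    base = {"Y98": 60 + 1 + 6, "CNFGTR": 60 + 5 + 6, "GNC": 60 + 3 * 13}[family]
    return base - (1 if omega_shared else 0)


# ---------------------------------------------------------------------------
# objective


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = np.concatenate([logits, [0.0]])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


class _Objective:
    """Negative log-likelihood with an adjoint gradient.

    One matrix exponential per edge evaluates the likelihood; one transposed
    Frechet-derivative call per edge pulls the per-pattern cotangents back to
    the generator, after which every parameter derivative is a cheap chain
    rule through the generator construction.  The root-weighting part of the
    root-frequency gradient is analytic (softmax chain rule); for GNC the
    transition matrices do not depend on the root distribution at all."""

    _H = 1e-6

    def __init__(self, family: str, aln: CodonAlignment, config: FitConfig):
        self.family = family
        self.space = aln.space
        self.st = structure(self.space)
        self.taxa = tuple(aln.taxa)
        self.ix, self.iy, self.iz, self.ns = aln.arrays()
        self.leaf_idx = (self.ix, self.iy, self.iz)
        self.config = config
        shared = config.omega_shared_edges
        if shared is not None:
            missing = set(shared) - set(self.taxa)
            if missing:
                raise ValueError(f"shared-omega edges not in taxa: {missing}")
        self.shared = tuple(shared) if shared else None
        self._layout()
        self.nfev = 0

    # -- parameter layout -------------------------------------------------
    def _layout(self) -> None:
        n = 0
        n_pi = self.space.n - 1  # 60 free simplex coordinates for 61 states
        self.sl_pi = slice(n, n + n_pi)
        n += n_pi
        if self.family == "Y98":
            self.sl_global = slice(n, n + 1)
            n += 1
        elif self.family == "CNFGTR":
            self.sl_global = slice(n, n + 5)
            n += 5
        else:
            self.sl_global = slice(n, n)
        # per-edge blocks; omega possibly shared between two edges
        self.edge_slices: dict[str, slice] = {}
        per_edge = 13 if self.family == "GNC" else 2
        self.omega_pos: dict[str, int] = {}
        shared_omega_pos: int | None = None
        for t in self.taxa:
            if self.shared and t in self.shared:
                width = per_edge - 1 if shared_omega_pos is not None else per_edge
            else:
                width = per_edge
            self.edge_slices[t] = slice(n, n + width)
            if self.shared and t in self.shared:
                if shared_omega_pos is None:
                    shared_omega_pos = n + width - 1
                    self.omega_pos[t] = shared_omega_pos
                else:
                    self.omega_pos[t] = shared_omega_pos
            else:
                self.omega_pos[t] = n + width - 1
            n += width
        self.n_params = n

    def bounds(self) -> list[tuple[float, float]]:
        c = self.config
        b: list[tuple[float, float]] = [(-30.0, 30.0)] * (self.space.n - 1)
        if self.family == "Y98":
            b.append(tuple(np.log(c.kappa_bounds)))
        elif self.family == "CNFGTR":
            b.extend([(-7.0, 7.0)] * 5)
        lw = tuple(np.log(c.omega_bounds))
        lt = (np.log(c.tau_min), np.log(c.tau_max))
        seen_omega: set[int] = set()
        for t in self.taxa:
            sl = self.edge_slices[t]
            width = sl.stop - sl.start
            if self.family == "GNC":
                nrates = width - (1 if self.omega_pos[t] == sl.stop - 1 else 0)
                b.extend([c.rate_log_bounds] * nrates)
            else:
                b.append(lt)
            if self.omega_pos[t] == sl.stop - 1 and self.omega_pos[t] not in seen_omega:
                b.append(lw)
                seen_omega.add(self.omega_pos[t])
        assert len(b) == self.n_params
        return b

    # -- model pieces ------------------------------------------------------
    def _pi(self, theta: np.ndarray) -> np.ndarray:
        return _softmax(theta[self.sl_pi])

    def _edge_A(self, theta: np.ndarray, taxon: str, pi: np.ndarray) -> np.ndarray:
        """The matrix whose exponential is this edge's transition matrix."""
        sl = self.edge_slices[taxon]
        omega = float(np.exp(theta[self.omega_pos[taxon]]))
        if self.family == "GNC":
            rho = np.exp(theta[sl][:12])
            return self._gnc_raw(rho, omega)
        tau = float(np.exp(theta[sl.start]))
        if self.family == "Y98":
            kappa = float(np.exp(theta[self.sl_global][0]))
            Q0 = build_y98_generator(CodonFreqs(pi), kappa, omega, self.space)
        else:
            ex = np.exp(theta[self.sl_global])
            rates = NucRates.from_gtr(np.append(ex, 1.0))
            Q0 = build_cnfgtr_generator(CodonFreqs(pi), rates, omega, self.space)
        Qcal, _ = calibrate(Q0, pi)
        return Qcal * tau

    def _edge_P(self, theta: np.ndarray, taxon: str, pi: np.ndarray) -> np.ndarray:
        return expm(self._edge_A(theta, taxon, pi))

    def _gnc_raw(self, rho: np.ndarray, omega: float) -> np.ndarray:
        r = np.zeros((4, 4))
        r[~np.eye(4, dtype=bool)] = rho
        st = self.st
        Q = np.where(st.single, r[st.fr, st.to], 0.0)
        Q[st.nonsyn] *= omega
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def _all_P(self, theta: np.ndarray, pi: np.ndarray) -> list[np.ndarray]:
        return [self._edge_P(theta, t, pi) for t in self.taxa]

    def _lnl_from(self, pi: np.ndarray, Ts: list[np.ndarray]) -> float:
        U = Ts[0] * Ts[1] * Ts[2]
        probs = np.clip(pi @ U, _LOG_FLOOR, None)
        return float(self.ns @ np.log(probs))

    def neg_lnl(self, theta: np.ndarray) -> float:
        self.nfev += 1
        pi = self._pi(theta)
        Ps = self._all_P(theta, pi)
        Ts = [P[:, idx] for P, idx in zip(Ps, self.leaf_idx)]
        return -self._lnl_from(pi, Ts)

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        self.nfev += 1
        h = self._H
        pi = self._pi(theta)
        As = [self._edge_A(theta, t, pi) for t in self.taxa]
        Ps = [expm(A) for A in As]
        Ts = [P[:, idx] for P, idx in zip(Ps, self.leaf_idx)]
        U = Ts[0] * Ts[1] * Ts[2]
        probs = np.clip(pi @ U, _LOG_FLOOR, None)
        lnl = float(self.ns @ np.log(probs))
        w = self.ns / probs
        grad = np.zeros(self.n_params)

        # root-weighting part of the pi-logit gradient (analytic, all families)
        gpi = U @ w  # d lnL / d pi_c at fixed transition matrices
        dot = float(pi @ gpi)
        full = pi * (gpi - dot)  # softmax chain rule over the 61 logits
        grad[self.sl_pi] -= full[: self.space.n - 1]

        # adjoint sensitivity: dlnL/dP_e scattered into Gbar, pulled back
        # through the exponential by one transposed Frechet call per edge
        pairs = [Ts[1] * Ts[2], Ts[0] * Ts[2], Ts[0] * Ts[1]]
        Ms = []
        for e in range(3):
            V = (pi[:, np.newaxis] * pairs[e]) * w[np.newaxis, :]
            Gbar = np.zeros_like(As[e])
            np.add.at(Gbar.T, self.leaf_idx[e], V.T)
            Ms.append(expm_frechet(As[e].T, Gbar, compute_expm=False))

        # chain rule: finite differences touch only the cheap generator
        # construction, never another matrix exponential
        theta2 = theta.copy()

        def matrix_part(i: int, edges: tuple[int, ...]) -> None:
            theta2[i] = theta[i] + h
            pi2 = self._pi(theta2) if i < self.sl_pi.stop else pi
            acc = 0.0
            for e in edges:
                dA = (self._edge_A(theta2, self.taxa[e], pi2) - As[e]) / h
                acc += float(np.sum(Ms[e] * dA))
            theta2[i] = theta[i]
            grad[i] -= acc

        if self.family != "GNC":
            # for the time-reversible families pi and the global
            # exchangeabilities enter every edge's generator
            for i in range(self.sl_pi.start, self.sl_pi.stop):
                matrix_part(i, (0, 1, 2))
            for i in range(self.sl_global.start, self.sl_global.stop):
                matrix_part(i, (0, 1, 2))
        for t in self.taxa:
            sl = self.edge_slices[t]
            for i in range(sl.start, sl.stop):
                edges = tuple(
                    k
                    for k, tx in enumerate(self.taxa)
                    if self.edge_slices[tx].start <= i < self.edge_slices[tx].stop
                    or self.omega_pos[tx] == i
                )
                matrix_part(i, edges)
        return -lnl, grad

    # -- init and unpacking ------------------------------------------------
    def initial_theta(self, aln: CodonAlignment) -> np.ndarray:
        pooled = np.zeros(self.space.n)
        for t in self.taxa:
            pooled += aln.taxon_frequencies(t)
        pooled = (pooled / 3 + 0.1 / self.space.n)
        pooled /= pooled.sum()
        logits = np.log(pooled) - np.log(pooled[-1])
        theta = np.zeros(self.n_params)
        theta[self.sl_pi] = logits[: self.space.n - 1]
        taus = _edge_tau_init(aln)
        if self.family == "Y98":
            theta[self.sl_global] = np.log(2.0)  # kappa
        elif self.family == "CNFGTR":
            theta[self.sl_global] = 0.0
        omega0 = 0.3
        for t in self.taxa:
            sl = self.edge_slices[t]
            tau0 = taus[t]
            if self.family == "GNC":
                Q1 = self._gnc_raw(np.ones(12), omega0)
                f = float(-(pooled @ np.diag(Q1)))
                theta[sl][:12] = np.log(tau0 / f)
            else:
                theta[sl.start] = np.log(tau0)
            theta[self.omega_pos[t]] = np.log(omega0)
        return theta

    def build_fit(
        self, theta: np.ndarray, result, aln: CodonAlignment, topology: Topology
    ) -> ModelFit:
        pi = self._pi(theta)
        pi_freqs = CodonFreqs(pi)
        procs: dict[str, EdgeProcess] = {}
        at_bound: dict[str, bool] = {}
        c = self.config
        for t in self.taxa:
            sl = self.edge_slices[t]
            omega = float(np.exp(theta[self.omega_pos[t]]))
            lo, hi = c.omega_bounds
            at_bound[f"omega[{t}]"] = bool(
                omega <= lo * (1 + 1e-4) or omega >= hi * (1 - 1e-4)
            )
            if self.family == "GNC":
                rho = np.exp(theta[sl][:12])
                Qraw = self._gnc_raw(rho, omega)
                Qcal, tau = calibrate(Qraw, pi)
                P = expm(Qraw)
                r = np.zeros((4, 4))
                r[~np.eye(4, dtype=bool)] = rho / tau
                procs[t] = EdgeProcess(
                    family="GNC", omega=omega, tau=tau, Q=Qcal, P=P,
                    params={"rates": r},
                )
            else:
                tau = float(np.exp(theta[sl.start]))
                if self.family == "Y98":
                    kappa = float(np.exp(theta[self.sl_global][0]))
                    procs[t] = EdgeProcess.y98(pi_freqs, kappa, omega, tau, self.space)
                else:
                    ex = np.exp(theta[self.sl_global])
                    rates = NucRates.from_gtr(np.append(ex, 1.0))
                    procs[t] = EdgeProcess.cnfgtr(pi_freqs, rates, omega, tau, self.space)
            at_bound[f"tau[{t}]"] = bool(
                procs[t].tau >= c.tau_max * (1 - 1e-4)
                or procs[t].tau <= c.tau_min * (1 + 1e-4)
            )
        sharing = "per-edge omega/tau"
        if self.shared:
            sharing = f"omega shared on {self.shared}"
        model = TreeModel(
            topology=topology, root_freqs=pi_freqs, edge_processes=procs,
            sharing=sharing,
        )
        return ModelFit(
            model=model,
            lnL=-float(result.fun),
            n_free_params=self.n_params,
            converged=bool(result.success),
            at_bound=at_bound,
            evaluations=self.nfev,
            config=self.config,
            theta=theta.copy(),
        )


def _edge_tau_init(aln: CodonAlignment) -> dict[str, float]:
    """Three-point decomposition of pairwise codon mismatch fractions."""
    ix, iy, iz, ns = aln.arrays()
    n = ns.sum()
    d = {
        (0, 1): float(ns[ix != iy].sum() / n),
        (0, 2): float(ns[ix != iz].sum() / n),
        (1, 2): float(ns[iy != iz].sum() / n),
    }
    taus = {}
    for k, t in enumerate(aln.taxa):
        others = [o for o in range(3) if o != k]
        ab = d[tuple(sorted((k, others[0])))]
        ac = d[tuple(sorted((k, others[1])))]
        bc = d[tuple(sorted(others))]
        taus[t] = float(np.clip((ab + ac - bc) / 2, 0.02, 3.0))
    return taus


# ---------------------------------------------------------------------------
# fitting


def fit(
    aln: CodonAlignment,
    config: FitConfig,
    topology: Topology | None = None,
    init_theta: np.ndarray | None = None,
) -> ModelFit:
    """Maximum-likelihood fit of one model family to a triad alignment.

    Multi-start local optimisation (L-BFGS-B on a structure-aware gradient)
    from a warm start at observed codon frequencies, with seeded jitter for
    restarts.  ``init_theta`` adds an extra (typically warm) starting point.
    """
    if topology is None:
        topology = Topology.node_rooted(aln.taxa)
    verdict = validate_fittable(config.model_family, topology, intent="fit")
    if not verdict.ok:
        raise ValueError(verdict.reason)
    obj = _Objective(config.model_family, aln, config)
    bounds = obj.bounds()
    lob = np.array([b[0] for b in bounds])
    upb = np.array([b[1] for b in bounds])
    base = obj.initial_theta(aln)
    rng = np.random.default_rng(config.seed)
    candidates = [base]
    if init_theta is not None:
        if len(init_theta) != obj.n_params:
            raise ValueError("init_theta has wrong length for this scheme")
        candidates.insert(0, np.asarray(init_theta, dtype=float))
    while len(candidates) < max(1, config.restarts):
        candidates.append(base + rng.normal(0.0, 0.25, size=obj.n_params))
    starts = candidates[: max(1, config.restarts)]
    best = None
    scale = max(1.0, abs(float(obj.neg_lnl(base))))
    options = {
        "maxiter": config.maxiter,
        "ftol": config.tol / scale,
        "gtol": 1e-4,
        "maxcor": 25,
    }
    for theta0 in starts:
        theta0 = np.clip(theta0, lob, upb)
        res = minimize(
            obj.value_and_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options=options,
        )
        if best is None or res.fun < best.fun:
            best = res
    return obj.build_fit(np.asarray(best.x), best, aln, topology)


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    p_value: float
    fit_null: ModelFit
    fit_alt: ModelFit
    ok: bool


def lrt_omega_equality(
    aln: CodonAlignment,
    family: str,
    edges: tuple[str, str],
    config: FitConfig | None = None,
) -> LrtResult:
    """Likelihood-ratio test that omega is equal on two named edges.

    The null shares omega between the two edges (no scale parameters are
    constrained); the alternative leaves omega free per edge.  The statistic
    is 2(lnL_alt - lnL_null), compared with chi-square on 1 df.
    """
    if config is None:
        config = FitConfig(model_family=family)
    else:
        config = replace(config, model_family=family)
    if len(edges) != 2 or len(set(edges)) != 2:
        raise ValueError("exactly two distinct edges required")
    null_cfg = replace(config, omega_shared_edges=tuple(edges))
    alt_cfg = replace(config, omega_shared_edges=None)
    fit_null = fit(aln, null_cfg)
    # warm-start the alternative from the null optimum
    obj_alt = _Objective(family, aln, alt_cfg)
    obj_null = _Objective(family, aln, null_cfg)
    warm = np.zeros(obj_alt.n_params)
    warm[obj_alt.sl_pi] = fit_null.theta[obj_null.sl_pi]
    warm[obj_alt.sl_global] = fit_null.theta[obj_null.sl_global]
    for t in aln.taxa:
        sa, sn = obj_alt.edge_slices[t], obj_null.edge_slices[t]
        nrates = (sa.stop - sa.start) - 1
        if nrates:
            warm[sa][:nrates] = fit_null.theta[sn][
                : (sn.stop - sn.start) - (1 if obj_null.omega_pos[t] == sn.stop - 1 else 0)
            ][:nrates]
        warm[obj_alt.omega_pos[t]] = fit_null.theta[obj_null.omega_pos[t]]
    fit_alt = fit(aln, alt_cfg, init_theta=warm)
    raw = 2.0 * (fit_alt.lnL - fit_null.lnL)
    ok = raw > -1e-4
    stat = max(0.0, raw)
    return LrtResult(
        statistic=stat,
        df=1,
        p_value=float(chi2.sf(stat, df=1)),
        fit_null=fit_null,
        fit_alt=fit_alt,
        ok=ok,
    )
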