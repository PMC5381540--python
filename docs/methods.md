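# Methods

## Models

All three model families are continuous-time Markov processes on the sense
codons of a genetic code (61 states under the standard code; a 64-state
stop-inclusive variant serves neutral intronic controls, with STOP treated as
a 21st amino-acid symbol so that sense↔stop changes are nonsynonymous and
stop↔stop changes synonymous). Codons are ordered lexicographically over
A<C<G<T everywhere. Changes at more than one codon position always have rate
zero.

**GNC (general nucleotide codon), nonstationary.** The rate of the single-
nucleotide change i→j inside a codon is `r[i,j]`, an arbitrary nonnegative
4×4 nucleotide rate matrix, multiplied by ω when the codon change is
nonsynonymous. Codon frequencies do not appear in the generator; a free root
distribution π^r (60 simplex coordinates) sets the initial composition, and
composition may drift along every edge. Each edge carries its own `r` and ω.

**Y98, time-reversible.** Rates are proportional to the frequency of the
target codon: π_j for a synonymous transversion, κπ_j for a synonymous
transition, ωπ_j and ωκπ_j for the nonsynonymous counterparts. The
transition set is {A↔G, C↔T}.

**CNFGTR, time-reversible.** Rates combine a symmetric GTR exchangeability
`r[i,j]` with the conditional frequency of the target nucleotide given the
two unchanged codon positions, i.e. π(codon j) normalised over the
nucleotides that give a sense codon in that context; nonsynonymous changes
are again scaled by ω. Both reversible families satisfy detailed balance
π_i q_ij = π_j q_ji exactly, hence πQ = 0.

**Calibration.** A generator is scaled so that the expected substitution
rate at a reference composition is one: −π_ref·diag(Q) = 1. The reversible
families calibrate against their stationary π; GNC calibrates every edge
against the root distribution π^r. The scale parameter τ is then the
expected number of substitutions per codon *at the calibration composition*;
under nonstationarity the realised expected number of substitutions differs
(see Distances).

## Parameterization and counts

The standard three-taxon scheme keeps codon frequencies global, Y98's κ and
CNFGTR's five free exchangeabilities (the sixth fixed at 1) global, and τ
and ω free per edge; GNC frees everything per edge. Free-parameter totals:
60+1+2·3 = **67** (Y98), 60+5+2·3 = **71** (CNFGTR), 60+3·13 = **99** (GNC).

For GNC the 12 nucleotide rates of an edge are confounded with τ through an
overall scale, so internally the rates absorb the edge scale: the optimizer
works with `A = Q_raw` (rates × time) per edge, the transition matrix is
`exp(A)`, and τ is recovered afterwards as −π^r·diag(A). This removes the
redundancy without a constraint and makes the transition matrices
independent of π^r, which in turn makes the root-frequency gradient exact
and cheap. A consequence is that for GNC the τ ≤ τ_max bound (default 10,
matching the usual saturation guard) is reported as an `at_bound` flag on
the derived τ rather than enforced as a box constraint; for the reversible
families τ is an explicit parameter with box bounds [1e−6, 10]. ω is
optimised in log space with bounds [1e−4, 100]; π^r uses 60 unconstrained
softmax coordinates.

## Optimization

L-BFGS-B with an analytic/adjoint gradient. One matrix exponential per edge
gives the likelihood; the gradient needs one *transposed Fréchet* call per
edge: for f(A) = ⟨Ḡ, exp(A)⟩ the adjoint is L*(A)(Ḡ) = L(Aᵀ, Ḡ), where Ḡ
collects the per-pattern likelihood cotangents. Parameter derivatives then
chain through the (cheap) generator construction by finite differences on
the generator entries only — no additional exponentials. The
root-weighting part of the π^r gradient is analytic for every family.

Starts: the first start sets π^r to pooled observed codon frequencies
(plus a small pseudocount), nucleotide rates to 1, ω to 0.3, κ to 2, and τ
to a three-point decomposition of pairwise codon mismatch fractions.
`restarts` is the total number of starts (default 3); extra starts jitter
the first with seeded N(0, 0.25) noise, and a caller-supplied warm start
(used by the bootstrap and the LRT alternative) takes precedence over the
cold start. Convergence: L-BFGS-B with an absolute log-likelihood
improvement tolerance of 1e−6 (scaled into `ftol`) and projected-gradient
tolerance 1e−4. Fits report convergence flags, per-parameter bound flags
and evaluation counts; non-convergence is flagged, never silent.

## Distances

The expected number of substitutions per codon on an edge with calibrated
generator Q, scale τ and parent composition π^a is

    d = −π^a · [∫₀^τ exp(Qs) ds] · diag(Q),

evaluated through the block identity: the top-right block of
`exp([[Q, I], [0, 0]]·τ)` equals the integral. This is one 122×122
exponential and is robust to defective generators, which eigendecomposition
is not. When π^a is the stationary distribution of a calibrated process the
identity d = τ holds (the time-reversible case); path distances add edge
distances, each taken at its own parent-node composition. Distances are per
codon; no per-nucleotide rescaling is applied.

Bias conventions: distance bias is d(reversible) − d(GNC) (positive =
reversible overestimation); ω bias is ω(GNC) − ω(reversible) (positive =
reversible underestimation).

## Consistency diagnostics

DLC (diagonal largest in column) requires every diagonal entry of a fitted
transition matrix to strictly exceed the rest of its column; it resolves the
root-state relabelling ambiguity of general Markov fits. Generator
uniqueness is certified only conservatively: `det(P) > 1/2`, or all
eigenvalues real, distinct and positive with the principal logarithm a valid
generator (nonnegative off-diagonals, zero row sums). Anything else —
including any complex eigenvalue pair — is declined as "nonunique or
undetermined". Both certificates are deliberately strict: at 61 states
`det(P) = exp(τ·tr Q)` decays fast in τ, so the determinant route only fires
very near the identity, while the principal-logarithm route covers
symmetric-rate (reversible-like) processes at realistic divergences. The
certificate that fired is recorded for auditability. A fit failing either
check on any edge is flagged for exclusion.

Compositional divergence uses the Jensen–Shannon divergence between observed
codon-frequency vectors, base-2 logarithm so JSD ∈ [0, 1]. The base is a
convention; changing it rescales all JSD values by a constant.

## Goodness of fit

G = 2 Σ O·ln(O/E) over observed site patterns, E = n·P(pattern) under the
fitted model; unobserved patterns contribute nothing, so the 61³ table is
never materialised. The parametric bootstrap simulates `n_boot` (default 49)
alignments of the same length from the fitted model, refits the same family
and scheme to each (warm-started at the original optimum), and reports
p = #(G_boot ≥ G_obs)/n_boot — the denominator is `n_boot` itself, not
n_boot+1. Replicate random streams are keyed on (seed, replicate), so
results do not depend on evaluation order. Non-converged refits are
retained and flagged.

## Synthetic nonstationary fixture

The fixture emulates triads selected for maximal compositional divergence:
an edge-rooted GNC model (root on the outgroup stem) whose two ingroup edges
drift toward G/C. The base neutral process is transition-biased (rate 4 for
A↔G, C↔T against 1 for transversions), ω = 0.3 (typical purifying
selection for coding genes), and edge scales 0.5 (outgroup), 0.15
(internal), 0.25 (each ingroup tip) — magnitudes of a moderately diverged
amniote-like triad. All non-scale parameters are shared between the
outgroup and internal edges, the identifiability-motivated constraint used
for edge-rooted simulation. The GC drift multiplies rates into G/C targets
by exp(+0.8·level) and into A/T targets by exp(−0.8·level), level ∈ [0, 1];
at level 0 the model collapses to a single stationary process (root = its
stationary distribution), so leaf compositions agree in expectation and
max-pairwise JSD tends to 0 as alignments grow. The tilt is this package's
own parameterization of composition drift; real lineages need not drift in
this one-dimensional GC fashion, so passing recovery/bias tests on the
fixture demonstrates correctness of the machinery, not that real data obey
the fixture's drift geometry.

Simulation draws each site independently: root codon from π^r, then one
categorical draw per edge from the corresponding row of P. There is no
rate heterogeneity across sites, matching the model definitions.

## Problem sizes used by the test suite

Chosen to exercise every guarantee on a single core: parameter recovery
fits GNC to 20 alignments of 1000 codons (median |Δω| < 0.1, median
relative distance error < 5%) plus 8 each at 500 and 4000 codons for the
RMSE comparison; goodness-of-fit calibration uses 50 outer replicates ×
19 bootstraps at 300 codons with a KS test at the 1% level; the
likelihood/integral oracles use 20 and 10 random draws; detailed-balance
certificates use 50 draws; LRT null behaviour uses 8 replicates of 400
codons.

### Calibration caveat

The test suite measures the null calibration of the bootstrap p-values by
simulating data from a fitted Y98 model (300 codons), running the full test
on each replicate (19 bootstraps, 50 outer replicates) and comparing the
p-value distribution against uniform. The p-values come out anti-
conservative (mean ≈ 0.26 rather than 0.5; the Kolmogorov–Smirnov test
rejects uniformity decisively), and the effect is not an optimization
artifact: re-optimising with extra restarts and tighter tolerances changes
no fitted log-likelihood by more than 0.01. The mechanism is sparseness.
With 61³ possible site patterns, alignments of a few hundred to a few
thousand codons consist almost entirely of singleton patterns, and in that
regime the expected G tracks the pattern-entropy of the generating model.
A maximum-likelihood fit with ~67 free parameters is systematically
sharper (lower entropy) than the process that generated the data, so
alignments simulated from the fitted model yield stochastically smaller G
than the observed alignment even after refitting. The shift is of the same
order as the spread of G and shrinks only slowly with alignment length
(still present at 1000 codons). Consequence for practice: small bootstrap
p-values from this test overstate the evidence against a model at these
alignment lengths; rejection rates should be read comparatively (model A
versus model B on the same data), where the sharpness bias largely cancels,
rather than as absolute type-I-error-calibrated tests. For four-state
nucleotide models the pattern table is dense and the same procedure is
close to calibrated; the issue is specific to the codon state space at
desk-scale alignment lengths.

## Known limitations

* Three taxa only; no topology search. The node-rooted triad is the only
  fittable topology for GNC (edge-rooted fitting is rejected, simulation
  allowed), as general Markov models are not identifiable on edge-rooted
  trees.
* No among-site rate variation or site-class (positive-selection) mixtures.
* The uniqueness certificates are sufficient conditions only; a "declined"
  verdict does not prove nonuniqueness, and at codon dimension they decline
  most strongly asymmetric fits at large divergence.
* π for the reversible families is a free ML parameter vector (not moment-
  matched to observed frequencies); observed frequencies serve only as the
  optimizer's starting point.
* The stop-inclusive variant treats STOP as one extra symbol; alternatives
  (e.g. ω applied only among sense codons) are defensible, and the choice
  matters only for intronic-control analyses.
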