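import numpy as np
import pytest

from nscodon.codes import codon_state_space
from nscodon.models import (
    CodonFreqs,
    ModelError,
    NucRates,
    build_cnfgtr_generator,
    build_gnc_generator,
    build_y98_generator,
    calibrate,
    conditional_nucleotide_freq,
    stationary_distribution,
    transition_matrix,
)

SP = codon_state_space()


def random_freqs(rng, n=61):
    return CodonFreqs(rng.dirichlet(np.ones(n) * 3))


def random_gtr(rng):
    return NucRates.from_gtr(rng.uniform(0.2, 2.5, size=6))


def random_asym_rates(rng):
    r = rng.uniform(0.2, 2.5, size=(4, 4))
    np.fill_diagonal(r, 0.0)
    return NucRates(r)


# ---------------------------------------------------------------------------
# GNC


def test_gnc_rate_product():
    r = np.full((4, 4), 0.1)
    r[0, 1] = 0.3  # A -> C
    Q = build_gnc_generator(NucRates(r), 0.5, SP)
    i, j = SP.index["AAA"], SP.index["AAC"]
    # Lys -> Asn is nonsynonymous: omega * r[A,C]
    assert Q[i, j] == pytest.approx(0.15)


def test_gnc_multi_position_changes_forbidden():
    Q = build_gnc_generator(np.full((4, 4), 0.3), 0.5, SP)
    assert Q[SP.index["AAA"], SP.index["ACC"]] == 0.0


def test_gnc_rows_sum_to_zero(rng):
    Q = build_gnc_generator(random_asym_rates(rng), 0.7, SP)
    assert np.max(np.abs(Q.sum(axis=1))) < 1e-10


def test_gnc_rejects_nonpositive_omega():
    with pytest.raises(ModelError):
        build_gnc_generator(np.full((4, 4), 0.3), 0.0, SP)


def test_gnc_independent_of_codon_frequencies(rng):
    """The GNC generator is built from nucleotide rates and omega alone."""
    r = random_asym_rates(rng)
    Q = build_gnc_generator(r, 0.4, SP)
    # no frequency argument exists; the entries depend only on (r, omega):
    Q2 = build_gnc_generator(NucRates(r.r.copy()), 0.4, SP)
    assert np.array_equal(Q, Q2)


def test_gnc_neutral_limit_equal_syn_nonsyn_rates(rng):
    """At omega=1 synonymous and nonsynonymous changes with the same
    nucleotide pair have equal rates."""
    r = random_asym_rates(rng)
    Q = build_gnc_generator(r, 1.0, SP)
    # AAA->AAG (syn, A->G at pos 3) vs AAA->GAA (nonsyn, A->G at pos 1)
    assert Q[SP.index["AAA"], SP.index["AAG"]] == pytest.approx(
        Q[SP.index["AAA"], SP.index["GAA"]]
    )


# ---------------------------------------------------------------------------
# Y98


def test_y98_rate_structure(rng):
    pi = random_freqs(rng)
    kappa, omega = 3.0, 0.4
    Q = build_y98_generator(pi, kappa, omega, SP)
    p = pi.pi
    # TTT -> TTC: Phe synonymous, T->C transition
    assert Q[SP.index["TTT"], SP.index["TTC"]] == pytest.approx(
        kappa * p[SP.index["TTC"]]
    )
    # TTT -> TTA: Phe->Leu nonsynonymous, T->A transversion
    assert Q[SP.index["TTT"], SP.index["TTA"]] == pytest.approx(
        omega * p[SP.index["TTA"]]
    )


@pytest.mark.parametrize("family", ["Y98", "CNFGTR"])
def test_reversible_families_detailed_balance_and_stationarity(family, rng):
    for _ in range(50):
        pi = random_freqs(rng)
        if family == "Y98":
            Q = build_y98_generator(pi, rng.uniform(1, 6), rng.uniform(0.05, 2), SP)
        else:
            Q = build_cnfgtr_generator(pi, random_gtr(rng), rng.uniform(0.05, 2), SP)
        F = pi.pi[:, None] * Q
        assert np.max(np.abs(F - F.T)) < 1e-10  # detailed balance
        assert np.max(np.abs(pi.pi @ Q)) < 1e-10  # pi Q = 0


# ---------------------------------------------------------------------------
# conditional nucleotide frequency


def test_conditional_freq_uniform_all_sense():
    pi = CodonFreqs(np.full(61, 1 / 61))
    # context AA_: AAA, AAC, AAG, AAT all sense
    assert conditional_nucleotide_freq(pi, 3, "AA", "A", SP) == pytest.approx(0.25)


def test_conditional_freq_excludes_stops():
    pi = CodonFreqs(np.full(61, 1 / 61))
    # context TG_: TGA is a stop, so only TGT, TGC, TGG normalise
    assert conditional_nucleotide_freq(pi, 3, "TG", "G", SP) == pytest.approx(1 / 3)


def test_conditional_freq_normalizes(rng):
    pi = random_freqs(rng)
    total = sum(
        conditional_nucleotide_freq(pi, 3, "TG", x, SP)
        for x in "ACGT"
        if "TG" + x in SP.index
    )
    assert total == pytest.approx(1.0)


def test_conditional_freq_rejects_stop_target():
    pi = CodonFreqs(np.full(61, 1 / 61))
    with pytest.raises(ModelError):
        conditional_nucleotide_freq(pi, 3, "TG", "A", SP)  # TGA is a stop


# ---------------------------------------------------------------------------
# calibration and exponentiation


def test_calibrate_unit_rate_and_scale_invariance(rng):
    pi = random_freqs(rng)
    Q = build_cnfgtr_generator(pi, random_gtr(rng), 0.5, SP)
    Qs, factor = calibrate(Q, pi)
    assert -(pi.pi @ np.diag(Qs)) == pytest.approx(1.0, abs=1e-12)
    Qs2, _ = calibrate(2 * Q, pi)
    assert np.allclose(Qs, Qs2)
    Qs3, f3 = calibrate(Qs, pi)
    assert f3 == pytest.approx(1.0)


def test_transition_matrix_identity_at_zero(rng):
    Q = build_gnc_generator(random_asym_rates(rng), 0.5, SP)
    Qc, _ = calibrate(Q, CodonFreqs(np.full(61, 1 / 61)))
    assert np.array_equal(transition_matrix(Qc, 0.0), np.eye(61))


def test_transition_matrix_row_stochastic(rng):
    Q = build_gnc_generator(random_asym_rates(rng), 0.5, SP)
    Qc, _ = calibrate(Q, CodonFreqs(np.full(61, 1 / 61)))
    for tau in (0.01, 0.5, 3.0):
        P = transition_matrix(Qc, tau)
        assert np.max(np.abs(P.sum(axis=1) - 1)) < 1e-10
        assert P.min() >= -1e-12
        assert 0 < np.linalg.det(P) <= 1 + 1e-12


def test_transition_matrix_small_tau_series(rng):
    """P(tau) matches the truncated series I + Q tau + (Q tau)^2/2 to O(tau^3)."""
    Q = build_gnc_generator(random_asym_rates(rng), 0.5, SP)
    Qc, _ = calibrate(Q, CodonFreqs(np.full(61, 1 / 61)))
    tau = 1e-4
    series = np.eye(61) + Qc * tau + (Qc * tau) @ (Qc * tau) / 2
    assert np.max(np.abs(transition_matrix(Qc, tau) - series)) < 1e-10


def test_transition_matrix_rejects_negative_tau():
    with pytest.raises(ModelError):
        transition_matrix(np.zeros((61, 61)), -0.1)


def test_stationary_distribution_solves_piQ(rng):
    Q = build_gnc_generator(random_asym_rates(rng), 0.5, SP)
    pi = stationary_distribution(Q)
    assert pi.sum() == pytest.approx(1.0)
    assert np.max(np.abs(pi @ Q)) < 1e-10


def test_freqs_validation():
    with pytest.raises(ModelError):
        CodonFreqs(np.full(61, 0.5))
    with pytest.raises(ModelError):
        NucRates(-np.ones((4, 4)))
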