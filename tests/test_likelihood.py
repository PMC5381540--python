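import numpy as np
import pytest

from conftest import gnc_triad_model

from nscodon.likelihood import (
    AlignmentFilterError,
    CodonAlignment,
    FitConfig,
    fit,
    log_likelihood,
    lrt_omega_equality,
    n_free_params,
    pattern_counts,
)
from nscodon.simulate import SimSpec, simulate_alignment
from nscodon.trees import Topology


# ---------------------------------------------------------------------------
# pattern counting and filtering


def _triad(seq_a, seq_b, seq_c):
    return {"A": seq_a, "B": seq_b, "C": seq_c}


def test_pattern_counts_drops_gap_columns(space):
    seqs = _triad("AAATTT", "AA-TTT", "AAATTT")
    aln = pattern_counts(seqs, space, min_codons=1)
    assert aln.n_codons == 1
    assert aln.counts == {("TTT", "TTT", "TTT"): 1}


def test_pattern_counts_drops_stop_columns(space):
    seqs = _triad("TAATTT", "AAATTT", "AAATTT")
    aln = pattern_counts(seqs, space, min_codons=1)
    assert aln.n_codons == 1


def test_pattern_counts_min_codons_rejects(space):
    seqs = _triad("AAA" * 499, "AAA" * 499, "AAA" * 499)
    with pytest.raises(AlignmentFilterError, match="at least 500"):
        pattern_counts(seqs, space, min_codons=500)
    aln = pattern_counts(
        {k: v + "TTT" for k, v in seqs.items()}, space, min_codons=500
    )
    assert aln.n_codons == 500


def test_pattern_counts_clean_alignment(space):
    seqs = _triad("AAACCCGGG", "AAACCCGGG", "AAGCCAGGG")
    aln = pattern_counts(seqs, space, min_codons=1)
    assert aln.n_codons == 3
    assert sum(aln.counts.values()) == 3


def test_pattern_counts_requires_equal_lengths(space):
    with pytest.raises(AlignmentFilterError):
        pattern_counts(_triad("AAATTT", "AAA", "AAATTT"), space, min_codons=1)


# ---------------------------------------------------------------------------
# likelihood against a brute-force oracle


def brute_force_lnl(model, aln):
    """Explicit loop over patterns and root states (independent oracle)."""
    idx = aln.space.index
    total = 0.0
    Ps = {t: model.edge_processes[t].P for t in aln.taxa}
    for pat, count in aln.counts.items():
        p = 0.0
        for c in range(aln.space.n):
            term = model.root_freqs.pi[c]
            for t, codon in zip(aln.taxa, pat):
                term *= Ps[t][c, idx[codon]]
            p += term
        total += count * np.log(p)
    return total


def test_pruning_equals_root_enumeration(space, rng):
    for rep in range(20):
        taus = rng.uniform(0.05, 0.8, 3)
        omegas = rng.uniform(0.1, 1.5, 3)
        model = gnc_triad_model(space, taus=taus, omegas=omegas)
        aln = simulate_alignment(SimSpec(model=model, n_codons=40, seed=100 + rep))
        assert log_likelihood(model, aln) == pytest.approx(
            brute_force_lnl(model, aln), abs=1e-10
        )


def test_lnl_degenerate_zero_tau_limit(space):
    model = gnc_triad_model(space, taus=(0.0, 0.0, 0.0))
    aln = CodonAlignment(
        taxa=("A", "B", "C"), space=space, counts={("AAA", "AAA", "AAA"): 5}
    )
    c = space.index["AAA"]
    assert log_likelihood(model, aln) == pytest.approx(
        5 * np.log(model.root_freqs.pi[c])
    )


def test_lnl_invariant_to_pattern_storage_order(space, triad_model, triad_alignment):
    shuffled = CodonAlignment(
        taxa=triad_alignment.taxa,
        space=space,
        counts=dict(reversed(list(triad_alignment.counts.items()))),
    )
    assert log_likelihood(triad_model, shuffled) == pytest.approx(
        log_likelihood(triad_model, triad_alignment)
    )


# ---------------------------------------------------------------------------
# fitting


@pytest.mark.parametrize(
    "family,expected",
    [("Y98", 67), ("CNFGTR", 71), ("GNC", 99)],
)
def test_free_parameter_counts(family, expected, triad_alignment):
    cfg = FitConfig(model_family=family, restarts=1, min_codons=1, maxiter=2)
    result = fit(triad_alignment, cfg)
    assert result.n_free_params == expected
    assert len(result.theta) == expected
    assert n_free_params(family) == expected


def test_fit_reported_lnl_matches_model(space, triad_alignment):
    cfg = FitConfig(model_family="GNC", restarts=1, min_codons=1)
    result = fit(triad_alignment, cfg)
    assert result.converged
    assert log_likelihood(result.model, triad_alignment) == pytest.approx(
        result.lnL, abs=1e-6
    )


def test_fit_rejects_edge_rooted_gnc(space, triad_alignment):
    cfg = FitConfig(model_family="GNC", restarts=1, min_codons=1)
    topo = Topology.edge_rooted("A", ("B", "C"))
    with pytest.raises(ValueError, match="edge-rooted"):
        fit(triad_alignment, cfg, topology=topo)


def test_nested_schemes_likelihood_ordering(triad_alignment):
    """Sharing omega across two edges can never beat the free model."""
    base = FitConfig(model_family="Y98", restarts=1, min_codons=1)
    res = lrt_omega_equality(triad_alignment, "Y98", ("A", "B"), base)
    assert res.ok
    assert res.fit_null.n_free_params == 66
    assert res.fit_alt.n_free_params == 67
    assert res.statistic >= 0.0
    assert res.df == 1
    assert 0.0 <= res.p_value <= 1.0


def test_lrt_null_pvalues_spread_under_equal_omega(space):
    """With data generated under equal omega the LRT p-values spread over
    (0,1) rather than piling near zero."""
    model = gnc_triad_model(space, taus=(0.3, 0.3, 0.4), omegas=(0.4, 0.4, 0.4))
    cfg = FitConfig(model_family="Y98", restarts=1, min_codons=1)
    ps = []
    for rep in range(8):
        aln = simulate_alignment(SimSpec(model=model, n_codons=400, seed=900 + rep))
        ps.append(lrt_omega_equality(aln, "Y98", ("A", "B"), cfg).p_value)
    ps = np.array(ps)
    assert ps.min() < 0.9
    assert ps.max() > 0.1
    assert np.median(ps) > 0.05
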