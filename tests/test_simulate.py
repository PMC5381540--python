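import numpy as np
import pytest
from scipy.stats import chisquare

from conftest import gnc_triad_model

from nscodon.diagnostics import max_pairwise_jsd
from nscodon.simulate import (
    SimSpec,
    make_nonstationary_fixture,
    simulate_alignment,
    simulate_sequences,
)
from nscodon.trees import node_distribution


def test_zero_tau_copies_root_state(space):
    model = gnc_triad_model(space, taus=(0.0, 0.0, 0.0))
    aln = simulate_alignment(SimSpec(model=model, n_codons=50, seed=1))
    for pat in aln.counts:
        assert pat[0] == pat[1] == pat[2]


def test_fixed_seed_reproducible(triad_model):
    a1 = simulate_alignment(SimSpec(model=triad_model, n_codons=100, seed=9))
    a2 = simulate_alignment(SimSpec(model=triad_model, n_codons=100, seed=9))
    assert a1.counts == a2.counts
    a3 = simulate_alignment(SimSpec(model=triad_model, n_codons=100, seed=10))
    assert a1.counts != a3.counts


def test_replicate_streams_independent_of_order(triad_model):
    r2 = simulate_alignment(
        SimSpec(model=triad_model, n_codons=50, seed=3, replicate_id=2)
    )
    r1 = simulate_alignment(
        SimSpec(model=triad_model, n_codons=50, seed=3, replicate_id=1)
    )
    r2_again = simulate_alignment(
        SimSpec(model=triad_model, n_codons=50, seed=3, replicate_id=2)
    )
    assert r2.counts == r2_again.counts
    assert r1.counts != r2.counts


def test_leaf_frequencies_match_propagated_distribution(space, triad_model):
    """Sampled leaf codon frequencies agree with pi_root . P(path) by a
    chi-square test at the 1% level."""
    aln = simulate_alignment(SimSpec(model=triad_model, n_codons=100_000, seed=5))
    for taxon in aln.taxa:
        expected = node_distribution(triad_model, taxon).pi
        observed = aln.taxon_frequencies(taxon) * aln.n_codons
        # pool tiny-expectation cells for test validity
        keep = expected * aln.n_codons >= 5
        obs, exp = observed[keep], expected[keep] * aln.n_codons
        if (~keep).any():
            obs = np.append(obs, observed[~keep].sum())
            exp = np.append(exp, expected[~keep].sum() * aln.n_codons)
        stat, p = chisquare(obs, exp * obs.sum() / exp.sum())
        assert p > 0.01


def test_sequences_match_alignment_tally(triad_model, space):
    spec = SimSpec(model=triad_model, n_codons=80, seed=21)
    seqs = simulate_sequences(spec)
    aln = simulate_alignment(spec)
    from nscodon.likelihood import pattern_counts

    rebuilt = pattern_counts(seqs, space, min_codons=1)
    assert rebuilt.counts == aln.counts


def test_fixture_stationary_at_level_zero(space):
    model, aln = make_nonstationary_fixture(0.0, 4000, seed=13)
    _, value = max_pairwise_jsd(aln)
    assert value < 0.02  # sampling noise only
    # all edges share one process at level zero
    Qs = [p.Q for p in model.edge_processes.values()]
    for Q in Qs[1:]:
        assert np.allclose(Q, Qs[0])


def test_fixture_jsd_increases_with_divergence(space):
    levels = np.linspace(0.0, 1.0, 5)
    means = []
    for lev in levels:
        vals = [
            max_pairwise_jsd(make_nonstationary_fixture(lev, 800, seed=50 + k)[1])[1]
            for k in range(10)
        ]
        means.append(np.mean(vals))
    assert means[-1] > means[0]
    # overall increasing trend across the grid
    assert np.all(np.diff(np.maximum.accumulate(means)) >= 0)
    assert np.corrcoef(levels, means)[0, 1] > 0.9


def test_fixture_reproducible(space):
    m1, a1 = make_nonstationary_fixture(0.4, 200, seed=3)
    m2, a2 = make_nonstationary_fixture(0.4, 200, seed=3)
    assert a1.counts == a2.counts
    assert np.array_equal(m1.root_freqs.pi, m2.root_freqs.pi)


def test_fixture_outgroup_internal_share_parameters(space):
    model, _ = make_nonstationary_fixture(0.7, 100, seed=1)
    po = model.edge_processes["outgroup"]
    pi_ = model.edge_processes["internal"]
    assert np.allclose(po.Q, pi_.Q)  # same calibrated generator
    assert po.omega == pi_.omega
    assert po.tau != pi_.tau  # scales differ


def test_bias_experiment_table_and_filters(space):
    fixture = make_nonstationary_fixture(0.0, 600, seed=31)
    from nscodon.simulate import bias_experiment

    table, fits = bias_experiment(fixture, config_overrides={"restarts": 1})
    # 2 reversible models x 3 edges x 2 quantities
    assert len(table) == 12
    assert set(table["model"]) == {"Y98", "CNFGTR"}
    assert set(table["quantity"]) == {"distance", "omega"}
    # proxy - true = (generating value - GNC estimate), identical across the
    # reversible models for a given edge and quantity
    for (_, q), sub in table.groupby(["edge", "quantity"]):
        assert sub["proxy_bias"].sub(sub["true_bias"]).round(8).nunique() == 1
    # stationary generating process: distance recovered without large bias
    dist = table[table["quantity"] == "distance"]
    assert dist["true_bias"].abs().median() < 0.08
    assert not table["excluded"].any()
    # the omega filter flags fits whose omega exceeds the threshold
    table2, _ = bias_experiment(
        fixture,
        config_overrides={"restarts": 1, "maxiter": 5},
        omega_exclude_above=1e-9,
    )
    assert table2["excluded"].all()
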