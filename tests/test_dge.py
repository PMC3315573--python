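"""Empirical-Bayes DE machinery: likelihood, prior fit, posterior, calls."""

import numpy as np
import pandas as pd
import pytest

from tagomics import dge
from tagomics.synthetic import SimConfig, generate_truth, simulate_count_table

from oracles import posterior_integrate


@pytest.fixture(scope="module")
def fitted():
    """A prior fitted on a mixed null/DE table with planted truth."""
    cfg = SimConfig(
        n_genes=800,
        n_de_genes=80,
        log2_fc_values=(2.0, 3.0),
        library_sizes=(400_000, 400_000),
        seed=5,
    )
    truth = generate_truth(cfg)
    table = simulate_count_table(truth, cfg)
    prior = dge.fit_prior(table, 400_000, 400_000)
    return cfg, truth, table, prior


def test_tpm_examples():
    assert dge.normalize_tpm(50, 100_000) == 500.0
    assert dge.normalize_tpm(0, 123) == 0.0
    assert dge.normalize_tpm(777, 777) == 1e6
    with pytest.raises(ValueError):
        dge.normalize_tpm(1, 0)


def test_marginal_likelihood_symmetry_at_null():
    assert dge.marginal_likelihood(1, 1, 1e6, 1e6, 0.0) == pytest.approx(0.5)


def test_marginal_likelihood_limits():
    # strongly positive fold change (condition 2 up) makes x1 = 0 certain
    assert dge.marginal_likelihood(0, 10, 1e6, 1e6, 30.0) == pytest.approx(1.0)
    assert dge.marginal_likelihood(10, 0, 1e6, 1e6, -30.0) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(3))
def test_marginal_likelihood_equals_profiled_poisson(seed):
    """Conditioning on x1+x2 profiles out the shared baseline exactly:
    the conditional binomial equals the two-Poisson ratio for any baseline."""
    from math import exp, factorial

    rng = np.random.default_rng(seed)
    for _ in range(20):
        x1, x2 = int(rng.integers(0, 12)), int(rng.integers(0, 12))
        n1, n2 = rng.uniform(0.5e6, 2e6, 2)
        delta = rng.uniform(-4, 4)
        lam = rng.uniform(1e-7, 3e-6)  # arbitrary baseline proportion (keeps exp(-mu) in range)
        mu1, mu2 = n1 * lam, n2 * lam * 2.0**delta

        def pois(k, mu):
            return exp(-mu) * mu**k / factorial(k)

        n = x1 + x2
        joint = pois(x1, mu1) * pois(x2, mu2)
        marg = sum(pois(k, mu1) * pois(n - k, mu2) for k in range(n + 1))
        assert dge.marginal_likelihood(x1, x2, n1, n2, delta) == pytest.approx(
            joint / marg, rel=1e-9
        )


def test_fit_prior_all_null_recovers_high_pi0():
    for seed in range(5):
        cfg = SimConfig(
            n_genes=600, n_de_genes=0, library_sizes=(500_000, 500_000), seed=seed
        )
        table = simulate_count_table(generate_truth(cfg), cfg)
        prior = dge.fit_prior(table, 500_000, 500_000)
        assert prior.pi0 >= 0.9
        assert prior.converged


def test_fit_prior_half_de_recovers_pi0_near_half():
    cfg = SimConfig(
        n_genes=600,
        n_de_genes=300,
        log2_fc_values=(3.0,),
        library_sizes=(600_000, 600_000),
        seed=2,
    )
    table = simulate_count_table(generate_truth(cfg), cfg)
    prior = dge.fit_prior(table, 600_000, 600_000)
    assert prior.pi0 == pytest.approx(0.5, abs=0.1)


def test_fit_prior_warns_on_tiny_table():
    table = pd.DataFrame({"gene_id": ["g1"], "x1": [10], "x2": [20]})
    with pytest.warns(UserWarning, match="only 1 genes"):
        prior = dge.fit_prior(table, 1000, 1000)
    assert np.isfinite(prior.pi0) and np.isfinite(prior.tau)


def test_posterior_matches_integration_oracle(fitted):
    """Independently coded direct-summation integrator agrees to 1e-6."""
    _, _, _, prior = fitted
    rng = np.random.default_rng(17)
    floor = prior.spacing / np.sqrt(12.0)
    for _ in range(100):
        x1, x2 = int(rng.integers(0, 500)), int(rng.integers(0, 500))
        r = dge.posterior_de(x1, x2, 1e6, 1.3e6, prior)
        mean, sd, spike = posterior_integrate(
            x1, x2, 1e6, 1.3e6, prior.pi0, prior.tau, prior.grid
        )
        assert r.delta_hat == pytest.approx(mean, abs=1e-6)
        assert r.se == pytest.approx(max(sd, floor), abs=1e-6)
        assert r.lfdr == pytest.approx(spike, abs=1e-6)


def test_posterior_null_input_stays_null(fitted):
    _, _, _, prior = fitted
    r = dge.posterior_de(100, 100, 1e6, 1e6, prior)
    assert r.delta_hat == pytest.approx(0.0, abs=1e-9)
    assert r.lfdr >= prior.pi0  # data at the null reinforce the spike


def test_posterior_shrinks_extreme_ratios(fitted):
    _, _, _, prior = fitted
    r = dge.posterior_de(0, 50, 1e6, 1e6, prior)
    naive = abs(np.log2(0.5 / 50.5))
    assert 0 < abs(r.delta_hat) < naive


def test_posterior_swap_symmetry(fitted):
    _, _, _, prior = fitted
    a = dge.posterior_de(7, 150, 1e6, 2e6, prior)
    b = dge.posterior_de(150, 7, 2e6, 1e6, prior)
    assert a.delta_hat == pytest.approx(-b.delta_hat, abs=1e-12)
    assert a.lfdr == pytest.approx(b.lfdr, abs=1e-12)
    assert a.se == pytest.approx(b.se, abs=1e-12)


def test_posterior_monotone_in_x1(fitted):
    _, _, _, prior = fitted
    n = 200
    deltas = [dge.posterior_de(x1, n - x1, 1e6, 1e6, prior).delta_hat for x1 in range(0, n + 1, 20)]
    assert all(d1 >= d2 - 1e-12 for d1, d2 in zip(deltas, deltas[1:]))


def test_posterior_shrinkage_bound(fitted):
    """|delta_hat| never exceeds the pseudocount log-ratio by more than one
    grid step, and never exceeds the grid limit."""
    _, _, table, prior = fitted
    res = dge.de_table(table, 400_000, 400_000, prior)
    naive = np.abs(
        np.log2(((table.x2 + 0.5) / 400_000) / ((table.x1 + 0.5) / 400_000))
    )
    assert (np.abs(res.delta_hat) <= prior.grid.max() + 1e-12).all()
    assert (np.abs(res.delta_hat) <= naive + prior.spacing + 1e-9).all()


def test_posterior_no_data_flag(fitted):
    _, _, _, prior = fitted
    r = dge.posterior_de(0, 0, 1e6, 1e6, prior)
    assert r.no_data
    assert r.delta_hat == pytest.approx(0.0)
    assert r.lfdr == pytest.approx(prior.pi0, abs=1e-9)


def test_call_differential_threshold_and_sorting(fitted):
    cfg, truth, table, prior = fitted
    res = dge.de_table(table, *cfg.library_sizes, prior)
    assert dge.call_differential(res, 0.0).empty
    with pytest.raises(ValueError):
        dge.call_differential(res, 1.5)
    called = dge.call_differential(res, 0.05)
    assert (called.z.to_numpy()[:-1] >= called.z.to_numpy()[1:]).all()
    assert called.attrs["n_up"] + called.attrs["n_down"] == len(called)


def test_calls_recover_planted_genes(fitted):
    cfg, truth, table, prior = fitted
    res = dge.de_table(table, *cfg.library_sizes, prior)
    called = set(dge.call_differential(res, 0.05).gene_id)
    de = truth.genes[truth.genes.delta != 0]
    strong = de[(table.set_index("gene_id").loc[de.gene_id, ["x1", "x2"]].mean(axis=1) >= 50).to_numpy()]
    sensitivity = np.mean([g in called for g in strong.gene_id])
    assert sensitivity >= 0.8
    null_ids = set(truth.genes[truth.genes.delta == 0].gene_id)
    false_calls = len(called & null_ids)
    assert false_calls / max(len(called), 1) <= 0.1
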