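"""Omega estimation, whitening, X^T^X and the closed-form Bayes factor."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from poolgea import core
from poolgea.containers import AlleleFreqMatrix
from poolgea.simulate import (
    SimulationConfig,
    simulate_environment,
    simulate_frequencies,
    spike_environment,
)


def _freq_matrix(p, scaffold="s1"):
    n, k = p.shape
    return AlleleFreqMatrix(
        freq=p,
        mask=np.zeros_like(p, dtype=bool),
        pi=p.mean(axis=1),
        snps=pd.DataFrame({"scaffold": [scaffold] * n, "pos": np.arange(1, n + 1)}),
        pop_labels=[f"POP{i + 1:02d}" for i in range(k)],
    )


# ---------------------------------------------------------------- omega


def test_identity_omega_recovery_off_diagonals():
    cfg = SimulationConfig(
        n_snps=50_000, omega_spec="identity", pi_range=(0.2, 0.8), seed=21
    )
    freqs, truth = simulate_frequencies(cfg)
    om = core.estimate_omega(freqs)
    off = om.matrix[~np.eye(om.n_pops, dtype=bool)]
    assert np.abs(off).max() < 0.03
    # diagonal close to the true drift variance
    assert np.abs(np.diag(om.matrix) - np.diag(truth.true_omega)).max() < 0.03


def test_block_omega_recovery_frobenius():
    cfg = SimulationConfig(
        n_snps=50_000, omega_spec="block", pi_range=(0.2, 0.8), seed=22
    )
    freqs, truth = simulate_frequencies(cfg)
    om = core.estimate_omega(freqs)
    rel = np.linalg.norm(om.matrix - truth.true_omega) / np.linalg.norm(truth.true_omega)
    assert rel < 0.10


def test_duplicated_population_shows_as_full_covariance(rng):
    p = np.clip(0.5 + 0.1 * rng.standard_normal((20_000, 6)), 0.01, 0.99)
    p[:, 5] = p[:, 4]  # duplicate the last population
    om = core.estimate_omega(_freq_matrix(p))
    assert om.matrix[4, 5] == pytest.approx(om.matrix[4, 4], rel=0.05)


def test_shrinkage_moves_toward_diagonal():
    cfg = SimulationConfig(n_snps=5_000, omega_spec="block", pi_range=(0.2, 0.8), seed=23)
    freqs, _ = simulate_frequencies(cfg)
    plain = core.estimate_omega(freqs).matrix
    shrunk = core.estimate_omega(freqs, method="shrinkage", shrinkage=0.5).matrix
    off = ~np.eye(plain.shape[0], dtype=bool)
    assert np.abs(shrunk[off]).sum() < np.abs(plain[off]).sum()
    with pytest.raises(ValueError):
        core.estimate_omega(freqs, method="bogus")


def test_omega_cholesky_consistency(small_identity_sim):
    _, freqs, _ = small_identity_sim
    om = core.estimate_omega(freqs)
    np.testing.assert_allclose(om.chol @ om.chol.T, om.matrix, atol=1e-10)


# ---------------------------------------------------------------- whitening / xtx


def test_standardize_with_identity_omega_returns_scaled_deviations(small_identity_sim):
    _, freqs, _ = small_identity_sim
    om = core.OmegaMatrix.from_matrix(np.eye(freqs.n_pops))
    z = core.standardize(freqs, om)
    np.testing.assert_allclose(z, core.scaled_deviations(freqs), atol=1e-12)


def test_whitening_property_with_known_truth():
    # interior frequencies and modest drift keep the clamp inactive, so the
    # generator is linear and the whitening identity is exact
    cfg = SimulationConfig(
        n_snps=50_000, omega_spec="block", omega_scale=0.08,
        pi_range=(0.3, 0.7), seed=24,
    )
    freqs, truth = simulate_frequencies(cfg)
    om = core.OmegaMatrix.from_matrix(truth.true_omega)
    z = core.standardize(freqs, om, pi=truth.true_pi)
    cov = (z.T @ z) / z.shape[0]
    assert np.abs(cov - np.eye(cfg.n_pops)).max() < 0.05


def test_xtx_zero_vector_and_null_mean(small_identity_sim):
    _, freqs, _ = small_identity_sim
    assert core.xtx(np.zeros((1, 21)))[0] == 0.0
    om = core.estimate_omega(freqs)
    z = core.standardize(freqs, om)
    k = freqs.n_pops
    assert abs(core.xtx(z).mean() - k) / k < 0.02
    # df correction is exactly K/(K-1)
    np.testing.assert_allclose(
        core.xtx(z, df_correction=False) * k / (k - 1), core.xtx(z)
    )


def test_spiked_differentiation_lands_in_xtx_tail():
    cfg = SimulationConfig(
        n_snps=20_000, n_adaptive=5, beta=0.25, pi_range=(0.2, 0.8), seed=25
    )
    freqs, truth = simulate_frequencies(cfg)
    env = simulate_environment(cfg.n_pops, seed=25)["env_noise_2"].to_numpy()
    freqs, truth = spike_environment(freqs, env, cfg, truth)
    om = core.estimate_omega(freqs)
    x = core.xtx(core.standardize(freqs, om))
    cutoff = np.quantile(x, 0.999)
    assert (x[truth.adaptive_snp_ids] > cutoff).mean() >= 0.8


# ---------------------------------------------------------------- bayes factor


def _quadrature_bf(z, e, tau):
    """Independent oracle: integrate N(z; beta e, I) N(beta; 0, tau) dbeta
    over N(z; 0, I) by 1-D quadrature."""
    ez = float(e @ z)
    ee = float(e @ e)

    def integrand(b):
        return np.exp(b * ez - 0.5 * b**2 * ee) * stats.norm.pdf(b, 0, np.sqrt(tau))

    val, _ = integrate.quad(integrand, -np.inf, np.inf)
    return val


def test_bf_matches_quadrature_oracle(rng):
    k = 21
    om = core.OmegaMatrix.from_matrix(np.eye(k))
    for _ in range(100):
        z = rng.standard_normal((1, k))
        env = rng.standard_normal(k)
        tau = float(rng.uniform(0.02, 1.0))
        bfdb = core.bf_env(z, env, tau, om)[0]
        e = (env - env.mean()) / env.std()
        oracle = 10 * np.log10(_quadrature_bf(z[0], e, tau))
        assert bfdb == pytest.approx(oracle, rel=1e-6, abs=1e-6)


def test_bf_negative_when_projection_zero():
    k = 10
    om = core.OmegaMatrix.from_matrix(np.eye(k))
    env = np.linspace(-1, 1, k)
    e = (env - env.mean()) / env.std()
    z = np.zeros((1, k))  # e'z = 0
    assert core.bf_env(z, env, 0.3, om)[0] < 0


def test_bf_invariant_to_affine_env_rescaling(rng):
    k = 21
    om = core.OmegaMatrix.from_matrix(np.eye(k))
    z = rng.standard_normal((50, k))
    env = rng.standard_normal(k)
    a = core.bf_env(z, env, 0.1, om)
    b = core.bf_env(z, 3.7 * env - 11.0, 0.1, om)
    np.testing.assert_allclose(a, b, atol=1e-10)


def test_constant_env_rejected():
    om = core.OmegaMatrix.from_matrix(np.eye(4))
    with pytest.raises(ValueError, match="constant"):
        core.bf_env(np.zeros((1, 4)), np.ones(4), 0.1, om)


# ---------------------------------------------------------------- run_gea


def test_scan_preserves_order_and_chunking_is_invisible(small_identity_sim, env_table):
    _, freqs, _ = small_identity_sim
    scan1 = core.run_gea(freqs, env_table, core.GeaConfig(n_subdatasets=19))
    scan19 = core.run_gea(freqs, env_table, core.GeaConfig(n_subdatasets=1))
    assert len(scan1.table) == freqs.n_snps
    pd.testing.assert_frame_equal(
        scan1.table[["scaffold", "pos"]], freqs.snps[["scaffold", "pos"]]
    )
    for v in scan1.variables:
        np.testing.assert_allclose(scan1.bf(v), scan19.bf(v), atol=1e-10)
    np.testing.assert_allclose(
        scan1.table["xtx"], scan19.table["xtx"], atol=1e-10
    )


def test_scan_requires_matching_populations(small_identity_sim, env_table):
    _, freqs, _ = small_identity_sim
    with pytest.raises(ValueError, match="mismatch"):
        core.run_gea(freqs, env_table.iloc[:-1], core.GeaConfig())


def test_gea_config_validation():
    with pytest.raises(ValueError):
        core.GeaConfig(tau=0.0)
    with pytest.raises(ValueError):
        core.GeaConfig(tail_fraction=0.7)
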