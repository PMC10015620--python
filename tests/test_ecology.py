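"""Network indices against hand oracles, BLUP recovery, pruning, PCA."""

import numpy as np
import pandas as pd
import pytest

from poolgea import ecology
from poolgea.simulate import (
    SimulationConfig,
    simulate_frequencies,
)


def _visits(matrix, categories=None):
    m = np.asarray(matrix)
    cats = categories or [f"cat{i}" for i in range(m.shape[1])]
    return pd.DataFrame(m, index=[f"P{i}" for i in range(m.shape[0])], columns=cats)


# ---------------------------------------------------------------- indices


def test_uniform_community_symmetry():
    v = _visits(np.full((3, 12), 5))
    idx = ecology.network_indices(v)
    assert (idx["normalized_degree"] == 1.0).all()
    np.testing.assert_allclose(idx["partner_diversity"], np.log(12))
    np.testing.assert_allclose(idx["d_index"], 0.0, atol=1e-12)
    np.testing.assert_allclose(idx["proportional_similarity"], 1.0)
    np.testing.assert_allclose(idx["species_specificity"], 0.0)


def test_single_category_specialist():
    m = np.full((2, 6), 3)
    m[0] = [30, 0, 0, 0, 0, 0]
    idx = ecology.network_indices(_visits(m))
    assert idx.loc["P0", "partner_diversity"] == 0.0
    assert idx.loc["P0", "effective_partners"] == 1.0
    assert idx.loc["P0", "normalized_degree"] == pytest.approx(1 / 6)
    assert idx.loc["P0", "species_specificity"] == pytest.approx(1.0)


def test_two_by_two_hand_oracle():
    idx = ecology.network_indices(_visits([[9, 1], [1, 9]]))
    # row symmetry
    for col in idx.columns:
        assert idx.iloc[0][col] == pytest.approx(idx.iloc[1][col])
    row = idx.iloc[0]
    p = np.array([0.9, 0.1])
    q = np.array([0.5, 0.5])
    h = -(p * np.log(p)).sum()
    assert row["normalized_degree"] == 1.0
    assert row["species_strength"] == pytest.approx(0.9 + 0.1)
    assert row["species_specificity"] == pytest.approx((4.0 / 5.0) / 1.0)
    assert row["partner_diversity"] == pytest.approx(h)
    assert row["effective_partners"] == pytest.approx(np.exp(h))
    assert row["proportional_similarity"] == pytest.approx(1 - 0.5 * (0.4 + 0.4))
    assert row["proportional_generality"] == pytest.approx(np.exp(h) / 2.0)
    d = (p * np.log(p / q)).sum()
    assert row["d_index"] == pytest.approx(d / np.log(2.0))


def test_index_invariants_on_random_matrices(rng):
    for _ in range(25):
        m = rng.integers(0, 40, size=(rng.integers(2, 8), rng.integers(2, 13)))
        m[m.sum(axis=1) == 0, 0] = 1  # no all-zero rows
        idx = ecology.network_indices(_visits(m))
        assert idx["normalized_degree"].between(0, 1).all()
        assert idx["d_index"].between(0, 1).all()
        np.testing.assert_allclose(
            idx["effective_partners"], np.exp(idx["partner_diversity"]), rtol=1e-12
        )
        assert (idx["effective_partners"] <= m.shape[1] + 1e-9).all()
        assert idx["species_specificity"].between(0, 1).all()


def test_partner_diversity_maximal_iff_uniform(rng):
    m = np.vstack([[10, 10, 10, 10], [37, 1, 1, 1]])
    idx = ecology.network_indices(_visits(m))
    assert idx.iloc[0]["partner_diversity"] == pytest.approx(np.log(4))
    assert idx.iloc[1]["partner_diversity"] < np.log(4)


# ---------------------------------------------------------------- BLUP


def test_blup_degenerate_cases():
    df = pd.DataFrame({"population": list("aabb"), "visits": [5.0, 5.0, 5.0, 5.0]})
    out = ecology.blup_visits(df)
    np.testing.assert_allclose(out["predictions"], out["mu"])

    rng = np.random.default_rng(3)
    # group means identical, pure residual noise: var_pop ~ 0, preds ~ mu
    df = pd.DataFrame(
        {
            "population": np.repeat(list("abcde"), 20),
            "visits": rng.normal(10, 1, 100),
        }
    )
    out = ecology.blup_visits(df)
    assert out["var_pop"] < 0.2
    assert np.abs(out["predictions"] - out["mu"]).max() < 0.5


def test_blup_single_population_rejected():
    df = pd.DataFrame({"population": ["a"] * 5, "visits": range(5)})
    with pytest.raises(ValueError):
        ecology.blup_visits(df)


def test_blup_matches_mixedlm_random_effects():
    rng = np.random.default_rng(8)
    pops = np.repeat([f"p{i}" for i in range(12)], 6)
    effects = rng.normal(0, 2, 12)
    y = 20 + effects[np.repeat(np.arange(12), 6)] + rng.normal(0, 1, 72)
    df = pd.DataFrame({"population": pops, "visits": y})
    out = ecology.blup_visits(df)
    # dual route: shrinkage formula vs the fitted model's own BLUPs
    re = out["fit"].random_effects
    for pop in df["population"].unique():
        assert out["population_effects"][pop] == pytest.approx(
            float(re[pop].iloc[0]), abs=1e-2
        )


def test_blup_variance_component_recovery():
    rng = np.random.default_rng(15)
    vp, vr = [], []
    for _ in range(200):
        effects = rng.normal(0, 2.0, 50)  # var_pop = 4
        y = 10 + np.repeat(effects, 5) + rng.normal(0, 1.0, 250)
        df = pd.DataFrame(
            {"population": np.repeat(np.arange(50), 5).astype(str), "visits": y}
        )
        out = ecology.blup_visits(df)
        vp.append(out["var_pop"])
        vr.append(out["var_res"])
    assert np.mean(vp) == pytest.approx(4.0, rel=0.3)
    assert np.mean(vr) == pytest.approx(1.0, rel=0.3)


def test_blup_shrinkage_monotone_in_group_size():
    rng = np.random.default_rng(21)
    sizes = [2, 5, 10, 40]
    rows = []
    for i, n in enumerate(sizes * 5):  # 20 groups, varying sizes
        rows.append(
            pd.DataFrame(
                {
                    "population": f"g{i}",
                    "visits": 10 + rng.normal(0, 2) + rng.normal(0, 1, n),
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    out = ecology.blup_visits(df)
    shrink = out["shrinkage"]
    n_k = df.groupby("population").size()
    order = n_k.sort_values().index
    s = shrink[order].to_numpy()
    assert (np.diff(s) >= -1e-9).all()


# ---------------------------------------------------------------- pruning


def _oracle_prune(env, rho_max):
    """Independent restatement of the greedy rule."""
    from scipy.stats import spearmanr

    cols = list(env.columns)
    pairs = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            rho = abs(spearmanr(env[a], env[b])[0])
            if rho >= rho_max:
                pairs.append((rho, tuple(sorted((a, b))), a, b))
    pairs.sort(key=lambda t: (-t[0], t[1]))
    dropped = set()
    for rho, _, a, b in pairs:
        if a in dropped or b in dropped:
            continue
        dropped.add(b if cols.index(b) > cols.index(a) else a)
    return [c for c in cols if c not in dropped]


def test_perfectly_correlated_pair_keeps_one(rng):
    x = rng.normal(size=30)
    env = pd.DataFrame({"a": x, "b": np.exp(x)})  # same ranks
    assert ecology.spearman_prune(env) == ["a"]


def test_uncorrelated_variables_all_retained(rng):
    env = pd.DataFrame(rng.normal(size=(50, 6)), columns=list("abcdef"))
    assert ecology.spearman_prune(env) == list("abcdef")


def test_prune_matches_oracle_on_correlated_triple(rng):
    x = rng.normal(size=40)
    env = pd.DataFrame(
        {
            "v1": x,
            "v2": x + 0.01 * rng.normal(size=40),
            "v3": -x + 0.01 * rng.normal(size=40),
            "v4": rng.normal(size=40),
            "v5": rng.normal(size=40),
        }
    )
    assert ecology.spearman_prune(env) == _oracle_prune(env, 0.8)


def test_prune_invariant_to_population_row_order(rng):
    env = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
    env["f"] = env["a"] * 2 + 0.001 * rng.normal(size=30)
    perm = rng.permutation(30)
    assert ecology.spearman_prune(env) == ecology.spearman_prune(env.iloc[perm])


def test_constant_variable_flagged_not_pruned(rng):
    env = pd.DataFrame({"a": rng.normal(size=20), "c": np.ones(20)})
    retained = ecology.spearman_prune(env)
    assert "c" in retained and "a" in retained


# ---------------------------------------------------------------- ordinations


def test_pca_identical_variables_collapse_to_one_axis(rng):
    x = rng.normal(size=25)
    env = pd.DataFrame({"a": x, "b": x})
    out = ecology.env_pca(env)
    assert out["variance_explained"][0] == pytest.approx(1.0)


def test_pca_sign_convention_stable(rng):
    env = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
    o1 = ecology.env_pca(env)
    o2 = ecology.env_pca(env)
    pd.testing.assert_frame_equal(o1["scores"], o2["scores"])
    for k in range(4):
        lead = o1["loadings"].iloc[:, k].abs().idxmax()
        assert o1["loadings"].loc[lead].iloc[k] > 0


def test_pca_rejects_constant_column(rng):
    env = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
    with pytest.raises(ValueError):
        ecology.env_pca(env)


def test_genomic_pc_detects_planted_gradient(env_table, rng):
    # rank-one construction: every SNP follows the same latitudinal gradient
    from poolgea.containers import AlleleFreqMatrix
    import pandas as pd

    n, k = 2_000, 21
    grad = np.linspace(-1, 1, k)
    load = rng.uniform(0.05, 0.15, n)
    p = np.clip(0.5 + load[:, None] * grad[None, :] + 0.005 * rng.standard_normal((n, k)), 0.01, 0.99)
    freqs = AlleleFreqMatrix(
        freq=p,
        mask=np.zeros_like(p, dtype=bool),
        pi=p.mean(axis=1),
        snps=pd.DataFrame({"scaffold": ["s1"] * n, "pos": np.arange(1, n + 1)}),
        pop_labels=list(env_table.index),
    )
    out = ecology.genomic_pc(env_table, freqs)
    assert out["variance_explained"][0] > 0.9
    # an env variable equal to PC1 itself correlates perfectly
    env2 = env_table.copy()
    env2["pc1_copy"] = out["scores"].iloc[:, 0].to_numpy()
    out2 = ecology.genomic_pc(env2, freqs)
    assert out2["env_pc1_correlation"]["pc1_copy"] == pytest.approx(1.0, abs=1e-9)


def test_genomic_pc_permuted_env_uncorrelated(env_table, rng):
    cfg = SimulationConfig(n_snps=3_000, seed=33)
    freqs, _ = simulate_frequencies(cfg)
    env2 = env_table.copy()
    corrs = []
    for _ in range(30):
        env2["shuffled"] = rng.permutation(env_table.iloc[:, 0].to_numpy())
        out = ecology.genomic_pc(env2, freqs)
        corrs.append(out["env_pc1_correlation"]["shuffled"])
    assert abs(np.mean(corrs)) < 0.15


def test_genomic_pc_needs_three_populations(env_table):
    cfg = SimulationConfig(n_pops=2, n_snps=100, omega_spec="identity", seed=1)
    freqs, _ = simulate_frequencies(cfg)
    with pytest.raises(ValueError):
        ecology.genomic_pc(env_table.iloc[:2], freqs)
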