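import numpy as np
import pytest

import spanmf
from spanmf import FactorParams, SpatialDataset, build_graph, fit, fit_multislice
from spanmf.factorize import compute_pss, objective, update_h, update_w

from conftest import random_dataset


def brute_force_objective(X, W, H, A, alpha, beta, gamma, pss):
    """Loop-based term-by-term evaluation of the objective."""
    n, p = len(X), len(X[0])
    r = len(W[0])
    WH = [[sum(W[i][k] * H[k][j] for k in range(r)) for j in range(p)] for i in range(n)]
    recon = sum((X[i][j] - WH[i][j]) ** 2 for i in range(n) for j in range(p))
    spatial = 0.0
    for k in range(r):
        quad = 0.0
        for i in range(n):
            for j in range(n):
                quad += 0.5 * A[i][j] * (W[i][k] - W[j][k]) ** 2
        spatial += alpha * pss[k] * quad
    sparsity = beta * sum(abs(W[i][k]) for i in range(n) for k in range(r))
    ortho = 0.0
    for a in range(r):
        for b in range(a + 1, r):
            ortho += (gamma / 2.0) * sum(H[a][j] * H[b][j] for j in range(p)) ** 2
    return recon, spatial, sparsity, ortho


def brute_force_pss(X, W, H):
    n, p = len(X), len(X[0])
    r = len(W[0])
    out = []
    for i in range(r):
        l1 = sum(abs(W[s][i]) for s in range(n))
        if l1 == 0:
            out.append(0.0)
            continue
        pi = [sum(X[s][j] * W[s][i] for s in range(n)) / l1 for j in range(p)]
        pn = np.sqrt(sum(v * v for v in pi))
        hn = np.sqrt(sum(H[i][j] ** 2 for j in range(p)))
        if pn == 0 or hn == 0:
            out.append(0.0)
            continue
        out.append(sum(pi[j] * H[i][j] for j in range(p)) / (pn * hn))
    return np.array(out)


def small_instance(seed, n=12, p=9, r=3, alpha=0.8):
    rng = np.random.default_rng(seed)
    ds = random_dataset(rng, n=n, p=p, coord_range=6.0)
    g = build_graph(ds, lam=2.0)
    params = FactorParams(r=r, alpha=alpha, n_cluster=2, seed=seed).resolve(p)
    W = rng.uniform(0.1, 1.0, size=(n, r))
    H = rng.uniform(0.1, 1.0, size=(r, p))
    return ds, g, params, W, H


class TestObjective:
    def test_perfect_fit_without_penalties_is_zero(self, rng):
        W = rng.uniform(size=(6, 2))
        H = rng.uniform(size=(2, 4))
        X = W @ H
        params = FactorParams(alpha=0.0, beta=0.0, gamma=0.0, r=2)
        terms = objective(X, W, H, None, params, np.ones(2))
        assert terms.total == pytest.approx(0.0, abs=1e-20)

    def test_zero_factors_leave_reconstruction_only(self, rng):
        X = rng.uniform(size=(5, 4))
        params = FactorParams(alpha=0.7, beta=0.3, gamma=0.2, r=3)
        g_dummy = build_graph(
            SpatialDataset(X=X, coords=rng.uniform(0, 2, size=(5, 2))), lam=3.0
        )
        terms = objective(X, np.zeros((5, 3)), np.zeros((3, 4)), g_dummy, params, np.ones(3))
        assert terms.total == pytest.approx(np.linalg.norm(X) ** 2, rel=1e-12)
        assert terms.spatial == terms.sparsity == terms.ortho == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        ds, g, params, W, H = small_instance(seed)
        pss = compute_pss(ds.dense(), W, H)
        terms = objective(ds.X, W, H, g, params, pss)
        recon, spatial, sparsity, ortho = brute_force_objective(
            ds.dense().tolist(), W.tolist(), H.tolist(), g.A.toarray().tolist(),
            params.alpha, params.beta, params.gamma, pss.tolist(),
        )
        assert terms.recon == pytest.approx(recon, rel=1e-12)
        assert terms.spatial == pytest.approx(spatial, rel=1e-12)
        assert terms.sparsity == pytest.approx(sparsity, rel=1e-12)
        assert terms.ortho == pytest.approx(ortho, rel=1e-12)
        assert terms.total == terms.recon + terms.spatial + terms.sparsity + terms.ortho


class TestPatternSignificance:
    def test_exact_rank_one_data_scores_one(self, rng):
        w = rng.uniform(0.1, 1.0, size=(20, 1))
        h = rng.uniform(0.1, 1.0, size=(1, 8))
        pss = compute_pss(w @ h, w, h)
        assert pss[0] == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_conventions_score_zero(self, rng):
        X = rng.uniform(size=(6, 4))
        W = np.column_stack([np.zeros(6), rng.uniform(size=6)])
        H = rng.uniform(size=(2, 4))
        assert compute_pss(X, W, H)[0] == 0.0
        H2 = np.vstack([np.zeros(4), H[1]])
        assert compute_pss(X, W, H2)[0] == 0.0

    def test_disjoint_supports_score_zero(self):
        X = np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        W = np.array([[1.0], [1.0], [1.0]])
        H = np.array([[0.0, 1.0]])  # signature on the gene the pattern never touches
        assert compute_pss(X, W, H)[0] == 0.0

    def test_scale_exchange_invariance(self, rng):
        X = rng.uniform(size=(15, 6))
        W = rng.uniform(size=(15, 3))
        H = rng.uniform(size=(3, 6))
        base = compute_pss(X, W, H)
        for c in (0.01, 3.7, 250.0):
            W2, H2 = W.copy(), H.copy()
            W2[:, 1] *= c
            H2[1] /= c
            np.testing.assert_allclose(compute_pss(X, W2, H2), base, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_and_range(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(size=(10, 7))
        W = rng.uniform(size=(10, 4))
        H = rng.uniform(size=(4, 7))
        got = compute_pss(X, W, H)
        expected = brute_force_pss(X.tolist(), W.tolist(), H.tolist())
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert np.all((got >= 0) & (got <= 1))


class TestMultiplicativeUpdates:
    def test_zeros_are_absorbing(self):
        ds, g, params, W, H = small_instance(0)
        W[3, 1] = 0.0
        H[2, 4] = 0.0
        pss = compute_pss(ds.dense(), W, H)
        assert update_w(ds.X, W, H, g, params, pss)[3, 1] == 0.0
        assert update_h(ds.X, W, H, params)[2, 4] == 0.0
        assert np.all(update_w(ds.X, W, H, g, params, pss) >= 0)
        assert np.all(update_h(ds.X, W, H, params) >= 0)

    def test_gamma_zero_reduces_to_classical_nmf_h_update(self):
        ds, g, params, W, H = small_instance(1)
        params0 = FactorParams(alpha=params.alpha, beta=params.beta, gamma=0.0,
                               r=params.r, delta=params.delta).resolve(ds.n_features)
        expected = H * (W.T @ ds.dense()) / (W.T @ W @ H + params.delta)
        np.testing.assert_allclose(update_h(ds.X, W, H, params0), expected, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_each_step_does_not_increase_objective(self, seed):
        ds, g, params, W, H = small_instance(seed, n=25, p=15, r=4)
        X = ds.X
        for _ in range(30):
            pss = compute_pss(X, W, H)
            f0 = objective(X, W, H, g, params, pss).total
            W = update_w(X, W, H, g, params, pss)
            f1 = objective(X, W, H, g, params, pss).total
            H = update_h(X, W, H, params)
            f2 = objective(X, W, H, g, params, pss).total
            assert f1 <= f0 * (1 + 1e-9)
            assert f2 <= f1 * (1 + 1e-9)


class TestFit:
    def test_identical_seeds_are_bit_identical(self, rng):
        ds = random_dataset(rng, n=30, p=12)
        g = build_graph(ds, lam=2.0)
        params = FactorParams(r=4, n_cluster=2, max_iter=40, seed=11)
        m1 = fit(ds, g, params)
        m2 = fit(ds, g, params)
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(m1.H, m2.H)
        np.testing.assert_array_equal(m1.objective_trace, m2.objective_trace)

    def test_noiseless_rank_one_data_is_recovered(self, rng):
        w = rng.uniform(0.5, 1.5, size=(40, 1))
        h = rng.uniform(0.5, 1.5, size=(1, 15))
        X = w @ h
        ds = SpatialDataset(X=X, coords=rng.uniform(0, 5, size=(40, 2)))
        params = FactorParams(r=1, alpha=0.0, beta=0.0, gamma=0.0, n_cluster=1,
                              N1=0, N2=0, max_iter=500, tol=1e-12, seed=0)
        model = fit(ds, None, params)
        rel = np.linalg.norm(X - model.W @ model.H) / np.linalg.norm(X)
        assert rel < 1e-3

    def test_factors_nonnegative_and_trace_consistent(self, rng):
        ds = random_dataset(rng, n=25, p=10)
        g = build_graph(ds, lam=2.0)
        model = fit(ds, g, FactorParams(r=3, n_cluster=2, max_iter=30, seed=2))
        assert np.all(model.W >= 0) and np.all(model.H >= 0)
        tr = model.objective_trace
        np.testing.assert_allclose(tr[:, 0], tr[:, 1:].sum(axis=1), rtol=1e-12)
        assert np.all((model.pss >= 0) & (model.pss <= 1))
        assert np.all(np.diff(model.pss) <= 1e-12)  # reported in descending PSS order

    def test_all_zero_feature_is_rejected(self, rng):
        X = rng.uniform(size=(10, 4))
        X[:, 2] = 0.0
        ds = SpatialDataset(X=X, coords=rng.uniform(0, 3, size=(10, 2)))
        g = build_graph(ds, lam=3.0)
        with pytest.raises(ValueError, match="zero total expression"):
            fit(ds, g, FactorParams(r=2, n_cluster=1, max_iter=5))


class TestMultislice:
    def test_single_slice_reduces_to_fit(self, rng):
        ds = random_dataset(rng, n=20, p=8)
        g = build_graph(ds, lam=2.0)
        params = FactorParams(r=3, n_cluster=2, max_iter=25, seed=7)
        single = fit(ds, g, params)
        multi = fit_multislice([ds], [g], params)
        np.testing.assert_array_equal(single.W, multi.W_list[0])
        np.testing.assert_array_equal(single.H, multi.H)
        np.testing.assert_array_equal(single.objective_trace, multi.objective_trace)

    def test_feature_axis_mismatch_is_rejected(self, rng):
        a = random_dataset(rng, n=10, p=5)
        b = random_dataset(rng, n=10, p=6)
        g_a = build_graph(a, lam=3.0)
        g_b = build_graph(b, lam=3.0)
        with pytest.raises(ValueError, match="feature axis"):
            fit_multislice([a, b], [g_a, g_b], FactorParams(r=2, n_cluster=1, max_iter=5))

    def test_duplicated_slices_converge_to_symmetric_patterns(self):
        ds, _ = spanmf.make_layered_dataset(n_side=15, r_true=4, p=60,
                                            n_background=12, noise_sd=0.2, seed=0)
        g = build_graph(ds)
        params = FactorParams(r=5, n_cluster=4, max_iter=300, tol=1e-8, seed=0)
        model = fit_multislice([ds, ds], [g, g], params)
        W1, W2 = model.W_list
        assert np.linalg.norm(W1 - W2) / np.linalg.norm(W1) < 0.05

    def test_summed_objective_non_increasing(self, rng):
        a = random_dataset(rng, n=18, p=7)
        b = random_dataset(rng, n=22, p=7)
        b.feature_ids = list(a.feature_ids)
        model = fit_multislice(
            [a, b], [build_graph(a, lam=2.0), build_graph(b, lam=2.0)],
            FactorParams(r=3, n_cluster=2, max_iter=60, seed=3),
        )
        totals = model.objective_trace[:, 0]
        assert np.all(np.diff(totals) <= np.abs(totals[:-1]) * 1e-9)
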