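"""PLSR fitting, component selection, bootstrap inference, network, hubs."""

import numpy as np
import pytest

from iphdnet import (
    build_histone_phospho_network,
    coefficient_pvalues,
    find_hubs,
    fit_plsr,
    select_components,
    simulate_plsr_system,
)
from iphdnet.plsr_net import HistonePhosphoEdge, benjamini_hochberg


def ols_oracle(X, Y):
    """Normal-equations least squares on centered data (independent check)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    return np.linalg.solve(Xc.T @ Xc, Xc.T @ Yc)


class TestFitPlsr:
    def test_univariate_noiseless_slope(self, rng):
        x = rng.normal(size=(30, 1))
        y = 2.0 * x
        fit = fit_plsr(x, y, n_components=1)
        assert fit.B[0, 0] == pytest.approx(2.0, abs=1e-8)

    def test_full_rank_matches_least_squares_oracle(self, rng):
        X = rng.normal(size=(50, 10))
        B0 = rng.normal(size=(10, 5))
        Y = X @ B0
        fit = fit_plsr(X, Y, n_components=10)
        np.testing.assert_allclose(fit.B, ols_oracle(X, Y), atol=1e-6)
        np.testing.assert_allclose(fit.predict(X), Y, atol=1e-6)

    def test_component_bounds_enforced(self, rng):
        X = rng.normal(size=(10, 4))
        Y = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            fit_plsr(X, Y, n_components=0)
        with pytest.raises(ValueError):
            fit_plsr(X, Y, n_components=5)

    def test_constant_predictor_dropped_with_warning(self, rng):
        X = rng.normal(size=(20, 4))
        X[:, 2] = 7.0
        Y = rng.normal(size=(20, 2))
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_plsr(X, Y, n_components=2, predictor_ids=list("abcd"))
        assert np.all(fit.B[2] == 0.0)


class TestSelectComponents:
    def test_rank_one_noiseless_selects_one(self, rng):
        u = rng.normal(size=(30, 1))
        X = u @ rng.normal(size=(1, 6)) + 1e-9 * rng.normal(size=(30, 6))
        Y = u @ rng.normal(size=(1, 3))
        best, press = select_components(X, Y, max_components=5, n_folds=5)
        assert best == 1

    def test_pure_noise_does_not_prefer_large_models(self, rng):
        X = rng.normal(size=(30, 6))
        Y = rng.normal(size=(30, 3))
        best, press = select_components(X, Y, max_components=5, n_folds=5)
        assert press[best] >= press[1] * 0.99

    def test_planted_three_component_system(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            T = r.normal(size=(40, 3))
            X = T @ r.normal(size=(3, 8)) + 0.05 * r.normal(size=(40, 8))
            Y = T @ r.normal(size=(3, 4)) + 0.05 * r.normal(size=(40, 4))
            best, _ = select_components(X, Y, max_components=6, n_folds=5)
            hits += best == 3
        assert hits >= 8

    def test_too_many_folds_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        Y = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            select_components(X, Y, n_folds=6)


class TestCoefficientPvalues:
    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(25, 5))
        Y = rng.normal(size=(25, 3))
        f1 = coefficient_pvalues(fit_plsr(X, Y, 2), X, Y, n_boot=50, seed=9)
        f2 = coefficient_pvalues(fit_plsr(X, Y, 2), X, Y, n_boot=50, seed=9)
        np.testing.assert_array_equal(f1.p_value, f2.p_value)

    def test_planted_signal_detected_null_retained(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 10))
        B = np.zeros((10, 5))
        B[3, 2] = 1.0
        noise_sd = np.sqrt((X @ B).var(axis=0).max() / 10.0)  # SNR 10
        Y = X @ B + rng.normal(0, noise_sd, size=(40, 5))
        fit = fit_plsr(X, Y, n_components=3)
        fit = coefficient_pvalues(fit, X, Y, n_boot=2000, seed=7)
        assert fit.p_value[3, 2] < 1e-4
        null = np.delete(fit.p_value.ravel(), np.ravel_multi_index((3, 2), (10, 5)))
        assert (null > 1e-4).mean() >= 0.95

    def test_tstat_sign_matches_coefficient(self, rng):
        X = rng.normal(size=(30, 6))
        Y = X @ rng.normal(size=(6, 3)) + 0.3 * rng.normal(size=(30, 3))
        fit = coefficient_pvalues(fit_plsr(X, Y, 4), X, Y, n_boot=100, seed=1)
        nz = fit.t_stat != 0
        assert np.all(np.sign(fit.t_stat[nz]) == np.sign(fit.B[nz]))
        assert (fit.se >= 0).all()
        assert ((fit.p_value >= 0) & (fit.p_value <= 1)).all()


class TestNetwork:
    def _fit_with_p(self, p):
        B = np.array([[0.5, -0.3], [0.2, 0.9]])
        fit = fit_plsr(
            np.random.default_rng(0).normal(size=(10, 2)),
            np.random.default_rng(1).normal(size=(10, 2)),
            n_components=1,
            predictor_ids=["pA", "pB"],
            response_ids=["h1", "h2"],
        )
        fit.B = B
        fit.p_value = np.asarray(p, dtype=float)
        return fit

    def test_threshold_rule(self):
        fit = self._fit_with_p([[5e-5, 1.0], [1.0, 1.0]])
        edges = build_histone_phospho_network(fit, alpha=1e-4)
        assert edges == {HistonePhosphoEdge("pA", "h1", 0.5, 1, 5e-5)}

    def test_all_insignificant_gives_empty_network(self):
        fit = self._fit_with_p(np.ones((2, 2)))
        assert build_histone_phospho_network(fit, alpha=1e-4) == set()

    def test_negative_coefficient_sign_and_weight(self):
        fit = self._fit_with_p([[1.0, 5e-5], [1.0, 1.0]])
        (edge,) = build_histone_phospho_network(fit, alpha=1e-4)
        assert edge.sign == -1 and edge.weight == pytest.approx(0.3)

    def test_edge_count_monotone_in_alpha(self, rng):
        X = rng.normal(size=(30, 8))
        Y = X @ (rng.random((8, 5)) < 0.3) * 1.0 + 0.2 * rng.normal(size=(30, 5))
        fit = coefficient_pvalues(fit_plsr(X, Y, 5), X, Y, n_boot=200, seed=3)
        counts = [
            len(build_histone_phospho_network(fit, alpha=a))
            for a in (1e-1, 1e-2, 1e-3, 1e-4)
        ]
        assert counts == sorted(counts, reverse=True)


class TestFindHubs:
    def test_star_graph_center_first(self):
        edges = {HistonePhosphoEdge(f"p{i}", "H", 1.0, 1, 1e-5) for i in range(4)}
        (top, degree), *_ = find_hubs(edges, top_n=1)
        assert top == "H" and degree == 4

    def test_lexicographic_tie_break(self):
        edges = {
            HistonePhosphoEdge("B", "h1", 1.0, 1, 1e-5),
            HistonePhosphoEdge("B", "h2", 1.0, 1, 1e-5),
            HistonePhosphoEdge("A", "h1", 1.0, 1, 1e-5),
            HistonePhosphoEdge("A", "h2", 1.0, 1, 1e-5),
        }
        ranked = find_hubs(edges, top_n=4)
        assert [n for n, _ in ranked] == ["A", "B", "h1", "h2"]

    def test_agrees_with_brute_force_recount(self, rng):
        edges = set()
        while len(edges) < 15:
            edges.add(
                HistonePhosphoEdge(
                    f"p{rng.integers(6)}", f"h{rng.integers(6)}", 1.0, 1, 1e-5
                )
            )
        ranked = dict(find_hubs(edges, top_n=100))
        for node, deg in ranked.items():
            manual = sum(1 for e in edges if node in (e.phosphoprotein, e.histone))
            assert deg == manual

    def test_empty_edges_rejected(self):
        with pytest.raises(ValueError):
            find_hubs(set())


def test_benjamini_hochberg_monotone_and_ge_p(rng):
    p = rng.random((6, 4))
    q = benjamini_hochberg(p)
    assert (q >= p - 1e-12).all()
    order_p = np.argsort(p.ravel())
    assert np.all(np.diff(q.ravel()[order_p]) >= -1e-12)


def test_edge_recovery_on_planted_sparse_system():
    """Planted 5%-density coefficient map at n=60: significant-edge F1 >= 0.8
    at alpha 1e-3 (small version of the full benchmark for speed)."""
    X, Y, B0 = simulate_plsr_system(
        n_samples=60, n_predictors=40, n_responses=30, seed=4
    )
    best, _ = select_components(X, Y, max_components=40, n_folds=5)
    fit = fit_plsr(X, Y, n_components=best)
    fit = coefficient_pvalues(fit, X, Y, n_boot=300, seed=4)
    pred = fit.p_value < 1e-3
    true = B0 != 0
    tp = (pred & true).sum()
    prec = tp / max(pred.sum(), 1)
    rec = tp / true.sum()
    assert 2 * prec * rec / (prec + rec) >= 0.8
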