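"""Weighted graph metrics vs. brute-force oracles; null models; AUC."""
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirsnet.netmetrics import (
    ThresholdGrid,
    auc,
    degree_check,
    normalize_and_smallworld,
    random_reference,
    sparsity_range,
    threshold_graph,
    weighted_metrics,
)
from tests.conftest import random_connected_weighted_graph


# ---------------------------------------------------------------------------
# independent brute-force oracles (exhaustive enumeration, small graphs only)


def oracle_shortest_paths(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest 1/w path lengths by enumerating simple paths."""
    n = weights.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)

    def visit(node, target, seen, length):
        if node == target:
            dist[start, target] = min(dist[start, target], length)
            return
        for nxt in range(n):
            if weights[node, nxt] > 0 and nxt not in seen:
                visit(nxt, target, seen | {nxt}, length + 1.0 / weights[node, nxt])

    for start in range(n):
        for target in range(n):
            if start != target:
                visit(start, target, {start}, 0.0)
    return dist


def oracle_clustering(weights: np.ndarray) -> np.ndarray:
    """Geometric-mean weighted clustering, written as an explicit triple loop."""
    n = weights.shape[0]
    wmax = weights.max()
    out = np.zeros(n)
    if wmax == 0:
        return out
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        total = 0.0
        for j in nbrs:
            for h in nbrs:
                if j != h and weights[j, h] > 0:
                    total += (
                        (weights[i, j] / wmax) * (weights[i, h] / wmax) * (weights[j, h] / wmax)
                    ) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def oracle_efficiency(weights: np.ndarray) -> float:
    n = weights.shape[0]
    if n < 2:
        return 0.0
    d = oracle_shortest_paths(weights)
    vals = [
        (1.0 / d[i, j] if np.isfinite(d[i, j]) and d[i, j] > 0 else 0.0)
        for i in range(n)
        for j in range(n)
        if i != j
    ]
    return float(np.mean(vals))


def oracle_metrics(weights: np.ndarray) -> dict:
    n = weights.shape[0]
    d = oracle_shortest_paths(weights)
    finite = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    gamma = oracle_clustering(weights)
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        if len(nbrs) >= 2:
            eloc[i] = oracle_efficiency(weights[np.ix_(nbrs, nbrs)])
    return {
        "gamma": float(np.mean(gamma)),
        "eloc": float(np.mean(eloc)),
        "lambda": float(np.mean(finite)),
        "eglob": oracle_efficiency(weights),
    }


# ---------------------------------------------------------------------------


class TestThresholdGraph:
    def test_all_below_threshold_empty(self):
        b = np.full((5, 5), 0.1)
        np.fill_diagonal(b, 0)
        assert not threshold_graph(b, 0.17).any()

    def test_negative_values_keep_absolute_weight(self):
        b = np.zeros((3, 3))
        b[0, 1] = b[1, 0] = -0.5
        w = threshold_graph(b, 0.3)
        assert w[0, 1] == 0.5

    def test_low_threshold_limit_keeps_everything(self, rng):
        b = rng.uniform(0.2, 0.8, (6, 6))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        w = threshold_graph(b, 0.01)
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(w[off], np.abs(b[off]))

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            threshold_graph(np.zeros((3, 3)), 0.0)

    def test_r_scale_back_transforms_before_thresholding(self):
        b = np.zeros((3, 3))
        b[0, 1] = b[1, 0] = 0.35  # z scale; tanh(0.35) ~ 0.336
        assert threshold_graph(b, 0.34, scale="z")[0, 1] == 0.35
        assert threshold_graph(b, 0.34, scale="r")[0, 1] == 0.0
        assert threshold_graph(b, 0.3, scale="r")[0, 1] == pytest.approx(np.tanh(0.35))


class TestDegreeCheck:
    @pytest.mark.parametrize(
        "builder,min_deg,k_ok",
        [
            (lambda: 1 - np.eye(4), 3, True),  # complete K4
            (lambda: np.diag([0.0] * 5), 0, False),  # edgeless: isolated nodes
            (
                lambda: np.diag(np.ones(4), 1) + np.diag(np.ones(4), -1),  # path P5
                1,
                True,
            ),
        ],
    )
    def test_degree_summaries(self, builder, min_deg, k_ok):
        d = degree_check(builder())
        assert d["min_degree"] == min_deg
        assert d["k_ge_1"] is k_ok

    def test_single_isolated_node_fails_k(self):
        w = 1 - np.eye(4)
        w[3, :] = w[:, 3] = 0
        assert not degree_check(w)["k_ge_1"]


class TestWeightedMetrics:
    def test_complete_unit_k4(self):
        m = weighted_metrics(1 - np.eye(4))
        assert m["gamma"] == pytest.approx(1.0, abs=1e-12)
        assert m["lambda"] == pytest.approx(1.0, abs=1e-12)
        assert m["eglob"] == pytest.approx(1.0, abs=1e-12)

    def test_path_p3_closed_form(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        m = weighted_metrics(w)
        assert m["eglob"] == pytest.approx(5.0 / 6.0, abs=1e-12)
        assert m["lambda"] == pytest.approx(4.0 / 3.0, abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_graphs(self, rng):
        """Exhaustive-enumeration oracle agreement on small random graphs."""
        for _ in range(20):
            n = int(rng.integers(4, 8))
            w = random_connected_weighted_graph(rng, n)
            got = weighted_metrics(w)
            want = oracle_metrics(w)
            for key in ("gamma", "eloc", "lambda", "eglob"):
                assert got[key] == pytest.approx(want[key], abs=1e-12), key

    def test_empty_graph_undefined(self):
        assert weighted_metrics(np.zeros((4, 4))) is None

    def test_hemispheric_means_on_full_graph(self, rng):
        w = random_connected_weighted_graph(rng, 6)
        hemi = np.array(["L", "L", "L", "R", "R", "R"])
        m = weighted_metrics(w, hemisphere=hemi)
        assert m["gamma_L"] == pytest.approx(np.mean(m["gamma_nodal"][:3]))
        assert m["eloc_R"] == pytest.approx(np.mean(m["eloc_nodal"][3:]))
        sub = weighted_metrics(w, hemisphere=hemi, hemisphere_subgraphs=True)
        left_only = weighted_metrics(w[np.ix_(range(3), range(3))])
        expect = left_only["gamma"] if left_only else np.nan
        assert sub["gamma_L"] == pytest.approx(expect, nan_ok=True)


class TestRandomReference:
    def test_degree_sequence_and_weights_preserved(self, rng):
        w = random_connected_weighted_graph(rng, 12)
        for ref in random_reference(w, n=5, seed=3):
            np.testing.assert_array_equal((ref > 0).sum(0), (w > 0).sum(0))
            np.testing.assert_allclose(np.sort(ref[ref > 0]), np.sort(w[w > 0]))
            np.testing.assert_allclose(ref, ref.T)

    def test_ring_lattice_clustering_drops_under_rewiring(self):
        """Small-world regime: the lattice has high clustering that random
        rewiring destroys."""
        n = 20
        w = np.zeros((n, n))
        for i in range(n):
            for step in (1, 2):
                j = (i + step) % n
                w[i, j] = w[j, i] = 1.0
        base = weighted_metrics(w)["gamma"]
        refs = random_reference(w, n=20, seed=0)
        rewired = np.mean([weighted_metrics(r)["gamma"] for r in refs])
        assert rewired < base

    def test_determinism(self, rng):
        w = random_connected_weighted_graph(rng, 10)
        a = random_reference(w, n=3, seed=7)
        b = random_reference(w, n=3, seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestNormalization:
    def test_identity_when_raw_equals_null(self):
        raw = {k: 1.7 for k in ("gamma", "gamma_L", "gamma_R", "eloc", "eloc_L", "eloc_R", "lambda", "eglob")}
        norm = normalize_and_smallworld(raw, dict(raw))
        assert norm["gamma"] == pytest.approx(1.0)
        assert norm["sigma"] == pytest.approx(1.0)

    def test_sigma_is_quotient(self):
        raw = {"gamma": 2.0, "lambda": 1.0, "eglob": 1.0, "eloc": 1.0,
               "gamma_L": 2.0, "gamma_R": 2.0, "eloc_L": 1.0, "eloc_R": 1.0}
        m_rand = {k: 1.0 for k in raw}
        norm = normalize_and_smallworld(raw, m_rand)
        assert norm["sigma"] == pytest.approx(2.0)
        assert norm["sigma"] == pytest.approx(norm["gamma"] / norm["lambda"])

    def test_nonpositive_null_marks_invalid(self):
        raw = {"gamma": 1.0, "lambda": 1.0, "eglob": 1.0, "eloc": 1.0,
               "gamma_L": 1.0, "gamma_R": 1.0, "eloc_L": 1.0, "eloc_R": 1.0}
        m_rand = dict(raw, gamma=0.0)
        assert np.isnan(normalize_and_smallworld(raw, m_rand)["gamma"])


class TestAUC:
    def test_constant_profile_closed_form(self):
        grid = ThresholdGrid()
        assert auc(np.ones(grid.taus.size), grid.taus) == pytest.approx(0.16, abs=1e-12)

    def test_linear_ramp_triangle_area(self):
        grid = ThresholdGrid()
        ramp = np.linspace(0, 1, grid.taus.size)
        assert auc(ramp, grid.taus) == pytest.approx(0.08, abs=1e-12)

    def test_matches_independent_trapezoid_sum(self, rng):
        grid = ThresholdGrid()
        y = rng.uniform(0.5, 2.0, grid.taus.size)
        t = grid.taus
        manual = sum(
            0.5 * (y[i] + y[i + 1]) * (t[i + 1] - t[i]) for i in range(t.size - 1)
        )
        assert auc(y, t) == pytest.approx(manual, abs=1e-12)

    def test_too_few_valid_points_missing(self):
        vals = np.full(17, np.nan)
        vals[3] = 1.0
        assert np.isnan(auc(vals, ThresholdGrid().taus))


class TestSparsityRange:
    def test_modular_cohort_validates_full_default_grid(self, rng):
        from nirsnet.simcohort import modular_network

        mats = [modular_network(rng) for _ in range(3)]
        grid, report = sparsity_range(mats, ThresholdGrid(), n_random=8, seed=0)
        assert grid.tau1 == pytest.approx(0.01)
        assert grid.tau_m == pytest.approx(0.17)
        assert report.pass_all.all()

    def test_weak_networks_truncate_range_at_degree_break(self, rng):
        """When weights die out above some tau, isolated nodes break the
        K >= 1 criterion and the validated range stops before it."""
        from nirsnet.simcohort import modular_network

        mats = [
            modular_network(rng, within=(0.05, 0.12), bridge=(0.06, 0.12))
            for _ in range(3)
        ]
        grid, report = sparsity_range(mats, ThresholdGrid(), n_random=6, seed=0)
        assert grid.tau1 == pytest.approx(0.01)
        assert grid.tau_m < 0.17
        first_fail = report.loc[~report.pass_all, "tau"].min()
        assert grid.tau_m < first_fail

    def test_all_empty_graphs_error(self):
        mats = [np.zeros((6, 6)) for _ in range(2)]
        with pytest.raises(ValueError):
            sparsity_range(mats, ThresholdGrid(), n_random=3, seed=0)


class TestMonotonicity:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_edge_count_and_efficiency_nonincreasing_in_tau(self, seed):
        rng = np.random.default_rng(seed)
        b = rng.uniform(-0.6, 0.6, (10, 10))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        taus = ThresholdGrid(0.02, 0.3, 0.04).taus
        prev_edges = np.inf
        prev_eff = np.inf
        for tau in taus:
            w = threshold_graph(b, tau)
            edges = int((w > 0).sum()) // 2
            assert edges <= prev_edges
            m = weighted_metrics(w)
            eff = m["eglob"] if m is not None else 0.0
            assert eff <= prev_eff + 1e-12
            prev_edges, prev_eff = edges, eff
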