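"""Weighted graph metrics over a sparsity range, normalized by null models.

Stage-B task matrices are thresholded on absolute value over a grid of
sparsity thresholds tau (default 0.01..0.17, step 0.01; edges keep their
absolute weight). Per threshold the segregation metrics (weighted
clustering gamma, local efficiency E_local; also split by hemisphere) and
integration metrics (characteristic path length lambda on 1/w lengths,
global efficiency E_global) are computed, normalized by the group-pooled
mean of the same metric over degree-preserving random reference graphs
(M_rand), combined into the small-world index sigma = gamma_norm /
lambda_norm, and finally integrated over the validated threshold range into
per-subject AUC summaries.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FCMatrix, Montage

__all__ = [
    "ThresholdGrid",
    "GLOBAL_METRICS",
    "threshold_graph",
    "degree_check",
    "weighted_metrics",
    "random_reference",
    "normalize_and_smallworld",
    "sparsity_range",
    "auc",
    "cohort_network_analysis",
]

GLOBAL_METRICS = ("gamma", "gamma_L", "gamma_R", "eloc", "eloc_L", "eloc_R", "lambda", "eglob")


@dataclass(frozen=True)
class ThresholdGrid:
    """Inclusive sparsity-threshold grid [tau1, tau_m] with step dtau."""

    tau1: float = 0.01
    tau_m: float = 0.17
    dtau: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.tau1 < self.tau_m < 1):
            raise ValueError("need 0 < tau1 < tau_m < 1")
        if self.dtau <= 0:
            raise ValueError("dtau must be positive")

    @property
    def taus(self) -> np.ndarray:
        n = int(round((self.tau_m - self.tau1) / self.dtau)) + 1
        return np.linspace(self.tau1, self.tau_m, n)


def threshold_graph(
    values: np.ndarray | FCMatrix, tau: float, scale: str = "z"
) -> np.ndarray:
    """Undirected weighted graph: w_ij = |b_ij| when >= tau, else 0.

    ``scale='z'`` thresholds the stage-B values as they are (Fisher-z);
    ``scale='r'`` back-transforms to correlations (tanh) first.
    """
    if isinstance(values, FCMatrix):
        values = values.values
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    if scale not in ("z", "r"):
        raise ValueError("scale must be 'z' or 'r'")
    vals = np.asarray(values, dtype=float)
    if scale == "r":
        vals = np.tanh(vals)
    w = np.abs(vals)
    w[w < tau] = 0.0
    np.fill_diagonal(w, 0.0)
    return w


def degree_check(weights: np.ndarray) -> dict:
    """Binary degree summary: min, mean, and the K >= 1 connectedness flag."""
    deg = (weights > 0).sum(axis=1)
    return {
        "degree": deg,
        "min_degree": int(deg.min()),
        "mean_degree": float(deg.mean()),
        "k_ge_1": bool(deg.min() >= 1),
    }


def _shortest_paths(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths on l_ij = 1/w_ij (inf when absent).

    Floyd-Warshall as vectorized min-plus updates; for the <=50-node graphs
    here this beats sparse-graph routines on call overhead.
    """
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / weights, np.inf)
    np.fill_diagonal(lengths, 0.0)
    D = lengths.copy()
    with np.errstate(invalid="ignore"):
        for k in range(D.shape[0]):
            np.minimum(D, D[:, k, None] + D[None, k, :], out=D)
    return D


def _clustering_onnela(weights: np.ndarray) -> np.ndarray:
    """Weighted clustering via geometric-mean triangle intensity.

    Weights are scaled by the largest weight in the graph; nodes with fewer
    than two neighbors get 0.
    """
    wmax = weights.max()
    if wmax == 0:
        return np.zeros(weights.shape[0])
    w = (weights / wmax) ** (1.0 / 3.0)
    cyc = np.diag(w @ w @ w)  # 2 * sum of triangle intensities per node
    deg = (weights > 0).sum(axis=1)
    denom = deg * (deg - 1)
    out = np.zeros(weights.shape[0])
    ok = denom > 0
    out[ok] = cyc[ok] / denom[ok]
    return out


def _efficiency_from_distances(dist: np.ndarray) -> float:
    """Mean inverse distance over ordered off-diagonal pairs (0 if none)."""
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist), 1.0 / np.where(dist > 0, dist, np.inf), 0.0)
    return float(inv[off].mean())


def weighted_metrics(
    weights: np.ndarray,
    hemisphere: np.ndarray | None = None,
    hemisphere_subgraphs: bool = False,
) -> dict | None:
    """gamma / E_local (nodal + hemispheric means) and lambda / E_global.

    Shortest paths use lengths 1/w; lambda is the mean finite shortest path
    over ordered pairs (disconnected pairs excluded), E_global the mean of
    1/d with disconnected pairs contributing 0, E_local the global
    efficiency of each node's neighborhood subgraph. Returns None for an
    edgeless graph (metrics undefined at that threshold).

    Hemispheric summaries average nodal values over each hemisphere's
    channels on the full graph (cross-hemispheric neighborhoods count);
    with ``hemisphere_subgraphs=True`` they are recomputed on the
    hemisphere-induced subgraphs instead.
    """
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    if not (weights > 0).any():
        return None
    dist = _shortest_paths(weights)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    lam = float(dist[finite].mean()) if finite.any() else np.inf
    eglob = _efficiency_from_distances(dist)
    gamma_nodal = _clustering_onnela(weights)
    eloc_nodal = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(weights[i] > 0)
        if nbrs.size < 2:
            continue
        sub = weights[np.ix_(nbrs, nbrs)]
        eloc_nodal[i] = _efficiency_from_distances(_shortest_paths(sub))
    out = {
        "gamma_nodal": gamma_nodal,
        "eloc_nodal": eloc_nodal,
        "gamma": float(gamma_nodal.mean()),
        "eloc": float(eloc_nodal.mean()),
        "lambda": lam,
        "eglob": eglob,
    }
    if hemisphere is not None:
        hemisphere = np.asarray(hemisphere)
        for h in ("L", "R"):
            idx = hemisphere == h
            if not idx.any():
                out[f"gamma_{h}"] = out[f"eloc_{h}"] = np.nan
            elif hemisphere_subgraphs:
                sub = weighted_metrics(weights[np.ix_(idx, idx)])
                out[f"gamma_{h}"] = sub["gamma"] if sub else np.nan
                out[f"eloc_{h}"] = sub["eloc"] if sub else np.nan
            else:
                out[f"gamma_{h}"] = float(gamma_nodal[idx].mean())
                out[f"eloc_{h}"] = float(eloc_nodal[idx].mean())
    return out


def random_reference(
    weights: np.ndarray,
    n: int = 100,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> list[np.ndarray]:
    """Degree-preserving rewired null graphs with permuted weight multiset.

    Maslov-Sneppen double-edge swaps on the binary structure (``swaps_per_edge``
    attempted swaps per edge), then the original weight multiset is
    reassigned to the rewired edges in random order. With too few edges to
    swap, copies of the original graph are returned with a warning.
    """
    import warnings

    rng = np.random.default_rng(seed)
    iu = np.triu_indices_from(weights, k=1)
    present = weights[iu] > 0
    edge_weights = weights[iu][present]
    edges0 = np.array([(i, j) for i, j, p in zip(iu[0], iu[1], present) if p])
    m = len(edges0)
    if m < 2:
        warnings.warn("too few edges for degree-preserving rewiring; returning copies")
        return [weights.copy() for _ in range(n)]
    out = []
    n_nodes = weights.shape[0]
    for _ in range(n):
        edges = {tuple(e) for e in edges0}
        edge_list = list(edges)
        n_attempts = swaps_per_edge * m
        ks = rng.integers(0, m, size=(n_attempts, 2))
        flips = rng.random(n_attempts) < 0.5
        for (k1, k2), flip in zip(ks, flips):
            if k1 == k2:
                continue
            a, b = edge_list[k1]
            c, d = edge_list[k2]
            if flip:
                c, d = d, c
            if a == c or a == d or b == c or b == d:
                continue
            new1 = (min(a, d), max(a, d))
            new2 = (min(c, b), max(c, b))
            if new1 in edges or new2 in edges:
                continue
            edges.discard((a, b))
            edges.discard((c, d))
            edges.add(new1)
            edges.add(new2)
            edge_list[k1] = new1
            edge_list[k2] = new2
        perm = rng.permutation(m)
        w = np.zeros((n_nodes, n_nodes))
        for (i, j), wv in zip(edge_list, edge_weights[perm]):
            w[i, j] = w[j, i] = wv
        out.append(w)
    return out


def normalize_and_smallworld(raw: dict, m_rand: dict) -> dict:
    """Divide each metric by its M_rand; sigma = gamma_norm / lambda_norm.

    Metrics with a nonpositive or undefined M_rand come back as NaN
    (invalid at that threshold).
    """
    norm = {}
    for key in GLOBAL_METRICS:
        mr = m_rand.get(key, np.nan)
        rv = raw.get(key, np.nan)
        norm[key] = rv / mr if np.isfinite(mr) and mr > 0 and np.isfinite(rv) else np.nan
    norm["sigma"] = (
        norm["gamma"] / norm["lambda"]
        if np.isfinite(norm["gamma"]) and np.isfinite(norm["lambda"]) and norm["lambda"] != 0
        else np.nan
    )
    return norm


def auc(values: np.ndarray, taus: np.ndarray) -> float:
    """Trapezoidal integral of a metric profile over the threshold grid."""
    values = np.asarray(values, dtype=float)
    taus = np.asarray(taus, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < 2:
        return np.nan
    return float(np.trapezoid(values[ok], taus[ok]))


def _cohort_raw_profiles(matrices, taus, hemisphere):
    """Raw metric profiles and degree summaries per subject per tau."""
    profiles = []
    for m in matrices:
        vals = m.values if isinstance(m, FCMatrix) else m
        per_tau = []
        for tau in taus:
            w = threshold_graph(vals, tau)
            met = weighted_metrics(w, hemisphere=hemisphere)
            deg = degree_check(w)
            per_tau.append((met, deg))
        profiles.append(per_tau)
    return profiles


def _mrand_profiles(matrices, taus, hemisphere, n_random, seed, groups=None):
    """Group-pooled M_rand per metric per tau.

    Null metrics are averaged over the ``n_random`` reference graphs of
    every subject of a group (pooled, matching the normalization
    convention); with ``groups`` None all subjects form one pool.
    """
    groups = ["all"] * len(matrices) if groups is None else list(groups)
    rng = np.random.default_rng(seed)
    pools: dict[str, list[list[dict]]] = {}
    for m, g in zip(matrices, groups):
        vals = m.values if isinstance(m, FCMatrix) else m
        per_tau = []
        for tau in taus:
            w = threshold_graph(vals, tau)
            entries = []
            if (w > 0).any():
                refs = random_reference(w, n=n_random, seed=int(rng.integers(2**31)))
                for ref in refs:
                    met = weighted_metrics(ref, hemisphere=hemisphere)
                    if met is not None:
                        entries.append(met)
            per_tau.append(entries)
        pools.setdefault(g, []).append(per_tau)
    m_rand: dict[str, list[dict]] = {}
    for g, subject_lists in pools.items():
        per_tau_out = []
        for t_idx in range(len(taus)):
            pooled: dict[str, list[float]] = {k: [] for k in GLOBAL_METRICS}
            for subj in subject_lists:
                for met in subj[t_idx]:
                    for k in GLOBAL_METRICS:
                        v = met.get(k, np.nan)
                        if np.isfinite(v):
                            pooled[k].append(v)
            per_tau_out.append(
                {k: (float(np.mean(v)) if v else np.nan) for k, v in pooled.items()}
            )
        m_rand[g] = per_tau_out
    return m_rand


def sparsity_range(
    matrices,
    grid: ThresholdGrid | None = None,
    n_random: int = 100,
    seed: int = 0,
    hemisphere: np.ndarray | None = None,
    groups=None,
) -> tuple[ThresholdGrid, pd.DataFrame]:
    """Validate the threshold grid on a cohort.

    Criteria per tau (cohort means): minimal binary degree >= 1 in the
    group mean, normalized gamma > 1 and normalized lambda > 1 (for small
    networks the gamma criterion gamma > gamma_rand is the same
    inequality). The returned grid is the largest contiguous sub-grid
    passing all criteria; the report carries per-criterion flags per tau.
    Raises when no tau passes.
    """
    grid = grid or ThresholdGrid()
    taus = grid.taus
    profiles = _cohort_raw_profiles(matrices, taus, hemisphere)
    m_rand = _mrand_profiles(matrices, taus, hemisphere, n_random, seed, groups=groups)
    groups_list = ["all"] * len(matrices) if groups is None else list(groups)

    rows = []
    for t_idx, tau in enumerate(taus):
        min_degrees, gam_norm, lam_norm = [], [], []
        any_edges = False
        for subj_idx, per_tau in enumerate(profiles):
            met, deg = per_tau[t_idx]
            min_degrees.append(deg["min_degree"])
            if met is None:
                continue
            any_edges = True
            norm = normalize_and_smallworld(met, m_rand[groups_list[subj_idx]][t_idx])
            gam_norm.append(norm["gamma"])
            lam_norm.append(norm["lambda"])
        mean_min_k = float(np.mean(min_degrees))
        g = float(np.nanmean(gam_norm)) if gam_norm else np.nan
        l = float(np.nanmean(lam_norm)) if lam_norm else np.nan
        rows.append(
            {
                "tau": tau,
                "mean_min_degree": mean_min_k,
                "gamma_norm": g,
                "lambda_norm": l,
                "pass_k": mean_min_k >= 1 and any_edges,
                "pass_gamma": bool(np.isfinite(g) and g > 1),
                "pass_lambda": bool(np.isfinite(l) and l > 1),
            }
        )
    report = pd.DataFrame(rows)
    report["pass_all"] = report.pass_k & report.pass_gamma & report.pass_lambda
    if not report.pass_all.any():
        raise ValueError("no threshold satisfies the sparsity criteria")
    # largest contiguous run of passing thresholds
    best_start, best_len, cur_start, cur_len = 0, 0, None, 0
    for i, ok in enumerate(report.pass_all):
        if ok:
            if cur_start is None:
                cur_start, cur_len = i, 1
            else:
                cur_len += 1
            if cur_len > best_len:
                best_start, best_len = cur_start, cur_len
        else:
            cur_start, cur_len = None, 0
    validated = ThresholdGrid(
        tau1=float(taus[best_start]),
        tau_m=float(taus[best_start + best_len - 1]),
        dtau=grid.dtau,
    )
    return validated, report


def cohort_network_analysis(
    matrices,
    groups,
    subjects,
    montage: Montage | None = None,
    grid: ThresholdGrid | None = None,
    n_random: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject normalized metric profiles and AUC summaries.

    Returns ``(profiles, summaries)``: tidy frames with one row per
    (subject, metric, tau) holding raw, M_rand and normalized values, and
    one row per (subject, metric) holding the AUC over the grid.
    """
    grid = grid or ThresholdGrid()
    taus = grid.taus
    hemisphere = montage.hemisphere if montage is not None else None
    raw_profiles = _cohort_raw_profiles(matrices, taus, hemisphere)
    m_rand = _mrand_profiles(matrices, taus, hemisphere, n_random, seed, groups=groups)

    prof_rows, auc_rows = [], []
    metric_names = GLOBAL_METRICS + ("sigma",)
    for subj_idx, (per_tau, group, subject) in enumerate(zip(raw_profiles, groups, subjects)):
        normed = {k: [] for k in metric_names}
        for t_idx, tau in enumerate(taus):
            met, deg = per_tau[t_idx]
            mr = m_rand[group][t_idx]
            norm = (
                normalize_and_smallworld(met, mr)
                if met is not None
                else {k: np.nan for k in metric_names}
            )
            for k in metric_names:
                normed[k].append(norm[k])
                prof_rows.append(
                    {
                        "subject": subject,
                        "group": group,
                        "metric": k,
                        "tau": tau,
                        "raw": (met or {}).get(k, np.nan),
                        "m_rand": mr.get(k, np.nan) if k != "sigma" else np.nan,
                        "normalized": norm[k],
                        "mean_min_degree": deg["min_degree"],
                    }
                )
        for k in metric_names:
            auc_rows.append(
                {
                    "subject": subject,
                    "group": group,
                    "metric": k,
                    "auc": auc(np.asarray(normed[k]), taus),
                }
            )
    return pd.DataFrame(prof_rows), pd.DataFrame(auc_rows)
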