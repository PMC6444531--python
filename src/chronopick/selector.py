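"""Exact selection of M time points by fixed-edge-count shortest path.

The N grid times become nodes 1..N of a DAG with a virtual start node 0 and
end node N+1.  The weight of the forward edge i→k is the Monte-Carlo L²
reconstruction error over [τ_i, τ_k] when only τ_i and τ_k are sampled
(start/end edges use constant extrapolation from the single available
point).  The optimal M-point selection is the minimal-cost start→end path
with exactly M+1 edges, found by a modified Viterbi recursion
Θ(j, k) = min_{i<j} [Θ(i, k−1) + edge(i, j)]; a brute-force enumerator with
the identical tie-break (lexicographically smallest index sequence) serves
as an oracle in tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Optional

import numpy as np

from .curve_io import Selection, TimeGrid
from .curve_distribution import SampledCurves
from .objectives import ObjectiveSpec, _criterion_curves, interpolate_subset

__all__ = ["EdgeMatrix", "build_edge_matrix", "dp_select",
           "brute_force_select", "spline_select", "baseline_select"]


@dataclass
class EdgeMatrix:
    """Edge weights over nodes {0 (start), 1..N (time points), N+1 (end)}."""

    weights: np.ndarray             # (N+2, N+2); +inf off the forward cone
    times: Optional[np.ndarray] = None
    criterion: str = "f1"
    n_samples: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] < 3:
            raise ValueError("weights must be a square (N+2)x(N+2) matrix")
        fwd = np.triu(np.ones_like(w, dtype=bool), k=1)
        if np.any(w[fwd] < 0):
            raise ValueError("edge weights must be non-negative")
        w = np.where(fwd, w, np.inf)
        self.weights = w

    @property
    def n_times(self) -> int:
        return int(self.weights.shape[0] - 2)


def build_edge_matrix(
    samples: SampledCurves,
    spec: ObjectiveSpec,
    pin_endpoints: bool = False,
) -> EdgeMatrix:
    """Evaluate every forward edge weight on the sample curves.

    Edge costs are the *mean* over the J samples (a monotone transform of
    the summed error; the argmin is unchanged).  ``pin_endpoints`` forces
    the first and last grid times into every selection by making all other
    start/end edges infinite.
    """
    t = samples.grid.times
    N = t.size
    curves = _criterion_curves(samples, spec)
    J = curves.shape[0]
    if spec.criterion == "f3" and not spec.cv_target and J < 3:
        raise ValueError("f3 needs at least 3 samples")
    W = np.full((N + 2, N + 2), np.inf)

    tw = np.empty(N)                      # per-point trapezoid half-widths
    dts = np.diff(t)
    for i in range(N + 1):
        for k in range(i + 1, N + 2):
            if i == 0 and k == N + 1:
                continue                  # a path always visits >= 1 point
            g0 = i - 1 if i >= 1 else 0
            g1 = k - 1 if k <= N else N - 1
            tseg = t[g0:g1 + 1]
            seg = curves[:, g0:g1 + 1]
            if i >= 1 and k <= N:
                lam = (tseg - t[g0]) / (t[g1] - t[g0])
                recon = seg[:, :1] * (1.0 - lam) + seg[:, -1:] * lam
            elif i == 0:                  # only τ_k sampled; constant left
                recon = np.repeat(seg[:, -1:], tseg.size, axis=1)
            else:                         # only τ_i sampled; constant right
                recon = np.repeat(seg[:, :1], tseg.size, axis=1)
            z = seg - recon
            if spec.criterion == "f3" and not spec.cv_target:
                var = z.var(axis=0, ddof=1)
                vmax = float(var.max(initial=0.0))
                if vmax > 0:
                    z = z / np.sqrt(np.maximum(var, spec.variance_floor * vmax))
            W[i, k] = float(np.mean(np.trapezoid(z * z, tseg, axis=-1)))
    if pin_endpoints:
        W[0, 2:N + 1] = np.inf
        W[1:N, N + 1] = np.inf
    return EdgeMatrix(weights=W, times=t.copy(), criterion=spec.criterion,
                      n_samples=J, seed=spec.seed)


def _selection_from_nodes(edges: EdgeMatrix, nodes: list[int], cost: float) -> Selection:
    times = None
    if edges.times is not None:
        times = tuple(float(edges.times[i - 1]) for i in nodes)
    return Selection(
        indices=tuple(nodes), times=times, criterion=edges.criterion,
        objective_estimate=float(cost), n_samples=edges.n_samples,
        seed=edges.seed,
    )


def _backward_table(W: np.ndarray, K: int) -> np.ndarray:
    """B[i, r] = min cost from node i to the end node using exactly r edges."""
    n_nodes = W.shape[0]
    B = np.full((n_nodes, K + 1), np.inf)
    B[n_nodes - 1, 0] = 0.0
    for r in range(1, K + 1):
        for i in range(n_nodes - 2, -1, -1):
            tot = W[i, i + 1:] + B[i + 1:, r - 1]
            if tot.size:
                B[i, r] = np.min(tot)
    return B


def dp_select(edges: EdgeMatrix, M: int) -> Selection:
    """Globally optimal M-point selection via the fixed-edge-count DP.

    Ties are broken toward the lexicographically smallest index sequence.
    """
    N = edges.n_times
    if not (1 <= M <= N):
        raise ValueError(f"M must satisfy 1 <= M <= N={N}")
    K = M + 1
    W = edges.weights
    B = _backward_table(W, K)
    cost = float(B[0, K])
    if not np.isfinite(cost):
        raise RuntimeError("no feasible path (all-inf edges?)")
    # Greedy forward traceback: smallest next node consistent with the table.
    nodes: list[int] = []
    cur, rem = 0, K
    while rem > 1:
        tot = W[cur, cur + 1:] + B[cur + 1:, rem - 1]
        nxt = cur + 1 + int(np.flatnonzero(tot == B[cur, rem])[0])
        nodes.append(nxt)
        cur, rem = nxt, rem - 1
    return _selection_from_nodes(edges, nodes, cost)


def brute_force_select(edges: EdgeMatrix, M: int) -> Selection:
    """Exact minimum by exhaustive enumeration (test oracle).

    Costs are accumulated in the same (right-fold) order as the DP so that
    agreement with :func:`dp_select` is bitwise exact.
    """
    N = edges.n_times
    if not (1 <= M <= N):
        raise ValueError(f"M must satisfy 1 <= M <= N={N}")
    if comb(N, M) > 10**6:
        raise ValueError("combinatorial bound exceeded for brute force")
    W = edges.weights
    best_cost = np.inf
    best: Optional[tuple[int, ...]] = None
    for subset in itertools.combinations(range(1, N + 1), M):
        c = W[subset[-1], N + 1]
        for a, b in zip(reversed(subset[:-1]), reversed(subset[1:])):
            c = W[a, b] + c
        c = W[0, subset[0]] + c
        if c < best_cost:
            best_cost, best = c, subset
    if best is None or not np.isfinite(best_cost):
        raise RuntimeError("no feasible subset")
    return _selection_from_nodes(edges, list(best), float(best_cost))


def baseline_select(
    N: int,
    M: int,
    strategy: str,
    seed: int = 0,
    times: Optional[np.ndarray] = None,
) -> Selection:
    """Evenly spaced or uniformly random baseline selections."""
    if not (1 <= M <= N):
        raise ValueError(f"M must satisfy 1 <= M <= N={N}")
    if strategy == "even":
        idx = np.round(np.linspace(1, N, M)).astype(int)
        for i in range(1, M):                     # dedupe by shifting right
            if idx[i] <= idx[i - 1]:
                idx[i] = idx[i - 1] + 1
        for i in range(M - 2, -1, -1):            # repair any overflow at N
            if idx[i] >= idx[i + 1]:
                idx[i] = idx[i + 1] - 1
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(np.arange(1, N + 1), size=M, replace=False))
    else:
        raise ValueError("strategy must be 'even' or 'random'")
    t = None if times is None else tuple(float(times[i - 1]) for i in idx)
    return Selection(indices=tuple(int(i) for i in idx), times=t,
                     criterion=strategy, seed=seed)


# ---------------------------------------------------------------------------
# Spline mode: history-dependent edges, forward and backward runs
# ---------------------------------------------------------------------------

def _spline_edge_cost(
    curves: np.ndarray,
    times: np.ndarray,
    history: list[int],
    i: int,
    j: int,
    spec: ObjectiveSpec,
) -> float:
    """Edge cost i→j with the spline conditioned on the recent history.

    ``history`` lists the grid nodes (1-based) already on the path up to and
    including i; the local reconstruction uses the last R+1 of them plus j.
    """
    N = times.size
    R = spec.spline_degree
    pts = [p - 1 for p in history if 1 <= p <= N]
    if j <= N:
        pts = pts[-R:] + [j - 1]
    else:
        pts = pts[-(R + 1):]
    if not pts:
        return np.inf
    g0 = i - 1 if i >= 1 else 0
    g1 = j - 1 if j <= N else N - 1
    if g1 <= g0 and not (i == 0 or j == N + 1):
        return 0.0
    recon = interpolate_subset(curves, times, pts, "spline", R)
    z = (curves - recon)[:, g0:g1 + 1]
    tseg = times[g0:g1 + 1]
    if spec.criterion == "f3" and not spec.cv_target:
        var = z.var(axis=0, ddof=1)
        vmax = float(var.max(initial=0.0))
        if vmax > 0:
            z = z / np.sqrt(np.maximum(var, spec.variance_floor * vmax))
    return float(np.mean(np.trapezoid(z * z, tseg, axis=-1)))


def _spline_dp(curves: np.ndarray, times: np.ndarray, spec: ObjectiveSpec,
               M: int) -> list[int]:
    N = times.size
    K = M + 1
    F = np.full((N + 2, K + 1), np.inf)
    pred = np.full((N + 2, K + 1), -1, dtype=int)
    F[0, 0] = 0.0

    def path_to(node: int, k: int) -> list[int]:
        out = []
        while node > 0:
            out.append(node)
            node, k = pred[node, k], k - 1
        return out[::-1]

    for k in range(1, K + 1):
        lo = 1 if k < K else N + 1
        hi = N if k < K else N + 1
        for j in range(lo, hi + 1):
            for i in range(j):
                if not np.isfinite(F[i, k - 1]):
                    continue
                if i == 0 and j == N + 1:
                    continue
                hist = path_to(i, k - 1)
                c = F[i, k - 1] + _spline_edge_cost(curves, times, hist, i, j, spec)
                if c < F[j, k]:
                    F[j, k] = c
                    pred[j, k] = i
    return path_to(N + 1, K)[:-1]


def spline_select(samples: SampledCurves, spec: ObjectiveSpec, M: int) -> Selection:
    """Approximate DP selection with spline (degree R > 1) reconstruction.

    With splines the edge cost depends on the R previous points, which are
    recovered approximately from the traceback; the DP is run once on the
    forward grid and once on the time-reversed grid.  The exact linear-mode
    DP selection is kept as a third candidate, and whichever of the three
    scores best under exact full-spline re-evaluation is returned (so spline
    mode is never worse than re-scoring the linear selection with splines).
    """
    R = spec.spline_degree
    if spec.interpolation != "spline" or R < 2:
        return dp_select(build_edge_matrix(samples, spec), M)
    if M <= R:
        raise ValueError(f"spline mode needs M > spline_degree (M={M}, R={R})")
    t = samples.grid.times
    curves = _criterion_curves(samples, spec)

    fwd_nodes = _spline_dp(curves, t, spec, M)

    t_rev = (t[-1] - t)[::-1].copy()
    rev_nodes_r = _spline_dp(curves[:, ::-1].copy(), t_rev, spec, M)
    rev_nodes = sorted(t.size + 1 - n for n in rev_nodes_r)

    linear_spec = ObjectiveSpec(
        criterion=spec.criterion, control=spec.control, J=spec.J,
        seed=spec.seed, interpolation="linear",
        variance_floor=spec.variance_floor, cv_target=spec.cv_target)
    lin_nodes = list(dp_select(build_edge_matrix(samples, linear_spec), M).indices)

    best_nodes, best_cost = None, np.inf
    for nodes in (fwd_nodes, rev_nodes, lin_nodes):
        cost = _exact_spline_score(curves, t, nodes, spec)
        if cost < best_cost:
            best_nodes, best_cost = nodes, cost
    assert best_nodes is not None
    return Selection(
        indices=tuple(best_nodes),
        times=tuple(float(t[i - 1]) for i in best_nodes),
        criterion=spec.criterion,
        objective_estimate=float(best_cost),
        n_samples=curves.shape[0],
        seed=spec.seed,
    )


def _exact_spline_score(curves: np.ndarray, times: np.ndarray,
                        nodes: list[int], spec: ObjectiveSpec) -> float:
    recon = interpolate_subset(curves, times, [n - 1 for n in nodes],
                               "spline", spec.spline_degree)
    z = curves - recon
    if spec.criterion == "f3" and not spec.cv_target:
        var = z.var(axis=0, ddof=1)
        vmax = float(var.max(initial=0.0))
        if vmax > 0:
            z = z / np.sqrt(np.maximum(var, spec.variance_floor * vmax))
    return float(np.mean(np.trapezoid(z * z, times, axis=-1)))
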