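"""Independent oracles used to validate the package's implementations.

Each oracle deliberately takes a different route from the code it
checks: generic smooth optimization instead of coordinate descent,
exhaustive path/partition enumeration instead of Dijkstra/annealing.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from sympy.utilities.iterables import multiset_partitions

SMOOTH_EPS = 1e-10


def penalized_objective(S: np.ndarray, theta: np.ndarray, lam: float) -> float:
    """log det(theta) - tr(S theta) - lam * sum_{i != j} |theta_ij|."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    off = theta - np.diag(np.diag(theta))
    return logdet - float(np.sum(S * theta)) - lam * float(np.abs(off).sum())


def brute_force_glasso(S: np.ndarray, lam: float) -> np.ndarray:
    """Maximize the penalized likelihood with a generic quasi-Newton solver.

    |x| is smoothed as sqrt(x^2 + eps^2) with tiny eps, the free
    parameters are the upper triangle including the diagonal, and
    non-PD iterates get an infinite objective so the line search
    backtracks.  Entirely independent of the coordinate-descent path.
    """
    p = S.shape[0]
    iu = np.triu_indices(p)
    off_mask = iu[0] != iu[1]

    def unpack(x):
        theta = np.zeros((p, p))
        theta[iu] = x
        theta = theta + theta.T - np.diag(np.diag(theta))
        return theta

    def fun_grad(x):
        theta = unpack(x)
        try:
            np.linalg.cholesky(theta)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(x)
        inv = np.linalg.inv(theta)
        sabs = np.sqrt(x**2 + SMOOTH_EPS)
        f = -np.linalg.slogdet(theta)[1] + float(np.sum(S * theta))
        f += 2.0 * lam * float(sabs[off_mask].sum())
        grad_mat = -inv + S
        grad = grad_mat[iu].copy()
        grad[off_mask] *= 2.0  # each off-diagonal parameter appears twice
        grad[off_mask] += 2.0 * lam * (x[off_mask] / sabs[off_mask])
        return f, grad

    x0 = np.linalg.inv(S + 1e-6 * np.eye(p))[iu]
    res = minimize(
        fun_grad, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12},
    )
    return unpack(res.x)


def shortest_path_oracle(weights: np.ndarray):
    """Exhaustive simple-path enumeration (feasible for p <= 6).

    Returns (distance matrix, closeness, betweenness) under edge length
    1/|w|, fractional betweenness credit for ties within 1e-12.
    """
    p = weights.shape[0]
    dist = np.full((p, p), np.inf)
    np.fill_diagonal(dist, 0.0)
    betw = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            best = np.inf
            best_paths = []
            others = [v for v in range(p) if v not in (s, t)]
            for k in range(len(others) + 1):
                for mids in itertools.permutations(others, k):
                    nodes = (s, *mids, t)
                    length = 0.0
                    ok = True
                    for a, b in zip(nodes[:-1], nodes[1:]):
                        w = abs(weights[a, b])
                        if w == 0.0:
                            ok = False
                            break
                        length += 1.0 / w
                    if not ok:
                        continue
                    if length < best - 1e-12:
                        best = length
                        best_paths = [nodes]
                    elif abs(length - best) <= 1e-12:
                        best_paths.append(nodes)
            dist[s, t] = dist[t, s] = best
            if best_paths:
                for nodes in best_paths:
                    for v in nodes[1:-1]:
                        betw[v] += 1.0 / len(best_paths)
    closeness = np.zeros(p)
    for i in range(p):
        row = np.delete(dist[i], i)
        closeness[i] = 0.0 if (row.size == 0 or np.isinf(row).any()) else 1.0 / row.sum()
    return dist, closeness, betw


def all_partitions(p: int):
    """Every set partition of range(p) as an assignment array."""
    for parts in multiset_partitions(list(range(p))):
        assignment = np.zeros(p, dtype=int)
        for label, block in enumerate(parts, start=1):
            for node in block:
                assignment[node] = label
        yield assignment


def exhaustive_min_energy(net, hamiltonian_fn, **params) -> float:
    """Optimal signed Potts energy by full set-partition enumeration."""
    return min(
        hamiltonian_fn(net, assignment, **params)
        for assignment in all_partitions(net.n_items)
    )


def binned_tv_distance(sample: np.ndarray, exact: np.ndarray, n_bins: int = 5) -> float:
    """Total-variation distance between two samples over exact-quantile bins."""
    edges = np.quantile(exact, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    p_exact = np.histogram(exact, bins=edges)[0] / len(exact)
    p_sample = np.histogram(sample, bins=edges)[0] / len(sample)
    return 0.5 * float(np.abs(p_exact - p_sample).sum())
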