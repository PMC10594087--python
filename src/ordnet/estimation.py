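"""Sparse partial-correlation network estimation.

An L1-penalized Gaussian likelihood (graphical lasso, diagonal
unpenalized) is fit over a descending log-spaced penalty grid and the
model minimizing the extended BIC,

    EBIC = -2 loglik + E log n + 4 gamma E log p,

is selected (``gamma=0.5`` by default).  The solver is block coordinate
descent on the covariance (per-column lasso subproblems), warm-started
along the grid.  A true adaptive-weights variant (penalty weights
``1 / |theta_hat|`` from the least-penalized fit) is available via
``penalty="adaptive"``.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._compat import maybe_njit
from .datatypes import (
    ConvergenceError,
    CorrelationMatrix,
    Network,
    ValidationError,
    symmetric_network,
)

logger = logging.getLogger(__name__)

#: Partial correlations below this magnitude are snapped to exact zero.
ZERO_TOL = 1e-10


def _glasso_cd_impl(S, Lam, W, Beta, tol, max_sweeps, inner_max):
    """Block coordinate descent. Mutates W, Beta in place.

    Returns (n_sweeps, last_max_change). Convergence is declared when
    the largest absolute covariance update in a full sweep is < tol.
    """
    p = S.shape[0]
    max_delta = 0.0
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            for _ in range(inner_max):
                inner_delta = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = S[k, j]
                    for l in range(p):
                        if l != j and l != k:
                            r -= W[k, l] * Beta[l, j]
                    b_old = Beta[k, j]
                    t = abs(r) - Lam[k, j]
                    if t <= 0.0:
                        b_new = 0.0
                    else:
                        b_new = math.copysign(t, r) / W[k, k]
                    if b_new != b_old:
                        Beta[k, j] = b_new
                        d = abs(b_new - b_old)
                        if d > inner_delta:
                            inner_delta = d
                if inner_delta < tol:
                    break
            for i in range(p):
                if i == j:
                    continue
                v = 0.0
                for l in range(p):
                    if l != j:
                        v += W[i, l] * Beta[l, j]
                d = abs(v - W[i, j])
                if d > max_delta:
                    max_delta = d
                W[i, j] = v
            for i in range(p):
                if i != j:
                    W[j, i] = W[i, j]
        if max_delta < tol:
            return sweep + 1, max_delta
    return max_sweeps, max_delta


_glasso_cd = maybe_njit(_glasso_cd_impl)


def _theta_from_wb_impl(W, Beta):
    p = W.shape[0]
    theta = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        for l in range(p):
            if l != j:
                dot += W[l, j] * Beta[l, j]
        tjj = 1.0 / (W[j, j] - dot)
        theta[j, j] = tjj
        for k in range(p):
            if k != j:
                theta[k, j] = -Beta[k, j] * tjj
    return 0.5 * (theta + theta.T)


_theta_from_wb_fast = maybe_njit(_theta_from_wb_impl)


def _as_corr(S) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(S, CorrelationMatrix):
        return S.values, S.item_labels
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValidationError("S must be a square matrix")
    if np.max(np.abs(S - S.T), initial=0.0) > 1e-10:
        raise ValidationError("S must be symmetric")
    if np.linalg.eigvalsh(S).min() < -1e-8:
        raise ValidationError("S must be positive semidefinite within 1e-8")
    return (S + S.T) / 2.0, None


def _theta_from_wb(W: np.ndarray, Beta: np.ndarray) -> np.ndarray:
    return _theta_from_wb_fast(W, Beta)


def glasso_fit(
    S,
    lam: float,
    *,
    penalty_weights: np.ndarray | None = None,
    tol: float = 1e-7,
    max_sweeps: int = 500,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Precision matrix maximizing ``logdet(T) - tr(S T) - lam * ||T||_1,off``.

    Only off-diagonal entries are penalized; at ``lam = 0`` the exact
    unpenalized MLE ``S^{-1}`` is returned in closed form.
    ``penalty_weights`` (p x p, symmetric) scales the penalty per entry
    for the adaptive variant.  ``warm`` optionally carries ``(W, Beta)``
    from a neighbouring penalty for warm starts; both are updated in
    place.
    """
    S, _ = _as_corr(S)
    p = S.shape[0]
    if lam < 0:
        raise ValidationError("lam must be nonnegative")
    Lam = np.full((p, p), float(lam))
    if penalty_weights is not None:
        Lam = Lam * np.asarray(penalty_weights, dtype=float)
    np.fill_diagonal(Lam, 0.0)

    if np.all(Lam == 0.0):
        try:
            theta = np.linalg.inv(S)
        except np.linalg.LinAlgError as exc:
            raise ValidationError("S is singular; lam=0 fit undefined") from exc
        theta = (theta + theta.T) / 2.0
        if warm is not None:
            W, Beta = warm
            W[:] = S
            d = np.diag(theta).copy()
            Beta[:] = -theta / d[None, :]
            np.fill_diagonal(Beta, 0.0)
        return theta

    if warm is not None:
        W, Beta = warm
    else:
        W, Beta = S.copy(), np.zeros((p, p))
    n_sweeps, last = _glasso_cd(S, Lam, W, Beta, tol, max_sweeps, 200)
    if last >= tol:
        raise ConvergenceError(
            f"graphical lasso did not converge in {max_sweeps} sweeps "
            f"(last max change {last:.3g} >= tol {tol:g})"
        )
    return _theta_from_wb(W, Beta)


def precision_to_partialcorr(theta: np.ndarray, item_labels: list[str] | None = None) -> Network:
    """Edge weights ``e_ij = -theta_ij / sqrt(theta_ii theta_jj)``, zero diagonal."""
    theta = np.asarray(theta, dtype=float)
    d = np.diag(theta)
    if np.any(d <= 0):
        raise ValidationError("precision matrix has non-positive diagonal")
    weights = -theta / np.sqrt(np.outer(d, d))
    np.fill_diagonal(weights, 0.0)
    weights[np.abs(weights) < ZERO_TOL] = 0.0
    if item_labels is None:
        item_labels = [f"item{j + 1}" for j in range(theta.shape[0])]
    return symmetric_network(weights, item_labels)


def gaussian_loglik(S: np.ndarray, theta: np.ndarray, n: int) -> float:
    """Gaussian log-likelihood of n observations with sample covariance S."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise ValidationError("precision matrix is not positive definite")
    return 0.5 * n * (logdet - float(np.sum(S * theta)) - p * math.log(2.0 * math.pi))


def ebic(loglik: float, n: int, p: int, n_edges: int, gamma: float) -> float:
    """Extended BIC: ``-2 loglik + E log n + 4 gamma E log p``."""
    if min(n, p, n_edges) < 0 or gamma < 0:
        raise ValidationError("n, p, n_edges must be nonnegative and gamma >= 0")
    return -2.0 * loglik + n_edges * math.log(n) + 4.0 * gamma * n_edges * math.log(p)


@dataclass
class EstimatorSettings:
    """Settings shared by every network-estimation call in the pipeline."""

    gamma: float = 0.5
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    penalty: str = "glasso"  # or "adaptive"
    tol: float = 1e-7
    max_sweeps: int = 500
    correlation: str = "npn"  # or "polychoric"

    def __post_init__(self):
        if self.penalty not in ("glasso", "adaptive"):
            raise ValidationError(f"unknown penalty {self.penalty!r}")
        if self.correlation not in ("npn", "polychoric"):
            raise ValidationError(f"unknown correlation type {self.correlation!r}")

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "n_lambdas": self.n_lambdas,
            "lambda_min_ratio": self.lambda_min_ratio,
            "penalty": self.penalty,
            "tol": self.tol,
            "max_sweeps": self.max_sweeps,
            "correlation": self.correlation,
        }


@dataclass
class RegularizationPath:
    """Per-lambda fits, EBIC scores and the selected model.

    Per-lambda networks are materialized lazily (``networks``) from the
    stored partial-correlation weight matrices.
    """

    lambdas: np.ndarray
    thetas: list[np.ndarray]
    weight_mats: list[np.ndarray]
    item_labels: list[str]
    logliks: np.ndarray
    edge_counts: np.ndarray
    ebics: np.ndarray
    gamma: float
    n: int
    selected_index: int

    @property
    def networks(self) -> list[Network]:
        return [Network(w, self.item_labels) for w in self.weight_mats]

    @property
    def network(self) -> Network:
        """The EBIC-selected network (the headline output)."""
        return Network(self.weight_mats[self.selected_index], self.item_labels)

    @property
    def theta(self) -> np.ndarray:
        return self.thetas[self.selected_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lambdas,
                "edges": self.edge_counts,
                "loglik": self.logliks,
                "ebic": self.ebics,
                "selected": [i == self.selected_index for i in range(len(self.lambdas))],
            }
        )


def estimate_network(
    S,
    n: int,
    *,
    gamma: float = 0.5,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
    penalty: str = "glasso",
    tol: float = 1e-7,
    max_sweeps: int = 500,
) -> RegularizationPath:
    """Fit the penalty path and select the EBIC-minimizing network.

    The grid is log-spaced from ``lambda_max = max_{i!=j} |S_ij|`` (at
    which the selected model is empty by the KKT conditions) down to
    ``lambda_max * lambda_min_ratio``.
    """
    values, labels = _as_corr(S)
    if labels is None:
        labels = [f"item{j + 1}" for j in range(values.shape[0])]
    p = values.shape[0]
    if n < p:
        warnings.warn(f"estimating a {p}-node network from n={n} < p observations")

    off = np.abs(values - np.diag(np.diag(values)))
    lam_max = float(off.max()) if p > 1 else 0.0
    if lam_max <= 0.0:
        lambdas = np.array([0.0])
    else:
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

    penalty_weights = None
    if penalty == "adaptive":
        theta_ref = glasso_fit(values, lambdas[-1], tol=tol, max_sweeps=max_sweeps)
        w = 1.0 / np.maximum(np.abs(theta_ref), 1e-4)
        np.fill_diagonal(w, 0.0)
        iu = np.triu_indices(p, k=1)
        if len(iu[0]):
            w = w / w[iu].mean()  # keep the lambda grid on a comparable scale
        penalty_weights = w
    elif penalty != "glasso":
        raise ValidationError(f"unknown penalty {penalty!r}")

    W = values.copy()
    Beta = np.zeros((p, p))
    base_lam = np.ones((p, p)) if penalty_weights is None else penalty_weights
    iu = np.triu_indices(p, k=1)
    thetas, weight_mats, logliks, edge_counts, ebics, kept = [], [], [], [], [], []
    failures = []
    for lam in lambdas:
        try:
            if lam == 0.0:
                theta = glasso_fit(values, 0.0, tol=tol, max_sweeps=max_sweeps)
            else:
                Lam = float(lam) * base_lam
                np.fill_diagonal(Lam, 0.0)
                _, last = _glasso_cd(values, Lam, W, Beta, tol, max_sweeps, 200)
                if last >= tol:
                    raise ConvergenceError(
                        f"no convergence at lambda={lam:.4g} (last change {last:.3g})"
                    )
                theta = _theta_from_wb(W, Beta)
            d = np.diag(theta)
            if np.any(d <= 0):
                raise ValidationError("non-positive precision diagonal")
            weights = -theta / np.sqrt(np.outer(d, d))
            weights = 0.5 * (weights + weights.T)
            np.fill_diagonal(weights, 0.0)
            weights[np.abs(weights) < ZERO_TOL] = 0.0
            ll = gaussian_loglik(values, theta, n)
        except (ConvergenceError, ValidationError) as exc:
            failures.append((lam, exc))
            continue
        n_edges = int(np.count_nonzero(weights[iu]))
        kept.append(lam)
        thetas.append(theta)
        weight_mats.append(weights)
        logliks.append(ll)
        edge_counts.append(n_edges)
        ebics.append(ebic(ll, n, p, n_edges, gamma))
    if not thetas:
        raise ConvergenceError(
            f"all {len(lambdas)} penalty-path fits failed; first error: {failures[0][1]}"
        )
    ebics = np.asarray(ebics)
    selected = int(np.argmin(ebics))
    return RegularizationPath(
        lambdas=np.asarray(kept),
        thetas=thetas,
        weight_mats=weight_mats,
        item_labels=labels,
        logliks=np.asarray(logliks),
        edge_counts=np.asarray(edge_counts),
        ebics=ebics,
        gamma=gamma,
        n=n,
        selected_index=selected,
    )


def network_from_scores(scores: np.ndarray, item_labels, settings: EstimatorSettings) -> Network:
    """npn/polychoric -> correlation -> EBIC-glasso, returning the selected network."""
    from . import preprocess  # local import to keep module load order simple

    n = scores.shape[0]
    if settings.correlation == "polychoric":
        from .datatypes import ItemPanel

        panel = ItemPanel(
            np.arange(n), "baseline", np.asarray(scores), list(item_labels)
        )
        corr = preprocess.polychoric_correlation(panel)
    else:
        t = preprocess.nonparanormal_transform(np.asarray(scores), list(item_labels))
        corr = preprocess.correlation(t)
    path = estimate_network(
        corr,
        n,
        gamma=settings.gamma,
        n_lambdas=settings.n_lambdas,
        lambda_min_ratio=settings.lambda_min_ratio,
        penalty=settings.penalty,
        tol=settings.tol,
        max_sweeps=settings.max_sweeps,
    )
    return path.network


def network_from_panel(panel, settings: EstimatorSettings | None = None) -> Network:
    settings = settings or EstimatorSettings()
    return network_from_scores(panel.scores, panel.item_labels, settings)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_network(net: Network, stem: Path) -> list[Path]:
    """Write square CSV, long edge-list TSV, and GraphML next to ``stem``."""
    import networkx as nx

    stem = Path(stem)
    csv_path = stem.with_suffix(".csv")
    net.to_frame().to_csv(csv_path, index_label="item")
    tsv_path = stem.with_suffix(".tsv")
    net.edge_list().to_csv(tsv_path, sep="\t", index=False)
    graph = nx.Graph()
    graph.add_nodes_from(net.item_labels)
    for _, row in net.edge_list().iterrows():
        graph.add_edge(row["item_a"], row["item_b"], weight=float(row["weight"]))
    graphml_path = stem.with_suffix(".graphml")
    nx.write_graphml(graph, graphml_path)
    return [csv_path, tsv_path, graphml_path]


def read_network(path: Path) -> Network:
    frame = pd.read_csv(path, index_col=0)
    return Network(frame.to_numpy(dtype=float), list(frame.columns))
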