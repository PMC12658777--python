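"""DAG-constrained structure discovery over covariates, treatment, outcome.

Learns a weighted adjacency matrix A over the node set {covariates,
treatment, outcome} by minimizing a self-reconstruction loss (each node
predicted from its parents via A) plus an L1 sparsity penalty, under the
differentiable acyclicity constraint h(A) = tr(exp(A∘A)) − d = 0 enforced
with an augmented-Lagrangian schedule.  A two-hidden-layer ReLU readout
head is trained alongside to estimate E[Y|T, X] and reports train/test R².
Edges out of the outcome node are structurally masked to zero, encoding the
ordering constraint that the outcome causes neither covariates nor
treatment.

Edge stability is assessed by refitting on bootstrap row-resamples (with
reduced optimization budget) and recording how often each thresholded edge
reappears.  The consensus step merges the per-outcome adaptive-LASSO
selections with the graph evidence into a single top-k confounder set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import expm

from ._nn import MLP, Adam

__all__ = [
    "CGNNConfig",
    "StructureResult",
    "TrainingFailureError",
    "acyclicity",
    "fit_structure",
    "bootstrap_edges",
    "consensus_top_k",
]


class TrainingFailureError(RuntimeError):
    """Optimization diverged (NaN loss)."""


@dataclass(frozen=True)
class CGNNConfig:
    hidden_width: int = 16
    lr: float = 0.05
    epochs: int = 120  # Adam steps per augmented-Lagrangian iteration
    max_al_iters: int = 25
    lambda_sparse: float = 0.02
    edge_threshold: float = 0.1  # on |A| after standardization
    h_tol: float = 1e-8
    readout_epochs: int = 300
    readout_lr: float = 1e-2
    test_frac: float = 0.2
    bootstrap_epoch_divisor: int = 5
    seed: int = 0


@dataclass
class StructureResult:
    adjacency: np.ndarray  # (d, d), A[u, v] = strength of edge u -> v
    node_names: list
    edges: np.ndarray  # boolean, |A| > threshold
    edge_stability: np.ndarray | None
    confounder_rank: list  # covariates ordered by combined edge strength to T and Y
    fit_r2_train: float
    fit_r2_test: float
    h_value: float
    converged: bool

    def edge_list(self) -> pd.DataFrame:
        rows = []
        d = len(self.node_names)
        for u in range(d):
            for v in range(d):
                if self.edges[u, v]:
                    stab = (float(self.edge_stability[u, v])
                            if self.edge_stability is not None else np.nan)
                    rows.append((self.node_names[u], self.node_names[v],
                                 float(self.adjacency[u, v]), stab))
        return pd.DataFrame(rows, columns=["source", "target", "weight", "stability"])

    def thresholded_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        for u, v, w, _ in self.edge_list().itertuples(index=False):
            g.add_edge(u, v, weight=w)
        return g


def acyclicity(A) -> float:
    """Acyclicity score h(A) = tr(exp(A∘A)) − d; zero iff A is a DAG."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    d = A.shape[0]
    return float(np.trace(expm(A * A)) - d)


def _standardize_nodes(X, T, Y):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"x{j + 1}" for j in range(Xv.shape[1])]
    M = np.column_stack([Xv, np.asarray(T, dtype=float), np.asarray(Y, dtype=float)])
    mu, sd = M.mean(axis=0), M.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    M = (M - mu) / sd_safe
    M[:, sd == 0] = 0.0
    return M, names + ["treatment", "outcome"]


def _fit_adjacency(G, mask, config, rho0=1.0, alpha0=0.0, max_al=None, epochs=None):
    """Augmented-Lagrangian minimization of the masked structure loss.

    ``G`` is the (1/n) MᵀM Gram matrix of standardized node values, so each
    inner Adam step costs O(d²) regardless of sample size.
    """
    d = G.shape[0]
    A = np.zeros((d, d))
    opt = Adam([A], lr=config.lr)
    rho, alpha = rho0, alpha0
    max_al = max_al or config.max_al_iters
    epochs = epochs or config.epochs
    h_val = acyclicity(A)
    shrink = config.lr * config.lambda_sparse
    for _ in range(max_al):
        for _ in range(epochs):
            E = expm(A * A)
            h_val = float(np.trace(E) - d)
            grad_h = E.T * (2.0 * A)
            grad = (G @ A - G) + (rho * h_val + alpha) * grad_h
            opt.step([grad * mask])
            # proximal step for the L1 sparsity penalty: exact zeros
            np.copyto(A, np.sign(A) * np.maximum(np.abs(A) - shrink, 0.0))
            A *= mask
        if not np.isfinite(A).all():
            raise TrainingFailureError("adjacency optimization diverged (NaN)")
        h_val = acyclicity(A)
        if h_val <= config.h_tol:
            break
        alpha += rho * h_val
        rho = min(rho * 10.0, 1e16)
    return A, h_val


def _readout_r2(X, T, Y, config):
    """Two-hidden-layer ReLU readout for E[Y|T, X]; train/test R²."""
    rng = np.random.default_rng(config.seed + 1)
    F = np.column_stack([np.asarray(X, dtype=float), np.asarray(T, dtype=float)])
    mu, sd = F.mean(axis=0), F.std(axis=0)
    sd[sd == 0] = 1.0
    F = (F - mu) / sd
    y = np.asarray(Y, dtype=float)
    ym, ys = y.mean(), y.std() or 1.0
    yz = (y - ym) / ys

    n = len(y)
    perm = rng.permutation(n)
    n_test = max(1, int(round(config.test_frac * n)))
    test, train = perm[:n_test], perm[n_test:]

    net = MLP([F.shape[1], config.hidden_width, config.hidden_width, 1], rng)
    opt = Adam(net.params, lr=config.readout_lr)
    Ftr, ytr = F[train], yz[train]
    for _ in range(config.readout_epochs):
        pred = net.forward(Ftr)[:, 0]
        err = pred - ytr
        if not np.isfinite(err).all():
            raise TrainingFailureError("readout training diverged (NaN)")
        net.backward((2.0 / len(ytr)) * err[:, None])
        opt.step(net.grads)

    def r2(idx):
        pred = net.forward(F[idx])[:, 0]
        ss_res = float(np.sum((yz[idx] - pred) ** 2))
        ss_tot = float(np.sum((yz[idx] - yz[idx].mean()) ** 2)) or 1.0
        return 1.0 - ss_res / ss_tot

    return r2(train), r2(test)


def _edge_mask(d):
    """Allowed-edge mask: no self-loops, no edges out of the outcome node."""
    mask = np.ones((d, d))
    np.fill_diagonal(mask, 0.0)
    mask[d - 1, :] = 0.0  # outcome is last
    return mask


def fit_structure(X, T, Y, config: CGNNConfig = CGNNConfig(),
                  edge_stability: np.ndarray | None = None) -> StructureResult:
    """Learn the DAG-constrained adjacency and the readout fit for E[Y|T,X]."""
    M, node_names = _standardize_nodes(X, T, Y)
    if np.isnan(M).any():
        raise ValueError("inputs contain missing cells")
    d = M.shape[1]
    G = (M.T @ M) / M.shape[0]
    mask = _edge_mask(d)
    A, h_val = _fit_adjacency(G, mask, config)
    edges = np.abs(A) > config.edge_threshold

    if edges.any():
        g = nx.from_numpy_array(edges.astype(int), create_using=nx.DiGraph)
        if not nx.is_directed_acyclic_graph(g):
            warnings.warn("thresholded graph contains a cycle", stacklevel=2)

    r2_train, r2_test = _readout_r2(X, T, Y, config)

    t_idx, y_idx = d - 2, d - 1
    cov_names = node_names[:-2]
    if edge_stability is not None:
        strength = edge_stability[:-2, t_idx] + edge_stability[:-2, y_idx]
    else:
        strength = np.abs(A[:-2, t_idx]) + np.abs(A[:-2, y_idx])
    order = sorted(range(len(cov_names)), key=lambda j: (-strength[j], cov_names[j]))
    rank = [cov_names[j] for j in order]

    return StructureResult(
        adjacency=A,
        node_names=node_names,
        edges=edges,
        edge_stability=edge_stability,
        confounder_rank=rank,
        fit_r2_train=r2_train,
        fit_r2_test=r2_test,
        h_value=h_val,
        converged=h_val <= config.h_tol,
    )


def bootstrap_edges(X, T, Y, config: CGNNConfig = CGNNConfig(), B: int = 1000) -> np.ndarray:
    """Edge selection frequency over B bootstrap row-resamples.

    Each replicate refits the adjacency with a reduced optimization budget
    (epochs divided by ``bootstrap_epoch_divisor``) and records which edges
    survive thresholding; the returned matrix holds per-edge frequencies in
    [0, 1].
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    M, _ = _standardize_nodes(X, T, Y)
    n, d = M.shape
    mask = _edge_mask(d)
    epochs = max(10, config.epochs // config.bootstrap_epoch_divisor)
    rng = np.random.default_rng(config.seed)
    counts = np.zeros((d, d))
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        Mb = M[idx]
        sd = Mb.std(axis=0)
        Mb = np.where(sd == 0, 0.0, Mb - Mb.mean(axis=0))
        G = (Mb.T @ Mb) / n
        A, _ = _fit_adjacency(G, mask, config, max_al=max(3, config.max_al_iters // 3),
                              epochs=epochs)
        counts += np.abs(A) > config.edge_threshold
    return counts / B


def _minmax(v):
    v = np.asarray(v, dtype=float)
    span = v.max() - v.min()
    return np.zeros_like(v) if span == 0 else (v - v.min()) / span


def consensus_top_k(oal_sets: dict, structure: StructureResult, k: int = 25):
    """Merge adaptive-LASSO selections with graph evidence into a top-k set.

    Covariates are ranked by the mean of (min-max normalized selection
    frequency across outcome-specific sets, min-max normalized edge strength
    or stability toward treatment and outcome); ties break lexicographically.
    Returns ``(ordered top-k names, DataFrame of per-covariate scores)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cov_names = structure.node_names[:-2]
    d = len(structure.node_names)
    t_idx, y_idx = d - 2, d - 1

    freq = np.array([np.mean([name in s for s in oal_sets.values()])
                     for name in cov_names]) if oal_sets else np.zeros(len(cov_names))
    if structure.edge_stability is not None:
        graph_score = (structure.edge_stability[:-2, t_idx]
                       + structure.edge_stability[:-2, y_idx])
    else:
        graph_score = (np.abs(structure.adjacency[:-2, t_idx])
                       + np.abs(structure.adjacency[:-2, y_idx]))
    combined = 0.5 * (_minmax(freq) + _minmax(graph_score))

    order = sorted(range(len(cov_names)), key=lambda j: (-combined[j], cov_names[j]))
    scores = pd.DataFrame({
        "covariate": [cov_names[j] for j in order],
        "oal_frequency": freq[order],
        "graph_score": graph_score[order],
        "consensus_score": combined[order],
    })
    if k > len(cov_names):
        warnings.warn(f"requested top-{k} but only {len(cov_names)} candidates; "
                      "returning all", stacklevel=2)
        k = len(cov_names)
    return [cov_names[j] for j in order[:k]], scores
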