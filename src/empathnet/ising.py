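"""Sparse Ising network estimation by nodewise l1 logistic regression (eLasso).

The joint model over binary items x in {0,1}^p has per-node thresholds tau_i
and symmetric pairwise couplings beta_ij, so each conditional is logistic:

    P(x_j = 1 | x_-j) = sigmoid(tau_j + sum_i beta_ij x_i).

Each node is regressed on all others with an l1 penalty along a descending
lambda path (cyclic coordinate descent, majorized curvature bound 1/4, warm
starts — deterministic, no RNG). The extended BIC picks the penalty level per
node, and the two directed neighbourhood estimates are combined by the AND
(default) or OR rule with the arithmetic mean of the two coefficients.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .instruments import item_columns

logger = logging.getLogger(__name__)

#: Default EBIC hyperparameter (the published default of the estimator family).
DEFAULT_EBIC_GAMMA = 0.25
#: Lambda path: this many log-spaced values from lambda_max down.
DEFAULT_N_LAMBDAS = 100
#: ... to lambda_min = ratio * lambda_max.
DEFAULT_LAMBDA_MIN_RATIO = 0.01

_CD_TOL = 1e-6
_CD_MAX_ITER = 10_000
#: |coefficient| above this triggers a near-separation warning.
_SEPARATION_BOUND = 10.0


class DegenerateNodeError(ValueError):
    """A node with constant responses cannot be regressed on."""


@dataclass(frozen=True)
class IsingNetwork:
    """A fitted (or ground-truth) Ising model.

    ``weights`` is the symmetric coupling matrix with zero diagonal;
    ``thresholds`` holds the per-node intercepts tau.
    """

    node_labels: tuple[str, ...]
    weights: np.ndarray
    thresholds: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        t = np.asarray(self.thresholds, dtype=float)
        p = len(self.node_labels)
        if w.shape != (p, p):
            raise ValueError(f"weights shape {w.shape} != ({p}, {p})")
        if t.shape != (p,):
            raise ValueError(f"thresholds shape {t.shape} != ({p},)")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0.0):
            raise ValueError("weight diagonal must be exactly zero")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def index_of(self, label: str) -> int:
        return self.node_labels.index(label)

    def edges(self) -> list[tuple[str, str, float]]:
        """Upper-triangle nonzero edges as (node_a, node_b, weight)."""
        out = []
        p = self.n_nodes
        for i in range(p):
            for j in range(i + 1, p):
                if self.weights[i, j] != 0.0:
                    out.append((self.node_labels[i], self.node_labels[j], float(self.weights[i, j])))
        return out

    def save(self, edge_path, sidecar_path) -> None:
        """Write a weighted edge-list TSV plus a JSON sidecar (thresholds, meta)."""
        with open(edge_path, "w") as fh:
            fh.write("node_a\tnode_b\tweight\tsign\n")
            for a, b, w in self.edges():
                sign = "+" if w > 0 else "-"
                fh.write(f"{a}\t{b}\t{w:.10g}\t{sign}\n")
        sidecar = {
            "node_labels": list(self.node_labels),
            "thresholds": [float(t) for t in self.thresholds],
            "meta": _jsonable(self.meta),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)
            fh.write("\n")

    def to_graphml(self, path) -> None:
        """Optional export in graph-exchange XML for external network viewers."""
        import networkx as nx

        g = nx.Graph()
        for i, lab in enumerate(self.node_labels):
            g.add_node(lab, threshold=float(self.thresholds[i]))
        for a, b, w in self.edges():
            g.add_edge(a, b, weight=w, sign="+" if w > 0 else "-")
        nx.write_graphml(g, path)

    @classmethod
    def load(cls, edge_path, sidecar_path) -> "IsingNetwork":
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        labels = sidecar["node_labels"]
        idx = {lab: i for i, lab in enumerate(labels)}
        w = np.zeros((len(labels), len(labels)))
        edges = pd.read_csv(edge_path, sep="\t")
        for _, row in edges.iterrows():
            i, j = idx[row["node_a"]], idx[row["node_b"]]
            w[i, j] = w[j, i] = float(row["weight"])
        return cls(tuple(labels), w, np.asarray(sidecar["thresholds"], dtype=float), sidecar.get("meta", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@njit(cache=True)
def _log1pexp(t):
    if t > 0.0:
        return t + np.log1p(np.exp(-t))
    return np.log1p(np.exp(t))


@njit(cache=True)
def _objective(y, eta, beta, lam):
    n = eta.shape[0]
    nll = 0.0
    for i in range(n):
        nll += _log1pexp(eta[i]) - y[i] * eta[i]
    nll /= n
    pen = 0.0
    for j in range(beta.shape[0]):
        pen += abs(beta[j])
    return nll + lam * pen


@njit(cache=True)
def _cd_sweep(X, y, eta, prob, beta, b0, lam, cap, newton):
    """One cyclic pass over the intercept and all coordinates.

    Proximal steps use the observed (Newton) curvature when ``newton`` is
    true, otherwise the 1/4 majorization bound (guaranteed descent). Steps
    are clipped to +-1 and coefficients to +-cap, which tames perfect
    separation. Returns (new intercept, largest coefficient move).
    """
    n, k = X.shape
    moved = 0.0
    g0 = 0.0
    h0 = 0.0
    for i in range(n):
        g0 += prob[i] - y[i]
        h0 += prob[i] * (1.0 - prob[i])
    g0 /= n
    h0 = max(h0 / n, 1e-3) if newton else 0.25
    step = -g0 / h0
    if step > 1.0:
        step = 1.0
    elif step < -1.0:
        step = -1.0
    if step != 0.0:
        b0 += step
        moved = abs(step)
        for i in range(n):
            eta[i] += step
            prob[i] = 1.0 / (1.0 + np.exp(-eta[i]))
    for j in range(k):
        g = 0.0
        h = 0.0
        sx2 = 0.0
        for i in range(n):
            xij = X[i, j]
            if xij != 0.0:
                g += xij * (prob[i] - y[i])
                h += xij * xij * prob[i] * (1.0 - prob[i])
                sx2 += xij * xij
        if sx2 == 0.0:
            continue
        g /= n
        h = max(h / n, 1e-3) if newton else 0.25 * sx2 / n
        u = h * beta[j] - g
        if u > lam:
            newb = (u - lam) / h
        elif u < -lam:
            newb = (u + lam) / h
        else:
            newb = 0.0
        d = newb - beta[j]
        if d > 1.0:
            newb = beta[j] + 1.0
        elif d < -1.0:
            newb = beta[j] - 1.0
        if newb > cap:
            newb = cap
        elif newb < -cap:
            newb = -cap
        if newb != beta[j]:
            d = newb - beta[j]
            if abs(d) > moved:
                moved = abs(d)
            for i in range(n):
                if X[i, j] != 0.0:
                    eta[i] += X[i, j] * d
                    prob[i] = 1.0 / (1.0 + np.exp(-eta[i]))
            beta[j] = newb
    return b0, moved


@njit(cache=True)
def _cd_path(X, y, lambdas, tol, max_iter):
    """Cyclic coordinate descent over a descending lambda path.

    Minimizes (1/n) * sum(log(1+exp(eta)) - y*eta) + lam * ||beta||_1 with an
    unpenalized intercept. Sweeps use clipped proximal Newton steps and stop
    when a sweep improves the penalized objective by less than ``tol`` (or
    moves no coefficient); if a Newton sweep ever increases the objective,
    the lambda falls back to the monotone 1/4-majorization update. Warm
    starts carry solutions down the path; coefficients are capped at +-15 so
    perfect separation cannot diverge. Returns per-lambda intercepts,
    coefficients, and UNPENALIZED total log-likelihoods.
    """
    n, k = X.shape
    n_lam = lambdas.shape[0]
    cap = 15.0
    intercepts = np.zeros(n_lam)
    coefs = np.zeros((n_lam, k))
    logliks = np.zeros(n_lam)

    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    b0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(k)
    eta = np.full(n, b0)
    prob = np.empty(n)
    for i in range(n):
        prob[i] = 1.0 / (1.0 + np.exp(-eta[i]))

    for l in range(n_lam):
        lam = lambdas[l]
        obj = _objective(y, eta, beta, lam)
        newton = True
        it = 0
        while it < max_iter:
            b0, moved = _cd_sweep(X, y, eta, prob, beta, b0, lam, cap, newton)
            it += 1
            if moved < 1e-10:
                break
            new_obj = _objective(y, eta, beta, lam)
            if new_obj > obj + 1e-12 and newton:
                newton = False  # safeguard: fall back to monotone updates
                obj = new_obj
                continue
            if obj - new_obj < tol:
                obj = new_obj
                break
            obj = new_obj
        intercepts[l] = b0
        for j in range(k):
            coefs[l, j] = beta[j]
        ll = 0.0
        for i in range(n):
            ll -= _log1pexp(eta[i]) - y[i] * eta[i]
        logliks[l] = ll
    return intercepts, coefs, logliks


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which all coefficients are zero: (1/n) max|X'(y - ybar)|."""
    n = len(y)
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / n)


def lambda_path(
    lam_max: float,
    n_lambdas: int = DEFAULT_N_LAMBDAS,
    min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> np.ndarray:
    """Descending log-spaced penalty path from lambda_max to min_ratio*lambda_max."""
    if lam_max <= 0.0:
        # the node is empirically independent of all predictors at the linear
        # score; any positive path keeps everything at zero
        return np.array([1.0])
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)


def logistic_lasso_path(
    y: np.ndarray,
    X: np.ndarray,
    lambdas: Sequence[float],
    tol: float = _CD_TOL,
    max_iter: int = _CD_MAX_ITER,
) -> dict:
    """l1-penalized logistic path of y on X over descending lambdas.

    Returns a dict with ``intercepts`` (L,), ``coefs`` (L, k) and ``logliks``
    (L,), where the log-likelihood is the unpenalized value at the solution.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambdas must be non-increasing")
    if y.min() == y.max():
        raise DegenerateNodeError("degenerate node: constant response")
    intercepts, coefs, logliks = _cd_path(X, y, lambdas, tol, max_iter)
    if np.any(np.abs(coefs[-1]) > _SEPARATION_BOUND):
        logger.warning("near-separation: |coefficient| > %.0f at smallest lambda", _SEPARATION_BOUND)
    return {"intercepts": intercepts, "coefs": coefs, "logliks": logliks, "lambdas": lambdas}


def ebic(loglik: float, k: int, n: int, p: int, gamma: float) -> float:
    """Extended BIC: -2*loglik + k*log(n) + 2*gamma*k*log(p - 1)."""
    return -2.0 * loglik + k * np.log(n) + 2.0 * gamma * k * np.log(max(p - 1, 1))


def ebic_select(path_fit: dict, n: int, p: int, gamma: float = DEFAULT_EBIC_GAMMA) -> int:
    """Index of the EBIC-minimizing lambda; ties go to the sparser (larger) lambda."""
    coefs = path_fit["coefs"]
    logliks = path_fit["logliks"]
    ks = np.count_nonzero(coefs, axis=1)
    scores = np.array([ebic(ll, int(k), n, p, gamma) for ll, k in zip(logliks, ks)])
    best = scores.min()
    # path is descending in lambda, so the first index within tolerance of the
    # minimum is the largest (sparsest) lambda
    return int(np.flatnonzero(scores <= best + 1e-9)[0])


def _binary_matrix(binary, labels=None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(binary, pd.DataFrame):
        cols = labels if labels is not None else item_columns(binary)
        mat = binary.loc[:, cols].to_numpy(dtype=float)
        return mat, tuple(cols)
    mat = np.asarray(binary, dtype=float)
    if labels is None:
        labels = tuple(f"node_{i}" for i in range(mat.shape[1]))
    return mat, tuple(labels)


def fit_ising_matrix(
    X: np.ndarray,
    gamma: float = DEFAULT_EBIC_GAMMA,
    rule: str = "AND",
    n_lambdas: int = DEFAULT_N_LAMBDAS,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    node_labels: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """eLasso core on a plain {0,1} matrix.

    Returns (weights, thresholds, directed) where ``directed[j, i]`` is node
    j's selected coefficient on node i. Used directly by the permutation
    machinery to avoid DataFrame overhead.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-d binary matrix")
    # canonicalize row order: the fit is row-exchangeable, and sorting makes
    # it bitwise invariant to permutations of the participants
    X = np.ascontiguousarray(X[np.lexsort(X.T[::-1])])
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 nodes")
    if rule not in ("AND", "OR"):
        raise ValueError("rule must be 'AND' or 'OR'")
    directed = np.zeros((p, p))
    tau = np.zeros(p)
    others_idx = np.arange(p)
    for j in range(p):
        y = X[:, j]
        if y.min() == y.max():
            label = node_labels[j] if node_labels is not None else f"node_{j}"
            raise DegenerateNodeError(f"degenerate node: {label!r} has constant responses")
        others = others_idx[others_idx != j]
        Xo = np.ascontiguousarray(X[:, others])
        lams = lambda_path(lambda_max(Xo, y), n_lambdas, lambda_min_ratio)
        fit = logistic_lasso_path(y, Xo, lams)
        sel = ebic_select(fit, n, p, gamma)
        directed[j, others] = fit["coefs"][sel]
        tau[j] = fit["intercepts"][sel]
    present = directed != 0.0
    keep = (present & present.T) if rule == "AND" else (present | present.T)
    weights = np.where(keep, 0.5 * (directed + directed.T), 0.0)
    np.fill_diagonal(weights, 0.0)
    return weights, tau, directed


def fit_ising(
    binary,
    gamma: float = DEFAULT_EBIC_GAMMA,
    rule: str = "AND",
    n_lambdas: int = DEFAULT_N_LAMBDAS,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    node_labels: Sequence[str] | None = None,
) -> IsingNetwork:
    """Estimate a signed Ising network from a binary response table.

    ``binary`` may be a response DataFrame (item columns are used) or a plain
    {0,1} matrix. Edge beta_ij is the mean of the two directed nodewise
    coefficients when the AND/OR rule admits the edge, else 0; tau_j is the
    EBIC-selected intercept of node j's regression.
    """
    X, labels = _binary_matrix(binary, node_labels)
    weights, tau, _ = fit_ising_matrix(
        X, gamma=gamma, rule=rule, n_lambdas=n_lambdas,
        lambda_min_ratio=lambda_min_ratio, node_labels=labels,
    )
    if np.any(np.abs(weights) > _SEPARATION_BOUND):
        logger.warning("selected model has |weight| > %.0f: possible near-separation", _SEPARATION_BOUND)
    meta = {
        "n_observations": int(X.shape[0]),
        "ebic_gamma": float(gamma),
        "rule": rule,
        "lambda_path_spec": {"n_lambdas": int(n_lambdas), "min_ratio": float(lambda_min_ratio)},
        "signed": True,
    }
    return IsingNetwork(labels, weights, tau, meta)


def to_absolute_network(net: IsingNetwork) -> IsingNetwork:
    """Elementwise |weights|; thresholds untouched; edge signs kept in meta."""
    signs = np.sign(net.weights)
    meta = dict(net.meta)
    meta["signed"] = False
    meta["edge_signs"] = [
        (net.node_labels[i], net.node_labels[j], int(signs[i, j]))
        for i in range(net.n_nodes)
        for j in range(i + 1, net.n_nodes)
        if signs[i, j] != 0
    ]
    return replace(net, weights=np.abs(net.weights), meta=meta)
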