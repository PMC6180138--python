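"""Permutation null for pre/post change in a regional network measure.

The observed statistic is the post-minus-pre difference of a node's regional
measure (clustering, strength, betweenness or closeness), each time point's
network refit by eLasso on that time point's records. The null is built by
pooling all 2N participant-time records, randomly splitting them into two
pseudo-groups of N (unrestricted by participant, following the study design;
a paired-flip mode is available), refitting both networks and recording the
measure difference. The two-sided p-value uses the add-one estimator
p = (1 + #{|null| >= |observed|}) / (1 + n_permutations), so p is never 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from . import metrics
from .instruments import item_columns
from .ising import fit_ising_matrix

logger = logging.getLogger(__name__)

#: Production default; tests and desk-scale runs use a few hundred.
DEFAULT_N_PERMUTATIONS = 5000
_MAX_REDRAW_FACTOR = 50

MEASURES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "clustering": metrics.clustering_coefficient,
    "strength": metrics.node_strength,
    "betweenness": metrics.betweenness_centrality,
    "closeness": lambda w: metrics.closeness_centrality(w),
}


@dataclass(frozen=True)
class PermutationResult:
    node: str
    measure: str
    observed_pre: float
    observed_post: float
    observed_diff: float
    null_diffs: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    n_redraws: int = 0


def _table_matrix(table, node=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        cols = item_columns(table)
        return table.loc[:, cols].to_numpy(dtype=float), cols
    mat = np.asarray(table, dtype=float)
    return mat, [f"node_{i}" for i in range(mat.shape[1])]


def _node_index(node, labels) -> int:
    if isinstance(node, (int, np.integer)):
        return int(node)
    if node not in labels:
        raise ValueError(f"node {node!r} not in the retained node set")
    return labels.index(node)


def _measure_value(X: np.ndarray, node_idx: int, measure: str, fit_kwargs: dict) -> float:
    weights, _, _ = fit_ising_matrix(X, **fit_kwargs)
    return float(MEASURES[measure](np.abs(weights))[node_idx])


def observed_difference(
    binary_pre,
    binary_post,
    node,
    measure: str = "clustering",
    **fit_kwargs,
) -> dict:
    """Post-minus-pre difference of one node's regional measure.

    Fits one Ising network per time point (absolute weights) and evaluates the
    requested measure. Returns ``{"pre": ..., "post": ..., "diff": ...}``.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {sorted(MEASURES)}")
    X_pre, labels_pre = _table_matrix(binary_pre)
    X_post, labels_post = _table_matrix(binary_post)
    if labels_pre != labels_post:
        raise ValueError("pre and post tables must share the retained node set")
    idx = _node_index(node, labels_pre)
    pre = _measure_value(X_pre, idx, measure, fit_kwargs)
    post = _measure_value(X_post, idx, measure, fit_kwargs)
    return {"pre": pre, "post": post, "diff": post - pre}


def permutation_null(
    binary_pre,
    binary_post,
    node,
    measure: str = "clustering",
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    paired: bool = False,
    **fit_kwargs,
) -> PermutationResult:
    """Permutation test of a pre/post change in a regional network measure.

    Each permutation reassigns the pooled 2N records into two pseudo-groups of
    N (``paired=True`` instead flips each participant's pair of records with
    probability 1/2), refits both networks and records the measure
    difference. Permutations in which a pseudo-group has a constant node
    (degenerate for the nodewise regressions) are redrawn and counted.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {sorted(MEASURES)}")
    X_pre, labels_pre = _table_matrix(binary_pre)
    X_post, labels_post = _table_matrix(binary_post)
    if labels_pre != labels_post:
        raise ValueError("pre and post tables must share the retained node set")
    if X_pre.shape[0] != X_post.shape[0]:
        raise ValueError("equal participant counts per time point required")
    idx = _node_index(node, labels_pre)

    obs = observed_difference(binary_pre, binary_post, node, measure, **fit_kwargs)
    n_per_group = X_pre.shape[0]
    pooled = np.vstack([X_pre, X_post])
    rng = np.random.default_rng(seed)

    null_diffs = np.empty(n_permutations)
    n_redraws = 0
    max_redraws = _MAX_REDRAW_FACTOR * n_permutations
    k = 0
    while k < n_permutations:
        if paired:
            flip = rng.random(n_per_group) < 0.5
            take_a = np.where(flip, np.arange(n_per_group) + n_per_group, np.arange(n_per_group))
            take_b = np.where(flip, np.arange(n_per_group), np.arange(n_per_group) + n_per_group)
        else:
            perm = rng.permutation(2 * n_per_group)
            take_a, take_b = perm[:n_per_group], perm[n_per_group:]
        A, B = pooled[take_a], pooled[take_b]
        if _degenerate(A) or _degenerate(B):
            n_redraws += 1
            if n_redraws > max_redraws:
                raise RuntimeError("too many degenerate pseudo-groups; data too sparse to permute")
            continue
        diff = _measure_value(B, idx, measure, fit_kwargs) - _measure_value(A, idx, measure, fit_kwargs)
        null_diffs[k] = diff
        k += 1
    if n_redraws:
        logger.info("%d degenerate pseudo-group draw(s) redrawn", n_redraws)

    p = (1.0 + np.sum(np.abs(null_diffs) >= abs(obs["diff"]))) / (1.0 + n_permutations)
    return PermutationResult(
        node=str(node),
        measure=measure,
        observed_pre=obs["pre"],
        observed_post=obs["post"],
        observed_diff=obs["diff"],
        null_diffs=null_diffs,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        n_redraws=n_redraws,
    )


def _degenerate(X: np.ndarray) -> bool:
    return bool(np.any(X.min(axis=0) == X.max(axis=0)))


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values (optional screen over nodes x measures)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out
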