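"""Ground-truth Ising models, Gibbs sampling, Likert expansion, paired designs.

The study's raw item-level responses are not available, so this module is the
pipeline's data stand-in: it draws binary response tables from known sparse
Ising models (sequential-scan Gibbs sampling), can calibrate per-node
thresholds so the sampled marginal "presence" frequencies match printed
per-item counts, expands binary values back to Likert scores through the
preimages of the binarization rules, and produces paired pre/post datasets
with planted network changes whose ground truth downstream recovery tests
can check. All generators are fully determined by their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import logit

from .instruments import META_COLUMNS, InstrumentSpec, spec_for_label
from .ising import IsingNetwork

logger = logging.getLogger(__name__)

DEFAULT_BURN_IN = 1000
DEFAULT_THIN = 10

#: The 24 retained items of the study scenario, with the printed number of
#: participants (out of N = 40) giving a "presence/empathic/expressive"
#: response at each time point. These serve as default calibration targets
#: for paper-scale synthetic data.
STUDY_N_PARTICIPANTS = 40
STUDY_PRESENCE_COUNTS: dict[str, tuple[int, int]] = {
    # label: (pre, post)
    "DASS-21: 5": (21, 22),
    "DASS-21: 16": (16, 15),
    "DASS-21: 9": (19, 17),
    "DASS-21: 6": (27, 23),
    "DASS-21: 11": (22, 23),
    "DASS-21: 12": (26, 23),
    "DASS-21: 14": (22, 19),
    "EQ-short: 2": (21, 22),
    "EQ-short: 4": (16, 21),
    "EQ-short: 5": (20, 24),
    "EQ-short: 7": (20, 24),
    "EQ-short: 8": (16, 22),
    "EQ-short: 9": (22, 25),
    "JSE-S: 6": (20, 14),
    "EES: 2": (18, 16),
    "EES: 3": (17, 15),
    "EES: 4": (16, 14),
    "EES: 9": (18, 21),
    "EES: 10": (14, 16),
    "EES: 11": (18, 16),
    "EES: 12": (17, 17),
    "EES: 13": (22, 25),
    "EES: 14": (14, 16),
    "EES: 15": (20, 15),
}
STUDY_NODE_LABELS: tuple[str, ...] = tuple(STUDY_PRESENCE_COUNTS)


@dataclass(frozen=True)
class NetworkChange:
    """Planted pre-to-post model edits for paired designs.

    ``remove_edges``: label pairs to zero out; ``add_edges``: (a, b, weight)
    triples; ``set_weights``: (a, b, weight) reweightings;
    ``isolate_nodes``: labels whose every incident edge is removed.
    """

    remove_edges: tuple[tuple[str, str], ...] = ()
    add_edges: tuple[tuple[str, str, float], ...] = ()
    set_weights: tuple[tuple[str, str, float], ...] = ()
    isolate_nodes: tuple[str, ...] = ()

    def is_empty(self) -> bool:
        return not (self.remove_edges or self.add_edges or self.set_weights or self.isolate_nodes)


@dataclass(frozen=True)
class GroundTruth:
    """A generated paired dataset together with its generating models."""

    model_pre: IsingNetwork
    model_post: IsingNetwork
    change: NetworkChange
    params: dict = field(default_factory=dict)


def random_ising_model(
    p: int,
    edge_density: float,
    weight_range: tuple[float, float] = (-1.0, 1.0),
    threshold_range: tuple[float, float] = (-1.0, 0.0),
    seed: int = 0,
    node_labels: Sequence[str] | None = None,
) -> IsingNetwork:
    """Random sparse Ising model: Erdos-Renyi support, uniform weights/thresholds."""
    if not 0.0 <= edge_density <= 1.0:
        raise ValueError("edge_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    w = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    support = rng.random(len(iu[0])) < edge_density
    vals = rng.uniform(*weight_range, size=len(iu[0]))
    w[iu] = np.where(support, vals, 0.0)
    w = w + w.T
    tau = rng.uniform(*threshold_range, size=p)
    labels = tuple(node_labels) if node_labels is not None else tuple(f"node_{i}" for i in range(p))
    return IsingNetwork(labels, w, tau, {"seed": int(seed), "edge_density": float(edge_density)})


@njit(cache=True)
def _gibbs_kernel(weights, thresholds, n_samples, burn_in, thin, seed):
    p = weights.shape[0]
    np.random.seed(seed)
    x = np.zeros(p)
    for i in range(p):
        if np.random.random() < 0.5:
            x[i] = 1.0
    out = np.empty((n_samples, p))
    kept = 0
    sweep = 0
    while kept < n_samples:
        for i in range(p):
            eta = thresholds[i]
            for j in range(p):
                eta += weights[i, j] * x[j]
            prob = 1.0 / (1.0 + np.exp(-eta))
            x[i] = 1.0 if np.random.random() < prob else 0.0
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            for i in range(p):
                out[kept, i] = x[i]
            kept += 1
        sweep += 1
    return out


def gibbs_sample(
    model: IsingNetwork,
    n_samples: int,
    burn_in: int = DEFAULT_BURN_IN,
    thin: int = DEFAULT_THIN,
    seed: int = 0,
) -> np.ndarray:
    """Sequential-scan Gibbs samples from the model, shape (n_samples, p).

    Site i is resampled from P(x_i = 1 | x_-i) = sigmoid(tau_i + sum_j b_ij x_j);
    the first ``burn_in`` sweeps are discarded and every ``thin``-th sweep kept.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return _gibbs_kernel(
        np.ascontiguousarray(model.weights),
        np.ascontiguousarray(model.thresholds),
        int(n_samples),
        int(burn_in),
        int(thin),
        int(seed) % (2**31 - 1),
    )


def make_response_table(
    samples: np.ndarray,
    node_labels: Sequence[str],
    time_point: str = "PRE",
    participant_offset: int = 0,
) -> pd.DataFrame:
    """Wrap a sample matrix as a response table with participant/time metadata."""
    n = samples.shape[0]
    table = pd.DataFrame(samples, columns=list(node_labels))
    table.insert(0, "time_point", time_point)
    table.insert(0, "participant_id", [f"P{participant_offset + i + 1:03d}" for i in range(n)])
    return table


def exact_distribution(model: IsingNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive state enumeration (p <= 20): returns (states, probabilities).

    The unnormalized log-mass of x is sum_i tau_i x_i + sum_{i<j} b_ij x_i x_j.
    Oracle for Gibbs-sampler tests at small p.
    """
    p = model.n_nodes
    if p > 20:
        raise ValueError("exact enumeration limited to 20 nodes")
    states = ((np.arange(2**p)[:, None] >> np.arange(p)) & 1).astype(float)
    energy = states @ model.thresholds + 0.5 * np.einsum("si,ij,sj->s", states, model.weights, states)
    m = energy.max()
    probs = np.exp(energy - m)
    probs /= probs.sum()
    return states, probs


def exact_marginals(model: IsingNetwork) -> np.ndarray:
    states, probs = exact_distribution(model)
    return probs @ states


def calibrate_marginals(
    model: IsingNetwork,
    target_presence_counts: Mapping[str, int] | Sequence[int],
    N: int,
    tol: float = 0.03,
    max_iter: int = 200,
    seed: int = 0,
    samples_per_iter: int = 400,
) -> IsingNetwork:
    """Adjust thresholds (couplings fixed) until sampled marginals match targets.

    Stochastic approximation on the logit scale: each iteration Gibbs-samples
    the current model and nudges tau_i by a damped difference between target
    and achieved logit-marginals. Because a single iteration's estimate is
    noisy at the tolerance scale, apparent convergence is confirmed on a
    sample about ten times larger before stopping. Non-convergence logs a
    warning with the residuals.
    """
    if isinstance(target_presence_counts, Mapping):
        targets = np.array([target_presence_counts[lab] for lab in model.node_labels], dtype=float)
    else:
        targets = np.asarray(target_presence_counts, dtype=float)
    if np.any(targets <= 0) or np.any(targets >= N):
        raise ValueError("targets must lie strictly between 0 and N")
    target_freq = targets / N
    tau = model.thresholds.copy()
    rng = np.random.default_rng(seed)
    best_err = np.inf
    converged = False
    for it in range(max_iter):
        # decaying step and growing sample: classic stochastic approximation
        step = max(0.05, 0.8 * 0.97**it)
        n_iter_samples = samples_per_iter * (1 + it // 30)
        cur = replace(model, thresholds=tau)
        samples = gibbs_sample(cur, n_iter_samples, burn_in=300, thin=2,
                               seed=int(rng.integers(2**31 - 1)))
        achieved = samples.mean(axis=0)
        if np.max(np.abs(achieved - target_freq)) <= tol:
            confirm = gibbs_sample(cur, 10 * samples_per_iter, burn_in=300, thin=2,
                                   seed=int(rng.integers(2**31 - 1))).mean(axis=0)
            err = float(np.max(np.abs(confirm - target_freq)))
            if err <= tol:
                converged = True
                break
            achieved = confirm  # use the better estimate for the next update
        best_err = min(best_err, float(np.max(np.abs(achieved - target_freq))))
        clipped = np.clip(achieved, 0.5 / n_iter_samples, 1 - 0.5 / n_iter_samples)
        tau += step * (logit(target_freq) - logit(clipped))
    if not converged:
        logger.warning(
            "marginal calibration did not converge: best max |achieved - target| = %.3f",
            best_err,
        )
    meta = dict(model.meta)
    meta["calibrated_to"] = [float(t) for t in target_freq]
    return replace(model, thresholds=tau, meta=meta)


def likert_expand(
    binary: pd.DataFrame,
    specs: Mapping[str, InstrumentSpec],
    seed: int = 0,
) -> pd.DataFrame:
    """Replace each binary value by a uniform draw from its Likert preimage.

    Inverse of the binarization rules (reversed items respected), so
    ``binarize_table(likert_expand(B)) == B`` for any binary table B.
    """
    rng = np.random.default_rng(seed)
    out = binary.copy()
    for col in binary.columns:
        if col in META_COLUMNS:
            continue
        spec, item_no = spec_for_label(col, specs)
        pres = np.array(spec.presence_scores(item_no))
        full = np.arange(spec.scale_min, spec.scale_max + 1)
        absent = np.setdiff1d(full, pres)
        vals = binary[col].to_numpy(dtype=float)
        drawn = np.where(
            vals == 1.0,
            pres[rng.integers(0, len(pres), size=len(vals))],
            absent[rng.integers(0, len(absent), size=len(vals))],
        ).astype(float)
        out[col] = np.where(np.isnan(vals), np.nan, drawn)
    return out


def apply_change(model: IsingNetwork, change: NetworkChange) -> IsingNetwork:
    """Return the post-period model with the planted edits applied."""
    w = model.weights.copy()
    idx = {lab: i for i, lab in enumerate(model.node_labels)}
    for a, b in change.remove_edges:
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = 0.0
    for a, b, val in change.add_edges + change.set_weights:
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = float(val)
    for a in change.isolate_nodes:
        w[idx[a], :] = 0.0
        w[:, idx[a]] = 0.0
    meta = dict(model.meta)
    meta["planted_change"] = True
    return replace(model, weights=w, meta=meta)


def generate_paired_dataset(
    model_pre: IsingNetwork,
    change: NetworkChange | None = None,
    N: int = STUDY_N_PARTICIPANTS,
    seed: int = 0,
    burn_in: int = DEFAULT_BURN_IN,
    thin: int = DEFAULT_THIN,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Two independent binary response tables (PRE, POST) with a planted change.

    The post model is the pre model with ``change`` applied; both time points
    are sampled independently at N participants each (a known simplification:
    no within-participant dependence across time).
    """
    change = change or NetworkChange()
    model_post = apply_change(model_pre, change) if not change.is_empty() else model_pre
    ss = np.random.SeedSequence(seed)
    seed_pre, seed_post = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))
    pre = gibbs_sample(model_pre, N, burn_in=burn_in, thin=thin, seed=seed_pre)
    post = gibbs_sample(model_post, N, burn_in=burn_in, thin=thin, seed=seed_post)
    table_pre = make_response_table(pre, model_pre.node_labels, "PRE")
    table_post = make_response_table(post, model_pre.node_labels, "POST")
    truth = GroundTruth(
        model_pre=model_pre,
        model_post=model_post,
        change=change,
        params={"n_samples": int(N), "burn_in": int(burn_in), "thin": int(thin), "seed": int(seed)},
    )
    return table_pre, table_post, truth


def study_scale_models(
    edge_density: float = 0.12,
    weight_range: tuple[float, float] = (-0.8, 1.2),
    seed: int = 0,
    calibrate: bool = True,
    calibration_tol: float = 0.03,
) -> tuple[IsingNetwork, IsingNetwork]:
    """Paper-scale scenario: two 24-node models whose marginals match the
    printed per-item presence counts at each time point.

    Couplings are a shared sparse random graph (psychometric networks are
    mostly positive, hence the asymmetric weight range); thresholds are
    calibrated separately against the PRE and POST presence-count columns.
    """
    labels = STUDY_NODE_LABELS
    base = random_ising_model(
        len(labels), edge_density, weight_range=weight_range,
        threshold_range=(-0.5, 0.5), seed=seed, node_labels=labels,
    )
    if not calibrate:
        return base, base
    pre_targets = {lab: c[0] for lab, c in STUDY_PRESENCE_COUNTS.items()}
    post_targets = {lab: c[1] for lab, c in STUDY_PRESENCE_COUNTS.items()}
    model_pre = calibrate_marginals(base, pre_targets, STUDY_N_PARTICIPANTS,
                                    tol=calibration_tol, seed=seed + 1)
    model_post = calibrate_marginals(base, post_targets, STUDY_N_PARTICIPANTS,
                                     tol=calibration_tol, seed=seed + 2)
    return model_pre, model_post
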