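# Methods

`empathnet` implements a longitudinal item-level network analysis for
multi-instrument questionnaire data: binarize Likert responses, select items
by prevalence, estimate one sparse Ising network per time point, describe
each network by regional graph measures and map-equation communities, and
test pre/post change in a node's regional measure against a permutation
null. This note records the models, the defaults and why they were chosen,
the numerical decisions, and what the synthetic-data experiments do and do
not establish.

## Binarization and item selection

Each instrument has a cut point `c` on its response scale: an ordinary item
is scored "present/empathic/expressive" (1) iff `score >= c`; a reverse-keyed
item uses the exact complement, 1 iff `score < c`. The packaged metadata
(`data/instruments.yaml`) encodes the four instruments:

| instrument | scale | cut `c` | reversed items |
|---|---|---|---|
| DASS-21 | 0–3 | 1 | none |
| EQ-short (Korean 11-item) | 0–3 | 2 | none |
| JSE-S | 1–7 | 4 | 1, 3, 6, 7, 8, 11, 12, 14 |
| EES | 1–5 | 3 | 2, 3, 4, 7, 9, 10, 11, 12, 15, 16, 17 |

So a reversed 7-point JSE-S item maps 1–3 to "empathic" and 4–7 to "no
empathy", and a reversed EES item maps 1–2 to "expressive". The complement
rule (rather than a mirror about the scale midpoint) is deliberate: on
odd-length scales the midpoint response belongs to exactly one category and
the published dichotomization ranges above assign it to the "not endorsed"
side of the reversed key.

An item enters the network iff **both** response categories reach the
prevalence threshold `ceil(f * N)` with `f = 0.30` by default (N = 40 gives
the threshold 12). By default the criterion must hold at every time point so
both longitudinal networks share one node set; a pooled mode is available.
Near-constant items are excluded because the nodewise logistic regressions
are ill-posed for them and their network role is uninformative.

Scale totals follow each instrument's published scoring: JSE-S and EES
reverse-score their reversed items (`min + max − score`) before summing;
DASS-21 (and its depression/anxiety/stress subscales) and EQ-short sum raw
scores. Binarization is independent of total scoring. Totals are compared
between time points by a paired t-test (df = n − 1); a zero-variance
difference vector is reported as undefined rather than silently given a
p-value, except for the all-zero case, which is t = 0, p = 1.

## Ising network estimation (eLasso)

Items are binary, so the joint model is an Ising distribution with node
thresholds `tau_i` and symmetric pairwise couplings `beta_ij` in the {0,1}
coding, whose conditionals are logistic:

    P(x_j = 1 | x_-j) = sigmoid(tau_j + sum_i beta_ij x_i).

Each node is regressed on all others with an l1 penalty along a path of 100
log-spaced lambdas from `lambda_max = (1/n) max |X'(y - ybar)|` down to
`0.01 * lambda_max` (both configurable). Per node the extended BIC,
`EBIC = -2 loglik + k log n + 2 gamma k log(p-1)`, selects the penalty level;
`gamma = 0.25` by default, the convention of the estimator family this
follows. The two directed estimates for a pair are combined by the AND rule
(edge present only if both regressions select it; OR available), and the
edge weight is the arithmetic mean of the two coefficients (an absent
direction counts as 0 under OR).

Numerics: the solver is cyclic coordinate descent on the penalized logistic
objective, one proximal Newton step per coordinate with the observed
curvature, step size clipped to ±1 and coefficients capped at ±15 so
perfect separation cannot diverge (a |coefficient| > 10 in a selected model
logs a near-separation warning). A lambda is converged when a sweep improves
the objective by less than 1e-6 (or moves nothing); if a Newton sweep ever
increases the objective the lambda falls back to the provably monotone
1/4-curvature majorization update. Warm starts carry solutions down the
path. The fit is deterministic, and rows are lexicographically sorted before
fitting so the result is bitwise invariant to participant order. Unit tests
check the solution objective against an independent L-BFGS-B optimizer and
the coefficients against scikit-learn's saga l1 solver.

## Regional measures, hubs, shortest paths

Analyses run on the absolute-weight undirected network (edge signs are kept
in metadata for reporting polarity). Weight-to-length conversion is
`L_ij = 1/w_ij`, the convention of the connectivity toolbox tradition this
mirrors; `-log w` is a reasonable alternative not used here.

- **Strength**: row sums of |W|.
- **Betweenness**: Brandes algorithm on the length graph, unordered pairs,
  endpoints excluded, unnormalized (only ranks matter for hub detection).
- **Closeness**: component-scaled, `CC(v) = (r/(n-1)) * (r / sum of
  distances to the r reachable nodes)`; isolates get 0. On a connected graph
  this is the familiar `(n-1)/sum`.
- **Clustering**: the Onnela weighted form — normalize weights by the
  network maximum, average the cube root of triangle weight products over
  neighbour pairs; degree < 2 gives 0.
- **Shortest paths**: Floyd–Warshall distances; path reconstruction greedily
  takes the lowest-index next hop among geodesic-consistent neighbours, so
  reported sequences are the lexicographically smallest geodesics and
  reproducible when ties occur.

Hubs: competition ranks (ties share the best rank) on strength, betweenness
and closeness; a node is a hub if it ranks within the top
`round(0.20 * p)` (p = 24 gives 5) on at least two of the three measures.
Clustering never enters hub detection. If ties push more than the cutoff
number of nodes into the top set, all tied nodes are kept and a warning
logged. Hub sets are reported per time point plus their union, since a
"hub at either time point" reading is also defensible.

## Map-equation communities

Communities minimize the two-level map equation on the absolute-weight
network: with stationary visit rates `p_i = s_i / 2W` (strength-proportional,
no teleportation — appropriate for undirected networks) and module exit
rates `q_m = cut(m) / 2W`,

    L(M) = (sum_m q_m) H(Q) + sum_m p_m_circ H(P_m),   all logs base 2,

the expected per-step description length of a random walk under a module
index codebook plus per-module codebooks. The optimizer is a seeded
Louvain-style local search: from singleton modules, repeated single-node
moves to the neighbouring module with the largest codelength decrease,
alternated with module merges, until no move improves L by more than 1e-10;
10 random-restart node orders by default, best partition returned, and never
worse than the single-module baseline. Two-level only — no hierarchical
recursion. For networks of up to 10 nodes an exhaustive set-partition
enumeration provides the exact optimum and is used as the test oracle
(the optimizer matches it on ≥95% of random instances in the suite).
Codelengths are reported for logging, but community output is compared
structurally; no restart count was tuned per dataset.

## Permutation test for longitudinal change

The observed statistic for node v and measure m (clustering by default;
strength, betweenness, closeness available) is `m_post(v) - m_pre(v)` with
each network refit on its own time point's records. The null distribution
refits both networks after randomly splitting the pooled 2N records into
two pseudo-groups of N, unrestricted by participant — matching a design in
which all participant-time records are permuted into two subgroups; a
paired-flip mode (per-participant label swap) is provided as an option.
The two-sided p-value uses the add-one estimator
`p = (1 + #{|null| >= |obs|}) / (1 + B)`, so p is never exactly zero.
Pseudo-groups in which any node is constant are redrawn (counted and
reported); the production default is B = 5000, while tests and examples use
a few hundred for desk-scale runtime. No multiple-testing correction is
applied by default (the pipeline screens at a fixed threshold, 0.015 by
default); an optional Benjamini–Hochberg step over all tested nodes is
available.

## Synthetic data

The generator emulates the structure the analysis assumes: a known sparse
Ising model (Erdős–Rényi support, uniform signed weights, uniform
thresholds), sequential-scan Gibbs sampling (default burn-in 1000 sweeps,
thinning 10), a Likert-expansion layer that draws uniformly from the exact
preimage of each binary value under the binarization rules (so
binarize ∘ expand is the identity), and paired pre/post datasets in which
the post model differs by a declared edit (edges added, removed, reweighted,
or a node isolated). For up to ~20 nodes the exact state distribution is
computable by enumeration and anchors the sampler's correctness tests
(chi-square against the 2^p probabilities; total-variation < 0.05 at 10k
sweeps).

The study-scale scenario builds a 24-node model whose node labels are the
retained items of the study and calibrates thresholds (couplings fixed) by
damped stochastic approximation on the logit scale until sampled marginal
frequencies match the published per-item presence counts (tolerance ±0.03,
at most 200 iterations, non-convergence logged with residuals).

What the generator does **not** emulate: within-participant dependence
across time points (the two waves are independent draws), item wording
effects, and covariate structure. Passing tests therefore demonstrate that
the pipeline recovers network structure and planted longitudinal change from
data whose generating process matches the model class — not that the model
class fits any particular real dataset.

## Validation experiment design

The heavyweight suites fix these conditions (chosen once, a priori, at desk
scale):

- **Chain recovery**: 6-node chain, couplings +1, thresholds −0.5, 1000
  Gibbs samples, default estimator settings; support, false positives and
  sign agreement summarized by the median over 20 seeds.
- **Type-I calibration**: both "time points" drawn from one 5-node chain
  (couplings +1, thresholds −0.5) at N = 40 per group — the study's sample
  size; monitored measure: strength of the middle node. Strength was chosen
  over clustering because a sparse 40-subject network's clustering is almost
  always exactly 0, which degenerates the null into ties; strength varies
  continuously. Thinning is generous (every 25th sweep) because the
  permutation null assumes exchangeable records: leftover autocorrelation
  within a Gibbs chain groups records by chain and measurably inflates the
  rejection rate. 200 replicate datasets × 200 permutations.
- **Planted-change recovery**: a 6-node model with a 4-clique (couplings
  +1.2, clique thresholds −1.8) plus a 3-node tail; the post model isolates
  one clique node. The clique makes the node's clustering degrade gracefully
  when single edges drop out of a refit, so the permutation null is
  continuous rather than 0/1-valued. 200 records per group, 200
  permutations, 50 seeds; recovery = the planted node tops |clustering
  change| and is flagged at p < 0.05 in the majority of seeds.

Permutation-heavy simulations use a shortened penalty path (25 lambdas down
to 0.05·lambda_max); EBIC selections on these problems are insensitive to
the deep tail of the path, which is the expensive, near-separated region.

## Known limitations

- eLasso estimates conditional dependence; strongly collinear blocks (very
  large couplings) can legitimately drop redundant triangle edges, deflating
  clustering estimates.
- N = 40 is small for 24-node network estimation; fitted study-scale
  networks are sparse and individual edges unstable. The pipeline reports
  what the method yields at that size; it does not bootstrap edge stability.
- The permutation null assumes exchangeable records under the null;
  within-participant pairing is broken by the default unrestricted split
  (the paired mode exists but changes the null hypothesis).
- The map-equation optimizer is a local search; global optimality is only
  guaranteed where enumeration is feasible (n ≤ 10).
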