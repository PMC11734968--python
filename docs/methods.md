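# Methods

## Model and estimation

The core object is a pairwise Markov random field over $p$ variables of
mixed domains. Continuous nodes have linear-Gaussian conditionals;
categorical nodes (with $L \ge 2$ unordered levels) have
multinomial-logistic conditionals; a single symmetric matrix of pairwise
interaction weights (zero = conditional independence) couples them. For an
all-continuous model this is the Gaussian graphical model: with weights $W$
and a diagonal loading $a$, the precision matrix is $\Theta = aI - W$ and
the partial correlation of a pair is $-\Theta_{ij}/\sqrt{\Theta_{ii}\Theta_{jj}}$.

Estimation is neighborhood selection: every node is regressed on all
others with an ℓ1 penalty. Continuous responses use coordinate-descent
lasso over a log-spaced grid of 50 penalties from $\lambda_{\max}$ (the
smallest penalty with an all-zero fit) down to $0.01\,\lambda_{\max}$;
categorical responses use saga-solver multinomial logistic regression,
warm-started along the same kind of grid. The per-node penalty is chosen by
EBIC with $\gamma = 0.25$; `df` counts nonzero coefficients of the
penalized fit (no refitting), and EBIC ties go to the larger penalty
(sparser model). Continuous variables are standardized (mean 0, sample SD
1, ddof = 1) before every fit so edge weights are comparable across
variables; categorical predictors are dummy-coded against their first
level.

Aggregation: the directed strength $s \to t$ is the mean absolute value of
all coefficient terms linking $t$ in $s$'s regression (several terms when
dummy levels are involved). Under the default AND rule an edge exists only
if both directions are nonzero, with magnitude the mean of the two directed
strengths; the OR rule keeps single-direction edges. A sign (±1) is
attached only to continuous–continuous edges whose two directed
coefficients agree; all categorical-involving edges are unsigned. The AND
rule is the stricter, higher-specificity convention; OR networks always
contain the AND network as an edge subset.

Nodewise predictability is in-sample: $R^2$ of the selected linear model
for continuous nodes, classification accuracy (with the marginal-mode
baseline alongside) for categorical nodes.

Moderated models augment every nodewise regression (except the moderator's
own) with product terms between each remaining predictor term and a
designated continuous, standardized moderator. Three-way strengths are
aggregated with the same mean-of-absolutes + AND convention applied to the
two product coefficients of a pair. Categorical moderators are not
supported.

## Bootstrap stability

$B$ resamples of $n$ rows with replacement (default $B = 1000$; the test
profile uses $B = 100$); the whole estimation — standardization, penalty
re-selection, aggregation — is re-run per resample. Per edge we report the
nonzero proportion, the empirical quantile interval (default level 0.95) of
resampled magnitudes, and a band: very stable (> 0.90), relatively stable
(0.85–0.90, boundary inclusive], unstable otherwise. Resamples with a
zero-variance continuous column are redrawn and counted. Edges absent from
the full-data network still receive bootstrap statistics and are flagged.

## Communities

A $k$-clique ($k \ge 3$) is admitted when its intensity — the geometric
mean of its edge magnitudes (signs ignored; percolation operates on
strength) — is at least $I$ (closed threshold). Communities are node
unions of connected components of the clique adjacency graph (two cliques
adjacent when sharing $k-1$ nodes); nodes may belong to several
communities or to none. The threshold grid evaluates every $k \in \{3,4\}$
(configurable) and $I \in \{0, \delta, 2\delta, \dots\}$ with
$\delta = 0.005$.

Partition entropy pools isolated nodes as one pseudo-community and splits a
shared node equally among its communities, then takes the Shannon entropy
(bits) of the effective size distribution. The permutation null shuffles
the multiset of edge magnitudes onto a uniformly random set of node pairs
(edge count preserved, degree sequence not), records the maximal entropy
over the $I$ grid per permutation and $k$ (default 100 permutations), and
uses the 97.5th percentile of those maxima as the 95% upper bound.

Solution selection is codified as a deterministic rule so runs are
auditable: the *ratio candidate* is, for the smallest $k$ that has one, the
largest $I$ with a largest/second-largest size ratio ≥ 2 (at least two
communities required — a lone community has ratio ∞ but no crossing); the
*entropy candidate* maximizes grid entropy. The final choice applies, in
order: no giant component (largest community ≤ 50% of non-isolated nodes),
fewer isolated nodes, more communities, higher entropy; the emitted
rationale records every comparison.

Local structure: for node $v$ in community $c$, the stabilizing index sums
$|w|$ over $v$'s edges to co-members of $c$ and the communicating index
sums $|w|$ over edges to members of other communities; edges to
community-less nodes count toward neither (their omitted strength share is
logged). Absolute weights are the default because the indices are read as
strengths; signed sums are available behind a flag. Per community the top
two stabilizers/communicators are flagged, extended to three when the third
trails the second by at most 0.05 (an explicitly arbitrary, configurable
window). Subscale re-analysis replaces mapped constructs by their subscale
columns, re-estimates the MGM on the community's node set alone, and
exports a display view suppressing (not deleting) edges ≤ 0.05.

## Synthetic data

The generator samples from the same pairwise family the estimator assumes,
so consistency checks are meaningful. Planted models are block-structured:
every within-community pair gets $\pm w_\text{within}$ (a fixed ≈ 25%
negative share mirrors real mixed-sign networks), a sparse set of
between-community pairs gets $\pm w_\text{between}$, and isolated nodes get
no edges. Categorical nodes interact through centered unit-variance level
scores, giving multinomial-logistic conditionals.

**Positive-definiteness and attenuation.** Equal partial correlations
$\rho$ across a complete $m$-clique are only realizable for
$\rho < 1/(m-1)$. When the requested block weights violate this, the
minimal diagonal loading $a = \max(1, \lambda_{\max}(W) + 0.05)$ restores
positive definiteness and attenuates every partial uniformly by $1/a$
(preserving the within/between contrast that matters for structure
recovery); a warning reports attenuation beyond 5%. For a 12-node block at
weight 0.3 the realized partials are ≈ 0.13. Consequences for testing are
discussed under *Limitations*.

All-continuous models without moderation are sampled exactly from the
implied Gaussian on the unit-variance (correlation) scale. Mixed or
moderated models use parallel-chain Gibbs: one independent chain per
observation, 200 burn-in sweeps of sequential full-conditional updates,
one draw per chain — exactly independent rows, vectorized across chains
(thinning is moot in this scheme). Because a pairwise density with
three-way terms is non-normalizable on an unbounded domain, continuous
Gibbs draws are truncated to ±3 SD, and the loading additionally bounds the
worst-case moderation coupling $|t| \cdot 3$ on the three pairs each term
touches, keeping every conditional subsystem well-defined on the truncated
support. Gibbs-sampled continuous columns are empirically standardized
before de-standardization, so requested means/SDs are matched exactly.

The 30-node *study mimic* has 28 continuous constructs calibrated to
published descriptive statistics (e.g. mental well-being 55.6/5.88,
quality of life 94.7/9.46), one 8-level and one 3-level categorical
history variable, and five planted overlapping communities of sizes
(12, 6, 6, 4, 4) chained by single shared nodes, with the categorical
nodes attached only weakly (community-less). Default $n = 2000$,
$w_\text{within} = 0.3$, $w_\text{between} = 0.05$. The generator does not
emulate item-level responses, skewness, floor/ceiling effects, or
longitudinal structure — passing tests demonstrate correctness of the
machinery under the assumed model class, not robustness to real-data
violations of it.

A separate helper emulates a preprocessing exclusion flow: a 2886-row
completer table with 176 invalid-postal rows and 217 planted
physical-activity outliers whose bulk distribution is uniform, so the
robust MAD filter (normal-consistent constant 1.4826, threshold 2.5) flags
exactly the planted rows after the postal exclusion; ordered application
yields 2493 eligible and the first 2000 selected.

## Numerical choices

- MAD = 0 (degenerate scale): no observations are flagged and a warning is
  emitted; a constant column carries no outlier information.
- Coefficients with absolute value ≤ 1e−6 count as zero (the saga solver
  can leave sub-threshold noise where coordinate descent returns exact
  zeros).
- The multinomial penalty path stops early after 8 consecutive
  non-improving EBIC evaluations; descending further only densifies the
  model. Non-converged penalties are skipped with a warning.
- Gaussian log-likelihoods use the profile variance RSS/$n$ with a 1e−12
  floor.
- Quantile intervals are empirical percentiles; no bias correction.
- All pipeline randomness derives from one root seed via independent
  spawned substreams (data, bootstrap, permutations), each below $2^{31}$.

## Test problem sizes

The suite validates each stage at sizes chosen for fast, stable checks:
exact two-route oracles at $p \le 10$; sampler calibration at
$n = 50{,}000$; estimator oracles at $p = 10$, $n = 5000$ (20 seeds for
false-positive rates); percolation against brute-force subset enumeration
on 100 random networks with ≤ 10 nodes; the full pipeline on the 30-node
mimic at $n = 2000$ with $B = 100$ and 100 permutations; stability banding
over 20 seeded runs at $B = 100$; moderation power/null at $n = 5000$ /
$n = 2000$.

## Known limitations

- **Attenuated planted weights.** Large planted cliques cannot carry their
  nominal partial correlations (see above); per-edge recovery power at the
  feasible ≈ 0.13 partials with $n = 2000$ and the AND rule is ~93–98%,
  so exact recovery of every planted community is itself a stochastic
  event — the pipeline recovers the cover exactly in a minority of seeds
  and near-exactly (per-community Jaccard > 0.9) in all tested seeds.
- **Entropy permutation null under homogeneous weights.** Shuffling edge
  magnitudes onto random pairs places the permuted graph near its clique-
  percolation transition for some $I$, where it splinters into many small
  communities with entropies that can exceed the clean modular partition's
  entropy. For planted networks whose edge weights are nearly equal, the
  observed maximal entropy therefore typically falls *inside* the null
  band; the null comparison is informative mainly for networks with
  heterogeneous weights. The permutation scheme is isolated behind one
  function and swappable.
- In-sample predictability is optimistic relative to cross-validated
  estimates for weakly connected nodes.
- The moderated stage supports a single continuous moderator per run and
  no higher-order interactions beyond the three-way products.
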