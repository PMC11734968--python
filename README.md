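# mgmnet

Cross-sectional **network analysis of mixed psychological and lifestyle
data**: estimate a pairwise Mixed Graphical Model (MGM) over continuous and
categorical variables, quantify edge stability by bootstrap, measure
nodewise predictability, find **overlapping communities** by weighted clique
percolation with a principled threshold search, and summarize each node's
local role through stabilizing/communicating indices. A moderated-model
stage estimates three-way interactions for a designated moderator.

The package is aimed at researchers in epidemiology and psychometrics who
relate a panel of risk/protective factors (well-being, coping, stress,
health, demographics, disease history, …) to outcomes such as mental
well-being and quality of life, and who need every stage of that analysis
to be reproducible and testable. Because such inventories are rarely
shareable, a first-class synthetic-data module generates mixed datasets
from *planted* models — block-structured dependence with known community
labels, calibrated to realistic construct means/SDs — so each stage of the
pipeline can be validated against ground truth.

## The model

For variables $x_1,\dots,x_p$ of mixed domains, the pairwise MGM is a
Markov random field in which each node's conditional distribution is in an
exponential family — Gaussian for continuous nodes, multinomial for
categorical ones. Estimation is by **nodewise ℓ1-regularized regression**:
node $s$ is regressed on all other variables (categorical predictors
dummy-coded) over a descending λ path, and λ is selected by the Extended
Bayesian Information Criterion

$$\mathrm{EBIC}_\gamma = -2\,\ell + \mathrm{df}\,\ln n + 2\gamma\,\mathrm{df}\,\ln q,
\qquad \gamma = 0.25,$$

with $q$ the number of candidate terms. An edge $(s,t)$ is kept under the
AND rule when both nodewise fits select the pair; its magnitude is the mean
of the absolute coefficients linking the two nodes, comparable to a partial
correlation for Gaussian pairs (edges touching a categorical node are
unsigned). Edge stability is banded from $B$ nonparametric bootstrap
re-estimations (very stable > 90% nonzero resamples; relatively stable
85–90%; otherwise unstable). Communities are unions of adjacent $k$-cliques
(sharing $k-1$ nodes) whose **intensity** — the geometric mean of the
clique's edge magnitudes — reaches a threshold $I$; $(k, I)$ is chosen by
the largest-to-second-largest size *ratio* (crossing 2) and the partition
*entropy* (isolated nodes pooled, shared nodes split equally), checked
against a 100-permutation null.

## Worked example

```python
from mgmnet import (study_mimic, estimate_mgm, threshold_grid,
                    permute_entropy_null, select_solution, predictability)

model, data = study_mimic(seed=7, n=2000)      # 30-node mixed mimic
network, fits = estimate_mgm(data)              # EBIC(γ=0.25) + AND rule
print(f"estimated edges: {int((network.magnitude > 0).sum()) // 2}")

grid = threshold_grid(network, k_values=(3, 4), I_step=0.005)
null = permute_entropy_null(network, n_perm=100, seed=8)
solution = select_solution(grid, null).chosen
print(f"chosen k={solution.k}, I={solution.I:.3f}")
print(f"community sizes: {sorted(solution.sizes, reverse=True)}")
print(f"size ratio: {solution.ratio:.2f}, entropy: {solution.entropy_bits:.2f} bits")

pred = predictability(data, fits)
print(f"R2(MWB) = {pred.r2['MWB']:.2f}, R2(QoL) = {pred.r2['QoL']:.2f}")
```

prints

```
estimated edges: 109
chosen k=3, I=0.115
community sizes: [12, 6, 6, 4, 3]
size ratio: 2.00, entropy: 2.36 bits
R2(MWB) = 0.62, R2(QoL) = 0.74
```

The generator planted five overlapping communities of sizes
(12, 6, 6, 4, 4) over 28 continuous constructs plus two categorical
disease-history variables; the pipeline re-identifies that structure from
the sampled data (here one node of the smallest block fell below the
detection threshold), and the nodewise R² quantify how well each construct
is explained by its estimated neighborhood.

The same analysis runs from the shell: `mgmnet run --config config.yaml`
(with verbs `simulate`, `preprocess`, `estimate`, `bootstrap`,
`communities`, `indices`, `moderate` for individual stages). All outputs —
edge lists, stability and predictability tables, threshold grid, chosen
solution with its selection rationale, index tables and a run manifest —
are written as CSV/GraphML/YAML into the configured output directory, and a
fixed seed reproduces every file byte-identically.

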