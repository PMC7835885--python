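# Methods

This note documents the models and procedures implemented in `physnet`, the
parameter choices that matter, and the limits of what the synthetic-data
tests demonstrate.

## Synthetic cohorts

Real biomarker panels in cohorts of ~100–150 subjects show (i) asymmetric,
heavier-tailed-than-normal marginals, (ii) a block-structured inter-variable
correlation reflecting functional systems (body size, immune cells, lipids,
red-cell indices, endocrine regulation, ...), and (iii) rare gross outliers
from measurement or transcription error. The generator reproduces exactly
these three features and nothing more.

**Model.** A Gaussian copula: latent Z ~ N(0, R) with R block-constant —
`within_rho` on the diagonal blocks, `between_rho` elsewhere — mapped to
uniforms by the normal CDF and to lognormal, gamma, or normal marginals by
their quantile functions. The copula was chosen over empirical resampling
because it gives a closed-form population Spearman correlation,
ρ_S = (6/π)·asin(ρ_latent/2), which the tests use as an exact target.
R must be positive definite; generation rejects otherwise, reporting the
offending eigenvalue. `between_rho` must be strictly below every
`within_rho` so the planted partition is the natural block structure.

**Defaults.** Marginals are lognormal with σ = 0.6 (strong right skew and
excess kurtosis, typical of hormone and inflammation markers) and unit scale;
the benchmark cohort has 150 subjects and six blocks of 8–12 variables with
`within_rho` = 0.6 and `between_rho` = 0.1 — block counts and cohort size in
the range typical of physiological-network studies, within-block correlation
strong enough that a cohort of 150 resolves it at p < 0.001, between-block
correlation weak enough to be mostly filtered at that threshold. No study
reports per-variable distribution parameters for its biomarkers, so the
defaults are generic placeholders, not estimates of any real cohort.

**Outliers and missingness.** Outliers are injected after the marginal
transform (a transcription error is unrelated to the biological tail): each
cell is displaced with probability `rate` by `magnitude` × column IQR with
random sign; positions are logged. Missingness is optional
missing-completely-at-random, present to exercise the pairwise-complete
correlation path.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: realistic per-biomarker value ranges and units,
longitudinal structure, non-monotone dependence, heteroscedastic measurement
error, and informative missingness.

## Preprocessing

*Normalization* is x_i = (V_i − Me)/(Max − Min) per variable (median center,
range scale — the robust choice for skewed, leptokurtic marginals). It is
affine per column, so Spearman matrices before and after agree entrywise;
constant columns raise an error naming the variable.

*Outlier screen (ROUT).* ROUT is defined for regression; biomarker columns
are screened as a robust constant fit (the column-outlier reading): location
= median, robust scale RSDR = 68.27th percentile of absolute residuals with
an n/(n−1) small-sample correction, residual/RSDR referred to a t
distribution with n−1 df, and Benjamini–Hochberg control at level Q
(default 0.01) flags outliers. Flagged values become missing cells rather
than dropped subjects, so the pairwise-complete correlations keep every
untouched observation. Columns with fewer than 10 values or zero robust
scale are skipped and reported. At Q = 1 the procedure degenerates to
BH at level 1 — it flags the most extreme residuals and flags nothing when
residuals carry no variation.

*Normality screen.* Shapiro–Wilk W and p per variable, reported only; the
routine rejection of normality is the justification for rank-based
correlation, never a data modification.

*Derived variables.* The clinically standard indices are computed from their
parents: MAP, BMI, body-composition percentages, differential leukocyte
proportions, Castelli ratios, HOMA-IR and HOMA-β, BUN, and FEV1/FVC. HOMA
uses glucose in mmol/L (mg/dL ÷ 18.016) and insulin in mIU/L — fixed
explicitly because published formula tables mix units. The fat-free-mass
proportion uses the bioimpedance lean-mass variable as the fat-free mass.
Spirometry predicted-value equations are excluded (they depend on external
reference equations), as are the body-fat and lean-mass height indices whose
published formulas are not recoverable. Derived variables append columns
only; parents are never mutated, and which deriveds enter the network is a
configuration choice.

## Network inference

Spearman ρ is the Pearson correlation of midrank vectors computed on each
pair's complete observations; the per-pair sample count feeds the
significance t = ρ·√((n−2)/(1−ρ²)) with n−2 df (two-sided; p = 0 at |ρ| = 1
by convention, untestable below 4 shared observations). The t approximation
is retained with ties. No multiple-testing correction is applied by default
— the threshold grid is the sensitivity analysis — but Bonferroni/BH
options exist on `build_network`.

Edges carry weight ρ² (association strength regardless of sign) with signed
ρ, p, and n kept as attributes; isolates are retained as nodes. The default
scan grid is {0.05, 0.01, 5e−3, 1e−3, 5e−4, 1e−4, 1e−5, 1e−6};
`select_threshold` returns the smallest α with connectedness ≥ 0.95
(largest grid α with a warning if none qualifies). Because thresholds are
nested, edge counts are monotone along the grid, and the links removed by
tightening are on average the weakest.

## Topology panel

- **Density** m/C(n,2); **Krackhardt connectedness** = fraction of node
  pairs joined by a path; **Krackhardt efficiency**
  1 − (m − (n − c))/(C(n,2) − (n − c)) clipped to [0,1] (trees score 1,
  complete graphs 0; defined as 1 when the denominator vanishes).
- **Characteristic path length L**: mean hop count over reachable pairs
  only (the social-network-toolkit convention for disconnected graphs).
  Path metrics are deliberately unweighted: reported L values on the
  1–3 scale reflect hop-based paths even on weighted networks.
- **Clustering**: Barrat's weighted local coefficient
  c_i = [1/(s_i(k_i−1))]·Σ_(j,h) (w_ij + w_ih)/2 over ordered connected
  neighbor pairs; T is the k_i(k_i−1)-weighted mean (reduces to classical
  transitivity at unit weights) and CC the plain mean, both over nodes with
  degree ≥ 2.
- **Small world**: SWI = (C/C_rand)/(L/L_rand) with analytic baselines
  C_rand = k̄/n, L_rand = ln n/ln k̄ on the main component (unweighted
  transitivity for C); *smallworldness* is the Humphries–Gurney σ with
  baselines averaged over B seeded G(n, m) graphs (default B = 100; B = 20
  inside threshold scans to keep them fast).
- **Scale-free fitting index**: non-isolated degrees binned into 10
  equal-width bins; OLS of log10 frequency on log10 mean bin degree; R² is
  reported as the index and the slope separately (a regular graph, with one
  bin, is undefined).
- **Reciprocity** is identically 1 for undirected graphs and is reported as
  such, never analyzed.

## Centrality

Eigencentrality is the Perron eigenvector of the weighted adjacency,
computed by power iteration on A + I (the shift prevents period-2
oscillation on bipartite components without changing the eigenvector) to
relative tolerance 1e−10 and rescaled so max = 1. Freeman flow betweenness
uses edge capacities = ρ² weights — chosen for consistency with the
weighted graph, with binarization available by dropping weights — and is
computed exactly via Gomory–Hu trees (one tree per node deletion gives all
pairwise max flows); values are raw, with a fraction-of-flow normalization
flag. Edge betweenness counts unweighted shortest paths fractionally.
Freeman centralization defaults to the relative form
Σ(c_max − c_i)/((n−1)·c_max) with the observed maximum; the canonical
(n−1)(n−2) star denominator for raw degree is available as an option.
Centrality assortativity is the Pearson correlation of endpoint centralities
with each undirected edge counted in both orientations. Hub scores are
omitted: on undirected graphs they coincide with eigencentrality.

## Communities

Louvain (two-phase greedy weighted-modularity optimization, resolution 1,
seeded node order) and a two-level map-equation method. The map-equation
search delegates to igraph's InfoMap; the description length
L(M) = q·H(Q) + Σ_i p_i⟲·H(P_i) (bits, stationary probabilities ∝ node
strength on undirected graphs) is evaluated in-package for every returned
membership, so reported codelengths are reproducible from the membership
alone and serve as an independent check on the search. Reported modularity
always equals the exact weighted Newman Q of the returned membership.
Community labels are contiguous from 1 with a deterministic canonical
ordering. Subclustering reruns the chosen method on each induced community
subgraph. Partition agreement uses the plain Rand index (the common toolkit
default) and variation of information in nats; the adjusted Rand index is
used for planted-recovery criteria because it is chance-corrected. Cluster
contraction collapses each community onto its strongest member (ties by node
id) and keeps every inter-community edge individually as a multigraph; a
simple projection summing parallel weights is provided for path-based
metrics.

## Permutation inference

CUG tests binarize the observed graph (conditioning "uniform given edges"
is ill-posed for continuous weights) and compare a statistic against R
random graphs conditioned on size (each edge Bernoulli 0.5) or on the
observed edge count (uniform G(n, m); the dyad-census condition coincides
with it for undirected graphs). QAP correlates two aligned weighted
adjacencies (upper triangles, absent edges contributing 0) and permutes
node labels of the second network simultaneously in rows and columns.
Defaults: R = 1000 draws, seeded; p-values use add-one smoothing
(1 + #{draws ≥ observed})/(R + 1), so they are never exactly zero; the
one-sided p_greater is the headline QAP value. Two-network comparison
restricts node strength, eigencentrality, and flow betweenness to shared
nodes (Spearman correlations), correlates weights over edges present in
both (reported missing below 3 shared edges), and runs gcor + QAP on the
shared-node subgraphs.

## Robustness

Connectivity loss after removing a node set is 1 − (connected surviving
pairs)/(connected intact pairs). Strategies: random failure (curve averaged
over 50 repetitions by default), static degree- and betweenness-ranked
attacks, and a cascading attack that recomputes shortest-path betweenness
after every removal — the recalculated-betweenness convention, not a
load-capacity cascade model. Betweenness is unweighted, the robustness-
literature default. Ties break by ascending node id, making deterministic
curves bit-for-bit reproducible; loss is monotone non-decreasing along any
removal sequence. Curves and their AUC are exported; significance testing
across strategies is left to external tools.

## Numerical choices and degenerate inputs

Undefined metrics (no reachable pairs, no degree-2 node, a single degree
bin, zero centrality variance) raise a typed error at the function level and
are recorded as missing by the summary and scan layers, which continue.
Constant columns are rejected by normalization, skipped by the outlier
screen, and marked untestable by correlation (p = 1, no NaN propagation).
Every stochastic stage (simulation, Louvain order, InfoMap, permutation
draws, random-graph baselines, attacks, layouts) draws a named child seed
from one master seed, so pipeline reports are byte-identical across runs of
the same configuration.

## Problem sizes

The bundled benchmarks use cohorts of 150 subjects × ~60 variables,
calibration sweeps of 200 replicates (null-edge and QAP type-I rates),
20-seed recovery and attack-ordering panels, and n = 5000 draws for the
copula closed-form check — sizes at which Monte-Carlo standard errors are
small relative to the tested tolerances while the full suite stays
inexpensive to run.

## Known limitations

Correlation networks infer association, not causation or direct interaction;
partial-correlation and Gaussian graphical models are out of scope. The
efficiency and connectedness formulas follow the Krackhardt definitions;
published analyses sometimes use toolkit-specific variants, so printed
values from other software may differ in the second decimal. CUG conditioning
ignores weights by design. The map-equation optimizer is two-level only (no
hierarchical coding), and spinglass clustering, overlapping communities,
consensus clustering, edge-removal attacks, and percolation theory are not
implemented.
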