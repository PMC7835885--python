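# physnet

Correlation-based **physiological networks** from biomarker panels.

Clinical and physiological studies routinely measure dozens of heterogeneous
variables per subject — blood pressure, anthropometry, bioimpedance, blood
counts, blood chemistry, hormones. `physnet` turns such a subjects × variables
table into a weighted, significance-thresholded association network and
characterizes it: which variables cluster into functional systems, which act
as hubs or gatekeepers, how the topology depends on the significance
threshold, and how fragile the network is under targeted node removal.

The package is aimed at systems-physiology and network-medicine researchers
who want a reproducible, fully seeded implementation of this workflow, with a
synthetic-cohort generator (Gaussian copula with planted correlation blocks)
so every stage is testable without access to patient data.

## Method

For every pair of variables (X, Y), the Spearman rank correlation is computed
on pairwise-complete observations with midranks for ties,

ρ = cov(rk_X, rk_Y) / (σ_rk_X · σ_rk_Y),

and its two-sided significance from t = ρ·√((n−2)/(1−ρ²)) on n−2 degrees of
freedom. Pairs with p < α become edges with weight ρ² (the sign and p-value
are retained as edge attributes); isolated variables stay in the node set.
Rank correlation makes the network invariant under the median-range
normalization x_i = (V_i − Me)/(Max − Min) applied per variable, and robust
to the asymmetric, leptokurtic marginals typical of biomarkers. Gross
outliers are screened per variable beforehand with a ROUT-style robust-fit,
FDR-controlled test (flagged cells become missing values, not dropped
subjects).

The threshold α is chosen by scanning a decreasing grid and taking the
smallest α that keeps Krackhardt connectedness above a floor (default 0.95):
strict enough to delete redundant collinear links, loose enough to keep the
network connected. The thresholded network is then summarized by density,
Krackhardt connectedness and efficiency, hop-based characteristic path
length L, Barrat weighted transitivity T and clustering coefficient CC,
small-world indices against analytic and Monte-Carlo random baselines, a
log-log binned scale-free fitting index R², eigencentrality and Freeman flow
betweenness with their centralizations and assortativities, Louvain and
two-level map-equation communities, conditionally-uniform-graph (CUG) and
quadratic-assignment (QAP) permutation tests, and attack-tolerance curves
(random failure vs degree-, betweenness- and cascading-betweenness-directed
removal).

## Worked example

```python
import physnet as pn

spec = pn.CohortSpec(
    n_subjects=150,
    blocks=[
        pn.BlockSpec("body_size", 10, 0.6),
        pn.BlockSpec("immune_cells", 9, 0.6),
        pn.BlockSpec("lipids", 8, 0.6),
        pn.BlockSpec("red_cell_indices", 8, 0.6),
        pn.BlockSpec("endocrine", 7, 0.6),
        pn.BlockSpec("oxidative_stress", 6, 0.6),
    ],
    between_rho=0.1,
    seed=42,
)
table, planted = pn.generate_cohort(spec)
table, _ = pn.normalize_median_range(table)
corr = pn.spearman_matrix(table)
scan = pn.threshold_scan(corr, seed=0, B=20)
alpha = pn.select_threshold(scan, min_connectedness=0.95)
net = pn.build_network(corr, alpha, meta=table.meta)
summ = pn.summarize(net, B=100, seed=0)
part = pn.louvain(net, seed=0)
```

printing

```
selected alpha: 0.005
nodes=48 edges=225 density=0.199 connectedness=1.00
L=2.51 T=0.75 CC=0.81 SWI=2.42 sigma=2.66
louvain: 6 communities, Q=0.767
adjusted Rand vs planted blocks: 1.000
```

A cohort of 150 subjects and 48 variables in six planted functional blocks
(latent correlation 0.6 inside blocks, 0.1 across) yields, at the selected
threshold α = 0.005 — the smallest grid value keeping connectedness ≥ 0.95 —
a fully connected 48-node network. Its characteristic path length
(~2.5 hops), high clustering (CC ≈ 0.8) and small-world sigma ≈ 2.7 mark a
topology between ordered and random, and Louvain recovers the six planted
blocks exactly (adjusted Rand = 1).

The same workflow is available from the shell:

```bash
physnet simulate --config cohort.yaml --out cohort
physnet correlate --values cohort.csv --meta cohort.variables.csv --out corr
physnet scan --corr corr --out scan.csv
physnet build --corr corr --alpha 0.001 --out net.graphml
physnet topology --network net.graphml
physnet cluster --network net.graphml --method both --out members.csv
physnet attack --network net.graphml --out attack.csv
physnet run --config pipeline.yaml   # everything, from one declarative file
```

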