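# mutnet

Tools for asking how the **topology of a metabolic network** relates to the
**sensitivity of its metabolites to spontaneous mutation**, in the setting of
a mutation-accumulation (MA) experiment: replicate lines descended from a
common ancestor, propagated at minimal effective population size for *t*
generations so that new mutations fix nearly free of selection, then assayed
for metabolite concentrations in replicate.

The package is aimed at evolutionary systems biologists who have (a) a
reaction database from which a directed metabolite network can be built and
(b) line × replicate × metabolite trait measurements from an MA panel — or
who want to explore the design by simulation, for which a generator with
closed-form ground truth is included.

## What it computes

**Network layer.** From a reaction table, a simple directed graph on
metabolites (substrate → product; reversible reactions contribute both
directions) after removal of currency metabolites (ATP, H₂O, NADH, …), which
otherwise collapse nearly all shortest paths to ≤ 3 steps. Six per-metabolite
network parameters: betweenness c_B(v), closeness C(v) (incoming distances,
reachable-set scaling), degree centrality (deg⁺+deg⁻)/(n−1), in-degree,
out-degree, and core number k(v) from k-core peeling of the undirected
projection. Directed and undirected shortest-path-length matrices, with
unreachable pairs kept as an explicit marker.

**Mutational layer.** Per metabolite, from MA trait data by REML under a
one-way random-effects model (lines random, unbalanced replication):

- mutational bias ΔM = (z̄_MA − z̄₀)/(t·z̄₀) and ΔM\* = log₂(z̄_MA/z̄₀);
- mutational variance V_M = (V_L,MA − V_L,G0)/2t from the among-line
  variance component (V_L,G0 = 0 when the ancestor has no pseudolines);
- scalings I_M = V_M/z̄², I_E = V_E/z̄², mutational heritability
  h²_M = V_M/V_E;
- pairwise mutational correlations r_M = COV_L(X,Y)/√(V_L(X)·V_L(Y)) from
  bivariate among-line REML (EM algorithm; the among-line matrix stays
  positive semi-definite, so r_M ∈ [−1, 1] by construction), with a
  family-wise significance criterion α/(number of pairs);
- a joint-subset REML resampling diagnostic for the sensitivity of each
  pairwise r_M to the surrounding covariance structure, and the
  sampling-variance inflation bound k ≤ N/(N−x+1) when x of N lines share
  mutations.

**Association layer.** Pearson correlations between the six network
parameters and four mutational parameters (ΔM\*, |ΔM\*|, ln h²_M, ln I_M)
with Benjamini–Hochberg FDR; hierarchical canonical correlation analysis
(all mutational parameters jointly, then each alone) with Rao's F per root;
closed-form sign-pattern probabilities (how surprising the observed
arrangement of correlation signs and maxima is under independence); and
Spearman's ρ between r_M and shortest path length, tested against a
parametric bootstrap null that re-pairs each r_M element with a path length
drawn from the empirical path-length distribution (10,000 iterations by
default; signed, absolute-value, and undirected variants).

## Worked example

Simulate a 29-metabolite MA experiment (43 lines, 2–5 replicates each, 9
ancestor replicates, t = 250 generations, ~70 mutations per line, pleiotropy
decaying geometrically along directed edges) and run the full pipeline:

```yaml
# config.yaml
out_dir: out
seed: 42
bootstrap_iters: 2000
simulate:
  n_nodes: 29
```

```bash
mutnet run-all --config config.yaml
```

The run writes the network (edge-list TSV + Pajek .net), the centrality
table, path-length matrices, the per-metabolite mutational-parameter table,
the r_M matrix with p-values, the parameter-correlation table with FDR, a
CCA report, bootstrap null distributions with histograms, and
`out/summary.json`. With the config above it prints:

```json
{
  "signed": {
    "observed": -0.5510238102254551,
    "ci_low": -0.15327858755280327,
    "ci_high": 0.14753416936021532,
    "p_value": 0.0004997501249375312
  },
  "absolute": { "observed": -0.5510238102254551, "...": "..." },
  "undirected": { "observed": -0.47870951045401117, "...": "..." }
}
```

Reading this: 14 of the 29 simulated metabolites lie in the network's great
strong component and enter the ρ analysis; the observed Spearman correlation
between r_M and directed shortest path length is −0.55, far outside the
central 95% of its bootstrap null (−0.15, 0.15), with add-one empirical
p ≈ 5×10⁻⁴ at 2000 iterations. A strongly negative ρ is expected here: the
generator's pleiotropy attenuates along edges (λ^distance), so metabolites
close in the network receive correlated mutational input. The signed and
absolute variants coincide in this run because every included r_M estimate
happened to be positive.

Individual stages are available as `mutnet build-net`, `mutnet centrality`,
`mutnet quantgen`, `mutnet associate`, and `mutnet simulate`; the same
functionality is importable from `mutnet.reaction_net`, `mutnet.centrality`,
`mutnet.ma_quantgen`, `mutnet.association`, and `mutnet.synthetic_data`.

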