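# Methods

## Network construction

A reaction table (reaction id, substrates, products, reversibility flag)
defines a simple directed graph on metabolites: every (substrate, product)
pair of a reaction contributes an edge, reversible reactions contribute the
antiparallel edge too, and parallel support merges into one edge annotated
with all supporting reaction ids. Stoichiometric coefficients are ignored —
all downstream analyses are purely topological.

Currency metabolites (ubiquitous cofactors: ATP/ADP, NAD(P)H, H₂O, …) are
removed *before* edge creation. With them included, nearly every metabolite
pair is connected within ≤ 3 steps through a shared cofactor and path length
loses biological meaning; the test suite checks the direction of this effect
(including currency metabolites can only shorten shortest paths). There is
no universally correct currency list — the appropriate set is
database-specific and has compound-specific exceptions — so the packaged
default (`mutnet/data/currency_metabolites.txt`) is an ordinary config file
meant to be overridden.

Self-loops (a metabolite on both sides of a reaction) are dropped: the six
centralities are defined on simple graphs. A reaction whose substrates or
products are *all* currency contributes no edges; this is logged, not fatal.

Subnetwork growth from seed metabolites follows edges in both directions
(reactions forward to products and backward to substrates) to closure;
connected components containing no seed are excluded. The great strong
component (GSC) is the largest strongly connected component, with a
deterministic tie-break (lexicographically smallest member set) so outputs
are reproducible; focal metabolites outside the GSC are reported and
excluded from path-length analyses, because directed distances to or from
them are systematically undefined.

## Centrality conventions

The six per-metabolite parameters and the conventions that matter on
directed, not-strongly-connected graphs:

| parameter | definition | convention |
|---|---|---|
| betweenness c_B(v) | Σ σ(s,t\|v)/σ(s,t) / (n−1)(n−2) | unconnected (s,t) pairs skipped |
| closeness C(v) | (n−1)/Σ_u d(u,v) | **incoming** distances; Wasserman–Faust scaling (r−1)/(n−1) over the set that can reach v; 0 if nothing can |
| degree centrality | (deg⁺+deg⁻)/(n−1) | distinct neighbours per direction |
| in-/out-degree | edge counts | — |
| core number k(v) | largest k-core containing v | degree peeling on the undirected projection |

The closeness direction is easy to get silently wrong: summing outgoing
instead of incoming distances changes every value on a directed graph. Both
betweenness/closeness and core number are verified in the tests against
brute-force oracles (exhaustive path enumeration; maximum over all node
subsets of the minimum within-subset degree) on all fixture graphs of ≤ 8–10
nodes.

Unreachable ordered pairs in path-length matrices are NaN — a marker, never
a sentinel integer or ∞ — and every downstream consumer excludes them
explicitly.

## Mutational parameters

A "trait" is a normalised metabolite concentration. With z̄_MA the mean over
MA-line means, z̄₀ the ancestor mean and t the generations of MA:

- ΔM = (z̄_MA − z̄₀)/(t·z̄₀), the per-generation proportional change;
  ΔM\* = log₂(z̄_MA/z̄₀) is the variable carried into the association
  analyses (ΔM is strongly non-normal across metabolites), together with
  |ΔM\*|. The identity ΔM = 2^ΔM\* − 1 holds only at t = 1; both forms are
  always returned.
- V_M = (V_L,MA − V_L,G0)/2t. Without ancestor pseudolines V_L,G0 is not
  estimable and is fixed at 0; the API accepts it when available.
- I_M = V_M/z̄², I_E = V_E/z̄² (squared CVs, z̄ the MA mean), h²_M = V_M/V_E,
  so h²_M = I_M/I_E. ln h²_M and ln I_M are provided for the association
  layer (both are right-skewed across metabolites). h²_M is an explicit
  undefined marker when V_E = 0.

### REML estimation

Univariate variance components use the one-way random-effects model
y_ij = μ + b_i + e_ij (line i, replicate j, unbalanced n_i). The restricted
likelihood is profiled on the ratio γ = V_L/V_E: given γ, V̂_E has a closed
form, leaving a bounded scalar minimisation over γ ∈ [0, 10⁷] to an absolute
tolerance of 10⁻⁹ — deterministic, no starting-value sensitivity. V_L is
constrained to ≥ 0 with a boundary flag; the unconstrained ANOVA-moment
estimate (MSB−MSW)/n₀ is reported alongside for diagnostics, and on balanced
data with an interior optimum the two coincide (tested to 10⁻⁶). Degenerate
input with zero within-line variance short-circuits to V_E = 0 and the
sample variance of line means.

Multivariate components (pairwise r_M; joint subsets) use EM-REML for the
same model with vector traits: b ~ N(0, B), e ~ N(0, E). The EM treats
(μ, b) as missing data with a flat prior on μ, which yields the REML rather
than ML solution; updates keep B positive semi-definite, so implied
correlations never leave [−1, 1]. Convergence is declared when the largest
relative parameter change falls below 10⁻¹⁰ (10⁻⁷ for the joint-subset
diagnostic, which routinely sits near variance boundaries where EM's linear
convergence is slow); the fit is cross-validated in the test suite against
direct numerical maximisation of the restricted likelihood.

### Mutational correlations

r_M(X,Y) = B₀₁/√(B₀₀·B₁₁) from the bivariate among-line matrix. A pair is
**undefined** (NaN + flag) when either trait's *univariate* REML among-line
variance is pinned at the zero boundary — without that gate the bivariate EM
crawls toward a rank-deficient B with a spurious |r_M| ≈ 1 and an absurd
p-value. Rank deficiency of B (PSD boundary) is also flagged.

Significance is a two-sided Z-test via Fisher's z-transform with effective
sample size equal to the number of lines (the replicates inform V_E, not the
among-line correlation); the exact small-sample null of a REML-based r_M is
not available in closed form, so this is an approximation, flagged as such.
The family-wise criterion for a k-trait matrix is α/C(k,2) — 0.05/300 ≈
1.67×10⁻⁴ at 25 traits.

A full joint covariance matrix for tens of traits is not estimable from
~40 lines; the matrix is therefore assembled pairwise. The joint-subset
diagnostic quantifies what that choice hides: for a focal pair, repeatedly
fit an (n_fill+2)-trait joint model with a random subset of other traits and
record the implied focal r_M. The resampled distribution is reported
*without* confidence intervals — traits are not exchangeable, so the spread
is a sensitivity heuristic, not an inferential interval. Non-converged
replicates are dropped and counted, never silently ignored.

When x of N lines share mutations (cross-contamination), among-line sampling
(co)variances inflate by at most k = N/(N−x+1); the package reports this
bound rather than excluding the affected lines.

## Association analyses

**Pairwise correlations.** Pearson r over metabolites between each of the
six network parameters and each of the four mutational parameters (24 cross
tests as one Benjamini–Hochberg FDR family), plus within-set correlations
and I_E as a diagnostic column outside the family.

**Hierarchical CCA.** Canonical correlations via SVD of the whitened
cross-covariance (QR-orthonormalised standardised columns), with in-order
dropping of collinear columns rather than ridging. Per-root p-values use
Rao's F approximation to Wilks' Λ for roots k..s. The driver runs the full
four-variable mutational set, then each mutational parameter alone; the four
single-variable p-values form their own FDR family, separate from the 24
pairwise tests.

**Sign-pattern probabilities.** Under independence each cross correlation is
negative with probability ½ and each parameter's maximum lands uniformly, so
the observed patterns have closed-form probabilities: the lower binomial
tail P(X ≤ n_neg; 24, ½); (1/6)⁴ for all four mutational parameters
maximising at one pre-specified network parameter; the upper tail
P(X ≥ k; 6, ¼) for k of six network parameters maximising at the same
mutational parameter (k = 5 gives C(6,5)(¼)⁵(¾) + (¼)⁶ = 19/4096 ≈ 0.0046);
and (½)⁴ for in-degree beating out-degree in all four columns. These are
verified against enumeration in the tests.

**ρ(r_M, path length) and its bootstrap null.** The statistic is the
average-rank Spearman correlation between the r_M of a metabolite pair and
the shortest path length separating it. Two non-independence problems make
a textbook p-value invalid: each metabolite contributes to many pairs, and
d(i→j) may exist while d(j→i) does not. Handling:

- *signed* and *absolute* variants expand each unordered pair into up to two
  ordered observations, (r_ij, d(i→j)) and (r_ij, d(j→i)), dropping
  unreachable directions;
- the *undirected* variant uses one observation per pair with the shorter
  of the two directed lengths;
- metabolites outside the GSC are excluded before any of this;
- the null re-pairs every off-diagonal r_M element with a path length drawn
  with replacement from the empirical distribution of the included lengths,
  recomputes ρ, and repeats (10,000 iterations by default); the 95% interval
  is read from order statistics of the resampled values and the two-tailed
  empirical p uses the add-one rule, so p > 0 always.

One property one might expect — that the null interval widens as the
path-length distribution degenerates toward few distinct values — does not
hold: for any fixed (tied) rank vectors the expected squared correlation
under random re-pairing is exactly 1/(m−1), independent of tie structure.
What does drive the interval is m, the number of paired observations, and
the tests check that monotonicity instead. Fully degenerate rankings yield
the undefined marker.

## Synthetic data generator

No empirical generative model for mutational (co)variation of a metabolome
exists; the generator is this package's own stand-in, built so that every
pipeline stage has a testable ground truth.

Design defaults mirror the emulated experiment: 43 MA lines, replicate
counts drawn from {2,3,4,5} with weights (0.1, 0.2, 0.4, 0.3) (mean 3.9),
9 ancestor replicates, t = 250, Poisson(70) mutations per line.

Effect model: concentrations are positive and ratios are the natural scale,
so mutational effects are multiplicative — additive on the log scale. Each
mutation hits a uniformly chosen network node with log-effect
δ ~ N(α_mean, α_sd²) and propagates along directed edges with geometric
attenuation λ^d (unreachable ⇒ no effect). Replicates multiply in lognormal
noise with CV 0.2; ancestor replicates are noise-only. Defaults
α_mean = −0.01 (mild downward bias, most mutations mildly deleterious),
α_sd = 0.085 and λ = 0.5 were calibrated once so that mutational
heritability lands at the ~10⁻³/generation order typical of such traits,
with among-line variance roughly half the residual variance after 250
generations.

Because line log-deviations are compound-Poisson sums
L_v = Σ_k δ_k·λ^{d(U_k,v)}, the truth record is analytic: on the log scale
Cov(L_v,L_w) = m·E[δ²]·E_U[w_Uv·w_Uw] with w the propagation matrix (these
are exactly the among-line components the REML estimates target when run on
log concentrations), and raw-scale moments follow from
E[e^{ΣcL}] = exp(m(E_U E_δ[e^{δΣcw}] − 1)). The truth correlation matrix is
positive semi-definite by construction, λ = 0 gives exactly zero off-diagonal
r_M, and the analytic variances are validated against direct Monte-Carlo in
development.

A contamination helper re-draws two lines from a partially shared mutation
set, for exercising the shared-mutation inflation bound.

The toy network generator adds edges with uniform sources and
preferential-attachment targets (∝ in-degree + 1); a configurable fraction
(default 0.35) of "reactions" is reversible, contributing antiparallel
edges. The reversible fraction is what gives the graph a sizeable strongly
connected core, as in real metabolic networks — without it the graphs are
near-acyclic and the GSC collapses to one or two nodes.

**What passing recovery tests show, and what they do not.** Recovery checks
run the estimators on generator output and compare trait-averaged estimates
with analytic truth to within twice the Monte-Carlo standard error; traits
simulated on one network share lines, so the MC SE is computed over
dataset-level mean errors (cluster-robust), not over traits. V_M and r_M
recovery use log-transformed concentrations, where the generative model is
*exactly* the Gaussian-residual variance-components model; ΔM is recovered
on the raw scale. r_M recovery targets true values ≈ {0, 0.5, 0.9} via a
two-node reciprocal network, where true r_M = 2λ/(1+λ²) analytically.
Passing these says the estimators are calibrated *under this generative
model*; it says nothing about unmodelled features of real metabolomes —
developmental-stage heterogeneity between cultures, normalisation artefacts,
non-lognormal noise, residual heteroscedasticity across lines, or selection
during MA. Two known small biases are deliberately left visible rather than
absorbed into the truth record: the ΔM ratio estimator carries an
O(CV²/n₀) Jensen bias from the finite ancestor replicate count (≈ +10% of a
typical ΔM at 9 replicates, detectable only with far more simulated data
than the acceptance check uses), and correlation estimates carry the usual
O(1/q) attenuation.

## Pipeline and reproducibility

`run-all` executes network → centrality → quantgen → association in order,
writing each stage's outputs before the next starts. All randomness flows
from named seeds in the config (simulation and bootstrap both derive from
`seed`); every TSV carries a header comment with the package version, a
config hash, and the seed. Outputs contain no timestamps, so a rerun with
the same config is bit-identical. Validation is fail-fast: unknown keys,
type mismatches and missing files are rejected by name before any stage
runs. The packaged end-to-end check uses a 29-metabolite simulated
experiment with 2000 bootstrap iterations; the library default remains
10,000.

## Known limitations

- No flux-balance or stoichiometric modelling; topology only.
- No eigenvector/PageRank-style centralities; exactly the six parameters.
- The full joint M-matrix is out of reach at realistic line counts; the
  pairwise assembly is not guaranteed positive semi-definite as a matrix
  (each entry is, individually, a valid correlation).
- The Fisher-z test for r_M and Rao's F for CCA roots are approximations;
  a likelihood-ratio alternative for r_M is a natural extension.
- The generator fixes mutation counts at the line level (Poisson) rather
  than simulating per-generation fixation dynamics, and models no selection
  (N_e ≈ 1 neutrality assumed).
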