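"""Synthetic MA experiments over metabolite networks, with known truth.

The generator emulates the design of a metabolomic mutation-accumulation
study: ~43 MA lines propagated for t = 250 generations, each carrying a
Poisson(70) load of fixed mutations, assayed in 2–5 replicates (mean ≈ 3.9)
alongside 9 replicates of the unmutated ancestor.

Generative model (the package's own stand-in — no empirical generative model
for metabolite covariation exists):

* concentrations are positive, so mutational effects are multiplicative:
  additive on the natural-log scale;
* each mutation targets one metabolite uniformly at random and carries a
  log-scale effect δ ~ Normal(α_mean, α_sd²), with α_mean < 0 by default
  (most mutations mildly deleterious/concentration-lowering);
* pleiotropy propagates along directed edges with geometric attenuation:
  a metabolite at directed distance d from the target receives effect
  δ·λ^d (λ ∈ [0, 1]; unreachable ⇒ no effect);
* replicates multiply in lognormal residual noise of a given CV; ancestor
  replicates carry noise only.

Because line log-concentrations are compound-Poisson sums, the implied ΔM,
V_M and r_M are available in closed form from the effect-propagation matrix
W (w_uv = λ^d(u→v)); the :class:`SimulationTruth` record carries them on
both the log scale (exact variance components) and the raw concentration
scale (lognormal moment formulas).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .ma_quantgen import MATraitTable
from .reaction_net import MetaboliteNetwork

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "generate_toy_network",
    "simulate_MA",
    "contaminate_lines",
]

#: replicate-count distribution: counts 2..5 with mean 3.9, as in the study
REPLICATE_COUNTS = (2, 3, 4, 5)
REPLICATE_WEIGHTS = (0.1, 0.2, 0.4, 0.3)


@dataclass
class SimConfig:
    """Study-design and effect-model parameters for one simulated experiment.

    Defaults mirror the emulated experiment: 43 lines, 9 ancestor reps,
    t = 250 generations, Poisson(70) mutations per line.  Effect-model
    defaults (α on the natural-log scale, residual CV, attenuation λ) are
    the package's calibration to a mutational heritability of order
    10⁻³/generation with a mild negative bias; see docs/methods.md.
    """

    n_lines: int = 43
    n_ancestor_reps: int = 9
    t: int = 250
    mutations_per_line: float = 70.0
    alpha_log_mean: float = -0.01
    alpha_log_sd: float = 0.085
    decay_lambda: float = 0.5
    residual_cv: float = 0.2
    ancestral_mean: float = 1.0
    seed: int | None = None
    replicate_counts: tuple[int, ...] = REPLICATE_COUNTS
    replicate_weights: tuple[float, ...] = REPLICATE_WEIGHTS

    def __post_init__(self) -> None:
        if min(self.n_lines, self.n_ancestor_reps, self.t) <= 0:
            raise ValueError("counts and generations must be positive")
        if self.mutations_per_line <= 0:
            raise ValueError("mean mutation count must be positive")
        if not 0.0 <= self.decay_lambda <= 1.0:
            raise ValueError("attenuation λ must lie in [0, 1]")
        if self.residual_cv <= 0:
            raise ValueError("residual CV must be positive")
        if self.ancestral_mean <= 0:
            raise ValueError("ancestral mean must be positive")

    @property
    def residual_log_sd(self) -> float:
        """Log-scale noise SD giving the configured multiplicative CV."""
        return math.sqrt(math.log1p(self.residual_cv**2))


@dataclass
class SimulationTruth:
    """Ground truth implied by the generative model.

    ``mu_g`` is the genome-wide mutation rate per generation (mutation load
    divided by t); α parameters describe the per-mutation log-scale effect
    distribution.  Per-metabolite ΔM and V_M (and pairwise r_M) are given
    analytically on the log scale — where the generative model is exactly
    the one-way variance-components model — and on the raw concentration
    scale via compound-Poisson/lognormal moments.
    """

    metabolites: list[str]
    mu_g: float
    alpha_log_mean: float
    alpha_log_sd: float
    decay_lambda: float
    seed: int | None
    delta_m: pd.Series               # raw-scale per-generation bias
    v_m_log: pd.Series               # log-scale mutational variance /gen
    v_m_raw: pd.Series               # raw-scale mutational variance /gen
    r_m_log: pd.DataFrame            # log-scale mutational correlations
    r_m_raw: pd.DataFrame
    propagation: pd.DataFrame        # W matrix, w_uv = λ^d(u→v)


def generate_toy_network(
    n_nodes: int,
    mean_out_degree: float = 1.6,
    seed: int | None = None,
    reversible_fraction: float = 0.35,
) -> MetaboliteNetwork:
    """Random simple directed graph with a heavy-tailed in-degree profile.

    Preferential-attachment-style: edges are added one at a time with a
    uniform source and a target chosen proportional to (in-degree + 1);
    self-loops and duplicate edges are rejected.  A fraction of "reactions"
    is reversible and contributes the antiparallel edge too — this is what
    gives the graph a sizeable strongly connected core, as in real metabolic
    networks.  Total edge count ≈ n_nodes × mean_out_degree; deterministic
    per seed.
    """
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    if mean_out_degree <= 0:
        raise ValueError("mean out-degree must be positive (graph would be edgeless)")
    if not 0.0 <= reversible_fraction <= 1.0:
        raise ValueError("reversible_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    names = [f"M{i:03d}" for i in range(1, n_nodes + 1)]
    g = nx.DiGraph()
    g.add_nodes_from(names)
    n_edges = max(1, round(n_nodes * mean_out_degree))
    max_edges = n_nodes * (n_nodes - 1)
    n_edges = min(n_edges, max_edges)
    in_deg = np.ones(n_nodes)
    attempts = 0
    rxn = 0
    while g.number_of_edges() < n_edges and attempts < 50 * n_edges:
        attempts += 1
        u = int(rng.integers(n_nodes))
        v = int(rng.choice(n_nodes, p=in_deg / in_deg.sum()))
        if u == v or g.has_edge(names[u], names[v]):
            continue
        rxn += 1
        g.add_edge(names[u], names[v], reactions=(f"R{rxn:04d}",))
        in_deg[v] += 1.0
        if rng.random() < reversible_fraction and not g.has_edge(names[v], names[u]):
            g.add_edge(names[v], names[u], reactions=(f"R{rxn:04d}",))
            in_deg[u] += 1.0
    return MetaboliteNetwork(graph=g)


def _propagation_matrix(network: MetaboliteNetwork, lam: float) -> pd.DataFrame:
    """W[u, v] = λ^d(u→v): effect on v of a mutation targeting u."""
    nodes = sorted(network.graph.nodes)
    w = pd.DataFrame(0.0, index=nodes, columns=nodes)
    for u in nodes:
        w.at[u, u] = 1.0
    if lam > 0.0:
        for u, lengths in nx.all_pairs_shortest_path_length(network.graph):
            for v, d in lengths.items():
                w.at[u, v] = lam**d
    return w


def _truth_from_propagation(
    w: pd.DataFrame, config: SimConfig
) -> SimulationTruth:
    """Closed-form truth from compound-Poisson moments of line log-effects.

    With M ~ Poisson(m) mutations, uniform targets U, and δ ~ N(a, s²), the
    line log-deviation for metabolite v is L_v = Σ_k δ_k · w(U_k, v), so
    Cov(L_v, L_w) = m·E[δ²]·E_U[w_Uv·w_Uw].  Raw-scale moments follow from
    E[e^{Σ c_v L_v}] = exp(m·(E_U E_δ[e^{δ Σ c_v w_Uv}] − 1)).
    """
    nodes = list(w.index)
    wm = w.to_numpy()                       # rows: target u, cols: metabolite v
    n = len(nodes)
    m = config.mutations_per_line
    a, s = config.alpha_log_mean, config.alpha_log_sd
    e_d2 = a**2 + s**2

    cov_log = m * e_d2 * (wm.T @ wm) / n
    var_log = np.diag(cov_log).copy()
    sd = np.sqrt(np.where(var_log > 0, var_log, np.nan))
    with np.errstate(invalid="ignore"):
        r_log = cov_log / np.outer(sd, sd)
    np.fill_diagonal(r_log, 1.0)

    def mgf(c: np.ndarray) -> np.ndarray:
        # E_U E_δ[exp(δ·c_U)] for per-target coefficient vector c
        return np.exp(a * c + 0.5 * s**2 * c**2).mean(axis=0)

    e1 = np.exp(m * (mgf(wm) - 1.0))        # E[e^{L_v}], per metabolite
    e2 = np.exp(m * (mgf(2.0 * wm) - 1.0))  # E[e^{2 L_v}]
    var_raw = e2 - e1**2
    cov_raw = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            eij = np.exp(m * (mgf(wm[:, i] + wm[:, j]) - 1.0))
            cov_raw[i, j] = cov_raw[j, i] = eij - e1[i] * e1[j]
    sd_raw = np.sqrt(np.where(var_raw > 0, var_raw, np.nan))
    with np.errstate(invalid="ignore"):
        r_raw = cov_raw / np.outer(sd_raw, sd_raw)
    np.fill_diagonal(r_raw, 1.0)

    t = float(config.t)
    z0 = config.ancestral_mean
    return SimulationTruth(
        metabolites=nodes,
        mu_g=m / t,
        alpha_log_mean=a,
        alpha_log_sd=s,
        decay_lambda=config.decay_lambda,
        seed=config.seed,
        delta_m=pd.Series((e1 - 1.0) / t, index=nodes),
        v_m_log=pd.Series(var_log / (2.0 * t), index=nodes),
        v_m_raw=pd.Series(z0**2 * var_raw / (2.0 * t), index=nodes),
        r_m_log=pd.DataFrame(r_log, index=nodes, columns=nodes),
        r_m_raw=pd.DataFrame(r_raw, index=nodes, columns=nodes),
        propagation=w,
    )


def _draw_line_log_effects(
    rng: np.random.Generator, wm: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Log-scale deviation vector L for one line's mutation set."""
    n_mut = rng.poisson(config.mutations_per_line)
    if n_mut == 0:
        return np.zeros(wm.shape[1])
    targets = rng.integers(wm.shape[0], size=n_mut)
    deltas = rng.normal(config.alpha_log_mean, config.alpha_log_sd, size=n_mut)
    return deltas @ wm[targets, :]


def simulate_MA(
    config: SimConfig,
    network: MetaboliteNetwork,
    metabolites: list[str] | None = None,
) -> tuple[MATraitTable, SimulationTruth]:
    """Simulate one MA metabolomics experiment on a metabolite network.

    Returns the long-format trait table (MA lines plus ancestor replicates)
    and the analytic :class:`SimulationTruth`.  Identical config + seed give
    an identical table.  ``metabolites`` restricts the assayed (focal) set;
    mutations still target every network node.
    """
    w = _propagation_matrix(network, config.decay_lambda)
    truth = _truth_from_propagation(w, config)
    nodes = truth.metabolites
    focal = nodes if metabolites is None else list(metabolites)
    missing = set(focal) - set(nodes)
    if missing:
        raise KeyError(f"focal metabolites absent from network: {sorted(missing)}")
    col = [nodes.index(mv) for mv in focal]
    wm = w.to_numpy()
    rng = np.random.default_rng(config.seed)
    sigma = config.residual_log_sd
    z0 = config.ancestral_mean

    rows: list[dict] = []
    for li in range(1, config.n_lines + 1):
        line_id = f"MA{li:03d}"
        log_eff = _draw_line_log_effects(rng, wm, config)[col]
        n_rep = int(rng.choice(config.replicate_counts, p=config.replicate_weights))
        for rep in range(1, n_rep + 1):
            noise = rng.normal(0.0, sigma, size=len(focal))
            conc = z0 * np.exp(log_eff + noise)
            for met, c in zip(focal, conc):
                rows.append({"line": line_id, "replicate": rep, "metabolite": met,
                             "concentration": float(c), "is_ancestor": False})
    for rep in range(1, config.n_ancestor_reps + 1):
        noise = rng.normal(0.0, sigma, size=len(focal))
        conc = z0 * np.exp(noise)
        for met, c in zip(focal, conc):
            rows.append({"line": "G0", "replicate": rep, "metabolite": met,
                         "concentration": float(c), "is_ancestor": True})
    table = MATraitTable(data=pd.DataFrame(rows), t=config.t)
    if metabolites is not None:
        truth = _restrict_truth(truth, focal)
    return table, truth


def _restrict_truth(truth: SimulationTruth, focal: list[str]) -> SimulationTruth:
    return SimulationTruth(
        metabolites=focal,
        mu_g=truth.mu_g,
        alpha_log_mean=truth.alpha_log_mean,
        alpha_log_sd=truth.alpha_log_sd,
        decay_lambda=truth.decay_lambda,
        seed=truth.seed,
        delta_m=truth.delta_m[focal],
        v_m_log=truth.v_m_log[focal],
        v_m_raw=truth.v_m_raw[focal],
        r_m_log=truth.r_m_log.loc[focal, focal],
        r_m_raw=truth.r_m_raw.loc[focal, focal],
        propagation=truth.propagation,
    )


def contaminate_lines(
    table: MATraitTable,
    network: MetaboliteNetwork,
    config: SimConfig,
    line_a: str,
    line_b: str,
    shared_fraction: float,
    seed: int | None = None,
) -> MATraitTable:
    """Re-draw two lines from a partly shared mutation set.

    Emulates cross-contamination during propagation: a fraction of the
    mutation load is common to both lines, the remainder independent.  Used
    to exercise the shared-mutation sampling-variance inflation report.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    for line in (line_a, line_b):
        if line not in set(table.data["line"]):
            raise KeyError(f"line {line!r} not present in table")
    w = _propagation_matrix(network, config.decay_lambda)
    nodes = list(w.index)
    focal = [m for m in table.metabolites if m in nodes]
    col = [nodes.index(m) for m in focal]
    wm = w.to_numpy()
    rng = np.random.default_rng(seed)

    shared_cfg_m = config.mutations_per_line * shared_fraction
    indep_cfg_m = config.mutations_per_line * (1.0 - shared_fraction)

    def draw(mean_m: float) -> np.ndarray:
        n_mut = rng.poisson(mean_m) if mean_m > 0 else 0
        if n_mut == 0:
            return np.zeros(len(nodes))
        targets = rng.integers(len(nodes), size=n_mut)
        deltas = rng.normal(config.alpha_log_mean, config.alpha_log_sd, size=n_mut)
        return deltas @ wm[targets, :]

    shared_eff = draw(shared_cfg_m)
    sigma = config.residual_log_sd
    data = table.data.copy()
    for line in (line_a, line_b):
        log_eff = (shared_eff + draw(indep_cfg_m))[col]
        mask = data["line"] == line
        reps = sorted(data.loc[mask, "replicate"].unique())
        for rep in reps:
            noise = rng.normal(0.0, sigma, size=len(focal))
            conc = config.ancestral_mean * np.exp(log_eff + noise)
            for met, c in zip(focal, conc):
                sel = mask & (data["replicate"] == rep) & (data["metabolite"] == met)
                data.loc[sel, "concentration"] = float(c)
    return MATraitTable(data=data, t=table.t)
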