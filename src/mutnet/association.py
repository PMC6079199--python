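"""Relating mutational parameters to metabolic-network topology.

Four analyses connect the per-metabolite mutational parameters (ΔM*, |ΔM*|,
ln h²_M, ln I_M) to the six network parameters (betweenness, closeness,
degree centrality, in-degree, out-degree, core number):

1. all pairwise Pearson correlations, with Benjamini–Hochberg FDR applied to
   the cross-set family;
2. a hierarchical canonical correlation analysis (all mutational parameters
   jointly, then each one alone against the six network parameters), with
   Rao's F approximation per canonical root;
3. closed-form sign-pattern probabilities — how surprising the observed
   arrangement of correlation signs and maxima would be under independence;
4. Spearman's ρ between the pairwise mutational correlation r_M and the
   shortest path length separating the two metabolites, tested against a
   parametric bootstrap null that re-pairs each r_M element with a path
   length drawn from the empirical path-length distribution.  The bootstrap
   respects the two non-independence problems of such data: every metabolite
   contributes to many correlations, and the directed path i→j may exist
   while j→i does not.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .centrality import PathLengthMatrix

__all__ = [
    "MUTATIONAL_COLUMNS",
    "NETWORK_COLUMNS",
    "ParamCorrelationTable",
    "CCAResult",
    "BootstrapNull",
    "pairwise_correlations",
    "benjamini_hochberg",
    "cca",
    "hierarchical_cca",
    "sign_pattern_tests",
    "rho_vs_pathlength",
    "bootstrap_rho_null",
    "plot_null_histogram",
]

NETWORK_COLUMNS = (
    "betweenness",
    "closeness",
    "degree_centrality",
    "in_degree",
    "out_degree",
    "core_number",
)
MUTATIONAL_COLUMNS = ("delta_M_star", "abs_delta_M_star", "ln_h2_M", "ln_I_M")


# ---------------------------------------------------------------------------
# pairwise correlations + FDR
# ---------------------------------------------------------------------------

@dataclass
class ParamCorrelationTable:
    """Pearson correlations between and within the two parameter sets."""

    full: pd.DataFrame           # (net + mut [+ extra]) × same, correlation
    cross_r: pd.DataFrame        # network rows × mutational columns
    cross_p: pd.DataFrame
    cross_q: pd.DataFrame        # BH-FDR over the cross-set family
    n_negative: int              # negative cross-set correlations
    n_metabolites: int


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_correlations(
    mut_params: pd.DataFrame,
    centrality: pd.DataFrame,
    extra_mut_columns: Sequence[str] = ("ln_I_E",),
) -> ParamCorrelationTable:
    """Pearson correlations over metabolites between all parameter pairs.

    ``mut_params`` and ``centrality`` are indexed by metabolite; only
    metabolites present in both with complete rows enter.  BH-FDR is applied
    to the cross-set tests (6 network × 4 mutational = 24) as one family;
    the extra columns (residual-variance scaling I_E by default) appear in
    the full table but are outside the FDR family.
    """
    extra = [c for c in extra_mut_columns if c in mut_params.columns]
    mcols = [c for c in MUTATIONAL_COLUMNS if c in mut_params.columns]
    if len(mcols) < len(MUTATIONAL_COLUMNS):
        missing = set(MUTATIONAL_COLUMNS) - set(mcols)
        raise ValueError(f"mutational parameter columns missing: {sorted(missing)}")
    shared = centrality.index.intersection(mut_params.index)
    joined = centrality.loc[shared, list(NETWORK_COLUMNS)].join(
        mut_params.loc[shared, mcols + extra]
    ).dropna()
    if len(joined) < 4:
        raise ValueError("need >= 4 metabolites with complete parameter rows")
    full = joined.corr(method="pearson")
    # zero-variance columns: mark undefined rather than emitting garbage
    zero_var = joined.std(ddof=0) == 0
    for col in joined.columns[zero_var]:
        full.loc[col, :] = np.nan
        full.loc[:, col] = np.nan
    cross_r = pd.DataFrame(index=list(NETWORK_COLUMNS), columns=mcols, dtype=float)
    cross_p = cross_r.copy()
    for nc in NETWORK_COLUMNS:
        for mc in mcols:
            if zero_var[nc] or zero_var[mc]:
                cross_r.loc[nc, mc] = np.nan
                cross_p.loc[nc, mc] = np.nan
            else:
                r, p = stats.pearsonr(joined[nc], joined[mc])
                cross_r.loc[nc, mc] = r
                cross_p.loc[nc, mc] = p
    flat_p = cross_p.to_numpy().ravel()
    mask = ~np.isnan(flat_p)
    flat_q = np.full_like(flat_p, np.nan)
    if mask.any():
        flat_q[mask] = benjamini_hochberg(flat_p[mask])
    cross_q = pd.DataFrame(flat_q.reshape(cross_p.shape),
                           index=cross_p.index, columns=cross_p.columns)
    n_neg = int((cross_r.to_numpy() < 0).sum())
    return ParamCorrelationTable(full=full, cross_r=cross_r, cross_p=cross_p,
                                 cross_q=cross_q, n_negative=n_neg,
                                 n_metabolites=len(joined))


# ---------------------------------------------------------------------------
# canonical correlation analysis
# ---------------------------------------------------------------------------

@dataclass
class CCAResult:
    correlations: np.ndarray     # canonical correlations, descending
    x_coef: np.ndarray           # columns = canonical X-variate coefficients
    y_coef: np.ndarray
    x_scores: pd.DataFrame       # per-metabolite canonical scores
    y_scores: pd.DataFrame
    p_values: np.ndarray         # Rao's F per root (testing roots k..s jointly)
    x_columns: tuple[str, ...]
    y_columns: tuple[str, ...]


def _drop_collinear(x: np.ndarray, cols: list[str], tol: float = 1e-10):
    """In-order column drop to full rank; returns (matrix, kept columns)."""
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    keep_rank = int((diag > tol * max(diag.max(), 1)).sum())
    if keep_rank == x.shape[1]:
        return x, cols
    # greedy re-selection: keep columns in order while rank increases
    kept_idx: list[int] = []
    for j in range(x.shape[1]):
        trial = x[:, kept_idx + [j]]
        if np.linalg.matrix_rank(trial, tol=tol * max(1.0, np.abs(trial).max())) > len(kept_idx):
            kept_idx.append(j)
    return x[:, kept_idx], [cols[j] for j in kept_idx]


def cca(x: pd.DataFrame, y: pd.DataFrame) -> CCAResult:
    """Canonical correlation analysis via SVD of the whitened cross-covariance.

    Columns are standardised; rank-deficient column sets are reduced by a
    documented in-order column drop (no ridge).  Per-root significance is
    Rao's F approximation to Wilks' Λ for roots k..s jointly.
    """
    shared = x.index.intersection(y.index)
    xj = x.loc[shared].dropna()
    yj = y.loc[shared].dropna()
    shared = xj.index.intersection(yj.index)
    xj, yj = xj.loc[shared], yj.loc[shared]
    n = len(shared)
    if n <= max(xj.shape[1], yj.shape[1]):
        raise ValueError("need more observations than variables in either set")
    xs = (xj - xj.mean()) / xj.std(ddof=1)
    ys = (yj - yj.mean()) / yj.std(ddof=1)
    xm, xcols = _drop_collinear(xs.to_numpy(float), list(xs.columns))
    ym, ycols = _drop_collinear(ys.to_numpy(float), list(ys.columns))
    if xm.shape[1] == 0 or ym.shape[1] == 0:
        raise ValueError("no usable columns after rank reduction")
    qx, rx = np.linalg.qr(xm - xm.mean(axis=0))
    qy, ry = np.linalg.qr(ym - ym.mean(axis=0))
    u, sv, vt = np.linalg.svd(qx.T @ qy)
    s = min(xm.shape[1], ym.shape[1])
    rho = np.clip(sv[:s], 0.0, 1.0)
    a = np.linalg.solve(rx, u[:, :s])       # X coefficients (standardised vars)
    b = np.linalg.solve(ry, vt.T[:, :s])
    x_scores = pd.DataFrame((xm - xm.mean(axis=0)) @ a, index=shared,
                            columns=[f"CV{i+1}" for i in range(s)])
    y_scores = pd.DataFrame((ym - ym.mean(axis=0)) @ b, index=shared,
                            columns=[f"CV{i+1}" for i in range(s)])
    p_values = _rao_f_pvalues(rho, n, xm.shape[1], ym.shape[1])
    return CCAResult(correlations=rho, x_coef=a, y_coef=b,
                     x_scores=x_scores, y_scores=y_scores, p_values=p_values,
                     x_columns=tuple(xcols), y_columns=tuple(ycols))


def _rao_f_pvalues(rho: np.ndarray, n: int, p: int, q: int) -> np.ndarray:
    """Rao's F approximation for Wilks' Λ of canonical roots k..s."""
    s = len(rho)
    out = np.empty(s)
    for k in range(s):
        pk, qk = p - k, q - k
        lam = float(np.prod(1.0 - rho[k:] ** 2))
        lam = min(max(lam, 1e-300), 1.0)
        m = n - 1 - k - (pk + qk + 1) / 2.0
        denom = pk**2 + qk**2 - 5
        t = math.sqrt((pk**2 * qk**2 - 4) / denom) if denom > 0 else 1.0
        df1 = pk * qk
        df2 = m * t - pk * qk / 2.0 + 1.0
        if df2 <= 0 or lam >= 1.0:
            out[k] = 1.0
            continue
        lam_t = lam ** (1.0 / t)
        f = (1.0 - lam_t) / lam_t * df2 / df1
        out[k] = float(stats.f.sf(f, df1, df2))
    return out


def hierarchical_cca(
    x: pd.DataFrame, y: pd.DataFrame
) -> tuple[CCAResult, dict[str, CCAResult], np.ndarray]:
    """Full CCA of Y on X, then each Y column alone; FDR across the singles.

    Returns (full result, per-column results, BH-FDR q-values of the four
    single-Y first-root p-values — a separate FDR family from the pairwise
    cross-set correlations).
    """
    full = cca(x, y)
    singles = {col: cca(x, y[[col]]) for col in y.columns}
    q = benjamini_hochberg([res.p_values[0] for res in singles.values()])
    return full, singles, q


# ---------------------------------------------------------------------------
# sign-pattern probabilities
# ---------------------------------------------------------------------------

def sign_pattern_tests(table: "ParamCorrelationTable | pd.DataFrame | None" = None,
                       n_negative: int | None = None) -> dict[str, float]:
    """Closed-form probabilities of the observed sign/maximum patterns.

    Under independence each cross-set correlation is negative with
    probability 1/2, each mutational parameter's largest correlation lands
    on any given network parameter with probability 1/6, and vice versa.
    The four tests:

    * ``negative_binomial``: P(X <= observed negatives), X ~ Bin(24, 1/2);
    * ``all_max_same_network_param``: (1/6)^4 — all four mutational
      parameters maximise at one pre-specified network parameter;
    * ``max_concentration``: P(X >= k), X ~ Bin(6, 1/4) — at least k of the
      six network parameters maximise at the same mutational parameter
      (k = 5 gives C(6,5)(1/4)^5(3/4) + (1/4)^6);
    * ``in_vs_out``: (1/2)^4 — all four mutational parameters correlate
      more strongly with in-degree than with out-degree.

    Pass a completed :class:`ParamCorrelationTable` to evaluate the observed
    pattern, or ``n_negative`` alone for the binomial count test.
    """
    if table is not None:
        if isinstance(table, pd.DataFrame):
            cr = table
            n_neg = int((cr.to_numpy() < 0).sum())
        else:
            cr = table.cross_r
            n_neg = table.n_negative
        n_net, n_mut = cr.shape
        argmax_net = cr.idxmax(axis=0)          # per mutational param
        all_same_net = argmax_net.nunique() == 1
        argmax_mut = cr.idxmax(axis=1)          # per network param
        conc = int(argmax_mut.value_counts().iloc[0])
        in_gt_out = int((cr.loc["in_degree"] > cr.loc["out_degree"]).sum())
    else:
        if n_negative is None:
            raise ValueError("need a correlation table or an observed negative count")
        n_neg, n_net, n_mut = n_negative, 6, 4
        all_same_net, conc, in_gt_out = True, n_net - 1, n_mut
    n_cross = n_net * n_mut
    return {
        "n_negative": float(n_neg),
        "negative_binomial": float(stats.binom.cdf(n_neg, n_cross, 0.5)),
        "all_max_same_network_param": float((1.0 / n_net) ** n_mut) if all_same_net else
            float("nan"),
        "max_concentration_count": float(conc),
        "max_concentration": float(stats.binom.sf(conc - 1, n_net, 1.0 / n_mut)),
        "n_in_greater_than_out": float(in_gt_out),
        "in_vs_out": float(stats.binom.pmf(n_mut, n_mut, 0.5)) if in_gt_out == n_mut
            else float(stats.binom.sf(in_gt_out - 1, n_mut, 0.5)),
    }


# ---------------------------------------------------------------------------
# r_M versus shortest path length
# ---------------------------------------------------------------------------

def _paired_observations(
    rm: pd.DataFrame, paths: PathLengthMatrix, variant: str
) -> tuple[np.ndarray, np.ndarray]:
    """Expand (r_M, path length) observations for a Spearman correlation.

    ``signed``/``absolute``: ordered-pair expansion on directed lengths —
    the symmetric r_ij is paired with both d(i→j) and d(j→i), and a
    direction with no path contributes nothing.  ``undirected``: one
    observation per unordered pair using the shorter of the two directions.
    Pairs with undefined r_M are excluded throughout.
    """
    if variant not in {"signed", "absolute", "undirected"}:
        raise ValueError(f"unknown variant {variant!r}")
    mets = [m for m in rm.index if m in paths.values.index]
    rs, ds = [], []
    for i, a in enumerate(mets):
        for j, b in enumerate(mets):
            if variant == "undirected" and j <= i:
                continue
            if j == i:
                continue
            r = rm.at[a, b]
            if variant == "undirected":
                d = float(np.fmin(paths.values.at[a, b], paths.values.at[b, a]))
            else:
                d = float(paths.values.at[a, b])
            if math.isnan(r) or math.isnan(d):
                continue
            rs.append(abs(r) if variant == "absolute" else r)
            ds.append(d)
    return np.asarray(rs, float), np.asarray(ds, float)


def rho_vs_pathlength(
    rm: pd.DataFrame, paths: PathLengthMatrix, variant: str = "signed"
) -> float:
    """Average-rank Spearman ρ between r_M and shortest path length.

    Callers restrict ``rm`` to metabolites inside the great strong component
    beforehand; unreachable directions are excluded here.  Returns NaN when
    either ranking is degenerate (zero variance).
    """
    rs, ds = _paired_observations(rm, paths, variant)
    if rs.size < 2 or np.all(rs == rs[0]) or np.all(ds == ds[0]):
        return math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(rs, ds).statistic
    return float(rho)


@dataclass
class BootstrapNull:
    """Empirical null distribution of a resampled statistic."""

    observed: float
    samples: np.ndarray
    ci_low: float                # order statistics of the resampled values
    ci_high: float
    p_value: float               # add-one two-tailed empirical p, in (0, 1]
    n_iter: int
    seed: int | None
    variant: str

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("empirical p-value must be in (0, 1]")


def _vectorised_spearman(fixed_ranks: np.ndarray, samples: np.ndarray) -> np.ndarray:
    """Pearson correlation of average ranks, one row of samples at a time."""
    r1 = fixed_ranks - fixed_ranks.mean()
    ranks = stats.rankdata(samples, axis=1)
    r2 = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((r1**2).sum() * (r2**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (r2 @ r1) / denom


def bootstrap_rho_null(
    rm: pd.DataFrame,
    paths: PathLengthMatrix,
    n_iter: int = 10000,
    seed: int | None = None,
    variant: str = "signed",
) -> BootstrapNull:
    """Parametric bootstrap null for ρ(r_M, shortest path length).

    Each iteration pairs every off-diagonal r_M element with a path length
    drawn with replacement from the empirical distribution of the included
    path lengths, then recomputes Spearman's ρ; the observed ρ is compared
    with the central 95% interval of the resulting distribution, and the
    two-tailed empirical p-value uses the add-one rule so it can never be 0.
    """
    if n_iter < 100:
        warnings.warn("n_iter < 100: bootstrap interval will be unstable",
                      stacklevel=2)
    rs, ds = _paired_observations(rm, paths, variant)
    if rs.size < 3:
        raise ValueError("too few (r_M, path length) observations")
    observed = rho_vs_pathlength(rm, paths, variant)
    rng = np.random.default_rng(seed)
    sampled = rng.choice(ds, size=(n_iter, rs.size), replace=True)
    fixed_ranks = stats.rankdata(rs)
    samples = _vectorised_spearman(fixed_ranks, sampled)
    samples = samples[~np.isnan(samples)]
    lo, hi = np.percentile(samples, [2.5, 97.5], method="nearest")
    if math.isnan(observed):
        p = 1.0
    else:
        p = (1.0 + float((np.abs(samples) >= abs(observed)).sum())) / (1.0 + len(samples))
    return BootstrapNull(observed=observed, samples=samples, ci_low=float(lo),
                         ci_high=float(hi), p_value=p, n_iter=n_iter,
                         seed=seed, variant=variant)


def plot_null_histogram(null: BootstrapNull, path: str) -> None:
    """Histogram of the bootstrap null with the observed ρ marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(null.samples, bins=60, color="0.7")
    ax.axvline(null.observed, color="tab:orange", lw=2, label="observed ρ")
    ax.axvline(null.ci_low, color="k", ls="--", lw=1)
    ax.axvline(null.ci_high, color="k", ls="--", lw=1, label="95% null interval")
    ax.set_xlabel("Spearman ρ under the null")
    ax.set_ylabel("count")
    ax.set_title(f"{null.variant} variant, p = {null.p_value:.4f}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
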