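"""Mutational quantitative genetics from mutation-accumulation (MA) data.

An MA experiment propagates replicate lines from a common ancestor at
minimal population size for t generations, so that spontaneous mutations fix
nearly free of selection.  For each trait (here, a normalised metabolite
concentration) the cumulative effect of mutation is summarised by:

* the mutational bias ``ΔM = (z̄_MA − z̄_0) / (t · z̄_0)`` and its log-ratio
  form ``ΔM* = log2(z̄_MA / z̄_0)``;
* the mutational variance ``V_M = (V_L,MA − V_L,G0) / 2t`` from the
  among-line variance component (the ancestor's among-line variance is
  assumed 0 when no ancestor pseudolines exist);
* scalings ``I_M = V_M / z̄²`` (squared mutational CV), ``I_E = V_E / z̄²``
  and the mutational heritability ``h²_M = V_M / V_E``;
* pairwise mutational correlations ``r_M = COV_L(X,Y)/√(V_L(X)·V_L(Y))``
  from the among-line components of (co)variance.

Variance components come from restricted maximum likelihood (REML) under a
one-way random-effects model: a bounded profile-likelihood search on the
variance ratio in the univariate case, and an EM-REML algorithm for the
multivariate (pairwise and joint-subset) case.  EM keeps the among-line
covariance matrix positive semi-definite, so estimated correlations are
automatically in [−1, 1]; estimates pinned at a boundary are flagged rather
than silently propagated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MATraitTable",
    "REMLResult",
    "MultitraitREMLResult",
    "PairwiseRM",
    "MutCorrMatrix",
    "SubsetREMLDistribution",
    "delta_M",
    "anova_oneway",
    "restricted_loglik_oneway",
    "reml_oneway",
    "mutational_variance",
    "scalings",
    "mutational_params",
    "reml_multitrait",
    "pairwise_rM",
    "rM_matrix",
    "subset_reml_sensitivity",
    "shared_mutation_inflation",
]


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

@dataclass
class MATraitTable:
    """Long-format MA trait measurements plus the generation count.

    ``data`` columns: line, replicate, metabolite, concentration,
    is_ancestor.  Ancestor replicates share a single pseudo-line id; MA
    lines need >= 2 replicates for within-line variance estimation.
    """

    data: pd.DataFrame
    t: int

    REQUIRED = ("line", "replicate", "metabolite", "concentration", "is_ancestor")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"trait table missing columns: {missing}")
        if self.t <= 0:
            raise ValueError("generation count t must be positive")
        if (self.data["concentration"] <= 0).any():
            raise ValueError("concentrations must be positive (log/ratio scales)")
        reps = (
            self.data[~self.data["is_ancestor"]]
            .groupby(["line", "metabolite"])["replicate"]
            .nunique()
        )
        if (reps < 2).any():
            bad = reps[reps < 2].index[0]
            raise ValueError(
                f"MA line {bad[0]!r} has < 2 replicates for metabolite {bad[1]!r}"
            )

    # -- accessors ----------------------------------------------------------

    @property
    def metabolites(self) -> list[str]:
        return sorted(self.data["metabolite"].unique())

    @property
    def ma_lines(self) -> list[str]:
        return sorted(self.data.loc[~self.data["is_ancestor"], "line"].unique())

    def line_groups(
        self, metabolite: str, transform: Callable[[np.ndarray], np.ndarray] | None = None
    ) -> dict[str, np.ndarray]:
        """Replicate values per MA line for one metabolite."""
        sub = self.data[(self.data["metabolite"] == metabolite) & ~self.data["is_ancestor"]]
        out = {
            line: grp["concentration"].to_numpy(float)
            for line, grp in sub.groupby("line", sort=True)
        }
        if transform is not None:
            out = {k: transform(v) for k, v in out.items()}
        return out

    def ancestor_values(
        self, metabolite: str, transform: Callable[[np.ndarray], np.ndarray] | None = None
    ) -> np.ndarray:
        sub = self.data[(self.data["metabolite"] == metabolite) & self.data["is_ancestor"]]
        vals = sub["concentration"].to_numpy(float)
        return transform(vals) if transform is not None else vals

    def multitrait_groups(
        self,
        metabolites: Sequence[str],
        transform: Callable[[np.ndarray], np.ndarray] | None = None,
    ) -> tuple[list[str], list[np.ndarray]]:
        """Per-line replicate matrices (n_i × p) over several metabolites.

        Replicates missing any of the requested metabolites are dropped.
        """
        sub = self.data[
            self.data["metabolite"].isin(metabolites) & ~self.data["is_ancestor"]
        ]
        wide = sub.pivot_table(
            index=["line", "replicate"], columns="metabolite", values="concentration"
        )[list(metabolites)].dropna()
        lines: list[str] = []
        groups: list[np.ndarray] = []
        for line, grp in wide.groupby(level="line", sort=True):
            arr = grp.to_numpy(float)
            if transform is not None:
                arr = transform(arr)
            lines.append(line)
            groups.append(arr)
        return lines, groups

    # -- IO -----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path, t: int) -> "MATraitTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        if df["is_ancestor"].dtype != bool:
            df["is_ancestor"] = df["is_ancestor"].astype(int).astype(bool)
        df["line"] = df["line"].astype(str)
        return cls(data=df, t=t)

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with Path(path).open("w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.data.assign(is_ancestor=self.data["is_ancestor"].astype(int)).to_csv(
                fh, sep="\t", index=False
            )


# ---------------------------------------------------------------------------
# mutational bias
# ---------------------------------------------------------------------------

def delta_M(zbar_ma: float, zbar_0: float, t: float) -> tuple[float, float]:
    """Mutational bias ΔM = (z̄_MA − z̄_0)/(t·z̄_0) and ΔM* = log2(z̄_MA/z̄_0).

    Both are returned; ΔM* is the variable carried into the association
    analyses (ΔM itself is strongly non-normal across metabolites).  The
    identity ΔM = 2^ΔM* − 1 holds only at t = 1.
    """
    if zbar_0 <= 0 or zbar_ma <= 0:
        raise ValueError("trait means must be positive")
    if t <= 0:
        raise ValueError("generation count t must be positive")
    dm = (zbar_ma - zbar_0) / (t * zbar_0)
    dm_star = math.log2(zbar_ma / zbar_0)
    return dm, dm_star


# ---------------------------------------------------------------------------
# univariate REML (one-way random effects, unbalanced)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class REMLResult:
    v_l: float           # among-line variance (constrained >= 0)
    v_e: float           # residual (within-line) variance
    loglik: float        # restricted log-likelihood at (v_l, v_e)
    boundary: bool       # True when v_l was pinned at 0 (or v_e at 0)
    v_l_anova: float     # unconstrained ANOVA-moment among-line estimate
    v_e_anova: float
    grand_mean: float    # GLS mean


def _group_stats(groups: Iterable[np.ndarray]) -> tuple[np.ndarray, np.ndarray, float]:
    arrs = [np.asarray(g, float).ravel() for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 lines")
    n_i = np.array([len(a) for a in arrs], float)
    if not np.any(n_i >= 2):
        raise ValueError("residual variance inestimable: no line has >= 2 replicates")
    means = np.array([a.mean() for a in arrs])
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    return n_i, means, ssw


def anova_oneway(groups: Iterable[np.ndarray]) -> tuple[float, float]:
    """Unconstrained ANOVA-moment estimates (V_L, V_E), V_L may be negative.

    V_L = (MSB − MSW)/n0 with the unbalanced-design effective replicate
    number n0 = (N − Σn_i²/N)/(q − 1); the REML estimate equals this
    whenever the design is balanced and the moment estimate is interior.
    """
    n_i, means, ssw = _group_stats(groups)
    q, n_tot = len(n_i), n_i.sum()
    grand = float((n_i * means).sum() / n_tot)
    msb = float((n_i * (means - grand) ** 2).sum() / (q - 1))
    msw = ssw / (n_tot - q) if n_tot > q else 0.0
    n0 = (n_tot - (n_i**2).sum() / n_tot) / (q - 1)
    return (msb - msw) / n0, msw


def restricted_loglik_oneway(
    groups: Iterable[np.ndarray], v_l: float, v_e: float
) -> float:
    """Restricted log-likelihood of (V_L, V_E) for the one-way model."""
    n_i, means, ssw = _group_stats(groups)
    n_tot = n_i.sum()
    v_e = max(v_e, 1e-300)
    v_l = max(v_l, 0.0)
    v_bar = v_l + v_e / n_i                       # variance of line means
    w = 1.0 / v_bar
    mu = float((w * means).sum() / w.sum())
    logdet_v = float(((n_i - 1) * math.log(v_e)).sum() + np.log(n_i * v_bar).sum())
    quad = ssw / v_e + float((w * (means - mu) ** 2).sum())
    log_xvx = math.log(float((n_i / (v_e + n_i * v_l)).sum()))
    return -0.5 * ((n_tot - 1) * math.log(2 * math.pi) + logdet_v + log_xvx + quad)


def reml_oneway(
    groups: Iterable[np.ndarray],
    ratio_max: float = 1e7,
    ratio_tol: float = 1e-9,
) -> REMLResult:
    """REML variance components by bounded profile search on γ = V_L/V_E.

    Given the ratio γ, the residual variance has the closed form
    V_E(γ) = Q(γ)/(N−1); the profile restricted likelihood is minimised over
    γ ∈ [0, ratio_max] to absolute tolerance ``ratio_tol``, making the
    estimate deterministic.  V_L is bounded below at 0 (boundary flagged);
    the unconstrained ANOVA-moment estimate is reported alongside for
    diagnostics.
    """
    groups = [np.asarray(g, float).ravel() for g in groups]
    n_i, means, ssw = _group_stats(groups)
    q, n_tot = len(n_i), float(n_i.sum())
    vl_anova, ve_anova = anova_oneway(groups)

    if ssw <= 0.0:
        # no within-line variation: V_E = 0, lines are observed exactly
        v_l = float(np.var(means, ddof=1))
        mu = float(means.mean())
        return REMLResult(v_l, 0.0, math.inf if v_l == 0 else math.nan,
                          boundary=True, v_l_anova=vl_anova, v_e_anova=ve_anova,
                          grand_mean=mu)

    def profile_neg2rl(gamma: float) -> float:
        c = gamma + 1.0 / n_i
        w = 1.0 / c
        mu = (w * means).sum() / w.sum()
        quad = ssw + (w * (means - mu) ** 2).sum()
        v_e = quad / (n_tot - 1.0)
        return ((n_tot - 1.0) * math.log(v_e)
                + float(np.log(c).sum())
                + math.log(float(w.sum())))

    res = optimize.minimize_scalar(
        profile_neg2rl, bounds=(0.0, ratio_max), method="bounded",
        options={"xatol": ratio_tol},
    )
    gamma = float(res.x)
    if profile_neg2rl(0.0) <= res.fun:
        gamma = 0.0
    c = gamma + 1.0 / n_i
    w = 1.0 / c
    mu = float((w * means).sum() / w.sum())
    v_e = float((ssw + (w * (means - mu) ** 2).sum()) / (n_tot - 1.0))
    v_l = gamma * v_e
    boundary = gamma <= ratio_tol
    ll = restricted_loglik_oneway(groups, v_l, v_e)
    return REMLResult(v_l, v_e, ll, boundary, vl_anova, ve_anova, mu)


# ---------------------------------------------------------------------------
# V_M and its scalings
# ---------------------------------------------------------------------------

def mutational_variance(v_l_ma: float, v_l_g0: float, t: float) -> float:
    """V_M = (V_L,MA − V_L,G0) / 2t; V_L,G0 defaults to 0 upstream."""
    if t <= 0:
        raise ValueError("generation count t must be positive")
    return (v_l_ma - v_l_g0) / (2.0 * t)


def scalings(v_m: float, v_e: float, mean_ma: float) -> tuple[float, float, float]:
    """(I_M, I_E, h²_M): mean-squared scalings and mutational heritability.

    h²_M is NaN (undefined marker) when V_E = 0.  Note h²_M = I_M / I_E.
    """
    if mean_ma <= 0:
        raise ValueError("MA-line mean must be positive for I-scalings")
    i_m = v_m / mean_ma**2
    i_e = v_e / mean_ma**2
    h2_m = v_m / v_e if v_e > 0 else math.nan
    return i_m, i_e, h2_m


def mutational_params(
    table: MATraitTable,
    v_l_g0: Mapping[str, float] | None = None,
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-metabolite mutational parameters (Δ-family and variance-family).

    One row per metabolite: trait means, ΔM, ΔM*, |ΔM*|, among-line and
    residual variances (REML, plus the unconstrained moment V_L), V_M, I_M,
    I_E, h²_M, and the natural-log transforms of h²_M and I_M used by the
    association layer.  ``v_l_g0`` supplies ancestor among-line variances
    when pseudolines exist; the default assumes V_L,G0 = 0.
    """
    rows = []
    for met in table.metabolites:
        groups = table.line_groups(met, transform=transform)
        anc = table.ancestor_values(met, transform=transform)
        line_means = np.array([g.mean() for g in groups.values()])
        zbar_ma = float(line_means.mean())
        zbar_0 = float(anc.mean()) if anc.size else math.nan
        if anc.size and zbar_0 > 0 and zbar_ma > 0:
            dm, dm_star = delta_M(zbar_ma, zbar_0, table.t)
        else:
            dm = dm_star = math.nan
        fit = reml_oneway(list(groups.values()))
        g0 = (v_l_g0 or {}).get(met, 0.0)
        v_m = mutational_variance(fit.v_l, g0, table.t)
        i_m, i_e, h2_m = scalings(v_m, fit.v_e, zbar_ma)
        rows.append({
            "metabolite": met,
            "zbar_MA": zbar_ma,
            "zbar_0": zbar_0,
            "delta_M": dm,
            "delta_M_star": dm_star,
            "abs_delta_M_star": abs(dm_star) if not math.isnan(dm_star) else math.nan,
            "V_L": fit.v_l,
            "V_L_anova": fit.v_l_anova,
            "V_E": fit.v_e,
            "V_M": v_m,
            "I_M": i_m,
            "I_E": i_e,
            "h2_M": h2_m,
            "ln_h2_M": math.log(h2_m) if h2_m and h2_m > 0 else math.nan,
            "ln_I_M": math.log(i_m) if i_m > 0 else math.nan,
            "ln_I_E": math.log(i_e) if i_e > 0 else math.nan,
            "boundary": fit.boundary,
        })
    return pd.DataFrame(rows).set_index("metabolite")


# ---------------------------------------------------------------------------
# multivariate EM-REML
# ---------------------------------------------------------------------------

@dataclass
class MultitraitREMLResult:
    among: np.ndarray        # among-line covariance matrix B (p × p, PSD)
    within: np.ndarray       # residual covariance matrix E (p × p)
    mean: np.ndarray         # GLS grand mean (p,)
    loglik: float
    converged: bool
    n_iter: int


def _restricted_loglik_multi(
    n_i: np.ndarray, ybar: np.ndarray, s_w: np.ndarray, B: np.ndarray, E: np.ndarray
) -> float:
    q, p = ybar.shape
    n_tot = float(n_i.sum())
    F = E[None, :, :] / n_i[:, None, None]
    V = B[None, :, :] + F
    W = np.linalg.inv(V)
    wsum = W.sum(axis=0)
    mu = np.linalg.solve(wsum, np.einsum("qij,qj->i", W, ybar))
    d = ybar - mu
    sign_e, logdet_e = np.linalg.slogdet(E)
    sign_v, logdet_v = np.linalg.slogdet(V)
    if sign_e <= 0 or np.any(sign_v <= 0):
        return -math.inf
    logdet_full = float(((n_i - 1) * logdet_e).sum() + (p * np.log(n_i)).sum()
                        + logdet_v.sum())
    sign_w, logdet_w = np.linalg.slogdet(wsum)
    quad = float(np.trace(np.linalg.solve(E, s_w)) + np.einsum("qi,qij,qj->", d, W, d))
    return -0.5 * ((n_tot - 1) * p * math.log(2 * math.pi)
                   + logdet_full + logdet_w + quad)


def reml_multitrait(
    groups: Sequence[np.ndarray],
    tol: float = 1e-10,
    max_iter: int = 20000,
) -> MultitraitREMLResult:
    """EM-REML for the multivariate one-way random-effects model.

    ``groups`` is one (n_i × p) replicate matrix per line; the model is
    y_ij = μ + b_i + e_ij with b ~ N(0, B) among lines and e ~ N(0, E)
    within.  The EM treats (μ, b) as missing data (flat prior on μ gives the
    REML solution), so B stays positive semi-definite throughout — the basis
    for bounded mutational-correlation estimates.  Convergence is declared
    when the largest relative parameter change drops below ``tol``.
    """
    arrs = [np.atleast_2d(np.asarray(g, float)) for g in groups]
    p = arrs[0].shape[1]
    if any(a.shape[1] != p for a in arrs):
        raise ValueError("all lines must have the same number of traits")
    q = len(arrs)
    if q < 3:
        raise ValueError("need at least 3 lines for multitrait REML")
    n_i = np.array([a.shape[0] for a in arrs], float)
    n_tot = float(n_i.sum())
    ybar = np.stack([a.mean(axis=0) for a in arrs])              # (q, p)
    s_w = sum((a - a.mean(axis=0)).T @ (a - a.mean(axis=0)) for a in arrs)

    # moment-based initialisation, clipped to positive definiteness
    E = s_w / max(n_tot - q, 1.0)
    E = E + np.eye(p) * (1e-8 * max(np.trace(E) / p, 1e-12) + 1e-300)
    grand = (n_i[:, None] * ybar).sum(axis=0) / n_tot
    msb = (n_i[:, None, None] * np.einsum("qi,qj->qij", ybar - grand, ybar - grand)
           ).sum(axis=0) / (q - 1)
    n0 = (n_tot - (n_i**2).sum() / n_tot) / (q - 1)
    B = (msb - E) / n0
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    floor = 1e-6 * max(np.trace(E) / p, 1e-12)
    B = (evecs * np.maximum(evals, floor)) @ evecs.T

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        F = E[None, :, :] / n_i[:, None, None]
        V = B[None, :, :] + F
        W = np.linalg.inv(V)
        wsum = W.sum(axis=0)
        C = np.linalg.inv(wsum)
        mu = C @ np.einsum("qij,qj->i", W, ybar)
        d = ybar - mu                                            # (q, p)
        BW = B[None, :, :] @ W                                   # (q, p, p)
        FW = F @ W
        b_hat = np.einsum("qij,qj->qi", BW, d)
        r_hat = np.einsum("qij,qj->qi", FW, d)
        var_mu_b = (B[None, :, :] - BW @ B[None, :, :]
                    + BW @ C[None, :, :] @ BW.transpose(0, 2, 1))
        B_new = (np.einsum("qi,qj->ij", b_hat, b_hat) + var_mu_b.sum(axis=0)) / q
        # residual mean g_i = ȳ_i − μ − b_i; Var(g|y) = Var(μ + b|y)
        var_g = (B[None, :, :] - BW @ B[None, :, :]
                 + FW @ C[None, :, :] @ FW.transpose(0, 2, 1))
        resid_second = (n_i[:, None, None]
                        * (np.einsum("qi,qj->qij", r_hat, r_hat) + var_g)).sum(axis=0)
        E_new = (s_w + resid_second) / n_tot
        B_new = (B_new + B_new.T) / 2
        E_new = (E_new + E_new.T) / 2
        scale = max(np.abs(B).max(), np.abs(E).max(), 1e-300)
        delta = max(np.abs(B_new - B).max(), np.abs(E_new - E).max()) / scale
        B, E = B_new, E_new
        if delta < tol:
            converged = True
            break
    ll = _restricted_loglik_multi(n_i, ybar, s_w, B, E)
    return MultitraitREMLResult(among=B, within=E, mean=mu, loglik=ll,
                                converged=converged, n_iter=it)


# ---------------------------------------------------------------------------
# mutational correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseRM:
    r_m: float               # NaN marks undefined (among-line variance ~ 0)
    p_value: float
    cov_l: float
    v_l_x: float
    v_l_y: float
    defined: bool
    boundary: bool
    method: str              # "pairwise-REML" | "joint-subset-REML"


def _fisher_z_p(r: float, n_lines: int) -> float:
    """Two-sided Z-test of r = 0 via Fisher's z, effective n = line count."""
    if n_lines <= 3:
        return math.nan
    r = min(max(r, -1 + 1e-12), 1 - 1e-12)
    z = math.atanh(r) * math.sqrt(n_lines - 3)
    return 2.0 * stats.norm.sf(abs(z))


def _rm_from_among(B: np.ndarray, i: int, j: int, n_lines: int,
                   method: str, rel_floor: float = 1e-9) -> PairwiseRM:
    vx, vy, cov = float(B[i, i]), float(B[j, j]), float(B[i, j])
    floor = rel_floor * max(abs(B).max(), 1e-300)
    if vx <= floor or vy <= floor:
        return PairwiseRM(math.nan, math.nan, cov, vx, vy,
                          defined=False, boundary=True, method=method)
    r = cov / math.sqrt(vx * vy)
    evals = np.linalg.eigvalsh(np.array([[vx, cov], [cov, vy]]))
    # rank deficiency of the among-line matrix = the PSD boundary, |r| -> 1
    boundary = abs(r) >= 1.0 - 1e-9 or evals[0] <= 1e-6 * evals[-1]
    r = min(max(r, -1.0), 1.0)
    return PairwiseRM(r, _fisher_z_p(r, n_lines), cov, vx, vy,
                      defined=True, boundary=boundary, method=method)


def pairwise_rM(
    table: MATraitTable,
    trait_x: str,
    trait_y: str,
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> PairwiseRM:
    """Mutational correlation of two traits from bivariate among-line REML.

    Significance is a two-sided Fisher-z test with effective sample size
    equal to the number of MA lines; r_M is undefined (NaN, flagged) when
    either trait's among-line variance collapses to the zero boundary.
    """
    lines, groups = table.multitrait_groups([trait_x, trait_y], transform=transform)
    if len(lines) < 3:
        raise ValueError("need >= 3 shared lines for a mutational correlation")
    # a trait whose own among-line variance REMLs to the zero boundary has no
    # defined mutational correlation; the bivariate EM would otherwise crawl
    # to a rank-deficient matrix with a spurious |r| near 1
    uni = [reml_oneway([g[:, k] for g in groups]) for k in (0, 1)]
    if any(f.boundary and f.v_l <= 0.0 for f in uni):
        return PairwiseRM(math.nan, math.nan, math.nan,
                          uni[0].v_l, uni[1].v_l,
                          defined=False, boundary=True, method="pairwise-REML")
    fit = reml_multitrait(groups)
    return _rm_from_among(fit.among, 0, 1, len(lines), "pairwise-REML")


@dataclass
class MutCorrMatrix:
    """Symmetric r_M matrix with per-pair p-values and method tags."""

    r: pd.DataFrame
    p: pd.DataFrame
    n_lines: int
    n_pairs: int
    familywise_alpha: float
    n_significant: int
    boundary: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def rM_matrix(
    table: MATraitTable,
    metabolites: Sequence[str] | None = None,
    alpha: float = 0.05,
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> MutCorrMatrix:
    """All pairwise mutational correlations among the given metabolites.

    The full joint among-line covariance matrix is not estimable for tens of
    traits from ~tens of lines, so every off-diagonal entry comes from a
    separate bivariate REML fit.  Significance is counted at the family-wise
    criterion alpha / (number of pairs).
    """
    mets = list(metabolites) if metabolites is not None else table.metabolites
    if len(mets) < 2:
        raise ValueError("need >= 2 metabolites")
    k = len(mets)
    r = pd.DataFrame(np.eye(k), index=mets, columns=mets)
    p = pd.DataFrame(np.nan, index=mets, columns=mets)
    bound = pd.DataFrame(False, index=mets, columns=mets)
    n_pairs = k * (k - 1) // 2
    crit = alpha / n_pairs
    n_sig = 0
    n_lines = len(table.ma_lines)
    for a in range(k):
        for b in range(a + 1, k):
            est = pairwise_rM(table, mets[a], mets[b], transform=transform)
            r.iloc[a, b] = r.iloc[b, a] = est.r_m
            p.iloc[a, b] = p.iloc[b, a] = est.p_value
            bound.iloc[a, b] = bound.iloc[b, a] = est.boundary
            if est.defined and est.p_value < crit:
                n_sig += 1
    return MutCorrMatrix(r=r, p=p, n_lines=n_lines, n_pairs=n_pairs,
                         familywise_alpha=crit, n_significant=n_sig, boundary=bound)


# ---------------------------------------------------------------------------
# joint-subset sensitivity of pairwise r_M
# ---------------------------------------------------------------------------

@dataclass
class SubsetREMLDistribution:
    """Resampled joint-REML r_M estimates for one focal pair.

    No confidence interval is attached: traits are not exchangeable, so the
    resampled spread is a heuristic sensitivity picture, not an inferential
    interval.
    """

    focal_pair: tuple[str, str]
    samples: np.ndarray          # converged replicates only
    n_dropped: int               # non-converged joint fits
    median: float
    point_estimate: float        # pairwise-REML r_M for comparison
    seed: int | None


def subset_reml_sensitivity(
    table: MATraitTable,
    focal_pair: tuple[str, str],
    n_fill: int = 6,
    n_reps: int = 100,
    seed: int | None = None,
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> SubsetREMLDistribution:
    """Sensitivity of a pairwise r_M to the surrounding covariance structure.

    Each replicate samples ``n_fill`` of the non-focal traits without
    replacement, fits the joint (n_fill + 2)-trait REML among-line
    covariance matrix, and records the implied focal r_M.  Replicates whose
    joint fit does not converge are dropped and counted.
    """
    others = [m for m in table.metabolites if m not in focal_pair]
    if len(others) < n_fill:
        raise ValueError(
            f"need >= {n_fill} non-focal traits, have {len(others)}")
    rng = np.random.default_rng(seed)
    point = pairwise_rM(table, *focal_pair, transform=transform)
    samples = []
    n_dropped = 0
    for _ in range(n_reps):
        fill = list(rng.choice(others, size=n_fill, replace=False))
        mets = list(focal_pair) + fill
        lines, groups = table.multitrait_groups(mets, transform=transform)
        # joint fits sit near variance boundaries more often than bivariate
        # ones; a slightly looser tolerance keeps the replicate budget cheap
        fit = reml_multitrait(groups, tol=1e-7)
        if not fit.converged:
            n_dropped += 1
            continue
        est = _rm_from_among(fit.among, 0, 1, len(lines), "joint-subset-REML")
        samples.append(est.r_m)
    arr = np.array(samples, float)
    med = float(np.nanmedian(arr)) if arr.size else math.nan
    return SubsetREMLDistribution(
        focal_pair=tuple(focal_pair), samples=arr, n_dropped=n_dropped,
        median=med, point_estimate=point.r_m, seed=seed)


# ---------------------------------------------------------------------------
# shared-mutation sampling-variance inflation
# ---------------------------------------------------------------------------

def shared_mutation_inflation(n_lines: int, x_sharing: int) -> float:
    """Upper bound k <= N/(N − x + 1) on sampling-(co)variance inflation.

    When x of N lines share mutations (e.g., by cross-contamination during
    propagation), among-line sampling (co)variances inflate by at most this
    factor; equality holds when the sharing lines share all their mutations.
    With x = 1 there is no sharing and k = 1.
    """
    if n_lines < 1:
        raise ValueError("need at least one line")
    if not 0 <= x_sharing <= n_lines:
        raise ValueError("x must satisfy 0 <= x <= N")
    return n_lines / (n_lines - x_sharing + 1)
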