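"""Gamma log-link mixed models via penalised quasi-likelihood (PQL).

The fitter iterates the classic PQL scheme: a working response
``z = eta + (y - mu)/mu`` (for the gamma family with log link the working
weights are constant) is fitted with a linear mixed model with a species
random intercept by restricted maximum likelihood, and the linear
predictor is updated until convergence.  The residual variance of the
working model estimates the gamma dispersion.

Marginal R-squared follows the latent-scale variance decomposition
``var(X beta) / (var(X beta) + sigma2_species + sigma2_dist)`` with the
gamma/log distribution-specific variance ``trigamma(1/dispersion)``
(a lognormal approximation ``ln(1 + dispersion)`` is available).

Inference: Wald t statistics with denominator df = n - rank(X); terms
spanning several columns (categorical traits) get a joint Wald F test.
This df convention is a documented choice, not a claim about any
particular reference implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from poleward.screening import TRAIT_LEVELS

PQL_TOL = 1e-8
PQL_MAX_ITER = 50

#: full fixed-effect structure: five physical drivers, six traits and the
#: stated interactions (including the three-way term)
FULL_FIXED_TERMS = (
    "climate_velocity",
    "kinetic_energy",
    "directional_agreement",
    "mhw_displacement",
    "mcs_cumulative_intensity",
    "trophic_category",
    "reproductive_mode",
    "adult_mobility",
    "habitat",
    "water_column",
    "range_size",
    "climate_velocity:directional_agreement",
    "directional_agreement:kinetic_energy",
    "climate_velocity:directional_agreement:kinetic_energy",
    "climate_velocity:mhw_displacement",
)


@dataclass
class ModelSpec:
    """Response, fixed-term list and grouping factor of one model."""

    response: str
    fixed_terms: tuple[str, ...] = FULL_FIXED_TERMS
    random: str = "species_id"
    standardize: bool = False

    def without(self, *terms: str) -> "ModelSpec":
        return replace(self, fixed_terms=tuple(t for t in self.fixed_terms if t not in terms))


@dataclass
class GlmmFit:
    """A fitted gamma log-link mixed model."""

    spec: ModelSpec
    coef: pd.Series  # natural-log scale
    se: pd.Series
    pvalues: pd.Series  # per-coefficient Wald t
    term_pvalues: pd.Series  # per-term (joint Wald F for multi-column terms)
    term_columns: dict[str, list[str]]
    sigma2_species: float
    dispersion: float
    df_resid: int
    n_iter: int
    converged: bool
    fitted: np.ndarray = field(repr=False, default=None)
    linear_predictor: np.ndarray = field(repr=False, default=None)
    ranef: dict = field(repr=False, default_factory=dict)
    _X: np.ndarray = field(repr=False, default=None)

    @property
    def coef_log10(self) -> pd.Series:
        """Coefficients rescaled for base-10 display."""
        return self.coef / np.log(10.0)


# ---------------------------------------------------------------------------
# design matrix


def _components(term: str) -> tuple[str, ...]:
    return tuple(term.split(":"))


def build_design(table: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    """Expand fixed terms into a design matrix with an intercept.

    Categorical variables are dummy-coded against the first level of their
    fixed vocabulary; interactions are products of component columns.
    Aliased (constant) columns are dropped with a warning.
    """
    base: dict[str, np.ndarray] = {}

    def var_columns(name: str) -> dict[str, np.ndarray]:
        if name in base:
            return {name: base[name]}
        col = table[name]
        if name in TRAIT_LEVELS or col.dtype == object or str(col.dtype) == "category":
            levels = TRAIT_LEVELS.get(name)
            if levels is None:
                levels = tuple(sorted(col.dropna().unique()))
            out = {}
            for lv in levels[1:]:
                out[f"{name}[{lv}]"] = (col == lv).to_numpy(dtype=float)
            return out
        v = col.to_numpy(dtype=float)
        if spec.standardize:
            sd = v.std()
            v = (v - v.mean()) / (sd if sd > 0 else 1.0)
        return {name: v}

    names: list[str] = ["(Intercept)"]
    cols: list[np.ndarray] = [np.ones(len(table))]
    term_columns: dict[str, list[str]] = {}
    for term in spec.fixed_terms:
        parts = [var_columns(p) for p in _components(term)]
        prod: dict[str, np.ndarray] = parts[0]
        for nxt in parts[1:]:
            prod = {
                f"{n1}:{n2}": c1 * c2 for n1, c1 in prod.items() for n2, c2 in nxt.items()
            }
        kept = []
        for n, c in prod.items():
            if np.ptp(c) == 0:
                warnings.warn(f"dropping aliased column {n}")
                continue
            names.append(n)
            cols.append(c)
            kept.append(n)
        term_columns[term] = kept
    X = np.column_stack(cols)
    return X, names, term_columns


# ---------------------------------------------------------------------------
# random-intercept LMM by profiled REML


def _lmm_reml(X: np.ndarray, z: np.ndarray, group_idx: np.ndarray, n_groups: int):
    """REML fit of z = X b + u_group + e; returns (beta, cov, s2e, s2u, blup)."""
    n, p = X.shape
    XtX = X.T @ X
    Xtz = X.T @ z
    ztz = float(z @ z)
    # per-group sums
    Sx = np.zeros((n_groups, p))
    Sz = np.zeros(n_groups)
    np.add.at(Sx, group_idx, X)
    np.add.at(Sz, group_idx, z)
    ng = np.bincount(group_idx, minlength=n_groups).astype(float)

    def solve(lam: float):
        c = lam / (1.0 + lam * ng)  # (G,)
        A = XtX - (Sx * c[:, None]).T @ Sx
        b = Xtz - Sx.T @ (c * Sz)
        beta = np.linalg.solve(A, b)
        quad = ztz - float(Sz @ (c * Sz)) - float(beta @ b)
        return beta, A, max(quad, 1e-300)

    def neg_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        _, A, rss = solve(lam)
        s2 = rss / (n - p)
        logdet_v = float(np.sum(np.log1p(lam * ng)))
        sign, logdet_a = np.linalg.slogdet(A)
        return (n - p) * np.log(s2) + logdet_v + logdet_a

    res = optimize.minimize_scalar(neg_reml, bounds=(-25.0, 15.0), method="bounded")
    # prefer the lam -> 0 boundary (no random effect) on ties: the criterion is
    # flat in lam when every group is a singleton
    lam = float(np.exp(res.x))
    if neg_reml(-40.0) <= res.fun + 1e-8:
        lam = 0.0
    beta, A, rss = solve(lam if lam > 0 else 0.0)
    s2e = rss / (n - p)
    s2u = lam * s2e
    cov = s2e * np.linalg.inv(A)
    c = lam / (1.0 + lam * ng) if lam > 0 else np.zeros_like(ng)
    resid_sums = Sz - Sx @ beta
    blup = c * resid_sums
    return beta, cov, float(s2e), float(s2u), blup


# ---------------------------------------------------------------------------
# PQL


def fit_pql(
    spec: ModelSpec,
    table: pd.DataFrame,
    tol: float = PQL_TOL,
    max_iter: int = PQL_MAX_ITER,
) -> GlmmFit:
    """Fit a gamma log-link mixed model by penalised quasi-likelihood."""
    y = table[spec.response].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("gamma response must be finite and strictly positive")
    groups = table[spec.random].astype(str)
    codes, uniques = pd.factorize(groups, sort=True)
    if len(uniques) < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    X, names, term_columns = build_design(table, spec)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("design matrix is rank deficient; drop aliased terms")

    mu = y.copy()
    eta = np.log(mu)
    converged = False
    beta = cov = None
    s2e = s2u = 0.0
    blup = np.zeros(len(uniques))
    for it in range(1, max_iter + 1):
        z = eta + (y - mu) / mu
        beta, cov, s2e, s2u, blup = _lmm_reml(X, z, codes, len(uniques))
        eta_new = X @ beta + blup[codes]
        delta = float(np.max(np.abs(eta_new - eta)))
        eta = eta_new
        mu = np.exp(np.clip(eta, -700, 700))
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"PQL did not reach tol={tol} in {max_iter} iterations (last step {delta:.3g})")

    df_resid = n - rank
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)

    coef = pd.Series(beta, index=names)
    se_s = pd.Series(se, index=names)
    pv = pd.Series(pvals, index=names)

    term_p = {}
    name_pos = {nm: k for k, nm in enumerate(names)}
    for term, colnames in term_columns.items():
        idx = [name_pos[c] for c in colnames]
        if len(idx) == 1:
            term_p[term] = float(pv.iloc[idx[0]])
        else:
            b = beta[idx]
            C = cov[np.ix_(idx, idx)]
            f = float(b @ np.linalg.solve(C, b)) / len(idx)
            term_p[term] = float(stats.f.sf(f, len(idx), df_resid))

    return GlmmFit(
        spec=spec,
        coef=coef,
        se=se_s,
        pvalues=pv,
        term_pvalues=pd.Series(term_p),
        term_columns=term_columns,
        sigma2_species=s2u,
        dispersion=s2e,
        df_resid=df_resid,
        n_iter=it,
        converged=converged,
        fitted=mu,
        linear_predictor=X @ beta,
        ranef=dict(zip(uniques, blup)),
        _X=X,
    )


def marginal_r2(fit: GlmmFit, method: str = "trigamma") -> float:
    """Latent-scale proportion of variance explained by the fixed effects."""
    var_f = float(np.var(fit.linear_predictor))
    s2d = _distribution_variance(fit.dispersion, method)
    return var_f / (var_f + fit.sigma2_species + s2d)


def conditional_r2(fit: GlmmFit, method: str = "trigamma") -> float:
    """As :func:`marginal_r2` but crediting the random intercept too."""
    var_f = float(np.var(fit.linear_predictor))
    s2d = _distribution_variance(fit.dispersion, method)
    return (var_f + fit.sigma2_species) / (var_f + fit.sigma2_species + s2d)


def _distribution_variance(dispersion: float, method: str) -> float:
    if method == "trigamma":
        return float(special.polygamma(1, 1.0 / dispersion))
    if method == "lognormal":
        return float(np.log1p(dispersion))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# backward selection and term importance


def _shielded(term: str, retained) -> bool:
    """True when ``term``'s components are a strict subset of another term's."""
    mine = set(_components(term))
    for other in retained:
        if other != term and mine < set(_components(other)):
            return True
    return False


def backward_select(
    full: ModelSpec, table: pd.DataFrame, alpha: float = 0.05, tie_tol: float = 1e-6
):
    """Stepwise removal by largest p-value (ties: smallest marginal-R2 drop).

    Main effects (or lower-order interactions) contained in a retained
    interaction are never candidates for removal.  Stops when every
    removable term is significant at ``alpha``.  Returns the final spec,
    its fit and a per-step trace ``(term, p, delta_r2)``.
    """
    spec = full
    fit = fit_pql(spec, table)
    trace: list[tuple[str, float, float]] = []
    while spec.fixed_terms:
        removable = [t for t in spec.fixed_terms if not _shielded(t, spec.fixed_terms)]
        pv = fit.term_pvalues
        worst = [t for t in removable if pv[t] >= alpha]
        if not worst:
            break
        pmax = max(pv[t] for t in worst)
        tied = [t for t in worst if pv[t] >= pmax - tie_tol]
        r2_before = marginal_r2(fit)
        if len(tied) == 1:
            drop = tied[0]
            new_spec = spec.without(drop)
            new_fit = fit_pql(new_spec, table)
            delta = r2_before - marginal_r2(new_fit)
        else:
            best = None
            for t in tied:
                cand_spec = spec.without(t)
                cand_fit = fit_pql(cand_spec, table)
                d = r2_before - marginal_r2(cand_fit)
                if best is None or d < best[3]:
                    best = (t, cand_spec, cand_fit, d)
            drop, new_spec, new_fit, delta = best
        trace.append((drop, float(pv[drop]), float(delta)))
        spec, fit = new_spec, new_fit
    return spec, fit, trace


def term_importance(final: ModelSpec, table: pd.DataFrame, fit: GlmmFit | None = None) -> pd.Series:
    """Marginal-R2 drop from removing each retained term (with its dependents).

    Removing a term also removes every retained interaction built on it,
    so the reduced model always respects the hierarchy.
    """
    if fit is None:
        fit = fit_pql(final, table)
    r2_full = marginal_r2(fit)
    out = {}
    for term in final.fixed_terms:
        mine = set(_components(term))
        dependents = [t for t in final.fixed_terms if t != term and mine <= set(_components(t))]
        reduced = final.without(term, *dependents)
        out[term] = r2_full - marginal_r2(fit_pql(reduced, table))
    return pd.Series(out)
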