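"""Phylogenetic generalized least squares with Pagel's lambda.

The regression model is y = X beta + e with e ~ N(0, sigma^2 V(lambda)),
where V(lambda) is the tree-derived covariance with off-diagonals scaled
by lambda.  lambda is profiled by maximum likelihood (coarse grid plus
bounded refinement); with lambda = 0 the fit reduces exactly to ordinary
least squares, which is also exposed directly as the non-phylogenetic
GLM comparator.

Estimation notes
----------------
* beta-hat = (X' V^-1 X)^-1 X' V^-1 y, computed by whitening with the
  Cholesky factor of V — no explicit matrix inverse anywhere.
* sigma^2 is ML (RSS_V / n) inside the log-likelihood and AIC; standard
  errors of beta use the unbiased RSS_V / (n - p) so the t statistics
  follow exact t distributions under Gaussian errors.  Both variants are
  reported.
* AIC = -2 loglik + 2k with k = p (coefficients) + 1 (sigma^2) + 1 more
  when lambda was estimated from the data.
* F and R^2 are computed in the whitened space against the
  intercept-only fit under the same V.
* V with reciprocal condition number below 1e-12 is a hard error, never
  a silent pseudo-inverse.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .curation import SpeciesTrait
from .trees import PhyloCovariance, lambda_transform

__all__ = [
    "ModelSpec",
    "PGLSFit",
    "parse_formula",
    "build_design",
    "gls_fit",
    "profile_lambda",
    "aic_select",
    "glm_fit",
]

ALPHA = 0.05                    # significance level used in reports
RCOND_MIN = 1e-12               # below this, V is treated as singular
LAMBDA_GRID = np.linspace(0.0, 1.0, 101)
LAMBDA_XTOL = 1e-6

#: factor covariates and their reference (0) / alternative (1) levels
FACTOR_CODING = {
    "group": ("temperate", "tropical"),
    "habitat": ("freshwater", "marine"),
    "hemisphere": ("northern", "southern"),
}
NUMERIC_TERMS = {"delta_t", "ctmax", "n_individuals", "heating_rate"}


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    """A model formula: response, main effects, and interactions.

    ``terms`` holds main-effect names; ``interactions`` holds (a, b)
    pairs, both of which must also appear as main effects.
    """

    response: str = "log10_sd_ctmax"
    terms: list[str] = field(default_factory=list)
    interactions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = set(FACTOR_CODING) | NUMERIC_TERMS
        for t in self.terms:
            if t not in known:
                raise ModelError(f"unknown term {t!r}")
        for a, b in self.interactions:
            if a not in self.terms or b not in self.terms:
                raise ModelError(
                    f"interaction {a}:{b} requires both main effects"
                )

    def formula(self) -> str:
        parts = list(self.terms) + [f"{a}:{b}" for a, b in self.interactions]
        return f"{self.response} ~ " + " + ".join(parts)

    @property
    def n_coefficients(self) -> int:
        return 1 + len(self.terms) + len(self.interactions)


def parse_formula(text: str) -> ModelSpec:
    """Parse ``"response ~ a + b + a:b"`` into a :class:`ModelSpec`."""
    m = re.fullmatch(r"\s*(\w+)\s*~\s*(.+?)\s*", text)
    if not m:
        raise ModelError(f"cannot parse formula {text!r}")
    response, rhs = m.group(1), m.group(2)
    terms: list[str] = []
    interactions: list[tuple[str, str]] = []
    for raw in rhs.split("+"):
        token = raw.strip()
        if not token:
            raise ModelError(f"empty term in formula {text!r}")
        if ":" in token:
            parts = [p.strip() for p in token.split(":")]
            if len(parts) != 2 or not all(parts):
                raise ModelError(f"bad interaction term {token!r}")
            interactions.append((parts[0], parts[1]))
        else:
            terms.append(token)
    return ModelSpec(response=response, terms=terms, interactions=interactions)


# ---------------------------------------------------------------------------
# Design matrix


def build_design(
    traits: list[SpeciesTrait], spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Response vector, design matrix and column names.

    Intercept first; binary factors coded 0/1 against the references
    temperate / freshwater / northern; interactions are elementwise
    products of their parents' columns.  Rank deficiency and unobserved
    factor levels are errors.
    """
    n = len(traits)
    if n == 0:
        raise ModelError("no species to build a design from")
    y = np.array([getattr(t, spec.response) for t in traits], dtype=float)

    columns: dict[str, np.ndarray] = {}
    names = ["(Intercept)"]
    X_cols = [np.ones(n)]
    for term in spec.terms:
        if term in FACTOR_CODING:
            ref, alt = FACTOR_CODING[term]
            values = [getattr(t, term) for t in traits]
            bad = sorted({v for v in values if v not in (ref, alt)})
            if bad:
                raise ModelError(f"unknown level(s) {bad} for factor {term}")
            col = np.array([1.0 if v == alt else 0.0 for v in values])
            if len(set(values)) < 2:
                raise ModelError(
                    f"factor {term} has a single observed level ({values[0]})"
                )
            name = f"{term}[{alt}]"
        else:
            vals = [getattr(t, term) for t in traits]
            if any(v is None for v in vals):
                raise ModelError(
                    f"term {term} has missing values; drop those species first"
                )
            col = np.asarray(vals, dtype=float)
            name = term
        columns[term] = col
        names.append(name)
        X_cols.append(col)
    for a, b in spec.interactions:
        col = columns[a] * columns[b]
        names.append(f"{_col_name(a)}:{_col_name(b)}")
        X_cols.append(col)
    X = np.column_stack(X_cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError(
            f"design matrix is rank deficient (columns: {', '.join(names)})"
        )
    return y, X, names


def _col_name(term: str) -> str:
    if term in FACTOR_CODING:
        return f"{term}[{FACTOR_CODING[term][1]}]"
    return term


# ---------------------------------------------------------------------------
# Fit container


@dataclass
class PGLSFit:
    """A fitted (P)GLS model."""

    term_names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    lambda_hat: float | None        # None for the ordinary GLM
    lambda_estimated: bool
    lambda_at_boundary: bool
    sigma2_ml: float
    sigma2_unbiased: float
    loglik: float
    aic: float
    f_statistic: float
    f_df: tuple[int, int]
    f_p_value: float
    r_squared: float
    n: int
    residuals_whitened: np.ndarray

    @property
    def k_parameters(self) -> int:
        return len(self.coefficients) + 1 + (1 if self.lambda_estimated else 0)

    @property
    def r_squared_percent(self) -> float:
        return 100.0 * self.r_squared

    def to_dict(self) -> dict:
        return {
            "terms": self.term_names,
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "t_values": self.t_values.tolist(),
            "p_values": self.p_values.tolist(),
            "lambda_hat": self.lambda_hat,
            "lambda_estimated": self.lambda_estimated,
            "lambda_at_boundary": self.lambda_at_boundary,
            "sigma2_ml": self.sigma2_ml,
            "sigma2_unbiased": self.sigma2_unbiased,
            "loglik": self.loglik,
            "aic": self.aic,
            "aic_k": self.k_parameters,
            "f_statistic": self.f_statistic,
            "f_df": list(self.f_df),
            "f_p_value": self.f_p_value,
            "r_squared": self.r_squared,
            "r_squared_percent": self.r_squared_percent,
            "n": self.n,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        """R-style fixed-width coefficient table."""
        lines = []
        lam = "n/a" if self.lambda_hat is None else f"{self.lambda_hat:.4f}"
        lines.append(
            f"n = {self.n}   lambda = {lam}   logLik = {self.loglik:.4f}   "
            f"AIC = {self.aic:.4f}"
        )
        lines.append(
            f"F({self.f_df[0]}, {self.f_df[1]}) = {self.f_statistic:.4f}   "
            f"p = {self.f_p_value:.4g}   R^2 = {self.r_squared_percent:.2f}%"
        )
        lines.append("")
        lines.append(
            f"{'term':<28}{'estimate':>12}{'std.err':>12}"
            f"{'t':>10}{'p':>12}"
        )
        for name, b, se, t, p in zip(
            self.term_names, self.coefficients, self.standard_errors,
            self.t_values, self.p_values,
        ):
            star = " *" if p < ALPHA else ""
            lines.append(
                f"{name:<28}{b:>12.5f}{se:>12.5f}{t:>10.3f}{p:>12.4g}{star}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# GLS core


def _whiten(V: np.ndarray):
    """Cholesky factor and log|V|, with a conditioning check."""
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise ModelError(
            "phylogenetic covariance is not positive definite; "
            "reduce lambda or repair the tree's branch lengths"
        ) from exc
    anorm = np.linalg.norm(V, 1)
    rcond, _ = linalg.lapack.dpocon(c, anorm, uplo="L")
    if rcond < RCOND_MIN:
        raise ModelError(
            f"phylogenetic covariance is numerically singular "
            f"(rcond={rcond:.2e}); reduce lambda or repair the tree"
        )
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    return (c, low), logdet


def _gls_core(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Whitened least squares; returns beta, RSS, logdet, whitened (y, X)."""
    (c, low), logdet = _whiten(V)
    L = np.tril(c)
    yw = linalg.solve_triangular(L, y, lower=True, check_finite=False)
    Xw = linalg.solve_triangular(L, X, lower=True, check_finite=False)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < X.shape[1]:
        raise ModelError("whitened design matrix is rank deficient")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    return beta, rss, logdet, yw, Xw, resid


def _loglik_from(rss: float, logdet: float, n: int) -> tuple[float, float]:
    sigma2_ml = rss / n
    ll = -0.5 * (n * math.log(2.0 * math.pi * sigma2_ml) + logdet + n)
    return ll, sigma2_ml


def gls_fit(
    y: np.ndarray,
    X: np.ndarray,
    V: PhyloCovariance | np.ndarray,
    term_names: list[str] | None = None,
    lambda_hat: float | None = None,
    lambda_estimated: bool = False,
) -> PGLSFit:
    """GLS fit at a fixed error covariance V.

    ``V`` may be a :class:`PhyloCovariance` (lambda already applied) or a
    plain matrix.  ``lambda_hat``/``lambda_estimated`` only annotate the
    result (and set the AIC parameter count); the covariance passed in is
    used as-is.
    """
    if isinstance(V, PhyloCovariance):
        lam = V.lambda_applied
        V = V.matrix
        if lambda_hat is None:
            lambda_hat = lam
    V = np.asarray(V, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.shape[0] != n or V.shape != (n, n):
        raise ModelError(
            f"dimension mismatch: y {y.shape}, X {X.shape}, V {V.shape}"
        )
    if n <= p:
        raise ModelError(f"need n > p (n={n}, p={p})")
    if term_names is None:
        term_names = [f"x{i}" for i in range(p)]

    beta, rss, logdet, yw, Xw, resid = _gls_core(y, X, V)
    loglik, sigma2_ml = _loglik_from(rss, logdet, n)
    sigma2_unb = rss / (n - p)

    XtX_inv = np.linalg.inv(Xw.T @ Xw)   # p x p, small
    se = np.sqrt(np.diag(XtX_inv) * sigma2_unb)
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)

    # intercept-only fit under the same V for F and R^2
    has_intercept = np.allclose(X[:, 0], 1.0)
    if p > 1 and has_intercept:
        _, tss, _, _, _, _ = _gls_core(y, X[:, :1], V)
        df1, df2 = p - 1, n - p
        f = ((tss - rss) / df1) / (rss / df2)
        f_p = float(stats.f.sf(f, df1, df2))
        r2 = 1.0 - rss / tss
    else:
        tss = rss
        df1, df2 = max(p - 1, 1), n - p
        f, f_p, r2 = float("nan"), float("nan"), 0.0

    k = p + 1 + (1 if lambda_estimated else 0)
    aic = -2.0 * loglik + 2.0 * k
    at_boundary = lambda_hat is not None and lambda_hat in (0.0, 1.0)
    return PGLSFit(
        term_names=list(term_names),
        coefficients=beta,
        standard_errors=se,
        t_values=tvals,
        p_values=pvals,
        lambda_hat=lambda_hat,
        lambda_estimated=lambda_estimated,
        lambda_at_boundary=at_boundary,
        sigma2_ml=sigma2_ml,
        sigma2_unbiased=sigma2_unb,
        loglik=loglik,
        aic=aic,
        f_statistic=f,
        f_df=(df1, df2),
        f_p_value=f_p,
        r_squared=r2,
        n=n,
        residuals_whitened=resid,
    )


def glm_fit(
    y: np.ndarray, X: np.ndarray, term_names: list[str] | None = None
) -> PGLSFit:
    """Ordinary least squares (Gaussian GLM): GLS with identity covariance.

    The non-phylogenetic comparator; ``lambda_hat`` is None in the result.
    """
    n = np.asarray(y).ravel().shape[0]
    fit = gls_fit(
        y, X, np.eye(n), term_names=term_names,
        lambda_hat=None, lambda_estimated=False,
    )
    fit.lambda_at_boundary = False
    return fit


# ---------------------------------------------------------------------------
# Lambda profiling


def _profile_loglik(lam, y, X, diag_part, offdiag_part, n):
    V = diag_part + lam * offdiag_part
    _, rss, logdet, _, _, _ = _gls_core(y, X, V)
    ll, _ = _loglik_from(rss, logdet, n)
    return ll


def profile_lambda(
    y: np.ndarray,
    X: np.ndarray,
    vcv_raw: PhyloCovariance,
    term_names: list[str] | None = None,
) -> PGLSFit:
    """ML estimate of Pagel's lambda with the GLS fit at the optimum.

    The profile log-likelihood is evaluated on a 101-point grid over
    [0, 1], then refined with bounded scalar optimization around the grid
    argmax (tolerance 1e-6 in lambda).  The returned lambda-hat is
    guaranteed to have log-likelihood >= every grid point; a maximum at
    0 or 1 is flagged on the fit.
    """
    if vcv_raw.lambda_applied is not None:
        raise ModelError("profile_lambda expects the raw (untransformed) VCV")
    V0 = vcv_raw.matrix
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.shape[0]
    diag_part = np.diag(np.diag(V0))
    offdiag_part = V0 - diag_part

    lls = np.empty_like(LAMBDA_GRID)
    for i, lam in enumerate(LAMBDA_GRID):
        ll = _profile_loglik(lam, y, X, diag_part, offdiag_part, n)
        if not math.isfinite(ll):
            raise ModelError(f"non-finite log-likelihood at lambda={lam}")
        lls[i] = ll
    i_best = int(np.argmax(lls))
    lo = LAMBDA_GRID[max(i_best - 1, 0)]
    hi = LAMBDA_GRID[min(i_best + 1, len(LAMBDA_GRID) - 1)]
    res = optimize.minimize_scalar(
        lambda lam: -_profile_loglik(lam, y, X, diag_part, offdiag_part, n),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": LAMBDA_XTOL},
    )
    lam_hat = float(res.x)
    # never return worse than the grid argmax
    if -res.fun < lls[i_best]:
        lam_hat = float(LAMBDA_GRID[i_best])
    V_hat = lambda_transform(vcv_raw, lam_hat)
    fit = gls_fit(
        y, X, V_hat, term_names=term_names,
        lambda_hat=lam_hat, lambda_estimated=True,
    )
    fit.lambda_at_boundary = lam_hat <= LAMBDA_XTOL or lam_hat >= 1 - LAMBDA_XTOL
    return fit


# ---------------------------------------------------------------------------
# Model selection


def aic_select(candidates: list[tuple[ModelSpec, PGLSFit]]):
    """Rank fitted models by AIC (ascending), with delta-AIC.

    All fits must share the same n (same species, same response).  Ties
    are broken by fewer parameters, then by input order.  Returns a list
    of dicts: formula, aic, delta_aic, k, loglik, lambda_hat, rank.
    """
    if not candidates:
        raise ModelError("no candidate models")
    ns = {fit.n for _, fit in candidates}
    if len(ns) != 1:
        raise ModelError(f"fits disagree on n: {sorted(ns)}")
    order = sorted(
        range(len(candidates)),
        key=lambda i: (candidates[i][1].aic, candidates[i][1].k_parameters, i),
    )
    best = candidates[order[0]][1].aic
    table = []
    for rank, i in enumerate(order, start=1):
        spec, fit = candidates[i]
        table.append(
            {
                "rank": rank,
                "formula": spec.formula(),
                "aic": fit.aic,
                "delta_aic": fit.aic - best,
                "k": fit.k_parameters,
                "loglik": fit.loglik,
                "lambda_hat": fit.lambda_hat,
            }
        )
    return table


#: the full model of the main analysis: latitudinal group, habitat,
#: hemisphere, delta-T, CTmax, sample size, plus the three interactions
#: with group.
FULL_MODEL = ModelSpec(
    response="log10_sd_ctmax",
    terms=["group", "habitat", "hemisphere", "delta_t", "ctmax",
           "n_individuals"],
    interactions=[("group", "delta_t"), ("group", "hemisphere"),
                  ("group", "habitat")],
)

#: the supplementary model adds heating rate as a main effect; species
#: without heating-rate data are dropped before fitting.
HEATING_RATE_MODEL = ModelSpec(
    response="log10_sd_ctmax",
    terms=["group", "habitat", "hemisphere", "delta_t", "ctmax",
           "n_individuals", "heating_rate"],
    interactions=[("group", "delta_t"), ("group", "hemisphere"),
                  ("group", "habitat")],
)
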