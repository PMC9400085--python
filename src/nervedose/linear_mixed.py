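"""Linear and Gaussian linear mixed models with crossed random intercepts.

The inferential engine behind the longitudinal analyses: ordinary
least squares for cross-sectional tables (counts, widths) and REML-
estimated mixed models with up to two *crossed* random intercepts
(animal identity and SPL) for repeated measurements.  Wald t statistics
for fixed effects use Satterthwaite effective degrees of freedom
computed from the inverse expected information of the REML criterion,
the approach of lmerTest.

The solver is dense: with variance ratios lam_g = sigma_g^2/sigma_eps^2
the scaled covariance V* = I + sum_g lam_g Z_g Z_g' is factored by
Cholesky, beta is profiled out by generalised least squares and
sigma_eps^2 analytically, leaving a bounded quasi-Newton search over
the (at most two) ratios from a fixed multi-start grid.  Datasets in
this pipeline are at most a few thousand rows, for which the dense
n x n factorisation is both simple and fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, stats


class ModelError(ValueError):
    """Raised for unusable model specifications or degenerate designs."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description.

    fixed terms are column names or pairwise interactions "a:b";
    an intercept is always included.  Categorical columns are dummy-coded
    with the first sorted level as reference (so "control" is the
    reference treatment).  ``random`` lists 0-2 grouping columns, each
    contributing a crossed random intercept.
    """

    response: str
    fixed: tuple = ()
    random: tuple = ()
    method: str = "REML"

    def __post_init__(self):
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "random", tuple(self.random))
        if self.method not in ("REML", "ML"):
            raise ModelError("method must be 'REML' or 'ML'")
        if len(self.random) > 2:
            raise ModelError("at most two crossed random intercepts are supported")
        if self.response in self.random:
            raise ModelError("random grouping columns must differ from the response")

    def to_dict(self) -> dict:
        return {"response": self.response, "fixed": list(self.fixed),
                "random": list(self.random), "method": self.method}


def _encode_column(df: pd.DataFrame, col: str):
    """Return (matrix, names) for one column: numeric as-is, else treatment dummies."""
    if col not in df.columns:
        raise ModelError(f"column {col!r} not in table")
    s = df[col]
    if pd.api.types.is_numeric_dtype(s):
        return s.to_numpy(dtype=float)[:, None], [col]
    levels = sorted(map(str, s.unique()))
    if len(levels) < 2:
        raise ModelError(f"categorical column {col!r} has a single level")
    vals = s.astype(str).to_numpy()
    cols = [(vals == lv).astype(float) for lv in levels[1:]]
    names = [f"{col}[{lv}]" for lv in levels[1:]]
    return np.column_stack(cols), names


def build_design(spec: ModelSpec, df: pd.DataFrame):
    """Fixed-effect design matrix (with intercept) and crossed random-intercept Zs."""
    if spec.response not in df.columns:
        raise ModelError(f"response column {spec.response!r} not in table")
    n = len(df)
    X_parts = [np.ones((n, 1))]
    names = ["Intercept"]
    for term in spec.fixed:
        if ":" in term:
            a, b = term.split(":", 1)
            Ma, na = _encode_column(df, a)
            Mb, nb = _encode_column(df, b)
            for i, ni in enumerate(na):
                for j, nj in enumerate(nb):
                    X_parts.append((Ma[:, i] * Mb[:, j])[:, None])
                    names.append(f"{ni}:{nj}")
        else:
            M, nn = _encode_column(df, term)
            X_parts.append(M)
            names.extend(nn)
    X = np.hstack(X_parts)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        bad = []
        keep = [0]
        for j in range(1, X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
            else:
                bad.append(names[j])
        raise ModelError(f"design matrix is rank deficient; offending columns: {bad}")

    Z_list = []
    for col in spec.random:
        if col not in df.columns:
            raise ModelError(f"random grouping column {col!r} not in table")
        vals = df[col].astype(str).to_numpy()
        levels = sorted(set(vals))
        if len(levels) < 2:
            raise ModelError(f"random grouping {col!r} has fewer than 2 levels")
        Z = np.column_stack([(vals == lv).astype(float) for lv in levels])
        Z_list.append((col, Z))
    y = df[spec.response].to_numpy(dtype=float)
    return y, X, names, Z_list


@dataclass
class MixedModelFit:
    """Fitted linear (mixed) model.

    ``vc`` maps each random grouping to its variance component sigma_u^2;
    ``sigma2`` is the residual variance.  ``df`` holds the per-coefficient
    Satterthwaite degrees of freedom (n - p for plain OLS fits).
    """

    spec: ModelSpec
    coef_names: list
    beta: np.ndarray
    cov_beta: np.ndarray
    vc: dict
    sigma2: float
    loglik: float
    method: str
    n_obs: int
    t: np.ndarray = None
    df: np.ndarray = None
    pvalues: np.ndarray = None
    converged: bool = True
    boundary: bool = False
    _X: np.ndarray = field(default=None, repr=False)
    _y: np.ndarray = field(default=None, repr=False)
    _Z: list = field(default=None, repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_beta), 0.0, None))

    @property
    def p_fixed(self) -> int:
        return len(self.coef_names)

    def coef_index(self, name_or_idx) -> int:
        if isinstance(name_or_idx, (int, np.integer)):
            return int(name_or_idx)
        matches = [i for i, n in enumerate(self.coef_names)
                   if n == name_or_idx or name_or_idx in n]
        if not matches:
            raise ModelError(f"no coefficient matching {name_or_idx!r}; "
                             f"available: {self.coef_names}")
        return matches[0]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef_names, "estimate": self.beta, "se": self.se,
            "t": self.t, "df": self.df, "p": self.pvalues,
        })

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "coefficients": {
                n: {"estimate": float(b), "se": float(s), "t": float(t),
                    "df": float(d), "p": float(p)}
                for n, b, s, t, d, p in zip(self.coef_names, self.beta, self.se,
                                            self.t, self.df, self.pvalues)
            },
            "variance_components": {k: float(v) for k, v in self.vc.items()},
            "residual_variance": float(self.sigma2),
            "loglik": float(self.loglik),
            "method": self.method,
            "n_obs": self.n_obs,
            "converged": bool(self.converged),
            "boundary": bool(self.boundary),
        }


def fit_lm(spec: ModelSpec, table: pd.DataFrame) -> MixedModelFit:
    """Ordinary least squares; t statistics with df = n - p."""
    if spec.random:
        raise ModelError("fit_lm takes a spec without random terms; use fit_lmem")
    y, X, names, _ = build_design(spec, table)
    n, p = X.shape
    if n <= p:
        raise ModelError(f"n={n} rows cannot identify p={p} coefficients")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    s2 = rss / (n - p)
    XtX_inv = np.linalg.inv(X.T @ X)
    cov = s2 * XtX_inv
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    dfv = np.full(p, float(n - p))
    pv = 2.0 * stats.t.sf(np.abs(t), n - p)
    ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    return MixedModelFit(
        spec=spec, coef_names=names, beta=beta, cov_beta=cov, vc={},
        sigma2=s2, loglik=float(ll), method="OLS", n_obs=n,
        t=t, df=dfv, pvalues=pv, _X=X, _y=y, _Z=[],
    )


def _profiled_criterion(lam, y, X, ZZ_or_Z_list, reml, Z_list=None):
    """-2 log-likelihood (REML or ML) with beta and sigma^2 profiled out.

    When ``Z_list`` is given, also returns the analytic gradient of the
    criterion in the variance ratios: with P* the projected inverse of
    V* = I + sum lam_g Z_g Z_g',

        d(-2l)/dlam_g = tr(P* Z_g Z_g') - (n-p) (y'P* Z_g Z_g' P* y)/q   (REML)
        d(-2l)/dlam_g = tr(V*^-1 Z_g Z_g') - n (y'P* Z_g Z_g' P* y)/q   (ML)
    """
    n, p = X.shape
    Vs = np.eye(n)
    for lam_g, ZZ in zip(lam, ZZ_or_Z_list):
        if lam_g != 0.0:
            Vs = Vs + lam_g * ZZ
    try:
        c, low = sla.cho_factor(Vs, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return np.inf, None
    logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vinv_X = sla.cho_solve((c, low), X, check_finite=False)
    Vinv_y = sla.cho_solve((c, low), y, check_finite=False)
    XtVX = X.T @ Vinv_X
    try:
        beta = np.linalg.solve(XtVX, X.T @ Vinv_y)
    except np.linalg.LinAlgError:
        return np.inf, None
    r = y - X @ beta
    Py = Vinv_y - Vinv_X @ beta        # P* y = V*^-1 (y - X beta_hat)
    q = float(r @ Py)
    if q <= 0:
        q = 1e-300
    if reml:
        s2 = q / (n - p)
        sign, logdetXtVX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf, None
        m2l = ((n - p) * np.log(2 * np.pi * s2) + logdetV + logdetXtVX + (n - p))
    else:
        s2 = q / n
        m2l = n * np.log(2 * np.pi * s2) + logdetV + n
    aux = {"beta": beta, "s2": s2, "XtVX": XtVX, "chol": (c, low)}
    if Z_list is not None:
        grad = np.empty(len(Z_list))
        for g, Z in enumerate(Z_list):
            Vinv_Z = sla.cho_solve((c, low), Z, check_finite=False)
            tr_vinv = float(np.sum(Z * Vinv_Z))
            quad = float(np.sum((Z.T @ Py) ** 2))
            if reml:
                A = Vinv_X.T @ Z                       # p x q_g
                tr_corr = float(np.sum(np.linalg.solve(XtVX, A) * A))
                grad[g] = (tr_vinv - tr_corr) - (n - p) * quad / q
            else:
                grad[g] = tr_vinv - n * quad / q
        aux["grad"] = grad
    return float(m2l), aux


_START_GRID_1 = [(0.01,), (0.5,), (5.0,)]
_START_GRID_2 = [(0.01, 0.01), (0.5, 0.5), (5.0, 5.0), (5.0, 0.1), (0.1, 5.0)]

_BOUNDARY_TOL = 1e-7


def fit_lmem(spec: ModelSpec, table: pd.DataFrame) -> MixedModelFit:
    """REML (or ML) fit of a Gaussian mixed model with 1-2 crossed intercepts.

    Deterministic for fixed data: variance ratios are optimised by
    L-BFGS-B from a fixed grid of starting points.  A ratio converging to
    the zero boundary is clamped at 0 and the fit flagged ``boundary``;
    the t statistics then fall back to the OLS degrees of freedom.
    """
    if not spec.random:
        raise ModelError("fit_lmem requires at least one random grouping; use fit_lm")
    y, X, names, Z_named = build_design(spec, table)
    n, p = X.shape
    if n <= p:
        raise ModelError(f"n={n} rows cannot identify p={p} coefficients")
    Zs = [Z for _, Z in Z_named]
    ZZ_list = [Z @ Z.T for Z in Zs]
    reml = spec.method == "REML"
    q = len(ZZ_list)

    def obj(lam):
        val, aux = _profiled_criterion(lam, y, X, ZZ_list, reml, Z_list=Zs)
        if aux is None:
            return np.inf, np.zeros(q)
        return val, aux["grad"]

    grid = _START_GRID_1 if q == 1 else _START_GRID_2
    best = None
    n_fail = 0
    for start in grid:
        res = optimize.minimize(
            obj, np.array(start), jac=True, method="L-BFGS-B",
            bounds=[(0.0, 1e8)] * q,
            options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-11},
        )
        if not res.success:
            n_fail += 1
        if best is None or res.fun < best.fun:
            best = res
    lam = np.asarray(best.x)
    boundary = bool(np.any(lam < _BOUNDARY_TOL))
    lam = np.where(lam < _BOUNDARY_TOL, 0.0, lam)
    m2l, aux = _profiled_criterion(lam, y, X, ZZ_list, reml)
    if aux is None:
        raise ModelError("mixed-model criterion is degenerate at the optimum")
    s2 = aux["s2"]
    beta = aux["beta"]
    cov_beta = s2 * np.linalg.inv(aux["XtVX"])
    vc = {name: float(l * s2) for (name, _), l in zip(Z_named, lam)}
    converged = n_fail < len(grid)

    fit = MixedModelFit(
        spec=spec, coef_names=names, beta=beta, cov_beta=cov_beta, vc=vc,
        sigma2=float(s2), loglik=float(-0.5 * m2l), method=spec.method,
        n_obs=n, converged=converged, boundary=boundary,
        _X=X, _y=y, _Z=Z_named,
    )
    p_coef = np.empty(p)
    t_coef = np.empty(p)
    df_coef = np.empty(p)
    for j in range(p):
        dfj, tj, pj = satterthwaite_df(fit, j)
        df_coef[j], t_coef[j], p_coef[j] = dfj, tj, pj
    fit.t, fit.df, fit.pvalues = t_coef, df_coef, p_coef
    return fit


def _contrast_vector(fit: MixedModelFit, contrast) -> np.ndarray:
    p = fit.p_fixed
    if isinstance(contrast, (str, int, np.integer)):
        c = np.zeros(p)
        c[fit.coef_index(contrast)] = 1.0
        return c
    c = np.asarray(contrast, dtype=float)
    if c.shape != (p,):
        raise ModelError(f"contrast must have length {p}")
    return c


def _theta_variance(fit: MixedModelFit, theta, c):
    """c' (X' V(theta)^-1 X)^-1 c with theta = (sigma_u^2 per group..., sigma_eps^2)."""
    X = fit._X
    n = X.shape[0]
    V = theta[-1] * np.eye(n)
    for s2g, (_, Z) in zip(theta[:-1], fit._Z):
        if s2g != 0.0:
            V += s2g * (Z @ Z.T)
    cf = sla.cho_factor(V, lower=True, check_finite=False)
    XtVX = X.T @ sla.cho_solve(cf, X, check_finite=False)
    C = np.linalg.inv(XtVX)
    return float(c @ C @ c)


def satterthwaite_df(fit: MixedModelFit, contrast):
    """Satterthwaite df, t and p for a fixed-effect contrast.

    df = 2 g^2 / (grad g' A grad g) with g(theta) the contrast variance,
    the gradient by central finite differences in the variance components
    and A the inverse expected information of the REML criterion
    (I_ij = tr(P V_i P V_j)/2).  In the OLS limit (all variance
    components at the zero boundary) df = n - p exactly.
    """
    c = _contrast_vector(fit, contrast)
    n, p = fit.n_obs, fit.p_fixed
    est = float(c @ fit.beta)
    var_c = float(c @ fit.cov_beta @ c)
    if var_c <= 0:
        raise ModelError("contrast has non-positive variance; singular fit")
    tval = est / np.sqrt(var_c)

    theta_u = np.array([fit.vc[name] for name, _ in fit._Z]) if fit._Z else np.empty(0)
    if theta_u.size == 0 or np.all(theta_u <= 0):
        dfv = float(n - p)
        return dfv, float(tval), float(2.0 * stats.t.sf(abs(tval), dfv))

    theta = np.append(theta_u, fit.sigma2)
    X = fit._X
    V = theta[-1] * np.eye(n)
    ZZ = [Z @ Z.T for _, Z in fit._Z]
    for s2g, M in zip(theta[:-1], ZZ):
        V += s2g * M
    cf = sla.cho_factor(V, lower=True, check_finite=False)
    Vinv = sla.cho_solve(cf, np.eye(n), check_finite=False)
    VX = Vinv @ X
    C = np.linalg.inv(X.T @ VX)
    P = Vinv - VX @ C @ VX.T
    derivs = ZZ + [np.eye(n)]
    k = len(derivs)
    PV = [P @ M for M in derivs]
    info = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            info[i, j] = info[j, i] = 0.5 * float(np.sum(PV[i] * PV[j].T))
    try:
        A = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise ModelError("expected information of the variance components is "
                         "singular; Satterthwaite df unavailable") from exc

    # numerical gradient of g(theta) = Var(c'beta_hat)
    grad = np.empty(k)
    eps3 = np.finfo(float).eps ** (1.0 / 3.0)
    scale = max(fit.sigma2, 1e-12)
    for i in range(k):
        h = eps3 * max(abs(theta[i]), 0.1 * scale)
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] = max(tm[i] - h, 0.0)
        gp = _theta_variance(fit, tp, c)
        gm = _theta_variance(fit, tm, c)
        grad[i] = (gp - gm) / (tp[i] - tm[i])

    denom = float(grad @ A @ grad)
    if denom <= 0 or not np.isfinite(denom):
        dfv = float(n - p)
    else:
        dfv = 2.0 * var_c ** 2 / denom
        dfv = float(min(max(dfv, 1e-6), n - p))
    return dfv, float(tval), float(2.0 * stats.t.sf(abs(tval), dfv))


def cohens_d(group_a, group_b) -> float:
    """Cohen's d = (mean_a - mean_b) / pooled SD (n_a + n_b - 2 denominator)."""
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ModelError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        raise ModelError("zero pooled standard deviation; d undefined")
    return float((a.mean() - b.mean()) / pooled)
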