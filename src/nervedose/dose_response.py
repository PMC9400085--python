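"""Four-parameter log-linear (4PL) dose-response modelling.

The response of the auditory nerve (the sigma ratio) or of a single
auditory neuron (the transduction current) to a tone is modelled as a
logistic function of sound pressure level X (dB SPL):

    Y = c + (d - c) / (1 + exp(b * (X - e)))

with ``c``/``d`` the lower/upper asymptotes, ``e`` the SPL at the
half-maximal response and ``b`` the slope at the inflexion point (the
"Hill coefficient" of audiometric dose-response plots).  Under this
parameterisation an *increasing* curve has ``b < 0`` — the convention of
the drc/LL.4 family used in pharmacology.

Treatment effects are tested two ways: per-parameter Wald t statistics
from independent group fits, and a nested-model (extra sum of squares)
F statistic comparing one curve per treatment group against a single
pooled curve with treatment omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "FourPLParams",
    "FourPLFit",
    "GroupedFourPLFit",
    "TreatmentComparison",
    "PowerLawFit",
    "fourpl",
    "fit_fourpl",
    "fit_grouped_fourpl",
    "treatment_F",
    "fit_power_law",
]

PARAM_NAMES = ("b", "c", "d", "e")


class FitError(ValueError):
    """Raised when a dose-response fit cannot be attempted."""


@dataclass(frozen=True)
class FourPLParams:
    """Parameters of the four-parameter log-linear curve.

    b : slope at the inflexion point, per dB (negative for rising curves)
    c : lower asymptote, response units
    d : upper asymptote, response units
    e : SPL producing the half-way response, dB SPL
    """

    b: float
    c: float
    d: float
    e: float

    def as_array(self) -> np.ndarray:
        return np.array([self.b, self.c, self.d, self.e], dtype=float)

    @classmethod
    def from_array(cls, theta) -> "FourPLParams":
        b, c, d, e = (float(v) for v in theta)
        return cls(b=b, c=c, d=d, e=e)

    def to_dict(self) -> dict:
        return {"b": self.b, "c": self.c, "d": self.d, "e": self.e}


def fourpl(x, params: FourPLParams):
    """Evaluate Y = c + (d-c)/(1+exp(b(x-e))) with an overflow-guarded exponent."""
    x = np.asarray(x, dtype=float)
    # 1/(1+exp(u)) == expit(-u); expit handles extreme arguments without overflow
    s = special.expit(-params.b * (x - params.e))
    return params.c + (params.d - params.c) * s


def _fourpl_theta(x, theta):
    b, c, d, e = theta
    s = special.expit(-b * (x - e))
    return c + (d - c) * s


def _fourpl_jac(x, theta):
    """Analytic Jacobian of the 4PL model wrt (b, c, d, e)."""
    b, c, d, e = theta
    s = special.expit(-b * (x - e))
    sp = s * (1.0 - s)
    J = np.empty((x.size, 4))
    J[:, 0] = -(d - c) * sp * (x - e)   # d/db
    J[:, 1] = 1.0 - s                   # d/dc
    J[:, 2] = s                         # d/dd
    J[:, 3] = (d - c) * sp * b          # d/de
    return J


@dataclass
class FourPLFit:
    """A fitted 4PL curve with uncertainty and diagnostics."""

    params: FourPLParams
    covariance: np.ndarray
    rss: float
    df_residual: int
    converged: bool
    n_obs: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def predict(self, x):
        return fourpl(x, self.params)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "se": dict(zip(PARAM_NAMES, self.se.tolist())),
            "covariance": self.covariance.tolist(),
            "rss": self.rss,
            "df_residual": self.df_residual,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }


def _heuristic_start(x, y):
    c0 = float(np.min(y))
    d0 = float(np.max(y))
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    # SPL nearest the half response
    half = 0.5 * (c0 + d0)
    e0 = float(xs[np.argmin(np.abs(ys - half))])
    # central slope estimate -> b via dY/dX|e = -b (d-c)/4
    span = xs[-1] - xs[0]
    slope = (ys[-1] - ys[0]) / span if span > 0 else 0.0
    if abs(slope) < 1e-12:
        slope = 1e-3
    b0 = -4.0 * slope / max(d0 - c0, 1e-12)
    if b0 == 0.0:
        b0 = -0.1
    return np.array([b0, c0, d0, e0])


def fit_fourpl(xs, ys, weights=None, n_starts: int = 8,
               extra_starts=None) -> FourPLFit:
    """Least-squares fit of the 4PL curve with multi-start initialisation.

    Requires at least 5 distinct (x, y) points spanning more than one SPL
    level.  ``extra_starts`` may supply additional parameter vectors to
    seed the optimiser (used to guarantee nesting between full and
    reduced treatment models).
    """
    x = np.asarray(xs, dtype=float).ravel()
    y = np.asarray(ys, dtype=float).ravel()
    if x.size != y.size:
        raise FitError("x and y must have equal length")
    pts = {(float(a), float(b)) for a, b in zip(x, y)}
    if len(pts) < 5:
        raise FitError(f"need >= 5 distinct (x, y) points, got {len(pts)}")
    if np.unique(x).size < 2:
        raise FitError("responses span a single SPL level; curve is under-determined")
    if np.allclose(y, y[0]):
        raise FitError("all responses identical; 4PL parameters are not identifiable")

    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float).ravel())
        if w.size != x.size or np.any(w < 0):
            raise FitError("weights must be non-negative and match the data length")
    else:
        w = None

    def resid(theta):
        r = _fourpl_theta(x, theta) - y
        return r * w if w is not None else r

    def jac(theta):
        J = _fourpl_jac(x, theta)
        return J * w[:, None] if w is not None else J

    start0 = _heuristic_start(x, y)
    rng = np.random.default_rng(12345)  # fixed: fitting is deterministic
    xrange = float(np.ptp(x))
    starts = [start0]
    for _ in range(max(n_starts - 1, 0)):
        jit = start0.copy()
        jit[0] *= rng.uniform(0.5, 1.5)
        jit[1] += rng.normal(0.0, 0.25 * max(abs(start0[2] - start0[1]), 1e-6))
        jit[2] += rng.normal(0.0, 0.25 * max(abs(start0[2] - start0[1]), 1e-6))
        jit[3] += rng.uniform(-0.35, 0.35) * max(xrange, 1.0)
        starts.append(jit)
    if extra_starts is not None:
        starts.extend(np.asarray(s, dtype=float) for s in extra_starts)

    best = None
    for s0 in starts:
        try:
            res = optimize.least_squares(
                resid, s0, jac=jac, method="trf",
                xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=400,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("all optimisation starts failed")

    rss = float(2.0 * best.cost)
    n = x.size
    dfres = n - 4
    s2 = rss / dfres if dfres > 0 else np.nan
    J = best.jac
    JTJ = J.T @ J
    try:
        cov = s2 * np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(JTJ)
    converged = bool(best.success)
    return FourPLFit(
        params=FourPLParams.from_array(best.x),
        covariance=cov,
        rss=rss,
        df_residual=dfres,
        converged=converged,
        n_obs=n,
    )


@dataclass
class GroupedFourPLFit:
    """Full (per-treatment) and reduced (treatment-omitted) 4PL models."""

    group_names: tuple
    group_fits: dict
    pooled: FourPLFit
    n_obs: int

    @property
    def rss_full(self) -> float:
        return float(sum(f.rss for f in self.group_fits.values()))

    @property
    def rss_reduced(self) -> float:
        return float(self.pooled.rss)

    @property
    def df_full(self) -> int:
        return self.n_obs - 8

    def to_dict(self) -> dict:
        return {
            "groups": {g: f.to_dict() for g, f in self.group_fits.items()},
            "pooled": self.pooled.to_dict(),
            "rss_full": self.rss_full,
            "rss_reduced": self.rss_reduced,
            "df_full": self.df_full,
            "n_obs": self.n_obs,
        }


def fit_grouped_fourpl(table: pd.DataFrame, response_col: str = "sigma",
                       group_col: str = "treatment", spl_col: str = "spl_db",
                       n_starts: int = 8) -> GroupedFourPLFit:
    """Fit one 4PL per treatment group (full model) and one pooled curve (reduced).

    The pooled fit is seeded with both group solutions and each group fit
    with the pooled solution, so the full model's residual sum of squares
    can never exceed the reduced model's (nesting holds numerically).
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise FitError(f"exactly two treatment levels required, got {groups}")
    sub = {g: table[table[group_col] == g] for g in groups}
    for g, t in sub.items():
        if len(t) < 5:
            raise FitError(f"group {g!r} has {len(t)} points; >= 5 required")

    first = {
        g: fit_fourpl(t[spl_col], t[response_col], n_starts=n_starts)
        for g, t in sub.items()
    }
    pooled = fit_fourpl(
        table[spl_col], table[response_col], n_starts=n_starts,
        extra_starts=[f.params.as_array() for f in first.values()],
    )
    group_fits = {
        g: fit_fourpl(t[spl_col], t[response_col], n_starts=n_starts,
                      extra_starts=[first[g].params.as_array(),
                                    pooled.params.as_array()])
        for g, t in sub.items()
    }
    return GroupedFourPLFit(
        group_names=tuple(groups),
        group_fits=group_fits,
        pooled=pooled,
        n_obs=len(table),
    )


@dataclass
class TreatmentComparison:
    """Parameter-wise t tests and the treatment-omitted F statistic."""

    group_names: tuple
    param_diff: dict           # name -> (second group - first group)
    param_se: dict
    param_t: dict
    param_p: dict
    F: float
    F_df: tuple
    F_p: float
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "groups": list(self.group_names),
            "params": {
                k: {
                    "diff": self.param_diff[k],
                    "se": self.param_se[k],
                    "t": self.param_t[k],
                    "p": self.param_p[k],
                }
                for k in PARAM_NAMES
            },
            "F": self.F,
            "F_df": list(self.F_df),
            "F_p": self.F_p,
            "note": self.note,
        }


_RSS_TOL = 1e-10


def treatment_F(grouped: GroupedFourPLFit) -> TreatmentComparison:
    """Extra-sum-of-squares F test of the treatment factor, plus Wald t per parameter.

    F = ((rss_reduced - rss_full)/4) / (rss_full/(n - 8)); larger F means a
    stronger treatment effect.  When both models fit exactly (rss ~ 0 and no
    extra misfit) there is nothing for treatment to explain and F = 0; a
    vanishing full-model rss with genuine reduced-model misfit yields +inf.
    """
    g1, g2 = grouped.group_names
    f1, f2 = grouped.group_fits[g1], grouped.group_fits[g2]
    diff, se, tstat, pval = {}, {}, {}, {}
    df_t = grouped.df_full
    for i, name in enumerate(PARAM_NAMES):
        d_i = f2.params.as_array()[i] - f1.params.as_array()[i]
        s_i = float(np.sqrt(f1.covariance[i, i] + f2.covariance[i, i]))
        diff[name] = float(d_i)
        se[name] = s_i
        if s_i > 0:
            t_i = d_i / s_i
            tstat[name] = float(t_i)
            pval[name] = float(2.0 * stats.t.sf(abs(t_i), df_t))
        else:
            tstat[name] = np.inf if d_i != 0 else 0.0
            pval[name] = 0.0 if d_i != 0 else 1.0

    rss_full = grouped.rss_full
    rss_red = grouped.rss_reduced
    extra = max(rss_red - rss_full, 0.0)
    scale = max(rss_red, 1.0)
    note = ""
    df_num, df_den = 4, grouped.df_full
    if rss_full <= _RSS_TOL * scale:
        if extra <= _RSS_TOL * scale:
            F = 0.0
            Fp = 1.0
            note = "both models fit exactly; no treatment misfit to explain"
        else:
            F = np.inf
            Fp = 0.0
            note = "full model fits exactly while the reduced model does not"
    else:
        F = (extra / df_num) / (rss_full / df_den)
        Fp = float(stats.f.sf(F, df_num, df_den))
    return TreatmentComparison(
        group_names=grouped.group_names,
        param_diff=diff, param_se=se, param_t=tstat, param_p=pval,
        F=float(F), F_df=(df_num, df_den), F_p=Fp, note=note,
    )


@dataclass
class PowerLawFit:
    """Power-law fit of tympanal displacement against sound pressure.

    ``slope_per_db`` is the slope of log10(displacement) per dB SPL;
    ``pressure_exponent`` = slope * 20 is the exponent of displacement as a
    power of sound pressure (pressure doubles every 20/log10-units of dB).
    """

    slope_per_db: float
    pressure_exponent: float
    log10_intercept: float
    r_squared: float
    n_used: int

    def to_dict(self) -> dict:
        return {
            "slope_per_db": self.slope_per_db,
            "pressure_exponent": self.pressure_exponent,
            "log10_intercept": self.log10_intercept,
            "r_squared": self.r_squared,
            "n_used": self.n_used,
        }


def fit_power_law(table: pd.DataFrame, floor_spl: float,
                  displacement_col: str = "displacement_nm",
                  spl_col: str = "spl_db") -> PowerLawFit:
    """OLS of log10(displacement) on SPL for points above the noise floor.

    Points at or below ``floor_spl`` are excluded (they sit on the
    vibrometer noise floor and would bias the exponent).  At least two
    points above the floor are required; two points give an exact line.
    """
    spl = np.asarray(table[spl_col], dtype=float)
    disp = np.asarray(table[displacement_col], dtype=float)
    mask = spl > floor_spl
    spl, disp = spl[mask], disp[mask]
    if spl.size < 2:
        raise FitError(f"need >= 2 points above floor_spl={floor_spl}, got {spl.size}")
    if np.any(disp <= 0):
        raise FitError("non-positive displacements above the floor; cannot take log10")
    res = stats.linregress(spl, np.log10(disp))
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 1.0
    return PowerLawFit(
        slope_per_db=float(res.slope),
        pressure_exponent=float(res.slope * 20.0),
        log10_intercept=float(res.intercept),
        r_squared=r2,
        n_used=int(spl.size),
    )
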