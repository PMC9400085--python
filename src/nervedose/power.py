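"""Power analysis: simulation-based power for mixed models and analytic
noncentral-t power for the two-sample t test.

Two procedures mirror the planning stages of a longitudinal hearing
study.  ``simulate_power_lmem`` repeatedly generates dose-response data
from a known truth, fits the requested (mixed) model and counts how
often the treatment term is declared significant by its Satterthwaite
p value — the simr-style Monte-Carlo power estimate.  ``t_test_power``
and ``a_priori_n`` re-implement the analytic two-sample engine: under a
true standardised difference d the t statistic follows a noncentral t
distribution with df = n1 + n2 - 2 and noncentrality
d * sqrt(n1 n2 / (n1 + n2)); power is the mass beyond the central-t
critical value, and the a-priori sample size is the smallest even total
N (equal groups) reaching a target power.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .linear_mixed import ModelSpec, fit_lm, fit_lmem
from .synthetic import DoseResponseSimConfig, simulate_dose_response


class PowerError(ValueError):
    """Raised for invalid power-analysis settings or unusable simulations."""


@dataclass(frozen=True)
class PowerResult:
    """A power estimate with its provenance.

    ``ci`` is the exact (Clopper-Pearson) binomial 95% interval for
    Monte-Carlo estimates and degenerates to (power, power) for analytic
    values.
    """

    power: float
    n_sims: int
    ci: tuple
    alpha: float
    rule: str
    seed: int | None = None
    n_nonconverged: int = 0

    def __post_init__(self):
        if not (0.0 <= self.power <= 1.0):
            raise PowerError("power must lie in [0, 1]")
        lo, hi = self.ci
        if not (lo - 1e-12 <= self.power <= hi + 1e-12):
            raise PowerError("confidence interval must contain the estimate")

    def to_dict(self) -> dict:
        return {"power": self.power, "n_sims": self.n_sims,
                "ci95": list(self.ci), "alpha": self.alpha, "rule": self.rule,
                "seed": self.seed, "n_nonconverged": self.n_nonconverged}


def _check_alpha(alpha):
    if not (0.0 < alpha < 1.0):
        raise PowerError(f"alpha must lie in (0, 1), got {alpha}")


def _tails(tails):
    if tails not in ("one", "two"):
        raise PowerError("tails must be 'one' or 'two'")
    return tails


def t_test_power(d: float, n_per_group, alpha: float = 0.05,
                 tails: str = "two") -> float:
    """Analytic power of the two-sample t test at standardised effect d."""
    _check_alpha(alpha)
    _tails(tails)
    if not np.isfinite(d):
        raise PowerError("effect size d must be finite")
    if np.isscalar(n_per_group):
        n1 = n2 = int(n_per_group)
    else:
        n1, n2 = (int(v) for v in n_per_group)
    if n1 < 2 or n2 < 2:
        raise PowerError("need at least 2 observations per group")
    df = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    if tails == "one":
        tcrit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(tcrit, df, nc))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


_N_CAP = 1_000_000


def a_priori_n(d: float, target_power: float = 0.95, alpha: float = 0.05,
               tails: str = "one") -> int:
    """Smallest even total N (equal groups, >= 2 per group) with power >= target.

    Starts from the normal-approximation size and searches by increments
    of one animal per group; refuses effects too small to reach the
    target below a one-million cap.
    """
    _check_alpha(alpha)
    _tails(tails)
    if not (0.0 < target_power < 1.0):
        raise PowerError("target_power must lie in (0, 1)")
    if d == 0 or not np.isfinite(d):
        raise PowerError("effect size d must be nonzero and finite")
    a_eff = alpha if tails == "one" else alpha / 2.0
    za = stats.norm.ppf(1.0 - a_eff)
    zb = stats.norm.ppf(target_power)
    approx = 2.0 * ((za + zb) / abs(d)) ** 2
    n = max(2, int(np.floor(approx)) - 2)
    while t_test_power(d, n, alpha, tails) < target_power:
        n += 1
        if 2 * n > _N_CAP:
            raise PowerError(f"target power {target_power} unreachable below "
                             f"N = {_N_CAP} for d = {d}")
    while n > 2 and t_test_power(d, n - 1, alpha, tails) >= target_power:
        n -= 1
    return 2 * n


def _binom_ci(k, n):
    res = stats.binomtest(k, n)
    ci = res.proportion_ci(confidence_level=0.95, method="exact")
    return (float(ci.low), float(ci.high))


def simulate_power_lmem(truth: DoseResponseSimConfig, spec: ModelSpec,
                        n_sims: int = 1000, alpha: float = 0.05,
                        seed: int = 0, term=None,
                        max_nonconverged_frac: float = 0.05) -> PowerResult:
    """Monte-Carlo power of the treatment test under a generative truth.

    Each replicate draws a fresh dose-response table from ``truth``
    (seeded by spawning from ``seed``, so chunked evaluation gives
    identical results), fits ``spec`` (mixed model if it has random
    terms, OLS otherwise) and rejects when the Satterthwaite p of the
    treatment term (default: the first coefficient whose name contains
    "treatment") is below alpha.
    """
    _check_alpha(alpha)
    if n_sims < 100:
        raise PowerError("n_sims must be >= 100 for a usable power estimate")
    children = np.random.SeedSequence(seed).spawn(n_sims)
    rejections = 0
    nonconv = 0
    used = 0
    term_name = None
    for child in children:
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        cfg = replace(truth, seed=rep_seed)
        table = simulate_dose_response(cfg)
        try:
            fit = fit_lmem(spec, table) if spec.random else fit_lm(spec, table)
        except Exception:
            nonconv += 1
            continue
        if not fit.converged:
            nonconv += 1
            continue
        if term_name is None:
            if term is not None:
                idx = fit.coef_index(term)
            else:
                cand = [i for i, nm in enumerate(fit.coef_names)
                        if "treatment" in nm and ":" not in nm]
                if not cand:
                    raise PowerError("no treatment coefficient found; pass term=")
                idx = cand[0]
            term_name = fit.coef_names[idx]
        else:
            idx = fit.coef_index(term_name)
        used += 1
        if fit.pvalues[idx] < alpha:
            rejections += 1
    if nonconv > max_nonconverged_frac * n_sims:
        raise PowerError(f"{nonconv}/{n_sims} replicates failed to converge "
                         f"(> {max_nonconverged_frac:.0%}); power estimate refused")
    power = rejections / used
    return PowerResult(
        power=float(power), n_sims=used, ci=_binom_ci(rejections, used),
        alpha=alpha,
        rule=f"Satterthwaite p of {term_name!r} < {alpha}",
        seed=seed, n_nonconverged=nonconv,
    )
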