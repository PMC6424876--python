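"""Maximum-likelihood machinery shared by the PACE and LKB models.

Both models have the same 3-parameter structure: a volume-effect exponent
(nu or n) turns each patient's map into a scalar summary g_i (gEUp or gEUD),
and a probit sigmoid Phi((g - loc)/(slope * loc)) turns that summary into an
outcome probability, with loc = Tp50 or TD50 and slope = mu or m.

The joint MLE is computed by nested optimization: a deterministic grid plus
bounded scalar refinement over the volume exponent, with the two sigmoid
parameters profiled out exactly by an inner bounded fit at every step.  Since
the inner problem is solved to optimality, the nested optimum is the joint
MLE; the outer grid spans the bounds, guarding against multi-modality, and
the whole procedure is deterministic.

95% confidence intervals come from Wilks' theorem for nested models: the
profile interval {theta : 2 [lnL_max - lnL_profile(theta)] <= 3.841}, with
the other two parameters re-optimized at every profiled value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize
from scipy.special import ndtr
from scipy.stats import chi2

__all__ = ["SigmoidFit", "sigmoid_prob", "bernoulli_loglik", "fit_summary_sigmoid", "wilks_profile_ci"]

EPS_PROB = 1e-12  # probability clipping in the likelihood

PARAM_NAMES = ("volume_exponent", "slope", "loc")


def sigmoid_prob(g: np.ndarray, slope: float, loc: float) -> np.ndarray:
    """Probit dose/probability-response: Phi((g - loc) / (slope * loc))."""
    t = (np.asarray(g, float) - loc) / (slope * loc)
    return ndtr(t)


def bernoulli_loglik(pi: np.ndarray, y: np.ndarray) -> float:
    pi = np.clip(pi, EPS_PROB, 1.0 - EPS_PROB)
    y = np.asarray(y, float)
    return float((y * np.log(pi) + (1.0 - y) * np.log1p(-pi)).sum())


@dataclass
class SigmoidFit:
    """MLE of (volume exponent, slope, loc) with profile-likelihood CIs."""

    volume_exponent: float
    slope: float
    loc: float
    loglik: float
    ci95: dict | None = None
    ci_at_bound: dict | None = None
    n_obs: int = 0

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.volume_exponent, self.slope, self.loc])


class _SummaryLikelihood:
    """Negative log-likelihood over (vol, slope, loc) with a g(vol) cache."""

    def __init__(self, g_of, y, extra_loglik: float = 0.0):
        self.g_of = g_of
        self.y = np.asarray(y, float)
        self.extra = extra_loglik  # constant term from fallback patients
        self._cache: dict[float, np.ndarray] = {}

    def g(self, vol: float) -> np.ndarray:
        key = float(vol)
        if key not in self._cache:
            if len(self._cache) > 256:
                self._cache.clear()
            self._cache[key] = np.asarray(self.g_of(key), float)
        return self._cache[key]

    def nll(self, vol: float, slope: float, loc: float) -> float:
        pi = sigmoid_prob(self.g(vol), slope, loc)
        return -(bernoulli_loglik(pi, self.y) + self.extra)


def _probit_start(g: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Unconstrained probit a + b*g fit; map to (slope, loc) when admissible."""

    def nll(ab):
        pi = ndtr(ab[0] + ab[1] * g)
        pi = np.clip(pi, EPS_PROB, 1 - EPS_PROB)
        return -(y * np.log(pi) + (1 - y) * np.log1p(-pi)).sum()

    res = optimize.minimize(nll, x0=np.array([0.0, 0.0]), method="Nelder-Mead")
    a, b = res.x
    if b > 0 and a < 0:
        return (-1.0 / a, -a / b)  # slope = -1/a, loc = -a/b
    return None


def _inner_fit(
    lik: _SummaryLikelihood,
    vol: float,
    slope_bounds: tuple[float, float],
    loc_bounds: tuple[float, float],
    warm: tuple[float, float] | None = None,
) -> tuple[float, float, float]:
    """Exact MLE of (slope, loc) at a fixed volume exponent."""
    g = lik.g(vol)
    y = lik.y

    def nll2(x):
        return lik.nll(vol, x[0], x[1])

    starts = []
    if warm is not None:
        starts.append(warm)
    ps = _probit_start(g, y)
    if ps is not None:
        starts.append(
            (
                float(np.clip(ps[0], *slope_bounds)),
                float(np.clip(ps[1], *loc_bounds)),
            )
        )
    med = float(np.clip(np.median(g), *loc_bounds))
    for s in (0.15, 0.6):
        starts.append((float(np.clip(s, *slope_bounds)), med))

    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll2,
            x0=np.asarray(x0, float),
            method="L-BFGS-B",
            bounds=[slope_bounds, loc_bounds],
        )
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(best.x[1]), float(best.fun)


def fit_summary_sigmoid(
    g_of: Callable[[float], np.ndarray],
    outcomes: np.ndarray,
    vol_bounds: tuple[float, float],
    slope_bounds: tuple[float, float],
    loc_bounds: tuple[float, float] | None = None,
    loc_bounds_factor: tuple[float, float] = (1.0, 10.0),
    n_grid: int = 12,
    extra_loglik: float = 0.0,
    compute_ci: bool = True,
    ci_level: float = 0.95,
) -> SigmoidFit:
    """Joint MLE of (volume exponent, slope, loc) by nested optimization.

    ``g_of(vol)`` maps the volume exponent to the per-patient summary vector.
    When ``loc_bounds`` is None they are derived from the observed summary
    range over the volume grid: [min * factor_lo, max * factor_hi].
    """
    y = np.asarray(outcomes, float)
    if y.min() == y.max():
        raise ValueError("outcomes must contain both classes")
    lik = _SummaryLikelihood(g_of, y, extra_loglik)

    grid = np.geomspace(vol_bounds[0], vol_bounds[1], n_grid)
    if loc_bounds is None:
        gs = [lik.g(v) for v in grid]
        g_lo = min(float(np.min(g)) for g in gs)
        g_hi = max(float(np.max(g)) for g in gs)
        loc_bounds = (
            max(g_lo * loc_bounds_factor[0], 1e-9),
            g_hi * loc_bounds_factor[1],
        )

    warm = None
    results = []
    for v in grid:
        s, l, f = _inner_fit(lik, v, slope_bounds, loc_bounds, warm)
        warm = (s, l)
        results.append((f, v, s, l))
    results.sort(key=lambda r: r[0])
    f_best, v_best, s_best, l_best = results[0]

    # bounded scalar refinement of the volume exponent around the grid optimum
    i = int(np.argmin(np.abs(grid - v_best)))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    warm_ref = (s_best, l_best)

    def profile_vol(v):
        s, l, f = _inner_fit(lik, v, slope_bounds, loc_bounds, warm_ref)
        return f, s, l

    if hi > lo:
        res = optimize.minimize_scalar(
            lambda v: profile_vol(v)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": max(1e-4, 1e-3 * v_best)},
        )
        f_ref, s_ref, l_ref = profile_vol(float(res.x))
        if f_ref < f_best:
            f_best, v_best, s_best, l_best = f_ref, float(res.x), s_ref, l_ref

    fit = SigmoidFit(
        volume_exponent=v_best,
        slope=s_best,
        loc=l_best,
        loglik=-f_best,
        n_obs=len(y),
    )
    if compute_ci:
        bounds = {
            "volume_exponent": vol_bounds,
            "slope": slope_bounds,
            "loc": loc_bounds,
        }
        fit.ci95, fit.ci_at_bound = _all_profile_cis(
            lik, fit, bounds, level=ci_level
        )
    return fit


# ---------------------------------------------------------------------------
# Wilks profile-likelihood confidence intervals
# ---------------------------------------------------------------------------

def _profile_nll(
    lik: _SummaryLikelihood,
    k: int,
    value: float,
    theta_hat: np.ndarray,
    bounds: dict,
    warm: np.ndarray | None = None,
) -> float:
    """min nll over the other two parameters with parameter k fixed."""
    vol_b = bounds["volume_exponent"]
    slope_b = bounds["slope"]
    loc_b = bounds["loc"]
    start = theta_hat if warm is None else warm

    if k == 0:  # volume exponent fixed: exact inner fit
        _, _, f = _inner_fit(lik, value, slope_b, loc_b, (start[1], start[2]))
        return f

    free = [i for i in range(3) if i != k]
    fb = [(vol_b, slope_b, loc_b)[i] for i in free]

    def nll_free(x):
        theta = np.empty(3)
        theta[k] = value
        theta[free[0]], theta[free[1]] = x
        return lik.nll(*theta)

    best = np.inf
    x0s = [np.array([start[free[0]], start[free[1]]])]
    x0s.append(np.array([theta_hat[free[0]], theta_hat[free[1]]]))
    for x0 in x0s:
        x0 = np.array([np.clip(x0[j], *fb[j]) for j in range(2)])
        res = optimize.minimize(nll_free, x0=x0, method="L-BFGS-B", bounds=fb)
        best = min(best, float(res.fun))
    return best


def wilks_profile_ci(
    lik_nll_profile: Callable[[float], float],
    theta_k_hat: float,
    nll_min: float,
    bounds_k: tuple[float, float],
    level: float = 0.95,
) -> tuple[tuple[float, float], tuple[bool, bool]]:
    """Profile-likelihood interval for one parameter.

    Returns the interval and per-endpoint flags marking endpoints that hit
    the parameter bound with the profile still inside the confidence region.
    """
    target = nll_min + 0.5 * chi2.ppf(level, df=1)

    def excess(v):
        return lik_nll_profile(v) - target

    endpoints = []
    flags = []
    for bound in (bounds_k[0], bounds_k[1]):
        if bound == theta_k_hat:
            endpoints.append(bound)
            flags.append(excess(bound) < 0)
            continue
        # walk toward the bound until the profile exits the confidence region
        fracs = (0.15, 0.35, 0.6, 0.8, 0.95, 1.0)
        prev_v, prev_e = theta_k_hat, -0.5 * chi2.ppf(level, df=1)
        hit = None
        for f in fracs:
            v = theta_k_hat + f * (bound - theta_k_hat)
            e = excess(v)
            if e > 0:
                hit = (prev_v, v)
                break
            prev_v, prev_e = v, e
        if hit is None:
            endpoints.append(bound)
            flags.append(True)  # still inside the region at the bound
        else:
            root = optimize.brentq(excess, hit[0], hit[1], xtol=1e-6, rtol=1e-5)
            endpoints.append(float(root))
            flags.append(False)
    lo, hi = sorted(endpoints)
    return (lo, hi), (flags[0], flags[1])


def _all_profile_cis(
    lik: _SummaryLikelihood,
    fit: SigmoidFit,
    bounds: dict,
    level: float = 0.95,
) -> tuple[dict, dict]:
    nll_min = -fit.loglik
    theta_hat = fit.theta
    ci, at_bound = {}, {}
    for k, name in enumerate(PARAM_NAMES):
        warm = theta_hat.copy()

        def prof(v, k=k):
            return _profile_nll(lik, k, v, theta_hat, bounds, warm)

        interval, flags = wilks_profile_ci(
            prof, theta_hat[k], nll_min, bounds[name], level
        )
        ci[name] = interval
        at_bound[name] = flags
    return ci, at_bound
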