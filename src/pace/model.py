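"""The PACE model: LKB-style aggregation of per-voxel outcome odds.

Given a test patient's per-voxel probability map P(x_j) and reliability map
W(x_j) from the voxelwise backbone, the model summarizes them as the
generalized equivalent uniform probability

    gEUp = [ sum_j P(x_j)^(1/nu) W(x_j) / sum_j W(x_j) ]^nu

and maps it through a probit sigmoid

    PACE = Phi(t),   t = (gEUp - Tp50) / (mu * Tp50),

exactly the LKB functional form with dose replaced by probability.  The three
free parameters — the volume-effect exponent nu, the slope mu, and the
tolerance probability Tp50 — are estimated by maximum likelihood with Wilks
profile-likelihood confidence intervals.

Patients whose W map is identically zero have no defined gEUp; the model
falls back to the training prevalence for them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from . import mle
from .backbone import Backbone, fit_backbone, predict_batch
from .grids import DoseMap, GridSpec, stack_roi_values
from .mle import bernoulli_loglik, sigmoid_prob, wilks_profile_ci  # noqa: F401 (re-export)

__all__ = [
    "PaceParams",
    "PaceModel",
    "geup",
    "geup_batch",
    "pace_probability",
    "pace_loglik",
    "fit_pace",
    "wilks_profile_ci",
]

NU_BOUNDS = (0.01, 1.0)
MU_BOUNDS = (0.01, 2.0)
TP50_BOUNDS = (0.01, 0.99)


# ---------------------------------------------------------------------------
# Eq.-level operations
# ---------------------------------------------------------------------------

def geup_batch(p: np.ndarray, w: np.ndarray, nu: float) -> np.ndarray:
    """gEUp for an (N, M) batch of P/W maps; rows must have sum(W) > 0.

    Computed in log space so tiny P^(1/nu) terms underflow gracefully.
    """
    if nu <= 0:
        raise ValueError("nu must be positive")
    p = np.atleast_2d(np.asarray(p, float))
    w = np.atleast_2d(np.asarray(w, float))
    if p.shape != w.shape:
        raise ValueError("P and W must have the same shape")
    if (w < 0).any():
        raise ValueError("W must be nonnegative")
    wsum = w.sum(axis=1)
    if (wsum <= 0).any():
        raise ValueError("sum of W is zero for at least one patient")
    log_p = np.log(np.clip(p, 1e-300, 1.0))
    log_num = logsumexp(log_p / nu, b=w, axis=1)
    return np.exp(nu * (log_num - np.log(wsum)))


def geup(p_map: np.ndarray, w_map: np.ndarray, nu: float) -> float:
    """gEUp of one patient: W-weighted power mean of P with exponent 1/nu."""
    return float(geup_batch(np.ravel(p_map)[None, :], np.ravel(w_map)[None, :], nu)[0])


def pace_probability(geup_value, mu: float, tp50: float):
    """Probit sigmoid Phi((gEUp - Tp50) / (mu * Tp50))."""
    if mu <= 0 or not 0 < tp50 < 1:
        raise ValueError("require mu > 0 and 0 < Tp50 < 1")
    out = sigmoid_prob(np.asarray(geup_value, float), mu, tp50)
    return float(out) if np.isscalar(geup_value) else out


# ---------------------------------------------------------------------------
# Parameters and likelihood
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PaceParams:
    """MLE of (nu, mu, Tp50) with 95% profile-likelihood intervals."""

    nu: float
    mu: float
    tp50: float
    loglik: float
    ci95: dict | None = None
    ci_at_bound: dict | None = None

    def __post_init__(self) -> None:
        if not (self.nu > 0 and self.mu > 0 and 0 < self.tp50 < 1):
            raise ValueError("invalid PACE parameters")

    def as_dict(self) -> dict:
        return {
            "nu": self.nu,
            "mu": self.mu,
            "tp50": self.tp50,
            "loglik": self.loglik,
            "ci95": self.ci95,
            "ci_at_bound": self.ci_at_bound,
        }


def _split_valid(w: np.ndarray) -> np.ndarray:
    return w.sum(axis=1) > 0


def pace_loglik(
    params: PaceParams | tuple[float, float, float],
    p_maps: np.ndarray,
    w_maps: np.ndarray,
    outcomes: np.ndarray,
    fallback_probability: float | None = None,
) -> float:
    """Bernoulli log-likelihood of the PACE model over a cohort.

    Patients with an all-zero W map get ``fallback_probability`` (default:
    the cohort event rate).
    """
    if isinstance(params, PaceParams):
        nu, mu, tp50 = params.nu, params.mu, params.tp50
    else:
        nu, mu, tp50 = params
    p_maps = np.atleast_2d(p_maps)
    w_maps = np.atleast_2d(w_maps)
    y = np.asarray(outcomes, float)
    valid = _split_valid(w_maps)
    if fallback_probability is None:
        fallback_probability = float(y.mean())
    pi = np.full(len(y), fallback_probability)
    if valid.any():
        g = geup_batch(p_maps[valid], w_maps[valid], nu)
        pi[valid] = pace_probability(g, mu, tp50)
    return bernoulli_loglik(pi, y)


def fit_pace(
    p_maps: np.ndarray,
    w_maps: np.ndarray,
    outcomes: np.ndarray,
    *,
    fallback_probability: float | None = None,
    compute_ci: bool = True,
    n_grid: int = 12,
) -> PaceParams:
    """MLE of (nu, mu, Tp50) given per-patient P/W maps and outcomes.

    Nested optimization: a deterministic grid plus bounded refinement over
    nu, with (mu, Tp50) profiled out exactly at each step (see
    :mod:`pace.mle`).  Patients with all-zero W maps contribute a constant
    fallback term to the likelihood.
    """
    p_maps = np.atleast_2d(np.asarray(p_maps, float))
    w_maps = np.atleast_2d(np.asarray(w_maps, float))
    y = np.asarray(outcomes, float)
    if y.min() == y.max():
        raise ValueError("outcomes must contain both classes")
    valid = _split_valid(w_maps)
    if fallback_probability is None:
        fallback_probability = float(y.mean())
    extra = 0.0
    if (~valid).any():
        warnings.warn(
            f"{int((~valid).sum())} patient(s) with all-zero W map use the "
            "fallback probability",
            stacklevel=2,
        )
        extra = bernoulli_loglik(
            np.full((~valid).sum(), fallback_probability), y[~valid]
        )
    if y[valid].min() == y[valid].max():
        raise ValueError("patients with defined gEUp are single-class")

    pv, wv, yv = p_maps[valid], w_maps[valid], y[valid]

    fit = mle.fit_summary_sigmoid(
        g_of=lambda nu: geup_batch(pv, wv, nu),
        outcomes=yv,
        vol_bounds=NU_BOUNDS,
        slope_bounds=MU_BOUNDS,
        loc_bounds=TP50_BOUNDS,
        n_grid=n_grid,
        extra_loglik=extra,
        compute_ci=compute_ci,
    )
    ci = None
    flags = None
    if fit.ci95 is not None:
        names = {"volume_exponent": "nu", "slope": "mu", "loc": "tp50"}
        ci = {names[k]: v for k, v in fit.ci95.items()}
        flags = {names[k]: v for k, v in fit.ci_at_bound.items()}
    return PaceParams(
        nu=fit.volume_exponent,
        mu=fit.slope,
        tp50=fit.loc,
        loglik=fit.loglik,
        ci95=ci,
        ci_at_bound=flags,
    )


# ---------------------------------------------------------------------------
# End-to-end model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PaceModel:
    """A trained PACE model: voxel backbone + aggregation parameters."""

    backbone: Backbone
    params: PaceParams
    fallback_probability: float

    @classmethod
    def fit(
        cls,
        dose_maps: Sequence[DoseMap] | np.ndarray,
        outcomes: np.ndarray,
        covariates=None,
        grid: GridSpec | None = None,
        *,
        compute_ci: bool = False,
    ) -> "PaceModel":
        """Train backbone and aggregation parameters on one cohort.

        Training predictions are in-sample (backbone and parameters fit on
        the same cohort); honest assessment is delegated to cross-validation
        in :mod:`pace.evaluation`.
        """
        backbone = fit_backbone(dose_maps, outcomes, covariates, grid)
        doses = (
            np.asarray(dose_maps, float)
            if isinstance(dose_maps, np.ndarray)
            else stack_roi_values(dose_maps)
        )
        p, _, w = predict_batch(backbone, doses, covariates)
        params = fit_pace(
            p, w, outcomes,
            fallback_probability=backbone.prevalence,
            compute_ci=compute_ci,
        )
        return cls(
            backbone=backbone,
            params=params,
            fallback_probability=backbone.prevalence,
        )

    def predict_batch(self, doses: np.ndarray, covariates=None) -> np.ndarray:
        """PACE probabilities for an (N, M) matrix of ROI doses."""
        doses = np.atleast_2d(np.asarray(doses, float))
        p, _, w = predict_batch(self.backbone, doses, covariates)
        valid = _split_valid(w)
        out = np.full(len(doses), self.fallback_probability)
        if (~valid).any():
            warnings.warn(
                f"{int((~valid).sum())} test patient(s) with all-zero W map: "
                "returning the fallback probability",
                stacklevel=2,
            )
        if valid.any():
            g = geup_batch(p[valid], w[valid], self.params.nu)
            out[valid] = pace_probability(g, self.params.mu, self.params.tp50)
        return out

    def predict(self, test_dose: DoseMap, test_covariates=None) -> float:
        """PACE probability for one test patient."""
        if not self.backbone.grid.compatible(test_dose.grid):
            raise ValueError("test dose map is not on the model grid")
        cov = None
        if test_covariates is not None:
            cov = np.atleast_2d(np.asarray(test_covariates, float))
        return float(self.predict_batch(test_dose.roi_values()[None, :], cov)[0])
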