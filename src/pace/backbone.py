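"""Voxelwise logistic backbone: one GLM per ROI voxel.

For every ROI voxel x_j a logistic regression ties the N binary outcomes to
the N local doses D_i(x_j) (plus optional scalar covariates shared across
voxels).  Applying the backbone to a test dose map yields, per voxel,

* P(x_j)  — predicted outcome probability at the local test dose,
* CI(x_j) — width of the 95% confidence interval of P(x_j), and
* W(x_j)  — reliability 1/CI(x_j), set to 0 where the fitted dose odds
  ratio is < 1 (dose locally "protective") or the CI is unbounded.

The M fits are performed by a ridge-stabilized Newton (IRLS) solver batched
over voxels with numpy; statsmodels' Logit is used as an independent oracle
in the test suite.  Voxels with (quasi-)separated data are refit with a small
fixed ridge penalty and flagged; voxels with zero dose variance keep a zero
slope with an unbounded interval (hence W = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .grids import DoseMap, GridSpec, stack_roi_values

__all__ = [
    "VoxelGLM",
    "Backbone",
    "PredictionMaps",
    "fit_voxel_glm",
    "fit_backbone",
    "predict_maps",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile
SEPARATION_RIDGE = 0.5  # ridge penalty (standardized scale) for separated fits
BASE_JITTER = 1e-10
W_MAX = 1e6  # reliability cap when the CI width underflows to 0


# ---------------------------------------------------------------------------
# Batched penalized logistic Newton solver
# ---------------------------------------------------------------------------

def _newton_logistic(
    X: np.ndarray,  # (M, N, p) standardized design
    y: np.ndarray,  # (N,)
    penalty: np.ndarray,  # (M, p) ridge weight per coefficient
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit M independent penalized logistic regressions at once.

    Minimizes  -loglik + penalty * beta^2  per voxel.  Returns
    (beta (M,p), covariance (M,p,p) = inverse penalized Hessian, converged).
    """
    m, n, p = X.shape
    y = y.astype(float)
    prev = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    beta = np.zeros((m, p))
    beta[:, 0] = logit(prev)
    eye = np.eye(p)
    converged = np.zeros(m, dtype=bool)

    def _nll(b: np.ndarray) -> np.ndarray:
        eta = np.einsum("mnp,mp->mn", X, b)
        # log(1 + e^eta) - y*eta, computed stably
        ll = np.logaddexp(0.0, eta) - y[None, :] * eta
        return ll.sum(axis=1) + (penalty * b**2).sum(axis=1)

    f = _nll(beta)
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        Xa, ba = X[active], beta[active]
        eta = np.einsum("mnp,mp->mn", Xa, ba)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = np.einsum("mnp,mn->mp", Xa, mu - y[None, :]) + 2.0 * penalty[active] * ba
        hess = np.einsum("mnp,mn,mnq->mpq", Xa, w, Xa)
        hess += 2.0 * penalty[active][:, :, None] * eye[None, :, :]
        hess += BASE_JITTER * eye[None, :, :]
        step = np.linalg.solve(hess, grad[:, :, None])[:, :, 0]
        # backtracking: halve steps that do not decrease the penalized nll
        fa = f[active]
        scale = np.ones(len(ba))
        new_beta = ba - step
        new_f = _nll_rows(X, y, penalty, active, new_beta)
        for _ in range(8):
            worse = new_f > fa + 1e-12
            if not worse.any():
                break
            scale[worse] *= 0.5
            new_beta[worse] = ba[worse] - scale[worse, None] * step[worse]
            new_f[worse] = _nll_rows(X, y, penalty, active, new_beta, rows=worse)[worse]
        delta = np.abs(new_beta - ba).max(axis=1)
        beta[active] = new_beta
        f[active] = new_f
        done = delta < tol
        idx = np.flatnonzero(active)
        converged[idx[done]] = True

    # covariance from the penalized Hessian at the optimum
    eta = np.einsum("mnp,mp->mn", X, beta)
    mu = expit(eta)
    w = mu * (1.0 - mu)
    hess = np.einsum("mnp,mn,mnq->mpq", X, w, X)
    hess += 2.0 * penalty[:, :, None] * eye[None, :, :]
    hess += BASE_JITTER * eye[None, :, :]
    cov = np.linalg.inv(hess)
    return beta, cov, converged


def _nll_rows(X, y, penalty, active, beta_active, rows=None):
    """Penalized nll for the active voxels (optionally only selected rows)."""
    if rows is None:
        Xa, pa, ba = X[active], penalty[active], beta_active
        eta = np.einsum("mnp,mp->mn", Xa, ba)
        ll = np.logaddexp(0.0, eta) - y[None, :] * eta
        return ll.sum(axis=1) + (pa * ba**2).sum(axis=1)
    out = np.empty(len(beta_active))
    idx = np.flatnonzero(active)[rows]
    Xa, pa, ba = X[idx], penalty[idx], beta_active[rows]
    eta = np.einsum("mnp,mp->mn", Xa, ba)
    ll = np.logaddexp(0.0, eta) - y[None, :] * eta
    out[rows] = ll.sum(axis=1) + (pa * ba**2).sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# Public containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelGLM:
    """One voxel's fitted logistic model (original, unstandardized scale).

    ``coefficients`` is ordered (intercept, dose slope, covariates...);
    ``covariance`` is the matching Wald covariance matrix.
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    converged: bool
    separation_flag: bool
    zero_variance: bool = False

    def predict(self, dose: float, covariates: Sequence[float] = ()) -> tuple[float, float]:
        """Return (probability, 95% CI width of the probability) at a dose."""
        x = np.concatenate([[1.0, dose], np.asarray(covariates, float)])
        eta = float(x @ self.coefficients)
        if self.zero_variance:
            return float(expit(eta)), np.inf
        var = float(x @ self.covariance @ x)
        se = np.sqrt(max(var, 0.0))
        lo, hi = expit(eta - Z95 * se), expit(eta + Z95 * se)
        return float(expit(eta)), float(hi - lo)


@dataclass(frozen=True)
class Backbone:
    """The full per-voxel atlas: M fitted logistic models on one grid.

    Coefficients are stored on the standardized feature scale together with
    the standardization constants; :meth:`voxel_glm` converts a single
    voxel's model back to the original dose/covariate scale.
    """

    grid: GridSpec
    coef: np.ndarray = field(repr=False)  # (M, p) standardized scale
    cov: np.ndarray = field(repr=False)  # (M, p, p)
    dose_mean: np.ndarray = field(repr=False)
    dose_sd: np.ndarray = field(repr=False)
    cov_mean: np.ndarray = field(repr=False)
    cov_sd: np.ndarray = field(repr=False)
    covariate_names: tuple[str, ...]
    n_train: int
    prevalence: float
    converged: np.ndarray = field(repr=False)
    separation: np.ndarray = field(repr=False)
    zero_variance: np.ndarray = field(repr=False)

    @property
    def n_voxels(self) -> int:
        return self.grid.n_roi

    def _transform(self, j: int) -> np.ndarray:
        """Linear map A with beta_original = A @ beta_standardized."""
        p = self.coef.shape[1]
        A = np.eye(p)
        sd = self.dose_sd[j] if self.dose_sd[j] > 0 else 1.0
        A[0, 1] = -self.dose_mean[j] / sd
        A[1, 1] = 1.0 / sd
        for k, (cm, cs) in enumerate(zip(self.cov_mean, self.cov_sd)):
            s = cs if cs > 0 else 1.0
            A[0, 2 + k] = -cm / s
            A[2 + k, 2 + k] = 1.0 / s
        return A

    def voxel_glm(self, j: int) -> VoxelGLM:
        A = self._transform(j)
        return VoxelGLM(
            coefficients=A @ self.coef[j],
            covariance=A @ self.cov[j] @ A.T,
            converged=bool(self.converged[j]),
            separation_flag=bool(self.separation[j]),
            zero_variance=bool(self.zero_variance[j]),
        )


@dataclass(frozen=True)
class PredictionMaps:
    """Per-voxel prediction P, CI width, and reliability W for one test map."""

    grid: GridSpec
    p_map: np.ndarray = field(repr=False)
    ci_width_map: np.ndarray = field(repr=False)
    w_map: np.ndarray = field(repr=False)

    def roi_p(self) -> np.ndarray:
        return self.grid.to_roi(self.p_map)

    def roi_w(self) -> np.ndarray:
        return self.grid.to_roi(np.nan_to_num(self.w_map))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _as_covariate_matrix(covariates, n: int) -> tuple[np.ndarray, tuple[str, ...]]:
    if covariates is None:
        return np.empty((n, 0)), ()
    try:  # pandas DataFrame
        names = tuple(str(c) for c in covariates.columns)
        arr = np.asarray(covariates, dtype=float)
    except AttributeError:
        arr = np.atleast_2d(np.asarray(covariates, dtype=float))
        if arr.shape[0] != n and arr.shape[1] == n:
            arr = arr.T
        names = tuple(f"cov{k}" for k in range(arr.shape[1]))
    if arr.shape[0] != n:
        raise ValueError("covariate rows must match the number of patients")
    return arr, names


def _fit_standardized(
    doses: np.ndarray,  # (N, M)
    cov_matrix: np.ndarray,  # (N, K)
    outcomes: np.ndarray,  # (N,)
) -> dict:
    n, m = doses.shape
    k = cov_matrix.shape[1]
    p = 2 + k

    dose_mean = doses.mean(axis=0)
    dose_sd = doses.std(axis=0)
    zero_var = dose_sd == 0
    sd_safe = np.where(zero_var, 1.0, dose_sd)
    z_dose = (doses - dose_mean) / sd_safe  # (N, M)

    cov_mean = cov_matrix.mean(axis=0) if k else np.empty(0)
    cov_sd = cov_matrix.std(axis=0) if k else np.empty(0)
    if k and (cov_sd == 0).any():
        raise ValueError("constant covariate column")
    z_cov = (cov_matrix - cov_mean) / cov_sd if k else cov_matrix

    X = np.empty((m, n, p))
    X[:, :, 0] = 1.0
    X[:, :, 1] = z_dose.T
    if k:
        X[:, :, 2:] = np.broadcast_to(z_cov[None, :, :], (m, n, k))

    # zero-variance dose columns carry no signal: pin the slope at 0
    penalty = np.zeros((m, p))
    penalty[zero_var, 1] = 1.0

    beta, cov, converged = _newton_logistic(X, outcomes, penalty)

    # (quasi-)separation: runaway standardized coefficients or no convergence
    suspect = (~converged) | (np.abs(beta[:, 1:]).max(axis=1) > 15.0)
    suspect &= ~zero_var
    if suspect.any():
        pen = penalty[suspect].copy()
        pen[:, 1:] += SEPARATION_RIDGE
        b2, c2, conv2 = _newton_logistic(X[suspect], outcomes, pen)
        beta[suspect], cov[suspect] = b2, c2
        converged[suspect] = conv2

    return dict(
        coef=beta,
        cov=cov,
        dose_mean=dose_mean,
        dose_sd=dose_sd,
        cov_mean=cov_mean,
        cov_sd=cov_sd,
        converged=converged,
        separation=suspect,
        zero_variance=zero_var,
    )


def fit_backbone(
    dose_maps: Sequence[DoseMap] | np.ndarray,
    outcomes: np.ndarray,
    covariates=None,
    grid: GridSpec | None = None,
) -> Backbone:
    """Fit one logistic model per ROI voxel over the training cohort.

    ``dose_maps`` may be a list of :class:`DoseMap` on a shared grid or a
    pre-stacked (N, M) matrix of ROI doses (then ``grid`` is required).
    Deterministic given its inputs and equivariant under patient reordering.
    """
    if isinstance(dose_maps, np.ndarray):
        if grid is None:
            raise ValueError("grid is required with a pre-stacked dose matrix")
        doses = np.asarray(dose_maps, dtype=float)
        if doses.shape[1] != grid.n_roi:
            raise ValueError("dose matrix does not match the grid ROI size")
    else:
        grid = dose_maps[0].grid
        doses = stack_roi_values(dose_maps)
    outcomes = np.asarray(outcomes).astype(int)
    if set(np.unique(outcomes)) - {0, 1}:
        raise ValueError("outcomes must be binary 0/1")
    if outcomes.min() == outcomes.max():
        raise ValueError("outcomes must contain both classes")
    if len(outcomes) != doses.shape[0]:
        raise ValueError("outcomes length must match the number of dose maps")
    cov_matrix, names = _as_covariate_matrix(covariates, len(outcomes))

    parts = _fit_standardized(doses, cov_matrix, outcomes)
    return Backbone(
        grid=grid,
        covariate_names=names,
        n_train=len(outcomes),
        prevalence=float(outcomes.mean()),
        **parts,
    )


def fit_voxel_glm(
    local_doses: np.ndarray,
    covariates,
    outcomes: np.ndarray,
) -> VoxelGLM:
    """Fit a single voxel's logistic model (original-scale coefficients)."""
    local_doses = np.asarray(local_doses, dtype=float)
    outcomes = np.asarray(outcomes).astype(int)
    cov_matrix, _ = _as_covariate_matrix(covariates, len(outcomes))
    if outcomes.min() == outcomes.max():
        raise ValueError("outcomes must contain both classes")
    if len(outcomes) < cov_matrix.shape[1] + 2:
        raise ValueError("too few patients for the number of covariates")
    parts = _fit_standardized(local_doses[:, None], cov_matrix, outcomes)
    grid = GridSpec((2, 2), roi_mask=np.array([[True, False], [False, False]]))
    bb = Backbone(
        grid=grid,
        covariate_names=tuple(f"cov{k}" for k in range(cov_matrix.shape[1])),
        n_train=len(outcomes),
        prevalence=float(outcomes.mean()),
        **parts,
    )
    return bb.voxel_glm(0)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_batch(
    backbone: Backbone,
    doses: np.ndarray,  # (Nt, M) ROI doses
    covariates=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """P, CI width and W for a batch of test patients; each (Nt, M)."""
    doses = np.atleast_2d(np.asarray(doses, dtype=float))
    nt, m = doses.shape
    if m != backbone.n_voxels:
        raise ValueError("test doses do not match the backbone grid")
    k = len(backbone.covariate_names)
    cov_matrix, _ = _as_covariate_matrix(covariates, nt)
    if cov_matrix.shape[1] != k:
        raise ValueError(
            f"expected {k} covariates {backbone.covariate_names}, "
            f"got {cov_matrix.shape[1]}"
        )
    sd_safe = np.where(backbone.zero_variance, 1.0, backbone.dose_sd)
    z_dose = (doses - backbone.dose_mean) / sd_safe
    z_dose[:, backbone.zero_variance] = 0.0

    p = 2 + k
    F = np.empty((nt, m, p))
    F[:, :, 0] = 1.0
    F[:, :, 1] = z_dose
    if k:
        z_cov = (cov_matrix - backbone.cov_mean) / backbone.cov_sd
        F[:, :, 2:] = z_cov[:, None, :]

    eta = np.einsum("nmp,mp->nm", F, backbone.coef)
    var = np.einsum("nmp,mpq,nmq->nm", F, backbone.cov, F)
    se = np.sqrt(np.maximum(var, 0.0))
    prob = expit(eta)
    ci_width = expit(eta + Z95 * se) - expit(eta - Z95 * se)

    slope_nonneg = backbone.coef[:, 1] >= 0
    informative = slope_nonneg & ~backbone.zero_variance
    with np.errstate(divide="ignore"):
        w = np.where(ci_width > 0, 1.0 / np.maximum(ci_width, 1.0 / W_MAX), W_MAX)
    w = np.where(informative[None, :], w, 0.0)
    ci_width = np.where(backbone.zero_variance[None, :], np.inf, ci_width)
    return prob, ci_width, w


def predict_maps(
    backbone: Backbone,
    test_dose: DoseMap,
    test_covariates=None,
) -> PredictionMaps:
    """Per-voxel prediction (P), CI-width and reliability (W) maps for one patient."""
    if not backbone.grid.compatible(test_dose.grid):
        raise ValueError("test dose map is not on the backbone grid")
    cov = None
    if test_covariates is not None:
        cov = np.atleast_2d(np.asarray(test_covariates, dtype=float))
    prob, ci, w = predict_batch(backbone, test_dose.roi_values()[None, :], cov)
    g = backbone.grid
    return PredictionMaps(
        grid=g,
        p_map=g.from_roi(prob[0]),
        ci_width_map=g.from_roi(ci[0]),
        w_map=g.from_roi(w[0]),
    )
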