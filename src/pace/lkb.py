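"""Reference Lyman-Kutcher-Burman (LKB) NTCP model.

The classical DVH-based benchmark: each dose map is summarized by the
generalized equivalent uniform dose

    gEUD = [ (1/M) sum_j D(x_j)^(1/n) ]^n

and mapped through the probit sigmoid NTCP = Phi((gEUD - TD50)/(m * TD50)).
gEUD is computed directly over ROI voxels, which makes it exactly the
homogeneous-RS special case of the g2EUD statistic; a DVH export utility is
provided for parity with convention.  Parameters (n, m, TD50) are estimated
with the same nested-MLE / Wilks-profile machinery as the PACE model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import mle
from .grids import DoseMap, stack_roi_values
from .mle import sigmoid_prob

__all__ = ["LKBParams", "LKBModel", "geud", "geud_batch", "lkb_probability", "fit_lkb", "dvh"]

N_BOUNDS = (0.01, 1.0)
M_BOUNDS = (0.01, 1.0)


def geud_batch(doses: np.ndarray, n: float) -> np.ndarray:
    """gEUD for an (N_pat, M) matrix of ROI doses: unweighted power mean.

    Computed as the homogeneous special case of the RS-weighted statistic so
    the two agree exactly (bit for bit), not just to rounding.
    """
    from .synthetic import g2eud_batch

    doses = np.atleast_2d(np.asarray(doses, float))
    return g2eud_batch(doses, np.ones(doses.shape[1]), n)


def geud(dose: DoseMap | np.ndarray, n: float) -> float:
    """gEUD of one dose map over its ROI."""
    roi = dose.roi_values() if isinstance(dose, DoseMap) else np.ravel(dose)
    return float(geud_batch(roi[None, :], n)[0])


def lkb_probability(geud_value, m: float, td50: float):
    """NTCP = Phi((gEUD - TD50) / (m * TD50))."""
    if m <= 0 or td50 <= 0:
        raise ValueError("require m > 0 and TD50 > 0")
    out = sigmoid_prob(np.asarray(geud_value, float), m, td50)
    return float(out) if np.isscalar(geud_value) else out


@dataclass(frozen=True)
class LKBParams:
    """MLE of (n, m, TD50) with 95% profile-likelihood intervals."""

    n: float
    m: float
    td50: float
    loglik: float
    ci95: dict | None = None
    ci_at_bound: dict | None = None

    def __post_init__(self) -> None:
        if not (self.n > 0 and self.m > 0 and self.td50 > 0):
            raise ValueError("LKB parameters must be positive")

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "m": self.m,
            "td50": self.td50,
            "loglik": self.loglik,
            "ci95": self.ci95,
            "ci_at_bound": self.ci_at_bound,
        }


def fit_lkb(
    dose_maps: Sequence[DoseMap] | np.ndarray,
    outcomes: np.ndarray,
    *,
    compute_ci: bool = True,
    n_grid: int = 12,
) -> LKBParams:
    """MLE of (n, m, TD50) on a cohort of dose maps.

    TD50 bounds follow the observed gEUD range over the volume-exponent
    grid: [min observed, 10 x max observed].
    """
    doses = (
        np.atleast_2d(np.asarray(dose_maps, float))
        if isinstance(dose_maps, np.ndarray)
        else stack_roi_values(dose_maps)
    )
    y = np.asarray(outcomes, float)
    if y.min() == y.max():
        raise ValueError("outcomes must contain both classes")
    fit = mle.fit_summary_sigmoid(
        g_of=lambda n: geud_batch(doses, n),
        outcomes=y,
        vol_bounds=N_BOUNDS,
        slope_bounds=M_BOUNDS,
        loc_bounds=None,
        loc_bounds_factor=(1.0, 10.0),
        n_grid=n_grid,
        compute_ci=compute_ci,
    )
    ci = None
    flags = None
    if fit.ci95 is not None:
        names = {"volume_exponent": "n", "slope": "m", "loc": "td50"}
        ci = {names[k]: v for k, v in fit.ci95.items()}
        flags = {names[k]: v for k, v in fit.ci_at_bound.items()}
    return LKBParams(
        n=fit.volume_exponent,
        m=fit.slope,
        td50=fit.loc,
        loglik=fit.loglik,
        ci95=ci,
        ci_at_bound=flags,
    )


@dataclass(frozen=True)
class LKBModel:
    """A trained LKB model."""

    params: LKBParams

    @classmethod
    def fit(cls, dose_maps, outcomes, **kwargs) -> "LKBModel":
        return cls(fit_lkb(dose_maps, outcomes, compute_ci=False, **kwargs))

    def predict_batch(self, doses: np.ndarray) -> np.ndarray:
        g = geud_batch(doses, self.params.n)
        return lkb_probability(g, self.params.m, self.params.td50)

    def predict(self, test_dose: DoseMap) -> float:
        return float(self.predict_batch(test_dose.roi_values()[None, :])[0])


def dvh(dose: DoseMap, n_bins: int = 100) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Differential and cumulative DVH of one map over its ROI.

    Returns (bin centers, differential volume fraction, cumulative volume
    fraction at-or-above each bin's lower edge).
    """
    v = dose.roi_values()
    edges = np.linspace(0.0, max(v.max(), 1e-12), n_bins + 1)
    hist, _ = np.histogram(v, bins=edges)
    diff = hist / v.size
    cum = 1.0 - np.concatenate([[0.0], np.cumsum(diff)[:-1]])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, diff, cum
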