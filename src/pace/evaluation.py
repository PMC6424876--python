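"""Model evaluation: discrimination, calibration, cross-validation, learning curves.

Implements the comparison methodology used to benchmark the voxel-based
model against LKB:

* ROC AUC with the Hanley-McNeil standard error and a Z-test for paired
  (correlated) ROC curves;
* calibration plots: observed event fraction vs. mean predicted probability
  in equal-count bins, summarized by an OLS slope/intercept/R^2
  (ideal: slope 1, intercept 0);
* accuracy, balanced accuracy and F1 at a probability threshold;
* leave-one-out cross-validation with full refitting per fold;
* learning curves on synthetic cohorts (train/validation accuracy vs.
  training-set size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, logit, ndtr
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

from .grids import GridSpec
from .lkb import LKBModel
from .model import PaceModel
from .synthetic import SimulationConfig, simulate_cohort, with_n_maps

__all__ = [
    "AUCResult",
    "CalibrationResult",
    "EvaluationReport",
    "LearningCurve",
    "roc_auc",
    "compare_auc",
    "calibration",
    "classification_metrics",
    "evaluate_predictions",
    "loo_cv",
    "learning_curve",
    "fit_model",
]

Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AUCResult:
    auc: float
    se: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_auc(probs: np.ndarray, outcomes: np.ndarray) -> AUCResult:
    """ROC AUC (Mann-Whitney) with Hanley-McNeil SE and a logit-Wald 95% CI."""
    y = np.asarray(outcomes).astype(int)
    p = np.asarray(probs, float)
    if y.min() == y.max():
        raise ValueError("outcomes must contain both classes")
    auc = float(roc_auc_score(y, p))
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    a = float(np.clip(auc, 1e-6, 1 - 1e-6))
    if se == 0:
        ci = (auc, auc)
    else:
        halfwidth = Z95 * se / (a * (1.0 - a))
        ci = (float(expit(logit(a) - halfwidth)), float(expit(logit(a) + halfwidth)))
    return AUCResult(auc=auc, se=se, ci95=ci, n_pos=n_pos, n_neg=n_neg)


def compare_auc(
    probs_a: np.ndarray, probs_b: np.ndarray, outcomes: np.ndarray
) -> tuple[float, float]:
    """Z-test for two paired ROC AUCs (Hanley-McNeil correlated correction).

    The between-model correlation is estimated as the average of the
    within-class Spearman correlations of the two predictors.  Returns
    (Z statistic, two-sided p-value).
    """
    pa = np.asarray(probs_a, float)
    pb = np.asarray(probs_b, float)
    y = np.asarray(outcomes).astype(int)
    if pa.shape != pb.shape or pa.shape != y.shape:
        raise ValueError("predictions and outcomes must be paired (same patients)")
    ra = roc_auc(pa, y)
    rb = roc_auc(pb, y)
    rs = []
    for cls in (0, 1):
        sel = y == cls
        if np.ptp(pa[sel]) == 0 or np.ptp(pb[sel]) == 0:
            rs.append(0.0)
        else:
            rs.append(float(spearmanr(pa[sel], pb[sel]).statistic))
    r = float(np.clip(np.mean(rs), -1.0, 1.0))
    var = ra.se**2 + rb.se**2 - 2.0 * r * ra.se * rb.se
    diff = ra.auc - rb.auc
    if diff == 0:
        return 0.0, 1.0
    if var <= 0:
        return float(np.sign(diff) * np.inf), 0.0
    z = diff / np.sqrt(var)
    p = 2.0 * (1.0 - ndtr(abs(z)))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Calibration and classification metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    bin_pred: np.ndarray = field(repr=False)
    bin_obs: np.ndarray = field(repr=False)


def calibration(
    probs: np.ndarray, outcomes: np.ndarray, n_bins: int = 10
) -> CalibrationResult:
    """Binned calibration line: observed event fraction ~ mean predicted.

    Patients are split into ``n_bins`` equal-count bins by predicted
    probability (bins emptied by ties/small N are merged with a neighbor);
    slope, intercept and R^2 come from an OLS fit on the binned points.
    """
    p = np.asarray(probs, float)
    y = np.asarray(outcomes).astype(int)
    if n_bins < 3:
        raise ValueError("need at least 3 bins")
    if np.ptp(p) == 0:
        raise ValueError("constant predictions: calibration slope undefined")
    order = np.argsort(p, kind="stable")
    chunks = [c for c in np.array_split(order, n_bins) if len(c)]
    bin_pred = np.array([p[c].mean() for c in chunks])
    bin_obs = np.array([y[c].mean() for c in chunks])
    if np.ptp(bin_pred) == 0:
        raise ValueError("all bins share one mean prediction: slope undefined")
    X = sm.add_constant(bin_pred)
    fit = sm.OLS(bin_obs, X).fit()
    return CalibrationResult(
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
        r_squared=float(fit.rsquared),
        bin_pred=bin_pred,
        bin_obs=bin_obs,
    )


def classification_metrics(
    probs: np.ndarray, outcomes: np.ndarray, threshold: float = 0.5
) -> dict:
    """Accuracy, balanced accuracy and F1 at a probability threshold."""
    y = np.asarray(outcomes).astype(int)
    pred = (np.asarray(probs, float) >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n_pos, n_neg = tp + fn, tn + fp
    acc = (tp + tn) / len(y)
    sens = tp / n_pos if n_pos else np.nan
    spec = tn / n_neg if n_neg else np.nan
    bal = np.nanmean([sens, spec])
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return {
        "accuracy": float(acc),
        "balanced_accuracy": float(bal),
        "f1": float(f1),
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
    }


@dataclass(frozen=True)
class EvaluationReport:
    """Discrimination, calibration and classification summary for one model."""

    auc: AUCResult
    calibration: CalibrationResult | None
    accuracy: float
    balanced_accuracy: float
    f1: float
    probs: np.ndarray = field(repr=False)
    outcomes: np.ndarray = field(repr=False)
    threshold: float = 0.5

    def as_dict(self) -> dict:
        cal = None
        if self.calibration is not None:
            cal = {
                "slope": self.calibration.slope,
                "slope_se": self.calibration.slope_se,
                "intercept": self.calibration.intercept,
                "intercept_se": self.calibration.intercept_se,
                "r_squared": self.calibration.r_squared,
            }
        return {
            "auc": self.auc.auc,
            "auc_se": self.auc.se,
            "auc_ci95": list(self.auc.ci95),
            "calibration": cal,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "f1": self.f1,
            "threshold": self.threshold,
        }


def evaluate_predictions(
    probs: np.ndarray,
    outcomes: np.ndarray,
    n_bins: int = 10,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Build a full report from per-patient predicted probabilities."""
    auc = roc_auc(probs, outcomes)
    try:
        cal = calibration(probs, outcomes, n_bins=n_bins)
    except ValueError as err:
        warnings.warn(f"calibration not computed: {err}", stacklevel=2)
        cal = None
    metrics = classification_metrics(probs, outcomes, threshold)
    return EvaluationReport(
        auc=auc,
        calibration=cal,
        accuracy=metrics["accuracy"],
        balanced_accuracy=metrics["balanced_accuracy"],
        f1=metrics["f1"],
        probs=np.asarray(probs, float),
        outcomes=np.asarray(outcomes).astype(int),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Model factory, LOO cross-validation, learning curves
# ---------------------------------------------------------------------------

class PrevalenceModel:
    """Constant predictor: the training event rate (a null baseline)."""

    def __init__(self, rate: float):
        self.rate = float(rate)

    def predict_batch(self, doses: np.ndarray, covariates=None) -> np.ndarray:
        return np.full(np.atleast_2d(doses).shape[0], self.rate)


def fit_model(
    spec: str,
    doses: np.ndarray,
    outcomes: np.ndarray,
    covariates=None,
    grid: GridSpec | None = None,
):
    """Fit a model by name: ``pace``, ``lkb`` or ``prevalence``."""
    if spec == "pace":
        return PaceModel.fit(doses, outcomes, covariates, grid)
    if spec == "lkb":
        return LKBModel.fit(doses, outcomes)
    if spec == "prevalence":
        return PrevalenceModel(np.asarray(outcomes, float).mean())
    raise ValueError(f"unknown model spec {spec!r}")


def _predict(model, doses: np.ndarray, covariates=None) -> np.ndarray:
    if isinstance(model, (PaceModel, PrevalenceModel)):
        return model.predict_batch(doses, covariates)
    return model.predict_batch(doses)


def loo_cv(
    doses: np.ndarray,
    outcomes: np.ndarray,
    covariates=None,
    grid: GridSpec | None = None,
    model: str = "pace",
    fast: bool = False,
    n_bins: int = 10,
    threshold: float = 0.5,
) -> tuple[np.ndarray, EvaluationReport]:
    """Leave-one-out cross-validation with full refitting per fold.

    For every patient the model (voxel backbone and aggregation parameters
    for ``pace``) is refit on the remaining N-1 patients and applied to the
    held-out one, so the out-of-sample prediction never depends on that
    patient's outcome.  ``fast=True`` keeps a single backbone fit on the full
    cohort and only refits the aggregation parameters per fold — cheaper but
    optimistic, since the held-out outcome leaks into the backbone.  Folds
    whose training split loses one class are skipped with a warning (NaN
    prediction, excluded from the report).
    """
    doses = np.atleast_2d(np.asarray(doses, float))
    y = np.asarray(outcomes).astype(int)
    n = len(y)
    if n < 10:
        raise ValueError("LOO needs at least 10 patients")
    cov = None
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T

    fixed_backbone = None
    if fast and model == "pace":
        from .backbone import fit_backbone

        fixed_backbone = fit_backbone(doses, y, cov, grid)

    probs = np.full(n, np.nan)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        y_tr = y[keep]
        if y_tr.min() == y_tr.max():
            warnings.warn(f"fold {i} skipped: single-class training split", stacklevel=2)
            continue
        cov_tr = cov[keep] if cov is not None else None
        cov_te = cov[[i]] if cov is not None else None
        if fixed_backbone is not None:
            from .backbone import predict_batch as _pb
            from .model import fit_pace

            p_tr, _, w_tr = _pb(fixed_backbone, doses[keep], cov_tr)
            params = fit_pace(
                p_tr, w_tr, y_tr,
                fallback_probability=float(y_tr.mean()),
                compute_ci=False,
            )
            m = PaceModel(fixed_backbone, params, float(y_tr.mean()))
        else:
            m = fit_model(model, doses[keep], y_tr, cov_tr, grid)
        probs[i] = _predict(m, doses[[i]], cov_te)[0]

    ok = ~np.isnan(probs)
    report = evaluate_predictions(probs[ok], y[ok], n_bins=n_bins, threshold=threshold)
    return probs, report


@dataclass(frozen=True)
class LearningCurve:
    """Train/validation accuracy vs. training-set size for one model."""

    model: str
    train_sizes: tuple[int, ...]
    train_accuracy: np.ndarray  # (sizes, replicates)
    validation_accuracy: np.ndarray  # (sizes, replicates)
    seed: int
    n_resampled: int = 0

    def mean_train(self) -> np.ndarray:
        return self.train_accuracy.mean(axis=1)

    def mean_validation(self) -> np.ndarray:
        return self.validation_accuracy.mean(axis=1)

    def std_validation(self) -> np.ndarray:
        return self.validation_accuracy.std(axis=1)


def _simulate_split(
    config: SimulationConfig, n_train: int, n_val: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, GridSpec]:
    """One labelled train/validation split under shared threshold and RS map.

    Train and validation maps are drawn from one pooled cohort so a single
    g2EUD threshold (hence one labelling rule) applies to both.
    """
    cohort = simulate_cohort(with_n_maps(config, n_train + n_val), seed)
    doses = cohort.dose_matrix()
    y = cohort.outcomes
    return doses[:n_train], y[:n_train], doses[n_train:], y[n_train:], cohort.grid


def fit_and_score(
    spec: str,
    train_doses: np.ndarray,
    train_y: np.ndarray,
    val_doses: np.ndarray,
    val_y: np.ndarray,
    grid: GridSpec | None = None,
    threshold: float = 0.5,
) -> tuple[float, float]:
    """Fit one model and return (train accuracy, validation accuracy)."""
    m = fit_model(spec, train_doses, train_y, grid=grid)
    acc_tr = classification_metrics(_predict(m, train_doses), train_y, threshold)["accuracy"]
    acc_va = classification_metrics(_predict(m, val_doses), val_y, threshold)["accuracy"]
    return acc_tr, acc_va


def learning_curve(
    config: SimulationConfig,
    model: str,
    train_sizes: Sequence[int] = (25, 50, 100, 200, 400, 800),
    n_replicates: int = 10,
    validation_size: int = 500,
    seed: int = 0,
    threshold: float = 0.5,
) -> LearningCurve:
    """Learning curve on synthetic cohorts, fully seeded.

    For each size and replicate a fresh pooled cohort is simulated, split
    into train/validation, the model is fit on the training part and its
    accuracy recorded on both parts.  Simulated cohorts that come out
    single-class (possible at small sizes) are redrawn with a fresh child
    seed; the count of redraws is reported.
    """
    if min(train_sizes) < 20:
        raise ValueError("training sizes below 20 are not supported")
    master = np.random.default_rng(seed)
    tr = np.empty((len(train_sizes), n_replicates))
    va = np.empty((len(train_sizes), n_replicates))
    n_resampled = 0
    for si, size in enumerate(train_sizes):
        for rep in range(n_replicates):
            for _attempt in range(20):
                child = int(master.integers(2**31))
                dtr, ytr, dva, yva, grid = _simulate_split(
                    config, size, validation_size, child
                )
                if ytr.min() != ytr.max() and yva.min() != yva.max():
                    break
                n_resampled += 1
            else:
                raise RuntimeError("could not simulate a two-class cohort")
            tr[si, rep], va[si, rep] = fit_and_score(
                model, dtr, ytr, dva, yva, grid, threshold
            )
    return LearningCurve(
        model=model,
        train_sizes=tuple(int(s) for s in train_sizes),
        train_accuracy=tr,
        validation_accuracy=va,
        seed=int(seed),
        n_resampled=n_resampled,
    )
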