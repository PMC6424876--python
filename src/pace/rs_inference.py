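"""Radio-sensitivity map inference by probing a trained model.

A trained PACE model can be queried as a learning tool: feeding it a probe
set of synthetic dose maps — each with a single narrow Gaussian hot spot
whose position sweeps the ROI — and reading the predicted complication
probability as a function of hot-spot position reconstructs the level sets
of the underlying radio-sensitivity (RS) map.

Agreement with a ground-truth RS map is scored by the Dice index between
equal-size superlevel sets (the top v*M voxels of each map) as a function of
the volume fraction v, summarized by the normalized area under that curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grids import GridSpec, RSMap
from .model import PaceModel

__all__ = [
    "ProbeSet",
    "RSEstimate",
    "make_probe_set",
    "infer_rs_map",
    "dice_index",
    "superlevel_set",
    "di_v_curve",
    "DEFAULT_V_FRACTIONS",
]

DEFAULT_V_FRACTIONS = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


@dataclass(frozen=True)
class ProbeSet:
    """Single-hot-spot dose maps tiling the ROI at a fixed stride.

    ``doses`` holds one ROI dose vector per probed position (rows);
    ``positions`` the ROI voxel index of each hot-spot center;
    ``boundary_flags`` marks probes whose hot spot is clipped by the ROI
    edge (center within 3 sigma of it).
    """

    grid: GridSpec
    sigma: float  # physical units
    amplitude: float
    stride: int
    doses: np.ndarray = field(repr=False)  # (n_probes, M)
    positions: np.ndarray = field(repr=False)  # (n_probes,) ROI voxel indices
    boundary_flags: np.ndarray = field(repr=False)

    @property
    def n_probes(self) -> int:
        return len(self.positions)


def make_probe_set(
    grid: GridSpec,
    sigma_probe: float = 1.5,
    amplitude: float = 1.0,
    stride: int = 1,
) -> ProbeSet:
    """Build the probe set: one Gaussian hot spot per strided ROI position.

    ``sigma_probe`` is the hot-spot width in voxels (converted to physical
    units with the smallest spacing); ``amplitude`` the peak dose.
    """
    if sigma_probe < 1:
        raise ValueError("probe width must be at least 1 voxel")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride >= min(grid.shape):
        raise ValueError("stride larger than the ROI extent")
    coords = grid.roi_coords()  # (M, ndim)
    idx = np.stack(np.nonzero(grid.roi_mask), axis=-1)  # (M, ndim) voxel indices
    keep = np.all(idx % stride == 0, axis=1)
    centers = coords[keep]
    positions = np.flatnonzero(keep)
    sigma = sigma_probe * min(grid.spacing)

    diff = coords[None, :, :] - centers[:, None, :]
    sq = (diff**2).sum(axis=2)
    doses = amplitude * np.exp(-sq / (2.0 * sigma**2))

    lo, hi = grid.roi_bbox()
    margin = 3.0 * sigma
    clipped = np.any(
        (centers - lo[None, :] < margin) | (hi[None, :] - centers < margin), axis=1
    )
    return ProbeSet(
        grid=grid,
        sigma=float(sigma),
        amplitude=float(amplitude),
        stride=int(stride),
        doses=doses,
        positions=positions,
        boundary_flags=clipped,
    )


@dataclass(frozen=True)
class RSEstimate:
    """PACE probability per probed position, filled to the whole ROI."""

    grid: GridSpec
    values: np.ndarray = field(repr=False)  # full-grid array (NaN outside ROI)
    probe_values: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)
    fallback_flags: np.ndarray = field(repr=False)

    def roi_values(self) -> np.ndarray:
        return self.grid.to_roi(self.values)


def infer_rs_map(model: PaceModel, probes: ProbeSet) -> RSEstimate:
    """Read out the RS level sets: PACE prediction per probe position.

    Positions skipped by the stride are filled by nearest-neighbor
    interpolation.  Probes whose W map is identically zero fall back to the
    model's prevalence and are flagged.
    """
    if not model.backbone.grid.compatible(probes.grid):
        raise ValueError("probe set and model are on different grids")
    from .backbone import predict_batch

    p, _, w = predict_batch(model.backbone, probes.doses)
    wsum = w.sum(axis=1)
    fallback = wsum <= 0
    values = np.full(probes.n_probes, model.fallback_probability)
    if (~fallback).any():
        from .model import geup_batch, pace_probability

        g = geup_batch(p[~fallback], w[~fallback], model.params.nu)
        values[~fallback] = pace_probability(g, model.params.mu, model.params.tp50)
    if fallback.any():
        warnings.warn(
            f"{int(fallback.sum())} probe(s) with all-zero W map use the fallback",
            stacklevel=2,
        )

    grid = probes.grid
    coords = grid.roi_coords()
    full = np.empty(grid.n_roi)
    if probes.n_probes == grid.n_roi:
        full[probes.positions] = values
    else:
        from scipy.spatial import cKDTree

        tree = cKDTree(coords[probes.positions])
        _, nearest = tree.query(coords)
        full = values[nearest]
        full[probes.positions] = values
    return RSEstimate(
        grid=grid,
        values=grid.from_roi(full),
        probe_values=values,
        positions=probes.positions,
        fallback_flags=fallback,
    )


# ---------------------------------------------------------------------------
# Dice index over superlevel sets
# ---------------------------------------------------------------------------

def dice_index(set_a: np.ndarray, set_b: np.ndarray) -> float:
    """Dice overlap 2|A & B| / (|A| + |B|); 1.0 when both sets are empty."""
    a = np.asarray(set_a, bool)
    b = np.asarray(set_b, bool)
    if a.shape != b.shape:
        raise ValueError("sets must share one grid")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def superlevel_set(values: np.ndarray, v_fraction: float) -> np.ndarray:
    """Boolean mask of the top round(v*M) voxels by value.

    Rank-based (not threshold-based) so two sets at the same v always have
    exactly equal size, as the Dice-index construction requires; ties are
    broken by voxel index (stable sort).
    """
    v = np.ravel(np.asarray(values, float))
    m = v.size
    k = int(round(v_fraction * m))
    mask = np.zeros(m, dtype=bool)
    if k > 0:
        order = np.argsort(-v, kind="stable")
        mask[order[:k]] = True
    return mask


def di_v_curve(
    rs_true: RSMap | np.ndarray,
    rs_est: RSEstimate | np.ndarray,
    v_fractions: Sequence[float] = DEFAULT_V_FRACTIONS,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Dice index between equal-size superlevel sets across volume fractions.

    Returns (v fractions, DI_V values, normalized trapezoidal AUC over the
    v range).  Invariant under any strictly monotone transform of either map.
    """
    v_fractions = np.asarray(v_fractions, float)
    if v_fractions.size == 0:
        raise ValueError("empty list of volume fractions")
    if ((v_fractions <= 0) | (v_fractions >= 1)).any():
        raise ValueError("volume fractions must lie in (0, 1)")
    a = rs_true.roi_values() if isinstance(rs_true, RSMap) else np.ravel(rs_true)
    b = rs_est.roi_values() if isinstance(rs_est, RSEstimate) else np.ravel(rs_est)
    if a.shape != b.shape:
        raise ValueError("maps must share one grid")
    di = np.array(
        [dice_index(superlevel_set(a, v), superlevel_set(b, v)) for v in v_fractions]
    )
    if v_fractions.size == 1:
        auc = float(di[0])
    else:
        auc = float(
            np.trapezoid(di, v_fractions) / (v_fractions[-1] - v_fractions[0])
        )
    return v_fractions, di, float(np.clip(auc, 0.0, 1.0))
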