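"""File formats: NIfTI maps, CSV cohort manifests, JSON/YAML configs, model archives.

Conventions
-----------
* Maps (dose, RS, P/W, estimates) are NIfTI volumes; 2D grids are stored as
  single-slice 3D volumes with the voxel spacing in the header.  Coordinates
  are plain 0-based voxel indices (affine = diag(spacing)); no world-space
  math beyond the spacing.
* A cohort is a directory of NIfTI dose maps plus ``manifest.csv`` with
  columns ``id, dose_path, outcome`` and one column per covariate, and an
  ``roi_mask.nii.gz`` defining the common grid.
* Fitted models are saved as a compressed ``.npz`` of arrays plus embedded
  JSON metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .backbone import Backbone
from .grids import DoseMap, GridSpec, RSMap
from .lkb import LKBParams
from .model import PaceModel, PaceParams
from .synthetic import S2GParams, SimulationConfig, SyntheticCohort

__all__ = [
    "Cohort",
    "write_map",
    "read_map",
    "write_cohort",
    "read_cohort",
    "save_pace_model",
    "load_pace_model",
    "load_config",
    "simulation_config_from_dict",
]


# ---------------------------------------------------------------------------
# NIfTI maps
# ---------------------------------------------------------------------------

def _to_volume(grid: GridSpec, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vol = np.asarray(values, float)
    spacing = grid.spacing
    if grid.ndim == 2:
        vol = vol[:, :, None]
        spacing = (*spacing, 1.0)
    affine = np.diag((*spacing, 1.0))
    return vol, affine


def write_map(path, grid: GridSpec, values: np.ndarray) -> None:
    vol, affine = _to_volume(grid, values)
    nib.save(nib.Nifti1Image(vol.astype(np.float64), affine), str(path))


def read_map(path) -> tuple[tuple[int, ...], tuple[float, ...], np.ndarray]:
    """Read a NIfTI volume -> (shape, spacing, values); drops trailing singleton."""
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[: vol.ndim])
    if vol.ndim == 3 and vol.shape[2] == 1:
        vol = vol[:, :, 0]
        spacing = spacing[:2]
    return vol.shape, spacing, vol


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Dose maps on one grid with outcomes and optional scalar covariates."""

    dose_maps: list[DoseMap]
    outcomes: np.ndarray
    covariates: pd.DataFrame | None
    ids: list[str]
    rs_map: RSMap | None = None
    meta: dict = field(default_factory=dict)

    @property
    def grid(self) -> GridSpec:
        return self.dose_maps[0].grid

    def dose_matrix(self) -> np.ndarray:
        from .grids import stack_roi_values

        return stack_roi_values(self.dose_maps)


def write_cohort(
    directory,
    cohort: SyntheticCohort | Cohort,
    covariates: pd.DataFrame | None = None,
) -> Path:
    """Write a cohort directory: dose NIfTIs, ROI mask, manifest.csv (+ meta)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(cohort, SyntheticCohort):
        maps, outcomes, rs, meta = (
            cohort.dose_maps,
            cohort.outcomes,
            cohort.rs_map,
            {
                "threshold": cohort.threshold,
                "n_volume": cohort.n_volume,
                "rng_seed": cohort.rng_seed,
                "g2euds": [float(g) for g in cohort.g2euds],
            },
        )
        ids = [f"p{i:04d}" for i in range(len(maps))]
        cov = covariates
    else:
        maps, outcomes, rs, meta = (
            cohort.dose_maps,
            cohort.outcomes,
            cohort.rs_map,
            dict(cohort.meta),
        )
        ids = cohort.ids
        cov = cohort.covariates if covariates is None else covariates

    grid = maps[0].grid
    write_map(directory / "roi_mask.nii.gz", grid, grid.roi_mask.astype(float))
    rows = []
    for pid, dm, o in zip(ids, maps, outcomes):
        fname = f"dose_{pid}.nii.gz"
        write_map(directory / fname, grid, dm.values)
        rows.append({"id": pid, "dose_path": fname, "outcome": int(o)})
    manifest = pd.DataFrame(rows)
    if cov is not None:
        cov = cov.reset_index(drop=True)
        manifest = pd.concat([manifest, cov], axis=1)
    manifest.to_csv(directory / "manifest.csv", index=False)
    if rs is not None:
        write_map(directory / "rs_map.nii.gz", grid, rs.weights)
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    return directory / "manifest.csv"


def read_cohort(manifest_path) -> Cohort:
    """Read and validate a cohort from its manifest.

    Raises a ValueError naming the offending row on a missing file, a
    non-binary outcome or a grid mismatch.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.csv"
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    required = {"id", "dose_path", "outcome"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate patient id {dup!r} in manifest")

    mask_file = base / "roi_mask.nii.gz"
    roi_mask = None
    grid = None
    if mask_file.exists():
        shape, spacing, vals = read_map(mask_file)
        roi_mask = vals > 0.5
        grid = GridSpec(shape, spacing, roi_mask)

    maps: list[DoseMap] = []
    outcomes = []
    for _, row in df.iterrows():
        pid = row["id"]
        path = base / str(row["dose_path"])
        if not path.exists():
            raise ValueError(f"row {pid!r}: dose map file {path.name} not found")
        o = row["outcome"]
        if o not in (0, 1):
            raise ValueError(f"row {pid!r}: outcome must be 0 or 1, got {o!r}")
        shape, spacing, vals = read_map(path)
        if grid is None:
            grid = GridSpec(shape, spacing, roi_mask)
        if shape != grid.shape or spacing != grid.spacing:
            raise ValueError(f"row {pid!r}: dose map is not on the common grid")
        maps.append(DoseMap(grid, vals))
        outcomes.append(int(o))

    cov_cols = [c for c in df.columns if c not in required]
    cov = df[cov_cols].astype(float) if cov_cols else None
    rs = None
    rs_file = base / "rs_map.nii.gz"
    if rs_file.exists():
        _, _, w = read_map(rs_file)
        rs = RSMap(grid, w)
    meta = {}
    meta_file = base / "meta.json"
    if meta_file.exists():
        meta = json.loads(meta_file.read_text())
    return Cohort(
        dose_maps=maps,
        outcomes=np.asarray(outcomes, dtype=int),
        covariates=cov,
        ids=[str(i) for i in df["id"]],
        rs_map=rs,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Model archives
# ---------------------------------------------------------------------------

def save_pace_model(path, model: PaceModel) -> None:
    """Serialize a trained PACE model to one compressed .npz archive."""
    bb = model.backbone
    meta = {
        "covariate_names": list(bb.covariate_names),
        "n_train": bb.n_train,
        "prevalence": bb.prevalence,
        "params": model.params.as_dict(),
        "fallback_probability": model.fallback_probability,
        "spacing": list(bb.grid.spacing),
    }
    np.savez_compressed(
        str(path),
        meta=json.dumps(meta),
        roi_mask=bb.grid.roi_mask,
        coef=bb.coef,
        cov=bb.cov,
        dose_mean=bb.dose_mean,
        dose_sd=bb.dose_sd,
        cov_mean=bb.cov_mean,
        cov_sd=bb.cov_sd,
        converged=bb.converged,
        separation=bb.separation,
        zero_variance=bb.zero_variance,
    )


def load_pace_model(path) -> PaceModel:
    with np.load(str(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        mask = z["roi_mask"]
        grid = GridSpec(mask.shape, tuple(meta["spacing"]), mask)
        bb = Backbone(
            grid=grid,
            coef=z["coef"],
            cov=z["cov"],
            dose_mean=z["dose_mean"],
            dose_sd=z["dose_sd"],
            cov_mean=z["cov_mean"],
            cov_sd=z["cov_sd"],
            covariate_names=tuple(meta["covariate_names"]),
            n_train=int(meta["n_train"]),
            prevalence=float(meta["prevalence"]),
            converged=z["converged"],
            separation=z["separation"],
            zero_variance=z["zero_variance"],
        )
    p = meta["params"]
    params = PaceParams(
        nu=p["nu"],
        mu=p["mu"],
        tp50=p["tp50"],
        loglik=p["loglik"],
        ci95={k: tuple(v) for k, v in p["ci95"].items()} if p["ci95"] else None,
    )
    return PaceModel(bb, params, float(meta["fallback_probability"]))


def save_params_json(path, params: PaceParams | LKBParams) -> None:
    Path(path).write_text(json.dumps(params.as_dict(), indent=1))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML or JSON run configuration into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def simulation_config_from_dict(cfg: dict) -> SimulationConfig:
    """Build a SimulationConfig from the ``simulation`` section of a config."""
    kwargs = {}
    if "grid_shape" in cfg:
        kwargs["grid_shape"] = tuple(int(s) for s in cfg["grid_shape"])
    for key in ("n_maps", "rs_kind", "volume_exponent", "event_rate", "equalize", "d_max"):
        if key in cfg:
            kwargs[key] = cfg[key]
    for key in ("k_range", "sigma_frac_range", "height_range"):
        if key in cfg:
            kwargs[key] = tuple(cfg[key])
    if "s2g_params" in cfg:
        s = cfg["s2g_params"]
        kwargs["s2g_params"] = S2GParams(
            centers=tuple(tuple(c) for c in s.get("centers", S2GParams().centers)),
            sigma_fracs=tuple(s.get("sigma_fracs", S2GParams().sigma_fracs)),
            amplitudes=tuple(s.get("amplitudes", S2GParams().amplitudes)),
        )
    return SimulationConfig(**kwargs)
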