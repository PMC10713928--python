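"""File formats, study configuration and the full pipeline runner.

Volumes travel as NIfTI-1 (4D for occupancy series, 3D for masks, labels and
parametric maps); concentrations and tables as CSV; study configuration as a
YAML key-value file; every pipeline run writes a JSON manifest with SHA-256
checksums of its artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .emax import ParametricMaps, fit_clusterwise, fit_voxelwise
from .evaluation import cv_reduction, region_summary
from .phantom import (
    Ellipsoid,
    GroundTruth,
    OccupancySeries,
    PhantomSpec,
    simulate_study,
    stage_seed,
)
from .slic import ClusterLabeling, run_slic_occ

__all__ = [
    "read_occupancy_study",
    "write_series",
    "read_labeling",
    "write_labeling",
    "write_maps",
    "write_truth",
    "load_config",
    "spec_from_config",
    "run_pipeline",
]

log = logging.getLogger("slicocc")


def _save_nifti(path: Path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def write_series(series: OccupancySeries, outdir: Path, prefix: str = "occupancy") -> list[Path]:
    """Write a series as one 4D NIfTI (x, y, z, V) + concentration CSV + mask."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img_path = outdir / f"{prefix}_{series.stage}.nii.gz"
    _save_nifti(img_path, np.moveaxis(series.data, 0, -1), series.affine)
    mask_path = outdir / "brain_mask.nii.gz"
    _save_nifti(mask_path, series.brain_mask.astype(np.uint8), series.affine)
    conc_path = outdir / "concentrations.csv"
    pd.DataFrame(
        {"index": np.arange(series.n_volumes), "concentration_ng_ml": series.concentrations}
    ).to_csv(conc_path, index=False, float_format="%.17g")
    return [img_path, mask_path, conc_path]


def read_occupancy_study(series_path, mask_path, conc_path) -> OccupancySeries:
    """Load an externally produced occupancy study and validate its geometry."""
    img = nib.load(str(series_path))
    data4 = np.asarray(img.dataobj, dtype=float)
    if data4.ndim != 4:
        raise ValueError("occupancy series must be a 4D NIfTI")
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    if mask.shape != data4.shape[:3]:
        raise ValueError("mask grid does not match the series grid")
    table = pd.read_csv(conc_path, float_precision="round_trip")
    conc = table.iloc[:, -1].to_numpy(dtype=float)
    if conc.size != data4.shape[3]:
        raise ValueError(
            f"series has {data4.shape[3]} volumes but the table lists {conc.size}"
        )
    if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be positive and strictly increasing")
    data = np.moveaxis(data4, -1, 0).copy()
    data[:, ~mask] = np.nan
    return OccupancySeries(
        data=data,
        concentrations=conc,
        brain_mask=mask,
        stage="external",
        affine=np.asarray(img.affine),
    )


def write_truth(truth: GroundTruth, outdir: Path, affine=None) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    paths = []
    for name, arr, dtype in [
        ("ec50_truth", truth.ec50_image, np.float64),
        ("occmax_truth", truth.occmax_image, np.float64),
        ("labels_truth", truth.label_image, np.int32),
        ("brain_mask", truth.brain_mask.astype(np.uint8), np.uint8),
    ]:
        p = outdir / f"{name}.nii.gz"
        _save_nifti(p, arr.astype(dtype), affine)
        paths.append(p)
    rp = outdir / "regions.json"
    rp.write_text(
        json.dumps({"labels": truth.region_labels, "ec50": truth.region_ec50}, indent=2)
    )
    paths.append(rp)
    return paths


def write_labeling(labeling: ClusterLabeling, outdir: Path, affine=None) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    lab_path = outdir / "cluster_labels.nii.gz"
    _save_nifti(lab_path, labeling.label_image.astype(np.int32), affine)
    rows = [
        {
            "cluster": i + 1,
            "x": c.spatial[0],
            "y": c.spatial[1],
            "z": c.spatial[2],
            "size": c.member_count,
            **{f"f{v}": c.feature[v] for v in range(c.feature.size)},
        }
        for i, c in enumerate(labeling.centers)
    ]
    centers_path = outdir / "cluster_centers.csv"
    pd.DataFrame(rows).to_csv(centers_path, index=False)
    side_path = outdir / "clustering.json"
    side_path.write_text(
        json.dumps(
            {
                "K_initial": labeling.K_initial,
                "K_final": labeling.K_final,
                "m": labeling.m,
                "S": labeling.S,
                "n_iterations": labeling.n_iterations,
                "converged": labeling.converged,
            },
            indent=2,
        )
    )
    return [lab_path, centers_path, side_path]


def read_labeling(lab_path, side_path=None) -> ClusterLabeling:
    img = nib.load(str(lab_path))
    lab = np.asarray(img.dataobj).astype(np.int32)
    meta = {}
    if side_path is not None and Path(side_path).exists():
        meta = json.loads(Path(side_path).read_text())
    kf = int(lab.max())
    return ClusterLabeling(
        label_image=lab,
        centers=[],
        K_initial=int(meta.get("K_initial", kf)),
        K_final=kf,
        m=float(meta.get("m", np.nan)),
        S=float(meta.get("S", np.nan)),
        n_iterations=int(meta.get("n_iterations", 0)),
        converged=bool(meta.get("converged", False)),
    )


def write_maps(maps: ParametricMaps, outdir: Path, prefix: str) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in [
        ("ec50", maps.ec50_image),
        ("cv_ec50", maps.cv_ec50_image),
        ("occmax", maps.occmax_image),
        ("model", maps.model_image.astype(np.int8)),
    ]:
        p = outdir / f"{prefix}_{name}.nii.gz"
        _save_nifti(p, arr, maps.affine)
        paths.append(p)
    return paths


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def spec_from_config(cfg: dict) -> PhantomSpec:
    """Build a PhantomSpec from the ``phantom`` section of a study config."""
    ph = dict(cfg.get("phantom", {}))
    kwargs = {}
    if "grid_shape" in ph:
        kwargs["grid_shape"] = tuple(ph["grid_shape"])
    if "brain_region" in ph:
        b = ph["brain_region"]
        kwargs["brain_region"] = Ellipsoid(tuple(b["center"]), tuple(b["radii"]))
    if "hotspot_regions" in ph:
        kwargs["hotspot_regions"] = [
            (h["name"], Ellipsoid(tuple(h["center"]), tuple(h["radii"])), float(h["ec50"]))
            for h in ph["hotspot_regions"]
        ]
    for key in [
        "voxel_size_mm",
        "background_ec50_range",
        "background_mode",
        "occ_max_true",
        "noise_slope",
        "noise_intercept",
        "sigma_gauss_voxels",
        "smooth_kernel",
    ]:
        if key in ph:
            val = ph[key]
            if key == "background_ec50_range":
                val = tuple(val)
            kwargs[key] = val
    if "concentrations" in ph:
        kwargs["concentrations"] = np.asarray(ph["concentrations"], dtype=float)
    kwargs["seed"] = int(cfg.get("seed", ph.get("seed", 0)))
    return PhantomSpec(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: dict, outdir) -> dict:
    """simulate -> cluster -> fit (voxel + cluster) -> evaluate, with manifest.

    The config either contains a ``phantom`` section (simulation mode) or an
    ``external`` section with series/mask/concentration paths; exactly one of
    the two. Returns the manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    has_phantom = "phantom" in cfg
    has_external = "external" in cfg
    if has_phantom == has_external:
        raise ValueError("config must contain exactly one of 'phantom' or 'external'")

    seed = int(cfg.get("seed", 0))
    artifacts: list[Path] = []
    truth = None
    if has_phantom:
        spec = spec_from_config(cfg)
        log.info("simulating phantom study (grid=%s seed=%d)", spec.grid_shape, seed)
        truth, series = simulate_study(spec)
        artifacts += write_truth(truth, outdir / "truth")
        artifacts += write_series(series, outdir / "series")
    else:
        ext = cfg["external"]
        series = read_occupancy_study(ext["series"], ext["mask"], ext["concentrations"])
        log.info("loaded external series %s", ext["series"])

    clus = dict(cfg.get("clustering", {}))
    K = int(clus.get("K", max(1, int(round(series.brain_mask.sum() / 265.4)))))
    m = float(clus.get("m", 0.5))
    labeling = run_slic_occ(
        series,
        K=K,
        m=m,
        max_iter=int(clus.get("max_iter", 10)),
        tol=float(clus.get("tol", 0.1)),
        enforce_connectivity=bool(clus.get("connectivity", False)),
    )
    log.info("clustering: K=%d -> K_final=%d, %d iterations, converged=%s",
             K, labeling.K_final, labeling.n_iterations, labeling.converged)
    artifacts += write_labeling(labeling, outdir / "clusters", series.affine)

    fit_cfg = dict(cfg.get("fitting", {}))
    occmax_fixed = float(fit_cfg.get("occmax_fixed", 1.0))
    voxel_mask = None
    sub = fit_cfg.get("voxel_subsample")
    if sub:
        # keep the voxel-level stage tractable: hot spots in full plus a
        # random background sample (or a plain mask sample without truth)
        rng = np.random.default_rng(stage_seed(seed, "voxel-subsample"))
        if truth is not None:
            voxel_mask = truth.label_image >= 2
            pool = np.argwhere(truth.label_image == 1)
        else:
            voxel_mask = np.zeros(series.brain_mask.shape, dtype=bool)
            pool = np.argwhere(series.brain_mask)
        take = min(int(sub), pool.shape[0])
        sel = pool[rng.choice(pool.shape[0], size=take, replace=False)]
        voxel_mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    vox_maps = fit_voxelwise(series, occmax_fixed, voxel_mask=voxel_mask)
    artifacts += write_maps(vox_maps, outdir / "maps", "voxel")
    clu_maps, table = fit_clusterwise(series, labeling, occmax_fixed)
    artifacts += write_maps(clu_maps, outdir / "maps", "cluster")
    tpath = outdir / "maps" / "cluster_fits.csv"
    table.to_csv(tpath, index=False)
    artifacts.append(tpath)

    if truth is not None:
        rows = []
        regions = list(truth.region_labels) + ["whole_brain"]
        for region in regions:
            for level, maps_ in [("voxel", vox_maps), ("cluster", clu_maps)]:
                s = region_summary(maps_, truth, region)
                ratio, red = cv_reduction(vox_maps, clu_maps, truth, region)
                rows.append(
                    {
                        "region": s.region_name,
                        "level": level,
                        "n_voxels": s.n_voxels,
                        "ec50_mean": s.ec50_mean,
                        "ec50_sd": s.ec50_sd,
                        "cv_mean": s.cv_mean,
                        "cv_sd": s.cv_sd,
                        "bias_percent": s.bias_percent,
                        "cv_ratio": ratio,
                        "cv_reduction_percent": red,
                    }
                )
        spath = outdir / "region_summaries.csv"
        pd.DataFrame(rows).to_csv(spath, index=False)
        artifacts.append(spath)

    manifest = {
        "seed": seed,
        "mode": "phantom" if has_phantom else "external",
        "K": K,
        "K_final": labeling.K_final,
        "m": m,
        "n_iterations": labeling.n_iterations,
        "artifacts": {str(p.relative_to(outdir)): _sha256(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
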