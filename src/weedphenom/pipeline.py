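"""End-to-end reproducible pipeline: simulate -> process -> validate.

``cmd_simulate`` emits synthetic field scenes for three species-like
configurations (two broad-leaved, one grass-like) with exact trait
truth; ``cmd_process`` reproduces the cloud-processing chain (scale
calibration, statistical filtering, off-surface filtering, bounding-box
isolation, ground fitting, trait extraction); ``cmd_image_la`` runs the
image-based leaf-area procedure on rendered layouts; ``cmd_validate``
joins estimates to truth and writes per-species and pooled validation
reports.

Every stage is driven by one integer seed and a flat configuration
record, and every output carries a provenance block (package version,
seed, configuration hash), so identical configurations yield
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as wio
from .cloudproc import (
    apply_scale,
    calibrate_scale,
    crop_bounding_box,
    fit_ground_plane,
    grid_distance_filter,
    remove_statistical_outliers,
    scale_mesh,
)
from .degrade import DegradationSpec, degrade_mesh, sample_point_cloud
from .errors import InputError, JoinError
from .layout import render_leaf_layout
from .imaging import PRESETS, leaf_area_from_image
from .plants import generate_dicot, generate_monocot
from .scene import build_scene
from .stats import PairedSample, validation_report
from .traits import TraitConfig, extract_traits

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SPECIES_PRESETS", "cmd_simulate", "cmd_process",
           "cmd_image_la", "cmd_validate", "cmd_all"]

#: Morphology regimes for the three emulated species classes.  Height
#: ranges stay inside the 4-30 cm span of the target weed populations;
#: the two dicot classes centre near 12 cm and 7 cm, the monocot class
#: covers the taller grass habit.
SPECIES_PRESETS = {
    "dicot_large": dict(morphotype="dicot", height_range=(8.0, 16.0),
                        n_leaves_range=(5, 8)),
    "dicot_small": dict(morphotype="dicot", height_range=(4.0, 10.5),
                        n_leaves_range=(4, 7)),
    "monocot": dict(morphotype="monocot", height_range=(12.0, 30.0),
                    n_leaves_range=(4, 7)),
}


@dataclass
class PipelineConfig:
    """Flat parameter record for the whole pipeline."""

    seed: int = 0
    n_per_species: int = 10
    species: tuple = ("dicot_large", "dicot_small", "monocot")
    # degradation
    point_density: float = 40.0
    noise_sigma_cm: float = 0.1
    outlier_rate: float = 0.02
    tip_dropout_dicot: float = 0.0
    tip_dropout_monocot: float = 0.05
    mesh_noise_sigma_cm: float = 0.05
    # scene
    scale_range: tuple = (0.5, 3.0)
    n_neighbors: int = 0
    # filters
    sor_k: int = 12
    sor_std_ratio: float = 2.0
    grid_max_dist_cm: float = 0.5
    grid_k: int = 12
    use_crop_box: bool = True
    # ground / traits
    ransac_inlier_cm: float = 0.3
    ransac_trials: int = 300
    stem_radius_cm: float = 1.0
    base_mode: str = "ground"
    subtract_stem_area: bool = True
    # imaging
    coeffs_preset: str = "ga2018"
    px_per_cm: float = 20.0
    square_area_cm2: float = 100.0
    # reporting
    make_plots: bool = False
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for key in ("species", "scale_range"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["species"] = list(d["species"])
        d["scale_range"] = list(d["scale_range"])
        return d

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()


def _provenance(config: PipelineConfig) -> dict:
    from . import __version__

    return {
        "package": "weedphenom",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.sha256(),
    }


def _write_provenance(config: PipelineConfig, out_dir: Path) -> None:
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(_provenance(config), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _stage(name: str, n_in: int, n_out: int, t0: float) -> None:
    log.info("stage=%s in=%d out=%d elapsed=%.3fs",
             name, n_in, n_out, time.perf_counter() - t0)


def _generate_plant(species: str, seed: int):
    preset = SPECIES_PRESETS[species]
    rng = np.random.default_rng(seed)
    h = rng.uniform(*preset["height_range"])
    n_leaves = int(rng.integers(preset["n_leaves_range"][0],
                                preset["n_leaves_range"][1] + 1))
    sub_seed = int(rng.integers(0, 2**31 - 1))
    if preset["morphotype"] == "dicot":
        return generate_dicot(h, n_leaves=n_leaves, seed=sub_seed)
    return generate_monocot(h, n_leaves=n_leaves, seed=sub_seed)


def cmd_simulate(config: PipelineConfig, out_dir) -> pd.DataFrame:
    """Emit synthetic plants: meshes, degraded scenes, layouts, truth CSV.

    Returns the truth table that was written to ``truth.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    rows = []
    for species in config.species:
        for i in range(config.n_per_species):
            pid = f"{species}_{i:03d}"
            seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(seed)
            t0 = time.perf_counter()
            plant = _generate_plant(species, seed)
            dropout = (
                config.tip_dropout_monocot
                if plant.morphotype == "monocot"
                else config.tip_dropout_dicot
            )
            cloud_spec = DegradationSpec(
                point_density=config.point_density,
                noise_sigma_cm=config.noise_sigma_cm,
                outlier_rate=config.outlier_rate,
                tip_dropout_fraction=dropout,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            mesh_spec = DegradationSpec(
                point_density=config.point_density,
                noise_sigma_cm=config.mesh_noise_sigma_cm,
                tip_dropout_fraction=dropout,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            cloud = sample_point_cloud(plant, cloud_spec)
            recon_mesh, recon_info = degrade_mesh(plant, mesh_spec)
            scale = float(rng.uniform(*config.scale_range))
            scn = build_scene(
                cloud,
                scale_factor=scale,
                n_neighbors=config.n_neighbors,
                seed=int(rng.integers(0, 2**31 - 1)),
                ground_density=config.point_density,
            )
            combined, _ = scn.combined()
            layout = render_leaf_layout(
                plant, px_per_cm=config.px_per_cm,
                square_area_cm2=config.square_area_cm2,
                seed=int(rng.integers(0, 2**31 - 1)),
            )

            wio.save_mesh(plant.mesh, out / f"{pid}_mesh.ply")
            wio.save_mesh(recon_mesh.scaled(1.0 / scale),
                          out / f"{pid}_recon_mesh.ply")
            wio.save_cloud(combined, out / f"{pid}_scene.ply")
            wio.save_markers_csv(scn.markers, out / f"{pid}_markers.csv")
            wio.save_image(layout.image, out / f"{pid}_layout.png")

            lo = plant.mesh.vertices.min(axis=0) - 2.0
            hi = plant.mesh.vertices.max(axis=0) + 2.0
            lo[2] = -1.0
            meta = {
                "plant_id": pid,
                "species": species,
                "crop_box_cm": [list(map(float, lo)), list(map(float, hi))],
                "stem_area_cm2": recon_info["stem_area_cm2"],
            }
            with open(out / f"{pid}_meta.json", "w") as fh:
                json.dump(meta, fh, indent=2, sort_keys=True)
                fh.write("\n")

            rows.append({
                "plant_id": pid,
                "species": species,
                "morphotype": plant.morphotype,
                "truth_height_cm": plant.truth_height_cm,
                "truth_leaf_area_cm2": plant.truth_leaf_area_cm2,
                "seed": seed,
            })
            _stage(f"simulate:{pid}", 0, len(combined), t0)

    truth = pd.DataFrame(
        rows,
        columns=["plant_id", "species", "morphotype", "truth_height_cm",
                 "truth_leaf_area_cm2", "seed"],
    )
    truth.to_csv(out / "truth.csv", index=False)
    _write_provenance(config, out)
    return truth


def process_scene(
    config: PipelineConfig,
    cloud,
    markers,
    recon_mesh=None,
    crop_box=None,
    subtract_area_cm2: float = 0.0,
    plant_id: str = "plant",
):
    """Run the processing chain on one loaded scene; returns a TraitRecord.

    Chain: scale calibration -> statistical outlier removal ->
    off-surface (grid) filter -> bounding-box crop -> ground-plane fit ->
    trait extraction.  Calibration runs first because the two distance
    filters operate on metric thresholds.
    """
    t0 = time.perf_counter()
    est = calibrate_scale(markers)
    log.info("stage=calibrate cm_per_unit=%.6g residual_pct=%.3f",
             est.cm_per_unit, est.residual_pct)
    cloud = apply_scale(cloud, est)
    if recon_mesh is not None:
        recon_mesh = scale_mesh(recon_mesh, est)

    n0 = len(cloud)
    t1 = time.perf_counter()
    cloud, removed_sor = remove_statistical_outliers(
        cloud, k=config.sor_k, std_ratio=config.sor_std_ratio
    )
    _stage("statistical_outliers", n0, len(cloud), t1)

    n1 = len(cloud)
    t1 = time.perf_counter()
    cloud, removed_grid = grid_distance_filter(
        cloud, max_dist_cm=config.grid_max_dist_cm, k=config.grid_k
    )
    _stage("grid_filter", n1, len(cloud), t1)

    if crop_box is not None and config.use_crop_box:
        n2 = len(cloud)
        t1 = time.perf_counter()
        cloud = crop_bounding_box(cloud, crop_box[0], crop_box[1])
        _stage("crop", n2, len(cloud), t1)

    ground = fit_ground_plane(
        cloud, inlier_dist_cm=config.ransac_inlier_cm,
        n_trials=config.ransac_trials, seed=config.seed,
    )
    record = extract_traits(
        cloud, recon_mesh, ground,
        TraitConfig(
            stem_radius_cm=config.stem_radius_cm,
            base_mode=config.base_mode,
            subtract_area_cm2=subtract_area_cm2,
        ),
        plant_id=plant_id,
    )
    record.method_flags.update({
        "cm_per_unit": est.cm_per_unit,
        "scale_residual_pct": est.residual_pct,
        "removed_statistical": int(len(removed_sor)),
        "removed_grid": int(len(removed_grid)),
    })
    _stage(f"process:{plant_id}", n0, len(cloud), t0)
    return record


def cmd_process(config: PipelineConfig, scene_dir, out_dir=None) -> pd.DataFrame:
    """Process every ``*_scene.ply`` in ``scene_dir``; write traits.csv."""
    scene_dir = Path(scene_dir)
    out = Path(out_dir) if out_dir is not None else scene_dir
    out.mkdir(parents=True, exist_ok=True)
    records = []
    scenes = sorted(scene_dir.glob("*_scene.ply"))
    if not scenes:
        raise InputError(f"no *_scene.ply files under {scene_dir}")
    for scene_path in scenes:
        pid = scene_path.name[: -len("_scene.ply")]
        markers_path = scene_dir / f"{pid}_markers.csv"
        if not markers_path.exists():
            raise InputError(f"missing marker CSV for {pid}: {markers_path}")
        cloud = wio.load_cloud(scene_path)
        markers = wio.load_markers_csv(markers_path)
        mesh_path = scene_dir / f"{pid}_recon_mesh.ply"
        recon = wio.load_mesh(mesh_path) if mesh_path.exists() else None
        crop_box = None
        subtract = 0.0
        meta_path = scene_dir / f"{pid}_meta.json"
        if meta_path.exists():
            with open(meta_path) as fh:
                meta = json.load(fh)
            crop_box = meta.get("crop_box_cm")
            if config.subtract_stem_area:
                subtract = float(meta.get("stem_area_cm2", 0.0))
        records.append(
            process_scene(
                config, cloud, markers, recon,
                crop_box=crop_box, subtract_area_cm2=subtract, plant_id=pid,
            )
        )
    wio.save_trait_records(records, out / "traits.csv")
    _write_provenance(config, out)
    return pd.DataFrame([r.to_row() for r in records])


def cmd_image_la(config: PipelineConfig, layout_dir, out_dir=None) -> pd.DataFrame:
    """Measure leaf area on every ``*_layout.png``; write image_la.csv."""
    layout_dir = Path(layout_dir)
    out = Path(out_dir) if out_dir is not None else layout_dir
    out.mkdir(parents=True, exist_ok=True)
    coeffs = PRESETS[config.coeffs_preset]
    rows = []
    layouts = sorted(layout_dir.glob("*_layout.png"))
    if not layouts:
        raise InputError(f"no *_layout.png files under {layout_dir}")
    for path in layouts:
        pid = path.name[: -len("_layout.png")]
        img = wio.load_image(path)
        area = leaf_area_from_image(
            img, coeffs, square_area_cm2=config.square_area_cm2
        )
        rows.append({"plant_id": pid, "est_leaf_area_cm2": area})
        log.info("stage=image_la plant=%s area=%.2f", pid, area)
    df = pd.DataFrame(rows, columns=["plant_id", "est_leaf_area_cm2"])
    df.to_csv(out / "image_la.csv", index=False)
    _write_provenance(config, out)
    return df


_TRAIT_COLUMNS = {
    "height": ("truth_height_cm", "est_height_cm"),
    "leaf_area": ("truth_leaf_area_cm2", "est_leaf_area_cm2"),
}


def cmd_validate(truth_csv, estimates_csv, out_dir,
                 config: Optional[PipelineConfig] = None,
                 prefix: str = "validation") -> Dict[str, dict]:
    """Join estimates to truth by plant_id and write validation reports.

    Reports are produced pooled and per species for every trait whose
    estimate column is present.  Plant ids present on one side only
    raise :class:`JoinError` listing the orphans.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = pd.read_csv(truth_csv)
    est = pd.read_csv(estimates_csv)
    orphans = sorted(
        set(truth.plant_id).symmetric_difference(set(est.plant_id))
    )
    if orphans:
        raise JoinError(f"unmatched plant ids: {orphans}", orphans)
    merged = truth.merge(est, on="plant_id", how="inner").sort_values(
        "plant_id", kind="stable"
    )

    groups = {"pooled": merged}
    if "species" in merged.columns:
        for name, sub in merged.groupby("species", sort=True):
            groups[str(name)] = sub

    results: Dict[str, dict] = {}
    tidy_rows = []
    for gname, sub in groups.items():
        results[gname] = {}
        for trait, (tcol, ecol) in _TRAIT_COLUMNS.items():
            if ecol not in sub.columns or tcol not in sub.columns:
                continue
            if len(sub) < 2:
                continue
            report = validation_report(
                PairedSample(sub[tcol].to_numpy(), sub[ecol].to_numpy(),
                             labels=list(sub.plant_id))
            )
            results[gname][trait] = dataclasses.asdict(report)
            tidy_rows.append({"group": gname, "trait": trait,
                              **dataclasses.asdict(report)})
            if config.make_plots:
                _scatter_plot(sub[tcol], sub[ecol], report, trait, gname,
                              out / f"{prefix}_{gname}_{trait}.png")

    with open(out / f"{prefix}.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")
    pd.DataFrame(tidy_rows).to_csv(out / f"{prefix}.csv", index=False)
    _write_provenance(config, out)
    return results


def _scatter_plot(actual, estimated, report, trait, group, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(actual, estimated, s=18)
    xs = np.linspace(min(actual), max(actual), 2)
    ax.plot(xs, report.slope * xs + report.intercept, "r-", lw=1)
    ax.set_xlabel(f"actual {trait}")
    ax.set_ylabel(f"estimated {trait}")
    ax.set_title(f"{group}: R²={report.r_squared:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def cmd_all(config: PipelineConfig, out_dir) -> Dict[str, dict]:
    """simulate -> process -> image-la -> validate, in one directory."""
    out = Path(out_dir)
    cmd_simulate(config, out)
    cmd_process(config, out)
    cmd_image_la(config, out)
    results = cmd_validate(out / "truth.csv", out / "traits.csv", out, config)
    cmd_validate(out / "truth.csv", out / "image_la.csv", out, config,
                 prefix="validation_image_la")
    return results
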