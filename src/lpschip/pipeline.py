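"""End-to-end orchestration: simulate -> generate images -> quantify -> stats.

One reproducible run produces the quantitative panels the study reports:
the LPS concentration profiles and region time courses, per-condition
ICAM-1 / VE-cadherin / THP-1 measurements on synthetic imagery with known
ground truth, condition summaries and pairwise t-tests, plus a manifest
(config snapshot, seeds, file hashes) from which a rerun is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imaging, quantify, stats, transport

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Configuration failed validation."""


# conditions with an ICAM-1 panel; VE-cadherin and THP-1 stop at 8 h because
# 12 h exposure compromised monolayer integrity in the study design
ICAM_CONDITIONS = ("normal", "lps_4h", "lps_8h", "lps_12h")
VECAD_CONDITIONS = ("normal", "lps_4h", "lps_8h")
THP1_CONDITIONS = ("normal", "lps_4h", "lps_8h")


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults reproduce the study conditions."""

    geometry: transport.ChipGeometry = field(
        default_factory=transport.ChipGeometry)
    params: transport.TransportParams = field(
        default_factory=transport.TransportParams)
    dx_um: float = 1.0
    dt_s: float = 10.0
    t_end_s: float = 12 * transport.HOUR
    barrier_mode: str = "resolved"
    source_mode: str = "well_mixed"
    scheme: str = "backward_euler"

    image_shape: tuple = imaging.DEFAULT_SHAPE
    pixel_size_um: float = imaging.DEFAULT_PIXEL_SIZE_UM
    n_images_icam: int = 9          # 3 images x 3 devices
    n_images_vecad: dict = field(default_factory=lambda: {
        "normal": 12, "lps_4h": 12, "lps_8h": 9})
    n_scenes_thp1: int = 4          # devices
    n_dummies: int = 3
    icam_noise_q99: float = 9.0
    vecad_noise_q99: float = 14.0
    tracker_noise_q99: float = 9.0
    thp1_count_scale: float = 0.05  # scene-sized scaling of per-device counts
    wall_fraction: float = 0.4      # wall position as fraction of image width
    min_area_px: int = 20
    save_images: bool = False       # write TIFF stacks + truth sidecars

    icam_conditions: tuple = ICAM_CONDITIONS
    vecad_conditions: tuple = VECAD_CONDITIONS
    thp1_conditions: tuple = THP1_CONDITIONS


_SECTION_FIELDS = {
    "geometry": {f.name: f for f in dataclasses.fields(transport.ChipGeometry)},
    "transport": {f.name: f for f in dataclasses.fields(transport.TransportParams)},
    "simulation": {"dx_um", "dt_s", "t_end_s", "barrier_mode", "source_mode",
                   "scheme"},
    "imaging": {"image_shape", "pixel_size_um", "n_images_icam",
                "n_images_vecad", "n_scenes_thp1", "n_dummies",
                "icam_noise_q99", "vecad_noise_q99", "tracker_noise_q99",
                "thp1_count_scale", "wall_fraction", "save_images",
                "icam_conditions", "vecad_conditions", "thp1_conditions"},
    "quantify": {"min_area_px"},
}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a TOML file.

    Sections [geometry], [transport], [simulation], [imaging], [quantify]
    are all optional; unknown sections or keys raise a
    :class:`ValidationError` naming the offender, as does a condition name
    not present in the calibration table.
    """
    cfg = PipelineConfig()
    if path is None:
        return cfg
    raw = tomllib.loads(Path(path).read_text())
    for section, entries in raw.items():
        if section not in _SECTION_FIELDS:
            raise ValidationError(f"unknown config section [{section}]")
        if not isinstance(entries, dict):
            raise ValidationError(f"section [{section}] must be a table")
        known = _SECTION_FIELDS[section]
        unknown = set(entries) - set(known)
        if unknown:
            raise ValidationError(
                f"unknown key(s) {sorted(unknown)} in [{section}]")
        if section == "geometry":
            cfg.geometry = transport.ChipGeometry(**entries)
        elif section == "transport":
            cfg.params = transport.TransportParams(**entries)
        else:
            for k, v in entries.items():
                if k in ("image_shape", "icam_conditions", "vecad_conditions",
                         "thp1_conditions"):
                    v = tuple(v)
                setattr(cfg, k, v)
    for cond in (*cfg.icam_conditions, *cfg.vecad_conditions,
                 *cfg.thp1_conditions):
        if cond not in imaging.CONDITION_TABLE:
            raise ValidationError(
                f"condition {cond!r} missing from the calibration table; "
                f"known: {sorted(imaging.CONDITION_TABLE)}")
    return cfg


def _seed_for(root_seed: int, *tags: str) -> int:
    """Stable per-stage sub-seed below 2^31."""
    h = hashlib.sha256(("/".join(map(str, tags)) + f"#{root_seed}").encode())
    return int.from_bytes(h.digest()[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_transport_stage(cfg: PipelineConfig, out: Path) -> dict:
    res = transport.run_default_simulation(
        cfg.geometry, cfg.params, dx_um=cfg.dx_um, dt_s=cfg.dt_s,
        t_end_s=cfg.t_end_s, barrier_mode=cfg.barrier_mode,
        source_mode=cfg.source_mode, scheme=cfg.scheme)
    hours = [0, 4, 8, 12]
    prof = pd.DataFrame({"position_um": res.field.x_um})
    for hh in hours:
        t = hh * transport.HOUR
        if t <= cfg.t_end_s:
            prof[f"conc_ugml_{hh}h"] = res.field.line_profile(t)["concentration"]
    prof.to_csv(out / "line_profiles.csv", index=False)
    res.region_series.to_csv(out / "region_means.csv", index=False)
    res.mass_audit.to_csv(out / "mass_audit.csv", index=False)
    vessel_4h = res.field.region_mean("vessel", 4 * transport.HOUR)
    logger.info("vessel mean at 4 h: %.4f ug/mL (mass drift %.2e)",
                vessel_4h, res.max_mass_drift)
    return {"result": res, "vessel_mean_4h_ugml": vessel_4h}


def _project_marker(stack: imaging.ImageStack) -> np.ndarray:
    return quantify.project(stack, "marker", "max")


def _dummy_threshold(cfg: PipelineConfig, q99: float, channel: str,
                     seed: int, tag: str) -> quantify.Threshold:
    dummies = [imaging.generate_dummy_stack(
        imaging.NoiseModel(q99=q99), shape=cfg.image_shape,
        pixel_size_um=cfg.pixel_size_um, seed=_seed_for(seed, tag, i))
        for i in range(cfg.n_dummies)]
    imgs = [quantify.project(d, channel, "max") for d in dummies]
    return quantify.noise_threshold(imgs, dummy_set=tag)


def run_imaging_stage(cfg: PipelineConfig, seed: int, out: Path) -> list:
    """Generate per-condition stacks, quantify them, return QuantRecords."""
    records: list = []
    t_icam = _dummy_threshold(cfg, cfg.icam_noise_q99, "marker", seed, "icam_dummy")
    t_vecad = _dummy_threshold(cfg, cfg.vecad_noise_q99, "marker", seed, "vecad_dummy")
    t_track = _dummy_threshold(cfg, cfg.tracker_noise_q99, "tracker", seed, "tracker_dummy")
    logger.info("thresholds: icam=%d vecad=%d tracker=%d",
                t_icam.value, t_vecad.value, t_track.value)
    img_dir = out / "images"
    if cfg.save_images:
        img_dir.mkdir(exist_ok=True)

    icam_markers: dict = {}
    for cond in cfg.icam_conditions:
        rel = imaging.CONDITION_TABLE[cond]["icam1_rel_int"]
        icam_markers[cond] = []
        for i in range(cfg.n_images_icam):
            s = _seed_for(seed, "icam", cond, i)
            rng = np.random.default_rng(s)
            f = imaging.sample_condition_fraction(cond, "icam1", rng)
            stack, truth = imaging.generate_marker_stack(
                f=f, marker_mean=60.0 * rel,
                noise=imaging.NoiseModel(q99=cfg.icam_noise_q99),
                shape=cfg.image_shape, pixel_size_um=cfg.pixel_size_um,
                seed=s, condition=cond)
            image_id = f"icam_{cond}_{i:02d}"
            records += quantify.quantify_marker_stack(
                stack, t_icam, metric="icam1", image_id=image_id)
            icam_markers[cond].append(_project_marker(stack))
            if cfg.save_images:
                stack.save_tiff(img_dir / f"{image_id}.tif")
                truth.save(img_dir / f"{image_id}.truth.json")
    norm = quantify.icam1_norm_intensity(icam_markers, t_icam,
                                         normal_condition="normal")
    for cond, vals in norm.items():
        for i, v in enumerate(vals):
            records.append(quantify.QuantRecord(
                f"icam_{cond}_{i:02d}", cond, "icam1_norm_intensity", v))

    for cond in cfg.vecad_conditions:
        for i in range(cfg.n_images_vecad.get(cond, cfg.n_images_icam)):
            s = _seed_for(seed, "vecad", cond, i)
            rng = np.random.default_rng(s)
            j = imaging.sample_condition_fraction(cond, "vecad", rng)
            stack, truth = imaging.generate_junction_stack(
                j=j, noise=imaging.NoiseModel(q99=cfg.vecad_noise_q99),
                shape=cfg.image_shape, pixel_size_um=cfg.pixel_size_um,
                seed=s, condition=cond)
            image_id = f"vecad_{cond}_{i:02d}"
            records += quantify.quantify_marker_stack(
                stack, t_vecad, metric="vecad", image_id=image_id)
            if cfg.save_images:
                stack.save_tiff(img_dir / f"{image_id}.tif")
                truth.save(img_dir / f"{image_id}.truth.json")

    nz, h, w = cfg.image_shape
    wall = int(round(cfg.wall_fraction * w))
    # scene counts refer to the default 1024x1024 field; smaller fields hold
    # proportionally fewer cells
    area_factor = (h * w) / (1024 * 1024)
    for cond in cfg.thp1_conditions:
        row = imaging.CONDITION_TABLE[cond]
        for i in range(cfg.n_scenes_thp1):
            s = _seed_for(seed, "thp1", cond, i)
            rng = np.random.default_rng(s)
            # transmigrated counts are scene-sized already; only the ~10^3
            # adhered cells per device are scaled down to fit one field
            n_mig = max(0, int(round(rng.normal(row["n_migrated"],
                                                row["n_migrated_sd"])
                                     * area_factor)))
            n_adh_mean = ((row["n_affected"] - row["n_migrated"])
                          * cfg.thp1_count_scale * area_factor)
            n_adh_sd = row["n_affected_sd"] * cfg.thp1_count_scale * area_factor
            n_adh = max(0, int(round(rng.normal(n_adh_mean, n_adh_sd))))
            dists = imaging.sample_migration_distances(cond, n_mig, rng)
            max_d = (w - wall - 25) * cfg.pixel_size_um
            dists = np.clip(dists, 0.5, max_d)
            stack, truth = imaging.generate_thp1_scene(
                wall_x_px=wall, n_adhered=n_adh, distances_um=list(dists),
                noise=imaging.NoiseModel(q99=cfg.tracker_noise_q99),
                shape=cfg.image_shape, pixel_size_um=cfg.pixel_size_um,
                seed=s, condition=cond)
            image_id = f"thp1_{cond}_{i:02d}"
            records += quantify.quantify_thp1_stack(
                stack, t_track, wall_x_px=wall,
                min_area_px=cfg.min_area_px, image_id=image_id)
            if cfg.save_images:
                stack.save_tiff(img_dir / f"{image_id}.tif")
                truth.save(img_dir / f"{image_id}.truth.json")
    return records


def run_stats_stage(frame: pd.DataFrame, cfg: PipelineConfig,
                    out: Path) -> pd.DataFrame:
    """Summaries and the study's pairwise comparisons per panel."""
    panels = [
        ("icam1_area_ratio_pct", "fig3",
         [("normal", c) for c in cfg.icam_conditions if c != "normal"]),
        ("icam1_norm_intensity", "fig3d",
         [("normal", c) for c in cfg.icam_conditions if c != "normal"]),
        ("vecad_area_ratio_pct", "fig4",
         [("normal", c) for c in cfg.vecad_conditions if c != "normal"]),
        ("n_transmigrated", "fig5",
         [("normal", c) for c in cfg.thp1_conditions if c != "normal"]),
        ("migration_distance_um", "fig5d",
         [("normal", c) for c in cfg.thp1_conditions if c != "normal"]),
    ]
    tables = []
    for metric, tmap, pairs in panels:
        present = set(frame.loc[frame["metric"] == metric, "condition"])
        pairs = [p for p in pairs if set(p) <= present]
        if pairs:
            tables.append(stats.compare_conditions(frame, metric, pairs, tmap))
    result = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    result.to_csv(out / "stats.csv", index=False)

    summaries = (frame.groupby(["metric", "condition"])["value"]
                 .agg(n="count", mean="mean",
                      sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
                 .reset_index())
    summaries.to_csv(out / "condition_summaries.csv", index=False)
    return result


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig | str | Path | None = None,
            seed: int = 0, out_dir: str | Path = "pipeline_out") -> dict:
    """Run every stage and write the report bundle.

    Returns a manifest dict (also written as ``manifest.json``) with the
    config snapshot, seeds and output hashes. The simulation stage is fully
    deterministic; imaging/quantify/stats change only with ``seed``.
    """
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        sim = run_transport_stage(cfg, out)
    except (transport.TransportError, ValidationError):
        raise
    except transport.NumericalFailure as exc:
        raise transport.NumericalFailure(f"[transport] {exc}") from exc

    records = run_imaging_stage(cfg, seed, out)
    frame = quantify.records_to_frame(records)
    frame.to_csv(out / "quant_records.csv", index=False)
    run_stats_stage(frame, cfg, out)

    outputs = sorted(p for p in out.glob("*.csv"))
    manifest = {
        "seed": seed,
        "config": json.loads(json.dumps(dataclasses.asdict(cfg), default=list)),
        "vessel_mean_4h_ugml": sim["vessel_mean_4h_ugml"],
        "outputs": {p.name: _hash_file(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
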