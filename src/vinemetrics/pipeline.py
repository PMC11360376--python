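"""End-to-end orchestration: simulate -> normalize -> clip -> metrics -> compare.

A run is driven by a :class:`PipelineConfig` (built in code or loaded
from YAML) and produces a deterministic output tree::

    out/
      manifest.json                   run parameters, seeds, stage counts
      truth.csv                       per-vine oracle values (simulation only)
      clouds/<sensor>.las             simulated clouds (optional)
      metrics/<sensor>_metrics.csv    per-vine geometric parameters
      tables/descriptives_<metric>.csv   descriptives + significance letters
      tables/agreement_<metric>.csv      r, R^2, RMSE and model-II fits vs reference
      tables/correlation_<metric>.csv    sensor-by-sensor Pearson matrix
      tables/games_howell_<metric>.csv   full pairwise post-hoc table

Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from vinemetrics import __version__, cloud_io
from vinemetrics.canopy_metrics import (
    ALPHA_TLS,
    ALPHA_UAV,
    AlphaParams,
    GeometryMetrics,
    compute_vine_metrics,
)
from vinemetrics.cloud_io import PointCloud, write_metrics_table
from vinemetrics.ground_normalize import SmrfParams, normalize_cloud
from vinemetrics.sensor_stats import (
    correlation_matrix,
    descriptive,
    games_howell,
    model2_regression,
    rmse_paired,
)
from vinemetrics.synthetic_vineyard import (
    GrassSpec,
    SensorProfile,
    Terrain,
    VineJitter,
    build_scene,
    default_profiles,
    default_scene_config,
    sample_cloud,
    truth_table,
)
from vinemetrics.vine_segmentation import ClipSpec, build_vine_polygons, segment_vines

logger = logging.getLogger(__name__)

METRIC_NAMES = ("h_max", "h90", "h95", "area_m2", "volume_m3")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass
class SimulationBlock:
    n_rows: int = 2
    n_vines: int = 10
    profiles: tuple[str, ...] = ("tls", "panchromatic", "tir")
    terrain_slope: float = 0.0
    grass_density: float = 30.0
    master_seed: int = 0
    write_clouds: bool = False
    oracle_resolution: float = 0.01


@dataclass
class PipelineConfig:
    """Either a simulation block or explicit input clouds must be given."""

    simulation: SimulationBlock | None = None
    input_clouds: list[dict] = field(default_factory=list)
    # each input cloud dict: {path, sensor_name, alpha}
    polygons_path: str | None = None
    vine_coordinates: list[tuple[str, float, float]] | None = None
    clip: ClipSpec = field(default_factory=ClipSpec)
    smrf: SmrfParams = field(default_factory=SmrfParams)
    reference_path: str | None = None  # CSV: vine_id + metric columns
    alpha_by_sensor: dict[str, float] = field(default_factory=dict)
    output_dir: str = "out"

    def __post_init__(self) -> None:
        if self.simulation is None and not self.input_clouds:
            raise PipelineError("config: need a simulation block or input clouds")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config whose keys mirror the dataclass fields."""
    raw = yaml.safe_load(Path(path).read_text())
    sim = None
    if "simulation" in raw:
        sim = SimulationBlock(**raw["simulation"])
    clip = ClipSpec(**raw.get("clip", {}))
    smrf = SmrfParams(**raw.get("smrf", {}))
    return PipelineConfig(
        simulation=sim,
        input_clouds=raw.get("input_clouds", []),
        polygons_path=raw.get("polygons_path"),
        vine_coordinates=[tuple(v) for v in raw["vine_coordinates"]]
        if "vine_coordinates" in raw else None,
        clip=clip, smrf=smrf,
        reference_path=raw.get("reference_path"),
        alpha_by_sensor=raw.get("alpha_by_sensor", {}),
        output_dir=raw.get("output_dir", "out"),
    )


def default_alpha(sensor_name: str) -> float:
    return ALPHA_TLS if "tls" in sensor_name.lower() else ALPHA_UAV


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _simulate(config: PipelineConfig, out: Path, manifest: dict):
    sim = config.simulation
    scene_cfg = default_scene_config(
        n_rows=sim.n_rows, n_vines=sim.n_vines,
        terrain=Terrain(slope=sim.terrain_slope),
        grass=GrassSpec(density=sim.grass_density),
    )
    scene = build_scene(scene_cfg, seed=sim.master_seed)
    truths = truth_table(scene, oracle_resolution=sim.oracle_resolution)
    write_metrics_table(
        [dataclasses.asdict(t) for t in truths], out / "truth.csv",
        columns=[("vine_id", None), ("h_max_true", 3), ("area_true", 3),
                 ("volume_true", 4), ("oracle_resolution", 3)],
    )
    profiles = default_profiles()
    clouds = {}
    for i, name in enumerate(sim.profiles):
        if name not in profiles:
            raise PipelineError(f"simulate: unknown profile {name!r}")
        cloud = sample_cloud(scene, profiles[name], seed=sim.master_seed + 1000 + i)
        clouds[name] = cloud
        if sim.write_clouds:
            (out / "clouds").mkdir(exist_ok=True)
            cloud_io.write_las(cloud, out / "clouds" / f"{name}.las")
    manifest["scene"] = {
        "n_rows": sim.n_rows, "n_vines": sim.n_vines,
        "terrain_slope": sim.terrain_slope,
        "grass_density": sim.grass_density,
        "master_seed": sim.master_seed,
        "extent": [round(v, 3) for v in scene_cfg.extent],
    }
    vine_coords = [(v.vine_id, v.origin[0], v.origin[1]) for v in scene.vines]
    reference = {
        t.vine_id: {"h_max": t.h_max_true, "area_m2": t.area_true,
                    "volume_m3": t.volume_true}
        for t in truths
    }
    return clouds, vine_coords, reference


def _load_reference(path: str) -> dict[str, dict[str, float]]:
    import csv

    out: dict[str, dict[str, float]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            vid = row.pop("vine_id")
            out[vid] = {k: float(v) for k, v in row.items() if v not in ("", None)}
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full flow; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": {}}

    # --- acquire clouds -----------------------------------------------------
    reference = None
    vine_coords = config.vine_coordinates
    if config.simulation is not None:
        clouds, sim_coords, reference = _simulate(config, out, manifest)
        if vine_coords is None:
            vine_coords = sim_coords
    else:
        clouds = {}
        for spec in config.input_clouds:
            try:
                cloud = cloud_io.read_point_cloud(spec["path"])
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"read: {spec.get('sensor_name')}: {exc}") from exc
            cloud.sensor_name = spec.get("sensor_name", Path(spec["path"]).stem)
            clouds[cloud.sensor_name] = cloud
    if config.reference_path:
        reference = _load_reference(config.reference_path)

    # --- polygons -----------------------------------------------------------
    if config.polygons_path:
        polygons = cloud_io.read_polygons(config.polygons_path)
    elif vine_coords is not None:
        polygons = build_vine_polygons(vine_coords, config.clip)
    else:
        raise PipelineError("clip: no polygons or vine coordinates supplied")

    # --- per-sensor normalize / clip / metrics ------------------------------
    (out / "metrics").mkdir(exist_ok=True)
    all_metrics: dict[str, list[GeometryMetrics]] = {}
    for name, cloud in clouds.items():
        try:
            normalized, _ = normalize_cloud(cloud, config.smrf)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"normalize: sensor {name}: {exc}") from exc
        vine_clouds = segment_vines(normalized, polygons,
                                    config.clip.trellis_height)
        alpha = AlphaParams(config.alpha_by_sensor.get(name, default_alpha(name)))
        records = [compute_vine_metrics(vc, alpha) for vc in vine_clouds]
        for rec, vc in zip(records, vine_clouds):
            rec.sensor_name = name
        all_metrics[name] = records
        write_metrics_table(
            [r.as_dict() for r in records], out / "metrics" / f"{name}_metrics.csv"
        )
        manifest["stages"][name] = {
            "n_points": len(cloud),
            "n_clipped": int(sum(r.n_points for r in records)),
            "n_canopy": int(sum(r.n_canopy_points for r in records)),
            "alpha": alpha.alpha,
            "sensor_seed": None,
        }

    # --- statistics ---------------------------------------------------------
    (out / "tables").mkdir(exist_ok=True)
    vine_ids = [p.vine_id for p in polygons]
    for metric in METRIC_NAMES:
        columns: dict[str, np.ndarray] = {}
        if reference is not None:
            ref_vals = np.array([
                reference.get(v, {}).get(metric, np.nan) for v in vine_ids
            ])
            if np.isfinite(ref_vals).any():
                columns["reference"] = ref_vals
        for name, records in all_metrics.items():
            by_id = {r.vine_id: r for r in records}
            columns[name] = np.array([
                getattr(by_id[v], metric) if v in by_id else np.nan
                for v in vine_ids
            ])
        _write_metric_tables(metric, columns, out / "tables")
    _write_manifest(manifest, config, out)
    return out


def _write_metric_tables(metric: str, columns: dict[str, np.ndarray], tdir: Path):
    groups = {k: v[np.isfinite(v)] for k, v in columns.items()}
    groups = {k: v for k, v in groups.items() if v.size >= 2}
    if len(groups) >= 2:
        comparison = games_howell(groups, seed=0)
        letters = comparison.letters
        rows = []
        for name, values in groups.items():
            d = descriptive(values)
            rows.append({
                "sensor": name, "n": d.n, "min": d.min, "max": d.max,
                "mean": d.mean, "sd": d.sd, "cv_percent": d.cv_percent,
                "letters": letters.get(name, ""),
            })
        write_metrics_table(
            rows, tdir / f"descriptives_{metric}.csv",
            columns=[("sensor", None), ("n", 0), ("min", 3), ("max", 3),
                     ("mean", 3), ("sd", 3), ("cv_percent", 2),
                     ("letters", None)],
        )
        gh_rows = [{
            "group_a": c.group_a, "group_b": c.group_b,
            "mean_diff": c.mean_diff, "se": c.se, "t": c.t, "df": c.df,
            "p_adjusted": c.p_adjusted, "ci_low": c.ci_low, "ci_high": c.ci_high,
        } for c in comparison.pairwise]
        write_metrics_table(
            gh_rows, tdir / f"games_howell_{metric}.csv",
            columns=[("group_a", None), ("group_b", None), ("mean_diff", 4),
                     ("se", 4), ("t", 3), ("df", 2), ("p_adjusted", 4),
                     ("ci_low", 4), ("ci_high", 4)],
        )

    # agreement vs reference (Table-4 style)
    if "reference" in columns:
        ref = columns["reference"]
        rows = []
        for name, vals in columns.items():
            if name == "reference":
                continue
            ok = np.isfinite(ref) & np.isfinite(vals)
            if ok.sum() < 3:
                continue
            fit = model2_regression(ref[ok], vals[ok])
            rows.append({
                "sensor": name, "n": int(ok.sum()), "r": fit.r,
                "r_squared": fit.r_squared, "p_value": fit.p_value,
                "rmse": rmse_paired(vals[ok], ref[ok]),
                "ols_slope": fit.ols.slope, "ols_intercept": fit.ols.intercept,
                "ma_slope": fit.ma.slope, "sma_slope": fit.sma.slope,
            })
        if rows:
            write_metrics_table(
                rows, tdir / f"agreement_{metric}.csv",
                columns=[("sensor", None), ("n", 0), ("r", 3),
                         ("r_squared", 3), ("p_value", 6), ("rmse", 4),
                         ("ols_slope", 4), ("ols_intercept", 4),
                         ("ma_slope", 4), ("sma_slope", 4)],
            )

    # correlation matrix among sensors (and reference)
    finite_cols = {k: v for k, v in columns.items()
                   if np.isfinite(v).sum() >= 3}
    if len(finite_cols) >= 2:
        r, _ = correlation_matrix(finite_cols)
        r.round(4).to_csv(tdir / f"correlation_{metric}.csv")


def _write_manifest(manifest: dict, config: PipelineConfig, out: Path) -> None:
    manifest["clip"] = dataclasses.asdict(config.clip)
    manifest["smrf"] = dataclasses.asdict(config.smrf)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n"
    )


def demo_config(output_dir: str = "out", master_seed: int = 7) -> PipelineConfig:
    """Small, fast demonstration run: 3 vines, two sensor classes."""
    return PipelineConfig(
        simulation=SimulationBlock(
            n_rows=1, n_vines=3, profiles=("tls", "tir"),
            master_seed=master_seed, oracle_resolution=0.02,
        ),
        output_dir=output_dir,
    )
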