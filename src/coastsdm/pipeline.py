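"""End-to-end orchestration: simulate -> effort -> layers -> screen -> fit -> zones.

Each stage writes its outputs (CSV / GeoJSON / ASCII grid / JSON) into an
output directory and can be re-run in isolation from those files; a run
manifest records the configuration hash and the per-stage seeds derived
from the master seed, so a complete run is reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point
from shapely.ops import unary_union

from . import io as cio
from .effort import assign_presence, buffer_tracklines, effort_per_cell, select_absences
from .ensemble import ALGORITHMS, EnsembleSDM
from .grid import GridSpec
from .layers import (
    PredictorLayer,
    SphericalVariogram,
    assemble_feature_table,
    cost_distance_layer,
    euclidean_distance_layer,
    grid_feature_frame,
    krige_layer,
    sample_categorical,
    slope_complexity_layers,
)
from .screening import CollinearityConfig, vifcor, vifstep
from .synthetic import (
    OccurrenceModelParams,
    SightingSet,
    StudyAreaConfig,
    TracklineSet,
    ZigzagDesign,
    generate_study_area,
    generate_transects,
    simulate_sightings,
)
from .zones import OccurrenceBands, band_proportions, randomization_test, zone_summary

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "stage_seed",
           "default_config"]

MODEL_PREDICTORS = (
    "habitat",
    "depth_m",
    "slope",
    "complexity",
    "dist_coast_m",
    "dist_ramp_m",
    "dist_reef_m",
    "dist_sz_m",
    "dist_passage_m",  # screening candidate, collinear with dist_reef_m
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Full configuration of a synthetic-data pipeline run."""

    study_area: StudyAreaConfig = field(default_factory=StudyAreaConfig)
    occurrence: OccurrenceModelParams = field(default_factory=OccurrenceModelParams)
    design: ZigzagDesign = field(default_factory=ZigzagDesign)
    screening: CollinearityConfig = field(default_factory=CollinearityConfig)
    bands: OccurrenceBands = field(default_factory=OccurrenceBands)
    buffer_m: float = 250.0
    n_runs: int = 10
    calib_fraction: float = 0.75
    algorithms: tuple = ALGORITHMS
    n_importance_perm: int = 10
    n_permutations: int = 5_000
    seed: int = 0

    def to_dict(self):
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        nested = {
            "study_area": StudyAreaConfig,
            "occurrence": OccurrenceModelParams,
            "design": ZigzagDesign,
            "screening": CollinearityConfig,
            "bands": OccurrenceBands,
        }
        kwargs = {}
        for key, klass in nested.items():
            if key in d:
                sub = dict(d.pop(key))
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                kwargs[key] = klass(**sub)
        for key in ("buffer_m", "n_runs", "calib_fraction", "n_importance_perm",
                    "n_permutations", "seed"):
            if key in d:
                kwargs[key] = d.pop(key)
        if "algorithms" in d:
            kwargs["algorithms"] = tuple(d.pop("algorithms"))
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def default_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig(seed=seed)


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    outputs: list
    warnings: list = field(default_factory=list)

    def to_dict(self):
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# stages (each reads its inputs from ``outdir`` when no context is passed)
# ---------------------------------------------------------------------------


def _out(outdir, name):
    path = Path(outdir) / name
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


def stage_simulate(config: PipelineConfig, outdir):
    """Generate the study area, transects and sightings; write them out."""
    sa_seed = stage_seed(config.seed, "study_area")
    study_area = generate_study_area(replace(config.study_area, seed=sa_seed))
    transects = generate_transects(study_area, config.design)
    sightings = simulate_sightings(
        study_area, transects, config.occurrence,
        seed=stage_seed(config.seed, "sightings"), buffer_m=config.buffer_m,
    )
    grid = study_area.grid
    cio.write_grid_cells(_out(outdir, "cells.csv"), grid, {"depth_m": study_area.depth})
    cio.write_ascii_grid(_out(outdir, "depth.asc"), study_area.depth, grid.origin, grid.cell_size_m)
    cio.write_geojson(_out(outdir, "coastline.geojson"), [(study_area.coastline, {})])
    cio.write_geojson(
        _out(outdir, "zones.geojson"),
        [(poly, {"zone": code, "name": name}) for code, name, poly in study_area.zone_polygons],
    )
    cio.write_geojson(
        _out(outdir, "habitat.geojson"),
        [(poly, {"class": cls}) for cls, poly in study_area.habitat_polygons],
    )
    structures = (
        [(study_area.reef_crest, {"kind": "reef_crest"})]
        + [(p, {"kind": "passage"}) for p in study_area.passages]
        + [(p, {"kind": "boat_ramp"}) for p in study_area.boat_ramps]
    )
    cio.write_geojson(_out(outdir, "structures.geojson"), structures)
    cio.write_geojson(
        _out(outdir, "transects.geojson"),
        [(LineString(line), {"index": i}) for i, line in enumerate(transects.lines)],
    )
    cio.write_geojson(
        _out(outdir, "sightings.geojson"),
        [
            (Point(*pt), {"school_size": int(sz)})
            for pt, sz in zip(sightings.points, sightings.school_size)
        ],
    )
    cio.write_table(
        _out(outdir, "sst_samples.csv"),
        pd.DataFrame(study_area.sst_samples, columns=["x", "y", "sst"]),
    )
    cio.write_json(_out(outdir, "config.json"), config.to_dict())
    return {"study_area": study_area, "transects": transects, "sightings": sightings}


def _load_simulated(outdir):
    grid, extra = cio.read_grid_cells(Path(outdir) / "cells.csv")
    depth = extra["depth_m"]
    lines, _ = cio.read_geojson(Path(outdir) / "transects.geojson")
    transects = TracklineSet([np.asarray(g.coords) for g, _ in lines])
    pts, _ = cio.read_geojson(Path(outdir) / "sightings.geojson")
    sightings = SightingSet(
        np.array([[g.x, g.y] for g, _ in pts]).reshape(-1, 2),
        np.array([p.get("school_size", 1) for _, p in pts], dtype=int),
    )
    return grid, depth, transects, sightings


def stage_effort(config: PipelineConfig, outdir, ctx=None):
    """Grid the survey effort and build the presence/absence response."""
    if ctx is not None:
        study_area = ctx["study_area"]
        grid, depth = study_area.grid, study_area.depth
        transects, sightings = ctx["transects"], ctx["sightings"]
    else:
        grid, depth, transects, sightings = _load_simulated(outdir)
    effort = effort_per_cell(transects, grid)
    presence = assign_presence(sightings, grid)
    response = select_absences(effort, presence, grid)
    cio.write_ascii_grid(
        _out(outdir, "effort.asc"), effort.effort_m, grid.origin, grid.cell_size_m
    )
    rows, cols = grid.rowcol(np.arange(grid.n_cells))
    cio.write_table(
        _out(outdir, "response.csv"),
        pd.DataFrame(
            {
                "cell_id": np.arange(grid.n_cells),
                "row": rows,
                "col": cols,
                "effort_m": effort.effort_m.ravel(),
                "response": response.response.ravel(),
            }
        ),
    )
    survey = pd.DataFrame(
        [
            ("Survey effort (km)", round(transects.total_length_km, 1)),
            ("No. of dolphin schools", len(sightings)),
            ("No. of grid cells with dolphin presences", len(presence)),
            ("True-absence effort threshold (m)", response.absence_threshold_m),
            ("Highest cell effort (m)", float(effort.effort_m.max())),
        ],
        columns=["quantity", "value"],
    )
    cio.write_table(_out(outdir, "survey_summary.csv"), survey)
    out = {"grid": grid, "depth": depth, "effort": effort, "response": response}
    if ctx is not None:
        ctx.update(out)
        return ctx
    return out


def _load_vectors(outdir):
    outdir = Path(outdir)
    coast, _ = cio.read_geojson(outdir / "coastline.geojson")
    zones, _ = cio.read_geojson(outdir / "zones.geojson")
    habitat, _ = cio.read_geojson(outdir / "habitat.geojson")
    structures, _ = cio.read_geojson(outdir / "structures.geojson")
    sst = cio.read_table(outdir / "sst_samples.csv").to_numpy()
    return {
        "coastline": coast[0][0],
        "sz_polygons": [g for g, p in zones if p.get("zone") == "SZ"],
        "habitat_polygons": [(p["class"], g) for g, p in habitat],
        "reef_crest": [g for g, p in structures if p["kind"] == "reef_crest"][0],
        "passages": [g for g, p in structures if p["kind"] == "passage"],
        "boat_ramps": [g for g, p in structures if p["kind"] == "boat_ramp"],
        "sst_samples": sst,
    }


def stage_layers(config: PipelineConfig, outdir, ctx=None):
    """Derive the ecogeographic predictor layers and the feature table."""
    if ctx is not None:
        sa = ctx["study_area"]
        vectors = {
            "coastline": sa.coastline,
            "sz_polygons": [poly for code, _, poly in sa.zone_polygons if code == "SZ"],
            "habitat_polygons": sa.habitat_polygons,
            "reef_crest": sa.reef_crest,
            "passages": sa.passages,
            "boat_ramps": sa.boat_ramps,
            "sst_samples": sa.sst_samples,
        }
        grid, depth = sa.grid, sa.depth
        effort, response = ctx["effort"], ctx["response"]
    else:
        prior = stage_effort(config, outdir)  # rebuilt from files, cheap
        grid, depth = prior["grid"], prior["depth"]
        effort, response = prior["effort"], prior["response"]
        vectors = _load_vectors(outdir)

    depth_layer = PredictorLayer("depth_m", "continuous", depth, units="m")
    slope, complexity = slope_complexity_layers(depth, grid)
    layers = [
        sample_categorical(vectors["habitat_polygons"], grid, name="habitat"),
        depth_layer,
        slope,
        complexity,
        euclidean_distance_layer(grid, vectors["coastline"], name="dist_coast_m"),
        cost_distance_layer(grid, unary_union(vectors["boat_ramps"]), name="dist_ramp_m"),
        cost_distance_layer(grid, vectors["reef_crest"], name="dist_reef_m"),
        cost_distance_layer(grid, unary_union(vectors["sz_polygons"]), name="dist_sz_m"),
        cost_distance_layer(grid, unary_union(vectors["passages"]), name="dist_passage_m"),
    ]
    # SST is kriged and written for inspection but not a default predictor
    sst_layer = krige_layer(
        vectors["sst_samples"], grid,
        SphericalVariogram(nugget=0.05, sill=1.0, range_m=15_000.0),
        name="sst",
    )
    features = assemble_feature_table(grid, layers, response, effort)
    grid_features = grid_feature_frame(grid, layers)
    cio.write_table(_out(outdir, "features.csv"), features)
    cio.write_table(_out(outdir, "grid_features.csv"), grid_features)
    cio.write_ascii_grid(_out(outdir, "sst.asc"), sst_layer.values, grid.origin, grid.cell_size_m)
    out = {"grid": grid, "features": features, "grid_features": grid_features}
    if ctx is not None:
        ctx.update(out)
        return ctx
    prior.update(out)
    return prior


def stage_screen(config: PipelineConfig, outdir, ctx=None):
    """Collinearity screening: vifcor then vifstep on continuous predictors."""
    if ctx is None:
        ctx = {}
        grid, _ = cio.read_grid_cells(Path(outdir) / "cells.csv")
        ctx["grid"] = grid
        ctx["features"] = cio.read_table(Path(outdir) / "features.csv")
        ctx["grid_features"] = cio.read_table(Path(outdir) / "grid_features.csv")
    features = ctx["features"]
    continuous = [
        c for c in features.columns
        if c not in ("habitat", "response", "effort_m", "cell_id")
    ]
    rep_cor = vifcor(features[continuous], config.screening)
    rep_step = vifstep(features[rep_cor.retained], config.screening)
    removed = [c for c in continuous if c not in rep_step.retained]
    if removed:
        logger.info("screening removed: %s", removed)
    keep = ["habitat"] + rep_step.retained
    ctx["features"] = features[keep + ["response", "effort_m", "cell_id"]]
    ctx["grid_features"] = ctx["grid_features"][keep + ["cell_id"]]
    cio.write_json(
        _out(outdir, "screening.json"),
        {"vifcor": rep_cor.to_dict(), "vifstep": rep_step.to_dict(), "removed": removed},
    )
    cio.write_table(_out(outdir, "features_screened.csv"), ctx["features"])
    return ctx


def stage_fit(config: PipelineConfig, outdir, ctx=None):
    """Fit the six-algorithm ensemble and predict the occurrence surface."""
    if ctx is None:
        ctx = {}
        grid, _ = cio.read_grid_cells(Path(outdir) / "cells.csv")
        ctx["grid"] = grid
        ctx["features"] = cio.read_table(Path(outdir) / "features_screened.csv")
        gf = cio.read_table(Path(outdir) / "grid_features.csv")
        keep = [c for c in ctx["features"].columns if c not in ("response", "effort_m")]
        ctx["grid_features"] = gf[keep]
    grid = ctx["grid"]
    model = EnsembleSDM.from_feature_table(ctx["features"], algorithms=config.algorithms)
    results = model.fit(
        n_runs=config.n_runs,
        calib_fraction=config.calib_fraction,
        seed=stage_seed(config.seed, "ensemble"),
        n_importance_perm=config.n_importance_perm,
    )
    surface, prob = results.predict_grid(grid, ctx["grid_features"])
    cio.write_table(
        _out(outdir, "model_runs.csv"),
        pd.DataFrame(
            [
                (r.algorithm, r.run_index, r.split_seed, r.auc_test)
                for r in results.runs
            ],
            columns=["algorithm", "run", "split_seed", "auc_test"],
        ),
    )
    imp = results.importance_table
    imp.insert(0, "model", imp.index)
    cio.write_table(_out(outdir, "importance_table.csv"), imp)
    cio.write_ascii_grid(_out(outdir, "ensemble.asc"), prob, grid.origin, grid.cell_size_m)
    cio.write_table(
        _out(outdir, "ensemble_surface.csv"),
        pd.DataFrame({"cell_id": surface.cell_ids, "probability": surface.probability}),
    )
    cio.write_json(
        _out(outdir, "evaluation.json"),
        {
            "ensemble_auc": results.ensemble_auc,
            "median_single_auc": results.median_single_auc,
            "n_runs": len(results.runs),
        },
    )
    _out(outdir, "summary.txt").write_text(results.summary() + "\n")
    ctx.update({"results": results, "surface": surface, "probability": prob})
    return ctx


def stage_zones(config: PipelineConfig, outdir, ctx=None):
    """Band classification, zone summaries and the sanctuary overlap test."""
    if ctx is None:
        ctx = {}
        grid, _ = cio.read_grid_cells(Path(outdir) / "cells.csv")
        prob, _, _ = cio.read_ascii_grid(Path(outdir) / "ensemble.asc")
        ctx["grid"], ctx["probability"] = grid, prob
    grid, prob = ctx["grid"], ctx["probability"]
    from .zones import classify_occurrence

    labels = classify_occurrence(prob, config.bands)
    bands_df = band_proportions(prob, grid, config.bands)
    summary = zone_summary(prob, grid)
    high = (labels == "High") & grid.marine_mask
    marine_valid = grid.marine_mask & np.isfinite(prob)
    test = randomization_test(
        high & marine_valid,
        (grid.zone_label == "SZ") & marine_valid,
        marine_valid,
        n_permutations=config.n_permutations,
        seed=stage_seed(config.seed, "randomization"),
    )
    cio.write_table(_out(outdir, "zone_summary.csv"), summary)
    cio.write_table(_out(outdir, "band_proportions.csv"), bands_df)
    cio.write_json(_out(outdir, "randomization_test.json"), test.to_dict())
    band_df = pd.DataFrame(
        {"cell_id": np.arange(grid.n_cells), "band": labels.ravel()}
    )
    cio.write_table(_out(outdir, "bands.csv"), band_df)
    ctx.update({"zone_summary": summary, "band_proportions": bands_df, "rand_test": test})
    return ctx


STAGES = ("simulate", "effort", "layers", "screen", "fit", "zones")


def run_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    """Run every stage in order and write the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx = stage_simulate(config, outdir)
    ctx = stage_effort(config, outdir, ctx)
    ctx = stage_layers(config, outdir, ctx)
    ctx = stage_screen(config, outdir, ctx)
    ctx = stage_fit(config, outdir, ctx)
    ctx = stage_zones(config, outdir, ctx)
    manifest = RunManifest(
        config_hash=config.config_hash,
        seeds={
            "study_area": stage_seed(config.seed, "study_area"),
            "sightings": stage_seed(config.seed, "sightings"),
            "ensemble": stage_seed(config.seed, "ensemble"),
            "randomization": stage_seed(config.seed, "randomization"),
        },
        outputs=sorted(
            {p.name for p in outdir.iterdir() if p.is_file()} | {"manifest.json"}
        ),
    )
    cio.write_json(outdir / "manifest.json", manifest.to_dict())
    return manifest
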