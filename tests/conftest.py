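"""Shared fixtures: one default study area and survey, plus the 50-seed
driver-recovery experiment used by the acceptance-level checks."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from shapely.ops import unary_union

from coastsdm.effort import assign_presence, effort_per_cell, select_absences
from coastsdm.ensemble import EnsembleSDM
from coastsdm.layers import (
    PredictorLayer,
    assemble_feature_table,
    cost_distance_layer,
    euclidean_distance_layer,
    sample_categorical,
    slope_complexity_layers,
)
from coastsdm.screening import vifcor, vifstep
from coastsdm.synthetic import (
    OccurrenceModelParams,
    StudyAreaConfig,
    generate_study_area,
    generate_transects,
    simulate_sightings,
)

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def study_area():
    return generate_study_area(StudyAreaConfig(seed=7))


@pytest.fixture(scope="session")
def transects(study_area):
    return generate_transects(study_area)


@pytest.fixture(scope="session")
def sightings(study_area, transects):
    return simulate_sightings(study_area, transects, OccurrenceModelParams(), seed=70)


@pytest.fixture(scope="session")
def effort_map(study_area, transects):
    return effort_per_cell(transects, study_area.grid)


@pytest.fixture(scope="session")
def response(study_area, effort_map, sightings):
    presence = assign_presence(sightings, study_area.grid)
    return select_absences(effort_map, presence, study_area.grid)


def build_layers(sa):
    """The eight default ecogeographic layers plus the passage candidate."""
    grid = sa.grid
    slope, complexity = slope_complexity_layers(sa.depth, grid)
    sz_union = unary_union([poly for code, _, poly in sa.zone_polygons if code == "SZ"])
    return [
        sample_categorical(sa.habitat_polygons, grid, name="habitat"),
        PredictorLayer("depth_m", "continuous", sa.depth, units="m"),
        slope,
        complexity,
        euclidean_distance_layer(grid, sa.coastline, name="dist_coast_m"),
        cost_distance_layer(grid, unary_union(sa.boat_ramps), name="dist_ramp_m"),
        cost_distance_layer(grid, sa.reef_crest, name="dist_reef_m"),
        cost_distance_layer(grid, sz_union, name="dist_sz_m"),
        cost_distance_layer(grid, unary_union(sa.passages), name="dist_passage_m"),
    ]


@pytest.fixture(scope="session")
def all_layers(study_area):
    return build_layers(study_area)


@pytest.fixture(scope="session")
def feature_table(study_area, all_layers, response, effort_map):
    return assemble_feature_table(study_area.grid, all_layers, response, effort_map)


def run_survey_to_table(seed: int):
    """Full synthetic survey -> screened feature table for one seed."""
    sa = generate_study_area(StudyAreaConfig(seed=seed))
    grid = sa.grid
    tr = generate_transects(sa)
    s = simulate_sightings(sa, tr, OccurrenceModelParams(), seed=seed + 1_000)
    eff = effort_per_cell(tr, grid)
    presence = assign_presence(s, grid)
    resp = select_absences(eff, presence, grid)
    table = assemble_feature_table(grid, build_layers(sa), resp, eff)
    continuous = [
        c for c in table.columns if c not in ("habitat", "response", "effort_m", "cell_id")
    ]
    retained = vifstep(table[vifcor(table[continuous]).retained]).retained
    return table[["habitat"] + retained + ["response", "effort_m", "cell_id"]]


N_EXPERIMENT_SEEDS = 50


@pytest.fixture(scope="session")
def driver_recovery_experiment():
    """Fit the reduced ensemble (3 splits) on 50 independent surveys.

    Returns one record per seed: whether depth and distance-to-coast hold
    the top-2 mean-of-means importance ranks, the ensemble and median
    single-model held-out AUCs, and the screened table (for null refits).
    """
    records = []
    for seed in range(N_EXPERIMENT_SEEDS):
        table = run_survey_to_table(seed)
        results = EnsembleSDM.from_feature_table(table).fit(n_runs=3, seed=seed)
        mom = results.importance_table.loc["Mean of means"].sort_values(ascending=False)
        records.append(
            {
                "seed": seed,
                "top2": set(mom.index[:2]),
                "ensemble_auc": results.ensemble_auc,
                "median_single_auc": results.median_single_auc,
                "table": table,
            }
        )
    return records
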