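"""Shared fixtures: one full-scale synthetic run and one small run.

The full-scale run uses the default screen geometry (30 compounds x 8
concentrations x 4 wells x 3 plates, 300 features, 250 cells/well) and is
expensive, so it is built once per session and shared; the single-cell table
is released after aggregation to keep memory flat.
"""
from __future__ import annotations

import logging
from types import SimpleNamespace

import pytest

from myoscreen import (
    ModelSpec,
    SmognConfig,
    SyntheticConfig,
    aggregate_treatments,
    aggregate_wells,
    filter_features,
    generate_experiment,
    global_model,
    normalize_profiles,
    normalize_viability,
    per_compound_models,
)
from myoscreen.smogn import make_augmenter

logging.getLogger("myoscreen").setLevel(logging.ERROR)

DEFAULT_SEED = 42
SMOGN_SEED = 7


def _run(cfg: SyntheticConfig) -> SimpleNamespace:
    cells, viability, truth = generate_experiment(cfg)
    raw = aggregate_wells(cells)
    del cells
    norm = normalize_profiles(raw, method="robust_mad")
    filtered, ledger = filter_features(norm)
    treatments = aggregate_treatments(filtered)
    vn = normalize_viability(viability)
    targets = vn.data[["plate_id", "well", "viability_pct"]].merge(
        raw.well_counts[["plate_id", "well", "cell_count"]].rename(
            columns={"cell_count": "target_cell_count"}
        ),
        on=["plate_id", "well"],
    )
    return SimpleNamespace(
        cfg=cfg,
        truth=truth,
        raw=raw,
        norm=norm,
        filtered=filtered,
        ledger=ledger,
        treatments=treatments,
        viability=vn,
        targets=targets,
    )


@pytest.fixture(scope="session")
def default_run() -> SimpleNamespace:
    """Full-scale synthetic experiment (seed 42), profiled and normalized."""
    return _run(SyntheticConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def small_run() -> SimpleNamespace:
    """Small experiment (6 compounds, 3 mechanisms) for cheap module tests."""
    cfg = SyntheticConfig(
        n_compounds=6,
        n_mechanisms=3,
        n_features=60,
        baseline_cells_per_well=80,
        wells_per_condition_per_plate=2,
        n_plates=2,
        vehicle_wells_per_plate=12,
        emax_ladder=(0.0, 0.9),
        seed=7,
    )
    return _run(cfg)


@pytest.fixture(scope="session")
def model_spec() -> ModelSpec:
    return ModelSpec(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def global_viability(default_run, model_spec):
    """Panel-wide viability forest on the default run."""
    return global_model(
        default_run.filtered,
        default_run.targets,
        model_spec,
        target="viability_pct",
    )


@pytest.fixture(scope="session")
def smogn_global_viability(default_run, model_spec):
    """Same forest with SMOGN applied to the training split only."""
    return global_model(
        default_run.filtered,
        default_run.targets,
        model_spec,
        target="viability_pct",
        augmenter=make_augmenter(SmognConfig(seed=SMOGN_SEED)),
    )


@pytest.fixture(scope="session")
def compound_reports(default_run, model_spec):
    """Per-compound forests for both targets on the default run."""
    return per_compound_models(
        default_run.filtered,
        default_run.targets,
        model_spec,
        target_names=("viability_pct", "target_cell_count"),
    )
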