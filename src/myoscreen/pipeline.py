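"""Stage orchestration: simulate -> profile -> cluster -> model -> augment -> dose.

Each stage reads the previous stage's CSVs from ``outdir`` and writes its
own, so any stage can be re-run in isolation; ``run_all`` chains them and
writes a run log (seed, parameters, library versions).  All configuration
comes from a YAML file with one block per stage; unknown keys are an error.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    METADATA_COLUMNS,
    read_cell_features,
    read_metadata,
    read_viability,
    write_table,
    ViabilityTable,
)
from .simulate import SyntheticConfig, generate_experiment
from .profiling import (
    ProfileMatrix,
    aggregate_treatments,
    aggregate_wells,
    filter_features,
    normalize_profiles,
    read_profiles,
    write_profiles,
)
from .clustering import cluster_profiles, export_clustergram, filter_by_induction
from .models import (
    ModelSpec,
    export_importance_heatmap,
    global_model,
    importance_matrix,
    importances_to_frame,
    per_compound_models,
    reports_to_frame,
)
from .smogn import SmognConfig, make_augmenter
from .doseresponse import (
    condition_tests,
    decoupling_report,
    normalize_viability,
    potency_table,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProfilingConfig:
    method: str = "robust_mad"
    sd_max: float = 2000.0
    corr_max: float = 0.9


@dataclass(frozen=True)
class ClusteringConfig:
    linkage: str = "average"
    metric: str = "pearson"
    min_induction: float = 20.0
    z_thresh: float = 3.0
    clip: float = 8.0


@dataclass(frozen=True)
class ModelsConfig:
    targets: tuple = ("viability_pct", "cell_count")
    n_trees: int = 200
    seed: int = 42
    split_fraction: float = 0.8
    low_variance_floor: float = 0.15

    def spec(self, sd_max: float, corr_max: float) -> ModelSpec:
        return ModelSpec(
            n_trees=self.n_trees,
            seed=self.seed,
            split_fraction=self.split_fraction,
            low_variance_floor=self.low_variance_floor,
            sd_max=sd_max,
            corr_max=corr_max,
        )


@dataclass(frozen=True)
class DoseConfig:
    alpha: float = 0.05
    decoupling_floor: float = 0.2
    fdr: bool = False
    flat_min_range: float = 10.0


@dataclass(frozen=True)
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    profiling: ProfilingConfig = field(default_factory=ProfilingConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    models: ModelsConfig = field(default_factory=ModelsConfig)
    smogn: SmognConfig = field(default_factory=SmognConfig)
    dose: DoseConfig = field(default_factory=DoseConfig)

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Propagate one master seed into every stochastic stage."""
        ss = np.random.SeedSequence(seed).generate_state(3)
        return replace(
            self,
            synthetic=replace(self.synthetic, seed=int(ss[0] % 2**31)),
            models=replace(self.models, seed=int(ss[1] % 2**31)),
            smogn=replace(self.smogn, seed=int(ss[2] % 2**31)),
        )


_BLOCKS = {
    "synthetic": SyntheticConfig,
    "profiling": ProfilingConfig,
    "clustering": ClusteringConfig,
    "models": ModelsConfig,
    "smogn": SmognConfig,
    "dose": DoseConfig,
}


def _build_block(cls, values: dict):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - allowed
    if unknown:
        raise ValueError(
            f"invalid config key(s) {sorted(unknown)} for block "
            f"{cls.__name__}; allowed: {sorted(allowed)}"
        )
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in values:
            v = values[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_config(path=None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from YAML (defaults when ``path`` is None)."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of stage blocks")
    unknown = set(raw) - set(_BLOCKS)
    if unknown:
        raise ValueError(
            f"invalid config block(s) {sorted(unknown)}; "
            f"allowed: {sorted(_BLOCKS)}"
        )
    blocks = {
        name: _build_block(cls, raw.get(name, {}) or {})
        for name, cls in _BLOCKS.items()
    }
    return PipelineConfig(**blocks)


def _path(outdir, name: str) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir / name


def run_simulate(cfg: PipelineConfig, outdir) -> None:
    """Generate a synthetic experiment and write the standard CSV inputs."""
    cells, viability, truth = generate_experiment(cfg.synthetic)
    write_table(cells.data, _path(outdir, "cells.csv"))
    write_table(cells.wells, _path(outdir, "metadata.csv"))
    write_table(
        viability.data[METADATA_COLUMNS + ["luminescence"]],
        _path(outdir, "luminescence.csv"),
    )
    write_table(truth.compounds_frame(), _path(outdir, "ground_truth_compounds.csv"))
    write_table(truth.wells, _path(outdir, "ground_truth_wells.csv"))
    informative = set(truth.informative_features.tolist())
    write_table(
        pd.DataFrame(
            {
                "feature": truth.feature_names,
                "informative": [
                    i in informative for i in range(len(truth.feature_names))
                ],
            }
        ),
        _path(outdir, "ground_truth_features.csv"),
    )


def run_profile(cfg: PipelineConfig, outdir) -> None:
    """Aggregate, normalize, and prune well profiles from the input CSVs."""
    cells = read_cell_features(
        _path(outdir, "cells.csv"), _path(outdir, "metadata.csv")
    )
    pm = aggregate_wells(cells)
    pm = normalize_profiles(pm, method=cfg.profiling.method)
    pm, ledger = filter_features(
        pm, sd_max=cfg.profiling.sd_max, corr_max=cfg.profiling.corr_max
    )
    treatments = aggregate_treatments(pm)
    write_profiles(pm, _path(outdir, "profiles.csv"))
    write_table(pm.well_counts, _path(outdir, "well_counts.csv"))
    write_profiles(treatments, _path(outdir, "treatment_profiles.csv"))
    write_table(ledger, _path(outdir, "drop_ledger.csv"))


def _load_treatments(cfg: PipelineConfig, outdir) -> ProfileMatrix:
    return read_profiles(
        _path(outdir, "treatment_profiles.csv"),
        level="treatment",
        normalization=cfg.profiling.method,
    )


def run_cluster(cfg: PipelineConfig, outdir) -> None:
    """Induction-filter treatment profiles and export the clustergram."""
    treatments = _load_treatments(cfg, outdir)
    kept, excluded = filter_by_induction(
        treatments,
        min_induction=cfg.clustering.min_induction,
        z_thresh=cfg.clustering.z_thresh,
    )
    induction = pd.concat(
        [kept.assign(kept=True), excluded.assign(kept=False)]
    ).sort_index()
    write_table(
        induction[
            ["compound", "concentration_m", "vehicle", "induction_pct", "kept"]
        ],
        _path(outdir, "induction.csv"),
    )
    if len(kept) < 2:
        log.warning("fewer than 2 profiles pass the induction filter; no tree")
        return
    kept_pm = ProfileMatrix(
        data=kept.reset_index(drop=True),
        features=treatments.features,
        level="treatment",
        normalization=treatments.normalization,
    )
    result = cluster_profiles(
        kept_pm, linkage=cfg.clustering.linkage, metric=cfg.clustering.metric
    )
    export_clustergram(
        result,
        kept_pm,
        _path(outdir, "clustergram.png"),
        _path(outdir, "clustergram_ordered.csv"),
        clip_bound=cfg.clustering.clip,
    )


def _well_targets(cfg: PipelineConfig, outdir) -> pd.DataFrame:
    viability = read_viability(
        _path(outdir, "luminescence.csv"), _path(outdir, "metadata.csv")
    )
    viability = normalize_viability(viability)
    counts = pd.read_csv(
        _path(outdir, "well_counts.csv"),
        dtype={"plate_id": str, "well": str},
        float_precision="round_trip",
    )
    return viability.data[["plate_id", "well", "viability_pct"]].merge(
        counts[["plate_id", "well", "cell_count"]], on=["plate_id", "well"]
    )


def run_model(cfg: PipelineConfig, outdir) -> None:
    """Per-compound and global forests on well-level profiles."""
    pm = read_profiles(
        _path(outdir, "profiles.csv"), normalization=cfg.profiling.method
    )
    targets = _well_targets(cfg, outdir)
    # profiles.csv carries its own cell_count column; predict the well targets
    target_frame = targets.rename(columns={"cell_count": "target_cell_count"})
    spec = cfg.models.spec(cfg.profiling.sd_max, cfg.profiling.corr_max)
    name_map = {"viability_pct": "viability_pct", "cell_count": "target_cell_count"}
    reports = per_compound_models(
        pm,
        target_frame,
        spec,
        target_names=[name_map[t] for t in cfg.models.targets],
    )
    for r in reports:  # undo the merge-safe renaming in the written report
        r.target = {v: k for k, v in name_map.items()}.get(r.target, r.target)
    global_reports = [
        global_model(pm, target_frame, spec, target=name_map[t])
        for t in cfg.models.targets
    ]
    for r in global_reports:
        r.target = {v: k for k, v in name_map.items()}.get(r.target, r.target)
    reports = reports + global_reports
    write_table(reports_to_frame(reports), _path(outdir, "model_reports.csv"))
    write_table(importances_to_frame(reports), _path(outdir, "importances.csv"))
    via_reports = [
        r for r in reports if r.target == "viability_pct" and r.scope != "GLOBAL"
    ]
    if len(via_reports) >= 2:
        matrix, row_res, col_res = importance_matrix(via_reports)
        export_importance_heatmap(
            matrix, row_res, col_res, _path(outdir, "importance_heatmap.png")
        )
        matrix.rename_axis("scope").to_csv(_path(outdir, "importance_matrix.csv"))


def run_augment(cfg: PipelineConfig, outdir) -> None:
    """Global viability model with SMOGN applied to the training split."""
    pm = read_profiles(
        _path(outdir, "profiles.csv"), normalization=cfg.profiling.method
    )
    targets = _well_targets(cfg, outdir)
    spec = cfg.models.spec(cfg.profiling.sd_max, cfg.profiling.corr_max)
    report = global_model(
        pm,
        targets[["plate_id", "well", "viability_pct"]],
        spec,
        target="viability_pct",
        augmenter=make_augmenter(cfg.smogn),
    )
    write_table(
        reports_to_frame([report]), _path(outdir, "model_reports_smogn.csv")
    )
    # materialize the augmented training set with provenance flags
    from .smogn import augment
    from .models import split_train_test

    data = pm.data.merge(
        targets[["plate_id", "well", "viability_pct"]],
        on=["plate_id", "well"],
        how="left",
    )
    data = data.loc[~data["vehicle"].astype(bool)].reset_index(drop=True)
    X = data[pm.features].to_numpy(dtype=float)
    y = data["viability_pct"].to_numpy(dtype=float)
    idx_train, _ = split_train_test(X, y, spec)
    X_aug, y_aug, synthetic = augment(X[idx_train], y[idx_train], cfg.smogn)
    aug = pd.DataFrame(X_aug, columns=pm.features)
    aug.insert(0, "synthetic", synthetic)
    aug.insert(1, "viability_pct", y_aug)
    write_table(aug, _path(outdir, "augmented_profiles.csv"))


def run_dose(cfg: PipelineConfig, outdir) -> None:
    """Condition screen, potency table, and decoupling report."""
    pm = read_profiles(
        _path(outdir, "profiles.csv"), normalization=cfg.profiling.method
    )
    pm.well_counts = pd.read_csv(
        _path(outdir, "well_counts.csv"),
        dtype={"plate_id": str, "well": str},
        float_precision="round_trip",
    )
    viability = read_viability(
        _path(outdir, "luminescence.csv"), _path(outdir, "metadata.csv")
    )
    viability = normalize_viability(viability)
    summaries = condition_tests(
        pm, viability, alpha=cfg.dose.alpha, fdr=cfg.dose.fdr
    )
    write_table(summaries, _path(outdir, "condition_summaries.csv"))
    write_table(
        potency_table(summaries, flat_min_range=cfg.dose.flat_min_range),
        _path(outdir, "potency.csv"),
    )
    write_table(
        decoupling_report(
            summaries, alpha=cfg.dose.alpha, count_drop_floor=cfg.dose.decoupling_floor
        ),
        _path(outdir, "decoupling.csv"),
    )


STAGES = {
    "simulate": run_simulate,
    "profile": run_profile,
    "cluster": run_cluster,
    "model": run_model,
    "augment": run_augment,
    "dose": run_dose,
}


def run_all(cfg: PipelineConfig, outdir) -> None:
    """Run every stage in order and write the run log."""
    _write_run_log(cfg, outdir)
    for name in ("simulate", "profile", "cluster", "model", "augment", "dose"):
        log.info("stage: %s", name)
        STAGES[name](cfg, outdir)


def _plain(obj):
    """Recursively convert tuples/numpy scalars for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_run_log(cfg: PipelineConfig, outdir) -> None:
    import sklearn
    import scipy

    payload = {
        "myoscreen": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "seed": cfg.synthetic.seed,
        "config": _plain(dataclasses.asdict(cfg)),
    }
    with open(_path(outdir, "run_log.yaml"), "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
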