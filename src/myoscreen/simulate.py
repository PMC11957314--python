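"""Synthetic Cell Painting experiment generator.

Emulates the statistical structure of a plate-based cytotoxicity screen:
30 compounds x 8 concentrations (10 nM - 30 uM, half-log spacing) x 4 wells
per plate x 3 plate replicates, with 35 vehicle-control wells per plate.
Each compound belongs to one of a small number of mechanism groups; compounds
in a group push morphology along a shared direction in feature space
(up to a small per-compound jitter), with dose dependence following a Hill
curve.  Cell counts decline along a compound-specific Hill curve; ATP
luminescence follows a second Hill curve that is usually coupled to the count
curve, except for one designated "decoupled" compound whose count collapses
while ATP content is preserved (the colchicine-like regime: cells fuse or
deform until they are no longer segmentable, but remain metabolically alive).

Every output is a pure function of ``(config, seed)``, and a
:class:`GroundTruth` object records the generating parameters so that
downstream stages can be tested for parameter recovery.
"""
from __future__ import annotations

import logging
import math
import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    METADATA_COLUMNS,
    VEHICLE_COMPOUND,
    CellFeatureTable,
    ViabilityTable,
)

log = logging.getLogger(__name__)

#: 8-point half-log series from 10 nM to 30 uM.
DEFAULT_CONCENTRATIONS = tuple(
    float(c) for c in np.logspace(-8.0, math.log10(3e-5), 8)
)

#: Maximal fractional cell-count loss per compound, cycled across mechanism
#: groups: one no-effect compound and a spread of toxic severities per group.
DEFAULT_EMAX_LADDER = (0.0, 0.5, 0.65, 0.8, 0.9, 1.0)

_CHANNELS = ("33342", "488", "568", "Mito", "ER")
_COMPARTMENTS = ("Nucleus", "Cytoplasm", "Cell", "Membrane", "Ring")
_KINDS = ("Intensity_Mean", "SER_Bright", "SER_Dark", "Profile", "Radial_Mean")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating conditions for one synthetic experiment.

    The defaults reproduce the screen geometry described above; the noise
    knobs are documented in docs/methods.md.
    """

    n_compounds: int = 30
    n_mechanisms: int = 5
    concentrations: tuple = DEFAULT_CONCENTRATIONS
    wells_per_condition_per_plate: int = 4
    n_plates: int = 3
    vehicle_wells_per_plate: int = 35
    n_features: int = 300
    baseline_cells_per_well: int = 250
    seed: int = 0
    # noise / effect structure
    n_informative: int | None = None
    feature_shift_scale: float = 15.0
    block_size: int = 20
    block_corr: float = 0.5
    plate_offset_sd: float = 0.05
    count_lognorm_sd: float = 0.1
    lum_noise_sd: float = 0.05
    lum_per_cell: float = 55.0
    plate_lum_gain_sd: float = 0.1
    direction_jitter: float = 0.15
    shared_tox_weight: float = 0.6
    emax_ladder: tuple = DEFAULT_EMAX_LADDER

    @property
    def informative_count(self) -> int:
        if self.n_informative is not None:
            return self.n_informative
        return max(2, self.n_features // 3)

    def validate(self) -> None:
        positive = {
            "n_compounds": self.n_compounds,
            "n_mechanisms": self.n_mechanisms,
            "wells_per_condition_per_plate": self.wells_per_condition_per_plate,
            "n_plates": self.n_plates,
            "vehicle_wells_per_plate": self.vehicle_wells_per_plate,
            "n_features": self.n_features,
            "baseline_cells_per_well": self.baseline_cells_per_well,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive (got {value})")
        if len(self.concentrations) < 1 or any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive molar values")
        if self.n_mechanisms > self.n_compounds:
            raise ValueError("more mechanisms than compounds")
        if self.informative_count > self.n_features:
            raise ValueError("n_informative exceeds n_features")
        if not 0 <= self.block_corr < 1:
            raise ValueError("block_corr must be in [0, 1)")


@dataclass
class CompoundTruth:
    """Generating parameters of one compound."""

    compound: str
    mechanism_id: int
    ec50_count: float
    ec50_atp: float
    hill: float
    emax_count: float
    emax_atp: float
    toxic: bool
    decoupled: bool = False
    no_effect: bool = False
    effect_direction: np.ndarray = field(default=None, repr=False)


@dataclass
class GroundTruth:
    """Everything needed to score downstream stages against the generator."""

    compounds: list[CompoundTruth]
    wells: pd.DataFrame
    informative_features: np.ndarray
    feature_names: list[str]
    config: SyntheticConfig

    def compounds_frame(self) -> pd.DataFrame:
        rows = [
            {
                "compound": c.compound,
                "mechanism_id": c.mechanism_id,
                "ec50_count": c.ec50_count,
                "ec50_atp": c.ec50_atp,
                "hill": c.hill,
                "emax_count": c.emax_count,
                "emax_atp": c.emax_atp,
                "toxic": c.toxic,
                "decoupled": c.decoupled,
                "no_effect": c.no_effect,
            }
            for c in self.compounds
        ]
        return pd.DataFrame(rows)

    def mechanism_of(self) -> dict[str, int]:
        return {c.compound: c.mechanism_id for c in self.compounds}


def hill_effect(c, ec50: float, hill: float, emax: float):
    """Sigmoidal dose effect ``emax * c^h / (c^h + ec50^h)``.

    Returns 0 at ``c = 0`` and ``emax/2`` at ``c = ec50``.  Accepts scalar or
    array concentrations.
    """
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    if hill <= 0:
        raise ValueError("hill must be positive")
    c = np.asarray(c, dtype=float)
    if (c < 0).any():
        raise ValueError("concentration must be non-negative")
    ch = np.power(c, hill)
    out = emax * ch / (ch + ec50**hill)
    return float(out) if out.ndim == 0 else out


def _feature_names(cfg: SyntheticConfig) -> list[str]:
    # channel/compartment-style names; features in the same correlation block
    # share a channel, mimicking how real morphology features co-vary
    names = []
    for i in range(cfg.n_features):
        block = i // cfg.block_size
        chan = _CHANNELS[block % len(_CHANNELS)]
        comp = _COMPARTMENTS[(block // len(_CHANNELS)) % len(_COMPARTMENTS)]
        kind = _KINDS[i % len(_KINDS)]
        names.append(f"{comp}_{chan}_{kind}_{i:04d}")
    return names


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0:
        raise ValueError("zero vector cannot be normalized")
    return v / n


def _make_truth(cfg: SyntheticConfig, rng: np.random.Generator, null: bool):
    n_inf = cfg.informative_count
    informative = np.sort(
        rng.choice(cfg.n_features, size=n_inf, replace=False)
    )
    # heavy-tailed loadings: a handful of features dominate each mechanism's
    # morphological signature, as in real screens where one or two texture
    # features carry most of a model's importance
    def _heavy_dir() -> np.ndarray:
        v = np.zeros(cfg.n_features)
        v[informative] = rng.standard_t(df=3, size=n_inf)
        return _unit(v)

    # universal stress/death signature shared by every toxic compound, on top
    # of which mechanism-specific signatures sit; dying cells look alike
    # before they look different
    shared_tox_dir = _heavy_dir()
    mech_dirs = [_heavy_dir() for _ in range(cfg.n_mechanisms)]

    compounds: list[CompoundTruth] = []
    ladder = cfg.emax_ladder
    for i in range(cfg.n_compounds):
        mech = i % cfg.n_mechanisms
        emax = 0.0 if null else float(ladder[(i // cfg.n_mechanisms) % len(ladder)])
        ec50_count = float(10 ** rng.uniform(math.log10(3e-8), math.log10(3e-6)))
        hill = float(rng.uniform(1.0, 2.5))
        ec50_atp = float(ec50_count * rng.uniform(1.0, 2.0))
        jitter = np.zeros(cfg.n_features)
        jitter[informative] = rng.standard_t(df=3, size=n_inf)
        own = _unit(mech_dirs[mech] + cfg.direction_jitter * _unit(jitter))
        direction = _unit(
            cfg.shared_tox_weight * shared_tox_dir
            + math.sqrt(1.0 - cfg.shared_tox_weight**2) * own
        )
        compounds.append(
            CompoundTruth(
                compound=f"C{i + 1:03d}",
                mechanism_id=mech,
                ec50_count=ec50_count,
                ec50_atp=ec50_atp,
                hill=hill,
                emax_count=emax,
                emax_atp=emax,
                toxic=emax > 0,
                effect_direction=direction,
            )
        )

    if not null:
        # one colchicine-like compound: count collapses, ATP preserved
        for c in compounds:
            if 0.85 <= c.emax_count < 1.0:
                c.emax_atp = 0.0
                c.decoupled = True
                break
        for c in compounds:
            if c.emax_count == 0.0:
                c.no_effect = True
                break
    return compounds, informative


def _well_names(n: int) -> list[str]:
    letters = string.ascii_uppercase
    n_cols = math.ceil(n / len(letters))
    if n_cols > 99:
        raise ValueError("plate layout exceeds the well naming grid")
    names = [
        f"{row}{col:02d}" for col in range(1, n_cols + 1) for row in letters
    ]
    return names[:n]


def generate_experiment(
    cfg: SyntheticConfig,
) -> tuple[CellFeatureTable, ViabilityTable, GroundTruth]:
    """Simulate a full screen: cells, luminescence and ground truth.

    Per treated well the expected cell count is
    ``baseline * (1 - hill_effect(c; count params))`` modulated by a per-well
    lognormal factor and realized as a Poisson draw.  Each cell's feature
    vector is the experiment baseline plus the plate offset plus
    ``shift_scale * hill_effect(c; count params) * effect_direction`` plus
    block-correlated unit-variance noise.  Luminescence is the well's baseline
    biomass times ``(1 - hill_effect(c; ATP params))`` with multiplicative
    noise and a per-plate gain.
    """
    return _generate(cfg, null=False)


def make_null_experiment(
    cfg: SyntheticConfig,
) -> tuple[CellFeatureTable, ViabilityTable, GroundTruth]:
    """Same generator with every compound forced non-toxic (all emax = 0)."""
    return _generate(cfg, null=True)


def _generate(cfg: SyntheticConfig, null: bool):
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    compounds, informative = _make_truth(cfg, rng, null)
    feature_names = _feature_names(cfg)
    F = cfg.n_features
    baseline_mu = rng.normal(0.0, 1.0, F)
    block_of = np.arange(F) // cfg.block_size
    n_blocks = int(block_of.max()) + 1
    rho = cfg.block_corr
    shift_scale = cfg.feature_shift_scale

    conditions = [
        (ci, conc)
        for ci in range(cfg.n_compounds)
        for conc in cfg.concentrations
    ]
    per_plate = (
        len(conditions) * cfg.wells_per_condition_per_plate
        + cfg.vehicle_wells_per_plate
    )
    names = _well_names(per_plate)

    meta_rows = []
    lum_rows = []
    truth_rows = []
    blocks: list[np.ndarray] = []
    block_meta_idx: list[tuple[int, int]] = []  # (meta row index, n_cells)

    for p in range(cfg.n_plates):
        plate_id = f"P{p + 1}"
        plate_offset = rng.normal(0.0, cfg.plate_offset_sd, F)
        plate_gain = math.exp(rng.normal(0.0, cfg.plate_lum_gain_sd))
        slots: list[tuple[int | None, float]] = [
            (ci, conc)
            for (ci, conc) in conditions
            for _ in range(cfg.wells_per_condition_per_plate)
        ] + [(None, 0.0)] * cfg.vehicle_wells_per_plate
        order = rng.permutation(len(slots))
        for slot_pos, well in zip(order, names):
            ci, conc = slots[slot_pos]
            if ci is None:
                compound, vehicle = VEHICLE_COMPOUND, True
                e_cnt = e_atp = e_morph = 0.0
                direction = None
            else:
                t = compounds[ci]
                compound, vehicle = t.compound, False
                e_cnt = hill_effect(conc, t.ec50_count, t.hill, t.emax_count)
                e_atp = hill_effect(conc, t.ec50_atp, t.hill, t.emax_atp)
                e_morph = e_cnt
                direction = t.effect_direction

            well_f = math.exp(rng.normal(0.0, cfg.count_lognorm_sd))
            expected = cfg.baseline_cells_per_well * (1.0 - e_cnt) * well_f
            n_cells = int(rng.poisson(expected))
            lum = (
                cfg.baseline_cells_per_well
                * well_f
                * (1.0 - e_atp)
                * cfg.lum_per_cell
                * plate_gain
                * math.exp(rng.normal(0.0, cfg.lum_noise_sd))
            )

            meta_idx = len(meta_rows)
            meta_rows.append((plate_id, well, compound, float(conc), vehicle))
            lum_rows.append(lum)
            truth_rows.append(
                (
                    plate_id,
                    well,
                    compound,
                    float(conc),
                    1.0 - e_atp,
                    expected,
                    n_cells,
                )
            )
            if n_cells > 0:
                g = rng.standard_normal((n_cells, n_blocks))
                e = rng.standard_normal((n_cells, F))
                noise = math.sqrt(rho) * g[:, block_of] + math.sqrt(1 - rho) * e
                x = baseline_mu + plate_offset + noise
                if direction is not None and e_morph > 0:
                    x = x + shift_scale * e_morph * direction
                blocks.append(x.astype(np.float32))
                block_meta_idx.append((meta_idx, n_cells))

    meta = pd.DataFrame(meta_rows, columns=METADATA_COLUMNS)

    if blocks:
        matrix = np.vstack(blocks)
    else:  # degenerate: every well empty
        matrix = np.empty((0, F), dtype=np.float32)
    del blocks
    rep_idx = np.repeat(
        [i for i, _ in block_meta_idx], [n for _, n in block_meta_idx]
    )
    cells = pd.DataFrame(matrix, columns=feature_names, copy=False)
    for col in reversed(METADATA_COLUMNS):  # insert-at-front, no reindex copy
        values = meta[col].to_numpy()[rep_idx]
        if col in ("plate_id", "compound"):
            cells.insert(0, col, pd.Categorical(values))
        else:
            cells.insert(0, col, values)

    viability = meta.copy()
    viability["luminescence"] = lum_rows
    viability["viability_pct"] = np.nan

    truth_wells = pd.DataFrame(
        truth_rows,
        columns=[
            "plate_id",
            "well",
            "compound",
            "concentration_m",
            "true_viability",
            "expected_count",
            "n_cells",
        ],
    )
    truth = GroundTruth(
        compounds=compounds,
        wells=truth_wells,
        informative_features=informative,
        feature_names=feature_names,
        config=cfg,
    )
    log.info(
        "simulated %d wells / %d cells (%d plates, %d compounds, seed %d)",
        len(meta),
        len(cells),
        cfg.n_plates,
        cfg.n_compounds,
        cfg.seed,
    )
    return (
        CellFeatureTable(data=cells, features=feature_names, wells=meta),
        ViabilityTable(data=viability),
        truth,
    )
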