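"""Random-forest prediction of viability and cell count from profiles.

One regressor per compound (96 well observations each under the default
screen geometry) plus a single global model across the whole panel.  Forests
use 200 trees, bootstrapping, unlimited depth and a fixed seed; models are
validated on a random 80/20 well split.  Importances are scikit-learn's mean
decrease in impurity, which sum to 1 by construction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import train_test_split

from .profiling import ProfileMatrix, filter_features
from .clustering import ClusterResult, cluster_profiles

log = logging.getLogger(__name__)

GLOBAL_SCOPE = "GLOBAL"
TARGETS = ("viability_pct", "cell_count")


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters shared by every forest in the stage."""

    n_trees: int = 200
    seed: int = 42
    split_fraction: float = 0.8  # train share
    low_variance_floor: float = 0.15  # flag when sd(y) < floor * |mean(y)|
    sd_max: float = 2000.0
    corr_max: float = 0.9

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")

    def sub_seeds(self) -> tuple[int, int]:
        """Deterministic (split, forest) sub-seeds derived from ``seed``."""
        state = np.random.SeedSequence(self.seed).generate_state(2)
        return int(state[0] % 2**31), int(state[1] % 2**31)


@dataclass
class ModelReport:
    """Metrics and ranked importances of one fitted model."""

    scope: str  # compound code or "GLOBAL"
    target: str
    r2_train: float
    r2_test: float
    mse_train: float
    mse_test: float
    n_train: int
    n_test: int
    importances: pd.Series
    low_variance: bool = False
    augmented: bool = False
    train_ids: list = field(default_factory=list, repr=False)
    test_ids: list = field(default_factory=list, repr=False)


def split_train_test(X, y, spec: ModelSpec):
    """Seeded uniform random 80/20 split over rows (disjoint, exhaustive)."""
    spec.validate()
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    split_seed, _ = spec.sub_seeds()
    idx_train, idx_test = train_test_split(
        np.arange(n),
        test_size=1.0 - spec.split_fraction,
        random_state=split_seed,
        shuffle=True,
    )
    return np.sort(idx_train), np.sort(idx_test)


def fit_rf(X_train, y_train, spec: ModelSpec) -> RandomForestRegressor:
    """Fit the bagged regression forest (200 trees, unlimited depth)."""
    if len(y_train) < 2:
        raise ValueError("need at least 2 training rows")
    X_train = np.asarray(X_train, dtype=float)
    if X_train.ndim != 2 or X_train.shape[1] < 1:
        raise ValueError("training matrix must have at least one feature")
    _, forest_seed = spec.sub_seeds()
    model = RandomForestRegressor(
        n_estimators=spec.n_trees,
        bootstrap=True,
        max_depth=None,
        random_state=forest_seed,
        n_jobs=1,
    )
    model.fit(X_train, np.asarray(y_train, dtype=float))
    return model


def evaluate(model, X_test, y_test) -> tuple[float, float]:
    """(R^2, MSE) on held-out rows.

    R^2 is ``1 - SS_res / SS_tot``; with a zero-variance test target it is
    undefined and reported as NaN while the MSE is still returned.
    """
    y_test = np.asarray(y_test, dtype=float)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(np.asarray(X_test, dtype=float))
    mse = float(mean_squared_error(y_test, pred))
    if np.var(y_test) == 0:
        log.warning("test target has zero variance; R^2 undefined")
        return float("nan"), mse
    return float(r2_score(y_test, pred)), mse


def _fit_report(
    scope: str,
    target: str,
    X: np.ndarray,
    y: np.ndarray,
    ids,
    features: list[str],
    spec: ModelSpec,
    augmenter=None,
) -> ModelReport:
    idx_train, idx_test = split_train_test(X, y, spec)
    X_train, y_train = X[idx_train], y[idx_train]
    augmented = False
    if augmenter is not None:
        X_train, y_train, _flags = augmenter(X_train, y_train)
        augmented = True
    model = fit_rf(X_train, y_train, spec)
    r2_tr, mse_tr = evaluate(model, X_train, y_train)
    r2_te, mse_te = evaluate(model, X[idx_test], y[idx_test])
    mean_abs = abs(float(np.mean(y)))
    low_var = float(np.std(y)) < spec.low_variance_floor * max(mean_abs, 1e-12)
    ids = list(ids)
    return ModelReport(
        scope=scope,
        target=target,
        r2_train=r2_tr,
        r2_test=r2_te,
        mse_train=mse_tr,
        mse_test=mse_te,
        n_train=len(idx_train),
        n_test=len(idx_test),
        importances=pd.Series(model.feature_importances_, index=features),
        low_variance=low_var,
        augmented=augmented,
        train_ids=[ids[i] for i in idx_train],
        test_ids=[ids[i] for i in idx_test],
    )


def _well_ids(df: pd.DataFrame) -> list[str]:
    return (df["plate_id"].astype(str) + ":" + df["well"].astype(str)).tolist()


def per_compound_models(
    pm: ProfileMatrix,
    targets: pd.DataFrame,
    spec: ModelSpec,
    target_names=TARGETS,
) -> list[ModelReport]:
    """One report per compound per target, vehicle wells excluded.

    ``targets`` is a per-well frame keyed by ``(plate_id, well)`` carrying
    the target columns.  Feature filtering (SD cap + correlation pruning) is
    refit inside each compound's own 96-well slice.  Reports whose target
    barely varies (a no-effect compound: the model mostly fits noise) carry
    ``low_variance=True``.
    """
    spec.validate()
    data = pm.data.merge(targets, on=["plate_id", "well"], how="left")
    reports: list[ModelReport] = []
    compounds = sorted(
        c for c in data["compound"].unique() if not data.loc[data["compound"] == c, "vehicle"].iloc[0]
    )
    if not compounds:
        raise ValueError("no non-vehicle compounds in profiles")
    for compound in compounds:
        sub = data.loc[data["compound"] == compound].reset_index(drop=True)
        sub_pm = ProfileMatrix(
            data=sub,
            features=list(pm.features),
            level="well",
            normalization=pm.normalization,
        )
        filtered, _ledger = filter_features(
            sub_pm, sd_max=spec.sd_max, corr_max=spec.corr_max
        )
        X = filtered.matrix()
        for target in target_names:
            if target not in sub.columns:
                raise KeyError(f"target column {target!r} missing")
            y = sub[target].to_numpy(dtype=float)
            reports.append(
                _fit_report(
                    compound,
                    target,
                    X,
                    y,
                    _well_ids(sub),
                    filtered.features,
                    spec,
                )
            )
    return reports


def global_model(
    pm: ProfileMatrix,
    targets: pd.DataFrame,
    spec: ModelSpec,
    target: str = "viability_pct",
    augmenter=None,
) -> ModelReport:
    """Single panel-wide model; SMOGN (if any) touches only the train split.

    ``augmenter`` is a callable ``(X_train, y_train) -> (X_aug, y_aug,
    synthetic_flags)`` — typically a :mod:`myoscreen.smogn` closure.  Test
    rows are split off before augmentation and never synthesized.
    """
    spec.validate()
    data = pm.data.merge(targets, on=["plate_id", "well"], how="left")
    data = data.loc[~data["vehicle"].astype(bool)].reset_index(drop=True)
    if data["compound"].nunique() < 2:
        raise ValueError("global model needs at least 2 compounds")
    X = data[pm.features].to_numpy(dtype=float)
    y = data[target].to_numpy(dtype=float)
    return _fit_report(
        GLOBAL_SCOPE,
        target,
        X,
        y,
        _well_ids(data),
        list(pm.features),
        spec,
        augmenter=augmenter,
    )


def importance_matrix(
    reports: list[ModelReport], k: int = 30
) -> tuple[pd.DataFrame, ClusterResult, ClusterResult]:
    """Top-``k`` importance matrix across models, with row/column trees.

    Features are ranked per model by descending importance (absent features
    rank last), ordered by their median rank across models, and the top
    ``k`` kept.  Rows and columns are clustered with single linkage on
    Pearson dissimilarity.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 model reports")
    scopes = [r.scope for r in reports]
    if len(set(scopes)) != len(scopes):
        raise ValueError("reports must have unique scopes (filter by target)")
    imp = pd.DataFrame([r.importances for r in reports], index=scopes).fillna(0.0)
    ranks = imp.rank(axis=1, ascending=False, method="average")
    median_rank = ranks.median(axis=0).sort_values(kind="stable")
    top = list(median_rank.index[: min(k, len(median_rank))])
    matrix = imp[top]

    try:
        row_res = cluster_profiles(
            matrix.to_numpy(), linkage="single", metric="pearson",
            labels=list(matrix.index),
        )
    except ValueError:
        row_res = cluster_profiles(
            matrix.to_numpy(), linkage="single", metric="euclidean",
            labels=list(matrix.index),
        )
    try:
        col_res = cluster_profiles(
            matrix.to_numpy().T, linkage="single", metric="pearson",
            labels=top,
        )
    except ValueError:
        col_res = cluster_profiles(
            matrix.to_numpy().T, linkage="single", metric="euclidean",
            labels=top,
        )
    return matrix, row_res, col_res


def informative_feature_test(
    importances: pd.Series, informative: list[str]
) -> float:
    """One-sided Mann-Whitney p that informative features out-rank the rest."""
    inf_set = set(informative)
    a = importances[[f for f in importances.index if f in inf_set]]
    b = importances[[f for f in importances.index if f not in inf_set]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both feature groups must be non-empty")
    return float(stats.mannwhitneyu(a, b, alternative="greater").pvalue)


def reports_to_frame(reports: list[ModelReport]) -> pd.DataFrame:
    rows = [
        {
            "scope": r.scope,
            "target": r.target,
            "r2_train": r.r2_train,
            "r2_test": r.r2_test,
            "mse_train": r.mse_train,
            "mse_test": r.mse_test,
            "n_train": r.n_train,
            "n_test": r.n_test,
            "low_variance": r.low_variance,
            "augmented": r.augmented,
        }
        for r in reports
    ]
    return pd.DataFrame(rows)


def importances_to_frame(reports: list[ModelReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for feature, value in r.importances.items():
            rows.append(
                {
                    "scope": r.scope,
                    "target": r.target,
                    "feature": feature,
                    "importance": value,
                }
            )
    return pd.DataFrame(rows)


def export_importance_heatmap(matrix: pd.DataFrame, row_res, col_res, path) -> None:
    """Clustered heatmap of the top-importance matrix."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ordered = matrix.iloc[row_res.order, col_res.order]
    fig, ax = plt.subplots(figsize=(10, max(4.0, 0.25 * len(matrix))))
    mesh = ax.pcolormesh(ordered.to_numpy(), cmap="viridis")
    ax.set_yticks(np.arange(len(ordered)) + 0.5)
    ax.set_yticklabels(ordered.index, fontsize=6)
    ax.set_xticks(np.arange(len(ordered.columns)) + 0.5)
    ax.set_xticklabels(ordered.columns, fontsize=5, rotation=90)
    fig.colorbar(mesh, ax=ax, label="mean decrease in impurity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
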