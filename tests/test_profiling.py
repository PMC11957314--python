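"""Aggregation, normalization, and feature-filter contracts."""
import logging

import numpy as np
import pandas as pd
import pytest

from myoscreen import (
    aggregate_treatments,
    aggregate_wells,
    filter_features,
    normalize_profiles,
)
from myoscreen.io import CellFeatureTable
from myoscreen.profiling import MAD_CONSISTENCY, ProfileMatrix


def _cell_table(well_values: dict[str, list[float]], feature="f0"):
    """One-feature cell table from a {well: values} mapping (plate P1)."""
    rows = []
    for well, values in well_values.items():
        for v in values:
            rows.append({"plate_id": "P1", "well": well, "compound": "CPDA",
                         "concentration_m": 1e-6, "vehicle": False, feature: v})
    data = pd.DataFrame(rows)
    wells = (
        data[["plate_id", "well", "compound", "concentration_m", "vehicle"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    return CellFeatureTable(data=data, features=[feature], wells=wells)


def _profile_matrix(values_by_well, vehicle_wells, feature="f0"):
    rows = []
    for well, v in values_by_well.items():
        rows.append(
            {
                "plate_id": "P1",
                "well": well,
                "compound": "VEHICLE" if well in vehicle_wells else "CPDA",
                "concentration_m": 0.0 if well in vehicle_wells else 1e-6,
                "vehicle": well in vehicle_wells,
                "cell_count": 10,
                feature: v,
            }
        )
    return ProfileMatrix(data=pd.DataFrame(rows), features=[feature])


class TestAggregateWells:
    def test_median_of_three_cells(self):
        pm = aggregate_wells(_cell_table({"A01": [1.0, 2.0, 9.0]}))
        assert pm.data["f0"].iloc[0] == 2.0
        assert pm.data["cell_count"].iloc[0] == 3

    def test_single_cell_identity(self):
        pm = aggregate_wells(_cell_table({"A01": [7.25]}))
        assert pm.data["f0"].iloc[0] == 7.25

    def test_matches_sort_and_pick_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=50).tolist()
        pm = aggregate_wells(_cell_table({"A01": values}))
        s = sorted(values)
        oracle = 0.5 * (s[24] + s[25])  # even count: mean of middle pair
        assert pm.data["f0"].iloc[0] == oracle

    def test_permutation_invariant_over_cells(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=31).tolist()
        a = aggregate_wells(_cell_table({"A01": values}))
        b = aggregate_wells(_cell_table({"A01": values[::-1]}))
        assert a.data["f0"].iloc[0] == b.data["f0"].iloc[0]

    def test_missing_feature_rows_dropped(self):
        table = _cell_table({"A01": [1.0, 2.0, np.nan, 9.0]})
        pm = aggregate_wells(table)
        assert pm.data["cell_count"].iloc[0] == 3
        assert pm.data["f0"].iloc[0] == 2.0

    def test_empty_table_rejected(self):
        table = _cell_table({"A01": [1.0]})
        table.data = table.data.iloc[:0]
        with pytest.raises(ValueError):
            aggregate_wells(table)


class TestNormalize:
    def _pm(self, extra=None):
        ctrl = {f"A{i:02d}": float(i) for i in range(1, 6)}  # controls 1..5
        values = dict(ctrl)
        if extra:
            values.update(extra)
        return _profile_matrix(values, vehicle_wells=set(ctrl))

    def test_robust_mad_centers_on_control_median(self):
        pm = self._pm({"B01": 3.0})
        out = normalize_profiles(pm, "robust_mad")
        row = out.data.loc[out.data["well"] == "B01", "f0"].iloc[0]
        assert row == pytest.approx(0.0, abs=1e-12)

    def test_robust_mad_unit_scale(self):
        # controls {1..5}: median 3, MAD 1 -> (4.4826 - 3) / 1.4826 = 1
        pm = self._pm({"B01": 3.0 + MAD_CONSISTENCY})
        out = normalize_profiles(pm, "robust_mad")
        row = out.data.loc[out.data["well"] == "B01", "f0"].iloc[0]
        assert row == pytest.approx(1.0, abs=1e-12)

    def test_vehicle_median_zero_after_robust_mad(self, small_run):
        out = small_run.norm
        for _, plate in out.data.groupby("plate_id"):
            ctrl = plate.loc[plate["vehicle"], out.features].to_numpy()
            med = np.median(ctrl, axis=0)
            mad = MAD_CONSISTENCY * np.median(np.abs(ctrl - med), axis=0)
            assert np.abs(med).max() < 1e-9
            assert np.abs(mad - 1).max() < 1e-9

    def test_zero_mad_feature_dropped_with_warning(self, caplog):
        pm = self._pm()
        pm.data["f1"] = [2.0] * len(pm.data)  # constant in controls
        pm.features = ["f0", "f1"]
        with caplog.at_level(logging.WARNING, logger="myoscreen.profiling"):
            out = normalize_profiles(pm, "robust_mad")
        assert out.features == ["f0"]
        assert any("zero control scale" in r.message for r in caplog.records)

    def test_zscore_uses_control_mean_and_sd(self):
        pm = self._pm({"B01": 3.0 + np.std([1, 2, 3, 4, 5], ddof=1)})
        out = normalize_profiles(pm, "zscore")
        row = out.data.loc[out.data["well"] == "B01", "f0"].iloc[0]
        assert row == pytest.approx(1.0, abs=1e-12)

    def test_minmax_maps_control_range_to_unit(self):
        pm = self._pm({"B01": 5.0})
        out = normalize_profiles(pm, "minmax")
        row = out.data.loc[out.data["well"] == "B01", "f0"].iloc[0]
        assert row == pytest.approx(1.0, abs=1e-12)

    def test_normalization_is_plate_local(self, small_run):
        """Perturbing plate P2's raw profiles never changes plate P1's output."""
        pm = small_run.raw
        tampered = ProfileMatrix(
            data=pm.data.copy(),
            features=pm.features,
            level="well",
            well_counts=pm.well_counts,
        )
        mask = tampered.data["plate_id"] == "P2"
        tampered.data.loc[mask, pm.features] += 17.0
        a = normalize_profiles(pm, "robust_mad")
        b = normalize_profiles(tampered, "robust_mad")
        common = [f for f in a.features if f in b.features]
        p1 = a.data["plate_id"] == "P1"
        np.testing.assert_allclose(
            a.data.loc[p1, common].to_numpy(),
            b.data.loc[p1, common].to_numpy(),
        )

    def test_too_few_vehicle_wells_rejected(self):
        pm = _profile_matrix({"A01": 1.0, "B01": 2.0}, vehicle_wells={"A01"})
        with pytest.raises(ValueError, match="vehicle"):
            normalize_profiles(pm, "robust_mad")


def _matrix_pm(X: np.ndarray) -> ProfileMatrix:
    n, p = X.shape
    features = [f"f{j}" for j in range(p)]
    data = pd.DataFrame(X, columns=features)
    data.insert(0, "plate_id", "P1")
    data.insert(1, "well", [f"A{i + 1:02d}" for i in range(n)])
    data.insert(2, "compound", "CPDA")
    data.insert(3, "concentration_m", 1e-6)
    data.insert(4, "vehicle", False)
    data.insert(5, "cell_count", 10)
    return ProfileMatrix(data=data, features=features, normalization="robust_mad")


def _greedy_oracle(X: np.ndarray, sd_max=2000.0, corr_max=0.9) -> list[int]:
    """Exhaustive reimplementation of the documented filter semantics."""
    sd = X.std(axis=0, ddof=1)
    cand = [j for j in range(X.shape[1]) if sd[j] <= sd_max]
    kept: list[int] = []
    for j in cand:
        ok = True
        for k in kept:
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(X[:, j], X[:, k])[0, 1]
            if np.isfinite(r) and abs(r) > corr_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return kept


class TestFilterFeatures:
    def test_duplicate_column_second_copy_dropped(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        X[:, 2] = X[:, 0]  # r = 1.0 with column 0
        pm, ledger = filter_features(_matrix_pm(X))
        assert pm.features == ["f0", "f1"]
        assert ledger.loc[0, "feature"] == "f2"
        assert ledger.loc[0, "reason"] == "correlation"

    def test_random_matrix_matches_greedy_oracle(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(40, 8))
        mix = rng.normal(size=(8, 20)) * (rng.random((8, 20)) > 0.4)
        X = base @ mix + 0.3 * rng.normal(size=(40, 20))
        X[:, 4] *= 5000.0  # trips the SD cap
        pm, _ = filter_features(_matrix_pm(X))
        oracle = _greedy_oracle(X)
        assert pm.features == [f"f{j}" for j in oracle]

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 12))
        X[:, 5] = X[:, 1] * 1.001
        once, _ = filter_features(_matrix_pm(X))
        twice, ledger = filter_features(once)
        assert twice.features == once.features
        assert len(ledger) == 0

    def test_unnormalized_matrix_rejected(self):
        pm = _matrix_pm(np.eye(5))
        pm.normalization = None
        with pytest.raises(ValueError):
            filter_features(pm)


class TestAggregateTreatments:
    def test_condition_spanning_wells_collapses_to_one_row(self, small_run):
        tr = small_run.treatments
        treated = tr.data[~tr.data["vehicle"]]
        assert (treated["n_wells"] == 4).all()  # 2 wells x 2 plates
        n_cond = small_run.cfg.n_compounds * len(small_run.cfg.concentrations)
        assert len(treated) == n_cond

    def test_median_matches_sort_based_oracle(self, small_run):
        pm = small_run.filtered
        tr = small_run.treatments
        feat = pm.features[0]
        cond = tr.data[~tr.data["vehicle"]].iloc[0]
        wells = pm.data[
            (pm.data["compound"] == cond["compound"])
            & (pm.data["concentration_m"] == cond["concentration_m"])
        ][feat].tolist()
        s = sorted(wells)
        n = len(s)
        oracle = s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])
        assert cond[feat] == pytest.approx(oracle, rel=1e-12)

    def test_single_well_condition_is_identity(self):
        pm = _matrix_pm(np.array([[1.0, 2.0, 3.0]]))
        pm.well_counts = pm.data[
            ["plate_id", "well", "compound", "concentration_m", "vehicle", "cell_count"]
        ]
        tr = aggregate_treatments(pm)
        assert len(tr.data) == 1
        np.testing.assert_array_equal(tr.matrix(), [[1.0, 2.0, 3.0]])

    def test_zero_cell_wells_pull_count_median_down(self, default_run):
        """Treatment-level counts must see dead wells that have no profile."""
        tr = default_run.treatments
        tf = default_run.truth.compounds_frame()
        lethal = tf.loc[tf["emax_count"] == 1.0, "compound"]
        top = max(default_run.cfg.concentrations)
        rows = tr.data[
            tr.data["compound"].isin(lethal) & (tr.data["concentration_m"] == top)
        ]
        assert (rows["cell_count"] < 20).all()
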