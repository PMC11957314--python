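"""Viability normalization, significance screening, and potency fits.

Luminescence is expressed as a percentage of the same plate's vehicle-median
read (vehicle wells therefore have median exactly 100%).  Each compound x
concentration condition is screened against vehicle controls with a Welch
two-sample t-test on cell count and on viability, with the conventional
significance tiers.  Potency (IC50 from viability, LC50 from cell count) is
summarized by a four-parameter log-logistic fit per compound.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import ViabilityTable
from .profiling import ProfileMatrix

log = logging.getLogger(__name__)

TIER_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_tier(p: float) -> str:
    for threshold, symbol in TIER_THRESHOLDS:
        if p < threshold:
            return symbol
    return "ns"


def normalize_viability(vt: ViabilityTable) -> ViabilityTable:
    """Scale luminescence to percent of the same plate's vehicle median.

    A plate whose vehicle-median luminescence is 0 carries no reference
    signal and is rejected.
    """
    df = vt.data.copy()
    for plate_id, plate in df.groupby("plate_id", observed=True):
        ctrl = plate.loc[plate["vehicle"].astype(bool), "luminescence"]
        if len(ctrl) < 1:
            raise ValueError(f"plate {plate_id!r} has no vehicle wells")
        ref = float(ctrl.median())
        if ref <= 0:
            raise ValueError(
                f"plate {plate_id!r} rejected: vehicle median luminescence is 0"
            )
        # divide first: the median control well maps to exactly 100.0
        df.loc[plate.index, "viability_pct"] = (
            plate["luminescence"] / ref
        ) * 100.0
    return ViabilityTable(data=df)


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value with degenerate-sample handling."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return p if math.isfinite(p) else 1.0


def condition_tests(
    profiles: ProfileMatrix,
    viability: ViabilityTable,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Screen every condition against vehicle controls on both endpoints.

    Cell counts come from the full well-count table (zero-cell wells
    included); viability must already be normalized.  The control scope for
    a condition is the set of vehicle wells on the plates that carry it.
    With ``fdr=True`` p-values are Benjamini-Hochberg adjusted per endpoint
    before tier assignment (off by default).
    """
    counts = profiles.well_counts
    if counts is None:
        counts = profiles.data[
            ["plate_id", "well", "compound", "concentration_m", "vehicle", "cell_count"]
        ]
    via = viability.data
    if via["viability_pct"].isna().any():
        raise ValueError("viability must be normalized before screening")
    wells = counts.merge(
        via[["plate_id", "well", "luminescence", "viability_pct"]],
        on=["plate_id", "well"],
        how="inner",
    )
    vehicle_wells = wells.loc[wells["vehicle"].astype(bool)]
    treated = wells.loc[~wells["vehicle"].astype(bool)]

    rows = []
    for (compound, conc), cond in treated.groupby(
        ["compound", "concentration_m"], observed=True, sort=True
    ):
        scope = vehicle_wells.loc[
            vehicle_wells["plate_id"].isin(cond["plate_id"].unique())
        ]
        if len(cond) < 2 or len(scope) < 2:
            raise ValueError(
                f"insufficient replication for {compound} @ {conc:g} M"
            )
        p_count = _welch_p(cond["cell_count"], scope["cell_count"])
        p_via = _welch_p(cond["viability_pct"], scope["viability_pct"])
        rows.append(
            {
                "compound": compound,
                "concentration_m": conc,
                "n_wells": len(cond),
                "median_count": float(cond["cell_count"].median()),
                "median_viability_pct": float(cond["viability_pct"].median()),
                "vehicle_median_count": float(scope["cell_count"].median()),
                "vehicle_median_viability_pct": float(
                    scope["viability_pct"].median()
                ),
                "p_count": p_count,
                "p_viability": p_via,
            }
        )
    out = pd.DataFrame(rows)
    if fdr and len(out):
        out["p_count"] = stats.false_discovery_control(out["p_count"])
        out["p_viability"] = stats.false_discovery_control(out["p_viability"])
    out["tier_count"] = out["p_count"].map(significance_tier)
    out["tier_viability"] = out["p_viability"].map(significance_tier)
    return out


@dataclass
class PotencyFit:
    """One fitted four-parameter log-logistic curve."""

    midpoint: float  # molar; NaN when not determined
    floor: float
    ceiling: float
    slope: float
    converged: bool
    determined: bool
    rss: float
    extrapolated: bool


def _four_pl(logc, ceiling, floor, logmid, slope):
    return floor + (ceiling - floor) / (1.0 + 10 ** (slope * (logc - logmid)))


def fit_potency(
    concentrations,
    responses,
    flat_min_range: float = 10.0,
    mid_bounds_factor: float = 100.0,
) -> PotencyFit:
    """Least-squares 4PL fit of a declining response; midpoint is the potency.

    Initialization: ceiling = max response, floor = min response, midpoint =
    geometric mean of the tested range, slope = 1; the midpoint is bounded
    within ``mid_bounds_factor`` times the tested range.  A response whose
    total range is below ``flat_min_range`` (percentage points) is reported
    as not determined, as is a failed fit.  A midpoint outside the tested
    range is flagged extrapolated.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    nd = PotencyFit(
        midpoint=float("nan"),
        floor=float("nan"),
        ceiling=float("nan"),
        slope=float("nan"),
        converged=False,
        determined=False,
        rss=float("nan"),
        extrapolated=False,
    )
    if float(np.ptp(resp)) < flat_min_range:
        return nd

    logc = np.log10(conc)
    lo, hi = logc.min(), logc.max()
    bound_span = math.log10(mid_bounds_factor)
    p0 = [float(resp.max()), float(resp.min()), float((lo + hi) / 2.0), 1.0]
    bounds = (
        [-1e3, -1e3, lo - bound_span, 0.05],
        [1e3, 1e3, hi + bound_span, 50.0],
    )
    try:
        popt, _ = optimize.curve_fit(
            _four_pl, logc, resp, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError):
        return nd
    ceiling, floor, logmid, slope = (float(v) for v in popt)
    rss = float(np.sum((resp - _four_pl(logc, *popt)) ** 2))
    midpoint = 10.0**logmid
    return PotencyFit(
        midpoint=midpoint,
        floor=floor,
        ceiling=ceiling,
        slope=slope,
        converged=True,
        determined=True,
        rss=rss,
        extrapolated=not (10.0**lo <= midpoint <= 10.0**hi),
    )


def potency_table(summaries: pd.DataFrame, flat_min_range: float = 10.0) -> pd.DataFrame:
    """IC50 (viability) and LC50 (cell count) per compound from summaries.

    Count responses are scaled to percent of the vehicle-median count so both
    endpoints share the 0-100 response scale.
    """
    rows = []
    for compound, sub in summaries.groupby("compound", observed=True, sort=True):
        sub = sub.sort_values("concentration_m")
        conc = sub["concentration_m"].to_numpy()
        via = sub["median_viability_pct"].to_numpy()
        cnt = (
            100.0
            * sub["median_count"].to_numpy()
            / sub["vehicle_median_count"].to_numpy()
        )
        fit_v = fit_potency(conc, via, flat_min_range=flat_min_range)
        fit_c = fit_potency(conc, cnt, flat_min_range=flat_min_range)
        rows.append(
            {
                "compound": compound,
                "ic50_m": fit_v.midpoint,
                "ic50_determined": fit_v.determined,
                "ic50_extrapolated": fit_v.extrapolated,
                "ic50_rss": fit_v.rss,
                "lc50_m": fit_c.midpoint,
                "lc50_determined": fit_c.determined,
                "lc50_extrapolated": fit_c.extrapolated,
                "lc50_rss": fit_c.rss,
            }
        )
    return pd.DataFrame(rows)


def decoupling_report(
    summaries: pd.DataFrame,
    alpha: float = 0.05,
    count_drop_floor: float = 0.2,
) -> pd.DataFrame:
    """Conditions where cell count drops significantly but viability does not.

    Flags rows with ``p_count < alpha``, ``p_viability >= alpha`` and a
    median count decrease of at least ``count_drop_floor`` (fraction of the
    vehicle-median count) — the colchicine-like regime where segmentable
    cells vanish while ATP content persists.
    """
    drop = 1.0 - summaries["median_count"] / summaries["vehicle_median_count"]
    mask = (
        (summaries["p_count"] < alpha)
        & (summaries["p_viability"] >= alpha)
        & (drop >= count_drop_floor)
    )
    out = summaries.loc[mask].copy()
    out["count_drop_fraction"] = drop[mask]
    return out.reset_index(drop=True)
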