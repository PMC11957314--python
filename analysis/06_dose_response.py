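"""Significance screen, decoupling report, and IC50/LC50 potency table.

Welch t-tests of every compound x concentration condition against vehicle
controls (cell count and viability), the list of conditions where count
collapses while ATP-based viability does not (colchicine-like decoupling),
and 4PL potency fits per compound.
"""
import sys
from pathlib import Path

import pandas as pd

from myoscreen import condition_tests, decoupling_report, potency_table
from myoscreen.io import read_viability, write_table
from myoscreen.doseresponse import normalize_viability
from myoscreen.profiling import read_profiles

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    profiles = read_profiles(OUT / "profiles.csv")
    profiles.well_counts = pd.read_csv(
        OUT / "well_counts.csv",
        dtype={"plate_id": str, "well": str},
        float_precision="round_trip",
    )
    viability = normalize_viability(
        read_viability(OUT / "luminescence.csv", OUT / "metadata.csv")
    )
    summaries = condition_tests(profiles, viability)
    n_sig = summaries.loc[
        (summaries["p_count"] < 0.05)
        & (summaries["median_count"] < summaries["vehicle_median_count"]),
        "compound",
    ].nunique()
    print(
        f"{n_sig} of {summaries['compound'].nunique()} compounds show a "
        "significant cell-count decrease at >= 1 dose"
    )

    flagged = decoupling_report(summaries)
    print(
        f"decoupled conditions (count down, viability flat): "
        f"{flagged[['compound', 'concentration_m']].to_dict('records')}"
    )

    potency = potency_table(summaries)
    determined = potency["ic50_determined"].sum()
    print(f"IC50 determined for {determined} of {len(potency)} compounds")

    write_table(summaries, OUT / "condition_summaries.csv")
    write_table(flagged, OUT / "decoupling.csv")
    write_table(potency, OUT / "potency.csv")


if __name__ == "__main__":
    sys.exit(main())
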