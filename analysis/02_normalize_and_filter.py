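"""Robust-MAD normalize raw well profiles and prune the feature set.

Normalization is per plate against that plate's vehicle wells; filtering
drops features with SD > 2000 and then prunes |r| > 0.9 redundancy in
column order.  Treatment-level profiles (median over each condition's 12
wells) are written for clustering.
"""
import sys
from pathlib import Path

import pandas as pd

from myoscreen import aggregate_treatments, filter_features, normalize_profiles
from myoscreen.io import write_table
from myoscreen.profiling import read_profiles, write_profiles

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    raw = read_profiles(OUT / "profiles_raw.csv", normalization=None)
    raw.normalization = None
    raw.well_counts = pd.read_csv(
        OUT / "well_counts.csv",
        dtype={"plate_id": str, "well": str},
        float_precision="round_trip",
    )
    norm = normalize_profiles(raw, method="robust_mad")
    filtered, ledger = filter_features(norm)
    print(
        f"normalized {len(norm.data)} profiles; kept "
        f"{len(filtered.features)}/{len(raw.features)} features "
        f"({len(ledger)} dropped: {ledger['reason'].value_counts().to_dict()})"
    )
    treatments = aggregate_treatments(filtered)
    print(f"{len(treatments.data)} treatment-level profiles")

    write_profiles(filtered, OUT / "profiles.csv")
    write_profiles(treatments, OUT / "treatment_profiles.csv")
    write_table(ledger, OUT / "drop_ledger.csv")


if __name__ == "__main__":
    sys.exit(main())
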