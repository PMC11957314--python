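"""Generate the default synthetic screen and build well-level profiles.

30 compounds x 8 concentrations (10 nM - 30 uM) x 4 wells x 3 plates, 35
vehicle wells per plate, 300 features, ~250 cells per well.  The single-cell
table (~0.5M rows) is held in memory only; what lands in results/ are the
per-well median profiles, the plate metadata, luminescence reads, and the
generator's ground truth.
"""
import sys
from pathlib import Path

import pandas as pd

from myoscreen import SyntheticConfig, aggregate_wells, generate_experiment
from myoscreen.io import METADATA_COLUMNS, write_table
from myoscreen.profiling import write_profiles

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 42


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SyntheticConfig(seed=SEED)
    cells, viability, truth = generate_experiment(cfg)
    print(f"simulated {cells.n_cells} cells across {len(cells.wells)} wells")

    profiles = aggregate_wells(cells)
    n_empty = int((profiles.well_counts["cell_count"] == 0).sum())
    print(f"aggregated {len(profiles.data)} well profiles; {n_empty} wells empty")

    write_table(cells.wells, OUT / "metadata.csv")
    write_table(
        viability.data[METADATA_COLUMNS + ["luminescence"]],
        OUT / "luminescence.csv",
    )
    write_profiles(profiles, OUT / "profiles_raw.csv")
    write_table(profiles.well_counts, OUT / "well_counts.csv")
    write_table(truth.compounds_frame(), OUT / "ground_truth_compounds.csv")
    write_table(truth.wells, OUT / "ground_truth_wells.csv")
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
        OUT / "ground_truth_features.csv",
    )
    print(f"wrote inputs + raw profiles to {OUT}")


if __name__ == "__main__":
    sys.exit(main())
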