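"""Rebalance rare cytotoxic profiles with SMOGN and refit the global model.

SMOGN is applied to the training split only; the held-out test rows are
identical to the unaugmented model's.  The check that matters: the
augmented model's top-10 importance set stays close to the original's
(Jaccard), i.e. synthetic profiles do not distort what the model learns.
"""
import sys
from pathlib import Path

from myoscreen import ModelSpec, SmognConfig, global_model
from myoscreen.io import write_table
from myoscreen.models import reports_to_frame
from myoscreen.profiling import read_profiles
from myoscreen.smogn import make_augmenter

OUT = Path(__file__).resolve().parents[1] / "results"
SMOGN_SEED = 7


def main() -> None:
    sys.path.insert(0, str(Path(__file__).parent))
    from importlib import import_module

    load_targets = import_module("04_viability_models").load_targets
    profiles = read_profiles(OUT / "profiles.csv")
    _, targets = load_targets()
    spec = ModelSpec(seed=42)

    plain = global_model(profiles, targets, spec, target="viability_pct")
    augmented = global_model(
        profiles,
        targets,
        spec,
        target="viability_pct",
        augmenter=make_augmenter(SmognConfig(seed=SMOGN_SEED)),
    )
    top_a = set(plain.importances.nlargest(10).index)
    top_b = set(augmented.importances.nlargest(10).index)
    jaccard = len(top_a & top_b) / len(top_a | top_b)
    print(
        f"unaugmented test R^2 = {plain.r2_test:.3f}; "
        f"SMOGN-augmented test R^2 = {augmented.r2_test:.3f}"
    )
    print(f"top-10 importance Jaccard (augmented vs plain): {jaccard:.2f}")
    write_table(
        reports_to_frame([plain, augmented]), OUT / "model_reports_smogn.csv"
    )


if __name__ == "__main__":
    sys.exit(main())
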