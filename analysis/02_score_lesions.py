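"""Score the simulated cohort: KS, the vascular adjustment to KS*, BI-RADS.

Reads results/cohort.csv (written by 01_simulate_cohort.py), scores every
lesion with the default flowchart, appends the score columns, and prints
the upgrade audit: how many lesions gained 3 points, how many of those were
malignant, and how many crossed the biopsy cutoff (>4).
"""

from pathlib import Path

import pandas as pd

from ksvasc.pipeline import read_cohort_csv, score_cohort, upgrade_audit
from ksvasc.trees import load_builtin_tree

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    records = read_cohort_csv(RESULTS / "cohort.csv")
    scored = score_cohort(records, load_builtin_tree("kaiser_reconstructed"))
    base = pd.read_csv(RESULTS / "cohort.csv", dtype=str)
    merged = base.merge(
        scored[["id", "increased_vascularity", "ks", "ks_star", "birads"]], on="id"
    )
    merged.to_csv(RESULTS / "cohort_scored.csv", index=False)

    audit = upgrade_audit(scored, cutoff=4)
    by = audit["by_truth_and_type"]
    print(f"scored {len(merged)} lesions -> {RESULTS / 'cohort_scored.csv'}")
    print(f"upgraded (KS* = KS + 3): {audit['n_upgraded']}")
    print(
        f"  malignant: {sum(by['malignant'].values())} "
        f"(mass {by['malignant']['mass']}, non-mass {by['malignant']['non_mass']})"
    )
    print(
        f"  benign:    {sum(by['benign'].values())} "
        f"(mass {by['benign']['mass']}, non-mass {by['benign']['non_mass']})"
    )
    crossed = audit["crossed_cutoff"]
    print(
        f"crossed the >4 cutoff because of the upgrade: "
        f"{crossed['malignant']} malignant, {crossed['benign']} benign"
    )


if __name__ == "__main__":
    main()
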