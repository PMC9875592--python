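"""Baseline characteristics by retinopathy status.

Classifies glycemic status, applies the exclusion cascade, encodes the
analysis covariates, and writes the descriptive table (mean ± SD with
t-tests; counts and column percentages with chi-square tests) to
results/table1_descriptives.csv.

Usage: python analysis/02_descriptives.py
"""

from pathlib import Path

import pandas as pd

from dii_retinopathy.association import descriptive_table
from dii_retinopathy.cohort import apply_exclusions, encode_covariates

RESULTS = Path(__file__).resolve().parents[1] / "results"

CONTINUOUS = ["edii", "age", "bmi"]
CATEGORICAL = [
    "gender", "age_group", "race", "education", "marital", "pir_band",
    "glycemic_status", "hypertension", "high_cholesterol", "smoking", "bmi_cat",
]


def main(cohort_path: Path = RESULTS / "cohort.csv") -> pd.DataFrame:
    cohort = pd.read_csv(cohort_path)
    kept, tally = apply_exclusions(cohort)
    print(f"exclusions: {tally}; analyzed n={len(kept)}")
    enc = encode_covariates(kept)
    table = descriptive_table(
        enc, group_by="retinopathy", continuous=CONTINUOUS, categorical=CATEGORICAL
    )
    out = RESULTS / "table1_descriptives.csv"
    table.to_csv(out, index=False)
    print(table.to_string(index=False))
    print(f"wrote {out}")
    enc.to_csv(RESULTS / "cohort_analysis_ready.csv", index=False)
    return table


if __name__ == "__main__":
    main()
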