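"""Tertile and continuous E-DII models under the adjustment ladder.

For the diabetes and the aged (65+) subsets, fits the four-model ladder —
unadjusted; + age, sex, race; + education, marital status, income band,
smoking, BMI band; + hypertension, high cholesterol — with the exposure
continuous, as total-sample tertiles, and as an ordinal tertile index for
the Wald trend test.  The aged subset drops the age term from the ladder.

Writes results/table3_ladder_<subset>.csv.

Usage: python analysis/04_tertile_models.py
"""

from pathlib import Path

import pandas as pd

from dii_retinopathy.association import model_ladder

RESULTS = Path(__file__).resolve().parents[1] / "results"


def fmt(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in ("per_unit_ci", "T2_ci", "T3_ci"):
        out[col] = out[col].map(lambda t: f"({t[0]:.2f}, {t[1]:.2f})")
    return out.round(3)


def main(path: Path = RESULTS / "cohort_analysis_ready.csv") -> None:
    enc = pd.read_csv(path)
    subsets = {
        "diabetes": (enc["glycemic_status"] == "diabetes", False),
        "aged": (enc["age"] >= 65, True),
    }
    for name, (mask, drop_age) in subsets.items():
        lad = model_ladder(enc, subset=mask, drop_age=drop_age)
        frame = lad.frame()
        dest = RESULTS / f"table3_ladder_{name}.csv"
        fmt(frame).to_csv(dest)
        print(f"\n=== {name} subset (n={int(mask.sum())}, "
              f"tertile cuts {lad.cuts[0]:.2f}/{lad.cuts[1]:.2f}) ===")
        print(fmt(frame).to_string())
        print(f"wrote {dest}")


if __name__ == "__main__":
    main()
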