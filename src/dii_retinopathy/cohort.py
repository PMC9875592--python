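"""Cohort definitions: glycemic status, exclusions, covariate encoding.

Glycemic status is a three-level classification from self-reported physician
diagnoses and laboratory values, with inclusive cutoffs on the high side:

* diabetes: self-reported diagnosis, fasting glucose >= 126 mg/dL,
  HbA1c >= 6.5 %, or OGTT 2-h glucose >= 200 mg/dL;
* prediabetes: self-reported diagnosis, fasting glucose >= 100 mg/dL,
  HbA1c >= 5.7 %, or OGTT >= 140 mg/dL (and no diabetes criterion met);
* normal: no self-reported history and fasting glucose AND HbA1c measured
  and below the prediabetes cutoffs.

Missing lab criteria are treated as "not met", never as disqualifying — the
definition is a disjunction.  A record with no labs at all cannot be called
normal and is classified indeterminate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

NORMAL = "normal"
PREDIABETES = "prediabetes"
DIABETES = "diabetes"
INDETERMINATE = "indeterminate"
GLYCEMIC_LEVELS = (NORMAL, PREDIABETES, DIABETES)

MISSING = "Missing"

# lab cutoffs (inclusive on the high side)
FASTING_DM, FASTING_PRE = 126.0, 100.0      # mg/dL
HBA1C_DM, HBA1C_PRE = 6.5, 5.7              # %
OGTT_DM, OGTT_PRE = 200.0, 140.0            # mg/dL


class IndeterminateStatusError(ValueError):
    """Raised when neither diagnoses nor labs allow a classification."""


def _present(v) -> bool:
    return v is not None and not (isinstance(v, float) and np.isnan(v))


def _ge(v, cutoff: float) -> bool:
    return _present(v) and float(v) >= cutoff


def _flag(v) -> bool:
    return _present(v) and bool(v)


def classify_glycemic_status(record) -> str:
    """Classify one participant (mapping / Series with the lab fields).

    Diabetes criteria are checked first, so labs in the diabetic range
    override a self-reported prediabetes diagnosis.  Raises
    :class:`IndeterminateStatusError` when no criterion is met and the
    normal-range labs (fasting glucose and HbA1c) are not both present.
    """
    fg = record.get("fasting_glucose")
    a1c = record.get("hba1c")
    ogtt = record.get("ogtt")
    if (
        _flag(record.get("self_dm"))
        or _ge(fg, FASTING_DM)
        or _ge(a1c, HBA1C_DM)
        or _ge(ogtt, OGTT_DM)
    ):
        return DIABETES
    if (
        _flag(record.get("self_predm"))
        or _ge(fg, FASTING_PRE)
        or _ge(a1c, HBA1C_PRE)
        or _ge(ogtt, OGTT_PRE)
    ):
        return PREDIABETES
    # normal requires an actual normal glucose and HbA1c measurement
    if _present(fg) and _present(a1c):
        return NORMAL
    raise IndeterminateStatusError(
        f"participant {record.get('participant_id', '?')}: no diagnosis, "
        "no qualifying labs, and fasting glucose / HbA1c not both measured"
    )


def classify_cohort(df: pd.DataFrame) -> pd.Series:
    """Vectorised classification; indeterminate rows get the label
    ``"indeterminate"`` instead of raising (exclusions handle them)."""
    fg = pd.to_numeric(df.get("fasting_glucose"), errors="coerce")
    a1c = pd.to_numeric(df.get("hba1c"), errors="coerce")
    ogtt = pd.to_numeric(df.get("ogtt"), errors="coerce")
    self_dm = df.get("self_dm", pd.Series(False, index=df.index)).fillna(False).astype(bool)
    self_pre = df.get("self_predm", pd.Series(False, index=df.index)).fillna(False).astype(bool)

    dm = self_dm | fg.ge(FASTING_DM) | a1c.ge(HBA1C_DM) | ogtt.ge(OGTT_DM)
    pre = self_pre | fg.ge(FASTING_PRE) | a1c.ge(HBA1C_PRE) | ogtt.ge(OGTT_PRE)
    measured = fg.notna() & a1c.notna()

    out = pd.Series(INDETERMINATE, index=df.index, dtype=object)
    out[measured] = NORMAL
    out[pre] = PREDIABETES
    out[dm] = DIABETES
    out.name = "glycemic_status"
    return out


def apply_exclusions(
    df: pd.DataFrame, diet_col: str = "edii"
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop unusable records, tallying counts per reason.

    Reasons are applied in order — missing dietary data, missing retinopathy
    outcome, indeterminate glycemic status, pregnancy — and each dropped
    record is tallied under the first reason that applies.  The returned
    frame gains a ``glycemic_status`` column if it did not have one.
    """
    df = df.copy()
    if "glycemic_status" not in df.columns:
        df["glycemic_status"] = classify_cohort(df)

    diet_missing = (
        df[diet_col].isna()
        if diet_col in df.columns
        else pd.Series(True, index=df.index)
    )
    outcome_missing = (
        df["retinopathy"].isna()
        if "retinopathy" in df.columns
        else pd.Series(True, index=df.index)
    )
    indeterminate = df["glycemic_status"].eq(INDETERMINATE)
    pregnant = (
        df["pregnant"].fillna(False).astype(bool)
        if "pregnant" in df.columns
        else pd.Series(False, index=df.index)
    )

    reason = pd.Series("kept", index=df.index, dtype=object)
    reason[pregnant] = "pregnancy"
    reason[indeterminate] = "glycemic_status"
    reason[outcome_missing] = "retinopathy"
    reason[diet_missing] = "diet"

    tally = {
        k: int((reason == k).sum())
        for k in ("diet", "retinopathy", "glycemic_status", "pregnancy")
    }
    kept = df.loc[reason == "kept"].copy()
    return kept, tally


# ---------------------------------------------------------------------------
# covariate encoding

PIR_BANDS = ("<1", "1 to 3", ">3", MISSING)
BMI_BANDS = ("<25", "≥25", MISSING)
AGE_BANDS = ("<65", "≥65")


def _pir_band(v) -> str:
    if not _present(v):
        return MISSING
    v = float(v)
    if v < 1.0:
        return "<1"
    if v > 3.0:
        return ">3"
    return "1 to 3"  # boundaries 1.0 and 3.0 fall in the middle band


def _bmi_band(v) -> str:
    if not _present(v):
        return MISSING
    return "≥25" if float(v) >= 25.0 else "<25"


def _yes_no(v) -> str:
    if not _present(v):
        return MISSING
    return "yes" if bool(v) else "no"


def encode_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Add the categorical analysis covariates to a cohort frame.

    Emits: ``aged`` (bool, age >= 65) and ``age_group``; ``overweight``
    (bool, BMI >= 25) and ``bmi_cat``; ``pir_band``; and normalises
    education / marital / smoking / hypertension / high_cholesterol with
    ``"Missing"`` as an explicit factor level so adjusted models keep the
    full sample.
    """
    out = df.copy()
    age = pd.to_numeric(out["age"], errors="coerce")
    out["aged"] = age.ge(65)
    out["age_group"] = np.where(out["aged"], "≥65", "<65")

    bmi = pd.to_numeric(out.get("bmi"), errors="coerce")
    out["overweight"] = bmi.ge(25)
    out["bmi_cat"] = [_bmi_band(v) for v in bmi]

    out["pir_band"] = [_pir_band(v) for v in pd.to_numeric(out.get("pir"), errors="coerce")]

    for col in ("education", "marital", "smoking"):
        if col in out.columns:
            out[col] = out[col].where(out[col].notna(), MISSING).astype(str)
        else:
            out[col] = MISSING
    for col in ("hypertension", "high_cholesterol"):
        src = out[col] if col in out.columns else out.get("self_" + col)
        if src is None:
            out[col] = MISSING
        else:
            out[col] = [_yes_no(v) for v in src]
    return out


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_nhanes_xpt(paths, id_col: str = "SEQN") -> pd.DataFrame:
    """Merge one or more SAS transport (XPT) files on the participant id.

    Thin wrapper over :func:`pandas.read_sas`; column renaming to the
    analysis schema is left to the caller.
    """
    frames = [pd.read_sas(p, format="xport") for p in paths]
    out = frames[0]
    for f in frames[1:]:
        out = out.merge(f, on=id_col, how="outer")
    return out
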