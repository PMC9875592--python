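"""DII / E-DII scoring engine.

The score for one participant is built in three steps from a 24-h recall:

1. standardise each component intake against the global reference,
   ``z = (intake - global_mean) / global_sd``;
2. map the z-score to a centered percentile ``2 * Phi(z) - 1`` in (-1, 1),
   where Phi is the standard normal CDF, so the reference median maps to 0
   and the transform is symmetric;
3. multiply by the component's signed inflammatory effect score and sum
   over components.

The energy-adjusted variant (E-DII) first expresses every intake per
1,000 kcal of total energy and scores it against a density-mode reference
table, which removes confounding by total consumption: proportionally
scaling a whole diet leaves the E-DII unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .reference import PER_1000_KCAL, RAW, DIIReferenceTable


class ScoringError(ValueError):
    """Raised on invalid scoring inputs (mode mismatch, bad energy, ...)."""


@dataclass(frozen=True)
class DietaryRecord:
    """One participant's 24-h recall: intakes by component name plus energy.

    ``density_adjusted`` marks a record whose intakes are already expressed
    per 1,000 kcal; the engine refuses to score such a record against a
    raw-mode table and vice versa.
    """

    participant_id: str
    intakes: Mapping[str, float]
    energy_kcal: float | None = None
    density_adjusted: bool = False

    def __post_init__(self) -> None:
        for name, v in self.intakes.items():
            if v < 0:
                raise ScoringError(
                    f"record {self.participant_id}: negative intake "
                    f"for {name!r} ({v})"
                )


@dataclass(frozen=True)
class DIIScore:
    participant_id: str
    value: float
    n_components_used: int
    n_missing: int
    mode: str  # "DII" or "E-DII"


def z_score(intake: float, mean: float, sd: float) -> float:
    """Standardise an intake against the global reference distribution."""
    if not sd > 0:
        raise ScoringError(f"sd must be > 0, got {sd}")
    return (intake - mean) / sd


def centered_percentile(z):
    """Map a z-score to ``2 * Phi(z) - 1``, a symmetric score in (-1, 1).

    Strictly increasing in z; z = 0 (the reference median) maps to 0.
    Accepts scalars or arrays; non-finite input raises.
    """
    arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ScoringError("z must be finite")
    out = 2.0 * ndtr(arr) - 1.0
    return float(out) if np.isscalar(z) or arr.ndim == 0 else out


def _check_mode(record: DietaryRecord, table: DIIReferenceTable) -> None:
    if table.mode == PER_1000_KCAL and not record.density_adjusted:
        raise ScoringError(
            "per-1000-kcal table requires a density-adjusted record; "
            "call energy_adjust first or use compute_edii"
        )
    if table.mode == RAW and record.density_adjusted:
        raise ScoringError("raw-mode table cannot score a density-adjusted record")


def compute_dii(record: DietaryRecord, table: DIIReferenceTable) -> DIIScore:
    """Score one record against a reference table.

    Components present in the table but absent from the record are skipped
    and counted in ``n_missing`` (the index is routinely computed on a
    subset of its 45 food parameters).  An empty intersection is an error.
    """
    _check_mode(record, table)
    total = 0.0
    used = 0
    for comp in table:
        intake = record.intakes.get(comp.name)
        if intake is None or (isinstance(intake, float) and math.isnan(intake)):
            continue
        z = z_score(intake, comp.global_mean, comp.global_sd)
        total += centered_percentile(z) * comp.effect_score
        used += 1
    if used == 0:
        raise ScoringError(
            f"record {record.participant_id}: no scoreable components "
            "(empty intersection with the table)"
        )
    mode = "E-DII" if table.mode == PER_1000_KCAL else "DII"
    return DIIScore(
        participant_id=record.participant_id,
        value=total,
        n_components_used=used,
        n_missing=len(table) - used,
        mode=mode,
    )


def energy_adjust(record: DietaryRecord) -> DietaryRecord:
    """Express every intake per 1,000 kcal of total energy.

    Invariant: scaling all intakes and the energy by a common factor k > 0
    leaves the adjusted record unchanged.
    """
    if record.energy_kcal is None or not record.energy_kcal > 0:
        raise ScoringError(
            f"record {record.participant_id}: energy_kcal must be > 0 "
            "for density adjustment"
        )
    if record.density_adjusted:
        return record
    scale = record.energy_kcal / 1000.0
    adjusted = {k: v / scale for k, v in record.intakes.items()}
    return replace(record, intakes=adjusted, density_adjusted=True)


def compute_edii(record: DietaryRecord, density_table: DIIReferenceTable) -> DIIScore:
    """Energy-adjusted score: density-adjust the record, then score it."""
    if density_table.mode != PER_1000_KCAL:
        raise ScoringError(
            "compute_edii requires a per-1000-kcal reference table "
            f"(got mode {density_table.mode!r})"
        )
    return compute_dii(energy_adjust(record), density_table)


# ---------------------------------------------------------------------------
# batch interface

def score_cohort(
    intakes: pd.DataFrame,
    table: DIIReferenceTable,
    id_col: str = "participant_id",
    energy_col: str = "energy_kcal",
    energy_adjusted: bool | None = None,
    percentile: str = "normal",
) -> pd.DataFrame:
    """Vectorised scoring of a wide table (one row per participant).

    Columns are matched to table component names; NaN cells count as missing
    for that participant.  When the table is density-mode and
    ``energy_adjusted`` is not True, intakes are divided by
    ``energy_col / 1000`` first.

    ``percentile`` selects the z-to-percentile strategy: ``"normal"``
    (standard normal CDF, the default construction) or ``"empirical"``
    (within-sample rank percentile).

    Returns a frame with participant_id, score, n_components_used, n_missing.
    """
    if percentile not in ("normal", "empirical"):
        raise ScoringError(f"unknown percentile strategy {percentile!r}")
    df = intakes.copy()
    density = table.mode == PER_1000_KCAL
    if density and not (energy_adjusted is True):
        if energy_col not in df.columns:
            raise ScoringError(
                f"density-mode scoring needs column {energy_col!r}"
            )
        energy = df[energy_col].to_numpy(dtype=float)
        if np.any(~(energy > 0)):
            raise ScoringError("energy_kcal must be > 0 for all rows")
        scale = energy / 1000.0
    else:
        scale = None

    n = len(df)
    total = np.zeros(n)
    used = np.zeros(n, dtype=int)
    for comp in table:
        if comp.name not in df.columns:
            continue
        x = df[comp.name].to_numpy(dtype=float)
        if scale is not None:
            x = x / scale
        ok = np.isfinite(x)
        z = np.zeros(n)
        z[ok] = (x[ok] - comp.global_mean) / comp.global_sd
        if percentile == "normal":
            p = 2.0 * ndtr(z) - 1.0
        else:
            # mid-rank empirical percentile within the scored sample
            p = np.zeros(n)
            r = pd.Series(x[ok]).rank(method="average").to_numpy()
            p[ok] = 2.0 * ((r - 0.5) / ok.sum()) - 1.0
        total += np.where(ok, p * comp.effect_score, 0.0)
        used += ok.astype(int)

    if used.max() == 0:
        raise ScoringError("no scoreable components: no table column present")
    out = pd.DataFrame(
        {
            id_col: df[id_col] if id_col in df.columns else np.arange(n),
            "score": total,
            "n_components_used": used,
            "n_missing": len(table) - used,
        }
    )
    out.loc[out["n_components_used"] == 0, "score"] = np.nan
    return out


def score_csv(
    in_path: str | Path,
    out_path: str | Path,
    raw_table: DIIReferenceTable | None = None,
    density_table: DIIReferenceTable | None = None,
    id_col: str = "participant_id",
    energy_col: str = "energy_kcal",
) -> pd.DataFrame:
    """Read a wide intake CSV, write participant_id, DII and/or E-DII.

    Either table may be omitted; at least one is required.  The input may be
    a single-day recall or a pre-averaged file — the reader does not guess.
    """
    if raw_table is None and density_table is None:
        raise ScoringError("provide raw_table and/or density_table")
    df = pd.read_csv(in_path)
    out = pd.DataFrame({id_col: df[id_col]})
    if raw_table is not None:
        s = score_cohort(df, raw_table, id_col=id_col, energy_col=energy_col)
        out["DII"] = s["score"]
        out["n_components_used"] = s["n_components_used"]
        out["n_missing"] = s["n_missing"]
    if density_table is not None:
        s = score_cohort(df, density_table, id_col=id_col, energy_col=energy_col)
        out["E-DII"] = s["score"]
        out["n_components_used"] = s["n_components_used"]
        out["n_missing"] = s["n_missing"]
    out.to_csv(out_path, index=False)
    return out
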