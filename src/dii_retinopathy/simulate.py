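"""Synthetic NHANES-like cohorts with known ground truth.

The generator emulates the structure of the study population — a 40+
cross-sectional sample with three glycemic strata, 24-h recall nutrient
intakes, demographic covariates with explicit "Missing" levels, and a binary
retinopathy outcome — so that every downstream stage (scoring,
classification, subgroup models, threshold search) can be tested without any
external data.

The stated world (the defaults) mirrors the study: n = 2,403; stratum
proportions 1089 / 823 / 491 (normal / prediabetes / diabetes); baseline
retinopathy prevalence 82/1089, 69/823 and 154/491 within strata; a per-unit
E-DII odds ratio of 1.14 in the diabetes stratum and 1.0 elsewhere.
Nutrient intakes are lognormal with median at the reference mean (positive
support and right skew typical of dietary data), so the expected E-DII is
approximately zero.  Lab values are placed on the correct side of the
classification cutoffs, making planted stratum labels exactly recoverable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import cohort as coh
from .reference import PER_1000_KCAL, DIIComponent, DIIReferenceTable
from .scoring import score_cohort


class ConfigError(ValueError):
    pass


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic world; defaults are the study's conditions."""

    n: int = 2403
    seed: int = 0
    # log-OR per E-DII unit, by stratum
    beta_edii_dm: float = math.log(1.14)
    beta_edii_other: float = 0.0
    # optional two-segment (hinge) effect in the diabetes stratum
    inflection: float | None = None
    beta_left: float = 0.0
    beta_right: float = 0.0
    # stratum-specific baseline retinopathy prevalence (normal, pre, dm)
    baseline_prev: tuple[float, float, float] = (82 / 1089, 69 / 823, 154 / 491)
    strata_props: tuple[float, float, float] = (1089 / 2403, 823 / 2403, 491 / 2403)
    # extra log-odds for boolean covariate columns, e.g. {"aged": 0.4}
    covariate_effects: dict = field(default_factory=dict)
    # nutrient-density model: "lognormal" (median at the reference mean,
    # right-skewed like real diet data) or "normal" (the reference
    # distribution the z-score assumes; gives mean E-DII exactly ~0)
    intake_distribution: str = "lognormal"
    # lognormal sigma of nutrient densities (SD multiplier in normal mode)
    intake_dispersion: float = 0.5
    # share of intake variance from a common diet-pattern factor that loads
    # positively on pro- and negatively on anti-inflammatory components;
    # correlated intakes give the cohort E-DII the spread real diets show
    intake_correlation: float = 0.3
    # lognormal median / sigma of total energy (kcal/day)
    energy_median: float = 2000.0
    energy_dispersion: float = 0.25
    # planted missingness (for exclusion-logic tests; zero in the base world)
    covariate_missing_rate: float = 0.005
    diet_missing_rate: float = 0.0
    outcome_missing_rate: float = 0.0
    pregnant_rate: float = 0.0

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if abs(sum(self.strata_props) - 1.0) > 1e-9:
            raise ConfigError("strata_props must sum to 1")
        if any(not (0 < p < 1) for p in self.baseline_prev):
            raise ConfigError("baseline_prev entries must lie in (0, 1)")
        if any(p < 0 for p in self.strata_props):
            raise ConfigError("strata_props must be nonnegative")
        if self.intake_distribution not in ("lognormal", "normal"):
            raise ConfigError("intake_distribution must be 'lognormal' or 'normal'")
        if not (0 <= self.intake_correlation < 1):
            raise ConfigError("intake_correlation must lie in [0, 1)")
        for r in (
            self.covariate_missing_rate,
            self.diet_missing_rate,
            self.outcome_missing_rate,
            self.pregnant_rate,
        ):
            if not (0 <= r <= 1):
                raise ConfigError("rates must lie in [0, 1]")


def _draw_labs(rng: np.random.Generator, stratum: np.ndarray) -> dict[str, np.ndarray]:
    """Lab values on the correct side of every cutoff for each stratum."""
    n = len(stratum)
    fg = np.empty(n)
    a1c = np.empty(n)
    ogtt = np.full(n, np.nan)
    self_dm = np.zeros(n, dtype=bool)
    self_pre = np.zeros(n, dtype=bool)

    nm = stratum == coh.NORMAL
    fg[nm] = rng.uniform(80.0, 99.9, nm.sum())
    a1c[nm] = rng.uniform(4.8, 5.69, nm.sum())

    pre = stratum == coh.PREDIABETES
    fg[pre] = rng.uniform(100.0, 125.9, pre.sum())
    a1c[pre] = rng.uniform(5.0, 6.49, pre.sum())
    self_pre[pre] = rng.random(pre.sum()) < 0.3

    dm = stratum == coh.DIABETES
    fg[dm] = rng.uniform(126.0, 240.0, dm.sum())
    a1c[dm] = rng.uniform(6.5, 10.0, dm.sum())
    self_dm[dm] = rng.random(dm.sum()) < 0.55

    # OGTT observed for a minority, in the stratum's range
    has_ogtt = rng.random(n) < 0.3
    ogtt[has_ogtt & nm] = rng.uniform(80.0, 139.9, (has_ogtt & nm).sum())
    ogtt[has_ogtt & pre] = rng.uniform(140.0, 199.9, (has_ogtt & pre).sum())
    ogtt[has_ogtt & dm] = rng.uniform(200.0, 350.0, (has_ogtt & dm).sum())
    return {
        "fasting_glucose": fg,
        "hba1c": a1c,
        "ogtt": ogtt,
        "self_dm": self_dm,
        "self_predm": self_pre,
    }


def simulate_cohort(
    config: SimulationConfig, table: DIIReferenceTable
) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort and its ground-truth log.

    ``table`` must be a density-mode (per-1,000 kcal) reference table;
    nutrient densities are lognormal with median at the table means, total
    energy is lognormal, and raw daily intakes are density * energy / 1000,
    so the engine's energy adjustment recovers the drawn densities exactly.

    Returns ``(cohort, truth)`` where ``truth`` records the config, the
    planted stratum labels, the true E-DII and event probabilities.
    """
    config.validate()
    if table.mode != PER_1000_KCAL:
        raise ConfigError("simulate_cohort needs a per-1000-kcal reference table")
    rng = np.random.default_rng(config.seed)
    n = config.n

    stratum = rng.choice(
        list(coh.GLYCEMIC_LEVELS), size=n, p=list(config.strata_props)
    )
    labs = _draw_labs(rng, stratum)

    # --- demographics -----------------------------------------------------
    age = rng.uniform(40.0, 85.0, n)
    gender = np.where(rng.random(n) < 0.514, "male", "female")
    race = np.where(rng.random(n) < 0.567, "non-Hispanic White", "other")
    education = rng.choice(
        ["<HS", "HS/equivalent", ">HS"], size=n, p=[0.277, 0.248, 0.475]
    )
    marital = rng.choice(
        ["married", "live separated", "never married"], size=n, p=[0.644, 0.290, 0.066]
    )
    pir = rng.gamma(shape=2.0, scale=1.25, size=n)
    smoking = rng.choice(["never", "ever", "current"], size=n, p=[0.455, 0.337, 0.208])
    bmi = np.clip(rng.normal(28.6, 6.0, n), 15.0, None)
    pregnant = (
        (gender == "female") & (age < 50) & (rng.random(n) < config.pregnant_rate)
        if config.pregnant_rate > 0
        else np.zeros(n, dtype=bool)
    )

    # --- diet -------------------------------------------------------------
    energy = config.energy_median * np.exp(
        rng.normal(0.0, config.energy_dispersion, n)
    )
    intake_cols: dict[str, np.ndarray] = {}
    rho = config.intake_correlation
    pattern = rng.normal(0.0, 1.0, n)  # common diet-pattern factor
    for comp in table:
        load = 1.0 if comp.effect_score >= 0 else -1.0
        zlat = np.sqrt(1.0 - rho) * rng.normal(0.0, 1.0, n) + np.sqrt(rho) * load * pattern
        if config.intake_distribution == "lognormal":
            density = comp.global_mean * np.exp(config.intake_dispersion * zlat)
        else:  # the reference normal the z-score standardises against
            density = np.maximum(comp.global_mean + comp.global_sd * zlat, 0.0)
        intake_cols[comp.name] = density * energy / 1000.0

    df = pd.DataFrame(
        {
            "participant_id": [f"S{i:06d}" for i in range(n)],
            "age": age,
            "gender": gender,
            "race": race,
            "education": education,
            "marital": marital,
            "pir": pir,
            "smoking": smoking,
            "bmi": bmi,
            "pregnant": pregnant,
            **labs,
            **intake_cols,
            "energy_kcal": energy,
        }
    )

    scored = score_cohort(df, table)
    edii = scored["score"].to_numpy()
    df["edii"] = edii

    # --- outcome ----------------------------------------------------------
    alpha = dict(zip(coh.GLYCEMIC_LEVELS, map(_logit, config.baseline_prev)))
    eta = np.array([alpha[s] for s in stratum])
    is_dm = stratum == coh.DIABETES
    if config.inflection is None:
        eta += np.where(is_dm, config.beta_edii_dm, config.beta_edii_other) * edii
    else:
        k = config.inflection
        hinge = (
            config.beta_left * np.minimum(edii - k, 0.0)
            + config.beta_right * np.maximum(edii - k, 0.0)
        )
        eta += np.where(is_dm, hinge, config.beta_edii_other * edii)
    for col, b in config.covariate_effects.items():
        if col == "aged":
            v = (age >= 65).astype(float)
        elif col in df.columns:
            v = pd.to_numeric(df[col], errors="coerce").fillna(0.0).to_numpy()
        else:
            raise ConfigError(f"unknown covariate_effects key {col!r}")
        eta += b * v
    p_event = 1.0 / (1.0 + np.exp(-eta))
    df["retinopathy"] = (rng.random(n) < p_event).astype(float)

    # --- planted missingness ----------------------------------------------
    if config.covariate_missing_rate > 0:
        for col in ("education", "marital", "smoking", "pir", "bmi"):
            mask = rng.random(n) < config.covariate_missing_rate
            df.loc[mask, col] = np.nan
    if config.outcome_missing_rate > 0:
        mask = rng.random(n) < config.outcome_missing_rate
        df.loc[mask, "retinopathy"] = np.nan
    if config.diet_missing_rate > 0:
        mask = rng.random(n) < config.diet_missing_rate
        df.loc[mask, "edii"] = np.nan

    df["hypertension"] = rng.random(n) < 0.445
    df["high_cholesterol"] = rng.random(n) < 0.48

    truth = {
        "config": asdict(config),
        "stratum": stratum.tolist(),
        "edii": edii.tolist(),
        "p_event": p_event.tolist(),
        "stratum_counts": {
            s: int((stratum == s).sum()) for s in coh.GLYCEMIC_LEVELS
        },
    }
    return df, truth


def study_scale_table() -> DIIReferenceTable:
    """Synthetic density-mode table whose induced score spread matches the
    study population (cohort E-DII SD ≈ 1.7, 5th–95th percentile ≈ ±2.8
    under the default generator).

    Twelve components with effect weights of realistic magnitude and
    alternating sign; means and SDs are round numbers.  Used as the default
    world for cohort-level simulations so results never depend on the
    bundled literature transcription.
    """
    effects = (
        -0.663, 0.373, -0.584, 0.298, -0.484, 0.18,
        -0.424, 0.11, -0.365, 0.097, -0.436, 0.106,
    )
    comps = tuple(
        DIIComponent(f"comp{i:02d}", 10.0 * (i + 1), 3.0 * (i + 1), e)
        for i, e in enumerate(effects)
    )
    return DIIReferenceTable(
        components=comps, mode=PER_1000_KCAL, source="study-scale synthetic table"
    )


# ---------------------------------------------------------------------------
# worked fixture

#: Small density-mode table with round numbers, used by the worked fixture.
WORKED_TABLE = DIIReferenceTable(
    components=(
        DIIComponent("fiber", 10.0, 2.0, -0.6, unit="g/1000kcal"),
        DIIComponent("saturated_fat", 14.0, 4.0, 0.4, unit="g/1000kcal"),
        DIIComponent("vitamin_c", 60.0, 20.0, -0.4, unit="mg/1000kcal"),
    ),
    mode=PER_1000_KCAL,
    source="worked-example fixture table (synthetic)",
)


def make_worked_fixture() -> tuple[pd.DataFrame, dict]:
    """A deterministic 48-row cohort with hand-checkable structure.

    Built without a RNG: densities are the reference means shifted by a
    fixed grid of z-offsets, so scores follow directly from the three-step
    formula.  The fixture covers every glycemic stratum, a row scoring
    exactly zero, one "Missing" row per categorical covariate, and splits
    into tertiles of exactly 16/16/16.
    """
    n = 48
    rows = []
    z_grid = [(-1.5 + 3.0 * i / (n - 1)) for i in range(n)]  # z offsets
    z_grid[24] = 0.0  # one row exactly at the reference means (score 0)
    strata = [coh.GLYCEMIC_LEVELS[i % 3] for i in range(n)]
    for i in range(n):
        z = z_grid[i]
        s = strata[i]
        energy = 1500.0 + 25.0 * i
        dens = {
            "fiber": 10.0 + 2.0 * (-z),      # anti-inflammatory: move against z
            "saturated_fat": 14.0 + 4.0 * z,
            "vitamin_c": 60.0 + 20.0 * (-z),
        }
        row = {
            "participant_id": f"W{i:02d}",
            "age": 45.0 + i if 45.0 + i < 90 else 89.0,
            "gender": "male" if i % 2 == 0 else "female",
            "race": "non-Hispanic White" if i % 3 else "other",
            "education": ["<HS", "HS/equivalent", ">HS"][i % 3],
            "marital": ["married", "live separated", "never married"][i % 3],
            "pir": [0.5, 2.0, 4.0][i % 3],
            "smoking": ["never", "ever", "current"][i % 3],
            "bmi": 22.0 + (i % 5) * 2.5,
            "pregnant": False,
            "fasting_glucose": {"normal": 90.0, "prediabetes": 110.0, "diabetes": 150.0}[s],
            "hba1c": {"normal": 5.2, "prediabetes": 6.0, "diabetes": 7.5}[s],
            "ogtt": np.nan,
            "self_dm": s == "diabetes" and i % 2 == 0,
            "self_predm": False,
            "energy_kcal": energy,
            "retinopathy": float(i % 4 == 0 or (s == "diabetes" and i % 2 == 1)),
            "hypertension": i % 2 == 0,
            "high_cholesterol": i % 3 == 0,
        }
        for k, d in dens.items():
            row[k] = d * energy / 1000.0  # raw daily intake
        rows.append(row)
    df = pd.DataFrame(rows)
    # one Missing level per categorical covariate, each on a distinct row
    df.loc[1, "education"] = np.nan
    df.loc[2, "marital"] = np.nan
    df.loc[4, "smoking"] = np.nan
    df.loc[5, "pir"] = np.nan
    df.loc[7, "bmi"] = np.nan

    scored = score_cohort(df, WORKED_TABLE)
    df["edii"] = scored["score"]
    truth = {
        "stratum": strata,
        "zero_score_row": int(np.argmin(np.abs(np.array(z_grid)))),
        "z_grid": z_grid,
        "table": "WORKED_TABLE",
    }
    return df, truth
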