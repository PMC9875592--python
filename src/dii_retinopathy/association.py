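"""Descriptive statistics, logistic models, subgroups, tertiles, trends.

This module reproduces the standard cross-sectional association battery for
a continuous exposure (here the energy-adjusted dietary inflammatory index)
against a binary outcome (retinopathy):

* a descriptive table by outcome status (mean ± SD with Student's t-tests
  for continuous variables; counts with column percentages and Pearson
  chi-square tests for categoricals, "Missing" shown but never tested);
* crude per-stratum logistic fits with a log-likelihood-ratio interaction
  test across strata (all exposure × stratum product terms jointly,
  df = levels − 1);
* total-sample tertile categorisation and a ladder of increasingly adjusted
  models with a Wald test on the ordinal tertile index as the trend test.

All fits are maximum-likelihood logistic regressions (Newton), with 95%
confidence intervals from the normal approximation on the log-odds scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

Z95 = st.norm.ppf(0.975)


class FitError(RuntimeError):
    """Non-convergence, separation, or rank deficiency in a logistic fit."""


@dataclass
class FitResult:
    """A fitted logistic model: coefficients, covariance, likelihood, ORs."""

    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    formula: str = ""

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        self.bse = np.asarray(self.bse, dtype=float)

    @property
    def pvalues(self) -> np.ndarray:
        z = self.params / self.bse
        return 2 * st.norm.sf(np.abs(z))

    def summary_frame(self) -> pd.DataFrame:
        lo = self.params - Z95 * self.bse
        hi = self.params + Z95 * self.bse
        with np.errstate(over="ignore"):  # unbounded CI on separated levels
            return pd.DataFrame(
                {
                    "coef": self.params,
                    "se": self.bse,
                    "OR": np.exp(self.params),
                    "ci_low": np.exp(lo),
                    "ci_high": np.exp(hi),
                    "p": self.pvalues,
                },
                index=self.terms,
            )

    def term(self, name: str) -> pd.Series:
        """Row of the summary frame for one design term (exact name)."""
        frame = self.summary_frame()
        if name in frame.index:
            return frame.loc[name]
        matches = [t for t in frame.index if name in t]
        if len(matches) == 1:
            return frame.loc[matches[0]]
        raise KeyError(
            f"term {name!r} not found (have {list(frame.index)})"
        )


def _check_rank(exog: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name the columns involved in the deficiency
        r = np.linalg.qr(exog, mode="r")
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise FitError(f"design matrix rank deficient; collinear terms: {bad}")


def fit_logistic(
    df: pd.DataFrame,
    terms: list[str] | tuple[str, ...] = (),
    outcome: str = "retinopathy",
    subset: pd.Series | np.ndarray | None = None,
    require_se: bool = True,
) -> FitResult:
    """Maximum-likelihood logistic fit of ``outcome`` on patsy ``terms``.

    Rows with missing values in any used variable are dropped (explicit
    "Missing" factor levels keep rows in).  Separation and non-convergence
    raise :class:`FitError`, never pass silently.

    ``require_se=False`` accepts a fit whose likelihood is maximised but
    whose covariance is singular (a weakly identified nuisance cell); such
    fits are valid inputs to likelihood-ratio tests only.
    """
    data = df if subset is None else df.loc[np.asarray(subset, dtype=bool)]
    rhs = " + ".join(terms) if terms else "1"
    formula = f"{outcome} ~ {rhs}"
    try:
        model = smf.logit(formula, data=data)
    except Exception as e:  # patsy errors on bad terms
        raise FitError(f"could not build design for {formula!r}: {e}") from e
    names = list(model.exog_names)
    _check_rank(model.exog, names)
    import warnings as _warnings
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    def _fit(method, **kw):
        with _warnings.catch_warnings(record=True) as rec:
            _warnings.simplefilter("always")
            r = model.fit(method=method, disp=0, **kw)
        if any(issubclass(w.category, PerfectSeparationWarning) for w in rec):
            raise FitError(f"perfect separation in {formula!r}")
        return r

    try:
        res = _fit("newton", tol=1e-10, maxiter=200)
    except PerfectSeparationError as e:
        raise FitError(f"perfect separation in {formula!r}") from e
    except np.linalg.LinAlgError:
        # Newton overshoot through a near-singular Hessian; quasi-Newton is
        # slower but robust, and the score-norm contract below still applies
        try:
            res = _fit("lbfgs", maxiter=2000)
        except (np.linalg.LinAlgError, PerfectSeparationError) as e:
            raise FitError(f"singular Hessian in {formula!r}") from e
    # convergence contract: score norm at the estimate below tolerance.
    # statsmodels' parameter-change criterion can flag quasi-separated
    # nuisance cells (e.g. a zero-event "Missing" level) whose coefficient
    # drifts to -inf while the likelihood is maximised in every identified
    # direction; those fits are valid and kept, with a logged warning.
    score_norm = float(np.max(np.abs(model.score(res.params))))
    if not res.mle_retvals.get("converged", False):
        # scale: the score is a sum over n observations
        if score_norm > 1e-6 * max(1.0, model.endog.shape[0]):
            raise FitError(
                f"no convergence for {formula!r} (score norm {score_norm:.2e})"
            )
        drifting = [t for t, b in zip(names, res.params) if abs(b) > 15]
        logger.info(
            "quasi-separated level(s) %s in %r; coefficients unbounded but "
            "likelihood converged", drifting, formula,
        )
    if require_se and not np.all(np.isfinite(res.bse)):
        raise FitError(f"non-finite standard errors for {formula!r} (separation?)")
    return FitResult(
        terms=names,
        params=res.params.to_numpy(),
        bse=res.bse.to_numpy(),
        cov=np.asarray(res.cov_params()),
        loglik=float(res.llf),
        n=int(res.nobs),
        formula=formula,
    )


def lrt(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits → (statistic, df, p)."""
    stat = 2.0 * (full.loglik - reduced.loglik)
    df = len(full.terms) - len(reduced.terms)
    if df <= 0:
        raise ValueError("models are not nested (df <= 0)")
    stat = max(stat, 0.0)
    return stat, df, float(st.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# descriptives

def descriptive_table(
    df: pd.DataFrame,
    group_by: str = "retinopathy",
    continuous: list[str] = (),
    categorical: list[str] = (),
    missing_label: str = "Missing",
) -> pd.DataFrame:
    """Two-group descriptive table with tests.

    Continuous rows: ``mean ± SD`` per group, Student's (pooled-variance)
    t-test.  Categorical rows: ``count (column %)`` per group, Pearson
    chi-square without continuity correction; the ``missing_label`` level is
    displayed but excluded from the test, and levels with zero total count
    are dropped with a logged warning.
    """
    g = df[group_by]
    levels = sorted(pd.unique(g.dropna()))
    if len(levels) != 2:
        raise ValueError(f"{group_by!r} must have exactly 2 levels, got {levels}")
    g0, g1 = (df[g == lv] for lv in levels)
    rows = []
    for var in continuous:
        a, b = g0[var].dropna(), g1[var].dropna()
        _, p = st.ttest_ind(a, b, equal_var=True)
        rows.append(
            {
                "variable": var,
                "level": "",
                f"{group_by}={levels[0]}": f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                f"{group_by}={levels[1]}": f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
                "p": p,
            }
        )
    for var in categorical:
        counts = pd.crosstab(df[var], g, dropna=False)
        counts = counts.reindex(columns=levels, fill_value=0)
        counts = counts.loc[counts.index.notna()]
        zero = counts.sum(axis=1) == 0
        if zero.any():
            logger.warning(
                "descriptive_table: dropping empty level(s) %s of %r",
                list(counts.index[zero]), var,
            )
            counts = counts.loc[~zero]
        tested = counts.loc[[ix for ix in counts.index if ix != missing_label]]
        if tested.shape[0] >= 2 and (tested.to_numpy().sum(axis=0) > 0).all():
            chi2, p, _, _ = st.chi2_contingency(tested.to_numpy(), correction=False)
        else:
            p = np.nan
        totals = counts.sum(axis=0)
        first = True
        for lv in counts.index:
            row = {"variable": var, "level": str(lv), "p": p if first else np.nan}
            for col in levels:
                c = counts.loc[lv, col]
                pct = 100.0 * c / totals[col] if totals[col] else 0.0
                row[f"{group_by}={col}"] = f"{c} ({pct:.2f}%)"
            rows.append(row)
            first = False
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subgroups

@dataclass
class SubgroupTable:
    """Per-stratum crude exposure fits plus per-grouping interaction p."""

    rows: pd.DataFrame
    interaction_p: dict[str, float]
    fits: dict[tuple[str, str], FitResult] = field(default_factory=dict)


def subgroup_analysis(
    df: pd.DataFrame,
    groupings: list[str],
    exposure: str = "edii",
    outcome: str = "retinopathy",
    min_events: int = 10,
) -> SubgroupTable:
    """Crude per-stratum fits and joint-product-term interaction LRTs.

    For each grouping variable, every stratum gets a crude
    ``outcome ~ exposure`` fit (strata with fewer than ``min_events`` events
    are flagged unstable but still reported); heterogeneity is tested by a
    likelihood-ratio comparison of pooled models with and without all
    exposure × stratum product terms (df = levels − 1).
    """
    rows = []
    inter: dict[str, float] = {}
    fits: dict[tuple[str, str], FitResult] = {}
    for g in groupings:
        sub = df[df[g].notna() & df[exposure].notna() & df[outcome].notna()]
        levels = list(pd.unique(sub[g]))
        if len(levels) < 2:
            raise ValueError(f"grouping {g!r} has fewer than 2 non-empty strata")
        # deterministic order: natural sort with Missing last
        levels = sorted(levels, key=lambda v: (str(v) == "Missing", str(v)))
        for lv in levels:
            s = sub[sub[g] == lv]
            n_events = int(s[outcome].sum())
            entry = {
                "grouping": g,
                "stratum": str(lv),
                "n": len(s),
                "events": n_events,
                "unstable": n_events < min_events,
            }
            try:
                fr = fit_logistic(s, [exposure], outcome=outcome)
                t = fr.term(exposure)
                entry.update(
                    OR=t["OR"], ci_low=t["ci_low"], ci_high=t["ci_high"], p=t["p"]
                )
                fits[(g, str(lv))] = fr
            except FitError as e:
                logger.warning("subgroup %s=%s: %s", g, lv, e)
                entry.update(OR=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan)
                entry["unstable"] = True
            rows.append(entry)
        full = fit_logistic(
            sub, [exposure, f"C({g})", f"{exposure}:C({g})"], outcome,
            require_se=False,
        )
        red = fit_logistic(sub, [exposure, f"C({g})"], outcome, require_se=False)
        _, lrt_df, p = lrt(full, red)
        assert lrt_df == len(levels) - 1
        inter[g] = p
    return SubgroupTable(rows=pd.DataFrame(rows), interaction_p=inter, fits=fits)


# ---------------------------------------------------------------------------
# tertiles and the model ladder

@dataclass
class TertileAssignment:
    cuts: tuple[float, float]
    tertile: pd.Series  # values in {1, 2, 3}


def assign_tertiles(values: pd.Series) -> TertileAssignment:
    """Total-sample tertiles: cuts at the 1/3 and 2/3 quantiles.

    Ties at a cut point go to the lower tertile.  Requires at least three
    distinct non-missing values.
    """
    v = pd.Series(values).dropna()
    if v.nunique() < 3:
        raise ValueError("need at least 3 distinct values for tertiles")
    c1, c2 = np.quantile(v.to_numpy(dtype=float), [1 / 3, 2 / 3])
    x = pd.Series(values, dtype=float)
    t = 1 + (x > c1).astype(int) + (x > c2).astype(int)
    t = t.where(x.notna())
    return TertileAssignment(cuts=(float(c1), float(c2)), tertile=t)


#: Covariate blocks of the adjustment ladder.
MODEL_I_TERMS = ["age", "C(gender)", "C(race)"]
MODEL_II_EXTRA = ["C(education)", "C(marital)", "C(pir_band)", "C(smoking)", "C(bmi_cat)"]
MODEL_III_EXTRA = ["C(hypertension)", "C(high_cholesterol)"]


def ladder_terms(drop_age: bool = False) -> dict[str, list[str]]:
    """Adjustment sets: Unadjusted ⊂ Model I ⊂ Model II ⊂ Model III.

    ``drop_age`` removes the age term from every model, for ladders run
    within an age-defined subset.
    """
    m1 = [t for t in MODEL_I_TERMS if not (drop_age and t == "age")]
    return {
        "unadjusted": [],
        "model_i": m1,
        "model_ii": m1 + MODEL_II_EXTRA,
        "model_iii": m1 + MODEL_II_EXTRA + MODEL_III_EXTRA,
    }


@dataclass
class LadderResult:
    """Per-model continuous and tertile fits plus the trend p-value."""

    models: dict[str, dict]
    cuts: tuple[float, float]

    def frame(self, exposure: str = "edii") -> pd.DataFrame:
        """Publication-style summary: per-unit OR, tertile ORs, P for trend."""
        rows = []
        for name, m in self.models.items():
            cont = m["continuous"].term(exposure)
            t2 = m["tertiles"].term("C(tertile, Treatment(1))[T.2]")
            t3 = m["tertiles"].term("C(tertile, Treatment(1))[T.3]")
            rows.append(
                {
                    "model": name,
                    "per_unit_OR": cont["OR"],
                    "per_unit_ci": (cont["ci_low"], cont["ci_high"]),
                    "T2_OR": t2["OR"],
                    "T2_ci": (t2["ci_low"], t2["ci_high"]),
                    "T3_OR": t3["OR"],
                    "T3_ci": (t3["ci_low"], t3["ci_high"]),
                    "p_trend": m["p_trend"],
                }
            )
        return pd.DataFrame(rows).set_index("model")


def model_ladder(
    df: pd.DataFrame,
    subset: pd.Series | np.ndarray | None = None,
    exposure: str = "edii",
    outcome: str = "retinopathy",
    drop_age: bool = False,
) -> LadderResult:
    """Fit the four-model adjustment ladder on a subset of the cohort.

    Tertile cut points come from the exposure distribution of the TOTAL
    analyzed sample (``df``), not the subset, so subgroup ladders share the
    same categories.  Each model is fitted with the exposure (a) continuous,
    (b) as tertile indicators against the lowest tertile, and (c) as the
    ordinal tertile index 1/2/3, whose Wald p is the P for trend.
    """
    ta = assign_tertiles(df[exposure])
    work = df.copy()
    work["tertile"] = ta.tertile
    if subset is not None:
        work = work.loc[np.asarray(subset, dtype=bool)]
    work = work[work["tertile"].notna()].copy()
    work["tertile"] = work["tertile"].astype(int)
    models: dict[str, dict] = {}
    for name, covs in ladder_terms(drop_age=drop_age).items():
        cont = fit_logistic(work, [exposure, *covs], outcome=outcome)
        tert = fit_logistic(
            work, ["C(tertile, Treatment(1))", *covs], outcome=outcome
        )
        trend_fit = fit_logistic(work, ["tertile", *covs], outcome=outcome)
        p_trend = float(trend_fit.term("tertile")["p"])
        models[name] = {
            "continuous": cont,
            "tertiles": tert,
            "trend": trend_fit,
            "p_trend": p_trend,
            "covariates": covs,
        }
    return LadderResult(models=models, cuts=ta.cuts)
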