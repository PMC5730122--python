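"""Cohort-level statistics: correlations, standardized regression, GEE.

Implements the tabular analysis of the study: univariate Pearson
correlations between regional cortical thickness and candidate predictors
(age, hypertension, diabetes, hemispheral and regional GM CBF, WMH volume)
per region and side; a multiple linear regression on the predictors that
pass univariate screening at p <= 0.05, reporting standardized
coefficients; and a generalized estimating equation for thickness pooling
the two hemispheres of each subject (identity link, Gaussian family,
exchangeable working correlation, robust sandwich standard errors).

All analyses are complete-case: rows flagged with missing ASL-derived
fields are excluded from every CBF-involving fit, never silently imputed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import CollinearityError, DegenerateInputError
from .io import ASL_COLUMNS
from .roi import asymmetry_count, paired_t

__all__ = [
    "CorrelationResult",
    "RegressionResultStd",
    "GEEResult",
    "pearson",
    "variable_screen",
    "fit_ols_standardized",
    "make_long",
    "fit_gee_thickness",
    "stats_report",
]

#: Candidate predictors of regional cortical thickness (Table-1 rows).
SCREEN_CANDIDATES = ["age", "htn", "dm", "hcbf", "rcbf", "hwmh"]


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass
class RegressionResultStd:
    """Standardized OLS: per-predictor standardized beta and p-value."""

    outcome: str
    beta: dict[str, float]
    p: dict[str, float]
    n: int


@dataclass
class GEEResult:
    """Marginal (GEE) linear model with subject clustering."""

    outcome: str
    coef: dict[str, float]
    robust_se: dict[str, float]
    p: dict[str, float]
    working_correlation: str
    n_subjects: int
    n_rows: int


def _complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with two-sided p from the t distribution."""
    x, y = _complete(x, y)
    n = x.size
    if n < 3:
        raise DegenerateInputError(f"pearson requires >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("pearson is undefined for a constant input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def variable_screen(table: pd.DataFrame, outcome: str, candidates, alpha: float = 0.05):
    """Candidates whose univariate Pearson p-value against `outcome` is <= alpha."""
    selected = []
    for cand in candidates:
        res = pearson(table[cand], table[outcome])
        if res.p <= alpha:
            selected.append(cand)
    return selected


def _zscore(a: np.ndarray) -> np.ndarray:
    return (a - a.mean()) / a.std(ddof=1)


def fit_ols_standardized(table: pd.DataFrame, outcome: str, predictors) -> RegressionResultStd:
    """OLS of the z-scored outcome on z-scored predictors.

    The coefficients are standardized betas (invariant to affine rescaling
    of any predictor); p-values are classical two-sided t-tests.  A single
    predictor's standardized beta equals its Pearson r with the outcome.
    """
    predictors = list(predictors)
    sub = table[[outcome] + predictors].dropna()
    n = len(sub)
    if n < len(predictors) + 2:
        raise DegenerateInputError(
            f"need >= {len(predictors) + 2} complete cases for {len(predictors)} predictors, got {n}"
        )
    Xz = np.column_stack([_zscore(sub[p].to_numpy(dtype=np.float64)) for p in predictors])
    if not np.all(np.isfinite(Xz)):
        bad = [p for p in predictors if sub[p].std(ddof=1) == 0]
        raise DegenerateInputError(f"constant predictor(s): {bad}")
    if np.linalg.cond(Xz) > 1e8:
        corr = np.corrcoef(Xz, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise CollinearityError(
            f"collinear predictors: {predictors[i]!r} and {predictors[j]!r}"
        )
    yz = _zscore(sub[outcome].to_numpy(dtype=np.float64))
    fit = sm.OLS(yz, sm.add_constant(Xz)).fit()
    return RegressionResultStd(
        outcome=outcome,
        beta={p: float(b) for p, b in zip(predictors, fit.params[1:])},
        p={p: float(v) for p, v in zip(predictors, fit.pvalues[1:])},
        n=n,
    )


def make_long(table: pd.DataFrame, region: str = "M1") -> pd.DataFrame:
    """Two-rows-per-subject long format for the GEE (occluded/unoccluded).

    Columns: subject_id, thickness (outcome), rcbf, age, side_occ (1 on the
    occluded row), collateral (3-level, 'unknown' kept as a category),
    occlusion_complete.
    """
    reg = region.lower()
    rows = []
    for side, flag in (("occ", 1), ("unocc", 0)):
        part = pd.DataFrame(
            {
                "subject_id": table["subject_id"],
                "thickness": table[f"{reg}_thick_{side}"],
                "rcbf": table[f"{reg}_cbf_{side}"],
                "age": table["age"],
                "side_occ": flag,
                "collateral": table["collateral"],
                "occlusion_complete": table["occlusion_complete"],
            }
        )
        rows.append(part)
    long = pd.concat(rows, ignore_index=True).dropna()
    counts = long["subject_id"].value_counts()
    bad = counts[counts != 2]
    if len(bad):
        raise DegenerateInputError(
            f"GEE long table requires exactly 2 rows per subject; offending: {list(bad.index)}"
        )
    return long.sort_values(["subject_id", "side_occ"]).reset_index(drop=True)


def fit_gee_thickness(
    long_table: pd.DataFrame,
    covariates=("rcbf", "age", "side_occ", "collateral", "occlusion_complete"),
    working_correlation: str = "exchangeable",
) -> GEEResult:
    """Marginal linear GEE for cortical thickness with subject clusters.

    Identity link, Gaussian family; working correlation 'exchangeable'
    (default) or 'independence'; inference uses robust sandwich standard
    errors.  Categorical covariates (``collateral``) are dummy-coded.
    """
    counts = long_table.groupby("subject_id").size()
    if (counts != 2).any() and working_correlation != "independence":
        raise DegenerateInputError("each subject must contribute exactly 2 rows")
    terms = []
    for c in covariates:
        terms.append(f"C({c})" if long_table[c].dtype == object else c)
    formula = "thickness ~ " + " + ".join(terms)
    cov = {"exchangeable": sm.cov_struct.Exchangeable, "independence": sm.cov_struct.Independence}[
        working_correlation
    ]()
    model = sm.GEE.from_formula(
        formula,
        groups="subject_id",
        data=long_table,
        family=sm.families.Gaussian(),
        cov_struct=cov,
    )
    fit = model.fit()
    names = list(fit.model.exog_names)
    return GEEResult(
        outcome="thickness",
        coef={k: float(v) for k, v in zip(names, fit.params)},
        robust_se={k: float(v) for k, v in zip(names, fit.bse)},
        p={k: float(v) for k, v in zip(names, fit.pvalues)},
        working_correlation=working_correlation,
        n_subjects=int(long_table["subject_id"].nunique()),
        n_rows=int(len(long_table)),
    )


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------


def _side_frame(table: pd.DataFrame, region: str, side: str) -> pd.DataFrame:
    """Per-region-side analysis frame with generic candidate column names."""
    reg = region.lower()
    return pd.DataFrame(
        {
            "thickness": table[f"{reg}_thick_{side}"],
            "age": table["age"],
            "htn": table["htn"],
            "dm": table["dm"],
            "hcbf": table[f"h_cbf_{side}"],
            "rcbf": table[f"{reg}_cbf_{side}"],
            "hwmh": table[f"wmh_{side}"],
        }
    )


def stats_report(table: pd.DataFrame, screen_alpha: float = 0.05) -> dict:
    """Full cohort statistics report as a JSON-serializable dict.

    Blocks: paired hemispheric comparisons (CBF and thickness per region,
    Bonferroni over the two regions), per-region-side univariate
    correlations, screened standardized multiple regression, asymmetry
    direction counts, and per-region GEEs.  Deterministic for a fixed
    input table.
    """
    if "asl_missing" in table.columns:
        missing = table["asl_missing"].astype(bool)
    else:
        present = [c for c in ASL_COLUMNS if c in table.columns]
        missing = table[present].isna().any(axis=1)
    complete = table.loc[~missing].reset_index(drop=True)
    report: dict = {
        "n_total": int(len(table)),
        "n_complete": int(len(complete)),
    }

    paired = {}
    for region in ("M1", "V1"):
        reg = region.lower()
        for quantity, stem in (("cbf", f"{reg}_cbf"), ("thickness", f"{reg}_thick")):
            res = paired_t(complete[f"{stem}_occ"], complete[f"{stem}_unocc"], bonferroni_m=2)
            paired[f"{region}_{quantity}"] = {
                "mean_occ": res.mean_a,
                "mean_unocc": res.mean_b,
                "t": res.t_statistic,
                "df": res.df,
                "p": res.p_two_sided,
                "significant": res.significant_after_bonferroni,
            }
    report["paired"] = paired

    count, percent = asymmetry_count(complete, "M1")
    report["asymmetry"] = {"region": "M1", "n_expected_direction": count,
                           "n": int(len(complete)), "percent": percent}

    correlations: dict = {}
    regressions: dict = {}
    for region in ("M1", "V1"):
        for side in ("occ", "unocc"):
            frame = _side_frame(complete, region, side).dropna()
            key = f"{region}_{side}"
            correlations[key] = {
                cand: vars(pearson(frame[cand], frame["thickness"]))
                for cand in SCREEN_CANDIDATES
            }
            selected = variable_screen(frame, "thickness", SCREEN_CANDIDATES, screen_alpha)
            if selected:
                fit = fit_ols_standardized(frame, "thickness", selected)
                regressions[key] = {
                    "predictors": selected,
                    "beta_std": fit.beta,
                    "p": fit.p,
                    "n": fit.n,
                }
            else:
                regressions[key] = {"predictors": [], "beta_std": {}, "p": {}, "n": int(len(frame))}
    report["correlations"] = correlations
    report["regressions"] = regressions

    gee = {}
    for region in ("M1", "V1"):
        res = fit_gee_thickness(make_long(complete, region))
        gee[region] = {
            "coef": res.coef,
            "robust_se": res.robust_se,
            "p": res.p,
            "working_correlation": res.working_correlation,
            "n_subjects": res.n_subjects,
            "n_rows": res.n_rows,
        }
    report["gee"] = gee
    return report
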