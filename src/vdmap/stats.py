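"""Vasculature vs. cortical thickness statistics.

Two layers:

* **group tests with data-driven selection** — given per-category thickness
  samples, normality (Shapiro-Wilk) and homoscedasticity (median-centered
  Levene) checks pick among paired/unpaired t-test, one-way ANOVA, Welch
  ANOVA, and the Kruskal-Wallis H-test;
* **OLS model comparison** — a full model ``thickness ~ age + sex +
  vascular category`` against the reduced covariate-only model
  ``thickness ~ age + sex``. Coefficient inference uses HC3 robust standard
  errors; the full-vs-reduced comparison is the partial F-test on residual
  sums of squares; both models report adjusted R². For plotting-style group
  summaries, thickness is covariate-adjusted by adding the reduced model's
  residuals to its intercept, which removes linear age/sex effects while
  preserving the baseline level.

Hemispheres are treated as independent observations; within-subject
correlation between the two hemispheres is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "ModelSpec",
    "FitResult",
    "ModelComparison",
    "GroupTestResult",
    "select_group_test",
    "fit_model",
    "compare_models",
    "adjust_thickness",
]

NORMALITY_ALPHA = 0.05
HOMOSCEDASTICITY_ALPHA = 0.05


@dataclass(frozen=True)
class GroupTestResult:
    test: str
    statistic: float
    pvalue: float


def select_group_test(
    groups: Sequence[Sequence[float]], paired: bool = False
) -> GroupTestResult:
    """Pick and run the appropriate test for a categorical predictor.

    Decision rule: Shapiro-Wilk per group at alpha 0.05 for normality and
    median-centered Levene at alpha 0.05 for equal variances. All groups
    normal and homoscedastic -> t-test (2 groups, paired if requested) or
    one-way ANOVA; normal but heteroscedastic -> Welch t-test / Welch
    ANOVA; any non-normal group -> Kruskal-Wallis H-test.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 3 for g in samples):
        raise ValueError("every group needs at least 3 observations")
    if paired and (len(samples) != 2 or len(samples[0]) != len(samples[1])):
        raise ValueError("paired testing requires two equal-length groups")

    normal = all(sps.shapiro(g).pvalue >= NORMALITY_ALPHA for g in samples)
    homoscedastic = (
        sps.levene(*samples, center="median").pvalue >= HOMOSCEDASTICITY_ALPHA
    )

    if not normal:
        stat, p = sps.kruskal(*samples)
        return GroupTestResult("kruskal-wallis", float(stat), float(p))
    if len(samples) == 2:
        if paired:
            res = sps.ttest_rel(samples[0], samples[1])
            return GroupTestResult("paired t-test", float(res.statistic), float(res.pvalue))
        res = sps.ttest_ind(samples[0], samples[1], equal_var=homoscedastic)
        name = "t-test" if homoscedastic else "welch t-test"
        return GroupTestResult(name, float(res.statistic), float(res.pvalue))
    if homoscedastic:
        stat, p = sps.f_oneway(*samples)
        return GroupTestResult("one-way anova", float(stat), float(p))
    # Welch's heteroscedasticity-robust one-way ANOVA
    import pingouin as pg

    long = pd.DataFrame(
        {
            "value": np.concatenate(samples),
            "group": np.repeat(np.arange(len(samples)), [len(g) for g in samples]),
        }
    )
    row = pg.welch_anova(data=long, dv="value", between="group").iloc[0]
    p_col = "p_unc" if "p_unc" in row.index else "p-unc"
    return GroupTestResult("welch anova", float(row["F"]), float(row[p_col]))


@dataclass(frozen=True)
class ModelSpec:
    """OLS model layout: response, linear covariates, optional vascular term.

    Categorical variables use treatment coding; reference levels default to
    female sex, the 3-vessel pattern, and the equal-contribution dominance
    category, so coefficients read as contrasts against those baselines.
    """

    response: str = "thickness_mm"
    covariates: tuple[str, ...] = ("age", "sex")
    vascular: str | None = None
    references: dict[str, str] = field(
        default_factory=lambda: {
            "sex": "female",
            "n_vessels": "3",
            "aca_vdom": "equal",
            "mca_vdom": "equal",
        }
    )
    categorical: tuple[str, ...] = ("sex",)

    def formula(self) -> str:
        terms = []
        for cov in self.covariates:
            terms.append(self._term(cov))
        if self.vascular is not None:
            terms.append(self._term(self.vascular, force_categorical=True))
        return f"{self.response} ~ " + (" + ".join(terms) if terms else "1")

    def _term(self, name: str, force_categorical: bool = False) -> str:
        if force_categorical or name in self.categorical:
            ref = self.references.get(name)
            if ref is not None:
                return f"C({name}, Treatment('{ref}'))"
            return f"C({name})"
        return name


@dataclass
class FitResult:
    """OLS fit summary: HC3-based coefficient table plus fit diagnostics."""

    coefficients: pd.DataFrame  # index term; columns estimate, se_hc3, pvalue
    adj_r2: float
    n: int
    rss: float
    df_resid: float
    resid: np.ndarray
    intercept: float
    terms: tuple[str, ...]
    spec: ModelSpec


@dataclass(frozen=True)
class ModelComparison:
    f_statistic: float
    df_num: int
    df_den: int
    pvalue: float
    adj_r2_full: float
    adj_r2_reduced: float


def _check_full_rank(model) -> None:
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # pivoted QR exposes which columns are linear combinations of others
        from scipy.linalg import qr

        _, r, piv = qr(exog, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(exog.shape) * np.finfo(float).eps
        aliased = [model.exog_names[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        aliased += [model.exog_names[p] for p in piv[len(diag):]]
        raise ValueError(f"design matrix is rank deficient; aliased terms: {aliased}")


def fit_model(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit an OLS model with HC3 robust standard errors.

    The vascular term (if any) must be categorical with at least two
    observed levels; a rank-deficient design raises with the aliased terms
    named rather than silently dropping them.
    """
    data = table.copy()
    if spec.vascular is not None:
        data[spec.vascular] = data[spec.vascular].astype(str)
        levels = data[spec.vascular].nunique()
        if levels < 2:
            raise ValueError(
                f"vascular term {spec.vascular!r} has {levels} observed level(s); "
                "need >= 2"
            )
    model = smf.ols(spec.formula(), data=data)
    _check_full_rank(model)
    if model.exog.shape[0] <= model.exog.shape[1]:
        raise ValueError("more parameters than observations")
    fit = model.fit(cov_type="HC3")
    coefficients = pd.DataFrame(
        {
            "estimate": fit.params,
            "se_hc3": fit.bse,
            "pvalue": fit.pvalues,
        }
    )
    return FitResult(
        coefficients=coefficients,
        adj_r2=float(fit.rsquared_adj),
        n=int(fit.nobs),
        rss=float(fit.ssr),
        df_resid=float(fit.df_resid),
        resid=np.asarray(fit.resid, dtype=float),
        intercept=float(fit.params["Intercept"]),
        terms=tuple(model.exog_names),
        spec=spec,
    )


def compare_models(full: FitResult, reduced: FitResult) -> ModelComparison:
    """Partial F-test of a full against a nested reduced model.

    F = ((RSS_r - RSS_f) / Δdf) / (RSS_f / df_f), with the p-value from the
    F(Δdf, df_f) distribution. Identical models return F = 0, p = 1.
    """
    if full.n != reduced.n:
        raise ValueError("models were fitted on different numbers of rows")
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError(
            "models are not nested: reduced terms "
            f"{sorted(set(reduced.terms) - set(full.terms))} absent from full model"
        )
    df_num = int(round(reduced.df_resid - full.df_resid))
    df_den = int(round(full.df_resid))
    if df_num == 0:
        return ModelComparison(0.0, 0, df_den, 1.0, full.adj_r2, reduced.adj_r2)
    f_stat = ((reduced.rss - full.rss) / df_num) / (full.rss / df_den)
    f_stat = max(float(f_stat), 0.0)
    pvalue = float(sps.f.sf(f_stat, df_num, df_den))
    return ModelComparison(f_stat, df_num, df_den, pvalue, full.adj_r2, reduced.adj_r2)


def adjust_thickness(table: pd.DataFrame, reduced: FitResult) -> pd.Series:
    """Covariate-adjusted thickness: reduced-model intercept plus residuals.

    Removes the fitted linear age/sex effects while keeping values on the
    baseline thickness scale; the adjusted mean equals the intercept.
    """
    if len(table) != len(reduced.resid):
        raise ValueError("fit residuals do not match the table rows")
    return pd.Series(
        reduced.intercept + reduced.resid, index=table.index, name="thickness_adj_mm"
    )
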