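"""Inference for the quantified perfusion and morphometry outputs.

Paired t-tests with Bonferroni correction for fractured-vs-intact limb
comparisons, one-way ANOVA with Fisher's LSD post hoc for time-point
comparisons, Spearman rank correlation for operator-repeatability studies,
and a random-intercept mixed-effects growth model of perfusion against time
(linear or quadratic) with likelihood-ratio model comparison.

The mixed model is fitted by maximum likelihood (not REML) so that
likelihood-ratio tests between nested fixed-effect structures are valid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf


class ConvergenceError(RuntimeError):
    """Raised when the mixed-model optimiser fails to converge."""


# ---------------------------------------------------------------------------
# paired t with Bonferroni
# ---------------------------------------------------------------------------

@dataclass
class PairedTResult:
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    m: int
    mean_difference: float
    degenerate: bool = False  # zero variance of the paired differences


def paired_t_bonferroni(
    x: Sequence[float], y: Sequence[float], m: int = 1
) -> PairedTResult:
    """Paired Student's t-test with Bonferroni adjustment.

    t = mean(d) / (sd(d)/sqrt(n)) on differences d = x - y with df = n - 1;
    the adjusted p-value is min(1, m * p_raw) for a family of ``m``
    comparisons. ``m`` is always explicit — it is never inferred.

    Degenerate differences (zero sample variance) are flagged: identical
    pairs give t = 0, p = 1; a constant nonzero difference gives an
    infinite t (an exact difference) with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    if m < 1:
        raise ValueError("Bonferroni family size m must be >= 1")
    d = x - y
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean_d == 0.0:
            return PairedTResult(0.0, df, 1.0, 1.0, m, 0.0, degenerate=True)
        t = np.inf if mean_d > 0 else -np.inf
        return PairedTResult(float(t), df, 0.0, 0.0, m, mean_d, degenerate=True)
    t = mean_d / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return PairedTResult(
        float(t), df, float(p), float(min(1.0, m * p)), m, mean_d
    )


# ---------------------------------------------------------------------------
# one-way ANOVA with LSD post hoc
# ---------------------------------------------------------------------------

@dataclass
class LSDComparison:
    group_i: int
    group_j: int
    mean_difference: float
    t: float
    df: int
    p: float


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: list[float]
    mse: float
    lsd: list[LSDComparison]


def one_way_anova_lsd(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way ANOVA with Fisher's least-significant-difference post hoc.

    Standard between/within sums-of-squares decomposition. The LSD pairwise
    comparisons are t-tests on the pooled within-group mean square with
    df = N - k and no multiplicity adjustment — that is what LSD means.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ValueError(f"group {i} has n < 2")
    ns = np.array([g.size for g in gs])
    means = np.array([g.mean() for g in gs])
    grand = np.concatenate(gs).mean()
    n_total = int(ns.sum())
    k = len(gs)

    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    df_b, df_w = k - 1, n_total - k
    msb = ss_between / df_b
    mse = ss_within / df_w

    if mse == 0.0:
        F = 0.0 if msb == 0.0 else np.inf
        p = 1.0 if msb == 0.0 else 0.0
    else:
        F = msb / mse
        p = float(sps.f.sf(F, df_b, df_w))

    lsd = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[i] - means[j])
            se = np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0.0:
                t_ij = 0.0 if diff == 0.0 else np.copysign(np.inf, diff)
                p_ij = 1.0 if diff == 0.0 else 0.0
            else:
                t_ij = diff / se
                p_ij = float(2.0 * sps.t.sf(abs(t_ij), df_w))
            lsd.append(LSDComparison(i, j, diff, float(t_ij), df_w, p_ij))

    return AnovaResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=float(p),
        group_means=[float(mu) for mu in means],
        mse=mse,
        lsd=lsd,
    )


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rank correlation: mid-ranks for ties, then Pearson on ranks.

    Returns NaN (with a warning) when either variable has zero rank
    variance, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if x.size < 3:
        raise ValueError("Spearman correlation needs at least 3 observations")
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    if rx.std() == 0.0 or ry.std() == 0.0:
        warnings.warn("zero rank variance: Spearman's rho undefined")
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


# ---------------------------------------------------------------------------
# random-intercept growth model
# ---------------------------------------------------------------------------

@dataclass
class GrowthModelSpec:
    """Specification of the longitudinal perfusion growth model.

    ``time_model`` selects linear (day) or quadratic (day + day²) fixed
    effects of time since operation; ``covariates`` are additional fixed
    regressors aligned by (animal, day), e.g. the matched intact-limb
    measure or body temperature. The grouping factor gets a random
    intercept per animal.
    """

    response: str = "perfusion"
    time: str = "day"
    time_model: str = "quadratic"
    covariates: tuple[str, ...] = ()
    group: str = "animal"

    def __post_init__(self) -> None:
        if self.time_model not in ("linear", "quadratic"):
            raise ValueError("time_model must be 'linear' or 'quadratic'")
        self.covariates = tuple(self.covariates)

    @property
    def fixed_terms(self) -> tuple[str, ...]:
        terms = ("Intercept", self.time)
        if self.time_model == "quadratic":
            terms += (f"I({self.time} ** 2)",)
        return terms + self.covariates

    @property
    def formula(self) -> str:
        rhs = [self.time]
        if self.time_model == "quadratic":
            rhs.append(f"I({self.time} ** 2)")
        rhs.extend(self.covariates)
        return f"{self.response} ~ " + " + ".join(rhs)


@dataclass
class GrowthModelFit:
    """Maximum-likelihood fit of the random-intercept growth model."""

    spec: GrowthModelSpec
    params: pd.Series
    bse: pd.Series
    fixed_effect_tests: pd.DataFrame
    llf: float
    n_params: int
    n_obs: int
    n_groups: int
    residual_var: float
    random_intercept_var: float
    converged: bool
    boundary_variance: bool = False


def fit_growth_model(
    data: pd.DataFrame, spec: GrowthModelSpec | None = None
) -> GrowthModelFit:
    """Fit a random-intercept linear mixed model by maximum likelihood.

    Fixed effects follow ``spec`` (time linear or quadratic plus optional
    covariates); each animal contributes a random intercept. Rows with
    missing values in any model variable are dropped (available-case
    analysis, as the staggered sacrifice schedule implies). Approximate
    F-tests for fixed effects use F = (coef/se)² with 1 numerator df and a
    between–within (containment) denominator df,
    ``n_obs - n_groups - (p_fixed - 1)``, reported as approximate.

    A random-intercept variance estimated at (or numerically on) the
    boundary of zero is flagged, not hidden.
    """
    spec = spec or GrowthModelSpec()
    cols = [spec.response, spec.time, spec.group, *spec.covariates]
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValueError(f"data lacks required columns: {missing_cols}")
    df = data[cols].dropna()
    if df[spec.group].nunique() < 2:
        raise ValueError("need at least 2 groups (animals)")
    if len(df) < 3:
        raise ValueError("need at least 3 observations in total")

    model = smf.mixedlm(spec.formula, df, groups=df[spec.group])
    result = None
    tried = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for opt in ("lbfgs", "bfgs", "cg", "powell"):
            tried.append(opt)
            try:
                candidate = model.fit(reml=False, method=opt)
            except np.linalg.LinAlgError:
                continue
            if candidate.converged:
                result = candidate
                break
            if result is None:
                result = candidate
    if not result.converged:
        # a variance estimate pinned at zero is a boundary solution, not a
        # genuine optimiser failure; accept it flagged
        at_boundary = (
            result.cov_re.size and float(result.cov_re.iloc[0, 0]) <= 1e-6 * float(result.scale)
        )
        if not at_boundary:
            raise ConvergenceError(
                "mixed-model ML fit did not converge with any of "
                f"{tried}; optimiser history: {getattr(model, 'hist', None)!r}"
            )

    fe_names = list(result.fe_params.index)
    n_obs = int(len(df))
    n_groups = int(df[spec.group].nunique())
    p_fixed = len(fe_names)
    df_denom = max(n_obs - n_groups - (p_fixed - 1), 1)

    rows = []
    for name in fe_names:
        coef = float(result.fe_params[name])
        se = float(result.bse_fe[name])
        F = (coef / se) ** 2 if se > 0 else np.inf
        rows.append(
            {
                "term": name,
                "coef": coef,
                "se": se,
                "F": F,
                "df1": 1,
                "df2": df_denom,
                "p": float(sps.f.sf(F, 1, df_denom)),
            }
        )
    tests = pd.DataFrame(rows).set_index("term")

    resid_var = float(result.scale)
    ri_var = float(result.cov_re.iloc[0, 0]) if result.cov_re.size else 0.0
    boundary = ri_var <= 1e-8 * max(resid_var, 1.0)
    if int(df.groupby(spec.group).size().max()) == 1:
        # one observation per animal: tau^2 and sigma^2 are not separately
        # identifiable, so the variance decomposition sits on a ridge/boundary
        boundary = True
    if boundary:
        warnings.warn("random-intercept variance at the zero boundary")

    return GrowthModelFit(
        spec=spec,
        params=result.fe_params.copy(),
        bse=result.bse_fe.copy(),
        fixed_effect_tests=tests,
        llf=float(result.llf),
        n_params=p_fixed + 2,  # fixed effects + intercept var + residual var
        n_obs=n_obs,
        n_groups=n_groups,
        residual_var=resid_var,
        random_intercept_var=ri_var,
        converged=bool(result.converged),
        boundary_variance=bool(boundary),
    )


@dataclass
class LRTResult:
    chi2: float
    df: int
    p: float


def lrt_compare(fit_reduced: GrowthModelFit, fit_full: GrowthModelFit) -> LRTResult:
    """Likelihood-ratio test between nested ML growth-model fits.

    chi² = 2 (ll_full − ll_reduced) with df equal to the difference in
    parameter counts. A slightly negative chi² (numerical noise on nested
    ML fits) is clamped to zero with a warning.
    """
    red = set(fit_reduced.spec.fixed_terms)
    full = set(fit_full.spec.fixed_terms)
    if not red <= full:
        raise ValueError(
            "models are not nested: reduced fixed effects "
            f"{sorted(red - full)} absent from the full model"
        )
    if fit_reduced.n_obs != fit_full.n_obs:
        raise ValueError("fits use different data (observation counts differ)")
    df = fit_full.n_params - fit_reduced.n_params
    if df < 0:
        raise ValueError("full model has fewer parameters than the reduced one")
    chi2 = 2.0 * (fit_full.llf - fit_reduced.llf)
    if chi2 < 0:
        if chi2 < -1e-6 * max(abs(fit_full.llf), 1.0):
            warnings.warn(f"negative LRT statistic {chi2:.3g} clamped to 0")
        chi2 = 0.0
    if df == 0:  # identical models: no evidence either way
        return LRTResult(float(chi2), 0, 1.0 if chi2 == 0.0 else 0.0)
    return LRTResult(float(chi2), int(df), float(sps.chi2.sf(chi2, df)))
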