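"""Ecological summaries, linear-model selection, and sensitivity analysis.

Implements the statistical layer of the iPOC analysis:

* species- and month-binned box-plot summaries of iPOC,
* the share of consumers above an iPOC threshold (default 50%: a stronger
  sea-ice than phytoplankton carbon signature),
* multiple linear regression of iPOC on sampling covariates (month, year,
  latitude, habitat, and the month x habitat interaction), solved exactly
  by QR least squares, with model ranking by AIC,
* an omitted-variable-bias sensitivity analysis (partial R^2 and
  robustness values) for a chosen treatment term, and
* a wraparound month-shift robustness check.

AIC uses the full Gaussian log-likelihood (constants included) and counts
the error variance among the estimated parameters, so values are
comparable to standard statistical software (R's ``AIC`` for ``lm``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ipoc.sample_io import Habitat

# --------------------------------------------------------------------------
# Group summaries (box-plot statistics)
# --------------------------------------------------------------------------

#: Default ordered habitat score used for single-column habitat coding.
#: Ordered by increasing reliance on ice-derived carbon pathways.
DEFAULT_HABITAT_SCORES: dict[str, float] = {
    "pelagic": 0.0,
    "mixed": 1.0,
    "sympagic": 2.0,
    "benthic": 3.0,
}


@dataclass(frozen=True)
class GroupSummary:
    """Box-plot statistics for one group of iPOC values (percent units)."""

    group_key: tuple
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outlier_values: tuple[float, ...] = ()


def summarize_values(
    group_key: tuple, values: Sequence[float], whiskers: str = "tukey"
) -> GroupSummary:
    """Box-plot summary of one group.

    Quartiles use linear interpolation.  ``whiskers`` is ``"tukey"``
    (1.5 x IQR fences, points beyond reported as outliers) or ``"minmax"``
    (whiskers at the extremes, no outliers).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError(f"empty group {group_key}")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    if whiskers == "minmax":
        lo, hi = float(v.min()), float(v.max())
        out: tuple[float, ...] = ()
    elif whiskers == "tukey":
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        lo, hi = float(inside.min()), float(inside.max())
        out = tuple(sorted(float(x) for x in v[(v < lo_fence) | (v > hi_fence)]))
    else:
        raise ValueError(f"unknown whisker convention {whiskers!r}")
    return GroupSummary(
        group_key=group_key,
        n=int(v.size),
        mean=float(v.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=lo,
        whisker_high=hi,
        outlier_values=out,
    )


def _included_frame(results, samples) -> pd.DataFrame:
    """Join results to sample metadata, keeping included samples only."""
    meta = {s.sample_id: s for s in samples}
    rows = []
    for r in results:
        if not r.included:
            continue
        s = meta.get(r.sample_id)
        if s is None:
            raise KeyError(f"result {r.sample_id} has no matching sample")
        rows.append(
            {
                "sample_id": r.sample_id,
                "ipoc_pct": r.ipoc_pct,
                "species": s.species,
                "taxon_group": s.taxon_group.value,
                "habitat": s.habitat.value,
                "month": s.month,
                "year": s.year,
                "latitude": s.latitude,
            }
        )
    return pd.DataFrame(rows)


def species_summary(
    results, samples, whiskers: str = "tukey"
) -> list[GroupSummary]:
    """One box-plot summary per species, ordered within taxon groups."""
    df = _included_frame(results, samples)
    if df.empty:
        raise ValueError("no included results to summarize")
    out = []
    for (taxon, species), grp in df.groupby(
        ["taxon_group", "species"], sort=True
    ):
        out.append(
            summarize_values((taxon, species), grp["ipoc_pct"].values, whiskers)
        )
    return out


def monthly_summary(
    results, samples, whiskers: str = "tukey"
) -> tuple[list[GroupSummary], int]:
    """Month-binned summaries plus the count of samples lacking a month.

    Samples without a recorded month cannot be placed in a bin; they are
    excluded from the summaries and reported in the returned count.
    """
    df = _included_frame(results, samples)
    if df.empty:
        raise ValueError("no included results to summarize")
    missing = int(df["month"].isna().sum())
    df = df.dropna(subset=["month"])
    if df.empty:
        raise ValueError("no included results carry a recorded month")
    out = [
        summarize_values((int(month),), grp["ipoc_pct"].values, whiskers)
        for month, grp in df.groupby("month", sort=True)
    ]
    return out, missing


def proportion_above(
    results, threshold: float = 50.0
) -> tuple[int, float]:
    """Count and share of included samples with iPOC strictly above threshold.

    Strict inequality: a sample at exactly the threshold does not have a
    *stronger* sea-ice than phytoplankton signature.
    """
    if not (0.0 <= threshold <= 100.0):
        raise ValueError(f"threshold must be in [0, 100], got {threshold}")
    vals = [r.ipoc_pct for r in results if r.included]
    if not vals:
        raise ValueError("no included samples")
    count = sum(1 for v in vals if v > threshold)
    return count, count / len(vals)


# --------------------------------------------------------------------------
# Linear models
# --------------------------------------------------------------------------

#: Terms accepted in model formulas.
VALID_TERMS = (
    "month",
    "year",
    "latitude",
    "habitat",
    "species",
    "taxa",
    "month:habitat",
)


@dataclass(frozen=True)
class Encoding:
    """Design-matrix coding options.

    ``habitat_coding`` is ``"score"`` (single ordered-score column, the
    default — matching analyses that report one t-value for habitat) or
    ``"treatment"`` (3 dummy columns against a reference level).
    ``month_coding`` is ``"numeric"`` (1-12 covariate, default) or
    ``"circular"`` (sin/cos pair).
    """

    habitat_coding: str = "score"
    habitat_scores: tuple[tuple[str, float], ...] = tuple(
        DEFAULT_HABITAT_SCORES.items()
    )
    habitat_reference: str = "pelagic"
    month_coding: str = "numeric"

    def score_map(self) -> dict[str, float]:
        return dict(self.habitat_scores)


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


@dataclass(frozen=True)
class ModelFit:
    """An OLS fit of iPOC on a term list.

    ``aic = 2k - 2*loglik`` with ``k`` counting every estimated parameter
    including the error variance; ``t = coef / se`` and two-sided p-values
    come from the t distribution with ``df_residual`` degrees of freedom.
    """

    formula: tuple[str, ...]
    columns: tuple[str, ...]
    coefficients: tuple[float, ...]
    standard_errors: tuple[float, ...]
    t_values: tuple[float, ...]
    p_values: tuple[float, ...]
    nobs: int
    df_residual: int
    rss: float
    log_likelihood: float
    aic: float
    n_params: int  # regression coefficients + error variance
    _y_signature: tuple[float, float] = field(repr=False, default=(0.0, 0.0))

    def coef(self, column: str) -> float:
        return self.coefficients[self.columns.index(column)]

    def se(self, column: str) -> float:
        return self.standard_errors[self.columns.index(column)]

    def t(self, column: str) -> float:
        return self.t_values[self.columns.index(column)]

    def p(self, column: str) -> float:
        return self.p_values[self.columns.index(column)]


def build_design(
    df: pd.DataFrame,
    formula: Sequence[str],
    encoding: Encoding = Encoding(),
) -> tuple[np.ndarray, list[str]]:
    """Build the design matrix (with intercept) for a term list."""
    for term in formula:
        if term not in VALID_TERMS:
            raise ValueError(f"unknown term {term!r}; valid: {VALID_TERMS}")
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]

    def habitat_columns() -> tuple[list[np.ndarray], list[str]]:
        if encoding.habitat_coding == "score":
            scores = encoding.score_map()
            return (
                [df["habitat"].map(scores).to_numpy(dtype=float)],
                ["habitat"],
            )
        if encoding.habitat_coding == "treatment":
            levels = [
                h.value
                for h in Habitat
                if h.value != encoding.habitat_reference
            ]
            arrs = [
                (df["habitat"] == lvl).to_numpy(dtype=float) for lvl in levels
            ]
            return arrs, [f"habitat[{lvl}]" for lvl in levels]
        raise ValueError(f"unknown habitat coding {encoding.habitat_coding!r}")

    def month_columns() -> tuple[list[np.ndarray], list[str]]:
        m = df["month"].to_numpy(dtype=float)
        if encoding.month_coding == "numeric":
            return [m], ["month"]
        if encoding.month_coding == "circular":
            ang = 2 * np.pi * m / 12.0
            return [np.sin(ang), np.cos(ang)], ["month_sin", "month_cos"]
        raise ValueError(f"unknown month coding {encoding.month_coding!r}")

    for term in formula:
        if term == "habitat":
            arrs, nms = habitat_columns()
        elif term == "month":
            arrs, nms = month_columns()
        elif term in ("year", "latitude"):
            arrs, nms = [df[term].to_numpy(dtype=float)], [term]
        elif term in ("species", "taxa"):
            key = "species" if term == "species" else "taxon_group"
            levels = sorted(df[key].unique())[1:]  # first level is reference
            arrs = [(df[key] == lvl).to_numpy(dtype=float) for lvl in levels]
            nms = [f"{term}[{lvl}]" for lvl in levels]
        elif term == "month:habitat":
            marrs, mnames = month_columns()
            harrs, hnames = habitat_columns()
            arrs, nms = [], []
            for ma, mn in zip(marrs, mnames):
                for ha, hn in zip(harrs, hnames):
                    arrs.append(ma * ha)
                    nms.append(f"{mn}:{hn}")
        cols.extend(arrs)
        names.extend(nms)
    return np.column_stack(cols), names


def fit_ols(
    df: pd.DataFrame,
    formula: Sequence[str],
    response: str = "ipoc_pct",
    encoding: Encoding = Encoding(),
) -> ModelFit:
    """Exact least-squares fit of ``response`` on the term list.

    Solves via QR decomposition; requires a full-rank design and
    ``n > k``.  Rows with a missing value in any used column are
    rejected (callers drop e.g. month-less samples first).
    """
    formula = tuple(formula)
    used = {"month" if t == "month:habitat" else t for t in formula}
    for term in sorted(used & {"month", "year", "latitude"}):
        if df[term].isna().any():
            raise ValueError(
                f"column {term!r} contains missing values; drop those rows "
                "before fitting"
            )
    X, names = build_design(df, formula, encoding)
    y = df[response].to_numpy(dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # identify offending columns by QR pivoting on the diagonal of R
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {k}; collinear terms involve: "
            f"{bad or names}"
        )

    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = n - k
    sigma2_hat = rss / df_resid
    Rinv = np.linalg.solve(R, np.eye(k))
    cov = sigma2_hat * (Rinv @ Rinv.T)
    se = np.sqrt(np.diag(cov))
    t_vals = beta / se
    p_vals = 2 * stats.t.sf(np.abs(t_vals), df_resid)

    # Gaussian log-likelihood at the MLE variance rss/n, constants included
    loglik = -0.5 * n * (math.log(2 * math.pi) + math.log(rss / n) + 1.0)
    n_params = k + 1  # + error variance
    aic = 2 * n_params - 2 * loglik
    return ModelFit(
        formula=formula,
        columns=tuple(names),
        coefficients=tuple(float(b) for b in beta),
        standard_errors=tuple(float(s) for s in se),
        t_values=tuple(float(t) for t in t_vals),
        p_values=tuple(float(p) for p in p_vals),
        nobs=n,
        df_residual=df_resid,
        rss=rss,
        log_likelihood=float(loglik),
        aic=float(aic),
        n_params=n_params,
        _y_signature=(float(y.sum()), float((y * y).sum())),
    )


@dataclass(frozen=True)
class RankedModel:
    fit: ModelFit
    delta_aic: float
    rank: int


def compare_models(fits: Sequence[ModelFit]) -> list[RankedModel]:
    """Rank fits by ascending AIC (Delta-AIC relative to the best).

    All fits must be on the identical response vector.  Ties are broken by
    fewer parameters, then by formula lexicographic order.
    """
    if not fits:
        raise ValueError("no fits to compare")
    sig0, n0 = fits[0]._y_signature, fits[0].nobs
    for f in fits[1:]:
        if f.nobs != n0 or not np.allclose(f._y_signature, sig0):
            raise ValueError(
                "models fit on differing response vectors cannot be compared"
            )
    ordered = sorted(fits, key=lambda f: (f.aic, f.n_params, f.formula))
    best = ordered[0].aic
    return [
        RankedModel(fit=f, delta_aic=f.aic - best, rank=i + 1)
        for i, f in enumerate(ordered)
    ]


# --------------------------------------------------------------------------
# Omitted-variable-bias sensitivity analysis
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SensitivityResult:
    """Partial R^2 and robustness values for one treatment column.

    ``robustness_value`` (q = 1, alpha = 1) is the minimal strength of
    association — partial R^2 with both treatment and outcome — an
    unobserved confounder needs to reduce the treatment estimate to zero;
    ``robustness_value_alpha`` is the strength needed merely to make it
    statistically insignificant at the stated alpha.
    """

    treatment_term: str
    partial_r2_outcome: float
    robustness_value: float
    robustness_value_alpha: float
    alpha: float
    q: float
    t_value: float
    df_residual: int


def partial_r2(t: float, df: int) -> float:
    """Partial R^2 of a regressor with the outcome: t^2 / (t^2 + df)."""
    return t * t / (t * t + df)


def _rv_from_f(fq: float, f_crit: float) -> float:
    """Closed-form robustness value for partial Cohen's f_q and critical f."""
    fqa = fq - f_crit
    if fqa < 0:
        return 0.0
    if f_crit > 0 and fq > 0 and f_crit > 1.0 / fq:
        # extreme case: the bound is attained at R^2 with outcome = 1
        return (fq * fq - f_crit * f_crit) / (1.0 + fq * fq)
    if fqa == 0:
        return 0.0
    # algebraically (sqrt(fqa^4 + 4 fqa^2) - fqa^2)/2, written in a form
    # stable for large fqa
    return 2.0 / (math.sqrt(1.0 + 4.0 / (fqa * fqa)) + 1.0)


def robustness_value(
    t: float, df: int, q: float = 1.0, alpha: float = 1.0
) -> float:
    """Robustness value from a treatment t-statistic.

    With partial Cohen's f = |t|/sqrt(df) and f_q = q*f, the q=1, alpha=1
    value is RV_q = (sqrt(f_q^4 + 4 f_q^2) - f_q^2)/2.  For alpha < 1 the
    critical f uses the two-sided alpha-quantile of the t distribution
    with df - 1 degrees of freedom (one lost to the hypothetical
    confounder); the result is floored at 0.
    """
    if df < 2:
        raise ValueError("df_residual must be >= 2")
    f = abs(t) / math.sqrt(df)
    fq = q * f
    if alpha >= 1.0:
        f_crit = 0.0
    else:
        t_crit = abs(stats.t.ppf(alpha / 2, df - 1))
        f_crit = t_crit / math.sqrt(df - 1)
    return _rv_from_f(fq, f_crit)


def sensitivity(
    fit: ModelFit,
    treatment: str,
    q: float = 1.0,
    alpha: float = 0.05,
) -> SensitivityResult:
    """Omitted-variable-bias sensitivity statistics for one design column.

    ``treatment`` names a single column of the fitted design (for score
    habitat coding, simply ``"habitat"``).  Raises ``ValueError`` when the
    treatment's standard error is zero (t undefined).
    """
    if treatment not in fit.columns:
        raise KeyError(
            f"treatment {treatment!r} not among fitted columns {fit.columns}"
        )
    if fit.df_residual < 2:
        raise ValueError("sensitivity requires df_residual >= 2")
    se = fit.se(treatment)
    if se == 0 or not math.isfinite(se):
        raise ValueError(f"treatment {treatment!r} has zero/invalid SE")
    t = fit.t(treatment)
    return SensitivityResult(
        treatment_term=treatment,
        partial_r2_outcome=partial_r2(t, fit.df_residual),
        robustness_value=robustness_value(t, fit.df_residual, q=q, alpha=1.0),
        robustness_value_alpha=robustness_value(
            t, fit.df_residual, q=q, alpha=alpha
        ),
        alpha=alpha,
        q=q,
        t_value=t,
        df_residual=fit.df_residual,
    )


# --------------------------------------------------------------------------
# Month-shift robustness check
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ShiftComparison:
    original: ModelFit
    shifted: ModelFit
    original_sensitivity: SensitivityResult
    shifted_sensitivity: SensitivityResult
    shift: int


def shift_months(months: pd.Series, shift: int) -> pd.Series:
    """Shift month labels by ``shift`` with modular wraparound (Jan-3 -> Oct)."""
    return ((months - 1 + shift) % 12) + 1


def month_shift_check(
    df: pd.DataFrame,
    formula: Sequence[str],
    shift: int = -3,
    treatment: str = "habitat",
    alpha: float = 0.05,
    response: str = "ipoc_pct",
    encoding: Encoding = Encoding(),
) -> ShiftComparison:
    """Refit the model after shifting every observation's month.

    Checks that conclusions (sign and significance of the treatment term)
    do not hinge on the month labels' alignment with the seasonal cycle.
    The formula must contain a month term.
    """
    if not any(t in ("month", "month:habitat") for t in formula):
        raise ValueError("month_shift_check requires a formula with month")
    if df["month"].isna().any():
        raise ValueError("months must be present for all shifted samples")
    base = fit_ols(df, formula, response=response, encoding=encoding)
    shifted_df = df.copy()
    shifted_df["month"] = shift_months(shifted_df["month"], shift)
    alt = fit_ols(shifted_df, formula, response=response, encoding=encoding)
    return ShiftComparison(
        original=base,
        shifted=alt,
        original_sensitivity=sensitivity(base, treatment, alpha=alpha),
        shifted_sensitivity=sensitivity(alt, treatment, alpha=alpha),
        shift=shift,
    )
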