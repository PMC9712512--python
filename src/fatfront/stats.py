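"""Inferential layer: random-intercept linear mixed models, the exact
Wilcoxon signed-rank test, and Bonferroni correction.

Muscles are nested within patients, so muscle-level analyses use linear
mixed models with a random intercept per patient, a variance-components
covariance structure, and REML estimation.  Fixed-effect p-values use the
Wald normal approximation (the grouping structure here has few patients,
so p-values are indicative; estimates and SEs are the primary output).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .dixon import ValidationError

logger = logging.getLogger(__name__)

BONFERRONI_M = 8  # eight baseline-bin contrasts against the 0-10% reference


@dataclass(frozen=True)
class MixedModelResult:
    """Fixed effects with SE/p, variance components and fit metadata."""

    fixed: pd.DataFrame  # index: term; columns: estimate, se, p
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_groups: int
    converged: bool


def _fit_mixedlm(formula: str, data: pd.DataFrame, groups: str) -> MixedModelResult:
    if data[groups].nunique() < 2:
        raise ValidationError("mixed model needs >= 2 patients")
    model = smf.mixedlm(formula, data, groups=data[groups])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    fe = pd.DataFrame({
        "estimate": fit.fe_params,
        "se": fit.bse_fe,
        "p": fit.pvalues.loc[fit.fe_params.index],
    })
    converged = bool(getattr(fit, "converged", True))
    if not converged:
        logger.warning("mixed model did not converge; reporting final iterate")
    return MixedModelResult(
        fixed=fe,
        random_intercept_var=float(np.asarray(fit.cov_re).ravel()[0]),
        residual_var=float(fit.scale),
        n_obs=int(fit.nobs),
        n_groups=int(data[groups].nunique()),
        converged=converged,
    )


def fit_segment_gradient(
    segment_table: pd.DataFrame, subset: str | None = None
) -> MixedModelResult:
    """Proximo-distal gradient model: FF = b0 + b1*segment + patient + e.

    ``segment_table`` needs columns patient, segment (numeric 1..5), ff and
    — when ``subset`` names a Mercuri class — a ``mercuri`` column.  b1 is
    in percent FF per segment; negative means fat declines towards the
    proximal end.
    """
    df = segment_table
    if subset is not None:
        df = df[df["mercuri"] == subset]
        if df.empty:
            raise ValidationError(f"no muscles in Mercuri class {subset!r}")
    if df["segment"].nunique() < 2:
        raise ValidationError("need >= 2 distinct segments")
    df = df.assign(segment=df["segment"].astype(float))
    return _fit_mixedlm("ff ~ segment", df, "patient")


def fit_bin_contrasts(longitudinal: pd.DataFrame, m: int = BONFERRONI_M) -> pd.DataFrame:
    """Yearly-change contrasts of each baseline bin against the 0-10% bin.

    Random-intercept model with baseline bin as a fixed factor
    (reference 0-10).  Returns one row per non-reference bin present, with
    estimate (difference in change/yr vs reference), SE, raw p and
    Bonferroni-adjusted p (m tests, capped at 1).
    """
    df = longitudinal
    required = {"patient", "bin", "change_per_year"}
    if not required.issubset(df.columns):
        raise ValidationError(f"longitudinal table needs columns {sorted(required)}")
    if (df["bin"] == "0-10").sum() == 0:
        raise ValidationError("reference bin 0-10 is empty")
    order = sorted(df["bin"].unique(), key=lambda b: int(b.split("-")[0]))
    df = df.assign(bin=pd.Categorical(df["bin"], categories=order, ordered=True))
    res = _fit_mixedlm("change_per_year ~ C(bin, Treatment(reference='0-10'))", df, "patient")
    rows = []
    for term, row in res.fixed.iterrows():
        if "T." not in term:
            continue
        b = term.split("T.")[-1].rstrip("]")
        rows.append({
            "bin": b,
            "estimate": row["estimate"],
            "se": row["se"],
            "p_raw": row["p"],
            "p_adj": bonferroni(row["p"], m),
        })
    return pd.DataFrame(rows)


def bonferroni(p: float, m: int = BONFERRONI_M) -> float:
    """Bonferroni-adjusted p-value, min(1, m*p)."""
    if not 0 <= p <= 1:
        raise ValidationError(f"p must lie in [0, 1], got {p}")
    return min(1.0, m * p)


def wilcoxon_signed_rank(
    x, y=None, two_sided: bool = True, exact_max_n: int = 25
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired values (or differences).

    Zero differences are dropped (Wilcoxon convention) and ties midranked.
    The exact null distribution is used for n <= ``exact_max_n`` (and no
    tied ranks); larger samples use the normal approximation with
    continuity correction.  Returns (W statistic, p).
    """
    d = np.asarray(x, dtype=float) - (0.0 if y is None else np.asarray(y, dtype=float))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValidationError("all differences are zero; test undefined")
    if n < 5:
        raise ValidationError(f"need >= 5 non-zero differences, got {n}")
    ranks_tied = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= exact_max_n and not ranks_tied) else "approx"
    alternative = "two-sided" if two_sided else "greater"
    res = sps.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"),
        alternative=alternative, method=method,
    )
    return float(res.statistic), float(res.pvalue)


def intercept_only_mixed(
    values: pd.Series | np.ndarray, patients: pd.Series | np.ndarray
) -> MixedModelResult:
    """Intercept-only random-intercept model (e.g. mean absolute error).

    With a single patient there is no between-patient variance to
    estimate; falls back to a one-sample t-test on the values with a
    logged caveat, reported in the same structure.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "patient": np.asarray(patients)})
    if df.empty:
        raise ValidationError("no observations")
    if df["patient"].nunique() < 2:
        logger.warning("single patient: falling back to one-sample t-test")
        y = df["y"].to_numpy()
        est = float(y.mean())
        se = float(y.std(ddof=1) / np.sqrt(len(y))) if len(y) > 1 else np.nan
        t = est / se if se and se > 0 else np.inf
        p = float(2 * sps.t.sf(abs(t), df=len(y) - 1)) if len(y) > 1 else np.nan
        fixed = pd.DataFrame(
            {"estimate": [est], "se": [se], "p": [p]}, index=["Intercept"]
        )
        return MixedModelResult(
            fixed=fixed, random_intercept_var=0.0,
            residual_var=float(y.var(ddof=1)) if len(y) > 1 else 0.0,
            n_obs=len(y), n_groups=1, converged=True,
        )
    return _fit_mixedlm("y ~ 1", df, "patient")
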