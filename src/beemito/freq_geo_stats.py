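"""Lineage frequencies with exact binomial CIs and logistic clines.

Frequency estimation is plain binomial counting per structure string and
per lineage, with exact (Clopper-Pearson) confidence intervals from Beta
quantiles.  The geographic analysis fits a binomial GLM with logit link:
lineage presence ~ latitude + transect, where transect is a two-level
factor (west/east of a demarcation meridian, eastern as reference level),
reporting Wald tests, the model chi-square against the intercept-only
null, and McFadden's pseudo-R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import beta

__all__ = [
    "FrequencyEstimate",
    "LogisticFit",
    "clopper_pearson",
    "lineage_frequencies",
    "frequency_report",
    "fit_logistic",
    "round_half_up",
    "p_value_stars",
]


@dataclass(frozen=True)
class FrequencyEstimate:
    label: str
    k: int
    n: int
    p_hat: float
    ci_low: float
    ci_high: float
    conf: float


@dataclass
class LogisticFit:
    """Binomial-logit GLM fit for lineage presence on latitude and transect."""

    response: str
    coef: dict
    se: dict
    z: dict
    p_values: dict
    model_chi2: float
    model_df: int
    mcfadden_r2: float
    n: int
    separation_flag: bool = False
    estimable: bool = True


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI via Beta quantiles.

    Lower bound is Beta^-1(alpha/2; k, n-k+1) (0 when k=0); upper is
    Beta^-1(1-alpha/2; k+1, n-k) (1 when k=n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if not 0.0 < conf < 1.0:
        raise ValueError("conf must be in (0, 1)")
    alpha = (1.0 - conf) / 2.0
    low = 0.0 if k == 0 else float(beta.ppf(alpha, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1.0 - alpha, k + 1, n - k))
    return low, high


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (0.0005 -> 0.001 at 3 decimals)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


#: lineage aggregate rows emitted alongside per-structure rows
_LINEAGE_ORDER = ("C", "A", "M")


def lineage_frequencies(
    typing: pd.DataFrame,
    conf: float = 0.95,
) -> list[FrequencyEstimate]:
    """Frequency estimates per structure and per lineage.

    ``typing`` needs columns ``structure`` and ``lineage`` (one row per
    sample).  Output holds one row per observed structure plus an
    ``"all <L>"`` aggregate per observed lineage, each with its exact CI.
    """
    if not {"structure", "lineage"} <= set(typing.columns):
        raise ValueError("typing table needs 'structure' and 'lineage' columns")
    n = len(typing)
    out = []
    for lineage in _LINEAGE_ORDER + ("unknown",):
        sub = typing[typing["lineage"] == lineage]
        if sub.empty:
            continue
        for structure, k in sub["structure"].value_counts().sort_index().items():
            lo, hi = clopper_pearson(int(k), n, conf)
            out.append(FrequencyEstimate(structure, int(k), n, k / n, lo, hi, conf))
        lo, hi = clopper_pearson(len(sub), n, conf)
        out.append(
            FrequencyEstimate(f"all {lineage}", len(sub), n, len(sub) / n, lo, hi, conf)
        )
    return out


def frequency_report(estimates: Sequence[FrequencyEstimate]) -> pd.DataFrame:
    """Rounded report: proportions to 3 decimals, percentages to 2 (half-up)."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "label": e.label,
                "k": e.k,
                "n": e.n,
                "p_hat": round_half_up(e.p_hat, 3),
                "ci_low": round_half_up(e.ci_low, 3),
                "ci_high": round_half_up(e.ci_high, 3),
                "percent": round_half_up(100 * e.p_hat, 2),
                "percent_low": round_half_up(100 * e.ci_low, 2),
                "percent_high": round_half_up(100 * e.ci_high, 2),
            }
        )
    return pd.DataFrame(rows)


def p_value_stars(p: float) -> str:
    """Significance bands as commonly printed: ***, **, *, + (0.05-0.1)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "+"
    return ""


def fit_logistic(
    presence: Sequence[int],
    latitude: Sequence[float],
    longitude: Optional[Sequence[float]] = None,
    transect: Optional[Sequence[str]] = None,
    demarcation_lon: float = 20.0,
    response: str = "presence",
) -> LogisticFit:
    """Logistic cline fit: presence ~ latitude + transect(west vs east).

    The transect factor comes either from ``transect`` labels
    ('west'/'east') or from ``longitude`` against ``demarcation_lon``.
    Eastern transect is the reference level, so the reported coefficient
    is western relative to eastern.  Fitting is maximum likelihood by
    IRLS; quasi-perfect separation is flagged rather than raised, and a
    one-class response is returned as non-estimable.
    """
    y = np.asarray(presence, dtype=float)
    lat = np.asarray(latitude, dtype=float)
    if y.shape != lat.shape:
        raise ValueError("presence and latitude must have equal length")
    if len(y) < 10:
        raise ValueError("need n >= 10 observations")
    if transect is not None:
        west = np.asarray([str(t).lower().startswith("w") for t in transect], float)
    elif longitude is not None:
        west = (np.asarray(longitude, dtype=float) < demarcation_lon).astype(float)
    else:
        raise ValueError("provide either longitude or transect labels")

    names = ["intercept", "latitude", "transect_west"]
    if len(set(y.tolist())) < 2:
        return LogisticFit(
            response,
            {k: np.nan for k in names},
            {k: np.nan for k in names},
            {k: np.nan for k in names},
            {k: np.nan for k in names},
            np.nan,
            2,
            np.nan,
            len(y),
            estimable=False,
        )

    has_transect = len(set(west.tolist())) > 1
    if has_transect:
        X = np.column_stack([np.ones_like(y), lat, west])
        used = names
    else:
        # all samples on one side: the factor is unidentifiable, drop it
        X = np.column_stack([np.ones_like(y), lat])
        used = names[:2]
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
        null = sm.GLM(y, np.ones_like(y)[:, None], family=sm.families.Binomial()).fit()
    for w in caught:
        if "separation" in str(w.message).lower() or "converge" in str(w.message).lower():
            separation = True
    fitted = res.predict(X)
    if np.any(fitted < 1e-10) or np.any(fitted > 1 - 1e-10):
        separation = True

    nan = float("nan")
    params = {k: nan for k in names}
    bse = {k: nan for k in names}
    zvals = {k: nan for k in names}
    pvals = {k: nan for k in names}
    params.update(zip(used, res.params))
    bse.update(zip(used, res.bse))
    zvals.update(zip(used, res.params / res.bse))
    pvals.update(zip(used, res.pvalues))
    model_chi2 = float(null.deviance - res.deviance)
    mcfadden = float(1.0 - res.llf / null.llf)
    return LogisticFit(
        response,
        params,
        bse,
        zvals,
        pvals,
        model_chi2,
        len(used) - 1,
        mcfadden,
        len(y),
        separation_flag=separation,
    )
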