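"""Robust outlier screening, the 36-case correlation grid, BH correction and
the minimum-detectable-effect calculator.

Each correlation case pairs a TI aggregate with a TeamSTEPPS score over
sessions (group level) or session-subjects (individual level). Bivariate
outliers are removed per case with the Minimum Covariance Determinant
(FastMCD, 75% support): points whose robust squared Mahalanobis distance
exceeds the chi-square(2 df) quantile at 1 - alpha (alpha = .001, cutoff
~13.816) are dropped. Pearson's r with the exact t reference is computed on
the survivors, and the Benjamini-Hochberg step-up procedure is applied
across the grid's fixed 36 cases (6 scores x 3 regions x 2 bands) at a
combined threshold of P < .05.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.covariance import MinCovDet

from .scores import OVERALL, TOPICS

__all__ = [
    "mcd_outliers",
    "pearson_r",
    "bh_adjust",
    "correlation_grid",
    "min_detectable_r",
    "GRID_SCORES",
    "GRID_REGIONS",
    "GRID_BANDS",
]


class StatsError(ValueError):
    """Raised on degenerate inference inputs."""


GRID_SCORES: tuple[str, ...] = TOPICS + (OVERALL,)
GRID_REGIONS: tuple[str, ...] = ("anterior", "central", "posterior")
GRID_BANDS: tuple[str, ...] = ("all", "alpha")

DEFAULT_MCD_SUPPORT = 0.75
DEFAULT_MCD_ALPHA = 0.001
DEFAULT_BH_ALPHA = 0.05


def mcd_outliers(
    points: np.ndarray,
    support: float = DEFAULT_MCD_SUPPORT,
    alpha: float = DEFAULT_MCD_ALPHA,
    seed: int | None = 0,
) -> np.ndarray:
    """Boolean outlier flags from a FastMCD robust covariance fit.

    The MCD scatter is estimated on the best-determinant subset of
    ``ceil(support * n)`` points; a point is an outlier when its robust
    squared Mahalanobis distance exceeds ``chi2.ppf(1 - alpha, df=2)``
    (about 13.816 at alpha = .001).
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise StatsError("points must be an n x 2 matrix")
    n = x.shape[0]
    if n < 10:
        raise StatsError(f"need at least 10 points for MCD (got {n})")
    if not np.isfinite(x).all():
        raise StatsError("points must be finite")
    if np.linalg.matrix_rank(np.cov(x, rowvar=False)) < 2:
        raise StatsError("rank-deficient scatter: MCD undefined")

    h = int(np.ceil(support * n))
    mcd = MinCovDet(
        support_fraction=h / n, random_state=np.random.RandomState(seed)
    ).fit(x)
    d2 = mcd.mahalanobis(x)
    cutoff = sp_stats.chi2.ppf(1 - alpha, df=2)
    return d2 > cutoff


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with the two-sided exact-t p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsError("need at least 3 matched observations")
    if x.std() == 0 or y.std() == 0:
        raise StatsError("zero variance: correlation undefined")
    res = sp_stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adj(i) = min_{j >= i} p(j) * m / j`` over the sorted p-values, capped
    at 1. ``m`` defaults to the number of p-values but may be larger when
    undefined cases still count toward the family (NaNs are passed through
    and do not consume a rank).
    """
    p = np.asarray(p_values, dtype=float)
    defined = ~np.isnan(p)
    if ((p[defined] < 0) | (p[defined] > 1)).any():
        raise StatsError("p-values must lie in [0, 1]")
    m_total = m if m is not None else int(defined.sum())
    if m_total < int(defined.sum()):
        raise StatsError("family size m smaller than the number of p-values")
    out = np.full_like(p, np.nan)
    pd_ = p[defined]
    order = np.argsort(pd_, kind="stable")
    ranked = pd_[order] * m_total / np.arange(1, len(pd_) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty_like(pd_)
    vals[order] = np.minimum(adjusted, 1.0)
    out[defined] = vals
    return out


def correlation_grid(
    ti_df: pd.DataFrame,
    score_df: pd.DataFrame,
    level: str = "group",
    mcd_support: float = DEFAULT_MCD_SUPPORT,
    mcd_alpha: float = DEFAULT_MCD_ALPHA,
    bh_alpha: float = DEFAULT_BH_ALPHA,
    seed: int | None = 0,
) -> pd.DataFrame:
    """The full 6-score x 3-region x 2-band correlation grid (36 cases).

    Parameters
    ----------
    ti_df : DataFrame
        Group level: columns ``session, region, band, group_ti``.
        Individual level: columns ``session, profession, region, band,
        student_ti``.
    score_df : DataFrame
        Group level: columns ``session, scaled_<score>...`` (from group
        scores per topic). Individual level: ``session, profession,
        scaled_<score>...``.
    level : str
        ``"group"`` or ``"individual"``; sets the merge keys and the TI
        value column.

    Returns
    -------
    DataFrame
        Exactly 36 rows with n_total, n_after_outliers, r, p_raw, p_adjusted
        and the significance flag; cases that cannot be computed (too few
        points, zero variance, rank deficiency) are reported undefined (NaN)
        but still count toward the BH family of 36.
    """
    if level == "group":
        keys, value_col = ["session"], "group_ti"
    elif level == "individual":
        keys, value_col = ["session", "profession"], "student_ti"
    else:
        raise StatsError(f"unknown level {level!r}")

    rows = []
    for score in GRID_SCORES:
        score_col = f"scaled_{score}"
        if score_col not in score_df.columns:
            raise StatsError(f"score table lacks column {score_col!r}")
        for region in GRID_REGIONS:
            for band in GRID_BANDS:
                ti_case = ti_df[(ti_df["region"] == region) & (ti_df["band"] == band)]
                merged = ti_case.merge(score_df[keys + [score_col]], on=keys)
                merged = merged.dropna(subset=[value_col, score_col])
                pts = merged[[value_col, score_col]].to_numpy(float)
                n_total = pts.shape[0]
                rec = {
                    "level": level,
                    "score": score,
                    "region": region,
                    "band": band,
                    "n_total": n_total,
                    "n_after_outliers": np.nan,
                    "r": np.nan,
                    "p_raw": np.nan,
                }
                try:
                    flags = mcd_outliers(pts, mcd_support, mcd_alpha, seed=seed)
                    kept = pts[~flags]
                    rec["n_after_outliers"] = kept.shape[0]
                    r, p = pearson_r(kept[:, 0], kept[:, 1])
                    rec["r"], rec["p_raw"] = r, p
                except StatsError:
                    pass
                rows.append(rec)

    grid = pd.DataFrame(rows)
    grid["p_adjusted"] = bh_adjust(grid["p_raw"].to_numpy(), m=len(grid))
    grid["significant"] = grid["p_adjusted"] < bh_alpha
    grid["significant"] = grid["significant"].fillna(False)
    return grid


def min_detectable_r(
    n: int, power: float = 0.8, alpha: float = 0.05
) -> float:
    """Smallest correlation detectable with the given power at two-sided
    ``alpha``, under the Fisher-z approximation:

        r = tanh( (z_{1-alpha/2} + z_{power}) / sqrt(n - 3) )

    At n = 30 sessions, power 0.8 and alpha .05 this gives 0.49.
    """
    if n <= 3:
        raise StatsError("need more than 3 observations")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise StatsError("alpha and power must lie in (0, 1)")
    z = sp_stats.norm.ppf(1 - alpha / 2) + sp_stats.norm.ppf(power)
    return float(np.tanh(z / np.sqrt(n - 3)))
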