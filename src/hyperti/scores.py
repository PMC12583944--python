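"""TeamSTEPPS score preprocessing and interrater reliability.

Each of the six simulated professions is rated by two trained raters on five
teamwork topics (team structure, communication, leadership, situation
monitoring, mutual support), each topic on its own Likert-sum range which
varies by profession. Preprocessing averages the two raters, min-max scales
each topic to [0, 1] against its declared range, forms an overall score by
summing the five raw topic scores and scaling against the overall range
(the sum of the topic ranges), and finally averages the six professions'
scaled overall scores into a group score per session.

Interrater reliability is quantified with ICC(2,1): the intraclass
correlation from a two-way random-effects ANOVA (both raters and
participants treated as random samples), single-rater type, absolute
agreement definition.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TOPICS",
    "OVERALL",
    "PROFESSIONS",
    "DEFAULT_RANGES",
    "scale_scores",
    "group_score",
    "icc_2way_random_single_absolute",
    "icc_interpret",
    "icc_report",
    "ICCLabels",
]


class ScoreError(ValueError):
    """Raised on malformed score tables or out-of-range scores."""


TOPICS: tuple[str, ...] = (
    "team structure",
    "communication",
    "leadership",
    "situation monitoring",
    "mutual support",
)
OVERALL = "overall"

#: The six simulated professions of one resuscitation-team session.
PROFESSIONS: tuple[str, ...] = (
    "radiological technologist",
    "medical technologist",
    "medical doctor",
    "pharmacist",
    "circulation nurse",
    "airway nurse",
)


def _ranges(rows: Sequence[tuple[int, int]]) -> dict[str, tuple[int, int]]:
    d = dict(zip(TOPICS, rows))
    d[OVERALL] = (sum(lo for lo, _ in rows), sum(hi for _, hi in rows))
    return d


#: Instrument metadata: per-profession (min, max) of each topic's Likert sum,
#: plus the implied overall range. Item counts differ between professions,
#: hence the differing ranges.
DEFAULT_RANGES: dict[str, dict[str, tuple[int, int]]] = {
    "radiological technologist": _ranges([(2, 10), (4, 20), (5, 25), (5, 25), (4, 20)]),
    "medical technologist": _ranges([(2, 10), (4, 20), (5, 25), (4, 20), (3, 15)]),
    "medical doctor": _ranges([(4, 20), (4, 20), (6, 30), (5, 25), (4, 20)]),
    "pharmacist": _ranges([(2, 10), (4, 20), (5, 25), (2, 10), (4, 20)]),
    "circulation nurse": _ranges([(3, 15), (4, 20), (5, 25), (5, 25), (4, 20)]),
    "airway nurse": _ranges([(3, 15), (4, 20), (5, 25), (5, 25), (4, 20)]),
}


def _range_for(
    ranges: Mapping[str, Mapping[str, tuple[float, float]]],
    profession: str,
    topic: str,
) -> tuple[float, float]:
    try:
        return ranges[profession][topic]
    except KeyError:
        raise ScoreError(f"no range declared for ({profession!r}, {topic!r})") from None


def scale_scores(
    table: pd.DataFrame,
    ranges: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
) -> pd.DataFrame:
    """Rater-average and min-max scale topic and overall scores.

    Parameters
    ----------
    table : DataFrame
        Long format with columns ``session, profession, rater, topic, score``;
        exactly two raters per (session, profession, topic).

    Returns
    -------
    DataFrame
        One row per (session, profession) with columns ``scaled_<topic>`` for
        the five topics and ``scaled_overall``. Scaled values satisfy
        ``scaled = (rater mean - min) / (max - min)`` and lie in [0, 1]; the
        overall score is the sum of the five raw topic scores scaled against
        the overall range (sum of topic mins / maxes), not the mean of the
        scaled topics.
    """
    ranges = ranges or DEFAULT_RANGES
    required = {"session", "profession", "rater", "topic", "score"}
    missing = required - set(table.columns)
    if missing:
        raise ScoreError(f"score table missing column(s) {sorted(missing)}")

    for row in table.itertuples(index=False):
        lo, hi = _range_for(ranges, row.profession, row.topic)
        if not lo <= row.score <= hi:
            raise ScoreError(
                f"score {row.score} outside range [{lo}, {hi}] for "
                f"session={row.session!r} profession={row.profession!r} "
                f"topic={row.topic!r} rater={row.rater!r}"
            )

    counts = table.groupby(["session", "profession", "topic"])["rater"].nunique()
    if (counts != 2).any():
        bad = counts[counts != 2].index[0]
        raise ScoreError(f"expected exactly 2 raters for {bad}")

    mean_scores = (
        table.groupby(["session", "profession", "topic"])["score"].mean().unstack()
    )
    out_rows = []
    for (session, profession), row in mean_scores.iterrows():
        rec: dict[str, object] = {"session": session, "profession": profession}
        raw_sum = 0.0
        for topic in TOPICS:
            lo, hi = _range_for(ranges, profession, topic)
            rec[f"scaled_{topic}"] = (row[topic] - lo) / (hi - lo)
            raw_sum += row[topic]
        lo, hi = _range_for(ranges, profession, OVERALL)
        rec["scaled_overall"] = (raw_sum - lo) / (hi - lo)
        out_rows.append(rec)
    return pd.DataFrame(out_rows)


def group_score(
    scaled: pd.DataFrame, roster: Sequence[str] = PROFESSIONS
) -> pd.DataFrame:
    """Session-level group score: mean of the rostered professions' scaled
    overall scores; undefined (NaN, ``complete=False``) when any is missing."""
    rows = []
    for session, sub in scaled.groupby("session"):
        present = sub.set_index("profession")["scaled_overall"]
        complete = all(p in present.index and np.isfinite(present[p]) for p in roster)
        value = float(present.reindex(roster).mean()) if complete else float("nan")
        rows.append({"session": session, "group_score": value, "complete": complete})
    return pd.DataFrame(rows)


def icc_2way_random_single_absolute(matrix: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, single rater, absolute agreement.

    From the two-way ANOVA mean squares of an n x k matrix (subjects x raters):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    where MSR, MSC and MSE are the between-subject, between-rater and
    residual mean squares.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ScoreError("score matrix must be 2-D (subjects x raters)")
    n, k = m.shape
    if n < 3:
        raise ScoreError("need at least 3 subjects for ICC")
    if k != 2:
        raise ScoreError("this analysis assumes exactly 2 raters")
    if not np.isfinite(m).all():
        raise ScoreError("ICC requires complete (finite) cells")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((m - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    if np.var(row_means) == 0:
        warnings.warn(
            "zero between-subject variance: ICC is uninformative", stacklevel=2
        )
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return 0.0
    return float((msr - mse) / denom)


class ICCLabels(NamedTuple):
    cicchetti: str
    koo_li: str


def icc_interpret(value: float) -> ICCLabels:
    """Qualitative reliability labels for an ICC value.

    Cicchetti bands: excellent 0.75-1.00, good 0.60-0.74, fair 0.40-0.59,
    poor <0.40 (band edges inclusive at the lower bound, so 0.75 is
    excellent). Koo-Li bands: <0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good,
    >0.9 excellent.
    """
    if value > 1:
        raise ScoreError("ICC cannot exceed 1")
    if value >= 0.75:
        cic = "excellent"
    elif value >= 0.60:
        cic = "good"
    elif value >= 0.40:
        cic = "fair"
    else:
        cic = "poor"
    if value >= 0.9:
        koo = "excellent"
    elif value >= 0.75:
        koo = "good"
    elif value >= 0.5:
        koo = "moderate"
    else:
        koo = "poor"
    return ICCLabels(cicchetti=cic, koo_li=koo)


def icc_report(
    table: pd.DataFrame,
    topics: Iterable[str] = TOPICS + (OVERALL,),
) -> pd.DataFrame:
    """Per (profession, topic) interrater ICC(2,1) with qualitative labels.

    For ``overall`` the per-rater overall score (sum of the five topics) is
    formed first. Sessions missing either rater for a topic are dropped.
    """
    pivot = table.pivot_table(
        index=["session", "profession"], columns=["topic", "rater"], values="score"
    )
    rows = []
    for topic in topics:
        for profession in table["profession"].unique():
            try:
                sub = pivot.xs(profession, level="profession")
            except KeyError:
                continue
            if topic == OVERALL:
                per_rater = {}
                for rater in (1, 2):
                    cols = [(t, rater) for t in TOPICS if (t, rater) in sub.columns]
                    if len(cols) != len(TOPICS):
                        continue
                    per_rater[rater] = sub[cols].sum(axis=1, min_count=len(TOPICS))
                if len(per_rater) != 2:
                    continue
                m = pd.concat(per_rater, axis=1).dropna().to_numpy()
            else:
                cols = [(topic, r) for r in (1, 2) if (topic, r) in sub.columns]
                if len(cols) != 2:
                    continue
                m = sub[cols].dropna().to_numpy()
            if m.shape[0] < 3:
                continue
            icc = icc_2way_random_single_absolute(m)
            labels = icc_interpret(min(icc, 1.0))
            rows.append(
                {
                    "profession": profession,
                    "topic": topic,
                    "n": m.shape[0],
                    "icc": icc,
                    "cicchetti": labels.cicchetti,
                    "koo_li": labels.koo_li,
                }
            )
    return pd.DataFrame(rows)
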