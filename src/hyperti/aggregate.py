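"""Aggregation of normalized TI from pair x communication level upward.

The hierarchy mirrors the study design: a pair-level TI exists per
(communication, subject pair, region, band); a subject's communication TI is
the mean over the valid pairs that include the subject; the student TI is
the mean of those over the subject's valid communications; the group TI is
the mean of the six student TIs and is defined only when all six are present
("complete" sessions). All means are unweighted.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_K_MIN",
    "student_communication_ti",
    "student_ti",
    "group_ti",
    "student_table",
    "group_table",
]

#: Minimum commonly clean epochs for a pair-communication TI to count as
#: valid; below this the coherence estimate is dominated by its 1/K bias.
DEFAULT_K_MIN = 10


def student_communication_ti(
    pair_tis: Iterable[tuple[tuple[str, str], float]], subject: str
) -> float:
    """Mean z over the valid pairs of one communication that include
    ``subject``; NaN when the subject appears in no valid pair."""
    vals = [z for (a, b), z in pair_tis if subject in (a, b)]
    return float(np.mean(vals)) if vals else math.nan


def student_ti(comm_values: Iterable[float]) -> float:
    """Unweighted mean over a subject's defined communication TIs."""
    vals = [v for v in comm_values if not math.isnan(v)]
    return float(np.mean(vals)) if vals else math.nan


def group_ti(student_tis: Sequence[float], roster_size: int = 6) -> tuple[float, bool]:
    """Mean of the student TIs; undefined unless all ``roster_size`` present."""
    vals = [v for v in student_tis if not math.isnan(v)]
    complete = len(vals) == roster_size
    return (float(np.mean(vals)) if complete else math.nan), complete


def student_table(
    pair_table: pd.DataFrame,
    subjects: Sequence[str],
    k_min: int = DEFAULT_K_MIN,
) -> pd.DataFrame:
    """Student-level TI from the tidy pair-level table.

    ``pair_table`` columns: session, comm_id, subject_a, subject_b, region,
    band, K, z (one row per pair-communication-region-band). Rows with
    ``K < k_min`` are invalid and ignored.

    Returns one row per (session, subject, region, band) with the student TI
    and the number of communications that contributed.
    """
    valid = pair_table[pair_table["K"] >= k_min]
    rows = []
    for (session, region, band), sub in valid.groupby(["session", "region", "band"]):
        for subject in subjects:
            comm_vals = []
            for _, comm in sub.groupby("comm_id"):
                pairs = [
                    ((r.subject_a, r.subject_b), r.z)
                    for r in comm.itertuples(index=False)
                ]
                comm_vals.append(student_communication_ti(pairs, subject))
            value = student_ti(comm_vals)
            n_comms = sum(0 if math.isnan(v) else 1 for v in comm_vals)
            if n_comms:
                rows.append(
                    {
                        "session": session,
                        "subject": subject,
                        "region": region,
                        "band": band,
                        "student_ti": value,
                        "n_communications": n_comms,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "session", "subject", "region", "band", "student_ti", "n_communications",
        ],
    )


def group_table(
    student_df: pd.DataFrame, subjects: Sequence[str]
) -> pd.DataFrame:
    """Group-level TI per (session, region, band); complete sessions only
    carry a value, incomplete ones carry NaN with ``complete=False``."""
    rows = []
    for (session, region, band), sub in student_df.groupby(
        ["session", "region", "band"]
    ):
        present = sub.set_index("subject")["student_ti"]
        vals = [
            float(present[s]) if s in present.index else math.nan for s in subjects
        ]
        value, complete = group_ti(vals, roster_size=len(subjects))
        rows.append(
            {
                "session": session,
                "region": region,
                "band": band,
                "group_ti": value,
                "complete": complete,
            }
        )
    return pd.DataFrame(
        rows, columns=["session", "region", "band", "group_ti", "complete"]
    )
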