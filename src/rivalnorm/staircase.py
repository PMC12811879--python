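"""Staircase-ordering evaluation, exact binomial tests, and dominance summaries.

The background-context prediction is ordinal: for the green percept the
dominance proportion should rise strictly from green to neutral to red
background, and fall in the mirrored order for the red percept.  Among the
six possible strict orderings of three distinct proportions exactly one
matches, so under the null each staircase succeeds with probability 1/6,
and k successes out of n staircases are scored with an exact one-tailed
binomial tail.  A per-observer variant requires both of an observer's
staircases to match (null probability 1/36).

Dominance summaries follow the button-press protocol: the proportion of a
trial's measured window occupied by each percept, with time not covered by
any report (withheld presses) assigned to no percept, and the SEM computed
over repeat (day) means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ObserverStaircase",
    "StaircaseTestResult",
    "ReportDataError",
    "staircase_success",
    "binomial_tail",
    "binomial_test_result",
    "dominance_summary",
    "trace_to_records",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = ["observer", "day", "trial", "percept", "onset_s", "offset_s"]

#: chance probability that one staircase matches the predicted strict ordering
CHANCE_SINGLE = 1.0 / 6.0
#: chance that both of an observer's staircases match
CHANCE_BOTH = 1.0 / 36.0


class ReportDataError(ValueError):
    """Malformed observer report records (e.g. overlapping intervals)."""


@dataclass(frozen=True)
class ObserverStaircase:
    """Dominance proportions of one percept color across the three backgrounds."""

    percept: str  # "green" | "red"
    green_background: float
    neutral_background: float
    red_background: float

    def __post_init__(self) -> None:
        for v in (self.green_background, self.neutral_background, self.red_background):
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"proportions must be finite and in [0, 1], got {v}")
        if self.percept not in ("green", "red"):
            raise ValueError(f"percept must be 'green' or 'red', got {self.percept!r}")


@dataclass(frozen=True)
class StaircaseTestResult:
    successes: int
    trials: int
    null_probability: float
    p_value: float


def staircase_success(s: ObserverStaircase) -> bool:
    """Whether the strict predicted ordering holds; ties count as failures.

    Green percept: green background < neutral < red background.
    Red percept: red background < neutral < green background.
    """
    if s.percept == "green":
        return s.green_background < s.neutral_background < s.red_background
    return s.red_background < s.neutral_background < s.green_background


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Exact upper-tail probability P(X >= k) for X ~ Binomial(n, p0)."""
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("k and n must be integers")
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"require 0 < p0 < 1, got {p0}")
    return float(stats.binom.sf(k - 1, n, p0))


def binomial_test_result(k: int, n: int, p0: float = CHANCE_SINGLE) -> StaircaseTestResult:
    """One-tailed (directional) exact binomial test on k successes out of n."""
    return StaircaseTestResult(
        successes=int(k), trials=int(n), null_probability=p0, p_value=binomial_tail(k, n, p0)
    )


def trace_to_records(
    trace, observer: str = "sim", day: int = 1, trial: int = 1
) -> pd.DataFrame:
    """Convert a simulator percept trace into the report-record dialect."""
    rows = []
    sel = trace.times >= trace.condition.settle_duration
    times = trace.times[sel] - trace.condition.settle_duration
    labels = trace.dominant[sel]
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            rows.append(
                {
                    "observer": observer,
                    "day": day,
                    "trial": trial,
                    "percept": labels[start],
                    "onset_s": float(times[start]),
                    "offset_s": float(times[i - 1] + trace.dt),
                }
            )
            start = i
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def _check_no_overlap(group: pd.DataFrame) -> None:
    g = group.sort_values("onset_s")
    onsets = g["onset_s"].to_numpy()
    offsets = g["offset_s"].to_numpy()
    if np.any(offsets < onsets):
        raise ReportDataError("interval with offset before onset")
    if np.any(onsets[1:] < offsets[:-1] - 1e-9):
        raise ReportDataError(
            f"overlapping report intervals for observer {g['observer'].iloc[0]!r}"
        )


def dominance_summary(
    records: pd.DataFrame,
    window_s: float = 60.0,
    by: str = "day",
) -> pd.DataFrame:
    """Per-percept dominance proportions with dispersion over repeats.

    ``records`` uses the report dialect (observer, day, trial, percept,
    onset_s, offset_s); intervals within one (observer, day, trial) must not
    overlap.  The proportion for a percept is its summed report duration
    divided by the total measured time (trials x window_s); unreported time
    belongs to no percept.  The SEM is computed across the repeat (``by``,
    default day) means; with a single repeat it is reported as NaN.
    """
    missing = [c for c in REPORT_COLUMNS if c not in records.columns]
    if missing:
        raise ReportDataError(f"report records missing columns {missing}")
    if len(records) == 0:
        return pd.DataFrame(columns=["observer", "percept", "proportion", "sem", "n_repeats"])
    for _, group in records.groupby(["observer", "day", "trial"]):
        _check_no_overlap(group)

    rec = records.copy()
    rec["duration"] = rec["offset_s"] - rec["onset_s"]
    rows = []
    for obs, obs_rec in rec.groupby("observer"):
        percepts = sorted(obs_rec["percept"].unique())
        repeat_props: Dict[str, list] = {p: [] for p in percepts}
        for _, rep_rec in obs_rec.groupby(by):
            n_trials = rep_rec[["day", "trial"]].drop_duplicates().shape[0]
            total_time = n_trials * window_s
            summed = rep_rec.groupby("percept")["duration"].sum()
            for p in percepts:
                repeat_props[p].append(float(summed.get(p, 0.0)) / total_time)
        for p in percepts:
            vals = np.asarray(repeat_props[p])
            sem = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            )
            rows.append(
                {
                    "observer": obs,
                    "percept": p,
                    "proportion": float(vals.mean()),
                    "sem": sem,
                    "n_repeats": len(vals),
                }
            )
    return pd.DataFrame(rows)
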