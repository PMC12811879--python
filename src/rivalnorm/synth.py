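"""Synthetic observer report streams for exercising the statistics stage.

These generators are not a model of human observers.  They emit the same
report dialect the statistics module consumes, with controlled long-run
dominance structure: gamma-distributed dominance durations (shape ~3, the
standard empirical description of rivalry dominance-duration histograms),
percept labels drawn to hit target proportions, and an optional unreported
(piecemeal/withheld-press) fraction carved out between reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .staircase import REPORT_COLUMNS, ObserverStaircase

__all__ = [
    "SyntheticObserverParams",
    "generate_report_stream",
    "make_staircase_observer",
]


@dataclass(frozen=True)
class SyntheticObserverParams:
    """Targets and shapes for one synthetic observer's report stream."""

    target_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"green": 0.5, "red": 0.5}
    )
    mean_duration_s: float = 2.0
    gamma_shape: float = 3.0
    unreported_fraction: float = 0.0
    trial_length_s: float = 60.0
    n_days: int = 3
    trials_per_day: int = 1
    observer: str = "synth"
    seed: int = 0

    def __post_init__(self) -> None:
        props = dict(self.target_proportions)
        if not props or any(v < 0 for v in props.values()):
            raise ValueError("target proportions must be nonnegative and nonempty")
        total = sum(props.values()) + self.unreported_fraction
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(
                f"proportions plus unreported fraction must sum to 1, got {total}"
            )
        if self.mean_duration_s <= 0 or self.trial_length_s <= 0:
            raise ValueError("durations must be > 0")
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be > 0")


def generate_report_stream(params: SyntheticObserverParams) -> pd.DataFrame:
    """Generate report records (observer, day, trial, percept, onset, offset).

    Within each trial, labeled intervals with i.i.d. gamma durations are
    laid down until the trial ends; labels are i.i.d. draws from the
    normalized target proportions, and when an unreported fraction is
    requested, gamma-distributed gaps are interleaved so the expected gap
    share equals that fraction.  The same seed reproduces the records
    byte-for-byte.
    """
    rng = np.random.default_rng(params.seed)
    labels = sorted(params.target_proportions)
    reported_total = sum(params.target_proportions.values())
    probs = np.array([params.target_proportions[l] / reported_total for l in labels])
    scale = params.mean_duration_s / params.gamma_shape
    u = params.unreported_fraction
    gap_scale = None
    if u > 0:
        gap_mean = params.mean_duration_s * u / (1.0 - u)
        gap_scale = gap_mean / params.gamma_shape

    rows = []
    for day in range(1, params.n_days + 1):
        for trial in range(1, params.trials_per_day + 1):
            t = 0.0
            while t < params.trial_length_s:
                lab = labels[int(rng.choice(len(labels), p=probs))]
                dur = float(rng.gamma(params.gamma_shape, scale))
                end = min(t + dur, params.trial_length_s)
                if end > t:
                    prev = rows[-1] if rows else None
                    if (
                        prev is not None
                        and prev["day"] == day
                        and prev["trial"] == trial
                        and prev["percept"] == lab
                        and np.isclose(prev["offset_s"], t)
                    ):
                        prev["offset_s"] = end  # merge adjacent same-label reports
                    else:
                        rows.append(
                            {
                                "observer": params.observer,
                                "day": day,
                                "trial": trial,
                                "percept": lab,
                                "onset_s": t,
                                "offset_s": end,
                            }
                        )
                t = end
                if gap_scale is not None and t < params.trial_length_s:
                    t += float(rng.gamma(params.gamma_shape, gap_scale))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def make_staircase_observer(
    effect_size: float,
    noise_level: float = 0.08,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, ObserverStaircase]:
    """Draw one observer's two staircases around a monotone pattern.

    The green percept's proportions center on (0.5 - e, 0.5, 0.5 + e) across
    green/neutral/red backgrounds and the red percept mirrors them; i.i.d.
    normal jitter of SD ``noise_level`` is added to each cell.  At effect
    size 0 the three cells of a staircase are exchangeable, so the predicted
    strict ordering holds with probability exactly 1/6 (the test's null).
    """
    if effect_size < 0:
        raise ValueError("effect size must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    e = effect_size

    def triplet(center: Tuple[float, float, float]) -> Tuple[float, float, float]:
        vals = np.asarray(center) + rng.normal(0.0, noise_level, size=3)
        return tuple(float(np.clip(v, 0.0, 1.0)) for v in vals)

    g = triplet((0.5 - e, 0.5, 0.5 + e))
    r = triplet((0.5 + e, 0.5, 0.5 - e))
    return {
        "green": ObserverStaircase("green", *g),
        "red": ObserverStaircase("red", *r),
    }
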