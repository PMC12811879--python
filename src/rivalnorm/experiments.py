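"""Simulation campaigns for the two background-context experiments.

Experiment 1: red/green patchwork disks on a stable green, gray, or red
background.  The background-matching channel is attenuated by the shared
normalization pool, producing the staircase prediction: the green percept is
rarest on a green background, intermediate on gray, and most frequent on a
red background (mirrored for red percepts).

Experiment 2: the same disks on dichoptically rivalrous backgrounds (one eye
green, one eye red).  Each whole-field color hypothesis pools one background
plus one disk per eye, so the two drives are equal and the only reachable
percepts are the two similarity-enhanced (uniform) ones; difference-enhanced
percepts are structurally impossible.

A campaign seed deterministically spawns one child seed per condition and
per trial, so campaigns with different seeds are independent and campaigns
with the same seed are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import ModelParams, PerceptTrace, run_trial
from .normalization import NoiseParams
from .stimulus import ConditionSpec

__all__ = [
    "exp1_condition",
    "exp2_condition",
    "run_campaign",
    "run_experiment1",
    "run_experiment2",
    "sensitivity_sweep",
    "EXP1_BACKGROUNDS",
]

EXP1_BACKGROUNDS = ("green", "gray", "red")
PERCEPTS = ("green", "red")

SUMMARY_COLUMNS = [
    "condition",
    "background",
    "percept",
    "mean_proportion",
    "sd",
    "n_runs",
    "seed",
]

SWEEP_COLUMNS = [
    "parameter",
    "value",
    "condition",
    "percept",
    "mean_proportion",
    "mean_dominance_duration_s",
    "switch_rate_hz",
    "n_runs",
]


def exp1_condition(background: str) -> ConditionSpec:
    """Stable-background condition with default patchwork disks."""
    return ConditionSpec(experiment="exp1", background=background)


def exp2_condition() -> ConditionSpec:
    """Symmetric-pool condition: rivalrous backgrounds, patchwork disks."""
    return ConditionSpec(experiment="exp2", background="rivalrous")


def run_campaign(
    condition: ConditionSpec,
    params: ModelParams,
    n_runs: int,
    seed_seq: np.random.SeedSequence,
) -> Dict[str, object]:
    """Run ``n_runs`` independent trials of one condition.

    Returns per-trial dominance proportions, mean dominance durations, and
    switch rates.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    props: Dict[str, List[float]] = {lab: [] for lab in PERCEPTS}
    durations: Dict[str, List[float]] = {lab: [] for lab in PERCEPTS}
    rates: List[float] = []
    for child in seed_seq.spawn(n_runs):
        try:
            trace = run_trial(condition, params, rng=np.random.default_rng(child))
        except Exception as exc:  # propagate with condition context
            raise RuntimeError(
                f"trial failed for condition {condition.background!r}: {exc}"
            ) from exc
        p = trace.dominance_proportions()
        d = trace.dominance_durations()
        for lab in PERCEPTS:
            props[lab].append(p.get(lab, 0.0))
            durations[lab].extend(d.get(lab, []))
        rates.append(trace.switch_rate())
    return {"proportions": props, "durations": durations, "switch_rates": rates}


def run_experiment1(
    params: ModelParams = ModelParams(),
    n_runs: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the three stable-background conditions.

    Returns a summary table with one row per (background, percept): the mean
    proportion of measured time the percept was dominant, its SD across
    runs, n_runs, and the campaign seed.
    """
    root = np.random.SeedSequence(seed)
    rows = []
    for bg, child in zip(EXP1_BACKGROUNDS, root.spawn(len(EXP1_BACKGROUNDS))):
        res = run_campaign(exp1_condition(bg), params, n_runs, child)
        for lab in PERCEPTS:
            arr = np.asarray(res["proportions"][lab])
            rows.append(
                {
                    "condition": f"exp1-{bg}",
                    "background": bg,
                    "percept": lab,
                    "mean_proportion": float(arr.mean()),
                    "sd": float(arr.std(ddof=1)) if n_runs > 1 else 0.0,
                    "n_runs": n_runs,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def run_experiment2(
    params: ModelParams = ModelParams(),
    n_runs: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the symmetric-pool condition.

    The dominant channel at each sample is the whole-field color hypothesis,
    so a green-dominant sample is the uniform all-green (similarity) percept.
    Difference-enhanced rows are included with proportion exactly 0: they are
    unreachable because both hypotheses share the same pooled normalization.
    """
    root = np.random.SeedSequence(seed)
    res = run_campaign(exp2_condition(), params, n_runs, root.spawn(1)[0])
    rows = []
    for lab in PERCEPTS:
        arr = np.asarray(res["proportions"][lab])
        rows.append(
            {
                "condition": "exp2-rivalrous",
                "background": "rivalrous",
                "percept": f"similarity_{lab}",
                "mean_proportion": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if n_runs > 1 else 0.0,
                "n_runs": n_runs,
                "seed": seed,
            }
        )
    for lab in PERCEPTS:
        rows.append(
            {
                "condition": "exp2-rivalrous",
                "background": "rivalrous",
                "percept": f"difference_{lab}",
                "mean_proportion": 0.0,
                "sd": 0.0,
                "n_runs": n_runs,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def _with_parameter(base: ModelParams, name: str, value: float) -> ModelParams:
    if name == "noise_bound":
        if value <= 0:
            raise ValueError("noise_bound must be > 0")
        return replace(base, noise=replace(base.noise, lower=-value, upper=value))
    if name == "gain":
        return replace(base, dynamics=replace(base.dynamics, gain=value))
    if name == "gain_bias":
        return replace(base, dynamics=replace(base.dynamics, gain_bias=value))
    if name == "tau_d":
        return replace(base, dynamics=replace(base.dynamics, tau_d=value))
    if name == "tau_r":
        return replace(base, dynamics=replace(base.dynamics, tau_r=value))
    raise ValueError(f"unknown sweep parameter {name!r}")


def sensitivity_sweep(
    grid: Mapping[str, Sequence[float]],
    base: ModelParams = ModelParams(),
    n_runs: int = 20,
    seed: int = 0,
    backgrounds: Iterable[str] = EXP1_BACKGROUNDS,
) -> pd.DataFrame:
    """Sweep model parameters over a grid, one parameter at a time.

    For each grid value and each stable-background condition, reports the
    per-percept mean proportion and mean dominance duration, and the
    condition's mean switch rate.
    """
    backgrounds = tuple(backgrounds)
    rows = []
    for pi, (name, values) in enumerate(grid.items()):
        for vi, value in enumerate(values):
            params = _with_parameter(base, name, value)
            # one deterministic sub-seed per (parameter, value, background)
            for bi, bg in enumerate(backgrounds):
                child = np.random.SeedSequence(
                    entropy=seed, spawn_key=(pi, vi, bi)
                )
                res = run_campaign(exp1_condition(bg), params, n_runs, child)
                rate = float(np.mean(res["switch_rates"]))
                for lab in PERCEPTS:
                    arr = np.asarray(res["proportions"][lab])
                    durs = res["durations"][lab]
                    rows.append(
                        {
                            "parameter": name,
                            "value": value,
                            "condition": f"exp1-{bg}",
                            "percept": lab,
                            "mean_proportion": float(arr.mean()),
                            "mean_dominance_duration_s": float(np.mean(durs)) if durs else np.nan,
                            "switch_rate_hz": rate,
                            "n_runs": n_runs,
                        }
                    )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)
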