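"""Stochastic winner-take-all competition with gain, adaptation, and recovery.

Two normalized chromatic representations compete on a three-clock scheme:

* base grid (1 ms): bookkeeping resolution for traces and durations;
* adaptation clock (10 ms): explicit-Euler decay of the dominant strength
  toward 0 with time constant tau_D, and relaxation of the suppressed
  strength toward its ceiling P_M with time constant tau_R;
* sampling clock (Delta-t = 250 ms, 4 Hz): multiplicative truncated-normal
  noise is resampled per channel, the gain multiplier g is assigned
  stochastically (probability p to the currently dominant percept), and the
  winner-take-all comparison selects the dominant percept for the next
  interval.

On a switch the winning representation is re-driven by the stimulus to its
ceiling P_M and the loser is fully suppressed to 0, from which it recovers;
this makes the zero-noise, p = 1 alternation period the crossing time of
g * exp(-t/tau_D) with 1 - exp(-t/tau_R).  The gain is transient: it biases
the comparison within the current interval but is never compounded into the
stored strengths (compounding 1.3x at 4 Hz would diverge within seconds).
Noise, by contrast, is retained in the stored values, per the recursive
max update.

Because every update is homogeneous of degree 1 in (P, P_M), the dynamics
are invariant to a common rescaling of both drives; only the drive ratio
matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .normalization import NoiseParams, drives as compute_drives
from .stimulus import ConditionSpec, PoolAccounting, channel_sums, render_fields, rivalry_mask

__all__ = [
    "DynamicsParams",
    "ModelParams",
    "ChannelState",
    "PerceptTrace",
    "IntegrationError",
    "apply_gain",
    "wta_compare",
    "adapt_step",
    "recover_step",
    "run_trial",
]


class IntegrationError(RuntimeError):
    """Non-finite state encountered during a trial."""


@dataclass(frozen=True)
class DynamicsParams:
    """Clocks, gain, and time constants of the competition stage.

    dt: sampling interval for noise/gain/WTA, seconds (0.25 -> 4 Hz).
    adaptation_update: Euler step for adaptation/recovery, seconds (0.01).
    base_step: bookkeeping grid, seconds (0.001).
    gain: transient multiplier g applied to one channel per interval.
    gain_bias: probability the gain goes to the currently dominant percept.
    tau_d / tau_r: adaptation and recovery time constants, seconds.
    store_gained: if True, the gain is compounded into the stored dominant
        value (exposed for exploration; diverges at default g and dt).
    """

    gain: float = 1.3
    gain_bias: float = 0.55
    dt: float = 0.25
    adaptation_update: float = 0.01
    base_step: float = 0.001
    tau_d: float = 2.5
    tau_r: float = 1.5
    store_gained: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.base_step <= self.adaptation_update <= self.dt):
            raise ValueError("require base_step <= adaptation_update <= dt, all > 0")
        if self.tau_d <= 0 or self.tau_r <= 0:
            raise ValueError("time constants must be > 0")
        if self.gain < 1:
            raise ValueError("gain must be >= 1")
        if not 0 <= self.gain_bias <= 1:
            raise ValueError("gain_bias must be in [0, 1]")


@dataclass(frozen=True)
class ModelParams:
    """Full model configuration: noise, dynamics, and pool accounting."""

    noise: NoiseParams = field(default_factory=NoiseParams)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    accounting: PoolAccounting = field(default_factory=PoolAccounting)


@dataclass
class ChannelState:
    """One competing representation: current strength and recovery ceiling."""

    label: str
    P: float
    P_M: float
    role: str  # "dominant" | "suppressed"


@dataclass
class PerceptTrace:
    """Trial record on the sampling (Delta-t) grid.

    The dominant label is constant within each [t, t + dt) interval; the
    first interval starts at t = 0 with the winner of the initial comparison.
    """

    times: np.ndarray
    dominant: np.ndarray  # label per interval
    strengths: Dict[str, np.ndarray]
    condition: ConditionSpec
    params: ModelParams
    seed: Optional[int]
    xi: Optional[Dict[str, np.ndarray]] = None
    gain_target: Optional[np.ndarray] = None

    @property
    def dt(self) -> float:
        return self.params.dynamics.dt

    def _measured(self) -> np.ndarray:
        return self.times >= self.condition.settle_duration

    def dominance_proportions(self) -> Dict[str, float]:
        """Fraction of the measured window each channel was dominant."""
        sel = self._measured()
        n = int(np.sum(sel))
        out = {}
        for lab in self.strengths:
            out[lab] = float(np.sum(self.dominant[sel] == lab)) / n
        return out

    def dominance_durations(self) -> Dict[str, List[float]]:
        """Lengths (s) of maximal same-label runs inside the measured window."""
        sel = self._measured()
        labels = self.dominant[sel]
        out: Dict[str, List[float]] = {lab: [] for lab in self.strengths}
        if len(labels) == 0:
            return out
        run_lab, run_len = labels[0], 1
        for lab in labels[1:]:
            if lab == run_lab:
                run_len += 1
            else:
                out[run_lab].append(run_len * self.dt)
                run_lab, run_len = lab, 1
        out[run_lab].append(run_len * self.dt)
        return out

    def switch_count(self) -> int:
        sel = self._measured()
        labels = self.dominant[sel]
        return int(np.sum(labels[1:] != labels[:-1]))

    def switch_rate(self) -> float:
        """Perceptual switches per second of measured time."""
        sel = self._measured()
        return self.switch_count() / (int(np.sum(sel)) * self.dt)

    def to_frame(self, audit: bool = False) -> pd.DataFrame:
        cols = {"time_s": self.times, "dominant_channel": self.dominant}
        for lab in sorted(self.strengths):
            cols[f"P_{lab}"] = self.strengths[lab]
        if audit and self.xi is not None:
            for lab in sorted(self.xi):
                cols[f"xi_{lab}"] = self.xi[lab]
            cols["gain_target"] = self.gain_target
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# elementary operations


def apply_gain(
    states: Tuple[ChannelState, ChannelState],
    params: DynamicsParams,
    rng: np.random.Generator,
) -> str:
    """Assign the transient gain for the current interval.

    Returns the label of the channel receiving g; the currently dominant
    (stronger) percept receives it with probability ``gain_bias``.
    """
    dom = next(s for s in states if s.role == "dominant")
    sup = next(s for s in states if s.role == "suppressed")
    return dom.label if rng.uniform() < params.gain_bias else sup.label


def wta_compare(
    value_d: float,
    value_s: float,
    incumbent: str,
    labels: Tuple[str, str],
) -> Tuple[str, float]:
    """Winner-take-all comparison of two gain-modulated, noise-perturbed values.

    ``labels`` is (dominant_label, suppressed_label).  Returns the winner and
    the max value; exact ties retain the incumbent.
    """
    if not (np.isfinite(value_d) and np.isfinite(value_s)):
        raise IntegrationError("non-finite comparison value")
    if value_s > value_d:
        return labels[1], value_s
    if value_d > value_s:
        return labels[0], value_d
    return incumbent, value_d


def adapt_step(P: float, dt: float, tau_d: float) -> float:
    """One explicit-Euler adaptation update of the dominant strength."""
    return P - dt * P / tau_d


def recover_step(P: float, P_M: float, dt: float, tau_r: float) -> float:
    """One explicit-Euler recovery update of the suppressed strength toward P_M."""
    return P + dt * (P_M - P) / tau_r


# ---------------------------------------------------------------------------
# trial loop


def _structural_channel_order(condition: ConditionSpec) -> Tuple[str, str]:
    """Channels ordered by stimulus structure (left-eye top disk first).

    Ordering by position rather than label makes a full red/green relabel of
    the stimulus map each channel onto the same draw stream, so mirrored
    conditions produce exactly mirrored trajectories under matched seeds.
    """
    first = condition.disk_assignment[("L", "top")]
    second = next(lab for lab in ("red", "green") if lab != first)
    return first, second


def run_trial(
    condition: ConditionSpec,
    params: ModelParams = ModelParams(),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    audit: bool = False,
) -> PerceptTrace:
    """Simulate one rivalry trial and return its percept trace.

    Both channels start at their normalized drives (P = P_M = drive); the
    initial dominant is chosen by a first noisy comparison, after which the
    loser is suppressed to 0.  Each subsequent interval applies the
    deterministic adaptation/recovery relaxation on the 10 ms clock, then
    noise injection, gain assignment, and the winner-take-all comparison.
    """
    condition.validate()
    if rng is None:
        rng = np.random.default_rng(seed)

    dyn = params.dynamics
    stim = render_fields(condition)
    mask = rivalry_mask(condition.geometry)
    sums = channel_sums(stim, mask, params.accounting)
    drv = compute_drives(sums, params.noise)

    order = _structural_channel_order(condition)
    n_steps = int(round(condition.trial_duration / dyn.dt))
    n_sub = int(round(dyn.dt / dyn.adaptation_update))
    decay = (1.0 - dyn.adaptation_update / dyn.tau_d) ** n_sub
    recov = (1.0 - dyn.adaptation_update / dyn.tau_r) ** n_sub

    # Draw order: xi for the structurally first channel (whole trial), xi for
    # the second channel, then the gain-assignment uniforms.  The initial
    # comparison uses the first xi of each channel's stream.
    xi_streams = {
        lab: np.asarray(params.noise.distribution().rvs(size=n_steps + 1, random_state=rng))
        for lab in order
    }
    uniforms = rng.uniform(size=n_steps)

    P = {lab: drv[lab] for lab in order}
    P_M = dict(P)

    # initial noisy comparison; tie -> structurally first channel
    v0 = {lab: P[lab] * (1.0 + xi_streams[lab][0]) for lab in order}
    if v0[order[1]] > v0[order[0]]:
        dominant = order[1]
    else:
        dominant = order[0]
    suppressed = order[1] if dominant == order[0] else order[0]
    P[dominant] = P_M[dominant]
    P[suppressed] = 0.0

    times = np.arange(n_steps) * dyn.dt
    dom_rec = np.empty(n_steps, dtype=object)
    strengths = {lab: np.empty(n_steps) for lab in order}
    xi_rec = {lab: np.empty(n_steps) for lab in order} if audit else None
    gain_rec = np.empty(n_steps, dtype=object) if audit else None

    for k in range(n_steps):
        # the percept during [t, t+dt) is the incumbent chosen at t
        dom_rec[k] = dominant
        for lab in order:
            strengths[lab][k] = P[lab]

        # adaptation/recovery relaxation over the interval (n_sub Euler steps)
        P[dominant] = P[dominant] * decay
        P[suppressed] = P_M[suppressed] - (P_M[suppressed] - P[suppressed]) * recov

        # noise injection at the sampling clock, retained in the stored values
        xi = {lab: float(xi_streams[lab][k + 1]) for lab in order}
        for lab in order:
            P[lab] = P[lab] * (1.0 + xi[lab])
            if not np.isfinite(P[lab]):
                raise IntegrationError(f"non-finite strength at t={times[k]:.3f}s")

        # transient gain and winner-take-all comparison
        target = dominant if uniforms[k] < dyn.gain_bias else suppressed
        m_dom = P[dominant] * (dyn.gain if target == dominant else 1.0)
        m_sup = P[suppressed] * (dyn.gain if target == suppressed else 1.0)
        winner, value = wta_compare(m_dom, m_sup, dominant, (dominant, suppressed))

        if audit:
            for lab in order:
                xi_rec[lab][k] = xi[lab]
            gain_rec[k] = target

        if winner != dominant:
            # switch: winner re-driven by the stimulus, loser fully suppressed
            dominant, suppressed = winner, dominant
            P[dominant] = P_M[dominant]
            P[suppressed] = 0.0
        elif dyn.store_gained:
            P[dominant] = value

    return PerceptTrace(
        times=times,
        dominant=dom_rec,
        strengths=strengths,
        condition=condition,
        params=params,
        seed=seed,
        xi=xi_rec,
        gain_target=gain_rec,
    )
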