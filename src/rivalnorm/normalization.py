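"""Normalized chromatic drives and signal-proportional truncated-normal noise.

The divisive-normalization stage reduces each chromatic channel to a single
dimensionless multiplier: the channel's signal inside the rivalrous regions
divided by its pooled signal over the whole stimulus (both eyes).  A channel
whose signal lies entirely inside the rivalry mask gets a drive of exactly 1;
a channel that also fills the background is attenuated in proportion to the
background's pool weight.

Noise is multiplicative: eta = S * xi with xi drawn from a standard normal
truncated to [a, b] (default +-0.35).  Sampling uses the renormalized
truncated density (inverse-CDF via scipy), so the post-truncation standard
deviation (~0.2) is exact in distribution rather than an artifact of
rejection or clipping.  The ratio here is deterministic; noise is injected
downstream by the competition dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy import stats

from .stimulus import ChannelSums

__all__ = [
    "NoiseParams",
    "NormalizedDrive",
    "UndefinedChannelError",
    "normalized_drive",
    "drives",
    "sample_noise_multiplier",
    "effective_noise_sd",
    "channel_noise",
]


class UndefinedChannelError(ValueError):
    """Channel absent from the stimulus: its normalization pool is empty."""


@dataclass(frozen=True)
class NoiseParams:
    """Truncated-normal noise multiplier: xi ~ N(0, sigma^2) restricted to [a, b].

    ``semisaturation`` is an optional stabilizing constant added to the
    normalization denominator (the canonical semisaturation term); the model
    proper uses 0, matching the worked example in which a fully masked
    channel has a drive of exactly 1.
    """

    sigma: float = 1.0
    lower: float = -0.35
    upper: float = 0.35
    semisaturation: float = 0.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("noise bounds require lower < upper")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.semisaturation < 0:
            raise ValueError("semisaturation must be >= 0")

    def distribution(self):
        """Frozen scipy distribution of xi."""
        a = self.lower / self.sigma
        b = self.upper / self.sigma
        return stats.truncnorm(a, b, loc=0.0, scale=self.sigma)


@dataclass(frozen=True)
class NormalizedDrive:
    """Per-channel dimensionless multipliers feeding the competition stage."""

    values: Dict[str, float]

    def __getitem__(self, label: str) -> float:
        return self.values[label]


def normalized_drive(
    sums: ChannelSums, channel: str, noise: Optional[NoiseParams] = None
) -> float:
    """Masked-to-total signal ratio for one channel (noise-free).

    Equals 1 exactly when all of the channel's signal lies inside the rivalry
    mask; strictly smaller when the channel also feeds the background pool.
    """
    if channel not in sums.masked:
        raise UndefinedChannelError(f"channel {channel!r} absent from stimulus")
    denom = sums.total[channel]
    if noise is not None:
        denom = denom + noise.semisaturation
    if denom <= 0:
        raise UndefinedChannelError(
            f"channel {channel!r} has empty normalization pool (total sum 0)"
        )
    return sums.masked[channel] / denom


def drives(sums: ChannelSums, noise: Optional[NoiseParams] = None) -> NormalizedDrive:
    """Normalized drives for every channel present in the stimulus."""
    return NormalizedDrive(
        {lab: normalized_drive(sums, lab, noise) for lab in sums.labels()}
    )


def sample_noise_multiplier(
    params: NoiseParams, rng: np.random.Generator, size: Optional[int] = None
):
    """Draw xi from the truncated normal; scalar float when size is None."""
    draws = params.distribution().rvs(size=1 if size is None else size, random_state=rng)
    return float(draws[0]) if size is None else draws


def effective_noise_sd(params: NoiseParams) -> float:
    """Closed-form standard deviation of xi after truncation (~0.200 at defaults)."""
    return float(params.distribution().std())


def channel_noise(signal: float, xi: float) -> float:
    """Signal-proportional perturbation eta = S * xi; zero signal gives zero noise."""
    if signal < 0:
        raise ValueError(f"channel strength must be >= 0, got {signal}")
    return signal * xi
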