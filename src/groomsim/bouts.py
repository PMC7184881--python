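"""Bout-duration models.

The dust model selects which body part is groomed but does not itself model
how long each grooming bout lasts; durations only render the bout sequence
onto the 30 Hz frame axis.  Two samplers are provided: a heavy-tailed
log-normal default with per-behavior medians, and an empirical sampler that
resamples observed bout lengths with replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["BoutDurationModel", "LogNormalBoutModel", "EmpiricalBoutModel"]

# sweeps directed at a body surface vs. leg rubbing movements
_SWEEPS = {"head_sweep", "body_sweep", "wing_sweep"}
_RUBS = {"front_leg_rub", "back_leg_rub"}


class BoutDurationModel:
    """Interface: draw one bout duration (in frames) for a behavior."""

    def sample(self, behavior: str, rng: np.random.Generator, frame_rate_hz: float) -> int:
        raise NotImplementedError


@dataclass
class LogNormalBoutModel(BoutDurationModel):
    """Log-normal bout durations with per-behavior medians (seconds).

    Defaults: median 2 s for sweeps, 1.5 s for leg rubs, log-space shape 0.6.
    Behaviors without an explicit median (walk, stand, other) fall back to
    ``default_median_s``.
    """

    medians_s: dict[str, float] = field(default_factory=dict)
    sigma: float = 0.6
    default_median_s: float = 2.0

    def _median(self, behavior: str) -> float:
        if behavior in self.medians_s:
            return self.medians_s[behavior]
        if behavior in _RUBS:
            return 1.5
        if behavior in _SWEEPS:
            return 2.0
        return self.default_median_s

    def sample(self, behavior: str, rng: np.random.Generator, frame_rate_hz: float) -> int:
        seconds = rng.lognormal(mean=math.log(self._median(behavior)), sigma=self.sigma)
        return max(1, int(round(seconds * frame_rate_hz)))


@dataclass
class EmpiricalBoutModel(BoutDurationModel):
    """Resample observed bout durations (frame counts) with replacement."""

    durations: Mapping[str, Sequence[int]]

    def __post_init__(self) -> None:
        self._arrays = {}
        for behavior, vals in self.durations.items():
            arr = np.asarray(list(vals), dtype=int)
            if arr.size == 0:
                raise ValueError(f"empty duration list for behavior {behavior!r}")
            if (arr < 1).any():
                raise ValueError(f"durations must be >= 1 frame for {behavior!r}")
            self._arrays[behavior] = arr

    def sample(self, behavior: str, rng: np.random.Generator, frame_rate_hz: float) -> int:
        try:
            arr = self._arrays[behavior]
        except KeyError:
            raise KeyError(f"no observed durations for behavior {behavior!r}") from None
        return int(arr[rng.integers(arr.size)])
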